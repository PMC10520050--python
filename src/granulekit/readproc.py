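"""Read collapsing, exact alignment with multi-mapping, and structural filtering.

Small-RNA libraries are collapsed to unique sequences with occurrence counts,
then every perfect (0-mismatch) genomic occurrence of each sequence is
enumerated on both strands. Reads that map to more locations than ``max_hits``
(default 1000) are dropped entirely and tallied. Reads with any alignment
intersecting a structural-RNA annotation (tRNA/snRNA/snoRNA/ncRNA, either
strand) are partitioned out before class calling; this single-pass,
annotation-driven filter yields the same partition as pre-aligning to a
separate structural reference when the structural loci are annotated on the
genome.
"""

from __future__ import annotations

import gzip
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO

from .annotations import FeatureIndex

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class CollapsedRead:
    id: str
    sequence: str
    count: int


@dataclass
class CollapseReport:
    total_reads: int = 0
    dropped_n: int = 0


@dataclass(frozen=True)
class Alignment:
    """One perfect genomic occurrence of a collapsed read.

    ``n_hits`` is the total number of genomic locations for the read and is
    identical across all of its alignments. For a minus-strand alignment the
    reverse complement of the read matches the forward genome at
    ``[start, start + length)``.
    """

    read_id: str
    contig: str
    start: int
    strand: str
    length: int
    n_hits: int

    @property
    def end(self) -> int:
        return self.start + self.length


@dataclass
class AlignReport:
    n_reads: int = 0
    n_unaligned: int = 0
    n_dropped_max_hits: int = 0
    dropped_read_ids: list[str] = field(default_factory=list)


def _open_maybe_gzip(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def _guess_format(path: str | Path) -> str:
    name = Path(path).name.removesuffix(".gz")
    if name.endswith((".fq", ".fastq")):
        return "fastq"
    return "fasta"


def collapse_reads(
    source: str | Path | Iterable[str], fmt: str | None = None
) -> tuple[list[CollapsedRead], CollapseReport]:
    """Collapse raw reads to unique sequences with occurrence counts.

    ``source`` may be a FASTA/FASTQ path (optionally gzipped) or an iterable
    of sequence strings. Sequences containing N are dropped and tallied; any
    other non-ACGT character raises. The sum of counts equals the number of
    retained input reads. Output is ordered by descending count, then
    sequence, with ids ``r<rank>_x<count>``.
    """
    report = CollapseReport()
    counts: Counter[str] = Counter()

    if isinstance(source, (str, Path)):
        fmt = fmt or _guess_format(source)
        with _open_maybe_gzip(source) as fh:
            seqs: Iterable[str] = (str(rec.seq) for rec in SeqIO.parse(fh, fmt))
            _tally(seqs, counts, report)
    else:
        _tally(source, counts, report)

    collapsed = [
        CollapsedRead(id=f"r{i}_x{count}", sequence=seq, count=count)
        for i, (seq, count) in enumerate(
            sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])), start=1
        )
    ]
    return collapsed, report


def _tally(seqs: Iterable[str], counts: Counter, report: CollapseReport) -> None:
    for seq in seqs:
        seq = seq.upper()
        if "N" in seq:
            report.total_reads += 1
            report.dropped_n += 1
            continue
        if seq.strip("ACGT"):
            raise ValueError(f"non-ACGTN characters in read: {seq!r}")
        report.total_reads += 1
        counts[seq] += 1


class GenomeIndex:
    """Exact-occurrence index over a small genome (both strands).

    Seed-and-verify: every ``k``-mer start position is recorded; a query looks
    up the seed of the read (and of its reverse complement) and verifies the
    full sequence. Queries shorter than ``k`` fall back to a linear scan.
    """

    def __init__(self, contigs: Mapping[str, str], k: int = 12) -> None:
        self.contigs = {name: seq.upper() for name, seq in contigs.items()}
        self.k = k
        self._seeds: dict[str, list[tuple[str, int]]] = defaultdict(list)
        for name, seq in self.contigs.items():
            for i in range(len(seq) - k + 1):
                self._seeds[seq[i : i + k]].append((name, i))

    def _forward_occurrences(self, seq: str) -> list[tuple[str, int]]:
        if len(seq) >= self.k:
            out = []
            for contig, pos in self._seeds.get(seq[: self.k], ()):
                if self.contigs[contig].startswith(seq, pos):
                    out.append((contig, pos))
            return out
        out = []
        for contig, ref in self.contigs.items():
            i = ref.find(seq)
            while i != -1:
                out.append((contig, i))
                i = ref.find(seq, i + 1)
        return out

    def occurrences(self, seq: str) -> list[tuple[str, int, str]]:
        """All exact occurrences of ``seq`` as ``(contig, start, strand)``."""
        seq = seq.upper()
        hits = [(c, p, "+") for c, p in self._forward_occurrences(seq)]
        rc = revcomp(seq)
        if rc != seq:
            hits += [(c, p, "-") for c, p in self._forward_occurrences(rc)]
        else:
            # palindromic read: each position matches on both strands
            hits += [(c, p, "-") for c, p, _ in list(hits)]
        return sorted(hits)


def align_reads(
    collapsed: Iterable[CollapsedRead],
    genome: Mapping[str, str] | GenomeIndex,
    max_hits: int = 1000,
) -> tuple[list[Alignment], AlignReport]:
    """Enumerate all perfect occurrences of each collapsed read on both strands.

    Reads with more than ``max_hits`` genomic locations are dropped entirely
    (and tallied); reads with no occurrence are tallied as unaligned.
    """
    index = genome if isinstance(genome, GenomeIndex) else GenomeIndex(genome)
    report = AlignReport()
    alignments: list[Alignment] = []
    for read in collapsed:
        report.n_reads += 1
        occ = index.occurrences(read.sequence)
        if not occ:
            report.n_unaligned += 1
            continue
        if len(occ) > max_hits:
            report.n_dropped_max_hits += 1
            report.dropped_read_ids.append(read.id)
            continue
        n = len(occ)
        for contig, pos, strand in occ:
            alignments.append(
                Alignment(
                    read_id=read.id,
                    contig=contig,
                    start=pos,
                    strand=strand,
                    length=len(read.sequence),
                    n_hits=n,
                )
            )
    return alignments, report


def group_by_read(alignments: Iterable[Alignment]) -> dict[str, list[Alignment]]:
    grouped: dict[str, list[Alignment]] = defaultdict(list)
    for aln in alignments:
        grouped[aln.read_id].append(aln)
    return dict(grouped)


def filter_structural(
    alignments: Iterable[Alignment], index: FeatureIndex
) -> tuple[list[Alignment], list[Alignment]]:
    """Partition alignments into (structural, retained) at read level.

    A read is structural if *any* of its alignments intersects a
    structural-RNA feature, sense or antisense; all of its alignments then
    move to the structural partition, so the partition is exhaustive and
    disjoint at read level.
    """
    grouped = group_by_read(alignments)
    structural: list[Alignment] = []
    retained: list[Alignment] = []
    for read_id, alns in grouped.items():
        if any(
            index.overlaps_structural(a.contig, a.start, a.end) for a in alns
        ):
            structural.extend(alns)
        else:
            retained.extend(alns)
    return structural, retained


def write_alignments_bed(alignments: Iterable[Alignment], path: str) -> None:
    """Export alignments as BED6 (name = read id, score = n_hits)."""
    with open(path, "w") as fh:
        for a in alignments:
            fh.write(
                f"{a.contig}\t{a.start}\t{a.end}\t{a.read_id}\t{a.n_hits}\t{a.strand}\n"
            )
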