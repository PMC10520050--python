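"""Genomic feature model, GFF3/BED I/O, interval indexing, and promoter derivation.

All internal coordinates are 0-based half-open ``[start, end)``. GFF3 files are
1-based inclusive at the boundary (``start - 1`` on read, ``start + 1`` on
write); BED is 0-based half-open and passes through unchanged.

The feature vocabulary mirrors the annotation categories used in C. elegans
small-RNA analysis: protein-coding genes, pseudogenes, lincRNAs, rRNAs,
structural RNAs (tRNA/snRNA/snoRNA/ncRNA), transposons, piRNA-producing loci,
and operons (polycistronic gene clusters; promoter attribution uses the first
gene of the operon).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import gffutils
import pandas as pd
from intervaltree import IntervalTree

BIOTYPES = frozenset(
    {
        "protein_coding",
        "pseudogene",
        "lincRNA",
        "rRNA",
        "tRNA",
        "snRNA",
        "snoRNA",
        "ncRNA",
        "transposon",
        "piRNA_locus",
    }
)

#: Biotypes whose reads are treated as structural-RNA contamination and
#: removed before small-RNA class calling (rRNA is handled separately: it is
#: a 22G-eligible feature with precedence, not a structural filter category).
STRUCTURAL_BIOTYPES = frozenset({"tRNA", "snRNA", "snoRNA", "ncRNA"})

#: Biotypes counted at exon resolution; all others count over the full span.
EXONIC_BIOTYPES = frozenset({"protein_coding", "pseudogene"})

#: Default set of biotypes eligible for promoter derivation.
PROMOTER_ELIGIBLE = frozenset({"protein_coding", "lincRNA", "pseudogene"})


class GffParseError(ValueError):
    """Raised for malformed GFF3 input; the message names the offending line."""


@dataclass
class Feature:
    """One genomic feature.

    ``utr5_start`` marks the transcription-start side of the gene in genome
    coordinates: for a plus-strand gene it is the 0-based position of the
    5'-most transcribed base; for a minus-strand gene it is the exclusive end
    coordinate (one past the 5'-most base), so that the upstream interval is
    always ``[utr5_start, utr5_start + L)`` on the minus strand and
    ``[utr5_start - L, utr5_start)`` on the plus strand.
    """

    id: str
    contig: str
    start: int
    end: int
    strand: str
    biotype: str
    exons: list[tuple[int, int]] = field(default_factory=list)
    utr5_start: int | None = None

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"feature {self.id}: strand must be + or -")
        if not 0 <= self.start < self.end:
            raise ValueError(
                f"feature {self.id}: invalid interval [{self.start}, {self.end})"
            )
        if self.biotype not in BIOTYPES:
            raise ValueError(f"feature {self.id}: unknown biotype {self.biotype!r}")
        self.exons = sorted(tuple(e) for e in self.exons)
        prev_end = self.start
        for s, e in self.exons:
            if s < self.start or e > self.end:
                raise ValueError(f"feature {self.id}: exon [{s}, {e}) outside span")
            if s < prev_end and (s, e) != (self.start, self.end):
                raise ValueError(f"feature {self.id}: overlapping exons")
            prev_end = max(prev_end, e)

    @property
    def five_prime(self) -> int:
        """Genome coordinate of the 5'-most base (0-based)."""
        return self.start if self.strand == "+" else self.end - 1

    def tss(self) -> int:
        """Transcription-start coordinate in the ``utr5_start`` convention."""
        if self.utr5_start is not None:
            return self.utr5_start
        return self.start if self.strand == "+" else self.end

    def countable_intervals(self) -> list[tuple[int, int]]:
        """Intervals over which reads are assigned to this feature."""
        if self.biotype in EXONIC_BIOTYPES and self.exons:
            return self.exons
        return [(self.start, self.end)]


@dataclass
class Operon:
    """Polycistronic gene cluster; ``members`` are ordered 5'-to-3' on the
    operon strand (the first member owns the shared promoter)."""

    id: str
    members: list[str]

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValueError(f"operon {self.id}: needs >=2 member genes")


@dataclass(frozen=True)
class PromoterInterval:
    gene_id: str
    contig: str
    start: int
    end: int
    derived_from_operon: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"promoter {self.gene_id}: empty interval")
        if self.end - self.start > 1000:
            raise ValueError(f"promoter {self.gene_id}: longer than 1 kb")


class AnnotationSet:
    """Container for the features, operons, and contig sizes of one genome."""

    def __init__(
        self,
        contigs: Mapping[str, int],
        features: Iterable[Feature],
        operons: Iterable[Operon] = (),
    ) -> None:
        self.contigs: dict[str, int] = dict(contigs)
        self.features: list[Feature] = list(features)
        self.operons: list[Operon] = list(operons)
        self._by_id = {f.id: f for f in self.features}
        if len(self._by_id) != len(self.features):
            raise ValueError("duplicate feature ids")
        for f in self.features:
            if f.contig not in self.contigs:
                raise ValueError(f"feature {f.id}: unknown contig {f.contig}")
            if f.end > self.contigs[f.contig]:
                raise ValueError(f"feature {f.id}: extends past contig end")

    def __len__(self) -> int:
        return len(self.features)

    def __getitem__(self, feature_id: str) -> Feature:
        return self._by_id[feature_id]

    def __contains__(self, feature_id: str) -> bool:
        return feature_id in self._by_id

    def by_biotype(self, *biotypes: str) -> list[Feature]:
        want = set(biotypes)
        return [f for f in self.features if f.biotype in want]

    def genes(self) -> list[Feature]:
        return self.by_biotype("protein_coding", "pseudogene", "lincRNA")

    def pirna_loci(self) -> list[Feature]:
        return self.by_biotype("piRNA_locus")

    def structural(self) -> list[Feature]:
        return [f for f in self.features if f.biotype in STRUCTURAL_BIOTYPES]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AnnotationSet):
            return NotImplemented
        return (
            self.contigs == other.contigs
            and self.features == other.features
            and self.operons == other.operons
        )


class FeatureIndex:
    """Per-contig interval lookup over feature spans and countable intervals.

    Backed by :class:`intervaltree.IntervalTree`; queries use half-open
    semantics, so a point query at a feature's end coordinate misses it.
    """

    def __init__(self, annots: AnnotationSet) -> None:
        self.annots = annots
        self._span: dict[str, IntervalTree] = {}
        self._countable: dict[str, IntervalTree] = {}
        self._structural: dict[str, IntervalTree] = {}
        for f in annots.features:
            self._span.setdefault(f.contig, IntervalTree()).addi(f.start, f.end, f)
            tree = self._countable.setdefault(f.contig, IntervalTree())
            for s, e in f.countable_intervals():
                tree.addi(s, e, f)
            if f.biotype in STRUCTURAL_BIOTYPES:
                self._structural.setdefault(f.contig, IntervalTree()).addi(
                    f.start, f.end, f
                )

    @staticmethod
    def _query(
        trees: dict[str, IntervalTree],
        contig: str,
        start: int,
        end: int,
        strand: str | None,
        biotypes: frozenset[str] | set[str] | None,
    ) -> list[Feature]:
        tree = trees.get(contig)
        if tree is None:
            return []
        hits: dict[str, Feature] = {}
        for iv in tree.overlap(start, end):
            f = iv.data
            if strand is not None and f.strand != strand:
                continue
            if biotypes is not None and f.biotype not in biotypes:
                continue
            hits[f.id] = f
        return sorted(hits.values(), key=lambda f: f.id)

    def query(
        self,
        contig: str,
        start: int,
        end: int,
        strand: str | None = None,
        biotypes: frozenset[str] | set[str] | None = None,
    ) -> list[Feature]:
        """Features whose full span intersects ``[start, end)``."""
        return self._query(self._span, contig, start, end, strand, biotypes)

    def query_countable(
        self,
        contig: str,
        start: int,
        end: int,
        strand: str | None = None,
        biotypes: frozenset[str] | set[str] | None = None,
    ) -> list[Feature]:
        """Features with a countable interval intersecting ``[start, end)``."""
        return self._query(self._countable, contig, start, end, strand, biotypes)

    def overlaps_structural(self, contig: str, start: int, end: int) -> bool:
        """True if the interval touches any structural-RNA feature, either strand."""
        tree = self._structural.get(contig)
        return bool(tree is not None and tree.overlap(start, end))


def derive_promoters(
    annots: AnnotationSet,
    length: int = 1000,
    eligible: frozenset[str] = PROMOTER_ELIGIBLE,
) -> tuple[list[PromoterInterval], list[str]]:
    """Define promoters as up to ``length`` bp upstream of the 5'UTR start.

    Genes inside an operon all receive the promoter of the operon's first
    gene. Genes without an annotated 5'UTR fall back to the gene's 5'-most
    coordinate. Intervals are clipped at contig bounds; genes whose promoter
    would be empty after clipping are reported in the skipped list rather
    than raising.
    """
    first_of_operon: dict[str, Feature] = {}
    in_operon: dict[str, str] = {}
    for op in annots.operons:
        first = annots[op.members[0]]
        for m in op.members:
            first_of_operon[m] = first
            in_operon[m] = op.id

    promoters: list[PromoterInterval] = []
    skipped: list[str] = []
    for gene in annots.features:
        if gene.biotype not in eligible:
            continue
        anchor = first_of_operon.get(gene.id, gene)
        s = anchor.tss()
        clen = annots.contigs[anchor.contig]
        if anchor.strand == "+":
            start, end = max(0, s - length), min(clen, s)
        else:
            start, end = max(0, s), min(clen, s + length)
        if start >= end:
            skipped.append(gene.id)
            continue
        promoters.append(
            PromoterInterval(
                gene_id=gene.id,
                contig=anchor.contig,
                start=start,
                end=end,
                derived_from_operon=gene.id in in_operon,
            )
        )
    return promoters, skipped


# ---------------------------------------------------------------------------
# GFF3 and BED I/O
# ---------------------------------------------------------------------------

_GFF_SOURCE = "granulekit"


def write_gff(annots: AnnotationSet, path: str) -> None:
    """Write an :class:`AnnotationSet` as GFF3 (1-based inclusive coordinates).

    Contig sizes are recorded as ``##sequence-region`` pragmas, exons as child
    records, and operons as ``operon`` records carrying a ``members`` list.
    """
    lines = ["##gff-version 3"]
    for contig in sorted(annots.contigs):
        lines.append(f"##sequence-region {contig} 1 {annots.contigs[contig]}")
    for f in annots.features:
        attrs = [f"ID={f.id}", f"biotype={f.biotype}"]
        if f.utr5_start is not None:
            attrs.append(f"utr5_start={f.utr5_start}")
        lines.append(
            "\t".join(
                (
                    f.contig,
                    _GFF_SOURCE,
                    f.biotype,
                    str(f.start + 1),
                    str(f.end),
                    ".",
                    f.strand,
                    ".",
                    ";".join(attrs),
                )
            )
        )
        for i, (s, e) in enumerate(f.exons, start=1):
            lines.append(
                "\t".join(
                    (
                        f.contig,
                        _GFF_SOURCE,
                        "exon",
                        str(s + 1),
                        str(e),
                        ".",
                        f.strand,
                        ".",
                        f"ID={f.id}.e{i};Parent={f.id}",
                    )
                )
            )
    for op in annots.operons:
        members = [annots[m] for m in op.members]
        start = min(m.start for m in members)
        end = max(m.end for m in members)
        lines.append(
            "\t".join(
                (
                    members[0].contig,
                    _GFF_SOURCE,
                    "operon",
                    str(start + 1),
                    str(end),
                    ".",
                    members[0].strand,
                    ".",
                    f"ID={op.id};members={','.join(op.members)}",
                )
            )
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def _validate_gff_lines(text: str) -> None:
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 9:
            raise GffParseError(f"line {lineno}: expected 9 columns, got {len(cols)}")
        try:
            start, end = int(cols[3]), int(cols[4])
        except ValueError as exc:
            raise GffParseError(f"line {lineno}: non-integer coordinates") from exc
        if start < 1 or end < start:
            raise GffParseError(
                f"line {lineno}: invalid coordinates start={start} end={end}"
            )


def read_gff(path: str) -> AnnotationSet:
    """Read a GFF3 file produced by :func:`write_gff` (or an equivalent subset).

    Coordinate violations (``end < start``, ``start < 1``) are reported with
    their line number. Unknown record types are ignored.
    """
    with open(path) as fh:
        text = fh.read()
    _validate_gff_lines(text)

    contigs: dict[str, int] = {}
    for line in text.splitlines():
        if line.startswith("##sequence-region"):
            _, contig, _one, size = line.split()
            contigs[contig] = int(size)

    db = gffutils.create_db(
        text, ":memory:", from_string=True, keep_order=True, merge_strategy="error"
    )
    features: list[Feature] = []
    operons: list[Operon] = []
    exons: dict[str, list[tuple[int, int]]] = {}
    order: list[str] = []
    raw: dict[str, gffutils.Feature] = {}
    for rec in db.all_features():
        if rec.featuretype == "exon":
            parent = rec.attributes["Parent"][0]
            exons.setdefault(parent, []).append((rec.start - 1, rec.end))
        elif rec.featuretype == "operon":
            operons.append(
                # gffutils splits comma-separated attribute values already
                Operon(id=rec.id, members=list(rec.attributes["members"]))
            )
        elif rec.featuretype in BIOTYPES or "biotype" in rec.attributes:
            raw[rec.id] = rec
            order.append(rec.id)
    for fid in order:
        rec = raw[fid]
        biotype = rec.attributes.get("biotype", [rec.featuretype])[0]
        utr5 = rec.attributes.get("utr5_start")
        features.append(
            Feature(
                id=fid,
                contig=rec.seqid,
                start=rec.start - 1,
                end=rec.end,
                strand=rec.strand,
                biotype=biotype,
                exons=exons.get(fid, []),
                utr5_start=int(utr5[0]) if utr5 else None,
            )
        )
    if not contigs:
        # fall back to the rightmost coordinate seen per contig
        for f in features:
            contigs[f.contig] = max(contigs.get(f.contig, 0), f.end)
    return AnnotationSet(contigs, features, operons)


def write_bed(
    intervals: Sequence, path: str, *, name_attr: str = "gene_id", score: float = 0.0
) -> None:
    """Write promoter-like intervals as BED6."""
    with open(path, "w") as fh:
        for iv in intervals:
            name = getattr(iv, name_attr)
            fh.write(
                f"{iv.contig}\t{iv.start}\t{iv.end}\t{name}\t{score:g}\t+\n"
            )


def read_bed(path: str) -> pd.DataFrame:
    """Read a BED6 file into a DataFrame (0-based half-open, as on disk)."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["contig", "start", "end", "name", "score", "strand"],
        dtype={"contig": str, "start": int, "end": int, "name": str},
        comment="#",
    )
    if (df["end"] <= df["start"]).any():
        bad = df.index[(df["end"] <= df["start"])][0] + 1
        raise ValueError(f"BED line {bad}: end <= start")
    return df
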