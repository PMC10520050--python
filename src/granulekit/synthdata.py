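"""Ground-truth synthetic data for every pipeline stage.

The generator emulates the study design the pipeline targets: a compact
worm-like genome with overlapping features (including an rRNA inside a
protein-coding gene, to exercise rRNA precedence, and operons of >=2 genes),
small-RNA libraries drawn per class with condition-dependent abundances and a
fold-depleted 22G target set in the "mutant" condition, 2'-O-methylation
flags with periodate-oxidation survival, replicate ChIP peak sets over
promoters, and 3D image stacks of Gaussian-blurred spheres with Poisson
noise. Every simulated read and granule carries a truth label.

All randomness flows from ``SimConfig.seed`` through
``numpy.random.default_rng``; identical configurations give byte-identical
output files.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .annotations import AnnotationSet, Feature, FeatureIndex, Operon
from .chiptargets import Peak
from .readproc import GenomeIndex, revcomp
from .volumetrics import ImageStack

_BASES = np.array(list("ACGT"))

DEFAULT_CLASS_MIX = {
    "piRNA": 0.30,
    "22G": 0.45,
    "26G": 0.10,
    "structural": 0.05,
    "background": 0.10,
}


class SizingError(ValueError):
    """Requested features do not fit on the configured contigs."""


@dataclass
class SimConfig:
    seed: int = 0
    n_contigs: int = 2
    contig_length: int = 100_000
    n_genes: int = 120
    n_pirna_loci: int = 60
    n_structural: int = 12
    n_transposons: int = 8
    n_operons: int = 3
    class_mix: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_CLASS_MIX))
    depletion_set_size: int = 20
    depletion_fold: float = 4.0
    replicates_per_condition: int = 2
    methylated_survival: float = 0.95
    unmethylated_survival: float = 0.05

    def __post_init__(self) -> None:
        if abs(sum(self.class_mix.values()) - 1.0) > 1e-9:
            raise ValueError("class_mix proportions must sum to 1")
        if self.depletion_fold <= 0:
            raise ValueError("depletion_fold must be > 0")
        for name in (
            "n_contigs",
            "contig_length",
            "n_genes",
            "n_pirna_loci",
            "n_structural",
            "n_transposons",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("methylated_survival", "unmethylated_survival"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be a probability")
        if self.depletion_set_size > self.n_genes:
            raise ValueError("depletion_set_size exceeds n_genes")


@dataclass(frozen=True)
class SimRead:
    id: str
    sequence: str
    methylated: bool
    true_class: str
    feature_id: str | None
    condition: str


# ---------------------------------------------------------------------------
# genome + annotations
# ---------------------------------------------------------------------------

_STRUCTURAL_CYCLE = ("tRNA", "snRNA", "snoRNA", "ncRNA")


def make_genome(config: SimConfig) -> tuple[dict[str, str], AnnotationSet]:
    """Random contigs plus a feature layout with deliberate overlaps.

    Layout guarantees: at least one rRNA overlapping a protein-coding gene,
    at least one operon with >=2 members (adjacent, same strand), piRNA loci
    whose first three locus-strand bases are T (so reads starting at offsets
    0-2 carry a 5' T) and whose 21-mers are unique in the genome, and every
    gene carrying strand, exons, biotype, and a 5'UTR start.
    """
    rng = np.random.default_rng([config.seed, 1])
    contig_names = [f"chr{i+1}" for i in range(config.n_contigs)]
    seqs = {
        name: rng.choice(_BASES, size=config.contig_length)
        for name in contig_names
    }

    features: list[Feature] = []
    operons: list[Operon] = []

    # round-robin distribution of feature requests over contigs
    requests: dict[str, list[tuple[str, int]]] = {n: [] for n in contig_names}

    def spread(kind: str, n: int) -> None:
        for i in range(n):
            requests[contig_names[i % config.n_contigs]].append((kind, i))

    spread("gene", config.n_genes)
    spread("pirna", config.n_pirna_loci)
    spread("structural", config.n_structural)
    spread("transposon", config.n_transposons)

    # operon membership: the first genes, grouped in pairs/triples
    operon_sizes = [2 + (i % 2) for i in range(config.n_operons)]
    operon_gene_idx: dict[int, int] = {}
    gi = 0
    for oi, size in enumerate(operon_sizes):
        for _ in range(size):
            operon_gene_idx[gi] = oi
            gi += 1
    if gi > config.n_genes:
        raise SizingError(
            f"{config.n_operons} operons need {gi} genes but only "
            f"{config.n_genes} requested"
        )

    gene_count = 0
    operon_members: dict[int, list[str]] = {i: [] for i in range(config.n_operons)}
    for contig in contig_names:
        pos = 200
        rlist = requests[contig]
        rng.shuffle(rlist)  # interleave feature kinds along the contig
        current_operon: int | None = None
        operon_strand = "+"
        for kind, i in rlist:
            if kind == "gene":
                length = int(rng.integers(500, 1200))
                oi = operon_gene_idx.get(i)
                if oi is not None and oi == current_operon:
                    strand = operon_strand
                    gap = int(rng.integers(60, 120))
                else:
                    strand = rng.choice(["+", "-"])
                    gap = int(rng.integers(80, 250))
                    if oi is not None:
                        current_operon = oi
                        operon_strand = strand
                if oi is None:
                    current_operon = None
                start = pos + gap
                end = start + length
                if end > config.contig_length - 200:
                    raise SizingError(
                        f"contig_length={config.contig_length} too short for the "
                        f"requested features on {contig}"
                    )
                gid = f"gene{i+1:03d}"
                biotype = (
                    "protein_coding"
                    if i % 12 != 10
                    else ("pseudogene" if i % 24 != 10 else "lincRNA")
                )
                exons = _make_exons(rng, start, end)
                features.append(
                    Feature(
                        id=gid,
                        contig=contig,
                        start=start,
                        end=end,
                        strand=strand,
                        biotype=biotype,
                        exons=exons,
                        utr5_start=start if strand == "+" else end,
                    )
                )
                if oi is not None:
                    operon_members[oi].append(gid)
                gene_count += 1
                pos = end
            else:
                if kind == "pirna":
                    length, gap = 21, int(rng.integers(60, 160))
                elif kind == "structural":
                    length, gap = int(rng.integers(70, 150)), int(rng.integers(80, 250))
                else:  # transposon
                    length, gap = int(rng.integers(300, 700)), int(rng.integers(80, 250))
                start = pos + gap
                end = start + length
                if end > config.contig_length - 200:
                    raise SizingError(
                        f"contig_length={config.contig_length} too short for the "
                        f"requested features on {contig}"
                    )
                strand = rng.choice(["+", "-"])
                if kind == "pirna":
                    fid = f"pirna{i+1:04d}"
                    biotype = "piRNA_locus"
                    _force_locus_prefix(seqs[contig], start, end, strand, "TTT")
                elif kind == "structural":
                    fid = f"struct{i+1:03d}"
                    biotype = _STRUCTURAL_CYCLE[i % len(_STRUCTURAL_CYCLE)]
                else:
                    fid = f"tn{i+1:03d}"
                    biotype = "transposon"
                features.append(
                    Feature(
                        id=fid,
                        contig=contig,
                        start=start,
                        end=end,
                        strand=strand,
                        biotype=biotype,
                    )
                )
                pos = end

    # deliberate overlap: one rRNA inside the first protein-coding gene,
    # one standalone rRNA in the tail of chr1
    host = next(f for f in features if f.biotype == "protein_coding")
    r_start = host.start + (host.end - host.start) // 4
    r_end = min(host.end, r_start + 120)
    features.append(
        Feature(
            id="rrna001",
            contig=host.contig,
            start=r_start,
            end=r_end,
            strand="-" if host.strand == "+" else "+",
            biotype="rRNA",
        )
    )
    features.append(
        Feature(
            id="rrna002",
            contig=contig_names[0],
            start=config.contig_length - 180,
            end=config.contig_length - 60,
            strand="+",
            biotype="rRNA",
        )
    )

    for oi in range(config.n_operons):
        members = operon_members[oi]
        if len(members) >= 2:
            operons.append(Operon(id=f"operon{oi+1}", members=members))

    genome = {name: "".join(seq) for name, seq in seqs.items()}
    _ensure_unique_pirna_loci(genome, seqs, features, rng)
    genome = {name: "".join(seq) for name, seq in seqs.items()}

    annots = AnnotationSet(
        {name: config.contig_length for name in contig_names}, features, operons
    )
    return genome, annots


def _make_exons(
    rng: np.random.Generator, start: int, end: int
) -> list[tuple[int, int]]:
    n_exons = int(rng.integers(1, 4))
    n_seg = 2 * n_exons - 1  # exons and introns alternate
    length = end - start
    if n_exons == 1 or length < 40 * n_seg:
        return [(start, end)]
    extra = rng.multinomial(length - 30 * n_seg, [1.0 / n_seg] * n_seg)
    bounds = [start]
    for seg in 30 + extra:  # every segment at least 30 bp
        bounds.append(bounds[-1] + int(seg))
    return [(bounds[i], bounds[i + 1]) for i in range(0, n_seg, 2)]


def _force_locus_prefix(
    seq: np.ndarray, start: int, end: int, strand: str, prefix: str
) -> None:
    """Write ``prefix`` at the 5' end of a locus on its own strand."""
    if strand == "+":
        seq[start : start + len(prefix)] = list(prefix)
    else:
        rc = revcomp(prefix)
        seq[end - len(prefix) : end] = list(rc)


def _ensure_unique_pirna_loci(
    genome: Mapping[str, str],
    seqs: Mapping[str, np.ndarray],
    features: Sequence[Feature],
    rng: np.random.Generator,
) -> None:
    """Re-randomize any piRNA locus whose 21-mer occurs more than once.

    piRNA calling requires unique mapping; a duplicated locus sequence would
    make its reads unclassifiable by construction. Collisions are vanishingly
    rare for random 21-mers but are checked so that recovery is exact.
    """
    full = " ".join(genome.values())
    for f in features:
        if f.biotype != "piRNA_locus":
            continue
        locus = genome[f.contig][f.start : f.end]
        for _ in range(20):
            if full.count(locus) + full.count(revcomp(locus)) <= 1:
                break
            body = rng.choice(_BASES, size=f.end - f.start - 3)
            if f.strand == "+":
                seqs[f.contig][f.start + 3 : f.end] = body
            else:
                seqs[f.contig][f.start : f.end - 3] = body
            genome = {name: "".join(s) for name, s in seqs.items()}
            full = " ".join(genome.values())
            locus = genome[f.contig][f.start : f.end]


# ---------------------------------------------------------------------------
# small-RNA reads
# ---------------------------------------------------------------------------


def _condition_index(condition: str) -> int:
    return {"wildtype": 0, "mutant": 1}.get(
        condition, zlib.crc32(condition.encode()) % 2**16
    )


class _TruthPicker:
    """Per-gene abundance structure shared by all samples of one config."""

    def __init__(self, config: SimConfig, annots: AnnotationSet) -> None:
        rng = np.random.default_rng([config.seed, 777])
        genes = [f for f in annots.genes() if f.biotype == "protein_coding"]
        self.genes = genes
        self.gene_ids = [g.id for g in genes]
        self.depleted = sorted(
            rng.choice(self.gene_ids, size=config.depletion_set_size, replace=False)
        )
        self.base_weight = dict(
            zip(self.gene_ids, rng.lognormal(0.0, 0.5, len(genes)))
        )
        loci = annots.pirna_loci()
        self.pirna_loci = loci
        self.pirna_weight = dict(
            zip((l.id for l in loci), rng.lognormal(0.0, 0.5, len(loci)))
        )
        n26 = max(1, len(genes) // 4)
        self.g26_targets = sorted(
            rng.choice(self.gene_ids, size=n26, replace=False)
        )

    def base_probs(self) -> np.ndarray:
        w = np.array([self.base_weight[g] for g in self.gene_ids])
        return w / w.sum()


def simulate_small_rna_reads(
    genome: Mapping[str, str],
    annots: AnnotationSet,
    config: SimConfig,
    condition: str = "wildtype",
    n_reads: int = 50_000,
    replicate: int = 1,
    unambiguous: bool = True,
    genome_index: GenomeIndex | None = None,
) -> tuple[list[SimRead], pd.DataFrame]:
    """Draw one small-RNA library with truth labels.

    Per-class read counts follow ``config.class_mix``; 22G reads are drawn
    per gene with a shared log-normal baseline, divided by
    ``config.depletion_fold`` for the depletion set in any non-wild-type
    condition. piRNA-class reads are 21 nt, 5' T, sense to a piRNA locus at
    offset 0-2, and methylated; all other classes are unmethylated. With
    ``unambiguous=True`` each drawn read is checked against the class
    templates (unique mapping for piRNAs, no structural-RNA overlap at any
    genomic occurrence, non-classifiable backgrounds) and re-drawn otherwise,
    so feeding the library to the classifier recovers the truth exactly.
    """
    for name, frac in config.class_mix.items():
        if frac > 0:
            if name == "piRNA" and not annots.pirna_loci():
                raise ValueError("class_mix requests piRNAs but no piRNA loci exist")
            if name == "structural" and not annots.structural():
                raise ValueError(
                    "class_mix requests structural reads but no structural RNAs exist"
                )

    rng = np.random.default_rng(
        [config.seed, 2, _condition_index(condition), replicate]
    )
    picker = _TruthPicker(config, annots)
    index = genome_index
    findex = FeatureIndex(annots) if unambiguous else None
    if unambiguous and index is None:
        index = GenomeIndex(genome)

    class_names = sorted(config.class_mix)
    counts = rng.multinomial(n_reads, [config.class_mix[c] for c in class_names])
    n_by_class = dict(zip(class_names, counts))

    reads: list[SimRead] = []
    truth_rows: list[dict] = []
    serial = 0

    def emit(seq: str, true_class: str, feature_id: str | None, methylated: bool):
        nonlocal serial
        serial += 1
        rid = f"{condition}.r{replicate}.{serial:06d}"
        reads.append(
            SimRead(rid, seq, methylated, true_class, feature_id, condition)
        )
        truth_rows.append(
            {
                "read_id": rid,
                "true_class": true_class,
                "feature_id": feature_id,
                "methylated": methylated,
            }
        )

    _draw_pirna(rng, genome, picker, n_by_class.get("piRNA", 0), index, emit)
    _draw_antisense(
        rng,
        genome,
        annots,
        picker,
        n_by_class.get("22G", 0),
        condition,
        config.depletion_fold,
        (21, 23),
        "GA",
        "22G",
        index,
        findex,
        emit,
    )
    _draw_26g(rng, genome, annots, picker, n_by_class.get("26G", 0), index, findex, emit)
    _draw_structural(rng, genome, annots, n_by_class.get("structural", 0), emit)
    _draw_background(
        rng, genome, annots, n_by_class.get("background", 0), findex, index, emit
    )

    truth = pd.DataFrame(
        truth_rows, columns=["read_id", "true_class", "feature_id", "methylated"]
    )
    return reads, truth


def _draw_pirna(rng, genome, picker, n, index, emit) -> None:
    if n == 0:
        return
    loci = picker.pirna_loci
    w = np.array([picker.pirna_weight[l.id] for l in loci])
    probs = w / w.sum()
    per_locus = rng.multinomial(n, probs)
    for locus, k in zip(loci, per_locus):
        contig = genome[locus.contig]
        for _ in range(k):
            offset = int(rng.integers(0, 3))
            if locus.strand == "+":
                s = locus.start + offset
                seq = contig[s : s + 21]
            else:
                e = locus.end - offset
                seq = revcomp(contig[e - 21 : e])
            if index is not None and len(index.occurrences(seq)) != 1:
                continue  # duplicated locus 21-mer; skip rather than mislabel
            emit(seq, "piRNA", locus.id, True)


def _sample_antisense_read(
    rng, genome, feature, length_range, first_bases, max_tries=60
) -> str | None:
    contig = genome[feature.contig]
    intervals = feature.countable_intervals()
    for _ in range(max_tries):
        lo, hi = length_range
        L = int(rng.integers(lo, hi + 1))
        s_int, e_int = intervals[int(rng.integers(0, len(intervals)))]
        if e_int - s_int < L:
            continue
        s = int(rng.integers(s_int, e_int - L + 1))
        if feature.strand == "+":
            seq = revcomp(contig[s : s + L])
        else:
            seq = contig[s : s + L]
        if seq[0] in first_bases:
            return seq
    return None


def _occurrence_clean(index, findex, seq) -> bool:
    """No genomic occurrence of the read intersects a structural RNA."""
    if index is None or findex is None:
        return True
    for contig, pos, _strand in index.occurrences(seq):
        if findex.overlaps_structural(contig, pos, pos + len(seq)):
            return False
    return True


def _draw_antisense(
    rng,
    genome,
    annots,
    picker,
    n,
    condition,
    depletion_fold,
    length_range,
    first_bases,
    cls,
    index,
    findex,
    emit,
) -> None:
    if n == 0:
        return
    # depletion by binomial thinning: the expected mutant/wild-type raw count
    # ratio for a depleted gene is exactly 1/depletion_fold
    per_gene = rng.multinomial(n, picker.base_probs())
    if condition != "wildtype":
        dep_mask = np.isin(picker.gene_ids, picker.depleted)
        per_gene = np.where(
            dep_mask, rng.binomial(per_gene, 1.0 / depletion_fold), per_gene
        )
    for gene, k in zip(picker.genes, per_gene):
        for _ in range(k):
            for _attempt in range(20):
                seq = _sample_antisense_read(rng, genome, gene, length_range, first_bases)
                if seq is not None and _occurrence_clean(index, findex, seq):
                    emit(seq, cls, gene.id, False)
                    break


def _draw_26g(rng, genome, annots, picker, n, index, findex, emit) -> None:
    if n == 0:
        return
    targets = [annots[g] for g in picker.g26_targets]
    w = np.array([picker.base_weight[g.id] for g in targets])
    probs = w / w.sum()
    per_gene = rng.multinomial(n, probs)
    for gene, k in zip(targets, per_gene):
        for _ in range(k):
            for _attempt in range(20):
                seq = _sample_antisense_read(rng, genome, gene, (26, 26), "G")
                if seq is not None and _occurrence_clean(index, findex, seq):
                    emit(seq, "26G", gene.id, False)
                    break


def _draw_structural(rng, genome, annots, n, emit) -> None:
    feats = annots.structural()
    if n == 0 or not feats:
        return
    for _ in range(n):
        f = feats[int(rng.integers(0, len(feats)))]
        contig = genome[f.contig]
        L = int(rng.integers(18, 31))
        L = min(L, f.end - f.start)
        s = int(rng.integers(f.start, f.end - L + 1))
        seq = contig[s : s + L] if f.strand == "+" else revcomp(contig[s : s + L])
        emit(seq, "structural", f.id, False)


def _draw_background(rng, genome, annots, n, findex, index, emit) -> None:
    """Reads from unannotated regions that match no class template (5' C)."""
    if n == 0:
        return
    findex = findex or FeatureIndex(annots)
    contigs = sorted(genome)
    drawn = 0
    while drawn < n:
        contig = contigs[int(rng.integers(0, len(contigs)))]
        seq_str = genome[contig]
        L = int(rng.integers(18, 31))
        s = int(rng.integers(0, len(seq_str) - L))
        if findex.query(contig, s, s + L):
            continue
        strand = "+" if rng.random() < 0.5 else "-"
        seq = seq_str[s : s + L] if strand == "+" else revcomp(seq_str[s : s + L])
        if seq[0] != "C":
            continue
        if not _occurrence_clean(index, findex, seq):
            continue
        emit(seq, "background", None, False)
        drawn += 1


def apply_oxidation(
    reads: Sequence[SimRead],
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> list[SimRead]:
    """Periodate-oxidation survival: Bernoulli-thin reads by methylation status.

    2'-O-methylated reads survive with ``methylated_survival``, unmethylated
    with ``unmethylated_survival``; collapsed counts are therefore binomially
    thinned. Output sequences are a subset of input sequences.
    """
    for p in (config.methylated_survival, config.unmethylated_survival):
        if not 0.0 <= p <= 1.0:
            raise ValueError("survival probabilities must lie in [0, 1]")
    rng = rng if rng is not None else np.random.default_rng([config.seed, 3])
    out = []
    for read in reads:
        p = (
            config.methylated_survival
            if read.methylated
            else config.unmethylated_survival
        )
        if rng.random() < p:
            out.append(read)
    return out


# ---------------------------------------------------------------------------
# ChIP peaks
# ---------------------------------------------------------------------------


def _longest_free_segment(
    start: int, end: int, blocked: list[tuple[int, int]]
) -> tuple[int, int] | None:
    """Longest sub-interval of [start, end) not covered by ``blocked``."""
    merged: list[list[int]] = []
    for s, e in sorted((max(start, s), min(end, e)) for s, e in blocked):
        if s >= e:
            continue
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    best = None
    cursor = start
    for s, e in merged + [[end, end]]:
        if s > cursor and (best is None or s - cursor > best[1] - best[0]):
            best = (cursor, s)
        cursor = max(cursor, e)
    return best


def resolvable_target_genes(annots: AnnotationSet) -> list[str]:
    """Genes whose promoter keeps a free segment (>=20 bp) outside every
    other gene's promoter, so a peak there supports that gene alone.

    Operon members other than the first gene share the first gene's promoter
    exactly and are therefore never individually resolvable."""
    from .annotations import derive_promoters

    promoters, _ = derive_promoters(annots)
    out = []
    for pr in promoters:
        blocked = [
            (o.start, o.end)
            for o in promoters
            if o.gene_id != pr.gene_id
            and o.contig == pr.contig
            and o.start < pr.end
            and pr.start < o.end
        ]
        seg = _longest_free_segment(pr.start, pr.end, blocked)
        if seg is not None and seg[1] - seg[0] >= 20:
            out.append(pr.gene_id)
    return sorted(set(out))


def simulate_chip_peaks(
    annots: AnnotationSet,
    target_genes: Iterable[str],
    config: SimConfig,
    decoy_fraction: float = 0.3,
    rep1_only_fraction: float = 0.1,
    rng: np.random.Generator | None = None,
) -> tuple[list[Peak], list[Peak]]:
    """Replicate peak sets: every target promoter gets a qualifying peak in
    both replicates; decoys avoid all promoters; rep1-only peaks sit on
    non-target promoters and must not survive the both-replicate rule."""
    from .annotations import derive_promoters

    rng = rng if rng is not None else np.random.default_rng([config.seed, 4])
    promoters, _ = derive_promoters(annots)
    by_gene = {p.gene_id: p for p in promoters}
    targets = sorted(set(target_genes))
    missing = [g for g in targets if g not in by_gene]
    if missing:
        raise ValueError(f"target genes without promoters: {missing}")

    # a target peak must not spill into a non-target promoter (shared operon
    # promoters or overlapping upstream regions would otherwise create
    # unplanted targets), so confine it to the free part of the promoter
    target_set = set(targets)
    reps: tuple[list[Peak], list[Peak]] = ([], [])
    for gene in targets:
        pr = by_gene[gene]
        blocked = [
            (o.start, o.end)
            for o in promoters
            if o.gene_id not in target_set
            and o.contig == pr.contig
            and o.start < pr.end
            and pr.start < o.end
        ]
        segment = _longest_free_segment(pr.start, pr.end, blocked)
        if segment is None or segment[1] - segment[0] < 20:
            raise ValueError(
                f"target gene {gene}: promoter fully shared with non-target "
                "genes; planted set is not promoter-resolvable"
            )
        seg_start, seg_end = segment
        for ri, peaks in enumerate(reps, start=1):
            width = min(int(rng.integers(150, 400)), seg_end - seg_start)
            start = int(rng.integers(seg_start, seg_end - width + 1))
            peaks.append(
                Peak(
                    pr.contig,
                    start,
                    start + width,
                    q_value=float(rng.uniform(1e-8, 0.05)),
                    replicate=f"rep{ri}",
                )
            )

    n_decoys = round(decoy_fraction * len(targets))
    prom_trees: dict[str, list[tuple[int, int]]] = {}
    for p in promoters:
        prom_trees.setdefault(p.contig, []).append((p.start, p.end))
    contigs = sorted(annots.contigs)
    for ri, peaks in enumerate(reps, start=1):
        placed = 0
        while placed < n_decoys:
            contig = contigs[int(rng.integers(0, len(contigs)))]
            width = int(rng.integers(150, 400))
            start = int(rng.integers(0, annots.contigs[contig] - width))
            if any(
                s < start + width and start < e
                for s, e in prom_trees.get(contig, ())
            ):
                continue
            peaks.append(
                Peak(
                    contig,
                    start,
                    start + width,
                    q_value=float(rng.uniform(1e-8, 0.09)),
                    replicate=f"rep{ri}",
                )
            )
            placed += 1

    non_targets = [g for g in sorted(by_gene) if g not in targets]
    n_rep1 = min(round(rep1_only_fraction * len(targets)), len(non_targets))
    for gene in non_targets[:n_rep1]:
        pr = by_gene[gene]
        width = int(rng.integers(150, 400))
        center = int(rng.integers(pr.start, pr.end))
        start = max(0, center - width // 2)
        reps[0].append(
            Peak(
                pr.contig,
                start,
                start + width,
                q_value=float(rng.uniform(1e-8, 0.05)),
                replicate="rep1",
            )
        )
    return reps


# ---------------------------------------------------------------------------
# granule stacks
# ---------------------------------------------------------------------------


def simulate_granule_stack(
    spheres: Sequence[tuple[tuple[float, float, float], float]],
    shape: tuple[int, int, int] = (40, 80, 80),
    voxel_size: tuple[float, float, float] = (0.2, 0.1, 0.1),
    amplitude: float = 200.0,
    background: float = 10.0,
    blur_sigma_um: float = 0.1,
    poisson_noise: bool = True,
    rng: np.random.Generator | None = None,
    stack_id: str = "sim",
) -> tuple[ImageStack, pd.DataFrame]:
    """Render spheres into a 3D stack: fill, Gaussian blur, Poisson noise,
    constant background. ``spheres`` is a list of ((z, y, x) center in um,
    radius in um); truth records the analytic volume 4/3*pi*r^3 per sphere."""
    rng = rng if rng is not None else np.random.default_rng(0)
    dz, dy, dx = voxel_size
    zz = (np.arange(shape[0]) + 0.5) * dz
    yy = (np.arange(shape[1]) + 0.5) * dy
    xx = (np.arange(shape[2]) + 0.5) * dx
    img = np.zeros(shape, dtype=float)
    rows = []
    for i, ((cz, cy, cx), r) in enumerate(spheres, start=1):
        d2 = (
            (zz[:, None, None] - cz) ** 2
            + (yy[None, :, None] - cy) ** 2
            + (xx[None, None, :] - cx) ** 2
        )
        img[d2 <= r * r] = amplitude
        rows.append(
            {
                "granule_id": f"{stack_id}.g{i}",
                "cz_um": cz,
                "cy_um": cy,
                "cx_um": cx,
                "radius_um": r,
                "volume_um3": 4.0 / 3.0 * np.pi * r**3,
            }
        )
    if blur_sigma_um > 0:
        img = ndimage.gaussian_filter(
            img, sigma=[blur_sigma_um / v for v in voxel_size]
        )
    if poisson_noise:
        img = rng.poisson(img).astype(float)
    img = img + background
    truth = pd.DataFrame(
        rows,
        columns=["granule_id", "cz_um", "cy_um", "cx_um", "radius_um", "volume_um3"],
    )
    return ImageStack(img, voxel_size, stack_id), truth


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------


def write_fasta(genome: Mapping[str, str], path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in sorted(genome):
            fh.write(f">{name}\n")
            seq = genome[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_fastq(reads: Iterable[SimRead], path: str) -> None:
    with open(path, "w") as fh:
        for read in reads:
            fh.write(f"@{read.id}\n{read.sequence}\n+\n{'I' * len(read.sequence)}\n")


def write_truth(truth: pd.DataFrame, path: str) -> None:
    truth.to_csv(path, sep="\t", index=False)
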