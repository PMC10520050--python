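"""Transcription-factor target calling from replicate ChIP-seq peak sets.

Peaks (already called upstream; peak calling itself is out of scope) are
filtered at q < q_cutoff (strict, default 0.1), intersected with
operon-aware promoters, and a gene is a target only when at least one
qualifying peak overlaps its promoter in *both* replicates. A peak that
overlaps two promoters supports both genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .annotations import PromoterInterval, read_bed
from .smallrna_stats import EnrichmentResult, set_enrichment


@dataclass(frozen=True)
class Peak:
    contig: str
    start: int
    end: int
    q_value: float
    replicate: str = "rep1"

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(f"peak: invalid interval [{self.start}, {self.end})")
        if self.q_value < 0:
            raise ValueError("peak: q_value must be >= 0")


@dataclass
class TargetCall:
    gene_id: str
    peaks_rep1: list[Peak] = field(default_factory=list)
    peaks_rep2: list[Peak] = field(default_factory=list)

    @property
    def is_target(self) -> bool:
        return bool(self.peaks_rep1) and bool(self.peaks_rep2)


def read_peaks_bed(path: str, replicate: str, q_column: str = "score") -> list[Peak]:
    """Read a BED6 peak file; the score column holds -log10(q) by convention
    (MACS2 narrowPeak style), or q directly with ``q_column='q'``."""
    df = read_bed(path)
    peaks = []
    for row in df.itertuples():
        q = 10.0 ** (-row.score) if q_column == "score" else float(row.score)
        peaks.append(Peak(row.contig, row.start, row.end, q, replicate))
    return peaks


def write_peaks_bed(peaks: Iterable[Peak], path: str) -> None:
    import math

    with open(path, "w") as fh:
        for i, p in enumerate(sorted(peaks, key=lambda p: (p.contig, p.start)), 1):
            score = -math.log10(p.q_value) if p.q_value > 0 else 999.0
            fh.write(
                f"{p.contig}\t{p.start}\t{p.end}\tpeak{i}\t{score:.4f}\t+\n"
            )


def _promoter_tree(promoters: Sequence[PromoterInterval]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for pr in promoters:
        trees.setdefault(pr.contig, IntervalTree()).addi(pr.start, pr.end, pr.gene_id)
    return trees


def call_targets(
    peaks_rep1: Sequence[Peak],
    peaks_rep2: Sequence[Peak],
    promoters: Sequence[PromoterInterval],
    q_cutoff: float = 0.1,
) -> tuple[list[TargetCall], set[str]]:
    """Intersect replicate peak sets with promoters and call target genes.

    Overlap is >=1 bp intersection (half-open intervals). The q threshold is
    strict (q < q_cutoff). An empty replicate yields zero targets, not an
    error. Returns all per-gene calls plus the set of genes supported by both
    replicates.
    """
    trees = _promoter_tree(promoters)
    calls: dict[str, TargetCall] = {}

    for peaks, attr in ((peaks_rep1, "peaks_rep1"), (peaks_rep2, "peaks_rep2")):
        for peak in peaks:
            if not peak.q_value < q_cutoff:
                continue
            tree = trees.get(peak.contig)
            if tree is None:
                continue
            for iv in tree.overlap(peak.start, peak.end):
                call = calls.setdefault(iv.data, TargetCall(gene_id=iv.data))
                getattr(call, attr).append(peak)

    call_list = sorted(calls.values(), key=lambda c: c.gene_id)
    targets = {c.gene_id for c in call_list if c.is_target}
    return call_list, targets


def intersect_targets_with_set(
    targets: Iterable[str],
    gene_set: Iterable[str],
    universe: Iterable[str] | None = None,
) -> tuple[set[str], EnrichmentResult | None]:
    """Overlap of called targets with an external gene set.

    Returns the overlapping gene ids and, when a universe is supplied, the
    fold-enrichment statistics for the overlap.
    """
    targets = set(targets)
    gene_set = set(gene_set)
    overlap = targets & gene_set
    result = None
    if universe is not None:
        result = set_enrichment(targets, gene_set, universe, set_name="targets")
    return overlap, result


def targets_to_tsv(calls: Sequence[TargetCall], path: str) -> None:
    rows = [
        {
            "gene": c.gene_id,
            "is_target": c.is_target,
            "n_peaks_rep1": len(c.peaks_rep1),
            "n_peaks_rep2": len(c.peaks_rep2),
        }
        for c in calls
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
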