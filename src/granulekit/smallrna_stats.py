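"""Differential 22G-RNA calling, gene-set enrichment, and oxidation statistics.

Differential analysis is a per-gene two-sample two-tailed t-test on replicate
RPM values, with the fold change computed from condition means as
log2((mean_mut + pc) / (mean_wt + pc)). A gene is called up when
log2FC >= log2(fold_threshold) and p < alpha; down symmetrically. The default
statistic is the pooled-variance (Student) t: with two replicates per
condition the Welch/Satterthwaite approximation is drastically conservative
(type-I error roughly half nominal), while the pooled test is exact under the
equal-variance null. Welch remains available via ``equal_var=False``.

Gene-set enrichment is log2 of the ratio of the fraction of the DE list in
the set to the fraction of the universe in the set, with a two-sided Fisher's
exact p (exact hypergeometric tail).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .classify import GeneCountTable


@dataclass
class DEConfig:
    fold_threshold: float = 4.0
    alpha: float = 0.05
    pseudocount: float = 0.5
    equal_var: bool = True  # pooled-variance t; False -> Welch
    aggregate: bool = False  # pool replicates before the fold change (no test)

    def __post_init__(self) -> None:
        if self.fold_threshold <= 1:
            raise ValueError("fold_threshold must be > 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be >= 0")


def _as_matrix(tables: Sequence[pd.Series], genes: pd.Index) -> np.ndarray:
    return np.column_stack([t.reindex(genes).fillna(0.0).to_numpy() for t in tables])


def differential_expression(
    wt_reps: Sequence[pd.Series],
    mut_reps: Sequence[pd.Series],
    cfg: DEConfig | None = None,
) -> pd.DataFrame:
    """Per-gene two-tailed t-test and fold-change calls (mutant over wild type).

    ``wt_reps``/``mut_reps`` are per-replicate RPM series indexed by gene;
    genes absent from a replicate count as 0. Returns a DataFrame indexed by
    gene with columns mean_wt, mean_mut, log2fc, p, call.
    """
    cfg = cfg or DEConfig()
    if len(wt_reps) < 2 or len(mut_reps) < 2:
        raise ValueError("each condition needs >=2 replicates for the t-test")
    genes = pd.Index(
        sorted(set().union(*(set(t.index) for t in list(wt_reps) + list(mut_reps)))),
        name="gene",
    )
    wt = _as_matrix(wt_reps, genes)
    mut = _as_matrix(mut_reps, genes)
    mean_wt = wt.mean(axis=1)
    mean_mut = mut.mean(axis=1)
    log2fc = np.log2((mean_mut + cfg.pseudocount) / (mean_wt + cfg.pseudocount))
    with np.errstate(invalid="ignore", divide="ignore"):
        p = stats.ttest_ind(mut, wt, axis=1, equal_var=cfg.equal_var).pvalue
    p = np.where(np.isnan(p), 1.0, p)  # zero-variance ties carry no evidence

    thr = math.log2(cfg.fold_threshold)
    call = np.where(
        (log2fc >= thr) & (p < cfg.alpha),
        "up",
        np.where((log2fc <= -thr) & (p < cfg.alpha), "down", "unchanged"),
    )
    return pd.DataFrame(
        {
            "mean_wt": mean_wt,
            "mean_mut": mean_mut,
            "log2fc": log2fc,
            "p": p,
            "call": call,
        },
        index=genes,
    )


def differential_22g(
    wt_tables: Sequence[GeneCountTable],
    mut_tables: Sequence[GeneCountTable],
    cfg: DEConfig | None = None,
    cls: str = "22G",
) -> pd.DataFrame:
    """Differential analysis of one small-RNA class from per-replicate tables."""
    return differential_expression(
        [t.rpm(cls) for t in wt_tables], [t.rpm(cls) for t in mut_tables], cfg
    )


@dataclass
class EnrichmentResult:
    set_name: str
    n_overlap: int
    n_de: int
    n_set: int
    n_universe: int
    log2_enrichment: float
    p: float

    def as_dict(self) -> dict:
        return self.__dict__.copy()


def set_enrichment(
    de_genes: Iterable[str],
    target_set: Iterable[str],
    universe: Iterable[str],
    set_name: str = "set",
    alternative: str = "two-sided",
) -> EnrichmentResult:
    """Fold enrichment of a gene set within a DE list, with Fisher's exact p.

    log2 enrichment = log2( (|DE ∩ set| / |DE|) / (|universe ∩ set| / |universe|) ).
    Empty DE list or empty set is reported as undefined enrichment (NaN) with
    p = 1 rather than raising.
    """
    universe = set(universe)
    de = set(de_genes) & universe
    target = set(target_set) & universe
    u, d, s = len(universe), len(de), len(target)
    a = len(de & target)
    if d == 0 or s == 0 or u == 0:
        return EnrichmentResult(set_name, a, d, s, u, float("nan"), 1.0)
    if a == 0:
        enr = float("-inf")
    else:
        enr = math.log2((a / d) / (s / u))
    table = [[a, d - a], [s - a, u - d - (s - a)]]
    p = stats.fisher_exact(table, alternative=alternative)[1]
    return EnrichmentResult(set_name, a, d, s, u, enr, float(p))


def enrichment_table(
    de_genes: Iterable[str],
    gene_sets: Mapping[str, Iterable[str]],
    universe: Iterable[str],
) -> pd.DataFrame:
    """Run :func:`set_enrichment` for several sets; one row per set."""
    universe = set(universe)
    de = set(de_genes)
    rows = [
        set_enrichment(de, members, universe, set_name=name).as_dict()
        for name, members in gene_sets.items()
    ]
    return pd.DataFrame(rows).set_index("set_name")


def median_fold(a: Sequence[float] | pd.Series, b: Sequence[float] | pd.Series) -> float:
    """Fold of medians median(b) / median(a) on matched per-locus abundances."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("median_fold: empty input")
    ma = float(np.median(a))
    if ma == 0:
        raise ValueError("median_fold: median of reference is zero")
    return float(np.median(b)) / ma


def oxidation_enrichment(
    untreated: pd.Series,
    oxidized: pd.Series,
    locus_classes: Mapping[str, str],
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Per-class summary of RPM before and after periodate oxidation.

    ``untreated`` and ``oxidized`` are RPM series indexed by locus, each
    normalized on its own sequencing depth. 2'-O-methylated species (mature
    piRNAs) survive oxidation while unmethylated RNAs are lost, so the
    methylated class's share of the (smaller) oxidized library rises. Returns
    one row per class: n loci, median RPM in each library, and the median
    per-locus log2 ratio (oxidized / untreated, with a pseudocount).
    """
    if len(oxidized) == 0:
        raise ValueError("oxidation_enrichment: empty oxidized table")
    loci = sorted(set(untreated.index) | set(oxidized.index))
    pre = untreated.reindex(loci).fillna(0.0)
    post = oxidized.reindex(loci).fillna(0.0)
    cls = pd.Series({l: locus_classes.get(l, "other") for l in loci})
    ratio = np.log2((post + pseudocount) / (pre + pseudocount))
    df = pd.DataFrame(
        {"cls": cls, "rpm_untreated": pre, "rpm_oxidized": post, "log2_ratio": ratio}
    )
    out = (
        df.groupby("cls")
        .agg(
            n=("cls", "size"),
            median_rpm_untreated=("rpm_untreated", "median"),
            median_rpm_oxidized=("rpm_oxidized", "median"),
            median_log2_ratio=("log2_ratio", "median"),
        )
        .sort_index()
    )
    return out


def simulate_null_tables(
    n_genes: int,
    n_reps: int,
    rng: np.random.Generator,
    baseline_sigma: float = 0.5,
    rep_cv: float = 0.1,
    mean_rpm: float = 500.0,
) -> tuple[list[pd.Series], list[pd.Series]]:
    """Replicate RPM tables for two conditions with no true effect.

    Per gene, a shared log-normal baseline (sigma ``baseline_sigma``) sets the
    expected RPM; replicates add Gaussian noise with standard deviation
    ``rep_cv`` x baseline. Both conditions draw from the identical per-gene
    distribution, so under the pooled t-test the per-gene p values are exactly
    uniform and rejections at level alpha are Binomial(n_genes, alpha). Used
    to calibrate the type-I error of :func:`differential_expression`.
    """
    genes = pd.Index([f"g{i}" for i in range(n_genes)], name="gene")
    base = mean_rpm * rng.lognormal(0.0, baseline_sigma, n_genes)

    def draw() -> list[pd.Series]:
        return [
            pd.Series(base + rng.normal(0.0, rep_cv * base), index=genes)
            for _ in range(n_reps)
        ]

    return draw(), draw()


def simulate_depletion_tables(
    n_genes: int,
    depleted_genes: Sequence[str] | int,
    depletion_fold: float,
    depth: int,
    n_reps: int,
    rng: np.random.Generator,
    baseline_sigma: float = 0.5,
) -> tuple[list[pd.Series], list[pd.Series], list[str]]:
    """Count-level simulation of a 22G depletion experiment.

    Per gene, a shared log-normal baseline weight; the wild-type expected
    counts are ``depth x weight / sum(weights)``; in the mutant the depleted
    genes' expected counts are divided by ``depletion_fold`` (binomial-style
    thinning: the rest of the library is untouched, so the mutant's realized
    depth is smaller). Replicates are independent Poisson draws, converted to
    RPM on their own realized depth. Returns (wt_reps, mut_reps, depleted
    gene ids).
    """
    genes = [f"g{i}" for i in range(n_genes)]
    if isinstance(depleted_genes, int):
        depleted = list(rng.choice(genes, size=depleted_genes, replace=False))
    else:
        depleted = list(depleted_genes)
    dep_mask = np.isin(genes, depleted)
    base = rng.lognormal(0.0, baseline_sigma, n_genes)
    w_wt = base / base.sum()
    w_mut = np.where(dep_mask, w_wt / depletion_fold, w_wt)

    def draw(w: np.ndarray) -> list[pd.Series]:
        reps = []
        for _ in range(n_reps):
            counts = rng.poisson(depth * w).astype(float)
            total = counts.sum()
            reps.append(pd.Series(1e6 * counts / total, index=pd.Index(genes, name="gene")))
        return reps

    return draw(w_wt), draw(w_mut), depleted
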