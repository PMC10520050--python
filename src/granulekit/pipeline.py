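"""End-to-end orchestration: simulate, process, and report.

Each run writes its outputs plus a ``manifest.json`` recording the parameters
and package version, so every output file is re-derivable from the manifest
alone. A ``summary.json`` carries the headline numbers of the run in
machine-readable form. No step mutates its inputs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .annotations import AnnotationSet, FeatureIndex, derive_promoters, write_gff
from .chiptargets import call_targets, targets_to_tsv, write_peaks_bed
from .classify import (
    DEFAULT_RULES,
    GeneCountTable,
    classify_all,
    length_firstnt_profile,
    quantify_genes,
)
from .readproc import (
    GenomeIndex,
    align_reads,
    collapse_reads,
    filter_structural,
    group_by_read,
)
from .smallrna_stats import DEConfig, differential_22g, set_enrichment
from .synthdata import (
    SimConfig,
    make_genome,
    simulate_chip_peaks,
    simulate_granule_stack,
    simulate_small_rna_reads,
    write_fasta,
    write_fastq,
    write_truth,
)
from .volumetrics import (
    consensus_threshold,
    granules_to_csv,
    segment_granules,
    subtract_background,
    summarize_volumes,
)


@dataclass
class LibraryResult:
    """Read-level and gene-level outcome of one small-RNA library."""

    sample: str
    table: GeneCountTable
    outcome_by_sequence: dict[str, str]
    depth: int
    n_raw_reads: int
    n_structural: int
    n_unaligned: int
    n_dropped_max_hits: int
    profile: pd.DataFrame = field(repr=False, default=None)


def run_library(
    sequences: Sequence[str],
    genome: Mapping[str, str] | GenomeIndex,
    annots: AnnotationSet,
    sample: str = "sample",
    max_hits: int = 1000,
    rules=DEFAULT_RULES,
    findex: FeatureIndex | None = None,
) -> LibraryResult:
    """Collapse -> align -> structural filter -> classify -> quantify.

    ``outcome_by_sequence`` maps each unique read sequence to its read-level
    outcome: a class name, "unassigned", "structural", "unaligned", or
    "dropped_max_hits". Depth is the raw-read count with >=1 genomic
    alignment after structural filtering.
    """
    findex = findex or FeatureIndex(annots)
    collapsed, _ = collapse_reads(sequences)
    alignments, areport = align_reads(collapsed, genome, max_hits=max_hits)
    structural, retained = filter_structural(alignments, findex)

    by_read = group_by_read(retained)
    structural_ids = {a.read_id for a in structural}
    dropped_ids = set(areport.dropped_read_ids)

    retained_reads = [c for c in collapsed if c.id in by_read]
    classified = classify_all(retained_reads, by_read, findex, rules=rules)
    depth = sum(c.count for c in retained_reads)
    table = quantify_genes(classified, depth=depth, sample=sample)

    outcome: dict[str, str] = {}
    cls_by_id = {c.read_id: c.cls for c in classified}
    for c in collapsed:
        if c.id in structural_ids:
            outcome[c.sequence] = "structural"
        elif c.id in dropped_ids:
            outcome[c.sequence] = "dropped_max_hits"
        elif c.id in cls_by_id:
            outcome[c.sequence] = cls_by_id[c.id]
        else:
            outcome[c.sequence] = "unaligned"

    profile = length_firstnt_profile(retained_reads)
    return LibraryResult(
        sample=sample,
        table=table,
        outcome_by_sequence=outcome,
        depth=depth,
        n_raw_reads=sum(c.count for c in collapsed),
        n_structural=sum(c.count for c in collapsed if c.id in structural_ids),
        n_unaligned=areport.n_unaligned,
        n_dropped_max_hits=areport.n_dropped_max_hits,
        profile=profile,
    )


def _write_manifest(out_dir: Path, command: str, params: dict) -> None:
    manifest = {
        "tool": "granulekit",
        "version": __version__,
        "command": command,
        "parameters": params,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


def run_smallrna(
    config: SimConfig,
    out_dir: str | Path,
    n_reads: int = 20_000,
    de_config: DEConfig | None = None,
) -> dict:
    """Full synthetic small-RNA experiment: two conditions x replicates.

    Emits genome FASTA, GFF3, per-sample FASTQ + truth + gene tables, a
    differential 22G table, the depletion-set enrichment, length/first-nt
    profiles, and a summary JSON.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genome, annots = make_genome(config)
    write_fasta(genome, str(out / "genome.fa"))
    write_gff(annots, str(out / "annotations.gff3"))

    gindex = GenomeIndex(genome)
    findex = FeatureIndex(annots)

    tables: dict[str, list[GeneCountTable]] = {"wildtype": [], "mutant": []}
    depleted: list[str] = []
    for condition in ("wildtype", "mutant"):
        for rep in range(1, config.replicates_per_condition + 1):
            reads, truth = simulate_small_rna_reads(
                genome,
                annots,
                config,
                condition=condition,
                n_reads=n_reads,
                replicate=rep,
                genome_index=gindex,
            )
            name = f"{condition}_rep{rep}"
            write_fastq(reads, str(out / f"{name}.fastq"))
            write_truth(truth, str(out / f"{name}.truth.tsv"))
            result = run_library(
                [r.sequence for r in reads], gindex, annots, sample=name, findex=findex
            )
            result.table.to_tsv(str(out / f"{name}.counts.tsv"))
            result.profile.to_csv(out / f"{name}.profile.tsv", sep="\t")
            tables[condition].append(result.table)

    from .synthdata import _TruthPicker

    depleted = _TruthPicker(config, annots).depleted

    de_config = de_config or DEConfig()
    de = differential_22g(tables["wildtype"], tables["mutant"], de_config)
    de.to_csv(out / "differential_22g.tsv", sep="\t")

    universe = list(de.index)
    down = list(de.index[de["call"] == "down"])
    enr = set_enrichment(down, depleted, universe, set_name="depleted_truth")
    pd.DataFrame([enr.as_dict()]).to_csv(out / "enrichment.tsv", sep="\t", index=False)

    down_set = set(down)
    dep_set = set(depleted) & set(universe)
    summary = {
        "n_genes_tested": len(universe),
        "n_down": len(down),
        "n_up": int((de["call"] == "up").sum()),
        "depletion_recall": (
            len(down_set & dep_set) / len(dep_set) if dep_set else float("nan")
        ),
        "depletion_precision": (
            len(down_set & dep_set) / len(down_set) if down_set else float("nan")
        ),
        "depleted_set_log2_enrichment": enr.log2_enrichment,
        "depleted_set_fisher_p": enr.p,
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    _write_manifest(
        out,
        "smallrna",
        {"sim": asdict(config), "n_reads": n_reads, "de": asdict(de_config)},
    )
    return summary


def run_chip(config: SimConfig, out_dir: str | Path, n_targets: int = 20) -> dict:
    """Synthetic ChIP target definition: simulate peaks, call targets."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _genome, annots = make_genome(config)
    write_gff(annots, str(out / "annotations.gff3"))
    promoters, _skipped = derive_promoters(annots)
    rng = np.random.default_rng([config.seed, 4])
    from .synthdata import resolvable_target_genes

    eligible = resolvable_target_genes(annots)
    targets_true = sorted(rng.choice(eligible, size=min(n_targets, len(eligible)), replace=False))
    rep1, rep2 = simulate_chip_peaks(annots, targets_true, config, rng=rng)
    write_peaks_bed(rep1, str(out / "peaks_rep1.bed"))
    write_peaks_bed(rep2, str(out / "peaks_rep2.bed"))
    calls, called = call_targets(rep1, rep2, promoters)
    targets_to_tsv(calls, str(out / "targets.tsv"))
    summary = {
        "n_true_targets": len(targets_true),
        "n_called_targets": len(called),
        "n_recovered": len(called & set(targets_true)),
        "exact_recovery": called == set(targets_true),
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    _write_manifest(out, "chip", {"sim": asdict(config), "n_targets": n_targets})
    return summary


def run_volumes(config: SimConfig, out_dir: str | Path, n_nuclei: int = 15) -> dict:
    """Synthetic granule volumetry: wild-type vs mutant nuclei plus a rachis
    region, using the wild-type consensus Li threshold throughout."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng([config.seed, 5])

    def nucleus(radius_mean: float, n_spheres: int, sid: str):
        spheres = []
        for _ in range(n_spheres):
            r = float(rng.uniform(0.85, 1.15)) * radius_mean
            c = tuple(float(x) for x in rng.uniform(2.0, 6.0, size=3))
            spheres.append((c, r))
        stack, truth = simulate_granule_stack(spheres, rng=rng, stack_id=sid)
        return subtract_background(stack, stack.data[:2, :5, :5]), truth

    groups = {"wildtype_nucleus": 0.48, "mutant_nucleus": 0.35, "mutant_rachis": 0.60}
    stacks: dict[str, list] = {g: [] for g in groups}
    for gname, r in groups.items():
        for i in range(n_nuclei if gname != "mutant_rachis" else 4):
            stacks[gname].append(nucleus(r, 4, f"{gname}_{i+1}"))

    threshold = consensus_threshold([s for s, _ in stacks["wildtype_nucleus"]])
    records = {g: [] for g in groups}
    for gname in groups:
        for stack, _truth in stacks[gname]:
            records[gname].extend(segment_granules(stack, threshold))
        granules_to_csv(records[gname], str(out / f"{gname}.granules.csv"))
    summary_df = summarize_volumes(records)
    summary_df.to_csv(out / "volume_summary.tsv", sep="\t")
    summary = {
        "consensus_threshold": threshold,
        "mean_volume_um3": summary_df["mean_volume_um3"].to_dict(),
        "fold_wt_over_mutant_nucleus": float(
            summary_df.loc["wildtype_nucleus", "fold_vs_mutant_nucleus"]
        ),
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    _write_manifest(out, "volumes", {"sim": asdict(config), "n_nuclei": n_nuclei})
    return summary
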