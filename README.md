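# granulekit

Small-RNA class calling and statistics for *C. elegans* germ-granule studies,
with a ground-truth synthetic-data generator, operon-aware ChIP-seq target
definition, and 3D germ-granule volumetry.

## What it does

Perinuclear germ granules (P granules, Z granules, Mutator foci) organize
small-RNA biogenesis in the *C. elegans* germ line. Comparing small-RNA
libraries between wild-type animals and germ-granule mutants requires a
chain of well-defined computational steps, each with sharp, convention-laden
rules. `granulekit` implements that chain as a tested, reusable library:

* **Read processing** — collapse raw FASTA/FASTQ reads to unique sequences
  with counts; enumerate every perfect (0-mismatch) genomic occurrence on
  both strands with multi-mapping up to 1000 locations (reads beyond that
  are dropped and tallied); partition out reads touching structural-RNA
  annotations (snRNA, snoRNA, tRNA, ncRNA).
* **Class calling** —
  * *piRNA (21U-RNA)*: unique, perfect, sense to a piRNA locus, 5′ T,
    15–40 nt, 5′ end at offset 0–2 of the locus's annotated 5′ end;
  * *22G-RNA*: 21–23 nt, 5′ G or A, antisense to protein-coding exons,
    pseudogene exons, lincRNAs, rRNAs, or transposons, multi-mapping
    allowed;
  * *26G-RNA*: 25–27 nt, 5′ G, antisense to protein-coding exons
    (configurable, as conventions for this class vary).

  A read of count *c* with *n* genomic locations contributes
  *c* · (1/*n*) · (1/*f*) to each of the *f* eligible features at a
  location; rRNA takes the whole location weight where it overlaps another
  gene. Per-gene totals are scaled to reads per million genome-mapped reads
  (RPM).
* **Statistics** — per-gene two-tailed t-tests on replicate RPMs with
  log₂FC = log₂((mutant + pc)/(wild type + pc)) and four-fold/α = 0.05
  calls; gene-set fold enrichment
  log₂[(|DE ∩ S|/|DE|) / (|U ∩ S|/|U|)] with two-sided Fisher's exact p;
  median-abundance folds; periodate-oxidation enrichment summaries
  (2′-O-methylated piRNAs survive oxidation, unmethylated RNAs do not).
* **ChIP targets** — promoters are 1 kb upstream of the 5′UTR start
  (operon members inherit the first gene's promoter); a gene is a target
  only when a q < 0.1 peak overlaps its promoter in both replicates.
* **Volumetry** — background subtraction, Li (minimum cross-entropy)
  thresholding of wild-type max projections, the median threshold applied
  to all stacks, 26-connected 3D components, volumes in µm³.
* **Synthetic data** — every input above can be generated with truth
  labels (class templates, depleted gene sets, methylation flags, planted
  ChIP targets, analytic sphere volumes), so the whole pipeline is testable
  without downloads.

## Worked example

```python
from granulekit import SimConfig, make_genome
from granulekit.pipeline import run_library
from granulekit.synthdata import simulate_small_rna_reads

config = SimConfig(seed=1)
genome, annots = make_genome(config)
reads, truth = simulate_small_rna_reads(genome, annots, config, n_reads=20_000)
result = run_library([r.sequence for r in reads], genome, annots, sample="wildtype_rep1")

print(f"depth (genome-mapped reads): {result.depth}")
print(f"structural-RNA reads removed: {result.n_structural}")
print(result.table.df.groupby("cls")["raw"].agg(["count", "sum"]).round(1))
```

```
depth (genome-mapped reads): 19016
structural-RNA reads removed: 984
       count     sum
cls
22G      110  9035.0
26G       27  1945.0
piRNA     60  6038.0
```

19,016 of 20,000 simulated reads map to the genome after the structural
filter (the 984 removed reads are the simulated tRNA/snoRNA/... fraction);
the fractional class counts recover the simulated class mix (45% 22G, 30%
piRNA, 10% 26G; the remaining reads are deliberate background and stay
unassigned). The length × 5′-base profile (`result.profile`) shows the
expected modes: 21 nt/T for piRNAs, 21–23 nt/G+A for 22G-RNAs, 26 nt/G for
26G-RNAs.

Differential analysis on a simulated four-fold 22G depletion:

```python
import numpy as np
from granulekit import DEConfig
from granulekit.smallrna_stats import (
    differential_expression, set_enrichment, simulate_depletion_tables,
)

rng = np.random.default_rng(1)
wt, mut, depleted = simulate_depletion_tables(
    n_genes=2000, depleted_genes=200, depletion_fold=4.0,
    depth=100_000, n_reps=2, rng=rng,
)
de = differential_expression(wt, mut, DEConfig())
down = set(de.index[de["call"] == "down"])
enr = set_enrichment(down, depleted, list(de.index), set_name="depleted_truth")
print(f"down-called genes: {len(down)} of {len(de)}")
print(f"log2 fold enrichment: {enr.log2_enrichment:.2f}   Fisher p: {enr.p:.3g}")
```

```
down-called genes: 80 of 2000
log2 fold enrichment: 3.32   Fisher p: 4.84e-88
```

All 80 down-called genes lie in the planted 200-gene set — the call is
perfectly precise, while a true fold sitting exactly at the four-fold call
threshold caps recall near 50% (see `docs/methods.md`).

There is also a CLI (`granulekit simulate|classify|stats|chip|volumes|demo`);
`granulekit demo --seed 0 --out-dir demo/` runs the full synthetic pipeline
end to end in about a minute.

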