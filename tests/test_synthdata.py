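"""Generator contracts: determinism, layout guarantees, class templates,
oxidation thinning, and granule-stack truth."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from granulekit.annotations import read_gff, write_gff
from granulekit.synthdata import (
    SimConfig,
    SizingError,
    apply_oxidation,
    make_genome,
    simulate_granule_stack,
    simulate_small_rna_reads,
    write_fasta,
    write_fastq,
)


class TestConfig:
    def test_class_mix_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            SimConfig(class_mix={"piRNA": 0.5, "22G": 0.6})

    def test_bad_survival_rejected(self):
        with pytest.raises(ValueError, match="probability"):
            SimConfig(methylated_survival=1.5)


class TestMakeGenome:
    def test_deterministic_bytes(self, tmp_path, sim_config):
        paths = []
        for run in ("a", "b"):
            genome, annots = make_genome(sim_config)
            fa = tmp_path / f"{run}.fa"
            gff = tmp_path / f"{run}.gff3"
            write_fasta(genome, str(fa))
            write_gff(annots, str(gff))
            paths.append((fa.read_bytes(), gff.read_bytes()))
        assert paths[0] == paths[1]

    def test_operon_has_two_plus_members(self, tmp_path, sim_config):
        _, annots = make_genome(sim_config)
        gff = tmp_path / "x.gff3"
        write_gff(annots, str(gff))
        back = read_gff(str(gff))
        assert back.operons and all(len(op.members) >= 2 for op in back.operons)

    def test_rrna_overlaps_coding_gene_in_emitted_gff(self, tmp_path, sim_config):
        _, annots = make_genome(sim_config)
        gff = tmp_path / "x.gff3"
        write_gff(annots, str(gff))
        back = read_gff(str(gff))
        rrnas = back.by_biotype("rRNA")
        coding = back.by_biotype("protein_coding")
        assert any(
            r.contig == g.contig and r.start < g.end and g.start < r.end
            for r in rrnas
            for g in coding
        )

    def test_too_small_contig_raises_sizing_error(self):
        with pytest.raises(SizingError, match="contig_length"):
            make_genome(SimConfig(contig_length=5000))

    def test_every_gene_has_strand_exons_utr(self, annots):
        for gene in annots.genes():
            assert gene.strand in "+-"
            assert gene.exons
            assert gene.utr5_start is not None


class TestReadSimulation:
    def test_pure_pirna_mix_template(self, genome, annots, sim_config, gindex):
        cfg = replace(
            sim_config,
            class_mix={"piRNA": 1.0, "22G": 0.0, "26G": 0.0,
                       "structural": 0.0, "background": 0.0},
        )
        reads, truth = simulate_small_rna_reads(
            genome, annots, cfg, n_reads=500, genome_index=gindex
        )
        assert all(len(r.sequence) == 21 for r in reads)
        assert all(r.sequence[0] == "T" for r in reads)
        assert (truth["true_class"] == "piRNA").all()
        assert truth["methylated"].all()

    def test_depletion_expected_ratio(self, genome, annots, sim_config, gindex):
        """Binomial thinning forces E[mutant]/E[wildtype] = 1/fold for the
        depleted genes."""
        from granulekit.synthdata import _TruthPicker

        picker = _TruthPicker(sim_config, annots)
        counts = {}
        for condition in ("wildtype", "mutant"):
            tallies = []
            for rep in range(1, 9):
                _, truth = simulate_small_rna_reads(
                    genome, annots, sim_config, condition=condition,
                    n_reads=4000, replicate=rep, genome_index=gindex,
                )
                t22 = truth[truth["true_class"] == "22G"]
                tallies.append(t22["feature_id"].value_counts())
            counts[condition] = pd.concat(tallies, axis=1).fillna(0).sum(axis=1)
        dep = picker.depleted
        ratio = counts["mutant"].reindex(dep).sum() / counts["wildtype"].reindex(dep).sum()
        assert ratio == pytest.approx(1.0 / sim_config.depletion_fold, rel=0.15)

    def test_fixed_seed_identical_fastq(self, tmp_path, genome, annots, sim_config, gindex):
        outs = []
        for run in ("a", "b"):
            reads, _ = simulate_small_rna_reads(
                genome, annots, sim_config, n_reads=1000, genome_index=gindex
            )
            path = tmp_path / f"{run}.fastq"
            write_fastq(reads, str(path))
            outs.append(path.read_bytes())
        assert outs[0] == outs[1]

    def test_zero_loci_with_nonzero_proportion_errors(self, sim_config):
        from granulekit.annotations import AnnotationSet, Feature

        bare = AnnotationSet(
            {"c": 10_000},
            [Feature("g", "c", 100, 900, "+", "protein_coding", utr5_start=100)],
        )
        with pytest.raises(ValueError, match="piRNA"):
            simulate_small_rna_reads({"c": "A" * 10_000}, bare, sim_config, n_reads=10)

    def test_truth_label_closure(self, genome, annots, sim_config, gindex, findex):
        """Every read has exactly one truth label, and the classifier agrees
        on unambiguously generated reads."""
        from granulekit.pipeline import run_library

        reads, truth = simulate_small_rna_reads(
            genome, annots, sim_config, n_reads=3000, genome_index=gindex
        )
        assert len(truth) == len(reads)
        assert truth["read_id"].is_unique
        result = run_library(
            [r.sequence for r in reads], gindex, annots, findex=findex
        )
        expected = truth["true_class"].replace({"background": "unassigned"})
        outcome = [result.outcome_by_sequence[r.sequence] for r in reads]
        assert (np.array(outcome) == expected.to_numpy()).all()


class TestOxidation:
    def _reads(self, genome, annots, cfg, gindex, n=2000):
        reads, _ = simulate_small_rna_reads(
            genome, annots, cfg, n_reads=n, genome_index=gindex
        )
        return reads

    def test_degenerate_probabilities_keep_only_methylated(
        self, genome, annots, sim_config, gindex
    ):
        cfg = replace(sim_config, methylated_survival=1.0, unmethylated_survival=0.0)
        reads = self._reads(genome, annots, cfg, gindex)
        out = apply_oxidation(reads, cfg)
        assert out == [r for r in reads if r.methylated]

    def test_survival_fractions_within_3sd(self, genome, annots, sim_config, gindex, rng):
        reads = self._reads(genome, annots, sim_config, gindex, n=8000)
        out = apply_oxidation(reads, sim_config, rng=rng)
        for methylated, p in ((True, 0.95), (False, 0.05)):
            n = sum(1 for r in reads if r.methylated == methylated)
            k = sum(1 for r in out if r.methylated == methylated)
            sd = np.sqrt(p * (1 - p) * n)
            assert abs(k - p * n) <= 3 * sd

    def test_empty_input_empty_output(self, sim_config):
        assert apply_oxidation([], sim_config) == []

    def test_output_sequences_subset_of_input(self, genome, annots, sim_config, gindex):
        reads = self._reads(genome, annots, sim_config, gindex)
        out = apply_oxidation(reads, sim_config)
        assert {r.sequence for r in out} <= {r.sequence for r in reads}

    def test_invalid_probability_rejected(self, genome, annots, sim_config, gindex):
        cfg = replace(sim_config)
        cfg.methylated_survival = 1.2  # mutate after construction
        with pytest.raises(ValueError, match="survival"):
            apply_oxidation([], cfg)


class TestGranuleStack:
    def test_analytic_truth_volume(self):
        _, truth = simulate_granule_stack([((4.0, 4.0, 4.0), 0.5)])
        assert truth["volume_um3"].iloc[0] == pytest.approx(
            4.0 / 3.0 * np.pi * 0.5**3
        )

    def test_voxelization_oracle_noise_free(self):
        """With no blur and no noise, voxel count x voxel volume matches the
        analytic sphere volume to within one voxel shell."""
        stack, truth = simulate_granule_stack(
            [((4.0, 4.0, 4.0), 0.8)],
            shape=(40, 80, 80),
            blur_sigma_um=0.0,
            poisson_noise=False,
            background=0.0,
        )
        n_vox = int((stack.data > 0).sum())
        measured = n_vox * stack.voxel_volume
        r, (dz, dy, dx) = 0.8, stack.voxel_size
        shell = 4 * np.pi * r**2 * max(dz, dy, dx)  # one-voxel surface shell
        assert abs(measured - truth["volume_um3"].iloc[0]) < shell

    def test_two_disjoint_spheres_two_truth_rows(self):
        _, truth = simulate_granule_stack(
            [((2.0, 2.0, 2.0), 0.4), ((6.0, 6.0, 6.0), 0.4)]
        )
        assert len(truth) == 2 and truth["granule_id"].is_unique

    def test_deterministic_with_fixed_rng(self):
        a, _ = simulate_granule_stack(
            [((4.0, 4.0, 4.0), 0.5)], rng=np.random.default_rng(3)
        )
        b, _ = simulate_granule_stack(
            [((4.0, 4.0, 4.0), 0.5)], rng=np.random.default_rng(3)
        )
        np.testing.assert_array_equal(a.data, b.data)
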