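"""Generators: seed determinism, truth conservation, statistical calibration."""

import math

import numpy as np
import pandas as pd
import pytest

from halomag import (CommunitySpec, GenomeSpec, ProteomeSpec, ValidationError,
                     generate_annotation_table, generate_genome,
                     generate_proteome, generate_quality_table,
                     load_pathway_defs, mutate_genome, quality_tier, revcomp,
                     simulate_reads)


class TestGenerateGenome:
    def test_seed_determinism_and_alphabet(self):
        a = generate_genome(GenomeSpec("g", 1000, gc=0.5, seed=1))
        b = generate_genome(GenomeSpec("g", 1000, gc=0.5, seed=1))
        assert a.sequence == b.sequence
        assert set(a.sequence) <= set("ACGT")
        assert a.length == 1000

    def test_gc_one_forces_gc_alphabet(self):
        g = generate_genome(GenomeSpec("g", 10, gc=1.0, seed=2))
        assert set(g.sequence) <= set("GC")

    def test_gc_calibration_within_three_standard_errors(self):
        n, gc = 100_000, 0.4
        g = generate_genome(GenomeSpec("g", n, gc=gc, seed=3))
        observed = sum(g.sequence.count(b) for b in "GC") / n
        se = math.sqrt(gc * (1 - gc) / n)
        assert abs(observed - gc) <= 3 * se

    @pytest.mark.parametrize("length,gc", [(0, 0.5), (-5, 0.5), (10, 1.5), (10, -0.1)])
    def test_invalid_specs_rejected(self, length, gc):
        with pytest.raises(ValidationError):
            GenomeSpec("g", length, gc=gc)


class TestMutateGenome:
    def test_zero_rates_identity(self, small_genome):
        mut, truth = mutate_genome(small_genome, 0.0, 0.0, seed=4)
        assert mut.sequence == small_genome.sequence
        assert truth.realized_subs == 0 and truth.realized_indels == 0

    def test_realized_substitutions_binomial_envelope(self):
        n, rate = 100_000, 0.05
        g = generate_genome(GenomeSpec("g", n, seed=5))
        _, truth = mutate_genome(g, rate, 0.0, seed=6)
        sd = math.sqrt(n * rate * (1 - rate))
        assert abs(truth.realized_subs - n * rate) <= 3 * sd

    def test_seed_determinism(self, small_genome):
        m1, _ = mutate_genome(small_genome, 0.03, 0.001, seed=7)
        m2, _ = mutate_genome(small_genome, 0.03, 0.001, seed=7)
        assert m1.sequence == m2.sequence

    def test_rate_one_rejected(self, small_genome):
        with pytest.raises(ValidationError):
            mutate_genome(small_genome, 1.0, 0.0, seed=1)


class TestSimulateReads:
    def test_error_free_reads_are_substrings(self, small_genome):
        spec = CommunitySpec((("ref", 1.0),), n_reads=50, read_length=100, seed=8)
        reads, truth = simulate_reads(spec, {"ref": small_genome})
        seq = small_genome.sequence
        for read, row in zip(reads, truth.itertuples()):
            fwd = read.sequence if row.strand == "+" else revcomp(read.sequence)
            assert seq[row.start:row.start + 100] == fwd

    def test_source_proportions_follow_weight_times_length(self):
        g1 = generate_genome(GenomeSpec("a", 5000, seed=9))
        g2 = generate_genome(GenomeSpec("b", 5000, seed=10))
        spec = CommunitySpec((("a", 3.0), ("b", 1.0)), n_reads=100_000,
                             read_length=100, seed=11)
        _, truth = simulate_reads(spec, {"a": g1, "b": g2})
        n_a = (truth["source"] == "a").sum()
        sd = math.sqrt(100_000 * 0.75 * 0.25)
        assert abs(n_a - 75_000) <= 3 * sd

    def test_zero_reads_and_truth_conservation(self, small_genome):
        spec = CommunitySpec((("ref", 1.0),), n_reads=0, read_length=100, seed=12)
        reads, truth = simulate_reads(spec, {"ref": small_genome})
        assert reads == [] and truth.empty
        spec = CommunitySpec((("ref", 1.0),), n_reads=17, read_length=100, seed=13)
        reads, truth = simulate_reads(spec, {"ref": small_genome})
        assert len(reads) == len(truth) == 17
        assert [r.id for r in reads] == list(truth["read"])

    def test_read_longer_than_genome_rejected(self, small_genome):
        spec = CommunitySpec((("ref", 1.0),), n_reads=1,
                             read_length=small_genome.length + 1, seed=1)
        with pytest.raises(ValidationError):
            simulate_reads(spec, {"ref": small_genome})


class TestGenerateProteome:
    def test_zero_enrichment_has_no_acidic_residues(self):
        prot = generate_proteome(ProteomeSpec(20, (50, 100), 0.0, seed=14))
        assert all("D" not in s and "E" not in s for _, s in prot)

    def test_lengths_alphabet_and_determinism(self):
        spec = ProteomeSpec(30, (80, 120), 0.2, seed=15)
        p1, p2 = generate_proteome(spec), generate_proteome(spec)
        assert p1 == p2
        for _, seq in p1:
            assert 80 <= len(seq) <= 120
            assert set(seq) <= set("ACDEFGHIKLMNPQRSTVWY")

    def test_acidic_fraction_calibration(self):
        target = 0.4
        prot = generate_proteome(ProteomeSpec(100, (300, 300), target, seed=16))
        residues = "".join(s for _, s in prot)
        frac = sum(residues.count(a) for a in "DE") / len(residues)
        se = math.sqrt(target * (1 - target) / len(residues))
        assert abs(frac - target) <= 3 * se


class TestAnnotationTable:
    def test_plan_fractions_realized_with_floor(self):
        defs = load_pathway_defs()
        plan = {("g1", "emp_glycolysis"): 1.0, ("g2", "emp_glycolysis"): 0.0,
                ("g3", "emp_glycolysis"): 0.5}
        table, truth = generate_annotation_table(["g1", "g2", "g3"], defs, plan, seed=17)
        n_req = len(defs["emp_glycolysis"].required)
        counts = table.groupby("genome").size().reindex(["g1", "g2", "g3"], fill_value=0)
        assert counts["g1"] == n_req
        assert counts["g2"] == 0
        assert counts["g3"] == int(np.floor(0.5 * n_req))
        assert (truth["realized"] == truth["included"] / n_req).all()

    def test_unknown_pathway_rejected(self):
        with pytest.raises(ValidationError):
            generate_annotation_table(["g1"], load_pathway_defs(),
                                      {("g1", "nope"): 1.0}, seed=1)


def test_quality_table_tier_counts_recoverable():
    counts = {"near_complete": 4, "medium": 7, "fail": 3}
    table = generate_quality_table(counts, seed=18)
    tiers = pd.Series([quality_tier(c, r) for c, r in
                       zip(table["completeness"], table["contamination"])])
    assert tiers.value_counts().to_dict() == counts
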