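import numpy as np
import pytest

from mitodate.reads import reverse_complement
from mitodate.simulate import (
    AmplificationModel, DamageModel, FragmentModel, amplify_and_sequence,
    apply_damage, evolve_sequences, fragmentize, inject_errors, Fragment,
)
from mitodate.substmodel import SubstModel
from mitodate.trees import Tree


class TestEvolve:
    def test_zero_branch_gives_identical_child(self, jc):
        t = Tree.from_newick("(A:0.0,B:0.5);")
        sim = evolve_sequences(t, jc, length=500, seed=0)
        root = sim.sequences[sim.internal_names[0]]
        assert sim.sequences["A"] == root

    def test_jc_expected_divergence(self, jc):
        # two-taxon JC, 0.1 subst/site each branch: closed-form p-distance
        t = Tree.from_newick("(A:0.1,B:0.1);")
        sim = evolve_sequences(t, jc, length=20_000, seed=11)
        a, b = sim.sequences["A"], sim.sequences["B"]
        p = np.mean([x != y for x, y in zip(a, b)])
        expected = 0.75 * (1 - np.exp(-4 * 0.2 / 3))
        assert p == pytest.approx(expected, abs=3 * np.sqrt(expected * (1 - expected) / 20_000))

    def test_saturation_approaches_quarter_identity(self, jc):
        t = Tree.from_newick("(A:15,B:15);")
        sim = evolve_sequences(t, jc, length=20_000, seed=5)
        ident = np.mean([x == y for x, y in
                         zip(sim.sequences["A"], sim.sequences["B"])])
        assert ident == pytest.approx(0.25, abs=0.01)

    def test_internal_sequences_returned(self, jc):
        t = Tree.from_newick("((A:0.1,B:0.1)ab:0.1,C:0.2);")
        sim = evolve_sequences(t, jc, length=100, seed=0)
        assert "ab" in sim.internals()
        assert len(sim.internals()["ab"]) == 100

    def test_partitioned_lengths(self, jc):
        t = Tree.from_newick("(A:0.1,B:0.1);")
        spec = [("x", 30, jc), ("y", 70, SubstModel.jc(ncat=4, alpha=0.3))]
        sim = evolve_sequences(t, partition_spec=spec, seed=0)
        assert len(sim.sequences["A"]) == 100
        assert len(sim.partitions["x"]) == 30

    def test_determinism(self, jc):
        t = Tree.from_newick("(A:0.1,B:0.1);")
        s1 = evolve_sequences(t, jc, length=200, seed=9).sequences
        s2 = evolve_sequences(t, jc, length=200, seed=9).sequences
        assert s1 == s2

    def test_bad_frequencies_rejected(self):
        with pytest.raises(ValueError):
            SubstModel(np.ones(6), np.array([0.3, 0.3, 0.3, 0.3]))


class TestFragmentize:
    def test_zero_templates_empty(self):
        assert fragmentize("ACGT" * 100, FragmentModel(), 0) == []

    def test_hard_length_bounds(self):
        fm = FragmentModel(min_len=30, max_len=76)
        frags = fragmentize("ACGT" * 500, fm, 2000, seed=1)
        lens = [f.length for f in frags]
        assert min(lens) >= 30 and max(lens) <= 76

    def test_empirical_mean_matches_model(self):
        fm = FragmentModel()
        frags = fragmentize("ACGT" * 500, fm, 10_000, seed=2)
        mean = np.mean([f.length for f in frags])
        assert mean == pytest.approx(fm.truncated_mean, abs=0.5)

    def test_min_length_exceeding_genome_rejected(self):
        with pytest.raises(ValueError):
            fragmentize("ACGTACGT", FragmentModel(min_len=30, max_len=40,
                                                  mean=35), 10)

    def test_circular_wrap_coordinates(self):
        genome = "A" * 90 + "C" * 10
        fm = FragmentModel(family="constant", mean=20, min_len=20, max_len=20)
        frags = fragmentize(genome, fm, 500, seed=3)
        doubled = genome + genome
        for f in frags:
            expect = doubled[f.start:f.start + f.length]
            if f.strand == "-":
                expect = reverse_complement(expect)
            assert f.seq == expect

    def test_determinism(self):
        a = fragmentize("ACGT" * 100, FragmentModel(), 50, seed=4)
        b = fragmentize("ACGT" * 100, FragmentModel(), 50, seed=4)
        assert a == b


class TestDamage:
    def _frags(self, n=50_000, seed=0):
        return fragmentize("ACGT" * 400, FragmentModel(), n, seed=seed)

    def test_no_damage_is_identity(self):
        frags = self._frags(200)
        out = apply_damage(frags, DamageModel(0, 0, 0.3, 0), seed=1)
        assert [f.seq for f in out] == [f.seq for f in frags]

    def test_certain_terminal_deamination(self):
        # delta5=1 with instant decay: a terminal C always reads T, rest intact
        frags = [Fragment("t0", "CCGA", 0, 4, "+")]
        out = apply_damage(frags, DamageModel(1.0, 0.0, 50.0, 0.0), seed=0)
        assert out[0].seq == "TCGA"

    def test_terminal_ct_frequency_matches_model(self):
        dm = DamageModel(delta5=0.3, delta3=0.0, lam=0.3, epsilon=0.0)
        frags = self._frags()
        out = apply_damage(frags, dm, seed=7)
        n_c = sum(1 for f in frags if f.seq[0] == "C")
        n_ct = sum(1 for f0, f1 in zip(frags, out)
                   if f0.seq[0] == "C" and f1.seq[0] == "T")
        se = np.sqrt(0.3 * 0.7 / n_c)
        assert n_ct / n_c == pytest.approx(0.3, abs=4 * se)

    def test_decay_curve_second_position(self):
        dm = DamageModel(delta5=0.3, delta3=0.0, lam=0.3, epsilon=0.0)
        frags = self._frags()
        out = apply_damage(frags, dm, seed=8)
        n_c = sum(1 for f in frags if f.seq[1] == "C")
        n_ct = sum(1 for f0, f1 in zip(frags, out)
                   if f0.seq[1] == "C" and f1.seq[1] == "T")
        expect = 0.3 * np.exp(-0.3)
        se = np.sqrt(expect * (1 - expect) / n_c)
        assert n_ct / n_c == pytest.approx(expect, abs=4 * se)

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError):
            DamageModel(delta5=1.2)


class TestAmplify:
    def test_degenerate_multiplicity_reads_equal_fragments(self):
        frags = fragmentize("ACGT" * 100, FragmentModel(), 50, seed=0)
        reads = amplify_and_sequence(frags, AmplificationModel("constant", 1.0),
                                     seed=1)
        assert [r.seq for r in reads] == [f.seq for f in frags]

    def test_expected_read_count(self):
        frags = fragmentize("ACGT" * 100, FragmentModel(), 5000, seed=0)
        amp = AmplificationModel(mean=3.0)
        reads = amplify_and_sequence(frags, amp, seed=2)
        # reads ~ sum of 5000 zero-truncated geometrics with mean 3
        sd = np.sqrt(5000 * 3.0 * 2.0)  # var of geometric = (1-p)/p^2 = 6
        assert len(reads) == pytest.approx(15_000, abs=4 * sd)

    def test_duplicates_share_template_coordinates(self):
        frags = fragmentize("ACGT" * 100, FragmentModel(), 200, seed=0)
        reads = amplify_and_sequence(frags, AmplificationModel(mean=4.0), seed=3)
        by_template = {}
        for r in reads:
            key = r.meta["template_id"]
            coords = (r.meta["start"], r.meta["length"], r.meta["strand"])
            by_template.setdefault(key, set()).add(coords)
        assert all(len(v) == 1 for v in by_template.values())


class TestInjectErrors:
    def test_zero_rate_identity(self):
        s = "ACGTN-ACGT"
        assert inject_errors(s, 0.0, seed=0) == s

    def test_rate_one_changes_every_base(self):
        s = "ACGT" * 25
        out = inject_errors(s, 1.0, seed=1)
        assert all(a != b for a, b in zip(s, out))
        assert "N" not in out

    def test_n_and_gap_untouched(self):
        s = "N-N-" * 30
        assert inject_errors(s, 1.0, seed=2) == s

    def test_one_percent_binomial_count(self):
        # 13,000 sites at 1%: change count within 3 SD of 130
        s = "ACGT" * 3250
        sd = np.sqrt(13_000 * 0.01 * 0.99)
        for seed in range(5):
            out = inject_errors(s, 0.01, seed=seed)
            n = sum(a != b for a, b in zip(s, out))
            assert abs(n - 130) <= 3 * sd

    def test_reads_variant(self):
        from mitodate.reads import Read
        reads = [Read("r1", "ACGT" * 10)]
        out = inject_errors(reads, 0.0, seed=0)
        assert out[0].seq == reads[0].seq


class TestRoundTrip:
    def test_clean_reads_reconstruct_genome(self, jc):
        # no damage, multiplicity 1: reads match the genome wherever covered
        genome = evolve_sequences(Tree.from_newick("(A:0.0,B:0.0);"), jc,
                                  length=400, seed=3).sequences["A"]
        frags = fragmentize(genome, FragmentModel(), 300, seed=4)
        doubled = genome + genome
        for f in frags:
            seq = f.seq if f.strand == "+" else reverse_complement(f.seq)
            assert doubled[f.start:f.start + f.length] == seq
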