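"""Pruning likelihood, branch-length MLEs and ancestral states vs. oracles.

The independent oracle used throughout is exhaustive enumeration over
internal-node state assignments (feasible for <= 5 taxa), written directly in
this file and sharing nothing with the pruning implementation beyond the
transition matrices.
"""

import itertools

import numpy as np
import pytest

from conftest import random_subst_model
from mitodate.likelihood import (
    SupermatrixLikelihood, marginal_ancestral, mask_missing,
    optimize_branch_lengths, pruning_loglik,
)
from mitodate.simulate import evolve_sequences
from mitodate.substmodel import BASE_INDEX, SubstModel, transition_matrix
from mitodate.supermatrix import Supermatrix
from mitodate.trees import Tree


# ---------------------------------------------------------------- the oracle
def enumeration_loglik(matrix: Supermatrix, tree: Tree, model: SubstModel):
    """Brute-force likelihood: sum over all internal-state assignments."""
    rates, weights = model.mixture()
    internals = [v for v in range(tree.n_nodes) if not tree.is_tip[v]]
    tips = {tree.names[v]: v for v in range(tree.n_nodes) if tree.is_tip[v]}
    total = 0.0
    for si in range(matrix.n_sites):
        site_lik = 0.0
        for rate, w in zip(rates, weights):
            P = {v: transition_matrix(model, tree.lengths[v] * rate)
                 for v in range(tree.n_nodes) if tree.parent[v] >= 0}
            cat_lik = 0.0
            for assignment in itertools.product(range(4), repeat=len(internals)):
                states = dict(zip(internals, assignment))
                p = model.freqs[states[tree.root]]
                for v in range(tree.n_nodes):
                    pa = tree.parent[v]
                    if pa < 0:
                        continue
                    if tree.is_tip[v]:
                        obs = matrix.row(tree.names[v])[si]
                        if obs in BASE_INDEX:
                            p *= P[v][states[pa], BASE_INDEX[obs]]
                        # ambiguous tip: sum over states = row sum = 1
                    else:
                        p *= P[v][states[pa], states[v]]
                cat_lik += p
            site_lik += w * cat_lik
        total += np.log(site_lik)
    return total


def random_instance(seed, n_taxa, n_sites=12, ncat=1, p_inv=0.0,
                    with_ambiguity=True):
    rng = np.random.default_rng(seed)
    model = random_subst_model(rng, ncat=ncat, p_inv=p_inv)
    names = [chr(65 + i) for i in range(n_taxa)]
    # random rooted topology by sequential attachment
    newick = f"({names[0]}:{rng.uniform(0.01, 0.5):.3f},{names[1]}:{rng.uniform(0.01, 0.5):.3f})"
    for n in names[2:]:
        newick = f"({newick}:{rng.uniform(0.01, 0.5):.3f},{n}:{rng.uniform(0.01, 0.5):.3f})"
    tree = Tree.from_newick(newick + ";")
    alphabet = list("ACGT") + (["N", "-"] if with_ambiguity else [])
    probs = [0.22, 0.22, 0.22, 0.22, 0.06, 0.06] if with_ambiguity else None
    seqs = {n: "".join(rng.choice(alphabet, n_sites, p=probs)) for n in names}
    return Supermatrix.from_sequences(seqs), tree, model


class TestPruningOracle:
    @pytest.mark.parametrize("seed", range(25))
    def test_matches_enumeration_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        n_taxa = int(rng.integers(2, 6))
        ncat = int(rng.choice([1, 4]))
        p_inv = float(rng.choice([0.0, 0.2]))
        sm, tree, model = random_instance(seed, n_taxa, ncat=ncat, p_inv=p_inv)
        got = pruning_loglik(sm, tree, {"all": model})
        want = enumeration_loglik(sm, tree, model)
        assert got == pytest.approx(want, abs=1e-8)

    def test_single_taxon_is_stationary_logprob(self, rng):
        model = random_subst_model(rng)
        sm = Supermatrix.from_sequences({"A": "ACGTTA"})
        tree = Tree.from_newick("A;")
        want = sum(np.log(model.freqs[BASE_INDEX[c]]) for c in "ACGTTA")
        assert pruning_loglik(sm, tree, {"all": model}) == pytest.approx(want)

    def test_all_ambiguous_site_contributes_zero(self, jc):
        tree = Tree.from_newick("(A:0.1,B:0.2);")
        base = pruning_loglik(Supermatrix.from_sequences(
            {"A": "ACGT", "B": "ACGT"}), tree, {"all": jc})
        extended = pruning_loglik(Supermatrix.from_sequences(
            {"A": "ACGTN", "B": "ACGTN"}), tree, {"all": jc})
        assert extended == pytest.approx(base)

    def test_root_invariance_for_reversible_models(self, rng):
        # likelihood unchanged by re-rooting along an edge
        model = random_subst_model(rng, ncat=4)
        sm, tree, _ = random_instance(3, 4)
        t1 = Tree.from_newick("((A:0.1,B:0.2):0.05,(C:0.3,D:0.1):0.15);")
        t2 = Tree.from_newick("(A:0.1,(B:0.2,((C:0.3,D:0.1):0.2)):0.0);")
        # same unrooted tree: path lengths between all tip pairs agree
        l1 = pruning_loglik(sm, t1, {"all": model})
        l2 = pruning_loglik(sm, t2, {"all": model})
        assert l1 == pytest.approx(l2, abs=1e-8)

    def test_taxon_mismatch_reported(self, jc):
        sm = Supermatrix.from_sequences({"A": "ACGT", "X": "ACGT"})
        tree = Tree.from_newick("(A:0.1,B:0.1);")
        with pytest.raises(ValueError, match="X"):
            pruning_loglik(sm, tree, {"all": jc})

    def test_partition_groups_sum(self, rng):
        # two partitions with distinct models = sum of separate likelihoods
        m1 = random_subst_model(rng, ncat=4)
        m2 = random_subst_model(rng)
        tree = Tree.from_newick("((A:0.1,B:0.2):0.1,C:0.3);")
        rngs = np.random.default_rng(8)
        seqs = {n: "".join(rngs.choice(list("ACGT"), 40)) for n in "ABC"}
        sm = Supermatrix(
            ["A", "B", "C"],
            np.array([list(seqs[n]) for n in "ABC"], dtype="U1"),
            {"x": np.arange(15), "y": np.arange(15, 40)})
        joint = pruning_loglik(sm, tree, {"x": m1, "y": m2})
        sx = Supermatrix.from_sequences({n: seqs[n][:15] for n in "ABC"})
        sy = Supermatrix.from_sequences({n: seqs[n][15:] for n in "ABC"})
        assert joint == pytest.approx(
            pruning_loglik(sx, tree, {"all": m1})
            + pruning_loglik(sy, tree, {"all": m2}))


class TestBranchOptimization:
    def test_identical_sequences_shrink_to_bound(self, jc):
        sm = Supermatrix.from_sequences({"A": "ACGT" * 20, "B": "ACGT" * 20})
        tree = Tree.from_newick("(A:0.3,B:0.3);")
        opt, _ = optimize_branch_lengths(sm, tree, {"all": jc})
        assert opt.lengths[[0, 1]].sum() < 1e-6

    def test_two_taxon_jc_distance_closed_form(self, jc):
        # MLE total path length = -(3/4) ln(1 - 4p/3)
        tree = Tree.from_newick("(A:0.05,B:0.05);")
        sim = evolve_sequences(tree, jc, length=4000, seed=3)
        sm = Supermatrix.from_sequences(sim.tips())
        p = np.mean([a != b for a, b in
                     zip(sim.sequences["A"], sim.sequences["B"])])
        expect = -0.75 * np.log(1 - 4 * p / 3)
        opt, _ = optimize_branch_lengths(sm, tree, {"all": jc})
        got = opt.lengths[[0, 1]].sum()
        assert got == pytest.approx(expect, abs=1e-4)

    def test_loglik_never_decreases(self, rng):
        sm, tree, model = random_instance(11, 4, n_sites=60,
                                          with_ambiguity=False)
        ev = SupermatrixLikelihood(sm, tree, {"all": model})
        before = ev.loglik(tree.lengths)
        _, after = optimize_branch_lengths(sm, tree, {"all": model})
        assert after >= before - 1e-9


class TestMarginalAncestral:
    def test_zero_branches_identical_children_certain(self, jc):
        tree = Tree.from_newick("(A:0.0,B:0.0);")
        sm = Supermatrix.from_sequences({"A": "ACGT", "B": "ACGT"})
        sp = marginal_ancestral(sm, tree, {"all": jc}, tree.root)
        assert sp.map_sequence == "ACGT"
        np.testing.assert_allclose(sp.probs.max(axis=1), 1.0, atol=1e-12)

    def test_star_matches_enumeration(self, rng):
        # 3-taxon star: root posterior by direct Bayes over root states
        model = random_subst_model(rng, ncat=4)
        tree = Tree.from_newick("(A:0.2,B:0.2,C:0.2);")
        seqs = {"A": "AAGT", "B": "ACGT", "C": "CCGN"}
        sm = Supermatrix.from_sequences(seqs)
        sp = marginal_ancestral(sm, tree, {"all": model}, tree.root)
        rates, weights = model.mixture()
        for si in range(4):
            want = np.zeros(4)
            for rate, w in zip(rates, weights):
                P = transition_matrix(model, 0.2 * rate)
                for r in range(4):
                    p = model.freqs[r]
                    for t in "ABC":
                        obs = seqs[t][si]
                        if obs in BASE_INDEX:
                            p *= P[r, BASE_INDEX[obs]]
                    want[r] += w * p
            want /= want.sum()
            np.testing.assert_allclose(sp.probs[si], want, atol=1e-9)

    def test_posteriors_sum_to_one(self, rng):
        sm, tree, model = random_instance(21, 5, ncat=4)
        node = tree.root
        sp = marginal_ancestral(sm, tree, {"all": model}, node)
        np.testing.assert_allclose(sp.probs.sum(axis=1), 1.0, atol=1e-9)

    def test_exact_tie_emits_n(self, jc):
        # two children, symmetric branches, observations A and C: tie A vs C
        tree = Tree.from_newick("(A:0.1,B:0.1);")
        sm = Supermatrix.from_sequences({"A": "A", "B": "C"})
        sp = marginal_ancestral(sm, tree, {"all": jc}, tree.root)
        assert sp.map_sequence == "N"

    def test_tip_node_rejected(self, jc):
        tree = Tree.from_newick("(A:0.1,B:0.1);")
        sm = Supermatrix.from_sequences({"A": "A", "B": "C"})
        with pytest.raises(ValueError):
            marginal_ancestral(sm, tree, {"all": jc}, tree.tip_index("A"))

    def test_internal_recovery_on_short_branches(self, jc):
        # simulator truth: MAP accuracy > 95% at <= 0.05 subst/site
        correct = total = 0
        for seed in range(5):
            tree = Tree.from_newick(
                "((A:0.05,B:0.05)ab:0.05,(C:0.05,D:0.05)cd:0.05);")
            sim = evolve_sequences(tree, jc, length=2000, seed=seed)
            sm = Supermatrix.from_sequences(sim.tips())
            sp = marginal_ancestral(sm, tree, {"all": jc}, tree.mrca(["A", "B"]))
            truth = sim.sequences["ab"]
            correct += sum(a == b for a, b in zip(sp.map_sequence, truth))
            total += len(truth)
        assert correct / total > 0.95


class TestMaskMissing:
    def test_descendant_missing_masks_site(self):
        assert mask_missing("ACGT", ["ACNT"]) == "ACNT"

    def test_no_missing_identity(self):
        assert mask_missing("ACGT", ["TTTT", "CCCC"]) == "ACGT"

    def test_union_of_missing_sets(self):
        anc = "ACGTACGT"
        d1 = "NCGTACGN"  # missing {0, 7}
        d2 = "ACNTAC-T"  # missing {2, 6}
        out = mask_missing(anc, [d1, d2])
        assert [i for i, c in enumerate(out) if c == "N"] == [0, 2, 6, 7]

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mask_missing("ACGT", ["ACG"])
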