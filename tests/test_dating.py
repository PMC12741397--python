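import math

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

from mitodate.dating import (
    ExponentialPrior, LogNormalPrior, MCMCConfig, PriorSet, TipDatingModel,
    TruncatedNormalPrior, coalescent_logprior, effective_sample_size,
    hpd_interval, summarize_posterior, uln_clock_logprior,
)
from mitodate.supermatrix import Supermatrix
from mitodate.simulate import evolve_sequences
from mitodate.substmodel import SubstModel
from mitodate.trees import DatedTree, Tree


class TestCoalescentPrior:
    def test_two_tip_closed_form(self):
        dt = DatedTree.from_newick_ages("(A:1.5,B:1.5);")
        for ne in (0.5, 2.0, 10.0):
            assert coalescent_logprior(dt, ne) == pytest.approx(
                -math.log(ne) - 1.5 / ne)

    def test_three_tip_serial_hand_computation(self):
        # tips A,B at 0, C at 0.3; coalescences at 0.5 and 1.0; Ne = 2
        dt = DatedTree(parent=[3, 3, 4, 4, -1],
                       names=["A", "B", "C", None, None],
                       ages=[0.0, 0.0, 0.3, 0.5, 1.0])
        ne = 2.0
        # intervals: [0,0.3] k=2; [0.3,0.5] k=3; coal; [0.5,1.0] k=2; coal
        want = (-(1 / ne) * 0.3 - (3 / ne) * 0.2 - math.log(ne)
                - (1 / ne) * 0.5 - math.log(ne))
        assert coalescent_logprior(dt, ne) == pytest.approx(want)

    def test_two_tip_density_normalised(self):
        ne = 1.7

        def dens(t):
            dt = DatedTree.from_newick_ages(f"(A:{t},B:{t});")
            return math.exp(coalescent_logprior(dt, ne))

        total, _ = integrate.quad(dens, 0.001, 60)
        assert total == pytest.approx(1.0, abs=1e-3)

    def test_invalid_ne_rejected(self):
        dt = DatedTree.from_newick_ages("(A:1,B:1);")
        with pytest.raises(ValueError):
            coalescent_logprior(dt, 0.0)


class TestClockPrior:
    def test_additivity_over_branches(self):
        rates = np.array([0.01, 0.02, 0.05])
        total = uln_clock_logprior(rates, 0.02, 0.5)
        parts = sum(uln_clock_logprior(np.array([r]), 0.02, 0.5) for r in rates)
        assert total == pytest.approx(parts)

    def test_matches_scipy_lognormal_pdf(self):
        M, sigma = 0.02, 0.6
        mu = math.log(M) - sigma**2 / 2
        x = 0.015
        want = stats.lognorm.logpdf(x, s=sigma, scale=math.exp(mu))
        assert uln_clock_logprior(np.array([x]), M, sigma) == pytest.approx(want)

    def test_shrinking_sigma_concentrates_density(self):
        # at the lognormal median, density grows without bound as sigma -> 0
        vals = []
        for sigma in (0.5, 0.1, 0.02):
            M = 0.02
            mode = math.exp(math.log(M) - sigma**2 / 2)
            vals.append(uln_clock_logprior(np.array([mode]), M, sigma))
        assert vals[0] < vals[1] < vals[2]

    def test_nonpositive_rate_is_minus_inf(self):
        assert uln_clock_logprior(np.array([0.0]), 0.02, 0.5) == -np.inf


class TestSummaries:
    def test_hpd_integers_hand_case(self):
        samples = np.arange(1, 101)
        lo, hi = hpd_interval(samples, 0.95)
        assert hi - lo == 94  # shortest window holding 95 of 100 points
        assert np.median(samples) == pytest.approx(50.5)

    def test_constant_trace_zero_width(self):
        lo, hi = hpd_interval(np.full(50, 3.2))
        assert lo == hi == 3.2

    def test_hpd_finds_concentrated_region(self):
        rng = np.random.default_rng(0)
        x = np.concatenate([rng.normal(0, 0.1, 950), rng.uniform(5, 50, 50)])
        lo, hi = hpd_interval(x, 0.95)
        assert hi < 1.0  # excludes the diffuse tail

    def test_summary_invariant_to_order(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=400)
        df1 = summarize_posterior(pd.DataFrame({"x": x}), burn_in_frac=0.0)
        df2 = summarize_posterior(pd.DataFrame({"x": rng.permutation(x)}),
                                  burn_in_frac=0.0)
        for col in ("median", "hpd_lower", "hpd_upper"):
            assert df1.loc["x", col] == pytest.approx(df2.loc["x", col])

    def test_burn_in_removed(self):
        x = np.concatenate([np.full(10, 100.0), np.zeros(90)])
        df = summarize_posterior(pd.DataFrame({"x": x}), burn_in_frac=0.10)
        assert df.loc["x", "median"] == 0.0

    def test_empty_after_burn_in_rejected(self):
        with pytest.raises(ValueError):
            summarize_posterior(pd.DataFrame({"x": []}), burn_in_frac=0.0)

    def test_ess_iid_near_n(self):
        x = np.random.default_rng(2).normal(size=2000)
        assert effective_sample_size(x) > 1200

    def test_ess_correlated_much_smaller(self):
        rng = np.random.default_rng(3)
        x = np.zeros(2000)
        for i in range(1, 2000):
            x[i] = 0.99 * x[i - 1] + rng.normal()
        assert effective_sample_size(x) < 200


class TestPriors:
    def test_lognormal_real_space_parameterisation(self):
        p = LogNormalPrior(7.5, 1.0)
        x = p.sample(np.random.default_rng(0), size=20_000)
        assert x.mean() == pytest.approx(7.5, abs=0.05)
        assert x.std() == pytest.approx(1.0, abs=0.05)

    def test_truncated_normal_respects_bounds(self):
        p = TruncatedNormalPrior(0.05, 0.05, low=0.0503, high=0.43)
        x = p.sample(np.random.default_rng(0), size=5000)
        assert x.min() >= 0.0503 and x.max() <= 0.43
        assert p.logpdf(0.01) == -np.inf

    def test_truncated_normal_logpdf_matches_scipy(self):
        p = TruncatedNormalPrior(0.2, 0.1, low=0.0, high=0.43)
        ref = stats.truncnorm((0 - 0.2) / 0.1, (0.43 - 0.2) / 0.1,
                              loc=0.2, scale=0.1)
        for x in (0.05, 0.2, 0.4):
            assert p.logpdf(x) == pytest.approx(ref.logpdf(x))


def _tiny_model(seed=0, length=300):
    truth = DatedTree.from_newick_ages("((A:0.4,B:0.4)ab:0.6,C:1.0)r;")
    sim = evolve_sequences(truth, SubstModel.hky(4.0), length=length,
                           seed=seed, clock_rate=0.05)
    sm = Supermatrix.from_sequences(sim.tips())
    topo = Tree.from_newick("((A,B)ab,C)r;")
    priors = PriorSet(node_calibrations={"root": LogNormalPrior(1.0, 0.3)},
                      clock_mean=LogNormalPrior(0.05, 0.1))
    return TipDatingModel(sm, topo, priors,
                          tip_ages={"A": 0.0, "B": 0.0, "C": 0.0})


class TestMCMC:
    def test_identical_seed_identical_traces(self):
        m = _tiny_model()
        cfg = MCMCConfig(chain_length=2000, sample_every=20, seed=5)
        t1 = m.fit(cfg).traces
        t2 = m.fit(cfg).traces
        pd.testing.assert_frame_equal(t1, t2)

    def test_traces_have_expected_columns(self):
        m = _tiny_model()
        res = m.fit(MCMCConfig(chain_length=1000, sample_every=10, seed=1))
        for col in ("log_posterior", "Ne", "clock_mean", "clock_sd"):
            assert col in res.traces.columns
        assert len(res.traces) == 100

    def test_summary_hpd_brackets_median(self):
        m = _tiny_model()
        res = m.fit(MCMCConfig(chain_length=4000, sample_every=20, seed=2))
        s = res.summary()
        assert (s["hpd_lower"] <= s["median"]).all()
        assert (s["median"] <= s["hpd_upper"]).all()

    def test_node_age_summary_targets_mrca(self):
        m = _tiny_model()
        res = m.fit(MCMCConfig(chain_length=2000, sample_every=20, seed=3))
        s = res.node_age_summary(["A", "B"])
        assert 0 < s["median"] < s["hpd_upper"]

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            MCMCConfig(chain_length=1000, sample_every=33)
        with pytest.raises(ValueError):
            MCMCConfig(burn_in_frac=1.0)

    def test_unknown_dated_tip_rejected(self):
        with pytest.raises(KeyError):
            TipDatingModel(None, Tree.from_newick("(A,B);"),
                           PriorSet(tip_ages={
                               "Z": TruncatedNormalPrior(0.1, 0.05)}))

    def test_dated_tree_ages_consistent(self):
        m = _tiny_model()
        res = m.fit(MCMCConfig(chain_length=2000, sample_every=20, seed=4))
        dated = res.dated_tree()
        for v in range(dated.n_nodes):
            p = dated.parent[v]
            if p >= 0:
                assert dated.ages[p] > dated.ages[v]

    def test_prior_only_root_matches_calibration(self):
        # sampling from the prior: root age reproduces its lognormal prior
        topo = Tree.from_newick("(A,B)r;")
        priors = PriorSet(node_calibrations={"root": LogNormalPrior(2.0, 0.5)})
        m = TipDatingModel(None, topo, priors, tip_ages={"A": 0.0, "B": 0.0})
        res = m.fit(MCMCConfig(chain_length=60_000, sample_every=30, seed=6,
                               prior_only=True, tree_prior="none"))
        root = res.traces["age_node2"].iloc[200:]
        assert root.mean() == pytest.approx(2.0, abs=0.05)
        assert root.std() == pytest.approx(0.5, abs=0.05)

    def test_posterior_concentrates_with_more_data(self):
        # HPD width of the focal node age shrinks as sites grow 300 -> 3000
        widths = []
        for length in (300, 3000):
            m = _tiny_model(seed=9, length=length)
            res = m.fit(MCMCConfig(chain_length=12_000, sample_every=20,
                                   seed=7))
            s = res.node_age_summary(["A", "B"])
            widths.append(s["hpd_upper"] - s["hpd_lower"])
        assert widths[1] < widths[0]
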