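"""Bayesian tip-dating on a fixed topology.

The model: node ages (Ma) on a rooted topology with serially sampled
(radiocarbon-dated) tips; an uncorrelated lognormal (ULN) relaxed clock --
each branch's substitution rate drawn i.i.d. from a lognormal with real-space
mean ``M`` and log-space spread ``sigma``; a constant-population-size serial
coalescent tree prior; truncated-normal priors on dated tip ages and normal or
lognormal calibrations on selected internal nodes; HKY(+I)+Gamma sequence
likelihood per partition via :mod:`mitodate.likelihood`, with branch lengths
equal to duration times rate.

``TipDatingModel`` holds data and priors; ``fit`` runs Metropolis-Hastings
MCMC and returns a ``TipDatingResults`` with traces, posterior summaries
(median, shortest 95% HPD, ESS) and a ``summary()`` table.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from mitodate.likelihood import SupermatrixLikelihood
from mitodate.substmodel import SubstModel
from mitodate.supermatrix import Supermatrix
from mitodate.trees import DatedTree, Tree

logger = logging.getLogger(__name__)

__all__ = [
    "LogNormalPrior", "TruncatedNormalPrior", "ExponentialPrior",
    "PriorSet", "MCMCConfig", "TipDatingModel", "TipDatingResults",
    "coalescent_logprior", "uln_clock_logprior", "summarize_posterior",
    "hpd_interval", "effective_sample_size",
]


# ------------------------------------------------------------------- priors
class LogNormalPrior:
    """Lognormal prior parameterised by *real-space* mean and sd."""

    def __init__(self, mean: float, sd: float):
        if mean <= 0 or sd <= 0:
            raise ValueError("lognormal prior needs positive mean and sd")
        self.mean, self.sd = mean, sd
        self.sigma = math.sqrt(math.log(1.0 + (sd / mean) ** 2))
        self.mu = math.log(mean) - 0.5 * self.sigma**2

    def logpdf(self, x: float) -> float:
        if x <= 0:
            return -np.inf
        z = (math.log(x) - self.mu) / self.sigma
        return -0.5 * z * z - math.log(x * self.sigma * math.sqrt(2 * math.pi))

    def sample(self, rng: np.random.Generator, size=None):
        return np.exp(rng.normal(self.mu, self.sigma, size=size))

    def __repr__(self):
        return f"LogNormalPrior(mean={self.mean}, sd={self.sd})"


class TruncatedNormalPrior:
    """Normal prior truncated to [low, high] (defaults: low=0, high=inf)."""

    def __init__(self, mean: float, sd: float, low: float = 0.0,
                 high: float = np.inf):
        if sd <= 0 or not low < high:
            raise ValueError("invalid truncated normal parameters")
        self.mean, self.sd, self.low, self.high = mean, sd, low, high
        a, b = (low - mean) / sd, (high - mean) / sd
        self._dist = stats.truncnorm(a, b, loc=mean, scale=sd)
        self._log_z = math.log(stats.norm.cdf(b) - stats.norm.cdf(a))
        self._log_norm = -math.log(sd * math.sqrt(2 * math.pi)) - self._log_z

    def logpdf(self, x: float) -> float:
        if not (self.low <= x <= self.high):
            return -np.inf
        z = (x - self.mean) / self.sd
        return -0.5 * z * z + self._log_norm

    def sample(self, rng: np.random.Generator, size=None):
        return self._dist.rvs(size=size, random_state=rng)

    def __repr__(self):
        return (f"TruncatedNormalPrior(mean={self.mean}, sd={self.sd}, "
                f"low={self.low}, high={self.high})")


class ExponentialPrior:
    def __init__(self, mean: float):
        if mean <= 0:
            raise ValueError("exponential prior needs positive mean")
        self.mean = mean

    def logpdf(self, x: float) -> float:
        if x < 0:
            return -np.inf
        return -math.log(self.mean) - x / self.mean

    def sample(self, rng: np.random.Generator, size=None):
        return rng.exponential(self.mean, size=size)

    def __repr__(self):
        return f"ExponentialPrior(mean={self.mean})"


@dataclass
class PriorSet:
    """All priors of the dating model.

    ``tip_ages`` maps dated tip names to age priors; unlisted tips are fixed
    at their given age.  ``node_calibrations`` maps either ``"root"`` or a
    tuple of tip names (their MRCA) to an age prior.  Hyperpriors cover the
    coalescent population size and the ULN clock mean/sd; ``kappa`` and
    ``alpha`` priors apply when substitution parameters are estimated
    in-chain.
    """

    tip_ages: dict[str, object] = field(default_factory=dict)
    node_calibrations: dict[object, object] = field(default_factory=dict)
    ne: object = field(default_factory=lambda: LogNormalPrior(1.0, 2.0))
    clock_mean: object = field(default_factory=lambda: LogNormalPrior(0.02, 0.05))
    clock_sd: object = field(default_factory=lambda: ExponentialPrior(0.5))
    kappa: object = field(default_factory=lambda: LogNormalPrior(4.0, 4.0))
    alpha: object = field(default_factory=lambda: LogNormalPrior(0.5, 1.0))


@dataclass
class MCMCConfig:
    """Chain settings. The default is a desk-scale chain; scale up as needed."""

    chain_length: int = 200_000
    sample_every: int = 100
    burn_in_frac: float = 0.10
    seed: int = 0
    prior_only: bool = False
    tree_prior: str = "coalescent"  # or "none" (calibration densities only)
    proposal_scales: dict = field(default_factory=lambda: {
        "node_age": 1.0,  # uniform-in-bounds; scale unused
        "root_age": 0.6, "tip_age": 0.04, "rate": 0.5,
        "clock_mean": 0.4, "clock_sd": 0.4, "ne": 0.6,
        "kappa": 0.3, "alpha": 0.4, "scale_all": 0.15,
        "clock_mean_rates": 0.5, "clock_sd_rates": 0.5,
    })
    move_weights: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (0.0 <= self.burn_in_frac < 1.0):
            raise ValueError("burn_in_frac must be in [0, 1)")
        if self.chain_length % self.sample_every != 0:
            raise ValueError("sample_every must divide chain_length")
        if self.tree_prior not in ("coalescent", "none"):
            raise ValueError("tree_prior must be 'coalescent' or 'none'")


# ------------------------------------------------------- prior log-densities
def coalescent_logprior(tree: DatedTree, Ne: float) -> float:
    """Constant-size serial coalescent log density of the tree's node ages."""
    if Ne <= 0:
        raise ValueError("Ne must be > 0")
    tree.validate()
    tip_ages = [float(tree.ages[i]) for i in range(tree.n_nodes) if tree.is_tip[i]]
    coal_ages = [float(tree.ages[i]) for i in range(tree.n_nodes) if not tree.is_tip[i]]
    return _serial_coalescent_loglik(tip_ages, coal_ages, Ne)


def _serial_coalescent_loglik(tip_ages, coal_ages, Ne) -> float:
    events = sorted(
        [(a, 0) for a in tip_ages] + [(a, 1) for a in coal_ages]
    )  # sampling events before coalescences at equal age
    k = 0
    t = events[0][0]
    logp = 0.0
    for age, kind in events:
        dt = age - t
        if dt > 0:
            logp -= k * (k - 1) / 2.0 * dt / Ne
        t = age
        if kind == 0:
            k += 1
        else:
            if k < 2:
                raise ValueError("inconsistent ages: coalescence with <2 lineages")
            logp -= math.log(Ne)
            k -= 1
    return logp


def uln_clock_logprior(rates: np.ndarray, mean_rate: float, sigma: float) -> float:
    """Sum of i.i.d. lognormal log-densities over branch rates.

    Parameterised by the *real-space* mean rate and the log-space sd.
    """
    rates = np.asarray(rates, dtype=float)
    if np.any(rates <= 0):
        return -np.inf
    if mean_rate <= 0 or sigma <= 0:
        raise ValueError("mean_rate and sigma must be > 0")
    mu = math.log(mean_rate) - 0.5 * sigma**2
    z = (np.log(rates) - mu) / sigma
    return float((-0.5 * z * z - np.log(rates * sigma * math.sqrt(2 * math.pi))).sum())


# ---------------------------------------------------------------- summaries
def hpd_interval(samples: np.ndarray, mass: float = 0.95) -> tuple[float, float]:
    """Shortest contiguous interval containing ``mass`` of the samples."""
    s = np.sort(np.asarray(samples, dtype=float))
    n = len(s)
    if n == 0:
        raise ValueError("no samples")
    m = int(math.ceil(mass * n))
    if m >= n:
        return float(s[0]), float(s[-1])
    widths = s[m - 1:] - s[: n - m + 1]
    i = int(np.argmin(widths))
    return float(s[i]), float(s[i + m - 1])


def effective_sample_size(samples: np.ndarray) -> float:
    """ESS via the autocorrelation time (Geyer initial positive sequence)."""
    x = np.asarray(samples, dtype=float)
    n = len(x)
    if n < 4 or np.allclose(x, x[0]):
        return float(n)
    x = x - x.mean()
    nfft = 1 << (2 * n - 1).bit_length()
    f = np.fft.rfft(x, nfft)
    acov = np.fft.irfft(f * np.conjugate(f), nfft)[:n].real / n
    rho = acov / acov[0]
    tau = 1.0
    k = 1
    while k + 1 < n:
        g = rho[k] + rho[k + 1]
        if g <= 0:
            break
        tau += 2.0 * g
        k += 2
    return float(min(n, n / tau))


def summarize_posterior(traces: pd.DataFrame, burn_in_frac: float = 0.10,
                        mass: float = 0.95) -> pd.DataFrame:
    """Median, shortest HPD interval and ESS per trace column (after burn-in)."""
    if not (0.0 <= burn_in_frac < 1.0):
        raise ValueError("burn_in_frac must be in [0, 1)")
    n = len(traces)
    start = int(math.floor(burn_in_frac * n))
    kept = traces.iloc[start:]
    if len(kept) == 0:
        raise ValueError("no samples remain after burn-in")
    rows = []
    for col in kept.columns:
        v = kept[col].to_numpy(dtype=float)
        lo, hi = hpd_interval(v, mass)
        rows.append({
            "parameter": col, "median": float(np.median(v)),
            "hpd_lower": lo, "hpd_upper": hi,
            "ess": effective_sample_size(v), "n": len(v),
        })
    return pd.DataFrame(rows).set_index("parameter")


# -------------------------------------------------------------------- model
class TipDatingModel:
    """Fixed-topology Bayesian tip-dating model.

    Parameters
    ----------
    matrix : Supermatrix of the dated taxa (tips of ``topology``).
    topology : rooted tree; branch lengths are ignored (ages are sampled).
    priors : PriorSet.
    tip_ages : fixed ages (Ma) for undated tips; dated tips (those with a
        prior in ``priors.tip_ages``) are initialised at their prior mean.
    models : optional dict partition -> SubstModel; defaults to HKY+Gamma(4)
        with empirical frequencies, one shared model for all partitions
        (pass distinct objects for per-partition parameters).
    estimate_kappa, estimate_alpha : sample those parameters in-chain.
    """

    def __init__(
        self,
        matrix: Supermatrix | None,
        topology: Tree,
        priors: PriorSet,
        tip_ages: dict[str, float] | None = None,
        models: dict[str, SubstModel] | None = None,
        estimate_kappa: bool = True,
        estimate_alpha: bool = True,
    ):
        self.matrix = matrix
        self.tree = topology
        self.priors = priors
        self.fixed_tip_ages = dict(tip_ages or {})
        for name in priors.tip_ages:
            topology.tip_index(name)  # raises for unknown dated tips
        self.estimate_kappa = estimate_kappa
        self.estimate_alpha = estimate_alpha

        if matrix is not None:
            if models is None:
                freqs = _empirical_freqs(matrix)
                shared = SubstModel.hky(2.0, freqs, alpha=0.5, ncat=4)
                models = {p: shared for p in matrix.partitions}
            self.evaluator = SupermatrixLikelihood(matrix, topology, models)
            self._init_kappa = [float(m.rates[1] / m.rates[0])
                                for m in self.evaluator.group_models]
            self._init_alpha = [float(m.alpha)
                                for m in self.evaluator.group_models]
        else:
            self.evaluator = None
            self._init_kappa = []
            self._init_alpha = []

        # resolve calibrations to node indices
        self.calibrations: dict[int, object] = {}
        for key, prior in priors.node_calibrations.items():
            if key == "root":
                node = topology.root
            else:
                node = topology.mrca(key)
            self.calibrations[node] = prior
        self.dated_tips = [topology.tip_index(n) for n in priors.tip_ages]
        self._dated_prior = {topology.tip_index(n): p
                             for n, p in priors.tip_ages.items()}

    @classmethod
    def from_sequences(cls, sequences: dict[str, str], topology: Tree,
                       priors: PriorSet, **kw) -> "TipDatingModel":
        return cls(Supermatrix.from_sequences(sequences), topology, priors, **kw)

    # ------------------------------------------------------------------ state
    def _initial_state(self, rng: np.random.Generator) -> dict:
        tree = self.tree
        ages = np.zeros(tree.n_nodes)
        for i in range(tree.n_nodes):
            if tree.is_tip[i]:
                name = tree.names[i]
                if i in self._dated_prior:
                    p = self._dated_prior[i]
                    ages[i] = getattr(p, "mean", 0.1)
                    lo = getattr(p, "low", 0.0)
                    hi = getattr(p, "high", np.inf)
                    ages[i] = min(max(ages[i], lo + 1e-6), hi - 1e-6 if np.isfinite(hi) else ages[i])
                else:
                    ages[i] = self.fixed_tip_ages.get(name, 0.0)
        # node heights in "levels" scaled towards the root calibration mean
        height = np.zeros(tree.n_nodes, dtype=int)
        for v in tree.postorder:
            if not tree.is_tip[v]:
                height[v] = 1 + max(height[c] for c in tree.children[v])
        root_prior = self.calibrations.get(tree.root)
        root_guess = getattr(root_prior, "mean", None) if root_prior else None
        top = root_guess if root_guess else ages.max() + max(1.0, ages.max())
        for v in tree.postorder:
            if tree.is_tip[v]:
                continue
            kids = max(ages[c] for c in tree.children[v])
            level_age = ages.max() + (top - ages.max()) * height[v] / max(height[tree.root], 1)
            ages[v] = max(level_age, kids + 1e-4 * max(top, 1.0))
        M = getattr(self.priors.clock_mean, "mean", 0.01)
        sigma = 0.3
        rates = np.full(tree.n_nodes, M)
        return {
            "ages": ages, "rates": rates, "Ne": getattr(self.priors.ne, "mean", 1.0),
            "M": M, "sigma": sigma,
            "kappa": np.array(self._init_kappa),
            "alpha": np.array(self._init_alpha),
        }

    def _sync_models(self, state: dict) -> None:
        """Push current substitution parameters into the evaluator."""
        if self.evaluator is None:
            return
        for gi, old in enumerate(self.evaluator.group_models):
            kappa = state["kappa"][gi]
            alpha = state["alpha"][gi]
            m = SubstModel.hky(kappa, old.freqs, p_inv=old.p_inv,
                               alpha=alpha, ncat=old.ncat)
            self.evaluator.set_group_model(gi, m)

    # -------------------------------------------------------------- densities
    def log_likelihood(self, state: dict) -> float:
        if self.evaluator is None:
            return 0.0
        tree = self.tree
        ages, rates = state["ages"], state["rates"]
        has_parent = tree.parent >= 0
        blens = np.zeros(tree.n_nodes)
        blens[has_parent] = (
            (ages[tree.parent[has_parent]] - ages[has_parent]) * rates[has_parent]
        )
        if np.any(blens[has_parent] < 0):
            return -np.inf
        return self.evaluator.loglik(blens)

    def log_prior(self, state: dict, tree_prior: str = "coalescent") -> float:
        tree = self.tree
        ages = state["ages"]
        # topology-consistency of ages
        has_parent = tree.parent >= 0
        if np.any(ages[tree.parent[has_parent]] <= ages[has_parent]):
            return -np.inf
        logp = 0.0
        if tree_prior == "coalescent":
            tip_ages = [float(ages[i]) for i in range(tree.n_nodes) if tree.is_tip[i]]
            coal_ages = [float(ages[i]) for i in range(tree.n_nodes) if not tree.is_tip[i]]
            try:
                logp += _serial_coalescent_loglik(tip_ages, coal_ages, state["Ne"])
            except ValueError:
                return -np.inf
            logp += self.priors.ne.logpdf(state["Ne"])
        for node, prior in self.calibrations.items():
            logp += prior.logpdf(float(ages[node]))
        for node, prior in self._dated_prior.items():
            logp += prior.logpdf(float(ages[node]))
        rates = state["rates"][has_parent]
        logp += uln_clock_logprior(rates, state["M"], state["sigma"])
        logp += self.priors.clock_mean.logpdf(state["M"])
        logp += self.priors.clock_sd.logpdf(state["sigma"])
        if self.estimate_kappa:
            for k in state["kappa"]:
                logp += self.priors.kappa.logpdf(float(k))
        if self.estimate_alpha:
            for a in state["alpha"]:
                logp += self.priors.alpha.logpdf(float(a))
        return float(logp)

    # ------------------------------------------------------------------- fit
    def fit(self, config: MCMCConfig | None = None) -> "TipDatingResults":
        """Run Metropolis-Hastings MCMC and return results."""
        cfg = config or MCMCConfig()
        rng = np.random.default_rng(cfg.seed)
        tree = self.tree
        state = self._initial_state(rng)
        self._sync_models(state)
        use_lik = (not cfg.prior_only) and self.evaluator is not None

        lp = self.log_prior(state, cfg.tree_prior)
        ll = self.log_likelihood(state) if use_lik else 0.0
        retries = 0
        while not np.isfinite(lp + ll) and retries < 20:
            logger.warning("zero-probability start state; re-initialising")
            state = self._initial_state(rng)
            for v in range(tree.n_nodes):
                if not tree.is_tip[v]:
                    state["ages"][v] *= float(rng.uniform(0.8, 1.5))
            lp = self.log_prior(state, cfg.tree_prior)
            ll = self.log_likelihood(state) if use_lik else 0.0
            retries += 1
        if not np.isfinite(lp + ll):
            raise RuntimeError("could not find a valid starting state")

        internal = [v for v in range(tree.n_nodes)
                    if not tree.is_tip[v] and v != tree.root]
        branches = [v for v in range(tree.n_nodes) if tree.parent[v] >= 0]
        n_groups = len(state["kappa"])

        moves = ["node_age"] * max(len(internal), 1) + ["root_age"] \
            + ["tip_age"] * len(self.dated_tips) + ["rate"] * len(branches) \
            + ["clock_mean", "clock_sd", "clock_mean_rates", "clock_sd_rates"] \
            + ["clock_mean_prior", "clock_sd_prior"] \
            + ["scale_all"] * max(1 + len(internal), 2)
        if cfg.tree_prior == "coalescent":
            moves.append("ne")
        if use_lik and self.estimate_kappa:
            moves += ["kappa"] * n_groups
        if use_lik and self.estimate_alpha:
            moves += ["alpha"] * n_groups
        base_w = np.array([1.0] * len(moves))
        for i, mname in enumerate(moves):
            base_w[i] *= cfg.move_weights.get(mname, 1.0)
        probs = base_w / base_w.sum()
        sc = cfg.proposal_scales

        records: list[dict] = []
        n_acc = 0
        for gen in range(1, cfg.chain_length + 1):
            move = moves[rng.choice(len(moves), p=probs)]
            new_state = state
            log_hastings = 0.0
            lik_changed = False
            if move == "node_age":
                v = internal[rng.integers(len(internal))] if internal else None
                if v is None:
                    continue
                lo = max(state["ages"][c] for c in tree.children[v])
                hi = state["ages"][tree.parent[v]]
                if hi <= lo:
                    continue
                ages = state["ages"].copy()
                ages[v] = rng.uniform(lo, hi)
                new_state = {**state, "ages": ages}
                lik_changed = True
            elif move == "root_age":
                r = tree.root
                lo = max(state["ages"][c] for c in tree.children[r])
                excess = state["ages"][r] - lo
                u = rng.uniform(-sc["root_age"], sc["root_age"])
                ages = state["ages"].copy()
                ages[r] = lo + excess * math.exp(u)
                new_state = {**state, "ages": ages}
                log_hastings = u
                lik_changed = True
            elif move == "tip_age":
                v = self.dated_tips[rng.integers(len(self.dated_tips))]
                ages = state["ages"].copy()
                if rng.random() < 0.3:  # random walk
                    ages[v] = ages[v] + rng.normal(0.0, sc["tip_age"])
                else:  # independence draw from the tip's own prior
                    prior = self._dated_prior[v]
                    ages[v] = float(prior.sample(rng))
                    log_hastings = (prior.logpdf(float(state["ages"][v]))
                                    - prior.logpdf(float(ages[v])))
                new_state = {**state, "ages": ages}
                lik_changed = True
            elif move == "rate":
                v = branches[rng.integers(len(branches))]
                u = rng.uniform(-sc["rate"], sc["rate"])
                rates = state["rates"].copy()
                rates[v] = rates[v] * math.exp(u)
                new_state = {**state, "rates": rates}
                log_hastings = u
                lik_changed = True
            elif move == "scale_all":
                # traverse the rate-age ridge: all internal ages up, all
                # rates (and the clock mean) down by the same factor
                u = rng.uniform(-sc["scale_all"], sc["scale_all"])
                f = math.exp(u)
                ages = state["ages"].copy()
                n_up = 0
                for v in range(tree.n_nodes):
                    if not tree.is_tip[v]:
                        ages[v] *= f
                        n_up += 1
                rates = state["rates"].copy()
                rates[branches] /= f
                new_state = {**state, "ages": ages, "rates": rates,
                             "M": state["M"] / f}
                log_hastings = (n_up - len(branches) - 1) * u
                lik_changed = True
            elif move == "clock_mean_rates":
                # move the clock mean and carry all rates with it, keeping
                # each rate's quantile under the lognormal fixed
                u = rng.uniform(-sc["clock_mean_rates"], sc["clock_mean_rates"])
                rates = state["rates"].copy()
                rates[branches] *= math.exp(u)
                new_state = {**state, "M": state["M"] * math.exp(u),
                             "rates": rates}
                log_hastings = u + len(branches) * u
                lik_changed = True
            elif move in ("clock_sd_rates", "clock_sd_prior"):
                # move the lognormal spread, rescaling rates in log space so
                # their standardised values are unchanged
                if move == "clock_sd_rates":
                    u = rng.uniform(-sc["clock_sd_rates"], sc["clock_sd_rates"])
                    sig2 = state["sigma"] * math.exp(u)
                    log_q = u  # scale-move Jacobian on sigma
                else:  # independence draw from the sigma prior
                    sig2 = float(self.priors.clock_sd.sample(rng))
                    log_q = (self.priors.clock_sd.logpdf(state["sigma"])
                             - self.priors.clock_sd.logpdf(sig2))
                sig = state["sigma"]
                if sig2 <= 0 or sig2 > 25.0:
                    continue
                mu1 = math.log(state["M"]) - 0.5 * sig**2
                mu2 = math.log(state["M"]) - 0.5 * sig2**2
                with np.errstate(divide="ignore"):
                    logr = np.log(state["rates"][branches])
                if not np.all(np.isfinite(logr)):
                    continue
                logr2 = mu2 + (logr - mu1) * (sig2 / sig)
                if np.any(np.abs(logr2) > 600):
                    continue
                rates = state["rates"].copy()
                rates[branches] = np.exp(logr2)
                new_state = {**state, "sigma": sig2, "rates": rates}
                log_hastings = log_q + float((logr2 - logr).sum()) \
                    + len(branches) * math.log(sig2 / sig)
                lik_changed = True
            elif move == "clock_mean_prior":
                # independence draw of the clock mean, rates carried with it
                M2 = float(self.priors.clock_mean.sample(rng))
                f = M2 / state["M"]
                rates = state["rates"].copy()
                rates[branches] *= f
                new_state = {**state, "M": M2, "rates": rates}
                log_hastings = (self.priors.clock_mean.logpdf(state["M"])
                                - self.priors.clock_mean.logpdf(M2)
                                + len(branches) * math.log(f))
                lik_changed = True
            elif move in ("clock_mean", "clock_sd", "ne"):
                key = {"clock_mean": "M", "clock_sd": "sigma", "ne": "Ne"}[move]
                u = rng.uniform(-sc[move], sc[move])
                new_state = {**state, key: state[key] * math.exp(u)}
                log_hastings = u
            elif move in ("kappa", "alpha"):
                gi = int(rng.integers(n_groups))
                u = rng.uniform(-sc[move], sc[move])
                arr = state[move].copy()
                arr[gi] = arr[gi] * math.exp(u)
                new_state = {**state, move: arr}
                log_hastings = u
                lik_changed = True
                self._sync_models(new_state)

            new_lp = self.log_prior(new_state, cfg.tree_prior)
            if np.isfinite(new_lp):
                if use_lik and lik_changed:
                    new_ll = self.log_likelihood(new_state)
                else:
                    new_ll = ll
            else:
                new_ll = -np.inf
            log_ratio = (new_lp + new_ll) - (lp + ll) + log_hastings
            if math.log(rng.random() + 1e-300) < log_ratio:
                state, lp, ll = new_state, new_lp, new_ll
                n_acc += 1
            elif move in ("kappa", "alpha"):
                self._sync_models(state)  # restore evaluator models

            if gen % cfg.sample_every == 0:
                rec = {"gen": gen, "log_posterior": lp + ll,
                       "log_likelihood": ll, "log_prior": lp,
                       "Ne": state["Ne"], "clock_mean": state["M"],
                       "clock_sd": state["sigma"]}
                for v in range(tree.n_nodes):
                    if not tree.is_tip[v]:
                        rec[f"age_node{v}"] = state["ages"][v]
                for v in self.dated_tips:
                    rec[f"age_{tree.names[v]}"] = state["ages"][v]
                for v in branches:
                    rec[f"rate_node{v}"] = state["rates"][v]
                for gi in range(n_groups):
                    rec[f"kappa_g{gi}"] = state["kappa"][gi] if n_groups else np.nan
                    rec[f"alpha_g{gi}"] = state["alpha"][gi] if n_groups else np.nan
                records.append(rec)

        traces = pd.DataFrame(records)
        logger.info("MCMC finished: %d generations, acceptance %.3f",
                    cfg.chain_length, n_acc / cfg.chain_length)
        return TipDatingResults(self, cfg, traces,
                                acceptance_rate=n_acc / cfg.chain_length)

    # ----------------------------------------------------------------- utils
    def mrca_column(self, tip_names) -> str:
        """Trace-column name of the age of the MRCA of the given tips."""
        return f"age_node{self.tree.mrca(tip_names)}"


@dataclass
class TipDatingResults:
    """Posterior samples and summaries from :meth:`TipDatingModel.fit`."""

    model: TipDatingModel
    config: MCMCConfig
    traces: pd.DataFrame
    acceptance_rate: float

    def summary(self, burn_in_frac: float | None = None,
                mass: float = 0.95) -> pd.DataFrame:
        bif = self.config.burn_in_frac if burn_in_frac is None else burn_in_frac
        cols = [c for c in self.traces.columns if c != "gen"]
        return summarize_posterior(self.traces[cols], bif, mass)

    def node_age_summary(self, tip_names, burn_in_frac: float | None = None,
                         mass: float = 0.95) -> pd.Series:
        """Median/HPD/ESS of the age of the MRCA of ``tip_names``."""
        col = self.model.mrca_column(tip_names)
        return self.summary(burn_in_frac, mass).loc[col]

    def dated_tree(self, burn_in_frac: float | None = None) -> DatedTree:
        """Tree with posterior-median node ages."""
        s = self.summary(burn_in_frac)
        tree = self.model.tree
        ages = np.zeros(tree.n_nodes)
        state0 = self.model._initial_state(np.random.default_rng(0))
        ages[:] = state0["ages"]
        for v in range(tree.n_nodes):
            key = f"age_node{v}"
            if key in s.index:
                ages[v] = s.loc[key, "median"]
            name_key = f"age_{tree.names[v]}" if tree.names[v] else None
            if name_key and name_key in s.index:
                ages[v] = s.loc[name_key, "median"]
        # medians of independent marginals need not be jointly consistent;
        # nudge parents above children where necessary
        for v in tree.postorder:
            p = tree.parent[v]
            if p >= 0 and ages[p] <= ages[v]:
                ages[p] = ages[v] + 1e-9
        return DatedTree(tree.parent.copy(), list(tree.names), ages)


def _empirical_freqs(matrix: Supermatrix) -> np.ndarray:
    counts = np.zeros(4)
    for i, b in enumerate("ACGT"):
        counts[i] = (matrix.matrix == b).sum()
    if counts.sum() == 0:
        return np.full(4, 0.25)
    f = counts / counts.sum()
    return np.clip(f, 1e-4, None) / np.clip(f, 1e-4, None).sum()
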