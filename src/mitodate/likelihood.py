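"""Partitioned GTR(+I)+Gamma likelihood, branch-length MLEs and ancestral states.

The likelihood is Felsenstein's pruning algorithm with per-partition rate
mixtures (optional invariant class plus discrete Gamma categories).  ``N`` and
gap characters are fully ambiguous (partial likelihood 1 for every state).
Site patterns are compressed per model group, and partitions that share a
model object are evaluated together, so the same evaluator serves both ML
optimisation and MCMC tip-dating.

Ancestral states are *marginal* reconstructions: the per-site posterior over
states at one internal node, integrating over all other nodes, with the MAP
state reported (exact posterior ties give ``N``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from mitodate.substmodel import BASES, SubstModel
from mitodate.supermatrix import Supermatrix
from mitodate.trees import Tree

logger = logging.getLogger(__name__)

__all__ = [
    "SupermatrixLikelihood", "SitePosterior", "pruning_loglik",
    "optimize_branch_lengths", "marginal_ancestral", "mask_missing",
]

_MIN_BL = 1e-9
_MAX_BL = 20.0


def _tip_partial_row(seq: str) -> np.ndarray:
    """(n_sites, 4) partial likelihoods: one-hot for ACGT, ones otherwise."""
    out = np.ones((len(seq), 4))
    lut = {b: i for i, b in enumerate(BASES)}
    for i, c in enumerate(seq):
        j = lut.get(c)
        if j is not None:
            out[i] = 0.0
            out[i, j] = 1.0
    return out


@dataclass
class SitePosterior:
    """Per-site marginal posterior at one internal node."""

    node: int
    probs: np.ndarray  # (n_sites, 4)
    map_sequence: str
    masked: np.ndarray  # bool per site (set by mask_missing workflows)


class SupermatrixLikelihood:
    """Reusable pruning-likelihood evaluator on a fixed topology.

    Parameters
    ----------
    matrix : Supermatrix (or anything with ``taxa``, ``matrix``, ``partitions``)
    tree : rooted tree whose tip names match the matrix taxa
    models : dict partition name -> SubstModel; partitions sharing the *same
        object* are pooled into one model group (tied parameters).
    """

    def __init__(self, matrix: Supermatrix, tree: Tree,
                 models: dict[str, SubstModel]):
        taxa = set(matrix.taxa)
        tips = set(tree.tip_names())
        if taxa != tips:
            raise ValueError(
                f"taxon mismatch: matrix-only={sorted(taxa - tips)}, "
                f"tree-only={sorted(tips - taxa)}"
            )
        missing = set(matrix.partitions) - set(models)
        if missing:
            raise ValueError(f"no model for partitions {sorted(missing)}")
        self.tree = tree
        self.n_sites = matrix.n_sites
        self._tip_rows = [tree.tip_index(t) for t in matrix.taxa]

        # group partitions by model identity
        group_of: dict[int, int] = {}
        self.group_models: list[SubstModel] = []
        group_sites: list[list[np.ndarray]] = []
        for pname, sites in matrix.partitions.items():
            m = models[pname]
            gi = group_of.get(id(m))
            if gi is None:
                gi = len(self.group_models)
                group_of[id(m)] = gi
                self.group_models.append(m)
                group_sites.append([])
            group_sites[gi].append(np.asarray(sites))

        # pattern-compress each group
        self.groups = []
        row_of_tip = {tree.tip_index(t): i for i, t in enumerate(matrix.taxa)}
        enc = np.full((tree.n_nodes,), -1, dtype=int)
        for gi, sites_list in enumerate(group_sites):
            sites = np.concatenate(sites_list)
            cols = matrix.matrix[:, sites]  # (n_taxa, n_group_sites)
            joined = np.array(["".join(c) for c in cols.T])
            patterns, inverse, counts = np.unique(
                joined, return_inverse=True, return_counts=True
            )
            npat = len(patterns)
            tip_partials = np.ones((tree.n_nodes, npat, 4))
            for ti, taxon in enumerate(matrix.taxa):
                tip_partials[tree.tip_index(taxon)] = _tip_partial_row(
                    "".join(p[ti] for p in patterns)
                )
            self.groups.append({
                "sites": sites, "counts": counts.astype(float),
                "pattern_of_site": inverse, "tip_partials": tip_partials,
            })

    # ------------------------------------------------------------- evaluation
    def set_group_model(self, gi: int, model: SubstModel) -> None:
        self.group_models[gi] = model

    def _branch_P(self, model: SubstModel, blens: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """P[node, cat] for every non-root node; returns (P, rates, weights)."""
        rates, weights = model.mixture()
        lam, V, Vinv = model.decomposition()
        t_eff = blens[:, None] * rates[None, :]  # (n_nodes, m)
        E = np.exp(lam[None, None, :] * t_eff[:, :, None])  # (n, m, 4)
        P = (V[None, None] * E[:, :, None, :]) @ Vinv
        np.clip(P, 0.0, None, out=P)
        P /= P.sum(axis=3, keepdims=True)
        return P, rates, weights

    def _down_pass(self, gi: int, blens: np.ndarray):
        """Post-order partials for group gi.

        Returns ``(down, logscale, P, weights, model)`` where ``down[v]`` has
        shape (m, n_patterns, 4) -- mixture component first for fast matmul.
        """
        model = self.group_models[gi]
        g = self.groups[gi]
        P, rates, weights = self._branch_P(model, blens)
        Pt = P.swapaxes(2, 3)  # (n, m, 4, 4) transposed per branch/category
        npat = g["tip_partials"].shape[1]
        logscale = np.zeros(npat)
        m = len(rates)
        down: list = [None] * self.tree.n_nodes
        tips = g["tip_partials"]
        for v in self.tree.postorder:
            if self.tree.is_tip[v]:
                down[v] = np.broadcast_to(tips[v], (m, npat, 4))
                continue
            acc = None
            for c in self.tree.children[v]:
                contrib = np.matmul(down[c], Pt[c])  # (m, p, 4)
                acc = contrib if acc is None else acc * contrib
            mx = acc.max(axis=(0, 2))
            mx = np.where(mx > 0, mx, 1.0)
            acc /= mx[None, :, None]
            logscale += np.log(mx)
            down[v] = acc
        return down, logscale, P, weights, model

    def group_loglik(self, gi: int, blens: np.ndarray) -> float:
        down, logscale, P, weights, model = self._down_pass(gi, blens)
        g = self.groups[gi]
        site_lik = (down[self.tree.root] @ model.freqs).T @ weights
        site_lik = np.maximum(site_lik, 1e-300)
        return float((g["counts"] * (np.log(site_lik) + logscale)).sum())

    def loglik(self, blens: np.ndarray) -> float:
        blens = np.asarray(blens, dtype=float)
        return sum(self.group_loglik(gi, blens) for gi in range(len(self.groups)))

    # -------------------------------------------------- ancestral posteriors
    def node_posterior(self, node: int, blens: np.ndarray) -> np.ndarray:
        """(n_sites, 4) marginal posterior over states at ``node``."""
        if self.tree.is_tip[node]:
            raise ValueError("ancestral reconstruction targets an internal node")
        out = np.empty((self.n_sites, 4))
        for gi in range(len(self.groups)):
            g = self.groups[gi]
            down, _, P, weights, model = self._down_pass(gi, blens)
            m, npat, _ = down[self.tree.root].shape
            Pt = P.swapaxes(2, 3)
            up = {self.tree.root: np.broadcast_to(
                model.freqs, (m, npat, 4)).copy()}
            # pre-order: outside likelihood as a function of each node's state
            for v in self.tree.preorder:
                for c in self.tree.children[v]:
                    sib = np.array(up[v], copy=True)
                    for s in self.tree.children[v]:
                        if s != c:
                            sib *= np.matmul(down[s], Pt[s])
                    u = np.matmul(sib, P[c])  # contract over parent state j
                    mx = u.max(axis=(0, 2))
                    mx = np.where(mx > 0, mx, 1.0)
                    up[c] = u / mx[None, :, None]
            post = np.einsum("mpi,m->pi", up[node] * down[node], weights)
            tot = post.sum(axis=1, keepdims=True)
            tot = np.where(tot > 0, tot, 1.0)
            post /= tot
            out[g["sites"]] = post[g["pattern_of_site"]]
        return out


# --------------------------------------------------------------- public API
def pruning_loglik(matrix: Supermatrix, tree: Tree,
                   models: dict[str, SubstModel]) -> float:
    """Total log-likelihood of the partitioned matrix on the tree."""
    return SupermatrixLikelihood(matrix, tree, models).loglik(tree.lengths)


def optimize_branch_lengths(
    matrix: Supermatrix, tree: Tree, models: dict[str, SubstModel],
    tol: float = 1e-6, max_sweeps: int = 30,
) -> tuple[Tree, float]:
    """Coordinate-wise branch-length MLEs on the fixed topology.

    Each sweep optimises every branch in turn with bounded Brent search; the
    log-likelihood is non-decreasing per sweep.  Returns the re-lengthed tree
    and the final log-likelihood.  Non-convergence logs a warning.
    """
    ev = SupermatrixLikelihood(matrix, tree, models)
    blens = np.maximum(tree.lengths.copy(), _MIN_BL)
    blens[tree.root] = 0.0
    last = ev.loglik(blens)
    converged = False
    for sweep in range(max_sweeps):
        for v in range(tree.n_nodes):
            if v == tree.root:
                continue

            def nll(x, v=v):
                b = blens.copy()
                b[v] = x
                return -ev.loglik(b)

            res = minimize_scalar(nll, bounds=(_MIN_BL, _MAX_BL),
                                  method="bounded",
                                  options={"xatol": 1e-8})
            if -res.fun >= -nll(blens[v]):
                blens[v] = res.x
        cur = ev.loglik(blens)
        if cur < last - 1e-9:
            logger.warning("lnL decreased within a sweep (%.3g)", cur - last)
        if abs(cur - last) < tol:
            converged = True
            last = cur
            break
        last = cur
    if not converged:
        logger.warning("branch-length optimisation: no convergence after %d sweeps "
                       "(last lnL %.6f)", max_sweeps, last)
    out = tree.copy()
    out.lengths = blens
    return out, last


def marginal_ancestral(
    matrix: Supermatrix, tree: Tree, models: dict[str, SubstModel],
    node: int,
) -> SitePosterior:
    """Marginal ancestral posterior and MAP sequence at an internal node.

    The per-site posterior is proportional to the stationary-frequency-weighted
    product of the partial likelihoods above and below the node.  Exact MAP
    ties emit ``N``.
    """
    ev = SupermatrixLikelihood(matrix, tree, models)
    probs = ev.node_posterior(node, tree.lengths)
    best = probs.max(axis=1)
    # posterior ties emit N; "equal" means within floating-point noise
    is_tie = (probs >= best[:, None] * (1.0 - 1e-9)).sum(axis=1) > 1
    map_idx = probs.argmax(axis=1)
    chars = np.array(list(BASES))[map_idx]
    chars[is_tie] = "N"
    return SitePosterior(node=node, probs=probs, map_sequence="".join(chars),
                         masked=np.zeros(probs.shape[0], dtype=bool))


def mask_missing(ancestral_sequence: str, designated_descendants: list[str]) -> str:
    """N-out sites missing in any designated descendant.

    A site is treated as missing when any listed descendant has ``N`` or a gap
    there; elsewhere the reconstruction is kept.
    """
    for d in designated_descendants:
        if len(d) != len(ancestral_sequence):
            raise ValueError("descendant length does not match ancestral sequence")
    out = list(ancestral_sequence)
    for i in range(len(out)):
        for d in designated_descendants:
            if d[i] in "N-":
                out[i] = "N"
                break
    return "".join(out)
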