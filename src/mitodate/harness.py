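"""Robustness validation: down-sampling series, error injection, recovery.

The harness wires the whole chain together on truth-known synthetic data:

    simulate reads -> filter -> (down-sample) -> dereplicate -> cluster at 93%
    -> end-trim -> map -> pileup -> consensus -> supermatrix -> branch-length
    MLEs -> marginal ancestral reconstruction + missing-data mask -> tip-dating
    -> focal-node posterior summary

and repeats it across down-sampling levels, 1% error-injection modes and
seeds, reporting a stability table and verdicts.  The default scenario is a
scaled-down analogue of a two-ancient-specimen mitogenome study: two damaged,
PCR-duplicated ancient libraries from sister individuals, a related reference
taxon used for mapping, and two outgroup genomes, on a 1.5 kb circular
"mini-mitogenome" so that the full series runs at desk scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from mitodate.consensus import build_pileup, call_consensus, trim_reads
from mitodate.dating import (
    LogNormalPrior, MCMCConfig, PriorSet, TipDatingModel, TruncatedNormalPrior,
)
from mitodate.likelihood import (
    marginal_ancestral, mask_missing, optimize_branch_lengths,
)
from mitodate.reads import (
    Read, cluster_greedy, dereplicate, downsample, filter_reads,
    map_to_reference,
)
from mitodate.simulate import (
    AmplificationModel, DamageModel, FragmentModel, amplify_and_sequence,
    apply_damage, evolve_sequences, fragmentize, inject_errors,
)
from mitodate.substmodel import SubstModel
from mitodate.supermatrix import AnnotatedGenome, Gene, Supermatrix, build_supermatrix
from mitodate.trees import DatedTree, Tree

logger = logging.getLogger(__name__)

__all__ = [
    "ValidationScenario", "StabilityTable", "simulate_scenario_reads",
    "run_condition", "downsampling_series", "error_injection_series",
    "recovery_experiment", "paired_ancestor_tip_comparison", "stability_report",
]


# ------------------------------------------------------------------ scenario
def _default_genes() -> list[Gene]:
    return [
        Gene("CDS1", 0, 600, "H", "CDS"),
        Gene("CDS2", 594, 1200, "L", "CDS"),  # 6 bp overlap with CDS1
        Gene("RNA1", 1200, 1380, "H", "rRNA"),
        Gene("DLOOP", 1380, 1500, "H", "D-loop"),
    ]


@dataclass
class ValidationScenario:
    """Truth-known study design for the robustness series.

    Two ancient sister individuals (A1, A2; tip age 0.10 Ma, true tMRCA
    0.15 Ma) diverged from a related dated individual S at the focal node
    (0.40 Ma); two modern outgroups (O1, O2) and a root at 1.20 Ma complete
    the tree.  Reads are simulated with terminal deamination damage and PCR
    duplicate multiplicities, mapped against the true sequence of S (a
    congeneric reference, as in real ancient-mitogenome practice).
    """

    genome_length: int = 1500
    genes: list[Gene] = field(default_factory=_default_genes)
    newick: str = "(((A1,A2)anc,S)focal,(O1,O2)out)root;"
    tip_ages: dict = field(default_factory=lambda: {
        "A1": 0.10, "A2": 0.10, "S": 0.10, "O1": 0.0, "O2": 0.0})
    node_ages: dict = field(default_factory=lambda: {
        "anc": 0.15, "focal": 0.40, "out": 0.80, "root": 1.20})
    clock_rate: float = 0.05  # substitutions/site/Ma
    kappa: float = 8.0
    freqs: tuple = (0.32, 0.26, 0.13, 0.29)
    alpha: float = 0.5
    ancient_taxa: tuple = ("A1", "A2")
    reference_taxon: str = "S"
    n_templates: int = 1650
    frag: FragmentModel = field(default_factory=FragmentModel)
    damage: DamageModel = field(default_factory=DamageModel)
    amp: AmplificationModel = field(default_factory=lambda: AmplificationModel(mean=3.0))
    # read processing / consensus
    min_read_len: int = 30
    id_threshold: float = 0.93
    trim_k: int = 3
    max_mismatch_frac: float = 0.15
    # dating
    chain_length: int = 20_000
    sample_every: int = 20
    focal_tips: tuple = ("ANC", "S")  # MRCA defining the reported divergence

    def subst_model(self) -> SubstModel:
        return SubstModel.hky(self.kappa, np.array(self.freqs),
                              alpha=self.alpha, ncat=4)

    def dated_tree(self) -> DatedTree:
        tree = Tree.from_newick(self.newick)
        ages = np.zeros(tree.n_nodes)
        for i in range(tree.n_nodes):
            name = tree.names[i]
            if tree.is_tip[i]:
                ages[i] = self.tip_ages[name]
            else:
                ages[i] = self.node_ages[name]
        return DatedTree(tree.parent.copy(), list(tree.names), ages)

    def true_sequences(self, seed: int) -> dict[str, str]:
        sim = evolve_sequences(self.dated_tree(), self.subst_model(),
                               length=self.genome_length, seed=seed,
                               clock_rate=self.clock_rate)
        return sim.sequences

    def priors(self) -> PriorSet:
        return PriorSet(
            tip_ages={
                "ANC": TruncatedNormalPrior(0.20, 0.10, low=0.10, high=0.43),
                "S": TruncatedNormalPrior(0.1125, 0.05, low=0.0),
            },
            node_calibrations={"root": LogNormalPrior(1.2, 0.3)},
            clock_mean=LogNormalPrior(0.05, 0.1),
        )


@dataclass
class StabilityTable:
    """Per condition x seed: the focal-node posterior summary."""

    table: pd.DataFrame  # columns: condition, seed, median, hpd_lower, hpd_upper, ess

    def rows(self) -> pd.DataFrame:
        return self.table


# --------------------------------------------------------------- simulation
def simulate_scenario_reads(
    scenario: ValidationScenario, seed: int
) -> tuple[dict[str, str], dict[str, list[Read]]]:
    """(true sequences per taxon, damaged duplicate-inflated reads per ancient tip)."""
    truth = scenario.true_sequences(seed)
    reads: dict[str, list[Read]] = {}
    for k, taxon in enumerate(scenario.ancient_taxa):
        s = (seed * 101 + 7 * k + 1) % (2**31 - 1)
        frags = fragmentize(truth[taxon], scenario.frag, scenario.n_templates,
                            seed=s)
        frags = apply_damage(frags, scenario.damage, seed=s + 1)
        reads[taxon] = amplify_and_sequence(frags, scenario.amp, seed=s + 2)
    return truth, reads


# ----------------------------------------------------------------- pipeline
def _consensus_from_reads(scenario: ValidationScenario, reads: list[Read],
                          reference: str) -> str:
    reads = filter_reads(reads, scenario.min_read_len)
    uniq = dereplicate(reads)
    clusters = cluster_greedy(uniq, scenario.id_threshold, strand_both=True)
    centroids = [c.centroid for c in clusters]
    trimmed = trim_reads(centroids, scenario.trim_k)
    placements, _ = map_to_reference(
        trimmed, reference, k=16, max_mismatch_frac=scenario.max_mismatch_frac)
    pileup = build_pileup(placements, trimmed, reference)
    return call_consensus(pileup)


def run_condition(
    scenario: ValidationScenario,
    truth: dict[str, str],
    reads_by_taxon: dict[str, list[Read]],
    seed: int,
    downsample_to: int | None = None,
    error_mode: str | None = None,
    error_rate: float = 0.01,
    downsample_order: str = "before_clustering",
) -> dict:
    """One full pipeline run; returns the focal-node posterior summary row.

    ``downsample_to=None`` is the no-down-sampling baseline.  ``error_mode``
    is None, ``"consensus"`` (1% substitutions into finished consensus
    sequences) or ``"raw_reads"`` (into reads before consensus calling).
    """
    reference = truth[scenario.reference_taxon]
    consensus: dict[str, str] = {}
    for k, taxon in enumerate(scenario.ancient_taxa):
        reads = filter_reads(reads_by_taxon[taxon], scenario.min_read_len)
        if downsample_to is not None and downsample_order == "before_clustering":
            if downsample_to > len(reads):
                logger.info("level %d exceeds available reads (%d): using all",
                            downsample_to, len(reads))
            reads = downsample(reads, downsample_to, seed=seed * 17 + k)
        if error_mode == "raw_reads":
            reads = inject_errors(reads, error_rate, seed=seed * 23 + k)
        uniq = dereplicate(reads)
        clusters = cluster_greedy(uniq, scenario.id_threshold, strand_both=True)
        centroids = [c.centroid for c in clusters]
        if downsample_to is not None and downsample_order == "after_clustering":
            centroids = downsample(centroids, downsample_to, seed=seed * 17 + k)
        trimmed = trim_reads(centroids, scenario.trim_k)
        placements, _ = map_to_reference(
            trimmed, reference, k=16,
            max_mismatch_frac=scenario.max_mismatch_frac)
        pileup = build_pileup(placements, trimmed, reference)
        consensus[taxon] = call_consensus(pileup)
    if error_mode == "consensus":
        for k, taxon in enumerate(scenario.ancient_taxa):
            consensus[taxon] = inject_errors(consensus[taxon], error_rate,
                                             seed=seed * 29 + k)

    genomes = []
    for taxon in [*scenario.ancient_taxa, scenario.reference_taxon, "O1", "O2"]:
        seq = consensus.get(taxon, truth[taxon])
        genomes.append(AnnotatedGenome(taxon, seq, scenario.genes))
    matrix = build_supermatrix(genomes)

    # ancestral reconstruction of the ancient pair's MRCA on the fixed topology
    topo = Tree.from_newick(scenario.newick)
    recon_model = SubstModel(
        np.ones(6), np.asarray(_empirical_freqs(matrix)), alpha=scenario.alpha,
        ncat=4)
    models = {p: recon_model for p in matrix.partitions}
    opt_tree, _ = optimize_branch_lengths(matrix, topo, models, max_sweeps=5)
    anc_node = opt_tree.mrca(scenario.ancient_taxa)
    sp = marginal_ancestral(matrix, opt_tree, models, anc_node)
    masked = mask_missing(
        sp.map_sequence, [matrix.row(t) for t in scenario.ancient_taxa])

    dating_matrix = matrix.replace_taxon(list(scenario.ancient_taxa), "ANC", masked)
    dating_topo = Tree.from_newick("((ANC,S)focal,(O1,O2)out)root;")
    model = TipDatingModel(
        dating_matrix, dating_topo, scenario.priors(),
        tip_ages={"O1": 0.0, "O2": 0.0},
    )
    cfg = MCMCConfig(chain_length=scenario.chain_length,
                     sample_every=scenario.sample_every,
                     seed=(seed * 37 + 5) % (2**31 - 1))
    res = model.fit(cfg)
    row = res.node_age_summary(scenario.focal_tips)
    return {
        "median": float(row["median"]), "hpd_lower": float(row["hpd_lower"]),
        "hpd_upper": float(row["hpd_upper"]), "ess": float(row["ess"]),
        "n_unambiguous_anc": sum(1 for c in masked if c in "ACGT"),
    }


def _empirical_freqs(matrix: Supermatrix) -> np.ndarray:
    counts = np.array([(matrix.matrix == b).sum() for b in "ACGT"], float)
    if counts.sum() == 0:
        return np.full(4, 0.25)
    return counts / counts.sum()


# -------------------------------------------------------------------- series
def downsampling_series(
    scenario: ValidationScenario,
    levels=(None, 1000, 500, 300, 100),
    seeds=(1, 2, 3, 4, 5),
    downsample_order: str = "before_clustering",
) -> StabilityTable:
    """Down-sampling series: one pipeline run per level x seed.

    ``None`` in ``levels`` is the no-down-sampling baseline; a level exceeding
    the available reads degrades to the full set (logged).
    """
    rows = []
    for seed in seeds:
        truth, reads = simulate_scenario_reads(scenario, seed)
        for level in levels:
            label = "all" if level is None else f"reads={level}"
            out = run_condition(scenario, truth, reads, seed,
                                downsample_to=level,
                                downsample_order=downsample_order)
            rows.append({"condition": label, "seed": seed, **out})
    return StabilityTable(pd.DataFrame(rows))


def error_injection_series(
    scenario: ValidationScenario,
    rate: float = 0.01,
    modes=("consensus", "raw_reads"),
    seeds=(1, 2, 3, 4, 5),
) -> StabilityTable:
    """Baseline plus 1%-substitution injections into consensus and raw reads."""
    if not (0.0 <= rate <= 1.0):
        raise ValueError("rate must be in [0, 1]")
    rows = []
    for seed in seeds:
        truth, reads = simulate_scenario_reads(scenario, seed)
        out = run_condition(scenario, truth, reads, seed)
        rows.append({"condition": "baseline", "seed": seed, **out})
        for mode in modes:
            out = run_condition(scenario, truth, reads, seed,
                                error_mode=mode, error_rate=rate)
            rows.append({"condition": f"error={mode}", "seed": seed, **out})
    return StabilityTable(pd.DataFrame(rows))


# ------------------------------------------------------------------ recovery
def recovery_experiment(
    tree: DatedTree,
    model: SubstModel,
    clock_rate: float,
    seq_length: int,
    priors: PriorSet,
    focal_tips,
    n_replicates: int = 20,
    seed: int = 0,
    chain_length: int = 15_000,
    sample_every: int = 15,
    tip_ages: dict | None = None,
) -> pd.DataFrame:
    """Truth-known parameter recovery: simulate -> date -> compare to truth.

    Sequences are evolved directly on the chronogram (no read stage), dated
    on the true topology, and the focal MRCA age is compared with its true
    value per replicate.  Returns one row per replicate with the posterior
    median, HPD bounds, truth, error and coverage indicator; pipeline failures
    are recorded as rows with ``ok=False`` rather than raised.
    """
    focal_true = float(tree.ages[tree.mrca(focal_tips)])
    if tip_ages is None:
        tip_ages = {n: float(tree.ages[tree.tip_index(n)])
                    for n in tree.tip_names()}
    rows = []
    for rep in range(n_replicates):
        rep_seed = (seed * 1000 + rep) % (2**31 - 1)
        try:
            sim = evolve_sequences(tree, model, length=seq_length,
                                   seed=rep_seed, clock_rate=clock_rate)
            matrix = Supermatrix.from_sequences(sim.tips())
            topo = Tree.from_newick(tree.to_newick(lengths=False))
            dating = TipDatingModel(matrix, topo, priors, tip_ages=tip_ages)
            cfg = MCMCConfig(chain_length=chain_length,
                             sample_every=sample_every, seed=rep_seed + 1)
            res = dating.fit(cfg)
            s = res.node_age_summary(focal_tips)
            rows.append({
                "replicate": rep, "ok": True, "true_age": focal_true,
                "median": float(s["median"]), "hpd_lower": float(s["hpd_lower"]),
                "hpd_upper": float(s["hpd_upper"]), "ess": float(s["ess"]),
                "error": float(s["median"]) - focal_true,
                "covered": bool(s["hpd_lower"] <= focal_true <= s["hpd_upper"]),
            })
        except Exception as exc:  # recorded, not fatal
            logger.error("replicate %d failed: %s", rep, exc)
            rows.append({"replicate": rep, "ok": False, "true_age": focal_true,
                         "median": np.nan, "hpd_lower": np.nan,
                         "hpd_upper": np.nan, "ess": np.nan,
                         "error": np.nan, "covered": False})
    df = pd.DataFrame(rows)
    ok = df[df["ok"]]
    df.attrs["bias"] = float(ok["error"].mean()) if len(ok) else np.nan
    df.attrs["bias_mc_se"] = (float(ok["error"].std(ddof=1) / np.sqrt(len(ok)))
                              if len(ok) > 1 else np.nan)
    df.attrs["rmse"] = float(np.sqrt((ok["error"] ** 2).mean())) if len(ok) else np.nan
    df.attrs["coverage"] = float(ok["covered"].mean()) if len(ok) else np.nan
    return df


def paired_ancestor_tip_comparison(
    scenario: ValidationScenario | None = None,
    terminal_error_rate: float = 0.0035,
    n_replicates: int = 20,
    seed: int = 0,
) -> pd.DataFrame:
    """Ancestor-based vs tip-based dating under terminal sequence noise.

    Per replicate: evolve clean sequences, corrupt the two sister tips with
    independent random substitutions at ``terminal_error_rate`` (emulating
    residual damage inflating terminal branches by 0.3-0.4%), then estimate
    the focal divergence twice -- from the error-bearing tips directly, and
    from the masked reconstructed ancestor -- and record both absolute errors.
    """
    sc = scenario or ValidationScenario()
    truth_tree = sc.dated_tree()
    focal_true = float(truth_tree.ages[truth_tree.mrca(
        [*sc.ancient_taxa, sc.reference_taxon])])
    rows = []
    for rep in range(n_replicates):
        rep_seed = (seed * 1000 + rep) % (2**31 - 1)
        truth = sc.true_sequences(rep_seed)
        noisy = {
            t: inject_errors(truth[t], terminal_error_rate, seed=rep_seed + 10 + i)
            for i, t in enumerate(sc.ancient_taxa)
        }
        seqs = {**{t: truth[t] for t in ("S", "O1", "O2")}, **noisy}

        # tip-based: date with the two noisy tips present
        topo_full = Tree.from_newick(sc.newick)
        pr_full = sc.priors()
        pr_full.tip_ages = {
            "A1": TruncatedNormalPrior(0.125, 0.05, low=0.0),
            "A2": TruncatedNormalPrior(0.125, 0.05, low=0.0),
            "S": pr_full.tip_ages["S"],
        }
        m_full = TipDatingModel(Supermatrix.from_sequences(seqs), topo_full,
                                pr_full, tip_ages={"O1": 0.0, "O2": 0.0})
        cfg = MCMCConfig(chain_length=sc.chain_length // 2,
                         sample_every=sc.sample_every, seed=rep_seed + 3)
        tip_med = float(m_full.fit(cfg).node_age_summary(
            ["A1", "A2", "S"])["median"])

        # ancestor-based: reconstruct the pair's MRCA, mask, date
        matrix = Supermatrix.from_sequences(seqs)
        recon = SubstModel(np.ones(6), _empirical_freqs(matrix),
                           alpha=sc.alpha, ncat=4)
        models = {p: recon for p in matrix.partitions}
        opt_tree, _ = optimize_branch_lengths(matrix, topo_full, models,
                                              max_sweeps=5)
        sp = marginal_ancestral(matrix, opt_tree, models,
                                opt_tree.mrca(sc.ancient_taxa))
        masked = mask_missing(sp.map_sequence,
                              [seqs[t] for t in sc.ancient_taxa])
        dm = matrix.replace_taxon(list(sc.ancient_taxa), "ANC", masked)
        m_anc = TipDatingModel(dm, Tree.from_newick("((ANC,S)focal,(O1,O2)out)root;"),
                               sc.priors(), tip_ages={"O1": 0.0, "O2": 0.0})
        anc_med = float(m_anc.fit(cfg).node_age_summary(["ANC", "S"])["median"])

        rows.append({
            "replicate": rep, "true_age": focal_true,
            "tip_based_median": tip_med, "ancestor_based_median": anc_med,
            "tip_based_abs_error": abs(tip_med - focal_true),
            "ancestor_based_abs_error": abs(anc_med - focal_true),
        })
    return pd.DataFrame(rows)


# ------------------------------------------------------------------- report
def stability_report(table: StabilityTable | pd.DataFrame,
                     tolerance: float = 0.15,
                     baseline: str = "all") -> tuple[pd.DataFrame, str]:
    """Stable/unstable verdict per condition against the per-seed baseline.

    A condition x seed row is stable iff ``|median - baseline median| <=
    tolerance x baseline median`` (relative band, always printed); a condition
    is stable iff all its seeds are.  Returns (verdict table, summary text).
    """
    df = table.table if isinstance(table, StabilityTable) else table
    base = df[df["condition"] == baseline]
    if base.empty and "baseline" in set(df["condition"]):
        baseline = "baseline"
        base = df[df["condition"] == baseline]
    if base.empty:
        raise ValueError(f"missing baseline condition {baseline!r}")
    base_by_seed = base.set_index("seed")["median"]
    rows = []
    for _, r in df.iterrows():
        if r["seed"] not in base_by_seed.index:
            raise ValueError(f"no baseline row for seed {r['seed']}")
        b = base_by_seed[r["seed"]]
        dev = abs(r["median"] - b)
        rows.append({
            "condition": r["condition"], "seed": r["seed"],
            "median": r["median"], "baseline_median": b,
            "rel_deviation": dev / b if b > 0 else np.inf,
            "stable": bool(dev <= tolerance * b),
        })
    per_row = pd.DataFrame(rows)
    verdict = (per_row.groupby("condition", sort=False)["stable"]
               .all().rename("stable").reset_index())
    lines = [f"stability tolerance: {tolerance:.0%} of the baseline median"]
    for _, v in verdict.iterrows():
        worst = per_row[per_row["condition"] == v["condition"]]["rel_deviation"].max()
        tag = "stable" if v["stable"] else "UNSTABLE"
        lines.append(f"  {v['condition']:>18}: {tag} (max deviation {worst:.1%})")
    return per_row, "\n".join(lines)
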