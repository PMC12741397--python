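# mitodate

Divergence dating for low-coverage, damage-prone ancient mitochondrial
genomes.

Ancient-DNA mitogenome libraries are short-fragment and low-complexity:
post-mortem cytosine deamination produces C→T misincorporations at 5′ read
ends (apparent G→A at 3′ ends), and PCR over-amplification of a few template
molecules floods the library with duplicates. Both artifacts inflate the
terminal branches of the sequenced individuals in a phylogeny and bias
tip-based molecular dating. `mitodate` implements, as a tested reusable
pipeline, the ancestral-node dating strategy that sidesteps this: collapse
duplicates by dereplication and greedy 93%-identity clustering, end-trim and
call a majority consensus, assemble a partitioned mitogenome supermatrix,
reconstruct the most recent common ancestor of the ancient individuals by
maximum-likelihood marginal ancestral reconstruction (masking sites missing
in either descendant), and date from that reconstructed ancestor with a
Bayesian tip-dating model — plus the validation machinery (read
down-sampling and 1% error injection) that shows the resulting node ages are
stable where tip-based ages are not.

It is aimed at molecular palaeobiologists and phylogeneticists who want the
whole chain — from raw (or simulated) reads to posterior node ages — as
composable Python functions with a thin CLI.

## The models at the core

**Sequence likelihood.** Felsenstein pruning under partitioned GTR/HKY(+I)+Γ
models: Q normalised to unit expected rate, k = 4 discrete Gamma categories
(category means) plus an optional invariant class, N/gaps fully ambiguous.
Branch-length MLEs by coordinate-wise Brent; **marginal** ancestral
reconstruction gives the per-site posterior P(state at node | data) with MAP
ties emitted as N.

**Tip dating.** On a fixed rooted topology with node ages *t* (Ma) and
per-branch rates *r* (subst/site/Ma), the posterior is

  P(t, r, θ | D) ∝ L(D | durations × r) · p_coal(t | Ne) · ∏ᵦ LogNormal(rᵦ | M, σ) · calibrations(t) · p(θ),

with a constant-size **serial coalescent** tree prior (lineage counts change
at both sampling and coalescent events), an **uncorrelated lognormal relaxed
clock** (real-space mean rate M, log-space spread σ), truncated-normal
priors on radiocarbon-dated tip ages, and normal/lognormal calibrations on
selected internal nodes. `TipDatingModel.fit()` runs Metropolis–Hastings
MCMC and returns a `TipDatingResults` with traces, posterior medians,
shortest-interval 95% HPDs and ESS.

**Simulation.** `mitodate.simulate` generates the study conditions:
sequences evolved on a dated tree, circular-genome fragmentation (truncated
exponential lengths, mean ≈ 39 bp in [30, 76]), terminal deamination damage
δ·e^(−λ(i−1)), zero-truncated-geometric PCR duplicate multiplicities, and
uniform substitution-error injection — with true coordinates and true
ancestral sequences retained.

## Worked example

A scaled-down two-ancient-specimen study: two damaged, duplicate-inflated
libraries from sister individuals (tips 0.10 Ma, true tMRCA 0.15 Ma), a
dated relative S (the mapping reference) splitting from them at the focal
node 0.40 Ma, two modern outgroups, root 1.20 Ma, on a 1.5 kb circular
mini-mitogenome:

```python
from mitodate import ValidationScenario, filter_reads, dereplicate, cluster_greedy
from mitodate.harness import run_condition, simulate_scenario_reads

sc = ValidationScenario()
truth, reads = simulate_scenario_reads(sc, seed=1)
print("reads per ancient tip:", {k: len(v) for k, v in reads.items()})

uniq = dereplicate(filter_reads(reads["A1"], 30))
clusters = cluster_greedy(uniq, 0.93)
print(f"A1: {len(reads['A1'])} reads -> {len(uniq)} unique -> {len(clusters)} clusters")

out = run_condition(sc, truth, reads, seed=1)
print("focal divergence (true 0.40 Ma): "
      f"median {out['median']:.3f} Ma, 95% HPD [{out['hpd_lower']:.3f}, {out['hpd_upper']:.3f}]")
```

prints

```
reads per ancient tip: {'A1': 4954, 'A2': 4823}
A1: 4954 reads -> 1645 unique -> 1348 clusters
focal divergence (true 0.40 Ma): median 0.337 Ma, 95% HPD [0.220, 0.498]
```

Reading this: ~5,000 raw reads collapse to 1,348 clusters once PCR
duplicates are removed; the full pipeline (consensus → supermatrix →
ancestral reconstruction + mask → tip-dating MCMC) returns a posterior for
the focal divergence whose 95% HPD comfortably covers the true 0.40 Ma. The
robustness series repeats this under read down-sampling
(`mitodate.harness.downsampling_series`, levels all/1000/500/300/100) and 1%
error injection (`error_injection_series`), and `stability_report` flags any
condition whose median leaves the 15% band around the baseline.

The same stages are available from the shell:

```bash
mitodate simulate --seed 1 --out sim/
mitodate process-reads --reads sim/reads_A1.fasta --out proc/
mitodate consensus --reads proc/centroids.fasta --reference ref.fasta --out cons/
mitodate build-matrix --genomes genomes.fasta --genes genes.tsv --out matrix/
mitodate reconstruct --matrix matrix/supermatrix.fasta --tree tree.nwk \
    --node-tips A1,A2 --mask-by A1,A2 --out anc/
mitodate date --matrix matrix/supermatrix.fasta --tree tree.nwk \
    --config dating.cfg --out dated/
mitodate validate --levels 1000,500,300,100 --seeds 1,2,3 --out validation/
```

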