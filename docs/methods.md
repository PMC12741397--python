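# Methods

`mitodate` implements an end-to-end workflow for dating divergences from
low-coverage, damage-prone ancient mitochondrial genomes, together with a
synthetic-data generator that reproduces the statistical structure of such
libraries and a harness that probes the robustness of the estimates. This
note records the models, the defaults and why they were chosen, the
numerical choices, and what the synthetic experiments do and do not show.

## The problem

Ancient-DNA mitogenome libraries are short-fragment, low-complexity and
damage-bearing: cytosine deamination produces C→T misincorporations at 5′
read ends (and apparent G→A at 3′ ends), and PCR over-amplification of a few
template molecules inflates duplicate counts. Both effects lengthen the
terminal branches of the sequenced individuals in a phylogeny and bias
tip-based divergence dating upward. The workflow addresses this by (i)
dereplicating and clustering reads to collapse PCR duplicates, (ii)
end-trimming before consensus calling to remove the damage-enriched
positions, (iii) reconstructing the most recent common ancestor of the
ancient individuals by maximum-likelihood marginal ancestral reconstruction,
masking any site missing in either descendant, and (iv) dating from that
reconstructed ancestor — whose branch is free of the terminal noise — rather
than from the error-bearing tips.

## Sequence simulation (`mitodate.simulate`)

Sequences evolve site-i.i.d. along a dated tree under GTR(+I)+Γ models
(per-partition), with branch lengths = duration × rate. True internal-node
sequences are retained so reconstruction accuracy is directly measurable.

Fragmentation treats the mitogenome as circular; fragments spanning the
origin wrap, with forward-strand start coordinates. The default length
distribution is a truncated discrete exponential with offset 30 bp, mean
38.9 bp and maximum 76 bp — matching the read-length statistics typical of
filtered ancient mitochondrial libraries (minimum 30 bp is a filtering
cutoff, not a biological floor).

Damage follows the standard aDNA parameterisation: a C at 1-based 5′ offset
*i* reads as T with probability δ₅·e^(−λ(i−1)), symmetrically G→A from the
3′ end, plus an independent background error rate ε at every site. Defaults
δ₅ = δ₃ = 0.3, λ = 0.3, ε = 0.001 give terminal damage fractions of ~30%
decaying over the first ~10 positions, typical of non-UDG-treated Pleistocene
material. Background errors are applied after the deamination flips, so a
damaged T can subsequently be hit by ε like any other base.

PCR duplicate multiplicities default to a zero-truncated geometric with mean
3 (any positive-integer family is configurable); duplicates share the
template's true coordinates. Error injection replaces each A/C/G/T site with
a uniformly chosen *different* base at the given rate; N and gap characters
are never touched and never produced, because the perturbation models
substitution error, not missingness. Injections are applied independently of
earlier damage, i.e. they may hit already-damaged sites; with both at the
percent level the interaction term is negligible.

All randomness flows from one integer seed per call; identical seeds give
byte-identical outputs.

## Read processing (`mitodate.reads`)

Reads shorter than 30 bp are removed; full-length-identical reads are
collapsed with summed abundances (`;size=N;` annotations). Greedy clustering
visits reads in abundance-descending order (ties: length descending, then
id) and joins a read to the first centroid it matches at ≥ 93% identity on
either strand, else founds a new cluster. Identity is defined as matching
columns divided by the total alignment span of the best ungapped overlap
(overhangs count as gap columns; N never matches); this is a documented,
fixed definition rather than a reproduction of any particular tool's
internal semantics. A shared-k-mer prefilter (k = 8) prunes candidate
centroids for speed and never changes results at the 0.93 threshold.

The mapper is a minimal exact-seed (k = 16), ungapped-extension aligner over
both strands of a circular reference, keeping the placement with the fewest
mismatches (ties: lowest coordinate, then forward strand) subject to a
mismatch-fraction allowance. It is deliberately gap-free: the pipeline's
inputs are indel-free by construction, and on such reads it places ≥ 99% at
their true coordinates. Reads with > 50% N are dropped with a warning.

## Consensus and damage statistics (`mitodate.consensus`)

Damage profiles are computed on untrimmed reads in read orientation
(mismatch frequencies vs. the reference at each distance from either end,
restricted to reference-C / reference-G sites). Consensus is built from
cluster sequences end-trimmed by 3 bp — removing exactly the positions the
damage model enriches. A base is called only with depth ≥ 1, a strict
plurality, and more than half of the non-N observations; ties and
unresolved sites give N, because downstream masking logic expects honest
ambiguity rather than an arbitrary pick. The depth default of 1 reflects
genuinely low-coverage libraries and is configurable. The terminal partial
window of the depth profile is averaged over its own length.

## Supermatrix (`mitodate.supermatrix`)

Per protein-coding gene the first and last codons are stripped; columns
shared by the overlapping pairs ATP8/ATP6, ND4L/ND4 and ND5/ND6 are kept
once, via the first gene of each pair (a strict mode drops them from both
genes, matching the literal reading of "excluded"); L-strand genes (e.g.
ND6) enter as reverse complements to avoid strand composition bias. Codon
positions are tracked on the *original* reading frame, so exclusions cannot
silently shift the frame, and any CDS that is not a codon multiple after
exclusions is an error naming the gene. The matrix is CDS block + RNA block
+ D-loop, with partitions for codon positions 1/2/3, RNAs and D-loop.
Inputs must already be per-gene homologous columns — multiple alignment is
out of scope (real data is pre-aligned externally; simulated data is
indel-free).

## Likelihood and ancestral reconstruction (`mitodate.likelihood`)

Felsenstein pruning with per-partition rate mixtures: an optional invariant
class (weight p_inv, rate 0) plus k = 4 discrete Gamma categories using
category means, rescaled so the mixture mean is 1. Q is normalised to unit
expected rate at stationarity; P(t) comes from the symmetric
eigendecomposition, clipped and renormalised against rounding. N and gaps
are fully ambiguous. Partitions that share a model object are pooled and
pattern-compressed together, which is what makes the MCMC affordable.
Per-node scaling guards against underflow.

Branch lengths are optimised coordinate-wise (bounded Brent per branch,
lower bound 1e-9 to avoid degenerate matrices), iterated to a log-likelihood
tolerance; the log-likelihood is non-decreasing across sweeps.

Ancestral states are **marginal** reconstructions (per-site posterior at one
node, integrating over all others) — the joint reconstruction is out of
scope. MAP ties emit N, where "tie" means equality within 1e-9 relative
floating-point tolerance. The codon-model reconstruction used for real CDS
data elsewhere is deliberately approximated here by codon-position-
partitioned nucleotide models; this is a known, flagged approximation. The
missing-data mask sets the reconstruction to N at every site that is N or a
gap in any designated descendant, so the ancestor never claims information
its descendants lack.

## Tip dating (`mitodate.dating`)

The model: node ages (Ma) on a fixed rooted topology; serially sampled tips
with truncated-normal age priors; internal-node calibrations (normal or
lognormal); a constant-size serial coalescent tree prior with lineage counts
updated at sampling and coalescent events; an uncorrelated lognormal relaxed
clock — branch rates i.i.d. lognormal parameterised by the *real-space* mean
rate M and log-space spread σ (so "mean rate" means what it says; the
lognormal root-calibration prior is likewise real-space mean/sd, a
documented choice where log-space would be the alternative); HKY(+I)+Γ
likelihood per partition with branch length = duration × rate, substitution
parameters (κ, α) sampled in-chain under diffuse proper priors.

MCMC is Metropolis–Hastings with: uniform-within-bounds node-age moves, a
root stem scale move, tip-age moves (a 30/70 mixture of random walk and
independence draws from the tip's own prior), per-branch rate scale moves, a
joint "ages up / rates down" scale move that traverses the rate–time ridge,
hyperparameter moves for M and σ both alone and jointly with a deterministic
rescaling of all branch rates (keeping each rate's quantile fixed — the
hierarchical analogue of BEAST's upDown operator), including independence
draws from the hyperpriors, and Ne/κ/α scale moves. All Hastings ratios
account for the deterministic transformations; only genuine branch rates are
transformed. σ is capped at 25 (prior mass beyond is ~e⁻⁵⁰) and rate
magnitudes at e±600 for numerical safety. Prior-only mode (likelihood off)
samples the joint prior and is validated by Kolmogorov–Smirnov tests of
every directly-prior'd marginal; with the coalescent disabled
(`tree_prior="none"`) every free internal node must carry a calibration so
the prior stays proper.

Summaries: posterior medians, shortest-contiguous-interval 95% HPDs on
sorted samples, and ESS via the autocorrelation time (Geyer initial positive
sequence). The default chain is 200,000 generations thinned to every 100
with 10% burn-in — a desk-scale default chosen so a fit takes seconds to a
couple of minutes on one core; production analyses should scale
`chain_length` up by one to two orders of magnitude via the config, and the
harness uses 20,000-generation chains per condition so that the full
robustness series completes in minutes (the stability comparisons are
between medians of identically configured chains, which is insensitive to
this choice once ESS is a few tens).

## Robustness harness (`mitodate.harness`)

The default `ValidationScenario` is a scaled-down analogue of a
two-ancient-specimen study: a 1.5 kb circular "mini-mitogenome" with two CDS
(one L-strand, overlapping the other by 6 bp), an rRNA and a D-loop; two
ancient sister individuals (tips at 0.10 Ma, true tMRCA 0.15 Ma) whose
divergence from a dated relative S at 0.40 Ma is the focal node; two modern
outgroups; root 1.20 Ma; HKY (κ = 8, mitochondrial-like base composition,
Γ α = 0.5) at 0.05 substitutions/site/Ma; ~1,650 templates per ancient tip
amplified to ≈5,000 reads with damage on. The genome is scaled down ~10×
from a real mitogenome so that the 300-read condition still covers most
sites — the same *relative* coverage regime in which stability is claimed at
mitogenome scale — and so the full series runs at desk scale. Reads are
mapped against the true sequence of S, mimicking mapping against a related
reference species.

`downsampling_series` re-runs the full chain (down-sample → dereplicate →
cluster → trim → map → consensus → supermatrix → branch-length MLEs →
marginal ancestral + mask → tip-date) at read levels {all, 1000, 500, 300,
100}; `error_injection_series` injects 1% substitutions either into the
finished consensus sequences or into the raw reads before consensus calling.
Down-sampling applies to reads before clustering by default (the ordering is
exposed as an option). `stability_report` declares a condition stable when
its focal median is within 15% of the same seed's baseline median — an
explicit numeric stand-in for a qualitative "remained stable" judgement,
always printed with the report. `recovery_experiment` generalises this to
truth-known simulation (bias, RMSE, HPD coverage), and
`paired_ancestor_tip_comparison` contrasts ancestor-based with tip-based
dating under 0.3–0.4% terminal noise, the regime where terminal branches are
visibly inflated.

In the dating stage of the harness the reconstructed masked ancestor
replaces the two ancient tips as a single tip whose age prior is the
truncated-normal tMRCA prior — i.e. the ancestor's age is a free parameter
bounded by that prior, not fixed; fixing it is the documented alternative.
One GTR+Γ model is shared across partitions in the harness default (the
synthetic data is homogeneous, and tying halves the evaluation cost);
per-partition models are a constructor argument away.

## What the synthetic experiments do not show

The generator is indel-free, has no capture-bait bias, no contaminant reads
beyond an optional uniform decoy, no quality scores, and its damage obeys
the exact exponential form the profiler fits. Passing tests therefore
demonstrate the internal consistency and calibration of the pipeline — not
that real libraries satisfy these assumptions. Real-data use additionally
requires external multiple alignment, and real accessions are needed to
reproduce published mitogenome-scale numbers; the package reproduces the
*properties* (stability under down-sampling and error injection, ancestor-
over-tip accuracy) at scaled-down size.

## Known limitations

* The mapper is ungapped; indel-bearing reads will be placed with inflated
  mismatch counts or dropped.
* Marginal (not joint) ancestral reconstruction; posterior at one node at a
  time.
* The MCMC samples on a fixed topology; no tree search, no marginal
  likelihoods.
* HPD intervals assume unimodal-ish marginals (shortest contiguous
  interval).
* Medians of independent marginals need not be jointly tree-consistent; the
  exported dated tree nudges parents above children where needed.
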