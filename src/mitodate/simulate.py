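"""Synthetic data with the statistical structure of ancient mitogenome studies.

The generator chain mirrors how a damaged, PCR-over-amplified ancient library
arises from a true genome:

1. :func:`evolve_sequences` -- sequences evolved site-i.i.d. along a dated tree
   under per-partition GTR(+I)+Gamma models, retaining true internal-node
   sequences for reconstruction tests;
2. :func:`fragmentize` -- short fragments from a circular genome with an
   aDNA-like truncated length distribution;
3. :func:`apply_damage` -- terminal cytosine-deamination damage (C->T from the
   5' end, G->A from the 3' end) decaying exponentially with distance from the
   read end, plus a uniform background error rate;
4. :func:`amplify_and_sequence` -- PCR duplicate multiplicities (zero-truncated
   geometric by default) turning few templates into many reads;
5. :func:`inject_errors` -- uniform random substitutions at a fixed per-site
   rate (the 1% perturbation used in robustness checks).

All randomness flows from a single integer seed per call.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from mitodate.reads import Read, reverse_complement
from mitodate.substmodel import BASES, SubstModel, transition_matrix
from mitodate.trees import DatedTree, Tree

__all__ = [
    "DamageModel", "FragmentModel", "AmplificationModel", "Fragment",
    "SimulatedSequences", "evolve_sequences", "fragmentize", "apply_damage",
    "amplify_and_sequence", "inject_errors",
]

_A, _C, _G, _T = 0, 1, 2, 3


def _encode(seq: str) -> np.ndarray:
    lut = np.full(128, 255, dtype=np.uint8)
    for i, b in enumerate(BASES):
        lut[ord(b)] = i
    arr = lut[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    return arr


def _decode(codes: np.ndarray) -> str:
    lut = np.frombuffer(b"ACGTN", dtype=np.uint8)
    idx = np.where(codes > 3, 4, codes)
    return lut[idx].tobytes().decode("ascii")


# ----------------------------------------------------------------- models
@dataclass
class DamageModel:
    """Post-mortem deamination damage with exponential positional decay.

    The probability that a C at 5' offset ``i`` (1-based) reads as T is
    ``delta5 * exp(-lam * (i - 1))``; symmetrically G->A from the 3' end with
    amplitude ``delta3``.  ``epsilon`` is an independent uniform background
    substitution rate applied at every position.
    """

    delta5: float = 0.3
    delta3: float = 0.3
    lam: float = 0.3
    epsilon: float = 0.001

    def __post_init__(self):
        for name in ("delta5", "delta3", "epsilon"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.lam < 0:
            raise ValueError("decay rate lam must be >= 0")

    def p5(self, offsets: np.ndarray) -> np.ndarray:
        """C->T probability at 1-based 5' offsets."""
        return self.delta5 * np.exp(-self.lam * (np.asarray(offsets) - 1))

    def p3(self, offsets: np.ndarray) -> np.ndarray:
        return self.delta3 * np.exp(-self.lam * (np.asarray(offsets) - 1))


@dataclass
class FragmentModel:
    """Fragment length distribution with hard bounds.

    ``family='exponential'`` (the aDNA default) puts mass proportional to
    ``exp(-(L - min_len)/(mean - min_len))`` on integer lengths in
    ``[min_len, max_len]``; ``family='lognormal'`` uses a discretised lognormal
    with real-space mean ``mean`` and log-space sd ``dispersion``;
    ``family='constant'`` is degenerate at ``mean``.

    Defaults emulate observed ancient mitochondrial libraries: mean about
    39 bp with a hard filter window of 30-76 bp.
    """

    family: str = "exponential"
    mean: float = 38.9
    dispersion: float = 0.25
    min_len: int = 30
    max_len: int = 76

    def __post_init__(self):
        if self.min_len < 1:
            raise ValueError("min_len must be >= 1")
        if self.max_len < self.min_len:
            raise ValueError("max_len < min_len")
        if self.family not in ("exponential", "lognormal", "constant"):
            raise ValueError(f"unknown length family {self.family!r}")
        if self.family != "constant" and not (self.min_len <= self.mean <= self.max_len):
            raise ValueError("mean outside [min_len, max_len]")

    def pmf(self) -> tuple[np.ndarray, np.ndarray]:
        """(support lengths, probabilities) of the truncated distribution."""
        L = np.arange(self.min_len, self.max_len + 1)
        if self.family == "constant":
            p = (L == int(round(self.mean))).astype(float)
            if p.sum() == 0:
                raise ValueError("constant length outside bounds")
        elif self.family == "exponential":
            scale = max(self.mean - self.min_len, 1e-9)
            p = np.exp(-(L - self.min_len) / scale)
        else:  # lognormal
            sigma = self.dispersion
            mu = np.log(self.mean) - 0.5 * sigma**2
            p = np.exp(-((np.log(L) - mu) ** 2) / (2 * sigma**2)) / L
        return L, p / p.sum()

    @property
    def truncated_mean(self) -> float:
        L, p = self.pmf()
        return float((L * p).sum())

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        L, p = self.pmf()
        return rng.choice(L, size=n, p=p)


@dataclass
class AmplificationModel:
    """PCR duplicate multiplicity: how many reads each template yields.

    ``family='zt_geometric'`` draws from a zero-truncated geometric with the
    given ``mean`` (>= 1); ``family='constant'`` emits exactly ``mean`` copies.
    ``per_duplicate_error_rate`` adds independent substitutions to each copy.
    """

    family: str = "zt_geometric"
    mean: float = 3.0
    per_duplicate_error_rate: float = 0.0

    def __post_init__(self):
        if self.mean < 1:
            raise ValueError("mean multiplicity must be >= 1")
        if self.family not in ("zt_geometric", "constant"):
            raise ValueError(f"unknown multiplicity family {self.family!r}")
        if not (0.0 <= self.per_duplicate_error_rate <= 1.0):
            raise ValueError("per_duplicate_error_rate outside [0, 1]")

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.family == "constant":
            return np.full(n, int(round(self.mean)), dtype=int)
        # zero-truncated geometric on {1, 2, ...} with mean m has p = 1/m
        p = 1.0 / self.mean
        return rng.geometric(p, size=n)


@dataclass(frozen=True)
class Fragment:
    """A template molecule: contiguous (possibly origin-wrapping) substring."""

    template_id: str
    seq: str
    start: int  # 0-based on the source genome, forward strand
    length: int
    strand: str  # '+' or '-'


@dataclass
class SimulatedSequences:
    """Output of :func:`evolve_sequences`: one sequence per node."""

    tree: Tree
    sequences: dict[str, str]  # node label -> sequence
    tip_names: list[str]
    internal_names: list[str]
    node_labels: list[str]  # index-aligned with tree nodes
    partitions: dict[str, np.ndarray]  # partition name -> site indices

    def tips(self) -> dict[str, str]:
        return {n: self.sequences[n] for n in self.tip_names}

    def internals(self) -> dict[str, str]:
        return {n: self.sequences[n] for n in self.internal_names}


# ------------------------------------------------------------------ evolve
def evolve_sequences(
    tree: Tree | DatedTree,
    model: SubstModel | None = None,
    partition_spec: list[tuple[str, int, SubstModel]] | None = None,
    length: int | None = None,
    seed: int = 0,
    clock_rate: float | None = None,
) -> SimulatedSequences:
    """Evolve sequences along a tree; returns tip AND true internal sequences.

    Branch lengths in substitutions/site come from ``tree.lengths`` for a
    plain :class:`Tree`, or from ages x rates (or ``clock_rate``) for a
    :class:`DatedTree`.  Sites are i.i.d. given their partition and Gamma
    category.  ``partition_spec`` is a list of ``(name, length, model)``; when
    absent a single partition of ``length`` sites under ``model`` is used.
    """
    if partition_spec is None:
        if model is None or length is None:
            raise ValueError("need either partition_spec or (model, length)")
        partition_spec = [("all", length, model)]
    if isinstance(tree, DatedTree):
        blens = tree.branch_lengths(clock_rate)
    else:
        blens = tree.lengths
    if np.any(blens < 0):
        raise ValueError("negative branch length")

    rng = np.random.default_rng(seed)
    node_labels = [
        tree.names[i] if tree.names[i] else f"node{i}" for i in range(tree.n_nodes)
    ]
    total = sum(n for _, n, _ in partition_spec)
    seqs = np.empty((tree.n_nodes, total), dtype=np.uint8)
    partitions: dict[str, np.ndarray] = {}

    offset = 0
    for pname, plen, pmodel in partition_spec:
        sites = np.arange(offset, offset + plen)
        partitions[pname] = sites
        rates, weights = pmodel.mixture()
        cats = rng.choice(len(rates), size=plen, p=weights)
        root_states = pmodel.stationary_sample(plen, rng)
        seqs[tree.root, sites] = root_states
        for v in tree.preorder:
            p = tree.parent[v]
            if p < 0:
                continue
            parent_states = seqs[p, sites]
            child_states = parent_states.copy()
            for c, r in enumerate(rates):
                sel = cats == c
                if not sel.any():
                    continue
                t = blens[v] * r
                if t == 0:
                    continue
                P = transition_matrix(pmodel, t)
                cum = np.cumsum(P, axis=1)
                u = rng.random(int(sel.sum()))
                child_states[sel] = (
                    u[:, None] > cum[parent_states[sel]]
                ).sum(axis=1)
            seqs[v, sites] = child_states
        offset += plen

    sequences = {node_labels[i]: _decode(seqs[i]) for i in range(tree.n_nodes)}
    tip_names = [node_labels[i] for i in range(tree.n_nodes) if tree.is_tip[i]]
    internal_names = [node_labels[i] for i in range(tree.n_nodes) if not tree.is_tip[i]]
    return SimulatedSequences(tree, sequences, tip_names, internal_names,
                              node_labels, partitions)


# -------------------------------------------------------------- fragmentize
def fragmentize(
    genome: str,
    frag_model: FragmentModel,
    n_templates: int,
    seed: int = 0,
    circular: bool = True,
) -> list[Fragment]:
    """Draw template fragments with true coordinates and strand.

    The genome is treated as circular by default; fragments spanning the
    origin wrap, with ``start`` recorded on the forward strand.
    """
    if n_templates < 0:
        raise ValueError("n_templates must be >= 0")
    G = len(genome)
    if frag_model.min_len > G:
        raise ValueError("minimum fragment length exceeds genome length")
    rng = np.random.default_rng(seed)
    lengths = frag_model.sample(n_templates, rng)
    if not circular:
        lengths = np.minimum(lengths, G)
        starts = rng.integers(0, G - lengths + 1)
    else:
        starts = rng.integers(0, G, size=n_templates)
    strands = rng.choice(np.array(["+", "-"]), size=n_templates)
    doubled = genome + genome
    out = []
    for i in range(n_templates):
        s, l = int(starts[i]), int(lengths[i])
        sub = doubled[s:s + l]
        if strands[i] == "-":
            sub = reverse_complement(sub)
        out.append(Fragment(f"t{i}", sub, s, l, str(strands[i])))
    return out


# ------------------------------------------------------------------ damage
def apply_damage(
    fragments: list[Fragment], damage: DamageModel, seed: int = 0
) -> list[Fragment]:
    """Apply terminal deamination and background errors to fragment sequences.

    Damage operates in read orientation: C->T with probability
    ``delta5 * exp(-lam*(i-1))`` at 5' offset ``i``, G->A symmetrically from
    the 3' end, then independent background substitutions at rate ``epsilon``.
    """
    if not fragments:
        return []
    lens = np.array([len(f.seq) for f in fragments])
    starts = np.concatenate([[0], np.cumsum(lens)[:-1]])
    total = int(lens.sum())
    flat = _encode("".join(f.seq for f in fragments))
    pos = np.arange(total) - np.repeat(starts, lens)  # 0-based 5' offset
    from_3p = np.repeat(lens, lens) - 1 - pos  # 0-based 3' offset

    rng = np.random.default_rng(seed)
    p5 = damage.delta5 * np.exp(-damage.lam * pos)
    p3 = damage.delta3 * np.exp(-damage.lam * from_3p)
    u = rng.random(total)
    hit5 = (flat == _C) & (u < p5)
    u = rng.random(total)
    hit3 = (flat == _G) & (u < p3)
    flat = flat.copy()
    flat[hit5] = _T
    flat[hit3] = _A
    if damage.epsilon > 0:
        u = rng.random(total)
        err = (u < damage.epsilon) & (flat <= 3)
        shift = rng.integers(1, 4, size=total)
        flat[err] = (flat[err] + shift[err]) % 4

    out = []
    for i, f in enumerate(fragments):
        s = int(starts[i])
        out.append(replace(f, seq=_decode(flat[s:s + int(lens[i])])))
    return out


# ----------------------------------------------------------------- amplify
def amplify_and_sequence(
    fragments: list[Fragment], amp: AmplificationModel, seed: int = 0
) -> list[Read]:
    """Emit each fragment m times (m from the multiplicity distribution).

    Duplicates share the template's true coordinates in ``Read.meta``;
    optional per-duplicate errors model polymerase/sequencing noise that is
    *not* shared between copies.
    """
    rng = np.random.default_rng(seed)
    mult = amp.sample(len(fragments), rng)
    reads: list[Read] = []
    for f, m in zip(fragments, mult):
        for d in range(int(m)):
            seq = f.seq
            if amp.per_duplicate_error_rate > 0:
                seq = _substitute(seq, amp.per_duplicate_error_rate, rng)
            reads.append(Read(
                id=f"{f.template_id}.d{d}",
                seq=seq,
                meta={"template_id": f.template_id, "start": f.start,
                      "length": f.length, "strand": f.strand},
            ))
    return reads


def _substitute(seq: str, rate: float, rng: np.random.Generator) -> str:
    codes = _encode(seq)
    valid = codes <= 3
    hit = (rng.random(len(codes)) < rate) & valid
    if hit.any():
        shift = rng.integers(1, 4, size=len(codes))
        codes = codes.copy()
        codes[hit] = (codes[hit] + shift[hit]) % 4
    return _decode(codes)


# ------------------------------------------------------------ error inject
def inject_errors(obj, rate: float, seed: int = 0):
    """Substitute each A/C/G/T site with probability ``rate``.

    The replacement is a uniformly chosen *different* base; ``N`` and gap
    characters are never touched and never produced.  Accepts a sequence
    string, a list of strings, or a list of :class:`Read`.
    """
    if not (0.0 <= rate <= 1.0):
        raise ValueError("rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    if isinstance(obj, str):
        return _inject_str(obj, rate, rng)
    if isinstance(obj, list) and obj and isinstance(obj[0], Read):
        return [replace(r, seq=_inject_str(r.seq, rate, rng)) for r in obj]
    if isinstance(obj, list):
        return [_inject_str(s, rate, rng) for s in obj]
    raise TypeError(f"cannot inject errors into {type(obj)}")


def _inject_str(seq: str, rate: float, rng: np.random.Generator) -> str:
    lut = np.full(128, 255, dtype=np.uint8)
    for i, b in enumerate(BASES):
        lut[ord(b)] = i
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = lut[raw]
    valid = codes <= 3
    hit = (rng.random(len(codes)) < rate) & valid
    if not hit.any():
        return seq
    shift = rng.integers(1, 4, size=len(codes))
    new_codes = codes.copy()
    new_codes[hit] = (new_codes[hit] + shift[hit]) % 4
    out = raw.copy()
    basebytes = np.frombuffer(b"ACGT", dtype=np.uint8)
    out[hit] = basebytes[new_codes[hit]]
    return out.tobytes().decode("ascii")
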