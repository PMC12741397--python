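"""Read filtering, dereplication, greedy identity clustering and mapping.

This is the PCR-duplicate taming chain for low-complexity ancient libraries:
length filter, full-length dereplication with abundance (``size``) annotations,
greedy centroid clustering at a fixed identity threshold on both strands, and
a minimal exact-seed / ungapped-extension mapper onto a (circular) reference.

Coordinates are 0-based half-open everywhere; conversion to 1-based happens
only when writing SAM.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Read", "Cluster", "Placement", "filter_reads", "dereplicate",
    "cluster_greedy", "map_to_reference", "downsample",
    "reverse_complement", "pairwise_identity",
]

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class Read:
    """A sequencing read (or dereplicated unique sequence).

    ``abundance`` carries the ``;size=N;`` annotation used by dereplication
    and abundance-ordered clustering.  ``meta`` holds optional true-origin
    bookkeeping from the simulator (template id, coordinates, strand).
    """

    id: str
    seq: str
    abundance: int = 1
    meta: dict | None = None

    def __post_init__(self):
        if len(self.seq) < 1:
            raise ValueError(f"read {self.id!r} has empty sequence")
        if self.abundance < 1:
            raise ValueError(f"read {self.id!r} has abundance {self.abundance} < 1")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class Cluster:
    """Greedy cluster: a centroid read plus members on recorded strands."""

    centroid: Read
    members: list[tuple[str, str, float]] = field(default_factory=list)
    # (member read id, strand '+'/'-', identity to centroid)

    def __post_init__(self):
        self._size = self.centroid.abundance

    @property
    def size(self) -> int:
        """Total abundance of all member reads."""
        return self._size


@dataclass(frozen=True)
class Placement:
    """Ungapped placement of a read on a reference (0-based leftmost)."""

    read_id: str
    pos: int
    strand: str  # '+' or '-'
    n_mismatch: int
    length: int

    def __post_init__(self):
        if self.n_mismatch > self.length:
            raise ValueError("mismatch count exceeds aligned length")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")


# --------------------------------------------------------------------- filter
def filter_reads(reads: list[Read], min_len: int = 30) -> list[Read]:
    """Keep reads of length >= ``min_len`` (order preserved)."""
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    return [r for r in reads if len(r.seq) >= min_len]


# ---------------------------------------------------------------- dereplicate
def dereplicate(reads: list[Read]) -> list[Read]:
    """Collapse full-length-identical reads, summing abundances.

    Output is sorted by abundance descending, then length descending, then
    sequence lexicographically (a fixed, documented tie-break).  The record id
    is that of the first occurrence.
    """
    groups: dict[str, list[Read]] = {}
    for r in reads:
        groups.setdefault(r.seq, []).append(r)
    out = [
        Read(id=g[0].id, seq=seq, abundance=sum(r.abundance for r in g),
             meta=g[0].meta)
        for seq, g in groups.items()
    ]
    out.sort(key=lambda r: (-r.abundance, -len(r.seq), r.seq))
    return out


# ------------------------------------------------------------------- identity
def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def pairwise_identity(a: str, b: str, min_identity: float | None = None) -> float:
    """Ungapped best-overlap identity.

    The shorter sequence is slid along the longer at every offset; identity is
    matching columns divided by the total alignment span (overhangs count as
    terminal gap columns), maximised over offsets.  ``N`` never matches.

    ``min_identity`` is a pure speed hint: offsets whose best achievable
    identity (full overlap / span) is already below it are skipped; the
    returned value is unchanged whenever it is >= ``min_identity``.
    """
    if len(a) < len(b):
        a, b = b, a
    xa, xb = _encode(a), _encode(b)
    la, lb = len(xa), len(xb)
    if min_identity is not None and lb / la < min_identity:
        return lb / la if la else 0.0
    n_mask_a = xa == ord("N")
    n_mask_b = xb == ord("N")
    best = 0.0
    for off in range(-(lb - 1), la):
        lo = max(0, off)
        hi = min(la, off + lb)
        if hi <= lo:
            continue
        span = max(la, off + lb) - min(0, off)
        if min_identity is not None and (hi - lo) / span < min_identity:
            continue
        sa = slice(lo, hi)
        sb = slice(lo - off, hi - off)
        eq = (xa[sa] == xb[sb]) & ~n_mask_a[sa] & ~n_mask_b[sb]
        ident = eq.sum() / span
        if ident > best:
            best = ident
    return float(best)


# ----------------------------------------------------------------- clustering
def _kmers(seq: str, k: int) -> set[str]:
    return {seq[i:i + k] for i in range(len(seq) - k + 1)}


def cluster_greedy(
    reads: list[Read],
    id_threshold: float = 0.93,
    strand_both: bool = True,
    prefilter_k: int = 8,
) -> list[Cluster]:
    """Greedy abundance-ordered centroid clustering.

    Reads are visited in abundance-descending order (ties: length descending,
    then id); each read joins the first existing centroid it matches at
    >= ``id_threshold`` identity (testing the reverse complement too when
    ``strand_both``), otherwise it founds a new cluster.  A shared-k-mer
    prefilter only prunes candidate centroids; identity is always computed
    exactly for surviving candidates.
    """
    if not (0.0 < id_threshold <= 1.0):
        raise ValueError("id_threshold must be in (0, 1]")
    ordered = sorted(reads, key=lambda r: (-r.abundance, -len(r.seq), r.id))
    clusters: list[Cluster] = []
    kmer_index: dict[str, list[int]] = {}

    for r in ordered:
        variants = [(r.seq, "+")]
        if strand_both:
            variants.append((reverse_complement(r.seq), "-"))
        candidates: set[int] = set()
        for seq, _ in variants:
            for km in _kmers(seq, prefilter_k):
                candidates.update(kmer_index.get(km, ()))
        assigned = False
        for ci in sorted(candidates):
            cseq = clusters[ci].centroid.seq
            for seq, strand in variants:
                ident = pairwise_identity(cseq, seq, min_identity=id_threshold)
                if ident >= id_threshold:
                    clusters[ci].members.append((r.id, strand, ident))
                    clusters[ci]._size += r.abundance
                    assigned = True
                    break
            if assigned:
                break
        if not assigned:
            ci = len(clusters)
            clusters.append(Cluster(centroid=r, members=[(r.id, "+", 1.0)]))
            clusters[ci]._size = r.abundance
            for km in _kmers(r.seq, prefilter_k):
                kmer_index.setdefault(km, []).append(ci)
    return clusters


# -------------------------------------------------------------------- mapping
def map_to_reference(
    reads: list[Read],
    reference: str,
    k: int = 16,
    max_mismatch_frac: float = 0.1,
    circular: bool = True,
) -> tuple[list[Placement], list[str]]:
    """Exact k-mer seed, ungapped both-direction extension, both strands.

    Returns ``(placements, unplaced_ids)``.  The best placement minimises the
    mismatch count; ties break to the lowest reference coordinate, then the
    forward strand.  Reads with more than 50% ``N`` are dropped with a logged
    warning.  Placements on a circular reference may wrap (``pos`` is always
    in ``[0, len(reference))``).
    """
    L = len(reference)
    if L < k:
        raise ValueError("reference shorter than seed length k")
    if set(reference) <= {"N"}:
        raise ValueError("degenerate all-N reference")
    max_read = max((len(r.seq) for r in reads), default=0)
    ext = reference + (reference[: max_read - 1] if circular and max_read > 1 else "")
    xref = _encode(ext)

    index: dict[str, list[int]] = {}
    n_index = L if circular else L - k + 1
    for i in range(n_index):
        km = ext[i:i + k]
        if "N" not in km:
            index.setdefault(km, []).append(i)

    placements: list[Placement] = []
    unplaced: list[str] = []
    for r in reads:
        seq = r.seq
        if seq.count("N") > 0.5 * len(seq):
            logger.warning("read %s dropped: >50%% N", r.id)
            unplaced.append(r.id)
            continue
        allowed = int(max_mismatch_frac * len(seq))
        best: tuple[int, int, int] | None = None  # (mism, pos, strand_rank)
        for strand_rank, (query, strand) in enumerate(
            [(seq, "+"), (reverse_complement(seq), "-")]
        ):
            xq = _encode(query)
            nq = len(xq)
            seen: set[int] = set()
            for off in range(0, nq - k + 1):
                for hit in index.get(query[off:off + k], ()):
                    start = hit - off
                    if start < 0:
                        if not circular:
                            continue
                        start += L
                    if start + nq > len(xref):
                        continue
                    if start in seen:
                        continue
                    seen.add(start)
                    window = xref[start:start + nq]
                    mism = int(
                        ((window != xq) | (xq == ord("N")) | (window == ord("N"))).sum()
                    )
                    if mism <= allowed:
                        cand = (mism, start % L, strand_rank)
                        if best is None or cand < best:
                            best = cand
        if best is None:
            unplaced.append(r.id)
        else:
            mism, pos, strand_rank = best
            placements.append(Placement(r.id, pos, "+-"[strand_rank], mism, len(seq)))
    return placements, unplaced


# ----------------------------------------------------------------- downsample
def downsample(reads: list[Read], n: int, seed: int) -> list[Read]:
    """Uniform sample without replacement of ``min(n, len(reads))`` reads."""
    if n < 0:
        raise ValueError("n must be >= 0")
    if n >= len(reads):
        return list(reads)
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(reads), size=n, replace=False)
    return [reads[i] for i in sorted(idx)]
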