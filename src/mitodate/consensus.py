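"""Pileups, end-trimmed majority consensus, damage profiles and depth.

Consensus calling follows the low-coverage ancient-DNA convention: a base is
called only when it has a strict plurality and more than ``majority_frac`` of
the non-N observations at a position with depth >= ``min_depth``; everything
else is an honest ``N``.  Damage profiles are computed on untrimmed reads
(damage is observed at read ends); consensus is built from end-trimmed
cluster sequences (trimming removes exactly the damage-enriched positions).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from mitodate.reads import Placement, Read, reverse_complement
from mitodate.substmodel import BASES

logger = logging.getLogger(__name__)

__all__ = [
    "Pileup", "DamageTable", "trim_cluster_ends", "trim_reads",
    "build_pileup", "call_consensus", "damage_profile", "windowed_depth",
]


@dataclass
class Pileup:
    """Per-position base counts on the reference strand.

    ``counts`` has shape (L, 5): columns A, C, G, T, N.  ``depth`` is the row
    sum (every aligned base, including N, contributes).
    """

    counts: np.ndarray

    @property
    def depth(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def __len__(self) -> int:
        return self.counts.shape[0]


@dataclass
class DamageTable:
    """Mismatch frequencies by distance from the read end.

    For 1-based offsets ``1..L``: ``ct5`` is the C->T frequency at 5' offsets
    (computed over reference-C sites only), ``ga3`` the G->A frequency at 3'
    offsets (reference-G sites), with the opposite-end substitutions as
    background columns.  Frequencies are NaN where the site count is zero.
    """

    offsets: np.ndarray
    ct5: np.ndarray
    ga3: np.ndarray
    ga5: np.ndarray  # background: G->A seen from the 5' end
    ct3: np.ndarray  # background: C->T seen from the 3' end
    n_c5: np.ndarray
    n_g3: np.ndarray
    n_g5: np.ndarray
    n_c3: np.ndarray

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "offset": self.offsets,
            "ct_5p": self.ct5, "n_c_5p": self.n_c5,
            "ga_3p": self.ga3, "n_g_3p": self.n_g3,
            "ga_5p_background": self.ga5, "n_g_5p": self.n_g5,
            "ct_3p_background": self.ct3, "n_c_3p": self.n_c3,
        })


# ------------------------------------------------------------------ trimming
def trim_cluster_ends(sequence: str, k: int = 3) -> str:
    """Remove the first and last ``k`` characters.

    Sequences of length <= 2k are rejected (raises ValueError); use
    :func:`trim_reads` to trim a batch, dropping and logging rejects.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    if len(sequence) <= 2 * k:
        raise ValueError(f"sequence of length {len(sequence)} <= 2k = {2 * k}")
    return sequence[k:len(sequence) - k] if k else sequence


def trim_reads(reads: list[Read], k: int = 3) -> list[Read]:
    """End-trim each read; reads too short to trim are excluded and logged."""
    out = []
    for r in reads:
        try:
            trimmed = trim_cluster_ends(r.seq, k)
        except ValueError:
            logger.warning("read %s excluded by end-trimming (length %d <= %d)",
                           r.id, len(r.seq), 2 * k)
            continue
        out.append(Read(r.id, trimmed, r.abundance, r.meta))
    return out


# -------------------------------------------------------------------- pileup
_BASE5 = {b: i for i, b in enumerate(BASES + "N")}


def build_pileup(
    placements: list[Placement],
    reads: dict[str, Read] | list[Read],
    reference: str,
    circular: bool = True,
) -> Pileup:
    """Accumulate per-position base counts from ungapped placements.

    Reverse-strand placements contribute the reverse complement of the stored
    read sequence, so all counts are in reference orientation.  Positions wrap
    on a circular reference.
    """
    if isinstance(reads, list):
        reads = {r.id: r for r in reads}
    L = len(reference)
    counts = np.zeros((L, 5), dtype=np.int64)
    for pl in placements:
        r = reads[pl.read_id]
        seq = r.seq if pl.strand == "+" else reverse_complement(r.seq)
        if pl.pos < 0 or pl.pos >= L or (not circular and pl.pos + len(seq) > L):
            raise ValueError(f"placement of read {pl.read_id} out of bounds")
        for i, b in enumerate(seq):
            p = pl.pos + i
            if p >= L:
                if not circular:
                    raise ValueError(f"placement of read {pl.read_id} out of bounds")
                p -= L
            counts[p, _BASE5.get(b, 4)] += 1
    return Pileup(counts)


# ----------------------------------------------------------------- consensus
def call_consensus(
    pileup: Pileup, min_depth: int = 1, majority_frac: float = 0.5
) -> str:
    """Majority-rule consensus with N at unresolved sites.

    A base is called iff depth >= ``min_depth``, it is the strict plurality
    among A/C/G/T observations (ties give N), and its fraction of non-N
    observations exceeds ``majority_frac``.
    """
    if min_depth < 0 or not (0.0 <= majority_frac < 1.0):
        raise ValueError("invalid consensus thresholds")
    bc = pileup.counts[:, :4]
    depth = pileup.depth
    non_n = bc.sum(axis=1)
    order = np.argsort(bc, axis=1)
    top_i = order[:, -1]
    top = np.take_along_axis(bc, order[:, -1:], axis=1)[:, 0]
    second = np.take_along_axis(bc, order[:, -2:-1], axis=1)[:, 0]
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(non_n > 0, top / np.maximum(non_n, 1), 0.0)
    ok = (depth >= min_depth) & (top > second) & (frac > majority_frac) & (non_n > 0)
    out = np.full(len(pileup), "N", dtype="U1")
    basearr = np.array(list(BASES))
    out[ok] = basearr[top_i[ok]]
    return "".join(out)


# ------------------------------------------------------------ damage profile
def damage_profile(
    placements: list[Placement],
    reads: dict[str, Read] | list[Read],
    reference: str,
    L: int = 25,
    circular: bool = True,
) -> DamageTable:
    """Read-vs-reference mismatch frequencies by distance from each read end.

    Comparisons are made in *read* orientation (the strand the molecule was
    sequenced on), so deamination signatures appear as C->T near the 5' end
    and G->A near the 3' end regardless of mapping strand.
    """
    if not placements:
        raise ValueError("no placements")
    if isinstance(reads, list):
        reads = {r.id: r for r in reads}
    G = len(reference)
    ref2 = reference + reference[:max(len(reads[p.read_id].seq) for p in placements)]
    mism_ct5 = np.zeros(L); n_c5 = np.zeros(L)
    mism_ga3 = np.zeros(L); n_g3 = np.zeros(L)
    mism_ga5 = np.zeros(L); n_g5 = np.zeros(L)
    mism_ct3 = np.zeros(L); n_c3 = np.zeros(L)
    for pl in placements:
        r = reads[pl.read_id]
        ref_seg = ref2[pl.pos:pl.pos + len(r.seq)]
        if pl.strand == "-":
            ref_seg = reverse_complement(ref_seg)
        n = len(r.seq)
        for i in range(n):
            rb, qb = ref_seg[i], r.seq[i]
            if qb == "N" or rb == "N":
                continue
            if i < L:  # 5' offset i+1
                if rb == "C":
                    n_c5[i] += 1
                    if qb == "T":
                        mism_ct5[i] += 1
                if rb == "G":
                    n_g5[i] += 1
                    if qb == "A":
                        mism_ga5[i] += 1
            j = n - 1 - i
            if j < L:  # 3' offset j+1
                if rb == "G":
                    n_g3[j] += 1
                    if qb == "A":
                        mism_ga3[j] += 1
                if rb == "C":
                    n_c3[j] += 1
                    if qb == "T":
                        mism_ct3[j] += 1
    def freq(m, n):
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n > 0, m / np.maximum(n, 1), np.nan)
    return DamageTable(
        offsets=np.arange(1, L + 1),
        ct5=freq(mism_ct5, n_c5), ga3=freq(mism_ga3, n_g3),
        ga5=freq(mism_ga5, n_g5), ct3=freq(mism_ct3, n_c3),
        n_c5=n_c5, n_g3=n_g3, n_g5=n_g5, n_c3=n_c3,
    )


# ------------------------------------------------------------ windowed depth
def windowed_depth(
    placements: list[Placement],
    reference_length: int,
    window: int = 1000,
    circular: bool = True,
) -> tuple[np.ndarray, float]:
    """Mean per-base depth per consecutive window, plus the overall mean.

    The final partial window is averaged over its own length.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    L = reference_length
    depth = np.zeros(L + 1)
    for pl in placements:
        end = pl.pos + pl.length
        if end <= L:
            depth[pl.pos] += 1
            depth[end] -= 1
        else:
            if not circular:
                raise ValueError(f"placement of read {pl.read_id} out of bounds")
            depth[pl.pos] += 1
            depth[L] -= 1
            depth[0] += 1
            depth[end - L] -= 1
    per_base = np.cumsum(depth[:-1])
    n_win = (L + window - 1) // window
    means = np.array([
        per_base[w * window:min((w + 1) * window, L)].mean() for w in range(n_win)
    ])
    return means, float(per_base.mean())
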