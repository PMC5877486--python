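"""Synchronization likelihood (SL) between EEG channels.

SL measures generalized synchronization between time series through recurrences
of their time-delay embeddings. For each channel ``k`` and reference time ``i``
a critical distance ``eps_{k,i}`` is fixed so that a small target fraction
``p_ref`` of embedded vectors inside a window around ``i`` lies within
``eps_{k,i}`` of the reference vector (the window excludes a Theiler zone
``|i-j| <= w1`` of trivially autocorrelated neighbours and is capped at
``|i-j| < w2`` for time resolution). The pairwise SL of channels ``a`` and
``b`` is then the probability that a recurrence of one channel coincides with
a recurrence of the other, averaged over reference times and both channels.
Identical channels give SL = 1; independent channels give SL ~ p_ref.

Normalization note: averaging the coincidence indicator over the full window
(rather than over the recurrences themselves) would cap the identical-channel
value near p_ref; this implementation divides by the per-channel recurrence
count, the normalization under which SL spans [~p_ref, 1] and reads as a
likelihood.

Channels are z-scored per epoch before embedding so that a single Euclidean
critical distance is meaningful across channels of different amplitude.

The embedding lag, dimension, windows and p_ref are not standardized for sleep
EEG; :meth:`SLParams.from_band` derives defaults from the analysis band with
the usual heuristics (lag ~ fs/(3 f_hi), dimension ~ 3 f_hi/f_lo + 1 capped at
10). All of them are explicit, documented knobs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import ceil

import numpy as np

from .preprocess import Epoch

logger = logging.getLogger(__name__)

#: Rows per chunk when vectorizing distance computations (memory cap).
_CHUNK = 256


@dataclass(frozen=True)
class SLParams:
    """Embedding and recurrence parameters for synchronization likelihood.

    l : embedding lag in samples; m : embedding dimension; w1 : Theiler
    window (samples, exclusive); w2 : outer window (samples, exclusive);
    p_ref : target recurrence fraction; stride : subsampling step of the
    reference time index (1 = every embedded vector).
    """

    l: int = 1
    m: int = 10
    w1: int = 18
    w2: int = 1018
    p_ref: float = 0.01
    stride: int = 4

    def __post_init__(self) -> None:
        if self.m < 1 or self.l < 1:
            raise ValueError("Embedding requires m >= 1 and l >= 1")
        if not 0.0 < self.p_ref < 1.0:
            raise ValueError("p_ref must lie strictly between 0 and 1")
        if self.w2 <= self.w1 + 1:
            raise ValueError("Need w2 > w1 + 1 so the window is non-empty")
        if self.w1 < 0:
            raise ValueError("w1 must be >= 0")
        if self.stride < 1:
            raise ValueError("stride must be >= 1")

    @classmethod
    def from_band(
        cls,
        fs: float,
        f_lo: float = 0.5,
        f_hi: float = 50.0,
        p_ref: float = 0.01,
        stride: int = 4,
    ) -> "SLParams":
        """Derive parameters from the analysis band by the standard heuristics."""
        l = max(1, round(fs / (3.0 * f_hi)))
        m = min(10, ceil(3.0 * f_hi / f_lo) + 1)
        w1 = 2 * l * (m - 1)
        w2 = w1 + round(10.0 / p_ref)
        return cls(l=l, m=m, w1=w1, w2=w2, p_ref=p_ref, stride=stride)


@dataclass
class SLMatrix:
    """Symmetric per-epoch SL matrix; diagonal fixed at 0."""

    values: np.ndarray
    params: SLParams

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        m = self.values.shape[0]
        if self.values.shape != (m, m):
            raise ValueError("SL matrix must be square")


# ---------------------------------------------------------------------------
# embedding and critical distance
# ---------------------------------------------------------------------------

def embed(x: np.ndarray, m: int, l: int) -> np.ndarray:
    """Time-delay embed a scalar series into m-dimensional vectors with lag l.

    Vector ``i`` has components ``x[i + a*l]`` for a = 0..m-1; the result has
    shape (N - (m-1)*l, m).
    """
    x = np.asarray(x, dtype=np.float64).ravel()
    n_vec = x.size - (m - 1) * l
    if n_vec < 1:
        raise ValueError(
            f"Series of length {x.size} too short to embed with m={m}, l={l}; "
            f"need at least {(m - 1) * l + 1} samples"
        )
    if m == 1:
        return x[:, None].copy()
    idx = np.arange(n_vec)[:, None] + l * np.arange(m)[None, :]
    return x[idx]


def _eligible(i: int, n_vec: int, p: SLParams) -> np.ndarray:
    """Indices j with w1 < |i-j| < w2 inside [0, n_vec)."""
    off = np.arange(p.w1 + 1, p.w2)
    j = np.concatenate([i - off[::-1], i + off])
    return j[(j >= 0) & (j < n_vec)]


def critical_distance(emb: np.ndarray, i: int, p: SLParams) -> float:
    """Per-reference critical distance: the p_ref-quantile of window distances.

    Returns the smallest distance d such that the fraction of eligible
    neighbours within d is >= p_ref (k-th smallest with k = ceil(p_ref * |J|)).
    """
    n_vec = emb.shape[0]
    j = _eligible(i, n_vec, p)
    if j.size == 0:
        raise ValueError(f"No eligible neighbours for reference index {i}")
    d = np.linalg.norm(emb[j] - emb[i], axis=1)
    k = max(1, ceil(p.p_ref * d.size))
    return float(np.partition(d, k - 1)[k - 1])


# ---------------------------------------------------------------------------
# recurrence masks (shared by sl_pair and sl_matrix)
# ---------------------------------------------------------------------------

def _recurrence_masks(
    embs: list[np.ndarray], p: SLParams
) -> tuple[np.ndarray, np.ndarray]:
    """Boolean recurrence masks for every channel at strided reference times.

    Returns (masks, ref_idx): masks has shape (M, n_ref, n_off) where entry
    [k, r, c] says whether window neighbour c of reference r is a recurrence
    of channel k (distance <= its critical distance). Invalid (out-of-range)
    window slots are always False.
    """
    n_vec = embs[0].shape[0]
    if any(e.shape[0] != n_vec for e in embs):
        raise ValueError("All channels must produce equally many embedded vectors")
    ref_idx = np.arange(0, n_vec, p.stride)
    off = np.arange(p.w1 + 1, p.w2)
    offsets = np.concatenate([-off[::-1], off])
    jmat = ref_idx[:, None] + offsets[None, :]
    valid = (jmat >= 0) & (jmat < n_vec)
    if not valid.any():
        raise ValueError(
            "No eligible neighbours at any reference time; series too short "
            f"for w1={p.w1}, w2={p.w2}"
        )
    jclip = np.clip(jmat, 0, n_vec - 1)
    counts = valid.sum(axis=1)
    # per-row rank of the critical distance
    kth = np.maximum(1, np.ceil(p.p_ref * counts).astype(int))

    n_ref, n_off = jmat.shape
    masks = np.zeros((len(embs), n_ref, n_off), dtype=bool)
    for k_ch, emb in enumerate(embs):
        for lo in range(0, n_ref, _CHUNK):
            hi = min(lo + _CHUNK, n_ref)
            diff = emb[jclip[lo:hi]] - emb[ref_idx[lo:hi], None, :]
            d = np.sqrt(np.einsum("rcm,rcm->rc", diff, diff))
            d[~valid[lo:hi]] = np.inf
            rows = np.arange(hi - lo)
            ds = np.sort(d, axis=1)
            eps = ds[rows, kth[lo:hi] - 1]
            ok = counts[lo:hi] > 0
            mask = d <= eps[:, None]
            mask[~ok] = False
            masks[k_ch, lo:hi] = mask
    return masks, ref_idx


def _pair_value(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Average coincidence likelihood over both channels and reference times."""
    na = mask_a.sum(axis=1)
    nb = mask_b.sum(axis=1)
    nab = (mask_a & mask_b).sum(axis=1)
    vals: list[np.ndarray] = []
    for n_own, other in ((na, nab), (nb, nab)):
        good = n_own > 0
        if not np.all(good):
            logger.debug("Skipping %d reference times with zero recurrences",
                         int((~good).sum()))
        vals.append(other[good] / n_own[good])
    allv = np.concatenate(vals)
    if allv.size == 0:
        raise ValueError("Every reference time had zero recurrences")
    return float(allv.mean())


def _zscore(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=np.float64).ravel()
    sd = x.std()
    if sd == 0:
        raise ValueError("Flat (zero-variance) channel cannot be embedded")
    return (x - x.mean()) / sd


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def sl_pair(x_a: np.ndarray, x_b: np.ndarray, p: SLParams) -> float:
    """Synchronization likelihood between two equal-length series, in [0, 1]."""
    x_a = np.asarray(x_a, dtype=np.float64).ravel()
    x_b = np.asarray(x_b, dtype=np.float64).ravel()
    if x_a.size != x_b.size:
        raise ValueError("Series must have equal length")
    embs = [embed(_zscore(x_a), p.m, p.l), embed(_zscore(x_b), p.m, p.l)]
    masks, _ = _recurrence_masks(embs, p)
    return _pair_value(masks[0], masks[1])


def sl_matrix(epoch: Epoch, p: SLParams | None = None) -> SLMatrix:
    """Per-epoch symmetric SL matrix over all channel pairs; diagonal 0."""
    if p is None:
        p = SLParams.from_band(epoch.fs)
    m_ch = epoch.n_channels
    embs = []
    for k in range(m_ch):
        try:
            embs.append(embed(_zscore(epoch.data[k]), p.m, p.l))
        except ValueError as exc:
            raise ValueError(f"Channel {k}: {exc}") from exc
    masks, _ = _recurrence_masks(embs, p)
    out = np.zeros((m_ch, m_ch))
    for a in range(m_ch):
        for b in range(a + 1, m_ch):
            try:
                val = _pair_value(masks[a], masks[b])
            except ValueError as exc:
                raise ValueError(f"Channel pair ({a}, {b}): {exc}") from exc
            out[a, b] = out[b, a] = val
    return SLMatrix(values=out, params=p)
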