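"""Relative wavelet entropy (RWE) and band-energy ratios from orthogonal DWTs.

Each channel of an epoch is decomposed with an orthogonal discrete wavelet
transform; the squared coefficients at each level, normalized by total energy,
give a relative energy distribution ``p = (p_1, ..., p_depth, p_approx)`` over
dyadic frequency intervals. The RWE between channels a and b is the
Kullback-Leibler divergence

    RWE(a, b) = sum_j p_j ln(p_j / q_j) >= 0

between their energy distributions: zero iff the two channels distribute
energy identically over scales, asymmetric in general, so the per-epoch matrix
is the adjacency matrix of a weighted *directed* graph. (The dissimilarity is
used in its standard non-negative KL form.)

The decomposition uses periodized signal extension, the mode under which the
discrete transform is exactly orthogonal, so level energies sum to the signal
energy (Parseval) to machine precision and the relative energies are a true
partition of unity.

The five canonical EEG rhythms are recovered by mapping each dyadic level to
the band its frequency interval overlaps most; the per-channel energy
fractions of the mapped levels, averaged over channels, give the five
band-energy-ratio features (delta, theta, alpha, beta, gamma). The wavelet
family (db4), depth rule and band mapping are implementation choices — the
method itself fixes none of them — and are all configurable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pywt

from .preprocess import Epoch
from .synthetic import BANDS, BAND_NAMES

logger = logging.getLogger(__name__)

_FLOOR = 1e-12


@dataclass(frozen=True)
class WaveletParams:
    """Orthogonal DWT configuration for RWE.

    mother : orthogonal wavelet name (PyWavelets); depth : number of detail
    levels (>= 5); fs : sampling rate used to place dyadic intervals;
    band_map : band name -> set of level indices (1 = finest detail,
    depth + 1 = final approximation).
    """

    fs: float
    mother: str = "db4"
    depth: int | None = None
    band_map: dict[str, frozenset[int]] | None = None

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.depth is None:
            object.__setattr__(self, "depth", default_depth(self.fs))
        if self.depth < 5:
            raise ValueError("Decomposition depth must be >= 5")
        if self.band_map is None:
            object.__setattr__(
                self, "band_map", default_band_map(self.fs, self.depth)
            )
        seen: set[int] = set()
        for band, levels in self.band_map.items():
            if band not in BAND_NAMES:
                raise ValueError(f"Unknown band {band!r} in band_map")
            for j in levels:
                if not 1 <= j <= self.depth + 1:
                    raise ValueError(
                        f"band_map level {j} outside 1..{self.depth + 1}"
                    )
                if j in seen:
                    raise ValueError(f"band_map level {j} assigned twice")
                seen.add(j)

    @property
    def n_levels(self) -> int:
        """Number of energy levels: depth details + final approximation."""
        return self.depth + 1


def default_depth(fs: float) -> int:
    """Smallest depth whose final approximation band is <= 2 Hz wide.

    The approximation of a depth-d decomposition covers [0, fs / 2^(d+1)];
    keeping it within the delta band prevents slow-wave energy from being
    smeared over an over-wide lowest level. Never below 5 levels.
    """
    d = 1
    while fs / 2 ** (d + 1) > 2.0:
        d += 1
    return max(5, d)


def level_interval(fs: float, j: int, depth: int) -> tuple[float, float]:
    """Dyadic frequency interval (Hz) of level j (detail) or depth+1 (approx)."""
    if j == depth + 1:
        return (0.0, fs / 2 ** (depth + 1))
    return (fs / 2 ** (j + 1), fs / 2 ** j)


def default_band_map(fs: float, depth: int) -> dict[str, frozenset[int]]:
    """Assign each dyadic level to the canonical band it overlaps most.

    Levels whose interval does not intersect any of the five bands (e.g.
    detail levels above gamma at high sampling rates) are left unassigned, so
    the five ratios may sum to less than 1.
    """
    assign: dict[str, set[int]] = {b: set() for b in BAND_NAMES}
    for j in range(1, depth + 2):
        lo, hi = level_interval(fs, j, depth)
        best, best_ov = None, 0.0
        for band, (blo, bhi) in BANDS.items():
            ov = max(0.0, min(hi, bhi) - max(lo, blo))
            if ov > best_ov:
                best, best_ov = band, ov
        if best is not None:
            assign[best].add(j)
    return {b: frozenset(s) for b, s in assign.items()}


def describe_band_map(p: WaveletParams) -> str:
    """Human-readable level -> band table (logged when matrices are built)."""
    lines = []
    rev = {j: b for b, levels in p.band_map.items() for j in levels}
    for j in range(1, p.depth + 2):
        lo, hi = level_interval(p.fs, j, p.depth)
        kind = "approx" if j == p.depth + 1 else "detail"
        lines.append(
            f"level {j} ({kind}, {lo:.2f}-{hi:.2f} Hz) -> {rev.get(j, '-')}"
        )
    return "\n".join(lines)


@dataclass
class EnergyDistribution:
    """Relative wavelet energies per level (details finest-first, then approx)."""

    p: np.ndarray
    e_tot: float

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=np.float64)
        if np.any(self.p < 0) or abs(self.p.sum() - 1.0) > 1e-9:
            raise ValueError("Relative energies must be a distribution")
        if self.e_tot <= 0:
            raise ValueError("Total energy must be positive")

    @property
    def n_levels(self) -> int:
        return self.p.size


@dataclass
class RWEMatrix:
    """Directed per-epoch RWE matrix; diagonal exactly 0, entries >= 0."""

    values: np.ndarray
    params: WaveletParams

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)


@dataclass(frozen=True)
class BandRatios:
    """Energy fractions of the five rhythms, epoch-global (channel-averaged)."""

    delta: float
    theta: float
    alpha: float
    beta: float
    gamma: float

    def as_array(self) -> np.ndarray:
        return np.array([self.delta, self.theta, self.alpha, self.beta,
                         self.gamma])


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def dwt_energy_distribution(x: np.ndarray, p: WaveletParams) -> EnergyDistribution:
    """Relative energy per decomposition level of one channel.

    Level ordering of the returned distribution: detail level 1 (finest) up to
    level ``depth``, then the final approximation. Energy is conserved
    (Parseval) because the transform is orthogonal.
    """
    x = np.asarray(x, dtype=np.float64).ravel()
    if x.size < 2 ** p.depth:
        raise ValueError(
            f"Series of length {x.size} too short for depth {p.depth} "
            f"(need >= {2 ** p.depth} samples)"
        )
    coeffs = pywt.wavedec(x, p.mother, mode="periodization", level=p.depth)
    # wavedec returns [approx_depth, detail_depth, ..., detail_1]
    energies = np.array([float(np.sum(c ** 2)) for c in coeffs])
    e_approx = energies[0]
    e_details = energies[1:][::-1]  # reorder to finest-first
    e_levels = np.concatenate([e_details, [e_approx]])
    e_tot = float(e_levels.sum())
    if e_tot <= 0:
        raise ValueError("Zero-energy (flat) channel has no energy distribution")
    return EnergyDistribution(p=e_levels / e_tot, e_tot=e_tot)


def rwe(p: EnergyDistribution, q: EnergyDistribution) -> float:
    """Kullback-Leibler divergence between two level-energy distributions.

    Non-negative; zero iff p == q; asymmetric. Levels where p is zero
    contribute nothing; zeros are floored at 1e-12 (and renormalized) so the
    divergence stays finite for degenerate spectra.
    """
    if p.n_levels != q.n_levels:
        raise ValueError(
            f"Mismatched decomposition depths: {p.n_levels} vs {q.n_levels} levels"
        )
    pj = np.maximum(p.p, _FLOOR)
    qj = np.maximum(q.p, _FLOOR)
    pj = pj / pj.sum()
    qj = qj / qj.sum()
    return float(max(0.0, np.sum(pj * np.log(pj / qj))))


def _channel_distributions(
    epoch: Epoch, p: WaveletParams
) -> list[EnergyDistribution]:
    dists = []
    for k in range(epoch.n_channels):
        try:
            dists.append(dwt_energy_distribution(epoch.data[k], p))
        except ValueError as exc:
            label = epoch.channel_labels[k] if epoch.channel_labels else k
            raise ValueError(f"Channel {label}: {exc}") from exc
    return dists


def rwe_matrix(epoch: Epoch, p: WaveletParams | None = None) -> RWEMatrix:
    """Directed per-epoch RWE matrix: entry (a, b) = KL(dist_a || dist_b)."""
    if p is None:
        p = WaveletParams(fs=epoch.fs)
    logger.debug("RWE band mapping:\n%s", describe_band_map(p))
    dists = _channel_distributions(epoch, p)
    m = epoch.n_channels
    out = np.zeros((m, m))
    for a in range(m):
        for b in range(m):
            if a != b:
                out[a, b] = rwe(dists[a], dists[b])
    return RWEMatrix(values=out, params=p)


def band_energy_ratios(epoch: Epoch, p: WaveletParams | None = None) -> BandRatios:
    """Channel-averaged energy fraction of each canonical rhythm.

    Per channel, a band's energy is the summed relative energy of its mapped
    levels; fractions are averaged across channels. The five values sum to at
    most 1 (levels outside every band are excluded).
    """
    if p is None:
        p = WaveletParams(fs=epoch.fs)
    dists = _channel_distributions(epoch, p)
    ratios = np.zeros(5)
    for dist in dists:
        for bi, band in enumerate(BAND_NAMES):
            levels = p.band_map.get(band, frozenset())
            ratios[bi] += sum(dist.p[j - 1] for j in levels)
    ratios /= len(dists)
    return BandRatios(*ratios)
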