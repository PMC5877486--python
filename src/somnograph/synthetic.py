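"""Synthetic multichannel EEG with stage-dependent spectra and tunable synchrony.

Each sleep stage is described by a :class:`StageProfile`: the relative power it
places in the five canonical EEG rhythms (delta 0.5-4, theta 4-8, alpha 8-13,
beta 13-30, gamma 30-45 Hz), the strength of a shared drive mixed into every
channel, and an additive white-noise floor. A channel is the convex mixture

    x_k = c * s + (1 - c) * u_k + noise

of a band-limited shared drive ``s`` and an independent band-limited process
``u_k``, both built from filtered Gaussian noise so that the surrogate has the
broadband character of real EEG rather than a line spectrum. The coupling
coefficient ``c`` gives an analytic handle on expected inter-channel synchrony:
c=0 yields independent channels, c=1 identical ones.

Default stage profiles follow the qualitative AASM stage descriptions — N1 a
low-voltage alpha/theta mixture, N2 theta-dominant, N3 delta-dominant slow-wave
sleep, REM mixed theta/alpha with elevated fast (beta+gamma) activity and the
highest inter-channel synchrony. The quantitative numbers are this package's
own choices (no standard reference fixes them) and are fully configurable.
Sleep grapho-elements (spindles, K-complexes) are deliberately not simulated:
the connectivity features extracted downstream do not detect them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .preprocess import STAGES, Epoch, Recording

#: Canonical band edges in Hz, in fixed (delta, theta, alpha, beta, gamma) order.
BANDS: dict[str, tuple[float, float]] = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "gamma": (30.0, 45.0),
}
BAND_NAMES = tuple(BANDS)

#: Overall RMS amplitude of the rhythmic part of each channel, in microvolts.
SIGNAL_RMS_UV = 30.0


@dataclass(frozen=True)
class StageProfile:
    """Spectral and synchrony description of one sleep stage.

    band_weights are relative powers over (delta, theta, alpha, beta, gamma)
    and must be non-negative with a positive sum (they are normalized to sum
    to 1). coupling_strength in [0, 1] is the fraction of shared drive in each
    channel; noise_sd the standard deviation of additive white noise in uV.
    """

    stage: str
    band_weights: tuple[float, float, float, float, float]
    coupling_strength: float = 0.5
    noise_sd: float = 5.0

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"Unknown stage {self.stage!r}; expected one of {STAGES}")
        w = np.asarray(self.band_weights, dtype=float)
        if w.shape != (5,):
            raise ValueError("band_weights must have exactly 5 entries")
        if np.any(w < 0):
            raise ValueError(f"band_weights must be non-negative, got {tuple(w)}")
        if w.sum() <= 0:
            raise ValueError("band_weights must have a positive sum")
        if not 0.0 <= self.coupling_strength <= 1.0:
            raise ValueError("coupling_strength must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def weights(self) -> np.ndarray:
        """Band weights normalized to sum to 1."""
        w = np.asarray(self.band_weights, dtype=float)
        return w / w.sum()


@dataclass(frozen=True)
class ProfileMixture:
    """A transitional stage: each epoch is a random blend of two profiles.

    A mixing coefficient lam ~ U[0, 1] is drawn per epoch (deterministic given
    the epoch seed); band weights, coupling and noise are interpolated
    lam * endpoint_a + (1 - lam) * endpoint_b. At the extremes an epoch is
    distributed exactly like one of the endpoint stages, so the stage is
    ambiguous by construction — the natural model for transitional N1 sleep.
    """

    stage: str
    endpoint_a: StageProfile
    endpoint_b: StageProfile

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"Unknown stage {self.stage!r}; expected one of {STAGES}")

    def sample(self, seed: int) -> StageProfile:
        """The concrete interpolated profile of one epoch."""
        rng = np.random.default_rng(
            np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 0x31F])
        )
        lam = float(rng.uniform())
        a, b = self.endpoint_a, self.endpoint_b
        w = lam * a.weights + (1.0 - lam) * b.weights
        return StageProfile(
            stage=self.stage,
            band_weights=tuple(w),
            coupling_strength=lam * a.coupling_strength
            + (1.0 - lam) * b.coupling_strength,
            noise_sd=lam * a.noise_sd + (1.0 - lam) * b.noise_sd,
        )


@dataclass(frozen=True)
class SimConfig:
    """Geometry of a simulation run."""

    n_channels: int = 19
    fs: float = 128.0
    epoch_len: float = 30.0
    epochs_per_stage: dict[str, int] = field(
        default_factory=lambda: {s: 10 for s in STAGES}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_channels < 1:
            raise ValueError("n_channels must be >= 1")
        if self.fs <= 2 * BANDS["gamma"][1]:
            raise ValueError(
                f"fs={self.fs} must exceed twice the highest band edge "
                f"({2 * BANDS['gamma'][1]} Hz)"
            )
        if self.epoch_len <= 0:
            raise ValueError("epoch_len must be positive")
        for s, n in self.epochs_per_stage.items():
            if s not in STAGES:
                raise ValueError(f"Unknown stage {s!r} in epochs_per_stage")
            if n < 0:
                raise ValueError("epochs_per_stage values must be >= 0")

    @property
    def samples_per_epoch(self) -> int:
        n = self.fs * self.epoch_len
        if abs(n - round(n)) > 1e-9:
            raise ValueError("fs * epoch_len must be an integer sample count")
        return int(round(n))


def default_profiles() -> dict[str, StageProfile]:
    """Well-separated stage profiles following the AASM rhythm descriptions."""
    return {
        "N1": StageProfile("N1", (0.15, 0.35, 0.35, 0.10, 0.05),
                           coupling_strength=0.30),
        "N2": StageProfile("N2", (0.25, 0.45, 0.15, 0.10, 0.05),
                           coupling_strength=0.45),
        "N3": StageProfile("N3", (0.70, 0.15, 0.05, 0.05, 0.05),
                           coupling_strength=0.60),
        "REM": StageProfile("REM", (0.10, 0.35, 0.25, 0.18, 0.12),
                            coupling_strength=0.70),
    }


def overlapping_profiles() -> dict[str, StageProfile | ProfileMixture]:
    """Deliberately confusable profiles: N1 spans the N2-REM continuum.

    N1 is transitional sleep, so each N1 epoch is drawn from a random convex
    mixture of the N2 and REM profiles: at the extremes it is distributed
    exactly like a neighbour stage, making some N1 epochs irreducibly
    ambiguous. This reproduces the qualitative difficulty of scoring N1
    regardless of classifier power, while N2, N3 and REM remain compact (and
    closer to each other than in the separated defaults).
    """
    n2 = StageProfile("N2", (0.22, 0.42, 0.18, 0.12, 0.06),
                      coupling_strength=0.52)
    n3 = StageProfile("N3", (0.55, 0.25, 0.10, 0.06, 0.04),
                      coupling_strength=0.58)
    rem = StageProfile("REM", (0.14, 0.36, 0.25, 0.15, 0.10),
                       coupling_strength=0.56)
    n1 = ProfileMixture(
        "N1",
        StageProfile("N1", n2.band_weights, n2.coupling_strength, n2.noise_sd),
        StageProfile("N1", rem.band_weights, rem.coupling_strength,
                     rem.noise_sd),
    )
    return {"N1": n1, "N2": n2, "N3": n3, "REM": rem}


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _band_sos(lo: float, hi: float, fs: float) -> np.ndarray:
    return signal.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")


def _band_mixture(
    rng: np.random.Generator, weights: np.ndarray, n: int, fs: float
) -> np.ndarray:
    """One unit-RMS realization of the weighted band-limited noise mixture.

    Each band is Butterworth-filtered white noise normalized to unit variance,
    then scaled by sqrt(weight) so its share of total power equals the weight.
    Extra pre-roll samples are generated and trimmed to wash out filter
    transients.
    """
    pad = int(2 * fs)  # 2 s pre/post roll
    total = n + 2 * pad
    out = np.zeros(total)
    for w, (lo, hi) in zip(weights, BANDS.values()):
        if w <= 0:
            continue
        white = rng.standard_normal(total)
        band = signal.sosfiltfilt(_band_sos(lo, hi, fs), white)
        sd = band.std()
        if sd > 0:
            band /= sd
        out += np.sqrt(w) * band
    return out[pad:pad + n]


def generate_stage_epoch(
    profile: StageProfile | ProfileMixture, cfg: SimConfig, seed: int
) -> Epoch:
    """Generate one epoch of multichannel EEG for a single sleep stage.

    Deterministic given (profile, cfg, seed). Channels share a common
    band-limited drive weighted by the profile's coupling strength; the rest
    of each channel is an independent process with the same band weights, plus
    white measurement noise. A :class:`ProfileMixture` is first resolved to
    the epoch's concrete interpolated profile.
    """
    if isinstance(profile, ProfileMixture):
        profile = profile.sample(seed)
    n = cfg.samples_per_epoch
    c = profile.coupling_strength
    w = profile.weights
    ss = np.random.SeedSequence([int(seed) & 0x7FFFFFFF])
    children = ss.spawn(cfg.n_channels + 1)
    shared = _band_mixture(np.random.default_rng(children[0]), w, n, cfg.fs)
    data = np.empty((cfg.n_channels, n))
    for k in range(cfg.n_channels):
        rng_k = np.random.default_rng(children[k + 1])
        indep = _band_mixture(rng_k, w, n, cfg.fs)
        x = c * shared + (1.0 - c) * indep
        x *= SIGNAL_RMS_UV
        if profile.noise_sd > 0:
            x = x + profile.noise_sd * rng_k.standard_normal(n)
        data[k] = x
    labels = [f"ch{i}" for i in range(cfg.n_channels)]
    return Epoch(data=data, fs=cfg.fs, label=profile.stage, channel_labels=labels)


def generate_labelled_dataset(
    profiles: dict[str, StageProfile], cfg: SimConfig
) -> tuple[Recording, list[str]]:
    """Generate a shuffled labelled recording per ``cfg.epochs_per_stage``.

    Returns the concatenated recording and the aligned hypnogram (one stage
    label per epoch). Epoch order is a seeded permutation; per-stage counts
    match the request exactly.
    """
    requests = [
        (stage, cfg.epochs_per_stage.get(stage, 0)) for stage in STAGES
    ]
    total = sum(n for _, n in requests)
    if total == 0:
        raise ValueError("epochs_per_stage requests no epochs at all")
    for stage, n in requests:
        if n > 0 and stage not in profiles:
            raise ValueError(f"No profile supplied for requested stage {stage!r}")

    root = np.random.SeedSequence([int(cfg.seed) & 0x7FFFFFFF, 0xEEC])
    epoch_seeds = root.generate_state(total + 1)
    epochs: list[Epoch] = []
    i = 0
    for stage, n in requests:
        for _ in range(n):
            epochs.append(
                generate_stage_epoch(
                    profiles[stage], cfg, int(epoch_seeds[i]) & 0x7FFFFFFF
                )
            )
            i += 1
    order = np.random.default_rng(int(epoch_seeds[-1]) & 0x7FFFFFFF).permutation(total)
    epochs = [epochs[j] for j in order]
    data = np.concatenate([e.data for e in epochs], axis=1)
    labels = [e.label for e in epochs]
    rec = Recording(
        data=data, fs=cfg.fs, channel_labels=epochs[0].channel_labels
    )
    return rec, labels
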