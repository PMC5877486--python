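"""EEG preprocessing: DC removal, Butterworth filter cascade, 30-s epoching.

The pipeline renders a raw multichannel recording suitable for computerized
sleep staging: the per-channel mean is subtracted, a cascade of third-order
Butterworth filters restricts the signal to the 0.5--50 Hz analysis band and
notches out power-line interference (50 Hz and its first harmonic), and the
recording is cut into contiguous, non-overlapping 30-s epochs — the unit on
which all connectivity features are computed.

All filters are applied forward--backward (zero phase) so that waveform
timing, which the time-delay embedding of the synchronization analysis relies
on, is preserved.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import signal

logger = logging.getLogger(__name__)

#: Stage labels of the 4-class AASM sleep vocabulary used throughout.
STAGES = ("N1", "N2", "N3", "REM")


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class Recording:
    """A continuous multichannel EEG recording.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal in microvolts.
    fs : float
        Sampling frequency in Hz.
    channel_labels : sequence of str
        10-20 system electrode names, unique, one per row of ``data``.
    """

    data: np.ndarray
    fs: float
    channel_labels: Sequence[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("Recording data must be 2-D (channels x samples)")
        if self.fs <= 0:
            raise ValueError("Sampling frequency must be positive")
        if not self.channel_labels:
            self.channel_labels = [f"ch{i}" for i in range(self.n_channels)]
        self.channel_labels = list(self.channel_labels)
        if len(self.channel_labels) != self.n_channels:
            raise ValueError(
                f"{len(self.channel_labels)} labels for {self.n_channels} channels"
            )
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("Channel labels must be unique")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class Epoch:
    """One 30-s (by default) block of a recording, optionally stage-labelled."""

    data: np.ndarray
    fs: float
    index: int = 0
    label: str | None = None
    channel_labels: Sequence[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("Epoch data must be 2-D (channels x samples)")
        if self.label is not None and self.label not in STAGES:
            raise ValueError(f"Unknown stage label {self.label!r}")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class FilterSpec:
    """One Butterworth stage of the preprocessing cascade.

    kind is one of ``highpass``, ``lowpass``, ``bandstop``; ``edges`` holds one
    corner frequency (Hz) for the one-sided kinds and two for bandstop.
    """

    kind: str
    edges: tuple[float, ...]
    order: int = 3

    def __post_init__(self) -> None:
        if self.kind not in ("highpass", "lowpass", "bandstop"):
            raise ValueError(f"Unknown filter kind {self.kind!r}")
        n_expected = 2 if self.kind == "bandstop" else 1
        if len(self.edges) != n_expected:
            raise ValueError(
                f"{self.kind} filter needs {n_expected} edge(s), got {self.edges}"
            )
        if self.order < 1:
            raise ValueError("Filter order must be >= 1")
        if any(e <= 0 for e in self.edges):
            raise ValueError(f"Filter edges must be positive, got {self.edges}")

    def design(self, fs: float) -> np.ndarray:
        """Return second-order sections for this stage at sampling rate fs."""
        nyq = fs / 2.0
        if any(e >= nyq for e in self.edges):
            raise ValueError(
                f"Filter edge {max(self.edges)} Hz >= Nyquist {nyq} Hz "
                f"for spec {self.kind} {self.edges}"
            )
        wn = self.edges[0] if len(self.edges) == 1 else list(self.edges)
        return signal.butter(self.order, wn, btype=self.kind, fs=fs, output="sos")


def default_cascade(fs: float) -> list[FilterSpec]:
    """The standard cascade: HP 0.5 Hz, LP 50 Hz, notch 47-53 Hz, notch 97-103 Hz.

    The second power-line harmonic stop is dropped with a warning when the
    sampling rate cannot represent it (fs <= 206 Hz).
    """
    specs = [
        FilterSpec("highpass", (0.5,)),
        FilterSpec("lowpass", (50.0,)),
        FilterSpec("bandstop", (47.0, 53.0)),
    ]
    if fs > 206.0:
        specs.append(FilterSpec("bandstop", (97.0, 103.0)))
    else:
        logger.warning(
            "fs=%g Hz too low for the 97-103 Hz harmonic stop; stage skipped", fs
        )
    return specs


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def remove_mean(rec: Recording) -> Recording:
    """Subtract the arithmetic mean of every channel (DC removal).

    Idempotent; output channels have mean 0 to floating-point precision.
    """
    if rec.n_samples < 1:
        raise ValueError("Cannot remove mean of an empty channel")
    data = rec.data - rec.data.mean(axis=1, keepdims=True)
    return replace(rec, data=data)


def apply_filter_cascade(
    rec: Recording, specs: Sequence[FilterSpec] | None = None
) -> Recording:
    """Apply each Butterworth stage in order, zero-phase (forward-backward).

    With ``specs=None`` the default cascade for ``rec.fs`` is used.
    """
    if specs is None:
        specs = default_cascade(rec.fs)
    data = rec.data
    for spec in specs:
        sos = spec.design(rec.fs)
        data = signal.sosfiltfilt(sos, data, axis=1)
    if not np.all(np.isfinite(data)):
        raise FloatingPointError("Filter cascade produced non-finite output")
    return replace(rec, data=data)


def segment_epochs(rec: Recording, epoch_len_s: float = 30.0) -> list[Epoch]:
    """Cut the recording into contiguous, non-overlapping epochs.

    Returns floor(S / (fs * epoch_len_s)) epochs in temporal order; the
    trailing remainder is discarded (logged). A recording shorter than one
    epoch yields an empty list with a warning.
    """
    n_per = rec.fs * epoch_len_s
    if abs(n_per - round(n_per)) > 1e-9:
        raise ValueError(
            f"fs*epoch_len = {n_per} is not an integer number of samples"
        )
    n_per = int(round(n_per))
    n_epochs = rec.n_samples // n_per
    if n_epochs == 0:
        logger.warning(
            "Recording of %d samples shorter than one %g-s epoch", rec.n_samples,
            epoch_len_s,
        )
        return []
    remainder = rec.n_samples - n_epochs * n_per
    if remainder:
        logger.info("Dropping %d trailing samples (< one epoch)", remainder)
    return [
        Epoch(
            data=rec.data[:, i * n_per:(i + 1) * n_per],
            fs=rec.fs,
            index=i,
            channel_labels=rec.channel_labels,
        )
        for i in range(n_epochs)
    ]


def apply_component_rejection(
    rec: Recording, unmixing: np.ndarray, reject: set[int] | Sequence[int]
) -> Recording:
    """Zero selected components of an externally supplied linear decomposition.

    Given an invertible unmixing matrix W (components = W @ data), the
    recording is reconstructed with the rejected component rows zeroed:
    data' = inv(W) @ Z @ W @ data. The decomposition itself (e.g. Infomax ICA
    with manual pruning) is produced outside this package; accepting it here
    keeps the pipeline fully automatic.
    """
    unmixing = np.asarray(unmixing, dtype=np.float64)
    m = rec.n_channels
    if unmixing.shape != (m, m):
        raise ValueError(f"Unmixing matrix must be {m}x{m}, got {unmixing.shape}")
    reject = set(int(r) for r in reject)
    if any(r < 0 or r >= m for r in reject):
        raise ValueError(f"Rejected component index out of range 0..{m - 1}")
    if np.linalg.matrix_rank(unmixing) < m:
        raise np.linalg.LinAlgError("Unmixing matrix is singular")
    comps = unmixing @ rec.data
    comps[sorted(reject), :] = 0.0
    data = np.linalg.solve(unmixing, comps)
    return replace(rec, data=data)
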