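"""Standard-format I/O: EDF signals, hypnogram text files, run configuration.

EDF/EDF+ is the canonical container for polysomnographic signals; recordings
are read through MNE (microvolt-scaled, channel selection by 10-20 label) and
written with a minimal 16-bit EDF writer, so synthetic recordings round-trip
through the standard format within one quantization step.

Hypnograms are plain text, one stage label per line from the vocabulary
{N1, N2, N3, REM, EXCLUDED}; EXCLUDED marks epochs the scorers could not agree
on, which are dropped from datasets.

Run configuration is a YAML mapping with one block per pipeline stage;
validation is strict (unknown keys are rejected by name) and happens before
any computation.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from hashlib import sha256
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import yaml

from .preprocess import STAGES, Recording

logger = logging.getLogger(__name__)

HYPNOGRAM_VOCAB = STAGES + ("EXCLUDED",)


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------

def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii")[:width]
    return b + b" " * (width - len(b))


def _num8(x: float) -> str:
    """Format a number into <= 8 ASCII chars without truncation artefacts."""
    for prec in range(7, 0, -1):
        s = f"{x:.{prec}g}"
        if len(s) <= 8:
            return s
    raise ValueError(f"Cannot format {x} into 8 characters")


def write_edf(path: str | Path, rec: Recording) -> None:
    """Write a recording as 16-bit EDF with 1-s data records, physical unit uV.

    Requires an integer sampling rate; a trailing partial second is truncated
    with a warning (data records must be whole).
    """
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError(f"EDF writer requires an integer sampling rate, got {fs}")
    fs = int(round(fs))
    n_rec = rec.n_samples // fs
    if n_rec == 0:
        raise ValueError("Recording shorter than one EDF data record (1 s)")
    if n_rec * fs < rec.n_samples:
        logger.warning("Truncating %d trailing samples to whole EDF records",
                       rec.n_samples - n_rec * fs)
    data = rec.data[:, :n_rec * fs]
    m = rec.n_channels

    phys_max = float(np.abs(data).max())
    phys_max = max(phys_max, 1.0)
    dig_min, dig_max = -32768, 32767
    scale = dig_max / phys_max
    digital = np.clip(np.round(data * scale), dig_min, dig_max).astype("<i2")

    header = b"".join([
        _pad("0", 8),
        _pad("X X X X", 80),
        _pad("Startdate X X X X", 80),
        _pad("01.01.00", 8),
        _pad("00.00.00", 8),
        _pad(str(256 * (m + 1)), 8),
        _pad("", 44),
        _pad(str(n_rec), 8),
        _pad("1", 8),
        _pad(str(m), 4),
    ])
    labels = [_pad(lab, 16) for lab in rec.channel_labels]
    per_signal = b"".join([
        b"".join(labels),
        b"".join(_pad("", 80) for _ in range(m)),        # transducer
        b"".join(_pad("uV", 8) for _ in range(m)),       # physical dimension
        b"".join(_pad(_num8(dig_min / scale), 8) for _ in range(m)),
        b"".join(_pad(_num8(phys_max), 8) for _ in range(m)),
        b"".join(_pad(str(dig_min), 8) for _ in range(m)),
        b"".join(_pad(str(dig_max), 8) for _ in range(m)),
        b"".join(_pad("", 80) for _ in range(m)),        # prefiltering
        b"".join(_pad(str(fs), 8) for _ in range(m)),
        b"".join(_pad("", 32) for _ in range(m)),
    ])
    with open(path, "wb") as fh:
        fh.write(header + per_signal)
        for r in range(n_rec):
            block = digital[:, r * fs:(r + 1) * fs]
            fh.write(block.tobytes())


def read_edf(path: str | Path, channels: Sequence[str] | None = None) -> Recording:
    """Read an EDF/EDF+ file into a microvolt Recording via MNE.

    ``channels`` optionally selects 10-20 labels; a missing requested channel
    raises an error naming it, and mixed sampling rates across the selection
    are rejected.
    """
    import mne

    path = Path(path)
    if not path.exists() or path.stat().st_size == 0:
        raise ValueError(f"EDF file {path} is missing or empty")
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    if channels is not None:
        missing = [c for c in channels if c not in raw.ch_names]
        if missing:
            raise ValueError(
                f"Requested channel(s) not in EDF: {', '.join(missing)}"
            )
        raw.pick(list(channels))
    sfreqs = {raw.info["sfreq"]}
    if len(sfreqs) != 1:
        raise ValueError(f"Mixed sampling rates in EDF: {sorted(sfreqs)}")
    data_uv = raw.get_data() * 1e6  # MNE loads volts
    return Recording(data=data_uv, fs=float(raw.info["sfreq"]),
                     channel_labels=list(raw.ch_names))


# ---------------------------------------------------------------------------
# hypnograms
# ---------------------------------------------------------------------------

@dataclass
class Hypnogram:
    """Stage label sequence across a night's epochs."""

    labels: list[str]
    epoch_len: float = 30.0

    def __post_init__(self) -> None:
        bad = [(i, s) for i, s in enumerate(self.labels)
               if s not in HYPNOGRAM_VOCAB]
        if bad:
            i, s = bad[0]
            raise ValueError(f"Unknown stage token {s!r} at line {i + 1}")


def write_hypnogram(path: str | Path, hyp: Hypnogram) -> None:
    Path(path).write_text("\n".join(hyp.labels) + "\n")


def read_hypnogram(path: str | Path, n_epochs: int | None = None,
                   epoch_len: float = 30.0) -> Hypnogram:
    """Read one stage token per line; length is checked against n_epochs."""
    lines = [ln.strip() for ln in Path(path).read_text().splitlines()]
    labels = [ln for ln in lines if ln]
    for i, tok in enumerate(labels):
        if tok not in HYPNOGRAM_VOCAB:
            raise ValueError(
                f"{path}: unknown stage token {tok!r} at line {i + 1} "
                f"(vocabulary: {', '.join(HYPNOGRAM_VOCAB)})"
            )
    if n_epochs is not None and len(labels) != n_epochs:
        raise ValueError(
            f"{path}: hypnogram has {len(labels)} labels but the recording "
            f"has {n_epochs} epochs"
        )
    return Hypnogram(labels=labels, epoch_len=epoch_len)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

class ConfigError(ValueError):
    """Invalid run configuration (unknown key, bad type or value)."""


_SCHEMA: dict[str, set[str]] = {
    "": {"seed", "log_level", "sampling", "filter", "sl", "wavelet", "graph",
         "staging", "simulate"},
    "sampling": {"fs", "epoch_len", "channels"},
    "filter": {"cascade"},
    "sl": {"l", "m", "w1", "w2", "p_ref", "stride"},
    "wavelet": {"mother", "depth"},
    "graph": {"threshold_frac", "n_rand"},
    "staging": {"train_frac", "cv_folds", "methods"},
    "simulate": {"n_channels", "fs", "epoch_len", "epochs_per_stage",
                 "profiles", "seed"},
}


@dataclass
class RunConfig:
    """Validated run configuration with per-stage blocks."""

    seed: int = 0
    log_level: str = "INFO"
    sampling: dict = field(default_factory=dict)
    filter: dict = field(default_factory=dict)
    sl: dict = field(default_factory=dict)
    wavelet: dict = field(default_factory=dict)
    graph: dict = field(default_factory=dict)
    staging: dict = field(default_factory=dict)
    simulate: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed, "log_level": self.log_level,
            "sampling": self.sampling, "filter": self.filter, "sl": self.sl,
            "wavelet": self.wavelet, "graph": self.graph,
            "staging": self.staging, "simulate": self.simulate,
        }

    def digest(self) -> str:
        return sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def validate_config(raw: dict[str, Any]) -> RunConfig:
    """Validate a configuration mapping; unknown keys are rejected by name."""
    if not isinstance(raw, dict):
        raise ConfigError("Configuration must be a mapping")
    unknown = set(raw) - _SCHEMA[""]
    if unknown:
        raise ConfigError(f"Unknown configuration key: {sorted(unknown)[0]!r}")
    for block, allowed in _SCHEMA.items():
        if not block or block not in raw:
            continue
        sub = raw[block]
        if not isinstance(sub, dict):
            raise ConfigError(f"Block {block!r} must be a mapping")
        bad = set(sub) - allowed
        if bad:
            raise ConfigError(
                f"Unknown key {sorted(bad)[0]!r} in block {block!r}"
            )
    cfg = RunConfig(
        seed=int(raw.get("seed", 0)),
        log_level=str(raw.get("log_level", "INFO")),
        **{b: dict(raw.get(b, {})) for b in
           ("sampling", "filter", "sl", "wavelet", "graph", "staging",
            "simulate")},
    )
    if not 0 <= cfg.seed < 2 ** 31:
        raise ConfigError("seed must lie in [0, 2^31)")
    return cfg


def load_config(path: str | Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text())
    return validate_config(raw or {})


def write_manifest(path: str | Path, cfg: RunConfig, **extra: Any) -> None:
    """Record config hash, seeds and versions so a run is reproducible."""
    import somnograph

    manifest = {
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "somnograph_version": somnograph.__version__,
        "config_digest": cfg.digest(),
        "config": cfg.to_dict(),
        **extra,
    }
    Path(path).write_text(json.dumps(manifest, indent=2, default=str))
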