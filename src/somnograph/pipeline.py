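"""End-to-end orchestration: recording -> epochs -> features -> staging.

Thin glue over the computational modules, shared by the command-line interface
and the test/benchmark entry points. One root seed is expanded deterministically
into per-stage seeds so a single knob reproduces a whole run.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass

import numpy as np

from .graphs import graph_feature_block
from .preprocess import (Epoch, Recording, apply_filter_cascade, remove_mean,
                         segment_epochs)
from .rwe import WaveletParams, band_energy_ratios, rwe_matrix
from .sl import SLParams, sl_matrix
from .staging import Dataset, assemble_features

logger = logging.getLogger(__name__)


def derive_seed(root_seed: int, *tags: str) -> int:
    """Deterministic per-stage seed below 2^31 derived from the root seed."""
    ss = np.random.SeedSequence(
        [int(root_seed) & 0x7FFFFFFF]
        + [zlib.crc32(t.encode()) & 0x7FFFFFFF for t in tags]
    )
    return int(ss.generate_state(1)[0]) & 0x7FFFFFFF


@dataclass(frozen=True)
class FeatureParams:
    """Parameters of the feature-extraction stage, resolved at run time."""

    sl: SLParams | None = None
    wavelet: WaveletParams | None = None
    threshold_frac: float = 0.3
    n_rand: int = 20
    seed: int = 0


def preprocess_recording(
    rec: Recording, epoch_len_s: float = 30.0, filters=None
) -> list[Epoch]:
    """DC removal, Butterworth cascade, 30-s epoching."""
    rec = remove_mean(rec)
    rec = apply_filter_cascade(rec, filters)
    return segment_epochs(rec, epoch_len_s)


def epoch_features(epoch: Epoch, method: str, fp: FeatureParams) -> np.ndarray:
    """The full feature vector of one epoch for one connectivity method."""
    if method == "SL":
        mat = sl_matrix(epoch, fp.sl)
        gf = graph_feature_block(mat, fp.threshold_frac, fp.n_rand, fp.seed)
        return assemble_features(mat, gf)
    if method == "RWE":
        wp = fp.wavelet or WaveletParams(fs=epoch.fs)
        mat = rwe_matrix(epoch, wp)
        ratios = band_energy_ratios(epoch, wp)
        gf = graph_feature_block(mat, fp.threshold_frac, fp.n_rand, fp.seed)
        return assemble_features(mat, gf, ratios)
    raise ValueError(f"Unknown connectivity method {method!r}")


def synthetic_staging_study(
    profiles: dict | None = None,
    n_channels: int = 8,
    fs: float = 128.0,
    epochs_per_stage: int = 200,
    seed: int = 0,
    methods: tuple[str, ...] = ("SL", "RWE"),
    grid=None,
    train_frac: float = 0.7,
    cv_folds: int = 2,
):
    """Run the whole pipeline on synthetic EEG and return (results, reports).

    Generates ``epochs_per_stage`` labelled 30-s epochs per stage from the
    given stage profiles (defaults to the well-separated ones), preprocesses,
    extracts SL and/or RWE feature vectors, and evaluates a classifier grid
    (``compact_grid`` per method unless one is passed). Returns the tidy
    results table and, per method, the test-split evaluation report of the
    grid's best model. Fully deterministic given ``seed``.

    Scale defaults (8 channels, SL reference stride 32, 10 graph surrogates)
    keep a 200-epochs-per-stage run within minutes on one CPU.
    """
    from .staging import (compact_grid, evaluate, minmax_normalize, run_grid,
                          stratified_split, train_classifier)
    from .synthetic import SimConfig, default_profiles, generate_labelled_dataset

    profiles = profiles or default_profiles()
    cfg = SimConfig(
        n_channels=n_channels, fs=fs, epoch_len=30.0,
        epochs_per_stage={s: epochs_per_stage for s in
                          ("N1", "N2", "N3", "REM")},
        seed=derive_seed(seed, "simulate"),
    )
    rec, labels = generate_labelled_dataset(profiles, cfg)
    epochs = preprocess_recording(rec)
    fp = FeatureParams(
        sl=SLParams.from_band(fs, p_ref=0.02, stride=32),
        n_rand=10,
        seed=derive_seed(seed, "graph"),
    )
    feats = {m: build_dataset(epochs, labels, m, fp) for m in methods}
    grid = grid or {m: compact_grid(m) for m in methods}
    split_seed = derive_seed(seed, "split")
    results = run_grid(feats, grid, train_frac=train_frac, seed=split_seed,
                       cv_folds=cv_folds)
    reports = {}
    for method, ds in feats.items():
        sub = results[results.method == method].reset_index(drop=True)
        best_spec = grid[method][int(sub["test_acc"].idxmax())]
        train, test = stratified_split(ds, train_frac, split_seed)
        train, test, _ = minmax_normalize(train, test)
        model = train_classifier(best_spec, train, cv_folds, split_seed)
        reports[method] = evaluate(model, test)
    return results, reports


def build_dataset(
    epochs: list[Epoch],
    labels: list[str],
    method: str,
    fp: FeatureParams | None = None,
) -> Dataset:
    """Feature matrix over labelled epochs for one connectivity method."""
    if len(epochs) != len(labels):
        raise ValueError(
            f"{len(epochs)} epochs vs {len(labels)} hypnogram labels"
        )
    keep = [(e, lab) for e, lab in zip(epochs, labels) if lab != "EXCLUDED"]
    if not keep:
        raise ValueError("All epochs are excluded")
    if len(keep) < len(epochs):
        logger.info("Dropping %d excluded epochs", len(epochs) - len(keep))
    fp = fp or FeatureParams()
    vecs, ys = [], []
    for i, (ep, lab) in enumerate(keep):
        vecs.append(epoch_features(ep, method, fp))
        ys.append(lab)
        if (i + 1) % 100 == 0:
            logger.info("%s features: %d/%d epochs", method, i + 1, len(keep))
    return Dataset(np.vstack(vecs), np.array(ys), method=method)
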