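"""From continuous session recordings to standardized ERP feature matrices.

The chain is: zero-phase band-limiting (high-pass 0.5 Hz, then common
average reference, then low-pass 50 Hz), epoching to [-200, 600) ms around
each stimulus onset with baseline correction over [-200, 0), per-block
per-stimulus averaging of the repeated highlights, cropping to the
[100, 600) ms discriminative window (250 points per channel at 500 Hz),
channel concatenation, and per-feature standardization fit on the training
portion only.

With ``n_stimuli`` stimuli and ``B`` training blocks this yields ``B``
target samples and ``B * (n_stimuli - 1)`` nontarget samples — the 1:3 or
1:5 imbalance the resampling layer exists to correct.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

from .synth import BlockRecording, SessionRecording

__all__ = [
    "EpochSet",
    "FeatureDataset",
    "bandpass_and_car",
    "epoch_and_baseline",
    "extract_features",
    "session_features",
    "save_features",
    "load_features",
    "EPOCH_START_MS",
    "EPOCH_STOP_MS",
    "FEATURE_START_MS",
    "FEATURE_STOP_MS",
]

EPOCH_START_MS = -200.0
EPOCH_STOP_MS = 600.0  # half-open [start, stop)
FEATURE_START_MS = 100.0
FEATURE_STOP_MS = 600.0  # half-open; 500 ms * 500 Hz = 250 points exactly

_HP_HZ = 0.5
_LP_HZ = 50.0
_FILTER_ORDER = 4  # Butterworth, applied zero-phase (sosfiltfilt)


@dataclass
class EpochSet:
    """Baseline-corrected single-trial epochs with trial metadata.

    ``epochs`` is trials x channels x time over [-200, 600) ms; at 500 Hz
    that is 400 samples per epoch.
    """

    epochs: np.ndarray
    block_id: np.ndarray
    stimulus_id: np.ndarray
    is_target: np.ndarray
    sampling_rate: float

    def __len__(self) -> int:
        return self.epochs.shape[0]


@dataclass
class FeatureDataset:
    """Standardized ERP feature matrix with block/stimulus metadata.

    One row per (block, stimulus): the average over the repeated highlights,
    cropped to [100, 600) ms and flattened channel-major.  ``y`` is 1 for
    target rows (the minority class) and 0 for nontarget.  ``mean`` /
    ``scale`` are the per-feature standardization parameters learned from
    the training portion.
    """

    X: np.ndarray
    y: np.ndarray
    block_id: np.ndarray
    stimulus_id: np.ndarray
    mean: np.ndarray | None = None
    scale: np.ndarray | None = None

    @property
    def n_minority(self) -> int:
        return int(np.sum(self.y == 1))

    @property
    def n_majority(self) -> int:
        return int(np.sum(self.y == 0))


def _filter_sos(cutoff_hz: float, btype: str, fs: float) -> np.ndarray:
    return sps.butter(_FILTER_ORDER, cutoff_hz, btype=btype, fs=fs, output="sos")


def bandpass_and_car(recording: SessionRecording) -> SessionRecording:
    """High-pass 0.5 Hz, common average reference, low-pass 50 Hz.

    Both filters are zero-phase 4th-order Butterworth; CAR subtracts the
    across-channel mean at every sample.  Requires >= 2 channels (the
    common average of a single channel would null the signal).
    """
    cfg = recording.config
    if cfg.n_channels < 2:
        raise ValueError("common average reference needs at least 2 channels")
    hp = _filter_sos(_HP_HZ, "highpass", cfg.sampling_rate)
    lp = _filter_sos(_LP_HZ, "lowpass", cfg.sampling_rate)

    def _process(block: BlockRecording) -> BlockRecording:
        x = sps.sosfiltfilt(hp, block.signal, axis=1)
        x = x - x.mean(axis=0, keepdims=True)
        x = sps.sosfiltfilt(lp, x, axis=1)
        return BlockRecording(signal=x, events=block.events.copy(), target_id=block.target_id)

    return SessionRecording(
        config=cfg,
        train_blocks=[_process(b) for b in recording.train_blocks],
        test_blocks=[_process(b) for b in recording.test_blocks],
    )


def _epoch_window_samples(fs: float) -> tuple[int, int]:
    pre = int(round(-EPOCH_START_MS * fs / 1000.0))
    post = int(round(EPOCH_STOP_MS * fs / 1000.0))
    return pre, post


def epoch_and_baseline(recording: SessionRecording, split: str = "train") -> EpochSet:
    """Cut [-200, 600) ms epochs and subtract the [-200, 0) baseline mean.

    ``split`` selects ``"train"`` or ``"test"`` blocks.  Raises if any epoch
    would leave the recorded signal (the generator pads block edges so this
    only happens on foreign data).
    """
    cfg = recording.config
    blocks = recording.train_blocks if split == "train" else recording.test_blocks
    pre, post = _epoch_window_samples(cfg.sampling_rate)
    epochs, block_ids, stim_ids, targets = [], [], [], []
    for b, block in enumerate(blocks):
        n_samples = block.signal.shape[1]
        for stim, onset, is_target in block.events:
            lo, hi = onset - pre, onset + post
            if lo < 0 or hi > n_samples:
                raise ValueError(
                    f"epoch [{lo}, {hi}) outside block of {n_samples} samples"
                )
            ep = block.signal[:, lo:hi].astype(float)
            ep = ep - ep[:, :pre].mean(axis=1, keepdims=True)
            epochs.append(ep)
            block_ids.append(b)
            stim_ids.append(stim)
            targets.append(is_target)
    return EpochSet(
        epochs=np.asarray(epochs),
        block_id=np.asarray(block_ids, dtype=int),
        stimulus_id=np.asarray(stim_ids, dtype=int),
        is_target=np.asarray(targets, dtype=int),
        sampling_rate=cfg.sampling_rate,
    )


def extract_features(
    epochs: EpochSet,
    mean: np.ndarray | None = None,
    scale: np.ndarray | None = None,
    fit_standardizer: bool = True,
) -> FeatureDataset:
    """Average repeated highlights, crop the ERP window, standardize.

    Per (block, stimulus) the epochs are averaged into a single sample; the
    [100, 600) ms window is cropped (250 points per channel at 500 Hz) and
    channels concatenated.  With ``fit_standardizer`` the per-feature mean
    and scale are estimated from this data (training role); otherwise the
    provided parameters are applied (test role).  Zero-variance features get
    scale 1 with a warning.
    """
    fs = epochs.sampling_rate
    pre, _ = _epoch_window_samples(fs)
    lo = pre + int(round(FEATURE_START_MS * fs / 1000.0))
    hi = pre + int(round(FEATURE_STOP_MS * fs / 1000.0))

    keys = np.stack([epochs.block_id, epochs.stimulus_id], axis=1)
    uniq, inverse = np.unique(keys, axis=0, return_inverse=True)
    n_samples = uniq.shape[0]
    n_ch = epochs.epochs.shape[1]
    X = np.zeros((n_samples, n_ch * (hi - lo)))
    y = np.zeros(n_samples, dtype=int)
    for g in range(n_samples):
        sel = inverse == g
        avg = epochs.epochs[sel].mean(axis=0)[:, lo:hi]
        X[g] = avg.ravel()
        y[g] = int(round(epochs.is_target[sel].mean()))

    if fit_standardizer:
        mean = X.mean(axis=0)
        scale = X.std(axis=0, ddof=0)
        zero = scale == 0
        if np.any(zero):
            warnings.warn(f"{int(zero.sum())} zero-variance features; scale forced to 1")
            scale = scale.copy()
            scale[zero] = 1.0
    elif mean is None or scale is None:
        raise ValueError("mean and scale required when fit_standardizer=False")
    X = (X - mean) / scale
    return FeatureDataset(
        X=X,
        y=y,
        block_id=uniq[:, 0].copy(),
        stimulus_id=uniq[:, 1].copy(),
        mean=np.asarray(mean),
        scale=np.asarray(scale),
    )


def session_features(recording: SessionRecording) -> tuple[FeatureDataset, FeatureDataset]:
    """Full preprocessing of a session: (train features, test features).

    The standardizer is fit on the training portion and applied unchanged to
    the test portion.
    """
    filtered = bandpass_and_car(recording)
    train = extract_features(epoch_and_baseline(filtered, "train"), fit_standardizer=True)
    test = extract_features(
        epoch_and_baseline(filtered, "test"),
        mean=train.mean,
        scale=train.scale,
        fit_standardizer=False,
    )
    return train, test


def save_features(ds: FeatureDataset, path: str | Path) -> None:
    """TSV with block_id, stimulus_id, label and feature columns, plus a
    JSON sidecar holding the standardizer."""
    path = Path(path)
    df = pd.DataFrame(ds.X, columns=[f"f{i}" for i in range(ds.X.shape[1])])
    df.insert(0, "label", ds.y)
    df.insert(0, "stimulus_id", ds.stimulus_id)
    df.insert(0, "block_id", ds.block_id)
    df.to_csv(path, sep="\t", index=False)
    if ds.mean is not None:
        sidecar = path.with_suffix(path.suffix + ".scaler.json")
        sidecar.write_text(json.dumps({"mean": ds.mean.tolist(), "scale": ds.scale.tolist()}))


def load_features(path: str | Path) -> FeatureDataset:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    feat_cols = [c for c in df.columns if c.startswith("f")]
    mean = scale = None
    sidecar = path.with_suffix(path.suffix + ".scaler.json")
    if sidecar.exists():
        d = json.loads(sidecar.read_text())
        mean, scale = np.asarray(d["mean"]), np.asarray(d["scale"])
    return FeatureDataset(
        X=df[feat_cols].to_numpy(float),
        y=df["label"].to_numpy(int),
        block_id=df["block_id"].to_numpy(int),
        stimulus_id=df["stimulus_id"].to_numpy(int),
        mean=mean,
        scale=scale,
    )
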