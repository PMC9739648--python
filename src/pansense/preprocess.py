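"""Raw recordings to model-ready windows.

The fixed pipeline order is trim -> resample -> split_gravity ->
make_windows. Trimming drops the preparation/stop phase at the session ends;
resampling decimates the raw 100 Hz stream to the working rate F by
block-average; an incremental first-order low-pass tracks gravity so the
classifier sees body motion only; sliding windows of WS samples are the
classification unit; the train/test split is by session so overlapping
windows never leak across the split.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .domain import ActivityLabel, NodePosition, PANConfig, canonical_activity_order
from .synth_imu import LabeledSeries

__all__ = [
    "SensorWindow",
    "WindowedDataset",
    "trim_session",
    "resample",
    "alpha_for_rate",
    "split_gravity",
    "make_windows",
    "train_test_split",
    "series_to_windows",
    "manifest",
]

#: Reference gravity-filter constant and the rate it is quoted at. The pole
#: per second is alpha_ref**REF_RATE; alpha at another rate keeps that pole
#: (hence the cutoff) invariant: alpha = alpha_ref ** (REF_RATE / rate).
ALPHA_REF = 0.9
REF_RATE = 20.0


@dataclass
class SensorWindow:
    """One fixed-width slice of WS samples: the classifier input X_i(t).

    ``values`` columns are body-motion accel (gravity removed) then gyro.
    """

    values: np.ndarray
    label: ActivityLabel
    position: NodePosition
    step: int
    source_session: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("window values must be 2-D")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("window values must be finite")

    @property
    def window_size(self) -> int:
        return self.values.shape[0]


@dataclass
class WindowedDataset:
    windows: list[SensorWindow]
    config: PANConfig
    split_tag: str = "all"

    def __post_init__(self) -> None:
        sizes = {w.window_size for w in self.windows}
        if len(sizes) > 1:
            raise ValueError(f"mixed window sizes in dataset: {sorted(sizes)}")

    def __len__(self) -> int:
        return len(self.windows)

    def labels(self) -> np.ndarray:
        return np.array([w.label.index for w in self.windows], dtype=int)

    def sessions(self) -> list[str]:
        return sorted({w.source_session for w in self.windows})


def trim_session(series: LabeledSeries, fraction: float = 0.02) -> LabeledSeries:
    """Drop ``floor(fraction * T)`` samples from each end of the recording."""
    if not 0 <= fraction < 0.5:
        raise ValueError("trim fraction must be in [0, 0.5)")
    T = series.n_samples
    cut = int(np.floor(fraction * T))
    if T - 2 * cut <= 0:
        raise ValueError(f"trimming {cut} samples from each end empties a series of {T}")
    if cut == 0:
        return series
    return replace(series, samples=series.samples[cut:T - cut])


def resample(series: LabeledSeries, target_rate: float) -> LabeledSeries:
    """Decimate to ``target_rate`` by averaging each block of ``stride`` samples.

    The raw rate must be an integer multiple of the target; block averaging
    acts as the anti-alias filter and preserves constants exactly.
    """
    raw_rate = series.rate
    if target_rate <= 0:
        raise ValueError("target rate must be > 0")
    stride_f = raw_rate / target_rate
    stride = int(round(stride_f))
    if abs(stride_f - stride) > 1e-9 or stride < 1:
        divisors = [raw_rate / k for k in range(1, int(raw_rate) + 1)
                    if abs(raw_rate / round(raw_rate / k) - raw_rate / k) < 1e-9]
        nearest = min(divisors, key=lambda r: abs(r - target_rate))
        raise ValueError(
            f"target rate {target_rate} Hz does not divide the raw rate "
            f"{raw_rate:g} Hz; nearest valid rate is {nearest:g} Hz")
    if stride == 1:
        return series
    T = series.n_samples
    n_out = T // stride
    blocks = series.samples[: n_out * stride].reshape(n_out, stride, 6)
    return replace(series, samples=blocks.mean(axis=1),
                   sample_period=series.sample_period * stride)


def alpha_for_rate(rate: float, alpha_ref: float = ALPHA_REF,
                   ref_rate: float = REF_RATE) -> float:
    """Gravity-filter constant at ``rate`` keeping the cutoff rate-invariant."""
    return float(alpha_ref ** (ref_rate / rate))


def split_gravity(series: LabeledSeries, alpha: float | None = None,
                  return_gravity: bool = False):
    """Separate gravity from body motion in the accelerometer channels.

    Per accel channel: ``g_t = alpha * g_{t-1} + (1 - alpha) * a_t`` with
    ``g_0 = a_0``; body motion is ``a_t - g_t``. Gyro channels pass through.
    ``alpha=None`` picks :func:`alpha_for_rate` for the series' rate.
    """
    if alpha is None:
        alpha = alpha_for_rate(series.rate)
    if not 0 <= alpha < 1:
        raise ValueError("alpha must be in [0, 1)")
    acc = series.samples[:, :3]
    g = np.empty_like(acc)
    g[0] = acc[0]
    # scipy.signal.lfilter would do, but the 3-term recursion with the g_0
    # initial condition is clearer written out and is O(T) either way.
    for i in range(1, acc.shape[0]):
        g[i] = alpha * g[i - 1] + (1.0 - alpha) * acc[i]
    body = np.column_stack([acc - g, series.samples[:, 3:]])
    out = replace(series, samples=body)
    if return_gravity:
        return out, g
    return out


def make_windows(series: LabeledSeries, window_size: int,
                 overlap_fraction: float = 0.5) -> list[SensorWindow]:
    """Slice a series into fixed-width sliding windows.

    ``stride = max(1, round(window_size * (1 - overlap_fraction)))``; the
    trailing partial window is dropped. Returns [] (with a warning) when the
    series is shorter than one window.
    """
    if window_size < 2:
        raise ValueError("window_size must be >= 2")
    if not 0 <= overlap_fraction < 1:
        raise ValueError("overlap_fraction must be in [0, 1)")
    T = series.n_samples
    if T < window_size:
        warnings.warn(
            f"series {series.session_id} has {T} samples < window {window_size}")
        return []
    stride = max(1, int(round(window_size * (1.0 - overlap_fraction))))
    starts = range(0, T - window_size + 1, stride)
    return [
        SensorWindow(
            values=series.samples[s:s + window_size],
            label=series.label,
            position=series.position,
            step=k,
            source_session=series.session_id,
        )
        for k, s in enumerate(starts)
    ]


def series_to_windows(series: LabeledSeries, config: PANConfig,
                      trim_fraction: float = 0.02,
                      overlap_fraction: float = 0.5,
                      alpha: float | None = None) -> list[SensorWindow]:
    """Full per-series pipeline: trim -> resample -> split_gravity -> windows."""
    s = trim_session(series, trim_fraction)
    s = resample(s, config.sample_rate)
    s = split_gravity(s, alpha)
    return make_windows(s, config.window_size, overlap_fraction)


def train_test_split(dataset: WindowedDataset, train_fraction: float = 0.8,
                     seed: int = 0) -> tuple[WindowedDataset, WindowedDataset]:
    """Split by session, stratified by activity, deterministic per seed.

    All windows from one session land on the same side, so overlapping
    windows cannot leak between train and test.
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    by_session: dict[str, ActivityLabel] = {}
    for w in dataset.windows:
        by_session.setdefault(w.source_session, w.label)
    rng = np.random.default_rng(seed)
    train_sessions: set[str] = set()
    for activity in canonical_activity_order():
        sessions = sorted(s for s, lab in by_session.items() if lab == activity)
        if not sessions:
            continue
        n_train = int(round(train_fraction * len(sessions)))
        n_train = min(max(n_train, 1), len(sessions) - 1) if len(sessions) > 1 else 1
        picked = rng.permutation(len(sessions))[:n_train]
        train_sessions.update(sessions[i] for i in picked)
    train_w = [w for w in dataset.windows if w.source_session in train_sessions]
    test_w = [w for w in dataset.windows if w.source_session not in train_sessions]
    for tag, ws in (("train", train_w), ("test", test_w)):
        present = {w.label.name for w in ws}
        missing = [a.name for a in canonical_activity_order()
                   if a.name in {l.name for l in by_session.values()} and a.name not in present]
        if missing:
            warnings.warn(f"classes missing from {tag} split: {missing}")
    return (
        WindowedDataset(train_w, dataset.config, "train"),
        WindowedDataset(test_w, dataset.config, "test"),
    )


def manifest(dataset: WindowedDataset, raw_readings: int | None = None) -> dict:
    """Summary counts: windows total/per class, plus raw readings if known."""
    labels = dataset.labels()
    per_class = {a.name: int((labels == a.index).sum())
                 for a in canonical_activity_order()}
    out = {
        "split": dataset.split_tag,
        "window_size": dataset.config.window_size,
        "sample_rate": dataset.config.sample_rate,
        "n_windows": len(dataset),
        "windows_per_class": per_class,
        "n_sessions": len(dataset.sessions()),
    }
    if raw_readings is not None:
        out["n_raw_readings"] = int(raw_readings)
    return out


def save_windowed(dataset: WindowedDataset, directory: str | Path, name: str) -> Path:
    """Serialize a windowed dataset: flat CSV plus a JSON manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, w in enumerate(dataset.windows):
        flat = w.values.reshape(-1)
        rows.append({
            "window_id": i, "label": w.label.name, "position": w.position.code,
            "step": w.step, "session": w.source_session,
            **{f"v{j}": flat[j] for j in range(flat.size)},
        })
    path = directory / f"{name}.csv"
    pd.DataFrame(rows).to_csv(path, index=False)
    (directory / f"{name}.manifest.json").write_text(
        json.dumps(manifest(dataset), indent=1))
    return path
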