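"""Glue between the generator and the network-level stages.

Builds per-position windowed datasets whose windows are step-aligned across
positions (same activity/session/window order — the four devices worn at
once), splits them by session consistently, and trains one classifier per
position.
"""

from __future__ import annotations

from .domain import PANConfig
from .node_classifier import ModelSpec, TrainedModel, train
from .preprocess import WindowedDataset, series_to_windows, train_test_split
from .synth_imu import LabeledSeries

__all__ = [
    "corpus_to_datasets",
    "split_aligned",
    "train_position_models",
]


def corpus_to_datasets(
    corpus: list[LabeledSeries],
    config: PANConfig,
    trim_fraction: float = 0.02,
    overlap_fraction: float = 0.5,
) -> dict[str, WindowedDataset]:
    """Window a multi-position corpus into one dataset per position.

    The corpus order (activity, session, position) is preserved within each
    position, so window k of any two positions covers the same instant of
    the same session: the streams are step-aligned by construction.
    """
    per_pos: dict[str, list] = {}
    for series in corpus:
        per_pos.setdefault(series.position.code, []).extend(
            series_to_windows(series, config, trim_fraction, overlap_fraction))
    return {
        code: WindowedDataset(windows, config)
        for code, windows in per_pos.items()
    }


def split_aligned(
    datasets: dict[str, WindowedDataset],
    train_fraction: float = 0.8,
    seed: int = 0,
) -> tuple[dict[str, WindowedDataset], dict[str, WindowedDataset]]:
    """Session-level split applied identically to every position."""
    first = datasets[sorted(datasets)[0]]
    ref_train, _ = train_test_split(first, train_fraction, seed)
    train_sessions = set(ref_train.sessions())
    train_d, test_d = {}, {}
    for code, ds in datasets.items():
        tr = [w for w in ds.windows if w.source_session in train_sessions]
        te = [w for w in ds.windows if w.source_session not in train_sessions]
        train_d[code] = WindowedDataset(tr, ds.config, "train")
        test_d[code] = WindowedDataset(te, ds.config, "test")
    return train_d, test_d


def train_position_models(
    train_sets: dict[str, WindowedDataset],
    spec: ModelSpec | None = None,
    seed: int = 0,
) -> dict[str, TrainedModel]:
    """One classifier per position, seeded per-position for independence."""
    spec = spec or ModelSpec()
    models = {}
    for code in sorted(train_sets):
        pos_seed = seed * 16 + int(code[1])
        models[code] = train(spec, train_sets[code], seed=pos_seed)
    return models
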