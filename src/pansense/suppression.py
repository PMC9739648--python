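"""Transmit decision, suppression metric, and transmit-set minimisation.

A supporting node transmits its local result at step t only when the class
it just recognised is in its transmit set D_i^s (the event-type-driven
suppression rule, s_{i,t} = 1 iff d_{i,t} in D_i^s). Under balanced activity
durations and correct local recognition, the expected fraction of avoided
transmissions is simply one minus the density of transmit flags — that is
the suppression percentage reported for a configuration.

The transmit sets themselves are found greedily: start from the full
activity set for every support, tentatively drop one (node, activity)
obligation at a time, and keep the removal whenever the ensemble's training
accuracy falls by at most a tolerance epsilon. Each accepted removal
re-baselines the accuracy and (by default) restarts the scan. An exhaustive
enumeration over tiny instances serves as the optimality reference in tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import product

import numpy as np

from .domain import (
    ClassificationResult,
    N_CLASSES,
    NodePosition,
    PANConfig,
    TransmitSet,
    canonical_activity_order,
)
from .node_classifier import predict_dataset

__all__ = [
    "OptimizerConfig",
    "OptimizationTrace",
    "should_transmit",
    "expected_suppression",
    "ensemble_accuracy",
    "optimize_transmit_sets",
    "optimize_transmit_sets_from_streams",
    "brute_force_minimum_sets",
]


@dataclass
class OptimizerConfig:
    epsilon: float = 0.001
    node_scan_order: list[NodePosition] | None = None
    restart_on_removal: bool = True

    def __post_init__(self) -> None:
        if self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")


@dataclass
class OptimizationTrace:
    steps: list[dict] = field(default_factory=list)
    final_sets: dict = field(default_factory=dict)  # code -> TransmitSet
    baseline_accuracy: float = 0.0
    final_accuracy: float = 0.0

    @property
    def accepted_removals(self) -> int:
        return sum(1 for s in self.steps if s["accepted"])


def should_transmit(result: ClassificationResult, tset: TransmitSet) -> bool:
    """The per-step transmit decision s_{i,t} for a supporting node."""
    if result.node != tset.node:
        raise ValueError(
            f"result from {result.node.code} checked against {tset.node.code}'s set")
    return bool(tset.flags[result.label.index])


def expected_suppression(tsets: list[TransmitSet]) -> int:
    """Expected suppression percentage under balanced, correctly-recognised
    activities: ``100 * (1 - flags_on / (8 * n_supports))``, half-up rounded."""
    if not tsets:
        raise ValueError("need at least one transmit set")
    ones = sum(t.size for t in tsets)
    pct = 100.0 * (1.0 - ones / (N_CLASSES * len(tsets)))
    return int(math.floor(pct + 0.5))


# ------------------------------------------------------- vote evaluation ---

def ensemble_accuracy(
    main_labels: np.ndarray,
    main_weights: np.ndarray,
    support_labels: list[np.ndarray],
    support_weights: list[np.ndarray],
    support_flags: list,
    true_labels: np.ndarray,
) -> float:
    """Vectorised ensemble accuracy over an aligned step stream.

    Applies the transmit rule per support (``support_flags`` is one
    length-8 boolean sequence per support), sums top-1 vote weights per
    class, and scores the argmax against the true labels. Tie-breaking
    matches the online vote: lowest class index, main's label preferred
    among the tied.
    """
    n = len(true_labels)
    idx = np.arange(n)
    scores = np.zeros((n, N_CLASSES))
    np.add.at(scores, (idx, main_labels), main_weights)
    for labels, weights, flags in zip(support_labels, support_weights, support_flags):
        flags = np.asarray(flags, dtype=bool)
        mask = flags[labels]
        np.add.at(scores, (idx[mask], labels[mask]), weights[mask])
    best = scores.max(axis=1)
    tied = scores >= best[:, None] - 1e-12
    winner = scores.argmax(axis=1)
    main_tied = tied[idx, main_labels] & (tied.sum(axis=1) > 1)
    winner = np.where(main_tied, main_labels, winner)
    return float((winner == true_labels).mean())


def _aligned_streams(models: dict, train_sets: dict, pan: PANConfig):
    """Predict every node's stream once and check step alignment."""
    codes = [pan.main_node.code] + [s.code for s in pan.support_nodes]
    lengths = {c: len(train_sets[c]) for c in codes}
    if len(set(lengths.values())) != 1:
        raise ValueError(f"streams are not aligned: window counts {lengths}")
    ref = train_sets[codes[0]].labels()
    for c in codes[1:]:
        if not np.array_equal(train_sets[c].labels(), ref):
            raise ValueError(f"streams are not aligned: true labels differ for {c}")
    streams = {}
    for c in codes:
        labels, proba = predict_dataset(models[c], train_sets[c])
        streams[c] = (labels, proba[np.arange(len(labels)), labels])
    return streams, ref


def optimize_transmit_sets(
    models: dict,
    train_sets: dict,
    pan: PANConfig,
    opt: OptimizerConfig | None = None,
) -> OptimizationTrace:
    """Greedy minimisation of each support's transmit set.

    ``models`` and ``train_sets`` map position codes to the node's trained
    model and its (step-aligned) training windows. Starts from the full
    activity set on every support; a tentative removal is kept when the
    ensemble training accuracy drops by at most epsilon, after which the
    accuracy baseline moves to the new value and (by default) the node and
    activity scans restart from the beginning. Terminates when one complete
    scan accepts nothing. The main node is never gated.
    """
    streams, true_labels = _aligned_streams(models, train_sets, pan)
    return optimize_transmit_sets_from_streams(streams, true_labels, pan, opt)


def optimize_transmit_sets_from_streams(
    streams: dict,
    true_labels: np.ndarray,
    pan: PANConfig,
    opt: OptimizerConfig | None = None,
) -> OptimizationTrace:
    """Stream-level core of the greedy minimisation.

    ``streams`` maps position codes to ``(predicted_labels, top1_weights)``
    arrays over an aligned step sequence.
    """
    opt = opt or OptimizerConfig()
    scan = opt.node_scan_order or pan.support_nodes
    main_labels, main_weights = streams[pan.main_node.code]
    supports = [p.code for p in scan]
    sup_labels = [streams[c][0] for c in supports]
    sup_weights = [streams[c][1] for c in supports]

    flags = {c: np.ones(N_CLASSES, dtype=bool) for c in supports}

    def acc() -> float:
        return ensemble_accuracy(
            main_labels, main_weights, sup_labels, sup_weights,
            [flags[c] for c in supports], true_labels)

    trace = OptimizationTrace()
    a = trace.baseline_accuracy = acc()
    activities = canonical_activity_order()

    improved = True
    while improved:
        improved = False
        for node in scan:
            c = node.code
            for activity in activities:
                if not flags[c][activity.index]:
                    continue
                flags[c][activity.index] = False
                a_ij = acc()
                accepted = (a - a_ij) <= opt.epsilon
                trace.steps.append({
                    "node": c,
                    "activity_removed": activity.name,
                    "accuracy_before": a,
                    "accuracy_after": a_ij,
                    "accepted": accepted,
                })
                if accepted:
                    a = a_ij  # the shrunk set becomes the new baseline
                    improved = True
                    if opt.restart_on_removal:
                        break
                else:
                    flags[c][activity.index] = True
            if improved and opt.restart_on_removal:
                break
        # with restart off, `improved` removals were kept in place; loop
        # again until a full scan accepts nothing

    trace.final_sets = {
        node.code: TransmitSet(node, tuple(bool(f) for f in flags[node.code]))
        for node in scan
    }
    trace.final_accuracy = a
    return trace


def brute_force_minimum_sets(
    main_labels: np.ndarray,
    main_weights: np.ndarray,
    support_labels: list[np.ndarray],
    support_weights: list[np.ndarray],
    true_labels: np.ndarray,
    epsilon: float,
    n_classes: int | None = None,
) -> tuple[list[tuple[bool, ...]], float]:
    """Exhaustive minimum-size transmit sets for tiny instances.

    Enumerates every combination of per-support flag vectors (restricted to
    the first ``n_classes`` classes) and returns the flag tuples of minimum
    total size whose ensemble accuracy is at least the full-set accuracy
    minus epsilon, together with that accuracy. Intended as a test oracle:
    at most 2 supports and 4 classes.
    """
    n_sup = len(support_labels)
    if n_sup > 2:
        raise ValueError("exhaustive search supports at most 2 support nodes")
    if n_classes is None:
        used = set(np.concatenate([main_labels, true_labels] + list(support_labels)).tolist())
        n_classes = max(used) + 1
    if n_classes > 4:
        raise ValueError("exhaustive search supports at most 4 classes")

    def pad(bits):
        return tuple(bool(b) for b in bits) + (False,) * (N_CLASSES - n_classes)

    full = [pad((1,) * n_classes)] * n_sup
    baseline = ensemble_accuracy(
        main_labels, main_weights, support_labels, support_weights, full, true_labels)

    best_sets, best_size, best_acc = None, None, None
    combos = product(*[product((True, False), repeat=n_classes) for _ in range(n_sup)])
    for bits in combos:
        flag_vecs = [pad(b) for b in bits]
        size = sum(sum(f) for f in flag_vecs)
        if best_size is not None and size >= best_size:
            continue
        acc = ensemble_accuracy(
            main_labels, main_weights, support_labels, support_weights,
            flag_vecs, true_labels)
        if baseline - acc <= epsilon:
            best_sets, best_size, best_acc = flag_vecs, size, acc
    return best_sets, float(best_acc)
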