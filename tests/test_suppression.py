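"""Transmit rule, expected suppression against the packaged reference
table, and the greedy transmit-set optimiser against exhaustive search."""

import numpy as np
import pytest

from pansense.domain import (
    ClassificationResult,
    N_CLASSES,
    PANConfig,
    TransmitSet,
    activity_by_index,
    parse_transmit_vector,
    position_by_code,
    load_reference_transmit_sets,
)
from pansense.suppression import (
    OptimizerConfig,
    brute_force_minimum_sets,
    ensemble_accuracy,
    expected_suppression,
    optimize_transmit_sets,
    optimize_transmit_sets_from_streams,
    should_transmit,
)

S1, S2, S3 = (position_by_code(c) for c in ("s1", "s2", "s3"))

#: Published suppression percentages per (main, supports) configuration.
REFERENCE_SUPPRESSION = {
    ("s1", "s2"): 25, ("s1", "s3"): 50, ("s1", "s4"): 25,
    ("s1", "s2 s3"): 63, ("s1", "s2 s4"): 44, ("s1", "s3 s4"): 44,
    ("s1", "s2 s3 s4"): 58,
    ("s2", "s1"): 25, ("s2", "s3"): 25, ("s2", "s4"): 13,
    ("s2", "s1 s3"): 31, ("s2", "s1 s4"): 44, ("s2", "s3 s4"): 38,
    ("s2", "s1 s3 s4"): 58,
    ("s3", "s1"): 38, ("s3", "s2"): 25, ("s3", "s4"): 38,
    ("s3", "s1 s2"): 44, ("s3", "s1 s4"): 50, ("s3", "s2 s4"): 50,
    ("s3", "s1 s2 s4"): 67,
    ("s4", "s1"): 25, ("s4", "s2"): 25, ("s4", "s3"): 25,
    ("s4", "s1 s2"): 50, ("s4", "s1 s3"): 50, ("s4", "s2 s3"): 50,
    ("s4", "s1 s2 s3"): 63,
}


def _result(node, label_idx, weight=0.9):
    weights = np.full(N_CLASSES, (1.0 - weight) / (N_CLASSES - 1))
    weights[label_idx] = weight
    return ClassificationResult(node, 0, activity_by_index(label_idx),
                                weight, weights)


class TestShouldTransmit:
    def test_flagged_class_transmits(self):
        tset = parse_transmit_vector("[1, 0, 0, 0, 1, 1, 1, 0]", node=S3)
        assert should_transmit(_result(S3, 0), tset)  # walking
        assert not should_transmit(_result(S3, 2), tset)  # squats

    def test_all_false_never_transmits(self):
        tset = TransmitSet(S3, (False,) * 8)
        for j in range(8):
            assert not should_transmit(_result(S3, j), tset)

    def test_node_mismatch_rejected(self):
        tset = TransmitSet(S3, (True,) * 8)
        with pytest.raises(ValueError):
            should_transmit(_result(S2, 0), tset)


class TestExpectedSuppression:
    def test_single_support_half_density(self):
        tset = parse_transmit_vector("[1, 0, 0, 0, 1, 1, 1, 0]", node=S3)
        assert expected_suppression([tset]) == 50

    def test_three_supports_ten_flags(self):
        tsets = [
            parse_transmit_vector("[1, 0, 0, 0, 0, 0, 0, 0]", node=S2),
            parse_transmit_vector("[1, 0, 0, 0, 0, 1, 1, 0]", node=S3),
            parse_transmit_vector("[1, 1, 0, 1, 1, 1, 1, 0]",
                                  node=position_by_code("s4")),
        ]
        assert expected_suppression(tsets) == 58

    def test_all_ones_zero_suppression(self):
        assert expected_suppression([TransmitSet(S3, (True,) * 8)]) == 0

    def test_half_up_rounding(self):
        # 10/16 flags off -> 62.5 -> 63
        tsets = [
            parse_transmit_vector("[1, 0, 0, 0, 0, 1, 0, 0]", node=S2),
            parse_transmit_vector("[1, 0, 0, 0, 1, 1, 1, 0]", node=S3),
        ]
        assert expected_suppression(tsets) == 63

    def test_reference_table_reproduced_exactly(self):
        records = load_reference_transmit_sets()
        assert len(records) == len(REFERENCE_SUPPRESSION)
        for r in records:
            key = (r["main"].code, " ".join(p.code for p in r["supports"]))
            assert expected_suppression(r["tsets"]) == REFERENCE_SUPPRESSION[key]


# ---------------------------------------------------------------- toys -----

def _toy_pan(n_supports=1):
    supports = [S2, S3][:n_supports]
    return PANConfig(main_node=S1, support_nodes=supports)


def _streams(main, supports_pred, true, w_main=0.9, w_sup=0.8):
    """Build (labels, weights) streams from plain label lists."""
    streams = {"s1": (np.asarray(main), np.full(len(main), w_main))}
    for code, pred in supports_pred.items():
        streams[code] = (np.asarray(pred), np.full(len(pred), w_sup))
    return streams, np.asarray(true)


class TestGreedyOptimizer:
    def test_useless_support_shrinks_to_empty(self):
        true = [0, 1, 2, 3, 0, 1, 2, 3]
        streams, y = _streams(true, {"s2": [3, 2, 1, 0, 3, 2, 1, 0]}, true)
        trace = optimize_transmit_sets_from_streams(streams, y, _toy_pan(1))
        assert trace.final_sets["s2"].size == 0
        assert trace.final_accuracy == pytest.approx(trace.baseline_accuracy)

    def test_single_needed_class_kept(self):
        """Main errs only on class 1 (calls it 0); the support nails it with
        a higher weight. Only class 1 must stay in the transmit set."""
        true = [0, 1, 2, 3] * 4
        main = [0, 0, 2, 3] * 4
        sup = list(true)
        streams, y = _streams(main, {"s2": sup}, true, w_main=0.6, w_sup=0.9)
        trace = optimize_transmit_sets_from_streams(streams, y, _toy_pan(1))
        assert trace.final_sets["s2"].activities()[0].index == 1
        assert trace.final_sets["s2"].size == 1

    def test_epsilon_zero_with_costly_removals_keeps_full_set(self):
        """Main is always wrong, support always right: removing any class
        strictly costs accuracy, so with epsilon=0 nothing is removed."""
        true = list(range(8)) * 2
        main = [(t + 1) % 8 for t in true]
        streams, y = _streams(main, {"s2": list(true)}, true,
                              w_main=0.5, w_sup=0.9)
        trace = optimize_transmit_sets_from_streams(
            streams, y, _toy_pan(1), OptimizerConfig(epsilon=0.0))
        assert trace.final_sets["s2"].size == 8
        assert trace.accepted_removals == 0

    def test_trace_records_every_attempt_consistently(self):
        true = [0, 1, 2, 3] * 4
        main = [0, 0, 2, 3] * 4
        streams, y = _streams(main, {"s2": list(true)}, true,
                              w_main=0.6, w_sup=0.9)
        trace = optimize_transmit_sets_from_streams(streams, y, _toy_pan(1))
        eps = OptimizerConfig().epsilon
        for step in trace.steps:
            drop = step["accuracy_before"] - step["accuracy_after"]
            assert step["accepted"] == (drop <= eps)
        assert trace.final_accuracy >= (
            trace.baseline_accuracy - eps * trace.accepted_removals - 1e-12)


class TestBruteForceOracle:
    def _random_toy(self, rng, n_supports, n_classes, n_steps=24):
        true = rng.integers(0, n_classes, size=n_steps)
        main = np.where(rng.random(n_steps) < 0.7, true,
                        rng.integers(0, n_classes, size=n_steps))
        supports = {}
        for k in range(n_supports):
            code = ("s2", "s3")[k]
            supports[code] = np.where(rng.random(n_steps) < 0.85, true,
                                      rng.integers(0, n_classes, size=n_steps))
        return main, supports, true

    def test_greedy_respects_oracle_constraint_and_bound(self, rng):
        for trial in range(10):
            n_sup = 1 + trial % 2
            main, sups, true = self._random_toy(rng, n_sup, n_classes=4)
            streams, y = _streams(main, {k: list(v) for k, v in sups.items()},
                                  true, w_main=0.7, w_sup=0.8)
            # epsilon below the accuracy quantum (1/n_steps): accepted
            # removals are exactly cost-free, so the greedy ratchet cannot
            # drift below the oracle's one-shot accuracy constraint
            eps = 0.001
            pan = _toy_pan(n_sup)
            trace = optimize_transmit_sets_from_streams(
                streams, y, pan, OptimizerConfig(epsilon=eps))
            codes = [p.code for p in pan.support_nodes]
            best_sets, _ = brute_force_minimum_sets(
                streams["s1"][0], streams["s1"][1],
                [streams[c][0] for c in codes],
                [streams[c][1] for c in codes],
                y, epsilon=eps, n_classes=4)
            greedy_size = sum(trace.final_sets[c].size for c in codes)
            oracle_size = sum(sum(f) for f in best_sets)
            assert greedy_size >= oracle_size
            # greedy result satisfies the same accuracy constraint
            full_acc = ensemble_accuracy(
                streams["s1"][0], streams["s1"][1],
                [streams[c][0] for c in codes],
                [streams[c][1] for c in codes],
                [(True,) * 8] * n_sup, y)
            greedy_acc = ensemble_accuracy(
                streams["s1"][0], streams["s1"][1],
                [streams[c][0] for c in codes],
                [streams[c][1] for c in codes],
                [trace.final_sets[c].flags for c in codes], y)
            assert full_acc - greedy_acc <= eps + 1e-12

    def test_huge_epsilon_empty_sets_optimal(self, rng):
        main, sups, true = self._random_toy(rng, 1, n_classes=3)
        streams, y = _streams(main, {k: list(v) for k, v in sups.items()}, true)
        best_sets, _ = brute_force_minimum_sets(
            streams["s1"][0], streams["s1"][1], [streams["s2"][0]],
            [streams["s2"][1]], y, epsilon=1.0, n_classes=3)
        assert sum(sum(f) for f in best_sets) == 0

    def test_too_large_instance_rejected(self, rng):
        y = np.zeros(4, dtype=int)
        w = np.ones(4)
        with pytest.raises(ValueError):
            brute_force_minimum_sets(y, w, [y, y, y], [w, w, w], y, 0.1)

    def test_epsilon_monotone_in_final_size(self, rng):
        main, sups, true = self._random_toy(rng, 2, n_classes=4, n_steps=40)
        streams, y = _streams(main, {k: list(v) for k, v in sups.items()},
                              true, w_main=0.7, w_sup=0.8)
        sizes = []
        for eps in (0.0, 0.02, 0.05, 0.2, 1.0):
            trace = optimize_transmit_sets_from_streams(
                streams, y, _toy_pan(2), OptimizerConfig(epsilon=eps))
            sizes.append(sum(t.size for t in trace.final_sets.values()))
        assert sizes == sorted(sizes, reverse=True)


class TestFixtureOptimization:
    def test_trace_invariants_on_desk_fixture(self, desk_models, desk_split, desk_pan):
        train_d, _ = desk_split
        opt = OptimizerConfig()
        trace = optimize_transmit_sets(desk_models, train_d, desk_pan, opt)
        assert trace.accepted_removals > 0
        for step in trace.steps:
            drop = step["accuracy_before"] - step["accuracy_after"]
            assert step["accepted"] == (drop <= opt.epsilon)
        assert trace.final_accuracy >= (
            trace.baseline_accuracy - opt.epsilon * trace.accepted_removals - 1e-12)
        # every final set is a valid length-8 vector for its node
        for p in desk_pan.support_nodes:
            assert len(trace.final_sets[p.code].flags) == 8
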