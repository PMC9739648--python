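"""Time-stepped simulation of the personal area network.

One simulation step is one classification window. Per step every node
classifies its own window; each supporting node applies the transmit rule to
its *own* recognised class (not the ground truth); the main node aggregates
whatever arrived plus its local result with the weighted vote; transmissions
are counted against the supports x steps budget. Node outages can be
injected: a failed support simply does not transmit, and the main node still
produces a decision every step.

An *oracle* classifier mode (predictions equal the true labels with weight
one) is available: under balanced activity shares it reproduces the
combinatorial expected-suppression value exactly, which pins the simulator's
transmission bookkeeping to the closed-form metric.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .domain import (
    N_CLASSES,
    NodePosition,
    PANConfig,
)
from .node_classifier import predict_dataset
from .suppression import OptimizerConfig, optimize_transmit_sets

__all__ = ["FailureScenario", "SimulationTrace", "run", "compare_configurations"]


@dataclass
class FailureScenario:
    """A support outage: the node is silent during [start, stop) step spans."""

    node: NodePosition
    outages: list[tuple[int, int]]

    def down_at(self, step: int) -> bool:
        return any(a <= step < b for a, b in self.outages)


@dataclass
class SimulationTrace:
    steps: list[dict] = field(default_factory=list)
    n_steps: int = 0
    transmissions: int = 0
    possible_transmissions: int = 0
    accuracy: float = 0.0
    latency: bool = False

    @property
    def suppression_pct(self) -> float:
        if self.possible_transmissions == 0:
            return 0.0
        return 100.0 * (1.0 - self.transmissions / self.possible_transmissions)

    def decisions(self) -> np.ndarray:
        return np.array([s["decision"] for s in self.steps], dtype=int)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps)


def _node_streams(models: dict | None, streams: dict, codes: list[str],
                  oracle: bool) -> dict:
    """(labels, top-1 weights) per node; oracle mode echoes the truth."""
    out = {}
    for c in codes:
        true = streams[c].labels()
        if oracle:
            out[c] = (true.copy(), np.ones(len(true)))
        else:
            labels, proba = predict_dataset(models[c], streams[c])
            out[c] = (labels, proba[np.arange(len(labels)), labels])
    return out


def run(
    models: dict | None,
    tsets: dict,
    streams: dict,
    pan: PANConfig,
    failures: list[FailureScenario] | None = None,
    latency: bool = False,
    oracle: bool = False,
) -> SimulationTrace:
    """Simulate the PAN over an aligned window stream.

    ``streams`` maps position codes to step-aligned :class:`WindowedDataset`
    objects (same length, same true-label sequence); ``tsets`` maps each
    support's code to its transmit set. With ``latency=True`` each decision
    is emitted one step after its window, mirroring the main node's
    overlapped collect/process loop; labels are unaffected.
    """
    failures = failures or []
    main_c = pan.main_node.code
    sup_codes = [p.code for p in pan.support_nodes]
    codes = [main_c] + sup_codes
    for c in sup_codes:
        if c not in tsets:
            raise ValueError(f"no transmit set for support {c}")
    lengths = {c: len(streams[c]) for c in codes}
    if len(set(lengths.values())) != 1:
        raise ValueError(f"streams are not aligned: window counts {lengths}")
    true = streams[main_c].labels()
    for c in codes[1:]:
        if not np.array_equal(streams[c].labels(), true):
            raise ValueError(f"streams are not aligned: labels differ for {c}")

    node_pred = _node_streams(models, streams, codes, oracle)
    down = {c: np.zeros(len(true), dtype=bool) for c in sup_codes}
    for f in failures:
        if f.node.code in down:
            for a, b in f.outages:
                down[f.node.code][max(a, 0):b] = True

    n = len(true)
    trace = SimulationTrace(n_steps=n, possible_transmissions=n * len(sup_codes),
                            latency=latency)
    for t in range(n):
        scores = np.zeros(N_CLASSES)
        m_lab, m_w = node_pred[main_c][0][t], node_pred[main_c][1][t]
        scores[m_lab] += m_w
        transmitted = []
        for c in sup_codes:
            lab, w = node_pred[c][0][t], node_pred[c][1][t]
            if not down[c][t] and tsets[c].flags[lab]:
                scores[lab] += w
                transmitted.append(c)
        trace.transmissions += len(transmitted)
        best = scores.max()
        tied = np.flatnonzero(scores >= best - 1e-12)
        winner = int(tied[0])
        if len(tied) > 1 and m_lab in tied:
            winner = int(m_lab)
        trace.steps.append({
            "step": t,
            "emitted_at": t + 1 if latency else t,
            "true": int(true[t]),
            "main_label": int(m_lab),
            "main_weight": float(m_w),
            **{f"{c}_label": int(node_pred[c][0][t]) for c in sup_codes},
            "transmitted": ",".join(transmitted),
            "decision": winner,
        })
    trace.accuracy = float((trace.decisions() == true).mean())
    return trace


def compare_configurations(
    models: dict,
    train_sets: dict,
    test_sets: dict,
    opt: OptimizerConfig | None = None,
    mains: list[NodePosition] | None = None,
    include_single_node: bool = False,
) -> pd.DataFrame:
    """Sweep candidate main nodes against every non-empty support subset.

    For each (main, supports) configuration: minimise the transmit sets on
    the training stream, simulate on the test stream, and report accuracy
    and suppression. Four candidate mains over the three remaining positions
    give 4 x 7 = 28 multi-node rows; ``include_single_node`` prepends the
    four single-node rows.
    """
    from .domain import position_by_code

    opt = opt or OptimizerConfig()
    all_codes = sorted(train_sets)
    positions = [position_by_code(c) for c in all_codes]
    mains = mains or positions
    rows = []
    if include_single_node:
        for main in mains:
            pan = PANConfig(main_node=main, support_nodes=[],
                            window_size=train_sets[main.code].config.window_size,
                            sample_rate=train_sets[main.code].config.sample_rate)
            trace = run(models, {}, {main.code: test_sets[main.code]}, pan)
            rows.append({"main": main.code, "supports": "-",
                         "accuracy_pct": round(100.0 * trace.accuracy, 2),
                         "suppression_pct": float("nan")})
    for main in mains:
        others = [p for p in positions if p != main]
        for r in (1, 2, 3):
            for subset in combinations(others, r):
                pan = PANConfig(
                    main_node=main, support_nodes=list(subset),
                    window_size=train_sets[main.code].config.window_size,
                    sample_rate=train_sets[main.code].config.sample_rate)
                trace_opt = optimize_transmit_sets(models, train_sets, pan, opt)
                sim = run(models, trace_opt.final_sets,
                          {c: test_sets[c] for c in [main.code] + [p.code for p in subset]},
                          pan)
                rows.append({
                    "main": main.code,
                    "supports": " ".join(p.code for p in subset),
                    "accuracy_pct": round(100.0 * sim.accuracy, 2),
                    "suppression_pct": round(sim.suppression_pct, 2),
                })
    return pd.DataFrame(rows)
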