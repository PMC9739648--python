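"""Weighted-vote aggregation on the main node.

Each node contributes its top-1 (class, weight) pair; the ensemble decision
is the class with the largest summed weight over the contributing nodes,

    d_t = argmax_j  sum_{i : d_{i,t} = j}  w(d_{i,t}),

with the main node treated exactly like a support. Ties go to the lowest
class index; if the main node's own label is among the tied leaders it wins.

The main node overlaps collection and processing: while it collects support
reports for step t it finalises the decision for step t-1, so in streaming
mode the decision for step t is emitted one step late. ``decide_stream``
models both that delayed emission and an aligned offline mode.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np

from .domain import (
    ActivityLabel,
    ClassificationResult,
    N_CLASSES,
    NodePosition,
    activity_by_index,
)

__all__ = ["VoteInput", "EnsembleDecision", "vote", "decide_stream"]


@dataclass
class VoteInput:
    """All local results available to the main node for one step.

    The main node's own result is always present; supports appear only if
    they transmitted. ``main`` identifies which result is the main node's.
    """

    step: int
    results: list[ClassificationResult]
    main: NodePosition | None = None

    def __post_init__(self) -> None:
        if not self.results:
            raise ValueError("a vote needs at least one result")
        codes = [r.node.code for r in self.results]
        if len(set(codes)) != len(codes):
            dup = sorted({c for c in codes if codes.count(c) > 1})
            raise ValueError(f"duplicate node(s) in vote input: {dup}")


@dataclass
class EnsembleDecision:
    step: int
    label: ActivityLabel
    per_class_score: np.ndarray
    contributors: list[NodePosition] = field(default_factory=list)


def vote(inp: VoteInput) -> EnsembleDecision:
    """Aggregate one step's results into the ensemble decision."""
    scores = np.zeros(N_CLASSES)
    for r in inp.results:
        scores[r.label.index] += r.weight
    best = float(scores.max())
    tied = np.flatnonzero(scores >= best - 1e-12)
    winner = int(tied[0])  # lowest class index among the tied
    if inp.main is not None and len(tied) > 1:
        for r in inp.results:
            if r.node == inp.main and r.label.index in tied:
                winner = r.label.index
                break
    return EnsembleDecision(
        step=inp.step,
        label=activity_by_index(winner),
        per_class_score=scores,
        contributors=[r.node for r in inp.results],
    )


def decide_stream(inputs: Iterable[VoteInput], latency: bool = True) -> Iterator[tuple[int, EnsembleDecision]]:
    """Decide a time-ordered stream of vote inputs.

    Yields ``(emission_step, decision)`` pairs. With ``latency=True`` the
    decision about step t is emitted at step t+1 (the final one on stream
    flush); with ``latency=False`` decisions are emitted at their own step.
    The decisions themselves are identical either way.
    """
    prev_step = None
    pending: EnsembleDecision | None = None
    for inp in inputs:
        if prev_step is not None and inp.step <= prev_step:
            raise ValueError("steps must be strictly increasing")
        prev_step = inp.step
        decision = vote(inp)
        if latency:
            if pending is not None:
                yield inp.step, pending
            pending = decision
        else:
            yield inp.step, decision
    if latency and pending is not None:
        yield pending.step + 1, pending
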