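"""Shared vocabulary for the personal-area-network activity recognizer.

A PAN here is a star network of body-worn inertial sensor nodes: one *main*
node (a smartphone acting as cluster head) and up to three *supporting*
nodes. Every node classifies its own accelerometer/gyroscope stream into one
of eight activities; supports report their result to the main node only for
activities in their *transmit set*.

This module defines the fixed activity vocabulary, the four canonical mount
positions, the per-step classification result, and the transmit-set vector,
plus parsing/serialisation for the bracketed 0/1 vector notation used in the
packaged reference tables.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
import numpy as np

__all__ = [
    "N_CLASSES",
    "ActivityLabel",
    "NodePosition",
    "PANConfig",
    "ClassificationResult",
    "TransmitSet",
    "canonical_activity_order",
    "activity_by_name",
    "activity_by_index",
    "position_by_code",
    "all_positions",
    "parse_transmit_vector",
    "serialize_transmit_vector",
    "load_reference_transmit_sets",
]

N_CLASSES = 8

#: Canonical activity names, in the fixed vocabulary order. Index 0..7.
_ACTIVITY_NAMES = (
    "walking",
    "jogging",
    "squats",
    "jump",
    "lying",
    "arms_swing",
    "sitting",
    "standing",
)

#: Dynamic activities involve gross body motion; the rest are static postures.
DYNAMIC_ACTIVITIES = ("walking", "jogging", "squats", "jump", "arms_swing")
STATIC_ACTIVITIES = ("lying", "sitting", "standing")

_POSITION_CODES = {"s1": "waist", "s2": "chest", "s3": "leg", "s4": "arm"}


@dataclass(frozen=True, order=True)
class ActivityLabel:
    """One of the eight recognised activity classes.

    ``index`` is the zero-based position in the canonical order; display
    to users may add 1 where a 1-based numbering is conventional.
    """

    index: int
    name: str

    def __post_init__(self) -> None:
        if not 0 <= self.index < N_CLASSES:
            raise ValueError(f"activity index {self.index} outside 0..{N_CLASSES - 1}")
        if _ACTIVITY_NAMES[self.index] != self.name:
            raise ValueError(
                f"activity {self.name!r} does not sit at canonical index {self.index}"
            )


@dataclass(frozen=True, order=True)
class NodePosition:
    """A body mount position: s1=waist, s2=chest, s3=leg, s4=arm."""

    code: str
    placement: str

    def __post_init__(self) -> None:
        if _POSITION_CODES.get(self.code) != self.placement:
            raise ValueError(f"unknown position {self.code!r}/{self.placement!r}")


_ACTIVITIES = tuple(ActivityLabel(i, n) for i, n in enumerate(_ACTIVITY_NAMES))
_POSITIONS = tuple(NodePosition(c, p) for c, p in _POSITION_CODES.items())
_BY_NAME = {a.name: a for a in _ACTIVITIES}
_BY_CODE = {p.code: p for p in _POSITIONS}


def canonical_activity_order() -> list[ActivityLabel]:
    """Return the 8 activity labels in the fixed canonical order.

    The order (walking, jogging, squats, jump, lying, arms_swing, sitting,
    standing) also fixes the meaning of position ``j`` in every length-8
    transmit-set vector.
    """
    return list(_ACTIVITIES)


def activity_by_name(name: str) -> ActivityLabel:
    try:
        return _BY_NAME[name]
    except KeyError:
        raise KeyError(f"unknown activity {name!r}; expected one of {_ACTIVITY_NAMES}")


def activity_by_index(index: int) -> ActivityLabel:
    return _ACTIVITIES[index]


def position_by_code(code: str) -> NodePosition:
    try:
        return _BY_CODE[code]
    except KeyError:
        raise KeyError(f"unknown position {code!r}; expected one of {tuple(_POSITION_CODES)}")


def all_positions() -> list[NodePosition]:
    """The four mount positions in code order s1..s4."""
    return list(_POSITIONS)


@dataclass
class PANConfig:
    """Static description of one PAN deployment.

    Parameters
    ----------
    main_node
        The cluster head; always classifies locally and aggregates votes.
    support_nodes
        Ordered supporting nodes (the order fixes the optimiser's node scan).
    step_duration
        Seconds covered by one decision step (one classification window).
    sample_rate
        Post-resampling rate F in Hz; the study sweeps 5, 10 and 20.
    window_size
        Samples per classification window WS; the study sweeps 64, 128, 196.
    """

    main_node: NodePosition
    support_nodes: list[NodePosition] = field(default_factory=list)
    step_duration: float = 3.2
    sample_rate: float = 20.0
    window_size: int = 64

    def __post_init__(self) -> None:
        if self.main_node in self.support_nodes:
            raise ValueError("main node cannot also be a support node")
        if len(set(p.code for p in self.support_nodes)) != len(self.support_nodes):
            raise ValueError("duplicate support node")
        if not 1 <= self.n_nodes <= 4:
            raise ValueError("a PAN has between 1 and 4 nodes")
        if self.window_size < 2:
            raise ValueError("window_size must be >= 2")

    @property
    def n_nodes(self) -> int:
        return 1 + len(self.support_nodes)


@dataclass
class ClassificationResult:
    """One node's local decision at one time step.

    ``weights`` is the full softmax vector over the 8 classes; ``weight`` is
    the winning class's entry and is the node's vote mass in the ensemble.
    """

    node: NodePosition
    step: int
    label: ActivityLabel
    weight: float
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (N_CLASSES,):
            raise ValueError("weights must have length 8")
        if abs(float(self.weights.sum()) - 1.0) > 1e-6:
            raise ValueError("weights must sum to 1")
        if abs(self.weight - float(self.weights[self.label.index])) > 1e-9:
            raise ValueError("weight must equal weights[label.index]")
        if self.weight < float(self.weights.max()) - 1e-9:
            raise ValueError("label must be an argmax of weights")


@dataclass(frozen=True)
class TransmitSet:
    """The activity subset for which one supporting node must report.

    ``flags[j]`` is True iff activity ``j`` (canonical order) triggers a
    transmission when locally recognised.
    """

    node: NodePosition
    flags: tuple[bool, ...]

    def __post_init__(self) -> None:
        if len(self.flags) != N_CLASSES:
            raise ValueError("transmit-set vector must have length 8")
        object.__setattr__(self, "flags", tuple(bool(f) for f in self.flags))

    @property
    def size(self) -> int:
        return sum(self.flags)

    def without(self, index: int) -> "TransmitSet":
        flags = list(self.flags)
        flags[index] = False
        return TransmitSet(self.node, tuple(flags))

    def activities(self) -> list[ActivityLabel]:
        return [a for a in _ACTIVITIES if self.flags[a.index]]


_TOKEN_RE = re.compile(r"\s*,\s*")


def parse_transmit_vector(text: str, node: NodePosition | None = None) -> TransmitSet:
    """Parse a bracketed 0/1 vector like ``[1, 0, 0, 0, 1, 1, 1, 0]``.

    Raises ``ValueError`` naming the offending token on non-binary entries
    and on a wrong-length vector.
    """
    body = text.strip()
    if body.startswith("[") and body.endswith("]"):
        body = body[1:-1]
    tokens = [t.strip() for t in _TOKEN_RE.split(body.strip()) if t.strip() != ""]
    if len(tokens) != N_CLASSES:
        raise ValueError(
            f"transmit vector {text!r} has {len(tokens)} entries, expected {N_CLASSES}"
        )
    flags = []
    for tok in tokens:
        if tok not in ("0", "1"):
            raise ValueError(f"transmit vector {text!r}: token {tok!r} is not 0 or 1")
        flags.append(tok == "1")
    return TransmitSet(node or _POSITIONS[0], tuple(flags))


def serialize_transmit_vector(tset: TransmitSet) -> str:
    """Canonical bracketed form, inverse of :func:`parse_transmit_vector`."""
    return "[" + ", ".join("1" if f else "0" for f in tset.flags) + "]"


def load_reference_transmit_sets() -> list[dict]:
    """Load the packaged reference transmit-set table.

    Returns one record per network configuration:
    ``{"main": NodePosition, "supports": [NodePosition...],
    "tsets": [TransmitSet...]}`` with one transmit set per support, in the
    supports' listed order.
    """
    path = resources.files("pansense").joinpath("data/transmit_sets.txt")
    records = []
    for raw in path.read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        main_code, supports_field, vectors_field = line.split(",", 2)
        main = position_by_code(main_code.strip())
        supports = [position_by_code(c) for c in supports_field.split()]
        vectors = [v for v in vectors_field.split(";") if v.strip()]
        if len(vectors) != len(supports):
            raise ValueError(f"row {line!r}: {len(supports)} supports but {len(vectors)} vectors")
        tsets = [parse_transmit_vector(v, node=s) for s, v in zip(supports, vectors)]
        records.append({"main": main, "supports": supports, "tsets": tsets})
    return records
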