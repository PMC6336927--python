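"""Sensorimotor object recognition with hypothesis elimination and voting.

A column cannot identify an object from one ambiguous sensation, so it keeps
a *candidate set* — every (object, location) pose whose stored feature
matches what was sensed — and narrows it with movement: integrate each
hypothesis's location by the efference copy, sense again, and discard the
hypotheses whose model predicts something else.  Multiple columns touching
the same object at different places each maintain their own candidates;
lateral connections let them vote by intersecting their object-identity
sets, which typically collapses recognition to a single sensation even when
each column alone would need several.

Hypotheses are enumerated explicitly (one pose per stored key matching the
sensed feature) rather than superimposed in a sparse distributed code — an
exact, transparent stand-in for the same union-and-narrow computation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np

from .location_codes import (
    LocationCode,
    ModuleSet,
    bin_center_phase,
    discretize,
    integrate,
)
from .object_models import NONE_FEATURE, ObjectLibrary, feature_at

__all__ = [
    "UNDECIDED",
    "Hypothesis",
    "CandidateSet",
    "Column",
    "ColumnNetwork",
    "VoteResult",
    "init_from_feature",
    "step",
    "recognized",
    "vote",
    "sensations_to_recognition",
]

UNDECIDED = "undecided"
FAILED = "failed"


@dataclass(frozen=True)
class Hypothesis:
    """One candidate pose: an object and a location in that object's frame."""

    object_id: str
    loc: LocationCode

    def __post_init__(self) -> None:
        if self.loc.frame != self.object_id:
            raise ValueError("hypothesis location must be anchored to its object")


@dataclass
class CandidateSet:
    hypotheses: list[Hypothesis] = field(default_factory=list)

    def object_ids(self) -> set[str]:
        return {h.object_id for h in self.hypotheses}

    def __len__(self) -> int:
        return len(self.hypotheses)


def _dedupe(hyps: list[Hypothesis], ms: ModuleSet) -> list[Hypothesis]:
    """Enforce the invariant that no two hypotheses share (object, key)."""
    seen: set[tuple] = set()
    out: list[Hypothesis] = []
    for h in hyps:
        ident = (h.object_id, discretize(h.loc, ms).cells)
        if ident not in seen:
            seen.add(ident)
            out.append(h)
    return out


@dataclass
class Column:
    """One cortical column: its modules, its object library, its current
    candidate set, and its feature-mismatch policy.

    ``strict`` mode eliminates hypotheses whose model predicts no feature at
    a location where one was sensed (appropriate when learning traces covered
    the object); ``lenient`` keeps them.
    """

    ms: ModuleSet
    lib: ObjectLibrary
    state: CandidateSet = field(default_factory=CandidateSet)
    mode: str = "strict"
    depth_limit: int = 5

    def __post_init__(self) -> None:
        if self.mode not in ("strict", "lenient"):
            raise ValueError("mode must be 'strict' or 'lenient'")


def init_from_feature(col: Column, feature: str) -> CandidateSet:
    """Seed hypotheses from a first sensation: one pose per stored location
    whose feature matches, placed at the key's bin centres.  An empty result
    is legal and means the feature is unknown to this column."""
    hyps: list[Hypothesis] = []
    for oid, model in col.lib.objects.items():
        for key, feat in model.feature_map.items():
            if feat == feature:
                loc = LocationCode(
                    phases=tuple(
                        bin_center_phase(c, m) for c, m in zip(key.cells, col.ms)
                    ),
                    frame=oid,
                )
                hyps.append(Hypothesis(object_id=oid, loc=loc))
    col.state = CandidateSet(_dedupe(hyps, col.ms))
    return col.state


def step(col: Column, movement, sensed: str) -> CandidateSet:
    """Move, then sense: integrate every hypothesis by the movement and drop
    those whose model disagrees with the sensed feature.

    Sensing ``"none"`` updates poses but eliminates nothing (featureless
    locations are uninformative under either mode).
    """
    moved = [
        Hypothesis(h.object_id, integrate(h.loc, col.ms, movement))
        for h in col.state.hypotheses
    ]
    if sensed != NONE_FEATURE:
        kept = []
        for h in moved:
            predicted = feature_at(col.lib, h.object_id, h.loc, col.ms, col.depth_limit)
            if predicted == sensed:
                kept.append(h)
            elif predicted == NONE_FEATURE and col.mode == "lenient":
                kept.append(h)
        moved = kept
    col.state = CandidateSet(_dedupe(moved, col.ms))
    return col.state


def recognized(col: Column) -> str:
    """The unique object all hypotheses agree on, else ``"undecided"``."""
    ids = col.state.object_ids()
    if len(ids) == 1:
        return next(iter(ids))
    return UNDECIDED


@dataclass
class ColumnNetwork:
    """Columns observing one object at different sensor offsets, joined by
    lateral voting connections."""

    columns: list[Column]

    def __post_init__(self) -> None:
        if len(self.columns) < 1:
            raise ValueError("a network needs at least one column")


class VoteResult(NamedTuple):
    intersection: set[str]
    disagreement: bool


def vote(net: ColumnNetwork) -> VoteResult:
    """Lateral consensus: intersect the columns' candidate object sets and
    prune every column to the intersection.

    Columns with empty state abstain.  An empty intersection is flagged as
    disagreement and nothing is pruned (the conflict is surfaced, not hidden).
    """
    voting = [c for c in net.columns if len(c.state) > 0]
    if not voting:
        return VoteResult(set(), False)
    inter = set.intersection(*(c.state.object_ids() for c in voting))
    if not inter:
        return VoteResult(set(), True)
    for c in voting:
        c.state = CandidateSet([h for h in c.state.hypotheses if h.object_id in inter])
    return VoteResult(inter, False)


def sensations_to_recognition(
    net: ColumnNetwork,
    target_id: str,
    placements: dict[tuple[int, int], str],
    rng: np.random.Generator,
    sensor_points: Sequence[tuple[int, int]] | None = None,
    policy: str = "random",
    max_sensations: int = 50,
) -> int | str:
    """Simulate sensing the target object until every column recognises it.

    ``placements`` is the ground truth of the sensed object: feature label at
    each world point (relative to the object's origin).  Each column starts
    at its own sensor point and thereafter visits feature points according to
    the policy (``"random"``: an independent random walk over the feature
    points; ``"sweep"``: sorted order).  After every sensation the columns
    vote; the return value is the 1-based index of the sensation at which
    every column reports the target, or ``"failed"`` after ``max_sensations``.
    """
    if target_id not in net.columns[0].lib:
        raise KeyError(f"target {target_id!r} not in library")
    points = sorted(placements)
    if not points:
        raise ValueError("target object has no features to sense")
    if sensor_points is None:
        current = [points[int(rng.integers(len(points)))] for _ in net.columns]
    else:
        current = [tuple(p) for p in sensor_points]

    for t in range(1, max_sensations + 1):
        for i, col in enumerate(net.columns):
            sensed = placements.get(current[i], NONE_FEATURE)
            if t == 1:
                init_from_feature(col, sensed)
            else:
                movement = (
                    current[i][0] - previous[i][0],
                    current[i][1] - previous[i][1],
                )
                step(col, movement, sensed)
        vote(net)
        if all(recognized(c) == target_id for c in net.columns):
            return t
        previous = list(current)
        if policy == "sweep":
            current = [points[(points.index(p) + 1) % len(points)] for p in current]
        else:
            current = [
                points[int(rng.integers(len(points)))] for _ in net.columns
            ]
    return FAILED
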