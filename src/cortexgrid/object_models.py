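"""Objects as location -> feature maps, with composition via displacements.

A cortical column learns an object as a set of locations unique to that
object, some of which carry an observable feature.  Learning couples sensed
features with path-integrated locations: start from a random anchor (the
phases chosen for the object's origin), move, and store the discretised
location of each sensed feature.

Composition: a parent object may contain child objects, each placed by a
single displacement code that converts any point in parent space to the
equivalent point in child space.  Because the placement carries the whole
child model with it, the parent predicts every child feature without
relearning them, and recursion (a logo containing a picture of the cup that
bears it) is legal — resolution is bounded only by a depth limit.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np

from .displacement import DisplacementCode, apply_displacement, displacement_between
from .grid_modules import Phase
from .location_codes import (
    CodeKey,
    LocationCode,
    ModuleSet,
    discretize,
    integrate,
    random_code,
)

if TYPE_CHECKING:  # pragma: no cover
    from .behaviors import BehaviorSequence

__all__ = [
    "NONE_FEATURE",
    "ExplorationTrace",
    "Component",
    "ObjectModel",
    "ObjectLibrary",
    "FeatureConflictError",
    "learn_object",
    "add_component",
    "placement_from_world_offset",
    "feature_at",
    "library_to_json",
    "library_from_json",
    "trace_to_csv",
    "trace_from_csv",
]

#: Sentinel feature for locations that can be moved to but carry no feature.
NONE_FEATURE = "none"


class FeatureConflictError(ValueError):
    """Two different features were written to the same discretised location."""

    def __init__(self, key: CodeKey, existing: str, new: str):
        self.key = key
        super().__init__(
            f"location key {tuple(tuple(c) for c in key.cells)} already holds "
            f"feature {existing!r}; refusing to overwrite with {new!r}"
        )


@dataclass(frozen=True)
class ExplorationTrace:
    """A sensor's path over an object: a start offset (world point relative to
    the object's anchor) and ordered (movement, feature) steps."""

    steps: tuple[tuple[tuple[float, float], str], ...]
    start_offset: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.steps) < 1:
            raise ValueError("a trace needs at least one step")
        for (dx, dy), feat in self.steps:
            if not (np.isfinite(dx) and np.isfinite(dy)):
                raise ValueError("trace movements must be finite")
            if not feat:
                raise ValueError("feature labels must be non-empty (use 'none')")


@dataclass
class Component:
    """A child object placed inside a parent by one displacement code."""

    child_id: str
    placement: DisplacementCode


@dataclass
class ObjectModel:
    id: str
    anchor: LocationCode
    feature_map: dict[CodeKey, str] = field(default_factory=dict)
    components: list[Component] = field(default_factory=list)
    behaviors: "dict[str, BehaviorSequence]" = field(default_factory=dict)


@dataclass
class ObjectLibrary:
    """All object models known to one cortical column."""

    objects: dict[str, ObjectModel] = field(default_factory=dict)

    def __contains__(self, object_id: str) -> bool:
        return object_id in self.objects

    def __getitem__(self, object_id: str) -> ObjectModel:
        try:
            return self.objects[object_id]
        except KeyError:
            raise KeyError(f"unknown object {object_id!r}") from None


def learn_object(
    lib: ObjectLibrary,
    object_id: str,
    trace: ExplorationTrace,
    ms: ModuleSet,
    rng: np.random.Generator,
    *,
    force: bool = False,
) -> ObjectModel:
    """Learn an object from an exploration trace.

    Draws a uniform-random anchor (the object's frame origin), path-integrates
    along the trace, and stores ``discretize(location) -> feature`` for every
    step that senses a feature.  Revisiting a location with the same feature
    is idempotent; a different feature raises :class:`FeatureConflictError`
    (pass ``force=True`` to overwrite in noisy experiments).
    """
    if object_id in lib:
        raise ValueError(f"object {object_id!r} already in library")
    anchor = random_code(ms, rng, frame=object_id)
    model = ObjectModel(id=object_id, anchor=anchor)
    current = integrate(anchor, ms, trace.start_offset)
    for movement, feature in trace.steps:
        current = integrate(current, ms, movement)
        if feature != NONE_FEATURE:
            key = discretize(current, ms)
            existing = model.feature_map.get(key)
            if existing is not None and existing != feature and not force:
                raise FeatureConflictError(key, existing, feature)
            model.feature_map[key] = feature
    lib.objects[object_id] = model
    return model


def add_component(
    lib: ObjectLibrary, parent_id: str, child_id: str, placement: DisplacementCode
) -> None:
    """Place a learned child object inside a parent at the given displacement.

    The same child may be added more than once (an object can contain two
    copies), and cycles are allowed — recursive structure is resolved under a
    depth limit at query time.
    """
    parent = lib[parent_id]
    lib[child_id]  # existence check
    if placement.frame_from != parent_id or placement.frame_to != child_id:
        raise ValueError(
            f"placement frames {(placement.frame_from, placement.frame_to)!r} "
            f"do not match ({parent_id!r}, {child_id!r})"
        )
    parent.components.append(Component(child_id=child_id, placement=placement))


def placement_from_world_offset(
    lib: ObjectLibrary, parent_id: str, child_id: str, offset, ms: ModuleSet
) -> DisplacementCode:
    """Displacement that places the child's origin at a world offset from the
    parent's origin: child_anchor - (parent_anchor + offset), per module."""
    parent, child = lib[parent_id], lib[child_id]
    return displacement_between(integrate(parent.anchor, ms, offset), child.anchor, ms)


def feature_at(
    lib: ObjectLibrary,
    object_id: str,
    loc: LocationCode,
    ms: ModuleSet,
    depth_limit: int = 5,
) -> str:
    """Resolve the feature at a location, looking through composite structure.

    The object's own feature map shadows its components (direct observations
    are direct evidence); components are tried in insertion order, each by
    translating the query into the child's frame via the stored placement.
    The first feature found wins; ``"none"`` if nothing is found before the
    recursion depth is exhausted.
    """
    if depth_limit < 0:
        raise ValueError("depth_limit must be >= 0")
    model = lib[object_id]
    if loc.frame != object_id:
        raise ValueError(f"location is anchored to {loc.frame!r}, not {object_id!r}")
    own = model.feature_map.get(discretize(loc, ms))
    if own is not None:
        return own
    if depth_limit == 0:
        return NONE_FEATURE
    for comp in model.components:
        child_loc = apply_displacement(loc, comp.placement, ms)
        found = feature_at(lib, comp.child_id, child_loc, ms, depth_limit - 1)
        if found != NONE_FEATURE:
            return found
    return NONE_FEATURE


# --------------------------------------------------------------------------
# serialization
# --------------------------------------------------------------------------

def _phases_to_list(phases) -> list[list[float]]:
    return [[p.a, p.b] for p in phases]


def _phases_from_list(data) -> tuple[Phase, ...]:
    return tuple(Phase(a, b) for a, b in data)


def _key_to_list(key) -> list[list[int]]:
    return [[int(c.a), int(c.b)] for c in key.cells]


def library_to_json(lib: ObjectLibrary, ms: ModuleSet) -> str:
    """Serialise a library (with its module set) to deterministic JSON:
    sorted dictionary keys, sorted feature entries, list orders preserved.
    Writing, reading back, and writing again is byte-identical."""
    objects: dict[str, dict] = {}
    for oid in sorted(lib.objects):
        model = lib.objects[oid]
        features = sorted(
            ({"key": _key_to_list(k), "feature": v} for k, v in model.feature_map.items()),
            key=lambda e: e["key"],
        )
        components = [
            {
                "child": c.child_id,
                "delta": _phases_to_list(c.placement.deltas),
            }
            for c in model.components
        ]
        behaviors = [
            {
                "id": bid,
                "steps": [_key_to_list(step) for step in model.behaviors[bid].steps],
            }
            for bid in sorted(model.behaviors)
        ]
        objects[oid] = {
            "anchor": _phases_to_list(model.anchor.phases),
            "features": features,
            "components": components,
            "behaviors": behaviors,
        }
    doc = {"module_set": ms.to_config(), "objects": objects}
    return json.dumps(doc, indent=2, sort_keys=True) + "\n"


def library_from_json(text: str) -> tuple[ObjectLibrary, ModuleSet]:
    from .behaviors import BehaviorSequence
    from .displacement import DisplacementKey

    doc = json.loads(text)
    ms = ModuleSet.from_config(doc["module_set"])
    lib = ObjectLibrary()
    for oid, entry in doc["objects"].items():
        model = ObjectModel(
            id=oid,
            anchor=LocationCode(phases=_phases_from_list(entry["anchor"]), frame=oid),
        )
        for feat in entry["features"]:
            model.feature_map[CodeKey(tuple(tuple(c) for c in feat["key"]))] = feat["feature"]
        for comp in entry["components"]:
            model.components.append(
                Component(
                    child_id=comp["child"],
                    placement=DisplacementCode(
                        deltas=_phases_from_list(comp["delta"]),
                        frame_from=oid,
                        frame_to=comp["child"],
                    ),
                )
            )
        for beh in entry["behaviors"]:
            model.behaviors[beh["id"]] = BehaviorSequence(
                id=beh["id"],
                steps=tuple(
                    DisplacementKey(tuple(tuple(c) for c in step)) for step in beh["steps"]
                ),
            )
        lib.objects[oid] = model
    return lib, ms


def trace_to_csv(trace: ExplorationTrace, path) -> None:
    """Write a trace as CSV with columns step, dx, dy, feature.

    Only the steps are written; traces exchanged through CSV use the
    convention start_offset = (0, 0), with the first movement reaching the
    first sensed point.
    """
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["step", "dx", "dy", "feature"])
        for i, ((dx, dy), feature) in enumerate(trace.steps):
            writer.writerow([i, dx, dy, feature])


def trace_from_csv(path) -> ExplorationTrace:
    with open(path, newline="") as fh:
        rows = list(csv.DictReader(fh))
    steps = tuple(
        ((float(r["dx"]), float(r["dy"])), r["feature"]) for r in rows
    )
    return ExplorationTrace(steps=steps)
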