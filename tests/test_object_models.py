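"""Object models: learning location->feature maps from traces, composition
via displacement placements, recursive resolution, and serialization."""

import math

import numpy as np
import pytest

from cortexgrid import (
    CodeKey,
    ExplorationTrace,
    FeatureConflictError,
    LocationCode,
    ModuleParams,
    ModuleSet,
    ObjectLibrary,
    ObjectModel,
    Phase,
    add_component,
    discretize,
    displacement_between,
    feature_at,
    integrate,
    learn_object,
    library_from_json,
    library_to_json,
    placement_from_world_offset,
    random_code,
    trace_from_csv,
    trace_to_csv,
)
from cortexgrid.object_models import Component

# hand-oracle module set: axis-aligned, scales 2 and 3
MS = ModuleSet(
    (ModuleParams(scale=2.0, bins=(4, 4)), ModuleParams(scale=3.0, bins=(3, 3)))
)
SPECS = [(2.0, 4), (3.0, 3)]  # (scale, bins) per module, both axes


def hand_phase(anchor, scale, point):
    """Independent phase arithmetic: anchor plus point/scale, mod 1."""
    return ((anchor[0] + point[0] / scale) % 1.0, (anchor[1] + point[1] / scale) % 1.0)


def hand_key(anchors, point):
    cells = []
    for (scale, nbins), anc in zip(SPECS, anchors):
        pa, pb = hand_phase(anc, scale, point)
        ca = int(math.floor(pa * nbins + 1e-9)) % nbins
        cb = int(math.floor(pb * nbins + 1e-9)) % nbins
        cells.append((ca, cb))
    return CodeKey(tuple(cells))


def make_model(object_id, anchors, features):
    """Build an ObjectModel directly from hand-chosen anchors and integer
    feature points."""
    model = ObjectModel(
        id=object_id,
        anchor=LocationCode(
            phases=tuple(Phase(*a) for a in anchors), frame=object_id
        ),
    )
    for point, label in features.items():
        model.feature_map[hand_key(anchors, point)] = label
    return model


class TestLearnObject:
    def test_all_none_trace_gives_empty_map(self, ms_int, rng):
        lib = ObjectLibrary()
        trace = ExplorationTrace(steps=(((1, 0), "none"), ((0, 1), "none")))
        model = learn_object(lib, "blank", trace, ms_int, rng)
        assert model.feature_map == {}

    def test_storage_round_trip(self, ms_int, rng):
        lib = ObjectLibrary()
        trace = ExplorationTrace(
            steps=(((1, 0), "f1"), ((0, 2), "f2"), ((2, 1), "f3"))
        )
        model = learn_object(lib, "obj", trace, ms_int, rng)
        assert len(model.feature_map) == 3
        loc = integrate(model.anchor, ms_int, (1, 0))
        assert feature_at(lib, "obj", loc, ms_int) == "f1"
        loc = integrate(loc, ms_int, (0, 2))
        assert feature_at(lib, "obj", loc, ms_int) == "f2"
        loc = integrate(loc, ms_int, (2, 1))
        assert feature_at(lib, "obj", loc, ms_int) == "f3"

    def test_revisit_same_feature_idempotent(self, ms_int, rng):
        lib = ObjectLibrary()
        trace = ExplorationTrace(
            steps=(((1, 1), "f1"), ((2, 0), "f2"), ((-2, 0), "f1"))
        )
        model = learn_object(lib, "obj", trace, ms_int, rng)
        assert len(model.feature_map) == 2

    def test_conflicting_feature_raises_naming_key(self, ms_int, rng):
        lib = ObjectLibrary()
        trace = ExplorationTrace(
            steps=(((1, 1), "f1"), ((2, 0), "f2"), ((-2, 0), "DIFFERENT"))
        )
        with pytest.raises(FeatureConflictError, match="f1"):
            learn_object(lib, "obj", trace, ms_int, rng)

    def test_force_overwrites(self, ms_int, rng):
        lib = ObjectLibrary()
        trace = ExplorationTrace(steps=(((1, 1), "f1"), ((0, 0), "f2")))
        model = learn_object(lib, "obj", trace, ms_int, rng, force=True)
        assert list(model.feature_map.values()) == ["f2"]

    def test_duplicate_id_rejected(self, ms_int, rng):
        lib = ObjectLibrary()
        trace = ExplorationTrace(steps=(((1, 0), "f1"),))
        learn_object(lib, "obj", trace, ms_int, rng)
        with pytest.raises(ValueError, match="already"):
            learn_object(lib, "obj", trace, ms_int, rng)

    def test_frame_consistency_across_start_offsets(self, ms_int):
        """Learning the same physical object from a different starting point
        stores the same feature at every co-located world point."""
        placements = {(1, 1): "a", (4, 2): "b", (0, 3): "c"}
        lib = ObjectLibrary()

        def trace_from(start):
            steps, prev = [], start
            for p in sorted(placements):
                steps.append(
                    ((float(p[0] - prev[0]), float(p[1] - prev[1])), placements[p])
                )
                prev = p
            return ExplorationTrace(steps=tuple(steps), start_offset=tuple(map(float, start)))

        learn_object(lib, "m1", trace_from((0, 0)), ms_int, np.random.default_rng(1))
        learn_object(lib, "m2", trace_from((3, 2)), ms_int, np.random.default_rng(2))
        for p, label in placements.items():
            loc1 = integrate(lib["m1"].anchor, ms_int, p)
            loc2 = integrate(lib["m2"].anchor, ms_int, p)
            assert feature_at(lib, "m1", loc1, ms_int) == label
            assert feature_at(lib, "m2", loc2, ms_int) == label


class TestComponents:
    def _cup_and_logo(self):
        lib = ObjectLibrary()
        logo = make_model("logo", [(0.125, 0.125), (0.2, 0.4)], {(0, 0): "L", (1, 0): "O", (0, 1): "G"})
        cup = make_model("cup", [(0.3, 0.05), (0.45, 0.7)], {(0, 0): "handle"})
        lib.objects = {"logo": logo, "cup": cup}
        return lib, logo, cup

    def test_add_component_counts_and_multiplicity(self):
        lib, logo, cup = self._cup_and_logo()
        d1 = displacement_between(cup.anchor, logo.anchor, MS)
        add_component(lib, "cup", "logo", d1)
        assert len(cup.components) == 1
        d2 = displacement_between(integrate(cup.anchor, MS, (1, 1)), logo.anchor, MS)
        add_component(lib, "cup", "logo", d2)
        assert len(cup.components) == 2  # an object may hold two copies

    def test_frame_mismatch_rejected(self):
        lib, logo, cup = self._cup_and_logo()
        wrong = displacement_between(logo.anchor, cup.anchor, MS)
        with pytest.raises(ValueError, match="frames"):
            add_component(lib, "cup", "logo", wrong)

    def test_unknown_ids_rejected(self):
        lib, logo, cup = self._cup_and_logo()
        d = displacement_between(cup.anchor, logo.anchor, MS)
        with pytest.raises(KeyError):
            add_component(lib, "mug", "logo", d)

    def test_logo_feature_through_cup_hand_oracle(self):
        """Place the logo at world offset (2, 1) inside the cup; every cup
        location that translates onto a logo feature resolves to it.  The
        expected keys come from explicit modular arithmetic on the chosen
        anchors, not from the library code."""
        lib, logo, cup = self._cup_and_logo()
        t = (2, 1)
        placement = displacement_between(
            integrate(cup.anchor, MS, t), logo.anchor, MS
        )
        add_component(lib, "cup", "logo", placement)
        for p, label in {(0, 0): "L", (1, 0): "O", (0, 1): "G"}.items():
            world = (t[0] + p[0], t[1] + p[1])
            cup_loc = LocationCode(
                phases=tuple(
                    Phase(*hand_phase(anc, scale, world))
                    for (scale, _), anc in zip(SPECS, [(0.3, 0.05), (0.45, 0.7)])
                ),
                frame="cup",
            )
            assert feature_at(lib, "cup", cup_loc, MS) == label

    def test_empty_object_is_none_everywhere(self, rng):
        lib = ObjectLibrary()
        lib.objects["empty"] = ObjectModel(
            id="empty", anchor=random_code(MS, rng, "empty")
        )
        for _ in range(5):
            loc = integrate(lib["empty"].anchor, MS, rng.integers(-5, 5, size=2))
            assert feature_at(lib, "empty", loc, MS) == "none"

    def test_recursive_composite_terminates(self):
        """logo-contains-cup-contains-logo is legal; resolution is bounded by
        the depth limit and only reaches features within it."""
        lib, logo, cup = self._cup_and_logo()
        add_component(lib, "cup", "logo",
                      placement_from_world_offset(lib, "cup", "logo", (2, 1), MS))
        add_component(lib, "logo", "cup",
                      placement_from_world_offset(lib, "logo", "cup", (5, 5), MS))
        # cup handle seen through logo -> cup, one translation deep
        loc = LocationCode(
            phases=tuple(
                Phase(*hand_phase(anc, scale, (5, 5)))
                for (scale, _), anc in zip(SPECS, [(0.125, 0.125), (0.2, 0.4)])
            ),
            frame="logo",
        )
        assert feature_at(lib, "logo", loc, MS, depth_limit=3) == "handle"
        assert feature_at(lib, "logo", loc, MS, depth_limit=0) == "none"

    def test_own_features_shadow_components(self):
        lib, logo, cup = self._cup_and_logo()
        add_component(lib, "cup", "logo",
                      placement_from_world_offset(lib, "cup", "logo", (0, 0), MS))
        # (0,0) carries the cup's own "handle" even though the logo's "L"
        # sits at the same translated location
        loc = LocationCode(
            phases=tuple(
                Phase(*hand_phase(anc, scale, (0, 0)))
                for (scale, _), anc in zip(SPECS, [(0.3, 0.05), (0.45, 0.7)])
            ),
            frame="cup",
        )
        assert feature_at(lib, "cup", loc, MS) == "handle"

    def test_composite_prediction_exhaustive(self, ms_int):
        """After one placement, every child feature is retrievable through
        the parent at the translated locations."""
        child_placements = {(0, 0): "a", (2, 1): "b", (1, 3): "c", (3, 3): "d"}
        parent_placements = {(0, 1): "p"}
        lib = ObjectLibrary()

        def sweep(placements):
            steps, prev = [], (0, 0)
            for p in sorted(placements):
                steps.append(((float(p[0] - prev[0]), float(p[1] - prev[1])), placements[p]))
                prev = p
            return ExplorationTrace(steps=tuple(steps))

        learn_object(lib, "child", sweep(child_placements), ms_int, np.random.default_rng(3))
        learn_object(lib, "parent", sweep(parent_placements), ms_int, np.random.default_rng(4))
        t = (4, 2)
        add_component(lib, "parent", "child",
                      placement_from_world_offset(lib, "parent", "child", t, ms_int))
        for p, label in child_placements.items():
            loc = integrate(lib["parent"].anchor, ms_int, (t[0] + p[0], t[1] + p[1]))
            assert feature_at(lib, "parent", loc, ms_int) == label

    def test_resolution_is_deterministic(self):
        lib, logo, cup = self._cup_and_logo()
        add_component(lib, "cup", "logo",
                      placement_from_world_offset(lib, "cup", "logo", (2, 1), MS))
        loc = integrate(cup.anchor, MS, (2, 1))
        results = {feature_at(lib, "cup", loc, MS) for _ in range(5)}
        assert len(results) == 1


class TestSerialization:
    def _library(self):
        from cortexgrid import BehaviorSequence, displacement_key, vector_displacement

        lib = ObjectLibrary()
        logo = make_model("logo", [(0.125, 0.125), (0.2, 0.4)], {(0, 0): "L", (1, 0): "O"})
        cup = make_model("cup", [(0.3, 0.05), (0.45, 0.7)], {(0, 0): "handle"})
        lib.objects = {"logo": logo, "cup": cup}
        add_component(lib, "cup", "logo",
                      placement_from_world_offset(lib, "cup", "logo", (2, 1), MS))
        k1 = displacement_key(vector_displacement(MS, (1, 0), "cup", "logo"), MS)
        k2 = displacement_key(vector_displacement(MS, (2, 0), "cup", "logo"), MS)
        cup.behaviors["slide"] = BehaviorSequence(id="slide", steps=(k1, k2))
        return lib

    def test_json_round_trip_byte_identical(self):
        lib = self._library()
        text1 = library_to_json(lib, MS)
        lib2, ms2 = library_from_json(text1)
        text2 = library_to_json(lib2, ms2)
        assert text1 == text2

    def test_round_trip_preserves_content(self):
        lib = self._library()
        lib2, ms2 = library_from_json(library_to_json(lib, MS))
        assert set(lib2.objects) == {"logo", "cup"}
        assert lib2["cup"].feature_map == lib["cup"].feature_map
        assert lib2["cup"].components[0].child_id == "logo"
        assert lib2["cup"].behaviors["slide"].steps == lib["cup"].behaviors["slide"].steps
        loc = integrate(lib2["cup"].anchor, ms2, (2, 1))
        assert feature_at(lib2, "cup", loc, ms2) == "L"

    def test_trace_csv_round_trip(self, tmp_path):
        trace = ExplorationTrace(
            steps=(((1.0, 0.0), "f1"), ((0.0, 2.0), "none"), ((-1.0, 1.0), "f2"))
        )
        path = tmp_path / "trace.csv"
        trace_to_csv(trace, path)
        again = trace_from_csv(path)
        assert again.steps == trace.steps
        header = path.read_text().splitlines()[0]
        assert header == "step,dx,dy,feature"


class TestTraceValidation:
    def test_empty_trace_rejected(self):
        with pytest.raises(ValueError):
            ExplorationTrace(steps=())

    def test_nonfinite_movement_rejected(self):
        with pytest.raises(ValueError):
            ExplorationTrace(steps=(((float("nan"), 0.0), "f"),))
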