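"""Synthetic worlds and experiment runners.

Objects are sets of labelled features at distinct integer points on a small
canvas (a cup is "a set of locations with features", and an integer grid
keeps every worked example exact).  Traces are sensor paths over those
points.  The experiment runners reproduce the framework's quantitative
behaviour: capacity/collision statistics of multi-module codes, sensorimotor
recognition with and without column voting, and point-to-point navigation by
displacement decoding.

Every experiment is a pure function of (config, seed); reports carry a hash
of the config that produced them.

Coordinate convention throughout: 2-D Cartesian, x right, y up; movements
are allocentric world vectors.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from .displacement import (
    UndecodableError,
    decode_vector,
    displacement_between,
)
from .inference import (
    FAILED,
    Column,
    ColumnNetwork,
    sensations_to_recognition,
)
from .location_codes import (
    ModuleSet,
    bin_array,
    capacity,
    integrate,
    random_code,
)
from .object_models import ExplorationTrace, ObjectLibrary, learn_object

__all__ = [
    "ObjectSpec",
    "RecognitionSpec",
    "CapacitySpec",
    "NavigationSpec",
    "WorldConfig",
    "ExperimentReport",
    "make_object",
    "scripted_trace",
    "learn_library",
    "experiment_capacity",
    "experiment_recognition",
    "experiment_navigation",
]


class ObjectSpec(BaseModel):
    """How synthetic objects are generated."""

    n_objects: int = Field(default=50, gt=0)
    n_features: int = Field(default=10, ge=0)
    alphabet_size: int = Field(default=8, gt=0)
    canvas: int = Field(default=10, gt=0)
    min_spacing: float = Field(default=1.0, ge=1.0)


class RecognitionSpec(BaseModel):
    policy: str = "random"
    max_sensations: int = Field(default=50, gt=0)
    n_trials: int = Field(default=40, gt=0)
    n_columns: tuple[int, ...] = (1, 3)
    mode: str = "strict"


class CapacitySpec(BaseModel):
    n_draws: tuple[int, ...] = (2, 10, 50)
    n_trials: int = Field(default=10_000, gt=0)


class NavigationSpec(BaseModel):
    n_pairs: int = Field(default=100, gt=0)
    search_radius: float = Field(default=14.0, gt=0)
    grid_step: float = Field(default=1.0, gt=0)
    tol: float = Field(default=1e-6, gt=0)


class WorldConfig(BaseModel):
    """Full experiment configuration; every field has a sensible default, so
    an empty YAML file is a valid config."""

    seed: int = 0
    modules: list[dict] | None = None  # None -> the integer-tuned default set
    objects: ObjectSpec = ObjectSpec()
    recognition: RecognitionSpec = RecognitionSpec()
    capacity: CapacitySpec = CapacitySpec()
    navigation: NavigationSpec = NavigationSpec()

    def module_set(self) -> ModuleSet:
        if self.modules is None:
            return ModuleSet.integer_tuned()
        return ModuleSet.from_config(self.modules)

    def hash(self) -> str:
        return hashlib.sha1(
            self.model_dump_json().encode()
        ).hexdigest()[:12]


@dataclass
class ExperimentReport:
    """Per-trial rows plus summary statistics and the config hash."""

    rows: pd.DataFrame
    summary: dict
    config_hash: str

    def to_csv(self, path) -> None:
        self.rows.to_csv(path, index=False)


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, *key]))


def make_object(
    spec: ObjectSpec, rng: np.random.Generator
) -> dict[tuple[int, int], str]:
    """Place ``n_features`` labelled features at distinct integer points.

    Points are drawn without replacement from the canvas (greedy over a
    random permutation when a minimum spacing above one grid unit is asked
    for); labels are uniform over the alphabet.  Deterministic per generator
    state; raises if the canvas cannot hold the requested count.
    """
    if spec.n_features == 0:
        return {}
    all_points = [(x, y) for x in range(spec.canvas) for y in range(spec.canvas)]
    order = rng.permutation(len(all_points))
    chosen: list[tuple[int, int]] = []
    for idx in order:
        p = all_points[idx]
        if spec.min_spacing > 1.0 and any(
            np.hypot(p[0] - q[0], p[1] - q[1]) < spec.min_spacing for q in chosen
        ):
            continue
        chosen.append(p)
        if len(chosen) == spec.n_features:
            break
    if len(chosen) < spec.n_features:
        raise ValueError(
            f"cannot place {spec.n_features} features on a {spec.canvas}x"
            f"{spec.canvas} canvas at spacing {spec.min_spacing}"
        )
    labels = [f"f{int(i)}" for i in rng.integers(spec.alphabet_size, size=len(chosen))]
    return dict(zip(chosen, labels))


def scripted_trace(
    placements: dict[tuple[int, int], str],
    policy: str = "sweep",
    n_steps: int | None = None,
    rng: np.random.Generator | None = None,
) -> ExplorationTrace:
    """Sensor path over an object's feature points.

    ``sweep`` visits every placement once in row-major order; ``random``
    walks ``n_steps`` uniform choices over the feature points (reproducible
    for a seeded generator).  Features are emitted on arrival; movements are
    point-to-point.  The trace starts at the object origin (offset (0, 0)).
    """
    if not placements:
        raise ValueError("feature-seeking traces need a non-empty placement")
    points = sorted(placements)
    if policy == "sweep":
        visits = points
    elif policy == "random":
        if not n_steps or n_steps < 1:
            raise ValueError("random traces need n_steps >= 1")
        if rng is None:
            raise ValueError("random traces need an rng")
        visits = [points[int(rng.integers(len(points)))] for _ in range(n_steps)]
    else:
        raise ValueError(f"unknown policy {policy!r}")
    steps = []
    prev = (0, 0)
    for p in visits:
        steps.append(((float(p[0] - prev[0]), float(p[1] - prev[1])), placements[p]))
        prev = p
    return ExplorationTrace(steps=tuple(steps))


def learn_library(
    placements_by_id: dict[str, dict[tuple[int, int], str]],
    ms: ModuleSet,
    rng: np.random.Generator,
) -> ObjectLibrary:
    """Learn every object from a sweep trace, one random anchor each."""
    lib = ObjectLibrary()
    for oid in sorted(placements_by_id):
        learn_object(lib, oid, scripted_trace(placements_by_id[oid]), ms, rng)
    return lib


# --------------------------------------------------------------------------
# capacity / anchor-collision experiment
# --------------------------------------------------------------------------

def _collision_rate(
    ms: ModuleSet, n_draws: int, n_trials: int, rng: np.random.Generator
) -> float:
    """Fraction of trials in which ``n_draws`` random anchors contain at
    least one pair with identical discretised keys.

    Vectorised: uniform phases binned by floor(phase * bins) per module axis
    (the same arithmetic as ``random_code`` + ``discretize``, checked against
    them in the unit tests), with joint keys packed in mixed radix.
    """
    phases = rng.random((n_trials, n_draws, len(ms), 2))
    packed = np.zeros((n_trials, n_draws), dtype=np.int64)
    for i, m in enumerate(ms):
        for axis, nbins in enumerate(m.bins):
            cells = bin_array(phases[:, :, i, axis], nbins)
            packed = packed * nbins + cells
    packed.sort(axis=1)
    collided = (np.diff(packed, axis=1) == 0).any(axis=1)
    return float(collided.mean())


def experiment_capacity(cfg: WorldConfig) -> ExperimentReport:
    """Empirical anchor-collision rates versus the birthday approximation
    ``1 - exp(-N^2 / (2 * capacity))`` for growing numbers of modules.

    Capacity grows exponentially with module count, so for fixed N the
    collision rate is non-increasing as modules are added.
    """
    ms_full = cfg.module_set()
    rows = []
    for m_count in range(1, len(ms_full) + 1):
        ms = ModuleSet(ms_full.modules[:m_count])
        cap = capacity(ms)
        for n in cfg.capacity.n_draws:
            rate = _collision_rate(
                ms, n, cfg.capacity.n_trials, _rng(cfg.seed, 11, m_count, n)
            )
            approx = 1.0 - np.exp(-(n**2) / (2.0 * cap))
            rows.append(
                {
                    "n_modules": m_count,
                    "capacity": cap,
                    "n_draws": n,
                    "n_trials": cfg.capacity.n_trials,
                    "collision_rate": rate,
                    "birthday_approx": float(approx),
                }
            )
    frame = pd.DataFrame(rows)
    summary = {
        "max_abs_dev_from_birthday": float(
            (frame.collision_rate - frame.birthday_approx).abs().max()
        )
    }
    return ExperimentReport(frame, summary, cfg.hash())


# --------------------------------------------------------------------------
# recognition experiment
# --------------------------------------------------------------------------

def experiment_recognition(cfg: WorldConfig) -> ExperimentReport:
    """Sensorimotor recognition over a randomized object library.

    One shared world (the same feature placements and the same per-trial
    targets and sensor walks for every column-count condition) so that
    adding voting columns is the only difference between conditions; column
    0's library and trajectory are identical across conditions.
    """
    ms = cfg.module_set()
    world_rng = _rng(cfg.seed, 21)
    placements_by_id = {
        f"obj{i:03d}": make_object(cfg.objects, world_rng)
        for i in range(cfg.objects.n_objects)
    }
    object_ids = sorted(placements_by_id)

    rows = []
    for n_col in cfg.recognition.n_columns:
        libs = [
            learn_library(placements_by_id, ms, _rng(cfg.seed, 22, c))
            for c in range(n_col)
        ]
        for trial in range(cfg.recognition.n_trials):
            target = object_ids[
                int(_rng(cfg.seed, 23, trial).integers(len(object_ids)))
            ]
            columns = [
                Column(ms=ms, lib=lib, mode=cfg.recognition.mode) for lib in libs
            ]
            net = ColumnNetwork(columns)
            result = sensations_to_recognition(
                net,
                target,
                placements_by_id[target],
                rng=_rng(cfg.seed, 24, trial),
                policy=cfg.recognition.policy,
                max_sensations=cfg.recognition.max_sensations,
            )
            rows.append(
                {
                    "trial": trial,
                    "n_objects": cfg.objects.n_objects,
                    "n_columns": n_col,
                    "seed": cfg.seed,
                    "sensations": result if result != FAILED else np.nan,
                    "outcome": "recognized" if result != FAILED else "failed",
                }
            )
    frame = pd.DataFrame(rows)
    summary = {}
    for n_col, grp in frame.groupby("n_columns"):
        ok = grp[grp.outcome == "recognized"]
        summary[int(n_col)] = {
            "median_sensations": float(ok.sensations.median()) if len(ok) else np.nan,
            "fraction_at_1": float((ok.sensations == 1).sum() / len(grp)),
            "failure_rate": float((grp.outcome == "failed").mean()),
        }
    return ExperimentReport(frame, summary, cfg.hash())


# --------------------------------------------------------------------------
# navigation experiment
# --------------------------------------------------------------------------

def experiment_navigation(cfg: WorldConfig) -> ExperimentReport:
    """Point-to-point navigation: encode two points in one environment,
    take the displacement, decode it to a motor vector, move, and measure
    the arrival error.  Undecodable pairs (outside the search radius) are
    counted, not raised."""
    ms = cfg.module_set()
    rng = _rng(cfg.seed, 31)
    anchor = random_code(ms, rng, frame="environment")
    rows = []
    for trial in range(cfg.navigation.n_pairs):
        a = rng.integers(cfg.objects.canvas, size=2).astype(float)
        b = rng.integers(cfg.objects.canvas, size=2).astype(float)
        code_a = integrate(anchor, ms, a)
        code_b = integrate(anchor, ms, b)
        d = displacement_between(code_a, code_b, ms)
        row = {
            "trial": trial,
            "ax": a[0], "ay": a[1], "bx": b[0], "by": b[1],
            "vx": np.nan, "vy": np.nan, "norm": np.nan,
            "matched_tolerance": cfg.navigation.tol,
            "arrival_error": np.nan,
            "outcome": "undecodable",
        }
        try:
            v = decode_vector(
                d, ms,
                search_radius=cfg.navigation.search_radius,
                grid_step=cfg.navigation.grid_step,
                tol=cfg.navigation.tol,
            )
        except UndecodableError:
            pass
        else:
            row.update(
                vx=v[0], vy=v[1], norm=float(np.hypot(*v)),
                arrival_error=float(np.linalg.norm(a + v - b)),
                outcome="ok",
            )
        rows.append(row)
    frame = pd.DataFrame(rows)
    ok = frame[frame.outcome == "ok"]
    summary = {
        "n_ok": int(len(ok)),
        "n_undecodable": int((frame.outcome == "undecodable").sum()),
        "max_arrival_error": float(ok.arrival_error.max()) if len(ok) else np.nan,
    }
    return ExperimentReport(frame, summary, cfg.hash())
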