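"""Multi-module location codes: capacity, anchoring, and discrete code keys.

One periodic module cannot represent a unique location, but the joint phase
across several modules with different spacings/orientations can: the number of
distinguishable states is the product of the per-module cell counts, so
capacity grows exponentially with the number of modules (ten modules of twenty
cells each already give 20**10 distinct locations).  This is the residue-
number-system flavour of position coding: with coprime integer periods the
joint code is unique over the least common multiple of the periods.

A :class:`LocationCode` carries one phase per module plus a *reference frame*
tag — the object or environment the code is anchored to.  "Anchoring" an
object means choosing which cells are active at its origin; here anchors are
uniform-random phase assignments stored with the learned object.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np

from .grid_modules import (
    BIN_EDGE_EPS,
    CellIndex,
    ModuleParams,
    Phase,
    active_cell,
    path_integrate,
    phase_distance,
)

__all__ = [
    "ModuleSet",
    "LocationCode",
    "CodeKey",
    "Arena",
    "integrate",
    "discretize",
    "capacity",
    "random_code",
    "enumerate_unique_keys",
    "coactive_positions",
    "bin_center_phase",
]

#: Distinguished reference-frame tags for codes not anchored to an object.
BODY_FRAME = "body"
ENVIRONMENT_FRAME = "environment"


@dataclass(frozen=True)
class ModuleSet:
    """An ordered collection of grid-cell modules observing the same space."""

    modules: tuple[ModuleParams, ...]

    def __post_init__(self) -> None:
        mods = tuple(self.modules)
        if len(mods) < 1:
            raise ValueError("a ModuleSet needs at least one module")
        seen = {(m.scale, m.orientation) for m in mods}
        if len(seen) < len(mods):
            warnings.warn(
                "ModuleSet has modules with identical (scale, orientation); "
                "they add no representational capacity",
                stacklevel=2,
            )
        object.__setattr__(self, "modules", mods)

    def __len__(self) -> int:
        return len(self.modules)

    def __iter__(self) -> Iterator[ModuleParams]:
        return iter(self.modules)

    @property
    def min_bin_width(self) -> float:
        return min(1.0 / max(m.bins) for m in self.modules)

    @property
    def phase_tolerance(self) -> float:
        """Tolerance for continuous-phase comparisons: min bin width / 4."""
        return self.min_bin_width / 4.0

    @classmethod
    def default(cls, n_modules: int = 6, base_scale: float = 1.0, ratio: float = 1.4,
                bins: tuple[int, int] = (5, 5), lattice: str = "square") -> "ModuleSet":
        """Literature-convention set: geometric scale progression, fixed
        pseudo-random orientations, 5x5 bins per module."""
        orient_rng = np.random.default_rng(982451653)  # fixed: orientations are part of the geometry
        mods = tuple(
            ModuleParams(
                scale=base_scale * ratio**i,
                orientation=float(orient_rng.uniform(0.0, 2.0 * math.pi)),
                lattice=lattice,
                bins=bins,
            )
            for i in range(n_modules)
        )
        return cls(mods)

    @classmethod
    def integer_tuned(cls, scales: tuple[float, ...] = (2.0, 3.0, 4.0, 5.0),
                      bins: tuple[tuple[int, int], ...] = ((4, 4), (3, 3), (4, 4), (5, 5)),
                      ) -> "ModuleSet":
        """Axis-aligned square modules whose bin counts are integer multiples
        of their scales, so unit world movements shift phases by whole bins.

        On an integer canvas this keeps discretised keys exactly consistent
        under path integration from bin-centre poses — the configuration used
        by the object-learning and recognition experiments.
        """
        for s, (ba, bb) in zip(scales, bins):
            if abs(ba / s - round(ba / s)) > 1e-12 or abs(bb / s - round(bb / s)) > 1e-12:
                raise ValueError(f"bins {ba, bb} not integer multiples of scale {s}")
        mods = tuple(
            ModuleParams(scale=s, orientation=0.0, lattice="square", bins=b)
            for s, b in zip(scales, bins)
        )
        return cls(mods)

    @classmethod
    def from_config(cls, entries: Iterable[dict]) -> "ModuleSet":
        """Build from a list of ``{scale, orientation_deg, lattice, bins_a, bins_b, noise_sd}``."""
        mods = []
        for e in entries:
            mods.append(
                ModuleParams(
                    scale=float(e["scale"]),
                    orientation=math.radians(float(e.get("orientation_deg", 0.0))),
                    lattice=e.get("lattice", "square"),
                    bins=(int(e.get("bins_a", 5)), int(e.get("bins_b", 5))),
                    noise_sd=float(e.get("noise_sd", 0.0)),
                )
            )
        return cls(tuple(mods))

    def to_config(self) -> list[dict]:
        return [
            {
                "scale": m.scale,
                "orientation_deg": math.degrees(m.orientation),
                "lattice": m.lattice,
                "bins_a": m.bins[0],
                "bins_b": m.bins[1],
                "noise_sd": m.noise_sd,
            }
            for m in self.modules
        ]


@dataclass(frozen=True)
class LocationCode:
    """Per-module phases plus the reference frame the code is anchored to."""

    phases: tuple[Phase, ...]
    frame: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "phases", tuple(self.phases))


@dataclass(frozen=True)
class CodeKey:
    """Discretised location code: one active cell per module.

    Hashable and totally determined by (LocationCode, ModuleSet), so it serves
    as the identity for associative storage of locations.
    """

    cells: tuple[CellIndex, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "cells", tuple(CellIndex(*c) for c in self.cells))


def _check_conforms(code: LocationCode, ms: ModuleSet) -> None:
    if len(code.phases) != len(ms):
        raise ValueError(
            f"code has {len(code.phases)} phases but module set has {len(ms)} modules"
        )


def integrate(
    code: LocationCode,
    ms: ModuleSet,
    movement,
    rng: np.random.Generator | None = None,
) -> LocationCode:
    """Path-integrate every module's phase by a world movement; the frame tag
    is preserved (moving does not re-anchor)."""
    _check_conforms(code, ms)
    return LocationCode(
        phases=tuple(
            path_integrate(p, m, movement, rng) for p, m in zip(code.phases, ms)
        ),
        frame=code.frame,
    )


def discretize(code: LocationCode, ms: ModuleSet) -> CodeKey:
    """Active cell per module.  Stable under phase perturbations smaller than
    the distance to the nearest bin edge."""
    _check_conforms(code, ms)
    return CodeKey(tuple(active_cell(p, m) for p, m in zip(code.phases, ms)))


def capacity(ms: ModuleSet) -> int:
    """Number of distinct joint keys: product over modules of bins_a * bins_b.

    Exact (Python integer), so ten modules of twenty states give exactly
    20**10 = 10,240,000,000,000.
    """
    return math.prod(m.bins[0] * m.bins[1] for m in ms)


def random_code(ms: ModuleSet, rng: np.random.Generator, frame: str) -> LocationCode:
    """Draw a uniform-random anchor: independent uniform phases per module."""
    return LocationCode(
        phases=tuple(Phase(*rng.random(2)) for _ in ms),
        frame=frame,
    )


def bin_center_phase(cell: CellIndex, params: ModuleParams) -> Phase:
    """Phase at the centre of a cell's bin."""
    ba, bb = params.bins
    return Phase((cell.a + 0.5) / ba, (cell.b + 0.5) / bb)


@dataclass(frozen=True)
class Arena:
    """Axis-aligned rectangle of sample points with a fixed step.

    Degenerate extents (x0 == x1) give a line or single point.
    """

    x0: float
    x1: float
    y0: float
    y1: float
    step: float

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise ValueError("step must be > 0")
        if self.x1 < self.x0 or self.y1 < self.y0:
            raise ValueError("empty arena")
        for lo, hi in ((self.x0, self.x1), (self.y0, self.y1)):
            n = (hi - lo) / self.step
            if abs(n - round(n)) > 1e-9:
                raise ValueError("step must divide the arena extent evenly")

    def points(self) -> np.ndarray:
        nx = int(round((self.x1 - self.x0) / self.step)) + 1
        ny = int(round((self.y1 - self.y0) / self.step)) + 1
        xs = self.x0 + self.step * np.arange(nx)
        ys = self.y0 + self.step * np.arange(ny)
        gx, gy = np.meshgrid(xs, ys, indexing="ij")
        return np.column_stack([gx.ravel(), gy.ravel()])


def bin_array(ph: np.ndarray, nbins: int) -> np.ndarray:
    """Vectorised counterpart of :func:`cortexgrid.grid_modules.bin_index`."""
    c = np.floor(ph * nbins + BIN_EDGE_EPS).astype(int)
    c[c >= nbins] = 0
    return c


def _keys_for_points(ms: ModuleSet, pts: np.ndarray) -> list[tuple]:
    keys: list[tuple] = []
    cells_per_module = []
    for m in ms:
        lat = pts @ m.transform.T
        ph = lat % 1.0
        ph[ph >= 1.0] = 0.0
        ba, bb = m.bins
        ca = bin_array(ph[:, 0], ba)
        cb = bin_array(ph[:, 1], bb)
        cells_per_module.append(np.column_stack([ca, cb]))
    for i in range(len(pts)):
        keys.append(tuple((int(c[i, 0]), int(c[i, 1])) for c in cells_per_module))
    return keys


def enumerate_unique_keys(ms: ModuleSet, arena: Arena) -> int:
    """Brute-force capacity oracle: encode every arena sample point (world
    point pushed through each module's lattice transform, mod 1, binned) and
    count the distinct joint keys.  Never exceeds :func:`capacity`."""
    return len(set(_keys_for_points(ms, arena.points())))


def coactive_positions(ms: ModuleSet, preferred: CodeKey, arena: Arena) -> list[tuple[float, float]]:
    """Arena points at which every module's active cell equals its preferred
    cell — the joint firing-field intersection of one chosen cell per module.

    With coprime integer periods along one axis this is the Chinese-remainder
    construction: exactly one co-active position per joint period.
    """
    pts = arena.points()
    target = tuple((c.a, c.b) for c in preferred.cells)
    keys = _keys_for_points(ms, pts)
    return [(float(p[0]), float(p[1])) for p, k in zip(pts, keys) if k == target]
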