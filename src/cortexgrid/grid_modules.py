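"""A single grid-cell module: a periodic 2-D phase code updated by path integration.

A grid cell fires at multiple locations that tile an environment as a periodic
lattice.  A *module* is a population of such cells sharing one lattice spacing
and orientation but differing in phase offset.  Here a module is idealised as a
point on the unit torus: the pair of lattice coordinates of the current
location, reduced modulo one lattice tile.  Moving through the world shifts the
phase by the movement expressed in lattice coordinates ("path integration"
from an efference copy of the motor command); returning to the same physical
location by any path restores the same phase, and hence the same active cell.

Two lattice geometries are supported: ``square`` (the didactic default) and
``rhombic60`` (a 60-degree rhombus whose tiling emulates the hexagonal firing
fields of biological grid cells).  All phase arithmetic is done in oblique
lattice coordinates, so every invariant (path independence, periodicity,
linearity) holds for either basis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

__all__ = [
    "BIN_EDGE_EPS",
    "bin_index",
    "LATTICE_BASES",
    "ModuleParams",
    "Phase",
    "CellIndex",
    "world_to_lattice",
    "path_integrate",
    "active_cell",
    "phase_distance",
]

#: Columns are the lattice basis vectors (unit length, before scaling).
LATTICE_BASES: dict[str, np.ndarray] = {
    "square": np.eye(2),
    "rhombic60": np.array([[1.0, 0.5], [0.0, math.sqrt(3.0) / 2.0]]),
}


#: Phases this close below a bin edge are treated as on the edge.  Exact
#: lattice fractions (e.g. 2/3 for a period-3 module) otherwise round down
#: in floating point and land in the wrong bin.
BIN_EDGE_EPS = 1e-9


def bin_index(p: float, n: int) -> int:
    """Half-open binning of a unit-interval phase into n bins, with the
    1e-9 edge snap; an index reaching n wraps to 0 (the torus closes)."""
    c = int(math.floor(p * n + BIN_EDGE_EPS))
    return 0 if c >= n else c


def _wrap_unit(x: float) -> float:
    """Reduce a real into the half-open interval [0, 1).

    Python's modulo of a tiny negative float can round to exactly 1.0, which
    would violate the half-open contract; that edge is folded back to 0.0.
    """
    r = float(x) % 1.0
    return 0.0 if r >= 1.0 else r


@dataclass(frozen=True)
class ModuleParams:
    """Geometry and resolution of one grid-cell module.

    Parameters
    ----------
    scale
        Lattice period length in world-distance units; strictly positive.
    orientation
        Lattice orientation in radians, reduced into [0, 2*pi).
    lattice
        ``"square"`` or ``"rhombic60"``.
    bins
        Phase bins per lattice axis ``(bins_a, bins_b)``; each >= 1.  The
        module has ``bins_a * bins_b`` distinguishable cells.
    noise_sd
        Standard deviation of additive phase noise per integration step, in
        phase units.  Zero (the default) makes path integration exact.
    """

    scale: float
    orientation: float = 0.0
    lattice: str = "square"
    bins: tuple[int, int] = (5, 5)
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if not self.scale > 0:
            raise ValueError(f"scale must be > 0, got {self.scale}")
        if self.lattice not in LATTICE_BASES:
            raise ValueError(f"unknown lattice {self.lattice!r}")
        ba, bb = self.bins
        if ba < 1 or bb < 1:
            raise ValueError(f"bins must each be >= 1, got {self.bins}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        object.__setattr__(self, "orientation", float(self.orientation) % (2.0 * math.pi))
        object.__setattr__(self, "bins", (int(ba), int(bb)))

    @property
    def transform(self) -> np.ndarray:
        """2x2 matrix mapping world vectors to lattice coordinates."""
        c, s = math.cos(-self.orientation), math.sin(-self.orientation)
        rot = np.array([[c, -s], [s, c]])
        basis_inv = np.linalg.inv(LATTICE_BASES[self.lattice])
        return basis_inv @ rot / self.scale


@dataclass(frozen=True)
class Phase:
    """Position within one module's lattice tile, each coordinate in [0, 1)."""

    a: float
    b: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "a", _wrap_unit(self.a))
        object.__setattr__(self, "b", _wrap_unit(self.b))

    @property
    def p(self) -> tuple[float, float]:
        return (self.a, self.b)

    def as_array(self) -> np.ndarray:
        return np.array([self.a, self.b])

    @classmethod
    def from_array(cls, arr: np.ndarray) -> "Phase":
        return cls(float(arr[0]), float(arr[1]))


class CellIndex(NamedTuple):
    """Discrete cell within a module: bin indices along the two lattice axes."""

    a: int
    b: int


def world_to_lattice(params: ModuleParams, v) -> np.ndarray:
    """Express a 2-D world vector in the module's (scaled, rotated) lattice basis."""
    return params.transform @ np.asarray(v, dtype=float)


def path_integrate(
    phase: Phase,
    params: ModuleParams,
    movement,
    rng: np.random.Generator | None = None,
) -> Phase:
    """Advance the module phase by a world movement (efference copy).

    The movement is converted to lattice coordinates, optionally perturbed by
    Gaussian phase noise, added to the current phase, and reduced mod 1.
    """
    delta = world_to_lattice(params, movement)
    if params.noise_sd > 0:
        if rng is None:
            raise ValueError("noise_sd > 0 requires an explicit rng")
        delta = delta + rng.normal(0.0, params.noise_sd, size=2)
    return Phase(phase.a + delta[0], phase.b + delta[1])


def active_cell(phase: Phase, params: ModuleParams) -> CellIndex:
    """Discretise a phase into the single active cell of the module.

    Bins are half-open ``[k/bins, (k+1)/bins)``; phases within 1e-9 of an
    edge are assigned to the upper bin (wrapping to 0 at phase 1.0), so exact
    lattice fractions bin as mathematics says they should.
    """
    ba, bb = params.bins
    return CellIndex(bin_index(phase.a, ba), bin_index(phase.b, bb))


def phase_distance(a: Phase, b: Phase) -> float:
    """Max over axes of the circular distance between two phases.

    Symmetric, zero iff the phases are equal; used for all tolerance
    comparisons on the torus.
    """
    da = abs(a.a - b.a)
    db = abs(a.b - b.b)
    return max(min(da, 1.0 - da), min(db, 1.0 - db))
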