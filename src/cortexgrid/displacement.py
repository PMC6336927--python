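"""Displacement cells: per-module phase differences between two location codes.

Grid cells and displacement cells perform complementary operations:

* grid cells:          location1 + displacement -> location2
* displacement cells:  location2 - location1    -> displacement

The difference is taken module by module on the torus, so a single
displacement module is as ambiguous as a single grid module ("two to the
right and one up" activates the same cell as "five over and four up"), while
the joint code across modules is unique over the modules' joint period.
Because the two locations may be anchored to *different* frames, the same
arithmetic that yields a movement vector within one space also encodes the
relative placement of one object inside another — the basis of object
composition.

Decoding a displacement back to a Cartesian motor vector is a brute-force
search over candidate vectors on a grid: transparent, testable, and adequate
at desk scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid_modules import CellIndex, Phase, bin_index, phase_distance
from .location_codes import CodeKey, LocationCode, ModuleSet, _check_conforms

__all__ = [
    "DisplacementCode",
    "DisplacementKey",
    "FrameMismatchError",
    "UndecodableError",
    "displacement_between",
    "apply_displacement",
    "displacement_key",
    "vector_displacement",
    "decode_vector",
]


class FrameMismatchError(ValueError):
    """A displacement was applied to a code anchored in the wrong frame."""


class UndecodableError(ValueError):
    """No candidate vector within the search radius matches the displacement."""


@dataclass(frozen=True)
class DisplacementCode:
    """Per-module phase differences (mod 1) between two location codes.

    ``frame_from``/``frame_to`` record which frames the difference relates;
    they differ exactly when the displacement expresses a relative object
    placement rather than a movement within one space.
    """

    deltas: tuple[Phase, ...]
    frame_from: str
    frame_to: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "deltas", tuple(self.deltas))


@dataclass(frozen=True)
class DisplacementKey:
    """Discretised displacement: one displacement cell per module.

    Any two pairs of locations separated by the same physical displacement
    activate the same key, regardless of where either pair sits.
    """

    cells: tuple[CellIndex, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "cells", tuple(CellIndex(*c) for c in self.cells))


def displacement_between(a: LocationCode, b: LocationCode, ms: ModuleSet) -> DisplacementCode:
    """location2 - location1, module by module on the torus.

    The frames of ``a`` and ``b`` may differ — that is how a relative object
    placement is expressed.  Antisymmetric: swapping the arguments negates
    every delta mod 1.
    """
    _check_conforms(a, ms)
    _check_conforms(b, ms)
    return DisplacementCode(
        deltas=tuple(
            Phase(pb.a - pa.a, pb.b - pa.b) for pa, pb in zip(a.phases, b.phases)
        ),
        frame_from=a.frame,
        frame_to=b.frame,
    )


def apply_displacement(a: LocationCode, d: DisplacementCode, ms: ModuleSet) -> LocationCode:
    """location1 + displacement, module by module; the result is anchored in
    ``d.frame_to``.  The input frame must equal ``d.frame_from`` — a strict
    check that catches frame-plumbing errors early."""
    _check_conforms(a, ms)
    if len(d.deltas) != len(ms):
        raise ValueError("displacement length does not match module set")
    if a.frame != d.frame_from:
        raise FrameMismatchError(
            f"code is anchored to {a.frame!r} but displacement starts from {d.frame_from!r}"
        )
    return LocationCode(
        phases=tuple(
            Phase(p.a + dd.a, p.b + dd.b) for p, dd in zip(a.phases, d.deltas)
        ),
        frame=d.frame_to,
    )


def displacement_key(d: DisplacementCode, ms: ModuleSet) -> DisplacementKey:
    """Bin each module's delta with that module's bins.

    Displacement modules reuse the grid modules' resolution; override by
    constructing a ModuleSet with different bins if finer displacement coding
    is wanted.
    """
    if len(d.deltas) != len(ms):
        raise ValueError("displacement length does not match module set")
    cells = [
        CellIndex(bin_index(ph.a, m.bins[0]), bin_index(ph.b, m.bins[1]))
        for ph, m in zip(d.deltas, ms)
    ]
    return DisplacementKey(tuple(cells))


def vector_displacement(
    ms: ModuleSet, v, frame_from: str = "environment", frame_to: str = "environment"
) -> DisplacementCode:
    """Displacement code of a pure world vector: what displacement cells see
    when the second location is the first moved by ``v``."""
    deltas = []
    for m in ms:
        lat = m.transform @ np.asarray(v, dtype=float)
        deltas.append(Phase(lat[0], lat[1]))
    return DisplacementCode(tuple(deltas), frame_from=frame_from, frame_to=frame_to)


def decode_vector(
    d: DisplacementCode,
    ms: ModuleSet,
    search_radius: float,
    grid_step: float | None = None,
    tol: float = 1e-6,
) -> np.ndarray:
    """Recover the Cartesian vector a displacement encodes, if it is unique
    within ``search_radius``.

    Candidates are laid on a square grid of spacing ``grid_step`` (default:
    smallest module scale / 20) inside the disc of radius ``search_radius``.
    A candidate matches when every module's encoded phase difference is within
    ``tol`` (circular distance) of the target.  The minimum-norm match wins;
    ties break lexicographically on (norm, vx, vy).

    Raises
    ------
    UndecodableError
        If no candidate matches — e.g. the true vector lies outside the
        radius, or the radius exceeds the modules' joint period so the
        congruence has no unique solution nearby.
    """
    if search_radius <= 0:
        raise ValueError("search_radius must be > 0")
    if grid_step is None:
        grid_step = min(m.scale for m in ms) / 20.0
    grid_step = float(grid_step)
    n = int(np.floor(search_radius / grid_step))
    coords = grid_step * np.arange(-n, n + 1)
    gx, gy = np.meshgrid(coords, coords, indexing="ij")
    cand = np.column_stack([gx.ravel(), gy.ravel()])
    norms = np.hypot(cand[:, 0], cand[:, 1])
    keep = norms <= search_radius + 1e-12
    cand, norms = cand[keep], norms[keep]

    ok = np.ones(len(cand), dtype=bool)
    for ph_target, m in zip(d.deltas, ms):
        lat = cand @ m.transform.T
        ph = lat % 1.0
        ph[ph >= 1.0] = 0.0
        diff = np.abs(ph - np.array(ph_target.p))
        circ = np.minimum(diff, 1.0 - diff)
        ok &= circ.max(axis=1) <= tol
    if not ok.any():
        raise UndecodableError(
            f"no vector within radius {search_radius} matches the displacement "
            f"(tol={tol}, step={grid_step})"
        )
    cand, norms = cand[ok], norms[ok]
    best = np.lexsort((cand[:, 1], cand[:, 0], norms))[0]
    return cand[best].copy()
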