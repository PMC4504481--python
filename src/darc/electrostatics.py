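"""Electrostatic potential grids: import, masking/clamping, evaluation.

The electrostatic term of the combined score is sum(q_i * phi_i) over ligand
atoms, with phi obtained by trilinear interpolation of a regular scalar grid
of the receptor's electrostatic potential (kT/e).  Before use the grid is
conditioned: raw values are clamped to +/-10 kT/e (extreme values next to
charged atoms would otherwise dominate), the potential is zeroed inside the
protein interior, and every cell outside the pocket search box -- and any
query beyond the stored grid -- takes an unfavorable +100 so the penalty for
leaving the binding site has no holes.

Production grids come from an external Poisson-Boltzmann solver via OpenDX
import (:func:`darc.model_io.read_dx_grid`).  :func:`coulomb_grid` generates
a screened-Coulomb grid (distance-dependent dielectric eps = 4r) with the
same conditioning path, for self-contained runs and testing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import UnsupportedGridError

CLAMP_LIMIT = 10.0        # kT/e
OUTSIDE_PENALTY = 100.0   # applied outside the pocket box / stored grid
GRID_BUFFER = 2.0         # A beyond the protein extent
_EPS_CAP_R = 0.5          # A, cap for the 1/(4 r^2) kernel


@dataclass
class ESPGrid:
    """Regular scalar grid of electrostatic potential.

    ``values[i, j, k]`` is the potential at ``origin + (i, j, k) * spacing``
    (node-centered; C order matches the OpenDX file order, z fastest).
    """

    origin: np.ndarray            # (3,) A, node (0,0,0)
    spacing: float                # A
    values: np.ndarray            # (nx, ny, nz), kT/e
    clamped: bool = False
    masked: bool = False
    pocket_bounds: tuple | None = None   # (lo, hi) of the pocket search box
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, float)
        self.values = np.asarray(self.values, float)
        if self.values.ndim != 3:
            raise UnsupportedGridError("grid values must be 3-D")
        if self.spacing <= 0:
            raise UnsupportedGridError("grid spacing must be positive")

    @property
    def dims(self) -> tuple:
        return self.values.shape

    @property
    def upper(self) -> np.ndarray:
        return self.origin + (np.array(self.dims) - 1) * self.spacing

    def node_coords(self) -> np.ndarray:
        idx = np.indices(self.dims).reshape(3, -1).T
        return self.origin + idx * self.spacing

    def trilinear(self, points: np.ndarray) -> np.ndarray:
        """Standard 8-corner trilinear blend at each query point.

        Exact at grid nodes and on trilinear polynomials; every value is a
        convex combination of the enclosing cell's corners.  Queries outside
        the grid hull take the +100 outside penalty (the mask rule extended
        beyond the stored box).
        """
        pts = np.atleast_2d(np.asarray(points, float))
        rel = (pts - self.origin) / self.spacing
        n = np.array(self.dims)
        inside = np.all((rel >= 0) & (rel <= n - 1), axis=1)
        out = np.full(len(pts), OUTSIDE_PENALTY)
        if inside.any():
            r = rel[inside]
            i0 = np.minimum(np.floor(r).astype(int), n - 2)
            f = r - i0
            v = 0.0
            for corner in range(8):
                off = np.array([(corner >> 2) & 1, (corner >> 1) & 1, corner & 1])
                w = np.prod(np.where(off, f, 1.0 - f), axis=1)
                idx = i0 + off
                v = v + w * self.values[idx[:, 0], idx[:, 1], idx[:, 2]]
            out[inside] = v
        return out if np.asarray(points).ndim > 1 else out[0]


def mask_and_clamp(grid: ESPGrid, receptor, pocket) -> ESPGrid:
    """Condition a raw potential grid for docking.

    Order of operations (clamp first so the +100 sentinel survives):
    (1) clamp raw values to [-10, +10] kT/e; (2) zero nodes whose centers
    fall inside any receptor atom sphere (protein interior); (3) set nodes
    outside the pocket search box to exactly +100.  Idempotent.

    ``pocket`` is a :class:`~darc.pocket.PocketGrid` or a ``(lo, hi)`` pair.
    """
    bounds = pocket.bounds if hasattr(pocket, "bounds") else pocket
    lo, hi = (np.asarray(b, float) for b in bounds)
    if np.any(lo > grid.upper) or np.any(hi < grid.origin):
        raise UnsupportedGridError(
            "electrostatic grid and pocket box do not overlap")

    v = np.clip(grid.values, -CLAMP_LIMIT, CLAMP_LIMIT)

    # zero inside receptor atoms (per-atom local boxes)
    n = np.array(grid.dims)
    for xyz, r in zip(receptor.coords, receptor.radii):
        i0 = np.maximum(np.floor((xyz - r - grid.origin) / grid.spacing)
                        .astype(int), 0)
        i1 = np.minimum(np.ceil((xyz + r - grid.origin) / grid.spacing)
                        .astype(int), n - 1)
        if np.any(i1 < i0):
            continue
        ax = [np.arange(i0[d], i1[d] + 1) for d in range(3)]
        gx, gy, gz = np.meshgrid(*ax, indexing="ij")
        centers = grid.origin + np.stack([gx, gy, gz], axis=-1) * grid.spacing
        inside = ((centers - xyz) ** 2).sum(axis=-1) <= r * r
        sub = v[i0[0]:i1[0] + 1, i0[1]:i1[1] + 1, i0[2]:i1[2] + 1]
        sub[inside] = 0.0

    nodes = grid.node_coords()
    outside = np.any((nodes < lo) | (nodes > hi), axis=1).reshape(grid.dims)
    v[outside] = OUTSIDE_PENALTY
    return replace(grid, values=v, clamped=True, masked=True,
                   pocket_bounds=(lo, hi))


def electrostatic_sum(grid: ESPGrid, coords: np.ndarray,
                      charges: np.ndarray) -> float:
    """sum(q_i * phi(x_i)); atoms beyond the grid hull contribute q_i * 100."""
    phi = grid.trilinear(np.atleast_2d(coords))
    return float(np.asarray(charges, float) @ phi)


def coulomb_grid(receptor, spacing: float = 0.5, pocket=None,
                 buffer: float = GRID_BUFFER) -> ESPGrid:
    """Screened-Coulomb potential grid: phi(x) = sum_j q_j / (4 max(r, 0.5)^2).

    The distance-dependent dielectric eps = 4r gives the 1/(4 r^2) kernel;
    the grid extends ``buffer`` A beyond the protein extent.  When ``pocket``
    is given the result is masked and clamped ready for scoring.  The
    conditioning path (grid -> clamp -> mask -> interpolate -> sum) is
    identical to that applied to imported Poisson-Boltzmann grids.
    """
    lo = receptor.coords.min(axis=0) - buffer
    hi = receptor.coords.max(axis=0) + buffer
    dims = np.ceil((hi - lo) / spacing).astype(int) + 1
    grid = ESPGrid(origin=lo, spacing=spacing, values=np.zeros(tuple(dims)),
                   meta={"model": "coulomb_eps4r", "inner_dielectric": 1.0,
                         "outer_dielectric": 80.0, "buffer_A": buffer})
    charged = receptor.charges != 0
    if not charged.any():
        warnings.warn("receptor has no charged atoms: electrostatic grid is "
                      "all zeros", stacklevel=2)
    else:
        nodes = grid.node_coords()
        phi = np.zeros(len(nodes))
        for xyz, q in zip(receptor.coords[charged], receptor.charges[charged]):
            r = np.linalg.norm(nodes - xyz, axis=1)
            r = np.maximum(r, _EPS_CAP_R)
            phi += q / (4.0 * r * r)
        grid.values = phi.reshape(tuple(dims))
    if pocket is not None:
        grid = mask_and_clamp(grid, receptor, pocket)
    return grid


def crop_to_box(grid: ESPGrid, lo, hi, pad_cells: int = 1) -> ESPGrid:
    """Extract the subgrid covering [lo, hi] (plus a safety margin of nodes)."""
    lo = np.asarray(lo, float)
    hi = np.asarray(hi, float)
    n = np.array(grid.dims)
    i0 = np.maximum(np.floor((lo - grid.origin) / grid.spacing).astype(int)
                    - pad_cells, 0)
    i1 = np.minimum(np.ceil((hi - grid.origin) / grid.spacing).astype(int)
                    + pad_cells, n - 1)
    if np.any(i1 <= i0):
        raise UnsupportedGridError("crop box does not overlap the grid")
    vals = grid.values[i0[0]:i1[0] + 1, i0[1]:i1[1] + 1, i0[2]:i1[2] + 1]
    return replace(grid, origin=grid.origin + i0 * grid.spacing,
                   values=vals.copy())
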