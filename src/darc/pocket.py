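"""Grid-based surface-pocket detection around user-selected target residues.

The receptor is rasterized onto a regular grid and every cell is classified
as protein INTERIOR (within probe-inflated atom spheres), POCKET (solvent
cells near the target residues that are enclosed by protein along enough scan
axes, in the LIGSITE protein-solvent-protein spirit), a one-cell BOUNDARY
layer just outside the pocket mouth, or bulk SOLVENT.  The pocket center P
and the bounding box of POCKET+BOUNDARY cells (the docking search space)
derive from this classification.  The module is deterministic: no RNG.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

import numpy as np
from scipy.spatial import cKDTree

from .errors import EmptyPocketError
from .model_io import Receptor

PROBE_RADIUS = 1.4        # A, water probe inflating atom spheres
DEFAULT_SPACING = 0.5     # A, matches the electrostatic grid spacing
DEFAULT_NEAR_CUTOFF = 12.0  # A, "near target residues"
DEFAULT_ENCLOSURE = 4     # of the 7 scan axes

#: The 7 LIGSITE scan axes: 3 lattice axes + 4 cube diagonals.
SCAN_AXES = np.array([
    (1, 0, 0), (0, 1, 0), (0, 0, 1),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
])


class CellLabel(IntEnum):
    SOLVENT = 0
    INTERIOR = 1
    POCKET = 2
    BOUNDARY = 3


@dataclass
class PocketGrid:
    origin: np.ndarray        # (3,) corner of cell (0,0,0) center, A
    spacing: float
    labels: np.ndarray        # (nx, ny, nz) uint8 CellLabel values
    center: np.ndarray        # (3,) pocket center P: centroid of POCKET cells
    bounds: tuple             # (lo, hi) of POCKET+BOUNDARY cell centers

    @property
    def dims(self) -> tuple:
        return self.labels.shape

    def cell_centers(self, mask: np.ndarray) -> np.ndarray:
        """Centers of cells selected by a boolean mask, lexicographic order."""
        idx = np.argwhere(mask)
        return self.origin + idx * self.spacing

    def label_at(self, points: np.ndarray) -> np.ndarray:
        """Cell label at arbitrary points; outside the grid counts as SOLVENT."""
        pts = np.atleast_2d(points)
        idx = np.rint((pts - self.origin) / self.spacing).astype(int)
        out = np.full(len(pts), int(CellLabel.SOLVENT), dtype=np.uint8)
        ok = np.all((idx >= 0) & (idx < np.array(self.dims)), axis=1)
        out[ok] = self.labels[idx[ok, 0], idx[ok, 1], idx[ok, 2]]
        return out if points.ndim > 1 else out[0]

    def pocket_volume(self) -> float:
        return float((self.labels == CellLabel.POCKET).sum()) * self.spacing ** 3


def _shift(a: np.ndarray, step) -> np.ndarray:
    """Shift a boolean grid by an integer lattice step, zero-filling."""
    out = a
    for axis, s in enumerate(step):
        s = int(s)
        if s == 0:
            continue
        shifted = np.zeros_like(out)
        if s > 0:
            src = tuple(slice(None) if ax != axis else slice(0, out.shape[axis] - s)
                        for ax in range(3))
            dst = tuple(slice(None) if ax != axis else slice(s, None)
                        for ax in range(3))
        else:
            src = tuple(slice(None) if ax != axis else slice(-s, None)
                        for ax in range(3))
            dst = tuple(slice(None) if ax != axis else slice(0, out.shape[axis] + s)
                        for ax in range(3))
        shifted[dst] = out[src]
        out = shifted
    return out


def _reach(interior: np.ndarray, step: np.ndarray) -> np.ndarray:
    """True where protein exists somewhere along +step from the cell."""
    reach = np.zeros_like(interior)
    frontier = interior
    for _ in range(int(max(interior.shape))):
        frontier = _shift(frontier, step)
        new = frontier & ~reach
        if not new.any():
            break
        reach |= frontier
        frontier = reach
    return reach


def detect_pocket(receptor: Receptor, targets, spacing: float = DEFAULT_SPACING,
                  near_cutoff: float = DEFAULT_NEAR_CUTOFF,
                  enclosure_threshold: int = DEFAULT_ENCLOSURE,
                  near_points: np.ndarray | None = None) -> PocketGrid:
    """Classify a grid around the receptor and extract the target pocket.

    Parameters
    ----------
    targets
        Residue selection (see :meth:`Receptor.atom_mask_for_residues`)
        defining where to look for the pocket.
    spacing
        Grid spacing in (0.25, 2.0] A.
    near_cutoff
        POCKET candidates must lie within this distance of a target atom.
    enclosure_threshold
        Minimum number of the 7 scan axes along which a candidate cell must
        see protein in *both* directions.
    near_points
        Optional explicit points replacing target atoms for the "near" test
        (used to center the grid on a bound ligand instead of residues).
    """
    if not 0.25 < spacing <= 2.0:
        raise ValueError(f"spacing {spacing} outside (0.25, 2.0] A")
    if near_points is None:
        mask = receptor.atom_mask_for_residues(targets)
        near_points = receptor.coords[mask]
    near_points = np.atleast_2d(np.asarray(near_points, dtype=float))

    pad = receptor.radii.max() + PROBE_RADIUS + 2 * spacing
    lo = receptor.coords.min(axis=0) - pad
    hi = receptor.coords.max(axis=0) + pad
    dims = np.ceil((hi - lo) / spacing).astype(int) + 1
    origin = lo

    interior = np.zeros(tuple(dims), dtype=bool)
    # per-atom local boxes: cells within (radius + probe) of the atom center
    for xyz, r in zip(receptor.coords, receptor.radii):
        rr = r + PROBE_RADIUS
        i0 = np.maximum(np.floor((xyz - rr - origin) / spacing).astype(int), 0)
        i1 = np.minimum(np.ceil((xyz + rr - origin) / spacing).astype(int), dims - 1)
        ax = [np.arange(i0[d], i1[d] + 1) for d in range(3)]
        gx, gy, gz = np.meshgrid(*ax, indexing="ij")
        centers = origin + np.stack([gx, gy, gz], axis=-1) * spacing
        d2 = ((centers - xyz) ** 2).sum(axis=-1)
        sub = interior[i0[0]:i1[0] + 1, i0[1]:i1[1] + 1, i0[2]:i1[2] + 1]
        sub |= d2 <= rr * rr

    # enclosure count over the 7 scan axes (protein on both sides)
    enclosed = np.zeros(tuple(dims), dtype=np.int8)
    for axis in SCAN_AXES:
        fwd = _reach(interior, axis)
        bwd = _reach(interior, -axis)
        enclosed += (fwd & bwd).astype(np.int8)

    # near-target restriction
    idx = np.indices(tuple(dims)).reshape(3, -1).T
    centers = origin + idx * spacing
    tree = cKDTree(near_points)
    near = np.zeros(len(centers), dtype=bool)
    cand = ~interior.ravel() & (enclosed.ravel() >= enclosure_threshold)
    if cand.any():
        d, _ = tree.query(centers[cand], k=1)
        near_sub = d <= near_cutoff
        near[np.flatnonzero(cand)[near_sub]] = True
    pocket = near.reshape(tuple(dims))

    labels = np.full(tuple(dims), int(CellLabel.SOLVENT), dtype=np.uint8)
    labels[interior] = CellLabel.INTERIOR
    labels[pocket] = CellLabel.POCKET
    if not pocket.any():
        raise EmptyPocketError(
            "no pocket cells found near the target selection; try different "
            "target residues or a lower enclosure threshold")

    # one-cell BOUNDARY shell: solvent cells 26-adjacent to POCKET
    adj = _dilate26(pocket)
    boundary = adj & (labels == CellLabel.SOLVENT)
    labels[boundary] = CellLabel.BOUNDARY

    pocket_centers = origin + np.argwhere(pocket) * spacing
    center = pocket_centers.mean(axis=0)
    both = pocket | boundary
    both_centers = origin + np.argwhere(both) * spacing
    bounds = (both_centers.min(axis=0), both_centers.max(axis=0))
    return PocketGrid(origin=origin, spacing=spacing, labels=labels,
                      center=center, bounds=bounds)


def _dilate26(mask: np.ndarray) -> np.ndarray:
    out = np.zeros_like(mask)
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if dx == dy == dz == 0:
                    continue
                out |= _shift(mask, (dx, dy, dz))
    return out


def _adjacent26_to(labels: np.ndarray, which: int) -> np.ndarray:
    return _dilate26(labels == which)


def shell_points(grid: PocketGrid) -> np.ndarray:
    """Centers of POCKET cells that touch the protein wall (26-adjacency).

    Ordering is deterministic: lexicographic by cell index.  These are the
    ray-casting targets describing the pocket topography.
    """
    if not (grid.labels == CellLabel.POCKET).any():
        raise EmptyPocketError("grid has no POCKET cells")
    near_interior = _adjacent26_to(grid.labels, int(CellLabel.INTERIOR))
    mask = (grid.labels == CellLabel.POCKET) & near_interior
    return grid.cell_centers(mask)


def boundary_points(grid: PocketGrid) -> np.ndarray:
    """Centers of BOUNDARY cells (the layer outside the pocket mouth)."""
    return grid.cell_centers(grid.labels == CellLabel.BOUNDARY)
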