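"""High-level pipeline helpers shared by the CLI and programmatic users.

The two-step protocol: (1) detect the pocket, place the vantage point(s) and
build the ray map; (2) dock a conformer ensemble against the ray map (with
an optional conditioned electrostatic grid).
"""

from __future__ import annotations

import numpy as np

from .docking import DockResult, dock_sequential, optimize
from .electrostatics import ESPGrid, crop_to_box, mask_and_clamp
from .errors import DarcError
from .model_io import ConformerSet, Receptor
from .pocket import (DEFAULT_ENCLOSURE, DEFAULT_NEAR_CUTOFF, DEFAULT_SPACING,
                     PocketGrid, boundary_points, detect_pocket, shell_points)
from .raycast import (RayMap, build_ray_map, expand_origins,
                      place_primary_origin, single_origin_set)
from .scoring import (ORIGINAL_WEIGHTS, REFIT_ES_WEIGHTS, REFIT_SHAPE_WEIGHTS,
                      WeightSet)


def default_weights(with_electrostatics: bool) -> WeightSet:
    """Preset weights: the rank-fit set matching the electrostatics toggle."""
    return REFIT_ES_WEIGHTS if with_electrostatics else REFIT_SHAPE_WEIGHTS


WEIGHT_PRESETS = {"original": ORIGINAL_WEIGHTS,
                  "shape": REFIT_SHAPE_WEIGHTS,
                  "es": REFIT_ES_WEIGHTS}


def make_rays(receptor: Receptor, targets, spacing: float = DEFAULT_SPACING,
              multiple_origins: bool = False, origin_method: str = "com",
              residue=None, seed: int = 0,
              near_cutoff: float = DEFAULT_NEAR_CUTOFF,
              enclosure_threshold: int = DEFAULT_ENCLOSURE,
              near_points=None) -> tuple[RayMap, PocketGrid]:
    """Pocket detection -> origin placement -> ray map."""
    grid = detect_pocket(receptor, targets, spacing=spacing,
                         near_cutoff=near_cutoff,
                         enclosure_threshold=enclosure_threshold,
                         near_points=near_points)
    o1 = place_primary_origin(receptor, grid, method=origin_method,
                              residue=residue)
    if multiple_origins:
        origins = expand_origins(o1, grid.center, rng_seed=seed,
                                 method=origin_method)
    else:
        origins = single_origin_set(o1, grid.center, method=origin_method)
    raymap = build_ray_map(shell_points(grid), boundary_points(grid),
                           origins, bounds=grid.bounds)
    return raymap, grid


def prepare_esp_grid(grid: ESPGrid, receptor: Receptor, raymap: RayMap,
                     pad: float = 1.0) -> ESPGrid:
    """Crop an imported potential grid to the pocket search box and condition
    it (clamp, interior zero, outside penalty)."""
    lo, hi = (np.asarray(b, float) for b in raymap.bounds)
    cropped = crop_to_box(grid, lo - pad, hi + pad)
    return mask_and_clamp(cropped, receptor, (lo, hi))


def check_grid_matches(raymap: RayMap, grid: ESPGrid, tol: float = 1e-4) -> None:
    """A conditioned grid must have been masked to this ray map's pocket box."""
    if grid.pocket_bounds is None:
        raise DarcError("electrostatic grid has not been masked to a pocket "
                        "box; run make-rays with --add-electrostatics")
    lo, hi = (np.asarray(b, float) for b in raymap.bounds)
    glo, ghi = (np.asarray(b, float) for b in grid.pocket_bounds)
    if np.abs(glo - lo).max() > tol or np.abs(ghi - hi).max() > tol:
        raise DarcError("ray-file and electrostatic grid disagree on the "
                        "pocket box; regenerate them together")


def dock(raymap: RayMap, conformers: ConformerSet, espgrid: ESPGrid | None = None,
         weights: WeightSet | None = None, search_conformers: bool = False,
         n_particles: int = 100, n_steps: int = 100, seed: int = 0) -> DockResult:
    """Run the docking protocol chosen by ``search_conformers``.

    On-the-fly mode runs one trajectory with the conformer coordinate free;
    otherwise the sequential legacy protocol docks each conformer separately.
    """
    if weights is None:
        weights = default_weights(espgrid is not None)
    if espgrid is not None:
        check_grid_matches(raymap, espgrid)
    if search_conformers:
        return optimize(raymap, conformers, weights, espgrid=espgrid,
                        n_particles=n_particles, n_steps=n_steps, seed=seed,
                        mode="on_the_fly")
    return dock_sequential(raymap, conformers, weights, espgrid=espgrid,
                           n_particles=n_particles, n_steps=n_steps, seed=seed)
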