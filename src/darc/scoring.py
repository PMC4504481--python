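"""The ray-casting complementarity score and its component decomposition.

Per ray, the shape score compares the distance at which the ray meets the
pocket shell (rho_pocket) with the distance at which it first meets the
ligand surface (rho_ligand):

* pocket hit before ligand  -> underpacking, weighted by c1 (fixed at 1.00);
* ligand hit before pocket  -> steric clash, weighted by c2;
* pocket hit, ligand missed -> ligand too small, count weighted by c3;
* boundary ray hits ligand  -> ligand outside the pocket, count weighted by c4.

Because each weight applies to one disjoint group of rays, the four
unweighted group sums (plus the unweighted electrostatic sum, weighted by
c5) fully determine the score for *any* weights -- the decomposition that
makes rank-based weight fitting cheap.  Boundary rays that also miss the
ligand contribute nothing (the alternative reading, a pose-independent
constant per such ray, would not affect pose ranking).

Note on units: the c1/c2 terms scale Angstrom sums while c3/c4 scale
dimensionless ray counts; the weights absorb the mixed units.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .raycast import RADIUS_SCALE, RayMap, rho_ligand_batch


@dataclass(frozen=True)
class ScoreComponents:
    """The five unweighted score terms of one pose (the caching unit)."""

    underpack_sum: float        # A
    clash_sum: float            # A
    missed_ligand_count: int    # rays hitting pocket but not ligand
    outside_pocket_count: int   # boundary rays hitting the ligand
    es_sum: float = 0.0         # sum(q_i * phi_i), kT/e * e

    def as_array(self) -> np.ndarray:
        return np.array([self.underpack_sum, self.clash_sum,
                         float(self.missed_ligand_count),
                         float(self.outside_pocket_count), self.es_sum])


@dataclass(frozen=True)
class WeightSet:
    """Scoring weights; c1 is fixed at 1.00 because uniform scaling of all
    weights only rescales the total score (pose ranking is unchanged)."""

    c2: float
    c3: float
    c4: float
    c5: float = 0.0
    c1: float = 1.0

    def __post_init__(self) -> None:
        if self.c1 != 1.0:
            raise ValueError("c1 is fixed at 1.00")
        if min(self.c2, self.c3, self.c4) < 0:
            raise ValueError("weights must be non-negative")

    def as_vector(self) -> np.ndarray:
        return np.array([self.c1, self.c2, self.c3, self.c4, self.c5])


#: Weights of the original (2013) shape-only parameterization.
ORIGINAL_WEIGHTS = WeightSet(c2=3.12, c3=13.32, c4=8.13)
#: Rank-fit weights, shape terms only.
REFIT_SHAPE_WEIGHTS = WeightSet(c2=1.7, c3=4.2, c4=4.4)
#: Rank-fit weights including the electrostatic term.
REFIT_ES_WEIGHTS = WeightSet(c2=1.6, c3=2.0, c4=0.8, c5=0.025)

#: Legacy flag-name aliases for the weights.
FLAG_ALIASES = {"steric_weight": "c2", "missing_point_weight": "c3",
                "extra_point_weight": "c4", "esp_weight": "c5"}


def shape_components(rho_pocket: np.ndarray,
                     rho_ligand: np.ndarray) -> ScoreComponents:
    """Reduce paired per-ray distances to the four shape terms.

    NaN in ``rho_pocket`` marks a BOUNDARY ray, NaN in ``rho_ligand`` a MISS.
    """
    rho_pocket = np.asarray(rho_pocket, float)
    rho_ligand = np.asarray(rho_ligand, float)
    if rho_pocket.shape != rho_ligand.shape:
        raise ValueError("rho_pocket and rho_ligand must be paired per ray")
    comp = components_batch(rho_pocket, rho_ligand[None])[0]
    return ScoreComponents(underpack_sum=float(comp[0]), clash_sum=float(comp[1]),
                           missed_ligand_count=int(comp[2]),
                           outside_pocket_count=int(comp[3]))


def components_batch(rho_pocket: np.ndarray,
                     rho_ligand: np.ndarray) -> np.ndarray:
    """(P, 5) unweighted shape components for P poses (es column zero)."""
    rho_ligand = np.atleast_2d(rho_ligand)
    pocket = np.isfinite(rho_pocket)[None]
    lig = np.isfinite(rho_ligand)
    diff = np.where(pocket & lig, rho_ligand - rho_pocket[None], 0.0)
    under = np.where(diff > 0, diff, 0.0).sum(axis=1)
    clash = np.where(diff < 0, -diff, 0.0).sum(axis=1)
    missed = (pocket & ~lig).sum(axis=1)
    outside = (~pocket & lig).sum(axis=1)
    out = np.zeros((len(rho_ligand), 5))
    out[:, 0], out[:, 1], out[:, 2], out[:, 3] = under, clash, missed, outside
    return out


def shape_score(comp: ScoreComponents, w: WeightSet) -> float:
    """Weighted shape score from cached components (equals the per-ray sum)."""
    return (w.c1 * comp.underpack_sum + w.c2 * comp.clash_sum
            + w.c3 * comp.missed_ligand_count
            + w.c4 * comp.outside_pocket_count)


def darc_score(comp: ScoreComponents, w: WeightSet) -> float:
    """Shape score plus the weighted electrostatic sum."""
    return shape_score(comp, w) + w.c5 * comp.es_sum


def with_es(comp: ScoreComponents, es_sum: float) -> ScoreComponents:
    return replace(comp, es_sum=float(es_sum))


class RayScorer:
    """Batched pose scorer bound to one ray map (and optional ESP grid).

    Precomputes per-ray origins/directions once; scoring a batch of poses is
    then a handful of vectorized array operations.  This is the single score
    path used by docking, decoy generation and the acceptance checks.
    """

    def __init__(self, raymap: RayMap, espgrid=None,
                 radius_scale: float = RADIUS_SCALE):
        if raymap.n_rays == 0:
            raise ValueError("empty ray map")
        self.raymap = raymap
        self.espgrid = espgrid
        self.radius_scale = radius_scale
        self._origins = raymap.ray_origins()
        self._dirs = raymap.ray_dirs()
        self._rho_pocket = raymap.rho_pocket
        self.n_evaluations = 0  # pose-score bookkeeping

    def components(self, poses: np.ndarray, radii: np.ndarray,
                   charges: np.ndarray | None = None) -> np.ndarray:
        """(P, 5) components for poses of shape (P, A, 3) (or (A, 3))."""
        poses = np.asarray(poses, float)
        squeeze = poses.ndim == 2
        if squeeze:
            poses = poses[None]
        rho_lig = rho_ligand_batch(self._origins, self._dirs, poses, radii,
                                   self.radius_scale)
        comp = components_batch(self._rho_pocket, rho_lig)
        if self.espgrid is not None and charges is not None \
                and np.any(charges != 0):
            phi = self.espgrid.trilinear(poses.reshape(-1, 3))
            phi = phi.reshape(poses.shape[0], poses.shape[1])
            comp[:, 4] = phi @ np.asarray(charges, float)
        self.n_evaluations += len(poses)
        return comp[0] if squeeze else comp

    def score(self, poses: np.ndarray, radii: np.ndarray, weights: WeightSet,
              charges: np.ndarray | None = None):
        poses = np.asarray(poses, float)
        squeeze = poses.ndim == 2
        comp = np.atleast_2d(self.components(poses, radii, charges))
        s = comp @ weights.as_vector()
        return float(s[0]) if squeeze else s

    def components_single(self, pose: np.ndarray, radii: np.ndarray,
                          charges: np.ndarray | None = None) -> ScoreComponents:
        c = self.components(np.asarray(pose, float)[None], radii, charges)[0]
        return ScoreComponents(underpack_sum=float(c[0]), clash_sum=float(c[1]),
                               missed_ligand_count=int(c[2]),
                               outside_pocket_count=int(c[3]),
                               es_sum=float(c[4]))
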