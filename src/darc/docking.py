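"""Pose optimization: particle-swarm minimization of the complementarity score.

A candidate solution is a 7-vector: rigid-body translation (dx, dy, dz, A),
rotation as Euler angles (rx, ry, rz, rad, about the ligand centroid, ZYX
composition), and a continuous "conformer coordinate" kappa that rounds to
the index of one pre-generated ligand conformer.  Decoding centers the
chosen conformer on a reference point, rotates, then translates, so the zero
vector with kappa = 1 reproduces the reference conformer at the reference
point.

The swarm is the standard global-best form with constriction-style
coefficients (inertia 0.7298, cognitive = social = 1.49618), velocities
clamped to half the per-dimension range, translations and kappa reflected at
their bounds and angles wrapped modulo 2*pi.  All randomness flows from the
single input seed.  In ``fixed_conformer`` mode kappa is frozen, which is
also the building block of the legacy sequential-conformer protocol.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import DarcError
from .model_io import ConformerSet
from .raycast import RADIUS_SCALE, RayMap
from .scoring import RayScorer, ScoreComponents, WeightSet

INERTIA = 0.7298
ACCEL = 1.49618  # cognitive and social acceleration

N_PARTICLES_DEFAULT = 100
N_STEPS_DEFAULT = 100


@dataclass
class DockResult:
    pose: np.ndarray                 # (A, 3) best ligand coordinates
    score: float
    components: ScoreComponents
    conformer_index: int             # 1-based
    position: np.ndarray             # the winning 7-vector
    trajectory: np.ndarray           # per-step best-so-far score
    seed: int
    settings: dict = field(default_factory=dict)
    per_conformer: list = field(default_factory=list)  # sequential-mode log


def decode(position: np.ndarray, conformers: ConformerSet,
           reference_centroid: np.ndarray) -> tuple[np.ndarray, int]:
    """Decode one 7-vector into ligand coordinates and its conformer index."""
    pose, idx = decode_batch(np.asarray(position, float)[None], conformers,
                             reference_centroid)
    return pose[0], int(idx[0])


def decode_batch(positions: np.ndarray, conformers: ConformerSet,
                 reference_centroid: np.ndarray):
    """Vectorized decode of (P, 7) positions -> (P, A, 3) poses, (P,) indices.

    kappa rounds half-up and clamps to [1, n_conformers]."""
    positions = np.atleast_2d(np.asarray(positions, float))
    n = conformers.n_conformers
    idx = np.clip(np.floor(positions[:, 6] + 0.5).astype(int), 1, n)
    centered = conformers.coords - conformers.coords.mean(axis=1, keepdims=True)
    sel = centered[idx - 1]                              # (P, A, 3)
    # Rz(rz) @ Ry(ry) @ Rx(rx)
    rot = Rotation.from_euler(
        "zyx", positions[:, [5, 4, 3]]).as_matrix()      # (P, 3, 3)
    rotated = np.einsum("pij,paj->pai", rot, sel)
    ref = np.asarray(reference_centroid, float)
    return rotated + ref + positions[:, None, 0:3], idx


def rmsd(pose_a: np.ndarray, pose_b: np.ndarray,
         elements: list[str] | None = None) -> float:
    """Heavy-atom RMSD in the shared receptor frame (no superposition,
    no symmetry correction)."""
    a = np.asarray(pose_a, float)
    b = np.asarray(pose_b, float)
    if a.shape != b.shape:
        raise DarcError("poses must share atom count and ordering")
    if elements is not None:
        heavy = np.array([e.upper() != "H" for e in elements])
        a, b = a[heavy], b[heavy]
    return float(np.sqrt(((a - b) ** 2).sum(axis=1).mean()))


def pso_minimize(objective, bounds: np.ndarray, n_particles: int,
                 n_steps: int, seed, wrap_mask=None, frozen: dict | None = None):
    """Global-best PSO over a box.  ``objective`` maps (P, D) -> (P,) scores.

    ``wrap_mask`` marks periodic dimensions (wrapped modulo their range);
    the rest reflect at the bounds.  ``frozen`` pins dimensions to values.
    Returns (best_position, best_value, per-step best trace).
    """
    if n_particles < 1 or n_steps < 1:
        raise ValueError("n_particles and n_steps must be >= 1")
    bounds = np.asarray(bounds, float)
    lo, hi = bounds[:, 0], bounds[:, 1]
    span = hi - lo
    dim = len(lo)
    wrap = np.zeros(dim, bool) if wrap_mask is None else np.asarray(wrap_mask)
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)

    x = lo + rng.random((n_particles, dim)) * span
    vmax = 0.5 * span
    v = (rng.random((n_particles, dim)) * 2 - 1) * vmax
    if frozen:
        for d, val in frozen.items():
            x[:, d] = val
            v[:, d] = 0.0

    f = objective(x)
    pbest_x = x.copy()
    pbest_f = f.copy()
    g = int(np.argmin(f))
    gbest_x = x[g].copy()
    gbest_f = float(f[g])
    trace = [gbest_f]

    # attraction uses plain coordinate differences, also for the periodic
    # angle dims: pulling along the chart (rather than the shortest arc)
    # keeps the swarm in one Euler representation of each rotation, which
    # converges measurably better than per-angle shortest-arc pulls
    for _ in range(n_steps):
        r1 = rng.random((n_particles, dim))
        r2 = rng.random((n_particles, dim))
        v = (INERTIA * v + ACCEL * r1 * (pbest_x - x)
             + ACCEL * r2 * (gbest_x - x))
        np.clip(v, -vmax, vmax, out=v)
        x = x + v
        # reflect non-periodic dims at the box; wrap periodic ones
        for _pass in range(2):  # two passes cover overshoot past both walls
            low = ~wrap & (x < lo)
            x[low] = (2 * lo - x)[low]
            v[low] = -v[low]
            high = ~wrap & (x > hi)
            x[high] = (2 * hi - x)[high]
            v[high] = -v[high]
        nw = ~wrap
        x[:, nw] = np.clip(x[:, nw], lo[nw], hi[nw])  # guard residual overshoot
        if wrap.any():
            xw = x[:, wrap]
            x[:, wrap] = np.mod(xw - lo[wrap], span[wrap]) + lo[wrap]
        if frozen:
            for d, val in frozen.items():
                x[:, d] = val
                v[:, d] = 0.0
        f = objective(x)
        better = f < pbest_f
        pbest_x[better] = x[better]
        pbest_f[better] = f[better]
        g = int(np.argmin(pbest_f))
        if pbest_f[g] < gbest_f:
            gbest_f = float(pbest_f[g])
            gbest_x = pbest_x[g].copy()
        trace.append(gbest_f)
    return gbest_x, gbest_f, np.array(trace)


def _search_bounds(raymap: RayMap, conformers: ConformerSet,
                   reference_centroid: np.ndarray) -> np.ndarray:
    lo, hi = (np.asarray(b, float) for b in raymap.bounds)
    ref = np.asarray(reference_centroid, float)
    b = np.empty((7, 2))
    b[0:3, 0] = lo - ref
    b[0:3, 1] = hi - ref
    b[3:6, 0] = -np.pi
    b[3:6, 1] = np.pi
    b[6] = (1.0, float(conformers.n_conformers))
    if conformers.n_conformers == 1:
        b[6] = (1.0, 1.0 + 1e-9)
    return b


def optimize(raymap: RayMap, conformers: ConformerSet, weights: WeightSet,
             espgrid=None, n_particles: int = N_PARTICLES_DEFAULT,
             n_steps: int = N_STEPS_DEFAULT, seed: int = 0,
             mode: str = "on_the_fly", fixed_conformer_index: int = 1,
             radius_scale: float = RADIUS_SCALE,
             reference_centroid=None, scorer: RayScorer | None = None) -> DockResult:
    """Minimize the complementarity score over ligand placement.

    ``mode="on_the_fly"`` searches the conformer coordinate alongside the six
    rigid-body degrees of freedom; ``mode="fixed_conformer"`` freezes it at
    ``fixed_conformer_index``.  Deterministic for a fixed seed; the returned
    best-ever pose re-scores to exactly the reported score.
    """
    if mode not in ("on_the_fly", "fixed_conformer"):
        raise DarcError(f"unknown mode {mode!r}")
    if raymap.n_rays == 0:
        raise DarcError("empty ray map")
    if scorer is None:
        scorer = RayScorer(raymap, espgrid=espgrid, radius_scale=radius_scale)
    ref = raymap.pocket_center if reference_centroid is None \
        else np.asarray(reference_centroid, float)
    bounds = _search_bounds(raymap, conformers, ref)
    wrap = np.array([False] * 3 + [True] * 3 + [False])
    frozen = {6: float(fixed_conformer_index)} if mode == "fixed_conformer" \
        else None

    def objective(positions):
        poses, _ = decode_batch(positions, conformers, ref)
        return scorer.score(poses, conformers.radii, weights,
                            conformers.charges)

    best_x, best_f, trace = pso_minimize(objective, bounds, n_particles,
                                         n_steps, seed, wrap_mask=wrap,
                                         frozen=frozen)
    pose, conf_idx = decode(best_x, conformers, ref)
    comp = scorer.components_single(pose, conformers.radii, conformers.charges)
    from .scoring import darc_score
    return DockResult(pose=pose, score=darc_score(comp, weights),
                      components=comp, conformer_index=conf_idx,
                      position=best_x, trajectory=trace, seed=int(seed),
                      settings={"mode": mode, "n_particles": n_particles,
                                "n_steps": n_steps,
                                "radius_scale": radius_scale,
                                "weights": weights.as_vector().tolist(),
                                "n_evaluations": scorer.n_evaluations})


def dock_sequential(raymap: RayMap, conformers: ConformerSet,
                    weights: WeightSet, espgrid=None,
                    n_particles: int = N_PARTICLES_DEFAULT,
                    n_steps: int = N_STEPS_DEFAULT, seed: int = 0,
                    radius_scale: float = RADIUS_SCALE,
                    reference_centroid=None) -> DockResult:
    """Legacy protocol: one fixed-conformer trajectory per conformer,
    best overall wins.  Each trajectory gets an independent derived seed."""
    results = []
    for k in range(1, conformers.n_conformers + 1):
        sub_seed = int((seed * 7919 + k) % (2 ** 31))
        res = optimize(raymap, conformers, weights, espgrid=espgrid,
                       n_particles=n_particles, n_steps=n_steps,
                       seed=sub_seed, mode="fixed_conformer",
                       fixed_conformer_index=k, radius_scale=radius_scale,
                       reference_centroid=reference_centroid)
        results.append(res)
    best = min(results, key=lambda r: r.score)
    best.seed = int(seed)
    best.per_conformer = [(r.conformer_index, r.score) for r in results]
    best.settings = dict(best.settings, mode="sequential",
                         n_evaluations=sum(r.settings["n_evaluations"]
                                           for r in results))
    return best


def convergence_curve(raymap: RayMap, conformers: ConformerSet,
                      weights: WeightSet, budgets, seeds, espgrid=None,
                      gold=(1000, 1000), gold_seed: int = 10_007,
                      mode: str = "on_the_fly"):
    """Mean score gap to a gold-standard score as the budget grows.

    The gold standard is the sequential protocol at an intensive budget
    (particles, steps); each entry of ``budgets`` is a single number b used
    as both particle count and step count, averaged over ``seeds``.
    Returns (gold_score, list of (budget, mean_gap)).
    """
    if list(budgets) != sorted(budgets):
        raise ValueError("budgets must be ascending")
    gold_res = dock_sequential(raymap, conformers, weights, espgrid=espgrid,
                               n_particles=gold[0], n_steps=gold[1],
                               seed=gold_seed)
    rows = []
    for b in budgets:
        gaps = []
        for s in seeds:
            if mode == "sequential":
                res = dock_sequential(raymap, conformers, weights,
                                      espgrid=espgrid, n_particles=b,
                                      n_steps=b, seed=int(s))
            else:
                res = optimize(raymap, conformers, weights, espgrid=espgrid,
                               n_particles=b, n_steps=b, seed=int(s),
                               mode=mode)
            gaps.append(res.score - gold_res.score)
        rows.append((b, float(np.mean(gaps))))
    return gold_res.score, rows
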