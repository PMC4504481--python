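"""Rank-based fitting of the scoring weights.

Because the score is linear in its weights given the per-pose component
sums, a large library of randomly placed "decoy" poses can be reduced once
to cached components; re-scoring the whole library under new weights is then
a matrix-vector product.  The fitting objective is the sum over targets of
the rank of each target's native pose among all of that target's poses
(rank 1 = lowest score; ties take the average rank), i.e. the weights are
trained to discriminate natives from decoys, the virtual-screening task.

Minimization uses Nelder-Mead simplex in log-weight space (positivity for
free), with a few seeded jittered restarts because the objective is
piecewise constant in the weights.  Leave-one-out cross-validation over
targets reports the mean and spread of the weights and the held-out native
ranks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation
from scipy.stats import rankdata

from .errors import DarcError
from .model_io import ConformerSet
from .raycast import RADIUS_SCALE, RayMap
from .scoring import RayScorer, WeightSet

_COMP_COLS = ("underpack", "clash", "missed", "outside", "es")


@dataclass
class ComponentCache:
    """Cached unweighted score components for native and decoy poses."""

    target_ids: list                 # unique target labels
    row_target: np.ndarray           # (n,) index into target_ids
    pose_ids: list                   # (n,) pose labels
    is_native: np.ndarray            # (n,) bool
    comps: np.ndarray                # (n, 5)

    def __post_init__(self) -> None:
        self.row_target = np.asarray(self.row_target, int)
        self.is_native = np.asarray(self.is_native, bool)
        self.comps = np.asarray(self.comps, float)

    @property
    def n_targets(self) -> int:
        return len(self.target_ids)

    def validate(self) -> None:
        for t in range(self.n_targets):
            rows = self.row_target == t
            natives = (self.is_native & rows).sum()
            if natives != 1:
                raise DarcError(f"target {self.target_ids[t]!r}: expected "
                                f"exactly one native row, found {natives}")
            if (rows & ~self.is_native).sum() < 1:
                raise DarcError(f"target {self.target_ids[t]!r}: no decoy rows")

    def has_electrostatics(self) -> bool:
        return bool(np.any(self.comps[:, 4] != 0))

    def subset_excluding(self, target_id) -> "ComponentCache":
        t = self.target_ids.index(target_id)
        keep = self.row_target != t
        old_new = {old: new for new, old in
                   enumerate(i for i in range(self.n_targets) if i != t)}
        return ComponentCache(
            target_ids=[x for x in self.target_ids if x != target_id],
            row_target=np.array([old_new[v] for v in self.row_target[keep]]),
            pose_ids=[p for p, k in zip(self.pose_ids, keep) if k],
            is_native=self.is_native[keep], comps=self.comps[keep])

    # TSV interchange: pose id, target id, is_native, five component values
    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("pose_id\ttarget_id\tis_native\t"
                     + "\t".join(_COMP_COLS) + "\n")
            for i in range(len(self.pose_ids)):
                fh.write("\t".join([
                    str(self.pose_ids[i]),
                    str(self.target_ids[self.row_target[i]]),
                    "1" if self.is_native[i] else "0",
                    *(f"{v:.10g}" for v in self.comps[i])]) + "\n")

    @classmethod
    def from_tsv(cls, path) -> "ComponentCache":
        target_ids: list = []
        row_target, pose_ids, is_native, comps = [], [], [], []
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("pose_id\ttarget_id"):
                raise DarcError(f"{path}: not a component cache TSV")
            for lineno, line in enumerate(fh, 2):
                if not line.strip():
                    continue
                parts = line.rstrip("\n").split("\t")
                if len(parts) != 8:
                    raise DarcError(f"{path}: row {lineno}: expected 8 "
                                    f"columns, got {len(parts)}")
                try:
                    native = {"0": False, "1": True}[parts[2]]
                    vals = [float(v) for v in parts[3:8]]
                except (KeyError, ValueError) as exc:
                    raise DarcError(f"{path}: row {lineno}: {exc}") from exc
                if parts[1] not in target_ids:
                    target_ids.append(parts[1])
                row_target.append(target_ids.index(parts[1]))
                pose_ids.append(parts[0])
                is_native.append(native)
                comps.append(vals)
        return cls(target_ids=target_ids, row_target=np.array(row_target),
                   pose_ids=pose_ids, is_native=np.array(is_native),
                   comps=np.array(comps))


@dataclass
class FitReport:
    weights: WeightSet
    objective: float                       # sum of native ranks at `weights`
    per_target_rank: dict
    trace: np.ndarray                      # best objective per iteration
    include_es: bool
    holdout_weights: list = field(default_factory=list)   # LOOCV fits
    holdout_ranks: dict = field(default_factory=dict)
    weight_mean: dict = field(default_factory=dict)
    weight_sd: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        w = self.weights
        return {"weights": {"c1": w.c1, "c2": w.c2, "c3": w.c3, "c4": w.c4,
                            "c5": w.c5},
                "objective": self.objective,
                "per_target_rank": self.per_target_rank,
                "include_es": self.include_es,
                "holdout_ranks": self.holdout_ranks,
                "weight_mean": self.weight_mean,
                "weight_sd": self.weight_sd,
                "n_iterations": int(len(self.trace))}


def random_rotation_matrices(n: int, rng: np.random.Generator) -> np.ndarray:
    """n rotation matrices drawn uniformly (Haar) on SO(3)."""
    return Rotation.random(n, random_state=rng).as_matrix()


def generate_decoy_poses(raymap: RayMap, ligand_library: list[ConformerSet],
                         n_poses: int, seed: int, espgrid=None,
                         radius_scale: float = RADIUS_SCALE,
                         target_id: str = "target") -> list:
    """Uniform random placements of each library ligand, reduced to components.

    Translation is uniform over the search box, orientation Haar-uniform,
    conformer choice uniform.  Returns ``(pose_id, comps)`` rows; seeded and
    reproducible.
    """
    if n_poses < 1:
        raise ValueError("n_poses must be >= 1")
    rng = np.random.default_rng(seed)
    scorer = RayScorer(raymap, espgrid=espgrid, radius_scale=radius_scale)
    lo, hi = (np.asarray(b, float) for b in raymap.bounds)
    rows = []
    for lig in ligand_library:
        centered = lig.coords - lig.coords.mean(axis=1, keepdims=True)
        conf_idx = rng.integers(0, lig.n_conformers, size=n_poses)
        rots = random_rotation_matrices(n_poses, rng)
        trans = lo + rng.random((n_poses, 3)) * (hi - lo)
        poses = np.einsum("pij,paj->pai", rots, centered[conf_idx]) \
            + trans[:, None, :]
        comps = scorer.components(poses, lig.radii, lig.charges)
        for j in range(n_poses):
            rows.append((f"{target_id}:{lig.name}:{j}", comps[j]))
    return rows


def rank_objective(w: WeightSet, cache: ComponentCache) -> float:
    """Sum over targets of the native pose's rank (1 = best, ties averaged)."""
    scores = cache.comps @ w.as_vector()
    total = 0.0
    for t in range(cache.n_targets):
        rows = cache.row_target == t
        r = rankdata(scores[rows], method="average")
        total += float(r[cache.is_native[rows]][0])
    return total


def _ranks_per_target(w: WeightSet, cache: ComponentCache) -> dict:
    scores = cache.comps @ w.as_vector()
    out = {}
    for t in range(cache.n_targets):
        rows = cache.row_target == t
        r = rankdata(scores[rows], method="average")
        out[str(cache.target_ids[t])] = float(r[cache.is_native[rows]][0])
    return out


def _weights_from_log(logw: np.ndarray, include_es: bool) -> WeightSet:
    w = np.exp(logw)
    return WeightSet(c2=w[0], c3=w[1], c4=w[2],
                     c5=w[3] if include_es else 0.0)


def fit_weights(cache: ComponentCache, init: WeightSet | None = None,
                max_iter: int = 400, tol: float = 1e-3,
                include_es: bool | None = None, n_restarts: int = 3,
                restart_seed: int = 0) -> FitReport:
    """Nelder-Mead minimization of the sum-of-ranks objective, c1 fixed at 1.

    The search runs in log-space over (c2, c3, c4) and, when the cache
    carries electrostatic sums, c5.  Deterministic given ``init`` and
    ``restart_seed``; the best point across the init and the jittered
    restarts is returned, so the fitted objective never exceeds the init's.
    """
    cache.validate()
    if include_es is None:
        include_es = cache.has_electrostatics()
    if init is None:
        init = REFITTED_DEFAULT_INIT_ES if include_es else REFITTED_DEFAULT_INIT
    c5 = init.c5 if init.c5 > 0 else 0.01
    x0 = np.log([init.c2, init.c3, init.c4] + ([c5] if include_es else []))

    trace = []
    best = {"obj": rank_objective(init, cache),
            "w": init if not include_es or init.c5 > 0
            else WeightSet(c2=init.c2, c3=init.c3, c4=init.c4, c5=c5)}

    def fun(logw):
        obj = rank_objective(_weights_from_log(logw, include_es), cache)
        if obj < best["obj"]:
            best["obj"] = obj
            best["w"] = _weights_from_log(logw, include_es)
        trace.append(best["obj"])
        return obj

    rng = np.random.default_rng(restart_seed)
    # restarts are centered on the neutral unit-weight point rather than the
    # init: a degenerate init can sit on a plateau of the rank objective
    # whose neighborhood is entirely flat
    starts = [x0] + [rng.normal(0.0, 1.0, size=len(x0))
                     for _ in range(max(0, n_restarts - 1))]
    for s in starts:
        # the objective is piecewise constant; a wide initial simplex lets
        # the search step across plateaus instead of stalling at the start
        simplex = np.vstack([s, s + 2.0 * np.eye(len(s))])
        minimize(fun, s, method="Nelder-Mead",
                 options={"maxiter": max_iter, "xatol": tol, "fatol": 0.4,
                          "initial_simplex": simplex, "adaptive": False})
    return FitReport(weights=best["w"], objective=float(best["obj"]),
                     per_target_rank=_ranks_per_target(best["w"], cache),
                     trace=np.array(trace), include_es=include_es)


#: Neutral starting weights for the simplex when the caller has none.
REFITTED_DEFAULT_INIT = WeightSet(c2=1.0, c3=1.0, c4=1.0)
REFITTED_DEFAULT_INIT_ES = WeightSet(c2=1.0, c3=1.0, c4=1.0, c5=0.01)


def loocv(cache: ComponentCache, init: WeightSet | None = None,
          **fit_kwargs) -> FitReport:
    """Leave-one-target-out cross-validation of the weight fit.

    One fit per held-out target (trained on the rest), each evaluated by the
    holdout's native rank under the held-out-trained weights; the summary is
    the per-weight mean and standard deviation across the fits.
    """
    cache.validate()
    if cache.n_targets < 3:
        raise DarcError("LOOCV needs at least 3 targets")
    holdout_weights, holdout_ranks = [], {}
    traces = []
    for tid in list(cache.target_ids):
        sub = cache.subset_excluding(tid)
        rep = fit_weights(sub, init=init, **fit_kwargs)
        holdout_weights.append(rep.weights)
        holdout_ranks[str(tid)] = _ranks_per_target(rep.weights, cache)[str(tid)]
        traces.append(rep.trace)
    mat = np.array([w.as_vector() for w in holdout_weights])
    names = ("c1", "c2", "c3", "c4", "c5")
    mean = {n: float(m) for n, m in zip(names, mat.mean(axis=0))}
    sd = {n: float(s) for n, s in zip(names, mat.std(axis=0, ddof=1))}
    include_es = fit_kwargs.get("include_es")
    if include_es is None:
        include_es = cache.has_electrostatics()
    mean_w = WeightSet(c2=mean["c2"], c3=mean["c3"], c4=mean["c4"],
                       c5=mean["c5"] if include_es else 0.0)
    return FitReport(weights=mean_w,
                     objective=rank_objective(mean_w, cache),
                     per_target_rank=_ranks_per_target(mean_w, cache),
                     trace=np.concatenate(traces) if traces else np.array([]),
                     include_es=include_es,
                     holdout_weights=holdout_weights,
                     holdout_ranks=holdout_ranks,
                     weight_mean=mean, weight_sd=sd)
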