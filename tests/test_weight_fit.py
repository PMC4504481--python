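"""Weight calibration: decoy generation, rank objective, simplex fit, LOOCV."""

import numpy as np
import pytest

from darc import fixtures as fx
from darc.errors import DarcError
from darc.scoring import RayScorer, WeightSet
from darc.weight_fit import (ComponentCache, fit_weights,
                             generate_decoy_poses, loocv, rank_objective,
                             random_rotation_matrices)


def brute_force_rank(scores, native_idx):
    """Sort-based rank with average ties, independent of scipy."""
    s = np.asarray(scores)
    nat = s[native_idx]
    below = (s < nat).sum()
    ties = (s == nat).sum()
    return below + (ties + 1) / 2.0


def make_synthetic_cache(n_targets=3, n_decoys=20, seed=0, es=False):
    """Cache whose natives are rank-1 under w* = (1, 2, 4, 4) but not under
    small init weights: natives trade a large underpack term for tiny
    clash/missed/outside terms, decoys the reverse."""
    rng = np.random.default_rng(seed)
    target_ids, row_target, pose_ids, is_native, comps = [], [], [], [], []
    for t in range(n_targets):
        tid = f"T{t + 1}"
        target_ids.append(tid)
        native = [5.0 + rng.uniform(0, 0.5), 0.2, 0.0, 0.0,
                  rng.uniform(-1, 1) if es else 0.0]
        row_target.append(t)
        pose_ids.append(f"{tid}:native")
        is_native.append(True)
        comps.append(native)
        for d in range(n_decoys):
            row_target.append(t)
            pose_ids.append(f"{tid}:d{d}")
            is_native.append(False)
            comps.append([rng.uniform(0, 1), rng.uniform(1.5, 4),
                          rng.uniform(0.5, 2), rng.uniform(0.5, 2),
                          rng.uniform(-1, 1) if es else 0.0])
    return ComponentCache(target_ids=target_ids,
                          row_target=np.array(row_target),
                          pose_ids=pose_ids, is_native=np.array(is_native),
                          comps=np.array(comps))


@pytest.fixture(scope="module")
def raymap():
    lig = fx.make_ligand(8, seed=5)
    rec, tp, targets = fx.make_complementary_receptor(lig)
    from darc.workflow import make_rays
    rm, _ = make_rays(rec, targets, near_points=tp,
                      near_cutoff=fx.SELFDOCK_NEAR_CUTOFF)
    return rm


class TestDecoyGeneration:
    def test_row_count_and_invariants(self, raymap):
        lib = fx.make_decoy_library(3, seed=2)
        rows = generate_decoy_poses(raymap, lib, n_poses=10, seed=1)
        assert len(rows) == 30
        comps = np.array([c for _, c in rows])
        assert np.isfinite(comps).all()
        assert (comps[:, :4] >= 0).all()

    def test_seed_determinism(self, raymap):
        lib = fx.make_decoy_library(2, seed=2)
        a = generate_decoy_poses(raymap, lib, n_poses=5, seed=9)
        b = generate_decoy_poses(raymap, lib, n_poses=5, seed=9)
        for (ia, ca), (ib, cb) in zip(a, b):
            assert ia == ib
            np.testing.assert_array_equal(ca, cb)

    def test_rotation_uniformity(self):
        """Haar-uniform rotations: the mean matrix trace over many draws is
        ~0 (the standard 3-D rotation representation integrates to zero)."""
        rng = np.random.default_rng(11)
        mats = random_rotation_matrices(10_000, rng)
        mean_trace = np.trace(mats, axis1=1, axis2=2).mean()
        assert mean_trace == pytest.approx(0.0, abs=0.05)


class TestRankObjective:
    def test_all_natives_best(self):
        cache = make_synthetic_cache()
        # weights that put natives on top by construction
        w = WeightSet(c2=2.0, c3=4.0, c4=4.0)
        assert rank_objective(w, cache) == cache.n_targets

    def test_tie_gives_average_rank(self):
        cache = ComponentCache(
            target_ids=["T"], row_target=np.zeros(3, int),
            pose_ids=["n", "d1", "d2"],
            is_native=np.array([True, False, False]),
            comps=np.array([[1.0, 0, 0, 0, 0],
                            [1.0, 0, 0, 0, 0],
                            [5.0, 0, 0, 0, 0]]))
        assert rank_objective(WeightSet(c2=1, c3=1, c4=1), cache) == 1.5

    def test_matches_brute_force(self, rng):
        cache = make_synthetic_cache(n_targets=3, n_decoys=20, seed=4)
        w = WeightSet(c2=rng.uniform(0, 3), c3=rng.uniform(0, 3),
                      c4=rng.uniform(0, 3))
        scores = cache.comps @ w.as_vector()
        want = 0.0
        for t in range(3):
            rows = np.flatnonzero(cache.row_target == t)
            nat = np.flatnonzero(cache.is_native[rows])[0]
            want += brute_force_rank(scores[rows], nat)
        assert rank_objective(w, cache) == pytest.approx(want)

    def test_scale_invariance(self):
        """Uniformly scaling all weights (incl. c1) preserves every rank --
        the rationale for fixing c1 = 1."""
        cache = make_synthetic_cache(seed=8)
        w = WeightSet(c2=2.0, c3=4.0, c4=4.0)
        scaled = cache.comps @ (3.0 * w.as_vector())
        unscaled = cache.comps @ w.as_vector()
        assert np.array_equal(np.argsort(scaled), np.argsort(unscaled))

    def test_per_target_shift_invariance(self):
        """Adding a constant to every pose's es term within a target leaves
        the objective unchanged."""
        cache = make_synthetic_cache(es=True, seed=3)
        w = WeightSet(c2=2.0, c3=4.0, c4=4.0, c5=0.5)
        base = rank_objective(w, cache)
        shifted = ComponentCache(
            target_ids=cache.target_ids, row_target=cache.row_target,
            pose_ids=cache.pose_ids, is_native=cache.is_native,
            comps=cache.comps.copy())
        for t in range(cache.n_targets):
            shifted.comps[cache.row_target == t, 4] += 7.0 * (t + 1)
        assert rank_objective(w, shifted) == base


class TestFitWeights:
    def test_recovers_grid_oracle_minimum(self):
        """The simplex fit reaches the exhaustive-lattice minimum of the
        sum-of-ranks objective on a cache built around w* = (1, 2, 4, 4)."""
        cache = make_synthetic_cache(n_targets=5, n_decoys=20, seed=1)
        init = WeightSet(c2=0.05, c3=0.05, c4=0.05)
        assert rank_objective(init, cache) > cache.n_targets  # init is bad
        report = fit_weights(cache, init=init)
        grid = np.geomspace(0.25, 8.0, 10)
        oracle = min(rank_objective(WeightSet(c2=a, c3=b, c4=c), cache)
                     for a in grid for b in grid for c in grid)
        assert report.objective <= oracle

    def test_never_worse_than_init(self):
        cache = make_synthetic_cache(seed=2)
        init = WeightSet(c2=2.0, c3=4.0, c4=4.0)  # already optimal
        report = fit_weights(cache, init=init)
        assert report.objective <= rank_objective(init, cache)
        assert (np.diff(report.trace) <= 1e-12).all()  # best-so-far record

    def test_degenerate_cache_rejected(self):
        cache = ComponentCache(target_ids=["T"], row_target=np.zeros(1, int),
                               pose_ids=["n"], is_native=np.array([True]),
                               comps=np.zeros((1, 5)))
        with pytest.raises(DarcError):
            fit_weights(cache)

    def test_tsv_round_trip(self, tmp_path):
        cache = make_synthetic_cache(es=True, seed=5)
        p = tmp_path / "cache.tsv"
        cache.to_tsv(p)
        back = ComponentCache.from_tsv(p)
        assert back.target_ids == cache.target_ids
        np.testing.assert_allclose(back.comps, cache.comps, rtol=1e-9)
        np.testing.assert_array_equal(back.is_native, cache.is_native)

    def test_malformed_tsv_row_numbered(self, tmp_path):
        cache = make_synthetic_cache(seed=5)
        p = tmp_path / "cache.tsv"
        cache.to_tsv(p)
        lines = p.read_text().splitlines()
        lines[3] = "broken\trow"
        p.write_text("\n".join(lines))
        with pytest.raises(DarcError, match="row 4"):
            ComponentCache.from_tsv(p)


class TestLoocv:
    def test_bookkeeping(self):
        cache = make_synthetic_cache(n_targets=5, n_decoys=15, seed=6)
        report = loocv(cache, init=WeightSet(c2=0.3, c3=0.3, c4=0.3))
        assert len(report.holdout_weights) == 5
        assert set(report.holdout_ranks) == set(cache.target_ids)
        assert set(report.weight_sd) == {"c1", "c2", "c3", "c4", "c5"}
        assert report.weight_sd["c1"] == 0.0

    def test_cloned_targets_agree(self):
        """Identical targets make every holdout fit see the same data, so
        the per-weight spread collapses."""
        base = make_synthetic_cache(n_targets=1, n_decoys=15, seed=7)
        tids, rt, pids, nat, comps = [], [], [], [], []
        for t in range(4):
            tids.append(f"C{t}")
            rows = base.row_target == 0
            rt.extend([t] * rows.sum())
            pids.extend(f"C{t}:{p}" for p in np.array(base.pose_ids)[rows])
            nat.extend(base.is_native[rows])
            comps.extend(base.comps[rows])
        clone = ComponentCache(target_ids=tids, row_target=np.array(rt),
                               pose_ids=pids, is_native=np.array(nat),
                               comps=np.array(comps))
        report = loocv(clone, init=WeightSet(c2=0.3, c3=0.3, c4=0.3))
        mats = np.array([w.as_vector() for w in report.holdout_weights])
        assert np.allclose(mats.std(axis=0), 0.0, atol=1e-12)

    def test_too_few_targets(self):
        cache = make_synthetic_cache(n_targets=2, seed=1)
        with pytest.raises(DarcError):
            loocv(cache)


class TestCachingEquivalence:
    def test_cached_components_equal_rescoring(self):
        """Scores computed from cached components equal scoring the stored
        pose from scratch -- the correctness condition of the cache trick."""
        lig = fx.make_ligand(8, seed=5)
        rec, tp, targets = fx.make_complementary_receptor(lig)
        from darc.workflow import make_rays
        rm, _ = make_rays(rec, targets, near_points=tp,
                          near_cutoff=fx.SELFDOCK_NEAR_CUTOFF)
        scorer = RayScorer(rm)
        rng = np.random.default_rng(3)
        from scipy.spatial.transform import Rotation
        w = WeightSet(c2=1.7, c3=4.2, c4=4.4)
        cent = lig.coords[0] - lig.coords[0].mean(axis=0)
        lo, hi = rm.bounds
        for _ in range(100):
            pose = Rotation.random(random_state=rng).apply(cent) \
                + lo + rng.random(3) * (hi - lo)
            comp = scorer.components_single(pose, lig.radii)
            from darc.scoring import darc_score
            cached = darc_score(comp, w)
            scratch = scorer.score(pose, lig.radii, w)
            assert cached == pytest.approx(scratch, abs=1e-9)
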