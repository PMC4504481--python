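"""Vantage-point placement and ray casting.

The pocket topography is recorded as spherical coordinates of each pocket
shell point relative to an origin ("vantage point") placed 30 A behind the
pocket center.  In multi-origin mode four additional origins are generated by
rotating the first by +/-45 degrees about the pocket center in two orthogonal
planes, and each surface point is assigned to (only) its closest origin, so
the total ray count never changes.  Ligand topography along the same rays
comes from closed-form ray/sphere intersections against the union of scaled
atomic spheres.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import DarcError

ORIGIN_DISTANCE = 30.0     # A from the pocket center
FAN_ANGLE_DEG = 45.0       # rotation placing origins 2..5
RADIUS_SCALE = 0.9         # default ligand atom radius scaling

_AXES = np.eye(3)


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise DarcError("zero-length vector where a direction was required")
    return v / n


def origin_frame(origin: np.ndarray, pocket_center: np.ndarray) -> np.ndarray:
    """Right-handed orthonormal frame (rows x,y,z) for one origin.

    The +z axis points from the origin to the pocket center; x is the global
    axis least parallel to z, orthogonalized; y completes the frame.  The
    frame is a pure function of (origin, pocket_center), so angles written to
    a ray-file are recoverable from the header alone.
    """
    z = _unit(np.asarray(pocket_center, float) - np.asarray(origin, float))
    e = _AXES[np.argmin(np.abs(_AXES @ z))]
    x = _unit(e - (e @ z) * z)
    y = np.cross(z, x)
    return np.stack([x, y, z])


def to_spherical(points: np.ndarray, origin: np.ndarray,
                 pocket_center: np.ndarray):
    """(rho, theta, phi) of points in the origin's frame; phi in [-pi, pi)."""
    frame = origin_frame(origin, pocket_center)
    rel = np.atleast_2d(points) - origin
    rho = np.linalg.norm(rel, axis=1)
    d = rel / rho[:, None]
    theta = np.arccos(np.clip(d @ frame[2], -1.0, 1.0))
    phi = np.arctan2(d @ frame[1], d @ frame[0])
    phi = np.where(phi >= np.pi, -np.pi, phi)
    return rho, theta, phi


def angles_to_dirs(theta: np.ndarray, phi: np.ndarray,
                   frame: np.ndarray) -> np.ndarray:
    st = np.sin(theta)
    return (st * np.cos(phi))[:, None] * frame[0] \
        + (st * np.sin(phi))[:, None] * frame[1] \
        + np.cos(theta)[:, None] * frame[2]


@dataclass
class OriginSet:
    """One (k=1) or five (k=5) vantage points, all 30 A from the pocket center."""

    origins: np.ndarray        # (k, 3)
    pocket_center: np.ndarray  # (3,) P
    method: str = "com"

    def __post_init__(self) -> None:
        self.origins = np.atleast_2d(np.asarray(self.origins, float))
        self.pocket_center = np.asarray(self.pocket_center, float)
        d = np.linalg.norm(self.origins - self.pocket_center, axis=1)
        if not np.allclose(d, ORIGIN_DISTANCE, atol=1e-6):
            raise DarcError(f"origins must sit {ORIGIN_DISTANCE} A from the "
                            f"pocket center (got {d})")

    @property
    def k(self) -> int:
        return len(self.origins)


@dataclass
class RayMap:
    """The ray-file in memory: per-ray origin assignment, angles and distances.

    ``rho_pocket`` is NaN for boundary-layer rays (the mouth-defining layer
    outside the pocket); pocket rays store the shell-point distance from
    their assigned origin.
    """

    origins: np.ndarray         # (k, 3)
    pocket_center: np.ndarray   # (3,)
    bounds: tuple               # (lo, hi) docking search box, A
    origin_index: np.ndarray    # (R,) 1-based
    theta: np.ndarray           # (R,)
    phi: np.ndarray             # (R,)
    rho_pocket: np.ndarray      # (R,) A; NaN marks a BOUNDARY ray
    placement: str = "com"
    _frames: np.ndarray = field(default=None, repr=False, compare=False)

    @property
    def n_rays(self) -> int:
        return len(self.origin_index)

    @property
    def is_boundary(self) -> np.ndarray:
        return np.isnan(self.rho_pocket)

    def frames(self) -> np.ndarray:
        if self._frames is None:
            self._frames = np.stack([origin_frame(o, self.pocket_center)
                                     for o in self.origins])
        return self._frames

    def ray_origins(self) -> np.ndarray:
        return self.origins[self.origin_index - 1]

    def ray_dirs(self) -> np.ndarray:
        frames = self.frames()[self.origin_index - 1]
        st = np.sin(self.theta)
        return (st * np.cos(self.phi))[:, None] * frames[:, 0] \
            + (st * np.sin(self.phi))[:, None] * frames[:, 1] \
            + np.cos(self.theta)[:, None] * frames[:, 2]

    def shell_point_coords(self) -> np.ndarray:
        """Cartesian reconstruction of pocket shell points (NaN rows for boundary)."""
        return self.ray_origins() + self.rho_pocket[:, None] * self.ray_dirs()


# ---------------------------------------------------------------------------
# origin placement


def place_primary_origin(receptor, grid, method: str = "com",
                         residue=None) -> np.ndarray:
    """Place the first origin O1, 30 A from the pocket center P.

    Methods: ``com`` (toward the protein center of mass, the default),
    ``plane`` (normal of the least-squares plane through the pocket shell,
    choosing the solution closer to the protein center so rays come from
    inside the protein), ``vecsum`` (sum of surface-point-to-P vectors, the
    direction most facing away from solvent), ``residue`` (along P->R for a
    user residue R).
    """
    from .pocket import shell_points

    P = grid.center
    Q = receptor.coords.mean(axis=0)
    if method == "com":
        return P + ORIGIN_DISTANCE * _unit(Q - P)
    if method == "plane":
        pts = shell_points(grid)
        c = pts - pts.mean(axis=0)
        _, s, vt = np.linalg.svd(c, full_matrices=False)
        if len(pts) < 3 or s[1] < 1e-8 * max(s[0], 1e-30):
            import warnings
            warnings.warn("degenerate (collinear) pocket plane fit; "
                          "falling back to the center-of-mass method",
                          stacklevel=2)
            return P + ORIGIN_DISTANCE * _unit(Q - P)
        n = vt[2]
        cands = [P + ORIGIN_DISTANCE * n, P - ORIGIN_DISTANCE * n]
        return min(cands, key=lambda o: np.linalg.norm(o - Q))
    if method == "vecsum":
        pts = shell_points(grid)
        s = (P - pts).sum(axis=0)
        return P + ORIGIN_DISTANCE * _unit(s)
    if method == "residue":
        if residue is None:
            raise DarcError("residue method requires a residue selection")
        mask = receptor.atom_mask_for_residues([residue])
        R = receptor.coords[mask].mean(axis=0)
        return P + ORIGIN_DISTANCE * _unit(R - P)
    raise DarcError(f"unknown origin method {method!r}")


def expand_origins(o1: np.ndarray, pocket_center: np.ndarray,
                   rng_seed: int, method: str = "com") -> OriginSet:
    """Fan O1 out into five origins by +/-45 degree rotations about P.

    O2/O3 rotate O1 about w = u x v (u = P->O1, v = P->random point, drawn
    from a seeded RNG for reproducibility); O4/O5 rotate about z = u x w.
    Both axes are orthogonal to u, so all five origins keep |Oi - P| = 30 A
    and subtend 45 degrees at P from O1.
    """
    P = np.asarray(pocket_center, float)
    u = np.asarray(o1, float) - P
    un = _unit(u)
    rng = np.random.default_rng(rng_seed)
    while True:
        v = rng.standard_normal(3)
        w = np.cross(u, v)
        if np.linalg.norm(w) > 1e-6 * np.linalg.norm(u):
            break
    w = _unit(w)
    z = _unit(np.cross(un, w))
    ang = np.deg2rad(FAN_ANGLE_DEG)
    origins = [np.asarray(o1, float)]
    for axis in (w, z):
        for sign in (+1.0, -1.0):
            rot = Rotation.from_rotvec(sign * ang * axis)
            origins.append(P + rot.apply(u))
    return OriginSet(origins=np.stack(origins), pocket_center=P, method=method)


def single_origin_set(o1: np.ndarray, pocket_center: np.ndarray,
                      method: str = "com") -> OriginSet:
    return OriginSet(origins=np.asarray(o1, float)[None],
                     pocket_center=pocket_center, method=method)


# ---------------------------------------------------------------------------
# ray map construction


def build_ray_map(shell: np.ndarray, boundary: np.ndarray,
                  origins: OriginSet, bounds) -> RayMap:
    """Assign every shell/boundary point to its closest origin and record
    the spherical coordinates in that origin's frame.

    Ties go to the lowest origin index (np.argmin convention).  Boundary
    points produce BOUNDARY records (angles but no pocket distance).  One
    record per point: multi-origin mode redistributes, never adds, rays.
    """
    shell = np.atleast_2d(np.asarray(shell, float))
    if shell.size == 0:
        raise DarcError("cannot build a ray map from an empty pocket shell")
    boundary = np.asarray(boundary, float).reshape(-1, 3)

    def assign(points):
        d = np.linalg.norm(points[:, None, :] - origins.origins[None], axis=2)
        return np.argmin(d, axis=1)  # ties -> lowest index

    recs = []
    for pts, is_boundary in ((shell, False), (boundary, True)):
        if len(pts) == 0:
            continue
        oi = assign(pts)
        for k in range(origins.k):
            sel = oi == k
            if not sel.any():
                continue
            rho, theta, phi = to_spherical(pts[sel], origins.origins[k],
                                           origins.pocket_center)
            recs.append((np.flatnonzero(sel) + (0 if not is_boundary else len(shell)),
                         np.full(sel.sum(), k + 1), theta, phi,
                         np.full(sel.sum(), np.nan) if is_boundary else rho))
    # restore input point order (shell first, boundary after)
    order = np.concatenate([r[0] for r in recs])
    perm = np.argsort(order, kind="stable")
    cat = lambda j: np.concatenate([r[j] for r in recs])[perm]
    return RayMap(origins=origins.origins, pocket_center=origins.pocket_center,
                  bounds=bounds, origin_index=cat(1).astype(int),
                  theta=cat(2), phi=cat(3), rho_pocket=cat(4),
                  placement=origins.method)


# ---------------------------------------------------------------------------
# ray / ligand-sphere intersection


def intersect_ray_spheres(origin: np.ndarray, direction: np.ndarray,
                          centers: np.ndarray, radii: np.ndarray,
                          radius_scale: float = RADIUS_SCALE) -> float:
    """First intersection distance of one ray with a union of scaled spheres.

    Smallest positive root of the ray-sphere quadratic over all atoms;
    NaN (MISS) when no atom is hit.
    """
    if radius_scale <= 0:
        raise ValueError("radius_scale must be positive")
    d = _unit(np.asarray(direction, float))
    oc = np.atleast_2d(centers) - np.asarray(origin, float)
    b = oc @ d
    c = (oc ** 2).sum(axis=1) - (radius_scale * np.asarray(radii, float)) ** 2
    disc = b * b - c
    with np.errstate(invalid="ignore"):
        t = b - np.sqrt(disc)
    t = np.where((disc >= 0) & (t > 0), t, np.inf)
    # ray starting inside a sphere: the exit point is the first intersection
    t_exit = np.where((disc >= 0), b + np.sqrt(np.where(disc >= 0, disc, 0.0)), np.inf)
    t = np.where(np.isinf(t) & (t_exit > 0) & (c < 0), t_exit, t)
    tmin = t.min()
    return float(tmin) if np.isfinite(tmin) else float("nan")


def cast_ray_at_ligand(origin: np.ndarray, theta: float, phi: float,
                       pose_coords: np.ndarray, radii: np.ndarray,
                       radius_scale: float = RADIUS_SCALE,
                       pocket_center: np.ndarray | None = None) -> float:
    """Ray at (theta, phi) in the origin's frame vs a ligand pose.

    ``pocket_center`` fixes the spherical frame; it defaults to the +z world
    axis through the origin when omitted (single free-standing ray).
    """
    if pocket_center is None:
        pocket_center = np.asarray(origin, float) + np.array([0.0, 0.0, 1.0])
    frame = origin_frame(origin, pocket_center)
    d = angles_to_dirs(np.array([theta]), np.array([phi]), frame)[0]
    return intersect_ray_spheres(origin, d, pose_coords, radii, radius_scale)


def rho_ligand_batch(ray_origins: np.ndarray, ray_dirs: np.ndarray,
                     poses: np.ndarray, radii: np.ndarray,
                     radius_scale: float = RADIUS_SCALE) -> np.ndarray:
    """Vectorized first-intersection distances for a batch of poses.

    poses: (..., A, 3) ligand coordinates; returns (..., R) with NaN for MISS.
    Loops over atoms (small) and broadcasts over poses x rays (large).
    """
    poses = np.asarray(poses, float)
    squeeze = poses.ndim == 2
    if squeeze:
        poses = poses[None]
    P, A, _ = poses.shape
    R = len(ray_origins)
    best = np.full((P, R), np.inf)
    scaled2 = (radius_scale * np.asarray(radii, float)) ** 2
    # b = (x - o).d and |x - o|^2 expanded so the pose-dependent parts are
    # (P,3)x(3,R) matmuls (BLAS) instead of (P,R,3) temporaries
    od = (ray_origins * ray_dirs).sum(axis=1)        # (R,)
    oo = (ray_origins ** 2).sum(axis=1)              # (R,)
    dirs_T = np.ascontiguousarray(ray_dirs.T)
    orig_T = np.ascontiguousarray(ray_origins.T)
    for a in range(A):
        x = poses[:, a, :]                           # (P, 3)
        b = x @ dirs_T
        b -= od[None, :]
        c = x @ orig_T
        c *= -2.0
        c += (x ** 2).sum(axis=1)[:, None]
        c += oo[None, :] - scaled2[a]
        disc = b * b
        disc -= c
        with np.errstate(invalid="ignore"):
            np.sqrt(disc, out=disc)                  # NaN where no real root
        t = b - disc
        t[~(t > 0)] = np.inf                         # misses and behind-origin
        inside = c < 0                               # ray starts inside sphere
        if inside.any():
            t_exit = b + disc
            sel = inside & (t_exit > 0) & ~np.isfinite(t)
            t[sel] = t_exit[sel]
        np.minimum(best, t, out=best)
    out = np.where(np.isfinite(best), best, np.nan)
    return out[0] if squeeze else out


def cast_all(raymap: RayMap, pose_coords: np.ndarray, radii: np.ndarray,
             radius_scale: float = RADIUS_SCALE):
    """Paired (rho_pocket, rho_ligand) arrays for every ray, order-preserving.

    NaN in the first array marks BOUNDARY rays, NaN in the second a MISS.
    An empty ligand (0 atoms) misses every ray.
    """
    if len(np.atleast_2d(pose_coords)) == 0 or np.asarray(pose_coords).size == 0:
        return raymap.rho_pocket.copy(), np.full(raymap.n_rays, np.nan)
    rho_lig = rho_ligand_batch(raymap.ray_origins(), raymap.ray_dirs(),
                               np.asarray(pose_coords, float), radii,
                               radius_scale)
    return raymap.rho_pocket.copy(), rho_lig


# ---------------------------------------------------------------------------
# grid-visibility diagnostic (multi-origin "illumination")


def visible_shell_count(raymap: RayMap, grid, step_frac: float = 0.5) -> int:
    """Number of pocket shell points whose ray reaches them without first
    crossing a protein INTERIOR cell of the pocket grid.

    Marches each pocket ray from its assigned origin in ``step_frac * spacing``
    increments, stopping one cell short of the shell point so the wall cell
    the point touches does not count as an occluder.
    """
    from .pocket import CellLabel

    step = step_frac * grid.spacing
    count = 0
    origins = raymap.ray_origins()
    dirs = raymap.ray_dirs()
    for o, d, rho, bnd in zip(origins, dirs, raymap.rho_pocket,
                              raymap.is_boundary):
        if bnd:
            continue
        ts = np.arange(step, rho - grid.spacing, step)
        if len(ts) == 0:
            count += 1
            continue
        pts = o + ts[:, None] * d
        labels = grid.label_at(pts)
        if not (labels == CellLabel.INTERIOR).any():
            count += 1
    return count
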