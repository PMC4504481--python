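"""Synthetic receptors, ligands and libraries with known ground truth.

The scoring and search layers see only spheres with positions, radii and
charges, so these generators use sphere-cluster pseudo-molecules rather than
chemically valid structures; real PDB/SDF inputs remain first-class through
:mod:`darc.model_io`.  Every generator is a pure function of its seed and
parameters.

The keystone is the carved-complement ("self-dock") receptor: its wall
spheres sit along the outward normals of a ligand's union-of-spheres surface
at a distance chosen so that the probe-inflated protein interior ends where
the scaled ligand surface lies.  Perfect shape complementarity at the
generating pose is therefore achievable by construction (up to grid
discretization), making that pose a certified near-global optimum of the
shape score -- every score term is non-negative and the true pose nearly
zeroes them all.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model_io import ConformerSet, Receptor
from .pocket import PROBE_RADIUS
from .raycast import RADIUS_SCALE

CARBON_RADIUS = 1.70
BOND_MIN, BOND_MAX = 1.4, 1.8

#: Pocket-trim radius (A) used when centering the search on the bound ligand
#: in self-dock benchmarks: keeps the ligand-shaped void plus one shell of
#: cells, and excludes solvent lobes past the cavity mouth.
SELFDOCK_NEAR_CUTOFF = 2.5


@dataclass
class FixtureSpec:
    """Parameters of one complete synthetic docking problem."""

    seed: int = 0
    ligand_atoms: int = 15
    cavity_style: str = "carved-complement"  # hemisphere | carved-complement | flat-patch
    n_conformers: int = 5
    conformer_amplitude: float = 0.3
    decoy_library_size: int = 20
    charge_pattern: str = "none"             # none | dipole | random


def _fibonacci_sphere(n: int) -> np.ndarray:
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5 ** 0.5) * i
    return np.stack([np.sin(phi) * np.cos(theta),
                     np.sin(phi) * np.sin(theta), np.cos(phi)], axis=1)


def make_ligand(n_atoms: int, seed: int, name: str | None = None,
                tail_fraction: float = 1 / 3) -> ConformerSet:
    """Connected tadpole-shaped cluster of carbon-like spheres, centroid at
    the origin.

    Atoms attach one at a time at bonded distances in [1.4, 1.8] A,
    rejecting placements closer than 1.4 A to any other atom, so
    nearest-neighbor distances stay in the bonded band.  The first
    ``1 - tail_fraction`` of the atoms grow a compact globular body (among
    valid candidate placements per atom, the one closest to the seed atom
    wins); the rest extend a short tail along -z.  The shape is deliberate:
    a sprawling random walk has deep crevices invisible to rays (no
    complementarity signal there), while a plain compact blob is nearly
    ellipsoidal and admits flipped poses of almost equal complementarity --
    pose recovery would be ill-posed for any scoring function.  The tail
    breaks the pseudo-symmetry.
    """
    if n_atoms < 3:
        raise ValueError("need at least 3 atoms")
    rng = np.random.default_rng(seed)
    n_tail = max(0, int(round(n_atoms * tail_fraction))) if n_atoms >= 6 else 0
    n_body = n_atoms - n_tail
    coords = [np.zeros(3)]
    while len(coords) < n_body:
        arr = np.array(coords)
        best = None
        for _ in range(30):
            parent = arr[rng.integers(0, len(arr))]
            d = rng.uniform(BOND_MIN, BOND_MAX)
            v = rng.standard_normal(3)
            v /= np.linalg.norm(v)
            cand = parent + d * v
            if (np.linalg.norm(arr - cand, axis=1) >= BOND_MIN).all():
                if best is None or np.linalg.norm(cand) < np.linalg.norm(best):
                    best = cand
        if best is not None:
            coords.append(best)
    arr = np.array(coords)
    tip = arr[np.argmin(arr[:, 2])]
    placed = 0
    while placed < n_tail:
        d = rng.uniform(BOND_MIN, BOND_MAX)
        v = np.array([0.0, 0.0, -1.0]) + 0.35 * rng.standard_normal(3)
        v /= np.linalg.norm(v)
        cand = tip + d * v
        if (np.linalg.norm(np.array(coords) - cand, axis=1) >= BOND_MIN).all():
            coords.append(cand)
            tip = cand
            placed += 1
    xyz = np.array(coords)
    xyz -= xyz.mean(axis=0)
    n = len(xyz)
    return ConformerSet(name=name or f"lig{seed}", elements=["C"] * n,
                        radii=np.full(n, CARBON_RADIUS),
                        charges=np.zeros(n), coords=xyz[None])


def perturb_conformers(ligand: ConformerSet, n: int, amplitude: float,
                       seed: int) -> ConformerSet:
    """Conformer 1 is the input; 2..n are bounded coordinate perturbations.

    Per-atom displacement never exceeds ``amplitude``, which bounds each
    conformer's RMSD to conformer 1 by the same amount (recorded on the
    returned set as ``perturbation_rmsd``).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    base = ligand.coords[ligand.reference_index]
    confs = [base]
    for _ in range(n - 1):
        disp = rng.standard_normal(base.shape)
        norms = np.linalg.norm(disp, axis=1, keepdims=True)
        scale = rng.uniform(0.3, 1.0, size=(len(base), 1)) * amplitude
        disp = np.where(norms > 0, disp / np.maximum(norms, 1e-12) * scale, 0.0)
        confs.append(base + disp)
    out = ConformerSet(name=ligand.name, elements=list(ligand.elements),
                       radii=ligand.radii.copy(), charges=ligand.charges.copy(),
                       coords=np.stack(confs))
    out.perturbation_rmsd = np.array(
        [np.sqrt(((c - base) ** 2).sum(axis=1).mean()) for c in confs])
    return out


def make_complementary_receptor(ligand, open_cone_deg: float = 60.0,
                                margin: float = 0.1, n_dirs: int = 120,
                                min_sep: float = 1.1,
                                wall_radius: float = CARBON_RADIUS):
    """Carve a ligand-shaped cavity: wall spheres tile the offset surface.

    For ligand atom i (radius r_i), wall sphere centers sit at distance
    ``0.9 r_i + (wall_radius + probe) + margin`` along outward surface
    normals, so the probe-inflated interior boundary tracks the scaled
    ligand surface ``margin`` away.  Directions within ``open_cone_deg`` of
    +z (from the ligand centroid) are left open: the cavity mouth.

    Returns ``(receptor, true_pose, target_resids)``; the generating pose is
    the ground truth for self-docking.
    """
    coords = ligand.coords[ligand.reference_index] if hasattr(ligand, "coords") \
        else np.asarray(ligand, float)
    radii = ligand.radii if hasattr(ligand, "radii") \
        else np.full(len(coords), CARBON_RADIUS)
    centroid = coords.mean(axis=0)
    offsets = RADIUS_SCALE * radii + (wall_radius + PROBE_RADIUS) + margin
    dirs = _fibonacci_sphere(n_dirs)
    cos_open = np.cos(np.deg2rad(open_cone_deg))

    candidates = []
    for i, (c, t) in enumerate(zip(coords, offsets)):
        pts = c + t * dirs
        # keep only points on the union surface (not inside another lobe)
        keep = np.ones(len(pts), bool)
        for j, (cj, tj) in enumerate(zip(coords, offsets)):
            if j == i:
                continue
            keep &= np.linalg.norm(pts - cj, axis=1) >= tj - 0.05
        pts = pts[keep]
        # open face toward +z
        rel = pts - centroid
        ang_ok = rel[:, 2] / np.linalg.norm(rel, axis=1) < cos_open
        candidates.append(pts[ang_ok])
    cand = np.concatenate(candidates)
    order = np.lexsort((cand[:, 2], cand[:, 1], cand[:, 0]))
    cand = cand[order]
    kept: list[np.ndarray] = []
    for p in cand:
        if not kept or np.min(np.linalg.norm(np.array(kept) - p, axis=1)) >= min_sep:
            kept.append(p)
    wall = np.array(kept)
    n = len(wall)
    receptor = Receptor(elements=["C"] * n, coords=wall,
                        radii=np.full(n, wall_radius), charges=np.zeros(n),
                        chains=["A"] * n, resids=np.arange(1, n + 1),
                        name="carved")
    return receptor, coords.copy(), list(range(1, n + 1))


def make_well_receptor(well_radius: float = 4.0, well_depth: float = 6.0,
                       lattice: float = 1.8):
    """Slab receptor with a steep-walled cylindrical well (open at the top).

    The well's side walls are near-parallel to the axis from the pocket
    center to a single origin placed behind the pocket, so single-origin
    rays cannot see them directly -- the geometry that motivates multiple
    vantage points.  Deterministic (pure lattice construction).

    Returns ``(receptor, target_resids)``.
    """
    clear = well_radius + CARBON_RADIUS + PROBE_RADIUS  # keep-out radius
    top = well_depth / 2.0
    bot = -well_depth / 2.0
    xs = np.arange(-11.0, 11.0 + 1e-9, lattice)
    zs = np.arange(-8.0, top + 1e-9, lattice)
    pts = []
    for x in xs:
        for y in xs:
            for z in zs:
                rho = np.hypot(x, y)
                if rho < clear and z > bot - clear:
                    continue
                pts.append((x, y, z))
    xyz = np.array(pts)
    n = len(xyz)
    receptor = Receptor(elements=["C"] * n, coords=xyz,
                        radii=np.full(n, CARBON_RADIUS), charges=np.zeros(n),
                        chains=["A"] * n, resids=np.arange(1, n + 1),
                        name="well")
    rho = np.hypot(xyz[:, 0], xyz[:, 1])
    target = (rho < clear + 2 * lattice) & (xyz[:, 2] > bot - clear)
    return receptor, [int(r) for r in receptor.resids[target]]


def make_spherical_pocket_receptor(ball_radius: float = 12.0,
                                   cavity_radius: float = 4.0,
                                   cavity_depth_offset: float = 1.5,
                                   lattice: float = 1.8):
    """Ball of spheres with a spherical pocket carved just below the surface.

    The cavity sphere center S sits ``cavity_depth_offset`` below the ball
    surface so that the mouth is a minority cap and deep cells are enclosed
    by protein along the diagonal scan axes.

    Returns ``(receptor, cavity_center, target_resids)``.
    """
    S = np.array([0.0, 0.0, ball_radius - cavity_depth_offset])
    clear = cavity_radius + CARBON_RADIUS + PROBE_RADIUS
    xs = np.arange(-ball_radius, ball_radius + 1e-9, lattice)
    pts = []
    for x in xs:
        for y in xs:
            for z in xs:
                p = np.array([x, y, z])
                if np.linalg.norm(p) > ball_radius:
                    continue
                if np.linalg.norm(p - S) < clear:
                    continue
                pts.append(p)
    xyz = np.array(pts)
    n = len(xyz)
    receptor = Receptor(elements=["C"] * n, coords=xyz,
                        radii=np.full(n, CARBON_RADIUS), charges=np.zeros(n),
                        chains=["A"] * n, resids=np.arange(1, n + 1),
                        name="ballpocket")
    near = np.linalg.norm(xyz - S, axis=1) < clear + 2 * lattice
    return receptor, S, [int(r) for r in receptor.resids[near]]


def make_convex_receptor(radius: float = 8.0, lattice: float = 1.8) -> Receptor:
    """Solid convex ball: has no concavity, so pocket detection must fail."""
    xs = np.arange(-radius, radius + 1e-9, lattice)
    pts = [(x, y, z) for x in xs for y in xs for z in xs
           if x * x + y * y + z * z <= radius * radius]
    xyz = np.array(pts)
    n = len(xyz)
    return Receptor(elements=["C"] * n, coords=xyz,
                    radii=np.full(n, CARBON_RADIUS), charges=np.zeros(n),
                    chains=["A"] * n, resids=np.arange(1, n + 1),
                    name="convex")


def make_decoy_library(n_ligands: int, seed: int) -> list[ConformerSet]:
    """Library of sphere-cluster decoy ligands with varying sizes (5-30 atoms)."""
    if n_ligands == 0:
        return []
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n_ligands):
        n_atoms = int(rng.integers(5, 31))
        sub_seed = int(rng.integers(0, 2 ** 31))
        out.append(make_ligand(n_atoms, sub_seed, name=f"decoy{i + 1}"))
    return out


def apply_charge_pattern(receptor: Receptor, pattern: str, seed: int = 0) -> Receptor:
    """Assign receptor partial charges: none, a +1/-1 dipole along z, or
    uniform random charges in [-0.5, 0.5]."""
    q = np.zeros(receptor.n_atoms)
    if pattern == "dipole":
        q[int(np.argmax(receptor.coords[:, 2]))] = 1.0
        q[int(np.argmin(receptor.coords[:, 2]))] = -1.0
    elif pattern == "random":
        rng = np.random.default_rng(seed)
        q = rng.uniform(-0.5, 0.5, receptor.n_atoms)
    elif pattern != "none":
        raise ValueError(f"unknown charge pattern {pattern!r}")
    receptor.charges = q
    return receptor


def build_fixture(spec: FixtureSpec) -> dict:
    """Assemble a complete docking problem from a FixtureSpec.

    Returns a dict with the receptor, the conformer ensemble (conformer 1 is
    the generating pose's conformer), the true pose, target residues and the
    decoy library.
    """
    ligand = make_ligand(spec.ligand_atoms, spec.seed)
    if spec.cavity_style == "carved-complement":
        receptor, true_pose, targets = make_complementary_receptor(ligand)
    elif spec.cavity_style == "hemisphere":
        receptor, center, targets = make_spherical_pocket_receptor()
        true_pose = ligand.coords[0] + center
    elif spec.cavity_style == "flat-patch":
        receptor, targets = make_well_receptor()
        true_pose = ligand.coords[0]
    else:
        raise ValueError(f"unknown cavity style {spec.cavity_style!r}")
    receptor = apply_charge_pattern(receptor, spec.charge_pattern, spec.seed)
    conformers = perturb_conformers(ligand, spec.n_conformers,
                                    spec.conformer_amplitude, spec.seed + 1)
    decoys = make_decoy_library(spec.decoy_library_size, spec.seed + 2)
    return {"receptor": receptor, "conformers": conformers,
            "true_pose": true_pose, "target_resids": targets,
            "decoys": decoys, "spec": spec}
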