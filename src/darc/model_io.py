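"""Readers and writers for every external representation the engine touches.

Receptor structures come in as PDB (via gemmi), ligand conformer ensembles as
multi-record SDF or MOL2 (via rdkit), electrostatic potential grids as OpenDX
scalar grids, and the pocket topography as the versioned plain-text "ray-file"
dialect defined here.  All readers are total on their formats: any failure is
a typed :mod:`darc.errors` exception, never a partially filled object.

Units are Angstrom for coordinates/radii and elementary charges for partial
charges; PDB residue numbering is kept 1-based as authored.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np
from rdkit import Chem

from .errors import (
    ConformerMismatchError,
    DarcError,
    EmptyStructureError,
    RayFileError,
    SelectionError,
)

log = logging.getLogger(__name__)

#: Element -> van der Waals radius (A).  Unknown elements fall back to 1.7 A
#: (carbon-like) with a logged warning.
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "H": 1.20}
DEFAULT_RADIUS = 1.70

RAYFILE_VERSION = 1
_BOUNDARY_TOKEN = "B"


def element_radius(element: str) -> float:
    """Van der Waals radius for an element symbol, with a documented fallback."""
    r = VDW_RADII.get(element.capitalize())
    if r is None:
        log.warning("unknown element %r: assigning default radius %.2f A",
                    element, DEFAULT_RADIUS)
        return DEFAULT_RADIUS
    return r


@dataclass
class Receptor:
    """A rigid receptor: one sphere per atom plus residue bookkeeping.

    Residues are keyed by ``(chain, resid)`` so duplicate residue numbers in
    different chains stay distinct.
    """

    elements: list[str]
    coords: np.ndarray          # (N, 3) A
    radii: np.ndarray           # (N,) A
    charges: np.ndarray         # (N,) e
    chains: list[str]
    resids: np.ndarray          # (N,) int, PDB numbering
    atom_names: list[str] = field(default_factory=list)
    name: str = "receptor"

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        self.radii = np.asarray(self.radii, dtype=float).ravel()
        self.charges = np.asarray(self.charges, dtype=float).ravel()
        self.resids = np.asarray(self.resids, dtype=int).ravel()
        n = len(self.coords)
        if n == 0:
            raise EmptyStructureError(f"receptor {self.name!r} has no atoms")
        if not np.isfinite(self.coords).all():
            raise DarcError("receptor has non-finite coordinates")
        if (self.radii <= 0).any():
            raise DarcError("receptor radii must be positive")
        if not self.atom_names:
            self.atom_names = [f"{el}{i+1}" for i, el in enumerate(self.elements)]

    @property
    def n_atoms(self) -> int:
        return len(self.coords)

    def residue_keys(self) -> list[tuple[str, int]]:
        seen: dict[tuple[str, int], None] = {}
        for ch, rid in zip(self.chains, self.resids):
            seen.setdefault((ch, int(rid)), None)
        return list(seen)

    def atom_mask_for_residues(self, selection) -> np.ndarray:
        """Boolean atom mask for a residue selection.

        ``selection`` is an iterable of residue ids (ints, any chain) or
        ``(chain, resid)`` pairs.  Unknown residues raise
        :class:`~darc.errors.SelectionError` listing what exists.
        """
        keys = set(self.residue_keys())
        mask = np.zeros(self.n_atoms, dtype=bool)
        for item in selection:
            if isinstance(item, tuple):
                ch, rid = item[0], int(item[1])
                if (ch, rid) not in keys:
                    raise SelectionError(
                        f"residue {ch}:{rid} not in receptor; valid residues: "
                        + ", ".join(f"{c}:{r}" for c, r in sorted(keys)[:50]))
                for i, (c, r) in enumerate(zip(self.chains, self.resids)):
                    if c == ch and r == rid:
                        mask[i] = True
            else:
                rid = int(item)
                hit = self.resids == rid
                if not hit.any():
                    raise SelectionError(
                        f"residue {rid} not in receptor; valid residues: "
                        + ", ".join(f"{c}:{r}" for c, r in sorted(keys)[:50]))
                mask |= hit
        return mask


@dataclass
class ConformerSet:
    """An ordered ensemble of rigid conformers sharing one atom list."""

    name: str
    elements: list[str]
    radii: np.ndarray           # (A,)
    charges: np.ndarray         # (A,) partial charges, e
    coords: np.ndarray          # (n_conf, A, 3)
    reference_index: int = 0    # 0-based index of the reference conformer

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim == 2:
            self.coords = self.coords[None]
        self.radii = np.asarray(self.radii, dtype=float).ravel()
        self.charges = np.asarray(self.charges, dtype=float).ravel()
        n_conf, n_atoms, _ = self.coords.shape
        if n_conf < 1:
            raise ConformerMismatchError(f"{self.name!r}: no conformers")
        if not (len(self.elements) == len(self.radii) == len(self.charges) == n_atoms):
            raise ConformerMismatchError(
                f"{self.name!r}: atom annotation lengths disagree with coordinates")
        if not np.isfinite(self.charges).all():
            raise DarcError(f"{self.name!r}: non-finite partial charges")

    @property
    def n_conformers(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]


# ---------------------------------------------------------------------------
# receptor PDB


def read_receptor(path, charge_table=None) -> Receptor:
    """Read a receptor from a PDB file (ATOM and HETATM records).

    Hydrogens are kept if present.  Radii come from :data:`VDW_RADII`;
    partial charges are zero unless ``charge_table`` (a whitespace table of
    ``chain resid atom_name charge`` lines) is supplied.
    """
    path = Path(path)
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError, OSError) as exc:
        raise DarcError(f"cannot read PDB {path}: {exc}") from exc
    elements, coords, chains, resids, names = [], [], [], [], []
    for model in st:
        for chain in model:
            for res in chain:
                for atom in res:
                    elements.append(atom.element.name)
                    coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
                    chains.append(chain.name)
                    resids.append(res.seqid.num)
                    names.append(atom.name)
        break  # first model only
    if not coords:
        raise EmptyStructureError(f"{path} contains no atoms")
    radii = np.array([element_radius(e) for e in elements])
    charges = np.zeros(len(coords))
    if charge_table is not None:
        table = _read_charge_table(charge_table)
        for i, (ch, rid, nm) in enumerate(zip(chains, resids, names)):
            charges[i] = table.get((ch, int(rid), nm), 0.0)
    return Receptor(elements=elements, coords=np.array(coords), radii=radii,
                    charges=charges, chains=chains, resids=np.array(resids),
                    atom_names=names, name=path.stem)


def _read_charge_table(path) -> dict:
    table = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 4:
            raise DarcError(f"{path}:{lineno}: expected 'chain resid name charge'")
        table[(parts[0], int(parts[1]), parts[2])] = float(parts[3])
    return table


def write_charge_table(receptor: Receptor, path) -> None:
    with open(path, "w") as fh:
        fh.write("# chain resid atom_name charge_e\n")
        for ch, rid, nm, q in zip(receptor.chains, receptor.resids,
                                  receptor.atom_names, receptor.charges):
            fh.write(f"{ch} {rid} {nm} {q:.6f}\n")


def write_receptor_pdb(receptor: Receptor, path) -> None:
    """Write the receptor back out as a minimal PDB (ATOM records)."""
    _write_pdb(path, [(receptor, "ATOM")])


def write_complex_pdb(receptor: Receptor, pose_coords: np.ndarray,
                      ligand_elements: list[str], path,
                      ligand_name: str = "LIG") -> None:
    """Write a docked protein-ligand complex: receptor ATOMs + ligand HETATMs."""
    st = _as_gemmi(receptor, "ATOM")
    model = st[0]
    chain = gemmi.Chain("X")
    res = gemmi.Residue()
    res.name = ligand_name[:3].upper()
    res.seqid = gemmi.SeqId(1, " ")
    res.het_flag = "H"
    for i, (el, xyz) in enumerate(zip(ligand_elements, np.asarray(pose_coords))):
        atom = gemmi.Atom()
        atom.name = f"{el}{i+1}"
        atom.element = gemmi.Element(el)
        atom.pos = gemmi.Position(*map(float, xyz))
        res.add_atom(atom)
    chain.add_residue(res)
    model.add_chain(chain)
    st.write_pdb(str(path))


def _as_gemmi(receptor: Receptor, record: str) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = receptor.name
    model = gemmi.Model("1")
    by_chain: dict[str, gemmi.Chain] = {}
    cur_key = None
    cur_res = None
    for el, xyz, ch, rid, nm in zip(receptor.elements, receptor.coords,
                                    receptor.chains, receptor.resids,
                                    receptor.atom_names):
        if ch not in by_chain:
            by_chain[ch] = gemmi.Chain(ch)
        if cur_key != (ch, rid):
            if cur_res is not None:
                by_chain[cur_key[0]].add_residue(cur_res)
            cur_res = gemmi.Residue()
            cur_res.name = "UNK"
            cur_res.seqid = gemmi.SeqId(int(rid), " ")
            if record == "HETATM":
                cur_res.het_flag = "H"
            cur_key = (ch, int(rid))
        atom = gemmi.Atom()
        atom.name = nm[:4]
        atom.element = gemmi.Element(el)
        atom.pos = gemmi.Position(*map(float, xyz))
        cur_res.add_atom(atom)
    if cur_res is not None:
        by_chain[cur_key[0]].add_residue(cur_res)
    for chain in by_chain.values():
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    return st


def _write_pdb(path, groups) -> None:
    receptor, record = groups[0]
    _as_gemmi(receptor, record).write_pdb(str(path))


# ---------------------------------------------------------------------------
# ligand conformers (SDF / MOL2)

#: SD tag carrying whitespace-separated per-atom partial charges.
CHARGE_TAG = "PartialCharges"


def read_conformers(path) -> ConformerSet:
    """Read a multi-record SDF or MOL2 conformer ensemble.

    All records must share one atom ordering.  Partial charges are taken from
    the file's charge block when present (MOL2 charge column, or the
    ``PartialCharges`` SD tag); otherwise they default to zero with a warning,
    which keeps shape-only docking usable.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".sdf", ".sd", ".mol"):
        records = _read_sdf(path)
    elif suffix == ".mol2":
        records = _read_mol2(path)
    else:
        raise DarcError(f"unsupported conformer format: {path.suffix!r}")
    if not records:
        raise ConformerMismatchError(f"{path}: no conformer records")
    name, elements, charges0, coords0, had_q0 = records[0]
    all_coords = [coords0]
    for idx, (_, els, q, xyz, _had) in enumerate(records[1:], start=2):
        if len(els) != len(elements) or els != elements:
            raise ConformerMismatchError(
                f"{path}: record {idx} has {len(els)} atoms / ordering that "
                f"does not match record 1 ({len(elements)} atoms)")
        all_coords.append(xyz)
    if not any(r[4] for r in records):
        warnings.warn(f"{path}: no partial charges found; using zeros "
                      "(shape-only scoring)", stacklevel=2)
    radii = np.array([element_radius(e) for e in elements])
    name = re.sub(r"_conf\d+$", "", name)  # per-record suffix, not a name
    return ConformerSet(name=name or path.stem, elements=elements, radii=radii,
                        charges=np.asarray(charges0, dtype=float),
                        coords=np.stack(all_coords))


def _read_sdf(path):
    supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=False)
    records = []
    for mol in supplier:
        if mol is None:
            raise DarcError(f"{path}: unparseable SDF record "
                            f"{len(records) + 1}")
        conf = mol.GetConformer()
        elements = [a.GetSymbol() for a in mol.GetAtoms()]
        xyz = np.array(conf.GetPositions(), dtype=float)
        had_q = mol.HasProp(CHARGE_TAG)
        if had_q:
            q = [float(v) for v in mol.GetProp(CHARGE_TAG).split()]
            if len(q) != len(elements):
                raise DarcError(f"{path}: {CHARGE_TAG} length mismatch")
        else:
            q = [0.0] * len(elements)
        name = mol.GetProp("_Name") if mol.HasProp("_Name") else ""
        records.append((name, elements, q, xyz, had_q))
    return records


def _read_mol2(path):
    text = Path(path).read_text()
    blocks = ["@<TRIPOS>MOLECULE" + b for b in text.split("@<TRIPOS>MOLECULE")[1:]]
    records = []
    for i, block in enumerate(blocks, 1):
        mol = Chem.MolFromMol2Block(block, removeHs=False, sanitize=False)
        if mol is None:
            raise DarcError(f"{path}: unparseable MOL2 record {i}")
        conf = mol.GetConformer()
        elements = [a.GetSymbol() for a in mol.GetAtoms()]
        xyz = np.array(conf.GetPositions(), dtype=float)
        q, had_q = [], False
        for a in mol.GetAtoms():
            if a.HasProp("_TriposPartialCharge"):
                q.append(a.GetDoubleProp("_TriposPartialCharge"))
                had_q = True
            else:
                q.append(0.0)
        name = mol.GetProp("_Name") if mol.HasProp("_Name") else ""
        records.append((name, elements, q, xyz, had_q))
    return records


def write_conformers_sdf(conformers: ConformerSet, path) -> None:
    """Write a ConformerSet as a multi-record SDF readable by read_conformers."""
    writer = Chem.SDWriter(str(path))
    writer.SetKekulize(False)
    for k in range(conformers.n_conformers):
        mol = Chem.RWMol()
        for el in conformers.elements:
            mol.AddAtom(Chem.Atom(el))
        conf = Chem.Conformer(conformers.n_atoms)
        for i, xyz in enumerate(conformers.coords[k]):
            conf.SetAtomPosition(i, [float(v) for v in xyz])
        mol.AddConformer(conf)
        mol.SetProp("_Name", f"{conformers.name}_conf{k + 1}")
        mol.SetProp(CHARGE_TAG,
                    " ".join(f"{q:.6f}" for q in conformers.charges))
        mol.UpdatePropertyCache(strict=False)
        writer.write(mol)
    writer.close()


# ---------------------------------------------------------------------------
# ray-file


def write_rayfile(raymap, path) -> None:
    """Serialize a RayMap to the versioned plain-text ray-file dialect.

    The layout (header of origins, pocket center and search bounds, then one
    record per ray) is this package's own invention and is marked as such in
    the header; boundary-layer rays carry a sentinel token instead of a fake
    distance.  ``read_rayfile(write_rayfile(x)) == x`` to 1e-6 A / radian.
    """
    lines = [
        "# darc ray-file (package-defined dialect)",
        f"version {RAYFILE_VERSION}",
        f"placement {raymap.placement}",
        f"origin_count {len(raymap.origins)}",
    ]
    for i, o in enumerate(raymap.origins, 1):
        lines.append(f"origin {i} {o[0]:.8f} {o[1]:.8f} {o[2]:.8f}")
    p = raymap.pocket_center
    lines.append(f"pocket_center {p[0]:.8f} {p[1]:.8f} {p[2]:.8f}")
    lo, hi = raymap.bounds
    lines.append("bounds " + " ".join(f"{v:.8f}" for v in (*lo, *hi)))
    lines.append(f"ray_count {len(raymap.origin_index)}")
    for oi, th, ph, rho in zip(raymap.origin_index, raymap.theta,
                               raymap.phi, raymap.rho_pocket):
        tok = _BOUNDARY_TOKEN if np.isnan(rho) else f"{rho:.8f}"
        lines.append(f"{oi} {th:.8f} {ph:.8f} {tok}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_rayfile(path):
    """Parse a ray-file written by :func:`write_rayfile`."""
    from .raycast import RayMap  # deferred: raycast does not import model_io

    lines = Path(path).read_text().splitlines()
    lines = [ln for ln in lines if ln.strip() and not ln.startswith("#")]
    try:
        kv = dict([lines[0].split(maxsplit=1)])
        if "version" not in kv:
            raise RayFileError(f"{path}: missing version header")
        version = int(kv["version"])
        if version != RAYFILE_VERSION:
            raise RayFileError(
                f"{path}: unsupported ray-file version {version} "
                f"(this reader supports version {RAYFILE_VERSION})")
        it = iter(lines[1:])
        placement = next(it).split(maxsplit=1)[1]
        n_origins = int(next(it).split()[1])
        origins = np.empty((n_origins, 3))
        for i in range(n_origins):
            parts = next(it).split()
            if parts[0] != "origin" or int(parts[1]) != i + 1:
                raise RayFileError(f"{path}: corrupted origin block")
            origins[i] = [float(v) for v in parts[2:5]]
        parts = next(it).split()
        if parts[0] != "pocket_center":
            raise RayFileError(f"{path}: corrupted header (pocket_center)")
        pocket_center = np.array([float(v) for v in parts[1:4]])
        parts = next(it).split()
        if parts[0] != "bounds" or len(parts) != 7:
            raise RayFileError(f"{path}: corrupted header (bounds)")
        vals = [float(v) for v in parts[1:]]
        bounds = (np.array(vals[:3]), np.array(vals[3:]))
        n_rays = int(next(it).split()[1])
        oi = np.empty(n_rays, dtype=int)
        theta = np.empty(n_rays)
        phi = np.empty(n_rays)
        rho = np.empty(n_rays)
        for r in range(n_rays):
            parts = next(it).split()
            oi[r] = int(parts[0])
            theta[r] = float(parts[1])
            phi[r] = float(parts[2])
            rho[r] = np.nan if parts[3] == _BOUNDARY_TOKEN else float(parts[3])
        if (oi < 1).any() or (oi > n_origins).any():
            raise RayFileError(f"{path}: origin index out of range")
        pocket = ~np.isnan(rho)
        if (rho[pocket] <= 0).any():
            raise RayFileError(f"{path}: non-positive pocket distance")
    except RayFileError:
        raise
    except (StopIteration, ValueError, IndexError) as exc:
        raise RayFileError(f"{path}: corrupted ray-file: {exc}") from exc
    return RayMap(origins=origins, pocket_center=pocket_center, bounds=bounds,
                  placement=placement, origin_index=oi, theta=theta, phi=phi,
                  rho_pocket=rho)


# ---------------------------------------------------------------------------
# OpenDX scalar grids


def read_dx_grid(path):
    """Read an OpenDX scalar grid (APBS dialect) into an ESPGrid.

    Only orthogonal, uniformly spaced grids are supported.  Data order follows
    the DX convention (last index, z, varies fastest), which is also the
    internal storage order.
    """
    from .electrostatics import ESPGrid
    from .errors import UnsupportedGridError

    counts = origin = None
    deltas = []
    values = []
    n_items = None
    with open(path) as fh:
        for line in fh:
            s = line.strip()
            if not s or s.startswith("#"):
                continue
            if s.startswith("object") and "gridpositions" in s:
                counts = [int(v) for v in s.split("counts", 1)[1].split()]
            elif s.startswith("origin"):
                origin = [float(v) for v in s.split()[1:4]]
            elif s.startswith("delta"):
                deltas.append([float(v) for v in s.split()[1:4]])
            elif s.startswith("object") and "class array" in s:
                n_items = int(s.split("items", 1)[1].split()[0])
            elif s.startswith(("object", "attribute", "component")):
                continue
            else:
                values.extend(float(v) for v in s.split())
    if counts is None or origin is None or len(deltas) != 3 or n_items is None:
        raise DarcError(f"{path}: not a recognizable OpenDX scalar grid")
    D = np.array(deltas)
    off = D - np.diag(np.diag(D))
    if np.abs(off).max() > 1e-9:
        raise UnsupportedGridError(f"{path}: non-orthogonal grid axes")
    spacings = np.diag(D)
    if np.ptp(spacings) > 1e-9:
        raise UnsupportedGridError(
            f"{path}: non-uniform spacing {spacings.tolist()}")
    if len(values) != n_items or n_items != int(np.prod(counts)):
        raise DarcError(f"{path}: expected {n_items} values, got {len(values)}")
    vals = np.array(values).reshape(counts)  # C order: z fastest, per DX
    return ESPGrid(origin=np.array(origin), spacing=float(spacings[0]),
                   values=vals)


def write_dx_grid(grid, path, comment: str = "darc potential grid") -> None:
    """Write an ESPGrid as an OpenDX scalar grid (round-trips bit-equal)."""
    nx, ny, nz = grid.values.shape
    h = grid.spacing
    with open(path, "w") as fh:
        fh.write(f"# {comment}\n")
        fh.write(f"object 1 class gridpositions counts {nx} {ny} {nz}\n")
        fh.write("origin {:.10g} {:.10g} {:.10g}\n".format(*grid.origin))
        fh.write(f"delta {h:.10g} 0 0\ndelta 0 {h:.10g} 0\ndelta 0 0 {h:.10g}\n")
        fh.write(f"object 2 class gridconnections counts {nx} {ny} {nz}\n")
        fh.write(f"object 3 class array type double rank 0 items "
                 f"{nx * ny * nz} data follows\n")
        flat = grid.values.ravel()  # C order: z fastest
        for i in range(0, len(flat), 3):
            fh.write(" ".join(repr(float(v)) for v in flat[i:i + 3]) + "\n")
        fh.write('attribute "dep" string "positions"\n')
        fh.write('object "regular positions regular connections" class field\n')
        fh.write('component "positions" value 1\n')
        fh.write('component "connections" value 2\n')
        fh.write('component "data" value 3\n')
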