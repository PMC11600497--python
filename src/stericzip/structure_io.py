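"""Coordinate I/O, atom normalization and crystal-symmetry expansion.

Structures are read with gemmi (PDB and mmCIF); everything downstream works
in orthonormal Angstrom coordinates. Fractional coordinates appear only
inside :func:`expand_symmetry`.
"""
from __future__ import annotations

import copy as _copymod
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np
from scipy.spatial import cKDTree

from .config import (
    FALLBACK_RADIUS,
    SOLVENT_RESIDUES,
    VDW_RADII,
    element_radius,
)

AMINO3 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AMINO1 = {v: k for k, v in AMINO3.items()}

BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT"}


@dataclass
class AtomRecord:
    """One atom of a crystal model (orthonormal Angstrom coordinates)."""

    serial: int
    name: str
    element: str
    residue_name: str
    residue_seq: int
    chain_id: str
    position: np.ndarray
    occupancy: float = 1.0
    altloc: str = ""
    vdw_radius: float = FALLBACK_RADIUS

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in ("H", "D")

    @property
    def is_solvent(self) -> bool:
        return self.residue_name.strip().upper() in SOLVENT_RESIDUES


@dataclass
class CrystalModel:
    """Atoms plus unit cell and space-group operators of one entry."""

    atoms: list[AtomRecord]
    cell: tuple[float, float, float, float, float, float]
    spacegroup: str
    #: list of (3x3 rotation, 3-vector translation) in fractional coords
    symmetry_ops: list[tuple[np.ndarray, np.ndarray]]
    name: str = "model"

    @property
    def chain_ids(self) -> list[str]:
        seen: list[str] = []
        for a in self.atoms:
            if a.chain_id not in seen:
                seen.append(a.chain_id)
        return seen

    def chain_atoms(self, chain_id: str) -> list[AtomRecord]:
        return [a for a in self.atoms if a.chain_id == chain_id]

    def orthogonalization_matrix(self) -> np.ndarray:
        a, b, c, al, be, ga = self.cell
        cell = gemmi.UnitCell(a, b, c, al, be, ga)
        return np.array(cell.orth.mat.tolist())

    @property
    def cell_volume(self) -> float:
        a, b, c, al, be, ga = self.cell
        return gemmi.UnitCell(a, b, c, al, be, ga).volume


class ChainCopy:
    """A symmetry/lattice copy of one chain, stored as flat numpy arrays.

    Solvent residues of the source chain are excluded here; they are expanded
    separately (see :class:`ExpandedLattice.solvent`).
    """

    def __init__(self, chain_id: str, op_index: int, shift: tuple[int, int, int],
                 atoms: list[AtomRecord], coords: np.ndarray):
        self.chain_id = chain_id
        self.op_index = op_index
        self.shift = shift
        self.atom_names = [a.name for a in atoms]
        self.elements = [a.element for a in atoms]
        self.res_names = [a.residue_name for a in atoms]
        self.res_seqs = np.array([a.residue_seq for a in atoms], dtype=int)
        self.radii = np.array([a.vdw_radius for a in atoms], dtype=float)
        self.coords = np.asarray(coords, dtype=float)
        # ordered residue table: (name, seq, {atom_name: index})
        self.residues: list[tuple[str, int, dict[str, int]]] = []
        seen: dict[int, int] = {}
        for i, a in enumerate(atoms):
            if a.residue_seq not in seen:
                seen[a.residue_seq] = len(self.residues)
                self.residues.append((a.residue_name, a.residue_seq, {}))
            self.residues[seen[a.residue_seq]][2][a.name] = i

    @property
    def key(self) -> tuple:
        return (self.chain_id, self.op_index, self.shift)

    @property
    def label(self) -> str:
        i, j, k = self.shift
        return f"{self.chain_id}/{self.op_index}/{i},{j},{k}"

    @property
    def is_identity(self) -> bool:
        return self.op_index == 0 and self.shift == (0, 0, 0)

    @property
    def n_atoms(self) -> int:
        return len(self.coords)

    def sequence(self) -> str:
        return "".join(AMINO3.get(r[0], "X") for r in self.residues)

    def residue_atom(self, res_index: int, name: str) -> int | None:
        return self.residues[res_index][2].get(name)

    def direction(self) -> np.ndarray:
        """Unit N->C chain direction from the CA trace."""
        from .geometry import fit_direction
        ca = self.ca_coords()
        hint = ca[-1] - ca[0]
        return fit_direction(ca, hint=hint)

    def ca_coords(self) -> np.ndarray:
        idx = [r[2]["CA"] for r in self.residues if "CA" in r[2]]
        return self.coords[idx]

    def centroid(self) -> np.ndarray:
        return self.coords.mean(axis=0)

    def transformed(self, rot: np.ndarray, trans: np.ndarray) -> "ChainCopy":
        new = _copymod.copy(self)
        new.coords = self.coords @ np.asarray(rot).T + np.asarray(trans)
        return new

    def sidechain_indices(self, res_index: int) -> list[int]:
        name, _, amap = self.residues[res_index]
        if name == "GLY":
            return [amap["CA"]] if "CA" in amap else []
        return [i for nm, i in amap.items() if nm not in BACKBONE_ATOMS]


@dataclass
class ExpandedLattice:
    """Finite neighborhood of the asymmetric unit under crystal symmetry."""

    model: CrystalModel
    copies: list[ChainCopy]
    #: solvent atoms over all generated copies: coords (M,3), radii (M,),
    #: residue names and provenance labels (op/shift strings)
    solvent_coords: np.ndarray = field(default_factory=lambda: np.zeros((0, 3)))
    solvent_radii: np.ndarray = field(default_factory=lambda: np.zeros(0))
    solvent_res: list[str] = field(default_factory=list)
    solvent_provenance: list[str] = field(default_factory=list)

    @property
    def provenance(self) -> dict[tuple, str]:
        return {c.key: c.chain_id for c in self.copies}

    def identity_copies(self) -> list[ChainCopy]:
        return [c for c in self.copies if c.is_identity]


def _guess_element(atom_name: str) -> str:
    name = atom_name.strip()
    if not name:
        return "C"
    if name[0].isdigit():
        name = name.lstrip("0123456789")
    two = name[:2].upper()
    if two in VDW_RADII and len(name) > 1 and name[1].isalpha() and two in (
            "CL", "BR", "NA", "MG", "ZN", "SE"):
        return two
    return name[0].upper()


def load_structure(path: str | Path, format: str = "auto") -> CrystalModel:
    """Read a PDB or mmCIF file into a :class:`CrystalModel`.

    Raises ``ValueError`` when the unit cell or space group record is
    missing. Unknown elements get the fallback radius with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = {"pdb": gemmi.CoorFormat.Pdb, "mmcif": gemmi.CoorFormat.Mmcif,
           "auto": gemmi.CoorFormat.Detect}[format]
    st = gemmi.read_structure(str(path), format=fmt)
    if not st.cell.is_crystal():
        raise ValueError(f"{path.name}: missing unit cell (no CRYST1/_cell)")
    sg_name = st.spacegroup_hm or ""
    sg = gemmi.find_spacegroup_by_name(sg_name) if sg_name else None
    if sg is None:
        raise ValueError(f"{path.name}: missing or unknown space group record")
    ops = []
    for op in sg.operations():
        rot = np.array(op.rot, dtype=float) / op.DEN
        tran = np.array(op.tran, dtype=float) / op.DEN
        ops.append((rot, tran))

    atoms: list[AtomRecord] = []
    serial = 0
    for chain in st[0]:
        for res in chain:
            for at in res:
                serial += 1
                elem = at.element.name if at.element.name else _guess_element(at.name)
                eu = elem.upper()
                if eu not in VDW_RADII:
                    warnings.warn(
                        f"unknown element {elem!r} for atom {at.name} "
                        f"({res.name} {res.seqid.num}); using fallback radius")
                atoms.append(AtomRecord(
                    serial=serial,
                    name=at.name,
                    element=elem,
                    residue_name=res.name,
                    residue_seq=res.seqid.num,
                    chain_id=chain.name,
                    position=np.array([at.pos.x, at.pos.y, at.pos.z]),
                    occupancy=at.occ,
                    altloc=at.altloc if at.altloc else "",
                    vdw_radius=element_radius(elem),
                ))
    return CrystalModel(
        atoms=atoms,
        cell=(st.cell.a, st.cell.b, st.cell.c,
              st.cell.alpha, st.cell.beta, st.cell.gamma),
        spacegroup=sg.hm,
        symmetry_ops=ops,
        name=st.name or path.stem,
    )


def sanitize(model: CrystalModel) -> CrystalModel:
    """Drop hydrogens and all but the best altloc conformer.

    Altloc groups keep the highest-occupancy conformer (ties: alphabetically
    first altloc id), with the altloc flag cleared. Idempotent; solvent is
    retained (tagged via :attr:`AtomRecord.is_solvent`).
    """
    # choose winning altloc per (chain, residue, atom name)
    winners: dict[tuple, tuple] = {}
    for a in model.atoms:
        if a.is_hydrogen:
            continue
        key = (a.chain_id, a.residue_seq, a.residue_name, a.name)
        cand = (-a.occupancy, a.altloc or "~")  # "~" sorts after letters
        if key not in winners or cand < winners[key][0]:
            winners[key] = (cand, a)
    kept = {id(v[1]) for v in winners.values()}
    atoms = []
    for a in model.atoms:
        if id(a) not in kept:
            continue
        b = _copymod.copy(a)
        b.altloc = ""
        atoms.append(b)
    return CrystalModel(atoms=atoms, cell=model.cell, spacegroup=model.spacegroup,
                        symmetry_ops=model.symmetry_ops, name=model.name)


def _split_chain(atoms: list[AtomRecord]) -> tuple[list[AtomRecord], list[AtomRecord]]:
    peptide = [a for a in atoms if not a.is_solvent]
    solvent = [a for a in atoms if a.is_solvent]
    return peptide, solvent


def expand_symmetry(model: CrystalModel, radius: float,
                    max_copies: int = 2000) -> ExpandedLattice:
    """Generate all chain copies with any atom within `radius` of the ASU.

    Lattice translations are searched over -2..+2 along each cell axis for
    every space-group operator; duplicate copies (identical coordinates, as
    on special positions) are dropped. The identity copy is always present.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    orth = model.orthogonalization_matrix()
    frac = np.linalg.inv(orth)

    asu_coords = np.array([a.position for a in model.atoms])
    tree = cKDTree(asu_coords)

    copies: list[ChainCopy] = []
    sol_coords: list[np.ndarray] = []
    sol_radii: list[float] = []
    sol_res: list[str] = []
    sol_prov: list[str] = []

    chain_data = []
    for cid in model.chain_ids:
        peptide, solvent = _split_chain(model.chain_atoms(cid))
        chain_data.append((cid, peptide, solvent))

    shifts = [(i, j, k) for i in range(-2, 3) for j in range(-2, 3)
              for k in range(-2, 3)]
    existing: dict[str, list[np.ndarray]] = {cid: [] for cid, _, _ in chain_data}

    for op_index, (rot, tran) in enumerate(model.symmetry_ops):
        for shift in shifts:
            sv = np.array(shift, dtype=float)
            for cid, peptide, solvent in chain_data:
                for group, is_pep in ((peptide, True), (solvent, False)):
                    if not group:
                        continue
                    xyz = np.array([a.position for a in group])
                    fr = xyz @ frac.T
                    fr = fr @ rot.T + tran + sv
                    new_xyz = fr @ orth.T
                    d, _ = tree.query(new_xyz, k=1,
                                      distance_upper_bound=radius)
                    if not np.any(np.isfinite(d)):
                        continue
                    if is_pep:
                        is_ident = (op_index == 0 and shift == (0, 0, 0)
                                    and np.allclose(rot, np.eye(3))
                                    and np.allclose(tran, 0))
                        dup = any(
                            prev.shape == new_xyz.shape
                            and np.max(np.abs(prev - new_xyz)) < 1e-3
                            for prev in existing[cid])
                        if dup and not is_ident:
                            continue
                        existing[cid].append(new_xyz)
                        copies.append(ChainCopy(cid, op_index, shift, group,
                                                new_xyz))
                        if len(copies) > max_copies:
                            raise RuntimeError(
                                "symmetry expansion exceeded copy cap "
                                f"({max_copies}); reduce the radius")
                    else:
                        prov = f"{cid}/{op_index}/{shift}"
                        for a, p in zip(group, new_xyz):
                            sol_coords.append(p)
                            sol_radii.append(a.vdw_radius)
                            sol_res.append(a.residue_name)
                            sol_prov.append(prov)

    # ensure identity copies exist even for an isolated molecule
    have_ident = {c.chain_id for c in copies if c.is_identity}
    for cid, peptide, _ in chain_data:
        if peptide and cid not in have_ident:
            xyz = np.array([a.position for a in peptide])
            copies.insert(0, ChainCopy(cid, 0, (0, 0, 0), peptide, xyz))

    return ExpandedLattice(
        model=model,
        copies=copies,
        solvent_coords=(np.array(sol_coords) if sol_coords
                        else np.zeros((0, 3))),
        solvent_radii=np.array(sol_radii),
        solvent_res=sol_res,
        solvent_provenance=sol_prov,
    )


def as_lattice(model: CrystalModel) -> ExpandedLattice:
    """Wrap the asymmetric-unit chains as identity copies (no expansion)."""
    copies = []
    sol_coords, sol_radii, sol_res, sol_prov = [], [], [], []
    for cid in model.chain_ids:
        peptide, solvent = _split_chain(model.chain_atoms(cid))
        if peptide:
            xyz = np.array([a.position for a in peptide])
            copies.append(ChainCopy(cid, 0, (0, 0, 0), peptide, xyz))
        for a in solvent:
            sol_coords.append(a.position)
            sol_radii.append(a.vdw_radius)
            sol_res.append(a.residue_name)
            sol_prov.append(f"{cid}/0/(0, 0, 0)")
    return ExpandedLattice(
        model=model, copies=copies,
        solvent_coords=np.array(sol_coords) if sol_coords else np.zeros((0, 3)),
        solvent_radii=np.array(sol_radii),
        solvent_res=sol_res, solvent_provenance=sol_prov)


_CHAIN_ID_POOL = ("ABCDEFGHIJKLMNOPQRSTUVWXYZ"
                  "abcdefghijklmnopqrstuvwxyz0123456789")


def write_pdb(model: CrystalModel, path: str | Path,
              copies: list[ChainCopy] | None = None) -> None:
    """Write a model (or a set of expanded chain copies) as a PDB file.

    Expanded copies get remapped single-character chain ids with the
    provenance recorded in REMARK 290 lines.
    """
    path = Path(path)
    a, b, c, al, be, ga = model.cell
    lines = [f"CRYST1{a:9.3f}{b:9.3f}{c:9.3f}{al:7.2f}{be:7.2f}{ga:7.2f} "
             f"{model.spacegroup:<11s}{1:4d}"]
    serial = 0

    def atom_line(serial, name, resname, chain_id, resseq, xyz, occ, elem):
        nm = name if len(name) >= 4 else f" {name:<3s}"
        return (f"ATOM  {serial:5d} {nm:<4s}{'':1s}{resname:>3s} {chain_id:1s}"
                f"{resseq:4d}    {xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
                f"{occ:6.2f}{0.0:6.2f}          {elem:>2s}")

    if copies is None:
        for at in model.atoms:
            serial += 1
            lines.append(atom_line(serial, at.name, at.residue_name,
                                   at.chain_id[:1] or "A", at.residue_seq,
                                   at.position, at.occupancy, at.element))
    else:
        for idx, cp in enumerate(copies):
            if idx >= len(_CHAIN_ID_POOL):
                raise ValueError("too many copies for PDB chain ids")
            cid = _CHAIN_ID_POOL[idx]
            lines.insert(1, f"REMARK 290 COPY {cid} FROM {cp.label}")
            for i in range(cp.n_atoms):
                serial += 1
                lines.append(atom_line(serial, cp.atom_names[i],
                                       cp.res_names[i], cid,
                                       int(cp.res_seqs[i]), cp.coords[i],
                                       1.0, cp.elements[i]))
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
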