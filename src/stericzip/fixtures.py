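"""Synthetic ideal peptide beta-sheet crystals with known ground truth.

Strands are built from internal coordinates (NeRF) at requested (phi, psi),
oriented into the canonical amyloid frame -- strand direction along z,
sheets stacked along y, inter-sheet packing along x -- and assembled into
sheets and steric zippers realizing topology classes 1-8, out-of-register
shifts and kinked (LARKS-like) chains. Construction is fully deterministic.

Zipper crystals are returned as P1 cells whose lattice translations
reproduce the infinite sheet along y and (for catemers) the zipper stacking
along x, so the symmetry-expansion and interface machinery can be exercised
end to end without real data.
"""
from __future__ import annotations

import copy as _copymod
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.spatial import cKDTree

from .config import element_radius
from .geometry import (
    bond_angle,
    fit_direction,
    place_atom,
    rotation_about_axis,
)
from .structure_io import AMINO1, AtomRecord, CrystalModel

# ---------------------------------------------------------------------------
# internal-coordinate tables
# ---------------------------------------------------------------------------

# backbone geometry (Engh-Huber-like ideal values)
B_N_CA, B_CA_C, B_C_N, B_C_O, B_CA_CB = 1.458, 1.525, 1.329, 1.231, 1.530
A_N_CA_C, A_CA_C_N, A_C_N_CA, A_CA_C_O = 111.2, 116.2, 121.7, 120.8
A_C_CA_CB, T_N_C_CA_CB = 110.6, 122.6  # CB improper (L-amino acids)
OMEGA = 180.0

# side chains beyond CB: (atom, (ref_a, ref_b, ref_c), bond, angle, torsion)
# refs name atoms of the same residue; torsions are fixed ideal rotamers.
SIDECHAIN_ZMAT: dict[str, list[tuple]] = {
    "ALA": [],
    "GLY": [],
    "SER": [("OG", ("N", "CA", "CB"), 1.417, 110.8, -65.0)],
    "VAL": [("CG1", ("N", "CA", "CB"), 1.527, 110.5, 175.0),
            ("CG2", ("N", "CA", "CB"), 1.527, 110.5, 52.7)],
    "LEU": [("CG", ("N", "CA", "CB"), 1.530, 116.3, -65.0),
            ("CD1", ("CA", "CB", "CG"), 1.521, 110.7, 175.0),
            ("CD2", ("CA", "CB", "CG"), 1.521, 110.7, -63.0)],
    "ILE": [("CG1", ("N", "CA", "CB"), 1.530, 110.4, -65.0),
            ("CG2", ("N", "CA", "CB"), 1.521, 110.5, 57.0),
            ("CD1", ("CA", "CB", "CG1"), 1.513, 113.8, 170.0)],
    "ASN": [("CG", ("N", "CA", "CB"), 1.516, 112.6, -65.0),
            ("OD1", ("CA", "CB", "CG"), 1.231, 120.8, -60.0),
            ("ND2", ("CA", "CB", "CG"), 1.328, 116.4, 120.0)],
    "GLN": [("CG", ("N", "CA", "CB"), 1.520, 114.1, 180.0),
            ("CD", ("CA", "CB", "CG"), 1.516, 112.6, 180.0),
            ("OE1", ("CB", "CG", "CD"), 1.231, 120.8, 0.0),
            ("NE2", ("CB", "CG", "CD"), 1.328, 116.4, 180.0)],
    "TYR": [("CG", ("N", "CA", "CB"), 1.512, 113.9, 180.0),
            ("CD1", ("CA", "CB", "CG"), 1.389, 120.8, 90.0),
            ("CD2", ("CA", "CB", "CG"), 1.389, 120.8, -90.0),
            ("CE1", ("CB", "CG", "CD1"), 1.382, 121.2, 180.0),
            ("CE2", ("CB", "CG", "CD2"), 1.382, 121.2, 180.0),
            ("CZ", ("CG", "CD1", "CE1"), 1.378, 119.6, 0.0),
            ("OH", ("CD1", "CE1", "CZ"), 1.376, 119.9, 180.0)],
    "TRP": [("CG", ("N", "CA", "CB"), 1.498, 113.6, 180.0),
            ("CD1", ("CA", "CB", "CG"), 1.365, 126.9, 90.0),
            ("CD2", ("CA", "CB", "CG"), 1.433, 126.7, -90.0),
            ("NE1", ("CB", "CG", "CD1"), 1.374, 110.2, 180.0),
            ("CE2", ("CG", "CD1", "NE1"), 1.370, 109.0, 0.0),
            ("CE3", ("CB", "CG", "CD2"), 1.398, 133.9, 180.0),
            ("CZ2", ("CD1", "NE1", "CE2"), 1.394, 130.4, 180.0),
            ("CZ3", ("CG", "CD2", "CE3"), 1.382, 118.8, 180.0),
            ("CH2", ("CD2", "CE3", "CZ3"), 1.400, 121.2, 0.0)],
}

PARALLEL_CLASSES = (1, 2, 3, 4)
ANTIPARALLEL_CLASSES = (5, 6, 7, 8)

#: rigid op applied to sheet A to obtain sheet B, per topology class:
#: axis of a 180-degree rotation (None = pure translation) and the
#: y-offset of sheet B in units of strand spacing. Classes 5/6 require
#: antifacial (parity-pure-face) antiparallel sheets, 7/8 equifacial ones.
CLASS_OPS: dict[int, tuple[str | None, int]] = {
    1: ("z", 0), 2: (None, 0), 3: ("y", 0), 4: ("x", 0),
    5: ("z", 0), 6: (None, 0), 7: (None, 0), 8: (None, 1),
}

CLASS_FACIAL: dict[int, str] = {
    5: "antifacial", 6: "antifacial", 7: "equifacial", 8: "equifacial"}


@dataclass
class SheetSpec:
    sequence: str
    n_strands: int = 3
    arrangement: str = "parallel"
    phi: float = -119.0
    psi: float = 113.0
    strand_spacing: float = 4.8
    register_shift: int = 0
    #: antiparallel sheets come in two flavors: "equifacial" (adjacent
    #: strands related by a 2-fold about the H-bond axis; every face shows
    #: all residues; the natural in-register choice for even-length chains)
    #: and "antifacial" (2-fold about the sheet normal; faces are
    #: residue-parity pure; in register only for odd-length chains).
    facial: str = "equifacial"

    def __post_init__(self):
        if len(self.sequence) < 3:
            raise ValueError("sequence must have >= 3 residues")
        if self.n_strands < 2:
            raise ValueError("n_strands must be >= 2")
        if not 3.5 < self.strand_spacing < 7.0:
            raise ValueError("strand_spacing outside (3.5, 7.0) A")
        if self.arrangement not in ("parallel", "antiparallel"):
            raise ValueError(f"unknown arrangement {self.arrangement!r}")
        if self.facial not in ("equifacial", "antifacial"):
            raise ValueError(f"unknown facial flavor {self.facial!r}")


@dataclass
class ZipperSpec:
    class_id: int
    sheet_spec: SheetSpec
    inter_sheet_gap: float = 3.8
    #: offset of sheet B along the strand direction; None picks half the
    #: side-chain ladder period (one residue rise) so the ladders of the
    #: two sheets interdigitate, as in real zippers
    lateral_offset: float | None = None
    isolated: bool = False       # True -> isolated sandwich (1D network)
    cell_margin_z: float = 30.0  # solvent margin along the strand direction
    #: explicit c-axis length; values near lateral_offset*2 produce
    #: brick-like 3D packings where sheets form more than two interfaces
    cell_c: float | None = None

    def __post_init__(self):
        if self.class_id in (9, 10):
            raise ValueError(
                "classes 9/10 construction unsupported (no such structure "
                "has been observed)")
        if self.class_id not in CLASS_OPS:
            raise ValueError(f"unknown topology class {self.class_id}")
        par = self.class_id in PARALLEL_CLASSES
        if par != (self.sheet_spec.arrangement == "parallel"):
            raise ValueError(
                f"class {self.class_id} requires "
                f"{'parallel' if par else 'antiparallel'} sheets")
        if self.class_id in CLASS_FACIAL:
            # the class dictates the sheet flavor
            self.sheet_spec.facial = CLASS_FACIAL[self.class_id]
        if self.inter_sheet_gap < 3.0:
            raise ValueError("inter-sheet gap < 3 A is geometrically impossible")


# ---------------------------------------------------------------------------
# strand construction
# ---------------------------------------------------------------------------


def _atom(name: str, element: str, resname: str, resseq: int, chain: str,
          pos: np.ndarray, serial: int) -> AtomRecord:
    return AtomRecord(serial=serial, name=name, element=element,
                      residue_name=resname, residue_seq=resseq,
                      chain_id=chain, position=np.asarray(pos, dtype=float),
                      vdw_radius=element_radius(element))


def build_ideal_strand(sequence: str, phi: float = -119.0, psi: float = 113.0,
                       phi_psi: list[tuple[float, float]] | None = None,
                       chain_id: str = "A") -> list[AtomRecord]:
    """Build an extended peptide chain at uniform (phi, psi).

    Backbone N, CA, C, O plus CB for non-Gly; side chains beyond CB from the
    ideal-rotamer table. `phi_psi` optionally gives per-residue angles
    (used for kinked chains). The chain is returned in the canonical frame:
    N->C direction along +z, amide groups along +/-y, pleat along +/-x.
    """
    seq3 = []
    for c in sequence.upper():
        if c not in AMINO1:
            raise ValueError(f"non-canonical residue {c!r}")
        if c not in "AGSVLINQYW" and c in AMINO1:
            # other canonical residues are accepted but truncated at CB
            pass
        seq3.append(AMINO1[c])
    n = len(seq3)
    angles = phi_psi if phi_psi is not None else [(phi, psi)] * n
    if len(angles) != n:
        raise ValueError("phi_psi length mismatch")
    for ph, ps in angles:
        if not (-180.0 < ph <= 180.0 and -180.0 < ps <= 180.0):
            raise ValueError("phi/psi outside (-180, 180]")

    atoms: list[AtomRecord] = []
    serial = 0
    # seed backbone of residue 1
    N = np.array([0.0, 0.0, 0.0])
    CA = np.array([B_N_CA, 0.0, 0.0])
    ang = np.radians(A_N_CA_C)
    C = CA + B_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])
    backbone = [(N, CA, C)]
    for i in range(1, n):
        ph, _ = angles[i]
        _, ps_prev = angles[i - 1]
        Np, CAp, Cp = backbone[-1]
        Nn = place_atom(Np, CAp, Cp, B_C_N, A_CA_C_N, ps_prev)
        CAn = place_atom(CAp, Cp, Nn, B_N_CA, A_C_N_CA, OMEGA)
        Cn = place_atom(Cp, Nn, CAn, B_CA_C, A_N_CA_C, ph)
        backbone.append((Nn, CAn, Cn))

    for i, (res3, (Ni, CAi, Ci)) in enumerate(zip(seq3, backbone)):
        _, ps = angles[i]
        Oi = place_atom(Ni, CAi, Ci, B_C_O, A_CA_C_O, ps - 180.0)
        resseq = i + 1
        coords = {"N": Ni, "CA": CAi, "C": Ci, "O": Oi}
        order = ["N", "CA", "C", "O"]
        if res3 != "GLY":
            coords["CB"] = place_atom(Ni, Ci, CAi, B_CA_CB, A_C_CA_CB,
                                      T_N_C_CA_CB)
            order.append("CB")
            for entry in SIDECHAIN_ZMAT.get(res3, []):
                nm, (ra, rb, rc), bond, angl, tors = entry
                coords[nm] = place_atom(coords[ra], coords[rb], coords[rc],
                                        bond, angl, tors)
                order.append(nm)
        for nm in order:
            serial += 1
            elem = nm[0] if nm[0] in "CNOS" else nm[:1]
            atoms.append(_atom(nm, elem, res3, resseq, chain_id,
                               coords[nm], serial))

    _canonicalize_frame(atoms)
    return atoms


def _canonicalize_frame(atoms: list[AtomRecord]) -> None:
    """Rotate/translate a strand in place into the canonical amyloid frame."""
    ca = np.array([a.position for a in atoms if a.name == "CA"])
    if len(ca) < 2:
        return
    z_dir = fit_direction(ca, hint=ca[-1] - ca[0])
    # rotate z_dir onto +z
    target = np.array([0.0, 0.0, 1.0])
    v = np.cross(z_dir, target)
    if np.linalg.norm(v) > 1e-12:
        angle = np.degrees(np.arccos(np.clip(np.dot(z_dir, target), -1, 1)))
        R = rotation_about_axis(v, angle)
    else:
        R = np.eye(3) if np.dot(z_dir, target) > 0 else rotation_about_axis(
            [1.0, 0.0, 0.0], 180.0)
    xyz = np.array([a.position for a in atoms]) @ R.T
    # orient mean carbonyl C->O of even residues along +y
    co = []
    by_res: dict[int, dict[str, np.ndarray]] = {}
    for a, p in zip(atoms, xyz):
        by_res.setdefault(a.residue_seq, {})[a.name] = p
    for seq, amap in by_res.items():
        if seq % 2 == 0 and "C" in amap and "O" in amap:
            co.append(amap["O"] - amap["C"])
    if co:
        m = np.mean(co, axis=0)
        m[2] = 0.0
        if np.linalg.norm(m) > 1e-9:
            ang = np.degrees(np.arctan2(m[0], m[1]))  # rotate onto +y
            xyz = xyz @ rotation_about_axis([0, 0, 1], ang).T
    ca_idx = [i for i, a in enumerate(atoms) if a.name == "CA"]
    xyz -= xyz[ca_idx].mean(axis=0)
    for a, p in zip(atoms, xyz):
        a.position = p


def build_kinked_chain(sequence: str, kink_position: int,
                       kink_phi: float = -60.0, kink_psi: float = -40.0,
                       phi: float = -119.0, psi: float = 113.0,
                       chain_id: str = "A") -> list[AtomRecord]:
    """Chain in the beta region except one interior residue at (kink_phi,
    kink_psi). `kink_position` is 1-based and must be interior."""
    n = len(sequence)
    if not 2 <= kink_position <= n - 1:
        raise ValueError("kink position must be an interior residue")
    angles = [(phi, psi)] * n
    angles[kink_position - 1] = (kink_phi, kink_psi)
    return build_ideal_strand(sequence, phi_psi=angles, chain_id=chain_id)


# ---------------------------------------------------------------------------
# sheet assembly
# ---------------------------------------------------------------------------


def _strand_arrays(atoms: list[AtomRecord]):
    xyz = np.array([a.position for a in atoms])
    n_idx = [i for i, a in enumerate(atoms) if a.name == "N"]
    o_idx = [i for i, a in enumerate(atoms) if a.name == "O"]
    c_idx = [i for i, a in enumerate(atoms) if a.name == "C"]
    return xyz, n_idx, o_idx, c_idx


def _pair_hb_score(xyz_a, xyz_b, idx_a, idx_b) -> float:
    """Negative count of plausible N-H...O=C bonds between two strands,
    softly penalizing distance deviation from 2.95 A and steric clashes."""
    score = 0.0
    nbonds = 0
    for (ni, xn), (oj, cj, xo) in (
            ((idx_a[0], xyz_a), (idx_b[1], idx_b[2], xyz_b)),
            ((idx_b[0], xyz_b), (idx_a[1], idx_a[2], xyz_a))):
        npos = xn[ni]                       # (n, 3)
        opos, cpos = xo[oj], xo[cj]         # (m, 3)
        d = np.linalg.norm(npos[:, None, :] - opos[None, :, :], axis=2)
        co = opos - cpos
        on = npos[:, None, :] - opos[None, :, :]
        cosang = np.einsum("ij,nij->ni", co, on) / (
            np.linalg.norm(co, axis=1)[None, :] * np.maximum(d, 1e-9))
        ok = (d < 3.4) & (cosang >= np.cos(np.radians(70.0)))  # angle >= 110
        dm = np.where(ok, d, np.inf).min(axis=1)
        hit = np.isfinite(dm)
        nbonds += int(hit.sum())
        score += float(np.sum(0.25 * (dm[hit] - 2.95) ** 2))
    dmin = cKDTree(xyz_a).query(xyz_b, k=1)[0].min()
    if dmin < 2.7:
        score += 30.0 * (2.7 - dmin)
    return score - float(nbonds)


def _strand_period(atoms: list[AtomRecord]) -> float:
    """z-rise per residue from the CA trace."""
    ca = np.array([a.position for a in atoms if a.name == "CA"])
    return float(np.mean(np.diff(ca[:, 2])))


def _transform(atoms: list[AtomRecord], rot: np.ndarray | None,
               trans: np.ndarray, chain_id: str,
               serial_start: int) -> list[AtomRecord]:
    out = []
    serial = serial_start
    for a in atoms:
        serial += 1
        p = a.position if rot is None else rot @ a.position
        b = _copymod.copy(a)
        b.position = p + trans
        b.chain_id = chain_id
        b.serial = serial
        out.append(b)
    return out


_CHAIN_LETTERS = "ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz"


def _refine_1d(obj, grid) -> float:
    vals = [obj(t) for t in grid]
    t0 = grid[int(np.argmin(vals))]
    res = minimize_scalar(obj, bounds=(t0 - 0.1, t0 + 0.1),
                          method="bounded", options={"xatol": 1e-4})
    return float(res.x)


def build_sheet(spec: SheetSpec, chain_offset: int = 0,
                ) -> tuple[list[list[AtomRecord]], dict]:
    """Assemble `n_strands` strands into an ideal sheet.

    Parallel sheets repeat by pure translation (0, spacing, dz) with dz
    chosen to optimize the backbone H-bond geometry. Antiparallel sheets
    alternate a flipped strand: the flip is a 2-fold about the H-bond axis
    (equifacial flavor) or about the sheet normal (antifacial flavor); the
    within-pair alignment tz and the pair-repeat shear uz are both chosen
    by H-bond optimization in a window set by the requested register shift.

    Returns the strands (each a list of AtomRecord with its own chain id)
    and a geometry dict with the repeating-unit translation, used by
    :func:`build_zipper` to size the unit cell.
    """
    strand = build_ideal_strand(spec.sequence, spec.phi, spec.psi)
    xyz, n_idx, o_idx, c_idx = _strand_arrays(strand)
    idx = (n_idx, o_idx, c_idx)
    rise = _strand_period(strand)
    s = spec.strand_spacing

    strands: list[list[AtomRecord]] = []
    serial = 0

    if spec.arrangement == "parallel":
        center = spec.register_shift * rise

        def obj(dz):
            return _pair_hb_score(xyz, xyz + np.array([0.0, s, dz]),
                                  idx, idx)

        tz = _refine_1d(obj, np.arange(center - 2.4, center + 2.4, 0.05))
        for k in range(spec.n_strands):
            cid = _CHAIN_LETTERS[chain_offset + k]
            placed = _transform(strand, None, np.array([0.0, k * s, k * tz]),
                                cid, serial)
            serial += len(placed)
            strands.append(placed)
        unit_vec = np.array([0.0, s, tz])
        units = spec.n_strands
    else:
        Mf = (np.diag([-1.0, 1.0, -1.0]) if spec.facial == "equifacial"
              else np.diag([1.0, -1.0, -1.0]))
        g = xyz[[i for i, a in enumerate(strand) if a.name == "CA"]].mean(axis=0)
        base = (xyz - g) @ Mf.T + g  # flipped about own centroid

        center = spec.register_shift * rise

        def obj_tz(tz):
            return _pair_hb_score(xyz, base + np.array([0.0, s, tz]),
                                  idx, idx)

        tz = _refine_1d(obj_tz, np.arange(center - 2.4, center + 2.4, 0.05))
        flipped = base + np.array([0.0, s, tz])

        def obj_uz(uz):
            return _pair_hb_score(flipped, xyz + np.array([0.0, 2 * s, uz]),
                                  idx, idx)

        uz = _refine_1d(obj_uz, np.arange(-4.0, 4.0, 0.05))
        for k in range(spec.n_strands):
            cid = _CHAIN_LETTERS[chain_offset + k]
            m = k // 2
            if k % 2 == 0:
                rot, tr = None, np.array([0.0, 2 * m * s, m * uz])
            else:
                rot, tr = Mf, (g - Mf @ g
                               + np.array([0.0, (2 * m + 1) * s, tz + m * uz]))
            placed = _transform(strand, rot, tr, cid, serial)
            serial += len(placed)
            strands.append(placed)
        unit_vec = np.array([0.0, 2 * s, uz])
        units = spec.n_strands // 2

    geom = {"unit_vec": unit_vec, "units": units, "rise": rise}
    return strands, geom


def sheet_model(spec: SheetSpec) -> CrystalModel:
    """A sheet fragment as a standalone P1 model (big isolating cell)."""
    strands, _ = build_sheet(spec)
    atoms = [a for st in strands for a in st]
    xyz = np.array([a.position for a in atoms])
    span = xyz.max(axis=0) - xyz.min(axis=0) + 40.0
    return CrystalModel(atoms=atoms, cell=(span[0], span[1], span[2],
                                           90.0, 90.0, 90.0),
                        spacegroup="P 1",
                        symmetry_ops=[(np.eye(3), np.zeros(3))],
                        name=f"sheet_{spec.arrangement}_{spec.sequence}")


def _closest_approach(xa: np.ndarray, xb: np.ndarray) -> float:
    return float(cKDTree(xa).query(xb, k=1)[0].min())


def build_zipper(spec: ZipperSpec, waters: list[np.ndarray] | None = None,
                 ) -> CrystalModel:
    """Two sheets facing along x, as a P1 crystal.

    The cell's b vector equals the full sheet translation (the lattice
    continues the sheets along y); the a vector stacks sandwiches along x
    (catemer) unless `spec.isolated`. Optional `waters` are inserted as HOH
    heteroatoms at the stated positions (for wetness fixtures).
    """
    ss = spec.sheet_spec
    strands_a, geom = build_sheet(ss)
    n = ss.n_strands

    axis_name, y_units = CLASS_OPS[spec.class_id]
    R = (np.eye(3) if axis_name is None else
         rotation_about_axis({"x": [1, 0, 0], "y": [0, 1, 0],
                              "z": [0, 0, 1]}[axis_name], 180.0))

    xyz_a = np.array([a.position for st in strands_a for a in st])
    center_a = xyz_a.mean(axis=0)
    # rotate sheet B about the sheet-A center so it stays superposed, then
    # translate along x until the closest approach equals the requested gap
    xyz_b0 = (xyz_a - center_a) @ R.T + center_a
    y_off = y_units * ss.strand_spacing
    # default stagger interleaves the side-chain knobs of the two faces:
    # parity-pure faces (parallel / antifacial) repeat every 2 residues
    # along the strand, equifacial antiparallel faces every residue
    if spec.lateral_offset is not None:
        lateral = spec.lateral_offset
    elif ss.arrangement == "antiparallel" and ss.facial == "equifacial":
        lateral = geom["rise"] / 2.0
    else:
        lateral = geom["rise"]

    def gap_at(dx: float) -> float:
        return _closest_approach(
            xyz_a, xyz_b0 + np.array([dx, y_off, lateral]))

    dx = 1.0
    while gap_at(dx) < spec.inter_sheet_gap:
        dx += 0.5
        if dx > 60:
            raise RuntimeError("could not place partner sheet")
    from scipy.optimize import brentq
    lo = dx - 0.5 if gap_at(dx - 0.5) < spec.inter_sheet_gap else 0.0
    dx = brentq(lambda d: gap_at(d) - spec.inter_sheet_gap, lo, dx,
                xtol=1e-4)
    t_b = np.array([dx, y_off, lateral])

    atoms: list[AtomRecord] = []
    serial = 0
    for st in strands_a:
        for a in st:
            serial += 1
            b = _copymod.copy(a)
            b.serial = serial
            atoms.append(b)
    for k in range(n):
        cid = _CHAIN_LETTERS[n + k]
        src = strands_a[k]
        moved = []
        for a in src:
            serial += 1
            b = _copymod.copy(a)
            b.position = R @ (a.position - center_a) + center_a + t_b
            b.chain_id = cid
            b.serial = serial
            moved.append(b)
        atoms.extend(moved)

    xyz_b = np.array([a.position for a in atoms[len(xyz_a):]])

    # cell vectors
    v2 = geom["unit_vec"] * geom["units"]          # full-sheet translation
    if spec.isolated:
        a_len = (xyz_b[:, 0].max() - xyz_a[:, 0].min()) + 50.0
    else:
        # catemer: lattice copy of sheet A packs against sheet B's far face
        def gap2(ax: float) -> float:
            return _closest_approach(xyz_b, xyz_a + np.array([ax, 0, 0]))
        hi = dx + 1.0
        while gap2(hi) < spec.inter_sheet_gap:
            hi += 0.5
            if hi > 120:
                raise RuntimeError("could not close the catemer cell")
        lo2 = max(dx, hi - 0.5)
        if gap2(lo2) >= spec.inter_sheet_gap:
            lo2 = dx
        a_len = brentq(lambda d: gap2(d) - spec.inter_sheet_gap, lo2, hi,
                       xtol=1e-4)
    v1 = np.array([a_len, 0.0, 0.0])
    if spec.cell_c is not None:
        v3 = np.array([0.0, 0.0, spec.cell_c])
    else:
        z_span = (max(xyz_a[:, 2].max(), xyz_b[:, 2].max())
                  - min(xyz_a[:, 2].min(), xyz_b[:, 2].min()))
        v3 = np.array([0.0, 0.0, z_span + spec.cell_margin_z])

    # rotate rigidly about x so v2 lies exactly along +y (PDB convention
    # frame: a || x, b in the xy plane); the tilt is a few degrees at most
    theta = np.degrees(np.arctan2(v2[2], v2[1]))
    Rx = rotation_about_axis([1.0, 0.0, 0.0], -theta)
    for a in atoms:
        a.position = Rx @ a.position
    v2 = Rx @ v2
    v3 = Rx @ v3

    if waters:
        for i, w in enumerate(waters):
            serial += 1
            atoms.append(_atom("O", "O", "HOH", 900 + i, "w",
                               Rx @ np.asarray(w, dtype=float), serial))

    a_, b_, c_ = (np.linalg.norm(v) for v in (v1, v2, v3))
    alpha = bond_angle(v2, np.zeros(3), v3)
    beta = bond_angle(v1, np.zeros(3), v3)
    gamma = bond_angle(v1, np.zeros(3), v2)
    return CrystalModel(
        atoms=atoms,
        cell=(a_, b_, c_, alpha, beta, gamma),
        spacegroup="P 1",
        symmetry_ops=[(np.eye(3), np.zeros(3))],
        name=f"zipper_class{spec.class_id}_{ss.sequence}",
    )
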