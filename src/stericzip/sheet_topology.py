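"""Backbone H-bond detection, beta-sheet assembly and topology assignment.

Chains of the expanded lattice are linked into sheets through inter-backbone
N-H...O=C bonds; each sheet gets principal axes (y = stacking/fibril axis,
z = strand direction, x = packing normal), an arrangement, facial sets and
a register analysis. Pairs of contacting sheets are assigned one of the
eight steric-zipper topology classes:

* parallel sheets (antifacial by construction) pair with the same or the
  other face, in the same or opposite strand direction -> classes 1-4;
* antifacial antiparallel sheets (faces are residue-parity pure) pair
  face-to-face (5) or face-to-back (6);
* equifacial antiparallel sheets (each face shows every residue) pair with
  facing strands parallel (7) or antiparallel (8).

Out-of-register sheets and kinked (LARKS-like) chains are flagged and keep
their pseudoclass.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from .config import RunConfig, DEFAULT_CONFIG
from .geometry import fit_direction, normalize
from .sequence_stats import backbone_dihedrals, beta_distance
from .structure_io import ChainCopy, ExpandedLattice


@dataclass
class HBond:
    donor_copy: int       # index into lattice.copies
    donor_res: int        # residue index within the chain (0-based)
    acceptor_copy: int
    acceptor_res: int
    distance: float

    def involves(self, copy_index: int) -> bool:
        return copy_index in (self.donor_copy, self.acceptor_copy)


@dataclass
class BetaSheet:
    strand_indices: list[int]            # ordered along axis_y
    strands: list[ChainCopy]
    strand_dirs: list[np.ndarray]        # unit N->C directions
    axis_y: np.ndarray
    axis_z: np.ndarray
    axis_x: np.ndarray
    arrangement: str                     # "parallel" | "antiparallel"
    mean_strand_spacing: float
    hbonds: list[HBond] = field(default_factory=list)

    @property
    def repeating_unit_size(self) -> int:
        return 1 if self.arrangement == "parallel" else 2

    @property
    def n_units(self) -> int:
        return len(self.strands) // self.repeating_unit_size

    def centroid(self) -> np.ndarray:
        return np.mean([s.centroid() for s in self.strands], axis=0)

    def residue_face_signs(self) -> list[list[float]]:
        """Per strand, per residue: sign of the side-chain direction along
        axis_x (which sheet face the residue decorates)."""
        out = []
        for st in self.strands:
            signs = []
            for ri, (name, _, amap) in enumerate(st.residues):
                v = _sidechain_vector(st, ri)
                signs.append(float(np.sign(np.dot(v, self.axis_x))))
            out.append(signs)
        return out

    def face_residues(self) -> dict[int, list[tuple[int, int]]]:
        """Residues per face: {+1: [(strand, res), ...], -1: [...]}"""
        faces: dict[int, list[tuple[int, int]]] = {1: [], -1: []}
        for si, signs in enumerate(self.residue_face_signs()):
            for ri, sg in enumerate(signs):
                if sg != 0:
                    faces[int(sg)].append((si, ri))
        return faces

    def facial_type(self) -> str:
        """"equifacial" when the two faces carry identical residue-type
        multisets, else "antifacial"."""
        faces = self.face_residues()
        def multiset(items):
            return Counter(self.strands[si].residues[ri][0]
                           for si, ri in items)
        return ("equifacial"
                if multiset(faces[1]) == multiset(faces[-1])
                else "antifacial")


@dataclass
class TopologyLabel:
    class_id: int | None
    arrangement: str
    pseudo: bool = False
    oor: bool = False
    shift: int = 0
    larks: bool = False
    diagnostic: str = ""

    def as_dict(self) -> dict:
        return {"class": self.class_id, "arrangement": self.arrangement,
                "pseudo": self.pseudo, "oor": self.oor, "shift": self.shift,
                "larks": self.larks, "diagnostic": self.diagnostic}


def _sidechain_vector(chain: ChainCopy, res_index: int) -> np.ndarray:
    """CB-CA direction; glycine uses the backbone bisector surrogate."""
    name, _, amap = chain.residues[res_index]
    ca = chain.coords[amap["CA"]]
    if "CB" in amap:
        return chain.coords[amap["CB"]] - ca
    if "N" in amap and "C" in amap:
        n, c = chain.coords[amap["N"]], chain.coords[amap["C"]]
        return 2 * ca - n - c
    return np.zeros(3)


def detect_backbone_hbonds(lattice: ExpandedLattice,
                           d_max: float = 3.5,
                           angle_min: float = 120.0) -> list[HBond]:
    """All inter-chain N(H)...O=C pairs with N...O <= d_max and a C=O...N
    angle >= angle_min, each reported once (donor side)."""
    donors = []   # (copy, res, coord)
    accept = []   # (copy, res, O coord, C coord)
    for ci, cp in enumerate(lattice.copies):
        for ri, (_, _, amap) in enumerate(cp.residues):
            if "N" in amap:
                donors.append((ci, ri, cp.coords[amap["N"]]))
            if "O" in amap and "C" in amap:
                accept.append((ci, ri, cp.coords[amap["O"]],
                               cp.coords[amap["C"]]))
    if not donors or not accept:
        return []
    o_xyz = np.array([a[2] for a in accept])
    tree = cKDTree(o_xyz)
    cos_min = np.cos(np.radians(180.0 - angle_min))
    bonds: list[HBond] = []
    for ci, ri, n in donors:
        for j in tree.query_ball_point(n, d_max):
            cj, rj, o, c = accept[j]
            if cj == ci:
                continue
            d = float(np.linalg.norm(n - o))
            co = normalize(o - c)
            on = normalize(n - o)
            if np.dot(co, on) >= -cos_min:  # angle(C=O...N) >= angle_min
                bonds.append(HBond(ci, ri, cj, rj, d))
    return bonds


def hbonds_per_chain(bonds: list[HBond], copy_index: int) -> int:
    return sum(b.involves(copy_index) for b in bonds)


def assemble_sheets(lattice: ExpandedLattice, bonds: list[HBond],
                    min_hbonds: int = 2) -> list[BetaSheet]:
    """Connected components of the strand graph (edges: >= `min_hbonds`
    H-bonds between two chain copies), with axes and arrangement."""
    pair_counts: Counter = Counter()
    for b in bonds:
        key = tuple(sorted((b.donor_copy, b.acceptor_copy)))
        pair_counts[key] += 1
    g = nx.Graph()
    g.add_nodes_from(range(len(lattice.copies)))
    for (i, j), n in pair_counts.items():
        if n >= min_hbonds:
            g.add_edge(i, j)

    sheets: list[BetaSheet] = []
    for comp in nx.connected_components(g):
        comp = sorted(comp)
        if len(comp) < 2:
            continue
        copies = [lattice.copies[i] for i in comp]
        dirs = [c.direction() for c in copies]
        centroids = np.array([c.centroid() for c in copies])
        axis_y = fit_direction(centroids, hint=centroids[-1] - centroids[0])
        order = np.argsort(centroids @ axis_y)
        comp = [comp[k] for k in order]
        copies = [copies[k] for k in order]
        dirs = [dirs[k] for k in order]
        centroids = centroids[order]
        dots = [float(np.dot(dirs[0], d)) for d in dirs[1:]]
        arrangement = "parallel" if all(d > 0 for d in dots) else "antiparallel"
        axis_z = dirs[0]
        axis_x = normalize(np.cross(axis_y, axis_z))
        axis_z = normalize(np.cross(axis_x, axis_y))
        spacing = float(np.mean(np.diff(centroids @ axis_y)))
        in_sheet = set(comp)
        sheet_bonds = [b for b in bonds
                       if b.donor_copy in in_sheet
                       and b.acceptor_copy in in_sheet]
        sheets.append(BetaSheet(
            strand_indices=comp, strands=copies, strand_dirs=dirs,
            axis_y=axis_y, axis_z=axis_z, axis_x=axis_x,
            arrangement=arrangement, mean_strand_spacing=spacing,
            hbonds=sheet_bonds))
    return sheets


def facial_analysis(sheet: BetaSheet) -> dict:
    """Facial type plus the per-face residue sets and their parity purity.

    Parity is the 1-based residue index modulo 2 (odd = 1). A face is
    "pure" when every residue on it has the same parity -- the signature of
    parallel and antifacial-antiparallel sheets; equifacial-antiparallel
    sheets mix parities on each face.
    """
    faces = sheet.face_residues()
    out: dict = {"facial_type": sheet.facial_type(), "faces": {}}
    for sign, items in faces.items():
        parities = {(ri + 1) % 2 for _, ri in items}
        residues = sorted(
            (si, sheet.strands[si].residues[ri][1],
             sheet.strands[si].residues[ri][0]) for si, ri in items)
        out["faces"][sign] = {
            "residues": residues,
            "parity": ("odd" if parities == {1} else
                       "even" if parities == {0} else "mixed"),
        }
    return out


def _contact_face_sign(sheet: BetaSheet, partner: BetaSheet) -> int:
    """Which face (+1/-1 along axis_x) of `sheet` points at `partner`."""
    v = partner.centroid() - sheet.centroid()
    return 1 if np.dot(v, sheet.axis_x) >= 0 else -1


def _contact_face_parity(sheet: BetaSheet, partner: BetaSheet) -> str:
    sign = _contact_face_sign(sheet, partner)
    return facial_analysis(sheet)["faces"][sign]["parity"]


def assign_topology_class(sheet_a: BetaSheet, sheet_b: BetaSheet
                          ) -> TopologyLabel:
    """Topology class of a contacting sheet pair (see module docstring)."""
    if sheet_a.arrangement != sheet_b.arrangement:
        return TopologyLabel(None, "mixed",
                             diagnostic="sheets of different arrangement")
    arrangement = sheet_a.arrangement
    pa = _contact_face_parity(sheet_a, sheet_b)
    pb = _contact_face_parity(sheet_b, sheet_a)

    if arrangement == "parallel":
        up = np.dot(np.mean(sheet_a.strand_dirs, axis=0),
                    np.mean(sheet_b.strand_dirs, axis=0)) > 0
        if "mixed" in (pa, pb):
            return TopologyLabel(None, arrangement,
                                 diagnostic="ambiguous face parity")
        same_face = pa == pb
        cid = {(True, True): 1, (False, True): 2,
               (True, False): 3, (False, False): 4}[(same_face, bool(up))]
        return TopologyLabel(cid, arrangement)

    # antiparallel: antifacial (pure-parity faces) -> 5/6,
    # equifacial (mixed faces) -> 7/8
    if pa != "mixed" and pb != "mixed":
        cid = 5 if pa == pb else 6
        return TopologyLabel(cid, arrangement)
    if pa == "mixed" and pb == "mixed":
        # orientation of y-aligned facing strands
        proj_b = [np.dot(c.centroid(), sheet_a.axis_y)
                  for c in sheet_b.strands]
        dots = []
        for st, d in zip(sheet_a.strands, sheet_a.strand_dirs):
            y = np.dot(st.centroid(), sheet_a.axis_y)
            j = int(np.argmin(np.abs(np.array(proj_b) - y)))
            dots.append(float(np.dot(d, sheet_b.strand_dirs[j])))
        cid = 7 if np.mean(np.sign(dots)) > 0 else 8
        return TopologyLabel(cid, arrangement)
    return TopologyLabel(None, arrangement,
                         diagnostic="inconsistent facial flavors")


def detect_out_of_register(sheet: BetaSheet) -> tuple[bool, int]:
    """Register shift of a sheet from its H-bond registry.

    Antiparallel: the modal donor+acceptor residue-number sum of the
    narrow-ring bonds is L+1 for an in-register sheet; the shift is the
    deviation. Parallel: adjacent strands of an in-register sheet are not
    displaced along the strand direction; the shift is the modal
    inter-strand offset in residue rises. The strand tilt relative to the
    sheet axis is a consequence of the shift and diagnostic only.
    """
    if not sheet.hbonds:
        return (False, 0)
    L = max(len(s.residues) for s in sheet.strands)
    if sheet.arrangement == "antiparallel":
        sums = [(b.donor_res + 1) + (b.acceptor_res + 1)
                for b in sheet.hbonds]
        modal = Counter(sums).most_common(1)[0][0]
        shift = modal - (L + 1)
    else:
        ca = [s.ca_coords() for s in sheet.strands]
        d = normalize(np.mean(sheet.strand_dirs, axis=0))
        rise = float(np.mean([np.mean(np.diff(c @ d))
                              for c in ca if len(c) > 1]))
        offsets = [abs((ca[k + 1].mean(axis=0) - ca[k].mean(axis=0)) @ d)
                   / abs(rise)
                   for k in range(len(ca) - 1)]
        shift = Counter(int(round(o)) for o in offsets).most_common(1)[0][0]
    return (shift != 0, int(shift))


def strand_tilt(sheet: BetaSheet) -> float:
    """Mean deviation (degrees) of strands from perpendicular to axis_y."""
    angles = [np.degrees(np.arcsin(abs(np.dot(d, sheet.axis_y))))
              for d in sheet.strand_dirs]
    return float(np.mean(angles))


def detect_larks(chain: ChainCopy, margin: float = 30.0) -> bool:
    """True when an interior residue lies farther than `margin` degrees
    outside the allowed beta region (a kinked, LARKS-like backbone)."""
    if len(chain.residues) < 4:
        raise ValueError("need >= 4 residues")
    for rec in backbone_dihedrals(chain):
        if rec.phi is None or rec.psi is None:
            continue  # terminal
        if beta_distance(rec.phi, rec.psi) > margin:
            return True
    return False


def label_pair(sheet_a: BetaSheet, sheet_b: BetaSheet,
               config: RunConfig = DEFAULT_CONFIG) -> TopologyLabel:
    """Full topology label of a sheet pair including OoR/LARKS flags."""
    label = assign_topology_class(sheet_a, sheet_b)
    oor_a, shift_a = detect_out_of_register(sheet_a)
    oor_b, shift_b = detect_out_of_register(sheet_b)
    label.oor = oor_a or oor_b
    label.shift = shift_a if abs(shift_a) >= abs(shift_b) else shift_b
    label.larks = any(
        detect_larks(st, margin=config.larks_margin)
        for sh in (sheet_a, sheet_b) for st in sh.strands
        if len(st.residues) >= 4)
    label.pseudo = (label.oor or label.larks) and label.class_id is not None
    return label
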