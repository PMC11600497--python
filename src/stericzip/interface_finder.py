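"""Enumeration and admission of steric-zipper interfaces.

A contacting beta-sheet pair becomes a zipper interface when it passes the
four published admission criteria:

(i)   buried area of at least 50 A^2 per peptide chain;
(ii)  every strand contributes at least one involved side chain;
(iii) on average at least 1.5 involved side chains per peptide chain;
(iv)  a side chain counts as involved with >= 10 A^2 interface burial
      (glycine: >= 5 A^2 on its CA atom).

Symmetry-equivalent observations (same interacting side chains, same
topology class) are merged with their descriptors averaged, and interfaces
are tagged dry or partially wet depending on trapped solvent.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Delaunay, cKDTree

from .config import RunConfig, DEFAULT_CONFIG
from .descriptors import (
    AnalysisSlab,
    DescriptorSet,
    buried_area,
    footprint_rectangle,
    select_slab,
    sidechain_burial,
    surface_detail_index,
    shape_complementarity,
)
from .sheet_topology import BetaSheet, TopologyLabel, label_pair
from .structure_io import AMINO3, ExpandedLattice


@dataclass
class ZipperInterface:
    sheet_a: BetaSheet
    sheet_b: BetaSheet
    slab: AnalysisSlab
    topology: TopologyLabel
    descriptors: DescriptorSet
    #: involved residues per side, e.g. ("L1 I3 W5", "Y2 Q4 L6")
    sides: tuple[str, str]
    wet: str = "dry"                  # "dry" | "partially_wet"
    multiplicity: int = 1
    burial_rows: list[dict] = field(default_factory=list)

    @property
    def signature(self) -> tuple:
        return (tuple(sorted(self.sides)), self.topology.class_id)

    def as_dict(self) -> dict:
        d = self.descriptors.rounded()
        d.update(self.topology.as_dict())
        d.update({"sides": " : ".join(self.sides), "wet": self.wet,
                  "multiplicity": self.multiplicity})
        return d


@dataclass
class Rejection:
    criterion: str
    detail: str

    def __bool__(self):  # pragma: no cover - convenience
        return False


def find_contacting_pairs(sheets: list[BetaSheet],
                          config: RunConfig = DEFAULT_CONFIG
                          ) -> list[tuple[int, int]]:
    """Unordered sheet pairs with any interatomic distance below the sum
    of vdW radii plus two probe radii."""
    pairs = []
    arrays = []
    for sh in sheets:
        coords = np.vstack([s.coords for s in sh.strands])
        radii = np.concatenate([s.radii for s in sh.strands])
        arrays.append((coords, radii, cKDTree(coords)))
    for i in range(len(sheets)):
        ci, ri, ti = arrays[i]
        for j in range(i + 1, len(sheets)):
            cj, rj, tj = arrays[j]
            cutoff = ri.max() + rj.max() + 2 * config.probe_radius
            hits = ti.query_ball_tree(tj, cutoff)
            found = False
            for a, nbrs in enumerate(hits):
                for b in nbrs:
                    if (np.linalg.norm(ci[a] - cj[b])
                            < ri[a] + rj[b] + 2 * config.probe_radius):
                        found = True
                        break
                if found:
                    break
            if found:
                pairs.append((i, j))
    return pairs


def _one_letter(resname: str) -> str:
    return AMINO3.get(resname, "X")


def _side_string(rows: list[dict], sheet_tag: str, config: RunConfig) -> str:
    involved = {}
    for r in rows:
        if r["sheet"] != sheet_tag:
            continue
        thr = config.min_gly_ca_ab if r["is_gly"] else config.min_sidechain_ab
        if r["burial"] >= thr:
            involved[(r["residue_seq"], r["residue_name"])] = True
    return " ".join(f"{_one_letter(rn)}{rs}"
                    for rs, rn in sorted(involved))


def admit_interface(sheet_a: BetaSheet, sheet_b: BetaSheet,
                    config: RunConfig = DEFAULT_CONFIG,
                    compute_descriptors: bool = True
                    ) -> ZipperInterface | Rejection:
    """Apply the four admission criteria to a candidate sheet pair.

    Returns the admitted interface with descriptors, or the first failed
    criterion as a :class:`Rejection`.
    """
    slab = select_slab(sheet_a, sheet_b, units=config.slab_units)
    ab, detail = buried_area(slab, config)
    if ab < config.min_interface_ab:
        return Rejection("i", f"per-chain buried area {ab:.1f} A^2 < "
                              f"{config.min_interface_ab:.0f} A^2")
    rows = sidechain_burial(slab, detail)
    involved_by_chain: dict[str, int] = {}
    for r in rows:
        thr = (config.min_gly_ca_ab if r["is_gly"]
               else config.min_sidechain_ab)
        involved_by_chain.setdefault(r["chain"], 0)
        if r["burial"] >= thr:
            involved_by_chain[r["chain"]] += 1
    if any(n == 0 for n in involved_by_chain.values()):
        missing = [c for c, n in involved_by_chain.items() if n == 0]
        return Rejection("ii", f"strand(s) without involved side chain: "
                               f"{', '.join(missing)}")
    mean_involved = np.mean(list(involved_by_chain.values()))
    if mean_involved < config.min_mean_sidechains:
        return Rejection("iii", f"mean involved side chains "
                                f"{mean_involved:.2f} < "
                                f"{config.min_mean_sidechains}")

    label = label_pair(sheet_a, sheet_b, config)
    if compute_descriptors:
        sc = shape_complementarity(slab, config)
        fp = footprint_rectangle(slab, config)
        sdi = surface_detail_index(ab, fp, slab.unit_size)
        desc = DescriptorSet(Sc=sc, Ab=ab, SDi=sdi, footprint=fp,
                             N=slab.n_chains_eq1)
    else:
        desc = DescriptorSet(Sc=float("nan"), Ab=ab, SDi=float("nan"),
                             footprint=(float("nan"), float("nan")),
                             N=slab.n_chains_eq1)
    sides = (_side_string(rows, "A", config), _side_string(rows, "B", config))
    return ZipperInterface(sheet_a=sheet_a, sheet_b=sheet_b, slab=slab,
                           topology=label, descriptors=desc, sides=sides,
                           burial_rows=rows)


def classify_wetness(interface: ZipperInterface,
                     lattice: ExpandedLattice,
                     config: RunConfig = DEFAULT_CONFIG) -> str:
    """"partially_wet" when a solvent molecule sits between the sheets.

    A solvent center counts as trapped when it falls inside the convex
    hull of the two slabs' atoms and within the footprint extent along the
    strand direction.
    """
    if len(lattice.solvent_coords) == 0:
        interface.wet = "dry"
        return interface.wet
    slab = interface.slab
    xa, _ = slab.coords_a()
    xb, _ = slab.coords_b()
    hull = Delaunay(np.vstack([xa, xb]))
    inside = hull.find_simplex(lattice.solvent_coords) >= 0
    if not inside.any():
        interface.wet = "dry"
        return interface.wet
    axis_z = slab.sheet_a.axis_z
    axis_x = slab.sheet_a.axis_x
    za, zb = xa @ axis_z, xb @ axis_z
    ua, ub = xa @ axis_x, xb @ axis_x
    zlo = max(za.min(), zb.min())
    zhi = min(za.max(), zb.max())
    ulo, uhi = sorted((float(np.mean(ua)), float(np.mean(ub))))
    wet = False
    for w in lattice.solvent_coords[inside]:
        z = float(np.dot(w, axis_z))
        u = float(np.dot(w, axis_x))
        if zlo <= z <= zhi and ulo <= u <= uhi:
            wet = True
            break
    interface.wet = "partially_wet" if wet else "dry"
    return interface.wet


def deduplicate(interfaces: list[ZipperInterface]
                ) -> list[ZipperInterface]:
    """Merge symmetry-equivalent observations (same involved side chains
    and topology class); descriptor values are arithmetic means."""
    groups: dict[tuple, list[ZipperInterface]] = {}
    for itf in interfaces:
        groups.setdefault(itf.signature, []).append(itf)
    out = []
    for sig, members in groups.items():
        rep = members[0]
        if len(members) > 1:
            rep.descriptors = DescriptorSet(
                Sc=float(np.mean([m.descriptors.Sc for m in members])),
                Ab=float(np.mean([m.descriptors.Ab for m in members])),
                SDi=float(np.mean([m.descriptors.SDi for m in members])),
                footprint=tuple(np.mean(
                    [m.descriptors.footprint for m in members], axis=0)),
                N=rep.descriptors.N)
            if any(m.wet == "partially_wet" for m in members):
                rep.wet = "partially_wet"
        rep.multiplicity = len(members)
        out.append(rep)
    return out
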