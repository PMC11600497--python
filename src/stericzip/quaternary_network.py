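"""Crystal-wide networks of zipper interfaces (quaternary structure).

Beta-sheets are nodes; admitted zipper interfaces are edges. A sheet whose
single face forms one zipper gives an isolated sandwich (1D network); a
sheet zippered on both faces gives infinite catemer layers (2D); a sheet
forming more than two interface contacts in the lattice (large lateral
shifts, brick-like packing) gives a 3D network.

Degrees are counted per lattice contact of a sheet instance (a brick-wall
sheet touches two shifted partners on each face even though the contacts
are symmetry-equivalent); dimensionality is read off the central sheets --
those containing asymmetric-unit chains -- because sheets at the rim of
the expanded neighborhood have truncated contact counts.
"""
from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .config import RunConfig, DEFAULT_CONFIG
from .interface_finder import ZipperInterface
from .sheet_topology import BetaSheet


def sheet_instance_key(sheet: BetaSheet) -> tuple:
    """Identity of one sheet instance in the expanded lattice."""
    return tuple(sorted(s.key for s in sheet.strands))


def sheet_key(sheet: BetaSheet) -> tuple:
    """Symmetry-unique identity: source chain ids and operator indices,
    lattice translations ignored."""
    return tuple(sorted({(s.chain_id, s.op_index) for s in sheet.strands}))


def _face_sign(sheet: BetaSheet, partner: BetaSheet) -> int:
    v = partner.centroid() - sheet.centroid()
    return 1 if float(np.dot(v, sheet.axis_x)) >= 0 else -1


@dataclass
class InterfaceGraph:
    graph: nx.Graph
    sheets: dict[tuple, BetaSheet]

    def degrees(self, central_only: bool = True) -> dict[tuple, int]:
        nodes = [n for n, d in self.graph.nodes(data=True)
                 if d.get("central") or not central_only]
        if not nodes:
            nodes = list(self.graph.nodes)
        return {n: self.graph.degree(n) for n in nodes}


def build_interface_graph(observations: list[ZipperInterface]
                          ) -> InterfaceGraph:
    """Graph over sheet instances from (non-deduplicated) admitted
    interface observations. Edges carry the lattice direction, the faces
    involved and the lateral shift along the strand direction."""
    g = nx.Graph()
    sheets: dict[tuple, BetaSheet] = {}
    for itf in observations:
        a, b = itf.sheet_a, itf.sheet_b
        ka, kb = sheet_instance_key(a), sheet_instance_key(b)
        for k, sh in ((ka, a), (kb, b)):
            sheets.setdefault(k, sh)
            g.add_node(k, central=any(s.is_identity for s in sh.strands))
        direction = b.centroid() - a.centroid()
        shift_z = float(np.dot(direction, a.axis_z))
        ca = np.vstack([s.coords for s in a.strands]) @ a.axis_z
        chain_len = float(ca.max() - ca.min())
        g.add_edge(ka, kb,
                   signature=itf.signature,
                   direction=direction,
                   shift_z=shift_z,
                   rel_shift=abs(shift_z) / max(chain_len, 1e-9),
                   faces={ka: _face_sign(a, b), kb: _face_sign(b, a)},
                   wet=itf.wet)
    return InterfaceGraph(graph=g, sheets=sheets)


def classify_network(ig: InterfaceGraph,
                     config: RunConfig = DEFAULT_CONFIG) -> dict:
    """Dimensionality (1D/2D/3D) and packing pattern of the network.

    1D: each central sheet forms a single interface (isolated sandwich).
    2D: two interfaces on opposite faces (catemer layers); the pattern is
    "straight" for small lateral shifts, "brick" for shifts near half the
    chain length, "tilted" in between and "fishbone" when shifts alternate
    sign. 3D: more than two interface contacts per sheet.
    """
    degs = ig.degrees()
    if not degs:
        return {"dimensionality": "0D", "pattern": "none", "degrees": {}}
    dmax = max(degs.values())
    diagnostic = ("mixed sheet degrees; classified by maximum"
                  if len(set(degs.values())) > 1 else "")
    if dmax <= 1:
        dim = "1D"
    elif dmax == 2:
        opposite = False
        for node in degs:
            signs = [d["faces"][node]
                     for _, _, d in ig.graph.edges(node, data=True)]
            if 1 in signs and -1 in signs:
                opposite = True
        dim = "2D" if opposite else "1D"
    else:
        dim = "3D"

    edges = list(ig.graph.edges(data=True))
    shifts = [d["rel_shift"] for _, _, d in edges]
    signed = [np.sign(d["shift_z"]) for _, _, d in edges
              if abs(d["rel_shift"]) > config.shift_straight]
    if not shifts:
        pattern = "none"
    else:
        m = float(np.median(shifts))
        if m < config.shift_straight:
            pattern = "straight"
        elif m > config.shift_brick:
            pattern = "brick"
        else:
            pattern = "fishbone" if len(set(signed)) > 1 else "tilted"
    return {"dimensionality": dim, "pattern": pattern,
            "degrees": {str(k[:2]): v for k, v in degs.items()},
            "diagnostic": diagnostic}
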