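"""Interface descriptors on a standardized 3-repeating-unit slab.

Three quantities characterize a steric-zipper interface between two
beta-sheets:

* **Ab** -- buried area per peptide chain: the solvent-accessible area the
  middle repeating unit of each sheet loses when the partner sheet is
  present, ``Ab = (SASA_A + SASA_B - SASA_U) / N`` with N the number of
  chains in the two middle units (2 parallel, 4 antiparallel). Computing
  the middle unit inside its own 3-unit slab cancels intra-sheet burial.
* **Sc** -- shape complementarity: the median agreement of opposed
  molecular-surface normals over the buried surface patches (1 = perfect
  steric fit), with the Lawrence-Colman distance weight exp(-w d^2).
* **SDi** -- surface detail index: the one-sided buried area of a repeating
  unit over the area of the flat rectangular footprint of the interface
  (width = repeating-unit spacing along the sheet axis, length from 2D
  probe-circle tangency in the projection along that axis). ~1 for flat
  interfaces, ~1.8 for strongly interdigitated ones.

The SASA engine is a deterministic Shrake-Rupley (Fibonacci point set);
molecular surfaces for Sc are extracted from a distance-transform grid.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import distance_transform_edt
from scipy.optimize import brentq
from scipy.spatial import cKDTree
from skimage.measure import marching_cubes

from .config import RunConfig, DEFAULT_CONFIG
from .sheet_topology import BetaSheet
from .structure_io import ChainCopy

__all__ = [
    "SasaResult", "AnalysisSlab", "DescriptorSet",
    "fibonacci_sphere", "compute_sasa", "select_slab", "buried_area",
    "sidechain_burial", "shape_complementarity", "footprint_rectangle",
    "surface_detail_index", "describe_interface", "molecular_surface",
]


@dataclass
class SasaResult:
    per_atom_area: np.ndarray
    probe_radius: float

    @property
    def total(self) -> float:
        return float(self.per_atom_area.sum())


@dataclass
class AnalysisSlab:
    """Three repeating units of each sheet, centered on the contact."""

    sheet_a: BetaSheet
    sheet_b: BetaSheet
    a_strands: list[ChainCopy]       # the 3-unit slab of sheet A
    b_strands: list[ChainCopy]
    a_middle: list[ChainCopy]        # middle repeating unit of A
    b_middle: list[ChainCopy]
    unit_size: int                   # chains per repeating unit (1 or 2)

    @property
    def n_chains_eq1(self) -> int:
        """N of the buried-area equation: chains in the two middle units."""
        return 2 * self.unit_size

    def _arrays(self, strands):
        coords = np.vstack([s.coords for s in strands])
        radii = np.concatenate([s.radii for s in strands])
        return coords, radii

    def coords_a(self):
        return self._arrays(self.a_strands)

    def coords_b(self):
        return self._arrays(self.b_strands)


@dataclass
class DescriptorSet:
    Sc: float
    Ab: float
    SDi: float
    footprint: tuple[float, float]   # (length, width) in A
    N: int

    def rounded(self) -> dict:
        return {"Sc": round(self.Sc, 2), "Ab": round(self.Ab, 1),
                "SDi": round(self.SDi, 2),
                "footprint_length": round(self.footprint[0], 1),
                "footprint_width": round(self.footprint[1], 1),
                "N": self.N}


def fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic, nearly uniform unit-sphere point set."""
    i = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0 ** 0.5) * i
    return np.column_stack([np.cos(theta) * np.sin(phi),
                            np.sin(theta) * np.sin(phi),
                            np.cos(phi)])


def compute_sasa(coords: np.ndarray, radii: np.ndarray,
                 probe_radius: float = 1.4, n_points: int = 960
                 ) -> SasaResult:
    """Shrake-Rupley solvent-accessible surface area, per atom."""
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    if coords.ndim != 2 or len(coords) == 0:
        raise ValueError("no atoms")
    sphere = fibonacci_sphere(n_points)
    ext = radii + probe_radius
    tree = cKDTree(coords)
    rmax = ext.max()
    areas = np.empty(len(coords))
    for i in range(len(coords)):
        pts = coords[i] + ext[i] * sphere
        nbrs = [j for j in tree.query_ball_point(coords[i], ext[i] + rmax)
                if j != i]
        if nbrs:
            d2 = np.sum((pts[:, None, :] - coords[nbrs][None, :, :]) ** 2,
                        axis=2)
            buried = (d2 < (ext[nbrs] ** 2)[None, :]).any(axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        areas[i] = frac * 4.0 * np.pi * ext[i] ** 2
    return SasaResult(per_atom_area=areas, probe_radius=probe_radius)


# ---------------------------------------------------------------------------
# slab selection
# ---------------------------------------------------------------------------


def _units(sheet: BetaSheet) -> list[list[int]]:
    """Group strand positions (indices into sheet.strands) into repeating
    units along axis_y."""
    size = sheet.repeating_unit_size
    n = len(sheet.strands) // size
    return [list(range(k * size, (k + 1) * size)) for k in range(n)]


def select_slab(sheet_a: BetaSheet, sheet_b: BetaSheet,
                units: int = 3) -> AnalysisSlab:
    """Central `units` repeating units of each sheet, centered on the
    closest-approach region of the pair."""
    if sheet_a.repeating_unit_size != sheet_b.repeating_unit_size:
        raise ValueError("sheet pair with inconsistent repeating units")
    size = sheet_a.repeating_unit_size

    ca, _ = _slab_arrays(sheet_a.strands)
    cb, _ = _slab_arrays(sheet_b.strands)
    d, idx = cKDTree(cb).query(ca, k=1)
    i = int(np.argmin(d))
    contact = 0.5 * (ca[i] + cb[int(idx[i])])

    out = []
    for sheet in (sheet_a, sheet_b):
        ulist = _units(sheet)
        if len(ulist) < units:
            raise ValueError("insufficient lattice expansion: "
                             f"{len(ulist)} repeating units < {units}")
        ycs = [np.mean([np.dot(sheet.strands[i].centroid(), sheet.axis_y)
                        for i in u]) for u in ulist]
        yc_contact = np.dot(contact, sheet.axis_y)
        mid = int(np.argmin(np.abs(np.array(ycs) - yc_contact)))
        mid = min(max(mid, units // 2), len(ulist) - 1 - units // 2)
        chosen = ulist[mid - units // 2: mid + units // 2 + 1]
        slab = [sheet.strands[i] for u in chosen for i in u]
        middle = [sheet.strands[i] for i in chosen[units // 2]]
        out.append((slab, middle))

    return AnalysisSlab(sheet_a=sheet_a, sheet_b=sheet_b,
                        a_strands=out[0][0], a_middle=out[0][1],
                        b_strands=out[1][0], b_middle=out[1][1],
                        unit_size=size)


def _slab_arrays(strands):
    coords = np.vstack([s.coords for s in strands])
    radii = np.concatenate([s.radii for s in strands])
    return coords, radii


# ---------------------------------------------------------------------------
# buried area (per-chain)
# ---------------------------------------------------------------------------


def _middle_mask(strands, middle) -> np.ndarray:
    keys = {id(s) for s in middle}
    parts = [np.full(s.n_atoms, id(s) in keys, dtype=bool) for s in strands]
    return np.concatenate(parts)


def buried_area(slab: AnalysisSlab, config: RunConfig = DEFAULT_CONFIG
                ) -> tuple[float, dict]:
    """Per-chain buried area of the middle repeating units (see module
    docstring) plus the intermediate SASA sums."""
    xa, ra = slab.coords_a()
    xb, rb = slab.coords_b()
    ma = _middle_mask(slab.a_strands, slab.a_middle)
    mb = _middle_mask(slab.b_strands, slab.b_middle)

    sasa_a = compute_sasa(xa, ra, config.probe_radius, config.sasa_points)
    sasa_b = compute_sasa(xb, rb, config.probe_radius, config.sasa_points)
    xu = np.vstack([xa, xb])
    ru = np.concatenate([ra, rb])
    sasa_u = compute_sasa(xu, ru, config.probe_radius, config.sasa_points)

    A = float(sasa_a.per_atom_area[ma].sum())
    B = float(sasa_b.per_atom_area[mb].sum())
    U = float(sasa_u.per_atom_area[np.concatenate([ma, mb])].sum())
    N = slab.n_chains_eq1
    ab = (A + B - U) / N
    if ab < -1.0:
        raise ValueError(f"negative buried area ({ab:.2f}): "
                         "inconsistent slab geometry")
    detail = {"SASA_A": A, "SASA_B": B, "SASA_U": U, "N": N,
              "per_atom_isolated": np.concatenate(
                  [sasa_a.per_atom_area, sasa_b.per_atom_area]),
              "per_atom_union": sasa_u.per_atom_area}
    return max(ab, 0.0), detail


def sidechain_burial(slab: AnalysisSlab, detail: dict
                     ) -> list[dict]:
    """Interface burial of each middle-unit residue's side chain.

    Burial = SASA(own sheet alone) - SASA(both sheets), summed over
    side-chain atoms (glycine: the CA atom). Uses the per-atom areas
    computed by :func:`buried_area`.
    """
    iso = detail["per_atom_isolated"]
    uni = detail["per_atom_union"]
    rows = []
    offset = 0
    for sheet_tag, strands, middle in (
            ("A", slab.a_strands, slab.a_middle),
            ("B", slab.b_strands, slab.b_middle)):
        mids = {id(s) for s in middle}
        for s in strands:
            if id(s) in mids:
                for ri, (rname, rseq, _) in enumerate(s.residues):
                    idx = [offset + k for k in s.sidechain_indices(ri)]
                    burial = float(iso[idx].sum() - uni[idx].sum()) if idx else 0.0
                    rows.append({"sheet": sheet_tag, "chain": s.label,
                                 "residue_name": rname, "residue_seq": rseq,
                                 "is_gly": rname == "GLY",
                                 "burial": burial})
            offset += s.n_atoms
    return rows


# ---------------------------------------------------------------------------
# molecular surface + shape complementarity
# ---------------------------------------------------------------------------


def molecular_surface(coords: np.ndarray, radii: np.ndarray,
                      probe_radius: float = 1.4, spacing: float = 0.35
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Solvent-excluded (molecular) surface as points + outward normals.

    The solvent-excluded volume is the set of points farther than the
    probe radius from the probe-accessible region; its boundary is
    extracted by marching cubes on the euclidean distance transform.
    """
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    pad = radii.max() + 2 * probe_radius + 3 * spacing
    lo = coords.min(axis=0) - pad
    hi = coords.max(axis=0) + pad
    shape = np.ceil((hi - lo) / spacing).astype(int) + 1
    # mask of the probe-forbidden region (probe center clashes an atom)
    mask = np.zeros(shape, dtype=bool)
    for c, r in zip(coords, radii):
        rr = r + probe_radius
        i0 = np.floor((c - rr - lo) / spacing).astype(int)
        i1 = np.ceil((c + rr - lo) / spacing).astype(int) + 1
        i0 = np.maximum(i0, 0)
        i1 = np.minimum(i1, shape)
        gx, gy, gz = np.meshgrid(*[np.arange(a, b) for a, b in zip(i0, i1)],
                                 indexing="ij")
        pts = np.stack([gx, gy, gz], axis=-1) * spacing + lo
        d2 = np.sum((pts - c) ** 2, axis=-1)
        mask[gx, gy, gz] |= d2 <= rr * rr
    # distance from forbidden voxels to the nearest allowed voxel
    dt = distance_transform_edt(mask, sampling=spacing)
    verts, faces, normals, _ = marching_cubes(
        dt, level=probe_radius, spacing=(spacing,) * 3)
    verts = verts + lo
    # marching-cubes normals point down the gradient of dt, i.e. away from
    # the molecular interior: already outward
    nn = np.linalg.norm(normals, axis=1)
    ok = nn > 1e-9
    return verts[ok], normals[ok] / nn[ok, None]


def shape_complementarity(slab: AnalysisSlab,
                          config: RunConfig = DEFAULT_CONFIG) -> float:
    """Lawrence-Colman style Sc over the buried molecular surfaces.

    Buried points are surface points within the cutoff distance (1 A) of
    the partner surface; each is paired with its nearest partner point and
    scored as -(n_a . n_b) exp(-w d^2). Sc is the median of the pooled
    scores of both directions.
    """
    va, na = molecular_surface(*slab.coords_a(), config.probe_radius,
                               config.sc_grid_spacing)
    vb, nb = molecular_surface(*slab.coords_b(), config.probe_radius,
                               config.sc_grid_spacing)
    ta, tb = cKDTree(va), cKDTree(vb)
    scores = []
    for (v1, n1, t2, v2, n2) in ((va, na, tb, vb, nb),
                                 (vb, nb, ta, va, na)):
        d, j = t2.query(v1, k=1)
        sel = d <= config.sc_buried_cutoff
        if not sel.any():
            continue
        dots = -np.einsum("ij,ij->i", n1[sel], n2[j[sel]])
        w = np.exp(-config.sc_weight * d[sel] ** 2)
        scores.append(dots * w)
    if not scores:
        raise ValueError("no buried surface: not an interface")
    return float(np.median(np.concatenate(scores)))


# ---------------------------------------------------------------------------
# footprint rectangle + SDi
# ---------------------------------------------------------------------------


def footprint_rectangle(slab: AnalysisSlab,
                        config: RunConfig = DEFAULT_CONFIG
                        ) -> tuple[float, float]:
    """(length, width) of the flat footprint rectangle.

    Width: repeating-unit extent along the sheet axis (strand spacing x
    strands per unit). Length: in the projection along the sheet axis,
    atoms become disks; a probe disk is brought into the groove from both
    open ends until it is simultaneously tangent to the disks of both
    sheets; each endpoint is the innermost point of that probe circle.
    """
    sheet = slab.sheet_a
    width = abs(sheet.mean_strand_spacing) * slab.unit_size
    rp = config.probe_radius

    xa, ra = slab.coords_a()
    xb, rb = slab.coords_b()
    # projection coordinates: u along axis_x (packing), v along axis_z
    ua, vaz = xa @ sheet.axis_x, xa @ sheet.axis_z
    ub, vbz = xb @ sheet.axis_x, xb @ sheet.axis_z

    ca = float(np.mean(ua))
    cb = float(np.mean(ub))
    ulo, uhi = min(ca, cb), max(ca, cb)
    ugrid = np.arange(ulo, uhi + 1e-9, 0.05)

    def gmin(u, v, uc, vc, r):
        d = np.hypot(u[:, None] - uc[None, :], v[:, None] - vc[None, :])
        return (d - r[None, :] - rp).min(axis=1)

    def h(v: float) -> float:
        """Max over probe x-positions of the clearance to both sheets;
        zero = probe tangent to both, negative = probe excluded."""
        vv = np.full(len(ugrid), v)
        g = np.minimum(gmin(ugrid, vv, ua, vaz, ra),
                       gmin(ugrid, vv, ub, vbz, rb))
        return float(g.max())

    vlo = min(vaz.min(), vbz.min()) - 2 * rp - 2.0
    vhi = max(vaz.max(), vbz.max()) + 2 * rp + 2.0
    vs = np.arange(vlo, vhi, 0.25)
    hs = np.array([h(v) for v in vs])
    inside = hs < 0
    if not inside.any():
        raise ValueError("no closed interface: probe passes the groove")
    i0, i1 = int(np.argmax(inside)), len(inside) - 1 - int(
        np.argmax(inside[::-1]))
    if i0 == 0 or i1 == len(vs) - 1:
        raise ValueError("no closed interface: groove open at the rim")
    z1 = brentq(h, vs[i0 - 1], vs[i0], xtol=1e-4)
    z2 = brentq(h, vs[i1], vs[i1 + 1], xtol=1e-4)
    length = (z2 - rp) - (z1 + rp)
    if length <= 0:
        raise ValueError("degenerate footprint")
    return float(length), float(width)


def surface_detail_index(ab: float, footprint: tuple[float, float],
                         unit_size: int) -> float:
    """SDi = one-sided repeating-unit burial over the footprint area."""
    length, width = footprint
    if length * width <= 0:
        raise ValueError("zero-area footprint")
    return ab * unit_size / (length * width)


def describe_interface(slab: AnalysisSlab,
                       config: RunConfig = DEFAULT_CONFIG) -> DescriptorSet:
    """All three descriptors of one interface slab."""
    ab, _ = buried_area(slab, config)
    sc = shape_complementarity(slab, config)
    fp = footprint_rectangle(slab, config)
    sdi = surface_detail_index(ab, fp, slab.unit_size)
    return DescriptorSet(Sc=sc, Ab=ab, SDi=sdi, footprint=fp,
                         N=slab.n_chains_eq1)
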