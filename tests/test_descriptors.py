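"""SASA engine, buried area (per-chain), Sc, footprint and SDi."""
import numpy as np
import pytest

import stericzip as sz
from stericzip.config import RunConfig
from stericzip.descriptors import (
    buried_area, compute_sasa, footprint_rectangle, select_slab,
    shape_complementarity, surface_detail_index,
)
from stericzip.geometry import rotation_about_axis
from stericzip.sheet_topology import BetaSheet
from stericzip.structure_io import AtomRecord, ChainCopy

from conftest import zipper_slab


# ---------------------------------------------------------------------------
# SASA engine vs analytic formulas
# ---------------------------------------------------------------------------


def test_sasa_isolated_sphere():
    res = compute_sasa(np.zeros((1, 3)), np.array([1.7]), 1.4)
    exact = 4 * np.pi * (1.7 + 1.4) ** 2
    assert res.total == pytest.approx(exact, rel=0.01)


def test_sasa_two_overlapping_spheres():
    """Closed form for two equal spheres: each loses a spherical cap of
    height R - d/2 (R = vdW + probe)."""
    d = 3.0
    R = 1.7 + 1.4
    exact = 2 * 4 * np.pi * R ** 2 - 2 * 2 * np.pi * R * (R - d / 2)
    res = compute_sasa(np.array([[0, 0, 0], [d, 0, 0.0]]),
                       np.array([1.7, 1.7]), 1.4)
    assert res.total == pytest.approx(exact, rel=0.01)


def test_sasa_additive_when_separated():
    one = compute_sasa(np.zeros((1, 3)), np.array([1.7]), 1.4).total
    two = compute_sasa(np.array([[0, 0, 0], [50, 0, 0.0]]),
                       np.array([1.7, 1.7]), 1.4).total
    assert two == pytest.approx(2 * one, abs=1e-9)


def test_sasa_zero_atoms_error():
    with pytest.raises(ValueError):
        compute_sasa(np.zeros((0, 3)), np.zeros(0), 1.4)


def test_sasa_against_biotite():
    """Independent cross-check of the Shrake-Rupley engine on a peptide."""
    biotite_struc = pytest.importorskip("biotite.structure")
    atoms = sz.build_ideal_strand("LYIQWL")
    coords = np.array([a.position for a in atoms])
    radii = np.array([a.vdw_radius for a in atoms])
    mine = compute_sasa(coords, radii, 1.4, n_points=2000).total

    arr = biotite_struc.AtomArray(len(atoms))
    arr.coord = coords.astype(np.float32)
    for i, a in enumerate(atoms):
        arr.chain_id[i] = "A"
        arr.res_id[i] = a.residue_seq
        arr.res_name[i] = a.residue_name
        arr.atom_name[i] = a.name
        arr.element[i] = a.element
    ref = biotite_struc.sasa(arr, probe_radius=1.4, vdw_radii=radii,
                             point_number=2000).sum()
    assert mine == pytest.approx(float(ref), rel=0.01)


# ---------------------------------------------------------------------------
# buried area
# ---------------------------------------------------------------------------


def _fake_sheet(chains):
    """Minimal BetaSheet around prebuilt ChainCopy strands (synthetic
    sphere models; axes are the lab frame)."""
    return BetaSheet(
        strand_indices=list(range(len(chains))), strands=chains,
        strand_dirs=[np.array([0.0, 0.0, 1.0])] * len(chains),
        axis_y=np.array([0.0, 1.0, 0.0]), axis_z=np.array([0.0, 0.0, 1.0]),
        axis_x=np.array([1.0, 0.0, 0.0]), arrangement="parallel",
        mean_strand_spacing=6.0, hbonds=[])


def _sphere_chain(cid, y, x, n_res=3, r=1.9, z_step=6.0):
    atoms = []
    for i in range(n_res):
        atoms.append(AtomRecord(i + 1, "CA", "C", "GLY", i + 1, cid,
                                np.array([x, y, i * z_step]), 1.0, "", r))
    return ChainCopy(cid, 0, (0, 0, 0), atoms,
                     np.array([a.position for a in atoms]))


def test_buried_area_matches_two_sphere_oracle():
    """On a synthetic slab of isolated sphere pairs the per-chain buried
    area equals the analytic two-sphere value (independent closed form)."""
    d, r, rp = 3.0, 1.9, 1.4
    R = r + rp
    cfg = RunConfig(sasa_points=8000)
    a_chains = [_sphere_chain(c, y=6.0 * k, x=0.0) for k, c in
                enumerate("ABC")]
    b_chains = [_sphere_chain(c, y=6.0 * k, x=d) for k, c in
                enumerate("DEF")]
    sheet_a, sheet_b = _fake_sheet(a_chains), _fake_sheet(b_chains)
    slab = select_slab(sheet_a, sheet_b)
    ab, detail = buried_area(slab, cfg)
    # each middle-unit sphere loses one cap against its partner
    cap = 2 * np.pi * R * (R - d / 2)
    n_spheres_per_chain = 3
    exact = (2 * n_spheres_per_chain * cap) / slab.n_chains_eq1
    assert ab == pytest.approx(exact, abs=0.1)
    assert detail["N"] == 2


def test_buried_area_zero_when_separated():
    a_chains = [_sphere_chain(c, y=6.0 * k, x=0.0) for k, c in
                enumerate("ABC")]
    b_chains = [_sphere_chain(c, y=6.0 * k, x=40.0) for k, c in
                enumerate("DEF")]
    slab = select_slab(_fake_sheet(a_chains), _fake_sheet(b_chains))
    ab, _ = buried_area(slab)
    assert ab == pytest.approx(0.0, abs=1e-9)


def test_buried_area_symmetric_under_swap(ala_flat_slab):
    ab1, _ = buried_area(ala_flat_slab)
    from stericzip.descriptors import AnalysisSlab
    swapped = AnalysisSlab(
        sheet_a=ala_flat_slab.sheet_b, sheet_b=ala_flat_slab.sheet_a,
        a_strands=ala_flat_slab.b_strands, a_middle=ala_flat_slab.b_middle,
        b_strands=ala_flat_slab.a_strands, b_middle=ala_flat_slab.a_middle,
        unit_size=ala_flat_slab.unit_size)
    ab2, _ = buried_area(swapped)
    assert ab1 == pytest.approx(ab2, abs=1e-9)


def test_eq1_arithmetic():
    """(500 + 480 - 700) / 2 = 140."""
    assert (500.0 + 480.0 - 700.0) / 2 == pytest.approx(140.0)


def test_slab_sizes_parallel_antiparallel():
    par = zipper_slab(sz.ZipperSpec(
        1, sz.SheetSpec("AAAAAA", 3, "parallel"), isolated=True))
    assert (len(par.a_strands), len(par.b_strands)) == (3, 3)
    assert len(par.a_middle) == 1 and par.n_chains_eq1 == 2
    anti = zipper_slab(sz.ZipperSpec(
        8, sz.SheetSpec("AAAAAA", 6, "antiparallel"), isolated=True))
    assert (len(anti.a_strands), len(anti.b_strands)) == (6, 6)
    assert len(anti.a_middle) == 2 and anti.n_chains_eq1 == 4


def test_slab_insufficient_units_error():
    a = [_sphere_chain(c, y=6.0 * k, x=0.0) for k, c in enumerate("AB")]
    b = [_sphere_chain(c, y=6.0 * k, x=3.0) for k, c in enumerate("DE")]
    with pytest.raises(ValueError, match="insufficient lattice expansion"):
        select_slab(_fake_sheet(a), _fake_sheet(b))


# ---------------------------------------------------------------------------
# shape complementarity
# ---------------------------------------------------------------------------


def _wall_chain(cid, x0, nx=1, ny=7, nz=7, step=1.5, r=1.9):
    atoms = []
    k = 0
    for iy in range(ny):
        for iz in range(nz):
            k += 1
            atoms.append(AtomRecord(k, "CA", "C", "GLY", k, cid,
                                    np.array([x0, iy * step, iz * step]),
                                    1.0, "", r))
    return ChainCopy(cid, 0, (0, 0, 0), atoms,
                     np.array([a.position for a in atoms]))


def _wall_slab(gap=0.6, curved=False):
    """Two dense atom walls facing along x; optionally convex-vs-convex."""
    a = [_wall_chain("A", 0.0)]
    bx = 2 * 1.9 + gap
    b_atoms = _wall_chain("B", bx)
    if curved:
        # bulge both walls toward each other (clashing curvature)
        for cp in (a[0], b_atoms):
            c = cp.coords.mean(axis=0)
            d2 = np.sum((cp.coords[:, 1:] - c[1:]) ** 2, axis=1)
            bump = 1.8 * np.exp(-d2 / 40.0)
            sign = 1.0 if cp.chain_id == "A" else -1.0
            cp.coords[:, 0] += sign * bump
    from stericzip.descriptors import AnalysisSlab
    return AnalysisSlab(sheet_a=_fake_sheet(a), sheet_b=_fake_sheet([b_atoms]),
                        a_strands=a, a_middle=a, b_strands=[b_atoms],
                        b_middle=[b_atoms], unit_size=1)


def test_sc_flat_walls_near_one():
    """Identical flat walls in contact: near-perfect complementarity."""
    sc = shape_complementarity(_wall_slab(gap=0.3))
    assert sc > 0.9


def test_sc_clashing_curvature_lower():
    flat = shape_complementarity(_wall_slab(gap=0.3))
    curved = shape_complementarity(_wall_slab(gap=0.3, curved=True))
    assert curved < flat - 0.05


def test_sc_rigid_motion_invariant(gln_interdigitated_slab):
    sc0 = shape_complementarity(gln_interdigitated_slab)
    R = rotation_about_axis([0.3, 1.0, -0.7], 49.0)
    t = np.array([3.0, -8.0, 2.0])
    import copy as cp
    slab = cp.copy(gln_interdigitated_slab)
    moved = {}
    for attr in ("a_strands", "a_middle", "b_strands", "b_middle"):
        new = []
        for s in getattr(slab, attr):
            if id(s) not in moved:
                moved[id(s)] = s.transformed(R, t)
            new.append(moved[id(s)])
        setattr(slab, attr, new)
    for sheet_attr, sheet in (("sheet_a", slab.sheet_a),
                              ("sheet_b", slab.sheet_b)):
        new_sheet = cp.copy(sheet)
        new_sheet.axis_x = R @ sheet.axis_x
        new_sheet.axis_y = R @ sheet.axis_y
        new_sheet.axis_z = R @ sheet.axis_z
        setattr(slab, sheet_attr, new_sheet)
    sc1 = shape_complementarity(slab)
    assert sc1 == pytest.approx(sc0, abs=0.03)


def test_sc_decreases_when_sheets_pulled_apart():
    s1 = shape_complementarity(_wall_slab(gap=0.3))
    s2 = shape_complementarity(_wall_slab(gap=0.8))
    assert s2 < s1
    with pytest.raises(ValueError, match="no buried surface|interface"):
        shape_complementarity(_wall_slab(gap=6.0))


# ---------------------------------------------------------------------------
# footprint + SDi
# ---------------------------------------------------------------------------


def _footprint_oracle(slab, rp=1.4, du=0.05, dv=0.05):
    """Brute-force probe placement on a dense 2D grid."""
    sheet = slab.sheet_a
    xa, ra = slab.coords_a()
    xb, rb = slab.coords_b()
    ua, va = xa @ sheet.axis_x, xa @ sheet.axis_z
    ub, vb = xb @ sheet.axis_x, xb @ sheet.axis_z
    ulo, uhi = sorted((float(np.mean(ua)), float(np.mean(ub))))
    ug = np.arange(ulo, uhi + 1e-9, du)
    vg = np.arange(min(va.min(), vb.min()) - 4, max(va.max(), vb.max()) + 4,
                   dv)
    U, V = np.meshgrid(ug, vg, indexing="ij")

    def clearance(uc, vc, rr):
        d = np.hypot(U[..., None] - uc, V[..., None] - vc) - rr - rp
        return d.min(axis=-1)

    g = np.minimum(clearance(ua, va, ra), clearance(ub, vb, rb))
    feasible_per_v = (g >= 0).any(axis=0)
    excluded = ~feasible_per_v
    idx = np.where(excluded)[0]
    v1, v2 = vg[idx[0]], vg[idx[-1]]
    return (v2 - rp) - (v1 + rp)


def test_footprint_matches_bruteforce_oracle(ala_flat_slab,
                                             gln_interdigitated_slab):
    for slab in (ala_flat_slab, gln_interdigitated_slab):
        length, width = footprint_rectangle(slab)
        oracle = _footprint_oracle(slab)
        assert length == pytest.approx(oracle, abs=1.4)


def test_footprint_two_disk_rows():
    """Two parallel rows of equal disks: length within one probe diameter
    of the row extent, width = spacing."""
    n = 8
    step = 2.2
    a = [_sphere_chain("A", y=6.0 * k, x=0.0) for k in range(3)]
    # replace z placement: dense row along z
    for cp in a:
        cp.coords[:, 2] = 0.0
    rows_a = []
    for k, cid in enumerate("ABC"):
        atoms = [AtomRecord(i + 1, "CA", "C", "GLY", i + 1, cid,
                            np.array([0.0, 6.0 * k, i * step]), 1.0, "", 1.9)
                 for i in range(n)]
        rows_a.append(ChainCopy(cid, 0, (0, 0, 0), atoms,
                                np.array([x.position for x in atoms])))
    rows_b = []
    for k, cid in enumerate("DEF"):
        atoms = [AtomRecord(i + 1, "CA", "C", "GLY", i + 1, cid,
                            np.array([2 * 1.9 + 0.5, 6.0 * k, i * step]),
                            1.0, "", 1.9)
                 for i in range(n)]
        rows_b.append(ChainCopy(cid, 0, (0, 0, 0), atoms,
                                np.array([x.position for x in atoms])))
    from stericzip.descriptors import AnalysisSlab
    slab = AnalysisSlab(sheet_a=_fake_sheet(rows_a),
                        sheet_b=_fake_sheet(rows_b),
                        a_strands=rows_a, a_middle=[rows_a[1]],
                        b_strands=rows_b, b_middle=[rows_b[1]],
                        unit_size=1)
    length, width = footprint_rectangle(slab)
    L0 = (n - 1) * step
    assert abs(length - L0) < 2 * 1.4
    assert width == pytest.approx(6.0, abs=1e-6)


def test_footprint_open_groove_error():
    slab = _wall_slab(gap=6.0)
    with pytest.raises(ValueError, match="no closed interface"):
        footprint_rectangle(slab)


def test_antiparallel_width_is_two_spacings():
    slab = zipper_slab(sz.ZipperSpec(
        8, sz.SheetSpec("AAAAAA", 6, "antiparallel"), isolated=True))
    _, width = footprint_rectangle(slab)
    assert width == pytest.approx(2 * 4.8, abs=0.2)


def test_sdi_flat_below_interdigitated(ala_flat_slab,
                                       gln_interdigitated_slab):
    """Interdigitated glutamine ladders give a strictly larger SDi than a
    flat-faced polyalanine zipper (monotonicity probe)."""
    vals = []
    for slab in (ala_flat_slab, gln_interdigitated_slab):
        ab, _ = buried_area(slab)
        fp = footprint_rectangle(slab)
        vals.append(surface_detail_index(ab, fp, slab.unit_size))
    assert vals[0] < vals[1]


def test_sdi_length_invariance():
    """Hexa- vs octa-alanine zippers: SDi differs by < 0.05."""
    vals = []
    for seq in ("AAAAAA", "AAAAAAAA"):
        slab = zipper_slab(sz.ZipperSpec(
            1, sz.SheetSpec(seq, 3, "parallel"), isolated=True,
            lateral_offset=0.0))
        ab, _ = buried_area(slab)
        fp = footprint_rectangle(slab)
        vals.append(surface_detail_index(ab, fp, slab.unit_size))
    assert abs(vals[0] - vals[1]) < 0.05


def test_sdi_zero_footprint_error():
    with pytest.raises(ValueError):
        surface_detail_index(100.0, (0.0, 4.8), 1)
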