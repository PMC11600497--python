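"""Interface admission criteria, deduplication and wetness."""
import copy

import numpy as np
import pytest

import stericzip as sz
from stericzip.config import RunConfig
from stericzip.descriptors import buried_area, sidechain_burial, select_slab
from stericzip.interface_finder import (
    Rejection, admit_interface, classify_wetness, deduplicate,
    find_contacting_pairs,
)

from conftest import zipper_sheets


@pytest.fixture(scope="module")
def class1_catemer():
    """Class-1 LYIQWL catemer lattice: two distinct zipper faces."""
    return zipper_sheets(sz.ZipperSpec(
        1, sz.SheetSpec("LYIQWL", 3, "parallel")), radius=12.0)


def test_class1_two_distinct_pair_types(class1_catemer):
    lat, _ = class1_catemer
    bonds = sz.detect_backbone_hbonds(lat)
    sheets = sz.assemble_sheets(lat, bonds)
    pairs = find_contacting_pairs(sheets)
    sides = set()
    for i, j in pairs:
        itf = admit_interface(sheets[i], sheets[j],
                              compute_descriptors=False)
        if not isinstance(itf, Rejection):
            sides.add(tuple(sorted(itf.sides)))
    assert len(sides) == 2  # the L1-I3-W5 face and the Y2-Q4-L6 face


def test_distant_sheets_not_candidates():
    _, sheets = zipper_sheets(sz.ZipperSpec(
        1, sz.SheetSpec("AAAAAA", 3, "parallel"), isolated=True,
        inter_sheet_gap=30.0), radius=6.0)
    assert find_contacting_pairs(sheets) == []


def test_isolated_sandwich_single_pair():
    lat, sheets = zipper_sheets(sz.ZipperSpec(
        1, sz.SheetSpec("AQAQAQ", 3, "parallel"), isolated=True),
        radius=6.0)
    assert find_contacting_pairs(sheets) == [(0, 1)]


def test_wide_gap_rejected_criterion_i():
    """A loose polyalanine pair fails the 50 A^2 size criterion first."""
    _, sheets = zipper_sheets(sz.ZipperSpec(
        1, sz.SheetSpec("AAAAAA", 3, "parallel"), isolated=True,
        inter_sheet_gap=6.5, lateral_offset=0.0), radius=6.0)
    res = admit_interface(sheets[0], sheets[1], compute_descriptors=False)
    assert isinstance(res, Rejection)
    assert res.criterion == "i"


def test_admission_monotone_in_gap():
    """Shrinking the inter-sheet gap never flips admitted -> rejected
    through the size criterion."""
    abs_per_gap = []
    for gap in (6.0, 5.0, 4.2, 3.8):
        _, sheets = zipper_sheets(sz.ZipperSpec(
            1, sz.SheetSpec("AQAQAQ", 3, "parallel"), isolated=True,
            inter_sheet_gap=gap), radius=6.0)
        slab = select_slab(sheets[0], sheets[1])
        ab, _ = buried_area(slab)
        abs_per_gap.append(ab)
    assert all(b2 >= b1 - 1.0 for b1, b2 in
               zip(abs_per_gap, abs_per_gap[1:]))


def test_admission_flips_exactly_at_thresholds():
    """Moving each admission threshold across the measured values flips
    the decision for that criterion and no earlier one."""
    _, sheets = zipper_sheets(sz.ZipperSpec(
        1, sz.SheetSpec("LYIQWL", 3, "parallel"), isolated=True),
        radius=6.0)
    slab = select_slab(sheets[0], sheets[1])
    ab, detail = buried_area(slab)
    rows = sidechain_burial(slab, detail)
    burials = sorted(r["burial"] for r in rows if r["burial"] > 0)

    base = RunConfig()
    ok = admit_interface(sheets[0], sheets[1], base,
                         compute_descriptors=False)
    assert not isinstance(ok, Rejection)

    # (i): threshold just above the measured per-chain Ab
    c = RunConfig(min_interface_ab=ab + 0.01)
    res = admit_interface(sheets[0], sheets[1], c,
                          compute_descriptors=False)
    assert isinstance(res, Rejection) and res.criterion == "i"
    c = RunConfig(min_interface_ab=ab - 0.01)
    assert not isinstance(admit_interface(sheets[0], sheets[1], c,
                                          compute_descriptors=False),
                          Rejection)

    # (iv)->(ii): raising the involvement threshold above the largest
    # side-chain burial removes all involved side chains
    c = RunConfig(min_sidechain_ab=burials[-1] + 0.01,
                  min_gly_ca_ab=burials[-1] + 0.01)
    res = admit_interface(sheets[0], sheets[1], c,
                          compute_descriptors=False)
    assert isinstance(res, Rejection) and res.criterion == "ii"

    # (iii): with the default involvement threshold, demand an impossible
    # mean count per chain
    c = RunConfig(min_mean_sidechains=6.1)
    res = admit_interface(sheets[0], sheets[1], c,
                          compute_descriptors=False)
    assert isinstance(res, Rejection) and res.criterion == "iii"
    n_involved = sum(r["burial"] >= base.min_sidechain_ab for r in rows
                     if not r["is_gly"])
    n_chains = slab.n_chains_eq1
    c = RunConfig(min_mean_sidechains=n_involved / n_chains - 0.01)
    assert not isinstance(admit_interface(sheets[0], sheets[1], c,
                                          compute_descriptors=False),
                          Rejection)


def test_backbone_only_contact_rejected():
    """Sheets touching without side-chain involvement fail criterion (ii):
    raise the involvement threshold so no side chain qualifies."""
    _, sheets = zipper_sheets(sz.ZipperSpec(
        1, sz.SheetSpec("AAAAAA", 3, "parallel"), isolated=True,
        lateral_offset=0.0), radius=6.0)
    c = RunConfig(min_sidechain_ab=1e6, min_gly_ca_ab=1e6,
                  min_interface_ab=10.0)
    res = admit_interface(sheets[0], sheets[1], c,
                          compute_descriptors=False)
    assert isinstance(res, Rejection) and res.criterion == "ii"


# ---------------------------------------------------------------------------
# deduplication
# ---------------------------------------------------------------------------


def _with_sc(itf, sc):
    dup = copy.copy(itf)
    dup.descriptors = copy.copy(itf.descriptors)
    dup.descriptors.Sc = sc
    return dup


@pytest.fixture(scope="module")
def admitted_interface(class1_catemer):
    lat, sheets = class1_catemer
    itf = admit_interface(sheets[0], sheets[1])
    assert not isinstance(itf, Rejection)
    return itf


def test_deduplicate_averages(admitted_interface):
    a = _with_sc(admitted_interface, 0.80)
    b = _with_sc(admitted_interface, 0.82)
    merged = deduplicate([a, b])
    assert len(merged) == 1
    assert merged[0].descriptors.Sc == pytest.approx(0.81)
    assert merged[0].multiplicity == 2


def test_deduplicate_idempotent_and_order_independent(admitted_interface):
    a = _with_sc(admitted_interface, 0.80)
    b = _with_sc(admitted_interface, 0.82)
    m1 = deduplicate([a, b])
    m2 = deduplicate(deduplicate([_with_sc(admitted_interface, 0.80),
                                  _with_sc(admitted_interface, 0.82)]))
    m3 = deduplicate([_with_sc(admitted_interface, 0.82),
                      _with_sc(admitted_interface, 0.80)])
    assert m1[0].descriptors.Sc == pytest.approx(m3[0].descriptors.Sc)
    assert m2[0].descriptors.Sc == pytest.approx(0.81)


def test_deduplicate_single_unchanged(admitted_interface):
    one = _with_sc(admitted_interface, 0.77)
    out = deduplicate([one])
    assert len(out) == 1
    assert out[0].descriptors.Sc == pytest.approx(0.77)
    assert out[0].multiplicity == 1


# ---------------------------------------------------------------------------
# wetness
# ---------------------------------------------------------------------------


def _wet_fixture(water_positions):
    spec = sz.ZipperSpec(1, sz.SheetSpec("AQAQAQ", 3, "parallel"),
                         isolated=True)
    model = sz.build_zipper(spec, waters=water_positions)
    lat = sz.expand_symmetry(sz.sanitize(model), 6.0)
    sheets = sz.assemble_sheets(lat, sz.detect_backbone_hbonds(lat))
    sheets = sorted(sheets, key=lambda s: -len(s.strands))[:2]
    itf = admit_interface(sheets[0], sheets[1], compute_descriptors=False)
    assert not isinstance(itf, Rejection)
    return itf, lat


def _gap_center():
    spec = sz.ZipperSpec(1, sz.SheetSpec("AQAQAQ", 3, "parallel"),
                         isolated=True)
    model = sz.build_zipper(spec)
    xyz = np.array([a.position for a in model.atoms])
    return xyz.mean(axis=0)


def test_water_mid_gap_partially_wet():
    itf, lat = _wet_fixture([_gap_center()])
    assert classify_wetness(itf, lat) == "partially_wet"


def test_anhydrous_dry():
    itf, lat = _wet_fixture([])
    assert classify_wetness(itf, lat) == "dry"


def test_water_beyond_rim_dry():
    """A water outside the footprint extent, past the groove rim, does not
    wet the interface (point-in-slab oracle by construction)."""
    c = _gap_center()
    far = c + np.array([0.0, 0.0, 30.0])
    itf, lat = _wet_fixture([far])
    assert classify_wetness(itf, lat) == "dry"
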