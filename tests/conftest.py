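"""Shared fixtures: synthetic sheets, zipper crystals and analysis slabs.

Everything is generated at test time; the expensive builds (symmetry
expansion + slab selection) are session-scoped and shared across files.
"""
from __future__ import annotations

import numpy as np
import pytest

import stericzip as sz
from stericzip.structure_io import ChainCopy, CrystalModel, as_lattice


def make_chain_copy(atoms) -> ChainCopy:
    return ChainCopy("A", 0, (0, 0, 0), atoms,
                     np.array([a.position for a in atoms]))


def sheet_fragment_model(spec: sz.SheetSpec) -> CrystalModel:
    strands, _ = sz.build_sheet(spec)
    atoms = [a for st in strands for a in st]
    span = np.ptp(np.array([a.position for a in atoms]), axis=0) + 40.0
    return CrystalModel(atoms, (span[0], span[1], span[2], 90, 90, 90),
                        "P 1", [(np.eye(3), np.zeros(3))], name="fragment")


def single_sheet(spec: sz.SheetSpec) -> sz.BetaSheet:
    lat = as_lattice(sheet_fragment_model(spec))
    bonds = sz.detect_backbone_hbonds(lat)
    sheets = sz.assemble_sheets(lat, bonds)
    assert len(sheets) == 1
    return sheets[0]


def zipper_sheets(spec: sz.ZipperSpec, radius: float = 8.0):
    """Build a zipper crystal, expand it and return the two largest
    sheets (sorted so the identity-containing sheet comes first)."""
    model = sz.build_zipper(spec)
    lat = sz.expand_symmetry(sz.sanitize(model), radius)
    bonds = sz.detect_backbone_hbonds(lat)
    sheets = sz.assemble_sheets(lat, bonds)
    sheets = sorted(sheets, key=lambda s: -len(s.strands))[:2]
    return lat, sheets


def zipper_slab(spec: sz.ZipperSpec, radius: float = 8.0):
    lat, sheets = zipper_sheets(spec, radius)
    return sz.select_slab(sheets[0], sheets[1])


@pytest.fixture(scope="session")
def parallel_hexa_sheet():
    return single_sheet(sz.SheetSpec("AAAAAA", 3, "parallel"))


@pytest.fixture(scope="session")
def antiparallel_hexa_sheet():
    return single_sheet(sz.SheetSpec("AAAAAA", 3, "antiparallel"))


@pytest.fixture(scope="session")
def lyiqwl_parallel_sheet():
    return single_sheet(sz.SheetSpec("LYIQWL", 3, "parallel"))


@pytest.fixture(scope="session")
def ala_flat_slab():
    """Flat-faced polyalanine zipper (no lateral stagger)."""
    return zipper_slab(sz.ZipperSpec(
        1, sz.SheetSpec("AAAAAA", 3, "parallel"),
        isolated=True, lateral_offset=0.0))


@pytest.fixture(scope="session")
def gln_interdigitated_slab():
    """Same zipper rebuilt with interdigitated glutamine ladders."""
    return zipper_slab(sz.ZipperSpec(
        1, sz.SheetSpec("QAQAQA", 3, "parallel"), isolated=True))


@pytest.fixture(scope="session")
def lyiqwl_class1_lattice_sheets():
    return zipper_sheets(sz.ZipperSpec(
        1, sz.SheetSpec("LYIQWL", 3, "parallel"), isolated=True))
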