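"""Run configuration and the van der Waals radii table.

The admission thresholds (50 A^2 per-chain buried area, 10 A^2 per side
chain, 5 A^2 for Gly CA, 1.5 involved side chains per chain) and the 1.4 A
water probe are the method's published constants; everything else (H-bond
cutoffs, expansion radius, surface sampling) is a package default exposed
here and echoed into report metadata.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict

#: Van der Waals radii (A) following the CCP4 AREAIMOL defaults for the
#: elements occurring in peptides and common solvent/ions.
VDW_RADII: dict[str, float] = {
    "C": 1.90,
    "N": 1.70,
    "O": 1.40,
    "S": 1.80,
    "P": 1.80,
    "SE": 1.90,
    "F": 1.30,
    "CL": 1.80,
    "BR": 1.95,
    "I": 2.15,
    "NA": 1.60,
    "K": 2.00,
    "MG": 1.00,
    "CA": 1.00,
    "ZN": 0.74,
    "H": 1.00,
    "D": 1.00,
}

#: Fallback radius for unknown elements (a warning is emitted when used).
FALLBACK_RADIUS = 1.80

#: Residue names treated as solvent / non-peptide heteroatoms.
SOLVENT_RESIDUES = {
    "HOH", "WAT", "DOD", "H2O", "SOL",
    "SO4", "GOL", "EDO", "ACT", "PEG", "PO4", "NO3", "DMS", "MPD", "TRS",
    "CL", "NA", "K", "MG", "CA", "ZN", "BR", "IOD", "NH4", "LI", "CD",
}


@dataclass
class RunConfig:
    """All tunable parameters of the analysis pipeline."""

    # solvent probe (water) radius, A
    probe_radius: float = 1.4
    # backbone H-bond criteria
    hbond_dmax: float = 3.5        # N...O distance cutoff, A
    hbond_angle_min: float = 120.0  # C=O...N angle minimum, degrees
    min_hbonds_per_neighbor: int = 2  # strand adjacency requires >= this
    # symmetry expansion
    expansion_radius: float = 20.0  # A around the asymmetric unit
    max_copies: int = 2000
    # contact search between sheets
    contact_radius: float = 8.0     # A, coarse sheet-sheet contact search
    # interface admission thresholds (published values)
    min_interface_ab: float = 50.0   # A^2 per chain, criterion (i)
    min_sidechain_ab: float = 10.0   # A^2, criterion (iv)
    min_gly_ca_ab: float = 5.0       # A^2, criterion (iv) glycine
    min_mean_sidechains: float = 1.5  # per chain, criterion (iii)
    # slab standardization
    slab_units: int = 3
    # SASA sampling
    sasa_points: int = 960
    # molecular-surface grid for shape complementarity
    sc_grid_spacing: float = 0.35   # A
    sc_buried_cutoff: float = 1.0   # A
    sc_weight: float = 0.5          # Lawrence-Colman w, A^-2
    # LARKS kink margin: distance (deg) outside the beta region
    larks_margin: float = 30.0
    # quaternary-network lateral-shift thresholds (fraction of chain length)
    shift_straight: float = 0.15
    shift_brick: float = 0.35
    # output
    formats: tuple[str, ...] = ("csv", "json")

    def metadata(self) -> dict:
        """Config echo written into every report."""
        return asdict(self)


DEFAULT_CONFIG = RunConfig()


def load_config(path) -> RunConfig:
    """Read a flat key = value config file into a :class:`RunConfig`.

    Lines starting with '#' are comments; values are coerced to the field
    type. Unknown keys are an error (typo guard).
    """
    import dataclasses
    from pathlib import Path

    fields = {f.name: f for f in dataclasses.fields(RunConfig)}
    kwargs = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValueError(f"malformed config line: {line!r}")
        key, _, value = line.partition("=")
        key, value = key.strip(), value.strip()
        if key not in fields:
            raise ValueError(f"unknown config key: {key!r}")
        ftype = fields[key].type
        if "float" in str(ftype):
            kwargs[key] = float(value)
        elif "int" in str(ftype):
            kwargs[key] = int(value)
        elif "tuple" in str(ftype):
            kwargs[key] = tuple(v.strip() for v in value.split(","))
        else:
            kwargs[key] = value
    return RunConfig(**kwargs)


def element_radius(element: str) -> float:
    return VDW_RADII.get(element.upper(), FALLBACK_RADIUS)
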