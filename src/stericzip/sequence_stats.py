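"""Primary/secondary-structure analytics for oligopeptide amyloid models.

Residue composition and parallel/antiparallel propensities, Kyte-Doolittle
GRAVY and the face-difference GRAVY of hexapeptides, and Ramachandran
(phi, psi) assignment against an explicit beta-region polygon.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.SeqUtils.ProtParamData import kd as KYTE_DOOLITTLE
from shapely.geometry import Point, Polygon

from .geometry import dihedral
from .structure_io import AMINO3, ChainCopy

# Broad (allowed) and strict (favored) beta/extended regions of the
# Ramachandran surface, as explicit polygons in (phi, psi) degrees. psi is
# taken modulo 360 into [-150, 210) so the region is simply connected.
BETA_ALLOWED = Polygon([(-180.0, 45.0), (-45.0, 45.0),
                        (-45.0, 210.0), (-180.0, 210.0)])
BETA_FAVORED = Polygon([(-170.0, 90.0), (-60.0, 90.0),
                        (-60.0, 180.0), (-170.0, 180.0)])


@dataclass
class DihedralRecord:
    chain_label: str
    residue_seq: int
    residue_name: str
    phi: float | None
    psi: float | None
    region: str  # "beta" | "other" | "unassigned-terminal"


def _unwrap_psi(psi: float) -> float:
    return psi + 360.0 if psi < -150.0 else psi


def in_beta_region(phi: float, psi: float, strict: bool = False) -> bool:
    poly = BETA_FAVORED if strict else BETA_ALLOWED
    return poly.covers(Point(phi, _unwrap_psi(psi)))


def beta_distance(phi: float, psi: float) -> float:
    """Wrap-aware Euclidean distance (degrees) from (phi, psi) to the
    allowed beta region; 0 when inside."""
    p0 = (phi, _unwrap_psi(psi))
    best = np.inf
    for dphi in (-360.0, 0.0, 360.0):
        for dpsi in (-360.0, 0.0, 360.0):
            d = BETA_ALLOWED.distance(Point(p0[0] + dphi, p0[1] + dpsi))
            best = min(best, d)
    return float(best)


def backbone_dihedrals(chain: ChainCopy, strict: bool = False
                       ) -> list[DihedralRecord]:
    """Standard phi/psi for every residue of a chain copy.

    Terminal residues (missing one angle) are reported as
    "unassigned-terminal"; residues with incomplete backbone are skipped.
    """
    res = chain.residues
    if len(res) < 3:
        raise ValueError("need >= 3 residues for dihedral analysis")
    out: list[DihedralRecord] = []
    for i, (name, seq, amap) in enumerate(res):
        if not {"N", "CA", "C"} <= amap.keys():
            continue
        phi = psi = None
        if i > 0 and "C" in res[i - 1][2]:
            phi = dihedral(chain.coords[res[i - 1][2]["C"]],
                           chain.coords[amap["N"]],
                           chain.coords[amap["CA"]],
                           chain.coords[amap["C"]])
        if i < len(res) - 1 and "N" in res[i + 1][2]:
            psi = dihedral(chain.coords[amap["N"]],
                           chain.coords[amap["CA"]],
                           chain.coords[amap["C"]],
                           chain.coords[res[i + 1][2]["N"]])
        if phi is None or psi is None:
            region = "unassigned-terminal"
        elif in_beta_region(phi, psi, strict=strict):
            region = "beta"
        else:
            region = "other"
        out.append(DihedralRecord(chain.label, seq, name, phi, psi, region))
    return out


def beta_fraction(records: list[DihedralRecord], strict: bool = False
                  ) -> float:
    """Fraction of assignable residues in the beta region."""
    assigned = [r for r in records if r.phi is not None and r.psi is not None]
    if not assigned:
        raise ValueError("no assignable residues")
    hits = sum(in_beta_region(r.phi, r.psi, strict=strict) for r in assigned)
    return hits / len(assigned)


def ramachandran_histogram(records: list[DihedralRecord],
                           bin_size: float = 4.0) -> pd.DataFrame:
    """2D (phi, psi) histogram with square bins (default 4 x 4 degrees).

    Returns a tidy table of occupied bins: phi_bin/psi_bin are the lower
    bin edges.
    """
    pts = [(r.phi, r.psi) for r in records
           if r.phi is not None and r.psi is not None]
    if not pts:
        raise ValueError("no assignable residues")
    edges = np.arange(-180.0, 180.0 + bin_size, bin_size)
    h, _, _ = np.histogram2d(*np.array(pts).T, bins=(edges, edges))
    ii, jj = np.nonzero(h)
    return pd.DataFrame({"phi_bin": edges[ii], "psi_bin": edges[jj],
                         "count": h[ii, jj].astype(int)})


def gravy(sequence: str) -> float:
    """Grand average of hydropathy (mean Kyte-Doolittle value)."""
    if not sequence:
        raise ValueError("empty sequence")
    try:
        return float(np.mean([KYTE_DOOLITTLE[c] for c in sequence.upper()]))
    except KeyError as e:
        raise ValueError(f"unknown residue {e.args[0]!r}") from None


def difference_gravy(hexapeptide: str) -> float:
    """|GRAVY(residues 1,3,5) - GRAVY(residues 2,4,6)| of a hexapeptide.

    The two odd/even residue sets are the two faces of an in-register
    sheet; the absolute value makes the result face-labeling independent.
    """
    if len(hexapeptide) != 6:
        raise ValueError("difference GRAVY is defined for hexapeptides")
    return abs(gravy(hexapeptide[0::2]) - gravy(hexapeptide[1::2]))


def composition_report(sequences: dict[str, str],
                       subsets: dict[str, str] | None = None
                       ) -> pd.DataFrame:
    """Residue counts, frequencies and propensities per subset.

    `sequences` maps structure id -> one-letter sequence; duplicates of an
    identical sequence are counted once. `subsets` optionally maps
    structure id -> label (e.g. "parallel"/"antiparallel"); the propensity
    of a subset is its frequency over the frequency in the whole set.
    """
    if not sequences:
        raise ValueError("empty structure set")
    uniq: dict[str, str] = {}
    for sid, seq in sequences.items():
        if seq not in uniq.values():
            uniq[sid] = seq
    labels = {sid: (subsets or {}).get(sid, "all") for sid in uniq}

    rows = []
    aas = sorted(set(AMINO3.values()))
    groups: dict[str, list[str]] = {"all": []}
    for sid, seq in uniq.items():
        groups["all"].append(seq)
        if labels[sid] != "all":
            groups.setdefault(labels[sid], []).append(seq)
    freq_all = None
    for label, seqs in groups.items():
        joined = "".join(seqs)
        counts = {aa: joined.count(aa) for aa in aas}
        total = sum(counts.values())
        if total == 0:
            continue
        freqs = {aa: c / total for aa, c in counts.items()}
        if label == "all":
            freq_all = freqs
        for aa in aas:
            rows.append({"subset": label, "residue": aa,
                         "count": counts[aa], "frequency": freqs[aa]})
    df = pd.DataFrame(rows)
    df["propensity"] = [
        (r.frequency / freq_all[r.residue]) if freq_all[r.residue] > 0
        else np.nan
        for r in df.itertuples()]
    return df
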