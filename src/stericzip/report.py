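"""End-to-end analysis pipeline and tabular reporting.

`analyze_structure` runs the full chain: load -> sanitize -> symmetry
expansion -> H-bond detection -> sheet assembly -> interface admission ->
descriptors -> wetness -> deduplication -> network classification, and
returns a JSON-serializable report. `summarize` aggregates per-structure
reports into database-level tables (class populations, composition,
parallel-vs-antiparallel descriptor means).
"""
from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .config import RunConfig, DEFAULT_CONFIG
from .interface_finder import (
    Rejection,
    admit_interface,
    classify_wetness,
    deduplicate,
    find_contacting_pairs,
)
from .quaternary_network import build_interface_graph, classify_network
from .sequence_stats import backbone_dihedrals, composition_report, gravy
from .sheet_topology import assemble_sheets, detect_backbone_hbonds
from .structure_io import CrystalModel, expand_symmetry, load_structure, sanitize

log = logging.getLogger("stericzip")


def _has_identity(sheet) -> bool:
    return any(s.is_identity for s in sheet.strands)


def analyze_structure(source: CrystalModel | str | Path,
                      config: RunConfig = DEFAULT_CONFIG,
                      descriptors: bool = True,
                      network: bool = True) -> dict:
    """Full per-structure analysis; see module docstring."""
    if isinstance(source, (str, Path)):
        model = load_structure(source)
    else:
        model = source
    model = sanitize(model)
    log.info("analyzing %s (%d atoms, %s)", model.name, len(model.atoms),
             model.spacegroup)
    lattice = expand_symmetry(model, config.expansion_radius,
                              config.max_copies)
    bonds = detect_backbone_hbonds(lattice, config.hbond_dmax,
                                   config.hbond_angle_min)
    sheets = assemble_sheets(lattice, bonds, config.min_hbonds_per_neighbor)
    pairs = find_contacting_pairs(sheets, config)

    observations = []
    rejections = []
    for i, j in pairs:
        if not (_has_identity(sheets[i]) or _has_identity(sheets[j])):
            continue
        try:
            res = admit_interface(sheets[i], sheets[j], config,
                                  compute_descriptors=descriptors)
        except ValueError as e:
            rejections.append({"pair": (i, j), "criterion": "error",
                               "detail": str(e)})
            continue
        if isinstance(res, Rejection):
            log.info("pair (%d,%d) rejected at criterion (%s): %s",
                     i, j, res.criterion, res.detail)
            rejections.append({"pair": (i, j), "criterion": res.criterion,
                               "detail": res.detail})
        else:
            classify_wetness(res, lattice, config)
            observations.append(res)
    unique = deduplicate(observations)

    report: dict = {
        "structure": model.name,
        "spacegroup": model.spacegroup,
        "cell_volume": round(model.cell_volume, 1),
        "n_chains_asu": len(model.chain_ids),
        "n_sheets": len(sheets),
        "sequences": {},
        "interfaces": [itf.as_dict() for itf in unique],
        "rejections": rejections,
        "config": config.metadata(),
    }
    identity = [c for c in lattice.copies if c.is_identity]
    for cp in identity:
        report["sequences"][cp.chain_id] = cp.sequence()
        try:
            report.setdefault("gravy", {})[cp.chain_id] = round(
                gravy(cp.sequence()), 3)
        except ValueError:
            pass
    # secondary structure summary over ASU chains
    beta = other = 0
    for cp in identity:
        if len(cp.residues) < 3:
            continue
        for rec in backbone_dihedrals(cp):
            if rec.region == "beta":
                beta += 1
            elif rec.region == "other":
                other += 1
    report["beta_fraction"] = (beta / (beta + other)
                               if beta + other else None)
    if network:
        ig = build_interface_graph(observations)
        report["network"] = classify_network(ig, config)
    return report


def interface_table(reports: list[dict]) -> pd.DataFrame:
    rows = []
    for rep in reports:
        for k, itf in enumerate(rep["interfaces"]):
            rows.append({"structure": rep["structure"], "interface": k,
                         **{key: itf[key] for key in
                            ("class", "arrangement", "pseudo", "oor",
                             "larks", "sides", "wet", "multiplicity",
                             "Sc", "Ab", "SDi")}})
    return pd.DataFrame(rows)


def summarize(reports: list[dict]) -> dict:
    """Database-level summary across per-structure reports."""
    table = interface_table(reports)
    summary: dict = {"n_structures": len(reports),
                     "n_interfaces": int(len(table))}
    if not table.empty:
        pops = table.groupby("class").size().to_dict()
        summary["class_populations"] = {str(k): int(v) for k, v in pops.items()}
        by_arr = table.groupby("arrangement")[["Sc", "Ab", "SDi"]].mean()
        summary["descriptor_means"] = {
            arr: {c: round(float(v), 3) for c, v in row.items()}
            for arr, row in by_arr.iterrows()}
        summary["mean_SDi"] = round(float(table["SDi"].mean()), 3)
        summary["wet_fraction"] = round(
            float((table["wet"] == "partially_wet").mean()), 3)
    seqs = {}
    arrs = {}
    for rep in reports:
        for cid, seq in rep.get("sequences", {}).items():
            sid = f"{rep['structure']}:{cid}"
            seqs[sid] = seq
            if rep["interfaces"]:
                arrs[sid] = rep["interfaces"][0]["arrangement"]
    if seqs:
        summary["composition"] = composition_report(seqs, arrs).to_dict(
            orient="records")
    betas = [rep["beta_fraction"] for rep in reports
             if rep.get("beta_fraction") is not None]
    if betas:
        summary["beta_fraction"] = round(float(np.mean(betas)), 4)
    return summary


def write_reports(reports: list[dict], out_dir: str | Path,
                  formats: tuple[str, ...] = ("csv", "json")) -> list[Path]:
    """Write per-structure JSON, the interface table and the summary."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    if "json" in formats:
        for rep in reports:
            p = out_dir / f"{rep['structure']}.json"
            p.write_text(json.dumps(rep, indent=1, sort_keys=True,
                                    default=_json_default))
            written.append(p)
        p = out_dir / "summary.json"
        p.write_text(json.dumps(summarize(reports), indent=1,
                                sort_keys=True, default=_json_default))
        written.append(p)
    if "csv" in formats:
        p = out_dir / "interfaces.csv"
        interface_table(reports).to_csv(p, index=False)
        written.append(p)
    return written


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, tuple):
        return list(o)
    raise TypeError(f"not JSON serializable: {type(o)}")
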