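"""Cross-experiment per-residue dossier assembly and structure annotation.

Joins exchange, model-free, denaturation, attenuation, RMSF and depth
results on ResidueID, derives consensus flags from configurable
thresholds, and writes structure-mappable outputs (flat TSV and a
B-factor-substituted PDB).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .peakio import ResidueID, StructureModel, write_structure

logger = logging.getLogger(__name__)

#: protection-factor class bounds; lower bound closed, i.e. P >= hi -> "high"
DEFAULT_PROTECTION_BOUNDS = (1.0e4, 1.0e5)

DEFAULT_THRESHOLDS = {
    "flexible_S2": 0.8,        # fitted S2 below this -> flexible
    "hotspot_A": 1.7,          # attenuation above this -> hotspot
    "protected_P": 1.0e4,      # protection factor at/above this -> protected
}


def protection_classes(results, bounds=DEFAULT_PROTECTION_BOUNDS) -> dict:
    """Three-way protection classification per residue.

    ``results`` is an iterable of objects with ``residue`` and ``P``
    attributes (or (ResidueID, P) pairs). Bounds are closed on the lower
    edge: P >= bounds[1] -> "high", bounds[0] <= P < bounds[1] -> "mid",
    P < bounds[0] -> "low".
    """
    lo, hi = bounds
    out = {}
    for item in results:
        rid, p = (item if isinstance(item, tuple)
                  else (item.residue, item.P))
        if not np.isfinite(p):
            out[rid] = "unclassified"
        elif p >= hi:
            out[rid] = "high"
        elif p >= lo:
            out[rid] = "mid"
        else:
            out[rid] = "low"
    return out


@dataclass
class ResidueDossier:
    residue: ResidueID
    P: float = math.nan
    dG_op: float = math.nan
    S2: float = math.nan
    C_half: float = math.nan
    A_i: float = math.nan
    rmsf: float = math.nan
    depth: float = math.nan
    flags: set = field(default_factory=set)


def assemble_dossiers(hx_results=(), mf_result=None, denat_fits=(),
                      atten_profile=None, rmsf_by_residue=None,
                      depth_by_residue=None, exchange_flags=None,
                      thresholds: Optional[dict] = None) -> list:
    """Join all per-residue results; the output residue set is exactly the
    union of the input residue sets (no invented rows)."""
    th = dict(DEFAULT_THRESHOLDS)
    th.update(thresholds or {})
    table: dict = {}

    def entry(rid: ResidueID) -> ResidueDossier:
        key = rid.seq_number
        if key not in table:
            table[key] = ResidueDossier(residue=rid)
        return table[key]

    for r in hx_results:
        d = entry(r.residue)
        d.P = r.P
        d.dG_op = r.dG_op
        if np.isfinite(r.P) and r.P >= th["protected_P"]:
            d.flags.add("protected")
    if mf_result is not None:
        for rid, s2 in zip(mf_result.residues, mf_result.S2):
            d = entry(rid)
            d.S2 = float(s2)
            if s2 < th["flexible_S2"]:
                d.flags.add("flexible")
    for f in denat_fits:
        if f.converged:
            entry(f.residue).C_half = f.C_half
    if atten_profile is not None:
        for rid, a in zip(atten_profile.residues, atten_profile.A):
            d = entry(rid)
            d.A_i = float(a)
            if np.isfinite(a) and a > th["hotspot_A"]:
                d.flags.add("hotspot")
    for rid, v in (rmsf_by_residue or {}).items():
        entry(rid).rmsf = float(v)
    for rid, v in (depth_by_residue or {}).items():
        entry(rid).depth = float(v)
    for rid, flagged in (exchange_flags or {}).items():
        if flagged:
            entry(rid).flags.add("exchange-affected")
    return [table[k] for k in sorted(table)]


def dossiers_to_frame(dossiers: Sequence[ResidueDossier]) -> pd.DataFrame:
    return pd.DataFrame(
        {"residue": [d.residue.label for d in dossiers],
         "seq_number": [d.residue.seq_number for d in dossiers],
         "P": [d.P for d in dossiers],
         "dG_op": [d.dG_op for d in dossiers],
         "S2": [d.S2 for d in dossiers],
         "C_half": [d.C_half for d in dossiers],
         "A_i": [d.A_i for d in dossiers],
         "rmsf": [d.rmsf for d in dossiers],
         "depth": [d.depth for d in dossiers],
         "flags": [",".join(sorted(d.flags)) for d in dossiers]})


def write_structure_annotation(path_prefix, dossiers, structure: StructureModel,
                               column: str = "dG_op") -> dict:
    """Write a per-residue scalar as B-factors (PDB) and a flat TSV.

    Residues with no datum get the neutral value 0 with mask=0; structure
    residues absent from the dossiers are returned as unmapped.
    """
    by_seq = {d.residue.seq_number: d for d in dossiers}
    values, mask = [], []
    unmapped = []
    for atom in structure.atoms:
        d = by_seq.get(atom.residue.seq_number)
        v = getattr(d, column) if d is not None else math.nan
        if d is None or not np.isfinite(v):
            values.append(0.0)
            mask.append(0)
        else:
            values.append(float(v))
            mask.append(1)
    seen = {a.residue.seq_number for a in structure.atoms}
    unmapped = sorted(seen - set(by_seq))
    if unmapped:
        logger.warning("%d structure residues have no dossier entry",
                       len(unmapped))
    pdb_path = f"{path_prefix}.pdb"
    tsv_path = f"{path_prefix}.tsv"
    write_structure(pdb_path, structure, bfactors=np.array(values),
                    remarks=[f"B-factor column: {column}"])
    frame = dossiers_to_frame(dossiers)
    frame["mask"] = [1 if np.isfinite(getattr(d, column)) else 0
                     for d in dossiers]
    frame.to_csv(tsv_path, sep="\t", index=False)
    return {"pdb": pdb_path, "tsv": tsv_path, "unmapped": unmapped}


def summary_json(path, tau_c_ns=None, mean_S2=None, mean_C_half=None,
                 hotspots=(), extra=None) -> None:
    """Global scalars in one machine-readable file."""
    payload = {"tau_c_ns": tau_c_ns, "mean_S2": mean_S2,
               "mean_C_half": mean_C_half,
               "hotspots": [r.label for r in hotspots]}
    payload.update(extra or {})
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
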