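"""Bioactivity record curation: filter, deduplicate, convert, aggregate.

The input is a flat ChEMBL-style activity table (one row per reported
measurement, dirty by design). Curation retains quantitative IC50/EC50
records, merges duplicated reports, converts concentrations to
pIC50 = -log10(value[nM] / 1e9), and aggregates to one value per
standardized molecule (InChIKey) x target pair. Pairs with fewer than five
measurements are kept only when the standard error of the mean is at most
0.3 pIC50 units; pairs with five or more are always averaged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .proteins import ResidueProfile
from .standardize import StandardizedMolecule, standardize, structural_filters

log = logging.getLogger(__name__)

REQUIRED_COLUMNS = [
    "molecule_chembl_id",
    "target_chembl_id",
    "document_chembl_id",
    "canonical_smiles",
    "standard_type",
    "standard_relation",
    "standard_value",
    "standard_units",
]

ALLOWED_TYPES = {"IC50", "EC50"}

#: multiplicative factor that brings a unit onto the nM scale
UNIT_TO_NM = {
    "nM": 1.0,
    "uM": 1e3,
    "µM": 1e3,
    "μM": 1e3,
    "mM": 1e6,
    "M": 1e9,
    "pM": 1e-3,
}

SEM_THRESHOLD = 0.3
SEM_MIN_N = 5


def _require_columns(records: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"activity table missing columns: {missing}")


def filter_records(records: pd.DataFrame) -> pd.DataFrame:
    """Keep quantitative IC50/EC50 records and normalize values to nM.

    Drops rows with missing type/relation/units, types outside
    {IC50, EC50}, relations other than "=", units not convertible to nM,
    and non-positive values. Surviving rows have ``standard_value`` in nM
    and ``standard_units == "nM"``.
    """
    _require_columns(records)
    df = records.copy()
    df = df.dropna(subset=["standard_type", "standard_relation", "standard_units"])
    df = df[df["standard_type"].isin(ALLOWED_TYPES)]
    df = df[df["standard_relation"] == "="]
    df = df[df["standard_units"].isin(UNIT_TO_NM)]
    df = df[pd.to_numeric(df["standard_value"], errors="coerce").notna()]
    df["standard_value"] = df["standard_value"].astype(float) * df[
        "standard_units"
    ].map(UNIT_TO_NM)
    df["standard_units"] = "nM"
    df = df[df["standard_value"] > 0]
    return df.reset_index(drop=True)


def deduplicate(records: pd.DataFrame) -> pd.DataFrame:
    """Merge duplicated reports of the same measurement.

    Two passes: (1) rows sharing (molecule, target, document) come from one
    source and are merged into a single record (mean value); (2) rows
    sharing (molecule, target, exact standard value) across documents are
    one measurement cited repeatedly and collapse to the first occurrence.
    """
    _require_columns(records)
    df = records.copy()
    keys1 = ["molecule_chembl_id", "target_chembl_id", "document_chembl_id"]
    agg = {c: "first" for c in df.columns if c not in keys1}
    agg["standard_value"] = "mean"
    df = df.groupby(keys1, sort=False, as_index=False).agg(agg)
    df = df[records.columns]
    keys2 = ["molecule_chembl_id", "target_chembl_id", "standard_value"]
    df = df.groupby(keys2, sort=False, as_index=False).first()
    return df[records.columns].reset_index(drop=True)


def to_pic50(standard_value_nm: float | np.ndarray) -> float | np.ndarray:
    """pIC50 = -log10(value[nM] / 1e9); defined only for positive values."""
    arr = np.asarray(standard_value_nm, dtype=float)
    if np.any(arr <= 0):
        raise ValueError("standard_value must be positive to convert to pIC50")
    out = -np.log10(arr / 1e9)
    return float(out) if np.isscalar(standard_value_nm) else out


@dataclass
class AggregationResult:
    datapoints: pd.DataFrame  # inchikey, target_id, pic50, n_source_records
    dropped_pairs: pd.DataFrame  # inchikey, target_id, n, sem


def aggregate(pairs: pd.DataFrame) -> AggregationResult:
    """One pIC50 per (inchikey, target) pair.

    ``pairs`` needs columns inchikey, target_id, pic50. SEM uses the sample
    standard deviation (n-1 denominator); singletons have SEM 0 by
    convention and always pass. Pairs with n < 5 and SEM > 0.3 are removed
    entirely; n >= 5 pairs are averaged unconditionally.
    """
    for col in ("inchikey", "target_id", "pic50"):
        if col not in pairs.columns:
            raise ValueError(f"aggregate input missing column {col!r}")
    kept_rows, dropped_rows = [], []
    grouped = pairs.groupby(["inchikey", "target_id"], sort=False)
    for (ikey, target), grp in grouped:
        vals = grp["pic50"].to_numpy(dtype=float)
        n = len(vals)
        sem = 0.0 if n == 1 else float(np.std(vals, ddof=1) / np.sqrt(n))
        if n < SEM_MIN_N and sem > SEM_THRESHOLD:
            dropped_rows.append(
                {"inchikey": ikey, "target_id": target, "n": n, "sem": sem}
            )
            continue
        kept_rows.append(
            {
                "inchikey": ikey,
                "target_id": target,
                "pic50": float(np.mean(vals)),
                "n_source_records": n,
            }
        )
    datapoints = pd.DataFrame(
        kept_rows, columns=["inchikey", "target_id", "pic50", "n_source_records"]
    )
    dropped = pd.DataFrame(dropped_rows, columns=["inchikey", "target_id", "n", "sem"])
    return AggregationResult(datapoints=datapoints, dropped_pairs=dropped)


@dataclass
class PocketConflict:
    targets: tuple[str, str]
    n_shared_molecules: int
    max_abs_difference: float
    suggest_drop: str


def detect_pocket_conflicts(
    datapoints: pd.DataFrame,
    profiles: Sequence[ResidueProfile],
    tolerance: float = 0.5,
) -> list[PocketConflict]:
    """Flag target pairs with identical binding-site residues but
    conflicting activities for shared molecules.

    Identical pockets make the targets indistinguishable to the model, so
    discordant shared activities (|difference| > ``tolerance`` pIC50 units
    for any shared molecule) are irreconcilable. The caller decides which
    member to drop; the suggestion is the one with fewer datapoints.
    """
    by_id = {p.target_id: p for p in profiles}
    present = [t for t in datapoints["target_id"].unique() if t in by_id]
    conflicts = []
    for t1, t2 in combinations(present, 2):
        if by_id[t1].residue_string() != by_id[t2].residue_string():
            continue
        d1 = datapoints[datapoints["target_id"] == t1].set_index("inchikey")["pic50"]
        d2 = datapoints[datapoints["target_id"] == t2].set_index("inchikey")["pic50"]
        shared = d1.index.intersection(d2.index)
        if len(shared) == 0:
            continue
        diff = (d1.loc[shared] - d2.loc[shared]).abs()
        if float(diff.max()) > tolerance:
            suggest = t1 if len(d1) < len(d2) else t2
            conflicts.append(
                PocketConflict(
                    targets=(t1, t2),
                    n_shared_molecules=int(len(shared)),
                    max_abs_difference=float(diff.max()),
                    suggest_drop=suggest,
                )
            )
    return conflicts


@dataclass
class CurationResult:
    """Curated datapoints plus the per-stage accounting."""

    datapoints: pd.DataFrame  # inchikey, target_id, pic50, n_source_records
    molecules: pd.DataFrame  # inchikey, standardized_smiles, molecule_ids
    report: dict = field(default_factory=dict)


def curate(
    records: pd.DataFrame,
    *,
    blocklist: Iterable[str] | None = None,
    profiles: Sequence[ResidueProfile] | None = None,
    conflict_tolerance: float = 0.5,
    drop_conflicts: bool = True,
) -> CurationResult:
    """Full curation chain: filter, dedup, standardize, filter structures,
    convert, aggregate, and optionally resolve identical-pocket conflicts.

    The report logs the record count surviving each stage and the reasons
    for removals, so a run can be audited end to end.
    """
    _require_columns(records)
    blockset = set(blocklist) if blocklist else set()
    report: dict = {"n_input_records": int(len(records))}

    df = filter_records(records)
    report["n_after_record_filters"] = int(len(df))
    df = deduplicate(df)
    report["n_after_dedup"] = int(len(df))
    if blockset:
        df = df[~df["molecule_chembl_id"].isin(blockset)].reset_index(drop=True)
    report["n_after_blocklist"] = int(len(df))

    # one standardization per unique molecule id (first SMILES wins)
    first_smiles = (
        df.groupby("molecule_chembl_id", sort=False)["canonical_smiles"].first()
    )
    std_map: dict[str, StandardizedMolecule] = {}
    parse_failures, filter_reasons = [], {}
    for mol_id, smi in first_smiles.items():
        try:
            sm = standardize(smi)
        except Exception:
            parse_failures.append(mol_id)
            continue
        verdict = structural_filters(sm)
        if not verdict.keep:
            filter_reasons[mol_id] = verdict.reason
            continue
        std_map[mol_id] = sm
    report["n_molecules_parse_failed"] = len(parse_failures)
    report["n_molecules_filtered"] = len(filter_reasons)
    report["structural_filter_reasons"] = {
        r: sum(1 for v in filter_reasons.values() if v == r)
        for r in sorted(set(filter_reasons.values()))
    }

    df = df[df["molecule_chembl_id"].isin(std_map)].reset_index(drop=True)
    report["n_after_structural_filters"] = int(len(df))

    df["inchikey"] = df["molecule_chembl_id"].map(
        lambda m: std_map[m].inchikey
    )
    df["pic50"] = to_pic50(df["standard_value"].to_numpy())
    df = df.rename(columns={"target_chembl_id": "target_id"})

    agg = aggregate(df[["inchikey", "target_id", "pic50"]])
    report["n_pairs_dropped_sem"] = int(len(agg.dropped_pairs))
    datapoints = agg.datapoints
    report["n_datapoints"] = int(len(datapoints))

    excluded_targets: list[str] = []
    if profiles is not None:
        conflicts = detect_pocket_conflicts(
            datapoints, profiles, tolerance=conflict_tolerance
        )
        report["pocket_conflicts"] = [
            {
                "targets": list(c.targets),
                "n_shared_molecules": c.n_shared_molecules,
                "max_abs_difference": c.max_abs_difference,
                "suggest_drop": c.suggest_drop,
            }
            for c in conflicts
        ]
        if drop_conflicts:
            excluded_targets = sorted({c.suggest_drop for c in conflicts})
            datapoints = datapoints[
                ~datapoints["target_id"].isin(excluded_targets)
            ].reset_index(drop=True)
    report["excluded_targets"] = excluded_targets
    report["n_final_datapoints"] = int(len(datapoints))
    report["n_unique_molecules"] = int(datapoints["inchikey"].nunique())

    mol_rows = []
    used_keys = set(datapoints["inchikey"])
    by_key: dict[str, list[str]] = {}
    for mol_id, sm in std_map.items():
        by_key.setdefault(sm.inchikey, []).append(mol_id)
    for ikey in sorted(used_keys):
        ids = sorted(by_key.get(ikey, []))
        smi = std_map[ids[0]].standardized_smiles if ids else ""
        mol_rows.append(
            {"inchikey": ikey, "standardized_smiles": smi, "molecule_ids": ";".join(ids)}
        )
    molecules = pd.DataFrame(
        mol_rows, columns=["inchikey", "standardized_smiles", "molecule_ids"]
    )
    return CurationResult(datapoints=datapoints, molecules=molecules, report=report)
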