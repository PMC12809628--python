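"""Independent brute-force oracles used to check pipeline outputs.

Everything here is deliberately written with plain Python loops and
elementary formulas (no pandas groupby, no sklearn, no RDKit descriptor
calls) so the checks do not share code paths with the implementation.
"""

from __future__ import annotations

import math

# CRC-style standard atomic weights, enough for the drug-like test set
ATOMIC_WEIGHTS = {
    "H": 1.008, "B": 10.81, "C": 12.011, "N": 14.007, "O": 15.999,
    "F": 18.998, "Na": 22.990, "P": 30.974, "S": 32.06, "Cl": 35.45,
    "Br": 79.904, "I": 126.904,
}


def formula_mass(mol) -> float:
    """Molecular weight from atomic composition (explicit + implicit H)."""
    total = 0.0
    for atom in mol.GetAtoms():
        total += ATOMIC_WEIGHTS[atom.GetSymbol()]
        total += atom.GetTotalNumHs() * ATOMIC_WEIGHTS["H"]
    return total


def oracle_filter(records: list[dict]) -> list[dict]:
    """Record filter: quantitative IC50/EC50 with convertible units, in nM."""
    unit_factor = {"nM": 1.0, "uM": 1e3, "µM": 1e3, "μM": 1e3, "mM": 1e6,
                   "M": 1e9, "pM": 1e-3}
    out = []
    for rec in records:
        t, r, u, v = (rec.get("standard_type"), rec.get("standard_relation"),
                      rec.get("standard_units"), rec.get("standard_value"))
        if t is None or r is None or u is None or v is None:
            continue
        if isinstance(u, float) and math.isnan(u):
            continue
        if t not in ("IC50", "EC50") or r != "=" or u not in unit_factor:
            continue
        v = float(v) * unit_factor[u]
        if not (v > 0):
            continue
        new = dict(rec)
        new["standard_value"] = v
        new["standard_units"] = "nM"
        out.append(new)
    return out


def oracle_dedup(records: list[dict]) -> list[dict]:
    """Two-pass duplicate merge: same source, then same value across docs."""
    by_source: dict[tuple, list[dict]] = {}
    order: list[tuple] = []
    for rec in records:
        key = (rec["molecule_chembl_id"], rec["target_chembl_id"],
               rec["document_chembl_id"])
        if key not in by_source:
            by_source[key] = []
            order.append(key)
        by_source[key].append(rec)
    merged = []
    for key in order:
        grp = by_source[key]
        rec = dict(grp[0])
        rec["standard_value"] = sum(g["standard_value"] for g in grp) / len(grp)
        merged.append(rec)
    seen_values: set[tuple] = set()
    out = []
    for rec in merged:
        key = (rec["molecule_chembl_id"], rec["target_chembl_id"],
               rec["standard_value"])
        if key in seen_values:
            continue
        seen_values.add(key)
        out.append(rec)
    return out


def oracle_aggregate(
    pairs: list[tuple[str, str, float]],
    *,
    sem_threshold: float = 0.3,
    min_n: int = 5,
) -> dict[tuple[str, str], float]:
    """SEM-gated mean per (inchikey, target): sample sd, n-1 denominator."""
    groups: dict[tuple[str, str], list[float]] = {}
    for ikey, target, pic in pairs:
        groups.setdefault((ikey, target), []).append(float(pic))
    out = {}
    for key, vals in groups.items():
        n = len(vals)
        mean = sum(vals) / n
        if n == 1:
            sem = 0.0
        else:
            var = sum((v - mean) ** 2 for v in vals) / (n - 1)
            sem = math.sqrt(var) / math.sqrt(n)
        if n < min_n and sem > sem_threshold:
            continue
        out[key] = mean
    return out
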