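"""ChEMBL-like synthetic bioactivity data with known ground truth.

The generator emulates the structure of a public SLC5-inhibitor extract so
curation, modeling, and interpretation are exercisable offline:

* congeneric series built from a small embedded library of drug-like cores
  (aryl-glycoside-like and diaryl-pyrazole-like chemotypes, among others)
  decorated with halogen/alkyl/hydroxy/alkoxy substituents, so each series
  contains positional-isomer pairs;
* a molecule's intrinsic potency is Free-Wilson-like: a per-scaffold base
  level plus additive substituent contributions (learnable from structure),
  with a designated fraction of molecules given a large activity cliff;
* a per-target potency offset driven by designated *causal* binding-site
  positions: effect size times the Euclidean (Z1, Z2, Z3) distance between
  the target's residue and the reference target's residue at that position;
* an active-biased pIC50 distribution (most values above 6), record
  duplication under both dedup regimes (same document; same value in a
  different document, optionally perturbed when noise is on), and a
  censored fraction with relation ">" or missing units to exercise filters.

The default eight synthetic targets reuse the real SLC5 alignment's sixteen
position labels. They are organized as two lineages that differ at all
fourteen non-causal positions, while the two causal positions (286, V/L;
460, S/T) vary independently of lineage. Non-causal positions therefore
carry no activity information — they only encode lineage — which is what
lets tests attribute recovered importance unambiguously.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem

from .proteins import Position, ResidueProfile, ZScaleTable, sandberg_zscales

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


class ConfigurationError(ValueError):
    """A SyntheticSpec field is out of range; the message names the field."""


# --------------------------------------------------------------------------
# scaffold library
# --------------------------------------------------------------------------

#: drug-like core templates; {R1}/{R2} are the series substitution sites,
#: {R3} is a scaffold-variant site fixed within a series.
SCAFFOLD_CORES = [
    # aryl C-glycoside diarylmethane (gliflozin-like chemotype)
    "OCC1OC(c2ccc{R1}c(Cc3ccc{R2}c{R3}c3)c2)C(O)C(O)C1O",
    # aryl O-glycoside
    "OCC1OC(Oc2ccc{R1}c(Cc3ccc{R2}c{R3}c3)c2)C(O)C(O)C1O",
    # diaryl pyrazole chemotype
    "Cc1cc(-c2ccc{R1}cc2)n(-c2ccc{R2}c{R3}c2)n1",
    # benzanilide
    "O=C(Nc1ccc{R1}cc1)c1ccc{R2}c{R3}c1",
    # sulfonanilide
    "O=S(=O)(Nc1ccc{R1}cc1)c1ccc{R2}c{R3}c1",
    # benzylic alcohol diarylmethane
    "OCc1ccc{R1}c(Cc2ccc{R2}c{R3}c2)c1",
    # arylpiperazine amide
    "O=C(c1ccc{R1}cc1)N1CCN(c2ccc{R2}c{R3}c2)CC1",
    # pyrazole carboxanilide
    "Cc1nn(-c2ccc{R1}cc2)cc1C(=O)Nc1ccc{R2}c{R3}c1",
    # cyclohexyl ether diarylmethane
    "OC1CCC(Oc2ccc{R1}c(Cc3ccc{R2}c{R3}c3)c2)CC1",
    # aryl benzoate
    "O=C(Oc1ccc{R1}cc1)c1ccc{R2}c{R3}c1",
    # phenylacetanilide
    "O=C(Cc1ccc{R1}cc1)Nc1ccc{R2}c{R3}c1",
    # biaryl ether benzonitrile
    "N#Cc1ccc(-c2ccc{R1}cc2)c(Oc2ccc{R2}c{R3}c2)c1",
]

#: enumerated decorations: H, halogens, short alkyl, hydroxy, methoxy, CF3
SUBSTITUENTS = ["", "(F)", "(Cl)", "(Br)", "(C)", "(CC)", "(O)", "(OC)", "(C(F)(F)F)"]

#: fixed {R3} decoration distinguishing scaffold variants that share a core
VARIANT_TOKENS = ["", "(C)", "(F)", "(OC)", "(Cl)"]

MAX_SCAFFOLDS = len(SCAFFOLD_CORES) * len(VARIANT_TOKENS)
MAX_SERIES_SIZE = len(SUBSTITUENTS) ** 2

# potency model constants (pIC50 units)
BASE_PIC_MEAN = 6.0
BASE_PIC_SD = 0.6
SUB_EFFECT_SD = 0.35
SITE_ADJUST_SD = 0.10
DUP_PERTURB_SD = 0.05
PROB_UNITS_UM = 0.10
PROB_TYPE_EC50 = 0.20
TARGETS_PER_MOLECULE = ((1, 2, 3), (0.30, 0.45, 0.25))


# --------------------------------------------------------------------------
# default synthetic target panel
# --------------------------------------------------------------------------

_POSITION_NUMBERS = [
    (79, 88), (87, 96), (95, 106), (98, 109), (102, 113), (153, 164),
    (157, 168), (274, 300), (283, 309), (286, 312), (287, 313), (290, 316),
    (453, 481), (454, 482), (457, 485), (460, 488),
]

#: per-position (lineage-A residue, lineage-B residue); the two causal
#: positions instead vary with their own independent bits
_LINEAGE_RESIDUES = {
    79: ("G", "N"), 87: ("T", "S"), 95: ("V", "I"), 98: ("F", "Y"),
    102: ("A", "G"), 153: ("T", "L"), 157: ("V", "A"), 274: ("L", "M"),
    283: ("L", "M"), 287: ("S", "T"), 290: ("Y", "H"), 453: ("F", "I"),
    454: ("D", "H"), 457: ("Q", "E"),
}
_CAUSAL_RESIDUES = {286: ("V", "L"), 460: ("S", "T")}

DEFAULT_CAUSAL_POSITIONS = {"7VSI:286": 1.0, "7VSI:460": 0.5}
DEFAULT_TARGET_WEIGHTS = (4, 3, 2, 2, 4, 3, 2, 2)


def default_targets() -> list[ResidueProfile]:
    """Eight synthetic targets over the sixteen SLC5 alignment positions.

    Target index bits: bit 0 flips the residue at 286, bit 1 at 460, bit 2
    flips the lineage (all fourteen non-causal positions at once).
    """
    positions = [Position(pdb=p, msa=m) for p, m in _POSITION_NUMBERS]
    profiles = []
    for idx in range(8):
        b0, b1, b2 = idx & 1, (idx >> 1) & 1, (idx >> 2) & 1
        residues = {}
        for pos in positions:
            if pos.pdb == 286:
                residues[pos] = _CAUSAL_RESIDUES[286][b0]
            elif pos.pdb == 460:
                residues[pos] = _CAUSAL_RESIDUES[460][b1]
            else:
                residues[pos] = _LINEAGE_RESIDUES[pos.pdb][b2]
        profiles.append(
            ResidueProfile(target_id=f"SYNT{idx + 1:03d}", residues=residues)
        )
    return profiles


# --------------------------------------------------------------------------
# spec and ground truth
# --------------------------------------------------------------------------


@dataclass
class SyntheticSpec:
    """Study conditions for one synthetic dataset."""

    n_scaffolds: int = 25
    series_size: int = 30
    targets: list[ResidueProfile] = field(default_factory=default_targets)
    causal_positions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CAUSAL_POSITIONS)
    )
    cliff_fraction: float = 0.04
    cliff_delta: float = 3.0
    noise_sd: float = 0.3
    duplicate_rate: float = 0.10
    censored_fraction: float = 0.05
    target_weights: Sequence[float] | None = DEFAULT_TARGET_WEIGHTS
    seed: int = 0

    def validate(self) -> None:
        if not 1 <= self.n_scaffolds <= MAX_SCAFFOLDS:
            raise ConfigurationError(
                f"n_scaffolds must be in [1, {MAX_SCAFFOLDS}], got {self.n_scaffolds}"
            )
        if not 1 <= self.series_size <= MAX_SERIES_SIZE:
            raise ConfigurationError(
                f"series_size must be in [1, {MAX_SERIES_SIZE}], got {self.series_size}"
            )
        if not self.targets:
            raise ConfigurationError("targets must contain at least one profile")
        for name, val in [
            ("cliff_fraction", self.cliff_fraction),
            ("duplicate_rate", self.duplicate_rate),
            ("censored_fraction", self.censored_fraction),
        ]:
            if not 0.0 <= val <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {val}")
        if self.noise_sd < 0:
            raise ConfigurationError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.cliff_delta < 0:
            raise ConfigurationError(f"cliff_delta must be >= 0, got {self.cliff_delta}")
        if self.target_weights is not None and len(self.target_weights) != len(
            self.targets
        ):
            raise ConfigurationError(
                "target_weights must have one weight per target "
                f"({len(self.target_weights)} weights, {len(self.targets)} targets)"
            )
        labels = {p.label: p for p in self.targets[0].positions}
        for lab in self.causal_positions:
            if lab not in labels:
                raise ConfigurationError(
                    f"causal_positions: {lab!r} is not a position of the target profiles"
                )
        for prof in self.targets:
            for lab in self.causal_positions:
                if labels[lab] not in prof.residues:
                    raise ConfigurationError(
                        f"causal_positions: target {prof.target_id!r} lacks {lab!r}"
                    )


@dataclass
class GroundTruth:
    """What the generator planted, keyed by molecule-target pair.

    ``pairs`` has one row per emitted unique pair with the noiseless pIC50
    (``pic50_true``) and the value actually encoded in the records
    (``pic50_measured``; equal to the truth when ``noise_sd == 0``).
    """

    pairs: pd.DataFrame  # molecule_id, target_id, smiles, pic50_true, pic50_measured
    effects: dict[str, float]
    cliff_molecules: list[str]
    cliff_partners: dict[str, str]

    def to_json(self, path) -> None:
        payload = {
            "pairs": self.pairs.to_dict(orient="list"),
            "effects": self.effects,
            "cliff_molecules": self.cliff_molecules,
            "cliff_partners": self.cliff_partners,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            pairs=pd.DataFrame(payload["pairs"]),
            effects=payload["effects"],
            cliff_molecules=payload["cliff_molecules"],
            cliff_partners=payload["cliff_partners"],
        )


# --------------------------------------------------------------------------
# series construction
# --------------------------------------------------------------------------


def _series_combos(series_size: int, rng: np.random.Generator) -> list[tuple[str, str]]:
    """Ordered substituent pairs for one series, arranged so that swapped
    (positional-isomer) pairs stay adjacent through the shuffle."""
    n = len(SUBSTITUENTS)
    blocks = [
        [(SUBSTITUENTS[i], SUBSTITUENTS[j]), (SUBSTITUENTS[j], SUBSTITUENTS[i])]
        for i in range(n)
        for j in range(i + 1, n)
    ]
    rng.shuffle(blocks)
    diag = [[(s, s)] for s in SUBSTITUENTS]
    flat = [c for b in blocks for c in b] + [c for b in diag for c in b]
    return flat


def _scaffold_template(scaffold_index: int) -> tuple[str, str]:
    core = SCAFFOLD_CORES[scaffold_index % len(SCAFFOLD_CORES)]
    variant = VARIANT_TOKENS[
        (scaffold_index // len(SCAFFOLD_CORES)) % len(VARIANT_TOKENS)
    ]
    return core, variant


def _build_series(
    scaffold_index: int, series_size: int, seed: int
) -> list[tuple[str, tuple[str, str]]]:
    """(canonical SMILES, substituent combo) for one congeneric series."""
    if series_size < 1:
        raise ValueError("series_size must be >= 1")
    core, variant = _scaffold_template(scaffold_index)
    rng = np.random.default_rng([int(seed) % (2**31), scaffold_index, 11])
    out, seen = [], set()
    for r1, r2 in _series_combos(series_size, rng):
        smi = core.format(R1=r1, R2=r2, R3=variant)
        mol = Chem.MolFromSmiles(smi)
        if mol is None:  # pragma: no cover - library templates all parse
            continue
        canon = Chem.MolToSmiles(mol)
        if canon in seen:
            continue
        seen.add(canon)
        out.append((canon, (r1, r2)))
        if len(out) == series_size:
            break
    return out


def generate_series_smiles(
    scaffold_index: int, series_size: int, seed: int
) -> list[str]:
    """Valid SMILES of one congeneric series sharing a common core.

    Members are decorations of the same scaffold; whenever the series has
    more than one member it contains at least one positional-isomer pair
    (the same substituent attached at the two alternative sites).
    """
    return [smi for smi, _ in _build_series(scaffold_index, series_size, seed)]


# --------------------------------------------------------------------------
# dataset generation
# --------------------------------------------------------------------------


def _target_offsets(
    spec: SyntheticSpec, ztable: ZScaleTable
) -> dict[str, float]:
    """Per-target potency offset: sum over causal positions of
    effect x Z-scale distance to the reference (first) target's residue."""
    ref = spec.targets[0]
    labels = {p.label: p for p in ref.positions}
    offsets = {}
    for prof in spec.targets:
        total = 0.0
        for lab, eff in spec.causal_positions.items():
            pos = labels[lab]
            total += eff * ztable.distance(prof.residues[pos], ref.residues[pos])
        offsets[prof.target_id] = total
    return offsets


def generate_dataset(
    spec: SyntheticSpec, ztable: ZScaleTable | None = None
) -> tuple[pd.DataFrame, GroundTruth]:
    """Emit a ChEMBL-like activity table plus the planted ground truth.

    The true pIC50 of molecule m against target t is
    ``base(scaffold) + substituent contributions + cliff term +
    sum over causal positions of effect x Z-distance(t, reference)``,
    with Gaussian noise of ``spec.noise_sd`` added to the measured value.
    ``standard_value`` is emitted in nM (occasionally uM) via the inverse
    of the pIC50 transform.
    """
    spec.validate()
    ztable = ztable or sandberg_zscales()
    rng = np.random.default_rng(int(spec.seed) % (2**31))
    offsets = _target_offsets(spec, ztable)
    target_ids = [p.target_id for p in spec.targets]
    n_targets = len(target_ids)
    if spec.target_weights is None:
        weights = np.full(n_targets, 1.0 / n_targets)
    else:
        weights = np.asarray(spec.target_weights, dtype=float)
        weights = weights / weights.sum()

    molecules: list[dict] = []  # molecule_id, smiles, potency, is_cliff, partner
    for s in range(spec.n_scaffolds):
        series = _build_series(s, spec.series_size, spec.seed)
        base = rng.normal(BASE_PIC_MEAN, BASE_PIC_SD)
        sub_eff = {tok: rng.normal(0.0, SUB_EFFECT_SD) for tok in SUBSTITUENTS}
        site_adj = {
            (site, tok): rng.normal(0.0, SITE_ADJUST_SD)
            for site in (0, 1)
            for tok in SUBSTITUENTS
        }
        members = []
        combo_index = {}
        for m, (smi, combo) in enumerate(series):
            potency = (
                base
                + sub_eff[combo[0]]
                + sub_eff[combo[1]]
                + site_adj[(0, combo[0])]
                + site_adj[(1, combo[1])]
            )
            mol_id = f"SYNMOL{s:02d}{m:03d}"
            members.append(
                {
                    "molecule_id": mol_id,
                    "smiles": smi,
                    "combo": combo,
                    "potency": potency,
                    "is_cliff": False,
                    "partner": None,
                }
            )
            combo_index[combo] = m

        # plant activity cliffs on members whose positional isomer is present
        frac = spec.cliff_fraction * len(members)
        n_cliff = int(frac) + int(rng.random() < frac - int(frac))
        candidates = [
            m
            for m in range(len(members))
            if members[m]["combo"][0] != members[m]["combo"][1]
            and members[m]["combo"][::-1] in combo_index
        ]
        chosen: list[int] = []
        for m in rng.permutation(len(candidates)):
            if len(chosen) >= n_cliff:
                break
            idx = candidates[int(m)]
            partner = combo_index[members[idx]["combo"][::-1]]
            if partner in chosen:
                continue
            chosen.append(idx)
            members[idx]["is_cliff"] = True
            members[idx]["potency"] -= spec.cliff_delta
            members[idx]["partner"] = members[partner]["molecule_id"]
        molecules.extend(members)

    # assign each molecule to a target subset (cliff partners share targets,
    # as congeneric pairs are typically assayed side by side)
    ks, kp = TARGETS_PER_MOLECULE
    assignment: dict[str, list[str]] = {}
    for mol in molecules:
        k = min(int(rng.choice(ks, p=kp)), n_targets)
        picked = rng.choice(n_targets, size=k, replace=False, p=weights)
        assignment[mol["molecule_id"]] = [target_ids[i] for i in sorted(picked)]
    by_id = {m["molecule_id"]: m for m in molecules}
    for mol in molecules:
        if mol["is_cliff"] and mol["partner"] in assignment:
            assignment[mol["molecule_id"]] = list(assignment[mol["partner"]])

    pair_rows, records = [], []
    for mol in molecules:
        mol_id = mol["molecule_id"]
        scaffold = int(mol_id[6:8])
        doc = f"SYNDOC{scaffold:04d}"
        alt_doc = f"SYNDOC9{scaffold:03d}"
        for target in assignment[mol_id]:
            true_pic = mol["potency"] + offsets[target]
            noise = rng.normal(0.0, spec.noise_sd) if spec.noise_sd > 0 else 0.0
            measured = true_pic + noise
            pair_rows.append(
                {
                    "molecule_id": mol_id,
                    "target_id": target,
                    "smiles": mol["smiles"],
                    "pic50_true": true_pic,
                    "pic50_measured": measured,
                }
            )

            def emit(pic: float, document: str) -> dict:
                value_nm = 1e9 * 10.0 ** (-pic)
                units = "nM"
                if rng.random() < PROB_UNITS_UM:
                    value_nm, units = value_nm / 1e3, "uM"
                stype = "EC50" if rng.random() < PROB_TYPE_EC50 else "IC50"
                return {
                    "molecule_chembl_id": mol_id,
                    "target_chembl_id": target,
                    "document_chembl_id": document,
                    "canonical_smiles": mol["smiles"],
                    "standard_type": stype,
                    "standard_relation": "=",
                    "standard_value": value_nm,
                    "standard_units": units,
                }

            rec = emit(measured, doc)
            if rng.random() < spec.censored_fraction:
                if rng.random() < 0.5:
                    rec["standard_relation"] = ">"
                else:
                    rec["standard_units"] = None
            records.append(rec)

            if rng.random() < spec.duplicate_rate:
                n_extra = int(rng.integers(1, 4))
                for _ in range(n_extra):
                    if rng.random() < 0.5:
                        dup = dict(rec)  # same document, same value
                    elif spec.noise_sd > 0 and rng.random() < 0.5:
                        dup = emit(
                            measured + rng.normal(0.0, DUP_PERTURB_SD), alt_doc
                        )
                    else:
                        dup = dict(rec)
                        dup["document_chembl_id"] = alt_doc
                    records.append(dup)

    records_df = pd.DataFrame(records, columns=REQUIRED_COLUMNS)
    truth = GroundTruth(
        pairs=pd.DataFrame(
            pair_rows,
            columns=["molecule_id", "target_id", "smiles", "pic50_true", "pic50_measured"],
        ),
        effects=dict(spec.causal_positions),
        cliff_molecules=[m["molecule_id"] for m in molecules if m["is_cliff"]],
        cliff_partners={
            m["molecule_id"]: m["partner"] for m in molecules if m["is_cliff"]
        },
    )
    return records_df, truth


def write_dataset(
    records: pd.DataFrame, truth: GroundTruth, out_dir, *, stem: str = "synthetic"
) -> dict[str, str]:
    """Write the activity CSV and the ground-truth JSON sidecar."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    act = out / f"{stem}_activities.csv"
    gt = out / f"{stem}_ground_truth.json"
    records.to_csv(act, index=False)
    truth.to_json(gt)
    return {"activities": str(act), "ground_truth": str(gt)}


def write_residue_table(profiles: Sequence[ResidueProfile], path) -> None:
    """Write profiles in the residue-table CSV layout consumed by curation."""
    positions = profiles[0].positions
    rows = []
    for p in profiles:
        row = {"target_id": p.target_id}
        row.update({pos.column_header: p.residues[pos] for pos in positions})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
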