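"""Binding-site residue profiles and their Z-scale encoding.

Targets are represented by the one-letter amino acids they present at a set
of aligned binding-site positions (anchored here to the SGLT2 structure,
PDB 7VSI, with a parallel multiple-sequence-alignment numbering). Each
position is encoded with the first three Sandberg Z-scales (Z1
lipophilicity, Z2 steric, Z3 electronic), giving three named numeric
features per position, e.g. ``pos286_Z2``.

The module ships two fixtures: the six-transporter SLC5 binding-site table
and the 20-residue three-component Z-scale lookup (Sandberg et al. 1998
values, embedded as a versioned CSV so the pipeline does not depend on any
library's built-in scales). Both can be overridden with user files of the
same layout.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")
GAP = "-"

_LABEL_RE = re.compile(r"^7VSI:(\d+)\|MSA:(\d+)$")
_MUTATION_RE = re.compile(r"^([A-Z])(\d+)([A-Z])$")


class ResidueTableError(ValueError):
    """Malformed residue table (ragged rows, bad letters, bad headers)."""


class ProfileGapError(ValueError):
    """A profile carries a gap at a position needed for modeling."""

    def __init__(self, targets: Sequence[str], position: "Position"):
        self.targets = list(targets)
        self.position = position
        super().__init__(
            f"gap at variable position {position.label} in target(s) "
            f"{', '.join(self.targets)}; exclude these targets before encoding"
        )


@dataclass(frozen=True, order=True)
class Position:
    """Aligned binding-site position with dual numbering.

    ``pdb`` is the residue number in the 7VSI structure (the canonical
    display numbering); ``msa`` is the column in the multiple sequence
    alignment.
    """

    pdb: int
    msa: int

    @property
    def label(self) -> str:
        return f"7VSI:{self.pdb}"

    @property
    def msa_label(self) -> str:
        return f"MSA:{self.msa}"

    @property
    def column_header(self) -> str:
        return f"7VSI:{self.pdb}|MSA:{self.msa}"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


@dataclass
class ResidueProfile:
    """One target's binding-site residues at the aligned positions."""

    target_id: str
    residues: dict[Position, str]

    def __post_init__(self) -> None:
        for pos, aa in self.residues.items():
            if aa not in AMINO_ACIDS and aa != GAP:
                raise ResidueTableError(
                    f"invalid residue {aa!r} at {pos.label} in target "
                    f"{self.target_id!r}"
                )

    @property
    def positions(self) -> list[Position]:
        return list(self.residues)

    def at(self, pdb_number: int) -> str:
        for pos, aa in self.residues.items():
            if pos.pdb == pdb_number:
                return aa
        raise KeyError(f"no position numbered {pdb_number} in profile")

    def position(self, pdb_number: int) -> Position:
        for pos in self.residues:
            if pos.pdb == pdb_number:
                return pos
        raise KeyError(f"no position numbered {pdb_number} in profile")

    def residue_string(self, positions: Iterable[Position] | None = None) -> str:
        positions = self.positions if positions is None else list(positions)
        return "".join(self.residues[p] for p in positions)

    def has_gap(self, positions: Iterable[Position] | None = None) -> bool:
        positions = self.positions if positions is None else list(positions)
        return any(self.residues[p] == GAP for p in positions)


@dataclass
class ZScaleTable:
    """Three-component Z-scale lookup: one (z1, z2, z3) triple per residue."""

    values: Mapping[str, tuple[float, float, float]]

    def __post_init__(self) -> None:
        missing = AMINO_ACIDS - set(self.values)
        if missing:
            raise ValueError(f"Z-scale table missing residues: {sorted(missing)}")
        if len(self.values) != 20:
            extra = set(self.values) - AMINO_ACIDS
            raise ValueError(f"Z-scale table must have exactly 20 entries; extra: {sorted(extra)}")

    def __getitem__(self, aa: str) -> tuple[float, float, float]:
        return self.values[aa]

    def vector(self, aa: str) -> np.ndarray:
        return np.asarray(self.values[aa], dtype=float)

    def distance(self, a: str, b: str) -> float:
        """Euclidean distance between two residues in (Z1, Z2, Z3) space."""
        return float(np.linalg.norm(self.vector(a) - self.vector(b)))

    @classmethod
    def from_csv(cls, path) -> "ZScaleTable":
        df = pd.read_csv(path)
        expected = ["amino_acid", "z1", "z2", "z3"]
        if list(df.columns) != expected:
            raise ValueError(f"Z-scale CSV must have columns {expected}, got {list(df.columns)}")
        return cls({r.amino_acid: (r.z1, r.z2, r.z3) for r in df.itertuples()})


def sandberg_zscales() -> ZScaleTable:
    """The embedded three-component Sandberg Z-scale fixture."""
    with resources.as_file(
        resources.files("slc5pcm.data") / "zscales_sandberg3.csv"
    ) as p:
        return ZScaleTable.from_csv(p)


def _parse_header(columns: Sequence[str]) -> list[Position]:
    positions = []
    for col in columns:
        m = _LABEL_RE.match(col.strip())
        if m is None:
            raise ResidueTableError(
                f"residue-table column {col!r} does not match '7VSI:<n>|MSA:<n>'"
            )
        positions.append(Position(pdb=int(m.group(1)), msa=int(m.group(2))))
    return positions


def load_residue_table(path) -> list[ResidueProfile]:
    """Read a residue table CSV (rows = targets, columns = dual-numbered positions)."""
    df = pd.read_csv(path, dtype=str)
    if df.empty or "target_id" not in df.columns or len(df.columns) < 2:
        raise ResidueTableError(
            f"residue table {path!r} is empty or lacks a 'target_id' column"
        )
    positions = _parse_header([c for c in df.columns if c != "target_id"])
    profiles = []
    for i, row in df.iterrows():
        target = row["target_id"]
        if not isinstance(target, str) or not target:
            raise ResidueTableError(f"row {i}: missing target_id")
        residues = {}
        for pos in positions:
            aa = row[pos.column_header]
            if not isinstance(aa, str) or aa.strip() == "":
                raise ResidueTableError(
                    f"row {i} (target {target}): missing residue in column "
                    f"{pos.column_header}"
                )
            aa = aa.strip().upper()
            if aa not in AMINO_ACIDS and aa != GAP:
                raise ResidueTableError(
                    f"row {i} (target {target}), column {pos.column_header}: "
                    f"invalid residue letter {aa!r}"
                )
            residues[pos] = aa
        profiles.append(ResidueProfile(target_id=target, residues=residues))
    return profiles


def slc5_residue_table() -> list[ResidueProfile]:
    """The embedded six-target SLC5 binding-site residue fixture."""
    with resources.as_file(
        resources.files("slc5pcm.data") / "binding_site_residues_slc5.csv"
    ) as p:
        return load_residue_table(p)


def _check_shared_positions(profiles: Sequence[ResidueProfile]) -> list[Position]:
    ref = profiles[0].positions
    for prof in profiles[1:]:
        if prof.positions != ref:
            raise ResidueTableError(
                f"profile {prof.target_id!r} has a different position list than "
                f"{profiles[0].target_id!r}"
            )
    return ref


def drop_gapped_profiles(
    profiles: Sequence[ResidueProfile],
) -> tuple[list[ResidueProfile], list[ResidueProfile]]:
    """Split profiles into (gap-free, gapped). Gapped targets are excluded
    from modeling rather than dropping the position for everyone."""
    kept = [p for p in profiles if not p.has_gap()]
    dropped = [p for p in profiles if p.has_gap()]
    return kept, dropped


def variable_positions(
    profiles: Sequence[ResidueProfile], *, on_gap: str = "raise"
) -> list[Position]:
    """Positions where at least two distinct residues occur across profiles.

    Order of the input position list is preserved. A gap at a variable
    position marks the carrying target for exclusion: with ``on_gap="raise"``
    (default) a :class:`ProfileGapError` identifies those targets; with
    ``on_gap="exclude"`` the gapped profiles are silently dropped before the
    variability scan.
    """
    if len(profiles) < 2:
        raise ValueError("need at least two profiles to assess variability")
    if on_gap not in ("raise", "exclude"):
        raise ValueError("on_gap must be 'raise' or 'exclude'")
    if on_gap == "exclude":
        profiles = drop_gapped_profiles(profiles)[0]
        if len(profiles) < 2:
            raise ValueError("fewer than two gap-free profiles remain")
    positions = _check_shared_positions(profiles)
    out = []
    for pos in positions:
        letters = {p.residues[pos] for p in profiles}
        if len(letters - {GAP}) >= 2:
            gapped = [p.target_id for p in profiles if p.residues[pos] == GAP]
            if gapped:
                raise ProfileGapError(gapped, pos)
            out.append(pos)
    return out


def feature_name(position: Position, k: int) -> str:
    return f"pos{position.pdb}_Z{k}"


def encode_zscales(
    profile: ResidueProfile,
    positions: Sequence[Position],
    table: ZScaleTable,
) -> pd.Series:
    """Concatenate (Z1, Z2, Z3) for the requested positions.

    Returns a named vector ``pos{N}_Z{k}`` of length ``3 * len(positions)``.
    """
    names, values = [], []
    for pos in positions:
        aa = profile.residues.get(pos)
        if aa is None:
            raise KeyError(f"profile {profile.target_id!r} lacks position {pos.label}")
        if aa == GAP:
            raise ProfileGapError([profile.target_id], pos)
        if aa not in table.values:
            raise ValueError(f"unknown residue {aa!r} at {pos.label}")
        for k, z in enumerate(table[aa], start=1):
            names.append(feature_name(pos, k))
            values.append(float(z))
    return pd.Series(values, index=names, name=profile.target_id)


def protein_feature_frame(
    profiles: Sequence[ResidueProfile],
    positions: Sequence[Position],
    table: ZScaleTable,
) -> pd.DataFrame:
    """Stack per-target Z-scale vectors into a (targets x features) frame."""
    rows = [encode_zscales(p, positions, table) for p in profiles]
    return pd.DataFrame(rows)


def parse_mutation(mutation: str) -> tuple[str, int, str]:
    m = _MUTATION_RE.match(mutation.strip())
    if m is None:
        raise ValueError(
            f"mutation {mutation!r} not in 'XnY' notation (e.g. 'V95I', 7VSI numbering)"
        )
    ref, num, new = m.group(1), int(m.group(2)), m.group(3)
    for aa in (ref, new):
        if aa not in AMINO_ACIDS:
            raise ValueError(f"mutation {mutation!r}: {aa!r} is not an amino acid")
    return ref, num, new


def mutate(
    profile: ResidueProfile, mutations: str | Iterable[str]
) -> ResidueProfile:
    """Apply point mutations like ``"V95I"`` (7VSI numbering) to a copy.

    The reference letter must match the profile's residue at that position;
    a mismatch raises, guarding against numbering mistakes.
    """
    if isinstance(mutations, str):
        mutations = [mutations]
    residues = dict(profile.residues)
    applied = []
    for mut in mutations:
        ref, num, new = parse_mutation(mut)
        pos = profile.position(num)
        found = residues[pos]
        if found != ref:
            raise ValueError(
                f"mutation {mut}: expected {ref!r} at {pos.label} of "
                f"{profile.target_id!r} but found {found!r}"
            )
        residues[pos] = new
        applied.append(mut)
    suffix = "+".join(applied)
    new_id = f"{profile.target_id}|{suffix}" if applied else profile.target_id
    return ResidueProfile(target_id=new_id, residues=residues)
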