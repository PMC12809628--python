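"""Ligand featurization: Morgan fingerprints, MACCS keys, physico-chemical
descriptors, and Tanimoto similarity diagnostics.

All schemes return a :class:`LigandFeatureBlock` with named columns and
constant columns removed (constant features carry no information for
regression). The physico-chemical scheme either computes a user-supplied
descriptor selection or, without one, applies automatic |Pearson| > 0.7
correlation pruning with a deterministic name-lexicographic tie-break.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml
from rdkit import Chem, DataStructs
from rdkit.Chem import Descriptors, MACCSkeys, rdFingerprintGenerator

MORGAN_RADIUS = 2
MORGAN_NBITS = 2048
MACCS_NBITS = 167
PEARSON_THRESHOLD = 0.7
TANIMOTO_CUTOFF = 0.4


class DescriptorNameError(ValueError):
    """A requested physico-chemical descriptor name is unknown to RDKit."""


@dataclass
class LigandFeatureBlock:
    """Molecules x named features for one featurization scheme."""

    scheme: str
    features: pd.DataFrame

    @property
    def feature_names(self) -> list[str]:
        return list(self.features.columns)

    @property
    def n_molecules(self) -> int:
        return len(self.features)


def _as_mols(molecules: Sequence) -> list[Chem.Mol]:
    mols = []
    for i, m in enumerate(molecules):
        if isinstance(m, Chem.Mol):
            mols.append(m)
        else:
            mol = Chem.MolFromSmiles(m)
            if mol is None:
                raise ValueError(f"molecule {i}: unparsable SMILES {m!r}")
            mols.append(mol)
    return mols


def _frame(matrix, names, ids) -> pd.DataFrame:
    df = pd.DataFrame(matrix, columns=names)
    if ids is not None:
        df.index = pd.Index(ids)
    return df


def _drop_constant(df: pd.DataFrame) -> pd.DataFrame:
    keep = [c for c in df.columns if df[c].nunique() > 1]
    return df[keep]


def morgan_features(
    molecules: Sequence,
    ids: Sequence[str] | None = None,
    *,
    radius: int = MORGAN_RADIUS,
    n_bits: int = MORGAN_NBITS,
    prune_constant: bool = True,
) -> LigandFeatureBlock:
    """Circular (Morgan) fingerprints, radius 2 over 2048 bits by default."""
    mols = _as_mols(molecules)
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    mat = np.zeros((len(mols), n_bits), dtype=np.uint8)
    for i, mol in enumerate(mols):
        DataStructs.ConvertToNumpyArray(gen.GetFingerprint(mol), mat[i])
    df = _frame(mat, [f"morgan_{b}" for b in range(n_bits)], ids)
    if prune_constant:
        df = _drop_constant(df)
    return LigandFeatureBlock(scheme="morgan", features=df)


def maccs_features(
    molecules: Sequence,
    ids: Sequence[str] | None = None,
    *,
    prune_constant: bool = True,
) -> LigandFeatureBlock:
    """MACCS substructure keys as bit vectors (167-bit standard set)."""
    mols = _as_mols(molecules)
    mat = np.zeros((len(mols), MACCS_NBITS), dtype=np.uint8)
    for i, mol in enumerate(mols):
        DataStructs.ConvertToNumpyArray(MACCSkeys.GenMACCSKeys(mol), mat[i])
    df = _frame(mat, [f"maccs_{b}" for b in range(MACCS_NBITS)], ids)
    if prune_constant:
        df = _drop_constant(df)
    return LigandFeatureBlock(scheme="maccs", features=df)


def available_descriptors() -> list[str]:
    """All RDKit descriptor names except the fragment counters (``fr_*``)."""
    return [n for n, _ in Descriptors._descList if not n.startswith("fr_")]


def default_descriptor_selection() -> list[str]:
    """The packaged 49-descriptor stand-in selection (see data file notes)."""
    with resources.as_file(
        resources.files("slc5pcm.data") / "physchem_selection_synthetic.yaml"
    ) as p:
        with open(p) as fh:
            payload = yaml.safe_load(fh)
    return list(payload["descriptors"])


def _pearson_prune(df: pd.DataFrame, threshold: float) -> pd.DataFrame:
    """Drop the later member (name-sorted) of every |r| > threshold pair."""
    kept: list[str] = []
    for col in sorted(df.columns):
        ok = True
        for other in kept:
            r = df[col].corr(df[other])
            if np.isfinite(r) and abs(r) > threshold:
                ok = False
                break
        if ok:
            kept.append(col)
    return df[kept]


def physchem_features(
    molecules: Sequence,
    ids: Sequence[str] | None = None,
    *,
    selection: Sequence[str] | None = None,
    pearson_threshold: float = PEARSON_THRESHOLD,
    prune_constant: bool = True,
) -> LigandFeatureBlock:
    """RDKit physico-chemical descriptors.

    With ``selection`` given, exactly those descriptors are computed (after
    constant-column pruning the block may be smaller). Without it, all
    non-fragment descriptors are computed and highly correlated ones
    (|Pearson| > 0.7) are pruned, keeping the first of each correlated pair
    in name-sorted order.
    """
    mols = _as_mols(molecules)
    avail = set(available_descriptors())
    if selection is not None:
        unknown = [n for n in selection if n not in avail]
        if unknown:
            raise DescriptorNameError(f"unknown descriptor name(s): {unknown}")
        names = list(selection)
    else:
        names = available_descriptors()
    fns = dict(Descriptors._descList)
    rows = []
    for mol in mols:
        rows.append([fns[n](mol) for n in names])
    df = _frame(np.asarray(rows, dtype=float), names, ids)
    df = df.loc[:, df.notna().all(axis=0)]  # a few descriptors can be NaN-prone
    if prune_constant:
        df = _drop_constant(df)
    if selection is None:
        df = _pearson_prune(df, pearson_threshold)
    return LigandFeatureBlock(scheme="physchem", features=df)


FEATURIZERS = {
    "morgan": morgan_features,
    "maccs": maccs_features,
    "physchem": physchem_features,
}


def featurize(
    scheme: str, molecules: Sequence, ids: Sequence[str] | None = None, **kwargs
) -> LigandFeatureBlock:
    if scheme not in FEATURIZERS:
        raise ValueError(f"unknown scheme {scheme!r}; choose from {sorted(FEATURIZERS)}")
    return FEATURIZERS[scheme](molecules, ids, **kwargs)


@dataclass
class TanimotoSummary:
    """All-pairs whole-structure similarity diagnostics."""

    n_pairs: int
    fraction_below_cutoff: float
    cutoff: float
    histogram_counts: np.ndarray
    bin_edges: np.ndarray


def pairwise_tanimoto(
    molecules: Sequence,
    *,
    cutoff: float = TANIMOTO_CUTOFF,
    n_bins: int = 20,
) -> TanimotoSummary:
    """All-pairs Tanimoto similarity on Morgan bits (self-pairs excluded)."""
    mols = _as_mols(molecules)
    if len(mols) < 2:
        raise ValueError("need at least two molecules for pairwise similarity")
    gen = rdFingerprintGenerator.GetMorganGenerator(
        radius=MORGAN_RADIUS, fpSize=MORGAN_NBITS
    )
    fps = [gen.GetFingerprint(m) for m in mols]
    sims = []
    for i in range(1, len(fps)):
        sims.extend(DataStructs.BulkTanimotoSimilarity(fps[i], fps[:i]))
    sims = np.asarray(sims)
    counts, edges = np.histogram(sims, bins=n_bins, range=(0.0, 1.0))
    return TanimotoSummary(
        n_pairs=len(sims),
        fraction_below_cutoff=float((sims < cutoff).mean()),
        cutoff=cutoff,
        histogram_counts=counts,
        bin_edges=edges,
    )
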