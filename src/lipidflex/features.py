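"""Condensation of lipidomes into per-class compositional features.

A lipidome of hundreds of species is reduced to three features per lipid
class and sample:

* ``<class>``      — class abundance as mol% of the total lipidome,
* ``<class>_db``   — amount-weighted mean of the total double-bond count of
  the class's species (unsaturation index),
* ``<class>_c``    — amount-weighted mean of the total carbon count
  (chain-length index).

The weighted mean of a feature q (total double bonds or total carbons) over
the species of a class is

    q̄ = (1/n_c) · Σ_j j · Σ_i n_ji

where n_c is the total molar amount of the class, j runs over the observed
feature values and n_ji is the amount of species i with feature value j —
i.e. a plain amount-weighted average over species-level records.  Subspecies
are collapsed to species level (summed totals) and merged before averaging.
Classes without hydrocarbon chains (sterol) contribute abundance only; their
chain indices are undefined (NaN), as are those of classes absent from a
sample — absence is undefined, not zero.

The module also provides per-sample fatty-acid profiles (each chain of each
subspecies-resolved lipid weighted by the lipid's amount) and a centered,
unit-variance PCA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .nomenclature import (
    DEFAULT_REGISTRY,
    LipidSpecies,
    fatty_acids_of,
    format_species,
    to_species_level,
)
from .qc import LipidomeMatrix, QCWarning

__all__ = [
    "FeatureTable",
    "PCAResult",
    "STORAGE_CLASSES",
    "normalize_mol_percent",
    "weighted_mean_feature",
    "condense",
    "fatty_acid_profile",
    "drop_classes",
    "pca",
]

#: Neutral storage lipids excluded in the membrane-lipid-only PCA variant.
STORAGE_CLASSES = ("CE", "DAG", "TAG")


def normalize_mol_percent(m: LipidomeMatrix) -> LipidomeMatrix:
    """Rescale every sample to mol% (rows sum to 100).

    Raises
    ------
    ValueError
        If any sample has zero total amount (blanks should be excluded
        before normalisation).
    """
    totals = m.amounts.sum(axis=1)
    zero = totals.index[totals <= 0]
    if len(zero):
        raise ValueError(f"cannot normalise all-zero sample(s): {list(zero)}")
    out = m.with_amounts(m.amounts.div(totals, axis=0) * 100.0)
    out.scale = "mol_percent"
    return out


def weighted_mean_feature(values, amounts) -> float:
    """Amount-weighted mean of a per-species feature (q̄).

    Returns NaN when the total amount is not positive (empty class:
    undefined, not zero).
    """
    values = np.asarray(values, dtype=float)
    amounts = np.asarray(amounts, dtype=float)
    total = amounts.sum()
    if total <= 0:
        return float("nan")
    return float((values * amounts).sum() / total)


@dataclass
class FeatureTable:
    """Per-sample condensed lipidomic features (3 per detected class).

    ``data`` is a wide DataFrame with columns ``<class>``, ``<class>_db``,
    ``<class>_c`` per detected class; abundance columns sum to 100 per
    sample, chain-index columns are NaN where the class is absent from a
    sample or carries no chains.
    """

    data: pd.DataFrame
    sample_meta: pd.DataFrame
    classes: list[str]

    @property
    def n_features(self) -> int:
        return self.data.shape[1]

    def feature_columns(self, kind: Optional[str] = None) -> list[str]:
        """Column names, optionally one kind of {"abundance", "db", "c"}."""
        if kind is None:
            return list(self.data.columns)
        if kind == "abundance":
            return [c for c in self.classes]
        if kind in ("db", "c"):
            return [f"{c}_{kind}" for c in self.classes]
        raise ValueError(f"unknown feature kind {kind!r}")

    def to_tidy(self) -> pd.DataFrame:
        """Tidy TSV-ready view: sample, lipid_class, feature, value."""
        rows = self.data.reset_index(names="sample").melt(
            id_vars="sample", var_name="feature", value_name="value"
        )
        def split(feat: str):
            for suffix, kind in (("_db", "mean_db"), ("_c", "mean_c")):
                if feat.endswith(suffix):
                    return feat[: -len(suffix)], kind
            return feat, "abundance"
        parts = rows["feature"].map(split)
        rows["lipid_class"] = parts.str[0]
        rows["feature_kind"] = parts.str[1]
        return rows[["sample", "lipid_class", "feature_kind", "feature", "value"]]

    def subset(self, samples: Iterable) -> "FeatureTable":
        idx = self.data.index.intersection(pd.Index(list(samples)))
        return FeatureTable(
            self.data.loc[idx].copy(), self.sample_meta.loc[idx].copy(), list(self.classes)
        )


def condense(m: LipidomeMatrix, registry=DEFAULT_REGISTRY) -> FeatureTable:
    """Condense a mol%-scale lipidome into the 3-per-class feature scheme."""
    if m.scale != "mol_percent":
        raise ValueError("condense expects a mol%-scale matrix; normalise first")

    # collapse subspecies to species level and merge duplicated records
    species_level: dict[str, list[str]] = {}
    sp_records: dict[str, LipidSpecies] = {}
    for col in m.species:
        sp = to_species_level(m.species_meta[col])
        key = format_species(sp, registry)
        species_level.setdefault(key, []).append(col)
        sp_records[key] = sp

    merged = pd.DataFrame(
        {key: m.amounts[cols].sum(axis=1) for key, cols in species_level.items()}
    )

    by_class: dict[str, list[str]] = {}
    for key, sp in sp_records.items():
        by_class.setdefault(sp.class_token, []).append(key)
    classes = sorted(cls for cls, cols in by_class.items()
                     if (merged[cols].to_numpy() > 0).any())

    out = {}
    for cls in classes:
        cols = by_class[cls]
        block = merged[cols]
        total = block.sum(axis=1)
        out[cls] = total
        chainless = cls in registry.tokens and not registry[cls].has_numeric_block
        if chainless:
            out[f"{cls}_db"] = pd.Series(np.nan, index=block.index)
            out[f"{cls}_c"] = pd.Series(np.nan, index=block.index)
            continue
        db = np.array([sp_records[k].total_double_bonds for k in cols], float)
        cc = np.array([sp_records[k].total_carbons for k in cols], float)
        with np.errstate(invalid="ignore", divide="ignore"):
            mean_db = block.to_numpy() @ db / total.to_numpy()
            mean_c = block.to_numpy() @ cc / total.to_numpy()
        out[f"{cls}_db"] = pd.Series(
            np.where(total > 0, mean_db, np.nan), index=block.index
        )
        out[f"{cls}_c"] = pd.Series(
            np.where(total > 0, mean_c, np.nan), index=block.index
        )

    order = [name for cls in classes for name in (cls, f"{cls}_db", f"{cls}_c")]
    data = pd.DataFrame(out)[order]
    return FeatureTable(data, m.sample_meta.copy(), classes)


def fatty_acid_profile(m: LipidomeMatrix) -> pd.DataFrame:
    """Per-sample mol% profile over individual hydrocarbon chains.

    Every lipid with resolved chains contributes each of its chains weighted
    by the lipid's amount; rows are renormalised to sum to 100 over the
    observed chain vocabulary.  Lipids annotated at species level only are
    excluded.
    """
    contributions: dict[str, pd.Series] = {}
    any_chains = False
    for col in m.species:
        sp = m.species_meta[col]
        if sp.chains is None:
            continue
        any_chains = True
        for chain in fatty_acids_of(sp):
            label = chain.label
            prev = contributions.get(label)
            contributions[label] = (
                m.amounts[col] if prev is None else prev + m.amounts[col]
            )
    if not any_chains:
        warnings.warn("no subspecies-level lipids; empty FA profile", QCWarning)
        return pd.DataFrame(index=m.samples)
    prof = pd.DataFrame(contributions)
    totals = prof.sum(axis=1)
    prof = prof.div(totals.where(totals > 0), axis=0) * 100.0
    return prof[sorted(prof.columns)]


def drop_classes(
    m: LipidomeMatrix, classes: Sequence[str] = STORAGE_CLASSES
) -> LipidomeMatrix:
    """Remove whole lipid classes (e.g. storage lipids before a membrane PCA)."""
    keep = [
        col for col in m.species if m.species_meta[col].class_token not in set(classes)
    ]
    return m.with_amounts(m.amounts[keep])


@dataclass
class PCAResult:
    """Scores, orthonormal loadings and variance-explained fractions."""

    scores: pd.DataFrame        # samples × components
    loadings: pd.DataFrame      # features × components
    explained_variance_ratio: np.ndarray
    dropped: list[str]


def pca(X, scale: bool = True, n_components: Optional[int] = None) -> PCAResult:
    """Principal component analysis on centered (and unit-variance) data.

    Accepts a DataFrame (samples × features) or a :class:`FeatureTable`.
    Columns containing NaN or with zero variance are dropped with a warning.
    """
    if isinstance(X, FeatureTable):
        X = X.data
    X = pd.DataFrame(X)
    if X.shape[0] < 2:
        raise ValueError("PCA requires at least 2 samples")

    dropped = [c for c in X.columns if X[c].isna().any()]
    if dropped:
        warnings.warn(f"dropping {len(dropped)} feature(s) with missing values", QCWarning)
        X = X.drop(columns=dropped)
    sd = X.std(axis=0, ddof=1)
    zero_var = list(sd.index[sd == 0])
    if zero_var:
        warnings.warn(f"dropping {len(zero_var)} zero-variance feature(s)", QCWarning)
        X = X.drop(columns=zero_var)
        sd = sd.drop(zero_var)
        dropped += zero_var
    if X.shape[1] < 2:
        raise ValueError("PCA requires at least 2 usable features")

    Z = X - X.mean(axis=0)
    if scale:
        Z = Z / sd
    U, S, Vt = np.linalg.svd(Z.to_numpy(float), full_matrices=False)
    n = Z.shape[0]
    var = S**2 / (n - 1)
    # variance explained relative to total variance of the (scaled) data
    total_var = (Z.to_numpy(float) ** 2).sum() / (n - 1)
    ratio = var / total_var
    k = len(S) if n_components is None else min(n_components, len(S))
    comps = [f"PC{i+1}" for i in range(k)]
    scores = pd.DataFrame(U[:, :k] * S[:k], index=X.index, columns=comps)
    loadings = pd.DataFrame(Vt[:k].T, index=X.columns, columns=comps)
    return PCAResult(scores, loadings, ratio[:k], dropped)
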