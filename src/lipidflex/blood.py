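"""Organ-versus-blood lipid correlations and organ clustering.

Asks whether diet-driven changes in an organ's lipids are mirrored in the
circulation.  For every lipid shared between an organ and a blood matrix
(plasma or full blood), the partial Spearman correlation across the paired
animals — spanning both diets, adjusted for sex and genotype — is computed
by rank-transforming both variables, residualising the ranks on the
covariates, and correlating the residuals (p from the t approximation with
df = n − 2 − #covariates).  Only significant positive correlations
(ρ > 0, p < alpha) count as "reflected in blood"; the per-organ fraction of
such lipids summarises how good a proxy blood is for that organ.

For clustering, each organ becomes a vector of its significant-positive ρ
values over the shared lipid vocabulary (all other cells zeroed so organs
share a common space), with blood plasma as the self-correlation reference
row; organs are then grouped by complete-linkage hierarchical clustering on
Euclidean distances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

from .qc import LipidomeMatrix, QCWarning

__all__ = [
    "partial_spearman",
    "organ_blood_matrix",
    "correlate_matrices",
    "cluster_organs",
    "ClusterResult",
]


def partial_spearman(x, y, covariates=None) -> tuple[float, float]:
    """Partial Spearman correlation of x and y given covariates.

    Ranks x, y and each covariate column, residualises the x/y ranks on the
    covariates (with intercept) and returns the Pearson correlation of the
    residuals together with a two-sided p-value from the t distribution with
    n − 2 − k degrees of freedom.  Constant covariates are dropped, so with
    no informative covariates this reduces to plain Spearman correlation.

    Returns ``(nan, nan)`` with a warning when x or y is constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if len(y) != n:
        raise ValueError("x and y must have equal length")
    if n < 6:
        raise ValueError(f"need at least 6 paired observations, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant input; partial correlation undefined", QCWarning)
        return float("nan"), float("nan")

    rx = stats.rankdata(x)
    ry = stats.rankdata(y)

    cov_cols = []
    if covariates is not None:
        C = pd.DataFrame(covariates).reset_index(drop=True)
        for col in C.columns:
            vals = C[col]
            if vals.dtype == object or str(vals.dtype) == "category":
                vals = pd.Series(pd.factorize(vals)[0])
            vals = np.asarray(vals, dtype=float)
            if np.ptp(vals) > 0:
                cov_cols.append(stats.rankdata(vals))
    k = len(cov_cols)
    Z = np.column_stack([np.ones(n)] + cov_cols)
    coef_x, *_ = np.linalg.lstsq(Z, rx, rcond=None)
    coef_y, *_ = np.linalg.lstsq(Z, ry, rcond=None)
    ex = rx - Z @ coef_x
    ey = ry - Z @ coef_y
    denom = np.sqrt((ex**2).sum() * (ey**2).sum())
    if denom == 0:
        warnings.warn("degenerate residuals; partial correlation undefined", QCWarning)
        return float("nan"), float("nan")
    rho = float(np.clip((ex * ey).sum() / denom, -1.0, 1.0))
    df = n - 2 - k
    if df <= 0:
        raise ValueError("not enough degrees of freedom for the p-value")
    if abs(rho) == 1.0:
        return rho, 0.0
    t = rho * np.sqrt(df / (1.0 - rho**2))
    p = float(2.0 * stats.t.sf(abs(t), df))
    return rho, p


def correlate_matrices(
    organ_df: pd.DataFrame,
    blood_df: pd.DataFrame,
    covariates: pd.DataFrame,
    alpha: float = 0.05,
    organ: str = "organ",
    blood_matrix: str = "plasma",
) -> pd.DataFrame:
    """Partial-Spearman records for every column shared by two aligned frames.

    Rows of the two frames must correspond to the same animals, in the same
    order as ``covariates``.
    """
    shared = [c for c in organ_df.columns if c in set(blood_df.columns)]
    records = []
    for lipid in shared:
        x = organ_df[lipid].to_numpy(float)
        y = blood_df[lipid].to_numpy(float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            warnings.warn(
                f"{organ}/{lipid}: constant values; record skipped", QCWarning
            )
            continue
        rho, p = partial_spearman(x, y, covariates)
        if np.isnan(rho):
            continue
        records.append(
            (organ, lipid, blood_matrix, rho, p, bool(rho > 0 and p < alpha))
        )
    return pd.DataFrame(
        records, columns=["organ", "lipid", "blood_matrix", "rho", "p", "kept"]
    )


def organ_blood_matrix(
    organ_m: LipidomeMatrix,
    blood_m: LipidomeMatrix,
    alpha: float = 0.05,
    diet: Optional[str] = None,
) -> tuple[pd.DataFrame, float]:
    """Correlate an organ's lipids with their counterparts in a blood matrix.

    Samples are paired by animal (``mouse`` metadata) across both diets —
    diet being the varying stimulus — or within one diet when ``diet`` is
    given.  Returns the per-lipid correlation records and the fraction of
    shared lipids with a significant positive correlation.
    """
    om, bm = organ_m.sample_meta, blood_m.sample_meta
    if diet is not None:
        organ_m = organ_m.subset(samples=om.index[om["diet"] == diet])
        blood_m = blood_m.subset(samples=bm.index[bm["diet"] == diet])
        om, bm = organ_m.sample_meta, blood_m.sample_meta
    organ_by_mouse = pd.Series(om.index.values, index=om["mouse"].values)
    blood_by_mouse = pd.Series(bm.index.values, index=bm["mouse"].values)
    mice = sorted(set(organ_by_mouse.index) & set(blood_by_mouse.index))
    if not mice:
        warnings.warn("no shared animals between organ and blood", QCWarning)
        return pd.DataFrame(
            columns=["organ", "lipid", "blood_matrix", "rho", "p", "kept"]
        ), float("nan")

    o_idx = organ_by_mouse.loc[mice].values
    b_idx = blood_by_mouse.loc[mice].values
    organ_df = organ_m.amounts.loc[o_idx]
    blood_df = blood_m.amounts.loc[b_idx]
    # restrict to lipids actually observed on both sides
    organ_df = organ_df.loc[:, (organ_df > 0).any(axis=0)]
    blood_df = blood_df.loc[:, (blood_df > 0).any(axis=0)]
    if not set(organ_df.columns) & set(blood_df.columns):
        warnings.warn("no shared lipids between organ and blood", QCWarning)
        return pd.DataFrame(
            columns=["organ", "lipid", "blood_matrix", "rho", "p", "kept"]
        ), float("nan")
    covariates = om.loc[o_idx, ["sex", "genotype"]].reset_index(drop=True)
    organ_name = str(om["sample_type"].iloc[0]) if len(om) else "organ"
    blood_name = str(bm["sample_type"].iloc[0]) if len(bm) else "blood"
    records = correlate_matrices(
        organ_df, blood_df, covariates, alpha=alpha,
        organ=organ_name, blood_matrix=blood_name,
    )
    fraction = float(records["kept"].mean()) if len(records) else float("nan")
    return records, fraction


@dataclass
class ClusterResult:
    """Complete-linkage clustering of organs in correlation space."""

    linkage: np.ndarray
    labels: list[str]
    leaf_order: list[str]
    matrix: pd.DataFrame

    def cophenetic(self) -> pd.DataFrame:
        """Pairwise cophenetic (dendrogram merge height) distances."""
        d = hierarchy.cophenet(self.linkage)
        from scipy.spatial.distance import squareform

        return pd.DataFrame(
            squareform(d), index=self.labels, columns=self.labels
        )


def cluster_organs(
    records: pd.DataFrame, reference: Optional[str] = "plasma"
) -> ClusterResult:
    """Cluster organs by their significant-positive correlation profiles.

    The clustering space is the set of lipids significantly positively
    correlated in at least one organ; each organ's vector holds ρ where
    ``kept`` and 0 elsewhere.  ``reference`` adds the blood matrix itself as
    a self-correlation row (ρ = 1).  Complete-linkage, Euclidean.
    """
    mat = records.pivot_table(
        index="organ",
        columns="lipid",
        values="rho",
        aggfunc="first",
    )
    keep = records.pivot_table(
        index="organ", columns="lipid", values="kept", aggfunc="first"
    ).fillna(False).astype(bool)
    mat = mat.where(keep, 0.0).fillna(0.0)
    informative = keep.any(axis=0)
    if informative.any():
        mat = mat.loc[:, informative[informative].index]
    if reference is not None and reference not in mat.index:
        mat.loc[reference] = 1.0
    if mat.shape[0] < 2:
        raise ValueError("clustering requires at least 2 organs")
    Z = hierarchy.linkage(mat.to_numpy(float), method="complete", metric="euclidean")
    labels = list(mat.index)
    order = [labels[i] for i in hierarchy.leaves_list(Z)]
    return ClusterResult(Z, labels, order, mat)
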