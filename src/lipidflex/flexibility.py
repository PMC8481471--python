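"""Organ-level factor regressions and the lipidome flexibility score.

Within each sample type, every condensed lipidomic feature is z-scored and
regressed on the experimental factors (ordinary least squares):

    z(feature) ~ sex + diet + genotype [+ interaction]

Factors use treatment coding with reference levels female / low-protein /
inbred (reference level coded 0, the other level 1), so a β of +0.8 for diet
means the high-protein group sits 0.8 within-organ standard deviations above
the low-protein group after adjusting for the other covariates.  p-values
come from the t distribution with residual degrees of freedom; no
multiple-testing correction is applied by default (raw p thresholds), with
an optional Benjamini–Hochberg adjustment.

The *flexibility* of a sample type with respect to a factor is the sum of
absolute effect sizes |β| over the features whose term is significant at
p < alpha (default 0.01): a single number per organ and factor measuring how
strongly the experimental condition reshapes that organ's lipidome.

A companion variance decomposition regresses every species' mol% on
sample type + sex + diet + genotype across the whole dataset and reports the
average fraction of variance attributable to each covariate.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .features import FeatureTable
from .qc import QCWarning

__all__ = [
    "REFERENCE_LEVELS",
    "design_matrix",
    "fit_factor_model",
    "fit_interaction_model",
    "flexibility_score",
    "variance_decomposition",
    "benjamini_hochberg",
]

#: Treatment-coding reference levels (coded 0); the other level is coded 1.
REFERENCE_LEVELS = {"sex": "F", "diet": "low_protein", "genotype": "inbred"}

FACTORS = ("sex", "diet", "genotype")


def _binary_code(series: pd.Series, factor: str) -> pd.Series:
    levels = sorted(series.dropna().unique())
    if len(levels) > 2:
        raise ValueError(f"factor {factor!r} has more than two levels: {levels}")
    ref = REFERENCE_LEVELS.get(factor)
    if ref is not None and ref in levels:
        return (series != ref).astype(float)
    return (series != levels[0]).astype(float)


def design_matrix(
    meta: pd.DataFrame,
    factors: Sequence[str] = FACTORS,
    interactions: Sequence[str] = (),
) -> pd.DataFrame:
    """Treatment-coded design matrix with intercept.

    Interactions are written ``"diet:genotype"`` and enter as the product of
    the two indicator columns.  Factors constant within the data are dropped
    with a warning (collinear with the intercept).
    """
    cols = {"intercept": pd.Series(1.0, index=meta.index)}
    for factor in factors:
        coded = _binary_code(meta[factor], factor)
        if coded.nunique() < 2:
            warnings.warn(
                f"factor {factor!r} is constant in this stratum; term dropped",
                QCWarning,
            )
            continue
        cols[factor] = coded
    for inter in interactions:
        a, b = inter.split(":")
        if a not in cols or b not in cols:
            raise ValueError(f"interaction {inter!r} references a dropped factor")
        cols[inter] = cols[a] * cols[b]
    return pd.DataFrame(cols)


def _ols(X: np.ndarray, Y: np.ndarray):
    """Vectorised OLS over feature columns: β, se, p, residual df."""
    n, p = X.shape
    XtXi = np.linalg.inv(X.T @ X)
    beta = XtXi @ X.T @ Y
    resid = Y - X @ beta
    df = n - p
    sigma2 = (resid**2).sum(axis=0) / df
    # residual variance at machine-noise level means an exact fit: the
    # t-ratio of two rounding errors is meaningless, so resolve such terms
    # exactly (zero coefficients are null, nonzero ones certain)
    exact = sigma2 < 1e-18 * max(float(np.abs(Y).max(initial=1.0)) ** 2, 1.0)
    sigma2 = np.where(exact, 0.0, sigma2)
    se = np.sqrt(np.outer(np.diag(XtXi), sigma2))
    with np.errstate(divide="ignore", invalid="ignore"):
        tval = beta / se
    pval = 2.0 * stats.t.sf(np.abs(tval), df)
    if exact.any():
        pval[:, exact] = np.where(np.abs(beta[:, exact]) > 1e-8, 0.0, 1.0)
    return beta, se, pval, df


def _zscore(block: pd.DataFrame) -> pd.DataFrame:
    mu = block.mean(axis=0)
    sd = block.std(axis=0, ddof=1)
    return (block - mu) / sd


def fit_factor_model(
    f: FeatureTable,
    factors: Sequence[str] = FACTORS,
    interactions: Sequence[str] = (),
    standardize: bool = True,
    min_samples: int = 8,
) -> pd.DataFrame:
    """Per-sample-type OLS of each feature on the experimental factors.

    Features are z-scored within sample type (unless ``standardize=False``);
    zero-variance or insufficiently observed features are skipped with a
    warning.  Returns a tidy frame with columns
    sample_type, feature, term, beta, se, p, n.
    """
    rows = []
    stypes = f.sample_meta["sample_type"]
    for stype in sorted(stypes.unique()):
        idx = stypes.index[stypes == stype]
        meta = f.sample_meta.loc[idx]
        if len(idx) < min_samples:
            warnings.warn(
                f"sample type {stype!r} has {len(idx)} < {min_samples} samples; skipped",
                QCWarning,
            )
            continue
        X_full = design_matrix(meta, factors=factors, interactions=interactions)
        block = f.data.loc[idx]

        usable, skipped = [], []
        for col in block.columns:
            vals = block[col]
            if vals.isna().any() or vals.nunique() <= 1:
                skipped.append(col)
            else:
                usable.append(col)
        if skipped:
            warnings.warn(
                f"{stype}: skipped {len(skipped)} constant/incomplete feature(s)",
                QCWarning,
            )
        if not usable:
            continue
        Y = block[usable]
        if standardize:
            Y = _zscore(Y)
        beta, se, pval, _ = _ols(X_full.to_numpy(float), Y.to_numpy(float))
        terms = list(X_full.columns)
        for j, feat in enumerate(usable):
            for i, term in enumerate(terms):
                if term == "intercept":
                    continue
                rows.append(
                    (stype, feat, term, beta[i, j], se[i, j], pval[i, j], len(idx))
                )
    return pd.DataFrame(
        rows, columns=["sample_type", "feature", "term", "beta", "se", "p", "n"]
    )


def fit_interaction_model(
    f: FeatureTable,
    interaction: str = "diet:genotype",
    standardize: bool = True,
) -> pd.DataFrame:
    """Factor model augmented with one interaction term.

    Requires a full factorial design (every sex × diet × genotype cell
    occupied) in each sample type; significance is read on the interaction
    term, conventionally at p < 0.05.
    """
    if interaction not in ("diet:genotype", "diet:sex"):
        raise ValueError(f"unsupported interaction {interaction!r}")
    meta = f.sample_meta
    stypes = meta["sample_type"]
    for stype in sorted(stypes.unique()):
        cells = meta.loc[stypes == stype].groupby(list(FACTORS), observed=True).size()
        if len(cells) < 8:
            raise ValueError(
                f"sample type {stype!r} is not a full factorial design "
                f"({len(cells)} of 8 condition cells occupied)"
            )
    return fit_factor_model(
        f, interactions=(interaction,), standardize=standardize
    )


def benjamini_hochberg(p: pd.Series) -> pd.Series:
    """Benjamini–Hochberg adjusted p-values (optional; off by default)."""
    p = p.astype(float)
    n = len(p)
    idx = np.argsort(p.to_numpy())
    out = np.empty_like(p.to_numpy())
    ranked = p.to_numpy()[idx] * n / (np.arange(n) + 1)
    out[idx] = np.minimum.accumulate(ranked[::-1])[::-1]
    return pd.Series(np.clip(out, 0, 1), index=p.index)


def flexibility_score(
    result: pd.DataFrame,
    alpha: float = 0.01,
    adjust: bool = False,
) -> pd.DataFrame:
    """Σ|β| over significant features, per (sample type, term).

    The score is 0 when no feature passes the threshold and is monotone
    non-decreasing in alpha.  ``adjust=True`` applies Benjamini–Hochberg
    within each (sample type, term) before thresholding.
    """
    res = result.copy()
    if adjust:
        res["p"] = res.groupby(["sample_type", "term"])["p"].transform(
            benjamini_hochberg
        )
    sig = res["p"] < alpha
    grouped = res.assign(abs_beta=res["beta"].abs().where(sig, 0.0), sig=sig).groupby(
        ["sample_type", "term"], sort=True
    )
    out = grouped.agg(
        flexibility=("abs_beta", "sum"), n_significant=("sig", "sum")
    ).reset_index()
    out["n_significant"] = out["n_significant"].astype(int)
    return out


def variance_decomposition(
    species_molpct: pd.DataFrame,
    meta: pd.DataFrame,
    covariates: Sequence[str] = ("sample_type",) + FACTORS,
    method: str = "sequential",
) -> pd.Series:
    """Average fraction of per-species variance explained by each covariate.

    Each species' mol% is regressed on all covariates (sample type as
    dummies, factors treatment-coded).  ``method="sequential"`` attributes
    variance by incremental R² in the listed order; ``method="partial"``
    uses the R² drop when the covariate is removed from the full model.
    Fractions plus the residual sum to 1 (sequential) or are reported as-is
    (partial, which need not sum to 1 under non-orthogonality).
    """
    meta = meta.loc[species_molpct.index]
    blocks: dict[str, np.ndarray] = {}
    for cov in covariates:
        if cov in FACTORS:
            blocks[cov] = _binary_code(meta[cov], cov).to_numpy(float)[:, None]
        else:
            dummies = pd.get_dummies(meta[cov], drop_first=True, dtype=float)
            blocks[cov] = dummies.to_numpy()

    Y = species_molpct.to_numpy(float)
    Y = Y - Y.mean(axis=0)
    tss = (Y**2).sum(axis=0)
    ok = tss > 0
    Y = Y[:, ok]
    tss = tss[ok]
    n = Y.shape[0]
    ones = np.ones((n, 1))

    def rss(design: np.ndarray) -> np.ndarray:
        coef, *_ = np.linalg.lstsq(design, Y, rcond=None)
        resid = Y - design @ coef
        return (resid**2).sum(axis=0)

    names = list(covariates)
    fractions = {}
    if method == "sequential":
        prev = tss.copy()
        design = ones
        for cov in names:
            design = np.hstack([design, blocks[cov]])
            cur = rss(design)
            fractions[cov] = float(np.mean((prev - cur) / tss))
            prev = cur
        fractions["residual"] = float(np.mean(prev / tss))
    elif method == "partial":
        full = np.hstack([ones] + [blocks[c] for c in names])
        rss_full = rss(full)
        for cov in names:
            reduced = np.hstack([ones] + [blocks[c] for c in names if c != cov])
            fractions[cov] = float(np.mean((rss(reduced) - rss_full) / tss))
        fractions["residual"] = float(np.mean(rss_full / tss))
    else:
        raise ValueError(f"unknown method {method!r}")
    return pd.Series(fractions)
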