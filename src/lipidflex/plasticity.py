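"""Lipid-class plasticity: scaled-range product scores per class and organ.

Plasticity quantifies how much latitude a lipid class has in its fatty-acid
composition within one sample type: for each (class, sample type) the
min–max range of the weighted-mean double-bond index and of the
weighted-mean carbon index is taken over all samples of that sample type
(all experimental conditions pooled).  Each feature's ranges are then mapped
affinely onto [1, 10] — the widest range in the scaling pool becomes 10, the
narrowest 1 — and the plasticity score is the product of the two scaled
ranges, bounded in [1, 100].

The scaling pool is, by default, the full set of (class, sample type) ranges
per feature ("pooled"); per-organ scaling is available via
``scaling_scope="per_organ"``.  Because of its degenerate, storage-dominated
composition, adipose tissue is excluded by default.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import pandas as pd

from .features import FeatureTable
from .qc import QCWarning

__all__ = ["class_ranges", "scale_ranges", "plasticity_score", "compute_plasticity"]

#: Lyso-lipid classes, omitted from headline plasticity displays by default.
LYSO_CLASSES = ("LPC", "LPC O-", "LPE", "LPE O-", "LPA", "LPG", "LPI", "LPS")


def class_ranges(f: FeatureTable, min_samples: int = 2) -> pd.DataFrame:
    """Raw min–max ranges of the chain indices per (class, sample type).

    Cells where the class is observed in fewer than ``min_samples`` samples
    of the sample type are excluded (range undefined).
    """
    rows = []
    stypes = f.sample_meta["sample_type"]
    for stype, idx in f.data.groupby(stypes, sort=True).groups.items():
        block = f.data.loc[idx]
        for cls in f.classes:
            vals_db = block.get(f"{cls}_db")
            vals_c = block.get(f"{cls}_c")
            if vals_db is None or vals_c is None:
                continue
            vals_db = vals_db.dropna()
            vals_c = vals_c.dropna()
            if len(vals_db) < min_samples or len(vals_c) < min_samples:
                continue
            rows.append(
                (
                    cls,
                    stype,
                    float(vals_db.max() - vals_db.min()),
                    float(vals_c.max() - vals_c.min()),
                )
            )
    return pd.DataFrame(
        rows, columns=["lipid_class", "sample_type", "raw_range_db", "raw_range_c"]
    )


def _affine_scale(raw: pd.Series) -> pd.Series:
    lo, hi = raw.min(), raw.max()
    if hi == lo:
        warnings.warn(
            "all raw ranges equal; scaled ranges degenerate to 1", QCWarning
        )
        return pd.Series(1.0, index=raw.index)
    return 1.0 + 9.0 * (raw - lo) / (hi - lo)


def scale_ranges(raw: pd.DataFrame, scope: str = "pooled") -> pd.DataFrame:
    """Map raw ranges onto [1, 10] per feature type (db and c separately).

    ``scope="pooled"`` scales over all (class, sample type) cells jointly;
    ``scope="per_organ"`` rescales within each sample type.
    """
    out = raw.copy()
    if scope == "pooled":
        out["scaled_db"] = _affine_scale(out["raw_range_db"])
        out["scaled_c"] = _affine_scale(out["raw_range_c"])
    elif scope == "per_organ":
        out["scaled_db"] = out.groupby("sample_type")["raw_range_db"].transform(
            _affine_scale
        )
        out["scaled_c"] = out.groupby("sample_type")["raw_range_c"].transform(
            _affine_scale
        )
    else:
        raise ValueError(f"unknown scaling scope {scope!r}")
    return out


def plasticity_score(scaled: pd.DataFrame) -> pd.DataFrame:
    """Product of the two scaled ranges; cells missing either are omitted."""
    out = scaled.dropna(subset=["scaled_db", "scaled_c"]).copy()
    out["plasticity"] = out["scaled_db"] * out["scaled_c"]
    return out


def compute_plasticity(
    f: FeatureTable,
    scaling_scope: str = "pooled",
    exclude_sample_types: Sequence[str] = ("adipose",),
    exclude_classes: Sequence[str] = (),
    min_samples: int = 2,
) -> pd.DataFrame:
    """Full plasticity computation: ranges → scaling → product score.

    Sample types in ``exclude_sample_types`` (default: adipose) are removed
    before the scaling pool is formed.  ``exclude_classes`` (e.g. the lyso
    classes, for display) filters the output only.
    """
    raw = class_ranges(f, min_samples=min_samples)
    raw = raw[~raw["sample_type"].isin(set(exclude_sample_types))]
    if raw.empty:
        raise ValueError("no (class, sample type) cells with defined ranges")
    scored = plasticity_score(scale_ranges(raw, scope=scaling_scope))
    if exclude_classes:
        scored = scored[~scored["lipid_class"].isin(set(exclude_classes))]
    return scored.reset_index(drop=True)
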