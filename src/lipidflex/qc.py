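"""Quality control for quantitative lipidome matrices.

Implements the acquisition- and dataset-level retention rules of a shotgun
lipidomics workflow:

* blank/signal filtering — per analytical batch, a species is kept only if
  its study-sample signal exceeds a fold threshold over the corresponding
  blank samples (and a signal-to-noise threshold, when S/N metadata is
  available);
* occupancy filtering — per sample type, a species is kept only if it was
  observed above a molar-amount threshold in enough biological replicates of
  at least one experimental condition;
* batch correction — multiplicative per-batch centering of each species so
  that reference-sample medians agree across batches, with an optional
  linear detrend against acquisition order;
* RSD summaries — per-group relative standard deviations (100·sd/mean) with
  medians over species, either for reference samples per batch (technical
  repeatability) or for biological replicate cells per sample type.

All thresholds are strict inequalities: a value exactly at the threshold is
removed.  Filters are idempotent and never increase any amount.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .nomenclature import parse_species

__all__ = [
    "LipidomeMatrix",
    "QCWarning",
    "blank_signal_filter",
    "occupancy_filter",
    "batch_correct",
    "rsd_summary",
]

REQUIRED_META = ("sample_type", "sex", "diet", "genotype", "replicate", "batch", "role")
ROLES = ("study", "blank", "reference")
CONDITION_FACTORS = ("sex", "diet", "genotype")

_LOG_COLUMNS = ("species", "rule", "group", "decision")


class QCWarning(UserWarning):
    """Emitted when a QC rule is skipped or evaluated on degraded input."""


def _empty_log() -> pd.DataFrame:
    return pd.DataFrame(columns=list(_LOG_COLUMNS))


@dataclass
class LipidomeMatrix:
    """Samples × lipid species molar amounts with per-sample metadata.

    Parameters
    ----------
    amounts : DataFrame
        Non-negative molar amounts (pmol, or mol% after normalisation);
        rows are samples, columns are canonical annotation strings.
    sample_meta : DataFrame
        Indexed by sample; must carry ``sample_type, sex, diet, genotype,
        replicate, batch, role`` (role ∈ study/blank/reference).  An optional
        ``acquisition_order`` column enables drift correction and an optional
        ``mouse`` column identifies the animal across sample types.
    species_meta : Series of LipidSpecies
        Parsed annotation per column; built from the column names when
        omitted.
    scale : str
        ``"pmol"`` or ``"mol_percent"``.
    """

    amounts: pd.DataFrame
    sample_meta: pd.DataFrame
    species_meta: Optional[pd.Series] = None
    scale: str = "pmol"
    filter_log: pd.DataFrame = field(default_factory=_empty_log)

    def __post_init__(self):
        if not self.amounts.index.equals(self.sample_meta.index):
            self.sample_meta = self.sample_meta.loc[self.amounts.index]
        missing = [c for c in REQUIRED_META if c not in self.sample_meta.columns]
        if missing:
            raise ValueError(f"sample_meta lacks required columns: {missing}")
        bad_roles = set(self.sample_meta["role"]) - set(ROLES)
        if bad_roles:
            raise ValueError(f"unknown sample roles: {sorted(bad_roles)}")
        vals = self.amounts.to_numpy()
        if np.nanmin(vals, initial=0.0) < 0:
            raise ValueError("amounts must be non-negative")
        if self.species_meta is None:
            self.species_meta = pd.Series(
                {name: parse_species(name) for name in self.amounts.columns}
            )
        if "mouse" not in self.sample_meta.columns:
            meta = self.sample_meta
            self.sample_meta = meta.assign(
                mouse=(
                    meta["genotype"].astype(str)
                    + "-" + meta["diet"].astype(str)
                    + "-" + meta["sex"].astype(str)
                    + "-" + meta["replicate"].astype(str)
                )
            )

    # -- convenience views -------------------------------------------------
    @property
    def samples(self) -> pd.Index:
        return self.amounts.index

    @property
    def species(self) -> pd.Index:
        return self.amounts.columns

    def role_mask(self, role: str) -> pd.Series:
        return self.sample_meta["role"] == role

    @property
    def study(self) -> pd.DataFrame:
        return self.amounts.loc[self.role_mask("study")]

    def subset(
        self,
        samples: Optional[Iterable] = None,
        roles: Optional[Iterable[str]] = None,
        sample_types: Optional[Iterable[str]] = None,
    ) -> "LipidomeMatrix":
        """Return a copy restricted to the requested samples."""
        keep = pd.Series(True, index=self.samples)
        if samples is not None:
            keep &= self.samples.isin(list(samples))
        if roles is not None:
            keep &= self.sample_meta["role"].isin(list(roles))
        if sample_types is not None:
            keep &= self.sample_meta["sample_type"].isin(list(sample_types))
        idx = self.samples[keep]
        return LipidomeMatrix(
            self.amounts.loc[idx].copy(),
            self.sample_meta.loc[idx].copy(),
            self.species_meta,
            scale=self.scale,
            filter_log=self.filter_log.copy(),
        )

    def with_amounts(self, amounts: pd.DataFrame, log: Optional[pd.DataFrame] = None):
        new_log = self.filter_log if log is None else pd.concat(
            [self.filter_log, log], ignore_index=True
        )
        return LipidomeMatrix(
            amounts,
            self.sample_meta.copy(),
            self.species_meta.loc[amounts.columns],
            scale=self.scale,
            filter_log=new_log,
        )

    def write_filter_log(self, path) -> None:
        """Write the accumulated filter decisions as a TSV report."""
        self.filter_log.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# blank / signal filtering
# ---------------------------------------------------------------------------

def blank_signal_filter(
    m: LipidomeMatrix,
    s2n_threshold: float = 5.0,
    blank_fold: float = 5.0,
    s2n: Optional[pd.Series] = None,
) -> LipidomeMatrix:
    """Zero species that fail the blank-fold or signal-to-noise rule per batch.

    For each analytical batch, a species is retained only if the mean study
    signal is *strictly* greater than ``blank_fold`` times the mean amount in
    the batch's blank samples.  When an instrument-side signal-to-noise
    series is supplied (indexed by species), species with S/N not strictly
    above ``s2n_threshold`` are likewise zeroed; S/N cannot be recomputed
    from amounts, so without it that rule is logged as skipped.
    """
    amounts = m.amounts.copy()
    records = []

    if s2n is not None:
        fail = m.species[~(s2n.reindex(m.species).fillna(np.inf) > s2n_threshold)]
        study_idx = m.samples[m.role_mask("study")]
        amounts.loc[study_idx, fail] = 0.0
        records += [(sp, "s2n", "all", "zeroed") for sp in fail]
    else:
        warnings.warn(
            "no signal-to-noise metadata supplied; S/N rule skipped", QCWarning
        )

    meta = m.sample_meta
    for batch, batch_meta in meta.groupby("batch", sort=True):
        blanks = batch_meta.index[batch_meta["role"] == "blank"]
        study = batch_meta.index[batch_meta["role"] == "study"]
        if len(study) == 0:
            continue
        if len(blanks) == 0:
            warnings.warn(
                f"batch {batch!r} has no blank samples; blank rule skipped",
                QCWarning,
            )
            continue
        blank_mean = amounts.loc[blanks].mean(axis=0)
        study_mean = amounts.loc[study].mean(axis=0)
        # species absent from the batch's study samples are a no-op
        fail = m.species[~(study_mean > blank_fold * blank_mean) & (study_mean > 0)]
        if len(fail):
            amounts.loc[study, fail] = 0.0
            records += [(sp, "blank", str(batch), "zeroed") for sp in fail]

    log = pd.DataFrame(records, columns=list(_LOG_COLUMNS))
    return m.with_amounts(amounts, log)


# ---------------------------------------------------------------------------
# occupancy filtering
# ---------------------------------------------------------------------------

def occupancy_filter(
    m: LipidomeMatrix,
    min_amount: float = 1.0,
    min_replicates: int = 2,
    of_replicates: int = 3,
) -> LipidomeMatrix:
    """Keep a species for a sample type only if some condition cell supports it.

    A species is kept for a sample type iff at least one experimental
    condition (sex × diet × genotype cell) has amounts strictly greater than
    ``min_amount`` pmol in at least ``min_replicates`` of its
    ``of_replicates`` biological replicates.  Failing (sample type, species)
    cells are zeroed; species retained by no sample type are dropped.
    """
    amounts = m.amounts.copy()
    meta = m.sample_meta
    study_meta = meta[meta["role"] == "study"]
    records = []

    for stype, type_meta in study_meta.groupby("sample_type", sort=True):
        kept = np.zeros(amounts.shape[1], dtype=bool)
        for _, cell_meta in type_meta.groupby(list(CONDITION_FACTORS), sort=True):
            if len(cell_meta) < of_replicates:
                warnings.warn(
                    f"condition cell in sample type {stype!r} has "
                    f"{len(cell_meta)} < {of_replicates} replicates; "
                    "occupancy evaluated on the available count",
                    QCWarning,
                )
            cell = amounts.loc[cell_meta.index]
            kept |= ((cell > min_amount).sum(axis=0) >= min_replicates).to_numpy()
        fail = m.species[~kept]
        present = amounts.loc[type_meta.index, fail]
        touched = fail[(present > 0).any(axis=0)]
        if len(touched):
            amounts.loc[type_meta.index, touched] = 0.0
            records += [(sp, "occupancy", str(stype), "dropped") for sp in touched]

    study_idx = study_meta.index
    keep_cols = m.species[(amounts.loc[study_idx] > 0).any(axis=0)]
    amounts = amounts[keep_cols]
    log = pd.DataFrame(records, columns=list(_LOG_COLUMNS))
    return m.with_amounts(amounts, log)


# ---------------------------------------------------------------------------
# batch correction
# ---------------------------------------------------------------------------

def batch_correct(m: LipidomeMatrix, detrend: Optional[bool] = None) -> LipidomeMatrix:
    """Align per-species reference medians across batches (multiplicative).

    For each species, all samples of a batch are rescaled so that the batch's
    reference-sample median matches the across-batch median of those medians.
    When ``acquisition_order`` metadata is present (or ``detrend=True``),
    a within-batch linear drift versus acquisition order, fitted on the
    reference samples, is removed first.  Batches with fewer than two
    reference samples are left untouched with a warning.
    """
    amounts = m.amounts.copy()
    meta = m.sample_meta
    has_order = "acquisition_order" in meta.columns
    if detrend is None:
        detrend = has_order
    if detrend and not has_order:
        raise ValueError("detrend requested but no acquisition_order metadata")

    batches = list(meta.groupby("batch", sort=True))
    ref_medians = {}
    for batch, batch_meta in batches:
        refs = batch_meta.index[batch_meta["role"] == "reference"]
        if len(refs) < 2:
            warnings.warn(
                f"batch {batch!r} has {len(refs)} reference samples; "
                "batch correction skipped for this batch",
                QCWarning,
            )
            continue

        if detrend:
            # analytic drift affects the whole run: fit one global log-level
            # slope per batch on the reference samples (robust to per-species
            # noise, unlike per-species line fits through few points)
            order = meta.loc[batch_meta.index, "acquisition_order"].to_numpy(float)
            ref_order = meta.loc[refs, "acquisition_order"].to_numpy(float)
            if np.ptp(ref_order) > 0:
                R = amounts.loc[refs]
                pos = (R > 0).all(axis=0)
                if pos.sum() >= 3:
                    logR = np.log(R.loc[:, pos].to_numpy(float))
                    rel = np.median(logR - logR.mean(axis=0), axis=1)
                    slope = np.polyfit(ref_order, rel, 1)[0]
                    factor = np.exp(slope * (order - ref_order.mean()))
                    amounts.loc[batch_meta.index] = amounts.loc[
                        batch_meta.index
                    ].div(pd.Series(factor, index=batch_meta.index), axis=0)

        ref_medians[batch] = amounts.loc[refs].median(axis=0)

    if ref_medians:
        med = pd.DataFrame(ref_medians)  # species × batch
        target = med.median(axis=1)
        for batch, batch_meta in batches:
            if batch not in ref_medians:
                continue
            bmed = med[batch]
            with np.errstate(divide="ignore", invalid="ignore"):
                factor = target / bmed
            factor = factor.where((bmed > 0) & np.isfinite(factor), 1.0)
            amounts.loc[batch_meta.index] = amounts.loc[batch_meta.index].mul(
                factor, axis=1
            )

    return m.with_amounts(amounts)


# ---------------------------------------------------------------------------
# reproducibility summaries
# ---------------------------------------------------------------------------

def _group_rsds(block: pd.DataFrame) -> pd.Series:
    """Per-species RSD (%) within one replicate group; absent species dropped."""
    mean = block.mean(axis=0)
    sd = block.std(axis=0, ddof=1)
    rsd = 100.0 * sd / mean
    return rsd[mean > 0]


def rsd_summary(
    m: LipidomeMatrix, grouping: str = "biological_triplicates"
) -> pd.DataFrame:
    """Median per-species RSD (%) per group.

    ``grouping="reference_per_batch"`` summarises the technical repeatability
    of the reference samples within each batch.
    ``grouping="biological_triplicates"`` computes RSDs within each
    (sex, diet, genotype) replicate cell of each sample type and reports the
    per-sample-type median over all species × cells.  Groups with fewer than
    two samples are excluded with a warning.
    """
    meta = m.sample_meta
    rows = []
    if grouping == "reference_per_batch":
        refs = meta[meta["role"] == "reference"]
        for batch, batch_meta in refs.groupby("batch", sort=True):
            if len(batch_meta) < 2:
                warnings.warn(
                    f"reference group for batch {batch!r} has <2 samples; excluded",
                    QCWarning,
                )
                continue
            rsds = _group_rsds(m.amounts.loc[batch_meta.index])
            rows.append((batch, float(rsds.median()), len(rsds)))
        out = pd.DataFrame(rows, columns=["batch", "median_rsd_pct", "n_species"])
    elif grouping == "biological_triplicates":
        study = meta[meta["role"] == "study"]
        for stype, type_meta in study.groupby("sample_type", sort=True):
            pooled = []
            for _, cell_meta in type_meta.groupby(list(CONDITION_FACTORS), sort=True):
                if len(cell_meta) < 2:
                    warnings.warn(
                        f"replicate cell in {stype!r} has <2 samples; excluded",
                        QCWarning,
                    )
                    continue
                pooled.append(_group_rsds(m.amounts.loc[cell_meta.index]))
            if not pooled:
                continue
            all_rsds = pd.concat(pooled)
            rows.append((stype, float(all_rsds.median()), len(all_rsds)))
        out = pd.DataFrame(
            rows, columns=["sample_type", "median_rsd_pct", "n_species"]
        )
    else:
        raise ValueError(f"unknown grouping {grouping!r}")
    return out
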