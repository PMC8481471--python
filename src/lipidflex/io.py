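"""Input/output and the end-to-end analysis pipeline.

The on-disk interchange format is a long (tidy) table with columns
``sample, lipid, amount_pmol`` plus a sample-metadata table keyed by
sample; long format is robust to ragged per-organ species sets.  The
pipeline executes the published analysis order — QC filtering and batch
correction, mol% normalisation, feature condensation, then PCA, plasticity,
flexibility (with interaction models) and organ–blood correlations — and
writes tidy TSV results together with a machine-readable manifest.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional, Union

import pandas as pd
import yaml

from . import __version__
from .blood import cluster_organs, organ_blood_matrix
from .features import (
    condense,
    drop_classes,
    fatty_acid_profile,
    normalize_mol_percent,
    pca,
    STORAGE_CLASSES,
)
from .flexibility import (
    fit_factor_model,
    fit_interaction_model,
    flexibility_score,
    variance_decomposition,
)
from .nomenclature import DEFAULT_REGISTRY, LipidNameError, parse_species
from .plasticity import compute_plasticity
from .qc import (
    LipidomeMatrix,
    batch_correct,
    blank_signal_filter,
    occupancy_filter,
    rsd_summary,
)

__all__ = [
    "read_lipidome",
    "write_lipidome",
    "RunConfig",
    "PipelineError",
    "run_pipeline",
]

LONG_COLUMNS = ("sample", "lipid", "amount_pmol")


def read_lipidome(
    long_table: Union[str, Path, pd.DataFrame],
    metadata: Union[str, Path, pd.DataFrame],
    registry=DEFAULT_REGISTRY,
) -> LipidomeMatrix:
    """Build a validated LipidomeMatrix from a long table plus metadata.

    Raises on duplicate (sample, lipid) rows (naming the first offending
    pair), on unparseable lipid annotations (listing all offenders), and on
    samples missing from the metadata.
    """
    if not isinstance(long_table, pd.DataFrame):
        long_table = pd.read_csv(long_table, sep="\t")
    if not isinstance(metadata, pd.DataFrame):
        metadata = pd.read_csv(metadata, sep="\t", index_col=0)
    missing = [c for c in LONG_COLUMNS if c not in long_table.columns]
    if missing:
        raise ValueError(f"long table lacks columns {missing}")

    dup = long_table.duplicated(subset=["sample", "lipid"], keep=False)
    if dup.any():
        first = long_table.loc[dup, ["sample", "lipid"]].iloc[0]
        raise ValueError(
            f"duplicate (sample, lipid) rows, e.g. "
            f"({first['sample']!r}, {first['lipid']!r})"
        )

    bad = []
    species_meta = {}
    for name in pd.unique(long_table["lipid"]):
        try:
            species_meta[name] = parse_species(name, registry)
        except LipidNameError as exc:
            bad.append(f"{name!r} ({exc})")
    if bad:
        raise ValueError("unparseable lipid annotation(s): " + "; ".join(bad))

    unknown = set(long_table["sample"]) - set(metadata.index)
    if unknown:
        raise ValueError(f"samples missing from metadata: {sorted(unknown)}")

    amounts = (
        long_table.pivot(index="sample", columns="lipid", values="amount_pmol")
        .fillna(0.0)
        .sort_index()
    )
    amounts = amounts[sorted(amounts.columns)]
    meta = metadata.loc[amounts.index]
    return LipidomeMatrix(amounts, meta, pd.Series(species_meta).loc[amounts.columns])


def write_lipidome(m: LipidomeMatrix, table_path, metadata_path) -> None:
    """Write the long-format table and metadata (inverse of read_lipidome)."""
    long_table = (
        m.amounts.rename_axis(index="sample", columns="lipid")
        .stack()
        .rename("amount_pmol")
        .reset_index()
    )
    long_table = long_table[long_table["amount_pmol"] != 0]
    long_table.to_csv(table_path, sep="\t", index=False)
    m.sample_meta.rename_axis(index="sample").to_csv(metadata_path, sep="\t")


@dataclass
class RunConfig:
    """Thresholds, exclusions and paths for a full pipeline run."""

    input_table: Optional[str] = None
    metadata: Optional[str] = None
    output_dir: str = "lipidflex_results"
    min_amount: float = 1.0
    min_replicates: int = 2
    of_replicates: int = 3
    s2n_threshold: float = 5.0
    blank_fold: float = 5.0
    alpha_main: float = 0.01
    alpha_interaction: float = 0.05
    scaling_scope: str = "pooled"
    plasticity_exclude: tuple = ("adipose",)
    pca_exclude_storage: tuple = STORAGE_CLASSES
    blood_reference: str = "plasma"
    interactions: tuple = ("diet:genotype", "diet:sex")
    variance_method: str = "sequential"
    seed: int = 0

    def __post_init__(self):
        for name in ("min_amount", "s2n_threshold", "blank_fold",
                     "alpha_main", "alpha_interaction"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        for key in ("plasticity_exclude", "pca_exclude_storage", "interactions"):
            if key in data and data[key] is not None:
                data[key] = tuple(data[key])
        return cls(**data)

    def to_yaml(self, path) -> None:
        data = asdict(self)
        for key, val in data.items():
            if isinstance(val, tuple):
                data[key] = list(val)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


def run_pipeline(
    config: RunConfig, matrix: Optional[LipidomeMatrix] = None
) -> dict:
    """Execute qc → normalise → condense → downstream analyses.

    Returns the result objects keyed by stage and writes TSV outputs plus a
    manifest to ``config.output_dir``.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    results: dict = {}

    def stage(name):
        def wrap(fn, *args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return wrap

    if matrix is None:
        matrix = stage("load")(read_lipidome, config.input_table, config.metadata)

    # ---- QC -------------------------------------------------------------
    run = stage("qc")
    m = run(blank_signal_filter, matrix,
            s2n_threshold=config.s2n_threshold, blank_fold=config.blank_fold)
    m = run(batch_correct, m)
    m = run(occupancy_filter, m,
            min_amount=config.min_amount,
            min_replicates=config.min_replicates,
            of_replicates=config.of_replicates)
    rsd_bio = run(rsd_summary, m, "biological_triplicates")
    rsd_ref = run(rsd_summary, m, "reference_per_batch")
    m.write_filter_log(outdir / "filter_log.tsv")
    rsd_bio.to_csv(outdir / "rsd_biological.tsv", sep="\t", index=False)
    rsd_ref.to_csv(outdir / "rsd_reference.tsv", sep="\t", index=False)
    results["qc"] = m
    results["rsd_biological"] = rsd_bio
    results["rsd_reference"] = rsd_ref

    # ---- features -------------------------------------------------------
    run = stage("features")
    study = run(m.subset, roles=("study",))
    molpct = run(normalize_mol_percent, study)
    features = run(condense, molpct)
    features.to_tidy().to_csv(outdir / "features.tsv", sep="\t", index=False)
    fa = run(fatty_acid_profile, molpct)
    fa.to_csv(outdir / "fatty_acid_profile.tsv", sep="\t")
    results["molpct"] = molpct
    results["features"] = features
    results["fatty_acid_profile"] = fa

    run = stage("pca")
    pca_all = run(pca, molpct.amounts)
    membranes = run(normalize_mol_percent,
                    drop_classes(study, config.pca_exclude_storage))
    pca_membrane = run(pca, membranes.amounts)
    pca_all.scores.iloc[:, :10].to_csv(outdir / "pca_scores.tsv", sep="\t")
    results["pca"] = pca_all
    results["pca_membrane"] = pca_membrane

    # ---- plasticity -----------------------------------------------------
    run = stage("plasticity")
    plast = run(compute_plasticity, features,
                scaling_scope=config.scaling_scope,
                exclude_sample_types=config.plasticity_exclude)
    plast.to_csv(outdir / "plasticity.tsv", sep="\t", index=False)
    results["plasticity"] = plast

    # ---- flexibility ----------------------------------------------------
    run = stage("flexibility")
    regression = run(fit_factor_model, features)
    flex = run(flexibility_score, regression, alpha=config.alpha_main)
    regression.to_csv(outdir / "regression.tsv", sep="\t", index=False)
    flex.to_csv(outdir / "flexibility.tsv", sep="\t", index=False)
    results["regression"] = regression
    results["flexibility"] = flex

    interactions = []
    for inter in config.interactions:
        res = run(fit_interaction_model, features, inter)
        res = res[res["term"] == inter]
        interactions.append(res)
    if interactions:
        inter_df = pd.concat(interactions, ignore_index=True)
        inter_df.to_csv(outdir / "interactions.tsv", sep="\t", index=False)
        results["interactions"] = inter_df

    vd = run(variance_decomposition, molpct.amounts, molpct.sample_meta,
             method=config.variance_method)
    vd.rename_axis("covariate").rename("variance_fraction").to_csv(
        outdir / "variance_decomposition.tsv", sep="\t"
    )
    results["variance_decomposition"] = vd

    # ---- blood correlations --------------------------------------------
    run = stage("blood_correlation")
    stypes = sorted(molpct.sample_meta["sample_type"].unique())
    ref = config.blood_reference
    if ref in stypes:
        blood = molpct.subset(sample_types=(ref,))
        records, fractions = [], {}
        for organ in stypes:
            if organ == ref:
                continue
            organ_m = molpct.subset(sample_types=(organ,))
            recs, frac = run(organ_blood_matrix, organ_m, blood,
                             config.alpha_interaction)
            records.append(recs)
            fractions[organ] = frac
        corr = pd.concat(records, ignore_index=True)
        corr.to_csv(outdir / "blood_correlations.tsv", sep="\t", index=False)
        frac_df = pd.Series(fractions, name="fraction_positive").rename_axis("organ")
        frac_df.to_csv(outdir / "blood_fraction_positive.tsv", sep="\t")
        clust = run(cluster_organs, corr, ref)
        (outdir / "cluster_order.txt").write_text("\n".join(clust.leaf_order) + "\n")
        results["blood_correlations"] = corr
        results["blood_fraction_positive"] = frac_df
        results["clustering"] = clust
    else:
        warnings.warn(f"blood reference {ref!r} not among sample types; "
                      "correlation stage skipped")

    manifest = {
        "package": "lipidflex",
        "version": __version__,
        "seed": config.seed,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()},
        "n_samples": int(matrix.amounts.shape[0]),
        "n_species_input": int(matrix.amounts.shape[1]),
        "n_species_kept": int(m.amounts.shape[1]),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    results["manifest"] = manifest
    return results
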