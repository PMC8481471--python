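"""Factor regressions, flexibility score and variance decomposition."""

import warnings

import numpy as np
import pandas as pd
import pytest

from lipidflex import (
    FeatureTable,
    design_matrix,
    fit_factor_model,
    fit_interaction_model,
    flexibility_score,
    variance_decomposition,
)
from lipidflex.qc import QCWarning


def _factorial_meta(n_rep=3, stype="liver"):
    rows = []
    for genotype in ("inbred", "outbred"):
        for diet in ("low_protein", "high_protein"):
            for sex in ("F", "M"):
                for rep in range(1, n_rep + 1):
                    rows.append((stype, sex, diet, genotype, rep, "b", "study"))
    meta = pd.DataFrame(
        rows,
        columns=["sample_type", "sex", "diet", "genotype", "replicate",
                 "batch", "role"],
        index=[f"s{i}" for i in range(len(rows))],
    )
    return meta


def _table(meta, data):
    return FeatureTable(pd.DataFrame(data, index=meta.index), meta, [])


class TestDesignMatrix:
    def test_treatment_coding_reference_levels(self):
        meta = _factorial_meta()
        X = design_matrix(meta)
        assert list(X.columns) == ["intercept", "sex", "diet", "genotype"]
        assert X.loc[meta["sex"] == "F", "sex"].eq(0).all()
        assert X.loc[meta["diet"] == "high_protein", "diet"].eq(1).all()
        assert X.loc[meta["genotype"] == "outbred", "genotype"].eq(1).all()

    def test_constant_factor_dropped_with_warning(self):
        meta = _factorial_meta()
        meta["genotype"] = "inbred"
        with pytest.warns(QCWarning):
            X = design_matrix(meta)
        assert "genotype" not in X.columns


class TestFactorModel:
    def test_noiseless_effect_recovered_exactly(self):
        meta = _factorial_meta()
        diet = (meta["diet"] == "high_protein").astype(float)
        f = _table(meta, {"TAG": 1.5 * diet})
        res = fit_factor_model(f, standardize=False)
        row = res[(res["feature"] == "TAG") & (res["term"] == "diet")].iloc[0]
        assert row["beta"] == pytest.approx(1.5, abs=1e-10)
        assert row["p"] == 0.0
        null = res[(res["feature"] == "TAG") & (res["term"] == "sex")].iloc[0]
        assert null["beta"] == pytest.approx(0.0, abs=1e-10)
        assert null["p"] == 1.0

    def test_matches_statsmodels_oracle(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(2)
        meta = _factorial_meta()
        y = rng.normal(size=len(meta))
        f = _table(meta, {"PC": y})
        res = fit_factor_model(f, standardize=False).set_index("term")
        X = design_matrix(meta)
        fit = sm.OLS(y, X.to_numpy()).fit()
        for i, term in enumerate(X.columns):
            if term == "intercept":
                continue
            assert res.loc[term, "beta"] == pytest.approx(fit.params[i], rel=1e-8)
            assert res.loc[term, "se"] == pytest.approx(fit.bse[i], rel=1e-8)
            assert res.loc[term, "p"] == pytest.approx(fit.pvalues[i], rel=1e-6)

    def test_features_zscored_before_fit(self):
        rng = np.random.default_rng(3)
        meta = _factorial_meta()
        raw = 100 + 50 * rng.normal(size=len(meta))
        res_raw = fit_factor_model(_table(meta, {"PC": raw}))
        res_scaled = fit_factor_model(_table(meta, {"PC": (raw - raw.mean())}))
        # invariance of z-scored betas under affine transforms of the feature
        pd.testing.assert_series_equal(
            res_raw["beta"], res_scaled["beta"], atol=1e-12, rtol=0
        )

    def test_constant_feature_skipped_with_warning(self):
        meta = _factorial_meta()
        with pytest.warns(QCWarning):
            res = fit_factor_model(_table(meta, {"PC": np.ones(len(meta))}))
        assert res.empty


class TestFlexibilityScore:
    def _result(self, betas_ps):
        return pd.DataFrame(
            [
                ("liver", f"f{i}", "diet", b, 0.1, p, 24)
                for i, (b, p) in enumerate(betas_ps)
            ],
            columns=["sample_type", "feature", "term", "beta", "se", "p", "n"],
        )

    def test_no_significant_features_scores_zero(self):
        out = flexibility_score(self._result([(1.0, 0.5), (2.0, 0.02)]), alpha=0.01)
        assert out["flexibility"].iloc[0] == 0.0
        assert out["n_significant"].iloc[0] == 0

    def test_absolute_sum(self):
        out = flexibility_score(
            self._result([(0.5, 0.001), (-0.7, 0.005), (3.0, 0.5)]), alpha=0.01
        )
        assert out["flexibility"].iloc[0] == pytest.approx(1.2)
        assert out["n_significant"].iloc[0] == 2

    def test_monotone_in_alpha(self, study_features):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = fit_factor_model(study_features)
        scores = [
            flexibility_score(res, alpha=a).set_index(["sample_type", "term"])[
                "flexibility"
            ]
            for a in (0.001, 0.01, 0.05, 1.0)
        ]
        for lo, hi in zip(scores, scores[1:]):
            assert (hi - lo >= -1e-12).all()

    def test_alpha_one_sums_all_betas(self, study_features):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = fit_factor_model(study_features)
        out = flexibility_score(res, alpha=1.1).set_index(["sample_type", "term"])
        manual = res.assign(a=res["beta"].abs()).groupby(["sample_type", "term"])[
            "a"
        ].sum()
        assert np.allclose(out["flexibility"], manual.loc[out.index])


class TestInteractionModel:
    def test_noiseless_interaction_equals_difference_of_diet_effects(self):
        meta = _factorial_meta()
        diet = (meta["diet"] == "high_protein").astype(float)
        inbred = (meta["genotype"] == "inbred").astype(float)
        # diet effect of +2 in inbred mice only
        f = _table(meta, {"Cer": 2.0 * diet * inbred})
        res = fit_interaction_model(f, "diet:genotype", standardize=False)
        res = res.set_index("term")
        # with treatment coding (inbred = reference): diet beta is the
        # reference-genotype diet effect, the interaction the difference
        assert res.loc["diet", "beta"] == pytest.approx(2.0, abs=1e-10)
        assert res.loc["diet:genotype", "beta"] == pytest.approx(-2.0, abs=1e-10)
        assert res.loc["diet:genotype", "p"] == 0.0

    def test_non_factorial_design_rejected(self):
        meta = _factorial_meta()
        meta = meta[~((meta["diet"] == "high_protein") & (meta["genotype"] == "outbred"))]
        f = FeatureTable(
            pd.DataFrame({"PC": np.arange(len(meta), dtype=float)}, index=meta.index),
            meta,
            [],
        )
        with pytest.raises(ValueError, match="factorial"):
            fit_interaction_model(f, "diet:genotype")

    def test_opposite_sign_diet_effects_detected(self):
        rng = np.random.default_rng(4)
        meta = _factorial_meta()
        diet = (meta["diet"] == "high_protein").to_numpy(float)
        outbred = (meta["genotype"] == "outbred").to_numpy(float)
        hits = 0
        n_sim = 200
        for _ in range(n_sim):
            y = 1.5 * diet * (1 - outbred) - 1.5 * diet * outbred + rng.normal(
                size=len(meta)
            )
            f = _table(meta, {"PC": y})
            res = fit_interaction_model(f, "diet:genotype", standardize=False)
            p = res.set_index("term").loc["diet:genotype", "p"]
            hits += p < 0.05
        assert hits / n_sim > 0.8  # power at a 3-sd genotype difference


class TestVarianceDecomposition:
    def test_fractions_sum_to_one(self, default_dataset):
        from lipidflex import normalize_mol_percent

        matrix, _ = default_dataset
        m = normalize_mol_percent(matrix.subset(roles=("study",)))
        out = variance_decomposition(m.amounts, m.sample_meta)
        assert out.between(0, 1).all()
        assert out.sum() == pytest.approx(1.0, abs=1e-8)
        # organ identity dominates a multi-organ lipidome
        assert out["sample_type"] > 0.5

    def test_pure_organ_effect_limit(self):
        rng = np.random.default_rng(5)
        metas = []
        for stype in ("brain", "liver"):
            m = _factorial_meta(stype=stype)
            m.index = [f"{stype}_{i}" for i in range(len(m))]
            metas.append(m)
        meta = pd.concat(metas)
        organ = (meta["sample_type"] == "brain").to_numpy(float)
        Y = pd.DataFrame(
            {f"sp{i}": 10 * organ + rng.normal(0, 1e-6, len(meta)) for i in range(5)},
            index=meta.index,
        )
        out = variance_decomposition(Y, meta)
        assert out["sample_type"] == pytest.approx(1.0, abs=1e-6)
        assert out["residual"] == pytest.approx(0.0, abs=1e-6)

    def test_known_variance_shares_recovered(self):
        # balanced two-level factors with controlled variance contributions
        rng = np.random.default_rng(6)
        metas = []
        for stype in ("brain", "liver", "lung", "kidney"):
            m = _factorial_meta(stype=stype)
            m.index = [f"{stype}_{i}" for i in range(len(m))]
            metas.append(m)
        meta = pd.concat(metas)
        n = len(meta)
        organ_codes = pd.factorize(meta["sample_type"])[0].astype(float)
        organ = (organ_codes - organ_codes.mean()) / organ_codes.std()
        sex = ((meta["sex"] == "M").to_numpy(float) - 0.5) * 2
        shares = {"sample_type": 0.6, "sex": 0.1}
        resid = 1 - sum(shares.values())
        Y = pd.DataFrame(
            {
                f"sp{i}": np.sqrt(shares["sample_type"]) * organ
                + np.sqrt(shares["sex"]) * sex
                + np.sqrt(resid) * rng.normal(size=n)
                for i in range(300)
            },
            index=meta.index,
        )
        out = variance_decomposition(Y, meta)
        assert out["sample_type"] == pytest.approx(0.6, abs=0.05)
        assert out["sex"] == pytest.approx(0.1, abs=0.05)

    def test_sequential_and_partial_agree_on_balanced_design(self, default_dataset):
        from lipidflex import normalize_mol_percent

        matrix, _ = default_dataset
        m = normalize_mol_percent(matrix.subset(roles=("study",)))
        seq = variance_decomposition(m.amounts, m.sample_meta, method="sequential")
        par = variance_decomposition(m.amounts, m.sample_meta, method="partial")
        # balanced factorial: covariate blocks are orthogonal
        assert np.allclose(seq[:-1], par[:-1], atol=1e-8)
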