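"""QC filters, batch correction and RSD summaries."""

import warnings

import numpy as np
import pandas as pd
import pytest

from lipidflex import (
    LipidomeMatrix,
    QCWarning,
    batch_correct,
    blank_signal_filter,
    occupancy_filter,
    rsd_summary,
)
from lipidflex.simulate import default_config, generate


def _tiny_matrix(study, blank=None, reference=None, batch="b1"):
    """Assemble a one-condition LipidomeMatrix from per-sample dicts."""
    frames, meta = {}, []
    for i, row in enumerate(study):
        sid = f"s{i}"
        frames[sid] = row
        meta.append((sid, "liver", "F" if i % 2 else "M", "low_protein",
                     "inbred", i % 3 + 1, batch, "study"))
    for i, row in enumerate(blank or []):
        sid = f"bl{i}"
        frames[sid] = row
        meta.append((sid, "blank", "F", "low_protein", "inbred", i + 1, batch, "blank"))
    for i, row in enumerate(reference or []):
        sid = f"r{i}"
        frames[sid] = row
        meta.append((sid, "reference", "F", "low_protein", "inbred", i + 1,
                     batch, "reference"))
    amounts = pd.DataFrame(frames).T.fillna(0.0)
    meta = pd.DataFrame(
        meta,
        columns=["sample", "sample_type", "sex", "diet", "genotype",
                 "replicate", "batch", "role"],
    ).set_index("sample")
    return LipidomeMatrix(amounts, meta)


class TestBlankFilter:
    def test_exact_fold_boundary_removed(self):
        # study amount exactly 5x mean blank fails the strict inequality
        m = _tiny_matrix(
            study=[{"PC 34:1;0": 50.0, "PE 38:4;0": 51.0}] * 3,
            blank=[{"PC 34:1;0": 10.0, "PE 38:4;0": 10.0}],
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out = blank_signal_filter(m)
        assert (out.amounts.loc[out.role_mask("study"), "PC 34:1;0"] == 0).all()
        assert (out.amounts.loc[out.role_mask("study"), "PE 38:4;0"] > 0).all()

    def test_zero_blank_retains_species(self):
        m = _tiny_matrix(study=[{"PC 34:1;0": 0.5}] * 3, blank=[{"PC 34:1;0": 0.0}])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out = blank_signal_filter(m)
        assert (out.amounts["PC 34:1;0"] == m.amounts["PC 34:1;0"]).all()

    def test_no_blanks_warns_not_silent(self):
        m = _tiny_matrix(study=[{"PC 34:1;0": 5.0}] * 3)
        with pytest.warns(QCWarning):
            out = blank_signal_filter(m)
        assert (out.amounts == m.amounts).all().all()

    def test_matches_bruteforce_on_qc_fixture(self, qc_fixture):
        matrix, truth = qc_fixture
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out = blank_signal_filter(matrix)
        # brute-force re-check of every species against the rule
        meta = matrix.sample_meta
        study = meta.index[meta["role"] == "study"]
        blanks = meta.index[meta["role"] == "blank"]
        removed = set()
        for sp in matrix.species:
            study_mean = matrix.amounts.loc[study, sp].mean()
            blank_mean = matrix.amounts.loc[blanks, sp].mean()
            if study_mean > 0 and not study_mean > 5 * blank_mean:
                removed.add(sp)
        assert removed == truth.qc["blank_removed"]
        zeroed = {
            sp for sp in matrix.species
            if (out.amounts.loc[study, sp] == 0).all()
            and (matrix.amounts.loc[study, sp] > 0).any()
        }
        assert zeroed == removed


class TestOccupancyFilter:
    def test_exact_amount_boundary_removed(self):
        m = _tiny_matrix(study=[{"PC 34:1;0": 1.0, "PE 38:4;0": 1.1}] * 3)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out = occupancy_filter(m)
        assert "PC 34:1;0" not in out.species
        assert "PE 38:4;0" in out.species

    def test_two_of_three_in_one_cell_suffices(self):
        rows = [{"PC 34:1;0": 5.0}, {"PC 34:1;0": 5.0}, {"PC 34:1;0": 0.0}]
        m = _tiny_matrix(study=rows)
        m.sample_meta["sex"] = "F"  # one condition cell of three replicates
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out = occupancy_filter(m)
        assert "PC 34:1;0" in out.species

    def test_matches_bruteforce_on_qc_fixture(self, qc_fixture):
        matrix, truth = qc_fixture
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out = occupancy_filter(matrix)
        meta = matrix.sample_meta
        study = meta[meta["role"] == "study"]
        kept = set()
        for sp in matrix.species:
            for _, cell in study.groupby(["sex", "diet", "genotype"]):
                if (matrix.amounts.loc[cell.index, sp] > 1.0).sum() >= 2:
                    kept.add(sp)
                    break
        assert kept == truth.qc["kept"] | truth.qc["blank_removed"]
        assert set(out.species) == kept


class TestFilterProperties:
    def test_idempotent_and_non_increasing(self, qc_fixture):
        matrix, _ = qc_fixture
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            once = occupancy_filter(blank_signal_filter(matrix))
            twice = occupancy_filter(blank_signal_filter(once))
        pd.testing.assert_frame_equal(once.amounts, twice.amounts)
        shared = once.species
        assert (once.amounts[shared] <= matrix.amounts[shared] + 1e-12).all().all()
        assert set(once.species) <= set(matrix.species)

    def test_filter_log_records_decisions(self, qc_fixture):
        matrix, truth = qc_fixture
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out = occupancy_filter(blank_signal_filter(matrix))
        log = out.filter_log
        assert set(log.columns) == {"species", "rule", "group", "decision"}
        assert truth.qc["blank_removed"] <= set(log[log["rule"] == "blank"]["species"])
        assert truth.qc["occupancy_removed"] <= set(
            log[log["rule"] == "occupancy"]["species"]
        )


class TestBatchCorrect:
    def test_reference_medians_aligned_across_batches(self):
        rng = np.random.default_rng(0)
        base = rng.uniform(5, 50, size=4)
        sp = ["PC 34:1;0", "PC 36:2;0", "PE 38:4;0", "SM 34:1;2"]
        rows, meta = {}, []
        for batch, factor in (("b1", 1.0), ("b2", 2.0)):
            for i in range(3):
                sid = f"{batch}_ref{i}"
                rows[sid] = dict(zip(sp, base * factor * rng.uniform(0.97, 1.03, 4)))
                meta.append((sid, "reference", "F", "low_protein", "inbred",
                             i + 1, batch, "reference"))
            for i in range(4):
                sid = f"{batch}_s{i}"
                rows[sid] = dict(zip(sp, base * factor * rng.uniform(0.9, 1.1, 4)))
                meta.append((sid, "liver", "F", "low_protein", "inbred",
                             i + 1, batch, "study"))
        amounts = pd.DataFrame(rows).T
        meta = pd.DataFrame(meta, columns=["sample", "sample_type", "sex", "diet",
                                           "genotype", "replicate", "batch", "role"]
                            ).set_index("sample")
        m = LipidomeMatrix(amounts, meta)
        out = batch_correct(m)
        refs = out.sample_meta["role"] == "reference"
        med = out.amounts[refs.values].groupby(out.sample_meta.loc[refs.values, "batch"]).median()
        assert np.allclose(med.loc["b1"], med.loc["b2"], rtol=0.05)

    def test_single_batch_without_refs_is_identity(self):
        m = _tiny_matrix(study=[{"PC 34:1;0": 5.0}] * 3)
        with pytest.warns(QCWarning):
            out = batch_correct(m)
        pd.testing.assert_frame_equal(out.amounts, m.amounts)

    def test_linear_drift_reduces_reference_rsd(self):
        cfg = default_config(seed=7, organs=("liver", "plasma"))
        cfg.drift_slope = 0.10
        drifted, _ = generate(cfg)
        cfg0 = default_config(seed=7, organs=("liver", "plasma"))
        clean, _ = generate(cfg0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            corrected = batch_correct(drifted)
            rsd_drift = rsd_summary(drifted, "reference_per_batch")
            rsd_corr = rsd_summary(corrected, "reference_per_batch")
        assert (
            rsd_corr["median_rsd_pct"].median()
            < rsd_drift["median_rsd_pct"].median()
        )


class TestRSDSummary:
    def test_identical_replicates_zero(self):
        m = _tiny_matrix(study=[{"PC 34:1;0": 5.0, "PE 38:4;0": 7.0}] * 3)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out = rsd_summary(m, "biological_triplicates")
        assert out["median_rsd_pct"].iloc[0] == 0.0

    def test_two_point_rsd_by_hand(self):
        # values (1, 3): sd = sqrt(2), mean = 2 -> RSD 70.7%
        m = _tiny_matrix(
            study=[{"PC 34:1;0": 1.0}, {"PC 34:1;0": 3.0}],
            reference=[{"PC 34:1;0": 1.0}, {"PC 34:1;0": 3.0}],
        )
        out = rsd_summary(m, "reference_per_batch")
        assert out["median_rsd_pct"].iloc[0] == pytest.approx(70.71067, abs=1e-3)

    def test_injected_noise_recovered(self):
        # lognormal sigma chosen to target ~15% median RSD in triplicates:
        # the n=3 sd estimate has median ~0.83 sigma, hence sigma = 0.18
        rng = np.random.default_rng(3)
        sigma = 0.18
        sp = [f"PC {30 + i // 20}:{i % 7};0" for i in range(400)]
        base = rng.uniform(5, 100, 400)
        rows = [dict(zip(sp, base * np.exp(rng.normal(0, sigma, 400))))
                for _ in range(3)]
        m = _tiny_matrix(study=rows)
        m.sample_meta["sex"] = "F"  # one replicate cell
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out = rsd_summary(m, "biological_triplicates")
        assert out["median_rsd_pct"].iloc[0] == pytest.approx(15.0, abs=3.0)

    def test_generator_rsds_in_study_band(self, default_dataset):
        matrix, _ = default_dataset
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out = rsd_summary(matrix, "biological_triplicates")
        assert out["median_rsd_pct"].between(10, 30).all()
        assert len(out) == 10
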