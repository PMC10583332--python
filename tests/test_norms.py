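"""Robust normative procedure: regression, z-scoring, one-sided exclusion,
refit, and the frozen-model contract."""

import numpy as np
import pandas as pd
import pytest

from noddinorms.cohort import CohortConfig, generate_participants, generate_roi_values
from noddinorms.norms import (MetricRegression, NormativeModel, build_norms,
                              compute_zscores, fit_metric_regression,
                              flag_outliers)


def _model_with(b0=0.5, b_age=-0.002, b_sex=0.01, rmse=0.05, age_center=65.0):
    reg = MetricRegression(b0=b0, b_age=b_age, b_sex=b_sex, rmse=rmse, n_fit=100)
    return NormativeModel(regressions={("hippocampus", "NDI", "GM"): reg},
                          age_center=age_center)


class TestMetricRegression:
    def test_exact_linear_data_recovered_to_machine_precision(self, rng):
        ages = rng.uniform(50, 90, 60)
        sexes = (rng.random(60) < 0.5).astype(float)
        sexes[:2] = [0, 1]  # both sexes guaranteed
        values = 0.55 - 0.002 * (ages - 65.0) + 0.01 * sexes
        fit = fit_metric_regression(values, ages, sexes, 65.0)
        assert fit.b0 == pytest.approx(0.55, abs=1e-12)
        assert fit.b_age == pytest.approx(-0.002, abs=1e-14)
        assert fit.b_sex == pytest.approx(0.01, abs=1e-12)
        assert fit.rmse == pytest.approx(0.0, abs=1e-10)

    def test_noisy_recovery_within_three_se(self, rng):
        n = 200
        ages = rng.uniform(50, 90, n)
        sexes = (rng.random(n) < 0.5).astype(float)
        noise_sd = 0.05
        values = 0.55 - 0.002 * (ages - 65.0) + 0.01 * sexes \
            + rng.normal(0, noise_sd, n)
        fit = fit_metric_regression(values, ages, sexes, 65.0)
        X = np.column_stack([np.ones(n), ages - 65.0, sexes])
        cov = noise_sd ** 2 * np.linalg.inv(X.T @ X)
        for est, truth, var in zip((fit.b0, fit.b_age, fit.b_sex),
                                   (0.55, -0.002, 0.01), np.diag(cov)):
            assert abs(est - truth) < 3 * np.sqrt(var)

    def test_constant_values_give_zero_slopes(self, rng):
        ages = rng.uniform(50, 90, 30)
        sexes = np.r_[np.zeros(15), np.ones(15)]
        fit = fit_metric_regression(np.full(30, 0.5), ages, sexes, 65.0)
        assert fit.b0 == pytest.approx(0.5)
        assert fit.b_age == pytest.approx(0.0, abs=1e-15)
        assert fit.rmse == pytest.approx(0.0, abs=1e-12)

    def test_single_sex_unidentifiable(self, rng):
        ages = rng.uniform(50, 90, 30)
        with pytest.raises(ValueError, match="both sexes"):
            fit_metric_regression(np.full(30, 0.5), ages, np.zeros(30), 65.0)

    def test_too_few_observations(self):
        with pytest.raises(ValueError, match="at least"):
            fit_metric_regression(np.ones(5), np.arange(5.0),
                                  np.r_[0, 1, 0, 1, 0.0], 65.0)


class TestComputeZscores:
    def _roi_row(self, value):
        return pd.DataFrame({"participant_id": ["P1"],
                             "roi_name": ["hippocampus"], "metric": ["NDI"],
                             "tissue_class": ["GM"], "value": [value]})

    def test_direct_substitution(self):
        """Female, 10 years above center, observed 0.44: predicted
        0.5 - 0.02 + 0.01 = 0.49, z = (0.44 - 0.49)/0.05 = -1."""
        model = _model_with()
        participants = pd.DataFrame({"participant_id": ["P1"], "age": [75.0],
                                     "sex": [1]})
        z = compute_zscores(model, self._roi_row(0.44), participants)
        assert z["z"].iloc[0] == pytest.approx(-1.0)

    def test_observed_equals_predicted_gives_zero(self):
        model = _model_with()
        participants = pd.DataFrame({"participant_id": ["P1"], "age": [75.0],
                                     "sex": [1]})
        z = compute_zscores(model, self._roi_row(0.49), participants)
        assert z["z"].iloc[0] == pytest.approx(0.0)

    def test_male_at_center_one_rmse_above(self):
        model = _model_with()
        participants = pd.DataFrame({"participant_id": ["P1"], "age": [65.0],
                                     "sex": [0]})
        z = compute_zscores(model, self._roi_row(0.55), participants)
        assert z["z"].iloc[0] == pytest.approx(1.0)

    def test_zero_rmse_rejected(self):
        model = _model_with(rmse=0.0)
        participants = pd.DataFrame({"participant_id": ["P1"], "age": [65.0],
                                     "sex": [0]})
        with pytest.raises(ValueError, match="RMSE"):
            compute_zscores(model, self._roi_row(0.5), participants)

    def test_missing_demographics_rejected(self):
        model = _model_with()
        participants = pd.DataFrame({"participant_id": ["P1"],
                                     "age": [np.nan], "sex": [0]})
        with pytest.raises(ValueError, match="P1"):
            compute_zscores(model, self._roi_row(0.5), participants)

    def test_monotone_in_observed_value(self):
        model = _model_with()
        participants = pd.DataFrame({"participant_id": ["P1"], "age": [70.0],
                                     "sex": [1]})
        z_lo = compute_zscores(model, self._roi_row(0.40), participants)
        z_hi = compute_zscores(model, self._roi_row(0.41), participants)
        assert z_lo["z"].iloc[0] < z_hi["z"].iloc[0]


class TestFlagOutliers:
    def _ztable(self, zmap):
        rows = []
        for pid, cells in zmap.items():
            for (roi, metric), z in cells.items():
                rows.append({"participant_id": pid, "roi_name": roi,
                             "metric": metric, "tissue_class": "GM", "z": z})
        return pd.DataFrame(rows)

    def test_boundary_is_inclusive_below_only(self):
        zt = self._ztable({
            "exact": {("a", "NDI"): -1.5, ("b", "NDI"): 0.0},
            "high": {("a", "NDI"): 2.5, ("b", "NDI"): 2.5},
            "near": {("a", "NDI"): -1.49, ("b", "NDI"): -1.49},
        })
        flagged = flag_outliers(zt, threshold=1.5)
        assert set(flagged) == {"exact"}
        assert flagged["exact"][0][:2] == ("a", "NDI")

    def test_triggers_record_every_offending_cell(self):
        zt = self._ztable({"p": {("a", "NDI"): -2.0, ("b", "ODI"): -1.6,
                                 ("c", "NDI"): 0.5}})
        flagged = flag_outliers(zt)
        assert len(flagged["p"]) == 2


class TestBuildNorms:
    def _cohort(self, n=240, seed=21, **kwargs):
        cfg = CohortConfig(seed=seed, n_per_group={("CU", "A-T-"): n},
                           group_effects={}, **kwargs)
        participants = generate_participants(cfg)
        roi, truth = generate_roi_values(participants, cfg)
        return cfg, participants, roi, truth

    def test_planted_low_outliers_are_flagged_and_refit_unbiased(self):
        """Ten subjects planted exactly 3 residual-SD low in one ROI are
        flagged; the refit slope stays within 3 SE of the generator truth."""
        cfg, participants, roi, truth = self._cohort(n=240, seed=31)
        planted = participants["participant_id"].iloc[:10].tolist()
        cell = (roi["roi_name"] == "hippocampus") & (roi["metric"] == "NDI")
        hit = cell & roi["participant_id"].isin(planted)
        exp = truth.loc[hit, "expected"].to_numpy()
        sd = truth.loc[hit, "residual_sd"].to_numpy()
        roi = roi.copy()
        roi.loc[hit, "value"] = exp - 3.0 * sd
        model, _ = build_norms(roi, participants)
        assert sum(pid in model.excluded for pid in planted) >= 9
        reg = model.regressions[("hippocampus", "NDI", "GM")]
        n_fit = reg.n_fit
        se_slope = reg.rmse / np.sqrt(n_fit) / participants["age"].std()
        assert abs(reg.b_age - cfg.age_slope[("GM", "NDI")]) < 3 * se_slope

    def test_null_flagged_fraction_matches_monte_carlo_oracle(self):
        """With no planted outliers the flagged fraction matches a direct
        Monte-Carlo simulation of the generator's correlated residual model
        within binomial 99% bounds."""
        from scipy import stats
        rng = np.random.default_rng(77)
        rho, cells, reps = 0.6, 24, 4000
        shared = rng.normal(size=(reps, 1))
        eps = rng.normal(size=(reps, cells))
        z = np.sqrt(rho) * shared + np.sqrt(1 - rho) * eps
        p_flag = (z.min(axis=1) <= -1.5).mean()

        flagged_total, n_total = 0, 0
        for seed in range(5):
            _, participants, roi, _ = self._cohort(n=240, seed=100 + seed)
            model, _ = build_norms(roi, participants)
            flagged_total += len(model.excluded)
            n_total += 240
        lo, hi = stats.binom.ppf([0.005, 0.995], n_total, p_flag)
        assert lo <= flagged_total <= hi

    def test_infinite_threshold_reduces_to_single_pass(self):
        _, participants, roi, _ = self._cohort(n=120, seed=41)
        model_inf, z_inf = build_norms(roi, participants,
                                       exclusion_threshold=np.inf)
        assert model_inf.excluded == {}
        assert len(model_inf.normative_ids_final) == 120
        # equals a plain single fit: z-scores of the full set have mean ~0
        g = z_inf.groupby(["roi_name", "metric"])["z"].mean()
        assert g.abs().max() < 1e-10

    def test_final_set_zscore_identity(self):
        """On the refit normative subset, per-cell z means vanish and SDs sit
        near 1 (OLS residual identity)."""
        _, participants, roi, _ = self._cohort(n=240, seed=51)
        model, ztable = build_norms(roi, participants)
        zf = ztable[ztable["participant_id"].isin(model.normative_ids_final)]
        g = zf.groupby(["roi_name", "metric"])["z"]
        assert g.mean().abs().max() < 1e-10
        assert g.std().min() > 0.95 and g.std().max() < 1.05

    def test_frozen_model_property(self):
        """Z-scores of non-normative participants are unchanged when more
        non-normative participants are appended: norms depend only on the
        normative set."""
        cfg = CohortConfig(seed=61, n_per_group={("CU", "A-T-"): 150,
                                                 ("MCI", "A+T+"): 5})
        participants = generate_participants(cfg)
        roi, _ = generate_roi_values(participants, cfg)
        model_a, z_a = build_norms(roi, participants)

        # Append extra non-normative participants (cloned MCI rows under new
        # ids); the normative set is untouched.
        mci = participants[participants["diagnosis"] == "MCI"]
        extra = mci.copy()
        extra["participant_id"] = [f"X{i}" for i in range(len(extra))]
        extra["age"] = extra["age"] + 1.0
        roi_extra = roi[roi["participant_id"].isin(mci["participant_id"])].copy()
        rename = dict(zip(mci["participant_id"], extra["participant_id"]))
        roi_extra["participant_id"] = roi_extra["participant_id"].map(rename)
        participants_b = pd.concat([participants, extra], ignore_index=True)
        roi_b = pd.concat([roi, roi_extra], ignore_index=True)
        model_b, z_b = build_norms(roi_b, participants_b)

        mci_ids = participants[participants["diagnosis"] == "MCI"]["participant_id"]
        za = z_a[z_a["participant_id"].isin(mci_ids)].set_index(
            ["participant_id", "roi_name", "metric"])["z"]
        zb = z_b[z_b["participant_id"].isin(mci_ids)].set_index(
            ["participant_id", "roi_name", "metric"])["z"]
        common = za.index.intersection(zb.index)
        assert len(common) == len(mci_ids) * 24
        assert np.allclose(za.loc[common], zb.loc[common])

    def test_excluded_plus_final_partitions_initial(self):
        _, participants, roi, _ = self._cohort(n=150, seed=71)
        model, _ = build_norms(roi, participants)
        assert set(model.normative_ids_final) | set(model.excluded) \
            == set(model.normative_ids_initial)
        assert not set(model.normative_ids_final) & set(model.excluded)

    def test_requires_normative_subset(self):
        cfg = CohortConfig(seed=81, n_per_group={("MCI", "A+T+"): 20})
        participants = generate_participants(cfg)
        roi, _ = generate_roi_values(participants, cfg)
        with pytest.raises(ValueError, match="A-T-"):
            build_norms(roi, participants)


def test_norms_json_roundtrip(tmp_path):
    cfg = CohortConfig(seed=91, n_per_group={("CU", "A-T-"): 120})
    participants = generate_participants(cfg)
    roi, _ = generate_roi_values(participants, cfg)
    model, ztable = build_norms(roi, participants)
    path = tmp_path / "norms.json"
    model.to_json(path)
    restored = NormativeModel.from_json(path)
    assert restored.regressions == model.regressions
    assert restored.age_center == model.age_center
    z2 = compute_zscores(restored, roi, participants)
    assert np.allclose(z2["z"], ztable["z"])
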