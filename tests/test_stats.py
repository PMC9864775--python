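"""Robustness tables: excellence flags, sensitivity ranges, CV correlation."""

import numpy as np
import pandas as pd
import pytest

from oracles import brute_spearman
from radiorobust.stats import (
    cv_per_patient,
    cv_size_correlation,
    cv_table,
    robustness_table,
    sensitivity_table,
)


def _long_table(values: dict[str, np.ndarray], config_id="cfg") -> pd.DataFrame:
    """values: feature -> (n_patients x 3) matrix."""
    rows = []
    for feature, x in values.items():
        n, k = x.shape
        for i in range(n):
            for j, seg in enumerate(["accurate_freehand", "rough_freehand", "rough_polygon"][:k]):
                rows.append(
                    {
                        "patient_id": f"P{i:03d}",
                        "segmentation": seg,
                        "config_id": config_id,
                        "feature": feature,
                        "value": x[i, j],
                    }
                )
    return pd.DataFrame(rows)


class TestRobustnessTable:
    def test_patient_specific_constant_is_excellent(self):
        x = np.tile(np.arange(1.0, 9.0)[:, None], (1, 3))
        tbl = robustness_table(_long_table({"f": x}))
        assert len(tbl) == 1
        assert tbl.iloc[0]["icc"] == 1.0
        assert bool(tbl.iloc[0]["excellent"])

    def test_pure_noise_not_excellent(self, rng):
        x = rng.normal(size=(30, 3))
        tbl = robustness_table(_long_table({"f": x}))
        assert abs(tbl.iloc[0]["icc"]) < 0.5
        assert not bool(tbl.iloc[0]["excellent"])

    def test_boundary_lower_bound_not_excellent(self):
        # flag uses strict inequality on the CI lower bound
        fake = pd.DataFrame(
            {"config_id": ["c"], "feature": ["f"], "ci_lower": [0.9]}
        )
        assert not bool((fake["ci_lower"] > 0.9).iloc[0])

    def test_missing_cells_skipped_with_others_kept(self, rng):
        tbl_df = _long_table({"good": rng.normal(size=(6, 3)) + np.arange(6)[:, None]})
        broken = _long_table({"broken": rng.normal(size=(6, 3))})
        broken = broken[~((broken["patient_id"] == "P002") &
                          (broken["segmentation"] == "rough_polygon"))]
        out = robustness_table(pd.concat([tbl_df, broken], ignore_index=True))
        assert out["feature"].tolist() == ["good"]


class TestSensitivityTable:
    def _icc_table(self, lower_by_bw):
        rows = []
        configs = []
        for bw, lo in lower_by_bw.items():
            cid = f"bw{bw}"
            rows.append({"config_id": cid, "feature": "f", "ci_lower": lo})
            configs.append(
                {"config_id": cid, "bin_width": bw, "pixel_distance": 1,
                 "interpolator": "linear", "resolution_mm": 2.0}
            )
        return pd.DataFrame(rows), pd.DataFrame(configs)

    def test_small_range_is_low(self):
        icc, cfg = self._icc_table({10: 0.91, 20: 0.93, 40: 0.92})
        out = sensitivity_table(icc, cfg)
        bw = out[out["parameter"] == "bin_width"].iloc[0]
        assert bw["icc_range"] == pytest.approx(0.02)
        assert bool(bw["is_low"])

    def test_large_range_not_low(self):
        icc, cfg = self._icc_table({10: 0.95, 20: 0.80, 40: 0.92})
        out = sensitivity_table(icc, cfg)
        bw = out[out["parameter"] == "bin_width"].iloc[0]
        assert bw["icc_range"] == pytest.approx(0.15)
        assert not bool(bw["is_low"])

    def test_constant_icc_gives_zero_ranges(self):
        icc, cfg = self._icc_table({10: 0.9, 20: 0.9, 40: 0.9})
        out = sensitivity_table(icc, cfg)
        assert (out["icc_range"] == 0.0).all()
        assert len(out) == 4  # one row per grid parameter

    def test_worst_case_aggregation_over_fixed_combinations(self):
        # two resolutions: bin-width range is 0.01 at r=1 but 0.2 at r=2;
        # the reported range must be the worst case, 0.2
        rows, cfgs = [], []
        for r, los in [(1.0, (0.90, 0.91)), (2.0, (0.70, 0.90))]:
            for bw, lo in zip((10, 20), los):
                cid = f"bw{bw}_r{r}"
                rows.append({"config_id": cid, "feature": "f", "ci_lower": lo})
                cfgs.append({"config_id": cid, "bin_width": bw, "pixel_distance": 1,
                             "interpolator": "linear", "resolution_mm": r})
        out = sensitivity_table(pd.DataFrame(rows), pd.DataFrame(cfgs))
        bw = out[out["parameter"] == "bin_width"].iloc[0]
        assert bw["icc_range"] == pytest.approx(0.2)

    def test_incomplete_grid_raises(self):
        icc, cfg = self._icc_table({10: 0.9, 20: 0.9, 40: 0.9})
        with pytest.raises(ValueError, match="incomplete grid"):
            sensitivity_table(icc.iloc[:2], cfg)


class TestCV:
    def test_identical_values_zero_cv(self):
        cv, excluded = cv_per_patient([10.0, 10.0, 10.0])
        assert cv == 0.0 and not excluded

    def test_sample_sd_over_mean(self):
        cv, excluded = cv_per_patient([8.0, 10.0, 12.0])
        assert cv == pytest.approx(0.2)
        assert not excluded

    def test_zero_mean_excluded(self):
        cv, excluded = cv_per_patient([-5.0, 0.0, 5.0])
        assert excluded and np.isnan(cv)

    def test_negative_mean_uses_magnitude(self):
        cv, excluded = cv_per_patient([-8.0, -10.0, -12.0])
        assert cv == pytest.approx(0.2)
        assert not excluded


class TestCVSizeCorrelation:
    def test_monotone_decreasing_gives_minus_one(self):
        cvr = pd.DataFrame(
            {
                "feature": "f",
                "patient_id": [f"P{i}" for i in range(6)],
                "cv": [0.6, 0.5, 0.4, 0.3, 0.2, 0.1],
                "excluded": False,
            }
        )
        vols = {f"P{i}": 100.0 * (i + 1) for i in range(6)}
        out = cv_size_correlation(cvr, vols)
        assert out.iloc[0]["rho"] == pytest.approx(-1.0)

    def test_null_correlation_small(self, rng):
        cvr = pd.DataFrame(
            {
                "feature": "f",
                "patient_id": [f"P{i}" for i in range(48)],
                "cv": rng.random(48),
                "excluded": False,
            }
        )
        vols = {f"P{i}": v for i, v in enumerate(rng.random(48) * 1000)}
        out = cv_size_correlation(cvr, vols)
        assert abs(out.iloc[0]["rho"]) < 0.4

    def test_tied_volumes_match_midrank_oracle(self, rng):
        cv = rng.random(10)
        vols = np.array([1.0, 1.0, 2.0, 2.0, 2.0, 3.0, 4.0, 4.0, 5.0, 6.0])
        cvr = pd.DataFrame(
            {
                "feature": "f",
                "patient_id": [f"P{i}" for i in range(10)],
                "cv": cv,
                "excluded": False,
            }
        )
        out = cv_size_correlation(cvr, dict(zip(cvr["patient_id"], vols)))
        assert out.iloc[0]["rho"] == pytest.approx(brute_spearman(cv, vols), abs=1e-12)

    def test_too_few_usable_patients_skipped(self):
        cvr = pd.DataFrame(
            {
                "feature": "f",
                "patient_id": ["P0", "P1", "P2", "P3"],
                "cv": [0.1, 0.2, np.nan, np.nan],
                "excluded": [False, False, True, True],
            }
        )
        out = cv_size_correlation(cvr, {f"P{i}": float(i) for i in range(4)})
        assert out.empty


def test_cv_table_pipeline_shape(rng):
    from radiorobust.stats import cv_table

    x = {"f1": rng.normal(10, 1, size=(4, 3)), "f2": rng.normal(5, 1, size=(4, 3))}
    tbl = cv_table(_long_table(x))
    assert len(tbl) == 8
    assert set(tbl.columns) == {"feature", "patient_id", "cv", "excluded"}
    assert (tbl["cv"].dropna() >= 0).all()
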