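"""Agreement and sensitivity statistics for feature robustness.

The robustness statistic is the lower bound of the 95% confidence interval
of the two-way random-effects, absolute-agreement, single-measure intraclass
correlation coefficient — ICC(A,1) in McGraw & Wong's taxonomy, ICC(2,1) in
Shrout & Fleiss's — with the three segmentation styles playing the role of
raters.  A feature is "excellent" when that lower bound strictly exceeds 0.9.
Sensitivity of a feature to one preprocessing parameter is the worst-case
(max over the other parameters held fixed) range of its ICC lower bound as
that parameter varies; below 0.1 counts as low.  Per-patient dispersion uses
the coefficient of variation (SD across the three segmentations over their
mean), correlated with lesion size by Spearman rank correlation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

ICC_MODEL_LABEL = "two-way random, absolute agreement, single measure (A,1)"

#: grid parameters a sensitivity range is computed over
GRID_PARAMETERS = ("bin_width", "pixel_distance", "interpolator", "resolution_mm")


@dataclass(frozen=True)
class ICCResult:
    icc: float
    ci_lower: float
    ci_upper: float
    ms_rows: float
    ms_cols: float
    ms_error: float
    n: int
    k: int
    model_label: str = ICC_MODEL_LABEL


def _mean_squares(x: np.ndarray) -> tuple[float, float, float]:
    """Two-way ANOVA mean squares: rows (subjects), columns (raters), error."""
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((x - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    return ss_rows / (n - 1), ss_cols / (k - 1), ss_err / ((n - 1) * (k - 1))


def icc_agreement(ratings: np.ndarray, alpha: float = 0.05) -> ICCResult:
    """ICC(A,1) with its F-based confidence interval.

    ``ratings`` is an (n subjects x k raters) matrix.  The point estimate is

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE))

    and the interval follows McGraw & Wong's construction for this model,
    with Satterthwaite degrees of freedom for the denominator.
    """
    x = np.asarray(ratings, dtype=np.float64)
    if x.ndim != 2:
        raise ValueError("ratings must be a 2D (subjects x raters) array")
    n, k = x.shape
    if n < 2 or k < 2:
        raise ValueError(f"need at least 2 subjects and 2 raters, got {n}x{k}")
    if not np.all(np.isfinite(x)):
        raise ValueError("ratings contain non-finite values")
    if np.ptp(x) == 0:
        raise ValueError("all ratings identical: agreement undefined")

    msr, msc, mse = _mean_squares(x)
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    icc = (msr - mse) / denom

    if (mse == 0 and msc == 0) or icc >= 1.0:
        # perfect agreement (possibly up to rounding): interval degenerates at 1
        return ICCResult(1.0, 1.0, 1.0, msr, msc, mse, n, k)

    # Satterthwaite df for the combined denominator mean square
    a = (k * icc) / (n * (1.0 - icc))
    b = 1.0 + (k * icc * (n - 1.0)) / (n * (1.0 - icc))
    if mse > 0:
        v_num = (a * msc + b * mse) ** 2
        v_den = (a * msc) ** 2 / (k - 1.0) + (b * mse) ** 2 / ((n - 1.0) * (k - 1.0))
        v = v_num / v_den
    else:
        v = k - 1.0
    fl = sps.f.ppf(1.0 - alpha / 2.0, n - 1.0, v)
    fu = sps.f.ppf(1.0 - alpha / 2.0, v, n - 1.0)
    lower = (n * (msr - fl * mse)) / (
        fl * (k * msc + (k * n - k - n) * mse) + n * msr
    )
    upper = (n * (fu * msr - mse)) / (
        k * msc + (k * n - k - n) * mse + n * fu * msr
    )
    lower, upper = min(lower, icc), max(upper, icc)
    return ICCResult(float(icc), float(lower), float(min(upper, 1.0)),
                     msr, msc, mse, n, k)


# ---------------------------------------------------------------------------
# Tables over a FeatureTable (long-form DataFrame)


def robustness_table(
    feature_table: pd.DataFrame,
    icc_excellent: float = 0.9,
) -> pd.DataFrame:
    """Per (config, feature) ICC across segmentation styles.

    ``feature_table`` is long-form with columns ``patient_id``,
    ``segmentation``, ``config_id``, ``feature``, ``value``.  Features whose
    ratings matrix has missing cells, non-finite entries, or zero spread are
    skipped with a log entry.  Returns columns: config_id, feature, icc,
    ci_lower, ci_upper, ms_rows, ms_cols, ms_error, excellent, model.
    """
    required = {"patient_id", "segmentation", "config_id", "feature", "value"}
    missing = required - set(feature_table.columns)
    if missing:
        raise ValueError(f"feature table missing columns: {sorted(missing)}")

    wide_all = feature_table.pivot_table(
        index=["config_id", "feature", "patient_id"],
        columns="segmentation",
        values="value",
        dropna=False,
    )
    rows = []
    for (config_id, feature), wide in wide_all.groupby(level=[0, 1], sort=True):
        x = wide.to_numpy()
        if np.isnan(x).any():
            logger.warning("skipping %s/%s: missing cells", config_id, feature)
            continue
        try:
            res = icc_agreement(x)
        except ValueError as e:
            logger.warning("skipping %s/%s: %s", config_id, feature, e)
            continue
        rows.append(
            {
                "config_id": config_id,
                "feature": feature,
                "icc": res.icc,
                "ci_lower": res.ci_lower,
                "ci_upper": res.ci_upper,
                "ms_rows": res.ms_rows,
                "ms_cols": res.ms_cols,
                "ms_error": res.ms_error,
                "excellent": bool(res.ci_lower > icc_excellent),
                "model": res.model_label,
            }
        )
    return pd.DataFrame(rows)


def sensitivity_table(
    icc_table: pd.DataFrame,
    configs: pd.DataFrame,
    sensitivity_low: float = 0.1,
    on_incomplete: str = "raise",
) -> pd.DataFrame:
    """Worst-case ICC-lower-bound range per (feature, grid parameter).

    ``icc_table`` comes from :func:`robustness_table`; ``configs`` maps
    ``config_id`` to the four parameter columns.  For each parameter, within
    each combination of the other three, the range (max - min) of ``ci_lower``
    across the varied parameter's values is computed; the maximum such range
    is reported.  A feature lacking an ICC value at some grid point (e.g.
    skipped because agreement was undefined there) makes the factorial
    incomplete: with ``on_incomplete="raise"`` this is an error naming the
    missing cells, with ``"skip"`` the feature is dropped with a log entry.
    """
    if on_incomplete not in ("raise", "skip"):
        raise ValueError("on_incomplete must be 'raise' or 'skip'")
    merged = icc_table.merge(configs, on="config_id", validate="many_to_one")
    n_expected = int(np.prod([configs[p].nunique() for p in GRID_PARAMETERS]))
    rows = []
    for feature, grp in merged.groupby("feature", sort=True):
        if grp["config_id"].nunique() != n_expected:
            missing = sorted(set(configs["config_id"]) - set(grp["config_id"]))
            msg = (
                f"feature {feature!r}: incomplete grid ({len(missing)} of "
                f"{n_expected} configs missing an ICC value: {missing[:5]}...)"
            )
            if on_incomplete == "raise":
                raise ValueError(msg)
            logger.warning("%s -- dropped from sensitivity table", msg)
            continue
        for param in GRID_PARAMETERS:
            others = [p for p in GRID_PARAMETERS if p != param]
            ranges = grp.groupby(others)["ci_lower"].agg(lambda s: s.max() - s.min())
            icc_range = float(ranges.max())
            rows.append(
                {
                    "feature": feature,
                    "parameter": param,
                    "icc_range": icc_range,
                    "is_low": bool(icc_range < sensitivity_low),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Coefficient of variation vs lesion size


def cv_per_patient(values: np.ndarray, rel_tol: float = 1e-8, scale: float | None = None) -> tuple[float, bool]:
    """CV of one feature across a patient's segmentations: sample SD / |mean|.

    Returns ``(cv, excluded)``.  Excluded (cv = NaN) when |mean| is below
    ``rel_tol`` times ``scale`` (a cohort-level magnitude for the feature;
    defaults to the in-patient magnitude), where the ratio is unstable.
    Negative means use |mean| so features that are legitimately negative
    (e.g. cluster shade) still get a dispersion measure.
    """
    v = np.asarray(values, dtype=np.float64)
    mean = v.mean()
    if scale is None:
        scale = float(np.max(np.abs(v))) or 1.0
    if abs(mean) < rel_tol * scale:
        return float("nan"), True
    return float(v.std(ddof=1) / abs(mean)), False


def cv_table(feature_table: pd.DataFrame, config_id: str | None = None) -> pd.DataFrame:
    """Per (feature, patient) CV across the three segmentations."""
    tbl = feature_table
    if config_id is not None:
        tbl = tbl[tbl["config_id"] == config_id]
    wide = tbl.pivot_table(
        index=["feature", "patient_id"], columns="segmentation", values="value"
    )
    mean = wide.mean(axis=1)
    sd = wide.std(axis=1, ddof=1)
    scale = (
        tbl.assign(absval=tbl["value"].abs())
        .groupby("feature")["absval"]
        .max()
        .replace(0.0, 1.0)
    )
    tol = 1e-8 * scale.reindex(wide.index.get_level_values("feature")).to_numpy()
    excluded = mean.abs().to_numpy() < tol
    cv = np.where(excluded, np.nan, sd.to_numpy() / np.abs(mean.to_numpy()))
    out = wide.index.to_frame(index=False)
    out["cv"] = cv
    out["excluded"] = excluded
    return out


def cv_size_correlation(
    cv_records: pd.DataFrame, volumes: pd.Series | dict
) -> pd.DataFrame:
    """Spearman correlation of per-patient CV with lesion voxel volume.

    ``volumes`` maps patient_id to the accurate-segmentation VoxelVolume.
    Features with fewer than 3 usable (unexcluded) patients are skipped with
    a log entry.  Ties are mid-ranked (Spearman's default).
    """
    volumes = pd.Series(volumes)
    rows = []
    for feature, grp in cv_records.groupby("feature", sort=True):
        usable = grp[~grp["excluded"]].dropna(subset=["cv"])
        if len(usable) < 3:
            logger.warning("skipping %s: only %d usable patients", feature, len(usable))
            continue
        if usable["cv"].nunique() == 1:
            logger.warning("skipping %s: constant CV, rank correlation undefined", feature)
            continue
        vols = volumes.loc[usable["patient_id"]].to_numpy()
        rho, pval = sps.spearmanr(usable["cv"].to_numpy(), vols)
        rows.append(
            {
                "feature": feature,
                "rho": float(rho),
                "p_value": float(pval),
                "n_patients": len(usable),
            }
        )
    return pd.DataFrame(rows)
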