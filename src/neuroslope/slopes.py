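"""Per-subject slope summaries, inverse normal transform, residualization.

The accelerated cognitive decline slope is defined as the residual of the
(inverse-normal transformed) median measured slope after regressing out the
transformed median model-predicted normal-aging slope — what is left of a
subject's decline once the expected aging trend is accounted for.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy import stats


def inverse_normal_transform(values, k: float = 3.0 / 8.0) -> np.ndarray:
    """Rank-based inverse normal transform (Blom offset k = 3/8 by default).

    Maps value with rank r (average ranks for ties) to
    ``Phi^-1((r - k) / (n - 2k + 1))``. Strictly monotone in the ranks;
    for odd n without ties the sample median maps to exactly 0.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or values.size < 2:
        raise ValueError("need a 1-D array of at least 2 values")
    if not np.isfinite(values).all():
        raise ValueError("values must be finite")
    if np.all(values == values[0]):
        raise ValueError("all values identical: ranks are degenerate")
    ranks = stats.rankdata(values, method="average")
    return stats.norm.ppf((ranks - k) / (values.size - 2 * k + 1))


def accelerated_slope_residuals(
    measured,
    predicted,
    covariates: np.ndarray | None = None,
    transform: bool = True,
) -> np.ndarray:
    """Residuals of INT(measured) on INT(predicted) [+ covariates] via OLS.

    An intercept is always included. Residuals are orthogonal to every
    regressor. ``transform=False`` skips the inverse normal transform (for
    already-transformed inputs).
    """
    measured = np.asarray(measured, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if measured.shape != predicted.shape:
        raise ValueError("measured and predicted must have equal length")
    y = inverse_normal_transform(measured) if transform else measured
    x = inverse_normal_transform(predicted) if transform else predicted

    cols = [np.ones_like(y), x]
    if covariates is not None:
        covariates = np.atleast_2d(np.asarray(covariates, dtype=float))
        if covariates.shape[0] != y.size:
            covariates = covariates.T
        cols.extend(covariates.T)
    design = np.column_stack(cols)
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("rank-deficient design matrix")
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    return y - design @ beta


def group_summaries(records: pd.DataFrame, value_col: str, group_col: str = "diagnosis"):
    """Per-group medians/IQRs plus pairwise two-sided rank-sum tests.

    Returns ``(summary, pairwise)`` DataFrames. The rank-sum test is the
    two-sided Mann-Whitney/Wilcoxon test, exact for small groups without
    ties (scipy's method="auto").
    """
    groups = {g: sub[value_col].to_numpy() for g, sub in records.groupby(group_col)}
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for g, v in groups.items():
        if len(v) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 records")

    summary = pd.DataFrame(
        {
            group_col: list(groups),
            "n": [len(v) for v in groups.values()],
            "median": [float(np.median(v)) for v in groups.values()],
            "q1": [float(np.percentile(v, 25)) for v in groups.values()],
            "q3": [float(np.percentile(v, 75)) for v in groups.values()],
        }
    )
    rows = []
    for a, b in itertools.combinations(sorted(groups), 2):
        res = stats.mannwhitneyu(groups[a], groups[b], alternative="two-sided")
        rows.append((a, b, float(res.statistic), float(res.pvalue)))
    pairwise = pd.DataFrame(rows, columns=["group_a", "group_b", "statistic", "p_value"])
    return summary, pairwise


def build_slope_records(
    measured_by_subject: pd.Series,
    predicted_by_subject: pd.Series,
    visits: pd.DataFrame,
    covariates: np.ndarray | None = None,
) -> pd.DataFrame:
    """Assemble per-subject slope records with the accelerated slope.

    ``visits`` supplies median age, last diagnosis, and (if present) sex.
    Only subjects present in both slope series are kept, in sorted order.
    """
    common = sorted(set(measured_by_subject.index) & set(predicted_by_subject.index))
    measured = measured_by_subject.loc[common]
    predicted = predicted_by_subject.loc[common]

    by_subj = visits[visits["subject_id"].isin(common)].groupby("subject_id")
    med_age = by_subj["age_years"].median().loc[common]
    last_dx = by_subj["diagnosis"].last().loc[common]

    accel = accelerated_slope_residuals(
        measured.to_numpy(), predicted.to_numpy(), covariates=covariates
    )
    records = pd.DataFrame(
        {
            "subject_id": common,
            "median_measured_slope": measured.to_numpy(),
            "median_predicted_slope": predicted.to_numpy(),
            "accelerated_slope": accel,
            "median_age_years": med_age.to_numpy(),
            "diagnosis": last_dx.to_numpy(),
        }
    )
    if "sex" in visits.columns:
        records["sex"] = by_subj["sex"].first().loc[common].to_numpy()
    return records
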