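"""Score-scan matching, inclusion rules, and longitudinal pair enumeration.

A cognitive assessment is linked to the nearest scan within a 45-day window
(ties go to the earlier scan). Subjects enter the analysis only if they keep
at least three matched visits and their diagnosis sequence never moves
backward along CN -> MCI -> AD. Pairs are all ordered visit combinations
(adjacent or not — the longitudinal "skip connection") whose time gap lies
in [6, 24] months, one month being 30.4375 days; both bounds inclusive.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

DAYS_PER_MONTH = 30.4375
DAYS_PER_YEAR = 365.25

DX_ORDER = {"CN": 0, "MCI": 1, "AD": 2}

#: Y = 1 when |delta score| >= this many ADAS-Cog13 points (clinically
#: meaningful change); configurable everywhere it is used.
DEFAULT_CHANGE_THRESHOLD = 4.0

PAIR_COLUMNS = [
    "subject_id",
    "day_i",
    "day_j",
    "scan_id_i",
    "scan_id_j",
    "score_i",
    "score_j",
    "delta_t_years",
    "delta_score",
    "label",
]


def match_scores_to_scans(
    visits: pd.DataFrame, scans: pd.DataFrame, window_days: float = 45.0
) -> pd.DataFrame:
    """Link each assessment to its nearest scan within ``window_days``.

    Unmatched assessments are dropped; the count is recorded in
    ``result.attrs['n_unmatched']``. Ties between two equidistant scans go
    to the earlier scan.
    """
    for name, df, day_col in (("visits", visits, "visit_day"), ("scans", scans, "scan_day")):
        if df.duplicated(subset=["subject_id", day_col]).any():
            raise ValueError(f"duplicate (subject_id, {day_col}) keys in {name}")

    scan_groups = {sid: sub for sid, sub in scans.groupby("subject_id")}
    rows = []
    n_unmatched = 0
    for _, visit in visits.iterrows():
        sub = scan_groups.get(visit.subject_id)
        if sub is None:
            n_unmatched += 1
            continue
        gaps = (sub["scan_day"] - visit.visit_day).abs()
        best = gaps.min()
        if best > window_days:
            n_unmatched += 1
            continue
        cand = sub.loc[gaps == best]
        chosen = cand.loc[cand["scan_day"].idxmin()]  # tie: earlier scan wins
        row = visit.to_dict()
        row.update(scan_day=chosen["scan_day"], scan_id=chosen["scan_id"], match_gap_days=best)
        rows.append(row)
    out = pd.DataFrame(rows).reset_index(drop=True)
    out.attrs["n_unmatched"] = n_unmatched
    return out


def filter_subjects(
    matched: pd.DataFrame, min_visits: int = 3, require_monotone_dx: bool = True
) -> pd.DataFrame:
    """Apply the inclusion rules; idempotent.

    Keeps subjects with at least ``min_visits`` matched visits whose
    diagnosis sequence (in time order) never steps backward along
    CN -> MCI -> AD.
    """
    unknown = set(matched["diagnosis"]) - set(DX_ORDER)
    if unknown:
        raise ValueError(f"unknown diagnosis labels: {sorted(unknown)}")

    keep = []
    for sid, sub in matched.groupby("subject_id", sort=False):
        sub = sub.sort_values("visit_day")
        if len(sub) < min_visits:
            continue
        codes = sub["diagnosis"].map(DX_ORDER).to_numpy()
        if require_monotone_dx and np.any(np.diff(codes) < 0):
            continue
        keep.append(sid)
    out = matched[matched["subject_id"].isin(keep)].copy()
    return out.sort_values(["subject_id", "visit_day"]).reset_index(drop=True)


def measured_slope(delta_score: float, delta_t_years: float) -> float:
    """Cognitive decline slope of one pair, in points per year."""
    if delta_t_years <= 0:
        raise ValueError("delta_t_years must be positive")
    return delta_score / delta_t_years


def label_pair(delta_score: float, change_threshold: float = DEFAULT_CHANGE_THRESHOLD) -> int:
    """Y = 1 iff |delta score| >= threshold (different-class pair), else 0."""
    if change_threshold < 0:
        raise ValueError("change_threshold must be >= 0")
    return int(abs(delta_score) >= change_threshold)


def build_pairs(
    matched: pd.DataFrame,
    min_gap_months: float = 6.0,
    max_gap_months: float = 24.0,
    change_threshold: float = DEFAULT_CHANGE_THRESHOLD,
) -> pd.DataFrame:
    """Enumerate all ordered visit pairs with gap in the configured window.

    All i<j combinations are considered, not only adjacent visits. The gap
    window is inclusive on both ends. Rows are ordered by
    (subject_id, day_i, day_j).
    """
    if min_gap_months >= max_gap_months:
        raise ValueError("min_gap_months must be < max_gap_months")
    lo_days = min_gap_months * DAYS_PER_MONTH
    hi_days = max_gap_months * DAYS_PER_MONTH

    rows = []
    for sid, sub in matched.groupby("subject_id", sort=True):
        sub = sub.sort_values("visit_day")
        recs = sub.to_dict("records")
        for a in range(len(recs)):
            for b in range(a + 1, len(recs)):
                vi, vj = recs[a], recs[b]
                gap = vj["visit_day"] - vi["visit_day"]
                if not (lo_days <= gap <= hi_days):
                    continue
                dscore = vj["adas13"] - vi["adas13"]
                rows.append(
                    (
                        sid,
                        vi["visit_day"],
                        vj["visit_day"],
                        vi.get("scan_id"),
                        vj.get("scan_id"),
                        vi["adas13"],
                        vj["adas13"],
                        gap / DAYS_PER_YEAR,
                        dscore,
                        label_pair(dscore, change_threshold),
                    )
                )
    pairs = pd.DataFrame(rows, columns=PAIR_COLUMNS)
    return pairs.sort_values(["subject_id", "day_i", "day_j"]).reset_index(drop=True)


def median_subject_slope(values) -> float:
    """Median of per-pair slopes; even counts average the two central values."""
    values = np.asarray(list(values), dtype=float)
    if values.size == 0:
        raise ValueError("need at least one slope value")
    return float(np.median(values))


def subject_median_slopes(pairs: pd.DataFrame, column: str = "delta_score") -> pd.Series:
    """Per-subject median measured slope (points/year) over all pairs."""
    slopes = pairs[column] / pairs["delta_t_years"]
    return slopes.groupby(pairs["subject_id"]).median()
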