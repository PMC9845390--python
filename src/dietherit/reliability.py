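"""One-way intra-class correlation for repeated questionnaire items.

Reliability of a raw dietary item across repeated questionnaires is measured
as between-subject variance / (between-subject + within-subject variance)
from the one-way random-effects ANOVA decomposition, on individuals with a
complete set of ratings (here, all five questionnaires). This is the
single-rater consistency form ICC(1,1); questionnaires are exchangeable
occasions, not distinguishable raters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class ICCEstimate:
    item: str
    icc: float
    sigma2_between: float
    sigma2_within: float
    n_subjects: int
    n_ratings: int


def icc_oneway(values: np.ndarray, item: str = "") -> ICCEstimate:
    """One-way random-effects ICC of a subjects x ratings matrix.

    sigma2_between = max(0, (MSB - MSW)/r) and sigma2_within = MSW, so the
    estimate is clamped to [0, 1]. Complete cases only: any missing rating
    is an error (subset upstream).
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least two subjects")
    if np.isnan(x).any():
        raise ValueError("missing ratings present; subset to complete cases first")
    n, r = x.shape
    if r < 2:
        raise ValueError("need at least two ratings per subject")

    subj_means = x.mean(axis=1)
    grand = x.mean()
    ssb = r * np.sum((subj_means - grand) ** 2)
    ssw = np.sum((x - subj_means[:, None]) ** 2)
    msb = ssb / (n - 1)
    msw = ssw / (n * (r - 1))
    if msb == 0 and msw == 0:
        raise ValueError("zero total variance; ICC undefined")

    sigma2_between = max(0.0, (msb - msw) / r)
    sigma2_within = msw
    icc = sigma2_between / (sigma2_between + sigma2_within)
    return ICCEstimate(
        item=item, icc=float(icc),
        sigma2_between=float(sigma2_between), sigma2_within=float(sigma2_within),
        n_subjects=n, n_ratings=r,
    )


def icc_table(
    q: pd.DataFrame, item_columns: list[str], n_ratings: int = 5
) -> pd.DataFrame:
    """ICC per raw item from individuals with at least ``n_ratings`` questionnaires.

    Subjects contribute their first ``n_ratings`` retained questionnaires so
    every subject has a complete, equal-sized set of ratings.
    """
    k = q.groupby("iid").size()
    complete = k.index[k >= n_ratings]
    sub = (
        q[q["iid"].isin(complete)]
        .sort_values(["iid", "qidx"])
        .groupby("iid")
        .head(n_ratings)
    )
    rows = []
    for col in item_columns:
        mat = sub[col].to_numpy(dtype=float).reshape(-1, n_ratings)
        est = icc_oneway(mat, item=col)
        rows.append(vars(est))
    return pd.DataFrame(rows)


def max_feasible_ratings(q: pd.DataFrame, min_subjects: int = 30, cap: int = 5) -> int:
    """Largest rating count r <= cap with at least ``min_subjects`` subjects having k >= r."""
    k = q.groupby("iid").size()
    for r in range(cap, 1, -1):
        if int((k >= r).sum()) >= max(min_subjects, 2):
            return r
    return 2
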