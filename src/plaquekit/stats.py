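"""Correlation and summary statistics for plaque composition vs FDG uptake.

The unit of analysis is the ROI table: one row per (subject, slice) with
mean fat fraction, mean R2* and slice TBR, plus per-subject whole-plaque
aggregates.  Associations are measured with the Pearson product-moment
coefficient; two-sided p-values come from the exact t transform
``t = r * sqrt((n - 2) / (1 - r^2))`` with n-2 degrees of freedom, with a
permutation p-value available as a distribution-free cross-check.  No
multiple-testing correction is applied across the correlation family.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "CorrelationResult",
    "GroupSummary",
    "pearson",
    "permutation_pvalue",
    "group_summary",
    "slice_profiles",
]


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    n: int
    slope: float
    intercept: float
    degenerate: bool = False  # zero variance in x or y

    @property
    def r2(self) -> float:
        return self.r**2


@dataclass(frozen=True)
class GroupSummary:
    mean: float
    sd: float  # sample SD (n-1 denominator); NaN when n < 2
    n: int
    sd_defined: bool = True


def pearson(x, y) -> CorrelationResult:
    """Pearson r with two-sided t-based p and the least-squares line.

    Requires n >= 3 finite pairs.  Zero variance in either variable leaves
    r undefined (NaN) and flags the result instead of raising.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in input")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(np.nan, np.nan, x.size, np.nan, np.nan, True)
    r, p = sps.pearsonr(x, y)
    fit = sps.linregress(x, y)
    return CorrelationResult(float(r), float(p), int(x.size), float(fit.slope), float(fit.intercept))


def permutation_pvalue(x, y, n_perm: int = 100_000, seed: int = 0) -> float:
    """Two-sided permutation p-value for the Pearson coefficient.

    Permutes ``y`` against ``x`` ``n_perm`` times and counts |r| at least as
    extreme as observed (add-one correction).  Serves as the
    distribution-free cross-check of the t-based p-value.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(seed)
    xc = (x - x.mean()) / x.std()
    yc = y - y.mean()
    obs = abs(float(np.dot(xc, yc / yc.std()) / x.size))
    perms = np.tile(yc, (n_perm, 1))
    perms = rng.permuted(perms, axis=1)
    perms = (perms - perms.mean(axis=1, keepdims=True)) / perms.std(axis=1, keepdims=True)
    rs = perms @ xc / x.size
    return float((np.sum(np.abs(rs) >= obs - 1e-12) + 1) / (n_perm + 1))


def group_summary(values) -> GroupSummary:
    """Mean and sample SD (n-1) of a group vector."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 2:
        if v.size == 0:
            raise ValueError("empty group")
        return GroupSummary(float(v.mean()), float("nan"), int(v.size), False)
    return GroupSummary(float(v.mean()), float(np.std(v, ddof=1)), int(v.size))


def slice_profiles(roi: pd.DataFrame, min_slices: int = 3) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-subject slice-by-slice profiles of composition vs uptake.

    ``roi`` needs columns ``subject``, ``slice_id``, ``ff_mean``,
    ``r2star_mean`` and ``tbr`` (slice TBR).  Returns

    * a tidy long table (subject, slice_id, measure, value) for dual-axis
      profile plotting, and
    * a per-subject table of Pearson r (and r^2, p) between each
      composition measure and TBR across slices.  Subjects with fewer than
      ``min_slices`` slices stay in the profiles but get NaN correlations.
    """
    required = {"subject", "slice_id", "ff_mean", "r2star_mean", "tbr"}
    missing = required - set(roi.columns)
    if missing:
        raise ValueError(f"ROI table lacks columns {sorted(missing)}")
    long = roi.melt(
        id_vars=["subject", "slice_id"],
        value_vars=["ff_mean", "r2star_mean", "tbr"],
        var_name="measure",
        value_name="value",
    ).sort_values(["subject", "slice_id", "measure"], ignore_index=True)

    rows = []
    for subject, grp in roi.groupby("subject"):
        grp = grp.dropna(subset=["ff_mean", "r2star_mean", "tbr"])
        row: dict = {"subject": subject, "n_slices": len(grp)}
        for measure in ("ff_mean", "r2star_mean"):
            if len(grp) >= min_slices and grp[measure].nunique() > 1 and grp["tbr"].nunique() > 1:
                res = pearson(grp[measure].to_numpy(), grp["tbr"].to_numpy())
                row[f"r_{measure}_tbr"] = res.r
                row[f"r2_{measure}_tbr"] = res.r2
                row[f"p_{measure}_tbr"] = res.p
            else:
                row[f"r_{measure}_tbr"] = np.nan
                row[f"r2_{measure}_tbr"] = np.nan
                row[f"p_{measure}_tbr"] = np.nan
        rows.append(row)
    return long, pd.DataFrame(rows).set_index("subject")
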