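"""ROI quantification and two-group comparison.

Left/right ROI means are averaged bilaterally per animal; groups are
screened for normality (Lilliefors-corrected Kolmogorov–Smirnov, since the
population mean and SD are estimated from the sample) and compared with an
independent two-sample t-test (equal-variance by default, Welch optional).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.diagnostic import lilliefors

ALPHA = 0.05


@dataclass
class ROISummary:
    mean: float
    sd: float
    n: int


def roi_mean(pmap, labels: np.ndarray, roi_code: int) -> ROISummary:
    """Mean/SD of a parametric map over the valid voxels of one ROI.

    Invalid voxels (failed fits, field-map dropouts) are excluded; an ROI
    left empty after validity masking is an error rather than a silent 0.
    """
    roi = np.asarray(labels) == roi_code
    ok = roi & pmap.valid & np.isfinite(pmap.values)
    n = int(ok.sum())
    if n == 0:
        raise ValueError(f"ROI {roi_code} has no valid voxels")
    v = pmap.values[ok]
    return ROISummary(mean=float(v.mean()), sd=float(v.std(ddof=1))
                      if n > 1 else 0.0, n=n)


@dataclass
class GroupComparison:
    """Independent t-test result with per-group normality screen."""

    statistic: float
    df: float
    p_value: float
    group_means: dict
    group_sds: dict
    group_ns: dict
    normality_p: dict
    equal_var: bool
    alpha: float = ALPHA

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


def compare_groups(values_by_group: dict, equal_var: bool = True
                   ) -> GroupComparison:
    """Two-sided independent t-test between exactly two groups.

    ``values_by_group`` maps group name to a 1-D array of per-animal
    values.  Normality p-values use the Lilliefors-corrected KS test
    (reported per group; requires n ≥ 4, otherwise NaN).
    """
    if len(values_by_group) != 2:
        raise ValueError("compare_groups expects exactly two groups")
    names = list(values_by_group)
    a = np.asarray(values_by_group[names[0]], dtype=float)
    b = np.asarray(values_by_group[names[1]], dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 animals per group")
    if a.std() == 0 and b.std() == 0:
        raise ValueError("zero variance in both groups")

    res = sps.ttest_ind(a, b, equal_var=equal_var)
    if equal_var:
        df = a.size + b.size - 2
    else:
        df = float(res.df) if hasattr(res, "df") else np.nan

    norm_p = {}
    for name, x in zip(names, (a, b)):
        if x.size >= 4 and x.std() > 0:
            norm_p[name] = float(lilliefors(x, dist="norm")[1])
        else:
            norm_p[name] = np.nan
    return GroupComparison(
        statistic=float(res.statistic), df=float(df),
        p_value=float(res.pvalue),
        group_means={n: float(x.mean()) for n, x in
                     zip(names, (a, b))},
        group_sds={n: float(x.std(ddof=1)) for n, x in zip(names, (a, b))},
        group_ns={names[0]: int(a.size), names[1]: int(b.size)},
        normality_p=norm_p, equal_var=equal_var)


@dataclass
class CohortResult:
    """Per-animal ROI table plus per-metric group statistics.

    ``table`` columns: animal, group, metric, left, right, bilateral
    (bilateral = (left + right)/2 exactly).  ``tests`` maps metric name to
    a :class:`GroupComparison` on the bilateral values (MRS concentrations,
    measured in the right hippocampus only, are carried in the ``right``
    and ``bilateral`` columns identically and compared as such).
    """

    table: pd.DataFrame
    tests: dict = field(default_factory=dict)

    def summary(self) -> pd.DataFrame:
        g = (self.table.groupby(["metric", "group"])["bilateral"]
             .agg(["mean", "std", "count"]).reset_index()
             .rename(columns={"std": "sd", "count": "n"}))
        return g

    def values(self, metric: str) -> dict:
        sub = self.table[self.table.metric == metric]
        return {g: sub[sub.group == g]["bilateral"].to_numpy()
                for g in sub.group.unique()}


def build_cohort_result(rows, equal_var: bool = True) -> CohortResult:
    """Assemble a CohortResult from per-animal ROI rows and run the tests.

    ``rows`` is an iterable of dicts with keys animal, group, metric,
    left, right (right may equal left for single-sided measures).
    """
    table = pd.DataFrame(rows)
    table["bilateral"] = (table["left"] + table["right"]) / 2.0
    tests = {}
    for metric in table.metric.unique():
        sub = table[table.metric == metric]
        groups = list(sub.group.unique())
        if len(groups) == 2:
            vals = {g: sub[sub.group == g]["bilateral"].to_numpy()
                    for g in groups}
            try:
                tests[metric] = compare_groups(vals, equal_var=equal_var)
            except ValueError:
                pass  # degenerate metric (e.g. zero variance): no test
    return CohortResult(table=table, tests=tests)
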