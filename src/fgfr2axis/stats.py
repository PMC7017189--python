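"""Association and survival statistics for the integrated cohort.

Categorical clinico-pathological factors are tested against dichotomized
expression (or copy-number) categories with the Pearson chi-square test,
Yates-corrected for 2x2 tables — the test that reproduces the published
association table from its printed counts.  The Wilcoxon rank-sum test and
Student's t-test serve the continuous expression contrasts.  Survival uses
the Kaplan-Meier product-limit estimator and the log-rank test (overall
and pairwise), with death as the event and alive patients censored at last
follow-up.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank_test
from lifelines.statistics import multivariate_logrank_test as _ll_multivariate_logrank

from .errors import DegenerateTableError


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: float | None
    p_value: float
    method: str
    correction: str = "none"
    flag: str | None = None


@dataclass(frozen=True)
class KMCurve:
    """Product-limit survival curve: stepwise survival at observed times."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def contingency_test(table) -> TestResult:
    """Pearson chi-square on an observed contingency table.

    2x2 tables get the Yates continuity correction; larger tables are
    uncorrected.  A structural zero margin (any expected count of zero)
    cannot support the test and raises.
    """
    observed = np.asarray(table, dtype=float)
    if observed.ndim != 2 or observed.shape[0] < 2 or observed.shape[1] < 2:
        raise DegenerateTableError(f"need at least a 2x2 table, got shape {observed.shape}")
    if (observed < 0).any():
        raise ValueError("contingency counts must be non-negative")
    if (observed.sum(axis=1) == 0).any() or (observed.sum(axis=0) == 0).any():
        raise DegenerateTableError("table has a zero row or column margin")
    is_2x2 = observed.shape == (2, 2)
    chi2, p, df, _ = sps.chi2_contingency(observed, correction=is_2x2)
    return TestResult(
        statistic=float(chi2),
        df=int(df),
        p_value=float(p),
        method="pearson-chi-square",
        correction="yates" if is_2x2 else "none",
    )


def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float], mode: str = "auto") -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    ``mode`` is "exact", "normal-approx", or "auto" (exact when the pooled
    size is at most 20 and there are no ties, otherwise the normal
    approximation with tie and continuity corrections).
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    if mode == "auto":
        method = "exact" if (pooled.size <= 20 and not has_ties) else "asymptotic"
    elif mode == "exact":
        method = "exact"
    elif mode == "normal-approx":
        method = "asymptotic"
    else:
        raise ValueError(f"unknown mode {mode!r}")
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method,
                           use_continuity=True)
    return TestResult(
        statistic=float(res.statistic),
        df=None,
        p_value=float(res.pvalue),
        method=f"wilcoxon-rank-sum-{method}",
    )


def students_t(x: Sequence[float], y: Sequence[float], equal_var: bool = True) -> TestResult:
    """Two-sided two-sample t-test (pooled variance by default, Welch optional)."""
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least two observations")
    if np.var(x) == 0 and np.var(y) == 0:
        # both groups constant: the t statistic is undefined
        if np.mean(x) == np.mean(y):
            return TestResult(0.0, float(x.size + y.size - 2), 1.0,
                              "students-t", flag="degenerate-variance")
        return TestResult(float("inf"), float(x.size + y.size - 2), 0.0,
                          "students-t", flag="degenerate-variance")
    res = sps.ttest_ind(x, y, equal_var=equal_var)
    df = float(res.df) if hasattr(res, "df") else float(x.size + y.size - 2)
    return TestResult(float(res.statistic), df, float(res.pvalue),
                      "students-t" if equal_var else "welch-t")


def km_estimate(times: Sequence[float], events: Sequence[int]) -> KMCurve:
    """Kaplan-Meier product-limit estimate of the survival function.

    ``events`` is 1 for death and 0 for censoring; individuals censored at
    an event time are counted at risk at that time (standard convention).
    """
    times = np.asarray(list(times), dtype=float)
    events = np.asarray(list(events), dtype=int)
    if times.size == 0:
        raise ValueError("no survival records")
    if (times < 0).any():
        raise ValueError("survival times must be non-negative")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    tbl = kmf.event_table.iloc[1:] if 0.0 not in times else kmf.event_table
    obs_times = tbl.index.to_numpy(dtype=float)
    surv = np.asarray(
        [float(kmf.survival_function_.loc[t].iloc[0]) for t in obs_times]
    )
    at_risk = tbl["at_risk"].to_numpy(dtype=int)
    return KMCurve(times=obs_times, survival=surv, at_risk=at_risk)


def logrank(
    times: Sequence[float],
    events: Sequence[int],
    groups: Sequence,
) -> TestResult:
    """Overall log-rank test across two or more groups (df = k - 1)."""
    times = np.asarray(list(times), dtype=float)
    events = np.asarray(list(events), dtype=int)
    groups = np.asarray(list(groups))
    labels = np.unique(groups)
    if labels.size < 2:
        raise DegenerateTableError("log-rank needs at least two groups")
    if events.sum() == 0:
        raise DegenerateTableError("log-rank needs at least one event")
    res = _ll_multivariate_logrank(times, groups, events)
    return TestResult(
        statistic=float(res.test_statistic),
        df=float(labels.size - 1),
        p_value=float(res.p_value),
        method="logrank",
    )


def pairwise_logrank(
    times: Sequence[float],
    events: Sequence[int],
    groups: Sequence,
) -> pd.DataFrame:
    """Log-rank test for every unordered pair of group labels."""
    times = np.asarray(list(times), dtype=float)
    events = np.asarray(list(events), dtype=int)
    groups = np.asarray(list(groups))
    labels = sorted(np.unique(groups).tolist())
    rows = []
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            ma, mb = groups == a, groups == b
            res = _ll_logrank_test(times[ma], times[mb], events[ma], events[mb])
            rows.append({"group_a": a, "group_b": b,
                         "statistic": float(res.test_statistic),
                         "p_value": float(res.p_value)})
    return pd.DataFrame(rows, columns=["group_a", "group_b", "statistic", "p_value"])


def survival_from_clinical(
    clinical: pd.DataFrame,
    death_col: str = "days_to_death",
    followup_col: str = "days_to_last_follow_up",
    vital_col: str = "vital_status",
    dead_label: str = "Dead",
) -> pd.DataFrame:
    """Derive (time, event) per sample from a TCGA-like clinical table."""
    dead = clinical[vital_col] == dead_label
    time = np.where(dead, clinical[death_col], clinical[followup_col]).astype(float)
    out = pd.DataFrame(
        {"sample_id": clinical["sample_id"], "time": time, "event": dead.astype(int)}
    )
    if (out["time"] < 0).any():
        raise ValueError("negative survival time in clinical table")
    return out


def build_table1(
    states: pd.DataFrame,
    factor: str,
    category_field: str,
    drop_levels: Iterable[str] = ("NA", "missing"),
    category_order: Sequence[str] = ("above", "below"),
) -> tuple[pd.DataFrame, TestResult]:
    """Cross-tabulate one clinical factor against one dichotomized category.

    Factor levels listed in ``drop_levels`` (and true NaN) are shown in the
    returned table but excluded from the chi-square test, mirroring how
    not-available stage rows are reported but not tested.
    """
    for col in (factor, category_field):
        if col not in states.columns:
            raise KeyError(f"column {col!r} absent from states")
    sub = states[[factor, category_field]].dropna()
    sub = sub[sub[category_field].isin(category_order)]
    display = pd.crosstab(sub[factor], sub[category_field])
    display = display.reindex(columns=list(category_order), fill_value=0)
    tested = display.drop(index=[l for l in drop_levels if l in display.index])
    tested = tested.loc[tested.sum(axis=1) > 0]
    if tested.shape[0] < 2:
        raise DegenerateTableError(
            f"factor {factor!r} has fewer than two usable levels"
        )
    return display, contingency_test(tested.to_numpy())


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (optional; off by default)."""
    return sps.false_discovery_control(np.asarray(list(p_values), dtype=float), method="bh")
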