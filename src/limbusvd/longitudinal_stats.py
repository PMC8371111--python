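"""Group statistics for longitudinal limbal vessel-density studies.

Three analyses are provided, matching the usual design of a serial-imaging
injury study with within-eye controls:

* an independent two-sample t-test of injured vs control quadrants at each
  timepoint (Student's pooled-variance test by default, Welch behind a
  flag), including a summary-statistics variant;
* a one-way ANOVA across timepoints within a group, with pairwise
  each-timepoint-vs-baseline comparisons adjusted by Bonferroni (capped at
  1; Tukey HSD available behind a flag);
* ordinary least squares of the per-eye day-1 VD response (sum of the four
  quadrant VDs by default, mean behind a flag) on the number of injured
  quadrants, with the Pearson correlation and a t-based 95% CI on the
  slope.

Quadrant-level records are treated as independent observations; clustering
of quadrants within eyes/subjects is not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

ALPHA = 0.05


@dataclass(frozen=True)
class GroupSummary:
    group: str
    timepoint: str
    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        # a singleton group can be summarized (sd = 0) but never tested
        if self.n < 1:
            raise ValueError("group summaries require n >= 1")
        if self.sd < 0:
            raise ValueError("sd must be non-negative")


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float


@dataclass(frozen=True)
class AnovaResult:
    F: float
    p: float
    #: timepoint -> (t, raw p, adjusted p) for each non-baseline timepoint
    pairwise: dict[str, tuple[float, float, float]]


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    ci_low: float
    ci_high: float
    pearson_r: float
    p_value: float
    n_eyes: int

    def __post_init__(self) -> None:
        if not -1.0 <= self.pearson_r <= 1.0:
            raise ValueError("pearson r out of [-1, 1]")
        if not self.ci_low <= self.slope <= self.ci_high:
            raise ValueError("slope CI does not bracket the slope")


def _as_array(x) -> np.ndarray:
    a = np.asarray(x, dtype=float).ravel()
    if a.size < 2:
        raise ValueError("each sample needs n >= 2")
    return a


def independent_t_test(a, b, equal_var: bool = True) -> TTestResult:
    """Two-sided independent-samples t-test.

    Student's pooled-variance test by default; ``equal_var=False`` gives
    Welch's test.  Degenerate zero-variance inputs follow the convention:
    equal means -> (t=0, p=1); unequal means -> t = +/-inf, p = 0.
    """
    a, b = _as_array(a), _as_array(b)
    if np.var(a, ddof=1) == 0.0 and np.var(b, ddof=1) == 0.0:
        df = a.size + b.size - 2
        if a.mean() == b.mean():
            return TTestResult(t=0.0, df=df, p=1.0)
        return TTestResult(t=np.inf if a.mean() > b.mean() else -np.inf,
                           df=df, p=0.0)
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    return TTestResult(t=float(res.statistic), df=float(res.df),
                       p=float(res.pvalue))


def t_test_from_summary(mean1: float, sd1: float, n1: int,
                        mean2: float, sd2: float, n2: int,
                        equal_var: bool = True) -> TTestResult:
    """Student's/Welch's t-test from group summary statistics."""
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    res = stats.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2,
                                     equal_var=equal_var)
    df = (n1 + n2 - 2) if equal_var else _welch_df(sd1, n1, sd2, n2)
    return TTestResult(t=float(res.statistic), df=float(df),
                       p=float(res.pvalue))


def _welch_df(sd1, n1, sd2, n2) -> float:
    v1, v2 = sd1 ** 2 / n1, sd2 ** 2 / n2
    return (v1 + v2) ** 2 / (v1 ** 2 / (n1 - 1) + v2 ** 2 / (n2 - 1))


def anova_vs_baseline(samples_by_timepoint: dict[str, np.ndarray],
                      baseline: str = "baseline",
                      adjust: str = "bonferroni",
                      equal_var: bool = True) -> AnovaResult:
    """One-way ANOVA across timepoints plus baseline-vs-each comparisons.

    ``samples_by_timepoint`` maps timepoint label to the VD sample of one
    group.  Pairwise p-values compare each non-baseline timepoint against
    baseline and are Bonferroni-adjusted (multiplied by the number of
    comparisons, capped at 1) by default; ``adjust='tukey'`` uses Tukey's
    HSD over all timepoints and reports its baseline-contrast p-values.
    """
    if baseline not in samples_by_timepoint:
        raise ValueError(f"baseline timepoint {baseline!r} missing")
    if len(samples_by_timepoint) < 2:
        raise ValueError("need at least two timepoints for ANOVA")
    if adjust not in ("bonferroni", "tukey"):
        raise ValueError(f"unknown adjustment {adjust!r}")
    groups = {tp: _as_array(v) for tp, v in samples_by_timepoint.items()}
    F, p = stats.f_oneway(*groups.values())

    others = [tp for tp in groups if tp != baseline]
    pairwise: dict[str, tuple[float, float, float]] = {}
    if adjust == "bonferroni":
        m = len(others)
        for tp in others:
            res = independent_t_test(groups[baseline], groups[tp],
                                     equal_var=equal_var)
            pairwise[tp] = (res.t, res.p, min(1.0, res.p * m))
    else:
        order = [baseline] + others
        hsd = stats.tukey_hsd(*[groups[tp] for tp in order])
        for i, tp in enumerate(others, start=1):
            p_adj = float(hsd.pvalue[0, i])
            res = independent_t_test(groups[baseline], groups[tp],
                                     equal_var=equal_var)
            pairwise[tp] = (res.t, res.p, p_adj)
    return AnovaResult(F=float(F), p=float(p), pairwise=pairwise)


def regress_vd_on_injured_quadrants(eye_table: pd.DataFrame,
                                    alpha: float = ALPHA) -> RegressionResult:
    """OLS of the per-eye VD response on the number of injured quadrants.

    ``eye_table`` needs columns ``n_injured`` (0-4) and ``vd_response``
    (per-eye sum — or mean, if the caller built it that way — of the four
    quadrant VDs).  Returns the slope with a t-based CI, and the Pearson
    correlation with its two-sided p-value.
    """
    required = {"n_injured", "vd_response"}
    missing = required - set(eye_table.columns)
    if missing:
        raise ValueError(f"eye_table missing column(s) {sorted(missing)}")
    x = eye_table["n_injured"].to_numpy(dtype=float)
    y = eye_table["vd_response"].to_numpy(dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 eyes for regression")
    if np.any((x < 0) | (x > 4) | (x != np.round(x))):
        raise ValueError("n_injured must be integers in 0..4")
    if np.var(x) == 0.0:
        raise ValueError("n_injured has zero variance; correlation undefined")
    if np.var(y) == 0.0:
        # flat response: slope and correlation are exactly zero
        return RegressionResult(slope=0.0, intercept=float(y[0]),
                                ci_low=0.0, ci_high=0.0, pearson_r=0.0,
                                p_value=1.0, n_eyes=int(x.size))

    res = stats.linregress(x, y)
    df = x.size - 2
    tcrit = stats.t.ppf(1 - alpha / 2, df)
    ci = (res.slope - tcrit * res.stderr, res.slope + tcrit * res.stderr)
    return RegressionResult(slope=float(res.slope),
                            intercept=float(res.intercept),
                            ci_low=float(ci[0]), ci_high=float(ci[1]),
                            pearson_r=float(res.rvalue),
                            p_value=float(res.pvalue),
                            n_eyes=int(x.size))


def eye_level_table(records: pd.DataFrame, timepoint: str = "day1",
                    response: str = "sum") -> pd.DataFrame:
    """Collapse quadrant records to one row per eye at one timepoint.

    ``records`` needs columns eye_id, quadrant, timepoint, group and a VD
    column named either ``vd`` or ``true_vd``.  The response is the sum of
    the four quadrant VDs (``response='mean'`` for the mean variant).
    """
    if response not in ("sum", "mean"):
        raise ValueError(f"response must be 'sum' or 'mean', got {response!r}")
    vd_col = "vd" if "vd" in records.columns else "true_vd"
    sub = records[records["timepoint"] == timepoint]
    rows = []
    for eye_id, g in sub.groupby("eye_id", sort=True):
        if len(g) != 4:
            raise ValueError(f"eye {eye_id} has {len(g)} quadrant records at "
                             f"{timepoint}; expected 4")
        agg = g[vd_col].sum() if response == "sum" else g[vd_col].mean()
        rows.append({"eye_id": eye_id,
                     "n_injured": int((g["group"] == "injury").sum()),
                     "vd_response": float(agg)})
    return pd.DataFrame(rows, columns=["eye_id", "n_injured", "vd_response"])


def group_summaries(records: pd.DataFrame) -> list[GroupSummary]:
    """Mean/SD of VD per (group, timepoint); sample SD (ddof=1)."""
    vd_col = "vd" if "vd" in records.columns else "true_vd"
    out = []
    for (group, tp), g in records.groupby(["group", "timepoint"], sort=True):
        sd = float(g[vd_col].std(ddof=1)) if len(g) > 1 else 0.0
        out.append(GroupSummary(group=group, timepoint=tp, n=len(g),
                                mean=float(g[vd_col].mean()), sd=sd))
    return out


def study_manifest(design) -> dict:
    """Design bookkeeping: eyes, quadrant split, records per modality.

    For the full replicate layout this reports 48 quadrants (28 injured,
    20 control) and 240 quadrant-level records per imaging modality.
    """
    n_eyes = design.n_eyes
    n_quadrants = design.n_quadrants
    n_injured = design.n_injured_quadrants
    n_control = design.n_control_quadrants
    if n_injured + n_control != n_quadrants:
        raise ValueError("inconsistent design: group counts do not sum to 4/eye")
    n_tp = len(design.timepoints)
    return {
        "n_eyes": n_eyes,
        "n_quadrants": n_quadrants,
        "n_injured_quadrants": n_injured,
        "n_control_quadrants": n_control,
        "n_timepoints": n_tp,
        "records_per_modality": n_quadrants * n_tp,
    }


def stats_report(records: pd.DataFrame, baseline: str = "baseline",
                 adjust: str = "bonferroni", equal_var: bool = True,
                 regression_timepoint: str = "day1",
                 regression_response: str = "sum") -> dict:
    """Full statistical report over a quadrant-level VD table.

    Returns a JSON-serializable dict with group summaries, per-timepoint
    injury-vs-control t-tests, within-group ANOVA vs baseline, and the
    eye-level regression on number of injured quadrants (when the design
    varies it).
    """
    vd_col = "vd" if "vd" in records.columns else "true_vd"
    report: dict = {"group_summaries": [
        {"group": s.group, "timepoint": s.timepoint, "n": s.n,
         "mean_vd": s.mean, "sd_vd": s.sd}
        for s in group_summaries(records)]}

    report["between_groups"] = {}
    for tp, g in records.groupby("timepoint", sort=True):
        inj = g[g["group"] == "injury"][vd_col].to_numpy()
        ctl = g[g["group"] == "control"][vd_col].to_numpy()
        if inj.size >= 2 and ctl.size >= 2:
            r = independent_t_test(inj, ctl, equal_var=equal_var)
            report["between_groups"][tp] = {"t": r.t, "df": r.df, "p": r.p}

    report["within_group_vs_baseline"] = {}
    for group, g in records.groupby("group", sort=True):
        samples = {tp: sub[vd_col].to_numpy()
                   for tp, sub in g.groupby("timepoint", sort=True)
                   if len(sub) >= 2}
        if baseline in samples and len(samples) >= 2:
            a = anova_vs_baseline(samples, baseline=baseline, adjust=adjust,
                                  equal_var=equal_var)
            report["within_group_vs_baseline"][group] = {
                "F": a.F, "p": a.p,
                "pairwise": {tp: {"t": t, "p_raw": praw, "p_adj": padj}
                             for tp, (t, praw, padj) in a.pairwise.items()},
            }

    try:
        eye_tab = eye_level_table(records, timepoint=regression_timepoint,
                                  response=regression_response)
        reg = regress_vd_on_injured_quadrants(eye_tab)
        report["regression_day1"] = {
            "slope": reg.slope, "intercept": reg.intercept,
            "slope_ci95": [reg.ci_low, reg.ci_high],
            "pearson_r": reg.pearson_r, "p": reg.p_value,
            "n_eyes": reg.n_eyes, "response": regression_response,
        }
    except ValueError as exc:
        report["regression_day1"] = {"error": str(exc)}
    return report
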