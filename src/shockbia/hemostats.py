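"""Hemodynamic endpoint extraction and the statistical layer.

Vitals (PR, MAP, SV, SVV) are compared at five named timepoints: start of
the experiment, end of controlled hemorrhage, start of resuscitation phase
2, the time at which 1 MHz impedance recovers its baseline, and the end of
fluid infusion.  Statistics follow the published analysis: Jarque-Bera
normality screening, pointwise independent two-sample t-tests at the five
timepoints, percent changes of group means, and the ΔSV >= 10% fluid
responsiveness rule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .protocol import ExperimentProtocol

__all__ = [
    "StatsError",
    "TestResult",
    "TIMEPOINT_MINUTES",
    "extract_endpoints",
    "jarque_bera",
    "ttest_two",
    "percent_change",
    "delta_sv_responsiveness",
    "endpoint_comparison_report",
]

VARIABLES = ("pr", "map", "sv", "svv")

#: Fixed named timepoints (minutes); recovery_1M is measured per group.
TIMEPOINT_MINUTES = {
    "start": 0.0,
    "end_hemorrhage": 60.0,
    "start_resus2": 120.0,
    "end_infusion": 180.0,
}

TIMEPOINT_ORDER = (
    "start",
    "end_hemorrhage",
    "start_resus2",
    "recovery_1M",
    "end_infusion",
)


class StatsError(ValueError):
    """Invalid statistical input."""


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    n1: int
    n2: int = 0
    alpha: float = 0.05

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


def extract_endpoints(
    vitals: pd.DataFrame,
    protocol: ExperimentProtocol,
    recovery_minute: float | None,
) -> pd.DataFrame:
    """Per-subject vitals at the five named timepoints.

    Takes the measurement nearest each named minute (ties go to the
    earlier sample); missing MAP/SV/SVV propagate as NaN.  A named minute
    with no measurement within one vitals interval is an error.  When
    ``recovery_minute`` is None the recovery endpoint is omitted
    (flagged absent) and the other four are filled.
    """
    minutes = dict(TIMEPOINT_MINUTES)
    if recovery_minute is not None:
        if not 60.0 < recovery_minute <= 180.0:
            raise StatsError(
                f"recovery minute {recovery_minute} outside the infusion window"
            )
        minutes["recovery_1M"] = float(recovery_minute)

    rows = []
    for sid, grp in vitals.groupby("subject_id", sort=True):
        grp = grp.sort_values("t_min")
        t = grp["t_min"].to_numpy(dtype=float)
        for name in TIMEPOINT_ORDER:
            if name not in minutes:
                continue
            target = minutes[name]
            idx = int(np.argmin(np.abs(t - target)))  # first min -> earlier tie
            if abs(t[idx] - target) > protocol.vitals_interval_min:
                raise StatsError(
                    f"no vitals measurement within {protocol.vitals_interval_min} "
                    f"min of timepoint {name} ({target} min)"
                )
            row = grp.iloc[idx]
            for var in VARIABLES:
                rows.append((sid, var, name, target, float(row[var])))
    return pd.DataFrame(
        rows, columns=["subject_id", "variable", "timepoint", "t_min", "value"]
    )


def jarque_bera(values, alpha: float = 0.05) -> TestResult:
    """Jarque-Bera normality test.

    JB = n/6 * (S^2 + (K - 3)^2 / 4) from the sample skewness S and
    kurtosis K (biased moment estimators); p from the chi-square(2)
    reference distribution.
    """
    v = np.asarray(values, dtype=float)
    n = v.size
    if n < 4:
        raise StatsError(f"Jarque-Bera needs n >= 4, got {n}")
    m = v.mean()
    m2 = np.mean((v - m) ** 2)
    if m2 == 0:
        raise StatsError("zero variance: normality test undefined")
    s = np.mean((v - m) ** 3) / m2**1.5
    k = np.mean((v - m) ** 4) / m2**2
    jb = n / 6.0 * (s**2 + (k - 3.0) ** 2 / 4.0)
    p = float(stats.chi2.sf(jb, df=2))
    return TestResult(statistic=float(jb), p_value=p, n1=n, alpha=alpha)


def ttest_two(values_a, values_b, equal_var: bool = True, alpha: float = 0.05) -> TestResult:
    """Independent two-sample t-test (pooled variance by default).

    Set ``equal_var=False`` for the Welch variant.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if a.size < 2 or b.size < 2:
        raise StatsError("each sample needs at least 2 finite values")
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    t = float(res.statistic)
    p = 1.0 if math.isnan(t) else float(res.pvalue)  # identical constant samples
    if math.isnan(t):
        t = 0.0
    return TestResult(statistic=t, p_value=p, n1=a.size, n2=b.size, alpha=alpha)


def percent_change(v_start: float, v_end: float) -> float:
    """Percent change from start, positive for decreases.

    (start - end)/start * 100, matching prose of the form
    'decreased by 21.0% from 49.9 to 39.4'.
    """
    if v_start == 0:
        raise StatsError("percent change undefined for zero start value")
    return (v_start - v_end) / v_start * 100.0


def delta_sv_responsiveness(sv_before: float, sv_after: float) -> dict:
    """Fluid-responsiveness by the ΔSV rule: responsive iff ΔSV >= 10%."""
    if sv_before <= 0:
        raise StatsError("stroke volume before the bolus must be positive")
    delta_pct = float((sv_after - sv_before) / sv_before * 100.0)
    return {"delta_pct": delta_pct, "responsive": bool(delta_pct >= 10.0)}


def endpoint_comparison_report(
    endpoints: pd.DataFrame,
    alpha: float = 0.05,
    equal_var: bool = True,
    bonferroni: bool = False,
) -> tuple[pd.DataFrame, dict]:
    """Pairwise timepoint comparisons per variable plus restored flags.

    For each adjacent timepoint pair in protocol order and for
    start vs end_infusion: t statistic, p value, and percent change of the
    group means.  A variable is flagged 'restored' when its start vs
    end_infusion difference is non-significant at ``alpha`` — recovery of
    the variable to its pre-hemorrhage level.
    """
    present = [
        tp for tp in TIMEPOINT_ORDER if tp in set(endpoints["timepoint"])
    ]
    pairs = list(zip(present[:-1], present[1:]))
    if ("start", "end_infusion") not in pairs:
        pairs.append(("start", "end_infusion"))

    n_tests = len(pairs) * len(VARIABLES)
    eff_alpha = alpha / n_tests if bonferroni else alpha

    rows = []
    flags: dict[str, dict] = {"restored": {}, "alpha": eff_alpha}
    for var in VARIABLES:
        sub = endpoints[endpoints["variable"] == var]
        by_tp = {
            tp: grp.sort_values("subject_id")["value"].to_numpy()
            for tp, grp in sub.groupby("timepoint")
        }
        for a_tp, b_tp in pairs:
            va, vb = by_tp[a_tp], by_tp[b_tp]
            res = ttest_two(va, vb, equal_var=equal_var, alpha=eff_alpha)
            pc = percent_change(np.nanmean(va), np.nanmean(vb))
            rows.append(
                (
                    var,
                    f"{a_tp}_vs_{b_tp}",
                    res.statistic,
                    res.p_value,
                    pc,
                    res.significant,
                )
            )
            if (a_tp, b_tp) == ("start", "end_infusion"):
                flags["restored"][var] = not res.significant
    table = pd.DataFrame(
        rows,
        columns=["variable", "pair", "t", "p", "percent_change", "significant"],
    )
    return table, flags
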