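"""Clinical-validation statistics: paired/unpaired comparisons with Cohen's D,
Pearson correlation, Bland--Altman accuracy summaries, and 1:1 case-control
matching.

Conventions
-----------
Paired Cohen's D = mean(x - y) / SD(x - y), the convention consistent with a
paired t-test.  Unpaired D = (mean_a - mean_b) / pooled SD.  Confidence
intervals for D use the normal approximation

    SE_paired   = sqrt(1/n + D^2 / (2 n))
    SE_unpaired = sqrt((n_a + n_b) / (n_a n_b) + D^2 / (2 (n_a + n_b)))

which reproduces published intervals; an exact noncentral-t interval is
available via ``ci_method="noncentral_t"``.  The unpaired test defaults to the
pooled-variance Student t; Welch's t is available by flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupComparison",
    "MatchCriteria",
    "MatchResult",
    "paired_compare",
    "unpaired_compare",
    "pearson_r",
    "bland_altman",
    "cohens_d_ci_paired",
    "cohens_d_ci_unpaired",
    "match_pairs",
]


@dataclass
class GroupComparison:
    design: str                       # "paired" | "unpaired"
    mean_a: float
    sd_a: float
    n_a: int
    mean_b: float
    sd_b: float
    n_b: int
    mean_diff: float
    mean_diff_ci: tuple[float, float]
    cohens_d: float
    cohens_d_ci: tuple[float, float]
    p_value: float

    def __post_init__(self) -> None:
        lo, hi = self.mean_diff_ci
        if not (lo <= self.mean_diff <= hi):
            raise ValueError("mean difference outside its own CI")
        if self.design == "paired" and self.n_a != self.n_b:
            raise ValueError("paired design requires equal group sizes")


@dataclass
class MatchCriteria:
    """Exact match on sex and pain frequency; calipers on age and BMI."""

    exact: tuple[str, ...] = ("sex", "painfreq")
    age_caliper: float = 5.0
    bmi_caliper: float = 5.0

    def __post_init__(self) -> None:
        if self.age_caliper <= 0 or self.bmi_caliper <= 0:
            raise ValueError("calipers must be positive")


@dataclass
class MatchResult:
    pairs: pd.DataFrame               # columns case_id, control_id, age_diff, bmi_diff
    unmatched_cases: list


def cohens_d_ci_paired(d: float, n: int, alpha: float = 0.05) -> tuple[float, float]:
    se = np.sqrt(1.0 / n + d**2 / (2.0 * n))
    z = sps.norm.ppf(1 - alpha / 2)
    return (d - z * se, d + z * se)


def cohens_d_ci_unpaired(d: float, n_a: int, n_b: int, alpha: float = 0.05,
                         method: str = "normal") -> tuple[float, float]:
    if method == "noncentral_t":
        nt = np.sqrt(n_a * n_b / (n_a + n_b))
        df = n_a + n_b - 2
        t_obs = d * nt
        lo = sps.nct.ppf(alpha / 2, df, t_obs) / nt
        hi = sps.nct.ppf(1 - alpha / 2, df, t_obs) / nt
        return (float(lo), float(hi))
    se = np.sqrt((n_a + n_b) / (n_a * n_b) + d**2 / (2.0 * (n_a + n_b)))
    z = sps.norm.ppf(1 - alpha / 2)
    return (d - z * se, d + z * se)


def paired_compare(x, y) -> GroupComparison:
    """Paired t-test with Cohen's D = mean(x-y) / SD(x-y)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired series must have equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 pairs")
    d = x - y
    mean_diff = float(d.mean())
    sd_diff = float(d.std(ddof=1))
    if sd_diff == 0:
        # degenerate: constant difference
        p = 1.0 if mean_diff == 0 else 0.0
        cd = 0.0 if mean_diff == 0 else float(np.sign(mean_diff) * np.inf)
        ci_md = (mean_diff, mean_diff)
    else:
        t_stat = mean_diff / (sd_diff / np.sqrt(n))
        p = float(2 * sps.t.sf(abs(t_stat), n - 1))
        cd = mean_diff / sd_diff
        tcrit = sps.t.ppf(0.975, n - 1)
        half = tcrit * sd_diff / np.sqrt(n)
        ci_md = (mean_diff - half, mean_diff + half)
    return GroupComparison(
        design="paired",
        mean_a=float(x.mean()), sd_a=float(x.std(ddof=1)), n_a=n,
        mean_b=float(y.mean()), sd_b=float(y.std(ddof=1)), n_b=n,
        mean_diff=mean_diff, mean_diff_ci=ci_md,
        cohens_d=cd,
        cohens_d_ci=cohens_d_ci_paired(cd, n) if np.isfinite(cd) else (cd, cd),
        p_value=p,
    )


def unpaired_compare(stats_a, stats_b, welch: bool = False,
                     ci_method: str = "normal") -> GroupComparison:
    """Two-group comparison from summary statistics ``(mean, sd, n)``.

    Cohen's D uses the pooled SD regardless of the test flavour; the t-test
    is pooled-variance Student by default, Welch when ``welch=True``.
    """
    mean_a, sd_a, n_a = float(stats_a[0]), float(stats_a[1]), int(stats_a[2])
    mean_b, sd_b, n_b = float(stats_b[0]), float(stats_b[1]), int(stats_b[2])
    if n_a < 2 or n_b < 2:
        raise ValueError("each group needs n >= 2")
    if sd_a <= 0 or sd_b <= 0:
        raise ValueError("degenerate (non-positive) SD")
    diff = mean_a - mean_b
    pooled_var = ((n_a - 1) * sd_a**2 + (n_b - 1) * sd_b**2) / (n_a + n_b - 2)
    pooled_sd = np.sqrt(pooled_var)
    d = diff / pooled_sd
    if welch:
        se = np.sqrt(sd_a**2 / n_a + sd_b**2 / n_b)
        df = se**4 / (
            (sd_a**2 / n_a) ** 2 / (n_a - 1) + (sd_b**2 / n_b) ** 2 / (n_b - 1)
        )
    else:
        se = pooled_sd * np.sqrt(1.0 / n_a + 1.0 / n_b)
        df = n_a + n_b - 2
    t_stat = diff / se
    p = float(2 * sps.t.sf(abs(t_stat), df))
    tcrit = sps.t.ppf(0.975, df)
    return GroupComparison(
        design="unpaired",
        mean_a=mean_a, sd_a=sd_a, n_a=n_a,
        mean_b=mean_b, sd_b=sd_b, n_b=n_b,
        mean_diff=diff, mean_diff_ci=(diff - tcrit * se, diff + tcrit * se),
        cohens_d=float(d), cohens_d_ci=cohens_d_ci_unpaired(d, n_a, n_b, method=ci_method),
        p_value=p,
    )


def unpaired_compare_series(x, y, **kw) -> GroupComparison:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return unpaired_compare(
        (x.mean(), x.std(ddof=1), len(x)), (y.mean(), y.std(ddof=1), len(y)), **kw
    )


def pearson_r(x, y) -> float:
    return float(sps.pearsonr(np.asarray(x, float), np.asarray(y, float))[0])


def bland_altman(x, y):
    """Bland--Altman bias and 95% limits of agreement.

    Returns ``(bias, sd_diff, loa_low, loa_high, table)`` where ``table`` has
    one (mean, diff) row per pair, ready for plotting.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("series must have equal length")
    d = x - y
    bias = float(d.mean())
    sd = float(d.std(ddof=1)) if len(d) > 1 else 0.0
    table = pd.DataFrame({"mean": (x + y) / 2.0, "diff": d})
    return bias, sd, bias - 1.96 * sd, bias + 1.96 * sd, table


def match_pairs(cases: pd.DataFrame, controls: pd.DataFrame,
                criteria: MatchCriteria | None = None, seed: int = 0) -> MatchResult:
    """Greedy 1:1 matching: exact on sex/pain frequency, nearest age within
    the age caliper, ties broken by nearest BMI within the BMI caliper.

    Each control is used at most once; cases are visited in a seed-shuffled
    order and unmatched cases are reported, not raised.
    """
    criteria = criteria or MatchCriteria()
    for col in (*criteria.exact, "age", "bmi", "id"):
        for tab, name in ((cases, "cases"), (controls, "controls")):
            if col not in tab.columns:
                raise ValueError(f"{name} table lacks required column '{col}'")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(cases))
    used: set = set()
    rows = []
    unmatched = []
    ctrl = controls.reset_index(drop=True)
    for i in order:
        case = cases.iloc[int(i)]
        ok = np.ones(len(ctrl), dtype=bool)
        for col in criteria.exact:
            ok &= (ctrl[col] == case[col]).to_numpy()
        age_diff = (ctrl["age"] - case["age"]).abs().to_numpy()
        bmi_diff = (ctrl["bmi"] - case["bmi"]).abs().to_numpy()
        ok &= (age_diff <= criteria.age_caliper) & (bmi_diff <= criteria.bmi_caliper)
        ok &= ~ctrl.index.isin(used)
        if not ok.any():
            unmatched.append(case["id"])
            continue
        cand = np.flatnonzero(ok)
        # nearest age, ties broken by nearest BMI
        best_age = age_diff[cand].min()
        tie = cand[age_diff[cand] == best_age]
        j = int(tie[np.argmin(bmi_diff[tie])])
        used.add(j)
        rows.append({
            "case_id": case["id"],
            "control_id": ctrl.iloc[j]["id"],
            "age_diff": float(age_diff[j]),
            "bmi_diff": float(bmi_diff[j]),
        })
    pairs = pd.DataFrame(rows, columns=["case_id", "control_id", "age_diff", "bmi_diff"])
    return MatchResult(pairs=pairs, unmatched_cases=unmatched)
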