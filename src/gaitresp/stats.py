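"""Speed matching, percent-change deltas, gated group comparisons, effect
sizes, improvement classification, correlations and paired-test power.

Test selection follows the usual clinical-biostatistics gate: Shapiro-Wilk
normality at alpha 0.05 per sample (on the paired differences for paired
designs) decides between the parametric test (pooled-variance Student t /
paired t) and its rank-based counterpart (Mann-Whitney U / Wilcoxon).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from gaitresp.types import GaitError

NORMALITY_ALPHA = 0.05


@dataclass(frozen=True)
class DeltaRecord:
    """Percent change of one variable for one subject between sessions."""

    subject_id: str
    variable: str
    value_baseline: float
    value_10week: float

    def __post_init__(self) -> None:
        if self.value_baseline == 0:
            raise GaitError("baseline value must be nonzero for a percent change")

    @property
    def delta_pct(self) -> float:
        return delta(self.value_baseline, self.value_10week)


@dataclass(frozen=True)
class ComparisonResult:
    variable: str
    test: str  # pooled-t | mann-whitney | paired-t | wilcoxon
    statistic: float
    p_value: float
    cohen_d: float
    n1: int
    n2: int
    normality_p: tuple[float, float]


def delta(value_baseline: float, value_10week: float) -> float:
    """Signed percent change, 100 * (follow-up - baseline) / baseline."""
    if value_baseline == 0:
        raise GaitError("baseline value must be nonzero")
    return 100.0 * (value_10week - value_baseline) / value_baseline


def match_speed_trials(control_trial_speeds, patient_speed_mean: float,
                       patient_speed_sd: float) -> np.ndarray:
    """Boolean mask of control trials inside the patients' speed band.

    The band is the closed interval [mean - SD, mean + SD] of the patient
    group's gait speed for the session being matched.
    """
    if patient_speed_sd <= 0:
        raise GaitError("patient_speed_sd must be > 0")
    speeds = np.asarray(control_trial_speeds, dtype=float)
    lo = patient_speed_mean - patient_speed_sd
    hi = patient_speed_mean + patient_speed_sd
    return (speeds >= lo) & (speeds <= hi)


def pooled_t_from_moments(m1: float, s1: float, n1: int,
                          m2: float, s2: float, n2: int) -> float:
    """Two-sample pooled-variance (Student) t from summary moments."""
    sp2 = ((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / (n1 + n2 - 2)
    return (m1 - m2) / math.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))


def cohen_d_from_moments(m1: float, s1: float, n1: int,
                         m2: float, s2: float, n2: int) -> float:
    """Unpaired Cohen's d (pooled SD denominator), absolute value."""
    sp2 = ((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / (n1 + n2 - 2)
    return abs(m1 - m2) / math.sqrt(sp2)


def cohen_d(sample1, sample2, paired: bool = False) -> float:
    """Effect size: mean difference over pooled SD (unpaired) or over the
    SD of differences (paired); reported as an absolute value."""
    x = np.asarray(sample1, dtype=float)
    y = np.asarray(sample2, dtype=float)
    if paired:
        if len(x) != len(y):
            raise GaitError("paired samples must have equal length")
        d = x - y
        sd = d.std(ddof=1)
        if sd == 0:
            raise GaitError("zero SD of differences")
        return abs(d.mean()) / sd
    return cohen_d_from_moments(x.mean(), x.std(ddof=1), len(x),
                                y.mean(), y.std(ddof=1), len(y))


def _shapiro_p(x: np.ndarray) -> float:
    if np.ptp(x) == 0:
        return 0.0  # degenerate sample: clearly non-normal
    return float(sps.shapiro(x).pvalue)


def compare_groups(sample1, sample2, paired: bool = False,
                   variable: str = "") -> ComparisonResult:
    """Normality-gated two-sample comparison with effect size.

    Unpaired: pooled-variance Student t if both samples pass Shapiro-Wilk
    at alpha 0.05, else Mann-Whitney U. Paired: paired t if the differences
    pass, else Wilcoxon signed-rank. scipy's default exact/approximate rank
    p-value switching applies.
    """
    x = np.asarray(sample1, dtype=float)
    y = np.asarray(sample2, dtype=float)
    if len(x) < 3 or len(y) < 3:
        raise GaitError("need n >= 3 per sample")
    if np.ptp(x) == 0 and np.ptp(y) == 0:
        raise GaitError("zero variance in both samples")

    if paired:
        if len(x) != len(y):
            raise GaitError("paired samples must have equal length")
        diffs = x - y
        p_norm = _shapiro_p(diffs)
        normal = p_norm >= NORMALITY_ALPHA
        if normal:
            res = sps.ttest_rel(x, y)
            test = "paired-t"
        else:
            res = sps.wilcoxon(x, y)
            test = "wilcoxon"
        d = cohen_d(x, y, paired=True)
        norm_ps = (p_norm, p_norm)
    else:
        p1, p2 = _shapiro_p(x), _shapiro_p(y)
        normal = p1 >= NORMALITY_ALPHA and p2 >= NORMALITY_ALPHA
        if normal:
            res = sps.ttest_ind(x, y, equal_var=True)
            test = "pooled-t"
        else:
            res = sps.mannwhitneyu(x, y, alternative="two-sided")
            test = "mann-whitney"
        d = cohen_d(x, y)
        norm_ps = (p1, p2)

    return ComparisonResult(variable, test, float(res.statistic),
                            float(res.pvalue), d, len(x), len(y), norm_ps)


def classify_improvement(value_baseline: float, value_10week: float,
                         control_mean: float) -> bool:
    """Improved iff the follow-up moved strictly closer to the control mean.

    Strict inequality: a follow-up exactly mirroring the baseline distance
    (or a baseline already at the control mean) counts as not improved.
    """
    return abs(value_10week - control_mean) < abs(value_baseline - control_mean)


def improvement_chi_square(n_improved: int, n_total: int
                           ) -> tuple[float, float]:
    """1-df goodness-of-fit of the improved count against an even split."""
    if not 0 <= n_improved <= n_total or n_total <= 0:
        raise GaitError("invalid counts")
    observed = [n_improved, n_total - n_improved]
    res = sps.chisquare(observed)
    return float(res.statistic), float(res.pvalue)


def bivariate_correlation(x, y) -> tuple[str, float, float]:
    """Pearson r if both variables pass the normality gate, else Spearman.

    Returns (method, coefficient, p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise GaitError("need paired samples with n >= 3")
    if _shapiro_p(x) >= NORMALITY_ALPHA and _shapiro_p(y) >= NORMALITY_ALPHA:
        res = sps.pearsonr(x, y)
        return "pearson", float(res.statistic), float(res.pvalue)
    res = sps.spearmanr(x, y)
    return "spearman", float(res.statistic), float(res.pvalue)


def paired_t_power(n: int, effect_size_d: float, alpha: float = 0.05,
                   two_sided: bool = True) -> float:
    """Achieved power of the paired t test at total sample size n."""
    if n < 2:
        return 0.0
    df = n - 1
    nc = effect_size_d * math.sqrt(n)
    if two_sided:
        tcrit = sps.t.ppf(1.0 - alpha / 2.0, df)
        return float(1.0 - sps.nct.cdf(tcrit, df, nc)
                     + sps.nct.cdf(-tcrit, df, nc))
    tcrit = sps.t.ppf(1.0 - alpha, df)
    return float(1.0 - sps.nct.cdf(tcrit, df, nc))


def paired_power_sample_size(effect_size_d: float, power: float = 0.80,
                             alpha: float = 0.05,
                             two_sided: bool = True) -> int:
    """Smallest n whose paired noncentral-t power reaches the target."""
    if effect_size_d == 0:
        raise GaitError("effect size must be nonzero")
    if not 0 < power < 1:
        raise GaitError("power must lie in (0, 1)")
    d = abs(effect_size_d)
    n = 2
    while paired_t_power(n, d, alpha, two_sided) < power:
        n += 1
        if n > 1_000_000:
            raise GaitError("required sample size exceeds 1e6")
    return n


def comparison_table(parameters: pd.DataFrame, variables: list[str],
                     session: str, paired: bool = False) -> pd.DataFrame:
    """Patients-vs-controls comparison of each variable at one session."""
    rows = []
    sub = parameters[parameters["session"] == session]
    pat = sub[sub["group"] == "patient"]
    ctl = sub[sub["group"] == "control"]
    for var in variables:
        res = compare_groups(pat[var].to_numpy(), ctl[var].to_numpy(),
                             paired=paired, variable=var)
        rows.append({
            "variable": var, "session": session, "test": res.test,
            "patients_mean": pat[var].mean(), "patients_sd": pat[var].std(ddof=1),
            "controls_mean": ctl[var].mean(), "controls_sd": ctl[var].std(ddof=1),
            "statistic": res.statistic, "p_value": res.p_value,
            "cohen_d": res.cohen_d, "n_patients": res.n1, "n_controls": res.n2,
        })
    return pd.DataFrame(rows)
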