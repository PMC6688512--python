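"""Anchor-based responsiveness: normalization labels, ROC/AUC, MCID
cut-offs, likelihood ratios, predictive values and post-test probabilities.

The anchor is "normalization": a patient counts as normalized when the
variable improved (moved closer to the control mean) AND the follow-up
value reached the healthy range, operationalised as the control mean plus
(lower-is-better) or minus (higher-is-better) k control SDs, k = 1 by
default.  The percent-change (delta) of the variable is then scored against
this binary anchor with an empirical ROC curve; the MCID is the delta
threshold minimising (1-Se)^2 + (1-Sp)^2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from gaitresp.stats import classify_improvement
from gaitresp.types import GaitError


@dataclass(frozen=True)
class AnchorLabel:
    subject_id: str
    variable: str
    normalized: bool


@dataclass(frozen=True)
class RocCurve:
    """Empirical ROC of a score against binary labels.

    ``direction`` is +1 if larger scores indicate the positive class (the
    orientation is chosen so AUC >= 0.5); thresholds are midpoints between
    sorted distinct scores, reported on the original score scale.
    """

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    direction: int
    n_pos: int
    n_neg: int


@dataclass(frozen=True)
class MCIDResult:
    variable: str
    auc: float
    auc_ci_low: float
    auc_ci_high: float
    mcid_cutoff: float
    direction: int  # +1: positive iff delta > cutoff; -1: delta < cutoff
    se_pct: float
    sp_pct: float
    lr_pos: float
    lr_neg: float
    pv_pos: float
    pv_neg: float
    posttest_prob_pos: float
    posttest_prob_neg: float
    n_normalized: int
    n_total: int


def anchor_classify(subject_id: str, variable: str,
                    value_baseline: float, value_10week: float,
                    control_mean: float, control_sd: float,
                    lower_is_better: bool, k: float = 1.0) -> AnchorLabel:
    """Normalized iff improved (distance rule) and inside the healthy band.

    The healthy band is one-sided: follow-up <= control_mean + k*SD for
    lower-is-better variables, mirrored for higher-is-better ones.
    """
    if control_sd <= 0:
        raise GaitError("control SD must be > 0")
    improved = classify_improvement(value_baseline, value_10week, control_mean)
    if lower_is_better:
        reached = value_10week <= control_mean + k * control_sd
    else:
        reached = value_10week >= control_mean - k * control_sd
    return AnchorLabel(subject_id, variable, bool(improved and reached))


def _auc_mann_whitney(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC as the Mann-Whitney concordance probability (ties count half)."""
    pos = scores[labels]
    neg = scores[~labels]
    ranks = sps.rankdata(scores)
    r_pos = ranks[labels].sum()
    n1, n0 = len(pos), len(neg)
    u = r_pos - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def roc_auc(deltas, labels, variable: str = "") -> RocCurve:
    """Empirical ROC over all midpoint thresholds with orientation choice.

    AUC equals the Mann-Whitney concordance estimate; if scores run opposite
    to the labels (AUC < 0.5) the score orientation is flipped and the flip
    is reported in ``direction``.
    """
    scores = np.asarray(deltas, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if y.all() or not y.any():
        raise GaitError("ROC requires both classes present")
    direction = 1
    auc = _auc_mann_whitney(scores, y)
    if auc < 0.5:
        direction = -1
        scores = -scores
        auc = 1.0 - auc

    uniq = np.unique(scores)
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    thresholds = np.concatenate(([uniq[0] - 1.0], mids, [uniq[-1] + 1.0]))
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    se = np.array([(scores[y] > t).mean() for t in thresholds])
    sp = np.array([(scores[~y] <= t).mean() for t in thresholds])
    return RocCurve(direction * thresholds, se, sp, auc, direction,
                    n_pos, n_neg)


def delong_auc_ci(deltas, labels, level: float = 0.95) -> tuple[float, float]:
    """DeLong variance-based confidence interval for the empirical AUC.

    Uses the structural-components formulation; the interval is clipped to
    [0, 1].  An exact-binomial alternative is available via
    ``binomial_auc_ci`` for degenerate (zero-variance) cases.
    """
    scores = np.asarray(deltas, dtype=float)
    y = np.asarray(labels, dtype=bool)
    auc = _auc_mann_whitney(scores, y)
    if auc < 0.5:
        scores, auc = -scores, 1.0 - auc
    pos, neg = scores[y], scores[~y]
    m, n = len(pos), len(neg)

    def psi(a, b):
        return np.where(a > b, 1.0, np.where(a == b, 0.5, 0.0))

    v10 = np.array([psi(x, neg).mean() for x in pos])
    v01 = np.array([psi(pos, x).mean() for x in neg])
    var = (np.var(v10, ddof=1) / m if m > 1 else 0.0) + \
          (np.var(v01, ddof=1) / n if n > 1 else 0.0)
    z = sps.norm.ppf(0.5 + level / 2.0)
    half = z * math.sqrt(max(var, 0.0))
    return max(0.0, auc - half), min(1.0, auc + half)


def binomial_auc_ci(auc: float, n_pos: int, n_neg: int,
                    level: float = 0.95) -> tuple[float, float]:
    """Hanley-McNeil style binomial interval on the AUC (fallback)."""
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc**2 / (1.0 + auc)
    var = (auc * (1 - auc) + (n_pos - 1) * (q1 - auc**2)
           + (n_neg - 1) * (q2 - auc**2)) / (n_pos * n_neg)
    z = sps.norm.ppf(0.5 + level / 2.0)
    half = z * math.sqrt(max(var, 0.0))
    return max(0.0, auc - half), min(1.0, auc + half)


def mcid_cutoff(roc: RocCurve) -> tuple[float, float, float]:
    """Threshold minimising (1-Se)^2 + (1-Sp)^2 on the ROC.

    Ties are broken toward higher sensitivity, then toward the higher
    threshold (in oriented-score space).  Returns (cutoff, se, sp) with the
    cutoff on the original delta scale.
    """
    se, sp = roc.sensitivity, roc.specificity
    crit = (1.0 - se) ** 2 + (1.0 - sp) ** 2
    oriented_thr = roc.direction * roc.thresholds  # ascending in score space
    best = 0
    for i in range(1, len(crit)):
        if crit[i] < crit[best] - 1e-12:
            best = i
        elif abs(crit[i] - crit[best]) <= 1e-12:
            if se[i] > se[best] + 1e-12:
                best = i
            elif abs(se[i] - se[best]) <= 1e-12 and oriented_thr[i] > oriented_thr[best]:
                best = i
    return float(roc.thresholds[best]), float(se[best]), float(sp[best])


def diagnostic_stats(se: float, sp: float, prevalence: float
                     ) -> dict[str, float]:
    """Likelihood ratios and predictive values from Se, Sp and prevalence.

    All inputs are proportions in (0, 1); Sp == 1 makes LR+ infinite
    (reported as ``inf``), Sp == 0 likewise for LR-.
    """
    if not (0 < se < 1 or se == 1.0) or not (0 <= sp <= 1):
        raise GaitError("se and sp must lie in (0, 1]")
    if not 0 < prevalence < 1:
        raise GaitError("prevalence must lie in (0, 1)")
    lr_pos = se / (1.0 - sp) if sp < 1 else math.inf
    lr_neg = (1.0 - se) / sp if sp > 0 else math.inf
    pv_pos = (se * prevalence
              / (se * prevalence + (1.0 - sp) * (1.0 - prevalence))
              if se * prevalence + (1 - sp) * (1 - prevalence) > 0 else math.nan)
    pv_neg = (sp * (1.0 - prevalence)
              / (sp * (1.0 - prevalence) + (1.0 - se) * prevalence)
              if sp * (1 - prevalence) + (1 - se) * prevalence > 0 else math.nan)
    return {"lr_pos": lr_pos, "lr_neg": lr_neg,
            "pv_pos": pv_pos, "pv_neg": pv_neg}


def posttest_probability(lr: float, pretest_prob: float) -> float:
    """Pre-test probability through a likelihood ratio, via odds.

    The arithmetic form of the Fagan nomogram: post-odds = pre-odds * LR.
    """
    if lr <= 0:
        raise GaitError("likelihood ratio must be > 0")
    if not 0 < pretest_prob < 1:
        raise GaitError("pretest probability must lie in (0, 1)")
    odds = pretest_prob / (1.0 - pretest_prob) * lr
    return odds / (1.0 + odds)


def mcid_analysis(deltas, labels, variable: str = "",
                  ci_method: str = "delong") -> MCIDResult:
    """Full anchor-based responsiveness analysis of one delta variable."""
    scores = np.asarray(deltas, dtype=float)
    y = np.asarray(labels, dtype=bool)
    roc = roc_auc(scores, y, variable)
    if ci_method == "delong":
        lo, hi = delong_auc_ci(scores, y)
    else:
        lo, hi = binomial_auc_ci(roc.auc, roc.n_pos, roc.n_neg)
    cutoff, se, sp = mcid_cutoff(roc)
    prevalence = roc.n_pos / (roc.n_pos + roc.n_neg)
    # guard the degenerate perfect-separation corners for the LR arithmetic
    se_c = min(max(se, 1e-9), 1.0)
    stats = diagnostic_stats(se_c, sp, prevalence)
    post_pos = (posttest_probability(stats["lr_pos"], prevalence)
                if math.isfinite(stats["lr_pos"]) else 1.0)
    # probability of the normalized state despite a negative classification
    post_neg = (posttest_probability(stats["lr_neg"], prevalence)
                if math.isfinite(stats["lr_neg"]) and stats["lr_neg"] > 0
                else 0.0)
    return MCIDResult(
        variable=variable, auc=roc.auc, auc_ci_low=lo, auc_ci_high=hi,
        mcid_cutoff=cutoff, direction=roc.direction,
        se_pct=100.0 * se, sp_pct=100.0 * sp,
        lr_pos=stats["lr_pos"], lr_neg=stats["lr_neg"],
        pv_pos=100.0 * stats["pv_pos"], pv_neg=100.0 * stats["pv_neg"],
        posttest_prob_pos=100.0 * post_pos, posttest_prob_neg=100.0 * post_neg,
        n_normalized=roc.n_pos, n_total=roc.n_pos + roc.n_neg,
    )
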