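"""Anchor labels, ROC/AUC, MCID cut-off, likelihood ratios, post-test
probabilities."""

import math

import numpy as np
import pytest

from gaitresp import responsiveness as resp
from gaitresp.types import GaitError


def brute_force_auc(scores, labels):
    """Concordant-pair counting: (concordant + 0.5 ties) / all pairs."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    total = conc = ties = 0
    for p in pos:
        for n in neg:
            total += 1
            if p > n:
                conc += 1
            elif p == n:
                ties += 1
    return (conc + 0.5 * ties) / total


def brute_force_mcid(scores, labels):
    """Exhaustive scan over midpoint thresholds with the documented
    tie rules (higher Se, then higher threshold)."""
    scores = np.asarray(scores, float)
    y = np.asarray(labels, bool)
    uniq = np.unique(scores)
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    thresholds = np.concatenate(([uniq[0] - 1.0], mids, [uniq[-1] + 1.0]))
    best = None
    for t in thresholds:
        se = (scores[y] > t).mean()
        sp = (scores[~y] <= t).mean()
        crit = (1 - se) ** 2 + (1 - sp) ** 2
        key = (-round(crit, 12), se, t)  # ties resolved by Se then threshold
        if best is None or key > best[0]:
            best = (key, t, se, sp)
    return best[1], best[2], best[3]


class TestAnchorClassify:
    def test_asymmetry_normalization_example(self):
        # 20% -> 5% against control 5.5 +/- 4.7 (lower is better, k=1)
        lab = resp.anchor_classify("s", "asym", 20.0, 5.0, 5.5, 4.7, True)
        assert lab.normalized

    def test_worsening_never_normalizes(self):
        lab = resp.anchor_classify("s", "asym", 8.0, 9.5, 5.5, 4.7, True)
        assert not lab.normalized

    def test_band_k_monotonicity(self):
        """Subjects normalized at k=0 are a subset of those at k=1."""
        rng = np.random.default_rng(0)
        base = rng.uniform(5, 30, 50)
        fu = base * rng.uniform(0.3, 1.1, 50)
        at_k0 = {i for i in range(50)
                 if resp.anchor_classify(str(i), "v", base[i], fu[i],
                                         5.5, 4.7, True, k=0.0).normalized}
        at_k1 = {i for i in range(50)
                 if resp.anchor_classify(str(i), "v", base[i], fu[i],
                                         5.5, 4.7, True, k=1.0).normalized}
        assert at_k0 <= at_k1


class TestRocAuc:
    def test_perfect_separation(self):
        roc = resp.roc_auc([1, 2, 3, 10, 11, 12],
                           [False] * 3 + [True] * 3)
        assert roc.auc == 1.0

    def test_uninformative_scores_near_half(self):
        rng = np.random.default_rng(1)
        scores = rng.normal(size=2000)
        labels = rng.random(2000) < 0.5
        assert resp.roc_auc(scores, labels).auc == pytest.approx(0.5, abs=0.04)

    def test_six_point_toy_matches_pair_counting(self):
        scores = [3.0, 1.0, 2.0, 2.0, 5.0, 4.0]
        labels = [True, False, False, True, True, False]
        roc = resp.roc_auc(scores, labels)
        assert roc.auc == pytest.approx(brute_force_auc(scores, labels))

    def test_single_class_rejected(self):
        with pytest.raises(GaitError):
            resp.roc_auc([1, 2, 3], [True, True, True])

    @pytest.mark.parametrize("seed", range(20))
    def test_exhaustive_toys_match_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(4, 13)
        scores = rng.integers(0, 6, n).astype(float)  # force ties
        labels = np.zeros(n, bool)
        labels[rng.choice(n, rng.integers(1, n), replace=False)] = True
        if labels.all() or not labels.any():
            labels[0] = not labels[0]
        expected = max(brute_force_auc(scores, labels),
                       1 - brute_force_auc(scores, labels))
        assert resp.roc_auc(scores, labels).auc == pytest.approx(expected)

    def test_sklearn_cross_check(self):
        from sklearn.metrics import roc_auc_score
        rng = np.random.default_rng(9)
        scores = rng.normal(size=60)
        labels = rng.random(60) < 1 / (1 + np.exp(-scores))
        if 0 < labels.sum() < 60:
            ours = resp.roc_auc(scores, labels).auc
            theirs = roc_auc_score(labels, scores)
            assert ours == pytest.approx(max(theirs, 1 - theirs), abs=1e-12)


class TestMcidCutoff:
    def test_perfect_separation_zero_criterion(self):
        roc = resp.roc_auc([1, 2, 3, 10, 11, 12], [False] * 3 + [True] * 3)
        cutoff, se, sp = resp.mcid_cutoff(roc)
        assert se == 1.0 and sp == 1.0
        assert 3.0 < cutoff < 10.0

    @pytest.mark.parametrize("seed", range(100))
    def test_matches_exhaustive_scan(self, seed):
        rng = np.random.default_rng(10_000 + seed)
        n = rng.integers(6, 30)
        scores = np.round(rng.normal(0, 2, n), 1)
        labels = rng.random(n) < 0.5
        if labels.all() or not labels.any():
            labels[0] = not labels[0]
        roc = resp.roc_auc(scores, labels)
        got = resp.mcid_cutoff(roc)
        oriented = roc.direction * np.asarray(scores)
        t, se, sp = brute_force_mcid(oriented, labels)
        assert roc.direction * got[0] == pytest.approx(t)
        assert got[1] == pytest.approx(se)
        assert got[2] == pytest.approx(sp)

    def test_threshold_cohort_recovery(self):
        """Cohorts built with a known normalization threshold return an
        MCID within 20% of that truth (improvement = large reduction)."""
        truth = -27.8
        errs = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            deltas = rng.normal(truth, 18.0, 36)
            labels = deltas < truth  # the generating rule
            if labels.all() or not labels.any():
                continue
            r = resp.mcid_analysis(deltas, labels, "asym")
            errs.append(abs(r.mcid_cutoff - truth) / abs(truth))
        assert np.median(errs) < 0.20
        assert np.mean(np.asarray(errs) < 0.20) > 0.8


class TestDiagnosticStats:
    def test_asymmetry_row_arithmetic(self):
        # Se 18/19, Sp 15/17, prevalence 19/36
        out = resp.diagnostic_stats(18 / 19, 15 / 17, 19 / 36)
        assert out["lr_pos"] == pytest.approx(8.05, abs=0.005)
        assert 100 * out["pv_pos"] == pytest.approx(90.0, abs=0.05)

    def test_trunk_rotation_row_arithmetic(self):
        # Se 19/20, Sp 9/16, prevalence 20/36
        out = resp.diagnostic_stats(19 / 20, 9 / 16, 20 / 36)
        assert out["lr_pos"] == pytest.approx(2.17, abs=0.005)
        assert 100 * out["pv_pos"] == pytest.approx(73.1, abs=0.05)

    def test_perfect_specificity_gives_infinite_lr(self):
        out = resp.diagnostic_stats(0.9, 1.0, 0.5)
        assert math.isinf(out["lr_pos"])

    def test_pv_pos_monotone_in_se_and_sp(self):
        grid = np.linspace(0.55, 0.95, 9)
        for sp in (0.6, 0.8):
            pvs = [resp.diagnostic_stats(se, sp, 0.5)["pv_pos"] for se in grid]
            assert all(a < b for a, b in zip(pvs, pvs[1:]))
        for se in (0.6, 0.8):
            pvs = [resp.diagnostic_stats(se, sp, 0.5)["pv_pos"] for sp in grid]
            assert all(a < b for a, b in zip(pvs, pvs[1:]))


class TestPosttestProbability:
    def test_neutral_lr_is_identity(self):
        assert resp.posttest_probability(1.0, 0.37) == pytest.approx(0.37)

    def test_asymmetry_posttest(self):
        lr = (18 / 19) / (1 - 15 / 17)
        assert resp.posttest_probability(lr, 19 / 36) == pytest.approx(0.900,
                                                                       abs=0.0005)

    def test_trunk_posttest(self):
        lr = (19 / 20) / (1 - 9 / 16)
        assert resp.posttest_probability(lr, 20 / 36) == pytest.approx(0.731,
                                                                       abs=0.0005)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(GaitError):
            resp.posttest_probability(0.0, 0.5)
        with pytest.raises(GaitError):
            resp.posttest_probability(2.0, 1.0)


class TestDelongCi:
    def test_interval_contains_auc_and_shrinks_with_n(self):
        rng = np.random.default_rng(2)
        widths = []
        for n in (40, 400):
            scores = rng.normal(size=n) + np.repeat([0.0, 1.2], n // 2)
            labels = np.repeat([False, True], n // 2)
            lo, hi = resp.delong_auc_ci(scores, labels)
            auc = resp.roc_auc(scores, labels).auc
            assert lo <= auc <= hi
            widths.append(hi - lo)
        assert widths[1] < widths[0]
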