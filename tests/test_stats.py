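import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from perfquant import stats as pqs
from perfquant.core_model_io import DegenerateInputError, ParameterError


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def brute_force_auc(values, labels, lower_is_positive=True):
    """Pair-concordance AUC by explicit enumeration (ties count one half)."""
    scores = -np.asarray(values, float) if lower_is_positive else np.asarray(values, float)
    labels = np.asarray(labels).astype(bool)
    pos, neg = scores[labels], scores[~labels]
    total = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos) * len(neg))


def brute_force_youden(values, labels, lower_is_positive=True):
    """Exhaustive threshold scan over midpoints of adjacent unique values."""
    values = np.asarray(values, float)
    labels = np.asarray(labels).astype(bool)
    uniq = np.unique(values)
    cands = (uniq[:-1] + uniq[1:]) / 2.0 if uniq.size >= 2 else uniq
    best = None
    for thr in cands:
        pred = values <= thr if lower_is_positive else values >= thr
        sens = (pred & labels).sum() / labels.sum()
        spec = (~pred & ~labels).sum() / (~labels).sum()
        j = sens + spec - 1.0
        key = (-j, abs(sens - spec), -spec)
        if best is None or key < best[0]:
            best = (key, thr, j)
    return best[1], best[2]


def exact_mann_whitney_p(a, b):
    """Two-sided exact p by enumerating every group assignment."""
    a, b = list(a), list(b)
    pooled = a + b
    n1 = len(a)

    def u_stat(group_a, group_b):
        u = 0.0
        for x in group_a:
            for y in group_b:
                u += (x > y) + 0.5 * (x == y)
        return u

    observed = u_stat(a, b)
    n1n2 = n1 * len(b)
    dev = abs(observed - n1n2 / 2.0)
    count = 0
    total = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        ga = [pooled[i] for i in idx]
        gb = [pooled[i] for i in range(len(pooled)) if i not in idx]
        u = u_stat(ga, gb)
        total += 1
        if abs(u - n1n2 / 2.0) >= dev - 1e-12:
            count += 1
    return count / total


def jackknife_se_auc_diff(v1, v2, labels):
    """Leave-one-out jackknife SE of AUC1 - AUC2."""
    labels = np.asarray(labels).astype(bool)
    n = len(labels)
    d = []
    for i in range(n):
        keep = np.arange(n) != i
        if labels[keep].all() or not labels[keep].any():
            continue
        d.append(
            brute_force_auc(v1[keep], labels[keep]) - brute_force_auc(v2[keep], labels[keep])
        )
    d = np.asarray(d)
    m = len(d)
    return np.sqrt((m - 1) / m * np.sum((d - d.mean()) ** 2))


# ---------------------------------------------------------------------------
# agreement
# ---------------------------------------------------------------------------

class TestPearson:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        assert np.isclose(pqs.pearson_r(x, 2 * x + 1), 1.0)

    def test_perfect_inverse(self):
        x = np.arange(10.0)
        assert np.isclose(pqs.pearson_r(x, -x), -1.0)

    def test_hand_computed_value(self):
        assert np.isclose(pqs.pearson_r([1, 2, 3], [1, 3, 2]), 0.5)

    def test_zero_variance(self):
        with pytest.raises(DegenerateInputError):
            pqs.pearson_r([1, 1, 1], [1, 2, 3])


class TestBlandAltman:
    def test_identical_measurements(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        res = pqs.bland_altman(a, a)
        assert res.bias == 0.0 and res.loa == (0.0, 0.0)
        assert res.bias_p == 1.0

    def test_constant_negative_shift(self):
        manual = np.array([1.0, 2.0, 3.0])
        res = pqs.bland_altman(manual - 0.25, manual)
        assert np.isclose(res.bias, -0.25)
        assert np.allclose(res.loa, (-0.25, -0.25))

    def test_symmetric_differences(self):
        res = pqs.bland_altman(np.array([0.0, 1.0, 2.0]), np.array([1.0, 1.0, 1.0]))
        assert np.isclose(res.bias, 0.0)
        assert np.allclose(res.loa, (-1.96, 1.96))

    def test_antisymmetry(self):
        rng = np.random.default_rng(0)
        a, b = rng.random(10), rng.random(10)
        assert np.isclose(pqs.bland_altman(a, b).bias, -pqs.bland_altman(b, a).bias)

    def test_too_short(self):
        with pytest.raises(ParameterError):
            pqs.bland_altman([1.0], [2.0])


class TestMannWhitney:
    def test_identical_groups(self):
        _, p = pqs.mann_whitney([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p > 0.99

    def test_separated_triplets_exact(self):
        u, p = pqs.mann_whitney([1.0, 2.0, 3.0], [10.0, 20.0, 30.0])
        assert u in (0.0, 9.0)
        assert np.isclose(p, 0.1)

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            a = rng.normal(size=3)
            b = rng.normal(size=3)
            _, p = pqs.mann_whitney(a, b)
            assert np.isclose(p, exact_mann_whitney_p(a, b), atol=1e-12)

    def test_monotone_transform_invariance(self):
        a = np.array([0.1, 0.7, 2.0, 5.0])
        b = np.array([0.3, 1.1, 4.0])
        _, p1 = pqs.mann_whitney(a, b)
        _, p2 = pqs.mann_whitney(np.exp(a), np.exp(b))
        assert np.isclose(p1, p2)

    def test_empty_group(self):
        with pytest.raises(ParameterError):
            pqs.mann_whitney([], [1.0])


# ---------------------------------------------------------------------------
# ROC / DeLong / Youden / McNemar
# ---------------------------------------------------------------------------

class TestRoc:
    def test_perfect_separation(self):
        values = np.array([0.5, 0.6, 0.7, 2.0, 2.1, 2.2])
        labels = np.array([1, 1, 1, 0, 0, 0])
        res = pqs.roc(values, labels, pqs.LOWER)
        assert res.auc == 1.0

    def test_all_tied_values(self):
        values = np.ones(10)
        labels = np.array([1, 0] * 5)
        res = pqs.roc(values, labels, pqs.LOWER)
        assert res.auc == 0.5

    def test_eight_point_example_matches_enumeration(self):
        values = np.array([1.0, 2.0, 3.0, 4.0, 3.0, 4.0, 5.0, 6.0])
        labels = np.array([1, 1, 1, 1, 0, 0, 0, 0])
        res = pqs.roc(values, labels, pqs.LOWER)
        assert np.isclose(res.auc, brute_force_auc(values, labels))

    def test_auc_matches_brute_force_on_random_cohorts(self):
        rng = np.random.default_rng(0)
        for _ in range(20)        :
            n = rng.integers(6, 50)
            values = np.round(rng.normal(size=n), 1)  # induce ties
            labels = rng.integers(0, 2, size=n)
            if labels.all() or not labels.any():
                continue
            res = pqs.roc(values, labels, pqs.LOWER)
            assert np.isclose(res.auc, brute_force_auc(values, labels))

    def test_curve_anchored_and_ci_contains_auc(self):
        rng = np.random.default_rng(2)
        values = rng.normal(size=30)
        labels = rng.integers(0, 2, size=30)
        labels[:2] = [0, 1]
        res = pqs.roc(values, labels, pqs.LOWER)
        assert res.sensitivities[0] == 0.0 and res.sensitivities[-1] == 1.0
        assert res.specificities[0] == 1.0 and res.specificities[-1] == 0.0
        assert res.ci95[0] <= res.auc <= res.ci95[1]

    def test_se_shrinks_with_sample_size(self):
        rng = np.random.default_rng(3)
        ses = []
        for n in (40, 80, 160):
            values = rng.normal(size=n) + rng.integers(0, 2, size=n)
            labels = np.r_[np.ones(n // 2), np.zeros(n // 2)].astype(int)
            values = np.r_[rng.normal(-0.5, 1, n // 2), rng.normal(0.5, 1, n // 2)]
            ses.append(pqs.roc(values, labels, pqs.LOWER).auc_se)
        assert ses[2] < ses[1] < ses[0]

    def test_single_class_rejected(self):
        with pytest.raises(ParameterError):
            pqs.roc([1.0, 2.0], [1, 1], pqs.LOWER)


class TestDelong:
    def test_self_comparison(self):
        rng = np.random.default_rng(4)
        values = rng.normal(size=20)
        labels = rng.integers(0, 2, size=20)
        labels[:2] = [0, 1]
        r = pqs.roc(values, labels, pqs.LOWER)
        assert pqs.delong_test(r, r) == 1.0

    def test_swap_symmetry(self):
        rng = np.random.default_rng(5)
        labels = np.r_[np.ones(10), np.zeros(10)].astype(int)
        v1 = rng.normal(size=20) - labels
        v2 = rng.normal(size=20) - 0.3 * labels
        r1 = pqs.roc(v1, labels, pqs.LOWER)
        r2 = pqs.roc(v2, labels, pqs.LOWER)
        assert np.isclose(pqs.delong_test(r1, r2), pqs.delong_test(r2, r1))

    def test_se_close_to_jackknife(self):
        labels = np.array([1, 1, 1, 0, 0, 0])
        v1 = np.array([0.8, 1.1, 1.6, 1.4, 2.2, 2.5])
        v2 = np.array([1.0, 1.8, 1.2, 1.9, 1.5, 2.6])
        se = pqs._delong_se_diff(
            pqs.roc(v1, labels, pqs.LOWER), pqs.roc(v2, labels, pqs.LOWER)
        )
        jk = jackknife_se_auc_diff(v1, v2, labels)
        assert abs(se - jk) / jk < 0.2

    def test_mismatched_labels_rejected(self):
        labels1 = np.array([1, 1, 0, 0])
        labels2 = np.array([1, 0, 1, 0])
        v = np.array([1.0, 2.0, 3.0, 4.0])
        with pytest.raises(ParameterError):
            pqs.delong_test(pqs.roc(v, labels1, pqs.LOWER), pqs.roc(v, labels2, pqs.LOWER))


class TestYouden:
    def test_perfect_separation(self):
        values = np.array([0.5, 0.6, 2.0, 2.1])
        labels = np.array([1, 1, 0, 0])
        res = pqs.youden_threshold(pqs.roc(values, labels, pqs.LOWER), values, labels)
        assert res.youden_j == 1.0
        assert 0.6 < res.threshold < 2.0
        assert res.accuracy == 100.0

    def test_uninformative_marker(self):
        values = np.ones(8)
        labels = np.array([1, 0] * 4)
        res = pqs.youden_threshold(pqs.roc(values, labels, pqs.LOWER), values, labels)
        assert res.youden_j == 0.0

    def test_matches_brute_force_scan(self):
        values = np.array([1.0, 2.0, 3.0, 4.0, 3.0, 4.0, 5.0, 6.0])
        labels = np.array([1, 1, 1, 1, 0, 0, 0, 0])
        res = pqs.youden_threshold(pqs.roc(values, labels, pqs.LOWER), values, labels)
        thr, j = brute_force_youden(values, labels)
        assert np.isclose(res.threshold, thr)
        assert np.isclose(res.youden_j, j)

    def test_reported_rates_reproduce_confusion_matrix(self):
        rng = np.random.default_rng(6)
        values = rng.normal(size=40)
        labels = (values + rng.normal(scale=0.8, size=40) < 0).astype(int)
        if labels.all() or not labels.any():
            labels[:2] = [0, 1]
        res = pqs.youden_threshold(pqs.roc(values, labels, pqs.LOWER), values, labels)
        pred = values <= res.threshold
        labels = labels.astype(bool)
        sens = 100.0 * (pred & labels).sum() / labels.sum()
        spec = 100.0 * (~pred & ~labels).sum() / (~labels).sum()
        acc = 100.0 * ((pred & labels).sum() + (~pred & ~labels).sum()) / labels.size
        assert np.isclose(res.sensitivity, sens)
        assert np.isclose(res.specificity, spec)
        assert np.isclose(res.accuracy, acc)


class TestMcNemar:
    def test_symmetric_discordance(self):
        assert pqs.mcnemar(5, 5) == 1.0

    def test_one_sided_discordance_binomial_tail(self):
        assert np.isclose(pqs.mcnemar(10, 0), 2.0 * 0.5**10)

    def test_no_discordance_convention(self):
        assert pqs.mcnemar(0, 0) == 1.0

    def test_large_sample_chi_square(self):
        from scipy.stats import chi2

        p = pqs.mcnemar(30, 10)
        expect = chi2.sf((abs(30 - 10) - 1) ** 2 / 40, 1)
        assert np.isclose(p, expect)

    def test_invalid_counts(self):
        with pytest.raises(ParameterError):
            pqs.mcnemar(-1, 2)


class TestEvaluateCohort:
    def _cohort(self, rng, n, informative):
        labels = rng.integers(0, 2, size=n)
        labels[:2] = [0, 1]
        rows = []
        for metric in ("mbf", "mpr", "rmbf", "rmpr"):
            shift = -3.0 if informative else 0.0
            vals = rng.normal(size=n) + shift * labels
            for i in range(n):
                rows.append(
                    {"unit_id": f"u{i}", "level": "patient", "metric": metric, "value": vals[i]}
                )
        truth = pd.DataFrame(
            {"unit_id": [f"u{i}" for i in range(n)], "level": "patient", "label": labels}
        )
        return pd.DataFrame(rows), truth

    def test_separated_cohort_has_perfect_aucs(self):
        rng = np.random.default_rng(7)
        summaries, truth = self._cohort(rng, 40, informative=True)
        report = pqs.evaluate_cohort(summaries, truth)
        assert np.allclose(report["table"]["auc"], 1.0, atol=0.02)

    def test_uninformative_cohort_near_half(self):
        rng = np.random.default_rng(8)
        summaries, truth = self._cohort(rng, 200, informative=False)
        report = pqs.evaluate_cohort(summaries, truth)
        assert np.all(np.abs(report["table"]["auc"] - 0.5) < 0.12)

    def test_report_shape(self):
        rng = np.random.default_rng(9)
        s1, t1 = self._cohort(rng, 30, informative=True)
        s2, t2 = self._cohort(rng, 30, informative=True)
        s2["level"] = "vessel"
        t2["level"] = "vessel"
        report = pqs.evaluate_cohort(pd.concat([s1, s2]), pd.concat([t1, t2]))
        assert len(report["table"]) == 8  # 4 metrics x 2 levels
        assert len(report["delong"]) == 12  # C(4,2) pairs x 2 levels
        assert set(report["table"].columns) >= {
            "auc", "ci_lo", "ci_hi", "threshold", "sensitivity", "specificity", "accuracy"
        }


class TestBookkeepingHelpers:
    def test_proportion_percent(self):
        assert pqs.proportion_percent(52, 240) == 22
        assert pqs.proportion_percent(35, 80) == 44
        assert pqs.proportion_percent(22, 35) == 63

    def test_accuracy_from_rates(self):
        assert pqs.accuracy_from_rates(91.4, 91.1, 35, 45) == 91.3

    def test_bad_denominator(self):
        with pytest.raises(ParameterError):
            pqs.proportion_percent(1, 0)


@given(
    st.lists(st.floats(-100, 100, allow_nan=False), min_size=2, max_size=30),
    st.integers(0, 2**31 - 1),
)
@settings(max_examples=40, deadline=None)
def test_roc_auc_equals_bruteforce_property(values, seed):
    values = np.asarray(values)
    rng = np.random.default_rng(seed)
    labels = rng.integers(0, 2, size=len(values))
    if labels.all() or not labels.any():
        labels[0] = 1 - labels[0]
    res = pqs.roc(values, labels, pqs.LOWER)
    assert np.isclose(res.auc, brute_force_auc(values, labels))
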