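"""Diagnostic-accuracy statistics: contingency metrics, ROC/AUC, Mann-Whitney."""
from __future__ import annotations

import math
from itertools import combinations

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from kflc import (
    ConfusionMatrix,
    DegenerateSetError,
    Diagnosis,
    DomainError,
    Endpoint,
    InvalidRecordError,
    assemble_analysis_set,
    auc,
    confusion,
    diagnostic_metrics,
    mann_whitney,
    optimal_cutoff,
    roc_curve,
    wilson_interval,
)
from kflc.core import CensoredConcentration, PatientRecord


def brute_force_auc(scores, labels):
    """Mean pairwise comparison oracle (1 / 0.5 / 0 for > / = / <)."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    total = sum(
        1.0 if a > b else (0.5 if a == b else 0.0) for a in pos for b in neg
    )
    return total / (len(pos) * len(neg))


class TestAssembleAnalysisSet:
    def test_ms_endpoint_drops_isolated_and_inconclusive(self, fixture_cohort):
        pairs = assemble_analysis_set(fixture_cohort, Endpoint.MS_VS_NONMS)
        assert len(pairs) == 242
        assert sum(lab for _, lab in pairs) == 45

    def test_ocb_endpoint_keeps_everyone(self, fixture_cohort):
        pairs = assemble_analysis_set(fixture_cohort, "OCB_pos_vs_neg")
        assert len(pairs) == 252
        assert sum(lab for _, lab in pairs) == 65

    def test_single_class_cohort_is_degenerate(self):
        cis_only = [
            PatientRecord(
                id=f"c{i}",
                diagnosis=Diagnosis.CIS,
                serum_kflc=1.5,
                csf_kflc=CensoredConcentration(0.1, False),
                serum_alb=4000,
                csf_alb=20,
                ocb_bands=2,
            )
            for i in range(3)
        ]
        with pytest.raises(DegenerateSetError):
            assemble_analysis_set(cis_only, Endpoint.MS_VS_NONMS)

    def test_ocb_endpoint_requires_testing(self, fixture_cohort):
        untested = PatientRecord(
            id="u1",
            diagnosis=Diagnosis.OTHER,
            serum_kflc=1.5,
            csf_kflc=CensoredConcentration(None, True),
            serum_alb=4000,
            csf_alb=20,
            ocb_bands=None,
        )
        with pytest.raises(InvalidRecordError):
            assemble_analysis_set(list(fixture_cohort) + [untested], Endpoint.OCB_POS_VS_NEG)


class TestConfusion:
    @pytest.mark.parametrize(
        "labels,preds,expected",
        [
            ([True, False], [True, False], (1, 0, 0, 1)),
            ([True, True, False], [False, True, True], (1, 1, 1, 0)),
        ],
    )
    def test_counts(self, labels, preds, expected):
        cm = confusion(labels, preds)
        assert (cm.tp, cm.fp, cm.fn, cm.tn) == expected

    def test_length_mismatch(self):
        with pytest.raises(DomainError):
            confusion([True], [True, False])

    def test_ocb_fixture_counts(self, fixture_cohort):
        from kflc import ocb_positive

        pairs = assemble_analysis_set(fixture_cohort, Endpoint.MS_VS_NONMS)
        cm = confusion(
            [lab for _, lab in pairs],
            [ocb_positive(r.ocb_bands) for r, _ in pairs],
        )
        assert (cm.tp, cm.fp, cm.fn, cm.tn) == (40, 18, 5, 179)


class TestWilsonInterval:
    @pytest.mark.parametrize(
        "k,n,lo,hi",
        [
            (40, 45, 0.7650, 0.9516),
            (42, 45, 0.8214, 0.9771),
            (179, 197, 0.8602, 0.9414),
        ],
    )
    def test_reproduces_reference_intervals(self, k, n, lo, hi):
        got = wilson_interval(k, n, 0.95)
        assert round(got[0], 4) == lo
        assert round(got[1], 4) == hi

    def test_zero_successes_lower_bound_is_zero(self):
        lo, hi = wilson_interval(0, 45, 0.95)
        assert lo == 0.0
        assert 0 < hi < 1

    @pytest.mark.parametrize("k,n", [(-1, 10), (11, 10), (5, 0)])
    def test_invalid_counts(self, k, n):
        with pytest.raises(DomainError):
            wilson_interval(k, n)

    @given(k=st.integers(0, 45), conf=st.floats(0.5, 0.999))
    def test_point_estimate_inside_interval(self, k, conf):
        lo, hi = wilson_interval(k, 45, conf)
        eps = 1e-9  # boundary cases (k = 0 or 45) are exact only in theory
        assert lo - eps <= k / 45 <= hi + eps
        assert 0.0 <= lo <= hi <= 1.0


class TestDiagnosticMetrics:
    def test_ocb_reference_column(self):
        m = diagnostic_metrics(ConfusionMatrix(tp=40, fp=18, fn=5, tn=179))
        assert round(m.sensitivity, 4) == 0.8889
        assert round(m.specificity, 4) == 0.9086
        assert round(m.ppv, 4) == 0.6897
        assert round(m.npv, 4) == 0.9728
        assert round(m.lr_pos, 3) == 9.728
        assert m.n == 242

    def test_high_sensitivity_cutoff_column(self):
        m = diagnostic_metrics(ConfusionMatrix(tp=44, fp=27, fn=1, tn=170))
        assert round(m.sensitivity, 4) == 0.9778

    def test_perfect_classifier(self):
        m = diagnostic_metrics(ConfusionMatrix(tp=5, fp=0, fn=0, tn=7))
        assert m.sensitivity == m.specificity == m.ppv == m.npv == 1.0
        assert math.isinf(m.lr_pos)

    def test_no_predicted_positives_flags_ppv_undefined(self):
        m = diagnostic_metrics(ConfusionMatrix(tp=0, fp=0, fn=3, tn=7))
        assert m.ppv is None and m.ppv_ci is None
        assert m.npv is not None

    @given(k=st.integers(2, 5))
    def test_point_estimates_invariant_under_count_scaling(self, k):
        base = ConfusionMatrix(tp=40, fp=18, fn=5, tn=179)
        scaled = ConfusionMatrix(tp=40 * k, fp=18 * k, fn=5 * k, tn=179 * k)
        mb, ms = diagnostic_metrics(base), diagnostic_metrics(scaled)
        assert ms.sensitivity == pytest.approx(mb.sensitivity)
        assert ms.specificity == pytest.approx(mb.specificity)
        assert ms.ppv == pytest.approx(mb.ppv)
        assert ms.npv == pytest.approx(mb.npv)
        # CIs shrink with more data
        assert (ms.sensitivity_ci[1] - ms.sensitivity_ci[0]) < (
            mb.sensitivity_ci[1] - mb.sensitivity_ci[0]
        )


class TestRocCurve:
    def test_enumerated_operating_points(self):
        curve = roc_curve([3, 5, 1, 4], [True, True, False, False])
        pts = {(p.threshold, p.sensitivity, p.specificity) for p in curve.points}
        assert (2.0, 1.0, 0.5) in pts
        assert (4.5, 0.5, 1.0) in pts

    def test_thresholds_are_ordered_and_sensitivity_monotone(self):
        curve = roc_curve([3, 5, 1, 4, 4, 2], [True, True, False, False, True, False])
        ts = [p.threshold for p in curve.points]
        assert ts == sorted(ts)
        sens = [p.sensitivity for p in curve.points]
        assert all(b <= a for a, b in zip(sens, sens[1:]))

    def test_complete_separation_contains_perfect_point(self):
        curve = roc_curve([10, 11, 1, 2], [True, True, False, False])
        assert any(p.sensitivity == 1.0 and p.specificity == 1.0 for p in curve.points)
        assert curve.auc == 1.0

    def test_identical_scores_leave_only_sentinels(self):
        curve = roc_curve([2.0, 2.0, 2.0], [True, False, True])
        assert len(curve.points) == 2
        assert {(p.sensitivity, p.specificity) for p in curve.points} == {
            (1.0, 0.0),
            (0.0, 1.0),
        }

    def test_single_class_rejected(self):
        with pytest.raises(DegenerateSetError):
            roc_curve([1, 2], [True, True])


class TestAuc:
    @pytest.mark.parametrize(
        "scores,labels,expected",
        [
            ([3, 5, 1, 4], [True, True, False, False], 0.75),
            ([2, 2], [True, False], 0.5),
            ([10, 11, 1, 2], [True, True, False, False], 1.0),
        ],
    )
    def test_reference_values(self, scores, labels, expected):
        assert auc(scores, labels) == pytest.approx(expected)

    @given(
        scores=st.lists(st.integers(0, 8), min_size=4, max_size=20),
        data=st.data(),
    )
    def test_rank_identity_matches_brute_force(self, scores, data):
        labels = data.draw(
            st.lists(st.booleans(), min_size=len(scores), max_size=len(scores))
        )
        if all(labels) or not any(labels):
            labels[0] = True
            labels[-1] = False
        assert auc(scores, labels) == pytest.approx(
            brute_force_auc(scores, labels), rel=1e-12
        )

    @given(st.lists(st.floats(0.01, 100), min_size=4, max_size=15, unique=True))
    def test_invariant_under_monotone_transform(self, scores):
        labels = [i % 2 == 0 for i in range(len(scores))]
        base = auc(scores, labels)
        assert auc(np.log(scores), labels) == pytest.approx(base)
        assert auc([2 * s + 1 for s in scores], labels) == pytest.approx(base)


class TestOptimalCutoff:
    def test_tie_breaks_toward_sensitivity_then_lower_threshold(self):
        curve = roc_curve([3, 5, 1, 4], [True, True, False, False])
        best = optimal_cutoff(curve)
        # J ties at 0.5 for thresholds 2.0 and 4.5; screening prefers
        # the sensitive operating point.
        assert best.threshold == pytest.approx(2.0)
        assert best.sensitivity == 1.0 and best.specificity == 0.5

    def test_complete_separation_reaches_j_of_one(self):
        curve = roc_curve([10, 11, 1, 2], [True, True, False, False])
        best = optimal_cutoff(curve)
        assert best.youden_j == pytest.approx(1.0)
        assert best.threshold == pytest.approx(6.0)

    def test_degenerate_curve_returns_its_only_informative_point(self):
        curve = roc_curve([2.0, 1.0], [True, False])
        best = optimal_cutoff(curve)
        assert best.threshold == pytest.approx(1.5)

    def test_unknown_criterion(self):
        curve = roc_curve([2.0, 1.0], [True, False])
        with pytest.raises(DomainError):
            optimal_cutoff(curve, criterion="closest_topleft")


def exact_mw_p(x, y):
    """Full enumeration oracle for the two-sided Mann-Whitney p-value
    (no ties): fraction of label reassignments at least as extreme in
    |U - n1*n2/2| as observed."""
    pooled = list(x) + list(y)
    n1 = len(x)
    half = len(x) * len(y) / 2.0

    def u_stat(xs, ys):
        return sum(1.0 if a > b else 0.5 if a == b else 0.0 for a in xs for b in ys)

    dev_obs = abs(u_stat(x, y) - half)
    idx = set(range(len(pooled)))
    hits = total = 0
    for comb in combinations(range(len(pooled)), n1):
        xs = [pooled[i] for i in comb]
        ys = [pooled[i] for i in idx - set(comb)]
        total += 1
        if abs(u_stat(xs, ys) - half) >= dev_obs - 1e-9:
            hits += 1
    return hits / total


class TestMannWhitney:
    def test_small_exact_cases(self):
        u, p = mann_whitney([1, 2], [3, 4])
        assert u == 0.0
        assert p == pytest.approx(2 / 6)
        u, p = mann_whitney([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(2 / 20)

    def test_identical_samples_give_p_one(self):
        _, p = mann_whitney([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == 1.0

    def test_empty_sample_rejected(self):
        with pytest.raises(DomainError):
            mann_whitney([], [1.0])

    def test_exact_matches_enumeration(self):
        rng = np.random.default_rng(42)
        for n1 in (1, 2, 3, 4, 5):
            for n2 in (1, 2, 3, 4, 5):
                vals = rng.permutation(rng.uniform(0, 1, n1 + n2))
                x, y = list(vals[:n1]), list(vals[n1:])
                _, p = mann_whitney(x, y)
                assert p == pytest.approx(exact_mw_p(x, y), abs=1e-12)

    def test_exact_close_to_normal_approximation(self):
        # For n1 = n2 = 6 without ties the exact p and the corrected
        # normal approximation differ by < 0.02.
        from scipy import stats

        rng = np.random.default_rng(7)
        for _ in range(20):
            x = list(rng.normal(0, 1, 6))
            y = list(rng.normal(0.5, 1, 6))
            _, p_exact = mann_whitney(x, y)
            p_norm = float(
                stats.mannwhitneyu(
                    x, y, alternative="two-sided", method="asymptotic",
                    use_continuity=True,
                ).pvalue
            )
            assert abs(p_exact - p_norm) < 0.02

    def test_separated_groups_on_fixture_kindex(self, fixture_cohort):
        from kflc import kappa_index

        ms = [
            kappa_index(r).k_index
            for r in fixture_cohort
            if r.diagnosis is Diagnosis.MS
        ]
        other = [
            kappa_index(r).k_index
            for r in fixture_cohort
            if r.diagnosis is Diagnosis.OTHER
        ]
        _, p = mann_whitney(ms, other)
        assert p < 0.0001
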