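"""Confusion metrics, ROC/AUROC, Youden, DeLong and Spearman against oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from fibrotriage import (
    ConfusionMatrix,
    DomainError,
    auroc_mann_whitney,
    delong,
    delong_compare,
    empirical_auroc,
    predictive_values,
    spearman,
    summarize,
    youden_cutoff,
)


def brute_force_auroc(scores, labels):
    """O(m*n) pairwise Mann–Whitney oracle: ties count 1/2."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    pos, neg = scores[labels], scores[~labels]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestSummarize:
    def test_reference_operating_point(self):
        # matrix inverted from printed sens 67.86 / spec 84.00 on 28 vs 125
        s = summarize(ConfusionMatrix(tp=19, fn=9, fp=20, tn=105))
        assert s.sensitivity == pytest.approx(0.6786, abs=5e-5)
        assert s.specificity == pytest.approx(0.84)
        assert s.ppv == pytest.approx(0.4872, abs=5e-5)
        assert s.prevalence == pytest.approx(28 / 153)

    def test_perfect_test(self):
        s = summarize(ConfusionMatrix(tp=1, fp=0, fn=0, tn=1))
        assert (s.sensitivity, s.specificity, s.ppv, s.npv, s.accuracy) == (1, 1, 1, 1, 1)

    def test_degenerate_margin_is_nan_not_zero(self):
        s = summarize(ConfusionMatrix(tp=0, fn=5, fp=0, tn=5))
        assert s.sensitivity == 0 and s.specificity == 1 and math.isnan(s.ppv)

    def test_all_zero_matrix_rejected(self):
        with pytest.raises(DomainError):
            summarize(ConfusionMatrix(0, 0, 0, 0))

    def test_negative_counts_rejected(self):
        with pytest.raises(DomainError):
            ConfusionMatrix(tp=-1, fp=0, fn=0, tn=1)


class TestPredictiveValues:
    def test_bayes_at_reference_operating_point(self):
        ppv, npv = predictive_values(0.6786, 0.8400, 28 / 153)
        assert ppv == pytest.approx(0.487, abs=5e-4)
        # hand evaluation: spec*(1-p) / (spec*(1-p) + (1-s)*p)
        assert npv == pytest.approx(0.921, abs=5e-4)

    def test_perfect_test_any_prevalence(self):
        assert predictive_values(1, 1, 0.3) == (1.0, 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(DomainError):
            predictive_values(1.2, 0.5, 0.5)

    def test_bayes_consistency_with_confusion_matrix(self, rng):
        """predictive_values at the matrix's own prevalence reproduces its PPV/NPV."""
        for _ in range(25):
            tp, fp, fn, tn = rng.integers(1, 50, size=4)
            s = summarize(ConfusionMatrix(int(tp), int(fp), int(fn), int(tn)))
            ppv, npv = predictive_values(s.sensitivity, s.specificity, s.prevalence)
            assert ppv == pytest.approx(s.ppv)
            assert npv == pytest.approx(s.npv)


class TestAUROC:
    def test_hand_counted_pairs(self):
        # pairs: (2>1)=1, (2=2)=.5, (3>1)=1, (3>2)=1 → 3.5/4
        assert auroc_mann_whitney([2, 3, 1, 2], [1, 1, 0, 0]) == pytest.approx(0.875)

    def test_all_tied_scores_give_half(self):
        res = empirical_auroc([5, 5, 5, 5], [1, 1, 0, 0])
        assert res.auroc == pytest.approx(0.5)
        assert res.youden_j == pytest.approx(0.0)

    def test_binary_score_auroc_is_mean_of_sens_and_spec(self, rng):
        for _ in range(10):
            m, n = 28, 125
            sens, spec = rng.uniform(0.2, 0.95, size=2)
            pos = (rng.random(m) < sens).astype(float)
            neg = (rng.random(n) >= spec).astype(float)
            scores = np.concatenate([pos, neg])
            labels = np.concatenate([np.ones(m, bool), np.zeros(n, bool)])
            s_hat = pos.mean()
            sp_hat = 1 - neg.mean()
            assert auroc_mann_whitney(scores, labels) == pytest.approx((s_hat + sp_hat) / 2)

    def test_matches_brute_force_on_random_instances(self, rng):
        for _ in range(100):
            n = int(rng.integers(4, 30))
            scores = rng.integers(0, 8, size=n).astype(float)  # heavy ties
            labels = np.zeros(n, bool)
            labels[rng.choice(n, size=int(rng.integers(1, n)), replace=False)] = True
            if labels.all() or not labels.any():
                continue
            assert auroc_mann_whitney(scores, labels) == pytest.approx(
                brute_force_auroc(scores, labels)
            )

    def test_matches_sklearn_reference(self, rng):
        from sklearn.metrics import roc_auc_score

        scores = rng.normal(size=200)
        labels = rng.random(200) < 0.3
        assert auroc_mann_whitney(scores, labels) == pytest.approx(
            roc_auc_score(labels, scores)
        )

    def test_single_class_rejected(self):
        with pytest.raises(DomainError):
            empirical_auroc([1.0, 2.0], [True, True])

    def test_trapezoid_of_stored_points_equals_auroc(self, rng):
        import warnings

        scores = rng.integers(0, 10, size=60).astype(float)
        labels = rng.random(60) < 0.4
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)  # orientation note on random data
            res = empirical_auroc(scores, labels)
        xs = np.concatenate([res.points[:, 2], [1.0]])
        ys = np.concatenate([res.points[:, 1], [1.0]])
        assert np.trapezoid(ys, xs) == pytest.approx(res.auroc)
        assert (res.points[0, 1], res.points[0, 2]) == (0.0, 0.0)

    def test_below_half_warns_but_reports_as_is(self):
        with pytest.warns(UserWarning, match="no auto-flip"):
            res = empirical_auroc([1, 2, 3, 4], [1, 1, 0, 0])
        assert res.auroc == pytest.approx(0.0)

    @given(
        # resolution-limited scores so the affine shift cannot merge distinct
        # values through float rounding
        st.lists(st.floats(-50, 50).map(lambda v: round(v, 3)), min_size=6, max_size=40),
        st.floats(0.1, 3.0),
    )
    @settings(max_examples=80, derandomize=True)
    def test_invariant_under_strictly_increasing_transforms(self, values, slope):
        scores = np.asarray(values)
        labels = np.arange(len(scores)) % 2 == 0
        base = auroc_mann_whitney(scores, labels)
        assert auroc_mann_whitney(slope * scores + 3.0, labels) == pytest.approx(base)
        assert auroc_mann_whitney(np.expm1(scores / 50.0), labels) == pytest.approx(base)


class TestYouden:
    def test_separable_classes(self):
        # any cutoff in [2, 3) gives J = 1; observed-value candidates return 2
        assert youden_cutoff([3, 4, 1, 2], [1, 1, 0, 0]) == (2.0, pytest.approx(1.0))

    def test_all_tied(self):
        _, j = youden_cutoff([7, 7, 7], [1, 0, 1])
        assert j == pytest.approx(0.0)

    def test_tie_broken_toward_higher_sensitivity_then_smaller_cutoff(self):
        # exhaustive scan of cutoffs {1,2,3}: J = 0.5 at c=1 (sens 1.0) and
        # c=2 (sens 0.5); the tie resolves to c=1
        cutoff, j = youden_cutoff([2, 3, 1, 2], [1, 1, 0, 0])
        assert (cutoff, j) == (1.0, pytest.approx(0.5))

    def test_matches_exhaustive_scan(self, rng):
        for _ in range(50):
            n = int(rng.integers(6, 25))
            scores = rng.integers(0, 6, size=n).astype(float)
            labels = rng.random(n) < 0.5
            if labels.all() or not labels.any():
                continue
            pos, neg = scores[labels], scores[~labels]
            best = max(
                ((float(np.mean(pos > c)) + float(np.mean(neg <= c)) - 1,
                  float(np.mean(pos > c)), -c)
                 for c in np.unique(scores)),
            )
            cutoff, j = youden_cutoff(scores, labels)
            assert j == pytest.approx(best[0])
            assert cutoff == pytest.approx(-best[2])

    def test_midpoint_candidates_option(self):
        cutoff, j = youden_cutoff([3, 4, 1, 2], [1, 1, 0, 0], candidates="midpoint")
        assert 2 < cutoff < 3 and j == pytest.approx(1.0)


class TestDeLong:
    def test_hand_computed_placements(self):
        # V10 = {0.5, 1}, V01 = {1, 0.5} → var = 0.125/2 + 0.125/2
        auc, var, ci = delong([2, 4, 1, 3], [1, 1, 0, 0])
        assert auc == pytest.approx(0.75)
        assert var == pytest.approx(0.125)
        assert ci[0] <= auc <= ci[1]

    def test_perfect_separation_collapses_ci(self):
        auc, var, ci = delong([5, 6, 1, 2], [1, 1, 0, 0])
        assert (auc, var) == (1.0, 0.0)
        assert ci == (1.0, 1.0)

    def test_degenerate_class_sizes_rejected(self):
        with pytest.raises(DomainError):
            delong([1, 2, 3], [1, 0, 0])

    def test_variance_nonnegative_and_ci_contains_estimate(self, rng):
        for _ in range(30):
            scores = rng.normal(size=40)
            labels = rng.random(40) < 0.4
            if labels.sum() < 2 or (~labels).sum() < 2:
                continue
            auc, var, ci = delong(scores, labels)
            assert var >= 0
            assert ci[0] <= auc <= ci[1]

    def test_variance_against_stratified_bootstrap(self):
        """DeLong variance within 15% of a 10,000-rep bootstrap on binormal 30+120."""
        rng = np.random.default_rng(4242)
        pos = rng.normal(10.11, 1.15, size=30)
        neg = rng.normal(8.70, 1.00, size=120)
        scores = np.concatenate([pos, neg])
        labels = np.concatenate([np.ones(30, bool), np.zeros(120, bool)])
        _, var_delong, _ = delong(scores, labels)
        reps = 10_000
        boot = np.empty(reps)
        for b in range(reps):
            bp = pos[rng.integers(0, 30, size=30)]
            bn = neg[rng.integers(0, 120, size=120)]
            boot[b] = auroc_mann_whitney(
                np.concatenate([bp, bn]), labels
            )
        var_boot = boot.var(ddof=1)
        assert var_delong == pytest.approx(var_boot, rel=0.15)


class TestDeLongCompare:
    def test_identical_vectors(self):
        scores = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        labels = [1, 0, 1, 0, 1, 0]
        delta, z, p = delong_compare(scores, scores, labels)
        assert (delta, z, p) == (0.0, 0.0, 1.0)

    def test_monotone_transform_gives_zero_delta(self, rng):
        scores = rng.normal(size=50)
        labels = rng.random(50) < 0.4
        delta, _, p = delong_compare(scores, np.exp(scores), labels)
        assert delta == 0.0 and p == 1.0

    def test_zero_variance_nonzero_delta_warns(self):
        a = [10, 11, 12, 1, 2, 3]   # perfect separation (AUROC 1, zero variance)
        b = [1, 2, 3, 10, 11, 12]   # perfect anti-separation (AUROC 0, zero variance)
        labels = [1, 1, 1, 0, 0, 0]
        with pytest.warns(UserWarning, match="zero estimated variance"):
            delta, z, p = delong_compare(a, b, labels)
        assert p == 0.0 and delta != 0.0

    def test_against_permutation_oracle(self):
        """Paired z-test p within Monte-Carlo error of 10,000 label-preserving swaps."""
        rng = np.random.default_rng(777)
        m, n = 30, 120
        latent = np.concatenate([rng.normal(1.0, 1.0, m), rng.normal(0.0, 1.0, n)])
        labels = np.concatenate([np.ones(m, bool), np.zeros(n, bool)])
        # two correlated markers reading the same latent severity
        a = latent + rng.normal(0, 0.7, m + n)
        b = 0.85 * latent + rng.normal(0, 0.7, m + n)
        _, _, p_delong = delong_compare(a, b, labels)
        reps = 10_000
        observed = abs(auroc_mann_whitney(a, labels) - auroc_mann_whitney(b, labels))
        hits = 0
        for _ in range(reps):
            swap = rng.random(m + n) < 0.5
            aa = np.where(swap, b, a)
            bb = np.where(swap, a, b)
            d = abs(auroc_mann_whitney(aa, labels) - auroc_mann_whitney(bb, labels))
            if d >= observed - 1e-12:
                hits += 1
        p_perm = hits / reps
        mc_err = 3.0 * math.sqrt(max(p_perm * (1 - p_perm), 1e-4) / reps)
        assert abs(p_delong - p_perm) <= 0.05 + mc_err


class TestSpearman:
    def test_strictly_monotone(self):
        rho, p = spearman([1.0, 2.5, 3.7, 9.0], ["F0", "F1", "F3", "F4"])
        assert rho == pytest.approx(1.0) and p == pytest.approx(0.0)

    def test_reversed_order(self):
        rho, _ = spearman([4, 3, 2, 1], [0, 1, 2, 3])
        assert rho == pytest.approx(-1.0)

    def test_hand_midranks(self):
        # midranks (1, 2.5, 2.5, 4) vs (1, 3, 2, 4); Pearson = 0.9487
        rho, _ = spearman([1, 2, 2, 4], [1, 3, 2, 4])
        assert rho == pytest.approx(0.9487, abs=5e-5)

    def test_matches_scipy_reference(self, rng):
        scores = rng.normal(size=100)
        stages = rng.integers(0, 5, size=100)
        rho, p = spearman(scores, stages)
        ref = stats.spearmanr(scores, stages)
        assert rho == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_zero_rank_variance_undefined(self):
        rho, p = spearman([1.0, 1.0, 1.0, 1.0], [0, 1, 2, 3])
        assert math.isnan(rho) and math.isnan(p)

    def test_too_few_subjects_rejected(self):
        with pytest.raises(DomainError):
            spearman([1, 2], [0, 1])
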