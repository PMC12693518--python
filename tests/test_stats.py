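"""Compositional statistics: closure, Dirichlet regression, per-class
beta regression, and BH FDR control."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from berpatch.stats import (
    DirichletRegression,
    beta_component_tests,
    bh_adjust,
    close,
    lrt_global,
)

CLASSES = list("abc")


def _table(rows, groups=None):
    df = pd.DataFrame(rows, columns=CLASSES[: len(rows[0])])
    if groups is not None:
        df["group"] = groups
    return df


class TestClose:
    def test_zeros_replaced_and_rows_renormalized(self):
        df = close(_table([[0.0, 0.5, 0.5]]), CLASSES, pseudocount=1e-6)
        row = df[CLASSES].to_numpy()[0]
        assert np.all(row > 0)
        assert row.sum() == pytest.approx(1.0, abs=1e-9)

    def test_interior_row_nearly_unchanged(self):
        df = close(_table([[0.2, 0.3, 0.5]]), CLASSES, pseudocount=1e-6)
        assert np.allclose(df[CLASSES].to_numpy()[0], [0.2, 0.3, 0.5], atol=3e-6)

    def test_all_zero_row_is_error(self):
        with pytest.raises(ValueError):
            close(_table([[0.0, 0.0, 0.0]]), CLASSES)

    def test_negative_is_error(self):
        with pytest.raises(ValueError):
            close(_table([[-0.1, 0.6, 0.5]]), CLASSES)


class TestDirichletRegression:
    def test_alpha_recovery_single_group(self):
        """MLE recovers the generating concentrations within 10% at n=500."""
        rng = np.random.default_rng(11)
        alpha = np.array([4.0, 8.0, 2.0])
        df = _table(rng.dirichlet(alpha, size=500))
        res = DirichletRegression.from_dataframe(df, CLASSES).fit()
        ahat = res.alpha([[1.0]])[0]
        assert res.converged
        assert np.all(np.abs(ahat - alpha) / alpha < 0.10)

    def test_intercept_only_mean_direction(self):
        """Fitted expected composition matches the sample mean direction."""
        rng = np.random.default_rng(12)
        df = _table(rng.dirichlet([5.0, 3.0, 2.0], size=200))
        res = DirichletRegression.from_dataframe(df, CLASSES).fit()
        expected = res.expected_composition([[1.0]])[0]
        mean = df[CLASSES].to_numpy().mean(axis=0)
        assert np.allclose(expected, mean / mean.sum(), atol=1e-2)

    def test_identical_groups_give_near_zero_coefficients(self):
        rng = np.random.default_rng(13)
        y = rng.dirichlet([5.0, 3.0, 2.0], size=20)
        df = _table(np.vstack([y, y]), groups=["g1"] * 20 + ["g2"] * 20)
        res = DirichletRegression.from_dataframe(df, CLASSES, group="group").fit()
        assert np.allclose(res.params[1], 0.0, atol=1e-4)

    def test_optimum_at_least_moment_start(self):
        rng = np.random.default_rng(14)
        df = _table(rng.dirichlet([2.0, 2.0, 6.0], size=30))
        res = DirichletRegression.from_dataframe(df, CLASSES).fit()
        assert res.llf >= res.start_llf - 1e-8

    def test_group_needs_two_samples(self):
        df = _table([[0.2, 0.3, 0.5]] * 3, groups=["g1", "g1", "g2"])
        with pytest.raises(ValueError):
            DirichletRegression.from_dataframe(df, CLASSES, group="group")

    def test_requires_interior_compositions(self):
        with pytest.raises(ValueError):
            DirichletRegression(np.array([[0.0, 0.5, 0.5]]), np.ones((1, 1)))

    def test_summary_mentions_loglik(self):
        rng = np.random.default_rng(15)
        df = _table(rng.dirichlet([3.0, 3.0, 3.0], size=12))
        res = DirichletRegression.from_dataframe(df, CLASSES).fit()
        text = res.summary()
        assert "logLik" in text and "intercept" in text


class TestLRT:
    def _fits(self, y, groups):
        df = _table(y, groups=groups)
        full = DirichletRegression.from_dataframe(df, CLASSES, group="group").fit()
        null = DirichletRegression.from_dataframe(df, CLASSES).fit()
        return full, null

    def test_no_signal_statistic_near_zero(self):
        """Identical data in the two groups: the group term buys ~nothing."""
        rng = np.random.default_rng(21)
        y = rng.dirichlet([4.0, 4.0, 4.0], size=10)
        full, null = self._fits(np.vstack([y, y]), ["g1"] * 10 + ["g2"] * 10)
        res = lrt_global(full, null)
        assert res.statistic == pytest.approx(0.0, abs=1e-4)
        assert res.pvalue > 0.999
        assert res.df == 3

    def test_separated_groups_highly_significant(self):
        rng = np.random.default_rng(22)
        y1 = rng.dirichlet([20.0, 5.0, 5.0], size=10)
        y2 = rng.dirichlet([5.0, 20.0, 5.0], size=10)
        full, null = self._fits(np.vstack([y1, y2]), ["g1"] * 10 + ["g2"] * 10)
        res = lrt_global(full, null)
        assert res.pvalue < 1e-6

    def test_statistic_invariant_to_class_reordering(self):
        rng = np.random.default_rng(23)
        y1 = rng.dirichlet([8.0, 3.0, 2.0], size=8)
        y2 = rng.dirichlet([3.0, 8.0, 2.0], size=8)
        y = np.vstack([y1, y2])
        groups = ["g1"] * 8 + ["g2"] * 8
        full, null = self._fits(y, groups)
        ref = lrt_global(full, null).statistic
        perm = [2, 0, 1]
        full2, null2 = self._fits(y[:, perm], groups)
        assert lrt_global(full2, null2).statistic == pytest.approx(ref, abs=1e-4)

    def test_not_nested_rejected(self):
        rng = np.random.default_rng(24)
        df = _table(rng.dirichlet([3.0, 3.0, 3.0], size=12))
        null = DirichletRegression.from_dataframe(df, CLASSES).fit()
        with pytest.raises(ValueError):
            lrt_global(null, null)


class TestBetaComponents:
    def test_mean_shift_detected_and_recovered(self):
        """A logit-mean shift in one class yields a small q there and an
        estimate close to the generating shift."""
        rng = np.random.default_rng(31)
        n = 40
        # class "a" mean shifts 0.25 -> 0.5; class "b" keeps the same
        # Beta(10, 30) marginal in both groups
        y1 = rng.dirichlet([10.0, 10.0, 20.0], size=n)
        y2 = rng.dirichlet([20.0, 10.0, 10.0], size=n)
        df = _table(np.vstack([y1, y2]), groups=["g1"] * n + ["g2"] * n)
        results = beta_component_tests(df, CLASSES, "group")
        by = {r.label: r for r in results}
        assert by["a"].qvalue < 0.01
        assert by["b"].pvalue > 0.01

    def test_null_type_one_error_near_nominal(self):
        """Per-class rejection rate on null data stays near 5%."""
        rng = np.random.default_rng(32)
        rejections = 0
        trials = 150
        for _ in range(trials):
            y = rng.dirichlet([10.0, 20.0, 10.0], size=12)
            df = _table(y, groups=["g1"] * 6 + ["g2"] * 6)
            res = beta_component_tests(df, CLASSES, "group")
            rejections += sum(r.pvalue < 0.05 for r in res)
        rate = rejections / (3 * trials)
        assert 0.01 < rate < 0.13

    def test_single_class_q_equals_p(self):
        rng = np.random.default_rng(33)
        df = pd.DataFrame({"a": rng.beta(5, 5, size=12),
                           "group": ["g1"] * 6 + ["g2"] * 6})
        res = beta_component_tests(df, ["a"], "group")
        assert res[0].qvalue == pytest.approx(res[0].pvalue)

    def test_degenerate_class_reported_not_raised(self):
        rng = np.random.default_rng(34)
        df = pd.DataFrame({
            "a": np.full(12, 0.5),
            "b": rng.beta(5, 5, size=12),
            "group": ["g1"] * 6 + ["g2"] * 6,
        })
        res = beta_component_tests(df, ["a", "b"], "group")
        by = {r.label: r for r in res}
        assert by["a"].status == "degenerate"
        assert by["b"].status == "ok" and by["b"].qvalue is not None


def _bh_brute_force(p):
    """Step-up oracle: q_(i) = min_{j>=i} m*p_(j)/j, capped at 1."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, m * p[i] / rank)
        q[i] = min(running, 1.0)
    return q


class TestBH:
    def test_worked_example(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_all_ones(self):
        assert np.allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_single_p(self):
        assert bh_adjust([0.2])[0] == pytest.approx(0.2)

    @settings(max_examples=100, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=25))
    def test_agrees_with_brute_force(self, pvals):
        assert np.allclose(bh_adjust(pvals), _bh_brute_force(pvals), atol=1e-12)

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=15))
    def test_never_decreases_and_order_preserving(self, pvals):
        q = bh_adjust(pvals)
        p = np.asarray(pvals)
        assert np.all(q >= p - 1e-15)
        # order preservation: smaller p never gets a larger q
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(q[order]) >= -1e-15)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])
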