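"""Normalization and moderated-t differential expression.

Oracles: hand-computed quantile example, the arsinh asymptote, a brute-force
BH step-up, the ordinary two-sample t-test (d0=0 limit), and parameter
recovery against the synthetic generator.
"""

import dataclasses
import math

import numpy as np
import pytest
from scipy import special, stats

from comorbsig.io_formats import ExpressionDataset, ValidationError
from comorbsig.normalize_dge import (
    ModeratedPrior,
    bh_adjust,
    call_degs,
    fit_moderated_prior,
    moderated_t_test,
    normalize_dataset,
    quantile_normalize,
    vs_transform,
)
from comorbsig.synthetic_data import SynthSpec, simulate_expression


def _toy_dataset(values, n_case=2):
    values = np.asarray(values, dtype=float)
    G, S = values.shape
    return ExpressionDataset(
        "toy",
        [f"g{i}" for i in range(G)],
        [f"s{j}" for j in range(S)],
        values,
        ["case"] * n_case + ["control"] * (S - n_case),
    )


class TestQuantileNormalize:
    def test_two_by_two_hand_example(self):
        out = quantile_normalize(np.array([[1.0, 4.0], [3.0, 2.0]]))
        assert np.array_equal(out, np.array([[1.5, 3.5], [3.5, 1.5]]))

    def test_single_column_unchanged(self, rng):
        x = rng.normal(size=(50, 1))
        assert np.allclose(quantile_normalize(x), x)

    def test_identical_columns_unchanged(self, rng):
        col = rng.normal(size=30)
        x = np.column_stack([col, col, col])
        assert np.allclose(quantile_normalize(x), x)

    def test_all_columns_share_sorted_values_exactly(self, rng):
        x = rng.normal(size=(200, 7))
        out = quantile_normalize(x)
        ref = np.sort(out[:, 0])
        for j in range(1, 7):
            assert np.array_equal(np.sort(out[:, j]), ref)

    def test_ties_stay_tied(self):
        x = np.array([[1.0, 5.0], [1.0, 2.0], [3.0, 1.0]])
        out = quantile_normalize(x)
        assert out[0, 0] == out[1, 0]
        assert out[0, 0] < out[2, 0]  # order preserved

    def test_nonfinite_rejected(self):
        with pytest.raises(ValidationError):
            quantile_normalize(np.array([[1.0, np.nan], [2.0, 3.0]]))


class TestVsTransform:
    def test_zero_maps_to_zero(self):
        assert vs_transform(np.array([[0.0, 1.0], [2.0, 3.0]]))[0, 0] == 0.0

    def test_large_intensities_behave_like_log(self, rng):
        x = rng.uniform(1, 10, size=(100, 3))
        c = float(np.median(x))
        big = x * 1000  # >= 100x the median scale
        out = vs_transform(big, scale=c)
        assert np.allclose(out, np.log(2 * big / c), rtol=0.01)

    def test_monotone(self, rng):
        x = np.sort(rng.uniform(0, 50, size=100))
        y = vs_transform(x.reshape(-1, 1))
        assert np.all(np.diff(y[:, 0]) > 0)

    def test_all_zero_matrix_rejected(self):
        with pytest.raises(ValidationError):
            vs_transform(np.zeros((3, 3)))


class TestModeratedPrior:
    def test_constant_variances_give_infinite_d0(self):
        prior = fit_moderated_prior(np.full(100, 0.25), df=10)
        assert math.isinf(prior.d0)
        # with d0 infinite the prior variance is the common s2 value,
        # up to the digamma bias correction of the log-mean
        expected = 0.25 * math.exp(-(special.digamma(5) - math.log(5)))
        assert prior.s0_sq == pytest.approx(expected, rel=1e-9)

    def test_d0_decreases_as_log_variance_spread_grows(self, rng):
        df = 20
        priors = []
        for d0_true in (16.0, 4.0, 1.0):  # increasing spread of log s2
            sig2 = 0.05 * d0_true / rng.chisquare(d0_true, 5000)
            s2 = sig2 * rng.chisquare(df, 5000) / df
            priors.append(fit_moderated_prior(s2, df).d0)
        assert priors[0] > priors[1] > priors[2]

    def test_recovery_at_moderate_scale(self, rng):
        sig2 = 0.05 * 4 / rng.chisquare(4, 5000)
        s2 = sig2 * rng.chisquare(20, 5000) / 20
        prior = fit_moderated_prior(s2, 20)
        assert prior.d0 == pytest.approx(4.0, rel=0.3)
        assert prior.s0_sq == pytest.approx(0.05, rel=0.15)

    def test_too_few_genes_rejected(self):
        with pytest.raises(ValidationError):
            fit_moderated_prior(np.full(5, 0.1), df=4)


class TestBHAdjust:
    def test_hand_examples(self):
        assert bh_adjust(np.array([0.03]))[0] == pytest.approx(0.03)
        assert np.allclose(bh_adjust(np.array([0.01, 0.02, 0.03])), [0.03, 0.03, 0.03])
        assert np.all(bh_adjust(np.ones(5)) == 1.0)

    def test_matches_brute_force_step_up(self, rng):
        def brute(p):
            m = len(p)
            order = np.argsort(p, kind="stable")
            adj = np.empty(m)
            running = 1.0
            for rank in range(m, 0, -1):
                i = order[rank - 1]
                running = min(running, m * p[i] / rank)
                adj[i] = running
            return adj

        for _ in range(1000):
            p = rng.uniform(size=rng.integers(1, 40))
            assert np.allclose(bh_adjust(p), brute(p), rtol=0, atol=1e-15)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_adjust(np.array([0.5, 1.5]))


class TestModeratedT:
    def test_identical_groups_give_unit_p(self):
        # one gene constant everywhere: zero effect, zero variance -> p = 1
        values = np.array([[2.0, 2.0, 2.0, 2.0], [1.0, 2.0, 3.0, 4.0]])
        table = moderated_t_test(_toy_dataset(values), prior=ModeratedPrior(1.0, 0.1))
        assert table.loc[0, "effect"] == 0.0
        assert table.loc[0, "p_raw"] == 1.0

    def test_d0_zero_reduces_to_ordinary_t(self, rng):
        values = rng.normal(size=(60, 12))
        ds = _toy_dataset(values, n_case=5)
        t_ref, p_ref = stats.ttest_ind(values[:, :5], values[:, 5:], axis=1, equal_var=True)
        table0 = moderated_t_test(ds, prior=_zero_prior())
        assert np.allclose(table0["t_mod"], t_ref, rtol=1e-10)
        assert np.allclose(table0["p_raw"], p_ref, rtol=1e-10)

    def test_infinite_d0_uses_prior_variance_and_normal_reference(self, rng):
        values = rng.normal(size=(30, 10))
        ds = _toy_dataset(values, n_case=5)
        s0 = 1.3
        table = moderated_t_test(ds, prior=ModeratedPrior(math.inf, s0))
        effect = values[:, :5].mean(axis=1) - values[:, 5:].mean(axis=1)
        t_exp = effect / (math.sqrt(s0) * math.sqrt(1 / 5 + 1 / 5))
        assert np.allclose(table["t_mod"], t_exp)
        assert np.allclose(table["p_raw"], 2 * stats.norm.sf(np.abs(t_exp)))

    def test_larger_effect_means_smaller_p_at_fixed_variance(self):
        base = np.array([[0.0, 0.0, 0.0, 1.0, -1.0, 0.0]])
        rows = []
        for shift in (0.5, 1.0, 2.0):
            v = base.copy()
            v[0, :3] += shift
            v = np.vstack([v, [[0.0, 1.0, -1.0, 0.0, 1.0, -1.0]]])
            t = moderated_t_test(_toy_dataset(v, n_case=3), prior=ModeratedPrior(2.0, 0.5))
            rows.append(t.loc[0, "p_raw"])
        assert rows[0] > rows[1] > rows[2]

    def test_null_simulation_type_I_error_near_nominal(self):
        spec = dataclasses.replace(SynthSpec(), delta=0.0)
        _, b, _ = simulate_expression(spec, seed=11)
        table = moderated_t_test(normalize_dataset(b[0]))
        frac = float((table["p_raw"] < 0.05).mean())
        assert 0.03 <= frac <= 0.07

    def test_all_zero_variance_rejected(self):
        values = np.ones((3, 6))
        with pytest.raises(ValidationError):
            moderated_t_test(_toy_dataset(values, n_case=3), prior=_zero_prior())


def _zero_prior():
    """An explicit no-shrinkage prior (ordinary t-test)."""
    prior = ModeratedPrior.__new__(ModeratedPrior)
    object.__setattr__(prior, "d0", 0.0)
    object.__setattr__(prior, "s0_sq", 1.0)
    return prior


class TestCallDegs:
    def test_threshold_is_strict(self):
        import pandas as pd

        table = pd.DataFrame(
            {"gene_id": ["a", "b"], "p_adj": [0.1, 0.0999], "direction": ["up", "down"]}
        )
        sig = call_degs(table, fdr_threshold=0.1)
        assert sig.genes == {"b"}

    def test_empty_stats_give_empty_signature(self):
        import pandas as pd

        sig = call_degs(pd.DataFrame(columns=["gene_id", "p_adj", "direction"]))
        assert len(sig) == 0
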