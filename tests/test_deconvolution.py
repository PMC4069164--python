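"""Marker-constrained KL-NMF: masking, monotonicity, recovery, invariances."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mixsurv import deconvolution as dec, simulate
from oracles import kl_oracle, simplex_lsq_proportions


class TestMarkerMask:
    def test_two_type_exclusive_mask(self):
        mask = dec.build_marker_mask({"T1": ["a"], "T2": ["b"]}, ["a", "b"])
        np.testing.assert_array_equal(mask.matrix, [[True, False], [False, True]])
        assert mask.genes == ["a", "b"] and mask.cell_types == ["T1", "T2"]

    def test_ambiguous_gene_dropped(self):
        mask = dec.build_marker_mask({"T1": ["a", "c"], "T2": ["b", "c"]}, ["a", "b", "c"])
        assert mask.n_genes == 2 and mask.dropped_ambiguous == ["c"]

    def test_five_set_rows_have_single_support(self):
        markers = {t: [f"{t}{k}" for k in range(3)] for t in ("B", "T", "NK", "DC", "Mo")}
        genes = [g for v in markers.values() for g in v]
        mask = dec.build_marker_mask(markers, genes)
        assert mask.matrix.shape == (15, 5)
        assert (mask.matrix.sum(axis=1) == 1).all()

    def test_type_without_matched_markers_raises(self):
        with pytest.raises(ValueError, match="T2"):
            dec.build_marker_mask({"T1": ["a"], "T2": ["zzz"]}, ["a", "b"])

    def test_all_genes_mode_appends_unconstrained_rows(self):
        mask = dec.build_marker_mask({"T1": ["a"], "T2": ["b"]}, ["a", "b", "x", "y"],
                                     include_non_markers=True)
        assert mask.n_genes == 4
        assert mask.matrix[2:].all()


class TestInitialize:
    @pytest.fixture()
    def small(self):
        mask = dec.build_marker_mask({"T1": ["a", "b"], "T2": ["c", "d"]},
                                     ["a", "b", "c", "d"])
        X = np.abs(np.random.default_rng(0).normal(50, 10, (4, 6)))
        return X, mask

    def test_deterministic_under_seed(self, small):
        X, mask = small
        np.testing.assert_array_equal(dec.initialize(X, mask, 5)[0],
                                      dec.initialize(X, mask, 5)[0])

    def test_masked_entries_exactly_zero(self, small):
        X, mask = small
        W0, _ = dec.initialize(X, mask, 5)
        assert (W0[~mask.matrix] == 0).all()

    def test_product_mean_scaled_to_data(self, small):
        X, mask = small
        W0, H0 = dec.initialize(X, mask, 5)
        ratio = (W0 @ H0).mean() / X.mean()
        assert 0.5 <= ratio <= 2.0

    def test_all_zero_matrix_rejected(self, small):
        _, mask = small
        with pytest.raises(ValueError):
            dec.initialize(np.zeros((4, 6)), mask, 0)


class TestKLDivergence:
    def test_zero_iff_equal(self):
        W = np.array([[1.0], [2.0]])
        H = np.array([[3.0, 4.0]])
        assert dec.kl_divergence(W @ H, W, H) == 0.0

    def test_scalar_closed_form(self):
        # D([1] || [e]) = 1*log(1/e) - 1 + e = e - 2
        X = np.array([[1.0]])
        W = np.array([[np.e]])
        H = np.array([[1.0]])
        assert dec.kl_divergence(X, W, H) == pytest.approx(np.e - 2.0, abs=1e-12)

    def test_infinite_when_model_zero_on_positive_data(self):
        assert dec.kl_divergence(np.array([[1.0]]), np.array([[0.0]]),
                                 np.array([[1.0]])) == np.inf

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 2**20))
    def test_matches_elementwise_oracle_and_is_nonnegative(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.uniform(0, 5, (4, 3))
        W = rng.uniform(0.1, 2, (4, 2))
        H = rng.uniform(0.1, 2, (2, 3))
        d = dec.kl_divergence(X, W, H)
        assert d >= 0
        assert d == pytest.approx(kl_oracle(X, W @ H), rel=1e-12)

    def test_moving_model_away_from_data_increases_divergence(self):
        X = np.full((2, 2), 3.0)
        W = np.array([[1.0], [1.0]])
        divs = [dec.kl_divergence(X, W, np.array([[c, c]])) for c in (3.0, 4.0, 6.0, 9.0)]
        assert divs[0] == 0 and divs[0] < divs[1] < divs[2] < divs[3]


class TestUpdateStep:
    def _instance(self, seed=0, n=10, r=4, p=6):
        rng = np.random.default_rng(seed)
        markers = {f"T{t}": [f"g{t}_{k}" for k in range(n // r)] for t in range(r)}
        genes = [g for v in markers.values() for g in v]
        mask = dec.build_marker_mask(markers, genes)
        X = rng.uniform(1, 100, (len(genes), p))
        return X, mask

    def test_fixed_point_is_stationary(self):
        X, mask = self._instance()
        rng = np.random.default_rng(1)
        W = rng.uniform(0.5, 2, mask.matrix.shape)
        W[~mask.matrix] = 0
        H = rng.uniform(0.5, 2, (mask.n_types, 6))
        X_exact = W @ H
        W2, H2 = dec.update_step(W, H, X_exact, mask)
        np.testing.assert_allclose(W2, W, atol=1e-10)
        np.testing.assert_allclose(H2, H, atol=1e-10)

    def test_divergence_monotone_over_fifty_steps(self):
        X, mask = self._instance(seed=2)
        W, H = dec.initialize(X, mask, 3)
        prev = dec.kl_divergence(X, W, H)
        for _ in range(50):
            W, H = dec.update_step(W, H, X, mask)
            d = dec.kl_divergence(X, W, H)
            assert d <= prev * (1 + 1e-12) + 1e-10
            prev = d

    def test_masked_entries_stay_zero_across_iterations(self):
        X, mask = self._instance(seed=4)
        W, H = dec.initialize(X, mask, 5)
        for _ in range(100):
            W, H = dec.update_step(W, H, X, mask)
        assert (W[~mask.matrix] == 0).all()


class TestFit:
    def test_noiseless_recovery_matches_constrained_lsq_oracle(
        self, noiseless_mixture, four_type_signatures
    ):
        mix = noiseless_mixture
        basis, _ = four_type_signatures
        res = dec.fit(mix.expression, mix.marker_sets, n_restarts=3, seed=0)
        recov = dec.evaluate_recovery(mix.true_proportions, res.proportions)
        assert res.divergence < 1e-6
        assert recov["mad"] <= 0.01
        # independent oracle: simplex-constrained least squares with the true basis
        marker_rows = [g for v in mix.marker_sets.values() for g in v]
        oracle_h = simplex_lsq_proportions(
            mix.expression.loc[marker_rows].to_numpy(),
            basis.loc[marker_rows].to_numpy(),
        )
        np.testing.assert_allclose(res.proportions.to_numpy(), oracle_h, atol=0.01)

    def test_noisy_recovery_beats_reference_benchmark(self, noisy_mixture):
        res = dec.fit(noisy_mixture.expression, noisy_mixture.marker_sets, seed=1)
        recov = dec.evaluate_recovery(noisy_mixture.true_proportions, res.proportions)
        assert recov["mad"] <= 0.05
        assert recov["pearson_r"] >= 0.91

    def test_proportions_are_simplex_and_mask_respected(self, noisy_mixture):
        res = dec.fit(noisy_mixture.expression, noisy_mixture.marker_sets,
                      n_restarts=2, seed=2)
        p = res.proportions.to_numpy()
        assert (p >= 0).all()
        np.testing.assert_allclose(p.sum(axis=0), 1.0, atol=1e-9)
        markers = noisy_mixture.marker_sets
        for t in res.basis.columns:
            own = markers[t]
            off = res.basis.loc[own].drop(columns=t)
            assert (off.to_numpy() == 0).all()

    def test_divergence_trace_non_increasing(self, noisy_mixture):
        res = dec.fit(noisy_mixture.expression, noisy_mixture.marker_sets,
                      n_restarts=1, seed=3)
        assert (np.diff(res.divergence_trace) <= 1e-8).all()

    def test_more_restarts_never_worse(self, noisy_mixture):
        r1 = dec.fit(noisy_mixture.expression, noisy_mixture.marker_sets,
                     n_restarts=1, seed=4)
        r10 = dec.fit(noisy_mixture.expression, noisy_mixture.marker_sets,
                      n_restarts=10, seed=4)
        assert r10.divergence <= r1.divergence + 1e-9

    def test_scale_invariance_of_proportions(self, noisy_mixture):
        res1 = dec.fit(noisy_mixture.expression, noisy_mixture.marker_sets,
                       n_restarts=2, seed=5)
        res2 = dec.fit(noisy_mixture.expression * 7.5, noisy_mixture.marker_sets,
                       n_restarts=2, seed=5)
        np.testing.assert_allclose(res1.proportions.to_numpy(),
                                   res2.proportions.to_numpy(), atol=1e-6)

    def test_recovery_degrades_with_noise_on_average(self, four_type_signatures):
        basis, markers = four_type_signatures
        mads = []
        for noise in (0.0, 30.0, 300.0):
            vals = []
            for seed in range(3):
                mix = simulate.generate_mixtures(basis, 24, [1.0] * 4,
                                                 noise_sd=noise, seed=seed)
                res = dec.fit(mix.expression, markers, n_restarts=2, seed=seed)
                vals.append(dec.evaluate_recovery(mix.true_proportions,
                                                  res.proportions)["mad"])
            mads.append(np.mean(vals))
        assert mads[0] < mads[1] < mads[2]

    def test_all_genes_mode_runs_and_recovers(self, noisy_mixture):
        res = dec.fit(noisy_mixture.expression, noisy_mixture.marker_sets,
                      mode="all_genes", n_restarts=2, max_iter=500, seed=6)
        recov = dec.evaluate_recovery(noisy_mixture.true_proportions, res.proportions)
        assert recov["mad"] <= 0.05

    def test_determinism(self, noisy_mixture):
        a = dec.fit(noisy_mixture.expression, noisy_mixture.marker_sets, seed=7)
        b = dec.fit(noisy_mixture.expression, noisy_mixture.marker_sets, seed=7)
        pd.testing.assert_frame_equal(a.proportions, b.proportions)
        np.testing.assert_array_equal(a.divergence_trace, b.divergence_trace)


class TestEvaluateRecovery:
    def test_identity(self):
        h = pd.DataFrame(np.random.default_rng(0).dirichlet([1] * 3, 5).T)
        out = dec.evaluate_recovery(h, h)
        assert out["mad"] == 0 and out["pearson_r"] == pytest.approx(1.0)

    def test_constant_shift_gives_mad_of_shift(self):
        h = pd.DataFrame(np.random.default_rng(1).uniform(0, 1, (3, 5)))
        out = dec.evaluate_recovery(h, h + 0.1)
        assert out["mad"] == pytest.approx(0.1, abs=1e-12)

    @settings(max_examples=20, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 2**20))
    def test_matches_textbook_formulas(self, seed):
        rng = np.random.default_rng(seed)
        t = rng.uniform(0, 1, (3, 6))
        e = rng.uniform(0, 1, (3, 6))
        out = dec.evaluate_recovery(pd.DataFrame(t), pd.DataFrame(e))
        assert out["mad"] == pytest.approx(np.abs(t - e).mean(), rel=1e-12)
        tf, ef = t.ravel() - t.mean(), e.ravel() - e.mean()
        r_manual = (tf * ef).sum() / np.sqrt((tf**2).sum() * (ef**2).sum())
        assert out["pearson_r"] == pytest.approx(r_manual, rel=1e-12)

    def test_zero_variance_reports_nan(self):
        with pytest.warns(UserWarning):
            out = dec.evaluate_recovery(pd.DataFrame(np.full((2, 2), 0.5)),
                                        pd.DataFrame(np.full((2, 2), 0.5)))
        assert np.isnan(out["pearson_r"])
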