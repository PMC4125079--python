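"""Drift-null estimation and whitening."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from polyadapt.datamodel import EffectTable, FrequencyPanel, ValidationError
from polyadapt.null_model import (
    DriftModel,
    center_projection,
    genetic_values,
    va_scale,
)
from polyadapt.stats_tests import qx


def _table(alpha, maf=None):
    L = len(alpha)
    return EffectTable(
        snp_id=[f"s{i}" for i in range(L)],
        effect_allele=["A"] * L,
        alpha=alpha,
        ascertainment_maf=maf if maf is not None else [0.2] * L,
        imputed=[False] * L,
        b_value=[0.5] * L,
    )


def _panel(freq):
    freq = np.asarray(freq, dtype=float)
    return FrequencyPanel(
        snp_ids=[f"s{i}" for i in range(freq.shape[0])],
        population_ids=[f"p{j}" for j in range(freq.shape[1])],
        freq=freq,
        chromosomes=np.full(freq.shape[1], 50),
    )


class TestGeneticValues:
    def test_single_locus_closed_form(self):
        z = genetic_values(_table([0.5]), _panel([[0.2, 0.2, 0.2]]))
        assert z == pytest.approx([0.2, 0.2, 0.2])

    def test_zero_effects_give_zero_values(self):
        z = genetic_values(_table([0.0, 0.0]), _panel([[0.2, 0.4], [0.1, 0.9]]))
        assert np.all(z == 0.0)

    def test_matches_hand_summed_oracle(self, rng):
        alpha = rng.uniform(0, 1, 3)
        freq = rng.uniform(0, 1, (3, 4))
        z = genetic_values(_table(alpha), _panel(freq))
        # independent summation oracle
        expected = [2 * sum(alpha[l] * freq[l, m] for l in range(3)) for m in range(4)]
        assert z == pytest.approx(expected)

    def test_empty_input_errors(self):
        with pytest.raises(ValidationError):
            genetic_values(_table([1.0]), _panel([[0.1, 0.2], [0.3, 0.4]]))


class TestCenterProjection:
    def test_two_populations_closed_form(self):
        T = center_projection(2)
        assert T @ np.array([3.0, 1.0]) == pytest.approx([1.0])

    @given(st.integers(2, 12))
    @settings(deadline=None, derandomize=True, max_examples=20)
    def test_constant_vectors_map_to_zero(self, M):
        T = center_projection(M)
        assert T @ np.full(M, 7.3) == pytest.approx(np.zeros(M - 1), abs=1e-12)
        assert T.sum(axis=1) == pytest.approx(np.zeros(M - 1), abs=1e-12)

    def test_equals_mean_centering_oracle(self, rng):
        v = rng.normal(size=5)
        assert center_projection(5) @ v == pytest.approx((v - v.mean())[:4])

    def test_too_few_populations(self):
        with pytest.raises(ValidationError):
            center_projection(1)


class TestEstimateF:
    def test_identical_frequencies_give_zero_covariance(self):
        freq = np.tile(np.linspace(0.2, 0.8, 40)[:, None], (1, 5))
        model = DriftModel().fit(freq)
        assert np.allclose(model.F_, 0.0, atol=1e-12)
        with pytest.raises(ValidationError, match="singular"):
            model.whiten(np.arange(5.0), va=1.0)

    def test_recovers_projected_star_covariance(self, rng):
        # population frequencies drawn exactly under the model, no binomial layer
        M, K, c = 5, 40000, 0.1
        eps = rng.uniform(0.2, 0.8, K)
        p = eps[:, None] + np.sqrt(c * eps * (1 - eps))[:, None] * rng.standard_normal((K, M))
        model = DriftModel().fit(np.clip(p, 0, 1))
        T = center_projection(M)
        expected = c * T @ T.T
        assert np.allclose(model.F_, expected, atol=0.01 * c * M)

    def test_duplicated_population_gives_matching_off_diagonal(self, rng):
        K = 30000
        eps = rng.uniform(0.3, 0.7, K)
        base = eps[:, None] + np.sqrt(0.05 * eps * (1 - eps))[:, None] * rng.standard_normal((K, 3))
        freq = np.column_stack([base, base[:, -1]])  # last population duplicated
        model = DriftModel().fit(np.clip(freq, 0, 1))
        W = model.base_cov_
        assert W[2, 3] == pytest.approx(W[3, 3], rel=0.05)

    def test_too_few_usable_snps_errors(self):
        with pytest.raises(ValidationError):
            DriftModel().fit(np.ones((3, 5)))  # all fixed -> excluded


class TestVaScale:
    def test_single_locus_closed_form(self):
        scale = va_scale(_table([1.0]), _panel([[0.5, 0.5]]))
        assert scale == pytest.approx(1.0)  # V_A = 0.5, returned 2*V_A

    def test_zero_effects_error_before_whitening(self):
        with pytest.raises(ValidationError):
            va_scale(_table([0.0, 0.0]), _panel([[0.2, 0.3], [0.4, 0.5]]))

    def test_genetic_value_variance_matches_2va_times_F(self, rng):
        # Monte Carlo oracle: on a star tree, Var(Z_m) ~= 2*V_A*c around the mean
        M, L, c, R = 4, 60, 0.05, 4000
        alpha = np.abs(rng.normal(0, 0.1, L))
        eps = rng.uniform(0.3, 0.7, L)
        draws = eps[None, :, None] + np.sqrt(c * eps * (1 - eps))[None, :, None] \
            * rng.standard_normal((R, L, M))
        Z = 2.0 * np.einsum("l,rlm->rm", alpha, draws)
        va = 4.0 * np.sum(alpha**2 * eps * (1 - eps))
        emp_var = Z.var(axis=0).mean()
        assert emp_var == pytest.approx(va * c, rel=0.1)


class TestWhitening:
    def test_constant_values_whiten_to_zero(self, small_model):
        x = small_model.whiten(np.full(8, 3.0), va=1.0)
        assert x == pytest.approx(np.zeros(7), abs=1e-10)

    def test_round_trip_reconstructs_projection(self, small_model, rng):
        v = rng.normal(size=8)
        va = 2.5
        x = small_model.whiten(v, va=va)
        # oracle: C x' sqrt(va) == T v
        recon = small_model.chol_ @ x * np.sqrt(va)
        assert recon == pytest.approx(small_model.T_ @ v, abs=1e-10)

    def test_whiten_env_matches_shared_transform(self, small_model, rng):
        v = rng.normal(size=8)
        small_model.va_scale_, keep = 4.0, small_model.va_scale_
        try:
            assert small_model.whiten_env(v) == pytest.approx(
                small_model.whiten(v) * 2.0, abs=1e-10)
        finally:
            small_model.va_scale_ = keep

    def test_constant_env_whitens_to_zero(self, small_model):
        assert small_model.whiten_env(np.full(8, 5.0)) == pytest.approx(
            np.zeros(7), abs=1e-10)

    def test_whitened_values_have_identity_covariance(self, rng):
        # values simulated from MVN(mu 1, 2 V_A F) whiten to iid standard normals
        M, R = 5, 6000
        A = rng.normal(size=(M, M))
        W = A @ A.T / M
        T = center_projection(M)
        model = DriftModel()
        model.population_ids_ = tuple(f"p{i}" for i in range(M))
        model._order_ = np.arange(M)
        model.T_, model.base_cov_ = T, W
        model.F_ = T @ W @ T.T
        model.chol_ = np.linalg.cholesky(model.F_)
        model.n_null_snps_, model.va_scale_ = 10**6, 3.0
        Lw = np.linalg.cholesky(3.0 * W + 1e-9 * np.eye(M))
        values = 1.7 + rng.standard_normal((R, M)) @ Lw.T
        x = model.whiten(values)
        cov = np.cov(x.T)
        assert np.allclose(cov, np.eye(M - 1), atol=0.12)

    def test_drop_choice_does_not_change_qx(self, small_dataset):
        # same null SNPs, different dropped population
        from polyadapt.matching import build_pool_index, sample_f_snps

        values = genetic_values(small_dataset.effects, small_dataset.gwas_panel)
        index = build_pool_index(small_dataset.pool_meta)
        rows = sample_f_snps(small_dataset.effects, index, 2000, 7)
        m_a = DriftModel(drop="last").fit(small_dataset.pool_panel.freq[rows])
        m_b = DriftModel(drop="pop2").fit(small_dataset.pool_panel.freq[rows])
        for m in (m_a, m_b):
            m.set_genetic_architecture(small_dataset.effects, small_dataset.gwas_panel)
        assert qx(values, m_a) == pytest.approx(qx(values, m_b), abs=1e-8)

    def test_save_load_roundtrip(self, small_model, tmp_path, rng):
        path = tmp_path / "model.tsv"
        small_model.save(path)
        back = DriftModel.load(path)
        v = rng.normal(size=8)
        assert back.whiten(v, va=1.3) == pytest.approx(
            small_model.whiten(v, va=1.3), abs=1e-12)
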