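"""Contingency-table matching and null-set resampling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from polyadapt.datamodel import EffectTable, FrequencyPanel, ValidationError
from polyadapt.matching import (
    BinKey,
    admixed_ascertainment_freq,
    bin_assign,
    bin_assign_arrays,
    build_pool_index,
    null_genetic_values,
    sample_null_index,
    sample_null_sets,
)
from polyadapt.null_model import genetic_values


def _effects(maf, imputed, b, alpha=None):
    n = len(maf)
    return EffectTable(
        snp_id=[f"g{i}" for i in range(n)],
        effect_allele=["A"] * n,
        alpha=alpha if alpha is not None else np.ones(n),
        ascertainment_maf=maf,
        imputed=imputed,
        b_value=b,
    )


def _pool_meta(maf, imputed, b):
    return pd.DataFrame(
        {"snp_id": [f"n{i}" for i in range(len(maf))], "maf": maf,
         "imputed": imputed, "b_value": b}
    )


class TestBinAssign:
    def test_printed_bin_widths(self):
        assert bin_assign(0.039, False, 0.95) == BinKey(1, 0, 9)

    def test_boundary_capping(self):
        assert bin_assign(0.5, True, 1.0) == BinKey(24, 1, 9)
        assert bin_assign(0.0, False, 0.0) == BinKey(0, 0, 0)

    @given(st.floats(0, 0.5), st.booleans(), st.floats(0, 1))
    @settings(deadline=None, derandomize=True, max_examples=100)
    def test_bins_always_in_range(self, maf, imp, b):
        key = bin_assign(maf, imp, b)
        assert 0 <= key.maf_bin <= 24 and 0 <= key.b_bin <= 9
        assert key.imputed_bin in (0, 1)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bin_assign(0.6, False, 0.5)
        with pytest.raises(ValidationError):
            bin_assign(0.2, False, 1.5)


class TestPoolIndex:
    def test_distinct_bins_give_singletons(self):
        idx = build_pool_index(_pool_meta([0.01, 0.21, 0.41], [0, 0, 0], [0.05, 0.5, 0.95]))
        assert len(idx) == 3
        assert all(len(v) == 1 for v in idx.values())

    def test_empty_pool_gives_empty_index(self):
        assert build_pool_index(_pool_meta([], [], [])) == {}

    def test_counts_sum_to_pool_size(self, rng):
        n = 10000
        meta = _pool_meta(rng.uniform(0, 0.5, n), rng.random(n) < 0.5,
                          rng.uniform(0, 1, n))
        idx = build_pool_index(meta)
        assert sum(len(v) for v in idx.values()) == n
        # agreement with the scalar assignment
        key = bin_assign(meta["maf"][17], meta["imputed"][17], meta["b_value"][17])
        assert 17 in idx[key]


class TestSampling:
    def test_singleton_bin_always_sampled(self):
        gwas = _effects([0.11], [False], [0.55])
        index = build_pool_index(_pool_meta([0.115], [False], [0.58]))
        sets = sample_null_sets(gwas, index, ["n0"], n_sets=20, seed=0)
        assert all(s.snp_ids == ("n0",) for s in sets)

    def test_same_seed_reproduces_sets(self, rng):
        n = 2000
        meta = _pool_meta(rng.uniform(0, 0.5, n), rng.random(n) < 0.5, rng.uniform(0, 1, n))
        gwas = _effects(rng.uniform(0, 0.5, 30), rng.random(30) < 0.5, rng.uniform(0, 1, 30))
        index = build_pool_index(meta)
        a = sample_null_index(gwas, index, 10, seed=42)
        b = sample_null_index(gwas, index, 10, seed=42)
        c = sample_null_index(gwas, index, 10, seed=43)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_matching_fidelity_of_bin_multisets(self, rng):
        n = 20000
        meta = _pool_meta(rng.uniform(0, 0.5, n), rng.random(n) < 0.5, rng.uniform(0, 1, n))
        gwas = _effects(rng.uniform(0, 0.5, 40), rng.random(40) < 0.5, rng.uniform(0, 1, 40))
        index = build_pool_index(meta)
        idx = sample_null_index(gwas, index, 50, seed=3)
        gwas_bins = sorted(map(tuple, bin_assign_arrays(
            gwas.ascertainment_maf, gwas.imputed, gwas.b_value)))
        for row in idx:
            null_bins = sorted(map(tuple, bin_assign_arrays(
                meta["maf"].values[row], meta["imputed"].values[row],
                meta["b_value"].values[row])))
            assert null_bins == gwas_bins

    def test_within_set_sampling_is_without_replacement(self):
        # two GWAS SNPs in one cell, pool of three in that cell
        gwas = _effects([0.101, 0.103], [False, False], [0.55, 0.56])
        index = build_pool_index(_pool_meta([0.105, 0.107, 0.109], [False] * 3,
                                            [0.55, 0.57, 0.59]))
        idx = sample_null_index(gwas, index, 200, seed=1)
        assert all(len(set(row)) == 2 for row in idx)

    def test_empty_bin_falls_back_to_neighboring_maf(self):
        gwas = _effects([0.10], [False], [0.55])       # maf bin 5
        index = build_pool_index(_pool_meta([0.13], [False], [0.55]))  # bin 6 only
        idx = sample_null_index(gwas, index, 5, seed=0)
        assert np.all(idx == 0)

    def test_unfillable_bin_errors_with_snp_names(self):
        gwas = _effects([0.10], [False], [0.55])
        index = build_pool_index(_pool_meta([0.40], [False], [0.55]))  # far away
        with pytest.raises(ValidationError, match="g0"):
            sample_null_index(gwas, index, 5, seed=0)


class TestNullGeneticValues:
    def test_identity_set_reproduces_observed_values(self, small_dataset):
        # pool rows chosen to be the GWAS loci themselves
        ds = small_dataset
        pool = FrequencyPanel(
            snp_ids=ds.gwas_panel.snp_ids,
            population_ids=ds.gwas_panel.population_ids,
            freq=ds.gwas_panel.freq,
            chromosomes=ds.gwas_panel.chromosomes,
        )
        idx = np.arange(len(ds.effects))[None, :]
        values, va = null_genetic_values(idx, pool, alpha=ds.effects.alpha)
        assert values[0] == pytest.approx(
            genetic_values(ds.effects, ds.gwas_panel), abs=1e-12)

    def test_zero_alpha_gives_zero_values(self, small_dataset):
        ds = small_dataset
        idx = np.arange(len(ds.effects))[None, :]
        values, va = null_genetic_values(idx, ds.pool_panel,
                                         alpha=np.zeros(len(ds.effects)))
        assert np.all(values == 0.0)

    def test_null_qx_mean_near_degrees_of_freedom(self, small_dataset, small_model):
        from polyadapt.matching import build_pool_index
        from polyadapt.stats_tests import qx_from_whitened

        ds = small_dataset
        idx = sample_null_index(ds.effects, small_model._pool_index, 800, seed=9)
        values, va = null_genetic_values(idx, ds.pool_panel, alpha=ds.effects.alpha)
        q = qx_from_whitened(small_model.whiten(values, va=va))
        # chi-square mean oracle: E[Q_X] = M - 1 = 7 (generous small-pool slack)
        assert q.mean() == pytest.approx(7.0, rel=0.25)


class TestAdmixedProxy:
    def test_pure_weight_folds_population_a(self, small_dataset):
        panel = small_dataset.pool_panel
        proxy = admixed_ascertainment_freq(panel, "pop0", "pop1", w=1.0)
        assert proxy == pytest.approx(np.minimum(panel.freq[:, 0], 1 - panel.freq[:, 0]))

    def test_weighted_mean_arithmetic(self):
        panel = FrequencyPanel(snp_ids=["s"], population_ids=["a", "b"],
                               freq=[[0.2, 0.6]], chromosomes=[10, 10])
        assert admixed_ascertainment_freq(panel, "a", "b", 0.5)[0] == pytest.approx(0.4)

    def test_half_weight_is_symmetric(self, small_dataset):
        panel = small_dataset.pool_panel
        ab = admixed_ascertainment_freq(panel, "pop0", "pop1", 0.5)
        ba = admixed_ascertainment_freq(panel, "pop1", "pop0", 0.5)
        assert ab == pytest.approx(ba)

    def test_missing_population_errors(self, small_dataset):
        with pytest.raises(ValidationError):
            admixed_ascertainment_freq(small_dataset.pool_panel, "pop0", "nope", 0.5)
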