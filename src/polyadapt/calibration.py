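"""End-to-end calibration experiments on synthetic neutral data.

These drive the whole pipeline -- fixture generation, matched resampling,
covariance estimation, whitening, test statistics, empirical p-values -- on
data simulated under the neutral drift model, to measure what the tests'
operating characteristics actually are:

* the null distribution of Q_X against its chi-square(M-1) approximation,
* type-I error of Q_X, the environmental tests and the single-locus
  enrichment comparator at the empirical 5% critical value,
* the null mean of the LD-like component,
* calibration of the conditional leave-one-out Z-scores.

The number of null sets per replicate defaults to 159 so the add-one
empirical p-value rule makes the 5% level exactly attainable: for the
upper-tail rule, p = (r+1)/160 <= 0.05 exactly when the observation ranks
in the top 8 of the 160 exchangeable draws (probability 8/160 = 0.05), and
the two-sided rule likewise rejects on the extreme 4 + 4 ranks.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .conditional import GroupPartition, recenter_F
from .fixtures import Dataset, FixtureSpec, make_dataset
from .matching import build_pool_index, null_genetic_values, sample_f_snps, sample_null_index
from .null_model import DriftModel, genetic_values
from .selection import per_locus_env_r2
from .stats_tests import empirical_pvalue, env_regression, qx_from_whitened

__all__ = [
    "fit_model_from_dataset",
    "qx_null_draws",
    "ld_like_null_draws",
    "type_one_error_experiment",
    "conditional_loo_zscores",
]


def fit_model_from_dataset(ds: Dataset, n_cov_snps: int, seed) -> DriftModel:
    """Fit the drift null from matched pool SNPs and set the GWAS V_A scale."""
    index = build_pool_index(ds.pool_meta)
    f_rows = sample_f_snps(ds.effects, index, n_cov_snps, seed)
    model = DriftModel().fit(ds.pool_panel.freq[f_rows])
    model.set_genetic_architecture(ds.effects, ds.gwas_panel)
    model._pool_index = index  # cached for reuse by the experiments below
    return model


def _null_qx(ds: Dataset, model: DriftModel, n_sets: int, rng):
    idx = sample_null_index(ds.effects, model._pool_index, n_sets, rng)
    values, va = null_genetic_values(idx, ds.pool_panel, alpha=ds.effects.alpha)
    x = model.whiten(values, va=va)
    return idx, values, va, x


def qx_null_draws(ds: Dataset, n_sets: int = 10000, n_cov_snps: int = 20000,
                  seed: int = 0) -> np.ndarray:
    """Q_X over matched null sets: one draw of the genome-wide null each."""
    rng = np.random.default_rng(seed)
    model = fit_model_from_dataset(ds, n_cov_snps, rng)
    _, _, _, x = _null_qx(ds, model, n_sets, rng)
    return qx_from_whitened(x)


def ld_like_null_draws(ds: Dataset, n_sets: int = 1000, n_cov_snps: int = 20000,
                       seed: int = 0):
    """(fst_like, ld_like, qx) per matched null set, for the decomposition null."""
    rng = np.random.default_rng(seed)
    model = fit_model_from_dataset(ds, n_cov_snps, rng)
    idx, values, va, x = _null_qx(ds, model, n_sets, rng)
    qx_vals = qx_from_whitened(x)
    fst = np.empty(n_sets)
    ld = np.empty(n_sets)
    a2 = (2.0 * ds.effects.alpha)
    L = len(ds.effects)
    for s in range(n_sets):
        Xl = model.whiten_frequencies(ds.pool_panel.freq[idx[s]])
        G = a2[:, None] * Xl
        per_locus_sq = float(np.sum(G**2))
        fst[s] = per_locus_sq / va[s]
        ld[s] = (float(np.sum(G.sum(axis=0) ** 2)) - per_locus_sq) / va[s]
    return fst, ld, qx_vals


@dataclass
class TypeOneErrorResult:
    """Rejection fractions at the empirical 5% level over neutral replicates."""

    qx: float
    beta: float
    r2: float
    rho: float
    enrichment: float
    enrichment_binomial: float
    n_replicates: int
    pvalues: dict


def type_one_error_experiment(n_replicates: int = 1000, spec: FixtureSpec | None = None,
                              n_null_sets: int = 159, n_cov_snps: int = 2000,
                              seed: int = 0, level: float = 0.05) -> TypeOneErrorResult:
    """Full-pipeline type-I error on fresh neutral studies.

    Each replicate generates a complete synthetic study (GWAS loci, null
    pool, environment), fits F from matched SNPs, builds the matched
    empirical null, and tests at the nominal ``level``:

    * Q_X, upper tail;
    * the environmental slope and Spearman rho, two-sided;
    * the squared environmental correlation, upper tail (equivalent to a
      two-sided test of the signed correlation);
    * the enrichment comparator's outlier count, upper tail, against the
      null sets' own counts (``enrichment``), and the same count put
      through the exact binomial tail test against Binomial(L, level)
      (``enrichment_binomial``; slightly conservative by discreteness).
    """
    from scipy import stats as sps

    if spec is None:
        spec = FixtureSpec(K_pool=4000)
    root = np.random.default_rng(seed)
    names = ("qx", "beta", "r2", "rho", "enrichment", "enrichment_binomial")
    pvals = {k: np.empty(n_replicates) for k in names}
    for r in range(n_replicates):
        rep_seed = int(root.integers(2**31))
        ds = make_dataset(replace(spec, seed=rep_seed))
        rng = np.random.default_rng(rep_seed + 1)
        model = fit_model_from_dataset(ds, n_cov_snps, rng)
        y_t = model.whiten_env(ds.env)

        obs_x = model.whiten(genetic_values(ds.effects, ds.gwas_panel))
        obs_qx = qx_from_whitened(obs_x)
        obs_beta, obs_r2, obs_rho = env_regression(obs_x, y_t)

        idx, values, va, x = _null_qx(ds, model, n_null_sets, rng)
        null_qx = qx_from_whitened(x)
        null_beta, null_r2c, null_rho = env_regression(x, y_t)

        # per-locus empirical null from the null sets' own loci
        flat = idx.ravel()
        r2_null_loci = per_locus_env_r2(ds.pool_panel.freq[flat], model, y_t)
        crit = np.quantile(r2_null_loci, 1.0 - level)
        obs_count = int(np.sum(
            per_locus_env_r2(ds.gwas_panel.freq, model, y_t) > crit))
        null_counts = (r2_null_loci.reshape(idx.shape) > crit).sum(axis=1)

        pvals["qx"][r] = empirical_pvalue(obs_qx, null_qx, "upper")
        pvals["beta"][r] = empirical_pvalue(obs_beta, null_beta, "two-sided")
        pvals["r2"][r] = empirical_pvalue(obs_r2, null_r2c, "upper")
        pvals["rho"][r] = empirical_pvalue(obs_rho, null_rho, "two-sided")
        pvals["enrichment"][r] = empirical_pvalue(obs_count, null_counts, "upper")
        pvals["enrichment_binomial"][r] = float(
            sps.binom.sf(obs_count - 1, len(ds.effects), level))
    rates = {k: float(np.mean(v <= level)) for k, v in pvals.items()}
    return TypeOneErrorResult(
        qx=rates["qx"], beta=rates["beta"], r2=rates["r2"], rho=rates["rho"],
        enrichment=rates["enrichment"],
        enrichment_binomial=rates["enrichment_binomial"],
        n_replicates=n_replicates, pvalues=pvals,
    )


def conditional_loo_zscores(n_replicates: int = 10000, spec: FixtureSpec | None = None,
                            n_cov_snps: int = 20000, seed: int = 0) -> np.ndarray:
    """Leave-one-out conditional Z-scores on fresh neutral genetic values.

    One base study supplies the matched covariance estimate; each replicate
    then draws a fresh set of L neutral loci from the same generative model
    (with the study's effect sizes) and scores population ``r mod M``
    against all others.  Under the null the scores are standard normal.
    """
    if spec is None:
        spec = FixtureSpec()
    ds = make_dataset(spec)
    rng = np.random.default_rng(seed)
    model = fit_model_from_dataset(ds, n_cov_snps, rng)
    pops = model.population_ids_
    M = len(pops)
    alpha = ds.effects.alpha
    L = alpha.size

    # linear functionals: z = (c_m . Z) / sqrt(va * schur_m)
    C = np.empty((M, M))
    schur = np.empty(M)
    for j, p in enumerate(pops):
        part = GroupPartition(group1=(p,), group2=tuple(q for q in pops if q != p))
        F2 = recenter_F(model, part)
        i1 = np.array([j])
        i2 = np.array([k for k in range(M) if k != j])
        S12 = F2[np.ix_(i1, i2)]
        S22 = F2[np.ix_(i2, i2)]
        S22_pinv = np.linalg.pinv(S22, rcond=1e-10, hermitian=True)
        A = (S12 @ S22_pinv).ravel()          # weights on (v2 - mean(v2))
        # z numerator = Z_j - mu_cond = Z_j - mean(Z_2) - A.(Z_2 - mean(Z_2))
        c = np.zeros(M)
        c[j] = 1.0
        c[i2] -= 1.0 / (M - 1)
        c[i2] -= A
        c[i2] += A.sum() / (M - 1)
        C[j] = c
        schur[j] = float((F2[j, j] - S12 @ S22_pinv @ S12.T).item())

    # model order may differ from simulation order only if drop != last
    F_chol = np.linalg.cholesky(ds.F_true + 1e-12 * np.eye(M))
    z_scores = np.empty(n_replicates)
    chunk = 500
    for s0 in range(0, n_replicates, chunk):
        b = min(chunk, n_replicates - s0)
        eps = rng.uniform(spec.ancestral_low, spec.ancestral_high, size=(b, L))
        g = rng.standard_normal((b, L, M))
        p = eps[..., None] + np.sqrt(eps * (1.0 - eps))[..., None] * (g @ F_chol.T)
        p = np.clip(p, 0.0, 1.0)
        freq = rng.binomial(spec.chromosomes, p) / float(spec.chromosomes)
        Z = 2.0 * np.einsum("l,blm->bm", alpha, freq)
        emean = freq.mean(axis=2)
        va = 4.0 * np.sum(alpha**2 * emean * (1.0 - emean), axis=1)
        m_idx = (np.arange(s0, s0 + b)) % M
        num = np.einsum("bm,bm->b", Z, C[m_idx])
        z_scores[s0:s0 + b] = num / np.sqrt(va * schur[m_idx])
    return z_scores
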