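"""Selection-perturbation power simulations.

Rather than forward-simulating selection, neutral frequency sets (matched
resamples of real or synthetic data, so drift and shared history are already
baked in) are perturbed to mimic directional selection along an
environmental gradient:

    p'_lm = clip(p_lm + s * alpha_l * Y_m * p_lm * (1 - p_lm), 0, 1)

so loci shift more when they experience extreme environments, have large
effects, or segregate at intermediate frequencies.  Variations: a pleiotropy
mode where the effect that selection sees (gamma) is only partially
correlated with the measured effect (alpha); locus downsampling with or
without rescaling effect sizes to hold the variance explained constant; and
population- or region-restricted shifts driven by a raw indicator
environment.  Power for each statistic is the fraction of perturbed
replicates beyond the 5% critical value established from the s = 0
replicates of the same experiment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .datamodel import EffectTable, EnvVector, FrequencyPanel, ValidationError
from .matching import build_pool_index, sample_f_snps, sample_null_index
from .null_model import DriftModel
from .stats_tests import env_regression

logger = logging.getLogger(__name__)

__all__ = [
    "SelectionScenario",
    "apply_shift",
    "pleiotropic_effects",
    "downsample_loci",
    "targeted_shift",
    "per_locus_env_r2",
    "enrichment_test",
    "replicate_statistics",
    "power_experiment",
    "UPPER_TAIL_STATS",
    "TWO_SIDED_STATS",
]

UPPER_TAIL_STATS = ("qx", "fst_like", "ld_like", "naive_qx", "enrichment_count")
TWO_SIDED_STATS = ("beta", "rho", "naive_rho")


@dataclass(frozen=True)
class SelectionScenario:
    """One grid point of the power experiments."""

    gradient_s: float = 0.0
    pleiotropy_rho: float = 1.0
    target: object = "all"          # "all", a population id, or a list of ids
    n_loci_subsample: int | None = None
    rescale_va: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.gradient_s < 0:
            raise ValidationError("gradient_s must be >= 0")
        if not (0.0 <= self.pleiotropy_rho <= 1.0):
            raise ValidationError("pleiotropy_rho must lie in [0, 1]")


def apply_shift(freqs: np.ndarray, alpha: np.ndarray, y: np.ndarray,
                s: float) -> np.ndarray:
    """Perturb an (L, M) frequency matrix along environment ``y``.

    ``y`` is used exactly as given (the gradient experiments pass a
    mean-centered environment; the targeted experiments pass a raw 0/1
    indicator).  Values pushed outside [0, 1] are clipped with a logged
    count.
    """
    freqs = np.asarray(freqs, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    y = np.asarray(y, dtype=float)
    shifted = freqs + s * alpha[:, None] * y[None, :] * freqs * (1.0 - freqs)
    n_clip = int(np.sum((shifted < 0.0) | (shifted > 1.0)))
    if n_clip:
        logger.debug("clipped %d perturbed frequencies to [0, 1]", n_clip)
    return np.clip(shifted, 0.0, 1.0)


def pleiotropic_effects(alpha: np.ndarray, rho: float, seed) -> np.ndarray:
    """Effects that selection acts on, correlated ``rho`` with the measured ones.

    (alpha, gamma) are modeled as mean-zero bivariate normal with equal
    variance and correlation rho; gamma is drawn from its conditional law
    given alpha: ``N(rho * alpha, (1 - rho^2) * v)``.  The shared variance
    ``v`` is the second moment of alpha about zero (its rms squared): the
    observed effects are oriented trait-increasing, so their mean-zero
    marginal variance is the mean square, and using it keeps the magnitude
    of the selected effects -- hence the per-locus shift scale -- constant
    across rho.  rho = 1 returns alpha exactly.
    """
    alpha = np.asarray(alpha, dtype=float)
    if not (0.0 <= rho <= 1.0):
        raise ValidationError("rho must lie in [0, 1]")
    if rho == 1.0:
        return alpha.copy()
    rng = np.random.default_rng(seed)
    rms = float(np.sqrt(np.mean(alpha**2)))
    return rho * alpha + np.sqrt(1.0 - rho**2) * rms * rng.standard_normal(alpha.size)


def downsample_loci(effects: EffectTable, n: int, rescale_va: bool = False,
                    va_target: float | None = None,
                    panel: FrequencyPanel | None = None, seed=None):
    """Uniform subsample of ``n`` loci, optionally rescaling to a V_A target.

    Returns ``(effects_subset, row_indices)``; with ``rescale_va`` the
    effect sizes are multiplied by the scalar that makes the subsample's
    additive variance (computed from ``panel``'s mean frequencies at the
    subsampled rows) equal ``va_target``, mimicking a study that explains
    the same variance with fewer mapped loci.
    """
    L = len(effects)
    if not (2 <= n <= L):
        raise ValidationError(f"subsample size {n} outside [2, {L}]")
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(L, size=n, replace=False))
    sub = effects.subset(idx)
    if rescale_va:
        if va_target is None or panel is None:
            raise ValidationError("rescaling requires va_target and a panel")
        eps = panel.freq[idx].mean(axis=1)
        va_sub = 2.0 * float(np.sum(sub.alpha**2 * eps * (1.0 - eps)))
        if va_sub <= 0:
            raise ValidationError("subsample has zero additive variance")
        sub = sub.with_alpha(sub.alpha * np.sqrt(va_target / va_sub))
    return sub, idx


def targeted_shift(freqs, alpha, s: float, target, membership: dict | None = None,
                   population_ids=None) -> np.ndarray:
    """Shift only the targeted population(s): indicator environment, used raw.

    ``target`` is a population id, a region label resolved through
    ``membership`` (population id -> region label), or an explicit list of
    population ids.  The indicator is deliberately not mean-centered.
    """
    pops = list(population_ids)
    if isinstance(target, (list, tuple, set)):
        chosen = set(target)
    elif membership is not None and target in set(membership.values()):
        chosen = {p for p, r in membership.items() if r == target}
    else:
        chosen = {target}
    unknown = chosen - set(pops)
    if unknown:
        raise ValidationError(f"unknown target populations: {sorted(unknown)[:5]}")
    indicator = np.array([1.0 if p in chosen else 0.0 for p in pops])
    return apply_shift(freqs, alpha, indicator, s)


def per_locus_env_r2(freqs, model: DriftModel, y_t: np.ndarray) -> np.ndarray:
    """Squared Pearson correlation of each locus's transformed frequencies with y."""
    Xl = model.whiten_frequencies(freqs)
    Xc = Xl - Xl.mean(axis=1, keepdims=True)
    yc = y_t - y_t.mean()
    denom = np.sqrt(np.sum(Xc**2, axis=1) * np.sum(yc**2))
    with np.errstate(invalid="ignore"):
        r = np.where(denom > 0, Xc @ yc / denom, 0.0)
    return r**2


def enrichment_test(freqs, model: DriftModel, y_t: np.ndarray,
                    null_r2: np.ndarray, level: float = 0.05):
    """Single-locus outlier enrichment comparator.

    Counts GWAS loci whose per-locus transformed-frequency correlation with
    the environment lies in the upper ``level`` tail of the per-locus
    empirical null (``null_r2``: pooled per-locus r^2 from matched null
    SNPs), then tests that count against Binomial(L, level) with an exact
    upper tail.  This comparator ignores effect sizes entirely, which is
    why its power is insensitive to pleiotropy but dilutes as the same
    variance spreads over more loci.

    Returns ``(count, p_binomial)``.
    """
    crit = np.quantile(np.asarray(null_r2, float), 1.0 - level)
    r2 = per_locus_env_r2(freqs, model, y_t)
    count = int(np.sum(r2 > crit))
    p = float(sps.binom.sf(count - 1, r2.size, level))
    return count, p


def replicate_statistics(alpha, freqs, model: DriftModel, y_t, env_raw,
                         locus_r2_crit: float) -> dict:
    """All competing statistics for one (possibly perturbed) replicate set.

    Structure-aware statistics use the whitening transform; the naive
    counterparts use raw mean-centered genetic values and the untransformed
    environment, exactly the comparison the power figures make.
    """
    alpha = np.asarray(alpha, dtype=float)
    freqs = np.asarray(freqs, dtype=float)
    eps = freqs.mean(axis=1)
    va = 4.0 * float(np.sum(alpha**2 * eps * (1.0 - eps)))
    Xl = model.whiten_frequencies(freqs)            # (L, M-1)
    G = (2.0 * alpha)[:, None] * Xl
    x = G.sum(axis=0) / np.sqrt(va)
    qx_val = float(np.sum(x**2))
    per_locus_sq = float(np.sum(G**2))
    fst_like = per_locus_sq / va
    ld_like = (float(np.sum(G.sum(axis=0) ** 2)) - per_locus_sq) / va
    beta, r2, rho = env_regression(x, y_t)
    # naive counterparts: no structure correction
    Z = 2.0 * alpha @ freqs
    Zc = Z - Z.mean()
    naive_qx = float(np.sum(Zc**2)) / va
    naive_rho = float(sps.spearmanr(Z, env_raw).statistic)
    # single-locus enrichment count against the per-locus empirical tail
    Xc = Xl - Xl.mean(axis=1, keepdims=True)
    yc = y_t - y_t.mean()
    denom = np.sqrt(np.sum(Xc**2, axis=1) * np.sum(yc**2))
    with np.errstate(invalid="ignore"):
        rl = np.where(denom > 0, Xc @ yc / denom, 0.0)
    count = int(np.sum(rl**2 > locus_r2_crit))
    return {
        "qx": qx_val,
        "fst_like": fst_like,
        "ld_like": ld_like,
        "beta": float(beta),
        "r2": float(r2),
        "rho": float(rho),
        "naive_qx": naive_qx,
        "naive_rho": naive_rho,
        "enrichment_count": count,
    }


def _critical_values(null_stats: dict, level: float = 0.05) -> dict:
    crit = {}
    for name in UPPER_TAIL_STATS:
        crit[name] = ("upper", float(np.quantile(null_stats[name], 1.0 - level)))
    for name in TWO_SIDED_STATS:
        lo = float(np.quantile(null_stats[name], level / 2.0))
        hi = float(np.quantile(null_stats[name], 1.0 - level / 2.0))
        crit[name] = ("two-sided", (lo, hi))
    return crit


def _rejects(stat_rows: dict, crit: dict) -> dict:
    out = {}
    for name, (tail, c) in crit.items():
        vals = np.asarray(stat_rows[name])
        if tail == "upper":
            out[name] = float(np.mean(vals > c))
        else:
            lo, hi = c
            out[name] = float(np.mean((vals < lo) | (vals > hi)))
    return out


def power_experiment(effects: EffectTable, pool_panel: FrequencyPanel,
                     pool_meta, env: EnvVector, scenarios,
                     n_replicates: int = 200, seed: int = 0,
                     model: DriftModel | None = None,
                     n_cov_snps: int = 10000, level: float = 0.05,
                     membership: dict | None = None) -> pd.DataFrame:
    """Run the full power-simulation grid and return a tidy power table.

    Replicate sets are matched resamples of the null pool (one per
    replicate, shared across scenarios), perturbed per scenario.  Scenarios
    sharing a locus-downsampling treatment share the critical values
    established from that treatment's own s = 0 replicates.  Columns:
    scenario fields, statistic, power.
    """
    if n_replicates < 100:
        logger.warning("power estimates with %d replicates are noisy", n_replicates)
    rng = np.random.default_rng(seed)
    index = build_pool_index(pool_meta)
    if model is None:
        f_rows = sample_f_snps(effects, index, n_cov_snps, rng)
        model = DriftModel().fit(pool_panel.freq[f_rows])
    # raw-space perturbations live in the panel's population order;
    # whiten_env re-aligns to the model's order internally
    env = env.aligned_to(pool_panel.population_ids)
    y_t = model.whiten_env(env)
    y_centered = env.value - env.value.mean()
    # per-locus empirical null tail from matched pool SNPs
    null_rows = sample_f_snps(effects, index, min(10000, pool_panel.n_loci * 2), rng)
    null_r2 = per_locus_env_r2(pool_panel.freq[null_rows], model, y_t)
    locus_crit = float(np.quantile(null_r2, 1.0 - level))

    base_idx = sample_null_index(effects, index, n_replicates, rng)
    families: dict = {}
    for sc in scenarios:
        families.setdefault((sc.n_loci_subsample, sc.rescale_va), []).append(sc)

    rows = []
    for (n_sub, rescale), fam in families.items():
        fam_rng = np.random.default_rng(rng.integers(2**31))
        # per-replicate locus treatment, shared within the family
        rep_alpha, rep_rows = [], []
        for r in range(n_replicates):
            freq_r = pool_panel.freq[base_idx[r]]
            if n_sub is None or n_sub == len(effects):
                rep_alpha.append(effects.alpha)
                rep_rows.append(freq_r)
            else:
                va_full = None
                if rescale:
                    eps = freq_r.mean(axis=1)
                    va_full = 2.0 * float(np.sum(effects.alpha**2 * eps * (1.0 - eps)))
                panel_r = FrequencyPanel(
                    snp_ids=[f"r{r}_{i}" for i in range(len(effects))],
                    population_ids=pool_panel.population_ids,
                    freq=freq_r, chromosomes=pool_panel.chromosomes,
                )
                sub, idx = downsample_loci(
                    effects, n_sub, rescale_va=rescale, va_target=va_full,
                    panel=panel_r, seed=fam_rng.integers(2**31),
                )
                rep_alpha.append(sub.alpha)
                rep_rows.append(freq_r[idx])
        null_stats = {k: [] for k in UPPER_TAIL_STATS + TWO_SIDED_STATS + ("r2",)}
        for r in range(n_replicates):
            st = replicate_statistics(rep_alpha[r], rep_rows[r], model, y_t,
                                      y_centered, locus_crit)
            for k, v in st.items():
                null_stats[k].append(v)
        crit = _critical_values(null_stats, level)
        for sc in fam:
            if sc.gradient_s == 0 and sc.pleiotropy_rho == 1.0:
                power = _rejects(null_stats, crit)
            else:
                sc_rng = np.random.default_rng(sc.seed)
                stat_rows = {k: [] for k in null_stats}
                for r in range(n_replicates):
                    a = rep_alpha[r]
                    gamma = pleiotropic_effects(a, sc.pleiotropy_rho,
                                                sc_rng.integers(2**31))
                    if sc.target == "all":
                        shifted = apply_shift(rep_rows[r], gamma, y_centered,
                                              sc.gradient_s)
                    else:
                        shifted = targeted_shift(
                            rep_rows[r], gamma, sc.gradient_s, sc.target,
                            membership=membership,
                            population_ids=pool_panel.population_ids,
                        )
                    st = replicate_statistics(a, shifted, model, y_t,
                                              y_centered, locus_crit)
                    for k, v in st.items():
                        stat_rows[k].append(v)
                power = _rejects(stat_rows, crit)
            for name, frac in power.items():
                rows.append(
                    {
                        "gradient_s": sc.gradient_s,
                        "pleiotropy_rho": sc.pleiotropy_rho,
                        "target": str(sc.target),
                        "n_loci": n_sub if n_sub is not None else len(effects),
                        "rescale_va": rescale,
                        "statistic": name,
                        "power": frac,
                    }
                )
    return pd.DataFrame(rows)
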