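"""Test statistics on whitened genetic values and their empirical p-values.

Q_X is the squared length of the whitened genetic-value vector: a
standardized measure of among-population variance in genetic values beyond
what drift and shared history explain, approximately chi-square with M-1
degrees of freedom under neutrality.  It decomposes exactly into a per-locus
variance ("F_ST-like") term and a cross-locus covariance ("LD-like") term;
under neutrality the latter has mean zero, while coordinated selection makes
like-effect alleles covary across populations and pushes it up -- which is
where most of the statistic's power comes from.

The environmental tests regress whitened genetic values on the identically
whitened environmental vector (no intercept: both are mean-free by
construction).  Significance for everything comes from an empirical null
built by recomputing each statistic on matched null SNP sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .datamodel import EffectTable, FrequencyPanel, ValidationError
from .null_model import DriftModel, genetic_values

__all__ = [
    "TestReport",
    "qx",
    "qx_from_whitened",
    "qx_decomposition",
    "env_regression",
    "per_locus_regression",
    "empirical_pvalue",
    "make_report",
]


@dataclass
class TestReport:
    statistic_name: str
    observed: float
    null_draws: np.ndarray
    p_empirical: float
    tail: str
    seed: int


def qx_from_whitened(x: np.ndarray) -> np.ndarray:
    """Sum of squared whitened coordinates; last axis is the M-1 coordinates."""
    return np.sum(np.asarray(x) ** 2, axis=-1)


def qx(values, model: DriftModel, va: float | None = None) -> float:
    """Q_X for a length-M genetic-value vector (or per-row for a batch)."""
    return qx_from_whitened(model.whiten(values, va=va))


def qx_decomposition(effects: EffectTable, panel: FrequencyPanel, model: DriftModel,
                     va: float | None = None):
    """Split Q_X into its F_ST-like and LD-like components.

    With per-locus transformed frequencies ``x'_l`` and weights ``2*alpha_l``,
    the whitened genetic value at transformed population m is
    ``sum_l 2*alpha_l x'_lm / sqrt(2 V_A)``, so

        fst_like = sum_m sum_l     (2 a_l)^2 x'_lm^2            / (2 V_A)
        ld_like  = sum_m sum_{l!=l'} (2 a_l)(2 a_l') x'_lm x'_l'm / (2 V_A)

    and ``fst_like + ld_like == Q_X`` exactly.  The cross term is computed
    as the difference of the squared column sum and the sum of squares, which
    is the algebraic cross-locus covariance, not a rearrangement of Q_X.
    """
    scale = va if va is not None else model.va_scale_
    if scale is None:
        raise ValidationError("no additive-variance scale on the model")
    G = (2.0 * effects.alpha)[:, None] * model.whiten_frequencies(panel.freq)  # (L, M-1)
    per_locus_sq = np.sum(G**2)
    col_sums = G.sum(axis=0)
    fst_like = per_locus_sq / scale
    ld_like = (np.sum(col_sums**2) - per_locus_sq) / scale
    return float(fst_like), float(ld_like)


def env_regression(x: np.ndarray, y: np.ndarray):
    """No-intercept slope, squared Pearson correlation, and Spearman rho.

    ``x`` are whitened genetic values (or an (R, M-1) batch), ``y`` the
    whitened environmental vector.  The linear model has no intercept
    because both vectors are mean-free by construction; the slope is
    ``sum(x*y) / sum(y*y)``.  Spearman uses average ranks for ties.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape[-1] != y.shape[0] or y.shape[0] < 3:
        raise ValidationError("need aligned vectors of length M-1 >= 3")
    yy = float(y @ y)
    if yy == 0.0:
        raise ValidationError("environmental vector has zero variance after whitening")
    beta = x @ y / yy
    xc = x - x.mean(axis=-1, keepdims=True)
    yc = y - y.mean()
    denom = np.sqrt(np.sum(xc**2, axis=-1) * np.sum(yc**2))
    with np.errstate(invalid="ignore"):
        r = np.where(denom > 0, xc @ yc / denom, 0.0)
    ry = sps.rankdata(y)
    rx = sps.rankdata(x, axis=-1)
    rxc = rx - rx.mean(axis=-1, keepdims=True)
    ryc = ry - ry.mean()
    rden = np.sqrt(np.sum(rxc**2, axis=-1) * np.sum(ryc**2))
    with np.errstate(invalid="ignore"):
        rho = np.where(rden > 0, rxc @ ryc / rden, 0.0)
    return beta, r**2, rho


def per_locus_regression(effects: EffectTable, panel: FrequencyPanel,
                         model: DriftModel, y: np.ndarray):
    """Per-locus environmental slopes and their combined estimate.

    Each locus's transformed frequencies get a no-intercept slope
    ``beta_l = x'_l . y / y . y`` on the transformed environment.  Assuming
    the per-locus coefficients are proportional to the effect sizes
    (``beta_l = alpha_l * B``), the stacked maximum-likelihood estimate is

        B = sum_l alpha_l beta_l / sum_l alpha_l^2

    which relates to the genetic-value regression by an exact identity:
    the slope of the *unscaled* whitened genetic values on y equals
    ``2 * sum_l alpha_l^2 * B``, i.e. the combined per-locus coefficient is
    the genetic-value slope times one over two times the sum of squared
    effect sizes.
    """
    Xl = model.whiten_frequencies(panel.freq)  # (L, M-1)
    y = np.asarray(y, dtype=float)
    yy = float(y @ y)
    if yy == 0.0:
        raise ValidationError("environmental vector has zero variance after whitening")
    beta_l = Xl @ y / yy
    a = effects.alpha
    denom = float(a @ a)
    if denom == 0.0:
        raise ValidationError("all effect sizes are zero")
    beta_bar = float(a @ beta_l) / denom
    return beta_bar, beta_l


def empirical_pvalue(observed: float, null_draws, tail: str = "upper") -> float:
    """Add-one empirical p-value: ``(r + 1) / (K + 1)``.

    ``r`` counts null draws as or more extreme than the observation under
    the stated tail; the add-one rule keeps p strictly positive.  Two-sided
    doubles the smaller tail and caps at 1.
    """
    null_draws = np.asarray(null_draws, dtype=float)
    K = null_draws.size
    if K == 0:
        raise ValidationError("need at least one null draw")
    upper = (np.sum(null_draws >= observed) + 1.0) / (K + 1.0)
    if tail == "upper":
        return float(upper)
    if tail == "two-sided":
        lower = (np.sum(null_draws <= observed) + 1.0) / (K + 1.0)
        return float(min(1.0, 2.0 * min(upper, lower)))
    raise ValidationError(f"unknown tail rule {tail!r}")


def make_report(name: str, observed: float, null_draws, tail: str, seed: int) -> TestReport:
    return TestReport(
        statistic_name=name,
        observed=float(observed),
        null_draws=np.asarray(null_draws, dtype=float),
        p_empirical=empirical_pvalue(observed, null_draws, tail),
        tail=tail,
        seed=seed,
    )
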