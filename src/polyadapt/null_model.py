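"""The multivariate-normal drift null and its whitening transform.

Under neutral drift, the vector of allele frequencies at a locus across M
populations is modeled as multivariate normal around its ancestral frequency
``eps``, with covariance ``eps * (1 - eps) * F``; ``F`` is an among-population
covariance matrix shared by all loci that absorbs shared history, gene flow
and (because it is estimated from sample frequencies) finite-sample noise.
A genetic value -- twice the effect-size-weighted sum of frequencies -- is a
linear combination of many such loci, so its across-population distribution
is multivariate normal with covariance ``2 * V_A * F``, where ``V_A`` is the
additive variance the loci contribute at the grand-mean frequencies.

Because the ancestral mean is unobserved, all vectors are mean-centered and
one population is dropped, leaving M-1 coordinates.  Multiplying by the
inverse Cholesky factor of the estimated F then yields coordinates that are
independent standard normals under the null; every downstream test statistic
is built on these whitened values.

:class:`DriftModel` packages this as a scikit-learn style estimator: ``fit``
on a panel of (matched) null SNPs estimates F, ``transform`` whitens
genetic-value vectors.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.linalg import cholesky, solve_triangular, LinAlgError
from sklearn.base import BaseEstimator, TransformerMixin

from .datamodel import EffectTable, EnvVector, FrequencyPanel, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "center_projection",
    "genetic_values",
    "standardized_deviations",
    "va_scale",
    "DriftModel",
]


def genetic_values(effects: EffectTable, panel: FrequencyPanel) -> np.ndarray:
    """Mean genetic value per population: ``Z_m = 2 * sum_l alpha_l * p_lm``.

    The factor 2 reflects diploidy (two copies per individual).
    """
    if len(effects) == 0 or panel.n_loci == 0:
        raise ValidationError("genetic values require at least one locus")
    if len(effects) != panel.n_loci:
        raise ValidationError("effects and panel must share the same loci, in order")
    return 2.0 * effects.alpha @ panel.freq


def center_projection(M: int) -> np.ndarray:
    """(M-1) x M matrix that subtracts the mean and drops the last coordinate.

    Entries are ``1 - 1/M`` on the diagonal and ``-1/M`` off it, restricted
    to the first M-1 rows; rows sum to zero, so constants map to zero.
    Which population is dropped is arbitrary: any M-1 rows of the full
    centering matrix span the same (M-1)-dimensional centered subspace, and
    every statistic below is invariant to the choice.
    """
    if M < 2:
        raise ValidationError("need at least 2 populations to center")
    T = np.full((M - 1, M), -1.0 / M)
    T[np.arange(M - 1), np.arange(M - 1)] += 1.0
    return T


def standardized_deviations(freq: np.ndarray):
    """Per-SNP standardized deviations from the across-population mean.

    For SNP k with unweighted mean frequency ``eps_k`` across populations,
    returns ``(p_km - eps_k) / sqrt(eps_k * (1 - eps_k))`` for the SNPs with
    ``eps_k`` strictly inside (0, 1), together with the keep mask.
    """
    freq = np.asarray(freq, dtype=float)
    eps = freq.mean(axis=1)
    keep = (eps > 0.0) & (eps < 1.0)
    e = eps[keep]
    s = (freq[keep] - e[:, None]) / np.sqrt(e * (1.0 - e))[:, None]
    return s, keep


def va_scale(effects: EffectTable, panel: FrequencyPanel) -> float:
    """Return ``2 * V_A``, the multiplier of F in the genetic-value covariance.

    ``V_A = 2 * sum_l alpha_l^2 * eps_l * (1 - eps_l)`` with ``eps_l`` the
    locus's unweighted mean frequency across the M populations.  Loci fixed
    across all populations contribute nothing and are flagged.
    """
    if len(effects) != panel.n_loci:
        raise ValidationError("effects and panel must share the same loci, in order")
    eps = panel.freq.mean(axis=1)
    het = eps * (1.0 - eps)
    n_fixed = int(np.sum(het == 0.0))
    if n_fixed:
        logger.warning("%d loci fixed across all populations contribute no variance", n_fixed)
    va = 2.0 * float(np.sum(effects.alpha**2 * het))
    scale = 2.0 * va
    if scale <= 0.0:
        raise ValidationError(
            "additive-variance scale is zero (all effects zero or all loci fixed); "
            "the whitening transform is undefined"
        )
    return scale


class DriftModel(BaseEstimator, TransformerMixin):
    """Fitted multivariate-normal drift null.

    Parameters
    ----------
    drop : str, default "last"
        Which population to drop when reducing to M-1 coordinates.  Either
        ``"last"`` or a population id.  The choice does not affect any
        statistic (it only changes the basis of the centered subspace).
    ridge : float, default 0.0
        Diagonal ridge, as a fraction of ``trace(F)/(M-1)``, added only
        after a hard Cholesky failure.  Logged when used; a silent
        regularization would distort p-values.

    Attributes
    ----------
    population_ids_ : tuple of str
        Population order of the fitted panel.
    T_ : ndarray of shape (M-1, M)
        Centering/dropping projection.
    F_ : ndarray of shape (M-1, M-1)
        Estimated among-population covariance of standardized frequency
        deviations (divisor K-1).
    chol_ : ndarray of shape (M-1, M-1)
        Lower-triangular Cholesky factor of ``F_``.
    base_cov_ : ndarray of shape (M, M)
        Raw M x M covariance of the standardized deviations (before
        projection); reused by the conditional-MVN machinery, which needs
        re-centerings other than the global mean.
    n_null_snps_ : int
        Number of usable null SNPs behind the estimate.
    va_scale_ : float or None
        ``2 * V_A`` for the loci under test; set by
        :meth:`set_genetic_architecture` or passed per-call.
    """

    def __init__(self, drop: str = "last", ridge: float = 1e-10):
        self.drop = drop
        self.ridge = ridge

    # -- fitting ---------------------------------------------------------

    def fit(self, panel, y=None):
        """Estimate F from a panel of (matched) null SNPs.

        ``panel`` may be a :class:`FrequencyPanel` or a bare (K, M) array of
        sample frequencies.  SNPs whose mean frequency is 0 or 1 carry no
        information and are excluded with a logged count.
        """
        if isinstance(panel, FrequencyPanel):
            freq = panel.freq
            pop_ids = panel.population_ids
        else:
            freq = np.asarray(panel, dtype=float)
            pop_ids = tuple(f"pop{i}" for i in range(freq.shape[1]))
        M = freq.shape[1]
        order = list(range(M))
        if self.drop != "last":
            if self.drop not in pop_ids:
                raise ValidationError(f"unknown population to drop: {self.drop!r}")
            j = pop_ids.index(self.drop)
            order = [i for i in range(M) if i != j] + [j]
        self.population_ids_ = tuple(pop_ids[i] for i in order)
        self._order_ = np.array(order)

        s, keep = standardized_deviations(freq[:, self._order_])
        n_excluded = int((~keep).sum())
        if n_excluded:
            logger.info("excluded %d null SNPs fixed across populations", n_excluded)
        if s.shape[0] < M:
            raise ValidationError(
                f"only {s.shape[0]} usable null SNPs for {M} populations; need at least M"
            )
        self.T_ = center_projection(M)
        # K-1 divisor; the same estimator is applied to null and observed
        # sets, so the normalization cannot affect test calibration.
        self.base_cov_ = np.cov(s.T)
        self.F_ = self.T_ @ self.base_cov_ @ self.T_.T
        self.F_ = 0.5 * (self.F_ + self.F_.T)
        self.n_null_snps_ = int(s.shape[0])
        self.chol_ = self._cholesky(self.F_)
        self.va_scale_ = None
        return self

    def _cholesky(self, F):
        """Lower Cholesky factor, or None for a singular F (checked at use)."""
        try:
            return cholesky(F, lower=True)
        except LinAlgError:
            bump = self.ridge * np.trace(F) / F.shape[0]
            logger.warning(
                "F not positive definite (duplicate populations or too few null "
                "SNPs?); retrying with ridge %.3g", bump,
            )
            try:
                return cholesky(F + bump * np.eye(F.shape[0]), lower=True)
            except LinAlgError:
                return None

    def set_genetic_architecture(self, effects: EffectTable, panel: FrequencyPanel):
        """Fix the additive-variance scale ``2*V_A`` from the loci under test."""
        self.va_scale_ = va_scale(effects, panel)
        return self

    # -- transforms ------------------------------------------------------

    def _check_fitted(self):
        if not hasattr(self, "F_"):
            raise ValidationError("DriftModel is not fitted")
        if self.chol_ is None:
            raise ValidationError(
                "F is singular; increase the number of null SNPs or drop "
                "duplicate populations"
            )

    def _reorder(self, values):
        values = np.asarray(values, dtype=float)
        return values[..., self._order_]

    def whiten(self, values, va: float | None = None) -> np.ndarray:
        """Whiten genetic-value vectors: ``x' = C^-1 T v / sqrt(2 V_A)``.

        ``values`` may be a length-M vector or an (R, M) batch.  Under the
        null each coordinate of the result is an independent standard
        normal.  ``va`` overrides the stored ``va_scale_`` (used when null
        sets carry their own locus frequencies, hence their own scale).
        """
        self._check_fitted()
        scale = self.va_scale_ if va is None else va
        if scale is None:
            raise ValidationError(
                "no additive-variance scale: call set_genetic_architecture first"
            )
        v = self._reorder(values)
        y = v @ self.T_.T
        x = solve_triangular(self.chol_, np.atleast_2d(y).T, lower=True).T
        scale = np.asarray(scale, dtype=float)
        x = x / np.sqrt(scale)[..., None] if scale.ndim else x / np.sqrt(scale)
        return x[0] if np.ndim(values) == 1 else x

    def transform(self, X):
        """sklearn alias: whiten rows of ``X`` using the stored va scale."""
        return self.whiten(X)

    def whiten_env(self, env) -> np.ndarray:
        """Whiten an environmental vector (no variance scaling: it keeps its units)."""
        self._check_fitted()
        if isinstance(env, EnvVector):
            env = env.aligned_to(self.population_ids_).value
            v = np.asarray(env, dtype=float)
        else:
            v = self._reorder(env)
        y = self.T_ @ v
        return solve_triangular(self.chol_, y, lower=True)

    def whiten_frequencies(self, freq) -> np.ndarray:
        """Per-locus transformed frequencies ``x'_l = C^-1 T p_l`` for an (L, M) matrix.

        Returns an (L, M-1) matrix.  These live in a set of transformed
        populations that are uncorrelated under the null, which is what lets
        the Q_X statistic be decomposed locus by locus.
        """
        self._check_fitted()
        p = np.atleast_2d(self._reorder(freq))
        return solve_triangular(self.chol_, (p @ self.T_.T).T, lower=True).T

    # -- persistence -----------------------------------------------------

    def save(self, path) -> None:
        """Plain-text dump (reloadable with :meth:`load`)."""
        self._check_fitted()
        with open(path, "w") as fh:
            fh.write("# polyadapt drift model\n")
            fh.write("populations\t" + "\t".join(self.population_ids_) + "\n")
            fh.write(f"n_null_snps\t{self.n_null_snps_}\n")
            va = "nan" if self.va_scale_ is None else f"{float(self.va_scale_):.17g}"
            fh.write(f"va_scale\t{va}\n")
            for row in self.base_cov_:
                fh.write("base_cov\t" + "\t".join(f"{x:.17g}" for x in row) + "\n")

    @classmethod
    def load(cls, path) -> "DriftModel":
        pops, rows, n_snps, va = None, [], None, None
        with open(path) as fh:
            for line in fh:
                if line.startswith("#"):
                    continue
                key, *vals = line.rstrip("\n").split("\t")
                if key == "populations":
                    pops = vals
                elif key == "n_null_snps":
                    n_snps = int(vals[0])
                elif key == "va_scale":
                    va = None if vals[0] == "nan" else float(vals[0])
                elif key == "base_cov":
                    rows.append([float(x) for x in vals])
        model = cls()
        model.population_ids_ = tuple(pops)
        model._order_ = np.arange(len(pops))
        model.base_cov_ = np.array(rows)
        M = len(pops)
        model.T_ = center_projection(M)
        model.F_ = model.T_ @ model.base_cov_ @ model.T_.T
        model.F_ = 0.5 * (model.F_ + model.F_.T)
        model.chol_ = model._cholesky(model.F_)
        model.n_null_snps_ = n_snps
        model.va_scale_ = va
        return model
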