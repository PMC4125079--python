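"""Conditional multivariate-normal machinery for localizing signals.

To ask whether particular populations (group 1) deviate from what their
relatives (group 2) predict, the drift covariance is re-estimated centered
on group 2's mean: group-1 coordinates keep their identity while every
coordinate has the group-2 mean subtracted.  Divergence from a subgroup mean
is larger than from the global mean even under neutrality, and the
re-centered covariance reflects that.  Standard MVN conditioning then gives
the expected mean and covariance of group 1 given group 2, and a Z-score

    z = (mean(Z_1) - mean(mu_cond)) / sqrt(mean of all elements of sigma_cond)

which is standard normal under the null.  A large |z| flags the tested group
as an outlier given its relatives, but cannot by itself attribute selection
to that group: conditioning on populations that were themselves selected
contaminates the score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .datamodel import FrequencyPanel, ValidationError
from .null_model import DriftModel, standardized_deviations

__all__ = [
    "GroupPartition",
    "ConditionalReport",
    "recenter_projection",
    "recenter_F",
    "conditional_distribution",
    "group_zscore",
    "conditional_test",
    "leave_one_out",
]


@dataclass(frozen=True)
class GroupPartition:
    """Disjoint split of all populations into tested (1) and conditioning (2) groups."""

    group1: tuple
    group2: tuple

    def __post_init__(self):
        object.__setattr__(self, "group1", tuple(self.group1))
        object.__setattr__(self, "group2", tuple(self.group2))
        if set(self.group1) & set(self.group2):
            raise ValidationError("groups must be disjoint")
        if len(self.group1) < 1:
            raise ValidationError("group 1 needs at least one population")
        if len(self.group2) < 2:
            raise ValidationError("group 2 needs at least two populations")


@dataclass
class ConditionalReport:
    group1: tuple
    cond_mean: float
    cond_var: float
    z: float
    p_two_sided: float


def _indices(population_ids, partition: GroupPartition):
    pos = {p: i for i, p in enumerate(population_ids)}
    missing = [p for p in partition.group1 + partition.group2 if p not in pos]
    if missing:
        raise ValidationError(f"unknown populations: {missing[:5]}")
    if len(partition.group1) + len(partition.group2) != len(population_ids):
        raise ValidationError("partition must cover all populations")
    i1 = np.array([pos[p] for p in partition.group1])
    i2 = np.array([pos[p] for p in partition.group2])
    return i1, i2


def recenter_projection(M: int, i1, i2) -> np.ndarray:
    """M x M projection subtracting the group-2 mean from every coordinate.

    Group-1 columns carry 1 on the diagonal and 0 elsewhere; group-2
    columns carry 1 - 1/M2 on their diagonal and -1/M2 elsewhere.
    """
    M2 = len(i2)
    T2 = np.eye(M)
    T2[:, i2] -= 1.0 / M2
    return T2


def recenter_F(source, partition: GroupPartition, population_ids=None) -> np.ndarray:
    """Covariance of standardized deviations re-centered on group 2's mean.

    ``source`` is a fitted :class:`DriftModel` (its stored M x M base
    covariance is reused) or a null-SNP :class:`FrequencyPanel` /
    (K, M) frequency array.  The group-2 block of the result has rank
    M2 - 1 by construction; only the needed blocks are ever inverted.
    """
    if isinstance(source, DriftModel):
        W = source.base_cov_
        pops = source.population_ids_
    elif isinstance(source, FrequencyPanel):
        s, _ = standardized_deviations(source.freq)
        W = np.cov(s.T)
        pops = source.population_ids
    else:
        s, _ = standardized_deviations(np.asarray(source, float))
        W = np.cov(s.T)
        pops = population_ids
    if population_ids is not None:
        pops = population_ids
    i1, i2 = _indices(pops, partition)
    T2 = recenter_projection(W.shape[0], i1, i2)
    F2 = T2 @ W @ T2.T
    return 0.5 * (F2 + F2.T)


def conditional_distribution(values2, F2: np.ndarray, partition: GroupPartition,
                             population_ids, va: float):
    """Conditional mean and covariance of group-1 genetic values given group 2.

    With ``Sigma = va * F2`` partitioned by groups,

        mu_cond    = mean(Z_2) 1 + S12 S22^- (Z_2 - mean(Z_2) 1)
        sigma_cond = S11 - S12 S22^- S21

    where ``S22^-`` is a pseudo-inverse restricted to the rank-(M2-1)
    support the re-centering construction guarantees.
    """
    i1, i2 = _indices(population_ids, partition)
    values2 = np.asarray(values2, dtype=float)
    if values2.shape[-1] != len(i2):
        raise ValidationError("values2 must have one entry per group-2 population")
    Sigma = va * F2
    S11 = Sigma[np.ix_(i1, i1)]
    S12 = Sigma[np.ix_(i1, i2)]
    S22 = Sigma[np.ix_(i2, i2)]
    S22_pinv = np.linalg.pinv(S22, rcond=1e-10, hermitian=True)
    mean2 = values2.mean(axis=-1, keepdims=True)
    dev = values2 - mean2
    mu_cond = mean2 + dev @ (S12 @ S22_pinv).T
    sigma_cond = S11 - S12 @ S22_pinv @ S12.T
    return mu_cond, sigma_cond


def group_zscore(values1, mu_cond, sigma_cond) -> ConditionalReport:
    """Z-score of group 1's mean genetic value against its conditional law."""
    values1 = np.asarray(values1, dtype=float)
    var = float(np.mean(sigma_cond))
    if var <= 0.0:
        raise ValidationError("nonpositive conditional variance")
    mu = float(np.mean(mu_cond))
    z = (float(np.mean(values1)) - mu) / np.sqrt(var)
    return ConditionalReport(
        group1=(),
        cond_mean=mu,
        cond_var=var,
        z=z,
        p_two_sided=float(2.0 * sps.norm.sf(abs(z))),
    )


def conditional_test(values, model: DriftModel, partition: GroupPartition,
                     va: float | None = None) -> ConditionalReport:
    """End-to-end conditional outlier test for one partition.

    ``values`` is the full length-M genetic-value vector in the model's
    population order.  The additive-variance scale is the global one fitted
    on the GWAS loci (a property of the loci, not of the partition) unless
    overridden.
    """
    scale = va if va is not None else model.va_scale_
    if scale is None:
        raise ValidationError("no additive-variance scale on the model")
    pops = model.population_ids_
    i1, i2 = _indices(pops, partition)
    values = np.asarray(values, dtype=float)
    F2 = recenter_F(model, partition)
    mu, S = conditional_distribution(values[i2], F2, partition, pops, scale)
    rep = group_zscore(values[i1], mu, S)
    rep.group1 = partition.group1
    return rep


def leave_one_out(values, model: DriftModel, va: float | None = None) -> list:
    """Conditional report for every population tested singly against the rest."""
    pops = model.population_ids_
    out = []
    for p in pops:
        part = GroupPartition(group1=(p,), group2=tuple(q for q in pops if q != p))
        out.append(conditional_test(values, model, part, va=va))
    return out
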