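"""Synthetic datasets with the statistical structure the method assumes.

The generator runs the drift model forward: for each SNP an ancestral
frequency ``eps`` is drawn, population frequencies are drawn from
``MVN(eps * 1, eps * (1 - eps) * F)`` truncated to [0, 1], and sample
frequencies are then drawn binomially with each population's chromosome
count -- so the finite-sample inflation of the covariance diagonal is
present in fixtures exactly as it is in real panels.  Ascertainment
metadata (MAF in a simulated ascertainment sample, B value, imputation
flag) is emitted for GWAS and pool SNPs alike so the matched-resampling
machinery is exercised end to end.  B values and imputation flags are drawn
independently of frequency: only the matching mechanics need exercising,
not a model of background selection.

Defaults emulate an HGDP-scale human study: 52 populations related by a
star tree with drift parameter 0.02 (continental-divergence scale, small
enough that the normal approximation to drift -- and hence the truncation of
frequency draws at [0, 1] -- stays in its validity range), 161 GWAS loci
(a height-GWAS-scale set), 50 chromosomes per population, effect sizes
|N(0, 0.1)| in trait units, and a latitude-like environment uniform on
[0, 60] degrees.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datamodel import EffectTable, EnvVector, FrequencyPanel, ValidationError

__all__ = ["FixtureSpec", "Dataset", "make_F", "simulate_panel", "make_dataset"]

_ALLELES = np.array(["A", "C", "G", "T"])


@dataclass
class FixtureSpec:
    """Generative settings for one synthetic study."""

    M: int = 52
    tree_or_F: object = ("star", 0.02)
    L_gwas: int = 161
    K_pool: int = 20000
    ancestral_low: float = 0.05
    ancestral_high: float = 0.95
    effect_sd: float = 0.1
    chromosomes: int = 50
    n_ascertainment_chroms: int = 2000
    imputed_rate: float = 0.3
    env_low: float = 0.0
    env_high: float = 60.0
    seed: int = 0

    def __post_init__(self):
        if self.L_gwas < 1 or self.K_pool < self.M:
            raise ValidationError("need L_gwas >= 1 and K_pool >= M")


@dataclass
class Dataset:
    """A complete synthetic study bundle."""

    effects: EffectTable
    gwas_panel: FrequencyPanel
    pool_meta: "object"            # DataFrame: snp_id, maf, imputed, b_value
    pool_panel: FrequencyPanel
    env: EnvVector
    F_true: np.ndarray
    truncated_fraction: float = 0.0


def make_F(spec: FixtureSpec) -> np.ndarray:
    """Among-population covariance from the spec's tree description.

    ``("star", c)`` gives ``c * I`` (equal independent drift on every tip);
    ``("balanced", c_shared, c_tip)`` gives two equal clades whose members
    share a branch of length ``c_shared`` plus private drift ``c_tip``;
    an explicit matrix is validated positive semi-definite.
    """
    t = spec.tree_or_F
    if isinstance(t, tuple) and t and t[0] == "star":
        return float(t[1]) * np.eye(spec.M)
    if isinstance(t, tuple) and t and t[0] == "balanced":
        _, c_shared, c_tip = t
        half = spec.M // 2
        F = np.zeros((spec.M, spec.M))
        F[:half, :half] = c_shared
        F[half:, half:] = c_shared
        F += (c_tip) * np.eye(spec.M)
        return F
    F = np.asarray(t, dtype=float)
    if F.shape != (spec.M, spec.M):
        raise ValidationError(f"explicit F must be {spec.M} x {spec.M}")
    eig = np.linalg.eigvalsh(0.5 * (F + F.T))
    if eig.min() < -1e-10 * max(1.0, eig.max()):
        raise ValidationError("explicit F is not positive semi-definite")
    return 0.5 * (F + F.T)


def simulate_panel(spec: FixtureSpec, F: np.ndarray, n_snps: int, rng,
                   prefix: str = "snp"):
    """Draw one panel of ``n_snps`` SNPs under the drift model.

    Returns ``(panel, metadata DataFrame, truncated_fraction)``.
    Population sample frequencies are binomial draws around the truncated
    MVN population frequencies; ascertainment MAF comes from an independent
    binomial sample of the ancestral frequency, folded to <= 0.5.
    """
    import pandas as pd

    M = spec.M
    eps = rng.uniform(spec.ancestral_low, spec.ancestral_high, size=n_snps)
    C = np.linalg.cholesky(F + 1e-12 * np.eye(M))
    z = rng.standard_normal((n_snps, M))
    p = eps[:, None] + np.sqrt(eps * (1.0 - eps))[:, None] * (z @ C.T)
    n_trunc = int(np.sum((p < 0.0) | (p > 1.0)))
    p = np.clip(p, 0.0, 1.0)
    counts = rng.binomial(spec.chromosomes, p)
    freq = counts / float(spec.chromosomes)
    asc = rng.binomial(spec.n_ascertainment_chroms, eps) / spec.n_ascertainment_chroms
    maf = np.minimum(asc, 1.0 - asc)
    meta = pd.DataFrame(
        {
            "snp_id": [f"{prefix}{i}" for i in range(n_snps)],
            "maf": maf,
            "imputed": rng.random(n_snps) < spec.imputed_rate,
            "b_value": rng.uniform(0.0, 1.0, size=n_snps),
        }
    )
    panel = FrequencyPanel(
        snp_ids=meta["snp_id"].tolist(),
        population_ids=[f"pop{m}" for m in range(M)],
        freq=freq,
        chromosomes=np.full(M, spec.chromosomes),
    )
    return panel, meta, n_trunc / float(n_snps * M)


def make_dataset(spec: FixtureSpec) -> Dataset:
    """Generate a full study bundle: GWAS loci, null pool, environment."""
    rng = np.random.default_rng(spec.seed)
    F = make_F(spec)
    gwas_panel, gwas_meta, tf1 = simulate_panel(spec, F, spec.L_gwas, rng, prefix="gwas")
    pool_panel, pool_meta, tf2 = simulate_panel(spec, F, spec.K_pool, rng, prefix="pool")
    alpha = np.abs(rng.normal(0.0, spec.effect_sd, size=spec.L_gwas))
    effects = EffectTable(
        snp_id=gwas_meta["snp_id"],
        effect_allele=_ALLELES[rng.integers(0, 4, size=spec.L_gwas)],
        alpha=alpha,
        ascertainment_maf=gwas_meta["maf"].to_numpy(),
        imputed=gwas_meta["imputed"].to_numpy(),
        b_value=gwas_meta["b_value"].to_numpy(),
    )
    env = EnvVector(
        population_ids=gwas_panel.population_ids,
        value=rng.uniform(spec.env_low, spec.env_high, size=spec.M),
    )
    total = spec.L_gwas + spec.K_pool
    return Dataset(
        effects=effects,
        gwas_panel=gwas_panel,
        pool_meta=pool_meta,
        pool_panel=pool_panel,
        env=env,
        F_true=F,
        truncated_fraction=(tf1 * spec.L_gwas + tf2 * spec.K_pool) / total,
    )
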