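"""Core data containers for polygenic-adaptation tests.

The method consumes four tabular inputs: a GWAS effect table (one row per
trait-associated SNP, oriented so every effect allele is trait-increasing),
an allele-frequency panel (loci x populations sample frequencies of the
effect allele, plus per-population chromosome counts), a genome-wide pool of
candidate null SNPs carrying the same ascertainment metadata, and per-
population environmental measurements.  These containers validate their
invariants once at construction so all downstream math can rely on them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EffectTable",
    "FrequencyPanel",
    "EnvVector",
    "RunConfig",
    "ValidationError",
    "FormatError",
]

_VALID_ALLELES = {"A", "C", "G", "T"}


class ValidationError(ValueError):
    """Raised when an input violates a model invariant."""


class FormatError(ValueError):
    """Raised when a tabular file does not match the expected layout."""


@dataclass(frozen=True)
class EffectTable:
    """GWAS loci with trait-increasing effect sizes and ascertainment metadata.

    Parameters
    ----------
    snp_id : sequence of str
        Unique SNP identifiers.
    effect_allele : sequence of str
        The trait-increasing allele at each locus (A/C/G/T).
    alpha : array-like of float
        Additive effect per copy of the effect allele, in trait units.
        Non-negative by convention: alleles are oriented at load time so
        every effect is trait-increasing.
    ascertainment_maf : array-like of float
        Minor allele frequency in the GWAS ascertainment population, in
        [0, 0.5]; used for null-SNP matching.
    imputed : array-like of bool
        Whether the SNP was imputed into the frequency panel.
    b_value : array-like of float
        Background-selection B value in [0, 1]; used for null-SNP matching.
    flipped : array-like of bool, optional
        Bookkeeping flag marking rows whose reported allele was flipped to
        the trait-increasing orientation at load time.
    """

    snp_id: tuple
    effect_allele: tuple
    alpha: np.ndarray
    ascertainment_maf: np.ndarray
    imputed: np.ndarray
    b_value: np.ndarray
    flipped: np.ndarray = field(default=None)

    def __post_init__(self):
        object.__setattr__(self, "snp_id", tuple(str(s) for s in self.snp_id))
        object.__setattr__(self, "effect_allele", tuple(self.effect_allele))
        object.__setattr__(self, "alpha", np.asarray(self.alpha, dtype=float))
        object.__setattr__(
            self, "ascertainment_maf", np.asarray(self.ascertainment_maf, dtype=float)
        )
        object.__setattr__(self, "imputed", np.asarray(self.imputed, dtype=bool))
        object.__setattr__(self, "b_value", np.asarray(self.b_value, dtype=float))
        if self.flipped is None:
            object.__setattr__(self, "flipped", np.zeros(len(self.snp_id), dtype=bool))
        else:
            object.__setattr__(self, "flipped", np.asarray(self.flipped, dtype=bool))
        n = len(self.snp_id)
        for name in ("effect_allele", "alpha", "ascertainment_maf", "imputed", "b_value", "flipped"):
            if len(getattr(self, name)) != n:
                raise ValidationError(f"column {name!r} has length != {n}")
        if len(set(self.snp_id)) != n:
            dupes = pd.Index(self.snp_id)
            dupes = sorted(set(dupes[dupes.duplicated()]))
            raise ValidationError(f"duplicate snp_id values: {dupes[:5]}")
        bad = [a for a in self.effect_allele if a not in _VALID_ALLELES]
        if bad:
            raise ValidationError(f"invalid effect alleles: {sorted(set(bad))[:5]}")
        if np.any(self.alpha < 0):
            raise ValidationError(
                "negative effect sizes remain after orientation; "
                "all effects must be trait-increasing"
            )
        if np.any((self.ascertainment_maf < 0) | (self.ascertainment_maf > 0.5)):
            raise ValidationError("ascertainment MAF must lie in [0, 0.5]")
        if np.any((self.b_value < 0) | (self.b_value > 1)):
            raise ValidationError("B values must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.snp_id)

    def subset(self, idx) -> "EffectTable":
        """Return a new table restricted to (and ordered by) integer rows ``idx``."""
        idx = np.asarray(idx)
        return EffectTable(
            snp_id=[self.snp_id[i] for i in idx],
            effect_allele=[self.effect_allele[i] for i in idx],
            alpha=self.alpha[idx],
            ascertainment_maf=self.ascertainment_maf[idx],
            imputed=self.imputed[idx],
            b_value=self.b_value[idx],
            flipped=self.flipped[idx],
        )

    def with_alpha(self, alpha) -> "EffectTable":
        """Return a copy with effect sizes replaced (used for V_A rescaling)."""
        return EffectTable(
            snp_id=self.snp_id,
            effect_allele=self.effect_allele,
            alpha=alpha,
            ascertainment_maf=self.ascertainment_maf,
            imputed=self.imputed,
            b_value=self.b_value,
            flipped=self.flipped,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "snp_id": list(self.snp_id),
                "effect_allele": list(self.effect_allele),
                "alpha": self.alpha,
                "maf": self.ascertainment_maf,
                "imputed": self.imputed.astype(int),
                "b_value": self.b_value,
            }
        )


@dataclass(frozen=True)
class FrequencyPanel:
    """Loci x populations sample frequencies of the effect allele.

    ``freq[l, m]`` is the sample frequency of locus ``l``'s (oriented) allele
    in population ``m``; ``chromosomes[m]`` is the number of sampled
    chromosomes in population ``m``.
    """

    snp_ids: tuple
    population_ids: tuple
    freq: np.ndarray
    chromosomes: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "snp_ids", tuple(str(s) for s in self.snp_ids))
        object.__setattr__(self, "population_ids", tuple(str(p) for p in self.population_ids))
        object.__setattr__(self, "freq", np.asarray(self.freq, dtype=float))
        object.__setattr__(self, "chromosomes", np.asarray(self.chromosomes, dtype=int))
        L, M = self.freq.shape if self.freq.ndim == 2 else (None, None)
        if L is None or L != len(self.snp_ids) or M != len(self.population_ids):
            raise ValidationError(
                f"freq shape {self.freq.shape} does not match "
                f"{len(self.snp_ids)} SNPs x {len(self.population_ids)} populations"
            )
        if np.any((self.freq < 0) | (self.freq > 1)) or not np.all(np.isfinite(self.freq)):
            raise ValidationError("frequencies must lie in [0, 1]")
        if len(self.chromosomes) != M:
            raise ValidationError("one chromosome count per population required")
        if np.any(self.chromosomes < 2):
            raise ValidationError("every population needs at least 2 chromosomes")

    @property
    def n_loci(self) -> int:
        return self.freq.shape[0]

    @property
    def n_populations(self) -> int:
        return self.freq.shape[1]

    def subset(self, idx) -> "FrequencyPanel":
        idx = np.asarray(idx)
        return FrequencyPanel(
            snp_ids=[self.snp_ids[i] for i in idx],
            population_ids=self.population_ids,
            freq=self.freq[idx],
            chromosomes=self.chromosomes,
        )


@dataclass(frozen=True)
class EnvVector:
    """One environmental measurement per population (e.g. absolute latitude)."""

    population_ids: tuple
    value: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "population_ids", tuple(str(p) for p in self.population_ids))
        object.__setattr__(self, "value", np.asarray(self.value, dtype=float))
        if len(self.population_ids) != len(self.value):
            raise ValidationError("one environmental value per population required")
        if not np.all(np.isfinite(self.value)):
            raise ValidationError("environmental values must be finite")

    def aligned_to(self, population_ids: Sequence[str]) -> "EnvVector":
        """Reorder to match ``population_ids``; error on any mismatch."""
        order = {p: i for i, p in enumerate(self.population_ids)}
        missing = [p for p in population_ids if p not in order]
        if missing:
            raise ValidationError(f"environment missing populations: {missing[:5]}")
        idx = [order[p] for p in population_ids]
        return EnvVector(population_ids=list(population_ids), value=self.value[idx])


@dataclass
class RunConfig:
    """Run-level knobs shared across CLI subcommands."""

    n_null_sets: int = 1000
    n_cov_snps: int = 20000
    rng_seed: int = 0
    dropped_population: str = "last"
    tails: dict = field(default_factory=lambda: {
        "QX": "upper",
        "qx_fst_like": "upper",
        "qx_ld_like": "upper",
        "beta": "two-sided",
        "r2": "upper",
        "rho": "two-sided",
    })

    def __post_init__(self):
        if self.n_null_sets < 1:
            raise ValidationError("n_null_sets must be >= 1")
        for stat, tail in self.tails.items():
            if tail not in ("upper", "two-sided"):
                raise ValidationError(f"tail for {stat} must be 'upper' or 'two-sided'")
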