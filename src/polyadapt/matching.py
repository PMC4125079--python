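"""Matched null-SNP resampling for the empirical null.

GWAS ascertainment can bias allele-frequency behavior in ways the drift
covariance does not capture (minor-allele-frequency spectrum, imputation
status, background-selection environment).  The empirical null therefore
resamples genome-wide SNPs matched to the GWAS loci on a three-way
contingency table: 25 MAF bins of width 0.02, 2 imputation bins, and 10
B-value bins of width 0.1.  Each null set draws one pool SNP from the same
cell as each GWAS SNP and carries over that GWAS SNP's effect size, giving a
single draw of "null genetic values" with the same ascertainment profile as
the observed set.  The same procedure supplies the SNPs used to estimate the
drift covariance F, so F describes the expected covariance structure of the
GWAS SNPs themselves.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .datamodel import EffectTable, FrequencyPanel, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "BinKey",
    "NullSet",
    "bin_assign",
    "bin_assign_arrays",
    "build_pool_index",
    "sample_null_index",
    "sample_null_sets",
    "sample_f_snps",
    "null_genetic_values",
    "admixed_ascertainment_freq",
]

N_MAF_BINS = 25
MAF_BIN_WIDTH = 0.02
N_B_BINS = 10
B_BIN_WIDTH = 0.1


class BinKey(NamedTuple):
    maf_bin: int
    imputed_bin: int
    b_bin: int


@dataclass(frozen=True)
class NullSet:
    """One matched resample: pool SNP ids with the GWAS effect sizes carried over."""

    snp_ids: tuple
    alpha: np.ndarray


def bin_assign(maf: float, imputed: bool, b_value: float) -> BinKey:
    """Contingency-table cell for one SNP (MAF width 0.02, B width 0.1, capped)."""
    if not (0.0 <= maf <= 0.5):
        raise ValidationError(f"MAF {maf} outside [0, 0.5]")
    if not (0.0 <= b_value <= 1.0):
        raise ValidationError(f"B value {b_value} outside [0, 1]")
    maf_bin = min(int(maf / MAF_BIN_WIDTH), N_MAF_BINS - 1)
    b_bin = min(int(b_value / B_BIN_WIDTH), N_B_BINS - 1)
    return BinKey(maf_bin, int(bool(imputed)), b_bin)


def bin_assign_arrays(maf, imputed, b_value) -> np.ndarray:
    """Vectorized bin assignment; returns a (n, 3) int array of bin triples."""
    maf = np.asarray(maf, dtype=float)
    b = np.asarray(b_value, dtype=float)
    if np.any((maf < 0) | (maf > 0.5)):
        raise ValidationError("MAF outside [0, 0.5]")
    if np.any((b < 0) | (b > 1)):
        raise ValidationError("B value outside [0, 1]")
    maf_bin = np.minimum((maf / MAF_BIN_WIDTH).astype(int), N_MAF_BINS - 1)
    b_bin = np.minimum((b / B_BIN_WIDTH).astype(int), N_B_BINS - 1)
    imp = np.asarray(imputed, dtype=bool).astype(int)
    return np.column_stack([maf_bin, imp, b_bin])


def build_pool_index(pool: EffectTable | "object") -> dict:
    """Map each contingency-table cell to the pool row indices it contains.

    ``pool`` needs ``ascertainment_maf``/``imputed``/``b_value`` attributes
    (an :class:`EffectTable` works; effect sizes are ignored) or ``maf``
    columns of a DataFrame-like with those names.
    """
    maf = getattr(pool, "ascertainment_maf", None)
    if maf is None:
        maf = np.asarray(pool["maf"])
        imputed = np.asarray(pool["imputed"]).astype(bool)
        b = np.asarray(pool["b_value"])
    else:
        imputed, b = pool.imputed, pool.b_value
    bins = bin_assign_arrays(maf, imputed, b)
    index: dict = {}
    order = np.lexsort(bins.T[::-1])
    sorted_bins = bins[order]
    change = np.ones(len(order), dtype=bool)
    if len(order) > 1:
        change[1:] = np.any(sorted_bins[1:] != sorted_bins[:-1], axis=1)
    starts = np.flatnonzero(change)
    ends = np.append(starts[1:], len(order))
    for s, e in zip(starts, ends):
        index[BinKey(*sorted_bins[s])] = order[s:e].copy()
    return index


def _bin_pool_with_fallback(key: BinKey, index: dict, needed: int):
    """Pool rows for a cell, widening MAF by +/-1 then +/-2 if undersized.

    The B and imputation coordinates are held fixed; fallbacks are logged.
    Returns (rows, widened_flag).
    """
    rows = index.get(key, np.empty(0, dtype=int))
    if rows.size >= needed:
        return rows, False
    for width in (1, 2):
        parts = [rows]
        for dm in (-width, width):
            mb = key.maf_bin + dm
            if 0 <= mb < N_MAF_BINS:
                parts.append(index.get(BinKey(mb, key.imputed_bin, key.b_bin),
                                       np.empty(0, dtype=int)))
        widened = np.unique(np.concatenate(parts))
        if widened.size >= needed:
            logger.debug("widened MAF search to +/-%d for cell %s", width, key)
            return widened, True
    return np.unique(np.concatenate(parts)), True


def sample_null_index(gwas: EffectTable, index: dict, n_sets: int, seed,
                      max_block_floats: int = 40_000_000) -> np.ndarray:
    """Sample matched null sets; returns an (n_sets, L) array of pool row indices.

    Column ``l`` of every set is matched (same contingency cell, up to the
    logged MAF-widening fallback) to GWAS SNP ``l``.  Within one set the
    draws for GWAS SNPs sharing a cell are distinct (sampling without
    replacement inside the cell); across sets draws are independent.
    Deterministic given ``seed`` (an int or a ``numpy.random.Generator``).
    """
    rng = np.random.default_rng(seed)
    bins = bin_assign_arrays(gwas.ascertainment_maf, gwas.imputed, gwas.b_value)
    out = np.empty((n_sets, len(gwas)), dtype=np.int64)
    # group GWAS columns by cell
    groups: dict = {}
    for col, triple in enumerate(map(tuple, bins)):
        groups.setdefault(BinKey(*triple), []).append(col)
    starved = []
    for key, cols in groups.items():
        g = len(cols)
        rows, _ = _bin_pool_with_fallback(key, index, g)
        n = rows.size
        if n < g:
            starved.extend(gwas.snp_id[c] for c in cols)
            continue
        # vectorized distinct draws: random keys per (set, pool row),
        # take the g smallest per set -> a uniform g-subset
        block = max(1, min(n_sets, max_block_floats // max(n, 1)))
        for s0 in range(0, n_sets, block):
            s1 = min(s0 + block, n_sets)
            u = rng.random((s1 - s0, n))
            pick = np.argpartition(u, g - 1, axis=1)[:, :g] if g < n else \
                np.tile(np.arange(n), (s1 - s0, 1))
            out[s0:s1, cols] = rows[pick]
    if starved:
        raise ValidationError(
            "contingency cells too sparse even after MAF widening for GWAS SNPs: "
            f"{starved[:10]}"
        )
    return out


def sample_null_sets(gwas: EffectTable, index: dict, pool_snp_ids, n_sets: int,
                     seed) -> list:
    """As :func:`sample_null_index`, wrapped into :class:`NullSet` objects."""
    idx = sample_null_index(gwas, index, n_sets, seed)
    ids = np.asarray(pool_snp_ids, dtype=object)
    return [NullSet(snp_ids=tuple(ids[row]), alpha=gwas.alpha.copy()) for row in idx]


def sample_f_snps(gwas: EffectTable, index: dict, n_snps: int, seed) -> np.ndarray:
    """Distinct matched pool rows for covariance estimation.

    Draws whole matched sets until at least ``n_snps`` distinct rows are
    collected (or the eligible pool is exhausted), so the SNPs behind F have
    the GWAS ascertainment profile; duplicates are removed because repeated
    rows add no information to the covariance but shrink its effective
    sample size.
    """
    rng = np.random.default_rng(seed)
    L = max(len(gwas), 1)
    n_sets = int(np.ceil(n_snps / L))
    seen = np.unique(sample_null_index(gwas, index, n_sets, rng).ravel())
    for _ in range(20):
        if seen.size >= n_snps:
            break
        extra = sample_null_index(gwas, index, max(n_sets // 2, 1), rng).ravel()
        new = np.union1d(seen, extra)
        if new.size == seen.size:   # eligible pool exhausted
            break
        seen = new
    if seen.size > n_snps:
        seen = rng.choice(seen, size=n_snps, replace=False)
    return seen


def null_genetic_values(sets, pool_panel: FrequencyPanel, alpha=None,
                        chunk: int = 500):
    """Genetic values and per-set additive-variance scales for null sets.

    ``sets`` is either an (n_sets, L) index array from
    :func:`sample_null_index` or a list of :class:`NullSet`.  Each set's
    genetic values use the carried-over effect sizes, and each set gets its
    own ``2*V_A`` computed from its own loci's mean frequencies -- the same
    scaling applied to the observed set.

    Returns ``(values, va)`` with shapes (n_sets, M) and (n_sets,).
    """
    if isinstance(sets, np.ndarray):
        idx = sets
        if alpha is None:
            raise ValidationError("alpha required with an index array")
        alphas = np.broadcast_to(np.asarray(alpha, float), (idx.shape[0], idx.shape[1]))
    else:
        pos = {s: i for i, s in enumerate(pool_panel.snp_ids)}
        idx = np.array([[pos[s] for s in ns.snp_ids] for ns in sets])
        alphas = np.array([ns.alpha for ns in sets])
    n_sets, L = idx.shape
    M = pool_panel.n_populations
    values = np.empty((n_sets, M))
    va = np.empty(n_sets)
    for s0 in range(0, n_sets, chunk):
        s1 = min(s0 + chunk, n_sets)
        P = pool_panel.freq[idx[s0:s1]]            # (b, L, M)
        a = alphas[s0:s1]
        values[s0:s1] = 2.0 * np.einsum("bl,blm->bm", a, P)
        eps = P.mean(axis=2)
        va[s0:s1] = 4.0 * np.sum(a**2 * eps * (1.0 - eps), axis=1)
    return values, va


def admixed_ascertainment_freq(panel: FrequencyPanel, pop_a: str, pop_b: str,
                               w: float) -> np.ndarray:
    """Proxy ascertainment MAF for an admixed GWAS population.

    The per-SNP frequency is the weighted mean ``w * p_a + (1 - w) * p_b``
    of two reference populations, folded to the minor allele (<= 0.5), for
    use in bin assignment when no direct ascertainment panel exists.
    """
    if not (0.0 <= w <= 1.0):
        raise ValidationError("admixture weight must lie in [0, 1]")
    pops = list(panel.population_ids)
    for p in (pop_a, pop_b):
        if p not in pops:
            raise ValidationError(f"population {p!r} not in panel")
    pa = panel.freq[:, pops.index(pop_a)]
    pb = panel.freq[:, pops.index(pop_b)]
    proxy = w * pa + (1.0 - w) * pb
    return np.minimum(proxy, 1.0 - proxy)
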