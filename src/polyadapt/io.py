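"""Tab-separated readers and writers for the method's inputs and reports.

All tabular interfaces are TSV with a header row.  Frequencies are always
frequencies of the effect allele; effect-allele orientation is resolved once
at load time (rows with negative effects are flipped to the trait-increasing
allele and their panel frequencies complemented), so downstream code can
assume alpha >= 0 everywhere.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datamodel import (
    EffectTable,
    EnvVector,
    FormatError,
    FrequencyPanel,
    RunConfig,
    ValidationError,
)

logger = logging.getLogger(__name__)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

_EFFECT_COLUMNS = ["snp_id", "effect_allele", "alpha", "maf", "imputed", "b_value"]


def _read_tsv(path, required=None) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"snp_id": str},
                     float_precision="round_trip")
    if required:
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise FormatError(f"{path}: missing required column(s) {missing}")
    return df


def load_effect_table(path) -> EffectTable:
    """Read a GWAS effect table, orienting every row to the trait-increasing allele.

    Rows with ``alpha < 0`` are flipped: the effect is negated, the allele
    label replaced by its complementary base (the other allele of the pair is
    not recorded in this format, so the complement stands in for it), and the
    ascertainment MAF kept as-is (MAF is fold-invariant).  The ``flipped``
    flag marks such rows so companion frequency panels complement their
    frequencies at load time.
    """
    df = _read_tsv(path, required=_EFFECT_COLUMNS)
    flip = df["alpha"].to_numpy(dtype=float) < 0
    alleles = [
        _COMPLEMENT[a] if f else a
        for a, f in zip(df["effect_allele"].astype(str), flip)
    ]
    if flip.any():
        logger.info("flipped %d rows to the trait-increasing allele", int(flip.sum()))
    return EffectTable(
        snp_id=df["snp_id"],
        effect_allele=alleles,
        alpha=np.abs(df["alpha"].to_numpy(dtype=float)),
        ascertainment_maf=df["maf"].to_numpy(dtype=float),
        imputed=df["imputed"].to_numpy().astype(bool),
        b_value=df["b_value"].to_numpy(dtype=float),
        flipped=flip,
    )


def write_effect_table(effects: EffectTable, path) -> None:
    effects.to_frame().to_csv(path, sep="\t", index=False)


def load_chromosome_counts(path, population_ids) -> np.ndarray:
    df = _read_tsv(path, required=["population_id", "chromosomes"])
    counts = dict(zip(df["population_id"].astype(str), df["chromosomes"].astype(int)))
    missing = [p for p in population_ids if p not in counts]
    if missing:
        raise FormatError(f"{path}: missing chromosome counts for {missing[:5]}")
    return np.array([counts[p] for p in population_ids], dtype=int)


def load_frequency_panel(path, chrom_path, effects: EffectTable | None = None) -> FrequencyPanel:
    """Read a loci x populations frequency matrix plus chromosome counts.

    When ``effects`` is given the panel is restricted to (and ordered as) the
    effect table's loci, frequencies of flipped rows are complemented so they
    refer to the trait-increasing allele, and loci absent from the panel are
    dropped with a logged count (the analysis proceeds on the intersection).
    Returns the panel; when loci were dropped the caller should re-intersect
    the effect table via :func:`intersect_effects_panel`.
    """
    df = _read_tsv(path, required=["snp_id"])
    pop_ids = [c for c in df.columns if c != "snp_id"]
    if not pop_ids:
        raise FormatError(f"{path}: no population columns found")
    freq = df[pop_ids].to_numpy(dtype=float)
    if np.any((freq < 0) | (freq > 1)):
        raise ValidationError(f"{path}: frequencies outside [0, 1]")
    snp_ids = df["snp_id"].astype(str).tolist()
    if effects is not None:
        pos = {s: i for i, s in enumerate(snp_ids)}
        present = [s for s in effects.snp_id if s in pos]
        n_dropped = len(effects) - len(present)
        if n_dropped:
            logger.warning(
                "%d of %d effect-table SNPs absent from the frequency panel; dropped",
                n_dropped, len(effects),
            )
        rows = [pos[s] for s in present]
        freq = freq[rows]
        keep = {s for s in present}
        flip_rows = [f for s, f in zip(effects.snp_id, effects.flipped) if s in keep]
        flip_rows = np.asarray(flip_rows, dtype=bool)
        freq[flip_rows] = 1.0 - freq[flip_rows]
        snp_ids = present
    chroms = load_chromosome_counts(chrom_path, pop_ids)
    return FrequencyPanel(snp_ids=snp_ids, population_ids=pop_ids, freq=freq, chromosomes=chroms)


def intersect_effects_panel(effects: EffectTable, panel: FrequencyPanel):
    """Restrict an effect table to the loci present in a panel, in panel order."""
    pos = {s: i for i, s in enumerate(effects.snp_id)}
    idx = [pos[s] for s in panel.snp_ids if s in pos]
    return effects.subset(idx)


def write_frequency_panel(panel: FrequencyPanel, path, chrom_path) -> None:
    df = pd.DataFrame(panel.freq, columns=list(panel.population_ids))
    df.insert(0, "snp_id", list(panel.snp_ids))
    df.to_csv(path, sep="\t", index=False)
    pd.DataFrame(
        {"population_id": list(panel.population_ids), "chromosomes": panel.chromosomes}
    ).to_csv(chrom_path, sep="\t", index=False)


def load_env(path) -> EnvVector:
    df = _read_tsv(path, required=["population_id", "value"])
    return EnvVector(
        population_ids=df["population_id"].astype(str).tolist(),
        value=df["value"].to_numpy(dtype=float),
    )


def write_env(env: EnvVector, path) -> None:
    pd.DataFrame(
        {"population_id": list(env.population_ids), "value": env.value}
    ).to_csv(path, sep="\t", index=False)


def write_report(report, path, sidecar: str | Path | None = None) -> None:
    """Serialize a TestReport, a list of them, or a ConditionalReport set.

    One summary row per statistic (or per tested group), with the observed
    value, empirical p-value, null-draw count and seed.  Null draws go to the
    optional ``sidecar`` TSV, one column per statistic.
    """
    reports = report if isinstance(report, (list, tuple)) else [report]
    rows, draws = [], {}
    for r in reports:
        if hasattr(r, "statistic_name"):  # TestReport
            rows.append(
                {
                    "statistic": r.statistic_name,
                    "observed": r.observed,
                    "p_empirical": r.p_empirical,
                    "tail": r.tail,
                    "n_null": len(r.null_draws),
                    "seed": r.seed,
                }
            )
            draws[r.statistic_name] = np.asarray(r.null_draws)
        else:  # ConditionalReport
            rows.append(
                {
                    "group1": ",".join(r.group1),
                    "cond_mean": r.cond_mean,
                    "cond_var": r.cond_var,
                    "z": r.z,
                    "p_two_sided": r.p_two_sided,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    if sidecar is not None and draws:
        pd.DataFrame(draws).to_csv(sidecar, sep="\t", index=False)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = RunConfig()
    for key, val in raw.items():
        if key == "tails":
            cfg.tails.update(val)
        elif hasattr(cfg, key):
            setattr(cfg, key, val)
        else:
            raise FormatError(f"unknown config key {key!r}")
    cfg.__post_init__()
    return cfg
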