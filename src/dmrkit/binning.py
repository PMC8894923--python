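"""Replicate pooling, fixed-bin weighted methylation levels, and per-site
differential calls.

The weighted methylation level of a set of cytosines is
``sum(methylated reads) / sum(total reads)`` — the count-weighted mean, not
the mean of per-site fractions — computed over sites whose coverage meets
``min_cov``.  Bins are fixed-width tiles anchored at position 0 of each
chromosome (the terminal bin may be short); a bin's level is undefined when
it contains no sufficiently covered cytosine of the requested context.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CONTEXTS, MethylomeTable, ValidationError

DEFAULT_BIN_SIZE = 100
DEFAULT_MIN_COV = 4

#: per-site level-difference thresholds by context (same values used per bin)
DEFAULT_DMC_THRESHOLD = {"CG": 0.40, "CHG": 0.35}


@dataclass(frozen=True)
class BinGrid:
    """Fixed tiling of each chromosome into ``bin_size``-bp bins from 0."""

    bin_size: int = DEFAULT_BIN_SIZE

    def bin_start(self, pos: np.ndarray) -> np.ndarray:
        return (np.asarray(pos) // self.bin_size) * self.bin_size


def pool_replicates(tables: list[MethylomeTable], sample_id: str | None = None) -> MethylomeTable:
    """Sum per-site counts across replicate tables.

    A site is present in the output iff present in at least one input; counts
    at shared sites are added.  All tables must share a genome_id.
    """
    if not tables:
        raise ValidationError("no tables to pool")
    genome_ids = {t.genome_id for t in tables}
    if len(genome_ids) != 1:
        raise ValidationError(f"mixed genome_id in pooled tables: {sorted(genome_ids)}")
    if len(tables) == 1:
        t = tables[0]
        return MethylomeTable(sample_id=sample_id or t.sample_id, df=t.df.copy(), genome_id=t.genome_id)
    cat = pd.concat([t.df for t in tables], ignore_index=True)
    pooled = (
        cat.groupby(["chrom", "pos", "strand", "context"], as_index=False, sort=False)[["count_m", "count_u"]]
        .sum()
    )
    label = sample_id or "+".join(t.sample_id for t in tables)
    return MethylomeTable(sample_id=label, df=pooled, genome_id=tables[0].genome_id)


def bin_methylation(
    table: MethylomeTable,
    context: str,
    grid: BinGrid = BinGrid(),
    min_cov: int = DEFAULT_MIN_COV,
    chrom_sizes: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Weighted methylation level per fixed bin for one context.

    Returns a frame (chrom, start, end, n_covered, sum_m, sum_t, level)
    containing every bin with >=1 record of the context (covered or not);
    ``level`` is NaN where ``n_covered == 0``.  When ``chrom_sizes`` is given,
    bin ends are clipped to the chromosome length (terminal short bin).
    """
    if context not in CONTEXTS:
        raise ValidationError(f"unknown context {context!r}")
    sub = table.subset_context(context)
    cov = (sub["count_m"] + sub["count_u"]).to_numpy()
    covered = cov >= min_cov
    start = grid.bin_start(sub["pos"].to_numpy()) if len(sub) else np.array([], dtype=int)
    agg = pd.DataFrame(
        {
            "chrom": sub["chrom"].to_numpy(),
            "start": start,
            "n_covered": covered.astype(int),
            "sum_m": np.where(covered, sub["count_m"].to_numpy(), 0),
            "sum_t": np.where(covered, cov, 0),
        }
    )
    out = agg.groupby(["chrom", "start"], as_index=False, sort=True).sum()
    out["end"] = out["start"] + grid.bin_size
    if chrom_sizes:
        lim = out["chrom"].map(chrom_sizes)
        out["end"] = np.minimum(out["end"], lim.fillna(out["end"]).astype(int))
    with np.errstate(invalid="ignore", divide="ignore"):
        out["level"] = np.where(out["sum_t"] > 0, out["sum_m"] / out["sum_t"].replace(0, np.nan), np.nan)
    return out[["chrom", "start", "end", "n_covered", "sum_m", "sum_t", "level"]]


def call_dmcs(
    table_a: MethylomeTable,
    table_b: MethylomeTable,
    context: str,
    threshold: float | None = None,
    min_cov: int = DEFAULT_MIN_COV,
) -> pd.DataFrame:
    """Per-site differential methylation calls between two samples.

    One call per site covered >= ``min_cov`` in *both* samples;
    ``delta = level_b - level_a`` and ``is_dmc`` iff ``|delta| >= threshold``
    (default: the context's bin-level threshold, 0.40 CG / 0.35 CHG).
    Returns a frame (chrom, pos, strand, context, level_a, level_b, delta,
    is_dmc, direction) with direction in {-1, 0, +1}.
    """
    if threshold is None:
        if context not in DEFAULT_DMC_THRESHOLD:
            raise ValidationError(f"no default threshold for context {context!r}")
        threshold = DEFAULT_DMC_THRESHOLD[context]
    if not (0 < threshold <= 1):
        raise ValidationError(f"threshold must be in (0, 1], got {threshold}")
    a = table_a.subset_context(context)
    b = table_b.subset_context(context)
    merged = a.merge(
        b, on=["chrom", "pos", "strand"], suffixes=("_a", "_b"), how="inner", sort=False
    )
    cov_a = (merged["count_m_a"] + merged["count_u_a"]).to_numpy()
    cov_b = (merged["count_m_b"] + merged["count_u_b"]).to_numpy()
    keep = (cov_a >= min_cov) & (cov_b >= min_cov)
    merged = merged[keep]
    cov_a, cov_b = cov_a[keep], cov_b[keep]
    level_a = merged["count_m_a"].to_numpy() / cov_a if len(merged) else np.array([])
    level_b = merged["count_m_b"].to_numpy() / cov_b if len(merged) else np.array([])
    delta = level_b - level_a
    out = pd.DataFrame(
        {
            "chrom": merged["chrom"].to_numpy(),
            "pos": merged["pos"].to_numpy(),
            "strand": merged["strand"].to_numpy(),
            "context": context,
            "level_a": level_a,
            "level_b": level_b,
            "delta": delta,
            "is_dmc": np.abs(delta) >= threshold,
            "direction": np.sign(delta).astype(int),
        }
    )
    return out.sort_values(["chrom", "pos", "strand"], kind="mergesort", ignore_index=True)


def weighted_level(df: pd.DataFrame, min_cov: int = DEFAULT_MIN_COV) -> float:
    """Weighted methylation level of an arbitrary set of cytosine records.

    NaN when no site meets ``min_cov``.
    """
    cov = (df["count_m"] + df["count_u"]).to_numpy()
    keep = cov >= min_cov
    total = int(cov[keep].sum())
    if total == 0:
        return float("nan")
    return float(df["count_m"].to_numpy()[keep].sum() / total)
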