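"""Bin-based DMR calling.

A DMR in the CG or CHG context is defined from fixed 100-bp bins: a bin is a
candidate when it contains at least ``min_dmc`` differentially methylated
cytosines (4 for CG, 5 for CHG) agreeing in direction with an absolute
bin-level methylation difference of at least ``min_diff`` (0.40 CG,
0.35 CHG).  Candidate bins whose edge-to-edge gap is at most 200 bp are
merged, and only bins that merged at least once — clusters of two or more —
are reported as DMRs.

Ectopic CHG gains are called with the same machinery but require the control
bin to be essentially unmethylated and use relaxed thresholds (3 DMCs,
+0.15 gain).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .binning import (
    DEFAULT_BIN_SIZE,
    DEFAULT_MIN_COV,
    BinGrid,
    bin_methylation,
    call_dmcs,
)
from .io import MethylomeTable, ValidationError

DIRECTIONS = ("hypo", "hyper", "ectopic")


@dataclass(frozen=True)
class DmrParams:
    """Thresholds of the bin-based DMR definition.

    ``direction`` is the sign of treated-minus-control the caller looks for:
    ``hypo`` (loss), ``hyper`` (gain) or ``ectopic`` (gain restricted to bins
    unmethylated in the control).  ``control_max_level`` and
    ``control_max_site_reads`` implement the unmethylated-control rule for
    ectopic calls and are ignored otherwise.
    """

    context: str = "CG"
    direction: str = "hypo"
    min_dmc: int = 4
    min_diff: float = 0.40
    merge_gap: int = 200
    bin_size: int = DEFAULT_BIN_SIZE
    min_cov: int = DEFAULT_MIN_COV
    control_max_level: float = 0.02
    control_max_site_reads: int = 1

    def __post_init__(self) -> None:
        if self.direction not in DIRECTIONS:
            raise ValidationError(f"unknown direction {self.direction!r}")
        if self.min_dmc < 1:
            raise ValidationError("min_dmc must be >= 1")
        if not (0 < self.min_diff <= 1):
            raise ValidationError("min_diff must be in (0, 1]")
        if self.merge_gap < 0:
            raise ValidationError("merge_gap must be >= 0")

    @classmethod
    def cg(cls, direction: str = "hypo", **kw) -> "DmrParams":
        return cls(context="CG", direction=direction, min_dmc=4, min_diff=0.40, **kw)

    @classmethod
    def chg(cls, direction: str = "hypo", **kw) -> "DmrParams":
        return cls(context="CHG", direction=direction, min_dmc=5, min_diff=0.35, **kw)

    @classmethod
    def ectopic_chg(cls, **kw) -> "DmrParams":
        return cls(context="CHG", direction="ectopic", min_dmc=3, min_diff=0.15, **kw)

    def flipped(self) -> "DmrParams":
        if self.direction == "ectopic":
            raise ValidationError("ectopic direction has no mirror")
        other = "hyper" if self.direction == "hypo" else "hypo"
        return replace(self, direction=other)


@dataclass(frozen=True)
class Dmr:
    """A merged run of >=2 candidate bins sharing context and direction."""

    chrom: str
    start: int
    end: int
    context: str
    direction: str
    member_bins: tuple[tuple[int, int], ...]  # (start, end) per member bin
    member_deltas: tuple[float, ...]
    member_n_dmc: tuple[int, ...]

    @property
    def n_bins(self) -> int:
        return len(self.member_bins)

    @property
    def mean_delta(self) -> float:
        return float(np.mean(self.member_deltas))

    @property
    def length(self) -> int:
        return self.end - self.start


def dmrs_to_frame(dmrs: list[Dmr]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": d.chrom,
                "start": d.start,
                "end": d.end,
                "context": d.context,
                "direction": d.direction,
                "n_bins": d.n_bins,
                "mean_delta": d.mean_delta,
            }
            for d in dmrs
        ],
        columns=["chrom", "start", "end", "context", "direction", "n_bins", "mean_delta"],
    )


def _dmc_counts_per_bin(dmcs: pd.DataFrame, bin_size: int, sign: int) -> pd.DataFrame:
    """Count direction-matching DMCs per (chrom, bin start)."""
    hits = dmcs[dmcs["is_dmc"] & (dmcs["direction"] == sign)]
    if not len(hits):
        return pd.DataFrame(
            {
                "chrom": pd.Series(dtype=object),
                "start": pd.Series(dtype=np.int64),
                "n_dmc": pd.Series(dtype=np.int64),
            }
        )
    starts = (hits["pos"].to_numpy() // bin_size) * bin_size
    counts = (
        pd.DataFrame({"chrom": hits["chrom"].to_numpy(), "start": starts})
        .groupby(["chrom", "start"], as_index=False)
        .size()
        .rename(columns={"size": "n_dmc"})
    )
    return counts


def screen_bins(
    bins_a: pd.DataFrame,
    bins_b: pd.DataFrame,
    dmcs: pd.DataFrame,
    params: DmrParams,
    eligible: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Select candidate bins.

    A bin qualifies iff (i) its level is defined in both samples, (ii) the
    signed level difference ``b - a`` matches ``params.direction`` with
    magnitude >= ``min_diff``, and (iii) it contains >= ``min_dmc`` DMCs of
    the matching direction.  ``eligible`` optionally restricts candidates to
    a set of (chrom, start) bin keys (used for the unmethylated-control rule).

    Returns a frame (chrom, start, end, level_a, level_b, delta, n_dmc)
    sorted by position.
    """
    if bins_a.attrs.get("bin_size", params.bin_size) != bins_b.attrs.get("bin_size", params.bin_size):
        raise ValidationError("bin grids differ between samples")
    sign = -1 if params.direction == "hypo" else 1
    merged = bins_a.merge(bins_b, on=["chrom", "start"], suffixes=("_a", "_b"), how="inner")
    defined = (merged["n_covered_a"] > 0) & (merged["n_covered_b"] > 0)
    merged = merged[defined].copy()
    merged["delta"] = merged["level_b"] - merged["level_a"]
    keep = sign * merged["delta"] >= params.min_diff
    merged = merged[keep]
    counts = _dmc_counts_per_bin(dmcs, params.bin_size, sign)
    merged = merged.merge(counts, on=["chrom", "start"], how="left")
    merged["n_dmc"] = merged["n_dmc"].fillna(0).astype(int)
    merged = merged[merged["n_dmc"] >= params.min_dmc]
    if eligible is not None:
        key = merged["chrom"].astype(str) + ":" + merged["start"].astype(str)
        ok = set(eligible["chrom"].astype(str) + ":" + eligible["start"].astype(str))
        merged = merged[key.isin(ok)]
    merged["end"] = merged[["end_a", "end_b"]].min(axis=1)
    out = merged[["chrom", "start", "end", "level_a", "level_b", "delta", "n_dmc"]]
    return out.sort_values(["chrom", "start"], kind="mergesort", ignore_index=True)


def merge_candidates(candidates: pd.DataFrame, params: DmrParams) -> list[Dmr]:
    """Single-linkage merge of candidate bins; singletons are discarded.

    Two bins merge when the gap from the end of one to the start of the next
    is <= ``merge_gap`` (edge-to-edge).  A cluster of a single bin is never a
    DMR.
    """
    dmrs: list[Dmr] = []
    if not len(candidates):
        return dmrs
    cand = candidates.sort_values(["chrom", "start"], kind="mergesort", ignore_index=True)
    for chrom, sub in cand.groupby("chrom", sort=True):
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        deltas = sub["delta"].to_numpy()
        ndmc = sub["n_dmc"].to_numpy()
        cluster: list[int] = []
        cluster_end = -1

        def flush(cluster: list[int]) -> None:
            if len(cluster) < 2:
                return
            dmrs.append(
                Dmr(
                    chrom=str(chrom),
                    start=int(starts[cluster[0]]),
                    end=int(ends[cluster[-1]]),
                    context=params.context,
                    direction=params.direction,
                    member_bins=tuple((int(starts[i]), int(ends[i])) for i in cluster),
                    member_deltas=tuple(float(deltas[i]) for i in cluster),
                    member_n_dmc=tuple(int(ndmc[i]) for i in cluster),
                )
            )

        for i in range(len(sub)):
            if cluster and starts[i] - cluster_end <= params.merge_gap:
                cluster.append(i)
            else:
                flush(cluster)
                cluster = [i]
            cluster_end = max(cluster_end, int(ends[i])) if len(cluster) > 1 else int(ends[i])
        flush(cluster)
    dmrs.sort(key=lambda d: (d.chrom, d.start))
    return dmrs


def call_dmrs(
    control: MethylomeTable,
    treated: MethylomeTable,
    params: DmrParams,
    chrom_sizes: dict[str, int] | None = None,
) -> list[Dmr]:
    """End-to-end DMR call: bin levels -> per-site calls -> screen -> merge.

    ``delta`` is treated minus control throughout.
    """
    if control.genome_id != treated.genome_id:
        raise ValidationError(
            f"genome_id mismatch: {control.genome_id!r} vs {treated.genome_id!r}"
        )
    if params.direction == "ectopic":
        return call_ectopic_chg(control, treated, params, chrom_sizes)
    grid = BinGrid(params.bin_size)
    bins_a = bin_methylation(control, params.context, grid, params.min_cov, chrom_sizes)
    bins_b = bin_methylation(treated, params.context, grid, params.min_cov, chrom_sizes)
    dmcs = call_dmcs(control, treated, params.context, params.min_diff, params.min_cov)
    candidates = screen_bins(bins_a, bins_b, dmcs, params)
    return merge_candidates(candidates, params)


def _unmethylated_control_bins(control: MethylomeTable, params: DmrParams) -> pd.DataFrame:
    """Bins whose control CHG methylation is effectively absent.

    Eligibility: weighted CHG level over covered sites <= ``control_max_level``
    AND no single site carries more than ``control_max_site_reads`` methylated
    reads.  Bins with zero covered CHG sites count as unmethylated.
    """
    sub = control.subset_context(params.context)
    if not len(sub):
        return pd.DataFrame(columns=["chrom", "start"])
    starts = (sub["pos"].to_numpy() // params.bin_size) * params.bin_size
    cov = (sub["count_m"] + sub["count_u"]).to_numpy()
    df = pd.DataFrame(
        {
            "chrom": sub["chrom"].to_numpy(),
            "start": starts,
            "sum_m": np.where(cov > 0, sub["count_m"].to_numpy(), 0),
            "sum_t": np.where(cov > 0, cov, 0),
            "max_m": sub["count_m"].to_numpy(),
        }
    )
    agg = df.groupby(["chrom", "start"], as_index=False).agg(
        sum_m=("sum_m", "sum"), sum_t=("sum_t", "sum"), max_m=("max_m", "max")
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        level = np.where(agg["sum_t"] > 0, agg["sum_m"] / agg["sum_t"].replace(0, np.nan), 0.0)
    ok = (level <= params.control_max_level) & (agg["max_m"] <= params.control_max_site_reads)
    return agg.loc[ok, ["chrom", "start"]].reset_index(drop=True)


def call_ectopic_chg(
    control: MethylomeTable,
    treated: MethylomeTable,
    params: DmrParams | None = None,
    chrom_sizes: dict[str, int] | None = None,
) -> list[Dmr]:
    """Detect ectopic CHG methylation gains over an unmethylated control.

    Candidate bins must be unmethylated in the control (near-zero weighted
    level, no site with >1 methylated read), gain >= ``min_diff`` with
    >= ``min_dmc`` gain-direction DMCs, then merge as usual.
    """
    if params is None:
        params = DmrParams.ectopic_chg()
    if control.genome_id != treated.genome_id:
        raise ValidationError(
            f"genome_id mismatch: {control.genome_id!r} vs {treated.genome_id!r}"
        )
    grid = BinGrid(params.bin_size)
    bins_a = bin_methylation(control, params.context, grid, params.min_cov, chrom_sizes)
    bins_b = bin_methylation(treated, params.context, grid, params.min_cov, chrom_sizes)
    dmcs = call_dmcs(control, treated, params.context, params.min_diff, params.min_cov)
    eligible = _unmethylated_control_bins(control, params)
    candidates = screen_bins(bins_a, bins_b, dmcs, params, eligible=eligible)
    return merge_candidates(candidates, params)
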