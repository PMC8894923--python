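"""Gene-body metaplots, chromosome-scale ratio tracks, and DMR x sample
level matrices.

Metaplots use fixed 100-bp absolute windows anchored at each gene's 5' and
3' ends in strand-aware orientation (not length-normalised body bins): the
profile walks ``flank`` bp outward and ``body_window`` bp inward from each
end.  Genes shorter than twice the body window contribute only the body
intervals that do not reach past their midpoint, so the two ends never
overlap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .binning import DEFAULT_MIN_COV, BinGrid, bin_methylation
from .dmr import Dmr
from .io import FeatureSet, MethylomeTable, ValidationError

METAPLOT_STEP = 100


@dataclass
class MetaProfile:
    """Averaged methylation profile around gene bodies.

    ``df`` rows are ordered intervals: upstream flank (distal -> 5' end),
    body from the 5' end (inward), body toward the 3' end (inward -> 3'),
    downstream flank (3' end -> distal).  ``offset`` is the signed bp of the
    interval start relative to the anchoring gene end (negative = outside
    the gene at the 5' anchor, etc.).
    """

    df: pd.DataFrame  # segment, index_in_segment, offset, level, n_genes
    flank: int = 2000
    body_window: int = 1500

    @property
    def levels(self) -> np.ndarray:
        return self.df["level"].to_numpy()


def _covered_arrays(table: MethylomeTable, context: str, min_cov: int):
    """Per-chromosome sorted positions and count cumsums over covered sites."""
    sub = table.subset_context(context)
    cov = (sub["count_m"] + sub["count_u"]).to_numpy()
    sub = sub[cov >= min_cov]
    out = {}
    for chrom, s in sub.groupby("chrom", sort=False):
        pos = s["pos"].to_numpy()
        cm = np.concatenate([[0], np.cumsum(s["count_m"].to_numpy())])
        ct = np.concatenate([[0], np.cumsum((s["count_m"] + s["count_u"]).to_numpy())])
        out[chrom] = (pos, cm, ct)
    return out


def _interval_level(arrays, chrom: str, start: int, end: int) -> tuple[float, int]:
    """(weighted level, total reads) over covered sites in [start, end)."""
    if chrom not in arrays or end <= start:
        return float("nan"), 0
    pos, cm, ct = arrays[chrom]
    i0 = np.searchsorted(pos, start, side="left")
    i1 = np.searchsorted(pos, end, side="left")
    total = int(ct[i1] - ct[i0])
    if total == 0:
        return float("nan"), 0
    return float((cm[i1] - cm[i0]) / total), total


def _gene_intervals(gs: int, ge: int, strand: str, flank: int, body: int):
    """Yield (segment, idx, offset, genomic_start, genomic_end) per interval.

    Body intervals that would cross the gene midpoint are yielded with a
    None genomic range (the gene skips them).
    """
    F = flank // METAPLOT_STEP
    B = body // METAPLOT_STEP
    L = ge - gs
    for i in range(F):
        off = -(F - i) * METAPLOT_STEP
        if strand == "+":
            yield "upstream", i, off, gs + off, gs + off + METAPLOT_STEP
        else:
            yield "upstream", i, off, ge - off - METAPLOT_STEP, ge - off
    for i in range(B):
        off = i * METAPLOT_STEP
        ok = 2 * (i + 1) * METAPLOT_STEP <= L
        if not ok:
            yield "body5", i, off, None, None
        elif strand == "+":
            yield "body5", i, off, gs + off, gs + off + METAPLOT_STEP
        else:
            yield "body5", i, off, ge - off - METAPLOT_STEP, ge - off
    for j in range(B):
        off = -(B - j) * METAPLOT_STEP  # relative to the 3' end
        ok = 2 * (B - j) * METAPLOT_STEP <= L
        if not ok:
            yield "body3", j, off, None, None
        elif strand == "+":
            yield "body3", j, off, ge + off, ge + off + METAPLOT_STEP
        else:
            yield "body3", j, off, gs - off - METAPLOT_STEP, gs - off
    for j in range(F):
        off = j * METAPLOT_STEP
        if strand == "+":
            yield "downstream", j, off, ge + off, ge + off + METAPLOT_STEP
        else:
            yield "downstream", j, off, gs - off - METAPLOT_STEP, gs - off


def gene_metaplot(
    table: MethylomeTable,
    features: FeatureSet,
    context: str = "CG",
    flank: int = 2000,
    body_window: int = 1500,
    min_cov: int = DEFAULT_MIN_COV,
    feature_class: str = "gene",
) -> MetaProfile:
    """Average methylation in 100-bp intervals anchored at gene ends.

    Per interval, the profile level is the mean over genes of each gene's
    interval weighted level; a gene with no covered site in an interval is
    skipped for that interval only.
    """
    if flank % METAPLOT_STEP or body_window % METAPLOT_STEP:
        raise ValidationError("flank and body_window must be multiples of 100")
    arrays = _covered_arrays(table, context, min_cov)
    genes = features.by_class(feature_class)
    n_int = 2 * (flank // METAPLOT_STEP) + 2 * (body_window // METAPLOT_STEP)
    sums = np.zeros(n_int)
    counts = np.zeros(n_int, dtype=int)
    meta_rows: list[tuple] = []
    first = True
    for chrom, gs, ge, strand, _cls, _fid in genes.itertuples(index=False):
        k = 0
        for seg, idx, off, s, e in _gene_intervals(gs, ge, strand, flank, body_window):
            if first:
                meta_rows.append((seg, idx, off))
            if s is not None and e > max(s, 0):
                level, total = _interval_level(arrays, chrom, max(s, 0), e)
                if total > 0:
                    sums[k] += level
                    counts[k] += 1
            k += 1
        first = False
    if not meta_rows:  # no genes at all: still emit the interval skeleton
        meta_rows = [(seg, idx, off) for seg, idx, off, _s, _e in _gene_intervals(0, 10**9, "+", flank, body_window)]
    with np.errstate(invalid="ignore"):
        levels = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    df = pd.DataFrame(meta_rows, columns=["segment", "index_in_segment", "offset"])
    df["level"] = levels
    df["n_genes"] = counts
    return MetaProfile(df=df, flank=flank, body_window=body_window)


def chromosome_ratio_profile(
    numerator: MethylomeTable,
    denominator: MethylomeTable,
    context: str = "CG",
    bin_size: int = 100_000,
    floor: float = 0.01,
    min_cov: int = DEFAULT_MIN_COV,
) -> pd.DataFrame:
    """Per-100-kb methylation ratio track (numerator / denominator levels).

    Returns a frame (chrom, start, end, level_num, level_den, ratio); the
    ratio is NaN where either level is undefined or the denominator is below
    ``floor``.
    """
    if numerator.genome_id != denominator.genome_id:
        raise ValidationError("genome_id mismatch between samples")
    grid = BinGrid(bin_size)
    num = bin_methylation(numerator, context, grid, min_cov)
    den = bin_methylation(denominator, context, grid, min_cov)
    merged = num.merge(den, on=["chrom", "start"], suffixes=("_num", "_den"), how="outer", sort=True)
    level_num = merged["level_num"].to_numpy()
    level_den = merged["level_den"].to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(
            np.isfinite(level_num) & np.isfinite(level_den) & (level_den >= floor),
            level_num / level_den,
            np.nan,
        )
    out = pd.DataFrame(
        {
            "chrom": merged["chrom"],
            "start": merged["start"],
            "end": merged["start"] + bin_size,
            "level_num": level_num,
            "level_den": level_den,
            "ratio": ratio,
        }
    )
    return out


def dmr_sample_matrix(
    dmrs: list[Dmr],
    tables: list[MethylomeTable],
    context: str = "CG",
    min_cov: int = DEFAULT_MIN_COV,
) -> pd.DataFrame:
    """Weighted methylation level of every sample over every DMR interval.

    Rows are DMRs (index ``chrom:start-end``, genomic order), columns are
    sample ids; a cell is NaN when the sample has no covered site in the
    DMR.  This is the input for restoration heatmaps.
    """
    index = [f"{d.chrom}:{d.start}-{d.end}" for d in dmrs]
    data = {}
    for t in tables:
        arrays = _covered_arrays(t, context, min_cov)
        col = [
            _interval_level(arrays, d.chrom, d.start, d.end)[0]
            for d in dmrs
        ]
        data[t.sample_id] = col
    return pd.DataFrame(data, index=index)
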