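"""DMR annotation against genomic features and set-overlap statistics.

The multi-set intersection test reproduces the exact distribution of the
size of the intersection of k subsets drawn independently and uniformly
without replacement from a common universe.  For k = 2 this is the
hypergeometric upper tail; for k > 2 the distribution is built by
conditioning on the running intersection: given the first j sets intersect
in m elements, intersecting with a new uniform subset of size s_j from a
universe of n leaves a Hypergeometric(n, m, s_j)-distributed count, so the
exact pmf is an iterated hypergeometric convolution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dmr import Dmr
from .io import FeatureSet, GeneList, ValidationError

FEATURE_PRIORITY = ("gene", "transposable_element")  # tie-break order


@dataclass(frozen=True)
class AnnotatedDmr:
    dmr: Dmr
    feature_class: str  # gene | transposable_element | intergenic
    overlapping_ids: tuple[str, ...]
    bp_overlap: dict  # class -> overlapped bp


@dataclass(frozen=True)
class IntersectionResult:
    labels: tuple[str, ...]
    set_sizes: tuple[int, ...]
    universe_size: int
    observed: int
    expected: float
    fold: float
    p_value: float


def _overlap_bp(start: int, end: int, f_start: np.ndarray, f_end: np.ndarray) -> np.ndarray:
    return np.maximum(0, np.minimum(end, f_end) - np.maximum(start, f_start))


def classify_dmrs(dmrs: list[Dmr], features: FeatureSet) -> list[AnnotatedDmr]:
    """Assign each DMR to the feature class with the largest bp overlap.

    Ties break gene > transposable_element; a DMR overlapping nothing is
    intergenic.  Overlap is computed by interval intersection, strand
    ignored.
    """
    by_class = {
        cls: {
            chrom: sub[["start", "end", "feature_id"]]
            for chrom, sub in features.by_class(cls).groupby("chrom")
        }
        for cls in FEATURE_PRIORITY
    }
    out = []
    for d in dmrs:
        bp: dict[str, int] = {}
        ids: list[str] = []
        for cls in FEATURE_PRIORITY:
            sub = by_class[cls].get(d.chrom)
            if sub is None:
                bp[cls] = 0
                continue
            ov = _overlap_bp(d.start, d.end, sub["start"].to_numpy(), sub["end"].to_numpy())
            bp[cls] = int(ov.sum())
            ids.extend(sub["feature_id"].to_numpy()[ov > 0])
        if all(v == 0 for v in bp.values()):
            cls_out = "intergenic"
        else:
            cls_out = max(FEATURE_PRIORITY, key=lambda c: (bp[c], -FEATURE_PRIORITY.index(c)))
        out.append(AnnotatedDmr(dmr=d, feature_class=cls_out, overlapping_ids=tuple(ids), bp_overlap=bp))
    return out


def annotation_to_frame(annotated: list[AnnotatedDmr]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": a.dmr.chrom,
                "start": a.dmr.start,
                "end": a.dmr.end,
                "context": a.dmr.context,
                "direction": a.dmr.direction,
                "feature_class": a.feature_class,
                "bp_gene": a.bp_overlap.get("gene", 0),
                "bp_te": a.bp_overlap.get("transposable_element", 0),
                "feature_ids": ",".join(a.overlapping_ids),
            }
            for a in annotated
        ]
    )


def genes_near_dmrs(dmrs: list[Dmr], features: FeatureSet, window: int = 1000) -> GeneList:
    """Genes overlapping or within ``window`` bp of any DMR.

    Distance is the gap between closest interval ends (0 when overlapping);
    strand is ignored.
    """
    if window < 0:
        raise ValidationError("window must be >= 0")
    genes = features.genes
    dmr_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for d in dmrs:
        dmr_by_chrom.setdefault(d.chrom, []).append((d.start, d.end))
    hits = []
    for chrom, sub in genes.groupby("chrom"):
        dlist = dmr_by_chrom.get(chrom)
        if not dlist:
            continue
        darr = np.array(dlist, dtype=int)
        for s, e, gid in sub[["start", "end", "feature_id"]].itertuples(index=False):
            gap = np.maximum(0, np.maximum(darr[:, 0] - e, s - darr[:, 1]))
            if (gap <= window).any():
                hits.append(gid)
    return GeneList(hits, label=f"genes_within_{window}bp_of_dmrs")


def intersect_gene_sets(list_a: GeneList, list_b: GeneList) -> GeneList:
    """Plain set intersection, labelled with both parents."""
    return GeneList(
        list_a.gene_ids & list_b.gene_ids,
        label=f"({list_a.label})&({list_b.label})",
    )


def _multiset_intersection_pmf(sizes: list[int], n: int) -> np.ndarray:
    """Exact pmf of |S_1 ∩ ... ∩ S_k| for independent uniform subsets.

    Returned array index t is P(X = t), t = 0..min(sizes).  Built by the
    hypergeometric recursion P(X_j = t) = Σ_m P(X_{j-1} = m)·h(t; n, m, s_j).
    """
    dist = np.zeros(sizes[0] + 1)
    dist[sizes[0]] = 1.0  # |S_1| is fixed
    for s_j in sizes[1:]:
        # the running intersection is bounded by the smallest set so far
        support_j = min(len(dist) - 1, s_j)
        new = np.zeros(support_j + 1)
        for m in np.flatnonzero(dist > 0):
            t_max = min(m, s_j)
            t = np.arange(0, t_max + 1)
            new[: t_max + 1] += dist[m] * stats.hypergeom.pmf(t, n, m, s_j)
        dist = new
    return dist


def multiset_exact_test(
    sets: list[GeneList] | list[set],
    universe_size: int,
    observed: int | None = None,
) -> IntersectionResult:
    """Exact upper-tail test for the intersection of k >= 2 sets.

    Under the null, each set is an independent uniform draw without
    replacement from a universe of ``universe_size`` elements.  The expected
    intersection size is n·Π(|S_i|/n) and the p-value is P(X >= observed)
    under the exact distribution (k = 2: closed-form hypergeometric tail).
    ``observed`` defaults to the actual intersection of the given sets.
    """
    if len(sets) < 2:
        raise ValidationError("need at least two sets")
    as_sets = [s.gene_ids if isinstance(s, GeneList) else frozenset(s) for s in sets]
    labels = tuple(
        s.label if isinstance(s, GeneList) else f"set_{i + 1}" for i, s in enumerate(sets)
    )
    sizes = [len(s) for s in as_sets]
    n = int(universe_size)
    if any(sz > n for sz in sizes):
        raise ValidationError("set larger than the universe")
    if observed is None:
        inter = frozenset.intersection(*as_sets)
        observed = len(inter)
    if observed > min(sizes):
        raise ValidationError("observed intersection exceeds the smallest set")
    expected = n * float(np.prod([sz / n for sz in sizes]))
    if len(sizes) == 2:
        # P(X >= obs) for X ~ Hypergeom(n, |A|, |B|)
        p = float(stats.hypergeom.sf(observed - 1, n, sizes[0], sizes[1]))
    else:
        pmf = _multiset_intersection_pmf(sizes, n)
        p = float(pmf[observed:].sum())
    p = min(max(p, 0.0), 1.0)
    if p == 0.0:
        p = float(np.finfo(float).tiny)
    fold = observed / expected if expected > 0 else float("inf")
    return IntersectionResult(
        labels=labels,
        set_sizes=tuple(sizes),
        universe_size=n,
        observed=int(observed),
        expected=expected,
        fold=fold,
        p_value=p,
    )
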