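"""Synthetic WGBS study generator with a planted-region truth registry.

Builds toy genomes and annotations, assigns per-cytosine true methylation
probabilities by context and genomic compartment, plants regional
epimutagenesis effects (demethylated 1-kb tiles in a treated generation),
models partial, stochastic restoration in the following generation, and
samples bisulfite read counts.  The planted-region registry is the ground
truth against which DMR recall and precision are measured.

The default configuration emulates a chemically epimutagenized Arabidopsis
population: an untreated control, a solvent control (both with replicates),
treated lines with strong genome-wide CG loss, non-suppressor lines with
near-control methylation, and third-generation sibling lines in which lost
CG methylation is partially and independently restored, so that epialleles
segregate between siblings.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import FeatureSet, MethylomeTable, ValidationError

GENERATIONS = ("control", "eM2", "eM3")

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class SimConfig:
    """Study-condition knobs for the simulator.

    ``base_levels`` maps context -> (mean level in genes, in TEs, intergenic).
    Baseline CG levels are high in every compartment so that a planted
    regional loss of magnitude ``|delta|`` produces a level difference of the
    same magnitude (the additive effect clips at 0); the simulator emulates
    the methylated fraction of a plant genome, where regional losses are
    observable, rather than genome-wide averages.

    ``treatment_prob`` is the per-1-kb-tile probability of a planted
    demethylation event and ``treatment_delta`` its additive effect on true
    CG methylation (negative = loss; positive values plant gains, used for
    ectopic-CHG scenarios).  ``restoration_prob`` is the per-planted-region
    probability that the next generation reverts to control levels.
    """

    n_chrom: int = 1
    chrom_length: int = 3_000_000
    gene_density: float = 10.0  # per 100 kb
    te_density: float = 5.0
    base_levels: dict = field(
        default_factory=lambda: {
            "CG": (0.80, 0.90, 0.70),
            "CHG": (0.05, 0.40, 0.05),
            "CHH": (0.02, 0.10, 0.02),
        }
    )
    jitter_concentration: float = 100.0
    region_size: int = 1000
    treatment_prob: float = 0.1
    treatment_delta: float = -0.6
    restoration_prob: float = 0.35
    mean_coverage: float = 20.0
    conversion_error: float = 0.005
    gc_content: float = 0.36
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("treatment_prob", "restoration_prob", "conversion_error"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        if not (-1.0 <= self.treatment_delta <= 1.0):
            raise ValidationError("treatment_delta must be in [-1, 1]")
        if self.chrom_length < 1000:
            raise ValidationError("chrom_length must be >= 1000")
        if self.mean_coverage <= 0:
            raise ValidationError("mean_coverage must be > 0")
        for ctx, levels in self.base_levels.items():
            if any(not (0.0 <= x <= 1.0) for x in levels):
                raise ValidationError(f"base level out of [0, 1] for {ctx}")


@dataclass
class TrueMethylome:
    """Per-cytosine true methylation probabilities for one generation."""

    df: pd.DataFrame  # chrom, pos, strand, context, p
    generation: str = "control"

    def __post_init__(self) -> None:
        if self.generation not in GENERATIONS:
            raise ValidationError(f"unknown generation {self.generation!r}")
        p = self.df["p"].to_numpy()
        if len(p) and (p.min() < 0 or p.max() > 1):
            raise ValidationError("true methylation probability outside [0, 1]")

    def copy(self, generation: str | None = None) -> "TrueMethylome":
        return TrueMethylome(self.df.copy(), generation or self.generation)


def _op_rng(config: SimConfig, tag: int, seed: int | None = None) -> np.random.Generator:
    """Deterministic per-operation generator derived from the config seed."""
    base = config.seed if seed is None else seed
    return np.random.default_rng([int(base) % (2**31), tag])


# ---------------------------------------------------------------------------
# genome and annotation
# ---------------------------------------------------------------------------


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(_BASES, size=length, p=p)


def _place_intervals(
    rng: np.random.Generator,
    length: int,
    n: int,
    len_range: tuple[int, int],
    occupied: list[tuple[int, int]],
    max_tries: int = 200,
) -> list[tuple[int, int]]:
    """Greedy non-overlapping placement; raises when the density is infeasible."""
    placed: list[tuple[int, int]] = []
    for _ in range(n):
        for _try in range(max_tries):
            flen = int(rng.integers(len_range[0], len_range[1] + 1))
            if flen >= length:
                continue
            start = int(rng.integers(0, length - flen))
            end = start + flen
            if all(end <= s or start >= e for s, e in occupied):
                placed.append((start, end))
                occupied.append((start, end))
                break
        else:
            raise ValidationError(
                "could not place features without overlap; lower the density"
            )
    return placed


def generate_genome_annotation(config: SimConfig) -> tuple[dict[str, str], FeatureSet]:
    """Random toy genome plus non-overlapping gene/TE annotation.

    Deterministic given ``config.seed``.  Gene lengths are 1.5-4 kb, TE
    lengths 0.5-3 kb, densities per 100 kb from the config.
    """
    rng = _op_rng(config, 1)
    sequences: dict[str, str] = {}
    rows = []
    for c in range(config.n_chrom):
        chrom = f"Chr{c + 1}"
        seq = _random_sequence(rng, config.chrom_length, config.gc_content)
        sequences[chrom] = seq.tobytes().decode("ascii")
        occupied: list[tuple[int, int]] = []
        n_genes = int(round(config.gene_density * config.chrom_length / 100_000))
        n_tes = int(round(config.te_density * config.chrom_length / 100_000))
        genes = _place_intervals(rng, config.chrom_length, n_genes, (1500, 4000), occupied)
        tes = _place_intervals(rng, config.chrom_length, n_tes, (500, 3000), occupied)
        for i, (s, e) in enumerate(sorted(genes)):
            strand = "+" if rng.random() < 0.5 else "-"
            rows.append((chrom, s, e, strand, "gene", f"{chrom}G{i + 1:04d}"))
        for i, (s, e) in enumerate(sorted(tes)):
            strand = "+" if rng.random() < 0.5 else "-"
            rows.append((chrom, s, e, strand, "transposable_element", f"{chrom}TE{i + 1:04d}"))
    features = FeatureSet(
        pd.DataFrame(rows, columns=["chrom", "start", "end", "strand", "feature_class", "feature_id"])
    )
    return sequences, features


def cytosine_sites(genome: dict[str, str]) -> pd.DataFrame:
    """Scan a genome for cytosines on both strands with trinucleotide context.

    Plus strand: a C at i is CG if base i+1 is G, CHG if i+2 is G, else CHH.
    Minus strand: a G at i is a cytosine on the reverse strand; CG if i-1 is
    C, CHG if i-2 is C, else CHH.  Chromosome-edge sites with a truncated
    trinucleotide are classified by the available bases (missing = H).
    """
    frames = []
    for chrom, seq in genome.items():
        arr = np.frombuffer(seq.encode("ascii"), dtype="S1")
        pad = np.concatenate([[b"N", b"N"], arr, [b"N", b"N"]])
        core = pad[2:-2]
        plus = np.flatnonzero(core == b"C")
        nxt1 = pad[plus + 3]
        nxt2 = pad[plus + 4]
        ctx_plus = np.where(nxt1 == b"G", "CG", np.where(nxt2 == b"G", "CHG", "CHH"))
        minus = np.flatnonzero(core == b"G")
        prv1 = pad[minus + 1]
        prv2 = pad[minus]
        ctx_minus = np.where(prv1 == b"C", "CG", np.where(prv2 == b"C", "CHG", "CHH"))
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": np.concatenate([plus, minus]),
                    "strand": np.repeat(["+", "-"], [len(plus), len(minus)]),
                    "context": np.concatenate([ctx_plus, ctx_minus]),
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["chrom", "pos", "strand"], kind="mergesort", ignore_index=True)


# ---------------------------------------------------------------------------
# true methylomes
# ---------------------------------------------------------------------------


def _compartment_labels(sites: pd.DataFrame, features: FeatureSet, chrom_length: dict[str, int]) -> np.ndarray:
    """0 = gene, 1 = TE, 2 = intergenic per site (features do not overlap)."""
    labels = np.full(len(sites), 2, dtype=np.int8)
    for chrom, sub in sites.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy()
        mask = np.zeros(chrom_length[chrom], dtype=np.int8) + 2
        for cls_idx, cls in enumerate(("gene", "transposable_element")):
            f = features.by_class(cls)
            f = f[f["chrom"] == chrom]
            for s, e in f[["start", "end"]].itertuples(index=False):
                mask[s:e] = cls_idx
        labels[sub.index.to_numpy()] = mask[pos]
    return labels


def generate_true_methylome(
    genome: dict[str, str], features: FeatureSet, config: SimConfig
) -> TrueMethylome:
    """Per-cytosine true methylation probabilities for the control generation.

    Each site's p is Beta-distributed around its context x compartment mean
    with concentration ``jitter_concentration`` (degenerate at 0 or 1), so a
    configured mean of 0 yields exactly 0 at every such site.
    """
    sites = cytosine_sites(genome)
    chrom_length = {c: len(s) for c, s in genome.items()}
    comp = _compartment_labels(sites, features, chrom_length)
    rng = _op_rng(config, 2)
    p = np.zeros(len(sites))
    kappa = config.jitter_concentration
    for ctx, levels in config.base_levels.items():
        for comp_idx in range(3):
            mask = (sites["context"].to_numpy() == ctx) & (comp == comp_idx)
            n = int(mask.sum())
            if n == 0:
                continue
            mean = levels[comp_idx]
            if mean <= 0.0:
                p[mask] = 0.0
            elif mean >= 1.0:
                p[mask] = 1.0
            else:
                p[mask] = rng.beta(mean * kappa, (1 - mean) * kappa, size=n)
    df = sites.copy()
    df["p"] = p
    return TrueMethylome(df, generation="control")


# ---------------------------------------------------------------------------
# epimutagenesis, restoration
# ---------------------------------------------------------------------------


def apply_epimutagenesis(
    truth: TrueMethylome,
    config: SimConfig,
    contexts: tuple[str, ...] = ("CG",),
    seed: int | None = None,
) -> tuple[TrueMethylome, pd.DataFrame]:
    """Plant regional methylation changes, returning the eM2 truth + registry.

    The genome is tiled into ``region_size``-bp regions; each region is
    independently affected with probability ``treatment_prob``, adding
    ``treatment_delta`` (clipped to [0, 1]) to the true p of every site of
    the given contexts inside it.  The registry frame (chrom, start, end,
    context, delta, generation) lists every affected region and is the truth
    standard for recall/precision.
    """
    if truth.generation != "control":
        raise ValidationError("epimutagenesis applies to the control generation")
    rng = _op_rng(config, 3, seed)
    df = truth.df.copy()
    registry_rows = []
    for chrom, sub in df.groupby("chrom", sort=True):
        length = int(sub["pos"].max()) + 1 if len(sub) else 0
        n_tiles = int(np.ceil(length / config.region_size))
        hit = rng.random(n_tiles) < config.treatment_prob
        if not hit.any():
            continue
        pos = sub["pos"].to_numpy()
        tile = pos // config.region_size
        in_hit = hit[tile]
        ctx_mask = sub["context"].isin(contexts).to_numpy()
        idx = sub.index.to_numpy()[in_hit & ctx_mask]
        df.loc[idx, "p"] = np.clip(df.loc[idx, "p"] + config.treatment_delta, 0.0, 1.0)
        for t in np.flatnonzero(hit):
            s = int(t * config.region_size)
            for ctx in contexts:
                registry_rows.append((chrom, s, s + config.region_size, ctx, config.treatment_delta, "eM2"))
    registry = pd.DataFrame(
        registry_rows, columns=["chrom", "start", "end", "context", "delta", "generation"]
    )
    return TrueMethylome(df, generation="eM2"), registry


def apply_restoration(
    em2_truth: TrueMethylome,
    control_truth: TrueMethylome,
    registry: pd.DataFrame,
    config: SimConfig,
    seed: int | None = None,
) -> tuple[TrueMethylome, pd.DataFrame]:
    """Independently revert planted regions to control levels (eM3 truth).

    Each registry region is restored with probability ``restoration_prob``:
    its sites' true p revert to the control values; unrestored regions keep
    eM2 values and unplanted sites are never touched.  Two calls with
    different seeds model sibling lines with segregating epialleles.

    Returns the eM3 truth and a copy of the registry with a boolean
    ``restored`` column recording the draw.
    """
    if len(em2_truth.df) != len(control_truth.df):
        raise ValidationError("eM2 and control truths cover different site sets")
    rng = _op_rng(config, 4, seed)
    df = em2_truth.df.copy()
    reg = registry.copy().reset_index(drop=True)
    restored = rng.random(len(reg)) < config.restoration_prob
    reg["restored"] = restored
    control_p = control_truth.df["p"].to_numpy()
    p_new = df["p"].to_numpy().copy()
    pos = df["pos"].to_numpy()
    ctx_arr = df["context"].to_numpy()
    # rows are sorted by (chrom, pos, strand): binary-search each region's slice
    chrom_bounds: dict[str, tuple[int, int]] = {}
    for chrom, sub in df.groupby("chrom", sort=False):
        chrom_bounds[chrom] = (int(sub.index[0]), int(sub.index[-1]) + 1)
    for row in reg[restored].itertuples(index=False):
        if row.chrom not in chrom_bounds:
            continue
        lo, hi = chrom_bounds[row.chrom]
        i0 = lo + np.searchsorted(pos[lo:hi], row.start, side="left")
        i1 = lo + np.searchsorted(pos[lo:hi], row.end, side="left")
        sel = slice(i0, i1)
        m = ctx_arr[sel] == row.context
        p_new[sel] = np.where(m, control_p[sel], p_new[sel])
    df["p"] = p_new
    return TrueMethylome(df, generation="eM3"), reg


# ---------------------------------------------------------------------------
# read counts
# ---------------------------------------------------------------------------


def simulate_wgbs_counts(
    truth: TrueMethylome,
    config: SimConfig,
    sample_id: str,
    seed: int | None = None,
    genome_id: str = "genome",
) -> MethylomeTable:
    """Sample bisulfite read counts from a true methylome.

    Coverage is Poisson(``mean_coverage``) per site; the methylated count is
    Binomial(coverage, p·(1−conversion_error)) — incomplete conversion thins
    methylated reads only.  Zero-coverage sites are retained in the table.
    """
    rng = _op_rng(config, 5, seed)
    df = truth.df
    n = len(df)
    cov = rng.poisson(config.mean_coverage, size=n)
    p_obs = df["p"].to_numpy() * (1.0 - config.conversion_error)
    count_m = rng.binomial(cov, p_obs)
    out = pd.DataFrame(
        {
            "chrom": df["chrom"].to_numpy(),
            "pos": df["pos"].to_numpy(),
            "strand": df["strand"].to_numpy(),
            "count_m": count_m,
            "count_u": cov - count_m,
            "context": df["context"].to_numpy(),
        }
    )
    return MethylomeTable(sample_id=sample_id, df=out, genome_id=genome_id)


# ---------------------------------------------------------------------------
# study assembly and truth-registry metrics
# ---------------------------------------------------------------------------


def simulate_study(
    config: SimConfig,
    n_suppressors: int = 2,
    n_nonsuppressors: int = 2,
    n_siblings: int = 2,
    nonsuppressor_prob: float = 0.005,
) -> dict:
    """Generate a full study: controls with replicates, treated lines, siblings.

    Emulates the deposited study structure: an untreated control (2
    replicates), a solvent control (2 replicates), treated suppressor lines
    with strong regional CG loss (one library each, independent planted
    registries), non-suppressor lines with near-control methylation, and,
    for the first suppressor, sibling eM3 lines with independent partial
    restoration.

    Returns a dict with genome, features, truths, registries and a
    ``samples`` mapping of sample_id -> MethylomeTable.
    """
    genome, features = generate_genome_annotation(config)
    control_truth = generate_true_methylome(genome, features, config)
    samples: dict[str, MethylomeTable] = {}
    for i, sid in enumerate(["untreated_1", "untreated_2", "solvent_1", "solvent_2"]):
        samples[sid] = simulate_wgbs_counts(control_truth, config, sid, seed=config.seed + 100 + i)
    registries: dict[str, pd.DataFrame] = {}
    truths: dict[str, TrueMethylome] = {"control": control_truth}
    for i in range(n_suppressors):
        sid = f"suppressor_{i + 1}"
        em2, reg = apply_epimutagenesis(control_truth, config, seed=config.seed + 200 + i)
        truths[sid] = em2
        registries[sid] = reg
        samples[sid] = simulate_wgbs_counts(em2, config, sid, seed=config.seed + 300 + i)
    weak = replace(config, treatment_prob=nonsuppressor_prob)
    for i in range(n_nonsuppressors):
        sid = f"nonsuppressor_{i + 1}"
        em2, reg = apply_epimutagenesis(control_truth, weak, seed=config.seed + 400 + i)
        registries[sid] = reg
        samples[sid] = simulate_wgbs_counts(em2, weak, sid, seed=config.seed + 500 + i)
    if n_suppressors >= 1:
        parent = truths["suppressor_1"]
        reg = registries["suppressor_1"]
        for i in range(n_siblings):
            sid = f"sibling_{i + 1}"
            em3, reg3 = apply_restoration(parent, control_truth, reg, config, seed=config.seed + 600 + i)
            truths[sid] = em3
            registries[sid] = reg3
            samples[sid] = simulate_wgbs_counts(em3, config, sid, seed=config.seed + 700 + i)
    return {
        "genome": genome,
        "features": features,
        "truths": truths,
        "registries": registries,
        "samples": samples,
    }


def registry_overlap_metrics(dmrs, registry: pd.DataFrame) -> dict:
    """Recall and precision of called DMRs against the planted registry.

    A planted region is recovered when >=1 DMR overlaps it; a DMR is a true
    positive when it overlaps >=1 planted region.
    """
    reg = registry
    n_regions = len(reg)
    n_dmrs = len(dmrs)
    recovered = 0
    tp = 0
    reg_by_chrom = {c: sub[["start", "end"]].to_numpy() for c, sub in reg.groupby("chrom")}
    dmr_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for d in dmrs:
        dmr_by_chrom.setdefault(d.chrom, []).append((d.start, d.end))
    for chrom, intervals in reg_by_chrom.items():
        dlist = np.array(dmr_by_chrom.get(chrom, []), dtype=int).reshape(-1, 2)
        for s, e in intervals:
            if len(dlist) and ((dlist[:, 0] < e) & (dlist[:, 1] > s)).any():
                recovered += 1
    for d in dmrs:
        rlist = reg_by_chrom.get(d.chrom)
        if rlist is not None and ((rlist[:, 0] < d.end) & (rlist[:, 1] > d.start)).any():
            tp += 1
    return {
        "n_planted": n_regions,
        "n_called": n_dmrs,
        "recall": recovered / n_regions if n_regions else float("nan"),
        "precision": tp / n_dmrs if n_dmrs else float("nan"),
    }
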