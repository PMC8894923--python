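"""Readers and writers for the formats the pipeline touches.

Per-cytosine bisulfite reports (the standard bismark cytosine/CX output),
GFF3 annotation, plain gene-identifier lists, and BED/bedGraph exports.

All coordinates are 0-based half-open internally.  The cytosine report's
1-based positions are converted on read (``pos_internal = pos - 1``) and
back on write; GFF3's 1-based inclusive intervals become ``[start-1, end)``.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

CONTEXTS = ("CG", "CHG", "CHH")
STRANDS = ("+", "-")

#: column order of the in-memory per-cytosine table
CYTOSINE_COLUMNS = ["chrom", "pos", "strand", "count_m", "count_u", "context"]


class ParseError(ValueError):
    """A malformed line in an input file; carries the offending line number."""


class ValidationError(ValueError):
    """Structurally valid input that violates a pipeline invariant."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class MethylomeTable:
    """Strand-resolved per-cytosine methylation counts for one library.

    ``df`` has columns chrom, pos (0-based), strand, count_m, count_u,
    context, sorted by (chrom, pos, strand) with no duplicate site keys.
    CG sites are *not* collapsed to symmetric dinucleotides; each strand's
    cytosine is an independent record.  Zero-coverage sites are retained
    (they matter for the unmethylated-control rule of ectopic-CHG calling)
    but never contribute to weighted levels.
    """

    sample_id: str
    df: pd.DataFrame
    genome_id: str = "genome"

    def __post_init__(self) -> None:
        self.df = _normalize_cytosine_frame(self.df)

    @property
    def n_sites(self) -> int:
        return len(self.df)

    def coverage(self) -> np.ndarray:
        return (self.df["count_m"] + self.df["count_u"]).to_numpy()

    def subset_context(self, context: str) -> pd.DataFrame:
        if context not in CONTEXTS:
            raise ValidationError(f"unknown context {context!r}")
        return self.df[self.df["context"] == context]


def _normalize_cytosine_frame(df: pd.DataFrame) -> pd.DataFrame:
    df = df[CYTOSINE_COLUMNS].copy()
    df = df.sort_values(["chrom", "pos", "strand"], kind="mergesort", ignore_index=True)
    if len(df):
        dup = df.duplicated(subset=["chrom", "pos", "strand"])
        if dup.any():
            first = df.loc[dup.idxmax()]
            raise ValidationError(
                f"duplicate site ({first['chrom']}, {first['pos'] + 1}, {first['strand']})"
            )
        if (df["count_m"] < 0).any() or (df["count_u"] < 0).any():
            raise ValidationError("negative read counts")
    return df


@dataclass
class FeatureSet:
    """Gene/TE intervals (0-based half-open) for annotation and metaplots."""

    df: pd.DataFrame  # chrom, start, end, strand, feature_class, feature_id

    FEATURE_CLASSES = ("gene", "transposable_element")

    def __post_init__(self) -> None:
        df = self.df[["chrom", "start", "end", "strand", "feature_class", "feature_id"]].copy()
        df = df.sort_values(["chrom", "start", "end"], kind="mergesort", ignore_index=True)
        if len(df):
            if (df["start"] >= df["end"]).any():
                raise ValidationError("feature with start >= end")
            for cls, sub in df.groupby("feature_class"):
                if sub["feature_id"].duplicated().any():
                    raise ValidationError(f"duplicate feature_id within class {cls!r}")
        self.df = df

    def by_class(self, feature_class: str) -> pd.DataFrame:
        return self.df[self.df["feature_class"] == feature_class]

    @property
    def genes(self) -> pd.DataFrame:
        return self.by_class("gene")

    @property
    def transposable_elements(self) -> pd.DataFrame:
        return self.by_class("transposable_element")


@dataclass
class GeneList:
    """A labelled set of gene identifiers (e.g. a DEG set)."""

    gene_ids: frozenset[str]
    label: str = ""

    def __init__(self, gene_ids: Iterable[str], label: str = "") -> None:
        self.gene_ids = frozenset(gene_ids)
        self.label = label

    def __len__(self) -> int:
        return len(self.gene_ids)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.gene_ids


# ---------------------------------------------------------------------------
# cytosine reports
# ---------------------------------------------------------------------------


def read_cytosine_report(path: str | Path, sample_id: str, genome_id: str = "genome") -> MethylomeTable:
    """Parse a bismark-style per-cytosine report into a :class:`MethylomeTable`.

    Expected columns (tab-separated): chrom, 1-based position, strand,
    methylated count, unmethylated count, context, with an optional seventh
    trinucleotide column that is ignored.  Rows are re-sorted if needed and
    zero-coverage rows are retained.
    """
    rows: list[tuple] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ParseError(f"{path}:{lineno}: expected >=6 tab-separated fields")
            chrom, pos_s, strand, m_s, u_s, context = parts[:6]
            if strand not in STRANDS:
                raise ParseError(f"{path}:{lineno}: unknown strand {strand!r}")
            if context not in CONTEXTS:
                raise ParseError(f"{path}:{lineno}: unknown context {context!r}")
            try:
                pos = int(pos_s)
                count_m = int(m_s)
                count_u = int(u_s)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer field ({exc})") from None
            if count_m < 0 or count_u < 0:
                raise ParseError(f"{path}:{lineno}: negative count")
            rows.append((chrom, pos - 1, strand, count_m, count_u, context))
    df = pd.DataFrame(rows, columns=CYTOSINE_COLUMNS)
    if not len(df):
        df = df.astype({"pos": int, "count_m": int, "count_u": int})
    return MethylomeTable(sample_id=sample_id, df=df, genome_id=genome_id)


def write_cytosine_report(table: MethylomeTable, path: str | Path) -> None:
    """Write a table back out as a 6-column cytosine report (1-based)."""
    df = table.df
    with open(path, "w") as fh:
        for chrom, pos, strand, m, u, ctx in df.itertuples(index=False):
            fh.write(f"{chrom}\t{pos + 1}\t{strand}\t{m}\t{u}\t{ctx}\n")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------


def read_gff3_features(
    path: str | Path,
    gene_types: set[str] = frozenset({"gene"}),
    te_types: set[str] = frozenset({"transposable_element"}),
) -> FeatureSet:
    """Extract gene and TE intervals from a GFF3 file.

    1-based inclusive GFF3 coordinates are converted to 0-based half-open.
    Feature class is assigned from the type sets; other types are skipped.
    The feature ID comes from the ``ID=`` attribute, falling back to
    ``Name=`` then a positional identifier.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ParseError(f"{path}:{lineno}: expected 9 GFF3 columns")
            chrom, _src, ftype, start_s, end_s, _score, strand, _phase, attrs = parts
            if ftype in gene_types:
                cls = "gene"
            elif ftype in te_types:
                cls = "transposable_element"
            else:
                continue
            try:
                start = int(start_s)
                end = int(end_s)
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from None
            if start < 1 or end < start:
                raise ParseError(f"{path}:{lineno}: invalid interval {start}..{end}")
            attr_map = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            fid = attr_map.get("ID") or attr_map.get("Name") or f"{ftype}:{chrom}:{start}"
            rows.append((chrom, start - 1, end, strand if strand in STRANDS else "+", cls, fid))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "strand", "feature_class", "feature_id"])
    return FeatureSet(df)


def write_gff3_features(features: FeatureSet, path: str | Path) -> None:
    """Write a FeatureSet as minimal GFF3 (back to 1-based inclusive)."""
    type_of = {"gene": "gene", "transposable_element": "transposable_element"}
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom, start, end, strand, cls, fid in features.df.itertuples(index=False):
            fh.write(
                f"{chrom}\tdmrkit\t{type_of[cls]}\t{start + 1}\t{end}\t.\t{strand}\t.\tID={fid}\n"
            )


# ---------------------------------------------------------------------------
# gene lists
# ---------------------------------------------------------------------------


def read_gene_list(path: str | Path, label: str | None = None) -> GeneList:
    """Read a one-gene-per-line identifier list; blank lines ignored."""
    ids = []
    with open(path) as fh:
        for line in fh:
            gid = line.strip()
            if gid:
                ids.append(gid)
    return GeneList(ids, label=label if label is not None else str(path))


def write_gene_list(genes: GeneList, path: str | Path) -> None:
    with open(path, "w") as fh:
        for gid in sorted(genes.gene_ids):
            fh.write(gid + "\n")


# ---------------------------------------------------------------------------
# BED / bedGraph
# ---------------------------------------------------------------------------


def write_dmr_bed(dmrs, path: str | Path, header: bool = False) -> None:
    """Write DMRs as BED6: name = ``context:direction``, score = 1000*|mean delta|.

    ``dmrs`` is a DmrList (see :mod:`dmrkit.dmr`) or any iterable of objects
    with chrom/start/end/context/direction/mean_delta attributes, pre-sorted.
    """
    with open(path, "w") as fh:
        if header:
            fh.write('track name="dmrkit DMRs"\n')
        for d in dmrs:
            score = int(round(1000 * abs(d.mean_delta)))
            fh.write(
                f"{d.chrom}\t{d.start}\t{d.end}\t{d.context}:{d.direction}\t{score}\t.\n"
            )


def read_bed_intervals(path: str | Path) -> pd.DataFrame:
    """Read BED (>=3 columns) into a frame: chrom, start, end [, name, score]."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: expected >=3 BED columns")
            row = {"chrom": parts[0], "start": int(parts[1]), "end": int(parts[2])}
            if len(parts) > 3:
                row["name"] = parts[3]
            if len(parts) > 4:
                row["score"] = float(parts[4])
            rows.append(row)
    return pd.DataFrame(rows)


def write_bedgraph(bins: pd.DataFrame, path: str | Path) -> None:
    """Write per-bin weighted levels as bedGraph, 4-decimal levels.

    ``bins`` is a BinMethylation frame (chrom, start, end, n_covered, level);
    bins with no covered cytosines are omitted.
    """
    covered = bins[bins["n_covered"] > 0]
    with open(path, "w") as fh:
        for chrom, start, end, level in covered[["chrom", "start", "end", "level"]].itertuples(index=False):
            fh.write(f"{chrom}\t{start}\t{end}\t{level:.4f}\n")


def read_bedgraph(path: str | Path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "#")):
                continue
            chrom, start, end, value = line.split("\t")
            rows.append((chrom, int(start), int(end), float(value)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "level"])


# ---------------------------------------------------------------------------
# FASTA (simulator output; sequences are small toy genomes)
# ---------------------------------------------------------------------------


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
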