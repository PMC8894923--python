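"""Per-DMR methylation restoration across generations and epiallele
segregation between sibling lines.

The restoration fraction of a DMR is the linear interpolation between the
progenitor's lost level and the control level:

    r = clip((m_eM3 - m_eM2) / (m_control - m_eM2), 0, 1)

so r = 1 when the third generation regained the control level and r = 0
when it kept the progenitor's level.  A DMR counts as *restored* when
r >= 0.8 (at least 80% of the lost methylation regained); the fraction is
undefined when the control-eM2 loss is below ``min_loss``.
"""

from __future__ import annotations

from dataclasses import dataclass

import math

import numpy as np
import pandas as pd

from .binning import DEFAULT_MIN_COV
from .dmr import Dmr
from .io import MethylomeTable, ValidationError
from .profiles import dmr_sample_matrix

DEFAULT_RESTORE_THRESHOLD = 0.8
DEFAULT_MIN_LOSS = 0.2

STATUSES = ("restored", "partial", "unrestored", "undefined")


@dataclass(frozen=True)
class RestorationRecord:
    dmr: Dmr
    level_control: float
    level_em2: float
    level_em3: float
    fraction: float  # NaN when undefined
    status: str

    @property
    def key(self) -> tuple[str, int, int]:
        return (self.dmr.chrom, self.dmr.start, self.dmr.end)


def restoration_fraction(
    level_control: float,
    level_em2: float,
    level_em3: float,
    min_loss: float = DEFAULT_MIN_LOSS,
) -> float:
    """Fraction of lost methylation regained in the third generation.

    NaN when any level is undefined or the control-eM2 loss magnitude is
    below ``min_loss`` (no meaningful loss to restore).
    """
    levels = (level_control, level_em2, level_em3)
    if any(not math.isfinite(x) for x in levels):
        return float("nan")
    if any(not (0.0 <= x <= 1.0) for x in levels):
        raise ValidationError("methylation levels must be in [0, 1]")
    loss = level_control - level_em2
    if abs(loss) < min_loss:
        return float("nan")
    return float(np.clip((level_em3 - level_em2) / loss, 0.0, 1.0))


def _status(r: float, restore_threshold: float, partial_floor: float = 0.2) -> str:
    if not math.isfinite(r):
        return "undefined"
    if r >= restore_threshold:
        return "restored"
    if r >= partial_floor:
        return "partial"
    return "unrestored"


def classify_restoration(
    dmrs: list[Dmr],
    control: MethylomeTable,
    em2: MethylomeTable,
    em3: MethylomeTable,
    context: str = "CG",
    restore_threshold: float = DEFAULT_RESTORE_THRESHOLD,
    min_loss: float = DEFAULT_MIN_LOSS,
    min_cov: int = DEFAULT_MIN_COV,
) -> tuple[list[RestorationRecord], dict]:
    """Per-DMR restoration records plus summary fractions.

    Levels are count-pooled weighted levels over each DMR interval (the
    heatmap semantics).  The summary gives, among records with a defined
    fraction, the share in each status and the restored fraction — the
    statistic reported per sibling line on real data.
    """
    cols = [control.sample_id, em2.sample_id, em3.sample_id]
    if len(set(cols)) != 3:
        raise ValidationError("control/eM2/eM3 tables must have distinct sample_ids")
    matrix = dmr_sample_matrix(dmrs, [control, em2, em3], context=context, min_cov=min_cov)
    records = []
    for d, (_idx, row) in zip(dmrs, matrix.iterrows()):
        lc, l2, l3 = (float(row[c]) for c in cols)
        r = restoration_fraction(lc, l2, l3, min_loss=min_loss)
        records.append(
            RestorationRecord(
                dmr=d,
                level_control=lc,
                level_em2=l2,
                level_em3=l3,
                fraction=r,
                status=_status(r, restore_threshold),
            )
        )
    defined = [rec for rec in records if rec.status != "undefined"]
    n_def = len(defined)
    summary = {
        "n_dmrs": len(records),
        "n_defined": n_def,
        "restored_fraction": (
            sum(rec.status == "restored" for rec in defined) / n_def if n_def else float("nan")
        ),
        "unrestored_fraction": (
            sum(rec.status == "unrestored" for rec in defined) / n_def if n_def else float("nan")
        ),
        "mean_fraction": (
            float(np.mean([rec.fraction for rec in defined])) if n_def else float("nan")
        ),
    }
    return records, summary


def records_to_frame(records: list[RestorationRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": rec.dmr.chrom,
                "start": rec.dmr.start,
                "end": rec.dmr.end,
                "context": rec.dmr.context,
                "level_control": rec.level_control,
                "level_em2": rec.level_em2,
                "level_em3": rec.level_em3,
                "restoration_fraction": rec.fraction,
                "status": rec.status,
            }
            for rec in records
        ]
    )


def compare_sibling_lines(
    records_a: list[RestorationRecord],
    records_b: list[RestorationRecord],
) -> pd.DataFrame:
    """Joint restoration status of two sibling lines over the same DMRs.

    A DMR *segregates* when the two siblings have defined but different
    statuses (restored in one line, not in the other), the epiallele
    behaviour visible as discordant regions on chromosome ratio tracks.
    Returns a frame with per-DMR statuses and a ``joint`` column in
    {concordant, segregating, undefined}.
    """
    if len(records_a) != len(records_b) or any(
        ra.key != rb.key for ra, rb in zip(records_a, records_b)
    ):
        raise ValidationError("sibling record collections cover different DMRs")
    rows = []
    for ra, rb in zip(records_a, records_b):
        if ra.status == "undefined" or rb.status == "undefined":
            joint = "undefined"
        elif (ra.status == "restored") == (rb.status == "restored"):
            joint = "concordant"
        else:
            joint = "segregating"
        rows.append(
            {
                "chrom": ra.dmr.chrom,
                "start": ra.dmr.start,
                "end": ra.dmr.end,
                "status_a": ra.status,
                "status_b": rb.status,
                "joint": joint,
            }
        )
    return pd.DataFrame(rows)


def segregating_fraction(joint: pd.DataFrame) -> float:
    defined = joint[joint["joint"] != "undefined"]
    if not len(defined):
        return float("nan")
    return float((defined["joint"] == "segregating").mean())
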