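"""Relative mitochondrial content from MTDR fluorescence, and normalization.

MitoTracker Deep Red (MTDR) fluorescence is read in duplicate per
homogenate at a fixed gain, on the same plate as all samples of a tissue.
Net signal is the duplicate mean minus the mean of the blank (dye + buffer
only) wells. Activity is normalized by this net signal; a sample whose net
fluorescence is not positive is excluded with a logged reason rather than
producing a meaningless ratio.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .activity import ActivityRecord
from .errors import JoinError, SchemaError

log = logging.getLogger(__name__)

EXCLUDE_NONPOSITIVE = "nonpositive_content"


@dataclass(frozen=True)
class MtdrReading:
    """Duplicate MTDR fluorescence readings plus the plate blank (a.u., gain 90)."""

    animal_id: str
    tissue: str
    fluor_values: tuple[float, ...]
    blank: float

    def __post_init__(self):
        vals = tuple(float(v) for v in self.fluor_values)
        if len(vals) < 1:
            raise ValueError("at least one fluorescence value required")
        if not all(math.isfinite(v) for v in vals):
            raise ValueError("fluorescence values must be finite")
        if not (math.isfinite(self.blank) and self.blank >= 0):
            raise ValueError("blank must be finite and >= 0")
        object.__setattr__(self, "fluor_values", vals)


@dataclass(frozen=True)
class NormalizedActivity:
    """An activity record joined to its mitochondrial-content estimate."""

    record: ActivityRecord
    mito_content: float  # net fluorescence, a.u.
    activity_norm: float | None  # mpH/min per fluorescence unit
    excluded_reason: str | None = None

    def __post_init__(self):
        if self.activity_norm is not None:
            if not self.mito_content > 0:
                raise ValueError("activity_norm requires mito_content > 0")
            if not math.isfinite(self.activity_norm):
                raise ValueError("activity_norm must be finite")


def net_fluorescence(reading: MtdrReading) -> float:
    """Net MTDR signal: mean of the duplicate readings minus the blank."""
    return float(np.mean(reading.fluor_values)) - reading.blank


def normalize_activity(
    record: ActivityRecord, reading: MtdrReading
) -> NormalizedActivity:
    """Normalize one sample's activity by its net MTDR fluorescence."""
    if (record.animal_id, record.tissue) != (reading.animal_id, reading.tissue):
        raise JoinError(
            f"activity ({record.animal_id}, {record.tissue}) does not match "
            f"MTDR reading ({reading.animal_id}, {reading.tissue})"
        )
    net = net_fluorescence(reading)
    if net <= 0:
        log.warning(
            "sample (%s, %s): net fluorescence %.4g <= 0, excluded",
            record.animal_id, record.tissue, net,
        )
        return NormalizedActivity(
            record=record,
            mito_content=net,
            activity_norm=None,
            excluded_reason=EXCLUDE_NONPOSITIVE,
        )
    return NormalizedActivity(
        record=record,
        mito_content=net,
        activity_norm=record.activity_raw / net,
    )


def normalize_table(
    records: Sequence[ActivityRecord], readings: Sequence[MtdrReading]
) -> list[NormalizedActivity]:
    """Join activity records with MTDR readings on (animal_id, tissue).

    Every record must match exactly one reading; anything unmatched on
    either side raises :class:`JoinError` (no silent drops).
    """
    by_key: dict[tuple[str, str], MtdrReading] = {}
    for r in readings:
        key = (r.animal_id, r.tissue)
        if key in by_key:
            raise JoinError(f"duplicate MTDR reading for sample {key}")
        by_key[key] = r
    out = []
    seen = set()
    for rec in records:
        key = (rec.animal_id, rec.tissue)
        if key not in by_key:
            raise JoinError(f"no MTDR reading for sample {key}")
        seen.add(key)
        out.append(normalize_activity(rec, by_key[key]))
    return out


MTDR_COLUMNS = ("animal_id", "tissue", "rep1", "rep2", "blank")


def read_mtdr_csv(path: str | Path) -> list[MtdrReading]:
    """Read an MTDR table (animal_id, tissue, rep1, rep2, blank).

    ``rep2`` may be empty for a single-replicate reading; ``blank`` is the
    plate-level blank already averaged over the blank wells.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in MTDR_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"MTDR table missing required column(s): {missing}")
    readings = []
    for _, row in df.iterrows():
        vals = [float(row["rep1"])]
        if pd.notna(row["rep2"]):
            vals.append(float(row["rep2"]))
        readings.append(
            MtdrReading(
                animal_id=str(row["animal_id"]),
                tissue=str(row["tissue"]),
                fluor_values=tuple(vals),
                blank=float(row["blank"]),
            )
        )
    return readings


def write_mtdr_csv(readings: Iterable[MtdrReading], path: str | Path) -> None:
    rows = []
    for r in readings:
        rows.append(
            {
                "animal_id": r.animal_id,
                "tissue": r.tissue,
                "rep1": r.fluor_values[0],
                "rep2": r.fluor_values[1] if len(r.fluor_values) > 1 else np.nan,
                "blank": r.blank,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


def normalized_to_frame(items: Iterable[NormalizedActivity]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "animal_id": n.record.animal_id,
                "tissue": n.record.tissue,
                "sex": n.record.sex,
                "age_group": n.record.age_group,
                "activity_raw": n.record.activity_raw,
                "mito_content": n.mito_content,
                "activity_norm": (
                    np.nan if n.activity_norm is None else n.activity_norm
                ),
                "excluded_reason": n.excluded_reason or "",
                "n_wells": n.record.n_wells,
                "qc_flags": ";".join(sorted(n.record.qc_flags)),
            }
            for n in items
        ]
    )
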