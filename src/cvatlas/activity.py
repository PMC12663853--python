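"""Per-well and per-sample Complex V hydrolytic activity.

Activity of one well is the difference between the mean AR of the three
time points after the ATP + FCCP injection (maximal hydrolysis) and the
mean AR of the three time points after oligomycin (non-Complex-V
acidification). Technical replicate wells of one biological sample are
combined by the arithmetic mean; negative activities are retained and
flagged, never clamped.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import GroupingError, MissingPhaseError
from .plate import InjectionSchedule, KineticTrace, WellMeta, segment_phases

log = logging.getLogger(__name__)

FLAG_NEGATIVE = "negative_activity"
FLAG_MISSING_REPLICATE = "missing_replicate"
FLAG_NONFINITE = "nonfinite_excluded"

#: Study design: each biological sample is measured in triplicate.
DESIGN_REPLICATES = 3


@dataclass(frozen=True)
class ActivityRecord:
    """Raw (pre-normalization) activity of one biological sample."""

    animal_id: str
    tissue: str
    sex: str
    age_group: str
    activity_raw: float  # mpH/min
    n_wells: int
    qc_flags: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self):
        if self.n_wells < 1:
            raise ValueError("n_wells must be >= 1")
        if not math.isfinite(self.activity_raw):
            raise ValueError("activity_raw must be finite")
        if (self.activity_raw < 0) != (FLAG_NEGATIVE in self.qc_flags):
            raise ValueError("negative_activity flag inconsistent with value")


def phase_mean(segmented: Mapping[str, np.ndarray], phase: str) -> float:
    """Arithmetic mean AR of a phase's finite measurements.

    Raises :class:`MissingPhaseError` when the phase is absent or has no
    finite values (non-finite points are excluded, not imputed).
    """
    if phase not in segmented:
        raise MissingPhaseError(f"phase {phase!r} absent from segmented trace")
    values = np.asarray(segmented[phase], dtype=float)
    finite = values[np.isfinite(values)]
    if finite.size == 0:
        raise MissingPhaseError(f"phase {phase!r} has no finite measurements")
    return float(finite.mean())


def well_activity(trace: KineticTrace, schedule: InjectionSchedule) -> float:
    """Complex V activity of one well: mean(atp_fccp) - mean(oligomycin).

    May be negative; the sign is preserved and flagged downstream.
    """
    seg = segment_phases(trace, schedule)
    return phase_mean(seg, "atp_fccp") - phase_mean(seg, "oligomycin")


def aggregate_replicates(
    wells: Iterable[tuple[WellMeta, float]],
    design_replicates: int = DESIGN_REPLICATES,
) -> list[ActivityRecord]:
    """Combine technical replicate wells into per-sample activity records.

    Wells are grouped by the biological sample key (animal_id, tissue);
    ``activity_raw`` is the mean of the finite well activities. Non-finite
    well activities are excluded and flagged; a sample with fewer than
    ``design_replicates`` contributing wells gets a ``missing_replicate``
    flag; a sample with no finite wells is dropped with a logged warning.
    """
    groups: dict[tuple[str, str], list[tuple[WellMeta, float]]] = {}
    for meta, act in wells:
        groups.setdefault(meta.sample_key, []).append((meta, float(act)))

    records = []
    for (animal_id, tissue), members in groups.items():
        metas = [m for m, _ in members]
        if len({(m.sex, m.age_group) for m in metas}) > 1:
            raise GroupingError(
                f"sample ({animal_id!r}, {tissue!r}): inconsistent sex/age metadata"
            )
        reps = [m.replicate_index for m in metas]
        if len(set(reps)) != len(reps):
            raise GroupingError(
                f"sample ({animal_id!r}, {tissue!r}): duplicate replicate_index"
            )
        acts = np.array([a for _, a in members], dtype=float)
        finite = acts[np.isfinite(acts)]
        flags = set()
        if finite.size < acts.size:
            flags.add(FLAG_NONFINITE)
        if finite.size == 0:
            log.warning(
                "sample (%s, %s): no finite well activities, dropped",
                animal_id, tissue,
            )
            continue
        if finite.size < design_replicates:
            flags.add(FLAG_MISSING_REPLICATE)
        mean_act = float(finite.mean())
        if mean_act < 0:
            flags.add(FLAG_NEGATIVE)
        records.append(
            ActivityRecord(
                animal_id=animal_id,
                tissue=tissue,
                sex=metas[0].sex,
                age_group=metas[0].age_group,
                activity_raw=mean_act,
                n_wells=int(finite.size),
                qc_flags=frozenset(flags),
            )
        )
    return records


def quantify_plate(
    traces: Iterable[KineticTrace], schedule: InjectionSchedule
) -> list[ActivityRecord]:
    """Plate traces -> per-sample activity records (segment, difference, pool)."""
    wells = []
    for t in traces:
        try:
            wells.append((t.meta, well_activity(t, schedule)))
        except MissingPhaseError:
            # a fully non-finite phase makes the well unusable
            wells.append((t.meta, float("nan")))
    return aggregate_replicates(wells)


def records_to_frame(records: Iterable[ActivityRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "animal_id": r.animal_id,
                "tissue": r.tissue,
                "sex": r.sex,
                "age_group": r.age_group,
                "activity_raw": r.activity_raw,
                "n_wells": r.n_wells,
                "qc_flags": ";".join(sorted(r.qc_flags)),
            }
            for r in records
        ]
    )
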