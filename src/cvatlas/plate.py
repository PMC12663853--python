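"""Data model and I/O for plate-based Complex V kinetic assays.

A well's readout is a short acidification-rate (AR, mpH/min) time series
partitioned into four injection phases:

1. ``baseline`` — untreated homogenate;
2. ``rot_aa`` — after rotenone + antimycin A block the electron transport
   chain (no forward ATP synthase rotation possible);
3. ``atp_fccp`` — after ATP + FCCP drive maximal ATP hydrolysis, whose
   proton release acidifies the medium;
4. ``oligomycin`` — after oligomycin inhibits ATP synthase, leaving only
   non-Complex-V acidification.

Phases are assigned purely by position from the :class:`InjectionSchedule`
(never by timestamps). Measurement indices are 1-based in files and 0-based
internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import SchemaError, ScheduleMismatchError, UnknownTissueError
from .tissues import ALL_TISSUES

PHASES: tuple[str, str, str, str] = ("baseline", "rot_aa", "atp_fccp", "oligomycin")

#: Metadata columns required in every plate export.
META_COLUMNS: tuple[str, ...] = (
    "well_id",
    "tissue",
    "animal_id",
    "sex",
    "age_group",
    "protein_ug",
    "replicate_index",
)

SEXES = ("male", "female")
AGE_GROUPS = ("young", "old")


@dataclass(frozen=True)
class InjectionSchedule:
    """Fixed four-phase injection layout of the assay.

    Parameters
    ----------
    measurements_per_phase
        Number of AR time points recorded in each phase, in the fixed
        phase order. An ``int`` applies the same count to all four phases;
        the protocol default is 3 per phase (12 measurements per well).
    """

    measurements_per_phase: tuple[int, int, int, int] = (3, 3, 3, 3)

    def __post_init__(self):
        counts = self.measurements_per_phase
        if isinstance(counts, int):
            counts = (counts,) * 4
        counts = tuple(int(c) for c in counts)
        if len(counts) != 4:
            raise ValueError("a schedule has exactly four phases")
        if any(c < 1 for c in counts):
            raise ValueError("every phase needs at least one measurement")
        object.__setattr__(self, "measurements_per_phase", counts)

    @property
    def phase_names(self) -> tuple[str, str, str, str]:
        return PHASES

    @property
    def total_measurements(self) -> int:
        return sum(self.measurements_per_phase)

    def phase_slices(self) -> dict[str, slice]:
        """0-based contiguous index block for each phase, in order."""
        out, start = {}, 0
        for name, count in zip(PHASES, self.measurements_per_phase):
            out[name] = slice(start, start + count)
            start += count
        return out

    def phase_of(self, index: int) -> str:
        """Phase label of a 0-based measurement index."""
        if not 0 <= index < self.total_measurements:
            raise IndexError(f"measurement index {index} outside schedule")
        for name, sl in self.phase_slices().items():
            if sl.start <= index < sl.stop:
                return name
        raise AssertionError("unreachable")


@dataclass(frozen=True)
class WellMeta:
    """Identity and loading of one assay well."""

    well_id: str
    tissue: str
    animal_id: str
    sex: str
    age_group: str
    protein_ug: float
    replicate_index: int = 1

    def __post_init__(self):
        for name in ("well_id", "tissue", "animal_id", "sex", "age_group"):
            if not str(getattr(self, name)):
                raise ValueError(f"{name} must be non-empty")
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if self.age_group not in AGE_GROUPS:
            raise ValueError(
                f"age_group must be one of {AGE_GROUPS}, got {self.age_group!r}"
            )
        if not self.protein_ug > 0:
            raise ValueError("protein_ug must be positive")
        if int(self.replicate_index) < 1:
            raise ValueError("replicate_index must be >= 1")

    @property
    def sample_key(self) -> tuple[str, str]:
        """(animal_id, tissue) identifies a biological sample."""
        return (self.animal_id, self.tissue)


@dataclass(frozen=True)
class KineticTrace:
    """One well's AR series, validated against a schedule at construction."""

    meta: WellMeta
    ar_values: tuple[float, ...]

    def __post_init__(self):
        object.__setattr__(
            self, "ar_values", tuple(float(v) for v in self.ar_values)
        )

    @property
    def has_nonfinite(self) -> bool:
        return any(not math.isfinite(v) for v in self.ar_values)

    def validate(self, schedule: InjectionSchedule) -> None:
        if len(self.ar_values) != schedule.total_measurements:
            raise ScheduleMismatchError(
                f"well {self.meta.well_id!r}: {len(self.ar_values)} measurements, "
                f"schedule expects {schedule.total_measurements}"
            )


def segment_phases(
    trace: KineticTrace, schedule: InjectionSchedule
) -> dict[str, np.ndarray]:
    """Partition a trace's AR values into contiguous per-phase blocks.

    The concatenation of the returned blocks, in schedule order,
    reproduces ``trace.ar_values`` exactly.
    """
    trace.validate(schedule)
    values = np.asarray(trace.ar_values, dtype=float)
    return {name: values[sl] for name, sl in schedule.phase_slices().items()}


# ---------------------------------------------------------------------------
# Assay configuration (reagents + per-tissue protein loading)
# ---------------------------------------------------------------------------

#: Protein loaded per well (ug), by tissue — the published per-tissue loadings.
DEFAULT_PROTEIN_UG: dict[str, float] = {
    "BAT": 2,
    "gWAT": 15,
    "iWAT": 15,
    "Cerebellum": 6,
    "Cortex": 6,
    "Hippocampus": 6,
    "Hypothalamus": 6,
    "Eye": 10,
    "Cecum": 10,
    "Distal colon": 10,
    "Proximal colon": 10,
    "Duodenum": 10,
    "Ileum": 10,
    "Jejunum": 10,
    "Heart atrium": 2,
    "Heart ventricle": 2,
    "Kidney cortex": 6,
    "Kidney medulla": 6,
    "Liver": 8,
    "Lung": 10,
    "Pancreas": 8,
    "Fallopian tubes": 10,
    "Testes": 8,
    "Diaphragm": 10,
    "Gastrocnemius": 10,
    "Hamstring": 8,
    "Plantaris": 10,
    "Quadriceps": 10,
    "Soleus": 8,
    "Tongue": 8,
    "Skin": 10,
    "Spleen": 8,
    "Stomach": 8,
}


@dataclass(frozen=True)
class AssayConfig:
    """Reagent concentrations and per-tissue protein loading.

    Defaults are the published protocol values: 4 uM rotenone, 4 uM
    antimycin A, 20 mM ATP, 7.87 mM FCCP, 10 uM oligomycin, and 1 uM
    ouabain (in the assay medium, to suppress V-type ATPase interference).
    """

    rotenone_um: float = 4.0
    antimycin_a_um: float = 4.0
    atp_mm: float = 20.0
    fccp_mm: float = 7.87
    oligomycin_um: float = 10.0
    ouabain_um: float = 1.0
    protein_ug_by_tissue: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PROTEIN_UG)
    )

    def __post_init__(self):
        unknown = set(self.protein_ug_by_tissue) - set(ALL_TISSUES)
        if unknown:
            raise UnknownTissueError(
                f"unknown tissue(s) in protein loading map: {sorted(unknown)}"
            )
        missing = set(ALL_TISSUES) - set(self.protein_ug_by_tissue)
        if missing:
            raise ValueError(f"protein loading missing for: {sorted(missing)}")


def load_assay_config(path: str | Path | None = None) -> AssayConfig:
    """Load an :class:`AssayConfig` from a YAML file of overrides.

    The file may contain ``reagents:`` (keys matching the reagent field
    names) and ``protein_ug_by_tissue:`` (tissue -> ug) sections; anything
    absent keeps its protocol default. ``path=None`` returns pure defaults.
    Tissue names not in the atlas set are rejected.
    """
    config = AssayConfig()
    if path is None:
        return config
    raw = yaml.safe_load(Path(path).read_text()) or {}
    reagents = raw.get("reagents", {}) or {}
    valid = {
        "rotenone_um", "antimycin_a_um", "atp_mm",
        "fccp_mm", "oligomycin_um", "ouabain_um",
    }
    unknown = set(reagents) - valid
    if unknown:
        raise SchemaError(f"unknown reagent key(s): {sorted(unknown)}")
    overrides = raw.get("protein_ug_by_tissue", {}) or {}
    unknown_tissues = set(overrides) - set(ALL_TISSUES)
    if unknown_tissues:
        raise UnknownTissueError(
            f"unknown tissue(s) in config: {sorted(unknown_tissues)}"
        )
    loading = dict(DEFAULT_PROTEIN_UG)
    loading.update({t: float(v) for t, v in overrides.items()})
    return replace(
        config,
        **{k: float(v) for k, v in reagents.items()},
        protein_ug_by_tissue=loading,
    )


# ---------------------------------------------------------------------------
# Plate CSV I/O
# ---------------------------------------------------------------------------


def _meta_from_row(row: pd.Series) -> WellMeta:
    return WellMeta(
        well_id=str(row["well_id"]),
        tissue=str(row["tissue"]),
        animal_id=str(row["animal_id"]),
        sex=str(row["sex"]),
        age_group=str(row["age_group"]),
        protein_ug=float(row["protein_ug"]),
        replicate_index=int(row["replicate_index"]),
    )


def read_plate_export(
    path: str | Path, schedule: InjectionSchedule
) -> list[KineticTrace]:
    """Read a plate export into validated :class:`KineticTrace` objects.

    Two dialects are auto-detected from the header:

    * **long** (canonical): one row per (well, measurement) with columns
      ``measurement_index`` (1-based) and ``ar``, plus the metadata columns;
    * **wide**: one row per well with columns ``ar_1`` ... ``ar_N``.

    An optional ``phase`` column is ignored for segmentation (phases come
    from the schedule, by position). Wells whose measurement count does not
    match the schedule raise :class:`ScheduleMismatchError` naming every
    offending well — they are never silently dropped.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in META_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"plate export missing required column(s): {missing}")

    wide_cols = sorted(
        (c for c in df.columns if c.startswith("ar_") and c[3:].isdigit()),
        key=lambda c: int(c[3:]),
    )
    if {"measurement_index", "ar"} <= set(df.columns):
        traces = _read_long(df, schedule)
    elif wide_cols:
        traces = _read_wide(df, wide_cols)
    else:
        raise SchemaError(
            "plate export is neither long (measurement_index + ar columns) "
            "nor wide (ar_1..ar_N columns)"
        )

    bad = [
        t.meta.well_id
        for t in traces
        if len(t.ar_values) != schedule.total_measurements
    ]
    if bad:
        raise ScheduleMismatchError(
            f"wells with measurement count != {schedule.total_measurements}: {bad}"
        )
    return traces


def _read_long(df: pd.DataFrame, schedule: InjectionSchedule) -> list[KineticTrace]:
    traces = []
    for well_id, grp in df.groupby("well_id", sort=False):
        grp = grp.sort_values("measurement_index")
        idx = grp["measurement_index"].to_numpy()
        if list(idx) != list(range(1, len(idx) + 1)):
            raise ScheduleMismatchError(
                f"well {well_id!r}: measurement_index must be 1..n without gaps"
            )
        traces.append(
            KineticTrace(
                meta=_meta_from_row(grp.iloc[0]),
                ar_values=tuple(grp["ar"].astype(float)),
            )
        )
    return traces


def _read_wide(df: pd.DataFrame, wide_cols: list[str]) -> list[KineticTrace]:
    return [
        KineticTrace(
            meta=_meta_from_row(row),
            ar_values=tuple(float(row[c]) for c in wide_cols),
        )
        for _, row in df.iterrows()
    ]


def traces_to_frame(traces: Iterable[KineticTrace]) -> pd.DataFrame:
    """Long-format canonical frame for a trace collection."""
    rows = []
    for t in traces:
        m = t.meta
        for i, v in enumerate(t.ar_values, start=1):
            rows.append(
                {
                    "well_id": m.well_id,
                    "tissue": m.tissue,
                    "animal_id": m.animal_id,
                    "sex": m.sex,
                    "age_group": m.age_group,
                    "protein_ug": m.protein_ug,
                    "replicate_index": m.replicate_index,
                    "measurement_index": i,
                    "ar": v,
                }
            )
    return pd.DataFrame(rows)


def write_plate_csv(traces: Sequence[KineticTrace], path: str | Path) -> None:
    """Write traces in the canonical long CSV dialect (round-trip safe)."""
    traces_to_frame(traces).to_csv(path, index=False, float_format="%.17g")
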