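"""Synthetic inputs with known ground truth for every pipeline stage.

The generator emulates the statistical structure of the study's three raw
input kinds — plate-reader kinetic exports, MTDR fluorescence tables, and
TPM expression matrices — with a fully serializable ground truth, so the
whole pipeline is testable without any instrument data. It is a testing
instrument: the default activity table carries illustrative tissue levels
and effect directions, not measured values.

Trace shape per well (additive Gaussian noise on every measurement):

* baseline phase      ~ ``baseline_ar``
* rot/AA phase        ~ ``baseline_ar - rotaa_drop``
* ATP+FCCP phase      ~ rot/AA level + activity_raw + ``noncv_residual``
* oligomycin phase    ~ rot/AA level + ``noncv_residual``

where ``activity_raw = true_norm_activity[tissue, group] *
true_mito_content[tissue, animal]``, so the well-activity difference
recovers activity x content, and MTDR normalization recovers the true
normalized activity (exactly, up to float round-off, at zero noise).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .expression import ExpressionPanel, GenePanel
from .plate import DEFAULT_PROTEIN_UG, InjectionSchedule, KineticTrace, WellMeta
from .mito import MtdrReading
from .stats import GROUPS
from .tissues import ALL_TISSUES, SEX_SPECIFIC_TISSUES, tissues_for_sex


@dataclass(frozen=True)
class AtlasDesign:
    """Study layout: which tissues, how many animals, wells, time points."""

    tissues: tuple[str, ...] = ALL_TISSUES
    groups: tuple[str, ...] = GROUPS
    n_per_group: int = 10
    replicates_per_sample: int = 3
    measurements_per_phase: int = 3

    def __post_init__(self):
        if min(self.n_per_group, self.replicates_per_sample,
               self.measurements_per_phase) < 1:
            raise ValueError("design counts must be positive")

    @property
    def schedule(self) -> InjectionSchedule:
        return InjectionSchedule((self.measurements_per_phase,) * 4)

    def animals(self, group: str) -> list[str]:
        return [f"{group}{i:02d}" for i in range(1, self.n_per_group + 1)]

    def group_sex(self, group: str) -> str:
        return "male" if group.endswith("M") else "female"

    def group_age(self, group: str) -> str:
        return "young" if group.startswith("Y") else "old"

    def tissues_for_group(self, group: str) -> list[str]:
        allowed = set(tissues_for_sex(self.group_sex(group)))
        return [t for t in self.tissues if t not in SEX_SPECIFIC_TISSUES
                or t in allowed]


# Illustrative young-male activity levels (mpH/min per fluorescence unit),
# high in contractile organs, low in gut/skin/pancreas/gWAT. Signs of the
# age and sex factors below follow the described direction changes; the
# numbers themselves are invented. Values are chosen so that every group's
# tissue means stay pairwise distinct after the factors are applied,
# keeping the true within-group ranking well-defined.
_BASE_ACTIVITY_YM: dict[str, float] = {
    "Tongue": 10.2, "Quadriceps": 9.5, "iWAT": 9.0, "Heart atrium": 8.5,
    "Hamstring": 8.0, "Heart ventricle": 7.0, "Diaphragm": 6.5,
    "Gastrocnemius": 6.0, "Plantaris": 5.5, "Cerebellum": 5.0,
    "Hippocampus": 4.8, "Hypothalamus": 4.6, "Cortex": 4.5, "Liver": 4.2,
    "Lung": 4.0, "Kidney cortex": 3.8, "Kidney medulla": 3.6, "Soleus": 3.5,
    "Eye": 3.05, "Spleen": 2.95, "Testes": 3.1, "Fallopian tubes": 3.1,
    "Stomach": 2.8, "Duodenum": 2.6, "Cecum": 2.5, "Proximal colon": 2.3,
    "BAT": 2.2, "Distal colon": 2.0, "Ileum": 1.85, "Jejunum": 1.6,
    "Pancreas": 1.5, "Skin": 1.3, "gWAT": 1.2,
}
_ACTIVITY_SCALE = 1e-3  # to normalized units given content ~ 1000 a.u.

_MALE_AGE_UP = ("Heart atrium", "Diaphragm", "Cecum", "Ileum", "gWAT")
_MALE_AGE_DOWN = ("Tongue", "Gastrocnemius", "Kidney cortex")
_FEMALE_AGE_UP = ("Diaphragm", "Ileum")
_FEMALE_AGE_DOWN = ("iWAT", "gWAT", "Liver", "Spleen", "Distal colon",
                    "Skin", "Fallopian tubes")
_YOUNG_FEMALE_UP = ("Skin", "gWAT", "Pancreas", "Heart atrium", "Spleen")
_YOUNG_FEMALE_DOWN = ("Tongue", "Cortex")
# Shared (both-sex) aging responses: a handful of shared increases and a
# larger block of moderate shared declines, so age touches far more
# tissues than sex does; shared factors cancel in old-male-vs-old-female.
_SHARED_AGE_UP = ("Lung", "Quadriceps")
_SHARED_AGE_DOWN = ("Eye", "Stomach", "Duodenum", "Jejunum", "Proximal colon",
                    "Cerebellum", "Hippocampus", "Hypothalamus", "Plantaris",
                    "Soleus")


@dataclass(frozen=True)
class GroundTruth:
    """Everything the generator needs, fully serializable."""

    true_norm_activity: pd.DataFrame  # tissues x groups
    true_mito_content: pd.DataFrame  # tissues x animal_ids, positive
    baseline_ar: float = 8.0
    rotaa_drop: float = 3.0
    noncv_residual: float = 1.0
    noise_sd_ar: float = 0.0  # absolute AR noise sd (mpH/min)
    noise_cv_ar: float = 0.0  # AR noise sd as a fraction of the well's signal
    noise_sd_fluor: float = 0.0
    blank_level: float = 500.0
    n_blank_wells: int = 4
    rng_seed: int = 0

    def __post_init__(self):
        if (self.true_norm_activity.to_numpy() < 0).any():
            raise ValueError("true activities must be nonnegative")
        if (self.true_mito_content.to_numpy() <= 0).any():
            raise ValueError("true mito content must be positive")
        for f in ("noise_sd_ar", "noise_cv_ar", "noise_sd_fluor"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be >= 0")

    def activity(self, tissue: str, group: str) -> float:
        return float(self.true_norm_activity.loc[tissue, group])

    def content(self, tissue: str, animal_id: str) -> float:
        return float(self.true_mito_content.loc[tissue, animal_id])

    def true_log2fc(self, sex: str) -> dict[str, float]:
        """True per-tissue log2(old/young) for one sex."""
        young, old = ("YM", "OM") if sex == "male" else ("YF", "OF")
        out = {}
        for tissue in self.true_norm_activity.index:
            if SEX_SPECIFIC_TISSUES.get(tissue, sex) != sex:
                continue
            y, o = self.activity(tissue, young), self.activity(tissue, old)
            if y > 0 and o > 0:
                out[tissue] = float(np.log2(o / y))
        return out

    def to_json(self, path: str | Path) -> None:
        payload = {
            "true_norm_activity": self.true_norm_activity.to_dict(),
            "true_mito_content": self.true_mito_content.to_dict(),
            **{
                f: getattr(self, f)
                for f in ("baseline_ar", "rotaa_drop", "noncv_residual",
                          "noise_sd_ar", "noise_cv_ar", "noise_sd_fluor",
                          "blank_level", "n_blank_wells", "rng_seed")
            },
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            true_norm_activity=pd.DataFrame(payload.pop("true_norm_activity")),
            true_mito_content=pd.DataFrame(payload.pop("true_mito_content")),
            **payload,
        )


def _content_table(design: AtlasDesign, rng: np.random.Generator) -> pd.DataFrame:
    """Per-(tissue, animal) mitochondrial content, lognormal around 1000 a.u."""
    animals = [a for g in design.groups for a in design.animals(g)]
    tissue_level = 1000.0 * np.exp(rng.normal(0.0, 0.25, size=len(design.tissues)))
    content = tissue_level[:, None] * np.exp(
        rng.normal(0.0, 0.10, size=(len(design.tissues), len(animals)))
    )
    return pd.DataFrame(content, index=list(design.tissues), columns=animals)


def default_ground_truth(
    design: AtlasDesign | None = None,
    seed: int = 0,
    noise_sd_ar: float = 0.0,
    noise_cv_ar: float = 0.0,
    noise_sd_fluor: float = 0.0,
) -> GroundTruth:
    """Illustrative ground truth whose effect *directions* mirror the
    described atlas patterns: more age- than sex-affected tissues, male
    age increases in heart atrium/diaphragm/cecum/ileum/gWAT, female age
    decreases in fat depots/liver/spleen/distal colon/skin/fallopian
    tubes, shared age increases in diaphragm and ileum, etc."""
    design = design or AtlasDesign()
    rng = np.random.default_rng(seed)
    act = pd.DataFrame(index=list(design.tissues), columns=list(GROUPS), dtype=float)
    for tissue in design.tissues:
        ym = _BASE_ACTIVITY_YM.get(tissue, 3.0) * _ACTIVITY_SCALE
        yf = ym
        if tissue in _YOUNG_FEMALE_UP:
            yf = ym * 1.5
        elif tissue in _YOUNG_FEMALE_DOWN:
            yf = ym * 0.7
        om = ym
        if tissue in _MALE_AGE_UP:
            om = ym * 1.5
        elif tissue in _MALE_AGE_DOWN:
            om = ym * 0.65
        of = yf
        if tissue in _FEMALE_AGE_UP:
            of = yf * 1.5
        elif tissue in _FEMALE_AGE_DOWN:
            of = yf * 0.6
        if tissue in _SHARED_AGE_UP:
            om, of = om * 1.25, of * 1.25
        elif tissue in _SHARED_AGE_DOWN:
            om, of = om * 0.8, of * 0.8
        act.loc[tissue] = [ym, yf, om, of]
    return GroundTruth(
        true_norm_activity=act,
        true_mito_content=_content_table(design, rng),
        noise_sd_ar=noise_sd_ar,
        noise_cv_ar=noise_cv_ar,
        noise_sd_fluor=noise_sd_fluor,
        rng_seed=seed,
    )


def ground_truth_with_effects(
    design: AtlasDesign | None = None,
    effect_log2fc: float = 1.0,
    noise_cv: float = 0.15,
    seed: int = 0,
) -> GroundTruth:
    """Ground truth where every tissue ages with |log2FC| = ``effect_log2fc``
    and a per-(tissue, sex) random sign, for category-recovery studies."""
    design = design or AtlasDesign()
    rng = np.random.default_rng(seed)
    act = pd.DataFrame(index=list(design.tissues), columns=list(GROUPS), dtype=float)
    for tissue in design.tissues:
        base = _BASE_ACTIVITY_YM.get(tissue, 3.0) * _ACTIVITY_SCALE
        sm, sf = rng.choice([-1.0, 1.0], size=2)
        act.loc[tissue] = [
            base, base,
            base * 2.0 ** (sm * effect_log2fc),
            base * 2.0 ** (sf * effect_log2fc),
        ]
    return GroundTruth(
        true_norm_activity=act,
        true_mito_content=_content_table(design, rng),
        noise_cv_ar=noise_cv,
        rng_seed=seed,
    )


def gen_plate(
    design: AtlasDesign, truth: GroundTruth
) -> tuple[list[KineticTrace], GroundTruth]:
    """Simulate every well's kinetic trace for the whole design."""
    rng = np.random.default_rng(truth.rng_seed)
    mpp = design.measurements_per_phase
    traces = []
    for tissue in design.tissues:
        for group in design.groups:
            if tissue not in design.tissues_for_group(group):
                continue
            sex, age = design.group_sex(group), design.group_age(group)
            for animal in design.animals(group):
                raw = truth.activity(tissue, group) * truth.content(tissue, animal)
                rot_level = truth.baseline_ar - truth.rotaa_drop
                levels = np.repeat(
                    [truth.baseline_ar,
                     rot_level,
                     rot_level + raw + truth.noncv_residual,
                     rot_level + truth.noncv_residual],
                    mpp,
                )
                sd = truth.noise_sd_ar + truth.noise_cv_ar * abs(raw)
                for rep in range(1, design.replicates_per_sample + 1):
                    ar = levels.copy()
                    if sd > 0:
                        ar = ar + rng.normal(0.0, sd, size=ar.size)
                    traces.append(
                        KineticTrace(
                            meta=WellMeta(
                                well_id=f"{tissue}|{animal}|r{rep}",
                                tissue=tissue,
                                animal_id=animal,
                                sex=sex,
                                age_group=age,
                                protein_ug=DEFAULT_PROTEIN_UG.get(tissue, 10.0),
                                replicate_index=rep,
                            ),
                            ar_values=tuple(ar),
                        )
                    )
    return traces, truth


def gen_mtdr(design: AtlasDesign, truth: GroundTruth) -> list[MtdrReading]:
    """Simulate duplicate MTDR readings + per-tissue-plate blank.

    Values are emitted as drawn (no clamping), so heavy fluorescence noise
    can exercise the nonpositive-net-content exclusion path downstream.
    """
    # independent stream so plate and MTDR noise don't alias
    rng = np.random.default_rng(truth.rng_seed + 1_000_003)
    readings = []
    for tissue in design.tissues:
        blanks = np.full(truth.n_blank_wells, truth.blank_level)
        if truth.noise_sd_fluor > 0:
            blanks = blanks + rng.normal(0, truth.noise_sd_fluor, blanks.size)
        blank = float(blanks.mean())
        for group in design.groups:
            if tissue not in design.tissues_for_group(group):
                continue
            for animal in design.animals(group):
                dup = np.full(2, truth.content(tissue, animal) + truth.blank_level)
                if truth.noise_sd_fluor > 0:
                    dup = dup + rng.normal(0, truth.noise_sd_fluor, 2)
                readings.append(
                    MtdrReading(
                        animal_id=animal,
                        tissue=tissue,
                        fluor_values=tuple(dup),
                        blank=blank,
                    )
                )
    return readings


DEFAULT_EXPR_TISSUES = (
    "Spleen", "BAT", "gWAT", "SubQ/iWAT", "Duodenum", "Pancreas", "Skin",
    "Muscle", "Heart", "Kidney", "Lung", "Liver", "Brain",
)


def gen_expression(
    panel: GenePanel,
    n_young: int = 20,
    n_old: int = 20,
    effect_log2fc: float = 0.0,
    null_fraction: float = 1.0,
    seed: int = 0,
    species: str = "mouse",
    tissues: tuple[str, ...] = DEFAULT_EXPR_TISSUES,
    sex: str = "male",
    sigma_log2: float = 0.5,
) -> tuple[ExpressionPanel, pd.DataFrame]:
    """Simulate a TPM panel matrix with known differential-expression truth.

    TPM is log-normal (log2 TPM ~ Normal(mu_col, sigma)); a random
    ``1 - null_fraction`` share of columns is non-null, with old
    individuals shifted by ``effect_log2fc`` (sign drawn per column).
    Returns the panel and a truth table (gene_tissue, is_null, true_effect).
    """
    if min(n_young, n_old) < 2:
        raise ValueError("need >= 2 individuals per age group")
    rng = np.random.default_rng(seed)
    genes = panel.symbols(species)
    columns = [f"{g}_{t}" for t in tissues for g in genes]
    m = len(columns)
    mu = rng.uniform(3.0, 7.0, size=m)
    is_null = rng.random(m) < null_fraction
    signs = rng.choice([-1.0, 1.0], size=m)
    effect = np.where(is_null, 0.0, signs * effect_log2fc)

    n = n_young + n_old
    log2tpm = rng.normal(0.0, sigma_log2, size=(n, m)) + mu
    log2tpm[n_young:] += effect  # old individuals are the tail block
    matrix = pd.DataFrame(
        np.exp2(log2tpm),
        index=[f"ind{i:03d}" for i in range(1, n + 1)],
        columns=columns,
    )
    if species == "mouse":
        young_ages = rng.choice([3.0, 6.0, 12.0, 15.0], size=n_young)
        old_ages = rng.choice([18.0, 21.0, 24.0, 27.0], size=n_old)
    else:
        young_ages = rng.uniform(25.0, 50.0, size=n_young)
        old_ages = rng.uniform(51.0, 75.0, size=n_old)
    covariates = pd.DataFrame(
        {"age": np.concatenate([young_ages, old_ages]), "sex": sex},
        index=matrix.index,
    )
    truth = pd.DataFrame(
        {"gene_tissue": columns, "is_null": is_null, "true_effect": effect}
    )
    return (
        ExpressionPanel(matrix=matrix, covariates=covariates, species=species),
        truth,
    )
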