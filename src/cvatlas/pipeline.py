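"""End-to-end orchestration: import -> quantify -> normalize -> stats ->
expression, as one reproducible run writing diff-able CSV tables.

All output tables use a pinned column order and 12-significant-digit
float formatting so a re-run with the same config and inputs is
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .activity import quantify_plate, records_to_frame
from .errors import CvAtlasError, PipelineError
from .expression import (
    concordance,
    diff_expression,
    dominant_tissue_direction,
    filter_detected,
    load_tissue_aliases,
    read_expression_csv,
)
from .mito import normalize_table, normalized_to_frame, read_mtdr_csv
from .plate import InjectionSchedule, read_plate_export
from .stats import (
    GROUPS,
    GroupMatrix,
    categorize_aging,
    category_counts,
    count_significant,
    cumulative_attribution,
    distribution_compare,
    group_profiles,
    pca_embed,
    rank_tissues,
    run_contrasts,
)

log = logging.getLogger(__name__)

FLOAT_FMT = "%.12g"


@dataclass
class RunConfig:
    """Paths and options of one pipeline run; serialized into the output."""

    plate_csv: str
    mtdr_csv: str
    out_dir: str
    expression_csv: dict[str, str] = field(default_factory=dict)  # sex -> path
    species: str = "mouse"
    measurements_per_phase: int = 3
    eps_category: float = 0.0
    fdr_method: str = "bh"
    mouse_age_cutoff: float = 15.0
    human_age_cutoff: float = 50.0
    seed: int = 0

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def digest(self) -> str:
        return hashlib.sha256(
            yaml.safe_dump(asdict(self), sort_keys=True).encode()
        ).hexdigest()


def design_counts(design) -> tuple[int, int]:
    """(biological samples, assay wells) implied by an AtlasDesign.

    Each animal contributes the tissues collectable from its sex; each
    sample is assayed once per technical replicate. The published design
    (32 tissues per mouse, 40 mice, triplicate wells) gives (1280, 3840).
    """
    n_samples = sum(
        design.n_per_group * len(design.tissues_for_group(g))
        for g in design.groups
    )
    return n_samples, n_samples * design.replicates_per_sample


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


def run_all(config: RunConfig) -> dict[str, object]:
    """Run every stage and write all result tables plus a run manifest.

    Any stage failure aborts with a :class:`PipelineError` naming the
    stage. Returns the in-memory results keyed by table name.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    results: dict[str, object] = {}
    schedule = InjectionSchedule((config.measurements_per_phase,) * 4)

    def stage(name, fn):
        try:
            return fn()
        except PipelineError:
            raise
        except (CvAtlasError, OSError, ValueError, KeyError) as e:
            raise PipelineError(name, str(e)) from e

    traces = stage("import-plate", lambda: read_plate_export(config.plate_csv, schedule))
    records = stage("quantify", lambda: quantify_plate(traces, schedule))
    _write(records_to_frame(records), out / "activity.csv")

    def _normalize():
        readings = read_mtdr_csv(config.mtdr_csv)
        return normalize_table(records, readings)

    normalized = stage("normalize", _normalize)
    _write(normalized_to_frame(normalized), out / "normalized.csv")

    def _stats():
        matrix = GroupMatrix.from_normalized(normalized)
        contrasts = run_contrasts(matrix)
        _write(contrasts.sort_values(["tissue", "contrast"]), out / "contrasts.csv")
        counts = count_significant(contrasts)
        (out / "significant_counts.json").write_text(json.dumps(counts, indent=1))

        for effect in ("age", "sex"):
            attr = cumulative_attribution(contrasts, effect)
            _write(attr.table, out / f"attribution_{effect}.csv")
            results[f"attribution_{effect}"] = attr

        for g in GROUPS:
            _write(rank_tissues(matrix, g), out / f"ranking_{g}.csv")

        # log2FC heatmap matrix: tissue x contrast, with tier annotations
        heat = contrasts.pivot(index="tissue", columns="contrast", values="log2fc")
        tiers = contrasts.pivot(index="tissue", columns="contrast", values="tier")
        heat.reset_index().to_csv(out / "log2fc_matrix.csv", index=False,
                                  float_format=FLOAT_FMT)
        tiers.reset_index().to_csv(out / "tier_matrix.csv", index=False)

        profiles = group_profiles(matrix)
        coords, evr = pca_embed(profiles)
        coords.reset_index(names="group").to_csv(
            out / "pca_coords.csv", index=False, float_format=FLOAT_FMT)
        (out / "pca_variance.json").write_text(
            json.dumps({f"PC{i+1}": round(float(v), 12)
                        for i, v in enumerate(evr)}, indent=1))

        dist_p = {}
        for name, (ga, gb) in {"OMvsYM": ("OM", "YM"), "OFvsYF": ("OF", "YF"),
                               "YMvsYF": ("YM", "YF"), "OMvsOF": ("OM", "OF")}.items():
            a = profiles.loc[ga].dropna()
            b = profiles.loc[gb].dropna()
            common = a.index.intersection(b.index)
            dist_p[name] = round(distribution_compare(a[common], b[common]), 12)
        (out / "distribution_pvals.json").write_text(json.dumps(dist_p, indent=1))

        male = contrasts[contrasts["contrast"] == "OMvsYM"].set_index("tissue")["log2fc"]
        female = contrasts[contrasts["contrast"] == "OFvsYF"].set_index("tissue")["log2fc"]
        cats = categorize_aging(male.dropna().to_dict(), female.dropna().to_dict(),
                                eps=config.eps_category)
        _write(cats, out / "aging_categories.csv")
        results.update(
            matrix=matrix, contrasts=contrasts, counts=counts,
            categories=cats, category_counts=category_counts(cats),
            pca_coords=coords, pca_variance=evr, distribution_pvals=dist_p,
        )
        return contrasts

    contrasts = stage("stats", _stats)

    def _expression():
        aliases = load_tissue_aliases()
        male_fc = contrasts[contrasts["contrast"] == "OMvsYM"].set_index("tissue")["log2fc"]
        female_fc = contrasts[contrasts["contrast"] == "OFvsYF"].set_index("tissue")["log2fc"]
        activity_dirs = {
            "male": {t: int(np.sign(v)) for t, v in male_fc.dropna().items()},
            "female": {t: int(np.sign(v)) for t, v in female_fc.dropna().items()},
        }
        for sex, path in config.expression_csv.items():
            panel = read_expression_csv(path, species=config.species)
            panel = filter_detected(panel)
            de = diff_expression(
                panel, fdr_method=config.fdr_method,
                mouse_cutoff=config.mouse_age_cutoff,
                human_cutoff=config.human_age_cutoff,
            )
            _write(de, out / f"expression_{sex}.csv")
            expr_dirs = dominant_tissue_direction(de)
            conc = concordance(activity_dirs.get(sex, {}), expr_dirs, aliases)
            _write(
                pd.DataFrame(
                    sorted(conc.items()), columns=["expression_tissue", "status"]
                ),
                out / f"concordance_{sex}.csv",
            )
            results[f"expression_{sex}"] = de
            results[f"concordance_{sex}"] = conc

    if config.expression_csv:
        stage("expression", _expression)

    manifest = {
        "cvatlas_version": __version__,
        "python": sys.version.split()[0],
        "seed": config.seed,
        "config_sha256": config.digest(),
        "n_traces": len(traces),
        "n_samples": len(records),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    results["manifest"] = manifest
    return results
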