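"""ATP synthase gene-panel expression analysis across age.

A 19-gene panel (F1/F0 subunits and assembly factors of ATP synthase,
with one-to-one human/mouse orthologs) is analyzed in individuals x
gene_tissue TPM matrices. Columns detected at TPM > 1 in at least 30% of
individuals are retained; individuals are dichotomized into young and old
(mouse: <= 15 months young; human: old strictly over 50 years); each
retained column gets a two-sided two-sample t-test of old vs young with
an FDR adjustment across columns — Benjamini–Hochberg by default, with a
Storey q-value smoother as an optional mode.
"""

from __future__ import annotations

import importlib.resources as resources
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.interpolate import CubicSpline
from statsmodels.stats.multitest import multipletests

from .errors import DegenerateInputError, SchemaError

COVARIATE_COLUMNS = ("individual_id", "age", "sex")
MOUSE_AGE_CUTOFF_MONTHS = 15.0
HUMAN_AGE_CUTOFF_YEARS = 50.0


@dataclass(frozen=True)
class GenePanel:
    """The packaged ATP synthase gene panel (human symbol <-> mouse ortholog)."""

    table: pd.DataFrame

    def __post_init__(self):
        required = {"human_symbol", "mouse_ortholog", "complex_part", "annotation"}
        if not required <= set(self.table.columns):
            raise SchemaError(f"gene panel needs columns {sorted(required)}")
        if self.table["human_symbol"].duplicated().any():
            raise ValueError("duplicate human symbols in panel")
        if self.table["mouse_ortholog"].duplicated().any():
            raise ValueError("duplicate mouse orthologs in panel")
        if self.table[["human_symbol", "mouse_ortholog"]].isna().any().any():
            raise ValueError("every panel entry needs both orthologs")

    def __len__(self) -> int:
        return len(self.table)

    def symbols(self, species: str) -> list[str]:
        col = "mouse_ortholog" if species == "mouse" else "human_symbol"
        return list(self.table[col])


def load_gene_panel() -> GenePanel:
    """Load the packaged 19-gene ATP synthase panel."""
    with resources.files("cvatlas.data").joinpath("atp_synthase_panel.csv").open() as f:
        return GenePanel(pd.read_csv(f))


def load_tissue_aliases(path: str | Path | None = None) -> dict[str, str]:
    """Expression-tissue -> activity-tissue label map (editable CSV).

    Labels absent from the map stay unmapped and end up *indeterminate* in
    concordance calls; they are never guessed.
    """
    if path is None:
        src = resources.files("cvatlas.data").joinpath("tissue_aliases.csv")
        with src.open() as f:
            df = pd.read_csv(f)
    else:
        df = pd.read_csv(path)
    return dict(zip(df["expression_label"], df["activity_tissue"]))


@dataclass(frozen=True)
class ExpressionPanel:
    """Individuals x gene_tissue TPM matrix with age/sex covariates."""

    matrix: pd.DataFrame  # index: individual_id; columns: gene_tissue
    covariates: pd.DataFrame  # index: individual_id; columns age, sex
    species: str  # "mouse" (age in months) or "human" (age in years)

    def __post_init__(self):
        if self.species not in ("mouse", "human"):
            raise ValueError("species must be 'mouse' or 'human'")
        if not self.matrix.index.equals(self.covariates.index):
            raise ValueError("matrix and covariates must share individuals")
        if {"age", "sex"} - set(self.covariates.columns):
            raise SchemaError("covariates need 'age' and 'sex'")
        if self.covariates[["age", "sex"]].isna().any().any():
            raise ValueError("covariates must be complete")
        if (self.matrix.to_numpy(dtype=float) < 0).any():
            raise ValueError("TPM values must be >= 0")
        for col in self.matrix.columns:
            if "_" not in col:
                raise SchemaError(f"column {col!r} does not parse as gene_tissue")

    def column_tissue(self, column: str) -> str:
        """Tissue part of a gene_tissue column name (first '_' splits)."""
        return column.split("_", 1)[1]


def read_expression_csv(path: str | Path, species: str) -> ExpressionPanel:
    """Read an expression CSV: covariate columns then gene_tissue TPM columns."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in COVARIATE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"expression table missing column(s): {missing}")
    df = df.set_index("individual_id")
    cov = df[["age", "sex"]]
    mat = df.drop(columns=["age", "sex"]).astype(float)
    return ExpressionPanel(matrix=mat, covariates=cov, species=species)


def write_expression_csv(panel: ExpressionPanel, path: str | Path) -> None:
    out = pd.concat([panel.covariates, panel.matrix], axis=1)
    out.index.name = "individual_id"
    out.to_csv(path, float_format="%.17g")


def filter_detected(
    panel: ExpressionPanel,
    tpm_threshold: float = 1.0,
    min_fraction: float = 0.30,
) -> ExpressionPanel:
    """Keep columns detected (TPM strictly > threshold) in >= min_fraction
    of individuals. A column at exactly 30% detection is retained."""
    detected = (panel.matrix > tpm_threshold).mean(axis=0)
    keep = detected[detected >= min_fraction].index
    return ExpressionPanel(
        matrix=panel.matrix[keep], covariates=panel.covariates, species=panel.species
    )


def split_by_age(
    panel: ExpressionPanel,
    mouse_cutoff: float = MOUSE_AGE_CUTOFF_MONTHS,
    human_cutoff: float = HUMAN_AGE_CUTOFF_YEARS,
) -> tuple[pd.Index, pd.Index]:
    """Dichotomize individuals into (young, old) index sets.

    Mouse: young iff age <= 15 months. Human: old iff age strictly > 50
    years (a 50-year-old is young). Cutoffs are parameters.
    """
    age = panel.covariates["age"].astype(float)
    cutoff = mouse_cutoff if panel.species == "mouse" else human_cutoff
    young = age.index[age <= cutoff]
    old = age.index[age > cutoff]
    return young, old


# ---------------------------------------------------------------------------
# FDR adjustment
# ---------------------------------------------------------------------------


def storey_qvalues(pvals: np.ndarray) -> np.ndarray:
    """Storey q-values with the cubic-spline pi0 smoother.

    pi0 is estimated from the p-value histogram over a lambda grid
    (0.05..0.95), smoothed with a natural cubic spline and evaluated at
    the largest lambda, clipped to (0, 1]; q-values are the step-up
    minimum of pi0 * m * p / rank.
    """
    p = np.asarray(pvals, dtype=float)
    m = p.size
    lam = np.arange(0.05, 0.96, 0.05)
    pi0_lam = np.array([(p > l).mean() / (1 - l) for l in lam])
    if m < 100:
        pi0 = 1.0  # too few tests for a stable smoother
    else:
        pi0 = float(CubicSpline(lam, pi0_lam, bc_type="natural")(lam[-1]))
    pi0 = min(max(pi0, 1.0 / m), 1.0)
    order = np.argsort(p)
    ranked = p[order] * pi0 * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def fdr_adjust(pvals: Sequence[float], method: str = "bh") -> np.ndarray:
    """Adjust p-values for multiple testing across columns.

    ``method='bh'`` (default) is Benjamini–Hochberg; ``method='qvalue'``
    is the Storey q-value with pi0 smoothing.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if method == "bh":
        return multipletests(p, method="fdr_bh")[1]
    if method == "qvalue":
        return storey_qvalues(p)
    raise ValueError(f"unknown FDR method {method!r}")


def diff_expression(
    panel: ExpressionPanel,
    fdr_method: str = "bh",
    min_per_group: int = 2,
    **age_cutoffs,
) -> pd.DataFrame:
    """Old-vs-young differential expression per retained gene_tissue column.

    Two-sided two-sample t-test per column; direction is the sign of
    (old mean - young mean); q-values are adjusted across the columns of
    the given panel (call per sex to adjust within sex). Columns with
    fewer than ``min_per_group`` individuals in either age group, or with
    no variance in both groups, are skipped with a reason.
    """
    young, old = split_by_age(panel, **age_cutoffs)
    if len(young) < min_per_group or len(old) < min_per_group:
        raise DegenerateInputError("both age groups need >= 2 individuals")
    Y = panel.matrix.loc[young].to_numpy(dtype=float)
    O = panel.matrix.loc[old].to_numpy(dtype=float)
    mean_diff = O.mean(axis=0) - Y.mean(axis=0)
    res = sps.ttest_ind(O, Y, axis=0, equal_var=True)
    p = np.asarray(res.pvalue, dtype=float)
    # identical/constant groups: t is 0/0 -> NaN; no evidence either way
    degenerate = ~np.isfinite(p)
    p = np.where(degenerate, 1.0, p)
    direction = np.sign(mean_diff).astype(int)
    direction[degenerate & (mean_diff == 0)] = 0
    q = fdr_adjust(p, method=fdr_method)
    return pd.DataFrame(
        {
            "gene_tissue": panel.matrix.columns,
            "tissue": [panel.column_tissue(c) for c in panel.matrix.columns],
            "direction": direction,
            "p_value": p,
            "q_value": q,
            "neglog10p": -np.log10(np.maximum(p, np.finfo(float).tiny)),
            "fdr_method": fdr_method,
        }
    )


def dominant_tissue_direction(results: pd.DataFrame) -> dict[str, int]:
    """Majority panel direction per tissue (ties and all-zero -> 0)."""
    out = {}
    for tissue, grp in results.groupby("tissue"):
        pos = int((grp["direction"] > 0).sum())
        neg = int((grp["direction"] < 0).sum())
        out[tissue] = 1 if pos > neg else (-1 if neg > pos else 0)
    return out


def concordance(
    activity_dirs: Mapping[str, int],
    expr_dirs: Mapping[str, int],
    aliases: Mapping[str, str] | None = None,
) -> dict[str, str]:
    """Per-tissue agreement between activity and expression directions.

    Expression tissue labels are mapped onto activity tissue labels via
    the alias table; unmapped labels are *indeterminate*. Equal nonzero
    signs -> concordant; opposite nonzero signs -> discordant; a zero or
    missing direction on either side -> indeterminate.
    """
    aliases = load_tissue_aliases() if aliases is None else aliases
    out = {}
    for expr_label, edir in expr_dirs.items():
        tissue = aliases.get(expr_label)
        if tissue is None or tissue not in activity_dirs:
            out[expr_label] = "indeterminate"
            continue
        adir = activity_dirs[tissue]
        if edir == 0 or adir == 0:
            out[expr_label] = "indeterminate"
        elif edir == adir:
            out[expr_label] = "concordant"
        else:
            out[expr_label] = "discordant"
    return out
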