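"""Cross-group analytics for the Complex V activity atlas.

Four groups are compared: young male (YM), young female (YF), old male
(OM), old female (OF). Four pairwise contrasts are computed per tissue —
OM vs YM and OF vs YF (age effect, within sex) and YM vs YF and OM vs OF
(sex effect, within age) — each as a two-sided Welch unequal-variance
t-test on per-animal normalized activities, reported with the mean
difference (delta), log2 fold change of group means, and a letter tier:
a (p < 0.05), b (p < 0.01), c (p < 0.001), d (p < 0.0001), strict
inequalities. No multiple-testing correction is applied to the activity
atlas; tiers are raw-p bins.

Reproductive tissues (testes, fallopian tubes) exist in one sex only and
are excluded from the cross-sex contrasts and from any statistic that
needs both sexes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.decomposition import PCA

from .errors import DegenerateInputError
from .mito import NormalizedActivity
from .tissues import SEX_SPECIFIC_TISSUES

GROUPS: tuple[str, ...] = ("YM", "YF", "OM", "OF")

#: contrast name -> (group a, group b); statistics are a minus b / a over b.
CONTRASTS: dict[str, tuple[str, str]] = {
    "OMvsYM": ("OM", "YM"),
    "OFvsYF": ("OF", "YF"),
    "YMvsYF": ("YM", "YF"),
    "OMvsOF": ("OM", "OF"),
}
AGE_CONTRASTS = ("OMvsYM", "OFvsYF")
SEX_CONTRASTS = ("YMvsYF", "OMvsOF")
CROSS_SEX_CONTRASTS = SEX_CONTRASTS

TIERS = ("none", "a", "b", "c", "d")
TIER_THRESHOLDS = ((0.0001, "d"), (0.001, "c"), (0.01, "b"), (0.05, "a"))


def group_label(sex: str, age_group: str) -> str:
    """(sex, age_group) -> YM/YF/OM/OF."""
    return ("Y" if age_group == "young" else "O") + ("M" if sex == "male" else "F")


class GroupMatrix:
    """Per-(tissue, group) vectors of per-animal normalized activity."""

    def __init__(self, data: pd.DataFrame):
        required = {"tissue", "group", "animal_id", "activity_norm"}
        missing = required - set(data.columns)
        if missing:
            raise ValueError(f"GroupMatrix frame missing columns: {sorted(missing)}")
        bad = set(data["group"]) - set(GROUPS)
        if bad:
            raise ValueError(f"unknown group label(s): {sorted(bad)}")
        self.data = data.reset_index(drop=True)

    @classmethod
    def from_normalized(cls, items: Iterable[NormalizedActivity]) -> "GroupMatrix":
        rows = [
            {
                "tissue": n.record.tissue,
                "group": group_label(n.record.sex, n.record.age_group),
                "animal_id": n.record.animal_id,
                "activity_norm": n.activity_norm,
            }
            for n in items
            if n.activity_norm is not None
        ]
        return cls(pd.DataFrame(rows))

    @property
    def tissues(self) -> list[str]:
        return sorted(self.data["tissue"].unique())

    def vector(self, tissue: str, group: str) -> np.ndarray:
        sel = self.data[
            (self.data["tissue"] == tissue) & (self.data["group"] == group)
        ]["activity_norm"].to_numpy(dtype=float)
        return sel[np.isfinite(sel)]

    def is_sex_restricted(self, tissue: str) -> bool:
        return tissue in SEX_SPECIFIC_TISSUES


@dataclass(frozen=True)
class ContrastResult:
    tissue: str
    contrast: str
    mean_a: float
    mean_b: float
    delta: float
    log2fc: float | None  # None when either group mean is not > 0
    t_stat: float
    df: float
    p_value: float
    tier: str


@dataclass(frozen=True)
class AttributionResult:
    """Cumulative |delta| attribution of one effect across tissues."""

    effect: str  # "age" or "sex"
    table: pd.DataFrame  # columns tissue, score, percent; ascending by score
    total: float


def significance_tier(p: float) -> str:
    """Letter tier for a p-value; strict '<' bins, most stringent wins."""
    if not (0 <= p <= 1):
        raise ValueError(f"p-value outside [0, 1]: {p}")
    for threshold, tier in TIER_THRESHOLDS:
        if p < threshold:
            return tier
    return "none"


def contrast_test(a: Sequence[float], b: Sequence[float]) -> ContrastResult:
    """Welch two-sided t-test between two activity vectors.

    Returns the full contrast record with tissue/contrast left blank (the
    caller fills them). Degenerate case: both groups constant with equal
    means -> t = 0, p = 1 by convention.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if a.size < 2 or b.size < 2:
        raise DegenerateInputError("each group needs >= 2 finite values")
    mean_a, mean_b = float(a.mean()), float(b.mean())
    delta = mean_a - mean_b
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if mean_a == mean_b:
            t, df, p = 0.0, float(a.size + b.size - 2), 1.0
        else:
            t = np.inf if delta > 0 else -np.inf
            df, p = float(a.size + b.size - 2), 0.0
    else:
        with warnings.catch_warnings():
            # near-identical data (e.g. zero-noise synthetic) is legitimate here
            warnings.simplefilter("ignore", RuntimeWarning)
            res = sps.ttest_ind(a, b, equal_var=False)
        t, p = float(res.statistic), float(res.pvalue)
        df = float(res.df)
    log2fc = (
        float(np.log2(mean_a / mean_b)) if (mean_a > 0 and mean_b > 0) else None
    )
    return ContrastResult(
        tissue="", contrast="",
        mean_a=mean_a, mean_b=mean_b, delta=delta, log2fc=log2fc,
        t_stat=t, df=df, p_value=p, tier=significance_tier(p),
    )


def run_contrasts(matrix: GroupMatrix) -> pd.DataFrame:
    """All four contrasts for every tissue with sufficient data.

    Sex-restricted tissues are skipped in cross-sex contrasts; a tissue is
    skipped in a contrast when either group has fewer than two values.
    """
    rows = []
    for tissue in matrix.tissues:
        for contrast, (ga, gb) in CONTRASTS.items():
            if contrast in CROSS_SEX_CONTRASTS and matrix.is_sex_restricted(tissue):
                continue
            a = matrix.vector(tissue, ga)
            b = matrix.vector(tissue, gb)
            if a.size < 2 or b.size < 2:
                continue
            r = contrast_test(a, b)
            rows.append(
                {
                    "tissue": tissue,
                    "contrast": contrast,
                    "mean_a": r.mean_a,
                    "mean_b": r.mean_b,
                    "delta": r.delta,
                    "log2fc": np.nan if r.log2fc is None else r.log2fc,
                    "t_stat": r.t_stat,
                    "df": r.df,
                    "p_value": r.p_value,
                    "tier": r.tier,
                }
            )
    return pd.DataFrame(rows)


def rank_tissues(matrix: GroupMatrix, group: str) -> pd.DataFrame:
    """Tissues ordered by descending mean normalized activity for one group.

    Ties are broken by tissue name for determinism. ``sem`` is the standard
    error of the mean over animals (sd / sqrt(n), sample sd).
    """
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}")
    rows = []
    for tissue in matrix.tissues:
        v = matrix.vector(tissue, group)
        if v.size == 0:
            continue
        sem = float(v.std(ddof=1) / np.sqrt(v.size)) if v.size > 1 else np.nan
        rows.append({"tissue": tissue, "mean": float(v.mean()), "sem": sem, "n": v.size})
    if not rows:
        raise DegenerateInputError(f"group {group!r} has no data")
    df = pd.DataFrame(rows)
    return (
        df.sort_values(["mean", "tissue"], ascending=[False, True])
        .reset_index(drop=True)
    )


def count_significant(results: pd.DataFrame) -> dict[str, int]:
    """Per-contrast counts of significant tissues plus per-effect sums.

    A tissue counts for a contrast when its tier is not 'none'. The age
    effect sums OMvsYM and OFvsYF; the sex effect sums YMvsYF and OMvsOF.
    """
    counts = {
        c: int(((results["contrast"] == c) & (results["tier"] != "none")).sum())
        for c in CONTRASTS
    }
    counts["age_effect"] = sum(counts[c] for c in AGE_CONTRASTS)
    counts["sex_effect"] = sum(counts[c] for c in SEX_CONTRASTS)
    return counts


def cumulative_attribution(results: pd.DataFrame, effect: str) -> AttributionResult:
    """Cumulative absolute mean-difference attribution of age or sex.

    Per tissue the score is |delta| of the effect's first contrast plus
    |delta| of its second (age: OMvsYM + OFvsYF; sex: YMvsYF + OMvsOF);
    only tissues carrying both contrasts contribute. Percent contribution
    is 100 * score / total; tissues are returned ascending by score.
    """
    pair = {"age": AGE_CONTRASTS, "sex": SEX_CONTRASTS}.get(effect)
    if pair is None:
        raise ValueError("effect must be 'age' or 'sex'")
    wide = results.pivot_table(
        index="tissue", columns="contrast", values="delta", aggfunc="first"
    )
    have = [c for c in pair if c in wide.columns]
    if len(have) < 2:
        raise DegenerateInputError(f"results lack both contrasts for {effect}")
    wide = wide[list(pair)].dropna()
    score = wide.abs().sum(axis=1)
    total = float(score.sum())
    if total == 0:
        raise DegenerateInputError(
            f"all deltas are zero for effect {effect!r}; percentages undefined"
        )
    table = (
        pd.DataFrame(
            {"tissue": score.index, "score": score.values,
             "percent": 100.0 * score.values / total}
        )
        .sort_values(["score", "tissue"])
        .reset_index(drop=True)
    )
    return AttributionResult(effect=effect, table=table, total=total)


def distribution_compare(a: Sequence[float], b: Sequence[float]) -> float:
    """Two-sample Kolmogorov–Smirnov p-value between per-tissue mean vectors.

    Used for the systems-level question of whether the *distribution* of
    activity across all tissues differs between two groups.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise DegenerateInputError("empty vector in distribution comparison")
    return float(sps.ks_2samp(a, b).pvalue)


def pca_embed(
    profiles: pd.DataFrame, n_components: int | None = None
) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of group activity profiles (rows = groups/samples, cols = tissues).

    Columns with any missing value (e.g. sex-specific tissues) are dropped,
    then columns are centered and unit-scaled (population sd); columns with
    zero variance are dropped too. Returns (coordinates indexed like the
    input rows, explained-variance fractions).
    """
    X = profiles.dropna(axis=1)
    if X.shape[0] < 2:
        raise DegenerateInputError("PCA needs at least two rows")
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    keep = sd > 0
    Xs = ((X.loc[:, keep] - mu[keep]) / sd[keep]).to_numpy(dtype=float)
    if Xs.shape[1] == 0:
        raise DegenerateInputError("no informative columns for PCA")
    k = n_components or min(Xs.shape[0] - 1, Xs.shape[1])
    k = max(1, min(k, Xs.shape[0] - 1 if Xs.shape[0] > 1 else 1, Xs.shape[1]))
    pca = PCA(n_components=k, svd_solver="full")
    coords = pca.fit_transform(Xs)
    cols = [f"PC{i+1}" for i in range(coords.shape[1])]
    return (
        pd.DataFrame(coords, index=profiles.index, columns=cols),
        pca.explained_variance_ratio_,
    )


def group_profiles(matrix: GroupMatrix) -> pd.DataFrame:
    """4 x n_tissues frame of group mean activities (NaN where absent)."""
    out = pd.DataFrame(index=list(GROUPS), columns=matrix.tissues, dtype=float)
    for tissue in matrix.tissues:
        for g in GROUPS:
            v = matrix.vector(tissue, g)
            out.loc[g, tissue] = v.mean() if v.size else np.nan
    return out


def categorize_aging(
    log2fc_male: Mapping[str, float],
    log2fc_female: Mapping[str, float],
    eps: float = 0.0,
) -> pd.DataFrame:
    """Shared/divergent aging categories from per-sex log2(old/young).

    Both sexes above ``eps`` -> Increased; both below ``-eps`` -> Decreased;
    strictly opposite signs -> Divergent; a magnitude <= eps in either sex
    -> NearZero (reported separately; with the default eps = 0 this hits
    only exact zeros and undefined values). Only tissues present in both
    maps are categorized.
    """
    rows = []
    for tissue in sorted(set(log2fc_male) & set(log2fc_female)):
        m, f = float(log2fc_male[tissue]), float(log2fc_female[tissue])
        if not (np.isfinite(m) and np.isfinite(f)):
            cat = "NearZero"
        elif m > eps and f > eps:
            cat = "Increased"
        elif m < -eps and f < -eps:
            cat = "Decreased"
        elif abs(m) <= eps or abs(f) <= eps:
            cat = "NearZero"
        else:
            cat = "Divergent"
        rows.append(
            {
                "tissue": tissue,
                "male_direction": int(np.sign(m)) if np.isfinite(m) else 0,
                "female_direction": int(np.sign(f)) if np.isfinite(f) else 0,
                "category": cat,
            }
        )
    return pd.DataFrame(rows)


def category_counts(categories: pd.DataFrame) -> dict[str, int]:
    return {
        cat: int((categories["category"] == cat).sum())
        for cat in ("Increased", "Decreased", "Divergent", "NearZero")
    }


def intersect_significant(set_a: Iterable[str], set_b: Iterable[str]) -> list[str]:
    """Sorted intersection of two significant-tissue sets."""
    return sorted(set(set_a) & set(set_b))
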