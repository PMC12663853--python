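import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from cvatlas import (
    categorize_aging,
    contrast_test,
    count_significant,
    cumulative_attribution,
    distribution_compare,
    intersect_significant,
    pca_embed,
    rank_tissues,
    run_contrasts,
    significance_tier,
)
from cvatlas.errors import DegenerateInputError
from cvatlas.stats import GROUPS, GroupMatrix, category_counts, group_profiles

act_vec = st.lists(st.floats(0.1, 100, allow_nan=False), min_size=3, max_size=12)


def matrix_from_means(means: dict, n=5, spread=1.0):
    """GroupMatrix with exact per-(tissue, group) means and symmetric jitter."""
    offsets = np.linspace(-spread, spread, n)
    rows = []
    for (tissue, group), mu in means.items():
        for i, off in enumerate(offsets):
            rows.append({"tissue": tissue, "group": group,
                         "animal_id": f"{group}{i:02d}",
                         "activity_norm": mu + off})
    return GroupMatrix(pd.DataFrame(rows))


class TestWelch:
    def test_identical_groups(self):
        r = contrast_test([1, 2, 3, 4, 5], [1, 2, 3, 4, 5])
        assert (r.delta, r.log2fc) == (0.0, 0.0)
        assert r.p_value == pytest.approx(1.0)
        assert r.tier == "none"

    def test_textbook_welch_oracle(self):
        """t, df and p match the Welch–Satterthwaite formulas to 1e-10."""
        a = np.array([10.0, 11.0, 12.0, 9.0, 10.0])
        b = np.array([2.0, 3.0, 2.0, 1.0, 2.0])
        va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
        t_oracle = (a.mean() - b.mean()) / math.sqrt(va + vb)
        df_oracle = (va + vb) ** 2 / (
            va**2 / (a.size - 1) + vb**2 / (b.size - 1)
        )
        p_oracle = 2 * sps.t.sf(abs(t_oracle), df_oracle)
        r = contrast_test(a, b)
        assert r.t_stat == pytest.approx(t_oracle, abs=1e-10)
        assert r.df == pytest.approx(df_oracle, abs=1e-10)
        assert r.p_value == pytest.approx(p_oracle, abs=1e-10)
        assert r.delta == pytest.approx(a.mean() - b.mean())
        assert r.log2fc == pytest.approx(math.log2(a.mean() / b.mean()))

    def test_single_value_group_raises(self):
        with pytest.raises(DegenerateInputError):
            contrast_test([1.0], [1.0, 2.0, 3.0])

    def test_zero_variance_equal_means_convention(self):
        r = contrast_test([2.0, 2.0, 2.0], [2.0, 2.0])
        assert (r.p_value, r.t_stat) == (1.0, 0.0)

    def test_log2fc_undefined_for_nonpositive_mean(self):
        r = contrast_test([-1.0, 0.0, 1.0], [1.0, 2.0, 3.0])
        assert r.log2fc is None
        assert math.isfinite(r.delta)

    @settings(deadline=None, derandomize=True)
    @given(act_vec, act_vec)
    def test_antisymmetry(self, a, b):
        """delta and log2fc flip sign when the groups are swapped."""
        r1, r2 = contrast_test(a, b), contrast_test(b, a)
        assert r1.delta == pytest.approx(-r2.delta, rel=1e-9, abs=1e-12)
        if r1.log2fc is not None:
            assert r1.log2fc == pytest.approx(-r2.log2fc, rel=1e-9, abs=1e-12)
        assert r1.p_value == pytest.approx(r2.p_value, rel=1e-9, abs=1e-12)


class TestTiers:
    @pytest.mark.parametrize(
        "p,tier",
        [(0.04, "a"), (0.009, "b"), (0.0009, "c"), (0.00009, "d"),
         (0.05, "none"), (0.01, "a"), (0.001, "b"), (0.0001, "c"),
         (0.3, "none"), (0.0, "d"), (1.0, "none")],
    )
    def test_strict_bins(self, p, tier):
        assert significance_tier(p) == tier

    @settings(deadline=None, derandomize=True)
    @given(st.floats(0, 1), st.floats(0, 1))
    def test_monotonicity(self, p1, p2):
        """A smaller p never gets a less stringent tier."""
        order = {"none": 0, "a": 1, "b": 2, "c": 3, "d": 4}
        lo, hi = sorted([p1, p2])
        assert order[significance_tier(lo)] >= order[significance_tier(hi)]


class TestRanking:
    def test_sorted_descending(self):
        gm = matrix_from_means({("A", "YM"): 5, ("B", "YM"): 9, ("C", "YM"): 1})
        assert list(rank_tissues(gm, "YM")["tissue"]) == ["B", "A", "C"]

    def test_tie_broken_by_name(self):
        gm = matrix_from_means({("B", "YM"): 5, ("A", "YM"): 5})
        assert list(rank_tissues(gm, "YM")["tissue"]) == ["A", "B"]

    def test_matches_brute_force_sort(self):
        rng = np.random.default_rng(3)
        means = {(f"T{i:02d}", "OF"): rng.uniform(1, 10) for i in range(12)}
        gm = matrix_from_means(means, n=6, spread=0.3)
        ranked = rank_tissues(gm, "OF")
        expect = sorted(means, key=lambda k: (-means[k], k[0]))
        assert list(ranked["tissue"]) == [t for t, _ in expect]
        # sem oracle: sd/sqrt(n) over the jitter offsets
        off = np.linspace(-0.3, 0.3, 6)
        sem = off.std(ddof=1) / np.sqrt(6)
        assert ranked["sem"].to_numpy() == pytest.approx(sem)


class TestCounting:
    def test_all_null_counts_zero(self):
        df = pd.DataFrame(
            {"tissue": ["A"] * 4, "contrast": list(GROUPS), "tier": ["none"] * 4}
        )
        df["contrast"] = ["OMvsYM", "OFvsYF", "YMvsYF", "OMvsOF"]
        counts = count_significant(df)
        assert all(v == 0 for v in counts.values())

    def test_enumeration_oracle(self):
        rows = []
        spec = {"OMvsYM": 3, "OFvsYF": 2, "YMvsYF": 1, "OMvsOF": 1}
        for contrast, k in spec.items():
            for i in range(5):
                rows.append({"tissue": f"T{i}", "contrast": contrast,
                             "tier": "a" if i < k else "none"})
        counts = count_significant(pd.DataFrame(rows))
        assert counts["age_effect"] == 5
        assert counts["sex_effect"] == 2

    def test_generated_atlas_has_more_age_than_sex_effects(self, noisy_atlas_matrix):
        """The default truth encodes more age- than sex-affected tissues."""
        gm, _ = noisy_atlas_matrix
        counts = count_significant(run_contrasts(gm))
        assert counts["age_effect"] > counts["sex_effect"]


class TestAttribution:
    @staticmethod
    def results_with_deltas(deltas: dict, contrasts=("OMvsYM", "OFvsYF")):
        rows = []
        for tissue, (d1, d2) in deltas.items():
            rows.append({"tissue": tissue, "contrast": contrasts[0], "delta": d1})
            rows.append({"tissue": tissue, "contrast": contrasts[1], "delta": d2})
        return pd.DataFrame(rows)

    def test_direct_arithmetic(self):
        res = self.results_with_deltas({"A": (1.5, -0.5), "B": (-4.0, 4.0)})
        attr = cumulative_attribution(res, "age")
        assert attr.total == pytest.approx(10.0)
        assert list(attr.table["tissue"]) == ["A", "B"]
        assert attr.table["percent"].to_numpy() == pytest.approx([20.0, 80.0])

    def test_single_tissue_is_100_percent(self):
        res = self.results_with_deltas({"A": (0.5, 0.25)})
        attr = cumulative_attribution(res, "age")
        assert attr.table["percent"].to_numpy() == pytest.approx([100.0])

    def test_all_zero_deltas_error(self):
        with pytest.raises(DegenerateInputError):
            cumulative_attribution(
                self.results_with_deltas({"A": (0.0, 0.0)}), "age"
            )

    @settings(deadline=None, derandomize=True)
    @given(st.dictionaries(st.sampled_from([f"T{i}" for i in range(20)]),
                           st.tuples(st.floats(-10, 10), st.floats(-10, 10)),
                           min_size=2))
    def test_conservation_and_drop_stability(self, deltas):
        """Percentages sum to 100; dropping the top contributor only
        renormalizes, preserving the relative order of the rest."""
        if sum(abs(a) + abs(b) for a, b in deltas.values()) == 0:
            return
        res = self.results_with_deltas(deltas)
        attr = cumulative_attribution(res, "age")
        assert attr.table["percent"].sum() == pytest.approx(100.0, abs=1e-9)
        top = attr.table["tissue"].iloc[-1]
        rest = {t: d for t, d in deltas.items() if t != top}
        if rest and sum(abs(a) + abs(b) for a, b in rest.values()) > 0:
            attr2 = cumulative_attribution(self.results_with_deltas(rest), "age")
            assert list(attr2.table["tissue"]) == [
                t for t in attr.table["tissue"] if t != top
            ]


class TestDistributionCompare:
    def test_identical_vectors(self):
        a = np.arange(1.0, 33.0)
        assert distribution_compare(a, a) == 1.0

    def test_large_shift_detected(self):
        rng = np.random.default_rng(0)
        b = rng.uniform(0, 1, 32)
        a = b + 10 * (b.max() - b.min())
        assert distribution_compare(a, b) < 0.01

    def test_permutation_invariance(self):
        rng = np.random.default_rng(1)
        a = rng.normal(5, 2, 32)
        assert distribution_compare(rng.permutation(a), a) == 1.0


class TestPCA:
    def test_identical_rows_identical_coords(self):
        X = pd.DataFrame([[1.0, 2, 3, 4]] * 2 + [[4.0, 3, 2, 1]],
                         index=["r1", "r2", "r3"])
        coords, _ = pca_embed(X)
        assert coords.loc["r1"].to_numpy() == pytest.approx(
            coords.loc["r2"].to_numpy(), abs=1e-12
        )

    def test_rank_one_first_component_explains_all(self):
        base = np.array([1.0, -2.0, 0.5, 3.0])
        X = pd.DataFrame(np.outer([1.0, 2.0, 3.0], base))
        _, evr = pca_embed(X)
        assert evr[0] == pytest.approx(1.0, abs=1e-12)

    def test_matches_independent_eigendecomposition(self):
        """Coordinates match an eigendecomposition of the standardized
        covariance up to per-component sign, to 1e-8."""
        rng = np.random.default_rng(5)
        X = pd.DataFrame(rng.normal(size=(8, 10)))
        coords, evr = pca_embed(X)
        Z = (X - X.mean()) / X.std(ddof=0)
        C = np.cov(Z.T, ddof=1)
        w, V = np.linalg.eigh(C)
        order = np.argsort(w)[::-1]
        w, V = w[order], V[:, order]
        proj = Z.to_numpy() @ V[:, : coords.shape[1]]
        for j in range(coords.shape[1]):
            col = coords.iloc[:, j].to_numpy()
            assert (
                col == pytest.approx(proj[:, j], abs=1e-8)
                or col == pytest.approx(-proj[:, j], abs=1e-8)
            )
        assert evr == pytest.approx(w[: len(evr)] / w.sum(), abs=1e-8)


class TestCategorization:
    def test_shared_and_divergent(self):
        cats = categorize_aging(
            {"A": 0.5, "B": -0.3, "C": -0.2}, {"A": 0.2, "B": 0.4, "C": -0.6}
        )
        by = cats.set_index("tissue")["category"]
        assert by["A"] == "Increased"
        assert by["B"] == "Divergent"
        assert by["C"] == "Decreased"

    def test_exact_zero_is_near_zero(self):
        cats = categorize_aging({"A": 0.0}, {"A": 0.4})
        assert cats["category"].iloc[0] == "NearZero"

    def test_eps_threshold(self):
        cats = categorize_aging({"A": 0.05}, {"A": 0.4}, eps=0.1)
        assert cats["category"].iloc[0] == "NearZero"

    def test_counts(self):
        cats = categorize_aging({"A": 1.0, "B": -1.0}, {"A": 1.0, "B": 1.0})
        assert category_counts(cats) == {
            "Increased": 1, "Decreased": 0, "Divergent": 1, "NearZero": 0
        }


class TestIntersection:
    def test_printed_age_increase_sets(self):
        male = {"Heart atrium", "Diaphragm", "Cecum", "Ileum", "gWAT"}
        female = {"Diaphragm", "Ileum"}
        shared = intersect_significant(male, female)
        assert shared == ["Diaphragm", "Ileum"]
        assert len(shared) == 2

    def test_empty_and_idempotent(self):
        assert intersect_significant({"A"}, set()) == []
        assert intersect_significant({"B", "A"}, {"A", "B"}) == ["A", "B"]


def test_sex_specific_tissues_excluded_from_cross_sex_contrasts(zero_noise_atlas):
    contrasts = run_contrasts(zero_noise_atlas[3])
    cross = contrasts[contrasts["contrast"].isin(["YMvsYF", "OMvsOF"])]
    assert not set(cross["tissue"]) & {"Testes", "Fallopian tubes"}
    age = contrasts[contrasts["contrast"] == "OMvsYM"]
    assert "Testes" in set(age["tissue"])


def test_group_profiles_has_nan_for_missing_sex(zero_noise_atlas):
    profiles = group_profiles(zero_noise_atlas[3])
    assert np.isnan(profiles.loc["YF", "Testes"])
    assert np.isfinite(profiles.loc["YM", "Testes"])
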