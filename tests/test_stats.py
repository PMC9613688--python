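"""The nonparametric statistical battery."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from helpers_oracles import enumerate_signed_rank_p, spearman_rho_by_definition
from oculosway.stats import (
    CONDITION,
    FACTORIAL_CONDITIONS,
    PARAMETER,
    SUBJECT,
    VALUE,
    adjust_p,
    art_rm_anova,
    check_distributions,
    condition_factors,
    effect_size_magnitude,
    friedman_by_factor,
    paper_comparison_pairs,
    rank_factorial_anova,
    spearman_matrix,
    wilcoxon_pairwise,
    wilcoxon_signed_rank,
)


def long_table(values: np.ndarray, conditions=FACTORIAL_CONDITIONS,
               parameter="latency_mean") -> pd.DataFrame:
    """values: (n_subjects, n_conditions) array -> long format."""
    n_s, n_c = values.shape
    rows = [(s, conditions[c], parameter, values[s, c])
            for s in range(n_s) for c in range(n_c)]
    return pd.DataFrame(rows, columns=[SUBJECT, CONDITION, PARAMETER, VALUE])


class TestDesignHelpers:
    def test_condition_factor_mapping(self):
        assert condition_factors(4) == ("2D", "pro")
        assert condition_factors(5) == ("2D", "anti")
        assert condition_factors(11) == ("SO", "anti")
        with pytest.raises(ValueError):
            condition_factors(3)

    def test_comparison_scheme(self):
        pairs = paper_comparison_pairs()
        assert len(pairs) == 16  # 6 env pairs x 2 tasks + 4 task pairs
        for a, b in pairs:
            ea, ta = condition_factors(a)
            eb, tb = condition_factors(b)
            assert ea == eb or ta == tb


class TestCheckDistributions:
    def test_identical_groups_levene_one(self, rng):
        vals = np.tile(rng.normal(size=(8, 1)), (1, 8))
        checks = check_distributions(long_table(vals))
        assert checks[0].levene_p == pytest.approx(1.0)

    def test_shapiro_under_normal_null(self):
        hits = 0
        for seed in range(100):
            r = np.random.default_rng(seed)
            vals = r.normal(size=(10, 8))
            checks = check_distributions(long_table(vals))
            hits += checks[0].shapiro_p > 0.05
        assert hits >= 90

    def test_shapiro_detects_heavy_tails(self):
        hits = 0
        for seed in range(100):
            r = np.random.default_rng(seed)
            vals = r.standard_t(df=1, size=(10, 8))
            checks = check_distributions(long_table(vals))
            hits += checks[0].shapiro_p < 0.05
        assert hits >= 90

    def test_constant_data_flagged(self):
        vals = np.ones((6, 8))
        checks = check_distributions(long_table(vals))
        assert checks[0].degenerate


class TestArtAnova:
    def test_constant_task_levels_null(self, rng):
        # environment varies, task does not
        env_eff = np.array([0.0, 1.0, 2.0, 3.0])
        cube = (rng.normal(size=(12, 1, 1))
                + env_eff[None, :, None]
                + rng.normal(scale=0.3, size=(12, 4, 2)))
        cube[:, :, 1] = cube[:, :, 0]  # identical task levels
        res = {r.effect: r for r in art_rm_anova(cube)}
        assert res["B"].p > 0.9
        assert res["A"].p < 0.001

    def test_matches_rm_anova_on_ranks_oracle(self, rng):
        """The within-subject F on ranks agrees with pingouin's RM ANOVA."""
        pingouin = pytest.importorskip("pingouin")
        cube = rng.normal(size=(10, 4, 2)) + rng.normal(size=(10, 1, 1))
        res = {r.effect: r for r in art_rm_anova(cube)}
        # reproduce the alignment + ranking for the A main effect
        grand = cube.mean()
        cell = cube.mean(axis=0)
        amean = cube.mean(axis=(0, 2))
        smean = cube.mean(axis=(1, 2))
        aligned = (cube - cell[None] - smean[:, None, None] + grand
                   + (amean - grand)[None, :, None])
        ranks = sps.rankdata(aligned.ravel()).reshape(cube.shape)
        df = pd.DataFrame({
            "y": ranks.ravel(),
            "subj": np.repeat(np.arange(10), 8),
            "A": np.tile(np.repeat(np.arange(4), 2), 10),
        })
        aov = pingouin.rm_anova(data=df, dv="y", within="A", subject="subj",
                                correction=False)
        p_col = "p-unc" if "p-unc" in aov.columns else "p_unc"
        assert res["A"].F == pytest.approx(float(aov["F"].iloc[0]), rel=1e-6)
        assert res["A"].p == pytest.approx(float(aov[p_col].iloc[0]), rel=1e-6)

    def test_long_table_interface(self, rng):
        vals = rng.normal(size=(10, 8))
        out = rank_factorial_anova(long_table(vals))
        assert set(out["effect"]) == {"environment", "saccade_task",
                                      "environment:saccade_task"}

    def test_missing_cell_reported(self, rng):
        table = long_table(rng.normal(size=(6, 8)))
        table = table[~((table[SUBJECT] == 2) & (table[CONDITION] == 9))]
        with pytest.raises(ValueError, match=r"\(2, 9\)"):
            rank_factorial_anova(table)

    def test_friedman_cross_check_agrees_on_strong_effect(self, rng):
        env_eff = np.array([0.0, 0.0, 3.0, 3.0])
        vals = rng.normal(scale=0.5, size=(12, 8))
        vals += np.repeat(env_eff, 2)[None, :]
        table = long_table(vals)
        art = rank_factorial_anova(table)
        fr = friedman_by_factor(table)
        p_art = art[art["effect"] == "environment"]["p"].iloc[0]
        p_fr = fr[fr["effect"] == "environment"]["p"].iloc[0]
        assert p_art < 0.001 and p_fr < 0.001


class TestWilcoxon:
    def test_all_positive_n6_exact(self):
        x = np.arange(1.0, 7.0)
        y = x - 1.0  # all differences +1... ties in |d| are fine
        res = wilcoxon_signed_rank(x, y)
        assert res.exact
        assert res.p == pytest.approx(2.0 / 64.0)

    def test_identical_pairs(self):
        x = np.arange(8.0)
        res = wilcoxon_signed_rank(x, x)
        assert res.all_zero and res.p == 1.0 and res.effect_size == 0.0
        assert effect_size_magnitude(res.effect_size) == "none"

    def test_exact_equals_enumeration(self, rng):
        for _ in range(40):
            n = rng.integers(4, 11)
            d = rng.normal(size=n)
            x = rng.normal(size=n)
            res = wilcoxon_signed_rank(x + d, x)
            assert res.p == pytest.approx(enumerate_signed_rank_p(d), abs=1e-12)

    def test_exact_equals_enumeration_with_ties(self, rng):
        for _ in range(20):
            n = int(rng.integers(5, 10))
            d = rng.integers(-3, 4, size=n).astype(float)
            if np.all(d == 0):
                continue
            # zero baseline keeps the integer ties exact
            res = wilcoxon_signed_rank(d, np.zeros(n))
            assert res.p == pytest.approx(enumerate_signed_rank_p(d), abs=1e-12)

    def test_matches_scipy_exact_on_tie_free_data(self, rng):
        for _ in range(20):
            n = int(rng.integers(6, 20))
            x, y = rng.normal(size=n), rng.normal(size=n)
            ours = wilcoxon_signed_rank(x, y)
            ref = sps.wilcoxon(x, y, mode="exact")
            assert ours.p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_large_n_normal_approximation(self, rng):
        x = rng.normal(size=60)
        y = x + rng.normal(0.3, 1.0, size=60)
        ours = wilcoxon_signed_rank(x, y)
        assert not ours.exact
        ref = sps.wilcoxon(x, y, mode="approx", correction=False)
        assert ours.p == pytest.approx(ref.pvalue, rel=1e-6)

    @pytest.mark.parametrize("r, label", [
        (0.58, "large"), (0.44, "moderate"), (0.50, "large"),
        (0.30, "moderate"), (0.12, "small"), (0.05, "none"),
    ])
    def test_magnitude_thresholds(self, r, label):
        assert effect_size_magnitude(r) == label

    def test_pairwise_families_and_holm(self, rng):
        vals = rng.normal(size=(10, 8))
        vals[:, 4:] += 2.0  # VM/SO shifted
        results = wilcoxon_pairwise(long_table(vals))
        assert len(results) == 16
        for r in results:
            assert r.p_adjusted >= r.p_raw - 1e-15
            assert 0.0 <= r.effect_size <= 1.0

    def test_pairwise_rejects_diagonal_pairs(self, rng):
        with pytest.raises(ValueError):
            wilcoxon_pairwise(long_table(np.random.default_rng(0).normal(size=(8, 8))),
                              pairs=[(4, 7)])  # crosses env and task


class TestAdjustP:
    def test_holm_by_hand(self):
        assert adjust_p([0.01, 0.04], "holm") == pytest.approx([0.02, 0.04])

    def test_single_p_unchanged(self):
        assert adjust_p([0.3], "holm") == pytest.approx([0.3])

    def test_bonferroni_by_hand(self):
        assert adjust_p([0.02, 0.03, 0.04], "bonferroni") == pytest.approx(
            [0.06, 0.09, 0.12])

    def test_holm_dominates_raw_and_caps_at_one(self, rng):
        p = rng.uniform(size=20)
        adj = adjust_p(list(p), "holm")
        assert all(a >= r - 1e-15 for a, r in zip(adj, p))
        assert all(a <= 1.0 for a in adj)
        # order consistency: larger raw p never gets smaller adjusted p
        order = np.argsort(p)
        assert np.all(np.diff(np.array(adj)[order]) >= -1e-12)

    def test_empty_and_invalid(self):
        assert adjust_p([]) == []
        with pytest.raises(ValueError):
            adjust_p([0.5, 1.2])


class TestSpearman:
    @staticmethod
    def _table(x, y, condition=4):
        rows = []
        for s, (a, b) in enumerate(zip(x, y)):
            rows.append((s, condition, "p1", a))
            rows.append((s, condition, "p2", b))
        return pd.DataFrame(rows, columns=[SUBJECT, CONDITION, PARAMETER, VALUE])

    def test_monotone_transform_rho_one(self):
        x = np.arange(1.0, 9.0)
        mat = spearman_matrix(self._table(x, x ** 3), 4)
        assert mat.rho.at["p1", "p2"] == pytest.approx(1.0)
        assert mat.rho.at["p1", "p1"] == 1.0

    def test_antitone_rho_minus_one(self):
        x = np.arange(1.0, 9.0)
        mat = spearman_matrix(self._table(x, -x), 4)
        assert mat.rho.at["p1", "p2"] == pytest.approx(-1.0)

    def test_ties_match_midrank_oracle(self, rng):
        x = rng.integers(0, 4, size=12).astype(float)
        y = rng.integers(0, 4, size=12).astype(float)
        mat = spearman_matrix(self._table(x, y), 4)
        assert mat.rho.at["p1", "p2"] == pytest.approx(
            spearman_rho_by_definition(x, y), abs=1e-12)

    def test_constant_column_masked(self):
        x = np.arange(1.0, 9.0)
        mat = spearman_matrix(self._table(x, np.ones(8)), 4)
        assert np.isnan(mat.rho.at["p1", "p2"])
        assert not mat.significant.at["p1", "p2"]

    def test_symmetry_and_significance_flag(self, rng):
        x = np.arange(10.0)
        y = x + rng.normal(scale=0.5, size=10)
        mat = spearman_matrix(self._table(x, y), 4)
        assert mat.rho.at["p1", "p2"] == mat.rho.at["p2", "p1"]
        assert bool(mat.significant.at["p1", "p2"]) == (mat.p.at["p1", "p2"] < 0.05)

    def test_requires_five_rows(self):
        x = np.arange(4.0)
        with pytest.raises(ValueError):
            spearman_matrix(self._table(x, x), 4)
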