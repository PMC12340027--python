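import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from scipy.linalg import helmert

import tonechange as tc
from tonechange.stats import (
    CORRELATION_COLUMNS,
    rm_anova_from_array,
    sphericity_from_scores,
)

# ---------------------------------------------------------------------------
# independent contrast-projection oracle for the within-subject ANOVA


def oracle_f(y: np.ndarray, effect_axes: tuple[int, ...]) -> float:
    """F of one effect by projecting subject cell vectors onto orthonormal
    effect contrasts (helmert-based), independent of the implementation."""
    n = y.shape[0]
    mats = []
    for ax, k in enumerate(y.shape[1:]):
        mats.append(helmert(k) if ax in effect_axes else np.ones((1, k)) / np.sqrt(k))
    C = mats[0]
    for m in mats[1:]:
        C = np.kron(C, m)
    Z = y.reshape(n, -1) @ C.T
    q = Z.shape[1]
    zbar = Z.mean(axis=0)
    ss_eff = n * (zbar**2).sum()
    ss_err = ((Z - zbar) ** 2).sum()
    return (ss_eff / q) / (ss_err / (q * (n - 1)))


def summaries_from_array(y: np.ndarray) -> pd.DataFrame:
    """(n, 3, 3, 2) cell array -> tidy condition-summaries table."""
    n = y.shape[0]
    rows = []
    for s in range(n):
        for i, p in enumerate(tc.LEVELS):
            for j, m in enumerate(tc.LEVELS):
                for k, d in enumerate(tc.DIRECTIONS):
                    rows.append((f"s{s:03d}", p, m, d, y[s, i, j, k]))
    return pd.DataFrame(
        rows,
        columns=["subject_id", "precision_level", "mean_change_level",
                 "direction", "mean_psc"],
    )


ALL_EFFECTS = [
    c for r in range(1, 4) for c in itertools.combinations(range(3), r)
]


class TestRmAnova:
    @pytest.mark.parametrize("seed", range(10))
    def test_matches_contrast_projection_oracle(self, seed):
        rng = np.random.default_rng(seed)
        y = rng.normal(size=(4 + seed % 5, 3, 3, 2))
        tab = rm_anova_from_array(y, effect_names=["a", "b", "c"])
        for combo in ALL_EFFECTS:
            name = ":".join("abc"[i] for i in combo)
            got = float(tab.loc[tab["effect"] == name, "F"].iloc[0])
            assert got == pytest.approx(oracle_f(y, combo), abs=1e-8, rel=1e-8)

    def test_location_invariance(self):
        rng = np.random.default_rng(1)
        y = rng.normal(size=(8, 3, 3, 2))
        a = rm_anova_from_array(y)
        b = rm_anova_from_array(y + 17.3)
        assert np.allclose(a["F"], b["F"])

    def test_dataframe_interface_matches_array_core(self, small_summaries):
        tab = tc.rm_anova(small_summaries)
        from tonechange.stats import pivot_to_array

        y, _ = pivot_to_array(
            small_summaries, "mean_psc",
            ("precision_level", "mean_change_level", "direction"),
        )
        tab2 = rm_anova_from_array(y, effect_names=["precision", "mean_change", "direction"])
        assert np.allclose(tab["F"], tab2["F"])

    def test_pingouin_cross_check_two_way(self):
        """Independent implementation agreement on a 3x3 within design."""
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(5)
        y = rng.normal(size=(12, 3, 3)) + rng.normal(size=(12, 1, 1))
        rows = [
            (s, f"a{i}", f"b{j}", y[s, i, j])
            for s in range(12) for i in range(3) for j in range(3)
        ]
        df = pd.DataFrame(rows, columns=["subject", "A", "B", "dv"])
        mine = rm_anova_from_array(y, effect_names=["A", "B"])
        theirs = pg.rm_anova(data=df, dv="dv", within=["A", "B"], subject="subject")
        for eff, src in [("A", "A"), ("B", "B"), ("A:B", "A * B")]:
            f_mine = float(mine.loc[mine["effect"] == eff, "F"].iloc[0])
            f_pg = float(theirs.loc[theirs["Source"] == src, "F"].iloc[0])
            assert f_mine == pytest.approx(f_pg, rel=1e-9)

    def test_incomplete_design_rejected(self, small_summaries):
        broken = small_summaries.iloc[:-1]
        with pytest.raises(tc.DomainError, match="incomplete|unbalanced"):
            tc.rm_anova(broken)

    def test_accuracy_dv(self, exp4_trials):
        resp = tc.simulate_cohort(exp4_trials, tc.REGIMES["bayesian"], 10, seed=4)
        summ = tc.condition_summaries(resp, exp4_trials)
        tab = tc.rm_anova(summ, dv="accuracy")
        assert len(tab) == 7
        assert np.isfinite(tab["F"]).all()


class TestSphericity:
    def test_two_level_effect_is_identity(self, small_summaries):
        res = tc.sphericity_correction(small_summaries, "direction")
        assert res.gg_epsilon == 1.0 and not res.applicable

    def test_spherical_scores_give_w_and_epsilon_one(self):
        rng = np.random.default_rng(0)
        Z = rng.normal(size=(12, 2))
        Z -= Z.mean(axis=0)
        L = np.linalg.cholesky(np.cov(Z, rowvar=False, ddof=1))
        Z = Z @ np.linalg.inv(L).T  # sample covariance exactly I
        res = sphericity_from_scores(Z)
        assert res.mauchly_W == pytest.approx(1.0, abs=1e-10)
        assert res.gg_epsilon == pytest.approx(1.0, abs=1e-10)
        assert res.mauchly_p == pytest.approx(1.0, abs=1e-6)

    def test_dominant_eigenvalue_hits_lower_bound(self):
        """k = 3 (q = 2): one dominant contrast -> epsilon -> 1/(k-1) = 0.5."""
        rng = np.random.default_rng(3)
        Z = np.column_stack([rng.normal(size=20), 1e-8 * rng.normal(size=20)])
        res = sphericity_from_scores(Z)
        assert res.gg_epsilon == pytest.approx(0.5, abs=1e-6)

    def test_pingouin_cross_check_one_way(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(8)
        y = rng.normal(size=(14, 3))
        y[:, 2] *= 2.5  # break sphericity
        tab = rm_anova_from_array(y, effect_names=["lvl"])
        df = pd.DataFrame({
            "subject": np.repeat(np.arange(14), 3),
            "lvl": np.tile(["a", "b", "c"], 14),
            "dv": y.ravel(),
        })
        W, _, chi2, dof, p_sph = 0, 0, 0, 0, 0
        sph = pg.sphericity(data=df, dv="dv", within="lvl", subject="subject")
        eps = pg.epsilon(df.pivot(index="subject", columns="lvl", values="dv"),
                         correction="gg")
        r = tab.iloc[0]
        assert r["mauchly_W"] == pytest.approx(sph.W, rel=1e-9)
        assert r["mauchly_p"] == pytest.approx(sph.pval, rel=1e-6)
        assert r["gg_epsilon"] == pytest.approx(float(eps), rel=1e-9)

    def test_correction_raises_p_when_gated(self):
        rng = np.random.default_rng(21)
        base = rng.normal(size=(16, 3, 3, 2))
        base[:, 0] += rng.normal(size=(16, 1, 1)) * 3.0  # inflate one precision level
        tab = rm_anova_from_array(base, effect_names=["precision", "mean_change", "direction"])
        corrected = tab[tab["corrected"]]
        assert len(corrected) >= 1  # gate fires for this construction
        for _, r in corrected.iterrows():
            assert r["mauchly_p"] < 0.05
            assert r["df_num_corr"] == pytest.approx(r["df_num"] * r["gg_epsilon"])
            assert r["df_den_corr"] == pytest.approx(r["df_den"] * r["gg_epsilon"])
            assert r["p_reported"] == pytest.approx(
                sps.f.sf(r["F"], r["df_num_corr"], r["df_den_corr"])
            )
        untouched = tab[~tab["corrected"]]
        assert (untouched["p_reported"] == untouched["p_uncorrected"]).all()


class TestBenjaminiHochberg:
    def test_hand_computed_step_up(self):
        q = tc.benjamini_hochberg([0.001, 0.01, 0.02, 0.04], m=4)
        assert np.allclose(q, [0.004, 0.02, 0.02 * 4 / 3, 0.04])

    def test_single_test_identity(self):
        assert tc.benjamini_hochberg([0.03]) == pytest.approx([0.03])

    def test_all_equal_fixed_point(self):
        q = tc.benjamini_hochberg([0.2] * 6)
        assert np.allclose(q, 0.2)

    def test_statsmodels_cross_check(self):
        sm = pytest.importorskip("statsmodels.stats.multitest")
        rng = np.random.default_rng(4)
        p = rng.uniform(size=54)
        mine = tc.benjamini_hochberg(p)
        _, theirs, _, _ = sm.multipletests(p, method="fdr_bh")
        assert np.allclose(mine, theirs)

    def test_monotone_in_rank_and_dominates_p(self):
        rng = np.random.default_rng(9)
        p = rng.uniform(size=30)
        q = tc.benjamini_hochberg(p)
        assert (q >= p - 1e-15).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()

    def test_nan_passthrough(self):
        q = tc.benjamini_hochberg([0.01, np.nan, 0.04])
        assert np.isnan(q[1]) and not np.isnan(q[0])


class TestSpearman:
    def test_perfect_monotone(self):
        x = [1, 2, 3, 4, 5]
        rho, p = tc.spearman(x, [10, 20, 30, 40, 50])
        assert rho == pytest.approx(1.0)
        rho2, _ = tc.spearman(x, [5, 4, 3, 2, 1])
        assert rho2 == pytest.approx(-1.0)

    def test_exact_p_matches_full_enumeration_n5(self):
        """Exact permutation p vs an independent 5! enumeration oracle."""
        x = np.array([0.3, -1.2, 0.8, 2.0, 0.1])
        y = np.array([1.0, 0.2, 1.4, 0.9, -0.3])
        rho_obs, p_exact = tc.spearman(x, y, method="exact")
        rx, ry = sps.rankdata(x), sps.rankdata(y)
        rhos = []
        for perm in itertools.permutations(range(5)):
            rhos.append(np.corrcoef(rx, ry[list(perm)])[0, 1])
        count = sum(abs(r) >= abs(rho_obs) - 1e-12 for r in rhos)
        assert p_exact == pytest.approx(count / 120)

    def test_exact_p_matches_scipy_exhaustive_permutation(self):
        """Cross-check against scipy.permutation_test at n = 7 (7! pairings)."""
        rng = np.random.default_rng(12)
        x, y = rng.normal(size=7), rng.normal(size=7)

        def statistic(yy):
            return np.corrcoef(sps.rankdata(x), sps.rankdata(yy))[0, 1]

        import math

        ref = sps.permutation_test(
            (y,), statistic, permutation_type="pairings",
            n_resamples=math.factorial(7), alternative="two-sided",
        )
        _, p_exact = tc.spearman(x, y, method="exact")
        assert p_exact == pytest.approx(ref.pvalue, abs=1e-12)

    def test_tied_ranks_match_scipy_rho(self):
        x = [1, 2, 2, 3, 4, 5, 5, 6]
        y = [3, 1, 4, 4, 5, 7, 6, 9]
        rho, _ = tc.spearman(x, y)
        assert rho == pytest.approx(sps.spearmanr(x, y).statistic)

    def test_constant_input_returns_nan(self):
        rho, p = tc.spearman([1, 1, 1, 1], [1, 2, 3, 4])
        assert np.isnan(rho) and np.isnan(p)


class TestCorrelationTable:
    def test_54_rows_with_bh_column(self, exp1_trials, small_cohort):
        tab = tc.extreme_value_correlations(
            exp1_trials, small_cohort, method="asymptotic"
        )
        assert list(tab.columns) == CORRELATION_COLUMNS
        assert len(tab) == 54
        assert (tab["n"] == 10).all()
        valid = tab.dropna(subset=["p"])
        assert (valid["q_bh"] >= valid["p"] - 1e-15).all()

    def test_constant_ratings_flag_all_rows(self, exp1_trials):
        from tests.test_metrics import _constant_responses

        resp = _constant_responses(exp1_trials, 3)
        tab = tc.extreme_value_correlations(exp1_trials, resp, method="asymptotic")
        assert tab["flagged"].all()
        assert tab["rho"].isna().all()


class TestPosthocCascade:
    def test_closed_gates_give_empty_cascade(self):
        rng = np.random.default_rng(30)
        y = rng.normal(size=(10, 3, 3, 2))
        summ = summaries_from_array(y)
        eff = tc.rm_anova(summ)
        casc = tc.posthoc_cascade(summ, eff, alpha=1e-12)
        assert casc.empty

    def test_bonferroni_adjustment_per_stage(self, small_summaries):
        eff = tc.rm_anova(small_summaries)
        casc = tc.posthoc_cascade(small_summaries, eff)
        for _, r in casc.iterrows():
            assert r["p_adj"] == pytest.approx(min(1.0, r["m_stage"] * r["p"]))

    def test_pure_precision_effect_opens_pairwise_branch(self):
        """A strong precision main effect alone opens the pairwise stage in
        >= 95% of replicates."""
        rng = np.random.default_rng(77)
        opened = 0
        reps = 100
        for _ in range(reps):
            y = rng.normal(0, 0.5, size=(12, 3, 3, 2))
            y += np.array([-1.0, 0.0, 1.0])[None, :, None, None]
            summ = summaries_from_array(y)
            eff = tc.rm_anova(summ)
            casc = tc.posthoc_cascade(summ, eff)
            rows = casc[(casc["stage"] == "pairwise_precision")
                        & (casc["context"] == "all")]
            opened += len(rows) == 3 and rows["significant"].all()
        assert opened >= 95

    def test_three_way_interaction_opens_breakdown(self):
        rng = np.random.default_rng(15)
        y = rng.normal(0, 0.3, size=(14, 3, 3, 2))
        bump = np.zeros((3, 3, 2))
        bump[2, 2, 0] = 2.0  # cell-specific effect drives the 3-way term
        y += bump
        summ = summaries_from_array(y)
        eff = tc.rm_anova(summ)
        p3 = eff.loc[eff["effect"] == "precision:mean_change:direction",
                     "p_reported"].iloc[0]
        assert p3 < 0.05
        casc = tc.posthoc_cascade(summ, eff)
        assert (casc["stage"] == "two_way_breakdown").any()
        assert (casc["stage"] == "simple_main_effect").any()


class TestPatternClassifier:
    def test_deterministic_increasing_is_bayesian(self):
        y = np.tile(np.array([1.0, 2.0, 3.0])[None, :, None, None], (6, 1, 3, 2))
        y += np.arange(6)[:, None, None, None] * 0.1  # subject offsets
        lab = tc.classify_precision_pattern(summaries_from_array(y))
        assert lab.label == "bayesian"
        assert lab.slope_statistic == pytest.approx(2.0)

    def test_deterministic_decreasing_is_counter(self):
        y = np.tile(np.array([3.0, 2.0, 1.0])[None, :, None, None], (6, 1, 3, 2))
        lab = tc.classify_precision_pattern(summaries_from_array(y))
        assert lab.label == "counter_bayesian"

    def test_nonmonotone_is_mixed(self):
        y = np.tile(np.array([3.0, 1.0, 3.0])[None, :, None, None], (8, 1, 3, 2))
        rng = np.random.default_rng(2)
        y += rng.normal(0, 0.05, size=y.shape)
        lab = tc.classify_precision_pattern(summaries_from_array(y))
        assert lab.label == "mixed"

    def test_null_pattern_mostly_non_bayesian(self):
        """Flat truth is labelled non-Bayesian at roughly 1 - alpha rate."""
        rng = np.random.default_rng(10)
        labels = [
            tc.classify_precision_pattern(
                summaries_from_array(rng.normal(size=(20, 3, 3, 2)))
            ).label
            for _ in range(200)
        ]
        rate = labels.count("non_bayesian") / len(labels)
        assert 0.85 <= rate <= 1.0

    def test_slice_selection(self, small_summaries):
        lab = tc.classify_precision_pattern(
            small_summaries, mean_change_level="high", direction="up"
        )
        assert lab.slice_id == "mean_change=high;direction=up"
        table = tc.classify_patterns(small_summaries)
        assert len(table) == 7  # overall + 6 slices
        assert set(table["label"]) <= set(
            ("bayesian", "non_bayesian", "counter_bayesian", "mixed")
        )
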