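"""Two-way ANOVA and Bonferroni post hoc: oracle equivalence and calibration."""

import numpy as np
import pandas as pd
import pytest

from idepsep.stats import bonferroni_posthoc, two_way_anova


def _make_obs(rng, n_levels=9, reps=(3, 4), cond_names=("n", "g"), means=None, sd=0.1):
    rows = []
    for c, (cond, n_rep) in enumerate(zip(cond_names, reps)):
        for lev in range(n_levels):
            mu = 0.5 if means is None else means[c][lev]
            for r in range(n_rep):
                rows.append(
                    {
                        "condition": cond,
                        "ekmr_level": lev,
                        "replicate": f"r{r + 1}",
                        "intensity": mu + sd * rng.standard_normal(),
                    }
                )
    return pd.DataFrame(rows)


def brute_force_anova(obs):
    """Cell-means sums of squares for a *balanced* two-way layout."""
    y = obs["intensity"].to_numpy()
    a_lab = obs["condition"].to_numpy()
    b_lab = obs["ekmr_level"].to_numpy()
    a_levels, b_levels = np.unique(a_lab), np.unique(b_lab)
    n = len(y) // (len(a_levels) * len(b_levels))
    grand = y.mean()
    mean_a = {a: y[a_lab == a].mean() for a in a_levels}
    mean_b = {b: y[b_lab == b].mean() for b in b_levels}
    mean_ab = {
        (a, b): y[(a_lab == a) & (b_lab == b)].mean()
        for a in a_levels
        for b in b_levels
    }
    ss_a = len(b_levels) * n * sum((mean_a[a] - grand) ** 2 for a in a_levels)
    ss_b = len(a_levels) * n * sum((mean_b[b] - grand) ** 2 for b in b_levels)
    ss_ab = n * sum(
        (mean_ab[a, b] - mean_a[a] - mean_b[b] + grand) ** 2
        for a in a_levels
        for b in b_levels
    )
    ss_e = sum(
        ((y[(a_lab == a) & (b_lab == b)] - mean_ab[a, b]) ** 2).sum()
        for a in a_levels
        for b in b_levels
    )
    return ss_a, ss_b, ss_ab, ss_e


class TestTwoWayAnova:
    def test_reference_design_df_structure(self):
        """2 conditions × 9 levels with 3 and 4 replicates ⇒ F(8, 45)."""
        obs = _make_obs(np.random.default_rng(0))
        res = two_way_anova(obs)
        assert res.interaction_df == 8
        assert res.error_df == 45

    @pytest.mark.parametrize("shape", [(2, 2, 3), (3, 3, 2), (2, 3, 3)])
    def test_balanced_designs_match_brute_force(self, shape):
        n_cond, n_lev, n_rep = shape
        rng = np.random.default_rng(42)
        obs = _make_obs(
            rng,
            n_levels=n_lev,
            reps=(n_rep,) * n_cond,
            cond_names=tuple(f"c{i}" for i in range(n_cond)),
        )
        res = two_way_anova(obs)
        ss_a, ss_b, ss_ab, ss_e = brute_force_anova(obs)
        eff = res.effects.set_index("term")["sum_of_squares"]
        assert eff["condition"] == pytest.approx(ss_a, rel=1e-8)
        assert eff["ekmr_level"] == pytest.approx(ss_b, rel=1e-8)
        assert eff["condition:ekmr_level"] == pytest.approx(ss_ab, rel=1e-8)
        assert eff["Residual"] == pytest.approx(ss_e, rel=1e-8)

    def test_balanced_ss_decomposition_is_exact(self):
        obs = _make_obs(np.random.default_rng(3), n_levels=4, reps=(3, 3))
        res = two_way_anova(obs)
        total = ((obs["intensity"] - obs["intensity"].mean()) ** 2).sum()
        assert res.effects["sum_of_squares"].sum() == pytest.approx(total, rel=1e-8)

    def test_identical_cells_give_undefined_F(self):
        obs = _make_obs(np.random.default_rng(0), n_levels=3, reps=(2, 2), sd=0.0)
        res = two_way_anova(obs)
        assert res.effects.set_index("term").loc["Residual", "sum_of_squares"] == pytest.approx(0.0, abs=1e-20)
        assert np.isnan(res.interaction_F)

    def test_empty_cell_rejected(self):
        obs = _make_obs(np.random.default_rng(1), n_levels=3, reps=(2, 2))
        obs = obs[~((obs.condition == "g") & (obs.ekmr_level == 2))]
        with pytest.raises(ValueError, match="empty"):
            two_way_anova(obs)

    def test_single_condition_rejected(self):
        obs = _make_obs(np.random.default_rng(1), n_levels=3, reps=(3,), cond_names=("n",))
        with pytest.raises(ValueError):
            two_way_anova(obs)

    def test_type_one_error_calibration(self):
        """Under the null, the interaction test rejects at ≈ α = 0.05.

        1000 simulated experiments in the reference layout (2 × 9, n = 3/4)
        with both conditions drawn from the same per-level means; the
        rejection rate must fall inside a 3-sigma binomial band around 0.05.
        """
        rng = np.random.default_rng(2024)
        level_means = rng.uniform(0.2, 0.8, size=9)
        means = (level_means, level_means)
        n_sims, alpha = 1000, 0.05
        rejections = 0
        for _ in range(n_sims):
            obs = _make_obs(rng, means=means, sd=0.05)
            res = two_way_anova(obs)
            if res.interaction_p < alpha:
                rejections += 1
        rate = rejections / n_sims
        band = 3 * np.sqrt(alpha * (1 - alpha) / n_sims)
        assert abs(rate - alpha) < band


class TestBonferroniPosthoc:
    def test_nine_levels_nine_comparisons(self):
        obs = _make_obs(np.random.default_rng(5))
        out = bonferroni_posthoc(obs)
        assert len(out) == 9
        # correction multiplier is the level count
        np.testing.assert_allclose(
            out["bonferroni_p"], np.minimum(out["raw_p"] * 9, 1.0)
        )

    def test_corrected_p_at_least_raw(self):
        obs = _make_obs(np.random.default_rng(6), n_levels=5)
        out = bonferroni_posthoc(obs)
        assert (out["bonferroni_p"] >= out["raw_p"] - 1e-15).all()
        assert (out["bonferroni_p"] <= 1.0).all()

    def test_identical_means_not_significant(self):
        obs = _make_obs(np.random.default_rng(7), n_levels=3, reps=(3, 3), sd=0.0)
        obs["intensity"] += np.tile([0.0, 1e-3, 0.0], len(obs) // 3)[: len(obs)]
        out = bonferroni_posthoc(obs)
        assert not out["significant"].any()

    def test_detects_single_shifted_level(self):
        rng = np.random.default_rng(8)
        means_n = np.full(9, 0.5)
        means_g = means_n.copy()
        means_g[4] = 0.9  # one level strongly shifted
        obs = _make_obs(rng, means=(means_n, means_g), sd=0.05)
        out = bonferroni_posthoc(obs)
        assert bool(out.loc[out.ekmr_level == 4, "significant"].iloc[0])
        assert out["significant"].sum() == 1
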