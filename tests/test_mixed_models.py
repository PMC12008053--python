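import numpy as np
import pandas as pd
import pytest

from phylopart.mixed_models import (
    NestingSpec,
    anova_balanced_oneway,
    env_screen,
    group_interaction_test,
    variance_decomposition,
)


def _balanced_oneway(seed=0, g=10, r=10, sd_group=2.0, sd_resid=1.0):
    rng = np.random.default_rng(seed)
    groups = np.repeat(np.arange(g), r)
    y = sd_group * rng.standard_normal(g)[groups] + sd_resid * rng.standard_normal(g * r)
    return pd.DataFrame({"log_sla": y, "grp": groups.astype(str)}), y, groups


class TestVarianceDecomposition:
    def test_balanced_design_matches_anova_closed_form(self):
        """On balanced data REML equals the ANOVA method-of-moments
        estimator, the independent closed-form oracle."""
        df, y, groups = _balanced_oneway()
        vc = variance_decomposition(df, NestingSpec(["grp"]))
        an = anova_balanced_oneway(y, groups)
        total = an["group"] + an["residual"]
        assert vc.fractions["grp"] == pytest.approx(an["group"] / total, abs=1e-6)
        assert vc.fractions["residual"] == pytest.approx(
            an["residual"] / total, abs=1e-6
        )

    def test_within_group_constant(self):
        g = np.repeat(np.arange(6), 5)
        y = np.array([0.0, 1, 2, 3, 4, 5])[g]
        df = pd.DataFrame({"log_sla": y, "grp": g.astype(str)})
        vc = variance_decomposition(df, NestingSpec(["grp"]))
        assert vc.fractions["grp"] == pytest.approx(1.0, abs=1e-6)
        assert vc.fractions["residual"] == pytest.approx(0.0, abs=1e-6)

    def test_fraction_invariance_under_affine_response(self):
        df, _, _ = _balanced_oneway(seed=3)
        base = variance_decomposition(df, NestingSpec(["grp"])).fractions
        df2 = df.assign(log_sla=5.0 * df["log_sla"] + 7.0)
        scaled = variance_decomposition(df2, NestingSpec(["grp"])).fractions
        for k in base:
            assert scaled[k] == pytest.approx(base[k], abs=1e-5)

    def test_nested_two_level_recovery(self):
        rng = np.random.default_rng(4)
        n_site, n_sp, r = 12, 6, 4
        site = np.repeat(np.arange(n_site), n_sp * r)
        sp = np.tile(np.repeat(np.arange(n_sp), r), n_site)
        y = (
            1.2 * rng.standard_normal(n_site)[site]
            + 0.8 * rng.standard_normal((n_site, n_sp))[site, sp]
            + 0.5 * rng.standard_normal(len(site))
        )
        df = pd.DataFrame(
            {"log_sla": y, "site_id": site.astype(str), "species": sp.astype(str)}
        )
        vc = variance_decomposition(df, NestingSpec(["site_id", "species"]))
        true = np.array([1.2**2, 0.8**2, 0.5**2])
        true = true / true.sum()
        assert vc.fractions["site_id"] == pytest.approx(true[0], abs=0.15)
        assert vc.fractions["species"] == pytest.approx(true[1], abs=0.15)
        assert sum(vc.fractions.values()) == pytest.approx(1.0, abs=1e-8)

    def test_singleton_innermost_level_warns(self):
        rng = np.random.default_rng(5)
        g = np.arange(40)  # every group a singleton
        df = pd.DataFrame(
            {
                "log_sla": rng.standard_normal(40),
                "site_id": (g // 10).astype(str),
                "species": g.astype(str),
            }
        )
        vc = variance_decomposition(df, NestingSpec(["site_id", "species"]))
        assert vc.warnings
        assert sum(vc.fractions.values()) == pytest.approx(1.0)

    def test_single_group_level_fatal(self):
        df = pd.DataFrame({"log_sla": [1.0, 2.0], "grp": ["a", "a"]})
        with pytest.raises(ValueError, match="< 2 groups"):
            variance_decomposition(df, NestingSpec(["grp"]))


def _screen_frame(seed, n=240, n_sp=40, beta=0.5, quad=0.0, sd_sp=0.4, sd_e=0.1):
    rng = np.random.default_rng(seed)
    sp = rng.integers(0, n_sp, n)
    env = rng.standard_normal(n)
    y = (
        beta * env
        + quad * env**2
        + sd_sp * rng.standard_normal(n_sp)[sp]
        + sd_e * rng.standard_normal(n)
    )
    return pd.DataFrame(
        {"log_sla": y, "species": sp.astype(str), "mat": env}
    )


class TestEnvScreen:
    def test_linear_signal_chooses_degree_one_and_recovers_r2(self):
        """Near-noiseless linear generation: degree 1 and the marginal R^2
        close to the generating variance fraction."""
        got_r2, degrees = [], []
        for seed in range(10):
            df = _screen_frame(seed, beta=0.5, sd_sp=0.4, sd_e=0.05)
            res = env_screen(df, "mat")
            degrees.append(res.degree)
            got_r2.append(res.marginal_r2)
        # AIC admits a spurious quadratic term with small probability
        assert degrees.count(1) >= 7
        want_r2 = 0.25 / (0.25 + 0.16 + 0.0025)
        assert np.mean(got_r2) == pytest.approx(want_r2, abs=0.05)

    def test_parabolic_signal_chooses_degree_two(self):
        df = _screen_frame(3, beta=0.0, quad=0.4)
        res = env_screen(df, "mat")
        assert res.degree == 2
        assert res.aic[2] < res.aic[1]

    def test_chosen_degree_has_lower_aic(self):
        df = _screen_frame(4)
        res = env_screen(df, "mat")
        assert res.aic[res.degree] == min(res.aic.values())
        assert 0.0 <= res.marginal_r2 <= 1.0

    def test_too_few_distinct_values_fatal(self):
        df = pd.DataFrame(
            {"log_sla": [1.0, 2, 3, 4], "species": list("aabb"), "mat": [1.0, 1, 2, 2]}
        )
        with pytest.raises(ValueError, match="distinct"):
            env_screen(df, "mat")

    def test_missing_rows_dropped(self):
        df = _screen_frame(5)
        df.loc[:10, "mat"] = np.nan
        res = env_screen(df, "mat")
        assert res.n == len(df) - 11


class TestGroupInteraction:
    def test_one_level_group_fatal(self):
        df = _screen_frame(6)
        df["cl"] = "a"
        with pytest.raises(ValueError, match="2 levels"):
            group_interaction_test(df, "mat", "cl")

    def test_small_group_fatal(self):
        df = _screen_frame(7)
        df["cl"] = np.where(np.arange(len(df)) < 5, "g", "a")
        with pytest.raises(ValueError, match="fewer than"):
            group_interaction_test(df, "mat", "cl")

    def test_type_one_error_calibration(self):
        """Identical generating slopes: rejection near the nominal level."""
        rejections = 0
        n_rep = 60
        for seed in range(n_rep):
            df = _screen_frame(100 + seed, n=160, n_sp=30)
            rng = np.random.default_rng(seed)
            df["cl"] = np.where(rng.random(len(df)) < 0.5, "a", "g")
            p = group_interaction_test(df, "mat", "cl", degree=1)
            rejections += p < 0.05
        assert rejections / n_rep <= 0.15

    def test_power_against_opposite_slopes(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(200 + seed)
            n, n_sp = 400, 40
            sp = rng.integers(0, n_sp, n)
            env = rng.standard_normal(n)
            grp = rng.random(n) < 0.5
            y = (
                np.where(grp, 1.0, -1.0) * env
                + 0.5 * rng.standard_normal(n_sp)[sp]
                + 0.5 * rng.standard_normal(n)
            )
            df = pd.DataFrame(
                {
                    "log_sla": y,
                    "species": sp.astype(str),
                    "mat": env,
                    "cl": np.where(grp, "a", "g"),
                }
            )
            hits += group_interaction_test(df, "mat", "cl", degree=1) < 0.05
        assert hits >= 9
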