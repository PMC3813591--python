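"""Tests of per-image normalization, assumption checks, ANOVA effect
fractions and t tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stripecluster.errors import MissingDesignCellError
from stripecluster.stats import (anova_effects, bonferroni_adjust,
                                 check_assumptions, normalize_within_image,
                                 one_sample_t, two_sample_t)

STRAINS = ("KD", "wt")
STIMULI = ("CD3", "CD3+CD28")


def make_records(n_images, surface_effect=0.0, strain_effect=0.0,
                 noise_sd=0.1, image_scale_sd=0.3, seed=0,
                 property_name="prop"):
    """Simulate raw per-image combo values with multiplicative factor
    effects, a lognormal per-image scale (what normalization removes) and
    within-image noise."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_images):
        scale = np.exp(rng.normal(0.0, image_scale_sd))
        for strain in STRAINS:
            for stim in STIMULI:
                mu = 1.0
                mu *= 1.0 + strain_effect / 2.0 if strain == "KD" \
                    else 1.0 - strain_effect / 2.0
                mu *= 1.0 + surface_effect / 2.0 if stim == "CD3+CD28" \
                    else 1.0 - surface_effect / 2.0
                value = scale * (mu + rng.normal(0.0, noise_sd))
                rows.append({"image_id": f"img{i:03d}", "strain": strain,
                             "stimulus": stim, "property": property_name,
                             "value": value})
    return pd.DataFrame(rows)


class TestNormalizeWithinImage:
    def test_simple_arithmetic(self):
        df = pd.DataFrame({
            "image_id": ["a"] * 4, "property": ["p"] * 4,
            "value": [2.0, 4.0, 6.0, 8.0]})
        out = normalize_within_image(df)
        assert out["normalized"].tolist() == [0.4, 0.8, 1.2, 1.6]

    def test_equal_combos_normalize_to_one(self):
        df = pd.DataFrame({
            "image_id": ["a"] * 4, "property": ["p"] * 4,
            "value": [5.0] * 4})
        out = normalize_within_image(df)
        assert (out["normalized"] == 1.0).all()

    def test_renormalization_is_identity(self):
        df = make_records(5, surface_effect=0.2, seed=1)
        once = normalize_within_image(df)
        twice = normalize_within_image(
            once.drop(columns=["value", "excluded"])
                .rename(columns={"normalized": "value"}))
        assert np.allclose(once["normalized"], twice["normalized"])

    def test_zero_mean_group_flagged_excluded(self):
        df = pd.DataFrame({
            "image_id": ["a", "a"], "property": ["p", "p"],
            "value": [0.0, 0.0]})
        out = normalize_within_image(df)
        assert out["excluded"].all()
        assert out["normalized"].isna().all()

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(values=st.lists(st.floats(0.1, 100.0), min_size=2, max_size=6))
    def test_normalized_mean_is_exactly_one(self, values):
        df = pd.DataFrame({"image_id": "a", "property": "p",
                           "value": values})
        out = normalize_within_image(df)
        assert out["normalized"].mean() == pytest.approx(1.0, abs=1e-12)

    def test_pooling_invariant_under_image_order(self):
        df = make_records(8, surface_effect=0.2, strain_effect=0.1, seed=3)
        shuffled = df.sample(frac=1.0, random_state=5).reset_index(drop=True)
        res1 = anova_effects(normalize_within_image(df), "prop")
        res2 = anova_effects(normalize_within_image(shuffled), "prop")
        for e1, e2 in zip(res1.effects, res2.effects):
            assert e1.effect_fraction == pytest.approx(e2.effect_fraction)
            assert e1.p_value == pytest.approx(e2.p_value)


class TestCheckAssumptions:
    def test_normal_subgroups_pass_at_expected_rate(self):
        # KS against the subgroup's own mean/sd is conservative, so the
        # pass rate should be at least nominal (>= 95%)
        passed = 0
        total = 0
        for seed in range(60):
            df = normalize_within_image(make_records(12, seed=seed))
            report = check_assumptions(df, "prop")
            passed += sum(p >= 0.05 for p in report.ks_p.values())
            total += len(report.ks_p)
        assert passed / total >= 0.95

    def test_heavy_tailed_subgroup_is_flagged(self):
        rng = np.random.default_rng(0)
        flagged = 0
        for _ in range(20):
            rows = []
            for strain in STRAINS:
                for stim in STIMULI:
                    if strain == "KD" and stim == "CD3":
                        vals = rng.standard_cauchy(200)
                    else:
                        vals = rng.normal(0, 1, 200)
                    for v in vals:
                        rows.append({"image_id": "x", "strain": strain,
                                     "stimulus": stim, "property": "p",
                                     "normalized": v})
            report = check_assumptions(pd.DataFrame(rows), "p")
            if not report.normality_pass:
                flagged += 1
        assert flagged >= 18  # heavy tails detected with high probability

    def test_constant_subgroup_flagged_degenerate(self):
        rows = []
        for strain in STRAINS:
            for stim in STIMULI:
                for _ in range(5):
                    rows.append({"image_id": "x", "strain": strain,
                                 "stimulus": stim, "property": "p",
                                 "normalized": 1.0})
        report = check_assumptions(pd.DataFrame(rows), "p")
        assert not report.variance_pass
        assert all("degenerate" in r for r in report.skipped.values())

    def test_tiny_subgroup_skipped(self):
        rows = [{"image_id": "x", "strain": s, "stimulus": t,
                 "property": "p", "normalized": v}
                for s in STRAINS for t in STIMULI
                for v in ([1.0, 1.1, 0.9, 1.05] if s == "KD" else [1.0])]
        report = check_assumptions(pd.DataFrame(rows), "p")
        assert any("n < 3" in r for r in report.skipped.values())


class TestAnovaEffects:
    def test_equal_group_means_give_zero_effect(self):
        # a pure-interaction pattern: both factors' level means are exactly
        # equal, residuals nonzero -> effect 0, t = 0, p = 1
        pattern = {("KD", "CD3"): 1.0, ("KD", "CD3+CD28"): 1.2,
                   ("wt", "CD3"): 1.2, ("wt", "CD3+CD28"): 1.0}
        rows = [{"image_id": f"i{i}", "strain": s, "stimulus": t,
                 "property": "p", "normalized": v}
                for i in range(6) for (s, t), v in pattern.items()]
        res = anova_effects(pd.DataFrame(rows), "p")
        for e in res.effects:
            assert e.effect_fraction == pytest.approx(0.0, abs=1e-10)
            assert e.p_value > 0.99

    def test_recovers_planted_effects(self):
        df = normalize_within_image(make_records(
            60, surface_effect=0.20, strain_effect=0.08, noise_sd=0.08,
            seed=42))
        res = anova_effects(df, "prop")
        by_factor = {e.factor: e for e in res.effects}
        surf = by_factor["stimulus"]
        strain = by_factor["strain"]
        sign_surf = 1.0 if surf.contrast.startswith("CD3+CD28") else -1.0
        sign_str = 1.0 if strain.contrast.startswith("KD") else -1.0
        assert sign_surf * surf.effect_fraction == pytest.approx(0.20,
                                                                 abs=0.05)
        assert sign_str * strain.effect_fraction == pytest.approx(0.08,
                                                                  abs=0.05)
        assert res.model_p < 1e-6

    def test_ci_covers_planted_value_at_nominal_rate(self):
        cover = 0
        n_rep = 120
        for seed in range(n_rep):
            df = normalize_within_image(make_records(
                20, surface_effect=0.2, noise_sd=0.1, seed=seed))
            res = anova_effects(df, "prop")
            e = [x for x in res.effects if x.factor == "stimulus"][0]
            sign = 1.0 if e.contrast.startswith("CD3+CD28") else -1.0
            lo, hi = sorted((sign * e.ci_low, sign * e.ci_high))
            if lo <= 0.2 <= hi:
                cover += 1
        # nominal 95%; binomial 3-sigma band around it for n_rep = 120
        assert cover / n_rep >= 0.95 - 3 * np.sqrt(0.95 * 0.05 / n_rep)

    def test_type_i_error_controlled_with_null_effects(self):
        rejections = 0
        n_rep = 300
        for seed in range(n_rep):
            df = normalize_within_image(make_records(12, seed=10_000 + seed))
            res = anova_effects(df, "prop")
            e = [x for x in res.effects if x.factor == "strain"][0]
            if e.p_value < 0.05:
                rejections += 1
        rate = rejections / n_rep
        assert 0.05 - 0.035 < rate < 0.05 + 0.035

    def test_missing_design_cell_raises_named_error(self):
        df = normalize_within_image(make_records(4, seed=0))
        df = df[~((df["strain"] == "wt") & (df["stimulus"] == "CD3"))]
        with pytest.raises(MissingDesignCellError, match="wt"):
            anova_effects(df, "prop")

    def test_interaction_p_reported(self):
        df = normalize_within_image(make_records(10, surface_effect=0.2,
                                                 seed=7))
        res = anova_effects(df, "prop", check_interaction=True)
        assert res.interaction_p is not None
        assert 0.0 <= res.interaction_p <= 1.0

    def test_one_image_per_experiment_limit_equals_mean_difference(self):
        """With balanced data the additive-model strain effect equals the
        raw difference of strain means (closed form)."""
        df = normalize_within_image(make_records(6, strain_effect=0.1,
                                                 noise_sd=0.05, seed=2))
        res = anova_effects(df, "prop")
        e = [x for x in res.effects if x.factor == "strain"][0]
        means = df.groupby("strain")["normalized"].mean()
        named = e.contrast.split(" - ")[0]
        other = e.contrast.split(" - ")[1]
        diff = means[named] - means[other]
        grand = df["normalized"].mean()
        assert e.effect_fraction == pytest.approx(diff / grand, abs=1e-10)


class TestTTests:
    def test_identical_groups_give_p_one(self):
        res = two_sample_t([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_sps_all_exactly_one_gives_t_zero(self):
        res = one_sample_t([1.0, 1.0, 1.0, 1.0], popmean=1.0)
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_zero_variance_with_different_means_raises(self):
        with pytest.raises(ValueError):
            two_sample_t([1.0, 1.0], [2.0, 2.0])
        with pytest.raises(ValueError):
            one_sample_t([2.0, 2.0], popmean=1.0)

    def test_clear_preference_detected_with_high_power(self):
        # SPS ~ N(1.3, 0.2), n = 40: one-sample p < 0.001 nearly always
        detected = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            vals = rng.normal(1.3, 0.2, 40)
            if one_sample_t(vals, popmean=1.0).p_value < 0.001:
                detected += 1
        assert detected >= 99

    def test_two_sample_against_scipy(self):
        from scipy import stats as sps_mod

        rng = np.random.default_rng(1)
        x, y = rng.normal(0, 1, 12), rng.normal(0.5, 1, 15)
        res = two_sample_t(x, y)
        ref = sps_mod.ttest_ind(x, y, equal_var=True)
        assert res.statistic == pytest.approx(ref.statistic)
        assert res.p_value == pytest.approx(ref.pvalue)


class TestBonferroni:
    @pytest.mark.parametrize("p,m,expected,sig", [
        (0.02, 3, 0.06, False),
        (0.001, 3, 0.003, True),
        (0.04, 1, 0.04, True),
    ])
    def test_adjustment(self, p, m, expected, sig):
        adj, flags = bonferroni_adjust([p], m)
        assert adj[0] == pytest.approx(expected)
        assert flags[0] == sig

    def test_caps_at_one(self):
        adj, _ = bonferroni_adjust([0.7], 5)
        assert adj[0] == 1.0
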