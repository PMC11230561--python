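"""The eleven pigmentation measures and the trait-level statistics."""

import numpy as np
import pandas as pd
import pytest

import barqtl as b
from conftest import random_profile


def three_block_profile(scale=0.01):
    vals = np.concatenate([np.full(10, 200.0), np.full(10, 50.0), np.full(10, 200.0)])
    return b.IntensityProfile(vals, scale_cm_per_px=scale, individual_id="toy")


class TestComputeTraits:
    def test_three_block_worked_example(self):
        p = three_block_profile()
        tv = b.compute_traits(p, b.segment_bars(p))
        assert tv.darkest_intensity == 50
        assert tv.lightest_intensity == 200
        assert tv.range_intensity == 150
        assert tv.avg_bar_intensity == 50
        assert tv.avg_interbar_intensity == 200
        assert tv.differential_intensity == 150
        assert tv.n_bars == 1
        assert tv.percent_barring == pytest.approx(1 / 3)
        assert tv.avg_bar_width_cm == pytest.approx(0.10)
        assert tv.avg_interbar_width_cm == pytest.approx(0.10)

    def test_covariance_is_sample_covariance_with_position(self):
        p = b.IntensityProfile(np.arange(100, dtype=float), scale_cm_per_px=0.01)
        tv = b.compute_traits(p, b.segment_bars(p))
        # cov(x, x) = var(0..99) with n-1 denominator
        assert tv.covariance == pytest.approx(np.var(np.arange(100.0), ddof=1))
        assert tv.covariance == pytest.approx(841.6666666, rel=1e-9)

    def test_positional_variance_alternative_definition(self):
        p = three_block_profile()
        tv = b.compute_traits(p, positional_variance=True)
        assert tv.covariance == pytest.approx(np.var(p.values, ddof=1))

    def test_constant_profile_bar_traits_missing(self):
        p = b.IntensityProfile(np.full(80, 120.0), scale_cm_per_px=0.01)
        tv = b.compute_traits(p, b.segment_bars(p))
        assert tv.range_intensity == 0
        assert tv.n_bars == 0
        assert tv.percent_barring == 0
        assert np.isnan(tv.avg_bar_intensity)
        assert np.isnan(tv.avg_bar_width_cm)
        assert np.isnan(tv.differential_intensity)

    def test_mismatched_segmentation_rejected(self, rng):
        p = random_profile(rng, length=100)
        seg = b.segment_bars(random_profile(rng, length=90))
        with pytest.raises(ValueError, match="length"):
            b.compute_traits(p, seg)

    @pytest.mark.parametrize("seed", range(8))
    def test_identities_on_random_profiles(self, seed):
        rng = np.random.default_rng(seed + 100)
        p = random_profile(rng)
        seg = b.segment_bars(p)
        tv = b.compute_traits(p, seg)
        assert tv.range_intensity == tv.lightest_intensity - tv.darkest_intensity
        bar_px = sum(e - s for s, e in seg.bars)
        assert tv.percent_barring * p.length_px == pytest.approx(bar_px)
        if tv.n_bars > 0:
            # percent_barring = n_bars * mean bar width (px) / length
            width_px = tv.avg_bar_width_cm / p.scale_cm_per_px
            assert tv.percent_barring == pytest.approx(
                tv.n_bars * width_px / p.length_px
            )
            if seg.interbars:
                assert tv.differential_intensity == pytest.approx(
                    tv.avg_interbar_intensity - tv.avg_bar_intensity
                )


class TestResidualize:
    def make_table(self, rng, n=60):
        sl = rng.uniform(3, 6, n)
        return pd.DataFrame(
            {
                "standard_length_cm": sl,
                "lin": 2.0 * sl + 1.0,
                "noisy": rng.normal(0, 1, n) + 0.5 * sl,
            }
        )

    def test_perfectly_allometric_trait_residuals_zero(self, rng):
        out = b.residualize(self.make_table(rng), traits=["lin"])
        assert np.allclose(out["lin_resid"], 0.0, atol=1e-10)

    def test_residuals_orthogonal_to_length(self, rng):
        out = b.residualize(self.make_table(rng), traits=["noisy"])
        r = np.corrcoef(out["noisy_resid"], out["standard_length_cm"])[0, 1]
        assert abs(r) < 1e-10

    def test_idempotent(self, rng):
        out = b.residualize(self.make_table(rng), traits=["noisy"])
        out2 = b.residualize(out, traits=["noisy_resid"])
        assert np.allclose(out2["noisy_resid_resid"], out["noisy_resid"], atol=1e-10)

    def test_constant_length_rejected(self, rng):
        tab = self.make_table(rng)
        tab["standard_length_cm"] = 4.0
        with pytest.raises(ValueError, match="zero variance"):
            b.residualize(tab, traits=["noisy"])

    def test_too_few_rows_rejected(self, rng):
        tab = self.make_table(rng).head(2)
        with pytest.raises(ValueError, match=">= 3"):
            b.residualize(tab, traits=["noisy"])

    def test_fit_population_subset(self, rng):
        tab = self.make_table(rng)
        mask = np.zeros(len(tab), dtype=bool)
        mask[:30] = True
        out = b.residualize(tab, traits=["noisy"], fit_population=mask)
        r = np.corrcoef(out["noisy_resid"][:30], tab["standard_length_cm"][:30])[0, 1]
        assert abs(r) < 1e-10


class TestGroupCompare:
    def test_identical_constant_groups_give_f0_p1(self):
        res = b.group_compare([5.0] * 12, ["a"] * 4 + ["b"] * 4 + ["c"] * 4)
        assert res.f_statistic == 0.0
        assert res.p_value == 1.0

    def test_two_groups_tukey_matches_anova(self, rng):
        vals = rng.normal(0, 1, 40)
        grp = np.repeat(["x", "y"], 20)
        res = b.group_compare(vals, grp)
        assert res.tukey["p_adj"].iloc[0] == pytest.approx(res.p_value, abs=1e-6)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            b.group_compare([1.0, 2.0, 3.0], ["a", "a", "b"])

    def test_type_one_error_calibration(self):
        rng = np.random.default_rng(7)
        rejections = 0
        n_reps = 2000
        for _ in range(n_reps):
            vals = rng.normal(0, 1, 30)
            grp = np.repeat(["a", "b", "c"], 10)
            n = vals.size
            grand = vals.mean()
            ssb = sum(10 * (vals[grp == g].mean() - grand) ** 2 for g in "abc")
            ssw = sum(((vals[grp == g] - vals[grp == g].mean()) ** 2).sum() for g in "abc")
            from scipy import stats

            p = stats.f.sf((ssb / 2) / (ssw / (n - 3)), 2, n - 3)
            rejections += p < 0.05
        assert 0.04 <= rejections / n_reps <= 0.06
        # spot-check the wrapped implementation agrees with the direct formula
        vals = rng.normal(0, 1, 30)
        grp = np.repeat(["a", "b", "c"], 10)
        from scipy import stats

        res = b.group_compare(vals, grp)
        f_ref, p_ref = stats.f_oneway(*(vals[grp == g] for g in "abc"))
        assert res.f_statistic == pytest.approx(f_ref)
        assert res.p_value == pytest.approx(p_ref)


class TestCorrelations:
    def make_table(self, rng, n=300):
        cols = {f"t{i}": rng.normal(0, 1, n) for i in range(6)}
        cols["standard_length_cm"] = rng.uniform(3, 6, n)
        return pd.DataFrame(cols)

    def test_self_correlation_is_one(self, rng):
        tab = self.make_table(rng)
        r, _ = b.trait_correlations(tab, traits=["t0", "t1"], use_residuals=False)
        assert r.loc["t0", "t0"] == 1.0

    def test_independent_traits_mostly_uncorrelated(self, rng):
        tab = self.make_table(rng)
        traits = [f"t{i}" for i in range(6)]
        r, _ = b.trait_correlations(tab, traits=traits, use_residuals=False)
        off = r.loc[traits, traits].to_numpy()[np.triu_indices(6, 1)]
        assert (np.abs(off) < 0.2).mean() >= 0.95

    def test_affine_invariance(self, rng):
        tab = self.make_table(rng)
        r1, _ = b.trait_correlations(tab, traits=["t0", "t1"], use_residuals=False)
        tab2 = tab.assign(t0=3.0 * tab["t0"] - 11.0)
        r2, _ = b.trait_correlations(tab2, traits=["t0", "t1"], use_residuals=False)
        assert r1.loc["t0", "t1"] == pytest.approx(r2.loc["t0", "t1"])

    def test_zero_variance_trait_warns_and_nans(self, rng):
        tab = self.make_table(rng)
        tab["t0"] = 1.0
        with pytest.warns(UserWarning, match="zero variance"):
            r, _ = b.trait_correlations(tab, traits=["t0", "t1"], use_residuals=False)
        assert np.isnan(r.loc["t0", "t1"])

    def test_residual_columns_preferred(self, rng):
        tab = self.make_table(rng)
        tab["t0_resid"] = tab["t1"]  # residual column deliberately equals t1
        r, _ = b.trait_correlations(tab, traits=["t0", "t1"])
        assert r.loc["t0", "t1"] == pytest.approx(1.0)


def test_build_trait_table_from_population(rng):
    profiles = b.generate_population_profiles(
        b.default_cohorts(4, 4, 8), seed=3
    )
    table = b.build_trait_table(profiles)
    assert len(table) == 16
    assert set(b.TRAIT_NAMES) <= set(table.columns)
    assert table["group"].value_counts()["F2"] == 8
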