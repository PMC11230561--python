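"""Haley-Knott scan, permutation thresholds, intervals and effects."""

import numpy as np
import pytest

import barqtl as b
from barqtl.scan import ScanGroup, ScanResult
from _oracles import marker_lod_oracle


class TestScanHK:
    def test_marker_lod_matches_group_mean_oracle(self, small_cross, small_probs):
        res = b.scan_hk(small_probs, small_cross.phenotypes["pheno"])
        y = small_cross.phenotypes["pheno"].to_numpy()
        for lg in ("LG1", "LG2", "LG3"):
            g = res.group(lg)
            gp = small_probs.group(lg)
            for k in np.flatnonzero(gp.is_marker):
                marker = gp.marker_names[k]
                lod_ref, _ = marker_lod_oracle(
                    small_cross.genotypes[marker].to_numpy(), y
                )
                assert g.lod[k] == pytest.approx(lod_ref, abs=1e-8), marker

    def test_affine_phenotype_invariance(self, small_cross, small_probs):
        y = small_cross.phenotypes["pheno"]
        r1 = b.scan_hk(small_probs, y)
        r2 = b.scan_hk(small_probs, 3.0 * y + 7.0)
        for g1, g2 in zip(r1.groups, r2.groups):
            assert np.allclose(g1.lod, g2.lod, atol=1e-9)

    def test_lod_nonnegative_everywhere(self, small_cross, small_probs):
        res = b.scan_hk(small_probs, small_cross.phenotypes["pheno"])
        for g in res.groups:
            assert np.all(g.lod >= -1e-9)

    def test_planted_qtl_found_on_true_group(self, small_cross, small_probs):
        res = b.scan_hk(small_probs, small_cross.phenotypes["pheno"])
        lg, pos, lod = res.peak()
        assert lg == "LG2"
        assert abs(pos - 35.0) <= 10.0

    def test_zero_variance_phenotype_rejected(self, small_probs):
        with pytest.raises(ValueError, match="zero variance"):
            b.scan_hk(small_probs, np.ones(small_probs.n_individuals))

    def test_missing_phenotypes_dropped(self, small_cross, small_probs):
        y = small_cross.phenotypes["pheno"].copy()
        y.iloc[:50] = np.nan
        res = b.scan_hk(small_probs, y)
        assert res.max_lod() > 0

    def test_collinear_cofactor_dropped_with_warning(self, small_cross, small_probs):
        cof = b.Cofactor("LG2", 35.0)
        with pytest.warns(UserWarning, match="collinear"):
            res = b.scan_hk(
                small_probs, small_cross.phenotypes["pheno"], [cof, cof]
            )
        assert len(res.cofactors) == 1

    def test_cofactor_absorbs_linked_signal(self, small_cross, small_probs):
        y = small_cross.phenotypes["pheno"]
        plain = b.scan_hk(small_probs, y)
        with_cof = b.scan_hk(small_probs, y, [b.Cofactor("LG2", 35.0)])
        # moderately linked positions lose their signal once the QTL is a
        # cofactor (their marginal LOD was borrowed from the linked QTL)
        g0, g1 = plain.group("LG2"), with_cof.group("LG2")
        linked = (np.abs(g0.positions - 35.0) >= 15.0) & (
            np.abs(g0.positions - 35.0) <= 40.0
        )
        assert g1.lod[linked].max() < g0.lod[linked].max()
        # near the cofactor it is scanned with the cofactor dropped: unchanged
        near = np.abs(g0.positions - 35.0) < 10.0
        assert np.allclose(g0.lod[near], g1.lod[near], atol=1e-9)


class TestPermutationThresholds:
    def test_monotone_in_alpha_and_deterministic(self, small_cross, small_probs):
        y = small_cross.phenotypes["pheno"]
        thr1 = b.permutation_thresholds(small_probs, y, n_perm=200, seed=5)
        thr2 = b.permutation_thresholds(small_probs, y, n_perm=200, seed=5)
        assert thr1 == thr2
        assert thr1[0.05] >= thr1[0.10]

    def test_stable_across_seeds_at_1000_perms(self, small_cross, small_probs):
        y = small_cross.phenotypes["pheno"]
        a = b.permutation_thresholds(small_probs, y, n_perm=1000, seed=1)[0.05]
        c = b.permutation_thresholds(small_probs, y, n_perm=1000, seed=2)[0.05]
        assert abs(a - c) < 0.2

    def test_too_few_permutations_rejected(self, small_cross, small_probs):
        with pytest.raises(ValueError, match="n_perm"):
            b.permutation_thresholds(
                small_probs, small_cross.phenotypes["pheno"], n_perm=50
            )


class TestBayesInterval:
    def make_scan(self, lod):
        positions = np.arange(len(lod), dtype=float) * 2.0
        names = [f"m{k}" if k % 2 == 0 else None for k in range(len(lod))]
        return ScanResult("t", [ScanGroup("LG1", positions, np.asarray(lod, float), names)])

    def test_full_coverage_spans_group(self):
        scan = self.make_scan([1.0, 2.0, 5.0, 2.0, 1.0])
        ci = b.bayes_interval(scan, "LG1", coverage=1.0)
        assert (ci.lo_cM, ci.hi_cM) == (0.0, 8.0)

    def test_sharp_peak_single_step(self):
        lod = np.zeros(11)
        lod[5] = 20.0
        ci = b.bayes_interval(self.make_scan(lod), "LG1")
        assert ci.lo_cM == ci.hi_cM == 10.0

    def test_interval_contains_peak(self, small_cross, small_probs):
        res = b.scan_hk(small_probs, small_cross.phenotypes["pheno"])
        for lg in ("LG1", "LG2", "LG3"):
            ci = b.bayes_interval(res, lg)
            g = res.group(lg)
            peak = g.positions[np.argmax(g.lod)]
            assert ci.lo_cM <= peak <= ci.hi_cM

    def test_flanking_markers_reported(self):
        lod = np.zeros(11)
        lod[5] = 20.0
        ci = b.bayes_interval(self.make_scan(lod), "LG1")
        assert ci.lo_marker is not None and ci.hi_marker is not None

    def test_bad_coverage_rejected(self):
        scan = self.make_scan([1.0, 2.0, 1.0])
        with pytest.raises(ValueError, match="coverage"):
            b.bayes_interval(scan, "LG1", coverage=0.0)

    def test_width_shrinks_with_sample_size(self):
        widths = {}
        for n in (100, 400):
            w = []
            for rep in range(15):
                spec = b.CrossSimSpec(
                    lmap=b.make_grid_map(1, 10, 10.0), n_individuals=n,
                    qtl=[b.PlantedQTL("LG1", 45.0, "pheno", a=0.7)],
                    seed=3000 + 17 * rep + n,
                )
                cross = b.simulate_f2_cross(spec)
                probs = b.genotype_probabilities(cross, step_cM=2.0, error_rate=0.0)
                res = b.scan_hk(probs, cross.phenotypes["pheno"])
                ci = b.bayes_interval(res, "LG1")
                w.append(ci.hi_cM - ci.lo_cM)
            widths[n] = np.median(w)
        assert widths[400] < widths[100]


class TestEffectsAndPVE:
    def test_additive_pattern(self):
        g = np.array([0] * 5 + [1] * 5 + [2] * 5)
        y = np.array([10.0] * 5 + [15.0] * 5 + [20.0] * 5)
        means, a, d = b.qtl_effects(g, y)
        assert (means["AA"], means["AB"], means["BB"]) == (10, 15, 20)
        assert a == 5 and d == 0

    def test_underdominant_pattern(self):
        g = np.array([0] * 5 + [1] * 5 + [2] * 5)
        y = np.array([10.0] * 5 + [20.0] * 5 + [10.0] * 5)
        _, a, d = b.qtl_effects(g, y)
        assert a == 0 and d == 10

    def test_label_swap_negates_additive(self, rng):
        g = rng.integers(0, 3, 120)
        y = rng.normal(0, 1, 120) + g
        _, a1, d1 = b.qtl_effects(g, y)
        _, a2, d2 = b.qtl_effects(2 - g, y)
        assert a2 == pytest.approx(-a1)
        assert d2 == pytest.approx(d1)

    def test_empty_class_warns_nan(self):
        g = np.array([0] * 5 + [1] * 5)
        y = np.arange(10.0)
        with pytest.warns(UserWarning, match="homozygote"):
            means, a, d = b.qtl_effects(g, y)
        assert np.isnan(means["BB"]) and np.isnan(a)

    def test_pve_zero_lod(self):
        assert b.pve(0.0, 100) == 0.0

    def test_pve_monotone_in_lod(self):
        lods = np.linspace(0, 20, 30)
        vals = [b.pve(l, 200) for l in lods]
        assert np.all(np.diff(vals) > 0)

    def test_pve_equals_marker_r_squared(self, small_cross):
        y = small_cross.phenotypes["pheno"].to_numpy()
        g = small_cross.genotypes["LG2_m4"].to_numpy()
        lod_ref, r2 = marker_lod_oracle(g, y)
        assert b.pve(lod_ref, len(y)) == pytest.approx(100 * r2, abs=1e-6)

    def test_detection_strength_grows_with_planted_pve(self):
        mean_lod = []
        for pve_pct in (5, 10, 20):
            frac = pve_pct / 100
            a = np.sqrt(2 * frac / (1 - frac))  # additive variance a^2/2, sd 1
            lods = []
            for rep in range(12):
                spec = b.CrossSimSpec(
                    lmap=b.make_grid_map(1, 10, 10.0), n_individuals=250,
                    qtl=[b.PlantedQTL("LG1", 45.0, "pheno", a=a)],
                    seed=7000 + 31 * rep + pve_pct,
                )
                cross = b.simulate_f2_cross(spec)
                probs = b.genotype_probabilities(cross, step_cM=5.0, error_rate=0.0)
                lods.append(b.scan_hk(probs, cross.phenotypes["pheno"]).max_lod())
            mean_lod.append(np.mean(lods))
        assert mean_lod[0] < mean_lod[1] < mean_lod[2]
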