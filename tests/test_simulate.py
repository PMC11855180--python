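import numpy as np
import pytest
from scipy import stats

import pairkin as pk
from pairkin.simulate import _merged_intervals, sample_crossovers


class TestCrossovers:
    def test_poisson_mean_short(self):
        rng = np.random.default_rng(0)
        counts = [len(sample_crossovers(100.0, rng)) for _ in range(10_000)]
        assert abs(np.mean(counts) - 1.0) < 0.04  # 4 SE of Poisson(1)

    def test_poisson_mean_genome_scale(self):
        rng = np.random.default_rng(1)
        counts = [len(sample_crossovers(3280.0, rng)) for _ in range(10_000)]
        assert abs(np.mean(counts) - 32.8) < 0.25

    def test_tiny_length_almost_always_empty(self):
        rng = np.random.default_rng(2)
        counts = [len(sample_crossovers(1e-4, rng)) for _ in range(2_000)]
        assert np.mean(counts) < 1e-3

    def test_positions_sorted_and_in_range(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            xs = sample_crossovers(250.0, rng)
            assert np.all(np.diff(xs) >= 0)
            assert np.all((xs >= 0) & (xs <= 250.0))

    def test_gamma_interference_mean_preserved(self):
        rng = np.random.default_rng(4)
        counts = [
            len(sample_crossovers(300.0, rng, model="gamma")) for _ in range(4_000)
        ]
        assert abs(np.mean(counts) - 3.0) < 0.15

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            sample_crossovers(0.0, 1)
        with pytest.raises(ValueError):
            sample_crossovers(10.0, 1, model="chi")


class TestGenomeSimulation:
    def test_unrelated_spec_rejected(self, panel_small, gmap_small):
        with pytest.raises(ValueError):
            pk.simulate_pair(pk.UN, panel_small, gmap_small, rng=0)

    def test_unrelated_pair_has_no_ibd(self, panel_small, gmap_small):
        obs = pk.simulate_unrelated_pair(panel_small, gmap_small, rng=0)
        assert obs.true_ibd == []
        stats_ = pk.true_ibd_stats(obs, min_cm=5.0)
        assert (stats_.total_cm, stats_.n_segments, stats_.n_panel_snps_in_ibd) == (0, 0, 0)

    def test_unrelated_heterozygosity_hardy_weinberg(self, panel_small, gmap_small):
        rng = np.random.default_rng(7)
        het = np.zeros(panel_small.n_markers)
        n = 300
        for _ in range(n):
            obs = pk.simulate_unrelated_pair(panel_small, gmap_small, rng)
            het += obs.genotypes_a == 1
        expected = 2 * panel_small.freqs * (1 - panel_small.freqs)
        assert abs((het / n).mean() - expected.mean()) < 0.01

    def test_sibling_level2_segments_force_identity(self, panel_small, gmap_small):
        cms = panel_small.markers["cm"].to_numpy()
        for seed in range(10):
            obs = pk.simulate_pair(pk.S1, panel_small, gmap_small, rng=seed)
            for seg in obs.true_ibd:
                idx = panel_small.chrom_index(seg.chrom)
                inside = idx[(cms[idx] >= seg.start_cm) & (cms[idx] <= seg.end_cm)]
                ga, gb = obs.genotypes_a[inside], obs.genotypes_b[inside]
                if seg.level == 2:
                    np.testing.assert_array_equal(ga, gb)
                else:  # level 1: no opposite homozygotes before errors
                    assert not np.any(((ga == 0) & (gb == 2)) | ((ga == 2) & (gb == 0)))

    @pytest.mark.parametrize("spec", [pk.S1, pk.S2])
    def test_genome_wide_sharing_matches_kappa(self, spec, gmap_default):
        """Mean total IBD>=1 length (5 cM cutoff) ~ (1-k0) * map length."""
        rng = np.random.default_rng(11)
        tots = []
        for _ in range(250):
            _, segs = pk.simulate_ibd_track(spec, gmap_default, rng)
            merged = _merged_intervals(segs)
            tots.append(
                sum(b - a for iv in merged.values() for a, b in iv if b - a >= 5)
            )
        expected = (1 - spec.kappa[0]) * gmap_default.total_cm
        assert abs(np.mean(tots) - expected) / expected < 0.02

    def test_conservation_invariants(self, panel_small, gmap_small):
        rng = np.random.default_rng(13)
        for _ in range(30):
            obs = pk.simulate_pair(pk.S2, panel_small, gmap_small, rng=rng)
            st = pk.true_ibd_stats(obs, min_cm=0.0)
            assert st.total_cm <= gmap_small.total_cm + 1e-9
            if st.n_segments == 0:
                assert st.total_cm == 0

    def test_raising_min_cm_never_increases_total(self, gmap_small, panel_small):
        obs = pk.simulate_pair(pk.S2, panel_small, gmap_small, rng=99)
        totals = [pk.true_ibd_stats(obs, min_cm=c).total_cm for c in (0, 2, 5, 10)]
        assert all(a >= b for a, b in zip(totals, totals[1:]))

    def test_real_data_signalled_by_missing_track(self, panel_small):
        obs = pk.PairObservation(
            panel=panel_small,
            genotypes_a=np.zeros(panel_small.n_markers, dtype=np.int8),
            genotypes_b=np.zeros(panel_small.n_markers, dtype=np.int8),
            true_ibd=None,
        )
        with pytest.raises(ValueError):
            pk.true_ibd_stats(obs)


class TestErrorInjection:
    def test_zero_rates_are_identity(self, panel_small, gmap_small):
        obs = pk.simulate_pair(pk.S1, panel_small, gmap_small, rng=0)
        out = pk.inject_errors(obs, pk.ErrorModel(), rng=1)
        np.testing.assert_array_equal(out.genotypes_a, obs.genotypes_a)
        np.testing.assert_array_equal(out.genotypes_b, obs.genotypes_b)

    def test_forced_hom_to_het(self, panel_small):
        from conftest import make_obs

        n = panel_small.n_markers
        obs = make_obs(panel_small, np.zeros(n), np.zeros(n), true_ibd=[])
        out = pk.inject_errors(obs, pk.ErrorModel(rate_hom_to_het=1.0), rng=0)
        assert np.all(out.genotypes_a == 1)
        np.testing.assert_array_equal(out.genotypes_b, obs.genotypes_b)

    def test_opposite_homozygote_rate_is_binomial(self):
        from conftest import make_obs, manual_panel

        n = 100_000
        rng = np.random.default_rng(5)
        panel, _ = manual_panel(np.linspace(0, 99, n), np.full(n, 0.5))
        obs = make_obs(panel, np.zeros(n), np.zeros(n), true_ibd=[])
        out = pk.inject_errors(obs, pk.ErrorModel(rate_hom_to_opp=0.01), rng=rng)
        flipped = int((out.genotypes_a == 2).sum())
        se = np.sqrt(n * 0.01 * 0.99)
        assert abs(flipped - 1000) < 4 * se

    def test_error_category_counts_goodness_of_fit(self):
        """Observed mutation counts per error type follow the configured
        binomial rates (chi-square on a large vector)."""
        from conftest import make_obs, manual_panel

        n = 60_000
        rng = np.random.default_rng(6)
        panel, _ = manual_panel(np.linspace(0, 99, n), np.full(n, 0.5))
        ga = rng.integers(0, 3, n)
        obs = make_obs(panel, ga, ga.copy(), true_ibd=[])
        em = pk.ErrorModel(0.02, 0.005, 0.01)
        out = pk.inject_errors(obs, em, rng=rng)
        hom = (ga == 0) | (ga == 2)
        n_hom, n_het = int(hom.sum()), int((~hom).sum())
        to_het = int(((out.genotypes_a == 1) & hom).sum())
        to_opp = int((hom & (out.genotypes_a == 2 - ga)).sum())
        to_hom = int((~hom & (out.genotypes_a != 1)).sum())
        for obs_count, n_total, rate in [
            (to_het, n_hom, 0.02), (to_opp, n_hom, 0.005), (to_hom, n_het, 0.01),
        ]:
            exp = n_total * rate
            chi2 = (obs_count - exp) ** 2 / exp + (obs_count - exp) ** 2 / (
                n_total - exp
            )
            assert chi2 < stats.chi2.ppf(0.999, df=1)

    def test_het_to_hom_splits_evenly(self):
        from conftest import make_obs, manual_panel

        n = 50_000
        panel, _ = manual_panel(np.linspace(0, 99, n), np.full(n, 0.5))
        obs = make_obs(panel, np.ones(n), np.ones(n), true_ibd=[])
        out = pk.inject_errors(obs, pk.ErrorModel(rate_het_to_hom=1.0), rng=1)
        frac0 = np.mean(out.genotypes_a == 0)
        assert np.all(out.genotypes_a != 1)
        assert abs(frac0 - 0.5) < 0.01

    def test_true_ibd_untouched(self, panel_small, gmap_small):
        obs = pk.simulate_pair(pk.S1, panel_small, gmap_small, rng=3)
        out = pk.inject_errors(obs, pk.ErrorModel(0.1, 0.1, 0.1), rng=4)
        assert out.true_ibd == obs.true_ibd

    def test_invalid_rates_rejected(self):
        with pytest.raises(ValueError):
            pk.ErrorModel(rate_hom_to_het=1.5)
        with pytest.raises(ValueError):
            pk.ErrorModel(0.6, 0.6, 0.0)
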