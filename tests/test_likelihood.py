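import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import pairkin as pk
from conftest import make_obs, manual_panel
from pairkin.likelihood import (
    genotype_pair_prob,
    genotype_pair_tables,
    ibd_transition_matrix,
    lr_classify,
)
from pairkin.relationship import CLASSES


class TestGenotypePairProb:
    def test_known_values(self):
        assert np.isclose(genotype_pair_prob(0, 0, 0.5, 0), 0.0625)  # (1-p)^4
        assert np.isclose(genotype_pair_prob(0, 0, 0.5, 1), 0.125)   # (1-p)^3
        assert genotype_pair_prob(0, 2, 0.5, 2) == 0.0  # IBD2 forbids discordance
        assert np.isclose(genotype_pair_prob(0, 0, 0.5, 2), 0.25)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            genotype_pair_prob(3, 0, 0.5, 0)
        with pytest.raises(ValueError):
            genotype_pair_prob(0, 0, 0.5, 4)
        with pytest.raises(ValueError):
            genotype_pair_prob(0, 0, 1.0, 0)

    @given(p=st.floats(0.01, 0.99))
    @settings(max_examples=50, deadline=None)
    def test_tables_are_distributions(self, p):
        T = genotype_pair_tables(np.array([p]))[0]
        np.testing.assert_allclose(T.sum(axis=0), 1.0, atol=1e-12)
        # k=2 slice is diagonal: discordant pairs impossible
        for ga, gb in itertools.product(range(3), range(3)):
            if ga != gb:
                assert T[3 * ga + gb, 2] == 0.0

    def test_enumeration_oracle_k1(self):
        """k=1 table equals the shared-allele construction, enumerated."""
        p, q = 0.3, 0.7
        expect = np.zeros((3, 3))
        for s, ps in ((0, q), (1, p)):  # shared allele
            for xa, pa in ((0, q), (1, p)):
                for xb, pb in ((0, q), (1, p)):
                    expect[s + xa, s + xb] += ps * pa * pb
        T = genotype_pair_tables(np.array([p]))[0]
        np.testing.assert_allclose(T[:, 1].reshape(3, 3), expect, atol=1e-12)


class TestUnlinkedLoglik:
    def test_single_marker_hand_value(self):
        panel, _ = manual_panel([10.0], [0.5])
        obs = make_obs(panel, [0], [0])
        ll = pk.unlinked_loglik(obs, None, (0.25, 0.5, 0.25))
        assert np.isclose(ll, np.log(0.25 * 0.0625 + 0.5 * 0.125 + 0.25 * 0.25))

    def test_unrelated_kappa_factorizes(self):
        panel, _ = manual_panel([1.0, 2.0, 3.0], [0.2, 0.5, 0.8])
        obs = make_obs(panel, [0, 1, 2], [2, 1, 0])
        ll = pk.unlinked_loglik(obs, None, (1, 0, 0))
        T = genotype_pair_tables(panel.freqs)
        expect = sum(
            np.log(T[i, 3 * obs.genotypes_a[i] + obs.genotypes_b[i], 0])
            for i in range(3)
        )
        assert np.isclose(ll, expect)

    def test_impossible_observation_is_minus_inf(self):
        panel, _ = manual_panel([1.0], [0.5])
        obs = make_obs(panel, [0], [2])
        assert pk.unlinked_loglik(obs, None, (0, 0, 1)) == -np.inf

    def test_self_lr_is_zero(self, panel_small, gmap_small):
        obs = pk.simulate_pair(pk.S2, panel_small, gmap_small, rng=0)
        ll = pk.unlinked_loglik(obs, None, pk.S2.kappa)
        assert ll - ll == 0.0


class TestTransitionMatrix:
    @pytest.mark.parametrize("spec", CLASSES)
    def test_zero_distance_is_identity(self, spec):
        T = ibd_transition_matrix(spec, 0.0)
        np.testing.assert_allclose(T, np.eye(T.shape[0]), atol=1e-12)

    @pytest.mark.parametrize("spec", CLASSES)
    @pytest.mark.parametrize("d", [0.01, 1.0, 25.0, 500.0])
    def test_rows_stochastic_and_stationary_invariant(self, spec, d):
        T = ibd_transition_matrix(spec, d)
        np.testing.assert_allclose(T.sum(axis=1), 1.0, atol=1e-12)
        if spec.label == "S1":
            pi = np.array([0.25, 0.5, 0.25])
        elif spec.label == "Un":
            pi = np.array([1.0])
        else:
            pi = np.array(spec.kappa[:2])
        np.testing.assert_allclose(pi @ T, pi, atol=1e-12)

    @pytest.mark.parametrize("spec", [pk.S1, pk.S2, pk.S4])
    def test_long_distance_reaches_stationarity(self, spec):
        T = ibd_transition_matrix(spec, 1e5)
        pi = T[0]
        for row in T:
            np.testing.assert_allclose(row, pi, atol=1e-12)


def brute_force_linked(obs, gmap, spec):
    """Exhaustive enumeration over IBD-state sequences (oracle)."""
    if spec.label == "S1":
        pi = np.array([0.25, 0.5, 0.25])
        states = [0, 1, 2]
    elif spec.label == "Un":
        pi, states = np.array([1.0]), [0]
    else:
        pi, states = np.array(spec.kappa[:2]), [0, 1]
    cms = obs.panel.markers["cm"].to_numpy()
    ds = np.diff(cms)
    total = 0.0
    for path in itertools.product(range(len(states)), repeat=obs.n_markers):
        p = pi[path[0]]
        for j in range(1, len(path)):
            p *= ibd_transition_matrix(spec, ds[j - 1])[path[j - 1], path[j]]
        for j, s in enumerate(path):
            p *= genotype_pair_prob(
                int(obs.genotypes_a[j]), int(obs.genotypes_b[j]),
                float(obs.panel.freqs[j]), states[s],
            )
        total += p
    return np.log(total)


class TestLinkedLoglik:
    @pytest.mark.parametrize("spec", CLASSES)
    @pytest.mark.parametrize(
        "ga,gb", [([0, 1], [0, 1]), ([2, 1], [0, 1]), ([1, 1, 0], [1, 2, 0])]
    )
    def test_matches_exhaustive_enumeration(self, spec, ga, gb):
        panel, gmap = manual_panel(
            [10.0, 18.0, 40.0][: len(ga)], [0.5, 0.3, 0.7][: len(ga)]
        )
        obs = make_obs(panel, ga, gb)
        ll = pk.linked_loglik(obs, None, gmap, spec)
        oracle = brute_force_linked(obs, gmap, spec)
        assert np.isclose(ll, oracle, rtol=1e-9)

    def test_unrelated_equals_unlinked(self, panel_small, gmap_small):
        obs = pk.simulate_unrelated_pair(panel_small, gmap_small, rng=0)
        ll = pk.linked_loglik(obs, None, gmap_small, pk.UN)
        lu = pk.unlinked_loglik(obs, None, (1, 0, 0))
        assert np.isclose(ll, lu, rtol=1e-12)

    def test_wide_spacing_limit_equals_unlinked(self):
        rng = np.random.default_rng(3)
        n = 20
        panel, gmap = manual_panel(
            10_000.0 * np.arange(1, n + 1), rng.uniform(0.1, 0.9, n),
            length_cm=10_000.0 * (n + 2),
        )
        obs = pk.simulate_unrelated_pair(panel, gmap, rng=4)
        for spec in CLASSES:
            ll = pk.linked_loglik(obs, None, gmap, spec)
            lu = pk.unlinked_loglik(obs, None, spec.kappa)
            assert abs(ll - lu) / n < 1e-9

    def test_fictive_100cm_map_roughly_independent(self):
        """At 100 cM spacing the chain is close to (not exactly at)
        stationarity; per-marker agreement with the unlinked likelihood is
        within the exp(-meioses) residual."""
        rng = np.random.default_rng(5)
        n = 30
        panel, gmap = manual_panel(
            100.0 * np.arange(1, n + 1), rng.uniform(0.1, 0.9, n),
            length_cm=100.0 * (n + 2),
        )
        obs = pk.simulate_unrelated_pair(panel, gmap, rng=6)
        for spec in CLASSES:
            ll = pk.linked_loglik(obs, None, gmap, spec)
            lu = pk.unlinked_loglik(obs, None, spec.kappa)
            assert abs(ll - lu) / n < 1e-2

    def test_unsorted_markers_rejected(self):
        import pandas as pd

        from pairkin.panel import PanelDef

        with pytest.raises(ValueError):
            PanelDef(
                "bad",
                pd.DataFrame(
                    {"chrom": "1", "bp": [200, 100], "cm": [2.0, 1.0],
                     "freq": [0.5, 0.5]}
                ),
            )


class TestLRClassify:
    def test_empty_marker_set_ties_to_unrelated(self):
        import pandas as pd

        from pairkin.panel import PanelDef

        panel = PanelDef.__new__(PanelDef)
        object.__setattr__(panel, "name", "empty")
        object.__setattr__(
            panel, "markers",
            pd.DataFrame({"chrom": [], "bp": [], "cm": [], "freq": []}),
        )
        obs = make_obs(panel, [], [])
        call = lr_classify(obs, mode="unlinked")
        assert call.label == "Un"

    def test_sibling_pairs_recovered(self, gmap_default):
        panel = pk.make_fixture_panel(gmap_default, 4_073, seed=17)
        hits = 0
        for seed in range(20):
            obs = pk.simulate_pair(pk.S1, panel, gmap_default, rng=seed)
            hits += lr_classify(obs, None, gmap_default, mode="linked").label == "S1"
        assert hits == 20

    def test_lr_threshold_flag_can_abstain(self, panel_small, gmap_small):
        obs = pk.simulate_unrelated_pair(panel_small, gmap_small, rng=0)
        call = lr_classify(obs, None, gmap_small, mode="linked",
                           lr_threshold=1e12)
        assert call.label in (pk.INCONCLUSIVE, "Un")

    def test_calibration_grows_with_marker_count(self, gmap_small):
        """Mean log-LR of the true class vs unrelated increases with the
        number of markers."""
        gaps = []
        for size in (100, 800):
            panel = pk.make_fixture_panel(gmap_small, size, seed=5)
            diffs = []
            for seed in range(10):
                obs = pk.simulate_pair(pk.S2, panel, gmap_small, rng=seed)
                diffs.append(
                    pk.unlinked_loglik(obs, None, pk.S2.kappa)
                    - pk.unlinked_loglik(obs, None, pk.UN.kappa)
                )
            gaps.append(np.mean(diffs))
        assert gaps[0] > 0
        assert gaps[1] > gaps[0]
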