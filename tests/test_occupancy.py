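import itertools
import math

import numpy as np
import pytest

from msbind.occupancy import (
    OccupancyState,
    count_states,
    ensemble_average,
    factorized_distribution,
    macrostate_probabilities,
    marginal_occupancy,
    mean_occupancy,
    ranked_states,
    state_constant,
    state_probabilities,
    titration_curve,
)

from conftest import brute_force_probabilities, make_constants


class TestCountStates:
    def test_twelve_sites_saturating_at_two(self):
        sites = [make_constants(f"s{j}", [1.0, 1.0]) for j in range(12)]
        assert count_states(sites) == 3**12 == 531441

    def test_bundled_receptor_state_count(self, kv12_constants):
        # four extracellular sites never double: 3⁸ × 2⁴ states
        assert count_states(kv12_constants) == 3**8 * 2**4

    def test_empty_receptor_has_single_state(self):
        assert count_states([]) == 1

    def test_mixed_maxima(self):
        sites = [
            make_constants("a", [1.0, 1.0]),
            make_constants("b", [1.0]),
            make_constants("c", []),
        ]
        assert count_states(sites) == 6


class TestStateConstant:
    def test_empty_state_is_unity(self, toy3):
        assert state_constant(toy3, OccupancyState((0, 0, 0))) == 1.0

    def test_single_site_reduces_to_site_constant(self, toy3):
        assert state_constant(toy3, OccupancyState((0, 2, 0))) == pytest.approx(1.5)

    def test_two_linker_singles_multiply(self):
        """Occupying two strong sites at once multiplies their printed K₁."""
        sites = [make_constants("s10", [2.51e1]), make_constants("s11", [4.19e1])]
        K = state_constant(sites, OccupancyState((1, 1)))
        assert K == pytest.approx(1.0517e3, rel=1e-4)

    def test_occupancy_above_max_rejected(self, toy3):
        with pytest.raises(ValueError):
            state_constant(toy3, OccupancyState((2, 0, 0)))


class TestStateProbabilities:
    def test_zero_concentration_pins_empty_state(self, toy3):
        dist = state_probabilities(toy3, 0.0)
        assert dist.state_probability(OccupancyState((0, 0, 0))) == pytest.approx(1.0)

    def test_single_site_even_odds(self):
        dist = state_probabilities([make_constants("s", [1.0])], 1.0)
        assert dist.state_probability(OccupancyState((0,))) == pytest.approx(0.5)
        assert dist.state_probability(OccupancyState((1,))) == pytest.approx(0.5)

    def test_two_site_brute_force(self):
        """ρ(1,1) = K_a K_b ρ̄² / Σ = 6/12 for K = 2, 3 mM⁻¹ at 1 mM."""
        sites = [make_constants("a", [2.0]), make_constants("b", [3.0])]
        dist = state_probabilities(sites, 1.0)
        assert dist.state_probability(OccupancyState((1, 1))) == pytest.approx(6 / 12)

    def test_matches_independent_enumeration(self, toy3):
        expected = brute_force_probabilities(toy3, 2.5)
        dist = state_probabilities(toy3, 2.5)
        for st, p in expected.items():
            assert dist.state_probability(OccupancyState(st)) == pytest.approx(
                p, abs=1e-12
            )

    def test_probabilities_normalized(self, toy3):
        dist = state_probabilities(toy3, 10.0)
        assert np.exp(dist.log_probs).sum() == pytest.approx(1.0, abs=1e-9)

    def test_enumeration_cap_enforced(self, kv12_constants):
        with pytest.raises(ValueError, match="factorized"):
            state_probabilities(kv12_constants, 1.0, enumeration_cap=1000)

    def test_molar_concentration_warns(self, toy3):
        with pytest.warns(UserWarning, match="dilute"):
            state_probabilities(toy3, 1000.0)


class TestFactorizedAgreement:
    @pytest.mark.parametrize("conc", [0.0, 0.3, 5.0, 400.0])
    def test_marginals_match_enumeration(self, toy3, conc):
        enum = state_probabilities(toy3, conc)
        fact = factorized_distribution(toy3, conc)
        for sid in ("a", "b", "c"):
            np.testing.assert_allclose(
                marginal_occupancy(enum, sid),
                marginal_occupancy(fact, sid),
                atol=1e-12,
            )

    def test_marginals_normalized(self, toy3):
        fact = factorized_distribution(toy3, 7.0)
        for m in fact.marginals:
            assert m.sum() == pytest.approx(1.0, abs=1e-12)

    def test_kv12_factorized_equals_enumerated(self, kv12_constants):
        enum = state_probabilities(kv12_constants, 10.0)
        fact = factorized_distribution(kv12_constants, 10.0)
        for j in range(12):
            np.testing.assert_allclose(
                enum.marginals[j], fact.marginals[j], atol=1e-10
            )

    def test_unknown_site_is_lookup_error(self, toy3):
        with pytest.raises(KeyError):
            marginal_occupancy(factorized_distribution(toy3, 1.0), "nope")


class TestMacrostates:
    def test_zero_concentration(self, toy3):
        rho_n = macrostate_probabilities(factorized_distribution(toy3, 0.0))
        assert rho_n[0] == pytest.approx(1.0)

    def test_single_site_closed_form(self):
        site = make_constants("s", [2.0, 5.0])  # weights 1, 2ρ̄, 5ρ̄²
        rho_n = macrostate_probabilities(factorized_distribution([site], 1.0))
        assert rho_n[2] == pytest.approx(5.0 / 8.0)

    def test_convolution_equals_enumeration_coarse_graining(self, toy3):
        conc = 3.0
        dist = state_probabilities(toy3, conc)
        expected = np.zeros(5)
        for st, p in brute_force_probabilities(toy3, conc).items():
            expected[sum(st)] += p
        np.testing.assert_allclose(
            macrostate_probabilities(dist), expected, atol=1e-12
        )
        assert macrostate_probabilities(dist).sum() == pytest.approx(1.0, abs=1e-12)


class TestEnsembleAverage:
    def test_constant_property_is_normalization(self, toy3):
        dist = state_probabilities(toy3, 2.0)
        assert ensemble_average(dist, state_fn=lambda s: 1.0) == pytest.approx(1.0)

    def test_single_site_closed_form(self):
        dist = state_probabilities([make_constants("s", [4.0])], 1.0)
        assert ensemble_average(dist, state_fn=sum) == pytest.approx(4.0 / 5.0)

    def test_marginal_route_matches_enumeration(self, toy3):
        dist = state_probabilities(toy3, 2.0)
        via_states = ensemble_average(dist, state_fn=sum)
        via_marginals = ensemble_average(
            dist,
            site_level_values={
                "a": [0, 1],
                "b": [0, 1, 2],
                "c": [0, 1],
            },
        )
        assert via_marginals == pytest.approx(via_states, abs=1e-12)
        assert mean_occupancy(dist)[0] == pytest.approx(via_states, abs=1e-12)

    def test_missing_values_rejected(self, toy3):
        dist = factorized_distribution(toy3, 1.0)
        with pytest.raises(ValueError):
            ensemble_average(dist, site_level_values={"a": [0, 1]})
        with pytest.raises(ValueError):
            ensemble_average(dist)


class TestTitration:
    def test_zero_concentration_empty(self, toy3):
        df = titration_curve(toy3, [0.0])
        assert df["n_mean"].iloc[0] == 0.0

    def test_saturation_limit(self, toy3):
        df = titration_curve(toy3, [1e9])
        assert df["n_mean"].iloc[0] == pytest.approx(4.0, rel=1e-4)

    def test_half_occupancy_at_inverse_K(self):
        df = titration_curve([make_constants("s", [1.0])], [1.0])
        assert df["n_mean"].iloc[0] == pytest.approx(0.5)

    def test_monotone_nondecreasing(self, kv12_constants):
        concs = np.logspace(-3, 3, 25)
        df = titration_curve(kv12_constants, concs)
        assert (np.diff(df["n_mean"].to_numpy()) >= -1e-12).all()

    def test_empty_state_probability_monotone_nonincreasing(self, kv12_constants):
        probs = [
            np.prod([m[0] for m in factorized_distribution(kv12_constants, c).marginals])
            for c in np.logspace(-3, 3, 25)
        ]
        assert (np.diff(probs) <= 1e-12).all()

    def test_dilute_limit_slope_is_sum_of_K1(self, kv12_constants):
        rho = 1e-9
        df = titration_curve(kv12_constants, [rho])
        slope = df["n_mean"].iloc[0] / rho
        K1_sum = sum(p.K(1) for p in kv12_constants)
        assert slope == pytest.approx(K1_sum, rel=1e-4)


class TestRankedStates:
    def test_sorted_descending_with_lexicographic_ties(self):
        sites = [make_constants("a", [1.0]), make_constants("b", [1.0])]
        df = ranked_states(state_probabilities(sites, 1.0))
        assert list(df["state"]) == ["00", "01", "10", "11"]
        assert (np.diff(df["probability"]) <= 1e-15).all()

    def test_kv12_top_state_at_low_concentration_is_empty(self, kv12_constants):
        dist = state_probabilities(kv12_constants, 0.001)
        df = ranked_states(dist, top=3)
        assert df["state"].iloc[0] == "0" * 12
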