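import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from msbind import LigandReservoir
from msbind.affinity import (
    AffinityLevel,
    SiteAffinity,
    compose_two_step_work,
    compute_site_constants,
    effective_volume,
    free_energy_decomposition,
    site_binding_constant,
    standard_binding_free_energy,
)
from msbind.thermo import STANDARD_VOLUME_A3


def one_level_site(k, work, err=0.0, site_id="s"):
    return SiteAffinity(site_id, "r", {1: AffinityLevel((k,), work, err)})


def two_level_site(k1, k2, w1, w2, site_id="s"):
    return SiteAffinity(
        site_id,
        "r",
        {1: AffinityLevel((k1,), w1), 2: AffinityLevel((k1, k2), w2)},
    )


class TestEffectiveVolume:
    @pytest.mark.parametrize("k, vol", [(0.127, 158.6), (0.053, 588.0)])
    def test_known_values(self, ctx, k, vol):
        assert effective_volume(k, ctx) == pytest.approx(vol, rel=2e-3)

    def test_strictly_decreasing_in_stiffness(self, ctx):
        vols = [effective_volume(k, ctx) for k in (0.01, 0.1, 1.0, 10.0, 1e6)]
        assert all(a > b for a, b in zip(vols, vols[1:]))
        assert vols[-1] < 1e-6  # k → ∞ limit

    @pytest.mark.parametrize("k", [0.0, -0.5])
    def test_nonpositive_k_rejected(self, ctx, k):
        with pytest.raises(ValueError):
            effective_volume(k, ctx)

    @pytest.mark.parametrize("k", [0.003, 0.05, 0.6])
    def test_monte_carlo_integration_oracle(self, ctx, k):
        """(2π/βk)^{3/2} equals ∫exp(−βk|r|²/2)dr by direct MC integration."""
        rng = np.random.default_rng(k.as_integer_ratio()[0] % 2**31)
        sigma = math.sqrt(1.0 / (ctx.beta * k))
        L = 4.0 * sigma
        pts = rng.uniform(-L, L, size=(1_000_000, 3))
        f = np.exp(-0.5 * ctx.beta * k * (pts**2).sum(axis=1))
        estimate = (2 * L) ** 3 * f.mean()
        assert effective_volume(k, ctx) == pytest.approx(estimate, rel=0.01)


class TestComposeTwoStepWork:
    @pytest.mark.parametrize(
        "w1, w21, total", [(-4.5, -3.6, -8.1), (0.0, 0.0, 0.0), (-7.5, -5.2, -12.7)]
    )
    def test_cumulative_sum(self, w1, w21, total):
        assert compose_two_step_work(w1, w21).work == pytest.approx(total)

    def test_errors_add_in_quadrature(self):
        assert compose_two_step_work(-1.0, -2.0, 0.3, 0.4).error == pytest.approx(0.5)


class TestSiteBindingConstant:
    def test_high_affinity_linker_site(self, ctx):
        """k = 0.127, W*₁ = −7.5, μ̄ = −0.1 gives K₁ ≈ 2.5e1 mM⁻¹."""
        res = LigandReservoir(-0.1, 0.0)
        K = site_binding_constant(one_level_site(0.127, -7.5), 1, res, ctx)
        assert K == pytest.approx(25.1, rel=0.02)

    @pytest.mark.parametrize("n", [1, 2, 3])
    def test_cancellation_identity(self, ctx, n):
        """W*_n = nμ̄ and unit-volume restraints leave only the 1/n! factor."""
        # pick k so each ligand's effective volume is exactly 1660 Å³
        k = 2 * math.pi / (ctx.beta * STANDARD_VOLUME_A3 ** (2.0 / 3.0))
        mu = -0.1
        aff = SiteAffinity(
            "s",
            "r",
            {
                m: AffinityLevel((k,) * m, m * mu)
                for m in range(1, n + 1)
            },
        )
        res = LigandReservoir(mu, 0.0)
        K = site_binding_constant(aff, n, res, ctx)
        assert K * 1e3**n == pytest.approx(1.0 / math.factorial(n), rel=1e-10)

    def test_missing_level_is_lookup_error(self, ctx):
        res = LigandReservoir(-0.1, 0.0)
        with pytest.raises(KeyError):
            site_binding_constant(one_level_site(0.1, -5.0), 2, res, ctx)

    def test_double_occupancy_uses_both_force_constants(self, ctx):
        """Mixed-k double for the strongest linker site: ΔG°₂ ≈ −12.4."""
        res = LigandReservoir(-0.1, 0.0)
        aff = two_level_site(0.127, 0.004, -7.5, -12.7)
        K2 = site_binding_constant(aff, 2, res, ctx)
        assert K2 == pytest.approx(1.2e3, rel=0.05)
        assert standard_binding_free_energy(K2, 2, ctx) == pytest.approx(-12.4, abs=0.05)

    def test_extreme_work_does_not_overflow(self, ctx):
        res = LigandReservoir(-0.1, 0.0)
        aff = one_level_site(0.1, -500.0)
        lk = compute_site_constants(aff, res, ctx).log_K[1]
        assert np.isfinite(lk) and lk > 700  # K itself would overflow a float


class TestStandardFreeEnergy:
    @pytest.mark.parametrize(
        "K, n, dg", [(2.51e1, 1, -6.0), (5.41e-3, 2, -5.1)]
    )
    def test_published_values(self, ctx, K, n, dg):
        assert standard_binding_free_energy(K, n, ctx) == pytest.approx(dg, abs=0.05)

    def test_unit_standard_state_gives_zero(self, ctx):
        assert standard_binding_free_energy(1e-3, 1, ctx) == pytest.approx(0.0, abs=1e-12)
        assert standard_binding_free_energy(1e-6, 2, ctx) == pytest.approx(0.0, abs=1e-12)

    def test_invalid_inputs_rejected(self, ctx):
        with pytest.raises(ValueError):
            standard_binding_free_energy(-1.0, 1, ctx)
        with pytest.raises(ValueError):
            standard_binding_free_energy(1.0, 0, ctx)


class TestDecomposition:
    def test_terms_sum_to_total(self, ctx):
        res = LigandReservoir(-0.1, 0.0)
        aff = two_level_site(0.127, 0.004, -7.5, -12.7)
        for n in (1, 2):
            terms = free_energy_decomposition(aff, n, res, ctx)
            K = site_binding_constant(aff, n, res, ctx)
            assert sum(terms) == pytest.approx(
                standard_binding_free_energy(K, n, ctx), abs=1e-10
            )

    def test_single_ligand_reduction(self, ctx):
        """For n = 1 the third term vanishes and the second is the familiar
        −β⁻¹ln(V_eff/V°) volume correction."""
        res = LigandReservoir(-0.1, 0.0)
        aff = one_level_site(0.127, -7.5)
        work, expansion, indist = free_energy_decomposition(aff, 1, res, ctx)
        assert indist == 0.0
        assert work == pytest.approx(-7.5 - (-0.1))
        v_eff = effective_volume(0.127, ctx)
        assert expansion == pytest.approx(
            -math.log(v_eff / STANDARD_VOLUME_A3) / ctx.beta, abs=1e-12
        )

    def test_standard_volume_restraint_zeroes_expansion(self, ctx):
        res = LigandReservoir(0.0, 0.0)
        k = 2 * math.pi / (ctx.beta * STANDARD_VOLUME_A3 ** (2.0 / 3.0))
        aff = one_level_site(k, -1.0)
        _, expansion, _ = free_energy_decomposition(aff, 1, res, ctx)
        assert expansion == pytest.approx(0.0, abs=1e-10)


class TestMonotonicityProperties:
    @given(
        k=st.floats(0.003, 0.6),
        w=st.floats(-15.0, 5.0),
        dw=st.floats(0.1, 5.0),
    )
    @settings(max_examples=60, deadline=None)
    def test_K_increases_as_work_decreases(self, ctx, reservoir, k, w, dw):
        K_hi = site_binding_constant(one_level_site(k, w - dw), 1, reservoir, ctx)
        K_lo = site_binding_constant(one_level_site(k, w), 1, reservoir, ctx)
        assert K_hi > K_lo

    @given(
        k=st.floats(0.003, 0.5),
        dk=st.floats(0.01, 0.5),
        w=st.floats(-15.0, 5.0),
    )
    @settings(max_examples=60, deadline=None)
    def test_K_decreases_as_restraint_stiffens(self, ctx, reservoir, k, dk, w):
        K_soft = site_binding_constant(one_level_site(k, w), 1, reservoir, ctx)
        K_stiff = site_binding_constant(one_level_site(k + dk, w), 1, reservoir, ctx)
        assert K_stiff < K_soft


class TestErrorPropagation:
    def test_bounds_are_exp_beta_eps_factors(self, ctx, reservoir):
        aff = one_level_site(0.1, -5.0, err=0.3)
        c = compute_site_constants(aff, reservoir, ctx)
        lo, hi = c.K_bounds(1)
        factor = math.exp(ctx.beta * 0.3)
        assert hi / c.K(1) == pytest.approx(factor, rel=1e-10)
        assert c.K(1) / lo == pytest.approx(factor, rel=1e-10)


class TestValidation:
    def test_levels_must_be_contiguous(self):
        with pytest.raises(ValueError):
            SiteAffinity("s", "r", {2: AffinityLevel((0.1, 0.1), -5.0)})

    def test_level_n_needs_n_force_constants(self):
        with pytest.raises(ValueError):
            SiteAffinity(
                "s",
                "r",
                {1: AffinityLevel((0.1,), -5.0), 2: AffinityLevel((0.1,), -9.0)},
            )

    def test_nonpositive_force_constant_rejected(self):
        with pytest.raises(ValueError):
            AffinityLevel((0.0,), -5.0)
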