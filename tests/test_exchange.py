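"""Kinetics, speciation and the combined exchange generator."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from zulfsim.exchange import (
    ExchangePair,
    ExchangeParams,
    ExchangeState,
    association_rate,
    build_generator,
    concentration_kinetics,
    dissociation_return_generator,
    pair_superops,
    speciation,
)
from zulfsim.fixtures import ammonium_pair, ax_pair, axb_pair
from zulfsim.liouville import hamiltonian_superop, trace_of_vec, vectorize
from zulfsim.spin_system import zero_field_hamiltonian

from conftest import random_density_matrix


def _liouvillians(pair):
    l_a = -1j * hamiltonian_superop(zero_field_hamiltonian(pair.species_a))
    l_c = -1j * hamiltonian_superop(zero_field_hamiltonian(pair.species_c))
    return l_a, l_c


def _trace_functional(pair):
    da, dc = pair.dim_a, pair.dim_c
    tau = np.zeros(da * da + dc * dc)
    tau[: da * da][:: da + 1] = 1.0
    tau[da * da:][:: dc + 1] = 1.0
    return tau


class TestSpeciation:
    def test_ph_equals_pka_gives_half(self):
        x_a, x_c = speciation(4.0, 10.0 ** -4.0)
        assert x_c == pytest.approx(0.5)
        assert x_a == pytest.approx(0.5)

    def test_strong_acid_limit(self):
        _, x_c = speciation(-6.0, 1e-4)
        assert x_c == pytest.approx(1.0, abs=1e-2)

    def test_two_units_below_pka(self):
        """pH = pKa - 2 -> x_C = 100/101 from the printed formula."""
        _, x_c = speciation(2.0, 1e-4)
        assert x_c == pytest.approx(100.0 / 101.0, rel=1e-12)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.floats(-3, 14), st.floats(1, 13))
    def test_fractions_in_unit_interval_and_sum_to_one(self, ph, pka):
        x_a, x_c = speciation(ph, 10.0 ** -pka)
        assert 0.0 <= x_a <= 1.0 and 0.0 <= x_c <= 1.0
        assert x_a + x_c == pytest.approx(1.0)


class TestAssociationRate:
    def test_at_pka_equals_kd(self):
        assert association_rate(7.0, ph=5.0, ka=1e-5) == pytest.approx(7.0)

    def test_zero_kd_gives_zero(self):
        assert association_rate(0.0, ph=3.0, ka=1e-5) == 0.0

    def test_one_unit_below_pka_tenfold(self):
        assert association_rate(2.0, ph=4.0, ka=1e-5) == pytest.approx(20.0)

    def test_detailed_balance_with_speciation(self):
        kd, ph, ka = 13.0, 3.3, 10 ** -4.7
        wa = association_rate(kd, ph, ka)
        x_a, x_c = speciation(ph, ka)
        assert x_c * kd == pytest.approx(x_a * wa, rel=1e-12)

    def test_zero_ka_rejected(self):
        with pytest.raises(ValueError):
            association_rate(1.0, ph=3.0, ka=0.0)


class TestConcentrationKinetics:
    def test_symmetric_rates_equilibrate_to_half(self):
        a, c = concentration_kinetics(1.0, 1.0, 1.0, 0.0, 50.0)
        assert a == pytest.approx(0.5)
        assert c == pytest.approx(0.5)

    def test_single_exponential_with_total_rate(self):
        """Approach to equilibrium follows the 2x2 eigenvalue k_d + W_a."""
        kd, wa = 2.0, 3.0
        t = np.linspace(0.0, 2.0, 7)
        a, c = concentration_kinetics(kd, wa, 1.0, 0.0, t)
        a_eq = kd / (kd + wa)
        resid = a - a_eq
        expected = (1.0 - a_eq) * np.exp(-(kd + wa) * t)
        assert np.allclose(resid, expected, rtol=1e-12)
        assert np.allclose(a + c, 1.0)

    def test_irreversible_association_absorbs_everything(self):
        a, c = concentration_kinetics(0.0, 1.5, 1.0, 0.0, np.array([0.5, 2.0, 30.0]))
        assert np.all(np.diff(c) > 0)
        assert c[-1] == pytest.approx(1.0, abs=1e-12)


class TestExchangeParams:
    def test_requires_speciation_or_explicit_rate(self):
        with pytest.raises(ValueError):
            ExchangeParams(kd_s=1.0)

    def test_negative_rates_rejected(self):
        with pytest.raises(ValueError):
            ExchangeParams(kd_s=-1.0, wa_s=1.0)

    def test_mole_fractions_from_detailed_balance(self):
        p = ExchangeParams(kd_s=2.0, wa_s=6.0)
        x_a, x_c = p.mole_fractions()
        assert x_c == pytest.approx(0.75)
        assert x_a == pytest.approx(0.25)


class TestBuildGenerator:
    def test_zero_rates_block_diagonal(self):
        pair = axb_pair()
        l_a, l_c = _liouvillians(pair)
        m = build_generator(pair, ExchangeParams(kd_s=0.0, wa_s=0.0), l_a, l_c)
        da2 = pair.dim_a ** 2
        assert np.allclose(m[:da2, da2:], 0.0)
        assert np.allclose(m[da2:, :da2], 0.0)
        assert np.allclose(m[:da2, :da2], l_a)
        assert np.allclose(m[da2:, da2:], l_c)

    @pytest.mark.parametrize("pair_factory,mech", [
        (lambda: ax_pair(), "generic"),
        (lambda: axb_pair(), "generic"),
        (lambda: ammonium_pair("generic"), "generic"),
        (lambda: ammonium_pair("single-site"), "single-site"),
    ])
    def test_total_trace_conserved_for_random_rates(self, rng, pair_factory, mech):
        pair = pair_factory()
        l_a, l_c = _liouvillians(pair)
        params = ExchangeParams(kd_s=float(rng.uniform(0, 300)),
                                wa_s=float(rng.uniform(0, 300)))
        m = build_generator(pair, params, l_a, l_c)
        tau = _trace_functional(pair)
        # d(Tr rho_A + Tr rho_C)/dt = tau^T M rho = 0 for every state
        assert np.abs(tau @ m).max() < 1e-12 * max(1.0, np.abs(m).max())

    def test_detailed_balance_fixed_point(self):
        """(x_A 1_A/d_A, x_C 1_C/d_C) is stationary under pure exchange."""
        pair = ammonium_pair("single-site")
        params = ExchangeParams(kd_s=35.0, pka=9.25, ph=8.0)
        da2, dc2 = pair.dim_a ** 2, pair.dim_c ** 2
        m = build_generator(pair, params, np.zeros((da2, da2)), np.zeros((dc2, dc2)))
        x_a, x_c = params.mole_fractions()
        state = ExchangeState(
            rho_a=vectorize(x_a * np.eye(pair.dim_a) / pair.dim_a),
            rho_c=vectorize(x_c * np.eye(pair.dim_c) / pair.dim_c),
        ).concat()
        assert np.abs(m @ state).max() < 1e-14 * max(params.kd_s, 1.0)

    def test_dimension_mismatch_rejected(self):
        pair = ax_pair()
        with pytest.raises(ValueError, match="L_A"):
            build_generator(pair, ExchangeParams(kd_s=1.0, wa_s=1.0),
                            np.zeros((3, 3)), np.zeros((16, 16)))

    def test_equal_rates_give_equal_mole_fractions(self):
        params = ExchangeParams(kd_s=50.0, wa_s=50.0)
        x_a, x_c = params.mole_fractions()
        assert x_a == 0.5 and x_c == 0.5


class TestSingleSiteMechanism:
    def test_requires_equivalent_sites(self):
        # inequivalent couplings: 0-3 proton exchanged together with 13C spin
        with pytest.raises(ValueError, match="equivalent"):
            ExchangePair(species_c=axb_pair().species_c, exchanged=(0, 2),
                         mechanism="single-site")

    def test_superops_trace_preserving(self, rng):
        pair = ammonium_pair("single-site")
        t, d = pair_superops(pair)
        rho = random_density_matrix(rng, pair.dim_c)
        assert trace_of_vec(t @ vectorize(rho)) == pytest.approx(1.0)
        rho_a = random_density_matrix(rng, pair.dim_a)
        assert trace_of_vec(d @ vectorize(rho_a)) == pytest.approx(1.0)

    def test_unknown_mechanism_rejected(self):
        with pytest.raises(ValueError, match="mechanism"):
            ExchangePair(species_c=ammonium_pair().species_c,
                         exchanged=(0, 1, 2, 3), mechanism="pairwise")


class TestDissociationReturnGenerator:
    @pytest.mark.parametrize("mech", ["generic", "single-site"])
    def test_trace_conserved(self, rng, mech):
        pair = ammonium_pair(mech)
        dc2 = pair.dim_c ** 2
        m = dissociation_return_generator(pair, 500.0, np.zeros((dc2, dc2)))
        tau = np.zeros(dc2)
        tau[:: pair.dim_c + 1] = 1.0
        assert np.abs(tau @ m).max() < 1e-12 * 500.0

    def test_maximally_mixed_is_stationary(self):
        pair = ammonium_pair("single-site")
        dc2 = pair.dim_c ** 2
        m = dissociation_return_generator(pair, 100.0, np.zeros((dc2, dc2)))
        state = vectorize(np.eye(pair.dim_c) / pair.dim_c)
        assert np.abs(m @ state).max() < 1e-13
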