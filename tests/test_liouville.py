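"""Vectorization contracts and generator building blocks."""

import numpy as np
import pytest
import scipy.linalg
from hypothesis import given, settings, strategies as st

from zulfsim.liouville import (
    attach,
    attach_superop,
    devectorize,
    expectation,
    hamiltonian_superop,
    partial_trace,
    partial_trace_superop,
    permute_spins,
    relaxation_superop,
    trace_of_vec,
    vectorize,
)
from zulfsim.spin_system import spin_operators, system

from conftest import random_density_matrix, random_hermitian


def _oracle_partial_trace(rho, n, traced):
    """Element-wise partial trace over explicit basis indices (independent
    of the reshape/einsum implementation)."""
    keep = [i for i in range(n) if i not in traced]
    dk, dt = 2 ** len(keep), 2 ** len(traced)
    out = np.zeros((dk, dk), dtype=complex)

    def full_index(kbits, tbits):
        bits = [0] * n
        for pos, i in enumerate(keep):
            bits[i] = kbits[pos]
        for pos, i in enumerate(sorted(traced)):
            bits[i] = tbits[pos]
        idx = 0
        for b in bits:
            idx = 2 * idx + b
        return idx

    def tobits(x, m):
        return [(x >> (m - 1 - i)) & 1 for i in range(m)]

    for a in range(dk):
        for b in range(dk):
            for t in range(dt):
                ia = full_index(tobits(a, len(keep)), tobits(t, len(traced)))
                ib = full_index(tobits(b, len(keep)), tobits(t, len(traced)))
                out[a, b] += rho[ia, ib]
    return out


class TestVectorization:
    def test_identity_vectorizes_column_wise(self):
        assert np.allclose(vectorize(np.eye(2)), [1, 0, 0, 1])

    def test_round_trip_exact(self, rng):
        rho = random_density_matrix(rng, 8)
        assert np.array_equal(devectorize(vectorize(rho)), rho)

    @settings(deadline=None, derandomize=True, max_examples=20)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_kron_identity_for_sandwich_products(self, seed):
        """vec(P rho Q) == kron(Q.T, P) vec(rho) -- the normative contract."""
        gen = np.random.default_rng(seed)
        d = int(gen.integers(2, 5))
        rho = gen.normal(size=(d, d)) + 1j * gen.normal(size=(d, d))
        p = gen.normal(size=(d, d)) + 1j * gen.normal(size=(d, d))
        q = gen.normal(size=(d, d)) + 1j * gen.normal(size=(d, d))
        lhs = vectorize(p @ rho @ q)
        rhs = np.kron(q.T, p) @ vectorize(rho)
        assert np.allclose(lhs, rhs, atol=1e-12 * max(1, np.abs(lhs).max()))

    def test_trace_functional(self, rng):
        rho = random_density_matrix(rng, 4)
        assert trace_of_vec(vectorize(rho)) == pytest.approx(np.trace(rho))

    def test_expectation_matches_matrix_trace(self, rng):
        rho = random_density_matrix(rng, 4)
        op = random_hermitian(rng, 4)
        assert expectation(op, vectorize(rho)) == pytest.approx(np.trace(op @ rho))

    def test_non_square_rejected(self):
        with pytest.raises(ValueError):
            vectorize(np.zeros((2, 3)))


class TestHamiltonianSuperop:
    def test_identity_hamiltonian_gives_zero(self):
        assert np.allclose(hamiltonian_superop(np.eye(4)), 0.0)

    def test_matches_direct_commutator(self, rng):
        h = random_hermitian(rng, 4)
        rho = random_density_matrix(rng, 4)
        lhs = devectorize(hamiltonian_superop(h) @ vectorize(rho))
        assert np.allclose(lhs, h @ rho - rho @ h, atol=1e-12)

    def test_non_hermitian_warns(self, rng):
        h = rng.normal(size=(3, 3)) + 1j * rng.normal(size=(3, 3))
        with pytest.warns(UserWarning, match="not Hermitian"):
            hamiltonian_superop(h)

    def test_liouvillian_spectrum_purely_imaginary(self, rng):
        ev = np.linalg.eigvals(-1j * hamiltonian_superop(random_hermitian(rng, 4)))
        assert np.abs(ev.real).max() < 1e-10


class TestPartialTrace:
    def test_product_state_recovers_factor(self, rng):
        rho_a = random_density_matrix(rng, 2)
        rho_b = random_density_matrix(rng, 4)
        assert np.allclose(partial_trace(np.kron(rho_a, rho_b), 3, [1, 2]), rho_a,
                           atol=1e-13)

    def test_pure_up_up_traces_to_up(self):
        up = np.zeros((2, 2)); up[0, 0] = 1.0
        rho = np.kron(up, up)
        assert np.allclose(partial_trace(rho, 2, [1]), up)

    def test_superop_matches_elementwise_oracle(self, rng):
        rho = random_density_matrix(rng, 8)
        for traced in ([0], [2], [0, 2]):
            t = partial_trace_superop(3, traced)
            via_superop = devectorize(t @ vectorize(rho))
            assert np.allclose(via_superop, _oracle_partial_trace(rho, 3, traced),
                               atol=1e-12)

    def test_trace_preserving(self, rng):
        rho = random_density_matrix(rng, 8)
        t = partial_trace_superop(3, [1])
        assert trace_of_vec(t @ vectorize(rho)) == pytest.approx(1.0)

    def test_index_out_of_range(self):
        with pytest.raises(IndexError):
            partial_trace_superop(2, [5])

    def test_tracing_everything_rejected(self):
        with pytest.raises(ValueError):
            partial_trace_superop(2, [0, 1])


class TestAttach:
    def test_unpolarized_proton_attachment(self):
        up = np.zeros((2, 2), dtype=complex); up[0, 0] = 1.0
        combined = attach(up, np.eye(2) / 2, positions=[1])
        assert np.allclose(combined, np.kron(up, np.eye(2) / 2))

    def test_insert_position_reorders_spins(self, rng):
        rho_a = random_density_matrix(rng, 2)
        rho_b = random_density_matrix(rng, 2)
        combined = attach(rho_a, rho_b, positions=[0])
        assert np.allclose(combined, np.kron(rho_b, rho_a), atol=1e-13)

    def test_trace_then_attach_is_identity(self, rng):
        for pos in ([0], [1], [2]):
            d = attach_superop(2, 1, pos)
            t = partial_trace_superop(3, pos)
            assert np.allclose(t @ d, np.eye(16), atol=1e-12)

    def test_trace_multiplicativity(self, rng):
        rho_a = 0.37 * random_density_matrix(rng, 4)  # sub-normalized species
        d = attach_superop(2, 1, [2])
        out = d @ vectorize(rho_a)
        assert trace_of_vec(out) == pytest.approx(0.37)

    def test_non_unit_trace_bath_rejected(self):
        with pytest.raises(ValueError, match="unit trace"):
            attach_superop(1, 1, [0], rho_b=np.eye(2))

    def test_permute_spins_involution(self, rng):
        rho = random_density_matrix(rng, 8)
        assert np.allclose(permute_spins(permute_spins(rho, [2, 0, 1]), [1, 2, 0]),
                           rho)


class TestRelaxation:
    def test_identity_is_stationary(self):
        sys = system(["1H", "13C"], [[0.0, 120.0], [120.0, 0.0]])
        r = relaxation_superop(sys, [3.0, 5.0])
        assert np.abs(r @ vectorize(np.eye(4) / 4)).max() < 1e-14

    def test_single_spin_longitudinal_decay_calibration(self):
        """Propagating I_z under R alone decays as exp(-t/T1)."""
        sys = system(["1H"], [[0.0]])
        t1 = 10.0
        r = relaxation_superop(sys, [t1])
        iz = spin_operators(sys)[0, 2]
        rho0 = np.eye(2) / 2 + 1e-5 * iz
        for t in (1.0, 5.0, 20.0):
            rho_t = devectorize(scipy.linalg.expm(r * t) @ vectorize(rho0))
            amp = np.trace(rho_t @ iz).real
            assert amp == pytest.approx(1e-5 * 0.5 * np.exp(-t / t1), rel=1e-9)

    def test_infinite_t1_disables_one_spin(self):
        sys = system(["1H", "15N"], np.zeros((2, 2)))
        r = relaxation_superop(sys, [np.inf, 2.0])
        ops = spin_operators(sys)
        decay_h = devectorize(r @ vectorize(ops[0, 2]))
        assert np.abs(decay_h).max() < 1e-14

    def test_trace_preserving(self, rng):
        sys = system(["1H", "13C"], [[0.0, 120.0], [120.0, 0.0]])
        r = relaxation_superop(sys, [1.0, 2.0])
        rho = random_density_matrix(rng, 4)
        assert abs(trace_of_vec(r @ vectorize(rho))) < 1e-12

    def test_missing_or_invalid_t1_rejected(self):
        sys = system(["1H", "13C"], np.zeros((2, 2)))
        with pytest.raises(ValueError):
            relaxation_superop(sys, [1.0])
        with pytest.raises(ValueError):
            relaxation_superop(sys, [1.0, -2.0])


class TestHermiticityPreservation:
    def test_generators_preserve_hermiticity(self, rng):
        """devec(G vec(rho)) stays Hermitian for every generator block."""
        sys = system(["1H", "13C"], [[0.0, 120.0], [120.0, 0.0]])
        rho = random_density_matrix(rng, 4)
        h = random_hermitian(rng, 4, scale=100.0)
        gens = [
            -1j * hamiltonian_superop(h),
            relaxation_superop(sys, [1.0, 3.0]),
        ]
        for g in gens:
            out = devectorize(g @ vectorize(rho))
            assert np.allclose(out, out.conj().T, atol=1e-10)
        t = partial_trace_superop(2, [1])
        out = devectorize(t @ vectorize(rho))
        assert np.allclose(out, out.conj().T, atol=1e-12)
        d = attach_superop(2, 1, [1])
        out = devectorize(d @ vectorize(rho))
        assert np.allclose(out, out.conj().T, atol=1e-12)
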