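"""Superoperator algebra on column-vectorized density matrices.

Density matrices are flattened by column-wise concatenation,
``vec(rho) = rho.flatten(order="F")``, and every superoperator is an ordinary
(generally rectangular) numpy matrix acting on such vectors.  The normative
contract is the Kronecker identity

    vec(P @ rho @ Q) == kron(Q.T, P) @ vec(rho)

which fixes the storage scheme once and is unit-tested.

The module provides the four generator building blocks of the exchange master
equation: Hamiltonian commutators, fluctuating-field relaxation, partial
trace (removal of an exchanged subsystem) and attachment of a bath subsystem.
"""

from __future__ import annotations

import warnings

import numpy as np

from .spin_system import SpinSystem, spin_operators

__all__ = [
    "vectorize",
    "devectorize",
    "trace_of_vec",
    "expectation",
    "hamiltonian_superop",
    "partial_trace",
    "partial_trace_superop",
    "attach",
    "attach_superop",
    "permute_spins",
    "relaxation_superop",
    "superop_from_map",
]


def vectorize(rho: np.ndarray) -> np.ndarray:
    """Column-wise stacking of a square matrix into a length-d^2 vector."""
    rho = np.asarray(rho)
    if rho.ndim != 2 or rho.shape[0] != rho.shape[1]:
        raise ValueError(f"expected a square matrix, got shape {rho.shape}")
    return rho.flatten(order="F")


def devectorize(vec: np.ndarray) -> np.ndarray:
    """Inverse of :func:`vectorize`."""
    vec = np.asarray(vec)
    d = int(round(np.sqrt(vec.size)))
    if d * d != vec.size:
        raise ValueError(f"vector length {vec.size} is not a perfect square")
    return vec.reshape((d, d), order="F")


def trace_of_vec(vec: np.ndarray) -> complex:
    """Trace of the density matrix underlying a vectorized state."""
    d = int(round(np.sqrt(np.asarray(vec).size)))
    return complex(np.sum(vec[:: d + 1]))


def expectation(op: np.ndarray, vec: np.ndarray) -> complex:
    """``Tr(op @ rho)`` evaluated directly on the vectorized state."""
    return complex(vectorize(np.asarray(op).T) @ vec)


def hamiltonian_superop(h: np.ndarray) -> np.ndarray:
    """Commutator superoperator ``vec(rho) -> vec(H rho - rho H)``.

    The Liouvillian coherent part is ``-1j * hamiltonian_superop(H)``; its
    spectrum is purely imaginary for Hermitian H.  A non-Hermitian H is
    accepted with a warning (the commutator is still well defined).
    """
    h = np.asarray(h, dtype=complex)
    if not np.allclose(h, h.conj().T, atol=1e-10 * max(1.0, np.abs(h).max())):
        warnings.warn("Hamiltonian is not Hermitian; commutator computed anyway",
                      stacklevel=2)
    eye = np.eye(h.shape[0])
    return np.kron(eye, h) - np.kron(h.T, eye)


def superop_from_map(fn, d_in: int, d_out: int) -> np.ndarray:
    """Matrix of an arbitrary linear map on density matrices.

    ``fn`` maps a ``d_in x d_in`` matrix to a ``d_out x d_out`` matrix; the
    columns of the result are the vectorized images of the matrix units,
    enumerated in column-stacking order.
    """
    s = np.zeros((d_out * d_out, d_in * d_in), dtype=complex)
    e = np.zeros((d_in, d_in), dtype=complex)
    for k in range(d_in * d_in):
        e[k % d_in, k // d_in] = 1.0
        s[:, k] = vectorize(fn(e))
        e[k % d_in, k // d_in] = 0.0
    return s


def partial_trace(rho: np.ndarray, n_spins: int, traced) -> np.ndarray:
    """Partial trace of an ``n_spins`` spin-1/2 density matrix.

    ``traced`` lists the spin indices to remove; the remaining spins keep
    their declaration order.
    """
    traced = sorted(set(traced))
    if any(t < 0 or t >= n_spins for t in traced):
        raise IndexError("traced spin index out of range")
    if len(traced) >= n_spins:
        raise ValueError("traced indices must be a proper subset of the spins")
    keep = [i for i in range(n_spins) if i not in traced]
    t = np.asarray(rho).reshape((2,) * (2 * n_spins))
    row = list(range(n_spins))
    col = [i if i in traced else n_spins + i for i in range(n_spins)]
    out = [i for i in keep] + [n_spins + i for i in keep]
    res = np.einsum(t, row + col, out)
    dk = 2 ** len(keep)
    return res.reshape((dk, dk))


def partial_trace_superop(system_c, traced) -> np.ndarray:
    """Superoperator form of the partial trace, ``d_A^2 x d_C^2``.

    ``system_c`` is the full species (a :class:`SpinSystem` or a spin count);
    ``traced`` indexes the exchanged subsystem B.  Trace preserving:
    ``Tr(T rho) == Tr(rho)``.
    """
    n = system_c.n_spins if isinstance(system_c, SpinSystem) else int(system_c)
    traced = sorted(set(traced))
    d_c = 2 ** n
    d_a = 2 ** (n - len(traced))
    return superop_from_map(lambda r: partial_trace(r, n, traced), d_c, d_a)


def permute_spins(rho: np.ndarray, source_of) -> np.ndarray:
    """Reorder the spins of a density matrix.

    Slot ``p`` of the result holds the spin ``source_of[p]`` of the input.
    """
    n = len(source_of)
    t = np.asarray(rho).reshape((2,) * (2 * n))
    axes = list(source_of) + [s + n for s in source_of]
    return t.transpose(axes).reshape((2 ** n, 2 ** n))


def attach(rho_a: np.ndarray, rho_b: np.ndarray, positions) -> np.ndarray:
    """``rho_A (x) rho_B`` with the attached spins placed at ``positions``.

    ``positions`` are the indices the B spins occupy in the combined system;
    the A spins fill the remaining slots in order.
    """
    positions = list(positions)
    n_a = int(round(np.log2(rho_a.shape[0])))
    n_b = int(round(np.log2(rho_b.shape[0])))
    n = n_a + n_b
    combined = np.kron(rho_a, rho_b)  # order: A spins then B spins
    source_of = []
    a_next = 0
    for p in range(n):
        if p in positions:
            source_of.append(n_a + positions.index(p))
        else:
            source_of.append(a_next)
            a_next += 1
    return permute_spins(combined, source_of)


def attach_superop(system_a, attached, positions, rho_b: np.ndarray | None = None) -> np.ndarray:
    """Attachment superoperator ``d_C^2 x d_A^2`` with a fixed bath state.

    Forms species C from species A by adjoining subsystem B in the fixed state
    ``rho_b`` (default: maximally mixed, the unpolarized-bath assumption for
    freely exchanging protons).  Satisfies ``T . D = identity`` when T traces
    the attached spins, and multiplies the trace by ``Tr(rho_b) = 1``.
    """
    n_a = system_a.n_spins if isinstance(system_a, SpinSystem) else int(system_a)
    n_b = attached.n_spins if isinstance(attached, SpinSystem) else int(attached)
    d_a, d_b = 2 ** n_a, 2 ** n_b
    if rho_b is None:
        rho_b = np.eye(d_b, dtype=complex) / d_b
    else:
        rho_b = np.asarray(rho_b, dtype=complex)
        if rho_b.shape != (d_b, d_b):
            raise ValueError(f"bath state must be {d_b}x{d_b}")
        if abs(np.trace(rho_b) - 1.0) > 1e-10:
            raise ValueError("bath state must have unit trace")
    positions = list(positions)
    if len(positions) != n_b:
        raise ValueError("need one insertion position per attached spin")
    return superop_from_map(lambda r: attach(r, rho_b, positions), d_a, 2 ** (n_a + n_b))


def _double_commutator_superop(a: np.ndarray) -> np.ndarray:
    # vec([A,[A,rho]]) = (kron(I, A^2) + kron((A^2).T, I) - 2 kron(A.T, A)) vec(rho)
    eye = np.eye(a.shape[0])
    a2 = a @ a
    return np.kron(eye, a2) + np.kron(a2.T, eye) - 2.0 * np.kron(a.T, a)


def relaxation_superop(sys: SpinSystem, t1_s) -> np.ndarray:
    """Isotropic fluctuating-field relaxation superoperator (extreme narrowing).

    R = -sum_i b_i sum_{q in xyz} [I_iq, [I_iq, . ]]  with  b_i = 1/(2 T1_i),

    calibrated so an isolated spin i relaxes its longitudinal deviation with
    the high-field time constant ``T1_i`` (and transverse coherences with the
    same constant -- uncorrelated isotropic local fields, no spectral-density
    input needed beyond T1).  Trace preserving; the identity is stationary.

    ``t1_s`` is one T1 per spin in seconds; ``math.inf`` switches relaxation
    off for that spin.
    """
    t1 = list(t1_s)
    if len(t1) != sys.n_spins:
        raise ValueError(f"need one T1 per spin ({sys.n_spins}), got {len(t1)}")
    if any(t is None for t in t1):
        raise ValueError("missing T1 value")
    if any(t <= 0 for t in t1):
        raise ValueError("T1 values must be positive")
    d2 = sys.dim ** 2
    r = np.zeros((d2, d2), dtype=complex)
    ops = spin_operators(sys)
    for i, t1_i in enumerate(t1):
        b = 1.0 / (2.0 * t1_i)
        if b == 0.0:
            continue
        for q in range(3):
            r -= b * _double_commutator_superop(ops[i, q])
    return r
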