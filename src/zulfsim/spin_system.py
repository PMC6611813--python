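"""Spin-1/2 systems: operators, Hamiltonians, and thermal initial states.

A :class:`SpinSystem` is an ordered list of spin-1/2 isotopes together with a
symmetric matrix of scalar (J) couplings in Hz.  At zero magnetic field the
spin Hamiltonian is the pure J-coupling form

    H = 2*pi * sum_{i<j} J_ij (I_i . I_j)            [rad/s]

whose eigenstate structure alone fixes the positions of the lines in a
J-spectrum.  At high field the heteronuclear couplings are truncated to their
secular part ``2*pi*J_ij*I_iz*I_jz`` (doubly rotating frame, all chemical-shift
offsets zero); homonuclear couplings keep the full scalar form.

Conventions
-----------
* Hamiltonians are returned in angular-frequency units (rad/s); all
  user-facing coupling constants and spectral axes are in Hz.
* Spins are indexed ``0..n-1`` in declaration order and every tensor product
  follows that order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Isotope",
    "SpinSystem",
    "UnsupportedIsotopeError",
    "isotope",
    "spin_operators",
    "zero_field_hamiltonian",
    "highfield_hamiltonian",
    "zeeman_hamiltonian",
    "thermal_state",
    "subsystem",
    "total_operator",
    "magnetometer_operator",
    "allowed_transition_frequencies",
]

HBAR = 1.054571817e-34  # J s
K_B = 1.380649e-23  # J/K

#: gyromagnetic ratios, rad s^-1 T^-1 (signed); spin-1/2 isotopes only
GAMMA = {
    "1H": 267.522187e6,
    "13C": 67.28284e6,
    "15N": -27.126e6,
    "19F": 251.81508e6,
    "31P": 108.291e6,
}

_SIGMA_HALF = {
    "x": np.array([[0.0, 0.5], [0.5, 0.0]], dtype=complex),
    "y": np.array([[0.0, -0.5j], [0.5j, 0.0]], dtype=complex),
    "z": np.array([[0.5, 0.0], [0.0, -0.5]], dtype=complex),
}


class UnsupportedIsotopeError(ValueError):
    """Raised for isotopes outside the supported spin-1/2 table."""


@dataclass(frozen=True)
class Isotope:
    """A spin-1/2 nucleus with its gyromagnetic ratio (rad/s/T, signed)."""

    symbol: str
    gamma: float
    spin: float = 0.5

    def __post_init__(self) -> None:
        if self.spin != 0.5:
            raise UnsupportedIsotopeError(
                f"only spin-1/2 nuclei are supported, got spin={self.spin}"
            )


def isotope(symbol: str) -> Isotope:
    """Look up a supported isotope by symbol, e.g. ``"1H"`` or ``"15N"``."""
    try:
        return Isotope(symbol=symbol, gamma=GAMMA[symbol])
    except KeyError:
        raise UnsupportedIsotopeError(
            f"unsupported isotope {symbol!r}; supported: {sorted(GAMMA)}"
        ) from None


@dataclass(frozen=True)
class SpinSystem:
    """One chemical species: ordered spin-1/2 nuclei plus their J network.

    Parameters
    ----------
    isotopes
        Isotope objects (or symbols via :func:`system`) in declaration order.
    j_hz
        Symmetric ``n x n`` scalar-coupling matrix in Hz with zero diagonal.
    label
        Free-form species label used in reports.
    """

    isotopes: tuple[Isotope, ...]
    j_hz: np.ndarray = field(repr=False)
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "isotopes", tuple(self.isotopes))
        j = np.array(self.j_hz, dtype=float)
        n = len(self.isotopes)
        if j.shape != (n, n):
            raise ValueError(f"J matrix must be {n}x{n}, got {j.shape}")
        if not np.allclose(j, j.T, atol=1e-12):
            raise ValueError("J matrix must be symmetric")
        if not np.allclose(np.diag(j), 0.0, atol=1e-12):
            raise ValueError("J matrix must have zero diagonal")
        j = 0.5 * (j + j.T)
        j.flags.writeable = False
        object.__setattr__(self, "j_hz", j)

    @property
    def n_spins(self) -> int:
        return len(self.isotopes)

    @property
    def dim(self) -> int:
        """Hilbert-space dimension, ``2**n_spins``."""
        return 2 ** self.n_spins

    @property
    def gammas(self) -> np.ndarray:
        return np.array([iso.gamma for iso in self.isotopes])


def system(isotopes, j_hz, label: str = "") -> SpinSystem:
    """Convenience constructor accepting isotope symbols."""
    isos = tuple(iso if isinstance(iso, Isotope) else isotope(iso) for iso in isotopes)
    return SpinSystem(isotopes=isos, j_hz=np.asarray(j_hz, dtype=float), label=label)


def spin_operators(sys: SpinSystem) -> np.ndarray:
    """Cartesian angular-momentum operators in the full Hilbert space.

    Returns an array of shape ``(n_spins, 3, d, d)`` indexed as
    ``ops[i, q]`` with ``q = 0, 1, 2`` for x, y, z.  Standard Pauli/Kronecker
    construction with identity on every other slot.
    """
    n = sys.n_spins
    d = sys.dim
    ops = np.zeros((n, 3, d, d), dtype=complex)
    eye = np.eye(2, dtype=complex)
    for i in range(n):
        for q, axis in enumerate("xyz"):
            op = np.array([[1.0]], dtype=complex)
            for k in range(n):
                op = np.kron(op, _SIGMA_HALF[axis] if k == i else eye)
            ops[i, q] = op
    return ops


def zero_field_hamiltonian(sys: SpinSystem) -> np.ndarray:
    """Pure J-coupling Hamiltonian ``2*pi*sum_{i<j} J_ij I_i.I_j`` in rad/s."""
    ops = spin_operators(sys)
    d = sys.dim
    h = np.zeros((d, d), dtype=complex)
    for i in range(sys.n_spins):
        for j in range(i + 1, sys.n_spins):
            jij = sys.j_hz[i, j]
            if jij == 0.0:
                continue
            h += 2.0 * np.pi * jij * sum(ops[i, q] @ ops[j, q] for q in range(3))
    return h


def highfield_hamiltonian(sys: SpinSystem) -> np.ndarray:
    """Secular rotating-frame Hamiltonian (rad/s), all offsets zero.

    Heteronuclear couplings are truncated to ``2*pi*J*I_iz*I_jz``;
    homonuclear couplings keep the full scalar form (between magnetically
    equivalent spins this commutes with the detection operator and shifts no
    line).
    """
    ops = spin_operators(sys)
    d = sys.dim
    h = np.zeros((d, d), dtype=complex)
    for i in range(sys.n_spins):
        for j in range(i + 1, sys.n_spins):
            jij = sys.j_hz[i, j]
            if jij == 0.0:
                continue
            if sys.isotopes[i].symbol == sys.isotopes[j].symbol:
                h += 2.0 * np.pi * jij * sum(ops[i, q] @ ops[j, q] for q in range(3))
            else:
                h += 2.0 * np.pi * jij * (ops[i, 2] @ ops[j, 2])
    return h


def zeeman_hamiltonian(sys: SpinSystem, b_field_t) -> np.ndarray:
    """Zeeman Hamiltonian ``-sum_i gamma_i B . I_i`` in rad/s.

    ``b_field_t`` is either a scalar (field along z) or a 3-vector in tesla.
    """
    b = np.asarray(b_field_t, dtype=float)
    if b.ndim == 0:
        b = np.array([0.0, 0.0, float(b)])
    if b.shape != (3,):
        raise ValueError("b_field_t must be a scalar or a 3-vector (tesla)")
    ops = spin_operators(sys)
    h = np.zeros((sys.dim, sys.dim), dtype=complex)
    for i, iso in enumerate(sys.isotopes):
        for q in range(3):
            if b[q] != 0.0:
                h -= iso.gamma * b[q] * ops[i, q]
    return h


def thermal_state(
    sys: SpinSystem,
    b_field_t: float,
    temperature_k: float,
    polarized_spins=None,
) -> np.ndarray:
    """High-temperature thermal density matrix at field ``b_field_t`` (z).

    rho = (1 + sum_i gamma_i*hbar*B/(k_B*T) * I_iz) / 2**n  -- unit trace,
    deviation linear in B.  ``polarized_spins`` optionally restricts the
    deviation to a subset of spin indices (used to isolate the 1H-borne part
    of a signal); ``None`` polarizes every spin.
    """
    if temperature_k <= 0:
        raise ValueError("temperature must be positive")
    if b_field_t < 0:
        raise ValueError("polarizing field must be nonnegative")
    d = sys.dim
    rho = np.eye(d, dtype=complex) / d
    if b_field_t == 0.0:
        return rho
    ops = spin_operators(sys)
    idx = range(sys.n_spins) if polarized_spins is None else polarized_spins
    for i in idx:
        eps = sys.isotopes[i].gamma * HBAR * b_field_t / (K_B * temperature_k)
        rho += eps * ops[i, 2] / d
    return rho


def subsystem(sys: SpinSystem, keep_indices, label: str | None = None) -> SpinSystem:
    """Sub-system on a subset of spins (declaration order preserved)."""
    keep = list(keep_indices)
    if any(i < 0 or i >= sys.n_spins for i in keep):
        raise IndexError(f"spin index out of range for {sys.n_spins}-spin system")
    isos = tuple(sys.isotopes[i] for i in keep)
    j = sys.j_hz[np.ix_(keep, keep)]
    return SpinSystem(isotopes=isos, j_hz=j, label=label if label is not None else sys.label)


def total_operator(sys: SpinSystem, axis: str = "z", weights=None) -> np.ndarray:
    """Weighted total angular momentum ``sum_i w_i I_i,axis`` (default w=1)."""
    q = "xyz".index(axis)
    ops = spin_operators(sys)
    w = np.ones(sys.n_spins) if weights is None else np.asarray(weights, dtype=float)
    return np.tensordot(w, ops[:, q], axes=(0, 0))


def magnetometer_operator(sys: SpinSystem, axis: str = "z") -> np.ndarray:
    """ZULF detection operator: gamma-weighted total magnetization.

    ``sum_i (gamma_i/|gamma_1H|) I_i,axis`` -- the magnetometer measures the
    total magnetization along its sensitive axis; amplitudes are arbitrary
    units, so the weights are normalized to the proton gyromagnetic ratio.
    """
    return total_operator(sys, axis=axis, weights=sys.gammas / abs(GAMMA["1H"]))


def allowed_transition_frequencies(
    h_rad: np.ndarray,
    detection_op: np.ndarray,
    min_overlap: float = 1e-8,
    min_frequency_hz: float = 1e-6,
) -> np.ndarray:
    """Transition frequencies (Hz, positive) connected by a detection operator.

    Exhaustive eigen-decomposition oracle: diagonalize H, transform the
    detection operator into the eigenbasis, and collect ``|E_i - E_j|/2pi``
    wherever the matrix element exceeds ``min_overlap`` times the largest one.
    Zero-frequency coherences between degenerate states are dropped
    (``min_frequency_hz`` floor).
    """
    energies, vecs = np.linalg.eigh(h_rad)
    o = vecs.conj().T @ detection_op @ vecs
    scale = np.abs(o).max()
    if scale == 0.0:
        return np.array([])
    freqs = []
    n = len(energies)
    for i in range(n):
        for j in range(i + 1, n):
            if abs(o[i, j]) > min_overlap * scale:
                f = abs(energies[i] - energies[j]) / (2.0 * np.pi)
                if f > min_frequency_hz:
                    freqs.append(f)
    return np.array(sorted(freqs))
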