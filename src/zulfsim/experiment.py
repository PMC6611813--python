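"""Measurement protocols: propagation, ZULF detection, high-field detection.

The ZULF sequence mirrors the prepolarize / shuttle / sudden-drop / detect
experiment: the sample is thermally polarized at ``B_p`` (a few tesla),
transported for ``t_s`` under a weak guiding field ``B_g`` (exchange and
relaxation active all along), after which the field is switched off much
faster than any spin-dynamics timescale (sudden approximation: the density
matrix is continuous across the drop) and the magnetometer records the
gamma-weighted total z-magnetization while the state evolves under the pure
J-coupling Hamiltonian plus any residual field.

High-field acquisition is the usual pulse-acquire convention: an ideal,
instantaneous 90-degree pulse turns the observed isotope's polarization into
unit transverse magnetization, whose complex FID ``Tr(F+ rho(t))`` is then
recorded under the secular Hamiltonian with exchange and relaxation.

Propagation uses the single-step matrix exponential ``U = exp(M dt)`` applied
iteratively -- the generator is time independent once the field profile is
piecewise constant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.sparse
import scipy.sparse.linalg

from . import liouville
from .exchange import ExchangePair, ExchangeParams, build_generator, dissociation_return_generator
from .spin_system import (
    SpinSystem,
    highfield_hamiltonian,
    magnetometer_operator,
    thermal_state,
    total_operator,
    zeeman_hamiltonian,
    zero_field_hamiltonian,
)

__all__ = [
    "Protocol",
    "Trajectory",
    "NyquistError",
    "propagate",
    "zulf_experiment",
    "highfield_experiment",
]

# above this Liouville dimension, one-shot propagations (the shuttle interval)
# go through the sparse Krylov-free expm-times-vector routine instead of a
# dense matrix exponential
_SPARSE_ONESHOT_DIM = 500


class NyquistError(ValueError):
    """Sampling rate too low for the largest spectral frequency present."""


@dataclass(frozen=True)
class Protocol:
    """Experiment settings (defaults mirror the ammonium ZULF protocol)."""

    polarizing_field_t: float = 2.0
    polarizing_temperature_k: float = 298.0
    shuttle_time_s: float = 0.5
    guiding_field_t: float = 30e-6
    residual_field_t: tuple[float, float, float] = (0.0, 0.0, 0.0)
    dwell_time_s: float = 1e-3
    n_points: int = 16000
    detection_axis: str = "z"

    def __post_init__(self) -> None:
        if self.dwell_time_s <= 0:
            raise ValueError("dwell time must be positive")
        if self.n_points < 2:
            raise ValueError("need at least two acquisition points")
        if self.detection_axis not in ("x", "y", "z"):
            raise ValueError("detection axis must be x, y or z")
        if self.polarizing_field_t < 0 or self.shuttle_time_s < 0:
            raise ValueError("field and shuttle time must be nonnegative")

    @property
    def nyquist_hz(self) -> float:
        return 0.5 / self.dwell_time_s

    @property
    def acquisition_time_s(self) -> float:
        return self.n_points * self.dwell_time_s


@dataclass
class Trajectory:
    """Detected time-domain signal on a uniform grid."""

    times: np.ndarray
    signal: np.ndarray
    dwell_time_s: float
    metadata: dict = field(default_factory=dict)

    @property
    def is_complex(self) -> bool:
        return np.iscomplexobj(self.signal)


def propagate(m: np.ndarray, state0: np.ndarray, dt: float, n_points: int,
              observables=None):
    """Evolve ``d rho/dt = M rho`` on a uniform grid by exponentiation.

    The single-step propagator ``U = exp(M dt)`` is computed once and applied
    iteratively.  With ``observables`` (a sequence of row functionals, i.e.
    ``vec(O.T)`` vectors) the per-step signals are returned as an array of
    shape ``(len(observables), n_points)``; otherwise the full state
    trajectory ``(n_points, len(state0))`` is returned.
    """
    u = scipy.linalg.expm(np.asarray(m, dtype=complex) * dt)
    state = np.asarray(state0, dtype=complex).copy()
    if observables is not None:
        obs = np.atleast_2d(np.asarray(observables, dtype=complex))
        out = np.empty((obs.shape[0], n_points), dtype=complex)
        for k in range(n_points):
            out[:, k] = obs @ state
            state = u @ state
        return out
    states = np.empty((n_points, state.size), dtype=complex)
    for k in range(n_points):
        states[k] = state
        state = u @ state
    return states


def propagate_times(m: np.ndarray, state0: np.ndarray, times) -> np.ndarray:
    """States at arbitrary (possibly non-uniform) times.

    Non-uniform grids fall back to per-interval exponentials, which is slower;
    a warning says so.
    """
    times = np.asarray(times, dtype=float)
    dts = np.diff(times)
    if times.size > 2 and not np.allclose(dts, dts[0], rtol=1e-9, atol=0.0):
        warnings.warn("non-uniform time grid: using per-interval exponentials",
                      stacklevel=2)
        states = [np.asarray(state0, dtype=complex)]
        for dt in dts:
            states.append(scipy.linalg.expm(np.asarray(m) * dt) @ states[-1])
        return np.array(states)
    dt = dts[0] if dts.size else 0.0
    return propagate(m, state0, dt if dt > 0 else 1.0, times.size)


def _apply_exponential(m: np.ndarray, t: float, state: np.ndarray) -> np.ndarray:
    """One-shot ``exp(M t) @ state``; sparse path for large generators."""
    if t == 0.0:
        return state
    if m.shape[0] > _SPARSE_ONESHOT_DIM:
        sp = scipy.sparse.csr_matrix(m)
        return scipy.sparse.linalg.expm_multiply(sp * t, state)
    return scipy.linalg.expm(np.asarray(m, dtype=complex) * t) @ state


def _check_nyquist(h_rad: np.ndarray, protocol: Protocol, what: str) -> None:
    # conservative bound: full eigenvalue spread of the detection Hamiltonian
    ev = np.linalg.eigvalsh(h_rad)
    fmax = float(ev.max() - ev.min()) / (2.0 * np.pi)
    if fmax > protocol.nyquist_hz * (1.0 + 1e-9):
        raise NyquistError(
            f"{what}: largest transition frequency {fmax:.2f} Hz exceeds the "
            f"Nyquist frequency {protocol.nyquist_hz:.2f} Hz; shorten the dwell time"
        )


def _liouvillian(h: np.ndarray, sys: SpinSystem, t1_s) -> np.ndarray:
    l = -1j * liouville.hamiltonian_superop(h)
    if t1_s is not None:
        l = l + liouville.relaxation_superop(sys, t1_s)
    return l


def _split_relaxation(pair: ExchangePair, t1_s):
    if t1_s is None:
        return None, None
    t1_c = list(t1_s)
    if len(t1_c) != pair.species_c.n_spins:
        raise ValueError("need one T1 per spin of species C")
    return [t1_c[i] for i in pair.a_spin_map()], t1_c


def _proton_indices(sys: SpinSystem):
    return [i for i, iso in enumerate(sys.isotopes) if iso.symbol == "1H"]


def _initial_zulf_state(sys: SpinSystem, protocol: Protocol, weight: float,
                        initial: str) -> np.ndarray:
    if initial == "thermal":
        pol = None
    elif initial == "proton-thermal":
        pol = _proton_indices(sys)
    else:
        raise ValueError("initial must be 'thermal' or 'proton-thermal'")
    rho = thermal_state(sys, protocol.polarizing_field_t,
                        protocol.polarizing_temperature_k, polarized_spins=pol)
    return weight * liouville.vectorize(rho)


def zulf_experiment(
    target,
    protocol: Protocol | None = None,
    params: ExchangeParams | None = None,
    relaxation=None,
    initial: str = "thermal",
) -> Trajectory:
    """Prepolarize / shuttle / sudden-drop / detect sequence.

    ``target`` is a plain :class:`SpinSystem` (no exchange) or an
    :class:`ExchangePair` with ``params``.  ``relaxation`` is a per-spin T1
    list for the full species C (``math.inf`` entries switch single spins
    off).  ``initial="proton-thermal"`` restricts the prepolarized deviation
    to the 1H spins, isolating the proton-borne part of the signal.

    Returns the real detected signal ``sum_species Tr(O rho(t))`` with
    ``O = sum_i (gamma_i/|gamma_H|) I_i`` along the detection axis.
    """
    protocol = protocol or Protocol()
    dt, n = protocol.dwell_time_s, protocol.n_points
    b_res = np.asarray(protocol.residual_field_t, dtype=float)
    b_shuttle = np.array([0.0, 0.0, protocol.guiding_field_t])

    if isinstance(target, SpinSystem):
        return _zulf_single_species(target, protocol, relaxation, initial,
                                    b_shuttle, b_res, dt, n)
    if not isinstance(target, ExchangePair):
        raise TypeError("target must be a SpinSystem or an ExchangePair")
    if params is None:
        raise ValueError("an ExchangePair target requires exchange params")

    pair = target
    x_a, x_c = params.mole_fractions()
    t1_a, t1_c = _split_relaxation(pair, relaxation)

    h_det_a = zero_field_hamiltonian(pair.species_a) + zeeman_hamiltonian(pair.species_a, b_res)
    h_det_c = zero_field_hamiltonian(pair.species_c) + zeeman_hamiltonian(pair.species_c, b_res)
    _check_nyquist(h_det_c, protocol, pair.species_c.label or "species C")

    state = np.concatenate([
        _initial_zulf_state(pair.species_a, protocol, x_a, initial),
        _initial_zulf_state(pair.species_c, protocol, x_c, initial),
    ])

    if protocol.shuttle_time_s > 0:
        m_shuttle = build_generator(
            pair, params,
            _liouvillian(zero_field_hamiltonian(pair.species_a)
                         + zeeman_hamiltonian(pair.species_a, b_shuttle),
                         pair.species_a, t1_a),
            _liouvillian(zero_field_hamiltonian(pair.species_c)
                         + zeeman_hamiltonian(pair.species_c, b_shuttle),
                         pair.species_c, t1_c),
        )
        state = _apply_exponential(m_shuttle, protocol.shuttle_time_s, state)

    m_det = build_generator(
        pair, params,
        _liouvillian(h_det_a, pair.species_a, t1_a),
        _liouvillian(h_det_c, pair.species_c, t1_c),
    )
    o_a = magnetometer_operator(pair.species_a, protocol.detection_axis)
    o_c = magnetometer_operator(pair.species_c, protocol.detection_axis)
    functional = np.concatenate([liouville.vectorize(o_a.T), liouville.vectorize(o_c.T)])
    signal = propagate(m_det, state, dt, n, observables=[functional])[0]
    times = np.arange(n) * dt
    return Trajectory(times=times, signal=signal.real, dwell_time_s=dt,
                      metadata={"kind": "zulf", "x_a": x_a, "x_c": x_c,
                                "label": pair.label or pair.species_c.label})


def _zulf_single_species(sys, protocol, relaxation, initial, b_shuttle, b_res, dt, n):
    h_shuttle = zero_field_hamiltonian(sys) + zeeman_hamiltonian(sys, b_shuttle)
    h_det = zero_field_hamiltonian(sys) + zeeman_hamiltonian(sys, b_res)
    _check_nyquist(h_det, protocol, sys.label or "spin system")
    o = magnetometer_operator(sys, protocol.detection_axis)
    pol = None if initial == "thermal" else _proton_indices(sys)
    if initial not in ("thermal", "proton-thermal"):
        raise ValueError("initial must be 'thermal' or 'proton-thermal'")
    rho = thermal_state(sys, protocol.polarizing_field_t,
                        protocol.polarizing_temperature_k, polarized_spins=pol)
    # the maximally mixed part neither evolves nor contributes to the
    # (traceless) detection operator; dropping it keeps the tiny thermal
    # deviation free of rounding noise from the large identity background
    rho = rho - np.eye(sys.dim) / sys.dim
    times = np.arange(n) * dt
    if relaxation is None:
        # exchange-free, relaxation-free: exact Hilbert-space propagation
        if protocol.shuttle_time_s > 0:
            u_s = scipy.linalg.expm(-1j * h_shuttle * protocol.shuttle_time_s)
            rho = u_s @ rho @ u_s.conj().T
        u = scipy.linalg.expm(-1j * h_det * dt)
        signal = np.empty(n)
        for k in range(n):
            signal[k] = np.trace(o @ rho).real
            rho = u @ rho @ u.conj().T
        return Trajectory(times=times, signal=signal, dwell_time_s=dt,
                          metadata={"kind": "zulf", "label": sys.label})
    state = liouville.vectorize(rho)
    if protocol.shuttle_time_s > 0:
        state = _apply_exponential(_liouvillian(h_shuttle, sys, relaxation),
                                   protocol.shuttle_time_s, state)
    m = _liouvillian(h_det, sys, relaxation)
    functional = liouville.vectorize(o.T)
    signal = propagate(m, state, dt, n, observables=[functional])[0]
    return Trajectory(times=times, signal=signal.real, dwell_time_s=dt,
                      metadata={"kind": "zulf", "label": sys.label})


def _observed_indices(sys: SpinSystem, observed: str):
    idx = [i for i, iso in enumerate(sys.isotopes) if iso.symbol == observed]
    return idx


def _transverse_init(sys: SpinSystem, observed: str, weight: float) -> np.ndarray:
    idx = _observed_indices(sys, observed)
    fx = sum(total_operator(sys, "x", weights=np.eye(sys.n_spins)[i]) for i in idx)
    # per-molecule transverse magnetization after an ideal 90-degree pulse;
    # 2/d normalization makes Tr(F+ rho0) = (number of observed spins)/2
    return weight * liouville.vectorize(2.0 * fx / sys.dim)


def highfield_experiment(
    target,
    protocol: Protocol | None = None,
    params: ExchangeParams | None = None,
    relaxation=None,
    observed: str = "15N",
    fast_reassociation: bool = False,
) -> Trajectory:
    """Pulse-acquire FID of one isotope in the doubly rotating frame.

    Initial state: unit transverse magnetization of ``observed`` (ideal,
    instantaneous 90-degree pulse), weighted by the species mole fractions.
    Evolution: secular high-field Hamiltonians + exchange + relaxation.
    Signal: complex ``Tr(F+ rho(t))`` summed over species containing the
    observed isotope.

    ``fast_reassociation=True`` uses the adiabatically eliminated
    dissociation-return generator on species C alone (valid when
    ``W_a >> k_d`` and all spectral widths; the acidic-ammonium regime).
    """
    protocol = protocol or Protocol()
    dt, n = protocol.dwell_time_s, protocol.n_points
    times = np.arange(n) * dt

    if isinstance(target, SpinSystem):
        if not _observed_indices(target, observed):
            raise ValueError(f"observed isotope {observed} absent from {target.label!r}")
        h = highfield_hamiltonian(target)
        _check_nyquist(h, protocol, target.label or "spin system")
        m = _liouvillian(h, target, relaxation)
        state = _transverse_init(target, observed, 1.0)
        fplus = _fplus_functional(target, observed)
        signal = propagate(m, state, dt, n, observables=[fplus])[0]
        return Trajectory(times=times, signal=signal, dwell_time_s=dt,
                          metadata={"kind": "highfield", "observed": observed})

    if not isinstance(target, ExchangePair):
        raise TypeError("target must be a SpinSystem or an ExchangePair")
    if params is None:
        raise ValueError("an ExchangePair target requires exchange params")
    pair = target
    if not _observed_indices(pair.species_c, observed):
        raise ValueError(f"observed isotope {observed} absent from species C")
    x_a, x_c = params.mole_fractions()
    t1_a, t1_c = _split_relaxation(pair, relaxation)
    h_c = highfield_hamiltonian(pair.species_c)
    _check_nyquist(h_c, protocol, pair.species_c.label or "species C")
    l_c = _liouvillian(h_c, pair.species_c, t1_c)

    if fast_reassociation:
        m = dissociation_return_generator(pair, params.kd_s, l_c)
        state = _transverse_init(pair.species_c, observed, 1.0)
        fplus = _fplus_functional(pair.species_c, observed)
        signal = propagate(m, state, dt, n, observables=[fplus])[0]
        return Trajectory(times=times, signal=signal, dwell_time_s=dt,
                          metadata={"kind": "highfield", "observed": observed,
                                    "fast_reassociation": True})

    h_a = highfield_hamiltonian(pair.species_a)
    l_a = _liouvillian(h_a, pair.species_a, t1_a)
    m = build_generator(pair, params, l_a, l_c)
    init_a = (_transverse_init(pair.species_a, observed, x_a)
              if _observed_indices(pair.species_a, observed)
              else np.zeros(pair.dim_a ** 2, dtype=complex))
    state = np.concatenate([init_a, _transverse_init(pair.species_c, observed, x_c)])
    fplus = np.concatenate([
        _fplus_functional(pair.species_a, observed)
        if _observed_indices(pair.species_a, observed)
        else np.zeros(pair.dim_a ** 2, dtype=complex),
        _fplus_functional(pair.species_c, observed),
    ])
    signal = propagate(m, state, dt, n, observables=[fplus])[0]
    return Trajectory(times=times, signal=signal, dwell_time_s=dt,
                      metadata={"kind": "highfield", "observed": observed,
                                "x_a": x_a, "x_c": x_c})


def _fplus_functional(sys: SpinSystem, observed: str) -> np.ndarray:
    idx = _observed_indices(sys, observed)
    w = np.zeros(sys.n_spins)
    for i in idx:
        w[i] = 1.0
    fplus = total_operator(sys, "x", weights=w) + 1j * total_operator(sys, "y", weights=w)
    return liouville.vectorize(fplus.T)
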