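"""Chemical kinetics and the combined exchange + spin-dynamics generator.

The exchange scheme is ``A + B <=> C``: species A reversibly binds the
subsystem B (e.g. one or more solvent-exchangeable protons) to form species C.
With B in excess the association is pseudo-first-order, ``W_a = k_a [B]``, and
the concentrations obey a 2x2 linear rate law.  The same bookkeeping carries
over to the nuclear spin system: the joint state ``(rho_A, rho_C)`` of
column-vectorized density matrices evolves under the block generator

    M = [[ L_A - W_a*1,   k_d * T ],
         [ W_a * D,       L_C - k_d*1 ]]

where ``L = -i[H, .] + R`` is the Liouvillian of each species, ``T`` removes
the exchanged spins (partial trace) and ``D`` re-attaches them in the fixed,
unpolarized bath state.  This is the coupled-spin analogue of the
Bloch-McConnell equations; the dissociating spins leave with their state and
return uncorrelated, which is what erodes zero-field J-coherences.

Two mechanisms are supported for species whose exchangeable sites are
magnetically equivalent (ammonium):

* ``"generic"`` -- the whole subsystem B leaves and returns at once (for
  ammonium: all four protons simultaneously);
* ``"single-site"`` -- one uniformly chosen site leaves at a time, realized
  deterministically as the uniform average of per-site trace/attach
  superoperators (the ensemble picture of "a random proton").
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property

import numpy as np

from . import liouville
from .spin_system import SpinSystem, subsystem

__all__ = [
    "ExchangeParams",
    "ExchangePair",
    "ExchangeState",
    "speciation",
    "association_rate",
    "concentration_kinetics",
    "pair_superops",
    "build_generator",
    "dissociation_return_generator",
    "ammonium_generator",
]

MECHANISMS = ("generic", "single-site")


def speciation(ph: float, ka: float) -> tuple[float, float]:
    """Equilibrium mole fractions ``(x_A, x_C)`` of base and acid forms.

    ``x_C = 10**-pH / (10**-pH + K_a)`` (fraction of the protonated, acidic
    form C) and ``x_A = 1 - x_C`` by mass balance.
    """
    if ka <= 0:
        raise ValueError("K_a must be positive")
    h = 10.0 ** (-ph)
    x_c = h / (h + ka)
    return 1.0 - x_c, x_c


def association_rate(kd_s: float, ph: float, ka: float) -> float:
    """Pseudo-first-order association rate ``W_a = k_d * 10**-pH / K_a``.

    Follows from ``K_a = k_d/k_a`` with ``[B] = 10**-pH``; satisfies detailed
    balance ``x_C k_d = x_A W_a`` with :func:`speciation` exactly.
    """
    if kd_s < 0:
        raise ValueError("k_d must be nonnegative")
    if ka <= 0:
        raise ValueError("K_a must be positive")
    return kd_s * 10.0 ** (-ph) / ka


def concentration_kinetics(kd_s: float, wa_s: float, a0: float, c0: float, t):
    """Closed-form solution of the two-species rate equations.

    d/dt [A, C] = [[-W_a, +k_d], [+W_a, -k_d]] [A, C]; the total is conserved
    and the approach to equilibrium is single-exponential with rate
    ``k_d + W_a``.  Returns ``(A(t), C(t))`` for scalar or array ``t``.
    """
    if kd_s < 0 or wa_s < 0 or a0 < 0 or c0 < 0:
        raise ValueError("rates and concentrations must be nonnegative")
    t = np.asarray(t, dtype=float)
    total = a0 + c0
    rate = kd_s + wa_s
    if rate == 0.0:
        a = np.broadcast_to(a0, t.shape).copy()
        return a, total - a
    a_eq = total * kd_s / rate
    a = a_eq + (a0 - a_eq) * np.exp(-rate * t)
    return a, total - a


@dataclass(frozen=True)
class ExchangeParams:
    """Exchange rates and acid-base speciation for one A + B <=> C pair.

    Either give ``ph``/``pka`` (then ``W_a`` and the mole fractions follow
    from the speciation formulas) or set ``wa_s`` explicitly (then the mole
    fractions follow from detailed balance, ``x_C = W_a/(W_a + k_d)``).
    """

    kd_s: float
    pka: float | None = None
    ph: float | None = None
    wa_s: float | None = None

    def __post_init__(self) -> None:
        if self.kd_s < 0:
            raise ValueError("k_d must be nonnegative")
        if self.wa_s is not None and self.wa_s < 0:
            raise ValueError("W_a must be nonnegative")
        if self.wa_s is None and (self.pka is None or self.ph is None):
            raise ValueError("give either wa_s or both ph and pka")

    @property
    def ka(self) -> float:
        if self.pka is None:
            raise ValueError("pKa not set")
        return 10.0 ** (-self.pka)

    def association(self) -> float:
        """W_a in 1/s, explicit or derived from pH and pKa."""
        if self.wa_s is not None:
            return self.wa_s
        return association_rate(self.kd_s, self.ph, self.ka)

    def mole_fractions(self) -> tuple[float, float]:
        """(x_A, x_C), normalized to 1."""
        if self.wa_s is None:
            return speciation(self.ph, self.ka)
        denom = self.kd_s + self.wa_s
        if denom == 0.0:
            # no exchange at all: put everything in the bound form C
            return 0.0, 1.0
        x_c = self.wa_s / denom
        return 1.0 - x_c, x_c


@dataclass(frozen=True)
class ExchangePair:
    """Species C, its exchanged spins B, and the residual species A.

    ``exchanged`` indexes the B spins within C.  For the ``"single-site"``
    mechanism it lists the magnetically equivalent sites of which one leaves
    per event; for ``"generic"`` the whole set leaves together.
    """

    species_c: SpinSystem
    exchanged: tuple[int, ...]
    mechanism: str = "generic"
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "exchanged", tuple(sorted(set(self.exchanged))))
        n = self.species_c.n_spins
        if not self.exchanged:
            raise ValueError("exchanged spin set must be nonempty")
        if any(i < 0 or i >= n for i in self.exchanged):
            raise IndexError("exchanged spin index out of range")
        if len(self.exchanged) >= n:
            raise ValueError("exchanged spins must be a proper subset of C")
        if self.mechanism not in MECHANISMS:
            raise ValueError(f"unknown mechanism {self.mechanism!r}; one of {MECHANISMS}")
        if self.mechanism == "single-site":
            syms = {self.species_c.isotopes[i].symbol for i in self.exchanged}
            if len(syms) != 1:
                raise ValueError("single-site mechanism requires equivalent sites")
            j = self.species_c.j_hz
            for s in self.exchanged[1:]:
                perm = list(range(n))
                perm[self.exchanged[0]], perm[s] = perm[s], perm[self.exchanged[0]]
                if not np.allclose(j[np.ix_(perm, perm)], j, atol=1e-9):
                    raise ValueError(
                        "single-site mechanism requires J-equivalent sites"
                    )

    @cached_property
    def species_a(self) -> SpinSystem:
        """Residual species after one exchange event."""
        if self.mechanism == "single-site":
            removed = (self.exchanged[0],)
        else:
            removed = self.exchanged
        keep = [i for i in range(self.species_c.n_spins) if i not in removed]
        lbl = (self.species_c.label + "-B") if self.species_c.label else ""
        return subsystem(self.species_c, keep, label=lbl)

    @cached_property
    def species_b(self) -> SpinSystem:
        """Exchanged subsystem (a single spin for single-site)."""
        if self.mechanism == "single-site":
            idx = [self.exchanged[0]]
        else:
            idx = list(self.exchanged)
        return subsystem(self.species_c, idx, label="B")

    def a_spin_map(self) -> list[int]:
        """Indices of C's spins retained in A (declaration order)."""
        removed = (self.exchanged[0],) if self.mechanism == "single-site" else self.exchanged
        return [i for i in range(self.species_c.n_spins) if i not in removed]

    @property
    def dim_a(self) -> int:
        return self.species_a.dim

    @property
    def dim_c(self) -> int:
        return self.species_c.dim


def pair_superops(pair: ExchangePair, rho_b: np.ndarray | None = None):
    """Trace and attachment superoperators ``(T, D)`` for one pair.

    For ``"single-site"`` these are the uniform averages over the equivalent
    sites, ``T = (1/m) sum_j T_j`` and ``D = (1/m) sum_j D_j``; both remain
    exactly trace preserving.
    """
    c = pair.species_c
    if pair.mechanism == "generic":
        t = liouville.partial_trace_superop(c, pair.exchanged)
        d = liouville.attach_superop(pair.species_a, pair.species_b,
                                     pair.exchanged, rho_b)
        return t, d
    t = np.mean(
        [liouville.partial_trace_superop(c, (s,)) for s in pair.exchanged], axis=0
    )
    d = np.mean(
        [
            liouville.attach_superop(pair.species_a, pair.species_b, (s,), rho_b)
            for s in pair.exchanged
        ],
        axis=0,
    )
    return t, d


def build_generator(
    pair: ExchangePair,
    params: ExchangeParams,
    l_a: np.ndarray,
    l_c: np.ndarray,
    rho_b: np.ndarray | None = None,
) -> np.ndarray:
    """Assemble the combined exchange + spin-dynamics generator M.

    ``l_a`` and ``l_c`` are the species Liouvillians on their own Liouville
    spaces.  The result conserves the total trace ``Tr rho_A + Tr rho_C``
    exactly for any rates.
    """
    da2, dc2 = pair.dim_a ** 2, pair.dim_c ** 2
    if l_a.shape != (da2, da2):
        raise ValueError(f"L_A must be {da2}x{da2}, got {l_a.shape}")
    if l_c.shape != (dc2, dc2):
        raise ValueError(f"L_C must be {dc2}x{dc2}, got {l_c.shape}")
    kd = params.kd_s
    wa = params.association()
    t, d = pair_superops(pair, rho_b)
    return np.block(
        [
            [l_a - wa * np.eye(da2), kd * t],
            [wa * d, l_c - kd * np.eye(dc2)],
        ]
    )


def dissociation_return_generator(
    pair: ExchangePair,
    kd_s: float,
    l_c: np.ndarray,
    rho_b: np.ndarray | None = None,
) -> np.ndarray:
    """Fast-reassociation limit of the exchange generator, on C alone.

    When ``W_a`` far exceeds ``k_d`` and every spin-dynamics frequency (the
    acidic regime of ammonium, where a free proton is recaptured within
    nanoseconds), species A can be eliminated adiabatically and each
    dissociation acts as an instantaneous dissociation-return event:

        M_eff = L_C + k_d * (E - 1),   E = D.T  (generic)
                                       E = (1/m) sum_j D_j T_j (single-site).

    ``E`` is trace preserving, so M_eff conserves ``Tr rho_C``.
    """
    if kd_s < 0:
        raise ValueError("k_d must be nonnegative")
    dc2 = pair.dim_c ** 2
    if l_c.shape != (dc2, dc2):
        raise ValueError(f"L_C must be {dc2}x{dc2}, got {l_c.shape}")
    c = pair.species_c
    if pair.mechanism == "generic":
        t = liouville.partial_trace_superop(c, pair.exchanged)
        d = liouville.attach_superop(pair.species_a, pair.species_b,
                                     pair.exchanged, rho_b)
        event = d @ t
    else:
        event = np.mean(
            [
                liouville.attach_superop(pair.species_a, pair.species_b, (s,), rho_b)
                @ liouville.partial_trace_superop(c, (s,))
                for s in pair.exchanged
            ],
            axis=0,
        )
    return l_c + kd_s * (event - np.eye(dc2))


@dataclass(frozen=True)
class ExchangeState:
    """Concatenated vectorized states ``(rho_A, rho_C)`` of one pair."""

    rho_a: np.ndarray
    rho_c: np.ndarray

    def concat(self) -> np.ndarray:
        return np.concatenate([self.rho_a, self.rho_c])

    @classmethod
    def from_concat(cls, vec: np.ndarray, dim_a: int) -> "ExchangeState":
        return cls(rho_a=vec[: dim_a ** 2], rho_c=vec[dim_a ** 2:])

    def total_trace(self) -> complex:
        return liouville.trace_of_vec(self.rho_a) + liouville.trace_of_vec(self.rho_c)


def ammonium_generator(
    mechanism: str,
    params: ExchangeParams,
    t1_s=None,
    hamiltonian: str = "highfield",
    b_field_t=None,
):
    """Combined generator for 15NH4+ proton exchange.

    ``mechanism`` is ``"single-site"`` (one random proton per event; the
    realistic scenario) or ``"generic"`` (all four protons leave at once).
    ``t1_s`` is an optional per-spin T1 list for species C (order: 4 x 1H then
    15N); species A inherits the retained entries.  ``hamiltonian`` selects
    the secular high-field form or the zero-field J form; ``b_field_t`` adds a
    Zeeman term (tesla, scalar z or 3-vector) to either.

    Returns ``(pair, M)``.
    """
    from .fixtures import ammonium_pair  # local import; fixtures sits above
    from .spin_system import highfield_hamiltonian, zeeman_hamiltonian, zero_field_hamiltonian

    pair = ammonium_pair(mechanism)
    h_of = {"highfield": highfield_hamiltonian, "zero-field": zero_field_hamiltonian}
    try:
        h_fn = h_of[hamiltonian]
    except KeyError:
        raise ValueError(f"hamiltonian must be one of {sorted(h_of)}") from None

    def liouvillian(sys, t1):
        h = h_fn(sys)
        if b_field_t is not None:
            h = h + zeeman_hamiltonian(sys, b_field_t)
        l = -1j * liouville.hamiltonian_superop(h)
        if t1 is not None:
            l = l + liouville.relaxation_superop(sys, t1)
        return l

    t1_a = None
    if t1_s is not None:
        t1_s = list(t1_s)
        if len(t1_s) != pair.species_c.n_spins:
            raise ValueError("need one T1 per spin of species C")
        t1_a = [t1_s[i] for i in pair.a_spin_map()]
    l_c = liouvillian(pair.species_c, t1_s)
    l_a = liouvillian(pair.species_a, t1_a)
    return pair, build_generator(pair, params, l_a, l_c)
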