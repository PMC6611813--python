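"""Named spin systems, exchange pairs and protocols for the studied molecules.

Every fixture is generated from published coupling constants -- no external
data files.  The registry covers:

* ``AX``               -- 1H-13C pair, J = 120 Hz; dissociates into A + X.
* ``AXB``              -- 13C + two 1H, J_AX = 120 Hz, J_AB = 3 Hz,
                          J_XB = 0; the B proton exchanges.
* ``formate``          -- the same AXB topology with the one-bond coupling of
                          [13C]formic acid, J_AX = 222 Hz.
* ``ammonium``         -- 15NH4+ (A4X), J_NH = 73.4 Hz; whole-network proton
                          exchange, pKa 9.25.
* ``pyruvate``         -- the A3X methyl group of [2-13C]pyruvic acid,
                          J_CH = 6.25 Hz (exchange-free at zero field).
* ``pyruvate-hydrate`` -- 2,2-dihydroxypropionic acid modeled as (A3X)B2
                          <=> A3X + 2B, with a nominal small 13C-OH coupling
                          on the water-derived protons (synthetic value; the
                          hydrate's couplings to B are not published).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exchange import ExchangePair, ExchangeParams
from .experiment import Protocol
from .spin_system import SpinSystem, system

__all__ = [
    "Fixture",
    "paper_fixtures",
    "ax_system",
    "ax_pair",
    "axb_system",
    "axb_pair",
    "formate_pair",
    "ammonium_system",
    "ammonium_pair",
    "pyruvate_system",
    "pyruvate_hydrate_pair",
    "AMMONIUM_PKA",
]

#: acid dissociation constant of NH4+ (room temperature)
AMMONIUM_PKA = 9.25


def ax_system(j_hz: float = 120.0) -> SpinSystem:
    """1H-13C pair with a single scalar coupling (order: A=1H, X=13C)."""
    return system(["1H", "13C"], [[0.0, j_hz], [j_hz, 0.0]], label="AX")


def ax_pair(j_hz: float = 120.0) -> ExchangePair:
    """AX <=> A + X: the 13C partner dissociates and returns unpolarized."""
    return ExchangePair(species_c=ax_system(j_hz), exchanged=(1,),
                        mechanism="generic", label="AX")


def axb_system(j_ax: float = 120.0, j_ab: float = 3.0, j_xb: float = 0.0,
               label: str = "AXB") -> SpinSystem:
    """13C plus two protons (order: X=13C, A=1H, B=1H)."""
    j = np.array([
        [0.0, j_ax, j_xb],
        [j_ax, 0.0, j_ab],
        [j_xb, j_ab, 0.0],
    ])
    return system(["13C", "1H", "1H"], j, label=label)


def axb_pair(j_ax: float = 120.0, j_ab: float = 3.0, j_xb: float = 0.0,
             label: str = "AXB") -> ExchangePair:
    """AXB <=> AX + B: the labile B proton exchanges; AX stays intact."""
    return ExchangePair(species_c=axb_system(j_ax, j_ab, j_xb, label=label),
                        exchanged=(2,), mechanism="generic", label=label)


def formate_pair() -> ExchangePair:
    """[13C]formic acid: J_CH = 222 Hz, weakly coupled acidic proton."""
    return axb_pair(j_ax=222.0, j_ab=3.0, j_xb=0.0, label="formate")


def ammonium_system(j_nh_hz: float = 73.4) -> SpinSystem:
    """15NH4+: four equivalent protons each coupled to 15N (A4X)."""
    j = np.zeros((5, 5))
    j[:4, 4] = j[4, :4] = j_nh_hz
    return system(["1H", "1H", "1H", "1H", "15N"], j, label="ammonium")


def ammonium_pair(mechanism: str = "single-site", j_nh_hz: float = 73.4) -> ExchangePair:
    """Proton exchange in 15NH4+.

    ``"single-site"``: one random proton per event (A = 15NH3);
    ``"generic"``: all four protons leave simultaneously (A = bare 15N).
    """
    return ExchangePair(species_c=ammonium_system(j_nh_hz),
                        exchanged=(0, 1, 2, 3), mechanism=mechanism,
                        label="ammonium")


def pyruvate_system(j_ch_hz: float = 6.25) -> SpinSystem:
    """[2-13C]pyruvic acid methyl group: A3X, two-bond J_CH."""
    j = np.zeros((4, 4))
    j[:3, 3] = j[3, :3] = j_ch_hz
    return system(["1H", "1H", "1H", "13C"], j, label="pyruvate")


def pyruvate_hydrate_pair(j_ch_hz: float = 6.25, j_xb_hz: float = 1.0) -> ExchangePair:
    """Hydration exchange (A3X)B2 <=> A3X + 2B.

    C is 2,2-dihydroxypropionic acid: the A3X core plus two water-derived
    hydroxyl protons B2.  Their coupling to the 13C, ``j_xb_hz``, is a
    synthetic order-of-magnitude value (a typical small multi-bond 13C-OH
    coupling); couplings to the methyl protons are taken as zero.
    """
    j = np.zeros((6, 6))
    j[:3, 3] = j[3, :3] = j_ch_hz  # methyl protons to 13C
    j[3, 4] = j[4, 3] = j_xb_hz  # 13C to each hydroxyl proton
    j[3, 5] = j[5, 3] = j_xb_hz
    sys_c = system(["1H", "1H", "1H", "13C", "1H", "1H"], j, label="pyruvate-hydrate")
    return ExchangePair(species_c=sys_c, exchanged=(4, 5), mechanism="generic",
                        label="pyruvate-hydrate")


@dataclass(frozen=True)
class Fixture:
    """A ready-to-run scenario: target, default rates, default protocol."""

    name: str
    target: object  # SpinSystem or ExchangePair
    params: ExchangeParams | None
    protocol: Protocol
    notes: str = ""


def _fig2_protocol() -> Protocol:
    # generic exchange-sweep conditions: prepolarize and detect immediately
    return Protocol(shuttle_time_s=0.0, guiding_field_t=0.0,
                    dwell_time_s=1e-3, n_points=8000)


def _ammonium_zulf_protocol() -> Protocol:
    # shuttled ammonium run; 500 Hz sampling comfortably covers 5J/2 = 183.5 Hz
    return Protocol(shuttle_time_s=0.5, guiding_field_t=30e-6,
                    dwell_time_s=2e-3, n_points=4000)


def _pyruvate_protocol() -> Protocol:
    # hyperpolarized-pyruvate acquisition: 16 s; 250 Hz sampling covers 2J
    return Protocol(shuttle_time_s=0.0, guiding_field_t=0.0,
                    dwell_time_s=4e-3, n_points=4000)


def _highfield_protocol() -> Protocol:
    return Protocol(shuttle_time_s=0.0, guiding_field_t=0.0,
                    dwell_time_s=1e-3, n_points=3000)


def paper_fixtures() -> dict[str, Fixture]:
    """Registry of all named fixtures with their default settings."""
    return {
        "AX": Fixture(
            name="AX", target=ax_pair(),
            params=ExchangeParams(kd_s=5.0, wa_s=5.0),
            protocol=_fig2_protocol(),
            notes="1H-13C pair, J = 120 Hz; equal forward/backward rates",
        ),
        "AXB": Fixture(
            name="AXB", target=axb_pair(),
            params=ExchangeParams(kd_s=100.0, wa_s=100.0),
            protocol=_fig2_protocol(),
            notes="J_AX = 120 Hz, J_AB = 3 Hz, J_XB = 0; labile B proton",
        ),
        "formate": Fixture(
            name="formate", target=formate_pair(),
            params=ExchangeParams(kd_s=1000.0, wa_s=1000.0),
            protocol=_fig2_protocol(),
            notes="[13C]formic acid, J_CH = 222 Hz; fast acidic-proton exchange",
        ),
        "ammonium": Fixture(
            name="ammonium", target=ammonium_pair(),
            params=ExchangeParams(kd_s=20.0, pka=AMMONIUM_PKA, ph=AMMONIUM_PKA - 2.0),
            protocol=_ammonium_zulf_protocol(),
            notes="15NH4+, J_NH = 73.4 Hz; single-random-proton mechanism; "
                  "pH two units below pKa keeps the protonated fraction at 0.99",
        ),
        "pyruvate": Fixture(
            name="pyruvate", target=pyruvate_system(),
            params=None,
            protocol=_pyruvate_protocol(),
            notes="[2-13C]pyruvic acid A3X, J_CH = 6.25 Hz; exchange-free",
        ),
        "pyruvate-hydrate": Fixture(
            name="pyruvate-hydrate", target=pyruvate_hydrate_pair(),
            params=ExchangeParams(kd_s=1000.0, wa_s=2000.0 / 3.0),
            protocol=_pyruvate_protocol(),
            notes="(A3X)B2 <=> A3X + 2B hydration model; rates chosen for a "
                  "40% hydrated fraction",
        ),
        "highfield-ammonium": Fixture(
            name="highfield-ammonium", target=ammonium_pair(),
            params=ExchangeParams(kd_s=0.1, pka=AMMONIUM_PKA, ph=AMMONIUM_PKA - 2.0),
            protocol=_highfield_protocol(),
            notes="18.8 T 15N pulse-acquire of 15NH4+; vary kd_s for the "
                  "broadening/coalescence series",
        ),
    }
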