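"""Run-configuration parsing and serialization.

Configs are JSON with unit-suffixed keys (``*_hz``, ``*_s``, ``*_t``), one
file per run.  A config either names a registry fixture or spells out the
spin system; exchange, protocol and processing blocks override the fixture
defaults field by field.  The reader validates the schema before any
computation and the writer round-trips exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .exchange import MECHANISMS, ExchangePair, ExchangeParams
from .experiment import Protocol
from .fixtures import paper_fixtures
from .spin_system import SpinSystem, system

__all__ = ["ConfigError", "RunConfig", "read_config", "write_config",
           "system_to_dict", "system_from_dict"]


class ConfigError(ValueError):
    """Malformed or inconsistent run configuration."""


_PROTOCOL_KEYS = {
    "polarizing_field_t", "polarizing_temperature_k", "shuttle_time_s",
    "guiding_field_t", "residual_field_t", "dwell_time_s", "n_points",
    "detection_axis",
}
_EXCHANGE_KEYS = {"mechanism", "kd_s", "pka", "ph", "wa_s", "exchanged_indices"}
_PROCESSING_KEYS = {"apodization_rate_s", "zero_fill", "min_rel_amplitude",
                    "exclude_below_hz", "mode"}
_TOP_KEYS = {"fixture", "spin_system", "exchange", "protocol", "processing", "seed"}


def system_to_dict(sys: SpinSystem) -> dict:
    return {
        "label": sys.label,
        "isotopes": [iso.symbol for iso in sys.isotopes],
        "j_hz": [[float(v) for v in row] for row in np.asarray(sys.j_hz)],
    }


def system_from_dict(d: dict) -> SpinSystem:
    try:
        return system(d["isotopes"], d["j_hz"], label=d.get("label", ""))
    except (KeyError, ValueError, TypeError) as exc:
        raise ConfigError(f"invalid spin_system block: {exc}") from exc


@dataclass
class RunConfig:
    """Validated run settings resolved against the fixture registry."""

    target: object  # SpinSystem or ExchangePair
    params: ExchangeParams | None
    protocol: Protocol
    processing: dict = field(default_factory=dict)
    seed: int = 0
    raw: dict = field(default_factory=dict)


def _check_keys(block: dict, allowed: set, where: str) -> None:
    unknown = set(block) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} in {where} block")


def parse_config(cfg: dict) -> RunConfig:
    """Validate a config dict and resolve it into runnable objects."""
    if not isinstance(cfg, dict):
        raise ConfigError("config root must be a JSON object")
    _check_keys(cfg, _TOP_KEYS, "top-level")

    fixture = None
    if "fixture" in cfg:
        reg = paper_fixtures()
        if cfg["fixture"] not in reg:
            raise ConfigError(
                f"unknown fixture {cfg['fixture']!r}; available: {sorted(reg)}")
        fixture = reg[cfg["fixture"]]
        target = fixture.target
        params = fixture.params
        protocol = fixture.protocol
    elif "spin_system" in cfg:
        target = system_from_dict(cfg["spin_system"])
        params = None
        protocol = Protocol()
    else:
        raise ConfigError("config needs either 'fixture' or 'spin_system'")

    exch = cfg.get("exchange")
    if exch is not None:
        _check_keys(exch, _EXCHANGE_KEYS, "exchange")
        if "exchanged_indices" in exch:
            base = target.species_c if isinstance(target, ExchangePair) else target
            try:
                target = ExchangePair(
                    species_c=base,
                    exchanged=tuple(exch["exchanged_indices"]),
                    mechanism=exch.get("mechanism", "generic"),
                    label=base.label,
                )
            except (ValueError, IndexError) as exc:
                raise ConfigError(str(exc)) from exc
        elif "mechanism" in exch:
            if exch["mechanism"] not in MECHANISMS:
                raise ConfigError(f"unknown mechanism {exch['mechanism']!r}")
            if isinstance(target, ExchangePair):
                target = ExchangePair(species_c=target.species_c,
                                      exchanged=target.exchanged,
                                      mechanism=exch["mechanism"],
                                      label=target.label)
        base_params = params
        kwargs = {
            "kd_s": exch.get("kd_s", base_params.kd_s if base_params else 0.0),
            "pka": exch.get("pka", base_params.pka if base_params else None),
            "ph": exch.get("ph", base_params.ph if base_params else None),
            "wa_s": exch.get("wa_s", base_params.wa_s if base_params else None),
        }
        if "ph" in exch or "pka" in exch:
            kwargs.setdefault("wa_s", None)
            if "wa_s" not in exch:
                kwargs["wa_s"] = None  # explicit pH overrides an inherited W_a
        try:
            params = ExchangeParams(**kwargs)
        except ValueError as exc:
            raise ConfigError(str(exc)) from exc

    proto = cfg.get("protocol")
    if proto is not None:
        _check_keys(proto, _PROTOCOL_KEYS, "protocol")
        merged = {k: getattr(protocol, k) for k in _PROTOCOL_KEYS}
        merged.update(proto)
        if isinstance(merged["residual_field_t"], (list, tuple)):
            merged["residual_field_t"] = tuple(float(v) for v in merged["residual_field_t"])
        try:
            protocol = Protocol(**merged)
        except (TypeError, ValueError) as exc:
            raise ConfigError(str(exc)) from exc

    processing = dict(cfg.get("processing") or {})
    _check_keys(processing, _PROCESSING_KEYS, "processing")

    seed = cfg.get("seed", 0)
    if not isinstance(seed, int):
        raise ConfigError("seed must be an integer")

    return RunConfig(target=target, params=params, protocol=protocol,
                     processing=processing, seed=seed, raw=cfg)


def read_config(path) -> RunConfig:
    """Load and validate a JSON config file."""
    try:
        with open(path) as fh:
            cfg = json.load(fh)
    except FileNotFoundError:
        raise ConfigError(f"config file not found: {path}") from None
    except json.JSONDecodeError as exc:
        raise ConfigError(f"config is not valid JSON: {exc}") from exc
    return parse_config(cfg)


def write_config(cfg: dict, path) -> None:
    """Write a config dict canonically (sorted keys, two-space indent)."""
    with open(path, "w") as fh:
        json.dump(cfg, fh, indent=2, sort_keys=True)
        fh.write("\n")
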