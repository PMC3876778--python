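"""YAML run configuration: parameters, protocol, integrator settings.

A config file fully determines a run (together with the seed for stochastic
commands); every command echoes its resolved configuration next to its
outputs so results can be reproduced bit-identically.

Temperatures are written in degC in configs (clinical convention) and
converted to kelvin internally with the +273.16 offset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

from .experiments import fractionation_protocol
from .kinetics import (
    RadiationParams,
    RepairProbabilityModel,
    ThermalParams,
    celsius_to_kelvin,
)
from .simulate import DEFAULT_HORIZON, DT_OFF, DT_ON, Protocol, Segment

__all__ = ["RunConfig", "ConfigError", "load_config", "save_config"]

#: Advisory parameter ranges typical of published fits, used in validation
#: messages (units: alpha, mu_gamma per Gy; c_r, c_e, gamma per hour;
#: dose rate Gy/h).
TYPICAL_RANGES = {
    "alpha": (0.5, 2.0),
    "c_r": (4.0, 100.0),
    "c_e": (1.0, 60.0),
    "mu_gamma": (0.2, 1.0),
    "gamma": (1.0, 10.0),
    "dose_rate": (0.49, 240.0),
}


class ConfigError(ValueError):
    """Raised for malformed or invalid run configurations."""


def _check_keys(section: dict, allowed: set[str], where: str) -> None:
    unknown = set(section) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) in {where}: {sorted(unknown)}")


@dataclass
class RunConfig:
    """Fully resolved run configuration."""

    radiation: RadiationParams
    thermal: ThermalParams | None = None
    repair_model: RepairProbabilityModel | None = None
    protocol: Protocol | None = None
    dt: float = DT_ON
    dt_off: float = DT_OFF
    horizon: float = DEFAULT_HORIZON
    seed: int | None = None

    def to_dict(self) -> dict:
        out: dict = {
            "radiation": {
                "alpha": self.radiation.alpha,
                "c_r": self.radiation.c_r,
                "c_e": self.radiation.c_e,
                "mu_gamma": self.radiation.mu_gamma,
                "gamma": self.radiation.gamma,
                "k_max": self.radiation.k_max,
            }
        }
        if self.thermal is not None:
            out["thermal"] = {
                "a": self.thermal.a,
                "E_a": self.thermal.E_a,
                "k2": self.thermal.k2,
                "mu_lambda": self.thermal.mu_lambda,
            }
        if self.repair_model is not None:
            m = self.repair_model
            out["repair_model"] = {
                "variant": m.variant,
                "mu_gamma": m.mu_gamma,
                "mu_lambda": m.mu_lambda,
                "xi": m.xi,
                "gamma_c": m.gamma_c,
                "midpoint": m.midpoint,
                "steepness": m.steepness,
            }
        if self.protocol is not None:
            out["protocol"] = {
                "segments": [
                    {
                        "start": s.t_start,
                        "end": s.t_end,
                        "dose_rate": s.dose_rate,
                        "temp_C": round(s.temperature - 273.16, 6),
                    }
                    for s in self.protocol
                ]
            }
        out["integrator"] = {
            "dt": self.dt,
            "dt_off": self.dt_off,
            "horizon": self.horizon,
        }
        if self.seed is not None:
            out["seed"] = self.seed
        return out


def _parse_protocol(section: dict) -> Protocol:
    _check_keys(section, {"segments", "fractionation"}, "protocol")
    if ("segments" in section) == ("fractionation" in section):
        raise ConfigError("protocol needs exactly one of 'segments' or 'fractionation'")
    if "fractionation" in section:
        frac = section["fractionation"]
        _check_keys(frac, {"n", "d", "R", "gap"}, "protocol.fractionation")
        return fractionation_protocol(
            int(frac["n"]), float(frac["d"]), float(frac["R"]),
            float(frac.get("gap", 24.0)),
        )
    segments = []
    for i, seg in enumerate(section["segments"]):
        _check_keys(seg, {"start", "end", "dose_rate", "temp_C"}, f"segment {i}")
        segments.append(
            Segment(
                float(seg["start"]),
                float(seg["end"]),
                float(seg.get("dose_rate", 0.0)),
                celsius_to_kelvin(float(seg.get("temp_C", 37.0))),
            )
        )
    return Protocol(segments)


def _build(section: dict, cls, allowed: set[str], where: str):
    _check_keys(section, allowed, where)
    try:
        return cls(**section)
    except (TypeError, ValueError) as exc:
        hint = ""
        for key in section:
            if key in TYPICAL_RANGES and f"{key} " in str(exc):
                lo, hi = TYPICAL_RANGES[key]
                hint = f" (typical range for {key}: {lo}-{hi})"
        raise ConfigError(f"invalid {where}: {exc}{hint}") from exc


def from_dict(raw: dict) -> RunConfig:
    """Build and validate a :class:`RunConfig` from plain mappings."""
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    _check_keys(
        raw,
        {"radiation", "thermal", "repair_model", "protocol", "integrator", "seed"},
        "config",
    )
    if "radiation" not in raw:
        raise ConfigError("config must define a 'radiation' section")
    radiation = _build(
        dict(raw["radiation"]),
        RadiationParams,
        {"alpha", "c_r", "c_e", "mu_gamma", "gamma", "k_max"},
        "radiation parameters",
    )
    thermal = None
    if "thermal" in raw:
        thermal = _build(
            dict(raw["thermal"]),
            ThermalParams,
            {"a", "E_a", "k2", "mu_lambda"},
            "thermal parameters",
        )
    repair_model = None
    if "repair_model" in raw:
        repair_model = _build(
            dict(raw["repair_model"]),
            RepairProbabilityModel,
            {"variant", "mu_gamma", "mu_lambda", "xi", "gamma_c", "midpoint", "steepness"},
            "repair model",
        )
    protocol = _parse_protocol(dict(raw["protocol"])) if "protocol" in raw else None
    integrator = dict(raw.get("integrator", {}))
    _check_keys(integrator, {"dt", "dt_off", "horizon"}, "integrator")
    dt = float(integrator.get("dt", DT_ON))
    dt_off = float(integrator.get("dt_off", DT_OFF))
    horizon = float(integrator.get("horizon", DEFAULT_HORIZON))
    if dt <= 0 or dt_off <= 0 or horizon <= 0:
        raise ConfigError("integrator settings must be > 0")
    seed = raw.get("seed")
    if seed is not None:
        seed = int(seed)
    return RunConfig(
        radiation=radiation,
        thermal=thermal,
        repair_model=repair_model,
        protocol=protocol,
        dt=dt,
        dt_off=dt_off,
        horizon=horizon,
        seed=seed,
    )


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return from_dict(raw if raw is not None else {})


def save_config(config: RunConfig, path) -> None:
    """Write the fully resolved configuration as YAML (round-trips exactly)."""
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
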