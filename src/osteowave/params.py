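"""Model parameters and configuration I/O.

The continuum model treats the expanding skull-cap tissue as a 1D viscous
fluid of two cell populations — undifferentiated mesenchyme and osteoblasts —
whose local composition sets the tissue stiffness, which in turn feeds back on
the differentiation rate.  :class:`SimulationParams` collects every physical
and numerical constant of that model.  Default values live in a versioned YAML
file shipped with the package (``data/default_params.yaml``), not in code.
"""

from __future__ import annotations

import dataclasses
import importlib.resources
import json
from pathlib import Path
from typing import Any, Mapping

import yaml


class ConfigurationError(ValueError):
    """A parameter set violates one or more model invariants."""


_FLOAT_FIELDS = (
    "E_m", "E_o", "rho0_m", "rho0_o", "eta", "xi", "D", "tau", "alpha",
    "beta", "pi0", "tau_P", "chi", "xi_ratio", "r_col", "domain_length", "dt", "t_end",
)


@dataclasses.dataclass(frozen=True)
class SimulationParams:
    """Physical and numerical constants of the calvarial expansion model.

    Units: stiffness kPa, densities cells/µm (1D-projected), viscosity kPa·h,
    friction kPa·h/µm², diffusion µm²/h, rates 1/h, lengths µm, times h.
    ``beta`` is the single free coupling between stiffness and the
    differentiation rate; all other constants are estimated independently.
    """

    E_m: float
    E_o: float
    rho0_m: float
    rho0_o: float
    eta: float
    xi: float
    D: float
    tau: float
    alpha: float
    beta: float
    pi0: float
    tau_P: float
    chi: float
    xi_ratio: float
    r_col: float
    domain_length: float
    n_grid: int
    dt: float
    t_end: float
    seed: int = 0

    def __post_init__(self) -> None:
        errors = self.validation_errors()
        if errors:
            raise ConfigurationError(
                "invalid SimulationParams: " + "; ".join(errors)
            )

    def validation_errors(self) -> list[str]:
        """Return every violated invariant (empty list = valid)."""
        errs: list[str] = []
        for name in _FLOAT_FIELDS:
            v = getattr(self, name)
            if not isinstance(v, (int, float)) or isinstance(v, bool):
                errs.append(f"{name} must be a number, got {v!r}")
        if errs:
            return errs
        if not self.E_m > 0:
            errs.append("E_m > 0 violated")
        if not self.E_o > self.E_m:
            errs.append("E_o > E_m violated (bone center stiffer than mesenchyme)")
        if not self.rho0_m > 0:
            errs.append("rho0_m > 0 violated")
        if not self.rho0_o > self.rho0_m:
            errs.append("rho0_o > rho0_m violated (bone more densely packed)")
        for name in ("eta", "xi", "D", "tau", "alpha", "beta", "pi0", "chi", "r_col"):
            if getattr(self, name) < 0:
                errs.append(f"{name} >= 0 violated")
        if self.xi_ratio < 1:
            errs.append("xi_ratio >= 1 violated (bone at least as anchored as mesenchyme)")
        if not self.tau_P > 0:
            errs.append("tau_P > 0 violated")
        if self.eta == 0 and self.xi == 0:
            errs.append("eta and xi cannot both be zero (force balance singular)")
        if not self.dt > 0:
            errs.append("dt > 0 violated")
        if not self.domain_length > 0:
            errs.append("domain_length > 0 violated")
        if not (isinstance(self.n_grid, int) and self.n_grid >= 8):
            errs.append("n_grid must be an integer >= 8")
        if self.t_end < 0:
            errs.append("t_end >= 0 violated")
        if not isinstance(self.seed, int):
            errs.append("seed must be an integer")
        return errs

    @property
    def dx(self) -> float:
        """Grid spacing (µm); the grid is node-centred on [0, domain_length]."""
        return self.domain_length / (self.n_grid - 1)

    def replace(self, **changes: Any) -> "SimulationParams":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping[str, Any], fill_defaults: bool = True) -> "SimulationParams":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(d) - known)
        if unknown:
            raise ConfigurationError(
                "unknown parameter key(s): " + ", ".join(unknown)
            )
        merged: dict[str, Any] = dict(_default_dict()) if fill_defaults else {}
        merged.update(d)
        if "n_grid" in merged and isinstance(merged["n_grid"], float) and merged["n_grid"].is_integer():
            merged["n_grid"] = int(merged["n_grid"])
        return cls(**merged)


def _default_dict() -> dict[str, Any]:
    ref = importlib.resources.files("osteowave").joinpath("data/default_params.yaml")
    return yaml.safe_load(ref.read_text())


def default_params(**overrides: Any) -> SimulationParams:
    """The shipped default parameter set, optionally with overrides."""
    return SimulationParams.from_dict(overrides)


def load_config(path: str | Path) -> SimulationParams:
    """Load and validate a flat YAML/JSON config of SimulationParams keys.

    Missing keys are filled from the packaged defaults; unknown keys are
    rejected by name; a validation failure reports every violated invariant.
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        raw = json.loads(text)
    else:
        raw = yaml.safe_load(text)
    if not isinstance(raw, Mapping):
        raise ConfigurationError(f"config {path} is not a flat mapping")
    return SimulationParams.from_dict(raw)


def save_config(params: SimulationParams, path: str | Path) -> None:
    """Write a canonical (sorted-key YAML) config; reloading round-trips."""
    path = Path(path)
    d = params.to_dict()
    path.write_text(yaml.safe_dump(d, sort_keys=True))
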