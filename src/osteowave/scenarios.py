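"""In-silico perturbation scenarios: bone-center excision and BAPN-style
gradient steepening.

Both scenarios mirror the corresponding tissue experiments: excision removes
the stiff, matured bone center from a developed explant, retaining only a
thin band of partially differentiated tissue at the osteogenic front;
gradient steepening softens the front tissue and mildly stiffens the bone
center (the effect of blocking collagen crosslinking), which steepens the
stiffness gradient driving the wave.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .params import ConfigurationError, SimulationParams
from .model import FieldState, simulate, step_preset
from .fronts import FrontTrajectory, front_trajectory, front_speed, detect_front

__all__ = [
    "ExcisionResult",
    "SteepeningResult",
    "scenario_excision",
    "scenario_gradient_steepening",
    "excise_bone_center",
]


@dataclasses.dataclass
class ExcisionResult:
    """Paired control/excised front records over the same horizon."""

    control: FrontTrajectory
    excised: FrontTrajectory
    control_states: list[FieldState]
    excised_states: list[FieldState]
    base_state: FieldState
    band_width: float

    @property
    def displacement_ratio(self) -> float:
        """|excised| / |control| front displacement at the end of the horizon."""
        return abs(self.excised.displacement()) / abs(self.control.displacement())


def excise_bone_center(
    state: FieldState, params: SimulationParams, band_width: float = 20.0
) -> FieldState:
    """Remove the bone bulk, retaining ``band_width`` µm behind the front.

    Everything lateral of (front - band_width) is replaced by homeostatic
    mesenchyme with no matrix and no stored growth pressure.  With
    ``band_width`` at least the bone extent the state is returned unchanged,
    so the excision converges to the control in that limit.
    """
    out = state.copy()
    front = detect_front(state.x, state.phi)
    cut = front - band_width
    mask = out.x < cut
    out.rho_m[mask] = params.rho0_m
    out.rho_o[mask] = 0.0
    out.col[mask] = 0.0
    out.k[mask] = 0.0
    out.pg[mask] = 0.0
    return out


def scenario_excision(
    params: SimulationParams,
    band_width: float = 20.0,
    settle_time: float = 24.0,
    horizon: float = 6.0,
    save_every: float = 0.5,
    x_front0: float = 300.0,
) -> ExcisionResult:
    """Excise the bone center from a developed wave and track both fronts.

    The wave is first evolved for ``settle_time`` hours so the explant has
    the structure of a developed bone (mature center, partially
    differentiated front zone); the excision then crops it to the leading
    ``band_width`` µm and both control and excised tissues are followed for
    ``horizon`` hours.
    """
    if band_width < 0:
        raise ValueError("band_width must be non-negative")
    p_settle = params.replace(t_end=settle_time)
    base = simulate(p_settle, "step", save_every=max(settle_time, 1.0),
                    x_front0=x_front0)[-1]
    p_run = params.replace(t_end=horizon)
    control_states = simulate(p_run, base, save_every=save_every)
    excised0 = excise_bone_center(base, params, band_width)
    excised_states = simulate(p_run, excised0, save_every=save_every)
    return ExcisionResult(
        control=front_trajectory(control_states, sample_id="control"),
        excised=front_trajectory(excised_states, sample_id="excised"),
        control_states=control_states,
        excised_states=excised_states,
        base_state=base,
        band_width=band_width,
    )


@dataclasses.dataclass
class SteepeningResult:
    """Control vs. crosslinking-inhibited (gradient-steepened) runs."""

    control: FrontTrajectory
    treated: FrontTrajectory
    control_states: list[FieldState]
    treated_states: list[FieldState]
    control_speed: float
    treated_speed: float
    control_domain_size: float
    treated_domain_size: float


def _osteoblast_domain_size(state: FieldState, level: float = 0.5) -> float:
    """Extent (µm) of the region with phi >= level."""
    return float(np.sum(state.phi >= level) * state.dx)


def scenario_gradient_steepening(
    params: SimulationParams,
    front_softening: float = 0.5,
    center_stiffening: float = 1.1,
    save_every: float = 1.0,
    x_front0: float = 300.0,
) -> SteepeningResult:
    """Steepen the stiffness gradient (softer front, mildly stiffer center).

    The treated run multiplies ``E_m`` by ``front_softening`` (< 1 softens
    the fresh tissue, as crosslink inhibition does) and ``E_o`` by
    ``center_stiffening`` (>= 1).  Both runs start from the step preset and
    share ``params.t_end``; returns front trajectories, post-transient
    speeds, and the final size of the phi >= 1/2 osteoblast domain.
    """
    if front_softening <= 0 or center_stiffening <= 0:
        raise ValueError("softening/stiffening factors must be positive")
    E_m_t = params.E_m * front_softening
    E_o_t = params.E_o * center_stiffening
    if E_o_t <= E_m_t:
        raise ConfigurationError(
            f"treated stiffnesses invalid: E_o={E_o_t} <= E_m={E_m_t}"
        )
    treated_params = params.replace(E_m=E_m_t, E_o=E_o_t)
    control_states = simulate(params, "step", save_every=save_every,
                              x_front0=x_front0)
    treated_states = simulate(treated_params, "step", save_every=save_every,
                              x_front0=x_front0)
    control = front_trajectory(control_states, sample_id="control")
    treated = front_trajectory(treated_states, sample_id="treated")
    return SteepeningResult(
        control=control,
        treated=treated,
        control_states=control_states,
        treated_states=treated_states,
        control_speed=front_speed(control).speed,
        treated_speed=front_speed(treated).speed,
        control_domain_size=_osteoblast_domain_size(control_states[-1]),
        treated_domain_size=_osteoblast_domain_size(treated_states[-1]),
    )


def reporter_profiles_from_state(
    state: FieldState,
    params: SimulationParams,
    n_samples: int = 6,
    baseline: float = 100.0,
    plateau: float = 500.0,
    noise_sd: float = 0.05,
    seed: int = 0,
):
    """Synthesize reporter-intensity profiles from a simulated state.

    Reporter intensity tracks osteoblast maturity, so the matrix-maturity
    profile is mapped to ``baseline + (plateau - baseline) * col(x)`` and
    multiplicative log-normal noise is added per sample — the same noise
    model as the profile generator.  The baseline region is annotated in
    the mesenchyme well ahead of the front.  Used to compare aligned
    front-intensity slopes between scenario runs.
    """
    from .profiles import IntensityProfile

    rng = np.random.default_rng(seed)
    front = detect_front(state.x, state.phi)
    # imaging-resolution sampling (1 µm), finer than the simulation grid
    x = np.arange(state.x[0], state.x[-1] + 0.5, 1.0)
    col = np.interp(x, state.x, np.clip(state.col, 0.0, 1.0))
    clean = baseline + (plateau - baseline) * col
    base_start = int(np.searchsorted(x, front + 100.0))
    base_start = min(base_start, len(x) - 5)
    out = []
    for s in range(n_samples):
        noise = np.exp(rng.normal(0.0, noise_sd, len(clean)) - noise_sd**2 / 2)
        out.append(
            IntensityProfile(
                positions=x.copy(),
                intensities=clean * noise,
                baseline=slice(base_start, len(x)),
                sample_id=f"rep{s:02d}",
            )
        )
    return out
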