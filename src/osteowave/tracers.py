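"""Lagrangian tracers: material points advected by the tissue flow.

Tracked nuclei are modelled as passive material points of the continuum flow
plus Brownian motion with the cell diffusion constant: an Euler–Maruyama
update ``x <- x + v(x, t) dt + sqrt(2 D dt) N(0, 1)`` with the velocity field
interpolated from the saved simulation states.  Tracers are labelled by where
they start relative to the initial front: at the front, 200 µm lateral
(intermediate), or 400 µm lateral (bone center).
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .model import FieldState
from .fronts import FrontTrajectory

__all__ = [
    "VelocityHistory",
    "TracerEnsemble",
    "advect_tracers",
    "seed_positions",
    "relative_displacement_curve",
    "RelativeDisplacement",
]

REGION_OFFSETS = {"front": 0.0, "intermediate": -200.0, "lateral": -400.0}


@dataclasses.dataclass
class VelocityHistory:
    """Velocity field v(x, t) sampled on the simulation grid and save times."""

    times: np.ndarray          # (n_t,)
    x: np.ndarray              # (n_x,)
    v: np.ndarray              # (n_t, n_x)

    @classmethod
    def from_states(cls, states: Sequence[FieldState]) -> "VelocityHistory":
        times = np.array([s.t for s in states])
        x = states[0].x
        v = np.stack([s.v for s in states])
        return cls(times, x, v)

    def __call__(self, xq: np.ndarray, t: float) -> np.ndarray:
        """Linear interpolation in t then in x."""
        it = np.searchsorted(self.times, t, side="right") - 1
        it = np.clip(it, 0, len(self.times) - 2)
        t0, t1 = self.times[it], self.times[it + 1]
        w = 0.0 if t1 == t0 else np.clip((t - t0) / (t1 - t0), 0.0, 1.0)
        v_row = (1 - w) * self.v[it] + w * self.v[it + 1]
        return np.interp(xq, self.x, v_row)


@dataclasses.dataclass
class TracerEnsemble:
    """Tracks of material tracers sharing the simulation time base."""

    times: np.ndarray          # (n_t,)
    positions: np.ndarray      # (n_tracers, n_t)
    labels: list[str]          # initial-region label per tracer
    seed: int = 0

    def displacements(self) -> np.ndarray:
        """Net displacement of each tracer over the record (µm)."""
        return self.positions[:, -1] - self.positions[:, 0]

    def mean_position(self) -> np.ndarray:
        return self.positions.mean(axis=0)


def seed_positions(
    front_x: float,
    n_per_region: int,
    regions: Sequence[str] = ("front", "intermediate", "lateral"),
    jitter: float = 10.0,
    seed: int = 0,
) -> tuple[np.ndarray, list[str]]:
    """Initial tracer positions at the front and 200/400 µm toward the bone."""
    rng = np.random.default_rng(seed)
    pos, labels = [], []
    for r in regions:
        base = front_x + REGION_OFFSETS[r]
        pos.append(base + rng.uniform(-jitter, jitter, size=n_per_region))
        labels.extend([r] * n_per_region)
    return np.concatenate(pos), labels


def advect_tracers(
    velocity_history: VelocityHistory,
    params,
    n_tracers: int | None = None,
    initial_positions: np.ndarray | None = None,
    seed: int = 0,
    labels: list[str] | None = None,
    dt: float = 0.05,
    D: float | None = None,
) -> TracerEnsemble:
    """Advect tracers through a stored velocity history (Euler–Maruyama).

    Velocity is interpolated linearly in x and t; boundaries reflect;
    the walk is reproducible given ``seed``.  ``D`` defaults to the cell
    diffusion constant of ``params``.
    """
    if initial_positions is None:
        raise ValueError("initial_positions are required")
    x = np.asarray(initial_positions, dtype=float).copy()
    if n_tracers is not None and len(x) != n_tracers:
        raise ValueError("n_tracers does not match initial_positions")
    lo, hi = velocity_history.x[0], velocity_history.x[-1]
    if np.any(x < lo) or np.any(x > hi):
        raise ValueError("tracer initial position outside domain")
    D = params.D if D is None else D
    rng = np.random.default_rng(seed)
    times = velocity_history.times
    out = np.empty((len(x), len(times)))
    out[:, 0] = x
    sig = np.sqrt(2.0 * D)
    t = times[0]
    for j in range(1, len(times)):
        t_target = times[j]
        while t < t_target - 1e-12:
            h = min(dt, t_target - t)
            v = velocity_history(x, t)
            x = x + v * h
            if D > 0:
                x = x + sig * np.sqrt(h) * rng.standard_normal(len(x))
            # reflecting walls
            x = np.where(x < lo, 2 * lo - x, x)
            x = np.where(x > hi, 2 * hi - x, x)
            x = np.clip(x, lo, hi)
            t += h
        out[:, j] = x
        t = t_target
    if labels is None:
        labels = ["front"] * len(x)
    return TracerEnsemble(times.copy(), out, list(labels), seed=seed)


@dataclasses.dataclass
class RelativeDisplacement:
    """Front and mean-cell displacement normalised by the front at t_ref."""

    times: np.ndarray
    front_curve: np.ndarray
    cell_curve: np.ndarray
    t_ref: float


def relative_displacement_curve(
    front: FrontTrajectory,
    tracers: TracerEnsemble,
    t_ref: float = 6.0,
) -> RelativeDisplacement:
    """Displacement of front and tracked cells, normalised to the front at t_ref.

    Times are measured from the start of each record; the front curve ends at
    exactly 1 at ``t_ref`` by construction.
    """
    ft = front.times - front.times[0]
    tt = tracers.times - tracers.times[0]
    if ft[-1] < t_ref - 1e-9 or tt[-1] < t_ref - 1e-9:
        raise ValueError(f"records do not reach t_ref = {t_ref}")
    denom = front.position_at(front.times[0] + t_ref) - front.front_positions[0]
    if denom == 0:
        raise ValueError("front displacement at t_ref is zero; normalisation undefined")
    times = tt[tt <= t_ref + 1e-9]
    if times[-1] < t_ref - 1e-9:
        times = np.append(times, t_ref)
    front_curve = (
        np.interp(times, ft, front.front_positions) - front.front_positions[0]
    ) / denom
    mean_disp = (tracers.positions - tracers.positions[:, :1]).mean(axis=0)
    cell_curve = np.interp(times, tt, mean_disp) / denom
    front_curve[-1] = 1.0  # exact by definition
    return RelativeDisplacement(times, front_curve, cell_curve, t_ref)
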