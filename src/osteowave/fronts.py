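"""Osteogenic front detection and kinematics.

The osteogenic front is the leading edge of the differentiated bone, defined
as the medial-most position where the osteoblast fraction crosses a level
(default phi = 1/2), reported in the fixed lab frame.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy import stats

from .model import FieldState

__all__ = [
    "FrontTrajectory",
    "FrontNotFoundError",
    "detect_front",
    "front_trajectory",
    "front_speed",
    "front_fluctuations",
    "phi_collapse_rms",
]


class FrontNotFoundError(ValueError):
    """The profile never crosses the requested detection level."""


@dataclasses.dataclass
class FrontTrajectory:
    """Detected front position vs. time for one sample or simulation."""

    times: np.ndarray
    front_positions: np.ndarray
    detection_level: float = 0.5
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.front_positions = np.asarray(self.front_positions, dtype=float)
        if len(self.times) != len(self.front_positions):
            raise ValueError("times and front_positions must have equal length")
        if len(self.times) > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if not 0 < self.detection_level < 1:
            raise ValueError("detection_level must lie in (0, 1)")

    def displacement(self) -> float:
        return float(self.front_positions[-1] - self.front_positions[0])

    def position_at(self, t: float) -> float:
        return float(np.interp(t, self.times, self.front_positions))


def detect_front(x: np.ndarray, phi: np.ndarray, level: float = 0.5) -> float:
    """Medial-most crossing of ``phi`` through ``level`` (µm).

    Scanning from the bone (lateral, low-x) side, every bracketing pair of
    grid points where the profile crosses the level is considered and the
    largest-x pair is kept; the crossing is linearly interpolated.  This is
    robust to small non-monotonicity behind the leading edge.
    """
    x = np.asarray(x, dtype=float)
    phi = np.asarray(phi, dtype=float)
    d = phi - level
    exact = np.nonzero(d == 0)[0]
    sign_change = np.nonzero(d[:-1] * d[1:] < 0)[0]
    best = -np.inf
    if len(exact):
        best = float(x[exact[-1]])
    if len(sign_change):
        i = int(sign_change[-1])
        xc = x[i] + (x[i + 1] - x[i]) * (level - phi[i]) / (phi[i + 1] - phi[i])
        best = max(best, float(xc))
    if not np.isfinite(best):
        raise FrontNotFoundError(f"front not in domain (no crossing of level {level})")
    return best


def front_trajectory(
    states: Sequence[FieldState], level: float = 0.5, sample_id: str = "simulation"
) -> FrontTrajectory:
    """Detect the front in every saved state of a simulation."""
    times = np.array([s.t for s in states])
    pos = np.array([detect_front(s.x, s.phi, level) for s in states])
    return FrontTrajectory(times, pos, detection_level=level, sample_id=sample_id)


@dataclasses.dataclass
class SpeedFit:
    """Least-squares front speed with linear-fit diagnostics."""

    speed: float          # µm/h
    intercept: float
    stderr: float
    r_squared: float
    n_points: int
    window: tuple[float, float]

    def ci95(self) -> tuple[float, float]:
        if self.n_points < 3:
            return (-np.inf, np.inf)
        tcrit = stats.t.ppf(0.975, self.n_points - 2)
        return (self.speed - tcrit * self.stderr, self.speed + tcrit * self.stderr)


def front_speed(traj: FrontTrajectory, transient_fraction: float = 0.5) -> SpeedFit:
    """Front expansion rate: slope of position vs. time after the transient.

    The first ``transient_fraction`` of the record (by time) is discarded to
    exclude the wave-formation transient before fitting.
    """
    if not 0 <= transient_fraction < 1:
        raise ValueError("transient_fraction must lie in [0, 1)")
    t0, t1 = traj.times[0], traj.times[-1]
    cut = t0 + transient_fraction * (t1 - t0)
    keep = traj.times >= cut - 1e-12
    if np.sum(keep) < 3:
        raise ValueError("fewer than 3 points after discarding the transient")
    t = traj.times[keep]
    y = traj.front_positions[keep]
    res = stats.linregress(t, y)
    return SpeedFit(
        speed=float(res.slope),
        intercept=float(res.intercept),
        stderr=float(res.stderr),
        r_squared=float(res.rvalue**2),
        n_points=int(np.sum(keep)),
        window=(float(t[0]), float(t[-1])),
    )


def front_speed_cv(traj: FrontTrajectory, transient_fraction: float = 0.5) -> float:
    """Coefficient of variation of the interval speeds after the transient."""
    t0, t1 = traj.times[0], traj.times[-1]
    keep = traj.times >= t0 + transient_fraction * (t1 - t0) - 1e-12
    t = traj.times[keep]
    y = traj.front_positions[keep]
    speeds = np.diff(y) / np.diff(t)
    m = np.mean(speeds)
    if m == 0:
        return np.inf
    return float(np.std(speeds) / abs(m))


def phi_collapse_rms(
    states: Sequence[FieldState],
    transient_fraction: float = 0.5,
    level: float = 0.5,
    half_window: float = 150.0,
) -> float:
    """RMS mismatch of front-aligned phi profiles (traveling-wave collapse).

    Each retained profile is translated so its detected front sits at 0 and
    interpolated onto a common window; the RMS deviation from the pointwise
    mean across times measures how well the profiles collapse onto a single
    traveling shape.
    """
    times = np.array([s.t for s in states])
    t0, t1 = times[0], times[-1]
    keep = [s for s in states if s.t >= t0 + transient_fraction * (t1 - t0) - 1e-12]
    if len(keep) < 2:
        raise ValueError("need at least 2 profiles after the transient")
    s_grid = np.linspace(-half_window, half_window, 301)
    aligned = []
    for s in keep:
        xf = detect_front(s.x, s.phi, level)
        aligned.append(np.interp(s_grid, s.x - xf, s.phi))
    aligned = np.array(aligned)
    mean = aligned.mean(axis=0)
    return float(np.sqrt(np.mean((aligned - mean) ** 2)))


def front_fluctuations(
    times: np.ndarray,
    front_lines: np.ndarray,
    window: tuple[float, float] | None = None,
) -> tuple[np.ndarray, float | None]:
    """Roughness W(t) of a transversely resolved front, and its growth slope.

    ``front_lines`` has shape (n_times, n_transverse): the front position at
    each transverse coordinate.  W(t) is the RMS deviation of the front line
    from its transverse mean.  The growth slope is the least-squares slope of
    log W vs. log t over ``window`` (all positive times by default); it is
    omitted (None) when fewer than 2 usable times remain.
    """
    times = np.asarray(times, dtype=float)
    lines = np.asarray(front_lines, dtype=float)
    if lines.ndim != 2 or lines.shape[1] < 2:
        raise ValueError("need >= 2 transverse samples per time")
    if lines.shape[0] != len(times):
        raise ValueError("front_lines rows must match times")
    W = lines.std(axis=1)  # RMS about the transverse mean
    mask = (times > 0) & (W > 0)
    if window is not None:
        mask &= (times >= window[0]) & (times <= window[1])
    if np.sum(mask) < 2:
        return W, None
    res = stats.linregress(np.log(times[mask]), np.log(W[mask]))
    return W, float(res.slope)
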