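"""Division-orientation circular statistics and daughter-displacement pairing.

Division angles are measured relative to the osteogenic front so that 90°
means a division parallel to the medial-lateral axis of expansion.  Angles
are treated as plain circular data by default (the mean angle is the
reported statistic); axial doubling is available behind a flag.  The
Rayleigh statistic is z = n R² with R the mean resultant length.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CircularSummary",
    "circular_stats",
    "daughter_displacement",
    "displacement_bias",
]


@dataclasses.dataclass
class CircularSummary:
    """Circular statistics of a sample of angles (degrees)."""

    mean_angle_deg: float
    R: float                    # mean resultant length, in [0, 1]
    z: float                    # Rayleigh statistic, n * R²
    p_value: float
    n: int
    axial: bool = False


def circular_stats(angles_deg: Sequence[float], axial: bool = False) -> CircularSummary:
    """Mean angle, resultant length R, Rayleigh z = nR² and its p-value.

    ``axial=True`` doubles the angles before averaging (for orientation-only
    data) and halves the resulting mean angle; the default treats angles as
    plain circular data.  The p-value uses the standard Rayleigh-test
    approximation p ≈ exp(sqrt(1 + 4n + 4(n² − z n)) − (1 + 2n)).
    """
    a = np.asarray(angles_deg, dtype=float)
    if a.size == 0:
        raise ValueError("empty angle sample")
    theta = np.deg2rad(a * (2.0 if axial else 1.0))
    C = np.mean(np.cos(theta))
    S = np.mean(np.sin(theta))
    R = float(np.hypot(C, S))
    mean = np.rad2deg(np.arctan2(S, C))
    if axial:
        mean = mean / 2.0
    mean = float(mean % 360.0)
    n = int(a.size)
    z = n * R**2
    # standard approximation; exact for the asymptotic regime, clipped to [0, 1]
    p = float(np.exp(np.sqrt(1.0 + 4.0 * n + 4.0 * (n**2 - z * n)) - (1.0 + 2.0 * n)))
    p = min(max(p, 0.0), 1.0)
    return CircularSummary(mean, R, float(z), p, n, axial)


def daughter_displacement(
    events: pd.DataFrame,
    axis_deg: float = 0.0,
) -> pd.DataFrame:
    """Signed daughter displacements along the expansion axis, paired per event.

    ``events`` columns: event_id, plate_x, plate_y, d1_x, d1_y, d2_x, d2_y —
    the metaphase-plate centroid and the two daughter centroids (µm).
    ``axis_deg`` is the direction of the expansion axis (0° = +x medial).
    Each daughter's displacement is its signed projection onto the axis,
    measured from the plate centroid; the daughter with the larger
    projection is called "medial".  Events whose daughters coincide are
    flagged (both projections zero-like).

    Returns a DataFrame with columns event_id, medial, lateral, coincident —
    ready for a paired test (the test itself is delegated to standard
    statistical routines).
    """
    required = {"event_id", "plate_x", "plate_y", "d1_x", "d1_y", "d2_x", "d2_y"}
    missing = required - set(events.columns)
    if missing:
        raise ValueError(f"events missing column(s): {sorted(missing)}")
    axis = np.array([np.cos(np.deg2rad(axis_deg)), np.sin(np.deg2rad(axis_deg))])
    plate = events[["plate_x", "plate_y"]].to_numpy()
    d1 = events[["d1_x", "d1_y"]].to_numpy() - plate
    d2 = events[["d2_x", "d2_y"]].to_numpy() - plate
    p1 = d1 @ axis
    p2 = d2 @ axis
    medial = np.maximum(p1, p2)
    lateral = np.minimum(p1, p2)
    coincident = np.all(
        np.isclose(events[["d1_x", "d1_y"]].to_numpy(),
                   events[["d2_x", "d2_y"]].to_numpy()),
        axis=1,
    )
    medial = np.where(coincident, 0.0, medial)
    lateral = np.where(coincident, 0.0, lateral)
    return pd.DataFrame(
        {
            "event_id": events["event_id"].to_numpy(),
            "medial": medial,
            "lateral": lateral,
            "coincident": coincident,
        }
    )


def displacement_bias(paired: pd.DataFrame) -> tuple[float, float]:
    """Mean medial-vs-lateral magnitude difference and its standard error.

    The per-event difference is medial − |lateral| = medial + lateral for
    daughters on opposite sides; a positive value means the medial daughter
    moves further from the metaphase plate.
    """
    diff = paired["medial"].to_numpy() + paired["lateral"].to_numpy()
    n = len(diff)
    if n == 0:
        raise ValueError("no events")
    se = float(np.std(diff, ddof=1) / np.sqrt(n)) if n > 1 else np.inf
    return float(np.mean(diff)), se
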