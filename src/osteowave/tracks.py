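"""Cell-track statistics: MSD, scaling exponents, velocity correlations.

Implements the measurements applied to manually tracked nuclei in
live-imaged skull explants.  The MSD uses the displacement-from-origin
definition ``MSD(T) = (1/N) sum_i |x_i(T) - x_i(0)|^2`` (not time-lag
averaging), and the per-track mean velocity is ``|x_i(T) - x_i(0)| / T``.
The spatial velocity correlation ``C_vv(|y_i - y_j|, t)`` is the mean dot
product of unit velocity vectors, binned by transverse (y) separation.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CellTrack",
    "MsdCurve",
    "CorrelationCurve",
    "msd",
    "msd_by_region",
    "msd_scaling_exponent",
    "mean_track_velocities",
    "velocity_spatial_correlation",
    "read_tracks_csv",
    "write_tracks_csv",
]

REGIONS = ("front", "intermediate", "lateral")


@dataclasses.dataclass
class CellTrack:
    """One tracked nucleus: times (h) and 2D positions (µm)."""

    track_id: str
    times: np.ndarray
    positions: np.ndarray          # (n, 2)
    region: str | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 2:
            raise ValueError("positions must be (n, 2)")
        if len(self.times) != len(self.positions):
            raise ValueError("times and positions must have equal length")
        if len(self.times) > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    def displacement(self) -> float:
        return float(np.linalg.norm(self.positions[-1] - self.positions[0]))

    def mean_velocity(self) -> float:
        """Average track velocity |x(T) - x(0)| / T (µm/h)."""
        T = self.times[-1] - self.times[0]
        if T <= 0:
            raise ValueError("track duration must be positive")
        return self.displacement() / T


@dataclasses.dataclass
class MsdCurve:
    """Mean squared displacement from the track origin vs. elapsed time."""

    lags: np.ndarray               # elapsed times (h), lags[0] = 0
    msd: np.ndarray                # µm²
    n_tracks: int

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        self.msd = np.asarray(self.msd, dtype=float)
        if len(self.lags) != len(self.msd):
            raise ValueError("lags and msd must have equal length")
        if np.any(self.msd < -1e-12):
            raise ValueError("msd must be non-negative")


@dataclasses.dataclass
class CorrelationCurve:
    """Velocity-direction correlation vs. transverse distance."""

    bin_centers: np.ndarray        # µm
    C: np.ndarray                  # dimensionless, in [-1, 1]
    pair_counts: np.ndarray


def _common_time_base(tracks: Sequence[CellTrack]) -> np.ndarray:
    base = tracks[0].times
    for tr in tracks[1:]:
        if len(tr.times) != len(base) or not np.allclose(tr.times, base):
            raise ValueError(
                f"track {tr.track_id!r} does not share the common time base"
            )
    return base


def msd(tracks: Sequence[CellTrack]) -> MsdCurve:
    """MSD(T) = mean over tracks of |x_i(T) - x_i(0)|² (µm²).

    All tracks must share one time base; mismatched bases are an error
    (interpolation is deliberately not performed).
    """
    tracks = list(tracks)
    if not tracks:
        raise ValueError("no tracks given")
    base = _common_time_base(tracks)
    disp = np.stack([tr.positions - tr.positions[0] for tr in tracks])
    sq = np.sum(disp**2, axis=2)          # (n_tracks, n_times)
    return MsdCurve(base - base[0], sq.mean(axis=0), len(tracks))


def msd_by_region(tracks: Sequence[CellTrack]) -> dict[str, MsdCurve]:
    """Per-region MSD curves for tracks carrying region labels."""
    out: dict[str, MsdCurve] = {}
    for region in REGIONS:
        sub = [tr for tr in tracks if tr.region == region]
        if sub:
            out[region] = msd(sub)
    return out


def msd_scaling_exponent(
    curve: MsdCurve, window: tuple[float, float]
) -> float:
    """Log-log slope of the MSD over a lag window (2 = ballistic, 1 = diffusive)."""
    lo, hi = window
    mask = (curve.lags >= lo) & (curve.lags <= hi) & (curve.lags > 0)
    if np.sum(mask) < 3:
        raise ValueError("need >= 3 positive-lag points in the window")
    if np.any(curve.msd[mask] <= 0):
        raise ValueError("msd must be positive in the fit window")
    res = stats.linregress(np.log(curve.lags[mask]), np.log(curve.msd[mask]))
    return float(res.slope)


def mean_track_velocities(tracks: Sequence[CellTrack]) -> pd.DataFrame:
    """Per-track mean velocity |x(T) - x(0)|/T, with region labels."""
    return pd.DataFrame(
        {
            "track_id": [tr.track_id for tr in tracks],
            "region": [tr.region for tr in tracks],
            "v_mean_um_per_h": [tr.mean_velocity() for tr in tracks],
        }
    )


def _velocities_at(tracks: Sequence[CellTrack], t: float) -> tuple[np.ndarray, np.ndarray]:
    """Finite-difference velocities at the frame nearest t.

    Centred differences at interior frames, one-sided at the ends (the
    imaging protocol does not prescribe a scheme).
    """
    base = _common_time_base(tracks)
    j = int(np.argmin(np.abs(base - t)))
    pos = np.stack([tr.positions for tr in tracks])      # (n, T, 2)
    if len(base) < 2:
        raise ValueError("need at least 2 frames for velocities")
    if j == 0:
        v = (pos[:, 1] - pos[:, 0]) / (base[1] - base[0])
    elif j == len(base) - 1:
        v = (pos[:, -1] - pos[:, -2]) / (base[-1] - base[-2])
    else:
        v = (pos[:, j + 1] - pos[:, j - 1]) / (base[j + 1] - base[j - 1])
    return pos[:, j], v


def velocity_spatial_correlation(
    tracks: Sequence[CellTrack],
    t: float,
    bin_width: float = 20.0,
) -> CorrelationCurve:
    """C_vv(|y_i - y_j|, t): mean dot product of unit velocities per y-distance bin.

    Velocities are normalised to unit vectors; cells with zero velocity at
    ``t`` are excluded.  Distances are transverse (y) separations, as in the
    imaging quantification.
    """
    tracks = list(tracks)
    if len(tracks) < 2:
        raise ValueError("need >= 2 tracks")
    pos, vel = _velocities_at(tracks, t)
    norms = np.linalg.norm(vel, axis=1)
    keep = norms > 0
    if np.sum(keep) < 2:
        raise ValueError("fewer than 2 tracks with non-zero velocity at t")
    pos, vel = pos[keep], vel[keep] / norms[keep, None]
    n = len(pos)
    iu, ju = np.triu_indices(n, k=1)
    dy = np.abs(pos[iu, 1] - pos[ju, 1])
    dots = np.sum(vel[iu] * vel[ju], axis=1)
    n_bins = int(np.floor(dy.max() / bin_width)) + 1
    idx = np.minimum((dy / bin_width).astype(int), n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    sums = np.bincount(idx, weights=dots, minlength=n_bins)
    with np.errstate(invalid="ignore"):
        C = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    centers = (np.arange(n_bins) + 0.5) * bin_width
    return CorrelationCurve(centers, C, counts)


# ---------------------------------------------------------------------------
# CSV dialect: track_id, t_h, x_um, y_um[, region]
# ---------------------------------------------------------------------------

def write_tracks_csv(tracks: Iterable[CellTrack], path: str | Path) -> None:
    rows = []
    for tr in tracks:
        for t, (x, y) in zip(tr.times, tr.positions):
            rows.append((tr.track_id, t, x, y, tr.region or ""))
    df = pd.DataFrame(rows, columns=["track_id", "t_h", "x_um", "y_um", "region"])
    df.to_csv(path, index=False)


def read_tracks_csv(path: str | Path) -> list[CellTrack]:
    df = pd.read_csv(path)
    required = {"track_id", "t_h", "x_um", "y_um"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"tracks CSV missing column(s): {sorted(missing)}")
    out = []
    for tid, g in df.groupby("track_id", sort=False):
        g = g.sort_values("t_h")
        region = None
        if "region" in g.columns:
            vals = g["region"].dropna().unique()
            region = str(vals[0]) if len(vals) and str(vals[0]) else None
        out.append(
            CellTrack(
                track_id=str(tid),
                times=g["t_h"].to_numpy(),
                positions=g[["x_um", "y_um"]].to_numpy(),
                region=region,
            )
        )
    return out
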