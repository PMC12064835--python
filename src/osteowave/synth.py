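"""Synthetic-data generators with the statistical structure of the imaging data.

Each generator is a pure function of its spec and seed and emits data in the
exact dialects the quantification functions consume, so every analysis stage
can run and be validated with no external data:

* ``generate_tracks`` — persistent random walks per region, persistent at
  the osteogenic front and diffusive toward the bone center, with a medial
  drift that decreases toward the bone center;
* ``generate_profiles`` — travelling sigmoidal reporter-intensity profiles
  with per-sample alignment jitter and multiplicative (fluorescence-like)
  noise;
* ``generate_division_data`` — von Mises division angles concentrated
  around 90° plus paired daughter displacements with a medial bias;
* ``generate_bone_image`` — grayscale rasters of bright bone blobs on a
  background, with known ground-truth areas.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .tracks import CellTrack
from .profiles import IntensityProfile

__all__ = [
    "TrackGeneratorSpec",
    "ProfileGeneratorSpec",
    "AngleGeneratorSpec",
    "BoneImageSpec",
    "generate_tracks",
    "generate_profiles",
    "generate_division_data",
    "generate_bone_image",
]


# ---------------------------------------------------------------------------
# Tracks
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class TrackGeneratorSpec:
    """Persistent-random-walk generator, one parameter set per region.

    Region counts default to the live-imaging cohort sizes (front 199,
    intermediate 117, lateral 139); the frame interval defaults to 10 min
    and the session to 6 h.  Persistence times make front cells ballistic
    over the session and bone-center (lateral) cells diffusive; drift is
    medial (+x) and strongest at the front.
    """

    n_tracks: Mapping[str, int] = dataclasses.field(
        default_factory=lambda: {"front": 199, "intermediate": 117, "lateral": 139}
    )
    frame_interval_h: float = 1.0 / 6.0
    duration_h: float = 6.0
    speed_um_per_h: float = 2.0
    tau_p_h: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: {"front": 4.0, "intermediate": 2.0, "lateral": 0.3}
    )
    diffusion_floor: float = 0.5          # µm²/h
    drift_um_per_h: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: {"front": 1.5, "intermediate": 0.75, "lateral": 0.2}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frame_interval_h <= 0 or self.duration_h <= 0:
            raise ValueError("frame interval and duration must be positive")
        if self.speed_um_per_h < 0 or self.diffusion_floor < 0:
            raise ValueError("speed and diffusion floor must be non-negative")


REGION_X0 = {"front": 0.0, "intermediate": -200.0, "lateral": -400.0}


def generate_tracks(spec: TrackGeneratorSpec) -> list[CellTrack]:
    """Generate 2D persistent-random-walk tracks, reproducible by seed.

    The velocity follows an Ornstein-Uhlenbeck process per axis with
    stationary RMS speed ``speed_um_per_h`` and relaxation time ``tau_p``;
    positions additionally drift medially and diffuse with the floor
    constant.  ``tau_p = inf`` with zero floor gives exactly straight
    tracks.
    """
    rng = np.random.default_rng(spec.seed)
    n_frames = int(round(spec.duration_h / spec.frame_interval_h)) + 1
    times = np.arange(n_frames) * spec.frame_interval_h
    dt = spec.frame_interval_h
    sigma_axis = spec.speed_um_per_h / np.sqrt(2.0)
    out: list[CellTrack] = []
    for region, n in spec.n_tracks.items():
        tau_p = float(spec.tau_p_h.get(region, 1.0))
        drift = float(spec.drift_um_per_h.get(region, 0.0))
        if np.isinf(tau_p):
            a = 1.0
        else:
            a = np.exp(-dt / tau_p) if tau_p > 0 else 0.0
        noise_amp = sigma_axis * np.sqrt(max(0.0, 1.0 - a * a))
        x0 = REGION_X0.get(region, 0.0)
        for i in range(n):
            heading = rng.uniform(0, 2 * np.pi)
            v = spec.speed_um_per_h * np.array([np.cos(heading), np.sin(heading)])
            pos = np.empty((n_frames, 2))
            pos[0] = [x0 + rng.uniform(-20, 20), rng.uniform(0, 300)]
            for j in range(1, n_frames):
                step = (v + np.array([drift, 0.0])) * dt
                if spec.diffusion_floor > 0:
                    step = step + np.sqrt(2 * spec.diffusion_floor * dt) * rng.standard_normal(2)
                pos[j] = pos[j - 1] + step
                v = a * v + noise_amp * rng.standard_normal(2)
            out.append(
                CellTrack(
                    track_id=f"{region}_{i:04d}",
                    times=times.copy(),
                    positions=pos,
                    region=region,
                )
            )
    return out


# ---------------------------------------------------------------------------
# Intensity profiles
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class ProfileGeneratorSpec:
    """Travelling sigmoidal intensity wavefront with realistic noise.

    ``center_times``/``center_positions`` give the front-center trajectory
    (µm vs. h); each sample gets a positional offset jitter and pointwise
    multiplicative log-normal noise.  Intensity is high in the bone (low x)
    and at the baseline in the mesenchyme (high x).
    """

    center_times: np.ndarray = dataclasses.field(
        default_factory=lambda: np.array([0.0, 6.0, 12.0])
    )
    center_positions: np.ndarray = dataclasses.field(
        default_factory=lambda: np.array([300.0, 315.0, 330.0])
    )
    sigmoid_width_um: float = 25.0
    baseline: float = 100.0
    plateau: float = 500.0
    noise_sd: float = 0.05                # multiplicative (log-normal) sd
    offset_jitter_sd_um: float = 10.0
    n_samples: int = 6
    x_min: float = 0.0
    x_max: float = 600.0
    dx_um: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.plateau > self.baseline > 0:
            raise ValueError("need plateau > baseline > 0")
        if self.sigmoid_width_um <= 0:
            raise ValueError("sigmoid width must be positive")


def generate_profiles(spec: ProfileGeneratorSpec) -> list[IntensityProfile]:
    """One IntensityProfile per (sample, time), with baseline annotation.

    ``intensity(x) = baseline + (plateau − baseline) · logistic((c − x)/w)``
    with per-sample center jitter and multiplicative log-normal noise
    (mean-one); the baseline region is annotated well medial of the front.
    """
    rng = np.random.default_rng(spec.seed)
    x = np.arange(spec.x_min, spec.x_max + spec.dx_um / 2, spec.dx_um)
    out: list[IntensityProfile] = []
    for s in range(spec.n_samples):
        offset = rng.normal(0.0, spec.offset_jitter_sd_um)
        for t, c in zip(spec.center_times, spec.center_positions):
            center = c + offset
            clean = spec.baseline + (spec.plateau - spec.baseline) / (
                1.0 + np.exp(-(center - x) / spec.sigmoid_width_um)
            )
            if spec.noise_sd > 0:
                lognorm = np.exp(
                    rng.normal(0.0, spec.noise_sd, size=len(x)) - spec.noise_sd**2 / 2
                )
                vals = clean * lognorm
            else:
                vals = clean
            base_start = np.searchsorted(x, center + 4 * spec.sigmoid_width_um)
            base_start = min(base_start, len(x) - 5)
            out.append(
                IntensityProfile(
                    positions=x.copy(),
                    intensities=vals,
                    baseline=slice(int(base_start), len(x)),
                    sample_id=f"sample{s:02d}",
                    time_label=f"t{t:g}h",
                )
            )
    return out


# ---------------------------------------------------------------------------
# Divisions
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class AngleGeneratorSpec:
    """Von Mises division angles around the expansion-parallel direction."""

    mu_deg: float = 90.0
    kappa: float = 2.0
    n: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kappa < 0:
            raise ValueError("kappa must be non-negative")
        if self.n < 1:
            raise ValueError("n must be at least 1")


def generate_division_data(
    spec: AngleGeneratorSpec,
    displacement_bias_um: float = 1.0,
    base_displacement_um: float = 3.0,
    noise_sd_um: float = 0.5,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Division angles plus paired daughter-displacement events.

    Angles are von Mises(mu, kappa) in degrees.  Each event places the two
    daughters on opposite sides of the metaphase plate along the expansion
    axis, the medial one at ``d + bias/2 + noise`` and the lateral one at
    ``d − bias/2 + noise``, so the generating medial bias equals
    ``displacement_bias_um``.
    """
    rng = np.random.default_rng(spec.seed)
    if spec.kappa == 0:
        angles = rng.uniform(0.0, 360.0, size=spec.n)
    else:
        angles = np.rad2deg(
            rng.vonmises(np.deg2rad(spec.mu_deg), spec.kappa, size=spec.n)
        ) % 360.0
    plate = rng.uniform(-50, 50, size=(spec.n, 2))
    med = base_displacement_um + displacement_bias_um / 2 + rng.normal(0, noise_sd_um, spec.n)
    lat = base_displacement_um - displacement_bias_um / 2 + rng.normal(0, noise_sd_um, spec.n)
    events = pd.DataFrame(
        {
            "event_id": [f"div{i:04d}" for i in range(spec.n)],
            "plate_x": plate[:, 0],
            "plate_y": plate[:, 1],
            "d1_x": plate[:, 0] + med,
            "d1_y": plate[:, 1],
            "d2_x": plate[:, 0] - lat,
            "d2_y": plate[:, 1],
        }
    )
    return angles, events


# ---------------------------------------------------------------------------
# Bone images
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class BoneImageSpec:
    """Bright elliptical bone blobs on a dark background."""

    shape: tuple[int, int] = (256, 256)
    ellipses: Sequence[tuple[float, float, float, float]] = (
        (128.0, 128.0, 60.0, 40.0),
    )                                  # (row, col, r_row, r_col) per blob
    plateau: float = 200.0
    background: float = 50.0
    noise_sd: float = 0.0              # additive Gaussian, a.u.
    seed: int = 0


@dataclasses.dataclass
class BoneImage:
    image: np.ndarray
    true_masks: list[np.ndarray]
    true_areas_px: list[int]

    @property
    def largest_true_area_px(self) -> int:
        return max(self.true_areas_px)


def generate_bone_image(spec: BoneImageSpec) -> BoneImage:
    """Raster with known blob geometry; returns ground-truth pixel areas."""
    rng = np.random.default_rng(spec.seed)
    rows, cols = np.mgrid[0 : spec.shape[0], 0 : spec.shape[1]]
    image = np.full(spec.shape, spec.background, dtype=float)
    masks, areas = [], []
    for (cy, cx, ry, rx) in spec.ellipses:
        if cy - ry < 0 or cy + ry >= spec.shape[0] or cx - rx < 0 or cx + rx >= spec.shape[1]:
            raise ValueError("ellipse does not fit inside the raster")
        mask = ((rows - cy) / ry) ** 2 + ((cols - cx) / rx) ** 2 <= 1.0
        image[mask] = spec.plateau
        masks.append(mask)
        areas.append(int(mask.sum()))
    if spec.noise_sd > 0:
        image = image + rng.normal(0.0, spec.noise_sd, size=spec.shape)
    return BoneImage(image, masks, areas)
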