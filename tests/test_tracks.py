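"""Track statistics: MSD, scaling exponents, velocity correlations, CSV I/O."""

import numpy as np
import pytest

from osteowave import (
    CellTrack,
    MsdCurve,
    msd,
    msd_by_region,
    msd_scaling_exponent,
    read_tracks_csv,
    velocity_spatial_correlation,
    write_tracks_csv,
)
from osteowave.tracks import mean_track_velocities


def _track(tid, times, xy, region=None):
    return CellTrack(tid, np.asarray(times, float), np.asarray(xy, float), region)


TIMES = np.linspace(0, 6, 13)


class TestMsd:
    def test_stationary_track_is_zero(self):
        tr = _track("a", TIMES, np.tile([3.0, 4.0], (len(TIMES), 1)))
        curve = msd([tr])
        assert np.allclose(curve.msd, 0.0)
        assert curve.msd[0] == 0.0

    def test_ballistic_track_is_exactly_quadratic(self):
        s = 1.7
        xy = np.stack([s * TIMES, np.zeros_like(TIMES)], axis=1)
        curve = msd([_track("a", TIMES, xy)])
        assert np.allclose(curve.msd, (s * curve.lags) ** 2)

    def test_diffusive_ensemble_matches_4Dt(self, rng):
        """2000 independent 2D random walks: MSD within 5% of 4*D*t."""
        D = 0.8
        dt = TIMES[1] - TIMES[0]
        steps = rng.normal(0, np.sqrt(2 * D * dt), size=(2000, len(TIMES) - 1, 2))
        pos = np.concatenate(
            [np.zeros((2000, 1, 2)), np.cumsum(steps, axis=1)], axis=1
        )
        tracks = [_track(f"t{i}", TIMES, pos[i]) for i in range(2000)]
        curve = msd(tracks)
        expected = 4 * D * curve.lags[1:]
        assert np.max(np.abs(curve.msd[1:] - expected) / expected) <= 0.05

    def test_matches_naive_double_loop(self, rng):
        """Vectorised MSD equals the brute-force per-track, per-time loop."""
        tracks = [
            _track(f"t{i}", TIMES, rng.normal(0, 5, size=(len(TIMES), 2)))
            for i in range(50)
        ]
        curve = msd(tracks)
        naive = np.zeros(len(TIMES))
        for j in range(len(TIMES)):
            acc = 0.0
            for tr in tracks:
                d = tr.positions[j] - tr.positions[0]
                acc += d[0] ** 2 + d[1] ** 2
            naive[j] = acc / len(tracks)
        assert np.max(np.abs(curve.msd - naive)) <= 1e-12 * max(1.0, naive.max())

    def test_mismatched_time_bases_rejected(self):
        a = _track("a", TIMES, np.zeros((len(TIMES), 2)))
        b = _track("b", TIMES + 0.01, np.zeros((len(TIMES), 2)))
        with pytest.raises(ValueError, match="time base"):
            msd([a, b])

    def test_region_split(self):
        a = _track("a", TIMES, np.zeros((len(TIMES), 2)), region="front")
        b = _track("b", TIMES, np.zeros((len(TIMES), 2)), region="lateral")
        curves = msd_by_region([a, b])
        assert set(curves) == {"front", "lateral"}
        assert curves["front"].n_tracks == 1


class TestScalingExponent:
    def test_exact_ballistic_and_diffusive_exponents(self):
        lags = np.linspace(0, 6, 25)
        ballistic = MsdCurve(lags, 3.0 * lags**2, 1)
        diffusive = MsdCurve(lags, 3.0 * lags, 1)
        assert msd_scaling_exponent(ballistic, (0.5, 6)) == pytest.approx(2.0, abs=1e-9)
        assert msd_scaling_exponent(diffusive, (0.5, 6)) == pytest.approx(1.0, abs=1e-9)

    def test_too_few_points_rejected(self):
        curve = MsdCurve(np.array([0.0, 1.0, 2.0]), np.array([0.0, 1.0, 2.0]), 1)
        with pytest.raises(ValueError):
            msd_scaling_exponent(curve, (0.9, 1.1))


class TestVelocityCorrelation:
    def test_common_heading_gives_unit_correlation(self):
        tracks = [
            _track(f"t{i}", TIMES,
                   np.stack([2.0 * TIMES, np.full_like(TIMES, 10.0 * i)], axis=1))
            for i in range(6)
        ]
        curve = velocity_spatial_correlation(tracks, t=3.0, bin_width=15.0)
        occupied = curve.pair_counts > 0
        assert np.allclose(curve.C[occupied], 1.0)

    def test_opposite_headings_give_minus_one(self):
        a = _track("a", TIMES, np.stack([TIMES, np.zeros_like(TIMES)], axis=1))
        b = _track("b", TIMES, np.stack([-TIMES, np.full_like(TIMES, 5.0)], axis=1))
        curve = velocity_spatial_correlation([a, b], t=3.0, bin_width=10.0)
        occupied = curve.pair_counts > 0
        assert np.allclose(curve.C[occupied], -1.0)

    def test_isotropic_headings_decorrelate(self, rng):
        """500 cells with random headings: |C| < 0.1 in well-filled bins."""
        n = 500
        headings = rng.uniform(0, 2 * np.pi, n)
        y0 = rng.uniform(0, 200, n)
        tracks = [
            _track(
                f"t{i}", TIMES,
                np.stack([np.cos(headings[i]) * TIMES,
                          y0[i] + np.sin(headings[i]) * TIMES], axis=1),
            )
            for i in range(n)
        ]
        curve = velocity_spatial_correlation(tracks, t=3.0, bin_width=20.0)
        filled = curve.pair_counts >= 50
        assert np.all(np.abs(curve.C[filled]) < 0.1)

    def test_all_zero_velocities_rejected(self):
        tracks = [
            _track(f"t{i}", TIMES, np.tile([float(i), 0.0], (len(TIMES), 1)))
            for i in range(3)
        ]
        with pytest.raises(ValueError):
            velocity_spatial_correlation(tracks, t=3.0)


class TestMeanVelocityAndIO:
    def test_mean_track_velocity_from_origin(self):
        xy = np.stack([3.0 * TIMES, 4.0 * TIMES], axis=1)   # speed 5
        table = mean_track_velocities([_track("a", TIMES, xy, region="front")])
        assert table["v_mean_um_per_h"].iloc[0] == pytest.approx(5.0)

    def test_csv_round_trip(self, tmp_path, rng):
        tracks = [
            _track(f"t{i}", TIMES, rng.normal(0, 5, size=(len(TIMES), 2)),
                   region="front" if i % 2 else "lateral")
            for i in range(4)
        ]
        path = tmp_path / "tracks.csv"
        write_tracks_csv(tracks, path)
        back = read_tracks_csv(path)
        assert len(back) == 4
        for a, b in zip(tracks, back):
            assert a.track_id == b.track_id
            assert a.region == b.region
            assert np.allclose(a.positions, b.positions)
            assert np.allclose(a.times, b.times)
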