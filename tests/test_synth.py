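"""Synthetic-data generators: determinism, limits, and recoverability.

Each generator must be a pure function of its spec and seed, and its
generating parameters must be recoverable by the corresponding analysis
stage — that round trip is the module's core purpose.
"""

import numpy as np
import pytest

from osteowave import (
    AngleGeneratorSpec,
    BoneImageSpec,
    ProfileGeneratorSpec,
    TrackGeneratorSpec,
    circular_stats,
    daughter_displacement,
    displacement_bias,
    generate_bone_image,
    generate_division_data,
    generate_profiles,
    generate_tracks,
    msd,
    msd_scaling_exponent,
    segment_bone_area,
)


class TestTrackGenerator:
    def test_same_seed_identical_output(self):
        spec = TrackGeneratorSpec(n_tracks={"front": 5, "lateral": 5}, seed=9)
        a = generate_tracks(spec)
        b = generate_tracks(spec)
        for ta, tb in zip(a, b):
            assert ta.track_id == tb.track_id
            assert np.array_equal(ta.positions, tb.positions)

    def test_infinite_persistence_without_noise_is_ballistic(self):
        spec = TrackGeneratorSpec(
            n_tracks={"front": 10},
            tau_p_h={"front": np.inf},
            drift_um_per_h={"front": 0.0},
            diffusion_floor=0.0,
            speed_um_per_h=2.0,
            seed=1,
        )
        tracks = generate_tracks(spec)
        curve = msd(tracks)
        # exactly straight lines at the stationary speed
        assert msd_scaling_exponent(curve, (0.5, 6.0)) == pytest.approx(2.0, abs=1e-9)
        for tr in tracks:
            assert tr.mean_velocity() == pytest.approx(2.0, rel=1e-9)

    def test_vanishing_persistence_leaves_the_diffusion_floor(self):
        """tau_p -> 0 with floor D: ensemble MSD within 5% of 4*D*t."""
        D = 1.1
        spec = TrackGeneratorSpec(
            n_tracks={"lateral": 2000},
            tau_p_h={"lateral": 0.0},
            drift_um_per_h={"lateral": 0.0},
            diffusion_floor=D,
            speed_um_per_h=0.05,   # negligible against the floor
            seed=4,
        )
        curve = msd(generate_tracks(spec))
        expected = 4 * D * curve.lags[1:]
        assert np.max(np.abs(curve.msd[1:] - expected) / expected) <= 0.05

    def test_region_structure_matches_the_imaging_cohorts(self):
        tracks = generate_tracks(TrackGeneratorSpec(seed=0))
        regions = {r: sum(t.region == r for t in tracks)
                   for r in ("front", "intermediate", "lateral")}
        assert regions == {"front": 199, "intermediate": 117, "lateral": 139}
        # front cells persist; bone-center cells do not
        from osteowave import msd_by_region

        curves = msd_by_region(tracks)
        late = (3.0, 6.0)
        assert msd_scaling_exponent(curves["front"], late) > \
            msd_scaling_exponent(curves["lateral"], late)


class TestProfileGenerator:
    def test_noise_free_alignment_recovers_the_center(self):
        spec = ProfileGeneratorSpec(noise_sd=0.0, offset_jitter_sd_um=0.0,
                                    n_samples=3, seed=0)
        profiles = generate_profiles(spec)
        for prof, (t, c) in zip(profiles[:3], zip(spec.center_times,
                                                  spec.center_positions)):
            # invert the logistic at this profile's actual threshold (the
            # annotated baseline region includes a little of the tail)
            thr = 1.1 * prof.baseline_value()
            u = (thr - spec.baseline) / (spec.plateau - spec.baseline)
            expected = c + spec.sigmoid_width_um * np.log((1 - u) / u)
            assert abs(prof.alignment_point() - expected) <= spec.dx_um

    def test_noiseless_slope_matches_the_analytic_logistic(self):
        """Fitted 0-100 µm slope equals the same fit on the closed form."""
        from osteowave import align_intensity_profiles, front_intensity_slope
        from scipy import stats

        spec = ProfileGeneratorSpec(noise_sd=0.0, offset_jitter_sd_um=0.0,
                                    n_samples=2, seed=0, dx_um=1.0)
        profiles = [p for p in generate_profiles(spec) if p.time_label == "t0h"]
        aligned = align_intensity_profiles(profiles)
        slope = front_intensity_slope(aligned)
        prof = profiles[0]
        s = prof.alignment_point() - prof.positions
        mask = (s >= 0) & (s <= 100)
        oracle = stats.linregress(s[mask], prof.intensities[mask]).slope
        assert slope == pytest.approx(oracle, rel=1e-6)

    def test_sd_band_shrinks_with_sample_count(self):
        """Doubling n_samples roughly halves the s.e. of the mean profile."""
        ratios = []
        for seed in range(10):
            bands = []
            for n in (4, 16):
                from osteowave import align_intensity_profiles

                spec = ProfileGeneratorSpec(n_samples=n, seed=seed,
                                            center_times=np.array([0.0]),
                                            center_positions=np.array([300.0]))
                aligned = align_intensity_profiles(generate_profiles(spec))
                good = aligned.n_samples == n
                sem = aligned.sd[good] / np.sqrt(n)
                bands.append(np.nanmean(sem))
            ratios.append(bands[0] / bands[1])
        # expectation: sqrt(16/4) = 2
        assert abs(np.mean(ratios) - 2.0) <= 0.4

    def test_determinism(self):
        spec = ProfileGeneratorSpec(seed=3, n_samples=2)
        a = generate_profiles(spec)
        b = generate_profiles(spec)
        assert all(np.array_equal(x.intensities, y.intensities)
                   for x, y in zip(a, b))


class TestDivisionGenerator:
    def test_concentrated_angles_center_on_mu(self):
        angles, _ = generate_division_data(AngleGeneratorSpec(kappa=100.0, n=500,
                                                              seed=2), 0.0)
        s = circular_stats(angles)
        assert abs((s.mean_angle_deg - 90 + 180) % 360 - 180) <= 2.0

    def test_uniform_angles_pass_the_rayleigh_null(self):
        """kappa = 0: R below the 95% Rayleigh bound in >= 90% of seeds."""
        n = 200
        bound = np.sqrt(-np.log(0.05) / n)
        ok = 0
        for seed in range(20):
            angles, _ = generate_division_data(AngleGeneratorSpec(kappa=0.0, n=n,
                                                                  seed=seed), 0.0)
            ok += circular_stats(angles).R < bound
        assert ok >= 18

    def test_unbiased_daughters_cover_zero(self):
        """delta = 0: the paired-difference CI covers 0 in >= 90% of seeds."""
        ok = 0
        for seed in range(20):
            _, events = generate_division_data(AngleGeneratorSpec(n=200, seed=seed),
                                               displacement_bias_um=0.0)
            bias, se = displacement_bias(daughter_displacement(events))
            ok += abs(bias) <= 1.96 * se
        assert ok >= 18

    def test_bias_recovered(self):
        _, events = generate_division_data(AngleGeneratorSpec(n=500, seed=7),
                                           displacement_bias_um=1.5)
        bias, se = displacement_bias(daughter_displacement(events))
        assert abs(bias - 1.5) <= 3 * se


class TestBoneImageGenerator:
    def test_noise_free_segmentation_is_exact(self):
        img = generate_bone_image(BoneImageSpec(noise_sd=0.0, seed=0))
        res = segment_bone_area(img.image, threshold=125.0)
        assert res.n_pixels == img.largest_true_area_px

    def test_moderate_noise_stays_within_two_percent(self):
        spec = BoneImageSpec(noise_sd=15.0, seed=3)   # 10% of the contrast
        img = generate_bone_image(spec)
        res = segment_bone_area(img.image, threshold=125.0)
        assert abs(res.n_pixels - img.largest_true_area_px) \
            <= 0.02 * img.largest_true_area_px

    def test_two_blobs_largest_returned(self):
        spec = BoneImageSpec(
            ellipses=((80.0, 80.0, 50.0, 40.0), (200.0, 200.0, 20.0, 15.0)),
            noise_sd=0.0, seed=0,
        )
        img = generate_bone_image(spec)
        res = segment_bone_area(img.image, threshold=125.0)
        assert res.n_pixels == max(img.true_areas_px)

    def test_out_of_raster_ellipse_rejected(self):
        with pytest.raises(ValueError, match="fit"):
            generate_bone_image(BoneImageSpec(ellipses=((10.0, 10.0, 40.0, 40.0),)))

    def test_determinism(self):
        a = generate_bone_image(BoneImageSpec(noise_sd=5.0, seed=11))
        b = generate_bone_image(BoneImageSpec(noise_sd=5.0, seed=11))
        assert np.array_equal(a.image, b.image)
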