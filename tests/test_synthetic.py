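"""Generators: determinism, sectioning geometry, truth-table completeness."""

import numpy as np
import pandas as pd
import pytest

from wpbmorph import synthetic
from wpbmorph.errors import ConfigError
from wpbmorph.synthetic import (
    ExoSceneSpec,
    PhSceneSpec,
    RodPopulationSpec,
    SpherePopulationSpec,
    StringSceneSpec,
    section_profile_radius,
)


class TestSectionProfiles:
    def test_diametric_section_recovers_exact_diameter(self):
        # slab centred on the equator projects the full great circle
        r = section_profile_radius(np.array([150.0]), np.array([0.0]), 0.0)
        assert r[0] == pytest.approx(150.0)
        # anywhere inside the slab half-thickness still sees the equator
        r = section_profile_radius(np.array([150.0]), np.array([25.0]), 60.0)
        assert r[0] == pytest.approx(150.0)

    def test_offset_section_shrinks_profile(self):
        r = section_profile_radius(np.array([150.0]), np.array([90.0]), 0.0)
        assert r[0] == pytest.approx(np.sqrt(150.0**2 - 90.0**2))

    def test_miss_returns_nan(self):
        r = section_profile_radius(np.array([150.0]), np.array([200.0]), 0.0)
        assert np.isnan(r[0])

    def test_mean_apparent_diameter_is_pi_over_4_of_true(self, sphere_profiles_t0):
        profiles, _ = sphere_profiles_t0
        apparent = (profiles["long_axis_nm"] + profiles["short_axis_nm"]) / 2
        assert apparent.mean() / 300.0 == pytest.approx(np.pi / 4, rel=0.01)

    def test_apparent_never_exceeds_true_without_jitter(self, sphere_profiles_t0):
        profiles, truth = sphere_profiles_t0
        assert (profiles["long_axis_nm"].to_numpy()
                <= truth["true_diameter_nm"].to_numpy() + 1e-9).all()
        assert (profiles["short_axis_nm"] <= profiles["long_axis_nm"] + 1e-12).all()

    def test_size_biased_sampling_matches_brute_force_oracle(self):
        # two-size mixture: intersection counts must scale with D + t
        t = 60.0
        spec = SpherePopulationSpec(
            n_spheres=100_000, diameter_model="mixture",
            mixture_diameters_nm=(200.0, 400.0), mixture_weights=(0.5, 0.5),
            section_thickness_nm=t, seed=5)
        _, truth = synthetic.generate_section_profiles(spec)
        counts = truth["true_diameter_nm"].round().value_counts()
        observed_ratio = counts[400] / counts[200]

        # brute-force oracle: fixed sphere positions at uniform depths,
        # count slab intersections per size class directly
        rng = np.random.default_rng(123)
        span = 400.0 + t
        n = 100_000
        hits = {}
        for d in (200.0, 400.0):
            z = rng.uniform(-span / 2, span / 2, n)
            hits[d] = int((np.abs(z) <= d / 2 + t / 2).sum())
        oracle_ratio = hits[400.0] / hits[200.0]

        assert observed_ratio == pytest.approx(460.0 / 260.0, rel=0.03)
        assert observed_ratio == pytest.approx(oracle_ratio, rel=0.03)

    def test_jitter_orders_axes(self, jittered_profiles):
        assert (jittered_profiles["long_axis_nm"]
                >= jittered_profiles["short_axis_nm"]).all()

    def test_determinism_and_truth_completeness(self):
        spec = SpherePopulationSpec(n_spheres=500, diameter_model="lognormal",
                                    diameter_median_nm=300, seed=3)
        p1, t1 = synthetic.generate_section_profiles(spec)
        p2, t2 = synthetic.generate_section_profiles(spec)
        pd.testing.assert_frame_equal(p1, p2)
        pd.testing.assert_frame_equal(t1, t2)
        assert sorted(p1["profile_id"]) == sorted(t1["profile_id"])
        assert t1["profile_id"].is_unique

    def test_invalid_spec_rejected(self):
        with pytest.raises(ConfigError):
            synthetic.generate_section_profiles(SpherePopulationSpec(n_spheres=0))
        with pytest.raises(ConfigError):
            synthetic.generate_section_profiles(
                SpherePopulationSpec(n_spheres=10, section_thickness_nm=-1))


class TestRodLengths:
    def test_sample_median_matches_model(self):
        spec = RodPopulationSpec(n_rods=10_000, length_median_um=1.0,
                                 length_sigma_log=0.3, seed=9)
        rods, truth = synthetic.generate_rod_lengths(spec)
        assert np.median(rods["length_um"]) == pytest.approx(1.0, rel=0.02)
        assert len(truth) == len(rods)

    def test_single_rod_and_determinism(self):
        spec = RodPopulationSpec(n_rods=1, seed=4)
        r1, _ = synthetic.generate_rod_lengths(spec)
        r2, _ = synthetic.generate_rod_lengths(spec)
        assert len(r1) == 1
        pd.testing.assert_frame_equal(r1, r2)


class TestPhScene:
    def test_noiseless_ratio_at_pka_is_half_of_ref_fluorescence(self):
        spec = PhSceneSpec(n_organelles=5, true_ph_mean=6.0, true_ph_sd=0.0,
                           pka=6.0, hill_n=1.0, ph_ref=7.4, noise_sd=0.0, seed=1)
        meas, _, _ = synthetic.generate_ph_measurements(spec)
        f_ref = 1.0 / (1.0 + 10.0 ** (6.0 - 7.4))
        np.testing.assert_allclose(meas["f_rest"] / meas["f_max"], 0.5 / f_ref)

    def test_rest_equals_max_at_reference_ph(self):
        spec = PhSceneSpec(n_organelles=3, true_ph_mean=7.4, true_ph_sd=0.0,
                           noise_sd=0.0, seed=1)
        meas, _, _ = synthetic.generate_ph_measurements(spec)
        np.testing.assert_allclose(meas["f_rest"], meas["f_max"])

    def test_trace_steps_at_nh4cl_time(self):
        spec = PhSceneSpec(n_organelles=1, true_ph_mean=5.4, true_ph_sd=0.0,
                           noise_sd=0.0, nh4cl_time_s=30.0, trace_duration_s=60.0,
                           seed=1)
        meas, traces, _ = synthetic.generate_ph_measurements(spec)
        pre = traces.loc[traces["time_s"] < 30.0, "fluorescence"]
        post = traces.loc[traces["time_s"] >= 30.0, "fluorescence"]
        assert pre.nunique() == 1 and post.nunique() == 1
        assert post.iloc[0] > pre.iloc[0]


class TestFusionEvents:
    def test_zero_rate_gives_no_events(self):
        spec = ExoSceneSpec(n_cells=3, rate_per_s=0.0, seed=2)
        events, cells, _, truth = synthetic.generate_fusion_events(spec)
        assert len(events) == 0
        assert (truth["n_events"] == 0).all()

    def test_constant_rate_recovered_from_event_gaps(self):
        spec = ExoSceneSpec(n_cells=50, total_wpb_mean=400, releasable_fraction=0.5,
                            rate_per_s=4.0, latency_sd_s=0.0, trace_duration_s=200.0,
                            seed=6)
        events, cells, _, truth = synthetic.generate_fusion_events(spec)
        # events per cell / active duration estimates the Poisson rate
        rates = []
        for cid, grp in events.groupby("cell_id"):
            t = np.sort(grp["event_time_s"].to_numpy())
            if len(t) > 10:
                rates.append((len(t) - 1) / (t[-1] - t[0]))
        assert np.mean(rates) == pytest.approx(4.0, rel=0.15)

    def test_determinism(self):
        spec = ExoSceneSpec(n_cells=4, seed=13)
        e1, c1, t1, _ = synthetic.generate_fusion_events(spec)
        e2, c2, t2, _ = synthetic.generate_fusion_events(spec)
        pd.testing.assert_frame_equal(e1, e2)
        pd.testing.assert_frame_equal(t1, t2)

    def test_events_within_trace_and_after_onset(self):
        spec = ExoSceneSpec(n_cells=5, seed=8)
        events, _, traces, truth = synthetic.generate_fusion_events(spec)
        assert (events["event_time_s"] < spec.trace_duration_s).all()
        assert (events["event_time_s"] > spec.onset_time_s).all()


class TestStrings:
    def test_straight_string_length_equals_endpoint_distance(self):
        spec = StringSceneSpec(n_strings=1, turn_angle_sd=0.0, length_median_um=50,
                               length_sigma_log=0.0, seed=5)
        points, _, _, truth = synthetic.generate_strings(spec)
        v = points[["x_um", "y_um"]].to_numpy()
        arc = np.sum(np.hypot(*np.diff(v, axis=0).T))
        chord = np.hypot(*(v[-1] - v[0]))
        assert arc == pytest.approx(chord, rel=1e-9)
        assert arc == pytest.approx(truth["true_length_um"].iloc[0], rel=1e-9)

    def test_arc_length_within_one_step_of_target(self):
        spec = StringSceneSpec(n_strings=1, length_median_um=100.0,
                               length_sigma_log=0.0, step_length_um=0.5, seed=5)
        points, _, _, truth = synthetic.generate_strings(spec)
        assert abs(truth["true_length_um"].iloc[0] - 100.0) <= 0.5

    def test_platelet_counts_follow_poisson_mean(self):
        spec = StringSceneSpec(n_strings=20, length_median_um=500.0,
                               length_sigma_log=0.0, platelet_density_per_um=0.2,
                               seed=17)
        _, _, platelets, truth = synthetic.generate_strings(spec)
        total_len = truth["true_length_um"].sum()
        expected = 0.2 * total_len
        # Poisson sd = sqrt(mean); allow 4 sigma
        assert abs(len(platelets) - expected) < 4 * np.sqrt(expected)

    def test_raster_has_foreground_and_is_2d(self):
        spec = StringSceneSpec(n_strings=2, length_median_um=30, seed=3)
        points, _, _, _ = synthetic.generate_strings(spec)
        img = synthetic.rasterize_strings(points, 0.5)
        assert img.ndim == 2 and img.dtype == bool and img.any()

    def test_truth_ids_unique_and_complete(self):
        spec = StringSceneSpec(n_strings=7, seed=1)
        points, meta, _, truth = synthetic.generate_strings(spec)
        assert set(points["string_id"]) == set(truth["string_id"])
        assert truth["string_id"].is_unique
        assert set(meta["string_id"]) == set(truth["string_id"])


def test_substreams_are_independent_of_other_generators():
    # adding or removing one generator's draws must not perturb another's
    s1, _ = synthetic.generate_rod_lengths(RodPopulationSpec(n_rods=10, seed=42))
    _ = synthetic.generate_section_profiles(
        SpherePopulationSpec(n_spheres=100, seed=42))
    s2, _ = synthetic.generate_rod_lengths(RodPopulationSpec(n_rods=10, seed=42))
    pd.testing.assert_frame_equal(s1, s2)
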