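"""Stereology: sphericity filter, pi/4 correction, volume models, recovery."""

import numpy as np
import pandas as pd
import pytest

from wpbmorph import stereology, synthetic
from wpbmorph.config import StereologyConfig
from wpbmorph.errors import InvalidMeasurementError
from wpbmorph.stereology import (
    apparent_diameter,
    axis_ratio,
    correct_diameter,
    estimate_volume_distribution,
    filter_spherical,
    rod_volume,
    sphere_volume,
    summarize_rings,
)


def _profiles(pairs):
    return pd.DataFrame(
        {
            "profile_id": [f"p{i}" for i in range(len(pairs))],
            "cell_id": "c0",
            "group": "g",
            "long_axis_nm": [a for a, _ in pairs],
            "short_axis_nm": [b for _, b in pairs],
        }
    )


class TestAxisRatio:
    @pytest.mark.parametrize(
        "long_nm,short_nm,expected",
        [(110, 100, 1.1), (100, 100, 1.0), (140, 100, 1.4)],
    )
    def test_values(self, long_nm, short_nm, expected):
        assert axis_ratio(long_nm, short_nm) == pytest.approx(expected)

    def test_nonpositive_short_axis_rejected(self):
        with pytest.raises(InvalidMeasurementError):
            axis_ratio(100, 0)


class TestFilterSpherical:
    def test_strict_inequality_at_boundary(self):
        profiles = _profiles([(110, 100), (130, 100), (140, 100)])
        kept, report = filter_spherical(profiles, 1.3)
        assert report == {"n_total": 3, "n_kept": 1, "max_ratio": 1.3}
        assert kept["profile_id"].tolist() == ["p0"]

    def test_all_circular_profiles_kept(self):
        profiles = _profiles([(100, 100)] * 4)
        kept, report = filter_spherical(profiles)
        assert report["n_kept"] == 4

    def test_empty_input_gives_zero_counts(self):
        kept, report = filter_spherical(_profiles([]))
        assert len(kept) == 0 and report == {"n_total": 0, "n_kept": 0, "max_ratio": 1.3}

    def test_infinite_cut_is_identity(self, jittered_profiles):
        kept, _ = filter_spherical(jittered_profiles, np.inf)
        pd.testing.assert_frame_equal(kept, jittered_profiles.reset_index(drop=True))

    def test_matches_brute_force_recount(self, jittered_profiles):
        kept, report = filter_spherical(jittered_profiles, 1.3)
        recount = sum(
            1
            for a, b in zip(jittered_profiles["long_axis_nm"],
                            jittered_profiles["short_axis_nm"])
            if a / b < 1.3
        )
        assert report["n_kept"] == recount == len(kept)


class TestApparentDiameter:
    def test_arithmetic_mean(self):
        assert apparent_diameter(110, 100) == pytest.approx(105)
        assert apparent_diameter(100, 100) == pytest.approx(100)

    def test_batch_equals_columnwise_mean(self, jittered_profiles):
        batch = apparent_diameter(
            jittered_profiles["long_axis_nm"].to_numpy(),
            jittered_profiles["short_axis_nm"].to_numpy(),
        )
        brute = (jittered_profiles["long_axis_nm"].to_numpy()
                 + jittered_profiles["short_axis_nm"].to_numpy()) / 2
        np.testing.assert_allclose(batch, brute)

    def test_geometric_mean_mode(self):
        assert apparent_diameter(200, 50, "geometric_mean") == pytest.approx(100)


class TestCorrectDiameter:
    def test_four_over_pi(self):
        assert correct_diameter(100.0) == pytest.approx(127.32395, abs=1e-5)
        assert correct_diameter(0.0) == 0.0

    def test_negative_rejected(self):
        with pytest.raises(InvalidMeasurementError):
            correct_diameter(-1.0)

    def test_linear_and_increasing(self):
        d = np.linspace(0, 500, 50)
        out = correct_diameter(d)
        assert (np.diff(out) > 0).all()
        np.testing.assert_allclose(out, d * 4 / np.pi)
        assert (out[1:] >= d[1:]).all()  # factor 4/pi > 1

    def test_monte_carlo_recovery_at_zero_thickness(self, sphere_profiles_t0):
        profiles, _ = sphere_profiles_t0
        d_app = apparent_diameter(profiles["long_axis_nm"].to_numpy(),
                                  profiles["short_axis_nm"].to_numpy())
        assert correct_diameter(d_app).mean() == pytest.approx(300.0, rel=0.01)

    def test_finite_section_thickness_bias_is_positive_and_monotone(self):
        # thicker slabs project larger circles -> corrected mean overshoots
        means = []
        for t in (0.0, 30.0, 60.0, 120.0):
            spec = synthetic.SpherePopulationSpec(
                n_spheres=30_000, diameter_nm=300.0, section_thickness_nm=t, seed=15)
            profiles, _ = synthetic.generate_section_profiles(spec)
            d_app = apparent_diameter(profiles["long_axis_nm"].to_numpy(),
                                      profiles["short_axis_nm"].to_numpy())
            means.append(correct_diameter(d_app).mean())
        assert means[0] == pytest.approx(300.0, rel=0.01)
        assert means[1] > means[0] and means[2] > means[1] and means[3] > means[2]


class TestVolumes:
    def test_sphere_volume_values(self):
        assert sphere_volume(100.0) == pytest.approx(4.18879, abs=1e-4)
        assert sphere_volume(160.0) == pytest.approx(17.157, abs=2e-3)
        assert sphere_volume(0.0) == 0.0

    def test_rod_volume_values(self):
        assert rod_volume(1.0, 150.0) == pytest.approx(17.671, abs=1e-3)
        assert rod_volume(0.5, 150.0) == pytest.approx(8.836, abs=1e-3)
        assert rod_volume(1.0, 0.0) == 0.0

    def test_volumes_strictly_increasing(self):
        r = np.linspace(0.1, 300, 40)
        assert (np.diff(sphere_volume(r)) > 0).all()
        lengths = np.linspace(0.1, 5, 40)
        assert (np.diff(rod_volume(lengths)) > 0).all()


class TestVolumeDistribution:
    def test_identical_corrected_radii(self):
        # corrected radius 100 nm <=> apparent diameter 200 * pi/4
        d_app = 200.0 * np.pi / 4
        profiles = _profiles([(d_app, d_app)] * 3)
        table, summary = estimate_volume_distribution(profiles, "profiles")
        np.testing.assert_allclose(table["corrected_radius_nm"], 100.0)
        assert summary.mean_al == pytest.approx(4.18879, abs=1e-4)
        assert summary.sem_al == 0.0

    def test_rod_pipeline(self):
        rods = pd.DataFrame({"wpb_id": ["a", "b"], "cell_id": "c", "group": "g",
                             "length_um": [1.028, 1.028]})
        table, summary = estimate_volume_distribution(rods, "rods")
        assert summary.mean_al == pytest.approx(18.17, abs=0.01)

    def test_summary_consistent_with_table(self, jittered_profiles):
        table, summary = estimate_volume_distribution(jittered_profiles, "profiles")
        vols = table["volume_al"].to_numpy()
        assert summary.n == len(table) == summary.counts.sum()
        assert summary.mean_al == pytest.approx(vols.mean())
        assert summary.sem_al == pytest.approx(vols.std(ddof=1) / np.sqrt(len(vols)))

    def test_monodisperse_recovery_of_true_volume(self, sphere_profiles_t0):
        profiles, _ = sphere_profiles_t0
        table, _ = estimate_volume_distribution(profiles, "profiles")
        # volume of the recovered mean diameter; the per-object volume mean
        # carries the cubic's Jensen bias and is checked in test_acceptance
        mean_r = table["corrected_radius_nm"].mean()
        assert sphere_volume(mean_r) == pytest.approx(14.137, rel=0.03)

    def test_empty_after_filter_raises(self):
        profiles = _profiles([(200, 100)])  # ratio 2.0, filtered out
        with pytest.raises(InvalidMeasurementError, match="no profiles remain"):
            estimate_volume_distribution(profiles, "profiles")


class TestRings:
    def test_two_ring_summary(self):
        rings = pd.DataFrame({"tubule_id": ["t1", "t2"],
                              "inner_nm": [10.0, 14.0], "outer_nm": [20.0, 24.0]})
        out = summarize_rings(rings)
        assert out["inner"]["mean_nm"] == pytest.approx(12.0)
        assert out["inner"]["sem_nm"] == pytest.approx(2.0)
        assert out["outer"]["mean_nm"] == pytest.approx(22.0)
        assert out["outer"]["sem_nm"] == pytest.approx(2.0)

    def test_single_ring_flags_undefined_sem(self):
        rings = pd.DataFrame({"tubule_id": ["t1"], "inner_nm": [12.0],
                              "outer_nm": [22.0]})
        out = summarize_rings(rings)
        assert out["sem_defined"] is False and out["inner"]["sem_nm"] == 0.0

    def test_inverted_ring_rejected_with_id(self):
        rings = pd.DataFrame({"tubule_id": ["ok", "bad"],
                              "inner_nm": [10.0, 25.0], "outer_nm": [20.0, 24.0]})
        with pytest.raises(InvalidMeasurementError, match="bad"):
            summarize_rings(rings)

    def test_synthetic_normal_rings_recovered_within_3_sem(self):
        rng = np.random.default_rng(31)
        n = 80
        inner = rng.normal(12.0, 1.0, n)
        outer = rng.normal(22.3, 2.1, n)
        outer = np.maximum(outer, inner + 0.5)
        rings = pd.DataFrame({"tubule_id": [f"t{i}" for i in range(n)],
                              "inner_nm": inner, "outer_nm": outer})
        out = summarize_rings(rings)
        assert abs(out["inner"]["mean_nm"] - 12.0) < 3 * out["inner"]["sem_nm"]
        assert abs(out["outer"]["mean_nm"] - 22.3) < 3 * out["outer"]["sem_nm"]
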