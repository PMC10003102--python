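"""Synthetic measurement generators with known ground truth.

Every input the analysis stages consume can be generated here with the
corresponding truth table, so each estimator can be validated by round trip:
simulate -> analyse -> compare with truth.  The sphere-sectioning generator
doubles as the Monte Carlo oracle for the stereology correction: it forward
models random slab sectioning of a sphere population, including the
size-biased intersection probability that real thin sections have (a larger
sphere is more likely to be cut by a given slab).

All randomness derives from a single integer seed via named substreams, one
per generator, so adding a generator never perturbs the draws of another.

Units: sphere/EM quantities in nm, rod/string lengths in µm, times in s.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .errors import ConfigError

__all__ = [
    "SpherePopulationSpec",
    "RodPopulationSpec",
    "PhSceneSpec",
    "ExoSceneSpec",
    "StringSceneSpec",
    "substream",
    "section_profile_radius",
    "generate_section_profiles",
    "generate_rod_lengths",
    "generate_ph_measurements",
    "generate_fusion_events",
    "generate_strings",
    "rasterize_strings",
]


def substream(seed: int, name: str) -> np.random.Generator:
    """Independent generator derived from (seed, generator name).

    The name is hashed with crc32 so streams are stable across sessions and
    independent of dictionary order or the set of other generators.
    """
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(name.encode())])
    )


# ---------------------------------------------------------------------------
# Sphere sectioning (stereology forward model / oracle)
# ---------------------------------------------------------------------------

@dataclass
class SpherePopulationSpec:
    """Population of spherical organelles sectioned by random EM slabs.

    diameter_model 'fixed' uses ``diameter_nm`` for every sphere;
    'lognormal' draws diameters with the given median (nm) and log-space sd;
    'mixture' draws from the discrete sizes ``mixture_diameters_nm`` with
    probabilities ``mixture_weights`` (two-point mixtures exercise the
    size-biased sampling oracle).
    ``section_thickness_nm`` is the slab thickness t; a sphere of radius R is
    cut when the slab centre lies within R + t/2 of the sphere centre, which
    makes intersection probability proportional to (2R + t).
    ``axis_jitter_sd`` is the log-space sd of independent multiplicative
    perturbations applied to the two profile axes, emulating non-spherical
    profiles for the sphericity filter.
    """

    n_spheres: int
    diameter_model: str = "fixed"
    diameter_nm: float = 300.0
    diameter_median_nm: float = 300.0
    diameter_sigma_log: float = 0.2
    mixture_diameters_nm: tuple = (200.0, 400.0)
    mixture_weights: tuple = (0.5, 0.5)
    section_thickness_nm: float = 60.0
    axis_jitter_sd: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_spheres <= 0:
            raise ConfigError(f"n_spheres must be > 0, got {self.n_spheres}")
        if self.diameter_model not in ("fixed", "lognormal", "mixture"):
            raise ConfigError(
                "diameter_model must be 'fixed', 'lognormal' or 'mixture', "
                f"got {self.diameter_model!r}"
            )
        if self.diameter_model == "mixture":
            if len(self.mixture_diameters_nm) != len(self.mixture_weights):
                raise ConfigError("mixture diameters and weights differ in length")
            if any(d <= 0 for d in self.mixture_diameters_nm):
                raise ConfigError("mixture diameters must be > 0")
            if any(w < 0 for w in self.mixture_weights) or sum(self.mixture_weights) <= 0:
                raise ConfigError("mixture weights must be non-negative and sum > 0")
        if self.diameter_model == "fixed" and not self.diameter_nm > 0:
            raise ConfigError(f"diameter_nm must be > 0, got {self.diameter_nm}")
        if self.diameter_model == "lognormal" and not self.diameter_median_nm > 0:
            raise ConfigError(
                f"diameter_median_nm must be > 0, got {self.diameter_median_nm}"
            )
        if self.section_thickness_nm < 0:
            raise ConfigError(
                f"section_thickness_nm must be >= 0, got {self.section_thickness_nm}"
            )
        if self.axis_jitter_sd < 0:
            raise ConfigError(f"axis_jitter_sd must be >= 0, got {self.axis_jitter_sd}")


def section_profile_radius(
    radius_nm: np.ndarray, z_offset_nm: np.ndarray, thickness_nm: float
) -> np.ndarray:
    """Radius of the circle a slab of given thickness projects from a sphere.

    ``z_offset_nm`` is the signed distance from sphere centre to slab centre.
    Within the slab the largest cut circle dominates the projection, so the
    effective distance from the equator is d = max(0, |z| - t/2) and the
    profile radius is sqrt(R^2 - d^2).  Offsets beyond R + t/2 miss the
    sphere and yield NaN.
    """
    radius_nm = np.asarray(radius_nm, dtype=float)
    z = np.abs(np.asarray(z_offset_nm, dtype=float))
    d = np.maximum(0.0, z - thickness_nm / 2.0)
    with np.errstate(invalid="ignore"):
        r = np.sqrt(radius_nm**2 - d**2)
    return np.where(z <= radius_nm + thickness_nm / 2.0, r, np.nan)


def generate_section_profiles(
    spec: SpherePopulationSpec,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Forward model of EM thin-sectioning of a sphere population.

    Each sphere receives a slab at a uniform random depth spanning the
    largest possible intersection range of the population; spheres the slab
    misses emit no profile (this reproduces size-biased sampling).  Returns
    ``(profiles, truth)`` where profiles has columns profile_id, cell_id,
    group, long_axis_nm, short_axis_nm and truth carries the true diameter
    and slab offset per emitted profile.
    """
    spec.validate()
    rng = substream(spec.seed, "sections")
    t = spec.section_thickness_nm

    if spec.diameter_model == "fixed":
        diameters = np.full(spec.n_spheres, float(spec.diameter_nm))
    elif spec.diameter_model == "lognormal":
        diameters = spec.diameter_median_nm * np.exp(
            rng.normal(0.0, spec.diameter_sigma_log, spec.n_spheres)
        )
    else:
        weights = np.asarray(spec.mixture_weights, dtype=float)
        diameters = rng.choice(
            np.asarray(spec.mixture_diameters_nm, dtype=float),
            size=spec.n_spheres,
            p=weights / weights.sum(),
        )
    radii = diameters / 2.0

    # Slab centre depth uniform over the widest intersection interval of the
    # population; P(cut sphere i) = (D_i + t) / (D_max + t), conditional
    # offset uniform over [-(R_i + t/2), R_i + t/2].
    half_span = radii.max() + t / 2.0
    z = rng.uniform(-half_span, half_span, spec.n_spheres)
    hit = np.abs(z) <= radii + t / 2.0

    r_profile = section_profile_radius(radii[hit], z[hit], t)
    apparent = 2.0 * r_profile

    if spec.axis_jitter_sd > 0:
        jitter = np.exp(rng.normal(0.0, spec.axis_jitter_sd, (hit.sum(), 2)))
    else:
        jitter = np.ones((int(hit.sum()), 2))
    axes = apparent[:, None] * jitter
    long_axis = axes.max(axis=1)
    short_axis = axes.min(axis=1)

    ids = [f"p{i:06d}" for i in range(int(hit.sum()))]
    profiles = pd.DataFrame(
        {
            "profile_id": ids,
            "cell_id": "sim",
            "group": "synthetic",
            "long_axis_nm": long_axis,
            "short_axis_nm": short_axis,
        }
    )
    truth = pd.DataFrame(
        {
            "profile_id": ids,
            "true_diameter_nm": diameters[hit],
            "z_offset_nm": z[hit],
            "section_thickness_nm": t,
        }
    )
    return profiles, truth


# ---------------------------------------------------------------------------
# Rod lengths (confocal forward model)
# ---------------------------------------------------------------------------

@dataclass
class RodPopulationSpec:
    """Rod-shaped organelle population; lengths are measured directly from
    confocal images so no sectioning model is applied."""

    n_rods: int
    length_median_um: float = 1.0
    length_sigma_log: float = 0.3
    diameter_nm: float = 150.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_rods <= 0:
            raise ConfigError(f"n_rods must be > 0, got {self.n_rods}")
        if not self.length_median_um > 0:
            raise ConfigError(f"length_median_um must be > 0, got {self.length_median_um}")
        if self.length_sigma_log < 0:
            raise ConfigError(f"length_sigma_log must be >= 0, got {self.length_sigma_log}")
        if not self.diameter_nm > 0:
            raise ConfigError(f"diameter_nm must be > 0, got {self.diameter_nm}")


def generate_rod_lengths(spec: RodPopulationSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw rod lengths from a lognormal model; returns (rods, truth)."""
    spec.validate()
    rng = substream(spec.seed, "rods")
    lengths = spec.length_median_um * np.exp(
        rng.normal(0.0, spec.length_sigma_log, spec.n_rods)
    )
    ids = [f"r{i:06d}" for i in range(spec.n_rods)]
    rods = pd.DataFrame(
        {
            "wpb_id": ids,
            "cell_id": "sim",
            "group": "synthetic",
            "length_um": lengths,
        }
    )
    truth = pd.DataFrame(
        {
            "wpb_id": ids,
            "true_length_um": lengths,
            "true_diameter_nm": spec.diameter_nm,
        }
    )
    return rods, truth


# ---------------------------------------------------------------------------
# Luminal pH sensor fluorescence
# ---------------------------------------------------------------------------

@dataclass
class PhSceneSpec:
    """Organelles with a luminal pH sensor, imaged at rest and after an
    alkalinizing NH4Cl step that clamps the lumen to the reference pH."""

    n_organelles: int
    true_ph_mean: float = 5.41
    true_ph_sd: float = 0.2
    pka: float = 6.0
    hill_n: float = 1.0
    ph_ref: float = 7.4
    noise_sd: float = 0.01         # relative fluorescence noise
    scale_au: float = 1000.0       # per-organelle brightness scale (a.u.)
    nh4cl_time_s: float = 60.0
    trace_dt_s: float = 0.5
    trace_duration_s: float = 90.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_organelles <= 0:
            raise ConfigError(f"n_organelles must be > 0, got {self.n_organelles}")
        if not (3.0 < self.true_ph_mean < 9.0):
            raise ConfigError(f"true_ph_mean must be in (3, 9), got {self.true_ph_mean}")
        if self.true_ph_sd < 0:
            raise ConfigError(f"true_ph_sd must be >= 0, got {self.true_ph_sd}")
        if self.noise_sd < 0:
            raise ConfigError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if not (0 < self.nh4cl_time_s < self.trace_duration_s):
            raise ConfigError(
                "nh4cl_time_s must lie inside the trace duration "
                f"({self.nh4cl_time_s} vs {self.trace_duration_s})"
            )


def _hill_fluorescence(ph: np.ndarray, pka: float, hill_n: float) -> np.ndarray:
    return 1.0 / (1.0 + 10.0 ** (hill_n * (pka - np.asarray(ph, dtype=float))))


def generate_ph_measurements(
    spec: PhSceneSpec,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate rest/max sensor fluorescence per organelle plus step traces.

    Returns ``(measurements, traces, truth)``.  Measurements carry f_rest,
    f_max, f_background per organelle; traces are long-format
    (organelle_id, time_s, fluorescence) with the NH4Cl step at
    ``nh4cl_time_s``; truth holds the true pH per organelle.
    """
    spec.validate()
    rng = substream(spec.seed, "ph")
    n = spec.n_organelles
    true_ph = rng.normal(spec.true_ph_mean, spec.true_ph_sd, n)
    true_ph = np.clip(true_ph, 3.01, 8.99)

    f_rest_clean = _hill_fluorescence(true_ph, spec.pka, spec.hill_n) * spec.scale_au
    f_max_clean = (
        _hill_fluorescence(np.full(n, spec.ph_ref), spec.pka, spec.hill_n)
        * spec.scale_au
    )
    noise = spec.noise_sd * spec.scale_au
    f_rest = f_rest_clean + rng.normal(0.0, noise, n) if noise else f_rest_clean.copy()
    f_max = f_max_clean + rng.normal(0.0, noise, n) if noise else f_max_clean.copy()

    ids = [f"o{i:05d}" for i in range(n)]
    measurements = pd.DataFrame(
        {
            "organelle_id": ids,
            "cell_id": "sim",
            "group": "synthetic",
            "f_rest": f_rest,
            "f_max": f_max,
            "f_background": 0.0,
        }
    )

    time = np.arange(0.0, spec.trace_duration_s + spec.trace_dt_s / 2, spec.trace_dt_s)
    step = time >= spec.nh4cl_time_s
    frames = []
    for i, oid in enumerate(ids):
        clean = np.where(step, f_max_clean[i], f_rest_clean[i])
        trace = clean + (rng.normal(0.0, noise, time.size) if noise else 0.0)
        frames.append(
            pd.DataFrame({"organelle_id": oid, "time_s": time, "fluorescence": trace})
        )
    traces = pd.concat(frames, ignore_index=True)

    truth = pd.DataFrame({"organelle_id": ids, "true_ph": true_ph})
    return measurements, traces, truth


# ---------------------------------------------------------------------------
# Fusion-event streams + Ca2+ traces
# ---------------------------------------------------------------------------

@dataclass
class ExoSceneSpec:
    """Histamine-style stimulation: a Ca2+ rise at ``onset_time_s`` followed,
    after a per-cell latency, by Poisson fusion events drawn from a
    releasable pool (releasable_fraction of the cell's labelled organelles)."""

    n_cells: int = 11
    total_wpb_mean: float = 100.0
    onset_time_s: float = 10.0
    latency_mean_s: float = 2.6
    latency_sd_s: float = 0.5
    rate_per_s: float = 4.0
    releasable_fraction: float = 0.2
    trace_dt_s: float = 0.2
    # 45 s at a 10 s onset keeps the default onset-detection baseline
    # (first 20% of the trace) clear of the stimulus
    trace_duration_s: float = 45.0
    ca_baseline: float = 0.5
    ca_amplitude: float = 1.0
    ca_noise_sd: float = 0.0
    dose_um: float = 100.0
    group: str = "synthetic"
    seed: int = 0

    def validate(self) -> None:
        if self.n_cells <= 0:
            raise ConfigError(f"n_cells must be > 0, got {self.n_cells}")
        if self.onset_time_s < 0:
            raise ConfigError(f"onset_time_s must be >= 0, got {self.onset_time_s}")
        if not (0.0 <= self.releasable_fraction <= 1.0):
            raise ConfigError(
                f"releasable_fraction must be in [0, 1], got {self.releasable_fraction}"
            )
        if self.rate_per_s < 0:
            raise ConfigError(f"rate_per_s must be >= 0, got {self.rate_per_s}")
        if self.total_wpb_mean <= 0:
            raise ConfigError(f"total_wpb_mean must be > 0, got {self.total_wpb_mean}")


def generate_fusion_events(
    spec: ExoSceneSpec,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate per-cell fusion-event streams and Ca2+ indicator traces.

    Returns ``(events, cells, traces, truth)``:

    - events: cell_id, event_time_s (one row per fusion event)
    - cells: cell_id, group, dose_um, total_wpb
    - traces: cell_id, time_s, ratio (sigmoid Ca2+ rise at onset)
    - truth: per-cell true onset, latency, rate, releasable fraction
    """
    spec.validate()
    rng = substream(spec.seed, "events")
    time = np.arange(0.0, spec.trace_duration_s + spec.trace_dt_s / 2, spec.trace_dt_s)

    event_rows, cell_rows, trace_frames, truth_rows = [], [], [], []
    for i in range(spec.n_cells):
        cid = f"c{i:03d}"
        total = max(1, int(np.round(rng.poisson(spec.total_wpb_mean))))
        latency = max(0.0, rng.normal(spec.latency_mean_s, spec.latency_sd_s))
        n_releasable = int(np.round(spec.releasable_fraction * total))

        times = []
        if spec.rate_per_s > 0 and n_releasable > 0:
            gaps = rng.exponential(1.0 / spec.rate_per_s, n_releasable)
            arrivals = spec.onset_time_s + latency + np.cumsum(gaps)
            times = arrivals[arrivals < spec.trace_duration_s]
        for t_ev in times:
            event_rows.append((cid, float(t_ev)))

        cell_rows.append((cid, spec.group, spec.dose_um, total))

        # Ca2+ rise begins exactly at the stimulation onset: saturating
        # exponential (tau 0.3 s, ~0.7 s 10-90%) from the baseline.
        dt_on = np.maximum(0.0, time - spec.onset_time_s)
        ratio = spec.ca_baseline + spec.ca_amplitude * (
            1.0 - np.exp(-dt_on / 0.3)
        ) * (time >= spec.onset_time_s)
        if spec.ca_noise_sd > 0:
            ratio = ratio + rng.normal(0.0, spec.ca_noise_sd, time.size)
        trace_frames.append(pd.DataFrame({"cell_id": cid, "time_s": time, "ratio": ratio}))

        truth_rows.append(
            (cid, spec.onset_time_s, latency, spec.rate_per_s,
             spec.releasable_fraction, total, len(times))
        )

    events = pd.DataFrame(event_rows, columns=["cell_id", "event_time_s"])
    cells = pd.DataFrame(cell_rows, columns=["cell_id", "group", "dose_um", "total_wpb"])
    traces = pd.concat(trace_frames, ignore_index=True)
    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "cell_id", "true_onset_s", "true_latency_s", "true_rate_per_s",
            "true_releasable_fraction", "total_wpb", "n_events",
        ],
    )
    return events, cells, traces, truth


# ---------------------------------------------------------------------------
# VWF string polylines + platelets
# ---------------------------------------------------------------------------

@dataclass
class StringSceneSpec:
    """Tortuous extracellular VWF strings as persistent random walks with
    Poisson-placed platelets along their arc length."""

    n_strings: int
    length_median_um: float = 60.0
    length_sigma_log: float = 0.4
    step_length_um: float = 0.5
    turn_angle_sd: float = 0.15     # radians per step
    platelet_density_per_um: float = 0.2
    seed: int = 0

    def validate(self) -> None:
        if self.n_strings <= 0:
            raise ConfigError(f"n_strings must be > 0, got {self.n_strings}")
        if not self.length_median_um > 0:
            raise ConfigError(f"length_median_um must be > 0, got {self.length_median_um}")
        if not self.step_length_um > 0:
            raise ConfigError(f"step_length_um must be > 0, got {self.step_length_um}")
        if self.turn_angle_sd < 0:
            raise ConfigError(f"turn_angle_sd must be >= 0, got {self.turn_angle_sd}")
        if self.platelet_density_per_um < 0:
            raise ConfigError(
                f"platelet_density_per_um must be >= 0, got {self.platelet_density_per_um}"
            )


def generate_strings(
    spec: StringSceneSpec,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate string polylines, metadata, platelet positions and truth.

    Returns ``(points, meta, platelets, truth)`` in the CSV schemas the
    string-morphometry stage reads: points (string_id, point_index, x_um,
    y_um), meta (string_id, field_id, group), platelets (string_id,
    position_um), truth (string_id, true_length_um, n_platelets).
    """
    spec.validate()
    rng = substream(spec.seed, "strings")

    point_rows, meta_rows, platelet_rows, truth_rows = [], [], [], []
    for i in range(spec.n_strings):
        sid = f"s{i:05d}"
        target = spec.length_median_um * np.exp(rng.normal(0.0, spec.length_sigma_log))
        n_steps = max(1, int(np.round(target / spec.step_length_um)))
        true_len = n_steps * spec.step_length_um

        headings = np.cumsum(
            np.concatenate(
                [[rng.uniform(0, 2 * np.pi)],
                 rng.normal(0.0, spec.turn_angle_sd, n_steps - 1)]
            )
        )
        dx = spec.step_length_um * np.cos(headings)
        dy = spec.step_length_um * np.sin(headings)
        x = np.concatenate([[0.0], np.cumsum(dx)])
        y = np.concatenate([[0.0], np.cumsum(dy)])
        for j in range(n_steps + 1):
            point_rows.append((sid, j, x[j], y[j]))

        n_platelets = rng.poisson(spec.platelet_density_per_um * true_len)
        positions = np.sort(rng.uniform(0.0, true_len, n_platelets))
        for pos in positions:
            platelet_rows.append((sid, float(pos)))

        meta_rows.append((sid, "f000", "synthetic"))
        truth_rows.append((sid, true_len, int(n_platelets)))

    points = pd.DataFrame(point_rows, columns=["string_id", "point_index", "x_um", "y_um"])
    meta = pd.DataFrame(meta_rows, columns=["string_id", "field_id", "group"])
    platelets = pd.DataFrame(platelet_rows, columns=["string_id", "position_um"])
    truth = pd.DataFrame(truth_rows, columns=["string_id", "true_length_um", "n_platelets"])
    return points, meta, platelets, truth


def rasterize_strings(
    points: pd.DataFrame, raster_scale_um_per_px: float, pad_px: int = 4
) -> np.ndarray:
    """Binary raster of string polylines at the given pixel size (µm/px).

    Coordinates use the raster convention (origin top-left, y down); the
    image is padded so no string touches the border.
    """
    from skimage.draw import line as draw_line

    if raster_scale_um_per_px <= 0:
        raise ConfigError(
            f"raster_scale_um_per_px must be > 0, got {raster_scale_um_per_px}"
        )
    x = points["x_um"].to_numpy() / raster_scale_um_per_px
    y = points["y_um"].to_numpy() / raster_scale_um_per_px
    col = np.round(x - x.min()).astype(int) + pad_px
    row = np.round(y - y.min()).astype(int) + pad_px
    img = np.zeros((row.max() + pad_px + 1, col.max() + pad_px + 1), dtype=bool)
    for sid, grp in points.assign(_row=row, _col=col).groupby("string_id", sort=False):
        r = grp["_row"].to_numpy()
        c = grp["_col"].to_numpy()
        for k in range(len(r) - 1):
            rr, cc = draw_line(r[k], c[k], r[k + 1], c[k + 1])
            img[rr, cc] = True
    return img
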