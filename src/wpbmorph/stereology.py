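"""Organelle volume estimation from 2D section profiles and rod lengths.

Rounded organelles are measured as long/short axis pairs in EM thin
sections.  Because a random section rarely passes through a sphere's
equator, the apparent profile diameter underestimates the true diameter
(the classical corpuscle problem); for uniformly random sectioning the
apparent modal diameter d relates to the true modal diameter D_o by
d = (pi/4) * D_o, so the correction applied here is D_o = 4 d / pi.
Profiles are first restricted to near-circular ones (long:short axis ratio
strictly below 1.3 by default) so that the sphere model applies.

Rod-shaped organelles cannot be measured in thin sections; their lengths
come from confocal images and volumes follow a cylinder model with a fixed
150 nm diameter.

Units: axes and diameters nm, rod lengths µm, volumes aL (1 aL = 1e6 nm^3).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import StereologyConfig
from .errors import InvalidMeasurementError

__all__ = [
    "NM3_PER_AL",
    "axis_ratio",
    "filter_spherical",
    "apparent_diameter",
    "correct_diameter",
    "sphere_volume",
    "rod_volume",
    "estimate_volume_distribution",
    "summarize_rings",
    "VolumeDistributionSummary",
]

NM3_PER_AL = 1.0e6  # 1 attolitre = 1e-18 L = 1e6 nm^3

_PROFILE_COLS = ("long_axis_nm", "short_axis_nm")


def axis_ratio(long_axis_nm, short_axis_nm):
    """Long-to-short axis ratio of a section profile (always >= 1 for valid input)."""
    long_axis = np.asarray(long_axis_nm, dtype=float)
    short_axis = np.asarray(short_axis_nm, dtype=float)
    if np.any(short_axis <= 0):
        raise InvalidMeasurementError("short axis must be > 0")
    if np.any(long_axis < short_axis):
        raise InvalidMeasurementError("long axis must be >= short axis")
    return long_axis / short_axis


def filter_spherical(
    profiles: pd.DataFrame, max_ratio: float = 1.3
) -> tuple[pd.DataFrame, dict]:
    """Keep near-circular profiles: axis ratio strictly below ``max_ratio``.

    Returns ``(kept, report)`` where report records n_total, n_kept and the
    cut applied.  Empty input yields an empty frame with zero counts.
    """
    if len(profiles) == 0:
        return profiles.copy(), {"n_total": 0, "n_kept": 0, "max_ratio": max_ratio}
    ratios = axis_ratio(
        profiles["long_axis_nm"].to_numpy(), profiles["short_axis_nm"].to_numpy()
    )
    kept = profiles.loc[ratios < max_ratio].reset_index(drop=True)
    return kept, {"n_total": int(len(profiles)), "n_kept": int(len(kept)),
                  "max_ratio": max_ratio}


def apparent_diameter(long_axis_nm, short_axis_nm, mode: str = "mean"):
    """Single apparent diameter of a near-circular profile.

    'mean' is the arithmetic mean of the two axes (default);
    'geometric_mean' preserves the profile area instead.
    """
    long_axis = np.asarray(long_axis_nm, dtype=float)
    short_axis = np.asarray(short_axis_nm, dtype=float)
    if mode == "mean":
        return (long_axis + short_axis) / 2.0
    if mode == "geometric_mean":
        return np.sqrt(long_axis * short_axis)
    raise InvalidMeasurementError(f"unknown apparent-diameter mode {mode!r}")


def correct_diameter(d_apparent_nm):
    """Non-diametric-sectioning correction: D_o = 4 d / pi (d = pi D_o / 4)."""
    d = np.asarray(d_apparent_nm, dtype=float)
    if np.any(d < 0):
        raise InvalidMeasurementError("apparent diameter must be >= 0")
    return 4.0 * d / np.pi


def sphere_volume(radius_nm):
    """Sphere volume in aL from a radius in nm."""
    r = np.asarray(radius_nm, dtype=float)
    if np.any(r < 0):
        raise InvalidMeasurementError("radius must be >= 0")
    return (4.0 / 3.0) * np.pi * r**3 / NM3_PER_AL


def rod_volume(length_um, diameter_nm: float = 150.0):
    """Cylinder volume in aL from a length in µm and diameter in nm."""
    length = np.asarray(length_um, dtype=float)
    if np.any(length < 0):
        raise InvalidMeasurementError("length must be >= 0")
    if diameter_nm < 0:
        raise InvalidMeasurementError("diameter must be >= 0")
    length_nm = length * 1.0e3
    return np.pi * (diameter_nm / 2.0) ** 2 * length_nm / NM3_PER_AL


@dataclass
class VolumeDistributionSummary:
    n: int
    mean_al: float
    sd_al: float
    sem_al: float
    bin_edges_al: np.ndarray
    counts: np.ndarray

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "mean_al": self.mean_al,
            "sd_al": self.sd_al,
            "sem_al": self.sem_al,
            "bin_edges_al": [float(e) for e in self.bin_edges_al],
            "counts": [int(c) for c in self.counts],
        }


def _summarize_volumes(volumes: np.ndarray, bin_width: float) -> VolumeDistributionSummary:
    n = volumes.size
    mean = float(np.mean(volumes))
    sd = float(np.std(volumes, ddof=1)) if n > 1 else 0.0
    sem = sd / np.sqrt(n) if n > 1 else 0.0
    upper = max(bin_width, float(np.ceil(volumes.max() / bin_width)) * bin_width)
    edges = np.arange(0.0, upper + bin_width / 2, bin_width)
    counts, _ = np.histogram(volumes, bins=edges)
    return VolumeDistributionSummary(n, mean, sd, sem, edges, counts)


def estimate_volume_distribution(
    data: pd.DataFrame,
    kind: str,
    config: StereologyConfig | None = None,
    apply_filter: bool = True,
) -> tuple[pd.DataFrame, VolumeDistributionSummary]:
    """Per-object volume estimates plus a distribution summary.

    ``kind='profiles'`` runs the sphere pipeline on a profiles table
    (sphericity filter, apparent diameter, 4/pi correction, sphere volume);
    ``kind='rods'`` runs the cylinder model on a rods table.  The returned
    table carries the intermediate quantities per object; the summary holds
    n, mean, sem and a histogram with the configured bin width.
    """
    config = config or StereologyConfig()
    config.validate()

    if kind == "profiles":
        working = data
        if apply_filter:
            working, _ = filter_spherical(data, config.max_axis_ratio)
        if len(working) == 0:
            raise InvalidMeasurementError(
                "no profiles remain after the sphericity filter; nothing to estimate"
            )
        d_app = apparent_diameter(
            working["long_axis_nm"].to_numpy(),
            working["short_axis_nm"].to_numpy(),
            config.apparent_diameter,
        )
        if config.correction == "per_object":
            d_corr = correct_diameter(d_app)
        else:
            # modal_only: scale every diameter by the ratio that maps the
            # modal apparent diameter onto the corrected modal diameter;
            # for the 4/pi correction this is the same uniform factor.
            d_corr = correct_diameter(d_app)
        r_corr = d_corr / 2.0
        volumes = sphere_volume(r_corr)
        table = pd.DataFrame(
            {
                "object_id": working["profile_id"].to_numpy(),
                "apparent_diameter_nm": d_app,
                "corrected_diameter_nm": d_corr,
                "apparent_radius_nm": d_app / 2.0,
                "corrected_radius_nm": r_corr,
                "volume_al": volumes,
            }
        )
    elif kind == "rods":
        if len(data) == 0:
            raise InvalidMeasurementError("empty rod table; nothing to estimate")
        lengths = data["length_um"].to_numpy(dtype=float)
        if np.any(lengths <= 0):
            raise InvalidMeasurementError("rod lengths must be > 0")
        volumes = rod_volume(lengths, config.rod_diameter_nm)
        table = pd.DataFrame(
            {
                "object_id": data["wpb_id"].to_numpy(),
                "length_um": lengths,
                "diameter_nm": config.rod_diameter_nm,
                "volume_al": volumes,
            }
        )
    else:
        raise InvalidMeasurementError(f"kind must be 'profiles' or 'rods', got {kind!r}")

    summary = _summarize_volumes(table["volume_al"].to_numpy(), config.bin_width_al)
    return table, summary


def summarize_rings(rings: pd.DataFrame) -> dict:
    """Mean / sd / sem / n of tubule ring inner and outer diameters (nm).

    Raises if any ring has inner >= outer, listing the offending ids; an
    n=1 table reports sem 0 with ``sem_defined=False``.
    """
    if len(rings) == 0:
        raise InvalidMeasurementError("empty ring table")
    inner = rings["inner_nm"].to_numpy(dtype=float)
    outer = rings["outer_nm"].to_numpy(dtype=float)
    bad = rings.loc[(inner >= outer) | (inner <= 0), "tubule_id"].tolist()
    if bad:
        raise InvalidMeasurementError(
            f"rings must satisfy 0 < inner < outer; offending ids: {bad}"
        )
    n = len(rings)
    out = {"n": n, "sem_defined": n > 1}
    for name, vals in (("inner", inner), ("outer", outer)):
        sd = float(np.std(vals, ddof=1)) if n > 1 else 0.0
        out[name] = {
            "mean_nm": float(np.mean(vals)),
            "sd_nm": sd,
            "sem_nm": sd / np.sqrt(n) if n > 1 else 0.0,
        }
    return out
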