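"""Intra-organelle pH inference from pH-sensor fluorescence.

A luminal GFP-family sensor is quenched at acidic pH following a
single-protonation (Hill) curve

    f(pH) = 1 / (1 + 10^(n * (pKa - pH)))

The measurement protocol records each organelle's steady-state fluorescence
F_rest and the maximal fluorescence F_max reached after acute application of
the weak base NH4Cl, which collapses the pH gradient and clamps the lumen
near the reference pH (default 7.4).  The background-corrected ratio
F_rest/F_max = f(pH)/f(pH_ref) is then inverted for the resting luminal pH.

Calibration constants (pKa, Hill n, pH_ref) are configurable inputs with
canonical eGFP defaults; they are echoed into all output metadata.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .config import PhCalibration, PhConfig
from .errors import ConfigError, InvalidMeasurementError, OutOfRangeError, WindowingError

__all__ = [
    "relative_fluorescence",
    "rest_to_max_ratio",
    "estimate_ph",
    "extract_rest_and_max",
    "ph_dataset",
]


def relative_fluorescence(ph, calib: PhCalibration | None = None):
    """Relative sensor fluorescence f(pH) in (0, 1) under the Hill model."""
    calib = calib or PhCalibration()
    calib.validate()
    ph = np.asarray(ph, dtype=float)
    return 1.0 / (1.0 + 10.0 ** (calib.hill_n * (calib.pka - ph)))


def rest_to_max_ratio(f_rest, f_max, f_background=0.0):
    """Background-corrected rest/max fluorescence ratio."""
    f_rest = np.asarray(f_rest, dtype=float)
    f_max = np.asarray(f_max, dtype=float)
    f_background = np.asarray(f_background, dtype=float)
    if np.any(f_max <= f_background):
        raise InvalidMeasurementError("f_max must exceed f_background")
    if np.any(f_rest <= f_background):
        raise InvalidMeasurementError("f_rest must exceed f_background")
    return (f_rest - f_background) / (f_max - f_background)


def ratio_upper_bound(calib: PhCalibration) -> float:
    """Supremum of admissible rest/max ratios: 1 / f(pH_ref)."""
    return float(1.0 / relative_fluorescence(calib.ph_ref, calib))


def estimate_ph(ratio, calib: PhCalibration | None = None):
    """Invert the rest/max ratio for luminal pH.

    ratio = f(pH)/f(pH_ref) implies
    pH = pKa - (1/n) * log10((1 + 10^(n (pKa - pH_ref))) / ratio - 1).
    The ratio must lie strictly inside (0, 1/f(pH_ref)).
    """
    calib = calib or PhCalibration()
    calib.validate()
    ratio = np.asarray(ratio, dtype=float)
    upper = ratio_upper_bound(calib)
    if np.any(ratio <= 0) or np.any(ratio >= upper):
        raise OutOfRangeError(
            f"ratio must lie in the open interval (0, {upper:.6g}); "
            "values at or beyond the bound have no finite pH under the model"
        )
    inner = (1.0 + 10.0 ** (calib.hill_n * (calib.pka - calib.ph_ref))) / ratio - 1.0
    return calib.pka - np.log10(inner) / calib.hill_n


def extract_rest_and_max(
    time_s: np.ndarray,
    fluorescence: np.ndarray,
    nh4cl_time_s: float,
    config: PhConfig | None = None,
) -> tuple[float, float]:
    """F_rest and F_max from a fluorescence time trace.

    F_rest is the mean over the last ``rest_window_s`` seconds before NH4Cl
    application; F_max is the maximum of the boxcar-smoothed post-application
    segment (smoothing resists single-sample noise spikes).
    """
    config = config or PhConfig()
    config.validate()
    time_s = np.asarray(time_s, dtype=float)
    fluorescence = np.asarray(fluorescence, dtype=float)

    pre = (time_s >= nh4cl_time_s - config.rest_window_s) & (time_s < nh4cl_time_s)
    post = time_s >= nh4cl_time_s
    if not pre.any():
        raise WindowingError(
            f"no samples in the pre-application window "
            f"[{nh4cl_time_s - config.rest_window_s}, {nh4cl_time_s})"
        )
    if not post.any():
        raise WindowingError(f"no samples at or after nh4cl_time = {nh4cl_time_s}")

    f_rest = float(np.mean(fluorescence[pre]))
    seg = fluorescence[post]
    w = min(config.smooth_samples, seg.size)
    smoothed = np.convolve(seg, np.ones(w) / w, mode="valid")
    f_max = float(np.max(smoothed))
    return f_rest, f_max


def ph_dataset(
    recs: pd.DataFrame,
    calib: PhCalibration | None = None,
    compare: bool = True,
) -> tuple[pd.DataFrame, dict]:
    """Per-organelle pH estimates plus group summaries and a two-group test.

    ``recs`` needs columns organelle_id, group, f_rest, f_max and optionally
    f_background.  Organelles whose ratio falls outside the admissible open
    interval are flagged (``qc_pass = False``) and excluded from summaries
    rather than clamped.  With exactly two groups (each n >= 2) a Welch
    t-test is reported; a requested comparison on fewer than two groups
    raises ConfigError.
    """
    calib = calib or PhCalibration()
    calib.validate()
    bg = recs["f_background"].to_numpy(dtype=float) if "f_background" in recs else 0.0
    ratio = rest_to_max_ratio(
        recs["f_rest"].to_numpy(dtype=float), recs["f_max"].to_numpy(dtype=float), bg
    )
    upper = ratio_upper_bound(calib)
    ok = (ratio > 0) & (ratio < upper)
    ph = np.full(ratio.shape, np.nan)
    if ok.any():
        ph[ok] = estimate_ph(ratio[ok], calib)

    table = pd.DataFrame(
        {
            "organelle_id": recs["organelle_id"].to_numpy(),
            "group": recs["group"].to_numpy() if "group" in recs else "all",
            "ratio": ratio,
            "ph": ph,
            "qc_pass": ok,
        }
    )

    summary: dict = {
        "calibration": {"pka": calib.pka, "hill_n": calib.hill_n, "ph_ref": calib.ph_ref},
        "n_excluded_qc": int((~ok).sum()),
        "groups": {},
    }
    usable = table.loc[table["qc_pass"]]
    for name, grp in usable.groupby("group"):
        vals = grp["ph"].to_numpy()
        n = vals.size
        sd = float(np.std(vals, ddof=1)) if n > 1 else 0.0
        summary["groups"][str(name)] = {
            "n": int(n),
            "mean_ph": float(np.mean(vals)),
            "sd_ph": sd,
            "sem_ph": sd / np.sqrt(n) if n > 1 else 0.0,
        }

    if compare:
        groups = list(usable.groupby("group"))
        if len(groups) != 2:
            raise ConfigError(
                f"two-group comparison requested but {len(groups)} group(s) present"
            )
        (name_a, a), (name_b, b) = groups
        if len(a) < 2 or len(b) < 2:
            raise ConfigError(
                "two-group comparison needs >= 2 organelles per group "
                f"(got {len(a)} in {name_a!r}, {len(b)} in {name_b!r})"
            )
        t, p = stats.ttest_ind(a["ph"], b["ph"], equal_var=False)
        summary["comparison"] = {
            "test": "welch_t",
            "groups": [str(name_a), str(name_b)],
            "statistic": float(t),
            "p_value": float(p),
        }
    return table, summary
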