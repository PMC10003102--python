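"""Pipeline configuration.

All stage parameters live in one validated container so that a single YAML
file (or the defaults) fully determines an analysis run.  Defaults follow the
conventions used throughout the package: EM lengths in nm, confocal lengths
in µm, volumes in attolitres (1 aL = 1e6 nm^3), times in seconds.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any, Mapping

import yaml

from .errors import ConfigError


@dataclass
class StereologyConfig:
    """Settings for the organelle volume estimators.

    max_axis_ratio
        Sphericity cut: profiles with long/short axis ratio >= this value
        are excluded (strict '<' keeps a profile).
    rod_diameter_nm
        Cylinder diameter assumed for rod-shaped organelles.
    correction
        'per_object' applies the 4/pi non-diametric-sectioning correction to
        every profile's apparent diameter; 'modal_only' corrects only the
        modal diameter of the population.
    apparent_diameter
        'mean' (arithmetic mean of the two axes) or 'geometric_mean'.
    bin_width_al
        Histogram bin width for volume distributions, in aL.
    """

    max_axis_ratio: float = 1.3
    rod_diameter_nm: float = 150.0
    correction: str = "per_object"
    apparent_diameter: str = "mean"
    bin_width_al: float = 2.0

    def validate(self) -> None:
        if not self.max_axis_ratio > 1.0:
            raise ConfigError(
                f"stereology.max_axis_ratio must be > 1, got {self.max_axis_ratio}"
            )
        if not self.rod_diameter_nm > 0:
            raise ConfigError(
                f"stereology.rod_diameter_nm must be > 0, got {self.rod_diameter_nm}"
            )
        if self.correction not in ("per_object", "modal_only"):
            raise ConfigError(
                f"stereology.correction must be 'per_object' or 'modal_only', got {self.correction!r}"
            )
        if self.apparent_diameter not in ("mean", "geometric_mean"):
            raise ConfigError(
                "stereology.apparent_diameter must be 'mean' or 'geometric_mean', "
                f"got {self.apparent_diameter!r}"
            )
        if not self.bin_width_al > 0:
            raise ConfigError(
                f"stereology.bin_width_al must be > 0, got {self.bin_width_al}"
            )


@dataclass
class PhCalibration:
    """Single-protonation (Hill) model of pH-sensor fluorescence.

    The fluorescence-vs-pH constants for the eGFP-based sensor are not part
    of this package's data; they are treated as configurable calibration
    inputs with canonical eGFP defaults (pKa 6.0, Hill coefficient 1.0) and
    a reference lumen pH of 7.4 assumed after the NH4Cl clamp.
    """

    pka: float = 6.0
    hill_n: float = 1.0
    ph_ref: float = 7.4

    def validate(self) -> None:
        if not (3.0 < self.pka < 9.0):
            raise ConfigError(f"ph.pka must be in (3, 9), got {self.pka}")
        if not self.hill_n > 0:
            raise ConfigError(f"ph.hill_n must be > 0, got {self.hill_n}")
        if not self.ph_ref > self.pka - 3.0:
            raise ConfigError(
                f"ph.ph_ref must exceed pka - 3 = {self.pka - 3.0}, got {self.ph_ref}"
            )


@dataclass
class PhConfig:
    """pH-inference settings: calibration constants plus trace windows."""

    calibration: PhCalibration = field(default_factory=PhCalibration)
    rest_window_s: float = 10.0       # pre-application averaging window
    smooth_samples: int = 3           # boxcar width for the post-NH4Cl maximum

    def validate(self) -> None:
        self.calibration.validate()
        if not self.rest_window_s > 0:
            raise ConfigError(f"ph.rest_window_s must be > 0, got {self.rest_window_s}")
        if self.smooth_samples < 1:
            raise ConfigError(f"ph.smooth_samples must be >= 1, got {self.smooth_samples}")


@dataclass
class KineticsConfig:
    """Exocytosis-kinetics settings.

    onset_k, onset_m
        Ca2+ onset = first time the indicator ratio exceeds baseline mean +
        onset_k * baseline sd for onset_m consecutive samples.
    baseline_fraction
        Fraction of the trace (from the start) used as baseline when no
        explicit window is given.
    rate_window_s
        Sliding-window width for the maximal exocytosis rate (WPB/s).
    delay_mode
        'first_event' (first post-onset event minus onset) or 'p5'
        (time to 5% of events).
    """

    onset_k: float = 5.0
    onset_m: int = 3
    baseline_fraction: float = 0.2
    rate_window_s: float = 1.0
    delay_mode: str = "first_event"

    def validate(self) -> None:
        if not self.onset_k > 0:
            raise ConfigError(f"kinetics.onset_k must be > 0, got {self.onset_k}")
        if self.onset_m < 1:
            raise ConfigError(f"kinetics.onset_m must be >= 1, got {self.onset_m}")
        if not (0 < self.baseline_fraction < 1):
            raise ConfigError(
                f"kinetics.baseline_fraction must be in (0, 1), got {self.baseline_fraction}"
            )
        if not self.rate_window_s > 0:
            raise ConfigError(
                f"kinetics.rate_window_s must be > 0, got {self.rate_window_s}"
            )
        if self.delay_mode not in ("first_event", "p5"):
            raise ConfigError(
                f"kinetics.delay_mode must be 'first_event' or 'p5', got {self.delay_mode!r}"
            )


@dataclass
class StringsConfig:
    """VWF string morphometry settings.

    min_length_um
        Minimum string length retained; strings *shorter* than this are
        excluded, so a string of exactly min_length_um is kept.
    density_mode
        'per_string' averages platelets/µm over strings; 'pooled' divides
        total platelets by total length.
    length_mode
        'arc' follows string curvature; 'chord' uses end-to-end distance.
    """

    min_length_um: float = 20.0
    density_mode: str = "per_string"
    length_mode: str = "arc"

    def validate(self) -> None:
        if self.min_length_um < 0:
            raise ConfigError(
                f"strings.min_length_um must be >= 0, got {self.min_length_um}"
            )
        if self.density_mode not in ("per_string", "pooled"):
            raise ConfigError(
                f"strings.density_mode must be 'per_string' or 'pooled', got {self.density_mode!r}"
            )
        if self.length_mode not in ("arc", "chord"):
            raise ConfigError(
                f"strings.length_mode must be 'arc' or 'chord', got {self.length_mode!r}"
            )


@dataclass
class PipelineConfig:
    """Validated configuration for the whole pipeline."""

    stereology: StereologyConfig = field(default_factory=StereologyConfig)
    ph: PhConfig = field(default_factory=PhConfig)
    kinetics: KineticsConfig = field(default_factory=KineticsConfig)
    strings: StringsConfig = field(default_factory=StringsConfig)
    seed: int = 0

    def validate(self) -> "PipelineConfig":
        self.stereology.validate()
        self.ph.validate()
        self.kinetics.validate()
        self.strings.validate()
        if not isinstance(self.seed, int) or self.seed < 0:
            raise ConfigError(f"seed must be a non-negative integer, got {self.seed!r}")
        return self

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "PipelineConfig":
        data = dict(data or {})
        unknown = set(data) - {"stereology", "ph", "kinetics", "strings", "seed"}
        if unknown:
            raise ConfigError(f"unknown config section(s): {sorted(unknown)}")

        def build(klass, section):
            payload = dict(data.get(section) or {})
            names = {f.name for f in dataclasses.fields(klass)}
            bad = set(payload) - names
            if bad:
                raise ConfigError(f"unknown key(s) in '{section}': {sorted(bad)}")
            return klass(**payload)

        ph_payload = dict(data.get("ph") or {})
        calib = PhCalibration(**dict(ph_payload.pop("calibration", {}) or {}))
        ph_names = {f.name for f in dataclasses.fields(PhConfig)} - {"calibration"}
        bad = set(ph_payload) - ph_names
        if bad:
            raise ConfigError(f"unknown key(s) in 'ph': {sorted(bad)}")
        cfg = cls(
            stereology=build(StereologyConfig, "stereology"),
            ph=PhConfig(calibration=calib, **ph_payload),
            kinetics=build(KineticsConfig, "kinetics"),
            strings=build(StringsConfig, "strings"),
            seed=int(data.get("seed", 0)),
        )
        return cfg.validate()

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            payload = yaml.safe_load(fh)
        return cls.from_dict(payload or {})
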