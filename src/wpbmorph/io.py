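"""Table schemas, validated CSV I/O, run manifests and the pipeline driver.

All tables are UTF-8 CSV with a header, '.' decimal and no thousands
separators; column names carry their unit as a suffix (_nm, _um, _s) so
nanometre and micrometre quantities cannot be confused.  String coordinates
are Cartesian µm in image space (origin top-left, y down).
"""

from __future__ import annotations

import hashlib
import json
import logging
from datetime import datetime, timezone
from importlib.metadata import PackageNotFoundError, version as _pkg_version
from pathlib import Path

import numpy as np
import pandas as pd

from . import ph as ph_mod
from . import kinetics as kin_mod
from . import stereology as stereo_mod
from . import strings as str_mod
from .config import PipelineConfig
from .errors import SchemaError, WpbMorphError

__all__ = ["SCHEMAS", "read_table", "write_table", "RunManifest", "run_pipeline"]

logger = logging.getLogger("wpbmorph")

#: schema name -> (required columns, unique-id column or None)
SCHEMAS: dict[str, tuple[tuple[str, ...], str | None]] = {
    "profiles": (("profile_id", "cell_id", "group", "long_axis_nm", "short_axis_nm"), "profile_id"),
    "rods": (("wpb_id", "cell_id", "group", "length_um"), "wpb_id"),
    "rings": (("tubule_id", "inner_nm", "outer_nm"), "tubule_id"),
    "ph_measurements": (("organelle_id", "cell_id", "group", "f_rest", "f_max"), "organelle_id"),
    "ph_traces": (("organelle_id", "time_s", "fluorescence"), None),
    "events": (("cell_id", "event_time_s"), None),
    "cells": (("cell_id", "group", "dose_um", "total_wpb"), "cell_id"),
    "ca_traces": (("cell_id", "time_s", "ratio"), None),
    "strings_points": (("string_id", "point_index", "x_um", "y_um"), None),
    "strings_meta": (("string_id", "field_id", "group"), "string_id"),
    "platelets": (("string_id", "position_um"), None),
}

_ID_COLUMNS = {"profile_id", "cell_id", "group", "wpb_id", "tubule_id",
               "organelle_id", "string_id", "field_id"}


def read_table(path, schema_name: str) -> pd.DataFrame:
    """Read and validate a CSV against a named schema.

    Extra columns are allowed; missing required columns, non-numeric cells
    in numeric columns, and duplicated unique ids raise SchemaError naming
    the offending column/id.
    """
    if schema_name not in SCHEMAS:
        raise SchemaError(f"unknown schema {schema_name!r}; know {sorted(SCHEMAS)}")
    required, unique_col = SCHEMAS[schema_name]
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"input file not found: {path}")
    # round_trip float parsing keeps write(read(x)) byte-stable
    table = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing required column(s) {missing}")
    for col in required:
        if col in _ID_COLUMNS:
            table[col] = table[col].astype(str)
            continue
        coerced = pd.to_numeric(table[col], errors="coerce")
        bad = coerced.isna() & table[col].notna()
        if bad.any():
            row = int(bad.idxmax())
            raise SchemaError(
                f"{path.name}: non-numeric value {table.loc[row, col]!r} "
                f"in column {col!r}, row {row}"
            )
        if coerced.isna().any():
            row = int(coerced.isna().idxmax())
            raise SchemaError(f"{path.name}: missing value in column {col!r}, row {row}")
        table[col] = coerced
    if unique_col is not None:
        dupes = table.loc[table[unique_col].duplicated(), unique_col].tolist()
        if dupes:
            raise SchemaError(f"{path.name}: duplicated {unique_col} value(s): {dupes}")
    return table


def write_table(table: pd.DataFrame, path) -> Path:
    """Write a table as canonical CSV (UTF-8, '.' decimal, no index)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False)
    return path


def _package_version() -> str:
    try:
        return _pkg_version("wpbmorph")
    except PackageNotFoundError:
        return "unknown"


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


class RunManifest:
    """Reproducibility record written alongside every pipeline run."""

    def __init__(self, config: PipelineConfig, seed: int):
        self.payload = {
            "package": "wpbmorph",
            "version": _package_version(),
            "seed": int(seed),
            "config": config.to_dict(),
            "inputs": {},
            "outputs": [],
            "timestamp_utc": datetime.now(timezone.utc).isoformat(),
        }

    def add_input(self, role: str, path) -> None:
        p = Path(path)
        self.payload["inputs"][role] = {"path": str(p), "sha256": _sha256(p)}

    def add_output(self, path) -> None:
        self.payload["outputs"].append(str(Path(path)))

    def write(self, out_dir) -> Path:
        out = Path(out_dir) / "manifest.json"
        out.parent.mkdir(parents=True, exist_ok=True)
        with open(out, "w", encoding="utf-8") as fh:
            json.dump(self.payload, fh, indent=2, sort_keys=True)
        return out


def _write_json(payload: dict, path: Path) -> Path:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
    return path


# ---------------------------------------------------------------------------
# Stage runners (library surface behind the CLI)
# ---------------------------------------------------------------------------

def run_stereology_profiles(profiles: pd.DataFrame, config: PipelineConfig, out_dir: Path) -> dict:
    kept, report = stereo_mod.filter_spherical(profiles, config.stereology.max_axis_ratio)
    logger.info("sphericity filter kept %d/%d profiles", report["n_kept"], report["n_total"])
    table, summary = stereo_mod.estimate_volume_distribution(
        kept, "profiles", config.stereology, apply_filter=False
    )
    write_table(table, out_dir / "volumes_profiles.csv")
    payload = {"filter": report, "summary": summary.to_dict()}
    _write_json(payload, out_dir / "summary_profiles.json")
    return payload


def run_stereology_rods(rods: pd.DataFrame, config: PipelineConfig, out_dir: Path) -> dict:
    table, summary = stereo_mod.estimate_volume_distribution(rods, "rods", config.stereology)
    write_table(table, out_dir / "volumes_rods.csv")
    payload = {"summary": summary.to_dict()}
    _write_json(payload, out_dir / "summary_rods.json")
    return payload


def run_stereology_rings(rings: pd.DataFrame, config: PipelineConfig, out_dir: Path) -> dict:
    payload = stereo_mod.summarize_rings(rings)
    _write_json(payload, out_dir / "summary_rings.json")
    return payload


def run_ph(
    measurements: pd.DataFrame,
    config: PipelineConfig,
    out_dir: Path,
    traces: pd.DataFrame | None = None,
    nh4cl_time_s: float | None = None,
    compare: bool | None = None,
) -> dict:
    if traces is not None:
        if nh4cl_time_s is None:
            raise WpbMorphError("nh4cl_time_s is required when analysing traces")
        rows = []
        for oid, grp in traces.groupby("organelle_id"):
            f_rest, f_max = ph_mod.extract_rest_and_max(
                grp["time_s"].to_numpy(), grp["fluorescence"].to_numpy(),
                nh4cl_time_s, config.ph,
            )
            rows.append((oid, f_rest, f_max))
        extracted = pd.DataFrame(rows, columns=["organelle_id", "f_rest", "f_max"])
        meta_cols = [c for c in ("cell_id", "group", "f_background") if c in measurements]
        measurements = extracted.merge(
            measurements[["organelle_id", *meta_cols]], on="organelle_id", how="left"
        )
        if "group" not in measurements:
            measurements["group"] = "all"
    if compare is None:
        compare = measurements["group"].nunique() == 2
    table, summary = ph_mod.ph_dataset(measurements, config.ph.calibration, compare=compare)
    if summary["n_excluded_qc"]:
        logger.warning("excluded %d organelle(s) with out-of-range ratios",
                       summary["n_excluded_qc"])
    write_table(table, out_dir / "ph_estimates.csv")
    _write_json(summary, out_dir / "ph_summary.json")
    return summary


def run_kinetics(
    events: pd.DataFrame,
    cells: pd.DataFrame,
    traces: pd.DataFrame,
    config: PipelineConfig,
    out_dir: Path,
) -> dict:
    summaries, doses, rows = [], [], []
    curves = []
    for _, cell in cells.iterrows():
        cid = cell["cell_id"]
        tr = traces.loc[traces["cell_id"] == cid]
        if len(tr) == 0:
            raise WpbMorphError(f"no Ca2+ trace for cell {cid!r}")
        t0 = kin_mod.detect_onset(tr["time_s"].to_numpy(), tr["ratio"].to_numpy(),
                                  config.kinetics)
        ev = events.loc[events["cell_id"] == cid, "event_time_s"].to_numpy()
        s = kin_mod.align_and_summarize(cid, ev, int(cell["total_wpb"]), t0,
                                        config.kinetics)
        if s.n_pre_onset_excluded:
            logger.warning("cell %s: excluded %d pre-onset event(s)",
                           cid, s.n_pre_onset_excluded)
        summaries.append(s)
        doses.append(float(cell["dose_um"]))
        curves.append((ev[ev >= t0], t0))
        rows.append((cid, cell["group"], float(cell["dose_um"]), t0, s.delay_s,
                     s.max_rate_per_s, s.fraction_released_pct, s.n_events,
                     s.total_wpb))
    kinetics_table = pd.DataFrame(
        rows,
        columns=["cell_id", "group", "dose_um", "onset_s", "delay_s",
                 "max_rate_per_s", "fraction_released_pct", "n_events", "total_wpb"],
    )
    write_table(kinetics_table, out_dir / "kinetics.csv")

    curve_frames = []
    for dose in sorted(set(doses)):
        sets = [c for c, d in zip(curves, doses) if d == dose]
        times, values = kin_mod.cumulative_curve(
            [ev for ev, _ in sets], [t0 for _, t0 in sets]
        )
        curve_frames.append(pd.DataFrame(
            {"dose_um": dose, "aligned_time_s": times, "cumulative_fraction": values}
        ))
    write_table(pd.concat(curve_frames, ignore_index=True)
                if curve_frames else pd.DataFrame(
                    columns=["dose_um", "aligned_time_s", "cumulative_fraction"]),
                out_dir / "cumulative_curves.csv")

    payload = kin_mod.dose_response_table(summaries, doses)
    payload["rate_window_s"] = config.kinetics.rate_window_s
    _write_json(payload, out_dir / "dose_response.json")
    return payload


def run_strings(
    points: pd.DataFrame,
    meta: pd.DataFrame,
    config: PipelineConfig,
    out_dir: Path,
    platelets: pd.DataFrame | None = None,
) -> dict:
    lengths = str_mod.string_length_table(points, meta, config.strings.length_mode)
    kept, report = str_mod.filter_min_length(lengths, config.strings.min_length_um)
    logger.info("min-length filter kept %d/%d strings", report["n_kept"], report["n_total"])
    write_table(kept, out_dir / "string_lengths.csv")

    payload: dict = {"filter": report, "groups": {}}
    for name, grp in kept.groupby("group"):
        payload["groups"][str(name)] = str_mod.whisker_summary(grp["length_um"].to_numpy())
    if kept["group"].nunique() >= 2 and (kept.groupby("group").size() >= 2).all():
        densities = None
        if platelets is not None and kept["group"].nunique() == 2:
            dens_table, _ = str_mod.platelet_density(kept, platelets,
                                                     config.strings.density_mode)
            merged = dens_table.merge(kept[["string_id", "group"]], on="string_id")
            densities = {
                str(g): grp["density_per_um"].dropna().to_numpy()
                for g, grp in merged.groupby("group")
            }
        payload["comparison"] = str_mod.compare_groups(
            {str(g): grp["length_um"].to_numpy() for g, grp in kept.groupby("group")},
            densities,
        )
    if platelets is not None:
        dens_table, aggregate = str_mod.platelet_density(kept, platelets,
                                                         config.strings.density_mode)
        write_table(dens_table, out_dir / "platelet_densities.csv")
        payload["platelet_density_per_um"] = aggregate
        payload["density_mode"] = config.strings.density_mode
    _write_json(payload, out_dir / "string_stats.json")
    return payload


def run_pipeline(config: PipelineConfig, inputs: dict[str, str], out_dir) -> dict:
    """Execute every stage whose inputs are present, writing outputs + manifest.

    ``inputs`` maps schema roles (profiles, rods, rings, ph_measurements,
    ph_traces + nh4cl_time_s, events + cells + ca_traces, strings_points +
    strings_meta [+ platelets]) to file paths.  Stage errors are re-raised
    with the stage name prefixed.
    """
    config.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config, config.seed)
    known_roles = set(SCHEMAS) | {"nh4cl_time_s"}
    unknown = set(inputs) - known_roles
    if unknown:
        raise WpbMorphError(f"unknown input role(s): {sorted(unknown)}")
    for role, path in inputs.items():
        if role != "nh4cl_time_s":
            manifest.add_input(role, path)

    results: dict = {}

    def stage(name, fn, *args, **kwargs):
        try:
            results[name] = fn(*args, **kwargs)
        except WpbMorphError as exc:
            raise WpbMorphError(f"[{name}] {exc}") from exc

    ran_any = False
    if "profiles" in inputs:
        stage("stereology_profiles", run_stereology_profiles,
              read_table(inputs["profiles"], "profiles"), config, out_dir)
        ran_any = True
    if "rods" in inputs:
        stage("stereology_rods", run_stereology_rods,
              read_table(inputs["rods"], "rods"), config, out_dir)
        ran_any = True
    if "rings" in inputs:
        stage("stereology_rings", run_stereology_rings,
              read_table(inputs["rings"], "rings"), config, out_dir)
        ran_any = True
    if "ph_measurements" in inputs or "ph_traces" in inputs:
        measurements = (read_table(inputs["ph_measurements"], "ph_measurements")
                        if "ph_measurements" in inputs else
                        pd.DataFrame(columns=["organelle_id", "cell_id", "group",
                                              "f_rest", "f_max"]))
        traces = (read_table(inputs["ph_traces"], "ph_traces")
                  if "ph_traces" in inputs else None)
        stage("ph", run_ph, measurements, config, out_dir,
              traces=traces, nh4cl_time_s=inputs.get("nh4cl_time_s"))
        ran_any = True
    if "events" in inputs:
        if not {"cells", "ca_traces"} <= set(inputs):
            raise WpbMorphError("kinetics stage needs events + cells + ca_traces")
        stage("kinetics", run_kinetics,
              read_table(inputs["events"], "events"),
              read_table(inputs["cells"], "cells"),
              read_table(inputs["ca_traces"], "ca_traces"),
              config, out_dir)
        ran_any = True
    if "strings_points" in inputs:
        if "strings_meta" not in inputs:
            raise WpbMorphError("strings stage needs strings_points + strings_meta")
        platelets = (read_table(inputs["platelets"], "platelets")
                     if "platelets" in inputs else None)
        stage("strings", run_strings,
              read_table(inputs["strings_points"], "strings_points"),
              read_table(inputs["strings_meta"], "strings_meta"),
              config, out_dir, platelets=platelets)
        ran_any = True

    if not ran_any:
        raise WpbMorphError("no stage inputs provided; nothing to run")

    for p in sorted(out_dir.glob("*.csv")) + sorted(out_dir.glob("*.json")):
        if p.name != "manifest.json":
            manifest.add_output(p)
    manifest.write(out_dir)
    return results
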