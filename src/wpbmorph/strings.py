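"""Secreted VWF string morphometry and platelet-binding density.

Strings are polylines traced in image coordinates (µm); their length is the
arc length along the trace (a chord-length alternative is configurable).
Strings shorter than the minimum length (default 20 µm) are excluded — a
string of exactly the minimum is kept.  Platelet binding is summarised as
platelets per µm of string, either per string (default) or pooled.  Group
comparisons follow the conventions of the flow-chamber literature: one-way
ANOVA across length groups, Welch t-test for two-group density contrasts,
and whisker-plot summaries (25-75% box, median, mean, 1.5*IQR whiskers).

An optional image pathway recovers string traces from a single-channel
fluorescence image by Otsu thresholding and skeletonization; branched
skeletons are resolved to their longest path.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .config import StringsConfig
from .errors import ConfigError, InvalidMeasurementError

__all__ = [
    "polyline_length",
    "string_length_table",
    "filter_min_length",
    "platelet_density",
    "whisker_summary",
    "compare_groups",
    "trace_strings_from_image",
]


def polyline_length(vertices: np.ndarray, mode: str = "arc") -> float:
    """Length of a polyline in µm: arc length (default) or chord length.

    Fewer than 2 vertices cannot define a measurable string; the length is
    reported as 0 (callers flag such records rather than erroring).
    """
    v = np.asarray(vertices, dtype=float).reshape(-1, 2)
    if v.shape[0] < 2:
        return 0.0
    if mode == "chord":
        return float(np.hypot(*(v[-1] - v[0])))
    if mode != "arc":
        raise ConfigError(f"length mode must be 'arc' or 'chord', got {mode!r}")
    return float(np.sum(np.hypot(*np.diff(v, axis=0).T)))


def string_length_table(
    points: pd.DataFrame,
    meta: pd.DataFrame | None = None,
    mode: str = "arc",
) -> pd.DataFrame:
    """Per-string lengths from a points table (string_id, point_index, x_um, y_um).

    Returns string_id, length_um, n_vertices, qc_pass (False for strings
    with fewer than 2 vertices) merged with metadata when supplied.
    """
    rows = []
    for sid, grp in points.sort_values("point_index").groupby("string_id", sort=False):
        verts = grp[["x_um", "y_um"]].to_numpy()
        rows.append((sid, polyline_length(verts, mode), len(verts), len(verts) >= 2))
    table = pd.DataFrame(rows, columns=["string_id", "length_um", "n_vertices", "qc_pass"])
    if meta is not None:
        table = table.merge(meta, on="string_id", how="left")
    return table


def filter_min_length(
    lengths: pd.DataFrame, min_length_um: float = 20.0
) -> tuple[pd.DataFrame, dict]:
    """Exclude strings shorter than ``min_length_um`` (exact boundary kept)."""
    kept = lengths.loc[lengths["length_um"] >= min_length_um].reset_index(drop=True)
    return kept, {
        "n_total": int(len(lengths)),
        "n_kept": int(len(kept)),
        "min_length_um": min_length_um,
    }


def platelet_density(
    lengths: pd.DataFrame,
    platelets: pd.DataFrame,
    mode: str = "per_string",
) -> tuple[pd.DataFrame, float]:
    """Platelets per µm of string.

    Returns a per-string table (string_id, length_um, n_platelets,
    density_per_um) and the aggregate: the mean of per-string densities
    ('per_string', default, matching per-string plotting conventions) or
    total platelets / total length ('pooled').  Zero-length strings are
    excluded with a QC flag rather than dividing by zero.
    """
    if mode not in ("per_string", "pooled"):
        raise ConfigError(f"density mode must be 'per_string' or 'pooled', got {mode!r}")
    counts = platelets.groupby("string_id").size() if len(platelets) else pd.Series(dtype=int)
    table = lengths[["string_id", "length_um"]].copy()
    table["n_platelets"] = table["string_id"].map(counts).fillna(0).astype(int)
    table["qc_pass"] = table["length_um"] > 0
    table["density_per_um"] = np.where(
        table["qc_pass"], table["n_platelets"] / table["length_um"].replace(0, np.nan), np.nan
    )
    usable = table.loc[table["qc_pass"]]
    if len(usable) == 0:
        return table, float("nan")
    if mode == "per_string":
        aggregate = float(usable["density_per_um"].mean())
    else:
        aggregate = float(usable["n_platelets"].sum() / usable["length_um"].sum())
    return table, aggregate


def whisker_summary(values: np.ndarray) -> dict:
    """Box-and-whisker numbers: 25-75% box, median, mean, 1.5*IQR whiskers.

    Quantiles use linear interpolation (type-7, the numpy default); whisker
    ends are clipped to the most extreme data point inside 1.5*IQR.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise InvalidMeasurementError("empty sample for whisker summary")
    q25, q50, q75 = np.percentile(v, [25, 50, 75])
    iqr = q75 - q25
    lo_fence, hi_fence = q25 - 1.5 * iqr, q75 + 1.5 * iqr
    inside = v[(v >= lo_fence) & (v <= hi_fence)]
    return {
        "n": int(v.size),
        "mean": float(np.mean(v)),
        "median": float(q50),
        "q25": float(q25),
        "q75": float(q75),
        "whisker_low": float(inside.min()),
        "whisker_high": float(inside.max()),
        "quantile_rule": "linear (type-7)",
    }


def compare_groups(
    lengths_by_group: dict[str, np.ndarray],
    densities_by_group: dict[str, np.ndarray] | None = None,
) -> dict:
    """Group statistics: one-way ANOVA on lengths, Welch t on densities.

    ``lengths_by_group`` needs >= 2 groups with >= 2 observations each; the
    optional density comparison needs exactly 2 groups.  Whisker summaries
    are reported per group.
    """
    if len(lengths_by_group) < 2:
        raise ConfigError("ANOVA requires >= 2 groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in lengths_by_group.items()}
    for name, arr in arrays.items():
        if arr.size < 2:
            raise ConfigError(f"group {name!r} has fewer than 2 observations")
    f_stat, p = stats.f_oneway(*arrays.values())
    out: dict = {
        "lengths": {
            "test": "one_way_anova",
            "groups": list(arrays),
            "F": float(f_stat),
            "p_value": float(p),
            "summaries": {name: whisker_summary(arr) for name, arr in arrays.items()},
        }
    }
    if densities_by_group is not None:
        if len(densities_by_group) != 2:
            raise ConfigError("density comparison requires exactly 2 groups")
        (na, a), (nb, b) = [(k, np.asarray(v, float)) for k, v in densities_by_group.items()]
        if a.size < 2 or b.size < 2:
            raise ConfigError("density comparison needs >= 2 observations per group")
        t, pd_ = stats.ttest_ind(a, b, equal_var=False)
        out["densities"] = {
            "test": "welch_t",
            "groups": [na, nb],
            "statistic": float(t),
            "p_value": float(pd_),
            "summaries": {na: whisker_summary(a), nb: whisker_summary(b)},
        }
    return out


# ---------------------------------------------------------------------------
# Optional image pathway
# ---------------------------------------------------------------------------

def _skeleton_longest_path_length(skeleton: np.ndarray, subsample: int = 5) -> float:
    """Longest path through an 8-connected skeleton, in pixel units.

    Steps are weighted 1 (orthogonal) / sqrt(2) (diagonal) to find the
    longest topological path between skeleton endpoints; the returned
    length is then measured along that path subsampled every ``subsample``
    pixels, which suppresses the staircase overestimate digitized curves
    otherwise carry.
    """
    import networkx as nx

    rows, cols = np.nonzero(skeleton)
    pixels = set(zip(rows.tolist(), cols.tolist()))
    g = nx.Graph()
    g.add_nodes_from(pixels)
    for (r, c) in pixels:
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if (dr, dc) == (0, 0):
                    continue
                nb = (r + dr, c + dc)
                if nb in pixels:
                    g.add_edge((r, c), nb, weight=np.hypot(dr, dc))
    if g.number_of_nodes() <= 1:
        return 0.0
    endpoints = [n for n in g.nodes if g.degree(n) == 1] or list(g.nodes)
    best_len, best_pair = 0.0, None
    # skeleton components are small; all-pairs over endpoints is affordable
    for src in endpoints:
        dist = nx.single_source_dijkstra_path_length(g, src, weight="weight")
        far = max(dist, key=dist.get)
        if dist[far] > best_len:
            best_len, best_pair = dist[far], (src, far)
    if best_pair is None:
        return 0.0
    path = nx.dijkstra_path(g, *best_pair, weight="weight")
    pts = np.asarray(path, dtype=float)
    idx = np.arange(0, len(pts), subsample)
    if idx[-1] != len(pts) - 1:
        idx = np.append(idx, len(pts) - 1)
    sampled = pts[idx]
    return float(np.sum(np.hypot(*np.diff(sampled, axis=0).T)))


def trace_strings_from_image(
    image: np.ndarray,
    pixel_size_um: float,
    min_skeleton_px: int = 3,
) -> pd.DataFrame:
    """String lengths from a single-channel image.

    Otsu threshold -> skeletonize -> per connected skeleton component, the
    length is the longest topological path (orthogonal steps weight 1,
    diagonal steps sqrt(2)) times the pixel size.  An empty segmentation
    yields an empty table, not an error.
    """
    from skimage.filters import threshold_otsu
    from skimage.measure import label
    from skimage.morphology import skeletonize

    if pixel_size_um <= 0:
        raise ConfigError(f"pixel_size_um must be > 0, got {pixel_size_um}")
    img = np.asarray(image)
    if img.ndim != 2:
        raise InvalidMeasurementError("image must be single-channel (2D)")

    if img.dtype == bool:
        mask = img
    else:
        flat = img.ravel()
        if flat.max() == flat.min():
            return pd.DataFrame(columns=["string_id", "length_um", "n_pixels"])
        mask = img > threshold_otsu(img)

    skel = skeletonize(mask)
    labels = label(skel, connectivity=2)
    rows = []
    for lab in range(1, labels.max() + 1):
        comp = labels == lab
        if comp.sum() < min_skeleton_px:
            continue
        length = _skeleton_longest_path_length(comp) * pixel_size_um
        rows.append((f"img{lab:04d}", length, int(comp.sum())))
    return pd.DataFrame(rows, columns=["string_id", "length_um", "n_pixels"])
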