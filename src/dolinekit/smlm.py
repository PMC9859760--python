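"""dSTORM localization-cluster analysis pipeline.

Works directly on blink coordinate tables (ThunderSTORM-style CSV) rather
than on reconstructed images.  The pipeline is deterministic and its order
is fixed:

    read -> filter -> merge -> homogenize -> cluster -> measure -> stratify

* filter: strict-inequality quality gates on intensity, localization
  uncertainty and PSF width;
* merge: consecutive-frame events within 20 nm averaged into one blink
  (re-blinking of a single fluorophore);
* homogenize: truncate to the first k frames so the global blink density
  over the segmented cell area best approximates 2e-4 blinks/nm^2, making
  cluster densities comparable across samples;
* cluster: DBSCAN (eps = 20 nm, minpts = 30, self-counting cores) with
  deterministic labels;
* measure: convex-hull area, blink density, Feret diameter per cluster,
  optional exclusion of clusters touching the ROI border;
* stratify: small/medium/large area strata (bounds 25^2*pi and 50^2*pi
  nm^2) with per-stratum median blink density and cluster densities per
  ROI area.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError, cKDTree
from shapely.geometry import MultiPoint, Polygon

__all__ = [
    "COLUMNS",
    "LocalizationTable",
    "PipelineConfig",
    "Cluster",
    "ClusterSet",
    "StrataSummary",
    "read_localizations",
    "write_localizations",
    "filter_localizations",
    "merge_consecutive",
    "homogenize_density",
    "cluster_dbscan",
    "measure_clusters",
    "stratify_and_summarize",
    "run_pipeline",
]

COLUMNS = ("frame", "x", "y", "sigma", "intensity", "uncertainty")

# ThunderSTORM header dialect and common aliases -> canonical names
_ALIASES = {
    "frame": "frame",
    "x [nm]": "x", "x[nm]": "x", "x": "x",
    "y [nm]": "y", "y[nm]": "y", "y": "y",
    "sigma [nm]": "sigma", "sigma[nm]": "sigma", "sigma": "sigma",
    "intensity [photon]": "intensity", "intensity[photon]": "intensity",
    "intensity": "intensity",
    "uncertainty [nm]": "uncertainty", "uncertainty[nm]": "uncertainty",
    "uncertainty_xy [nm]": "uncertainty", "uncertainty": "uncertainty",
}


@dataclass
class LocalizationTable:
    """Blink records plus the segmented cell (ROI) they came from."""

    df: pd.DataFrame
    roi_area: float                       # nm^2
    roi_polygon: list[tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        missing = [c for c in COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        if not self.roi_area > 0:
            raise ValueError("roi_area must be positive")
        if len(self.df):
            if (self.df["frame"] < 1).any():
                raise ValueError("frames must start at 1")
            for c in ("sigma", "intensity", "uncertainty"):
                if (self.df[c] < 0).any():
                    raise ValueError(f"{c} must be non-negative")
        if self.roi_polygon is not None:
            poly = Polygon(self.roi_polygon)
            if not poly.is_valid:
                raise ValueError("roi_polygon is not a valid simple polygon")
            if abs(poly.area - self.roi_area) > 1e-6 * self.roi_area:
                raise ValueError("roi_polygon area inconsistent with roi_area")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def xy(self) -> np.ndarray:
        return self.df[["x", "y"]].to_numpy(dtype=float)

    def replace_df(self, df: pd.DataFrame) -> "LocalizationTable":
        return LocalizationTable(df.reset_index(drop=True), self.roi_area,
                                 self.roi_polygon)


@dataclass(frozen=True)
class PipelineConfig:
    """Pipeline thresholds; the defaults are the published protocol."""

    intensity_min: float = 300.0       # exclusive
    intensity_max: float = 5000.0      # exclusive
    uncertainty_max: float = 35.0      # nm, exclusive
    sigma_max: float = 300.0           # nm, exclusive
    merge_radius: float = 20.0         # nm
    target_density: float = 2e-4       # blinks / nm^2
    eps: float = 20.0                  # nm
    minpts: int = 30
    a_small: float = 25.0**2 * math.pi   # nm^2
    a_large: float = 50.0**2 * math.pi   # nm^2
    exclude_border_clusters: bool = True

    def __post_init__(self) -> None:
        for name in ("intensity_min", "intensity_max", "uncertainty_max",
                     "sigma_max", "merge_radius", "target_density", "eps"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.minpts < 1:
            raise ValueError("minpts must be >= 1")
        if not self.a_small < self.a_large:
            raise ValueError("require a_small < a_large")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def read_localizations(path, roi_area: float = 1.0,
                       roi_polygon=None) -> LocalizationTable:
    """Read a ThunderSTORM-style CSV of blinks.

    Column headers are mapped through an alias table ("x [nm]" -> x, ...);
    row order is preserved.  Malformed (non-numeric) rows raise with their
    line numbers.
    """
    raw = pd.read_csv(path, skipinitialspace=True)
    rename = {}
    for col in raw.columns:
        key = col.strip().strip('"').lower()
        if key in _ALIASES:
            rename[col] = _ALIASES[key]
    raw = raw.rename(columns=rename)
    missing = [c for c in COLUMNS if c not in raw.columns]
    if missing:
        raise ValueError(f"mandatory columns missing from {path}: {missing}")
    df = raw[list(COLUMNS)].copy()
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna().any(axis=1) & ~df.isna().all(axis=1)
    if bad.any():
        lines = (np.flatnonzero(bad) + 2).tolist()  # 1-based + header
        raise ValueError(f"non-numeric fields at line(s) {lines} of {path}")
    numeric["frame"] = numeric["frame"].astype(int)
    return LocalizationTable(numeric.reset_index(drop=True), roi_area,
                             roi_polygon)


def write_localizations(table: LocalizationTable, path) -> None:
    """Write blinks back out in the ThunderSTORM header dialect."""
    out = table.df.rename(columns={
        "x": "x [nm]", "y": "y [nm]", "sigma": "sigma [nm]",
        "intensity": "intensity [photon]", "uncertainty": "uncertainty [nm]"})
    out.to_csv(path, index=False)


def filter_localizations(table: LocalizationTable,
                         config: PipelineConfig = PipelineConfig()
                         ) -> LocalizationTable:
    """Keep blinks satisfying the four strict quality inequalities:
    intensity_min < intensity < intensity_max, uncertainty < uncertainty_max,
    sigma < sigma_max.  Order preserved."""
    df = table.df
    keep = ((df["intensity"] > config.intensity_min)
            & (df["intensity"] < config.intensity_max)
            & (df["uncertainty"] < config.uncertainty_max)
            & (df["sigma"] < config.sigma_max))
    return table.replace_df(df[keep])


def merge_consecutive(table: LocalizationTable,
                      merge_radius: float = 20.0) -> LocalizationTable:
    """Average consecutive-frame re-blinks of one fluorophore.

    A chain is grown greedily in frame order: a blink in frame f joins the
    nearest open chain whose last event was in frame f-1 and lies within
    ``merge_radius`` (ties to the oldest chain); otherwise it opens a new
    chain.  Each chain collapses to one record at the unweighted mean
    position, with frame = first frame, intensity summed, uncertainty the
    minimum and sigma the mean of its members.
    """
    df = table.df
    if len(df) == 0:
        return table
    df = df.sort_values("frame", kind="stable").reset_index(drop=True)
    frames = df["frame"].to_numpy()
    xy = df[["x", "y"]].to_numpy(dtype=float)

    chain_of = np.full(len(df), -1, dtype=int)
    n_chains = 0
    prev_frame = None
    prev_rows: list[int] = []    # last events of open chains, previous frame
    for start in np.flatnonzero(np.r_[True, np.diff(frames) != 0]):
        f = int(frames[start])
        if prev_frame is None or f != prev_frame + 1:
            prev_rows = []
        stop = start + 1
        while stop < len(df) and frames[stop] == f:
            stop += 1
        for i in range(start, stop):
            best, best_d = -1, math.inf
            for j in prev_rows:
                d = math.hypot(xy[i, 0] - xy[j, 0], xy[i, 1] - xy[j, 1])
                if d <= merge_radius and (d < best_d or
                        (d == best_d and chain_of[j] < chain_of[best])):
                    best, best_d = j, d
            if best >= 0:
                chain_of[i] = chain_of[best]
                prev_rows.remove(best)  # one extension per chain per frame
            else:
                chain_of[i] = n_chains
                n_chains += 1
        prev_rows = list(range(start, stop))
        prev_frame = f

    g = df.groupby(chain_of, sort=True)
    merged = pd.DataFrame({
        "frame": g["frame"].min().astype(int),
        "x": g["x"].mean(),
        "y": g["y"].mean(),
        "sigma": g["sigma"].mean(),
        "intensity": g["intensity"].sum(),
        "uncertainty": g["uncertainty"].min(),
    }).sort_values("frame", kind="stable").reset_index(drop=True)
    return table.replace_df(merged)


def homogenize_density(table: LocalizationTable,
                       config: PipelineConfig = PipelineConfig()
                       ) -> tuple[LocalizationTable, int, float]:
    """Truncate to the first k frames approximating the target density.

    k = argmin over k in [1, max frame] of |density(k) - target| with
    density(k) = #blinks(frame <= k) / roi_area; ties toward smaller k.
    When even the full video undershoots the target, all frames are kept
    and a warning (not an error) is issued.
    """
    df = table.df
    if len(df) == 0:
        raise ValueError("cannot homogenize an empty table")
    max_frame = int(df["frame"].max())
    counts = np.bincount(df["frame"].to_numpy(), minlength=max_frame + 1)
    cum = np.cumsum(counts)[1:]          # blinks with frame <= k, k = 1..max
    dens = cum / table.roi_area
    # deviation on the count scale keeps exact ties exact
    dev = np.abs(cum - config.target_density * table.roi_area)
    k = int(np.argmin(dev)) + 1          # argmin returns first (smallest k) tie
    if dens[-1] < config.target_density:
        warnings.warn(
            f"sample never reaches target density "
            f"({dens[-1]:.3g} < {config.target_density:.3g} blinks/nm^2); "
            f"keeping all {max_frame} frames", stacklevel=2)
        k = max_frame
    out = table.replace_df(df[df["frame"] <= k])
    return out, k, float(cum[k - 1] / table.roi_area)


def cluster_dbscan(table: LocalizationTable | np.ndarray, eps: float = 20.0,
                   minpts: int = 30) -> np.ndarray:
    """DBSCAN on blink (x, y) positions, Euclidean metric.

    Core points have >= ``minpts`` neighbours within ``eps`` *counting
    themselves*.  Noise is labelled -1.  Labels are deterministic and
    independent of record order: clusters are numbered by their smallest
    core-point index and border points join the lowest-id eligible cluster.
    """
    pts = table.xy if isinstance(table, LocalizationTable) else np.asarray(table, float)
    m = len(pts)
    labels = np.full(m, -1, dtype=int)
    if m == 0:
        return labels
    tree = cKDTree(pts)
    neigh = tree.query_ball_point(pts, eps)          # includes self
    core = np.array([len(nb) >= minpts for nb in neigh])
    # connected components over core points (core-core reachability)
    cid = 0
    for i in np.flatnonzero(core):
        if labels[i] != -1:
            continue
        stack = [i]
        labels[i] = cid
        while stack:
            j = stack.pop()
            for k in neigh[j]:
                if core[k] and labels[k] == -1:
                    labels[k] = cid
                    stack.append(k)
        cid += 1
    # border points: lowest cluster id among core neighbours
    for i in np.flatnonzero(~core):
        cands = [labels[k] for k in neigh[i] if core[k]]
        if cands:
            labels[i] = min(cands)
    return labels


@dataclass
class Cluster:
    """One DBSCAN cluster with its boundary-based measurements."""

    label: int
    member_idx: np.ndarray
    n_members: int
    hull_area: float            # nm^2, convex hull of member coordinates
    blink_density: float        # members / hull_area [nm^-2]
    feret_diameter: float       # nm, max pairwise distance on the hull
    stratum: str                # small / medium / large
    centroid: tuple[float, float] = (0.0, 0.0)   # nm, mean member position
    touches_border: bool = False
    degenerate: bool = False


@dataclass
class ClusterSet:
    clusters: list[Cluster]
    roi_area: float

    @property
    def measured(self) -> list[Cluster]:
        """Clusters entering density statistics (non-degenerate, inside ROI)."""
        return [c for c in self.clusters
                if not c.degenerate and not c.touches_border]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "label": c.label, "n_blinks": c.n_members,
            "hull_area_nm2": c.hull_area,
            "blink_density_per_nm2": c.blink_density,
            "feret_nm": c.feret_diameter, "stratum": c.stratum,
            "touches_border": c.touches_border, "degenerate": c.degenerate,
        } for c in self.clusters])


def _stratum(area: float, config: PipelineConfig) -> str:
    if area < config.a_small:
        return "small"
    if area < config.a_large:
        return "medium"
    return "large"


def _feret(points: np.ndarray) -> float:
    """Longest pairwise distance, exhaustive over hull vertices."""
    if len(points) < 2:
        return 0.0
    d2 = ((points[:, None, :] - points[None, :, :]) ** 2).sum(-1)
    return float(np.sqrt(d2.max()))


def measure_clusters(table: LocalizationTable, labels: np.ndarray,
                     config: PipelineConfig = PipelineConfig()) -> ClusterSet:
    """Hull area, blink density, Feret diameter and stratum per cluster.

    Clusters with degenerate hulls (area < 1 nm^2 or fewer than 3 distinct
    points) are flagged and excluded from density statistics; clusters
    whose hull is not strictly inside the ROI polygon are flagged as
    border-touching and excluded when configured.  With only ``roi_area``
    given, border exclusion is skipped.
    """
    xy = table.xy
    roi_poly = None
    if config.exclude_border_clusters and table.roi_polygon is not None:
        roi_poly = Polygon(table.roi_polygon)
    clusters: list[Cluster] = []
    for lab in sorted(set(labels) - {-1}):
        idx = np.flatnonzero(labels == lab)
        pts = xy[idx]
        hull_pts = pts
        area = 0.0
        degenerate = False
        try:
            hull = ConvexHull(pts)
            area = float(hull.volume)    # 2-D: volume is the area (shoelace)
            hull_pts = pts[hull.vertices]
        except QhullError:
            degenerate = True
        if area < 1.0:
            degenerate = True
        density = len(idx) / area if area > 0 else float("nan")
        touches = False
        if roi_poly is not None:
            geom = MultiPoint(pts).convex_hull
            touches = not roi_poly.contains(geom)
        clusters.append(Cluster(
            label=int(lab), member_idx=idx, n_members=int(len(idx)),
            hull_area=area, blink_density=density,
            feret_diameter=_feret(hull_pts),
            stratum=_stratum(area, config),
            centroid=(float(pts[:, 0].mean()), float(pts[:, 1].mean())),
            touches_border=touches, degenerate=degenerate))
    return ClusterSet(clusters=clusters, roi_area=table.roi_area)


@dataclass
class StrataSummary:
    """Per-stratum medians and densities plus pipeline globals."""

    strata: dict                     # name -> {count, median_blink_density,
    #                                           clusters_per_um2}
    k_frames_used: int | None = None
    achieved_density: float | None = None
    total_clusters: int = 0

    def to_json(self) -> str:
        return json.dumps({
            "strata": self.strata,
            "k_frames_used": self.k_frames_used,
            "achieved_density_per_nm2": self.achieved_density,
            "total_clusters": self.total_clusters,
        }, indent=2)


def stratify_and_summarize(clusters: ClusterSet,
                           config: PipelineConfig = PipelineConfig(),
                           roi_area: float | None = None) -> StrataSummary:
    """Median blink density and cluster density per stratum.

    Strata use the printed half-open bounds: small (area < 25^2 pi),
    medium (25^2 pi <= area < 50^2 pi), large (area >= 50^2 pi).  The
    median over an even count is the mean of the central pair; an empty
    stratum reports its median as missing (None), never zero.
    """
    roi = roi_area if roi_area is not None else clusters.roi_area
    meas = clusters.measured
    out = {}
    for name in ("small", "medium", "large"):
        dens = [c.blink_density for c in meas if c.stratum == name]
        out[name] = {
            "count": len(dens),
            "median_blink_density": float(np.median(dens)) if dens else None,
            "clusters_per_um2": len(dens) / roi * 1e6,
        }
    return StrataSummary(strata=out, total_clusters=len(meas))


def run_pipeline(table: LocalizationTable,
                 config: PipelineConfig = PipelineConfig()
                 ) -> tuple[ClusterSet, StrataSummary, dict]:
    """Full fixed-order pipeline on an already-read localization table.

    Returns the measured clusters, the strata summary and a log dict
    recording counts at each stage (the pipeline has no stochastic steps,
    so identical inputs give bit-identical outputs).
    """
    log = {"n_input": len(table)}
    t = filter_localizations(table, config)
    log["n_after_filter"] = len(t)
    t = merge_consecutive(t, config.merge_radius)
    log["n_after_merge"] = len(t)
    t, k, dens = homogenize_density(t, config)
    log.update(n_after_homogenize=len(t), k_frames_used=k,
               achieved_density=dens)
    if table.roi_polygon is None and config.exclude_border_clusters:
        log["border_exclusion"] = "skipped (no ROI polygon)"
    labels = cluster_dbscan(t, config.eps, config.minpts)
    cs = measure_clusters(t, labels, config)
    summary = stratify_and_summarize(cs, config)
    summary.k_frames_used = k
    summary.achieved_density = dens
    log["n_clusters"] = len(cs.clusters)
    return cs, summary, log
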