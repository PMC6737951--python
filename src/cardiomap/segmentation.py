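"""12-segment partition of the mid-slice LV myocardium and segment statistics.

The myocardial wall between the manually traced (here: analytically derived)
epicardial and endocardial contours is divided into six equal angular
sectors at basal/mid level (four at the apex), named per the standard AHA
convention — A, AS, IS, I, IL, AL counter-clockwise from the anterior
reference angle. The innermost fraction of the wall (default 5%) is excluded
to avoid blood-pool contamination, then each mid-level sector is split at
half transmural depth into subepicardial and subendocardial halves, giving
12 segments per slice.

Transmural depth is defined in polar convention: along the ray from the
contour centroid, depth 0 at the endocardial contour and 1 at the epicardial
contour, with contour radii interpolated periodically between polygon
vertices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from shapely.geometry import Polygon

from .phantom import PhantomGroundTruth
from .relaxometry import ParameterMap

__all__ = [
    "ContourSet",
    "SegmentLabelMap",
    "contours_from_phantom",
    "transmural_depth",
    "build_segments",
    "exclude_inner_rim",
    "split_transmural",
    "exclude_bright_blood",
    "segment_statistics",
]

SECTOR_NAMES = {
    6: ("A", "AS", "IS", "I", "IL", "AL"),
    4: ("A", "S", "I", "L"),
}


@dataclass
class ContourSet:
    """Closed epicardial and endocardial polygons in pixel coordinates.

    Vertices are (row, col) pairs; polygons are implicitly closed (last
    vertex joins the first). ``reference_angle_deg`` anchors segment 1.
    """

    epicardial: np.ndarray
    endocardial: np.ndarray
    reference_angle_deg: float = 0.0

    def __post_init__(self) -> None:
        self.epicardial = np.asarray(self.epicardial, dtype=float)
        self.endocardial = np.asarray(self.endocardial, dtype=float)
        for name, poly in (("epicardial", self.epicardial), ("endocardial", self.endocardial)):
            if poly.ndim != 2 or poly.shape[1] != 2 or poly.shape[0] < 3:
                raise ValueError(f"{name} contour must be an (n>=3, 2) vertex array")
        epi = Polygon(self.epicardial)
        endo = Polygon(self.endocardial)
        if not epi.is_simple or not endo.is_simple:
            raise ValueError("contours must be simple (non-self-intersecting) polygons")
        if not epi.contains(endo):
            raise ValueError("endocardial contour must lie strictly inside the epicardial one")


def contours_from_phantom(phantom: PhantomGroundTruth, n_vertices: int = 128) -> ContourSet:
    """Sample epi/endo polygons on the phantom's true circles.

    Analytic stand-in for manual contour tracing; requires an annular
    phantom with geometry attached.
    """
    geom = phantom.geometry
    if geom is None:
        raise ValueError("phantom has no geometry; cannot derive contours")
    mask = phantom.myocardium_mask
    interior = ~mask
    # annular check: some background must be enclosed (the blood pool)
    from scipy import ndimage
    bg_labels, _ = ndimage.label(interior)
    border_ids = np.unique(np.concatenate([
        bg_labels[0, :], bg_labels[-1, :], bg_labels[:, 0], bg_labels[:, -1]]))
    enclosed = set(np.unique(bg_labels[bg_labels > 0])) - set(border_ids)
    if not enclosed:
        raise ValueError("phantom mask is not annular (no enclosed blood pool)")
    if n_vertices < 64:
        raise ValueError("need at least 64 contour vertices")
    theta = np.linspace(0.0, 2 * np.pi, n_vertices, endpoint=False)
    cr, cc = geom.center

    def circle(radius_mm: float) -> np.ndarray:
        r_px = radius_mm / geom.pixel_size_mm
        return np.column_stack((cr - r_px * np.sin(theta), cc + r_px * np.cos(theta)))

    return ContourSet(
        epicardial=circle(geom.epi_radius_mm),
        endocardial=circle(geom.endo_radius_mm),
        reference_angle_deg=geom.reference_angle_deg,
    )


def _polar_radius_fn(poly: np.ndarray, centre: tuple[float, float]):
    """Periodic interpolant of contour radius (px) versus angle (rad, CCW)."""
    d_row = poly[:, 0] - centre[0]
    d_col = poly[:, 1] - centre[1]
    ang = np.mod(np.arctan2(-d_row, d_col), 2 * np.pi)
    rad = np.hypot(d_row, d_col)
    order = np.argsort(ang)
    ang, rad = ang[order], rad[order]

    def f(theta: np.ndarray) -> np.ndarray:
        return np.interp(np.mod(theta, 2 * np.pi), ang, rad, period=2 * np.pi)

    return f


def _pixel_polar(contours: ContourSet, shape: tuple[int, int]):
    """Per-pixel angle (rad), radius (px) and centroid for a raster shape."""
    centre = (float(np.mean(contours.epicardial[:, 0])),
              float(np.mean(contours.epicardial[:, 1])))
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
    theta = np.mod(np.arctan2(-(rr - centre[0]), cc - centre[1]), 2 * np.pi)
    radius = np.hypot(rr - centre[0], cc - centre[1])
    return theta, radius, centre


def transmural_depth(contours: ContourSet, shape: tuple[int, int]) -> np.ndarray:
    """Normalized wall depth per pixel: 0 at endocardium, 1 at epicardium.

    Values outside [0, 1] indicate pixels outside the wall.
    """
    theta, radius, centre = _pixel_polar(contours, shape)
    r_endo = _polar_radius_fn(contours.endocardial, centre)(theta)
    r_epi = _polar_radius_fn(contours.epicardial, centre)(theta)
    with np.errstate(divide="ignore", invalid="ignore"):
        return (radius - r_endo) / (r_epi - r_endo)


@dataclass
class SegmentLabelMap:
    """Integer raster of myocardial segment labels (0 = background)."""

    labels: np.ndarray
    names: dict[int, str]
    level: str  # "basal" | "mid" | "apical"

    def present_labels(self) -> np.ndarray:
        return np.unique(self.labels[self.labels > 0])

    def n_segments(self) -> int:
        return len(self.present_labels())


def build_segments(
    contours: ContourSet,
    level: str = "mid",
    raster_shape: tuple[int, int] = (64, 64),
) -> SegmentLabelMap:
    """Assign each myocardial pixel to one equal angular sector.

    Six sectors at basal/mid level, four at the apex, counter-clockwise from
    the reference angle, named per the AHA convention. Pixels straddling a
    sector boundary are assigned by pixel-center angle, ties toward the
    lower label id.
    """
    if level not in ("basal", "mid", "apical"):
        raise ValueError(f"unknown level {level!r}")
    n_sectors = 4 if level == "apical" else 6
    if (contours.epicardial[:, 0].max() > raster_shape[0] - 1
            or contours.epicardial[:, 1].max() > raster_shape[1] - 1
            or contours.epicardial.min() < 0):
        raise ValueError("raster too small to contain the contours")

    depth = transmural_depth(contours, raster_shape)
    theta, _, _ = _pixel_polar(contours, raster_shape)
    myocardium = (depth >= 0.0) & (depth <= 1.0)

    width = 2 * np.pi / n_sectors
    rel = np.mod(theta - np.radians(contours.reference_angle_deg), 2 * np.pi)
    sector = np.floor(rel / width).astype(int)
    on_boundary = np.isclose(np.mod(rel, width), 0.0, atol=1e-12) & (rel > 0)
    sector[on_boundary] -= 1  # ties toward the lower label id
    sector = np.mod(sector, n_sectors)

    labels = np.where(myocardium, sector + 1, 0).astype(np.int16)
    names = {i + 1: SECTOR_NAMES[n_sectors][i] for i in range(n_sectors)}
    return SegmentLabelMap(labels=labels, names=names, level=level)


def exclude_inner_rim(
    labelmap: SegmentLabelMap,
    contours: ContourSet,
    fraction: float = 0.05,
) -> SegmentLabelMap:
    """Remove the innermost wall fraction (blood-pool contamination guard)."""
    if not (0.0 <= fraction < 0.5):
        raise ValueError("fraction must be in [0, 0.5)")
    if fraction == 0.0:
        return SegmentLabelMap(labels=labelmap.labels.copy(),
                               names=dict(labelmap.names), level=labelmap.level)
    depth = transmural_depth(contours, labelmap.labels.shape)
    labels = labelmap.labels.copy()
    labels[(labels > 0) & (depth < fraction)] = 0
    before = set(labelmap.present_labels().tolist())
    after = set(np.unique(labels[labels > 0]).tolist())
    lost = before - after
    if lost:
        lost_names = ", ".join(labelmap.names[i] for i in sorted(lost))
        raise ValueError(f"rim exclusion removed entire segment(s): {lost_names}")
    return SegmentLabelMap(labels=labels, names=dict(labelmap.names), level=labelmap.level)


def split_transmural(
    labelmap: SegmentLabelMap,
    contours: ContourSet,
    depth_threshold: float = 0.5,
) -> SegmentLabelMap:
    """Split each of the six sectors into subendo/subepi halves (12 labels).

    Sector ``s`` keeps label ``s`` for its subepicardial half (depth >=
    threshold) and gets ``s + 6`` for the subendocardial half.
    """
    present = labelmap.present_labels()
    if labelmap.level == "apical" or present.max(initial=0) > 6:
        raise ValueError("transmural split expects a 6-sector basal/mid labelmap")
    depth = transmural_depth(contours, labelmap.labels.shape)
    labels = labelmap.labels.copy().astype(np.int16)
    endo = (labels > 0) & (depth < depth_threshold)
    labels[endo] += 6
    names: dict[int, str] = {}
    for s in present:
        s = int(s)
        epi_n = int(((labels == s)).sum())
        endo_n = int(((labels == s + 6)).sum())
        if epi_n == 0 or endo_n == 0:
            raise ValueError(
                f"sector {labelmap.names[s]} too thin to split transmurally")
        names[s] = f"{labelmap.names[s]}-epi"
        names[s + 6] = f"{labelmap.names[s]}-endo"
    return SegmentLabelMap(labels=labels, names=names, level=labelmap.level)


def exclude_bright_blood(
    labelmap: SegmentLabelMap,
    t2_map: ParameterMap,
    z_threshold: float = 5.0,
) -> SegmentLabelMap:
    """Drop labeled pixels with implausibly bright T2 (stagnant blood signal).

    A pixel is removed when its T2 exceeds the per-slice median of labeled
    valid pixels by more than ``z_threshold`` robust (MAD-based) standard
    deviations. Used on the T2 analysis path only; never adds pixels.
    """
    if t2_map.values.shape != labelmap.labels.shape:
        raise ValueError("t2_map and labelmap are not co-registered")
    labeled = labelmap.labels > 0
    vals = t2_map.values[labeled & t2_map.valid_mask]
    if vals.size == 0:
        raise ValueError("no valid myocardial T2 values to threshold")
    med = np.median(vals)
    mad_sigma = 1.4826 * np.median(np.abs(vals - med))
    mad_sigma = max(mad_sigma, 1e-9 * max(abs(med), 1.0))
    with np.errstate(invalid="ignore"):
        bright = labeled & t2_map.valid_mask & ((t2_map.values - med) / mad_sigma > z_threshold)
    labels = labelmap.labels.copy()
    labels[bright] = 0
    if not (labels > 0).any():
        raise ValueError("bright-blood exclusion emptied the myocardium")
    return SegmentLabelMap(labels=labels, names=dict(labelmap.names), level=labelmap.level)


def segment_statistics(pmap: ParameterMap, labelmap: SegmentLabelMap) -> pd.DataFrame:
    """Per-segment mean/SD/median over valid pixels, with a normality check.

    Returns a table with columns (segment_id, name, n_pixels, mean, sd,
    median, normality_p); the Shapiro-Wilk p documents the per-segment
    normality assumption under which segment means are reported. Segments
    with no valid pixel yield an n=0 NaN row plus a warning — they are never
    silently dropped.
    """
    if pmap.values.shape != labelmap.labels.shape:
        raise ValueError("map and labelmap shapes differ")
    rows = []
    for seg_id in sorted(labelmap.names):
        sel = (labelmap.labels == seg_id) & pmap.valid_mask
        vals = pmap.values[sel]
        n = int(vals.size)
        if n == 0:
            warnings.warn(f"segment {labelmap.names[seg_id]} has no valid pixels")
            rows.append((seg_id, labelmap.names[seg_id], 0,
                         np.nan, np.nan, np.nan, np.nan))
            continue
        p_norm = np.nan
        if 3 <= n <= 5000 and np.ptp(vals) > 0:
            p_norm = float(sps.shapiro(vals).pvalue)
        rows.append((
            seg_id, labelmap.names[seg_id], n,
            float(vals.mean()), float(vals.std(ddof=1)) if n > 1 else 0.0,
            float(np.median(vals)), p_norm,
        ))
    return pd.DataFrame(
        rows,
        columns=["segment_id", "name", "n_pixels", "mean", "sd", "median", "normality_p"],
    )
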