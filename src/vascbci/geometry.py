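"""Stent-to-cortex geometry: line fitting, distances, overlap, width, thickness.

The device is modelled as a 25 mm line through the middle of the sinus —
the mean electrode-to-cortex separation across the whole array, not the
smallest clearance of its nearest contact.  Overlap with cortical regions
is defined purely on the rostro-caudal (coronal) axis: the fraction of
the stent's rostro-caudal extent intersecting each region's band.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

from .types import (
    BAND_LABELS,
    LAT_AXIS,
    RC_AXIS,
    DistanceSummary,
    OverlapSummary,
    StentLine,
    StentSegmentation,
    SurfaceModel,
    VesselModel,
)

LINE_SPACING = 0.5  # mm between stent-line samples: 51 points per 25 mm


def fit_stent_line(
    seg: StentSegmentation,
    vessel: VesselModel,
    length: float = 25.0,
    spacing: float = LINE_SPACING,
) -> StentLine:
    """Fit the device line: start at the centerline point nearest (by
    rostro-caudal station) the most rostral segmentation point, then follow
    the centerline caudally until the arc length reaches ``length``.

    The returned polyline is resampled at ``spacing`` mm of arc length so
    downstream quadrature has sub-millimetre error.
    """
    tip_rc = seg.most_rostral_station()
    pts = vessel.points
    rc = pts[:, RC_AXIS]
    start = int(np.argmin(np.abs(rc - tip_rc)))

    # walk caudally accumulating arc length, interpolating the final point
    path = [pts[start]]
    acc = 0.0
    i = start
    while acc < length:
        if i + 1 >= len(pts):
            raise ValueError("centerline exhausted before reaching the stent length")
        step = np.linalg.norm(pts[i + 1] - pts[i])
        if acc + step >= length:
            frac = (length - acc) / step
            path.append(pts[i] + frac * (pts[i + 1] - pts[i]))
            acc = length
        else:
            path.append(pts[i + 1])
            acc += step
        i += 1
    path = np.asarray(path)

    # resample uniformly in arc length
    seglen = np.linalg.norm(np.diff(path, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seglen)])
    targets = np.arange(0.0, s[-1] + 0.5 * spacing, spacing)
    targets = np.clip(targets, 0.0, s[-1])
    resampled = np.stack(
        [np.interp(targets, s, path[:, k]) for k in range(3)], axis=1
    )
    return StentLine(points=resampled, length=length)


def stent_to_cortex(
    line: StentLine, surface: SurfaceModel, roi: str = "ALL"
) -> DistanceSummary:
    """Stent-to-cortex separation, accounting for cortical folding by
    averaging the two per-hemisphere nearest-vertex distances.

    For each line sample the nearest pial vertex is found per hemisphere
    (restricted to ``roi`` unless ``ALL``).  The summary mean is the
    average over line samples of the two-hemisphere mean; the minimum is
    the global minimum over samples and hemispheres.
    """
    per_hemi: dict[str, np.ndarray] = {}
    for hemi in surface.hemispheres:
        if roi == "ALL":
            verts = hemi.pial
        else:
            m = hemi.roi_mask(roi)
            if not m.any():
                raise ValueError(f"ROI {roi!r} absent from hemisphere {hemi.tag}")
            verts = hemi.pial[m]
        d, _ = cKDTree(verts).query(line.points)
        per_hemi[hemi.tag] = d
    stacked = np.stack([per_hemi["L"], per_hemi["R"]])
    return DistanceSummary(
        mean=float(stacked.mean(axis=0).mean()),
        minimum=float(stacked.min()),
        per_hemisphere_mean={t: float(v.mean()) for t, v in per_hemi.items()},
        roi=roi,
    )


def roi_band_intervals(
    surface: SurfaceModel,
    dorsal_band_halfwidth: float = 15.0,
) -> dict[str, tuple[float, float]]:
    """Estimate each region's rostro-caudal interval from the dorsal strip.

    Vertices within ``dorsal_band_halfwidth`` mm of the midline are binned
    by rostro-caudal station; contiguous runs of a label are bounded at
    midpoints between adjacent stations (outermost edges extended by half
    the local spacing), so exhaustive disjoint bands tile the axis and
    overlap percentages sum to 100.
    """
    stations, labels = [], []
    for hemi in surface.hemispheres:
        keep = np.abs(hemi.pial[:, LAT_AXIS]) <= dorsal_band_halfwidth
        stations.append(hemi.pial[keep, RC_AXIS])
        labels.append(hemi.labels[keep])
    stations = np.concatenate(stations)
    labels = np.concatenate(labels)
    if len(stations) == 0:
        raise ValueError("dorsal band contains no labeled vertices")

    # unique stations (rounded to micron to merge mirrored hemispheres) with
    # the label seen at each station
    key = np.round(stations, 3)
    uniq, idx = np.unique(key, return_index=True)
    lab = labels[idx]
    edges = np.empty(len(uniq) + 1)
    edges[1:-1] = (uniq[:-1] + uniq[1:]) / 2.0
    h0 = uniq[1] - uniq[0] if len(uniq) > 1 else 1.0
    h1 = uniq[-1] - uniq[-2] if len(uniq) > 1 else 1.0
    edges[0] = uniq[0] - h0 / 2.0
    edges[-1] = uniq[-1] + h1 / 2.0

    intervals: dict[str, tuple[float, float]] = {}
    for roi in BAND_LABELS:
        where = np.flatnonzero(lab == roi)
        if len(where) == 0:
            continue
        intervals[roi] = (float(edges[where[0]]), float(edges[where[-1] + 1]))
    return intervals


def interval_overlap(
    stent_interval: tuple[float, float],
    roi_intervals: dict[str, tuple[float, float]],
) -> OverlapSummary:
    """Pure interval arithmetic: percent of the stent interval intersecting
    each region interval."""
    lo, hi = stent_interval
    if hi <= lo:
        raise ValueError("stent interval must have positive width")
    out = {}
    for roi in BAND_LABELS:
        if roi not in roi_intervals:
            out[roi] = 0.0
            continue
        a, b = roi_intervals[roi]
        inter = max(0.0, min(hi, b) - max(lo, a))
        out[roi] = 100.0 * inter / (hi - lo)
    return OverlapSummary(percent=out)


def roi_overlap(
    line: StentLine,
    surface: SurfaceModel,
    dorsal_band_halfwidth: float = 15.0,
) -> OverlapSummary:
    """Percent of the stent's rostro-caudal extent overlapping each band."""
    return interval_overlap(
        line.rc_interval(), roi_band_intervals(surface, dorsal_band_halfwidth)
    )


def sinus_width(vessel: VesselModel, line: StentLine) -> float:
    """Mean sinus width (2 x lumen radius) sampled at each stent-line point."""
    rc_lo, rc_hi = vessel.rc_range()
    stations = line.points[:, RC_AXIS]
    if stations.min() < rc_lo - 1e-6 or stations.max() > rc_hi + 1e-6:
        raise ValueError("stent line extends beyond the vessel centerline")
    return float((2.0 * vessel.radius_at(stations)).mean())


def cortical_thickness(surface: SurfaceModel, roi: str) -> float:
    """Mean per-vertex pial-to-white separation over the region's vertices,
    pooled across hemispheres."""
    dists = []
    for hemi in surface.hemispheres:
        m = hemi.roi_mask(roi) if roi != "ALL" else np.ones(hemi.n_vertices, bool)
        if not m.any():
            raise ValueError(f"ROI {roi!r} absent from hemisphere {hemi.tag}")
        dists.append(np.linalg.norm(hemi.pial[m] - hemi.white[m], axis=1))
    return float(np.concatenate(dists).mean())
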