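"""Slice-based targeting analysis along the rostro-caudal axis.

Activation statistics per region, the dorsal-strip slice activity
profile, its center of gravity (the "ideal" implant station if targeting
were driven by functional activity alone), the slice span of the
implanted stent, the signed distance between the two, and the percent of
stent slices covered by the M1 band.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import LAT_AXIS, RC_AXIS, SliceProfile, StentLine, SurfaceModel

Z_THRESHOLD = 2.3


@dataclass
class SliceGrid:
    """Half-open rostro-caudal slice bins: slice i covers
    [origin + i*spacing, origin + (i+1)*spacing)."""

    origin: float = 0.0
    spacing: float = 1.0
    n_slices: int | None = None

    def bin_of(self, station: float) -> int:
        return int(np.floor((station - self.origin) / self.spacing))

    def slices_intersecting(self, interval: tuple[float, float]) -> np.ndarray:
        """Indices of slices whose bin has positive-length intersection with
        the closed interval."""
        lo, hi = interval
        if hi < lo:
            raise ValueError("interval must be ordered")
        first = self.bin_of(lo)
        # a bin starting exactly at hi intersects only with zero measure
        last = int(np.ceil((hi - self.origin) / self.spacing)) - 1
        last = max(last, first)
        idx = np.arange(first, last + 1)
        if self.n_slices is not None:
            if first < 0 or last >= self.n_slices:
                raise ValueError("interval outside the slice grid")
        return idx

    def nearest_slice(self, station: float) -> int:
        """Slice whose index is nearest ``(station - origin) / spacing``,
        with exact .5 ties resolved to the nearest even index."""
        return int(np.round((station - self.origin) / self.spacing))


@dataclass
class ActivationStats:
    """Per-region activation summary at a fixed z threshold."""

    roi: str
    mean: float
    suprathreshold_count: int
    threshold: float


def roi_activation_stats(
    statmap: np.ndarray,
    labels: np.ndarray,
    roi: str,
    threshold: float = Z_THRESHOLD,
) -> ActivationStats:
    """Mean statistic over the region's elements and the count strictly
    above ``threshold`` (an element exactly at threshold is not counted)."""
    statmap = np.asarray(statmap, dtype=float)
    labels = np.asarray(labels)
    if statmap.shape != labels.shape:
        raise ValueError("statmap and labels must align element-for-element")
    vals = statmap[labels == roi]
    if len(vals) == 0:
        raise ValueError(f"ROI {roi!r} is empty")
    return ActivationStats(
        roi=roi,
        mean=float(vals.mean()),
        suprathreshold_count=int(np.count_nonzero(vals > threshold)),
        threshold=threshold,
    )


def dorsal_strip_profile(
    surface: SurfaceModel,
    statmaps: dict[str, np.ndarray],
    grid: SliceGrid,
    halfwidth: float = 15.0,
    n_slices: int | None = None,
) -> SliceProfile:
    """Project per-vertex activity within the dorsal strip onto slice bins.

    Each slice's value is the mean statistic over strip vertices whose
    rostro-caudal station falls in the slice bin; empty bins get 0.
    """
    stations, values = [], []
    for hemi in surface.hemispheres:
        keep = np.abs(hemi.pial[:, LAT_AXIS]) <= halfwidth
        stations.append(hemi.pial[keep, RC_AXIS])
        values.append(np.asarray(statmaps[hemi.tag])[keep])
    stations = np.concatenate(stations)
    values = np.concatenate(values)
    bins = np.floor((stations - grid.origin) / grid.spacing).astype(int)
    if n_slices is None:
        n_slices = bins.max() + 1
    sums = np.bincount(bins[bins >= 0], weights=values[bins >= 0], minlength=n_slices)
    counts = np.bincount(bins[bins >= 0], minlength=n_slices)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
    centers = grid.origin + (np.arange(n_slices) + 0.5) * grid.spacing
    return SliceProfile(stations=centers, values=means[:n_slices])


def center_of_gravity(profile: SliceProfile, clamp_negative: bool = True) -> float:
    """Mass-weighted mean station of the profile.

    Negative values are clamped to zero by default so the profile behaves
    as a mass distribution; pass ``clamp_negative=False`` to require a
    non-negative profile instead.
    """
    w = profile.values.copy()
    if clamp_negative:
        w = np.clip(w, 0.0, None)
    elif np.any(w < 0):
        raise ValueError("profile has negative mass and clamping is disabled")
    total = w.sum()
    if total <= 0:
        raise ValueError("profile has zero total mass")
    return float((w * profile.stations).sum() / total)


def stent_slice_span(
    line: StentLine, grid: SliceGrid
) -> tuple[np.ndarray, int]:
    """Slices intersected by the stent's rostro-caudal interval, plus the
    slice nearest the interval midpoint (nearest-even on exact ties)."""
    interval = line.rc_interval()
    slices = grid.slices_intersecting(interval)
    midpoint = (interval[0] + interval[1]) / 2.0
    return slices, grid.nearest_slice(midpoint)


def cog_to_stent_distance(cog_station: float, stent_mid_station: float) -> float:
    """Signed separation in mm: positive when the activity centroid lies
    rostral of the stent midpoint."""
    return float(cog_station - stent_mid_station)


def stent_m1_slice_overlap(
    stent_slices: np.ndarray, m1_slices: np.ndarray
) -> float:
    """Percent of stent slices that are also M1 slices."""
    stent_slices = np.asarray(stent_slices)
    if len(stent_slices) == 0:
        raise ValueError("stent slice set is empty")
    inter = np.intersect1d(stent_slices, np.asarray(m1_slices))
    return float(100.0 * len(inter) / len(stent_slices))
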