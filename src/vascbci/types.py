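"""Core domain containers shared by every analysis stage.

Coordinate convention (used throughout the package): RAS millimetres.
The rostro-caudal ("coronal") axis is ``y`` — anterior positive,
posterior negative.  The midline plane is ``x = 0``; dorsal is ``+z``.
Slice grids bin the rostro-caudal axis into half-open mm intervals,
indexed from 0 at the configured origin.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: rostro-caudal axis index within RAS coordinate triples
RC_AXIS = 1
#: lateral (left-right) axis index
LAT_AXIS = 0

#: canonical region labels, rostral to caudal bands plus everything else
ROI_LABELS = ("SMA", "M1", "S1", "CAUDAL", "OTHER")
#: the four exhaustive rostro-caudal bands used for overlap accounting
BAND_LABELS = ("SMA", "M1", "S1", "CAUDAL")

MOVE = "MOVE"
REST = "REST"


@dataclass
class Hemisphere:
    """One cortical hemisphere as a paired pial/white triangle mesh.

    ``pial`` and ``white`` are (n, 3) vertex arrays in mm with identical
    vertex count and ordering, so vertex ``i`` of one surface corresponds
    to vertex ``i`` of the other.  ``labels`` holds one region name from
    :data:`ROI_LABELS` per vertex.
    """

    pial: np.ndarray
    white: np.ndarray
    triangles: np.ndarray
    labels: np.ndarray
    tag: str  # "L" or "R"

    def __post_init__(self) -> None:
        self.pial = np.asarray(self.pial, dtype=float)
        self.white = np.asarray(self.white, dtype=float)
        self.triangles = np.asarray(self.triangles, dtype=np.int64)
        self.labels = np.asarray(self.labels)
        if self.pial.shape != self.white.shape:
            raise ValueError("pial and white surfaces must pair vertex-for-vertex")
        if len(self.labels) != len(self.pial):
            raise ValueError("one label required per vertex")
        if self.tag not in ("L", "R"):
            raise ValueError(f"hemisphere tag must be 'L' or 'R', got {self.tag!r}")
        if not np.all(np.isfinite(self.pial)) or not np.all(np.isfinite(self.white)):
            raise ValueError("surface coordinates must be finite")
        if self.triangles.size and (
            self.triangles.min() < 0 or self.triangles.max() >= len(self.pial)
        ):
            raise ValueError("triangle indices out of range")
        bad = set(np.unique(self.labels)) - set(ROI_LABELS)
        if bad:
            raise ValueError(f"unknown ROI labels: {sorted(bad)}")

    @property
    def n_vertices(self) -> int:
        return len(self.pial)

    def roi_mask(self, roi: str) -> np.ndarray:
        return self.labels == roi


@dataclass
class SurfaceModel:
    """Paired left/right hemisphere meshes with per-vertex ROI labels."""

    left: Hemisphere
    right: Hemisphere

    def __post_init__(self) -> None:
        if self.left.tag != "L" or self.right.tag != "R":
            raise ValueError("hemispheres must carry tags 'L' and 'R'")

    @property
    def hemispheres(self) -> tuple[Hemisphere, Hemisphere]:
        return (self.left, self.right)

    def rc_extent(self) -> tuple[float, float]:
        """Rostro-caudal extent (caudal_min, rostral_max) over both pial sheets."""
        stations = np.concatenate(
            [self.left.pial[:, RC_AXIS], self.right.pial[:, RC_AXIS]]
        )
        return float(stations.min()), float(stations.max())


@dataclass
class VesselModel:
    """A vessel centerline with per-point lumen radii.

    Points are ordered rostral to caudal: the rostro-caudal coordinate is
    strictly decreasing along the point order.
    """

    points: np.ndarray
    radii: np.ndarray

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.radii = np.asarray(self.radii, dtype=float)
        if len(self.points) < 2:
            raise ValueError("centerline needs at least two points")
        if len(self.radii) != len(self.points):
            raise ValueError("one lumen radius required per centerline point")
        if np.any(self.radii <= 0):
            raise ValueError("lumen radii must be positive")
        rc = self.points[:, RC_AXIS]
        if not np.all(np.diff(rc) < 0):
            raise ValueError("centerline must run strictly rostral to caudal")

    def rc_range(self) -> tuple[float, float]:
        rc = self.points[:, RC_AXIS]
        return float(rc[-1]), float(rc[0])

    def radius_at(self, rc_station: np.ndarray | float) -> np.ndarray:
        """Lumen radius linearly interpolated at rostro-caudal station(s)."""
        rc = self.points[::-1, RC_AXIS]  # increasing for np.interp
        return np.interp(rc_station, rc, self.radii[::-1])


@dataclass
class StentSegmentation:
    """Unordered imaged-device point cloud (mm)."""

    points: np.ndarray

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim == 1:
            self.points = self.points.reshape(1, -1)
        if len(self.points) == 0:
            raise ValueError("segmentation must contain at least one point")

    def most_rostral_station(self) -> float:
        return float(self.points[:, RC_AXIS].max())


@dataclass
class Epoch:
    start: float
    end: float
    label: str

    @property
    def duration(self) -> float:
        return self.end - self.start

    def contains_onset(self, t: float) -> bool:
        """Half-open membership [start, end): no event is counted twice."""
        return self.start <= t < self.end


@dataclass
class EpochSchedule:
    """Ordered, non-overlapping move/rest cue intervals."""

    epochs: list[Epoch]

    def __post_init__(self) -> None:
        if not self.epochs:
            raise ValueError("schedule must contain at least one epoch")
        prev_end = -np.inf
        for ep in self.epochs:
            if ep.label not in (MOVE, REST):
                raise ValueError(f"epoch label must be MOVE or REST, got {ep.label!r}")
            if ep.end <= ep.start:
                raise ValueError("epochs must have positive duration")
            if ep.start < prev_end:
                raise ValueError("epochs must be ordered and non-overlapping")
            prev_end = ep.end

    def __iter__(self):
        return iter(self.epochs)

    def __len__(self) -> int:
        return len(self.epochs)

    @property
    def end(self) -> float:
        return self.epochs[-1].end

    def of_label(self, label: str) -> list[Epoch]:
        return [ep for ep in self.epochs if ep.label == label]

    @classmethod
    def block_design(
        cls,
        move_s: float = 10.0,
        rest_s: float = 10.0,
        repetitions: int = 10,
        start: float = 0.0,
    ) -> "EpochSchedule":
        """The cued paradigm: ``move_s`` s of attempted movement followed by
        ``rest_s`` s of rest, repeated ``repetitions`` times."""
        epochs, t = [], start
        for _ in range(repetitions):
            epochs.append(Epoch(t, t + move_s, MOVE))
            t += move_s
            epochs.append(Epoch(t, t + rest_s, REST))
            t += rest_s
        return cls(epochs)


@dataclass
class Recording:
    """Multichannel field-potential recording in microvolts.

    ``data`` has shape (n_channels, n_samples).  ``active`` marks channels
    with a live electrode connection; inactive channels carry noise only.
    ``planted_bursts`` (synthetic recordings only) stores the ground-truth
    burst onset times per channel.
    """

    data: np.ndarray
    fs: float
    active: np.ndarray
    planted_bursts: list[np.ndarray] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be (n_channels, n_samples)")
        self.active = np.asarray(self.active, dtype=bool)
        if len(self.active) != self.n_channels:
            raise ValueError("active mask length must equal channel count")
        if self.fs <= 400:
            raise ValueError(
                "sampling rate must exceed 400 Hz (twice the 200 Hz band edge)"
            )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    @property
    def n_active(self) -> int:
        return int(self.active.sum())


@dataclass
class StentLine:
    """The device modelled as an ordered centerline polyline of fixed arc
    length, running rostral to caudal inside the lumen."""

    points: np.ndarray
    length: float = 25.0

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if len(self.points) < 2:
            raise ValueError("stent line needs at least two points")

    @property
    def arc_length(self) -> float:
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())

    @property
    def rostral_tip(self) -> np.ndarray:
        return self.points[0]

    def rc_interval(self) -> tuple[float, float]:
        """Projection onto the rostro-caudal axis as (caudal, rostral)."""
        rc = self.points[:, RC_AXIS]
        return float(rc.min()), float(rc.max())


@dataclass
class SliceProfile:
    """Per-slice mean activity along the rostro-caudal axis."""

    stations: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.stations = np.asarray(self.stations, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.stations) != len(self.values):
            raise ValueError("one value per slice station required")
        if len(self.stations) and not np.all(np.diff(self.stations) > 0):
            raise ValueError("slice stations must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("slice activity must be finite")


@dataclass
class DistanceSummary:
    """Stent-to-cortex separation summary (mm)."""

    mean: float
    minimum: float
    per_hemisphere_mean: dict[str, float] = field(default_factory=dict)
    roi: str = "ALL"

    def __post_init__(self) -> None:
        if self.minimum > self.mean + 1e-9:
            raise ValueError("minimum distance cannot exceed the mean")


@dataclass
class OverlapSummary:
    """Percent of the stent's rostro-caudal extent overlapping each band."""

    percent: dict[str, float]

    def __post_init__(self) -> None:
        for roi, val in self.percent.items():
            if not -1e-9 <= val <= 100 + 1e-9:
                raise ValueError(f"overlap percent out of range for {roi}: {val}")

    def __getitem__(self, roi: str) -> float:
        return self.percent[roi]
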