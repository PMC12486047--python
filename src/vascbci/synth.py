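"""Synthetic-cohort generators with known ground truth.

Every generator is deterministic given its seed: the same seed and
configuration produce bitwise-identical arrays.  The generators emulate
the statistical structure the downstream analyses assume — folded
two-hemisphere surfaces with rostro-caudal region bands, a midline
venous sinus carrying a stent, cued move/rest recordings with planted
high-gamma burst-rate modulation, unimodal slice activity profiles, and
a covariate table with a planted monotone overlap-to-strength relation —
without claiming anatomical realism.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy import signal as sps
from scipy.ndimage import uniform_filter1d

from .types import (
    BAND_LABELS,
    LAT_AXIS,
    MOVE,
    RC_AXIS,
    REST,
    EpochSchedule,
    Hemisphere,
    Recording,
    SliceProfile,
    StentSegmentation,
    SurfaceModel,
    VesselModel,
)

#: rostro-caudal band extents (mm), rostral to caudal: SMA, M1, S1, then
#: everything caudal of S1.  Half-open [lo, hi) assignment.
DEFAULT_BANDS: dict[str, tuple[float, float]] = {
    "SMA": (45.0, 70.0),
    "M1": (20.0, 45.0),
    "S1": (5.0, 20.0),
    "CAUDAL": (-40.0, 5.0),
}


def _validate_bands(bands: dict[str, tuple[float, float]]) -> None:
    for roi in BAND_LABELS:
        if roi not in bands:
            raise ValueError(f"band extents must include {roi}")
    order = [bands[r] for r in BAND_LABELS]
    for (lo, hi) in order:
        if hi <= lo:
            raise ValueError("each band must have positive width")
    # rostral to caudal: each band must sit caudal of the previous one
    for (lo_r, _), (_, hi_c) in zip(order, order[1:]):
        if hi_c > lo_r:
            raise ValueError("bands overlap or are out of rostro-caudal order")


def _label_by_band(stations: np.ndarray, bands: dict[str, tuple[float, float]]) -> np.ndarray:
    labels = np.full(len(stations), "OTHER", dtype="U6")
    for roi in BAND_LABELS:
        lo, hi = bands[roi]
        labels[(stations >= lo) & (stations < hi)] = roi
    return labels


def _grid_triangles(n_rc: int, n_lat: int) -> np.ndarray:
    """Triangulate an (n_rc x n_lat) vertex grid."""
    idx = np.arange(n_rc * n_lat).reshape(n_rc, n_lat)
    a = idx[:-1, :-1].ravel()
    b = idx[1:, :-1].ravel()
    c = idx[:-1, 1:].ravel()
    d = idx[1:, 1:].ravel()
    return np.concatenate(
        [np.stack([a, b, c], axis=1), np.stack([b, d, c], axis=1)]
    )


def generate_surface(
    bands: dict[str, tuple[float, float]] | None = None,
    fold_amplitude: float = 2.0,
    thickness: float = 2.5,
    *,
    station_range: tuple[float, float] = (-40.0, 70.0),
    lateral_range: tuple[float, float] = (3.0, 35.0),
    spacing: float = 1.5,
    fold_wavelength: float = 12.0,
    dome_height: float = 30.0,
    dome_curvature: float = 0.012,
    jitter: float = 0.0,
    seed: int = 0,
) -> SurfaceModel:
    """Generate a folded two-hemisphere surface with rostro-caudal ROI bands.

    Each hemisphere is a rectangular sheet of vertices mirrored about the
    midline plane ``x = 0``.  The pial surface is a lateral dome modulated
    by sinusoidal rostro-caudal folds of ``fold_amplitude`` mm; the white
    surface is the pial surface offset inward along per-vertex normals by
    ``thickness`` mm.  Vertex labels are assigned by half-open rostro-caudal
    band ``[lo, hi)`` with everything outside the four bands ``OTHER``.

    Parameters
    ----------
    bands
        ``{roi: (lo, hi)}`` rostro-caudal extents in mm for SMA, M1, S1 and
        CAUDAL, ordered rostral to caudal.  Defaults to
        :data:`DEFAULT_BANDS`.
    thickness
        Pial-to-white offset in mm; must be positive.
    jitter
        Optional isotropic vertex jitter SD (mm) for irregular test meshes.
    """
    if thickness <= 0:
        raise ValueError("cortical thickness must be positive")
    bands = dict(DEFAULT_BANDS if bands is None else bands)
    _validate_bands(bands)
    rng = np.random.default_rng(seed)

    rc = np.arange(station_range[0], station_range[1] + 0.5 * spacing, spacing)
    lat = np.arange(lateral_range[0], lateral_range[1] + 0.5 * spacing, spacing)
    rc_g, lat_g = np.meshgrid(rc, lat, indexing="ij")

    z = (
        dome_height
        - dome_curvature * lat_g**2
        + fold_amplitude * np.sin(2 * math.pi * rc_g / fold_wavelength)
    )
    verts_r = np.stack([lat_g.ravel(), rc_g.ravel(), z.ravel()], axis=1)
    if jitter > 0:
        verts_r = verts_r + rng.normal(0.0, jitter, size=verts_r.shape)
    tris = _grid_triangles(len(rc), len(lat))

    hemis = {}
    for tag, sign in (("R", 1.0), ("L", -1.0)):
        pial = verts_r.copy()
        pial[:, LAT_AXIS] *= sign
        mesh = trimesh.Trimesh(vertices=pial, faces=tris, process=False)
        normals = np.array(mesh.vertex_normals, dtype=float)
        # orient normals outward (away from the interhemispheric interior):
        # outward here means dorsally, +z on the dome
        flip = normals[:, 2] < 0
        normals[flip] *= -1.0
        white = pial - thickness * normals
        labels = _label_by_band(pial[:, RC_AXIS], bands)
        hemis[tag] = Hemisphere(pial=pial, white=white, triangles=tris, labels=labels, tag=tag)
    return SurfaceModel(left=hemis["L"], right=hemis["R"])


def generate_flat_surface(
    bands: dict[str, tuple[float, float]] | None = None,
    thickness: float = 2.5,
    **kwargs,
) -> SurfaceModel:
    """Degenerate fold-free surface: flat sheets, exact vertical normals."""
    return generate_surface(bands, fold_amplitude=0.0, thickness=thickness,
                            dome_curvature=0.0, **kwargs)


def generate_vessel_and_stent(
    surface: SurfaceModel,
    lumen_radius: float = 3.55,
    stent_length: float = 25.0,
    rostral_tip: float = 45.0,
    *,
    clearance: float = 2.0,
    centerline_spacing: float = 1.0,
    n_stent_points: int = 200,
    seed: int = 0,
) -> tuple[VesselModel, StentSegmentation]:
    """Generate a midline sinus centerline and a stent point cloud on its wall.

    The centerline runs along the midline above the surfaces, its dorsal
    height following the surface dorsal profile (so a fold-free surface
    yields a collinear centerline).  Stent points are scattered on the
    lumen wall — at exactly ``lumen_radius`` from the local centerline —
    spanning ``[rostral_tip - stent_length, rostral_tip]`` rostro-caudally.
    """
    if lumen_radius <= 0:
        raise ValueError("lumen radius must be positive")
    caudal_min, rostral_max = surface.rc_extent()
    if not (caudal_min <= rostral_tip <= rostral_max):
        raise ValueError("rostral tip outside surface rostro-caudal extent")
    if rostral_tip - stent_length < caudal_min:
        raise ValueError("stent extent falls outside the centerline extent")
    rng = np.random.default_rng(seed)

    # dorsal profile: max pial height near the midline, per station bin.
    # The sinus sits in the dural space and bridges sulci, so the profile
    # is smoothed over ~15 mm before the centerline follows it.
    pial = np.concatenate([surface.left.pial, surface.right.pial])
    near = np.abs(pial[:, LAT_AXIS]) <= np.abs(pial[:, LAT_AXIS]).min() + 1e-6
    prof_rc = pial[near, RC_AXIS]
    prof_z = pial[near, 2]
    order = np.argsort(prof_rc)
    prof_rc, prof_z = prof_rc[order], prof_z[order]

    rc = np.arange(rostral_max, caudal_min - 0.5 * centerline_spacing, -centerline_spacing)
    z = np.interp(rc, prof_rc, prof_z)
    win = max(int(round(15.0 / centerline_spacing)), 1)
    z = uniform_filter1d(z, size=win, mode="nearest")
    z = z + clearance + lumen_radius
    centerline = np.stack([np.zeros_like(rc), rc, z], axis=1)
    radii = np.full(len(rc), float(lumen_radius))
    vessel = VesselModel(points=centerline, radii=radii)

    # stent points on the lumen wall, uniform in station and wall angle
    st_rc = rng.uniform(rostral_tip - stent_length, rostral_tip, size=n_stent_points)
    # guarantee the span endpoints are present so the extent is exact
    st_rc[0], st_rc[1] = rostral_tip, rostral_tip - stent_length
    theta = rng.uniform(0.0, 2 * math.pi, size=n_stent_points)
    st_z = np.interp(st_rc, rc[::-1], z[::-1])
    centers = np.stack([np.zeros_like(st_rc), st_rc, st_z], axis=1)
    # local wall frame: lateral unit and dorsal unit (centerline is nearly
    # axial, so this is within curvature error of the exact normal plane)
    offset = np.stack(
        [np.cos(theta), np.zeros_like(theta), np.sin(theta)], axis=1
    ) * lumen_radius
    seg = StentSegmentation(points=centers + offset)
    return vessel, seg


@dataclass
class BurstParams:
    """Shape of the planted high-gamma burst events.

    A burst is a Gaussian-windowed tone at ``tone_hz`` lasting
    ``duration_s`` seconds, scaled to ``amplitude_snr`` times the in-band
    (100-200 Hz) noise standard deviation.
    """

    tone_hz: float = 150.0
    duration_s: float = 0.08
    amplitude_snr: float = 5.0


def _pink_noise(rng: np.random.Generator, n_channels: int, n_samples: int,
                fs: float, rms: float, white_floor: float = 0.15) -> np.ndarray:
    """1/f-amplitude noise with a white floor, scaled to the requested RMS."""
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    shape = np.empty_like(freqs)
    shape[0] = 0.0
    shape[1:] = 1.0 / np.sqrt(freqs[1:]) + white_floor
    spec = rng.normal(size=(n_channels, len(freqs))) + 1j * rng.normal(
        size=(n_channels, len(freqs))
    )
    x = np.fft.irfft(spec * shape, n=n_samples, axis=1)
    x *= rms / x.std(axis=1, keepdims=True)
    return x


def _burst_waveform(fs: float, params: BurstParams, phase: float) -> np.ndarray:
    n = max(int(round(params.duration_s * fs)), 3)
    t = np.arange(n) / fs
    mid = t[-1] / 2.0
    window = np.exp(-0.5 * ((t - mid) / (params.duration_s / 6.0)) ** 2)
    return window * np.cos(2 * math.pi * params.tone_hz * t + phase)


def generate_recording(
    schedule: EpochSchedule,
    n_channels: int = 16,
    n_active: int = 16,
    fs: float = 1000.0,
    rest_burst_rate: float = 0.5,
    move_burst_rate: float = 3.0,
    burst_params: BurstParams | None = None,
    *,
    noise_rms: float = 10.0,
    seed: int = 0,
) -> Recording:
    """Generate a cued-block recording with planted burst-rate modulation.

    All channels carry pink background noise.  On each active channel,
    band-limited burst events are inserted as an independent Poisson
    process at ``rest_burst_rate`` during REST epochs and
    ``move_burst_rate`` during MOVE epochs.  Planted burst onset times are
    stored on the returned recording as ground truth.
    """
    if n_active > n_channels:
        raise ValueError("n_active cannot exceed n_channels")
    if move_burst_rate < 0 or rest_burst_rate < 0:
        raise ValueError("burst rates must be non-negative")
    if fs <= 400:
        raise ValueError("sampling rate must exceed 400 Hz")
    burst_params = burst_params or BurstParams()
    rng = np.random.default_rng(seed)

    n_samples = int(round(schedule.end * fs))
    data = _pink_noise(rng, n_channels, n_samples, fs, noise_rms)

    # in-band noise SD measured on one channel sets the burst amplitude
    sos = sps.butter(4, [100.0, 200.0], btype="bandpass", fs=fs, output="sos")
    inband_sd = float(sps.sosfiltfilt(sos, data[0]).std())

    active_idx = rng.choice(n_channels, size=n_active, replace=False)
    active = np.zeros(n_channels, dtype=bool)
    active[active_idx] = True

    planted: list[np.ndarray] = [np.empty(0) for _ in range(n_channels)]
    for ch in np.sort(active_idx):
        onsets = []
        for ep in schedule:
            rate = move_burst_rate if ep.label == MOVE else rest_burst_rate
            n_ev = rng.poisson(rate * ep.duration)
            onsets.extend(rng.uniform(ep.start, ep.end, size=n_ev))
        onsets = np.sort(np.asarray(onsets, dtype=float))
        planted[ch] = onsets
        amp = burst_params.amplitude_snr * inband_sd
        for t0 in onsets:
            wav = amp * _burst_waveform(fs, burst_params, rng.uniform(0, 2 * math.pi))
            i0 = int(round(t0 * fs))
            i1 = min(i0 + len(wav), n_samples)
            if i0 < n_samples:
                data[ch, i0:i1] += wav[: i1 - i0]

    return Recording(data=data, fs=fs, active=active, planted_bursts=planted)


def generate_slice_profile(
    n_slices: int,
    peak_slice: float,
    spread: float,
    noise_sd: float = 0.0,
    *,
    amplitude: float = 3.0,
    seed: int = 0,
) -> SliceProfile:
    """Unimodal per-slice activity: a Gaussian bump plus truncated noise.

    ``spread`` is the Gaussian SD in slice units; ``spread == 0`` puts all
    mass in the ``peak_slice`` bin.  Values are clamped at zero so the
    profile can serve as a mass distribution.
    """
    if spread < 0:
        raise ValueError("spread must be non-negative")
    if not 0 <= peak_slice < n_slices:
        raise ValueError("peak_slice must lie within [0, n_slices)")
    rng = np.random.default_rng(seed)
    idx = np.arange(n_slices, dtype=float)
    if spread == 0:
        bump = np.zeros(n_slices)
        bump[int(round(peak_slice))] = amplitude
    else:
        bump = amplitude * np.exp(-0.5 * ((idx - peak_slice) / spread) ** 2)
    values = bump + rng.normal(0.0, noise_sd, size=n_slices)
    return SliceProfile(stations=idx, values=np.clip(values, 0.0, None))


def generate_vertex_statmap(
    surface: SurfaceModel,
    peak_station: float,
    spread: float = 8.0,
    amplitude: float = 4.0,
    noise_sd: float = 0.4,
    *,
    seed: int = 0,
) -> dict[str, np.ndarray]:
    """Per-vertex z-statistic maps emulating a movement-vs-rest contrast:
    a rostro-caudal Gaussian ridge of activity centred at ``peak_station``
    that falls off laterally, plus noise.  Returns ``{'L': ..., 'R': ...}``."""
    rng = np.random.default_rng(seed)
    maps = {}
    for hemi in surface.hemispheres:
        rc = hemi.pial[:, RC_AXIS]
        lat = np.abs(hemi.pial[:, LAT_AXIS])
        ridge = amplitude * np.exp(-0.5 * ((rc - peak_station) / spread) ** 2)
        ridge *= np.exp(-0.5 * (lat / 20.0) ** 2)
        maps[hemi.tag] = ridge + rng.normal(0.0, noise_sd, size=len(rc))
    return maps


def dprime_to_move_rate(
    d_target: float, rest_rate: float, n_active: int, epoch_s: float = 10.0
) -> float:
    """Invert the Poisson-count model of the sensitivity index.

    With burst counts pooled over ``n_active`` channels in epochs of
    ``epoch_s`` seconds, the expected index for per-channel rates
    (r_move, r_rest) is ``sqrt(epoch_s * 2 * n_active) * (r_m - r_r) /
    sqrt(r_m + r_r)``.  Given a target index and the rest rate this solves
    for the move rate in closed form.
    """
    if d_target < 0:
        raise ValueError("target index must be non-negative under this inversion")
    s = d_target / math.sqrt(2.0 * epoch_s * n_active)
    x = (s + math.sqrt(s * s + 8.0 * rest_rate)) / 2.0  # sqrt(r_m + r_r)
    return x * x - rest_rate


@dataclass
class PlantedRelation:
    """Ground-truth linear relation strength = a + b * (M1 overlap %) + noise."""

    intercept: float = 0.2
    slope: float = 0.05
    noise_sd: float = 0.3


@dataclass
class Participant:
    """One synthetic participant: covariates, scene geometry and the
    parameters needed to synthesise their recordings on demand."""

    pid: str
    years_since_diagnosis: float
    muscle_strength: int
    n_active: int
    m1_overlap_target: float
    planted_strength: float
    rest_burst_rate: float
    move_burst_rate: float
    thickness: float
    surface: SurfaceModel
    vessel: VesselModel
    stent_seg: StentSegmentation
    statmaps: dict[str, np.ndarray]
    recording_seed: int
    n_channels: int = 16

    def make_recording(
        self, schedule: EpochSchedule, session: int = 0, fs: float = 1000.0
    ) -> Recording:
        """Synthesise one test-block recording (seeded per session)."""
        return generate_recording(
            schedule,
            n_channels=self.n_channels,
            n_active=self.n_active,
            fs=fs,
            rest_burst_rate=self.rest_burst_rate,
            move_burst_rate=self.move_burst_rate,
            seed=(self.recording_seed + 1009 * session) % (2**31),
        )


@dataclass
class CohortConfig:
    """Study-condition defaults for the synthetic cohort.

    Covariate ranges follow the printed cohort: years since diagnosis
    uniform on [1, 12]; residual muscle strength an integer 0-50 declining
    with disease duration; active channels uniform integers on [9, 16].
    """

    n_participants: int = 10
    relation: PlantedRelation = field(default_factory=PlantedRelation)
    overlap_range: tuple[float, float] = (10.0, 95.0)
    rest_burst_rate: float = 0.5
    bands: dict[str, tuple[float, float]] | None = None
    fold_amplitude: float = 2.0
    base_thickness: float = 3.2
    atrophy_per_year: float = 0.09
    lumen_radius_mean: float = 3.55
    lumen_radius_sd: float = 0.45
    tip_jitter_sd: float = 1.5
    #: probability a placement approaches M1 from the rostral side
    #: (overshooting into SMA) rather than the caudal side (through S1)
    rostral_placement_prob: float = 0.3


def generate_cohort(
    n_participants: int = 10,
    relation: PlantedRelation | None = None,
    config: CohortConfig | None = None,
    *,
    seed: int = 0,
) -> list[Participant]:
    """Generate a synthetic cohort with a planted overlap-to-strength relation.

    Each participant receives a surface (thickness declining with years
    since diagnosis, emulating motor-cortical atrophy), a sinus and stent
    placed so the M1 overlap is drawn across ``overlap_range``, a vertex
    activity map, and burst rates chosen so the expected sensitivity index
    equals the planted strength ``a + b * overlap + noise``.
    """
    config = config or CohortConfig()
    if relation is not None:
        config.relation = relation
    if n_participants < 3:
        raise ValueError("a cohort needs at least three participants")
    lo, hi = config.overlap_range
    if hi <= lo:
        raise ValueError("overlap range must have positive width")
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(3 * n_participants)]

    bands = dict(DEFAULT_BANDS if config.bands is None else config.bands)
    m1_lo, m1_hi = bands["M1"]
    participants = []
    for i in range(n_participants):
        years = float(rng.uniform(1.0, 12.0))
        muscle = int(np.clip(round(50 - 3.3 * years + rng.normal(0, 4)), 0, 50))
        n_active = int(rng.integers(9, 17))
        # stent placement: the M1 intersection fraction is drawn across the
        # configured range and realised either from the caudal side (excess
        # extent in S1/caudal territory) or, with some probability, from
        # the rostral side (overshooting into SMA); the planted strength
        # follows the *realized* overlap after placement jitter
        stent_len = 25.0
        f = rng.uniform(lo, hi) / 100.0
        if rng.uniform() < config.rostral_placement_prob:
            tip = m1_hi + (1.0 - f) * stent_len
        else:
            tip = m1_lo + f * stent_len
        tip += rng.normal(0.0, config.tip_jitter_sd)
        rc_lo, rc_hi = bands["CAUDAL"][0], bands["SMA"][1]
        tip = float(np.clip(tip, rc_lo + stent_len + 1.0, rc_hi - 0.5))
        overlap = (
            100.0
            * max(0.0, min(m1_hi, tip) - max(m1_lo, tip - stent_len))
            / stent_len
        )
        lumen_radius = float(
            np.clip(rng.normal(config.lumen_radius_mean, config.lumen_radius_sd), 2.5, 4.8)
        )
        thickness = float(
            np.clip(
                config.base_thickness - config.atrophy_per_year * years + rng.normal(0, 0.15),
                1.2,
                4.5,
            )
        )
        strength = max(
            0.05,
            config.relation.intercept
            + config.relation.slope * overlap
            + rng.normal(0, config.relation.noise_sd),
        )
        move_rate = dprime_to_move_rate(strength, config.rest_burst_rate, n_active)

        surf = generate_surface(
            bands,
            fold_amplitude=config.fold_amplitude,
            thickness=thickness,
            seed=child_seeds[3 * i],
        )
        vessel, seg = generate_vessel_and_stent(
            surf,
            lumen_radius=lumen_radius,
            stent_length=stent_len,
            rostral_tip=tip,
            seed=child_seeds[3 * i + 1],
        )
        peak = float(rng.normal((m1_lo + m1_hi) / 2.0, 8.0))
        statmaps = generate_vertex_statmap(
            surf, peak_station=peak, seed=child_seeds[3 * i + 1]
        )
        participants.append(
            Participant(
                pid=f"S{i + 1:02d}",
                years_since_diagnosis=years,
                muscle_strength=muscle,
                n_active=n_active,
                m1_overlap_target=overlap,
                planted_strength=strength,
                rest_burst_rate=config.rest_burst_rate,
                move_burst_rate=move_rate,
                thickness=thickness,
                surface=surf,
                vessel=vessel,
                stent_seg=seg,
                statmaps=statmaps,
                recording_seed=child_seeds[3 * i + 2],
            )
        )
    return participants
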