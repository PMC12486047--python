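"""Motor signal strength: high-gamma burst-density sensitivity index.

The statistic chain is: zero-phase band-pass to the high-gamma band
(100-200 Hz), envelope burst detection against a rest-epoch baseline,
per-epoch burst-count densities for move and rest cues, and a
sensitivity index d' comparing the two density distributions.  A
participant's motor signal strength is the best block-level d' across
sessions, and a per-participant Wilcoxon signed-rank test asks whether
session values exceed zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy import stats as spstats
from scipy.ndimage import uniform_filter1d

from .types import MOVE, REST, EpochSchedule, Recording

HIGH_GAMMA = (100.0, 200.0)


@dataclass
class BurstSeries:
    """Per-channel burst onset times and durations (seconds)."""

    onsets: list[np.ndarray]
    durations: list[np.ndarray]
    degenerate: np.ndarray | None = None  # channels with zero baseline spread

    def __post_init__(self) -> None:
        for ons in self.onsets:
            if len(ons) > 1 and not np.all(np.diff(ons) > 0):
                raise ValueError("burst onsets must be strictly increasing")
        if self.degenerate is None:
            self.degenerate = np.zeros(len(self.onsets), dtype=bool)

    @property
    def n_channels(self) -> int:
        return len(self.onsets)


@dataclass
class BurstConfig:
    """Burst-detection operator parameters.

    The envelope is a moving-RMS of the band-passed signal; a burst is an
    excursion above ``baseline median + threshold_k * robust SD`` lasting
    at least ``min_duration_s``, with excursions closer than
    ``merge_gap_s`` merged.
    """

    threshold_k: float = 3.0
    min_duration_s: float = 0.02
    merge_gap_s: float = 0.01
    envelope_window_s: float = 0.02


@dataclass
class SignalStrengthResult:
    """Block-level motor signal strength and its intermediates."""

    dprime: float
    move_densities: np.ndarray
    rest_densities: np.ndarray
    aggregation: str
    degenerate: bool = False
    extras: dict = field(default_factory=dict)


def bandpass_highgamma(
    recording: Recording, band: tuple[float, float] = HIGH_GAMMA, order: int = 4
) -> Recording:
    """Zero-phase band-pass of every channel to the high-gamma band.

    Uses a Butterworth filter applied forward and backward (``sosfiltfilt``),
    so the effective magnitude response is the squared single-pass response
    and the phase is zero.
    """
    lo, hi = band
    if hi <= lo or lo <= 0:
        raise ValueError("band must satisfy 0 < low < high")
    if recording.fs <= 2 * hi:
        raise ValueError("sampling rate must exceed twice the band upper edge")
    sos = sps.butter(order, [lo, hi], btype="bandpass", fs=recording.fs, output="sos")
    filtered = sps.sosfiltfilt(sos, recording.data, axis=1)
    return Recording(
        data=filtered,
        fs=recording.fs,
        active=recording.active.copy(),
        planted_bursts=recording.planted_bursts,
    )


def envelope(filtered: Recording, window_s: float = 0.02) -> np.ndarray:
    """Moving-RMS envelope of each channel (same shape as the data)."""
    n = max(int(round(window_s * filtered.fs)), 1)
    sq = uniform_filter1d(filtered.data**2, size=n, axis=1, mode="nearest")
    return np.sqrt(sq)


def _excursions(above: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as half-open index intervals."""
    if not above.any():
        return []
    d = np.diff(above.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    ends = list(np.flatnonzero(d == -1) + 1)
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(len(above))
    return list(zip(starts, ends))


def detect_bursts(
    filtered: Recording,
    schedule: EpochSchedule,
    config: BurstConfig | None = None,
) -> BurstSeries:
    """Detect high-gamma bursts per channel against a rest-epoch baseline.

    The baseline for each channel is its own envelope restricted to the
    REST epochs of the same block; the threshold is the baseline median
    plus ``threshold_k`` times the baseline robust SD (1.4826 * MAD).
    Channels whose baseline has zero spread are flagged degenerate and
    yield no bursts.
    """
    config = config or BurstConfig()
    if config.threshold_k <= 0:
        raise ValueError("threshold_k must be positive")
    env = envelope(filtered, config.envelope_window_s)
    fs = filtered.fs
    rest_idx = np.concatenate(
        [
            np.arange(int(round(ep.start * fs)), int(round(ep.end * fs)))
            for ep in schedule.of_label(REST)
        ]
    )
    if len(rest_idx) == 0:
        raise ValueError("schedule contains no REST baseline samples")
    rest_idx = rest_idx[rest_idx < filtered.n_samples]

    min_len = max(int(round(config.min_duration_s * fs)), 1)
    gap_len = int(round(config.merge_gap_s * fs))

    onsets, durations = [], []
    degenerate = np.zeros(filtered.n_channels, dtype=bool)
    for ch in range(filtered.n_channels):
        base = env[ch, rest_idx]
        med = np.median(base)
        robust_sd = 1.4826 * np.median(np.abs(base - med))
        if robust_sd == 0:
            degenerate[ch] = True
            onsets.append(np.empty(0))
            durations.append(np.empty(0))
            continue
        thresh = med + config.threshold_k * robust_sd
        runs = _excursions(env[ch] > thresh)
        merged: list[list[int]] = []
        for s, e in runs:
            if merged and s - merged[-1][1] < gap_len:
                merged[-1][1] = e
            else:
                merged.append([s, e])
        keep = [(s, e) for s, e in merged if e - s >= min_len]
        onsets.append(np.array([s / fs for s, _ in keep]))
        durations.append(np.array([(e - s) / fs for s, e in keep]))
    return BurstSeries(onsets=onsets, durations=durations, degenerate=degenerate)


def epoch_counts(
    bursts: BurstSeries, schedule: EpochSchedule, mask: np.ndarray
) -> np.ndarray:
    """Burst counts per (channel, epoch): a burst belongs to the epoch whose
    half-open interval [start, end) contains its onset."""
    mask = np.asarray(mask, dtype=bool)
    counts = np.zeros((bursts.n_channels, len(schedule)), dtype=float)
    for ch in np.flatnonzero(mask):
        ons = bursts.onsets[ch]
        for j, ep in enumerate(schedule):
            counts[ch, j] = np.count_nonzero((ons >= ep.start) & (ons < ep.end))
    return counts


def epoch_densities(
    bursts: BurstSeries,
    schedule: EpochSchedule,
    mask: np.ndarray,
    aggregation: str = "pooled",
) -> tuple[np.ndarray, np.ndarray]:
    """Per-epoch burst densities (bursts/s) for MOVE and REST epochs.

    ``pooled`` sums counts over active channels before dividing by epoch
    duration (so densities are additive over channels); ``mean`` averages
    per-channel densities (invariant to channel duplication);
    ``best_channel`` returns the densities of the single active channel
    with the largest move-minus-rest density difference.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() < 1:
        raise ValueError("at least one active channel required")
    for ep in schedule:
        if ep.duration <= 0:
            raise ValueError("zero-duration epoch")
    counts = epoch_counts(bursts, schedule, mask)
    durs = np.array([ep.duration for ep in schedule])
    labels = np.array([ep.label for ep in schedule])
    per_channel = counts / durs  # (n_channels, n_epochs)

    if aggregation == "pooled":
        dens = per_channel[mask].sum(axis=0)
    elif aggregation == "mean":
        dens = per_channel[mask].mean(axis=0)
    elif aggregation == "best_channel":
        contrast = (
            per_channel[:, labels == MOVE].mean(axis=1)
            - per_channel[:, labels == REST].mean(axis=1)
        )
        contrast[~mask] = -np.inf
        dens = per_channel[int(np.argmax(contrast))]
    else:
        raise ValueError(f"unknown aggregation {aggregation!r}")
    return dens[labels == MOVE], dens[labels == REST]


def sensitivity_index(move: np.ndarray, rest: np.ndarray) -> float:
    """Sensitivity index d' between move and rest density distributions.

    ``d' = (mean_move - mean_rest) / sqrt((var_move + var_rest) / 2)`` with
    unbiased (n-1) sample variances.  If both variances are zero the index
    is 0 for equal means and +/-inf otherwise (flagged degenerate by the
    caller).
    """
    move = np.asarray(move, dtype=float)
    rest = np.asarray(rest, dtype=float)
    if len(move) < 2 or len(rest) < 2:
        raise ValueError("need at least two epochs per condition")
    diff = move.mean() - rest.mean()
    pooled = (move.var(ddof=1) + rest.var(ddof=1)) / 2.0
    if pooled == 0:
        return 0.0 if diff == 0 else float(np.sign(diff) * np.inf)
    return float(diff / np.sqrt(pooled))


def block_signal_strength(
    recording: Recording,
    schedule: EpochSchedule,
    burst_config: BurstConfig | None = None,
    aggregation: str = "pooled",
) -> SignalStrengthResult:
    """Full block-level chain: filter, detect, densities, sensitivity index."""
    if schedule.end > recording.duration + 1e-9:
        raise ValueError("schedule extends beyond the recording")
    filtered = bandpass_highgamma(recording)
    bursts = detect_bursts(filtered, schedule, burst_config)
    move, rest = epoch_densities(bursts, schedule, recording.active, aggregation)
    d = sensitivity_index(move, rest)
    return SignalStrengthResult(
        dprime=d,
        move_densities=move,
        rest_densities=rest,
        aggregation=aggregation,
        degenerate=not np.isfinite(d),
        extras={"n_bursts": int(sum(len(o) for o in bursts.onsets))},
    )


def best_session_strength(
    blocks: list[tuple[int, float]]
) -> tuple[float, int]:
    """Best signal strength over all blocks of all sessions.

    ``blocks`` is a list of ``(session_id, dprime)``.  Returns the maximum
    d' and its session; ties go to the earliest session.
    """
    if not blocks:
        raise ValueError("no blocks provided")
    best_val = max(d for _, d in blocks)
    best_session = min(s for s, d in blocks if d == best_val)
    return float(best_val), int(best_session)


def strength_vs_zero_test(session_values: np.ndarray) -> float:
    """Two-sided Wilcoxon signed-rank p-value of session strengths vs zero.

    Exact null enumeration for n <= 25 (after dropping zeros), normal
    approximation above.  Refuses fewer than 5 sessions: the exact test
    cannot reach significance and the result would be uninterpretable.
    """
    vals = np.asarray(session_values, dtype=float)
    vals = vals[vals != 0.0]  # zeros carry no sign information
    if len(vals) < 5:
        raise ValueError("need at least 5 nonzero session values")
    method = "exact" if len(vals) <= 25 else "approx"
    res = spstats.wilcoxon(vals, alternative="two-sided", method=method)
    return float(res.pvalue)
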