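"""End-to-end orchestration: synthetic cohort -> per-participant factor
extraction -> motor signal strength -> predictor screen and Lasso.

A single run seed fans out to per-participant, per-stage child seeds via
``numpy.random.SeedSequence`` so any stage can be re-run in isolation.
Given the same configuration and seed, a run is fully deterministic and
the output manifest (file list + SHA-256 checksums) is identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import geometry, signal, slices, stats, synth
from .types import EpochSchedule, Recording, SurfaceModel, VesselModel

log = logging.getLogger("vascbci")

#: the default user-specific factor set screened against signal strength:
#: clinical status (2), device integrity (1), pre-implant functional
#: activity (mean + suprathreshold spread per region, 6), peri-implant
#: neuroanatomy (distances, overlaps, M1 thickness, 6), and
#: neurovasculature (sinus width, 1) - 16 factors in total.
DEFAULT_FACTORS = [
    "years_since_diagnosis",
    "muscle_strength",
    "active_channels",
    "act_mean_SMA",
    "act_mean_M1",
    "act_mean_S1",
    "act_spread_SMA",
    "act_spread_M1",
    "act_spread_S1",
    "dist_mean",
    "dist_min",
    "sss_width",
    "overlap_SMA",
    "overlap_M1",
    "overlap_S1",
    "thickness_M1",
]


@dataclass
class RunConfig:
    """Everything a reproducible run needs."""

    seed: int = 0
    n_participants: int = 10
    #: test sessions per participant; signal strength is the best block
    #: across sessions, as in the repeated longitudinal testing design
    n_sessions: int = 3
    relation: synth.PlantedRelation = field(default_factory=synth.PlantedRelation)
    cohort: synth.CohortConfig = field(default_factory=synth.CohortConfig)
    burst: signal.BurstConfig = field(default_factory=signal.BurstConfig)
    aggregation: str = "pooled"
    dorsal_halfwidth_mm: float = 15.0
    slice_spacing_mm: float = 1.0
    factors: list[str] = field(default_factory=lambda: list(DEFAULT_FACTORS))
    fs_hz: float = 1000.0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "relation" in d and isinstance(d["relation"], dict):
            d["relation"] = synth.PlantedRelation(**d["relation"])
        if "cohort" in d and isinstance(d["cohort"], dict):
            c = dict(d["cohort"])
            if isinstance(c.get("relation"), dict):
                c["relation"] = synth.PlantedRelation(**c["relation"])
            if c.get("overlap_range") is not None:
                c["overlap_range"] = tuple(c["overlap_range"])
            if c.get("bands") is not None:
                c["bands"] = {k: tuple(v) for k, v in c["bands"].items()}
            d["cohort"] = synth.CohortConfig(**c)
        if "burst" in d and isinstance(d["burst"], dict):
            d["burst"] = signal.BurstConfig(**d["burst"])
        return cls(**d)


def participant_factors(
    p: synth.Participant,
    config: RunConfig,
) -> dict[str, float]:
    """Extract the geometric, vascular and functional factors for one
    participant from their scene."""
    line = geometry.fit_stent_line(p.stent_seg, p.vessel)
    dist_all = geometry.stent_to_cortex(line, p.surface, roi="ALL")
    overlap = geometry.roi_overlap(line, p.surface, config.dorsal_halfwidth_mm)
    width = geometry.sinus_width(p.vessel, line)
    thick_m1 = geometry.cortical_thickness(p.surface, "M1")

    out = {
        "years_since_diagnosis": p.years_since_diagnosis,
        "muscle_strength": float(p.muscle_strength),
        "active_channels": float(p.n_active),
        "dist_mean": dist_all.mean,
        "dist_min": dist_all.minimum,
        "sss_width": width,
        "overlap_SMA": overlap["SMA"],
        "overlap_M1": overlap["M1"],
        "overlap_S1": overlap["S1"],
        "thickness_M1": thick_m1,
    }
    for roi in ("SMA", "M1", "S1"):
        means, counts = [], []
        for hemi in p.surface.hemispheres:
            st = slices.roi_activation_stats(p.statmaps[hemi.tag], hemi.labels, roi)
            means.append(st.mean)
            counts.append(st.suprathreshold_count)
        out[f"act_mean_{roi}"] = float(np.mean(means))
        out[f"act_spread_{roi}"] = float(np.sum(counts))
    return out


def participant_slice_factors(
    p: synth.Participant, config: RunConfig
) -> dict[str, float]:
    """Volume/slice-based targeting factors: CoG-to-stent distance and the
    slice-defined M1 coverage."""
    line = geometry.fit_stent_line(p.stent_seg, p.vessel)
    caudal_min, _ = p.surface.rc_extent()
    grid = slices.SliceGrid(origin=float(caudal_min), spacing=config.slice_spacing_mm)
    profile = slices.dorsal_strip_profile(
        p.surface, p.statmaps, grid, halfwidth=config.dorsal_halfwidth_mm
    )
    cog = slices.center_of_gravity(profile)
    stent_sl, mid = slices.stent_slice_span(line, grid)
    bands = geometry.roi_band_intervals(p.surface, config.dorsal_halfwidth_mm)
    m1_sl = grid.slices_intersecting(bands["M1"])
    return {
        "cog_station": cog,
        "cog_to_stent_mm": slices.cog_to_stent_distance(
            cog, grid.origin + (mid + 0.5) * grid.spacing
        ),
        "slice_overlap_M1": slices.stent_m1_slice_overlap(stent_sl, m1_sl),
    }


def participant_signal_strength(
    p: synth.Participant, config: RunConfig
) -> tuple[float, int, list[float]]:
    """Best block-level sensitivity index over sessions for one participant."""
    schedule = EpochSchedule.block_design()
    blocks = []
    session_values = []
    for s in range(config.n_sessions):
        rec = p.make_recording(schedule, session=s, fs=config.fs_hz)
        res = signal.block_signal_strength(
            rec, schedule, config.burst, config.aggregation
        )
        blocks.append((s, res.dprime))
        session_values.append(res.dprime)
    best, sess = signal.best_session_strength(blocks)
    return best, sess, session_values


def build_factor_table(config: RunConfig) -> tuple[pd.DataFrame, list[synth.Participant]]:
    """Generate the cohort and assemble the participants x factors table
    with the measured response."""
    participants = synth.generate_cohort(
        config.n_participants, config.relation, config.cohort, seed=config.seed
    )
    rows = []
    for p in participants:
        row = {"id": p.pid, "planted_strength": p.planted_strength,
               "m1_overlap_target": p.m1_overlap_target}
        row.update(participant_factors(p, config))
        row.update(participant_slice_factors(p, config))
        best, sess, _ = participant_signal_strength(p, config)
        row["signal_strength"] = best
        row["best_session"] = sess
        rows.append(row)
        log.info("participant %s: d'=%.2f (session %d)", p.pid, best, sess)
    return pd.DataFrame(rows), participants


def run_end_to_end(config: RunConfig, out_dir: Path | str) -> dict:
    """Full pipeline run; persists every intermediate plus a checksum
    manifest and returns the screen/Lasso summary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    from . import io as vio

    vio.save_config(config.to_dict(), out / "config.yaml")
    table, _ = build_factor_table(config)
    table.to_csv(out / "cohort.csv", index=False)

    matrix = stats.PredictorMatrix(table, factors=list(config.factors))
    screen = stats.screen_factors(matrix)
    screen.table.to_csv(out / "screen.csv", index=False)
    lasso = stats.lasso_select(matrix)

    summary = {
        "seed": config.seed,
        "n_participants": config.n_participants,
        "top_factor": screen.top_factor(),
        "screen": screen.table.to_dict(orient="records"),
        "lasso": {
            "alpha": lasso.alpha,
            "coefficients": {k: float(v) for k, v in lasso.coefficients.items()},
            "nonzero": lasso.nonzero,
        },
    }
    (out / "report.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    _write_manifest(out)
    return summary


def _write_manifest(out: Path) -> None:
    entries = {}
    for p in sorted(out.glob("*")):
        if p.name == "manifest.json" or p.is_dir():
            continue
        entries[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()
    (out / "manifest.json").write_text(json.dumps(entries, indent=2, sort_keys=True))


def validate_scene(
    surface: SurfaceModel | None = None,
    vessel: VesselModel | None = None,
    schedule: EpochSchedule | None = None,
    recording: Recording | None = None,
) -> list[str]:
    """Check every type invariant that construction cannot enforce across
    objects, reporting violations without raising."""
    violations: list[str] = []
    if surface is not None:
        for hemi in surface.hemispheres:
            if hemi.pial.shape != hemi.white.shape:
                violations.append(f"hemisphere {hemi.tag}: pial/white vertex mismatch")
            if not np.all(np.isfinite(hemi.pial)):
                violations.append(f"hemisphere {hemi.tag}: non-finite coordinates")
            if set(np.unique(hemi.labels)) - {"SMA", "M1", "S1", "CAUDAL", "OTHER"}:
                violations.append(f"hemisphere {hemi.tag}: unknown labels")
    if vessel is not None:
        rc = vessel.points[:, 1]
        if not np.all(np.diff(rc) < 0):
            violations.append("vessel centerline not strictly rostral-to-caudal")
        if np.any(vessel.radii <= 0):
            violations.append("vessel has non-positive lumen radii")
    if schedule is not None:
        # accept a raw epoch list so defective schedules (which the
        # EpochSchedule constructor would reject) can still be reported
        epochs = list(schedule.epochs) if isinstance(schedule, EpochSchedule) else list(schedule)
        prev = None
        for ep in epochs:
            if prev is not None and ep.start < prev.end:
                violations.append(
                    f"epochs overlap: [{prev.start}, {prev.end}] and [{ep.start}, {ep.end}]"
                )
            prev = ep
        if recording is not None and epochs and max(ep.end for ep in epochs) > recording.duration + 1e-9:
            violations.append("schedule extends beyond recording duration")
    if recording is not None:
        if recording.fs <= 400:
            violations.append(
                f"sampling rate {recording.fs} Hz violates the 2 x 200 Hz bound"
            )
        if recording.active.sum() > recording.n_channels:
            violations.append("active count exceeds channel count")
    return violations


def validate_files(
    recording_path: Path | str | None = None,
    schedule_path: Path | str | None = None,
    surface_stem: Path | str | None = None,
) -> list[str]:
    """Validate on-disk inputs, reporting invariant violations without
    raising (defective files are read at the raw level, bypassing the
    constructors that would reject them)."""
    import h5py

    violations: list[str] = []
    duration = None
    if recording_path is not None:
        with h5py.File(recording_path, "r") as f:
            fs = float(f.attrs["fs_hz"])
            sig = f["signal_uV"]
            mask = f["active_mask"][()]
            if fs <= 400:
                violations.append(
                    f"sampling rate {fs} Hz violates the 2 x 200 Hz bound"
                )
            if len(mask) != sig.shape[0]:
                violations.append("active mask length differs from channel count")
            duration = sig.shape[1] / fs
    if schedule_path is not None:
        payload = json.loads(Path(schedule_path).read_text())
        prev_end = None
        for e in payload:
            if e["label"] not in ("MOVE", "REST"):
                violations.append(f"unknown epoch label {e['label']!r}")
            if e["end_s"] <= e["start_s"]:
                violations.append(f"non-positive epoch [{e['start_s']}, {e['end_s']}]")
            if prev_end is not None and e["start_s"] < prev_end:
                violations.append(
                    f"epochs overlap: previous ends {prev_end}, next starts {e['start_s']}"
                )
            prev_end = e["end_s"]
        if duration is not None and payload and payload[-1]["end_s"] > duration + 1e-9:
            violations.append("schedule extends beyond recording duration")
    if surface_stem is not None:
        from . import io as vio

        try:
            surf = vio.load_surface(surface_stem)
            violations.extend(validate_scene(surface=surf))
        except Exception as exc:  # defective geometry files
            violations.append(f"surface failed to load: {exc}")
    return violations
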