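"""File round-tripping for the standard interchange formats.

Surfaces travel as GIfTI (``.surf.gii`` geometry plus ``.label.gii``
labels, one pair per hemisphere/layer), vessels and stents as CSV point
lists with a JSON sidecar for radii, recordings as HDF5 with the cue
schedule as JSON, cohort/factor tables as CSV, and run configurations as
YAML.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .types import (
    ROI_LABELS,
    Epoch,
    EpochSchedule,
    Hemisphere,
    Recording,
    SliceProfile,
    StentSegmentation,
    SurfaceModel,
    VesselModel,
)

_LABEL_CODES = {name: i for i, name in enumerate(ROI_LABELS)}


def save_surface(surface: SurfaceModel, stem: Path | str) -> list[Path]:
    """Write ``<stem>.<H>.{pial,white}.surf.gii`` and ``<stem>.<H>.label.gii``."""
    stem = Path(stem)
    written = []
    for hemi in surface.hemispheres:
        for layer, verts in (("pial", hemi.pial), ("white", hemi.white)):
            img = nib.gifti.GiftiImage(
                darrays=[
                    nib.gifti.GiftiDataArray(
                        verts.astype(np.float32), intent="NIFTI_INTENT_POINTSET"
                    ),
                    nib.gifti.GiftiDataArray(
                        hemi.triangles.astype(np.int32), intent="NIFTI_INTENT_TRIANGLE"
                    ),
                ]
            )
            p = stem.with_suffix(f".{hemi.tag}.{layer}.surf.gii")
            nib.save(img, p)
            written.append(p)
        codes = np.array([_LABEL_CODES[l] for l in hemi.labels], dtype=np.int32)
        limg = nib.gifti.GiftiImage(
            darrays=[nib.gifti.GiftiDataArray(codes, intent="NIFTI_INTENT_LABEL")]
        )
        p = stem.with_suffix(f".{hemi.tag}.label.gii")
        nib.save(limg, p)
        written.append(p)
    return written


def load_surface(stem: Path | str) -> SurfaceModel:
    stem = Path(stem)
    hemis = {}
    for tag in ("L", "R"):
        layers = {}
        for layer in ("pial", "white"):
            img = nib.load(stem.with_suffix(f".{tag}.{layer}.surf.gii"))
            layers[layer] = np.asarray(img.darrays[0].data, dtype=float)
            tris = np.asarray(img.darrays[1].data, dtype=np.int64)
        codes = np.asarray(
            nib.load(stem.with_suffix(f".{tag}.label.gii")).darrays[0].data
        )
        labels = np.array([ROI_LABELS[c] for c in codes])
        hemis[tag] = Hemisphere(
            pial=layers["pial"], white=layers["white"], triangles=tris,
            labels=labels, tag=tag,
        )
    return SurfaceModel(left=hemis["L"], right=hemis["R"])


def save_vessel(vessel: VesselModel, path: Path | str) -> None:
    """CSV of centerline points + radii; a JSON sidecar records the schema."""
    path = Path(path)
    df = pd.DataFrame(vessel.points, columns=["x_mm", "y_mm", "z_mm"])
    df["radius_mm"] = vessel.radii
    df.to_csv(path, index=False)
    sidecar = {"kind": "vessel_centerline", "units": "mm", "order": "rostral_to_caudal"}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_vessel(path: Path | str) -> VesselModel:
    df = pd.read_csv(path)
    return VesselModel(
        points=df[["x_mm", "y_mm", "z_mm"]].to_numpy(),
        radii=df["radius_mm"].to_numpy(),
    )


def save_stent_points(seg: StentSegmentation, path: Path | str) -> None:
    pd.DataFrame(seg.points, columns=["x_mm", "y_mm", "z_mm"]).to_csv(path, index=False)


def load_stent_points(path: Path | str) -> StentSegmentation:
    df = pd.read_csv(path)
    return StentSegmentation(points=df[["x_mm", "y_mm", "z_mm"]].to_numpy())


def save_recording(recording: Recording, path: Path | str) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("signal_uV", data=recording.data, compression="gzip")
        f.create_dataset("active_mask", data=recording.active.astype(np.uint8))
        f.attrs["fs_hz"] = recording.fs


def load_recording(path: Path | str) -> Recording:
    with h5py.File(path, "r") as f:
        return Recording(
            data=f["signal_uV"][()],
            fs=float(f.attrs["fs_hz"]),
            active=f["active_mask"][()].astype(bool),
        )


def save_schedule(schedule: EpochSchedule, path: Path | str) -> None:
    payload = [
        {"start_s": ep.start, "end_s": ep.end, "label": ep.label} for ep in schedule
    ]
    Path(path).write_text(json.dumps(payload, indent=2))


def load_schedule(path: Path | str) -> EpochSchedule:
    payload = json.loads(Path(path).read_text())
    return EpochSchedule(
        [Epoch(e["start_s"], e["end_s"], e["label"]) for e in payload]
    )


def save_profile(profile: SliceProfile, path: Path | str) -> None:
    pd.DataFrame(
        {"station_mm": profile.stations, "activity": profile.values}
    ).to_csv(path, index=False)


def load_profile(path: Path | str) -> SliceProfile:
    df = pd.read_csv(path)
    return SliceProfile(
        stations=df["station_mm"].to_numpy(), values=df["activity"].to_numpy()
    )


def save_config(config: dict, path: Path | str) -> None:
    Path(path).write_text(yaml.safe_dump(config, sort_keys=True))


def load_config(path: Path | str) -> dict:
    return yaml.safe_load(Path(path).read_text())
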