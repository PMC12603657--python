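"""HDF5 dataset container.

Layout::

    /meta                 format version, seed (attrs)
    /sensors              positions, orientations, baseline, channel ids
    /head                 sphere center + radius (attrs)
    /subjects/<id>/raw    channels × samples (attr: sampling_rate)
    /subjects/<id>/events (n, 2) sample index + code
    /subjects/<id>/truth  simulation ground truth (attrs, optional)
    /derived/<stage>      arrays written by pipeline stages, with
                          provenance attributes (stage, params, input hash)

Round-trips are lossless; derived groups refuse to be overwritten
unless ``force`` is passed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import h5py
import numpy as np

from .forward import HeadModel, SensorArray
from .simulate import Recording, SubjectTruth

__all__ = [
    "FORMAT_VERSION",
    "Dataset",
    "IntegrityError",
    "MigrationError",
    "write_dataset",
    "read_dataset",
    "write_derived",
    "sensor_array_to_csv",
    "export_fif",
    "export_nifti",
]

FORMAT_VERSION = "1.0"


class IntegrityError(RuntimeError):
    """The file is missing required groups or is truncated."""


class MigrationError(RuntimeError):
    """The file was written by an incompatible format version."""


@dataclass
class Dataset:
    """In-memory image of the container."""

    head: HeadModel
    sensors: SensorArray
    recordings: dict[str, Recording]
    truths: dict[str, SubjectTruth] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)


def write_dataset(ds: Dataset, path) -> None:
    with h5py.File(path, "w") as f:
        meta = f.create_group("meta")
        meta.attrs["format_version"] = FORMAT_VERSION
        for k, v in ds.meta.items():
            meta.attrs[k] = v
        sens = f.create_group("sensors")
        sens.create_dataset("coil_position", data=ds.sensors.coil_position)
        sens.create_dataset("coil_orientation",
                            data=ds.sensors.coil_orientation)
        sens.create_dataset(
            "channel_id",
            data=np.array(ds.sensors.channel_id, dtype="S"))
        sens.attrs["gradiometer_baseline"] = ds.sensors.gradiometer_baseline
        head = f.create_group("head")
        head.attrs["sphere_center"] = ds.head.sphere_center
        head.attrs["sphere_radius"] = ds.head.sphere_radius
        subs = f.create_group("subjects")
        for sid, rec in ds.recordings.items():
            g = subs.create_group(sid)
            raw = g.create_dataset("raw", data=rec.data)
            raw.attrs["sampling_rate"] = rec.sampling_rate
            raw.attrs["provenance"] = json.dumps(rec.provenance)
            g.create_dataset("events", data=rec.events)
            if sid in ds.truths:
                tg = g.create_group("truth")
                for k, v in dataclasses.asdict(ds.truths[sid]).items():
                    tg.attrs[k] = v


def read_dataset(path) -> Dataset:
    with h5py.File(path, "r") as f:
        for group in ("meta", "sensors", "head", "subjects"):
            if group not in f:
                raise IntegrityError(f"missing required group /{group}")
        version = f["meta"].attrs.get("format_version")
        if version != FORMAT_VERSION:
            raise MigrationError(
                f"file format {version!r} != supported {FORMAT_VERSION!r}")
        sens = f["sensors"]
        sensors = SensorArray(
            [c.decode() for c in sens["channel_id"][()]],
            sens["coil_position"][()],
            sens["coil_orientation"][()],
            float(sens.attrs["gradiometer_baseline"]))
        head = HeadModel(np.asarray(f["head"].attrs["sphere_center"]),
                         float(f["head"].attrs["sphere_radius"]))
        recordings, truths = {}, {}
        for sid, g in f["subjects"].items():
            if "raw" not in g or "events" not in g:
                raise IntegrityError(f"subject {sid} missing raw or events")
            raw = g["raw"]
            recordings[sid] = Recording(
                raw[()], float(raw.attrs["sampling_rate"]),
                g["events"][()], sid,
                provenance=json.loads(raw.attrs.get("provenance", "[]")))
            if "truth" in g:
                attrs = dict(g["truth"].attrs)
                attrs = {k: (v.item() if hasattr(v, "item") else v)
                         for k, v in attrs.items()}
                truths[sid] = SubjectTruth(**attrs)
        meta = {k: v for k, v in f["meta"].attrs.items()
                if k != "format_version"}
    return Dataset(head, sensors, recordings, truths, meta)


def write_derived(path, stage: str, arrays: dict[str, np.ndarray],
                  params: dict, input_hash: str = "",
                  force: bool = False) -> None:
    """Write stage outputs with provenance; refuse overwrite sans force."""
    with h5py.File(path, "a") as f:
        name = f"derived/{stage}"
        if name in f:
            if not force:
                raise FileExistsError(
                    f"{name} already exists; pass force=True to overwrite")
            del f[name]
        g = f.create_group(name)
        g.attrs["stage"] = stage
        g.attrs["params"] = json.dumps(params, sort_keys=True, default=str)
        g.attrs["input_hash"] = input_hash
        for k, v in arrays.items():
            g.create_dataset(k, data=v)


def data_hash(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()[:16]


def export_fif(recording: Recording, sensors: SensorArray, path) -> None:
    """Optional FIF export for interoperability with MEG toolchains.

    Channels are written as gradiometers with stimulus onsets as
    annotations.  Requires mne.
    """
    import mne
    info = mne.create_info(list(sensors.channel_id),
                           recording.sampling_rate, ch_types="grad")
    raw = mne.io.RawArray(recording.data, info, verbose="error")
    onsets = recording.events[:, 0] / recording.sampling_rate
    raw.set_annotations(mne.Annotations(
        onset=onsets, duration=0.0,
        description=[f"stim/{int(c)}" for c in recording.events[:, 1]]))
    raw.save(path, overwrite=True, verbose="error")


def export_nifti(image, path) -> None:
    """Optional volumetric export of a source image on its lattice.

    Values outside the inside mask are NaN.  Requires nibabel.
    """
    import nibabel as nib
    grid = image.grid
    vol = np.full(grid.shape, np.nan)
    vol[tuple(grid.ijk.T)] = image.pseudo_t
    origin = grid.voxel_coords[0] - grid.ijk[0] * grid.spacing
    affine = np.eye(4)
    affine[:3, :3] *= grid.spacing
    affine[:3, 3] = origin
    nib.save(nib.Nifti1Image(vol.astype(np.float32), affine), path)


def sensor_array_to_csv(sensors: SensorArray, path) -> None:
    """Plain-text export: channel_id, x, y, z, ox, oy, oz."""
    import pandas as pd
    pd.DataFrame({
        "channel_id": sensors.channel_id,
        "x": sensors.coil_position[:, 0],
        "y": sensors.coil_position[:, 1],
        "z": sensors.coil_position[:, 2],
        "ox": sensors.coil_orientation[:, 0],
        "oy": sensors.coil_orientation[:, 1],
        "oz": sensors.coil_orientation[:, 2],
    }).to_csv(path, index=False)
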