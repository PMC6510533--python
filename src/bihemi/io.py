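"""File round-tripping for every serialized type.

Movies: multi-page TIFF (one file per channel) or a single HDF5 file with
datasets ``/channel_signal`` and ``/channel_artifact`` and attribute
``fs_hz``. Trial tables: CSV with header
``trial,onset_frame,side,contrast,choice,condition``. Ground truth: JSON.
ROI traces: CSV (frame column + one column per area). Compressed movies:
HDF5 (``/U``, ``/S``, ``/V``, attrs ``fs_hz``, ``rank``). Epochs: HDF5.
Fits: JSON. Seed maps: float32 TIFF with a JSON sidecar naming the seed.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Union

import h5py
import numpy as np
import pandas as pd
import tifffile

from .evoked import EpochSet, NakaRushtonParams
from .observer import GParams
from .preprocess import CompressedMovie
from .synth import AreaSpec, GroundTruth, ImagingSession

PathLike = Union[str, Path]

TRIAL_COLUMNS = ["trial", "onset_frame", "side", "contrast", "choice", "condition"]


# ---------------------------------------------------------------- movies

def save_movie_hdf5(session: ImagingSession, path: PathLike) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("channel_signal", data=session.signal.astype(np.float32))
        f.create_dataset("channel_artifact", data=session.artifact.astype(np.float32))
        f.attrs["fs_hz"] = session.fs


def load_movie_hdf5(path: PathLike) -> ImagingSession:
    with h5py.File(path, "r") as f:
        for key in ("channel_signal", "channel_artifact"):
            if key not in f:
                raise ValueError(f"movie file missing dataset /{key}")
        return ImagingSession(
            signal=f["channel_signal"][...].astype(float),
            artifact=f["channel_artifact"][...].astype(float),
            fs=float(f.attrs["fs_hz"]),
        )


def save_movie_tiff(session: ImagingSession, signal_path: PathLike, artifact_path: PathLike) -> None:
    tifffile.imwrite(signal_path, session.signal.astype(np.float32))
    tifffile.imwrite(artifact_path, session.artifact.astype(np.float32))


def load_movie_tiff(signal_path: PathLike, artifact_path: PathLike, fs: float) -> ImagingSession:
    return ImagingSession(
        signal=tifffile.imread(signal_path).astype(float),
        artifact=tifffile.imread(artifact_path).astype(float),
        fs=fs,
    )


# ---------------------------------------------------------------- trial tables

def save_trials(trials: pd.DataFrame, path: PathLike) -> None:
    trials[TRIAL_COLUMNS].to_csv(path, index=False)


def load_trials(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trial table missing column(s): {missing}")
    return df[TRIAL_COLUMNS]


# ---------------------------------------------------------------- ground truth

def _truth_to_dict(truth: GroundTruth) -> dict:
    d = dataclasses.asdict(truth)
    d["areas"] = [dataclasses.asdict(a) for a in truth.areas]
    d["nr"] = dataclasses.asdict(truth.nr)
    d["observer_g"] = dataclasses.asdict(truth.observer_g)
    return d


def save_truth(truth: GroundTruth, path: PathLike) -> None:
    Path(path).write_text(json.dumps(_truth_to_dict(truth), indent=2, sort_keys=True))


def load_truth(path: PathLike) -> GroundTruth:
    d = json.loads(Path(path).read_text())
    d["areas"] = [AreaSpec(**a) for a in d["areas"]]
    d["nr"] = NakaRushtonParams(**d["nr"])
    d["observer_g"] = GParams(**d["observer_g"])
    d["band"] = tuple(d["band"])
    return GroundTruth(**d)


# ---------------------------------------------------------------- traces

def save_traces(traces: np.ndarray, names: list[str], path: PathLike) -> None:
    df = pd.DataFrame(traces.T, columns=names)
    df.insert(0, "frame", np.arange(traces.shape[1]))
    df.to_csv(path, index=False)


def load_traces(path: PathLike) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path)
    if "frame" not in df.columns:
        raise ValueError("trace table missing 'frame' column")
    names = [c for c in df.columns if c != "frame"]
    return df[names].to_numpy().T, names


# ---------------------------------------------------------------- compressed movies

def save_compressed(cm: CompressedMovie, path: PathLike) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("U", data=cm.spatial_components)
        f.create_dataset("S", data=cm.singular_values)
        f.create_dataset("V", data=cm.temporal_components)
        f.attrs["fs_hz"] = cm.fs
        f.attrs["rank"] = cm.rank


def load_compressed(path: PathLike) -> CompressedMovie:
    with h5py.File(path, "r") as f:
        for key in ("U", "S", "V"):
            if key not in f:
                raise ValueError(f"compressed movie missing dataset /{key}")
        return CompressedMovie(
            spatial_components=f["U"][...],
            singular_values=f["S"][...],
            temporal_components=f["V"][...],
            fs=float(f.attrs["fs_hz"]),
        )


# ---------------------------------------------------------------- epochs

def save_epochs(epochs: EpochSet, path: PathLike) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("epochs", data=epochs.data)
        f.create_dataset("time_s", data=epochs.time_s)
        grp = f.create_group("trials")
        for col in epochs.meta.columns:
            values = epochs.meta[col].to_numpy()
            if values.dtype == object or values.dtype.kind in "US":
                grp.create_dataset(col, data=np.asarray(values, dtype="S"))
            else:
                grp.create_dataset(col, data=values)
        grp.attrs["columns"] = json.dumps(list(epochs.meta.columns))


def load_epochs(path: PathLike) -> EpochSet:
    with h5py.File(path, "r") as f:
        if "epochs" not in f or "time_s" not in f:
            raise ValueError("epoch file missing /epochs or /time_s")
        cols = json.loads(f["trials"].attrs["columns"])
        meta = {}
        for col in cols:
            values = f["trials"][col][...]
            if values.dtype.kind == "S":
                values = values.astype(str)
            meta[col] = values
        return EpochSet(
            data=f["epochs"][...], time_s=f["time_s"][...], meta=pd.DataFrame(meta)
        )


# ---------------------------------------------------------------- fits / maps

def save_json(record: dict, path: PathLike) -> None:
    Path(path).write_text(json.dumps(record, indent=2, sort_keys=True, default=_jsonify))


def load_json(path: PathLike) -> dict:
    return json.loads(Path(path).read_text())


def _jsonify(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj):
        return dataclasses.asdict(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def save_seed_map(corr_map: np.ndarray, seed_name: str, path: PathLike) -> None:
    path = Path(path)
    tifffile.imwrite(path, corr_map.astype(np.float32))
    path.with_suffix(".json").write_text(json.dumps({"seed": seed_name}))


def load_seed_map(path: PathLike) -> tuple[np.ndarray, str]:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    return tifffile.imread(path).astype(float), sidecar["seed"]
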