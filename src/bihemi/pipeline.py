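"""End-to-end pipeline: simulate/load -> preprocess -> bilateral -> evoked
-> additive -> psychometric -> summary.

A :class:`RunConfig` captures every knob (preprocessing chain, windows,
split criterion, seed); it serializes to JSON losslessly and its SHA-256
hash is recorded in every summary, so identical config + seed reproduces
byte-identical output.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import additive, bilateral, evoked, io, observer, preprocess, synth
from .areas import AreaSet

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; partial outputs are preserved on disk."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    """Everything a run needs; defaults are the reference analysis constants."""

    seed: int = 0
    simulate: bool = True
    movie_path: Optional[str] = None
    trials_path: Optional[str] = None
    truth_path: Optional[str] = None
    n_trials: int = 120
    contrast_set: tuple = (0.0, 0.06, 0.12, 0.25, 0.5, 1.0)
    image_shape: Optional[tuple] = (24, 24)
    iti_s: float = 2.0
    rank: int = preprocess.DEFAULT_RANK
    cutoff_hz: float = preprocess.DEFAULT_CUTOFF_HZ
    chain: tuple = ("correct", "lowpass")
    band: tuple = (2.0, 7.0)
    response_window: tuple = evoked.RESPONSE_WINDOW
    prestim_window: tuple = evoked.PRESTIM_WINDOW
    epoch_window: tuple = (-0.5, 0.6)
    split_criterion: str = "contralateral_activity"
    target_area: str = "PM_R"
    regressor_area: str = "PM_L"
    sweep: bool = False
    exclude_areas: tuple = ("V1m", "M2")

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        d = json.loads(text)
        for key in ("contrast_set", "chain", "band", "response_window",
                    "prestim_window", "epoch_window", "exclude_areas"):
            if d.get(key) is not None:
                d[key] = tuple(d[key])
        if d.get("image_shape") is not None:
            d["image_shape"] = tuple(d["image_shape"])
        return cls(**d)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


@dataclass
class TraceSession:
    """Analysis-ready session: ROI traces + trial table (movie already reduced)."""

    areas: AreaSet
    trials: pd.DataFrame
    measured: np.ndarray
    measured_artifact: np.ndarray
    fs: float
    movie: Optional[synth.ImagingSession] = None

    def trace(self, area_name: str, which: str = "measured") -> np.ndarray:
        idx = self.areas.index(area_name)
        return (self.measured if which == "measured" else self.measured_artifact)[idx]


def _stage(name: str, log: list):
    class _Ctx:
        def __enter__(self):
            logger.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise PipelineError(name, exc) from exc
            log.append(name)
            logger.info("stage %s: done", name)
            return False

    return _Ctx()


def _acquire(config: RunConfig):
    if config.simulate:
        truth = (io.load_truth(config.truth_path) if config.truth_path
                 else synth.GroundTruth())
        session = synth.generate_session(
            truth, config.n_trials, list(config.contrast_set), config.seed,
            iti_s=config.iti_s, image_shape=config.image_shape,
        )
        return session, truth
    for label, path in (("movie", config.movie_path), ("trials", config.trials_path),
                        ("truth", config.truth_path)):
        if path is None or not Path(path).exists():
            raise FileNotFoundError(f"{label} path missing and simulation not requested: {path}")
    movie = io.load_movie_hdf5(config.movie_path)
    trials = io.load_trials(config.trials_path)
    truth = io.load_truth(config.truth_path)
    areas = truth.area_set()
    shape = movie.signal.shape[1:]
    areas = areas.with_masks(synth.default_masks(areas, shape))
    measured = preprocess.extract_roi_traces(movie.signal, areas)
    artifact = preprocess.extract_roi_traces(movie.artifact, areas)
    session = TraceSession(areas=areas, trials=trials, measured=measured,
                           measured_artifact=artifact, fs=movie.fs, movie=movie)
    return session, truth


def _preprocess(session, config: RunConfig, outdir: Path):
    areas = session.areas
    if getattr(session, "movie", None) is not None:
        movie = session.movie
        n_frames = movie.signal.shape[0]
        flat = movie.signal.reshape(n_frames, -1).T
        rank = min(config.rank, *flat.shape)
        cm = preprocess.svd_compress(flat, rank, fs=session.fs)
        io.save_compressed(cm, outdir / "compressed.h5")
        shape = movie.signal.shape[1:]
        measured = preprocess.extract_roi_traces(cm, areas, image_shape=shape)
        artifact = preprocess.extract_roi_traces(movie.artifact, areas)
    else:
        measured = session.measured
        artifact = session.measured_artifact
    processed = np.stack([
        preprocess.apply_chain(measured[i], artifact[i], session.fs,
                               chain=config.chain, cutoff_hz=config.cutoff_hz)
        for i in range(len(areas))
    ])
    artifact = artifact[:, : processed.shape[1]]
    io.save_traces(processed, areas.names, outdir / "roi_traces.csv")
    return TraceSession(areas=areas, trials=session.trials, measured=processed,
                        measured_artifact=artifact, fs=session.fs)


def _bilateral_stage(session: TraceSession, config: RunConfig, outdir: Path) -> dict:
    table = bilateral.bilateral_correlation_by_area(session.measured, session.areas)
    slope, intercept = bilateral.fit_correlation_vs_distance(
        table, exclude=list(config.exclude_areas))
    table.to_csv(outdir / "bilateral_correlation.csv", index=False)
    tgt = session.areas[config.target_area]
    left = session.trace(f"{tgt.base}_L")
    right = session.trace(f"{tgt.base}_R")
    dec = bilateral.decompose_sym_asym(left, right, fs=session.fs)
    in_band = (dec.freqs >= config.band[0]) & (dec.freqs <= config.band[1])
    return {
        "table": table.drop(columns=["condition"]).to_dict(orient="records"),
        "slope": slope,
        "intercept": intercept,
        "rel_power_sym_band_mean": float(np.nanmean(dec.rel_power_sym[in_band])),
    }


def _amplitudes(session: TraceSession, area: str, config: RunConfig,
                window: Optional[tuple] = None) -> np.ndarray:
    ep = evoked.epoch_trials(
        session.trace(area), session.trials["onset_frame"].to_numpy(),
        config.epoch_window, session.fs, meta=session.trials)
    return evoked.response_amplitude(ep, window or config.response_window)


def _evoked_stage(session: TraceSession, config: RunConfig) -> dict:
    tgt = session.areas[config.target_area]
    partner = session.areas.partner(config.target_area)
    trials = session.trials
    # trials whose stimulus is contralateral to the target area, plus blanks
    stim_side = "L" if tgt.hemisphere == "R" else "R"
    sel = ((trials["side"] == stim_side) | (trials["contrast"] == 0)).to_numpy()
    sub = trials.loc[sel].reset_index(drop=True)
    amps = _amplitudes(session, config.target_area, config)[sel]
    amps_unstim = _amplitudes(session, partner.name, config)[sel]
    split = evoked.split_by_contralateral_activity(amps_unstim)
    contrasts = sub["contrast"].to_numpy(dtype=float)
    grand, groups = evoked.fit_naka_rushton_groups(contrasts, amps, split)
    out = {
        "grand": dataclasses.asdict(grand),
        "groups": {k: dataclasses.asdict(v) for k, v in groups.items()},
        "split_sizes": split.group_sizes,
    }
    if {"low", "high"} <= set(groups):
        out["offset_diff"] = groups["high"].r0 - groups["low"].r0
        out["scale_ratio"] = (groups["high"].rmax / groups["low"].rmax
                              if groups["low"].rmax != 0 else np.nan)
    return out


def _psychometric_stage(session: TraceSession, config: RunConfig) -> dict:
    trials = session.trials
    # ongoing bilateral activity read out from the hemisphere ipsilateral to
    # the stimulus (the unstimulated one) of the target area pair
    base = session.areas[config.target_area].base
    amps = np.empty(len(trials))
    for hemi in ("L", "R"):
        sel = (trials["side"] == hemi).to_numpy()
        if sel.any():
            amps[sel] = _amplitudes(session, f"{base}_{hemi}", config)[sel]
    split = evoked.split_by_contralateral_activity(amps)
    result = observer.fit_observer(trials, groups=split.labels)
    fits = {"global": dataclasses.asdict(result.global_fit)}
    for label, fit in result.group_fits.items():
        fits[label] = dataclasses.asdict(fit)
    table = observer.psychometric_table(trials, groups=split.labels)
    return {"fits": fits, "split_sizes": split.group_sizes,
            "table": table.to_dict(orient="records")}


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Run every stage, write per-stage outputs plus ``summary.json``.

    Any stage failure aborts with the stage name; outputs of completed
    stages remain on disk.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "config.json").write_text(config.to_json())
    completed: list = []
    summary: dict = {"config_hash": config.config_hash, "seed": config.seed}

    with _stage("acquire", completed):
        session, truth = _acquire(config)
        io.save_trials(session.trials, outdir / "trials.csv")
        summary["n_trials"] = int(len(session.trials))
    with _stage("preprocess", completed):
        analysis = _preprocess(session, config, outdir)
    with _stage("bilateral", completed):
        summary["bilateral"] = _bilateral_stage(analysis, config, outdir)
    with _stage("evoked", completed):
        summary["naka_rushton"] = _evoked_stage(analysis, config)
    with _stage("additive", completed):
        fit = additive.crossval_additive(analysis, config.target_area,
                                         config.regressor_area,
                                         window=config.response_window)
        summary["additive"] = fit.to_record()
        if config.sweep:
            sweep = additive.regressor_distance_sweep(analysis, config.target_area)
            summary["additive"]["sweep"] = {
                "table": sweep.table.to_dict(orient="records"),
                "a": sweep.a, "decay_mm": sweep.decay_mm, "c": sweep.c,
                "fit_ok": sweep.fit_ok,
            }
    with _stage("psychometric", completed):
        summary["psychometric"] = _psychometric_stage(analysis, config)

    summary["stages_completed"] = completed
    io.save_json(summary, outdir / "summary.json")
    (outdir / "provenance.log").write_text(
        "\n".join([f"config_hash={config.config_hash}", f"seed={config.seed}"]
                  + [f"stage={s}" for s in completed]) + "\n")
    return summary
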