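"""Readers and writers for every format the pipeline touches.

Image dialect: multi-page float32 TIFF of heights in nm plus a JSON
sidecar ``<stem>.json`` carrying pixel_size_nm, fps and provenance; class
masks as multi-page uint8 TIFF (0/1/2 = background/NCP/DNA); tabular
outputs (events, drift, arms, angles, volumes, lifetimes, clusters) as
CSV; classifier weights as NPZ with a JSON metadata entry.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from sklearn.neural_network import MLPClassifier

from .preprocess import DriftTrack, RasterStack
from .segmentation import PatchClassifier
from .synthetic import DisassemblyEvent, DisassemblySchedule, SimulatedMovie

__all__ = ["write_stack", "read_stack", "write_masks", "read_masks",
           "write_events", "read_events", "write_drift", "read_drift",
           "save_model", "load_model", "write_movie"]


def _sidecar_path(path) -> Path:
    p = Path(path)
    return p.with_suffix(p.suffix + ".json") if p.suffix != ".tif" \
        else p.with_suffix(".json")


def write_stack(path, stack: RasterStack, **extra):
    """Multi-page float32 TIFF plus JSON sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, np.asarray(stack.frames, dtype=np.float32),
                     photometric="minisblack")
    meta = {"pixel_size_nm": stack.pixel_size, "fps": stack.fps, **extra}
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))


def read_stack(path) -> tuple[RasterStack, dict]:
    frames = tifffile.imread(path)
    if frames.ndim == 2:
        frames = frames[None]
    meta = json.loads(_sidecar_path(path).read_text())
    return RasterStack(frames, meta["pixel_size_nm"], meta["fps"]), meta


def write_masks(path, masks):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, np.asarray(masks, dtype=np.uint8),
                     photometric="minisblack")


def read_masks(path):
    masks = tifffile.imread(path)
    return masks[None] if masks.ndim == 2 else masks


def write_events(path, schedule: DisassemblySchedule, fps: float):
    rows = [{"frame": int(e.time_s * fps), "time_s": e.time_s,
             "transition": "->".join(e.transition), "mode": e.mode,
             "side": e.side} for e in schedule.events]
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows, columns=["frame", "time_s", "transition", "mode",
                                "side"]).to_csv(path, index=False)


def read_events(path) -> DisassemblySchedule:
    df = pd.read_csv(path)
    events = [
        DisassemblyEvent(float(r.time_s), tuple(r.transition.split("->")),
                         r.mode, r.side)
        for r in df.itertuples()
    ]
    return DisassemblySchedule(events)


def write_drift(path, track: DriftTrack):
    df = pd.DataFrame(track.shifts, columns=["dy_px", "dx_px"])
    df.insert(0, "frame", np.arange(len(df)))
    df.to_csv(path, index=False)


def read_drift(path) -> DriftTrack:
    df = pd.read_csv(path)
    return DriftTrack(df[["dy_px", "dx_px"]].to_numpy())


def save_model(path, model: PatchClassifier):
    """Portable NPZ weights file with JSON metadata."""
    mlp = model.mlp
    arrays = {f"coef_{i}": c for i, c in enumerate(mlp.coefs_)}
    arrays.update({f"intercept_{i}": b for i, b in enumerate(mlp.intercepts_)})
    arrays["classes"] = mlp.classes_
    meta = {"seed": model.seed, "epochs": model.epochs,
            "learning_rate": model.learning_rate,
            "layer_sizes": list(model.layer_sizes)}
    arrays["meta_json"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_model(path) -> PatchClassifier:
    data = np.load(path, allow_pickle=False)
    meta = json.loads(bytes(data["meta_json"]).decode())
    mlp = MLPClassifier(hidden_layer_sizes=(121,), activation="relu")
    mlp.coefs_ = [data["coef_0"], data["coef_1"]]
    mlp.intercepts_ = [data["intercept_0"], data["intercept_1"]]
    mlp.classes_ = data["classes"]
    mlp.n_layers_ = 3
    mlp.n_outputs_ = len(mlp.classes_)
    mlp.out_activation_ = "softmax"
    from sklearn.preprocessing import LabelBinarizer
    mlp._label_binarizer = LabelBinarizer().fit(mlp.classes_)
    return PatchClassifier(mlp, meta["seed"], meta["epochs"],
                           meta["learning_rate"])


def write_movie(outdir, movie: SimulatedMovie, stem: str = "movie"):
    """Write a simulated movie: stack, truth masks, event log, ground truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stack = RasterStack(movie.frames, movie.pixel_size, movie.fps)
    write_stack(outdir / f"{stem}.tif", stack,
                seed=movie.seed, start_species=movie.start_species,
                construct={"arm_bp_long": movie.construct.arm_bp_long,
                           "arm_bp_short": movie.construct.arm_bp_short,
                           "nps_bp": movie.construct.nps_bp})
    write_masks(outdir / f"{stem}_masks.tif", movie.truth_masks)
    write_events(outdir / f"{stem}_events.csv", movie.event_log, movie.fps)
    truth = pd.DataFrame({
        "frame": np.arange(len(movie.true_volumes)),
        "time_s": np.arange(len(movie.true_volumes)) / movie.fps,
        "true_volume_nm3": movie.true_volumes,
        "true_theta_long_deg": movie.true_angles[:, 0],
        "true_theta_short_deg": movie.true_angles[:, 1],
    })
    truth.to_csv(outdir / f"{stem}_truth.csv", index=False)
    return outdir / f"{stem}.tif"
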