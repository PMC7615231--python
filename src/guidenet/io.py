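"""On-disk layout for scan datasets and model checkpoints.

A dataset directory holds one subdirectory per sequence::

    data/seq_0000/
        features.h5   # dataset "features", (T, D)  (or frames.h5, "frames")
        gaze.csv      # t,x_px,y_px       raw pixels; normalized on load
        probe.csv     # t,qw,qx,qy,qz    one row per 6 Hz frame
        manifest.json # q_target, plane_type, seed, image size

Checkpoints are a single ``.npz`` archive holding every parameter array plus
the model configuration as a JSON string.
"""

from __future__ import annotations

import json
import shutil
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .gaze import denormalize_gaze, GazeSample
from .graph import FRAME_SHAPE
from .model import GuideNet, PolicyPair
from .quat import UnitQuaternion, canonicalize
from .simulate import SimSequence

__all__ = ["write_dataset", "read_dataset", "save_checkpoint", "load_checkpoint"]

_IMAGE_SIZE = (FRAME_SHAPE[1], FRAME_SHAPE[0])  # (width, height)


def write_dataset(sequences: list[SimSequence], out_dir: str | Path) -> Path:
    """Write sequences in the standard layout; partial writes are cleaned up."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        for i, seq in enumerate(sequences):
            d = out_dir / f"seq_{i:04d}"
            d.mkdir(exist_ok=True)
            written.append(d)
            if seq.features is not None:
                with h5py.File(d / "features.h5", "w") as f:
                    f.create_dataset("features", data=seq.features)
            if seq.frames is not None:
                with h5py.File(d / "frames.h5", "w") as f:
                    f.create_dataset("frames", data=seq.frames)
            px = np.array([denormalize_gaze(GazeSample(x, y), _IMAGE_SIZE) for x, y in seq.gaze])
            pd.DataFrame({"t": np.arange(seq.T), "x_px": px[:, 0], "y_px": px[:, 1]}).to_csv(
                d / "gaze.csv", index=False
            )
            q = seq.quats
            pd.DataFrame(
                {"t": np.arange(seq.T), "qw": q[:, 0], "qx": q[:, 1], "qy": q[:, 2], "qz": q[:, 3]}
            ).to_csv(d / "probe.csv", index=False)
            manifest = {
                "q_target": list(map(float, seq.q_target.to_array())),
                "plane_type": seq.plane_type,
                "seed": int(seq.seed),
                "image_size": list(_IMAGE_SIZE),
                "n_frames": int(seq.T),
            }
            (d / "manifest.json").write_text(json.dumps(manifest, indent=1))
        (out_dir / "manifest.json").write_text(json.dumps({"n_sequences": len(sequences)}, indent=1))
    except BaseException:
        for d in written:
            shutil.rmtree(d, ignore_errors=True)
        raise
    return out_dir


def read_dataset(data_dir: str | Path) -> list[SimSequence]:
    """Load a dataset directory back into memory. Round trips are
    bit-identical for quaternions/features; gaze round-trips to within half
    a pixel (pixels are the storage unit)."""
    data_dir = Path(data_dir)
    seqs: list[SimSequence] = []
    for d in sorted(data_dir.glob("seq_*")):
        manifest = json.loads((d / "manifest.json").read_text())
        w, h = manifest["image_size"]
        gz = pd.read_csv(d / "gaze.csv")
        gaze = np.column_stack([gz["x_px"].to_numpy() / w - 0.5, gz["y_px"].to_numpy() / h - 0.5])
        gaze = np.clip(gaze, -0.5 + 1e-9, 0.5 - 1e-9)
        pr = pd.read_csv(d / "probe.csv")
        quats = canonicalize(pr[["qw", "qx", "qy", "qz"]].to_numpy())
        features = frames = None
        if (d / "features.h5").exists():
            with h5py.File(d / "features.h5", "r") as f:
                features = f["features"][...]
        if (d / "frames.h5").exists():
            with h5py.File(d / "frames.h5", "r") as f:
                frames = f["frames"][...]
        q_target = UnitQuaternion.from_array(manifest["q_target"])
        from .quat import _angle_arr

        seqs.append(
            SimSequence(
                features=features,
                frames=frames,
                gaze=gaze,
                quats=quats,
                q_target=q_target,
                angle_to_target=_angle_arr(quats, q_target.to_array()),
                true_centers=np.zeros((len(gaze), 0, 2)),  # latent; not persisted
                fixation_index=np.full(len(gaze), -1),
                plane_type=manifest["plane_type"],
                seed=int(manifest["seed"]),
            )
        )
    return seqs


def save_checkpoint(model: GuideNet, path: str | Path) -> None:
    state = model.state_dict()
    config = {
        "probe": model.policy_pair.probe,
        "gaze": model.policy_pair.gaze,
        "feature_dim": model.feature_dim,
        "embed": model.embed,
        "hidden": model.hidden,
        "proj": model.proj,
        "L": model.L,
        "bidirectional": model.bidirectional,
    }
    np.savez(path, __config__=np.frombuffer(json.dumps(config).encode(), dtype=np.uint8), **state)


def load_checkpoint(path: str | Path) -> GuideNet:
    with np.load(path) as z:
        config = json.loads(bytes(z["__config__"]).decode())
        state = {k: z[k] for k in z.files if k != "__config__"}
    model = GuideNet(
        PolicyPair(probe=config["probe"], gaze=config["gaze"]),
        feature_dim=config["feature_dim"],
        embed=config["embed"],
        hidden=config["hidden"],
        proj=config["proj"],
        L=config["L"],
        bidirectional=config["bidirectional"],
    )
    model.load_state_dict(state)
    return model
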