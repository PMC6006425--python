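"""File round-trips: NIfTI volumes/runs, BIDS-style events TSV, JSON configs."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .design import Block, TaskDesign, Trial
from .network import NetworkModel
from .roi_vectors import ProfileResult, ROIVector
from .volumes import Run, StatMap, Volume

__all__ = [
    "save_volume",
    "load_volume",
    "save_run",
    "load_run",
    "events_to_tsv",
    "design_from_tsv",
    "model_to_json",
    "model_from_json",
    "vector_to_json",
    "vector_from_json",
    "profile_to_tsv",
]


def save_volume(volume: Volume, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(volume.data, dtype=np.float64), volume.affine), str(path))


def load_volume(path: str | Path) -> Volume:
    img = nib.load(str(path))
    return Volume(np.asanyarray(img.dataobj).astype(np.float64), img.affine)


def save_run(run: Run, path: str | Path) -> None:
    img = nib.Nifti1Image(np.asarray(run.data, dtype=np.float64), run.affine)
    zooms = list(img.header.get_zooms()[:3]) + [run.tr_s]
    img.header.set_zooms(zooms)
    nib.save(img, str(path))


def load_run(path: str | Path) -> Run:
    img = nib.load(str(path))
    tr = float(img.header.get_zooms()[3])
    return Run(np.asanyarray(img.dataobj).astype(np.float64), img.affine, tr)


def events_to_tsv(design: TaskDesign, path: str | Path, rt_s: np.ndarray | None = None) -> None:
    """One row per trial (onset, duration, trial_type, response_time) plus
    rest rows; block membership is recoverable from contiguous trial timing."""
    rows = []
    for i, tr in enumerate(design.trials):
        rows.append(
            {
                "onset": tr.onset_s,
                "duration": tr.duration_s,
                "trial_type": tr.condition,
                "fixation": tr.fixation_s,
                "response_time": float(rt_s[i]) if rt_s is not None else np.nan,
            }
        )
    for onset, dur in design.rests:
        rows.append(
            {
                "onset": onset,
                "duration": dur,
                "trial_type": "rest",
                "fixation": 0.0,
                "response_time": np.nan,
            }
        )
    df = pd.DataFrame(rows).sort_values("onset")
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def design_from_tsv(path: str | Path):
    """Rebuild a TaskDesign (and the RT covariate) from an events table."""
    df = pd.read_csv(path, sep="\t")
    trials: list[Trial] = []
    rests: list[tuple[float, float]] = []
    rt = []
    for _, row in df.sort_values("onset").iterrows():
        if row["trial_type"] == "rest":
            rests.append((float(row["onset"]), float(row["duration"])))
        else:
            fix = float(row.get("fixation", 0.0))
            trials.append(
                Trial(row["trial_type"], float(row["onset"]), fix, float(row["duration"]) - fix)
            )
            rt.append(float(row["response_time"]))
    # merge contiguous same-condition trials back into blocks
    blocks: list[Block] = []
    for tr in trials:
        if (
            blocks
            and blocks[-1].condition == tr.condition
            and abs(blocks[-1].offset_s - tr.onset_s) < 1e-6
        ):
            blocks[-1] = Block(tr.condition, blocks[-1].onset_s, blocks[-1].duration_s + tr.duration_s)
        else:
            blocks.append(Block(tr.condition, tr.onset_s, tr.duration_s))
    conditions = tuple(dict.fromkeys(b.condition for b in blocks))
    ends = [b.offset_s for b in blocks] + [o + d for o, d in rests]
    total = max(ends) if ends else 0.0
    design = TaskDesign(conditions, blocks, trials, rests, total)
    return design, np.array(rt)


def model_to_json(model: NetworkModel, path: str | Path) -> None:
    payload = {
        "name": model.name,
        "nodes": list(model.nodes),
        "a": model.a.tolist(),
        "a_free": model.a_free.tolist(),
        "b": {k: v.tolist() for k, v in model.b.items()},
        "b_free": {k: v.tolist() for k, v in model.b_free.items()},
        "c": {k: v.tolist() for k, v in model.c.items()},
        "c_free": {k: v.tolist() for k, v in model.c_free.items()},
        "input_conditions": {k: list(v) for k, v in model.input_conditions.items()},
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def model_from_json(path: str | Path) -> NetworkModel:
    payload = json.loads(Path(path).read_text())
    return NetworkModel(
        nodes=tuple(payload["nodes"]),
        a=np.array(payload["a"]),
        b={k: np.array(v) for k, v in payload["b"].items()},
        c={k: np.array(v) for k, v in payload["c"].items()},
        input_conditions={k: tuple(v) for k, v in payload["input_conditions"].items()},
        a_free=np.array(payload["a_free"], dtype=bool),
        b_free={k: np.array(v, dtype=bool) for k, v in payload["b_free"].items()},
        c_free={k: np.array(v, dtype=bool) for k, v in payload["c_free"].items()},
        name=payload.get("name", "model"),
    )


def vector_to_json(vector: ROIVector, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "label": vector.label,
                "radius_mm": vector.radius_mm,
                "centres_mm": vector.centres_mm.tolist(),
            },
            indent=2,
        )
    )


def vector_from_json(path: str | Path) -> ROIVector:
    payload = json.loads(Path(path).read_text())
    return ROIVector(
        np.array(payload["centres_mm"]), payload["radius_mm"], label=payload.get("label", "")
    )


def profile_to_tsv(profile: ProfileResult, path: str | Path) -> None:
    profile.to_frame().to_csv(path, sep="\t", index=False)
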