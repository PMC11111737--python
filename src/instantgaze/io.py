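"""Readers and writers for session logs, prior models and target layouts.

Session logs are JSONL (one fixation record per line) or an equivalent CSV
dialect with a fixed header.  Prior models travel as a single JSON bundle
carrying the space tag, the samples with weights, and provenance ids.
Target layouts are YAML; dwell trigger logs are JSONL.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, List, Optional, Sequence, Union

import pandas as pd
import yaml

from .exceptions import ValidationError
from .interaction import InteractiveTarget, TriggerRecord
from .model import FixationSample, ScreenPoint, TrainingSet
from .engine import PriorModel
from .spaces import FeatureVector, RawObservation, SpaceKind

__all__ = [
    "write_session_jsonl",
    "read_session_jsonl",
    "write_session_csv",
    "read_session_csv",
    "save_prior",
    "load_prior",
    "write_triggers_jsonl",
    "save_target_layout",
    "load_target_layout",
]

CSV_HEADER = [
    "subject_id",
    "fixation_index",
    "timestamp",
    "pupil_x",
    "pupil_y",
    "corner_m",
    "corner_n",
    "tx",
    "ty",
]

PathLike = Union[str, Path]


def _obs_record(obs: RawObservation) -> dict:
    rec = {
        "subject_id": obs.subject_id,
        "fixation_index": obs.fixation_index,
        "timestamp": obs.timestamp,
        "pupil_x": obs.pupil_x,
        "pupil_y": obs.pupil_y,
        "corner_m": obs.corner_m,
        "corner_n": obs.corner_n,
    }
    if obs.target is not None:
        rec["tx"], rec["ty"] = obs.target
    return rec


def _record_obs(rec: dict) -> RawObservation:
    target = None
    if rec.get("tx") is not None and not pd.isna(rec.get("tx")):
        target = (float(rec["tx"]), float(rec["ty"]))
    return RawObservation(
        pupil_x=float(rec["pupil_x"]),
        pupil_y=float(rec["pupil_y"]),
        corner_m=float(rec["corner_m"]),
        corner_n=float(rec["corner_n"]),
        target=target,
        fixation_index=int(rec.get("fixation_index", 0)),
        subject_id=str(rec.get("subject_id", "")),
        timestamp=float(rec.get("timestamp", 0.0)),
    )


def write_session_jsonl(observations: Iterable[RawObservation], path: PathLike) -> None:
    with open(path, "w") as fh:
        for obs in observations:
            fh.write(json.dumps(_obs_record(obs)) + "\n")


def read_session_jsonl(path: PathLike) -> List[RawObservation]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                out.append(_record_obs(json.loads(line)))
    return out


def write_session_csv(observations: Iterable[RawObservation], path: PathLike) -> None:
    rows = [_obs_record(o) for o in observations]
    pd.DataFrame(rows, columns=CSV_HEADER).to_csv(path, index=False)


def read_session_csv(path: PathLike) -> List[RawObservation]:
    df = pd.read_csv(path)
    missing = set(CSV_HEADER[:7]) - set(df.columns)
    if missing:
        raise ValidationError(f"session CSV missing columns: {sorted(missing)}")
    return [_record_obs(rec) for rec in df.to_dict("records")]


def save_prior(prior: PriorModel, path: PathLike) -> None:
    payload = {
        "space": prior.space.value,
        "base_weight": prior.base_weight,
        "samples": [
            {
                "feature": list(s.feature.as_tuple()),
                "target": [s.target.gx, s.target.gy],
                "weight": s.weight,
                "provenance": s.provenance,
            }
            for s in prior.training
        ],
    }
    Path(path).write_text(json.dumps(payload))


def load_prior(path: PathLike) -> PriorModel:
    d = json.loads(Path(path).read_text())
    space = SpaceKind(d["space"])
    samples = [
        FixationSample(
            FeatureVector(*rec["feature"], space=space),
            ScreenPoint(*rec["target"]),
            float(rec.get("weight", 1.0)),
            str(rec.get("provenance", "prior")),
        )
        for rec in d["samples"]
    ]
    return PriorModel(TrainingSet(samples), base_weight=float(d.get("base_weight", 1.0)))


def write_triggers_jsonl(records: Iterable[TriggerRecord], path: PathLike) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(
                json.dumps(
                    {
                        "event_id": r.event_id,
                        "gaze": [r.gaze.gx, r.gaze.gy],
                        "target_center": [r.target_center.gx, r.target_center.gy],
                        "trigger_time": r.trigger_time,
                    }
                )
                + "\n"
            )


def save_target_layout(targets: Sequence[InteractiveTarget], path: PathLike) -> None:
    payload = [
        {
            "event_id": t.event_id,
            "center": [t.center.gx, t.center.gy],
            "visual_radius": t.visual_radius,
            "collider_radius": t.collider_radius,
        }
        for t in targets
    ]
    Path(path).write_text(yaml.safe_dump(payload))


def load_target_layout(path: PathLike) -> List[InteractiveTarget]:
    payload = yaml.safe_load(Path(path).read_text())
    return [
        InteractiveTarget(
            ScreenPoint(*rec["center"]),
            float(rec["visual_radius"]),
            float(rec["collider_radius"]),
            str(rec.get("event_id", "")),
        )
        for rec in payload
    ]
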