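"""File formats for the CLI's stage-wise handoffs.

Datasets are a directory with ``labels.csv`` (recording_id, subject_id,
epoch_index, stage) and ``signals.npz`` (one array per recording id).
Per-epoch probability tables, fused labels, confusion matrices and metric
reports are plain CSV/JSON; HMM parameters travel as YAML.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .evaluation import ConfusionMatrix, MetricReport
from .hmm import HmmParameters
from .simulate import SyntheticRecording
from .stages import STAGES, decode_stages, encode_stages

_HEADS = ("backward", "current", "forward")


def save_dataset(recordings: Sequence[SyntheticRecording], out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    arrays = {}
    for r in recordings:
        arrays[r.recording_id] = r.signals
        for i, code in enumerate(r.labels):
            rows.append(
                {
                    "recording_id": r.recording_id,
                    "subject_id": r.subject_id,
                    "epoch_index": i,
                    "stage": STAGES[int(code)],
                }
            )
    pd.DataFrame(rows).to_csv(out / "labels.csv", index=False)
    np.savez_compressed(out / "signals.npz", **arrays)


def load_dataset(in_dir: str | Path) -> list[SyntheticRecording]:
    path = Path(in_dir)
    labels = pd.read_csv(path / "labels.csv")
    signals = np.load(path / "signals.npz")
    recordings = []
    for rec_id, grp in labels.groupby("recording_id", sort=False):
        grp = grp.sort_values("epoch_index")
        recordings.append(
            SyntheticRecording(
                recording_id=str(rec_id),
                subject_id=str(grp["subject_id"].iloc[0]),
                signals=signals[str(rec_id)],
                labels=encode_stages(grp["stage"].tolist()),
            )
        )
    return recordings


def save_probability_table(
    path: str | Path,
    context_probs: np.ndarray,
    recording_ids: np.ndarray,
    epoch_indices: np.ndarray,
) -> None:
    """Write per-epoch context probabilities as long-format CSV."""
    probs = np.asarray(context_probs)
    rows = []
    for n in range(probs.shape[0]):
        for h, head in enumerate(_HEADS):
            row = {
                "recording_id": recording_ids[n],
                "epoch_index": int(epoch_indices[n]),
                "head": head,
            }
            row.update({f"p_{s}": probs[n, h, j] for j, s in enumerate(STAGES)})
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def load_probability_table(path: str | Path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Read a probability CSV back to ((n,3,5) probs, recording_ids, epoch_indices)."""
    df = pd.read_csv(path)
    df["__head"] = df["head"].map({h: i for i, h in enumerate(_HEADS)})
    df = df.sort_values(["recording_id", "epoch_index", "__head"], kind="stable")
    pcols = [f"p_{s}" for s in STAGES]
    n = len(df) // len(_HEADS)
    probs = df[pcols].to_numpy().reshape(n, len(_HEADS), len(STAGES))
    sub = df.iloc[:: len(_HEADS)]
    return probs, sub["recording_id"].to_numpy(), sub["epoch_index"].to_numpy()


def save_labels_csv(path: str | Path, recording_ids, epoch_indices, codes, scores=None) -> None:
    df = pd.DataFrame(
        {
            "recording_id": recording_ids,
            "epoch_index": epoch_indices,
            "stage": decode_stages(codes),
        }
    )
    if scores is not None:
        for j, s in enumerate(STAGES):
            df[f"score_{s}"] = np.asarray(scores)[:, j]
    df.to_csv(path, index=False)


def load_labels_csv(path: str | Path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    df = pd.read_csv(path).sort_values(["recording_id", "epoch_index"], kind="stable")
    return (
        encode_stages(df["stage"].tolist()),
        df["recording_id"].to_numpy(),
        df["epoch_index"].to_numpy(),
    )


def save_checkpoint(path: str | Path, net_params: dict, meta: dict) -> None:
    """Branch checkpoint: parameter arrays + JSON metadata (config, accuracies)."""
    np.savez_compressed(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **net_params)


def load_checkpoint(path: str | Path) -> tuple[dict, dict]:
    data = np.load(path)
    meta = json.loads(bytes(data["__meta__"]).decode())
    params = {k: data[k] for k in data.files if k != "__meta__"}
    return params, meta


def save_hmm_parameters(path: str | Path, params: HmmParameters) -> None:
    payload = {
        "stage_order": list(STAGES),
        "transition": params.transition.tolist(),
        "emission": params.emission.tolist(),
        "initial": params.initial.tolist(),
        "window_length": int(params.window_length),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def load_hmm_parameters(path: str | Path) -> HmmParameters:
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    return HmmParameters(
        transition=np.asarray(payload["transition"]),
        emission=np.asarray(payload["emission"]),
        initial=np.asarray(payload["initial"]),
        window_length=int(payload["window_length"]),
    )


def save_confusion_csv(path: str | Path, cm: ConfusionMatrix) -> None:
    pd.DataFrame(cm.counts, index=list(STAGES), columns=list(STAGES)).to_csv(path)


def load_confusion_csv(path: str | Path) -> ConfusionMatrix:
    df = pd.read_csv(path, index_col=0)
    return ConfusionMatrix(df.loc[list(STAGES), list(STAGES)].to_numpy())


def save_report_json(path: str | Path, report: MetricReport, extra: dict | None = None) -> None:
    payload = {"raw": report.to_dict(), "display": report.rounded()}
    if extra:
        payload.update(extra)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
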