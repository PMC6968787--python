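"""On-disk interchange formats.

Recordings travel as two-channel CSV sample tables (columns ``time_s``,
``left_uv``, ``right_uv``) with a JSON sidecar holding the generating
spec and the impact sample; epochs as per-epoch CSVs.  A compact ``.npy``
codec backs the pipeline's stage handoffs, where sample tables would be
needlessly large.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import Epoch
from .synth import Recording, SubjectSpec


def write_recording_csv(rec: Recording, path: str | Path) -> None:
    """CSV sample table plus ``<stem>.json`` sidecar manifest."""
    path = Path(path)
    t = np.arange(rec.n_samples) / rec.fs
    df = pd.DataFrame({"time_s": t, "left_uv": rec.left, "right_uv": rec.right})
    df.to_csv(path, index=False, float_format="%.6f")
    sidecar = {
        "fs": rec.fs,
        "cci_sample": int(rec.cci_sample),
        "ipsilateral_channel": rec.ipsilateral_channel,
        "spec": rec.meta.to_dict() if rec.meta is not None else None,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1, sort_keys=True))


def read_recording_csv(path: str | Path) -> Recording:
    path = Path(path)
    df = pd.read_csv(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    spec = SubjectSpec.from_dict(sidecar["spec"]) if sidecar.get("spec") else None
    return Recording(
        left=df["left_uv"].to_numpy(),
        right=df["right_uv"].to_numpy(),
        fs=float(sidecar["fs"]),
        cci_sample=int(sidecar["cci_sample"]),
        meta=spec,
        ipsilateral_channel=sidecar.get("ipsilateral_channel", "right"),
    )


def write_recording_npy(rec: Recording, path: str | Path) -> None:
    """Compact binary stage artifact: stacked float32 channels + sidecar JSON.

    Raw ``.npy`` (not a zip archive) so repeated runs are byte-identical.
    """
    path = Path(path)
    np.save(path, np.stack([rec.left, rec.right]).astype(np.float32))
    sidecar = {
        "fs": rec.fs,
        "cci_sample": int(rec.cci_sample),
        "ipsilateral_channel": rec.ipsilateral_channel,
        "spec": rec.meta.to_dict() if rec.meta is not None else None,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1, sort_keys=True))


def read_recording_npy(path: str | Path) -> Recording:
    path = Path(path)
    stacked = np.load(path)
    left = stacked[0].astype(float)
    right = stacked[1].astype(float)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    spec = SubjectSpec.from_dict(sidecar["spec"]) if sidecar.get("spec") else None
    return Recording(
        left=left, right=right, fs=float(sidecar["fs"]),
        cci_sample=int(sidecar["cci_sample"]), meta=spec,
        ipsilateral_channel=sidecar.get("ipsilateral_channel", "right"),
    )


def write_epoch_csv(epoch: Epoch, path: str | Path) -> None:
    t = np.arange(len(epoch.left)) / epoch.fs
    df = pd.DataFrame({"time_s": t, "left_uv": epoch.left, "right_uv": epoch.right})
    df.to_csv(path, index=False, float_format="%.6f")


def read_epoch_csv(path: str | Path, label: str, fs: float,
                   source_subject: str = "") -> Epoch:
    df = pd.read_csv(path)
    return Epoch(
        label=label,
        left=df["left_uv"].to_numpy(),
        right=df["right_uv"].to_numpy(),
        fs=fs,
        source_subject=source_subject,
    )
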