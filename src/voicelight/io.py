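"""Readers/writers for the pipeline's on-disk formats.

Events travel as BIDS-style TSV (tab-delimited, UTF-8, "n/a" for absent
values); volumes as NIfTI-1 (.nii or .nii.gz); configuration as YAML or
JSON; every written output may carry a JSON provenance sidecar.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .design import EVENT_COLUMNS


class SchemaError(ValueError):
    pass


REQUIRED_EVENT_COLUMNS = ["onset", "duration", "speaker", "word", "run"]


def read_events(path) -> pd.DataFrame:
    """Read a BIDS-style events TSV; sorts on onset (with a warning) if
    the file is out of order; missing required columns raise SchemaError."""
    df = pd.read_csv(path, sep="\t", na_values=["n/a"], keep_default_na=False,
                     dtype={"speaker": str, "word": str})
    missing = [c for c in REQUIRED_EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"events file {path} missing columns: {missing}")
    if "response" not in df.columns:
        df["response"] = np.nan
    if "response_time" not in df.columns:
        df["response_time"] = np.nan
    if "missing" not in df.columns:
        df["missing"] = df["response"].isna()
    df["missing"] = df["missing"].astype(bool)
    df["response"] = df["response"].where(df["response"].notna(), "n/a")
    per_run_sorted = df.groupby("run")["onset"].apply(
        lambda s: s.is_monotonic_increasing
    )
    if not per_run_sorted.all():
        warnings.warn(f"{path}: onsets out of order; sorting", UserWarning)
        df = df.sort_values(["run", "onset"]).reset_index(drop=True)
    return df[[c for c in EVENT_COLUMNS if c in df.columns]]


def write_events(events: pd.DataFrame, path) -> Path:
    path = Path(path)
    out = events.copy()
    out["response"] = out["response"].fillna("n/a")
    out.to_csv(path, sep="\t", index=False, na_rep="n/a",
               float_format="%.6f")
    return path


def read_volume(path):
    """Load a NIfTI volume; returns (data, affine). 3D or 4D only."""
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata())
    if data.ndim not in (3, 4):
        raise SchemaError(f"{path}: expected 3D or 4D volume, got {data.ndim}D")
    return data, img.affine


def write_volume(data, affine, path) -> Path:
    path = Path(path)
    nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine).to_filename(
        str(path)
    )
    return path


def check_coregistered(affines, atol=1e-4):
    """Raise if subject affines differ (shared-grid contract)."""
    ref = np.asarray(affines[0])
    for i, a in enumerate(affines[1:], start=2):
        if not np.allclose(ref, a, atol=atol):
            raise SchemaError(
                f"affine mismatch between subject 1 and subject {i}: "
                "volumes are not co-registered"
            )


def load_config(path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        import yaml

        return yaml.safe_load(text)
    return json.loads(text)


def save_config(config: dict, path) -> Path:
    path = Path(path)
    if path.suffix in (".yaml", ".yml"):
        import yaml

        path.write_text(yaml.safe_dump(config, sort_keys=False))
    else:
        path.write_text(json.dumps(config, indent=2, default=str))
    return path


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def write_sidecar(path, config: dict, seeds=None, extra=None) -> Path:
    """JSON provenance sidecar next to an output file."""
    side = Path(str(path) + ".json")
    payload = {"config_hash": config_hash(config), "seeds": seeds or {}}
    if extra:
        payload.update(extra)
    side.write_text(json.dumps(payload, indent=2, default=str))
    return side
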