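"""File I/O and run manifests.

Tables are TSV (tab-delimited, header row, UTF-8; angles in degrees, times
in seconds), volumetric data NIfTI, configs JSON, motion parameters a
6-column whitespace-delimited text file.  A run manifest records the config
hash, package version and per-artifact checksums so identical configs
reproduce identical checksums for deterministic stages.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "DataError",
    "save_table",
    "load_table",
    "save_map",
    "load_map",
    "save_motion",
    "load_motion",
    "file_checksum",
    "write_manifest",
]

TRIAL_COLUMNS = [
    "trial_id", "block", "within_block_index", "start_id", "target_id",
    "direction_deg", "is_catch", "catch_view_correct", "cue_onset_s",
    "imagination_end_s",
]


class DataError(ValueError):
    pass


def save_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def load_table(path, kind: str | None = None) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if kind == "trials":
        missing = set(TRIAL_COLUMNS) - set(df.columns)
        if missing:
            raise DataError(f"trial table {path} missing columns {sorted(missing)}")
        df = df[TRIAL_COLUMNS + [c for c in df.columns if c not in TRIAL_COLUMNS]]
        for col in ("is_catch", "catch_view_correct"):
            df[col] = df[col].astype(bool)
    return df


def save_map(arr: np.ndarray, path, voxel_size_mm: float = 2.0) -> None:
    """Write a 3-D (or 4-D) array as NIfTI; NaNs mark undefined voxels."""
    import nibabel as nib

    affine = np.diag([voxel_size_mm] * 3 + [1.0])
    nib.save(nib.Nifti1Image(np.asarray(arr, dtype=np.float64), affine), str(path))


def load_map(path) -> np.ndarray:
    import nibabel as nib

    return np.asarray(nib.load(str(path)).get_fdata())


def save_motion(motion: pd.DataFrame, path) -> None:
    if motion.shape[1] != 6:
        raise DataError("motion table must have exactly 6 columns")
    np.savetxt(path, motion.to_numpy(), fmt="%.10g")


def load_motion(path) -> pd.DataFrame:
    arr = np.loadtxt(path)
    if arr.ndim == 1:
        arr = arr[None, :]
    if arr.shape[1] != 6:
        raise DataError(f"motion table {path} must have 6 columns, found {arr.shape[1]}")
    return pd.DataFrame(arr, columns=[f"mot{k}" for k in range(1, 7)])


def file_checksum(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(out_dir, config_dict: dict, artifacts: list[str]) -> Path:
    """Manifest with config hash and artifact checksums under ``out_dir``."""
    from hexdir import __version__

    out_dir = Path(out_dir)
    payload = {
        "package_version": __version__,
        "config_sha256": hashlib.sha256(
            json.dumps(config_dict, sort_keys=True).encode()
        ).hexdigest(),
        "artifacts": {
            str(Path(a).relative_to(out_dir)): file_checksum(a) for a in artifacts
        },
    }
    path = out_dir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
    return path
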