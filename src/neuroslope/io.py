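"""TSV/NIfTI readers and writers plus run provenance records.

TSV is the interchange dialect: tab-separated, UTF-8, "." for missing, one
header line. Volumes are NIfTI (.nii.gz) via nibabel.
"""

from __future__ import annotations

import hashlib
import json
import platform
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd


def write_tsv(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, na_rep=".")


def read_tsv(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input file not found: {path}")
    return pd.read_csv(path, sep="\t", na_values=".")


def write_volume(vol: np.ndarray, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    nib.save(nib.Nifti1Image(np.asarray(vol, dtype=np.float32), affine=np.eye(4)), str(path))


def read_volume(path) -> np.ndarray:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume not found: {path}")
    return np.asarray(nib.load(str(path)).get_fdata(), dtype=float)


def write_volumes(volumes: dict[str, np.ndarray], directory) -> pd.DataFrame:
    """Write each volume as <scan_id>.nii.gz; returns a scan_id->path table."""
    directory = Path(directory)
    rows = []
    for scan_id, vol in volumes.items():
        path = directory / f"{scan_id}.nii.gz"
        write_volume(vol, path)
        rows.append((scan_id, str(path)))
    return pd.DataFrame(rows, columns=["scan_id", "scan_path"])


def read_volumes(scan_table: pd.DataFrame) -> dict[str, np.ndarray]:
    return {row.scan_id: read_volume(row.scan_path) for row in scan_table.itertuples()}


def write_provenance(path, config_dict: dict, seed: int, stage: str) -> None:
    """Machine-readable record of what produced an output directory."""
    from . import __version__

    canonical = json.dumps(config_dict, sort_keys=True, default=str)
    record = {
        "stage": stage,
        "seed": seed,
        "config_sha256": hashlib.sha256(canonical.encode()).hexdigest(),
        "package_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
    }
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(record, fh, indent=2, sort_keys=True)
        fh.write("\n")
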