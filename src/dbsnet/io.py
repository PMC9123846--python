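"""NIfTI and table I/O helpers shared by the pipeline and the CLI."""

from __future__ import annotations

import hashlib
import os
from typing import List, Tuple

import nibabel as nib
import numpy as np

from .seedmap import GridMismatchError, SeedMask, StatMap, SubjectScan

__all__ = [
    "read_nifti",
    "write_nifti",
    "load_scan",
    "load_seed_mask",
    "write_stat_map",
    "file_sha256",
]


def read_nifti(path) -> Tuple[np.ndarray, np.ndarray]:
    """Load a NIfTI file; returns (data array, affine). 3-D and 4-D supported."""
    try:
        img = nib.load(str(path))
    except Exception as exc:            # nibabel raises several error types
        raise IOError(f"cannot read NIfTI file {path}: {exc}") from exc
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim not in (3, 4):
        raise IOError(f"{path}: expected a 3-D or 4-D volume, got {data.ndim}-D")
    return data, np.asarray(img.affine, dtype=np.float64)


def write_nifti(volume: np.ndarray, affine: np.ndarray, path) -> None:
    """Write a volume losslessly (float64 for maps, uint8 for binary data)."""
    volume = np.asarray(volume)
    nib.Nifti1Image(volume, np.asarray(affine)).to_filename(str(path))


def load_scan(path, tr_seconds: float = 3.0) -> SubjectScan:
    data, affine = read_nifti(path)
    if data.ndim != 4:
        raise IOError(f"{path}: subject scans must be 4-D")
    sid = os.path.basename(str(path)).split(".")[0].replace("_bold", "")
    return SubjectScan(data=data, affine=affine, tr_seconds=tr_seconds,
                       subject_id=sid)


def load_seed_mask(path, name: str = "") -> SeedMask:
    data, affine = read_nifti(path)
    if data.ndim != 3:
        raise IOError(f"{path}: seed masks must be 3-D")
    if not name:
        name = os.path.basename(str(path)).split(".")[0]
        name = name.replace("region-", "").replace("_mask", "")
    return SeedMask(name=name, mask=data > 0, affine=affine)


def write_stat_map(stat_map: StatMap, path) -> None:
    if stat_map.kind == "binary":
        write_nifti(stat_map.data.astype(np.uint8), stat_map.affine, path)
    else:
        write_nifti(stat_map.data, stat_map.affine, path)


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
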