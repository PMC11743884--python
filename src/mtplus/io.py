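"""File I/O: NIfTI-1 volumes and delimited connectome/ROI tables."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from mtplus.roi import ConnectomeMatrix
from mtplus.voxel import CODE_NAMES, MPMLabelVolume


def save_volume(
    data: np.ndarray,
    path: str | Path,
    voxel_size: Sequence[float] = (1.0, 1.0, 1.0),
    dtype=None,
) -> None:
    """Write a 3D array as NIfTI-1 with a diagonal affine from voxel size."""
    arr = np.asarray(data)
    if dtype is not None:
        arr = arr.astype(dtype)
    affine = np.diag(list(voxel_size) + [1.0])
    nib.save(nib.Nifti1Image(arr, affine), str(path))


def load_volume(path: str | Path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj)


def save_mpm(mpm: MPMLabelVolume, path: str | Path) -> None:
    """Integer-coded label volume plus a sidecar label-map CSV."""
    path = Path(path)
    save_volume(mpm.labels, path, dtype=np.int16)
    sidecar = path.with_suffix("").with_suffix("")  # strip .nii / .nii.gz
    table = pd.DataFrame(
        sorted(CODE_NAMES.items()), columns=["code", "label"]
    )
    table.to_csv(f"{sidecar}_labels.csv", index=False)


def save_connectome(conn: ConnectomeMatrix, path: str | Path) -> None:
    """Square table with a header row/column of region labels."""
    df = pd.DataFrame(conn.weights, index=conn.labels, columns=conn.labels)
    df.to_csv(path)
    if conn.node_volumes is not None:
        vols = pd.DataFrame(
            {"label": conn.labels, "volume": conn.node_volumes}
        )
        vols.to_csv(Path(str(path)).with_suffix(".volumes.csv"), index=False)


def load_connectome(
    path: str | Path, subject_id: str = "group"
) -> ConnectomeMatrix:
    df = pd.read_csv(path, index_col=0)
    vol_path = Path(str(path)).with_suffix(".volumes.csv")
    vols = None
    if vol_path.exists():
        vt = pd.read_csv(vol_path)
        vols = vt.set_index("label").loc[list(df.index), "volume"].to_numpy()
    return ConnectomeMatrix(
        weights=df.to_numpy(),
        labels=tuple(df.index),
        node_volumes=vols,
        subject_id=subject_id,
    )
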