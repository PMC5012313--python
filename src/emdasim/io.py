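"""NIfTI volume I/O and report serialization.

Volumes are written as NIfTI-1 with the grid spacing (mm) on the affine
diagonal and the origin in the translation column; the label legend
travels as a JSON sidecar ``{label: tissue}`` next to the label volume.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .grid import LabelVolume, VoxelGrid

__all__ = [
    "write_labels",
    "read_labels",
    "write_volume",
    "read_volume",
    "write_json",
]


def _affine(grid: VoxelGrid) -> np.ndarray:
    aff = np.diag(list(grid.spacing) + [1.0])
    aff[:3, 3] = grid.origin
    return aff


def _grid_from(img: nib.Nifti1Image) -> VoxelGrid:
    aff = img.affine
    spacing = tuple(float(aff[i, i]) for i in range(3))
    if not np.allclose(aff[:3, :3], np.diag(spacing)):
        raise ValueError("only axis-aligned NIfTI volumes are supported")
    return VoxelGrid(shape=img.shape[:3], spacing=spacing,
                     origin=tuple(float(v) for v in aff[:3, 3]))


def write_volume(path: str | Path, data: np.ndarray, grid: VoxelGrid) -> None:
    """Write a scalar volume aligned to ``grid`` as NIfTI."""
    img = nib.Nifti1Image(np.asarray(data), _affine(grid))
    nib.save(img, str(path))


def read_volume(path: str | Path) -> tuple[np.ndarray, VoxelGrid]:
    img = nib.load(str(path))
    return np.asarray(img.dataobj), _grid_from(img)


def write_labels(path: str | Path, volume: LabelVolume) -> Path:
    """Write a label volume (int16 NIfTI) plus its JSON legend sidecar."""
    path = Path(path)
    img = nib.Nifti1Image(volume.labels.astype(np.int16), _affine(volume.grid))
    nib.save(img, str(path))
    sidecar = path.with_suffix("").with_suffix("")  # strip .nii.gz / .nii
    legend_path = Path(str(sidecar) + "_legend.json")
    legend_path.write_text(
        json.dumps({str(k): v for k, v in volume.legend.items()}, indent=2)
    )
    return legend_path


def read_labels(path: str | Path, legend_path: str | Path | None = None) -> LabelVolume:
    """Read a label volume and its legend sidecar."""
    path = Path(path)
    data, grid = read_volume(path)
    if legend_path is None:
        sidecar = path.with_suffix("").with_suffix("")
        legend_path = Path(str(sidecar) + "_legend.json")
    legend_raw = json.loads(Path(legend_path).read_text())
    legend = {int(k): str(v) for k, v in legend_raw.items()}
    return LabelVolume(grid=grid, labels=np.asarray(data).astype(np.int32),
                       legend=legend)


def write_json(path: str | Path, obj) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=default))
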