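"""NIfTI / JSON-sidecar / TSV plumbing.

CEST stacks travel as NIfTI-1 volumes (x, y, slice, offset) with a JSON
sidecar holding the offset list and saturation parameters, since NIfTI has
no native metadata slot for a saturation-frequency axis.  Masks and maps
are plain 3-D NIfTI; cohort and summary tables are TSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .bmsim import AcquisitionProtocol
from .phantom import CESTStack

__all__ = [
    "write_stack",
    "read_stack",
    "write_map",
    "read_map",
    "write_table",
    "read_table",
]


def _affine(voxel_mm: float, slice_mm: float) -> np.ndarray:
    return np.diag([voxel_mm, voxel_mm, slice_mm, 1.0])


def write_stack(stack: CESTStack, path, voxel_mm: float = 30.0 / 128,
                slice_mm: float = 1.5, seed: int | None = None) -> None:
    """Write a saturated stack + S0 + sidecar.

    ``path`` is the stem: writes ``<stem>.nii``, ``<stem>_s0.nii`` and
    ``<stem>.json``.
    """
    path = Path(path)
    aff = _affine(voxel_mm, slice_mm)
    nib.save(nib.Nifti1Image(stack.voxels.astype(np.float32), aff), str(path) + ".nii")
    nib.save(nib.Nifti1Image(stack.s0.astype(np.float32), aff), str(path) + "_s0.nii")
    sidecar = {
        "offsets_ppm": list(stack.protocol.offsets),
        "b1_amplitude_uT": stack.protocol.b1_amplitude,
        "saturation_duration_s": stack.protocol.saturation_duration,
        "field_strength_T": stack.protocol.field_strength,
        "phase": stack.phase,
        "voxel_mm": voxel_mm,
        "slice_mm": slice_mm,
    }
    if seed is not None:
        sidecar["seed"] = seed
    with open(str(path) + ".json", "w") as fh:
        json.dump(sidecar, fh, indent=2)


def read_stack(path) -> CESTStack:
    path = Path(path)
    sidecar_path = Path(str(path) + ".json")
    if not sidecar_path.exists():
        raise FileNotFoundError(
            f"missing JSON sidecar {sidecar_path}: cannot interpret the offset axis"
        )
    with open(sidecar_path) as fh:
        sidecar = json.load(fh)
    for key in ("offsets_ppm", "b1_amplitude_uT", "saturation_duration_s",
                "field_strength_T", "phase"):
        if key not in sidecar:
            raise KeyError(f"sidecar {sidecar_path} lacks required key {key!r}")
    voxels = np.asarray(nib.load(str(path) + ".nii").dataobj, dtype=np.float32)
    s0 = np.asarray(nib.load(str(path) + "_s0.nii").dataobj, dtype=np.float32)
    protocol = AcquisitionProtocol(
        b1_amplitude=sidecar["b1_amplitude_uT"],
        saturation_duration=sidecar["saturation_duration_s"],
        field_strength=sidecar["field_strength_T"],
        offsets=tuple(sidecar["offsets_ppm"]),
    )
    return CESTStack(voxels=voxels, s0=s0, protocol=protocol, phase=sidecar["phase"])


def write_map(values: np.ndarray, path, voxel_mm: float = 30.0 / 128,
              slice_mm: float = 1.5) -> None:
    """3-D map (pH, acidity, mask, ST) as NIfTI."""
    aff = _affine(voxel_mm, slice_mm)
    nib.save(nib.Nifti1Image(np.asarray(values, dtype=np.float32), aff), str(path))


def read_map(path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj, dtype=np.float32)


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t")
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed TSV {path}: {exc}") from exc
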