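"""Volume, mask and table input/output.

Multi-echo volumes are stored as 4D NIfTI files with the echo dimension last,
accompanied by a JSON sidecar carrying the acquisition metadata (echo times,
repetition time, voxel spacing).  Label masks are integer NIfTI volumes with a
JSON label dictionary.  Result tables are plain CSV.

All voxel indices are 0-based; physical distances are in millimetres and
respect anisotropic voxel spacing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "MESEVolume",
    "LabelMask",
    "FormatError",
    "MetadataError",
    "read_mese",
    "write_mese",
    "read_mask",
    "write_mask",
    "read_table",
    "write_table",
]


class FormatError(ValueError):
    """Raised when file contents violate the expected on-disk format."""


class MetadataError(ValueError):
    """Raised when sidecar metadata is missing or inconsistent."""


@dataclass
class MESEVolume:
    """A multi-echo spin-echo acquisition.

    Attributes
    ----------
    intensities
        4D array indexed ``(echo, slice, row, col)``, arbitrary units.
        Axis 1 runs over sagittal slices (medial--lateral), axis 2
        superior--inferior, axis 3 anterior--posterior.
    spacing_mm
        Physical voxel spacing ``(slice, row, col)`` in mm.  The slice value
        includes any inter-slice gap.
    echo_times_ms
        Strictly increasing echo times, one per echo image.
    tr_ms
        Repetition time (metadata only).
    """

    intensities: np.ndarray
    spacing_mm: tuple[float, float, float]
    echo_times_ms: tuple[float, ...]
    tr_ms: float = 2700.0

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities)
        self.echo_times_ms = tuple(float(t) for t in self.echo_times_ms)
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if self.intensities.ndim != 4:
            raise FormatError("intensities must be 4D (echo, slice, row, col)")
        if self.intensities.shape[0] != len(self.echo_times_ms):
            raise FormatError(
                f"echo count mismatch: {self.intensities.shape[0]} echo images "
                f"vs {len(self.echo_times_ms)} echo times"
            )
        te = np.asarray(self.echo_times_ms)
        if te.size == 0 or np.any(te <= 0) or np.any(np.diff(te) <= 0):
            raise MetadataError("echo times must be positive and strictly increasing")
        if np.any(self.intensities < 0):
            raise FormatError("intensities must be non-negative")

    @property
    def n_echoes(self) -> int:
        return self.intensities.shape[0]

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.intensities.shape[1:]


@dataclass
class LabelMask:
    """Integer voxel labels plus a name -> value dictionary (0 = background)."""

    labels: np.ndarray
    label_dict: dict[str, int]
    spacing_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise FormatError("labels must be a 3D integer array")
        if not np.issubdtype(self.labels.dtype, np.integer):
            self.labels = self.labels.astype(np.int16)
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        self.label_dict = {str(k): int(v) for k, v in self.label_dict.items()}
        known = set(self.label_dict.values()) | {0}
        present = set(np.unique(self.labels).tolist())
        unknown = present - known
        if unknown:
            raise FormatError(f"mask contains values {sorted(unknown)} absent from label_dict")

    def value_of(self, name: str) -> int:
        return self.label_dict[name]

    def binary(self, name: str) -> np.ndarray:
        """Boolean mask of a single named label."""
        return self.labels == self.label_dict[name]

    def names(self) -> list[str]:
        return [n for n in self.label_dict if self.label_dict[n] != 0]


# ---------------------------------------------------------------------------
# NIfTI round trips
# ---------------------------------------------------------------------------

def _affine(spacing_mm) -> np.ndarray:
    aff = np.diag(list(spacing_mm) + [1.0])
    return aff


def write_mese(volume: MESEVolume, volume_path, sidecar_path) -> None:
    """Write a 4D NIfTI (echo last) plus JSON sidecar."""
    data = np.moveaxis(volume.intensities, 0, -1)  # (slice,row,col,echo)
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), _affine(volume.spacing_mm))
    nib.save(img, str(volume_path))
    meta = {
        "echo_times_ms": list(volume.echo_times_ms),
        "tr_ms": volume.tr_ms,
        "spacing_mm": list(volume.spacing_mm),
    }
    Path(sidecar_path).write_text(json.dumps(meta, indent=1))


def read_mese(volume_path, sidecar_path) -> MESEVolume:
    """Read a 4D multi-echo NIfTI and its JSON sidecar."""
    img = nib.load(str(volume_path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 4:
        raise FormatError(f"expected a 4D volume, got {data.ndim}D")
    try:
        meta = json.loads(Path(sidecar_path).read_text())
    except FileNotFoundError as exc:
        raise MetadataError(f"sidecar not found: {sidecar_path}") from exc
    for key in ("echo_times_ms", "spacing_mm"):
        if key not in meta:
            raise MetadataError(f"sidecar missing required field '{key}'")
    te = meta["echo_times_ms"]
    if len(te) != data.shape[-1]:
        raise FormatError(
            f"echo count mismatch: volume has {data.shape[-1]} echoes, sidecar lists {len(te)}"
        )
    return MESEVolume(
        intensities=np.moveaxis(data, -1, 0),
        spacing_mm=tuple(meta["spacing_mm"]),
        echo_times_ms=tuple(te),
        tr_ms=float(meta.get("tr_ms", 2700.0)),
    )


def write_mask(mask: LabelMask, path, label_dict_path) -> None:
    img = nib.Nifti1Image(np.asarray(mask.labels, dtype=np.int16), _affine(mask.spacing_mm))
    nib.save(img, str(path))
    Path(label_dict_path).write_text(json.dumps(mask.label_dict, indent=1))


def read_mask(path, label_dict_path) -> LabelMask:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    label_dict = json.loads(Path(label_dict_path).read_text())
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return LabelMask(labels=np.rint(data).astype(np.int16), label_dict=label_dict, spacing_mm=spacing)


# ---------------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------------

def write_table(frame: pd.DataFrame, path) -> None:
    """Write a result table as CSV with a header row."""
    frame.to_csv(path, index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path)
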