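"""NIfTI / TSV / JSON input-output and run manifests."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import nibabel as nib
import numpy as np
import pandas as pd

from . import __version__


def save_nifti(
    data: np.ndarray,
    path: str | Path,
    affine: np.ndarray | None = None,
    tr_s: float | None = None,
    voxel_size_mm: float | None = None,
) -> None:
    """Write a 3D/4D array as NIfTI-1; TR goes into the time zoom."""
    if affine is None:
        scale = voxel_size_mm if voxel_size_mm else 1.0
        affine = np.diag([scale, scale, scale, 1.0])
    img = nib.Nifti1Image(np.asarray(data), affine)
    if tr_s is not None and data.ndim == 4:
        zooms = list(img.header.get_zooms())
        zooms[3] = tr_s
        img.header.set_zooms(zooms)
        img.header.set_xyzt_units(xyz="mm", t="sec")
    nib.save(img, str(path))


def load_nifti(path: str | Path) -> tuple[np.ndarray, np.ndarray, float | None]:
    """Read a NIfTI file; returns (data, affine, TR or None for 3D)."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    tr = None
    if data.ndim == 4:
        zooms = img.header.get_zooms()
        if len(zooms) > 3 and zooms[3] > 0:
            tr = float(zooms[3])
    return data, img.affine, tr


def write_tsv(df: pd.DataFrame, path: str | Path, units_comment: str | None = None) -> None:
    """TSV with an optional leading '#' comment line documenting units."""
    path = Path(path)
    with open(path, "w") as fh:
        if units_comment:
            fh.write(f"# {units_comment}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Audit record of one pipeline run: config, seed, outputs, warnings."""

    command: str
    seed: int | None
    config: dict[str, Any]
    version: str = __version__
    outputs: dict[str, str] = field(default_factory=dict)  # path -> sha256
    warnings: list[str] = field(default_factory=list)

    def add_output(self, path: str | Path) -> None:
        self.outputs[str(path)] = sha256_of(path)

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, default=str)
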