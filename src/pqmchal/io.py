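"""File formats and provenance.

Volumes travel as NIfTI (dose as float32 Gy, masks as uint8) with the grid
geometry in the header affine; structure naming uses either one file per
structure or a label volume plus a JSON sidecar mapping label integers to
names (nested targets require the per-structure form).  Tables are UTF-8
comma-separated CSV with a single ``#``-prefixed provenance header line, so
they stay trivially diffable and hashable; configs are JSON.

Provenance: every table and manifest records the tool version, the root seed
and a hash of the generating configuration.  Identical config + seed yields
byte-identical tables (timestamps live only in the run manifest).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import FormatError
from .grids import DoseGrid, StructureMask

__all__ = [
    "ProvenanceHeader",
    "write_dose_nifti",
    "read_dose_nifti",
    "write_mask_nifti",
    "read_mask_nifti",
    "write_label_volume",
    "read_structure_masks",
    "write_table_csv",
    "read_table_csv",
    "config_hash",
]

PROVENANCE_PREFIX = "# pqmchal-provenance: "


def config_hash(config: dict) -> str:
    """Stable short hash of a JSON-serialisable configuration."""
    canon = json.dumps(config, sort_keys=True, separators=(",", ":"), default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


@dataclass(frozen=True)
class ProvenanceHeader:
    tool_version: str
    seed: int
    config_hash: str

    def as_dict(self) -> dict:
        return {
            "tool_version": self.tool_version,
            "seed": self.seed,
            "config_hash": self.config_hash,
        }


def _affine(spacing_mm, origin_mm=(0.0, 0.0, 0.0)) -> np.ndarray:
    aff = np.diag(list(spacing_mm) + [1.0])
    aff[:3, 3] = origin_mm
    return aff


def write_dose_nifti(dose: DoseGrid, path: str | Path) -> None:
    img = nib.Nifti1Image(
        dose.values.astype(np.float32), _affine(dose.spacing_mm, dose.origin_mm)
    )
    nib.save(img, str(path))


def read_dose_nifti(path: str | Path) -> DoseGrid:
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(v) for v in img.affine[:3, 3])
    return DoseGrid(
        values=np.asarray(img.dataobj, dtype=np.float64),
        spacing_mm=spacing,
        origin_mm=origin,
    )


def write_mask_nifti(mask: StructureMask, path: str | Path) -> None:
    img = nib.Nifti1Image(mask.voxels.astype(np.uint8), _affine(mask.spacing_mm))
    nib.save(img, str(path))


def read_mask_nifti(path: str | Path, name: str | None = None) -> StructureMask:
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    data = np.asarray(img.dataobj)
    return StructureMask(
        name=name or Path(path).name.split(".")[0],
        voxels=data > 0,
        spacing_mm=spacing,
    )


def write_label_volume(
    masks: dict[str, StructureMask], path: str | Path, names_path: str | Path
) -> None:
    """Write non-overlapping structures as one integer label volume + name map.

    Overlapping structures (the nested targets) cannot be represented this
    way; later structures would overwrite earlier ones, so overlap raises.
    """
    first = next(iter(masks.values()))
    labels = np.zeros(first.shape, dtype=np.int16)
    names = {}
    for i, (name, mask) in enumerate(masks.items(), start=1):
        if np.any(labels[mask.voxels] != 0):
            raise FormatError(
                f"structure {name!r} overlaps another structure; use "
                "per-structure masks for overlapping sets"
            )
        labels[mask.voxels] = i
        names[str(i)] = name
    nib.save(nib.Nifti1Image(labels, _affine(first.spacing_mm)), str(path))
    Path(names_path).write_text(json.dumps(names, indent=2) + "\n")


def read_structure_masks(
    source: str | Path, names_path: str | Path | None = None
) -> dict[str, StructureMask]:
    """Read structures from a directory of per-structure NIfTI masks, or from
    a label volume plus a label→name JSON sidecar."""
    source = Path(source)
    if source.is_dir():
        masks = {}
        for f in sorted(source.glob("*.nii*")):
            name = f.name.split(".")[0]
            masks[name] = read_mask_nifti(f, name=name)
        if not masks:
            raise FormatError(f"no NIfTI masks found in directory {source}")
        return masks
    if names_path is None:
        raise FormatError("a label volume needs a label→name JSON sidecar")
    try:
        names = json.loads(Path(names_path).read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"cannot parse names file {names_path}: {exc}") from exc
    img = nib.load(str(source))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    labels = np.asarray(img.dataobj)
    return {
        name: StructureMask(name=name, voxels=labels == int(lbl), spacing_mm=spacing)
        for lbl, name in names.items()
    }


def write_table_csv(df: pd.DataFrame, path: str | Path, provenance: ProvenanceHeader) -> None:
    path = Path(path)
    header = PROVENANCE_PREFIX + json.dumps(provenance.as_dict(), sort_keys=True)
    with open(path, "w", newline="") as fh:
        fh.write(header + "\n")
        df.to_csv(fh, index=False)


def read_table_csv(path: str | Path) -> tuple[pd.DataFrame, dict | None]:
    path = Path(path)
    provenance = None
    with open(path) as fh:
        first = fh.readline()
        if first.startswith(PROVENANCE_PREFIX):
            provenance = json.loads(first[len(PROVENANCE_PREFIX):])
        else:
            fh.seek(0)
        df = pd.read_csv(fh)
    return df, provenance
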