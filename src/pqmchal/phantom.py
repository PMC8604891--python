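"""Voxel phantom construction for the synthetic planning-challenge cohort.

The phantom emulates the topology of a head-and-neck case planned with a
simultaneous integrated boost: three nested planning target volumes (high /
intermediate / low risk, prescribed 69.96 / 59.4 / 54 Gy in 33 fractions)
surrounded by the ten organs at risk the challenge scored.  There is no
anatomical realism beyond topology — shapes are analytic primitives placed so
that every scored structure exists and the spatial trade-off between target
conformity and organ sparing is geometrically real.

Shape primitives (all sizes in mm, ``size_mm`` holds semi-axes / radii /
half-extents):

* ``ellipsoid`` — semi-axes ``(a, b, c)`` about ``center_mm``;
* ``cylinder``  — circular cross-section of radius ``size_mm[i]`` for the two
  non-axis components and half-length along ``axis``;
* ``box``       — axis-aligned half-extents.

A voxel belongs to a structure when its *center* lies inside the primitive.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from .errors import FormatError, InvalidSpecError
from .grids import DoseGrid, StructureMask

__all__ = ["ShapeSpec", "PhantomSpec", "build_phantom", "default_phantom_spec", "load_phantom_spec"]

PTV_NAMES = ("ptv1", "ptv2", "ptv3")
OAR_NAMES = (
    "spinal_canal",
    "parotid_left",
    "parotid_right",
    "brainstem",
    "brachial_plexus",
    "brain",
    "esophagus",
    "glottis",
    "mandible",
    "oral_cavity",
)


@dataclass(frozen=True)
class ShapeSpec:
    name: str
    shape: str  # "ellipsoid" | "cylinder" | "box"
    center_mm: tuple[float, float, float]
    size_mm: tuple[float, float, float]
    axis: int = 2  # cylinder axis


@dataclass
class PhantomSpec:
    grid_shape: tuple[int, int, int]
    spacing_mm: tuple[float, float, float]
    structures: list[ShapeSpec]
    prescriptions_gy: dict[str, float] = field(
        default_factory=lambda: {"ptv1": 69.96, "ptv2": 59.4, "ptv3": 54.0}
    )
    fractions: int = 33
    name: str = "phantom"

    def structure_names(self) -> list[str]:
        return [s.name for s in self.structures]


def _voxel_centers(grid_shape, spacing_mm):
    axes = [
        (np.arange(n) + 0.5) * s for n, s in zip(grid_shape, spacing_mm)
    ]
    return np.meshgrid(*axes, indexing="ij")


def _rasterize(shape: ShapeSpec, coords) -> np.ndarray:
    cx, cy, cz = (coords[i] - shape.center_mm[i] for i in range(3))
    a, b, c = shape.size_mm
    if shape.shape == "ellipsoid":
        return (cx / a) ** 2 + (cy / b) ** 2 + (cz / c) ** 2 <= 1.0
    if shape.shape == "box":
        return (np.abs(cx) <= a) & (np.abs(cy) <= b) & (np.abs(cz) <= c)
    if shape.shape == "cylinder":
        offs = [cx, cy, cz]
        ax = shape.axis
        radial = [offs[i] for i in range(3) if i != ax]
        radii = [shape.size_mm[i] for i in range(3) if i != ax]
        in_disc = (radial[0] / radii[0]) ** 2 + (radial[1] / radii[1]) ** 2 <= 1.0
        return in_disc & (np.abs(offs[ax]) <= shape.size_mm[ax])
    raise InvalidSpecError(f"unknown shape primitive {shape.shape!r}")


def _in_bounds(shape: ShapeSpec, grid_shape, spacing_mm) -> bool:
    extent = [n * s for n, s in zip(grid_shape, spacing_mm)]
    for i in range(3):
        half = shape.size_mm[i]
        if shape.center_mm[i] - half < 0 or shape.center_mm[i] + half > extent[i]:
            return False
    return True


def build_phantom(spec: PhantomSpec) -> tuple[dict[str, StructureMask], DoseGrid]:
    """Rasterize every structure and return the masks plus an empty dose grid.

    Raises :class:`InvalidSpecError` when the PTV nesting (ptv1 ⊂ ptv2 ⊂ ptv3)
    is broken, a required structure is missing or empty, or a structure
    extends beyond the grid.
    """
    names = spec.structure_names()
    missing = [n for n in PTV_NAMES + OAR_NAMES if n not in names]
    if missing:
        raise InvalidSpecError(f"phantom is missing required structures: {', '.join(missing)}")
    for s in spec.structures:
        if not _in_bounds(s, spec.grid_shape, spec.spacing_mm):
            raise InvalidSpecError(f"structure {s.name!r} extends beyond the grid bounds")

    coords = _voxel_centers(spec.grid_shape, spec.spacing_mm)
    masks: dict[str, StructureMask] = {}
    for s in spec.structures:
        vox = _rasterize(s, coords)
        if not vox.any():
            raise InvalidSpecError(f"structure {s.name!r} rasterizes to zero volume")
        masks[s.name] = StructureMask(name=s.name, voxels=vox, spacing_mm=spec.spacing_mm)

    p1, p2, p3 = (masks[n].voxels for n in PTV_NAMES)
    if not (np.all(p2[p1]) and p1.sum() < p2.sum()):
        raise InvalidSpecError("PTV nesting violated: ptv1 must be a strict subset of ptv2")
    if not (np.all(p3[p2]) and p2.sum() < p3.sum()):
        raise InvalidSpecError("PTV nesting violated: ptv2 must be a strict subset of ptv3")

    empty = DoseGrid(
        values=np.zeros(spec.grid_shape), spacing_mm=spec.spacing_mm
    )
    return masks, empty


def _spec_from_dict(raw: dict, name: str) -> PhantomSpec:
    try:
        structures = [
            ShapeSpec(
                name=s["name"],
                shape=s["shape"],
                center_mm=tuple(float(v) for v in s["center_mm"]),
                size_mm=tuple(float(v) for v in s["size_mm"]),
                axis=int(s.get("axis", 2)),
            )
            for s in raw["structures"]
        ]
        return PhantomSpec(
            grid_shape=tuple(int(v) for v in raw["grid_shape"]),
            spacing_mm=tuple(float(v) for v in raw["spacing_mm"]),
            structures=structures,
            prescriptions_gy={k: float(v) for k, v in raw.get(
                "prescriptions_gy", {"ptv1": 69.96, "ptv2": 59.4, "ptv3": 54.0}
            ).items()},
            fractions=int(raw.get("fractions", 33)),
            name=raw.get("name", name),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise FormatError(f"malformed phantom spec: {exc!r}") from exc


def load_phantom_spec(path: str | Path) -> PhantomSpec:
    path = Path(path)
    try:
        raw = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"cannot parse phantom spec {path}: {exc}") from exc
    return _spec_from_dict(raw, name=path.stem)


def default_phantom_spec() -> PhantomSpec:
    raw = json.loads(resources.files("pqmchal.data").joinpath("phantom.json").read_text())
    return _spec_from_dict(raw, name="default")
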