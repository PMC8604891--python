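"""Cumulative dose-volume histograms and the challenge dose metrics.

All plan metrics reduce to a handful of DVH queries on a dose grid restricted
to a structure mask:

* ``D_x%``  — minimum dose to the hottest *x* percent of the structure volume
  (so ``D_95%`` is a coverage metric, ``D_100%`` the structure minimum),
* ``D_xcc`` — minimum dose to the hottest *x* cm^3 (``D_0.1cc`` is the usual
  near-maximum surrogate),
* ``D_mean`` — arithmetic mean voxel dose,
* ``V_xGy`` — percent of the structure receiving at least *x* Gy,
* the conformation number ``CN = (TVRI/TV) * (TVRI/VRI)`` of a target against
  a reference isodose, the product of target coverage and isodose
  selectivity.

Histograms use full-voxel counting: every voxel contributes its whole volume
at its dose value.  Inverse queries interpolate linearly on the cumulative
curve, so their discretisation error is bounded by the histogram bin width
(0.01 Gy by default, far below any tier gap in the scoring scheme).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import AlignmentError, EmptyStructureError
from .grids import DoseGrid, StructureMask

__all__ = [
    "DVHCurve",
    "ConformityComponents",
    "compute_dvh",
    "dose_at_volume_percent",
    "dose_at_volume_cc",
    "mean_dose",
    "volume_at_dose_percent",
    "ring",
    "conformation_number",
    "extract_metrics",
]

DEFAULT_BIN_WIDTH_GY = 0.01


@dataclass(frozen=True)
class DVHCurve:
    """Cumulative DVH: fraction of structure volume receiving >= each edge dose."""

    dose_edges: np.ndarray
    cum_volume_fraction: np.ndarray
    structure_volume_cc: float

    def __post_init__(self):
        object.__setattr__(self, "dose_edges", np.asarray(self.dose_edges, float))
        object.__setattr__(
            self, "cum_volume_fraction", np.asarray(self.cum_volume_fraction, float)
        )
        e, c = self.dose_edges, self.cum_volume_fraction
        if e.shape != c.shape or e.ndim != 1 or e.size < 2:
            raise ValueError("dose_edges and cum_volume_fraction must be equal-length 1D")
        if c[0] != 1.0 or np.any(np.diff(c) > 1e-12) or c[-1] < 0 or np.any(c > 1):
            raise ValueError("cumulative fraction must start at 1 and be non-increasing in [0, 1]")

    @property
    def bin_width(self) -> float:
        return float(self.dose_edges[1] - self.dose_edges[0])


@dataclass(frozen=True)
class ConformityComponents:
    """Conformation-number decomposition for a target and reference isodose."""

    tvri_cc: float  # target volume covered by the reference dose
    tv_cc: float  # total target volume
    vri_cc: float  # total volume of the reference isodose
    cn: float
    degenerate_isodose: bool = False  # no voxel reached the reference dose

    @property
    def coverage(self) -> float:
        return self.tvri_cc / self.tv_cc if self.tv_cc > 0 else 0.0

    @property
    def selectivity(self) -> float:
        return self.tvri_cc / self.vri_cc if self.vri_cc > 0 else 0.0


def _masked_doses(dose: DoseGrid, mask: StructureMask) -> np.ndarray:
    mask.require_aligned(dose)
    mask.require_nonempty()
    return dose.values[mask.voxels]


def compute_dvh(
    dose: DoseGrid, mask: StructureMask, bin_width_gy: float = DEFAULT_BIN_WIDTH_GY
) -> DVHCurve:
    """Cumulative DVH of ``mask`` on ``dose`` by full-voxel counting.

    Bin edges are aligned multiples of ``bin_width_gy`` spanning
    ``[0, max dose in mask + one bin]``.
    """
    if bin_width_gy <= 0:
        raise ValueError("bin width must be positive")
    doses = np.sort(_masked_doses(dose, mask))
    n = doses.size
    n_edges = int(np.ceil(doses[-1] / bin_width_gy)) + 2
    edges = bin_width_gy * np.arange(n_edges)
    # fraction of voxels with dose >= edge
    cum = 1.0 - np.searchsorted(doses, edges, side="left") / n
    cum[0] = 1.0
    return DVHCurve(edges, cum, mask.volume_cc)


def dose_at_volume_fraction(dvh: DVHCurve, fraction: float) -> float:
    """Greatest dose D such that at least ``fraction`` of the volume gets >= D."""
    if not 0 < fraction <= 1:
        raise ValueError(f"volume fraction must be in (0, 1], got {fraction}")
    cum = dvh.cum_volume_fraction
    edges = dvh.dose_edges
    idx = int(np.nonzero(cum >= fraction)[0][-1])
    if idx == cum.size - 1 or cum[idx] == fraction:
        return float(edges[idx])
    drop = cum[idx] - cum[idx + 1]
    if drop <= 0:
        return float(edges[idx])
    return float(edges[idx] + (cum[idx] - fraction) / drop * dvh.bin_width)


def dose_at_volume_percent(dvh: DVHCurve, x_percent: float) -> float:
    """``D_x%``: minimum dose to the hottest ``x_percent`` of the structure."""
    if not 0 < x_percent <= 100:
        raise ValueError(f"x_percent must be in (0, 100], got {x_percent}")
    return dose_at_volume_fraction(dvh, x_percent / 100.0)


def dose_at_volume_cc(dvh: DVHCurve, v_cc: float) -> float:
    """``D_xcc``: minimum dose to the hottest ``v_cc`` cm^3 of the structure."""
    if v_cc <= 0:
        raise ValueError(f"v_cc must be positive, got {v_cc}")
    if v_cc > dvh.structure_volume_cc * (1 + 1e-9):
        raise ValueError(
            f"queried volume {v_cc} cc exceeds structure volume "
            f"{dvh.structure_volume_cc:.4f} cc"
        )
    return dose_at_volume_fraction(dvh, min(v_cc / dvh.structure_volume_cc, 1.0))


def mean_dose(dose: DoseGrid, mask: StructureMask) -> float:
    """Arithmetic mean voxel dose inside the mask (equal voxel volumes)."""
    return float(np.mean(_masked_doses(dose, mask)))


def volume_at_dose_percent(dvh: DVHCurve, d_gy: float) -> float:
    """``V_xGy``: percent of structure volume receiving at least ``d_gy``."""
    if d_gy < 0:
        raise ValueError("query dose must be non-negative")
    edges = dvh.dose_edges
    if d_gy >= edges[-1]:
        return 0.0
    frac = float(np.interp(d_gy, edges, dvh.cum_volume_fraction))
    return 100.0 * frac


def ring(outer: StructureMask, inner: StructureMask) -> StructureMask:
    """Set-difference structure ``outer AND NOT inner`` (e.g. PTV3−PTV2 shell)."""
    if outer.shape != inner.shape:
        raise AlignmentError(
            f"ring operands {outer.name!r} {outer.shape} and "
            f"{inner.name!r} {inner.shape} are on different grids"
        )
    return StructureMask(
        name=f"{outer.name}-{inner.name}",
        voxels=outer.voxels & ~inner.voxels,
        spacing_mm=outer.spacing_mm,
    )


def conformation_number(
    dose: DoseGrid, target: StructureMask, reference_dose_gy: float
) -> ConformityComponents:
    """Conformation number of ``target`` against the ``reference_dose_gy`` isodose.

    ``CN = (TVRI/TV) * (TVRI/VRI)`` where TVRI is the target volume covered by
    the reference dose, TV the target volume and VRI the reference-isodose
    volume.  A reference isodose reached by no voxel yields CN = 0 with the
    ``degenerate_isodose`` flag set instead of an exception.
    """
    if reference_dose_gy <= 0:
        raise ValueError("reference dose must be positive")
    target.require_aligned(dose)
    target.require_nonempty()
    vv = dose.voxel_volume_cc
    covered = dose.values >= reference_dose_gy
    vri = float(covered.sum()) * vv
    tvri = float((covered & target.voxels).sum()) * vv
    tv = target.volume_cc
    if vri == 0.0:
        return ConformityComponents(0.0, tv, 0.0, 0.0, degenerate_isodose=True)
    cn = (tvri / tv) * (tvri / vri)
    return ConformityComponents(tvri, tv, vri, cn)


def _resolve_structure(expr: str, masks: dict[str, StructureMask]) -> StructureMask:
    """A structure name, or a ring expression ``outer-inner``."""
    if expr in masks:
        return masks[expr]
    if "-" in expr:
        outer, inner = expr.split("-", 1)
        if outer in masks and inner in masks:
            return ring(masks[outer], masks[inner])
    raise KeyError(f"unknown structure {expr!r}")


def extract_metrics(
    dose: DoseGrid,
    masks: dict[str, StructureMask],
    metric_specs,
    bin_width_gy: float = DEFAULT_BIN_WIDTH_GY,
) -> dict[str, float]:
    """Evaluate every metric of a scoring scheme on one dose grid.

    ``metric_specs`` is an iterable of objects with ``metric_id``,
    ``structure``, ``kind`` and ``parameter`` attributes (the scheme's
    :class:`~pqmchal.scoring.MetricSpec` entries).  DVH curves are computed
    once per distinct structure expression.
    """
    dvh_cache: dict[str, DVHCurve] = {}
    struct_cache: dict[str, StructureMask] = {}

    def get_struct(expr: str) -> StructureMask:
        if expr not in struct_cache:
            struct_cache[expr] = _resolve_structure(expr, masks)
        return struct_cache[expr]

    def get_dvh(expr: str) -> DVHCurve:
        if expr not in dvh_cache:
            dvh_cache[expr] = compute_dvh(dose, get_struct(expr), bin_width_gy)
        return dvh_cache[expr]

    values: dict[str, float] = {}
    for spec in metric_specs:
        kind = spec.kind
        if kind == "D_percent":
            values[spec.metric_id] = dose_at_volume_percent(get_dvh(spec.structure), spec.parameter)
        elif kind == "D_cc":
            values[spec.metric_id] = dose_at_volume_cc(get_dvh(spec.structure), spec.parameter)
        elif kind == "D_mean":
            values[spec.metric_id] = mean_dose(dose, get_struct(spec.structure))
        elif kind == "V_gy_percent":
            values[spec.metric_id] = volume_at_dose_percent(get_dvh(spec.structure), spec.parameter)
        elif kind == "conformation":
            values[spec.metric_id] = conformation_number(
                dose, get_struct(spec.structure), spec.parameter
            ).cn
        else:
            raise ValueError(f"unknown metric kind {kind!r} for {spec.metric_id}")
    return values
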