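"""Analytic dose painting: turn sampled metric targets into a 3D dose grid.

The painter is the inverse of the DVH engine: given a phantom and one plan's
intended values for the 16 scored metrics, it constructs a dose distribution
whose *measured* metrics match the intended ones (well inside the 2% relative
contract; the pinned quantiles are exact up to voxel discretisation).

Construction, per plan:

* Each painted region (PTV1, the PTV2−PTV1 and PTV3−PTV2 shells, each OAR)
  gets a monotone piecewise-linear dose-versus-volume-rank profile.  Pinned
  quantiles realise the targets exactly: ``D_95%`` pins sit on small plateaus
  at the right cumulative-volume fraction (corrected for the hotter nested
  volumes inside), ``D_xcc`` pins are plateaus of just over x cm^3 at the hot
  end, ``D_mean`` targets use a symmetric ramp whose discrete mean is exact,
  and the ``V_56.7Gy`` pin places the 56.7 Gy crossing at the target volume
  fraction of the PTV3−PTV2 shell.
* Ranks are tied to geometry (distance from the boost centre, or from the
  target for OARs) so dose falls smoothly across each structure.
* The conformation-number target fixes how much of the reference isodose may
  spill outside PTV3; the painter realises exactly that much spill as a shell
  of nearest outside voxels, after crediting whatever OAR hot spots already
  exceed the reference dose.  Beyond the shell the background falls off
  smoothly and monotonically with distance from PTV3.
* OAR interiors are painted exclusively by their own profile (sparing carves
  them out of the background and the spill shell); overlapping *structures*
  resolve by voxelwise maximum.

Infeasible target combinations (a hot spot colder than a coverage pin, a
conformation number exceeding the achievable coverage, shell-crossing pins
out of order) raise :class:`InfeasibleTargetError` naming the metric pair.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import InfeasibleTargetError, InvalidSpecError
from .grids import DoseGrid, StructureMask, voxel_volume_cc
from .phantom import OAR_NAMES, PTV_NAMES

__all__ = ["DosePainter", "paint_dose", "MAX_PAINT_DOSE_GY"]

MAX_PAINT_DOSE_GY = 80.45  # 1.15 x the highest prescription (69.96 Gy)


def _require(cond: bool, message: str) -> None:
    if not cond:
        raise InfeasibleTargetError(message)


@dataclass(frozen=True)
class _RegionPlan:
    """A painted region: flat voxel indices ordered hot-to-cold."""

    name: str
    order: np.ndarray  # flat indices, hottest first


class DosePainter:
    """Paints cohort dose grids on one phantom; per-phantom geometry is cached.

    Parameters
    ----------
    masks:
        Structure masks from :func:`pqmchal.phantom.build_phantom`.
    spacing_mm:
        Voxel spacing shared by all masks.
    metric_specs:
        The scheme's :class:`~pqmchal.scoring.MetricSpec` list; provides each
        target's structure, DVH kind and parameter (including the
        conformation reference dose).
    """

    def __init__(self, masks: dict[str, StructureMask], spacing_mm, metric_specs):
        for name in PTV_NAMES + OAR_NAMES:
            if name not in masks:
                raise InvalidSpecError(f"painter needs structure {name!r}")
        self.masks = masks
        self.spacing_mm = tuple(float(s) for s in spacing_mm)
        self.voxvol = voxel_volume_cc(self.spacing_mm)
        self.shape = masks["ptv3"].shape
        self.metric_specs = list(metric_specs)
        self._spec_by_id = {m.metric_id: m for m in self.metric_specs}

        cn_specs = [m for m in self.metric_specs if m.kind == "conformation"]
        if len(cn_specs) != 1 or cn_specs[0].structure != "ptv3":
            raise InvalidSpecError("painter expects exactly one conformation metric on ptv3")
        self.reference_dose_gy = float(cn_specs[0].parameter)

        p1 = masks["ptv1"].voxels
        p2 = masks["ptv2"].voxels
        p3 = masks["ptv3"].voxels
        self._n1, self._n2, self._n3 = int(p1.sum()), int(p2.sum()), int(p3.sum())

        # hot-to-cold orders follow distance from the boost centre
        centre = np.array(ndimage.center_of_mass(p1))
        grids = np.indices(self.shape, dtype=float)
        d2 = np.zeros(self.shape)
        for ax in range(3):
            d2 += ((grids[ax] - centre[ax]) * self.spacing_mm[ax]) ** 2
        dist_centre = np.sqrt(d2).ravel()

        def hot_order(region: np.ndarray) -> np.ndarray:
            idx = np.flatnonzero(region.ravel())
            return idx[np.argsort(dist_centre[idx], kind="stable")]

        self.ptv1 = _RegionPlan("ptv1", hot_order(p1))
        self.ring2 = _RegionPlan("ptv2-ptv1", hot_order(p2 & ~p1))
        self.ring3 = _RegionPlan("ptv3-ptv2", hot_order(p3 & ~p2))
        self._ptv3_flat = np.flatnonzero(p3.ravel())

        oar_union = np.zeros(self.shape, dtype=bool)
        self.oars: dict[str, _RegionPlan] = {}
        for name in OAR_NAMES:
            vox = masks[name].voxels
            oar_union |= vox
            self.oars[name] = _RegionPlan(name, hot_order(vox))
        self._oar_outside_ptv3 = np.flatnonzero((oar_union & ~p3).ravel())

        # background: distance from PTV3 surface, OAR interiors carved out
        dist_out = ndimage.distance_transform_edt(~p3, sampling=self.spacing_mm).ravel()
        eligible = np.flatnonzero((~p3 & ~oar_union).ravel())
        order = np.argsort(dist_out[eligible], kind="stable")
        self._bg_idx = eligible[order]
        self._bg_dist = dist_out[self._bg_idx]

    # -- profile helpers ---------------------------------------------------

    @staticmethod
    def _assign(n: int, knots_u, knots_d) -> np.ndarray:
        u = (np.arange(n) + 0.5) / n
        return np.interp(u, np.asarray(knots_u, float), np.asarray(knots_d, float))

    def _plateau_fraction(self, v_cc: float, n_voxels: int) -> float:
        count = math.ceil(v_cc / self.voxvol) + 2
        _require(
            count < 0.5 * n_voxels,
            f"hot-spot volume {v_cc} cc too large for a structure of "
            f"{n_voxels * self.voxvol:.2f} cc",
        )
        return count / n_voxels

    def _target(self, targets: dict[str, float], metric_id: str) -> float:
        if metric_id not in targets:
            raise InfeasibleTargetError(f"profile has no target for metric {metric_id!r}")
        return float(targets[metric_id])

    # -- main entry --------------------------------------------------------

    def paint(self, profile) -> DoseGrid:
        """Paint one plan's dose grid from its sampled metric targets."""
        t = profile.metric_targets
        for mid, val in t.items():
            if not (0.0 <= val <= 80.0):
                raise InfeasibleTargetError(
                    f"target {mid} = {val} Gy outside the physical range 0-80 Gy"
                )
        flat = np.zeros(int(np.prod(self.shape)))
        ref = self.reference_dose_gy

        # PTV1: coverage pin at 95%, near-max plateau of just over 0.1 cc
        t95_1 = self._target(t, "ptv1_d95")
        thot = self._target(t, "ptv1_d0p1cc")
        _require(
            thot > t95_1 + 0.5,
            f"ptv1_d0p1cc target {thot:.2f} Gy must exceed ptv1_d95 target "
            f"{t95_1:.2f} Gy (hot spot cannot be colder than coverage)",
        )
        spec_hot = self._spec_by_id["ptv1_d0p1cc"]
        u_hot = self._plateau_fraction(float(spec_hot.parameter), self.ptv1.order.size)
        flat[self.ptv1.order] = self._assign(
            self.ptv1.order.size,
            [0.0, u_hot, 0.94, 0.96, 1.0],
            [thot, thot, t95_1, t95_1, t95_1 - 1.2],
        )

        # PTV2 shell: pin PTV2 D95 at the shell rank that corresponds to the
        # 95% quantile of the whole (hotter-core-included) PTV2
        t2 = self._target(t, "ptv2_d95")
        _require(t2 + 1.2 < t95_1 - 1.2, f"ptv2_d95 target {t2:.2f} Gy too close to ptv1 doses")
        u2 = (0.95 * self._n2 - self._n1) / (self._n2 - self._n1)
        _require(0.02 < u2 < 0.98, "ptv1/ptv2 volume ratio leaves no room for the D95 pin")
        flat[self.ring2.order] = self._assign(
            self.ring2.order.size,
            [0.0, u2 - 0.01, u2 + 0.01, 1.0],
            [t2 + 1.2, t2, t2, t2 - 1.2],
        )

        # PTV3 shell: V_56.7Gy crossing pin plus the PTV3 D95 pin
        t3 = self._target(t, "ptv3_d95")
        v_pct = self._target(t, "ptv3_minus_ptv2_v56p7")
        spec_v = self._spec_by_id["ptv3_minus_ptv2_v56p7"]
        v_dose = float(spec_v.parameter)
        _require(
            t3 < v_dose - 0.3,
            f"ptv3_d95 target {t3:.2f} Gy must lie below the {v_dose} Gy "
            f"hot-volume level of ptv3_minus_ptv2_v56p7",
        )
        _require(t2 - 1.2 > t3, f"ptv3_d95 target {t3:.2f} Gy too close to ptv2 doses")
        u3 = (0.95 * self._n3 - self._n2) / (self._n3 - self._n2)
        _require(0.02 < u3 < 0.98, "ptv2/ptv3 volume ratio leaves no room for the D95 pin")
        uv = v_pct / 100.0
        _require(
            0.005 < uv < u3 - 0.02,
            f"ptv3_minus_ptv2_v56p7 target {v_pct:.1f}% incompatible with the "
            f"ptv3_d95 pin position {100 * u3:.1f}%",
        )
        flat[self.ring3.order] = self._assign(
            self.ring3.order.size,
            [0.0, uv, u3 - 0.01, u3 + 0.01, 1.0],
            [v_dose + 2.1, v_dose, t3, t3, t3 - 1.2],
        )

        # OARs: one metric each — mean-dose ramp or near-max plateau
        for name in OAR_NAMES:
            region = self.oars[name]
            specs = [m for m in self.metric_specs if m.structure == name]
            _require(len(specs) == 1, f"painter expects exactly one metric on {name!r}")
            spec = specs[0]
            target = self._target(t, spec.metric_id)
            n = region.order.size
            if spec.kind == "D_mean":
                a = min(5.0, target - 1.0)
                vals = self._assign(n, [0.0, 1.0], [target + a, target - a])
            elif spec.kind == "D_cc":
                u_h = self._plateau_fraction(float(spec.parameter), n)
                low = max(target - 12.0, 1.0)
                vals = self._assign(n, [0.0, u_h, 1.0], [target, target, low])
            else:
                raise InfeasibleTargetError(
                    f"unsupported OAR metric kind {spec.kind!r} on {name!r}"
                )
            flat[region.order] = np.maximum(flat[region.order], vals)

        # conformity: realise the target spill outside PTV3
        cn = self._target(t, "ptv3_conformation")
        _require(0.0 < cn <= 1.0, f"conformation target {cn} outside (0, 1]")
        coverage = float(np.count_nonzero(flat[self._ptv3_flat] >= ref)) / self._n3
        _require(
            cn <= coverage,
            f"ptv3_conformation target {cn:.3f} exceeds the achievable coverage "
            f"{coverage:.3f} implied by the ptv3_d95 target",
        )
        v3_cc = self._n3 * self.voxvol
        spill_total_cc = (coverage**2 / cn - coverage) * v3_cc
        oar_spill_cc = (
            float(np.count_nonzero(flat[self._oar_outside_ptv3] >= ref)) * self.voxvol
        )
        shell_cc = spill_total_cc - oar_spill_cc
        _require(
            shell_cc >= -0.5,
            f"ptv3_conformation target {cn:.3f} infeasible: OAR hot spots alone "
            f"spill {oar_spill_cc:.1f} cc of the reference isodose "
            f"(target allows {spill_total_cc:.1f} cc)",
        )
        k = int(np.clip(round(max(shell_cc, 0.0) / self.voxvol), 0, self._bg_idx.size))

        # background: spill shell ramp, then smooth monotone falloff
        bg = np.empty(self._bg_idx.size)
        if k > 0:
            bg[:k] = np.linspace(ref + 1.6, ref + 0.02, k)
        d_edge = self._bg_dist[k - 1] if k > 0 else self._bg_dist[0]
        tail = self._bg_dist[k:] - d_edge
        bg[k:] = (ref - 0.1) * np.exp(-np.clip(tail, 0.0, None) / 8.0)
        flat[self._bg_idx] = bg

        values = flat.reshape(self.shape)
        peak = float(values.max())
        if peak > MAX_PAINT_DOSE_GY and not getattr(profile, "allow_hot", False):
            raise InfeasibleTargetError(
                f"painted dose peaks at {peak:.2f} Gy, above the "
                f"{MAX_PAINT_DOSE_GY} Gy cap"
            )
        return DoseGrid(values=values, spacing_mm=self.spacing_mm)


def paint_dose(masks: dict[str, StructureMask], profile, metric_specs, spacing_mm=None) -> DoseGrid:
    """One-shot convenience wrapper around :class:`DosePainter`.

    For cohorts, build one :class:`DosePainter` and reuse it — the geometry
    caches (distance transforms, rank orders) dominate the per-plan cost.
    """
    spacing = spacing_mm if spacing_mm is not None else masks["ptv3"].spacing_mm
    return DosePainter(masks, spacing, metric_specs).paint(profile)
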