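"""Calibrated sampling of per-plan quality profiles.

Each synthetic plan is described by a :class:`PlanQualityProfile`: intended
values for the 16 scored dose metrics, delivery metadata (beams, segments,
monitor units, beam-on and total delivery time) and planner experience.
Profiles are drawn jointly so that

* every marginal is a truncated normal whose scale and bounds come straight
  from the published cohort table, with the location solved numerically so
  the population *median* equals the published median (the table reports both
  mean and median; the median is what the pipeline is asked to recover), and
* the dependence structure is a Gaussian copula reproducing the rank
  correlations the study reports (beams↔segments 0.67, beams↔MU −0.63,
  segments↔quality latents 0.75/0.76, experience↔spinal-canal and
  experience↔glottis −0.55).

Printed Spearman targets are converted to latent normal correlations via
``rho_latent = 2 sin(pi * rho_s / 6)`` so the sampled cohort's *Spearman*
correlation matches the printed value.  Unprinted entries of the correlation
matrix are not free: the printed partners of ``n_segments`` alone have
squared sum > 1, so a zero-filled matrix is indefinite.  The calibration's
correlation graph is therefore completed over the forest of printed edges by
Markov (product-along-path) completion, which preserves every printed
coefficient exactly and is guaranteed positive semi-definite; pairs in
different components stay at 0.  :func:`nearest_psd` remains available (and
is applied as a final safety net) for user-supplied matrices.

Overall plan quality (which the scoring stage computes downstream) enters
through two latent factors rather than through the score itself, avoiding a
circular dependence on the scoring configuration; the latents load on the
metric columns with ±0.4 (sign = direction of improvement).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
from scipy import optimize, stats

from .errors import CalibrationError, FormatError

__all__ = [
    "MarginalSpec",
    "CohortCalibration",
    "PlanQualityProfile",
    "nearest_psd",
    "complete_forest_correlation",
    "sample_cohort_profiles",
    "default_calibration",
    "load_calibration",
]

METADATA_FIELDS = (
    "n_beams",
    "n_segments",
    "mu",
    "beam_on_min",
    "delivery_min",
    "experience_years",
    "viewray_years",
)
SPEARMAN_TO_LATENT = lambda r: 2.0 * math.sin(math.pi * r / 6.0)  # noqa: E731


@dataclass(frozen=True)
class MarginalSpec:
    """Truncated-normal marginal for one cohort field."""

    field: str
    kind: str  # "metric" | "metadata" | "latent"
    mean: float = 0.0
    sd: float = 1.0
    median: float | None = None
    min: float = -np.inf
    max: float = np.inf
    integer: bool = False

    def solve_location(self) -> float:
        """Location such that the truncated normal's median equals ``self.median``."""
        if self.median is None or not np.isfinite(self.min):
            return self.mean
        lo, hi, sd, target = self.min, self.max, self.sd, self.median

        def med(loc):
            a, b = (lo - loc) / sd, (hi - loc) / sd
            return float(stats.truncnorm.median(a, b, loc=loc, scale=sd))

        span = 10 * sd + (hi - lo)
        try:
            return float(optimize.brentq(lambda L: med(L) - target, lo - span, hi + span))
        except ValueError as exc:  # pragma: no cover - calibration data keeps this solvable
            raise CalibrationError(
                f"cannot calibrate marginal location for {self.field!r}"
            ) from exc


@dataclass
class CohortCalibration:
    marginals: list[MarginalSpec]
    correlations: list[tuple[str, str, float]]  # Spearman targets on printed pairs
    name: str = "calibration"

    def fields(self) -> list[str]:
        return [m.field for m in self.marginals]

    def metric_fields(self) -> list[str]:
        return [m.field for m in self.marginals if m.kind == "metric"]

    def metadata_fields(self) -> list[str]:
        return [m.field for m in self.marginals if m.kind == "metadata"]

    def validate(self, required_metrics: list[str] | None = None) -> None:
        names = self.fields()
        if len(names) != len(set(names)):
            raise CalibrationError("duplicate fields in calibration")
        missing_meta = [f for f in METADATA_FIELDS if f not in names]
        if missing_meta:
            raise CalibrationError(f"calibration missing metadata fields: {missing_meta}")
        if required_metrics:
            missing = [m for m in required_metrics if m not in names]
            if missing:
                raise CalibrationError(f"calibration missing metric fields: {missing}")
        for a, b, r in self.correlations:
            if a not in names or b not in names:
                raise CalibrationError(f"correlation references unknown field: ({a}, {b})")
            if not -1.0 < r < 1.0:
                raise CalibrationError(f"correlation rho({a}, {b}) = {r} outside (-1, 1)")


@dataclass
class PlanQualityProfile:
    """One sampled plan: intended metric values, delivery metadata, provenance."""

    plan_id: str
    metric_targets: dict[str, float]
    n_beams: int
    n_segments: int
    mu: int
    beam_on_min: float
    delivery_min: float
    experience_years: float
    viewray_years: float
    seed: int
    latent: dict[str, float] = field(default_factory=dict)

    def metadata(self) -> dict:
        return {
            "n_beams": self.n_beams,
            "n_segments": self.n_segments,
            "mu": self.mu,
            "beam_on_min": self.beam_on_min,
            "delivery_min": self.delivery_min,
            "experience_years": self.experience_years,
            "viewray_years": self.viewray_years,
        }


# ---------------------------------------------------------------------------
# correlation matrix construction


def nearest_psd(matrix: np.ndarray, tol: float = 0.25, max_iter: int = 50) -> np.ndarray:
    """Nearest positive semi-definite correlation matrix by eigenvalue clipping.

    Alternates clipping negative eigenvalues with restoring the unit diagonal.
    Raises :class:`CalibrationError` when the repair moves any entry by more
    than ``tol`` — a matrix that far from PSD is treated as a calibration
    mistake, not noise.
    """
    a = np.asarray(matrix, float)
    if a.ndim != 2 or a.shape[0] != a.shape[1] or not np.allclose(a, a.T, atol=1e-12):
        raise CalibrationError("correlation matrix must be square and symmetric")
    x = a.copy()
    for _ in range(max_iter):
        w, v = np.linalg.eigh((x + x.T) / 2)
        if w.min() >= -1e-10:
            break
        w = np.clip(w, 1e-10, None)
        x = (v * w) @ v.T
        d = np.sqrt(np.clip(np.diag(x), 1e-12, None))
        x = x / np.outer(d, d)
        np.fill_diagonal(x, 1.0)
    if np.max(np.abs(x - a)) > tol:
        raise CalibrationError(
            f"correlation matrix not repairable within tolerance {tol} "
            f"(max change {np.max(np.abs(x - a)):.3f})"
        )
    return x


def complete_forest_correlation(
    fields: list[str], edges: list[tuple[str, str, float]]
) -> np.ndarray:
    """PSD completion of a partially specified correlation matrix.

    The specified entries must form a forest (no cycles); the completion sets
    each unspecified entry to the product of edge correlations along the
    unique connecting path (0 across components).  This is the Markov-field
    completion: it preserves every specified entry exactly and is always PSD.
    """
    index = {f: i for i, f in enumerate(fields)}
    adj: dict[str, list[tuple[str, float]]] = {f: [] for f in fields}
    seen = set()
    for a, b, r in edges:
        if a == b:
            raise CalibrationError(f"self-correlation on {a!r}")
        key = frozenset((a, b))
        if key in seen:
            raise CalibrationError(f"duplicate correlation entry for ({a}, {b})")
        seen.add(key)
        adj[a].append((b, r))
        adj[b].append((a, r))

    n = len(fields)
    corr = np.eye(n)
    visited_global: set[str] = set()
    for root in fields:
        if root in visited_global:
            continue
        # BFS over this component accumulating path products; a revisit means a cycle
        paths = {root: 1.0}
        order = [root]
        parent = {root: None}
        head = 0
        while head < len(order):
            cur = order[head]
            head += 1
            for nxt, r in adj[cur]:
                if nxt == parent[cur]:
                    continue
                if nxt in paths:
                    raise CalibrationError(
                        "correlation graph contains a cycle; forest completion "
                        f"is not applicable (cycle through {nxt!r})"
                    )
                paths[nxt] = paths[cur] * r
                parent[nxt] = cur
                order.append(nxt)
        visited_global.update(order)
        # pairwise products via a BFS re-rooted at each node of the component
        for a in order:
            pa = {a: 1.0}
            stack = [a]
            par = {a: None}
            while stack:
                cur = stack.pop()
                for nxt, r in adj[cur]:
                    if nxt == par[cur]:
                        continue
                    pa[nxt] = pa[cur] * r
                    par[nxt] = cur
                    stack.append(nxt)
            ia = index[a]
            for b, v in pa.items():
                ib = index[b]
                corr[ia, ib] = corr[ib, ia] = v
    return corr


def _copula_matrix(calibration: CohortCalibration) -> np.ndarray:
    fields = calibration.fields()
    latent_edges = [
        (a, b, SPEARMAN_TO_LATENT(r)) for a, b, r in calibration.correlations
    ]
    corr = complete_forest_correlation(fields, latent_edges)
    return nearest_psd(corr)


# ---------------------------------------------------------------------------
# sampling


def _child_seed(root_seed: int, index: int) -> int:
    # fixed arithmetic, no global state; stays below 2**31
    return (root_seed * 1_000_003 + 7919 * (index + 1)) % (2**31 - 1)


def sample_cohort_profiles(
    n_plans: int,
    calibration: CohortCalibration | None = None,
    seed: int = 0,
    required_metrics: list[str] | None = None,
) -> list[PlanQualityProfile]:
    """Draw ``n_plans`` correlated plan profiles; deterministic given the seed."""
    if n_plans < 1:
        raise ValueError(f"n_plans must be >= 1, got {n_plans}")
    cal = calibration if calibration is not None else default_calibration()
    cal.validate(required_metrics)

    fields = cal.fields()
    corr = _copula_matrix(cal)
    rng = np.random.default_rng(seed)
    # jitter guards Cholesky against the PSD boundary
    chol = np.linalg.cholesky(corr + 1e-10 * np.eye(len(fields)))
    z = rng.standard_normal((n_plans, len(fields))) @ chol.T
    u = stats.norm.cdf(z)

    columns: dict[str, np.ndarray] = {}
    for j, m in enumerate(cal.marginals):
        if m.kind == "latent":
            columns[m.field] = z[:, j]
            continue
        loc = m.solve_location()
        a, b = (m.min - loc) / m.sd, (m.max - loc) / m.sd
        x = stats.truncnorm.ppf(u[:, j], a, b, loc=loc, scale=m.sd)
        x = np.clip(x, m.min, m.max)
        if m.integer:
            x = np.rint(x)
        columns[m.field] = x

    metric_names = cal.metric_fields()
    latent_names = [m.field for m in cal.marginals if m.kind == "latent"]
    profiles = []
    for i in range(n_plans):
        profiles.append(
            PlanQualityProfile(
                plan_id=f"plan_{i:03d}",
                metric_targets={f: float(columns[f][i]) for f in metric_names},
                n_beams=int(columns["n_beams"][i]),
                n_segments=int(columns["n_segments"][i]),
                mu=int(columns["mu"][i]),
                beam_on_min=float(columns["beam_on_min"][i]),
                delivery_min=float(columns["delivery_min"][i]),
                experience_years=round(float(columns["experience_years"][i]), 1),
                viewray_years=round(float(columns["viewray_years"][i]), 1),
                seed=_child_seed(seed, i),
                latent={f: float(columns[f][i]) for f in latent_names},
            )
        )
    return profiles


# ---------------------------------------------------------------------------
# calibration (de)serialisation


def _calibration_from_dict(raw: dict, name: str) -> CohortCalibration:
    try:
        marginals = [
            MarginalSpec(
                field=m["field"],
                kind=m["kind"],
                mean=float(m.get("mean", 0.0)),
                sd=float(m.get("sd", 1.0)),
                median=(None if m.get("median") is None else float(m["median"])),
                min=float(m.get("min", -np.inf)),
                max=float(m.get("max", np.inf)),
                integer=bool(m.get("integer", False)),
            )
            for m in raw["marginals"]
        ]
        correlations = [
            (c["field_a"], c["field_b"], float(c["rho"])) for c in raw.get("correlations", [])
        ]
        return CohortCalibration(
            marginals=marginals, correlations=correlations, name=raw.get("name", name)
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise FormatError(f"malformed calibration: {exc!r}") from exc


def load_calibration(path: str | Path) -> CohortCalibration:
    path = Path(path)
    try:
        raw = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"cannot parse calibration {path}: {exc}") from exc
    return _calibration_from_dict(raw, name=path.stem)


def default_calibration() -> CohortCalibration:
    raw = json.loads(resources.files("pqmchal.data").joinpath("calibration.json").read_text())
    return _calibration_from_dict(raw, name="default")
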