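"""Tiered plan-quality-metric (PQM) scoring.

A plan is evaluated on 16 dose submetrics — 6 on the nested planning target
volumes (worth 78 points) and 10 on organs at risk (worth 72 points) — for a
maximum PQM of 150.  Each submetric is scored by a :class:`TierSchedule`,
either *tiered* (unacceptable / marginal / acceptable / good / ideal, with
flat points per tier) or *binary* (pass awards the full points, fail awards
0).  A value falling exactly on a tier boundary takes the better tier; the
same inclusive rule makes the 20-minute delivery-time gate pass at exactly
20.0 min.

Gates (the delivery-time limit and the hard dose constraints) never change
the numeric PQM — an over-time plan keeps its score — they only flag the plan
as unacceptable.

The shipped default scheme is *reconstructed*: the challenge's exact tier
boundaries and per-metric weights were never published, so the defaults
derive ideal thresholds from the prescriptions and the cohort's reported
better/worse-than-ideal pattern, conformation tiers from the published
0.6/0.7/0.8 bands, and weights that satisfy the printed 78/72/150 subtotals.
Everything is config-driven; no clinical value is hard-coded in logic.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from .errors import FormatError, InputError, SchemeValidationError

__all__ = [
    "MetricSpec",
    "TierSchedule",
    "HardConstraint",
    "ScoringScheme",
    "GateFailure",
    "ScoreCard",
    "TIER_LABELS",
    "score_metric",
    "apply_gates",
    "score_plan",
    "load_scheme",
    "validate_scheme",
    "default_scheme",
]

TIER_LABELS = ("unacceptable", "marginal", "acceptable", "good", "ideal")
METRIC_KINDS = ("D_percent", "D_cc", "D_mean", "V_gy_percent", "conformation")

PTV_MAX_POINTS = 78.0
OAR_MAX_POINTS = 72.0
PQM_MAX_POINTS = PTV_MAX_POINTS + OAR_MAX_POINTS


@dataclass(frozen=True)
class MetricSpec:
    """One scored submetric: which structure, which DVH quantity, which way is better."""

    metric_id: str
    structure: str  # structure name, or ring expression "outer-inner"
    kind: str  # one of METRIC_KINDS
    parameter: float | None  # x% / x cc / x Gy / reference dose, per kind
    direction: str  # "higher_better" | "lower_better"
    group: str  # "PTV" | "OAR"


@dataclass(frozen=True)
class TierSchedule:
    """Points awarded as a function of a metric value.

    ``boundaries`` are tier cut values ordered from worst to best in the
    metric's direction of improvement; ``tier_points`` are the flat points per
    tier from unacceptable to ideal (binary schedules carry the two-entry
    list ``[fail, pass]``).
    """

    mode: str  # "tiered" | "binary"
    boundaries: tuple[float, ...]
    tier_points: tuple[float, ...]
    max_points: float

    @property
    def ideal_threshold(self) -> float:
        """The max-points threshold: best boundary (tiered) or pass bound (binary)."""
        return self.boundaries[-1]


@dataclass(frozen=True)
class HardConstraint:
    metric_id: str
    bound: float
    direction: str  # "le" | "ge"


@dataclass
class ScoringScheme:
    metrics: list[tuple[MetricSpec, TierSchedule]]
    max_delivery_min: float
    hard_constraints: list[HardConstraint] = field(default_factory=list)
    name: str = "unnamed"

    def metric_ids(self) -> list[str]:
        return [m.metric_id for m, _ in self.metrics]

    def find(self, metric_id: str) -> tuple[MetricSpec, TierSchedule]:
        for m, s in self.metrics:
            if m.metric_id == metric_id:
                return m, s
        raise KeyError(metric_id)


@dataclass(frozen=True)
class GateFailure:
    gate: str  # "delivery_time" or "hard_constraint"
    metric_id: str | None
    bound: float
    observed: float
    message: str


@dataclass
class ScoreCard:
    plan_id: str
    metric_values: dict[str, float]
    metric_points: dict[str, float]
    metric_tiers: dict[str, str]
    ptv_points: float
    oar_points: float
    pqm: float
    acceptable: bool
    gate_failures: list[GateFailure]


def _improved(value: float, boundary: float, direction: str) -> bool:
    """True when value meets/beats the boundary; exact ties take the better tier."""
    if direction == "higher_better":
        return value >= boundary
    return value <= boundary


def score_metric(value: float, schedule: TierSchedule, direction: str) -> tuple[str, float]:
    """Tier label and points for one metric value."""
    if not math.isfinite(value):
        raise InputError(f"cannot score non-finite metric value {value!r}")
    if schedule.mode == "binary":
        if _improved(value, schedule.boundaries[0], direction):
            return "pass", schedule.tier_points[-1]
        return "fail", schedule.tier_points[0]
    tier_idx = 0
    for i, b in enumerate(schedule.boundaries):
        if _improved(value, b, direction):
            tier_idx = i + 1
    return TIER_LABELS[tier_idx], schedule.tier_points[tier_idx]


def apply_gates(
    metadata: dict, metric_values: dict[str, float], scheme: ScoringScheme
) -> list[GateFailure]:
    """Evaluate the delivery-time gate and every hard dose constraint."""
    if "delivery_min" not in metadata:
        raise InputError("metadata is missing required field 'delivery_min'")
    failures: list[GateFailure] = []
    delivery = float(metadata["delivery_min"])
    if delivery > scheme.max_delivery_min:
        failures.append(
            GateFailure(
                gate="delivery_time",
                metric_id=None,
                bound=scheme.max_delivery_min,
                observed=delivery,
                message=(
                    f"delivery time {delivery:.1f} min exceeds the "
                    f"{scheme.max_delivery_min:.1f} min limit"
                ),
            )
        )
    for hc in scheme.hard_constraints:
        if hc.metric_id not in metric_values:
            raise InputError(f"metric values are missing {hc.metric_id!r} for a hard constraint")
        v = float(metric_values[hc.metric_id])
        ok = v <= hc.bound if hc.direction == "le" else v >= hc.bound
        if not ok:
            op = "<=" if hc.direction == "le" else ">="
            failures.append(
                GateFailure(
                    gate="hard_constraint",
                    metric_id=hc.metric_id,
                    bound=hc.bound,
                    observed=v,
                    message=f"{hc.metric_id} = {v:.2f} violates hard constraint {op} {hc.bound}",
                )
            )
    return failures


def score_plan(
    metric_values: dict[str, float],
    metadata: dict,
    scheme: ScoringScheme,
    plan_id: str = "plan",
) -> ScoreCard:
    """Score all submetrics, total the PTV/OAR subtotals and apply the gates."""
    missing = [mid for mid in scheme.metric_ids() if mid not in metric_values]
    if missing:
        raise InputError(f"metric values are missing: {', '.join(missing)}")
    points: dict[str, float] = {}
    tiers: dict[str, str] = {}
    ptv = oar = 0.0
    for mspec, sched in scheme.metrics:
        tier, pts = score_metric(float(metric_values[mspec.metric_id]), sched, mspec.direction)
        points[mspec.metric_id] = pts
        tiers[mspec.metric_id] = tier
        if mspec.group == "PTV":
            ptv += pts
        else:
            oar += pts
    failures = apply_gates(metadata, metric_values, scheme)
    return ScoreCard(
        plan_id=plan_id,
        metric_values={mid: float(metric_values[mid]) for mid in scheme.metric_ids()},
        metric_points=points,
        metric_tiers=tiers,
        ptv_points=ptv,
        oar_points=oar,
        pqm=ptv + oar,
        acceptable=not failures,
        gate_failures=failures,
    )


# ---------------------------------------------------------------------------
# scheme (de)serialisation and validation


def _scheme_from_dict(raw: dict, name: str) -> ScoringScheme:
    try:
        metrics = []
        for entry in raw["metrics"]:
            mspec = MetricSpec(
                metric_id=entry["metric_id"],
                structure=entry["structure"],
                kind=entry["kind"],
                parameter=entry.get("parameter"),
                direction=entry["direction"],
                group=entry["group"],
            )
            sched_raw = entry["schedule"]
            sched = TierSchedule(
                mode=sched_raw["mode"],
                boundaries=tuple(float(b) for b in sched_raw["boundaries"]),
                tier_points=tuple(float(p) for p in sched_raw["tier_points"]),
                max_points=float(sched_raw["max_points"]),
            )
            metrics.append((mspec, sched))
        gates = raw["gates"]
        hard = [
            HardConstraint(hc["metric_id"], float(hc["bound"]), hc["direction"])
            for hc in gates.get("hard_constraints", [])
        ]
        return ScoringScheme(
            metrics=metrics,
            max_delivery_min=float(gates["max_delivery_min"]),
            hard_constraints=hard,
            name=raw.get("name", name),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise FormatError(f"malformed scoring scheme: {exc!r}") from exc


def validate_scheme(scheme: ScoringScheme) -> list[str]:
    """Return every invariant violation (empty list means the scheme is valid)."""
    v: list[str] = []
    ids = scheme.metric_ids()
    if len(ids) != len(set(ids)):
        v.append("metric_ids are not unique")
    if len(ids) != 16:
        v.append(f"scheme has {len(ids)} metrics, expected 16")
    n_ptv = sum(1 for m, _ in scheme.metrics if m.group == "PTV")
    n_oar = sum(1 for m, _ in scheme.metrics if m.group == "OAR")
    if n_ptv != 6:
        v.append(f"PTV group has {n_ptv} metrics, expected 6")
    if n_oar != 10:
        v.append(f"OAR group has {n_oar} metrics, expected 10")
    ptv_pts = sum(s.max_points for m, s in scheme.metrics if m.group == "PTV")
    oar_pts = sum(s.max_points for m, s in scheme.metrics if m.group == "OAR")
    if abs(ptv_pts - PTV_MAX_POINTS) > 1e-9:
        v.append(f"PTV max points sum to {ptv_pts}, expected {PTV_MAX_POINTS}")
    if abs(oar_pts - OAR_MAX_POINTS) > 1e-9:
        v.append(f"OAR max points sum to {oar_pts}, expected {OAR_MAX_POINTS}")
    if not scheme.max_delivery_min > 0:
        v.append("max_delivery_min must be positive")
    for m, s in scheme.metrics:
        mid = m.metric_id
        if m.kind not in METRIC_KINDS:
            v.append(f"{mid}: unknown metric kind {m.kind!r}")
        if m.direction not in ("higher_better", "lower_better"):
            v.append(f"{mid}: unknown direction {m.direction!r}")
        if m.group not in ("PTV", "OAR"):
            v.append(f"{mid}: unknown group {m.group!r}")
        if s.mode == "binary":
            if len(s.boundaries) != 1 or len(s.tier_points) != 2:
                v.append(f"{mid}: binary schedule needs 1 boundary and 2 tier points")
            elif s.tier_points[0] != 0 or s.tier_points[1] != s.max_points:
                v.append(f"{mid}: binary schedule must award 0 (fail) and max_points (pass)")
        elif s.mode == "tiered":
            if len(s.boundaries) != 4 or len(s.tier_points) != 5:
                v.append(f"{mid}: tiered schedule needs 4 boundaries and 5 tier points")
            else:
                diffs = [b - a for a, b in zip(s.boundaries, s.boundaries[1:])]
                improving = all(d > 0 for d in diffs) if m.direction == "higher_better" \
                    else all(d < 0 for d in diffs)
                if not improving:
                    v.append(f"{mid}: boundaries not strictly monotone toward improvement")
                if any(b - a < 0 for a, b in zip(s.tier_points, s.tier_points[1:])):
                    v.append(f"{mid}: tier points must be non-decreasing toward ideal")
                if s.tier_points[0] != 0:
                    v.append(f"{mid}: unacceptable tier must award 0 points")
                if s.tier_points[-1] != s.max_points:
                    v.append(f"{mid}: ideal tier must award max_points")
        else:
            v.append(f"{mid}: unknown schedule mode {s.mode!r}")
    return v


def load_scheme(path: str | Path, strict: bool = True) -> ScoringScheme:
    """Load and validate a scoring scheme JSON file."""
    path = Path(path)
    try:
        raw = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"cannot parse scheme file {path}: {exc}") from exc
    scheme = _scheme_from_dict(raw, name=path.stem)
    if strict:
        violations = validate_scheme(scheme)
        if violations:
            raise SchemeValidationError(violations)
    return scheme


def default_scheme() -> ScoringScheme:
    """The shipped (reconstructed) 16-metric challenge scheme."""
    raw = json.loads(resources.files("pqmchal.data").joinpath("scheme.json").read_text())
    scheme = _scheme_from_dict(raw, name="default")
    violations = validate_scheme(scheme)
    if violations:  # pragma: no cover - shipped data must be valid
        raise SchemeValidationError(violations)
    return scheme
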