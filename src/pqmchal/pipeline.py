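"""End-to-end challenge run: generate → evaluate → score → cohort statistics.

:func:`run_challenge` chains the four stages on one configuration and writes
a self-describing output tree::

    out/
      structures/<name>.nii.gz     one binary mask per structure
      plans/<plan_id>_dose.nii.gz  painted dose grids (optional)
      cohort_metadata.csv          delivery metadata per plan
      metrics.csv                  measured metric values per plan
      scorecards.csv               points, subtotals, PQM, acceptability
      stats/deviations.csv         threshold deviations + signed-rank tests
      stats/correlations.csv       Spearman matrix (long form)
      stats/tradeoffs.csv          PTV-vs-OAR-points OLS fits
      manifest.json                config hash, seed, file hashes, timings

Two runs with the same configuration and seed produce byte-identical tables;
the manifest is the only file carrying a timestamp.  Plans flagged
unacceptable are results, not errors.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .cohort import (
    CohortCalibration,
    default_calibration,
    load_calibration,
    sample_cohort_profiles,
)
from .dvh import extract_metrics
from .errors import PqmchalError
from .io import ProvenanceHeader, config_hash, write_dose_nifti, write_mask_nifti, write_table_csv
from .painter import DosePainter
from .phantom import PhantomSpec, build_phantom, default_phantom_spec, load_phantom_spec
from .scoring import ScoringScheme, default_scheme, load_scheme, score_plan
from .stats import analyze_cohort, build_cohort_table

logger = logging.getLogger("pqmchal")

__all__ = ["RunConfig", "run_challenge", "evaluate_cohort"]


@dataclass
class RunConfig:
    n_plans: int = 14
    seed: int = 42
    out_dir: str | Path = "pqmchal_run"
    phantom_path: str | Path | None = None  # None → shipped default
    calibration_path: str | Path | None = None
    scheme_path: str | Path | None = None
    write_volumes: bool = True
    bin_width_gy: float = 0.01
    log_level: str = "INFO"

    def as_dict(self) -> dict:
        return {
            "n_plans": self.n_plans,
            "seed": self.seed,
            "phantom": str(self.phantom_path) if self.phantom_path else "default",
            "calibration": str(self.calibration_path) if self.calibration_path else "default",
            "scheme": str(self.scheme_path) if self.scheme_path else "default",
            "write_volumes": self.write_volumes,
            "bin_width_gy": self.bin_width_gy,
        }


def _load_inputs(config: RunConfig) -> tuple[PhantomSpec, CohortCalibration, ScoringScheme]:
    spec = (
        load_phantom_spec(config.phantom_path) if config.phantom_path else default_phantom_spec()
    )
    cal = (
        load_calibration(config.calibration_path)
        if config.calibration_path
        else default_calibration()
    )
    scheme = load_scheme(config.scheme_path) if config.scheme_path else default_scheme()
    return spec, cal, scheme


def evaluate_cohort(profiles, painter: DosePainter, masks, scheme, bin_width_gy=0.01):
    """Paint, measure and score every profile; returns (metrics, scorecards)."""
    all_metrics: list[dict] = []
    scorecards = []
    for prof in profiles:
        try:
            dose = painter.paint(prof)
            measured = extract_metrics(dose, masks, [m for m, _ in scheme.metrics], bin_width_gy)
            card = score_plan(measured, prof.metadata(), scheme, plan_id=prof.plan_id)
        except PqmchalError as exc:
            raise type(exc)(f"[evaluate:{prof.plan_id}] {exc}") from exc
        all_metrics.append({"plan_id": prof.plan_id, **measured})
        scorecards.append(card)
    return all_metrics, scorecards


def run_challenge(config: RunConfig) -> Path:
    """Run all stages and return the output directory."""
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "stats").mkdir(exist_ok=True)

    if config.n_plans < 1:
        raise ValueError("n_plans must be >= 1")
    spec, cal, scheme = _load_inputs(config)
    chash = config_hash(config.as_dict())
    prov = ProvenanceHeader(tool_version=__version__, seed=config.seed, config_hash=chash)
    timings: dict[str, float] = {}

    t0 = time.perf_counter()
    logger.info("stage generate: building phantom %s", spec.name)
    masks, _ = build_phantom(spec)
    if config.write_volumes:
        (out / "structures").mkdir(exist_ok=True)
        for name, mask in masks.items():
            write_mask_nifti(mask, out / "structures" / f"{name}.nii.gz")
    metric_ids = [m.metric_id for m, _ in scheme.metrics]
    profiles = sample_cohort_profiles(
        config.n_plans, cal, seed=config.seed, required_metrics=metric_ids
    )
    meta_df = pd.DataFrame(
        [{"plan_id": p.plan_id, **p.metadata(), "seed": p.seed} for p in profiles]
    )
    write_table_csv(meta_df, out / "cohort_metadata.csv", prov)
    timings["generate"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    logger.info("stage evaluate+score: %d plans", len(profiles))
    painter = DosePainter(masks, spec.spacing_mm, [m for m, _ in scheme.metrics])
    all_metrics, scorecards = evaluate_cohort(
        profiles, painter, masks, scheme, config.bin_width_gy
    )
    if config.write_volumes:
        (out / "plans").mkdir(exist_ok=True)
        for prof in profiles:
            dose = painter.paint(prof)
            write_dose_nifti(dose, out / "plans" / f"{prof.plan_id}_dose.nii.gz")
    write_table_csv(pd.DataFrame(all_metrics), out / "metrics.csv", prov)
    card_rows = []
    for card in scorecards:
        row = {"plan_id": card.plan_id}
        row.update({f"{k}_value": v for k, v in card.metric_values.items()})
        row.update({f"{k}_points": v for k, v in card.metric_points.items()})
        row.update(
            ptv_points=card.ptv_points,
            oar_points=card.oar_points,
            pqm=card.pqm,
            acceptable=card.acceptable,
            gate_failures="; ".join(f.message for f in card.gate_failures),
        )
        card_rows.append(row)
    write_table_csv(pd.DataFrame(card_rows), out / "scorecards.csv", prov)
    timings["evaluate_score"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    if config.n_plans >= 4:
        logger.info("stage cohort-stats")
        table = build_cohort_table(scorecards, profiles)
        results = analyze_cohort(table, scheme)
        write_table_csv(results["deviations"], out / "stats" / "deviations.csv", prov)
        write_table_csv(results["correlations"], out / "stats" / "correlations.csv", prov)
        write_table_csv(results["tradeoffs"], out / "stats" / "tradeoffs.csv", prov)
    else:
        logger.info("stage cohort-stats: skipped (insufficient n=%d)", config.n_plans)
    timings["cohort_stats"] = time.perf_counter() - t0

    files = {}
    for f in sorted(out.rglob("*")):
        if f.is_file() and f.name != "manifest.json":
            files[str(f.relative_to(out))] = hashlib.sha256(f.read_bytes()).hexdigest()[:16]
    manifest = {
        "tool_version": __version__,
        "config": config.as_dict(),
        "config_hash": chash,
        "seed": config.seed,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "timings_s": {k: round(v, 3) for k, v in timings.items()},
        "n_plans": config.n_plans,
        "stats_computed": config.n_plans >= 4,
        "files": files,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    logger.info("run complete: %s", out)
    return out
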