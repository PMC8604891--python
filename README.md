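# pqmchal

Synthetic re-creation of a multicenter head-and-neck MR-linac **planning
challenge**: generate a cohort of treatment plans on a voxel phantom, extract
the challenge's 16 dose–volume-histogram (DVH) submetrics, score them with a
tiered 150-point **plan quality metric (PQM)** under hard-constraint gating,
and run the cohort deviation and correlation analysis.

## Who this is for

Medical-physics and treatment-planning researchers who want a fully
reproducible, end-to-end sandbox of the plan-comparison methodology used in
multicenter planning challenges: the original challenge plans (14 planner
submissions on one oropharyngeal-carcinoma case, planned on a 0.35 T MR-linac
with step-and-shoot IMRT) are not public, so this package *synthesizes* a
cohort whose metric distributions and metadata correlations are calibrated to
the published summary statistics, and re-runs the entire evaluation pipeline
on it.

## The model

**Case.** Three nested planning target volumes with a simultaneous integrated
boost in 33 fractions — 69.96 Gy (PTV1, high risk), 59.4 Gy (PTV2), 54 Gy
(PTV3, elective) — plus ten organs at risk (spinal canal, both parotids,
brainstem, brachial plexus, brain, esophagus, glottis, mandible, oral
cavity). The phantom is topological: analytic ellipsoids/cylinders/boxes on a
160 mm cube at 2 mm voxels.

**Metrics.** All plan quality reduces to cumulative-DVH queries on a dose
grid `D` restricted to a structure `S`:

- `D_x%` / `D_xcc` — minimum dose to the hottest x % (or x cm³) of `S`;
  `D_0.1cc` is the near-maximum surrogate,
- `D_mean`, and `V_xGy` — percent of `S` receiving ≥ x Gy,
- the conformation number of PTV3 against the reference isodose `VRI`:

  `CN = (TV_RI / TV) × (TV_RI / V_RI)`  (coverage × selectivity, CN ∈ [0,1]).

**Scoring.** 16 submetrics — 6 on the PTVs (max 78 points) and 10 on OARs
(max 72) — scored on flat per-tier points (unacceptable / marginal /
acceptable / good / ideal) or pass/fail for critical organs; PQM = sum ≤ 150.
A plan is *unacceptable* if delivery exceeds 20 min (inclusive limit) or any
hard dose constraint fails; gating flags the plan but never changes the
numeric score.

**Cohort synthesis.** Per-plan metric targets and delivery metadata are drawn
from truncated-normal marginals calibrated to the published cohort table
(medians matched exactly, spread and range as printed) and coupled through a
Gaussian copula that imposes the published Spearman correlations
(beams↔segments 0.67, beams↔MU −0.63, experience↔spinal-canal −0.55, …).
A dose *painter* then turns each profile into a 3D dose grid whose measured
metrics match the intended ones to well under 2 %, so the whole
generate → measure → score → analyze loop closes.

## Worked example

```python
import numpy as np
from pqmchal import (
    DosePainter, build_phantom, default_phantom_spec, default_scheme,
    extract_metrics, sample_cohort_profiles, score_plan,
)

spec = default_phantom_spec()
masks, _ = build_phantom(spec)
scheme = default_scheme()
mspecs = [m for m, _ in scheme.metrics]

profiles = sample_cohort_profiles(14, seed=42)
painter = DosePainter(masks, spec.spacing_mm, mspecs)

cards = []
for prof in profiles:
    dose = painter.paint(prof)                      # 80x80x80 @ 2 mm, Gy
    values = extract_metrics(dose, masks, mspecs)   # the 16 submetrics
    cards.append(score_plan(values, prof.metadata(), scheme, prof.plan_id))

print(f"median PQM      {np.median([c.pqm for c in cards]):.1f} / 150")
print(f"acceptable      {sum(c.acceptable for c in cards)} / 14")
print(f"PTV1 D95% range {min(c.metric_values['ptv1_d95'] for c in cards):.1f}"
      f"-{max(c.metric_values['ptv1_d95'] for c in cards):.1f} Gy")
```

prints

```
median PQM      138.1 / 150
acceptable      13 / 14
PTV1 D95% range 66.7-68.6 Gy
```

— a 14-plan cohort scoring close to the ceiling, with one plan flagged for
exceeding the 20-minute delivery limit, and high-risk-target coverage inside
the calibrated 66.2–69.7 Gy band. The same pipeline is available from the
shell:

```bash
pqmchal run --n 14 --seed 42 --out challenge_run/
```

which writes the structure masks and dose grids (NIfTI), `metrics.csv`,
`scorecards.csv`, the statistics tables under `stats/`, and a `manifest.json`
with config and file hashes (two runs with the same seed are byte-identical).

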