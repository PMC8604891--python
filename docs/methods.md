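# Methods

This note documents the models, parameter choices and numerical conventions
behind `pqmchal`, and what the synthetic pipeline does and does not show
about real treatment plans.

## 1. What is being emulated

A multicenter planning challenge for one head-and-neck case on a 0.35 T
MR-linac: every participant plans the same contoured patient (three nested
simultaneous-integrated-boost targets at 69.96 / 59.4 / 54 Gy in 33
fractions, ten scored organs at risk), uploads the plan, and is scored out of
150 points on 16 DVH submetrics with hard constraints and a 20-minute
delivery-time limit. The original 14 submissions are not public; the
published record consists of per-metric summary statistics (mean, SD, median,
quartiles, range), a handful of Spearman correlations, and the scoring-scale
facts (78 PTV + 72 OAR = 150; tier labels; binary pass/fail organs). The
package treats those published quantities as the calibration targets of a
generative model and rebuilds the full evaluation loop around them.

## 2. Phantom

Topology, not anatomy. Structures are analytic primitives (ellipsoids,
elliptic cylinders, boxes) rasterized on an 80×80×80 grid at 2 mm isotropic
voxels (160 mm cube); a voxel belongs to a structure when its centre is
inside the primitive. The three PTVs are concentric ellipsoids (strict
nesting is validated); organs sit where their anatomical counterparts would:
parotids lateral, spinal canal posterior midline, brainstem and brain
superior, brachial plexus / esophagus / glottis inferior, mandible and oral
cavity anterior. In the shipped geometry every organ is disjoint from PTV3 —
this keeps each organ's dose fully controlled by its own painting profile.
Geometry is configuration (`data/phantom.json`), not code; users can overlap
structures, in which case overlaps resolve by voxelwise maximum and painted
targets on the overlapped organs are no longer guaranteed.

What the phantom does *not* model: MRI/CT appearance, electron densities,
registration, contouring variability, or any beam/machine geometry.

## 3. Cohort sampling

Each plan is a vector of 16 intended metric values plus 7 metadata fields
(beams, segments, monitor units, beam-on and delivery time, general and
platform-specific planning experience).

**Marginals.** Truncated normal per field: scale = published SD, truncation =
published range, and the *location solved numerically (Brent) so the
truncated normal's median equals the published median*. The published table
reports both mean and median; with the location set to the mean, truncation
skews the median by several tenths of a Gy (e.g. PTV1 D95% would land at
67.66 Gy instead of 67.0), so the median — the quantity the pipeline is asked
to recover — anchors the fit. Integer fields (beams, segments, MU) are
rounded after sampling; experience fields are rounded to 0.1 yr.

The conformation row is the one reconstruction: its printed SD rounds to 0.0
and the printed range minimum (0.7) contradicts the reported 4/14 plans in
the 0.6–0.7 band. The calibration uses mean 0.705, SD 0.035, range
[0.63, 0.80], median 0.70, consistent with the reported tier counts
(10/14 good, 4/14 acceptable, none ideal).

**Dependence.** A Gaussian copula. Published Spearman coefficients are
converted to latent-normal correlations via `rho_latent = 2·sin(π·rho_s/6)`
so the *rank* correlation of the sampled cohort matches the printed value.
The published pairs alone do not determine a correlation matrix, and filling
the unspecified entries with zeros is provably impossible here: the printed
partners of the segment count have squared sum > 1, so every zero-filled
completion is indefinite. The default calibration therefore completes the
matrix over the *forest* of published edges by Markov (product-along-path)
completion — always positive semi-definite, and every published coefficient
is preserved exactly; pairs in different graph components remain at 0. An
eigenvalue-clipping nearest-PSD repair exists for user-supplied matrices and
runs as a final safety net.

**Latent quality factors.** The published segments↔PQM (0.75) and
segments↔PTV-points (0.76) correlations concern quantities the scoring stage
computes downstream; imposing them on the score itself would make the
generator depend on the scoring config. They are imposed on two latent
quality factors instead, which load on the metric columns with ±0.4 (sign =
direction of improvement). The spinal-canal and glottis metrics carry the
published experience edges instead of loadings, keeping the edge set a
forest. The loading value 0.4 is a design choice: strong enough that "better
plans are better across the board", weak enough to leave realistic per-metric
scatter.

**Determinism.** One root seed; per-plan child seeds by fixed integer
arithmetic (`(seed·1000003 + 7919·(i+1)) mod 2³¹−1`); no global RNG state.
Identical (calibration, seed) → identical cohort, byte-identical outputs.

## 4. Dose painting

The painter inverts the DVH engine: per plan it constructs a dose grid whose
measured metrics equal the intended ones. Within each painted region (PTV1,
the PTV2−PTV1 and PTV3−PTV2 shells, each organ) dose is a monotone
piecewise-linear function of volume rank, with rank tied to distance from the
boost centre (organs: hot side faces the target), so dose varies smoothly in
space.

Pinning rules:

- `D_95%` pins are plateaus (±1 % volume) placed at the rank that corresponds
  to the 95 % quantile of the *whole* nested target, correcting for the
  hotter core it contains; validity requires the painted dose bands of
  adjacent shells not to cross at the pin, which is checked and otherwise
  raised as an infeasible-target error.
- `D_xcc` pins are plateaus of ceil(x/voxel)+2 voxels at the hot end.
- `D_mean` targets use a symmetric ramp (±5 Gy), whose discrete mean is exact.
- The `V_56.7Gy` pin places the 56.7 Gy crossing at the target volume
  fraction of the PTV3−PTV2 shell.
- The conformation target fixes the allowed spill of the 51.3 Gy reference
  isodose outside PTV3: `spill = (c²/CN − c)·V(PTV3)` for measured coverage
  `c`. After crediting organ hot spots that already exceed the reference
  dose, exactly that much spill is painted as a shell of nearest outside
  voxels; beyond it the background decays exponentially (8 mm length
  constant), monotone in distance from PTV3. Organ interiors are excluded
  from shell and background — that exclusion *is* organ sparing, and it is
  what makes a 22 Gy parotid mean reachable 5 mm from a 51 Gy isodose.

Measured-vs-intended error is < 0.2 % for all 16 metrics on the shipped
phantom (the module contract is 2 % relative). Painted dose is capped at
80.45 Gy (115 % of the highest prescription). Infeasible combinations (hot
spot below coverage, CN above achievable coverage, crossing pins) raise
errors naming the metrics involved.

The reference isodose for the conformation number is 51.3 Gy (95 % of the
54 Gy elective prescription) — the conventional coverage isodose, and the
only choice consistent with a CN near 0.7 when the cohort's PTV3 D95 sits
near 52.6 Gy. It is a scheme parameter, not a constant.

## 5. DVH engine

Full-voxel counting (each voxel contributes its whole volume at its dose; no
partial-volume supersampling — the synthetic pipeline controls its own
grids). Cumulative histograms use 0.01 Gy bins by default (0.1 ‰ of
prescription, far below every tier gap); bin edges are aligned multiples of
the bin width. `D_x%` follows the dominant clinical convention — minimum dose
to the hottest x % — computed by linear interpolation on the inverse
cumulative curve; the discretisation error of inverse queries is bounded by
one bin width and halves with the bin. `V_xGy` and `D_mean` are exact up to
float arithmetic. Doses are total physical Gy over 33 fractions; no
radiobiological conversion. Masks must share the dose grid exactly; there is
no resampling anywhere.

## 6. Scoring scheme

The challenge's exact tier boundaries and per-metric weights were never
published; the shipped scheme (`data/scheme.json`, labelled "reconstructed")
is derived from what was: ideal thresholds at 95 % of prescription for
coverage (107 % for the PTV1 hot spot), conformation tiers at
0.5/0.6/0.7/0.8, organ ideal thresholds set so the cohort medians are better
than ideal for every organ except the right parotid and oral cavity means
(the published pattern), hard bounds set just above the published cohort
maxima (every challenge plan met all dose constraints), and weights 6×13 PTV
+ 4×9 binary OAR (spinal canal, brainstem, brachial plexus, brain) + 6×6
tiered OAR = 78 + 72 = 150. The PTV2 D95 ideal threshold is 57.0 Gy rather
than 95 % of prescription because the published statement that all four
coverage metrics deviate < 7 % from optimal bounds it from below given the
published range maximum.

Conventions: flat points per tier (no within-tier interpolation); a value
exactly on a boundary takes the better tier — the same inclusive rule that
makes the delivery gate pass at exactly 20.0 min; delivery time is a gate
only, never a scored submetric (the 16 submetrics are all dose metrics and
78 + 72 = 150 leaves no room); gates set the acceptability flag but never
alter the numeric PQM. Everything is config-driven and validated
structurally (16 metrics, 6/10 split, subtotals, monotone boundaries,
zero-point unacceptable tier).

## 7. Cohort statistics

- **Deviations**: per metric, `(value − T)/T` against the max-points
  threshold `T`, reported both raw and direction-aligned (positive = better)
  because a boxplot of raw deviations reads "higher/lower" while the
  clinical question is "better/worse"; the cohort median's side is flagged.
- **Signed-rank test**: two-sided, exact for ≤ 20 informative observations
  via a dynamic-programming convolution over doubled mid-ranks — identical
  to enumerating all 2ⁿ sign assignments, and exact under ties, which the
  textbook tables are not. Above 20: normal approximation with tie and
  continuity corrections (agrees with the exact branch to < 0.01 absolute at
  n = 20). Zeros are dropped by default (classic Wilcoxon); the Pratt
  signed-zero policy is available. Two-sided p = min(1, 2·min(P(W≤w),
  P(W≥w))).
- **Spearman matrix**: ranked Pearson with average mid-ranks; p-values from
  the t approximation (the behaviour of the standard rank-correlation
  routines); strength bands strict as published (|ρ| > 0.7 strong,
  > 0.5 moderate, else weak — |ρ| = 0.5 is weak); the display flag
  reproduces the |ρ| > 0.5 matrix filter. Constant columns are reported
  not-computable, never 0.
- **Trade-off fits**: OLS of each PTV metric against the OAR point subtotal
  with a pointwise 95 % confidence band for the mean response.
- No multiple-testing correction anywhere (matching the reported analysis);
  stars follow *p<0.05, **p<0.01, ***p<0.001.

## 8. Problem sizes

The acceptance script and test suite use the sizes the analyses need, chosen
once: 500 painted plans on the 80³ phantom for median recovery (sample-median
standard error ≈ 0.07 Gy for PTV1 D95%, comfortably inside the ±0.3 Gy
check), 2000 profile-only draws for correlation recovery (SE ≈ 0.02), 14
plans for the challenge-sized worked example, and ≤ 20³ random grids for the
brute-force oracle comparisons. A full 500-plan paint-and-measure pass takes
a few seconds.

## 9. What passing tests do and do not show

The pipeline demonstrates *internal* consistency: the generator hits the
published marginals and correlations, the painter realises sampled targets,
the engine measures them back, and the scorer and statistics reproduce the
published scale facts and band rules. It does not validate anything about
real plans: painted dose distributions are rank-monotone constructions, not
solutions of an optimization problem; delivery metadata is sampled, not
computed from machine physics; inter-metric correlations not published are
model artifacts (forest completion), not measurements. The PQM distribution
of a synthetic cohort depends on the reconstructed tier boundaries, so its
median (~138 at n = 14) should be read as "close to the published 141.5
given a reconstructed scheme", not as a recovery of it.

## 10. Known limitations

- Single-structure-per-organ metrics only in the painter: one pinned metric
  per OAR (the challenge's pattern). Multiple simultaneous pins per organ
  would need a joint profile solver.
- The label-volume output cannot represent nested targets; use
  per-structure masks (the default).
- Exact signed-rank p is O(n²·Σrank) via DP — fine to n ≈ 200, but the
  implementation switches to the approximation at 20 as calibrated.
- No DICOM-RT parsing; NIfTI only in v1.
- Whether the challenge's D_0.1cc used interpolated or whole-voxel volumes
  is unrecorded; both lie within the engine's tolerance contract.
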