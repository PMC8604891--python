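"""Cohort analysis: threshold deviations, signed-rank tests, rank correlations.

The cohort analysis mirrors how the planning challenge was reported:

* per metric, the relative deviation ``(value − T)/T`` of every plan from the
  threshold ``T`` that awards maximum points, with the two-sided Wilcoxon
  signed-rank test of "different from the ideal";
* the full Spearman rank-correlation matrix over metric values, score
  subtotals and delivery metadata, with the 0.5 / 0.7 strength bands
  (strict: |rho| = 0.5 is still "weak") and the display filter |rho| > 0.5;
* ordinary-least-squares trade-off fits of PTV metrics against the OAR point
  subtotal with a pointwise 95% confidence band.

The signed-rank test is exact for n ≤ 20 — the tail is evaluated by a
dynamic-programming convolution over doubled mid-ranks, equivalent to full
enumeration of the 2^n sign assignments but handling ties exactly — and
switches to the tie-corrected normal approximation above.  Zeros are dropped
by default (classic Wilcoxon); the Pratt signed-zero policy is available.

No multiple-testing correction is applied anywhere; significance stars follow
the usual *p<0.05, **p<0.01, ***p<0.001 legend.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .errors import DegenerateInputError

__all__ = [
    "DeviationRecord",
    "CorrelationPair",
    "TradeoffFit",
    "relative_deviation",
    "wilcoxon_signed_rank",
    "spearman_matrix",
    "classify_strength",
    "significance_stars",
    "tradeoff_fit",
    "build_cohort_table",
    "analyze_cohort",
    "EXACT_ENUMERATION_MAX_N",
]

EXACT_ENUMERATION_MAX_N = 20
SCORE_COLUMNS = ("ptv_points", "oar_points", "pqm")
METADATA_COLUMNS = (
    "n_beams",
    "n_segments",
    "mu",
    "beam_on_min",
    "delivery_min",
    "experience_years",
    "viewray_years",
)


@dataclass
class DeviationRecord:
    metric_id: str
    threshold: float
    direction: str
    deviations: np.ndarray  # raw signed (v - T)/T per plan
    aligned_deviations: np.ndarray  # positive = better than threshold
    median_better: bool
    p_value: float | None = None


@dataclass(frozen=True)
class CorrelationPair:
    field_a: str
    field_b: str
    rho: float
    p_value: float
    strength: str
    displayed: bool


@dataclass
class TradeoffFit:
    slope: float
    intercept: float
    r_squared: float
    n: int
    _results: object  # statsmodels results, kept for the band evaluation

    def band(self, x_new, alpha: float = 0.05):
        """Fitted mean response with pointwise (1−alpha) confidence band."""
        x_new = np.atleast_1d(np.asarray(x_new, float))
        exog = sm.add_constant(x_new, has_constant="add")
        pred = self._results.get_prediction(exog)
        ci = pred.conf_int(alpha=alpha)
        return pred.predicted_mean, ci[:, 0], ci[:, 1]


# ---------------------------------------------------------------------------
# deviations


def relative_deviation(
    values, threshold: float, direction: str, metric_id: str = ""
) -> DeviationRecord:
    """Signed relative deviations from a max-points threshold.

    For ``lower_better`` metrics a negative deviation is an improvement; the
    ``aligned_deviations`` column flips the sign so that positive always means
    better, and ``median_better`` reports the direction of the cohort median.
    """
    if threshold == 0:
        raise ValueError("threshold must be nonzero")
    v = np.asarray(values, float)
    if v.size < 1:
        raise ValueError("need at least one value")
    if not np.all(np.isfinite(v)):
        raise ValueError("deviations must be finite")
    dev = (v - threshold) / threshold
    sign = 1.0 if direction == "higher_better" else -1.0
    aligned = sign * dev
    return DeviationRecord(
        metric_id=metric_id,
        threshold=float(threshold),
        direction=direction,
        deviations=dev,
        aligned_deviations=aligned,
        median_better=bool(np.median(aligned) > 0),
    )


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank


def _signed_rank_statistic(d: np.ndarray, zero_policy: str) -> tuple[float, np.ndarray]:
    """W+ and the (mid-)ranks of the sign-flippable observations."""
    d = np.asarray(d, float)
    if np.all(d == 0):
        raise DegenerateInputError("all differences are zero; nothing to test")
    if zero_policy == "drop":
        d = d[d != 0]
        ranks = sps.rankdata(np.abs(d))
        flippable = ranks
    elif zero_policy == "pratt":
        ranks_all = sps.rankdata(np.abs(d))
        nz = d != 0
        d, flippable = d[nz], ranks_all[nz]
        ranks = flippable
    else:
        raise ValueError(f"unknown zero_policy {zero_policy!r}")
    w_plus = float(ranks[d > 0].sum())
    return w_plus, flippable


def _exact_two_sided_p(w_plus: float, ranks: np.ndarray) -> float:
    """Exact two-sided p over all 2^n sign assignments (DP on doubled ranks)."""
    doubled = np.rint(2 * ranks).astype(np.int64)
    total = int(doubled.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in doubled:
        shifted = np.concatenate([np.zeros(r), counts[: total + 1 - r]])
        counts = counts + shifted
    n_outcomes = 2.0 ** len(doubled)
    w2 = int(round(2 * w_plus))
    p_le = counts[: w2 + 1].sum() / n_outcomes
    p_ge = counts[w2:].sum() / n_outcomes
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def _approx_two_sided_p(w_plus: float, ranks: np.ndarray) -> float:
    """Normal approximation with tie correction and continuity correction."""
    n = len(ranks)
    mu = n * (n + 1) / 4.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts) / 48.0).sum())
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    if var <= 0:
        raise DegenerateInputError("zero variance in signed-rank statistic")
    delta = w_plus - mu
    z = (delta - 0.5 * np.sign(delta)) / np.sqrt(var)
    return float(2.0 * sps.norm.sf(abs(z)))


def wilcoxon_signed_rank(
    deviations, zero_policy: str = "drop", exact_max_n: int = EXACT_ENUMERATION_MAX_N
) -> tuple[float, float]:
    """Two-sided one-sample Wilcoxon signed-rank test.

    Returns ``(W+, p)``.  Exact (full sign-assignment enumeration, ties
    handled exactly) up to ``exact_max_n`` informative observations, normal
    approximation with tie and continuity corrections above.
    """
    d = np.asarray(deviations, float)
    if not np.all(np.isfinite(d)):
        raise ValueError("differences must be finite")
    w_plus, ranks = _signed_rank_statistic(d, zero_policy)
    if len(ranks) < 3:
        raise DegenerateInputError(
            f"need at least 3 nonzero differences, got {len(ranks)}"
        )
    if len(ranks) <= exact_max_n:
        return w_plus, _exact_two_sided_p(w_plus, ranks)
    return w_plus, _approx_two_sided_p(w_plus, ranks)


# ---------------------------------------------------------------------------
# Spearman correlations


def classify_strength(rho: float) -> str:
    """Strength bands: strong |rho| > 0.7, moderate 0.5 < |rho| <= 0.7, else weak."""
    if not np.isfinite(rho):
        return "not_computable"
    if not -1.0 - 1e-12 <= rho <= 1.0 + 1e-12:
        raise ValueError(f"rho must be in [-1, 1], got {rho}")
    a = abs(rho)
    if a > 0.7:
        return "strong"
    if a > 0.5:
        return "moderate"
    return "weak"


def significance_stars(p: float) -> str:
    if not np.isfinite(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def _spearman_pair(xr: np.ndarray, yr: np.ndarray, n: int) -> tuple[float, float]:
    sx, sy = xr.std(ddof=0), yr.std(ddof=0)
    if sx == 0 or sy == 0:
        return float("nan"), float("nan")
    rho = float(np.mean((xr - xr.mean()) * (yr - yr.mean())) / (sx * sy))
    rho = float(np.clip(rho, -1.0, 1.0))
    if abs(rho) > 1.0 - 1e-12:  # snap float-rounded perfect monotone pairs
        rho = float(np.sign(rho))
    if abs(rho) == 1.0:
        return rho, 0.0
    t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    return rho, float(2.0 * sps.t.sf(abs(t), df=n - 2))


def spearman_matrix(table: pd.DataFrame) -> list[CorrelationPair]:
    """All pairwise Spearman correlations of a cohort table.

    Ranked-Pearson with average mid-ranks for ties; p-values from the
    t-distribution approximation.  Constant columns yield not-computable
    pairs (NaN rho), never a silent 0.
    """
    n = len(table)
    if n < 4:
        raise ValueError(f"need at least 4 rows for the correlation matrix, got {n}")
    cols = list(table.columns)
    ranks = {c: sps.rankdata(table[c].to_numpy(float)) for c in cols}
    pairs: list[CorrelationPair] = []
    for i, a in enumerate(cols):
        for b in cols[i + 1:]:
            rho, p = _spearman_pair(ranks[a], ranks[b], n)
            strength = classify_strength(rho)
            pairs.append(
                CorrelationPair(
                    field_a=a,
                    field_b=b,
                    rho=rho,
                    p_value=p,
                    strength=strength,
                    displayed=bool(np.isfinite(rho) and abs(rho) > 0.5),
                )
            )
    return pairs


# ---------------------------------------------------------------------------
# trade-off fits


def tradeoff_fit(x, y) -> TradeoffFit:
    """OLS fit of a PTV metric against the OAR point subtotal."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need matched x/y with at least 3 points")
    if np.ptp(x) == 0:
        raise DegenerateInputError("constant predictor; trade-off fit undefined")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    return TradeoffFit(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        r_squared=float(res.rsquared),
        n=int(x.size),
        _results=res,
    )


# ---------------------------------------------------------------------------
# cohort table + full analysis


def build_cohort_table(scorecards, profiles) -> pd.DataFrame:
    """Plans × (metric values + score subtotals + delivery metadata) table."""
    by_id = {p.plan_id: p for p in profiles}
    rows = []
    for card in scorecards:
        prof = by_id[card.plan_id]
        row = {"plan_id": card.plan_id}
        row.update(card.metric_values)
        row.update(
            ptv_points=card.ptv_points, oar_points=card.oar_points, pqm=card.pqm
        )
        row.update(prof.metadata())
        rows.append(row)
    table = pd.DataFrame(rows).set_index("plan_id")
    if table.isna().any().any():
        missing = table.columns[table.isna().any()].tolist()
        raise ValueError(f"cohort table has missing cells in columns: {missing}")
    return table


def analyze_cohort(table: pd.DataFrame, scheme) -> dict[str, pd.DataFrame]:
    """Deviation, correlation and trade-off summaries for a scored cohort.

    Returns DataFrames ``deviations``, ``correlations`` and ``tradeoffs``.
    With fewer than 4 plans the statistical parts are skipped gracefully
    (empty frames), mirroring a degenerate cohort.
    """
    dev_rows = []
    for mspec, sched in scheme.metrics:
        rec = relative_deviation(
            table[mspec.metric_id].to_numpy(),
            sched.ideal_threshold,
            mspec.direction,
            metric_id=mspec.metric_id,
        )
        try:
            _, p = wilcoxon_signed_rank(rec.deviations)
        except DegenerateInputError:
            p = float("nan")
        dev_rows.append(
            {
                "metric_id": rec.metric_id,
                "threshold": rec.threshold,
                "direction": rec.direction,
                "median_deviation": float(np.median(rec.deviations)),
                "median_aligned_deviation": float(np.median(rec.aligned_deviations)),
                "max_abs_deviation": float(np.max(np.abs(rec.deviations))),
                "median_better": rec.median_better,
                "p_value": p,
                "stars": significance_stars(p),
            }
        )
    deviations = pd.DataFrame(dev_rows)

    if len(table) >= 4:
        pairs = spearman_matrix(table)
        correlations = pd.DataFrame(
            [
                {
                    "field_a": c.field_a,
                    "field_b": c.field_b,
                    "rho": c.rho,
                    "p_value": c.p_value,
                    "strength": c.strength,
                    "displayed": c.displayed,
                    "stars": significance_stars(c.p_value),
                }
                for c in pairs
            ]
        )
        fit_rows = []
        for mspec, _ in scheme.metrics:
            if mspec.group != "PTV":
                continue
            try:
                fit = tradeoff_fit(table["oar_points"], table[mspec.metric_id])
            except DegenerateInputError:
                continue
            fit_rows.append(
                {
                    "metric_id": mspec.metric_id,
                    "slope": fit.slope,
                    "intercept": fit.intercept,
                    "r_squared": fit.r_squared,
                    "n": fit.n,
                }
            )
        tradeoffs = pd.DataFrame(fit_rows)
    else:
        correlations = pd.DataFrame(
            columns=["field_a", "field_b", "rho", "p_value", "strength", "displayed", "stars"]
        )
        tradeoffs = pd.DataFrame(columns=["metric_id", "slope", "intercept", "r_squared", "n"])

    return {"deviations": deviations, "correlations": correlations, "tradeoffs": tradeoffs}
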