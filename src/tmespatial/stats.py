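"""Two-group comparison battery and bivariate correlations.

The cohort analysis compares each spatial metric between HLA-DR HIGH and LOW
patients and correlates it with the continuous HLA-DR area percent.  Test
selection follows a normality gate: both groups must pass Shapiro-Wilk at
alpha = 0.05 for a two-sided one-way ANOVA (equivalent to the pooled-variance
t test for two groups); otherwise the Wilcoxon rank-sum test is used (exact
null distribution for combined n <= 20 without ties, normal approximation
with continuity and tie correction otherwise).  Categorical contingency goes
through Fisher's exact test with the probability-ordering two-sided
convention.  Raw p-values are adjusted per metric family with the
Benjamini-Hochberg step-up FDR procedure.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

DEFAULT_NORMALITY_ALPHA = 0.05
_EXACT_WILCOXON_MAX_N = 20


class TestKind(str, Enum):
    __test__ = False  # not a pytest collection target

    ANOVA = "ANOVA"
    WILCOXON = "WILCOXON"
    FISHER = "FISHER"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass
class ComparisonResult:
    """One two-group comparison: group means, test used, raw and adjusted p."""

    metric: str
    group_high_mean: float | None
    group_low_mean: float | None
    n_high: int
    n_low: int
    test: TestKind | None
    statistic: float | None
    p_raw: float | None
    p_adjusted: float | None = None
    family: str | None = None

    @property
    def computable(self) -> bool:
        return self.p_raw is not None


@dataclass
class CorrelationResult:
    """Pearson correlation of one metric against a continuous covariate."""

    metric: str
    covariate: str
    r: float | None
    p: float | None
    n: int

    @property
    def r_squared(self) -> float | None:
        return None if self.r is None else self.r**2

    @property
    def computable(self) -> bool:
        return self.r is not None


def _clean(values) -> np.ndarray:
    a = np.asarray(
        [v for v in values if v is not None], dtype=float
    )
    return a[np.isfinite(a)]


def two_group_compare(
    values_high,
    values_low,
    metric: str = "",
    alpha_normality: float = DEFAULT_NORMALITY_ALPHA,
) -> ComparisonResult:
    """Compare a metric between two patient groups.

    Missing values (None/NaN) are dropped.  With fewer than 3 usable values
    in either group the comparison is returned not-computable (all test
    fields ``None``) rather than raising.
    """
    values_high = list(values_high)
    values_low = list(values_low)
    high = _clean(values_high)
    low = _clean(values_low)
    dropped = (len(values_high) - high.size) + (len(values_low) - low.size)
    if dropped:
        logger.debug("%s: dropped %d missing values", metric or "metric", dropped)
    base = ComparisonResult(
        metric=metric,
        group_high_mean=float(high.mean()) if high.size else None,
        group_low_mean=float(low.mean()) if low.size else None,
        n_high=int(high.size),
        n_low=int(low.size),
        test=None,
        statistic=None,
        p_raw=None,
    )
    if high.size < 3 or low.size < 3:
        return base

    normal = True
    for grp in (high, low):
        if np.ptp(grp) == 0:
            normal = False  # Shapiro undefined on constant data; treat as non-normal
            break
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, p_sw = sps.shapiro(grp)
        if p_sw < alpha_normality:
            normal = False
            break

    if normal:
        if np.ptp(np.concatenate([high, low])) == 0:
            stat, p = 0.0, 1.0
        else:
            stat, p = sps.f_oneway(high, low)
            if not np.isfinite(p):  # zero within-group variance, unequal means
                stat, p = np.inf, 0.0
        base.test = TestKind.ANOVA
    else:
        n_comb = high.size + low.size
        has_ties = np.unique(np.concatenate([high, low])).size < n_comb
        method = "exact" if (n_comb <= _EXACT_WILCOXON_MAX_N and not has_ties) else "asymptotic"
        res = sps.mannwhitneyu(
            high, low, alternative="two-sided", method=method, use_continuity=True
        )
        stat, p = res.statistic, res.pvalue
        base.test = TestKind.WILCOXON
    base.statistic = float(stat)
    base.p_raw = float(min(p, 1.0))
    return base


def fisher_exact_2x2(table, metric: str = "") -> ComparisonResult:
    """Two-sided Fisher's exact test on a 2x2 count table.

    Two-sidedness follows the probability-ordering convention (sum the
    hypergeometric probabilities of all tables no more likely than the one
    observed).  A zero row or column margin makes the test degenerate and
    returns p = 1 with a warning.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or np.any(t < 0) or np.any(t != np.floor(t)):
        raise ValueError("table must be 2x2 nonnegative integers")
    t = t.astype(int)
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        warnings.warn("degenerate 2x2 table (zero margin): Fisher p set to 1")
        odds, p = np.nan, 1.0
    else:
        odds, p = sps.fisher_exact(t, alternative="two-sided")
    return ComparisonResult(
        metric=metric,
        group_high_mean=None,
        group_low_mean=None,
        n_high=int(t[:, 0].sum()),
        n_low=int(t[:, 1].sum()),
        test=TestKind.FISHER,
        statistic=float(odds) if np.isfinite(odds) else None,
        p_raw=float(p),
    )


def bh_adjust(p_values) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    ``q_(i) = min_{j >= i} p_(j) * m / j`` on the ascending order statistics,
    capped at 1.  Adjusted values never fall below their raw value.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return []
    if np.any(p < 0) or np.any(p > 1) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return [float(v) for v in q]


def bivariate_correlation(xs, ys, metric: str = "", covariate: str = "") -> CorrelationResult:
    """Pearson correlation with two-sided p, pairwise deletion of missing."""
    x = np.asarray([np.nan if v is None else v for v in xs], dtype=float)
    y = np.asarray([np.nan if v is None else v for v in ys], dtype=float)
    if x.size != y.size:
        raise ValueError("xs and ys must have equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = int(x.size)
    if n < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(metric=metric, covariate=covariate, r=None, p=None, n=n)
    r, p = sps.pearsonr(x, y)
    return CorrelationResult(metric=metric, covariate=covariate, r=float(r), p=float(p), n=n)


# ---------------------------------------------------------------------------
# cohort battery
# ---------------------------------------------------------------------------

#: Default metric families: BH adjustment is applied within each family,
#: mirroring the result panels (distances, engagement, infiltration, mixing,
#: activation).
DEFAULT_FAMILIES: dict[str, tuple[str, ...]] = {
    "distances": (
        "mean_nn|T->APC",
        "mean_nn|Th->APC",
        "mean_nn|T->EC",
        "mean_nn|CTL->EC",
        "mean_nn|Treg->CTL",
    ),
    "engagement": (
        "engagement_pct|T->APC",
        "engagement_pct|Th->APC",
        "engagement_pct|CTL->EC",
        "engagement_pct|CTL->APC",
        "engagement_pct|Treg->CTL",
        "mean_contacts|Th->APC",
    ),
    "infiltration": (
        "fraction|immune",
        "fraction|T",
        "fraction|Th",
        "fraction|CTL",
        "ctl_treg_ratio",
    ),
    "mixing": (
        "g_auc|Th->APC",
        "g_auc|CTL->EC",
    ),
    "activation": (
        "activated_pct|T",
        "activated_pct|Th",
        "engagement_pct|CTL[act]->EC",
        "engagement_pct|Th[act]->APC",
        "engagement_pct|CTL->EC[PDL1-]",
        "engagement_pct|CTL->EC[PDL1+]",
    ),
}


def run_comparison_battery(
    patients,
    families: dict[str, tuple[str, ...]] | None = None,
    alpha_normality: float = DEFAULT_NORMALITY_ALPHA,
    covariate_name: str = "hladr_area_pct",
) -> tuple[list[ComparisonResult], list[CorrelationResult]]:
    """Run the full two-group + correlation battery over a stratified cohort.

    ``patients`` is a list of :class:`~tmespatial.io.PatientRecord` objects
    with ``stratum`` assigned and a ``summary`` attribute holding the
    patient-level :class:`~tmespatial.spatial.SpatialSummary`.  For each
    metric in each family, the HIGH and LOW groups are compared with
    :func:`two_group_compare` and the metric is correlated against the
    per-patient HLA-DR mean with :func:`bivariate_correlation`.  BH
    adjustment is applied within each family over the computable raw p's.
    Metrics absent from the summaries are skipped with a warning.
    """
    from .io import Stratum

    if families is None:
        families = DEFAULT_FAMILIES
    for p in patients:
        if p.stratum is None:
            raise ValueError(f"patient {p.patient_id}: stratum not assigned")
        if not hasattr(p, "summary"):
            raise ValueError(f"patient {p.patient_id}: spatial summary not computed")

    high = [p for p in patients if p.stratum is Stratum.HIGH]
    low = [p for p in patients if p.stratum is Stratum.LOW]

    comparisons: list[ComparisonResult] = []
    correlations: list[CorrelationResult] = []
    for family, metrics in families.items():
        fam_results: list[ComparisonResult] = []
        for metric in metrics:
            present = any(metric in p.summary.metrics for p in patients)
            if not present:
                warnings.warn(f"metric {metric!r} absent from summaries; skipped")
                continue
            vals_high = [p.summary.metrics.get(metric) for p in high]
            vals_low = [p.summary.metrics.get(metric) for p in low]
            res = two_group_compare(vals_high, vals_low, metric=metric,
                                    alpha_normality=alpha_normality)
            res.family = family
            fam_results.append(res)
            xs = [p.hladr_mean_pct for p in patients]
            ys = [p.summary.metrics.get(metric) for p in patients]
            correlations.append(
                bivariate_correlation(xs, ys, metric=metric, covariate=covariate_name)
            )
        computable = [r for r in fam_results if r.computable]
        if computable:
            adj = bh_adjust([r.p_raw for r in computable])
            for r, q in zip(computable, adj):
                r.p_adjusted = q
        comparisons.extend(fam_results)
    return comparisons, correlations


def comparisons_frame(comparisons: list[ComparisonResult]) -> pd.DataFrame:
    """Tidy DataFrame of comparison results (one row per metric)."""
    rows = []
    for c in comparisons:
        kind, _, pair = c.metric.partition("|")
        rows.append({
            "metric": c.metric,
            "family": c.family,
            "kind": kind,
            "pair": pair or None,
            "mean_high": c.group_high_mean,
            "mean_low": c.group_low_mean,
            "n_high": c.n_high,
            "n_low": c.n_low,
            "test": None if c.test is None else c.test.value,
            "statistic": c.statistic,
            "p_raw": c.p_raw,
            "p_bh": c.p_adjusted,
        })
    return pd.DataFrame(rows)


def correlations_frame(correlations: list[CorrelationResult]) -> pd.DataFrame:
    """Tidy DataFrame of correlation results."""
    return pd.DataFrame(
        {
            "metric": [c.metric for c in correlations],
            "covariate": [c.covariate for c in correlations],
            "r": [c.r for c in correlations],
            "r_squared": [c.r_squared for c in correlations],
            "p": [c.p for c in correlations],
            "n": [c.n for c in correlations],
        }
    )
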