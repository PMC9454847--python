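"""Per-core spatial statistics for phenotyped cell patterns.

Three families of metrics describe how a reference phenotype x relates to a
target phenotype y inside a TMA core:

* **nearest-neighbor distances** — Euclidean distance from each x cell to the
  closest y cell;
* **engagement** — the fraction of x cells with at least one y cell within a
  fixed interaction radius (40 um center-to-center by default), and the mean
  number of simultaneous y contacts among engaged x cells;
* **cross-type G-function** — the distribution function
  ``G_xy(r) = P(nearest y within r of an x cell)``, summarised by its area
  under the curve on [0, 60] um.  Under complete spatial randomness with
  target intensity lambda_y, ``G(r) = 1 - exp(-lambda_y * pi * r^2)``.

Because a core is a small window, the nearest y neighbor of an x cell near
the boundary may lie outside the observed tissue; the naive empirical CDF is
then biased low.  The estimator here applies the Kaplan-Meier edge
correction: each x cell's nearest-neighbor distance is right-censored at its
distance to the window boundary, and G is the product-limit estimate of the
censored distance distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .geometry import Window
from .io import CoreSample
from .phenotype import Phenotype, group_mask

#: Interaction radius defining "engagement", center-to-center microns.
DEFAULT_ENGAGEMENT_RADIUS_UM: float = 40.0
#: Upper distance bound for the G-function AUC, microns.
DEFAULT_G_RADIUS_UM: float = 60.0
#: Step of the distance grid the G curve is evaluated on, microns.
DEFAULT_R_STEP_UM: float = 1.0


def default_r_grid(
    r_max: float = DEFAULT_G_RADIUS_UM, step: float = DEFAULT_R_STEP_UM
) -> np.ndarray:
    """Distance grid 0..r_max inclusive at the given step."""
    n = int(round(r_max / step))
    if not np.isclose(n * step, r_max):
        raise ValueError("r_step must divide r_max")
    return np.linspace(0.0, r_max, n + 1)


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def nn_distances(
    ref_xy: np.ndarray, target_xy: np.ndarray, same_set: bool = False
) -> np.ndarray:
    """Distance from each reference cell to its nearest target cell.

    Parameters
    ----------
    ref_xy, target_xy
        ``(n, 2)`` coordinate arrays in microns.
    same_set
        True when ref and target are the same physical cells; self-pairs are
        then excluded.

    Returns
    -------
    ndarray of shape ``(len(ref_xy),)``.  Raises ``ValueError`` on an empty
    target set (callers record the metric as missing instead of calling).
    """
    ref_xy = np.atleast_2d(np.asarray(ref_xy, dtype=float))
    target_xy = np.atleast_2d(np.asarray(target_xy, dtype=float))
    if target_xy.shape[0] == 0 or (same_set and target_xy.shape[0] < 2):
        raise ValueError("target set empty (or singleton under self-exclusion)")
    if ref_xy.shape[0] == 0:
        return np.empty(0)
    tree = cKDTree(target_xy)
    if same_set:
        d, _ = tree.query(ref_xy, k=2)
        return d[:, 1]
    d, _ = tree.query(ref_xy, k=1)
    return d


def engagement_stats(
    ref_xy: np.ndarray,
    target_xy: np.ndarray,
    radius: float = DEFAULT_ENGAGEMENT_RADIUS_UM,
    same_set: bool = False,
) -> tuple[float, float | None]:
    """Engagement percentage and mean simultaneous contacts.

    A reference cell is *engaged* when at least one target cell lies within
    ``radius`` (boundary inclusive, center-to-center).  Returns
    ``(engaged_pct, mean_contacts)`` where ``mean_contacts`` averages the
    number of in-radius target cells over engaged reference cells only, and
    is ``None`` when no cell is engaged.  An empty target set yields
    ``(0.0, None)``.
    """
    ref_xy = np.atleast_2d(np.asarray(ref_xy, dtype=float))
    target_xy = np.atleast_2d(np.asarray(target_xy, dtype=float))
    if ref_xy.shape[0] == 0:
        raise ValueError("reference set is empty")
    if target_xy.shape[0] == 0:
        return 0.0, None
    tree = cKDTree(target_xy)
    counts = np.asarray(
        tree.query_ball_point(ref_xy, r=radius, return_length=True), dtype=float
    )
    if same_set:
        counts -= 1.0  # each cell finds itself at distance 0
    engaged = counts >= 1
    pct = 100.0 * float(engaged.mean())
    mean_contacts = float(counts[engaged].mean()) if engaged.any() else None
    return pct, mean_contacts


def theoretical_poisson_G(lambda_y: float, r: float | np.ndarray) -> float | np.ndarray:
    """CSR reference G-function ``1 - exp(-lambda_y * pi * r^2)``.

    ``lambda_y`` is the target intensity in cells/um^2 and ``r`` the distance
    in microns; both must be nonnegative.
    """
    r = np.asarray(r, dtype=float)
    if lambda_y < 0 or np.any(r < 0):
        raise ValueError("lambda_y and r must be nonnegative")
    out = 1.0 - np.exp(-lambda_y * np.pi * r**2)
    return float(out) if out.ndim == 0 else out


@dataclass
class GCurve:
    """A cross-type nearest-neighbor distance distribution on a grid.

    ``values[i]`` estimates ``P(nearest target within r_grid[i])``; the curve
    is nondecreasing with values in [0, 1].
    """

    r_grid: np.ndarray
    values: np.ndarray
    ref_phenotype: str = ""
    target_phenotype: str = ""
    n_ref: int = 0
    n_target: int = 0

    def __post_init__(self) -> None:
        self.r_grid = np.asarray(self.r_grid, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.r_grid.shape != self.values.shape:
            raise ValueError("r_grid and values must align")
        if self.r_grid.size < 2 or self.r_grid[0] != 0.0 or np.any(np.diff(self.r_grid) <= 0):
            raise ValueError("r_grid must be strictly increasing from 0")
        if np.any(self.values < -1e-12) or np.any(self.values > 1 + 1e-12):
            raise ValueError("G values must lie in [0, 1]")
        if np.any(np.diff(self.values) < -1e-12):
            raise ValueError("G values must be nondecreasing")


def km_distance_cdf(
    times: np.ndarray, events: np.ndarray, r_grid: np.ndarray
) -> np.ndarray:
    """Product-limit (Kaplan-Meier) CDF of right-censored distances.

    ``times`` are observed distances (event or censoring), ``events`` marks
    true observations (True) vs censorings (False).  Returns
    ``1 - S_hat(r)`` on ``r_grid``.  At tied times events are processed
    before censorings, the standard convention.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    n = times.size
    if n == 0:
        raise ValueError("no observations")
    order = np.argsort(times, kind="stable")
    t, e = times[order], events[order]
    uniq, inv = np.unique(t, return_inverse=True)
    d = np.bincount(inv, weights=e.astype(float))
    m = np.bincount(inv).astype(float)
    at_risk = n - np.concatenate(([0.0], np.cumsum(m)[:-1]))
    with np.errstate(invalid="ignore", divide="ignore"):
        factors = np.where(at_risk > 0, 1.0 - d / at_risk, 1.0)
    surv = np.cumprod(factors)
    idx = np.searchsorted(uniq, np.asarray(r_grid, dtype=float), side="right")
    cdf = np.where(idx == 0, 0.0, 1.0 - surv[np.maximum(idx - 1, 0)])
    return np.clip(cdf, 0.0, 1.0)


def empirical_cross_G(
    ref_xy: np.ndarray,
    target_xy: np.ndarray,
    window: Window,
    r_grid: np.ndarray | None = None,
    same_set: bool = False,
    correction: str = "km",
    ref_phenotype: str = "",
    target_phenotype: str = "",
) -> GCurve:
    """Estimate the cross-type G-function inside an observation window.

    With ``correction="km"`` each reference cell contributes its nearest
    target distance right-censored at its distance to the window boundary,
    and the curve is the Kaplan-Meier estimate of the distance distribution
    — the edge-corrected estimator.  ``correction="none"`` returns the raw
    empirical CDF of observed nearest-neighbor distances (biased low near
    the boundary; exposed for diagnostics).
    """
    if r_grid is None:
        r_grid = default_r_grid()
    ref_xy = np.atleast_2d(np.asarray(ref_xy, dtype=float))
    d = nn_distances(ref_xy, target_xy, same_set=same_set)
    if correction == "none":
        values = np.searchsorted(np.sort(d), r_grid, side="right") / d.size
    elif correction == "km":
        c = window.boundary_distance(ref_xy[:, 0], ref_xy[:, 1])
        times = np.minimum(d, c)
        events = d <= c
        values = km_distance_cdf(times, events, r_grid)
    else:
        raise ValueError(f"unknown correction {correction!r}")
    # enforce monotonicity against floating-point jitter
    values = np.maximum.accumulate(np.clip(values, 0.0, 1.0))
    return GCurve(
        r_grid=np.asarray(r_grid, dtype=float),
        values=values,
        ref_phenotype=ref_phenotype,
        target_phenotype=target_phenotype,
        n_ref=int(ref_xy.shape[0]),
        n_target=int(np.atleast_2d(target_xy).shape[0]),
    )


def curve_auc(curve: GCurve, r_max: float = DEFAULT_G_RADIUS_UM) -> float:
    """Trapezoidal area under a G curve over [0, r_max], in microns."""
    if curve.r_grid[-1] < r_max - 1e-9:
        raise ValueError(f"r_grid ends at {curve.r_grid[-1]}, below r_max={r_max}")
    mask = curve.r_grid <= r_max + 1e-9
    return float(np.trapezoid(curve.values[mask], curve.r_grid[mask]))


# ---------------------------------------------------------------------------
# per-core and per-patient summaries
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PairSpec:
    """A (reference, target) phenotype pair with optional state filters.

    ``ref``/``target`` name phenotype groups (``CTL``, ``Th``, ``Treg``,
    ``APC``, ``EC``, ``T``, ``immune``); states are filters such as ``act``
    (GZMB+Ki67+) or ``PDL1-`` applied before the spatial computation.
    """

    ref: str
    target: str
    ref_state: str | None = None
    target_state: str | None = None

    @property
    def label(self) -> str:
        r = self.ref if self.ref_state is None else f"{self.ref}[{self.ref_state}]"
        t = self.target if self.target_state is None else f"{self.target}[{self.target_state}]"
        return f"{r}->{t}"

    @property
    def is_same_set(self) -> bool:
        return self.ref == self.target and self.ref_state == self.target_state

    @classmethod
    def parse(cls, label: str) -> "PairSpec":
        def split(tok: str) -> tuple[str, str | None]:
            if "[" in tok:
                group, state = tok.split("[", 1)
                return group, state.rstrip("]")
            return tok, None

        ref_tok, target_tok = label.split("->")
        ref, ref_state = split(ref_tok)
        target, target_state = split(target_tok)
        return cls(ref, target, ref_state, target_state)


#: Analysis panel: the reference->target relationships summarised per core.
DEFAULT_PAIRS: tuple[PairSpec, ...] = tuple(
    PairSpec.parse(lbl)
    for lbl in (
        "T->APC",
        "Th->APC",
        "T->EC",
        "CTL->EC",
        "CTL->APC",
        "Treg->CTL",
        "CTL[act]->EC",
        "Th[act]->APC",
        "CTL->EC[PDL1-]",
        "CTL->EC[PDL1+]",
    )
)

#: Phenotype groups whose cell fractions (percent of all cells) are reported.
FRACTION_GROUPS: tuple[str, ...] = (
    "CTL", "Th", "Treg", "APC", "EC", "other", "T", "immune",
)
#: Groups whose activated (GZMB+Ki67+) share within the group is reported.
ACTIVATION_GROUPS: tuple[str, ...] = ("T", "Th", "CTL")


@dataclass
class SpatialSummary:
    """Spatial metric set for one unit (a core or a patient).

    ``metrics`` maps flat keys — ``"mean_nn|Th->APC"``,
    ``"engagement_pct|CTL->EC[PDL1-]"``, ``"g_auc|Th->APC"``,
    ``"fraction|immune"``, ``"activated_pct|Th"``, ``"ctl_treg_ratio"`` — to
    values, with ``None`` for metrics not computable on this unit (e.g. a
    core with no APCs).  ``pair_counts`` records (n_ref, n_target) per pair
    so analyses can filter on cell counts.
    """

    unit_id: str
    level: str  # "CORE" or "PATIENT"
    metrics: dict[str, float | None] = field(default_factory=dict)
    pair_counts: dict[str, tuple[int, int]] = field(default_factory=dict)

    def _by_kind(self, kind: str) -> dict[str, float | None]:
        prefix = kind + "|"
        return {k[len(prefix):]: v for k, v in self.metrics.items() if k.startswith(prefix)}

    @property
    def mean_nn(self) -> dict[str, float | None]:
        return self._by_kind("mean_nn")

    @property
    def engagement_pct(self) -> dict[str, float | None]:
        return self._by_kind("engagement_pct")

    @property
    def mean_contacts(self) -> dict[str, float | None]:
        return self._by_kind("mean_contacts")

    @property
    def g_auc(self) -> dict[str, float | None]:
        return self._by_kind("g_auc")

    @property
    def phenotype_fractions(self) -> dict[str, float | None]:
        return self._by_kind("fraction")

    @property
    def ctl_treg_ratio(self) -> float | None:
        return self.metrics.get("ctl_treg_ratio")


def _pair_sets(core: CoreSample, pair: PairSpec) -> tuple[np.ndarray, np.ndarray]:
    cells = core.cells
    ref_mask = group_mask(cells, pair.ref, pair.ref_state)
    target_mask = group_mask(cells, pair.target, pair.target_state)
    xy = cells[["x", "y"]].to_numpy(dtype=float)
    return xy[ref_mask], xy[target_mask]


def summarize_core(
    core: CoreSample,
    pairs: tuple[PairSpec, ...] = DEFAULT_PAIRS,
    engagement_radius: float = DEFAULT_ENGAGEMENT_RADIUS_UM,
    r_grid: np.ndarray | None = None,
    g_r_max: float = DEFAULT_G_RADIUS_UM,
    keep_curves: bool = False,
) -> SpatialSummary:
    """Compute the full spatial metric set for one core.

    Phenotypes must already be assigned.  Metrics whose reference or target
    set is empty are recorded as ``None`` (missing), never raised.  With
    ``keep_curves`` the G curves are attached as ``summary.curves`` keyed by
    pair label.
    """
    if "phenotype" not in core.cells.columns:
        raise ValueError(f"core {core.core_id}: phenotypes not assigned")
    if r_grid is None:
        r_grid = default_r_grid(g_r_max)
    summary = SpatialSummary(unit_id=core.core_id, level="CORE")
    curves: dict[str, GCurve] = {}
    n_total = core.n_cells

    for pair in pairs:
        ref_xy, target_xy = _pair_sets(core, pair)
        label = pair.label
        n_ref, n_target = ref_xy.shape[0], target_xy.shape[0]
        summary.pair_counts[label] = (n_ref, n_target)
        min_target = 2 if pair.is_same_set else 1
        if n_ref == 0 or n_target < min_target:
            summary.metrics[f"mean_nn|{label}"] = None
            summary.metrics[f"engagement_pct|{label}"] = None
            summary.metrics[f"mean_contacts|{label}"] = None
            summary.metrics[f"g_auc|{label}"] = None
            continue
        d = nn_distances(ref_xy, target_xy, same_set=pair.is_same_set)
        summary.metrics[f"mean_nn|{label}"] = float(d.mean())
        pct, contacts = engagement_stats(
            ref_xy, target_xy, radius=engagement_radius, same_set=pair.is_same_set
        )
        summary.metrics[f"engagement_pct|{label}"] = pct
        summary.metrics[f"mean_contacts|{label}"] = contacts
        curve = empirical_cross_G(
            ref_xy, target_xy, core.window, r_grid,
            same_set=pair.is_same_set,
            ref_phenotype=pair.ref, target_phenotype=pair.target,
        )
        summary.metrics[f"g_auc|{label}"] = curve_auc(curve, g_r_max)
        if keep_curves:
            curves[label] = curve

    cells = core.cells
    for grp in FRACTION_GROUPS:
        n = int(group_mask(cells, grp).sum())
        summary.metrics[f"fraction|{grp}"] = 100.0 * n / n_total if n_total else None
    for grp in ACTIVATION_GROUPS:
        n_grp = int(group_mask(cells, grp).sum())
        n_act = int(group_mask(cells, grp, "act").sum())
        summary.metrics[f"activated_pct|{grp}"] = (
            100.0 * n_act / n_grp if n_grp else None
        )
    n_ctl = int((cells["phenotype"] == Phenotype.TCELL_CTL.value).sum())
    n_treg = int((cells["phenotype"] == Phenotype.TCELL_TREG.value).sum())
    summary.metrics["ctl_treg_ratio"] = n_ctl / n_treg if n_treg else None

    if keep_curves:
        summary.curves = curves  # type: ignore[attr-defined]
    return summary


def aggregate_patient(
    core_summaries: list[SpatialSummary], patient_id: str
) -> SpatialSummary:
    """Average core summaries into one patient-level summary.

    Each metric is the unweighted mean over cores where it is non-missing
    (triplicate cores carry equal design weight); a metric missing in every
    core stays missing.  Pair counts are summed.
    """
    if not core_summaries:
        raise ValueError("no core summaries to aggregate")
    out = SpatialSummary(unit_id=patient_id, level="PATIENT")
    keys: list[str] = []
    for s in core_summaries:
        for k in s.metrics:
            if k not in keys:
                keys.append(k)
    for k in keys:
        vals = [s.metrics[k] for s in core_summaries if s.metrics.get(k) is not None]
        out.metrics[k] = float(np.mean(vals)) if vals else None
    labels = {lbl for s in core_summaries for lbl in s.pair_counts}
    for lbl in labels:
        counts = [s.pair_counts.get(lbl, (0, 0)) for s in core_summaries]
        out.pair_counts[lbl] = (
            sum(c[0] for c in counts), sum(c[1] for c in counts)
        )
    return out


def pooled_patient_summary(
    cores: list[CoreSample],
    patient_id: str,
    pairs: tuple[PairSpec, ...] = DEFAULT_PAIRS,
    **kwargs,
) -> SpatialSummary:
    """Patient summary from cells pooled across cores (alternative to
    per-core averaging).

    Cores are disjoint windows, so pooling is implemented by computing each
    metric per core and combining with cell-count weights (distances and
    engagement are per-reference-cell averages; G curves are KM fits pooled
    over all reference cells).  Fractions use pooled counts.
    """
    import pandas as pd

    summaries = [summarize_core(c, pairs, **kwargs) for c in cores]
    out = SpatialSummary(unit_id=patient_id, level="PATIENT")
    for key in summaries[0].metrics:
        if key.startswith(("fraction|", "activated_pct|", "ctl_treg_ratio")):
            continue
        pair_label = key.split("|", 1)[1] if "|" in key else None
        vals, weights = [], []
        for s in summaries:
            v = s.metrics.get(key)
            if v is None:
                continue
            w = s.pair_counts.get(pair_label, (1, 1))[0] if pair_label else 1
            vals.append(v)
            weights.append(max(w, 1))
        out.metrics[key] = (
            float(np.average(vals, weights=weights)) if vals else None
        )
    pooled = pd.concat([c.cells for c in cores], ignore_index=True)
    n_total = len(pooled)
    for grp in FRACTION_GROUPS:
        n = int(group_mask(pooled, grp).sum())
        out.metrics[f"fraction|{grp}"] = 100.0 * n / n_total if n_total else None
    for grp in ACTIVATION_GROUPS:
        n_grp = int(group_mask(pooled, grp).sum())
        n_act = int(group_mask(pooled, grp, "act").sum())
        out.metrics[f"activated_pct|{grp}"] = 100.0 * n_act / n_grp if n_grp else None
    n_ctl = int((pooled["phenotype"] == Phenotype.TCELL_CTL.value).sum())
    n_treg = int((pooled["phenotype"] == Phenotype.TCELL_TREG.value).sum())
    out.metrics["ctl_treg_ratio"] = n_ctl / n_treg if n_treg else None
    for lbl in summaries[0].pair_counts:
        counts = [s.pair_counts.get(lbl, (0, 0)) for s in summaries]
        out.pair_counts[lbl] = (sum(c[0] for c in counts), sum(c[1] for c in counts))
    return out
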