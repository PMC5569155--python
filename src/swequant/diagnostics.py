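"""Diagnostic-performance statistics for lesion stiffness parameters.

Covers the statistical layer of a benign/malignant SWE study: sensitivity,
specificity and diagnostic accuracy at fixed clinical thresholds
(E_max = 80 kPa, E_mean = 50 kPa, SD = 7 kPa), ROC curves and AUC, optimal
cutoffs by Youden's index, intraclass correlation between quantification
routes, and chi-square comparison of proportions between routes.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

__all__ = [
    "Cohort",
    "DiagnosticSummary",
    "ConfusionCounts",
    "CLINICAL_THRESHOLDS",
    "confusion_at_threshold",
    "se_sp_da",
    "roc_auc",
    "youden_optimal",
    "icc_absolute_single",
    "chi_square_2x2",
    "mcnemar_2x2",
    "apply_display_adjustment",
    "compare_routes",
]

#: Fixed clinical decision thresholds in kPa (SD threshold also in kPa).
CLINICAL_THRESHOLDS = {"e_max": 80.0, "e_mean": 50.0, "sd": 7.0}

PARAMETERS = ("e_max", "e_mean", "sd")


class ConfusionCounts(NamedTuple):
    tp: int
    fp: int
    tn: int
    fn: int


@dataclass
class Cohort:
    """Aligned per-lesion values for several quantification routes.

    ``values[route][parameter]`` is an array aligned with ``lesion_ids`` and
    ``labels`` (benign = 0, malignant = 1).
    """

    lesion_ids: list
    labels: np.ndarray
    values: dict

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if not set(np.unique(self.labels)) <= {0, 1}:
            raise ValueError("labels must be binary (0 benign, 1 malignant)")
        n = len(self.lesion_ids)
        if self.labels.shape != (n,):
            raise ValueError("labels must align with lesion_ids")
        for route, params in self.values.items():
            for p, arr in params.items():
                arr = np.asarray(arr, dtype=float)
                if arr.shape != (n,):
                    raise ValueError(f"values[{route}][{p}] misaligned")
                params[p] = arr

    @property
    def routes(self) -> list:
        return list(self.values.keys())


@dataclass
class DiagnosticSummary:
    """Per-route, per-parameter diagnostic performance."""

    sensitivity: float
    specificity: float
    diagnostic_accuracy: float
    roc_points: np.ndarray
    auc: float
    youden_cutoff: float
    youden_j: float


def confusion_at_threshold(
    values, labels, threshold: float, positive_if: str = "gt"
) -> ConfusionCounts:
    """Tally the confusion matrix of a thresholded stiffness classifier.

    A lesion is called positive (malignant) when its value exceeds the
    threshold; ``positive_if='ge'`` switches the comparator to >=.
    """
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels, dtype=int)
    if v.size == 0 or v.shape != y.shape:
        raise ValueError("values and labels must be non-empty and aligned")
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    if positive_if not in ("gt", "ge"):
        raise ValueError("positive_if must be 'gt' or 'ge'")
    pos = v > threshold if positive_if == "gt" else v >= threshold
    tp = int(np.sum(pos & (y == 1)))
    fp = int(np.sum(pos & (y == 0)))
    tn = int(np.sum(~pos & (y == 0)))
    fn = int(np.sum(~pos & (y == 1)))
    return ConfusionCounts(tp, fp, tn, fn)


def se_sp_da(counts: ConfusionCounts) -> tuple[float, float, float]:
    """Sensitivity, specificity and diagnostic accuracy in percent.

    A zero denominator yields NaN for that quantity rather than an error.
    """
    tp, fp, tn, fn = counts
    se = 100.0 * tp / (tp + fn) if tp + fn else float("nan")
    sp = 100.0 * tn / (tn + fp) if tn + fp else float("nan")
    total = tp + fp + tn + fn
    da = 100.0 * (tp + tn) / total if total else float("nan")
    return se, sp, da


def _check_two_classes(labels: np.ndarray) -> None:
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")


def roc_auc(values, labels) -> tuple[np.ndarray, float]:
    """ROC points and trapezoidal AUC.

    Thresholds are placed at every distinct value; the trapezoidal area
    equals the tie-corrected Mann–Whitney concordance statistic.  Returns
    ``(points, auc)`` where ``points`` has columns (fpr, tpr, threshold).
    """
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels, dtype=int)
    if v.shape != y.shape or v.size == 0:
        raise ValueError("values and labels must be non-empty and aligned")
    _check_two_classes(y)
    fpr, tpr, thr = _sk_roc_curve(y, v, drop_intermediate=False)
    return np.stack([fpr, tpr, thr], axis=1), float(_sk_auc(fpr, tpr))


def youden_optimal(values, labels, positive_if: str = "gt") -> tuple[float, float]:
    """Optimal cutoff by Youden's index J = Se + Sp - 1.

    Candidate cutoffs are the midpoints between adjacent distinct sorted
    values; ties in J resolve to the smallest cutoff.
    """
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels, dtype=int)
    if v.shape != y.shape or v.size == 0:
        raise ValueError("values and labels must be non-empty and aligned")
    _check_two_classes(y)
    distinct = np.unique(v)
    if distinct.size < 2:
        return float(distinct[0]), 0.0
    candidates = 0.5 * (distinct[:-1] + distinct[1:])
    best_cut, best_j = candidates[0], -np.inf
    for cut in candidates:
        se, sp, _ = se_sp_da(confusion_at_threshold(v, y, cut, positive_if))
        j = se / 100.0 + sp / 100.0 - 1.0
        if j > best_j + 1e-12:
            best_cut, best_j = cut, j
    return float(best_cut), float(best_j)


def icc_absolute_single(ratings, form: str = "icc2") -> float:
    """Intraclass correlation between measurement routes.

    The default ``form='icc2'`` is the two-way random-effects,
    absolute-agreement, single-measure coefficient (Shrout–Fleiss ICC(2,1)),
    the conventional choice for method-comparison agreement; ``'icc3'``
    gives the consistency form ICC(3,1), ``'icc2k'``/``'icc3k'`` the
    average-measure variants.  Computed from the two-way ANOVA mean squares.
    ``ratings`` is an (n_subjects, k_raters) grid with no missing cells.
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2:
        raise ValueError("ratings must be a 2-D (subjects x raters) grid")
    n, k = x.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 subjects and 2 raters")
    if np.isnan(x).any():
        raise ValueError("ratings contain missing cells")

    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ssr = k * np.sum((row_means - grand) ** 2)
    ssc = n * np.sum((col_means - grand) ** 2)
    sst = np.sum((x - grand) ** 2)
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))

    if form == "icc2":
        denom = msr + (k - 1) * mse + k * (msc - mse) / n
    elif form == "icc2k":
        denom = msr + (msc - mse) * k / (n * 1.0)
        return float((msr - mse) / denom) if denom else float("nan")
    elif form == "icc3":
        denom = msr + (k - 1) * mse
    elif form == "icc3k":
        return float((msr - mse) / msr) if msr else float("nan")
    else:
        raise ValueError("form must be one of icc2, icc2k, icc3, icc3k")
    if denom == 0:
        return float("nan")
    return float((msr - mse) / denom)


def chi_square_2x2(table, alpha: float = 0.05) -> tuple[float, float, bool]:
    """Pearson chi-square (no continuity correction) on a 2x2 table.

    Returns ``(chi2, p, significant)`` with significance at ``p <= alpha``.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ValueError("table must be a non-negative 2x2 count table")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("table has a zero marginal; test undefined")
    chi2, p, _, _ = stats.chi2_contingency(t, correction=False)
    return float(chi2), float(p), bool(p <= alpha)


def mcnemar_2x2(table, alpha: float = 0.05) -> tuple[float, float, bool]:
    """McNemar's test for paired proportions (optional alternative).

    Statistically preferable to Pearson's test when the two routes rate the
    same lesions; provided as an option, with Pearson as the primary test.
    """
    from statsmodels.stats.contingency_tables import mcnemar

    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ValueError("table must be a non-negative 2x2 count table")
    res = mcnemar(t, exact=False, correction=False)
    return float(res.statistic), float(res.pvalue), bool(res.pvalue <= alpha)


def apply_display_adjustment(cohort: Cohort, ceiling: float = 180.0) -> Cohort:
    """Clamp every route's E_max and E_mean to the display ceiling.

    When comparing routes that saturate at the colour-display ceiling with
    routes that do not, the unclamped values above the ceiling are set to it
    so the agreement analysis compares like with like.  SD receives no such
    adjustment — loss of within-ROI spread cannot be undone — which is
    precisely why SD agreement suffers on display-limited routes.
    """
    values = {
        route: {
            p: (np.minimum(arr, ceiling) if p in ("e_max", "e_mean") else arr.copy())
            for p, arr in params.items()
        }
        for route, params in cohort.values.items()
    }
    return Cohort(lesion_ids=list(cohort.lesion_ids), labels=cohort.labels.copy(), values=values)


@dataclass
class RouteComparison:
    """Full diagnostic report across quantification routes."""

    performance: pd.DataFrame
    icc: pd.DataFrame
    chi_square: pd.DataFrame

    def to_csv(self, out_dir) -> None:
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.performance.to_csv(out / "performance.csv", index=False, float_format="%.6f")
        self.icc.to_csv(out / "icc.csv", index=False, float_format="%.6f")
        self.chi_square.to_csv(out / "chi_square.csv", index=False, float_format="%.6f")

    def __str__(self) -> str:
        parts = [
            "Diagnostic performance (Se/Sp/DA at clinical thresholds, AUC, Youden):",
            self.performance.to_string(index=False, float_format=lambda v: f"{v:.3f}"),
            "",
            "Pairwise ICC between routes:",
            self.icc.to_string(index=False, float_format=lambda v: f"{v:.3f}"),
        ]
        if len(self.chi_square):
            parts += [
                "",
                "Pairwise chi-square on Se and Sp:",
                self.chi_square.to_string(index=False, float_format=lambda v: f"{v:.4f}"),
            ]
        return "\n".join(parts)


def compare_routes(
    cohort: Cohort,
    thresholds: dict | None = None,
    positive_if: str = "gt",
    alpha: float = 0.05,
    icc_form: str = "icc2",
) -> RouteComparison:
    """Evaluate every route x parameter and compare routes pairwise.

    Produces, per route and parameter: Se/Sp/DA at the fixed clinical
    thresholds, trapezoidal AUC and the Youden-optimal cutoff; plus the
    pairwise ICC matrix per parameter and pairwise chi-square tests on the
    sensitivity and specificity counts between routes.
    Routes with fewer than 2 lesions are skipped with a warning.
    """
    thresholds = dict(CLINICAL_THRESHOLDS if thresholds is None else thresholds)
    y = cohort.labels

    usable = []
    for route in cohort.routes:
        n_vals = len(next(iter(cohort.values[route].values())))
        if n_vals < 2:
            warnings.warn(f"route {route!r} has <2 lesions; skipped", stacklevel=2)
            continue
        usable.append(route)

    perf_rows = []
    confusions: dict = {}
    for route in usable:
        for param in PARAMETERS:
            if param not in cohort.values[route]:
                continue
            v = cohort.values[route][param]
            counts = confusion_at_threshold(v, y, thresholds[param], positive_if)
            se, sp, da = se_sp_da(counts)
            _, auc_val = roc_auc(v, y)
            cutoff, j = youden_optimal(v, y, positive_if)
            confusions[(route, param)] = counts
            perf_rows.append(
                {
                    "route": route,
                    "parameter": param,
                    "threshold_kpa": thresholds[param],
                    "se_pct": se,
                    "sp_pct": sp,
                    "da_pct": da,
                    "auc": auc_val,
                    "youden_cutoff_kpa": cutoff,
                    "youden_j": j,
                }
            )

    icc_rows = []
    chi_rows = []
    for param in PARAMETERS:
        have = [r for r in usable if param in cohort.values[r]]
        for ra, rb in itertools.combinations(have, 2):
            grid = np.stack(
                [cohort.values[ra][param], cohort.values[rb][param]], axis=1
            )
            icc_rows.append(
                {
                    "parameter": param,
                    "route_a": ra,
                    "route_b": rb,
                    "icc": icc_absolute_single(grid, form=icc_form),
                }
            )
            for quantity in ("se", "sp"):
                ca, cb = confusions[(ra, param)], confusions[(rb, param)]
                if quantity == "se":
                    tab = [[ca.tp, ca.fn], [cb.tp, cb.fn]]
                else:
                    tab = [[ca.tn, ca.fp], [cb.tn, cb.fp]]
                try:
                    chi2, p, sig = chi_square_2x2(tab, alpha=alpha)
                except ValueError:
                    continue
                chi_rows.append(
                    {
                        "parameter": param,
                        "quantity": quantity,
                        "route_a": ra,
                        "route_b": rb,
                        "chi2": chi2,
                        "p": p,
                        "significant": sig,
                    }
                )

    return RouteComparison(
        performance=pd.DataFrame(perf_rows),
        icc=pd.DataFrame(icc_rows),
        chi_square=pd.DataFrame(chi_rows),
    )
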