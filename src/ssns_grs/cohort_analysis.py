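"""Cohort-level statistics on genetic risk scores.

Scores are summarised per cohort as median and interquartile range
(linear-interpolation quantiles), compared with the Kruskal–Wallis rank
test (omnibus and planned two-group comparisons against a control cohort
at a Bonferroni-divided threshold — seven comparisons give p < 0.05/7 ≈
0.007), and the discrimination between two cohorts is quantified by an
empirical ROC curve: trapezoidal AUC (identical to the tie-corrected
pairwise concordance P(S+ > S-) + 0.5 P(=)), a DeLong or stratified
bootstrap confidence interval, and an optimal cutoff maximising Youden's
J = sensitivity + specificity - 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError, LabelError


@dataclass
class CohortSummary:
    cohort: str
    n: int
    median: float
    q25: float
    q75: float


@dataclass
class ComparisonResult:
    groups: tuple[str, ...]
    h_statistic: float
    df: int
    p_value: float
    alpha: float
    significant: bool


@dataclass
class RocResult:
    thresholds: np.ndarray  # ascending, observed scores
    sensitivity: np.ndarray  # P(score >= t | positive)
    specificity: np.ndarray  # P(score < t | negative)
    auc: float
    ci_lower: float
    ci_upper: float
    ci_method: str
    optimal_cutoff: float
    youden_j: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "sensitivity": self.sensitivity,
                "specificity": self.specificity,
            }
        )


def _groups_from_map(
    scores: pd.DataFrame, cohort_map: Mapping[str, str]
) -> dict[str, np.ndarray]:
    missing = [s for s in scores["sample_id"] if s not in cohort_map]
    if missing:
        raise LabelError(f"samples without a cohort label: {missing[:5]} ...")
    labels = scores["sample_id"].map(cohort_map)
    return {
        str(lab): grp["score"].to_numpy()
        for lab, grp in scores.groupby(labels, sort=False)
    }


def summarise_cohorts(
    scores: pd.DataFrame,
    cohort_map: Mapping[str, str],
    order: Sequence[str] | None = None,
) -> list[CohortSummary]:
    """Median and IQR per cohort (type-7 linear-interpolation quantiles)."""
    groups = _groups_from_map(scores, cohort_map)
    names = list(order) if order is not None else sorted(groups)
    unknown = [n for n in names if n not in groups]
    if unknown:
        raise LabelError(f"unknown cohort labels: {unknown}")
    out = []
    for name in names:
        vals = groups[name]
        q25, med, q75 = np.quantile(vals, [0.25, 0.5, 0.75])
        out.append(
            CohortSummary(cohort=name, n=len(vals), median=float(med), q25=float(q25), q75=float(q75))
        )
    return out


def summaries_to_frame(summaries: Sequence[CohortSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [(s.cohort, s.n, s.median, s.q25, s.q75) for s in summaries],
        columns=["cohort", "n", "median", "q25", "q75"],
    )


def kruskal_wallis(
    groups: Mapping[str, Sequence[float]], alpha: float = 0.05
) -> ComparisonResult:
    """Kruskal–Wallis H with tie correction; p from chi² with k-1 df.

    Degenerate input (every value identical) returns H = 0, p = 1 with a
    warning instead of failing.
    """
    names = tuple(groups)
    arrays = [np.asarray(groups[n], dtype=float) for n in names]
    if len(arrays) < 2 or any(len(a) < 1 for a in arrays):
        raise InputError("need >= 2 non-empty groups")
    if sum(len(a) for a in arrays) < 3:
        raise InputError("need >= 3 observations in total")
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        warnings.warn("all values identical; Kruskal-Wallis degenerate", stacklevel=2)
        return ComparisonResult(
            groups=names, h_statistic=0.0, df=len(arrays) - 1, p_value=1.0,
            alpha=alpha, significant=False,
        )
    h, p = stats.kruskal(*arrays)
    return ComparisonResult(
        groups=names,
        h_statistic=float(h),
        df=len(arrays) - 1,
        p_value=float(p),
        alpha=alpha,
        significant=bool(p < alpha),
    )


def planned_comparisons(
    scores: pd.DataFrame,
    cohort_map: Mapping[str, str],
    control_label: str,
    comparison_labels: Sequence[str],
    alpha: float = 0.05,
) -> list[ComparisonResult]:
    """Two-group Kruskal–Wallis of each cohort against the control.

    The per-comparison threshold is ``alpha / m`` for m planned
    comparisons (0.05 / 7 ≈ 0.00714, displayed as 0.007 with the usual
    3-decimal rounding).
    """
    groups = _groups_from_map(scores, cohort_map)
    if control_label not in groups:
        raise LabelError(f"control cohort {control_label!r} absent")
    missing = [l for l in comparison_labels if l not in groups]
    if missing:
        raise LabelError(f"comparison cohorts absent: {missing}")
    m = len(comparison_labels)
    if m < 1:
        raise InputError("need at least one planned comparison")
    threshold = alpha / m
    out = []
    for label in comparison_labels:
        res = kruskal_wallis(
            {label: groups[label], control_label: groups[control_label]},
            alpha=threshold,
        )
        out.append(res)
    return out


def pairwise_comparisons(
    scores: pd.DataFrame,
    cohort_map: Mapping[str, str],
    labels: Sequence[str],
    alpha: float = 0.05,
) -> list[ComparisonResult]:
    """All pairwise two-group rank tests among ``labels``, Bonferroni-adjusted."""
    groups = _groups_from_map(scores, cohort_map)
    pairs = [
        (a, b) for i, a in enumerate(labels) for b in labels[i + 1 :]
    ]
    threshold = alpha / len(pairs) if pairs else alpha
    return [
        kruskal_wallis({a: groups[a], b: groups[b]}, alpha=threshold)
        for a, b in pairs
    ]


def _delong_ci(
    pos: np.ndarray, neg: np.ndarray, auc: float, level: float = 0.95
) -> tuple[float, float]:
    """DeLong variance of the empirical AUC via midrank placements."""
    m, n = len(pos), len(neg)
    if m < 2 or n < 2:
        return 0.0, 1.0
    combined = np.concatenate([pos, neg])
    tz = stats.rankdata(combined)  # midranks
    tx = stats.rankdata(pos)
    ty = stats.rankdata(neg)
    v01 = (tz[:m] - tx) / n  # placement of each positive among negatives
    v10 = 1.0 - (tz[m:] - ty) / m  # placement of each negative among positives
    var = np.var(v01, ddof=1) / m + np.var(v10, ddof=1) / n
    z = stats.norm.ppf(0.5 + level / 2)
    half = z * np.sqrt(var)
    return float(max(0.0, auc - half)), float(min(1.0, auc + half))


def _auc_mannwhitney(pos: np.ndarray, neg: np.ndarray) -> float:
    """Tie-corrected concordance P(pos > neg) + 0.5 P(pos = neg) via midranks."""
    m, n = len(pos), len(neg)
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    return float((ranks[:m].sum() - m * (m + 1) / 2) / (m * n))


def roc_analysis(
    scores_positive: Sequence[float],
    scores_negative: Sequence[float],
    ci_method: str = "delong",
    n_boot: int = 2000,
    seed: int | None = None,
    cutoff_method: str = "youden",
    ci_level: float = 0.95,
) -> RocResult:
    """Empirical ROC over all observed thresholds.

    Positive samples are predicted positive when score >= threshold. AUC
    is the trapezoidal area, equal to the tie-corrected pairwise
    concordance. The optimal cutoff maximises Youden's J over observed
    thresholds (ties broken toward the lower threshold); the alternative
    ``cutoff_method='closest01'`` minimises distance to the (0, 1)
    corner. CI by DeLong (default) or seeded stratified bootstrap.
    """
    pos = np.asarray(scores_positive, dtype=float)
    neg = np.asarray(scores_negative, dtype=float)
    if len(pos) == 0 or len(neg) == 0:
        raise InputError("both score groups must be non-empty")

    thresholds = np.unique(np.concatenate([pos, neg]))  # ascending
    sens = (pos[None, :] >= thresholds[:, None]).mean(axis=1)
    spec = (neg[None, :] < thresholds[:, None]).mean(axis=1)

    # trapezoid over the full curve including the (0,0) and (1,1) corners
    fpr = np.concatenate([[1.0], 1.0 - spec, [0.0]])
    tpr = np.concatenate([[1.0], sens, [0.0]])
    auc = float(np.trapezoid(tpr[::-1], fpr[::-1]))

    if cutoff_method == "youden":
        j = sens + spec - 1.0
        best = int(np.flatnonzero(j == j.max())[0])  # lowest threshold wins ties
    elif cutoff_method == "closest01":
        d = (1.0 - sens) ** 2 + (1.0 - spec) ** 2
        best = int(np.flatnonzero(d == d.min())[0])
    else:
        raise InputError(f"unknown cutoff method {cutoff_method!r}")

    if ci_method == "delong":
        lo, hi = _delong_ci(pos, neg, auc, level=ci_level)
    elif ci_method == "bootstrap":
        rng = np.random.default_rng(seed)
        reps = np.empty(n_boot)
        for b in range(n_boot):
            bp = rng.choice(pos, size=len(pos), replace=True)
            bn = rng.choice(neg, size=len(neg), replace=True)
            reps[b] = _auc_mannwhitney(bp, bn)
        tail = (1.0 - ci_level) / 2
        lo, hi = np.quantile(reps, [tail, 1.0 - tail])
        lo, hi = float(min(lo, auc)), float(max(hi, auc))
    else:
        raise InputError(f"unknown CI method {ci_method!r}")

    return RocResult(
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        ci_lower=lo,
        ci_upper=hi,
        ci_method=ci_method,
        optimal_cutoff=float(thresholds[best]),
        youden_j=float(sens[best] + spec[best] - 1.0),
    )


def render_figures(
    summaries: Sequence[CohortSummary],
    scores: pd.DataFrame,
    cohort_map: Mapping[str, str],
    roc: RocResult | None,
    outdir: str | Path,
    formats: Sequence[str] = ("svg", "png"),
    stem: str = "grs",
) -> list[Path]:
    """Per-cohort score densities with median verticals, plus the ROC curve."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: list[Path] = []
    groups = _groups_from_map(scores, cohort_map)

    fig, ax = plt.subplots(figsize=(7, 4.5))
    order = [s.cohort for s in summaries]
    colors = plt.cm.tab10(np.linspace(0, 1, max(len(order), 1)))
    for color, summary in zip(colors, summaries):
        vals = groups[summary.cohort]
        grid = np.linspace(
            min(vals.min(), 0) - 0.02, vals.max() + 0.02, 256
        )
        if np.ptp(vals) > 0 and len(vals) > 1:
            density = stats.gaussian_kde(vals)(grid)
        else:
            # constant scores: bandwidth floor, draw a narrow bump
            density = stats.norm.pdf(grid, loc=vals[0], scale=0.005)
        ax.plot(grid, density, color=color, label=f"{summary.cohort} (n={summary.n})")
        ax.axvline(summary.median, color=color, linestyle="--", linewidth=0.8)
    ax.set_xlabel("genetic risk score")
    ax.set_ylabel("density")
    if summaries:
        ax.legend(fontsize=7)
    fig.tight_layout()
    for ext in formats:
        p = outdir / f"{stem}_density.{ext}"
        fig.savefig(p)
        paths.append(p)
    plt.close(fig)

    if roc is not None:
        fig, ax = plt.subplots(figsize=(4.5, 4.5))
        fpr = np.concatenate([[1.0], 1.0 - roc.specificity, [0.0]])[::-1]
        tpr = np.concatenate([[1.0], roc.sensitivity, [0.0]])[::-1]
        ax.plot(fpr, tpr, label=f"AUC {roc.auc:.3f} ({roc.ci_lower:.3f}-{roc.ci_upper:.3f})")
        ax.plot([0, 1], [0, 1], color="grey", linestyle=":")
        ax.set_xlabel("1 - specificity")
        ax.set_ylabel("sensitivity")
        ax.legend(loc="lower right", fontsize=8)
        fig.tight_layout()
        for ext in formats:
            p = outdir / f"{stem}_roc.{ext}"
            fig.savefig(p)
            paths.append(p)
        plt.close(fig)
    return paths
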