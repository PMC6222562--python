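"""ROC curves, midrank AUC and the DeLong paired test for GWAS scans.

Each SNP in a scan is treated as one classification instance: causal SNPs
are cases, all others controls, and the per-SNP ``-log10(p)`` is the
continuous predictor.  The empirical AUC is computed as the Mann-Whitney
statistic with midrank tie handling, and two correlated AUCs (two traits
scanned over the same SNP set, same causal truth) are compared with the
DeLong structural-component estimator of the variance of the AUC
difference.  The resulting Z statistic is *not* referred to a normal
distribution downstream; significance comes from an empirical null
(see :mod:`gwasroc.calibrate`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.metrics import roc_curve as _sk_roc_curve

__all__ = [
    "RocInput",
    "RocCurve",
    "PairedDelong",
    "DelongComponents",
    "empirical_roc",
    "auc_midrank",
    "mean_roc",
    "delong_components",
    "delong_from_components",
    "delong_paired_test",
]


@dataclass
class RocInput:
    """Scores and case labels for one ROC curve.

    ``scores`` are per-SNP ``-log10(p)`` values; ``labels`` flag the causal
    SNPs (cases).  Both classes must be non-empty.
    """

    scores: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.labels = np.asarray(self.labels, dtype=bool)
        if self.scores.shape != self.labels.shape or self.scores.ndim != 1:
            raise ValueError("scores and labels must be 1-D and aligned")
        if self.m == 0 or self.n_ctl == 0:
            raise ValueError("both cases and controls must be present")

    @property
    def m(self) -> int:
        """Number of cases (causal SNPs)."""
        return int(self.labels.sum())

    @property
    def n_ctl(self) -> int:
        """Number of controls (non-causal SNPs)."""
        return int((~self.labels).sum())


@dataclass
class RocCurve:
    """An empirical ROC curve: one point per distinct score threshold."""

    thresholds: np.ndarray  # descending; +inf sentinel for the (0,0) point
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float


@dataclass
class PairedDelong:
    """DeLong comparison of two correlated AUCs."""

    auc1: float
    auc2: float
    var1: float
    var2: float
    cov12: float
    z: float
    p_two_sided: float
    degenerate: bool = False

    @property
    def var_diff(self) -> float:
        return self.var1 + self.var2 - 2.0 * self.cov12


@dataclass
class DelongComponents:
    """Structural components of one curve: V10 per case, V01 per control.

    ``mean(v10) == mean(v01) == auc``.  Precompute these once per trait to
    make all-pairs comparisons cheap.
    """

    auc: float
    v10: np.ndarray
    v01: np.ndarray


def auc_midrank(input: RocInput) -> float:
    """Empirical AUC as the normalized Mann-Whitney statistic.

    ``auc = (1/(m*n)) * sum_ij psi(X_i, Y_j)`` with psi = 1 when the case
    score exceeds the control score, 1/2 on ties, 0 otherwise; computed in
    O(N log N) from midranks.
    """
    ranks = stats.rankdata(input.scores, method="average")
    m, n = input.m, input.n_ctl
    case_rank_sum = float(ranks[input.labels].sum())
    return (case_rank_sum - m * (m + 1) / 2.0) / (m * n)


def empirical_roc(input: RocInput) -> RocCurve:
    """Empirical ROC curve evaluated at every distinct score threshold.

    Sensitivity at threshold t is the fraction of cases with score >= t;
    specificity is the fraction of controls with score < t.  Tied scores
    collapse to one point; the curve runs from (FPR, TPR) = (0, 0)
    (threshold +inf) to (1, 1).  The attached AUC is the midrank AUC, which
    equals the trapezoidal area under this curve exactly.
    """
    fpr, tpr, thr = _sk_roc_curve(
        input.labels.astype(int), input.scores, drop_intermediate=False
    )
    return RocCurve(
        thresholds=np.asarray(thr, dtype=float),
        sensitivity=np.asarray(tpr, dtype=float),
        specificity=1.0 - np.asarray(fpr, dtype=float),
        auc=auc_midrank(input),
    )


def mean_roc(curves: list[RocCurve], grid_step: float = 0.002) -> RocCurve:
    """Pointwise mean of replicate ROC curves on a fixed specificity grid.

    Each curve's sensitivity is linearly interpolated onto a specificity
    grid from 0 to 1 (step ``grid_step``; at a vertical step the highest
    sensitivity is used), then averaged across replicates.  Intended for
    reporting and plotting, never for inference.  The returned AUC is the
    trapezoidal area of the mean curve.
    """
    if not curves:
        raise ValueError("mean_roc requires at least one curve")
    grid = np.arange(0.0, 1.0 + grid_step / 2, grid_step)
    sens = np.empty((len(curves), len(grid)))
    for i, c in enumerate(curves):
        order = np.argsort(c.specificity, kind="stable")
        spec_sorted = c.specificity[order]
        sens_sorted = c.sensitivity[order]
        # collapse duplicate specificities (vertical steps) to the max TPR
        uniq, inverse = np.unique(spec_sorted, return_inverse=True)
        best = np.zeros(len(uniq))
        np.maximum.at(best, inverse, sens_sorted)
        sens[i] = np.interp(grid, uniq, best)
    mean_sens = sens.mean(axis=0)
    auc = float(np.trapezoid(mean_sens[::-1], (1.0 - grid)[::-1]))
    return RocCurve(
        thresholds=np.full(len(grid), np.nan),
        sensitivity=mean_sens,
        specificity=grid,
        auc=auc,
    )


def delong_components(input: RocInput) -> DelongComponents:
    """Per-case and per-control structural components via midranks.

    ``V10(i) = (1/n) sum_j psi(X_i, Y_j)`` and
    ``V01(j) = (1/m) sum_i psi(X_i, Y_j)``; both average to the AUC.
    """
    scores, labels = input.scores, input.labels
    m, n = input.m, input.n_ctl
    r_all = stats.rankdata(scores, method="average")
    x = scores[labels]
    y = scores[~labels]
    r_x = stats.rankdata(x, method="average")
    r_y = stats.rankdata(y, method="average")
    v10 = (r_all[labels] - r_x) / n
    v01 = 1.0 - (r_all[~labels] - r_y) / m
    return DelongComponents(auc=float(v10.mean()), v10=v10, v01=v01)


def delong_from_components(
    c1: DelongComponents, c2: DelongComponents
) -> PairedDelong:
    """DeLong paired comparison from precomputed structural components."""
    if len(c1.v10) != len(c2.v10) or len(c1.v01) != len(c2.v01):
        raise ValueError("components come from inputs with different label vectors")
    m, n = len(c1.v10), len(c1.v01)
    s10 = np.cov(np.vstack([c1.v10, c2.v10]), ddof=1)
    s01 = np.cov(np.vstack([c1.v01, c2.v01]), ddof=1)
    cov = s10 / m + s01 / n
    var1, var2, cov12 = float(cov[0, 0]), float(cov[1, 1]), float(cov[0, 1])
    var_diff = var1 + var2 - 2.0 * cov12
    degenerate = var_diff <= 1e-15
    z = 0.0 if degenerate else float((c1.auc - c2.auc) / np.sqrt(var_diff))
    return PairedDelong(
        auc1=c1.auc,
        auc2=c2.auc,
        var1=var1,
        var2=var2,
        cov12=cov12,
        z=z,
        p_two_sided=float(2.0 * stats.norm.sf(abs(z))),
        degenerate=degenerate,
    )


def delong_paired_test(input1: RocInput, input2: RocInput) -> PairedDelong:
    """DeLong test for two correlated AUCs over the same instances.

    Both inputs must carry identical label vectors (the same causal truth
    set); only the scores differ.  The Z statistic is
    ``(auc1 - auc2)/sqrt(var1 + var2 - 2*cov12)``; the attached two-sided
    normal p-value is reported for reference, but significance decisions
    should use the empirical null calibration, which does not assume Z is
    normal.
    """
    if not np.array_equal(input1.labels, input2.labels):
        raise ValueError("paired DeLong test requires identical label vectors")
    return delong_from_components(delong_components(input1), delong_components(input2))
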