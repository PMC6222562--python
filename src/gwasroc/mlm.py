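"""Single-marker mixed-linear-model association scan.

The model per trait is ``y = 1*mu + x_s*beta + u + e`` with polygenic
background ``u ~ N(0, sigma_u^2 K)`` (K a VanRaden genomic relationship
matrix) and residual ``e ~ N(0, sigma_e^2 I)``.  Variance components are
estimated once per trait by REML under the null (no marker) and then held
fixed for every single-marker generalized-least-squares test — the
P3D/EMMAX approximation.  An exact per-marker REML mode is available but
slow.

All heavy linear algebra runs in the eigenbasis of K: with
``K = U S U^T`` and ``H = lambda*K + I``, rotating by ``U^T`` turns every
GLS fit into a diagonally weighted least squares with weights
``1/(lambda*s_i + 1)``, so a whole-genome scan is a handful of vectorized
reductions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .panel import GenotypePanel
from .traits import SimulatedTrait

__all__ = [
    "KinshipMatrix",
    "VarianceComponents",
    "AssociationResult",
    "vanraden_kinship",
    "fit_null_reml",
    "scan_markers",
    "scan_trait_set",
]

_P_FLOOR = np.finfo(float).tiny  # p = 0 underflow guard before -log10


@dataclass
class KinshipMatrix:
    """Genomic relationship matrix with its provenance."""

    values: np.ndarray
    snp_count_used: int
    method: str = "vanraden"
    _eig: tuple[np.ndarray, np.ndarray] | None = field(
        default=None, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.shape != (n, n):
            raise ValueError("kinship matrix must be square")
        if not np.allclose(self.values, self.values.T, atol=1e-8):
            raise ValueError("kinship matrix must be symmetric")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("kinship matrix must be finite")

    @property
    def n_ind(self) -> int:
        return self.values.shape[0]

    def eigen(self) -> tuple[np.ndarray, np.ndarray]:
        """Cached eigendecomposition ``(s, U)`` with tiny negative
        eigenvalues clipped to zero (K is PSD up to round-off)."""
        if self._eig is None:
            s, u = np.linalg.eigh((self.values + self.values.T) / 2.0)
            self._eig = (np.clip(s, 0.0, None), u)
        return self._eig


@dataclass
class VarianceComponents:
    """REML variance components for the null polygenic model."""

    sigma_u2: float
    sigma_e2: float
    lambda_: float
    reml_loglik: float

    def __post_init__(self) -> None:
        if self.sigma_u2 < 0 or self.sigma_e2 < 0:
            raise ValueError("variance components must be >= 0")

    @property
    def pseudo_heritability(self) -> float:
        """sigma_u^2 / (sigma_u^2 + sigma_e^2); the marker-based h2 proxy
        (diag(K) is ~1 under the VanRaden scaling)."""
        tot = self.sigma_u2 + self.sigma_e2
        return self.sigma_u2 / tot if tot > 0 else 0.0


@dataclass
class AssociationResult:
    """Per-SNP association statistics for one trait."""

    trait: str
    p_values: np.ndarray
    beta: np.ndarray
    se: np.ndarray
    degenerate: np.ndarray

    def __post_init__(self) -> None:
        self.p_values = np.asarray(self.p_values, dtype=float)
        if np.any((self.p_values <= 0) | (self.p_values > 1)):
            raise ValueError("p-values must lie in (0, 1]")

    @property
    def neg_log10_p(self) -> np.ndarray:
        return -np.log10(np.maximum(self.p_values, _P_FLOOR))

    @property
    def n_snp(self) -> int:
        return len(self.p_values)


def vanraden_kinship(
    panel: GenotypePanel,
    n_snps_sample: int = 10_000,
    seed: int | np.random.Generator | np.random.SeedSequence | None = None,
) -> KinshipMatrix:
    """VanRaden genomic relationship matrix from a random SNP sample.

    ``K = M M^T / (2 * sum_j f_j (1 - f_j))`` where M is the dosage matrix
    of the sampled SNPs centered by twice the counted-allele frequency
    ``f_j`` (the column mean / 2).  The sample size is capped at the number
    of SNPs; one matrix is computed per panel and reused for every trait.
    """
    if n_snps_sample < 1:
        raise ValueError("n_snps_sample must be >= 1")
    if np.isnan(panel.genotypes).any():
        raise ValueError("kinship requires an imputed panel")
    rng = np.random.default_rng(seed)
    m = min(n_snps_sample, panel.n_snp)
    idx = rng.choice(panel.n_snp, size=m, replace=False) if m < panel.n_snp else np.arange(m)
    g = panel.genotypes[:, idx]
    f = g.mean(axis=0) / 2.0
    denom = 2.0 * float(np.sum(f * (1.0 - f)))
    if denom <= 0.0:
        raise ValueError("all sampled SNPs are monomorphic; kinship undefined")
    centered = g - 2.0 * f
    k = centered @ centered.T / denom
    return KinshipMatrix(values=k, snp_count_used=m)


# ---------------------------------------------------------------------------
# REML in the eigenbasis

def _reml_neg2_profile(lam: float, xr: np.ndarray, yr: np.ndarray, s: np.ndarray,
                       logdet_xtx: float) -> tuple[float, float, np.ndarray]:
    """-2 * REML log-likelihood at a given lambda, with the residual scale
    profiled out.  Returns (criterion, sigma_e2_hat, beta_hat)."""
    n, p = xr.shape
    d = lam * s + 1.0
    w = 1.0 / d
    xtw = xr * w[:, None]
    a = xtw.T @ xr
    b = xtw.T @ yr
    beta = np.linalg.solve(a, b)
    r = yr - xr @ beta
    rss = float(r @ (w * r))
    sigma_e2 = rss / (n - p)
    if sigma_e2 <= 0:
        sigma_e2 = np.finfo(float).tiny
    sign, logdet_a = np.linalg.slogdet(a)
    crit = (
        (n - p) * (np.log(2.0 * np.pi * sigma_e2) + 1.0)
        + float(np.sum(np.log(d)))
        + logdet_a
        - logdet_xtx
    )
    return crit, sigma_e2, beta


def _reml_optimize(
    xr: np.ndarray,
    yr: np.ndarray,
    s: np.ndarray,
    x: np.ndarray,
    grid_points: int = 100,
    log10_bounds: tuple[float, float] = (-5.0, 5.0),
    tol: float = 1e-6,
) -> tuple[float, float, float]:
    """Maximize the REML likelihood over lambda = sigma_u^2/sigma_e^2.

    Log-spaced grid search (lambda = 0 included) followed by bounded
    Brent refinement between the best grid point's neighbours.
    Returns (lambda, sigma_e2, reml_loglik).
    """
    _, logdet_xtx = np.linalg.slogdet(x.T @ x)
    grid = np.concatenate([[0.0], np.logspace(*log10_bounds, grid_points)])
    crits = np.array([_reml_neg2_profile(l, xr, yr, s, logdet_xtx)[0] for l in grid])
    k = int(np.argmin(crits))
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, len(grid) - 1)]
    lam = grid[k]
    if hi > lo:
        res = optimize.minimize_scalar(
            lambda l: _reml_neg2_profile(l, xr, yr, s, logdet_xtx)[0],
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": tol * max(lam, 1.0)},
        )
        if res.fun <= crits[k]:
            lam = float(res.x)
    crit, sigma_e2, _ = _reml_neg2_profile(lam, xr, yr, s, logdet_xtx)
    return lam, sigma_e2, -0.5 * crit


def fit_null_reml(phenotype: np.ndarray, kinship: KinshipMatrix) -> VarianceComponents:
    """REML variance components for ``y = 1*mu + u + e`` under K.

    One-dimensional search over lambda = sigma_u^2/sigma_e^2 on a log grid
    with local refinement, in the eigenbasis of K.
    """
    y = np.asarray(phenotype, dtype=float)
    if y.ndim != 1 or len(y) != kinship.n_ind:
        raise ValueError("phenotype length must match kinship dimension")
    if not np.all(np.isfinite(y)):
        raise ValueError("phenotype must be finite")
    if np.var(y) == 0:
        raise ValueError("phenotype has zero variance")
    s, u = kinship.eigen()
    yr = u.T @ y
    ones = np.ones((len(y), 1))
    xr = u.T @ ones
    lam, sigma_e2, loglik = _reml_optimize(xr, yr, s, ones)
    return VarianceComponents(
        sigma_u2=lam * sigma_e2, sigma_e2=sigma_e2, lambda_=lam, reml_loglik=loglik
    )


# ---------------------------------------------------------------------------
# marker scan

def _scan_weighted(
    gr: np.ndarray,
    yr: np.ndarray,
    onesr: np.ndarray,
    w: np.ndarray,
    n: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized weighted simple regression of yr on each column of gr,
    with the rotated intercept column, weights w.  Returns
    (beta, se, p, degenerate)."""
    wc0 = w * onesr
    wy = w * yr
    a00 = float(onesr @ wc0)
    b0 = float(yr @ wc0)
    ywy = float(yr @ wy)
    a01 = wc0 @ gr
    a11 = (w[:, None] * gr * gr).sum(axis=0)
    b1 = wy @ gr
    det = a00 * a11 - a01 * a01
    degenerate = det <= 1e-12 * np.maximum(a00 * a11, np.finfo(float).tiny)
    det_safe = np.where(degenerate, 1.0, det)
    beta1 = (a00 * b1 - a01 * b0) / det_safe
    beta0 = (a11 * b0 - a01 * b1) / det_safe
    rss = np.maximum(ywy - beta0 * b0 - beta1 * b1, 0.0)
    dof = n - 2
    sigma2 = rss / dof
    se = np.sqrt(np.maximum(sigma2 * a00 / det_safe, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta1 / se, 0.0)
    p = 2.0 * stats.t.sf(np.abs(t), dof)
    p = np.clip(p, _P_FLOOR, 1.0)
    beta1 = np.where(degenerate, 0.0, beta1)
    se = np.where(degenerate, np.nan, se)
    p = np.where(degenerate, 1.0, p)
    return beta1, se, p, degenerate


def scan_markers(
    panel: GenotypePanel,
    phenotype: np.ndarray,
    kinship: KinshipMatrix,
    vc: VarianceComponents | None = None,
    trait_id: str = "trait",
    per_marker_reml: bool = False,
) -> AssociationResult:
    """GLS association test of every SNP against one phenotype.

    With the default P3D approximation, variance components fixed at ``vc``
    (fitted on this phenotype under the null) define the weights and each
    marker is tested with a Wald t statistic on ``n - 2`` degrees of
    freedom, the residual scale re-estimated per marker — identical to the
    1-df F test GAPIT reports.  Monomorphic markers (collinear with the
    intercept) are flagged and given p = 1 rather than raising.

    ``per_marker_reml=True`` re-estimates lambda for every marker (exact
    but slow; orders of magnitude more REML solves).
    """
    y = np.asarray(phenotype, dtype=float)
    if np.isnan(panel.genotypes).any():
        raise ValueError("scan requires an imputed panel")
    if len(y) != panel.n_ind:
        raise ValueError("phenotype length must match panel individuals")
    if vc is None:
        vc = fit_null_reml(y, kinship)
    s, u = kinship.eigen()
    n = panel.n_ind
    yr = u.T @ y
    onesr = u.T @ np.ones(n)
    gr = u.T @ panel.genotypes

    if not per_marker_reml:
        w = 1.0 / (vc.lambda_ * s + 1.0)
        beta, se, p, degen = _scan_weighted(gr, yr, onesr, w, n)
    else:
        m = panel.n_snp
        beta = np.zeros(m)
        se = np.full(m, np.nan)
        p = np.ones(m)
        degen = np.zeros(m, dtype=bool)
        ones = np.ones((n, 1))
        for j in range(m):
            xj = panel.genotypes[:, j]
            if np.ptp(xj) == 0:
                degen[j] = True
                continue
            x = np.column_stack([ones[:, 0], xj])
            xr = np.column_stack([onesr, gr[:, j]])
            lam_j, _, _ = _reml_optimize(xr, yr, s, x, grid_points=50)
            w = 1.0 / (lam_j * s + 1.0)
            bj, sj, pj, dj = _scan_weighted(
                gr[:, j : j + 1], yr, onesr, w, n
            )
            beta[j], se[j], p[j], degen[j] = bj[0], sj[0], pj[0], dj[0]
    return AssociationResult(trait=trait_id, p_values=p, beta=beta, se=se, degenerate=degen)


def scan_trait_set(
    panel: GenotypePanel,
    traits: list[SimulatedTrait],
    kinship: KinshipMatrix,
) -> list[AssociationResult]:
    """Run the P3D scan for a whole simulated trait set.

    The genotype rotation ``U^T G`` is computed once and shared; per trait
    only the null REML fit and the vectorized weighted reductions run.
    """
    s, u = kinship.eigen()
    n = panel.n_ind
    gr = u.T @ panel.genotypes
    onesr = u.T @ np.ones(n)
    ones = np.ones((n, 1))
    results = []
    for trait in traits:
        yr = u.T @ trait.phenotypes
        lam, _, _ = _reml_optimize(onesr[:, None], yr, s, ones)
        w = 1.0 / (lam * s + 1.0)
        beta, se, p, degen = _scan_weighted(gr, yr, onesr, w, n)
        results.append(
            AssociationResult(trait=trait.name, p_values=p, beta=beta, se=se, degenerate=degen)
        )
    return results
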