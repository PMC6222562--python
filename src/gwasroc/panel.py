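"""Synthetic inbred-panel genotypes and their preprocessing.

This module generates genotype matrices that emulate an inbred diversity
panel (e.g. a maize association panel): predominantly homozygous calls, a
configurable minor-allele-frequency spectrum, optional block-structured
linkage disequilibrium, and optional missingness.  It also implements the
two preprocessing steps applied before association mapping: mean imputation
of residual missing calls and removal of SNPs below a minor-allele-frequency
threshold.

Genotypes are coded as major-allele dosage ``g in {0, 1, 2}`` (fractional
after mean imputation); missing calls are ``NaN``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GenotypePanel",
    "simulate_panel",
    "impute_missing_mean",
    "filter_maf",
    "allele_freqs",
    "minor_allele_freqs",
    "write_genotype_tsv",
    "read_genotype_tsv",
    "read_vcf",
]


class MonomorphicSNPWarning(UserWarning):
    """A SNP with major-allele frequency 1 was encountered.

    Such a SNP cannot be standardized (the standardization divides by
    ``sqrt(2p(1-p))``), so downstream code must either drop it or flag it.
    """


@dataclass
class GenotypePanel:
    """Genotypes for a panel of (typically inbred) lines.

    Parameters
    ----------
    individuals : list of str
        Line identifiers, one per row of ``genotypes``.
    genotypes : ndarray of shape (n_ind, n_snp)
        Major-allele dosage in ``[0, 2]``; ``NaN`` marks a missing call.
        Entries may be fractional after mean imputation.
    snp_ids : list of str
        SNP identifiers, one per column.
    chrom : ndarray of shape (n_snp,)
        Chromosome label per SNP (synthetic chromosomes are integers).
    pos : ndarray of shape (n_snp,)
        1-based position per SNP.
    """

    individuals: list[str]
    genotypes: np.ndarray
    snp_ids: list[str]
    chrom: np.ndarray = field(default=None)  # type: ignore[assignment]
    pos: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=float)
        if self.genotypes.ndim != 2:
            raise ValueError("genotypes must be a 2-D matrix")
        n_ind, n_snp = self.genotypes.shape
        if len(self.individuals) != n_ind:
            raise ValueError("individuals length does not match genotype rows")
        if len(self.snp_ids) != n_snp:
            raise ValueError("snp_ids length does not match genotype columns")
        if self.chrom is None:
            self.chrom = np.ones(n_snp, dtype=int)
        if self.pos is None:
            self.pos = np.arange(1, n_snp + 1, dtype=int)
        self.chrom = np.asarray(self.chrom)
        self.pos = np.asarray(self.pos)
        if len(self.chrom) != n_snp or len(self.pos) != n_snp:
            raise ValueError("chrom/pos length does not match genotype columns")
        with np.errstate(invalid="ignore"):
            out_of_range = (self.genotypes < 0) | (self.genotypes > 2)
        if np.any(out_of_range):
            raise ValueError("genotype dosages must lie in [0, 2] (or NaN)")

    @property
    def n_ind(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snp(self) -> int:
        return self.genotypes.shape[1]

    @property
    def n_missing(self) -> int:
        return int(np.isnan(self.genotypes).sum())

    @property
    def major_allele_freq(self) -> np.ndarray:
        """Per-SNP major-allele frequency ``p = max(f, 1 - f)`` (see :func:`allele_freqs`)."""
        return allele_freqs(self, warn_monomorphic=False)


def _resolve_maf_dist(
    maf_dist: object,
) -> Callable[[np.random.Generator, int], np.ndarray]:
    """Normalize the accepted minor-allele-frequency distribution specs.

    Accepted forms: ``None`` (uniform on [0.05, 0.5]), a tuple
    ``("uniform", low, high)`` or ``("beta", a, b)`` (beta rescaled to
    (0, 0.5]), a scipy frozen distribution, or a callable ``f(rng, size)``.
    """
    if maf_dist is None:
        maf_dist = ("uniform", 0.05, 0.5)
    if callable(maf_dist) and not hasattr(maf_dist, "rvs"):
        return maf_dist  # type: ignore[return-value]
    if hasattr(maf_dist, "rvs"):
        frozen = maf_dist
        return lambda rng, size: np.asarray(frozen.rvs(size=size, random_state=rng))
    if isinstance(maf_dist, (tuple, list)):
        name, *params = maf_dist
        if name == "uniform":
            low, high = params
            if not (0 < low <= high <= 0.5):
                raise ValueError("uniform maf_dist must satisfy 0 < low <= high <= 0.5")
            return lambda rng, size: rng.uniform(low, high, size=size)
        if name == "beta":
            a, b = params
            return lambda rng, size: 0.5 * rng.beta(a, b, size=size)
        raise ValueError(f"unknown maf_dist family {name!r}")
    raise TypeError("maf_dist must be None, a tuple spec, a frozen distribution or a callable")


def simulate_panel(
    n_ind: int,
    n_snp: int,
    maf_dist: object = None,
    inbreeding: float = 1.0,
    ld_block: tuple[int, float] | None = None,
    missing_rate: float = 0.0,
    seed: int | np.random.Generator | np.random.SeedSequence | None = None,
    n_chrom: int = 10,
) -> GenotypePanel:
    """Simulate a synthetic inbred-panel genotype matrix.

    Each SNP's minor-allele frequency is drawn from ``maf_dist``; alleles
    are sampled through a Gaussian copula so that, when ``ld_block =
    (block_len, rho)`` is given, consecutive SNPs within a block share a
    latent haplotype with correlation ``rho``.  With ``inbreeding`` = F an
    individual is autozygous at a locus with probability F (dosage 0 or 2);
    F = 1 yields a fully homozygous panel, the default for an inbred
    diversity panel.

    Parameters
    ----------
    n_ind, n_snp : int
        Panel dimensions (``n_ind >= 2``, ``n_snp >= 1``).
    maf_dist : spec, optional
        Minor-allele-frequency distribution on (0, 0.5]; see
        :func:`_resolve_maf_dist`.  Default uniform on [0.05, 0.5].
    inbreeding : float in [0, 1]
        Per-locus autozygosity probability.
    ld_block : (int, float), optional
        Block length and within-block latent correlation in [0, 1).
    missing_rate : float in [0, 1]
        Independent per-call missingness probability.
    seed : int, Generator or SeedSequence
        Randomness source; required for reproducibility.
    n_chrom : int
        Number of synthetic chromosomes the SNPs are split across.

    Returns
    -------
    GenotypePanel
    """
    if n_ind < 2:
        raise ValueError("n_ind must be >= 2")
    if n_snp < 1:
        raise ValueError("n_snp must be >= 1")
    if not 0 <= inbreeding <= 1:
        raise ValueError("inbreeding must lie in [0, 1]")
    if not 0 <= missing_rate <= 1:
        raise ValueError("missing_rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)

    draw = _resolve_maf_dist(maf_dist)
    q = np.asarray(draw(rng, n_snp), dtype=float)  # minor allele freq per SNP
    if q.shape != (n_snp,):
        raise ValueError("maf_dist must produce one value per SNP")
    if np.any(q <= 0) or np.any(q > 0.5):
        raise ValueError("maf_dist must be supported on (0, 0.5]")
    p_major = 1.0 - q

    if ld_block is not None:
        block_len, rho = ld_block
        block_len = int(block_len)
        if block_len < 1:
            raise ValueError("ld_block length must be >= 1")
        if not 0 <= rho < 1:
            raise ValueError("ld_block correlation must lie in [0, 1)")
    else:
        block_len, rho = 1, 0.0

    def _latent(copies: int) -> np.ndarray:
        # latent N(0,1) field with block-equicorrelation rho
        z = rng.standard_normal((copies, n_ind, n_snp))
        if rho > 0.0:
            n_blocks = -(-n_snp // block_len)
            b = rng.standard_normal((copies, n_ind, n_blocks))
            b = np.repeat(b, block_len, axis=2)[:, :, :n_snp]
            z = np.sqrt(rho) * b + np.sqrt(1.0 - rho) * z
        return z

    # allele = 1 if the copy carries the major allele
    thresh = stats.norm.ppf(p_major)
    a1, a2 = _latent(2) < thresh
    if inbreeding >= 1.0:
        dosage = 2.0 * a1
    else:
        autozygous = rng.random((n_ind, n_snp)) < inbreeding
        dosage = np.where(autozygous, 2.0 * a1, a1.astype(float) + a2)

    if missing_rate > 0.0:
        dosage = np.where(rng.random((n_ind, n_snp)) < missing_rate, np.nan, dosage)

    width = len(str(n_snp))
    snp_ids = [f"snp{i + 1:0{width}d}" for i in range(n_snp)]
    individuals = [f"line{i + 1:0{len(str(n_ind))}d}" for i in range(n_ind)]
    per_chrom = -(-n_snp // max(n_chrom, 1))
    idx = np.arange(n_snp)
    chrom = idx // per_chrom + 1
    pos = (idx % per_chrom) * 100 + 1
    return GenotypePanel(individuals, dosage, snp_ids, chrom, pos)


def impute_missing_mean(panel: GenotypePanel) -> GenotypePanel:
    """Replace missing calls by the per-SNP mean of observed dosages.

    Observed entries are untouched; imputed entries may be fractional.
    Raises if any SNP has no observed call at all.
    """
    g = panel.genotypes
    missing = np.isnan(g)
    if not missing.any():
        return panel
    n_obs = (~missing).sum(axis=0)
    if np.any(n_obs == 0):
        bad = [panel.snp_ids[j] for j in np.flatnonzero(n_obs == 0)]
        raise ValueError(f"SNP(s) with zero observed calls cannot be imputed: {bad[:5]}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        col_mean = np.nanmean(g, axis=0)
    filled = np.where(missing, col_mean[None, :], g)
    return replace(panel, genotypes=filled)


def allele_freqs(panel: GenotypePanel, warn_monomorphic: bool = True) -> np.ndarray:
    """Per-SNP major-allele frequency.

    ``p_j = max(f_j, 1 - f_j)`` with ``f_j`` the mean observed dosage of the
    counted allele divided by 2.  A monomorphic SNP yields ``p = 1`` and, by
    default, a :class:`MonomorphicSNPWarning`, since the genotype
    standardization ``(g - 2p)/sqrt(2p(1-p))`` is undefined there.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        f = np.nanmean(panel.genotypes, axis=0) / 2.0
    p = np.maximum(f, 1.0 - f)
    if warn_monomorphic and np.any(p >= 1.0):
        n_mono = int((p >= 1.0).sum())
        warnings.warn(
            f"{n_mono} monomorphic SNP(s): p = 1, standardization undefined",
            MonomorphicSNPWarning,
            stacklevel=2,
        )
    return p


def minor_allele_freqs(panel: GenotypePanel) -> np.ndarray:
    """Per-SNP empirical minor-allele frequency (``1 - p`` of :func:`allele_freqs`)."""
    return 1.0 - allele_freqs(panel, warn_monomorphic=False)


def filter_maf(panel: GenotypePanel, threshold: float = 0.02) -> GenotypePanel:
    """Remove SNPs with minor-allele frequency strictly below ``threshold``.

    The panel must be fully imputed.  Frequencies are recomputed from the
    dosage means (``f = mean dosage / 2``); SNP order is preserved.  The
    removal rule is strict ``<``, so a SNP at exactly the threshold is kept.
    """
    if not 0 <= threshold < 0.5:
        raise ValueError("threshold must lie in [0, 0.5)")
    if np.isnan(panel.genotypes).any():
        raise ValueError("filter_maf requires a fully imputed panel")
    maf = minor_allele_freqs(panel)
    keep = maf >= threshold
    if not keep.any():
        raise ValueError("MAF filter removed every SNP")
    if keep.all():
        return panel
    idx = np.flatnonzero(keep)
    return replace(
        panel,
        genotypes=panel.genotypes[:, idx],
        snp_ids=[panel.snp_ids[j] for j in idx],
        chrom=panel.chrom[idx],
        pos=panel.pos[idx],
    )


# ---------------------------------------------------------------------------
# plain-text I/O

def write_genotype_tsv(panel: GenotypePanel, geno_path, meta_path=None) -> None:
    """Write the dosage matrix (and optionally SNP metadata) as TSV.

    Genotype layout: header of SNP ids, then one row per individual
    (identifier followed by dosages, ``NA`` for missing).  Metadata columns:
    snp_id, chrom, pos, major_allele_freq.
    """
    df = pd.DataFrame(panel.genotypes, index=panel.individuals, columns=panel.snp_ids)
    df.index.name = "individual"
    df.to_csv(geno_path, sep="\t", na_rep="NA", float_format="%.10g")
    if meta_path is not None:
        meta = pd.DataFrame(
            {
                "snp_id": panel.snp_ids,
                "chrom": panel.chrom,
                "pos": panel.pos,
                "major_allele_freq": allele_freqs(panel, warn_monomorphic=False),
            }
        )
        meta.to_csv(meta_path, sep="\t", index=False, float_format="%.10g")


def read_genotype_tsv(geno_path, meta_path=None) -> GenotypePanel:
    """Read a panel written by :func:`write_genotype_tsv`."""
    df = pd.read_csv(geno_path, sep="\t", index_col=0, na_values="NA")
    chrom = pos = None
    if meta_path is not None and Path(meta_path).exists():
        meta = pd.read_csv(meta_path, sep="\t")
        chrom = meta["chrom"].to_numpy()
        pos = meta["pos"].to_numpy()
    return GenotypePanel(
        individuals=[str(i) for i in df.index],
        genotypes=df.to_numpy(dtype=float),
        snp_ids=[str(c) for c in df.columns],
        chrom=chrom,
        pos=pos,
    )


def read_vcf(path, samples: Sequence[str] | None = None) -> GenotypePanel:
    """Read diploid genotypes from a VCF into a major-allele-dosage panel.

    Uses cyvcf2 (optional dependency).  GT is first converted to ALT-allele
    dosage (phased or unphased accepted; missing GT becomes NaN); columns
    where the ALT allele is the major allele are then flipped so that every
    dosage counts copies of the major allele.
    """
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError("reading VCF requires the optional cyvcf2 dependency") from exc

    vcf = VCF(str(path), samples=list(samples) if samples is not None else None)
    individuals = list(vcf.samples)
    rows, snp_ids, chroms, poss = [], [], [], []
    for var in vcf:
        gts = np.asarray(var.genotype.array())[:, :2].astype(float)
        gts[gts < 0] = np.nan
        alt_dosage = gts.sum(axis=1)
        rows.append(alt_dosage)
        snp_ids.append(var.ID or f"{var.CHROM}_{var.POS}")
        chroms.append(var.CHROM)
        poss.append(var.POS)
    geno = np.asarray(rows).T  # n_ind x n_snp, ALT dosage
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        alt_freq = np.nanmean(geno, axis=0) / 2.0
    flip = alt_freq < 0.5  # ALT is minor: major dosage = 2 - ALT dosage
    geno[:, flip] = 2.0 - geno[:, flip]
    return GenotypePanel(individuals, geno, snp_ids, np.asarray(chroms), np.asarray(poss))
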