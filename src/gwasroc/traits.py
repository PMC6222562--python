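"""Quantitative-trait simulation at a target heritability.

A trait controlled by *n* causal loci (NCL) is built as
``y_i = sum_l w_il a_l + eps_i`` where ``w_il = (g_il - 2p)/sqrt(2p(1-p))``
is the standardized genotype, the allelic effects ``a_l`` are i.i.d.
Normal(0, effect_variance), and the noise variance is set from the target
heritability: ``sigma_eps^2 = sigma_g^2/h^2 - sigma_g^2`` with ``sigma_g^2``
the sample variance of the genetic values.  Causal loci and effects are
drawn once per NCL level, so every trait sharing an NCL shares its causal
truth set — the paired ROC comparison downstream requires this.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .panel import GenotypePanel, allele_freqs

__all__ = [
    "TraitArchitecture",
    "SimulatedTrait",
    "SimulationDesign",
    "standardize_genotypes",
    "draw_architecture",
    "residual_variance",
    "simulate_trait_set",
]


@dataclass
class TraitArchitecture:
    """Causal loci, effects and genetic values for one NCL level."""

    ncl: int
    causal_indices: np.ndarray
    effects: np.ndarray
    genetic_values: np.ndarray
    genetic_variance: float

    def __post_init__(self) -> None:
        self.causal_indices = np.asarray(self.causal_indices, dtype=int)
        self.effects = np.asarray(self.effects, dtype=float)
        self.genetic_values = np.asarray(self.genetic_values, dtype=float)
        if len(self.causal_indices) != self.ncl or len(self.effects) != self.ncl:
            raise ValueError("causal_indices and effects must have length ncl")
        if len(np.unique(self.causal_indices)) != self.ncl:
            raise ValueError("causal_indices must be unique")

    def case_labels(self, n_snp: int) -> np.ndarray:
        """Boolean per-SNP vector: True at causal loci (ROC 'cases')."""
        labels = np.zeros(n_snp, dtype=bool)
        labels[self.causal_indices] = True
        return labels


@dataclass
class SimulatedTrait:
    """One simulated phenotype vector with its design coordinates."""

    ncl: int
    h2: float
    replicate: int
    phenotypes: np.ndarray
    noise_variance: float

    def __post_init__(self) -> None:
        self.phenotypes = np.asarray(self.phenotypes, dtype=float)
        if not 0 < self.h2 <= 1:
            raise ValueError("h2 must lie in (0, 1]")
        if self.noise_variance < 0:
            raise ValueError("noise_variance must be >= 0")

    @property
    def name(self) -> str:
        return f"ncl{self.ncl}_h{self.h2:g}_rep{self.replicate}"


@dataclass
class SimulationDesign:
    """Factorial design: NCL levels x heritability levels x replicates.

    Defaults reproduce the 3 x 9 x 10 = 270-trait grid (NCL in {10, 100,
    1000}, h2 from 0.1 to 0.9 in steps of 0.1, 10 replicates, effect
    variance 10).
    """

    ncl_levels: tuple[int, ...] = (10, 100, 1000)
    h2_levels: tuple[float, ...] = field(
        default_factory=lambda: tuple(np.round(np.arange(0.1, 1.0, 0.1), 10))
    )
    replicates: int = 10
    effect_variance: float = 10.0

    def __post_init__(self) -> None:
        self.ncl_levels = tuple(int(n) for n in self.ncl_levels)
        self.h2_levels = tuple(float(h) for h in self.h2_levels)
        if any(not 0 < h <= 1 for h in self.h2_levels):
            raise ValueError("all h2 levels must lie in (0, 1]")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.effect_variance <= 0:
            raise ValueError("effect_variance must be > 0")

    @property
    def n_traits(self) -> int:
        return len(self.ncl_levels) * len(self.h2_levels) * self.replicates


def standardize_genotypes(panel: GenotypePanel, snp_index) -> np.ndarray:
    """Standardized genotype ``w = (g - 2p) / sqrt(2p(1-p))`` at given SNPs.

    ``p`` is the panel's major-allele frequency.  The divisor is the
    Hardy-Weinberg-form standard deviation, applied as written even to
    fully inbred panels (where the empirical dosage s.d. is larger).
    Monomorphic SNPs (p = 1) raise, as the divisor is zero.
    """
    snp_index = np.atleast_1d(np.asarray(snp_index, dtype=int))
    p = allele_freqs(panel, warn_monomorphic=False)[snp_index]
    if np.any(p >= 1.0):
        bad = [panel.snp_ids[j] for j in snp_index[p >= 1.0]]
        raise ValueError(f"cannot standardize monomorphic SNP(s): {bad[:5]}")
    g = panel.genotypes[:, snp_index]
    if np.isnan(g).any():
        raise ValueError("standardization requires an imputed panel")
    return (g - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))


def draw_architecture(
    panel: GenotypePanel,
    ncl: int,
    effect_variance: float = 10.0,
    seed: int | np.random.Generator | np.random.SeedSequence | None = None,
) -> TraitArchitecture:
    """Draw causal loci and allelic effects for one NCL level.

    Causal SNPs are sampled uniformly without replacement; effects are
    i.i.d. Normal(0, ``effect_variance``).  Intended to be called once per
    NCL level — every trait at that level reuses the returned architecture.
    """
    if ncl > panel.n_snp:
        raise ValueError(f"ncl={ncl} exceeds the panel's {panel.n_snp} SNPs")
    if ncl < 1:
        raise ValueError("ncl must be >= 1")
    rng = np.random.default_rng(seed)
    idx = rng.choice(panel.n_snp, size=ncl, replace=False)
    effects = rng.normal(0.0, np.sqrt(effect_variance), size=ncl)
    w = standardize_genotypes(panel, idx)
    genetic_values = w @ effects
    genetic_variance = float(np.var(genetic_values, ddof=1))
    return TraitArchitecture(ncl, idx, effects, genetic_values, genetic_variance)


def residual_variance(genetic_variance: float, h2: float) -> float:
    """Noise variance attaining a target heritability.

    ``sigma_eps^2 = sigma_g^2 / h^2 - sigma_g^2``; zero when h2 = 1.
    """
    if not 0 < h2 <= 1:
        raise ValueError("h2 must lie in (0, 1]")
    if genetic_variance < 0:
        raise ValueError("genetic_variance must be >= 0")
    return genetic_variance / h2 - genetic_variance


def simulate_trait_set(
    panel: GenotypePanel,
    design: SimulationDesign,
    seed: int | np.random.SeedSequence | None = None,
    redraw_effects_per_cell: bool = False,
) -> tuple[list[SimulatedTrait], dict[int, TraitArchitecture]]:
    """Simulate the full factorial trait set for a design.

    One architecture is drawn per NCL level (shared across h2 levels and
    replicates), then for every (ncl, h2, replicate) cell a phenotype
    ``y = genetic_values + eps`` with ``eps ~ Normal(0, sigma_eps^2)`` is
    generated; replicates at the same (ncl, h2) differ only in the noise.

    Set ``redraw_effects_per_cell`` to draw a fresh architecture for every
    (ncl, h2) combination instead; this breaks the shared causal truth set
    the paired AUC comparison relies on and exists only for sensitivity
    analysis.

    Returns
    -------
    traits : list of SimulatedTrait
        Ordered by (ncl, h2, replicate), ``design.n_traits`` in total.
    architectures : dict mapping ncl -> TraitArchitecture
        With ``redraw_effects_per_cell`` the architecture of the *last* h2
        cell per NCL is returned (the mapping is then not shared).
    """
    if np.isnan(panel.genotypes).any():
        raise ValueError("simulate_trait_set requires an imputed panel")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    arch_seed, noise_seed = ss.spawn(2)
    arch_rngs = {ncl: s for ncl, s in zip(design.ncl_levels, arch_seed.spawn(len(design.ncl_levels)))}
    noise_rng = np.random.default_rng(noise_seed)

    traits: list[SimulatedTrait] = []
    architectures: dict[int, TraitArchitecture] = {}
    for ncl in design.ncl_levels:
        arch = draw_architecture(panel, ncl, design.effect_variance, arch_rngs[ncl])
        architectures[ncl] = arch
        for h2 in design.h2_levels:
            if redraw_effects_per_cell:
                arch = draw_architecture(
                    panel, ncl, design.effect_variance, noise_rng
                )
                architectures[ncl] = arch
            sigma_eps2 = residual_variance(arch.genetic_variance, h2)
            for rep in range(1, design.replicates + 1):
                eps = noise_rng.normal(0.0, np.sqrt(sigma_eps2), size=panel.n_ind)
                traits.append(
                    SimulatedTrait(
                        ncl=ncl,
                        h2=h2,
                        replicate=rep,
                        phenotypes=arch.genetic_values + eps,
                        noise_variance=sigma_eps2,
                    )
                )
    return traits, architectures
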