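"""File-based orchestration of the full experiment.

Stages: simulate genotypes -> simulate traits -> mixed-model GWAS ->
ROC/AUC summaries -> empirical-null calibration -> real-pair prediction.
Every stage reads its inputs from, and writes its outputs to, a single
output directory as TSV tables with headers, so any stage can be rerun in
isolation from the saved tables of the previous one.  Per-stage random
seeds are derived deterministically from the master seed and the stage
name, making the whole run reproducible byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import json
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .calibrate import (
    ComparisonRecord,
    NullCalibration,
    fit_z_on_d,
    null_thresholds,
    pairwise_z,
    predict_real_pairs,
)
from .mlm import AssociationResult, scan_trait_set, vanraden_kinship
from .panel import (
    GenotypePanel,
    filter_maf,
    impute_missing_mean,
    read_genotype_tsv,
    simulate_panel,
    write_genotype_tsv,
)
from .roc import RocInput, empirical_roc, mean_roc
from .traits import (
    SimulatedTrait,
    SimulationDesign,
    TraitArchitecture,
    simulate_trait_set,
)

__all__ = [
    "RunConfig",
    "RunManifest",
    "TASSEL_PAIRS_PRINTED_D",
    "TASSEL_PAIRS_H2",
    "run_experiment",
    "write_report",
    "stage_genotypes",
    "stage_traits",
    "stage_gwas",
    "stage_roc",
    "stage_calibrate",
    "stage_predict",
]

_FLOAT_FMT = "%.10g"

# Real tassel-trait pairs (manual vs image-based measurement of the same
# character).  Two equivalent input routes: the heritability differences D
# as printed (derived from unrounded estimates), or the rounded per-trait
# heritability estimates themselves.
TASSEL_PAIRS_PRINTED_D: list[tuple[str, float]] = [
    ("TW", 0.10),
    ("BN", 0.14),
    ("TL", 0.16),
    ("SL", 0.17),
]
TASSEL_PAIRS_H2: list[tuple[str, float, float]] = [
    ("TL", 0.95, 0.79),
    ("SL", 0.95, 0.79),
    ("BN", 0.97, 0.82),
    ("TW", 0.96, 0.86),
]


@dataclass
class RunConfig:
    """Configuration of one end-to-end experiment.

    Genotypes are either simulated (the default) or read from
    ``genotype_tsv``.  ``real_pairs`` entries are either ``(name, d)`` or
    ``(name, h2_a, h2_b)`` tuples/lists.
    """

    # genotype source
    genotype_tsv: str | None = None
    n_ind: int = 500
    n_snp: int = 5000
    maf_low: float = 0.05
    maf_high: float = 0.5
    inbreeding: float = 1.0
    ld_block_len: int = 0  # 0 disables LD blocks
    ld_rho: float = 0.0
    missing_rate: float = 0.003
    maf_threshold: float = 0.02
    # trait design
    ncl_levels: tuple[int, ...] = (10, 100, 1000)
    h2_levels: tuple[float, ...] = field(
        default_factory=lambda: tuple(np.round(np.arange(0.1, 1.0, 0.1), 10))
    )
    replicates: int = 10
    effect_variance: float = 10.0
    # GWAS
    kinship_snps: int = 10_000
    # calibration / prediction
    alpha: float = 0.05
    include_null_in_fit: bool = True
    real_pairs: list = field(default_factory=lambda: list(TASSEL_PAIRS_PRINTED_D))
    # reproducibility
    seed: int = 0

    @classmethod
    def desk(cls, seed: int = 0) -> "RunConfig":
        """Desk-scale preset: 500 x 5,000 panel, NCL {10, 100}, h2 0.2-0.8,
        5 replicates; minutes on one CPU."""
        return cls(
            n_ind=500,
            n_snp=5000,
            ncl_levels=(10, 100),
            h2_levels=tuple(np.round(np.arange(0.2, 0.9, 0.1), 10)),
            replicates=5,
            seed=seed,
        )

    @classmethod
    def full(cls, seed: int = 0) -> "RunConfig":
        """The published study's scale (942 lines x 529,018 SNPs x 270
        traits).  Supported, but a cluster-sized job in time and memory."""
        return cls(n_ind=942, n_snp=529_018, seed=seed)

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "RunConfig":
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - names
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.ncl_levels = tuple(int(n) for n in cfg.ncl_levels)
        cfg.h2_levels = tuple(float(h) for h in cfg.h2_levels)
        cfg.real_pairs = [tuple(p) for p in cfg.real_pairs]
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def design(self) -> SimulationDesign:
        return SimulationDesign(
            ncl_levels=self.ncl_levels,
            h2_levels=self.h2_levels,
            replicates=self.replicates,
            effect_variance=self.effect_variance,
        )

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["ncl_levels"] = list(self.ncl_levels)
        d["h2_levels"] = list(self.h2_levels)
        d["real_pairs"] = [list(p) for p in self.real_pairs]
        return d


@dataclass
class RunManifest:
    """Provenance record of one run: config echo, seeds, versions, table
    row counts and per-stage wall-clock seconds."""

    config: dict[str, Any]
    stage_seeds: dict[str, int]
    versions: dict[str, str]
    table_rows: dict[str, int] = field(default_factory=dict)
    wall_clock: dict[str, float] = field(default_factory=dict)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")


def stage_seed(master_seed: int, stage: str) -> np.random.SeedSequence:
    """Deterministic per-stage seed: master seed combined with a hash of
    the stage name, so stages can be rerun in isolation."""
    return np.random.SeedSequence([int(master_seed), zlib.crc32(stage.encode())])


def _versions() -> dict[str, str]:
    import scipy
    import sklearn

    return {
        "gwasroc": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "scikit-learn": sklearn.__version__,
    }


def _write_tsv(df: pd.DataFrame, path: Path) -> int:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
    return len(df)


# ---------------------------------------------------------------------------
# stages (file-based; each reads the previous stage's tables)

def stage_genotypes(cfg: RunConfig, outdir: Path) -> GenotypePanel:
    """Simulate (or load) the panel, mean-impute, MAF-filter, write TSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if cfg.genotype_tsv is not None:
        panel = read_genotype_tsv(cfg.genotype_tsv)
    else:
        ld = (cfg.ld_block_len, cfg.ld_rho) if cfg.ld_block_len > 0 else None
        panel = simulate_panel(
            cfg.n_ind,
            cfg.n_snp,
            maf_dist=("uniform", cfg.maf_low, cfg.maf_high),
            inbreeding=cfg.inbreeding,
            ld_block=ld,
            missing_rate=cfg.missing_rate,
            seed=stage_seed(cfg.seed, "genotypes"),
        )
    panel = impute_missing_mean(panel)
    panel = filter_maf(panel, cfg.maf_threshold)
    write_genotype_tsv(panel, outdir / "genotypes.tsv", outdir / "snp_metadata.tsv")
    return panel


def _load_panel(outdir: Path) -> GenotypePanel:
    geno = Path(outdir) / "genotypes.tsv"
    if not geno.exists():
        raise FileNotFoundError("genotypes.tsv missing: run the genotypes stage first")
    return read_genotype_tsv(geno, Path(outdir) / "snp_metadata.tsv")


def stage_traits(
    cfg: RunConfig, outdir: Path
) -> tuple[list[SimulatedTrait], dict[int, TraitArchitecture]]:
    """Simulate the factorial trait set; write phenotype/architecture TSVs."""
    outdir = Path(outdir)
    panel = _load_panel(outdir)
    traits, archs = simulate_trait_set(
        panel, cfg.design(), seed=stage_seed(cfg.seed, "traits")
    )
    pheno = pd.DataFrame(
        {t.name: t.phenotypes for t in traits}, index=panel.individuals
    )
    pheno.index.name = "individual"
    pheno.to_csv(outdir / "phenotypes.tsv", sep="\t", float_format=_FLOAT_FMT)
    meta = pd.DataFrame(
        [
            {
                "trait": t.name,
                "ncl": t.ncl,
                "h2": t.h2,
                "replicate": t.replicate,
                "noise_variance": t.noise_variance,
            }
            for t in traits
        ]
    )
    _write_tsv(meta, outdir / "traits.tsv")
    arch_rows = []
    for ncl, arch in archs.items():
        for j, (idx, eff) in enumerate(zip(arch.causal_indices, arch.effects)):
            arch_rows.append(
                {
                    "ncl": ncl,
                    "snp_index": int(idx),
                    "snp_id": panel.snp_ids[int(idx)],
                    "effect": eff,
                }
            )
    _write_tsv(pd.DataFrame(arch_rows), outdir / "architectures.tsv")
    return traits, archs


def _load_traits(outdir: Path) -> list[SimulatedTrait]:
    outdir = Path(outdir)
    meta_path = outdir / "traits.tsv"
    if not meta_path.exists():
        raise FileNotFoundError("traits.tsv missing: run the traits stage first")
    meta = pd.read_csv(meta_path, sep="\t")
    pheno = pd.read_csv(outdir / "phenotypes.tsv", sep="\t", index_col=0)
    return [
        SimulatedTrait(
            ncl=int(row.ncl),
            h2=float(row.h2),
            replicate=int(row.replicate),
            phenotypes=pheno[row.trait].to_numpy(),
            noise_variance=float(row.noise_variance),
        )
        for row in meta.itertuples()
    ]


def _load_architectures(outdir: Path, panel: GenotypePanel) -> dict[int, TraitArchitecture]:
    arch_path = Path(outdir) / "architectures.tsv"
    if not arch_path.exists():
        raise FileNotFoundError("architectures.tsv missing: run the traits stage first")
    df = pd.read_csv(arch_path, sep="\t")
    archs = {}
    from .traits import standardize_genotypes

    for ncl, grp in df.groupby("ncl"):
        idx = grp["snp_index"].to_numpy()
        effects = grp["effect"].to_numpy()
        w = standardize_genotypes(panel, idx)
        gv = w @ effects
        archs[int(ncl)] = TraitArchitecture(
            ncl=int(ncl),
            causal_indices=idx,
            effects=effects,
            genetic_values=gv,
            genetic_variance=float(np.var(gv, ddof=1)),
        )
    return archs


def stage_gwas(cfg: RunConfig, outdir: Path) -> list[AssociationResult]:
    """Kinship once, then the P3D mixed-model scan for every trait."""
    outdir = Path(outdir)
    panel = _load_panel(outdir)
    traits = _load_traits(outdir)
    kin = vanraden_kinship(
        panel, cfg.kinship_snps, seed=stage_seed(cfg.seed, "kinship")
    )
    kdf = pd.DataFrame(kin.values, index=panel.individuals, columns=panel.individuals)
    kdf.index.name = "individual"
    kdf.to_csv(outdir / "kinship.tsv", sep="\t", float_format=_FLOAT_FMT)
    results = scan_trait_set(panel, traits, kin)
    gwas_dir = outdir / "gwas"
    gwas_dir.mkdir(exist_ok=True)
    for res in results:
        df = pd.DataFrame(
            {
                "snp_id": panel.snp_ids,
                "chrom": panel.chrom,
                "pos": panel.pos,
                "beta": res.beta,
                "se": res.se,
                "p_value": res.p_values,
                "neg_log10_p": res.neg_log10_p,
                "degenerate": res.degenerate.astype(int),
            }
        )
        _write_tsv(df, gwas_dir / f"{res.trait}.tsv")
    return results


def _load_gwas(outdir: Path, trait_names: Sequence[str]) -> list[AssociationResult]:
    gwas_dir = Path(outdir) / "gwas"
    if not gwas_dir.is_dir():
        raise FileNotFoundError("gwas/ missing: run the gwas stage first")
    results = []
    for name in trait_names:
        df = pd.read_csv(gwas_dir / f"{name}.tsv", sep="\t")
        results.append(
            AssociationResult(
                trait=name,
                p_values=df["p_value"].to_numpy(),
                beta=df["beta"].to_numpy(),
                se=df["se"].to_numpy(),
                degenerate=df["degenerate"].to_numpy(dtype=bool),
            )
        )
    return results


def stage_roc(cfg: RunConfig, outdir: Path) -> pd.DataFrame:
    """Per-trait AUCs and per-(NCL, h2) mean ROC curves."""
    outdir = Path(outdir)
    panel = _load_panel(outdir)
    traits = _load_traits(outdir)
    archs = _load_architectures(outdir, panel)
    results = _load_gwas(outdir, [t.name for t in traits])
    rows, mean_rows = [], []
    curves_by_cell: dict[tuple[int, float], list] = {}
    for trait, res in zip(traits, results):
        labels = archs[trait.ncl].case_labels(res.n_snp)
        inp = RocInput(scores=res.neg_log10_p, labels=labels)
        curve = empirical_roc(inp)
        rows.append(
            {
                "trait": trait.name,
                "ncl": trait.ncl,
                "h2": trait.h2,
                "replicate": trait.replicate,
                "auc": curve.auc,
                "m": inp.m,
                "n_ctl": inp.n_ctl,
            }
        )
        curves_by_cell.setdefault((trait.ncl, trait.h2), []).append(curve)
    for (ncl, h2), curves in sorted(curves_by_cell.items()):
        mc = mean_roc(curves)
        for spec, sens in zip(mc.specificity, mc.sensitivity):
            mean_rows.append(
                {"ncl": ncl, "h2": h2, "specificity": spec, "mean_sensitivity": sens}
            )
    auc_df = pd.DataFrame(rows)
    _write_tsv(auc_df, outdir / "auc_summary.tsv")
    _write_tsv(pd.DataFrame(mean_rows), outdir / "mean_roc.tsv")
    return auc_df


def stage_calibrate(cfg: RunConfig, outdir: Path) -> pd.DataFrame:
    """All same-NCL pairwise DeLong Z values plus empirical-null thresholds."""
    outdir = Path(outdir)
    panel = _load_panel(outdir)
    traits = _load_traits(outdir)
    archs = _load_architectures(outdir, panel)
    results = _load_gwas(outdir, [t.name for t in traits])
    comp_rows, calib_rows = [], []
    for ncl in sorted({t.ncl for t in traits}):
        sub = [(t, r) for t, r in zip(traits, results) if t.ncl == ncl]
        records = pairwise_z([r for _, r in sub], [t for t, _ in sub], archs[ncl])
        for r in records:
            comp_rows.append(dataclasses.asdict(r))
        calib = null_thresholds(records, alpha=cfg.alpha)
        calib_rows.append(
            {
                "ncl": ncl,
                "lower": calib.lower,
                "upper": calib.upper,
                "n_null": len(calib.null_z),
                "alpha": cfg.alpha,
            }
        )
    comp_df = pd.DataFrame(comp_rows)
    comp_df["degenerate"] = comp_df["degenerate"].astype(int)
    _write_tsv(comp_df, outdir / "comparisons.tsv")
    _write_tsv(pd.DataFrame(calib_rows), outdir / "calibration.tsv")
    return comp_df


def _records_from_df(df: pd.DataFrame) -> list[ComparisonRecord]:
    return [
        ComparisonRecord(
            ncl=int(r.ncl),
            trait_a=r.trait_a,
            trait_b=r.trait_b,
            h2_a=float(r.h2_a),
            h2_b=float(r.h2_b),
            d=float(r.d),
            auc_a=float(r.auc_a),
            auc_b=float(r.auc_b),
            z=float(r.z),
            degenerate=bool(r.degenerate),
        )
        for r in df.itertuples()
    ]


def stage_predict(cfg: RunConfig, outdir: Path) -> pd.DataFrame | None:
    """Z ~ D regression per NCL and verdicts for the real trait pairs."""
    outdir = Path(outdir)
    comp_path = outdir / "comparisons.tsv"
    if not comp_path.exists():
        raise FileNotFoundError("comparisons.tsv missing: run the calibrate stage first")
    if not cfg.real_pairs:
        return None
    comp_df = pd.read_csv(comp_path, sep="\t")
    rows = []
    for ncl, grp in comp_df.groupby("ncl"):
        records = _records_from_df(grp)
        reg = fit_z_on_d(records, include_null=cfg.include_null_in_fit)
        calib = null_thresholds(records, alpha=cfg.alpha)
        for pred in predict_real_pairs(reg, calib, cfg.real_pairs):
            rows.append(
                {
                    "character": pred.character,
                    "d": pred.d,
                    "ncl": int(ncl),
                    "predicted_z": pred.predicted_z,
                    "lower": pred.lower,
                    "upper": pred.upper,
                    "significant": int(pred.significant),
                }
            )
    pred_df = pd.DataFrame(rows)
    _write_tsv(pred_df, outdir / "predictions.tsv")
    return pred_df


# ---------------------------------------------------------------------------
# orchestration

_STAGES = (
    ("genotypes", stage_genotypes),
    ("traits", stage_traits),
    ("gwas", stage_gwas),
    ("roc", stage_roc),
    ("calibrate", stage_calibrate),
    ("predict", stage_predict),
)

_TABLES = (
    "genotypes.tsv",
    "snp_metadata.tsv",
    "phenotypes.tsv",
    "traits.tsv",
    "architectures.tsv",
    "kinship.tsv",
    "auc_summary.tsv",
    "mean_roc.tsv",
    "comparisons.tsv",
    "calibration.tsv",
    "predictions.tsv",
)


def run_experiment(cfg: RunConfig, outdir) -> RunManifest:
    """Run every stage in order and write ``manifest.json`` and a report.

    Deterministic given ``cfg.seed``: rerunning with the same config and
    seed reproduces byte-identical tables.  A stage failure aborts with an
    error naming the stage; tables written so far remain on disk.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config=cfg.to_dict(),
        stage_seeds={
            name: int(stage_seed(cfg.seed, name).entropy[1]) for name, _ in _STAGES
        },
        versions=_versions(),
    )
    for name, fn in _STAGES:
        t0 = time.perf_counter()
        try:
            fn(cfg, outdir)
        except Exception as exc:
            manifest.wall_clock[name] = time.perf_counter() - t0
            manifest.write(outdir / "manifest.json")
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        manifest.wall_clock[name] = round(time.perf_counter() - t0, 3)
    for table in _TABLES:
        path = outdir / table
        if path.exists():
            with open(path) as fh:
                manifest.table_rows[table] = sum(1 for _ in fh) - 1  # minus header
    manifest.write(outdir / "manifest.json")
    write_report(outdir)
    return manifest


def write_report(outdir) -> Path:
    """Summarize a completed run as a Markdown report.

    Emits the mean AUC per (NCL, h2) cell, the fitted Z ~ D lines with
    their empirical thresholds, and — when real pairs were configured —
    the prediction verdicts.  Raises if a required table is missing,
    naming the absent stage.
    """
    outdir = Path(outdir)
    needed = {
        "auc_summary.tsv": "roc",
        "comparisons.tsv": "calibrate",
        "calibration.tsv": "calibrate",
    }
    for table, stage in needed.items():
        if not (outdir / table).exists():
            raise FileNotFoundError(f"{table} missing: run the {stage!r} stage first")
    auc = pd.read_csv(outdir / "auc_summary.tsv", sep="\t")
    comp = pd.read_csv(outdir / "comparisons.tsv", sep="\t")
    calib = pd.read_csv(outdir / "calibration.tsv", sep="\t")

    lines = ["# GWAS heritability-comparison run report", ""]
    lines.append("## Mean AUC by NCL and heritability")
    lines.append("")
    cell = auc.groupby(["ncl", "h2"])["auc"].agg(["mean", "std", "count"]).reset_index()
    lines.append("| NCL | h2 | mean AUC | sd | replicates |")
    lines.append("|---:|---:|---:|---:|---:|")
    for r in cell.itertuples():
        lines.append(
            f"| {r.ncl} | {r.h2:g} | {r.mean:.4f} | {r.std:.4f} | {int(r.count)} |"
        )
    lines.append("")
    lines.append("## Z ~ D regression and empirical null thresholds")
    lines.append("")
    lines.append("| NCL | slope | intercept | n pairs | null lower | null upper | n null |")
    lines.append("|---:|---:|---:|---:|---:|---:|---:|")
    for ncl, grp in comp.groupby("ncl"):
        reg = fit_z_on_d(_records_from_df(grp))
        row = calib[calib["ncl"] == ncl].iloc[0]
        lines.append(
            f"| {ncl} | {reg.slope:.4f} | {reg.intercept:.4f} | {reg.n_records} "
            f"| {row.lower:.4f} | {row.upper:.4f} | {int(row.n_null)} |"
        )
    lines.append("")
    pred_path = outdir / "predictions.tsv"
    if pred_path.exists():
        pred = pd.read_csv(pred_path, sep="\t")
        lines.append("## Real trait-pair predictions")
        lines.append("")
        lines.append("| character | D | NCL | predicted Z | thresholds | significant |")
        lines.append("|---|---:|---:|---:|---|---|")
        for r in pred.itertuples():
            verdict = "yes" if r.significant else "no"
            lines.append(
                f"| {r.character} | {r.d:g} | {r.ncl} | {r.predicted_z:.4f} "
                f"| ({r.lower:.3f}, {r.upper:.3f}) | {verdict} |"
            )
        lines.append("")
    path = outdir / "report.md"
    path.write_text("\n".join(lines))
    return path
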