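"""Empirical-null calibration of the paired-AUC Z statistic and the
Z-versus-heritability-difference regression.

GWAS ``-log10(p)`` scores violate the independence assumptions behind the
normal reference distribution of the DeLong Z, so significance is decided
against an empirical null instead: comparisons between traits simulated
with *identical* parameters (heritability difference D = 0) should not
differ, and the 2.5th/97.5th percentiles of their Z values are the alpha =
0.05 thresholds.  A per-NCL linear regression of Z on D then predicts
whether a pair of real measurements of one character — e.g. a manual and
an image-based measurement with different heritabilities — is expected to
yield significantly different GWAS results.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np

from .mlm import AssociationResult
from .roc import RocInput, delong_components, delong_from_components
from .traits import SimulatedTrait, TraitArchitecture

__all__ = [
    "ComparisonRecord",
    "NullCalibration",
    "ZRegression",
    "PairPrediction",
    "pairwise_z",
    "null_thresholds",
    "fit_z_on_d",
    "predict_real_pairs",
]


@dataclass
class ComparisonRecord:
    """One paired-AUC test between two traits sharing an NCL level.

    Orientation: ``trait_a`` is the higher-h2 member (ties broken by lower
    replicate index), and ``z`` is the DeLong statistic a-minus-b, so that
    a power *advantage* of the higher-heritability trait gives z > 0.
    """

    ncl: int
    trait_a: str
    trait_b: str
    h2_a: float
    h2_b: float
    d: float
    auc_a: float
    auc_b: float
    z: float
    degenerate: bool = False


@dataclass
class NullCalibration:
    """Empirical null of Z from D = 0 comparisons, with alpha thresholds."""

    ncl: int
    null_z: np.ndarray
    alpha: float = 0.05
    lower: float = field(init=False)
    upper: float = field(init=False)

    def __post_init__(self) -> None:
        self.null_z = np.asarray(self.null_z, dtype=float)
        if len(self.null_z) == 0:
            raise ValueError("empty null set")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if len(self.null_z) < 40:
            warnings.warn(
                f"only {len(self.null_z)} null comparisons; percentile "
                "thresholds will be noisy",
                stacklevel=2,
            )
        # linear-interpolation percentile definition (numpy default)
        self.lower = float(np.percentile(self.null_z, 100 * self.alpha / 2))
        self.upper = float(np.percentile(self.null_z, 100 * (1 - self.alpha / 2)))

    def is_significant(self, z: float | np.ndarray) -> np.ndarray | bool:
        """True when z falls outside the open interval (lower, upper)."""
        z = np.asarray(z, dtype=float)
        out = (z < self.lower) | (z > self.upper)
        return bool(out) if out.ndim == 0 else out


@dataclass
class ZRegression:
    """Ordinary-least-squares fit of Z on D for one NCL level."""

    ncl: int
    slope: float
    intercept: float
    n_records: int

    def predict(self, d: float | np.ndarray) -> float | np.ndarray:
        pred = self.intercept + self.slope * np.asarray(d, dtype=float)
        return float(pred) if pred.ndim == 0 else pred


@dataclass
class PairPrediction:
    """Predicted Z and significance verdict for one real trait pair."""

    character: str
    ncl: int
    d: float
    predicted_z: float
    lower: float
    upper: float
    significant: bool


def pairwise_z(
    results: Sequence[AssociationResult],
    traits: Sequence[SimulatedTrait],
    architecture: TraitArchitecture,
) -> list[ComparisonRecord]:
    """All C(T, 2) paired-AUC comparisons among traits of one NCL level.

    Every pair is compared exactly once, oriented higher-h2 minus lower-h2
    (equal h2: lower replicate index first).  Only traits sharing the NCL —
    hence the same causal truth set — may be compared, mirroring the design
    in which two measurements of a character share their causal loci.

    DeLong structural components are computed once per trait, so the
    all-pairs sweep costs O(T * N log N + T^2 * N).
    """
    if len(results) != len(traits):
        raise ValueError("results and traits must be parallel sequences")
    ncls = {t.ncl for t in traits}
    if len(ncls) != 1:
        raise ValueError(f"pairwise_z requires a single NCL level, got {sorted(ncls)}")
    (ncl,) = ncls
    if architecture.ncl != ncl:
        raise ValueError("architecture NCL does not match the traits")
    n_snp = results[0].n_snp
    labels = architecture.case_labels(n_snp)
    comps = [
        delong_components(RocInput(scores=res.neg_log10_p, labels=labels))
        for res in results
    ]
    # orientation sort key: higher h2 first, then lower replicate
    order = sorted(
        range(len(traits)), key=lambda i: (-traits[i].h2, traits[i].replicate)
    )
    records = []
    for ia, ib in combinations(order, 2):
        ta, tb = traits[ia], traits[ib]
        test = delong_from_components(comps[ia], comps[ib])
        records.append(
            ComparisonRecord(
                ncl=ncl,
                trait_a=ta.name,
                trait_b=tb.name,
                h2_a=ta.h2,
                h2_b=tb.h2,
                d=abs(ta.h2 - tb.h2),
                auc_a=test.auc1,
                auc_b=test.auc2,
                z=test.z,
                degenerate=test.degenerate,
            )
        )
    return records


def null_thresholds(
    records: Sequence[ComparisonRecord], alpha: float = 0.05
) -> NullCalibration:
    """Significance thresholds from the D = 0 comparisons.

    Thresholds are the empirical ``alpha/2`` and ``1 - alpha/2``
    percentiles (linear interpolation between order statistics) of the Z
    values of all records with d = 0.  Records with d > 0 are ignored, so
    the full record list may be passed.
    """
    null_z = np.array([r.z for r in records if r.d == 0.0])
    if len(null_z) == 0:
        raise ValueError("no D = 0 comparisons to calibrate on")
    ncls = {r.ncl for r in records}
    (ncl,) = ncls if len(ncls) == 1 else (min(ncls),)
    return NullCalibration(ncl=ncl, null_z=null_z, alpha=alpha)


def fit_z_on_d(
    records: Sequence[ComparisonRecord], include_null: bool = True
) -> ZRegression:
    """OLS regression of Z on D for one NCL level (intercept included).

    By default all records are pooled, including the D = 0 pairs; set
    ``include_null=False`` to fit on D > 0 records only.
    """
    recs = [r for r in records if include_null or r.d > 0.0]
    ncls = {r.ncl for r in recs}
    if len(ncls) != 1:
        raise ValueError("fit_z_on_d requires records from a single NCL level")
    d = np.array([r.d for r in recs])
    z = np.array([r.z for r in recs])
    if len(np.unique(d)) < 2:
        raise ValueError("need at least two distinct D values to fit a line")
    slope, intercept = np.polyfit(d, z, 1)
    if not (np.isfinite(slope) and np.isfinite(intercept)):
        raise ValueError("regression produced non-finite coefficients")
    return ZRegression(ncl=ncls.pop(), slope=float(slope), intercept=float(intercept),
                       n_records=len(recs))


def predict_real_pairs(
    regression: ZRegression,
    null: NullCalibration,
    pairs: Sequence[tuple],
) -> list[PairPrediction]:
    """Predict Z and a significance verdict for real trait pairs.

    Each pair is either ``(character, h2_a, h2_b)`` — D is computed as
    ``|h2_a - h2_b|`` — or ``(character, d)`` with the heritability
    difference supplied directly (e.g. when it was derived from unrounded
    heritability estimates).  A pair is flagged significant when its
    predicted Z falls outside the calibration's (lower, upper) interval.
    """
    preds = []
    for pair in pairs:
        if len(pair) == 3:
            name, h2_a, h2_b = pair
            for h in (h2_a, h2_b):
                if not 0 < h <= 1:
                    raise ValueError(f"heritability {h} for {name!r} not in (0, 1]")
            d = abs(float(h2_a) - float(h2_b))
        elif len(pair) == 2:
            name, d = pair
            d = float(d)
            if d < 0:
                raise ValueError("heritability difference D must be >= 0")
        else:
            raise ValueError("pair must be (name, h2_a, h2_b) or (name, d)")
        z = regression.predict(d)
        preds.append(
            PairPrediction(
                character=str(name),
                ncl=regression.ncl,
                d=d,
                predicted_z=z,
                lower=null.lower,
                upper=null.upper,
                significant=bool(null.is_significant(z)),
            )
        )
    return preds
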