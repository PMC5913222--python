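"""Efficiency-corrected relative quantification of qPCR data.

The chain implemented here goes from raw technical-replicate Cq values to
per-sample relative expression ratios:

1. a dilution standard curve is fit per gene and converted to an
   amplification efficiency ``E = 10**(-1/slope)``;
2. technical replicates are collapsed to a mean Cq, with a strict
   duplicate-SD quality filter (default SD < 0.05 cycles);
3. the efficiency-corrected ratio of a target gene against a reference
   gene is computed as ``R = E_t**dCq_t / E_r**dCq_r`` with
   ``dCq = Cq(calibrator) - Cq(sample)``;
4. normalized values more than ``z`` sample SDs from the mean (default
   z = 1.96) are removed in a single pass.

Ratios are computed in log2 space internally and exported on the linear
scale.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np
from scipy import stats

from .io import (
    CqRecord,
    InsufficientDataError,
    QpcrDataset,
    RefnormError,
    ValidationError,
)

logger = logging.getLogger(__name__)

DEFAULT_QC_SD = 0.05      # cycles, duplicate-SD acceptance threshold
DEFAULT_OUTLIER_Z = 1.96  # SD multiplier for post-normalization outlier removal
R_SQUARED_ACCEPT = 0.99   # standard curves below this draw a warning
EFFICIENCY_MAX = 2.2      # E > 2.2 implies a pathological curve (perfect doubling is 2)


class FitError(RefnormError):
    """Standard-curve fit is geometrically invalid (non-negative slope)."""


class InvalidEfficiencyError(RefnormError):
    """Amplification efficiency outside the meaningful range (1, EFFICIENCY_MAX]."""


class StandardCurveWarning(UserWarning):
    pass


# ---------------------------------------------------------------------------
# Standard curves
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StandardCurve:
    gene_id: str
    points: tuple[tuple[float, float], ...]
    slope: float
    intercept: float
    r_squared: float
    efficiency: float


def fit_standard_curve(
    gene_id: str, points: Sequence[tuple[float, float]]
) -> StandardCurve:
    """Fit Cq against log10 input by ordinary least squares.

    The amplification efficiency is ``E = 10**(-1/slope)``; a perfect
    doubling assay has slope -1/log10(2) = -3.3219 and E = 2.  A fit with
    r^2 <= 0.99 is returned with a :class:`StandardCurveWarning` (assay
    acceptance convention), never rejected outright.
    """
    if len(points) < 3 or len({x for x, _ in points}) < 3:
        raise InsufficientDataError(
            f"standard curve for {gene_id!r} needs >=3 distinct dilution levels"
        )
    x = np.array([p[0] for p in points], dtype=float)
    y = np.array([p[1] for p in points], dtype=float)
    fit = stats.linregress(x, y)
    if fit.slope >= 0:
        raise FitError(
            f"standard curve for {gene_id!r} has non-negative slope {fit.slope:.4f}; "
            "more input must lower Cq"
        )
    efficiency = 10.0 ** (-1.0 / fit.slope)
    r_squared = float(fit.rvalue**2)
    if r_squared <= R_SQUARED_ACCEPT:
        warnings.warn(
            f"standard curve for {gene_id!r}: r^2 = {r_squared:.4f} does not exceed "
            f"the {R_SQUARED_ACCEPT} acceptance level",
            StandardCurveWarning,
            stacklevel=2,
        )
    if not (1.0 < efficiency <= EFFICIENCY_MAX):
        warnings.warn(
            f"standard curve for {gene_id!r}: efficiency {efficiency:.3f} outside "
            f"(1, {EFFICIENCY_MAX}]",
            StandardCurveWarning,
            stacklevel=2,
        )
    return StandardCurve(
        gene_id=gene_id,
        points=tuple((float(a), float(b)) for a, b in points),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=r_squared,
        efficiency=float(efficiency),
    )


# ---------------------------------------------------------------------------
# Replicate QC
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CollapsedCq:
    sample_id: str
    gene_id: str
    group_label: str
    mean_cq: float
    replicate_sd: float
    passed_qc: bool


def collapse_replicates(record: CqRecord, sd_threshold: float = DEFAULT_QC_SD) -> CollapsedCq:
    """Collapse technical replicates to a mean Cq with a strict SD filter.

    ``passed_qc`` is true iff the sample SD (n-1 denominator) of the
    replicates is strictly below ``sd_threshold``.  A single replicate has
    SD 0 and passes, with a logged note.
    """
    reps = np.asarray(record.replicate_cq, dtype=float)
    mean_cq = float(reps.mean())
    if reps.size == 1:
        sd = 0.0
        logger.info(
            "collapse_replicates: sample %s gene %s has a single replicate; SD set to 0",
            record.sample_id, record.gene_id,
        )
    else:
        sd = float(reps.std(ddof=1))
    return CollapsedCq(
        sample_id=record.sample_id,
        gene_id=record.gene_id,
        group_label=record.group_label,
        mean_cq=mean_cq,
        replicate_sd=sd,
        passed_qc=bool(sd < sd_threshold),
    )


# ---------------------------------------------------------------------------
# Pfaffl ratio
# ---------------------------------------------------------------------------

def _check_efficiency(e: float, label: str) -> None:
    if not math.isfinite(e) or e <= 1.0:
        raise InvalidEfficiencyError(f"{label} efficiency {e} must exceed 1")
    if e > EFFICIENCY_MAX:
        warnings.warn(
            f"{label} efficiency {e:.3f} exceeds {EFFICIENCY_MAX}",
            StandardCurveWarning,
            stacklevel=3,
        )


def log2_pfaffl_ratio(
    cq_target_sample: float,
    cq_target_calibrator: float,
    e_target: float,
    cq_ref_sample: float,
    cq_ref_calibrator: float,
    e_ref: float,
) -> float:
    """Efficiency-corrected relative expression on the log2 scale.

    log2 R = dCq_t * log2(E_t) - dCq_r * log2(E_r),  dCq = calibrator - sample.
    """
    _check_efficiency(e_target, "target")
    _check_efficiency(e_ref, "reference")
    for cq in (cq_target_sample, cq_target_calibrator, cq_ref_sample, cq_ref_calibrator):
        if not math.isfinite(cq):
            raise ValidationError(f"non-finite Cq value {cq}")
    dcq_t = cq_target_calibrator - cq_target_sample
    dcq_r = cq_ref_calibrator - cq_ref_sample
    return dcq_t * math.log2(e_target) - dcq_r * math.log2(e_ref)


def pfaffl_ratio(
    cq_target_sample: float,
    cq_target_calibrator: float,
    e_target: float,
    cq_ref_sample: float,
    cq_ref_calibrator: float,
    e_ref: float,
) -> float:
    """Linear-scale efficiency-corrected ratio R = E_t**dCq_t / E_r**dCq_r."""
    return 2.0 ** log2_pfaffl_ratio(
        cq_target_sample, cq_target_calibrator, e_target,
        cq_ref_sample, cq_ref_calibrator, e_ref,
    )


# ---------------------------------------------------------------------------
# Dataset-level normalization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NormalizedExpression:
    sample_id: str
    group_label: str
    target_gene: str
    reference_gene: str
    ratio: float

    @property
    def log2_ratio(self) -> float:
        return math.log2(self.ratio)


@dataclass(frozen=True)
class Exclusion:
    sample_id: str
    gene_id: str
    reason: str


@dataclass
class NormalizationResult(Sequence):
    """Per-sample normalized ratios plus an account of QC exclusions."""

    values: list[NormalizedExpression]
    exclusions: list[Exclusion] = field(default_factory=list)

    def __iter__(self) -> Iterator[NormalizedExpression]:
        return iter(self.values)

    def __len__(self) -> int:
        return len(self.values)

    def __getitem__(self, i):  # Sequence protocol
        return self.values[i]

    def ratios(self) -> np.ndarray:
        return np.array([v.ratio for v in self.values])

    def group_labels(self) -> list[str]:
        return [v.group_label for v in self.values]


def _calibrator_cq(
    collapsed: Mapping[str, CollapsedCq],
    rule: str,
    control_label: str,
    calibrator_sample: str | None,
) -> float:
    passing = [c for c in collapsed.values() if c.passed_qc]
    if rule == "control_mean":
        pool = [c.mean_cq for c in passing if c.group_label == control_label]
    elif rule == "grand_mean":
        pool = [c.mean_cq for c in passing]
    elif rule == "sample":
        if calibrator_sample is None:
            raise ValidationError("calibrator_rule 'sample' requires calibrator_sample")
        if calibrator_sample not in collapsed:
            raise ValidationError(f"calibrator sample {calibrator_sample!r} not found")
        return collapsed[calibrator_sample].mean_cq
    else:
        raise ValidationError(f"unknown calibrator rule {rule!r}")
    if not pool:
        raise InsufficientDataError("no QC-passing samples available for calibrator")
    return float(np.mean(pool))


def normalize_dataset(
    ds: QpcrDataset,
    target: str,
    reference: str,
    efficiencies: Mapping[str, float] | None = None,
    *,
    control_label: str | None = None,
    calibrator_rule: str = "control_mean",
    calibrator_sample: str | None = None,
    sd_threshold: float = DEFAULT_QC_SD,
    allow_self: bool = False,
) -> NormalizationResult:
    """Pfaffl-normalize ``target`` against ``reference`` across a dataset.

    The per-gene calibrator Cq defaults to the mean of the QC-passing
    control-group mean Cq values for that gene, so control-group ratios
    centre near 1.  Samples whose target or reference record fails the
    duplicate-SD filter are excluded with a recorded reason.  Genes with no
    supplied efficiency default to E = 2 (perfect doubling), logged.
    """
    if target == reference and not allow_self:
        raise ValidationError(
            "target and reference are identical; pass allow_self=True for identity checks"
        )
    genes = set(ds.genes)
    for g in (target, reference):
        if g not in genes:
            raise ValidationError(f"gene {g!r} not present in dataset")
    control = control_label or ds.control_label
    if control is None:
        raise ValidationError(
            "control group label required (set on the dataset or pass control_label)"
        )
    if control not in ds.groups:
        raise ValidationError(f"control label {control!r} not among groups {ds.groups}")

    efficiencies = dict(efficiencies or {})
    for g in (target, reference):
        if g not in efficiencies:
            logger.info("normalize_dataset: no efficiency for %s; defaulting to 2.0", g)
            efficiencies[g] = 2.0

    collapsed: dict[str, dict[str, CollapsedCq]] = {}
    for gene in (target, reference):
        collapsed[gene] = {
            r.sample_id: collapse_replicates(r, sd_threshold)
            for r in ds.records_for(gene)
        }

    cal = {
        gene: _calibrator_cq(collapsed[gene], calibrator_rule, control, calibrator_sample)
        for gene in (target, reference)
    }

    values: list[NormalizedExpression] = []
    exclusions: list[Exclusion] = []
    for sample in ds.samples:
        ct = collapsed[target].get(sample)
        cr = collapsed[reference].get(sample)
        if ct is None or cr is None:
            exclusions.append(Exclusion(sample, target if ct is None else reference,
                                        "missing record"))
            continue
        failed = [c for c in (ct, cr) if not c.passed_qc]
        if failed:
            for c in failed:
                exclusions.append(Exclusion(
                    sample, c.gene_id,
                    f"replicate SD {c.replicate_sd:.4f} >= {sd_threshold}"))
                logger.info("normalize_dataset: excluding %s (%s replicate SD %.4f)",
                            sample, c.gene_id, c.replicate_sd)
            continue
        log2r = log2_pfaffl_ratio(
            ct.mean_cq, cal[target], efficiencies[target],
            cr.mean_cq, cal[reference], efficiencies[reference],
        )
        values.append(NormalizedExpression(
            sample_id=sample,
            group_label=ct.group_label,
            target_gene=target,
            reference_gene=reference,
            ratio=2.0 ** log2r,
        ))

    for label in ds.groups:
        n = sum(1 for v in values if v.group_label == label)
        if n < 2:
            raise InsufficientDataError(
                f"fewer than 2 QC-passing samples remain in group {label!r}"
            )
    return NormalizationResult(values=values, exclusions=exclusions)


# ---------------------------------------------------------------------------
# Outlier removal
# ---------------------------------------------------------------------------

def remove_outliers(
    values: Sequence[float],
    z: float = DEFAULT_OUTLIER_Z,
    groups: Sequence[str] | None = None,
) -> tuple[list[float], list[int]]:
    """Single-pass removal of values > z sample SDs from the mean.

    The mean and SD are computed once over all candidate values (no
    re-iteration).  By default the pass is pooled across groups; passing
    ``groups`` applies the rule within each group separately.  Returns the
    kept values and the removed indices (into the input order).
    """
    vals = np.asarray(values, dtype=float)
    if vals.size < 3:
        raise InsufficientDataError("outlier removal needs at least 3 values")
    if groups is not None:
        if len(groups) != vals.size:
            raise ValidationError("groups must align with values")
        removed: list[int] = []
        for label in sorted(set(groups)):
            idx = [i for i, g in enumerate(groups) if g == label]
            sub = vals[idx]
            if sub.size < 3:
                raise InsufficientDataError(
                    f"group {label!r} has fewer than 3 values for outlier removal"
                )
            mean, sd = sub.mean(), sub.std(ddof=1)
            if sd > 0:
                removed.extend(i for i, v in zip(idx, sub) if abs(v - mean) > z * sd)
        removed.sort()
    else:
        mean, sd = vals.mean(), vals.std(ddof=1)
        if sd == 0:
            removed = []
        else:
            removed = [i for i, v in enumerate(vals) if abs(v - mean) > z * sd]
    kept = [float(v) for i, v in enumerate(vals) if i not in set(removed)]
    return kept, removed


def remove_outlier_expressions(
    result: NormalizationResult,
    z: float = DEFAULT_OUTLIER_Z,
    per_group: bool = False,
) -> tuple[NormalizationResult, list[NormalizedExpression]]:
    """Apply :func:`remove_outliers` to a normalization result's ratios."""
    groups = result.group_labels() if per_group else None
    _, removed_idx = remove_outliers(result.ratios(), z=z, groups=groups)
    removed_set = set(removed_idx)
    kept = [v for i, v in enumerate(result.values) if i not in removed_set]
    removed = [v for i, v in enumerate(result.values) if i in removed_set]
    exclusions = result.exclusions + [
        Exclusion(v.sample_id, v.target_gene, f"normalized ratio outlier (z={z})")
        for v in removed
    ]
    return NormalizationResult(values=kept, exclusions=exclusions), removed
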