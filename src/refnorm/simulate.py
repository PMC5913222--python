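"""Synthetic-data generators for every stage of the pipeline.

Three generators, all seeded and deterministic:

* :func:`simulate_qpcr` — Cq-level two-group qPCR datasets.  Latent log2
  expression of animal i, gene j:

      x_ij = mu_j + beta_j * I(treated) + a_i + eps_ij

  with a shared per-animal scaling effect ``a_i`` (what normalization is
  meant to cancel) and per-gene biological noise ``eps_ij``.  The Cq
  readout inverts expression through the amplification efficiency:

      Cq_ijr = c_j - x_ij / log2(E_j) + tau_ijr

  so higher expression means lower Cq.  Because ``a_i`` enters every gene
  identically, the expected log2 Pfaffl ratio of a target against a
  reference is exactly ``beta_target - beta_reference`` — a treatment
  effect on the reference gene shows up, sign-flipped, in the normalized
  target.  The returned ground truth carries the betas and the a_i.

* :func:`simulate_compendium` — a stability compendium: per-gene Normal
  log2 signal with known median and SD across many independent arrays.

* :func:`simulate_de_matrix` — a two-group matrix with per-gene variances
  drawn from a scaled inverse chi-square (the moderated-t prior model) and
  a known fraction of genes shifted by +/- a fixed log2 fold change.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CqRecord, ExpressionMatrix, QpcrDataset, ValidationError


@dataclass(frozen=True)
class GeneSpec:
    gene_id: str
    baseline_log2: float        # mu_j
    treatment_effect: float     # beta_j, log2 units
    efficiency: float = 2.0     # E_j


@dataclass
class QpcrSimConfig:
    """Conditions of a simulated two-group qPCR experiment.

    Defaults mirror a chronic-treatment rodent design: 13 animals per
    group, duplicate technical replicates, and noise scales typical of a
    well-run assay (animal-to-animal input scaling SD 0.3 log2 units,
    per-gene biological SD 0.2 log2 units, replicate noise 0.02 cycles).
    """

    genes: list[GeneSpec]
    n_per_group: int = 13
    animal_effect_sd: float = 0.3   # log2 units, shared across genes of a sample
    biological_sd: float = 0.2      # log2 units, per gene per animal
    technical_sd: float = 0.02      # cycles, per replicate
    replicates: int = 2
    cq_intercept: float = 28.0      # c_j, cycles
    control_label: str = "RF"
    treatment_label: str = "Li"
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValidationError("QpcrSimConfig requires at least one gene")
        for sd in (self.animal_effect_sd, self.biological_sd, self.technical_sd):
            if sd < 0:
                raise ValidationError("noise SDs must be non-negative")
        for g in self.genes:
            if not (1.0 < g.efficiency <= 2.2):
                raise ValidationError(
                    f"gene {g.gene_id!r}: efficiency {g.efficiency} outside (1, 2.2]"
                )
        if self.n_per_group < 2:
            raise ValidationError("n_per_group must be >= 2")
        if self.replicates < 1:
            raise ValidationError("replicates must be >= 1")


@dataclass
class QpcrGroundTruth:
    betas: dict[str, float]
    animal_effects: dict[str, float]
    latent_log2: pd.DataFrame  # samples x genes


def simulate_qpcr(config: QpcrSimConfig) -> tuple[QpcrDataset, QpcrGroundTruth]:
    """Generate a Cq-level dataset plus the ground truth that produced it."""
    rng = np.random.default_rng(config.seed)
    n = config.n_per_group
    sample_ids = [f"{config.control_label}{i + 1:02d}" for i in range(n)] + \
                 [f"{config.treatment_label}{i + 1:02d}" for i in range(n)]
    treated = np.array([0] * n + [1] * n)
    a = rng.normal(0.0, config.animal_effect_sd, size=2 * n)

    records: list[CqRecord] = []
    latent = {}
    for g in config.genes:
        eps = rng.normal(0.0, config.biological_sd, size=2 * n)
        x = g.baseline_log2 + g.treatment_effect * treated + a + eps
        latent[g.gene_id] = x
        cq_mean = config.cq_intercept - x / math.log2(g.efficiency)
        for i, sample in enumerate(sample_ids):
            tau = rng.normal(0.0, config.technical_sd, size=config.replicates)
            reps = tuple(float(c) for c in cq_mean[i] + tau)
            records.append(CqRecord(
                sample_id=sample,
                group_label=config.treatment_label if treated[i] else config.control_label,
                gene_id=g.gene_id,
                plate_id="P1",
                replicate_cq=reps,
            ))
    ds = QpcrDataset(records=records, control_label=config.control_label)
    truth = QpcrGroundTruth(
        betas={g.gene_id: g.treatment_effect for g in config.genes},
        animal_effects=dict(zip(sample_ids, a.tolist())),
        latent_log2=pd.DataFrame(latent, index=sample_ids),
    )
    return ds, truth


# ---------------------------------------------------------------------------
# Stability compendium
# ---------------------------------------------------------------------------

@dataclass
class CompendiumSimConfig:
    """A compendium of independent arrays with known per-gene log2 spread.

    Defaults to 80 arrays, the size of a realistic single-tissue,
    single-platform compendium slice.
    """

    genes: list[tuple[str, float, float]]  # (gene_id, median_log2, sd_log2)
    n_samples: int = 80
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValidationError("CompendiumSimConfig requires at least one gene")
        for _, _, sd in self.genes:
            if sd < 0:
                raise ValidationError("sd_log2 must be non-negative")
        if self.n_samples < 1:
            raise ValidationError("n_samples must be >= 1")


def simulate_compendium(config: CompendiumSimConfig) -> ExpressionMatrix:
    rng = np.random.default_rng(config.seed)
    data = {}
    for gene_id, median, sd in config.genes:
        data[gene_id] = rng.normal(median, sd, size=config.n_samples)
    samples = [f"array{i + 1:03d}" for i in range(config.n_samples)]
    df = pd.DataFrame(data, index=samples).T
    df.columns = samples
    return ExpressionMatrix(values=df, log2=True)


# ---------------------------------------------------------------------------
# DE calibration matrices
# ---------------------------------------------------------------------------

@dataclass
class DeSimConfig:
    """Two-group matrix with scaled-inverse-chi-square gene variances."""

    n_genes: int = 1000
    n_per_group: int = 6
    fraction_de: float = 0.0
    logfc_magnitude: float = 1.0     # log2 units
    d0_true: float = 4.0             # prior df of the variance distribution
    s0_sq_true: float = 0.05         # prior scale (log2 units squared)
    baseline_mean: float = 8.0
    baseline_spread: float = 2.0     # SD of gene baseline means
    control_label: str = "control"
    treatment_label: str = "treated"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.fraction_de <= 1.0):
            raise ValidationError("fraction_de must be in [0, 1]")
        if self.d0_true <= 0 or self.s0_sq_true <= 0:
            raise ValidationError("variance-distribution parameters must be positive")
        if self.n_genes < 1 or self.n_per_group < 2:
            raise ValidationError("need >=1 gene and >=2 samples per group")


def simulate_de_matrix(
    config: DeSimConfig,
) -> tuple[ExpressionMatrix, pd.Series, np.ndarray]:
    """Returns (matrix, labels, is_de flags); DE genes shifted by +/-logfc."""
    rng = np.random.default_rng(config.seed)
    g, n = config.n_genes, config.n_per_group
    # sigma_g^2 ~ d0 * s0^2 / chi2_d0  (scaled inverse chi-square)
    sigma_sq = config.d0_true * config.s0_sq_true / rng.chisquare(config.d0_true, size=g)
    baseline = rng.normal(config.baseline_mean, config.baseline_spread, size=g)
    is_de = rng.random(g) < config.fraction_de
    sign = rng.choice([-1.0, 1.0], size=g)
    shift = np.where(is_de, sign * config.logfc_magnitude, 0.0)

    ctrl = rng.normal(baseline[:, None], np.sqrt(sigma_sq)[:, None], size=(g, n))
    trt = rng.normal((baseline + shift)[:, None], np.sqrt(sigma_sq)[:, None], size=(g, n))
    values = np.hstack([ctrl, trt])
    genes = [f"gene{i + 1:05d}" for i in range(g)]
    samples = [f"{config.control_label}{i + 1:02d}" for i in range(n)] + \
              [f"{config.treatment_label}{i + 1:02d}" for i in range(n)]
    df = pd.DataFrame(values, index=genes, columns=samples)
    labels = pd.Series([config.control_label] * n + [config.treatment_label] * n,
                       index=samples)
    matrix = ExpressionMatrix(values=df, sample_groups=labels, log2=True)
    return matrix, labels, is_de
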