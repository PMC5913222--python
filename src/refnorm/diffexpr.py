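"""Two-group differential expression with an empirical-Bayes moderated t.

The stage mirrors the standard microarray reanalysis workflow: quantile
normalization, a per-gene two-group linear fit, shrinkage of the residual
variances toward a pooled prior estimated by moment-matching on the log
sample variances (scaled-F model), a moderated t-statistic on the
augmented degrees of freedom, a B log-odds statistic, and Benjamini-
Hochberg FDR adjustment.

The hierarchical model: per-gene residual variance s_g^2 ~ s0^2 * F with a
scaled chi-square prior of d0 degrees of freedom; the posterior variance
is s~_g^2 = (d0*s0^2 + d_g*s_g^2) / (d0 + d_g) and the moderated t uses
d0 + d_g degrees of freedom.  (d0, s0^2) are estimated by equating the
empirical mean and variance of log s_g^2 to their theoretical values under
the scaled-F model, inverting the trigamma function by Newton iteration.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .io import (
    DE_COLUMNS,
    ExpressionMatrix,
    InsufficientDataError,
    ProbesetAnnotation,
    ValidationError,
)

logger = logging.getLogger(__name__)

DEFAULT_PROPORTION_DE = 0.01
#: Bounds on the prior fold-change standard deviation used for the B statistic.
LOGFC_SD_LIMITS = (0.1, 4.0)


# ---------------------------------------------------------------------------
# Quantile normalization
# ---------------------------------------------------------------------------

def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample (column) onto the cross-sample mean distribution.

    Each column's order statistics are replaced by the mean of the sorted
    values across columns; tied values within a column receive the mean of
    the reference values their positions span.  Afterwards all columns
    share the same value distribution.
    """
    df = matrix.values
    if df.shape[1] < 2:
        warnings.warn("quantile_normalize: single sample, returning input unchanged",
                      UserWarning, stacklevel=2)
        return ExpressionMatrix(values=df.copy(), sample_groups=matrix.sample_groups,
                                log2=matrix.log2)
    arr = df.to_numpy(dtype=float)
    reference = np.sort(arr, axis=0).mean(axis=1)
    out = np.empty_like(arr)
    for j in range(arr.shape[1]):
        col = arr[:, j]
        order = np.argsort(col, kind="mergesort")
        assigned = np.empty_like(col)
        assigned[order] = reference
        # average the reference values spanned by each tied group
        s = pd.Series(assigned)
        out[:, j] = s.groupby(pd.Series(col)).transform("mean").to_numpy()
    return ExpressionMatrix(
        values=pd.DataFrame(out, index=df.index, columns=df.columns),
        sample_groups=matrix.sample_groups,
        log2=matrix.log2,
    )


# ---------------------------------------------------------------------------
# Two-group linear fit
# ---------------------------------------------------------------------------

def fit_two_group(
    matrix: ExpressionMatrix,
    labels: pd.Series,
    control_label: str | None = None,
) -> pd.DataFrame:
    """Per-gene two-group fit: logFC, AveExpr, pooled variance, residual df.

    logFC is treatment minus control on the log2 scale; AveExpr is the
    grand mean; s2 the pooled within-group variance on n - 2 df.
    """
    labels = labels.reindex(matrix.values.columns)
    if labels.isna().any():
        raise ValidationError("labels missing for some samples")
    groups = sorted(labels.unique())
    if len(groups) != 2:
        raise ValidationError(f"expected exactly two groups, found {groups}")
    if control_label is None:
        control_label = groups[0]
        logger.info("fit_two_group: control label not given; using %r", control_label)
    if control_label not in groups:
        raise ValidationError(f"control label {control_label!r} not among {groups}")
    treatment_label = next(g for g in groups if g != control_label)
    ctrl = matrix.values.loc[:, (labels == control_label).to_numpy()]
    trt = matrix.values.loc[:, (labels == treatment_label).to_numpy()]
    n1, n2 = ctrl.shape[1], trt.shape[1]
    if n1 < 2 or n2 < 2:
        raise InsufficientDataError("each group needs at least 2 samples")
    logfc = trt.mean(axis=1) - ctrl.mean(axis=1)
    aveexpr = matrix.values.mean(axis=1)
    ss = ((ctrl.sub(ctrl.mean(axis=1), axis=0)) ** 2).sum(axis=1) + \
         ((trt.sub(trt.mean(axis=1), axis=0)) ** 2).sum(axis=1)
    df_resid = n1 + n2 - 2
    return pd.DataFrame({
        "logFC": logfc,
        "AveExpr": aveexpr,
        "s2": ss / df_resid,
        "df": float(df_resid),
        "n1": n1,
        "n2": n2,
    })


# ---------------------------------------------------------------------------
# Empirical-Bayes moderation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EbayesPrior:
    d0: float          # prior degrees of freedom (may be inf)
    s0_sq: float       # prior variance, log2 units squared
    proportion_de: float

    def __post_init__(self) -> None:
        if not (self.d0 > 0):
            raise ValidationError("d0 must be positive")
        if not (self.s0_sq > 0):
            raise ValidationError("s0_sq must be positive")
        if not (0.0 < self.proportion_de < 1.0):
            raise ValidationError("proportion_de must be in (0, 1)")


def trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    if x <= 0:
        raise ValidationError("trigamma_inverse requires a positive argument")
    if x > 1e7:
        return 1.0 / math.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = float(special.polygamma(1, y))
        dif = tri * (1.0 - tri / x) / float(special.polygamma(2, y))
        y += dif
        if -dif / y < 1e-8:
            break
    return y


def estimate_prior(
    s2: np.ndarray, df: float, proportion_de: float = DEFAULT_PROPORTION_DE
) -> EbayesPrior:
    """Moment-match (d0, s0^2) from the distribution of log sample variances."""
    s2 = np.asarray(s2, dtype=float)
    positive = s2[s2 > 0]
    if positive.size == 0:
        raise ValidationError("all sample variances are zero; prior is undefined")
    if positive.size < s2.size:
        warnings.warn(
            f"estimate_prior: dropping {s2.size - positive.size} zero variance(s) "
            "from moment estimation",
            UserWarning, stacklevel=2,
        )
    if positive.size < 10:
        warnings.warn("estimate_prior: fewer than 10 genes; prior estimates are noisy",
                      UserWarning, stacklevel=2)
    z = np.log(positive)
    if np.ptp(z) < 1e-12:
        # zero spread: the prior is a point mass on the common variance and
        # shrinkage leaves every gene where it already sits
        return EbayesPrior(d0=math.inf, s0_sq=float(positive[0]),
                           proportion_de=proportion_de)
    e = z - float(special.digamma(df / 2.0)) + math.log(df / 2.0)
    emean = float(e.mean())
    evar = float(e.var(ddof=1)) - float(special.polygamma(1, df / 2.0))
    if evar > 0:
        d0 = 2.0 * trigamma_inverse(evar)
        s0_sq = math.exp(emean + float(special.digamma(d0 / 2.0)) - math.log(d0 / 2.0))
    else:
        warnings.warn("estimate_prior: negative moment estimate; taking d0 = inf",
                      UserWarning, stacklevel=2)
        d0 = math.inf
        s0_sq = math.exp(emean)
    return EbayesPrior(d0=d0, s0_sq=s0_sq, proportion_de=proportion_de)


def _fold_change_prior_variance(
    t: np.ndarray,
    stdev_unscaled: float,
    df_total: np.ndarray,
    proportion: float,
    s0_sq: float,
) -> float:
    """Estimate the prior variance of true effects from the top |t|.

    Mixture-quantile estimator: the largest ``proportion/2 * G`` absolute
    t-statistics are matched against the quantiles a two-component mixture
    would place them at, yielding per-gene variance estimates (relative to
    the residual variance) that are clamped to
    ``LOGFC_SD_LIMITS**2 / s0_sq`` and averaged.
    """
    ngenes = t.size
    ntarget = math.ceil(proportion / 2.0 * ngenes)
    if ntarget < 1:
        return 1.0 / s0_sq
    p = max(ntarget / ngenes, proportion)
    tstat = np.abs(t)
    max_df = float(np.max(df_total))
    i = df_total < max_df
    if np.any(i):
        tail_logp = stats.t.logsf(tstat[i], df_total[i])
        tstat = tstat.copy()
        tstat[i] = stats.t.isf(np.exp(tail_logp), max_df)
    order = np.argsort(tstat)[::-1][:ntarget]
    ttop = tstat[order]
    v1 = np.full(ntarget, stdev_unscaled**2)
    r = np.arange(1, ntarget + 1)
    p0 = 2.0 * stats.t.sf(ttop, max_df)
    ptarget = ((r - 0.5) / ngenes - (1.0 - p) * p0) / p
    v0 = np.zeros(ntarget)
    pos = ptarget > p0
    if np.any(pos):
        qtarget = stats.t.isf(ptarget[pos] / 2.0, max_df)
        v0[pos] = v1[pos] * ((ttop[pos] / qtarget) ** 2 - 1.0)
    lo, hi = LOGFC_SD_LIMITS[0] ** 2 / s0_sq, LOGFC_SD_LIMITS[1] ** 2 / s0_sq
    return float(np.clip(v0, lo, hi).mean())


def ebayes_moderate(
    fits: pd.DataFrame,
    proportion_de: float = DEFAULT_PROPORTION_DE,
    d0_override: float | None = None,
) -> tuple[EbayesPrior, pd.DataFrame]:
    """Moderated t, p and B from a two-group fit table.

    Returns the estimated prior and a frame with columns ``t``, ``p_value``
    and ``B`` aligned to the input genes.  ``d0_override`` forces the prior
    degrees of freedom (``math.inf`` gives complete shrinkage to s0^2).
    """
    required = {"logFC", "s2", "df", "n1", "n2"}
    if not required.issubset(fits.columns):
        raise ValidationError(f"fit table must contain columns {sorted(required)}")
    s2 = fits["s2"].to_numpy(dtype=float)
    df_resid = float(fits["df"].iloc[0])
    n1, n2 = int(fits["n1"].iloc[0]), int(fits["n2"].iloc[0])
    stdev_unscaled = math.sqrt(1.0 / n1 + 1.0 / n2)

    if np.all(s2 == 0):
        logger.warning("ebayes_moderate: all residual variances are zero; degenerate "
                       "prior with d0 = inf")
        prior = EbayesPrior(d0=math.inf, s0_sq=1e-12, proportion_de=proportion_de)
    else:
        prior = estimate_prior(s2, df_resid, proportion_de)
    if d0_override is not None:
        prior = EbayesPrior(d0=d0_override, s0_sq=prior.s0_sq,
                            proportion_de=proportion_de)

    if math.isinf(prior.d0):
        s2_post = np.full_like(s2, prior.s0_sq)
        df_total = np.full_like(s2, math.inf)
    else:
        s2_post = (prior.d0 * prior.s0_sq + df_resid * s2) / (prior.d0 + df_resid)
        # cap the total df at the pooled residual df actually observed
        pooled_df = df_resid * len(fits)
        df_total = np.full_like(s2, min(prior.d0 + df_resid, pooled_df))

    logfc = fits["logFC"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = logfc / (np.sqrt(s2_post) * stdev_unscaled)
    t = np.nan_to_num(t, nan=0.0)
    if np.all(np.isinf(df_total)):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)

    v0 = _fold_change_prior_variance(t, stdev_unscaled, df_total, proportion_de,
                                     prior.s0_sq)
    r = (stdev_unscaled**2 + v0) / stdev_unscaled**2
    if np.all(np.isinf(df_total)):
        kernel = t**2 * (1.0 - 1.0 / r) / 2.0
    else:
        kernel = (1.0 + df_total) / 2.0 * np.log((t**2 + df_total) / (t**2 / r + df_total))
    lods = math.log(proportion_de / (1.0 - proportion_de)) - math.log(r) / 2.0 + kernel

    out = pd.DataFrame({"t": t, "p_value": p, "B": lods}, index=fits.index)
    return prior, out


# ---------------------------------------------------------------------------
# FDR adjustment
# ---------------------------------------------------------------------------

def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in the input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValidationError("bh_adjust requires at least one p-value")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    _, adj, _, _ = multipletests(p, method="fdr_bh")
    return adj


# ---------------------------------------------------------------------------
# End-to-end DE
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DeResult:
    probeset_id: str
    gene_symbol: str
    logFC: float
    AveExpr: float
    t: float
    p_value: float
    adj_p_value: float
    B: float

    def to_row(self) -> dict:
        row = {"probeset": self.probeset_id, "gene": self.gene_symbol}
        row.update(zip(DE_COLUMNS, (self.logFC, self.AveExpr, self.t,
                                    self.p_value, self.adj_p_value, self.B)))
        return row


def run_de(
    matrix: ExpressionMatrix,
    labels: pd.Series,
    annotation: ProbesetAnnotation | None = None,
    pre_normalized: bool = False,
    control_label: str | None = None,
    proportion_de: float = DEFAULT_PROPORTION_DE,
) -> list[DeResult]:
    """Quantile-normalize (unless already normalized), fit, moderate, adjust.

    Returns one :class:`DeResult` per probeset, gene-annotated, sorted by
    unadjusted p-value.
    """
    if not pre_normalized:
        matrix = quantile_normalize(matrix)
    fits = fit_two_group(matrix, labels, control_label=control_label)
    _, mod = ebayes_moderate(fits, proportion_de=proportion_de)
    adj = bh_adjust(mod["p_value"].to_numpy())
    results = []
    for i, probeset in enumerate(fits.index):
        symbol = annotation.gene_symbol(str(probeset)) if annotation else str(probeset)
        results.append(DeResult(
            probeset_id=str(probeset),
            gene_symbol=symbol,
            logFC=float(fits["logFC"].iloc[i]),
            AveExpr=float(fits["AveExpr"].iloc[i]),
            t=float(mod["t"].iloc[i]),
            p_value=float(mod["p_value"].iloc[i]),
            adj_p_value=float(adj[i]),
            B=float(mod["B"].iloc[i]),
        ))
    results.sort(key=lambda r: (r.p_value, r.probeset_id))
    return results
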