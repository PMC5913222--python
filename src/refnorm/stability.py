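"""Reference-gene stability scoring on an expression compendium.

A candidate normalizer is judged by the spread of its log2 signal across
many independent arrays of the relevant tissue: the per-gene sample SD is
converted to the expected maximal fold change a user of that gene could
see purely from its own variation, as ``2**(z * SD)`` with z = 1.96 (the
central 95% mass of a normal).  A gene with SD 0.12 implies at most a
~1.18-fold swing; an SD of 0.45 — typical of classic housekeeping genes —
already implies ~1.8-fold, of the same order as the biological effects
being hunted.

Ranking combines that stability with treatment-independence: among genes
below a stability cap, the recommended normalizer is the most stable one
whose expression shows no evidence of a treatment effect (two-group
rank-sum p above a floor).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, InsufficientDataError, ValidationError
from .robust import rank_sum_test

logger = logging.getLogger(__name__)

DEFAULT_Z = 1.96  # z for the central 95% mass


def expected_max_fold_change(sd_log2: float, z: float = DEFAULT_Z) -> float:
    """Expected maximal fold change implied by a log2-signal SD: 2**(z*SD)."""
    if sd_log2 < 0:
        raise ValidationError("sd_log2 must be non-negative")
    return float(2.0 ** (z * sd_log2))


@dataclass(frozen=True)
class StabilityRecord:
    gene_id: str
    median_log2: float
    sd_log2: float
    expected_max_fc: float
    n_samples: int


def gene_stability(matrix: ExpressionMatrix, z: float = DEFAULT_Z) -> list[StabilityRecord]:
    """Per-gene median and sample SD of log2 signal across arrays.

    Requires the matrix's ``log2`` flag — stability on a linear-scale
    matrix would conflate level with spread.
    """
    if not matrix.log2:
        raise ValidationError(
            "matrix is not flagged log2; transform explicitly before scoring stability"
        )
    n = matrix.shape[1]
    if n < 3:
        raise InsufficientDataError("stability estimation needs at least 3 samples")
    medians = matrix.values.median(axis=1)
    sds = matrix.values.std(axis=1, ddof=1)
    return [
        StabilityRecord(
            gene_id=str(g),
            median_log2=float(medians[g]),
            sd_log2=float(sds[g]),
            expected_max_fc=expected_max_fold_change(float(sds[g]), z),
            n_samples=n,
        )
        for g in matrix.gene_ids
    ]


@dataclass(frozen=True)
class CandidateRow:
    gene_id: str
    median_log2: float
    sd_log2: float
    expected_max_fc: float
    treatment_p_value: float | None
    selected: bool


@dataclass
class CandidateRanking:
    rows: list[CandidateRow]
    recommended: str | None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "gene": r.gene_id,
                    "median_log2": r.median_log2,
                    "sd_log2": r.sd_log2,
                    "expected_max_fc": r.expected_max_fc,
                    "treatment_p": "" if r.treatment_p_value is None else r.treatment_p_value,
                    "selected": int(r.selected),
                }
                for r in self.rows
            ]
        )


def rank_reference_candidates(
    matrix: ExpressionMatrix,
    treatment_labels: pd.Series | None = None,
    sd_max: float = 0.5,
    p_floor: float = 0.05,
    z: float = DEFAULT_Z,
) -> CandidateRanking:
    """Rank normalizer candidates by stability, vetoing treatment-responsive genes.

    Genes are sorted ascending by log2-signal SD (ties broken by gene id).
    When ``treatment_labels`` (two groups) is supplied, each gene also gets
    a rank-sum p-value for a group difference; selection requires both
    ``sd_log2 <= sd_max`` and ``p >= p_floor``.  The recommended normalizer
    is the most stable selected gene — so a very stable gene that responds
    to treatment is passed over in favour of the next stable one that does
    not.
    """
    records = gene_stability(matrix, z=z)
    labels = None
    if treatment_labels is not None:
        labels = treatment_labels.reindex(matrix.values.columns)
        if labels.isna().any():
            raise ValidationError("treatment_labels missing for some samples")
        groups = sorted(labels.unique())
        if len(groups) != 2:
            raise ValidationError(f"expected exactly two groups, found {groups}")

    rows: list[CandidateRow] = []
    for rec in sorted(records, key=lambda r: (r.sd_log2, r.gene_id)):
        p: float | None = None
        if labels is not None:
            vals = matrix.values.loc[rec.gene_id]
            x = vals[labels == groups[0]].to_numpy()
            y = vals[labels == groups[1]].to_numpy()
            _, p, _ = rank_sum_test(x, y)
        selected = rec.sd_log2 <= sd_max and (p is None or p >= p_floor)
        rows.append(CandidateRow(
            gene_id=rec.gene_id,
            median_log2=rec.median_log2,
            sd_log2=rec.sd_log2,
            expected_max_fc=rec.expected_max_fc,
            treatment_p_value=p,
            selected=selected,
        ))
    recommended = next((r.gene_id for r in rows if r.selected), None)
    if recommended is None:
        warnings.warn(
            f"no candidate satisfies sd_log2 <= {sd_max} and p >= {p_floor}; "
            "empty selection",
            UserWarning,
            stacklevel=2,
        )
    return CandidateRanking(rows=rows, recommended=recommended)
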