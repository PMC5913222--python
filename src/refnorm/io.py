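"""Readers and writers for the tabular formats the pipeline consumes.

All inputs are plain text: Cq tables and standard curves as CSV, expression
matrices and results tables as TSV (series-matrix style: first column row
ids, header row of sample ids).  Validation is total — a malformed file
raises a typed error rather than yielding a partial dataset.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

CQ_MAX = 45.0  # thermal-cycler programs run 40-45 cycles; Cq beyond is meaningless

#: Result-table column roles, in fixed output order, following the layout of
#: standard two-group differential-expression reports.
DE_COLUMNS = ("logFC", "AveExpr", "t", "p-value", "Adjusted p-value", "B")


class RefnormError(Exception):
    """Base class for all refnorm errors."""


class FormatError(RefnormError):
    """Structural problem in an input file (missing column, ragged row)."""


class CqParseError(RefnormError):
    """A cell could not be parsed as a quantification-cycle value."""


class ValidationError(RefnormError):
    """Parsed data violates a dataset invariant."""


class InsufficientDataError(RefnormError):
    """Too few observations to carry out the requested computation."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CqRecord:
    """Technical replicate Cq values for one sample x gene on one plate."""

    sample_id: str
    group_label: str
    gene_id: str
    plate_id: str
    replicate_cq: tuple[float, ...]

    def __post_init__(self) -> None:
        if not self.replicate_cq:
            raise ValidationError(
                f"sample {self.sample_id!r} gene {self.gene_id!r}: no replicate Cq values"
            )
        for cq in self.replicate_cq:
            if not (0.0 < cq <= CQ_MAX) or math.isnan(cq):
                raise ValidationError(
                    f"sample {self.sample_id!r} gene {self.gene_id!r}: "
                    f"Cq {cq} outside (0, {CQ_MAX}]"
                )


@dataclass
class QpcrDataset:
    """A two-group qPCR experiment: samples x genes x technical replicates."""

    records: list[CqRecord]
    control_label: str | None = None

    def __post_init__(self) -> None:
        self.validate()

    # -- derived views ------------------------------------------------
    @property
    def groups(self) -> tuple[str, str]:
        labels = sorted({r.group_label for r in self.records})
        return tuple(labels)  # type: ignore[return-value]

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(sorted({r.gene_id for r in self.records}))

    @property
    def samples(self) -> tuple[str, ...]:
        return tuple(sorted({r.sample_id for r in self.records}))

    def group_of(self, sample_id: str) -> str:
        for r in self.records:
            if r.sample_id == sample_id:
                return r.group_label
        raise KeyError(sample_id)

    def records_for(self, gene_id: str) -> list[CqRecord]:
        return [r for r in self.records if r.gene_id == gene_id]

    # -- validation ----------------------------------------------------
    def validate(self) -> None:
        if not self.records:
            raise ValidationError("dataset contains no records")
        labels = {r.group_label for r in self.records}
        if len(labels) != 2:
            raise ValidationError(
                f"expected exactly two group labels, found {sorted(labels)}"
            )
        if self.control_label is not None and self.control_label not in labels:
            raise ValidationError(
                f"control label {self.control_label!r} not among groups {sorted(labels)}"
            )
        seen: set[tuple[str, str, str]] = set()
        sample_group: dict[str, str] = {}
        for r in self.records:
            key = (r.plate_id, r.sample_id, r.gene_id)
            if key in seen:
                raise ValidationError(
                    f"duplicate record for sample {r.sample_id!r} gene {r.gene_id!r} "
                    f"on plate {r.plate_id!r}"
                )
            seen.add(key)
            prev = sample_group.setdefault(r.sample_id, r.group_label)
            if prev != r.group_label:
                raise ValidationError(
                    f"sample {r.sample_id!r} assigned to both groups {prev!r} and "
                    f"{r.group_label!r}"
                )
        # Balanced-plate design: each plate carries equal numbers of samples
        # from each group.
        for plate in {r.plate_id for r in self.records}:
            plate_samples = {
                (r.sample_id, r.group_label) for r in self.records if r.plate_id == plate
            }
            counts: dict[str, int] = {}
            for _, g in plate_samples:
                counts[g] = counts.get(g, 0) + 1
            if len(set(counts.values())) > 1:
                raise ValidationError(
                    f"plate {plate!r} is unbalanced across groups: {counts}"
                )


@dataclass
class ExpressionMatrix:
    """A genes x samples matrix of (log2) signal intensities.

    ``values`` is a DataFrame indexed by gene/probeset id with sample-id
    columns.  ``sample_groups`` optionally annotates each sample with a
    group or tissue label.  ``log2`` declares the scale of the values;
    operations that assume log2 signals check the flag.
    """

    values: pd.DataFrame
    sample_groups: pd.Series | None = None
    log2: bool = True
    n_dropped_rows: int = 0

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            raise ValidationError("expression matrix contains missing values")
        if self.sample_groups is not None:
            missing = set(self.values.columns) - set(self.sample_groups.index)
            if missing:
                raise ValidationError(
                    f"samples without group annotation: {sorted(missing)}"
                )

    @property
    def gene_ids(self) -> tuple[str, ...]:
        return tuple(self.values.index)

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return tuple(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass(frozen=True)
class ProbesetAnnotation:
    """Many-to-one probeset -> gene-symbol map."""

    mapping: Mapping[str, str]

    def gene_symbol(self, probeset_id: str) -> str:
        return self.mapping.get(probeset_id, probeset_id)


# ---------------------------------------------------------------------------
# Cq tables
# ---------------------------------------------------------------------------

_REQUIRED_CQ_COLUMNS = ("sample_id", "group", "gene", "plate")


def _parse_cq_cell(text: str, row_number: int, column: str) -> float:
    try:
        return float(text)
    except ValueError:
        raise CqParseError(
            f"row {row_number}, column {column!r}: cannot parse Cq value {text!r}"
        ) from None


def read_cq_table(path: str | Path, control_label: str | None = None) -> QpcrDataset:
    """Read a wide-format Cq CSV into a validated :class:`QpcrDataset`.

    Expected columns: ``sample_id, group, gene, plate, cq_rep1 .. cq_repK``.
    Empty replicate cells at the tail are allowed (variable replicate count);
    non-numeric cells such as ``Undetermined`` raise :class:`CqParseError`
    naming the offending row.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in _REQUIRED_CQ_COLUMNS if c not in header]
        if missing:
            raise FormatError(f"{path.name}: missing required columns {missing}")
        rep_cols = [c for c in header if c.startswith("cq_rep")]
        if not rep_cols:
            raise FormatError(f"{path.name}: no cq_rep* replicate columns found")
        records: list[CqRecord] = []
        for i, row in enumerate(reader, start=2):  # 1-based incl. header
            reps: list[float] = []
            for col in rep_cols:
                cell = (row.get(col) or "").strip()
                if cell == "":
                    continue
                reps.append(_parse_cq_cell(cell, i, col))
            records.append(
                CqRecord(
                    sample_id=row["sample_id"].strip(),
                    group_label=row["group"].strip(),
                    gene_id=row["gene"].strip(),
                    plate_id=row["plate"].strip(),
                    replicate_cq=tuple(reps),
                )
            )
    return QpcrDataset(records=records, control_label=control_label)


def read_long_cq_table(path: str | Path, control_label: str | None = None) -> QpcrDataset:
    """Convenience reader for long-format Cq tables.

    Columns: ``sample_id, group, gene, plate, cq`` — one row per technical
    replicate; replicates of the same sample x gene x plate are collected.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        required = (*_REQUIRED_CQ_COLUMNS, "cq")
        missing = [c for c in required if c not in header]
        if missing:
            raise FormatError(f"{path.name}: missing required columns {missing}")
        grouped: dict[tuple[str, str, str, str], list[float]] = {}
        for i, row in enumerate(reader, start=2):
            key = (
                row["sample_id"].strip(),
                row["group"].strip(),
                row["gene"].strip(),
                row["plate"].strip(),
            )
            grouped.setdefault(key, []).append(_parse_cq_cell(row["cq"].strip(), i, "cq"))
    records = [
        CqRecord(sample_id=s, group_label=g, gene_id=gene, plate_id=p,
                 replicate_cq=tuple(cqs))
        for (s, g, gene, p), cqs in grouped.items()
    ]
    return QpcrDataset(records=records, control_label=control_label)


def write_cq_table(ds: QpcrDataset, path: str | Path) -> None:
    """Write a :class:`QpcrDataset` in the wide CSV format ``read_cq_table`` reads."""
    path = Path(path)
    k = max(len(r.replicate_cq) for r in ds.records)
    header = [*_REQUIRED_CQ_COLUMNS, *[f"cq_rep{i + 1}" for i in range(k)]]
    with path.open("w", newline="\n", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(header)
        for r in sorted(ds.records, key=lambda r: (r.plate_id, r.sample_id, r.gene_id)):
            reps = [f"{cq:.6f}" for cq in r.replicate_cq]
            reps += [""] * (k - len(reps))
            writer.writerow([r.sample_id, r.group_label, r.gene_id, r.plate_id, *reps])


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------

def read_expression_matrix(
    path: str | Path,
    log2: bool = True,
    sample_groups: pd.Series | None = None,
) -> ExpressionMatrix:
    """Read a series-matrix-style TSV (first column row ids, header sample ids).

    Rows with missing/empty cells are dropped and the count logged; ragged
    rows raise :class:`FormatError`.
    """
    path = Path(path)
    with path.open(encoding="utf-8") as fh:
        rows = [line.rstrip("\n").split("\t") for line in fh if line.strip()]
    if not rows:
        raise FormatError(f"{path.name}: empty file")
    width = len(rows[0])
    for i, row in enumerate(rows[1:], start=2):
        if len(row) != width:
            raise FormatError(
                f"{path.name}: ragged row {i} (expected {width} fields, got {len(row)})"
            )
    header = rows[0][1:]
    index, data, dropped = [], [], 0
    for row in rows[1:]:
        vals: list[float] = []
        ok = True
        for cell in row[1:]:
            cell = cell.strip()
            if cell in ("", "NA", "NaN", "null"):
                ok = False
                break
            try:
                vals.append(float(cell))
            except ValueError:
                ok = False
                break
        if not ok:
            dropped += 1
            continue
        index.append(row[0])
        data.append(vals)
    if dropped:
        logger.info("read_expression_matrix(%s): dropped %d row(s) with missing cells",
                    path.name, dropped)
    df = pd.DataFrame(data, index=index, columns=header, dtype=float)
    return ExpressionMatrix(values=df, sample_groups=sample_groups, log2=log2,
                            n_dropped_rows=dropped)


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="\n", encoding="utf-8") as fh:
        fh.write("id\t" + "\t".join(matrix.sample_ids) + "\n")
        for gene, row in matrix.values.iterrows():
            fh.write(str(gene) + "\t" + "\t".join(f"{v:.9g}" for v in row) + "\n")


# ---------------------------------------------------------------------------
# Standard curves and annotations
# ---------------------------------------------------------------------------

def read_standard_curves(path: str | Path) -> dict[str, list[tuple[float, float]]]:
    """Read a dilution-series CSV (columns gene, log10_input, cq) into per-gene points."""
    path = Path(path)
    points: dict[str, list[tuple[float, float]]] = {}
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        required = ("gene", "log10_input", "cq")
        missing = [c for c in required if c not in (reader.fieldnames or [])]
        if missing:
            raise FormatError(f"{path.name}: missing required columns {missing}")
        for i, row in enumerate(reader, start=2):
            try:
                x = float(row["log10_input"])
                cq = float(row["cq"])
            except ValueError:
                raise CqParseError(f"row {i}: non-numeric standard-curve point") from None
            points.setdefault(row["gene"].strip(), []).append((x, cq))
    return points


def read_probeset_annotation(path: str | Path) -> ProbesetAnnotation:
    """Two-column TSV: probeset_id <TAB> gene_symbol (many-to-one allowed)."""
    path = Path(path)
    mapping: dict[str, str] = {}
    with path.open(encoding="utf-8") as fh:
        for i, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 2:
                raise FormatError(f"annotation row {i}: expected 2 fields, got {len(parts)}")
            mapping[parts[0]] = parts[1]
    return ProbesetAnnotation(mapping=mapping)


# ---------------------------------------------------------------------------
# Results tables
# ---------------------------------------------------------------------------

def write_results_table(results: Sequence | pd.DataFrame, path: str | Path) -> None:
    """Write a results table as TSV with deterministic column order.

    Differential-expression results use the six canonical column roles
    (:data:`DE_COLUMNS`) after the id columns.  Any sequence of dataclass
    instances or a DataFrame is accepted; empty results raise.
    """
    path = Path(path)
    if isinstance(results, pd.DataFrame):
        if results.empty:
            raise ValidationError("refusing to write an empty results table")
        df = results
    else:
        if not results:
            raise ValidationError("refusing to write an empty results table")
        first = results[0]
        if hasattr(first, "to_row"):  # DeResult and friends
            df = pd.DataFrame([r.to_row() for r in results])
        else:
            df = pd.DataFrame([vars(r) for r in results])
    with path.open("w", newline="\n", encoding="utf-8") as fh:
        fh.write("\t".join(str(c) for c in df.columns) + "\n")
        for _, row in df.iterrows():
            cells = []
            for v in row:
                if isinstance(v, float):
                    cells.append(f"{v:.10g}")
                else:
                    cells.append(str(v))
            fh.write("\t".join(cells) + "\n")


def read_results_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
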