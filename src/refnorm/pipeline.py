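"""Orchestration: the normalization-sensitivity report and config-driven runs.

The sensitivity analysis is the heart of the package: the same target gene
is normalized against each of a panel of reference genes, each normalized
series is outlier-filtered and compared between groups, and the per-
reference directions (up / down / NS at a significance threshold) are laid
side by side.  Discordant directions across references are the warning
sign the analysis exists to surface — they mean the conclusion belongs to
the normalizer, not the target.
"""

from __future__ import annotations

import datetime
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import __version__
from .diffexpr import run_de
from .evidence import (
    load_affected_normalizers,
    load_evidence_table,
    tally_affected_normalizers,
    tally_outcomes,
)
from .io import (
    ExpressionMatrix,
    QpcrDataset,
    RefnormError,
    ValidationError,
    read_cq_table,
    read_expression_matrix,
    write_cq_table,
    write_expression_matrix,
    write_results_table,
)
from .quantify import (
    DEFAULT_OUTLIER_Z,
    normalize_dataset,
    remove_outlier_expressions,
)
from .robust import GroupComparison, compare_groups
from .simulate import (
    CompendiumSimConfig,
    DeSimConfig,
    GeneSpec,
    QpcrSimConfig,
    simulate_compendium,
    simulate_de_matrix,
    simulate_qpcr,
)
from .stability import rank_reference_candidates

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05


# ---------------------------------------------------------------------------
# Sensitivity report
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SensitivityRow:
    reference_gene: str
    comparison: GroupComparison | None
    direction: str               # "up" | "down" | "NS" | "failed"
    n_excluded_qc: int
    n_excluded_outlier: int
    error: str | None = None


@dataclass
class SensitivityReport:
    target_gene: str
    rows: list[SensitivityRow]
    alpha: float

    @property
    def concordant(self) -> bool:
        """Do all (non-failed) references yield the same direction label?"""
        directions = {r.direction for r in self.rows if r.direction != "failed"}
        return len(directions) <= 1

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.rows:
            c = r.comparison
            rows.append({
                "target": self.target_gene,
                "reference": r.reference_gene,
                "direction": r.direction,
                "n_control": c.n_a if c else "",
                "n_treatment": c.n_b if c else "",
                "median_control": c.median_a if c else "",
                "median_treatment": c.median_b if c else "",
                "hl_shift": c.hl_shift if c else "",
                "ci_low": c.ci_low if c else "",
                "ci_high": c.ci_high if c else "",
                "p_value": c.p_value if c else "",
                "method": c.method if c else "",
                "n_excluded_qc": r.n_excluded_qc,
                "n_excluded_outlier": r.n_excluded_outlier,
                "error": r.error or "",
            })
        return pd.DataFrame(rows)


def run_sensitivity(
    ds: QpcrDataset,
    target: str,
    references: list[str],
    efficiencies: Mapping[str, float] | None = None,
    *,
    control_label: str | None = None,
    alpha: float = DEFAULT_ALPHA,
    outlier_z: float = DEFAULT_OUTLIER_Z,
    sd_threshold: float = 0.05,
) -> SensitivityReport:
    """Normalize ``target`` against each reference and compare the groups.

    Each reference runs independently: normalize -> single-pass outlier
    filter on the ratios -> rank-sum / Hodges-Lehmann comparison.  A
    reference whose preconditions fail is reported as ``failed`` rather
    than aborting the whole report.
    """
    control = control_label or ds.control_label
    rows: list[SensitivityRow] = []
    for ref in references:
        try:
            norm = normalize_dataset(
                ds, target, ref, efficiencies,
                control_label=control, sd_threshold=sd_threshold,
                allow_self=(target == ref),
            )
            n_qc = len(norm.exclusions)
            filtered, removed = remove_outlier_expressions(norm, z=outlier_z)
            comparison = compare_groups(filtered, control_label=control)
            if comparison.p_value < alpha:
                direction = "up" if comparison.hl_shift > 0 else "down"
            else:
                direction = "NS"
            rows.append(SensitivityRow(
                reference_gene=ref,
                comparison=comparison,
                direction=direction,
                n_excluded_qc=n_qc,
                n_excluded_outlier=len(removed),
            ))
        except RefnormError as exc:
            logger.warning("run_sensitivity: reference %s failed: %s", ref, exc)
            rows.append(SensitivityRow(
                reference_gene=ref, comparison=None, direction="failed",
                n_excluded_qc=0, n_excluded_outlier=0, error=str(exc),
            ))
    return SensitivityReport(target_gene=target, rows=rows, alpha=alpha)


def render_report(report: SensitivityReport) -> str:
    """Human-readable rendering; every number comes from stored values."""
    lines = [f"Normalization sensitivity report for target {report.target_gene}",
             f"(direction called at two-sided p < {report.alpha})", ""]
    for r in report.rows:
        if r.comparison is None:
            lines.append(f"  vs {r.reference_gene}: FAILED ({r.error})")
            continue
        lines.append(f"  vs {r.reference_gene}: {r.direction}")
        lines.append(f"    {r.comparison.format()}")
        lines.append(f"    excluded: {r.n_excluded_qc} by replicate QC, "
                     f"{r.n_excluded_outlier} as ratio outliers")
    lines.append("")
    lines.append("concordant" if report.concordant
                 else "DISCORDANT: direction depends on the reference gene")
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# Config-driven runs
# ---------------------------------------------------------------------------

_KNOWN_STAGES = ("simulate", "quantify", "sensitivity", "stability", "de", "evidence")


def _validate_config(config: Mapping[str, Any]) -> list[dict]:
    if "stages" not in config or not isinstance(config["stages"], list):
        raise ValidationError("config must contain a 'stages' list")
    stages = []
    for i, stage in enumerate(config["stages"]):
        if not isinstance(stage, dict) or "stage" not in stage:
            raise ValidationError(f"stage {i}: each stage needs a 'stage' name")
        if stage["stage"] not in _KNOWN_STAGES:
            raise ValidationError(
                f"stage {i}: unknown stage {stage['stage']!r}; "
                f"known stages: {_KNOWN_STAGES}"
            )
        stages.append(stage)
    return stages


def _build_qpcr_config(params: Mapping[str, Any]) -> QpcrSimConfig:
    genes = [GeneSpec(**g) for g in params.get("genes", [])]
    kwargs = {k: v for k, v in params.items() if k != "genes"}
    return QpcrSimConfig(genes=genes, **kwargs)


def run_config(config: str | Path | Mapping[str, Any], out_dir: str | Path) -> Path:
    """Execute the stages declared in a YAML config, writing artifacts.

    The whole config is schema-validated before any stage runs.  Outputs
    are deterministic given the config (stochastic stages re-seed from the
    config); the run log records seeds, thresholds and the software
    version.
    """
    if isinstance(config, (str, Path)):
        with Path(config).open(encoding="utf-8") as fh:
            config = yaml.safe_load(fh)
    stages = _validate_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines = [f"refnorm {__version__}",
                 f"run started {datetime.datetime.now().isoformat()}"]

    store: dict[str, Any] = {}
    for stage in stages:
        name = stage["stage"]
        params = {k: v for k, v in stage.items() if k != "stage"}
        log_lines.append(f"stage {name}: {params}")
        if name == "simulate":
            kind = params.pop("kind", "qpcr")
            if kind == "qpcr":
                cfg = _build_qpcr_config(params)
                ds, truth = simulate_qpcr(cfg)
                store["qpcr"] = ds
                store["qpcr_truth"] = truth
                write_cq_table(ds, out / "simulated_cq.csv")
            elif kind == "compendium":
                cfg = CompendiumSimConfig(
                    genes=[tuple(g) for g in params.pop("genes")], **params)
                store["compendium"] = simulate_compendium(cfg)
                write_expression_matrix(store["compendium"], out / "compendium.tsv")
            elif kind == "de":
                cfg = DeSimConfig(**params)
                matrix, labels, truth = simulate_de_matrix(cfg)
                store["de_matrix"], store["de_labels"] = matrix, labels
                write_expression_matrix(matrix, out / "de_matrix.tsv")
            else:
                raise ValidationError(f"unknown simulate kind {kind!r}")
        elif name in ("quantify", "sensitivity"):
            ds = store.get("qpcr")
            if ds is None and "cq_table" in params:
                ds = read_cq_table(params.pop("cq_table"),
                                   control_label=params.pop("control_label", None))
            if ds is None:
                raise ValidationError(f"stage {name}: no qPCR dataset available")
            report = run_sensitivity(
                ds, params["target"], params["references"],
                params.get("efficiencies"),
                alpha=params.get("alpha", DEFAULT_ALPHA),
            )
            store["sensitivity"] = report
            write_results_table(report.to_frame(), out / "sensitivity.tsv")
            (out / "sensitivity_report.txt").write_text(render_report(report) + "\n",
                                                        encoding="utf-8")
        elif name == "stability":
            matrix = store.get("compendium")
            if matrix is None and "matrix" in params:
                matrix = read_expression_matrix(params.pop("matrix"))
            if matrix is None:
                raise ValidationError("stability stage: no compendium available")
            ranking = rank_reference_candidates(
                matrix,
                sd_max=params.get("sd_max", 0.5),
                p_floor=params.get("p_floor", 0.05),
            )
            store["stability"] = ranking
            write_results_table(ranking.to_frame(), out / "stability.tsv")
        elif name == "de":
            matrix, labels = store.get("de_matrix"), store.get("de_labels")
            if matrix is None and "matrix" in params:
                matrix = read_expression_matrix(params.pop("matrix"))
                labels = pd.read_csv(params.pop("labels"), sep="\t", index_col=0)
                labels = labels.iloc[:, 0]
            if matrix is None:
                raise ValidationError("de stage: no expression matrix available")
            results = run_de(matrix, labels,
                             pre_normalized=params.get("pre_normalized", False),
                             control_label=params.get("control_label"))
            store["de"] = results
            write_results_table(results, out / "de_results.tsv")
        elif name == "evidence":
            entries = load_evidence_table()
            affected = load_affected_normalizers()
            tally = tally_outcomes(entries)
            frame = pd.DataFrame([{
                "total": tally.total,
                "ns": tally.ns,
                "sig_up": tally.sig_up,
                "sig_down": tally.sig_down,
                "direction_only": tally.direction_only,
                "sig_up_affected_normalizer":
                    tally_affected_normalizers(entries, affected),
            }])
            write_results_table(frame, out / "evidence_tally.tsv")
    log_lines.append(f"run finished {datetime.datetime.now().isoformat()}")
    (out / "run.log").write_text("\n".join(log_lines) + "\n", encoding="utf-8")
    return out
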