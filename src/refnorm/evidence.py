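"""Curated literature evidence on lithium's effect on BCL2 levels.

The package ships a machine-readable transcription of a systematic review
of 49 published experimental set-ups (species x tissue x dose x duration x
assay), each coded with the normalizer used and the reported outcome, plus
the companion list of normalizing genes/proteins themselves reported as
altered by lithium or disease state.  Tally operations reproduce the
review's headline counts: most set-ups found no significant effect, and a
portion of the significant-upregulation set-ups normalized their signal to
lithium-affected genes.
"""

from __future__ import annotations

import csv
import hashlib
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

from .io import ValidationError

ASSAY_CODES = frozenset({"qPCR", "WB", "MA", "NB", "IHC", "ELISA"})
OUTCOME_CODES = frozenset({"NS", "sig_up", "sig_down", "direction_only"})


@dataclass(frozen=True)
class EvidenceEntry:
    study_ref: str
    species: str
    tissue: str
    dose: str
    regimen: str
    n: str                 # count as printed; may be a range or "NA"
    assay: str
    normalizer: str        # gene/protein name or "NA"
    effect_size: str       # signed fold(s) as printed, "NS", or "increase"
    outcome: str
    significance_stars: int
    note: str = ""

    def __post_init__(self) -> None:
        if self.assay not in ASSAY_CODES:
            raise ValidationError(
                f"study {self.study_ref}: unknown assay code {self.assay!r}"
            )
        if self.outcome not in OUTCOME_CODES:
            raise ValidationError(
                f"study {self.study_ref}: unknown outcome code {self.outcome!r}"
            )
        if self.outcome in ("sig_up", "sig_down") and self.significance_stars < 1:
            raise ValidationError(
                f"study {self.study_ref}: significant outcome requires >=1 star"
            )
        if self.outcome == "NS" and self.effect_size != "NS":
            raise ValidationError(
                f"study {self.study_ref}: NS outcome must carry effect size 'NS'"
            )


@dataclass(frozen=True)
class AffectedNormalizerList:
    """Canonical symbols of normalizers reported as lithium/disease-affected."""

    genes: frozenset[str]
    aliases: dict[str, str]  # lowercase alias -> canonical

    def canonical(self, name: str) -> str:
        return self.aliases.get(name.strip().lower(), name.strip())

    def contains(self, name: str) -> bool:
        if name.strip().upper() == "NA" or not name.strip():
            return False
        return self.canonical(name) in self.genes


@dataclass(frozen=True)
class OutcomeTally:
    total: int
    ns: int
    sig_up: int
    sig_down: int
    direction_only: int


def _data_path(name: str) -> Path:
    return Path(resources.files("refnorm").joinpath("data", name))  # type: ignore[arg-type]


def _read_tsv(name: str) -> list[dict[str, str]]:
    path = _data_path(name)
    with path.open(encoding="utf-8") as fh:
        lines = [l for l in fh if not l.startswith("#")]
    reader = csv.DictReader(lines, delimiter="\t")
    return [row for row in reader]


def data_checksum(name: str = "evidence_table.tsv") -> str:
    """SHA-256 of a packaged data file — pins the transcription for tests."""
    return hashlib.sha256(_data_path(name).read_bytes()).hexdigest()


def load_evidence_table() -> list[EvidenceEntry]:
    """Load and schema-validate the packaged evidence transcription."""
    entries = []
    for i, row in enumerate(_read_tsv("evidence_table.tsv"), start=1):
        if row.get("study_ref") in (None, ""):
            raise ValidationError(f"evidence row {i}: missing study_ref")
        try:
            stars = int(row["stars"])
        except (KeyError, ValueError):
            raise ValidationError(f"evidence row {i}: bad star count") from None
        entries.append(EvidenceEntry(
            study_ref=row["study_ref"],
            species=row["species"],
            tissue=row["tissue"],
            dose=row["dose"],
            regimen=row["regimen"],
            n=row["n"],
            assay=row["assay"],
            normalizer=row["normalizer"],
            effect_size=row["effect_size"],
            outcome=row["outcome"],
            significance_stars=stars,
            note=row.get("note") or "",
        ))
    return entries


def load_affected_normalizers() -> AffectedNormalizerList:
    genes = frozenset(row["gene"] for row in _read_tsv("affected_normalizers.tsv"))
    if not genes:
        raise ValidationError("affected-normalizer list is empty")
    aliases = {
        row["alias"].strip().lower(): row["canonical"].strip()
        for row in _read_tsv("normalizer_aliases.tsv")
    }
    return AffectedNormalizerList(genes=genes, aliases=aliases)


def tally_outcomes(entries: list[EvidenceEntry]) -> OutcomeTally:
    """Partition a (possibly filtered) entry list by outcome category."""
    counts = {code: 0 for code in OUTCOME_CODES}
    for e in entries:
        counts[e.outcome] += 1
    return OutcomeTally(
        total=len(entries),
        ns=counts["NS"],
        sig_up=counts["sig_up"],
        sig_down=counts["sig_down"],
        direction_only=counts["direction_only"],
    )


def tally_affected_normalizers(
    entries: list[EvidenceEntry],
    affected: AffectedNormalizerList,
    distinct: bool = True,
) -> int:
    """Count significant-upregulation set-ups normalized to an affected gene.

    Matching is case-insensitive through the packaged alias table.  With
    ``distinct=True`` (default) the count is over distinct
    (study, canonical normalizer) combinations — one study measuring two
    tissues against the same normalizer contributes once, while one study
    using two different affected normalizers contributes twice.  With
    ``distinct=False`` every matching set-up is counted individually.
    """
    matches = [
        (e.study_ref, affected.canonical(e.normalizer))
        for e in entries
        if e.outcome == "sig_up" and affected.contains(e.normalizer)
    ]
    if distinct:
        return len(set(matches))
    return len(matches)


def filter_entries(
    entries: list[EvidenceEntry],
    assay: str | None = None,
    species: str | None = None,
) -> list[EvidenceEntry]:
    out = entries
    if assay is not None:
        if assay not in ASSAY_CODES:
            raise ValidationError(f"unknown assay code {assay!r}")
        out = [e for e in out if e.assay == assay]
    if species is not None:
        out = [e for e in out if e.species.lower() == species.lower()]
    return out
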