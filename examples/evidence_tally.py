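"""Tallies over the packaged literature-evidence table.

The package ships a curated transcription of 49 published experimental
set-ups assessing lithium's effect on BCL2 transcript/protein levels,
plus the list of normalizing genes/proteins themselves reported as
altered by lithium or disease state.  The tallies show how thin the
evidence for the widely-assumed BCL2 upregulation is — and how often the
positive reports leaned on an unstable normalizer.
"""

from refnorm.evidence import (
    filter_entries,
    load_affected_normalizers,
    load_evidence_table,
    tally_affected_normalizers,
    tally_outcomes,
)

entries = load_evidence_table()
affected = load_affected_normalizers()

t = tally_outcomes(entries)
print(f"experimental set-ups curated:        {t.total}")
print(f"  no significant effect:             {t.ns}")
print(f"  significant upregulation:          {t.sig_up}")
print(f"  significant downregulation:        {t.sig_down}")
print(f"  direction only (no statistics):    {t.direction_only}")

n_affected = tally_affected_normalizers(entries, affected)
print(f"upregulation set-ups normalized to a lithium-affected gene: {n_affected}")

ma = tally_outcomes(filter_entries(entries, assay="MA"))
print(f"microarray set-ups: {ma.total}, with significant upregulation: {ma.sig_up}")
print()
print("Every microarray study — which needs no reference gene — found nothing.")
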