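import numpy as np
import pytest

from refnorm.io import CqRecord, QpcrDataset


def make_dataset(cq_by_sample_gene, control_label="RF", plate="P1"):
    """Build a QpcrDataset from {(sample, group, gene): (cq, cq, ...)}."""
    records = [
        CqRecord(sample_id=s, group_label=g, gene_id=gene, plate_id=plate,
                 replicate_cq=tuple(cqs))
        for (s, g, gene), cqs in cq_by_sample_gene.items()
    ]
    return QpcrDataset(records=records, control_label=control_label)


@pytest.fixture
def small_dataset():
    """Balanced 2-group, 2-gene dataset with clean duplicates."""
    data = {}
    base = {"TGT": 30.0, "REF": 26.0}
    for i, (sample, group) in enumerate(
        [("c1", "RF"), ("c2", "RF"), ("c3", "RF"),
         ("t1", "Li"), ("t2", "Li"), ("t3", "Li")]
    ):
        for gene, cq in base.items():
            val = cq + 0.1 * i
            data[(sample, group, gene)] = (val, val)
    return make_dataset(data)
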