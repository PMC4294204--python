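import numpy as np
import pytest

from cpdscreen.alignment import AlignedRecord, Alignment


def build_alignment(rows, reference_id="REF", molecule="nucleotide"):
    """Construct an Alignment from (id, seq) or (id, seq, labels) tuples."""
    records = []
    for row in rows:
        rid, seq, *rest = row
        labels = tuple(rest[0]) if rest else ()
        records.append(AlignedRecord(id=rid, seq=seq, clade_labels=labels))
    return Alignment(records, reference_id=reference_id, molecule=molecule)


@pytest.fixture
def toy_nt_alignment():
    """Reference plus four taxa over ten columns, one reference gap."""
    return build_alignment(
        [
            ("REF", "AC-GTACGTA"),
            ("sp1", "ACAGTACGTA"),
            ("sp2", "ACAGTACGTT"),
            ("sp3", "ACAGAACGTA"),
            ("sp4", "AC-GTACGTA"),
        ]
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240114)


def random_dated_newick(rng, n_tips):
    """Random binary ultrametric tree in newick, tips t0..t{n-1}."""
    nodes = [(f"t{i}", 0.0) for i in range(n_tips)]
    age = 0.0
    while len(nodes) > 1:
        age += float(rng.uniform(0.5, 2.0))
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b_newick, b_age = nodes.pop(j)
        a_newick, a_age = nodes.pop(i)
        merged = f"({a_newick}:{age - a_age:.6f},{b_newick}:{age - b_age:.6f})"
        nodes.append((merged, age))
    return nodes[0][0] + ";"
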