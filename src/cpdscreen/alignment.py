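"""Reading, validating and coordinate-mapping multiple sequence alignments.

The screen consumes pre-computed alignments (FASTA, gap character ``-``)
with one designated *reference* row: the human sequence in rCRS numbering
for the mitochondrial 12S rRNA gene, or the human/macaque protein for
MRPS12.  All public coordinates are 1-based and closed, matching the
``m.NNNN`` convention of mitochondrial genetics: ``m.1494`` is the 1494th
base of the reference sequence, gaps excluded.

Taxonomy labels (family, subfamily, tribe) used for per-clade tallies are
carried either pipe-delimited in the FASTA header after the id
(``>Macaca_mulatta|Cercopithecidae|Cercopithecinae|Papionini``) or in a
sidecar TSV with columns ``id``, ``family``, ``subfamily``, ``tribe``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping

from Bio import SeqIO

from .errors import (
    AlignmentFormatError,
    AlignmentShapeError,
    MissingReferenceError,
    PositionRangeError,
)

Molecule = Literal["nucleotide", "protein"]

GAP = "-"
NT_CANONICAL = set("ACGTN-")
# IUPAC ambiguity codes collapsed to N: CI needs a single "unresolved" class.
NT_AMBIGUOUS = set("RYSWKMBDHV")
AA_CANONICAL = set("ACDEFGHIKLMNPQRSTVWYX-")


@dataclass(frozen=True)
class AlignedRecord:
    """One row of an alignment: taxon id, ordered clade labels, gapped sequence."""

    id: str
    seq: str
    clade_labels: tuple[str, ...] = ()

    def ungapped(self) -> str:
        return self.seq.replace(GAP, "")


def _normalize_seq(raw: str, molecule: Molecule, record_id: str) -> str:
    """Uppercase; for nucleotide, U→T and ambiguity codes→N (with a warning)."""
    seq = raw.upper()
    if molecule == "nucleotide":
        seq = seq.replace("U", "T")
        bad = set(seq) - NT_CANONICAL
        if bad & NT_AMBIGUOUS:
            warnings.warn(
                f"record {record_id!r}: ambiguity codes "
                f"{sorted(bad & NT_AMBIGUOUS)} replaced by N",
                stacklevel=3,
            )
            seq = "".join("N" if c in NT_AMBIGUOUS else c for c in seq)
            bad = set(seq) - NT_CANONICAL
        if bad:
            raise AlignmentFormatError(
                f"record {record_id!r}: characters {sorted(bad)} are not valid "
                "nucleotide alignment symbols"
            )
    else:
        bad = set(seq) - AA_CANONICAL
        if bad:
            raise AlignmentFormatError(
                f"record {record_id!r}: characters {sorted(bad)} are not valid "
                "protein alignment symbols"
            )
    return seq


class Alignment:
    """A validated, equal-length gapped alignment with one reference row.

    Parameters
    ----------
    records
        Aligned records; sequences must already be normalized (uppercase,
        T not U) or be passed through :func:`read_fasta_alignment`.
    reference_id
        Id of the reference row (present exactly once).
    molecule
        ``"nucleotide"`` or ``"protein"``.
    """

    def __init__(self, records: Iterable[AlignedRecord], reference_id: str,
                 molecule: Molecule = "nucleotide"):
        self.records: list[AlignedRecord] = list(records)
        self.reference_id = reference_id
        self.molecule: Molecule = molecule
        if len(self.records) < 2:
            raise AlignmentShapeError("an alignment needs at least 2 records")
        lengths = {len(r.seq) for r in self.records}
        if len(lengths) != 1:
            raise AlignmentShapeError(
                f"records have unequal lengths: {sorted(lengths)}"
            )
        self.length = lengths.pop()
        hits = [r for r in self.records if r.id == reference_id]
        if len(hits) != 1:
            raise MissingReferenceError(
                f"reference id {reference_id!r} occurs {len(hits)} times "
                "(must occur exactly once)"
            )
        self._reference = hits[0]
        # column index (0-based) of each ungapped reference position
        self._ref_columns = [
            i for i, c in enumerate(self._reference.seq) if c != GAP
        ]
        if not self._ref_columns:
            raise AlignmentShapeError("reference row contains only gaps")

    # -- basic accessors ---------------------------------------------------

    @property
    def reference(self) -> AlignedRecord:
        return self._reference

    @property
    def n_records(self) -> int:
        return len(self.records)

    def non_reference_records(self) -> list[AlignedRecord]:
        return [r for r in self.records if r.id != self.reference_id]

    @property
    def ungapped_reference_length(self) -> int:
        return len(self._ref_columns)

    # -- coordinate mapping ------------------------------------------------

    def map_reference_position(self, ref_pos: int) -> int:
        """Alignment column (1-based) holding the ``ref_pos``-th reference base.

        ``ref_pos`` is 1-based in ungapped reference coordinates (rCRS for
        the 12S gene, protein numbering for MRPS12).
        """
        if not 1 <= ref_pos <= len(self._ref_columns):
            raise PositionRangeError(
                f"reference position {ref_pos} outside 1.."
                f"{len(self._ref_columns)}"
            )
        return self._ref_columns[ref_pos - 1] + 1

    def column_states(self, column: int) -> dict[str, str]:
        """Mapping taxon id → single character at a 1-based column (gaps kept)."""
        if not 1 <= column <= self.length:
            raise PositionRangeError(
                f"column {column} outside 1..{self.length}"
            )
        return {r.id: r.seq[column - 1] for r in self.records}

    def reference_state(self, ref_pos: int) -> str:
        return self._reference.seq[self.map_reference_position(ref_pos) - 1]


def read_taxonomy_table(path: str | Path) -> dict[str, tuple[str, ...]]:
    """Read a sidecar TSV (id, family, subfamily, tribe) into a label map.

    A header row is recognised by its first cell being ``id`` and skipped.
    Trailing empty ranks are dropped so partial taxonomies are allowed.
    """
    labels: dict[str, tuple[str, ...]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            cells = line.split("\t")
            if cells[0].strip().lower() == "id":
                continue
            tags = tuple(c.strip() for c in cells[1:])
            while tags and not tags[-1]:
                tags = tags[:-1]
            labels[cells[0].strip()] = tags
    return labels


def read_fasta_alignment(
    path: str | Path,
    reference_id: str,
    molecule: Molecule = "nucleotide",
    taxonomy: Mapping[str, tuple[str, ...]] | str | Path | None = None,
) -> Alignment:
    """Read and validate an aligned FASTA file.

    Headers may carry pipe-delimited clade labels after the id; a sidecar
    taxonomy table (path or mapping) overrides header labels per id.
    Sequences are normalized: uppercase, and U→T for nucleotide input.
    """
    if taxonomy is not None and not isinstance(taxonomy, Mapping):
        taxonomy = read_taxonomy_table(taxonomy)

    records: list[AlignedRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        parts = rec.id.split("|")
        rid, labels = parts[0], tuple(parts[1:])
        if taxonomy is not None and rid in taxonomy:
            labels = tuple(taxonomy[rid])
        records.append(
            AlignedRecord(
                id=rid,
                seq=_normalize_seq(str(rec.seq), molecule, rid),
                clade_labels=labels,
            )
        )
    if not records:
        raise AlignmentFormatError(f"{path}: no FASTA records found")
    return Alignment(records, reference_id=reference_id, molecule=molecule)


def write_fasta_alignment(aln: Alignment, path: str | Path) -> None:
    """Write the alignment back to FASTA, clade labels pipe-delimited."""
    with open(path, "w") as fh:
        for rec in aln.records:
            header = "|".join((rec.id, *rec.clade_labels))
            fh.write(f">{header}\n{rec.seq}\n")
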