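"""Structural proximity of candidate protein residues to an rRNA nucleotide.

Candidate compensatory residues in a mitochondrial ribosomal protein are
screened by their distance, in a bacterial small-subunit ribosome crystal
structure, to the nucleotide homologous to the human pathogenic rRNA
position.  The module parses fixed-column PDB coordinate files, builds an
equivalence map between human numbering and structure residue numbers
(by global pairwise alignment, or from a curated table), and reports the
minimum inter-atomic distance between selections.

Defaults follow what a crystal structure at ribosome resolution supports:
heavy atoms only (no hydrogens are present), all-against-all atom-pair
minimum distance, and a strict ``< threshold`` contact test with the
threshold defaulting to 6 Å.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
from Bio.Align import PairwiseAligner
from Bio.PDB import PDBParser
from Bio.PDB.Polypeptide import protein_letters_3to1
from scipy.spatial.distance import cdist

from .errors import (
    LowConfidenceMappingError,
    MappingError,
    ModelRangeError,
    SelectionError,
    StructureParseError,
)

AtomClass = Literal["heavy", "all"]

# nucleotide residue names as they appear in PDB entries (RNA and DNA)
_NUC_NAMES = {
    "A": "A", "C": "C", "G": "G", "U": "U", "T": "T", "N": "N",
    "DA": "A", "DC": "C", "DG": "G", "DT": "T", "DN": "N",
}
_WATER_NAMES = {"HOH", "WAT", "DOD"}


@dataclass(frozen=True)
class Atom:
    chain: str
    residue_number: int
    residue_name: str
    atom_name: str
    element: str
    x: float
    y: float
    z: float


class StructureModel:
    """Atoms of one model of a coordinate file, with selection helpers."""

    def __init__(self, atoms: Sequence[Atom]):
        self.atoms: list[Atom] = list(atoms)
        self._coords = np.array(
            [(a.x, a.y, a.z) for a in self.atoms], dtype=float
        ).reshape(len(self.atoms), 3)
        if self.atoms and not np.isfinite(self._coords).all():
            raise StructureParseError("non-finite atomic coordinate")

    @property
    def coords(self) -> np.ndarray:
        return self._coords

    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.chain, None)
        return list(seen)

    def _select_indices(
        self, chain: str, residue_number: int, atom_class: AtomClass
    ) -> np.ndarray:
        idx = [
            i
            for i, a in enumerate(self.atoms)
            if a.chain == chain
            and a.residue_number == residue_number
            and (atom_class == "all" or a.element.upper() != "H")
        ]
        return np.array(idx, dtype=int)

    def chain_sequence(self, chain: str) -> tuple[str, list[int]]:
        """One-letter sequence of a chain plus its residue numbers, in
        order of appearance.  Unknown residue names become X (protein)
        or N (nucleotide)."""
        seq: list[str] = []
        numbers: list[int] = []
        seen: set[int] = set()
        for a in self.atoms:
            if a.chain != chain or a.residue_number in seen:
                continue
            seen.add(a.residue_number)
            name = a.residue_name.strip().upper()
            if name in _NUC_NAMES:
                seq.append(_NUC_NAMES[name].replace("U", "T"))
            else:
                seq.append(protein_letters_3to1.get(name, "X"))
            numbers.append(a.residue_number)
        return "".join(seq), numbers


def read_structure(
    path: str | Path, model_index: int = 0, include_waters: bool = False
) -> StructureModel:
    """Parse a fixed-column PDB file into a StructureModel.

    ``model_index`` selects among MODEL records (0-based; single-model
    files have exactly one).  For atoms with alternate locations the
    highest-occupancy conformer is kept; waters are excluded by default.
    """
    parser = PDBParser(PERMISSIVE=True, QUIET=True)
    try:
        structure = parser.get_structure("model", str(path))
    except Exception as exc:
        raise StructureParseError(f"{path}: {exc}") from exc
    models = list(structure)
    if not models:
        raise StructureParseError(f"{path}: no atoms parsed")
    if not 0 <= model_index < len(models):
        raise ModelRangeError(
            f"model index {model_index} out of range (file has "
            f"{len(models)} model(s))"
        )
    atoms: list[Atom] = []
    for chain in models[model_index]:
        for residue in chain:
            resname = residue.get_resname().strip()
            if not include_waters and (
                residue.id[0] == "W" or resname in _WATER_NAMES
            ):
                continue
            # residue.get_atoms() yields the selected (highest-occupancy)
            # conformer of disordered atoms
            for atom in residue.get_atoms():
                x, y, z = atom.get_coord()
                atoms.append(
                    Atom(
                        chain=chain.id,
                        residue_number=residue.id[1],
                        residue_name=resname,
                        atom_name=atom.get_name(),
                        element=(atom.element or "").strip(),
                        x=float(x), y=float(y), z=float(z),
                    )
                )
    if not atoms:
        raise StructureParseError(f"{path}: model contains no usable atoms")
    return StructureModel(atoms)


@dataclass(frozen=True)
class EquivalenceMap:
    """Injective map query position (1-based) → structure residue number."""

    chain: str
    mapping: Mapping[int, int]
    method: str  # "table" | "pairwise_alignment"

    def resolve(self, query_pos: int) -> int | None:
        return self.mapping.get(query_pos)


def equivalence_from_table(
    rows: Mapping[int, int] | Sequence[tuple[int, int]], chain: str
) -> EquivalenceMap:
    mapping = dict(rows) if isinstance(rows, Mapping) else dict(rows)
    if len(set(mapping.values())) != len(mapping):
        raise MappingError("equivalence table is not injective")
    return EquivalenceMap(chain=chain, mapping=mapping, method="table")


def read_equivalence_table(path: str | Path) -> dict[str, dict[int, int]]:
    """TSV columns query_pos, chain, residue_number → per-chain mapping."""
    per_chain: dict[str, dict[int, int]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            cells = [c.strip() for c in line.split("\t")]
            if cells[0].lower() == "query_pos":
                continue
            per_chain.setdefault(cells[1], {})[int(cells[0])] = int(cells[2])
    return per_chain


def build_equivalence(
    query_seq: str,
    structure_seq: str,
    residue_numbers: Sequence[int],
    chain: str,
    min_coverage: float = 0.5,
) -> EquivalenceMap:
    """Map query positions onto structure residue numbers by global
    pairwise alignment (match +1, mismatch −1, gap open −5, extend −1).

    Raises :class:`LowConfidenceMappingError` when fewer than
    ``min_coverage`` of the query positions end up aligned to a residue.
    """
    if not query_seq or not structure_seq:
        raise MappingError("both sequences must be non-empty")
    if len(structure_seq) != len(residue_numbers):
        raise MappingError("structure sequence and residue numbers disagree")
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -1
    alignment = aligner.align(query_seq.upper(), structure_seq.upper())[0]
    mapping: dict[int, int] = {}
    for (q_start, q_end), (s_start, s_end) in zip(*alignment.aligned):
        for offset in range(q_end - q_start):
            mapping[q_start + offset + 1] = residue_numbers[s_start + offset]
    coverage = len(mapping) / len(query_seq)
    if coverage < min_coverage:
        raise LowConfidenceMappingError(
            f"alignment covered {coverage:.0%} of the query "
            f"(< {min_coverage:.0%}); supply a curated equivalence table"
        )
    return EquivalenceMap(chain=chain, mapping=mapping,
                          method="pairwise_alignment")


def min_distance(
    model: StructureModel,
    sel_a: tuple[str, int],
    sel_b: tuple[str, int],
    atom_class: AtomClass = "heavy",
) -> float:
    """Minimum Euclidean distance (Å) over all atom pairs between two
    (chain, residue number) selections."""
    if sel_a == sel_b:
        raise SelectionError("the two selections must differ")
    idx_a = model._select_indices(*sel_a, atom_class)
    idx_b = model._select_indices(*sel_b, atom_class)
    if idx_a.size == 0 or idx_b.size == 0:
        empty = sel_a if idx_a.size == 0 else sel_b
        raise SelectionError(
            f"selection {empty} is empty after {atom_class}-atom filtering"
        )
    return float(cdist(model.coords[idx_a], model.coords[idx_b]).min())


@dataclass(frozen=True)
class ProximityResult:
    candidate_position: int
    chain: str | None
    residue_number: int | None
    min_distance_a: float | None
    within_threshold: bool | None
    threshold_a: float
    status: str  # "ok" | "unresolved"


def proximity_filter(
    model: StructureModel,
    candidates: Sequence[int],
    site: int,
    map_protein: EquivalenceMap,
    map_rna: EquivalenceMap,
    threshold_a: float = 6.0,
    atom_class: AtomClass = "heavy",
) -> list[ProximityResult]:
    """Distance of each candidate protein position to the target nucleotide.

    ``within_threshold`` uses a strict ``<`` comparison.  Candidates absent
    from the protein map are reported with status ``unresolved`` rather
    than dropped; an unmappable *site* is an error, since nothing could be
    measured at all.
    """
    site_residue = map_rna.resolve(site)
    if site_residue is None:
        raise MappingError(f"site position {site} has no structural equivalent")
    site_sel = (map_rna.chain, site_residue)
    results: list[ProximityResult] = []
    for pos in candidates:
        residue = map_protein.resolve(pos)
        if residue is None:
            results.append(
                ProximityResult(
                    candidate_position=pos, chain=None, residue_number=None,
                    min_distance_a=None, within_threshold=None,
                    threshold_a=threshold_a, status="unresolved",
                )
            )
            continue
        d = min_distance(
            model, (map_protein.chain, residue), site_sel, atom_class
        )
        results.append(
            ProximityResult(
                candidate_position=pos,
                chain=map_protein.chain,
                residue_number=residue,
                min_distance_a=d,
                within_threshold=bool(d < threshold_a),
                threshold_a=threshold_a,
                status="ok",
            )
        )
    return results
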