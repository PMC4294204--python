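"""Synthetic inputs with exactly specified statistical/geometric structure.

Real inputs to the screen — hundreds of GenBank rRNA orthologs, a dated
primate phylogeny, a ribosome crystal structure — cannot be bundled or
downloaded at test time.  These generators build stand-ins whose relevant
summary statistics are *specified exactly*: an alignment column with a
declared number of wild-type matches, a tree whose named nodes carry
declared ages in Mya, a coordinate file where each candidate residue sits
at a declared minimum distance from the target site.  There is no
evolutionary model here: columns are specified by counts, not simulated
along the tree, so generated data exercises the measurement code, not the
mutation process.

Every generator is a deterministic function of (spec, seed): one named
pseudorandom stream per call, no global state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import yaml

from .alignment import AlignedRecord, Alignment
from .dating import DatedTree, State, parse_dated_newick
from .errors import SpecError

NT_ALPHABET = "ACGT"
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


# ---------------------------------------------------------------------------
# alignments
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ColumnSpec:
    """Exact composition of one reference-position column.

    Counts refer to the ``n_records`` non-reference rows:
    ``n_match`` carry the wild-type state, ``n_other`` a different
    (non-gap) character — ``other_state`` if given, else uniformly random
    non-wildtype — and ``n_gap`` a gap; they must sum to ``n_records``.

    ``placement`` controls which rows receive which state: ``"shuffled"``
    (default) assigns by a seeded permutation; ``"ordered"`` walks rows in
    alignment order (matches first, then others, then gaps), which lets a
    taxonomy-block layout decide exactly which clade carries each state.
    """

    ref_position: int
    wildtype: str
    n_match: int
    n_other: int = 0
    n_gap: int = 0
    other_state: str | None = None
    placement: Literal["shuffled", "ordered"] = "shuffled"


@dataclass(frozen=True)
class AlignmentSpec:
    """Recipe for a synthetic orthologous alignment.

    ``n_records`` counts the analysis (non-reference) sequences; the
    reference row is added on top, so CI denominators equal ``n_records``.
    Unspecified columns are drawn i.i.d.: each row matches the reference
    with probability ``match_prob`` (default 0.776, the mean per-position
    conservation observed across mammals for the mitochondrial 12S gene).
    ``taxonomy`` assigns clade labels to consecutive blocks of rows.
    """

    n_records: int
    length: int
    reference_id: str = "Homo_sapiens"
    reference_seq: str | None = None
    molecule: Literal["nucleotide", "protein"] = "nucleotide"
    column_specs: tuple[ColumnSpec, ...] = ()
    taxonomy: tuple[tuple[tuple[str, ...], int], ...] = ()
    match_prob: float = 0.776
    seed: int = 0


def _validate_alignment_spec(spec: AlignmentSpec) -> None:
    if spec.n_records < 1 or spec.length < 1:
        raise SpecError("n_records and length must be positive")
    if not 0.0 <= spec.match_prob <= 1.0:
        raise SpecError("match_prob must lie in [0, 1]")
    seen: set[int] = set()
    for col in spec.column_specs:
        if not 1 <= col.ref_position <= spec.length:
            raise SpecError(
                f"column position {col.ref_position} outside 1..{spec.length}"
            )
        if col.ref_position in seen:
            raise SpecError(f"duplicate column spec at {col.ref_position}")
        seen.add(col.ref_position)
        if min(col.n_match, col.n_other, col.n_gap) < 0:
            raise SpecError("column counts must be non-negative")
        if col.n_match + col.n_other + col.n_gap != spec.n_records:
            raise SpecError(
                f"column {col.ref_position}: counts "
                f"{col.n_match}+{col.n_other}+{col.n_gap} != "
                f"n_records {spec.n_records}"
            )
        if col.other_state is not None and (
            col.other_state.upper() == col.wildtype.upper()
            or col.other_state == "-"
        ):
            raise SpecError(
                f"column {col.ref_position}: other_state must be a "
                "non-gap character different from the wild type"
            )
    if spec.taxonomy and sum(c for _, c in spec.taxonomy) != spec.n_records:
        raise SpecError("taxonomy block counts must sum to n_records")
    if spec.reference_seq is not None and len(spec.reference_seq) != spec.length:
        raise SpecError("reference_seq length disagrees with spec length")


def _record_ids(spec: AlignmentSpec) -> list[tuple[str, tuple[str, ...]]]:
    ids: list[tuple[str, tuple[str, ...]]] = []
    if spec.taxonomy:
        for labels, count in spec.taxonomy:
            stem = labels[-1] if labels else "taxon"
            for i in range(count):
                ids.append((f"{stem}_{i + 1:03d}", tuple(labels)))
    else:
        ids = [(f"taxon_{i + 1:04d}", ()) for i in range(spec.n_records)]
    return ids


def make_alignment(spec: AlignmentSpec) -> Alignment:
    """Generate an alignment whose specified columns have exact counts."""
    _validate_alignment_spec(spec)
    rng = np.random.default_rng(spec.seed)
    alphabet = NT_ALPHABET if spec.molecule == "nucleotide" else AA_ALPHABET
    letters = np.array(list(alphabet))

    if spec.reference_seq is not None:
        ref = np.array(list(spec.reference_seq.upper()))
    else:
        ref = rng.choice(letters, size=spec.length)
    # a declared wild-type state overrides the drawn reference character
    for col in spec.column_specs:
        ref[col.ref_position - 1] = col.wildtype.upper()

    n, length = spec.n_records, spec.length
    matrix = np.tile(ref, (n, 1))
    specified = {c.ref_position for c in spec.column_specs}

    for j in range(length):
        if (j + 1) in specified:
            continue
        mismatch = rng.random(n) >= spec.match_prob
        if mismatch.any():
            others = letters[letters != ref[j]]
            matrix[mismatch, j] = rng.choice(others, size=int(mismatch.sum()))

    for col in spec.column_specs:
        j = col.ref_position - 1
        order = (np.arange(n) if col.placement == "ordered"
                 else rng.permutation(n))
        match_rows = order[: col.n_match]
        other_rows = order[col.n_match: col.n_match + col.n_other]
        gap_rows = order[col.n_match + col.n_other:]
        matrix[match_rows, j] = col.wildtype.upper()
        if other_rows.size:
            if col.other_state is not None:
                matrix[other_rows, j] = col.other_state.upper()
            else:
                others = letters[letters != col.wildtype.upper()]
                matrix[other_rows, j] = rng.choice(others, size=other_rows.size)
        matrix[gap_rows, j] = "-"

    records = [AlignedRecord(id=spec.reference_id, seq="".join(ref))]
    for (rid, labels), row in zip(_record_ids(spec), matrix):
        records.append(AlignedRecord(id=rid, seq="".join(row),
                                     clade_labels=labels))
    return Alignment(records, reference_id=spec.reference_id,
                     molecule=spec.molecule)


# ---------------------------------------------------------------------------
# dated trees with tip states
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CladeSpec:
    """A named clade: either an internal node (age in Mya + children/tips)
    or a single tip (age None, no children)."""

    name: str
    age: float | None = None
    children: tuple["CladeSpec", ...] = ()
    tips: tuple[str, ...] = ()

    def is_tip(self) -> bool:
        return not self.children and not self.tips


@dataclass(frozen=True)
class CharacterSpec:
    """Tip-state rules for one binary character: tips under any clade in
    ``derived_clades`` are derived, under ``unknown_clades`` unknown,
    otherwise ancestral; per-tip ``exceptions`` applied last."""

    derived_clades: tuple[str, ...] = ()
    unknown_clades: tuple[str, ...] = ()
    exceptions: Mapping[str, State] = field(default_factory=dict)


@dataclass(frozen=True)
class TreeSpec:
    root: CladeSpec
    characters: Mapping[str, CharacterSpec] = field(default_factory=dict)
    seed: int = 0


def _clade_tips(clade: CladeSpec) -> list[str]:
    if clade.is_tip():
        return [clade.name]
    tips = list(clade.tips)
    for child in clade.children:
        tips.extend(_clade_tips(child))
    return tips


def _newick(clade: CladeSpec, parent_age: float | None) -> str:
    if clade.is_tip():
        if clade.age is not None:
            raise SpecError(f"tip {clade.name!r} must not carry an age")
        if parent_age is None:
            raise SpecError("a single-tip tree has no dated root")
        return f"{clade.name}:{parent_age:g}"
    if clade.age is None:
        raise SpecError(f"internal clade {clade.name!r} needs an age")
    if parent_age is not None and clade.age >= parent_age:
        raise SpecError(
            f"clade {clade.name!r} age {clade.age} must be younger than its "
            f"parent's age {parent_age}"
        )
    parts = [_newick(child, clade.age) for child in clade.children]
    parts += [f"{tip}:{clade.age:g}" for tip in clade.tips]
    if len(parts) < 2:
        raise SpecError(f"internal clade {clade.name!r} needs >= 2 descendants")
    inner = ",".join(parts)
    length = "" if parent_age is None else f":{parent_age - clade.age:g}"
    return f"({inner}){clade.name}{length}"


def tree_newick(spec: TreeSpec) -> str:
    """Deterministic newick serialization (branch lengths in Myr)."""
    return _newick(spec.root, None) + ";"


def make_dated_tree(spec: TreeSpec) -> tuple[DatedTree, dict[str, dict[str, State]]]:
    """Build the dated tree and per-character tip states from a TreeSpec."""
    tree = parse_dated_newick(tree_newick(spec))

    membership: dict[str, list[str]] = {}

    def collect(clade: CladeSpec) -> None:
        membership[clade.name] = _clade_tips(clade)
        for child in clade.children:
            collect(child)

    collect(spec.root)
    all_tips = membership[spec.root.name]

    states: dict[str, dict[str, State]] = {}
    for char, rules in spec.characters.items():
        for name in (*rules.derived_clades, *rules.unknown_clades):
            if name not in membership and name not in all_tips:
                raise SpecError(f"character {char!r} names unknown clade {name!r}")
        tip_state: dict[str, State] = {t: "ancestral" for t in all_tips}
        for name in rules.unknown_clades:
            for t in membership.get(name, [name]):
                tip_state[t] = "unknown"
        for name in rules.derived_clades:
            for t in membership.get(name, [name]):
                tip_state[t] = "derived"
        for tip, state in rules.exceptions.items():
            if tip not in tip_state:
                raise SpecError(f"exception names unknown tip {tip!r}")
            tip_state[tip] = state
        states[char] = tip_state
    return tree, states


def primate_screen_tree() -> TreeSpec:
    """Dated catarrhine tree used by the screen's worked example.

    Node ages follow published primate divergence estimates: apes split
    from Old World monkeys 32 Mya; the Cercopithecidae crown is 18 Mya;
    the Cercopithecini–Papionini split 12 Mya; the Papionini crown 8 Mya.
    Two characters are scored: the 12S rRNA m.1494T allele, fixed across
    Cercopithecidae save a single reversion in *Papio ursinus*; and the
    MRPS12 p.R68L substitution, found in Papionini, absent from the
    sampled Cercopithecini, and ungenotyped (unknown) in Colobinae.
    """
    root = CladeSpec(
        name="Catarrhini", age=32.0,
        children=(
            CladeSpec(
                name="Hominoidea", age=20.0,
                tips=("Homo_sapiens", "Pan_paniscus", "Pongo_pygmaeus"),
            ),
            CladeSpec(
                name="Cercopithecidae", age=18.0,
                children=(
                    CladeSpec(
                        name="Colobinae", age=13.0,
                        tips=("Procolobus_verus", "Trachypithecus_obscurus",
                              "Rhinopithecus_roxellana"),
                    ),
                    CladeSpec(
                        name="Cercopithecinae", age=12.0,
                        children=(
                            CladeSpec(
                                name="Cercopithecini", age=9.0,
                                tips=("Chlorocebus_sabaeus",
                                      "Chlorocebus_aethiops",
                                      "Erythrocebus_patas"),
                            ),
                            CladeSpec(
                                name="Papionini", age=8.0,
                                tips=("Macaca_mulatta", "Macaca_nemestrina",
                                      "Papio_ursinus", "Theropithecus_gelada"),
                            ),
                        ),
                    ),
                ),
            ),
        ),
    )
    characters = {
        "mt_1494T": CharacterSpec(
            derived_clades=("Cercopithecidae",),
            exceptions={"Papio_ursinus": "ancestral"},
        ),
        "mrps12_L68": CharacterSpec(
            derived_clades=("Papionini",),
            unknown_clades=("Colobinae",),
        ),
    }
    return TreeSpec(root=root, characters=characters)


# ---------------------------------------------------------------------------
# toy coordinate files
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CandidateSpec:
    """A candidate residue placed at an exact minimum distance (Å) from
    the site selection."""

    residue_number: int
    distance: float
    n_atoms: int = 3
    residue_name: str = "ALA"


@dataclass(frozen=True)
class GeometrySpec:
    site_atoms: tuple[tuple[float, float, float], ...] = ((0.0, 0.0, 0.0),)
    site_chain: str = "R"
    site_residue_number: int = 1
    site_residue_name: str = "C"
    candidate_chain: str = "P"
    candidates: tuple[CandidateSpec, ...] = ()
    seed: int = 0


def _pdb_atom_line(serial: int, name: str, resname: str, chain: str,
                   resseq: int, xyz: np.ndarray, element: str) -> str:
    pname = name if len(name) >= 4 else f" {name:<3s}"
    return (
        f"ATOM  {serial:5d} {pname:<4s} {resname:>3s} {chain:1s}"
        f"{resseq:4d}    {xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
        f"{1.00:6.2f}{0.00:6.2f}          {element:>2s}"
    )


def make_structure(spec: GeometrySpec) -> str:
    """Emit PDB-format text where each candidate's minimum heavy-atom
    distance to the site equals its declared distance (to < 1e-3 Å).

    Construction: draw a signed coordinate axis, place the candidate's
    closest atom at the declared radius from the extreme site atom along
    that direction (so no other site atom can be closer), and stack the
    remaining atoms strictly farther out along the same direction.  Axis-
    aligned placement keeps the distance exact through the file format's
    3-decimal coordinate rounding.
    """
    if not spec.site_atoms:
        raise SpecError("site needs at least one atom")
    rng = np.random.default_rng(spec.seed)
    site = np.asarray(spec.site_atoms, dtype=float).reshape(-1, 3)

    lines: list[str] = []
    serial = 1
    for i, xyz in enumerate(site):
        lines.append(
            _pdb_atom_line(serial, f"C{i + 1}", spec.site_residue_name,
                           spec.site_chain, spec.site_residue_number, xyz, "C")
        )
        serial += 1

    for cand in spec.candidates:
        if cand.distance < 0:
            raise SpecError("declared distance must be non-negative")
        if cand.n_atoms < 1:
            raise SpecError("a candidate needs at least one atom")
        u = np.zeros(3)
        u[rng.integers(3)] = rng.choice([-1.0, 1.0])
        anchor = site[np.argmax(site @ u)]
        first = anchor + cand.distance * u
        for k in range(cand.n_atoms):
            xyz = first + (1.5 * k) * u
            lines.append(
                _pdb_atom_line(serial, f"C{k + 1}", cand.residue_name,
                               spec.candidate_chain, cand.residue_number,
                               xyz, "C")
            )
            serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"


def write_structure(spec: GeometrySpec, path: str | Path) -> None:
    Path(path).write_text(make_structure(spec))


# ---------------------------------------------------------------------------
# YAML spec files (CLI surface)
# ---------------------------------------------------------------------------

def alignment_spec_from_dict(data: Mapping) -> AlignmentSpec:
    cols = tuple(
        ColumnSpec(
            ref_position=int(c["ref_position"]),
            wildtype=str(c["wildtype"]),
            n_match=int(c["n_match"]),
            n_other=int(c.get("n_other", 0)),
            n_gap=int(c.get("n_gap", 0)),
            other_state=c.get("other_state"),
            placement=c.get("placement", "shuffled"),
        )
        for c in data.get("column_specs", [])
    )
    taxonomy = tuple(
        (tuple(block["labels"]), int(block["count"]))
        for block in data.get("taxonomy", [])
    )
    return AlignmentSpec(
        n_records=int(data["n_records"]),
        length=int(data["length"]),
        reference_id=data.get("reference_id", "Homo_sapiens"),
        reference_seq=data.get("reference_seq"),
        molecule=data.get("molecule", "nucleotide"),
        column_specs=cols,
        taxonomy=taxonomy,
        match_prob=float(data.get("match_prob", 0.776)),
        seed=int(data.get("seed", 0)),
    )


def _clade_from_dict(data: Mapping) -> CladeSpec:
    return CladeSpec(
        name=data["name"],
        age=None if data.get("age") is None else float(data["age"]),
        children=tuple(_clade_from_dict(c) for c in data.get("children", [])),
        tips=tuple(data.get("tips", [])),
    )


def tree_spec_from_dict(data: Mapping) -> TreeSpec:
    characters = {
        name: CharacterSpec(
            derived_clades=tuple(c.get("derived_clades", [])),
            unknown_clades=tuple(c.get("unknown_clades", [])),
            exceptions=dict(c.get("exceptions", {})),
        )
        for name, c in data.get("characters", {}).items()
    }
    return TreeSpec(
        root=_clade_from_dict(data["root"]),
        characters=characters,
        seed=int(data.get("seed", 0)),
    )


def geometry_spec_from_dict(data: Mapping) -> GeometrySpec:
    return GeometrySpec(
        site_atoms=tuple(tuple(map(float, a)) for a in
                         data.get("site_atoms", [(0.0, 0.0, 0.0)])),
        site_chain=data.get("site_chain", "R"),
        site_residue_number=int(data.get("site_residue_number", 1)),
        site_residue_name=data.get("site_residue_name", "C"),
        candidate_chain=data.get("candidate_chain", "P"),
        candidates=tuple(
            CandidateSpec(
                residue_number=int(c["residue_number"]),
                distance=float(c["distance"]),
                n_atoms=int(c.get("n_atoms", 3)),
                residue_name=c.get("residue_name", "ALA"),
            )
            for c in data.get("candidates", [])
        ),
        seed=int(data.get("seed", 0)),
    )


def load_spec(path: str | Path, kind: Literal["alignment", "tree", "structure"]):
    """Load a YAML spec file for one of the three generators."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if kind == "alignment":
        return alignment_spec_from_dict(data)
    if kind == "tree":
        return tree_spec_from_dict(data)
    if kind == "structure":
        return geometry_spec_from_dict(data)
    raise ValueError(f"unknown spec kind {kind!r}")
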