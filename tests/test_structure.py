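"""PDB parsing, numbering equivalence and minimum-distance filtering."""

import numpy as np
import pytest

from cpdscreen.errors import (
    LowConfidenceMappingError,
    MappingError,
    ModelRangeError,
    SelectionError,
)
from cpdscreen.structure import (
    Atom,
    StructureModel,
    build_equivalence,
    equivalence_from_table,
    min_distance,
    proximity_filter,
    read_equivalence_table,
    read_structure,
)


def pdb_line(serial, name, resname, chain, resseq, x, y, z,
             occ=1.00, altloc=" ", element="C", record="ATOM  "):
    pname = name if len(name) >= 4 else f" {name:<3s}"
    return (f"{record}{serial:5d} {pname:<4s}{altloc}{resname:>3s} "
            f"{chain}{resseq:4d}    {x:8.3f}{y:8.3f}{z:8.3f}"
            f"{occ:6.2f}{0.0:6.2f}          {element:>2s}")


class TestReadStructure:
    def test_three_atom_toy(self, tmp_path):
        p = tmp_path / "toy.pdb"
        p.write_text("\n".join([
            pdb_line(1, "CA", "ALA", "A", 1, 1.0, 2.0, 3.0),
            pdb_line(2, "CB", "ALA", "A", 1, 4.0, 5.0, 6.0),
            pdb_line(3, "CA", "GLY", "A", 2, 7.0, 8.0, 9.0),
            "END",
        ]) + "\n")
        model = read_structure(p)
        assert len(model.atoms) == 3
        assert model.atoms[0] == Atom("A", 1, "ALA", "CA", "C", 1.0, 2.0, 3.0)

    def test_highest_occupancy_altloc_kept(self, tmp_path):
        p = tmp_path / "alt.pdb"
        p.write_text("\n".join([
            pdb_line(1, "CA", "ALA", "A", 1, 0.0, 0.0, 0.0, occ=0.6,
                     altloc="A"),
            pdb_line(2, "CA", "ALA", "A", 1, 9.0, 9.0, 9.0, occ=0.4,
                     altloc="B"),
            "END",
        ]) + "\n")
        model = read_structure(p)
        assert len(model.atoms) == 1
        assert (model.atoms[0].x, model.atoms[0].y) == (0.0, 0.0)

    def test_model_selection(self, tmp_path):
        p = tmp_path / "multi.pdb"
        p.write_text("\n".join([
            "MODEL        1",
            pdb_line(1, "CA", "ALA", "A", 1, 0.0, 0.0, 0.0),
            "ENDMDL",
            "MODEL        2",
            pdb_line(1, "CA", "ALA", "A", 1, 5.0, 0.0, 0.0),
            "ENDMDL",
            "END",
        ]) + "\n")
        assert read_structure(p, model_index=1).atoms[0].x == 5.0
        with pytest.raises(ModelRangeError):
            read_structure(p, model_index=2)

    def test_waters_excluded_by_default(self, tmp_path):
        p = tmp_path / "wat.pdb"
        p.write_text("\n".join([
            pdb_line(1, "CA", "ALA", "A", 1, 0.0, 0.0, 0.0),
            pdb_line(2, "O", "HOH", "A", 100, 1.0, 1.0, 1.0, element="O",
                     record="HETATM"),
            "END",
        ]) + "\n")
        assert len(read_structure(p).atoms) == 1
        assert len(read_structure(p, include_waters=True).atoms) == 2

    def test_chain_sequence(self, tmp_path):
        p = tmp_path / "seq.pdb"
        p.write_text("\n".join([
            pdb_line(1, "CA", "ALA", "P", 10, 0.0, 0.0, 0.0),
            pdb_line(2, "CA", "GLY", "P", 11, 3.0, 0.0, 0.0),
            pdb_line(3, "CA", "ARG", "P", 13, 6.0, 0.0, 0.0),
            pdb_line(4, "C1'", "U", "R", 5, 9.0, 0.0, 0.0),
            "END",
        ]) + "\n")
        model = read_structure(p)
        assert model.chain_sequence("P") == ("AGR", [10, 11, 13])
        assert model.chain_sequence("R") == ("T", [5])  # U stored as T


def needleman_wunsch(a, b, match=1, mismatch=-1, gap_open=-5, gap_extend=-1):
    """Independent affine-gap global alignment returning the aligned pairs
    (0-based index in a, 0-based index in b)."""
    n, m = len(a), len(b)
    neg = float("-inf")
    M = np.full((n + 1, m + 1), neg)  # a[i-1] aligned to b[j-1]
    X = np.full((n + 1, m + 1), neg)  # gap in b (a consumed)
    Y = np.full((n + 1, m + 1), neg)  # gap in a (b consumed)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = gap_open + gap_extend * (i - 1)
    for j in range(1, m + 1):
        Y[0, j] = gap_open + gap_extend * (j - 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1],
                          Y[i - 1, j - 1]) + s
            X[i, j] = max(M[i - 1, j] + gap_open, X[i - 1, j] + gap_extend)
            Y[i, j] = max(M[i, j - 1] + gap_open, Y[i, j - 1] + gap_extend)
    # traceback
    i, j = n, m
    state = int(np.argmax([M[i, j], X[i, j], Y[i, j]]))
    pairs = []
    while i > 0 or j > 0:
        if state == 0:
            pairs.append((i - 1, j - 1))
            s = match if a[i - 1] == b[j - 1] else mismatch
            prev = [M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]]
            state = int(np.argmax(prev))
            i, j = i - 1, j - 1
        elif state == 1:
            state = 0 if np.isclose(X[i, j], M[i - 1, j] + gap_open) else 1
            i -= 1
        else:
            state = 0 if np.isclose(Y[i, j], M[i, j - 1] + gap_open) else 2
            j -= 1
    return list(reversed(pairs))


class TestBuildEquivalence:
    def test_identical_sequences_identity_map(self):
        emap = build_equivalence("MKWVTF", "MKWVTF", [1, 2, 3, 4, 5, 6], "P")
        assert emap.mapping == {i: i for i in range(1, 7)}
        assert emap.method == "pairwise_alignment"

    def test_leading_insertion_shifts_map(self):
        emap = build_equivalence("XMKWVTF", "MKWVTF", [1, 2, 3, 4, 5, 6], "P")
        assert emap.mapping == {i + 1: i for i in range(1, 7)}

    def test_structure_residue_numbers_carried_through(self):
        emap = build_equivalence("MKW", "MKW", [101, 102, 110], "P")
        assert emap.mapping == {1: 101, 2: 102, 3: 110}

    def test_internal_gap_matches_dp_oracle(self):
        query, subject = "MKWVTFISLL", "MKWTFISLL"  # V deleted in subject
        emap = build_equivalence(query, subject,
                                 list(range(1, len(subject) + 1)), "P")
        expected = {
            qi + 1: sj + 1
            for qi, sj in needleman_wunsch(query, subject)
        }
        assert emap.mapping == expected

    def test_low_coverage_rejected(self):
        with pytest.raises(LowConfidenceMappingError):
            build_equivalence("MKWVTFISLLMKWVTFISLL", "QQ", [1, 2], "P")

    def test_table_override(self):
        emap = equivalence_from_table({68: 710, 101: 745}, chain="P")
        assert emap.method == "table"
        assert emap.resolve(68) == 710
        assert emap.resolve(999) is None

    def test_table_must_be_injective(self):
        with pytest.raises(MappingError):
            equivalence_from_table({1: 5, 2: 5}, chain="P")

    def test_equivalence_table_file(self, tmp_path):
        p = tmp_path / "eq.tsv"
        p.write_text("query_pos\tchain\tresidue_number\n"
                     "1494\tR\t1405\n68\tP\t710\n")
        tables = read_equivalence_table(p)
        assert tables == {"R": {1494: 1405}, "P": {68: 710}}


def toy_model(extra=()):
    atoms = [
        Atom("R", 1, "C", "C1'", "C", 0.0, 0.0, 0.0),
        Atom("R", 1, "C", "N3", "N", 1.0, 0.0, 0.0),
        Atom("P", 68, "ALA", "CA", "C", 0.0, 4.0, 0.0),
        Atom("P", 68, "ALA", "HB1", "H", 0.5, 0.0, 0.0),
        Atom("P", 101, "ALA", "CA", "C", 9.0, 0.0, 0.0),
    ]
    return StructureModel(atoms + list(extra))


class TestMinDistance:
    def test_three_four_five_triangle(self):
        model = StructureModel([
            Atom("A", 1, "ALA", "CA", "C", 0.0, 0.0, 0.0),
            Atom("B", 2, "ALA", "CA", "C", 3.0, 4.0, 0.0),
        ])
        assert min_distance(model, ("A", 1), ("B", 2)) == pytest.approx(5.0)

    def test_matches_brute_force_on_random_selections(self, rng):
        for _ in range(20):
            xa = rng.normal(size=(50, 3)) * 10
            xb = rng.normal(size=(50, 3)) * 10 + 5
            atoms = [Atom("A", 1, "ALA", f"C{i}", "C", *xyz)
                     for i, xyz in enumerate(xa)]
            atoms += [Atom("B", 2, "ALA", f"C{i}", "C", *xyz)
                      for i, xyz in enumerate(xb)]
            model = StructureModel(atoms)
            brute = min(
                float(np.linalg.norm(p - q)) for p in xa for q in xb
            )
            assert min_distance(model, ("A", 1), ("B", 2)) == pytest.approx(
                brute, abs=1e-9
            )

    def test_symmetric_and_nonnegative(self):
        model = toy_model()
        d = min_distance(model, ("R", 1), ("P", 68))
        assert d == min_distance(model, ("P", 68), ("R", 1))
        assert d >= 0

    def test_heavy_excludes_hydrogens(self):
        model = toy_model()
        heavy = min_distance(model, ("R", 1), ("P", 68), atom_class="heavy")
        all_atoms = min_distance(model, ("R", 1), ("P", 68), atom_class="all")
        assert heavy >= all_atoms
        assert all_atoms == pytest.approx(0.5)  # the hydrogen sits closest

    def test_rigid_motion_invariance(self, rng):
        xa = rng.normal(size=(10, 3))
        xb = rng.normal(size=(10, 3)) + 3
        # random rotation via QR, plus a translation
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        shift = rng.normal(size=3) * 7

        def model_from(pa, pb):
            atoms = [Atom("A", 1, "X", f"C{i}", "C", *p)
                     for i, p in enumerate(pa)]
            atoms += [Atom("B", 2, "X", f"C{i}", "C", *p)
                      for i, p in enumerate(pb)]
            return StructureModel(atoms)

        d0 = min_distance(model_from(xa, xb), ("A", 1), ("B", 2))
        d1 = min_distance(model_from(xa @ q.T + shift, xb @ q.T + shift),
                          ("A", 1), ("B", 2))
        assert d1 == pytest.approx(d0, abs=1e-6)

    def test_identical_selection_rejected(self):
        with pytest.raises(SelectionError):
            min_distance(toy_model(), ("R", 1), ("R", 1))

    def test_empty_selection_rejected(self):
        model = StructureModel([
            Atom("A", 1, "ALA", "HA", "H", 0.0, 0.0, 0.0),
            Atom("B", 2, "ALA", "CA", "C", 1.0, 0.0, 0.0),
        ])
        with pytest.raises(SelectionError):
            min_distance(model, ("A", 1), ("B", 2))  # A is hydrogen-only
        with pytest.raises(SelectionError):
            min_distance(model, ("C", 9), ("B", 2))


class TestProximityFilter:
    def setup_method(self):
        self.model = toy_model()
        self.map_protein = equivalence_from_table({68: 68, 101: 101}, "P")
        self.map_rna = equivalence_from_table({1494: 1}, "R")

    def filter(self, candidates, threshold=6.0):
        return proximity_filter(self.model, candidates, 1494,
                                self.map_protein, self.map_rna,
                                threshold_a=threshold)

    def test_within_and_outside(self):
        near, far = self.filter([68, 101])
        assert near.min_distance_a == pytest.approx(4.0)
        assert near.within_threshold is True
        assert far.min_distance_a == pytest.approx(8.0)
        assert far.within_threshold is False

    def test_threshold_zero_admits_nothing(self):
        assert not any(r.within_threshold for r in
                       self.filter([68, 101], threshold=0.0))

    def test_threshold_comparison_is_strict(self):
        exactly = self.filter([68], threshold=4.0)[0]
        assert exactly.within_threshold is False

    def test_unmapped_candidate_reported_unresolved(self):
        result = self.filter([68, 999])[1]
        assert result.status == "unresolved"
        assert result.min_distance_a is None
        assert result.within_threshold is None

    def test_unmappable_site_is_an_error(self):
        with pytest.raises(MappingError):
            proximity_filter(self.model, [68], 9999,
                             self.map_protein, self.map_rna)

    def test_verdicts_invariant_under_candidate_order(self):
        forward = {r.candidate_position: r.within_threshold
                   for r in self.filter([68, 101, 999])}
        backward = {r.candidate_position: r.within_threshold
                    for r in self.filter([999, 101, 68])}
        assert forward == backward
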