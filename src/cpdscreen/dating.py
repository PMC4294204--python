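"""Dating the fixation of a derived allele on a dated species tree.

Model: single-gain (Dollo-like) parsimony.  The derived allele arose
exactly once, on the branch above the most recent common ancestor (MRCA)
of all derived tips, and may have been lost up to ``max_losses`` times
inside that clade (a reversion such as the single *Papio ursinus* C at
m.1494 inside an otherwise T-fixed family).  Under that model the allele
was fixed somewhere on the stem branch of the gain clade, so its fixation
time is bounded by

* ``oldest_mya`` — the stem age: the age of the gain clade's parent node
  (the split from its sister lineage; the root age for a gain on the root
  edge), and
* ``youngest_mya`` — the crown age: the age of the gain clade itself
  (0 for a single tip),

e.g. a 12S rRNA allele fixed in all Old World monkeys but absent from apes
is dated to the 32–18 Mya window between the hominoid split and the family
crown.  Tips with ``unknown`` state are unconstrained (compatible with
either state): an unsequenced subfamily widens nothing and forbids nothing.

Node ages are in millions of years (Mya), computed from newick branch
lengths interpreted as Myr on an ultrametric tree.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Mapping

import dendropy

from .errors import (
    DatingError,
    EmptyStateError,
    NoSingleGainError,
    TreeFormatError,
)

State = Literal["derived", "ancestral", "unknown"]
VALID_STATES = ("derived", "ancestral", "unknown")


class DatedTree:
    """A rooted ultrametric tree with node ages in Mya.

    Wraps a :class:`dendropy.Tree`; ages are max root-to-tip distance minus
    the node's distance from the root, checked ultrametric to a relative
    tolerance (default 1e-6 of tree depth).
    """

    def __init__(self, tree: dendropy.Tree, ultrametric_rtol: float = 1e-6):
        self._tree = tree
        for edge in tree.preorder_edge_iter():
            if edge.head_node is tree.seed_node:
                continue
            if edge.length is None:
                raise TreeFormatError("a branch is missing its length")
            if edge.length < 0:
                raise TreeFormatError(f"negative branch length {edge.length}")
        depths: dict[dendropy.Node, float] = {}
        for node in tree.preorder_node_iter():
            if node.parent_node is None:
                depths[node] = 0.0
            else:
                depths[node] = depths[node.parent_node] + (node.edge.length or 0.0)
        max_depth = max(depths.values())
        tol = ultrametric_rtol * max(max_depth, 1.0)
        for leaf in tree.leaf_node_iter():
            if abs(depths[leaf] - max_depth) > tol:
                raise DatingError(
                    f"tree is not ultrametric: tip {leaf.taxon.label!r} at "
                    f"depth {depths[leaf]:.6g} vs tree depth {max_depth:.6g}"
                )
        self._age = {
            node: (0.0 if node.is_leaf() else max_depth - depths[node])
            for node in tree.preorder_node_iter()
        }

    # -- accessors ---------------------------------------------------------

    @property
    def root(self) -> dendropy.Node:
        return self._tree.seed_node

    @property
    def root_age(self) -> float:
        return self._age[self.root]

    def age(self, node: dendropy.Node) -> float:
        return self._age[node]

    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self._tree.leaf_node_iter()]

    def node_label(self, node: dendropy.Node) -> str:
        if node.is_leaf():
            return node.taxon.label
        return node.label or f"mrca_of_{self._clade_size(node)}_tips"

    def _clade_size(self, node: dendropy.Node) -> int:
        return sum(1 for _ in node.leaf_iter())

    def mrca(self, tip_labels: list[str]) -> dendropy.Node:
        taxa = [self._tree.taxon_namespace.get_taxon(t) for t in tip_labels]
        missing = [t for t, tax in zip(tip_labels, taxa) if tax is None]
        if missing:
            raise DatingError(f"tips not in tree: {missing}")
        return self._tree.mrca(taxa=taxa)

    def as_newick(self) -> str:
        return self._tree.as_string(schema="newick").strip()


def read_dated_newick(path: str | Path) -> DatedTree:
    """Read a newick tree whose branch lengths are in Myr."""
    try:
        tree = dendropy.Tree.get(
            path=str(path), schema="newick", rooting="force-rooted",
            preserve_underscores=True, suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several parse-error types
        raise TreeFormatError(f"{path}: {exc}") from exc
    return DatedTree(tree)


def parse_dated_newick(newick: str) -> DatedTree:
    """Parse a newick string (branch lengths in Myr) into a DatedTree."""
    try:
        tree = dendropy.Tree.get(
            file=io.StringIO(newick), schema="newick", rooting="force-rooted",
            preserve_underscores=True, suppress_internal_node_taxa=True,
        )
    except Exception as exc:
        raise TreeFormatError(str(exc)) from exc
    return DatedTree(tree)


def read_tip_states(path: str | Path) -> dict[str, State]:
    """Read a TSV of tip, state (derived/ancestral/unknown)."""
    states: dict[str, State] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            cells = [c.strip() for c in line.split("\t")]
            if cells[0].lower() == "tip":
                continue
            if len(cells) < 2 or cells[1] not in VALID_STATES:
                raise TreeFormatError(
                    f"state row must be 'tip<TAB>derived|ancestral|unknown', "
                    f"got {line!r}"
                )
            states[cells[0]] = cells[1]  # type: ignore[assignment]
    return states


@dataclass(frozen=True)
class GainClade:
    node: "dendropy.Node"
    n_losses_assumed: int
    label: str


@dataclass(frozen=True)
class FixationInterval:
    """[oldest, youngest] bound in Mya on when a derived allele was fixed."""

    oldest_mya: float
    youngest_mya: float
    gain_node: str
    n_losses_assumed: int

    def __post_init__(self):
        if not self.oldest_mya >= self.youngest_mya >= 0:
            raise DatingError(
                f"invalid interval ({self.oldest_mya}, {self.youngest_mya})"
            )


def _resolve_states(
    tree: DatedTree, states: Mapping[str, State]
) -> dict[str, State]:
    resolved: dict[str, State] = {}
    for tip in tree.tip_labels():
        s = states.get(tip, "unknown")
        if s not in VALID_STATES:
            raise DatingError(f"tip {tip!r} has invalid state {s!r}")
        resolved[tip] = s
    return resolved


def _count_losses(gain: dendropy.Node, states: Mapping[str, State]) -> int:
    """Maximal subclades inside the gain clade containing an ancestral tip
    and no derived tip — each needs one loss.  Unknown-only subclades are
    compatible with retention and cost nothing."""

    def tip_mix(node: dendropy.Node) -> tuple[bool, bool]:
        has_derived = has_ancestral = False
        for leaf in node.leaf_iter():
            s = states[leaf.taxon.label]
            if s == "derived":
                has_derived = True
            elif s == "ancestral":
                has_ancestral = True
        return has_derived, has_ancestral

    losses = 0
    stack = [gain]
    while stack:
        node = stack.pop()
        has_derived, has_ancestral = tip_mix(node)
        if not has_derived:
            if has_ancestral:
                losses += 1
            continue  # all-unknown or loss subtree: stop descending
        if node.is_leaf():
            continue
        stack.extend(node.child_nodes())
    return losses


def derived_clade(
    tree: DatedTree, states: Mapping[str, State], max_losses: int = 1
) -> GainClade:
    """MRCA of all derived tips, valid under the single-gain model.

    Raises :class:`NoSingleGainError` when explaining the tip pattern with
    one gain would need more than ``max_losses`` reversions.
    """
    resolved = _resolve_states(tree, states)
    derived_tips = [t for t, s in resolved.items() if s == "derived"]
    if not derived_tips:
        raise EmptyStateError("no tip carries the derived state")
    mrca = tree.mrca(derived_tips)
    losses = _count_losses(mrca, resolved)
    if losses > max_losses:
        raise NoSingleGainError(
            f"a single gain would need {losses} losses "
            f"(max_losses={max_losses}); the derived tips are effectively "
            "non-monophyletic"
        )
    return GainClade(
        node=mrca, n_losses_assumed=losses, label=tree.node_label(mrca)
    )


def fixation_interval(
    tree: DatedTree, states: Mapping[str, State], max_losses: int = 1
) -> FixationInterval:
    """Stem/crown age bounds on the fixation of the derived allele."""
    gain = derived_clade(tree, states, max_losses=max_losses)
    node = gain.node
    parent = node.parent_node
    oldest = tree.age(parent) if parent is not None else tree.age(node)
    youngest = tree.age(node)
    return FixationInterval(
        oldest_mya=oldest,
        youngest_mya=youngest,
        gain_node=gain.label,
        n_losses_assumed=gain.n_losses_assumed,
    )


def interval_gap(a: FixationInterval, b: FixationInterval) -> float:
    """Minimum Myr separating two fixation intervals (0 = possible overlap).

    The interval with the larger oldest bound is the earlier event; the gap
    is how much its youngest bound predates the later event's oldest bound.
    """
    earlier, later = (a, b) if a.oldest_mya >= b.oldest_mya else (b, a)
    return max(0.0, earlier.youngest_mya - later.oldest_mya)
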