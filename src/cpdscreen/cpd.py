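"""Compensated-pathogenic-deviation (CPD) calling and base-pair logic.

A CPD is a human pathogenic allele that is the fixed wild-type state in
another species: its carrier must also harbor a compensatory change.  The
scan takes a curated table of pathogenic sites in reference coordinates
(e.g. the deafness-associated 12S rRNA transitions m.1494C>T and
m.1555A>G), maps each to its alignment column, assigns every non-reference
taxon a verdict, and tallies carriers per clade so that fixation within a
family/subfamily/tribe becomes visible.

The decoding-site argument also needs Watson–Crick pairing status of two
interacting rRNA positions (1494 pairs with 1555 in the bacterial helix):
strict complementarity only, since aminoglycoside binding depends on the
canonical pair; G·U wobble is classified non-Watson–Crick.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .alignment import Alignment
from .errors import AlignmentFormatError

RANKS = ("family", "subfamily", "tribe")
UNRESOLVED_CHARS = set("-NX")
_WC_PAIRS = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}


class Verdict(str, Enum):
    WILDTYPE = "wildtype"
    PATHOGENIC = "pathogenic_allele"
    OTHER = "other"
    UNRESOLVED = "unresolved"


class PairStatus(str, Enum):
    WATSON_CRICK = "watson_crick"
    NON_WATSON_CRICK = "non_watson_crick"
    UNRESOLVED = "unresolved"


@dataclass(frozen=True)
class PathogenicSite:
    """A curated pathogenic position: wild-type vs pathogenic allele."""

    ref_position: int
    wildtype_allele: str
    pathogenic_allele: str
    label: str = ""

    def __post_init__(self):
        if self.wildtype_allele == self.pathogenic_allele:
            raise ValueError("wild-type and pathogenic alleles must differ")

    @property
    def name(self) -> str:
        return self.label or (
            f"m.{self.ref_position}{self.wildtype_allele}>"
            f"{self.pathogenic_allele}"
        )


@dataclass(frozen=True)
class CpdCall:
    """Per-taxon verdict at one pathogenic site."""

    taxon: str
    clade_labels: tuple[str, ...]
    observed_state: str
    verdict: Verdict


def read_sites_table(path: str | Path) -> list[PathogenicSite]:
    """Read a site table TSV: columns label, ref_position, wildtype, pathogenic."""
    sites: list[PathogenicSite] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            cells = [c.strip() for c in line.split("\t")]
            if cells[0].lower() == "label":
                continue
            if len(cells) < 4:
                raise AlignmentFormatError(
                    f"site table row needs 4 columns, got {len(cells)}: {line!r}"
                )
            sites.append(
                PathogenicSite(
                    label=cells[0],
                    ref_position=int(cells[1]),
                    wildtype_allele=cells[2].upper(),
                    pathogenic_allele=cells[3].upper(),
                )
            )
    return sites


def _verdict(state: str, site: PathogenicSite) -> Verdict:
    if state in UNRESOLVED_CHARS:
        return Verdict.UNRESOLVED
    if state == site.wildtype_allele:
        return Verdict.WILDTYPE
    if state == site.pathogenic_allele:
        return Verdict.PATHOGENIC
    return Verdict.OTHER


def call_cpd(aln: Alignment, site: PathogenicSite) -> list[CpdCall]:
    """One verdict per non-reference taxon at the site's homologous column.

    The declared site definition is authoritative: if the reference row
    disagrees with the declared wild-type allele a warning is logged and
    the declared alleles are still used for the verdicts.
    """
    column = aln.map_reference_position(site.ref_position)
    ref_state = aln.reference.seq[column - 1]
    if ref_state != site.wildtype_allele:
        warnings.warn(
            f"{site.name}: reference carries {ref_state!r} at position "
            f"{site.ref_position}, declared wild-type is "
            f"{site.wildtype_allele!r}; using the declared site definition",
            stacklevel=2,
        )
    return [
        CpdCall(
            taxon=rec.id,
            clade_labels=rec.clade_labels,
            observed_state=rec.seq[column - 1],
            verdict=_verdict(rec.seq[column - 1], site),
        )
        for rec in aln.non_reference_records()
    ]


def _label_at_rank(labels: tuple[str, ...], rank: str) -> str:
    try:
        idx = RANKS.index(rank)
    except ValueError:
        raise ValueError(f"rank must be one of {RANKS}, got {rank!r}") from None
    if idx < len(labels) and labels[idx]:
        return labels[idx]
    return "unassigned"


def tally_by_clade(calls: Sequence[CpdCall], rank: str = "family") -> pd.DataFrame:
    """Verdict counts per clade at a taxonomy rank.

    Returns a DataFrame indexed by clade with columns ``n_pathogenic,
    n_wildtype, n_other, n_unresolved``; taxa without a label at the
    requested rank fall in an ``unassigned`` bucket.  Counts across the
    table always sum to ``len(calls)``.
    """
    cols = ["n_pathogenic", "n_wildtype", "n_other", "n_unresolved"]
    key = {
        Verdict.PATHOGENIC: "n_pathogenic",
        Verdict.WILDTYPE: "n_wildtype",
        Verdict.OTHER: "n_other",
        Verdict.UNRESOLVED: "n_unresolved",
    }
    counts: dict[str, dict[str, int]] = {}
    for call in calls:
        clade = _label_at_rank(call.clade_labels, rank)
        row = counts.setdefault(clade, {c: 0 for c in cols})
        row[key[call.verdict]] += 1
    table = pd.DataFrame.from_dict(counts, orient="index", columns=cols)
    table.index.name = "clade"
    return table.sort_index()


def clade_fixation(
    tally: pd.DataFrame, fixation_fraction: float = 1.0
) -> pd.DataFrame:
    """Flag clades fixed for the pathogenic allele.

    A clade is ``fixed`` when at least ``fixation_fraction`` of its
    *resolved* members (pathogenic + wildtype + other) carry the pathogenic
    allele; ``n_exceptions`` counts the resolved members that do not, so a
    clade fixed save for a single reverted species remains easy to report.
    """
    resolved = (
        tally["n_pathogenic"] + tally["n_wildtype"] + tally["n_other"]
    )
    frac = tally["n_pathogenic"] / resolved.replace(0, np.nan)
    out = tally.copy()
    out["n_resolved"] = resolved
    out["fraction_pathogenic"] = frac
    out["n_exceptions"] = resolved - tally["n_pathogenic"]
    out["fixed"] = (resolved > 0) & (frac >= fixation_fraction)
    return out


def wc_pair_status(state_a: str, state_b: str) -> PairStatus:
    """Watson–Crick status of two nucleotide states (T≡U; symmetric).

    Strict complementarity only: A–T(U) and G–C.  Either state being a gap
    or N yields ``unresolved``.
    """
    a = state_a.upper().replace("U", "T")
    b = state_b.upper().replace("U", "T")
    if a in UNRESOLVED_CHARS or b in UNRESOLVED_CHARS:
        return PairStatus.UNRESOLVED
    if (a, b) in _WC_PAIRS:
        return PairStatus.WATSON_CRICK
    return PairStatus.NON_WATSON_CRICK


@dataclass(frozen=True)
class SitePair:
    """Two interacting reference positions (e.g. 1494 and 1555)."""

    pos_a: int
    pos_b: int

    def __post_init__(self):
        if self.pos_a == self.pos_b:
            raise ValueError("a site pair needs two distinct positions")

    def status_per_taxon(self, aln: Alignment) -> dict[str, PairStatus]:
        """Pairing status of the two homologous columns for every taxon."""
        col_a = aln.map_reference_position(self.pos_a)
        col_b = aln.map_reference_position(self.pos_b)
        return {
            rec.id: wc_pair_status(rec.seq[col_a - 1], rec.seq[col_b - 1])
            for rec in aln.records
        }
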