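"""Conservation-index statistics on alignment columns.

The conservation index (CI) of a position is the percentage of sequences
in an orthologous alignment that carry the human wild-type state at the
homologous column.  It is deliberately a plain match percentage, not an
entropy or substitution-rate score: a position where most mammals retain
the human allele is inferred to be under purifying selection, and a human
disease allele that is nonetheless the fixed state in another clade marks
a compensated pathogenic deviation.

Denominator convention: the reference row is excluded from both counts;
gaps and unresolved characters (N/X) count in ``n_total`` but never in
``n_match`` — a sequence with a gap does not harbor the wild-type variant.
This makes a CI of, say, 544 matches among 608 species reproducible as the
plain fraction 544/608 = 89.5%.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .alignment import Alignment
from .errors import (
    DegenerateAlignmentError,
    DegenerateVarianceError,
    EmptySetError,
    SampleSizeError,
)

UNRESOLVED = set("-NX")


@dataclass(frozen=True)
class SiteConservation:
    """CI of a single reference position.

    ``ci`` keeps full precision; use :attr:`ci_rounded` (1 decimal, the
    reporting convention) for display.
    """

    ref_position: int
    wildtype: str
    n_match: int
    n_total: int
    ci: float

    @property
    def ci_rounded(self) -> float:
        return round(self.ci, 1)


def conservation_index(aln: Alignment, ref_pos: int) -> SiteConservation:
    """CI of one reference position: % of non-reference rows matching the
    reference (wild-type) state at the mapped column."""
    column = aln.map_reference_position(ref_pos)
    wildtype = aln.reference.seq[column - 1]
    others = aln.non_reference_records()
    if not others:
        raise DegenerateAlignmentError(
            "alignment has no non-reference sequences to tally"
        )
    n_total = len(others)
    n_match = sum(1 for r in others if r.seq[column - 1] == wildtype)
    return SiteConservation(
        ref_position=ref_pos,
        wildtype=wildtype,
        n_match=n_match,
        n_total=n_total,
        ci=100.0 * n_match / n_total,
    )


def conservation_profile(
    aln: Alignment, positions: Sequence[int] | None = None
) -> pd.DataFrame:
    """Per-position CI table over the given reference positions (default all).

    Columns: ``ref_position, wildtype, n_match, n_total, ci`` with ``ci``
    rounded to the 1-decimal reporting precision.
    """
    if positions is None:
        positions = range(1, aln.ungapped_reference_length + 1)
    rows = [conservation_index(aln, p) for p in positions]
    return pd.DataFrame(
        {
            "ref_position": [r.ref_position for r in rows],
            "wildtype": [r.wildtype for r in rows],
            "n_match": [r.n_match for r in rows],
            "n_total": [r.n_total for r in rows],
            "ci": [r.ci_rounded for r in rows],
        }
    )


def gene_mean_ci(aln: Alignment) -> float:
    """Arithmetic mean CI over every ungapped reference position of the gene."""
    cis = [
        conservation_index(aln, p).ci
        for p in range(1, aln.ungapped_reference_length + 1)
    ]
    return float(np.mean(cis))


def mean_ci_of_set(cis: Sequence[float]) -> float:
    """Arithmetic mean of already-computed per-position CIs.

    Position-set summaries average the per-position percentages rather than
    pooling match counts, so a set's mean is exactly the mean of its
    printed CI list.
    """
    if len(cis) == 0:
        raise EmptySetError("cannot average an empty CI set")
    return float(np.mean(cis))


@dataclass(frozen=True)
class CiComparison:
    t: float
    p: float
    significant: bool
    alpha: float


def compare_ci_sets(
    cis_a: Sequence[float],
    cis_b: Sequence[float],
    alpha: float = 0.05,
    welch: bool = False,
) -> CiComparison:
    """Unpaired two-tailed t-test between two CI sets.

    Student's pooled-variance t by default (the classical two-sample test);
    pass ``welch=True`` for the unequal-variance form.  ``significant`` is
    the p < alpha verdict at the conventional 0.05 level.
    """
    if len(cis_a) < 2 or len(cis_b) < 2:
        raise SampleSizeError("each CI set needs at least 2 values")
    a = np.asarray(cis_a, dtype=float)
    b = np.asarray(cis_b, dtype=float)
    if not welch and a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        if np.allclose(a.mean(), b.mean()):
            # identical constant sets: no evidence of difference
            return CiComparison(t=0.0, p=1.0, significant=False, alpha=alpha)
        raise DegenerateVarianceError(
            "zero pooled variance with unequal means: t undefined"
        )
    t, p = stats.ttest_ind(a, b, equal_var=not welch)
    return CiComparison(
        t=float(t), p=float(p), significant=bool(p < alpha), alpha=alpha
    )
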