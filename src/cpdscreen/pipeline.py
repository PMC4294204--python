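"""Orchestration of the full modifier-factor screen from one config file.

The screen's evidence is modular — sequence (CPD scan + conservation),
structure (proximity), and time (fixation dating) — and partial inputs are
the common case, so each stage is independently invokable and the
orchestrator only chains them: every stage reads declared input files,
writes its own TSV/JSON under the output directory, and contributes one
block to a schema-validated top-level ``summary.json``.  Optional stages
whose inputs are absent are recorded as skipped rather than failing the
run; a stage that *does* run and errors aborts the screen with the stage
name and cause.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, Field

from . import __version__
from .alignment import Alignment, read_fasta_alignment
from .conservation import compare_ci_sets, conservation_profile, mean_ci_of_set
from .cpd import call_cpd, clade_fixation, read_sites_table, tally_by_clade
from .dating import (
    FixationInterval,
    fixation_interval,
    interval_gap,
    read_dated_newick,
    read_tip_states,
)
from .errors import CpdScreenError, StageError
from .structure import (
    build_equivalence,
    equivalence_from_table,
    proximity_filter,
    read_equivalence_table,
    read_structure,
)

log = logging.getLogger("cpdscreen")


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

class AlignmentInput(BaseModel):
    path: str
    reference_id: str
    molecule: Literal["nucleotide", "protein"] = "nucleotide"
    taxonomy: Optional[str] = None


class Thresholds(BaseModel):
    fixation_fraction: float = Field(default=1.0, gt=0.0, le=1.0)
    proximity_a: float = Field(default=6.0, gt=0.0)
    max_losses: int = Field(default=1, ge=0)
    alpha: float = Field(default=0.05, gt=0.0, lt=1.0)


class ScanConfig(BaseModel):
    alignment: str  # key into ScreenConfig.alignments
    sites_table: str
    rank: Literal["family", "subfamily", "tribe"] = "family"


class CiSetConfig(BaseModel):
    name: str
    alignment: str
    positions: list[int]


class CiComparisonConfig(BaseModel):
    set_a: str
    set_b: str


class DatingConfig(BaseModel):
    tree: str
    characters: dict[str, str]  # character name -> tip-states TSV
    pair: Optional[tuple[str, str]] = None  # compute the gap between these


class ProximityConfig(BaseModel):
    structure: str
    model_index: int = 0
    protein_chain: str
    rna_chain: str
    site: int
    candidates: list[int]
    # either a curated table (query_pos, chain, residue_number) or the key
    # of an alignment whose reference sequence seeds a pairwise mapping
    equivalence_table: Optional[str] = None
    protein_alignment: Optional[str] = None
    rna_alignment: Optional[str] = None


class ScreenConfig(BaseModel):
    alignments: dict[str, AlignmentInput] = Field(default_factory=dict)
    scan: Optional[ScanConfig] = None
    ci_sets: list[CiSetConfig] = Field(default_factory=list)
    ci_comparisons: list[CiComparisonConfig] = Field(default_factory=list)
    dating: Optional[DatingConfig] = None
    proximity: Optional[ProximityConfig] = None
    thresholds: Thresholds = Field(default_factory=Thresholds)
    outdir: str = "screen_out"
    seed: int = 0


def load_config(path: str | Path) -> ScreenConfig:
    with open(path) as fh:
        return ScreenConfig.model_validate(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# summary schema
# ---------------------------------------------------------------------------

class FixedCladeSummary(BaseModel):
    clade: str
    fraction_pathogenic: float
    n_exceptions: int


class SiteSummary(BaseModel):
    label: str
    ref_position: int
    n_pathogenic: int
    n_wildtype: int
    n_other: int
    n_unresolved: int
    fixed_clades: list[FixedCladeSummary]


class CiSetSummary(BaseModel):
    name: str
    positions: list[int]
    cis: list[float]
    mean_ci: float
    mean_ci_unrounded: float


class ComparisonSummary(BaseModel):
    set_a: str
    set_b: str
    t: float
    p: float
    significant: bool


class IntervalSummary(BaseModel):
    character: str
    gain_node: str
    oldest_mya: float
    youngest_mya: float
    n_losses_assumed: int


class DatingSummary(BaseModel):
    intervals: list[IntervalSummary]
    gap_pair: Optional[tuple[str, str]] = None
    gap_myr: Optional[float] = None


class CandidateSummary(BaseModel):
    position: int
    min_distance_a: Optional[float]
    within_threshold: Optional[bool]
    status: str


class ProximitySummary(BaseModel):
    site: int
    threshold_a: float
    candidates: list[CandidateSummary]


class ScreenSummary(BaseModel):
    version: str
    seed: int
    thresholds: Thresholds
    cpd_sites: Optional[list[SiteSummary]] = None
    ci_sets: Optional[list[CiSetSummary]] = None
    ci_comparisons: Optional[list[ComparisonSummary]] = None
    dating: Optional[DatingSummary] = None
    proximity: Optional[ProximitySummary] = None
    skipped_stages: list[str] = Field(default_factory=list)


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _load_alignments(config: ScreenConfig) -> dict[str, Alignment]:
    out: dict[str, Alignment] = {}
    for key, spec in config.alignments.items():
        out[key] = read_fasta_alignment(
            spec.path, reference_id=spec.reference_id,
            molecule=spec.molecule, taxonomy=spec.taxonomy,
        )
        log.info("alignment %r: %d records, length %d", key,
                 out[key].n_records, out[key].length)
    return out


def _run_scan(config: ScreenConfig, alignments: dict[str, Alignment],
              outdir: Path) -> list[SiteSummary]:
    scan = config.scan
    assert scan is not None
    aln = alignments[scan.alignment]
    fraction = config.thresholds.fixation_fraction
    log.info("scan: fixation fraction threshold %.3f at rank %s",
             fraction, scan.rank)
    summaries: list[SiteSummary] = []
    for site in read_sites_table(scan.sites_table):
        calls = call_cpd(aln, site)
        stem = site.name.replace(".", "_").replace(">", "_")
        with open(outdir / f"scan_calls_{stem}.tsv", "w") as fh:
            fh.write("taxon\tclades\tobserved\tverdict\n")
            for c in calls:
                fh.write(f"{c.taxon}\t{'|'.join(c.clade_labels)}\t"
                         f"{c.observed_state}\t{c.verdict.value}\n")
        tally = tally_by_clade(calls, rank=scan.rank)
        fixation = clade_fixation(tally, fixation_fraction=fraction)
        fixation.to_csv(outdir / f"scan_tally_{stem}.tsv", sep="\t")
        fixed = fixation[fixation["fixed"]]
        verdicts = [c.verdict.value for c in calls]
        summaries.append(
            SiteSummary(
                label=site.name,
                ref_position=site.ref_position,
                n_pathogenic=verdicts.count("pathogenic_allele"),
                n_wildtype=verdicts.count("wildtype"),
                n_other=verdicts.count("other"),
                n_unresolved=verdicts.count("unresolved"),
                fixed_clades=[
                    FixedCladeSummary(
                        clade=str(clade),
                        fraction_pathogenic=float(row["fraction_pathogenic"]),
                        n_exceptions=int(row["n_exceptions"]),
                    )
                    for clade, row in fixed.iterrows()
                ],
            )
        )
    return summaries


def _run_ci(config: ScreenConfig, alignments: dict[str, Alignment],
            outdir: Path) -> tuple[list[CiSetSummary], list[ComparisonSummary]]:
    set_summaries: list[CiSetSummary] = []
    cis_by_name: dict[str, list[float]] = {}
    for ci_set in config.ci_sets:
        aln = alignments[ci_set.alignment]
        profile = conservation_profile(aln, ci_set.positions)
        profile.to_csv(outdir / f"ci_{ci_set.name}.tsv", sep="\t", index=False)
        cis = [float(v) for v in profile["ci"]]
        cis_by_name[ci_set.name] = cis
        mean = mean_ci_of_set(cis)
        log.info("ci set %r: mean %.4f (reported %.1f)", ci_set.name,
                 mean, round(mean, 1))
        set_summaries.append(
            CiSetSummary(
                name=ci_set.name, positions=list(ci_set.positions),
                cis=cis, mean_ci=round(mean, 1), mean_ci_unrounded=mean,
            )
        )
    comparisons: list[ComparisonSummary] = []
    for comp in config.ci_comparisons:
        result = compare_ci_sets(
            cis_by_name[comp.set_a], cis_by_name[comp.set_b],
            alpha=config.thresholds.alpha,
        )
        log.info("t-test %s vs %s: t=%.4f p=%.4g (alpha %.2f)",
                 comp.set_a, comp.set_b, result.t, result.p, result.alpha)
        comparisons.append(
            ComparisonSummary(
                set_a=comp.set_a, set_b=comp.set_b,
                t=result.t, p=result.p, significant=result.significant,
            )
        )
    return set_summaries, comparisons


def _run_dating(config: ScreenConfig, outdir: Path) -> DatingSummary:
    dating = config.dating
    assert dating is not None
    tree = read_dated_newick(dating.tree)
    max_losses = config.thresholds.max_losses
    log.info("dating: max_losses %d", max_losses)
    intervals: dict[str, FixationInterval] = {}
    summaries: list[IntervalSummary] = []
    for character, states_path in dating.characters.items():
        states = read_tip_states(states_path)
        interval = fixation_interval(tree, states, max_losses=max_losses)
        intervals[character] = interval
        log.info("character %r: fixed between %.1f and %.1f Mya "
                 "(%d losses assumed)", character, interval.oldest_mya,
                 interval.youngest_mya, interval.n_losses_assumed)
        summaries.append(
            IntervalSummary(
                character=character,
                gain_node=interval.gain_node,
                oldest_mya=interval.oldest_mya,
                youngest_mya=interval.youngest_mya,
                n_losses_assumed=interval.n_losses_assumed,
            )
        )
    gap = None
    if dating.pair is not None:
        a, b = dating.pair
        gap = interval_gap(intervals[a], intervals[b])
        log.info("minimum gap between %r and %r: %.1f Myr", a, b, gap)
    summary = DatingSummary(intervals=summaries, gap_pair=dating.pair,
                            gap_myr=gap)
    (outdir / "dating.json").write_text(
        summary.model_dump_json(indent=2) + "\n"
    )
    return summary


def _run_proximity(config: ScreenConfig, alignments: dict[str, Alignment],
                   outdir: Path) -> ProximitySummary:
    prox = config.proximity
    assert prox is not None
    model = read_structure(prox.structure, model_index=prox.model_index)
    threshold = config.thresholds.proximity_a
    log.info("proximity: threshold %.2f A (strict <)", threshold)

    if prox.equivalence_table is not None:
        tables = read_equivalence_table(prox.equivalence_table)
        map_protein = equivalence_from_table(
            tables.get(prox.protein_chain, {}), chain=prox.protein_chain
        )
        map_rna = equivalence_from_table(
            tables.get(prox.rna_chain, {}), chain=prox.rna_chain
        )
    else:
        if prox.protein_alignment is None or prox.rna_alignment is None:
            raise CpdScreenError(
                "proximity needs either an equivalence_table or both "
                "protein_alignment and rna_alignment keys"
            )
        p_seq, p_nums = model.chain_sequence(prox.protein_chain)
        r_seq, r_nums = model.chain_sequence(prox.rna_chain)
        map_protein = build_equivalence(
            alignments[prox.protein_alignment].reference.ungapped(),
            p_seq, p_nums, chain=prox.protein_chain,
        )
        map_rna = build_equivalence(
            alignments[prox.rna_alignment].reference.ungapped(),
            r_seq, r_nums, chain=prox.rna_chain,
        )

    results = proximity_filter(
        model, prox.candidates, prox.site, map_protein, map_rna,
        threshold_a=threshold,
    )
    with open(outdir / "proximity.tsv", "w") as fh:
        fh.write("position\tmin_distance_A\twithin_threshold\tstatus\n")
        for r in results:
            d = "" if r.min_distance_a is None else f"{r.min_distance_a:.3f}"
            w = "" if r.within_threshold is None else str(r.within_threshold)
            fh.write(f"{r.candidate_position}\t{d}\t{w}\t{r.status}\n")
    return ProximitySummary(
        site=prox.site,
        threshold_a=threshold,
        candidates=[
            CandidateSummary(
                position=r.candidate_position,
                min_distance_a=r.min_distance_a,
                within_threshold=r.within_threshold,
                status=r.status,
            )
            for r in results
        ],
    )


# ---------------------------------------------------------------------------
# orchestrator
# ---------------------------------------------------------------------------

def run_screen(config: ScreenConfig) -> ScreenSummary:
    """Run every configured stage and write a schema-valid summary.json."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    skipped: list[str] = []

    def stage(name: str, func, *args):
        try:
            return func(*args)
        except CpdScreenError as exc:
            raise StageError(name, exc) from exc

    alignments = stage("alignments", _load_alignments, config)

    cpd_sites = None
    if config.scan is not None:
        cpd_sites = stage("scan", _run_scan, config, alignments, outdir)
    else:
        skipped.append("scan")

    ci_sets = ci_comparisons = None
    if config.ci_sets:
        ci_sets, ci_comparisons = stage("ci", _run_ci, config, alignments,
                                        outdir)
    else:
        skipped.append("ci")

    dating = None
    if config.dating is not None:
        dating = stage("dating", _run_dating, config, outdir)
    else:
        skipped.append("dating")

    proximity = None
    if config.proximity is not None:
        proximity = stage("proximity", _run_proximity, config, alignments,
                          outdir)
    else:
        skipped.append("proximity")

    summary = ScreenSummary(
        version=__version__,
        seed=config.seed,
        thresholds=config.thresholds,
        cpd_sites=cpd_sites,
        ci_sets=ci_sets,
        ci_comparisons=ci_comparisons,
        dating=dating,
        proximity=proximity,
        skipped_stages=skipped,
    )
    payload = json.loads(summary.model_dump_json())
    (outdir / "summary.json").write_text(
        json.dumps(payload, indent=2, sort_keys=True) + "\n"
    )
    return summary


def summary_json_schema() -> dict:
    """JSON schema of the top-level summary (also shipped as package data)."""
    return ScreenSummary.model_json_schema()
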