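# Methods

## The screen in outline

A compensated pathogenic deviation (CPD) is an allele that is pathogenic
on the human genetic background but is the fixed wild-type state in
another species; its carrier lineage must harbor a compensatory change.
`cpdscreen` operationalizes the three lines of evidence used to nominate
such compensatory modifiers for mitochondrial 12S rRNA decoding-site
mutations: sequence (which clades have fixed the pathogenic allele, and
how conserved are the candidate compensatory positions), structure (which
candidate residues physically neighbor the mutated nucleotide in a
ribosome model), and time (which allele was fixed first).

## Conservation index

For a reference position *p* the conservation index is

    CI(p) = 100 · n_match / n_total

over the non-reference rows of an orthologous alignment, where a row
"matches" iff it carries exactly the reference (human wild-type) state at
the column homologous to *p*.

Conventions, chosen once and applied everywhere:

* **Denominator.** The reference row is excluded from both counts. Gaps
  and unresolved characters (N for nucleotide, X for protein) stay in
  `n_total` but never count as matches — a gapped sequence does not harbor
  the wild-type variant. This makes CI an exact fraction of the species
  counted (544/608 → 89.5 %), with no secondary filtering that would make
  printed counts irreproducible.
* **Rounding.** CI is reported to one decimal; all comparisons and set
  means use the unrounded values.
* **Set means** average already-computed per-position CIs rather than
  pooling counts, so the mean of a printed CI list is exactly the list's
  arithmetic mean.
* **Set comparison** uses the classical unpaired two-tailed Student
  *t*-test with pooled variance (`scipy.stats.ttest_ind`), significance at
  p < 0.05. Welch's form is available behind a flag for unequal-variance
  sets. Two identical constant sets return t = 0, p = 1; constant sets
  with different means raise a degenerate-variance error rather than
  returning an infinite statistic.
* The gene-wide mean CI iterates over ungapped *reference* positions only;
  alignment columns where the human reference is gapped contribute
  nothing. A published gene-wide figure computed from a specific curated
  sequence set is therefore only reproducible with that exact set; the
  implementation is instead validated against per-column hand tallies.

Coordinates are 1-based and closed throughout (rCRS convention: m.1494 is
the 1494th reference base). U and T are equated at read time, lowercase is
uppercased, and IUPAC ambiguity codes beyond N are collapsed to N with a
warning so that "unresolved" is a single class in CI denominators.

## CPD calling and clade fixation

Each non-reference taxon gets one verdict per curated pathogenic site:
`wildtype`, `pathogenic_allele`, `other`, or `unresolved` (gap/N), by
exact state match at the mapped column. The curated site definition is
authoritative; if the reference row disagrees with the declared wild-type
allele the scan warns and proceeds with the declared alleles, since
coordinate standards occasionally differ from historical allele labels.

Per-clade tallies group verdicts at a requested taxonomy rank (family /
subfamily / tribe, carried as free-form ordered labels; unlabeled taxa go
to an `unassigned` bucket). A clade is flagged *fixed* when at least a
configurable fraction (default 1.0) of its resolved members carry the
pathogenic allele; the exception count is always reported alongside, so a
clade fixed save one reverted species (the *Papio ursinus* pattern — 47 of
48 family members) is visible either by relaxing the fraction or by
reading `n_exceptions` at the strict default. The cutoff is deliberately a
parameter: "fixed in a species set" has no canonical numeric definition.

Watson–Crick status of an interacting position pair (1494·1555) is strict
complementarity only — A–T(U) or G–C. G·U wobble counts as
non-Watson–Crick because aminoglycoside binding depends on the canonical
pair geometry; gap/N yields `unresolved`.

## Fixation dating

Model: **single gain, bounded losses** (Dollo-like parsimony). The derived
allele arose exactly once; within the gain clade up to `max_losses`
(default 1) maximal subclades may have reverted; regain is disallowed. The
gain clade is the MRCA of all derived tips. Losses are counted as the
maximal subclades inside it containing at least one ancestral-state tip
and no derived tip; subclades of only unknown-state tips are compatible
with retention and cost nothing (an unsequenced subfamily neither forces
nor forbids anything). If the required losses exceed the budget the
inference fails loudly — it never silently picks a smaller clade, because
the screen's temporal argument presumes a single origin.

The fixation interval is `[stem age, crown age]` of the gain clade: the
allele was fixed somewhere along the stem branch. For a gain on the root
edge the root age bounds both ends; for a single-tip gain the crown age
is 0. The minimum gap between two alleles' fixations is
`max(0, earlier.youngest − later.oldest)`, where "earlier" is the interval
with the older stem bound; 0 signals possible overlap.

Trees are read from newick with branch lengths in Myr; node ages are
computed as tree depth minus root distance and checked ultrametric to a
relative tolerance of 1e-6 of tree depth (tips at age 0). Negative branch
lengths are format errors. Ages are carried as continuous Myr, compared
exactly, reported to one decimal.

The built-in catarrhine tree (`synth.primate_screen_tree`) encodes
published primate divergence estimates for the four nodes that matter to
the screen — 32 (ape / Old World monkey), 18 (Cercopithecidae crown), 12
(Cercopithecini–Papionini), 8 (Papionini crown) Mya — plus representative
tips; crown ages of clades not involved in either interval (Hominoidea 20,
Colobinae 13, Cercopithecini 9 Mya) are plausible round values that do not
affect any reported bound.

## Structural proximity

PDB fixed-column files are parsed with Biopython's `Bio.PDB` (one model
selected by 0-based index; highest-occupancy altloc kept; waters excluded
by default). Distances are all-pair minima between two
(chain, residue-number) selections, by default over **heavy atoms** only —
crystal structures at ribosome resolution carry no hydrogens, so a
contact criterion stated from such a model cannot have used them. The
contact test is strict (`distance < threshold`), threshold default 6 Å.

Human numbering is mapped to structure residue numbering either by a
curated table or by global pairwise alignment
(match +1, mismatch −1, gap open −5, gap extend −1 via
`Bio.Align.PairwiseAligner`); a map covering under 50 % of the query is
rejected as low-confidence rather than used silently. Candidates missing
from the map are reported `unresolved`, never dropped; an unmappable
*target site* is an error. Which chains represent the small-subunit rRNA
and the S12 protein in a given structure file is configuration, not
inference. mmCIF input is out of scope for this version.

## Synthetic data: what it does and does not establish

The generators produce inputs whose *relevant summary statistics are
specified exactly*: alignment columns by (n_match, n_other, n_gap) counts,
trees by named node ages and clade-rule tip states, toy structures by
declared minimum distances (axis-aligned placement keeps the distance
exact through the format's 3-decimal coordinate rounding; verified to
1e-3 Å). Unspecified alignment columns are i.i.d. with a per-row match
probability defaulting to 0.776, a realistic mammal-wide mean conservation
for the mitochondrial rRNA gene. Each generator is a bit-reproducible
function of (spec, seed) via a private `numpy` Generator stream.

No substitution process is simulated along the tree: column composition
and tip states are declared, not evolved. Passing tests therefore
establish that the *measurement* code — counting, mapping, tallying,
dating, distance computation — is correct on data with known ground truth.
They do not establish robustness to real-data pathologies (alignment
error, fragmentary sequences, paralogy, calibration uncertainty in node
ages, structural disorder), which the pipeline surfaces only through its
explicit unresolved/error channels.

## Pipeline

`run_screen` chains the stages from one YAML config. Stages are
independently invokable; the orchestrator communicates only through
declared files, writes one TSV/JSON per stage plus a top-level
`summary.json` validated against a pydantic model (its JSON schema ships
with the package), logs every threshold used with both unrounded and
reporting-precision values, marks unconfigured optional stages as
skipped, and aborts with the stage name on any stage error. Runs are
deterministic: identical config and seed give byte-identical summaries.

## Known limitations

* CI is a plain match percentage; no entropy, rate, or phylogenetic
  correction, by design.
* Single-gain dating cannot represent recurrent origins; patterns needing
  two gains fail rather than date.
* The fixation interval inherits the node-age point estimates of the input
  tree; no calibration uncertainty is propagated.
* The proximity stage reports geometric distance only — no energetics and
  no contact-network context.
* Alignments are consumed as given; no trimming, filtering, or alignment
  computation is performed before CI estimation.
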