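# Methods

## The quantification model

The pipeline estimates relative protein abundance in each purification
with the exponentially modified Protein Abundance Index,

    emPAI = 10^(N_observed / N_observable) − 1,

where `N_observed` is the number of *distinct* peptide sequences
identified for the protein among high-confidence PSMs of that run
(re-sequenced peptides count once), and `N_observable` is the number of
unique in-silico tryptic peptides of the protein whose monoisotopic mass
lies in the instrument-accessible window.  emPAI is a coverage-based
proxy: it is 0 when nothing is observed, strictly increasing in
`N_observed`, and exactly 9 at full coverage.  It assumes that peptide
detectability is dominated by being inside the mass window — no
flyability, charge-state or modification modelling is attempted.

### High-confidence filter

A PSM is retained iff score ≥ 20, delta ≥ 5, |relative mass error| ≤ 5
ppm and 400 Da ≤ peptide mass ≤ 6000 Da.  All four bounds are inclusive
and configurable (`FilterCriteria`).  Interpretation choices:

* the error bound applies to the *absolute value* of the calibrated
  relative error in ppm (the input column is a signed ppm value);
* delta is treated as an opaque per-PSM margin supplied by the search
  engine; the pipeline never recomputes it;
* the mass window applies to the peptide's neutral monoisotopic mass in
  Da, not m/z, since no charge state accompanies the window.

### Digestion and masses

Digestion follows the Keil rule (cut C-terminal to K/R except before P).
With `missed_cleavages = 0` — the default — the observable-peptide count
assumes ideal digestion, which is how the index was originally defined;
`missed_cleavages = k` adds all concatenations of up to `k+1` adjacent
fragments.  Masses are monoisotopic (FT instruments resolve the
monoisotopic peak), computed as the sum of standard residue masses plus
one water via pyteomics.  No fixed or variable modifications enter the
mass model; cysteine alkylation performed at the bench is deliberately
ignored for observable-peptide masses.  Leucine and isoleucine are kept
distinct.  Peptides shared between paralogs or fusion moieties are
credited to every protein they map to ("all-mapped"); a consequence is
that `N_observed` can exceed `N_observable`, in which case the ratio is
clamped at 1 (emPAI ≤ 9) with a warning.

## The co-purification matrix

`build_matrix` composes filter → distinct-peptide count → emPAI per
(protein, run).  Detection is emPAI > 0, i.e. one high-confidence
peptide suffices; a configurable threshold exists for noisier data.
Proteins never observed anywhere are omitted; a protein observed despite
having zero observable peptides is a model inconsistency and raises.
Background flagging marks every protein with signal in the untagged
control column; flags annotate rows and are never subtracted from bait
columns, since contaminants (e.g. actin) legitimately appear in every
preparation at raw value.  The packaged reference matrix stores its
values as the exact printed decimal strings; serialization writes
shortest round-tripping decimals so that write → read → write is
byte-stable.

## BAF/PBAF classification

Marker sets default to the class-defining subunits: BAF = {ARID1A,
ARID1B}, PBAF = {ARID2, BAF180}.  Names are resolved through each row's
alternative-name annotation, so marker sets can be given in either
nomenclature.  The decision rule has three ingredients:

1. **Group presence.**  The BAF group is present if *any* marker is
   detected — BAF complexes carry either one of the two ARID1 paralogs,
   so the paralogs are pooled alternatives.  The PBAF group is present
   only if *all* its markers are detected — a PBAF complex carries both
   ARID2 and polybromo, so a single stray peptide of one marker is not
   credible evidence of the complex.  Both modes are configurable.
2. **Yields.**  Marker emPAI is summed per group (max is selectable);
   summing pools the mutually exclusive ARID1 alternatives.
3. **Specificity ratio.**  With only one group present the bait gets
   that label.  With both present, a one-sided call requires the summed
   yield of one group to exceed the other by at least
   `specificity_ratio`, default **50**; otherwise the call is "both".
   With neither, "unassigned".

The ratio default is the module's central editorial decision: no
numeric rule accompanies the qualitative calls the scheme is meant to
reproduce.  On the packaged reference matrix the informative columns
bracket the choice — a clearly PBAF-resident bait shows a ~98-fold
marker excess while the core-subunit bait, which genuinely pulls both
complex classes, shows ~21-fold — so any ratio in (21.4, 98.3)
reproduces the expected calls, and 50 is the round midpoint.  A mixed
column whose lopsidedness stays below the ratio (e.g. a 6.5-fold
BAF-leaning column) is reported as "both" with the leaning annotated,
not forced.  Raising the detection threshold can only move labels toward
"unassigned", never away from it.

The interaction network has one directed edge per nonzero (bait, prey)
cell of the non-control columns, weighted by raw emPAI (no per-bait
normalization).  Bait nodes keep their purification id so that two
constructs of the same protein (e.g. a wild-type and a fusion) remain
distinct; an optional bait→accession map records the reported fusion
accession and suppresses the bait's own row as a self-edge.

## The synthetic-data generator

`default_config()` mirrors a complex-walking study design: a 7-member
shared core, a BAF-specific set (with its ARID1-like marker pair) and a
PBAF-specific set (with its ARID2/polybromo-like pair), one abundant
actin-like contaminant, eight baits — five BAF-specific, one
PBAF-specific, one core subunit pulling both complexes, one
dual-resident subunit — and one untagged control.  Per run, a protein's
pull-down intensity is Σ efficiency × abundance over the complexes the
bait participates in, plus contaminant background.  Each observable
peptide is sequenced independently with probability `1 − exp(−κ·I)`
(default κ = 4): a saturating response chosen because it reproduces
emPAI's monotone abundance reading and reaches the full-coverage
(emPAI = 9) regime for efficiently pulled baits.  Retained PSMs draw
score = 20 + Exp(15), delta = 5 + Exp(5) and a mass error N(0, 1.5 ppm)
truncated to ±5; a decoy fraction (default 0.25 of the genuine PSM
count) adds PSMs violating exactly one criterion each, so the filter
stage is genuinely exercised.  Peptides are credited to every simulated
protein having them as a tryptic fragment, as a database search with
tryptic specificity would.  Protein sequences are uniform random
20-letter strings of length 100–600 (≈10 % K/R, hence realistic tryptic
fragment lengths), redrawn up to 100 times until at least one observable
peptide exists.  All randomness flows from one integer seed through
named substreams, so a fixed seed reproduces every byte of output
regardless of call order.

What the generator does *not* emulate: spectrum-level noise, retention
time, protein-length-dependent detectability, shared peptides between
designed paralogs, non-tryptic cleavage, and realistic contaminant
repertoires.  Passing recovery tests therefore show that the pipeline's
logic is sound under its own model assumptions, not that the classifier
is robust to every failure mode of real AP-MS data.

## Test and benchmark problem sizes

The replicate-recovery benchmark runs 50 independently seeded studies of
the default design (20 proteins, 9 runs each, ≈500 PSMs per run) and
requires ≥ 95 % per-bait label accuracy; with the noise model off,
recovery must be exact.  Oracle-equivalence suites use 1,000 random PSMs
against the four-way single-criterion intersection, exhaustive
enumeration on proteins ≤ 500 residues, and 1,000 random sequences for
the digestion partition property; pyteomics' cleavage rule serves as an
independent digestion oracle.

## Known limitations

* emPAI values are not comparable across instruments or search settings;
  the reference matrix's printed values are treated as data, not as
  round-trip targets from sequence databases (the original
  observable-peptide parameters behind them are unknown).
* The classifier is a two-class marker scheme; complexes defined by
  other marker logic need a different `MarkerScheme`, and genuinely
  mixed columns are only ever labelled "both", never deconvolved.
* Zeros in a matrix mean "no high-confidence peptide"; the pipeline
  cannot distinguish absence from below-detection abundance.
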