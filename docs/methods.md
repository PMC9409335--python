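# Methods

## Scope and model of the analysis chain

`legumepep` implements the desk side of a bioactive-peptide study on legume
storage proteins: rule-based in silico gastrointestinal proteolysis,
screening of peptides against a bioactive-fragment database, monoisotopic
mass verification of identified peptides, and the dose–response and kinetic
models behind antioxidant, antihypertensive (ACE-inhibition) and antidiabetic
(DPP-IV-inhibition) assays. Wet-lab procedures (digestion chemistry,
chromatography, spectral database searching) are out of scope; the package
consumes their outputs (sequences, identified peptides, plate readouts).

## In silico proteolysis

A protease is modelled as a pure P1/P1' predicate: the bond between residues
*i* and *i+1* (1-based) is cut when residue *i* belongs to the enzyme's P1
set and residue *i+1* is not in its P1' blocker set. Several enzymes acting
*simultaneously* cut the union of their site sets, and digestion is
exhaustive — every predicted site is cleaved, no missed cleavages — because
the release frequency A_E is defined on the fully released fragment set.

The packaged specificity tables follow ExPASy-PeptideCutter-style
conventions: trypsin cleaves after K/R unless followed by P; high-specificity
chymotrypsin after F/Y/W unless followed by P; pepsin (pH > 2) after F/L with
no blocker. These are an explicit approximation — web tools that perform the
same digestion publish slightly different tables, so per-protein A_E values
from such tools are not expected to be reproduced number-for-number. The
tables live in a tab-delimited data file (`enzyme_id, ec_number, p1_residues,
p1prime_blockers, description`) and users can substitute their own.
Extended-context rules (P4…P2') are intentionally unsupported; the rule type
carries a free-text description for documentation.

## Screening parameters A, B and A_E

For a peptide of length *N* and an activity class:

* **A = a/N**, where *a* is the total number of occurrences of that class's
  database fragments in the peptide. Occurrences are counted
  **overlap-inclusively** (every start position counts): for EEEDEDEPR
  against the stimulating fragments {EEE, EE}, EE occurs at positions 1 and 2
  inside the EEE run, so a = 3 and A = 0.33. This convention is the only one
  consistent with the published per-peptide values the regression fixture
  encodes.
* **B = (Σᵢ aᵢ/EC50ᵢ)/N** over the *k* distinct matched fragments that carry
  an EC50 (µM); fragments without an EC50 contribute nothing, and B is
  *missing* (not zero) when k = 0.
* **A_E**: the parent protein is digested exhaustively and released fragments
  whose whole sequence equals a database fragment of the class are counted
  (with multiplicity) and divided by protein length. Substring credit is
  deliberately not given — a released peptide that merely *contains* an
  active fragment is the business of A, not A_E. The choice of protein
  length as denominator mirrors A.

Reported values are rounded half-away-from-zero (0.625 → 0.63); Python's
built-in banker's rounding would disagree with published values at exact
halves. Full precision is kept internally.

The packaged fragment table contains only the fragments reported for the
study's eleven identified peptides; it is a fixture for regression tests, not
a redistribution of any external database, and it carries no EC50s because
those are not part of the published record. B is therefore tested against
hand-evaluated cases and synthetic EC50-bearing databases.

Ambiguous residues (X/B/Z/U) are rejected by default since the screening
arithmetic is undefined for them; a lenient mode maps them to a sentinel that
can never match a cleavage rule or database fragment (both are validated
canonical-only).

## Peptide masses

Neutral monoisotopic mass is the residue-mass sum plus one water plus
modification deltas. Residue masses and the water mass come from the
standard Unimod/IUPAC monoisotopic table (via pyteomics). The default
modification registry mirrors a typical identification search: fixed
carbamidomethyl-C (+57.021464), variable oxidation (+15.994915, M/W),
deamidation (+0.984016, N/Q), acetylation (+42.010565, K or N-terminus) and
phosphorylation (+79.966331, S/T/Y). All eleven identified peptides
reproduce their published calculated masses within 0.001 Da with this table,
deamidation applied where annotated.

Mass error is (observed − calculated)/observed × 10⁶ ppm. Published ppm
values were evidently computed on full-precision masses, so they cannot be
regenerated exactly from the 3-decimal printed masses; ppm tests assert the
formula, not that column.

## Assay models

Percent transforms are affine in the sample signal: scavenging/chelation and
DPP-IV inhibition are (1 − signal/control) × 100, viability is the plain
ratio × 100, ACE inhibition is (1 − (PA_control − PA_sample)/(PA_control −
PA_blank)) × 100 on substrate peak areas, and CAA is (1 − ∫SA/∫CA) × 100 on
integrated fluorescence. Transforms are applied per replicate; fitting pools
replicate points rather than averaging them first, preserving the error
structure (whether the original analyses fitted means or pooled replicates is
not documented; pooled is this package's choice).

**4PL fitting.** y = bottom + (top − bottom)/(1 + (x/midpoint)^(−hill)),
least squares via `scipy.optimize.curve_fit` with initial values bottom =
min response, top = max response, hill = 1, midpoint = the concentration
whose mean response is nearest halfway between the extremes; the midpoint is
bounded positive, other parameters free, and tolerances are tightened
(1e−14) so noiseless data is recovered to ≤ 1e−6 relative error. The
reported EC50/IC50 is the fitted midpoint parameter, not the absolute-50 %
crossing (these differ when top/bottom ≠ 100/0; callers wanting the crossing
can solve the fitted curve explicitly). Non-convergence and flat
(unidentifiable) data return a result flagged `converged=False` rather than
raising. Fewer than 4 distinct concentrations is an error.

Midpoint confidence intervals use a percentile **residual bootstrap**
(centred residuals resampled onto the fitted curve, model refitted): with
the ~3 replicates per concentration typical of plate assays, within-group
case resampling is too discrete to approximate the sampling distribution and
undercovers badly, while the residual scheme stays within 10 points of
nominal in the seeded simulation the tests run.

**ORAC.** AUC = 1 + Σₜ RFUₜ/RFU₀ over per-minute readings — the rectangular
sum exactly as the assay software defines it, not a trapezoid — so a constant
90-minute trace gives 91 and a linear decay to zero gives 45.5. Net AUC
subtracts the blank's AUC; a straight-line Trolox standard curve (≥ 3
standards) converts a sample's net AUC to µM Trolox equivalents. The
conversion to µmol TE per mg protein multiplies by the reaction volume
(default 200 µL: 25 sample + 150 fluorescein + 25 radical initiator) and any
pre-dilution, then divides by the protein loaded; volume and dilution are
explicit parameters because published values rarely document this
bookkeeping.

**CAA.** Sample and control traces are corrected by subtracting the blank
trace pointwise and then each trace's own time-0 reading, integrated by
rectangular summation over the first 60 minutes; negative intermediate areas
are kept (clipping would bias CAA upward).

## Synthetic data

The generators provide every pipeline input with known ground truth:

* random proteins with a chosen residue composition (uniform by default);
* fragment databases with unique (sequence, activity) pairs, log-uniform
  EC50s in a stated range (default 1–500 µM) and an exact fraction of
  records lacking EC50 (default 0.5);
* dose–response readouts: 4PL truth (default bottom 0, top 100, hill 1.2,
  midpoint 500) plus additive Gaussian noise (default sd 3 percentage
  points, 3 replicates) — additive homoscedastic noise matches readouts
  reported as mean ± SD, and a heteroscedastic option is deliberately left
  out of the defaults;
* fluorescein-decay traces: constant at RFU₀ through an antioxidant lag,
  then exponential decay — the minimal shape giving the lag-dependent AUC
  behaviour the ORAC assay assumes (real traces have sigmoidal shoulders and
  plate-edge artefacts the generator does not emulate).

One global seed fans out to fixed per-generator substreams, so adding a
generator never perturbs existing outputs and a fixed configuration is
byte-reproducible.

For the 4PL recovery study (200 seeded simulations) the design is an 8-point
log-spaced grid centred on the true midpoint and spanning ~1.7 decades each
side (10–25 000 for midpoint 500), the textbook design that pins both
plateaus; the median relative midpoint error is then below 5 %. Under the
truncated 100–6000 µg/mL range the assays themselves use, the same noise
model yields a median error nearer 6 % — EC50 precision degrades when the
plateaus are not sampled, which is a property of the design, not the
estimator.

What passing these tests shows — and does not show: the screening and mass
arithmetic is exact, the digestion engine satisfies its structural
invariants against brute-force oracles, and the fitting machinery recovers
known truths under the stated noise. It does not certify the enzyme
specificity tables against any particular web tool's snapshot, and it cannot
reproduce wet-lab EC50/IC50 tables, which depend on the physical digestates.

## Numerical and degenerate-input policy

* Percent transforms raise on non-positive controls (degenerate assay);
  ACE raises when control and blank peak areas coincide.
* ORAC integration raises on zero initial fluorescence; traces must start at
  t = 0 with non-negative readings.
* Trolox fitting requires ≥ 3 standards and a non-singular design.
* The screening engine treats an activity absent from the database as an
  empty profile (A = 0), not an error.
* FASTA accessions are the first whitespace-delimited header token with the
  `sp|ACC|NAME` / `tr|ACC|NAME` dialects unwrapped; duplicate accessions in
  one file are an error.

## Problem sizes used by the test suite

Property tests run 1000 random proteins (≤ 120 residues) for digestion
invariants, 1000 random (peptide, database) instances against the
all-substrings screening oracle, 200 seeded simulations for 4PL recovery and
a 40-dataset × 79-resample study for bootstrap coverage; the full suite
completes in well under a minute on a laptop-class core.

## Known limitations

* Digestion is binary and exhaustive: no missed cleavages, no kinetics, no
  pH-dependent rates.
* The A/B/A_E definitions assume exact string matching; no similarity or
  homology credit.
* m/z and isotope envelopes are out of scope; only neutral monoisotopic
  masses are computed.
* The 4PL midpoint is reported as-is even when the fitted plateaus are far
  from 0/100; interpret IC50s from truncated concentration ranges with care.
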