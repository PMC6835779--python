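# Methods

## Overview

`grainrisk` models a comparative peptidomic risk assessment of wheat
genotypes against a commercial reference: in-silico enzymatic digestion of
Osborne protein fractions, reliability filtering of peptide identification
tables, linear-epitope screening for celiac disease (CD) and wheat allergy
(WA), digestion-fate tracking through a gastroduodenal (GD) endpoint, and
conserved/differential hazard reporting. The pipeline starts from
identification tables (sequence plus search-engine evidence), not spectra;
spectral search, mass tolerances and FDR estimation are upstream concerns
whose outputs (PSM counts, scores, confidence labels) are consumed as given.

## Digestion model

Specific digestion treats a protease as a residue set and a cut side.
Chymotrypsin cuts C-terminal to F/L/W/Y; the dual thermolysin+chymotrypsin
protocol is modelled as the single union rule A/F/I/L/M/V/W/Y on the
C-terminal side, mirroring how a combined-specificity search treats the two
enzymes as one cleavage pattern. No proline exception is applied by default
(variants of chymotrypsin specificity that suppress cuts before P exist;
the rule set here is the plain one), but `EnzymeSpec.blocked_following`
exposes a configurable exception set, and `CleavageSide.N_TERMINAL` is
available for a thermolysin-faithful N-side rule.

Peptides are all windows between two boundaries (cut sites or protein
termini) with at most `max_missed_cleavages` skipped internal sites
(default 5 — storage proteins are poor protease substrates and wide limits
recover more of their sequence) and length within 4–144 AA. Protein termini
are boundaries, never missed cleavages. Coordinates are 1-based inclusive;
`to_zero_based` converts for slicing. Unspecific enumeration — the GD
search-space emulation — lists every substring in the length window; its
count obeys the closed form Σ_L (n − L + 1).

## Filtering and multiconsensus

Peptide rows are retained when PSMs ≥ 3, score ≥ 1.0, confidence ≥ medium
and the assignment is unambiguous (all thresholds inclusive, each
configurable). An audit object counts failures per criterion. Runs of one
sample are merged into a multiconsensus keyed by (sequence, stage) —
modification-blind, because epitope screening operates on bare sequences; a
strict mode keys on modifications too. Merged evidence is the permissive
reading of a multiconsensus: summed PSMs, maximum score, maximum confidence
(the resolution rule for conflicting labels is not dictated by the
search-engine convention, so the permissive choice is documented here), and
provenance records contributing digests. Protein-level rollups can reuse
the same engine on an aggregated table.

## Screening

Length gates: CD 9 AA (shorter fragments cannot occupy the MHC class II
groove), WA 5 AA (shortest database epitope). Intact matching reports every
occurrence offset of a full epitope inside a peptide (equality counts as
containment). Partial matching reports, for pairs without an intact hit,
the longest contiguous shared substring when ≥ `min_overlap` (default 5,
matching the WA gate), with ties broken by smallest epitope offset then
smallest peptide offset; it is implemented as plain dynamic programming —
peptides are tens of residues, so asymptotics are irrelevant. Matching is
case-insensitive and modification-blind. Q/E equivalence (deamidation-aware
CD matching) is deliberately not applied: the screening emulated here
matches native sequences. Hazard peptides are deduplicated per sample — a
peptide carrying several epitopes counts once.

## Fate and conservation

Per (epitope, sample): `NOT_EXPRESSED` when the epitope is never intact in
any Osborne fraction; otherwise `GD_RESISTANT` (intact in GD),
`PARTIALLY_DEGRADED` (only a partial GD trace), or `FULLY_DEGRADED`. An
epitope with GD evidence but no fraction expression — possible when the two
routes differ in sensitivity — is classified `NOT_EXPRESSED` and flagged as
an audit anomaly rather than silently promoted.

Partial traces for fate purposes are computed on GD peptides of
≥ `min_overlap` residues rather than the disease gate: the 9-AA CD gate
exists to exclude non-stimulatory fragments from *hazard counting*, but a
5–8 AA fragment is exactly the evidence that distinguishes partial from
full degradation, so hiding it would misclassify fates.

"Present" for conservation means ≥ 1 intact match in the sample's GD pool
(the hazard-relevant readout); a mode over fraction presence is available
via `presence_from_matches` on fraction match sets. Epitopes present in all
samples are CONSERVED, in some but not all DIFFERENTIAL, absent everywhere
excluded. The presence-matrix writer emits only DIFFERENTIAL rows — the
discriminating surface — ordered by (source label, ID).

## Reporting

Relative hazard: `rel% = round(100 · n_hazard / n_hazard(reference))`,
rounded half away from zero; the reference reports 100 and a zero reference
count is an error, not a NaN. Class distributions attribute each epitope to
one protein class via its source label (allergen codes beat free-text
keywords; gliadin subclasses take priority over glutenins); dual-source
epitopes (e.g. "γ-gliadin or LMW glutenin") count once under the first
listed family with the ambiguous label preserved.

## Packaged fixtures

Two differential GD-resistant epitope tables are packaged (34 CD rows,
30 WA rows) with restriction/allergen annotations, core names and
per-sample presence calls over a six-sample panel (reference + 5
genotypes). In the packaged presence tables no epitope is marked in every
column, so all fixture rows are DIFFERENTIAL. The panel-conserved
GD-resistant epitopes are shipped as ID-only annotation lists (8 CD IDs
plus five core names; 25 WA IDs): their sequences are not part of the
fixture, so they participate in bookkeeping but not in sequence matching.

## Synthetic data

The generator emulates the statistical structure the analysis assumes, not
mass spectrometry itself:

* **Proteome.** Per class, `n` proteins with lengths uniform in 250–400 AA
  (storage-protein scale); storage-class backgrounds drawn from a
  P/Q-dominated residue bias (Q 0.32, P 0.20, moderate F/L/Y/S/V), other
  classes from a flat alphabet. Epitopes are spliced in verbatim at
  recorded positions (the implant registry).
* **Fractions.** F1 ← albumin/globulin classes, F2 ← gliadins plus each
  glutenin leaked with probability 0.3 (partial glutenin extraction in
  ethanol produces the observed F2/F3 overlap), F3 ← glutenins. Fraction
  peptides are the single-enzyme and dual-enzyme specific digests.
* **GD pool.** Per implant, a Bernoulli draw with class-dependent survival
  decides whether a window containing the intact epitope (uniform 4–12 AA
  of flanking background) or only a sub-epitope fragment is emitted.
  Default survival probabilities encode the qualitative resistance ranking
  observed for wheat proteins: ns-LTP/ATI 0.9, γ/ω-gliadin 0.75,
  α-gliadin 0.4, LMW-GS 0.2, HMW-GS 0.05. Fragments are the longest proper
  prefix/suffix of the epitope that contains no fixture epitope (nested
  epitopes make this screen necessary) and at least `min_overlap` residues;
  emission can be disabled to force full degradation.
* **Noise.** Genuine rows always receive evidence passing the default
  filters; optional decoys draw weak evidence and are screened to contain
  no fixture epitope, so false-positive assertions are exact.
* **Ledger.** Ground truth (expression, GD presence, hazard sets, fates,
  conservation) is computed at generation time with plain substring
  containment over the full epitope table — independent of the screening
  module's offset-reporting scanner and LCS matcher, and automatically
  consistent on cross-contained epitopes (one fixture epitope can be a
  substring of another, so a surviving window for one implants intact
  evidence for both).

What the generator does **not** emulate: spectra, mass accuracy, retention
time, dynamic-exclusion acquisition, abundance-dependent sampling depth, or
INFOGEST enzyme kinetics. Passing end-to-end tests therefore demonstrate
the correctness of the computational pipeline on pools with realistic
sequence structure, not instrument-level fidelity.

## Numerical and design choices

* Rounding is half away from zero; no half-way case occurs in the packaged
  six-sample counts, so the choice is observationally equivalent to other
  conventions there.
* Determinism: every stochastic step flows from one integer seed through
  `numpy.random.default_rng`; identical seeds give byte-identical outputs.
* Degenerate inputs: empty FASTA → warning + empty list; empty match set →
  empty distribution; zero-reference hazard → explicit error; proteins
  shorter than `min_len` → empty unspecific enumeration.
* The acceptance script uses modest problem sizes (200 random sequences for
  the digestion oracle, 100 peptide/epitope pools for matching, a
  two-sample study per deterministic-survival setting, 1000 implants for
  the stochastic-survival check) — large enough for tight binomial bands,
  small enough to run in seconds.

## Known limitations

* The length gate for fraction-route screening defaults to the disease
  gate; whether ungated fraction screening is preferable is
  situation-dependent and exposed as `gate_fractions=False`.
* Class attribution is keyword-based and intentionally coarse (parent
  families only); hordein/secalin-homologous labels ("hor-1", "hor-2") are
  not attributable from text and map to UNKNOWN (implant targeting defaults
  them to ω-gliadin, whose solubility class they share).
* `fraction_overlap` reports peptide/protein set partitions; no statistical
  test of count differences is provided.
* FDR estimation, MHC-binding prediction and T-cell reactivity scoring are
  out of scope; confidence labels are consumed, never computed.
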