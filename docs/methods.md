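# Methods

## Mass model

All masses are neutral monoisotopic masses in daltons, built from
hard-coded light-isotope elemental masses (H 1.00782503207, C 12,
N 14.0030740048, O 15.9949146196, S 31.97207100, P 30.97376163) and
residue elemental compositions. A peptide's mass is the sum of its
residue masses plus one water. Substitution deltas are differences of
residue masses; the two that define the searches here are
V→S = −12.03639 Da and T→S = −14.01565 Da. Deltas are carried at full
double precision; four-decimal rounding is presentation only (printed
conventions differ between truncation and rounding at the fourth
decimal, which a ±0.0002 Da comparison tolerance absorbs).

The modification registry computes deltas from elemental composition,
never from typed-in decimals: carbamidomethyl +57.02146 (fixed, C),
oxidation +15.99491 (M), acetyl +42.01057 (N-terminus), among others.
Note that the elemental acetyl value is 42.0106 Da; a commonly printed
42.0102 appears in some search configurations but is not derivable from
any composition, so this package uses the elemental value.

`collision_scan` flags near-isobaric confusions: registry entries (all
380 ordered substitutions plus modifications) whose delta falls within a
caller-supplied tolerance of a given substitution. I and L are treated
as distinct residues with exactly equal mass, so I/L-involving pairs are
reported as unresolvable by mass. V→S (−12.0364) is exactly isobaric
with I→T and L→T — all three lose C2H4 and gain O — which is why
candidate substituted spectra warrant manual inspection.

## Sequence database and digestion

A database pairs each protein with its coding DNA sequence; loading
validates a one-to-one ID match, ACGT-only CDS (ambiguous bases are
rejected because per-codon counting needs exact codon identity), exact
standard-genetic-code translation, no internal stops, and an optional
trailing stop codon which is stored but never indexed. Coordinates are
0-based half-open internally; only rendered reports use 1-based.

In-silico Lys-C digestion cleaves C-terminal to every lysine, including
before proline (Lys-C, unlike trypsin, cleaves K|P). With `max_missed`
> 0, all concatenations of up to `max_missed + 1` adjacent fragments are
returned. Peptide location is an exact substring scan over a
concatenated protein corpus, returning every occurrence in
deterministic (gene, offset) order; shared peptides are resolved later
by the unique-localization filter rather than by any isoform heuristic.

## PSM processing

The PSM dialect is a tab-separated table with columns `spectrum_id,
base_sequence, sub_positions (1-based, ';'-joined), sub_from, sub_to,
charge, calc_mass, obs_mass, score, is_decoy`. Parsing validates each
row independently (substituted positions must carry the origin residue;
at most 2 substituted sites per peptide; precursor mass within the ppm
tolerance, 20 ppm by default) and collects violations per row instead of
failing the file.

q-values use plain target–decoy competition: at each score threshold s,
FDR(s) = #{decoys ≥ s} / max(1, #{targets ≥ s}), with decoys counted
before targets at tied scores (conservative); a target's q-value is the
minimum FDR over thresholds that admit it, so q is nonincreasing in
score. No semi-supervised rescoring is attempted — the analysis needs a
calibrated 1% PSM-level FDR gate, not a rescoring engine. Decoys inherit
the q of the nearest lower-scoring target. After filtering, PSMs
collapse to unique peptides keyed by (sequence, substituted positions,
origin, destination); wild-type and substituted forms are distinct keys.

## Frequency definitions

Residue level: the numerator is the number of unique substituted
peptides whose wild-type sibling (same base sequence) was observed in
the same replicate; the denominator is the number of unique peptides
whose base sequence contains the origin residue, counting wild-type
forms and (by default) the substituted forms themselves — excluding them
would let high mistranslation shrink its own denominator. Counts are
unique-peptide counts by default; PSM-weighted counting is available as
`count_mode="psm"`. An empty denominator raises rather than reporting
0%. Replicates are processed independently end to end; group comparisons
(Welch's t on per-replicate frequency vectors, Holm-corrected across a
codon family) operate on the per-replicate values.

Codon level: substituted peptides must carry exactly one substituted
site and locate to exactly one database position; wild-type peptides
must locate uniquely. Counting is occurrence-level — each origin-residue
site in a retained wild-type peptide is one wild-type event at its
codon; each retained substituted peptide is one substitution event at
its site's codon — because codons are properties of sites, not
peptides. The codon-level analysis does not require the sibling rule
(its denominator already conditions on the wild-type peptide being
observed); the residue-level analysis does not require unique
localization. The event-weighted mean of per-codon frequencies equals
the event-level overall frequency by construction.

## Decoding classification

Anticodon positions 35/36 must Watson–Crick pair codon positions 2/1;
the class is then decided at the wobble position (anticodon 34 vs codon
3): a Watson–Crick pair (including A34:U — such codons are read as fully
complementary) is `watson_crick`; A34 against C or A is `wobble_I34`
(readable only if A34 is deaminated to inosine, which pairs U, C, A);
G34:U and U34:G are `wobble_GU`; any other third-position combination is
`mismatch_3prime`; a 35/36 mispair is `other`. For the two tRNA variants
modeled here the defaults are anticodon AGU (reads ACN threonine codons)
and AAC (reads GUN valine codons).

## Phenotype statistics

Implementations delegate to established libraries behind this module's
surface: Welch's t (unequal variances, Satterthwaite df) and
Mann–Whitney/Wilcoxon via scipy (exact enumeration when n ≤ 12 without
ties, otherwise normal approximation with tie and continuity
corrections), Kaplan–Meier and the log-rank test via lifelines
(Greenwood variance, log-log 95% CIs; the estimator's synthetic S(0)=1
row is dropped so curves start at the first event time), and Wilson
score intervals via statsmodels (chosen for small-n coverage; the CI
method behind published error bars is rarely stated, so it is a
documented, configurable choice). Fisher's exact test is computed
in-package from the hypergeometric pmf using the two-sided
point-probability rule (sum of tables no more probable than the
observed, with 1e-12 relative slack for floating ties); degenerate
margins warn and return p = 1. Holm–Bonferroni is the five-line
step-down with running maxima, cross-checked against statsmodels.
Climbing and longevity p-values, coming from the same animals, are meant
to be corrected together: collect them into one vector before applying
the correction. `top_quantile_subset` retains, per group, the ⌈q·n⌉
longest-lived deaths (censored subjects excluded), with ties broken by
subject ID.

## Synthetic data

`SimulationSpec` defaults encode the study conditions the pipeline is
validated under: a 1,600-gene proteome (lognormal lengths, median ~350
residues, clipped to [60, 2000]; residues i.i.d. from average proteome
frequencies; synonymous codons uniform unless reweighted), serine
substitution at threonine codons with per-codon rates ACU 1%, ACC 0.5%,
ACA 0, ACG 0, wild-type detection probability 1.0, decoys emitted for
half the peptides as reversed sequences, and unit-variance Gaussian
scores with target and decoy means 4 and 0 (a separation that puts the
1% FDR cut around the 92% target-retention point). The proteome size is
chosen so each threonine codon accumulates ≥ 5,000 wild-type occurrence
events after the Lys-C length window (7–45 residues) discards short and
long fragments.

The generator walks every digest peptide once: the wild-type form is
emitted with the detection probability; each origin-residue site is
independently substituted with its codon's rate, emitting a single-site
substituted PSM (real substitution events are rare enough that
multi-site molecules are negligible; multi-site rows appear only in
hand-made fixtures). Masses are computed from the emitted sequence with
a clipped ~N(0, 3 ppm) precursor error. The ground-truth ledger records
per-codon substituted and wild-type event counts over uniquely-locating
peptides (ambiguously locating substituted rows are tallied separately),
so ledger totals reconcile exactly with the emitted table, and recovery
tests compare estimates to *realized*, not nominal, rates.

What the generator does not emulate: spectral intensity and peak-level
noise, retention time, missed cleavages, shared peptides between
homologous proteins (random sequences rarely collide), protein
abundance differences, and score distributions with realistic shapes.
Passing recovery tests therefore show estimator correctness under the
stated sampling model, not robustness to real-data pathologies such as
chimeric spectra or abundance-dependent detection.

Survival tables draw exponential death times discretized upward to a
3-day inspection grid (mirroring transfer-to-fresh-food scoring);
censoring is an independent exponential whose hazard is set so the
pre-discretization censoring probability equals `censor_rate`
(`censor_rate=1` censors everyone at their drawn time). Count tables are
independent binomials per group.

## Known limitations and numerical choices

- The residue-level frequency conditions its numerator on two FDR
  survivals (substituted row and sibling) but its denominator on one, so
  under score-based thinning it underestimates the ledger frequency by
  roughly the FDR-gate retention factor (~8% relative at the default
  score separation). This mirrors the estimand itself — the sibling rule
  trades a small downward bias for specificity — and the per-codon
  estimator, whose numerator and denominator condition symmetrically, is
  calibrated (recovery within 3 binomial SE at ≥ 5,000 events per
  codon).
- Estimator-recovery tests run at scaled-down problem sizes (12 seeded
  replicates of an 80-gene proteome for the residue-level check; one
  full-size run for the per-codon check) with tolerances derived from
  binomial standard errors at the realized denominators.
- Frequencies with zero events at a codon are reported as 0% when the
  denominator is positive and as 0% with zero events when both counts
  are zero; the residue-level estimator instead raises on an empty
  denominator.
- Ties: score ties in target–decoy competition favor decoys; ranking
  ties break by gene ID; top-quantile ties break by subject ID. All
  traversals run in sorted order so every output is deterministic under
  a fixed seed.
- I/L share a mass: substitution detection cannot distinguish them, and
  `collision_scan` reports such pairs as exact coincidences.
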