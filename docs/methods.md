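# Methods

## The processing model

The package assumes the canonical presequence-processing cascade of plant
mitochondria. A precursor carries an N-terminal presequence cleaved by MPP;
MPP sites fall into −2R, −3R and no-R recognition classes (an arginine two
or three residues upstream of the cut, or none). A subset of MPP products
is trimmed again: ICP55 removes one, occasionally two, residues whose
identity is destabilizing under the N-end rule; OCT1 removes a longer
stretch and can also act without prior MPP cleavage on proteins whose short
presequence it removes in one piece from position 2. Knockout of either
peptidase arrests its substrates at the intermediate stage.

Differential quantification is modelled at the peptide level: every
N-terminal peptide carries one ratio *r* = mutant/wild-type. The package
enforces this orientation at ingest; "upregulated in the knockout" always
means *r* ≥ threshold.

## Curation rules

Three criteria, applied in order, with counts conserved into a
`FilterReport` (every input peptide ends up in exactly one of kept or
discarded per stage):

* localization: only proteins annotated `mitochondrial` by the supplied
  consensus table; accessions without an annotation are discarded
  (reason `no_localization`) rather than kept.
* start position: peptides starting after residue 120 are discarded. The
  boundary is inclusive-keep — a start of exactly 120 survives — because
  the rule's intent is "after the 120th residue".
* representative N-terminus: per protein the minimal observed start wins;
  non-minimal peptides are retained as intermediate evidence only when
  differential. The differential exception reuses the global 3-fold
  threshold since no separate value is established for it.

A mature start at position 1 or 2 is classified `no_presequence`
(translation start with or without initiator-Met excision); position ≥ 3 is
`processed` and defines the presequence as residues 1..start−1.

Acetylated N-termini take part in curation and assignment jointly with
dimethylated ones, but are excluded from substrate evidence by default:
endogenous acetylation marks an in-vivo-blocked terminus, not a free
processing intermediate. Both choices are switchable.

## Substrate calling

Candidate evidence per protein, with priority paired > single-down >
single-up and the larger fold change breaking ties:

* paired: two termini with offset 1–2 (ICP55) or 1–20 (OCT1); qualifies
  when the upstream ratio ≥ threshold or the downstream ratio ≤
  1/threshold; the removed string is the protein subsequence between the
  starts, so it is exact by construction.
* single-down: a lone downregulated terminus; the residue immediately
  preceding it must be destabilizing. Skipped with a diagnostic when the
  peptide starts at position 1.
* single-up: a lone upregulated terminus whose first residue is
  destabilizing; the removed residue is then that first residue.

Thresholds are inclusive: primary tier at fold ≥ 3.0, secondary tier at
1.5 ≤ fold < 3.0. The default N-end-rule table marks
F, L, W, Y, I, R, K, H, D, E, N, Q destabilizing and
A, S, T, G, V, C, M, P stable; because the published substrate set includes
trimmed M and C, the bundled-fixture analyses run with M and C added to the
destabilizing set (`StabilityTable.with_unstable("MC")`). The table is
configuration, not a biological claim.

OCT1 calls accept evidence from a single knockout line by default
(`min_lines=1`), since published single-line substrates exist; a strict
mode requires both lines. Ladder detection reports maximal chains of ≥ 3
termini at gaps ≤ 2 whose regulation is non-increasing downstream
(up → flat → down), the signature of sequential trimming.

## Motif statistics

Windows span 20 presequence residues (−20..−1) and 10 mature residues
(+1..+10); −1 is the last removed residue, +1 the first mature one, and
short sequences are padded with `-` (pads never enter counts). The
reference set is the position-independent residue composition of the
supplied proteome FASTA — never hardcoded. The differential matrix is
(f_obs − f_ref) × 100 per cell, with a two-sided one-sample proportion
z-test using variance f_ref(1−f_ref)/n. No multiple-testing correction is
applied across cells, matching differential-logo convention; this is a
display statistic, not an inference procedure. The consensus string renders
positions −3..+2 (all published motifs fall in that range), listing
residues with frequency ≥ 0.20 that pass the significance gate at
α = 0.05; α is configurable since no threshold is established for this
analysis.

With very few windows (the OCT1 set has n = 7) the z-test is coarse and a
residue occurring 2–3 times can reach nominal significance; the package
reports what the test yields rather than suppressing small-n positions.

## Net charge and group statistics

Net charge at pH p sums Henderson–Hasselbalch partial charges:
+1/(1+10^(p−pKa)) per K, R, H and the free N-terminus, −1/(1+10^(pKa−p))
per D, E, C, Y and the free C-terminus. Default side-chain pKa values:
D 3.65, E 4.25, C 8.3, Y 10.07, H 6.0, K 10.53, R 12.48; termini 8.0 / 3.1,
both included by default because the quantity of interest is a bare excised
peptide. The set is fully configurable; different published pKa scales move
presequence-scale charges by a few tenths of a unit.

Group comparisons use Welch's two-sided two-sample t-test (the unspecified
"significance test" of this literature is implemented as Welch by
assumption; identical zero-variance groups return p = 1 by convention).
Cleavage-prediction scoring counts a protein correct when
|predicted − true| ≤ 1 residue, with missing predictions counted incorrect.
Prediction tools themselves are not wrapped; their output tables are
inputs.

## The simulator

`SimConfig` defaults are the study conditions the package is calibrated
for: 200 proteins, 80% mitochondrial, 20% of those without presequence,
half of the processed proteins ICP55 substrates and ~4% OCT1 substrates
(matching the observed composition of a mitochondrial N-terminome: 88 of
176 processed proteins, 7 OCT1 substrates among 179), presequence lengths
truncated-normal with mean 43.3 and range 7–117, MPP class weights
(−3R 0.50, −2R 0.35, no-R 0.15), log2-ratio noise sd 0.2, reporting cap
100, intermediate leak 0.02.

Presequences are drawn from a background composition with R, S, A and L
enriched ≥ 1.5×; this reproduces the qualitative composition of targeting
peptides and is a configuration default, not a claim. ICP55 substrates get
a planted destabilizing residue (F/Y/L/I, with a second C/T/N residue in
10% of cases) at the MPP site followed by S/A + S/T, so motif-recovery
tests have a defined target. Mature regions are built as 7–12-residue
stretches punctuated by arginine, so ArgC-like digestion (C-terminal side
cleaving after R only — lysines are dimethyl-blocked; any N-terminal start,
i.e. semi-specific) always yields a 7–45-residue peptide per terminus.

The observation model emits one peptide per terminus present in either
genotype; ratios are (mutant abundance)/(WT abundance) × 2^ε with
ε ~ N(0, sd), clipped to [1/cap, cap]; termini absent from one channel are
reported at the cap, mirroring how bounded extreme fold changes are
reported in practice. The leak fraction emits the MPP intermediate at 2%
in genotypes where secondary processing proceeds; no abundance model for
residual intermediates is established, so this is a free parameter chosen
to be small but detectable. Initiator-Met excision is simulated with
probability 0.5 when residue 2 is small (A/S/T/G/V/C/P) — a documented
heuristic to populate the start ≤ 2 class.

What the simulator does **not** model: spectra, peaks, retention times,
charge states, fractionation, identification error, shared peptides between
proteins, or abundance-dependent detectability. Passing recovery tests
therefore demonstrates the correctness of the analysis logic under the
stated noise model, not end-to-end performance on real LC-MS data.

## Numerical and design choices

* Coordinates are 1-based and inclusive throughout, matching the
  superscript convention of the field's tables.
* Peptide-to-protein mapping requires a unique exact match; I and L are
  distinct by default (collapsing is a switch); ambiguous or unmapped
  peptides are excluded with diagnostics rather than guessed.
* Determinism: all randomness flows from `SimConfig.seed` through
  `numpy.random.default_rng`; caller iteration orders are sorted, so
  results are independent of input row order.
* Problem sizes in the test suite (200-protein recovery runs, 50-seed
  motif-recovery sweeps, 100–500-protein invariant checks) were chosen as
  the smallest sizes at which the binomial/Gaussian expectations quoted in
  the tests are sharp.

## Known limitations

* The published raw differential set ("106 peptides / 78 proteins") is
  curated down to 74 tabulated proteins by unstated criteria; the package
  exposes both the raw differential peptide list and the curated call set
  and does not attempt to guess the four exclusions.
* OCT1 removed-stretch inference requires a paired terminus; single-line,
  single-terminus OCT1 calls leave the removed segment empty.
* The z-test consensus gate is unreliable below ~10 windows (see above).
* Simulated presequence net charge is not calibrated to the empirical
  mean (+5.6); composition enrichment targets R/S/A/L frequency, not
  charge. Property statistics on simulated data demonstrate the
  machinery, not empirical values.
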