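# Methods

This note documents the statistical model behind `duoquant`, the choices
made where the design was genuinely open, and what the synthetic-data tests
do and do not demonstrate about real data.

## Pipeline model and assumptions

The pipeline treats each engine's output as a table of peptide-spectrum
matches (PSMs) and assumes: (i) peak areas are proportional to peptide
amounts within a run up to a per-sample scale factor, which ppm
normalization removes; (ii) spectral counts are proportional to protein
amount times the number of peptides the protein *can* contribute, which the
APEX observability correction removes; (iii) the two engines' errors are
largely independent, so agreement between them is evidence of a real
difference. Assumption (iii) is optimistic — both engines see the same
spectra — and is the reason the simulator has an `engine_noise_correlation`
knob (default 0, i.e. the most favourable case for consolidation).

Missing values are treated as true zeros throughout (means, SDs, t-tests).
This follows the missing-equals-absent convention of the quantification
scheme; it is defensible when missingness is abundance-driven (low
abundance ⇒ not sampled) and harmful when values are missing at random at
high abundance. A config switch (`include_zeros=False`) excludes zeros
instead; it is off by default and cuts the effective sample size.

The Kolmogorov–Smirnov normality p-values are diagnostic only and never
gate the t-test: they are computed against a normal with the *sample's own*
mean and SD, so they are optimistic (the Lilliefors caveat). They are
reported per protein and group so a reader can judge whether the normality
premise of the t-test is tenable.

## Filtering

* Mass accuracy and XCorr cut-offs are **strict** inequalities (a deviation
  of exactly 5 ppm fails; an XCorr of exactly 2.0 at charge 2 fails). The
  ppm comparison is made at a resolution of 1e-9 ppm so that a nominally
  5.000-ppm deviation fails despite binary floating point.
* Charge ≥4 maps to the fourth XCorr class: charge classes are stated as
  1, 2, 3, >4, which leaves charge exactly 4 formally unassigned; we assign
  it to the top class since charge-4 peptides must fall somewhere.
* The decoy FDR estimator is the plain ratio #decoy(≥s)/#target(≥s),
  evaluated at every distinct score; the kept set uses the **lowest**
  passing cutoff (largest survivor set), ties at the cutoff all kept. It is
  applied at the PSM level. This is a deliberate, transparent stand-in for
  probabilistic rescoring (PeptideProphet-style mixture models): it keeps
  the filter auditable and exactly testable against brute-force cutoff
  enumeration.

## Quantification

* **Top-3 with fewer than three peptides**: mean of the available peptides.
  This keeps single-peptide proteins quantifiable, consistent with the
  decision not to group proteins or discard single-peptide identifications.
* **PSM→peptide roll-up**: a peptide observed several times in a sample
  contributes its maximum area (configurable to `sum`). Maximum is robust
  to fragmentation re-triggering; sum double-counts repeated sampling.
* **Peptide ranking scope**: the "three most abundant peptides" are ranked
  within each sample, not by cross-sample average (configurable upstream of
  the roll-up). Within-sample ranking is self-contained per run and needs no
  alignment across samples.
* **APEX observability O**: the number of distinct fully-tryptic peptides
  of length 6–30 (cleave C-terminal of K/R, never before P, no missed
  cleavages). The original APEX uses a machine-learned peptide
  detectability expectation; a deterministic digest count preserves the
  role of O — correcting the length/cleavage-site bias of spectral counts —
  while being exactly reproducible and testable. Proteins with O = 0 fall
  back to a denominator of 1 and are flagged.
* Column-sum conventions: engine A columns sum to 10⁶ (parts per million),
  engine B columns to 1. All-zero samples are left at zero with a warning
  rather than raising, so a single failed run does not abort a batch.

## Differential expression and consolidation

The detection rule retains a protein if it is detected in at least
⌈0.6·n⌉ samples of at least one group (3 of 5, 4 of 6 at the default
design). The threshold computation rounds the product to 9 decimals before
taking the ceiling so that 0.6 × 5 is 3, not 4, despite floating point.

Fold change is case/control on the ratio scale, with explicit sentinels:
`case_only` (control mean 0, direction up) and `control_only` (case mean 0,
direction down). Down-regulation at ≥1.5-fold means FC ≤ 1/1.5, never a
signed −1.5. Degenerate t-tests (zero variance in both groups) return p = 1
for equal means and p = 0 otherwise, flagged `degenerate`.

Tier 1 requires significance in **both** engines *and* agreeing direction;
a both-significant, direction-discordant protein is contradictory evidence
and goes to a separate `conflicts` list rather than either tier. Proteins
quantified by only one engine have no trend to check in the other and are
reported in `single_engine`, excluded from both tiers. Tier 2 adds proteins
significant in exactly one engine with a same-direction ≥1.5-fold trend in
the other. Tier 1 ⊆ Tier 2 by construction; the suite asserts it on every
run, along with engine-exchange symmetry.

The primary significance flag is the raw p < 0.05 (strict), matching the
workflow this pipeline reimplements; Benjamini–Hochberg q-values are
emitted as an extra column for modern use but do not drive tier membership.

## Enrichment

Over-representation uses the hypergeometric right tail P(X ≥ k) with the
**quantified background** as the universe (everything passing the detection
filter in either engine, configurable). Using all of UniProt instead would
anti-conservatively inflate enrichment of anything detectable by MS. A set
is flagged only when p < 0.05 *and* k ≥ 3 overlapping molecules; smaller
overlaps are reported unflagged. The activation z-score
(up − down)/√(up + down) is a transparent direction-consistency statistic;
it is **not** comparable to knowledge-base-weighted activation scores of
commercial tools, which weight each molecule by a curated edge sign.
Identifier mapping (accession → gene symbol) is a user-supplied two-column
table; unmapped identifiers are dropped from query and universe alike with
a logged count — no network lookups.

## The synthetic-data generator

The generator emulates the target study design at the peptide level so the
full pipeline, including both quantification paths and the consolidation
logic, runs hermetically. Defaults (all in `SimulationConfig`):

| parameter | default | rationale |
|---|---|---|
| groups | 5 control vs 6 case | the study design |
| n_proteins | 1000 | order of a quantified tissue proteome |
| de_fraction / fold | 0.10 / 2.0 (symmetric) | minority of true changes at a modest effect |
| base abundance | log10 ~ N(5, 0.7) | ~3 orders of magnitude across the quantified range |
| peptides per protein | geometric-like, mean 6, in [1, 30], drawn from the protein's actual tryptic digest | ties observability to sequence, exercising APEX |
| sequences | length 50–600, ~11% K/R | human-like tryptic site density |
| peptide efficiency | log10 ~ N(0, 0.3) | fixed ionization bias per peptide |
| peak-area noise | log-normal, ln-SD 0.4 | typical label-free CV ≈ 40% |
| dropout | logistic in ln(area), midpoint 8.0, slope 1.0 | ~95% detection at median abundance, falling steeply below |
| XCorr margin | N(1.0, 0.6) above the charge threshold | ~95% of target rows pass the default filters |
| ppm error | N(0, 2) | Orbitrap-class mass accuracy |
| engine-B PSM rate | 5.0 per peptide per sample × relative abundance (~40k PSMs/run) | depth of a long-gradient Orbitrap run; gives the two engines comparable protein coverage, as in the emulated study |
| decoys | 10% of engine-B rows, scores N(1.8, 0.9) vs targets N(3.5, 0.9) | a 5% FDR cutoff bites but keeps most targets |

One seeded generator drives everything; per-stream substreams are derived
by stable hashing of (seed, stream name), so a seed fully determines the
dataset, and engines A and B draw independent noise from the shared truth.

What the generator does **not** emulate: retention-time structure and
match-between-runs, correlated engine errors (off by default), interfering
co-eluting peptides, shared peptides across proteins (random sequences make
them vanishingly rare — shared-peptide crediting is exercised by
hand-written fixtures instead), protein grouping ambiguity, and any real
biological covariance between proteins. Passing the recovery tests
therefore shows the *pipeline logic* is correct under its own model
assumptions, not that the workflow has any particular power on real tissue.

A property worth knowing: because ppm/APEX normalization is compositional,
a strongly asymmetric true signal (e.g. many 4-fold up-regulations) shifts
*every* null protein's apparent abundance in the case group, inflating the
Tier-2 false discovery rate well above the per-test 5% — visible in the
acceptance output (empirical Tier-2 FDR ≈ 0.2 at the 4-fold setting). This
mirrors what the same normalization does on real data and is why Tier 1,
the conjunctive list, is the high-confidence deliverable.

## Problem sizes used in the checks

The statistical suites run at the study's own scale: null calibration uses
10 seeds × 1000 proteins (the per-engine significant fraction must sit
within 3 Monte-Carlo SEs of 0.05, where the SE is taken **across seeds**
because normalization correlates proteins within a run, over-dispersing
per-seed fractions relative to binomial); recovery uses 5 seeds × 1000
proteins at 4-fold. Oracle suites are exhaustive where feasible (every
hypergeometric tail with N ≤ 12, in rational arithmetic) and randomized
with fixed seeds elsewhere (100 digests vs a scan oracle, 100 t-tests vs
the closed form, 200 decoy-FDR inputs vs brute-force enumeration).

## Known limitations

* PSM-level FDR only; no protein-level FDR or probabilistic rescoring.
* The t-test on zero-inflated abundances is only approximately calibrated
  when dropout is heavy; the simulator's defaults keep dropout mild, and
  the KS diagnostics expose departures on real data.
* Fisher enrichment assumes exchangeable proteins within the universe;
  MS detectability bias is only partly absorbed by the quantified-background
  universe.
* The direction z-score has no null distribution attached; it ranks
  consistency, it does not test it.
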