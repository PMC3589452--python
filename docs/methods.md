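# Methods

This note documents the statistical procedure the package implements,
the choices made where the procedure was genuinely open, what the
synthetic-data generator does and does not emulate, and the numerical
conventions that matter for reproducing results.

## Quantification model

Spectral counts are a semi-quantitative proxy for protein abundance.
The pipeline works on a protein × sample matrix of summed peptide
spectral counts, transformed in a fixed order that is enforced through a
level tag on the matrix container:

1. **Length normalisation** — counts divided by amino-acid length, since
   longer proteins yield proportionally more tryptic peptides.
2. **Log transform** — base 10 by default.  Every observed cell is
   strictly positive at this point: a zero count never reaches the
   matrix (absence of identification is recorded as *missing*), and the
   single-count discard guarantees observed counts >= 1.
3. **Row Z-scores** — each protein standardised across the samples it
   was observed in.  "Conditions" are the individual samples, not the
   stages; a per-stage mode is not provided because stage membership is
   itself an output of the staging step.  The standardisation recipe can
   be read with either sign; the default is `(x − mean)/sd` so that
   higher abundance maps to higher Z (matching "abundance increase"
   language and heat-map orientation), with the inverted literal form
   `(mean − x)/sd` available as `ZPolicy(sign="literal")`.  The standard
   deviation uses the n−1 denominator by default (`sd_mode`
   configurable).  Constant rows (sd = 0) map to all-zero Z rather than
   NaN.  Rows with fewer than two observations have no defined sd and
   are resolved entirely by the imputation step.
4. **Presence/absence imputation** — the global minimum and maximum Z
   over observed cells are computed once; in every row containing at
   least one missing cell, missing cells are set to `min/1.5` and the
   row's observed cells to `max*1.5`.  This deliberately collapses
   gapped rows to a two-level present/absent pattern so that detection
   gains and losses dominate the subsequent stage contrasts.  Two
   consequences are worth stating plainly: (i) because the global
   minimum is typically negative, `min/1.5` has *smaller* magnitude than
   the minimum, so imputed-low cells sit strictly inside the observed
   range — the rule is applied literally, not "pushed below the floor";
   (ii) the extremes are matrix-wide, computed once per matrix, never
   per batch.
5. **Stage aggregation and ΔZ calls** — stage value = arithmetic mean of
   the protein's Z over the stage's samples; for each consecutive stage
   pair, `ΔZ = z(to) − z(from)` and the change is significant when
   `|ΔZ| >= 2` (boundary inclusive).  No multiple-testing correction is
   applied — the ΔZ rule is the inferential criterion.  An optional
   two-sided normal-tail p-value for `ΔZ/√2` can be attached for
   descriptive ranking; it is labelled heuristic because the imputed
   values violate any distributional assumption.

An intrinsic property of this statistic: for a fully observed row whose
profile is a clean two-level step across a 3+6 sample split, row
standardisation fixes `|ΔZ|` at exactly 2 regardless of the effect size.
Continuous shifts therefore sit on the threshold, and the calls are
dominated by presence/absence patterns amplified by the imputation —
which is precisely the regime the rule was designed for.

## Peptide filtering

Charge-specific Xcorr minima (1.9/2.2/3.5 for +1/+2/+3) and the MSGF
cutoff 1e−10 are boundary-inclusive (`>=` / `<=`); charges above +3 use
the +3 threshold by default (configurable to reject instead).  The
single-spectral-count discard sums a peptide's counts across **all**
samples before testing (a peptide seen once in each of two samples
survives); a per-sample scope is available, since the original
convention is ambiguous between the two readings — the global scope is
the more conservative discard.  Shared peptides credit every mapped
protein by default (option to drop them); duplicate rows of a shared
peptide are de-duplicated per (peptide, sample) before the count test so
one spectrum is never counted twice.

## Staging

Clustering uses Euclidean distance on square-root-transformed analyte
concentrations in native units (µM for Fe(II), S²⁻, U(VI); mM for
acetate and sulfate) with average linkage, implemented over
`scipy.cluster.hierarchy`; the square root is the only transform by
default because that is the stated recipe, and an optional
standardisation flag exists for users who want scale-free clustering
(Fe(II), being tens of µM, otherwise dominates the metric).  The tree is
cut into exactly k = 3 clusters and clusters are named early/middle/late
by ascending mean sampling day.  Contiguity of each stage in time is
*reported*, not enforced.  Equal-distance merges follow the library's
deterministic ordering; the brute-force reference oracle in the test
suite breaks ties by smallest cluster index, and agreement is checked on
continuous data where ties have probability zero.

## Orthology

Reciprocal best hits (RBH): b is a's highest-bitscore subject and vice
versa; bitscore ties break by higher percent identity, then smallest
subject id.  Groups are connected components of the RBH graph across all
genome pairs.  This is a deliberate simplification of in-paralog-aware
clustering (the INPARANOID family): no in-paralog clusters, no bootstrap
confidence.  When a component acquires two proteins of the same genome,
the lowest-bitscore in-component edge is removed (ties by lexicographic
endpoints) until every component is genome-unique — deterministic and
documented, but cruder than true paralog resolution.  The per-genome
"expressed fraction" extrapolates the focal genome's detected set across
the panel, mirroring the strain-table convention; fractions are rounded
to the nearest integer percent, ties away from zero.  The mean ortholog
identity is an unweighted per-pair mean (per-residue weighting is not
attempted).

## Synthetic-data generator

The generator emulates the study design: nine samples on days
5–43 binned into three stages, eight genomes at protein-coding sizes of
roughly 3.5–4.5 k (defaults are the panel's published counts), a core
fraction of 0.28 of the smallest genome, and planted stage shifts
concentrated in chosen COG categories (translation down after the early
stage; energy production and amino-acid metabolism up into the middle
stage).  Design choices, with defaults:

* **Counts**: negative binomial (dispersion 5) around
  `10^(baseline) × depth`, baseline log10 = 1.0 ± 0.3 across proteins,
  per-sample depth factors cycling 0.9/1.0/1.1.  Spectral counts are
  over-dispersed, hence the NB; absolute depth is a free parameter of
  the design (documented, not calibrated to any dataset).
* **Planted effects**: a differential protein sits `effect_log_fold`
  (default 2) decades lower in its "low" stages.  Planted proteins are
  seeded at the common reference baseline rather than the random one:
  a baseline drawn above the reference would lift the low state over
  the detection floor (sporadic low-stage detections that halve the
  imputed contrast), and one below it would censor the high state — in
  both cases the realised effect would differ from the ledgered one.
  With a two-decade effect the low state (mean count ~0.1) is below the
  detection floor, so planted shifts manifest as stage-wise
  presence/absence, the regime the imputation amplifies.
* **Dropout**: an independent Bernoulli mask per (protein, sample) with
  a stage-specific rate (default 0.05).  Per-sample rather than
  per-stage-block: under the literal imputation rule a null protein
  absent for a whole stage is *by design* a significant call
  (presence/absence is the method's signal), so stage-block dropout at
  plausible rates would make any false-positive bound unattainable;
  sample-level dropout models sporadic detection failure, which is what
  the imputation is meant to tolerate.
* **Filter exercise**: a configurable fraction (default 0.1) of PSM rows
  is emitted with deliberately failing Xcorr and/or MSGF scores; score
  distributions are uniform over pass/fail bands, since the filter
  logic, not score realism, is under test.
* **Similarity tables**: true pairs at bitscore 500, decoys in
  [50, 300], both directions emitted.  Decoy subjects are restricted to
  proteins with a true ortholog in the query genome so decoys can never
  form a spurious mutual-best pair; Gaussian score noise (SD
  40 × `noise_level`) breaks the mutual-top guarantee only as
  `noise_level` approaches ~2.5, where tails bridge the 200-point gap.
* **Geochemistry**: piecewise-linear anchors per stage — Fe(II) from a
  50 µM background to 100–130 µM (early), a 170–185 µM plateau
  (middle), decline to 105–85 µM with sulfide onset rising to 12 µM
  (late); acetate arrival to ~4.5 mM, ~5 mM plateau, late decline;
  U(VI) decay 1.2 → 0.05 µM; sulfate drifting 8.6 → 6 mM.  Additive
  Gaussian noise of 5 µM (Fe), 0.3 µM (S²⁻), 0.03 µM (U), 0.2 mM
  (acetate, sulfate) — roughly 3–5 % relative error, consistent with
  colorimetric/IC measurement — under which the planted bins are
  recovered in ≳95 of 100 seeds.
* **Determinism**: all randomness flows from one seed through four
  named sub-streams (catalogs, similarity, PSMs, geochemistry); the same
  seed reproduces byte-identical files.  `noiseless=True` replaces every
  stochastic element by its deterministic centre, which the test suite
  uses for exact ledger-recovery checks.

What the generator does **not** emulate: realistic peptide
fragmentation or retention time, decoy-database FDR structure, sequence
evolution (synthetic sequences are random; similarity scores are
planted, not computed from them), chimeric/shared peptides, sample
carry-over, or abundance correlation between orthologs.  Passing the
recovery tests therefore demonstrates that the pipeline's logic is
faithful and self-consistent, not that the thresholds are optimal for
any particular instrument or site.

## Problem sizes and measured operating point

The shipped test suite and the acceptance script run a scaled-down
design (`SimConfig.small`: eight genomes of 120–160 proteins, half the
focal proteome expressed, 26 planted shifts), which preserves every
structural property of the full-scale design while keeping a full
pipeline run under a second.  At this design the measured operating
point over 50 seeds is ~93 % sensitivity for two-decade planted shifts
at ~5 % false positives among nulls, exact recovery of groups, core,
stages and calls in deterministic mode, and stage-bin recovery under
default geochemical noise in ≥95/100 seeds.  These numbers are computed
fresh by `scripts/acceptance.py` and by `tests/test_acceptance.py`.

## Known limitations

* ΔZ on imputed rows reflects detection patterns, not graded abundance;
  proteins near the detection limit can be called on dropout alone.
  This is inherent to the method, and the false-positive bound holds
  only under sample-level (not stage-level) detection failure.
* RBH + components under-split gene families relative to
  in-paralog-aware tools; the weakest-edge conflict resolution is a
  heuristic.
* The expressed-fraction extrapolation assumes the focal genome's
  detected set transfers across the panel; it is a reporting convention,
  not a measurement, for the seven non-focal genomes.
* The staging template defines exactly three phases; other stage counts
  require user-supplied geochemistry.
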