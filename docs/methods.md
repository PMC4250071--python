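# Methods

## The model

stratmine reads a corpus of (synthetic) geological documents and emits a
probabilistic database of five relations: `formation_age`,
`formation_location`, `taxon_in_formation` (a fossil occurrence),
`opinion_belongs`, and `opinion_synonym`.  The statistical core is a boolean
factor graph defining an exponential-family distribution

    P(x) ∝ exp( Σ_e φ_e(x_e) ),

with three indicator-potential factor kinds:

* **unary feature** — one factor per (mention candidate, feature string),
  `φ = w · x_v`.  Weights are tied by exact feature-string equality, so a
  feature such as `taxon_in_formation::BTW=yields` has one weight across the
  whole corpus.
* **aggregation** — links the entity-level variable for a tuple
  (relation, subject, object) to every mention-level variable asserting it,
  `φ = w · 1{x_entity = max(x_mentions)}`: an OR-like coupling rewarding the
  cross-document assertion being true exactly when some mention is.
* **implication** — between a formation's coarse and fine age variables
  (F, Carboniferous) → (F, Namurian) whenever the coarse interval contains
  the fine one, `φ = w · 1{x_a = 0 or x_b = 1}`.  The strength of the
  implication is learned, not asserted.

Variables live in two strata — mention-level relation candidates and
entity-level tuples — with aggregation factors carrying the cross-document
layer; this realizes the mention / per-document / aggregation layering with
two variable strata plus coupling factors.

## Entity mentions and features

Entity recognition is dictionary (gazetteer) based, per type (taxon,
formation, interval, location), longest-match with leftmost tie-break,
0-based half-open token spans.  Formation entries also match with any
lithology trigger (`Fm`, `Formation`, `Shale`, `Limestone`, `Sandstone`), so
"Waldron Shale" is found when written "Waldron Fm".  A binomial pattern
(`<KnownGenus> <lowercase latinate epithet>`) recognizes species names no
dictionary lists and resolves them to the known genus.  Candidate features:
inter-mention tokens (`BTW=`), bucketed token distance (`DIST=`), mention
order, immediate context tokens (`PRE=`, `POST=`), and for table rows a
same-row flag and column-header tokens — all prefixed with the relation so
weights never tie across relations.  A deliberately excluded feature is the
full inter-mention gap string: it would identify sentence templates
uniquely, letting the learner memorize templates instead of generalizing
through shared tokens (observed to inflate scores of unseen constructions).

## Distant supervision

A candidate (or entity tuple) is labeled by matching against the seed
knowledge base:

1. **positive** — the tuple is in the seed KB; formation ages also match
   along the interval hierarchy (a seed age of Namurian supports a stated
   age of Carboniferous and vice versa);
2. **hard negative** — the (subject, object) pair is in the seed KB under a
   *different* relation (e.g. the synonymy reading of a belongs statement);
3. **closed-world negative** — the subject is known to the seed KB for this
   relation but only with incompatible objects; subsampled at
   `negative_rate` (default 1.0);
4. otherwise unlabeled.

Entity-level supervision uses rules 1–2 only by default
(`entity_negative_rate = 0`): at the entity level a tuple absent from a
partial seed KB is usually still true, and clamping such false negatives
measurably distorts both recall and probability calibration.  Closed-world
noise at the mention level is retained deliberately — it is the realistic
cost of distant supervision.

## Weight learning

Weights maximize an L2-penalized composite conditional likelihood
(pseudo-likelihood) of the evidence variables, restricted to factors whose
other variables are observed.  Two passes:

1. **unary pass** — evidence variables with their unary factors only; this
   is exactly penalized logistic regression on the feature indicators
   (unit-tested against an independent solver), optimized by L-BFGS with
   analytic gradients.
2. **rule pass** — only the two rule weights (aggregation, implication) are
   fit, with each row's unary score frozen as an offset.  Unlabeled mention
   variables are imputed from the unary model (score > 0), and entity
   variables as the OR of their mentions, so rule-factor neighborhoods are
   fully observed.  Refitting unary weights here would let the aggregation
   column act as a circular shortcut feature (the imputed entity value is
   derived from the very labels being predicted), which empirically
   destroys the unary weights; freezing them avoids that.

Learning requires at least one positive evidence variable; an all-positive
evidence set (e.g. a clean corpus with a complete seed KB) proceeds with a
warning, bounded by the L2 penalty (`l2` default 0.1, penalizing ½·l2·‖w‖²).

## Inference

Marginals come from single-site Gibbs sampling with evidence clamped:
fixed sweep order, one chain, seeded; burn-in defaults to 10% of the sample
count; retained samples are separated by `thin` sweeps (default 4) to
reduce autocorrelation; and the estimator is Rao-Blackwellised (it averages
the full conditional P(x_v = 1 | rest) over retained sweeps rather than the
sampled 0/1 values).  With these choices the sampler reproduces
brute-force enumeration marginals on random 3–12 variable graphs to within
0.01 at 20,000 samples.  The enumeration code (`exact_marginals`, up to 20
free variables) is the independent reference implementation of the same
exponential-family model and shares nothing with the sampler but the
potential definitions.

## Calibration report

The published probabilities are checked the way such extractors are
audited: a fraction of the distantly supervised labels is withheld from
learning; half of the withheld set fits a monotone recalibration of the
mention-layer probabilities (pool-adjacent-violators over same-score
classes, minimum block weight to keep each step statistically stable), and
the other half is the assessment set for the per-decile reliability table.
Candidates sharing a feature set share one raw score, so the recalibrated
probability of a class is its empirical frequency in the fit fold.  A
structural caveat documented here deliberately: prediction mass is atomic
(one value per feature class), so when a class's truth rate falls near a
decile boundary that bin's |accuracy − center| approaches half the bin
width (0.05) plus sampling noise — a geometry effect, not miscalibration;
accuracy always tracks the mean prediction within the bin.

## The probabilistic occurrence database

Entity tuples with marginal probability ≥ τ (default 0.95) are accepted.
Two editorial rules then shape occurrences:

* **best age** — per formation, the accepted age statements across all
  documents reduce to the most precise age (shortest duration in Myr),
  ties broken by most recent publication year, then probability, then name;
* **formal units only** — an accepted occurrence tuple whose formation has
  no accepted age yields no record.

Occurrence records carry genus (and species if the subject was a binomial),
formation, the unit-level inferred age, the formation's best accepted
location, one source document, and the tuple's probability (CSV export with
at least four decimal places).

## Taxonomy and macroevolutionary statistics

Opinions resolve per name by recency (tie: majority, then lexicographically
smallest parent); synonymy applies transitively to a terminal senior name;
synonym cycles are broken by dropping the most recently published
cycle-closing opinion (logged, never fatal).

Occurrences pass a temporal-resolution filter (`min_rank`, default epoch or
finer), are re-keyed to senior names, and map to analysis bins: an
occurrence whose interval overlaps more than one bin is dropped and
counted.  Genus ranges are first/last occupied bins under the range-through
assumption.  Per bin *i* the boundary-crosser classes are N_bt (cross both
boundaries), N_bL (cross bottom, end within), N_Ft (start within, cross
top), N_FL (confined), and the per-capita, per-interval rates are

    p_i = −ln(N_bt / N_t),   q_i = −ln(N_bt / N_b),

with N_t = N_bt + N_Ft, N_b = N_bt + N_bL; a rate is NaN where N_bt or its
denominator is zero.  Rates are per interval by default; supplying bin
durations converts to per-Myr.  Singletons enter diversity but not the
rates (a property of the formulas).  Two databases are compared by Spearman
rank correlation of first-differenced series (differences over consecutive
bins where both series are defined; the rank statistic is scipy's) and by
per-genus first/last occurrence offsets in Myr of bin-midpoint ages, with a
configurable sign convention (default: first database minus second).

## The timescale

One packaged table ships an ICS-like Phanerozoic hierarchy
(eon→era→period→epoch→stage, boundary ages close to the 2020 international
chart) including the regional stage Namurian under the Carboniferous;
sibling overlap is permitted (regional vs global stages), only parent
containment, rank refinement, and a single root are enforced.  Default
analysis bins are the 34 epoch spans (mean ≈ 15.8 Myr); an explicit bin CSV
(e.g. 52 equal bins of 10.4 Myr) can override.  Intervals and bins cover
half-open `[t_young, t_old)` spans; a degenerate point age on a shared
boundary belongs to the younger bin, and an age of exactly 0 to the
youngest bin.

## The synthetic corpus

The generator emulates the post-OCR/NLP layer of a literature-reading
system: a gold world of formations (one true age — 70% stage, 20% epoch,
10% period level — and one location each), genera with contiguous-ish
stratigraphic ranges built from a home formation plus similar-aged extras,
belongs-to chains (species→genus→family) and junior synonyms; every fact is
rendered at least once faithfully through one of ≥5 strong sentence
templates per relation or a table row, plus redundant renderings that may
use a junior synonym or a coarser age.  Noise knobs: character-level token
corruption (OCR damage), distractor sentences that must not yield tuples,
and three hedged templates per relation with graded reliability, used for
both true facts and false pairings.  Defaults: 30 formations, 120 genera,
100 documents, corruption 0, distractors 0.3, synonym usage 0.2, coarse
ages 0.25, hedged share 0.15, table share 0.3, mean 2 renderings per fact.

What the generator does **not** emulate: real grammar and discourse,
OCR/layout processing itself, document-level topical coherence, skewed
name-frequency distributions, and multilingual text.  Passing tests
therefore certify the statistical machinery and the editorial rules under
controlled noise, not performance on real literature.

## Problem sizes used in tests and the acceptance script

Sampler exactness: 100 random graphs, ≤12 free variables, 20,000 samples.
Weight recovery: 5,000 labeled instances, 12 features, l2 = 0.01.
Calibration: 4,000 documents (≈5,700 assessed candidates scored).
Clean end-to-end: 15 formations, 60 genera, 40 documents, full seed KB.
Training-size curve: seed-KB fractions {2%, 10%, 50%, 100%} × 5 replicates
on 60-document worlds.  Noisy-corpus quality: 150 documents at default
noise.  These sizes were chosen as the smallest at which the measured
quantities are stable.

## Known limitations

* Closed-world mention negatives are noisy on many-to-many relations; the
  learned scores are calibrated to the supervision distribution, not to
  gold truth, unless the seed KB is complete.
* The OR-aggregation semantics is one choice among several (noisy-OR,
  conjunction); its weight absorbs some of the difference but marginals of
  singleton mentions are pulled toward their entity's state.
* The pseudo-likelihood learner ignores unlabeled variables in the
  objective (they participate in inference only).
* Age inference conditions on the geological unit only, not on (unit,
  location) pairs.
* The packaged timescale is a convenience snapshot, not a maintained
  stratigraphic standard.
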