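# Methods

## Problem and scope

The package predicts the most recent (hence "next") three-level
cardiovascular-health category of a patient from all earlier categorized
measurements of the same five submetrics used in ambulatory quality
registries: smoking status (smk), body mass index (bmi), blood pressure
(bp), hemoglobin A1c (a1c) and LDL cholesterol (ldl). The real registries
this design targets are proprietary, so the package pairs the analysis
pipeline with a synthetic cohort generator whose dynamics are fully known;
all quantitative claims in the test suite are made against that planted
ground truth, not against clinical data.

## Categorization

Each measurement maps to poor (0) < intermediate (1) < ideal (2):

| submetric | poor | intermediate | ideal |
|---|---|---|---|
| bmi (kg/m²) | ≥ 30 | 25–29.9 | < 25 |
| ldl (mg/dL) | ≥ 160, untreated | 130–159 or treated | < 130, untreated |
| bp (mmHg) | sys ≥ 140 or dia ≥ 90, untreated | sys 120–139 or dia 80–89 or treated | sys < 120 and dia < 80, untreated |
| a1c (%) | ≥ 6.5, untreated | 5.7–6.4 or treated | < 5.7, untreated |
| smk | current | former, quit ≤ 12 months | never, or quit > 12 months |

Boundary comparisons are literal: 25.0 → intermediate, 30.0 → poor, and
analogously for every other cut. The a1c bands are the standard clinical
prediabetes/diabetes cuts in percent; fasting-glucose bands in mg/dL
(< 100 / 100–125 / ≥ 126) are shipped and selectable
(`CategorizationRules(a1c_bands=GLUCOSE_MGDL_BANDS)`) for glucose-valued
data, since threshold conventions differ between the two measures and the
choice is left open in practice.

**Treated to goal.** The category tables place medicated patients in the
intermediate column, but do not say how medication interacts with the
measured value. The default policy (`force_intermediate`) assigns
intermediate whenever a qualifying treatment exists, regardless of the
value; `cap_at_intermediate` is available and currently coincides with it
(both extremes are demoted). Treatment is assessed per measurement date:
orders dated on or before the measurement count — the clinically
conservative reading, since a drug cannot influence values recorded before
it was ordered.

**Drug-name matching.** Free-text order names are matched case-folded and
whitespace-stripped against a packaged table of ~70 canonical drug names
(statins, ACE inhibitors, ARBs, beta blockers, calcium-channel blockers,
diuretics, biguanides, sulfonylureas, insulins, ...), each carrying a drug
class and the subset of {a1c, ldl, bp} that class treats. The entry with
minimum Levenshtein distance wins if that minimum is strictly below 5;
equidistant entries break by table order, deterministically. Whole strings
are compared (no tokenization). The distance itself is an iterative
two-row dynamic programme, validated in the tests against an exhaustive
recursive oracle and against an independent alignment library.

## Synthetic cohorts

Per patient and submetric, visit counts are Poisson with mean
`visit_rate x window_years` and dates uniform in the window — i.e. a
homogeneous Poisson process over the default 13-year window
(2004-01-01 .. 2016-12-31). Default `visit_rate` is 0.5 measurements per
patient-year per submetric (mean ≈ 6.5, range ~1 to ~20), chosen as
typical of ambulatory follow-up where labs are checked at most annually
for most patients. Categories at successive visits follow a first-order
Markov chain over the three levels; the default transition matrix has
stay-probability 0.9 with the remainder split evenly (`stay_matrix(0.9)`),
giving trajectories persistent enough for history to carry signal but
noisy enough that prediction is non-trivial. Numeric values are drawn
uniformly inside the band of the planted category, with bounded tails for
open-ended bands (BMI poor in [30, 60], LDL poor in [160, 300], systolic
poor in [140, 220], diastolic poor in [90, 130], a1c poor in [6.5, 14]),
so that categorization recovers the hidden state exactly for untreated
measurements — the band-fidelity property the tests check exhaustively.
Former smokers quit uniformly within (0, 36] months so both intermediate
and ideal outcomes arise.

Initial states can be coupled across submetrics: with probability
`cross_metric_correlation` a submetric copies a patient-level shared
initial category. Dynamics after the initial state are independent across
submetrics, reflecting the weak cross-submetric label correlations seen in
real cohorts. Non-ideal a1c/ldl/bp visits spawn medication orders with
probability `medication_probability` (default 0 — planted-state recovery
stays exact; the pipeline demo configs use 0.2–0.3); order names are
canonical names perturbed by exactly `name_noise_edits` (default 2) edit
operations, verified against the distance function by rejection.

Randomness uses one global seed with per-patient, per-submetric substreams
spawned via `numpy.random.SeedSequence(seed, spawn_key=...)`, so enlarging
a cohort leaves existing patients' data bit-identical. A small same-date
duplication rate (1%) deliberately exercises the sequence builder's tie
rule.

What the generator does *not* emulate: state-dependent visit intensity
(sicker patients visiting more), dose/adherence/discontinuation dynamics,
continuous-valued drift within bands, measurement error, and
missing-not-at-random mechanisms. Passing tests therefore demonstrate that
the pipeline recovers planted first-order categorical dynamics under
irregular sampling — not that comparable AUROCs would be achieved on any
particular clinical registry.

## Sequences, embeddings, encoding

Per patient, rows are sorted by date (stable within equal dates); each
submetric's latest row is its label, all other rows become tokens with
offsets in days before the patient's global latest measurement date. On a
same-date tie the last row by input order takes the label slot and its
partners remain features at offset 0. Eligibility requires more than `m`
(default 1) distinct measurement dates — in every submetric for the
all-submetric analyses. Age is `floor((label_date - birth_date)/365.25)`.
The 80/20 split is by patient (`round(0.8 n)` train), never by
measurement.

Embeddings are CBOW word2vec with the exact full-softmax objective —
legitimate here because the vocabulary is at most 15 tokens — dimension
32, window 5 with the usual dynamic shrinkage, min_count 1, 20 epochs of
SGD with the canonical linearly decaying learning rate (0.025 → 1e-4),
single-threaded and seeded. Skip-gram is exposed but not the tested path.

Encoded inputs are left-padded to the dataset's maximum token count with a
boolean mask, so the most recent measurements sit adjacent to the
recurrent read-out; each step is the 32-d embedding plus the time offset
scaled by 1/3650 (days → decade fraction, keeping the channel commensurate
with unit-scale embeddings). Demographics — age standardized as
(age − 50)/20 and a three-level sex one-hot (female/male/unknown) — are
concatenated to the final recurrent state rather than repeated per step.

An embedding structure check worth recording: with persistent chains,
same-submetric tokens of *different* categories almost never co-occur
within a patient window, while cross-submetric tokens co-occur constantly,
so CBOW places same-submetric tokens far apart (measured cosine gap
≈ −0.4). The assertable structure is category coherence: with initial
states fully coupled across submetrics, same-category tokens cluster
strongly (gap ≈ +1.5; one-sided t-test over 20 embedding seeds in the
suite).

## Models

The LSTM is implemented in numpy: standard gates, forget bias 1, Glorot
initialization, masked states carried through padding (so prepending
masked positions provably cannot change predictions — tested), BPTT, Adam
at canonical rates, float32. The cell-output activation is configurable
(sigmoid default, tanh/selu/relu available); gate nonlinearities are
standard. Heads: 3-way softmax with categorical cross-entropy
(multiclass), or 15 independent sigmoids with binary cross-entropy
(multilabel, submetric-major class order a1c/ldl/bmi/bp/smk x
poor/intermediate/ideal). Defaults: 100 hidden units, batch 64, 30
epochs; early stopping (patience 3 on a 10% train-held-out slice) is off
by default and enabled in the long-running training recipes, where the
planted task plateaus well before 30 epochs.

Baselines receive a fixed-length summary of the identical information:
15 bag-of-token counts, last observed ordinal per submetric (−1 if never
observed), days since the previous measurement, age, sex one-hot.
Logistic regression uses L2 at C = 1.0, tol = 1e-4, behind a
standardizing scaler (the day-scale gap column otherwise dominates the
solver); random forest uses 100 trees, √p features per split, minimum
leaf 1, fixed seed. No class-imbalance correction is applied anywhere.

## Evaluation

`roc_auc` implements the pairwise probability definition
P(s⁺ > s⁻) + ½P(s⁺ = s⁻) via unique-score counting, which matches the
O(n²) brute force bit-for-bit (sums of halves are exact in binary
floating point). Micro-averaging flattens the one-vs-rest (sample, class)
indicator/score pairs; macro is the unweighted mean of per-class AUCs,
with absent classes reported as NaN and excluded (logged). Per-class
precision/recall/F1 report 0.0 with an explicit flag on zero
denominators. Multilabel accuracy thresholds at 0.5; multiclass accuracy
uses argmax.

`bayes_auroc_oracle` computes the exact micro-AUROC of the optimal
predictor under planted dynamics: for last state s the optimal score
vector is the transition row P[s, ·], and enumerating the nine
(state, next-state) cells weighted by π(s)P[s, y] gives the flattened
one-vs-rest AUC with no sampling. For the default stay-0.9 symmetric
chain with uniform stationary distribution this ceiling is 0.925.

## Problem sizes and numerical choices

End-to-end checks use 2000-patient cohorts (~1600 train / ~400 test after
eligibility filtering), three model seeds for stochastic comparisons, and
the early-stopping recipe above; the label-shuffle null permutes labels
across the whole dataset before splitting, so chance-level micro-AUROC is
the correct expectation. The coupled-correlation check uses persistent
chains (stay 0.98) with sparse visits (0.3/year): label correlation
between two coupled submetrics decays as roughly λ^(2k) with λ the
chain's second eigenvalue and k the number of observed transitions, so
default mixing (λ = 0.85, k ≈ 6) would erase initial-state coupling
regardless of implementation correctness — the persistent configuration
keeps the planted effect observable (expected r ≈ 0.8).

Known limitations: single recurrent layer only; no attention, calibration
or confidence intervals; the multilabel baselines use one-vs-rest
wrappers rather than native multilabel trees; treatment status is
resolved per patient-submetric from the earliest qualifying order, so
order discontinuation is not modelled.
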