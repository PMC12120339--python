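# Methods

This note documents the models behind `smoltfate`, the assumptions they
make, and the numerical and design choices a maintainer would want to
know. No number quoted here is asserted anywhere except where the tests
or the acceptance script compute it.

## 1. The synthetic telemetry generator

The generator is the package's stand-in for field data: it produces
ground-truthed cohorts whose statistical structure matches what the
analysis chain assumes, so every downstream stage can be validated
against known fates.

**Geometry.** Movement is one-dimensional along the migration axis. The
default array runs lake (F1–F7), lake exit (F8), estuary (E1–E2),
estuary exit (M1), inner bay (M2–M6) and an island gate (N1–N10) roughly
20 km out. Stations are ≥900 m apart and a transmission is heard within
a hard 150 m radius, so ranges tile the corridor without overlap. The
radius matters more than it looks: overlapping ranges make a tag flicker
between adjacent stations, fabricating reversals, and because
inter-station speed is station distance over the *unheard-gap* transit
time, large radii inflate apparent speeds several-fold. With the default
geometry the inflation factor is ≈1.5, which keeps apparent speeds in
the ranges field studies report. Both radius and positions are
configurable.

**Smolts.** Release at the lake head; lognormal lake residency (median
40 h — the ~2-day acclimation period — with wide scatter, sdlog 0.75,
because real cohorts include fish that linger for weeks); then seaward
transit at a per-fish speed ~N(0.6, 0.2) m/s truncated to [0.2, 1.3].
A small minority (3%) make exactly one foray from the first estuary
station back to the lake exit — a slow drift landward — giving at most
two direction changes, the empirical ceiling for live smolts. Short
dwells near each station produce the detection bursts real receivers
log.

**Predation.** A per-hour hazard by section and origin (ranched fish
are predator-naive and carry ~4× the wild hazard; defaults concentrate
predation in the lake with a sharper estuarine pinch-point). Once eaten,
the tag follows the predator: directional runs between stations at
0.8–1.6 m/s whose termini are sampled with section-occupancy weights
(lake 0.45, estuary 0.40, inner bay 0.15), separated by resting dwells
out of detection range that surface into range for ~30 min at least
daily. Each predator realizes a drawn total of 4–51 direction changes
over its ~45-day active span, with at least six placed in the first 16 h
(the post-capture hunting bout) so even the shortest tag retention
(0.7 d) shows unambiguous predator movement. Digestion triggers the
sensor 10–62 h after ingestion; the tag is expelled 0.7–45 d after
ingestion, always at least 30 h after the trigger so a triggered payload
reaches a receiver. Co-ingestion: with probability 0.3 a new predation
event attaches to an already-active predator whose scheduled movement is
predator-like over the new tag's window, and the tags share one track.
Temperature payloads are ~N(36.6, 0.2) °C after the trigger (clipped to
the mammalian band 36.1–38.5) and ~N(12.7, 0.4) °C ambient before it.

**Loss and tagging mortality.** Beyond predation, each fish can vanish
while transiting a section (tag silent thereafter; defaults 1–12% per
section, heaviest at sea). This non-predation loss is essential: without
it the never-predated subcohort survives every interval with probability
one and the biased/unbiased comparison is degenerate; published unbiased
success estimates well below 100% imply exactly such disappearance. A
2% tagging-mortality fraction is never detected or detected at one
station only.

**False detections** (signal collisions attributed to a transmitter)
arrive at 0.5/day per tag, uniformly over the tag's transmitting life,
at a random station. All randomness flows from one `numpy` generator;
the same seed reproduces byte-identical outputs.

What the generator does **not** emulate: tides and hydrodynamics, 2-D
movement, distance-dependent detection decay, receiver clock drift,
predator species mixtures (default is mammal-only, matching the study
system), and density-dependent predator behaviour. Passing tests
therefore demonstrate that the analysis chain is correct under the
stated structure, not that it is robust to every failure mode of real
arrays.

## 2. Detection QC and sensor decoding

The proprietary false-detection screening of receiver-vendor software is
replaced by a documented two-stage rule. Stage one (the spec'd filter):
a detection is flagged when no other detection of the same transmitter
occurs anywhere on the array within ±30 min; the rule is symmetric and
hence idempotent. Stage two (`confirm_station_visits`, applied in the
pipeline): a detection must additionally have a same-*station* neighbour
within the window. Stage one removes ~95% of injected false records but
passes those that land within half an hour of genuine activity; a single
surviving ping at a distant station fabricates movement events, so the
burst requirement — a real range pass at 20–40 s transmit intervals logs
many detections — removes the remainder. Movement-event extraction also
drops physically impossible speeds (>5 m/s), the standard velocity
screen.

Trigger decoding: the trigger instant is the earliest value of
(timestamp − decoded hours-since-trigger) over positive digestion
payloads (quantized to 0.1 h), so the estimate is accurate to one
transmit interval plus quantization. The trigger *location* is the
section of the last pre-trigger detection, falling back to the first
post-trigger detection for tags first heard already triggered — the
last known pre-digestion position is the defensible proxy. Hours from
first detection to trigger can be negative for tags first heard already
triggered; the value is reported as computed. Predator typing from the
post-trigger temperature mean: <20 °C ectotherm, 34–44 °C endotherm,
resolved to mammal inside the harbour-seal core band 36–38.5 °C, bird
otherwise; bands configurable.

## 3. Migration metrics

Per tag: total detections; time from first to last detection; mean and
maximum speed in each direction over all inter-station events (a
direction with no events contributes zeros); number of reversals
(adjacent event pairs with opposite direction — inter-station
granularity, not per-detection); residency per section as the union of
maximal same-section detection runs (predators re-enter sections, so
first-to-last spans would double-count); and hours from release to
trigger (zero for untriggered and plain tags). The lake-exit and
estuary-exit gates pool into lake and estuary residency respectively.
Only tags detected beyond the lake enter the classification matrix —
lake-only tags carry too little movement information.

## 4. Fate classification

Columns are centred and scaled to unit sample standard deviation
(zero-variance columns stay at zero). Ward's minimum-variance
agglomeration on Euclidean distances uses the Euclidean-height
convention (scipy's `ward`), verified in tests against brute-force
minimum-variance-increase agglomeration. The cluster count is the
silhouette argmax over k ∈ [2, 10] (ties toward smaller k) with the WSS
curve reported for the elbow diagnostic; analyses may fix k (the
pipeline's study-like default is k=2). A cluster containing triggered
predator tags is a predator cluster; anchor-free clusters fall back to a
metric heuristic (median reversals > 2, median upstream speed > 0.3 m/s,
or median lake+estuary residency more than 3× the cohort median — the
long-resident group a different predator produces). Sensitivity trials
re-run the chain with variable subsets removed; the labelling heuristic
always consults the full metric table so removing a variable from the
*clustering* never starves the *labelling*.

The random forest is trained, by default, on the full matrix with
cluster-assigned fates, so the supervised model acts as a cross-check of
the unsupervised grouping; its out-of-bag error measures how separable
the fates are, and its out-of-bag confusion matrix, per-class errors,
AUROC and F1 are reported together with permutation-importance and Gini
importance. This choice resolves an ambiguity in how such forests are
trained in the field: training only on sensor-confirmed tags leaves
hours-to-trigger a perfect single split (positive for every training
predator, zero elsewhere), which makes trees vote smolt for every
non-sensor tag regardless of movement; published confusion matrices in
this literature are only consistent with cluster-labelled training sets.
The anchors-only scheme (triggered tags as predators; non-triggered
predator-tagged fish plus outermost-line arrivals as smolts) remains
available as `label_source="anchors"`; outermost arrivals require at
least three detections there so a pair of coincident false records
cannot fake a known-fate smolt. ntree is the smallest grid value from
which OOB error stays within 0.5 percentage points of all later values;
mtry minimizes OOB error. Classifier agreement is the fraction of
non-anchor tags assigned the same fate by both methods. Classical
(Torgerson) MDS of a dissimilarity matrix is provided for reporting.

## 5. Cormack–Jolly–Seber survival

Occasions are the release plus the ordered array sections; a history bit
is 1 iff the tag has a kept detection in that section. The likelihood is
the exact CJS likelihood conditional on first release, computed per
individual so covariates (origin, standardized fork length and
tag-to-body-mass ratio, location factors and location×origin
interactions) enter logit-linear predictors for Φ (intervals) and p
(occasions). Each fish contributes survival/detection terms up to its
last detection and the recursive probability χ of never being seen
again. Estimation is L-BFGS-B from a null start plus random restarts;
covariance comes from the inverse central-difference Hessian; real-scale
estimates at mean covariates carry back-transformed Wald intervals.
All-ones histories drive the MLE to the boundary and are flagged rather
than rejected. The terminal interval's Φ and the final occasion's p are
separately identifiable only when one of them is constrained across
occasions; fits with location terms in both report the confounding flag
and the identifiable product.

**Over-dispersion.** ĉ is the observed deviance over the mean deviance
of datasets simulated from the fitted global model (same releases and
covariates) and refitted; deviance is measured against the saturated
multinomial over observed history patterns. Values below 1 are reported
but floored at 1 for QAICc. The single-dataset statistic is chi-square
distributed over the pattern cells, so its relative spread is roughly
√(2/df) — substantial with few occasions — and the calibration test
therefore averages replicates. On realistic simulated cohorts ĉ can be
large: per-fish detection heterogeneity (resting out of range, residual
false records) is real lack of fit relative to the global CJS model, and
the floored quasi-likelihood correction simply makes model selection
conservative.

**Ranking and averaging.** QAICc = 2·nll/ĉ + 2K + 2K(K+1)/(n−K−1) with
n the number of released individuals; weights are normalized
exp(−ΔQAICc/2). Model-averaged Φ and p are weight-sums of real-scale
estimates with unconditional variance Σᵢ wᵢ(varᵢ + (estᵢ − avg)²).

**Bias contrast.** Biased histories keep every tag; unbiased histories
drop predator-fate tags entirely (not censored at predation — the
detections before predation belong to a fish that did die there, and
removal matches how such corrections are applied; a censoring variant is
a candidate extension). The per-section detected-proportion profile uses
the full per-origin release count as denominator in both modes: a
predated fish is a failed migrant, not a removed trial, so predator
removal can only lower the curve and the biased profile bounds the
unbiased one from above at every section. The CJS fits, by contrast,
operate on the reduced unbiased history set.

## 6. Problem sizes and determinism

Default study conditions: 150 tagged smolts (50 wild, 100 ranched, 25
temperature predator tags), detection probability 0.85 per in-range
transmission, false detections at 0.5/day. The test suite exercises the
full default cohort once (shared fixture), 100 smaller replicates
(20/40/10) for the bias-direction properties, 2,000 simulated fish for
CJS parameter recovery, 200 replicates for Wald coverage, and exhaustive
or brute-force oracles for reversals (all sequences to length 8), Ward
merges (n ≤ 7) and silhouettes. Every stochastic component takes an
explicit seed or generator; identical seeds give byte-identical outputs,
including the whole pipeline run directory.

## 7. Known limitations

- One-dimensional geometry: no lateral structure, so "inner bay not a
  full gate" effects are only mimicked through detection probability.
- Hard-radius detection without distance decay.
- The predator movement model is phenomenological (runs, dwells,
  occupancy weights), not a foraging model; co-ingested tags share a
  track but predator identity is otherwise unused by the classifiers.
- ĉ from the parametric bootstrap has noticeable small-sample bias and
  spread at few occasions; the floor at 1 and QAICc make this
  conservative rather than misleading.
- The classifiers operate per track; a tag predated late in migration
  carries pre-predation smolt behaviour in its metrics, which is the
  same contamination field datasets have.
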