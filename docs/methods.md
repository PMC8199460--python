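# Methods

`spellersim` simulates, end to end and without hardware, a visual P300
row-column speller that controls smartphone messaging through voice
commands interpreted by a virtual assistant.  This note records the
models, the numerical choices, and what the simulation does and does not
establish.

## The paradigm being modeled

All four menus are 7×7 matrices (49 cells, dummies included).  A
*sequence* flashes each of the 7 rows and 7 columns exactly once in
pseudo-random order; a selection accumulates classifier evidence over a
per-subject number of sequences and picks the cell at the intersection
of the best-scoring row and column.  Stimuli last 192 ms with a 224 ms
stimulus onset asynchrony (SOA), sampled at 250 Hz on eight channels
(Fz, Cz, Pz, Oz, P3, P4, PO7, PO8).  One selection therefore takes
`14 · k · 0.224 s` of flash time at `k` sequences, plus any configured
inter-selection pause (default 0; see "Open timing questions" below).

The four menus implement an asynchronous design: a No-Control (NC) menu
whose only live cell is the central "IC" command (spurious exit chance
1/49 ≈ 2 % per selection), an Intentional-Control (IC) menu with ten
commands for the four messaging services, a Spelling menu (26 letters,
10 digits, comma, space, two deletes, OK/IC exits, and a column of seven
predicted words), and a Confirmation menu guarding the Spelling exits.
Voice-command strings are the canonical English renderings
("Ok Google, send a WhatsApp to …"); the speller emits them as strings —
no speech synthesis or assistant behavior is modeled.

## Synthetic EEG

A subject is a generative model: per-channel P300 template amplitude
(Gaussian bump, default peak 5 µV at Pz/PO7/PO8 scaled down frontally,
width σ = 60 ms), latency drawn uniformly in 300–400 ms (within the
physiological 250–500 ms band), per-flash uniform latency jitter, and
additive Gaussian background noise (white by default, 1/f optional).
Because the 0–800 ms analysis window exceeds the 224 ms SOA, responses
to consecutive flashes overlap; generation is therefore continuous per
selection — templates are superimposed additively on the noise stream at
every attended-row/column flash — and epochs are cut afterwards.
Non-target flashes evoke nothing by default (a small early visual
component is configurable but off).  All randomness derives from integer
seeds through named `SeedSequence` substreams, so identical inputs give
bit-identical signals.

A scalar **difficulty** d ∈ [0, 1] maps to subject parameters:

* noise σ = 150 · d³ µV (broadband, before filtering),
* template amplitude scale 1 − 0.8 d,
* latency jitter 5 + 25 d ms.

The cubic map was calibrated once, from the generator's own calibration
curves, so that d = 0 is a noiseless idealization, d ≈ 0.4–0.6 spans the
70–100 % accuracy range reported for healthy P300-speller users, and
d = 1 performs at chance (1/49).  The default simulated cohort uses
difficulties 0.40–0.62 across 12 subjects.

What the generator deliberately does **not** emulate: ocular and
muscular artifacts, electrode impedance drift, non-stationarity and
fatigue, gaze-dependence of the visual response, and any assistant
misrecognition.  Passing tests therefore show the pipeline's logic and
statistics are right under the stated signal model, not that the
classifier would reach the same numbers on real recordings.

## Preprocessing

The online chain is a 0.1 Hz first-order IIR high-pass, a 9 Hz
second-order Butterworth low-pass, and a 50 Hz notch.  The notch's
ripple and bandwidth are not specified by the acquisition description;
it is realized as a Chebyshev type-I band-stop of design order 3
(48–52 Hz, 0.5 dB ripple — two cascaded third-order half-sections), and
tests assert only attenuation contracts (≥ 40 dB at DC, ≥ 20 dB at
50 Hz relative to 5 Hz, ≤ 3 dB passband loss at 5 Hz).  Filtering is
causal (single forward pass) to mirror online operation; a zero-phase
flag exists for offline re-analysis.  Epochs are 0–800 ms post-onset
(200 samples); no artifact rejection, matching the original system.
Feature decimation before classification is available but off by
default.  Note the 0.1 Hz high-pass has a ~400-sample time constant, so
impulse-response tails are asserted at a horizon where they are actually
negligible (< 1e-6 of peak beyond 5000 samples).

## SWLDA classification

Features are raw amplitudes at (channel, sample) points, 1600 per epoch
at defaults, flattened channel-major.  Labels are coded −1/+1
(configurable) and regressed by OLS with classical stepwise selection:
forward-add the candidate with the smallest coefficient p-value when it
is below 0.1, then remove every included feature whose p-value exceeds
0.15, stopping at no change or 60 features — the standard P300
configuration.  Implementation notes:

* The forward scan residualizes all candidates against the included set
  (Gram–Schmidt update per step), giving each candidate's add-one
  t-statistic as a partial correlation; this is algebraically identical
  to refitting with the candidate included.  Tests verify equivalence
  against an independently written naive stepwise (full OLS refits via
  statsmodels) on small problems.
* Ties in p-value break toward the lowest feature index (determinism).
* Candidates whose residual is numerically zero against the included set
  (rank deficiency) are skipped and logged in the model metadata.
* The removal step drops *all* features above the threshold at once,
  then residuals are rebuilt from scratch; a seen-set guard makes
  termination unconditional.
* No feature standardization by default (regression on raw signals);
  z-scoring is a flag.

Scoring is linear; summing per-flash scores per stimulus and averaging
epochs before scoring give identical decisions (tested as an algebraic
identity), so the decision rule uses score sums.

## Sequence choice and metrics

Calibration spells "DOMOTICA2021" (12 selections) at 8 sequences; the
accuracy curve for k = 1..8 is evaluated on a fresh simulated run of the
same word by truncating each selection to its first k sequences (curves
across k share flashes, which also stabilizes the monotonicity
property).  The online sequence count maximizes the written symbol rate
with a floor of three sequences; WSR's selection time uses pure flash
time (pause 0) unless configured otherwise, since the original timing
convention is not stated.

Metrics use the standard N-alternative formulas (`B`, `ITR = B/T`,
`SR = B/log2 N`, `WSR = (2SR−1)/T` for SR > 0.5 else 0, with
`0·log 0 = 0` by continuity and N = 49).  OCM divides user-spelled
characters (spaces included, fixed command prefixes such as the
29-character "Ok Google, send a WhatsApp to" excluded) by spelling
minutes.  Study-level summaries average per-subject values, not ratios
of pooled sums.  SUS and Raw NASA-TLX use their standard scoring.

The published mean online ITR of the reference study cannot be
reproduced from its table under any single obvious selection-time
convention; `reference_itr_per_subject` exposes both a flash-time and a
total-time convention and asserts neither.

## Closed-loop simulation

A replanning user policy drives online tasks: it plans the shortest
selection sequence to the task goal by breadth-first search over the
speller state machine (prediction slots included) and attends the first
planned item; after any erroneous decision it replans from the new state
(wrong character → delete, wrong predicted word → delete-word,
unintended menu exit → navigate back).  The planner's restricted move
set is shortest-path-sound (omitted moves are no-ops or create
deviations that cost strictly more to undo) and is verified against an
exhaustive search on enumerable toy tasks.  Tasks are capped at 200
selections, after which they are marked failed.

Prediction-slot selection replaces the current partial word with the
predicted word plus a trailing space; this convention is required for
the protocol's printed 19-action minimum of the WhatsApp task to be
achievable.  The packaged corpus fixture is constructed so predictions
become available exactly as the protocol states (receiver after 1 typed
character, the two long payload words after 3 and 2, the e-mail receiver
after 2), with exactly seven higher-frequency pad words masking each
earlier prefix; the Spanish stopwords "en"/"la" are omitted so no
shortcut undercuts the printed minimum.

Task time is model time — selections × selection duration.  The
reference study's wall-clock seconds include human pauses a simulator
cannot reproduce, so timing columns are never compared against the
packaged table.  The protocol's two one-minute NC waits are simulated as
⌈60 s / selection duration⌉ consecutive noise-only selections.  Task 3's
free reply defaults to "PASTA" and Task 4's free e-mail body to a fixed
fixture string, keeping runs deterministic; both are configurable.
Subjects below 70 % overall accuracy are flagged excluded, as in the
study protocol.

## Problem sizes

Simulation-based tests use sizes chosen to make their statistics
informative while keeping the default suite quick: the chance-escape
Monte-Carlo uses 5000 full-pipeline selections (3 standard errors around
1/49), the accuracy-monotonicity property averages 20 calibrated
subjects at difficulty 0.5, and study-level regression tests use 2–12
subjects.  `scripts/acceptance.py` recomputes the minimum-action count
of the structured WhatsApp task from scratch via the planner.

## Known limitations

* The signal model is additive and Gaussian; real P300 amplitude varies
  trial-to-trial with attention and habituation.
* Grid positions of letters and commands inside the menus are a free
  layout choice; they affect nothing measured here (selection counts are
  position-independent), but would matter for gaze-dependent effects the
  model does not include.
* The notch parameters, label coding, and decimation settings of the
  original classifier tool are unknown; all are exposed as configuration
  with documented defaults.
* Assistant-side behavior (misrecognition, context timeouts, routines)
  is represented only as optional emitted strings, off by default.
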