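# spellersim

A desk-scale simulator of a **visual P300 row-column speller** that
controls smartphone messaging (WhatsApp, Telegram, SMS, e-mail) through
voice commands for a virtual assistant.  It is aimed at BCI researchers
and engineers who want to study the *system* — menu design, stimulus
scheduling, classifier configuration, throughput metrics — without EEG
hardware: every stage of the online loop is simulated and testable.

The package implements:

* **Synthetic EEG** — 8-channel, 250 Hz stimulus-locked recordings with
  P300-like deflections (Gaussian templates, parieto-occipital
  topography, latency jitter) superimposed on noise; continuous per
  selection because the 0–800 ms epoch outlasts the 224 ms SOA.
* **Online preprocessing** — 0.1–9 Hz band-pass (first-order IIR
  high-pass + second-order Butterworth low-pass), 50 Hz Chebyshev
  notch, causal filtering, 0–800 ms epoching.
* **SWLDA** — stepwise linear discriminant analysis: forward inclusion
  (p < 0.1) / backward elimination (p > 0.15) over (channel, time)
  features, at most 60, yielding a linear target/non-target scorer.
* **Row-column engine** — pseudo-random flash schedules (each row and
  column once per sequence), score accumulation, argmax row/column
  decision.
* **Four-menu control paradigm** — No-Control / Intentional-Control /
  Spelling / Confirmation state machine with a seven-slot word
  predictor, voice-command composition, a uniform-cost minimum-action
  planner, and a replanning simulated user for closed-loop runs.
* **Metrics** — accuracy, bits per selection
  `B = log2 N + P log2 P + (1−P) log2[(1−P)/(N−1)]`, `ITR = B/T`,
  symbol rate `SR = B/log2 N`, written symbol rate
  `WSR = (2SR−1)/T` (0 for SR ≤ 0.5), output characters per minute
  (OCM), WSR-maximizing sequence choice (floor 3), SUS and Raw
  NASA-TLX scoring.
* **Study runner** — calibration ("DOMOTICA2021", 8 sequences) →
  classifier → sequence choice → four messaging tasks with one-minute
  No-Control waits → per-subject result tables; plus the packaged
  per-subject results of the original 12-participant validation study
  and the summary operations over them.

See `docs/methods.md` for the model details and design choices.

## Worked example

Minimum actions for the structured WhatsApp task ("send *experimento en
la universidad* to Francisco"), planned over the four-menu FSM with the
packaged prediction corpus:

```sh
$ spellersim plan --task 1
{
 "task": 1,
 "minimum_actions": 19,
 "plan": ["IC", "Send WA", "F", "PRED1", "E", "X", "P", "PRED1",
          "E", "N", "SPC", "L", "A", "SPC", "U", "N", "PRED4",
          "OK", "Confirm"]
}
```

19 selections: enter Intentional Control, pick the WhatsApp command,
then spell with predictions — one letter plus a slot for "Francisco",
three letters plus a slot for "experimento", a slot after "UN" for
"universidad" — and confirm.  A simulated subject of moderate difficulty
then runs the task closed-loop (synthetic EEG → filters → SWLDA →
row/column decision → menu transition, replanning after every error):

```sh
$ spellersim run-task --seed 3 --difficulty 0.5 --task 1
{
 "task": 1,
 "selections": 24,
 "seconds": 376.32,
 "accuracy_pct": 91.67,
 "completed": true,
 "spoken": ["Ok Google, send a WhatsApp to Francisco experimento EN LA universidad "]
}
```

This subject made two misselections and corrected them (24 selections
against the 19-action minimum, 91.67 % selection accuracy); the final
voice command is emitted as a string.  The same subject's calibration
chose 5 sequences per selection, where its written symbol rate peaked
(accuracy 1.0 at k = 5, WSR 3.83 symbols/min):

```sh
$ spellersim calibrate --seed 3 --difficulty 0.5
{"chosen_n_seq": 5, "curve": {... "5": {"accuracy": 1.0, "wsr": 3.827} ...}}
```

The packaged reference table reproduces the validation study's printed
aggregates:

```sh
$ spellersim metrics | head -4
{
 "seq_mean": 4.25,
 "seq_sd": 1.4847711791873706,
 "sel_task1_mean": 23.166666666666668,
```

(mean accuracy 86.14 %, 82.92 selections versus a 61.17-action
minimum).  `spellersim run-study` runs a whole simulated cohort and
`spellersim simulate` exports raw labeled epochs as CSV.

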