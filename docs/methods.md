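# Methods

## Scope and data model

The package operates on *ResponseTables*: tidy per-trial records
(`participant_id, condition, encoding_order, event_id, cue_category,
target_category, correct`) with exactly the six directed within-event
questions per (participant, event). Three producers emit this format — the
experiment-schedule generator plus a human data file, the synthetic
behavioural generator, and the attractor-network simulation — and one
consumer analyses it, so every stage can be validated against every other.
Elements are abstract identifiers with a category (location / person /
object) and a valence; image content is never modelled because nothing
downstream consumes it.

## Experiment schedules

`make_events(n_neutral, n_negative, seed)` creates disjoint
person–location–object triples; only person elements can be negative, and an
event is negative exactly when its person is. Encoding schedules come in two
modes: `triples` (one simultaneous trial per event, one block) and `pairs`
(three trials per event, one per block, following the person-last or
person-first pair sequence, shuffled within block). Test schedules probe
every association in both directions (6 trials/event). Each 6-AFC choice
list holds the correct target, two foils from other events of the same
condition and three from the opposite condition — all of the target's
category — so every trial shows three neutral-event and three negative-event
options. Foils are drawn uniformly without replacement; their identity is
irrelevant downstream, so no further matching is attempted.

Trial order is randomised under the constraint that consecutive trials never
probe the same event, implemented as reject-and-reshuffle with a bounded
retry count (200) after which the last shuffle is accepted; the minimum
spacing of one intervening trial is this package's choice, as is treating
the 24 h study–test delay as pure schedule metadata (`delay_hours`) with no
computational effect. Schedules are byte-identical for equal seeds.

## Dependency analysis

Per participant × condition (× encoding order), six 2×2 contingency tables
over events: three *cue-common* tables (cue A → retrieve B vs. A → C) and
three *target-common* tables (B → A vs. C → A). Observed dependency D is the
diagonal proportion (both correct or both incorrect) averaged over the six
tables with equal weight.

The independent model uses the cell's marginal question accuracies:
`Di = P_AB·P_AC + (1−P_AB)(1−P_AC)` per table, averaged over tables. The
dependent model adjusts each event by an episodic factor

    E_i = (e_i − P_G/c) / (ē − P_G/c),

where `e_i` is event i's mean accuracy over its two reference questions,
`ē` the cell mean of the same quantity, `P_G` the guessing probability
(default 1) and `c = 6` the number of choices. Adjusted probabilities
`P'(i) = E_i (P − P_G/c) + P_G/c` are clipped to [0, 1] and
`Dd = mean_i [P'_AB(i) P'_AC(i) + (1−P'_AB(i))(1−P'_AC(i))]`, averaged over
tables.

Two properties of this definition were design drivers:

* **Identity.** `E ≡ 1` gives `Dd = Di` exactly; an event at the guessing
  floor gets `E = 0` and `P' = P_G/c`; uniform performance across events
  gives `E = 1` everywhere. Measuring `e_i` *above the guessing floor* is
  what lets a ceiling event map to `P' = 1`: a fully known event should be
  predicted to retrieve everything, which the uncorrected ratio `e_i/ē`
  cannot deliver (it predicts `P' < 1` whenever guessing dilutes `ē`).
* **Unbiasedness under full dependency.** The four questions outside a table
  are split into two disjoint pairs, one per adjusted probability (for a
  cue-common table on A, `P'_AB` is referenced by the two questions cued by
  B and `P'_AC` by those cued by C; target-common tables analogously use the
  two remaining questions involving each varying element). With a shared
  reference set the plug-in `Dd` is inflated by the convexity of the
  diagonal in `P'` (≈ +0.03 for an all-or-none responder at q = 0.5);
  disjoint references make the two factors' estimation noise independent,
  so on fully dependent data `Dd` converges to `D` (measured gap ≈ 0.004 at
  10⁴ events, within Monte-Carlo error). The published description of the
  factor leaves this level of detail to supplementary material; the split
  is this package's own resolution.

Cells whose reference performance does not exceed the guessing floor have no
defined relative performance; they are reported with `Dd = NaN` rather than
imputed. Events with missing questions are rejected with an error naming the
event, never imputed. `P_G` is a parameter: 1 by default (6-AFC guessing),
0 for data from generators with no guessing mechanism.

## Synthetic responders

Three regimes with known ground truth: *independent* (each question an
independent Bernoulli at its marginal; `D = Di = p² + (1−p)²`),
*all-or-none* (event known with probability q, else guesses at g = 1/6;
`D = q + (1−q)(g² + (1−g)²)`, the limiting fully dependent responder), and
*graded* (per-event strength s ~ Beta(2, 2), question accuracy
`g + s(1−g)`; intermediate dependency, Monte-Carlo only). Guessing is an
independent 1/6 success per question, mirroring the forced choice. The
generator emulates the *structure* the analysis assumes — not reaction
times, recognition judgements, foil confusability, participant-level
heterogeneity or fatigue — so passing calibration here shows the statistic
is correct, not that any particular human dataset satisfies its assumptions.

## Attractor network

N rate-coded neurons (one per element; N = 216 for the default protocol —
the published description leaves N open, and one-neuron-per-element is the
minimal faithful choice), fully recurrent, no self-connections.
Threshold-linear rates `r = clip(I_total − θ_T, 0, r_max)` with θ_T = 5 nA,
r_max = 10 Hz, iterated synchronously at 1 ms per step for the 1000 ms trial
duration. Iteration stops early at an exact fixed point (bitwise-equal
successive rate vectors), which is a pure optimisation: once reached, every
further update is the identity. Marginal gain-one loops — the pattern-
completion pathway — climb to r_max well within 1000 steps, so "saturation =
successful completion" is deterministic. Rates reset to zero between trials;
no carry-over activity.

Encoding: presented elements receive I_ext = 15 nA; weights then grow by
`Δw = m·k·r_pre·[r_post − θ_p]+` per step with θ_p = 7.5 Hz, integrated at
the settled rates over the trial, where additionally only neurons firing at
≥ θ_p participate as presynaptic partners. The symmetric gate is this
package's convention: it guarantees that an element incidentally reactivated
below θ_p (e.g. a negative person at ≤ 7 Hz during a later neutral-pair
trial) neither gains nor grants any weight, keeping the learned matrix
symmetric in all cases, while being indistinguishable from the one-sided
rule throughout the standard protocol. Learning is probabilistic: one draw
per trial (shared by both directions of the pair) sets k = k_neut = 1.6·10⁻⁴
with probability p_enc = 0.65, else 0. The modulation factor is m = 0.6
whenever any negative-element neuron fires at ≥ θ_neg = 1 Hz, else 1; the
threshold is inclusive because a single weak (0.6) association reactivates a
negative element at exactly 0.6·10 − 5 = 1 Hz, and that reactivation is the
mechanism behind the person-first deficit.

With these constants the per-step increment saturates any suprathreshold
pair within one trial, so weight magnitudes are governed by ceilings: each
trial's potentiation is capped at m·w_max (never decrementing an existing
stronger weight) and globally at w_max = 1. Neutral pairs therefore encode
at 1.0 and modulated pairs at 0.6 — the weak-link criterion: a 0.6 link
retrieves its association directly (6 Hz ≥ θ_ret = 5 Hz) but cannot drive
completion through an intermediate element (the two-weak-link fixed point
leaves the target at ≈ 0.94 Hz; a weak-then-strong chain at ≈ 4.7 Hz; only
a strong second link creates the gain-one loop that saturates). A plain
hard limit of w_max for all trials would saturate modulated pairs at 1.0 as
well, erasing the modulation; the m-scaled trial ceiling is the package's
reconstruction of the stated weak-link behaviour.

Retrieval: cue at 15 nA, the six choice neurons at 5 nA, learning off. A
trial is correct iff the correct target settles at ≥ θ_ret *and* is strictly
the most active choice; the argmax guard only matters for non-default
parameterisations, since cross-event weights never form and foils stay at
0 Hz. Each of the 26 simulated participants is an independent network with
its own RNG stream spawned from the master seed.

Enumerating the eight per-trial-draw configurations per event (implemented
in `enumerate_question_accuracy`, which encodes and probes the isolated
3-neuron event subnetwork) yields closed-form expectations: every neutral
question at `p_enc + (1−p_enc)p_enc² ≈ 0.798`; all negative person-first
questions at `p_enc = 0.65`; negative person-last questions at 0.65 except
the two person-cued ones, which complete through the strong location–object
link (≈ 0.798). These are the values the test-suite checks the simulation
against. Because the six outcomes of an event are driven by three shared
link draws, per-event correct counts cluster (0/2/6 for neutral events);
accuracy comparisons are therefore made per directed question type, where
each event contributes one independent Bernoulli trial and the binomial
interval is exact.

## Problem sizes and numerical choices

Default problem sizes were chosen to mirror the modelled study: 26
simulations × 72 events for the network (a full run takes a few seconds),
10⁴ events per cell for synthetic-calibration checks (Monte-Carlo SE ≈
0.004 on D), 10⁵ trials for the chance-level check. The settle/oracle
equivalence is verified exhaustively for all 2- and 3-neuron directed
weight configurations over {0, 0.6, 1.0} under multiple current patterns,
plus a seeded random sample of 4–6-neuron configurations (exhaustion at
n = 6 would require 3³⁰ cases). Statistical test tolerances are 99% binomial
intervals for accuracies and 3 Monte-Carlo standard errors for dependency
quantities. All thresholds (θ_T, θ_p, θ_neg, θ_ret) are inclusive (≥).

## Known limitations

* The dependency analysis requires complete 6-question events; real datasets
  with dropped trials need pre-filtering (the CSV reader reports offending
  events by name).
* The dependent model's episodic factors are estimated from two questions
  per retrieval; for small cells (≲ 10 events) `Dd` is noisy and the
  degenerate-cell condition (`ē ≤ P_G/c`) occurs at realistically low
  accuracies.
* The network is a minimal mechanism probe: no inhibition, no spiking, no
  consolidation or delay effects, no anatomical mapping, and foil valence
  plays no role at retrieval because cross-event weights never form.
* Simultaneous-triples encoding is representable in schedules but the
  network protocol deliberately supports only overlapping pairs, matching
  the design it models.
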