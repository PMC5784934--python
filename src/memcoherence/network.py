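"""Rate-coded attractor network of associative encoding and pattern completion.

One neuron per event element, fully recurrently connected (no self
connections). A neuron's firing rate is a threshold-linear function of its
total input current

    r_i = clip(I_ext,i + sum_j w_ij r_j - theta_T, 0, r_max)

iterated synchronously (1 step = 1 ms) until a fixed point or the trial
duration is reached. During encoding, presented elements are driven at
I_drive; weights then grow by a Hebbian rule gated by a BCM-like postsynaptic
threshold theta_p: only neurons firing at or above theta_p participate in
potentiation, so an element incidentally reactivated at a low rate neither
gains nor grants synaptic weight. Learning is probabilistic (a single
learning-rate draw per trial, probability p_enc) and is down-modulated by a
factor m_neg whenever any neuron coding a negative element fires at or above
theta_neg — whether that element is on screen or merely reactivated through
previously learned associations. Per-trial potentiation is capped at
m * w_max, so associations formed in the presence of (or via reactivation of)
a negative element saturate at a weaker strength: strong enough to be
retrieved directly, too weak to drive pattern completion.

At retrieval the cue neuron is driven at I_drive and the six forced-choice
candidates at I_choice; a trial is correct when the correct target settles at
or above theta_ret and is strictly the most active of the six choices.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd

from .design import (
    CATEGORIES,
    PAIR_SEQUENCES,
    QUESTIONS,
    EncodingSchedule,
    EventSet,
    TestSchedule,
)

__all__ = [
    "ModelParams",
    "NetworkState",
    "settle",
    "settle_bruteforce",
    "modulation_factor",
    "hebbian_update",
    "encode_trial",
    "retrieve_trial",
    "run_simulation",
    "enumerate_question_accuracy",
]


@dataclass(frozen=True)
class ModelParams:
    """All network constants. Currents in nA, rates in Hz, times in ms."""

    theta_T: float = 5.0  # activation threshold
    r_max: float = 10.0  # peak firing rate
    theta_p: float = 7.5  # BCM-like potentiation threshold
    w_max: float = 1.0  # hard weight ceiling
    k_neut: float = 1.6e-4  # learning rate for neutral associations
    p_enc: float = 0.65  # per-trial probability of a positive learning rate
    m_neg: float = 0.6  # learning-rate modulation under negative activity
    theta_neg: float = 1.0  # negative-reactivation rate threshold
    i_drive: float = 15.0  # current to presented / cue elements
    i_choice: float = 5.0  # current to forced-choice candidates
    theta_ret: float = 5.0  # retrieval rate threshold
    t_enc: float = 1000.0  # encoding trial duration
    t_ret: float = 1000.0  # retrieval trial duration
    dt: float = 1.0  # integration step
    n_sims: int = 26  # simulated participants

    def __post_init__(self) -> None:
        for name in ("theta_T", "r_max", "theta_p", "w_max", "theta_neg",
                     "i_drive", "i_choice", "theta_ret", "t_enc", "t_ret", "dt"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 <= self.p_enc <= 1.0:
            raise ValueError("p_enc must lie in [0, 1]")
        if not 0.0 < self.m_neg <= 1.0:
            raise ValueError("m_neg must lie in (0, 1]")

    @property
    def n_steps_enc(self) -> int:
        return int(round(self.t_enc / self.dt))

    @property
    def n_steps_ret(self) -> int:
        return int(round(self.t_ret / self.dt))


@dataclass
class NetworkState:
    """Weights, rates and the element->neuron mapping for one participant."""

    index: dict[str, int]  # element_id -> neuron index
    weights: np.ndarray  # N x N, w[i, j] = synapse from j onto i
    rates: np.ndarray  # length N, Hz
    negative_ids: frozenset[int]  # neurons coding negative elements

    @classmethod
    def fresh(cls, events: EventSet) -> "NetworkState":
        ids = events.element_ids
        index = {eid: i for i, eid in enumerate(ids)}
        n = len(ids)
        neg = frozenset(index[eid] for eid in events.negative_element_ids)
        return cls(index, np.zeros((n, n)), np.zeros(n), neg)

    def validate(self, params: ModelParams) -> None:
        w, r = self.weights, self.rates
        if np.any(w < 0) or np.any(w > params.w_max):
            raise ValueError("weights out of [0, w_max]")
        if np.any(np.diagonal(w) != 0):
            raise ValueError("self-connections must stay zero")
        if np.any(r < 0) or np.any(r > params.r_max):
            raise ValueError("rates out of [0, r_max]")


def settle(
    weights: np.ndarray,
    external_currents: np.ndarray,
    params: ModelParams,
    n_steps: int | None = None,
) -> np.ndarray:
    """Iterate r <- clip(I_ext + W r - theta_T, 0, r_max) synchronously.

    Runs at most ``n_steps`` updates (the trial duration) but stops as soon as
    an exact fixed point is reached, which changes nothing: once two
    successive rate vectors coincide, every further update is the identity.
    Marginal gain-one loops climb to r_max well inside 1000 steps, so the cap
    makes "saturation = successful pattern completion" deterministic.
    """
    currents = np.asarray(external_currents, dtype=float)
    if not (np.all(np.isfinite(weights)) and np.all(np.isfinite(currents))):
        raise ValueError("non-finite weights or currents")
    if n_steps is None:
        n_steps = params.n_steps_ret
    r = np.zeros_like(currents)
    for _ in range(n_steps):
        total = currents + weights @ r
        r_new = np.clip(total - params.theta_T, 0.0, params.r_max)
        if np.array_equal(r_new, r):
            break
        r = r_new
    return r


def settle_bruteforce(
    weights, external_currents, params: ModelParams, n_steps: int | None = None
) -> list[float]:
    """Scalar-loop reference for :func:`settle` (no linear algebra).

    Applies the threshold-linear update element by element for the full trial
    duration; used as an independent cross-check in the test-suite.
    """
    if n_steps is None:
        n_steps = params.n_steps_ret
    w = [[float(x) for x in row] for row in np.asarray(weights)]
    cur = [float(x) for x in np.asarray(external_currents)]
    n = len(cur)
    r = [0.0] * n
    for _ in range(n_steps):
        nxt = []
        for i in range(n):
            total = cur[i]
            for j in range(n):
                total += w[i][j] * r[j]
            x = total - params.theta_T
            if x < 0.0:
                x = 0.0
            elif x > params.r_max:
                x = params.r_max
            nxt.append(x)
        if nxt == r:
            break
        r = nxt
    return r


def modulation_factor(
    rates: np.ndarray, negative_ids, params: ModelParams
) -> float:
    """m_neg if any negative-element neuron fires at >= theta_neg, else 1.

    The threshold is inclusive: a single weak (m_neg * w_max) association
    reactivates a negative element at exactly (m_neg * w_max * r_max -
    theta_T) Hz = 1 Hz, and that reactivation must engage the modulation.
    """
    idx = list(negative_ids)
    if idx and np.any(np.asarray(rates)[idx] >= params.theta_neg):
        return params.m_neg
    return 1.0


def hebbian_update(
    weights: np.ndarray,
    rates: np.ndarray,
    k: float,
    m: float,
    params: ModelParams,
    n_steps: int | None = None,
) -> np.ndarray:
    """Apply one trial of Hebbian potentiation and return the new weights.

    dw_ij/step = m * k * r_j * [r_i - theta_p]+ for neurons j themselves
    firing at >= theta_p, integrated over the trial at the settled rates.
    Increments are capped at the per-trial ceiling m * w_max — existing
    stronger weights are never decremented — and at the global ceiling w_max.
    """
    if k == 0.0:
        return weights.copy()
    if n_steps is None:
        n_steps = params.n_steps_enc
    r = np.asarray(rates, dtype=float)
    post = np.clip(r - params.theta_p, 0.0, None)
    pre = np.where(r >= params.theta_p, r, 0.0)
    inc = (m * k * n_steps) * np.outer(post, pre)  # inc[i, j]: j -> i
    np.fill_diagonal(inc, 0.0)
    ceiling = np.maximum(weights, m * params.w_max)
    new = np.minimum(weights + inc, ceiling)
    return np.minimum(new, params.w_max)


def encode_trial(
    state: NetworkState,
    element_ids,
    params: ModelParams,
    rng: np.random.Generator,
) -> NetworkState:
    """Present a pair (or triple) of elements and let the weights grow.

    A single learning-rate draw per trial (probability p_enc of k = k_neut)
    is shared by both directions of every presented pair; rates are reset to
    zero afterwards.
    """
    try:
        idx = [state.index[eid] for eid in element_ids]
    except KeyError as exc:
        raise ValueError(f"unknown element {exc.args[0]!r}") from None
    currents = np.zeros(len(state.rates))
    currents[idx] = params.i_drive
    rates = settle(state.weights, currents, params, params.n_steps_enc)
    m = modulation_factor(rates, state.negative_ids, params)
    k = params.k_neut if rng.random() < params.p_enc else 0.0
    weights = hebbian_update(state.weights, rates, k, m, params)
    state.weights = weights
    state.rates = np.zeros_like(state.rates)
    return state


@dataclass(frozen=True)
class RetrievalOutcome:
    event_id: str
    cue_category: str
    target_category: str
    correct: bool
    choice_rates: tuple[float, ...]


def retrieve_trial(
    state: NetworkState,
    cue_id: str,
    choice_ids,
    target_id: str,
    params: ModelParams,
) -> tuple[bool, np.ndarray]:
    """Cue-driven forced choice with frozen weights (learning off).

    The cue neuron receives I_drive, the six candidates I_choice; the trial is
    correct iff the correct target settles at >= theta_ret and is strictly the
    most active choice (with within-event-only weights the five foils always
    stay silent, so the argmax guard never binds at default parameters).
    Returns the verdict and the settled rates of the choice neurons; weights
    are untouched and rates reset afterwards.
    """
    currents = np.zeros(len(state.rates))
    currents[state.index[cue_id]] = params.i_drive
    choice_idx = [state.index[c] for c in choice_ids]
    currents[choice_idx] = params.i_choice
    rates = settle(state.weights, currents, params, params.n_steps_ret)
    choice_rates = rates[choice_idx]
    t = list(choice_ids).index(target_id)
    target_rate = choice_rates[t]
    others = np.delete(choice_rates, t)
    correct = bool(target_rate >= params.theta_ret and np.all(target_rate > others))
    state.rates = np.zeros_like(state.rates)
    return correct, choice_rates


def run_simulation(
    events: EventSet,
    enc: EncodingSchedule,
    test: TestSchedule,
    params: ModelParams | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Run n_sims independent networks over the pairs-mode protocol.

    Each simulated participant gets a fresh zero-weight network and its own
    RNG stream spawned from the master seed; all encoding trials run in
    schedule order, then all test trials with learning switched off. Returns
    a ResponseTable with one row per (participant, test trial).
    """
    if params is None:
        params = ModelParams()
    if enc.mode != "pairs":
        raise ValueError("the simulation protocol requires a pairs-mode schedule")
    streams = np.random.SeedSequence(seed).spawn(params.n_sims)
    rows = []
    for p, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        state = NetworkState.fresh(events)
        for t in enc.trials:
            ev = events.by_id(t.event_id)
            element_ids = [ev.element(c).element_id for c in t.categories]
            encode_trial(state, element_ids, params, rng)
        w_before = state.weights.copy()
        for t in test.trials:
            ev = events.by_id(t.event_id)
            cue_id = ev.element(t.cue_category).element_id
            correct, choice_rates = retrieve_trial(
                state, cue_id, list(t.choices), t.target_id, params
            )
            rows.append(
                {
                    "participant_id": f"sim{p:02d}",
                    "condition": ev.condition,
                    "encoding_order": enc.order[t.event_id],
                    "event_id": t.event_id,
                    "cue_category": t.cue_category,
                    "target_category": t.target_category,
                    "correct": int(correct),
                }
            )
        if not np.array_equal(w_before, state.weights):
            raise AssertionError("retrieval must not change weights")
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Analytic enumeration of per-question accuracy


def _encode_event_weights(
    condition: str, order: str, draws: tuple[bool, bool, bool], params: ModelParams
) -> np.ndarray:
    """Weight matrix of one 3-neuron event after its three paired-associate
    encoding trials, with the per-trial learning-rate draws fixed to
    ``draws`` instead of sampled. Uses the same settle / modulation / Hebbian
    machinery as the full simulation."""
    w = np.zeros((3, 3))
    negative_ids = [CATEGORIES.index("person")] if condition == "negative" else []
    for pair, ok in zip(PAIR_SEQUENCES[order], draws):
        currents = np.zeros(3)
        for cat in pair:
            currents[CATEGORIES.index(cat)] = params.i_drive
        rates = settle(w, currents, params, params.n_steps_enc)
        m = modulation_factor(rates, negative_ids, params)
        k = params.k_neut if ok else 0.0
        w = hebbian_update(w, rates, k, m, params)
    return w


def enumerate_question_accuracy(
    condition: str, order: str, params: ModelParams | None = None
) -> dict[tuple[str, str], float]:
    """Expected accuracy of each cue->target question, by exhaustively
    enumerating the eight per-event learning-draw configurations.

    Each configuration is encoded and probed on the isolated 3-neuron event
    subnetwork (foil neurons never acquire weights, so they settle at zero
    and can be omitted); configurations are weighted by their probability
    under independent per-trial draws at p_enc.
    """
    if params is None:
        params = ModelParams()
    p = params.p_enc
    acc: dict[tuple[str, str], float] = {q: 0.0 for q in QUESTIONS}
    for draws in product([True, False], repeat=3):
        prob = float(np.prod([p if ok else 1 - p for ok in draws]))
        w = _encode_event_weights(condition, order, draws, params)
        for cue, tgt in QUESTIONS:
            currents = np.zeros(3)
            currents[CATEGORIES.index(cue)] = params.i_drive
            currents[CATEGORIES.index(tgt)] = params.i_choice
            rates = settle(w, currents, params, params.n_steps_ret)
            if rates[CATEGORIES.index(tgt)] >= params.theta_ret:
                acc[(cue, tgt)] += prob
    return acc
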