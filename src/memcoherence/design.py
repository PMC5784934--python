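"""Experimental design: events, encoding schedules, and 6-AFC test schedules.

Events are person-location-object triples. Half the events carry a negative
person image; the location and object are always neutral. Events are encoded
either simultaneously as triples (one trial per event) or as overlapping
paired associates across three blocks, with the purely neutral location-object
pair encoded either first (person-last order) or last (person-first order).
Every within-event association is then probed in both directions with a
six-alternative forced choice whose options are always three elements drawn
from neutral events and three from negative events.

Elements are abstract identifiers carrying a category and a valence; no image
content is modelled because nothing downstream consumes it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

CATEGORIES: tuple[str, str, str] = ("location", "person", "object")
CONDITIONS: tuple[str, str] = ("neutral", "negative")
ORDERS: tuple[str, str, str] = ("simultaneous", "person_last", "person_first")

#: Pair presentation sequence per encoding order, one pair per block.
PAIR_SEQUENCES: dict[str, tuple[tuple[str, str], ...]] = {
    "person_last": (
        ("location", "object"),
        ("person", "location"),
        ("object", "person"),
    ),
    "person_first": (
        ("object", "person"),
        ("person", "location"),
        ("location", "object"),
    ),
}

#: The six directed cue->target questions per event, in canonical order.
QUESTIONS: tuple[tuple[str, str], ...] = (
    ("location", "person"),
    ("location", "object"),
    ("person", "location"),
    ("person", "object"),
    ("object", "location"),
    ("object", "person"),
)


@dataclass(frozen=True)
class Element:
    element_id: str
    category: str
    valence: str

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.valence not in CONDITIONS:
            raise ValueError(f"unknown valence {self.valence!r}")
        if self.valence == "negative" and self.category != "person":
            raise ValueError("only person elements may be negative")


@dataclass(frozen=True)
class Event:
    event_id: str
    elements: tuple[Element, Element, Element]  # ordered location, person, object
    condition: str

    def __post_init__(self) -> None:
        cats = tuple(e.category for e in self.elements)
        if cats != CATEGORIES:
            raise ValueError("elements must be (location, person, object)")
        person_negative = self.elements[1].valence == "negative"
        if (self.condition == "negative") != person_negative:
            raise ValueError("condition must match the person element's valence")

    def element(self, category: str) -> Element:
        return self.elements[CATEGORIES.index(category)]


@dataclass
class EventSet:
    events: list[Event] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    def by_id(self, event_id: str) -> Event:
        for ev in self.events:
            if ev.event_id == event_id:
                return ev
        raise KeyError(event_id)

    @property
    def element_ids(self) -> list[str]:
        return [e.element_id for ev in self.events for e in ev.elements]

    @property
    def negative_element_ids(self) -> set[str]:
        return {
            e.element_id
            for ev in self.events
            for e in ev.elements
            if e.valence == "negative"
        }


@dataclass(frozen=True)
class EncodingTrial:
    event_id: str
    categories: tuple[str, ...]
    block: int


@dataclass
class EncodingSchedule:
    trials: list[EncodingTrial]
    mode: str  # "triples" | "pairs"
    order: dict[str, str]  # event_id -> encoding order
    delay_hours: float = 0.0  # study-test delay; metadata only

    @property
    def n_blocks(self) -> int:
        return max((t.block for t in self.trials), default=0)


@dataclass(frozen=True)
class TestTrial:
    event_id: str
    cue_category: str
    target_category: str
    choices: tuple[str, ...]  # six element_ids, correct target among them
    target_id: str


@dataclass
class TestSchedule:
    trials: list[TestTrial]
    includes_recognition: bool = False


def make_events(n_neutral: int, n_negative: int, seed: int) -> EventSet:
    """Build disjoint person-location-object events.

    Each event owns three unique elements; negative events differ only in the
    valence of their person element. Deterministic given ``seed`` (the seed
    currently only fixes identifier assignment, which is sequential).
    """
    if n_neutral < 0 or n_negative < 0:
        raise ValueError("event counts must be non-negative")
    rng = np.random.default_rng(seed)
    conditions = ["neutral"] * n_neutral + ["negative"] * n_negative
    rng.shuffle(conditions)
    events = []
    for i, cond in enumerate(conditions):
        person_val = "negative" if cond == "negative" else "neutral"
        els = (
            Element(f"loc{i:03d}", "location", "neutral"),
            Element(f"per{i:03d}", "person", person_val),
            Element(f"obj{i:03d}", "object", "neutral"),
        )
        events.append(Event(f"ev{i:03d}", els, cond))
    return EventSet(events)


def assign_orders(events: EventSet, mode: str, seed: int) -> dict[str, str]:
    """Assign encoding orders: simultaneous for triples; for pairs, split each
    condition half person-last / half person-first (the counterbalancing used
    with overlapping-pair encoding)."""
    if mode == "triples":
        return {ev.event_id: "simultaneous" for ev in events}
    rng = np.random.default_rng(seed)
    order: dict[str, str] = {}
    for cond in CONDITIONS:
        ids = [ev.event_id for ev in events if ev.condition == cond]
        rng.shuffle(ids)
        half = len(ids) // 2
        for eid in ids[:half]:
            order[eid] = "person_last"
        for eid in ids[half:]:
            order[eid] = "person_first"
    return order


def make_encoding_schedule(
    events: EventSet,
    mode: str,
    order_assignment: Mapping[str, str],
    seed: int,
) -> EncodingSchedule:
    """Lay out encoding trials.

    ``triples``: one trial per event presenting all three categories, one
    block, randomised order. ``pairs``: three trials per event, one per block,
    following the pair sequence of its assigned order; within a block, trials
    from different events are shuffled together.
    """
    if mode not in ("triples", "pairs"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    for ev in events:
        o = order_assignment.get(ev.event_id)
        if mode == "triples" and o != "simultaneous":
            raise ValueError(f"event {ev.event_id}: triples mode requires simultaneous order")
        if mode == "pairs" and o not in ("person_last", "person_first"):
            raise ValueError(f"event {ev.event_id}: pairs mode requires person_last or person_first")

    trials: list[EncodingTrial] = []
    if mode == "triples":
        block = [EncodingTrial(ev.event_id, CATEGORIES, 1) for ev in events]
        rng.shuffle(block)
        trials = block
    else:
        for b in range(3):
            block = [
                EncodingTrial(ev.event_id, PAIR_SEQUENCES[order_assignment[ev.event_id]][b], b + 1)
                for ev in events
            ]
            rng.shuffle(block)
            trials.extend(block)
    return EncodingSchedule(trials, mode, dict(order_assignment))


def _interleave(trials: list[TestTrial], rng: np.random.Generator, max_retries: int = 200) -> list[TestTrial]:
    """Shuffle so that no two consecutive trials probe the same event.

    Reject-and-reshuffle with bounded retries, then accept the last shuffle
    (the constraint is almost always satisfiable for >= 2 events).
    """
    order = list(trials)
    for _ in range(max_retries):
        rng.shuffle(order)
        if all(a.event_id != b.event_id for a, b in zip(order, order[1:])):
            return order
    return order


def make_test_schedule(
    events: EventSet, seed: int, includes_recognition: bool = False
) -> TestSchedule:
    """Build the six-alternative forced-choice schedule: every within-event
    association tested in both directions (6 trials per event).

    Each choice list holds the correct target, two foils from other events of
    the same condition, and three foils from events of the opposite condition,
    all of the target's category — so every trial offers three elements from
    neutral events and three from negative events.
    """
    rng = np.random.default_rng(seed)
    by_cond: dict[str, list[Event]] = {c: [] for c in CONDITIONS}
    for ev in events:
        by_cond[ev.condition].append(ev)
    for c in CONDITIONS:
        if len(by_cond[c]) < 3 and len(events) > 0:
            raise ValueError(
                f"need at least 3 {c} events to draw same- and opposite-valence foils"
            )

    trials: list[TestTrial] = []
    for ev in events:
        same_pool = [o for o in by_cond[ev.condition] if o.event_id != ev.event_id]
        other_cond = "negative" if ev.condition == "neutral" else "neutral"
        opp_pool = by_cond[other_cond]
        for cue_cat, tgt_cat in QUESTIONS:
            target = ev.element(tgt_cat).element_id
            same_foils = [
                same_pool[i].element(tgt_cat).element_id
                for i in rng.choice(len(same_pool), size=2, replace=False)
            ]
            opp_foils = [
                opp_pool[i].element(tgt_cat).element_id
                for i in rng.choice(len(opp_pool), size=3, replace=False)
            ]
            choices = [target] + same_foils + opp_foils
            rng.shuffle(choices)
            trials.append(
                TestTrial(ev.event_id, cue_cat, tgt_cat, tuple(choices), target)
            )
    trials = _interleave(trials, rng)
    return TestSchedule(trials, includes_recognition)


def encoding_to_frame(sched: EncodingSchedule, events: EventSet) -> pd.DataFrame:
    rows = []
    for i, t in enumerate(sched.trials):
        ev = events.by_id(t.event_id)
        rows.append(
            {
                "trial_index": i,
                "phase": "encoding",
                "block": t.block,
                "event_id": t.event_id,
                "condition": ev.condition,
                "encoding_order": sched.order[t.event_id],
                "presented_categories": "|".join(t.categories),
            }
        )
    return pd.DataFrame(rows)


def test_to_frame(sched: TestSchedule, events: EventSet, order: Mapping[str, str]) -> pd.DataFrame:
    rows = []
    for i, t in enumerate(sched.trials):
        ev = events.by_id(t.event_id)
        rows.append(
            {
                "trial_index": i,
                "phase": "test",
                "block": 1,
                "event_id": t.event_id,
                "condition": ev.condition,
                "encoding_order": order.get(t.event_id, "simultaneous"),
                "cue_category": t.cue_category,
                "target_category": t.target_category,
                "choice_ids": "|".join(t.choices),
            }
        )
    return pd.DataFrame(rows)


def schedules_to_json(
    events: EventSet,
    enc: EncodingSchedule,
    test: TestSchedule,
) -> str:
    payload = {
        "events": [
            {
                "event_id": ev.event_id,
                "condition": ev.condition,
                "elements": {e.category: e.element_id for e in ev.elements},
            }
            for ev in events
        ],
        "encoding": encoding_to_frame(enc, events).to_dict(orient="records"),
        "test": test_to_frame(test, events, enc.order).to_dict(orient="records"),
    }
    return json.dumps(payload, indent=1)
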