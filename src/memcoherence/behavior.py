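"""Synthetic responders with known ground-truth dependency structure.

Three regimes over per-event 6-question response sets:

* ``independent`` — every question is an independent Bernoulli at its
  marginal accuracy: zero true dependency (D = Di in expectation).
* ``all_or_none`` — with probability q the whole event is known and all six
  questions are correct; otherwise each question is an independent guess
  succeeding with probability g (default 1/6, the 6-AFC chance rate): the
  limiting fully dependent responder.
* ``graded`` — each event draws a strength s ~ Beta(a, b) and every question
  succeeds with probability g + s * (1 - g): intermediate dependency.

The output is a ResponseTable, the same tidy per-trial format the network
simulation emits, so the analysis pipeline can be validated against closed
forms without any experimental data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import QUESTIONS

__all__ = ["GeneratorSpec", "generate", "truth"]

CHANCE = 1.0 / 6.0

REGIMES = ("independent", "all_or_none", "graded")


@dataclass(frozen=True)
class GeneratorSpec:
    """Ground-truth description of a synthetic responder population."""

    n_participants: int = 1
    n_events: int = 18  # events per (condition, order) cell
    regime: str = "independent"
    marginal: float = 0.8  # per-question accuracy (independent regime)
    q: float = 0.5  # event-knowledge probability (all_or_none)
    beta_a: float = 2.0  # strength distribution (graded)
    beta_b: float = 2.0
    g: float = CHANCE  # guessing success probability
    conditions: tuple[str, ...] = ("neutral", "negative")
    orders: tuple[str, ...] = ("simultaneous",)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.regime not in REGIMES:
            raise ValueError(f"unknown regime {self.regime!r}")
        for name in ("marginal", "q", "g"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.regime == "independent" and self.marginal < self.g:
            raise ValueError("marginal accuracy cannot fall below the guessing rate")
        if self.n_participants < 1 or self.n_events < 1:
            raise ValueError("counts must be positive")


def generate(spec: GeneratorSpec) -> pd.DataFrame:
    """Draw a ResponseTable (6 rows per event) under ``spec``; deterministic
    given ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    rows = []
    for p in range(spec.n_participants):
        pid = f"synth{p:02d}"
        for cond in spec.conditions:
            for order in spec.orders:
                correct = _draw_cell(spec, rng)  # (n_events, 6) 0/1
                for e in range(spec.n_events):
                    eid = f"{cond[:3]}_{order[:6]}_{e:05d}"
                    for qi, (cue, tgt) in enumerate(QUESTIONS):
                        rows.append(
                            (pid, cond, order, eid, cue, tgt, int(correct[e, qi]))
                        )
    return pd.DataFrame(
        rows,
        columns=[
            "participant_id",
            "condition",
            "encoding_order",
            "event_id",
            "cue_category",
            "target_category",
            "correct",
        ],
    )


def _draw_cell(spec: GeneratorSpec, rng: np.random.Generator) -> np.ndarray:
    n, k = spec.n_events, len(QUESTIONS)
    if spec.regime == "independent":
        return (rng.random((n, k)) < spec.marginal).astype(int)
    if spec.regime == "all_or_none":
        known = rng.random(n) < spec.q
        guesses = rng.random((n, k)) < spec.g
        return np.where(known[:, None], 1, guesses).astype(int)
    strength = rng.beta(spec.beta_a, spec.beta_b, size=n)
    p = spec.g + strength * (1.0 - spec.g)
    return (rng.random((n, k)) < p[:, None]).astype(int)


def truth(spec: GeneratorSpec) -> dict[str, float]:
    """Closed-form expected D / Di / Dd where available.

    independent: every contingency table pairs two independent Bernoullis at
    the marginal p, so D = Di = Dd = p^2 + (1-p)^2.

    all_or_none: an event is known (both questions right) with probability q,
    else both are guesses, so D = q + (1-q)(g^2 + (1-g)^2); the marginal is
    p = q + (1-q) g and Di = p^2 + (1-p)^2; the data are maximally dependent,
    so Dd coincides with D asymptotically.
    """
    if spec.regime == "independent":
        p = spec.marginal
        d = p * p + (1 - p) * (1 - p)
        return {"D": d, "Di": d, "Dd": d}
    if spec.regime == "all_or_none":
        g, q = spec.g, spec.q
        d = q + (1 - q) * (g * g + (1 - g) * (1 - g))
        p = q + (1 - q) * g
        return {"D": d, "Di": p * p + (1 - p) * (1 - p), "Dd": d}
    raise ValueError("no closed form for the graded regime; use Monte Carlo")
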