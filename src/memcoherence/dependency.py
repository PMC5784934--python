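"""Statistical dependency of retrievals from the same event.

For each participant and condition (and encoding order, where applicable) six
2x2 contingency tables are built over events: for every category A, one table
crossing the two retrievals cued by A (A->B vs A->C, "cue-common"), and one
crossing the two retrievals of A cued by B and by C (B->A vs C->A,
"target-common"). Observed dependency D is the proportion of events falling
on the main diagonal (both correct or both incorrect), averaged over the six
tables.

Two model predictions are computed per table and averaged the same way:

* Independent model:  Di = P_AB * P_AC + (1 - P_AB)(1 - P_AC), where P_AB and
  P_AC are the participant's mean accuracies for those question types across
  the events of the cell — the dependency expected if the two retrievals
  succeed independently.
* Dependent model: each event i gets an episodic factor

      E_i = (e_i - P_G / c) / (e_bar - P_G / c)

  where e_i is event i's mean accuracy on reference questions outside the
  table, e_bar the cell grand mean of those, P_G the guessing probability
  and c = 6 the number of choices — i.e. relative event performance measured
  above the guessing floor, so that an event answered entirely by guessing
  gets E_i = 0 and a ceiling event maps to certainty. The four reference
  questions of a table are split between its two retrievals (each adjusted
  probability uses the two questions involving its own varying element), so
  the two factors carry independent estimation noise and the plug-in Dd is
  unbiased for fully dependent data rather than inflated by the convexity of
  the diagonal. Adjusted probabilities
  P'_AB(i) = E_AB(i) * (P_AB - P_G / c) + P_G / c are clipped to [0, 1] and
  Dd averages the per-event diagonal probability
  P'_AB(i) P'_AC(i) + (1 - P'_AB(i))(1 - P'_AC(i)) — the maximal dependency
  compatible with the participant's accuracy, guessing rate and across-event
  variance. Setting every E_i to 1 recovers the independent model exactly,
  and on fully dependent (all-or-none) data Dd converges to the observed D.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import CATEGORIES, QUESTIONS

__all__ = [
    "validate_response_table",
    "accuracy_summary",
    "build_contingency_tables",
    "compute_D",
    "compute_Di",
    "episodic_factors",
    "compute_Dd",
    "dependency_report",
    "DEFAULT_P_G",
    "N_CHOICES",
]

DEFAULT_P_G = 1.0
N_CHOICES = 6

GROUP_COLS = ["participant_id", "condition", "encoding_order"]
REQUIRED_COLS = GROUP_COLS + ["event_id", "cue_category", "target_category", "correct"]

PAIR_TYPES = {
    frozenset(("location", "object")): "location-object",
    frozenset(("person", "location")): "person-location",
    frozenset(("object", "person")): "object-person",
}


class MalformedResponseTable(ValueError):
    pass


def validate_response_table(rt: pd.DataFrame) -> pd.DataFrame:
    """Check the ResponseTable contract: required columns, binary
    correctness, and exactly the six directed questions per (participant,
    event)."""
    missing = [c for c in REQUIRED_COLS if c not in rt.columns]
    if missing:
        raise MalformedResponseTable(f"missing columns: {missing}")
    if not rt["correct"].isin([0, 1]).all():
        raise MalformedResponseTable("correct must be 0/1")
    dup = rt.duplicated(subset=["participant_id", "event_id", "cue_category", "target_category"])
    if dup.any():
        r = rt[dup].iloc[0]
        raise MalformedResponseTable(
            f"duplicate question for participant {r['participant_id']!r} event {r['event_id']!r}"
        )
    sizes = rt.groupby(["participant_id", "event_id"], sort=False).size()
    bad = sizes[sizes != 6]
    if len(bad):
        (pid, eid) = bad.index[0]
        raise MalformedResponseTable(
            f"participant {pid!r} event {eid!r} has {bad.iloc[0]} questions, expected 6"
        )
    return rt


def accuracy_summary(rt: pd.DataFrame) -> pd.DataFrame:
    """Mean accuracy per (participant, condition, order, pair type),
    collapsed over the two test directions of each pair."""
    validate_response_table(rt)
    df = rt.copy()
    df["pair_type"] = [
        PAIR_TYPES[frozenset((c, t))]
        for c, t in zip(df["cue_category"], df["target_category"])
    ]
    out = (
        df.groupby(GROUP_COLS + ["pair_type"], sort=False)["correct"]
        .agg(accuracy="mean", n_trials="size")
        .reset_index()
    )
    return out


def _question_matrix(cell: pd.DataFrame) -> pd.DataFrame:
    """events x questions 0/1 matrix for one participant-condition-order cell."""
    mat = cell.pivot_table(
        index="event_id",
        columns=["cue_category", "target_category"],
        values="correct",
        aggfunc="first",
    )
    mat = mat.reindex(columns=pd.MultiIndex.from_tuples(QUESTIONS))
    if mat.isna().any().any():
        eid = mat.index[mat.isna().any(axis=1)][0]
        raise MalformedResponseTable(f"event {eid!r} is missing questions")
    return mat.astype(int)


@dataclass(frozen=True)
class ContingencyTable:
    """One 2x2 table over events, plus the per-event outcome vectors and the
    identities of its two question types."""

    table_kind: str  # "cue_common" | "target_common"
    common_category: str
    question_b: tuple[str, str]  # cue->target of the first retrieval
    question_c: tuple[str, str]
    x: np.ndarray  # per-event correctness for question_b
    y: np.ndarray  # per-event correctness for question_c
    event_ids: tuple[str, ...]

    @property
    def n_events(self) -> int:
        return len(self.x)

    @property
    def counts(self) -> np.ndarray:
        """[[both correct, B only], [C only, both incorrect]]."""
        x, y = self.x, self.y
        return np.array(
            [
                [int(np.sum(x & y)), int(np.sum(x & ~y))],
                [int(np.sum(~x & y)), int(np.sum(~x & ~y))],
            ]
        )


def _six_tables(mat: pd.DataFrame) -> list[ContingencyTable]:
    tables = []
    eids = tuple(mat.index)
    for common in CATEGORIES:
        b, c = [cat for cat in CATEGORIES if cat != common]
        qb, qc = (common, b), (common, c)
        tables.append(
            ContingencyTable(
                "cue_common", common, qb, qc,
                mat[qb].to_numpy(bool), mat[qc].to_numpy(bool), eids,
            )
        )
    for common in CATEGORIES:
        b, c = [cat for cat in CATEGORIES if cat != common]
        qb, qc = (b, common), (c, common)
        tables.append(
            ContingencyTable(
                "target_common", common, qb, qc,
                mat[qb].to_numpy(bool), mat[qc].to_numpy(bool), eids,
            )
        )
    return tables


def build_contingency_tables(
    rt: pd.DataFrame, participant_id: str, condition: str, encoding_order: str
) -> list[ContingencyTable]:
    """The six 2x2 tables for one participant x condition x order cell."""
    validate_response_table(rt)
    cell = rt[
        (rt["participant_id"] == participant_id)
        & (rt["condition"] == condition)
        & (rt["encoding_order"] == encoding_order)
    ]
    if cell.empty:
        raise MalformedResponseTable(
            f"no events for participant {participant_id!r}, "
            f"condition {condition!r}, order {encoding_order!r}"
        )
    return _six_tables(_question_matrix(cell))


def compute_D(tables: list[ContingencyTable]) -> float:
    """Observed dependency: diagonal proportion, averaged over the tables."""
    vals = [(np.sum(t.x == t.y)) / t.n_events for t in tables]
    return float(np.mean(vals))


def compute_Di(tables: list[ContingencyTable]) -> float:
    """Independent-model dependency from the marginal question accuracies."""
    vals = []
    for t in tables:
        pab, pac = float(np.mean(t.x)), float(np.mean(t.y))
        vals.append(pab * pac + (1 - pab) * (1 - pac))
    return float(np.mean(vals))


@dataclass(frozen=True)
class EpisodicFactors:
    E_ab: np.ndarray  # per-event factor for the table's first retrieval
    E_ac: np.ndarray  # per-event factor for the second retrieval
    p_ab: np.ndarray  # adjusted P'_AB per event, clipped to [0, 1]
    p_ac: np.ndarray


class DegenerateReference(ValueError):
    """Reference-question performance does not exceed the guessing floor, so
    relative event performance is undefined."""


def _reference_questions(table: ContingencyTable) -> tuple[list, list]:
    """Disjoint two-question reference sets for the table's two retrievals.

    The four questions outside a table are split so that each adjusted
    probability is referenced by the two questions involving its own varying
    element: for a cue-common table on A, P'_AB uses the questions cued by B
    and P'_AC those cued by C; for a target-common table, P'_BA uses the
    other two questions involving B and P'_CA those involving C. Disjoint
    references keep the two factors' estimation noise independent, which
    makes the plug-in Dd unbiased for fully dependent data.
    """
    others = [q for q in QUESTIONS if q not in (table.question_b, table.question_c)]
    common = table.common_category
    if table.table_kind == "cue_common":
        b = table.question_b[1]  # varying element of the first retrieval
    else:
        b = table.question_b[0]
    refs_b = [q for q in others if q[0] == b or q == (common, b)]
    refs_c = [q for q in others if q not in refs_b]
    return refs_b, refs_c


def episodic_factors(
    mat_or_tables,
    table: ContingencyTable,
    p_g: float = DEFAULT_P_G,
    c: int = N_CHOICES,
) -> EpisodicFactors:
    """Per-event episodic factors and adjusted probabilities for one table.

    ``mat_or_tables`` is the events x questions matrix of the cell. Each
    factor is the event's reference-question accuracy above the guessing
    floor, relative to the cell grand mean above the floor.
    """
    mat = mat_or_tables
    floor = p_g / c

    def factor(refs) -> np.ndarray:
        per_event = mat[refs].to_numpy(float).mean(axis=1)
        grand = per_event.mean()
        if grand - floor <= 0.0:
            raise DegenerateReference(
                f"reference-question grand mean ({grand:.3f}) does not exceed "
                f"the guessing floor ({floor:.3f}) for table "
                f"{table.table_kind}/{table.common_category}"
            )
        return (per_event - floor) / (grand - floor)

    refs_b, refs_c = _reference_questions(table)
    E_ab, E_ac = factor(refs_b), factor(refs_c)
    pab = float(np.mean(table.x))
    pac = float(np.mean(table.y))
    adj_ab = np.clip(E_ab * (pab - floor) + floor, 0.0, 1.0)
    adj_ac = np.clip(E_ac * (pac - floor) + floor, 0.0, 1.0)
    return EpisodicFactors(E_ab, E_ac, adj_ab, adj_ac)


def compute_Dd(
    mat: pd.DataFrame,
    tables: list[ContingencyTable],
    p_g: float = DEFAULT_P_G,
    c: int = N_CHOICES,
) -> float:
    """Dependent-model dependency: per-event diagonal probability under the
    adjusted probabilities, averaged over events then tables."""
    vals = []
    for t in tables:
        ef = episodic_factors(mat, t, p_g, c)
        diag = ef.p_ab * ef.p_ac + (1 - ef.p_ab) * (1 - ef.p_ac)
        vals.append(float(np.mean(diag)))
    return float(np.mean(vals))


def dependency_report(
    rt: pd.DataFrame, p_g: float = DEFAULT_P_G, c: int = N_CHOICES
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """D, Di, Dd and contrasts per (participant, condition, order), plus
    unweighted across-participant means and standard errors per cell.

    Cells whose dependent model is degenerate (all reference questions wrong
    for every event) are reported with Dd = NaN rather than dropped.
    """
    validate_response_table(rt)
    rows = []
    for (pid, cond, order), cell in rt.groupby(GROUP_COLS, sort=False):
        mat = _question_matrix(cell)
        tables = _six_tables(mat)
        d = compute_D(tables)
        di = compute_Di(tables)
        try:
            dd = compute_Dd(mat, tables, p_g, c)
        except DegenerateReference:
            dd = float("nan")
        rows.append(
            {
                "participant_id": pid,
                "condition": cond,
                "encoding_order": order,
                "n_events": mat.shape[0],
                "D": d,
                "Di": di,
                "Dd": dd,
                "D_minus_Di": d - di,
                "D_minus_Dd": d - dd,
                "P_G": p_g,
                "c": c,
            }
        )
    results = pd.DataFrame(rows)
    agg = (
        results.groupby(["condition", "encoding_order"], sort=False)[
            ["D", "Di", "Dd", "D_minus_Di", "D_minus_Dd"]
        ]
        .agg(["mean", "sem", "count"])
        .reset_index()
    )
    agg.columns = [
        "_".join(c for c in col if c) if isinstance(col, tuple) else col
        for col in agg.columns
    ]
    return results, agg
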