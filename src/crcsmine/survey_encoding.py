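"""Encode categorical survey responses as class-labelled transactions.

Each (question, option) pair becomes a distinct integer item, so that a
participant's record is a set of disjoint coded items: at most one item per
question.  The binary outcome — adherent vs. non-adherent to colorectal
cancer screening (CRCS) guidelines — is either supplied directly or derived
from self-reported screening history (FOBT within 1 year, sigmoidoscopy
within 5 years, or colonoscopy within 10 years).

Item codes follow the scheme ``question_id * 1000 + option_index`` with
option indices starting at 1, e.g. question 130 option 1 -> 130001.  The
scheme keeps codes globally unique and decodable without the codebook.
"""

from __future__ import annotations

import csv
import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "ADHERENT",
    "NON_ADHERENT",
    "CodebookError",
    "EncodingError",
    "Question",
    "SurveyCodebook",
    "ScreeningIntervals",
    "ScreeningHistory",
    "Record",
    "TransactionDataset",
    "build_codebook",
    "classify_adherence",
    "derive_screening_history",
    "encode_responses",
    "item_question",
    "item_option_index",
]

ADHERENT = "adherent"
NON_ADHERENT = "non-adherent"

_CODE_BASE = 1000


class CodebookError(ValueError):
    """Invalid codebook schema (duplicate ids, code-space overflow, ...)."""


class EncodingError(ValueError):
    """A survey response could not be mapped to a codebook item."""


def item_question(code: int) -> int:
    """Question id encoded in an item code."""
    return code // _CODE_BASE


def item_option_index(code: int) -> int:
    """1-based option index encoded in an item code."""
    return code % _CODE_BASE


@dataclass(frozen=True)
class Question:
    qid: int
    text: str
    options: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.qid <= 0:
            raise CodebookError(f"question_id must be positive, got {self.qid}")
        if not self.options:
            raise CodebookError(f"question {self.qid} has no options")
        if len(self.options) >= _CODE_BASE:
            raise CodebookError(
                f"question {self.qid} has {len(self.options)} options; "
                f"the code space allows at most {_CODE_BASE - 1}"
            )
        if len(set(self.options)) != len(self.options):
            raise CodebookError(f"question {self.qid} has duplicate option labels")


@dataclass
class SurveyCodebook:
    """Ordered question -> option -> item-code mapping.

    ``code(qid, label)`` and ``decode(code)`` are exact inverses for every
    option of every question.
    """

    questions: list[Question]
    _by_qid: dict[int, Question] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        by_qid: dict[int, Question] = {}
        for q in self.questions:
            if q.qid in by_qid:
                raise CodebookError(f"duplicate question_id {q.qid}")
            by_qid[q.qid] = q
        self._by_qid = by_qid

    @property
    def n_questions(self) -> int:
        return len(self.questions)

    @property
    def n_items(self) -> int:
        return sum(len(q.options) for q in self.questions)

    def question(self, qid: int) -> Question:
        try:
            return self._by_qid[qid]
        except KeyError:
            raise CodebookError(f"unknown question_id {qid}") from None

    def code(self, qid: int, option_label: str) -> int:
        q = self.question(qid)
        try:
            k = q.options.index(option_label) + 1
        except ValueError:
            raise EncodingError(
                f"question {qid}: option {option_label!r} not in codebook"
            ) from None
        return qid * _CODE_BASE + k

    def code_by_index(self, qid: int, option_index: int) -> int:
        q = self.question(qid)
        if not 1 <= option_index <= len(q.options):
            raise CodebookError(
                f"question {qid}: option index {option_index} out of range"
            )
        return qid * _CODE_BASE + option_index

    def decode(self, code: int) -> tuple[int, str]:
        """Return (question_id, option_label) for an item code."""
        qid, k = item_question(code), item_option_index(code)
        q = self.question(qid)
        if not 1 <= k <= len(q.options):
            raise CodebookError(f"code {code}: option index {k} out of range")
        return qid, q.options[k - 1]

    def describe(self, code: int) -> str:
        qid, label = self.decode(code)
        return f"{code}: {self.question(qid).text} [{label}]"

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["question_id", "option_index", "option_label", "question_text"])
            for q in self.questions:
                for k, label in enumerate(q.options, start=1):
                    w.writerow([q.qid, k, label, q.text])

    @classmethod
    def from_csv(cls, path) -> "SurveyCodebook":
        rows = pd.read_csv(path, dtype={"question_id": int, "option_index": int})
        questions: list[Question] = []
        for qid, grp in rows.groupby("question_id", sort=True):
            grp = grp.sort_values("option_index")
            if list(grp["option_index"]) != list(range(1, len(grp) + 1)):
                raise CodebookError(f"question {qid}: option indices not 1..k")
            text = str(grp["question_text"].iloc[0]) if "question_text" in grp else ""
            questions.append(
                Question(int(qid), text, tuple(str(x) for x in grp["option_label"]))
            )
        return cls(questions)


def build_codebook(
    schema: Sequence[tuple[int, str]] | Sequence[int],
    option_labels: Mapping[int, Sequence[str]] | Sequence[str],
) -> SurveyCodebook:
    """Build a codebook from a raw-table schema.

    Parameters
    ----------
    schema
        Question ids, optionally with question text: ``[(qid, text), ...]``
        or plain ``[qid, ...]``.
    option_labels
        Either one shared option-label sequence for all questions, or a
        mapping ``{qid: labels}``.
    """
    questions = []
    for entry in schema:
        if isinstance(entry, tuple):
            qid, text = entry
        else:
            qid, text = entry, f"Question {entry}"
        if isinstance(option_labels, Mapping):
            labels = option_labels[qid]
        else:
            labels = option_labels
        questions.append(Question(int(qid), str(text), tuple(labels)))
    return SurveyCodebook(questions)


# ---------------------------------------------------------------------------
# Adherence outcome
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScreeningIntervals:
    """Guideline look-back windows in years for each screening test."""

    fobt_years: float = 1.0
    sig_years: float = 5.0
    col_years: float = 10.0


@dataclass(frozen=True)
class ScreeningHistory:
    """Within-guideline-interval flags; false when a test was never taken."""

    fobt_within_1y: bool
    sig_within_5y: bool
    col_within_10y: bool


def classify_adherence(h: ScreeningHistory) -> str:
    """Binary CRCS adherence from screening history.

    Adherent when any guideline criterion is met: FOBT within the last year,
    sigmoidoscopy within the last five years (with or without FOBT), or
    colonoscopy within the guideline window.  All-false -> non-adherent.
    """
    if h.fobt_within_1y or h.sig_within_5y or h.col_within_10y:
        return ADHERENT
    return NON_ADHERENT


def _within(ever, years_since, window: float) -> tuple[bool, bool]:
    """(flag, imputed): unknown fields resolve to False and are flagged."""
    if ever is None or (isinstance(ever, float) and math.isnan(ever)):
        return False, True
    if not ever:
        return False, False
    if years_since is None or (
        isinstance(years_since, float) and math.isnan(years_since)
    ):
        return False, True
    return float(years_since) <= window, False


def derive_screening_history(
    *,
    ever_fobt,
    years_since_fobt,
    ever_sig,
    years_since_sig,
    ever_col,
    years_since_col,
    intervals: ScreeningIntervals = ScreeningIntervals(),
) -> tuple[ScreeningHistory, list[str]]:
    """Resolve raw test-ever / years-since fields into interval flags.

    Unknown (None/NaN) fields cannot demonstrate adherence and resolve to
    False; the returned list names the fields that were imputed this way.
    """
    fobt, i1 = _within(ever_fobt, years_since_fobt, intervals.fobt_years)
    sig, i2 = _within(ever_sig, years_since_sig, intervals.sig_years)
    col, i3 = _within(ever_col, years_since_col, intervals.col_years)
    imputed = [
        name
        for name, flag in (("fobt", i1), ("sig", i2), ("col", i3))
        if flag
    ]
    return ScreeningHistory(fobt, sig, col), imputed


# ---------------------------------------------------------------------------
# Transactions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Record:
    participant_id: str
    items: frozenset[int]
    class_label: str

    def __post_init__(self) -> None:
        qids = [item_question(c) for c in self.items]
        if len(qids) != len(set(qids)):
            raise EncodingError(
                f"record {self.participant_id}: two items share a question"
            )
        if self.class_label not in (ADHERENT, NON_ADHERENT):
            raise EncodingError(
                f"record {self.participant_id}: bad class {self.class_label!r}"
            )


@dataclass
class TransactionDataset:
    records: list[Record]

    @property
    def n1(self) -> int:
        return sum(1 for r in self.records if r.class_label == ADHERENT)

    @property
    def n2(self) -> int:
        return sum(1 for r in self.records if r.class_label == NON_ADHERENT)

    def __len__(self) -> int:
        return len(self.records)

    def class_items(self, class_label: str) -> list[frozenset[int]]:
        return [r.items for r in self.records if r.class_label == class_label]

    def item_universe(self) -> set[int]:
        out: set[int] = set()
        for r in self.records:
            out |= r.items
        return out

    def to_jsonl(self, path) -> None:
        with open(path, "w") as fh:
            for r in self.records:
                fh.write(
                    json.dumps(
                        {
                            "participant_id": r.participant_id,
                            "class": r.class_label,
                            "items": sorted(r.items),
                        }
                    )
                    + "\n"
                )

    @classmethod
    def from_jsonl(cls, path) -> "TransactionDataset":
        records = []
        with open(path) as fh:
            for line in fh:
                if not line.strip():
                    continue
                obj = json.loads(line)
                records.append(
                    Record(
                        str(obj["participant_id"]),
                        frozenset(int(i) for i in obj["items"]),
                        obj["class"],
                    )
                )
        return cls(records)


_OUTCOME_MAP = {
    "1": ADHERENT,
    "0": NON_ADHERENT,
    "1.0": ADHERENT,
    "0.0": NON_ADHERENT,
    ADHERENT: ADHERENT,
    NON_ADHERENT: NON_ADHERENT,
}


def _normalize_outcome(value) -> str | None:
    if value is None:
        return None
    if isinstance(value, float) and math.isnan(value):
        return None
    s = str(value).strip()
    if not s:
        return None
    try:
        return _OUTCOME_MAP[s.lower()]
    except KeyError:
        raise EncodingError(f"unrecognized outcome value {value!r}") from None


def _question_column(qid: int, columns) -> str | None:
    for name in (f"Q{qid}", str(qid)):
        if name in columns:
            return name
    return None


def encode_responses(
    raw_table: pd.DataFrame,
    codebook: SurveyCodebook,
    outcome: str | pd.Series = "adherence",
    id_column: str | None = None,
) -> TransactionDataset:
    """Turn a raw survey table into class-labelled transactions.

    One record per participant with a non-missing outcome; rows whose outcome
    is blank are excluded.  Each answered question contributes exactly its
    chosen item; blank answers contribute nothing.  An answer absent from the
    codebook raises :class:`EncodingError` naming the row and column.

    ``outcome`` is either the name of a column holding 1/0 or
    adherent/non-adherent labels, or a precomputed Series aligned with the
    table (e.g. from :func:`classify_adherence` over screening history).
    """
    if isinstance(outcome, str):
        if outcome not in raw_table.columns:
            raise EncodingError(f"outcome column {outcome!r} not in table")
        outcome_values = raw_table[outcome]
    else:
        outcome_values = outcome.reindex(raw_table.index)

    col_of: dict[int, str] = {}
    for q in codebook.questions:
        name = _question_column(q.qid, raw_table.columns)
        if name is not None:
            col_of[q.qid] = name

    records: list[Record] = []
    for pos, (idx, row) in enumerate(raw_table.iterrows()):
        label = _normalize_outcome(outcome_values.loc[idx])
        if label is None:
            continue
        pid = str(row[id_column]) if id_column else str(idx)
        items = set()
        for qid, col in col_of.items():
            val = row[col]
            if val is None or (isinstance(val, float) and math.isnan(val)):
                continue
            s = str(val).strip()
            if not s:
                continue
            try:
                items.add(codebook.code(qid, s))
            except EncodingError:
                raise EncodingError(
                    f"row {pos} ({pid!r}), column {col!r}: "
                    f"response {s!r} not in codebook for question {qid}"
                ) from None
        records.append(Record(pid, frozenset(items), label))
    return TransactionDataset(records)
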