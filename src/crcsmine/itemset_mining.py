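"""Per-class frequent itemset mining (Apriori) over survey transactions.

Support of an itemset within a class is the fraction of that class's records
containing every item of the set.  Mining is class-conditional: each
adherence class is mined separately at the same threshold, following the
contrast-mining design where class-specific itemset tables are compared
afterwards.

Frequency is decided by exact integer comparison (count >= ceil(s * n) with
the threshold held as a rational number), so thresholds such as 0.6 on a
411-record class never suffer a floating-point boundary misclassification.

``brute_force_frequent`` enumerates every question-disjoint itemset directly
and exists as an independent oracle for testing the level-wise miner; it is
guarded to small item universes.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, replace
from fractions import Fraction
from typing import Iterable, Sequence

import pandas as pd

from .survey_encoding import (
    ADHERENT,
    NON_ADHERENT,
    SurveyCodebook,
    TransactionDataset,
    item_question,
)

__all__ = [
    "Itemset",
    "ItemsetEntry",
    "FrequentItemsetTable",
    "UndefinedSupportError",
    "ItemUniverseError",
    "support",
    "apriori",
    "maximal_filter",
    "brute_force_frequent",
    "support_sweep",
    "min_count",
    "meets_threshold",
    "below_threshold",
]

Itemset = tuple[int, ...]

BRUTE_FORCE_MAX_ITEMS = 16


class UndefinedSupportError(ValueError):
    """Support requested for an empty class."""


class ItemUniverseError(ValueError):
    """Brute-force oracle invoked beyond its item-universe guard."""


def _as_fraction(x) -> Fraction:
    if isinstance(x, Fraction):
        return x
    # floats arriving as 0.6, 0.2 etc. recover their short rational form
    return Fraction(x).limit_denominator(10**6)


def min_count(min_support, n: int) -> int:
    """Smallest containment count satisfying support >= min_support, exactly."""
    f = _as_fraction(min_support)
    return -((-f.numerator * n) // f.denominator)


def meets_threshold(count: int, n: int, threshold) -> bool:
    f = _as_fraction(threshold)
    return count * f.denominator >= f.numerator * n


def below_threshold(count: int, n: int, threshold) -> bool:
    """Strict support < threshold, exact."""
    f = _as_fraction(threshold)
    return count * f.denominator < f.numerator * n


def is_question_disjoint(items: Iterable[int]) -> bool:
    qids = [item_question(i) for i in items]
    return len(qids) == len(set(qids))


def _class_items(d: TransactionDataset, class_label: str) -> list[frozenset[int]]:
    recs = d.class_items(class_label)
    if not recs:
        raise UndefinedSupportError(f"class {class_label!r} has no records")
    return recs


def _count(items: Itemset, recs: Sequence[frozenset[int]]) -> int:
    s = frozenset(items)
    return sum(1 for r in recs if s <= r)


def support(s: Itemset | Iterable[int], d: TransactionDataset, class_label: str) -> float:
    """Fraction of class records containing every item of ``s`` (1.0 for the
    empty set)."""
    recs = _class_items(d, class_label)
    return _count(tuple(s), recs) / len(recs)


@dataclass(frozen=True)
class ItemsetEntry:
    items: Itemset  # sorted ascending
    support: float
    count: int
    is_maximal: bool | None = None


@dataclass
class FrequentItemsetTable:
    class_label: str
    min_support: float
    n_records: int
    entries: list[ItemsetEntry]

    def itemsets(self) -> set[Itemset]:
        return {e.items for e in self.entries}

    def entry(self, items: Itemset) -> ItemsetEntry | None:
        for e in self.entries:
            if e.items == items:
                return e
        return None

    def count_of(self, items: Itemset) -> int | None:
        e = self.entry(items)
        return None if e is None else e.count

    def sorted(self) -> "FrequentItemsetTable":
        """Deterministic order: by size, then lexicographic item codes."""
        entries = sorted(self.entries, key=lambda e: (len(e.items), e.items))
        return replace(self, entries=entries)

    def to_frame(self, codebook: SurveyCodebook | None = None) -> pd.DataFrame:
        rows = []
        for e in self.entries:
            row = {
                "class": self.class_label,
                "items": " ".join(str(i) for i in e.items),
                "size": len(e.items),
                "support": e.support,
                "count": e.count,
                "is_maximal": e.is_maximal,
            }
            if codebook is not None:
                row["decoded"] = " | ".join(codebook.describe(i) for i in e.items)
            rows.append(row)
        return pd.DataFrame(
            rows,
            columns=["class", "items", "size", "support", "count", "is_maximal"]
            + (["decoded"] if codebook is not None else []),
        )

    def to_tsv(self, path, codebook: SurveyCodebook | None = None) -> None:
        self.to_frame(codebook).to_csv(path, sep="\t", index=False)

    def to_json(self, path) -> None:
        obj = {
            "class": self.class_label,
            "min_support": self.min_support,
            "n_records": self.n_records,
            "itemsets": [
                {
                    "items": list(e.items),
                    "support": e.support,
                    "count": e.count,
                    "is_maximal": e.is_maximal,
                }
                for e in self.entries
            ],
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1)


def _join_level(level: list[Itemset], frequent: set[Itemset]) -> list[Itemset]:
    """Classic (k-1)-prefix join with subset pruning and question-disjointness
    enforced at join time."""
    out = []
    by_prefix: dict[Itemset, list[Itemset]] = {}
    for s in level:
        by_prefix.setdefault(s[:-1], []).append(s)
    for prefix, group in by_prefix.items():
        group.sort()
        for a, b in itertools.combinations(group, 2):
            cand = a + (b[-1],)
            if item_question(a[-1]) == item_question(b[-1]):
                continue  # two options of one question never co-occur
            # prune: every (k-1)-subset must itself be frequent
            if all(
                cand[:i] + cand[i + 1 :] in frequent for i in range(len(cand) - 2)
            ):
                out.append(cand)
    return sorted(out)


def apriori(
    d: TransactionDataset, class_label: str, min_support: float
) -> FrequentItemsetTable:
    """Level-wise frequent itemset extraction within one adherence class.

    Returns exactly the non-empty itemsets with support >= ``min_support``
    in the class, ordered by size then lexicographically by item code.
    """
    if not 0 < _as_fraction(min_support) <= 1:
        raise ValueError(f"min_support must be in (0, 1], got {min_support}")
    recs = _class_items(d, class_label)
    n = len(recs)
    minc = min_count(min_support, n)

    counts: dict[int, int] = {}
    for r in recs:
        for i in r:
            counts[i] = counts.get(i, 0) + 1
    level: list[Itemset] = sorted((i,) for i, c in counts.items() if c >= minc)
    table: dict[Itemset, int] = {s: counts[s[0]] for s in level}

    frequent = set(level)
    while level:
        candidates = _join_level(level, frequent)
        next_level = []
        for cand in candidates:
            c = _count(cand, recs)
            if c >= minc:
                table[cand] = c
                next_level.append(cand)
        frequent |= set(next_level)
        level = next_level

    entries = [
        ItemsetEntry(items=s, support=c / n, count=c)
        for s, c in sorted(table.items(), key=lambda kv: (len(kv[0]), kv[0]))
    ]
    return FrequentItemsetTable(class_label, float(min_support), n, entries)


def maximal_filter(t: FrequentItemsetTable) -> FrequentItemsetTable:
    """Keep only itemsets with no proper frequent superset in the table."""
    sets = [frozenset(e.items) for e in t.entries]
    kept = []
    for i, e in enumerate(t.entries):
        si = sets[i]
        if any(si < sj for sj in sets):
            continue
        kept.append(replace(e, is_maximal=True))
    return replace(t, entries=kept)


def brute_force_frequent(
    d: TransactionDataset,
    class_label: str,
    min_support: float,
    max_items: int = BRUTE_FORCE_MAX_ITEMS,
) -> FrequentItemsetTable:
    """Exhaustive frequent-itemset oracle (guarded to small item universes).

    Enumerates every question-disjoint combination of items appearing in the
    class and keeps those with support >= ``min_support``.  Independent of
    :func:`apriori` by construction; used to validate it in tests.
    """
    recs = _class_items(d, class_label)
    n = len(recs)
    universe = sorted(set().union(*recs)) if recs else []
    if len(universe) > max_items:
        raise ItemUniverseError(
            f"{len(universe)} distinct items exceeds the brute-force guard "
            f"({max_items})"
        )
    minc = min_count(min_support, n)
    entries = []
    for k in range(1, len(universe) + 1):
        for combo in itertools.combinations(universe, k):
            if not is_question_disjoint(combo):
                continue
            c = _count(combo, recs)
            if c >= minc:
                entries.append(ItemsetEntry(items=combo, support=c / n, count=c))
    entries.sort(key=lambda e: (len(e.items), e.items))
    return FrequentItemsetTable(class_label, float(min_support), n, entries)


def support_sweep(
    d: TransactionDataset, thresholds: Sequence[float]
) -> pd.DataFrame:
    """Frequent / maximal itemset counts per class at each threshold.

    Mirrors the threshold-selection procedure of running the miner at support
    levels spaced across (0, 1] and inspecting how output volume shrinks as
    the threshold rises.
    """
    for t in thresholds:
        if not 0 < _as_fraction(t) <= 1:
            raise ValueError(f"threshold {t} outside (0, 1]")
    rows = []
    for t in thresholds:
        for label in (ADHERENT, NON_ADHERENT):
            tab = apriori(d, label, t)
            rows.append(
                {
                    "threshold": float(t),
                    "class": label,
                    "n_frequent": len(tab.entries),
                    "n_maximal": len(maximal_filter(tab).entries),
                }
            )
    return pd.DataFrame(rows, columns=["threshold", "class", "n_frequent", "n_maximal"])
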