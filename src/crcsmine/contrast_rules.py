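"""Class-discriminating itemsets from per-class frequent-itemset tables.

Three contrast extractions operate on the adherent (C1) and non-adherent
(C2) tables:

* **strong class itemsets** — itemsets with support >= 0.8 in the target
  class that stay strictly below 0.6 support in the other class, reported
  after maximal filtering;
* **M1** — itemsets frequent in *both* classes whose supports differ by at
  least 20 percentage points (absolute);
* **M2** — itemsets frequent in exactly one class whose proper subsets are
  frequent in both: the shared subset plus the class-unique extension is
  the reported pair.  Only maximal shared subsets are reported by default
  (every sub-subset of a qualifying subset qualifies too, which would flood
  the output); pass ``maximal_shared_only=False`` for the full list.

Rule confidence — of all records containing the itemset, the fraction
belonging to the class — is attached to every strong rule; no confidence
cutoff is applied.

All threshold comparisons are exact rational comparisons on containment
counts, matching the mining module.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from fractions import Fraction
from typing import Iterable

import pandas as pd

from .itemset_mining import (
    FrequentItemsetTable,
    Itemset,
    UndefinedSupportError,
    below_threshold,
    meets_threshold,
    min_count,
)
from .survey_encoding import ADHERENT, NON_ADHERENT, SurveyCodebook, TransactionDataset

__all__ = [
    "ClassRule",
    "M1Entry",
    "M2Entry",
    "ContrastReport",
    "UndefinedConfidenceError",
    "ContrastParameterError",
    "rule_confidence",
    "strong_class_itemsets",
    "m1_contrast",
    "m2_contrast",
    "build_contrast_report",
]


class UndefinedConfidenceError(ValueError):
    """Confidence requested for an itemset contained in no record."""


class ContrastParameterError(ValueError):
    """Inconsistent contrast thresholds or mismatched input tables."""


@dataclass(frozen=True)
class ClassRule:
    items: Itemset
    class_label: str
    support_in_class: float
    support_in_other: float
    confidence: float


@dataclass(frozen=True)
class M1Entry:
    items: Itemset
    support_c1: float
    support_c2: float
    abs_difference: float


@dataclass(frozen=True)
class M2Entry:
    shared_subset: Itemset
    extension: Itemset
    class_label: str
    subset_support_c1: float
    subset_support_c2: float
    superset_support_c1: float
    superset_support_c2: float


def rule_confidence(
    s: Itemset | Iterable[int], d: TransactionDataset, class_label: str
) -> float:
    """Fraction of all records containing ``s`` that belong to the class."""
    items = frozenset(s)
    in_class = 0
    total = 0
    for r in d.records:
        if items <= r.items:
            total += 1
            if r.class_label == class_label:
                in_class += 1
    if total == 0:
        raise UndefinedConfidenceError(
            f"itemset {sorted(items)} is contained in no record"
        )
    return in_class / total


def _check_pair(table_c1: FrequentItemsetTable, table_c2: FrequentItemsetTable) -> None:
    if table_c1.class_label != ADHERENT or table_c2.class_label != NON_ADHERENT:
        raise ContrastParameterError(
            "expected (adherent, non-adherent) tables, got "
            f"({table_c1.class_label!r}, {table_c2.class_label!r})"
        )


def _maximal(items_list: list[Itemset]) -> list[Itemset]:
    sets = [frozenset(s) for s in items_list]
    return [
        s
        for s, fs in zip(items_list, sets)
        if not any(fs < other for other in sets)
    ]


def strong_class_itemsets(
    table_c1: FrequentItemsetTable,
    table_c2: FrequentItemsetTable,
    d: TransactionDataset,
    high: float = 0.8,
    low: float = 0.6,
) -> tuple[list[ClassRule], list[ClassRule]]:
    """Itemsets strongly characteristic of one class.

    For each class: itemsets with support >= ``high`` there and support
    strictly below ``low`` in the other class, maximal-filtered, each with
    its rule confidence.  Both tables must have been mined at a threshold
    <= ``low`` so the sub-``low`` condition is decidable from them.
    """
    _check_pair(table_c1, table_c2)
    if Fraction(high).limit_denominator(10**6) < Fraction(low).limit_denominator(10**6):
        raise ContrastParameterError(f"high ({high}) must be >= low ({low})")
    for t in (table_c1, table_c2):
        if Fraction(t.min_support).limit_denominator(10**6) > Fraction(
            low
        ).limit_denominator(10**6):
            raise ContrastParameterError(
                f"table for {t.class_label!r} mined at {t.min_support} > low={low}"
            )

    out: list[list[ClassRule]] = []
    for own, other in ((table_c1, table_c2), (table_c2, table_c1)):
        n_other = other.n_records
        qualifying: list[tuple[Itemset, int, int]] = []
        for e in own.entries:
            if not meets_threshold(e.count, own.n_records, high):
                continue
            other_count = other.count_of(e.items)
            if other_count is None:
                # absent from the other table mined at <= low: support < low
                other_count = sum(
                    1
                    for r in d.class_items(other.class_label)
                    if frozenset(e.items) <= r
                )
            if not below_threshold(other_count, n_other, low):
                continue
            qualifying.append((e.items, e.count, other_count))
        keep = set(_maximal([q[0] for q in qualifying]))
        rules = [
            ClassRule(
                items=s,
                class_label=own.class_label,
                support_in_class=c / own.n_records,
                support_in_other=oc / n_other,
                confidence=rule_confidence(s, d, own.class_label),
            )
            for s, c, oc in qualifying
            if s in keep
        ]
        rules.sort(key=lambda r: (-r.support_in_class, r.items))
        out.append(rules)
    return out[0], out[1]


def _diff_at_least(c1: int, n1: int, c2: int, n2: int, min_diff) -> bool:
    """Exact |c1/n1 - c2/n2| >= min_diff."""
    f = Fraction(min_diff).limit_denominator(10**6)
    return abs(c1 * n2 - c2 * n1) * f.denominator >= f.numerator * n1 * n2


def m1_contrast(
    table_c1: FrequentItemsetTable,
    table_c2: FrequentItemsetTable,
    min_diff: float = 0.20,
) -> list[M1Entry]:
    """Itemsets frequent in both classes with a large support gap.

    The gap is absolute (percentage points): |support_C1 - support_C2| >=
    ``min_diff``.  Sorted by descending gap, ties by item codes.
    """
    _check_pair(table_c1, table_c2)
    if table_c1.min_support != table_c2.min_support:
        raise ContrastParameterError(
            "M1 requires both tables mined at the same threshold"
        )
    n1, n2 = table_c1.n_records, table_c2.n_records
    counts_c2 = {e.items: e.count for e in table_c2.entries}
    out = []
    for e in table_c1.entries:
        c2 = counts_c2.get(e.items)
        if c2 is None:
            continue
        if _diff_at_least(e.count, n1, c2, n2, min_diff):
            out.append(
                M1Entry(
                    items=e.items,
                    support_c1=e.count / n1,
                    support_c2=c2 / n2,
                    abs_difference=abs(e.count / n1 - c2 / n2),
                )
            )
    out.sort(key=lambda m: (-m.abs_difference, m.items))
    return out


def m2_contrast(
    table_c1: FrequentItemsetTable,
    table_c2: FrequentItemsetTable,
    d: TransactionDataset | None = None,
    maximal_shared_only: bool = True,
) -> list[M2Entry]:
    """Shared-subset / class-unique-extension pairs.

    For each itemset S frequent in exactly one class and each nonempty
    proper subset B of S frequent in *both* classes, emit
    ``(shared_subset=B, extension=S\\B, class of S)``.  With
    ``maximal_shared_only`` (default) only subsets B maximal among the
    qualifying subsets of S are reported.  Out-of-table supports (the
    superset in the class where it is infrequent) are computed from ``d``
    when provided, else reported as NaN.
    """
    _check_pair(table_c1, table_c2)
    if table_c1.min_support != table_c2.min_support:
        raise ContrastParameterError(
            "M2 requires both tables mined at the same threshold"
        )
    sets_c1 = {e.items: e.count for e in table_c1.entries}
    sets_c2 = {e.items: e.count for e in table_c2.entries}
    shared = set(sets_c1) & set(sets_c2)
    n1, n2 = table_c1.n_records, table_c2.n_records

    def other_support(items: Itemset, class_label: str) -> float:
        if d is None:
            return float("nan")
        recs = d.class_items(class_label)
        return sum(1 for r in recs if frozenset(items) <= r) / len(recs)

    out: list[M2Entry] = []
    for own, own_counts, own_n, other_label in (
        (table_c1, sets_c1, n1, NON_ADHERENT),
        (table_c2, sets_c2, n2, ADHERENT),
    ):
        unique = [s for s in own_counts if s not in shared]
        for s in unique:
            fs = frozenset(s)
            subsets = [b for b in shared if frozenset(b) < fs]
            if maximal_shared_only:
                subsets = _maximal(subsets)
            for b in subsets:
                ext = tuple(sorted(fs - frozenset(b)))
                sup_sup_own = own_counts[s] / own_n
                if own.class_label == ADHERENT:
                    entry = M2Entry(
                        shared_subset=b,
                        extension=ext,
                        class_label=ADHERENT,
                        subset_support_c1=sets_c1[b] / n1,
                        subset_support_c2=sets_c2[b] / n2,
                        superset_support_c1=sup_sup_own,
                        superset_support_c2=other_support(s, NON_ADHERENT),
                    )
                else:
                    entry = M2Entry(
                        shared_subset=b,
                        extension=ext,
                        class_label=NON_ADHERENT,
                        subset_support_c1=sets_c1[b] / n1,
                        subset_support_c2=sets_c2[b] / n2,
                        superset_support_c1=other_support(s, ADHERENT),
                        superset_support_c2=sup_sup_own,
                    )
                out.append(entry)
    out.sort(
        key=lambda m: (
            m.class_label,
            -(m.superset_support_c1 if m.class_label == ADHERENT else m.superset_support_c2),
            m.shared_subset,
            m.extension,
        )
    )
    return out


@dataclass
class ContrastReport:
    strong_c1: list[ClassRule]
    strong_c2: list[ClassRule]
    m1: list[M1Entry]
    m2: list[M2Entry]

    def to_json(self, path) -> None:
        obj = {
            "strong_c1": [asdict(r) for r in self.strong_c1],
            "strong_c2": [asdict(r) for r in self.strong_c2],
            "m1": [asdict(m) for m in self.m1],
            "m2": [asdict(m) for m in self.m2],
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1, default=list)

    def to_tsv(self, path, codebook: SurveyCodebook | None = None) -> None:
        def describe(items: Itemset) -> str:
            if codebook is None:
                return " ".join(str(i) for i in items)
            return " | ".join(codebook.describe(i) for i in items)

        rows = []
        for r in self.strong_c1 + self.strong_c2:
            rows.append(
                {
                    "section": f"strong_{'c1' if r.class_label == ADHERENT else 'c2'}",
                    "class": r.class_label,
                    "itemset": describe(r.items),
                    "extension": "",
                    "support_c1": r.support_in_class
                    if r.class_label == ADHERENT
                    else r.support_in_other,
                    "support_c2": r.support_in_other
                    if r.class_label == ADHERENT
                    else r.support_in_class,
                    "confidence": r.confidence,
                }
            )
        for m in self.m1:
            rows.append(
                {
                    "section": "m1",
                    "class": "",
                    "itemset": describe(m.items),
                    "extension": "",
                    "support_c1": m.support_c1,
                    "support_c2": m.support_c2,
                    "confidence": "",
                }
            )
        for m in self.m2:
            rows.append(
                {
                    "section": "m2",
                    "class": m.class_label,
                    "itemset": describe(m.shared_subset),
                    "extension": describe(m.extension),
                    "support_c1": m.superset_support_c1,
                    "support_c2": m.superset_support_c2,
                    "confidence": "",
                }
            )
        pd.DataFrame(
            rows,
            columns=[
                "section",
                "class",
                "itemset",
                "extension",
                "support_c1",
                "support_c2",
                "confidence",
            ],
        ).to_csv(path, sep="\t", index=False)


def build_contrast_report(
    table_c1: FrequentItemsetTable,
    table_c2: FrequentItemsetTable,
    d: TransactionDataset,
    high: float = 0.8,
    low: float = 0.6,
    min_diff: float = 0.20,
    maximal_shared_only: bool = True,
) -> ContrastReport:
    strong_c1, strong_c2 = strong_class_itemsets(table_c1, table_c2, d, high, low)
    return ContrastReport(
        strong_c1=strong_c1,
        strong_c2=strong_c2,
        m1=m1_contrast(table_c1, table_c2, min_diff),
        m2=m2_contrast(table_c1, table_c2, d, maximal_shared_only),
    )
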