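"""Shared test utilities: toy dataset builders and definition-level oracles.

The oracles here recompute contrast extractions straight from their
definitions (exhaustive enumeration + exact rational arithmetic) and are
deliberately independent of the package's level-wise miner and contrast
code paths.
"""

from __future__ import annotations

import itertools
from fractions import Fraction

import numpy as np

from crcsmine import ADHERENT, NON_ADHERENT, Record, TransactionDataset


def make_dataset(c1_items, c2_items) -> TransactionDataset:
    """Build a dataset from two lists of item-code iterables."""
    records = []
    for i, items in enumerate(c1_items):
        records.append(Record(f"a{i}", frozenset(items), ADHERENT))
    for i, items in enumerate(c2_items):
        records.append(Record(f"n{i}", frozenset(items), NON_ADHERENT))
    return TransactionDataset(records)


def random_dataset(
    rng: np.random.Generator,
    max_items: int = 12,
    max_records_per_class: int = 50,
) -> TransactionDataset:
    """Random small transaction dataset with a bounded item universe.

    Questions get 1-3 options; per record each question is answered with
    probability 0.85, options drawn with a skewed distribution so some
    itemsets clear high support thresholds.
    """
    questions = []
    total = 0
    while True:
        k = int(rng.integers(1, 4))
        if total + k > max_items:
            break
        questions.append(k)
        total += k
        if len(questions) >= 5:
            break
    if not questions:
        questions = [1]

    def sample_record(q_offset=0):
        items = set()
        for qi, k in enumerate(questions, start=1):
            if rng.random() < 0.85:
                # skew toward option 1
                probs = np.array([2.0**-(j) for j in range(k)])
                probs /= probs.sum()
                opt = int(rng.choice(np.arange(1, k + 1), p=probs))
                items.add(qi * 1000 + opt)
        return frozenset(items)

    n1 = int(rng.integers(3, max_records_per_class + 1))
    n2 = int(rng.integers(3, max_records_per_class + 1))
    return make_dataset(
        [sample_record() for _ in range(n1)],
        [sample_record() for _ in range(n2)],
    )


# ---------------------------------------------------------------------------
# Definition-level oracles
# ---------------------------------------------------------------------------

def _recs(ds: TransactionDataset, label: str):
    return [r.items for r in ds.records if r.class_label == label]


def _count(items, recs) -> int:
    s = frozenset(items)
    return sum(1 for r in recs if s <= r)


def _frac(x) -> Fraction:
    return Fraction(x).limit_denominator(10**6)


def all_disjoint_itemsets(universe):
    """Every nonempty question-disjoint itemset over the item universe."""
    universe = sorted(universe)
    out = []
    for k in range(1, len(universe) + 1):
        for combo in itertools.combinations(universe, k):
            qs = [c // 1000 for c in combo]
            if len(qs) == len(set(qs)):
                out.append(combo)
    return out


def frequent_oracle(ds: TransactionDataset, label: str, min_support):
    """{itemset: count} of all frequent question-disjoint itemsets."""
    recs = _recs(ds, label)
    n = len(recs)
    f = _frac(min_support)
    universe = set().union(*recs) if recs else set()
    out = {}
    for s in all_disjoint_itemsets(universe):
        c = _count(s, recs)
        if Fraction(c, n) >= f:
            out[s] = c
    return out


def maximal_oracle(itemsets):
    """Filter-by-definition: pairwise subset scan."""
    sets = [frozenset(s) for s in itemsets]
    return [
        s for s, fs in zip(itemsets, sets) if not any(fs < other for other in sets)
    ]


def strong_oracle(ds: TransactionDataset, high=0.8, low=0.6):
    recs1, recs2 = _recs(ds, ADHERENT), _recs(ds, NON_ADHERENT)
    n1, n2 = len(recs1), len(recs2)
    hi, lo = _frac(high), _frac(low)
    universe = set().union(*(recs1 + recs2)) if (recs1 or recs2) else set()
    out1, out2 = [], []
    for s in all_disjoint_itemsets(universe):
        s1 = Fraction(_count(s, recs1), n1)
        s2 = Fraction(_count(s, recs2), n2)
        if s1 >= hi and s2 < lo:
            out1.append(s)
        if s2 >= hi and s1 < lo:
            out2.append(s)
    return sorted(maximal_oracle(out1)), sorted(maximal_oracle(out2))


def m1_oracle(ds: TransactionDataset, min_support=0.6, min_diff=0.20):
    recs1, recs2 = _recs(ds, ADHERENT), _recs(ds, NON_ADHERENT)
    n1, n2 = len(recs1), len(recs2)
    ms, md = _frac(min_support), _frac(min_diff)
    universe = set().union(*(recs1 + recs2)) if (recs1 or recs2) else set()
    out = []
    for s in all_disjoint_itemsets(universe):
        s1 = Fraction(_count(s, recs1), n1)
        s2 = Fraction(_count(s, recs2), n2)
        if s1 >= ms and s2 >= ms and abs(s1 - s2) >= md:
            out.append(s)
    return sorted(out)


def m2_oracle(ds: TransactionDataset, min_support=0.6, maximal_shared_only=True):
    """(shared_subset, extension, class_label) triples by direct definition."""
    f1 = frequent_oracle(ds, ADHERENT, min_support)
    f2 = frequent_oracle(ds, NON_ADHERENT, min_support)
    shared = set(f1) & set(f2)
    out = []
    for own, label in ((f1, ADHERENT), (f2, NON_ADHERENT)):
        for s in own:
            if s in shared:
                continue
            fs = frozenset(s)
            subsets = [b for b in shared if frozenset(b) < fs]
            if maximal_shared_only:
                subsets = maximal_oracle(subsets)
            for b in subsets:
                ext = tuple(sorted(fs - frozenset(b)))
                out.append((tuple(b), ext, label))
    return sorted(out)
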