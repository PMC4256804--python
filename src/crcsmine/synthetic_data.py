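"""Synthetic categorical survey generator with planted, recoverable structure.

Emulates the shape of the telephone-survey dataset the pipeline targets:
144 categorical questions with 5 options each (720 distinct items), an
adherent class of 608 and a non-adherent class of 411 participants (1019
analyzable records), plus a configurable number of rows with a missing
outcome (default 2, for 1021 surveyed).  Answers are drawn independently
per question given class from a per-class option-probability profile.

Two kinds of known structure can be planted:

* **itemset plants** — a question-disjoint set of (question, option) pairs
  forced to co-occur with a target support per class.  Deterministic mode
  overwrites the first ceil(support*n) records of the class (and removes
  the planted option elsewhere), so the realized support is exactly
  ceil(support*n)/n; stochastic mode includes each record by a Bernoulli
  draw.
* **a regression scenario** — binary indicators of chosen (question,
  option) pairs drive a Bernoulli outcome through a logistic model with
  known intercept and coefficients, for estimator-recovery tests.

Everything is reproducible from the single integer ``seed``; the truth
record returned alongside the table lists every plant's realized per-class
support and the regression truth.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .survey_encoding import ADHERENT, NON_ADHERENT, SurveyCodebook, build_codebook

__all__ = [
    "GeneratorSpecError",
    "Plant",
    "RegressionScenario",
    "GeneratorSpec",
    "DEFAULT_PROFILE",
    "default_codebook",
    "generate",
    "generate_regression_outcome",
    "write_outputs",
]

# Background option profile: one mildly dominant answer per question, the
# rest tapering off — a typical telephone-survey marginal.  The maximum
# (0.40) sits well below the 0.6 mining threshold, so without plants no
# background item is frequent.
DEFAULT_PROFILE: tuple[float, ...] = (0.40, 0.25, 0.15, 0.12, 0.08)

_STREAM_TABLE = 0
_STREAM_OUTCOME = 1


class GeneratorSpecError(ValueError):
    """Invalid or conflicting generator specification."""


@dataclass(frozen=True)
class Plant:
    """A question-disjoint itemset forced to given per-class supports."""

    items: tuple[tuple[int, int], ...]  # (question_id, option_index 1-based)
    support_c1: float
    support_c2: float
    mode: str = "deterministic"
    name: str = ""

    def __post_init__(self) -> None:
        qids = [q for q, _ in self.items]
        if len(qids) != len(set(qids)):
            raise GeneratorSpecError(f"plant {self.name!r}: items share a question")
        for s in (self.support_c1, self.support_c2):
            if not 0.0 <= s <= 1.0:
                raise GeneratorSpecError(f"plant {self.name!r}: support {s} outside [0,1]")
        if self.mode not in ("deterministic", "stochastic"):
            raise GeneratorSpecError(f"plant {self.name!r}: unknown mode {self.mode!r}")


@dataclass(frozen=True)
class RegressionScenario:
    """Logistic outcome model over binary (question, option) indicators."""

    predictors: tuple[tuple[int, int], ...]  # (question_id, option_index)
    coefficients: tuple[float, ...]
    intercept: float = 0.0

    def __post_init__(self) -> None:
        if len(self.predictors) != len(self.coefficients):
            raise GeneratorSpecError("one coefficient per predictor required")


@dataclass
class GeneratorSpec:
    n1: int = 608
    n2: int = 411
    n_questions: int = 144
    options_per_question: int = 5
    n_missing_outcome: int = 2
    profile_c1: tuple[float, ...] | None = None
    profile_c2: tuple[float, ...] | None = None
    plants: tuple[Plant, ...] = ()
    regression: RegressionScenario | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n1 < 1 or self.n2 < 1:
            raise GeneratorSpecError("class sizes must be >= 1")
        for label in (ADHERENT, NON_ADHERENT):
            seen: set[int] = set()
            for p in self.plants:
                for q, _ in p.items:
                    if not 1 <= q <= self.n_questions:
                        raise GeneratorSpecError(f"plant question {q} out of range")
                    if q in seen:
                        raise GeneratorSpecError(
                            f"two plants touch question {q} in class {label}"
                        )
                seen.update(q for q, _ in p.items)
        for prof in (self.profile_c1, self.profile_c2):
            if prof is not None:
                if len(prof) != self.options_per_question:
                    raise GeneratorSpecError("profile length != options per question")
                if abs(sum(prof) - 1.0) > 1e-9:
                    raise GeneratorSpecError("profile must sum to 1")

    def profile(self, class_label: str) -> tuple[float, ...]:
        prof = self.profile_c1 if class_label == ADHERENT else self.profile_c2
        if prof is not None:
            return prof
        if self.options_per_question == len(DEFAULT_PROFILE):
            return DEFAULT_PROFILE
        k = self.options_per_question
        return tuple([1.0 / k] * k)


def standard_plants() -> tuple[Plant, ...]:
    """The package's reference planted configuration.

    Four deterministic plants on dedicated questions exercise every contrast
    extraction: a strong-C1 itemset (0.85 vs 0.55 support), an M1 itemset
    frequent in both classes with a 23-point gap (0.85 vs 0.62), and an M2
    configuration — a subset frequent in both classes (question 31) whose
    extension (question 32) is frequent only in the adherent class.
    """
    return (
        Plant(items=((11, 1), (12, 1)), support_c1=0.85, support_c2=0.55,
              name="strong_c1"),
        Plant(items=((21, 1), (22, 1)), support_c1=0.85, support_c2=0.62,
              name="m1"),
        Plant(items=((31, 1),), support_c1=0.90, support_c2=0.90,
              name="m2_shared"),
        Plant(items=((32, 1),), support_c1=0.85, support_c2=0.40,
              name="m2_extension"),
    )


def default_codebook(spec: GeneratorSpec) -> SurveyCodebook:
    labels = tuple(f"opt{k}" for k in range(1, spec.options_per_question + 1))
    schema = [
        (q, f"Synthetic survey question {q}") for q in range(1, spec.n_questions + 1)
    ]
    return build_codebook(schema, labels)


def _plant_rows(
    rng: np.random.Generator, n: int, target: float, mode: str
) -> np.ndarray:
    if mode == "deterministic":
        k = math.ceil(target * n)
        mask = np.zeros(n, dtype=bool)
        mask[:k] = True
        return mask
    return rng.random(n) < target


def _sample_class(
    rng: np.random.Generator,
    n: int,
    spec: GeneratorSpec,
    class_label: str,
) -> tuple[np.ndarray, dict[str, float]]:
    """Answers as option indices (1-based), shape (n, n_questions)."""
    k = spec.options_per_question
    prof = np.asarray(spec.profile(class_label))
    answers = rng.choice(np.arange(1, k + 1), size=(n, spec.n_questions), p=prof)
    realized: dict[str, float] = {}
    for idx, plant in enumerate(spec.plants):
        target = plant.support_c1 if class_label == ADHERENT else plant.support_c2
        mask = _plant_rows(rng, n, target, plant.mode)
        for q, opt in plant.items:
            col = q - 1
            answers[mask, col] = opt
            if plant.mode == "deterministic":
                # exact realized support: remove the planted option elsewhere
                off = ~mask & (answers[:, col] == opt)
                if off.any():
                    others = np.array([o for o in range(1, k + 1) if o != opt])
                    p_others = np.delete(prof, opt - 1)
                    p_others = p_others / p_others.sum()
                    answers[off, col] = rng.choice(
                        others, size=int(off.sum()), p=p_others
                    )
        name = plant.name or f"plant_{idx}"
        realized[name] = float(mask.sum()) / n
    return answers, realized


def generate(spec: GeneratorSpec) -> tuple[pd.DataFrame, dict]:
    """Generate (raw survey table, truth record).

    The table has one row per participant: columns ``Q1..Qn`` holding option
    labels, an ``adherence`` outcome column (1/0, blank for the
    missing-outcome rows), and a ``participant_id`` column.  The truth
    record carries realized plant supports per class and the regression
    truth, for recovery tests.
    """
    rng = np.random.default_rng([spec.seed, _STREAM_TABLE])
    blocks = []
    realized: dict[str, dict[str, float]] = {}
    for label, n in ((ADHERENT, spec.n1), (NON_ADHERENT, spec.n2)):
        ans, real = _sample_class(rng, n, spec, label)
        realized[label] = real
        blocks.append((label, ans))
    if spec.n_missing_outcome:
        k = spec.options_per_question
        prof = np.asarray(spec.profile(ADHERENT))
        ans = rng.choice(
            np.arange(1, k + 1),
            size=(spec.n_missing_outcome, spec.n_questions),
            p=prof,
        )
        blocks.append((None, ans))

    frames = []
    offset = 0
    for label, ans in blocks:
        n = ans.shape[0]
        data = {
            f"Q{q}": [f"opt{o}" for o in ans[:, q - 1]]
            for q in range(1, spec.n_questions + 1)
        }
        frame = pd.DataFrame(data)
        frame.insert(
            0,
            "participant_id",
            [f"P{offset + i + 1:05d}" for i in range(n)],
        )
        if label is None:
            frame["adherence"] = ""
        else:
            frame["adherence"] = "1" if label == ADHERENT else "0"
        frames.append(frame)
        offset += n
    table = pd.concat(frames, ignore_index=True)

    truth = {
        "seed": spec.seed,
        "n1": spec.n1,
        "n2": spec.n2,
        "n_missing_outcome": spec.n_missing_outcome,
        "plants": [
            {
                "name": p.name or f"plant_{i}",
                "items": [list(it) for it in p.items],
                "item_codes": sorted(q * 1000 + o for q, o in p.items),
                "mode": p.mode,
                "target_support_c1": p.support_c1,
                "target_support_c2": p.support_c2,
                "realized_support_c1": realized[ADHERENT][p.name or f"plant_{i}"],
                "realized_support_c2": realized[NON_ADHERENT][p.name or f"plant_{i}"],
            }
            for i, p in enumerate(spec.plants)
        ],
        "regression": None
        if spec.regression is None
        else {
            "predictors": [list(pr) for pr in spec.regression.predictors],
            "coefficients": list(spec.regression.coefficients),
            "intercept": spec.regression.intercept,
        },
    }
    return table, truth


def generate_regression_outcome(
    spec: GeneratorSpec, covariate_table: pd.DataFrame
) -> pd.Series:
    """Bernoulli outcome from the spec's logistic regression scenario.

    Each predictor is the binary indicator of one (question, option) pair in
    the covariate table; P(outcome = 1) = logistic(intercept + sum(coef*x)).
    """
    if spec.regression is None:
        raise GeneratorSpecError("spec has no regression scenario")
    rng = np.random.default_rng([spec.seed, _STREAM_OUTCOME])
    n = len(covariate_table)
    eta = np.full(n, spec.regression.intercept, dtype=float)
    for (q, opt), coef in zip(spec.regression.predictors, spec.regression.coefficients):
        col = f"Q{q}"
        if col not in covariate_table.columns:
            raise GeneratorSpecError(f"predictor question {q} missing from table")
        x = (covariate_table[col] == f"opt{opt}").to_numpy(dtype=float)
        eta += coef * x
    p = expit(eta)
    return pd.Series(
        (rng.random(n) < p).astype(int), index=covariate_table.index, name="outcome"
    )


def write_outputs(
    spec: GeneratorSpec, out_dir, prefix: str = "synthetic"
) -> dict[str, str]:
    """Write survey CSV, codebook CSV and truth JSON; return the paths."""
    import os

    table, truth = generate(spec)
    codebook = default_codebook(spec)
    paths = {
        "survey": os.path.join(out_dir, f"{prefix}_survey.csv"),
        "codebook": os.path.join(out_dir, f"{prefix}_codebook.csv"),
        "truth": os.path.join(out_dir, f"{prefix}_truth.json"),
    }
    table.to_csv(paths["survey"], index=False)
    codebook.to_csv(paths["codebook"])
    with open(paths["truth"], "w") as fh:
        json.dump(truth, fh, indent=1)
    return paths
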