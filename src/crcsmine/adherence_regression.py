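"""Confirmatory logistic regression of CRCS adherence on selected variables.

The contrast-mining stage nominates survey variables; this module fits the
multivariate logistic model and reports the full confirmatory statistic set:
per-predictor B, SE, Wald statistic, odds ratio with 95% Wald CI, Cox &
Snell and Nagelkerke pseudo-R², the Hosmer–Lemeshow goodness-of-fit test,
and a classification table at a probability cutoff.

Fitting is maximum likelihood via iteratively reweighted least squares
(Newton–Raphson with step-halving, so the log-likelihood is non-decreasing
across iterations).  Convergence: max |score| < 1e-8 or relative
log-likelihood change < 1e-10, within 100 iterations.  Complete or
quasi-complete separation raises a diagnostic error naming the offending
predictor; an optional Firth (Jeffreys-prior) fallback is available.

Odds ratios are always exp(B) under the configured predictor coding; a
published table using the opposite indicator direction simply flips the
coefficient sign (OR -> 1/OR).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

__all__ = [
    "Predictor",
    "DesignSpec",
    "LogisticFit",
    "HosmerLemeshowResult",
    "ClassificationResult",
    "SeparationError",
    "RankDeficiencyError",
    "ConvergenceError",
    "InsufficientGroupsError",
    "LikelihoodOrderError",
    "DesignError",
    "build_design_matrix",
    "fit_logistic",
    "cox_snell_nagelkerke",
    "pseudo_r2",
    "hosmer_lemeshow",
    "classification_table",
    "write_regression_report",
]

WALD_Z = 1.96  # 95% Wald interval multiplier
SCORE_TOL = 1e-8
LL_RTOL = 1e-10
MAX_ITER = 100


class DesignError(ValueError):
    """Invalid design specification or unresolvable predictor."""


class SeparationError(RuntimeError):
    """Complete/quasi-complete separation; names the offending predictor."""


class RankDeficiencyError(ValueError):
    """Design matrix not full rank; lists collinear columns."""


class ConvergenceError(RuntimeError):
    """IRLS failed to converge within the iteration budget."""


class InsufficientGroupsError(ValueError):
    """Too few distinct risk groups for the Hosmer-Lemeshow test."""


class LikelihoodOrderError(RuntimeError):
    """Fitted log-likelihood below the null log-likelihood."""


@dataclass(frozen=True)
class Predictor:
    """One model term.

    coding 'binary': indicator that the value equals ``level`` (if given),
    else that it differs from ``reference``, else the raw column when it is
    already 0/1.
    coding 'ordinal': integer position of the value within ``levels``
    (or the raw column cast to float when ``levels`` is omitted).
    """

    name: str
    coding: str = "binary"
    reference: str | None = None
    level: str | None = None
    levels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.coding not in ("binary", "ordinal"):
            raise DesignError(f"{self.name}: unknown coding {self.coding!r}")
        if self.level is not None and self.reference is not None:
            raise DesignError(f"{self.name}: give level or reference, not both")


@dataclass
class DesignSpec:
    outcome: str
    predictors: list[Predictor]
    missing: str = "listwise"

    def __post_init__(self) -> None:
        names = [p.name for p in self.predictors]
        if len(names) != len(set(names)):
            raise DesignError("duplicate predictor names")
        if self.missing != "listwise":
            raise DesignError(f"unsupported missing policy {self.missing!r}")


_OUTCOME_ONES = {"1", "1.0", "adherent", "yes", "true"}
_OUTCOME_ZEROS = {"0", "0.0", "non-adherent", "no", "false"}


def _outcome_to01(series: pd.Series) -> pd.Series:
    def conv(v):
        if v is None or (isinstance(v, float) and math.isnan(v)):
            return np.nan
        s = str(v).strip().lower()
        if not s:
            return np.nan
        if s in _OUTCOME_ONES:
            return 1.0
        if s in _OUTCOME_ZEROS:
            return 0.0
        raise DesignError(f"outcome value {v!r} is not binary")

    return series.map(conv)


def _encode_predictor(series: pd.Series, p: Predictor) -> pd.Series:
    def is_missing(v):
        return (
            v is None
            or (isinstance(v, float) and math.isnan(v))
            or (isinstance(v, str) and not v.strip())
        )

    if p.coding == "binary":
        if p.level is not None:
            return series.map(
                lambda v: np.nan if is_missing(v) else float(str(v).strip() == p.level)
            )
        if p.reference is None:
            out = pd.to_numeric(series, errors="coerce")
            bad = set(out.dropna().unique()) - {0.0, 1.0}
            if bad:
                raise DesignError(
                    f"{p.name}: values {sorted(bad)} are not 0/1; give a reference level"
                )
            return out
        return series.map(
            lambda v: np.nan if is_missing(v) else float(str(v).strip() != p.reference)
        )
    # ordinal
    if p.levels is None:
        return pd.to_numeric(series, errors="coerce")
    order = {lev: i for i, lev in enumerate(p.levels)}

    def conv(v):
        if is_missing(v):
            return np.nan
        s = str(v).strip()
        if s not in order:
            raise DesignError(f"{p.name}: value {s!r} not in declared levels")
        return float(order[s])

    return series.map(conv)


def build_design_matrix(
    d: pd.DataFrame, spec: DesignSpec
) -> tuple[np.ndarray, np.ndarray, list[str], int]:
    """Design matrix with intercept, after listwise deletion.

    Returns (X, y, term_names, n_used); term_names[0] is '(intercept)'.
    """
    if spec.outcome not in d.columns:
        raise DesignError(f"outcome column {spec.outcome!r} not in data")
    cols = {spec.outcome: _outcome_to01(d[spec.outcome])}
    for p in spec.predictors:
        if p.name not in d.columns:
            raise DesignError(f"predictor column {p.name!r} not in data")
        cols[p.name] = _encode_predictor(d[p.name], p)
    frame = pd.DataFrame(cols).dropna()
    n_used = len(frame)
    y = frame[spec.outcome].to_numpy(dtype=float)
    X = np.column_stack(
        [np.ones(n_used)] + [frame[p.name].to_numpy(dtype=float) for p in spec.predictors]
    )
    names = ["(intercept)"] + [p.name for p in spec.predictors]
    return X, y, names, n_used


@dataclass
class HosmerLemeshowResult:
    chi2: float
    df: int
    p_value: float
    table: pd.DataFrame  # per-group observed/expected counts


@dataclass
class ClassificationResult:
    cutoff: float
    pct_correct_class0: float
    pct_correct_class1: float
    pct_correct_overall: float


@dataclass
class LogisticFit:
    terms: list[str]
    coef: np.ndarray
    se: np.ndarray
    wald: np.ndarray
    odds_ratio: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    p_values: np.ndarray
    ll_null: float
    ll_model: float
    ll_path: list[float]
    n_used: int
    n_iter: int
    converged: bool
    cox_snell_r2: float
    nagelkerke_r2: float
    fitted_probs: np.ndarray
    y: np.ndarray
    method: str = "mle"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "Item": self.terms,
                "B": self.coef,
                "SE(B)": self.se,
                "Wald": self.wald,
                "OR": self.odds_ratio,
                "CI95_low": self.ci_low,
                "CI95_high": self.ci_high,
                "p": self.p_values,
            }
        )


def _loglik(y: np.ndarray, eta: np.ndarray) -> float:
    # numerically stable: log(1+exp(eta)) via logaddexp
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def _null_loglik(y: np.ndarray) -> float:
    n = len(y)
    p = y.mean()
    if p in (0.0, 1.0):
        return 0.0
    return float(n * (p * math.log(p) + (1 - p) * math.log(1 - p)))


def _check_rank(X: np.ndarray, names: Sequence[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        _, R, piv = _qr_pivot(X)
        diag = np.abs(np.diag(R))
        tol = diag.max() * max(X.shape) * np.finfo(float).eps
        dropped = [names[piv[i]] for i in range(len(diag)) if diag[i] <= tol]
        dropped += [names[j] for j in piv[len(diag):]]
        raise RankDeficiencyError(
            f"design matrix rank {rank} < {X.shape[1]}; collinear columns: {dropped}"
        )


def _qr_pivot(X: np.ndarray):
    from scipy.linalg import qr

    Q, R, piv = qr(X, pivoting=True, mode="economic")
    return Q, R, piv


def fit_logistic(
    d: pd.DataFrame,
    spec: DesignSpec,
    max_iter: int = MAX_ITER,
    on_separation: str = "raise",
) -> LogisticFit:
    """Maximum-likelihood logistic fit with the full confirmatory statistic set.

    ``on_separation='firth'`` refits with Jeffreys-prior (Firth) penalization
    instead of raising when separation is detected.
    """
    X, y, names, n_used = build_design_matrix(d, spec)
    if n_used == 0 or y.min() == y.max():
        raise DesignError(
            "after listwise deletion the outcome has fewer than two levels"
        )
    _check_rank(X, names)

    try:
        beta, ll_path, n_iter, converged = _irls(X, y, max_iter, firth=False)
        method = "mle"
        if not converged or np.abs(beta).max() > 30.0:
            raise SeparationError(_separation_message(beta, names, converged))
    except SeparationError:
        if on_separation != "firth":
            raise
        beta, ll_path, n_iter, converged = _irls(X, y, max_iter, firth=True)
        method = "firth"
        if not converged:
            raise ConvergenceError("Firth fit failed to converge")

    eta = X @ beta
    p = expit(eta)
    W = p * (1 - p)
    info = X.T @ (X * W[:, None])
    cov = np.linalg.inv(info)
    se = np.sqrt(np.diag(cov))
    wald = (beta / se) ** 2
    p_values = stats.chi2.sf(wald, df=1)
    ll_model = ll_path[-1]
    ll_null = _null_loglik(y)
    cs, nk = cox_snell_nagelkerke(ll_null, ll_model, n_used)
    return LogisticFit(
        terms=names,
        coef=beta,
        se=se,
        wald=wald,
        odds_ratio=np.exp(beta),
        ci_low=np.exp(beta - WALD_Z * se),
        ci_high=np.exp(beta + WALD_Z * se),
        p_values=p_values,
        ll_null=ll_null,
        ll_model=ll_model,
        ll_path=ll_path,
        n_used=n_used,
        n_iter=n_iter,
        converged=converged,
        cox_snell_r2=cs,
        nagelkerke_r2=nk,
        fitted_probs=p,
        y=y,
        method=method,
    )


def _separation_message(beta: np.ndarray, names: Sequence[str], converged: bool) -> str:
    j = int(np.abs(beta[1:]).argmax()) + 1 if len(beta) > 1 else 0
    state = "diverging coefficients" if not converged else "extreme coefficient"
    return (
        f"separation suspected ({state}); predictor {names[j]!r} "
        f"has |B| = {abs(beta[j]):.1f}"
    )


def _irls(
    X: np.ndarray, y: np.ndarray, max_iter: int, firth: bool
) -> tuple[np.ndarray, list[float], int, bool]:
    n, k = X.shape
    beta = np.zeros(k)
    ll = _loglik(y, X @ beta)
    ll_path = [ll]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        p = expit(eta)
        W = np.clip(p * (1 - p), 1e-12, None)
        info = X.T @ (X * W[:, None])
        if firth:
            # hat diagonal of W^(1/2) X (X'WX)^-1 X' W^(1/2)
            try:
                Minv = np.linalg.inv(info)
            except np.linalg.LinAlgError as exc:
                raise SeparationError(f"singular information matrix: {exc}") from exc
            h = np.einsum("ij,jk,ik->i", X * W[:, None], Minv, X)
            score = X.T @ (y - p + h * (0.5 - p))
        else:
            score = X.T @ (y - p)
        if np.abs(score).max() < SCORE_TOL:
            converged = True
            break
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError as exc:
            raise SeparationError(f"singular information matrix: {exc}") from exc
        # step-halving keeps the (penalized) log-likelihood non-decreasing
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * step
            cand_ll = _penalized_loglik(y, X, cand) if firth else _loglik(y, X @ cand)
            ref_ll = _penalized_loglik(y, X, beta) if firth else ll
            if cand_ll >= ref_ll - 1e-12:
                break
            scale /= 2.0
        beta = beta + scale * step
        new_ll = _loglik(y, X @ beta)
        ll_path.append(new_ll)
        if abs(new_ll - ll) <= LL_RTOL * (abs(ll) + 1e-12):
            ll = new_ll
            converged = True
            break
        ll = new_ll
    return beta, ll_path, it, converged


def _penalized_loglik(y: np.ndarray, X: np.ndarray, beta: np.ndarray) -> float:
    eta = X @ beta
    p = expit(eta)
    W = np.clip(p * (1 - p), 1e-12, None)
    info = X.T @ (X * W[:, None])
    sign, logdet = np.linalg.slogdet(info)
    if sign <= 0:
        return -np.inf
    return _loglik(y, eta) + 0.5 * logdet


def cox_snell_nagelkerke(ll_null: float, ll_model: float, n: int) -> tuple[float, float]:
    """Cox & Snell R2 = 1 - exp(2(LL0 - LL1)/n); Nagelkerke rescales it by
    its attainable maximum 1 - exp(2 LL0 / n)."""
    if ll_model < ll_null - 1e-8:
        raise LikelihoodOrderError(
            f"fitted log-likelihood {ll_model} below null {ll_null}"
        )
    cs = 1.0 - math.exp(2.0 * (ll_null - ll_model) / n)
    denom = 1.0 - math.exp(2.0 * ll_null / n)
    nk = 0.0 if denom == 0 else cs / denom
    return cs, min(nk, 1.0)


def pseudo_r2(fit: LogisticFit) -> tuple[float, float]:
    return cox_snell_nagelkerke(fit.ll_null, fit.ll_model, fit.n_used)


def hosmer_lemeshow(
    fit: LogisticFit | None = None,
    groups: int = 10,
    *,
    probs: np.ndarray | None = None,
    y: np.ndarray | None = None,
) -> HosmerLemeshowResult:
    """Hosmer-Lemeshow chi-square over groups of fitted probability.

    Records are sorted by fitted probability and cut at the ``groups``
    quantile boundaries; ties on identical fitted probabilities are never
    split across bins.  With few distinct covariate patterns the number of
    realized groups g drops below ``groups`` (each pattern its own bin) and
    df = g - 2 shrinks accordingly.  Accepts a fit, or raw ``probs``/``y``
    arrays.
    """
    if probs is None:
        probs, y = fit.fitted_probs, fit.y
    probs = np.asarray(probs, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    order = np.argsort(probs, kind="stable")
    probs_sorted = probs[order]
    y_sorted = y[order]

    # runs of identical fitted probabilities (ties stay together)
    _, starts = np.unique(probs_sorted.round(12), return_index=True)
    run_stops = list(starts[1:]) + [n]
    targets = [i * n / groups for i in range(1, groups + 1)]
    bins: list[tuple[int, int]] = []  # (start, stop) index ranges
    cur_start = 0
    b_i = 0
    for stop in run_stops:
        if stop >= targets[b_i]:
            bins.append((cur_start, stop))
            cur_start = stop
            while b_i < groups - 1 and stop >= targets[b_i]:
                b_i += 1
    if cur_start < n:
        bins.append((cur_start, n))

    g = len(bins)
    if g < 3:
        raise InsufficientGroupsError(
            f"only {g} distinct risk groups; Hosmer-Lemeshow needs >= 3"
        )
    rows = []
    chi2 = 0.0
    for a, b in bins:
        o1 = float(y_sorted[a:b].sum())
        e1 = float(probs_sorted[a:b].sum())
        m = b - a
        o0, e0 = m - o1, m - e1
        for obs, exp in ((o1, e1), (o0, e0)):
            if exp > 1e-12:
                chi2 += (obs - exp) ** 2 / exp
            elif obs > 0:
                chi2 = float("inf")
        rows.append({"n": m, "obs_1": o1, "exp_1": e1, "obs_0": o0, "exp_0": e0})
    df = g - 2
    p = float(stats.chi2.sf(chi2, df))
    return HosmerLemeshowResult(chi2=chi2, df=df, p_value=p, table=pd.DataFrame(rows))


def classification_table(
    fit: LogisticFit | None = None,
    cutoff: float = 0.5,
    *,
    probs: np.ndarray | None = None,
    y: np.ndarray | None = None,
) -> ClassificationResult:
    """Percent correctly classified per observed class and overall, predicting
    class 1 when the fitted probability >= cutoff."""
    if probs is None:
        probs, y = fit.fitted_probs, fit.y
    probs = np.asarray(probs, dtype=float)
    y = np.asarray(y, dtype=float)
    pred = (probs >= cutoff).astype(float)
    correct = pred == y
    n0 = int((y == 0).sum())
    n1 = int((y == 1).sum())
    pct0 = 100.0 * correct[y == 0].mean() if n0 else float("nan")
    pct1 = 100.0 * correct[y == 1].mean() if n1 else float("nan")
    return ClassificationResult(
        cutoff=cutoff,
        pct_correct_class0=float(pct0),
        pct_correct_class1=float(pct1),
        pct_correct_overall=float(100.0 * correct.mean()),
    )


def write_regression_report(
    fit: LogisticFit,
    path_tsv,
    path_json=None,
    hl_groups: int = 10,
    cutoff: float = 0.5,
) -> dict:
    """Model report shaped like a published logistic-regression table:
    one line per term plus footer lines for pseudo-R2, Hosmer-Lemeshow and
    classification rates."""
    try:
        hl = hosmer_lemeshow(fit, hl_groups)
    except InsufficientGroupsError:
        hl = None  # too few distinct covariate patterns; test undefined
    cls = classification_table(fit, cutoff)
    frame = fit.to_frame()
    with open(path_tsv, "w") as fh:
        fh.write(frame.to_csv(sep="\t", index=False, float_format="%.4f"))
        fh.write(f"# n_used\t{fit.n_used}\n")
        fh.write(f"# Cox & Snell R2\t{fit.cox_snell_r2:.4f}\n")
        fh.write(f"# Nagelkerke R2\t{fit.nagelkerke_r2:.4f}\n")
        if hl is None:
            fh.write("# Hosmer-Lemeshow\tnot defined (fewer than 3 risk groups)\n")
        else:
            fh.write(
                f"# Hosmer-Lemeshow\tchi2={hl.chi2:.4f}\tdf={hl.df}\tp={hl.p_value:.4f}\n"
            )
        fh.write(
            f"# Classification (cutoff {cls.cutoff})\t"
            f"class0={cls.pct_correct_class0:.1f}%\t"
            f"class1={cls.pct_correct_class1:.1f}%\t"
            f"overall={cls.pct_correct_overall:.1f}%\n"
        )
    report = {
        "terms": [
            {
                "item": t,
                "B": float(b),
                "SE": float(s),
                "Wald": float(w),
                "OR": float(o),
                "CI95": [float(lo), float(hi)],
                "p": float(pv),
            }
            for t, b, s, w, o, lo, hi, pv in zip(
                fit.terms,
                fit.coef,
                fit.se,
                fit.wald,
                fit.odds_ratio,
                fit.ci_low,
                fit.ci_high,
                fit.p_values,
            )
        ],
        "n_used": fit.n_used,
        "ll_null": fit.ll_null,
        "ll_model": fit.ll_model,
        "cox_snell_r2": fit.cox_snell_r2,
        "nagelkerke_r2": fit.nagelkerke_r2,
        "hosmer_lemeshow": None
        if hl is None
        else {"chi2": hl.chi2, "df": hl.df, "p": hl.p_value},
        "classification": {
            "cutoff": cls.cutoff,
            "pct_correct_class0": cls.pct_correct_class0,
            "pct_correct_class1": cls.pct_correct_class1,
            "pct_correct_overall": cls.pct_correct_overall,
        },
        "method": fit.method,
    }
    if path_json is not None:
        with open(path_json, "w") as fh:
            json.dump(report, fh, indent=1)
    return report
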