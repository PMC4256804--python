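"""Logistic regression: IRLS fit, algebraic identities, diagnostics."""

import math

import numpy as np
import pandas as pd
import pytest

import crcsmine as cm
from crcsmine.adherence_regression import (
    DesignError,
    InsufficientGroupsError,
    LikelihoodOrderError,
    RankDeficiencyError,
    SeparationError,
    build_design_matrix,
)


def _binary_df(n00, n01, n10, n11):
    """(x, y) cell counts: n_xy records with predictor x and outcome y."""
    rows = (
        [(0, 0)] * n00 + [(0, 1)] * n01 + [(1, 0)] * n10 + [(1, 1)] * n11
    )
    return pd.DataFrame(rows, columns=["x", "y"])


def _random_df(rng, n=300, k=3, beta=None):
    X = rng.integers(0, 2, size=(n, k)).astype(float)
    if beta is None:
        beta = rng.normal(0, 0.8, size=k)
    eta = -0.2 + X @ beta
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
    df = pd.DataFrame(X, columns=[f"x{i}" for i in range(k)])
    df["y"] = y
    return df


def _spec(k=3):
    return cm.DesignSpec(
        outcome="y", predictors=[cm.Predictor(f"x{i}") for i in range(k)]
    )


def test_single_binary_predictor_or_equals_cross_product_ratio():
    df = _binary_df(30, 20, 15, 35)
    fit = cm.fit_logistic(
        df, cm.DesignSpec(outcome="y", predictors=[cm.Predictor("x")])
    )
    odds_ratio = fit.odds_ratio[1]
    expected = (35 * 30) / (15 * 20)  # ad/bc
    assert odds_ratio == pytest.approx(expected, abs=1e-6)


def test_wald_or_ci_identities_hold_on_every_fit():
    rng = np.random.default_rng(11)
    fit = cm.fit_logistic(_random_df(rng), _spec())
    assert np.allclose(fit.odds_ratio, np.exp(fit.coef))
    assert np.allclose(fit.ci_low, np.exp(fit.coef - 1.96 * fit.se))
    assert np.allclose(fit.ci_high, np.exp(fit.coef + 1.96 * fit.se))
    assert np.allclose(fit.wald, (fit.coef / fit.se) ** 2)
    assert 0 <= fit.cox_snell_r2 <= fit.nagelkerke_r2 <= 1


def test_loglik_nondecreasing_over_irls_iterations():
    rng = np.random.default_rng(12)
    fit = cm.fit_logistic(_random_df(rng), _spec())
    path = fit.ll_path
    assert all(b >= a - 1e-10 for a, b in zip(path, path[1:]))
    assert fit.converged


def test_fit_matches_statsmodels_oracle():
    """Coefficients and standard errors agree with an independent ML
    implementation on random data."""
    sm = pytest.importorskip("statsmodels.api")
    rng = np.random.default_rng(13)
    df = _random_df(rng, n=400)
    fit = cm.fit_logistic(df, _spec())
    X = np.column_stack([np.ones(len(df))] + [df[f"x{i}"] for i in range(3)])
    ref = sm.Logit(df["y"].to_numpy(), X).fit(disp=0)
    assert np.allclose(fit.coef, ref.params, atol=1e-6)
    assert np.allclose(fit.se, ref.bse, atol=1e-6)
    assert fit.ll_model == pytest.approx(ref.llf, abs=1e-8)


def test_listwise_deletion_counts():
    rng = np.random.default_rng(14)
    df = _random_df(rng, n=100)
    df.loc[0:4, "x0"] = np.nan
    df.loc[3:9, "y"] = np.nan
    X, y, names, n_used = build_design_matrix(df, _spec())
    complete = df.dropna()
    assert n_used == len(complete) == len(y)
    fit = cm.fit_logistic(df, _spec())
    assert fit.n_used == len(complete)


def test_null_model_pseudo_r2_zero():
    df = _binary_df(25, 25, 0, 0)[["y"]]
    fit = cm.fit_logistic(df, cm.DesignSpec(outcome="y", predictors=[]))
    cs, nk = cm.pseudo_r2(fit)
    assert cs == pytest.approx(0.0, abs=1e-12)
    assert nk == pytest.approx(0.0, abs=1e-12)


def test_pseudo_r2_formula_on_worked_values():
    """Direct evaluation of the Cox & Snell / Nagelkerke formulas."""
    n = 10
    ll0 = n * (0.6 * math.log(0.6) + 0.4 * math.log(0.4))
    ll1 = ll0 + 2.0
    cs, nk = cm.cox_snell_nagelkerke(ll0, ll1, n)
    assert cs == pytest.approx(1 - math.exp(2 * (ll0 - ll1) / n), abs=1e-10)
    assert nk == pytest.approx(cs / (1 - math.exp(2 * ll0 / n)), abs=1e-10)
    with pytest.raises(LikelihoodOrderError):
        cm.cox_snell_nagelkerke(ll0, ll0 - 1.0, n)


def test_separation_raises_and_firth_fallback_works():
    df = _binary_df(30, 0, 0, 30)  # y == x: complete separation
    spec = cm.DesignSpec(outcome="y", predictors=[cm.Predictor("x")])
    with pytest.raises(SeparationError, match="x"):
        cm.fit_logistic(df, spec)
    fit = cm.fit_logistic(df, spec, on_separation="firth")
    assert fit.method == "firth"
    assert np.isfinite(fit.coef).all() and np.isfinite(fit.se).all()


def test_rank_deficiency_names_collinear_columns():
    rng = np.random.default_rng(15)
    df = _random_df(rng, n=80, k=2)
    df["x2"] = df["x0"]  # exact copy
    spec = cm.DesignSpec(
        outcome="y", predictors=[cm.Predictor("x0"), cm.Predictor("x1"),
                                 cm.Predictor("x2")]
    )
    with pytest.raises(RankDeficiencyError, match="x"):
        cm.fit_logistic(df, spec)


def test_design_errors():
    df = pd.DataFrame({"y": [0, 1], "x": ["a", "b"]})
    with pytest.raises(DesignError):
        cm.fit_logistic(df, cm.DesignSpec(outcome="missing", predictors=[]))
    with pytest.raises(DesignError):
        # non-numeric binary predictor without a reference level
        cm.fit_logistic(
            df, cm.DesignSpec(outcome="y", predictors=[cm.Predictor("x")])
        )
    with pytest.raises(DesignError):
        cm.DesignSpec(outcome="y", predictors=[cm.Predictor("x"), cm.Predictor("x")])


def test_predictor_codings():
    df = pd.DataFrame(
        {
            "y": [0, 1, 0, 1],
            "q": ["yes", "no", "yes", "no"],
            "likert": ["low", "mid", "high", "mid"],
        }
    )
    spec = cm.DesignSpec(
        outcome="y",
        predictors=[
            cm.Predictor("q", coding="binary", reference="no"),
            cm.Predictor("likert", coding="ordinal",
                         levels=("low", "mid", "high")),
        ],
    )
    X, y, names, n = build_design_matrix(df, spec)
    assert X[:, 1].tolist() == [1.0, 0.0, 1.0, 0.0]
    assert X[:, 2].tolist() == [0.0, 1.0, 2.0, 1.0]
    # level-indicator coding
    spec2 = cm.DesignSpec(
        outcome="y", predictors=[cm.Predictor("likert", level="mid")]
    )
    X2, *_ = build_design_matrix(df, spec2)
    assert X2[:, 1].tolist() == [0.0, 1.0, 0.0, 1.0]


# ---------------------------------------------------------------------------
# Hosmer-Lemeshow
# ---------------------------------------------------------------------------

def test_hl_zero_chi2_when_probs_match_group_rates():
    probs = np.repeat([0.1, 0.3, 0.5, 0.7, 0.9], 20)
    y = np.concatenate(
        [([1] * int(p * 20) + [0] * (20 - int(p * 20))) for p in
         (0.1, 0.3, 0.5, 0.7, 0.9)]
    )
    hl = cm.hosmer_lemeshow(probs=probs, y=y, groups=10)
    assert hl.chi2 == pytest.approx(0.0, abs=1e-9)
    assert hl.df == 5 - 2


def test_hl_df_from_seven_covariate_patterns():
    """With 7 distinct covariate patterns the decile grouping collapses to
    g = 7 bins and df = g - 2 = 5."""
    rng = np.random.default_rng(16)
    patterns = [
        (0, 0, 0), (1, 0, 0), (0, 1, 0), (0, 0, 1),
        (1, 1, 0), (1, 0, 1), (0, 1, 1),
    ]
    rows = []
    for px in patterns:
        eta = -0.5 + 1.0 * px[0] - 0.8 * px[1] + 0.4 * px[2]
        p = 1 / (1 + math.exp(-eta))
        for _ in range(30):
            rows.append((*px, int(rng.random() < p)))
    df = pd.DataFrame(rows, columns=["x0", "x1", "x2", "y"])
    fit = cm.fit_logistic(df, _spec())
    assert len(np.unique(fit.fitted_probs.round(12))) == 7
    hl = cm.hosmer_lemeshow(fit, groups=10)
    assert hl.df == 5


def test_hl_insufficient_groups():
    probs = np.full(50, 0.5)
    y = np.zeros(50)
    y[:25] = 1
    with pytest.raises(InsufficientGroupsError):
        cm.hosmer_lemeshow(probs=probs, y=y)


def test_hl_matches_hand_computation():
    """Chi-square equals the by-hand O/E table for a two-group toy."""
    probs = np.array([0.2] * 10 + [0.8] * 10 + [0.5] * 10)
    y = np.array([0] * 8 + [1] * 2 + [1] * 7 + [0] * 3 + [1] * 5 + [0] * 5)
    hl = cm.hosmer_lemeshow(probs=probs, y=y, groups=3)
    # groups sorted by prob: (0.2: O1=2, E1=2), (0.5: O1=5, E1=5), (0.8: O1=7, E1=8)
    expected = (
        (2 - 2) ** 2 / 2 + (8 - 8) ** 2 / 8
        + (5 - 5) ** 2 / 5 + (5 - 5) ** 2 / 5
        + (7 - 8) ** 2 / 8 + (3 - 2) ** 2 / 2
    )
    assert hl.chi2 == pytest.approx(expected, abs=1e-9)
    assert hl.df == 1


# ---------------------------------------------------------------------------
# Classification table
# ---------------------------------------------------------------------------

def test_classification_table_cases():
    perfect = cm.classification_table(
        probs=np.array([0.9, 0.9, 0.1, 0.1]), y=np.array([1, 1, 0, 0])
    )
    assert perfect.pct_correct_class0 == 100.0
    assert perfect.pct_correct_class1 == 100.0

    constant = cm.classification_table(
        probs=np.full(10, 0.6), y=np.array([1] * 6 + [0] * 4), cutoff=0.5
    )
    assert constant.pct_correct_class1 == 100.0
    assert constant.pct_correct_class0 == 0.0
    assert constant.pct_correct_overall == pytest.approx(60.0)

    # hand-built confusion matrix on 20 records:
    # y=1: 8 predicted 1, 2 predicted 0; y=0: 7 predicted 0, 3 predicted 1
    probs = np.array([0.7] * 8 + [0.3] * 2 + [0.2] * 7 + [0.8] * 3)
    y = np.array([1] * 10 + [0] * 10)
    res = cm.classification_table(probs=probs, y=y)
    assert res.pct_correct_class1 == pytest.approx(80.0)
    assert res.pct_correct_class0 == pytest.approx(70.0)
    assert res.pct_correct_overall == pytest.approx(75.0)


def test_null_model_rarely_significant():
    """Outcome independent of all predictors: Wald p > 0.05 for the large
    majority of coefficient tests across seeds."""
    clear = 0
    total = 0
    for seed in range(60):
        rng = np.random.default_rng(7000 + seed)
        X = rng.integers(0, 2, size=(1000, 3)).astype(float)
        y = rng.integers(0, 2, size=1000)
        df = pd.DataFrame(X, columns=["x0", "x1", "x2"])
        df["y"] = y
        fit = cm.fit_logistic(df, _spec())
        assert np.abs(fit.coef[1:]).max() < 1.0
        clear += int((fit.p_values[1:] > 0.05).sum())
        total += 3
    assert clear / total >= 0.90


def test_coefficient_bias_shrinks_with_sample_size():
    """Estimated coefficients converge to the truth as n grows."""
    true_beta = np.array([-1.5, 1.5, -0.3])
    scenario = cm.RegressionScenario(
        predictors=((1, 1), (2, 1), (3, 1)),
        coefficients=tuple(true_beta), intercept=0.0,
    )
    design = cm.DesignSpec(
        outcome="outcome",
        predictors=[cm.Predictor(f"Q{q}", level="opt1") for q in (1, 2, 3)],
    )
    bias = {}
    for n in (500, 2000, 8000):
        est = np.zeros(3)
        reps = 30
        for rep in range(reps):
            spec = cm.GeneratorSpec(
                n1=n // 2, n2=n - n // 2, n_questions=3,
                n_missing_outcome=0, regression=scenario,
                seed=80_000 + 100 * rep + n % 97,
            )
            table, _ = cm.generate(spec)
            table["outcome"] = cm.generate_regression_outcome(spec, table)
            est += cm.fit_logistic(table, design).coef[1:]
        bias[n] = np.abs(est / reps - true_beta)
    for j in range(3):
        assert bias[8000][j] < bias[500][j]


def test_regression_report_written(tmp_path):
    rng = np.random.default_rng(17)
    fit = cm.fit_logistic(_random_df(rng), _spec())
    from crcsmine.adherence_regression import write_regression_report
    report = write_regression_report(
        fit, tmp_path / "reg.tsv", tmp_path / "reg.json"
    )
    assert (tmp_path / "reg.tsv").stat().st_size > 0
    assert report["n_used"] == fit.n_used
    assert {"terms", "cox_snell_r2", "hosmer_lemeshow", "classification"} <= set(report)
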