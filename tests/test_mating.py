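"""Pair universe, mating-success GLMs and the assortative-mating test."""

import math

import numpy as np
import pytest
from scipy import optimize, stats as sps

import oracles
from mesoped import mating
from mesoped.genotype_data import Individual, Origin, Tactic
from mesoped.mating import (
    COEF_NAMES,
    MatingSuccessModel,
    OffspringCountModel,
    assortative_test,
    build_pair_table,
    predict_offspring_count,
    predict_success_probability,
)
from mesoped.parentage import PedigreeAssignment


def _assign(off, mother, father, cls):
    return PedigreeAssignment(off, mother, father, 0.0, 0, cls, 0, "assigned")


# ---------------------------------------------------------------------------
# pair table
# ---------------------------------------------------------------------------

def test_pair_universe_size_and_conservation(adult_registry):
    assigns = [
        _assign("o1", "F1", "M1", "south"),
        _assign("o2", "F1", "M1", "south"),
        _assign("o3", "F2", "S1", "west"),
    ]
    pairs = build_pair_table(assigns, adult_registry)
    assert len(pairs) == 3 * 2  # 3 males x 2 females
    assert pairs["n_offspring"].sum() == 3
    assert (pairs["success"] == (pairs["n_offspring"] >= 1)).all()
    none = build_pair_table([], adult_registry)
    assert not none["success"].any()


def test_pair_table_missing_size_errors():
    registry = {
        "M": Individual("M", Origin.WEST, Tactic.NESTING_MALE, 12.0, 30.0),
        "F": Individual("F", Origin.WEST, None),  # no phenotype joined
    }
    registry["F"] = Individual("F", Origin.OFFSPRING)  # not an adult female
    pairs = build_pair_table([], registry)
    assert pairs.empty or "female_id" in pairs


def test_covariate_modes(adult_registry):
    pairs_len = build_pair_table([], adult_registry, "length")
    pairs_wl = build_pair_table([], adult_registry, "weight_length")
    m1_len = pairs_len[pairs_len.male_id == "M1"]["male_size"].iloc[0]
    m1_wl = pairs_wl[pairs_wl.male_id == "M1"]["male_size"].iloc[0]
    assert m1_len == pytest.approx(14.0)
    assert m1_wl == pytest.approx(40.0 / 14.0)
    with pytest.raises(ValueError):
        build_pair_table([], adult_registry, "girth")


# ---------------------------------------------------------------------------
# GLM fits vs independent numerical ML
# ---------------------------------------------------------------------------

def _toy_pairs(rng, n=200, beta=None, poisson_gamma=None):
    beta = np.array(beta if beta is not None else
                    [-1.0, 0.8, 0.5, -0.2, 0.05, -0.03, 0.4])
    x = np.column_stack([
        np.ones(n),
        rng.integers(0, 2, n),
        rng.integers(0, 2, n),
        rng.integers(0, 2, n),
        rng.normal(13, 2, n),
        rng.normal(13, 2, n),
        rng.integers(0, 2, n),
    ])
    eta = x @ beta
    p = 1 / (1 + np.exp(-eta))
    success = rng.random(n) < p
    if poisson_gamma is not None:
        lam = np.exp(x @ np.asarray(poisson_gamma))
        counts = np.where(success, 1 + rng.poisson(lam), 0)
    else:
        counts = success.astype(int)
    import pandas as pd

    df = pd.DataFrame(x[:, 1:], columns=COEF_NAMES[1:])
    df["success"] = success
    df["n_offspring"] = counts
    return df, x


def test_logistic_fit_matches_numerical_ml():
    rng = np.random.default_rng(4)
    df, x = _toy_pairs(rng)
    fit = MatingSuccessModel(df).fit()
    res = optimize.minimize(
        oracles.logistic_negll, np.zeros(7),
        args=(x, df["success"].to_numpy(float)), method="BFGS",
        options={"gtol": 1e-10, "maxiter": 2000},
    )
    assert np.allclose(fit.params.to_numpy(), res.x, atol=1e-5)


def test_poisson_fit_matches_numerical_ml():
    rng = np.random.default_rng(5)
    gamma = [0.1, 0.3, -0.2, 0.1, 0.02, 0.01, -0.4]
    df, x = _toy_pairs(rng, poisson_gamma=gamma)
    fit = OffspringCountModel(df).fit()
    mask = df["success"].to_numpy()
    res = optimize.minimize(
        oracles.poisson_negll, np.zeros(7),
        args=(x[mask], df.loc[mask, "n_offspring"].to_numpy(float)),
        method="BFGS", options={"gtol": 1e-10, "maxiter": 2000},
    )
    assert np.allclose(fit.params.to_numpy(), res.x, atol=1e-5)


def test_single_class_errors():
    rng = np.random.default_rng(6)
    df, _ = _toy_pairs(rng)
    df["success"] = False
    df["n_offspring"] = 0
    with pytest.raises(ValueError):
        MatingSuccessModel(df).fit()
    with pytest.raises(ValueError):
        OffspringCountModel(df).fit()


def test_null_simulation_no_spurious_effects():
    rng = np.random.default_rng(7)
    beta = [-1.5, 0, 0, 0, 0, 0, 0]
    df, _ = _toy_pairs(rng, n=4000, beta=beta)
    fit = MatingSuccessModel(df).fit()
    z = np.abs(fit.params.to_numpy()[1:] / fit.bse.to_numpy()[1:])
    assert (z < 3).all()


def test_doubling_counts_shifts_intercept_by_log2():
    rng = np.random.default_rng(8)
    gamma = [0.2, 0.3, -0.2, 0.1, 0.02, 0.01, -0.4]
    df, _ = _toy_pairs(rng, poisson_gamma=gamma)
    fit1 = OffspringCountModel(df).fit()
    df2 = df.copy()
    df2["n_offspring"] *= 2
    fit2 = OffspringCountModel(df2).fit()
    delta = fit2.params.to_numpy() - fit1.params.to_numpy()
    assert delta[0] == pytest.approx(math.log(2), abs=1e-6)
    assert np.allclose(delta[1:], 0, atol=1e-6)


def test_wald_interval_coverage():
    """95% Wald intervals cover the truth at roughly nominal rate."""
    rng = np.random.default_rng(9)
    beta = np.array([-1.0, 0.8, 0.5, -0.2, 0.05, -0.03, 0.4])
    cover = np.zeros(7)
    reps = 500
    for _ in range(reps):
        df, _ = _toy_pairs(rng, n=800, beta=beta)
        try:
            fit = MatingSuccessModel(df).fit()
        except ValueError:
            continue
        lo = fit.params.to_numpy() - 1.96 * fit.bse.to_numpy()
        hi = fit.params.to_numpy() + 1.96 * fit.bse.to_numpy()
        cover += (lo <= beta) & (beta <= hi)
    rate = cover / reps
    assert ((rate >= 0.90) & (rate <= 0.98)).all()


def test_summary_table_shape():
    rng = np.random.default_rng(10)
    df, _ = _toy_pairs(rng)
    s = MatingSuccessModel(df).fit().summary()
    assert list(s.columns) == ["parameter", "description", "estimate", "se",
                               "p_value"]
    assert len(s) == 7


# ---------------------------------------------------------------------------
# closed-form predictions
# ---------------------------------------------------------------------------

SUCCESS_COEFS = (-5.361, 1.133, 1.083, -0.167, -0.026, -0.029, 0.372)
COUNT_COEFS = (-2.620, 0.270, 0.599, 0.009, 0.180, 0.055, -0.752)


def test_success_probability_closed_form():
    base = predict_success_probability(SUCCESS_COEFS)
    assert base == pytest.approx(math.exp(-5.361) / (1 + math.exp(-5.361)))
    with_west_male = predict_success_probability(SUCCESS_COEFS, o_i=1)
    assert with_west_male == pytest.approx(0.0144, abs=5e-5)
    with pytest.raises(ValueError):
        predict_success_probability((1.0, 2.0))


def test_count_prediction_closed_form():
    lam = predict_offspring_count(COUNT_COEFS, l_i=12.806, l_j=13.194)
    assert lam == pytest.approx(
        math.exp(-2.620 + 0.180 * 12.806 + 0.055 * 13.194)
    )
    sneaker = predict_offspring_count(
        COUNT_COEFS, l_i=12.806, l_j=13.194, s_i=1
    )
    assert sneaker == pytest.approx(lam * math.exp(-0.752))


def test_prediction_model_kind_guard():
    rng = np.random.default_rng(11)
    df, _ = _toy_pairs(rng)
    logit_fit = MatingSuccessModel(df).fit()
    with pytest.raises(ValueError):
        predict_offspring_count(logit_fit)
    with pytest.raises(ValueError):
        predict_success_probability(
            OffspringCountModel(df).fit()
        )


# ---------------------------------------------------------------------------
# assortative test
# ---------------------------------------------------------------------------

def _pairs_to_assigns(table_counts, registry):
    """table_counts[(male_origin, female_origin)] = number of distinct pairs."""
    assigns = []
    k = 0
    for (mo, fo), n_pairs in table_counts.items():
        for _ in range(n_pairs):
            mid, fid = f"m{k}", f"f{k}"
            registry[mid] = Individual(
                mid, Origin(mo), Tactic.NESTING_MALE, 13.0, 30.0
            )
            registry[fid] = Individual(fid, Origin(fo), Tactic.FEMALE, 13.0, 30.0)
            assigns.append(_assign(f"o{k}", fid, mid, "x"))
            k += 1
    return assigns, registry


def test_assortative_balanced_table_is_null():
    registry = {}
    assigns, registry = _pairs_to_assigns(
        {("south", "south"): 10, ("south", "west"): 10,
         ("west", "south"): 10, ("west", "west"): 10}, registry,
    )
    res = assortative_test(assigns, registry)
    assert res.chi2 == pytest.approx(0.0)
    assert res.p_value == pytest.approx(1.0)


def test_assortative_hand_computed_yates():
    registry = {}
    counts = {("south", "south"): 11, ("south", "west"): 43,
              ("west", "south"): 50, ("west", "west"): 139}
    assigns, registry = _pairs_to_assigns(counts, registry)
    res = assortative_test(assigns, registry)
    # independent hand computation of the clamped Yates statistic
    obs = np.array([[11, 43], [50, 139]], dtype=float)
    exp = np.outer(obs.sum(1), obs.sum(0)) / obs.sum()
    chi2 = float(np.sum(np.maximum(np.abs(obs - exp) - 0.5, 0) ** 2 / exp))
    assert res.chi2 == pytest.approx(chi2, abs=1e-12)
    assert res.chi2 == pytest.approx(0.54, abs=0.01)
    assert res.p_value == pytest.approx(sps.chi2.sf(chi2, 1), abs=1e-12)


def test_assortative_counts_each_pair_once():
    registry = {
        "m0": Individual("m0", Origin.SOUTH, Tactic.NESTING_MALE, 13.0, 30.0),
        "f0": Individual("f0", Origin.WEST, Tactic.FEMALE, 13.0, 30.0),
        "m1": Individual("m1", Origin.WEST, Tactic.NESTING_MALE, 13.0, 30.0),
        "f1": Individual("f1", Origin.SOUTH, Tactic.FEMALE, 13.0, 30.0),
    }
    assigns = [_assign(f"o{i}", "f0", "m0", "hybrid") for i in range(5)]
    assigns += [_assign("o9", "f1", "m1", "hybrid")]
    res = assortative_test(assigns, registry)
    assert res.table.to_numpy().sum() == 2  # two distinct pairs
    weighted = assortative_test(assigns, registry, weight_by_offspring=True)
    assert weighted.table.to_numpy().sum() == 6


def test_assortative_zero_margin_flagged():
    registry = {}
    assigns, registry = _pairs_to_assigns(
        {("south", "south"): 5, ("south", "west"): 5}, registry
    )
    res = assortative_test(assigns, registry)
    assert math.isnan(res.chi2) and math.isnan(res.p_value)
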