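"""Count models: overdispersion test, IRR fits, quartile flags, sensitivities."""
import numpy as np
import pandas as pd
import pytest

from txcrowd.config import TruthConfig
from txcrowd import synthetic
from txcrowd.irr import (
    DEFAULT_COVARIATES,
    EstimationError,
    IRRModel,
    ModelSpec,
    fit_model,
    overdispersion_test,
    quartile_flags,
    run_sensitivities,
)


def _sim_counts(rng, n, family, alpha=0.8):
    x = rng.normal(size=n)
    mu = np.exp(1.0 + 0.3 * x)
    if family == "poisson":
        y = rng.poisson(mu)
    else:
        y = rng.poisson(rng.gamma(1.0 / alpha, alpha * mu))
    X = np.column_stack([np.ones(n), x])
    return y, X


def test_overdispersion_test_calibrated_under_poisson_null():
    hits = 0
    for seed in range(100):
        rng = np.random.default_rng(seed)
        y, X = _sim_counts(rng, 5000, "poisson")
        hits += overdispersion_test(y, X).family == "poisson"
    assert hits >= 90


def test_overdispersion_test_detects_nb_data():
    hits = 0
    for seed in range(100):
        rng = np.random.default_rng(1000 + seed)
        y, X = _sim_counts(rng, 5000, "negbin", alpha=0.8)
        hits += overdispersion_test(y, X).family == "negbin"
    assert hits >= 99


def test_constant_outcome_is_degenerate():
    X = np.ones((50, 1))
    with pytest.raises(EstimationError):
        overdispersion_test(np.full(50, 3.0), X)


@pytest.fixture(scope="module")
def truth_frame():
    cfg = TruthConfig(seed=17, n_campaigns=8000)
    gaz = synthetic.generate_gazetteer(cfg)
    records, truth = synthetic.generate_campaigns(cfg, gaz, stories=False)
    df = synthetic.truth_analysis_frame(records, truth)
    df["concordant"] = True
    df["passes_threshold"] = df.index % 3 != 0
    return cfg, df


def test_race_irr_recovered_within_three_sigma(truth_frame):
    """Single-replicate recovery check; 95% CI coverage over 100 replicates
    is asserted in the acceptance suite."""
    cfg, df = truth_frame
    res = IRRModel.from_dataframe(df, "amount_raised", family="auto").fit()
    assert res.family == "negbin"
    for race in ("Black", "Hispanic"):
        term = f"race_{race}"
        err = abs(res.params[term] - np.log(cfg.true_irr_amount[race]))
        assert err < 3 * res.bse[term], term


def test_null_covariate_has_irr_near_one(truth_frame):
    _, df = truth_frame
    df = df.copy()
    rng = np.random.default_rng(5)
    df["noise_flag"] = rng.integers(0, 2, size=len(df)).astype(float)
    res = IRRModel.from_dataframe(
        df, "amount_raised", DEFAULT_COVARIATES + ["noise_flag"], family="negbin"
    ).fit()
    assert abs(res.params["noise_flag"]) < 3 * res.bse["noise_flag"]
    assert abs(res.irr["noise_flag"] - 1.0) < 0.1


def test_nb_fit_with_vanishing_dispersion_equals_poisson():
    """In the alpha -> 0 limit the NB2 fit coincides with the Poisson fit."""
    rng = np.random.default_rng(11)
    n = 4000
    race = rng.choice(["White", "Black", "Hispanic", "Other"], size=n)
    state = rng.choice([f"S{i}" for i in range(20)], size=n)
    mu = np.exp(2.0 + 0.2 * (race == "Black"))
    df = pd.DataFrame({"y": rng.poisson(mu), "race": race, "state": state})
    pois = IRRModel.from_dataframe(df, "y", [], family="poisson").fit()
    nb = IRRModel.from_dataframe(df, "y", [], family="negbin").fit(alpha=1e-8)
    diff = (nb.params - pois.params).abs().max()
    assert diff < 1e-4
    # and the MLE estimates a near-zero dispersion on equidispersed data
    nb_mle = IRRModel.from_dataframe(df, "y", [], family="negbin").fit()
    assert nb_mle.alpha < 0.01


def test_cluster_robust_se_exceeds_classical_under_intracluster_correlation():
    rng = np.random.default_rng(23)
    n_states, per = 40, 200
    state = np.repeat([f"S{i}" for i in range(n_states)], per)
    u = np.repeat(rng.normal(0, 0.5, size=n_states), per)  # shared state effect
    race = rng.choice(["White", "Black", "Hispanic", "Other"], size=n_states * per)
    y = rng.poisson(np.exp(1.0 + u))
    df = pd.DataFrame({"y": y, "race": race, "state": state})
    clustered = IRRModel.from_dataframe(df, "y", [], family="poisson").fit()
    import statsmodels.api as sm

    model = IRRModel.from_dataframe(df, "y", [], family="poisson")
    classical = sm.GLM(model.endog, model.exog, family=sm.families.Poisson()).fit()
    assert clustered.bse["const"] > 2 * classical.bse["const"]


def test_irr_ci_is_exactly_exp_of_log_ci(truth_frame):
    _, df = truth_frame
    res = IRRModel.from_dataframe(df, "success_rate", family="poisson").fit()
    np.testing.assert_array_equal(
        res.conf_int_irr().to_numpy(), np.exp(res.conf_int().to_numpy())
    )
    assert (res.irr > 0).all()
    assert (res.conf_int_irr() > 0).all().all()


def test_estimates_invariant_to_row_permutation(truth_frame):
    _, df = truth_frame
    shuffled = df.sample(frac=1.0, random_state=99)
    a = IRRModel.from_dataframe(df, "amount_raised", family="negbin").fit()
    b = IRRModel.from_dataframe(shuffled, "amount_raised", family="negbin").fit()
    assert (a.params - b.params).abs().max() < 1e-10


def test_design_validation_errors(truth_frame):
    _, df = truth_frame
    with pytest.raises(EstimationError, match="rank deficient"):
        bad = df.copy()
        bad["dead"] = 0.0
        IRRModel.from_dataframe(bad, "amount_raised", DEFAULT_COVARIATES + ["dead"])
    with pytest.raises(EstimationError, match="clusters"):
        one = df[df["state"] == df["state"].iloc[0]]
        IRRModel.from_dataframe(one, "amount_raised", [])
    with pytest.raises(ValueError, match="missing columns"):
        IRRModel.from_dataframe(df.drop(columns=["shares"]), "amount_raised")


# ---------------------------------------------------------------------------
# quartile flags


def _rate_panel(values_by_state: dict[str, float], race: str = "White") -> pd.DataFrame:
    return pd.DataFrame(
        [{"state": s, "race": race, "rate": v} for s, v in values_by_state.items()]
    )


def test_quartile_flags_four_distinct_states_flag_one():
    flags = quartile_flags(_rate_panel({"A": 1.0, "B": 2.0, "C": 3.0, "D": 4.0}), "rate")
    assert flags["q4"].sum() == 1
    assert flags.loc[flags["state"] == "D", "q4"].item()


def test_quartile_flags_eight_distinct_states_flag_two():
    flags = quartile_flags(
        _rate_panel({s: float(i) for i, s in enumerate("ABCDEFGH", 1)}), "rate"
    )
    assert flags["q4"].sum() == 2


def test_quartile_flags_degenerate_ties_flag_all():
    flags = quartile_flags(_rate_panel({"A": 2.0, "B": 2.0, "C": 2.0, "D": 2.0}), "rate")
    assert flags["q4"].all()


def test_quartile_flags_too_few_states_raise():
    with pytest.raises(ValueError):
        quartile_flags(_rate_panel({"A": 1.0, "B": 2.0, "C": 3.0}), "rate")


# ---------------------------------------------------------------------------
# sensitivities


def test_sensitivity_runs_apply_their_subset_rules(truth_frame):
    _, df = truth_frame
    table = run_sensitivities(df, "amount_raised", family="negbin")
    assert set(table["run"]) == {
        "base", "solid_only", "exclude_2019", "concordant_only", "high_certainty",
        "race_year_only", "race_year_campaign",
    }
    base_n = table.loc[(table["run"] == "base"), "n"].dropna().iloc[0]
    no2019_n = table.loc[(table["run"] == "exclude_2019"), "n"].dropna().iloc[0]
    assert no2019_n == (df["creation_year"] != 2019).sum()
    thr_n = table.loc[(table["run"] == "high_certainty"), "n"].dropna().iloc[0]
    assert thr_n == df["passes_threshold"].sum()
    assert base_n == len(df)


def test_concordant_subset_on_fully_concordant_data_equals_base(truth_frame):
    _, df = truth_frame
    table = run_sensitivities(df, "amount_raised", family="negbin")
    base = table[(table["run"] == "base") & (table["term"] == "race_Black")]
    conc = table[(table["run"] == "concordant_only") & (table["term"] == "race_Black")]
    assert base["irr"].iloc[0] == pytest.approx(conc["irr"].iloc[0], abs=1e-12)


def test_too_small_subset_reported_not_estimable(truth_frame):
    _, df = truth_frame
    tiny = df.copy()
    tiny["passes_threshold"] = False
    table = run_sensitivities(tiny, "amount_raised", family="negbin")
    row = table[table["run"] == "high_certainty"].iloc[0]
    assert row["estimable"] == False  # noqa: E712
    assert table[table["run"] == "base"]["estimable"].iloc[0] == True  # noqa: E712


def test_fit_model_functional_wrapper(truth_frame):
    _, df = truth_frame
    spec = ModelSpec(outcome="amount_raised", family="negbin")
    res = fit_model(spec, df)
    assert res.nobs == len(df)
    assert res.n_clusters == df["state"].nunique()
    assert "IRR" in res.summary()
    tab = res.to_frame()
    assert {"term", "irr", "ci_low", "pvalue"} <= set(tab.columns)
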