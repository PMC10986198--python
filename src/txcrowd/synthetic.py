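"""Synthetic cohort generator with known ground truth.

Emulates the four pipeline inputs — campaign corpus, city gazetteer,
name/zip probability table, and the state-year-race panel — under a
generative model whose parameters are the study conditions: ~20 000
campaigns over 2015 to March 2019, race mix 52/17/15/16 percent,
negative-binomial donation counts (NB2, alpha 0.8) whose log-mean is linear
in the true covariates, amount raised = donations x a lognormal per-donation
amount, and lognormal goals.  Race effects are multiplicative on the
expected amount raised (Black 0.85, Hispanic 0.80 by default) and, through
goal scaling, on the expected success rate.  Every generated campaign is
recorded in a truth table so downstream stages have closed-loop tests.

All generators are deterministic under a fixed seed: each draws from its own
child stream of ``TruthConfig.seed``, so e.g. the gazetteer is byte-identical
whether or not campaigns are generated afterwards.
"""
from __future__ import annotations

import json
import pathlib

import numpy as np
import pandas as pd

from ._usstates import STATE_CODES
from .config import TruthConfig
from .constants import (
    LABEL_MISSING,
    LABEL_MULTIPLE,
    ORGANS,
    RACE_LEVELS,
    SOLID_ORGANS,
    STUDY_YEARS,
    organ_query_term,
)

# child-stream ids: one independent stream per generator
_STREAM_GAZETTEER = 0
_STREAM_POOL = 1
_STREAM_NAMES = 2
_STREAM_CAMPAIGNS = 3
_STREAM_PANEL = 4

#: z-score of the 0.9 normal quantile: the generative "high fraud" cut.
_FRAUD_Z90 = 1.2815515655446004

_PLATFORMS = [f"platform{i}" for i in range(1, 8)]

_SYL_A = ["Ar", "Bel", "Cor", "Dan", "El", "Fair", "Glen", "Hart", "Ives", "Jor",
          "Kel", "Lor", "Mal", "Nor", "Or", "Pel", "Quin", "Rav", "Sel", "Tor",
          "Ul", "Ver", "Wil", "Xan", "Yor", "Zel"]
_SYL_B = ["ton", "ville", "field", "burg", "ford", "haven", "wood", "dale"]

_RELATIONS = ["sister", "brother", "mother", "father", "daughter", "son", "cousin", "friend"]

_ORGAN_TEMPLATES = [
    "My {relation} urgently needs a {organ} transplant and we cannot afford the hospital bills.",
    "Doctors confirmed {organ} failure last month and a transplant is now the only option left.",
    "We are raising funds for a donor {organ} transplant at the regional medical center.",
]

_MISSING_TEMPLATES = [
    "Please help our family cover the costs of a transplant journey and the long recovery ahead.",
    "Funds will go toward transplant related travel and lodging expenses for the coming months.",
    "After years of illness the doctors say a transplant offers real hope and we need your support.",
]

# organ mentions in non-clinical contexts; never adjacent to a lexicon word
_DISTRACTORS = [
    "She has a heart of gold and never stops smiling.",
    "Their whole community has shown courage and heart through it all.",
    "We trek past the liver colored canyon rocks on our morning walks.",
]

# rule-3 violators: clinical organ story that never uses the word transplant
_NO_TRANSPLANT_TEMPLATE = "Help us pay for {organ} surgery and the long road to recovery."

_YEAR_WEIGHTS = {2015: 1.0, 2016: 1.0, 2017: 1.0, 2018: 1.0, 2019: 0.25}


def _rng(config: TruthConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, stream]))


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: float) -> np.ndarray:
    """NB2 via gamma-Poisson mixture: Var = mean + alpha * mean^2."""
    lam = rng.gamma(shape=1.0 / alpha, scale=alpha * np.asarray(mean, dtype=float))
    return rng.poisson(lam)


# ---------------------------------------------------------------------------
# gazetteer


def generate_gazetteer(config: TruthConfig) -> pd.DataFrame:
    """Synthetic city gazetteer: unique (city, state), zips, planar coordinates.

    States are laid out on a grid with cities scattered around each state
    center, so DBSCAN geometry is controllable; a configurable fraction of
    cities carries the hospital flag.
    """
    rng = _rng(config, _STREAM_GAZETTEER)
    states = STATE_CODES[: config.n_states]
    rows = []
    zip_counter = 10000
    n_b = len(_SYL_B)
    for j, state in enumerate(states):
        cx, cy = (j % 8) * 100.0, (j // 8) * 100.0
        for i in range(config.cities_per_state):
            g = j * config.cities_per_state + i
            a1, rem = divmod(g, len(_SYL_A) * n_b)
            a2, b = divmod(rem, n_b)
            city = _SYL_A[a2] + _SYL_A[a1 % len(_SYL_A)].lower() + _SYL_B[b]
            lat = cx + rng.uniform(-30, 30)
            lon = cy + rng.uniform(-30, 30)
            population = int(np.exp(rng.normal(11.0, 1.0)))
            if config.max_zips_per_city == 1 or rng.random() < config.single_zip_fraction:
                n_zips = 1
            else:
                n_zips = int(rng.integers(2, config.max_zips_per_city + 1))
            zips = tuple(f"{zip_counter + k:05d}" for k in range(n_zips))
            zip_counter += n_zips
            hospital = bool(rng.random() < config.hospital_fraction)
            rows.append((city, state, lat, lon, population, zips, hospital))
    df = pd.DataFrame(rows, columns=["city", "state", "lat", "lon", "population", "zips", "hospital"])
    if df[["city", "state"]].duplicated().any():
        raise RuntimeError("gazetteer (city, state) keys are not unique")
    df.attrs["metric"] = "planar" if config.geometry == "planar" else "haversine"
    return df


# ---------------------------------------------------------------------------
# name pool and name/zip probability table


def _name_pool(config: TruthConfig, gazetteer: pd.DataFrame) -> pd.DataFrame:
    """One synthetic organizer per campaign: name, home city, true race.

    Derived from its own seed stream so the name table and the campaign
    generator reconstruct the identical pool independently.
    """
    rng = _rng(config, _STREAM_POOL)
    n = config.n_campaigns
    races = rng.choice(RACE_LEVELS, size=n, p=[config.race_mix[r] for r in RACE_LEVELS])
    city_idx = rng.integers(0, len(gazetteer), size=n)
    return pd.DataFrame(
        {
            "first": [f"First{i:05d}" for i in range(n)],
            "last": [f"Last{i:05d}" for i in range(n)],
            "race": races,
            "city": gazetteer["city"].to_numpy()[city_idx],
            "state": gazetteer["state"].to_numpy()[city_idx],
            "zips": [gazetteer["zips"].iat[k] for k in city_idx],
        }
    )


def generate_name_table(
    config: TruthConfig, gazetteer: pd.DataFrame, fidelity: float | None = None
) -> pd.DataFrame:
    """Name/zip probability table emulating a recorded onomastic API output.

    One row per (first, last, zip): a probability vector over the four
    categories (columns p_*) summing to 1, the argmax category and its
    probability.  The argmax equals the generating race with probability
    ``fidelity`` (default ``config.name_fidelity``), independently per zip.
    """
    if gazetteer.empty:
        raise ValueError("gazetteer is empty")
    f = config.name_fidelity if fidelity is None else fidelity
    rng = _rng(config, _STREAM_NAMES)
    pool = _name_pool(config, gazetteer)
    rows = []
    for first, last, race, zips in pool[["first", "last", "race", "zips"]].itertuples(index=False):
        for z in zips:
            if rng.random() < f:
                top = race
            else:
                others = [r for r in RACE_LEVELS if r != race]
                top = others[rng.integers(0, 3)]
            p_top = rng.uniform(0.55, 0.95)
            rest = rng.dirichlet(np.ones(3)) * (1.0 - p_top)
            probs = {}
            k = 0
            for r in RACE_LEVELS:
                if r == top:
                    probs[r] = p_top
                else:
                    probs[r] = rest[k]
                    k += 1
            rows.append((first, last, z, top, p_top,
                         probs["White"], probs["Black"], probs["Hispanic"], probs["Other"]))
    return pd.DataFrame(
        rows,
        columns=["first", "last", "zip", "category", "probability",
                 "p_White", "p_Black", "p_Hispanic", "p_Other"],
    )


# ---------------------------------------------------------------------------
# state attributes and panel


def _state_attributes(config: TruthConfig) -> pd.DataFrame:
    """Per (state, race) generative attributes shared by panel and campaigns."""
    rng = _rng(config, _STREAM_PANEL)
    states = STATE_CODES[: config.n_states]
    wla_medians = {"White": 57.6, "Black": 122.6, "Hispanic": 39.2, "Other": 30.0}
    unins_means = {"White": 0.07, "Black": 0.10, "Hispanic": 0.19, "Other": 0.10}
    rows = []
    for state in states:
        medicaid = bool(rng.random() < 0.6)
        total_pop = np.exp(rng.normal(14.0, 0.8))
        for race in RACE_LEVELS:
            insufficient = rng.random() < config.insufficient_fraction
            pop = total_pop * config.race_mix[race] * np.exp(rng.normal(0, 0.3))
            if insufficient:
                pop = rng.uniform(1000, 8000)
            wla_rate = wla_medians[race] * np.exp(rng.normal(0, 0.4))
            mean_u = unins_means[race]
            conc = 50.0
            unins = rng.beta(mean_u * conc, (1 - mean_u) * conc)
            rows.append((state, race, medicaid, int(pop), wla_rate, unins, not insufficient))
    return pd.DataFrame(
        rows,
        columns=["state", "race", "medicaid_expansion", "population",
                 "base_wla_per_100k", "base_uninsured_rate", "sufficient_population"],
    )


def _truth_state_flags(attrs: pd.DataFrame) -> pd.DataFrame:
    """Ground-truth Q4 indicators from the base rates (race-specific quartiles)."""
    out = attrs.copy()
    for col, flag in (("base_wla_per_100k", "q4_wla"), ("base_uninsured_rate", "q4_unins")):
        flags = np.zeros(len(out), dtype=bool)
        for race in RACE_LEVELS:
            m = (out["race"] == race).to_numpy()
            vals = out.loc[m, col].to_numpy(dtype=float)
            if len(vals) >= 4:
                flags[m] = vals >= np.percentile(vals, 75)
        out[flag] = flags
    return out


def generate_state_panel(
    config: TruthConfig, races: tuple[str, ...] = RACE_LEVELS
) -> pd.DataFrame:
    """State x year x race panel of WLAs, uninsurance, population, Medicaid.

    WLAs are Poisson draws around the state-race base rate with a mild
    common year trend; uninsurance wiggles around the base proportion.
    Cells flagged population-insufficient exercise the KFF-style exclusion.
    """
    attrs = _state_attributes(config)
    attrs = attrs[attrs["race"].isin(races)]
    rng = _rng(config, _STREAM_PANEL + 100)
    y_lo, y_hi = config.panel_years
    rows = []
    for state, race, medicaid, pop, wla_rate, unins, sufficient in attrs[
        ["state", "race", "medicaid_expansion", "population", "base_wla_per_100k",
         "base_uninsured_rate", "sufficient_population"]
    ].itertuples(index=False):
        for year in range(y_lo, y_hi + 1):
            trend = 1.0 + 0.02 * (year - y_lo)
            wla = int(rng.poisson(wla_rate * pop / 1e5 * trend))
            u = float(np.clip(unins + rng.normal(0, 0.01), 0.0, 1.0))
            rows.append((state, year, race, wla, u, pop, medicaid, sufficient))
    return pd.DataFrame(
        rows,
        columns=["state", "year", "race", "wla", "uninsured_rate", "population",
                 "medicaid_expansion", "sufficient_population"],
    )


# ---------------------------------------------------------------------------
# campaigns


def _make_story(rng: np.random.Generator, organ: str, distractor: bool) -> str:
    if organ == LABEL_MISSING:
        story = _MISSING_TEMPLATES[rng.integers(0, len(_MISSING_TEMPLATES))]
    else:
        relation = _RELATIONS[rng.integers(0, len(_RELATIONS))]
        tmpl = _ORGAN_TEMPLATES[rng.integers(0, len(_ORGAN_TEMPLATES))]
        story = tmpl.format(relation=relation, organ=organ_query_term(organ))
    if distractor:
        story += " " + _DISTRACTORS[rng.integers(0, len(_DISTRACTORS))]
    return story


def _make_multiple_story(rng: np.random.Generator, distractor: bool) -> str:
    a, b = rng.choice(len(ORGANS), size=2, replace=False)
    relation = _RELATIONS[rng.integers(0, len(_RELATIONS))]
    story = (
        _ORGAN_TEMPLATES[0].format(relation=relation, organ=organ_query_term(ORGANS[a]))
        + " "
        + _ORGAN_TEMPLATES[1].format(organ=organ_query_term(ORGANS[b]))
    )
    if distractor:
        story += " " + _DISTRACTORS[rng.integers(0, len(_DISTRACTORS))]
    return story


def true_coefficients(config: TruthConfig, outcome: str = "amount_raised") -> dict[str, float]:
    """The generative coefficient vector on the model's term names."""
    irr = config.true_irr_amount if outcome != "success_rate" else config.true_irr_success
    coefs = {f"race_{r}": float(np.log(irr[r])) for r in RACE_LEVELS if r != "White"}
    for y in STUDY_YEARS[1:]:
        coefs[f"year_{y}"] = config.year_effect * (y - STUDY_YEARS[0])
    coefs.update(
        shares=config.shares_coef,
        shares_sq=config.shares_sq_coef,
        organizer_not_beneficiary=config.organizer_effect,
        high_fraud=config.fraud_effect,
        solid_organ=config.solid_effect,
        q4_wla=config.q4_wla_effect,
        q4_unins=config.q4_unins_effect,
        medicaid_expansion=config.medicaid_effect,
    )
    return coefs


def generate_campaigns(
    config: TruthConfig,
    gazetteer: pd.DataFrame,
    name_table: pd.DataFrame | None = None,
    stories: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate the campaign corpus and its truth table.

    Returns ``(records, truth)``: records follow the corpus schema (monetary
    fields in integer cents); truth holds per-campaign race, organ, state,
    the labeled exclusion violation (if any), and the true covariate values
    entering the donation-count log-mean.  ``stories=False`` replaces the
    template-generated stories with a minimal placeholder for speed in
    simulation studies that never touch the text.
    """
    rng = _rng(config, _STREAM_CAMPAIGNS)
    n = config.n_campaigns
    pool = _name_pool(config, gazetteer)
    attrs = _truth_state_flags(_state_attributes(config))
    flag_map = {
        (s, r): (q1, q2, m)
        for s, r, q1, q2, m in attrs[
            ["state", "race", "q4_wla", "q4_unins", "medicaid_expansion"]
        ].itertuples(index=False)
    }

    organ_keys = list(config.organ_mix)
    organs = rng.choice(organ_keys, size=n, p=[config.organ_mix[k] for k in organ_keys])
    years = rng.choice(
        list(_YEAR_WEIGHTS), size=n,
        p=np.array(list(_YEAR_WEIGHTS.values())) / sum(_YEAR_WEIGHTS.values()),
    )
    shares = _nb_draw(rng, np.full(n, config.shares_mean), config.shares_alpha)
    org_not_ben = rng.random(n) < config.organizer_not_beneficiary_rate
    fraud = rng.normal(0.0, 1.0, size=n)
    high_fraud = fraud > _FRAUD_Z90
    solid = np.array([o in SOLID_ORGANS for o in organs])

    races = pool["race"].to_numpy()
    q4_wla = np.empty(n, dtype=bool)
    q4_unins = np.empty(n, dtype=bool)
    medicaid = np.empty(n, dtype=bool)
    for i in range(n):
        q4_wla[i], q4_unins[i], medicaid[i] = flag_map[(pool["state"].iat[i], races[i])]

    log_irr_amt = np.array([np.log(config.true_irr_amount[r]) for r in races])
    log_irr_succ = np.array([np.log(config.true_irr_success[r]) for r in races])
    eta = (
        config.base_log_donations
        + log_irr_amt
        + config.year_effect * (years - STUDY_YEARS[0])
        + config.shares_coef * shares
        + config.shares_sq_coef * shares.astype(float) ** 2
        + config.organizer_effect * org_not_ben
        + config.fraud_effect * high_fraud
        + config.solid_effect * solid
        + config.q4_wla_effect * q4_wla
        + config.q4_unins_effect * q4_unins
        + config.medicaid_effect * medicaid
    )
    mu = np.exp(eta)
    donations = _nb_draw(rng, mu, config.dispersion_alpha)
    per_donation = np.exp(rng.normal(config.mean_donation_log, config.sd_donation_log, size=n))
    amount_cents = np.round(donations * per_donation * 100.0)
    goal_cents = np.maximum(
        100.0,
        np.round(np.exp(rng.normal(config.mean_goal_log + log_irr_amt - log_irr_succ,
                                   config.sd_goal_log, size=n)) * 100.0),
    )

    # labeled exclusion violations (first-match attribution order)
    p_rules = np.array([config.frac_non_us, config.frac_invalid,
                        config.frac_no_transplant, config.frac_outlier])
    p_none = 1.0 - p_rules.sum()
    if p_none < 0:
        raise ValueError("exclusion-violation fractions sum to more than 1")
    violation = rng.choice(
        ["none", "non_us", "invalid", "no_transplant", "outlier"],
        size=n, p=np.concatenate([[p_none], p_rules]),
    )

    country = np.where(violation == "non_us",
                       rng.choice(["CA", "MX", "GB"], size=n), "US")
    goal_cents = np.where(violation == "invalid", np.nan, goal_cents)
    is_outlier = violation == "outlier"
    amount_cents = np.where(is_outlier, amount_cents * 1000 + 1e9, amount_cents)
    donations = np.where(is_outlier, donations * 1000 + 10000, donations)

    if stories:
        story_list = []
        for i in range(n):
            distract = bool(rng.random() < config.distractor_fraction)
            if violation[i] == "no_transplant":
                o = organs[i] if organs[i] in ORGANS else "kidney"
                story_list.append(_NO_TRANSPLANT_TEMPLATE.format(organ=organ_query_term(o)))
            elif organs[i] == LABEL_MULTIPLE:
                story_list.append(_make_multiple_story(rng, distract))
            else:
                story_list.append(_make_story(rng, organs[i], distract))
    else:
        story_list = np.where(violation == "no_transplant",
                              "medical fundraiser", "transplant fundraiser").tolist()

    records = pd.DataFrame(
        {
            "url": [f"https://{_PLATFORMS[i % 7]}.example.com/c/{i:06d}" for i in range(n)],
            "platform": [_PLATFORMS[i % 7] for i in range(n)],
            "organizer_first": pool["first"],
            "organizer_last": pool["last"],
            "beneficiary_is_organizer": ~org_not_ben,
            "story": story_list,
            "city": pool["city"],
            "state": pool["state"],
            "country": country,
            "creation_year": years.astype(float),
            "amount_raised_cents": amount_cents,
            "goal_cents": goal_cents,
            "n_donations": donations.astype(float),
            "shares": shares.astype(float),
            "fraud_score": fraud,
        }
    )
    truth = pd.DataFrame(
        {
            "url": records["url"],
            "race": races,
            "organ": organs,
            "state": pool["state"],
            "city": pool["city"],
            "violation": violation,
            "creation_year": years.astype(int),
            "shares": shares.astype(int),
            "organizer_not_beneficiary": org_not_ben,
            "high_fraud": high_fraud,
            "solid_organ": solid,
            "q4_wla": q4_wla,
            "q4_unins": q4_unins,
            "medicaid_expansion": medicaid,
            "mu_donations": mu,
        }
    )
    truth.attrs["true_coef_amount"] = true_coefficients(config, "amount_raised")
    truth.attrs["true_coef_success"] = true_coefficients(config, "success_rate")
    return records, truth


def truth_analysis_frame(records: pd.DataFrame, truth: pd.DataFrame) -> pd.DataFrame:
    """Model-ready frame built from ground-truth labels (no pipeline noise).

    Used for parameter-recovery simulation: outcomes from the records,
    race/state/covariates straight from the truth table, restricted to
    campaigns without a labeled exclusion violation.
    """
    keep = truth["violation"].to_numpy() == "none"
    rec = records.loc[keep].reset_index(drop=True)
    tr = truth.loc[keep].reset_index(drop=True)
    amount = np.round(rec["amount_raised_cents"].to_numpy(dtype=float) / 100.0)
    goal = rec["goal_cents"].to_numpy(dtype=float)
    n_don = rec["n_donations"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        avg = np.where(n_don > 0, np.round(amount / n_don), np.nan)
    df = pd.DataFrame(
        {
            "amount_raised": amount,
            "success_rate": 100.0 * amount * 100.0 / goal,
            "average_donation": avg,
            "race": tr["race"],
            "state": tr["state"],
            "creation_year": tr["creation_year"],
            "shares": tr["shares"].astype(float),
            "shares_sq": tr["shares"].astype(float) ** 2,
            "organizer_not_beneficiary": tr["organizer_not_beneficiary"].astype(float),
            "high_fraud": tr["high_fraud"].astype(float),
            "solid_organ": tr["solid_organ"].astype(float),
            "q4_wla": tr["q4_wla"].astype(float),
            "q4_unins": tr["q4_unins"].astype(float),
            "medicaid_expansion": tr["medicaid_expansion"].astype(float),
        }
    )
    for y in STUDY_YEARS[1:]:
        df[f"year_{y}"] = (df["creation_year"] == y).astype(float)
    return df


# ---------------------------------------------------------------------------
# bundle writer


def write_synthetic_inputs(config: TruthConfig, outdir: str | pathlib.Path) -> dict:
    """Generate and write all four inputs plus truth labels and a manifest."""
    from . import corpus as corpus_io
    from .geo import write_gazetteer

    out = pathlib.Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    gaz = generate_gazetteer(config)
    names = generate_name_table(config, gaz)
    records, truth = generate_campaigns(config, gaz, names)
    panel = generate_state_panel(config)

    write_gazetteer(gaz, str(out / "gazetteer.csv"))
    names.to_csv(out / "name_table.csv", index=False)
    corpus_io.write_corpus_csv(records, str(out / "corpus.csv"))
    corpus_io.write_corpus_jsonl(records, str(out / "corpus.jsonl"))
    truth.to_csv(out / "truth_labels.csv", index=False)
    panel.to_csv(out / "state_panel.csv", index=False)
    manifest = {
        "seed": config.seed,
        "config": json.loads(config.model_dump_json()),
        "files": ["gazetteer.csv", "name_table.csv", "corpus.csv", "corpus.jsonl",
                  "truth_labels.csv", "state_panel.csv"],
        "counts": {"campaigns": len(records), "cities": len(gaz),
                   "name_rows": len(names), "panel_rows": len(panel)},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
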