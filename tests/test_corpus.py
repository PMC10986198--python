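"""Corpus data model: dedup, exclusions, outcomes, covariates, round-trip I/O."""
import io

import numpy as np
import pandas as pd
import pandas.testing as pdt
import pytest
from hypothesis import given, settings, strategies as st

from txcrowd.config import ExclusionConfig
from txcrowd import corpus


def _frame(rows: list[dict]) -> pd.DataFrame:
    base = {
        "url": "https://p.example.com/c/0", "platform": "p",
        "organizer_first": "A", "organizer_last": "B",
        "beneficiary_is_organizer": True, "story": "a transplant story",
        "city": "X", "state": "AA", "country": "US", "creation_year": 2016.0,
        "amount_raised_cents": 100_00.0, "goal_cents": 1000_00.0,
        "n_donations": 4.0, "shares": 2.0, "fraud_score": 0.0,
    }
    return pd.DataFrame([{**base, **r} for r in rows])


# ---------------------------------------------------------------------------
# deduplication


def test_deduplicate_exact_and_canonical_duplicates():
    df = _frame([
        {"url": "https://p.example.com/c/1"},
        {"url": "https://p.example.com/c/1"},
        {"url": "https://P.example.com/c/2/"},
        {"url": "https://p.example.com/c/2?ref=fb"},
        {"url": "https://p.example.com/c/3"},
    ])
    out = corpus.deduplicate(df)
    assert len(out) == 3
    assert out["url"].iloc[0] == "https://p.example.com/c/1"  # first kept


def test_deduplicate_reproduces_search_funnel_counts():
    """55 252 collected urls with 13 687 duplicates leave 41 565 campaigns."""
    n_unique, n_total = 41_565, 55_252
    urls = [f"https://p.example.com/c/{i}" for i in range(n_unique)]
    dupes = [urls[i % n_unique] + "/" for i in range(n_total - n_unique)]
    df = pd.DataFrame({"url": urls + dupes})
    assert len(corpus.deduplicate(df)) == n_unique


@given(st.lists(st.integers(0, 30), min_size=1, max_size=60))
@settings(max_examples=50, deadline=None)
def test_deduplicate_idempotent(ids):
    df = pd.DataFrame({"url": [f"https://p.example.com/c/{i}" for i in ids]})
    once = corpus.deduplicate(df)
    twice = corpus.deduplicate(once)
    pdt.assert_frame_equal(once, twice)


# ---------------------------------------------------------------------------
# exclusions


def test_exclusion_rules_in_order_with_first_match_attribution():
    df = _frame([
        {"url": "u1", "country": "CA", "story": "no transplant word here either"},
        {"url": "u2", "goal_cents": np.nan},
        {"url": "u3", "story": "kidney surgery fund"},
        {"url": "u4", "story": "Transplant needed"},
        {"url": "u5"},
    ])
    kept, audit = corpus.apply_exclusions(df)
    assert audit.removed == {"non_us": 1, "invalid": 1, "no_transplant": 1, "outlier": 0}
    assert set(kept["url"]) == {"u4", "u5"}
    assert audit.retained_count + sum(audit.removed.values()) == audit.input_count


def test_exclusions_empty_input_is_not_an_error():
    kept, audit = corpus.apply_exclusions(_frame([]).iloc[0:0])
    assert len(kept) == 0 and audit.input_count == 0


def test_outlier_rule_flags_exactly_the_record_above_the_quantile():
    rows = [{"url": f"u{i}", "amount_raised_cents": float(1000 + i)} for i in range(999)]
    rows.append({"url": "big", "amount_raised_cents": 1e9})
    kept, audit = corpus.apply_exclusions(_frame(rows))
    assert audit.removed["outlier"] == 1
    assert "big" not in set(kept["url"])


def test_exclusions_idempotent_with_realized_thresholds(small_world):
    records = small_world["records"]
    once, audit = corpus.apply_exclusions(records)
    thresholds = (audit.amount_threshold_cents, audit.donations_threshold)
    twice, audit2 = corpus.apply_exclusions(once, outlier_thresholds=thresholds)
    pdt.assert_frame_equal(once, twice)
    assert sum(audit2.removed.values()) == 0


def test_rules_one_to_three_unconditionally_idempotent(small_world):
    records = small_world["records"]
    cfg = ExclusionConfig(outlier_quantile=0.999)
    once, audit1 = corpus.apply_exclusions(records, cfg)
    twice, audit2 = corpus.apply_exclusions(once, cfg)
    for rule in ("non_us", "invalid", "no_transplant"):
        assert audit2.removed[rule] == 0


# ---------------------------------------------------------------------------
# outcomes


def test_outcome_arithmetic():
    df = _frame([
        {"amount_raised_cents": 1000_00.0, "goal_cents": 1000_00.0, "n_donations": 10.0},
        {"amount_raised_cents": 3050_00.0, "goal_cents": 10000_00.0, "n_donations": 5.0},
        {"amount_raised_cents": 0.0, "goal_cents": 500_00.0, "n_donations": 0.0},
    ])
    out = corpus.compute_outcomes(df)
    assert out["success_rate"].iloc[0] == 100.0
    assert out["success_rate"].iloc[1] == 30.5  # median raised over median goal
    assert out["average_donation"].iloc[1] == 610.0
    assert out["success_rate"].iloc[2] == 0.0
    assert np.isnan(out["average_donation"].iloc[2])


def test_outcomes_require_positive_goal():
    with pytest.raises(corpus.InvalidRecordError):
        corpus.compute_outcomes(_frame([{"goal_cents": 0.0}]))
    with pytest.raises(corpus.InvalidRecordError):
        corpus.compute_outcomes(_frame([{"goal_cents": np.nan}]))


@given(
    st.integers(1, 10**7), st.integers(1, 10**7), st.integers(0, 10**4)
)
@settings(max_examples=200, deadline=None)
def test_outcome_identity_average_donation_times_count(amount_c, goal_c, n_don):
    df = _frame([{"amount_raised_cents": float(amount_c), "goal_cents": float(goal_c),
                  "n_donations": float(n_don)}])
    out = corpus.compute_outcomes(df)
    assert out["success_rate"].iloc[0] >= 0
    if n_don > 0:
        recon = out["average_donation"].iloc[0] * n_don
        assert abs(recon - amount_c / 100.0) < 1e-6 * max(1.0, amount_c / 100.0)


# ---------------------------------------------------------------------------
# covariates


def test_covariate_construction():
    df = _frame([
        {"creation_year": 2015.0, "shares": 10.0, "fraud_score": 2.0,
         "beneficiary_is_organizer": False},
        {"creation_year": 2018.0, "shares": 0.0, "fraud_score": -1.0},
        {"creation_year": np.nan},
    ])
    labels = pd.Series(["kidney", "bone_marrow", "missing"], index=df.index)
    flags = pd.DataFrame(
        {"q4_wla": [1, 0, 0], "q4_unins": [0, 1, 0], "medicaid_expansion": [1, 1, 0]},
        index=df.index,
    )
    cov = corpus.build_covariates(df, labels, fraud_threshold=1.5, state_flags=flags)
    assert cov.loc[0, ["year_2016", "year_2017", "year_2018", "year_2019"]].sum() == 0
    assert cov.loc[1, "year_2018"] == 1
    assert cov.loc[0, "shares_sq"] == 100.0
    assert cov.loc[0, "organizer_not_beneficiary"] == 1.0
    assert cov.loc[0, "high_fraud"] == 1.0 and cov.loc[1, "high_fraud"] == 0.0
    assert cov.loc[0, "solid_organ"] == 1.0 and cov.loc[1, "solid_organ"] == 0.0
    assert not cov.loc[0, "model_exclude"] and bool(cov.loc[2, "model_exclude"])


# ---------------------------------------------------------------------------
# I/O round trip


def test_csv_round_trip_is_lossless(small_world):
    records = small_world["records"].head(200)
    buf = io.StringIO()
    corpus.write_corpus_csv(records, buf)
    buf.seek(0)
    back = corpus.read_corpus_csv(buf)
    pdt.assert_frame_equal(
        records.reset_index(drop=True)[back.columns], back, check_dtype=False
    )


def test_jsonl_round_trip_is_lossless(tmp_path, small_world):
    records = small_world["records"].head(200)
    path = str(tmp_path / "corpus.jsonl")
    corpus.write_corpus_jsonl(records, path)
    back = corpus.read_corpus_jsonl(path)
    pdt.assert_frame_equal(
        records.reset_index(drop=True)[back.columns], back, check_dtype=False
    )
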