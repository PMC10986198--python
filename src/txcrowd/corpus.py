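"""Campaign corpus: data model, I/O, deduplication, exclusions, outcomes.

A corpus is a pandas DataFrame with one row per campaign.  Monetary fields
are held in memory as integer cents (exact decimal arithmetic); on disk they
are dollars with two decimals.  The four exclusion rules are applied in a
fixed order with first-match attribution so the audit is additive:

1. non-US  — scraper identified the campaign as not US-based;
2. invalid — a numeric field is missing or out of range (bad scraper output);
3. story does not contain the word "transplant" (case-insensitive substring);
4. outlier in amount raised and/or number of donations (upper-quantile cut
   computed on the set surviving rules 1-3; realized thresholds are recorded
   in the audit and can be re-supplied for reproducible re-filtering).
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from decimal import Decimal, InvalidOperation
from typing import IO, Iterable

import numpy as np
import pandas as pd

from .config import ExclusionConfig
from .constants import BASELINE_YEAR, SOLID_ORGANS, STUDY_YEARS

#: on-disk column order; `amount_raised` and `goal` are dollars there.
CORPUS_COLUMNS = [
    "url", "platform", "organizer_first", "organizer_last",
    "beneficiary_is_organizer", "story", "city", "state", "country",
    "creation_year", "amount_raised", "goal", "n_donations", "shares",
    "fraud_score",
]

EXCLUSION_RULES = ("non_us", "invalid", "no_transplant", "outlier")


class InvalidRecordError(ValueError):
    """A record violates the corpus contract (e.g. non-positive goal)."""


# ---------------------------------------------------------------------------
# monetary conversion


def dollars_to_cents(value) -> float:
    """Exact dollars→cents; NaN for missing or unparseable input."""
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return np.nan
    try:
        return float(int(Decimal(str(value)).scaleb(2).to_integral_value()))
    except (InvalidOperation, ValueError):
        return np.nan


def cents_to_dollar_str(cents: float) -> str:
    if pd.isna(cents):
        return ""
    c = int(round(cents))
    sign = "-" if c < 0 else ""
    c = abs(c)
    return f"{sign}{c // 100}.{c % 100:02d}"


# ---------------------------------------------------------------------------
# I/O


def _to_memory(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    out["amount_raised_cents"] = [dollars_to_cents(v) for v in out.pop("amount_raised")]
    out["goal_cents"] = [dollars_to_cents(v) for v in out.pop("goal")]
    out["beneficiary_is_organizer"] = out["beneficiary_is_organizer"].astype(bool)
    for col in ("creation_year", "n_donations", "shares"):
        out[col] = pd.to_numeric(out[col], errors="coerce")
    out["fraud_score"] = pd.to_numeric(out["fraud_score"], errors="coerce")
    return out


def _to_disk(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    out["amount_raised"] = [cents_to_dollar_str(v) for v in out.pop("amount_raised_cents")]
    out["goal"] = [cents_to_dollar_str(v) for v in out.pop("goal_cents")]
    return out[CORPUS_COLUMNS]


def read_corpus_csv(path: str | IO) -> pd.DataFrame:
    raw = pd.read_csv(path, dtype={"amount_raised": str, "goal": str, "state": str, "city": str},
                      keep_default_na=True)
    raw["story"] = raw["story"].fillna("")
    raw["state"] = raw["state"].fillna("")
    raw["city"] = raw["city"].fillna("")
    return _to_memory(raw)


def write_corpus_csv(df: pd.DataFrame, path: str | IO) -> None:
    _to_disk(df).to_csv(path, index=False)


def read_corpus_jsonl(path: str) -> pd.DataFrame:
    records = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line:
                records.append(json.loads(line))
    return _to_memory(pd.DataFrame(records, columns=CORPUS_COLUMNS))


def write_corpus_jsonl(df: pd.DataFrame, path: str) -> None:
    disk = _to_disk(df)
    with open(path, "w", encoding="utf-8") as fh:
        for rec in disk.to_dict(orient="records"):
            fh.write(json.dumps(rec, default=_json_default) + "\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, (np.bool_,)):
        return bool(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


# ---------------------------------------------------------------------------
# deduplication


def canonical_url(url: str) -> str:
    """Lowercase, strip the query string and any trailing slash."""
    u = url.strip().lower()
    u = u.split("?", 1)[0]
    return u.rstrip("/")


def deduplicate(records: pd.DataFrame) -> pd.DataFrame:
    """One record per canonical url; the first occurrence is retained."""
    keys = records["url"].map(canonical_url)
    keep = ~keys.duplicated(keep="first")
    return records.loc[keep].reset_index(drop=True)


# ---------------------------------------------------------------------------
# exclusions


@dataclass
class ExclusionAudit:
    """Per-rule removal counts, in application order, plus realized thresholds."""

    input_count: int
    removed: dict[str, int]
    retained_count: int
    amount_threshold_cents: float
    donations_threshold: float
    quantile: float

    def __post_init__(self) -> None:
        assert self.retained_count + sum(self.removed.values()) == self.input_count

    def to_frame(self) -> pd.DataFrame:
        rows = [("input", self.input_count)]
        rows += [(f"removed_{rule}", self.removed[rule]) for rule in EXCLUSION_RULES]
        rows.append(("retained", self.retained_count))
        return pd.DataFrame(rows, columns=["stage", "count"])

    def to_text(self) -> str:
        lines = [f"records in: {self.input_count}"]
        for rule in EXCLUSION_RULES:
            lines.append(f"  removed by {rule}: {self.removed[rule]}")
        lines.append(
            f"  outlier thresholds (q={self.quantile}): "
            f"amount > {cents_to_dollar_str(self.amount_threshold_cents) or 'n/a'} USD, "
            f"donations > {self.donations_threshold}"
        )
        lines.append(f"records retained: {self.retained_count}")
        return "\n".join(lines)


def apply_exclusions(
    records: pd.DataFrame,
    config: ExclusionConfig | None = None,
    outlier_thresholds: tuple[float, float] | None = None,
) -> tuple[pd.DataFrame, ExclusionAudit]:
    """Apply the four exclusion rules in order with first-match attribution.

    ``outlier_thresholds`` (amount cents, donation count) overrides the
    quantile computation, e.g. to re-apply a previous audit's realized cut.
    """
    cfg = config or ExclusionConfig()
    n_in = len(records)
    removed = {rule: 0 for rule in EXCLUSION_RULES}
    if n_in == 0:
        audit = ExclusionAudit(0, removed, 0, np.nan, np.nan, cfg.outlier_quantile)
        return records.copy(), audit

    df = records

    non_us = df["country"].astype(str).str.upper() != "US"
    removed["non_us"] = int(non_us.sum())
    df = df.loc[~non_us]

    invalid = (
        df["amount_raised_cents"].isna()
        | (df["amount_raised_cents"] < 0)
        | df["goal_cents"].isna()
        | (df["goal_cents"] <= 0)
        | df["n_donations"].isna()
        | (df["n_donations"] < 0)
        | df["shares"].isna()
        | (df["shares"] < 0)
    )
    removed["invalid"] = int(invalid.sum())
    df = df.loc[~invalid]

    word = cfg.required_word.lower()
    no_word = ~df["story"].astype(str).str.lower().str.contains(word, regex=False)
    removed["no_transplant"] = int(no_word.sum())
    df = df.loc[~no_word]

    if outlier_thresholds is not None:
        amt_thr, don_thr = outlier_thresholds
    elif len(df):
        amt_thr = float(np.quantile(df["amount_raised_cents"], cfg.outlier_quantile))
        don_thr = float(np.quantile(df["n_donations"], cfg.outlier_quantile))
    else:
        amt_thr = don_thr = np.nan
    if len(df):
        outlier = (df["amount_raised_cents"] > amt_thr) | (df["n_donations"] > don_thr)
        removed["outlier"] = int(outlier.sum())
        df = df.loc[~outlier]

    out = df.reset_index(drop=True)
    audit = ExclusionAudit(
        input_count=n_in,
        removed=removed,
        retained_count=len(out),
        amount_threshold_cents=amt_thr,
        donations_threshold=don_thr,
        quantile=cfg.outlier_quantile,
    )
    return out, audit


# ---------------------------------------------------------------------------
# outcomes and covariates


def compute_outcomes(records: pd.DataFrame) -> pd.DataFrame:
    """Per-campaign outcome metrics.

    - amount_raised: USD;
    - success_rate: percent, 100 x amount / goal (may exceed 100);
    - average_donation: USD, amount / donations, missing when donations = 0;
    - n_donations.
    """
    goal = records["goal_cents"]
    if goal.isna().any() or (goal <= 0).any():
        raise InvalidRecordError("goal must be present and positive for every record")
    amount = records["amount_raised_cents"].astype(float)
    n_don = records["n_donations"].astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        avg = np.where(n_don > 0, amount / 100.0 / n_don, np.nan)
    return pd.DataFrame(
        {
            "amount_raised": amount / 100.0,
            "success_rate": 100.0 * amount / goal.astype(float),
            "average_donation": avg,
            "n_donations": n_don,
        },
        index=records.index,
    )


def build_covariates(
    records: pd.DataFrame,
    organ_labels: pd.Series,
    fraud_threshold: float,
    state_flags: pd.DataFrame,
) -> pd.DataFrame:
    """Model covariates for the adjusted IRR specification.

    Year dummies (baseline 2015), shares and shares squared, an indicator for
    organizer != beneficiary, a high-fraud indicator (score strictly above
    ``fraud_threshold``), a solid-organ indicator, and the three state-level
    indicators (4th-quartile WLA per 100k, 4th-quartile uninsurance, Medicaid
    expansion) supplied row-aligned via ``state_flags``.  Records with a
    missing creation year are flagged for model exclusion, not dropped.
    """
    cov = pd.DataFrame(index=records.index)
    year = records["creation_year"]
    for y in STUDY_YEARS:
        if y == BASELINE_YEAR:
            continue
        cov[f"year_{y}"] = (year == y).astype(float)
    cov["shares"] = records["shares"].astype(float)
    cov["shares_sq"] = cov["shares"] ** 2
    cov["organizer_not_beneficiary"] = (~records["beneficiary_is_organizer"]).astype(float)
    cov["high_fraud"] = (records["fraud_score"] > fraud_threshold).astype(float)
    cov["solid_organ"] = organ_labels.isin(SOLID_ORGANS).astype(float)
    for col in ("q4_wla", "q4_unins", "medicaid_expansion"):
        cov[col] = state_flags[col].astype(float).to_numpy()
    cov["model_exclude"] = year.isna()
    return cov
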