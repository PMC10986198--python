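"""Probabilistic race/ethnicity assignment from name + zip classifications.

The onomastic classifier itself is external; this module consumes its output
through a pluggable probability table keyed by (first name, last name, zip)
and implements the aggregation across a campaign's candidate zip codes:

- **weighted** (primary): for each category c observed as a top category over
  the N zips, score(c) = (n_c / N) x mean(top probability over the n_c zips
  naming c); the assigned category is the argmax of score.  With 7 of 10
  zips naming White at mean probability 0.8, White scores 0.7 x 0.8 = 0.56.
- **max** (sensitivity): the category of the single zip with the highest top
  probability.

Ties break toward the category with more top-category votes, then
alphabetically.  A certainty threshold (strict ``score > tau``) supports the
sensitivity restriction to high-certainty assignments.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, NamedTuple

import pandas as pd

from .constants import RACE_LEVELS

NAME_TABLE_COLUMNS = ["first", "last", "zip", "category", "probability"]


class NameKeyError(KeyError):
    """Requested (first, last, zip) key absent from the probability table."""


class ZipClassification(NamedTuple):
    """Top race/ethnicity category and its probability for one zip code."""

    zip: str
    top_category: str
    top_probability: float


@dataclass(frozen=True)
class RaceAssignment:
    """Aggregated race/ethnicity verdict for one campaign organizer."""

    category: str
    score: float
    n_zips: int
    procedure: str  # "weighted" | "max"
    concordant: bool | None = None
    passes_threshold: bool | None = None


class NameProbabilityTable:
    """Lookup table of top-category probabilities keyed by (first, last, zip).

    Stands in for a commercial onomastic API: rows are the recorded top
    category and probability per name/zip query.  Lookups are pure and an
    absent key raises, never silently defaults.
    """

    def __init__(self, frame: pd.DataFrame):
        missing = set(NAME_TABLE_COLUMNS) - set(frame.columns)
        if missing:
            raise ValueError(f"name table missing columns: {sorted(missing)}")
        bad = set(frame["category"]) - set(RACE_LEVELS)
        if bad:
            raise ValueError(f"name table has unknown categories: {sorted(bad)}")
        self._table: dict[tuple[str, str, str], tuple[str, float]] = {
            (str(f), str(l), str(z)): (c, float(p))
            for f, l, z, c, p in frame[NAME_TABLE_COLUMNS].itertuples(index=False)
        }
        self.frame = frame

    @classmethod
    def from_csv(cls, path: str) -> "NameProbabilityTable":
        return cls(pd.read_csv(path, dtype={"first": str, "last": str, "zip": str}))

    def to_csv(self, path: str) -> None:
        self.frame.to_csv(path, index=False)

    def __len__(self) -> int:
        return len(self._table)

    def classify_zip(self, first: str, last: str, zip_code: str) -> ZipClassification:
        key = (str(first), str(last), str(zip_code))
        try:
            category, prob = self._table[key]
        except KeyError:
            raise NameKeyError(f"no classification recorded for {key}") from None
        return ZipClassification(zip=key[2], top_category=category, top_probability=prob)


def classify_zip(first: str, last: str, zip_code: str, name_table: NameProbabilityTable) -> ZipClassification:
    """Functional wrapper around :meth:`NameProbabilityTable.classify_zip`."""
    return name_table.classify_zip(first, last, zip_code)


def _category_scores(zips: list[ZipClassification]) -> dict[str, tuple[float, int]]:
    """category -> (weighted score, vote count) over observed top categories."""
    n = len(zips)
    scores: dict[str, tuple[float, int]] = {}
    for cat in {z.top_category for z in zips}:
        probs = [z.top_probability for z in zips if z.top_category == cat]
        scores[cat] = (len(probs) / n * (sum(probs) / len(probs)), len(probs))
    return scores


def _pick(candidates: Iterable[tuple[str, float, int]]) -> tuple[str, float]:
    """argmax by score, ties toward more votes, then alphabetical category."""
    best = min(candidates, key=lambda t: (-t[1], -t[2], t[0]))
    return best[0], best[1]


def aggregate_weighted(zip_classifications: Iterable[ZipClassification]) -> RaceAssignment:
    """Vote-share-weighted mean-probability aggregation (primary procedure)."""
    zips = list(zip_classifications)
    if not zips:
        raise ValueError("aggregate_weighted requires at least one zip classification")
    scores = _category_scores(zips)
    category, score = _pick((c, s, n) for c, (s, n) in scores.items())
    return RaceAssignment(category=category, score=score, n_zips=len(zips), procedure="weighted")


def aggregate_max(zip_classifications: Iterable[ZipClassification]) -> RaceAssignment:
    """Highest single top-probability across zips (alternative procedure)."""
    zips = list(zip_classifications)
    if not zips:
        raise ValueError("aggregate_max requires at least one zip classification")
    votes = {z.top_category: sum(1 for y in zips if y.top_category == z.top_category) for z in zips}
    best_p = max(z.top_probability for z in zips)
    candidates = [
        (z.top_category, z.top_probability, votes[z.top_category])
        for z in zips
        if z.top_probability == best_p
    ]
    category, score = _pick(candidates)
    return RaceAssignment(category=category, score=score, n_zips=len(zips), procedure="max")


def assign(zip_classifications: Iterable[ZipClassification], tau: float = 0.6) -> RaceAssignment:
    """Full per-campaign assignment: weighted procedure, concordance, threshold."""
    zips = list(zip_classifications)
    weighted = aggregate_weighted(zips)
    alt = aggregate_max(zips)
    weighted = replace(weighted, concordant=(weighted.category == alt.category))
    return apply_threshold(weighted, tau)


def apply_threshold(assignment: RaceAssignment, tau: float = 0.6) -> RaceAssignment:
    """Set ``passes_threshold`` = (score strictly greater than tau)."""
    if not (0.0 < tau < 1.0):
        raise ValueError(f"certainty threshold must be in (0, 1), got {tau}")
    return replace(assignment, passes_threshold=assignment.score > tau)


def assign_corpus(
    records: pd.DataFrame,
    zip_sets: pd.Series,
    name_table: NameProbabilityTable,
    tau: float = 0.6,
) -> pd.DataFrame:
    """Assign race/ethnicity for every record with a non-empty zip set.

    ``zip_sets`` is row-aligned with ``records`` and holds the candidate zip
    codes from geographic resolution.  Returns a frame keyed by url with the
    weighted assignment, the alternative procedure's category, concordance,
    multi-category flag, and the certainty threshold verdict.
    """
    rows = []
    for idx, rec in records.iterrows():
        zips = zip_sets.loc[idx]
        if not zips:
            continue
        cls = [name_table.classify_zip(rec["organizer_first"], rec["organizer_last"], z)
               for z in sorted(zips)]
        weighted = aggregate_weighted(cls)
        alt = aggregate_max(cls)
        weighted = apply_threshold(
            replace(weighted, concordant=(weighted.category == alt.category)), tau
        )
        rows.append(
            {
                "url": rec["url"],
                "race": weighted.category,
                "score": weighted.score,
                "n_zips": weighted.n_zips,
                "race_max": alt.category,
                "score_max": alt.score,
                "concordant": weighted.concordant,
                "passes_threshold": weighted.passes_threshold,
                "multi_category": len({c.top_category for c in cls}) > 1,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["url", "race", "score", "n_zips", "race_max", "score_max",
                 "concordant", "passes_threshold", "multi_category"],
    )
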