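"""Geographic resolution and the three-subset query planner.

Self-reported "city, state" strings are resolved against a city gazetteer;
unresolved locations fall back to rule-based scanning of the story text for
"City, ST" or full state-name mentions (host mention preferred over
beneficiary mention).  The query planner reproduces the geographically
stratified search strategy: hospital cities, the k largest population
centers per state, and DBSCAN clusters grown around seed campaign
locations, with population-coverage statistics for the combined plan.

Distances are Euclidean on planar synthetic coordinates or haversine
kilometres on geodetic ones; the metric is declared in the gazetteer header.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import DBSCAN

from ._usstates import STATE_NAMES
from .constants import ORGANS, organ_query_term

EARTH_RADIUS_KM = 6371.0

GAZETTEER_COLUMNS = ["city", "state", "lat", "lon", "population", "zips", "hospital"]


# ---------------------------------------------------------------------------
# gazetteer I/O


def read_gazetteer(path: str) -> pd.DataFrame:
    """Read a gazetteer table; the `# metric=` header line sets the geometry."""
    metric = "planar"
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
        if first.startswith("#"):
            m = re.search(r"metric\s*=\s*(\w+)", first)
            if m:
                metric = m.group(1)
            df = pd.read_csv(fh, dtype={"zips": str})
        else:
            fh.seek(0)
            df = pd.read_csv(fh, dtype={"zips": str})
    df["zips"] = df["zips"].map(lambda s: tuple(s.split(";")) if isinstance(s, str) and s else ())
    df["hospital"] = df["hospital"].astype(bool)
    df.attrs["metric"] = metric
    return df


def write_gazetteer(gazetteer: pd.DataFrame, path: str) -> None:
    out = gazetteer.copy()
    out["zips"] = out["zips"].map(";".join)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# metric={gazetteer.attrs.get('metric', 'planar')}\n")
        out[GAZETTEER_COLUMNS].to_csv(fh, index=False)


def _coords(gazetteer: pd.DataFrame) -> np.ndarray:
    return gazetteer[["lat", "lon"]].to_numpy(dtype=float)


def pairwise_distance(a: np.ndarray, b: np.ndarray, metric: str) -> np.ndarray:
    """All-pairs distances between coordinate arrays (n,2) x (m,2)."""
    if metric == "planar":
        diff = a[:, None, :] - b[None, :, :]
        return np.sqrt((diff**2).sum(axis=2))
    if metric == "haversine":
        lat1, lon1 = np.radians(a[:, 0])[:, None], np.radians(a[:, 1])[:, None]
        lat2, lon2 = np.radians(b[:, 0])[None, :], np.radians(b[:, 1])[None, :]
        h = (
            np.sin((lat2 - lat1) / 2) ** 2
            + np.cos(lat1) * np.cos(lat2) * np.sin((lon2 - lon1) / 2) ** 2
        )
        return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0, 1)))
    raise ValueError(f"unknown metric {metric!r}")


# ---------------------------------------------------------------------------
# location resolution


@dataclass(frozen=True)
class GeoResolution:
    """Outcome of resolving one campaign's location.

    status: not_US | resolved | completed | missing.  ``resolved`` means the
    reported city/state matched the gazetteer (zip set non-empty);
    ``completed`` means the state was recovered from the story text.
    """

    status: str
    state: str | None = None
    zip_codes: frozenset[str] = field(default_factory=frozenset)
    source: str | None = None  # reported | story_host | story_beneficiary


_CITY_STATE_RE = re.compile(r"([A-Z][A-Za-z]*(?: [A-Z][A-Za-z]*)*),\s*([A-Z]{2})\b")
_BENEFICIARY_CUE = re.compile(r"beneficiary|for (?:my|his|her|their)\b", re.IGNORECASE)
_STATE_NAME_RE = re.compile(
    r"\b(" + "|".join(re.escape(n) for n in STATE_NAMES.values()) + r")\b"
)
_STATE_BY_NAME = {name: code for code, name in STATE_NAMES.items()}


def _gazetteer_index(gazetteer: pd.DataFrame) -> dict[tuple[str, str], tuple[str, tuple[str, ...]]]:
    return {
        (str(c).lower(), str(s).upper()): (str(s).upper(), tuple(z))
        for c, s, z in gazetteer[["city", "state", "zips"]].itertuples(index=False)
    }


def resolve_location(
    record: pd.Series,
    gazetteer: pd.DataFrame,
    story: str | None = None,
    _index: dict | None = None,
) -> GeoResolution:
    """Resolve a campaign's state and candidate zip codes.

    Order: non-US marker; exact (city, state) gazetteer match of the reported
    location; story scan for gazetteer-listed "City, ST" mentions (host cues
    preferred over beneficiary cues) and then for full state names; missing.
    """
    if str(record.get("country", "US")).upper() != "US":
        return GeoResolution(status="not_US")

    index = _index if _index is not None else _gazetteer_index(gazetteer)
    key = (str(record.get("city", "")).lower(), str(record.get("state", "")).upper())
    hit = index.get(key)
    if hit is not None:
        state, zips = hit
        return GeoResolution(status="resolved", state=state,
                             zip_codes=frozenset(zips), source="reported")

    text = story if story is not None else str(record.get("story", ""))
    host_hit = bene_hit = None
    for m in _CITY_STATE_RE.finditer(text):
        mention = index.get((m.group(1).lower(), m.group(2)))
        if mention is None:
            continue
        context = text[max(0, m.start() - 40): m.start()]
        is_beneficiary = bool(_BENEFICIARY_CUE.search(context))
        if is_beneficiary and bene_hit is None:
            bene_hit = mention
        elif not is_beneficiary and host_hit is None:
            host_hit = mention
    if host_hit is None and bene_hit is None:
        for m in _STATE_NAME_RE.finditer(text):
            code = _STATE_BY_NAME[m.group(1)]
            if (gazetteer["state"] == code).any():
                context = text[max(0, m.start() - 40): m.start()]
                src = "story_beneficiary" if _BENEFICIARY_CUE.search(context) else "story_host"
                return GeoResolution(status="completed", state=code, source=src)
    if host_hit is not None:
        state, zips = host_hit
        return GeoResolution(status="completed", state=state,
                             zip_codes=frozenset(zips), source="story_host")
    if bene_hit is not None:
        state, zips = bene_hit
        return GeoResolution(status="completed", state=state,
                             zip_codes=frozenset(zips), source="story_beneficiary")
    return GeoResolution(status="missing")


def resolve_corpus(records: pd.DataFrame, gazetteer: pd.DataFrame) -> pd.DataFrame:
    """Resolve every record; returns status/state/zips/source aligned by index."""
    index = _gazetteer_index(gazetteer)
    rows = [resolve_location(rec, gazetteer, _index=index) for _, rec in records.iterrows()]
    return pd.DataFrame(
        {
            "status": [r.status for r in rows],
            "state": [r.state for r in rows],
            "zip_codes": [r.zip_codes for r in rows],
            "source": [r.source for r in rows],
        },
        index=records.index,
    )


# ---------------------------------------------------------------------------
# query planning


@dataclass
class QueryPlan:
    """Union of the three city subsets and the resulting query strings."""

    hospital_cities: list[tuple[str, str]]
    top_cities: list[tuple[str, str]]
    cluster_cities: list[tuple[str, str]]
    cities: list[tuple[str, str]]
    queries: list[str]
    eps: float
    min_pts: int
    cluster_labels: np.ndarray  # per seed location, -1 = noise

    @property
    def n_clusters(self) -> int:
        labels = set(self.cluster_labels.tolist()) - {-1}
        return len(labels)


def plan_queries(
    gazetteer: pd.DataFrame,
    seed_locations: list[tuple[str, str]],
    k: int = 25,
    eps: float = 50.0,
    min_pts: int = 1,
) -> QueryPlan:
    """Build the three-subset query plan.

    Subset 1: hospital-flagged cities.  Subset 2: top-k cities by population
    within each state (ties broken by city name).  Subset 3: every gazetteer
    city within ``eps`` of a DBSCAN cluster grown over the seed locations
    (``min_pts=1`` makes every seed found a cluster).  Queries are the
    deduplicated strings "{organ} transplant in {City}, {ST}" over the seven
    organ terms and the union of subsets.
    """
    if gazetteer.empty:
        raise ValueError("gazetteer is empty")
    if eps <= 0:
        raise ValueError("eps must be positive")
    metric = gazetteer.attrs.get("metric", "planar")

    hospital = [
        (c, s) for c, s, h in gazetteer[["city", "state", "hospital"]].itertuples(index=False) if h
    ]

    ranked = gazetteer.sort_values(
        ["state", "population", "city"], ascending=[True, False, True], kind="mergesort"
    )
    top = [
        (row.city, row.state)
        for _, grp in ranked.groupby("state", sort=True)
        for row in grp.head(k).itertuples(index=False)
    ]

    city_index = {(c.lower(), s): i for i, (c, s) in
                  enumerate(gazetteer[["city", "state"]].itertuples(index=False))}
    seed_rows = []
    for city, state in seed_locations:
        i = city_index.get((city.lower(), state.upper()))
        if i is not None:
            seed_rows.append(i)
    cluster_cities: list[tuple[str, str]] = []
    labels = np.empty(0, dtype=int)
    if seed_rows:
        seeds = _coords(gazetteer)[seed_rows]
        if metric == "haversine":
            db = DBSCAN(eps=eps / EARTH_RADIUS_KM, min_samples=min_pts, metric="haversine")
            labels = db.fit_predict(np.radians(seeds))
        else:
            db = DBSCAN(eps=eps, min_samples=min_pts, metric="euclidean")
            labels = db.fit_predict(seeds)
        clustered = seeds[labels >= 0]
        if len(clustered):
            d = pairwise_distance(_coords(gazetteer), clustered, metric)
            near = (d <= eps).any(axis=1)
            cluster_cities = [
                (c, s) for (c, s), keep in
                zip(gazetteer[["city", "state"]].itertuples(index=False, name=None), near) if keep
            ]

    cities = sorted(set(hospital) | set(top) | set(cluster_cities))
    queries = sorted(
        {f"{organ_query_term(o)} transplant in {c}, {s}" for o in ORGANS for c, s in cities}
    )
    return QueryPlan(
        hospital_cities=sorted(set(hospital)),
        top_cities=sorted(set(top)),
        cluster_cities=sorted(set(cluster_cities)),
        cities=cities,
        queries=queries,
        eps=eps,
        min_pts=min_pts,
        cluster_labels=labels,
    )


def coverage_stats(plan: QueryPlan, gazetteer: pd.DataFrame, r: float) -> tuple[float, float]:
    """Fractions of gazetteer cities and population within ``r`` of the plan."""
    if r <= 0:
        raise ValueError("coverage radius must be positive")
    if not plan.cities:
        return 0.0, 0.0
    metric = gazetteer.attrs.get("metric", "planar")
    planned = set(plan.cities)
    mask = [
        (c, s) in planned
        for c, s in gazetteer[["city", "state"]].itertuples(index=False, name=None)
    ]
    d = pairwise_distance(_coords(gazetteer), _coords(gazetteer.loc[mask]), metric)
    near = (d <= r).any(axis=1)
    pop = gazetteer["population"].to_numpy(dtype=float)
    return float(near.mean()), float(pop[near].sum() / pop.sum())
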