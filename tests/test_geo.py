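"""Geographic resolution, query planning, DBSCAN oracle, coverage."""
import numpy as np
import pandas as pd
import pytest

from txcrowd import geo
from txcrowd.geo import (
    GeoResolution,
    QueryPlan,
    coverage_stats,
    plan_queries,
    resolve_location,
)


def _gazetteer(rows):
    df = pd.DataFrame(rows, columns=["city", "state", "lat", "lon", "population",
                                     "zips", "hospital"])
    df.attrs["metric"] = "planar"
    return df


@pytest.fixture
def gaz():
    return _gazetteer([
        ("Providence", "RI", 0.0, 0.0, 100_000, ("02901", "02902"), True),
        ("Austin", "TX", 500.0, 0.0, 900_000, ("73301",), True),
        ("Selwood", "TX", 510.0, 0.0, 50_000, ("73399",), False),
        ("Norville", "RI", 5.0, 5.0, 20_000, ("02990",), False),
    ])


def _record(city="", state="", story="", country="US"):
    return pd.Series({"city": city, "state": state, "story": story, "country": country})


# ---------------------------------------------------------------------------
# resolution


def test_reported_location_resolves_with_zip_set(gaz):
    r = resolve_location(_record(city="Providence", state="RI"), gaz)
    assert r.status == "resolved" and r.state == "RI"
    assert r.zip_codes == {"02901", "02902"} and r.source == "reported"


def test_story_host_mention_completes_bad_location(gaz):
    r = resolve_location(_record(city="???", story="My family lives in Austin, TX these days."), gaz)
    assert r.status == "completed" and r.state == "TX" and r.source == "story_host"


def test_beneficiary_mention_used_when_no_host_mention(gaz):
    r = resolve_location(
        _record(story="This fund is for my cousin in Austin, TX and her care."), gaz
    )
    assert r.status == "completed" and r.source == "story_beneficiary"


def test_state_name_mention_completes_state_only(gaz):
    r = resolve_location(_record(story="We recently moved to Texas for treatment."), gaz)
    assert r.status == "completed" and r.state == "TX" and len(r.zip_codes) == 0


def test_missing_and_non_us(gaz):
    assert resolve_location(_record(story="no location at all"), gaz).status == "missing"
    assert resolve_location(_record(country="CA"), gaz).status == "not_US"


def test_resolution_never_invents_a_state(small_world):
    res = geo.resolve_corpus(small_world["records"], small_world["gazetteer"])
    states = set(small_world["gazetteer"]["state"])
    found = set(res["state"].dropna())
    assert found <= states


# ---------------------------------------------------------------------------
# query planning


def test_topk_larger_than_state_city_count_takes_all(gaz):
    plan = plan_queries(gaz, [], k=25, eps=10.0)
    assert set(plan.top_cities) == set(
        gaz[["city", "state"]].itertuples(index=False, name=None)
    )


def test_far_apart_seeds_form_two_clusters(gaz):
    plan = plan_queries(gaz, [("Providence", "RI"), ("Austin", "TX")], eps=50.0, min_pts=1)
    assert plan.n_clusters == 2
    # every seed city is inside some cluster's eps-neighborhood
    assert {("Providence", "RI"), ("Austin", "TX")} <= set(plan.cluster_cities)


def test_no_hospitals_no_seeds_leaves_topk_only():
    g = _gazetteer([
        ("Aton", "AA", 0, 0, 10, ("00001",), False),
        ("Bton", "AA", 1, 1, 20, ("00002",), False),
    ])
    plan = plan_queries(g, [], k=1, eps=5.0)
    assert plan.hospital_cities == [] and plan.cluster_cities == []
    assert plan.cities == [("Bton", "AA")]  # larger population wins


def test_plan_is_monotone_in_hospitals_and_seeds(gaz):
    base = plan_queries(gaz, [], k=1, eps=20.0)
    with_seed = plan_queries(gaz, [("Selwood", "TX")], k=1, eps=20.0)
    assert set(base.cities) <= set(with_seed.cities)
    g2 = gaz.copy()
    g2.attrs["metric"] = "planar"
    g2.loc[g2["city"] == "Norville", "hospital"] = True
    with_hosp = plan_queries(g2, [], k=1, eps=20.0)
    assert set(base.cities) <= set(with_hosp.cities)


def test_empty_gazetteer_and_bad_eps_raise(gaz):
    with pytest.raises(ValueError):
        plan_queries(gaz.iloc[0:0], [])
    with pytest.raises(ValueError):
        plan_queries(gaz, [], eps=0.0)


# ---------------------------------------------------------------------------
# DBSCAN vs density-reachability oracle


def _dbscan_oracle(points: np.ndarray, eps: float, min_pts: int) -> np.ndarray:
    """Brute-force density reachability: BFS from core points."""
    n = len(points)
    d = np.sqrt(((points[:, None, :] - points[None, :, :]) ** 2).sum(axis=2))
    neighbors = [np.flatnonzero(d[i] <= eps) for i in range(n)]
    core = [len(nb) >= min_pts for nb in neighbors]  # neighborhood includes self
    labels = np.full(n, -1)
    cluster = 0
    for i in range(n):
        if labels[i] != -1 or not core[i]:
            continue
        queue = [i]
        labels[i] = cluster
        while queue:
            j = queue.pop()
            if not core[j]:
                continue
            for nb in neighbors[j]:
                if labels[nb] == -1:
                    labels[nb] = cluster
                    if core[nb]:
                        queue.append(nb)
        cluster += 1
    return labels


def _same_partition(a: np.ndarray, b: np.ndarray) -> bool:
    noise_match = np.array_equal(a == -1, b == -1)
    mapping: dict[int, int] = {}
    for x, y in zip(a, b):
        if x == -1:
            continue
        if mapping.setdefault(x, y) != y:
            return False
    return noise_match and len(set(mapping.values())) == len(mapping)


@pytest.mark.parametrize("seed,eps,min_pts", [
    (0, 0.3, 1), (1, 0.3, 3), (2, 0.5, 2), (3, 0.2, 4), (4, 1.0, 1),
])
def test_dbscan_matches_density_reachability_oracle(seed, eps, min_pts):
    rng = np.random.default_rng(seed)
    pts = rng.uniform(0, 3, size=(50, 2))
    from sklearn.cluster import DBSCAN

    sk = DBSCAN(eps=eps, min_samples=min_pts).fit_predict(pts)
    oracle = _dbscan_oracle(pts, eps, min_pts)
    # border points can legitimately attach to either adjacent cluster; with
    # min_pts small this does not arise, and partitions must agree exactly
    assert _same_partition(sk, oracle)


# ---------------------------------------------------------------------------
# coverage


def test_full_plan_covers_everything(gaz):
    plan = plan_queries(gaz, [], k=25, eps=10.0)
    cities, pop = coverage_stats(plan, gaz, r=1.0)
    assert cities == 1.0 and pop == 1.0


def test_empty_plan_covers_nothing(gaz):
    empty = QueryPlan([], [], [], [], [], eps=1.0, min_pts=1,
                      cluster_labels=np.empty(0, dtype=int))
    assert coverage_stats(empty, gaz, r=10.0) == (0.0, 0.0)


def test_three_city_line_population_weighted_coverage():
    g = _gazetteer([
        ("Aton", "AA", 0.0, 0.0, 1000, ("00001",), True),
        ("Bton", "AA", 0.0, 5.0, 3000, ("00002",), False),
        ("Cton", "AA", 0.0, 100.0, 6000, ("00003",), False),
    ])
    plan = plan_queries(g, [], k=1, eps=1.0)  # hospital Aton + top-1 Cton
    assert set(plan.cities) == {("Aton", "AA"), ("Cton", "AA")}
    cities, pop = coverage_stats(plan, g, r=6.0)
    assert cities == 1.0 and pop == 1.0
    cities2, pop2 = coverage_stats(plan, g, r=4.0)
    assert cities2 == pytest.approx(2 / 3)
    assert pop2 == pytest.approx((1000 + 6000) / 10000)


def test_bad_radius_raises(gaz):
    plan = plan_queries(gaz, [], k=1, eps=1.0)
    with pytest.raises(ValueError):
        coverage_stats(plan, gaz, r=0.0)
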