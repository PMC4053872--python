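"""Space-time scan statistic: window enumeration, likelihood arithmetic,
Monte-Carlo inference, and agreement with an independent brute-force oracle."""

import math

import numpy as np
import pandas as pd
import pytest

import greyscan as gs
from greyscan.errors import DomainError
from greyscan.scan import (
    ScanParams,
    enumerate_cylinders,
    expected_counts,
    max_interval_length,
    monte_carlo_pvalues,
    window_stats,
)


def brute_force_most_likely(panel, dinfo, max_pop_fraction=0.5, max_time_fraction=0.5):
    """Independent slow re-derivation of the most likely cluster.

    Plain nested loops and math.log only: every center district, every
    centroid-to-centroid radius, members by direct distance comparison, the
    population cap from study-average populations, every admissible year
    interval, and the one-sided Poisson LLR evaluated term by term.  Returns
    (member frozenset, year_start, year_end, llr) under the same tie-break
    order as the scan (fewer members, then lexicographic ids, then interval).
    """
    years = sorted(set(int(y) for y in panel["year"]))
    max_len = max(1, math.floor(max_time_fraction * len(years) + 1e-9))
    names = list(dinfo["district"])
    xy = {r.district: (r.x, r.y) for r in dinfo.itertuples()}
    avg_pop = {d: panel[panel.district == d]["population"].mean() for d in names}
    total_avg = sum(avg_pop.values())
    C = float(panel["admissions"].sum())
    total_pop = float(panel["population"].sum())
    g = C / total_pop

    def llr_of(members, y0, y1):
        O = E = 0.0
        for r in panel.itertuples():
            if r.district in members and y0 <= r.year <= y1:
                O += r.admissions
                E += g * r.population
        if O <= E:
            return 0.0
        val = O * math.log(O / E)
        if C - O > 0:
            val += (C - O) * math.log((C - O) / (C - E))
        return val

    candidates = set()
    for center in names:
        cx, cy = xy[center]
        radii = sorted(math.dist((cx, cy), xy[d]) for d in names)
        for radius in radii:
            members = frozenset(
                d for d in names if math.dist((cx, cy), xy[d]) <= radius + 1e-12
            )
            if sum(avg_pop[d] for d in members) / total_avg > max_pop_fraction:
                continue
            candidates.add(members)
    best = None
    for members in candidates:
        for a in range(len(years)):
            for b in range(a, min(a + max_len, len(years))):
                llr = llr_of(members, years[a], years[b])
                key = (-llr, len(members), tuple(sorted(members)), years[a], years[b])
                if best is None or key < best[0]:
                    best = (key, members, years[a], years[b], llr)
    return best[1], best[2], best[3], best[4]


def random_fixture_panel(n_districts, n_years, seed):
    rng = np.random.default_rng(seed)
    names = [f"D{i}" for i in range(n_districts)]
    rows = []
    for d in names:
        pop = int(rng.integers(500, 5000))
        for y in range(2000, 2000 + n_years):
            rows.append((d, y, pop, int(rng.integers(0, 60))))
    panel = pd.DataFrame(rows, columns=["district", "year", "population", "admissions"])
    coords = rng.uniform(0, 100, size=(n_districts, 2))
    dinfo = pd.DataFrame(
        {"district": names, "x": coords[:, 0], "y": coords[:, 1],
         "hospitals": [1] * n_districts}
    )
    return panel, dinfo


class TestEnumerate:
    def test_two_equal_districts_two_years_give_four_cylinders(self, hand_panel, hand_district_info):
        cyls = enumerate_cylinders(hand_district_info, hand_panel)
        assert len(cyls) == 4
        assert all(len(c.member_districts) == 1 for c in cyls)
        assert all(c.year_start == c.year_end for c in cyls)

    def test_count_matches_hand_enumeration_without_caps(self):
        # 3 collinear districts, equal populations, 3 years, no caps:
        # bases {A},{B},{C},{A,B},{B,C},{A,B,C} (6 distinct member sets)
        # x 6 contiguous intervals = 36 windows
        panel, _ = random_fixture_panel(3, 3, seed=0)
        panel["population"] = 1000
        dinfo = pd.DataFrame(
            {"district": ["D0", "D1", "D2"], "x": [0.0, 1.0, 2.0],
             "y": [0.0, 0.0, 0.0], "hospitals": [1, 1, 1]}
        )
        cyls = enumerate_cylinders(dinfo, panel, max_pop_fraction=1.0, max_time_fraction=1.0)
        assert len(cyls) == 36

    def test_single_district_single_interval(self):
        panel = pd.DataFrame(
            [("A", 1, 100, 1), ("B", 1, 100, 1)],
            columns=["district", "year", "population", "admissions"],
        )
        dinfo = pd.DataFrame(
            {"district": ["A", "B"], "x": [0.0, 1.0], "y": [0.0, 0.0], "hospitals": [1, 1]}
        )
        cyls = enumerate_cylinders(dinfo, panel, max_pop_fraction=0.5, max_time_fraction=1.0)
        assert len(cyls) == 2  # each single district x the single year

    def test_empty_panel_rejected(self, hand_district_info):
        with pytest.raises(DomainError):
            enumerate_cylinders(hand_district_info, pd.DataFrame(columns=["district", "year", "population", "admissions"]))

    @pytest.mark.parametrize("n_years, frac, expected", [(2, 0.5, 1), (10, 0.5, 5), (3, 1.0, 3), (10, 0.01, 1)])
    def test_max_interval_length(self, n_years, frac, expected):
        assert max_interval_length(n_years, frac) == expected


class TestWindowStats:
    def test_hand_computed_llr_and_relative_risk(self, hand_panel, hand_district_info):
        cyls = enumerate_cylinders(hand_district_info, hand_panel)
        cyl = next(c for c in cyls if c.member_districts == {"B"} and c.year_start == 2)
        O, E, llr, rr = window_stats(cyl, hand_panel)
        assert (O, E) == (30.0, 15.0)
        assert llr == pytest.approx(30 * np.log(2) + 30 * np.log(30 / 45), abs=1e-12)
        assert llr == pytest.approx(8.630, abs=1e-3)
        assert rr == pytest.approx(3.0)

    def test_llr_zero_when_observed_at_or_below_expected(self, hand_panel, hand_district_info):
        cyls = enumerate_cylinders(hand_district_info, hand_panel)
        low = next(c for c in cyls if c.member_districts == {"A"} and c.year_start == 1)
        O, E, llr, rr = window_stats(low, hand_panel)
        assert llr == 0.0 and O < E

    def test_equal_observed_expected_means_unit_relative_risk(self):
        panel = pd.DataFrame(
            [("A", 1, 100, 10), ("B", 1, 100, 10)],
            columns=["district", "year", "population", "admissions"],
        )
        dinfo = pd.DataFrame(
            {"district": ["A", "B"], "x": [0.0, 1.0], "y": [0.0, 0.0], "hospitals": [1, 1]}
        )
        cyl = enumerate_cylinders(dinfo, panel, max_time_fraction=1.0)[0]
        O, E, llr, rr = window_stats(cyl, panel)
        assert O == E and llr == 0.0 and rr == pytest.approx(1.0)

    def test_expected_counts_are_population_proportional(self, hand_panel):
        e = expected_counts(hand_panel)
        assert e.sum() == pytest.approx(hand_panel["admissions"].sum())
        assert e.nunique() == 1  # equal populations -> equal expectations


class TestMonteCarlo:
    def test_zero_llr_window_has_p_one(self, hand_panel, hand_district_info):
        cyls = enumerate_cylinders(hand_district_info, hand_panel)
        pvals = monte_carlo_pvalues(hand_panel, cyls, n_replicates=99, seed=5)
        for c, p in zip(cyls, pvals):
            if window_stats(c, hand_panel)[2] == 0.0:
                assert p == 1.0

    def test_pvalues_invariant_to_cylinder_order(self, hand_panel, hand_district_info):
        cyls = enumerate_cylinders(hand_district_info, hand_panel)
        p_fwd = monte_carlo_pvalues(hand_panel, cyls, n_replicates=99, seed=5)
        p_rev = monte_carlo_pvalues(hand_panel, cyls[::-1], n_replicates=99, seed=5)
        np.testing.assert_allclose(p_fwd, p_rev[::-1])


class TestDetect:
    def test_hand_panel_most_likely_cluster(self, hand_panel, hand_district_info):
        res = gs.detect_clusters(hand_panel, hand_district_info, ScanParams(n_replicates=99, seed=1))
        top = res[0]
        assert top.districts == ("B",)
        assert (top.cylinder.year_start, top.cylinder.year_end) == (2, 2)
        assert top.llr == pytest.approx(8.630, abs=1e-3)
        assert top.relative_risk == pytest.approx(3.0)

    def test_no_admissions_returns_empty_list(self, hand_district_info):
        empty = pd.DataFrame(
            [("A", 1, 100, 0), ("B", 1, 100, 0)],
            columns=["district", "year", "population", "admissions"],
        )
        assert gs.detect_clusters(empty, hand_district_info) == []

    @pytest.mark.parametrize("n_districts, n_years, seed", [
        (2, 2, 1), (3, 2, 2), (3, 3, 3), (4, 3, 4), (4, 3, 5), (4, 2, 6),
    ])
    def test_agrees_with_brute_force_oracle(self, n_districts, n_years, seed):
        panel, dinfo = random_fixture_panel(n_districts, n_years, seed)
        members, y0, y1, llr = brute_force_most_likely(panel, dinfo)
        res = gs.detect_clusters(panel, dinfo, ScanParams(n_replicates=19, seed=seed))
        top = res[0]
        assert frozenset(top.districts) == members
        assert (top.cylinder.year_start, top.cylinder.year_end) == (y0, y1)
        assert top.llr == pytest.approx(llr, rel=1e-12)

    def test_secondary_clusters_are_significant_and_disjoint(self):
        panel = gs.generate_panel(gs.null_config(seed=42), with_points=False)
        panel = gs.inject_cluster(panel, ["D01", "D06"], range(2008, 2013), 3.0, seed=42)
        panel = gs.inject_cluster(panel, ["D05"], range(2003, 2006), 4.0, seed=43)
        res = gs.detect_clusters(panel.records, panel.district_info,
                                 ScanParams(n_replicates=199, seed=7))
        assert len(res) >= 2
        seen = set()
        for i, r in enumerate(res):
            if i > 0:
                assert r.p_value <= 0.05
                assert not (set(r.districts) & seen)
            seen |= set(r.districts)
        llrs = [r.llr for r in res]
        assert llrs == sorted(llrs, reverse=True)
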