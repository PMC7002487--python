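"""Sighting filters, dyadic day tallies and the half-weight index."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from finsoc.associations import (
    dyad_counts,
    dyad_sightings_predictor,
    filter_sightings,
    gregariousness_predictor,
    hwi,
    validate_sightings,
)
from finsoc.dyadmatrix import DyadMatrix

from conftest import make_sightings


class TestFilterSightings:
    def test_individual_at_threshold_is_excluded(self):
        # the inclusion rule is strictly-greater-than the threshold
        rows = [(f"d{k}", f"g{k}", "A") for k in range(11)]
        rows += [(f"d{k}", f"g{k}b", "B") for k in range(12)]
        rec, ids = filter_sightings(make_sightings(rows), min_sightings=11)
        assert ids == ["B"]

    def test_poorly_identified_group_dropped(self):
        # 7 of 10 estimated members identified: 0.70 < 0.75
        rows = [("d1", "g1", f"I{k}", 10) for k in range(7)]
        rows += [(f"d{k}", f"g{k}", "I0") for k in range(2, 4)]
        rec, _ = filter_sightings(make_sightings(rows),
                                  min_identified_fraction=0.75, min_sightings=1)
        assert "g1" not in set(rec["group_id"])

    def test_identical_resighted_group_dropped(self):
        rows = [("d1", "g1", "A"), ("d1", "g1", "B"),
                ("d1", "g2", "A"), ("d1", "g2", "B"),  # same members, later group
                ("d2", "g3", "A"), ("d2", "g3", "B")]
        rec, _ = filter_sightings(make_sightings(rows), min_sightings=1)
        assert "g2" not in set(rec["group_id"])
        # first-per-day rule keeps each individual once per day
        assert rec.groupby(["date", "individual_id"]).size().max() == 1

    def test_sex_restriction_and_empty_error(self, toy_sightings):
        rec, ids = filter_sightings(toy_sightings, min_sightings=1,
                                    sexed_females={"A", "B"})
        assert set(ids) == {"A", "B"}
        with pytest.raises(ValueError, match="no individuals retained"):
            filter_sightings(toy_sightings, min_sightings=99)

    def test_duplicate_row_rejected(self, toy_sightings):
        bad = pd.concat([toy_sightings, toy_sightings.iloc[[0]]])
        with pytest.raises(ValueError, match="duplicate"):
            validate_sightings(bad)


class TestDyadCounts:
    def test_textbook_tallies(self, toy_sightings):
        c = dyad_counts(toy_sightings, ["A", "B"])
        ab = c.dyad("A", "B")
        assert ab == {"x": 2, "yA": 1, "yB": 1, "yAB": 0, "d": 3.0}

    def test_same_day_different_groups_is_yab(self):
        rows = [("d1", "g1", "A"), ("d1", "g2", "B")]
        c = dyad_counts(make_sightings(rows))
        assert c.dyad("A", "B") == {"x": 0, "yA": 0, "yB": 0, "yAB": 1, "d": 1.0}

    def test_unknown_id_raises(self, toy_sightings):
        with pytest.raises(ValueError, match="ZZ"):
            dyad_counts(toy_sightings, ["A", "ZZ"])

    def test_day_partition_exhaustive(self, small_truth_and_surveys):
        """Each (dyad, day) falls in exactly one tally; totals recount."""
        _, _, surveys = small_truth_and_surveys
        rec, ids = filter_sightings(surveys, min_sightings=5)
        c = dyad_counts(rec, ids)
        # brute-force recount from the raw table
        days = {i: set(rec.loc[rec.individual_id == i, "date"]) for i in ids}
        groups = {
            i: set(map(tuple, rec.loc[rec.individual_id == i, ["date", "group_id"]].values))
            for i in ids
        }
        rng = np.random.default_rng(0)
        for _ in range(60):
            a, b = rng.choice(len(ids), size=2, replace=False)
            i, j = ids[a], ids[b]
            both = days[i] & days[j]
            x = len({d for d, g in groups[i] if (d, g) in groups[j]})
            got = c.dyad(i, j)
            assert got["x"] == x
            assert got["yAB"] == len(both) - x
            assert got["yA"] == len(days[i] - days[j])
            assert got["yB"] == len(days[j] - days[i])


class TestHWI:
    @pytest.mark.parametrize(
        "tallies, expected",
        [((2, 1, 1, 0), 2 / 3), ((5, 0, 0, 0), 1.0), ((0, 3, 4, 2), 0.0)],
    )
    def test_formula(self, tallies, expected):
        x, ya, yb, yab = tallies
        c_x = np.array([[0, x], [x, 0]])
        c_yab = np.array([[0, yab], [yab, 0]])
        alone = np.array([[0, ya], [yb, 0]])
        from finsoc.associations import DyadCounts
        c = DyadCounts(ids=["A", "B"], x=c_x, yab=c_yab, alone=alone)
        assert hwi(c)["A", "B"] == pytest.approx(expected)

    def test_bounds_and_relabeling(self, small_truth_and_surveys):
        _, _, surveys = small_truth_and_surveys
        rec, ids = filter_sightings(surveys, min_sightings=5)
        h = hwi(dyad_counts(rec, ids))
        v = h.dyad_values()
        assert (v >= 0).all() and (v <= 1).all()
        perm = list(reversed(ids))
        h2 = hwi(dyad_counts(rec, perm))
        np.testing.assert_allclose(h2.reindex(ids).values, h.values)


class TestPredictors:
    def test_gregariousness_hand_computed(self):
        # 4-individual toy HWI; predictor is log of exclusive-sum products
        w = np.array([
            [0.0, 0.5, 0.2, 0.1],
            [0.5, 0.0, 0.3, 0.0],
            [0.2, 0.3, 0.0, 0.4],
            [0.1, 0.0, 0.4, 0.0],
        ])
        g = gregariousness_predictor(DyadMatrix(list("abcd"), w))
        sums = w.sum(axis=1)
        for i, j in [(0, 1), (0, 2), (2, 3)]:
            expect = np.log((sums[i] - w[i, j]) * (sums[j] - w[i, j]))
            assert g.values[i, j] == pytest.approx(expect)

    def test_constant_hwi_gives_constant_predictor(self):
        w = np.full((5, 5), 0.3)
        np.fill_diagonal(w, 0)
        g = gregariousness_predictor(DyadMatrix(list("abcde"), w))
        assert np.ptp(g.dyad_values()) < 1e-12

    def test_hub_dyads_exceed_peripheral(self):
        w = np.full((8, 8), 0.1)
        np.fill_diagonal(w, 0)
        w[0, 1:] = w[1:, 0] = 0.8  # node 0 is a hub
        g = gregariousness_predictor(DyadMatrix(list("abcdefgh"), w))
        assert g.values[0, 2] > g.values[2, 3]

    def test_single_individual_rejected(self):
        with pytest.raises(ValueError):
            gregariousness_predictor(DyadMatrix(["a"], np.zeros((1, 1))))

    def test_dyad_sightings_recount(self, toy_sightings):
        m = dyad_sightings_predictor(toy_sightings, ["A", "B", "C"])
        # A seen 3 days, B seen 3 days, C seen 3 days
        assert m["A", "B"] == 6.0
        np.testing.assert_allclose(m.values, m.values.T)

    @given(st.integers(1, 30), st.integers(1, 30))
    @settings(max_examples=20, deadline=None)
    def test_dyad_sightings_is_sum(self, na, nb):
        rows = [(f"d{k}", f"ga{k}", "A") for k in range(na)]
        rows += [(f"e{k}", f"gb{k}", "B") for k in range(nb)]
        m = dyad_sightings_predictor(make_sightings(rows), ["A", "B"])
        assert m["A", "B"] == na + nb
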