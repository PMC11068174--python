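"""Accuracy statistics and error-grid geometry."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from nirmetab.errorgrids import (load_parkes_t1d, load_rate_grid, parkes_zone,
                                 rate_grid_zone)
from nirmetab.metrics import (accuracy_report, mad, mard, rate_grid_summary,
                              rate_pairs, stratified_accuracy)


class TestMadMard:
    def test_hand_values(self):
        ref = np.array([100.0, 200.0])
        pred = np.array([110.0, 190.0])
        assert mad(ref, pred) == pytest.approx(10.0)
        assert mard(ref, pred) == pytest.approx(7.5)

    def test_perfect_fit_is_zero(self):
        ref = np.array([80.0, 120.0, 300.0])
        assert mad(ref, ref) == 0.0 and mard(ref, ref) == 0.0

    def test_constant_shift_identity(self):
        ref = np.array([90.0, 150.0, 240.0])
        assert mad(ref, ref - 12.5) == pytest.approx(12.5)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(c=st.floats(0.1, 10))
    def test_mard_scale_invariant(self, c):
        ref = np.array([50.0, 100.0, 400.0])
        pred = np.array([55.0, 90.0, 410.0])
        assert mard(c * ref, c * pred) == pytest.approx(mard(ref, pred))

    def test_mad_bounded_by_mard_consistency(self):
        rng = np.random.default_rng(0)
        ref = rng.uniform(40, 400, 200)
        pred = ref + rng.normal(0, 10, 200)
        m, r = mad(ref, pred), mard(ref, pred)
        assert ref.min() * r / 100 <= m <= ref.max() * r / 100

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ValueError):
            mard(np.array([0.0, 100.0]), np.array([1.0, 100.0]))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mad(np.ones(3), np.ones(4))


class TestStratified:
    def test_boundary_convention_left_closed(self):
        ref = np.array([69.9, 70.0])
        table = stratified_accuracy(ref, ref + 1.0)
        hypo = table[table.stratum == "40-70"].iloc[0]
        eu = table[table.stratum == "70-180"].iloc[0]
        assert hypo.n == 1 and eu.n == 1

    def test_single_stratum_reproduces_overall(self):
        ref = np.array([100.0, 120.0, 150.0])
        pred = ref + np.array([5.0, -5.0, 10.0])
        table = stratified_accuracy(ref, pred)
        eu = table[table.stratum == "70-180"].iloc[0]
        assert eu.mad == pytest.approx(mad(ref, pred))
        assert eu.mard == pytest.approx(mard(ref, pred))

    def test_hand_computed_mixed_set(self):
        ref = np.array([50.0, 60.0, 100.0, 160.0, 200.0, 400.0])
        pred = np.array([55.0, 54.0, 110.0, 150.0, 190.0, 440.0])
        table = stratified_accuracy(ref, pred).set_index("stratum")
        assert table.loc["40-70", "n"] == 2
        assert table.loc["40-70", "mad"] == pytest.approx(5.5)
        assert table.loc["40-70", "mard"] == pytest.approx(10.0)
        assert table.loc["70-180", "mad"] == pytest.approx(10.0)
        assert table.loc[">180", "mad"] == pytest.approx(25.0)
        assert table.n.sum() == 6

    def test_below_range_reported_not_dropped(self):
        ref = np.array([35.0, 100.0])
        table = stratified_accuracy(ref, ref)
        assert table[table.stratum == "<40"].iloc[0].n == 1

    def test_empty_stratum_null_metrics(self):
        ref = np.array([100.0, 120.0])
        table = stratified_accuracy(ref, ref).set_index("stratum")
        assert table.loc[">180", "n"] == 0
        assert pd.isna(table.loc[">180", "mad"])


class TestParkesGrid:
    def test_identity_line_is_zone_a(self):
        for v in (80.0, 350.0, 40.0, 550.0):
            assert parkes_zone(v, v) == "A"

    def test_published_vertex_case(self):
        # hypoglycemic reference with gross overestimate: three boundaries
        # above the identity line are crossed
        assert parkes_zone(70.0, 350.0) == "D"

    def test_extreme_underestimate(self):
        assert parkes_zone(550.0, 50.0) == "D"

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            parkes_zone(600.0, 100.0)

    def test_lattice_tiles_plane_and_matches_polygon_route(self):
        """Every lattice point gets exactly one zone, and an independent
        shapely point-in-polygon construction from the same vertex table
        agrees (boundary points excluded: the conventions differ there)."""
        shapely = pytest.importorskip("shapely")
        from shapely.geometry import Point, Polygon, box

        geometry = load_parkes_t1d()
        ref, pred = np.meshgrid(np.arange(0, 551, 10.3),
                                np.arange(0, 551, 10.3))
        zones = parkes_zone(ref.ravel(), pred.ravel(), geometry)
        assert set(zones) <= set("ABCDE")  # total classification

        # independent route: build the A polygon from the AB boundaries,
        # closing through the top-right and origin corners of the plane
        up = geometry.boundaries[("AB", "upper")]
        lo = geometry.boundaries[("AB", "lower")]
        ring = np.vstack([up, [[550.0, 550.0]], lo[::-1], [[0.0, 0.0]]])
        zone_a = Polygon(ring).intersection(box(0, 0, 550, 550))
        pts = np.column_stack([ref.ravel(), pred.ravel()])
        inside_a = np.array([zone_a.covers(Point(x, y)) for x, y in pts[:2000]])
        mine_a = zones[:2000] == "A"
        # agreement off the boundary polylines
        disagree = np.nonzero(inside_a != mine_a)[0]
        for i in disagree:
            x, y = pts[i]
            assert zone_a.boundary.distance(Point(x, y)) < 1e-6

    def test_monotone_away_from_identity(self):
        """Moving the prediction away from the identity line never improves
        the zone letter."""
        order = {z: i for i, z in enumerate("ABCDE")}
        for ref in np.arange(10.0, 550.0, 27.0):
            ups = [order[z] for z in
                   parkes_zone(np.full(40, ref), np.linspace(ref, 550, 40))]
            downs = [order[z] for z in
                     parkes_zone(np.full(40, ref), np.linspace(ref, 0, 40))]
            assert all(b >= a for a, b in zip(ups, ups[1:]))
            assert all(b >= a for a, b in zip(downs, downs[1:]))


class TestRateGrid:
    def test_hand_rate_value(self):
        rr, pr = rate_pairs(np.array([0.0, 5.0]), np.array([100.0, 110.0]),
                            np.array([100.0, 110.0]))
        assert rr[0] == pytest.approx(2.0)

    def test_constant_series_zero_rates(self):
        t = np.arange(0.0, 30.0, 5.0)
        rr, pr = rate_pairs(t, np.full(6, 120.0), np.full(6, 118.0))
        assert not rr.any() and not pr.any()

    def test_reversal_negates_rates(self):
        t = np.arange(0.0, 30.0, 5.0)
        v = np.array([100.0, 110.0, 105.0, 130.0, 120.0, 140.0])
        rr, _ = rate_pairs(t, v, v)
        rr_rev, _ = rate_pairs(t, v[::-1], v[::-1])
        np.testing.assert_allclose(rr_rev, -rr[::-1])

    def test_gap_filtering(self):
        t = np.array([0.0, 5.0, 30.0, 35.0])
        rr, _ = rate_pairs(t, t * 2, t * 2)  # 25-min gap excluded
        assert len(rr) == 2

    def test_perfect_rates_all_zone_a(self):
        rates = np.linspace(-3, 3, 20)
        summary = rate_grid_summary(rates, rates)
        assert summary["A"] == 1.0

    def test_fractions_sum_to_one(self, rng):
        rr = rng.normal(0, 2, 100)
        pr = rr + rng.normal(0, 1.5, 100)
        summary = rate_grid_summary(rr, pr)
        assert sum(summary[z] for z in "ABCDE") == pytest.approx(1.0, abs=1e-9)

    def test_single_gross_outlier(self):
        rr = np.zeros(10)
        pr = np.zeros(10)
        pr[4] = 3.0  # outside the B band (|error| > 2 mg/dl/min)
        summary = rate_grid_summary(rr, pr)
        assert summary["A+B"] == pytest.approx(0.9)


class TestAccuracyReport:
    def test_report_integrity(self, default_report):
        for analyte, rep in default_report.accuracy.items():
            assert rep.mad >= 0
            if rep.mard is not None:
                assert rep.mard >= 0
            if rep.parkes_fractions is not None:
                assert sum(rep.parkes_fractions.values()) == pytest.approx(1.0, abs=1e-9)
            if rep.strata is not None:
                assert rep.strata.n.sum() == rep.n

    def test_non_glucose_skips_grid(self):
        t = np.arange(0.0, 50.0, 5.0)
        ref = np.linspace(1.0, 3.0, 10)
        rep = accuracy_report(t, ref, ref + 0.1, analyte="lactate")
        assert rep.parkes_fractions is None and rep.strata is None
        assert rep.mad == pytest.approx(0.1)
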