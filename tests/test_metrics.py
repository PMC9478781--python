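"""Error metrics: multiplets, misassigned area, summaries, Wilcoxon."""

import numpy as np
import pytest
from scipy import stats as sps
from shapely.geometry import box

from trrlink import (count_multiplets, misassigned_area,
                     misassignment_records, summarize, wilcoxon_signed_rank)
from trrlink.geoio import Layer
from trrlink.linkage import AssignmentSet
from trrlink.metrics import MisassignmentRecord, compare_methods
from trrlink.trr import Trr

from conftest import exact_wilcoxon_oracle


def make_trr(trr_id="G1", geom=None):
    geom = geom if geom is not None else box(0, 0, 2, 1)
    return Trr(trr_id, geom, ("H1",), ("C1",))


def units_layer(**geoms):
    layer = Layer()
    for k, v in geoms.items():
        layer.add(k, v)
    return layer


class TestMultiplets:
    def test_spatial_assignments_have_none(self):
        aset = AssignmentSet("spatial", "tract",
                             {"U1": frozenset({"G1"})}, [], [])
        rep = count_multiplets(aset, units_layer(U1=box(0, 0, 2, 2)),
                               [make_trr()])
        assert rep.n_multiplets == 0
        assert rep.double_assigned_area == 0.0

    def test_single_multiplet_counts_its_area(self):
        aset = AssignmentSet("zip", "tract",
                             {"U1": frozenset({"G1", "G2"})}, [], [])
        rep = count_multiplets(aset, units_layer(U1=box(0, 0, 2, 2)),
                               [make_trr()])
        assert rep.n_multiplets == 1
        assert rep.double_assigned_area == pytest.approx(4.0)
        assert rep.pct_of_total_trr_area == pytest.approx(100.0 * 4 / 2)

    def test_empty_assignments(self):
        aset = AssignmentSet("zip", "tract", {}, [], [])
        rep = count_multiplets(aset, Layer(), [make_trr()])
        assert rep.n_multiplets == 0


class TestMisassignedArea:
    def test_rectangle_decomposition(self):
        rec = misassigned_area(make_trr(),
                               [box(0, 0, 1, 1), box(1, 0, 3, 1)],
                               "zip", "tract")
        assert rec.area_outside == pytest.approx(1.0)
        assert rec.area_uncovered == pytest.approx(0.0)
        assert rec.total_misassigned == pytest.approx(1.0)
        assert rec.pct_misassigned == pytest.approx(50.0)

    def test_exact_tiling_gives_zero(self):
        rec = misassigned_area(make_trr(),
                               [box(0, 0, 1, 1), box(1, 0, 2, 1)],
                               "spatial", "tract")
        assert rec.total_misassigned == pytest.approx(0.0, abs=1e-12)
        assert rec.pct_misassigned == pytest.approx(0.0, abs=1e-9)

    def test_no_units_means_fully_uncovered(self):
        rec = misassigned_area(make_trr(), [], "zip", "tract")
        assert rec.area_outside == 0.0
        assert rec.area_uncovered == pytest.approx(2.0)
        assert rec.pct_misassigned == pytest.approx(100.0)

    def test_percent_can_exceed_100(self):
        rec = misassigned_area(make_trr(), [box(0, 0, 10, 10)],
                               "zip", "tract")
        assert rec.pct_misassigned > 100.0

    def test_zero_area_trr_rejected(self):
        from shapely.geometry import Polygon
        with pytest.raises(ValueError):
            misassigned_area(Trr("G1", Polygon(), (), ()), [], "zip", "tract")

    def test_decomposition_identity_on_pipeline_run(self, misaligned_run):
        """outside + uncovered == symmetric difference, every TRR."""
        from trrlink import symmetric_difference_area, dissolve
        result, _ = misaligned_run
        for (method, scale), records in result["records"].items():
            aset = result["linked"][(method, scale)]
            units = result["clipped"][scale]
            for rec in records:
                trr = next(t for t in result["trrs"]
                           if t.trr_id == rec.trr_id)
                geoms = [units[u] for u in aset.units_of(trr.trr_id)
                         if u in units]
                if geoms:
                    sd = symmetric_difference_area(trr.geometry,
                                                   dissolve(geoms))
                else:
                    sd = trr.geometry.area
                assert rec.total_misassigned == pytest.approx(
                    sd, rel=1e-9, abs=1e-9)


class TestSummarize:
    def records(self, values):
        return [MisassignmentRecord("zip", "tract", f"G{i}", 0.0, 0.0,
                                    float(v), float(v))
                for i, v in enumerate(values)]

    def test_symmetric_triple(self):
        s = summarize(self.records([10, 20, 30]))
        assert (s.mean_pct, s.sd_pct, s.median_pct) == (20.0, 10.0, 20.0)
        assert (s.min_pct, s.max_pct) == (10.0, 30.0)

    def test_single_record_flags_undefined_sd(self):
        s = summarize(self.records([5.0]))
        assert s.sd_pct == 0.0
        assert s.sd_undefined

    def test_matches_two_pass_oracle_on_102_records(self):
        rng = np.random.default_rng(11)
        vals = rng.gamma(2.0, 10.0, 102)
        s = summarize(self.records(vals))
        # independent two-pass mean/SD
        mean = sum(vals) / len(vals)
        sd = (sum((v - mean) ** 2 for v in vals) / (len(vals) - 1)) ** 0.5
        assert s.mean_pct == pytest.approx(mean, rel=1e-9)
        assert s.sd_pct == pytest.approx(sd, rel=1e-9)
        assert s.median_pct == pytest.approx(float(np.median(vals)), rel=1e-9)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            summarize([])


class TestWilcoxon:
    def test_all_positive_triple(self):
        res = wilcoxon_signed_rank([1.0, 2.0, 3.0])
        assert res.w_plus == 6.0
        assert res.p_value == pytest.approx(0.25)
        assert res.exact

    def test_mixed_signs_triple(self):
        res = wilcoxon_signed_rank([1.0, 2.0, -3.0])
        assert res.w_plus == 3.0
        assert res.p_value == pytest.approx(1.0)

    def test_single_observation(self):
        res = wilcoxon_signed_rank([5.0])
        assert res.w_plus == 1.0
        assert res.p_value == pytest.approx(1.0)

    def test_all_zero_is_degenerate(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank([0.0, 0.0])

    def test_zeros_dropped_and_counted(self):
        res = wilcoxon_signed_rank([0.0, 1.0, 2.0, 0.0])
        assert res.n_zeros_dropped == 2
        assert res.n_used == 2

    @pytest.mark.parametrize("seed", range(8))
    def test_exact_p_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 11))
        # integer differences force ties with positive probability
        d = rng.integers(-4, 5, n).astype(float)
        d = d[d != 0]
        if len(d) == 0:
            d = np.array([1.0])
        res = wilcoxon_signed_rank(d)
        w_oracle, p_oracle = exact_wilcoxon_oracle(d)
        assert res.w_plus == pytest.approx(w_oracle)
        assert res.p_value == pytest.approx(p_oracle, abs=1e-12)

    @pytest.mark.parametrize("seed", range(3))
    def test_exact_mode_agrees_with_scipy_without_ties(self, seed):
        rng = np.random.default_rng(100 + seed)
        d = rng.normal(0.3, 1.0, 10)  # continuous: no ties, no zeros
        res = wilcoxon_signed_rank(d)
        ref = sps.wilcoxon(d, alternative="two-sided", mode="exact")
        w_ref = min(ref.statistic, len(d) * (len(d) + 1) / 2 - ref.statistic)
        assert min(res.w_plus,
                   len(d) * (len(d) + 1) / 2 - res.w_plus) == w_ref
        assert res.p_value == pytest.approx(ref.pvalue, abs=1e-9)

    def test_large_n_approximation_close_to_scipy(self):
        rng = np.random.default_rng(42)
        d = rng.normal(0.4, 1.0, 60)
        res = wilcoxon_signed_rank(d)
        ref = sps.wilcoxon(d, alternative="two-sided", mode="approx",
                           correction=True)
        assert not res.exact
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-6)


class TestCompareMethods:
    def recs(self, method, values):
        return [MisassignmentRecord(method, "tract", f"G{i}", 0, 0,
                                    float(v), float(v))
                for i, v in enumerate(values)]

    def test_pairs_on_trr_id(self):
        a = self.recs("zip", [10, 20, 30])
        b = self.recs("spatial", [9, 18, 27])
        out = compare_methods(a, b)
        assert out["pct"].w_plus == 6.0
        assert out["pct"].p_value == pytest.approx(0.25)

    def test_disjoint_trr_sets_rejected(self):
        a = self.recs("zip", [10])
        b = [MisassignmentRecord("spatial", "tract", "OTHER", 0, 0, 1, 1)]
        with pytest.raises(ValueError):
            compare_methods(a, b)
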