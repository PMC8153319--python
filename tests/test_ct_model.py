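import io

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from refstab import (
    CtTableError,
    efficiency_from_dilution,
    flag_unstable_by_range,
    read_ct_table,
    summarize,
)
from refstab.ct_model import CtTable


def long_text(rows):
    head = "gene\tsample\ttissue\treplicate\tct\n"
    return head + "\n".join("\t".join(map(str, r)) for r in rows)


class TestReadCtTable:
    def test_long_layout_record_count(self):
        rows = [
            (f"g{i}", f"s{j}", f"t{j}", 1, 20 + i + 0.1 * j)
            for i in range(19)
            for j in range(6)
        ]
        ct = read_ct_table(io.StringIO(long_text(rows)), layout="long")
        assert len(ct) == 114
        assert len(ct.genes) == 19 and len(ct.samples) == 6

    def test_packaged_survey_shape(self, schima_ct):
        assert len(schima_ct) == 114
        assert set(schima_ct.tissues) == {"leaf", "bud", "fruit", "phloem", "root", "xylem"}

    def test_wide_layout_with_annotation(self):
        wide = "gene\ts1\ts2\ng1\t20\t21\ng2\t22\t23\n"
        ann = pd.DataFrame({"sample": ["s1", "s2"], "tissue": ["a", "b"], "replicate": [1, 1]})
        ct = read_ct_table(io.StringIO(wide), layout="wide", samples=ann)
        assert len(ct) == 4
        assert ct.to_matrix().loc["g2", "b"] == 23

    def test_missing_cell_reported_with_coordinates(self):
        rows = [("g1", "s1", "t1", 1, 20.0), ("g1", "s2", "t2", 1, "NA")]
        with pytest.raises(CtTableError, match="g1.*s2"):
            read_ct_table(io.StringIO(long_text(rows)), layout="long")

    def test_duplicate_pair_rejected(self):
        rows = [("g1", "s1", "t1", 1, 20.0), ("g1", "s1", "t1", 2, 21.0)]
        with pytest.raises(CtTableError, match="duplicate"):
            read_ct_table(io.StringIO(long_text(rows)), layout="long")

    def test_nonpositive_ct_rejected(self):
        rows = [("g1", "s1", "t1", 1, -3.0)]
        with pytest.raises(CtTableError, match="non-positive"):
            read_ct_table(io.StringIO(long_text(rows)), layout="long")

    def test_unknown_layout(self):
        with pytest.raises(CtTableError, match="layout"):
            read_ct_table(io.StringIO("gene\tct\n"), layout="sideways")


class TestSummarize:
    def test_overall_means_match_survey(self, schima_summary):
        pg = schima_summary.per_gene
        assert pg.loc["SsuMet2", "overall_mean"] == pytest.approx(18.032, abs=1e-3)
        assert pg.loc["SsuMDH", "overall_mean"] == pytest.approx(25.556, abs=1e-3)
        assert pg.loc["SsuCas", "range_ct"] == pytest.approx(13.099, abs=1e-3)

    def test_replicates_collapse_first(self):
        rows = [("g1", f"t1_{r}", "t1", r, 20.0) for r in (1, 2, 3)]
        ct = CtTable(pd.DataFrame(rows, columns=["gene", "sample", "tissue", "replicate", "ct"]))
        s = summarize(ct)
        row = s.per_tissue.iloc[0]
        assert row["mean_ct"] == 20 and row["sd_ct"] == 0 and row["n"] == 3
        assert s.per_gene.loc["g1", "range_ct"] == 0

    def test_record_order_invariance(self, schima_ct, rng):
        shuffled = CtTable(schima_ct.data.sample(frac=1, random_state=7))
        a = summarize(schima_ct).per_gene.sort_index()
        b = summarize(shuffled).per_gene.sort_index()
        pd.testing.assert_frame_equal(a, b)

    def test_single_replicate_overall_equals_direct(self, rng):
        # one replicate per tissue: per-gene stats over tissue means equal raw stats
        from tests.conftest import random_ct_matrix

        mat = random_ct_matrix(rng)
        rows = [
            (g, c, c, 1, mat.loc[g, c]) for g in mat.index for c in mat.columns
        ]
        ct = CtTable(pd.DataFrame(rows, columns=["gene", "sample", "tissue", "replicate", "ct"]))
        s = summarize(ct)
        assert np.allclose(s.per_gene["overall_mean"], mat.mean(axis=1))
        assert np.allclose(s.per_gene["range_ct"], mat.max(axis=1) - mat.min(axis=1))


class TestRangeFlag:
    def test_survey_flags(self, schima_summary):
        assert flag_unstable_by_range(schima_summary, 4.0) == {
            "SsuCas",
            "SsuUBC17",
            "SsuUBC2",
            "SsuUDP",
        }

    def test_extreme_thresholds(self, schima_summary):
        assert flag_unstable_by_range(schima_summary, 0.0) == set(
            schima_summary.per_gene.index
        )
        assert flag_unstable_by_range(schima_summary, 14.0) == set()

    @pytest.mark.parametrize("lo,hi", [(0, 2), (2, 4), (4, 13.1)])
    def test_monotone_in_threshold(self, schima_summary, lo, hi):
        assert flag_unstable_by_range(schima_summary, hi) <= flag_unstable_by_range(
            schima_summary, lo
        )


class TestEfficiency:
    def test_perfect_doubling_slope(self):
        pts = [(x, 30 - 3.321928 * x) for x in (0, -1, -2, -3)]
        fit = efficiency_from_dilution(pts)
        assert fit.efficiency_percent == pytest.approx(100.0, abs=0.01)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_slope_minus_3_5(self):
        fit = efficiency_from_dilution([(0, 30), (-1, 33.5), (-2, 37)])
        # closed form: (10^(1/3.5) - 1) * 100
        assert fit.efficiency_percent == pytest.approx((10 ** (1 / 3.5) - 1) * 100, abs=1e-9)
        assert fit.efficiency_percent == pytest.approx(93.06, abs=0.05)

    @given(
        slope=st.floats(-4.5, -2.5),
        intercept=st.floats(25, 40),
    )
    @settings(max_examples=50, deadline=None)
    def test_noiseless_recovery_exact(self, slope, intercept):
        pts = [(x, intercept + slope * x) for x in (0.0, -1.0, -2.0, -3.0, -4.0)]
        fit = efficiency_from_dilution(pts)
        assert fit.slope == pytest.approx(slope, rel=1e-9)

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            efficiency_from_dilution([(0, 30), (-1, 33)])

    def test_degenerate_abscissa(self):
        with pytest.raises(ValueError):
            efficiency_from_dilution([(0, 30), (0, 31), (0, 32)])
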