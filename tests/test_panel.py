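"""Panel I/O, descriptive statistics, limit check, correlation and QC rules."""

import io
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from liplead import (
    Category,
    QcRun,
    check_limit,
    correlate,
    qc_validate,
    read_panel,
    summarize_panel,
    write_panel,
)
from liplead.errors import (
    ParameterError,
    SchemaError,
    UndefinedCorrelationError,
    UndefinedRpdError,
    ValidationError,
)

from conftest import make_panel, make_record


class TestReadPanel:
    def test_preserves_rows_and_order(self, panel_csv):
        panel = read_panel(panel_csv)
        assert [r.sample_id for r in panel] == ["LS1", "LS2", "LG1"]
        assert panel.records[0].pb_mg_per_kg == 0.13849
        assert panel.records[0].detected is True
        assert panel.records[0].category is Category.LIPSTICK

    def test_case_insensitive_category(self, panel_csv):
        panel = read_panel(panel_csv)
        assert panel.records[1].category is Category.LIPSTICK

    def test_zero_without_detect_column_is_nondetect(self, panel_csv):
        panel = read_panel(panel_csv)
        assert panel.records[1].detected is False

    def test_missing_column_names_it(self):
        csv = "sample_id,category\nLS1,lipstick\n"
        with pytest.raises(SchemaError, match="pb_mg_per_kg"):
            read_panel(io.StringIO(csv))

    def test_negative_concentration_cites_row(self):
        csv = (
            "sample_id,category,brand,production_country,color,price_rmb,pb_mg_per_kg\n"
            "A,lipstick,B,C,red,10,0.1\n"
            "B,lipstick,B,C,red,10,-0.1\n"
        )
        with pytest.raises(ValidationError, match="row 1"):
            read_panel(io.StringIO(csv))

    def test_duplicate_sample_id_rejected(self):
        csv = (
            "sample_id,category,brand,production_country,color,price_rmb,pb_mg_per_kg\n"
            "A,lipstick,B,C,red,10,0.1\n"
            "A,lip_gloss,B,C,red,10,0.2\n"
        )
        with pytest.raises(ValidationError, match="duplicate"):
            read_panel(io.StringIO(csv))

    def test_explicit_detect_column_overrides(self):
        csv = (
            "sample_id,category,brand,production_country,color,price_rmb,"
            "pb_mg_per_kg,detected\nA,lipstick,B,C,red,10,0,false\n"
            "B,lipstick,B,C,red,10,0.1,true\n"
        )
        panel = read_panel(io.StringIO(csv))
        assert panel.records[0].detected is False

    def test_roundtrip_write_read(self, panel_csv):
        panel = read_panel(panel_csv)
        buf = io.StringIO()
        write_panel(panel, buf)
        buf.seek(0)
        again = read_panel(buf)
        assert again == panel


class TestSummarize:
    def test_hand_computed_statistics(self, small_panel):
        g = summarize_panel(small_panel).groups["total"]
        assert g.mean == pytest.approx(0.2)
        assert g.sd == pytest.approx(0.1)
        assert (g.min, g.max) == (0.1, 0.3)
        assert g.nondetect_fraction == 0.0

    def test_zeros_included_in_mean(self):
        g = summarize_panel(make_panel([0, 0, 0.3])).groups["total"]
        assert g.mean == pytest.approx(0.1)
        assert g.nondetect_fraction == pytest.approx(2 / 3)

    def test_nondetect_fraction_14_of_34(self):
        vals = [0.0] * 14 + [0.05] * 20
        g = summarize_panel(make_panel(vals)).groups["total"]
        assert round(g.nondetect_fraction, 4) == 0.4118

    def test_group_counts_sum_to_total(self):
        panel = make_panel([0.1, 0.2], Category.LIPSTICK)
        panel2 = make_panel([0.3], Category.LIP_BALM)
        from liplead import SamplePanel
        merged = SamplePanel(tuple(
            make_record(sample_id=f"X{i}", category=r.category, pb=r.pb_mg_per_kg)
            for i, r in enumerate((*panel.records, *panel2.records))
        ))
        table = summarize_panel(merged)
        assert sum(g.n for k, g in table.groups.items() if k != "total") == \
            table.groups["total"].n

    def test_singleton_group_sd_unavailable(self):
        g = summarize_panel(make_panel([0.5])).groups["total"]
        assert g.sd is None

    def test_empty_panel_rejected(self):
        from liplead import SamplePanel
        with pytest.raises(ValidationError):
            summarize_panel(SamplePanel(()))

    def test_substitution_policy_half_dl(self):
        panel = make_panel([0, 0.2]).with_substitution(detection_limit=0.01)
        assert panel.values.tolist() == [0.005, 0.2]

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(min_value=0, max_value=1.0), min_size=2, max_size=20))
    def test_matches_brute_force(self, values):
        """Summary statistics equal a direct recomputation from the raw values."""
        g = summarize_panel(make_panel(values)).groups["total"]
        assert g.mean == pytest.approx(sum(values) / len(values))
        assert g.min == min(values) and g.max == max(values)
        mean = sum(values) / len(values)
        sd = math.sqrt(sum((v - mean) ** 2 for v in values) / (len(values) - 1))
        assert g.sd == pytest.approx(sd)
        assert g.nondetect_fraction == sum(v == 0 for v in values) / len(values)

    @settings(max_examples=25, deadline=None)
    @given(st.permutations([0.0, 0.1, 0.25, 0.3, 0.3]))
    def test_order_invariance(self, values):
        """Statistics are pure functions of the multiset of values."""
        ref = summarize_panel(make_panel([0.0, 0.1, 0.25, 0.3, 0.3])).groups["total"]
        g = summarize_panel(make_panel(values)).groups["total"]
        assert g.mean == pytest.approx(ref.mean)
        assert g.sd == pytest.approx(ref.sd)
        assert (g.min, g.max, g.n, g.nondetect_fraction) == \
            (ref.min, ref.max, ref.n, ref.nondetect_fraction)


class TestCheckLimit:
    def test_compliant_panel(self):
        lc = check_limit(make_panel([0.5237, 0.1]), limit=10.0)
        assert lc.verdict == "compliant" and lc.n_exceedances == 0

    def test_boundary_value_is_compliant(self):
        assert check_limit(make_panel([10.0])).verdict == "compliant"

    def test_exceedance_flagged(self):
        lc = check_limit(make_panel([10.5, 0.1]))
        assert lc.verdict == "non-compliant"
        assert lc.flags["S0"] is True and lc.flags["S1"] is False

    def test_nonpositive_limit_rejected(self):
        with pytest.raises(ParameterError):
            check_limit(make_panel([0.1]), limit=0.0)

    @pytest.mark.parametrize("limits", [(0.05, 0.1, 0.2, 10.0)])
    def test_flag_count_monotone_in_limit(self, limits):
        panel = make_panel([0.01, 0.08, 0.15, 0.3])
        counts = [check_limit(panel, lim).n_exceedances for lim in limits]
        assert counts == sorted(counts, reverse=True)


class TestCorrelate:
    def test_perfect_monotone_price(self):
        panel = make_panel([0.1, 0.2, 0.3, 0.4, 0.5])
        panel = type(panel)(tuple(
            make_record(sample_id=f"S{i}", pb=r.pb_mg_per_kg, price_rmb=10.0 * (i + 1))
            for i, r in enumerate(panel.records)
        ))
        rho, _ = correlate(panel, x="price", method="spearman")
        assert rho == pytest.approx(1.0)

    def test_hand_computed_spearman(self):
        """Ranks (1,2,3) vs (1,3,2): ρ = 1 − 6·2/(3·8) = 0.5."""
        recs = [
            make_record("A", Category.LIPSTICK, 0.1),
            make_record("B", Category.LIP_GLOSS, 0.3),
            make_record("C", Category.LIP_BALM, 0.2),
        ]
        from liplead import SamplePanel
        rho, p = correlate(SamplePanel(tuple(recs)), x="category_code")
        assert rho == pytest.approx(0.5)
        assert 0 <= p <= 1

    def test_constant_pb_undefined(self):
        panel = make_panel([0.1, 0.1, 0.1])
        with pytest.raises(UndefinedCorrelationError):
            correlate(panel, x="price")

    def test_monotone_transform_invariance(self):
        """Spearman is invariant under strictly monotone transforms."""
        vals = [0.03, 0.4, 0.11, 0.25, 0.07]
        prices = [20, 310, 95, 150, 60]
        def build(v):
            from liplead import SamplePanel
            return SamplePanel(tuple(
                make_record(f"S{i}", pb=x, price_rmb=pr)
                for i, (x, pr) in enumerate(zip(v, prices))
            ))
        rho1, _ = correlate(build(vals), x="price")
        rho2, _ = correlate(build([math.exp(5 * v) for v in vals]), x="price")
        assert rho1 == pytest.approx(rho2)

    def test_category_codes_overridable(self):
        recs = [
            make_record("A", Category.LIPSTICK, 0.1),
            make_record("B", Category.LIP_GLOSS, 0.3),
            make_record("C", Category.LIP_BALM, 0.2),
        ]
        from liplead import SamplePanel
        panel = SamplePanel(tuple(recs))
        flipped = {Category.LIPSTICK: 3, Category.LIP_GLOSS: 2, Category.LIP_BALM: 1}
        rho_default, _ = correlate(panel, x="category_code")
        rho_flipped, _ = correlate(panel, x="category_code", category_codes=flipped)
        assert rho_flipped == pytest.approx(-rho_default)


class TestQcValidate:
    def test_pair_within_tolerance_passes(self):
        run = QcRun(parallel_pairs=((0.10, 0.11),), calibration_r=0.999)
        rep = qc_validate(run)
        assert rep.pair_rpds[0] == pytest.approx(0.01 / 0.105)
        assert rep.pair_passes == (True,) and rep.passed

    def test_pair_beyond_tolerance_fails_named(self):
        run = QcRun(parallel_pairs=((0.10, 0.12),), calibration_r=0.999)
        rep = qc_validate(run)
        assert rep.pair_rpds[0] == pytest.approx(0.02 / 0.11)
        assert not rep.passed
        assert any("parallel_pair[0]" in item for item in rep.failed_items)

    def test_calibration_threshold_inclusive(self):
        rep = qc_validate(QcRun(parallel_pairs=(), calibration_r=0.995))
        assert rep.calibration_pass

    def test_calibration_below_threshold_fails_named(self):
        rep = qc_validate(QcRun(parallel_pairs=(), calibration_r=0.90))
        assert not rep.calibration_pass
        assert any("calibration" in item for item in rep.failed_items)

    def test_blank_at_detection_limit_fails(self):
        run = QcRun(parallel_pairs=(), calibration_r=0.999,
                    blank_values=(0.001,), detection_limit=0.001)
        assert not qc_validate(run).blanks_pass

    def test_zero_mean_pair_undefined(self):
        run = QcRun(parallel_pairs=((0.0, 0.0),), calibration_r=0.999)
        with pytest.raises(UndefinedRpdError):
            qc_validate(run)
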