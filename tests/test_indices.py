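import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import ogttbcf as o
from ogttbcf.indices import DEGENERATE, INCOMPLETE
from ogttbcf.io import InvalidInputError

from fixture_expected import EXPECTED


def _record(g, i, cp, sex="male", bmi=27.0, sid="r"):
    times = (0, 30, 60, 120)
    return o.OGTTRecord(subject_id=sid, sex=sex, bmi=bmi,
                        glucose=dict(zip(times, g)),
                        insulin=dict(zip(times, i)),
                        cpeptide=dict(zip(times, cp)))


class TestCatalog:
    def test_twenty_implemented_entries_by_phase(self):
        phases = pd.Series([e.phase for e in o.IMPLEMENTED]).value_counts()
        assert len(o.IMPLEMENTED) == 20
        assert phases["fasting"] == 3
        assert phases["early"] == 9
        assert phases["late"] == 6
        assert phases["overall"] == 2

    def test_orientation_inverted_for_fasting_ratios_only(self):
        inverted = {e.name for e in o.IMPLEMENTED if e.orientation == -1}
        assert inverted == {"igr_0", "cgr_0"}

    def test_homa_b2_reserved_not_available(self):
        entry = o.get_entry("homa_b2")
        assert not entry.available
        value, reason = o.compute_index(entry, o.worked_fixture().records()[0])
        assert value is None

    def test_catalog_exportable(self):
        table = o.catalog_table()
        assert len(table) == 21
        assert {"name", "phase", "formula", "orientation",
                "display_scale"} <= set(table.columns)


class TestFixtureFormulas:
    """All 20 formulas, Matsuda and DI against hand-evaluated values."""

    @pytest.mark.parametrize("sid", list(EXPECTED))
    def test_all_indices_to_ten_significant_digits(self, sid, fixture_cohort):
        matrix = o.compute_index_matrix(fixture_cohort)
        for name, expected in EXPECTED[sid].items():
            if name == "matsuda":
                continue
            got = matrix.values.loc[sid, name]
            if expected is None:
                assert np.isnan(got), name
            else:
                assert got == pytest.approx(expected, rel=1e-10), name

    @pytest.mark.parametrize("sid", list(EXPECTED))
    def test_matsuda_and_disposition(self, sid, fixture_cohort):
        record = next(r for r in fixture_cohort.records()
                      if r.subject_id == sid)
        matsuda = o.matsuda_index(record)
        assert matsuda == pytest.approx(EXPECTED[sid]["matsuda"], rel=1e-10)
        igi, _ = o.compute_index("igi_30", record)
        di = o.disposition_index(igi, matsuda)
        assert di == pytest.approx(EXPECTED[sid]["igi_30"] * matsuda, rel=1e-10)


class TestComputeIndex:
    def test_insulinogenic_hand_example(self):
        rec = _record((5.0, 8.0, 7.0, 6.0), (60, 300, 250, 150),
                      (600, 1800, 1700, 1500))
        value, reason = o.compute_index("igi_30", rec)
        assert value == pytest.approx(80.0, rel=1e-12) and reason is None

    def test_ratio_identity(self):
        rec = _record((5.0, 8.0, 7.0, 6.0), (60, 60, 250, 150),
                      (600, 1800, 1700, 1500))
        value, _ = o.compute_index("ir_30", rec)
        assert value == pytest.approx(1.0, rel=1e-12)

    def test_stumvoll_first_hand_sum(self):
        rec = _record((5.0, 8.0, 7.0, 6.0), (60, 300, 250, 150),
                      (600, 1800, 1700, 1500))
        value, _ = o.compute_index("stumvoll_first", rec)
        assert value == pytest.approx(948.42, rel=1e-10)

    def test_bigtt_hand_exponent(self):
        # exponent hand-summed: 8.20 + .1068 + .504 - .13405 - 1.57 - .872
        #                       + .4686 + 0 - .864 = 5.83935
        rec = _record((5.0, 8.0, 7.0, 6.0), (60, 300, 250, 350),
                      (600, 1800, 1700, 1500), sex="male", bmi=27.0)
        value, _ = o.compute_index("bigtt_air_0_30_120", rec)
        assert value == pytest.approx(math.exp(5.83935), rel=1e-10)
        assert value == pytest.approx(343.6, rel=1e-3)

    def test_degenerate_denominator_flagged(self):
        rec = _record((5.0, 5.0, 7.0, 6.0), (60, 300, 250, 150),
                      (600, 1800, 1700, 1500))
        value, reason = o.compute_index("igi_30", rec)
        assert value is None and reason == DEGENERATE

    def test_missing_input_never_raises(self):
        rec = o.OGTTRecord(subject_id="r", sex="male", bmi=27.0,
                           glucose={0: 5.0, 30: 8.0},
                           insulin={0: 60.0}, cpeptide={0: 600.0})
        value, reason = o.compute_index("ir_30", rec)
        assert value is None and reason == INCOMPLETE


class TestAucRatio:
    def test_constant_curves(self):
        num = {t: 100.0 for t in (0, 30, 60, 120)}
        den = {t: 5.0 for t in (0, 30, 60, 120)}
        assert o.compute_auc_ratio(num, den) == pytest.approx(20.0, rel=1e-12)

    def test_hand_trapezoid(self):
        num = dict(zip((0, 30, 60, 120), (60.0, 300.0, 250.0, 150.0)))
        den = dict(zip((0, 30, 60, 120), (5.0, 8.0, 7.0, 6.0)))
        assert o.compute_auc_ratio(num, den) == pytest.approx(
            25650.0 / 810.0, rel=1e-12)

    def test_numerator_linearity(self):
        num = dict(zip((0, 30, 60, 120), (60.0, 300.0, 250.0, 150.0)))
        den = dict(zip((0, 30, 60, 120), (5.0, 8.0, 7.0, 6.0)))
        double = {t: 2 * v for t, v in num.items()}
        assert o.compute_auc_ratio(double, den) == pytest.approx(
            2 * o.compute_auc_ratio(num, den), rel=1e-12)

    def test_missing_time_point(self):
        num = {0: 60.0, 30: 300.0, 60: 250.0}
        den = dict(zip((0, 30, 60, 120), (5.0, 8.0, 7.0, 6.0)))
        with pytest.raises(InvalidInputError):
            o.compute_auc_ratio(num, den)


class TestMatsuda:
    def test_hand_example_in_conventional_units(self):
        # G0=90 mg/dl, I0=10 uU/ml, meanG=120 mg/dl, meanI=50 uU/ml
        g = tuple(v / 18.016 for v in (90.0, 130.0, 130.0, 130.0))
        i = tuple(v * 6.945 for v in (10.0, 60.0, 60.0, 70.0))
        rec = _record(g, i, (600, 1800, 1700, 1500))
        expected = 10000.0 / math.sqrt(90.0 * 10.0 * 120.0 * 50.0)
        assert o.matsuda_index(rec) == pytest.approx(expected, rel=1e-12)
        assert o.matsuda_index(rec) == pytest.approx(4.3033, rel=1e-4)

    def test_insulin_scaling(self):
        # insulin enters the square root twice (I0 and meanI), so scaling all
        # insulin values by k scales the index by 1/k
        rec = _record((5.0, 8.0, 7.0, 6.0), (60, 300, 250, 150),
                      (600, 1800, 1700, 1500))
        scaled = _record((5.0, 8.0, 7.0, 6.0),
                         (240, 1200, 1000, 600), (600, 1800, 1700, 1500))
        assert o.matsuda_index(scaled) == pytest.approx(
            o.matsuda_index(rec) / 4.0, rel=1e-12)

    def test_pure_function(self):
        rec = _record((5.0, 8.0, 7.0, 6.0), (60, 300, 250, 150),
                      (600, 1800, 1700, 1500))
        assert o.matsuda_index(rec) == o.matsuda_index(rec)

    def test_nonpositive_raises(self):
        rec = _record((5.0, 8.0, 7.0, 6.0), (0.0, 300, 250, 150),
                      (600, 1800, 1700, 1500))
        with pytest.raises(InvalidInputError):
            o.matsuda_index(rec)


class TestDispositionIndex:
    def test_product_identity_and_sign(self):
        assert o.disposition_index(80.0, 4.3034) == pytest.approx(
            344.272, rel=1e-6)
        assert o.disposition_index(12.5, 1.0) == 12.5
        assert o.disposition_index(-5.0, 4.0) < 0

    def test_missing_propagates(self):
        assert o.disposition_index(np.nan, 4.0) is None


class TestIndexMatrix:
    def test_fixture_missing_cells(self, fixture_cohort):
        matrix = o.compute_index_matrix(fixture_cohort)
        assert matrix.values.shape == (6, 20)
        # only ngm_2 (G120 == G0) has degenerate 120 min incremental indices
        assert matrix.values.isna().sum().sum() == 2
        assert matrix.missing_reason.loc["ngm_2", "igi_120"] == DEGENERATE
        assert matrix.missing_reason.loc["ngm_2", "cgi_120"] == DEGENERATE

    def test_degenerate_delta_g30_propagation(self, fixture_cohort):
        df = fixture_cohort.data.copy()
        assert df.loc[0, "subject_id"] == "ngm_1"
        df.loc[0, "g30"] = df.loc[0, "g0"]
        matrix = o.compute_index_matrix(o.Cohort(data=df))
        missing = set(matrix.values.columns[matrix.values.loc["ngm_1"].isna()])
        # exactly the two delta-G30-denominator indices drop out
        assert missing == {"igi_30", "cgi_30"}

    def test_row_order_invariance(self, fixture_cohort):
        matrix = o.compute_index_matrix(fixture_cohort)
        shuffled = o.Cohort(
            data=fixture_cohort.data.sample(frac=1, random_state=3)
            .reset_index(drop=True))
        matrix2 = o.compute_index_matrix(shuffled)
        pd.testing.assert_frame_equal(
            matrix.values.sort_index(), matrix2.values.sort_index())

    @given(g0=st.floats(4.0, 7.0), dg=st.floats(0.5, 8.0),
           i0=st.floats(20.0, 200.0), di=st.floats(5.0, 2000.0),
           cp0=st.floats(200.0, 2000.0), dcp=st.floats(50.0, 5000.0))
    def test_rising_early_response_gives_positive_early_indices(
            self, g0, dg, i0, di, cp0, dcp):
        """A strictly rising 0->30 min response makes every early-phase ratio
        and incremental index strictly positive (post-load glucose above the
        3.89 mmol/l CIR offset)."""
        g30 = g0 + dg
        rec = _record((g0, g30, g30, g0 + 1.0),
                      (i0, i0 + di, i0 + di, i0),
                      (cp0, cp0 + dcp, cp0 + dcp, cp0))
        for name in ("ir_30", "cpr_30", "igi_30", "igi_mod_30", "cgi_30",
                     "cir_30"):
            value, reason = o.compute_index(name, rec)
            assert reason is None
            assert value > 0, name


class TestScaleInvariance:
    def test_affine_rescaling_preserves_auc(self):
        """Positive affine maps of an index never change its ROC AUC."""
        cohort = o.generate_baseline(o.CohortConfig(seed=11))
        status = cohort.data["subject_id"].map(cohort.baseline_status)
        ids = pd.concat([cohort.data.loc[status == o.NGM, "subject_id"][:30],
                         cohort.data.loc[status == o.T2DM, "subject_id"][:20]])
        cohort = cohort.subset(ids)
        matrix = o.compute_index_matrix(cohort)
        labels = (pd.Series(cohort.baseline_status)[matrix.values.index]
                  != o.NGM).astype(int).to_numpy()
        rng = np.random.default_rng(5)
        for entry in o.IMPLEMENTED:
            s = matrix.values[entry.name].to_numpy()
            base = o.roc_auc(s, labels, orientation=-entry.orientation)
            a, b = rng.uniform(0.01, 100), rng.uniform(-50, 50)
            scaled = o.roc_auc(a * s + b, labels,
                               orientation=-entry.orientation)
            assert scaled.auc == pytest.approx(base.auc, abs=1e-12)
            # the catalog display scale is one such map
            disp = o.roc_auc(entry.display_scale * s, labels,
                             orientation=-entry.orientation)
            assert disp.auc == pytest.approx(base.auc, abs=1e-12)


TABLE3_NGM_VS_T2DM = {
    # decreasing with worsening status
    "homa_b1": -1, "ir_30": -1, "cpr_30": -1, "igi_30": -1, "cgi_30": -1,
    "cir_30": -1, "stumvoll_first": -1, "bigtt_air_0_30_120": -1,
    "bigtt_air_0_60_120": -1, "stumvoll_second": -1, "cpr_120": -1,
    "igi_120": -1, "cgi_120": -1, "cir_120": -1, "auc_i_g": -1,
    "auc_cp_g": -1,
    # increasing with worsening status
    "igr_0": +1, "cgr_0": +1, "ir_120": +1,
}


def test_class_medians_follow_expected_direction():
    """On a large synthetic cohort the NGM vs T2DM median ordering of every
    index matches the cross-sectional pattern of impaired beta-cell function
    (e.g. CP30/CP0 falls, I0/G0 rises with worsening status)."""
    cohort = o.generate_baseline(o.CohortConfig(seed=2).scaled(10), seed=2)
    matrix = o.compute_index_matrix(cohort)
    status = matrix.values.index.map(cohort.baseline_status)
    med = matrix.values.groupby(status.to_numpy()).median()
    for name, sign in TABLE3_NGM_VS_T2DM.items():
        diff = med.loc[o.T2DM, name] - med.loc[o.NGM, name]
        assert np.sign(diff) == sign, name
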