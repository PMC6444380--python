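import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phenoranges.errors import (
    KeyMismatchError,
    MissingRangeError,
    PhenotypeMismatchError,
)
from phenoranges.meta import (
    HeterogeneityStats,
    MetaResult,
    PooledEstimate,
    run_meta,
)
from phenoranges.ranges import (
    OUTSIDE,
    OVERLAPPING,
    WITHIN,
    ControlRange,
    ExpectedRange,
    RangeConfig,
    build_control_range,
    classify_strain,
    compare_with_expert,
    expected_range,
    forest_table,
    labels_from_classifications,
    render_forest,
    render_funnel,
)
from phenoranges.bias import egger_regression
from phenoranges.stratify import StratumKey
from util import make_input


def _key(strain, phenotype="systolic blood pressure", sex="all"):
    return StratumKey(phenotype, strain, sex_group=sex)


def _range(strain, low, high, k=5, phenotype="systolic blood pressure"):
    center = (low + high) / 2
    return ExpectedRange(
        key=_key(strain, phenotype),
        center=center,
        sd_used=(high - low) / 2,
        low=low,
        high=high,
        k=k,
        confidence="confident",
    )


class TestExpectedRange:
    def test_fixed_model_uses_animal_variance_only(self):
        # 4 studies at mean 10, animal SD 2 (var 4), n=4 -> s_i^2 = 1
        m = make_input([10.0] * 4, [1.0] * 4, n=[4] * 4, sd_animals=[2.0] * 4)
        res = run_meta(m)
        er = expected_range(res, m)
        assert res.pooled.model == "fixed"
        assert er.center == pytest.approx(10.0)
        assert er.sd_used == pytest.approx(2.0)
        assert (er.low, er.high) == (pytest.approx(8.0), pytest.approx(12.0))

    def test_random_model_adds_between_study_variance(self):
        # tau2=3 on top of unit animal-level variance: sd_used = sqrt(3+1) = 2
        m = make_input([0.0, 2.0, 4.0], [1.0, 1.0, 1.0], n=[1, 1, 1],
                       sd_animals=[1.0, 1.0, 1.0])
        pooled = PooledEstimate("random", 2.0, 2 / np.sqrt(3), (0.0, 0.0))
        res = MetaResult(
            key=m.key, k=3, pooled=pooled,
            het=HeterogeneityStats(Q=8.0, df=2, i2=0.75, tau2=3.0),
            confidence="low_confidence", asymmetry_score=float("nan"),
            quadrant=None, egger=None, flags=set(),
        )
        er = expected_range(res, m)
        assert er.sd_used == pytest.approx(2.0)
        assert (er.low, er.high) == (pytest.approx(0.0), pytest.approx(4.0))

    def test_zero_width_flagged(self):
        m = make_input([5.0, 5.0], [1.0, 1.0], sd_animals=[0.0, 0.0])
        res = run_meta(m)
        er = expected_range(res, m)
        assert er.sd_used == 0.0
        assert "zero-width" in er.flags

    def test_pooled_se_mode_flagged(self):
        m = make_input([10.0] * 4, [1.0] * 4)
        res = run_meta(m)
        er = expected_range(res, m, RangeConfig(sd_source="pooled_se"))
        assert er.sd_used == pytest.approx(res.pooled.se)
        assert "sd-from-pooled-se" in er.flags

    def test_width_is_twice_sd(self):
        m = make_input([10.0, 11.0, 12.0], [1.0, 2.0, 3.0])
        er = expected_range(run_meta(m), m)
        assert er.width == pytest.approx(2 * er.sd_used)
        assert er.low <= er.center <= er.high


class TestControlRange:
    def test_initial_range_spans_founder_extremes(self):
        ranges = {"A": _range("A", 100, 120), "B": _range("B", 105, 125)}
        cr = build_control_range(["A", "B"], ranges)
        assert (cr.low, cr.high) == (100, 125)
        assert cr.included == ("A", "B")

    def test_intersecting_candidate_widens_range(self):
        ranges = {
            "A": _range("A", 100, 120),
            "B": _range("B", 105, 125),
            "C": _range("C", 110, 130),
        }
        cr = build_control_range(["A", "B"], ranges)
        assert "C" in cr.included
        assert (cr.low, cr.high) == (100, 130)

    def test_disjoint_candidate_excluded(self):
        ranges = {
            "A": _range("A", 100, 120),
            "B": _range("B", 105, 130),
            "D": _range("D", 140, 160),
        }
        cr = build_control_range(["A", "B"], ranges)
        assert "D" not in cr.included
        assert (cr.low, cr.high) == (100, 130)
        actions = {s: a for s, a, _ in cr.iteration_log}
        assert actions["D"] == "excluded"

    def test_missing_founder_named(self):
        with pytest.raises(MissingRangeError, match="ZZZ"):
            build_control_range(["ZZZ"], {"A": _range("A", 0, 1)})

    def test_veto_respected(self):
        ranges = {"A": _range("A", 100, 120), "C": _range("C", 110, 130)}
        cr = build_control_range(["A"], ranges, veto=["C"])
        assert "C" not in cr.included
        assert (cr.low, cr.high) == (100, 120)

    def test_monotone_iteration_log(self):
        ranges = {
            "A": _range("A", 100, 110),
            "B": _range("B", 108, 125),
            "C": _range("C", 124, 140),
            "D": _range("D", 139, 150),
        }
        cr = build_control_range(["A"], ranges, mode="fixed-point")
        prev = None
        for _, _, (lo, hi) in cr.iteration_log:
            if prev is not None:
                assert lo <= prev[0] and hi >= prev[1]
            prev = (lo, hi)
        assert cr.included == ("A", "B", "C", "D")

    def test_fixed_point_admits_chains_single_pass_may_not(self):
        # C only touches after B is admitted; sorted single-pass sees B then C,
        # so use names that put the bridge *after* the far strain.
        ranges = {
            "A": _range("A", 100, 110),
            "B": _range("B", 130, 140),   # far: needs the bridge first
            "Z": _range("Z", 109, 131),   # bridge, visited last
        }
        single = build_control_range(["A"], ranges, mode="single-pass")
        fixed = build_control_range(["A"], ranges, mode="fixed-point")
        assert "B" not in single.included and "Z" in single.included
        assert fixed.included == ("A", "B", "Z")

    @given(st.integers(0, 10_000))
    @settings(max_examples=40, derandomize=True, deadline=None)
    def test_fixed_point_independent_of_candidate_order(self, seed):
        rng = np.random.default_rng(seed)
        names = [f"S{i}" for i in range(8)]
        ranges = {}
        for name in names:
            lo = float(rng.uniform(0, 100))
            ranges[name] = _range(name, lo, lo + float(rng.uniform(1, 30)))
        founders = [names[0]]
        baseline = build_control_range(founders, ranges, mode="fixed-point")
        for _ in range(4):
            order = list(rng.permutation(names[1:]))
            cr = build_control_range(
                founders, ranges, mode="fixed-point", candidate_order=order
            )
            assert cr.included == baseline.included
            assert (cr.low, cr.high) == (baseline.low, baseline.high)

    def test_every_founder_inside_final_range(self):
        ranges = {
            "A": _range("A", 10, 20),
            "B": _range("B", 50, 60),  # disjoint founders still both covered
        }
        cr = build_control_range(["A", "B"], ranges)
        for f in cr.founders:
            assert cr.low <= ranges[f].low and cr.high >= ranges[f].high

    def test_min_overlap_fraction_blocks_hairline_contact(self):
        ranges = {"A": _range("A", 100, 110), "B": _range("B", 110, 120)}
        touch = build_control_range(["A"], ranges)
        blocked = build_control_range(
            ["A"], ranges, config=RangeConfig(min_overlap_frac=0.1)
        )
        assert "B" in touch.included
        assert "B" not in blocked.included


class TestClassification:
    @pytest.mark.parametrize(
        "low,high,expected",
        [
            (101, 119, WITHIN),
            (95, 110, OVERLAPPING),
            (150, 170, OUTSIDE),
            (100, 130, WITHIN),      # exact match counts as contained
            (130, 140, OVERLAPPING), # touching endpoint intersects
        ],
    )
    def test_interval_relations(self, low, high, expected):
        control = ControlRange("systolic blood pressure", ("A",), ("A",), 100, 130)
        c = classify_strain(_range("X", low, high), control)
        assert c.status == expected

    @given(
        st.floats(-100, 100), st.floats(0.1, 50),
        st.floats(-100, 100), st.floats(0.1, 50),
    )
    @settings(max_examples=200, derandomize=True)
    def test_trichotomy(self, lo1, w1, lo2, w2):
        control = ControlRange("p", ("A",), ("A",), lo2, lo2 + w2)
        c = classify_strain(_range("X", lo1, lo1 + w1, phenotype="p"), control)
        assert c.status in (WITHIN, OVERLAPPING, OUTSIDE)
        if c.status == WITHIN:
            assert lo1 >= lo2 and lo1 + w1 <= lo2 + w2
        if c.status == OUTSIDE:
            assert lo1 + w1 < lo2 or lo1 > lo2 + w2

    def test_phenotype_mismatch_error(self):
        control = ControlRange("heart rate", ("A",), ("A",), 100, 130)
        with pytest.raises(PhenotypeMismatchError):
            classify_strain(_range("X", 1, 2), control)


class TestExpertComparison:
    def test_identical_maps_agree_fully(self):
        labels = {"BN": "normal", "SHR": "abnormal"}
        rep = compare_with_expert(labels, dict(labels))
        assert rep.percent == 100.0
        assert rep.disagreements == []

    def test_one_mismatch_of_fifty(self):
        tool = {f"S{i}": "normal" for i in range(50)}
        expert = dict(tool)
        expert["S7"] = "abnormal"
        rep = compare_with_expert(tool, expert)
        assert rep.percent == pytest.approx(98.0)
        assert rep.disagreements == [("S7", "normal", "abnormal")]

    def test_key_mismatch_lists_missing(self):
        with pytest.raises(KeyMismatchError, match="SHR"):
            compare_with_expert({"BN": "normal", "SHR": "normal"}, {"BN": "normal"})
        with pytest.raises(KeyMismatchError):
            compare_with_expert({}, {})

    def test_overlapping_counts_as_normal(self):
        control = ControlRange("p", ("A",), ("A",), 100, 130)
        cls = [
            classify_strain(_range("IN", 105, 120, phenotype="p"), control),
            classify_strain(_range("EDGE", 95, 105, phenotype="p"), control),
            classify_strain(_range("OUT", 150, 160, phenotype="p"), control),
        ]
        labels = labels_from_classifications(cls)
        assert labels == {"IN": "normal", "EDGE": "normal", "OUT": "abnormal"}


class TestRendering:
    def _rows(self, n=3):
        rows = []
        for i in range(n):
            m = make_input(
                [100.0 + i, 102.0 + i, 104.0 + i], [1.0, 2.0, 1.5],
                key=StratumKey("p", f"S{i}", sex_group="male" if i % 2 else "female"),
            )
            res = run_meta(m)
            rows.append((res, expected_range(res, m)))
        return rows

    def test_forest_table_geometry(self):
        rows = self._rows(3)
        table = forest_table(rows)
        assert len(table) == 3
        for (res, er), row in zip(rows, table.itertuples()):
            assert row.extent == pytest.approx(2 * er.sd_used)
            assert row.center == pytest.approx(er.center)
            assert row.k == res.k

    def test_low_confidence_tagged(self):
        table = forest_table(self._rows(1))
        assert table.loc[0, "confidence"] == "low_confidence"  # k=3

    def test_sex_shape_mode_varies_marker(self):
        table = forest_table(self._rows(2))
        assert set(table["shape"]) == {"s", "o"}  # male square, female circle

    def test_render_writes_file_and_same_table(self, tmp_path):
        rows = self._rows(3)
        table, path = render_forest(rows, path=str(tmp_path / "forest.svg"))
        assert path and (tmp_path / "forest.svg").exists()
        table2, _ = render_forest(rows)
        assert table.equals(table2)

    def test_funnel_table_and_plot(self, tmp_path):
        m = make_input([7.0, 9.0, 13.0], [1.0, 4.0, 16.0])
        egger = egger_regression(m)
        table, path = render_funnel(m, egger, path=str(tmp_path / "funnel.png"))
        assert len(table) == 3
        assert path and (tmp_path / "funnel.png").exists()
        # overlay line consistency: slope comes straight from the Egger fit
        assert egger.slope == pytest.approx(5.0)

    def test_funnel_without_line_for_two_studies(self, tmp_path):
        m = make_input([7.0, 9.0], [1.0, 4.0])
        egger = egger_regression(m)
        assert not egger.evaluable
        table, path = render_funnel(m, egger, path=str(tmp_path / "f.svg"))
        assert len(table) == 2 and path
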