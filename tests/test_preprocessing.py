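"""Period enumeration, filtering rules, carry-forward, kind inference and
fold-safe imputation/encoding/scaling."""

import numpy as np
import pandas as pd
import pytest

from oaprogress import preprocessing
from oaprogress.data import AttributeMeta, CohortTable, enumerate_timepoint_pairs
from oaprogress.preprocessing import (
    EmptyDatasetError,
    Imputer,
    MinMaxScaler,
    OneHotEncoder,
    PreprocessPipeline,
    carry_forward_and_defaults,
    enumerate_periods,
    filter_table,
    infer_kinds,
)


def tiny_cohort(timepoints, replacements=None):
    rows = [{"patient_id": "A", "timepoint_years": t, "x": 1.0} for t in timepoints]
    repl = pd.DataFrame(replacements or [],
                        columns=["patient_id", "knee", "time_years"])
    return CohortTable(visits=pd.DataFrame(rows), replacements=repl)


class TestEnumeratePeriods:
    def test_check_like_grid_gives_six(self):
        periods = enumerate_periods(tiny_cohort([0, 2, 5, 8]))
        assert [(p.start, p.end) for p in periods] == [
            (0, 2), (0, 5), (0, 8), (2, 5), (2, 8), (5, 8)]

    def test_oai_like_grid_gives_seventeen(self):
        ts = [0, 1, 2, 3, 4, 6, 8]
        periods = enumerate_periods(tiny_cohort(ts))
        brute = [(a, b) for i, a in enumerate(ts) for b in ts[i + 1:] if b - a >= 2]
        assert len(periods) == 17
        assert [(p.start, p.end) for p in periods] == brute

    def test_replacement_drops_later_periods(self):
        cohort = tiny_cohort([0, 2, 5, 8],
                             [{"patient_id": "A", "knee": "left", "time_years": 4.0}])
        periods = enumerate_periods(cohort)
        assert [(p.start, p.end) for p in periods] == [(0, 2)]

    def test_consecutive_policy(self):
        pairs = enumerate_timepoint_pairs([0, 1, 2, 3, 4, 6, 8], policy="consecutive")
        assert pairs == [(0, 2), (1, 3), (2, 4), (3, 6), (4, 6), (6, 8)]


class TestFilterTable:
    def frame(self):
        return pd.DataFrame({
            "half_missing": [1.0, np.nan, 2.0, np.nan],   # exactly 50%
            "mostly_missing": [np.nan, np.nan, np.nan, 1.0],
            "constant": [3.0, 3.0, 3.0, 3.0],
            "id_col": ["a", "b", "c", "d"],
            "ok": [1.0, 2.0, 3.0, 4.0],
        })

    def meta(self):
        return {"id_col": AttributeMeta(name="id_col", kind="identifier")}

    def test_filter_rules(self):
        out = filter_table(self.frame(), self.meta())
        assert list(out.columns) == ["half_missing", "ok"]

    def test_attribute_at_exactly_half_retained(self):
        out = filter_table(self.frame(), self.meta())
        assert "half_missing" in out.columns       # strict > 50%

    def test_overly_missing_instance_dropped(self):
        frame = pd.DataFrame({f"a{i}": [1.0, np.nan if i < 5 else 1.0, 2.0]
                              for i in range(10)})
        out = filter_table(frame, {})
        assert list(out.index) == [0, 2]           # 5/10 > 0.4 missing

    def test_idempotent(self):
        frame = pd.DataFrame({
            "sparse": [1.0, np.nan, 2.0, 3.0, np.nan, 4.0],
            "ok": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
            "also_ok": [6.0, 5.0, 4.0, 3.0, 2.0, 1.0],
        })
        once = filter_table(frame, {})
        twice = filter_table(once, {})
        pd.testing.assert_frame_equal(once, twice)

    def test_idempotent_on_synthetic_instances(self, dataset):
        again = filter_table(dataset.instances, dataset.meta)
        pd.testing.assert_frame_equal(again, dataset.instances)

    def test_empty_result_raises(self):
        frame = pd.DataFrame({"x": [np.nan, np.nan, 1.0]})
        with pytest.raises(EmptyDatasetError):
            filter_table(frame, {}, attr_missing_max=0.5)


class TestCarryForward:
    def cohort(self):
        visits = pd.DataFrame({
            "patient_id": ["A"] * 3,
            "timepoint_years": [0.0, 2.0, 5.0],
            "past": [1.0, np.nan, np.nan],
            "rare": [np.nan, 1.0, np.nan],
            "plain": [np.nan, 4.0, np.nan],
        })
        meta = {
            "past": AttributeMeta(name="past", kind="categorical", carry_forward=True),
            "rare": AttributeMeta(name="rare", kind="categorical", default_value=0.0),
            "plain": AttributeMeta(name="plain", kind="continuous"),
        }
        return CohortTable(visits=visits, meta=meta)

    def test_carry_forward_fills_forward_only(self):
        out = carry_forward_and_defaults(self.cohort())
        assert out.visits["past"].tolist() == [1.0, 1.0, 1.0]

    def test_defaults_fill_remaining(self):
        out = carry_forward_and_defaults(self.cohort())
        assert out.visits["rare"].tolist() == [0.0, 1.0, 0.0]

    def test_unflagged_attribute_untouched(self):
        out = carry_forward_and_defaults(self.cohort())
        assert out.visits["plain"].isna().tolist() == [True, False, True]

    def test_never_copies_backwards(self):
        visits = pd.DataFrame({
            "patient_id": ["A", "A"], "timepoint_years": [0.0, 2.0],
            "past": [np.nan, 1.0],
        })
        meta = {"past": AttributeMeta(name="past", kind="categorical",
                                      carry_forward=True)}
        out = carry_forward_and_defaults(CohortTable(visits=visits, meta=meta))
        assert np.isnan(out.visits["past"].iloc[0])


class TestInferKinds:
    def test_level_threshold(self):
        frame = pd.DataFrame({
            "ten": list(range(10)) * 2,
            "eleven": list(range(11)) + list(range(9)),
        })
        meta = infer_kinds(frame, {})
        assert meta["ten"].kind == "categorical"
        assert meta["eleven"].kind == "continuous"

    def test_explicit_meta_wins(self):
        frame = pd.DataFrame({"x": [0, 1, 2, 0, 1]})
        given = {"x": AttributeMeta(name="x", kind="ordinal", n_levels=3)}
        assert infer_kinds(frame, given)["x"].kind == "ordinal"


class TestImputer:
    def test_mode_and_mean(self):
        meta = {"c": AttributeMeta(name="c", kind="categorical"),
                "x": AttributeMeta(name="x", kind="continuous")}
        train = pd.DataFrame({"c": [1, 1, 2], "x": [1.0, 3.0, np.nan]})
        imp = Imputer(meta).fit(train)
        out = imp.transform(pd.DataFrame({"c": [np.nan], "x": [np.nan]}))
        assert out["c"].iloc[0] == 1
        assert out["x"].iloc[0] == pytest.approx(2.0)

    def test_mode_tie_breaks_to_smallest(self):
        meta = {"c": AttributeMeta(name="c", kind="categorical")}
        imp = Imputer(meta).fit(pd.DataFrame({"c": [2, 2, 1, 1]}))
        assert imp.statistics_["c"] == 1

    def test_all_missing_names_attribute(self):
        meta = {"bad": AttributeMeta(name="bad", kind="continuous")}
        with pytest.raises(ValueError, match="bad"):
            Imputer(meta).fit(pd.DataFrame({"bad": [np.nan, np.nan]}))

    def test_no_leak_from_test_rows(self):
        meta = {"x": AttributeMeta(name="x", kind="continuous")}
        train = pd.DataFrame({"x": [1.0, 3.0]})
        imp = Imputer(meta).fit(train)
        before = dict(imp.statistics_)
        imp.transform(pd.DataFrame({"x": [999.0, np.nan]}))
        assert imp.statistics_ == before


class TestOneHot:
    def meta(self):
        return {
            "tri": AttributeMeta(name="tri", kind="categorical", n_levels=3),
            "bin": AttributeMeta(name="bin", kind="categorical", n_levels=2),
            "ordi": AttributeMeta(name="ordi", kind="ordinal", n_levels=3),
        }

    def test_encoding_shapes(self):
        train = pd.DataFrame({"tri": [0.0, 1.0, 2.0], "bin": [0.0, 1.0, 0.0],
                              "ordi": [0, 1, 2]})
        enc = OneHotEncoder(self.meta()).fit(train)
        out = enc.transform(train)
        tri_cols = [c for c in out.columns if c.startswith("tri=")]
        assert len(tri_cols) == 3
        assert (out[tri_cols].sum(axis=1) == 1.0).all()
        assert out["bin"].tolist() == [0.0, 1.0, 0.0]
        assert out["ordi"].tolist() == [0.0, 1.0, 2.0]

    def test_unseen_level_encodes_all_zero(self):
        train = pd.DataFrame({"tri": [0.0, 1.0, 2.0], "bin": [0.0, 1.0, 0.0],
                              "ordi": [0, 1, 2]})
        enc = OneHotEncoder(self.meta()).fit(train)
        out = enc.transform(pd.DataFrame({"tri": [7.0], "bin": [0.0], "ordi": [1]}))
        tri_cols = [c for c in out.columns if c.startswith("tri=")]
        assert out[tri_cols].sum(axis=1).iloc[0] == 0.0


class TestMinMax:
    def test_scaling_and_out_of_range(self):
        scaler = MinMaxScaler().fit(pd.DataFrame({"x": [2.0, 4.0]}))
        out = scaler.transform(pd.DataFrame({"x": [2.0, 4.0, 6.0]}))
        assert out["x"].tolist() == [0.0, 1.0, 2.0]

    def test_constant_column_maps_to_zero(self):
        scaler = MinMaxScaler().fit(pd.DataFrame({"x": [5.0, 5.0]}))
        out = scaler.transform(pd.DataFrame({"x": [5.0, 7.0]}))
        assert (out["x"] == 0.0).all()


class TestPipelineFoldSafety:
    def test_mutating_heldout_rows_never_changes_fitted_state(self, dataset):
        X = dataset.instances.iloc[:200]
        train, test = X.iloc[:150], X.iloc[150:]
        pipe = PreprocessPipeline(dataset.meta, scale=True).fit(train)
        state = pipe.state_dict()
        ref_train = pipe.transform(train)
        ref_test_cols = pipe.transform(test).columns
        rng = np.random.default_rng(4)
        for _ in range(10):
            mutated = test.copy()
            col = rng.choice(test.columns)
            mutated[col] = rng.normal(size=len(mutated))
            out = pipe.transform(mutated)
            assert pipe.state_dict() == state
            assert list(out.columns) == list(ref_test_cols)
        pd.testing.assert_frame_equal(pipe.transform(train), ref_train)

    def test_transform_output_is_dense_numeric(self, dataset):
        X = dataset.instances
        pipe = PreprocessPipeline(dataset.meta).fit(X)
        out = pipe.transform(X)
        assert out.notna().all().all()
        assert all(np.issubdtype(dt, np.number) for dt in out.dtypes)


class TestBuildDataset:
    def test_alignment_and_identifier_removal(self, dataset):
        assert len(dataset.instances) == len(dataset.labels)
        assert (dataset.instances.index == dataset.labels.index).all()
        assert "visit_barcode" not in dataset.instances.columns
        assert "visit_number" not in dataset.instances.columns

    def test_labels_are_progression_classes(self, dataset):
        assert set(dataset.labels.unique()) <= {"N", "P", "S", "P+S"}
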