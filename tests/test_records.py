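import numpy as np
import pandas as pd
import pytest

from conftest import make_captures
from roostnet.records import (
    RecordsError,
    RoostRegistry,
    RelatednessMatrix,
    filter_dataset,
    group_composition_summary,
    read_captures,
    read_relatedness,
    read_roosts,
    sightings_threshold_curve,
    write_captures,
    write_roosts,
)


class TestEventDerivation:
    def test_grouping_by_date_and_roost(self):
        ds = make_captures(
            [
                ("a", "2015-01-01", "r1", "P", "female", "adult"),
                ("b", "2015-01-01", "r1", "P", "male", "adult"),
                ("a", "2015-01-02", "r1", "P", "female", "adult"),
            ]
        )
        assert ds.n_events == 2
        assert sorted(ds.events["size"]) == [1, 2]

    def test_same_roost_different_dates_are_distinct_events(self):
        ds = make_captures(
            [
                ("a", "2015-01-01", "r1", "P", "female", "adult"),
                ("a", "2015-06-01", "r1", "P", "female", "adult"),
            ]
        )
        assert ds.n_events == 2
        assert ds.sighting_counts()["a"] == 2

    def test_duplicate_bat_in_event_rejected_naming_bat(self):
        with pytest.raises(RecordsError, match="a"):
            make_captures(
                [
                    ("a", "2015-01-01", "r1", "P", "female", "adult"),
                    ("a", "2015-01-01", "r1", "P", "female", "adult"),
                ]
            )

    def test_unknown_codes_rejected_with_row(self):
        with pytest.raises(RecordsError, match="sex"):
            make_captures([("a", "2015-01-01", "r1", "P", "unknown", "adult")])
        with pytest.raises(RecordsError, match="age"):
            make_captures([("a", "2015-01-01", "r1", "P", "female", "subadult")])

    def test_row_order_does_not_change_events(self, rng=np.random.default_rng(5)):
        rows = [
            ("a", "2015-01-01", "r1", "P", "female", "adult"),
            ("b", "2015-01-01", "r1", "P", "male", "adult"),
            ("c", "2015-01-02", "r2", "P", "male", "adult"),
            ("a", "2015-01-02", "r2", "P", "female", "adult"),
        ]
        ds1 = make_captures(rows)
        shuffled = [rows[i] for i in rng.permutation(len(rows))]
        ds2 = make_captures(shuffled)
        pd.testing.assert_frame_equal(ds1.records, ds2.records)
        pd.testing.assert_frame_equal(ds1.events, ds2.events)


class TestRegistryValidation:
    def test_unknown_roost_rejected(self, toy_registry):
        from roostnet.records import CaptureDataset

        df = pd.DataFrame(
            [
                dict(
                    bat_id="a", date="2015-01-01", roost_id="nowhere",
                    population="P", sex="female", age_class="adult",
                    repro_status="unknown",
                )
            ]
        )
        with pytest.raises(RecordsError, match="nowhere"):
            CaptureDataset(df, registry=toy_registry)

    def test_roost_population_constant(self):
        with pytest.raises(RecordsError, match="population"):
            make_captures(
                [
                    ("a", "2015-01-01", "r1", "P", "female", "adult"),
                    ("b", "2015-01-02", "r1", "G", "male", "adult"),
                ]
            )

    def test_planar_distances(self, toy_registry):
        d = toy_registry.distance_matrix(["r1", "r2", "r3"])
        assert d.loc["r1", "r2"] == pytest.approx(100.0)
        assert d.loc["r1", "r3"] == pytest.approx(400.0)
        assert np.allclose(d.to_numpy(), d.to_numpy().T)
        assert (d.to_numpy() >= 0).all()

    def test_geographic_distances_great_circle(self):
        reg = RoostRegistry(
            pd.DataFrame(
                {
                    "roost_id": ["a", "b"],
                    "population": ["P", "P"],
                    "x": [0.0, 0.0],
                    "y": [0.0, 1.0],  # one degree of latitude
                }
            ),
            coordinates="geographic",
        )
        assert reg.distance("a", "b") == pytest.approx(111_195, rel=1e-3)


class TestRoundTrip:
    def test_captures_roundtrip(self, toy_dataset, tmp_path):
        path = tmp_path / "captures.csv"
        write_captures(toy_dataset, path)
        back = read_captures(path)
        pd.testing.assert_frame_equal(toy_dataset.records, back.records)
        pd.testing.assert_frame_equal(toy_dataset.events, back.events)

    def test_roosts_roundtrip(self, toy_registry, tmp_path):
        path = tmp_path / "roosts.csv"
        write_roosts(toy_registry, path)
        back = read_roosts(path)
        assert back.coordinates == toy_registry.coordinates
        pd.testing.assert_frame_equal(
            back.table.reset_index(drop=True),
            toy_registry.table.reset_index(drop=True),
        )

    def test_roosts_header_required(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("roost_id,population,x,y\nr1,P,0,0\n")
        with pytest.raises(RecordsError, match="coordinates"):
            read_roosts(path)

    def test_relatedness_roundtrip_with_missing(self, tmp_path):
        r = np.array([[1.0, 0.25, np.nan], [0.25, 1.0, 0.0], [np.nan, 0.0, 1.0]])
        m = RelatednessMatrix(["a", "b", "c"], r)
        path = tmp_path / "relatedness.csv"
        m.write(path)
        back = read_relatedness(path)
        assert back.ids == m.ids
        np.testing.assert_array_equal(back.r, m.r)

    def test_relatedness_rejects_asymmetry_and_range(self):
        with pytest.raises(RecordsError):
            RelatednessMatrix(["a", "b"], np.array([[1.0, 0.2], [0.3, 1.0]]))
        with pytest.raises(RecordsError):
            RelatednessMatrix(["a", "b"], np.array([[1.0, 1.2], [1.2, 1.0]]))


class TestFiltering:
    def test_min_sightings_counts_post_adult_filter(self):
        # bat f: 1 juvenile + 3 adult captures -> only 3 count as adult sightings
        rows = [("f", f"2015-01-0{d}", "r1", "P", "female", age)
                for d, age in zip(range(1, 5), ["juvenile", "adult", "adult", "adult"])]
        rows += [("g", f"2015-01-0{d}", "r2", "P", "male", "adult") for d in range(1, 5)]
        ds = make_captures(rows)
        out = filter_dataset(ds, adults_only=True, min_sightings=4)
        assert out.bats == ["g"]
        out3 = filter_dataset(ds, adults_only=True, min_sightings=3)
        assert out3.bats == ["f", "g"]
        # juvenile record of f is dropped by the adult filter
        assert (out3.records["age_class"] == "adult").all()

    def test_min_sightings_one_equals_adult_filter(self, toy_dataset):
        a = filter_dataset(toy_dataset, adults_only=True, min_sightings=1)
        b = filter_dataset(toy_dataset, adults_only=True, min_sightings=1)
        assert a.bats == b.bats
        assert set(a.bats) == set(
            toy_dataset.records.loc[
                toy_dataset.records["age_class"] == "adult", "bat_id"
            ]
        )

    def test_idempotent(self, toy_dataset):
        once = filter_dataset(toy_dataset, adults_only=True, min_sightings=2)
        twice = filter_dataset(once, adults_only=True, min_sightings=2)
        pd.testing.assert_frame_equal(once.records, twice.records)

    def test_population_filter(self, toy_dataset):
        out = filter_dataset(toy_dataset, adults_only=False, population="G")
        assert out.bats == ["e"]

    def test_empty_result_warns_not_errors(self, toy_dataset):
        with pytest.warns(UserWarning):
            out = filter_dataset(toy_dataset, adults_only=True, min_sightings=99)
        assert out.n_bats == 0

    def test_brute_force_recount(self, small_bundle):
        ds = filter_dataset(small_bundle.dataset, adults_only=True, min_sightings=3)
        adult_rec = small_bundle.dataset.records
        adult_rec = adult_rec[adult_rec["age_class"] == "adult"]
        tally = {}
        for _, row in adult_rec.iterrows():
            key = (row["bat_id"])
            tally.setdefault(key, set()).add((row["date"], row["roost_id"]))
        expected = sorted(b for b, ev in tally.items() if len(ev) >= 3)
        assert ds.bats == expected


class TestSummaries:
    def test_threshold_curve_small(self):
        rows = [("a", f"2015-01-0{d}", "r1", "P", "female", "adult") for d in (1, 2, 3)]
        rows += [("b", "2015-01-01", "r1", "P", "male", "adult")]
        rows += [("c", "2015-01-02", "r1", "P", "male", "adult")]
        ds = make_captures(rows)
        curve = sightings_threshold_curve(ds)
        assert curve.set_index("N")["n_bats"].to_dict() == {1: 3, 2: 1, 3: 1}
        assert (np.diff(curve["n_bats"]) <= 0).all()
        assert curve.iloc[0]["n_bats"] == ds.n_bats

    def test_threshold_curve_matches_direct_tally(self, small_bundle):
        ds = small_bundle.dataset
        curve = sightings_threshold_curve(ds).set_index("N")["n_bats"]
        counts = ds.records.groupby("bat_id")["event_id"].nunique()
        for n in curve.index:
            assert curve[n] == (counts >= n).sum()

    def test_group_composition_classes(self, toy_dataset):
        comp = group_composition_summary(toy_dataset)
        by_event = comp.set_index("event_id")
        assert by_event.loc["2015-01-01@r1", "composition"] == "all-female"
        assert by_event.loc["2015-02-01@r2", "composition"] == "mixed"
        assert by_event.loc["2015-02-01@r2", "size"] == 3
        assert by_event.loc["2015-02-01@r2", "n_reproductive_males"] == 1
        # classes partition events and sizes agree with sex counts
        assert len(comp) == toy_dataset.n_events
        assert (comp["n_females"] + comp["n_males"] == comp["size"]).all()

    def test_group_composition_matches_simulator_log(self, small_bundle):
        ds, truth = small_bundle.dataset, small_bundle.sampled_truth
        sexes = small_bundle.pedigree.sex_of()
        comp = group_composition_summary(ds).set_index("event_id")
        for _, row in truth.iterrows():
            if not row["detected"]:
                continue
            eid = f"{row['date'].date()}@{row['roost_id']}"
            n_f = sum(sexes[b] == "female" for b in row["detected"])
            n_m = len(row["detected"]) - n_f
            assert comp.loc[eid, "n_females"] == n_f
            assert comp.loc[eid, "n_males"] == n_m
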