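import numpy as np
import pandas as pd
import pytest

from cfopt import plate
from cfopt.exceptions import (
    DegenerateReferenceError,
    IngestionError,
    InsufficientControlsError,
    NonPositiveSignalError,
    OverVolumeError,
    SchemaError,
    StockConcentrationError,
)
from cfopt.plate import (
    PlateDesign,
    complete_concentrations,
    compute_yield,
    concentrations_to_volumes,
    make_yield_record,
    match_measurements,
    plate_qc,
    remove_outliers,
    volumes_to_picklist,
    yields_to_frame,
    frame_to_yields,
)
from cfopt.space import Composition


class TestCompleteConcentrations:
    def test_appends_constant_columns(self, space2):
        partial = pd.DataFrame({"a": [1.0, 2.0], "b": [0.5, 0.5]})
        out = complete_concentrations(partial, {"lysate": 33.0, "hepes": 50.0}, space2)
        assert list(out.columns) == ["a", "b", "lysate", "hepes"]
        assert len(out) == 2
        assert (out["hepes"] == 50.0).all()

    def test_empty_constants_is_identity(self):
        partial = pd.DataFrame({"a": [1.0]})
        out = complete_concentrations(partial, {})
        pd.testing.assert_frame_equal(out, partial)

    def test_unknown_column_raises(self, space2):
        with pytest.raises(SchemaError):
            complete_concentrations(pd.DataFrame({"mystery": [1.0]}), {}, space2)


class TestConcentrationsToVolumes:
    def test_volume_formula_and_quantization(self):
        # 1 mM in 10.5 uL from a 807.7 mM stock -> 13.0 nL raw, nearest
        # droplet multiple is 12.5 (|13.0-12.5| < |13.0-15.0|)
        table = pd.DataFrame({"x": [1.0]})
        vol = concentrations_to_volumes(table, {"x": 10500.0 / 13.0}, replicates=1)
        assert vol.loc[0, "x"] == 12.5

    def test_minimum_transfer_accepted_exactly(self):
        table = pd.DataFrame({"x": [1.0]})
        vol = concentrations_to_volumes(table, {"x": 10500.0 / 12.5}, replicates=1)
        assert vol.loc[0, "x"] == 12.5

    def test_too_concentrated_stock_raises_with_fix(self):
        table = pd.DataFrame({"x": [1.0]})
        with pytest.raises(StockConcentrationError) as exc:
            concentrations_to_volumes(table, {"x": 10500.0 / 10.0}, replicates=1)
        assert exc.value.reagent == "x"
        # suggested stock makes the volume exactly dispensable
        vol = concentrations_to_volumes(table, {"x": exc.value.max_stock_conc}, replicates=1)
        assert vol.loc[0, "x"] >= 12.5

    def test_volume_conservation(self, rng):
        names = [f"r{j}" for j in range(5)]
        table = pd.DataFrame({n: rng.uniform(0.5, 2.0, size=8) for n in names})
        stocks = {n: 100.0 for n in names}
        vol = concentrations_to_volumes(table, stocks, lysate_volume_ul=3.5)
        total = vol[names].sum(axis=1) + vol["lysate"] + vol["water"]
        assert np.allclose(total, 10500.0)
        for n in names:
            v = vol[n].to_numpy()
            assert ((v == 0) | (v >= 12.5)).all()
            assert np.allclose(np.mod(v, 2.5), 0)

    def test_rows_replicated_three_times(self):
        table = pd.DataFrame({"x": [1.0, 2.0]})
        vol = concentrations_to_volumes(table, {"x": 100.0})
        assert len(vol) == 6
        assert list(vol["replicate"]) == [1, 2, 3, 1, 2, 3]

    def test_over_volume_raises(self):
        table = pd.DataFrame({"x": [2.0]})
        with pytest.raises(OverVolumeError):
            concentrations_to_volumes(table, {"x": 1.0}, replicates=1)


class TestPicklist:
    def _volumes(self):
        return pd.DataFrame(
            {
                "id": ["C000", "C001"],
                "x": [25.0, 0.0],
                "water": [1200.0, 500.0],
                "replicate": [1, 1],
            }
        )

    def test_zero_volume_emits_no_instruction(self):
        pick, manual, wmap = volumes_to_picklist(
            self._volumes(), {"x": "A1", "water": "A2"}
        )
        assert (pick["Transfer Volume"] > 0).all()
        assert not ((pick["Reagent"] == "x") & (pick["Destination Well"] == "B2")).any()

    def test_large_volumes_routed_to_manual_sheet(self):
        pick, manual, wmap = volumes_to_picklist(
            self._volumes(), {"x": "A1", "water": "A2"}
        )
        assert set(manual["Reagent"]) == {"water"}
        assert (manual["Transfer Volume"] > 1000.0).all()
        # the 500 nL water transfer stays on the picklist
        assert ((pick["Reagent"] == "water") & (pick["Transfer Volume"] == 500.0)).any()

    def test_roundtrip_reconstructs_volume_table(self):
        vol = self._volumes()
        pick, manual, wmap = volumes_to_picklist(vol, {"x": "A1", "water": "A2"})
        combined = pd.concat([pick, manual])
        rebuilt = combined.pivot_table(
            index="Destination Well", columns="Reagent", values="Transfer Volume", fill_value=0.0
        )
        merged = wmap.set_index("Destination Well").join(rebuilt).fillna(0.0)
        for _, row in vol.iterrows():
            m = merged[merged["Composition ID"] == row["id"]].iloc[0]
            assert m.get("x", 0.0) == row["x"]
            assert m.get("water", 0.0) == row["water"]

    def test_missing_source_well_raises(self):
        from cfopt.exceptions import LayoutError

        with pytest.raises(LayoutError):
            volumes_to_picklist(self._volumes(), {"x": "A1"})


class TestMatchMeasurements:
    def _export(self, wells, value=5.0):
        return pd.DataFrame(
            {"Well": wells, **{f"Read{i}": [value] * len(wells) for i in range(1, 6)}}
        )

    def test_joins_and_averages_reads(self):
        wmap = pd.DataFrame(
            {"Destination Well": ["B1"], "Composition ID": ["C000"], "Replicate": [1]}
        )
        out = match_measurements(wmap, self._export(["B1"]))
        assert len(out) == 1
        assert out.loc[0, "fluorescence"] == 5.0

    def test_missing_well_raises_listing_wells(self):
        wmap = pd.DataFrame(
            {"Destination Well": ["B1", "B2"], "Composition ID": ["C0", "C1"], "Replicate": [1, 1]}
        )
        with pytest.raises(IngestionError, match="B2"):
            match_measurements(wmap, self._export(["B1"]))

    def test_extra_wells_ignored(self):
        wmap = pd.DataFrame(
            {"Destination Well": ["B1"], "Composition ID": ["C0"], "Replicate": [1]}
        )
        out = match_measurements(wmap, self._export(["B1", "Z9"]))
        assert len(out) == 1


class TestOutlierFilter:
    def test_high_cv_removes_farthest_from_median(self):
        # CV of (1000, 1020, 2000) is ~0.42 > 0.30; 2000 is farthest
        kept, removed = remove_outliers([1000.0, 1020.0, 2000.0])
        assert removed == 2
        assert list(kept) == [1000.0, 1020.0]

    def test_identical_values_kept(self):
        kept, removed = remove_outliers([100.0, 100.0, 100.0])
        assert removed is None and len(kept) == 3

    def test_cv_exactly_at_threshold_keeps_all(self):
        # (7, 10, 13): mean 10, sample std 3 -> CV exactly 0.30
        kept, removed = remove_outliers([7.0, 10.0, 13.0])
        assert removed is None

    def test_tie_removes_larger_value(self):
        # symmetric spread: both extremes equidistant from the median
        kept, removed = remove_outliers([1.0, 5.0, 9.0])
        assert removed == 2

    def test_nonpositive_mean_raises(self):
        with pytest.raises(NonPositiveSignalError):
            remove_outliers([-5.0, 1.0, 1.0])

    def test_removes_at_most_one(self, rng):
        for _ in range(200):
            v = rng.lognormal(mean=8, sigma=1.0, size=3)
            kept, removed = remove_outliers(v)
            assert len(kept) == (2 if removed is not None else 3)


class TestYieldNormalization:
    def test_reference_yield_is_one_and_blank_zero(self):
        mean, _, _ = compute_yield([20000.0] * 3, 20000.0, 1000.0)
        assert mean == pytest.approx(1.0)
        mean, _, _ = compute_yield([1000.0] * 3, 20000.0, 1000.0)
        assert mean == pytest.approx(0.0)

    def test_linearity_reaches_large_fold_changes(self):
        auto, ref = 1000.0, 20000.0
        f = auto + 34.0 * (ref - auto)
        mean, _, _ = compute_yield([f] * 3, ref, auto)
        assert mean == pytest.approx(34.0)

    def test_affine_gain_invariance(self, rng):
        auto, ref = 800.0, 15000.0
        f = rng.uniform(1000, 50000, size=3)
        base = compute_yield(f, ref, auto)[0]
        gain = 3.7
        scaled = compute_yield(f * gain, ref * gain, auto * gain)[0]
        assert scaled == pytest.approx(base)

    def test_degenerate_reference_raises(self):
        with pytest.raises(DegenerateReferenceError):
            compute_yield([5.0] * 3, 100.0, 100.0)

    def test_yield_record_encodes_removed_outlier_as_minus_one(self):
        rec = make_yield_record(
            Composition([0, 0]), [1000.0, 1020.0, 2000.0], 2000.0, 500.0
        )
        assert rec.replicate_fluorescences[2] == -1.0
        assert rec.n_used == 2


class TestPlateQC:
    def test_identical_controls_pass(self):
        ctrl = {f"K{i:02d}": float(i + 1) for i in range(13)}
        report = plate_qc(ctrl, {"p1": ctrl})
        assert report.passed and report.r2_vs_previous["p1"] == pytest.approx(1.0)

    def test_systematic_offset_fails_despite_perfect_correlation(self):
        ctrl = {f"K{i:02d}": float(i + 1) for i in range(13)}
        shifted = {k: v * 1.5 for k, v in ctrl.items()}
        report = plate_qc(shifted, {"p1": ctrl})
        assert not report.passed
        assert report.systematic_bias["p1"] == 1
        assert report.r2_vs_previous["p1"] == pytest.approx(1.0)

    def test_shuffled_controls_fail_on_r2(self):
        values = np.arange(1.0, 14.0)
        shuffled = values[np.random.default_rng(0).permutation(13)]
        ctrl = {f"K{i:02d}": values[i] for i in range(13)}
        new = {f"K{i:02d}": shuffled[i] for i in range(13)}
        # independent check of the expected R^2
        expected_r2 = float(np.corrcoef(values, shuffled)[0, 1] ** 2)
        report = plate_qc(new, {"p1": ctrl})
        assert report.r2_vs_previous["p1"] == pytest.approx(expected_r2)
        assert expected_r2 < 0.75 and not report.passed

    def test_single_shared_control_raises(self):
        with pytest.raises(InsufficientControlsError):
            plate_qc({"K00": 1.0}, {"p1": {"K00": 1.0}})


class TestPlateDesign:
    def test_full_plate_well_counts(self, space11):
        comps = space11.sample_unseen(102, seed=0)
        controls = space11.sample_unseen(13, seed=1)
        design = PlateDesign(compositions=comps, controls=controls)
        wmap = design.well_map()
        assert len(wmap) == 102 * 3 + 13 * 3 == 345
        rows = wmap["Destination Well"].str[0]
        ctrl_mask = wmap["Composition ID"].str.startswith("K")
        assert set(rows[ctrl_mask]) <= {"A", "P"}
        assert set(rows[~ctrl_mask]).isdisjoint({"A", "P"})

    def test_capacity_enforced(self, space11):
        comps = space11.sample_unseen(120, seed=0)
        with pytest.raises(OverVolumeError):
            PlateDesign(compositions=comps, controls=[])


def test_yields_frame_roundtrip(space2):
    records = [
        make_yield_record(c, [5000.0, 5100.0, 4900.0], 6000.0, 1000.0, lysate_id="L1")
        for c in space2.initial_design()
    ]
    df = yields_to_frame(records, space2)
    back = frame_to_yields(df, space2)
    assert [r.composition for r in back] == [r.composition for r in records]
    assert np.allclose([r.yield_mean for r in back], [r.yield_mean for r in records])
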