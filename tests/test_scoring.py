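"""AUC integration, normalization, level binning and matrix assembly."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oligopm.errors import (
    DegeneratePlateError,
    MissingControlError,
    ValidationError,
)
from oligopm.scoring import (
    ConsumptionValue,
    KineticCurve,
    aggregate_replicates,
    area_under_curve,
    assign_level,
    blank_and_normalize,
    build_profile_matrix,
    read_kinetics,
    read_profile,
    write_kinetics,
    write_profile,
)

from conftest import make_tiny_catalog, make_tiny_kinetics


def _curve(times, signal, **kw):
    return KineticCurve(np.asarray(times, float), np.asarray(signal, float), **kw)


class TestAreaUnderCurve:
    def test_constant_signal_is_rectangle(self):
        t = np.linspace(0, 72, 97)
        assert area_under_curve(_curve(t, np.full(97, 100.0))).auc == pytest.approx(7200.0)

    def test_zero_signal_is_zero(self):
        t = np.linspace(0, 72, 10)
        assert area_under_curve(_curve(t, np.zeros(10))).auc == 0.0

    def test_trapezoid_exact_for_piecewise_linear(self):
        # signal(t) = t sampled hourly: triangle area 72^2/2
        t = np.arange(0.0, 73.0)
        assert area_under_curve(_curve(t, t)).auc == pytest.approx(2592.0)

    def test_rejects_single_timepoint(self):
        with pytest.raises(ValidationError):
            _curve([1.0], [5.0])

    def test_rejects_unsorted_times_and_range(self):
        with pytest.raises(ValidationError):
            _curve([0.0, 0.0, 1.0], [1, 1, 1])
        with pytest.raises(ValidationError):
            _curve([0.0, 80.0], [1, 1])


class TestAggregateReplicates:
    def test_mean_of_equal_values(self):
        vals = [ConsumptionValue(7200.0, "s", "PM6"), ConsumptionValue(7200.0, "s", "PM6")]
        assert aggregate_replicates(vals).auc == 7200.0

    def test_mean_of_two(self):
        vals = [ConsumptionValue(0.0, "s", "PM6"), ConsumptionValue(100.0, "s", "PM6")]
        assert aggregate_replicates(vals).auc == 50.0

    def test_empty_list_rejected(self):
        with pytest.raises(ValidationError):
            aggregate_replicates([])

    def test_mixed_strains_rejected(self):
        with pytest.raises(ValidationError):
            aggregate_replicates(
                [ConsumptionValue(1.0, "a", "PM6"), ConsumptionValue(1.0, "b", "PM6")]
            )

    def test_mean_approaches_generator_mean(self, rng):
        draws = rng.normal(500.0, 50.0, size=200)
        vals = [ConsumptionValue(float(d), "s", "PM6") for d in draws]
        se = 50.0 / np.sqrt(200)
        assert abs(aggregate_replicates(vals).auc - 500.0) < 4 * se


class TestBlankAndNormalize:
    neg = ConsumptionValue(300.0, "s", "PM6")
    gln = ConsumptionValue(4800.0, "s", "PM6")

    def test_positive_control_maps_to_100(self):
        assert blank_and_normalize(self.gln, self.neg, self.gln) == pytest.approx(100.0)

    def test_negative_control_maps_to_0(self):
        assert blank_and_normalize(self.neg, self.neg, self.gln) == 0.0

    def test_affine_linearity(self):
        v = ConsumptionValue(300.0 + 0.2 * (4800.0 - 300.0), "s", "PM6")
        assert blank_and_normalize(v, self.neg, self.gln) == pytest.approx(20.0)

    def test_below_blank_floored_at_zero(self):
        v = ConsumptionValue(100.0, "s", "PM6")
        assert blank_and_normalize(v, self.neg, self.gln) == 0.0

    def test_degenerate_plate_raises(self):
        with pytest.raises(DegeneratePlateError):
            blank_and_normalize(self.neg, self.gln, self.gln)

    def test_unblanked_mode(self):
        v = ConsumptionValue(2400.0, "s", "PM6")
        assert blank_and_normalize(v, self.neg, self.gln, blank=False) == pytest.approx(50.0)


class TestAssignLevel:
    @pytest.mark.parametrize(
        "percent, level",
        [
            (0.0, 0),
            (20.0, 0),  # utilization requires strictly more than 20 %
            (20.0001, 1),
            (40.0, 1),
            (41.0, 2),
            (60.0, 2),
            (80.0, 3),
            (100.0, 4),
            (100.0001, 5),
            (120.0, 5),
        ],
    )
    def test_bin_edges(self, percent, level):
        assert assign_level(percent) == level

    def test_negative_percent_rejected(self):
        with pytest.raises(ValidationError):
            assign_level(-0.1)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        st.floats(min_value=0, max_value=200),
        st.floats(min_value=0, max_value=200),
    )
    def test_monotone_in_percent(self, a, b):
        lo, hi = sorted((a, b))
        assert assign_level(lo) <= assign_level(hi)


class TestBuildProfileMatrix:
    def test_single_strain_gln_equal_signal_is_level_4(self):
        catalog = make_tiny_catalog(1)
        kin, _, cfg = make_tiny_kinetics({"s1": [4]}, catalog)
        # overwrite the substrate well signal with the glutamine well signal
        pos = kin[kin.well == "A2"].copy()
        sub_well = catalog[0].substrates()[0][0]
        pos["well"] = sub_well
        kin = pd.concat([kin[kin.well != sub_well], pos], ignore_index=True)
        m = build_profile_matrix(kin, catalog)
        assert m.levels.shape == (1, 1)
        assert int(m.levels.iloc[0, 0]) == 4
        assert float(m.percents.iloc[0, 0]) == pytest.approx(100.0)

    def test_zero_noise_round_trip_recovers_planted_levels(self):
        catalog = make_tiny_catalog(10)
        planted = {"s1": [0, 1, 2, 3, 4, 5, 0, 3, 1, 5], "s2": [5, 4, 3, 2, 1, 0, 2, 0, 4, 1]}
        kin, truth, _ = make_tiny_kinetics(planted, catalog, replicates=2)
        m = build_profile_matrix(kin, catalog)
        rec = m.levels.loc[truth.index, truth.columns].astype(int)
        assert (rec.to_numpy() == truth.to_numpy()).all()

    def test_failed_positive_control_names_the_plate(self):
        catalog = make_tiny_catalog(2)
        kin, _, _ = make_tiny_kinetics({"s1": [1, 2]}, catalog)
        # flatten the glutamine well to the baseline -> no dynamic range
        kin.loc[kin.well == "A2", "signal"] = 50.0
        with pytest.raises(DegeneratePlateError, match="PM6"):
            build_profile_matrix(kin, catalog)

    def test_missing_control_well_is_an_error(self):
        catalog = make_tiny_catalog(2)
        kin, _, _ = make_tiny_kinetics({"s1": [1, 2]}, catalog)
        with pytest.raises(MissingControlError, match="s1"):
            build_profile_matrix(kin[kin.well != "A1"], catalog)

    def test_missing_substrate_well_is_na_not_zero(self):
        catalog = make_tiny_catalog(3)
        kin, _, _ = make_tiny_kinetics({"s1": [2, 3, 4]}, catalog)
        dropped = catalog[0].substrates()[1][0]
        m = build_profile_matrix(kin[kin.well != dropped], catalog)
        assert m.levels.iloc[0].isna().tolist() == [False, True, False]

    def test_scale_invariance_of_percents_and_levels(self):
        catalog = make_tiny_catalog(5)
        kin, _, _ = make_tiny_kinetics(
            {"s1": [1, 2, 3, 4, 5]}, catalog, noise_sd=5.0, seed=7
        )
        m1 = build_profile_matrix(kin, catalog)
        scaled = kin.copy()
        scaled["signal"] *= 3.7
        m2 = build_profile_matrix(scaled, catalog)
        np.testing.assert_allclose(
            m1.percents.to_numpy(float), m2.percents.to_numpy(float), rtol=1e-12
        )
        assert m1.levels.equals(m2.levels)


class TestKineticIO:
    def test_long_and_wide_dialects_agree(self, tmp_path):
        catalog = make_tiny_catalog(2)
        kin, _, _ = make_tiny_kinetics({"s1": [1, 2]}, catalog)
        long_path = tmp_path / "long.tsv"
        write_kinetics(kin, str(long_path))
        wide = kin.pivot_table(
            index=["strain_id", "plate_id", "replicate_id", "time_h"],
            columns="well",
            values="signal",
        ).reset_index()
        wide_path = tmp_path / "wide.tsv"
        wide.to_csv(wide_path, sep="\t", index=False)
        a = read_kinetics(str(long_path))
        b = read_kinetics(str(wide_path))
        key = ["strain_id", "plate_id", "well", "replicate_id", "time_h"]
        a = a.sort_values(key).reset_index(drop=True)
        b = b.sort_values(key).reset_index(drop=True)
        b["replicate_id"] = b["replicate_id"].astype(str)
        np.testing.assert_allclose(a["signal"], b["signal"])

    def test_unrecognized_header_rejected(self, tmp_path):
        p = tmp_path / "bad.tsv"
        pd.DataFrame({"x": [1]}).to_csv(p, sep="\t", index=False)
        with pytest.raises(ValidationError):
            read_kinetics(str(p))

    def test_profile_round_trip_is_byte_stable(self, tmp_path):
        catalog = make_tiny_catalog(4)
        kin, _, _ = make_tiny_kinetics({"s1": [0, 1, 4, 5], "s2": [2, 3, 0, 1]}, catalog)
        m = build_profile_matrix(kin, catalog)
        lv1, pc1 = tmp_path / "lv1.tsv", tmp_path / "pc1.tsv"
        write_profile(m, str(lv1), str(pc1))
        back = read_profile(str(lv1), str(pc1))
        assert back.levels.equals(m.levels)
        lv2, pc2 = tmp_path / "lv2.tsv", tmp_path / "pc2.tsv"
        write_profile(back, str(lv2), str(pc2))
        assert lv1.read_bytes() == lv2.read_bytes()
        assert pc1.read_bytes() == pc2.read_bytes()
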