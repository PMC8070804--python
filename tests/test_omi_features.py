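"""Redox ratio, per-cell aggregation, normalization, OMI index, Z-scores."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from omiflim import omi_features as of
from omiflim import synthetic_data as sd


class TestRedoxRatioMap:
    def test_equal_images_all_ones(self):
        img = np.full((8, 8), 5.0)
        np.testing.assert_allclose(of.redox_ratio_map(img, img), 1.0)

    def test_double_nadh_gives_two(self):
        fad = np.full((8, 8), 3.0)
        np.testing.assert_allclose(of.redox_ratio_map(2 * fad, fad), 2.0)

    def test_zero_fad_pixels_invalid(self):
        nadh = np.ones((4, 4))
        fad = np.ones((4, 4))
        fad[1, 2] = 0.0
        out = of.redox_ratio_map(nadh, fad)
        assert np.isnan(out[1, 2])
        assert np.isfinite(out).sum() == 15

    def test_random_pair_elementwise_oracle(self, rng):
        nadh = rng.uniform(1, 10, (16, 16))
        fad = rng.uniform(1, 10, (16, 16))
        np.testing.assert_allclose(of.redox_ratio_map(nadh, fad),
                                   nadh / fad, rtol=1e-12)


class _UniformMaps:
    """Minimal LifetimeImageSet stand-in with uniform values."""

    def __init__(self, shape, tau1, tau2, alpha1, intensity, valid=None):
        self.tau1 = np.full(shape, tau1)
        self.tau2 = np.full(shape, tau2)
        self.alpha1 = np.full(shape, alpha1)
        self.tau_m = self.alpha1 * self.tau1 + (1 - self.alpha1) * self.tau2
        self.intensity = np.full(shape, float(intensity))
        self.valid_mask = np.ones(shape, bool) if valid is None else valid


class TestAggregateCell:
    def _cyto(self, shape=(20, 20)):
        cyto = np.zeros(shape, dtype=np.int32)
        cyto[2:8, 2:8] = 1
        cyto[12:18, 12:18] = 2
        return cyto

    def test_uniform_cell_record_equals_pixel_value(self):
        shape = (20, 20)
        nadh = _UniformMaps(shape, 0.4, 2.5, 0.7, 800.0)
        fad = _UniformMaps(shape, 0.3, 2.0, 0.75, 500.0)
        ratio = np.full(shape, 1.6)
        df = of.aggregate_cell(nadh, fad, ratio, self._cyto(), "P1", "control")
        assert len(df) == 2
        assert df["nadh_tau_m"].iloc[0] == pytest.approx(0.7 * 0.4 + 0.3 * 2.5)
        assert df["redox_ratio"].iloc[0] == pytest.approx(1.6)
        assert set(df["cell_id"]) == {1, 2}

    def test_masked_mean_oracle_two_cells(self, rng):
        shape = (20, 20)
        nadh = _UniformMaps(shape, 0.4, 2.5, 0.7, 800.0)
        nadh.tau_m = rng.uniform(0.8, 1.2, shape)
        fad = _UniformMaps(shape, 0.3, 2.0, 0.75, 500.0)
        ratio = rng.uniform(1.0, 2.0, shape)
        cyto = self._cyto()
        df = of.aggregate_cell(nadh, fad, ratio, cyto, "P1", "control")
        for cid in (1, 2):
            row = df[df.cell_id == cid].iloc[0]
            mask = cyto == cid
            assert row["nadh_tau_m"] == pytest.approx(nadh.tau_m[mask].mean())
            assert row["redox_ratio"] == pytest.approx(ratio[mask].mean())

    def test_fully_invalid_cell_dropped(self, caplog):
        shape = (20, 20)
        valid = np.ones(shape, bool)
        cyto = self._cyto()
        valid[cyto == 2] = False
        nadh = _UniformMaps(shape, 0.4, 2.5, 0.7, 800.0, valid=valid)
        fad = _UniformMaps(shape, 0.3, 2.0, 0.75, 500.0)
        with caplog.at_level("INFO", logger="omiflim.omi_features"):
            df = of.aggregate_cell(nadh, fad, np.ones(shape), cyto,
                                   "P1", "control")
        assert df["cell_id"].tolist() == [1]
        assert any("dropped" in r.message for r in caplog.records)


class TestNormalizeToControl:
    def test_control_means_exactly_one(self, cohort_table):
        out = of.normalize_to_control(cohort_table)
        ctrl = out[out.condition == "control"]
        for patient, grp in ctrl.groupby("patient_id"):
            for var in ("norm_redox_ratio", "norm_nadh_tau_m",
                        "norm_fad_tau_m"):
                assert grp[var].mean() == pytest.approx(1.0, abs=1e-12)

    def test_doubling_treated_redox_doubles_normalized(self, cohort_table):
        df = cohort_table.copy()
        out1 = of.normalize_to_control(df)
        df2 = df.copy()
        treated = df2.condition != "control"
        df2.loc[treated, "redox_ratio"] *= 2.0
        out2 = of.normalize_to_control(df2)
        np.testing.assert_allclose(
            out2.loc[treated, "norm_redox_ratio"],
            2.0 * out1.loc[treated, "norm_redox_ratio"])

    def test_missing_control_rejected(self, cohort_table):
        df = cohort_table[cohort_table.condition != "control"]
        with pytest.raises(ValueError, match="control"):
            of.normalize_to_control(df)

    def test_group_mean_division_oracle(self, cohort_table):
        out = of.normalize_to_control(cohort_table)
        sub = cohort_table[cohort_table.patient_id == "P3"]
        ctrl_mean = sub[sub.condition == "control"]["redox_ratio"].mean()
        oracle = sub["redox_ratio"] / ctrl_mean
        np.testing.assert_allclose(
            out.loc[sub.index, "norm_redox_ratio"], oracle)


class TestOmiIndex:
    def test_unit_triple_gives_one(self):
        assert of.omi_index(1.0, 1.0, 1.0) == pytest.approx(1.0)

    def test_printed_arithmetic(self):
        assert of.omi_index(0.8, 0.9, 1.1) == pytest.approx(0.6)

    @settings(deadline=None, max_examples=50)
    @given(st.floats(0.1, 3.0), st.floats(0.1, 3.0), st.floats(0.1, 3.0),
           st.floats(-1.0, 1.0))
    def test_linearity_in_redox(self, rr, ntm, ftm, delta):
        base = of.omi_index(rr, ntm, ftm)
        shifted = of.omi_index(rr + delta, ntm, ftm)
        assert shifted - base == pytest.approx(delta, abs=1e-12)

    def test_random_triples_dot_product_oracle(self, rng):
        triples = rng.uniform(0.2, 2.0, size=(500, 3))
        oracle = triples @ np.array([1.0, 1.0, -1.0])
        np.testing.assert_allclose(
            of.omi_index(triples[:, 0], triples[:, 1], triples[:, 2]),
            oracle, atol=1e-12)

    def test_control_mean_omi_index_near_one(self, cohort_table):
        out = of.add_omi_index(cohort_table)
        ctrl = out[(out.condition == "control")]
        for _, grp in ctrl.groupby("patient_id"):
            if len(grp) >= 300:
                assert abs(grp["omi_index"].mean() - 1.0) < 0.02

    def test_responder_preset_decreases_omi_index(self):
        # lower redox ratio + NAD(P)H tau_m, higher FAD tau_m => lower index
        tab = of.add_omi_index(sd.stc1_preset(seed=21))
        ctrl = tab[tab.condition == "control"]["omi_index"].mean()
        combo = tab[tab.condition == "combination"]["omi_index"].mean()
        assert combo < ctrl


class TestZscoreTable:
    def _table(self, shift, rng, n=200):
        ctrl = rng.normal(1.0, 0.1, n)
        treat = rng.normal(1.0 + shift * 0.1, 0.1, n)
        return pd.DataFrame({
            "patient_id": ["P1"] * (2 * n),
            "condition": ["control"] * n + ["everolimus"] * n,
            "redox_ratio": np.concatenate([ctrl, treat]),
        })

    def test_no_shift_z_near_zero(self, rng):
        z = of.zscore_table(self._table(0.0, rng), variables=["redox_ratio"])
        assert abs(z["z_score"].iloc[0]) < 0.3

    def test_one_sd_shift_z_near_one(self, rng):
        z = of.zscore_table(self._table(1.0, rng), variables=["redox_ratio"])
        assert z["z_score"].iloc[0] == pytest.approx(1.0, abs=0.35)

    def test_cohort_against_direct_formula(self, cohort_table):
        z = of.zscore_table(cohort_table)
        sub = cohort_table[cohort_table.patient_id == "P2"]
        ctrl = sub[sub.condition == "control"]["nadh_tau_m"]
        trt = sub[sub.condition == "combination"]["nadh_tau_m"]
        oracle = (trt.mean() - ctrl.mean()) / ctrl.std(ddof=1)
        got = z[(z.patient_id == "P2") & (z.condition == "combination")
                & (z.variable == "nadh_tau_m")]["z_score"].iloc[0]
        assert got == pytest.approx(oracle)
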