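"""Exclusion filters and analyte transforms against hand-computed oracles."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from twinprot import (
    filter_subjects,
    log_standardize,
    mask_outliers,
    normalize_volumes,
    van_der_waerden,
)
from conftest import matrix_from_columns

E = math.e


class TestFilterSubjects:
    def test_clean_roster_passes_unchanged(self, tiny_roster):
        roster = tiny_roster.copy()
        roster["apoe_e4_count"] = 0.0
        kept, audit = filter_subjects(roster)
        pd.testing.assert_frame_equal(kept, roster)
        assert len(audit) == 0

    def test_single_double_e4_subject_fully_excluded(self, tiny_roster):
        solo = tiny_roster.iloc[[4]].reset_index(drop=True)  # apoe_e4_count == 2
        kept, audit = filter_subjects(solo)
        assert len(kept) == 0
        assert audit["reason"].tolist() == ["double_apoe_e4"]

    def test_widowed_cotwin_becomes_singleton(self, tiny_roster):
        kept, audit = filter_subjects(tiny_roster)
        assert len(kept) == 5
        widow = kept[kept["subject_id"] == "P0003-2"].iloc[0]
        assert widow["pair_id"] is None or pd.isna(widow["pair_id"])
        assert widow["zygosity"] == "NA"

    def test_idempotent(self, tiny_roster):
        once, _ = filter_subjects(tiny_roster)
        twice, audit2 = filter_subjects(once)
        pd.testing.assert_frame_equal(once, twice)
        assert len(audit2) == 0

    def test_reason_priority_order(self, tiny_roster):
        roster = tiny_roster.copy()
        roster.loc[0, "haemolysed"] = True
        roster.loc[1, "qc_fail"] = True
        _, audit = filter_subjects(roster)
        reasons = dict(zip(audit["subject_id"], audit["reason"]))
        assert reasons["P0001-1"] == "haemolysed"
        assert reasons["P0001-2"] == "qc_fail"
        assert reasons["P0003-1"] == "double_apoe_e4"

    def test_empty_roster_rejected(self, tiny_roster):
        with pytest.raises(ValueError):
            filter_subjects(tiny_roster.iloc[0:0])


class TestLogStandardize:
    def test_geometric_ladder_maps_to_unit_zscores(self):
        m = matrix_from_columns({"A": [E, E**2, E**3]})
        out = log_standardize(m)
        assert out.transform_state == "standardized"
        np.testing.assert_allclose(out.values["A"], [-1.0, 0.0, 1.0], atol=1e-12)

    def test_constant_analyte_is_zero_variance_error(self):
        with pytest.raises(ValueError, match="zero-variance"):
            log_standardize(matrix_from_columns({"A": [5.0, 5.0, 5.0]}))

    def test_missing_entry_preserved_and_others_standardized_over_n2(self):
        m = matrix_from_columns({"A": [E, np.nan, E**3]})
        out = log_standardize(m)
        col = out.values["A"]
        assert np.isnan(col.iloc[1])
        # logs 1 and 3: mean 2, sample s.d. sqrt(2)
        np.testing.assert_allclose(
            col.dropna(), [-1 / np.sqrt(2), 1 / np.sqrt(2)], atol=1e-12
        )

    def test_non_positive_value_names_subject_and_analyte(self):
        m = matrix_from_columns({"A": [1.0, 2.0, 3.0], "B": [1.0, -4.0, 2.0]})
        with pytest.raises(ValueError, match=r"S001.*'B'"):
            log_standardize(m)

    def test_requires_raw_state(self):
        m = matrix_from_columns({"A": [0.1, 0.2, 0.3]}, transform_state="standardized")
        with pytest.raises(ValueError, match="raw"):
            log_standardize(m)


class TestMaskOutliers:
    def test_strict_two_sided_threshold(self):
        m = matrix_from_columns(
            {"A": [2.6, -2.6, 2.4, 2.5, 0.0]}, transform_state="standardized"
        )
        out, counts = mask_outliers(m, k=2.5)
        col = out.values["A"]
        assert np.isnan(col.iloc[0]) and np.isnan(col.iloc[1])
        assert col.iloc[2] == 2.4 and col.iloc[3] == 2.5  # exactly 2.5 is kept
        assert counts["A"] == 2

    def test_all_zero_column_untouched(self):
        m = matrix_from_columns({"A": [0.0, 0.0, 0.0]}, transform_state="standardized")
        out, counts = mask_outliers(m)
        assert counts["A"] == 0
        assert out.values["A"].notna().all()

    def test_nonpositive_threshold_rejected(self):
        m = matrix_from_columns({"A": [0.0]}, transform_state="standardized")
        with pytest.raises(ValueError):
            mask_outliers(m, k=0.0)

    def test_gaussian_exceedance_stays_below_ceiling(self):
        # expected |z| > 2.5 mass is ~1.24%; assert < 3% at n=1000
        rng = np.random.default_rng(3)
        raw = np.exp(rng.standard_normal((1000, 5)))
        m = matrix_from_columns({f"A{i}": raw[:, i] for i in range(5)})
        masked, counts = mask_outliers(log_standardize(m))
        assert counts.sum() / masked.values.size < 0.03


class TestVanDerWaerden:
    def test_three_value_oracle(self):
        out = van_der_waerden([5.0, 1.0, 9.0])
        np.testing.assert_allclose(out, [0.0, -0.67448975, 0.67448975], atol=1e-6)

    def test_too_few_observed_rejected(self):
        with pytest.raises(ValueError, match=">= 3"):
            van_der_waerden([1.0, 2.0, np.nan])

    def test_missing_stays_missing_and_mean_near_zero(self):
        out = van_der_waerden([3.0, np.nan, 1.0, 2.0, 10.0])
        assert np.isnan(out.iloc[1])
        assert abs(out.dropna().sum()) < 1e-9

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(
        st.lists(st.integers(-10_000, 10_000), min_size=3, max_size=40, unique=True)
    )
    def test_invariant_to_monotone_transform(self, values):
        arr = np.asarray(values, dtype=float)
        base = van_der_waerden(arr)
        cubed = van_der_waerden(arr**3)  # strictly monotone, exact in floats
        np.testing.assert_allclose(base, cubed, atol=1e-12)
        order = np.argsort(arr)
        assert (np.diff(base.to_numpy()[order]) > 0).all()


class TestNormalizeVolumes:
    def _phen(self, lh, icv=None):
        n = len(lh)
        return pd.DataFrame(
            {
                "lh_volume": lh,
                "rh_volume": np.linspace(1.0, 2.0, n),
                "le_volume": np.linspace(2.0, 3.0, n),
                "re_volume": np.linspace(1.5, 2.5, n),
                "icv": icv if icv is not None else np.full(n, np.nan),
            }
        )

    def test_log_zscore_oracle(self):
        out = normalize_volumes(self._phen([E, E**2, E**3]), use_icv=False)
        np.testing.assert_allclose(out["lh_volume"], [-1.0, 0.0, 1.0], atol=1e-12)

    def test_constant_region_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            normalize_volumes(self._phen([2.0, 2.0, 2.0]), use_icv=False)

    def test_icv_division_happens_before_log(self):
        icv = np.array([1.0, 2.0, 1.0])
        ph = self._phen([E, 2 * E**2, E**3], icv=icv)
        out = normalize_volumes(ph, use_icv=True)
        # after division the ladder is e, e^2, e^3 again
        np.testing.assert_allclose(out["lh_volume"], [-1.0, 0.0, 1.0], atol=1e-12)

    def test_missing_icv_rejected(self):
        with pytest.raises(ValueError, match="ICV"):
            normalize_volumes(self._phen([1.0, 2.0, 3.0]), use_icv=True)
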