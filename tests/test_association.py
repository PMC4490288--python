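"""GEE scans, BH correction and the stratified replication workflow."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.multitest import multipletests

from twinprot import (
    SimulationTruth,
    bh_adjust,
    gee_fit,
    scan,
    simulate_twin_cohort,
    subgroup_replication,
)
from twinprot.preprocess import log_standardize, normalize_volumes
from twinprot.simulate import make_anm_fixture
from conftest import simulate_standardized


class TestGEEFit:
    def test_all_singleton_gaussian_equals_ols_with_hc0(self):
        rng = np.random.default_rng(1)
        n = 60
        X = pd.DataFrame({"const": 1.0, "x": rng.standard_normal(n)})
        y = 0.4 * X["x"].to_numpy() + rng.standard_normal(n)
        fit = gee_fit(y, X, [f"s{i}" for i in range(n)])
        ols = sm.OLS(y, X).fit()
        np.testing.assert_allclose(fit.params, ols.params, atol=1e-10)
        np.testing.assert_allclose(fit.cov_robust, ols.cov_HC0, atol=1e-10)
        assert fit.alpha == 0.0
        assert "all_singleton_alpha_zero" in fit.flags

    def test_duplicated_subjects_flag_alpha_boundary(self):
        rng = np.random.default_rng(2)
        base_y = rng.standard_normal(40)
        base_x = rng.standard_normal(40)
        fit = gee_fit(
            np.repeat(base_y, 2),
            pd.DataFrame({"const": 1.0, "x": np.repeat(base_x, 2)}),
            np.repeat(np.arange(40), 2),
        )
        assert "alpha_boundary" in fit.flags

    def test_oversized_clusters_rejected(self):
        X = pd.DataFrame({"const": np.ones(6)})
        with pytest.raises(ValueError, match="size 1 or 2"):
            gee_fit(np.zeros(6), X, [1, 1, 1, 2, 2, 2])

    def test_rank_deficient_design_rejected(self):
        X = pd.DataFrame({"const": np.ones(10), "dup": np.ones(10)})
        with pytest.raises(ValueError, match="rank"):
            gee_fit(np.zeros(10), X, np.arange(10))

    def test_binomial_outcome_must_be_binary(self):
        X = pd.DataFrame({"const": np.ones(10)})
        with pytest.raises(ValueError, match="binomial"):
            gee_fit(np.arange(10, dtype=float), X, np.arange(10), family="binomial")

    def test_sandwich_covariance_symmetric_psd(self, small_twin_cohort):
        roster, prot, phen = small_twin_cohort
        X = pd.DataFrame(
            {"const": 1.0, "x": prot.values["A0001"].to_numpy()},
            index=prot.subjects,
        )
        clusters = roster.set_index("subject_id")["pair_id"].reindex(prot.subjects)
        fit = gee_fit(
            phen["delta_pal"].to_numpy(), X,
            clusters.fillna(pd.Series(prot.subjects, index=prot.subjects)),
        )
        cov = fit.cov_robust.to_numpy()
        np.testing.assert_allclose(cov, cov.T, atol=1e-12)
        assert np.linalg.eigvalsh(cov).min() >= -1e-12
        assert -1.0 < fit.alpha < 1.0


class TestBHAdjust:
    def test_step_up_oracle(self):
        np.testing.assert_allclose(
            bh_adjust([0.001, 0.02, 0.04, 0.5]),
            [0.004, 0.04, 0.04 * 4 / 3, 0.5],
            atol=1e-12,
        )

    def test_degenerate_inputs(self):
        np.testing.assert_array_equal(bh_adjust([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])
        assert bh_adjust([0.037]) == pytest.approx([0.037])
        with pytest.raises(ValueError):
            bh_adjust([0.2, 1.3])
        with pytest.raises(ValueError):
            bh_adjust([])

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=60), st.randoms())
    def test_matches_reference_and_is_permutation_equivariant(self, p, rnd):
        p = np.asarray(p)
        q = bh_adjust(p)
        _, q_ref, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(q, q_ref, atol=1e-12)
        perm = np.asarray(rnd.sample(range(len(p)), len(p)))
        np.testing.assert_allclose(bh_adjust(p[perm]), q[perm], atol=1e-12)
        assert (q >= p - 1e-15).all()


class TestScan:
    def test_constant_outcome_rejected(self, small_twin_cohort):
        roster, prot, phen = small_twin_cohort
        const = pd.Series(1.0, index=prot.subjects)
        with pytest.raises(ValueError, match="constant"):
            scan(prot, const, roster)

    def test_raw_matrix_rejected(self, small_twin_cohort):
        roster, _, phen = small_twin_cohort
        truth = SimulationTruth.uniform(
            a2=0.4, c2=0.1, e2=0.5, n_analytes=3,
            n_mz_pairs=50, n_dz_pairs=43, n_singletons=9,
            missing_rate=0.0, seed=101,
        )
        _, raw, _ = simulate_twin_cohort(truth)
        with pytest.raises(ValueError, match="preprocessed"):
            scan(raw, phen["delta_pal"], roster)

    def test_results_independent_of_analyte_and_row_order(self, small_twin_cohort):
        roster, prot, phen = small_twin_cohort
        res1 = scan(prot, phen["delta_pal"], roster).set_index("analyte")
        shuffled = type(prot)(
            prot.values[list(prot.analytes[::-1])].iloc[::-1], prot.transform_state
        )
        res2 = scan(
            shuffled, phen["delta_pal"], roster.iloc[::-1].reset_index(drop=True)
        ).set_index("analyte")
        for col in ("beta", "se", "p", "q"):
            np.testing.assert_allclose(
                res1[col].sort_index(), res2[col].sort_index(), atol=1e-9
            )

    def test_planted_effect_attains_minimum_q(self):
        """One analyte with a real effect should top every scan it appears in."""
        wins = 0
        n_reps = 40
        for rep in range(n_reps):
            beta = np.zeros(15)
            beta[7] = 0.6
            truth = SimulationTruth(
                a2=np.full(15, 0.3), c2=np.full(15, 0.1), e2=np.full(15, 0.6),
                beta=beta, n_mz_pairs=50, n_dz_pairs=43, n_singletons=9,
                missing_rate=0.0, seed=1000 + rep,
            )
            roster, prot, phen = simulate_standardized(truth)
            res = scan(prot, phen["delta_pal"], roster)
            wins += res.loc[res["q"].idxmin(), "analyte"] == "A0008"
        assert wins / n_reps >= 0.9

    def test_null_panel_controls_false_discoveries(self):
        """Under a global null the fraction of scans with any q<0.05 stays small.

        Tail calibration of sandwich-based Wald p-values needs a reasonable
        number of clusters, so this uses 300 pairs per zygosity.
        """
        any_hit = 0
        n_reps = 25
        for rep in range(n_reps):
            truth = SimulationTruth.uniform(
                a2=0.4, c2=0.1, e2=0.5, n_analytes=40, beta=0.0,
                n_mz_pairs=300, n_dz_pairs=300,
                missing_rate=0.0, seed=4000 + rep,
            )
            roster, prot, phen = simulate_standardized(truth)
            res = scan(prot, phen["delta_pal"], roster)
            any_hit += (res["q"] < 0.05).any()
        assert any_hit / n_reps <= 0.2

    def test_constant_covariate_dropped_with_all_female_cohort(self, small_twin_cohort):
        roster, prot, phen = small_twin_cohort  # sex is constant "F"
        res = scan(prot, phen["delta_pal"], roster, covariates=("age", "sex", "centre"))
        assert len(res) == prot.shape[1]


@pytest.fixture(scope="module")
def anm():
    roster, prot, phen = make_anm_fixture(
        n_analytes=6,
        planted={
            "analyte": "A0002", "region": "le_volume",
            "beta": -0.6, "stratum": "female-controls",
        },
    )
    prot = log_standardize(prot)
    phen = normalize_volumes(phen, use_icv=True)
    return roster, prot, phen


class TestSubgroupReplication:
    def test_bh_family_is_shortlist_by_region(self, anm):
        roster, prot, phen = anm
        res = subgroup_replication(prot, phen, roster, ["A0001", "A0002", "A0003"])
        for stratum, df in res.items():
            assert len(df) == 12  # 3 analytes x 4 regions

    def test_single_region_all_stratum_matches_scan(self, anm):
        roster, prot, phen = anm
        res = subgroup_replication(
            prot, phen, roster, list(prot.analytes),
            regions=["le_volume"], strata=("all",),
        )["all"].set_index("analyte")
        direct = scan(
            prot, phen["le_volume"], roster, covariates=("age", "centre")
        ).set_index("analyte")
        for col in ("beta", "se", "p", "q"):
            np.testing.assert_allclose(res[col], direct[col], atol=1e-9)

    def test_planted_effect_strongest_in_female_controls(self, anm):
        roster, prot, phen = anm
        res = subgroup_replication(prot, phen, roster, ["A0002"], regions=["le_volume"])
        r2 = {s: df["r_squared"].iloc[0] for s, df in res.items()}
        assert r2["female-controls"] == max(r2.values())
        assert res["female-controls"]["beta"].iloc[0] < 0

    def test_empty_shortlist_rejected(self, anm):
        roster, prot, phen = anm
        with pytest.raises(ValueError, match="shortlist"):
            subgroup_replication(prot, phen, roster, [])

    def test_empty_stratum_skipped(self, anm):
        roster, prot, phen = anm
        males_only = roster[roster["sex"] == "M"].reset_index(drop=True)
        res = subgroup_replication(
            prot.subset_subjects(males_only["subject_id"]), phen, males_only,
            ["A0001"], strata=("all", "female-controls"),
        )
        assert "all" in res and "female-controls" not in res
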