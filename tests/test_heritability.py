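"""ACE fitting: closed-form initializer, ML estimates, CIs, panel summary."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from twinprot import (
    PairedTrait,
    SimulationTruth,
    ace_confint,
    falconer,
    falconer_from_correlations,
    fit_ace,
    panel_heritability,
)
from twinprot.heritability import paired_trait_from_values
from conftest import simulate_standardized


def _paired_trait(a2, c2, e2, n_mz, n_dz, seed):
    truth = SimulationTruth.uniform(
        a2=a2, c2=c2, e2=e2, n_mz_pairs=n_mz, n_dz_pairs=n_dz,
        missing_rate=0.0, seed=seed,
    )
    roster, prot, _ = simulate_standardized(truth)
    return paired_trait_from_values(prot.values["A0001"], roster)


@pytest.mark.parametrize(
    "r_mz, r_dz, expected",
    [
        (0.6, 0.35, (0.50, 0.10, 0.40)),
        (0.0, 0.0, (0.0, 0.0, 1.0)),
        # negative raw a2 is clipped, then (0, 0.4, 0.8) renormalizes
        (0.2, 0.3, (0.0, 1.0 / 3.0, 2.0 / 3.0)),
    ],
)
def test_falconer_closed_form(r_mz, r_dz, expected):
    np.testing.assert_allclose(
        falconer_from_correlations(r_mz, r_dz), expected, atol=1e-12
    )


def test_falconer_from_data_tracks_truth():
    pt = _paired_trait(0.5, 0.2, 0.3, 4000, 4000, seed=9)
    a2, c2, e2 = falconer(pt)
    assert a2 == pytest.approx(0.5, abs=0.06)
    assert c2 == pytest.approx(0.2, abs=0.05)
    assert e2 == pytest.approx(0.3, abs=0.03)


def test_ml_recovery_of_moderate_heritability():
    pt = _paired_trait(0.26, 0.0, 0.74, 2000, 2000, seed=21)
    est = fit_ace(pt)
    assert est.a2 == pytest.approx(0.26, abs=0.05)
    assert est.e2 == pytest.approx(0.74, abs=0.05)
    assert est.converged


def test_e_only_model_matches_independent_normal_likelihood():
    pt = _paired_trait(0.4, 0.1, 0.5, 100, 100, seed=2)
    est = fit_ace(pt, model="E")
    x = pt.pooled() - pt.pooled().mean()
    sigma2 = np.mean(x**2)  # ML variance of iid zero-mean normals
    expected = stats.norm.logpdf(x, scale=np.sqrt(sigma2)).sum()
    assert est.loglik == pytest.approx(expected, abs=1e-5)
    assert est.a2 == 0.0 and est.c2 == 0.0 and est.e2 == 1.0


def test_mz_only_design_is_not_identifiable():
    pt = _paired_trait(0.4, 0.1, 0.5, 50, 50, seed=3)
    mz_only = PairedTrait(pt.mz, np.empty((0, 2)))
    with pytest.raises(ValueError, match="identifiab"):
        fit_ace(mz_only)


def test_nested_model_likelihood_ordering():
    pt = _paired_trait(0.3, 0.2, 0.5, 300, 300, seed=4)
    lls = {m: fit_ace(pt, model=m).loglik for m in ("ACE", "AE", "CE", "E")}
    for sub in ("AE", "CE", "E"):
        assert lls["ACE"] >= lls[sub] - 1e-6


def test_ace_equals_ae_when_c_hits_boundary():
    pt = _paired_trait(0.6, 0.0, 0.4, 1500, 1500, seed=5)
    ace = fit_ace(pt, model="ACE")
    ae = fit_ace(pt, model="AE")
    if ace.c2 < 1e-6:  # boundary solution reached
        assert ace.loglik == pytest.approx(ae.loglik, abs=1e-5)


def test_estimates_invariant_to_twin_order_swap():
    pt = _paired_trait(0.4, 0.1, 0.5, 200, 200, seed=6)
    swapped = PairedTrait(pt.mz[:, ::-1], pt.dz[:, ::-1])
    e1, e2 = fit_ace(pt), fit_ace(swapped)
    assert e1.a2 == pytest.approx(e2.a2, abs=1e-6)
    assert e1.c2 == pytest.approx(e2.c2, abs=1e-6)
    assert e1.loglik == pytest.approx(e2.loglik, abs=1e-6)


def test_degenerate_trait_rejected():
    flat = PairedTrait(np.ones((10, 2)), np.ones((10, 2)))
    with pytest.raises(ValueError, match="zero-variance"):
        fit_ace(flat)


class TestConfint:
    def test_interval_contains_point_estimate(self):
        pt = _paired_trait(0.4, 0.1, 0.5, 300, 300, seed=7)
        est = fit_ace(pt)
        cis = ace_confint(pt, est)
        for comp in ("a2", "c2", "e2"):
            lo, hi = cis[comp]
            assert lo - 1e-6 <= getattr(est, comp) <= hi + 1e-6
            assert 0.0 <= lo <= hi <= 1.0

    def test_component_at_zero_gives_zero_lower_bound(self):
        pt = _paired_trait(0.5, 0.0, 0.5, 800, 800, seed=8)
        est = fit_ace(pt)
        cis = ace_confint(pt, est, components=("c2",))
        assert cis["c2"][0] == 0.0


class TestPanelHeritability:
    def test_pure_e_panel_medians(self):
        truth = SimulationTruth.uniform(
            a2=0.0, c2=0.0, e2=1.0, n_analytes=12,
            n_mz_pairs=300, n_dz_pairs=300, missing_rate=0.0, seed=12,
        )
        roster, prot, _ = simulate_standardized(truth)
        _, summary = panel_heritability(prot, roster)
        assert summary["A"]["median"] == pytest.approx(0.0, abs=0.05)
        assert summary["E"]["median"] == pytest.approx(1.0, abs=0.05)

    def test_summary_invariant_to_analyte_order(self, small_twin_cohort):
        roster, prot, _ = small_twin_cohort
        _, s1 = panel_heritability(prot, roster)
        shuffled = prot.copy()
        shuffled.values = shuffled.values[list(prot.analytes[::-1])]
        _, s2 = panel_heritability(shuffled, roster)
        assert s1["A"]["median"] == pytest.approx(s2["A"]["median"], abs=1e-9)
        assert s1["E"]["iqr"] == pytest.approx(s2["E"]["iqr"], abs=1e-9)

    def test_underpowered_analyte_skipped_not_fatal(self, small_twin_cohort):
        roster, prot, _ = small_twin_cohort
        values = prot.values.copy()
        # knock out analyte A0002 in all but a handful of subjects
        values.loc[values.index[4:], "A0002"] = np.nan
        crippled = type(prot)(values, prot.transform_state)
        per_analyte, summary = panel_heritability(crippled, roster)
        assert summary["n_skipped"] == 1
        assert per_analyte.loc["A0002", "skip_reason"] is not None
        assert summary["n_fitted"] == 2

    def test_vdw_transform_gives_comparable_panel_summary(self, small_twin_cohort):
        roster, prot, _ = small_twin_cohort
        _, plain = panel_heritability(prot, roster)
        _, vdw = panel_heritability(prot, roster, transform="vdw")
        assert vdw["A"]["median"] == pytest.approx(plain["A"]["median"], abs=0.15)


def test_bootstrap_ci_cross_checks_profile_interval():
    from twinprot import ace_bootstrap_ci

    pt = _paired_trait(0.5, 0.1, 0.4, 400, 400, seed=31)
    est = fit_ace(pt)
    profile = ace_confint(pt, est, components=("a2",))["a2"]
    boot = ace_bootstrap_ci(pt, n_boot=120, seed=1)["a2"]
    # two interval constructions should roughly agree away from boundaries
    assert boot[0] == pytest.approx(profile[0], abs=0.08)
    assert boot[1] == pytest.approx(profile[1], abs=0.08)
    assert boot[0] <= est.a2 <= boot[1]
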