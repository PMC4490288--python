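"""Synthetic twin-cohort generator with known ACE ground truth.

Each analyte's latent (log-scale) level is built from three standard-normal
factors — an additive-genetic factor G (shared with correlation 1 within MZ
pairs, 0.5 within DZ pairs), a family-shared factor F, and a subject-specific
factor U — combined as ``a*G + c*F + e*U`` with ``a^2 + c^2 + e^2 = 1`` so the
latent trait has unit variance before covariate effects.  The DZ genetic
correlation of exactly 0.5 is obtained by construction: each DZ twin's G is a
pair-shared component of variance 0.5 plus an independent component of
variance 0.5.

Abundances are emitted on a relative-fluorescence-unit-like scale as
``scale * exp(latent)`` so the preprocessing log transform is exercised
non-trivially.  The cognitive-change outcome is a linear combination of
per-analyte signals plus noise; the ``confounding`` mode of
:class:`~twinprot.datatypes.SimulationTruth` selects whether an analyte's
effect is carried by its full signal, by G only (genetic confounding) or by
F only (shared-environment confounding).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import PHENOTYPE_COLUMNS, ProteinMatrix, SimulationTruth

__all__ = [
    "simulate_twin_cohort",
    "make_paper_fixture",
    "make_anm_fixture",
    "draw_panel_truth",
]

DEFAULT_SEED = 20150616

# latent-scale geometry of the simulated brain regions (log mm^3 means)
_REGION_LOG_MEANS = {
    "lh_volume": np.log(3500.0),
    "rh_volume": np.log(3600.0),
    "le_volume": np.log(1800.0),
    "re_volume": np.log(1850.0),
}
_REGION_LOG_SD = 0.12
_ICV_MEAN = 1.45e6
_ICV_SD = 1.2e5


def _roster_frame(n_mz: int, n_dz: int, n_single: int, rng, centres) -> pd.DataFrame:
    rows = []
    pair_counter = 0
    for zyg, n_pairs in (("MZ", n_mz), ("DZ", n_dz)):
        for _ in range(n_pairs):
            pair_counter += 1
            pid = f"P{pair_counter:04d}"
            for member in (1, 2):
                rows.append((f"{pid}-{member}", pid, zyg))
    for i in range(n_single):
        rows.append((f"I{i + 1:04d}", None, "NA"))
    df = pd.DataFrame(rows, columns=["subject_id", "pair_id", "zygosity"])
    n_sub = len(df)

    pair_ages = rng.normal(65.0, 5.5, size=n_mz + n_dz).clip(50, 85)
    single_ages = rng.normal(67.0, 6.0, size=n_single).clip(50, 88)
    ages = np.concatenate([np.repeat(pair_ages, 2), single_ages])
    df["age"] = np.round(ages, 1)
    df["sex"] = "F"
    centre_names = list(centres)
    df["centre"] = [centre_names[i % len(centre_names)] for i in range(n_sub)]
    df["apoe_e4_count"] = rng.choice([0.0, 1.0], size=n_sub, p=[0.8, 0.2])
    df["haemolysed"] = False
    df["qc_fail"] = False
    df["diagnosis"] = "control"
    return df


def _latent_components(truth: SimulationTruth, roster: pd.DataFrame, rng):
    """Draw the G, F, U factor matrices (subjects x analytes)."""
    k = truth.n_analytes
    n_mz, n_dz, n_s = truth.n_mz_pairs, truth.n_dz_pairs, truth.n_singletons
    n_sub = len(roster)

    g = np.empty((n_sub, k))
    f = np.empty((n_sub, k))
    row = 0
    if n_mz:
        g_mz = rng.standard_normal((n_mz, k))
        g[row : row + 2 * n_mz] = np.repeat(g_mz, 2, axis=0)
        f_mz = rng.standard_normal((n_mz, k))
        f[row : row + 2 * n_mz] = np.repeat(f_mz, 2, axis=0)
        row += 2 * n_mz
    if n_dz:
        g_shared = rng.standard_normal((n_dz, k))
        g_own = rng.standard_normal((2 * n_dz, k))
        g[row : row + 2 * n_dz] = (
            np.sqrt(0.5) * np.repeat(g_shared, 2, axis=0) + np.sqrt(0.5) * g_own
        )
        f_dz = rng.standard_normal((n_dz, k))
        f[row : row + 2 * n_dz] = np.repeat(f_dz, 2, axis=0)
        row += 2 * n_dz
    if n_s:
        g[row:] = rng.standard_normal((n_s, k))
        f[row:] = rng.standard_normal((n_s, k))
    u = rng.standard_normal((n_sub, k))
    return g, f, u


def _pair_shared_noise(truth: SimulationTruth, rng) -> np.ndarray:
    """Unit-variance noise with within-pair correlation phenotype_pair_corr."""
    n_mz, n_dz, n_s = truth.n_mz_pairs, truth.n_dz_pairs, truth.n_singletons
    rho = truth.phenotype_pair_corr
    shared = np.repeat(rng.standard_normal(n_mz + n_dz), 2)
    shared = np.concatenate([shared, rng.standard_normal(n_s)])
    own = rng.standard_normal(2 * (n_mz + n_dz) + n_s)
    return np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * own


def _default_volumes(n_sub: int, rng) -> dict[str, np.ndarray]:
    icv = rng.normal(_ICV_MEAN, _ICV_SD, size=n_sub).clip(1.0e6, 1.9e6)
    cols = {}
    for region, mu in _REGION_LOG_MEANS.items():
        z = rng.standard_normal(n_sub)
        cols[region] = (icv / _ICV_MEAN) * np.exp(mu + _REGION_LOG_SD * z)
    cols["icv"] = icv
    return cols


def simulate_twin_cohort(truth: SimulationTruth):
    """Generate (roster, proteins, phenotypes) from a known ACE truth.

    Returns
    -------
    roster : pandas.DataFrame
        One row per subject with pair membership, zygosity and covariates.
    proteins : ProteinMatrix
        Raw RFU-like abundances (``rfu_scale * exp(latent)``) with MCAR
        missingness at ``truth.missing_rate``.
    phenotypes : pandas.DataFrame
        Indexed by subject_id: ``delta_pal`` (10-year cognitive change built
        from the analyte effects), MMSE, four regional volumes and ICV.
    """
    rng = np.random.default_rng(truth.seed)
    roster = _roster_frame(
        truth.n_mz_pairs,
        truth.n_dz_pairs,
        truth.n_singletons,
        rng,
        truth.centre_offsets.keys(),
    )
    n_sub = len(roster)
    if n_sub == 0:
        raise ValueError("cohort is empty: all counts are zero")

    g, f, u = _latent_components(truth, roster, rng)
    signal = truth.a2**0.5 * g + truth.c2**0.5 * f + truth.e2**0.5 * u

    # outcome before covariates: which component carries the analyte effects
    driver = {"none": signal, "genetic": g, "shared-env": f}[truth.confounding]
    beta = truth.beta
    noise_var = max(1.0 - float(beta @ beta), 0.05)
    noise = np.sqrt(noise_var) * _pair_shared_noise(truth, rng)
    delta_pal = driver @ beta + noise

    # covariate effects enter the measured (log-scale) abundances
    z_age = (roster["age"].to_numpy() - roster["age"].mean()) / max(
        roster["age"].std(ddof=1), 1e-12
    )
    centre_shift = roster["centre"].map(truth.centre_offsets).to_numpy(dtype=float)
    latent = signal + (truth.age_slope * z_age + centre_shift)[:, None]

    raw = truth.rfu_scale * np.exp(latent)
    if truth.missing_rate > 0:
        raw[rng.random(raw.shape) < truth.missing_rate] = np.nan

    analyte_ids = [f"A{i + 1:04d}" for i in range(truth.n_analytes)]
    proteins = ProteinMatrix(
        pd.DataFrame(raw, index=pd.Index(roster["subject_id"], name="subject_id"),
                     columns=analyte_ids),
        transform_state="raw",
    )

    mmse = np.round(29.2 - np.abs(rng.standard_normal(n_sub)) * 1.3).clip(23, 30)
    phen = {"delta_pal": delta_pal, "mmse": mmse}
    phen.update(_default_volumes(n_sub, rng))
    phenotypes = pd.DataFrame(
        phen, index=pd.Index(roster["subject_id"], name="subject_id")
    )[PHENOTYPE_COLUMNS]
    return roster, proteins, phenotypes


# ---------------------------------------------------------------------------
# Worked-example fixtures mirroring the two published cohorts
# ---------------------------------------------------------------------------

def draw_panel_truth(n_analytes: int, rng):
    """Heritability fractions for a realistic plasma-protein panel.

    a2 ~ Beta(1.1, 2.579), whose median is 0.26, with a wide spread; the
    shared-environment share of the remainder is small on average.  Draws are
    stratified (inverse-CDF over a jittered, shuffled grid) so the panel's
    *realized* median heritability sits at the distribution median for any
    seed, not just in expectation.
    """
    u = (np.arange(n_analytes) + rng.random(n_analytes)) / n_analytes
    a2 = stats.beta.ppf(u, 1.1, 2.579)
    rng.shuffle(a2)
    c2 = (1.0 - a2) * rng.beta(0.5, 2.5, size=n_analytes)
    e2 = 1.0 - a2 - c2
    return a2, c2, e2


def make_paper_fixture(seed: int = DEFAULT_SEED, n_analytes: int = 1129):
    """Discovery-style twin cohort: 212 subjects in 106 pairs.

    Exclusion flags are placed so that the standard subject filter removes
    17 subjects (10 double-APOE-E4 carriers, 6 haemolysed samples, 1 assay QC
    failure; flags non-overlapping) and leaves 195 subjects: 93 intact pairs
    (55 MZ + 38 DZ) plus 9 newly single co-twins.  Four pairs lose both
    members and nine pairs lose one.  MRI volumes are populated for 34 MZ
    subjects and 2 of the surviving singles; elsewhere they are missing.
    """
    rng = np.random.default_rng(seed)
    a2, c2, e2 = draw_panel_truth(n_analytes, rng)
    truth = SimulationTruth(
        a2=a2,
        c2=c2,
        e2=e2,
        beta=np.zeros(n_analytes),
        n_mz_pairs=62,
        n_dz_pairs=44,
        n_singletons=0,
        seed=int(rng.integers(2**31 - 1)),
    )
    roster, proteins, phenotypes = simulate_twin_cohort(truth)

    # pair layout: MZ pairs are P0001..P0062, DZ pairs P0063..P0106
    mz_pairs = [f"P{i:04d}" for i in range(1, 63)]
    dz_pairs = [f"P{i:04d}" for i in range(63, 107)]
    # fully excluded: last 2 MZ + last 2 DZ pairs; half excluded: 5 MZ + 4 DZ
    both_excluded = mz_pairs[60:62] + dz_pairs[42:44]
    one_excluded = mz_pairs[55:60] + dz_pairs[38:42]
    flagged = [f"{p}-{m}" for p in both_excluded for m in (1, 2)]
    flagged += [f"{p}-2" for p in one_excluded]
    assert len(flagged) == 17

    roster = roster.set_index("subject_id", drop=False)
    roster["apoe_e4_count"] = roster["apoe_e4_count"].clip(upper=1.0)
    roster.loc[flagged[:10], "apoe_e4_count"] = 2.0
    roster.loc[flagged[10:16], "haemolysed"] = True
    roster.loc[flagged[16:], "qc_fail"] = True

    # age marginals by zygosity (MZ median ~65, DZ ~63)
    mz_rows = roster["pair_id"].isin(mz_pairs)
    dz_rows = roster["pair_id"].isin(dz_pairs)
    mz_age = np.repeat(rng.normal(66.0, 6.0, size=62).clip(52, 84), 2)
    dz_age = np.repeat(rng.normal(63.5, 5.5, size=44).clip(52, 84), 2)
    roster.loc[mz_rows, "age"] = np.round(mz_age, 1)
    roster.loc[dz_rows, "age"] = np.round(dz_age, 1)

    # MRI subset: 17 intact MZ pairs + 2 surviving MZ co-twins
    mri_subjects = [f"{p}-{m}" for p in mz_pairs[:17] for m in (1, 2)]
    mri_subjects += [f"{p}-1" for p in mz_pairs[55:57]]
    vol_cols = ["lh_volume", "rh_volume", "le_volume", "re_volume", "icv"]
    masked = ~phenotypes.index.isin(mri_subjects)
    phenotypes.loc[masked, vol_cols] = np.nan

    return roster.reset_index(drop=True), proteins, phenotypes


def make_anm_fixture(
    seed: int = DEFAULT_SEED,
    n_analytes: int = 1129,
    planted: dict | None = None,
):
    """Replication-style singleton cohort of 254 subjects.

    Diagnosis counts are 91 controls / 81 MCI / 82 AD with 51 female
    controls; ages and MMSE follow the replication cohort's marginals and
    regional volumes plus intracranial volume are populated for everyone.

    Parameters
    ----------
    planted : dict, optional
        ``{"analyte": id, "region": volume column, "beta": slope,
        "stratum": "all" | "controls" | "female-controls"}`` plants a linear
        protein -> volume effect (on the log/latent scale) restricted to the
        given stratum, for power and replication experiments.
    """
    rng = np.random.default_rng(seed)
    n = 254
    diagnosis = np.array(["control"] * 91 + ["MCI"] * 81 + ["AD"] * 82)
    sex = np.array(
        ["F"] * 51 + ["M"] * 40  # controls
        + ["F"] * 41 + ["M"] * 40  # MCI
        + ["F"] * 42 + ["M"] * 40  # AD
    )
    age = np.concatenate(
        [
            rng.normal(72.0, 5.5, size=91),
            rng.normal(75.5, 5.5, size=81),
            rng.normal(76.5, 6.0, size=82),
        ]
    ).clip(55, 92)
    centres = ["London", "Kuopio", "Lodz", "Perugia", "Thessaloniki", "Toulouse"]
    roster = pd.DataFrame(
        {
            "subject_id": [f"R{i + 1:04d}" for i in range(n)],
            "pair_id": None,
            "zygosity": "NA",
            "age": np.round(age, 1),
            "sex": sex,
            "centre": rng.choice(centres, size=n),
            "apoe_e4_count": rng.choice([0.0, 1.0, np.nan], size=n, p=[0.62, 0.36, 0.02]),
            "haemolysed": False,
            "qc_fail": False,
            "diagnosis": diagnosis,
        }
    )

    latent = rng.standard_normal((n, n_analytes))
    raw = 1000.0 * np.exp(latent)
    raw[rng.random(raw.shape) < 0.02] = np.nan
    analyte_ids = [f"A{i + 1:04d}" for i in range(n_analytes)]
    idx = pd.Index(roster["subject_id"], name="subject_id")
    proteins = ProteinMatrix(
        pd.DataFrame(raw, index=idx, columns=analyte_ids), transform_state="raw"
    )

    icv = rng.normal(_ICV_MEAN, _ICV_SD, size=n).clip(1.0e6, 1.9e6)
    vol_z = {r: rng.standard_normal(n) for r in _REGION_LOG_MEANS}
    if planted is not None:
        k = analyte_ids.index(planted["analyte"])
        b = float(planted["beta"])
        in_stratum = _stratum_mask(roster, planted.get("stratum", "all"))
        z = vol_z[planted["region"]]
        z[in_stratum] = np.sqrt(max(1.0 - b * b, 0.0)) * z[in_stratum] + b * latent[
            in_stratum, k
        ]
    phen = {
        "delta_pal": np.full(n, np.nan),
        "mmse": _anm_mmse(diagnosis, rng),
        "icv": icv,
    }
    for region, mu in _REGION_LOG_MEANS.items():
        phen[region] = (icv / _ICV_MEAN) * np.exp(mu + _REGION_LOG_SD * vol_z[region])
    phenotypes = pd.DataFrame(phen, index=idx)[PHENOTYPE_COLUMNS]
    return roster, proteins, phenotypes


def _anm_mmse(diagnosis: np.ndarray, rng) -> np.ndarray:
    out = np.empty(len(diagnosis))
    spec = {"control": (29.3, 0.9), "MCI": (27.6, 1.8), "AD": (21.5, 3.2)}
    for dx, (mu, sd) in spec.items():
        m = diagnosis == dx
        out[m] = np.round(rng.normal(mu, sd, size=m.sum())).clip(10, 30)
    return out


def _stratum_mask(roster: pd.DataFrame, stratum: str) -> np.ndarray:
    if stratum == "all":
        return np.ones(len(roster), dtype=bool)
    if stratum == "controls":
        return (roster["diagnosis"] == "control").to_numpy()
    if stratum == "female-controls":
        return ((roster["diagnosis"] == "control") & (roster["sex"] == "F")).to_numpy()
    raise ValueError(f"unknown stratum {stratum!r}")
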