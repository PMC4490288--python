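"""Subject exclusion filters and analyte-level transformations.

The canonical order, mirrored by the discovery pipeline, is:

1. :func:`filter_subjects` — drop double-APOE-E4 carriers, haemolysed
   samples and assay QC failures; co-twins of excluded subjects become
   singletons.
2. :func:`log_standardize` — natural log, then per-analyte z-score
   (sample s.d., n-1 denominator) over the observed entries.
3. :func:`mask_outliers` — entries more than 2.5 s.d. from the mean set to
   missing, in a single pass (z-scores are not recomputed afterwards).

:func:`van_der_waerden` provides the rank-based inverse-normal transform used
as a sensitivity analysis in the heritability stage, and
:func:`normalize_volumes` prepares regional brain volumes (optional ICV
division, then log + z-score).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import VOLUME_REGIONS, ProteinMatrix

__all__ = [
    "filter_subjects",
    "log_standardize",
    "mask_outliers",
    "van_der_waerden",
    "normalize_volumes",
]

# exclusion reasons in the order they are reported
EXCLUSION_RULES = (
    ("double_apoe_e4", lambda df: df["apoe_e4_count"] == 2),
    ("haemolysed", lambda df: df["haemolysed"].astype(bool)),
    ("qc_fail", lambda df: df["qc_fail"].astype(bool)),
)


def filter_subjects(roster: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the cohort exclusion flags and restore pair integrity.

    Removes subjects homozygous for APOE E4, with haemolysed plasma, or
    failing assay QC.  A subject whose co-twin is excluded keeps their row
    but loses their ``pair_id`` (they are analysed as a singleton from then
    on).  Returns the kept roster and an audit table with one row per
    excluded subject and the first matching reason.
    """
    if len(roster) == 0:
        raise ValueError("roster is empty")
    reason = pd.Series(pd.NA, index=roster.index, dtype="object")
    for name, rule in EXCLUSION_RULES:
        hit = rule(roster).fillna(False) & reason.isna()
        reason[hit] = name
    excluded = roster.loc[reason.notna(), ["subject_id"]].copy()
    excluded["reason"] = reason[reason.notna()].to_numpy()

    kept = roster.loc[reason.isna()].copy()
    kept["zygosity"] = kept["zygosity"].astype(object)
    # a pair with only one surviving member becomes a singleton
    counts = kept["pair_id"].value_counts()
    widowed = kept["pair_id"].map(counts).eq(1) & kept["pair_id"].notna()
    kept.loc[widowed, "pair_id"] = None
    kept.loc[widowed, "zygosity"] = "NA"
    return kept.reset_index(drop=True), excluded.reset_index(drop=True)


def pair_summary(roster: pd.DataFrame) -> dict:
    """Counts of intact pairs (by zygosity) and singletons in a roster."""
    counts = roster["pair_id"].value_counts()
    intact = counts[counts == 2].index
    by_zyg = (
        roster[roster["pair_id"].isin(intact)]
        .drop_duplicates("pair_id")["zygosity"]
        .value_counts()
        .to_dict()
    )
    return {
        "n_subjects": int(len(roster)),
        "n_intact_pairs": int(len(intact)),
        "n_singletons": int(roster["pair_id"].isna().sum()),
        "n_mz_pairs": int(by_zyg.get("MZ", 0)),
        "n_dz_pairs": int(by_zyg.get("DZ", 0)),
    }


def _zscore_columns(values: pd.DataFrame, what: str) -> pd.DataFrame:
    """Per-column z-score over observed entries; errors on zero variance."""
    mean = values.mean(axis=0, skipna=True)
    sd = values.std(axis=0, ddof=1, skipna=True)
    degenerate = sd.le(0) | sd.isna()
    if degenerate.any():
        bad = list(values.columns[degenerate])
        raise ValueError(f"zero-variance {what}: {bad[:5]}")
    return (values - mean) / sd


def log_standardize(m: ProteinMatrix) -> ProteinMatrix:
    """Natural log then per-analyte z-score (observed entries only)."""
    if m.transform_state != "raw":
        raise ValueError(f"expected a raw matrix, got {m.transform_state!r}")
    bad = m.values.le(0)
    if bad.any().any():
        col = m.values.columns[bad.any(axis=0)][0]
        subj = m.values.index[bad[col].fillna(False)][0]
        raise ValueError(
            f"non-positive abundance for subject {subj!r}, analyte {col!r}: "
            "log transform undefined"
        )
    logged = np.log(m.values)
    return ProteinMatrix(_zscore_columns(logged, "analyte"), "standardized")


def mask_outliers(
    m: ProteinMatrix, k: float = 2.5
) -> tuple[ProteinMatrix, pd.Series]:
    """Set standardized entries with ``|z| > k`` to missing (single pass).

    The threshold is strict (a value exactly at ``k`` s.d. is kept) and
    two-sided.  Returns the masked matrix and the per-analyte count of
    newly missing entries.  Z-scores are intentionally not recomputed after
    masking.
    """
    if k <= 0:
        raise ValueError("outlier threshold must be positive")
    if m.transform_state != "standardized":
        raise ValueError("mask_outliers requires a standardized matrix")
    exceed = m.values.abs().gt(k)
    masked = m.values.mask(exceed)
    return ProteinMatrix(masked, "standardized"), exceed.sum(axis=0)


def van_der_waerden(values) -> pd.Series:
    """Rank-based inverse-normal transform, Phi^-1(r / (n + 1)).

    Ties get average ranks; missing entries stay missing.  Requires at least
    three observed values.
    """
    s = pd.Series(np.asarray(values, dtype=float)) if not isinstance(values, pd.Series) else values.astype(float)
    observed = s.notna()
    n = int(observed.sum())
    if n < 3:
        raise ValueError(f"van der Waerden transform needs >= 3 observed values, got {n}")
    ranks = stats.rankdata(s[observed], method="average")
    out = s.copy()
    out[observed] = stats.norm.ppf(ranks / (n + 1))
    return out


def normalize_volumes(
    phenotypes: pd.DataFrame, use_icv: bool, regions=VOLUME_REGIONS
) -> pd.DataFrame:
    """Prepare regional brain volumes for regression.

    Optionally divides each region by intracranial volume, then applies a
    natural log and per-region z-score (observed entries, n-1 denominator).
    """
    out = phenotypes.copy()
    vols = out[list(regions)].astype(float)
    if use_icv:
        icv = out["icv"]
        needs_icv = vols.notna().any(axis=1) & icv.isna()
        if needs_icv.any():
            raise ValueError(
                f"missing ICV for subjects with volume data: {list(out.index[needs_icv])[:5]}"
            )
        vols = vols.div(icv, axis=0)
    if vols.le(0).any().any():
        raise ValueError("volumes must be positive for the log transform")
    out[list(regions)] = _zscore_columns(np.log(vols), "region")
    return out
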