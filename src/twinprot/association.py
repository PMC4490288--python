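"""Endophenotype association scans with twin-aware inference.

Twin cohorts are analysed with generalized estimating equations (GEE,
exchangeable working correlation, robust sandwich standard errors) so that
the two members of a pair form one cluster; singletons are clusters of size
one.  Non-twin cohorts fall back to ordinary least squares.  Each scan tests
every analyte against one outcome (protein level as predictor, endophenotype
as outcome) with age, sex and centre covariates, then applies the
Benjamini-Hochberg step-up correction across the analytes of that scan.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.genmod.cov_struct import Exchangeable, Independence
from statsmodels.genmod.families import Binomial, Gaussian

from .datatypes import VOLUME_REGIONS, GEEFit, ProteinMatrix

__all__ = ["gee_fit", "scan", "bh_adjust", "subgroup_replication", "stratum_mask"]

logger = logging.getLogger(__name__)

_FAMILIES = {"gaussian": Gaussian, "binomial": Binomial}


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (Q-values).

    With p-values sorted ascending, q(i) = min_{j >= i} m * p(j) / j, clipped
    to 1 and mapped back to the input order.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise ValueError("p must be a non-empty 1-d vector")
    if np.any(np.isnan(p)) or np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    q = np.empty(m, dtype=float)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def gee_fit(
    y,
    X: pd.DataFrame,
    clusters,
    family: str = "gaussian",
    independence: bool = False,
    maxiter: int = 50,
    tol: float = 1e-8,
) -> GEEFit:
    """GEE with exchangeable working correlation and sandwich covariance.

    Clusters must have size 1 or 2 (twin pairs and singletons).  When every
    cluster is a singleton the exchangeable correlation is undefined; the fit
    degrades to an independence working model with alpha reported as 0, which
    for the gaussian family reproduces OLS coefficients exactly.  Setting
    ``independence=True`` forces that working model (alpha fixed at 0).
    """
    X = pd.DataFrame(X).astype(float)
    y = np.asarray(y, dtype=float)
    clusters = pd.Series(clusters).astype(str).to_numpy()
    if len(y) != len(X) or len(y) != len(clusters):
        raise ValueError("y, X and clusters must have equal length")
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    sizes = pd.Series(clusters).value_counts()
    if sizes.max() > 2:
        raise ValueError("clusters must have size 1 or 2 (twin pairs/singletons)")
    if family not in _FAMILIES:
        raise ValueError(f"unknown family {family!r}")
    if family == "binomial" and not np.isin(y[~np.isnan(y)], [0.0, 1.0]).all():
        raise ValueError("binomial outcome must be coded in {0, 1}")

    flags: list[str] = []
    all_singleton = bool(sizes.max() == 1)
    if all_singleton and not independence:
        flags.append("all_singleton_alpha_zero")
    use_independence = independence or all_singleton
    cov_struct = Independence() if use_independence else Exchangeable()

    model = sm.GEE(
        y, X, groups=clusters, family=_FAMILIES[family](), cov_struct=cov_struct
    )
    converged = True
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        res = model.fit(maxiter=maxiter, ctol=tol)
        for w in caught:
            if "not converge" in str(w.message).lower():
                converged = False
                flags.append("non_convergence")
    alpha = 0.0 if use_independence else float(np.atleast_1d(cov_struct.dep_params)[0])
    if not use_independence and alpha > 0.95:
        flags.append("alpha_boundary")
    params = pd.Series(np.asarray(res.params), index=X.columns)
    cov = pd.DataFrame(
        np.asarray(res.cov_params()), index=X.columns, columns=X.columns
    )
    return GEEFit(
        params=params,
        cov_robust=cov,
        alpha=alpha,
        n_obs=len(y),
        n_clusters=int(len(sizes)),
        converged=converged,
        flags=tuple(flags),
    )


def _build_design(df: pd.DataFrame, covariates) -> tuple[pd.DataFrame, list[str]]:
    """Intercept + protein + covariates; constant covariates are dropped."""
    X = pd.DataFrame({"const": 1.0, "protein": df["protein"]}, index=df.index)
    dropped = []
    for cov in covariates:
        col = df[cov]
        if col.nunique(dropna=True) <= 1:
            dropped.append(cov)
            continue
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(col, prefix=cov, drop_first=True).astype(float)
            X = pd.concat([X, dummies], axis=1)
        else:
            X[cov] = col.astype(float)
    return X, dropped


def _single_fit(df, covariates, clusters, family, engine):
    """One analyte's regression; returns (beta, se, p, n, r2)."""
    X, dropped = _build_design(df, covariates)
    if dropped:
        logger.info("dropped constant covariates: %s", dropped)
    y = df["outcome"].to_numpy(dtype=float)
    if engine == "gee":
        fit = gee_fit(y, X, clusters, family=family)
        beta = float(fit.params["protein"])
        se = float(fit.bse["protein"])
        p = 2.0 * stats.norm.sf(abs(beta / se)) if se > 0 else np.nan
        return beta, se, float(p), len(df), None
    if family == "binomial":
        res = sm.Logit(y, X).fit(disp=0)
        return (
            float(res.params["protein"]),
            float(res.bse["protein"]),
            float(res.pvalues["protein"]),
            len(df),
            None,
        )
    res = sm.OLS(y, X).fit()
    return (
        float(res.params["protein"]),
        float(res.bse["protein"]),
        float(res.pvalues["protein"]),
        len(df),
        float(res.rsquared),
    )


def scan(
    proteins: ProteinMatrix,
    outcome: pd.Series,
    roster: pd.DataFrame,
    covariates=("age", "sex", "centre"),
    family: str = "gaussian",
    stratum: str = "all",
    engine: str = "auto",
) -> pd.DataFrame:
    """Regress one endophenotype on every analyte; BH across the scan.

    Each analyte is fit on its own complete cases.  With any twin pairs in
    the roster a GEE with pair clusters is used (``engine="auto"``);
    all-singleton cohorts use an ordinary linear (or logistic) model.
    Analytes whose fit fails are excluded from the BH family; the count is
    stored in ``result.attrs["n_failed"]``.
    """
    if proteins.transform_state == "raw":
        raise ValueError("scan requires a preprocessed (log-standardized) matrix")
    ros = roster.set_index("subject_id")
    subjects = proteins.subjects
    y = outcome.reindex(subjects)
    if y.nunique(dropna=True) <= 1:
        raise ValueError("outcome is constant or empty")

    pair_ids = ros["pair_id"].reindex(subjects)
    if engine == "auto":
        engine = "gee" if pair_ids.notna().any() else "ols"
    clusters_all = pair_ids.fillna(pd.Series(subjects, index=subjects)).astype(str)

    base = pd.DataFrame({"outcome": y}, index=subjects)
    for cov in covariates:
        base[cov] = ros[cov].reindex(subjects)

    rows, failures = [], []
    for analyte in proteins.analytes:
        df = base.copy()
        df["protein"] = proteins.values[analyte]
        df = df.dropna()
        try:
            if len(df) < len(covariates) + 3:
                raise ValueError("too few complete cases")
            beta, se, p, n, r2 = _single_fit(
                df, covariates, clusters_all.loc[df.index], family, engine
            )
            if not np.isfinite(p):
                raise ValueError("non-finite p-value")
        except (ValueError, np.linalg.LinAlgError) as exc:
            failures.append((analyte, str(exc)))
            continue
        rows.append(
            {
                "analyte": analyte,
                "beta": beta,
                "se": se,
                "p": p,
                "n": n,
                "r_squared": r2,
                "covariates": "+".join(covariates),
                "stratum": stratum,
            }
        )
    if not rows:
        raise ValueError("no analyte could be tested in this scan")
    result = pd.DataFrame(rows)
    result["q"] = bh_adjust(result["p"].to_numpy())
    result = result[
        ["analyte", "beta", "se", "p", "q", "n", "r_squared", "covariates", "stratum"]
    ]
    result.attrs["n_failed"] = len(failures)
    result.attrs["engine"] = engine
    if failures:
        logger.info("scan: %d analytes failed and were excluded from BH", len(failures))
    return result


def stratum_mask(roster: pd.DataFrame, stratum: str) -> pd.Series:
    """Boolean subject mask for the replication strata."""
    if stratum == "all":
        return pd.Series(True, index=roster.index)
    if stratum == "controls":
        return roster["diagnosis"] == "control"
    if stratum == "female-controls":
        return (roster["diagnosis"] == "control") & (roster["sex"] == "F")
    raise ValueError(f"unknown stratum {stratum!r}")


def subgroup_replication(
    proteins: ProteinMatrix,
    phenotypes: pd.DataFrame,
    roster: pd.DataFrame,
    shortlist,
    regions=VOLUME_REGIONS,
    strata=("all", "controls", "female-controls"),
    covariates=("age", "centre"),
    outlier_sd: float = 2.5,
) -> dict[str, pd.DataFrame]:
    """Replication of a protein shortlist against regional volumes by stratum.

    For each stratum an ordinary linear model (volume ~ protein + covariates)
    is fit per analyte x region; BH is applied within the stratum over the
    full shortlist-by-region family.  A sensitivity refit excludes points
    more than ``outlier_sd`` s.d. from the stratum mean on either variable.
    Empty strata are skipped with a log notice.
    """
    shortlist = list(shortlist)
    if not shortlist:
        raise ValueError("replication shortlist is empty")
    missing = [a for a in shortlist if a not in proteins.analytes]
    if missing:
        raise ValueError(f"shortlist analytes not in the panel: {missing}")
    ros = roster.set_index("subject_id")

    out: dict[str, pd.DataFrame] = {}
    for stratum in strata:
        keep = stratum_mask(roster, stratum)
        ids = roster.loc[keep, "subject_id"]
        ids = ids[ids.isin(proteins.subjects)]
        if len(ids) == 0:
            logger.info("stratum %r is empty; skipped", stratum)
            continue
        sub_prot = proteins.subset_subjects(ids)
        rows = []
        for analyte in shortlist:
            for region in regions:
                df = pd.DataFrame(
                    {
                        "protein": sub_prot.values[analyte],
                        "outcome": phenotypes[region].reindex(ids),
                    },
                    index=pd.Index(ids, name="subject_id"),
                )
                for cov in covariates:
                    df[cov] = ros[cov].reindex(ids)
                df = df.dropna()
                row = {"analyte": analyte, "region": region, "stratum": stratum}
                try:
                    if len(df) < len(covariates) + 3:
                        raise ValueError("too few complete cases")
                    beta, se, p, n, r2 = _single_fit(
                        df, covariates, None, "gaussian", "ols"
                    )
                except (ValueError, np.linalg.LinAlgError) as exc:
                    row.update(skip_reason=str(exc))
                    rows.append(row)
                    continue
                row.update(beta=beta, se=se, p=p, n=n, r_squared=r2, skip_reason=None)
                # outlier-sensitivity refit (|z| > outlier_sd on x or y)
                zx = (df["protein"] - df["protein"].mean()) / df["protein"].std(ddof=1)
                zy = (df["outcome"] - df["outcome"].mean()) / df["outcome"].std(ddof=1)
                inlier = (zx.abs() <= outlier_sd) & (zy.abs() <= outlier_sd)
                if inlier.sum() >= len(covariates) + 3 and inlier.sum() < len(df):
                    b2, _, p2, n2, _ = _single_fit(
                        df[inlier], covariates, None, "gaussian", "ols"
                    )
                    row.update(beta_sens=b2, p_sens=p2, n_sens=n2)
                else:
                    row.update(beta_sens=beta, p_sens=p, n_sens=len(df))
                rows.append(row)
        res = pd.DataFrame(rows)
        tested = res["skip_reason"].isna()
        q = np.full(len(res), np.nan)
        if tested.any():
            q[tested.to_numpy()] = bh_adjust(res.loc[tested, "p"].to_numpy())
        res["q"] = q
        out[stratum] = res
    return out
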