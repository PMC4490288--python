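"""ACE twin-model variance decomposition by maximum likelihood.

The classical twin design contrasts monozygotic (MZ) and dizygotic (DZ) pair
covariances to split a trait's variance into additive genetics (A), shared
environment (C) and non-shared environment (E).  Each complete pair is
modelled as a zero-mean (after centering) bivariate normal with

    Var(y)        = a^2 + c^2 + e^2
    Cov(MZ pair)  = a^2 + c^2
    Cov(DZ pair)  = 0.5 a^2 + c^2

where a, c, e are path coefficients; squaring keeps the variance components
non-negative, so boundary solutions (a = 0 or c = 0) are ordinary points of
the parameter space.  The joint MZ+DZ log-likelihood depends on the data only
through per-zygosity sufficient statistics (pair count, sum of squares, sum
of cross-products), which makes panel-wide fitting cheap.

Fits are initialized at the Falconer closed-form solution
(a2 = 2(rMZ - rDZ), c2 = 2 rDZ - rMZ, e2 = 1 - rMZ, clipped and
renormalized) and refined by Nelder-Mead with deterministic jittered
restarts.  Confidence intervals are profile-likelihood intervals on the
standardized proportions, truncated to [0, 1].
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .datatypes import ACEEstimate, ProteinMatrix

__all__ = [
    "PairedTrait",
    "intraclass_corr",
    "falconer",
    "falconer_from_correlations",
    "fit_ace",
    "ace_confint",
    "ace_bootstrap_ci",
    "panel_heritability",
]

MODELS = {"ACE": ("a", "c", "e"), "AE": ("a", "e"), "CE": ("c", "e"), "E": ("e",)}
_LOG2PI = math.log(2.0 * math.pi)
_CHI2_HALF = {0.95: stats.chi2.ppf(0.95, 1) / 2.0}  # 1.9207...


@dataclass(frozen=True)
class PairedTrait:
    """Complete MZ and DZ pair values for one trait."""

    mz: np.ndarray  # (n_mz, 2)
    dz: np.ndarray  # (n_dz, 2)
    label: str = ""

    def __post_init__(self):
        for name in ("mz", "dz"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.size == 0:
                arr = arr.reshape(0, 2)
            if arr.ndim != 2 or arr.shape[1] != 2 or np.isnan(arr).any():
                raise ValueError(f"{name} pairs must be a complete (n, 2) array")
            object.__setattr__(self, name, arr)

    @property
    def n_mz(self) -> int:
        return self.mz.shape[0]

    @property
    def n_dz(self) -> int:
        return self.dz.shape[0]

    def pooled(self) -> np.ndarray:
        return np.concatenate([self.mz.ravel(), self.dz.ravel()])


def intraclass_corr(pairs: np.ndarray) -> float:
    """ANOVA (one-way random effects) intraclass correlation for pairs."""
    pairs = np.asarray(pairs, dtype=float)
    n = pairs.shape[0]
    if n < 2:
        raise ValueError("need at least 2 pairs for an intraclass correlation")
    pair_means = pairs.mean(axis=1)
    grand = pairs.mean()
    msb = 2.0 * np.sum((pair_means - grand) ** 2) / (n - 1)
    msw = np.sum((pairs[:, 0] - pairs[:, 1]) ** 2) / (2.0 * n)
    denom = msb + msw
    if denom <= 0:
        raise ValueError("degenerate (zero-variance) trait")
    return float((msb - msw) / denom)


def falconer_from_correlations(r_mz: float, r_dz: float) -> tuple[float, float, float]:
    """Closed-form ACE fractions from twin correlations, clipped to the simplex.

    Raw values a2 = 2(rMZ - rDZ), c2 = 2 rDZ - rMZ, e2 = 1 - rMZ are each
    clipped to [0, 1] and renormalized to sum to one.
    """
    raw = np.array([2.0 * (r_mz - r_dz), 2.0 * r_dz - r_mz, 1.0 - r_mz])
    clipped = np.clip(raw, 0.0, 1.0)
    s = clipped.sum()
    if s <= 0:
        return (0.0, 0.0, 1.0)
    a2, c2, e2 = clipped / s
    return (float(a2), float(c2), float(e2))


def falconer(pt: PairedTrait) -> tuple[float, float, float]:
    """Falconer initializer from the observed intraclass correlations."""
    if pt.n_mz < 2 or pt.n_dz < 2:
        raise ValueError("falconer needs >= 2 pairs per zygosity")
    return falconer_from_correlations(intraclass_corr(pt.mz), intraclass_corr(pt.dz))


# ---------------------------------------------------------------------------
# likelihood on sufficient statistics
# ---------------------------------------------------------------------------

def _suffstats(pairs: np.ndarray) -> tuple[int, float, float]:
    return (
        pairs.shape[0],
        float(np.sum(pairs**2)),
        float(np.sum(pairs[:, 0] * pairs[:, 1])),
    )


def _group_ll(n: int, ss: float, sp: float, v: float, w: float) -> float:
    """Log-likelihood of n centered pairs under Var v, within-pair Cov w."""
    if n == 0:
        return 0.0
    det = v * v - w * w
    if det <= 0.0 or v <= 0.0:
        return -np.inf
    return -n * _LOG2PI - 0.5 * n * math.log(det) - (v * ss - 2.0 * w * sp) / (2.0 * det)


def _ll_from_components(stats_mz, stats_dz, a2: float, c2: float, e2: float) -> float:
    v = a2 + c2 + e2
    return _group_ll(*stats_mz, v, a2 + c2) + _group_ll(*stats_dz, v, 0.5 * a2 + c2)


def _center(pt: PairedTrait, center: bool) -> tuple[PairedTrait, float]:
    mu = float(pt.pooled().mean()) if center else 0.0
    return PairedTrait(pt.mz - mu, pt.dz - mu, pt.label), mu


def fit_ace(
    pt: PairedTrait,
    model: str = "ACE",
    center: bool = True,
    compute_ci: bool = False,
    ci_level: float = 0.95,
) -> ACEEstimate:
    """Maximum-likelihood ACE (or nested AE/CE/E) fit for one trait.

    The trait is centered at its pooled mean; free path coefficients are
    optimized by Nelder-Mead from the Falconer start plus two deterministic
    jittered restarts.  Boundary solutions (a = 0, c = 0) are valid results.
    Raises on degenerate traits and on designs lacking both zygosities
    (with MZ pairs only, A and C are not separately identifiable).
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}; choose from {sorted(MODELS)}")
    free = MODELS[model]
    if model == "ACE" and (pt.n_mz < 3 or pt.n_dz < 3):
        raise ValueError(
            "ACE is not identifiable here: need >= 3 complete pairs of each "
            f"zygosity (got {pt.n_mz} MZ, {pt.n_dz} DZ); with one zygosity "
            "absent, A and C cannot be separated"
        )
    centered, _ = _center(pt, center)
    pooled = centered.pooled()
    total_var = float(np.var(pooled, ddof=1)) if pooled.size > 1 else 0.0
    if total_var <= 0:
        raise ValueError(f"degenerate (zero-variance) trait {pt.label!r}")
    stats_mz = _suffstats(centered.mz)
    stats_dz = _suffstats(centered.dz)

    if pt.n_mz >= 2 and pt.n_dz >= 2:
        f_a2, f_c2, f_e2 = falconer(centered)
    else:  # AE/CE/E fits may run with a single zygosity
        f_a2, f_c2, f_e2 = (0.3, 0.2, 0.5)
    start_props = {"a": max(f_a2, 0.02), "c": max(f_c2, 0.02), "e": max(f_e2, 0.05)}

    def components(theta: np.ndarray) -> dict[str, float]:
        comp = dict.fromkeys(("a", "c", "e"), 0.0)
        for name, t in zip(free, theta):
            comp[name] = t * t
        return comp

    def nll(theta: np.ndarray) -> float:
        comp = components(theta)
        ll = _ll_from_components(stats_mz, stats_dz, comp["a"], comp["c"], comp["e"])
        return -ll if np.isfinite(ll) else 1e300

    base = np.array([math.sqrt(start_props[name] * total_var) for name in free])
    starts = [base, base * 0.6 + 1e-3, base * 1.5 + 1e-3]
    best = None
    for x0 in starts:
        res = optimize.minimize(
            nll,
            x0,
            method="Nelder-Mead",
            options={"fatol": 1e-10, "xatol": 1e-9, "maxiter": 4000},
        )
        if best is None or res.fun < best.fun:
            best = res

    comp = components(best.x)
    total = comp["a"] + comp["c"] + comp["e"]
    est = ACEEstimate(
        trait=pt.label,
        model=model,
        a2=comp["a"] / total,
        c2=comp["c"] / total,
        e2=comp["e"] / total,
        a=math.sqrt(comp["a"]),
        c=math.sqrt(comp["c"]),
        e=math.sqrt(comp["e"]),
        total_variance=total,
        loglik=-best.fun,
        n_mz=pt.n_mz,
        n_dz=pt.n_dz,
        converged=bool(best.success),
    )
    if compute_ci:
        cis = ace_confint(pt, est, level=ci_level, center=center)
        est = ACEEstimate(
            **{
                **est.__dict__,
                "ci_a2": cis["a2"],
                "ci_c2": cis["c2"],
                "ci_e2": cis["e2"],
            }
        )
    return est


# ---------------------------------------------------------------------------
# profile-likelihood confidence intervals
# ---------------------------------------------------------------------------

def _profile_ll(stats_mz, stats_dz, component: str, t: float, init: tuple) -> float:
    """Max log-likelihood with one standardized proportion fixed at t.

    The remaining freedom is the total variance V > 0 and the split u of the
    leftover proportion 1 - t between the other two components; both are
    optimized on unconstrained scales (log V, logit u).
    """
    rest = 1.0 - t

    def props(u: float) -> tuple[float, float, float]:
        if component == "a2":
            return t, u * rest, (1.0 - u) * rest
        if component == "c2":
            return u * rest, t, (1.0 - u) * rest
        return u * rest, (1.0 - u) * rest, t  # e2

    def nll(x: np.ndarray) -> float:
        v_tot = math.exp(min(x[0], 50.0))
        u = 1.0 / (1.0 + math.exp(-min(max(x[1], -35.0), 35.0)))
        a2p, c2p, e2p = props(u)
        ll = _ll_from_components(
            stats_mz, stats_dz, a2p * v_tot, c2p * v_tot, e2p * v_tot
        )
        return -ll if np.isfinite(ll) else 1e300

    v0, u0 = init
    u0 = min(max(u0, 1e-4), 1.0 - 1e-4)
    x0 = np.array([math.log(v0), math.log(u0 / (1.0 - u0))])
    best = np.inf
    for start in (x0, x0 + np.array([0.0, 1.0]), x0 - np.array([0.0, 1.0])):
        res = optimize.minimize(
            nll, start, method="Nelder-Mead",
            options={"fatol": 1e-9, "xatol": 1e-7, "maxiter": 800},
        )
        best = min(best, res.fun)
    return -best


def ace_confint(
    pt: PairedTrait,
    est: ACEEstimate,
    level: float = 0.95,
    center: bool = True,
    components=("a2", "c2", "e2"),
) -> dict[str, tuple[float, float]]:
    """Profile-likelihood CIs for the standardized A, C, E proportions.

    A proportion value t is inside the interval when its profile
    log-likelihood is within chi2_1(level)/2 of the maximum (1.92 for 95%);
    bounds are truncated to [0, 1] and a bound exactly at 0 or 1 is a valid
    boundary result.
    """
    crit = _CHI2_HALF.get(level, stats.chi2.ppf(level, 1) / 2.0)
    centered, _ = _center(pt, center)
    stats_mz = _suffstats(centered.mz)
    stats_dz = _suffstats(centered.dz)

    props = {"a2": est.a2, "c2": est.c2, "e2": est.e2}
    out: dict[str, tuple[float, float]] = {}
    for component in components:
        t_hat = props[component]
        others = [k for k in props if k != component]
        rest = max(1.0 - t_hat, 1e-9)
        u_hat = props[others[0]] / rest
        init = (est.total_variance, u_hat)

        def pll(t: float) -> float:
            return _profile_ll(stats_mz, stats_dz, component, t, init)

        ll_max = max(est.loglik, pll(min(max(t_hat, 1e-6), 1.0 - 1e-6)))
        target = ll_max - crit

        def f(t: float) -> float:
            return pll(t) - target

        eps = 1e-6
        lo_edge, hi_edge = eps, 1.0 - eps
        # lower bound
        if f(lo_edge) >= 0:
            lower = 0.0
        else:
            lower = float(
                optimize.brentq(f, lo_edge, max(t_hat, 2 * eps), xtol=5e-4)
            )
        # upper bound
        if f(hi_edge) >= 0:
            upper = 1.0
        else:
            upper = float(
                optimize.brentq(f, min(t_hat, 1.0 - 2 * eps), hi_edge, xtol=5e-4)
            )
        out[component] = (max(lower, 0.0), min(upper, 1.0))
    return out


def ace_bootstrap_ci(
    pt: PairedTrait,
    level: float = 0.95,
    n_boot: int = 200,
    seed: int = 0,
    model: str = "ACE",
) -> dict[str, tuple[float, float]]:
    """Percentile bootstrap CIs for the standardized proportions.

    Pairs are resampled with replacement within each zygosity group and the
    model refit per replicate.  Provided as a cross-check for the
    profile-likelihood intervals of :func:`ace_confint`; at boundaries the
    percentile interval is known to be narrower than the profile one.
    """
    rng = np.random.default_rng(seed)
    draws = np.empty((n_boot, 3))
    for b in range(n_boot):
        mz = pt.mz[rng.integers(pt.n_mz, size=pt.n_mz)]
        dz = pt.dz[rng.integers(pt.n_dz, size=pt.n_dz)]
        est = fit_ace(PairedTrait(mz, dz), model=model)
        draws[b] = (est.a2, est.c2, est.e2)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(draws, [alpha, 1.0 - alpha], axis=0)
    return {
        comp: (float(lo[i]), float(hi[i]))
        for i, comp in enumerate(("a2", "c2", "e2"))
    }


# ---------------------------------------------------------------------------
# panel-wide summaries
# ---------------------------------------------------------------------------

def complete_pair_indices(roster: pd.DataFrame, subject_index: pd.Index):
    """Row positions (into subject_index) of both members of each pair.

    Returns (mz_idx, dz_idx), each an (n_pairs, 2) integer array ordered by
    pair id with the lexicographically smaller subject first.
    """
    pos = pd.Series(np.arange(len(subject_index)), index=subject_index)
    paired = roster.dropna(subset=["pair_id"])
    paired = paired[paired["subject_id"].isin(subject_index)]
    sizes = paired["pair_id"].map(paired["pair_id"].value_counts())
    paired = paired[sizes == 2].sort_values(["pair_id", "subject_id"])
    if len(paired) == 0:
        empty = np.empty((0, 2), dtype=int)
        return empty, empty
    idx = pos[paired["subject_id"]].to_numpy().reshape(-1, 2)
    zyg = paired["zygosity"].to_numpy()[::2]
    return idx[zyg == "MZ"], idx[zyg == "DZ"]


def paired_trait_from_values(
    values: pd.Series, roster: pd.DataFrame, label: str = ""
) -> PairedTrait:
    """Assemble complete MZ/DZ pair values for one trait from a roster."""
    mz_idx, dz_idx = complete_pair_indices(roster, values.index)
    arr = values.to_numpy(dtype=float)
    groups = []
    for idx in (mz_idx, dz_idx):
        pairs = arr[idx] if len(idx) else np.empty((0, 2))
        pairs = pairs[~np.isnan(pairs).any(axis=1)] if len(pairs) else pairs
        groups.append(pairs)
    return PairedTrait(groups[0], groups[1], label=label)


def panel_heritability(
    proteins: ProteinMatrix,
    roster: pd.DataFrame,
    transform: str | None = None,
    model: str = "ACE",
    min_pairs: int = 3,
    compute_ci: bool = False,
) -> tuple[pd.DataFrame, dict]:
    """Fit the twin model to every analyte and summarize the panel.

    Parameters
    ----------
    transform : None or "vdw"
        Optionally re-express each analyte by the Van der Waerden rank-normal
        transform before fitting (the robustness analysis of the panel
        summary).
    Returns
    -------
    per_analyte : DataFrame
        One row per analyte (skipped analytes carry a ``skip_reason``).
    summary : dict
        Median and IQR of A, of A+C ("familial") and of E over fitted
        analytes, plus bookkeeping counts.
    """
    from .preprocess import van_der_waerden  # local import to avoid a cycle

    mz_idx, dz_idx = complete_pair_indices(roster, proteins.subjects)
    rows = []
    for analyte in proteins.analytes:
        col = proteins.values[analyte]
        try:
            if transform == "vdw":
                col = van_der_waerden(col)
            elif transform not in (None, "standardized"):
                raise ValueError(f"unknown transform {transform!r}")
            arr = col.to_numpy(dtype=float)
            mz = arr[mz_idx] if len(mz_idx) else np.empty((0, 2))
            dz = arr[dz_idx] if len(dz_idx) else np.empty((0, 2))
            mz = mz[~np.isnan(mz).any(axis=1)] if len(mz) else mz
            dz = dz[~np.isnan(dz).any(axis=1)] if len(dz) else dz
            if len(mz) < min_pairs or len(dz) < min_pairs:
                raise ValueError(
                    f"too few complete pairs ({len(mz)} MZ, {len(dz)} DZ)"
                )
            est = fit_ace(
                PairedTrait(mz, dz, label=str(analyte)),
                model=model,
                compute_ci=compute_ci,
            )
        except ValueError as exc:
            rows.append({"analyte": analyte, "skip_reason": str(exc)})
            continue
        row = {
            "analyte": analyte,
            "model": est.model,
            "a2": est.a2,
            "c2": est.c2,
            "e2": est.e2,
            "loglik": est.loglik,
            "n_mz": est.n_mz,
            "n_dz": est.n_dz,
            "converged": est.converged,
            "skip_reason": None,
        }
        if compute_ci:
            row.update(
                a2_lo=est.ci_a2[0], a2_hi=est.ci_a2[1],
                c2_lo=est.ci_c2[0], c2_hi=est.ci_c2[1],
                e2_lo=est.ci_e2[0], e2_hi=est.ci_e2[1],
            )
        rows.append(row)
    per_analyte = pd.DataFrame(rows).set_index("analyte").sort_index()

    fitted = per_analyte[per_analyte["skip_reason"].isna()]

    def _med_iqr(series: pd.Series) -> dict:
        if len(series) == 0:
            return {"median": np.nan, "iqr": (np.nan, np.nan)}
        return {
            "median": float(series.median()),
            "iqr": (float(series.quantile(0.25)), float(series.quantile(0.75))),
        }

    if len(fitted) and "a2" in fitted.columns:
        a_summ = _med_iqr(fitted["a2"])
        fam_summ = _med_iqr(fitted["a2"] + fitted["c2"])
        e_summ = _med_iqr(fitted["e2"])
    else:
        a_summ = fam_summ = e_summ = _med_iqr(pd.Series(dtype=float))
    summary = {
        "n_analytes": int(proteins.shape[1]),
        "n_fitted": int(len(fitted)),
        "n_skipped": int(per_analyte["skip_reason"].notna().sum()),
        "A": a_summ,
        "familial": fam_summ,
        "E": e_summ,
    }
    return per_analyte, summary
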