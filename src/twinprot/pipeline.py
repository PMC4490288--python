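"""Discovery -> replication orchestration and reporting.

`run_discovery` executes the full twin-cohort workflow — subject filters,
log/z-score transform, outlier masking, panel-wide ACE heritability, GEE
association scans and MZ twin-difference follow-up of the hits — and returns
one JSON-serializable report.  `run_replication` runs the stratified
(all / controls / female-controls) linear-model replication of a protein
shortlist against regional brain volumes, with outlier-sensitivity refits and
a direction-consistency table against the discovery effect signs.

Reports are deterministic functions of their inputs: rerunning with the same
configuration and seed yields byte-identical machine-readable output.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .association import scan, stratum_mask, subgroup_replication
from .datatypes import VOLUME_REGIONS, ProteinMatrix
from .heritability import panel_heritability
from .preprocess import (
    filter_subjects,
    log_standardize,
    mask_outliers,
    normalize_volumes,
    pair_summary,
)
from .twin_difference import diff_regression, make_pair_diffs

__all__ = ["RunConfig", "run_discovery", "run_replication", "write_report"]

logger = logging.getLogger(__name__)

# exit-code conventions for the CLI: config, data and convergence problems
EXIT_CONFIG_ERROR = 2
EXIT_DATA_ERROR = 3
EXIT_CONVERGENCE_ERROR = 4


@dataclass
class RunConfig:
    """Configuration shared by the discovery and replication workflows."""

    outlier_sd: float = 2.5
    heritability_transform: str | None = None  # None (standardized) or "vdw"
    covariates: tuple = ("age", "sex", "centre")
    q_association: float = 0.05
    q_suggestive: float = 0.1
    mmse_cutoff: float | None = None  # must be set explicitly to dichotomize MMSE
    strata: tuple = ("all", "controls", "female-controls")
    outcomes: tuple = ("delta_pal",)
    volume_scan: bool = False
    use_icv: bool = False
    seed: int = 20150616
    outdir: str | None = None

    def __post_init__(self):
        for name in ("q_association", "q_suggestive"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        if self.q_association > self.q_suggestive:
            raise ValueError("association threshold must not exceed the suggestive one")
        if self.outlier_sd <= 0:
            raise ValueError("outlier_sd must be positive")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        for key in ("covariates", "strata", "outcomes"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        for key in ("covariates", "strata", "outcomes"):
            d[key] = list(d[key])
        return d


def _preprocess(roster, proteins, phenotypes, cfg: RunConfig):
    kept, audit = filter_subjects(roster)
    ids = kept["subject_id"]
    prot = log_standardize(proteins.subset_subjects(ids))
    prot, mask_counts = mask_outliers(prot, k=cfg.outlier_sd)
    phen = phenotypes.loc[ids]
    return kept, audit, prot, phen, mask_counts


def run_discovery(
    roster: pd.DataFrame,
    proteins: ProteinMatrix,
    phenotypes: pd.DataFrame,
    cfg: RunConfig | None = None,
) -> dict:
    """Full discovery workflow on a twin cohort; returns the report dict."""
    cfg = cfg or RunConfig()
    stage = "filter/transform"
    try:
        kept, audit, prot, phen, mask_counts = _preprocess(
            roster, proteins, phenotypes, cfg
        )

        stage = "heritability"
        per_analyte, herit_summary = panel_heritability(
            prot, kept, transform=cfg.heritability_transform
        )

        stage = "association scans"
        scans: dict[str, pd.DataFrame] = {}
        for outcome in cfg.outcomes:
            scans[outcome] = scan(
                prot, phen[outcome], kept, covariates=cfg.covariates
            )
        if cfg.mmse_cutoff is not None:
            binary = (phen["mmse"] < cfg.mmse_cutoff).astype(float).where(
                phen["mmse"].notna()
            )
            scans["mmse_dichotomized"] = scan(
                prot, binary, kept, covariates=cfg.covariates, family="binomial"
            )
        region_hits: dict[str, list] = {}
        if cfg.volume_scan:
            phen_norm = normalize_volumes(phen, use_icv=cfg.use_icv)
            for region in VOLUME_REGIONS:
                scans[region] = scan(
                    prot, phen_norm[region], kept, covariates=cfg.covariates
                )
                hits = scans[region].loc[
                    scans[region]["q"] < cfg.q_suggestive, "analyte"
                ]
                for analyte in hits:
                    region_hits.setdefault(analyte, []).append(region)

        stage = "twin differences"
        primary = cfg.outcomes[0]
        hit_analytes = sorted(
            scans[primary].loc[scans[primary]["q"] < cfg.q_association, "analyte"]
        )
        twin_diff = {}
        for analyte in hit_analytes:
            try:
                diffs = make_pair_diffs(prot, phen[primary], kept, analyte)
                res = diff_regression(diffs)
            except ValueError as exc:
                twin_diff[analyte] = {"error": str(exc)}
                continue
            twin_diff[analyte] = {
                "beta": res.beta,
                "se": res.se,
                "p": res.p,
                "n_pairs": res.n_pairs,
            }
    except ValueError as exc:
        raise RuntimeError(f"discovery stage '{stage}' failed: {exc}") from exc

    report = {
        "workflow": "discovery",
        "config": cfg.to_dict(),
        "cohort": {
            "n_before_exclusion": int(len(roster)),
            "n_analyzed": int(len(kept)),
            "exclusions": audit["reason"].value_counts().sort_index().to_dict(),
            **pair_summary(kept),
        },
        "preprocessing": {
            "n_analytes": int(prot.shape[1]),
            "outlier_sd": cfg.outlier_sd,
            "n_outliers_masked": int(mask_counts.sum()),
        },
        "heritability": herit_summary,
        "scans": {
            name: {
                "n_tested": int(len(df)),
                "n_failed": int(df.attrs.get("n_failed", 0)),
                "hits": _hit_list(df, cfg.q_association),
                "suggestive": _hit_list(df, cfg.q_suggestive),
            }
            for name, df in scans.items()
        },
        "multi_region_analytes": sorted(
            a for a, regions in region_hits.items() if len(regions) >= 3
        ),
        "twin_difference": twin_diff,
    }
    if cfg.outdir:
        write_report(report, cfg.outdir, tables={
            "heritability_per_analyte": per_analyte.reset_index(),
            **{f"scan_{name}": df for name, df in scans.items()},
            "exclusion_audit": audit,
        })
    return report


def _hit_list(df: pd.DataFrame, threshold: float) -> list[dict]:
    hits = df[df["q"] < threshold].sort_values(["q", "analyte"])
    return [
        {
            "analyte": r.analyte,
            "beta": round(float(r.beta), 6),
            "p": float(r.p),
            "q": float(r.q),
            "n": int(r.n),
        }
        for r in hits.itertuples()
    ]


def run_replication(
    roster: pd.DataFrame,
    proteins: ProteinMatrix,
    phenotypes: pd.DataFrame,
    shortlist,
    cfg: RunConfig | None = None,
    discovery_signs: dict[str, float] | None = None,
) -> dict:
    """Stratified replication of a shortlist against regional volumes."""
    cfg = cfg or RunConfig(use_icv=True, covariates=("age", "centre"))
    shortlist = list(shortlist)
    if not shortlist:
        raise ValueError("replication shortlist is empty")
    stage = "filter/transform"
    try:
        kept, audit, prot, phen, _ = _preprocess(roster, proteins, phenotypes, cfg)
        phen = normalize_volumes(phen, use_icv=cfg.use_icv)

        stage = "subgroup replication"
        covs = tuple(c for c in cfg.covariates if c != "sex")
        results = subgroup_replication(
            prot,
            phen,
            kept,
            shortlist,
            strata=cfg.strata,
            covariates=covs,
            outlier_sd=cfg.outlier_sd,
        )
    except ValueError as exc:
        raise RuntimeError(f"replication stage '{stage}' failed: {exc}") from exc

    strata_report = {}
    for stratum, df in results.items():
        tested = df[df["skip_reason"].isna()]
        entry = {
            "n_subjects": int(tested["n"].max()) if len(tested) else 0,
            "n_tests": int(len(tested)),
            "mean_r_squared": float(tested["r_squared"].mean()) if len(tested) else np.nan,
            "hits": [
                {
                    "analyte": r.analyte,
                    "region": r.region,
                    "beta": round(float(r.beta), 6),
                    "p": float(r.p),
                    "q": float(r.q),
                    "beta_outlier_removed": round(float(r.beta_sens), 6),
                    "p_outlier_removed": float(r.p_sens),
                }
                for r in tested[tested["q"] < cfg.q_suggestive].itertuples()
            ],
        }
        if discovery_signs:
            agree = {}
            for r in tested.itertuples():
                key = f"{r.analyte}:{r.region}"
                expected = discovery_signs.get(r.analyte)
                if expected is not None and np.sign(expected) != 0:
                    agree[key] = bool(np.sign(r.beta) == np.sign(expected))
            entry["direction_consistent"] = agree
        strata_report[stratum] = entry

    report = {
        "workflow": "replication",
        "config": cfg.to_dict(),
        "shortlist": sorted(shortlist),
        "cohort": {
            "n_before_exclusion": int(len(roster)),
            "n_analyzed": int(len(kept)),
            # stratum sizes straight from the roster (subjects, not tests)
            "stratum_sizes": {
                s: int(stratum_mask(kept, s).sum()) for s in cfg.strata
            },
        },
        "strata": strata_report,
    }
    if cfg.outdir:
        write_report(
            report,
            cfg.outdir,
            tables={f"replication_{s}": df for s, df in results.items()},
        )
    return report


def render_text(report: dict) -> str:
    """Human-readable rendering; every number also lives in the JSON report."""
    lines = [f"twinprot {report['workflow']} report", "=" * 34]
    cohort = report["cohort"]
    lines.append(f"subjects before exclusion: {cohort['n_before_exclusion']}")
    lines.append(f"subjects analyzed:         {cohort['n_analyzed']}")
    if "n_intact_pairs" in cohort:
        lines.append(
            f"intact pairs: {cohort['n_intact_pairs']} "
            f"(MZ {cohort['n_mz_pairs']}, DZ {cohort['n_dz_pairs']}); "
            f"singletons: {cohort['n_singletons']}"
        )
    if "exclusions" in cohort:
        for reason, n in cohort["exclusions"].items():
            lines.append(f"  excluded [{reason}]: {n}")
    if "stratum_sizes" in cohort:
        for s, n in cohort["stratum_sizes"].items():
            lines.append(f"  stratum {s}: {n} subjects")
    if "heritability" in report:
        h = report["heritability"]
        lines.append(
            f"panel heritability (n={h['n_fitted']} analytes): "
            f"median A = {h['A']['median']:.2f} "
            f"(IQR {h['A']['iqr'][0]:.2f}-{h['A']['iqr'][1]:.2f}), "
            f"median A+C = {h['familial']['median']:.2f}, "
            f"median E = {h['E']['median']:.2f}"
        )
    for name, s in report.get("scans", {}).items():
        lines.append(
            f"scan [{name}]: {s['n_tested']} analytes tested, "
            f"{len(s['hits'])} hits (Q<assoc), {len(s['suggestive'])} suggestive"
        )
        for hit in s["hits"]:
            lines.append(
                f"  {hit['analyte']}: beta={hit['beta']:.3f}, q={hit['q']:.3g}, n={hit['n']}"
            )
    if report.get("multi_region_analytes"):
        lines.append(
            "analytes suggestive in >=3 of 4 regions: "
            + ", ".join(report["multi_region_analytes"])
        )
    for analyte, res in report.get("twin_difference", {}).items():
        if "error" in res:
            lines.append(f"twin-diff [{analyte}]: {res['error']}")
        else:
            lines.append(
                f"twin-diff [{analyte}]: beta={res['beta']:.3f}, "
                f"p={res['p']:.3g}, n_pairs={res['n_pairs']}"
            )
    for stratum, s in report.get("strata", {}).items():
        lines.append(
            f"stratum [{stratum}]: {s['n_tests']} tests, "
            f"mean R^2 = {s['mean_r_squared']:.3f}, {len(s['hits'])} suggestive hits"
        )
        for hit in s["hits"]:
            lines.append(
                f"  {hit['analyte']} ~ {hit['region']}: beta={hit['beta']:.3f}, "
                f"p={hit['p']:.3g}, q={hit['q']:.3g} "
                f"(outlier-removed beta={hit['beta_outlier_removed']:.3f}, "
                f"p={hit['p_outlier_removed']:.3g})"
            )
    return "\n".join(lines) + "\n"


def write_report(report: dict, outdir, tables: dict[str, pd.DataFrame] | None = None):
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True, default=_json_default) + "\n"
    )
    (out / "report.txt").write_text(render_text(report))
    for name, df in (tables or {}).items():
        df.to_csv(out / f"{name}.tsv", sep="\t", index=False)


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"cannot serialize {type(obj)}")
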