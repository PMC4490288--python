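"""Monozygotic co-twin control: within-pair difference regression.

Because MZ twins share their genome, age and family environment, regressing
the within-pair difference in a phenotype on the within-pair difference in a
protein level tests the association free of genetic and shared-environment
confounding.  Pair age (shared by both twins) is retained as a covariate.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .datatypes import DiffRegressionResult, ProteinMatrix

__all__ = ["make_pair_diffs", "diff_regression", "plot_pair_diffs"]

logger = logging.getLogger(__name__)


def make_pair_diffs(
    proteins: ProteinMatrix,
    phenotype: pd.Series,
    roster: pd.DataFrame,
    analyte: str,
    zygosity: str = "MZ",
) -> pd.DataFrame:
    """Within-pair differences for one analyte and one phenotype.

    Only pairs of the requested zygosity with both members complete on the
    protein and the phenotype are used.  Orientation is fixed by subject ID:
    twin A is the lexicographically smaller ID, and both deltas are
    twin A minus twin B.  Ages within a pair should agree; if they differ the
    mean is used and a warning is logged.
    """
    if analyte not in proteins.analytes:
        raise ValueError(f"analyte {analyte!r} not in panel")
    paired = roster.dropna(subset=["pair_id"])
    paired = paired[paired["zygosity"] == zygosity]
    paired = paired[paired["subject_id"].isin(proteins.subjects)]
    sizes = paired["pair_id"].map(paired["pair_id"].value_counts())
    # orientation: lexicographically smaller subject_id is twin A
    paired = paired[sizes == 2].sort_values(["pair_id", "subject_id"])
    if len(paired) == 0:
        raise ValueError(f"roster contains no complete {zygosity} pairs")

    ids = paired["subject_id"]
    x = proteins.values[analyte].reindex(ids).to_numpy(dtype=float).reshape(-1, 2)
    y = phenotype.reindex(ids).to_numpy(dtype=float).reshape(-1, 2)
    ages = paired["age"].to_numpy(dtype=float).reshape(-1, 2)
    pair_ids = paired["pair_id"].to_numpy()[::2]

    complete = ~(np.isnan(x).any(axis=1) | np.isnan(y).any(axis=1))
    if not complete.any():
        raise ValueError(
            f"no complete {zygosity} pairs for analyte {analyte!r} and this phenotype"
        )
    discordant = ages[complete, 0] != ages[complete, 1]
    if discordant.any():
        logger.warning(
            "%d pairs have discordant recorded ages; using the pair mean",
            int(discordant.sum()),
        )
    return pd.DataFrame(
        {
            "pair_id": pair_ids[complete],
            "delta_protein": x[complete, 0] - x[complete, 1],
            "delta_phenotype": y[complete, 0] - y[complete, 1],
            "pair_age": ages[complete].mean(axis=1),
        }
    )


def diff_regression(
    diffs: pd.DataFrame, include_intercept: bool = True
) -> DiffRegressionResult:
    """OLS of the phenotype delta on the protein delta, covarying pair age.

    Reports the protein-delta slope with a two-sided t-test.  At least four
    pairs are required (intercept + slope + age).  The slope is invariant to
    relabelling twin A/B within any pair.
    """
    n = len(diffs)
    if n < 4:
        raise ValueError(f"need >= 4 pairs for the difference regression, got {n}")
    X = pd.DataFrame(
        {
            "delta_protein": diffs["delta_protein"].to_numpy(dtype=float),
            "pair_age": diffs["pair_age"].to_numpy(dtype=float),
        }
    )
    if include_intercept:
        X.insert(0, "const", 1.0)
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError(
            "collinear design: protein deltas (or ages) carry no independent variation"
        )
    res = sm.OLS(diffs["delta_phenotype"].to_numpy(dtype=float), X).fit()
    return DiffRegressionResult(
        beta=float(res.params["delta_protein"]),
        se=float(res.bse["delta_protein"]),
        p=float(res.pvalues["delta_protein"]),
        n_pairs=n,
        intercept=float(res.params.get("const", 0.0)),
        age_beta=float(res.params["pair_age"]),
    )


def plot_pair_diffs(
    diffs: pd.DataFrame,
    result: DiffRegressionResult | None = None,
    path=None,
    analyte: str = "",
    phenotype: str = "",
):
    """Scatter of within-pair deltas with the fitted slope (age at its mean).

    Writes SVG/PNG according to the file extension when ``path`` is given;
    otherwise returns the matplotlib figure.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if result is None:
        result = diff_regression(diffs)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(diffs["delta_protein"], diffs["delta_phenotype"],
               s=18, alpha=0.7, edgecolor="none")
    xs = np.linspace(diffs["delta_protein"].min(), diffs["delta_protein"].max(), 50)
    ax.plot(
        xs,
        result.intercept + result.beta * xs + result.age_beta * diffs["pair_age"].mean(),
        color="firebrick",
        label=f"beta={result.beta:.2f}, p={result.p:.3g}",
    )
    ax.axhline(0, lw=0.5, color="grey")
    ax.axvline(0, lw=0.5, color="grey")
    ax.set_xlabel(f"MZ within-pair difference, {analyte or 'protein'} (s.d. units)")
    ax.set_ylabel(f"MZ within-pair difference, {phenotype or 'phenotype'}")
    ax.legend(frameon=False)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
        plt.close(fig)
        return None
    return fig
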