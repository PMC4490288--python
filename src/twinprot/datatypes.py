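"""Core containers shared across the pipeline.

The roster, protein matrix and phenotype table travel as pandas objects;
small result bundles are frozen dataclasses so they serialize cleanly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

#: roster columns every stage can rely on
ROSTER_COLUMNS = [
    "subject_id",
    "pair_id",
    "zygosity",
    "age",
    "sex",
    "centre",
    "apoe_e4_count",
    "haemolysed",
    "qc_fail",
    "diagnosis",
]

#: phenotype columns (volumes in arbitrary mm^3-like units before normalization)
PHENOTYPE_COLUMNS = [
    "delta_pal",
    "mmse",
    "lh_volume",
    "rh_volume",
    "le_volume",
    "re_volume",
    "icv",
]

VOLUME_REGIONS = ["lh_volume", "rh_volume", "le_volume", "re_volume"]

TRANSFORM_STATES = ("raw", "log", "standardized", "vanderwaerden")


class ProteinMatrix:
    """Subjects x analytes abundance table that tracks its transform state.

    Raw values are strictly positive relative-fluorescence-unit-like numbers;
    missing entries are NaN.  Downstream transforms (natural log + z-score,
    outlier masking, Van der Waerden) update ``transform_state`` so each
    stage can verify its precondition.
    """

    def __init__(self, values: pd.DataFrame, transform_state: str = "raw"):
        if transform_state not in TRANSFORM_STATES:
            raise ValueError(f"unknown transform state {transform_state!r}")
        if values.index.has_duplicates:
            raise ValueError("duplicate subject IDs in protein matrix")
        self.values = values.astype(float)
        self.transform_state = transform_state

    @property
    def subjects(self) -> pd.Index:
        return self.values.index

    @property
    def analytes(self) -> pd.Index:
        return self.values.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def copy(self) -> "ProteinMatrix":
        return ProteinMatrix(self.values.copy(), self.transform_state)

    def subset_subjects(self, subject_ids) -> "ProteinMatrix":
        return ProteinMatrix(self.values.loc[subject_ids], self.transform_state)

    def __repr__(self) -> str:  # pragma: no cover
        n, m = self.shape
        return f"<ProteinMatrix {n} subjects x {m} analytes [{self.transform_state}]>"


@dataclass(frozen=True)
class SimulationTruth:
    """Ground truth for a simulated twin cohort.

    Per-analyte variance fractions ``a2``/``c2``/``e2`` (additive genetic,
    shared environment, non-shared environment) must each sum to 1.  ``beta``
    gives each analyte's standardized effect on the cognitive-change outcome;
    ``confounding`` controls which latent component carries that effect:

    ``"none"``
        the full analyte signal drives the outcome (a true exposure effect —
        within MZ pairs it acts through the non-shared component),
    ``"genetic"``
        only the additive-genetic factor drives the outcome, so the
        individual-level association is purely genetic confounding,
    ``"shared-env"``
        only the family-shared factor drives the outcome.
    """

    a2: np.ndarray
    c2: np.ndarray
    e2: np.ndarray
    beta: np.ndarray
    n_mz_pairs: int
    n_dz_pairs: int
    n_singletons: int = 0
    confounding: str = "none"
    age_slope: float = 0.0
    centre_offsets: dict = field(default_factory=lambda: {"London": 0.0})
    missing_rate: float = 0.02
    phenotype_pair_corr: float = 0.3
    rfu_scale: float = 1000.0
    seed: int = 20150616

    def __post_init__(self):
        for name in ("a2", "c2", "e2", "beta"):
            object.__setattr__(self, name, np.atleast_1d(np.asarray(getattr(self, name), dtype=float)))
        n = len(self.a2)
        if not (len(self.c2) == len(self.e2) == len(self.beta) == n):
            raise ValueError("a2, c2, e2 and beta must have equal length")
        if n < 1:
            raise ValueError("panel size must be >= 1")
        for name in ("a2", "c2", "e2"):
            arr = getattr(self, name)
            if np.any((arr < 0) | (arr > 1)):
                raise ValueError(f"{name} fractions must lie in [0, 1]")
        total = self.a2 + self.c2 + self.e2
        if np.any(np.abs(total - 1.0) > 1e-12):
            raise ValueError("a2 + c2 + e2 must equal 1 for every analyte")
        for name in ("n_mz_pairs", "n_dz_pairs", "n_singletons"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.confounding not in ("none", "genetic", "shared-env"):
            raise ValueError(f"unknown confounding mode {self.confounding!r}")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        if not 0.0 <= self.phenotype_pair_corr < 1.0:
            raise ValueError("phenotype_pair_corr must lie in [0, 1)")

    @property
    def n_analytes(self) -> int:
        return len(self.a2)

    @classmethod
    def uniform(
        cls,
        a2: float,
        c2: float,
        e2: float,
        n_analytes: int = 1,
        beta: float = 0.0,
        **kwargs,
    ) -> "SimulationTruth":
        """Panel in which every analyte shares one (a2, c2, e2) and beta."""
        ones = np.ones(n_analytes)
        return cls(a2=a2 * ones, c2=c2 * ones, e2=e2 * ones, beta=beta * ones, **kwargs)

    def to_dict(self) -> dict:
        return {
            "a2": self.a2.tolist(),
            "c2": self.c2.tolist(),
            "e2": self.e2.tolist(),
            "beta": self.beta.tolist(),
            "n_mz_pairs": self.n_mz_pairs,
            "n_dz_pairs": self.n_dz_pairs,
            "n_singletons": self.n_singletons,
            "confounding": self.confounding,
            "age_slope": self.age_slope,
            "centre_offsets": dict(self.centre_offsets),
            "missing_rate": self.missing_rate,
            "phenotype_pair_corr": self.phenotype_pair_corr,
            "rfu_scale": self.rfu_scale,
            "seed": self.seed,
        }


@dataclass(frozen=True)
class ACEEstimate:
    """ML variance decomposition of one trait from MZ/DZ pair data."""

    trait: str
    model: str
    a2: float
    c2: float
    e2: float
    a: float
    c: float
    e: float
    total_variance: float
    loglik: float
    n_mz: int
    n_dz: int
    converged: bool
    ci_a2: Optional[tuple[float, float]] = None
    ci_c2: Optional[tuple[float, float]] = None
    ci_e2: Optional[tuple[float, float]] = None

    def __post_init__(self):
        s = self.a2 + self.c2 + self.e2
        if abs(s - 1.0) > 1e-8:
            raise ValueError(f"variance proportions sum to {s}, expected 1")


@dataclass(frozen=True)
class GEEFit:
    """Marginal regression fit with exchangeable working correlation."""

    params: pd.Series
    cov_robust: pd.DataFrame
    alpha: float
    n_obs: int
    n_clusters: int
    converged: bool
    flags: tuple[str, ...] = ()

    @property
    def bse(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov_robust)), index=self.params.index)


@dataclass(frozen=True)
class AssociationResult:
    """One analyte's row in an endophenotype scan."""

    analyte: str
    beta: float
    se: float
    p: float
    q: float
    n: int
    r_squared: Optional[float] = None
    covariates: str = ""
    stratum: str = "all"


@dataclass(frozen=True)
class TwinPairDiff:
    """Within-MZ-pair differences for one analyte/phenotype combination."""

    pair_id: str
    delta_protein: float
    delta_phenotype: float
    pair_age: float


@dataclass(frozen=True)
class DiffRegressionResult:
    """Twin-difference regression of a phenotype delta on a protein delta."""

    beta: float
    se: float
    p: float
    n_pairs: int
    intercept: float
    age_beta: float
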