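# twinprot

Twin-cohort plasma-proteomics analysis: panel-wide ACE heritability,
GEE association scans against Alzheimer's-disease endophenotypes, and
monozygotic twin-difference regression, with a synthetic-cohort generator
carrying known ground truth.

## The problem

Blood-based protein biomarkers of pre-symptomatic Alzheimer's disease are
attractive — cheap, non-invasive — but two questions precede any clinical
use. First, how heritable are plasma protein levels? If a protein's level is
mostly genetic, a genetic test may beat the protein assay. Second, when a
protein associates with an AD endophenotype (10-year cognitive decline on
CANTAB-PAL, regional brain volumes, MMSE), is the association causal-ish or
confounded by shared genes and family environment? Twin cohorts answer both:
contrasting monozygotic (MZ) and dizygotic (DZ) pair covariances decomposes
each analyte's variance, and within-MZ-pair differences test associations
with genetics and shared environment differenced away.

This package implements that workflow end to end for SOMAscan-style panels
(~1100 analytes, relative fluorescence units) and exercises it on synthetic
twin cohorts whose ground truth is known, so every stage is testable without
access to the (unreleased) cohort data.

## The models

**ACE decomposition.** Complete twin pairs are zero-mean bivariate normals
with variance a²+c²+e² and within-pair covariance a²+c² (MZ) or ½a²+c² (DZ),
where A = additive genetics, C = shared environment, E = non-shared
environment. Path coefficients are estimated by maximum likelihood
(Nelder–Mead from the Falconer start h² = 2(r_MZ − r_DZ)), with
profile-likelihood 95% CIs on the standardized proportions, truncated to
[0, 1].

**Association scans.** Each analyte is regressed against one endophenotype
(protein as predictor) by generalized estimating equations with twin-pair
clusters, exchangeable working correlation and robust sandwich SEs —
reducing exactly to OLS when every subject is a singleton — with age, sex
and centre covariates, and Benjamini–Hochberg Q-values within each scan
(Q < 0.05 association, Q < 0.1 suggestive).

**Twin-difference regression.** For MZ pairs, Δphenotype is regressed on
Δprotein covarying pair age. A purely genetic protein–phenotype association
survives the individual-level scan but collapses to zero within pairs; a
true non-shared effect survives both.

## Worked example

```python
import numpy as np
from twinprot import (SimulationTruth, simulate_twin_cohort, log_standardize,
                      scan, make_pair_diffs, diff_regression, fit_ace)
from twinprot.heritability import paired_trait_from_values

# 20-analyte panel, one true non-shared effect on cognitive change
beta = np.zeros(20); beta[4] = 0.6
truth = SimulationTruth(
    a2=np.full(20, 0.3), c2=np.full(20, 0.1), e2=np.full(20, 0.6),
    beta=beta, n_mz_pairs=50, n_dz_pairs=43, n_singletons=9, seed=11)
roster, proteins, phenotypes = simulate_twin_cohort(truth)
prot = log_standardize(proteins)

result = scan(prot, phenotypes["delta_pal"], roster)
print(result.nsmallest(1, "q")[["analyte", "beta", "q", "n"]])
#   analyte      beta             q    n
# 4   A0005  0.595037  4.962316e-26  193

diffs = make_pair_diffs(prot, phenotypes["delta_pal"], roster, "A0005")
r = diff_regression(diffs)
print(f"MZ-difference beta={r.beta:.3f}, p={r.p:.4f}, pairs={r.n_pairs}")
# MZ-difference beta=0.523, p=0.0004, pairs=49

est = fit_ace(paired_trait_from_values(prot.values["A0005"], roster))
print(f"A={est.a2:.2f} C={est.c2:.2f} E={est.e2:.2f}")
# A=0.30 C=0.00 E=0.70
```

The planted analyte (true slope 0.6) tops the scan at Q ≈ 5e-26 on 193
complete cases, keeps a positive within-pair slope (0.523, p = 0.0004 across
49 complete MZ pairs — the association is not genetically confounded), and
its fitted variance decomposition is consistent with the generating values
(0.3 / 0.1 / 0.6) at this cohort size.

The numbered drivers under `analysis/` run the same machinery as a
narrative: `01_simulate_cohorts.py` builds a discovery-style cohort (212
subjects, filtered to 195: 93 pairs + 9 singletons) and a replication-style
cohort (254 subjects; 91 controls, 51 of them female); `02`–`05` preprocess,
estimate panel heritability, scan, and run twin differences;
`06_replication.py` shows a planted female-control-only effect replicating
with the largest R² in exactly that stratum. Each writes its tables under
`results/`.

There is also a CLI mirroring the stages:

```bash
twinprot simulate --fixture discovery --outdir results/cohorts/discovery
twinprot preprocess --indir results/cohorts/discovery --outdir results/processed
twinprot heritability --indir results/processed --out herit.tsv
```

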