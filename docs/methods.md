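# Methods

`twinprot` implements a twin-cohort proteomics analysis pipeline: a synthetic
twin-cohort generator with known variance-component ground truth, subject and
analyte preprocessing, ACE heritability estimation across a protein panel,
generalized-estimating-equation (GEE) association scans against Alzheimer's
endophenotypes, monozygotic (MZ) twin-difference regression, and a stratified
replication workflow. This note records the models, the parameter choices and
their rationale, the numerical decisions, and what the synthetic data do and
do not establish.

## The generative model

Each analyte's latent (log-scale) level for subject *j* is

    y_j = a·G_j + c·F_j + e·U_j,        a² + c² + e² = 1,

with standard-normal factors: *G* is the additive-genetic factor (correlation
1 within MZ pairs; within DZ pairs it is built as a pair-shared component of
variance a²/2 plus an independent component of variance a²/2, giving a
genetic correlation of exactly 0.5 by construction rather than by sampling);
*F* is shared by both members of a pair; *U* is subject-specific. The implied
within-pair trait correlations are a²+c² (MZ) and a²/2+c² (DZ), which the
test suite verifies empirically at 10⁴ pairs.

Abundances are emitted as `rfu_scale · exp(latent)` (default scale 1000),
i.e. log-normal on a relative-fluorescence-unit-like scale, so the log
transform downstream is exercised non-trivially. Optional covariate effects
(a standardized-age slope, per-centre offsets) are added on the log scale
after the unit-variance ACE signal.

The cognitive-change outcome is `Σ_k β_k · X_k + noise`, where the
`confounding` mode picks the component carrying each analyte's effect:

- `none` — X is the full analyte signal; since G and F cancel within MZ
  pairs, this is a *non-shared* (true exposure-like) effect and the
  MZ-difference slope equals β;
- `genetic` — X is the G factor alone: the individual-level association is
  pure genetic confounding and the population MZ-difference slope is 0;
- `shared-env` — X is the F factor alone.

Outcome noise has variance `max(1 − Σβ², 0.05)` split between a pair-shared
and an independent part (`phenotype_pair_corr`, default 0.3) so outcomes are
clustered within pairs even under the null — the situation GEE exists for.

Defaults: missingness is injected completely at random at 2% (a placeholder
choice: panel-proteomics missingness mechanisms are rarely published, and no
mechanism is modelled); the master seed default is 20150616; all randomness
flows through one `numpy` generator so regeneration is byte-identical.

### Worked-example fixtures

`make_paper_fixture` emulates a discovery cohort of 212 all-female subjects
in 106 twin pairs with a 1129-analyte panel. Exclusion flags are placed
non-overlapping — 10 double-APOE-E4 carriers, 6 haemolysed samples, 1 assay
QC failure — so that four pairs lose both members and nine lose one, and the
filter leaves exactly 195 subjects: 93 intact pairs (55 MZ + 38 DZ) and 9
newly single co-twins. The pre-exclusion zygosity split is not uniquely
determined by those margins; the fixture uses 62 MZ + 44 DZ pairs with the
broken pairs split 2+5 (MZ) and 2+4 (DZ). MRI volumes are populated for 34
MZ subjects plus 2 singles only. Panel heritabilities are drawn with
a² ~ Beta(1.1, 2.6) (median ≈ 0.26, wide spread) and a small
shared-environment share of the remainder.

`make_anm_fixture` emulates a mixed-sex singleton replication cohort of 254
subjects: 91 controls (51 female) / 81 MCI / 82 AD, six recruitment centres,
regional volumes proportional to intracranial volume (so ICV normalization
has something to remove), and MMSE distributions by diagnosis. An optional
`planted` effect adds `β · protein-latent` to one region's log-volume in one
stratum only, for power and replication experiments.

## Preprocessing

Subject filtering removes double-APOE-E4 carriers, haemolysed samples and QC
failures, in that order of reported reason; a surviving co-twin keeps their
row but loses pair membership. The filter is idempotent.

Analyte transform: natural log, then per-analyte z-score over observed
entries with the n−1 (sample) standard deviation — the denominators differ
immaterially at these sizes, but the choice must be fixed for
reproducibility. Outlier masking then sets entries with |z| > 2.5 to missing
in a single pass. Two decisions here: the rule is two-sided ("more than 2.5
s.d. from the mean" read as distance), strict at the boundary (exactly 2.5
is kept), and z-scores are *not* recomputed after masking — a second pass
would re-flag new extremes and make the operation order-sensitive.
Standardization happens after subject exclusion, not before.

The Van der Waerden transform maps the rank r among n observed values to
Φ⁻¹(r/(n+1)), with average ranks for ties (the standard convention); it is
invariant to any strictly monotone transformation of its input, which the
suite checks property-based.

Regional brain volumes are optionally divided by intracranial volume (plain
division; no regression-calibration variant), then logged and z-scored per
region.

MMSE dichotomization has **no default cut-point**: the threshold is a
required configuration parameter, because no principled default exists and a
silent one would be worse than an explicit error.

## ACE heritability estimation

Each trait's complete MZ and DZ pairs are modelled as zero-mean (after
centering at the pooled mean) bivariate normals with

    Var = a² + c² + e²,   Cov_MZ = a² + c²,   Cov_DZ = a²/2 + c².

Parameters are the path coefficients (a, c, e); squaring enforces
non-negative variance components, mirroring classical twin structural
equation modelling, and makes boundary solutions (â = 0 or ĉ = 0) ordinary
results rather than constraint violations. Means are handled by centering
rather than estimated inside the model — analytes arrive standardized, and a
mean parameter would only dilute the covariance information.

The joint log-likelihood depends on the data only through per-zygosity
sufficient statistics (n, Σ(y₁²+y₂²), Σy₁y₂), so a single evaluation is a
few arithmetic operations; this is what makes 1129-analyte panels and
coverage simulations cheap.

Fits start from the Falconer closed form — intraclass correlations by the
one-way ANOVA estimator, then a² = 2(rMZ − rDZ), c² = 2rDZ − rMZ,
e² = 1 − rMZ, each clipped to [0, 1] and renormalized to sum to one — and are
refined by Nelder–Mead with two deterministic jittered restarts
(multiplicative factors 0.6 and 1.5), function tolerance 1e-10. Degenerate
(zero-variance) traits are rejected; with MZ pairs only, A and C are not
separately identifiable and the full ACE fit refuses with a diagnostic
rather than returning an arbitrary split (nested AE/CE/E fits remain
available). With the generating model's truth at c² = 0, the non-negativity
boundary induces a small downward finite-sample bias in â² (about 0.02 at
5000+5000 pairs) — a known property of boundary-constrained variance
components, visible in the acceptance numbers.

Confidence intervals are profile-likelihood intervals on the standardized
proportions: a value t is inside the 95% interval when the log-likelihood,
maximized over the total variance and the split of 1−t between the other two
components, is within χ²₁(0.95)/2 ≈ 1.921 of the maximum. Bounds are found
by bisection to 5e-4 and truncated to [0, 1]; a bound exactly at 0 is a
valid boundary statement (e.g. "C = 0%, CI 0–23%"-style results). Profile
intervals were chosen over the bootstrap because they respect the boundary
and the likelihood's asymmetry; coverage is verified by simulation (≥ 90% at
500+500 pairs for a high-heritability trait).

`panel_heritability` fits every analyte (optionally after the Van der
Waerden transform), skips — without failing the panel — analytes with fewer
than 3 complete pairs per zygosity, and reports the median and IQR of A, of
A+C ("familial") and of E across fitted analytes.

## Association scans

`gee_fit` delegates to statsmodels' GEE with an exchangeable working
correlation — the natural one-parameter structure when every cluster has
size ≤ 2 — and robust (sandwich) covariance. Singleton clusters contribute
as independent observations; when *all* clusters are singletons the
exchangeable correlation is undefined, so the fit uses an independence
working model, reports α = 0 with a flag, and (for the gaussian family)
reproduces OLS coefficients and HC0 covariance exactly — this equivalence is
tested to 1e-10. A moment-estimated α above 0.95 is flagged as a boundary.
Wald p-values use the normal reference; small-sample corrections are out of
scope, and one consequence is documented honestly: extreme-tail p-values at
~100 clusters are mildly anti-conservative, so the global-null
false-discovery property is tested at 300 pairs per zygosity, where tail
calibration is adequate, while the central type-I error (p < 0.05) is
verified at 100 pairs to fall in [0.03, 0.07].

`scan` tests every analyte against one outcome on that analyte's complete
cases (no imputation; n reported per analyte), protein level as the
predictor and endophenotype as the outcome, with age, sex and centre
covariates; covariates constant within the cohort (sex in an all-female
cohort) are dropped with a log notice. Benjamini–Hochberg is applied across
the analytes of one scan — one family per endophenotype, no
cross-endophenotype correction. Failed analytes are excluded from the family
and counted. `bh_adjust` is the explicit step-up
(q(i) = min_{j≥i} m·p(j)/j, clipped to 1) and is cross-checked in the tests
against both statsmodels and a brute-force quadratic implementation.

`subgroup_replication` runs plain linear models per analyte × region within
each stratum (all / controls / female-controls), age and centre covariates,
with BH applied within the stratum over the whole shortlist-by-region family
— the family composition is an explicit, configurable choice since several
conventions are defensible. Each fit carries an outlier-sensitivity refit
that drops points more than 2.5 s.d. from the stratum mean on either
variable (the same threshold as panel masking, applied within the
regression sample).

## Twin-difference regression

For one analyte and one phenotype, complete MZ pairs are oriented by
lexicographic subject ID (twin A = smaller ID) and both deltas are
A − B; the slope is invariant to flipping the orientation. The regression is
OLS of Δphenotype on Δprotein and pair age **with an intercept** — forcing
the fit through the origin is also defensible (differences of exchangeable
twins have mean zero), so both are implemented with intercept as default;
the slope's sign-symmetry property holds either way. Pairs with discordant
recorded ages (a data error) use the mean with a logged warning. DZ
differences are available behind a flag but excluded from default reports,
since only MZ differences remove genetic confounding fully.

## Orchestration

`run_discovery` chains filter → log/z-score → outlier mask → panel
heritability → scans → twin-difference follow-up of analytes at Q < 0.05,
and reports hits, suggestive hits (Q < 0.1), analytes suggestive in ≥ 3 of 4
brain regions, and the cohort accounting. `run_replication` adds the
stratified workflow, per-stratum R² and a sign-agreement table against
discovery effect directions. Reports are deterministic functions of inputs
(no timestamps in the machine-readable file); the text rendering is derived
from the JSON so no number exists only in prose. The CLI exposes each stage
(`simulate`, `preprocess`, `heritability`, `associate`, `twin-diff`,
`discover`, `replicate`, `report`) with exit codes separating configuration,
data and convergence failures.

## Problem sizes used in the tests and acceptance script

Generator-convergence checks use 10⁴ pairs per zygosity (tolerance 0.03 on
within-pair correlations, 0.01 in the degenerate pure-genetic case). ACE
recovery uses 5000+5000 pairs × 20 seeds per scenario; CI coverage 200
replicates at 500+500 pairs; GEE null calibration 2000 replicates at 100
pairs; the confounding contrast 200 replicates at 100 pairs; the panel
summary the full 1129 analytes at 500+500 pairs. These sizes make every
Monte-Carlo band comfortably wider than its standard error while keeping a
full run of the suite and the acceptance script to a few minutes each.

## What the synthetic data do not show

The generator realizes exactly the ACE covariance structure, linear effects
and log-normal marginals that the estimators assume, with MCAR missingness.
Passing tests therefore demonstrate correctness of the implementations and
internal consistency of the workflow — not robustness to assay batch
effects, plate drift, non-normal or heavy-tailed abundance distributions,
informative missingness, age-varying heritability, or selection into the
cohort, none of which are simulated. Real-data effect sizes for specific
proteins cannot be reproduced here because the underlying cohort data are
not public; the fixtures reproduce published *counts* and study structure,
and the statistical machinery is validated against known simulation truth.

## Known limitations

- No ADE/dominance, sex-limitation or bivariate twin models; no covariate
  adjustment inside the twin SEM (adjustment happens upstream on the trait).
- GEE inference uses asymptotic robust SEs; with few clusters the extreme
  tail is anti-conservative (see above).
- ICV normalization is ratio-based only.
- The exchangeable α estimator can exceed 1 on degenerate data (duplicated
  members); this is flagged, not silently clipped.
- Complete-pair and complete-case analyses throughout; no imputation.
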