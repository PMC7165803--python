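# Methods

## Scope and data model

The package re-implements a registry-based prognostic analysis for NUT
carcinoma as a testable pipeline. Because the underlying registry is not
public, all empirical work runs on synthetic cohorts whose *group-level*
survival and covariate structure are calibrated to the published numbers;
patient-level agreement with the real registry is out of reach by
construction and is not claimed anywhere.

A cohort is a flat table, one row per patient: demographics (age, sex),
tumor descriptors (primary site, *NUTM1* fusion partner, histology,
diameter, baseline metastasis), treatment-exposure flags (ever surgery /
radiation / chemotherapy), and two endpoints — overall survival (OS:
months + death indicator, mandatory) and event-free survival (EFS,
optional). Missing values are explicit (empty CSV cell / NaN); an
unidentified fusion is an observed state (`unknown_tested`, `not_tested`),
not a blank. The *analyzable* cohort keeps patients with known OS, known
primary site, and a BRD4, BRD3 or NSD3 fusion; rare ZNF fusions are
excluded, not pooled, mirroring the published model cohort of 124/141
patients.

## Synthetic cohort generator

Three latent risk groups with default proportions 12:45:67 (the published
group sizes). Each group's event-time law is Weibull,
S(t) = exp(−(t/λ)^k), with (k, λ) solved in closed form from the group's
two printed anchors (median OS m; survival s at the 24-month horizon):

    k = ln(ln s / ln ½) / ln(24 / m),    λ = m / (ln 2)^(1/k)

giving (k, λ) = (1.050, 51.7), (0.694, 16.95), (0.863, 6.73) for groups A
(36.5 mo, 64%), B (10 mo, 28%) and C (4.4 mo, 5%). A single exponential
cannot satisfy both anchors for groups B and C, which is why the
two-parameter family is the minimal adequate choice. Degenerate anchors
(s = 0.5, or survival above 0.5 past the median) are rejected.

Covariates are drawn conditionally on the group, using the published
group-by-characteristic fractions (site mix, sex, metastasis, size ≥6 cm,
histology). Group definitions are enforced: A and B are nonthoracic with
fusion in {BRD3, NSD3} and {BRD4} respectively; C is thoracic with an
unconstrained fusion mix. The thoracic fusion mix is not printed anywhere;
it defaults to BRD4 .79 / BRD3 .15 / NSD3 .045 / ZNF532 .0075 /
ZNF592 .0075, inferred from cohort-wide fusion totals minus the
nonthoracic counts, with the two rare ZNF fusions (2/127 registry-wide)
carried in this group since it is the only one whose definition permits
them. With the default missingness rates this puts the completeness
filter's expected retention at ≈ 0.886, matching the registry's 124/141.

Other generator choices:

* **Censoring** — administrative, uniform on [12, 96] months, independent
  of event times. The registry's true follow-up process (median 2.9 years
  among survivors) cannot be uniquely inverted from the printed summaries;
  a uniform accrual window is the standard neutral stand-in.
* **EFS** — progression time is Weibull with the group's shape and scale
  multiplied by `efs_scale` (default 0.71); EFS = min(progression, death,
  censoring). The default ratio places the overall EFS median below the OS
  median in the proportion of the published cohort-level medians
  (4.6 vs 6.5 months).
* **Missingness** — missing-completely-at-random per field at the
  registry's "unknown" fractions (age .12, size .39, metastasis .20,
  fusion .10, histology .02, site .007). MCAR keeps complete-case analyses
  unbiased, which the downstream analysis implicitly assumes; informative
  missingness is deliberately not modelled. OS is never masked. A masked
  fusion becomes `unknown_tested`/`not_tested` at the registry's 9:5 split.
* **Ages** — log-normal per group, matched to each group's median age and
  under-18 fraction; cosmetic for the tree (age is never selected by the
  calibrated signal) but keeps baseline tables realistic.
* **Tumor size** — the ≥6 cm indicator is drawn from the group
  conditional, then the magnitude uniformly within [0.4, 6) or [6, 16.2]
  cm (the registry's observed range): simplicity over realism, since only
  the dichotomy enters any model.

What the generator does **not** emulate: treatment effects are descriptive
covariates, not causal (surgery rates differ by site, inducing the
observed association without a treatment model); no informative censoring;
no within-group covariate–survival dependence. Consequently, passing
recovery tests show the pipeline recovers *its own* calibrated structure —
they say nothing about unmodelled real-data pathologies such as
informative follow-up or site-dependent data quality.

## Survival core

Kaplan–Meier, Cox and log-rank are implemented directly (numpy) because
they sit inside the tree search and the power loops; each is cross-checked
in the test suite against lifelines, closed forms, or brute-force oracles.

* **KM** — product-limit with Greenwood variance; pointwise 95% CI via the
  log(−log S) transform; median = first listed time with S ≤ 0.5, encoded
  `inf`/"NR" when unreached; median CI from the CI bands' threshold
  crossings (Brookmeyer–Crowley style), so an upper bound can itself be
  NR, as in the published "12.5 to NR".
* **Cox** — Newton–Raphson on the partial likelihood with step-halving.
  Efron tie handling is the default (months-resolution data tie heavily;
  Efron is the more accurate correction), Breslow available for
  cross-checks; the two coincide exactly without ties. Exact tied values
  are treated as ties — no jittering. Convergence: full Newton step below
  1e−9, or log-likelihood change below 1e−11. Constant covariates are
  errors; monotone likelihoods (risk-set separation, |β| > 18) are flagged
  `converged=False` with a diagnostic, never silently reported as
  estimates. P-values are two-sided Wald, matching the reporting
  convention of the source analysis; a score test at β=0 is exposed for
  the log-rank identity check.
* **Log-rank** — k-group hypergeometric observed-minus-expected with the
  usual variance (factor d(n−d)/(n−1), zero when n=1), chi-square on k−1
  groups; pseudo-inverse fallback for singular variance.
* **Fisher exact** — delegated to scipy.stats (two-sided by probability
  mass), validated against full hypergeometric enumeration for all small
  tables in the tests.

## Risk tree

Recursive dichotomization: at each node all eight candidate factors are
evaluated as univariate Cox dichotomies on the node's members,
complete-case *per factor*; a node splits on the eligible factor with the
lowest Wald p ≤ α (default .05) and recursion enters both children.
Stopping: fewer than `min_node` = 20 members (the gate applies to
*attempting* a split — children may be smaller, as in the published n=12
best-prognosis leaf), no significant factor, or no evaluable candidate.
Design points that were genuinely open:

* **Tie-breaking** on equal p: larger |ln HR| wins, then declaration
  order — any deterministic rule works; this one favours effect size.
* **Selection criterion** — `lowest_p` (default) or `strongest_hr`
  (largest significant |ln HR|); on calibrated cohorts both produce
  identical trees, reproducing the published robustness remark, and the
  equivalence is asserted over 20 seeds in the acceptance suite.
* **Missing split factor** — patients not evaluable on a chosen factor are
  excluded from both children and logged on the node, mirroring the
  varying per-factor denominators of the published univariate table;
  imputation or surrogate splits would go beyond the source procedure.
* **No multiplicity correction** — deliberate fidelity: the source
  analysis states it did not adjust for multiple testing. The measurable
  consequence (documented by the acceptance suite) is that a node with no
  true signal still splits with probability ≈ 1 − 0.95^c for c testable
  candidates (~26% at c = 6), so large-n trees usually carry spurious
  sub-splits below the two real ones. Structure-recovery checks therefore
  target the *site-then-fusion* top structure rather than an exact
  three-leaf tree, and the all-null "root stays a leaf in ≥90% of seeds"
  check fails honestly at the measured ≈66%.

Leaves are labelled A, B, C, … by decreasing KM median OS (ties by
24-month survival). Group summaries report KM median with CI, 24-month
survival with CI, and long-term survivors (observed time ≥ 36 months —
alive at 3 years regardless of later status).

## Multivariable models and power

Three fixed main-effects Cox specifications (site+metastasis, site+fusion,
site+fusion+metastasis) fitted on per-model complete cases; collinear or
within-sample-constant indicator sets are skipped with a reason. No
interactions, selection or penalization.

Validation power: a cohort of size n is simulated with complete site /
fusion / OS data (a prospective validation cohort requires these), group
proportions 12:45:67 and the calibrated Weibulls, censoring uniform on
[12, 96] months. The default criterion is *pairwise separation*: all three
pairwise log-rank tests p < .05 and observed KM medians strictly ordered
A > B > C (NR counts as infinite; an empty group fails). The stricter
*tree-recovery* criterion re-runs the tree search and requires the
site-then-fusion structure. The published simulation's exact predicate is
in unavailable supplementary material; pairwise separation is the most
direct reading of "validate the model", and the published 56%-power-at-124
figure is consequently not adopted as a target. Power estimates use 1,000
replicates by default (binomial SE ≤ 1.6 points at p = 0.8);
`minimal_validation_n` scans an ascending grid and returns the first n
meeting the target, or NOT_FOUND.

## Problem sizes and numerical conventions

Calibration-recovery checks use 50,000 uncensored draws per group (KM
median then resolves the anchors well inside 2% relative error);
structure-recovery uses 100 seeds at n = 5,000; null-behaviour checks use
200 seeds at n = 2,000; power uses 1,000 replicates at n = 198. Times are
months as decimals; probabilities are reported as percentages where the
registry tables print percentages; all randomness flows from explicit
integer seeds through `numpy.random.default_rng`, and every simulation in
the package is bit-reproducible given (config, seed).

## Known limitations

* Group-level calibration only: univariate hazard ratios of *secondary*
  factors (size, metastasis, treatment) emerge from the group mixture
  rather than being targeted, so they match the published table in
  direction but not magnitude.
* MCAR missingness and uniform censoring are simplifications; both are
  stated assumptions, not estimates.
* The tree is the published procedure exactly — no pruning or
  cross-validation — so its spurious-split behaviour at large n is a
  property of the method, faithfully reproduced rather than repaired.
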