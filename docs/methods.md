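# Methods

## The scale and its scoring rules

The NDS grades neurological dysfunction in dogs with meningoencephalitis
of unknown origin in seven ordinal categories, each 0 (normal) to 3
(most severe), summed to a total of 0–21. The engine treats the rubric
as a list of criteria rows per category and assigns **the
highest-severity row whose criteria the record satisfies** — the
worst-deficit rule standard in clinical grading. Consequences of that
rule: stupor, coma, compulsive circling or head pressing cap the
cerebral category at 3 regardless of accompanying disorientation,
obtundation or behaviour change; a one-level deficit in the milder triad
rates 1 and two or more rate 2.

Severity adjectives (mild/moderate/severe ataxia, "frequent falling")
are clinical judgements supplied as input fields. The engine combines
them but never re-derives them: subjective grading is exactly where
inter-rater variability originates, and the artifact's job is to record
and score, not to re-judge.

Decisions taken where the rubric is silent:

* **Moderate cerebellar ataxia without tremors** has no rubric row of
  its own (the mild row names mild ataxia; the 2-point row requires
  tremors; the 3-point row requires severe ataxia). It is graded 1, with
  mild ataxia: a literal no-row-satisfied → 0 reading would rank
  moderate ataxia below mild ataxia, violating monotonicity.
* **Pilot-scale binary items** (hyperesthesia, proprioceptive deficits —
  dropped from the final scale for poor reliability) contribute 1 point
  each when present. No point value is documented for them; the weight
  is an assumption and is configurable (`binary_weight`).
* **Per-eye menace**: one absent eye (other normal or reduced) and
  both-reduced both rate 2; the engine treats the eyes symmetrically.
* Record invariants enforced before scoring: stupor and coma are
  mutually exclusive; mild/moderate cerebellar ataxia requires truncal
  sway or hypermetria, severe requires any of tremors/sway/hypermetria.
  Violations are collected and reported per record, not raised one at a
  time.

Patients presenting **in status epilepticus** cannot be examined
(unconscious, recumbent, sedated); `apply_se_convention` assigns the
fixed sheet 3/3/3/3 in ambulatory, cerebral, visual and seizure, 0
elsewhere, total 12. It refuses records not flagged as in SE.

The scored sheet is a pure function of the record; the scale structure
(7 categories, range checks, total = sum) is re-validated on every sheet
construction.

## Agreement statistics

All agreement statistics are implemented from their defining formulas;
statsmodels, scikit-learn and pingouin serve only as independent
cross-checks in the test suite.

**Kappa.** For an L×L contingency table of two raters, weighted kappa is
`1 − Σw_ij o_ij / Σw_ij e_ij` with disagreement weights
`w_ij = |i−j|/(L−1)` (linear), `((i−j)/(L−1))²` (quadratic) or `1−δ_ij`
(identity, which reproduces unweighted Cohen's kappa exactly). The
default scheme for the ordinal 0–3 categories is **linear**, the
convention of the SPSS-era clinical literature; every result records the
scheme used. The 95% CI uses the Fleiss–Cohen–Everitt large-sample
variance with a normal interval, clipped to [−1, 1]; a seeded
multinomial bootstrap (`ci_method="bootstrap"`) is recommended below
roughly 30 subjects. Kappa is undefined when chance agreement is 1
(both raters constant at the same level); this raises
`UndefinedStatisticError` with the margins in the message.

**ICC.** Total scores use the two-way random-effects, absolute-agreement
model: subjects and raters both random, systematic rater offsets counted
as disagreement. From the two-way ANOVA mean squares (MSR subjects, MSC
raters, MSE residual),

    ICC(A,1) = (MSR − MSE) / (MSR + (k−1)·MSE + (k/n)·(MSC − MSE))
    ICC(A,k) = (MSR − MSE) / (MSR + (MSC − MSE)/n)

The CI is the McGraw–Wong F construction with Satterthwaite degrees of
freedom for A-1; A-k limits are the Spearman–Brown transform of the A-1
limits. The default measure form is **single**: with two assessors the
clinically relevant quantity is the reliability of one clinician's
score, not of their average. Published total-score ICCs cannot
adjudicate the form without the raw per-dog ratings, so both forms are
exposed. Negative estimates are reported as computed (banded "poor"),
never truncated at zero. Missing cells are deleted listwise per
statistic and the effective n is reported in the result's components,
alongside all mean squares for audit.

**Bands.** Kappa uses the Landis–Koch cut-points (≤0 none, then slight /
fair / moderate / substantial / almost perfect at 0.2 steps); the ICC
uses Koo–Li (<0.5 poor, 0.5–0.75 moderate, 0.75–0.9 good, >0.9
excellent). A value equal to a cut-point takes the higher band.
Cut-points are overridable.

## Outcome tests

All tests are two-sided (the clinical contrasts are non-directional).
Rank tests use midranks with tie-corrected variances, since NDS totals
are small integers and ties are certain.

* **Kruskal–Wallis** (NDS by good/fair/poor outcome): tie-corrected H;
  p from the chi-square approximation, from full enumeration of group
  assignments when pooled n ≤ 12, or from seeded Monte-Carlo
  permutation. All pooled values identical returns H = 0, p = 1.
* **Mann–Whitney** (NDS by survival to discharge, by relapse; time to
  relapse by response to rescue treatment): U counts pairs with the
  first sample larger, ties as ½. Exact p by enumeration of the
  C(n₁+n₂, n₁) assignments when pooled n ≤ 20 without ties (two-sided
  via symmetry of U about n₁n₂/2); otherwise the tie-corrected normal
  approximation with continuity correction (slightly conservative —
  exact null level 0.045 at n = 15 + 15, α = 0.05).
* **Pearson** (NDS vs ICU days): p via the t-transform on n − 2 df;
  permutation optional.
* **Power** is estimated by Monte Carlo against normal location-shift
  alternatives, with a Wilson interval for the simulation uncertainty.
  At zero shift it estimates the realized type-I error. A post hoc power
  of 0.18 was reported for the three-group outcome comparison in the
  original 27-dog follow-up cohort, but the underlying effect size was
  not published; `simulate_power` reproduces the procedure, not that
  number.

## The synthetic cohort generator

The generator defines the study conditions for all simulation-based
tests. Sign prevalences default to the 100-dog case-series values
(proprioceptive deficits 0.70 … tremors 0.10; see
`TABLE1_PREVALENCES`), and the 7-day seizure-history split among seizure
dogs to 10/35 controlled, 21/35 cluster/refractory, 4/35 status
epilepticus. Signs are drawn **independently** per dog — only marginal
prevalences were reported; an optional correlation structure is a listed
extension, off by default. Quantities the case series did not report are
fixed once at values plausible for a referral caseload and documented on
`CohortSpec`: the conditional severity mixtures (e.g. mild/moderate/
severe cerebellar ataxia at 0.50/0.30/0.20 given ataxia), the
persistent share of pathological nystagmus (0.40), the within-category
distribution of cranial-nerve deficits, and small prevalences for signs
below the series' reporting threshold (stupor 0.05, coma 0.02,
decerebrate rigidity 0.02, …). Consciousness level is a single
categorical draw, so stupor and coma cannot co-occur; graded ataxia is
always given a qualifying flag. Every generated record passes
validation, and the latent truth sheet is the deterministic score of the
noise-free record. Under the defaults the mean true total is ≈ 5.5,
within the range of, though below, the ≈ 8 reported at presentation in
the prospective cohort — unsurprising since severity mixtures are
assumptions and sign correlations are ignored.

**Rater noise** acts on category ratings, not raw findings: with
probability 1 − p_correct the rater errs by ±1 level (clipped at 0/3;
clipping at the boundary can return the true rating, so the effective
error rate is lower at the extremes) or uniformly over the other three
levels; an integer bias offset models a systematically harsh or lenient
assessor. Totals are recomputed from the perturbed categories, never
perturbed directly. Noise on the underlying findings themselves is a
listed extension.

**Outcome generation** draws good/fair/poor from an ordinal logit on the
true total with default slope 0 — reproducing a null score–outcome
association, with intercepts giving roughly the 8/8/11 split of the
follow-up cohort — and a positive-slope preset for power studies.

**Recovery experiment.** `recovery_experiment` maps rater accuracy to
expected agreement (mean total-score ICC and per-category linear
weighted kappa over replicate cohorts); the curve is monotone in
p_correct up to Monte-Carlo error. `find_noise_for_target_icc` bisects
p_correct until the mean 31-dog, 2-rater total-score ICC lands in a
target band, by default [0.80, 0.86]: this demonstrates that the
published good-agreement regime (total-score ICC 0.83 with 31 dogs) is
attainable under the simulator — an attainability statement, not a
recovery of the published value, which would require the unpublished
per-dog ratings.

## Numerical choices and problem sizes

* Enumeration thresholds: exact Kruskal–Wallis at pooled n ≤ 12
  (multinomial assignments), exact Mann–Whitney at pooled n ≤ 20 without
  ties; beyond these the asymptotic forms are used, with permutation
  available at any n.
* Comparisons of H-statistic permutations use a 1e-12 slack so midrank
  ties do not drop boundary assignments.
* ICC parameter-recovery checks average the estimate over replicate
  rater draws: with k = 2 the realized rater variance is a single
  χ²₁-distributed draw, so a lone simulation scatters (sd ≈ 0.05 at
  n = 5000) around the population value 4/(4+0.25+1) ≈ 0.762 even at
  large n. One hundred replicates bring the mean's sd below 0.006.
* Simulation sizes in the test suite — 10⁴ dogs for prevalence
  calibration, 10⁴ replicates for test-level calibration, 50 replicates
  of 31-dog cohorts inside the ICC bisection — were chosen so binomial /
  Monte-Carlo error is small against each tolerance while the full suite
  runs in well under five minutes.
* MSE is floored at 0 against floating-point cancellation in the ANOVA
  decomposition; a zero-total-variance matrix raises rather than
  returning a 0/0 ICC.

## Limitations

* The simulator reproduces marginal sign prevalences only; real MUO
  signs co-occur (multifocal disease), so simulated cohorts likely
  understate between-dog score variance. Passing calibration tests show
  the pipeline's statistics behave correctly under the stated generative
  model, not that the model captures real cohorts.
* Rater noise on ratings ignores the correlated, finding-level
  disagreement of real assessors (e.g. two raters disagreeing on the
  same borderline menace response across categories).
* The published per-dog ratings are not available, so the printed
  total-score ICCs (0.830 prospective, 0.843 retrospective, 0.706
  combined) are used only to anchor interpretation bands and the
  attainability band, never as recovery targets.
* The scale does not apply to dogs with spinal-cord-only presentations
  of meningoencephalomyelitis; no diagnosis (MRI/CSF/serology) or
  treatment logic is modelled.
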