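# Methods

## Model

`medpatterns` fits finite mixtures of independent Bernoulli distributions to
subject × item 0/1 matrices. A K-class model has parameters π (class
prevalences, K−1 free) and ρ (item-response probabilities, K·J free), so
p = K·J + (K−1). The two-phase latent transition model replaces π with an
initial distribution δ and adds a row-stochastic K×K transition matrix τ;
its parameter count is (K−1) + K(K−1) + K·J when the item-response
probabilities are constrained equal across phases (measurement invariance)
and (K−1) + K(K−1) + 2·K·J when they are free. δ and τ are free in both
models, so the invariance likelihood-ratio test has K·J degrees of freedom.

Key assumptions: items are conditionally independent given class; subjects
are exchangeable complete cases (no missing entries — rows with missing data
must be excluded before analysis); the two phases share one latent state
space of K classes; class transitions are first-order Markov. None of these
are tested by the package; they are the standard LCA/LTA working model.

## Estimation

EM in log space (log-sum-exp over classes, and over the K² joint states for
the two-phase model). Defaults and rationale:

- **Starts.** ρ initialized Uniform(0.2, 0.8) and π from Dirichlet(5·1):
  mild starts away from the boundary, 50 starts by default for a
  cross-sectional fit. The two-phase fit starts from the two phase-wise LCA
  solutions — classes matched across phases by solving the assignment
  problem on mean absolute profile difference — plus random restarts. The
  one-class MLE is closed-form, so extra starts are skipped.
- **Convergence.** Relative log-likelihood change below `tol` (default
  1e-8), capped at `max_iter` (5000 cross-sectional, 2000 two-phase). The
  log-likelihood is checked to be non-decreasing every iteration with
  tolerance 1e-9·(1+|ll|); a violation raises rather than returning a wrong
  fit. Simulation-scale fits inside the test-suite and acceptance script use
  `tol` 1e-6..1e-7 and fewer starts; at those settings every design below
  was verified stable.
- **Boundary handling.** ρ is clamped to [1e-6, 1−1e-6] so the likelihood
  stays finite; a class whose total posterior mass falls below 1e-8
  aborts the start (degenerate class) and the driver moves to the next
  start, erroring only if all starts degenerate.
- **Label switching.** Classes are reordered by descending prevalence
  (stable sort, ties to lower index) before a fit is returned, so the
  largest — low-medication-like — class is always class 0. Cross-phase and
  truth-vs-estimate comparisons re-match classes on item-response profiles,
  never on index.
- **Ties.** Modal assignment breaks posterior ties toward the lower class
  index.

## Fit statistics

G² is computed over the distinct *observed* response patterns,
2·Σ n_s ln(n_s/(N·P̂(s))) — the full 2^J contingency table is never formed.
AIC/BIC/CAIC/SABIC are the G²-based forms (AIC = G²+2p, BIC = G²+ln(N)p,
CAIC = BIC+p, SABIC = G²+ln((N+2)/24)p); the identities AIC−G² = 2p and
CAIC−BIC = p therefore hold exactly for every fit and are asserted in the
tests. N is the number of analyzed rows; no other effective-N convention is
applied. Relative entropy is 1 − Σ(−p ln p)/(N ln K), clipped to [0,1] and
undefined (NaN) for K = 1.

Both the K vs K+1 deviance test (df = J+1) and the invariance test use the
chi-square reference distribution. For the K vs K+1 comparison the smaller
model lies on the boundary of the parameter space, so chi-square regularity
is violated; the result object carries this caveat and the p-value should be
read as approximate. The invariance constraint is interior, and the test's
type-I error is verified by simulation to sit near the nominal 5%.

## Class labeling

An item is *high* for a class if ρ > 0.7 and *low* if ρ < 0.3; the closed
band [0.3, 0.7] is *moderate* (a probability of exactly 0.7 is moderate —
strictly-greater is the high rule). A class with every ρ below 0.06 is
labeled "Low medication". Otherwise the label joins the disease groups of
the class's high/moderate items in the fixed priority order HTN/CVD → T2D →
Hychol (yielding names like "HTN/CVD+T2D+Hychol predominant"); the
medication-to-disease map is a user-editable dictionary whose default covers
antihypertensives/cardiac drugs, diabetes drugs and lipid-lowering drugs.

## The synthetic-data generator

The generator draws phase-1 classes from π, phase-2 classes from τ rows, and
items as independent Bernoulli draws from the phase-specific ρ; comorbidity
flags are Bernoulli draws whose probability depends only on the latent
class. One explicitly seeded RNG stream per call; identical truth and seed
give bit-identical output.

The default COPDGene-like scenario uses the published study quantities as
its truth: N = 5564 subjects, 27 medication categories, four classes with
phase-1 prevalences (0.564, 0.124, 0.046, 0.266), the published signature
item-response probabilities per phase (e.g. ACE-inhibitor 0.9768 in the
phase-1 HTN/CVD class, beta-blocker 0.9817 in the phase-2 one), and the
published cross-phase row percentages as τ (rows renormalized to sum to 1).

The full 27-item response matrices are not published, so unlisted items need
a convention. A flat shared background was rejected on identifiability
grounds: it would leave the low-medication and Hychol-predominant classes
differing in the single statin item, and a two-component mixture on one
Bernoulli item is indistinguishable from a single Bernoulli — the split of
mass between those classes would be unrecoverable in principle. Instead each
class carries a small background graded by its medication burden (0.008 for
the low-medication class, 0.05 elsewhere), and the Hychol-predominant class
carries a handful of plausible secondary medications (other lipid-lowering
0.25, proton-pump inhibitor 0.18, NSAID 0.15, antihistamine 0.12, SSRI/SNRI
0.12, thyroid hormone 0.10) — all below the 0.3 labeling band, so labels are
unaffected. This calibration puts the fitted 4-class relative entropy on
synthetic cohorts at ≈ 0.78–0.80, close to the ~0.76 a comparable real
cohort shows, and makes all four prevalences recoverable (max-norm error
typically 0.01–0.025 at N = 5000; occasional ~0.05 excursions are sampling
variation in the weakly separated low-medication/Hychol split, not local
optima). Comorbidity links (hypertension, diabetes, high cholesterol,
cardiovascular disease) are class-conditional probabilities chosen so each
flag tracks the diseases its class's medications treat.

What the generator does **not** emulate: item dependence within class
(e.g. drug co-prescription beyond class structure), missingness and
loss-to-follow-up between phases, mortality, covariates, or drug-name-level
data. Passing tests therefore demonstrate correctness of the estimation and
reporting machinery under the working model, not robustness of LCA to
violations of conditional independence in real cohorts.

## Simulation designs in the test suite and acceptance script

Problem sizes were chosen to keep the whole suite at a few minutes on one
CPU while leaving each check well-powered:

- Oracle equivalence: brute-force enumeration on J ≤ 4, K ≤ 3, N ≤ 20
  instances, agreement to 1e-10.
- Parameter recovery: one N = 5000 cohort from the default scenario,
  4-class fit with 15 starts; matched-class π within ±0.03 and mean |ρ̂−ρ|
  below 0.05.
- Selection consistency: 20 replicates of a well-separated 4-class design
  (J = 12, block profiles with ρ ∈ {0.1, 0.9}, π = (0.4, 0.3, 0.2, 0.1),
  N = 3000), K swept over 2–6; BIC must pick K = 4 in ≥ 80%.
- Invariance-test calibration: 200 replicates (K = 2, J = 6, N = 1000,
  balanced classes, ρ rows 0.2/0.8, τ diagonal 0.8); type-I error within
  [0.02, 0.10] at nominal α = 0.05, and power above 0.9 when phase-2
  probabilities are shifted by 0.3 on half the items.
- Transition fidelity: one N = 5564 cohort from the published τ; every
  row percentage within 3 binomial standard errors of its generating value
  (< 1 point for the large rows; the smallest class row holds only ~256
  subjects, where one standard error on a 50% cell is 3.1 points).

## Known limitations

- No covariates on class membership or transitions; no mover–stayer or
  higher-order transition structure; two time points only.
- No missing-data handling: complete cases are a hard contract.
- The chi-square p-value for K vs K+1 enumeration is approximate (boundary
  problem); bootstrap LRTs are out of scope.
- Logistic associations are reported per comorbidity without a
  multiple-testing layer; complete separation is flagged (infinite
  odds-ratio marker), not resolved by penalization.
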