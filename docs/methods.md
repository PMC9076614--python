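# Methods

## The model

A subject's trial is a time-ordered sequence of fixations
$(x_t, y_t)$, $t = 1..T$, in screen pixels (origin top-left, y down,
default screen 1920×1080). We model it with a Gaussian-emission hidden
Markov model: hidden state $k \in \{1..K\}$ is a region of interest (ROI)
emitting fixations from $\mathcal N(\mu_k, \Sigma_k)$; the state sequence
is Markov with prior $\pi$ (where the first fixation lands) and
row-stochastic transition matrix $A$ (where gaze moves next, given where
it was). This captures both the spatial dimension of gaze (ROI placement)
and the temporal one (ROI order), which static heatmaps cannot.

### Fitting

- **Estimator.** Maximum-likelihood EM (Baum–Welch). The E-step uses the
  scaled forward–backward recursions with per-time-step max-shifting of
  log emission densities, so arbitrarily unlikely fixations cannot
  underflow. Likelihood evaluation (`log_likelihood`) and decoding
  (`viterbi_states`) are exact dynamic programs, tested against
  brute-force path enumeration on all small instances.
- **Initialization.** `n_restarts` (default 20) seeded k-means++ draws of
  the ROI means; shared data-covariance start for $\Sigma_k$; sticky
  uniform start for $A$. Equal-scoring restarts resolve to the lowest
  restart index, so a fixed seed gives a fully deterministic fit.
- **Model selection.** $K$ ranges over 1–4 by default (per-subject
  selection; group figures in this literature typically show ~3 ROIs, but
  no per-subject rule is standard). The fit score is BIC-penalized
  log-likelihood $\mathrm{LL} - \tfrac p2 \ln T$ with
  $p = (K{-}1) + K(K{-}1) + 2K + 3K$. Sequences shorter than $3K$ cap the
  candidate $K$ (logged).
- **Covariance floor.** Emission eigenvalues are clamped at $(5\,\mathrm{px})^2$:
  tighter ROIs are eye-tracker jitter, not structure, and the floor
  prevents likelihood blow-up on near-duplicate fixations.
- **Probability floor.** The *reported* prior/transition are floored at
  $10^{-2}$ / $10^{-3}$ and renormalized. ML estimates from a single
  sequence (one trial per subject, as in this design) otherwise collapse
  entries to exact zero, and a single first fixation on the "wrong" side
  then costs hundreds of nats in downstream model comparisons, corrupting
  E–F scales. EM itself remains a pure likelihood ascent; only the final
  model is regularized. (Variational-Bayes fitters never produce exact
  zeros, so this also matches the behaviour of the established EMHMM
  toolbox this pipeline is an alternative to.)
- **State order.** States are reported by descending stationary mass, a
  deterministic stand-in for the "by prominence" numbering conventional in
  figures.

### Stationary distribution and entropy

`stationary_distribution` returns the limiting time-average of
$\pi A^t$, computed by iterating the chain for a burn-in (default
$t_{\lim}/2$ of $t_{\lim}=1000$ steps) and averaging the remainder. The
time-average (Cesàro) limit is well defined for periodic and reducible
chains; the burn-in makes the result exact to machine precision for
ergodic chains and an even averaging window cancels period-2 oscillation
exactly. (A plain average from $t=0$ converges only at rate $1/t_{\lim}$
— about $10^{-4}$ error for mildly sticky chains — too coarse for the
closed-form checks in the test suite.)

**Overall entropy** is the stationary entropy rate of the hidden chain,
$H = -\sum_i \pi^*_i \sum_j A_{ij}\ln A_{ij}$ nats, with $0\ln 0 = 0$;
$0 \le H \le \ln K$, zero iff transitions are deterministic. It reads as
gaze (in)consistency: higher = more random ROI-to-ROI movement. The
alternative of adding Gaussian differential emission entropy is deliberately
not included: it mixes units (bits of choice vs px² of scatter) and the
transition-rate definition is the one that isolates *sequencing*
regularity. This is a definitional choice; no printed formula exists in
the literature this mirrors, so consumers comparing entropies across
toolboxes should compare within one definition only.

## Clustering subject HMMs

1. **Distance.** For subjects $i, j$ with models $M_i, M_j$ and sequences
   $s_i, s_j$: $d(i,j) = [\ell_i(s_i) - \ell_j(s_i)] + [\ell_j(s_j) -
   \ell_i(s_j)]$ with $\ell$ per-fixation log-likelihood — a symmetrized,
   length-normalized likelihood-ratio distance (clamped at 0).
2. **Initialize** with k-medoids on $d$.
3. **Iterate**: refit each representative by pooled EM on its members'
   sequences ($K$ selected as above), reassign each subject to the
   representative with the highest per-fixation log-likelihood (ties to
   Pattern 1), until assignments stabilize or 50 iterations. An emptied
   cluster is re-seeded with the worst-fitting subject.
4. **Best of `n_init`** seeded starts by total normalized log-likelihood.

Per-fixation normalization removes sequence-length bias from the
assignment; the E–F scale itself uses the raw log-likelihoods
$L_1, L_2$ (for a single sequence per subject the assignment argmax is
identical either way, so the E–F sign always agrees with the assignment).

**Orientation.** "Pattern 1 / explorative" is the representative with the
higher stationary between-image switching probability
$\sum_i \pi^*_i \sum_{j:\,\mathrm{side}(j)\ne\mathrm{side}(i)} A_{ij}$,
sides taken from ROI mean x vs the stimulus midline. This pins the
otherwise arbitrary cluster labels to the behavioural meaning
(explorative patterns transit between the images more).

This pooled-refit/reassign loop is an EM-flavoured alternative to
variational hierarchical EM over HMMs; it produces exactly the objects the
analysis consumes (representative HMMs, per-subject $L_1/L_2$,
assignments) with simpler, fully testable semantics.

## Fixed-ROI variant

Two elliptical ROIs are fixed on the tooth regions — ROI1 on the
no-diastema image, ROI2 on the diastema image. A drawn ellipse with
semi-axes $a, b$ and rotation $R$ is read as the 2-SD contour of its
Gaussian: $\Sigma = R\,\mathrm{diag}((a/2)^2, (b/2)^2)\,R^\top$. Every
fixation is assigned to the ROI with the higher log-density (equal
weights, ties to ROI1, no rejection class — distant fixations still go to
the nearest-by-density ROI). Priors are first-fixation indicators,
transitions are normalized bigram counts (unvisited rows set uniform and
flagged). Clustering reuses the refit/reassign loop with emissions frozen:
representatives are pooled-count priors/transitions, and "explorative" is
the representative with the higher mean off-diagonal switching.
**Gaze preference** is the fraction of fixations in ROI1, compared to the
0.5 no-preference point with a one-sample t-test.

Default ellipse geometry (tooth-centred, proportional to the image
rectangles) lives in the stimulus configuration; any reproduction against
recorded data must load the geometry actually used in that study.

## Pupillometry

Per sample, the diameter is invalid if tracker-flagged, non-physical
(≤ 0 mm or non-finite), off-stimulus, or jumping > 0.5 mm from the
previous usable sample (the blink/head-movement outlier rule; the 0.5 mm
threshold is configurable — no standard value exists). Diameters are
averaged in 300 ms bins time-locked to onset across the 10 s presentation
(trailing partial bin dropped); a bin is invalid if > 50% of its samples
are invalid. The response is
$100 \times (\max_b \bar d_b - \bar d_0)/\bar d_0$ — maximum *bin mean*
(not raw-sample max, consistent with the interval analysis) over the
first-bin baseline; it is never negative since the maximum includes the
baseline bin. A subject is excluded if the baseline bin is invalid or ≥ 3
consecutive bins are invalid anywhere in the trial.

## Statistics

Two-sample t (pooled df $= n_A + n_B - 2$, or Welch–Satterthwaite with
fractional df), one-sample t, one-way ANOVA (df $= (k-1, N-k)$) and
Pearson correlation with Fisher-z 95% CI, all two-tailed, computed via
scipy behind a uniform result type (statistic, df, p, mean difference ±
SEM, 95% CI). The variant is chosen per comparison (Welch for the pupil
contrasts, pooled elsewhere) and is overridable. No multiple-testing
correction is applied, matching the analysis convention this mirrors; the
report notes this. A zero-variance one-sample test at the null is defined
as $t = 0, p = 1$ rather than NaN.

Heatmaps are isotropic Gaussian kernel densities (default bandwidth
50 px) on a screen-shaped grid, normalized to unit mass over the grid.

## Synthetic cohorts

The generator emulates a single ~10 s trial of two side-by-side face
images (diastema right), subjects drawn from two archetypes and jittered
individually:

| parameter | default | why |
|---|---|---|
| explorative archetype | 3 ROIs: broad both-images + two circumoral; $\pi = (.42, .28, .30)$; dwell .63 / switch .37 between circumoral ROIs | matches the qualitative explorative pattern: broad looking, frequent between-image transits |
| focused archetype | 2 tight tooth ROIs; $\pi = (.51, .49)$; self-transitions .83 / .75 | matches the focused pattern: precise tooth ROIs, long dwells |
| fixations per trial | uniform 15–35 | ~25 ± 10 fixations in 10 s at typical child fixation durations |
| fixation durations | uniform 100–600 ms, onsets cumulative, truncated to the trial | no duration model is reported for this paradigm; this spans the plausible range |
| per-subject jitter | means ± 20 px; covariances × $e^{\mathcal N(0, 0.1)}$; transition rows ~ Dirichlet(60 × row) | the analysis presumes individual differences around group patterns |
| pupil trace | 60 Hz, 3 mm baseline, flat first 300 ms, smoothstep ramp to a plateau at the target % by 2.5 s, Poisson blinks (0.2/s, 100–300 ms), noise 0.002 mm | baseline and blink statistics typical of screen-based child recordings; the plateau makes the target % the exact max-bin response |

The per-sample noise (0.002 mm) is deliberately far below real
pupillometer noise: the trace generator is a closed-loop probe of the
binning/response arithmetic, not a noise model. Likewise the generator
omits saccade kinematics, salience-driven content effects, head movement
and calibration drift — so passing closed-loop tests demonstrates the
*pipeline arithmetic and recovery behaviour*, not robustness to every
artefact of real recordings.

Determinism: all randomness flows from one `numpy` generator seeded by the
cohort seed; identical spec + seed gives byte-identical CSVs, and the full
pipeline bundle is byte-identical across runs at a fixed seed.

## Validation conditions

Test and validation problem sizes are chosen so each check is
well-powered at its stated tolerance:

- Forward-likelihood exactness: every $K \le 3$, $T \le 6$ combination,
  randomized models, vs brute-force enumeration at $10^{-9}$.
- Parameter recovery: 20 replicates of $T = 500$ fixations from a sticky
  well-separated 2-state HMM ($A = [[.9, .1], [.1, .9]]$, ROI sd 20 px,
  deterministic start state — the center-fixation-start convention). At
  this $T$ the 0.05 entry-wise tolerance is ≈ 2.5 standard errors for the
  off-diagonals; flatter rows or broader ROIs make the tolerance
  unattainable for any estimator at $T = 500$, which is a sampling-theory
  fact, not an estimator deficiency. A non-degenerate prior is likewise
  unidentifiable from one sequence (one initial state observation), hence
  the deterministic start.
- Pattern recovery: the default 20 + 20 cohort, ARI ≥ 0.9 and 100% E–F
  sign agreement.
- Closed loops: pupil 0% / 10% targets recovered within 0.1 / 0.5;
  fixed-ROI regime separation on directly generated high-switch vs
  high-dwell label chains; gaze-preference group means within 0.03 on
  long-trial archetypes with known stationary occupancy.

## Known limitations

- The estimator is EM + BIC, not the variational-Bayes hierarchical EM of
  the established MATLAB toolbox; numeric outputs (especially entropy,
  which that toolbox defines differently) are not interchangeable across
  toolboxes even on identical data.
- One sequence per subject limits prior estimation (see above); designs
  with repeated trials should pass all sequences to `fit_subject_hmm`.
- Hard classification in the fixed-ROI variant ignores classification
  uncertainty near the midline.
- The entropy measure summarizes the *hidden* chain; two subjects with
  identical transition structure but different ROI sizes get the same
  entropy.
- Group comparisons assume approximate normality within groups; no
  non-parametric fallback is provided.
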