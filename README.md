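# gazehmm

Eye-movement analysis with hidden Markov models (EMHMM-style), built for
studies that ask *where* and *in what order* people look — here, the
paradigm of viewing two side-by-side face images, one with and one without
a midline diastema (a gap between the upper central incisors), with young
children and adult educators as the populations of interest.

## What it computes

**Per-subject HMMs (data-driven ROIs).** Each subject's fixation sequence
$(x_t, y_t)_{t=1..T}$ is modelled by a hidden Markov model whose hidden
states are that subject's regions of interest. State $k$ emits fixations
from a 2D Gaussian $\mathcal N(\mu_k, \Sigma_k)$; the gaze moves between
ROIs with a row-stochastic transition matrix $A$ and starts from a prior
$\pi$. Fitting is Baum–Welch EM with seeded k-means++ restarts; the number
of ROIs is selected by BIC, $\mathrm{LL} - \tfrac{p}{2}\ln T$.

**Pattern clustering.** Subjects' HMMs are clustered into representative
eye-movement patterns (default two): k-medoids initialization on a
symmetrized likelihood distance, then alternating pooled refits of each
representative and likelihood-based reassignment. Pattern 1 is oriented to
be the *explorative* pattern — the representative with the higher
stationary probability of switching between the two images; Pattern 2 is
the *focused* pattern. Each subject gets

- the **E–F scale** $(L_1 - L_2)/(|L_1| + |L_2|) \in [-1, 1]$, where
  $L_1, L_2$ are the subject's data log-likelihoods under the two
  representatives (positive = more explorative-like), and
- **overall entropy**, the stationary entropy rate of the hidden chain
  $H = -\sum_i \pi^*_i \sum_j A_{ij} \ln A_{ij}$ in nats (higher = less
  consistent gaze).

**Fixed-ROI variant.** Two investigator-defined elliptical ROIs on the
tooth regions (the drawn ellipse is the 2-SD contour of a Gaussian;
ROI1 = image without diastema). Fixations are hard-classified by Gaussian
likelihood, priors and transitions are estimated by counting, subjects are
clustered on their transition behaviour, and **gaze preference** — the
fraction of fixations in ROI1 — is tested against the 50% no-preference
point.

**Pupillometry.** Pupil diameters are cleaned (blinks, dropouts, >0.5 mm
jumps), averaged in 300 ms bins over the 10 s presentation, and summarised
as the percentage increase of the maximum bin mean over the first-bin
baseline; subjects with an invalid baseline or ≥ 3 consecutive invalid
bins are excluded.

**Synthetic cohorts.** `gazehmm.synthetic` generates full datasets
(fixation CSV, pupil CSV, metadata CSV, truth manifest) from explorative /
focused archetype HMMs with per-subject jitter, so every stage can be
validated closed-loop against known ground truth without any recordings.

## Worked example

```python
import numpy as np
import gazehmm as g
from sklearn.metrics import adjusted_rand_score

spec = g.CohortSpec(n_explorative=20, n_focused=20, seed=7)
cohort = g.generate_cohort(spec)

models = [g.fit_subject_hmm(s, k_range=(1, 2, 3, 4), n_restarts=10, seed=100 + i)
          for i, s in enumerate(cohort.sequences)]
cl = g.cluster_hmms(models, cohort.sequences, n_clusters=2, n_init=2,
                    seed=11, layout=spec.layout)

truth = [cohort.truth["subjects"][s.subject_id]["archetype"]
         for s in cohort.sequences]
print("ARI vs truth:", adjusted_rand_score(truth, cl.assignment))
print("pattern sizes:", np.bincount(cl.assignment))
print("mean E-F (explorative):", np.mean(cl.ef[cl.assignment == 0]).round(3))
print("mean E-F (focused):   ", np.mean(cl.ef[cl.assignment == 1]).round(3))
print("mean entropy:", np.mean([g.overall_entropy(m) for m in models]).round(3))
```

prints

```
ARI vs truth: 1.0
pattern sizes: [20 20]
mean E-F (explorative): 0.337
mean E-F (focused):    -0.068
mean entropy: 0.436
```

— the clustering recovers the two generative archetypes exactly, subjects
assigned to Pattern 1 have positive E–F values (their data are better
explained by the explorative representative) and vice versa, and the mean
hidden-chain entropy sits well below the 2-state maximum ln 2 ≈ 0.693,
i.e. gaze dynamics are fairly predictable.

The same analysis is available from the shell:

```bash
gazehmm simulate --out data/ --seed 7
gazehmm fit --fixations data/fixations.csv --out models.json --seed 7
gazehmm cluster --models models.json --fixations data/fixations.csv --out clusters.json
gazehmm fixedroi --fixations data/fixations.csv --out fixedroi.json
gazehmm pupil --pupil data/pupil.csv --out pupil.json
gazehmm report --out results/ --seed 7        # full pipeline
```

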