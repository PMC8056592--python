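# Methods

`longicluster` identifies genes whose longitudinal expression trajectories
separate treatment responders from non-responders, and estimates how
predictive the resulting signature is. This note records the model, the
defaults and the design choices a maintainer would want to know.

## The multi-view latent-variable model

A longitudinal study measures the same subjects at several time points. We
treat each time point's genes × subjects matrix as one *view* of the cohort
and couple the views through a shared subject-level latent score:

    x_it = W_t z_i + ε_it,   z_i ~ N(0, I_q),   ε_it ~ N(0, diag(ψ_t))

where `x_it` is subject *i*'s (standardized) expression vector in view *t*,
`W_t` the view's loading matrix and `ψ_t` diagonal residual variances.
Because the views are conditionally independent given `z_i`, row-stacking
them yields one ordinary factor-analysis model with diagonal noise; we fit
that stacked model by EM. With `K` clusters the latent dimension is
`q = K − 1`; the binary response question uses `K = 2`, so each subject gets
a single latent score and clusters come from those scores.

Implementation details:

- **E-step / M-step** are the standard factor-analysis updates; the
  observed-data log-likelihood is evaluated through the Woodbury identity so
  the per-iteration cost is `O(p·n·q)`, which is what makes fitting tens of
  thousands of small models affordable.
- **Initialization** is deterministic: loadings start from the top-`q` left
  singular vectors of the stacked matrix scaled by `s/√n`, residual
  variances start at 1. Deterministic initialization makes every fit, and
  therefore every ensemble, exactly reproducible from its seed.
- **Soft-thresholding.** After each M-step the loadings can be shrunk
  elementwise by `sign(w)·max(|w| − λ, 0)`, driving small coefficients to
  exact zero (feature selection). The ensemble below runs with `λ = 0`
  because each weak learner already sees only 20 genes.
- **Convergence.** With `λ = 0` we stop when the relative log-likelihood
  change falls below `tol` (default 1e-6; the trace is provably
  non-decreasing). Shrinkage breaks likelihood monotonicity, so with
  `λ > 0` the criterion is the max elementwise loading change. `max_iter`
  defaults to 200; non-convergence is flagged, not raised.
- **Numerical floors.** Residual variances are clamped at 1e-4 to prevent
  Heywood collapse; a gene row with sample variance below 1e-8 is centered
  but not divided during standardization (z-scoring uses the sample sd,
  ddof = 1).
- **Cluster labels.** Subjects are clustered on their posterior latent
  means. In one dimension (the `K = 2` case used throughout) the optimal
  k-means partition is contiguous in sorted order, so we solve it exactly by
  dynamic programming — deterministic and globally optimal, no restarts
  needed. In higher dimensions we fall back to seeded k-means with 10
  restarts. If all latent scores coincide (e.g. total shrinkage) the fit is
  flagged degenerate and everyone lands in one cluster.

## The random-subspace ensemble

A single unsupervised fit on all genes is noisy: every gene contributes to
the latent score, informative or not. The ensemble addresses this:

1. Draw `m = 20` genes uniformly without replacement (each replicate uses an
   independent, counter-based substream of the master seed, so replicate
   *r* is reproducible in isolation).
2. Fit the model above on those genes' views (`λ = 0`, `K = 2`).
3. Map the two clusters onto responder / non-responder by whichever of the
   two possible mappings agrees better with the labels (exact ties: the
   cluster with more responders, then the lower cluster id, maps to
   responder). The agreement is the learner's *accuracy*.
4. Keep the learner iff accuracy is strictly greater than the cutoff
   (default 0.75).
5. Every kept learner votes each subject's class; a strict majority wins
   and an exact tie predicts non-responder (the conservative clinical
   default; both the tie rule and voting over all replicates instead of
   kept ones are flags).
6. Gene importance: `score(g) = Σ_kept Σ_t |W_t[g]|` — summed, not maxed,
   over views so that genes with subtle but consistent loadings across time
   points are not missed (a max-variant is available behind a flag, as is
   sampling-frequency normalization). The signature is the top-k genes by
   score, ties broken lexicographically.

Defaults are 10,000 replicates, subset size 20, cutoff 0.75, `k = 20`.

A note on the vote accuracy: it is an *in-sample* quantity. Because
learners are kept by their agreement with the same labels the vote is then
scored against, the filtered vote accuracy is upward-biased — under
label permutation the few chance-passing learners still vote "correctly"
~77–87% of the time. Honest predictive performance therefore comes from the
nested LOO protocol below, and null calibration of the voting machinery is
done with the filter disabled.

## Evaluation harness

- **Pseudo-genes.** Longitudinal profiles are collapsed to one covariate per
  gene: the subject's mean expression over the early lesional time points
  (default LS0, W1, W2, W4 — the same four views the ensemble uses).
  Missing cells are averaged over the available time points.
- **LOO SVM.** Radial-basis SVC, cost 1, kernel width `1/(k·Var)` (the
  `gamma="scale"` convention, matching the common default of e1071-style
  implementations); a linear kernel is a flag away. Features are
  standardized with training-fold statistics only; the held-out subject is
  transformed with those same parameters, so no leakage.
- **Nested LOO.** Inside each fold the views are rebuilt and re-standardized
  on the n−1 training subjects, the whole ensemble is rerun (fold-specific
  seed substream), the top-k genes are selected, and only then is the
  held-out subject predicted. Per-fold replicates default to 2,000, which
  keeps a 30-subject run to a few minutes on one core while leaving the
  kept-learner count in the hundreds; 10,000 matches a production-scale
  run and does not change the ranking behavior, only its variance.
- **Random-gene baseline.** Mean LOO accuracy of `n_sets = 1000` random
  k-gene lists — the number a useful signature has to beat.
- **Trajectories.** For each gene and response group, mean expression (with
  n and SEM) per time point, plus the non-lesional reference mean. The
  *gap-closure ratio* `|mean(to) − NL| / |mean(from) − NL|` quantifies
  recovery: 0 = fully back to the healthy level, 1 = no movement; a
  starting gap below 1e-8 is reported as undefined rather than divided.

## Comparator selectors

- **Single fit:** the latent-variable model once on all genes, ranked by
  summed absolute loadings — identical to a one-replicate, full-subset,
  unfiltered ensemble (and tested to be so).
- **LASSO ensemble:** the same subsampling design with an L1-penalized
  logistic weak learner on pseudo-gene covariates, subset size 100; scores
  accumulate absolute coefficients (raw coefficients behind a flag). The
  penalty is chosen per replicate by 3-fold cross-validated deviance; a
  fixed-penalty mode is exposed. Plain LASSO on all genes at once tends to
  select almost nothing at these sample sizes, which is why the ensemble
  variant is the interesting comparator.

## Synthetic data generator

The generator emulates a two-tissue treatment time-course: a healthy
(non-lesional, NL) reference sample per subject plus lesional samples at
increasing times after treatment start. For informative gene *g* with
healthy mean `μ_g ~ U(5, 10)` (log2 scale) and displacement
`δ_g = ±U(1.5, 2.5)`:

- responders: lesional mean `μ_g + δ_g · r^t` at step *t* (geometric return
  to the healthy level, rate `r`, default 0.5 — chosen to produce the
  marked week-4 gap closure characteristic of treatment response; a linear
  recovery mode exists);
- non-responders: `μ_g + δ_g + drift·t` (default drift 0, a flat lesional
  trajectory);
- non-informative genes follow one common law for both groups.

Noise is a per-(gene, subject) random intercept (sd 0.3) shared across time
points — inducing the within-subject correlation longitudinal data actually
has — plus i.i.d. residual noise (sd 0.5). The *reference scenario* used
throughout the tests fixes 30 subjects (15/15), 300 genes with 20
informative, the parameters above, time points (NL, LS0, W1, W2, W4) and
seed 20210420.

What the generator does **not** emulate: probe/batch effects and
normalization residue, heavy-tailed noise, gene–gene correlation beyond the
planted factor, dropout/missingness patterns, and treatment-arm
heterogeneity. Passing recovery tests on this generator shows the machinery
is correct and well-calibrated under its assumptions — not that real
cohorts of this size will reach the same accuracies.

## Problem sizes used in the checks

The end-to-end checks run the reference scenario with 2,000 ensemble
replicates (also per LOO fold), five algorithm seeds for gene recovery and
three for the LOO protocols, and 200–1,000 random-gene sets — sizes chosen
so the full suite completes in minutes on a single core while leaving all
measured quantities far from their decision thresholds.

## Known limitations

- Latent dimension is tied to the cluster count (`q = K − 1`); no separate
  tuning.
- The accuracy filter makes in-sample vote accuracy optimistic (see above);
  report nested LOO numbers.
- `λ` selection (BIC/deviance tuning) is out of scope; the ensemble design
  deliberately runs unpenalized weak learners.
- Subjects missing any cell at a used time point are dropped entirely from
  the views (the only policy that keeps views aligned); missingness at
  unused time points is ignored.
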