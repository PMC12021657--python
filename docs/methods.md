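# Methods

## Problem and model

Structure-based virtual screening ranks compounds by a docking score (an
energy-like value in kcal/mol; lower is better). At ultralarge library
scale, docking every compound is infeasible, so `cpscreen` trains a
classifier surrogate on a docked training subset and uses it to triage the
rest of the library. The statistical core is an **aggregated Mondrian
inductive conformal predictor (CP)**:

1. **Labeling.** The top-scoring fraction of the docked training set
   (default 1%) defines the "virtual active" class. The threshold is the
   score at 0-based index `floor(f*N)` of the ascending sort; only
   compounds *strictly better* than it are actives, so ties at the boundary
   fall to the inactive class and the realized active fraction never
   exceeds `f`. "Virtual" is deliberate: no experimental activity is
   implied, the labels compress the docking function.
2. **Ensemble.** The labeled set is split `k = 5` times (stratified,
   independent derived seeds `seed + i`) into 80% proper-training / 20%
   calibration parts. One binary classifier per split is fit on the proper
   part only.
3. **Calibration.** The nonconformity of a compound for hypothesized class
   `c` is `1 - p_hat(c|x)`. Calibration is *class-conditional* (Mondrian):
   each member keeps two sorted score lists, one per true class, so the
   error guarantee covers the ~1% active minority, not just the average.
4. **p-values.** For a test compound each member reports, per class,
   `p = (#{calibration scores >= alpha} + 1) / (n + 1)` — the non-smoothed
   rank p-value. The deterministic variant was chosen over tie-randomized
   smoothing so that repeated runs with one seed give bit-identical
   predictions; the cost is slight conservatism (error rates land at or
   below the nominal level). The `k` per-class values are aggregated by
   coordinate-wise median (even `k`: mean of the central pair).
5. **Prediction sets.** At significance `eps`, class `c` is included iff
   `p_c > eps` (strict, so `eps = 0` gives `both` for every compound).
   The four outcomes are `active`, `inactive`, `both`, `null`. Under
   exchangeability, the probability that the true class is missing from
   the set is at most `eps` per class.
6. **Working significance.** `eps_opt` maximizes efficiency — the fraction
   of single-label predictions — over a uniform grid (step 0.01, ties to
   the smaller value). Compounds are then prioritized for explicit docking
   by the quality of information `q = P1 - P0`, or for multi-target work by
   `sum_t (P1_t - P0_t)` over targets, or by summed per-target docking
   ranks once docking results exist.

## Evaluation semantics

A compound errs iff its true class is absent from its prediction set:
`both` never errs, `null` always errs. The reported metrics are
sensitivity `TP/AP`, precision `TP/(TP+FP)`, efficiency
`({1}+{0})/(AP+AN)`, overall error `(FP+FN)/(AP+AN)`, and per-class error
rates `FN/AP`, `FP/AN`. **Caution:** `FP` here counts true inactives in the
predicted-active *or null* sets — not the conventional contingency-table
FP — so precision drops whenever the null set is populated. Ratios with
empty denominators are reported as missing, never coerced to 0.

## Classifier backend

The default backend is scikit-learn's `HistGradientBoostingClassifier`
(100 iterations, learning rate 0.1, 31 leaf nodes, early stopping off for
determinism) with inverse-class-frequency (`balanced`) weighting for the
~1:99 imbalance. The backend is pluggable (`logistic` for fast linear
fits, `lightgbm` where installed, or any object with
`fit`/`predict_proba`); conformal validity does not depend on backend
quality — only the sharpness of the triage does.

## Synthetic screens

The feature-mode generator draws i.i.d. compounds whose fingerprint-like
bits carry latent structure: `n_latent = 16` contiguous bit-clusters
(1024 bits total) co-activate as units with per-cluster activation
probabilities U(0.05, 0.3); active clusters light their bits with
probability 0.85 vs 0.03 otherwise. A fixed N(0,1) weight per cluster maps
activations to a standardized latent "druggability", and

    score = -30 - 10 * (signal_strength * latent + N(0, noise_sd))

with `signal_strength = 1.0`, `noise_sd = 0.3` — the latent then explains
roughly 90% of score variance, a learnable-but-noisy surrogate for the way
docking scores correlate with substructure content. The -30/10 affine map
is cosmetic (scores land in a docking-like -60..0 kcal/mol range); all
logic is affine-invariant. Because rows are i.i.d., any train/test split
is exchangeable by construction — the assumption CP validity rests on.

What the generator does *not* emulate: real fingerprint sparsity patterns,
activity cliffs, analog series, assay or forced-protonation artifacts, and
the covariate shift between a training sample and a differently-assembled
ultralarge library. Passing tests therefore demonstrate the statistical
machinery (validity, calibration, ranking arithmetic) and the end-to-end
plumbing, not chemistry-transferable accuracy.

Molecule mode enumerates valid SMILES from a fixed grammar of six
disubstituted aromatic scaffolds x 20 substituents (2,400 molecules) and
scores each as `-30 - bits @ w + noise`, with `w` a fixed N(0, 0.25)
per-bit weight vector independent of the library seed. It exists to
exercise the full SMILES -> filter -> fingerprint -> score-table path, not
to emulate make-on-demand library scale.

## Problem sizes

Benchmark-scale checks use a 100k-compound screen (50k train / 50k test,
1% actives, `k = 5` boosted members); that fit takes a few minutes on one
CPU. Unit-level statistical checks use 3k/3k screens with a 5% active
fraction and the logistic backend, which keeps per-class calibration sets
large enough (>= 100 actives) for meaningful p-value resolution at small
sample size.

## Numerical and design choices

- **Tie handling** at the labeling threshold: ties are inactive (strict
  "better than"), which changes active counts on discretized scores.
- **Score direction** is configurable (`lower_is_better`); docking
  energies default to lower-is-better.
- **Split guard:** stratified planning requires at least `2k` members per
  class — a conservative bound that guarantees every one of the `k`
  splits holds both classes in both parts.
- **Filter strictness:** rule-of-four bounds are strict (MW < 400,
  cLogP < 4); lead-like bounds are inclusive (20 <= HAC <= 25,
  -5 <= cLogP <= 3.5). The cLogP is RDKit's Crippen atom-contribution
  estimate; other estimators shift boundary-case membership slightly.
- **Ranking tie-breaks** are by identifier (lexicographic), making every
  ranking a pure function of its input table.
- **Multi-target ranking** is restricted to the intersection of the
  per-target tables; missing compounds are logged and excluded.
- **Scaffold definition** for diversity reporting: Bemis-Murcko framework
  (ring systems plus linkers, atom/bond types retained).
- **Serialization:** a predictor bundle is a directory of per-member
  joblib model files plus a JSON manifest holding calibration scores at
  full precision; a reloaded bundle reproduces p-values bit-exactly.
- **Streaming prediction** processes libraries in chunks (default 100k
  compounds), keeping peak memory independent of library size.

## Known limitations

- The single-label active set `{p1 > eps, p0 <= eps}` is *not* guaranteed
  monotone in `eps`. It grows with `eps` while the `p0` gate dominates and
  shrinks once the `p1` gate starts removing borderline compounds; with a
  sharp backend and small calibration sets the peak sits near `eps_opt`.
  In practice the workflow only tightens `eps` downward from `eps_opt`,
  where the shrinking behavior holds; the guaranteed monotonicities are
  those of the `both` (shrinks) and `null` (grows) sets.
- Median aggregation of member p-values preserves validity only
  approximately; empirically the per-class error rates track `eps`
  closely, and the test suite allows the ensemble twice the single-model
  binomial band.
- With `n_c` calibration compounds of a class, p-values are multiples of
  `1/(n_c + 1)`; tiny calibration sets make small significance levels
  unreachable (e.g. `p0 < 0.01` needs at least 100 calibration inactives).
- Featurization failures are excluded (and logged) rather than imputed;
  heavily corrupted inputs shrink the effective library silently except
  for the warning counts.
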