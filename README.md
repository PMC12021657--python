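# cpscreen

Conformal-prediction triage of ultralarge virtual screening libraries.

Structure-based docking screens of make-on-demand chemical libraries now
face billions of candidate compounds, far more than any docking engine can
score explicitly. `cpscreen` is for computational chemists who want to dock
a small training sample, train a classifier surrogate on the resulting
scores, and use **confidence-calibrated** predictions to decide which sliver
of the remaining library is worth docking at all.

## The statistic at the core

Docking scores (kcal/mol, lower = better) from the training sample are
thresholded at the top-scoring 1% into *virtual actives* (1) and *virtual
inactives* (0). Five gradient-boosted classifiers are trained on independent
stratified 80/20 proper/calibration splits and wrapped as a **Mondrian
(class-conditional) inductive conformal predictor**: each member assigns a
test compound per-class p-values

    p_c = ( #{ calibration alphas of class c  >=  alpha_c(x) } + 1 ) / (n_c + 1),
    alpha_c(x) = 1 - p_hat(c | x),

and the ensemble takes the median (P1, P0) pair. At a significance level
epsilon, class c enters the prediction set iff p_c > epsilon, giving a
four-way assignment — `active`, `inactive`, `both`, `null` — with the
guarantee (under exchangeability) that each class's error rate stays below
epsilon. Compounds are then prioritized for explicit docking by the quality
of information `q = P1 - P0`, or across targets by summed quality or summed
docking ranks (polypharmacology). Evaluation includes sensitivity,
precision, efficiency, per-class error rates under conformal error
semantics, calibration curves, recall-of-top-N enrichment curves and
Tanimoto / Bemis-Murcko diversity reports.

See `docs/methods.md` for assumptions, parameter defaults and limitations.

## Worked example

No docking engine is needed to try the workflow end to end — the built-in
simulator writes a standard score table (`id,smiles,score`):

```sh
cpscreen simulate --n 2000 --seed 5 --out screen.csv
cat > config.yaml <<EOF
paths:        {scores: screen.csv, output_dir: out}
labeling:     {top_fraction: 0.01}
ensemble:     {k: 5, seed: 1}
conformal:    {epsilon: auto}
prioritization: {mode: quality, top_k: 200}
fingerprint:  {radius: 2, n_bits: 1024}
EOF
cpscreen run config.yaml
```

which prints

```
INFO cpscreen: epsilon auto -> eps_opt = 0.200
run complete: artifacts in out (epsilon 0.200)
```

`out/training_report.json` records the labeling threshold (-32.69 kcal/mol
here) and the forced class sizes — exactly `floor(0.01 * 2000) = 20`
virtual actives, because scores are untied and boundary ties go to the
inactive class. `out/pvalues.csv` holds one `(P1, P0, set)` row per
compound, `out/ranked_selection.csv` the 200 compounds with the highest
`P1 - P0`, and `out/recall_checkpoints.csv` the fraction of the true
best-scoring compounds already recovered after 1/3/5% of the ranked list.
Evaluating the predictions against the docking truth:

```sh
cpscreen evaluate out/pvalues.csv screen.csv --out-dir eval
```

```
epsilon 0.200: sensitivity 1.000, efficiency 0.870, overall error 0.176
```

reads: at the efficiency-optimal significance, every true virtual active is
still inside its prediction set (sensitivity 1.0), 87% of compounds got a
useful single-label prediction, and 17.6% of compounds had their true class
missing from the set — at or below what the chosen significance tolerates.
(This demo is deliberately tiny; with realistic training sizes the optimal
significance drops to the few-percent range and the error rate with it.)

The same pipeline is scriptable without the CLI:

```python
from cpscreen import (SyntheticScreenConfig, generate_screen,
                      compute_score_threshold, assign_labels, ScoredLibrary,
                      make_split_plan, fit_conformal_ensemble, predict_pvalues)
```

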