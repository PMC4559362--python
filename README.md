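# tcellfate

Surrogate regression emulators for the steady-state cytokine behavior of a
kinetic model of CD4+ T helper cell differentiation.

## The problem

Mechanistic ODE models of CD4+ T cell differentiation capture how the
cytokine milieu (IFNγ, IL-12, IL-6, TGFβ) drives naïve cells toward the
Th1, Th17 or induced-Treg fates, but they are far too expensive to embed
inside agent-based multiscale tissue simulations, where every simulated
cell would otherwise carry its own ODE system.  A practical reduction is
to learn only the input → output map of the intracellular model,

    {C_o1, …, C_o5} = F(C_i1, …, C_i4),

i.e. to predict the five steady-state readouts — IL-17, RORγt, secreted
IFNγ, T-bet, FOXP3 — directly from the four input cytokine levels with a
fast statistical surrogate.

`tcellfate` provides the whole benchmark pipeline for this reduction:

* **`tcellfate.kinetics`** — a reduced five-state kinetic model (Hill
  activation/repression, first-order mass-action decay, mutual inhibition
  of the master regulators T-bet / RORγt / FOXP3) that produces the
  steady-state training data.  TGFβ alone drives FOXP3; TGFβ + IL-6 drive
  RORγt and IL-17 while suppressing FOXP3; IFNγ / IL-12 drive T-bet and
  secreted IFNγ.
* **`tcellfate.dataset`** — full-factorial "equal-distance" grid scan
  (5 levels per input → 5⁴ = 625 points), min-max normalization to [0, 1],
  relative uniform output noise, random 100/525 train/test splits, CSV I/O.
* **`tcellfate.surrogates`** — four regressors written in-package behind
  one `fit`/`predict` contract: multi-output ordinary least squares with an
  explicit 5×5 transformation matrix, a logistic multilayer perceptron
  (4 → 7 → 5) trained by back-propagation, per-output ε-insensitive SVR
  with an RBF kernel solved by SMO on the dual, and per-output random
  forests (CART, bootstrap, out-of-bag error).
* **`tcellfate.evaluation`** — per-output mean absolute error and its sum,
  hidden-size / kernel-width / forest-grid scans, noise-robustness runs,
  10-fold cross-validation, runtime measurement.
* **`tcellfate.validation`** — directional (up/down) comparison of trained
  surrogates against five published in vitro stimulation experiments.

## Worked example

```python
from tcellfate import (
    build_dataset, normalize, split, default_methods,
    evaluate_surrogate, agreement_count,
)

table = normalize(build_dataset())          # 625 steady states, outputs in [0, 1]
train, test = split(table, 100, seed=0)     # 100 training / 525 test rows

for spec in default_methods(seed=0):        # linear, mlp (h=7), svr (γ=0.25), rf (1000, 4)
    model = spec.make().fit(train)
    report = evaluate_surrogate(model, test)
    count, _ = agreement_count(model)
    print(f"{spec.name:6s} sum of prediction error = {report.sum_error:.3f}   "
          f"in vitro agreement = {count}/5")
```

Output:

```
linear sum of prediction error = 0.717   in vitro agreement = 4/5
mlp    sum of prediction error = 0.159   in vitro agreement = 4/5
svr    sum of prediction error = 0.481   in vitro agreement = 4/5
rf     sum of prediction error = 0.320   in vitro agreement = 4/5
```

The "sum of prediction error" adds the per-output mean absolute test
errors over the five readouts, so 0.159 for the neural network means an
average absolute error of about 0.03 per readout on the [0, 1] scale.  The
two nonlinear surrogates (MLP, random forest) clearly beat the
baseline-width SVR, which beats the linear model — the differentiation map
is strongly nonlinear.  Every surrogate reproduces four of the five
published in vitro directions; the single mismatch is the condition whose
published FOXP3 response contradicts a second study measuring the same
readout (the models predict FOXP3 suppression by IL-6, agreeing with the
contradicting study).

The same pipeline is available from the shell:

```bash
tcellfate generate --out dataset.csv          # 625-row normalized grid scan
tcellfate train --data dataset.csv --method mlp --model-out mlp.json
tcellfate evaluate --data dataset.csv --model mlp.json
tcellfate validate --model mlp.json
tcellfate benchmark --outdir results/         # everything above, all methods
```

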