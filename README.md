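# anisann

Neural-network modelling of factorial agronomic trials, built around aniseed
(*Pimpinella anisum* L.) agronomy and essential-oil chemistry.

Aniseed producers care about two linked things: yield-related traits
(plant height, umbel morphology, seed yield, germination) and the
composition of the seed's essential oil, whose dominant compound,
*trans*-anethole, makes up roughly 90% of the profile.  Both depend on
growing conditions — year, locality and fertilization treatment — in ways
that are nonlinear and interact.  `anisann` provides a tested pipeline for
modelling this dependence from a 2 (year) × 3 (locality) × 6 (fertilization)
replicated factorial trial and for turning the fitted model into agronomic
guidance.

The chain, end to end:

1. **Model** — a single-hidden-layer perceptron `Y = f1(W2·f2(W1·X + B1) + B2)`
   mapping the 10 encoded factor inputs to 30 responses (13 agronomic traits
   + 17 essential-oil shares), trained by BFGS on a sum-of-squares loss with
   analytic gradients, multistart initialization and validation-based model
   selection (reference architecture MLP 10-10-30, exponential activations).
2. **Fit diagnostics** — per response: reduced χ², RMSE, mean bias error,
   mean percentage error, r², and residual skewness/excess kurtosis/moments.
3. **Sensitivity** — the connection-weight (Yoon) method,
   `RI_ij(%) = Σ_k w_ik·w_kj / Σ_i|Σ_k w_ik·w_kj| · 100`, giving a signed
   percentage influence of each factor level on each response.
4. **Optimization** — NSGA-II Pareto maximization of all 30 predicted
   responses over growing conditions, with an exhaustive 36-point oracle in
   the discrete factor space.
5. **Synthetic trials** — a generator with known additive effect structure
   (signs matching the agronomic findings the package is built around), so
   every stage is testable against ground truth.

Core fitting is exposed sklearn-style (`MLPRegressor` with
`fit`/`predict`/`score`, `ResponseScaler` with `fit`/`transform`/
`inverse_transform`), with functional wrappers (`train_mlp`,
`search_architectures`, …) and a CLI on top.

## Worked example

```python
import anisann as a
from anisann.design import RESPONSE_NAMES

design  = a.DesignSpec()                      # 2 × 3 × 6, four replications
effects = a.default_effects(0)                # documented effect tables
table   = a.generate_trial(design, effects, seed=1)   # 144 plots
dm      = a.encode_design(table, design)      # N × 10 design matrix
Y       = table[list(RESPONSE_NAMES)].to_numpy()
split   = a.split_indices(len(table), seed=2)         # 60/20/20

cfg   = a.TrainingConfig(hidden_sizes=(10,), restarts=10,
                         max_iterations=400, seed=3)
model = a.train_mlp(dm.X, Y, split, cfg, 10, ("exponential", "exponential"),
                    output_names=list(RESPONSE_NAMES))
print(model.net_name, model.n_parameters)     # MLP 10-10-30, 440 parameters
print(model.performance)

ri = a.yoon_relative_importance(model.params.W1, model.params.W2,
                                input_names=design.input_names(),
                                output_names=list(RESPONSE_NAMES))
print(a.rank_influences(ri, "yield_per_plant")[:3])

res = a.ga_optimize(model, design,
                    a.GAConfig(population_size=100, generations=100), seed=4)
best = a.best_condition_per_output(res, list(RESPONSE_NAMES))
```

Output of this exact script (seeds included):

```
net: MLP 10-10-30 params: 440
performance: {'train': 0.756, 'validation': 0.673, 'test': 0.636}
top influences on yield_per_plant:
  fertilization=vermicompost    +25.38%
  locality=Mošorin              +20.78%
  fertilization=BactoFil        +18.66%
max yield_per_ha 2437.1 at (year_1, Mošorin, vermicompost)
```

Reading it: the overall performance is the mean over the 30 responses of the
squared correlation between observed and predicted values per partition
(0.756 on training data at this noise level and restart budget).  The
sensitivity ranking says vermicompost fertilization and the Mošorin site are
the strongest positive influences on per-plant seed yield — which is exactly
the structure the synthetic generator planted, recovered from the trained
weights alone.  The optimizer then reports, per response, which combination
of year, site and fertilization the model predicts to be best.

The same chain is available from the shell:

```sh
anisann simulate --seed 1 --out table.csv
anisann train --table table.csv --outdir model/ --seed 3 --hidden 10
anisann evaluate --table table.csv --model-dir model/ --out fits.csv
anisann sensitivity --model-dir model/ --out ri.csv
anisann optimize --model-dir model/ --out front.csv --seed 4
anisann run-all --outdir run/ --seed 0        # everything, one report bundle
```

An example `run-all` configuration is in `examples/run_config.yaml`.
See `docs/methods.md` for the model, its assumptions and the numerical
choices.

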