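# Example configuration for `anisann run-all --config examples/run_config.yaml`.
# Omitted keys fall back to the documented defaults; table_path may point at a
# measured trial CSV instead of simulating one.
outdir: anisann_run
seed: 0
table_path: null          # null -> simulate with the default effect tables
effects_path: null        # optional YAML of EffectsConfig.to_dict()
split_fractions: [0.6, 0.2, 0.2]
hidden_sizes: [10]        # widen (e.g. [5, 10, 15, 20]) for a full search
activations:
  - [exponential, exponential]
restarts: 50
max_iterations: 1000
n_const: 1                # constants n in the reduced chi-square
ga_population: 100
ga_generations: 200
ga_mode: discrete         # or "relaxed" for continuous [0,1] genomes
design:
  years: [year_1, year_2]
  localities: [Ostojićevo, Veliki Radinci, Mošorin]
  fertilizations: [control, Slavol, BactoFil, Royal Ofert, vermicompost, NPK]
  replications: 4
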