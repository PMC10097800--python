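# hemoswarm

Stress-based hemolysis power-law evaluation and multi-objective particle
swarm optimization (MOPSO) of the power-law constants, decoupled from any
flow solver.

The package works on discretized stress-field exports — one record per
finite volume with cell volume [m³] and effective scalar stress [Pa], plus
the operating point's flow rate — and provides:

- **`hemomodels`** — the power law `H = C·τ^α·t^β`, its linearization,
  MIH (modified index of hemolysis) conversions, the experimental MIH
  formula, and a registry of named constant sets (GW, HO, ZT, FZ, FT-M,
  FT-L). All power arithmetic runs in the log domain so extreme constants
  (C ~ 1e-30, α ~ 20) stay representable.
- **`stressfield`** — the stress-field data model, strain-rate /
  equivalent-stress kinematics including the modeled-turbulence
  contribution `τ_eff = sqrt(2μ²·mean(SijSij) + ρμε)`, and an analytic
  laminar pipe (Poiseuille) field generator.
- **`mihcalc`** — the volume-integral MIH evaluator
  `MIH = [(1/Q)·C^(1/β)·Σ τ^(α/β)·ΔV]^β·1e6`, computed via log-sum-exp,
  with a batch API that amortizes per-field preprocessing across many
  constant sets.
- **`fitness`** — the two optimization objectives: a mean error with
  experimental-uncertainty dead-bands (per-point error ξ ∈ [0, 1)) and a
  modified Pearson correlation r ∈ [0, 2]; overall fitness
  `F_n = (η + r)/2`.
- **`mopso`** — a constriction-factor multi-objective particle swarm
  optimizer with a Pareto repository, adaptive hypercube grid, sparse-cell
  leader roulette, dense-cell pruning, and no mutation operator.
  Bit-reproducible for a fixed seed.
- **`paretoline`** — PCA line fitting of good repository particles in
  (ln C, α, β) space, plus the exact plane-intersection oracle for
  two-uniform-operating-point problems.
- **`synthdata`** — lognormal stress-field and synthetic-experiment
  generators with known ground truth, field retargeting, Blasius friction
  and relative-deviation helpers.
- **`cli_io`** — versioned plain-text field/repository formats, published
  operating-point fixtures, YAML run configuration, and the `hemo` CLI.

## CLI

```sh
# list built-in constant sets and operating-point fixtures
hemo fixtures

# make a synthetic field and evaluate MIH on it
hemo synth lognormal --cells 10000 --seed 7 --out field.csv
hemo evaluate --field field.csv --constants HO,GW --out report.json

# analytic pipe-flow field
hemo synth poiseuille --radius-mm 1.0 --length-mm 70 --flow-rate-lmin 0.42 \
    --mu-mpas 2.0 --cells 400 --out ct_field.csv

# generate a parameter-recovery study, optimize, and fit the solution line
hemo synth study --true-constants HO --n-ops 4 --seed 1 --out study/
hemo optimize --config study/run.yaml --domain literature --seed 42 \
    --out repository.csv
hemo fitline --repository repository.csv --fn-threshold 0.5 --out line.json
```

Repository CSVs carry columns `lnC,C,alpha,beta,eta,r,Fn`; running
`hemo optimize` twice with the same seed produces byte-identical output.

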