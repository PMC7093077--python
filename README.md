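# sbmlfit

Simulation and parameter estimation for SBML-encoded biochemical models:

* **SBML core subset I/O** — compartments, species, global/local parameters,
  reactions with kinetic laws, assignment/rate rules, discrete events and
  function definitions (SBML Level 2 v1–5 and Level 3 v1–2 core; delays,
  algebraic rules, constraints, fast reactions and conversion factors are
  rejected with explicit "unsupported construct" errors).
* **ODE compilation** — models are flattened into a state vector of amounts,
  a stoichiometry matrix and generated rate evaluators (`dy/dt = N·v`), with
  events located by bisection during integration.
* **Adaptive solvers** — a stiff-capable 4(3) Rosenbrock method
  (linearly-implicit, finite-difference Jacobian) and an explicit
  Dormand–Prince 5(4) pair, both with embedded error control and cubic
  Hermite dense output. A numba-jitted fast path accelerates repeated
  integrations during estimation; the pure-Python interpreter path is the
  reference implementation.
* **Quality functions** — relative squared error (the estimation fitness),
  RMSE, mean absolute error, Euclidean distance; failed integrations map to
  a finite penalty so optimizers can reject them.
* **Optimizers** — differential evolution (DE/rand/1/bin), (μ,λ) evolution
  strategy with log-normal step-size self-adaptation, inertia-weight
  particle swarm, (1+1) hill climbing, and simulated annealing; all
  box-constrained and bitwise reproducible from a seed.
* **Identifiability** — repeated independent fits, retention of the best
  fraction, normalization by reference values, and per-parameter
  mean/sd/CV summaries with box-plot output.
* **Synthetic fixtures** — a two-compartment import/export +
  Michaelis–Menten chain generator producing models, noise-free or noisy
  artificial datasets, and parameter-range files with known ground truth,
  so the whole estimation workflow is testable offline.

## Command line

```bash
# generate a synthetic study fixture (model.xml, data.csv, ranges.txt, truth.csv)
sbmlfit make-fixture --pairs 3 --seed 1 --out fixture/

# simulate a model and compare against data
sbmlfit simulate --model fixture/model.xml --data fixture/data.csv \
    --t-end 120 --step 1 --out out/

# fit the parameters listed in the range file
sbmlfit fit --model fixture/model.xml --data fixture/data.csv \
    --ranges fixture/ranges.txt --algorithm de --pop 50 \
    --max-evals 30000 --seed 1 --out out/

# repeated-fit identifiability analysis (20 runs, best 50%)
sbmlfit identify --model fixture/model.xml --data fixture/data.csv \
    --ranges fixture/ranges.txt --runs 20 --fraction 0.5 \
    --truth fixture/truth.csv --seed 0 --out out/
```

`identify` supports cluster-style sharding: run `--shard i/k` for
`i = 1..k` (same `--seed` and `--runs` everywhere), then aggregate with
`sbmlfit identify --merge --out out/ --truth fixture/truth.csv`.

Solver flags: `--method rosenbrock|rk45`, `--abs-tol` (default `1e-12`),
`--rel-tol` (default `1e-6`), `--t-start/--t-end/--step`, `--quality`
(default `relative_squared_error`). A YAML `--config` file can mirror any
flag; explicit flags win.

### Parameter-range file format

One record per line, either five fields

```
id  initMin  initMax  min  max
```

or the three-field form `id min max` in which the initialization interval
equals the search interval. For example:

```
Import_ASLpOH_k 1e-6 0.1 1e-6 0.1
fu_AS 1e-6 1
CYP3A4_ASoOH_Vmax 1e-6 100 1e-6 100
```

`initMin/initMax` bound the random initialization of the population;
`min/max` are enforced throughout the estimation.

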