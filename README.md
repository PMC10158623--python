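# mdoe-carrier

Model-assisted design of experiments (mDoE) for microcarrier-based
expansion of adherent cells.

The package chains four stages around a kinetic batch model of attachment,
growth, death and metabolism on microcarriers:

1. **`kinetic_model`** — an eight-state ODE system (total/attached/suspension
   cells, glucose, glutamine, lactate, ammonia, and a lumped unobservable
   limiting substrate). Growth and death are controlled by the limiting
   substrate; space limitation enters via the free carrier-surface fraction;
   cells attach from suspension only during an initial attachment window.
2. **`calibration`** — joint weighted least-squares fitting of the kinetic
   parameters to multi-experiment time series, plus Monte-Carlo parameter
   uncertainty (perturb observations, refit; or direct parameter jitter).
3. **`doe_designs`** — central composite, Box-Behnken, Latin hypercube,
   D-optimal, I-optimal and LHS+D-optimal design generators over a bounded
   factor space (initial glucose, initial glutamine, carrier loading).
4. **`mdoe_evaluation`** — every design point is simulated repeatedly under
   the parameter distribution; mean target (maximum area-specific attached
   cell yield) and 10–90 % quantile spread are scalarised into a
   desirability; a quadratic response surface per design is grid-searched to
   recommend culture conditions and to compare designs on desirability vs.
   run count.

`synthetic_data` generates shake-flask campaigns (the eight-condition
experimental grid, daily-to-two-daily sampling, multiplicative measurement
noise) from a documented ground-truth parameter fixture, so the whole loop
is testable without laboratory data. `interface` provides the configuration
schema, delimited-text file formats and the CLI.

## CLI

All commands live under a single entry point:

```bash
mdoe-carrier --help
mdoe-carrier simulate --config examples/config.yaml --out traj.csv --t-end 264 --dt 4
mdoe-carrier synth    --truth examples/config.yaml --out data/ --seed 1
mdoe-carrier fit      --data data/train/manifest.csv --out fit/
mdoe-carrier mc       --data data/train/manifest.csv --fit fit/ --n 1000 --noise 0.15 --seed 1
mdoe-carrier design   --type ccd --space examples/config.yaml --out designs/ccd.csv
mdoe-carrier evaluate --design designs/ccd.csv --design designs/dopt.csv \
                      --params fit/parameter_samples.csv --space examples/config.yaml \
                      --n-sim 100 --seed 1 --out evaluation/
mdoe-carrier workflow --config examples/config.yaml --out run/ --seed 1
```

`workflow` executes synth → fit → mc → design → evaluate → recommend and
writes per-stage artifacts plus `summary.json`; identical config + seed
gives byte-identical tables. All artifacts are plain delimited text.

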