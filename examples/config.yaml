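# Full workflow configuration for the microcarrier expansion study.
# All stages derive their seeds from the single global seed below.
seed: 1

# ground-truth / initial-guess kinetic parameters; omitted keys use the
# package defaults (documented fixture values)
model: {}

carrier:
  name: cytodex3-like
  area_per_gram: 2700.0        # cm^2 per g
  max_area_density: 5.0e5      # cells per cm^2 at confluence

# batch used by `simulate` and as the template for design evaluation
setup:
  c_MC: 1.0                    # g/L
  seed_density: 6000.0         # cells/cm^2
  c_Glc: 25.0                  # mmol/L
  c_Gln: 4.0                   # mmol/L

factor_space:
  - {name: c_Glc, lower: 5.0, upper: 60.0, units: mmol/L}
  - {name: c_Gln, lower: 2.0, upper: 12.0, units: mmol/L}
  - {name: c_MC, lower: 1.0, upper: 20.0, units: g/L}

designs: [ccd, bbd, lhs, dopt, iopt, lhsd-dopt]

synthesis:
  noise: 0.15                  # relative measurement error
  sampling_interval: 24.0      # h
  horizon: 264.0               # h

calibration:
  n_starts: 2
  mc_n: 100                    # Monte-Carlo replicates (1000 at full scale)
  mc_noise: 0.15
  mc_mode: refit               # or "jitter" for a fast approximation
  mc_max_nfev: 20

evaluation:
  n_sim: 100                   # simulations per design point
  n_optimal: 16                # runs for the optimal/LHS designs
  top_k: 2
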