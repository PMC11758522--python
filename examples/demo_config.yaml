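# Demo: a crown-mammal-like cohort (sigmoidal growth, post-maturity
# texture shift) vs a stem-mammaliaform-like cohort (shallow quadratic
# decline, no texture shift).  Run with:
#   cementochron run examples/demo_config.yaml
out_dir: scratch/demo_run
seed: 1
image_rows: 220
image_cols: 120
taxa:
  - name: crown_mammal_like
    model_family: hill_sigmoid
    params: [1.0, 0.35, 5.0, 6.0]
    n_years: 10
    mass_g: 130.0
    n_specimens: 10
    min_lifespan: 8
    maturity_year: 5
    shift_contrast: 0.25
    shift_anisotropy: 4.0
    shift_noise_sd: -5.0
  - name: mammaliaform_like
    model_family: quadratic
    params: [9.5, -1.6, 0.1]
    n_years: 10
    mass_g: 20.0
    n_specimens: 10
    min_lifespan: 6
    maturity_year: null
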