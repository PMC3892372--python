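# Bundled synthetic clonal study: three populations along an invasion
# gradient (Chile = most recently founded, UK = older introduction,
# ME = native range), mirroring the study design this package analyses.
#
# Clone counts are 30 / 14 / 9 with 5 replicates per clonal family.
# Ground-truth G and E matrices (raw trait units: AFR days, body mass ug,
# size at birth mm) are built from broad-sense heritabilities that rise
# from ~0.14 (Chile) through ~0.35 (UK) to ~0.55-0.66 (ME), with the
# size-at-birth genetic variance most strongly eroded toward Chile —
# the founder-effect regime the analyses are designed to detect.
# Genetic correlations are mild (0.1-0.2) throughout.
#
# Trait means: the native ME population reproduces earlier, is heavier
# and has larger offspring; its mean offspring number is also higher.

seed_note: pass the master seed on the command line; one RNG substream per population

populations:
  Chile:
    n_clones: 30
    n_reps: 5
    mu: [8.4, 290.0, 0.330]
    on_mean: 20.0
    zones: [north, central, south]
    G_true:
      - [0.140,     0.8283,    4.628e-04]
      - [0.8283,    122.5,     2.054e-02]
      - [4.628e-04, 2.054e-02, 1.530e-04]
    E_true:
      - [0.860,     3.0792,    1.267e-03]
      - [3.0792,    1102.5,    9.075e-02]
      - [1.267e-03, 9.075e-02, 7.470e-04]
  UK:
    n_clones: 14
    n_reps: 5
    mu: [8.1, 305.0, 0.345]
    on_mean: 18.0
    G_true:
      - [0.350,     2.4627,    1.497e-03]
      - [2.4627,    433.2,     7.898e-02]
      - [1.497e-03, 7.898e-02, 6.400e-04]
    E_true:
      - [0.650,     2.5632,    1.249e-03]
      - [2.5632,    1010.8,    9.851e-02]
      - [1.249e-03, 9.851e-02, 9.600e-04]
  ME:
    n_clones: 9
    n_reps: 5
    mu: [7.3, 345.0, 0.370]
    on_mean: 28.0
    G_true:
      - [0.6655,    4.3779,    3.645e-03]
      - [4.3779,    720.0,     1.798e-01]
      - [3.645e-03, 1.798e-01, 1.997e-03]
    E_true:
      - [0.5445,    2.1890,    1.183e-03]
      - [2.1890,    880.0,     9.514e-02]
      - [1.183e-03, 9.514e-02, 1.029e-03]
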