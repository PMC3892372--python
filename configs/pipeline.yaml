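# Full-pipeline configuration for the bundled synthetic study.
# Run from the repository root:
#   qgclone run --config configs/pipeline.yaml --seed 1 --output results/pipeline
seed: 1
profile: test
simulate: configs/study.yaml
comparisons:
  - [Chile, UK]
  - [Chile, ME]
  - [UK, ME]
gradient: [Chile, UK, ME]
zone_population: Chile
selection:
  alpha: 0.05
output_dir: results/pipeline
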