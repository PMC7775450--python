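# Demo pipeline: simulate -> fit -> report for three stages.
# Run with:  glycobind run --config examples/pipeline_config.yaml -o report.json
seed: 1
stages:
  - stage: binding
    scenario: t24_control
    noise: 0.05
    n_replicates: 4
  - stage: vacuole
    scenario: cap250
    noise: 0.05
    n_replicates: 1
  - stage: ecis
    scenario: t24_cap250
    noise: 0.02
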