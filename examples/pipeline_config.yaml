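# End-to-end demo: simulated discovery and validation cohorts drawn from
# one population, carboplatin-specific marker hazard in validation.
# Run with:  dnamesig run --config examples/pipeline_config.yaml
discovery:
  simulation:
    n_pos: 35
    n_neg: 28
validation:
  simulation:
    n_pos: 100
    n_neg: 100
    treatment_probs: {carboplatin: 0.5, cisplatin: 0.5, none: 0.0}
    hr_marker_by_treatment: {carboplatin: 3.5, cisplatin: 1.0, none: 1.0}
candidate_sizes: [10, 25, 50, 100]
folds: 10
top_n: 500
fdr_max: 0.3
n_draws: 100
seed: 1
outdir: dnamesig_demo_run
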