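# End-to-end demo: simulate -> fit -> derive -> bootstrap -> untb
simulate:
  n_species: 12
  n_cells: 16
  plots_per_cell: 8
  seed: 7
  n_ecoregions: 1
  aux_presence_coverage: 0.5
  aux_absence_coverage: 0.3
fit:
  model_spec: integrated
  compute_se: false
derive:
  enabled: true
bootstrap:
  B: 10
  seed: 1
untb:
  models: [PMS, PLN]
  seed: 0
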