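# Demo pipeline config: 200 planted patients, bmi prediction, all models.
cohort:
  n_patients: 200
  stay_probability: 0.9
  visit_rate: 0.5
  medication_probability: 0.2
target: bmi
m: 1
split:
  train_fraction: 0.8
embedding:
  epochs: 10
lstm:
  epochs: 15
  early_stopping: true
models: [lstm, lr, rf]
seed: 4
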