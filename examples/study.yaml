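# Desk-scale simulation study: base case and high correlation, three
# learners, 10 replicates. Full scale would use n_replicates: 500 and
# n_boot: 200.
scenarios: [1, 3]
learners: [cox_ph, cox_en, cox_ph_ps]
learner_hyperparameters:
  cox_en: {cv_folds: 3, l1_ratio_grid: [0.5, 1.0]}
  cox_ph_ps: {penalty_grid: [10.0, 1000.0, 100000.0], cv_folds: 3}
n_replicates: 10
n_boot: 100
n_subjects: 3000
base_seed: 0
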