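# Full study protocol: 20 PD (paired OFF/ON) + 15 HC subjects, 18 trials
# each (3 perturbation levels x 2 start sides x 3 repetitions), 50-fold
# subject-grouped CV for DT/KNN/SVM (LOSO for the ANN), 80% selection gates.
n_pd: 20
n_hc: 15
effect_ml_amp_sd: 1.5
effect_pelvis_gain_sd: 1.5
on_normalization: 0.3
accel_noise_ms2: 0.05
orient_noise_deg: 0.2
fs_hz: 100.0
trial_duration_s: 34.0
ramp_duration_s: 2.0
n_repetitions: 3
average_repetitions: true
cv_kind: kfold
cv_k: 50
threshold_pct: 80.0
seed_cohort: 0
seed_folds: 0
seed_classifier: 0
save_sessions: false
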