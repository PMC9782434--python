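# posturebench

Simulation and machine-learning benchmark for IMU-based dynamic
posturography in Parkinson's disease (PD).

## The problem

Postural instability is one of the most debilitating motor symptoms of PD,
yet routine clinical examination detects it only once patients are already
symptomatic. Dynamic posturography — standing on a platform that rotates
sinusoidally about the vertical (yaw) axis while three inertial sensors
(head, trunk, pelvis) record the reactive postural response — can reveal
*subclinical* balance abnormalities, and machine-learning classifiers
trained on the extracted kinematics can separate patients from healthy
controls (HC) and probe whether dopaminergic medication (ON vs OFF state)
changes the response.

Clinical recordings of this kind are private, so this package provides the
full analysis chain plus a virtual cohort that stands in for the
unavailable recordings:

1. **Protocol simulation** — platform yaw trajectories
   `θ(t) = A sin(2πf t)` at three intensities (0.2 Hz/±55°, 0.3 Hz/±55°,
   0.5 Hz/±35°), with sigmoidal on/off ramps, and a seeded random schedule
   of 18 trials (3 levels × 2 start sides × 3 repetitions).
2. **Virtual cohort** — each subject is a chain of yaw links
   (pelvis←platform, trunk←pelvis, head←trunk) with per-link gain *g* and
   phase lag *φ*, plus sinusoidal medio-lateral (ML) and antero-posterior
   (AP) sway per segment; virtual IMUs render orientation quaternions,
   body-frame specific force (gravity included) and angular rate, with
   Gaussian sensor noise. PD subjects sway more in ML and transmit less
   yaw through the pelvis link than HC; ON-state parameters are only
   partially normalized toward HC.
3. **Feature extraction** — body accelerations are rotated to the world
   frame via the quaternion rotation matrix, gravity is subtracted,
   and displacement is obtained by double integration with a zero-lag
   first-order Butterworth high-pass (0.2 Hz) after each stage; ROM-ML and
   ROM-AP are max−min displacement (mm) over the steady window. The
   inter-segment coupling indices are computed in the Fourier domain:
   gain ratio G = |X_distal(f*)| / |X_proximal(f*)| at the proximal
   fundamental f*, phase shift φ = ∠X_proximal − ∠X_distal (deg, φ > 0 =
   distal lags). 4 features × 3 segments × 6 test types = 72 features per
   subject-state.
4. **Classifier benchmark** — 13 preset variants (fine/medium/coarse
   Decision Trees; fine/medium/coarse/cosine/cubic/weighted kNN;
   linear/quadratic/cubic polynomial SVMs; a 10-neuron shallow ANN) × 4
   experiments (PD vs HC, OFF vs HC, ON vs HC, OFF vs ON), with
   subject-grouped stratified 50-fold CV (leave-one-subject-out for the
   ANN) and pooled out-of-fold confusion matrices.
5. **Selection** — ordered 80% gates on accuracy, recall (TPR) and
   precision (PPV); survivors ranked by the goodness index
   `G = √((1−TPR)² + (1−TNR)²)` (distance from the perfect-classifier
   corner of ROC space: 0 = perfect, ≈0.70 = chance, √2 = worst;
   G ≤ 0.25 → "optimum", ≤ 0.70 → "good", else "bad"), plus pooled
   ROC/AUC.

## Worked example

```python
from posturebench.pipeline import RunConfig, run_pipeline

result = run_pipeline(RunConfig())   # 20 PD + 15 HC, 18 trials each
for exp, name in result.report.best.items():
    print(exp, "->", name)
```

Running the numbered drivers reproduces the full analysis
(`results/` outputs regenerated at each step):

```bash
python analysis/01_simulate_protocol.py
python analysis/02_simulate_cohort.py
python analysis/03_extract_features.py
python analysis/04_benchmark_classifiers.py
python analysis/05_select_best.py
```

With the default cohort (seed 0, 1.5 SD group contrasts) the final step
prints:

```
best classifier per experiment (lowest goodness index):
  OFFvsHC  -> KNN_cosine  ACC 82.9%  G 0.24 (optimum)  AUC 0.88
  OFFvsON  -> none passed all three gates
  ONvsHC   -> DT_coarse  ACC 85.7%  G 0.27 (good)  AUC 0.84
  PDvsHC   -> DT_coarse  ACC 87.3%  G 0.28 (good)  AUC 0.83
```

i.e. classifiers separate patients from controls well above the 80% gates
in every vs-HC experiment, while no classifier survives the gates for
OFF vs ON — the medication contrast is intentionally weak because axial
postural control responds poorly to L-Dopa. The same pipeline is also
exposed as a CLI (`posturebench run --config configs/paper_protocol.yaml
--out run/`, with per-stage subcommands `simulate-protocol`,
`simulate-cohort`, `extract`, `bench`, `evaluate`).

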