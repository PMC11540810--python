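# thumbrom

Contact-free estimation of the thumb's **radial abduction angle** — the
clinical range-of-motion measure normally taken with a goniometer — from
markerless hand-pose landmarks.

Hand surgeons and therapists need objective thumb range-of-motion numbers,
but goniometry requires contact and an examiner, and its reproducibility
for thumb abduction is modest.  Markerless hand tracking (21 keypoints per
hand in the MediaPipe-Hands convention) makes a contact-free readout
possible, but the *direct* geometric angle between the thumb-tip and
index rays is unreliable: detectors misplace the occluded thumb while it is
adducted over the palm.  `thumbrom` implements the two-stage alternative:
compute seven scale-free geometric parameters from the landmarks —

```
tip_joint_angle = ∠(p9, p0, p4)          tip_distance = |p4−p8| / |p0−p5|
mp_joint_angle  = ∠(p9, p0, p2)          mp_distance  = |p2−p5| / |p0−p5|
ip_joint_angle  = ∠(p9, p0, p3)          palmsize1 = area(p5,p0,p17) / |p0−p5|²
                                         palmsize2 = area(p3,p0,p6)  / |p0−p5|²
```

— and regress the abduction angle on them with five models (ordinary least
squares, ElasticNet, RBF-kernel SVR, random forest, LightGBM), evaluated by
RMSE, MAE, R² and Pearson CC on a held-out 20% split, with residual plots,
permutation feature importance, **exact** Shapley attributions (all 2⁷
coalitions enumerated, marginal value function) and a feature/label
correlation heatmap.

Because clinical video cannot ship with a package, a forward-kinematic
**hand simulator** provides labeled landmark data reproducing the capture
protocol: 10 subjects × commanded angles 0–80° in 10° steps × repeated
noisy frames (≈ 5 000 per experiment), dorsal pinhole camera at 70 cm
(optionally ±30° azimuth views), per-subject anthropometric variation, and
a two-part detector-error model (systematic occluded-tip bias plus
calibrated Gaussian jitter).  See `docs/methods.md` for the model and its
assumptions.

## Worked example

Run the whole pipeline — simulate, featurize, split/train, evaluate,
explain, report — on the default frontal protocol:

```bash
thumbrom run-all --seed 42 --out out/frontal
```

prints

```
direct geometric estimator CC: 0.840
linear_regression: rmse=3.361, mae=2.657, r2=0.983, cc=0.991
elastic_net: rmse=3.921, mae=3.091, r2=0.977, cc=0.988
svm_rbf: rmse=2.989, mae=2.326, r2=0.987, cc=0.993
random_forest: rmse=2.625, mae=1.275, r2=0.990, cc=0.995
gbdt: rmse=3.395, mae=1.735, r2=0.983, cc=0.992
report written to out/frontal/report.json
```

Reading: the single-angle geometric readout of the (simulated) detector
correlates only 0.84 with the commanded angle, while every learned model
reaches CC ≥ 0.99 and errors of ~2–4° — machine learning on the seven
parameters recovers the abduction angle far more reliably than the raw
geometry.  The output directory holds `dataset.csv` (the simulated
landmark table), `features.csv`, `metrics.csv`, per-model
`predictions_*.csv` / `residuals_*.csv`, `importance_*.csv` and `shap_*.csv`
for the best model, `correlations.csv`, and `report.json` with the fully
resolved seeded configuration.

Other subcommands: `simulate`, `featurize`, `train`, `evaluate`, `explain`,
and `calibrate-noise` (finds the jitter level at which the direct
estimator's CC matches a target, e.g. 0.84).  Every subcommand accepts
`--config experiment.yaml` and `--seed`; a config file looks like

```yaml
seed: 42
data:
  simulator: {n_subjects: 10, frames_per_angle: 56, azimuths_deg: [0, 30, -30]}
models:
  specs: [linear_regression, elastic_net, svm_rbf, random_forest, gbdt]
  train_fraction: 0.8
explain: {models: best, n_background: 100, n_instances: 40}
```

The library surface mirrors the CLI: `generate_dataset`,
`compute_features` / `feature_table`, `fit_all` / `predict`, `metrics` /
`residual_table`, `exact_shapley` / `permutation_importance` /
`correlation_matrix`, `run_experiment`, `calibrate_noise`.  Landmark tables
read/write as CSV or JSON-lines (header
`frame_id,subject_id,view_azimuth_deg,true_angle_deg,x0,y0,…,x20,y20`);
normalized detector output converts to pixels with `normalize_to_pixels`.

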