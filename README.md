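# fdm3pool

Frequency-difference mapping and three-pool analysis of complex multi-echo
gradient-echo (mGRE) MRI, for quantifying myelin in white matter — built
around the mid-sagittal corpus callosum and the study design used to probe
myelin breakdown in premanifest Huntington's disease.

The white-matter mGRE signal is modelled as three water pools — myelin
(m), intra-axonal (a) and extra-axonal (e) water — each with its own signal
fraction, frequency offset and effective relaxation rate:

    S(t) = f_a e^{iω_a t − R2*_a t} + f_e e^{−R2*_e t} + f_m e^{iω_m t − R2*_m t}

Two fitted quantities carry the myelin information: the myelin water signal
fraction `f_m` (a proxy for myelin content) and the myelin–axonal frequency
split `Δω = ω_m − ω_a` (sensitive to sheath susceptibility and g-ratio).
The phase route to these parameters is frequency difference mapping (FDM):
subtract a TE-independent offset and a linear-in-TE field term from the
unwrapped phase, leaving only the microstructural frequency evolution.

The package covers the full workflow, end to end, on synthetic data with
known ground truth:

* `signal_model` — the three-pool forward model and derived ROI curves;
* `synthetic_mgre` — a phantom slice (arc-shaped corpus callosum in three
  segments), the bipolar multi-channel acquisition with field / RF / eddy
  nuisances and noise, and multi-subject, multi-visit study generation;
* `preprocess` — read-polarity correction, image-based coil-sensitivity
  estimation and combination, segment splitting, ROI averaging;
* `fdm` — the FDM operator and per-echo 2-D polynomial detrending;
* `threepool_fit` — bounded nonlinear least squares on joint magnitude +
  FDM curves (with `R2*_a` fixed at 0), plus the constraint-bias analysis;
* `reproducibility` — discrete Fréchet distances between visit curves,
  coefficients of variation, and the modified signed-likelihood ratio test
  for CV equality;
* `stats` — group × age regression, Spearman and rank-partial
  correlations, disease burden score, Bonferroni correction;
* `pipeline` / `cli` — YAML-configured orchestration (`fdm3pool run-all`)
  and per-stage subcommands.

## Worked example

Fit the three-pool model to noiseless ROI curves generated at the
posterior-segment mean tissue parameters:

```python
from fdm3pool import ThreePoolParams, make_te_schedule, model_roi_curves
from fdm3pool.threepool_fit import fit_three_pool

schedule = make_te_schedule(1.62, 1.23, 25)   # TE1/ΔTE in ms, 25 echoes
truth = ThreePoolParams.from_hz(
    f_m=0.16, f_a=0.42, f_e=0.42,
    omega_m_hz=27.3, omega_a_hz=-8.5,
    r2s_m=150.0, r2s_a=0.0, r2s_e=25.0,
)
curves = model_roi_curves(truth, schedule)    # magnitude + FDM vs TE
result = fit_three_pool(curves)
print(f"f_m      = {result.params.f_m:.4f}")
print(f"omega_a  = {result.params.omega_a_hz:+.2f} Hz")
print(f"omega_m  = {result.params.omega_m_hz:+.2f} Hz")
print(f"delta_omega = {result.delta_omega_hz:.2f} Hz")
print(f"residual = {result.residual_norm:.2e}, converged = {result.converged}")
```

prints

```
f_m      = 0.1600
omega_a  = -8.50 Hz
omega_m  = +27.30 Hz
delta_omega = 35.80 Hz
residual = 1.57e-14, converged = True
```

i.e. the fit recovers the generating myelin fraction (0.16), the axonal
(−8.5 Hz) and myelin (27.3 Hz) frequency offsets, and hence a 35.8 Hz
myelin–axonal frequency split, at machine-precision residual. On real or
simulated data the same fit runs per callosal segment on ROI-averaged
curves produced by the preprocessing + FDM chain.

The full synthetic study — phantom acquisition, preprocessing, FDM,
fitting, test–retest reproducibility and group statistics — runs from one
config:

```sh
fdm3pool run-all -o out/            # defaults: 256x256 slice, 19 vs 21 cohort
cat out/summary.txt
```

See `docs/methods.md` for the model, operator conventions, generator
calibration and known limitations.

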