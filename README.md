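# megre

Quantitative T2* mapping with multi-echo gradient-echo (GRE) sequences:
a simulation and analysis toolkit for comparing **monopolar** and
**bipolar** readout gradients.

## The problem

T2* (effective transverse relaxation time) is quantified by sampling the
exponential signal decay at a train of echo times and fitting

```
s(TE_n) = M0 · E(α, TR, T1) · exp(−TE_n / T2*) · exp(i(φ0 + 2π Δf TE_n)) + ε,
E(α, TR, T1) = sin α (1 − e^{−TR/T1}) / (1 − cos α e^{−TR/T1}),
```

where ε is complex Gaussian noise, so magnitude images are Rician
distributed.  Monopolar readouts insert a fly-back gradient between
echoes (echo spacing ΔTE = T_acq + 2 T_ramp + T_fb); bipolar readouts
alternate the gradient polarity (ΔTE = T_acq + 2 T_ramp), collecting
roughly twice as many echoes in the same TE range — at the cost of
parity-dependent amplitude modulation between odd and even echoes.

This package provides, for users who design or evaluate such protocols:

* **`megre.protocol`** — echo-train timing (TE schedules for both
  polarities), echo counting in a TE range, acquisition-window rounding,
  and the √BW noise-bandwidth law, with shipped presets for 801/718/613/342
  Hz-per-pixel protocols;
* **`megre.signal_model`** — the spoiled-GRE signal equation, steady-state
  (Ernst) amplitude, parity modulation, Rician magnitude formation;
* **`megre.phantom_sim`** — a five-region digital phantom
  (T2* = 49/78/69/99/133 ms, T1 = 671/959/878/1134/1372 ms) with
  noise-only corners, plus the two retrospective echo-subsampling schemes
  (first-n, every-n-th);
* **`megre.estimation`** — background (Rayleigh) noise estimation,
  voxelwise maximum-likelihood T2* fitting under a Rician likelihood with
  known σ, and iterative amplitude-modulation correction for bipolar data;
* **`megre.crlb`** — Fisher information under Rician noise (numerical
  quadrature with a Gaussian high-SNR limit), Cramér–Rao lower bounds on
  the T2* estimator's standard deviation, and σ calibration by
  root-finding;
* **`megre.experiments`** — the four readout-comparison sweeps (flip
  angle × TR, TE range, ΔTE matching, bandwidth) as tidy DataFrames.

## Worked example

Predict the precision gain of a bipolar readout at flip angle 75°,
TR 1200 ms in a T2* = 69 ms region, then verify it by Monte-Carlo:

```python
import numpy as np
from megre import crlb
from megre.protocol import train_from_params
from megre.signal_model import AcquisitionParams, TissueParams
from megre.experiments import mc_voxel_curves
from megre.estimation import fit_t2star_batch

tissue = TissueParams(m0=1.0, t1=878.0, t2_star=69.0)
acq    = AcquisitionParams(alpha=75.0, tr=1200.0)
mono   = train_from_params(3.84, 2.92, "monopolar", te_max=97.0)  # 32 echoes
bip    = train_from_params(3.84, 1.47, "bipolar",   te_max=97.0)  # 64 echoes

# anchor sigma so the monopolar train predicts a CRLB std of 1.08 ms
sigma = crlb.calibrate_sigma(1.08, mono, tissue, acq)
print(f"sigma = {sigma:.5f}")
print(f"CRLB std, bipolar: {crlb.crlb_t2star_std(bip, tissue, acq, sigma=sigma):.3f} ms")

acq = AcquisitionParams(75.0, 1200.0, sigma=sigma)
for name, train in [("monopolar", mono), ("bipolar", bip)]:
    curves = mc_voxel_curves(tissue, acq, train, 2000, seed=1)
    t2, _, _ = fit_t2star_batch(train, curves, sigma)
    print(f"{name}: mean {t2.mean():.2f} ms, std {t2.std(ddof=1):.3f} ms")
```

Output:

```
sigma = 0.01280
CRLB std, bipolar: 0.770 ms
monopolar: mean 69.02 ms, std 1.069 ms
bipolar: mean 69.03 ms, std 0.761 ms
```

The bipolar train's doubled echo count lowers the predicted std by ≈√2
(1.08 → 0.77 ms), and the Monte-Carlo estimator stds of the
Rician-likelihood fit track both predictions closely — the two readouts
agree in the mean (accuracy) while the bipolar readout is ~29% more
precise.

A command-line interface wraps the same machinery:

```bash
megre simulate --protocol bw801_bipolar --alpha 75 --tr 1200 --out demo
megre fit --input demo --sigma auto --am-correct --out maps
megre crlb --protocol bw801_monopolar --calibrate-to 1.08
megre sweep te-range --seed 0 --out-dir results/
```

## Layout

```
src/megre/          library modules (see above)
src/megre/data/     protocol presets (YAML)
tests/              pytest suite, including end-to-end acceptance checks
scripts/            acceptance script
docs/methods.md     modelling and design notes
```
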