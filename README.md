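# xpcskit

Modelling and analysis tools for ultra-small-angle X-ray scattering (USAXS)
and multispeckle X-ray photon correlation spectroscopy (XPCS) of colloidal,
active and sheared suspensions — the regime probed by fourth-generation
synchrotron USAXS beamlines, where micron-scale structure and
millisecond-scale dynamics are measured simultaneously.

The package is aimed at scattering practitioners who need to

- fit high-resolution USAXS profiles with polydisperse-sphere,
  hollow-cylinder (microtube) and 1D lattice (e.g. muscle sarcomere) models,
  including instrumental resolution smearing;
- turn detector frame stacks into ensemble-averaged intensity
  autocorrelation functions g₂(q, t) with a pixel-wise multi-tau
  correlator;
- fit g₂(q, t) with Brownian, active (self-propelled) and Couette-shear
  correlation models, singly or globally across q;
- validate the full chain on synthetic data whose ground truth is known:
  Brownian/active/sheared particle trajectories rendered into coherent
  speckle movies by a phasor sum, or directly synthesized noisy g₂ and
  I(q) tables.

## Models

**Form factors** (q in nm⁻¹, sizes in nm). Sphere:
P(q, R) = [3(sin qR − qR cos qR)/(qR)³]², number-averaged over a truncated
Gaussian radius distribution with V(R)² weighting. Long hollow cylinder:
I(q) ∝ (1/q)·⟨A_cs(q)²⟩ with the annular cross-section amplitude
A_cs = [R_o²·2J₁(qR_o)/(qR_o) − R_i²·2J₁(qR_i)/(qR_i)]/(R_o² − R_i²),
averaged over Gaussian distributions of midwall radius and wall thickness.
Lattice: Gaussian reflections at qₙ = 2πn/d. All models can be smeared
with the Gaussian instrumental resolution of FWHM Δq.

**Correlation functions.** The Siegert relation links field and intensity
correlations, g₂ = 1 + β|g₁|². Brownian: g₁ = exp(−Γt), Γ = D₀q², with
D₀ = k_BT/(6πηR_H). Driven suspensions factorize as

    g₁(q, t) = exp(−Dq²t) · exp(−t²/2t_T²) · g₁_A(q, t),

with beam-transit time t_T = σ_B/v and a Gaussian,
g₁_A = exp(−(qδv t)²/2), or exponential (Lorentzian velocity spread)
advective factor. Ideal Couette flow probed along the flow direction gives
the homodyne form g₂ = 1 + β exp(−2Γt) sinc²(qδv t/2), whose first node
sits at qδv t = 2π.

## Worked example

Recover a diffusion coefficient from synthetic Brownian g₂ curves:

```python
import numpy as np
from xpcskit import FitSpec, fit_g2, g1_brownian, g2_siegert
from xpcskit.synthetic import synth_g2_curves

qs = np.array([2e-3, 3e-3, 4e-3, 6e-3, 8e-3])       # nm^-1
lags = np.geomspace(1e-4, 10, 60)                    # s
model = lambda q, t: g2_siegert(g1_brownian(q, t, 0.58), beta=0.4)
curves = synth_g2_curves(model, qs, lags, noise_sigma=0.005, seed=42)

result = fit_g2(curves, FitSpec(model="brownian"))
print(f"D0 = {result.value('D0'):.4f} +- {result.stderr('D0'):.4f} um^2/s")
print(f"beta = {result.value('beta'):.4f}")
```

This prints (exact values depend on the noise seed):

```
D0 = 0.5776 +- 0.0030 um^2/s
beta = 0.3996
```

i.e. the global five-curve fit recovers the generating diffusion
coefficient 0.58 µm²/s and speckle contrast 0.4 to a fraction of a
percent under 0.5% additive noise.

The same workflow is available from the shell:

```sh
xpcskit simulate --scenario brownian --seed 42 --noise 0.005 --out g2.csv
xpcskit fit --input g2.csv --model brownian --global --out fit.csv
```

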