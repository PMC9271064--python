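# prolifmap

Spatial tumor proliferation-rate mapping from serial breast DW/DCE-MRI
through a mechanically coupled reaction–diffusion growth model.

## The problem

During neoadjuvant therapy (NAT) for breast cancer, serial quantitative MRI
is acquired at baseline (T₀), ~3 weeks (T₁), mid-treatment (T₂) and before
surgery (T₃), but conventional readouts — tumor size, mean apparent
diffusion coefficient (ADC), functional tumor volume (FTV) — describe
morphology, not the underlying response biology. `prolifmap` inverts a
biophysical growth model against the imaging to estimate, for each pair of
visits, a spatial map of the net proliferation rate k(x) (day⁻¹; negative
under effective therapy) and a global cell diffusivity D₀, then summarizes
the maps with histogram metrics and correlates them with residual cancer
burden (RCB), the post-surgical pathology index of remaining disease.

## The model

Cellularity is read from imaging: ADC per voxel from the three-direction
DW signal model ADC = Σᵢ ln(S₀/Sᵢ)/bᵢ / 3, then

    N(x,t) = θ · (ADC_w − ADC(x,t)) / (ADC_w − ADC_min),

with ADC_w = 3×10⁻³ mm²/s (free water at 37 °C), ADC_min the patient's
densest tumor voxel, and θ the voxel carrying capacity (close-packed 10 µm
cells: packing fraction 0.7405, cell volume 4189 µm³). The tumor ROI is a
manual seed refined by the 80% DCE-enhancement rule (post ≥ 1.8 × pre).

Between visits, N evolves by a coupled PDE system on a triangular FEM mesh
(1.5 mm edges, Δt = 1 day):

    ∂N/∂t = ∇·(D∇N) + k(x) N (1 − N/θ)          (logistic growth + motility)
    D      = D₀ exp(−γ σ_VM)                     (stress-damped diffusion)
    ∇·G∇u + ∇[G/(1−2ν)](∇·u) − λ∇N = 0           (quasi-static elasticity)

with G = E/2(1+ν), ν = 0.45. Regional k (k-means regions of ~5 elements)
and global D₀ are fitted per visit pair (T₀₁, T₁₂, T₀₂) by L-BFGS-B, using
adjoint-state gradients for k (one backward sweep, independent of region
count) and a 1% forward-difference gradient for D₀. See
[docs/methods.md](docs/methods.md) for assumptions, discretization and
limitations.

Because the underlying patient MRI is not publicly available, the package
includes a first-class synthetic-phantom module that emulates the study's
observable structure (visit spacing 0/29/96/172 days, b-values
0/100/600/800 s/mm², enhancement thresholds, outcome ranges), so the whole
pipeline is testable end to end.

## Worked example

```python
import numpy as np
import prolifmap as pm
import prolifmap.synthetic_data as sd
from prolifmap.stats_report import PipelineConfig, analyze_patient

# phantom patient: 64x64 mm slice, 8 mm tumor, 8 ground-truth k regions
phantom = sd.make_phantom(
    (64, 64),
    tumor_spec={"radius_mm": 8.0},
    k_field_spec={"values": np.linspace(-0.15, 0.10, 8)},
    D0=5e-3,
    seed=5,
)
theta, cell_volume = pm.carrying_capacity((1.0, 1.0), 1.0)

sim = sd.simulate_cellularity_series(phantom, pm.ModelParams(theta=theta))
study = sd.render_images(sim, phantom, noise_sigma=0.0, seed=11)
study.outcome = sd.RCBOutcome(1.94, 1.75, False)

res = analyze_patient(phantom, study, PipelineConfig(pairs=("T01",)), "patient_00")
fit, h = res.fits["T01"], res.histograms["T01"]
```

which prints (via the obvious `print` statements):

```
carrying capacity theta = 176781 cells/voxel (cell volume 4189 um^3)
fitted 50 regions in 226 L-BFGS-B iterations, D0_hat = 0.0135 mm^2/day
proliferation histogram: mean = -0.0700, median = -0.0219, p75 = +0.0383 /day
recovery vs truth regions: r = 0.923
conventional: dLD = -1.8%, dADC = -5.0%, dFTV = -21.2%
```

Reading: over the first 29 days this phantom tumor is net-responding (mean
k < 0) but spatially heterogeneous — a quarter of its area still
proliferates (p75 > 0), exactly the kind of residual-resistance signal the
histogram metrics are designed to expose. The conventional size change
(−1.8% longest dimension) barely moves. The regional estimates correlate
r = 0.923 with the generative truth.

A cohort-level run (6 synthetic patients, all pairs, correlation tables
with significance flags) is one call — `prolifmap.run_pipeline()` — or one
shell command:

```sh
prolifmap all --seed 1 --outdir out/      # also: simulate, fit, metrics, correlate
```

writing NIfTI maps, CSV metric/correlation tables, JSON fit diagnostics and
PNG proliferation maps + histograms under `out/`.

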