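# Methods

## The model

`prolifmap` interprets serial quantitative breast MRI during neoadjuvant
therapy (NAT) through a mechanically coupled reaction–diffusion model of
tumor cell number N(x, t) on a 2D central tumor slice:

- **Growth/transport** — ∂N/∂t = ∇·(D∇N) + k(x) N (1 − N/θ). Net
  proliferation k(x) (day⁻¹) is signed: negative values mean therapy-induced
  net cell loss. θ is the voxel carrying capacity.
- **Stress damping** — D = D₀ exp(−γ σ_VM), where σ_VM is the von Mises
  stress of the host tissue and D₀ the stress-free cell diffusivity
  (mm²/day): compressed tissue impedes cell migration.
- **Quasi-static elasticity** — ∇·G∇u + ∇[G/(1−2ν)](∇·u) − λ∇N = 0 with
  G = E/2(1+ν): the growing tumor pushes on its surroundings in proportion
  to the cell-density gradient.

Cellularity is observed, not simulated: ADC maps from DW-MRI
(ADC = Σᵢ ln(S₀/Sᵢ)/bᵢ / 3 over three orthogonal directions) are converted
to N = θ (ADC_w − ADC)/(ADC_w − ADC_min), with ADC_w = 3×10⁻³ mm²/s (free
water at 37 °C) and ADC_min the per-patient minimum over the tumor ROI.
The ROI is a manual seed refined by the 80% DCE enhancement rule
(post ≥ 1.8 × pre, inclusive; largest 8-connected component kept). θ is the
voxel volume divided by the nominal tumor cell volume (spherical cells of
radius 10 µm → 4189 µm³) times the close-packing fraction 0.7405.

Between each pair of imaging visits (T₀₁, T₁₂, T₀₂) the model is run
forward from the first cellularity map and a piecewise-constant regional
proliferation field k plus a global D₀ are estimated by bound-constrained
L-BFGS-B minimization of the nodal least-squares misfit at the end visit.
Fitted maps are summarized by area-weighted histogram metrics and, across a
cohort, correlated with residual cancer burden (RCB).

## Parameters and defaults

| Parameter | Default | Units | Role |
|---|---|---|---|
| D₀ (init) | 1×10⁻² | mm²/day | stress-free diffusivity; fitted in [0, 1] |
| k (init) | 0 | day⁻¹ | regional proliferation; fitted in [−1, 1] |
| γ | 1.0 | kPa⁻¹ | diffusion damping per unit von Mises stress |
| λ | 1.0 | kPa per cell fraction | expansive force coupling |
| E | 2.0 | kPa | Young's modulus (homogeneous soft tissue) |
| ν | 0.45 | – | Poisson's ratio, near-incompressible |
| Δt | 1 | day | time step |
| bin width | 0.1 | day⁻¹ | proliferation histogram bins |
| edge | 1.5 | mm | target mean FEM edge length |
| elements/region | 5 | – | k-means granularity of the k field |

γ and λ are not identified from the data here (they come from empirical
calibration in the literature); the defaults are chosen so that mechanics
visibly feeds back on transport — peak von Mises stresses of a few tenths
of a kPa damp D by 10–30% near steep cellularity gradients — while keeping
the frozen-diffusion adjoint approximation (below) accurate to a few
percent. Stresses are kept in physical kPa; λ is per unit *cell fraction*
(N/θ), which conditions the elasticity right-hand side independently of θ.

## Discretization

- **Mesh**: structured right-triangle grid with checkerboard-alternating
  ("union-jack") diagonals, masked to the domain (triangle kept when its
  centroid is inside). Cell size is chosen so the *mean* edge equals the
  1.5 mm target; minimum angle is 45° by construction and symmetric domains
  mesh symmetrically. The meshed domain is the tumor plus a 1 cm host-tissue
  margin clipped to the breast mask, so the mechanics has surrounding tissue
  to push against.
- **Time stepping**: operator splitting at Δt = 1 day. The logistic
  reaction is advanced by its *exact* closed-form flow (no reaction-step
  error, unconditionally bound-preserving); diffusion is backward-Euler with
  a lumped mass matrix. On non-obtuse triangles this is an M-matrix scheme:
  cell fractions provably stay in [0, 1], and total cell number is conserved
  exactly under the natural no-flux boundary condition (any residual
  round-off clamp beyond 10⁻⁹ triggers a warning).
- **Elasticity**: P1 vector elements, plane strain, u = 0 on the outer mesh
  boundary (far-field fixation); element stresses by Hooke's law with
  σ_zz = ν(σ_xx+σ_yy) entering the von Mises measure. The stiffness matrix
  is constant per mesh and factorized once.
- **Field transfer**: images → nodes by bilinear sampling; nodes → pixels by
  barycentric (piecewise-linear) interpolation via a Delaunay triangulation
  of the node set. Both reproduce linear fields exactly. The cell field is
  carried internally as the fraction n = N/θ; θ is applied at I/O.

## The inverse problem

For one visit pair the misfit is J = ½ Σ_{nodes∈ROI} (n_model(T) − n_obs)²,
where the ROI is the *union* of the start and end tumor extents — a
shrinking tumor is penalized for predicted residual mass outside its end
ROI. Each pair is fitted independently with constant k over its interval
(piecewise-constant treatment effect per inter-scan interval).

- **k gradient**: discrete adjoint of the split scheme — one stored forward
  run plus one backward sweep, independent of region count. The per-step
  diffusion field is frozen in the backward pass, i.e. the sensitivity of
  the mechanics (∂D/∂N through σ_VM) is neglected. This is exact at γ = 0;
  with coupling on, the error against central finite differences is below
  5% (measured ≈ 0.06% at the default coupling).
- **D₀ gradient**: forward finite difference with a 1% relative
  perturbation (absolute 10⁻⁶ fallback at D₀ = 0).
- **Optimizer**: L-BFGS-B, k ∈ [−1, 1] day⁻¹, D₀ ∈ [0, 1] mm²/day,
  unbiased start (k = 0, D₀ = 10⁻²), ftol = 10⁻¹⁴, gtol = 10⁻¹⁰, iteration
  cap 500 (best iterate returned with `converged=False` on cap).

The regional estimate is invariant to region relabeling up to optimizer
tolerance, and the objective trace along accepted iterates is
non-increasing.

## Histogram and conventional metrics

Histogram summaries (mean, median, IQR, std, 25th/75th percentile) are
computed on the area-weighted element-level distribution of k, not on the
0.1 day⁻¹ bins (bins are kept for plotting only), with a weighted-quantile
rule that reduces to the standard linear-interpolation quantile at equal
weights. Conventional metrics are the ROI's longest in-plane dimension
(convex-hull diameter), mean valid ADC over the ROI, and functional tumor
volume (voxel count × voxel volume); changes between visits default to
percent change. Pearson r and its two-sided p (t distribution, n−2 df) are
reported per metric × pair × outcome (total and in-breast RCB) with
p < 0.05 / p < 0.01 flags and no multiple-testing correction.

## Synthetic phantoms

Patient MRI from the source cohort is not redistributable, so the package
ships a generator that emulates the study's observable structure: an
elliptical breast slice; a tumor whose initial cell fraction peaks at
carrying capacity (quadratic cap, or uniform on request); a ground-truth
regional k field (k-means regions of tumor pixels, mixed signs when
heterogeneous); visits at days 0/29/96/172 (the study's median 29/67/76-day
gaps); DW signals S = 1000·exp(−b·ADC) at b ∈ {0, 100, 600, 800} s/mm² in
three identical orthogonal directions with additive Gaussian noise (Rician
bias is negligible at the SNRs used and is not modeled); DCE pre/post with
2.0× enhancement inside the tumor and 1.2× outside, straddling the 80%
threshold; and ADC spanning adc_min = 0.8×10⁻³ mm²/s (dense tumor) to free
water. The per-time tumor extent is the region above 5% of that day's peak
cellularity, so shrinking tumors keep a non-empty (relative) ROI.

Outcomes are affine in a "residual burden" basis — the final simulated
total cell count by default, or the area-weighted mean of the true k field
— shifted so the cohort minimum sits at RCB = 0 and scaled to span 0–3.32,
with optional additive noise (clipped at 0). The affine map makes the
noise-free Pearson correlation between basis and outcome exactly 1 and
gives the most-responsive patient an exact pathological complete response.
With `shared_heterogeneity` the regional offset pattern and region layout
are shared across patients, so patients differ only by a base response rate
and *every* histogram metric is linear in the outcome basis — the
configuration used for end-to-end correlation-recovery checks.

What the phantoms do **not** emulate: realistic breast anatomy, 3D volumes,
k-space/MR physics, Rician noise, motion or registration error, and any
pathology-based RCB composition. Passing recovery tests therefore
demonstrates the correctness and stability of the estimation machinery
under the model's own assumptions, not clinical performance.

## Recovery measurement

Fits use ~5-element regions (the reconstruction granularity); phantom truth
is defined on 8 generative regions. Recovery is judged at the truth's
resolution: the fitted element field is area-averaged over each truth
region before correlating with the true rates. At the reconstruction
granularity the end-time-only misfit leaves rim regions with near-zero
cellularity weakly constrained, which is a property of the inverse problem
(two observations per interval), not of the implementation.

A related identifiability limit appears for strongly responding phantoms
fitted through the full imaging chain: when the end-visit cellularity has
decayed to a few percent of capacity, its amplitude is comparable to the
raster↔nodal transfer error of the 1.5 mm discretization, and the
optimizer can absorb that error field as inflated global diffusion
(D₀ far above truth) balanced by over-negative rim rates. The fit still
reduces the misfit — the degeneracy is between explanations, not a solver
defect — and cohort-level correlations of the fitted mean/median metrics
with a linear outcome remain ≈ 0.95. Constraining D₀ to a tight
physiological box was tried and rejected: without the diffusion degree of
freedom the optimizer drives whole fits to the proliferation bound.
Cohort-level conclusions should therefore rest on the area-weighted
summary metrics, which are robust to this trade-off, rather than on the
fitted D₀ itself.

## Problem sizes

Solver and gradient checks run on a 64×64 mm phantom (8 mm tumor, ~650
nodes, 29-day interval). Cohort-level checks use 6 patients with a single
fitted pair; the pipeline-contract test uses a reduced 40×40 grid with
7-day intervals and a capped iteration count, which exercises every stage
at identical code paths. These sizes were chosen to keep the full suite
fast while leaving every mechanism (coupling, noise, cohort correlation)
active at meaningful magnitudes.

## Known limitations

- 2D central-slice (slab) analysis; no 3D extension.
- The adjoint neglects mechanics sensitivity (bounded, documented above).
- Regional k near the tumor rim is weakly identified (see above); between
  strongly negative rates the logistic end state saturates near zero, so
  very responsive regions carry wide effective confidence.
- ADC_min is an extreme statistic; under heavy noise it biases the
  cellularity scale (mitigated in phantoms by a voxel at carrying
  capacity, pooled across visits per patient).
- Registration, RCB computation from pathology, and pCR classification are
  out of scope; co-registered input and RCB values are assumed given.
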