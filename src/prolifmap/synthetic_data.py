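"""Phantom patients for end-to-end testing of the proliferation pipeline.

Each phantom is a 2D central slice: an elliptical "breast" domain containing
a tumor whose ground-truth regional proliferation field drives the coupled
growth model forward over an imaging schedule mirroring the neoadjuvant
trial timing (visits at days 0/29/96/172, i.e. the median inter-scan gaps of
29, 67 and 76 days).  The simulated cellularity series is rendered into
noisy multi-b-value DW-MR signals (monoexponential decay from the implied
ADC) and pre/post-contrast DCE images (2.0x enhancement inside the tumor,
1.2x outside, straddling the 80% threshold).  Outcomes (RCB indices) are a
calibrated affine function of the simulated residual burden so that
correlation recovery is testable.

Noise is additive Gaussian on signal magnitudes; Rician bias is negligible
at the SNRs used and is deliberately not modeled.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import ndimage
from sklearn.cluster import KMeans

from . import image_prep
from .forward_model import ModelParams, run_forward
from .mesh import build_mesh, nodal_to_raster, raster_to_nodal, tumor_elements

#: Default acquisition days: baseline, +29 d, +67 d, +76 d (median gaps).
DEFAULT_SCHEDULE = (0.0, 29.0, 96.0, 172.0)

#: Acquired diffusion weightings, s/mm^2.
DEFAULT_B_VALUES = (0.0, 100.0, 600.0, 800.0)

#: Unweighted DW signal, arbitrary units.
S0_SIGNAL = 1000.0

#: DCE contrast enhancement inside / outside the tumor ROI.
ENHANCE_IN, ENHANCE_OUT = 2.0, 1.2

#: Span of the RCB index in the emulated cohort (Table-1-like range).
RCB_SPAN = 3.32

#: Margin of host tissue meshed around the tumor, mm.
MESH_MARGIN_MM = 10.0


@dataclass
class RCBOutcome:
    rcb_total: float
    rcb_in_breast: float
    is_pcr: bool

    def __post_init__(self):
        if self.rcb_total < 0 or self.rcb_in_breast < 0:
            raise ValueError("RCB indices must be >= 0")
        if self.is_pcr != (self.rcb_total == 0.0):
            raise ValueError("is_pcr must hold exactly when rcb_total == 0")


@dataclass
class PhantomTruth:
    domain_mask: np.ndarray  # breast slice
    roi_mask_per_time: list  # tumor extent per time point
    true_k_map: np.ndarray  # per-pixel rate, day^-1 (0 outside tumor)
    region_map: np.ndarray  # per-pixel region index (-1 outside tumor)
    true_k_regions: np.ndarray  # rate per region
    n0_frac: np.ndarray  # initial cell fraction N/theta per pixel
    true_D0: float  # mm^2/day
    pixel_spacing: tuple[float, float]  # mm
    slice_thickness: float  # mm
    schedule: list  # acquisition days, 0 first

    def __post_init__(self):
        sched = np.asarray(self.schedule, float)
        if sched[0] != 0 or np.any(np.diff(sched) <= 0):
            raise ValueError("schedule must be strictly increasing from day 0")
        if min(self.pixel_spacing) <= 0:
            raise ValueError("pixel_spacing must be > 0")
        for roi in self.roi_mask_per_time:
            if np.any(roi & ~self.domain_mask):
                raise ValueError("ROI must lie inside the breast domain")


@dataclass
class ImagingStudy:
    dw_signals: list  # per time: (n_b, 3, H, W)
    b_values: np.ndarray  # s/mm^2, includes 0
    dce_pre: list  # per time: (H, W)
    dce_post: list
    outcome: RCBOutcome | None
    seed: int
    pixel_spacing: tuple[float, float] = (1.0, 1.0)
    slice_thickness: float = 1.0


@dataclass
class SimulatedSeries:
    """Forward-simulated cellularity rasters plus the FEM objects behind them."""

    times: np.ndarray
    cell_maps: list  # per time: (H, W) cells/voxel
    theta: float
    mesh: object
    nodal_frac: list  # per time: nodal cell fraction
    k_elem: np.ndarray  # per-element true rate used in the run


def make_phantom(
    grid_shape=(64, 64),
    pixel_spacing=(1.0, 1.0),
    tumor_spec=None,
    k_field_spec=None,
    D0: float = 5e-3,
    seed: int = 0,
) -> PhantomTruth:
    """Build a phantom breast slice with a regional proliferation field.

    ``tumor_spec``: dict with ``center_mm`` (default: grid center),
    ``radius_mm`` (default 5) and optional ``axes_mm`` for an ellipse.
    ``k_field_spec``: either ``{"k": rate}`` for a uniform field or
    ``{"values": [...]}`` for one rate per k-means region of tumor pixels
    (``{"n_regions": n, "k_range": (lo, hi)}`` draws them from a seeded RNG;
    heterogeneous specs get at least one positive and one negative rate).
    """
    h, w = grid_shape
    sy, sx = pixel_spacing[1], pixel_spacing[0]
    tumor_spec = dict(tumor_spec or {})
    k_field_spec = dict(k_field_spec or {"k": 0.0})
    rng = np.random.default_rng(seed)

    yy, xx = np.mgrid[0:h, 0:w]
    x_mm, y_mm = xx * sx, yy * sy
    cx, cy = (w - 1) * sx / 2.0, (h - 1) * sy / 2.0
    ax_b, ay_b = 0.48 * (w - 1) * sx, 0.48 * (h - 1) * sy
    domain = ((x_mm - cx) / ax_b) ** 2 + ((y_mm - cy) / ay_b) ** 2 <= 1.0

    tcx, tcy = tumor_spec.get("center_mm", (cx, cy))
    if "axes_mm" in tumor_spec:
        tax, tay = tumor_spec["axes_mm"]
    else:
        tax = tay = tumor_spec.get("radius_mm", 5.0)
    r2 = ((x_mm - tcx) / tax) ** 2 + ((y_mm - tcy) / tay) ** 2
    tumor = r2 <= 1.0
    if not tumor.any():
        raise ValueError("tumor specification produced an empty ROI")
    if np.any(tumor & ~domain):
        raise ValueError("tumor extends outside the breast domain")

    # initial cell fraction: quadratic cap peaking at carrying capacity, or a
    # uniform fill when the spec asks for one (flat fields make closed-form
    # growth checks exact away from the rim)
    if "uniform_n0" in tumor_spec:
        n0 = np.where(tumor, float(tumor_spec["uniform_n0"]), 0.0)
    else:
        n0 = np.where(tumor, np.clip(1.0 - r2, 0.0, 1.0), 0.0)

    region_map = np.full((h, w), -1, dtype=int)
    if "k" in k_field_spec:
        k_regions = np.array([float(k_field_spec["k"])])
        region_map[tumor] = 0
    else:
        if "values" in k_field_spec:
            k_regions = np.asarray(k_field_spec["values"], float)
        else:
            nr = int(k_field_spec["n_regions"])
            lo, hi = k_field_spec.get("k_range", (-0.15, 0.1))
            k_regions = rng.uniform(lo, hi, size=nr)
            if nr >= 2:  # heterogeneous: force mixed signs
                k_regions[np.argmin(k_regions)] = min(lo, -abs(lo))
                k_regions[np.argmax(k_regions)] = max(hi, abs(hi))
        nr = k_regions.size
        pix = np.column_stack([x_mm[tumor], y_mm[tumor]])
        if nr == 1:
            labels = np.zeros(pix.shape[0], dtype=int)
        else:
            km = KMeans(n_clusters=nr, n_init=10, random_state=seed)
            raw = km.fit_predict(pix)
            order = np.lexsort((km.cluster_centers_[:, 1], km.cluster_centers_[:, 0]))
            relabel = np.empty(nr, dtype=int)
            relabel[order] = np.arange(nr)
            labels = relabel[raw]
        region_map[tumor] = labels
    true_k_map = np.where(region_map >= 0, k_regions[np.maximum(region_map, 0)], 0.0)

    return PhantomTruth(
        domain_mask=domain,
        roi_mask_per_time=[tumor],
        true_k_map=true_k_map,
        region_map=region_map,
        true_k_regions=k_regions,
        n0_frac=n0,
        true_D0=float(D0),
        pixel_spacing=tuple(pixel_spacing),
        slice_thickness=1.0,
        schedule=list(DEFAULT_SCHEDULE),
    )


def mesh_domain_mask(phantom: PhantomTruth) -> np.ndarray:
    """Tumor plus a 1 cm host-tissue margin, clipped to the breast mask."""
    sy = phantom.pixel_spacing[1]
    r_pix = max(1, int(round(MESH_MARGIN_MM / sy)))
    yy, xx = np.mgrid[-r_pix : r_pix + 1, -r_pix : r_pix + 1]
    disc = xx**2 + yy**2 <= r_pix**2
    dilated = ndimage.binary_dilation(phantom.roi_mask_per_time[0], structure=disc)
    return dilated & phantom.domain_mask


def simulate_cellularity_series(
    phantom: PhantomTruth,
    params: ModelParams,
    schedule=None,
    target_edge_mm: float = 1.5,
) -> SimulatedSeries:
    """Forward-simulate the phantom's cellularity at the scheduled days.

    Builds the FEM mesh over the tumor + margin domain, runs the coupled
    model with the phantom's true k field and D0, and rasterizes the nodal
    series back onto the pixel grid.  Updates ``phantom.roi_mask_per_time``
    with the simulated tumor extent at each day (pixels above 5% of that
    day's peak cellularity).
    """
    schedule = list(phantom.schedule if schedule is None else schedule)
    spacing = phantom.pixel_spacing
    domain = mesh_domain_mask(phantom)
    m = build_mesh(domain, spacing, target_edge_mm, roi_mask=phantom.roi_mask_per_time[0])

    n0 = raster_to_nodal(phantom.n0_frac, m, spacing)
    k_img = phantom.true_k_map
    # element rate = true rate at the centroid pixel (piecewise constant)
    cent = m.centroids()
    jj = np.clip(np.round(cent[:, 0] / spacing[0]).astype(int), 0, k_img.shape[1] - 1)
    ii = np.clip(np.round(cent[:, 1] / spacing[1]).astype(int), 0, k_img.shape[0] - 1)
    k_elem = k_img[ii, jj]

    p = ModelParams(
        D0=phantom.true_D0,
        gamma=params.gamma,
        lam=params.lam,
        E=params.E,
        nu=params.nu,
        theta=params.theta,
        dt=params.dt,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("error", RuntimeWarning)
        try:
            series = run_forward(
                n0, k_elem, p, schedule[-1], mesh=m, record_days=schedule,
                input_is_fraction=True,
            )
        except RuntimeWarning as exc:
            raise ValueError(
                f"unstable forward step within days 0..{schedule[-1]:g}: {exc}"
            ) from exc

    cell_maps, rois = [], []
    for n_frac in series.n_frac:
        img = nodal_to_raster(n_frac, m, phantom.domain_mask.shape, spacing)
        img = np.clip(img, 0.0, 1.0) * p.theta
        img[~domain] = 0.0
        cell_maps.append(img)
        peak = img.max()
        roi = (img >= 0.05 * peak) & (img > 0) if peak > 0 else np.zeros_like(domain)
        rois.append(roi & phantom.domain_mask)
    phantom.roi_mask_per_time = rois
    return SimulatedSeries(
        times=np.asarray(schedule, float),
        cell_maps=cell_maps,
        theta=p.theta,
        mesh=m,
        nodal_frac=series.n_frac,
        k_elem=k_elem,
    )


def implied_adc(cell_map: np.ndarray, theta: float, adc_min: float) -> np.ndarray:
    """ADC implied by a cellularity map: linear between free water and adc_min."""
    adc_w = image_prep.ADC_WATER
    if np.any(cell_map > theta * (1 + 1e-9)):
        raise ValueError("cellularity exceeds the carrying capacity")
    return adc_w - (cell_map / theta) * (adc_w - adc_min)


def render_images(
    series: SimulatedSeries,
    phantom: PhantomTruth,
    noise_sigma: float = 0.0,
    adc_min: float = 0.8e-3,
    seed: int = 0,
) -> ImagingStudy:
    """Render the simulated series into DW and DCE images.

    DW signal per direction: S_i = S0 * exp(-b * ADC) + N(0, noise_sigma);
    the implied ADC maps cellularity 0 to free water (3e-3 mm^2/s) and
    carrying capacity to ``adc_min``.  DCE post-contrast is 2.0x pre inside
    the current tumor ROI and 1.2x outside (before noise).
    """
    if not adc_min < image_prep.ADC_WATER:
        raise ValueError("adc_min must be below the free-water ADC")
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    rng = np.random.default_rng(seed)
    b_values = np.asarray(DEFAULT_B_VALUES)
    dw_all, pre_all, post_all = [], [], []
    for t_idx, cell_map in enumerate(series.cell_maps):
        adc = implied_adc(cell_map, series.theta, adc_min)
        sig = S0_SIGNAL * np.exp(-b_values[:, None, None] * adc[None])  # (n_b, H, W)
        sig = np.repeat(sig[:, None], 3, axis=1)  # identical across directions
        if noise_sigma > 0:
            sig = sig + rng.normal(0.0, noise_sigma, size=sig.shape)
        dw_all.append(sig)

        pre = np.full(cell_map.shape, 100.0)
        roi = phantom.roi_mask_per_time[t_idx]
        post = pre * np.where(roi, ENHANCE_IN, ENHANCE_OUT)
        if noise_sigma > 0:
            dce_sigma = noise_sigma * 100.0 / S0_SIGNAL  # same relative level
            pre = pre + rng.normal(0.0, dce_sigma, size=pre.shape)
            post = post + rng.normal(0.0, dce_sigma, size=post.shape)
        pre_all.append(pre)
        post_all.append(post)
    return ImagingStudy(
        dw_signals=dw_all,
        b_values=b_values,
        dce_pre=pre_all,
        dce_post=post_all,
        outcome=None,
        seed=seed,
        pixel_spacing=phantom.pixel_spacing,
        slice_thickness=phantom.slice_thickness,
    )


@dataclass
class ResponseSpec:
    """Cohort response structure for :func:`make_cohort`.

    Patients span base proliferation rates over ``base_rate_range`` with
    per-region heterogeneity; one complete responder (uniform strong decay)
    is included by default.  Outcomes are affine in the chosen basis
    quantity — final simulated burden (default) or the area-weighted mean of
    the true proliferation field — shifted so the cohort minimum sits at
    RCB = 0 and scaled to span the emulated clinical range (0..3.32), with
    optional additive outcome noise.
    """

    n_regions: int = 8
    base_rate_range: tuple = (-0.12, 0.08)
    heterogeneity: float = 0.05
    #: share one regional offset pattern across patients (patients then
    #: differ only by their base rate, a pure response-magnitude cohort)
    shared_heterogeneity: bool = False
    include_complete_responder: bool = True
    outcome_basis: str = "final_burden"  # or "mean_proliferation"
    outcome_noise: float = 0.0
    dw_noise_sigma: float = 0.0
    grid_shape: tuple = (48, 48)
    tumor_radius_mm: float = 7.0
    true_D0: float = 5e-3
    schedule: tuple = DEFAULT_SCHEDULE


def outcomes_from_basis(basis_values, spec: ResponseSpec, rng) -> list:
    """Affine outcome map: RCB = span * (v - min v) / (max v - min v) + noise."""
    v = np.asarray(basis_values, float)
    spread = v.max() - v.min()
    if spread <= 0:
        scaled = np.zeros_like(v)
    else:
        scaled = RCB_SPAN * (v - v.min()) / spread
    in_breast = 0.9 * scaled
    if spec.outcome_noise > 0:
        scaled = np.maximum(0.0, scaled + rng.normal(0, spec.outcome_noise, v.size))
        in_breast = np.maximum(0.0, in_breast + rng.normal(0, spec.outcome_noise, v.size))
    return [
        RCBOutcome(
            rcb_total=float(t), rcb_in_breast=float(b), is_pcr=bool(t == 0.0)
        )
        for t, b in zip(scaled, in_breast)
    ]


def make_cohort(
    n_patients: int,
    response_spec: ResponseSpec | None = None,
    seed: int = 0,
    params: ModelParams | None = None,
):
    """Generate ``n_patients`` phantom studies with correlated outcomes.

    Returns ``(patients, sim_series)`` where ``patients`` is a list of
    ``(PhantomTruth, ImagingStudy, RCBOutcome)`` and ``sim_series`` the
    matching :class:`SimulatedSeries` (kept for truth-based checks).
    """
    if n_patients < 3:
        raise ValueError("need at least 3 patients for a defined correlation")
    spec = response_spec or ResponseSpec()
    if params is None:
        theta, _ = image_prep.carrying_capacity((1.0, 1.0), 1.0)
        params = ModelParams(theta=theta)
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_patients + 2)]
    rng_outcome = np.random.default_rng(child_seeds[-2])
    shared_offsets = np.random.default_rng(child_seeds[-1]).uniform(
        -spec.heterogeneity, spec.heterogeneity, spec.n_regions
    )

    phantoms, sims, basis = [], [], []
    base_rates = np.linspace(*spec.base_rate_range, n_patients)
    for i in range(n_patients):
        p_seed = child_seeds[i]
        rng_i = np.random.default_rng(p_seed)
        if i == 0 and spec.include_complete_responder:
            k_values = np.full(spec.n_regions, -0.15)
        elif spec.shared_heterogeneity:
            k_values = base_rates[i] + shared_offsets
        else:
            offsets = rng_i.uniform(-spec.heterogeneity, spec.heterogeneity, spec.n_regions)
            k_values = base_rates[i] + offsets
        # with a shared offset pattern the region layout is shared too, so
        # patients are exact translates of one another in rate space
        layout_seed = child_seeds[-1] if spec.shared_heterogeneity else p_seed
        phantom = make_phantom(
            grid_shape=spec.grid_shape,
            tumor_spec={"radius_mm": spec.tumor_radius_mm},
            k_field_spec={"values": k_values},
            D0=spec.true_D0,
            seed=layout_seed,
        )
        phantom.schedule = list(spec.schedule)
        sim = simulate_cellularity_series(phantom, params)
        phantoms.append(phantom)
        sims.append(sim)
        if spec.outcome_basis == "final_burden":
            basis.append(float(sim.cell_maps[-1].sum()))
        elif spec.outcome_basis == "mean_proliferation":
            tumor = phantom.region_map >= 0
            basis.append(float(phantom.true_k_map[tumor].mean()))
        else:
            raise ValueError(f"unknown outcome_basis {spec.outcome_basis!r}")

    outcomes = outcomes_from_basis(basis, spec, rng_outcome)
    patients = []
    for i, (phantom, sim) in enumerate(zip(phantoms, sims)):
        study = render_images(
            sim, phantom, noise_sigma=spec.dw_noise_sigma, seed=child_seeds[i]
        )
        study.outcome = outcomes[i]
        patients.append((phantom, study, outcomes[i]))
    return patients, sims


def truth_region_recovery(k_regions_fit, partition, mesh, phantom: PhantomTruth):
    """Project a fitted regional k map onto the phantom's ground-truth regions.

    The fit's spatial resolution (k-means regions of ~5 elements) is finer
    than the phantom's generative regions; recovery is judged at the truth's
    resolution by area-weighted averaging of the fitted element field over
    each truth region.  Returns ``(k_estimated, k_true)`` per truth region.
    """
    sy, sx = phantom.pixel_spacing[1], phantom.pixel_spacing[0]
    cent = mesh.centroids()[partition.element_ids]
    jj = np.clip(np.round(cent[:, 0] / sx).astype(int), 0, phantom.region_map.shape[1] - 1)
    ii = np.clip(np.round(cent[:, 1] / sy).astype(int), 0, phantom.region_map.shape[0] - 1)
    truth_region = phantom.region_map[ii, jj]
    k_fit_elem = np.asarray(k_regions_fit, float)[partition.region_of_element]
    areas = mesh.areas()[partition.element_ids]
    nr = phantom.true_k_regions.size
    acc = np.zeros(nr)
    wsum = np.zeros(nr)
    sel = truth_region >= 0
    np.add.at(acc, truth_region[sel], (k_fit_elem * areas)[sel])
    np.add.at(wsum, truth_region[sel], areas[sel])
    covered = wsum > 0
    est = np.full(nr, np.nan)
    est[covered] = acc[covered] / wsum[covered]
    return est[covered], phantom.true_k_regions[covered]


# -- disk I/O ----------------------------------------------------------------


def save_cohort(patients, outdir):
    """Write a cohort to ``outdir``: NIfTI images per patient + outcomes CSV.

    Truth (k map, masks, schedule) goes to ``truth.json`` + NIfTI so
    recovery tests can reload it.
    """
    import nibabel as nib
    import pandas as pd
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for idx, (phantom, study, outcome) in enumerate(patients):
        pdir = outdir / f"patient_{idx:02d}"
        pdir.mkdir(exist_ok=True)
        sx, sy = phantom.pixel_spacing
        affine = np.diag([sx, sy, phantom.slice_thickness, 1.0])

        def save(name, arr):
            nib.save(nib.Nifti1Image(np.asarray(arr, np.float64), affine), pdir / name)

        for t, sig in enumerate(study.dw_signals):
            save(f"dw_t{t}.nii", np.moveaxis(sig, (0, 1), (2, 3)))  # (H, W, n_b, 3)
        for t in range(len(study.dce_pre)):
            save(f"dce_pre_t{t}.nii", study.dce_pre[t])
            save(f"dce_post_t{t}.nii", study.dce_post[t])
        save("true_k_map.nii", phantom.true_k_map)
        for t, roi in enumerate(phantom.roi_mask_per_time):
            save(f"roi_t{t}.nii", roi.astype(np.float64))
        save("domain_mask.nii", phantom.domain_mask.astype(np.float64))
        with open(pdir / "truth.json", "w") as fh:
            json.dump(
                {
                    "schedule": list(map(float, phantom.schedule)),
                    "true_D0": phantom.true_D0,
                    "true_k_regions": [float(v) for v in phantom.true_k_regions],
                    "pixel_spacing": list(phantom.pixel_spacing),
                    "slice_thickness": phantom.slice_thickness,
                    "b_values": [float(b) for b in study.b_values],
                    "seed": study.seed,
                },
                fh,
                indent=1,
            )
        rows.append(
            {
                "patient_id": f"patient_{idx:02d}",
                "rcb_total": outcome.rcb_total,
                "rcb_in_breast": outcome.rcb_in_breast,
                "is_pcr": outcome.is_pcr,
            }
        )
    pd.DataFrame(rows).to_csv(outdir / "outcomes.csv", index=False)
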