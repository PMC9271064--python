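"""Cohort correlation of response metrics with residual cancer burden.

Per patient and time-point pair the pipeline produces proliferation
histogram metrics (mean, median, IQR, std, 25th/75th percentile) and
conventional metrics (percent change in longest dimension, mean ADC, FTV).
Each metric is correlated across the cohort with total and in-breast RCB
using the Pearson coefficient and its two-sided p-value from the exact
t = r*sqrt((n-2)/(1-r^2)) reference distribution; the report tables flag
p < 0.05 (*) and p < 0.01 (**).  No multiple-testing correction is applied
— raw p-values with star flags, as is conventional for exploratory
response-biomarker tables.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import image_prep, response_metrics, synthetic_data
from .forward_model import ModelParams
from .inverse import ObservationPair, estimate
from .mesh import build_mesh, partition_regions, raster_to_nodal, tumor_elements

log = logging.getLogger(__name__)

PAIR_INDICES = {"T01": (0, 1), "T12": (1, 2), "T02": (0, 2)}

#: Default report rows: three histogram metrics plus the conventional deltas.
DEFAULT_METRICS = (
    "mean",
    "median",
    "p75",
    "delta_longest_dimension",
    "delta_mean_adc",
    "delta_ftv",
)
HISTOGRAM_METRICS = ("mean", "median", "p75", "p25", "iqr", "std")


@dataclass
class CorrelationResult:
    r: float
    p: float
    n: int
    metric: str = ""
    pair_label: str = ""
    outcome_kind: str = "total"


def pearson(x, y, **labels) -> CorrelationResult:
    """Pearson correlation with two-sided p from the t distribution (df = n-2)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    if n < 3 or y.size != n:
        raise ValueError("need n >= 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    r, p = stats.pearsonr(x, y)
    return CorrelationResult(r=float(r), p=float(p), n=n, **labels)


def p_from_r(r: float, n: int) -> float:
    """Two-sided p for a Pearson r at sample size n (t with n-2 df)."""
    if abs(r) >= 1.0:
        return 0.0
    t = abs(r) * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * stats.t.sf(t, df=n - 2))


def significance_flag(p: float) -> str:
    return "**" if p < 0.01 else ("*" if p < 0.05 else "")


# -- per-patient analysis ----------------------------------------------------


@dataclass
class PatientResult:
    patient_id: str
    theta: float = 0.0
    adc_maps: list = field(default_factory=list)
    roi_masks: list = field(default_factory=list)
    cellularity: list = field(default_factory=list)
    mesh: object = None
    partition: object = None
    fits: dict = field(default_factory=dict)
    histograms: dict = field(default_factory=dict)
    conventional: dict = field(default_factory=dict)
    outcome: object = None
    error: str | None = None


@dataclass
class PipelineConfig:
    """Everything the end-to-end synthetic pipeline needs.

    ``response`` defines the generated cohort; ``model`` the biophysics
    defaults used for fitting; ``pairs`` which time-point pairs to invert.
    """

    n_patients: int = 6
    seed: int = 0
    pairs: tuple = ("T01", "T12", "T02")
    metrics: tuple = DEFAULT_METRICS
    response: synthetic_data.ResponseSpec = field(
        default_factory=synthetic_data.ResponseSpec
    )
    target_edge_mm: float = 1.5
    elements_per_region: int = 5
    b_select: float = 800.0
    gamma: float = 1.0
    lam: float = 1.0
    E: float = 2.0
    nu: float = 0.45
    maxiter: int = 500
    delta_mode: str = "percent"

    def model_params(self, theta: float) -> ModelParams:
        return ModelParams(gamma=self.gamma, lam=self.lam, E=self.E, nu=self.nu, theta=theta)


def analyze_patient(
    phantom, study, config: PipelineConfig, patient_id: str = "patient"
) -> PatientResult:
    """Image prep, mesh, pairwise inversion and metrics for one patient."""
    res = PatientResult(patient_id=patient_id, outcome=study.outcome)
    spacing = study.pixel_spacing
    theta, _ = image_prep.carrying_capacity(spacing, study.slice_thickness)
    res.theta = theta
    params = config.model_params(theta)

    n_times = len(study.dw_signals)
    used_times = sorted({i for pair in config.pairs for i in PAIR_INDICES[pair]})
    adc_maps: list = [None] * n_times
    rois: list = [None] * n_times
    for t in used_times:
        adc = image_prep.compute_adc(study.dw_signals[t], study.b_values, config.b_select)
        adc.spacing = spacing
        # coarse seed segmentation: the truth ROI dilated by 2 px stands in
        # for the radiologist's manual outline
        from scipy import ndimage

        seed_mask = ndimage.binary_dilation(
            phantom.roi_mask_per_time[t], iterations=2
        ) & phantom.domain_mask
        roi = image_prep.segment_tumor(
            study.dce_pre[t], study.dce_post[t], seed_mask, f"T{t}", spacing
        )
        adc_maps[t] = adc
        rois[t] = roi
    res.adc_maps, res.roi_masks = adc_maps, rois

    # patient-level ADC_min pooled over the analyzed time points
    adc_min = min(
        float(np.nanmin(adc_maps[t].values[rois[t].mask & adc_maps[t].valid_mask]))
        for t in used_times
    )
    cell: list = [None] * n_times
    for t in used_times:
        cmap = image_prep.cellularity_from_adc(
            adc_maps[t], rois[t], theta, adc_min=adc_min
        )
        # fill invalid ROI voxels (unphysical DW fits under noise) with the
        # ROI median so the nodal interpolation sees no holes
        invalid = rois[t].mask & ~adc_maps[t].valid_mask
        if invalid.any():
            cmap.values[invalid] = np.median(
                cmap.values[rois[t].mask & adc_maps[t].valid_mask]
            )
        cell[t] = cmap
    res.cellularity = cell

    union_roi = np.zeros_like(phantom.domain_mask)
    for t in used_times:
        union_roi |= rois[t].mask
    domain = synthetic_data.mesh_domain_mask(phantom)
    m = build_mesh(domain, spacing, config.target_edge_mm, roi_mask=union_roi)
    elems = tumor_elements(m, union_roi, spacing)
    if elems.size == 0:
        raise ValueError("no tumor elements inside the mesh")
    part = partition_regions(m, elems, config.elements_per_region, seed=0)
    res.mesh, res.partition = m, part

    for pair_label in config.pairs:
        a, b = PAIR_INDICES[pair_label]
        interval = float(phantom.schedule[b] - phantom.schedule[a])
        n_start = np.clip(raster_to_nodal(cell[a].values / theta, m, spacing), 0, 1)
        n_end = np.clip(raster_to_nodal(cell[b].values / theta, m, spacing), 0, 1)
        pair_roi = rois[a].mask | rois[b].mask
        roi_nodes = raster_to_nodal(pair_roi.astype(float), m, spacing) >= 0.5
        pair = ObservationPair(pair_label, n_start, n_end, interval, roi_nodes)
        fit = estimate(pair, m, part, params, maxiter=config.maxiter)
        res.fits[pair_label] = fit
        res.histograms[pair_label] = response_metrics.proliferation_histogram(fit, part, m)

        conv = {}
        for name, fn in (
            ("longest_dimension", lambda t: response_metrics.longest_dimension(rois[t])),
            ("mean_adc", lambda t: response_metrics.mean_tumor_adc(adc_maps[t], rois[t])),
            (
                "ftv",
                lambda t: response_metrics.functional_tumor_volume(
                    rois[t], spacing, study.slice_thickness
                ),
            ),
        ):
            va, vb = fn(a), fn(b)
            conv[f"delta_{name}"] = response_metrics.delta_metric(
                va, vb, config.delta_mode
            )
            conv[name] = (va, vb)
        res.conventional[pair_label] = conv
    return res


def metric_value(res: PatientResult, metric: str, pair_label: str) -> float:
    if metric in HISTOGRAM_METRICS:
        return getattr(res.histograms[pair_label], metric)
    return res.conventional[pair_label][metric]


def cohort_table(results: list, pairs, metrics) -> pd.DataFrame:
    """Long-format table: one row per (patient, pair, metric)."""
    rows = []
    for res in results:
        if res.error is not None:
            continue
        for pair_label in pairs:
            for metric in metrics:
                rows.append(
                    {
                        "patient_id": res.patient_id,
                        "pair_label": pair_label,
                        "metric": metric,
                        "value": metric_value(res, metric, pair_label),
                        "rcb_total": res.outcome.rcb_total,
                        "rcb_in_breast": res.outcome.rcb_in_breast,
                    }
                )
    df = pd.DataFrame(rows)
    if not df.empty and df.duplicated(["patient_id", "pair_label", "metric"]).any():
        raise ValueError("duplicate (patient, pair, metric) keys")
    return df


def correlate_cohort(table: pd.DataFrame) -> list:
    """Pearson r/p for every metric x pair x outcome-kind cell."""
    out = []
    for (metric, pair_label), grp in table.groupby(["metric", "pair_label"], sort=False):
        grp = grp.sort_values("patient_id")
        for kind, col in (("total", "rcb_total"), ("in_breast", "rcb_in_breast")):
            try:
                out.append(
                    pearson(
                        grp["value"].to_numpy(),
                        grp[col].to_numpy(),
                        metric=metric,
                        pair_label=pair_label,
                        outcome_kind=kind,
                    )
                )
            except ValueError as exc:
                log.warning("correlation %s/%s/%s skipped: %s", metric, pair_label, kind, exc)
    return out


def build_report(cohort_results: list, metrics=DEFAULT_METRICS, pairs=("T01", "T12", "T02")):
    """r and p tables (rows = metrics, columns = pair x outcome) + star flags."""
    cols = [(pl, kind) for pl in pairs for kind in ("total", "in_breast")]
    col_names = [f"{pl}_{kind}" for pl, kind in cols]
    r_tab = pd.DataFrame(index=list(metrics), columns=col_names, dtype=float)
    p_tab = pd.DataFrame(index=list(metrics), columns=col_names, dtype=float)
    flags = pd.DataFrame("", index=list(metrics), columns=col_names)
    seen = {(c.metric, c.pair_label, c.outcome_kind): c for c in cohort_results}
    for metric in metrics:
        for (pl, kind), name in zip(cols, col_names):
            c = seen.get((metric, pl, kind))
            if c is None:
                log.warning("missing correlation cell %s/%s/%s -> NA", metric, pl, kind)
                continue
            r_tab.loc[metric, name] = c.r
            p_tab.loc[metric, name] = c.p
            flags.loc[metric, name] = significance_flag(c.p)
    text = (
        "Pearson r (metric vs RCB)\n"
        + r_tab.round(4).to_string()
        + "\n\np-values (* p<0.05, ** p<0.01)\n"
        + (p_tab.round(4).astype(str) + flags).to_string()
    )
    return r_tab, p_tab, flags, text


def run_pipeline(config: PipelineConfig | None = None, outdir=None):
    """Generate a synthetic cohort, fit all pairs, and correlate with RCB.

    Per-patient failures are isolated: the patient is excluded from the
    cohort tables with an explicit note, mirroring clinical exclusions for
    image quality or registration failure.
    """
    config = config or PipelineConfig()
    patients, _sims = synthetic_data.make_cohort(
        config.n_patients, config.response, seed=config.seed
    )
    results = []
    for idx, (phantom, study, outcome) in enumerate(patients):
        pid = f"patient_{idx:02d}"
        try:
            results.append(analyze_patient(phantom, study, config, pid))
        except Exception as exc:  # noqa: BLE001 - isolate per-patient failure
            log.warning("%s excluded: %s", pid, exc)
            res = PatientResult(patient_id=pid, outcome=outcome)
            res.error = str(exc)
            results.append(res)

    table = cohort_table(results, config.pairs, config.metrics)
    correlations = correlate_cohort(table)
    r_tab, p_tab, flags, text = build_report(correlations, config.metrics, config.pairs)

    out = {
        "config": config,
        "patients": results,
        "table": table,
        "correlations": correlations,
        "r_table": r_tab,
        "p_table": p_tab,
        "flags": flags,
        "report_text": text,
    }
    if outdir is not None:
        _write_outputs(out, patients, outdir)
    return out


def _write_outputs(out, patients, outdir):
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    synthetic_data.save_cohort(patients, outdir / "cohort")
    out["table"].to_csv(outdir / "metrics.csv", index=False)
    out["r_table"].to_csv(outdir / "correlation_r.csv")
    out["p_table"].to_csv(outdir / "correlation_p.csv")
    (outdir / "report.txt").write_text(out["report_text"])
    fits = {}
    for res in out["patients"]:
        if res.error is not None:
            fits[res.patient_id] = {"excluded": res.error}
            continue
        fits[res.patient_id] = {
            pl: {
                "k_regions": [float(v) for v in fit.k_regions],
                "D0_hat": fit.D0_hat,
                "converged": fit.converged,
                "n_iterations": fit.n_iterations,
                "final_misfit": float(fit.objective_trace[-1]),
            }
            for pl, fit in res.fits.items()
        }
    (outdir / "fits.json").write_text(json.dumps(fits, indent=1))
    try:
        save_figures(out, outdir / "figures")
    except Exception as exc:  # plotting must never sink the pipeline
        log.warning("figure output failed: %s", exc)


def save_figures(out, figdir):
    """PNG proliferation maps (rasterized k) and histograms per patient/pair."""
    from pathlib import Path

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .inverse import k_elem_from_regions
    from .mesh import nodal_to_raster

    figdir = Path(figdir)
    figdir.mkdir(parents=True, exist_ok=True)
    for res in out["patients"]:
        if res.error is not None:
            continue
        for pl, fit in res.fits.items():
            hist = res.histograms[pl]
            fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(8, 3.2))
            k_elem = k_elem_from_regions(
                fit.k_regions, res.partition, res.mesh.n_triangles
            )
            k_nodal = np.zeros(res.mesh.n_nodes)
            cnt = np.zeros(res.mesh.n_nodes)
            np.add.at(k_nodal, res.mesh.triangles.ravel(), np.repeat(k_elem, 3))
            np.add.at(cnt, res.mesh.triangles.ravel(), 1.0)
            k_nodal /= np.maximum(cnt, 1.0)
            img = nodal_to_raster(
                k_nodal, res.mesh, res.roi_masks[0].mask.shape, res.roi_masks[0].spacing,
                fill_value=np.nan,
            )
            im = ax1.imshow(img, cmap="RdYlBu_r", vmin=-0.3, vmax=0.3)
            fig.colorbar(im, ax=ax1, label="k (1/day)")
            ax1.set_title(f"{res.patient_id} {pl} proliferation")
            centers = 0.5 * (hist.bin_edges[:-1] + hist.bin_edges[1:])
            ax2.bar(centers, hist.bin_counts, width=hist.bin_width * 0.9)
            ax2.set_xlabel("k (1/day)")
            ax2.set_ylabel("tumor area (mm$^2$)")
            ax2.set_title(f"mean={hist.mean:.3f}, median={hist.median:.3f}")
            fig.tight_layout()
            fig.savefig(figdir / f"{res.patient_id}_{pl}.png", dpi=110)
            plt.close(fig)
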