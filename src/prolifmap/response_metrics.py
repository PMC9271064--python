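"""Summary metrics of estimated proliferation maps and conventional metrics.

The proliferation histogram is built over tumor elements (one value per
element, its region's rate) weighted by element area, with 0.1 day^-1 bins
for display; summary statistics (mean, median, IQR, std, 25th/75th
percentiles) are computed on the weighted empirical distribution with
linear-interpolation quantiles, not on binned midpoints, so they are free of
bin quantization.  Conventional response metrics are the tumor longest
dimension, mean tumor ADC and functional tumor volume (FTV), compared
between time points as percent (default) or absolute change.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .image_prep import ADCMap, ROIMask
from .inverse import ProliferationFit
from .mesh import RegionPartition, TriMesh

DEFAULT_BIN_WIDTH = 0.1  # day^-1


@dataclass
class HistogramSummary:
    mean: float
    median: float
    iqr: float
    std: float
    p25: float
    p75: float
    bin_width: float
    bin_edges: np.ndarray
    bin_counts: np.ndarray  # area-weighted, mm^2 per bin


def weighted_quantile(values, weights, q):
    """Weighted quantile reducing to numpy's 'linear' rule at equal weights.

    Sorted values get plotting positions s_i = (C_i - w_i) / (W - w_i)
    (C_i = cumulative weight through i), which for equal weights is
    i/(n-1); quantiles interpolate linearly between adjacent positions.
    """
    values = np.asarray(values, float)
    weights = np.asarray(weights, float)
    order = np.argsort(values, kind="stable")
    v, w = values[order], weights[order]
    if v.size == 1:
        return np.full(np.shape(q), v[0]) if np.ndim(q) else float(v[0])
    C = np.cumsum(w)
    W = C[-1]
    s = (C - w) / (W - w)
    s[-1] = 1.0  # guard against roundoff
    return np.interp(q, s, v)


def proliferation_histogram(
    fit: ProliferationFit,
    partition: RegionPartition,
    mesh: TriMesh,
    bin_width: float = DEFAULT_BIN_WIDTH,
) -> HistogramSummary:
    """Area-weighted histogram summary of a fitted proliferation map."""
    if partition.element_ids.size == 0:
        raise ValueError("empty partition")
    k_elem = np.asarray(fit.k_regions, float)[partition.region_of_element]
    areas = mesh.areas()[partition.element_ids]
    W = areas.sum()

    mean = float(np.sum(k_elem * areas) / W)
    var = float(np.sum(areas * (k_elem - mean) ** 2) / W)
    p25, median, p75 = (
        float(v) for v in weighted_quantile(k_elem, areas, [0.25, 0.5, 0.75])
    )

    lo = np.floor(k_elem.min() / bin_width) * bin_width
    hi = np.ceil(k_elem.max() / bin_width) * bin_width
    if hi <= lo:
        hi = lo + bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    counts, edges = np.histogram(k_elem, bins=edges, weights=areas)
    return HistogramSummary(
        mean=mean,
        median=median,
        iqr=p75 - p25,
        std=float(np.sqrt(var)),
        p25=p25,
        p75=p75,
        bin_width=bin_width,
        bin_edges=edges,
        bin_counts=counts,
    )


def longest_dimension(roi: ROIMask | np.ndarray, spacing=(1.0, 1.0)) -> float:
    """Maximum pairwise distance between ROI voxel centers, mm (in-plane)."""
    if isinstance(roi, ROIMask):
        spacing = roi.spacing
        mask = roi.mask
    else:
        mask = np.asarray(roi, bool)
    ii, jj = np.nonzero(mask)
    if ii.size == 0:
        raise ValueError("empty ROI")
    pts = np.column_stack([jj * spacing[0], ii * spacing[1]])
    if pts.shape[0] == 1:
        return 0.0
    # hull vertices suffice for the diameter; fall back to all points if flat
    try:
        from scipy.spatial import ConvexHull

        pts = pts[ConvexHull(pts).vertices]
    except Exception:
        pass
    d2 = np.sum((pts[:, None, :] - pts[None, :, :]) ** 2, axis=-1)
    return float(np.sqrt(d2.max()))


def mean_tumor_adc(adc_map: ADCMap, roi: ROIMask | np.ndarray) -> float:
    """Arithmetic mean of valid ADC values inside the ROI, mm^2/s."""
    mask = roi.mask if isinstance(roi, ROIMask) else np.asarray(roi, bool)
    sel = mask & adc_map.valid_mask
    if not sel.any():
        raise ValueError("ROI contains no valid ADC voxels")
    return float(adc_map.values[sel].mean())


def functional_tumor_volume(
    roi: ROIMask | np.ndarray, spacing=(1.0, 1.0), slice_thickness: float = 1.0
) -> float:
    """Enhancing-voxel count times voxel volume, mm^3."""
    if isinstance(roi, ROIMask):
        spacing = roi.spacing
        mask = roi.mask
    else:
        mask = np.asarray(roi, bool)
    return float(mask.sum()) * spacing[0] * spacing[1] * slice_thickness


def delta_metric(value_a: float, value_b: float, mode: str = "percent") -> float:
    """Change from a to b: percent (default) or absolute; shrinkage < 0."""
    if mode == "absolute":
        return value_b - value_a
    if mode == "percent":
        if value_a == 0:
            raise ValueError("percent change undefined for a baseline of 0")
        return (value_b - value_a) / value_a * 100.0
    raise ValueError(f"unknown mode {mode!r}")
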