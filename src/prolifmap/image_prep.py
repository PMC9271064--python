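"""Convert raw DW/DCE-MR images into model inputs.

The diffusion-weighted signal in direction *i* follows the monoexponential
model ``S_i = S_0 exp(-b ADC)``; averaging the per-direction log-ratios over
the three orthogonal encoding directions gives the apparent diffusion
coefficient (ADC, mm^2/s).  Cellularity is obtained from ADC by linear
interpolation between free water (ADC_w = 3e-3 mm^2/s at 37 C, zero cells)
and the densest tumor voxel (ADC_min, carrying capacity theta), where theta
is the number of close-packed 10-um spheres that fit in an imaging voxel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

#: ADC of free water at body temperature (37 C), mm^2/s.
ADC_WATER = 3.0e-3

#: Close-packing (FCC/HCP) density of equal spheres, pi/sqrt(18).
PACKING_DENSITY = 0.7405

#: Nominal tumor cell radius, micrometres.
CELL_RADIUS_UM = 10.0

#: DCE enhancement threshold: post-contrast >= 1.8x pre-contrast (an 80%
#: signal-intensity increase) marks enhancing tumor.
ENHANCEMENT_RATIO = 1.8


@dataclass
class ADCMap:
    """Per-voxel apparent diffusion coefficient (mm^2/s).

    ``values`` is NaN outside ``valid_mask`` (voxels whose signals admit no
    physical fit: non-positive, or above the b=0 signal).
    """

    values: np.ndarray
    valid_mask: np.ndarray
    spacing: tuple[float, float]


@dataclass
class ROIMask:
    """Enhancing-tumor region of interest on a single 2D slice."""

    mask: np.ndarray
    time_label: str
    spacing: tuple[float, float]


@dataclass
class CellularityMap:
    """Estimated tumor cells per voxel, defined on the ROI only."""

    values: np.ndarray
    theta: float
    adc_w: float
    adc_min: float
    time_label: str


def compute_adc(dw_signals: np.ndarray, b_values, b_select: float = 800.0) -> ADCMap:
    """Fit the ADC map from multi-b, 3-direction DW signals.

    Parameters
    ----------
    dw_signals
        Array of shape ``(n_b, 3, H, W)``: per b-value, per orthogonal
        diffusion-encoding direction.  The b=0 entry carries the unweighted
        signal S_0 (replicated across the direction axis).
    b_values
        Sequence of b-values in s/mm^2, must include 0.
    b_select
        The single non-zero b-value used for the log-ratio fit; the per-voxel
        ADC is the mean of ``ln(S_0/S_i)/b`` over the three directions.
    """
    dw_signals = np.asarray(dw_signals, dtype=float)
    b_values = np.asarray(b_values, dtype=float)
    if dw_signals.ndim != 4 or dw_signals.shape[1] != 3:
        raise ValueError("dw_signals must have shape (n_b, 3, H, W)")
    if 0.0 not in b_values:
        raise ValueError("b_values must include b=0")
    if b_select not in b_values or b_select == 0.0:
        raise ValueError(f"b_select={b_select} not among non-zero b_values")

    i0 = int(np.nonzero(b_values == 0.0)[0][0])
    ib = int(np.nonzero(b_values == b_select)[0][0])
    s0 = dw_signals[i0]  # (3, H, W); identical across directions by convention
    si = dw_signals[ib]

    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = s0 / si
        per_dir = np.log(ratio) / b_select
    invalid = (si <= 0) | (s0 <= 0) | (si > s0)
    per_dir[invalid] = np.nan
    valid = ~np.any(invalid, axis=0)
    if not valid.any():
        raise ValueError("ADC fit failed on every voxel (all signals unphysical)")
    values = per_dir.mean(axis=0)
    values[~valid] = np.nan
    return ADCMap(values=values, valid_mask=valid, spacing=(1.0, 1.0))


def segment_tumor(
    dce_pre: np.ndarray,
    dce_post: np.ndarray,
    seed_mask: np.ndarray,
    time_label: str = "T0",
    spacing: tuple[float, float] = (1.0, 1.0),
) -> ROIMask:
    """Refine a coarse tumor segmentation by the 80%-enhancement rule.

    Keeps voxels of ``seed_mask`` whose post-contrast signal is at least
    1.8x the pre-contrast signal (inclusive), then retains the largest
    8-connected component.
    """
    seed_mask = np.asarray(seed_mask, dtype=bool)
    pre = np.asarray(dce_pre, dtype=float)
    post = np.asarray(dce_post, dtype=float)
    with np.errstate(invalid="ignore"):
        enhancing = post >= ENHANCEMENT_RATIO * pre
    mask = seed_mask & enhancing
    if not mask.any():
        raise ValueError(
            "Empty ROI after 80%-enhancement refinement; review the seed mask "
            "or the enhancement threshold"
        )
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    if n > 1:
        sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
        mask = labels == (1 + int(np.argmax(sizes)))
    return ROIMask(mask=mask, time_label=time_label, spacing=spacing)


def carrying_capacity(
    pixel_spacing: tuple[float, float],
    slice_thickness: float,
    cell_radius_um: float = CELL_RADIUS_UM,
    packing_density: float = PACKING_DENSITY,
) -> tuple[float, float]:
    """Carrying capacity theta (cells/voxel) and the cell volume (um^3).

    theta = packing_density * voxel_volume / cell_volume with spherical cells
    of the given radius; spacing and thickness are in mm.
    """
    sx, sy = pixel_spacing
    if sx <= 0 or sy <= 0 or slice_thickness <= 0 or cell_radius_um <= 0:
        raise ValueError("geometry inputs must be positive")
    if packing_density <= 0:
        raise ValueError("packing_density must be positive")
    cell_volume_um3 = (4.0 / 3.0) * np.pi * cell_radius_um**3
    voxel_volume_um3 = (sx * 1e3) * (sy * 1e3) * (slice_thickness * 1e3)
    theta = packing_density * voxel_volume_um3 / cell_volume_um3
    return theta, cell_volume_um3


def cellularity_from_adc(
    adc_map: ADCMap,
    roi: ROIMask,
    theta: float,
    adc_w: float = ADC_WATER,
    adc_min: float | None = None,
) -> CellularityMap:
    """Estimate tumor cell number per voxel from ADC inside the ROI.

    ``N = theta * (ADC_w - ADC) / (ADC_w - ADC_min)``, clamped to [0, theta].
    ADC_min defaults to the minimum valid ADC inside the ROI (the densest
    voxel); pass the patient-level minimum pooled over time points for a
    consistent scale across a longitudinal series.
    """
    mask = roi.mask & adc_map.valid_mask
    if not mask.any():
        raise ValueError("ROI contains no valid ADC voxels")
    if adc_min is None:
        adc_min = float(np.nanmin(adc_map.values[mask]))
    if adc_min >= adc_w:
        raise ValueError(
            f"ADC_min={adc_min:g} >= ADC_w={adc_w:g}: degenerate cellularity scale"
        )
    values = np.zeros_like(adc_map.values, dtype=float)
    adc = adc_map.values[mask]
    n = theta * (adc_w - adc) / (adc_w - adc_min)
    values[mask] = np.clip(n, 0.0, theta)
    return CellularityMap(
        values=values,
        theta=theta,
        adc_w=adc_w,
        adc_min=adc_min,
        time_label=roi.time_label,
    )


def extract_central_slice(volume_stack, roi_stack):
    """Pick the central tumor slice at baseline and apply it to all times.

    ``volume_stack`` is a sequence of per-time 3D arrays (z, H, W) — or 2D
    arrays, which pass through unchanged.  The slice index is the midpoint of
    the baseline ROI's z-extent.
    """
    first = np.asarray(volume_stack[0])
    if first.ndim == 2:
        return [np.asarray(v) for v in volume_stack]
    roi0 = np.asarray(roi_stack[0], dtype=bool)
    zs = np.nonzero(roi0.any(axis=(1, 2)))[0]
    if zs.size == 0:
        raise ValueError("baseline ROI is empty; cannot locate the tumor midpoint")
    z = int((zs.min() + zs.max()) // 2)
    return [np.asarray(v)[z] for v in volume_stack]
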