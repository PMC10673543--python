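"""Per-animal processing pipeline: stacks -> pH map -> acidity score.

Thin orchestration over cestproc (spline ST extraction, B0 correction,
contrast-difference maps), calibration (ratio -> pH) and phmap (pH map,
acidity score).  Used by the CLI, the analysis drivers and the recovery
tests; all numerical work lives in the underlying modules.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .calibration import CalibrationCurve
from .cestproc import DEFAULT_SMOOTHING, DEFAULT_ST_FLOOR, process_stack_pair
from .phantom import AnimalScan
from .phmap import DEFAULT_ACIDITY_BINS, AcidityMap, PHeMap, compute_acidity, compute_phe_map

__all__ = ["AnimalResult", "process_animal"]


@dataclass
class AnimalResult:
    phe: PHeMap
    acidity: AcidityMap
    maps: dict  # per-offset STMap / DeltaSTMap products
    qc: dict  # per-animal QC summary


def process_animal(
    scan: AnimalScan,
    curve: CalibrationCurve,
    mask: np.ndarray | None = None,
    label_offsets: tuple[float, float] = (4.2, 5.5),
    smoothing: float = DEFAULT_SMOOTHING,
    noise_floor: float = DEFAULT_ST_FLOOR,
    acidity_bins: tuple[float, float] = DEFAULT_ACIDITY_BINS,
) -> AnimalResult:
    """Run the full Z-spectrum -> pHe -> acidity chain on one animal."""
    mask = scan.truth.tumor_mask if mask is None else mask
    offsets = np.asarray(scan.pre.protocol.offsets)
    maps = process_stack_pair(
        scan.pre.voxels, scan.pre.s0, scan.post.voxels, scan.post.s0,
        offsets, mask, label_offsets=label_offsets,
        smoothing=smoothing, noise_floor=noise_floor,
    )
    o42, o55 = label_offsets
    phe = compute_phe_map(maps[o42]["delta"], maps[o55]["delta"], curve, mask)
    acidity = compute_acidity(phe, acidity_bins)
    qc = {
        "n_mask": int(mask.sum()),
        "coverage": phe.coverage,
        "mean_pHe": phe.mean_pHe,
        "acidity_score": acidity.acidity_score,
        "mean_st42_post": float(np.nanmean(maps[o42]["st_post"].values[mask])),
        "mean_st55_post": float(np.nanmean(maps[o55]["st_post"].values[mask])),
        "mean_dst42": float(np.nanmean(maps[o42]["delta"].values[mask])),
        "mean_dst55": float(np.nanmean(maps[o55]["delta"].values[mask])),
        "frac_reliable": float(maps[o42]["delta"].reliability[mask].mean()),
        "median_water_shift": float(np.nanmedian(maps["water_shift"][mask])),
    }
    return AnimalResult(phe=phe, acidity=acidity, maps=maps, qc=qc)
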