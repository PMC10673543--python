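"""Ratiometric pH maps and the acidity score.

The ratio of the two iopamidol contrast-difference maps (4.2 over 5.5 ppm)
is inverted through the monotone calibration curve to give extracellular pH
per voxel.  The acidity score condenses the intratumoral pH distribution
into a 1-3 scale (1 = least acidic, 3 = most acidic) by classing voxels
against two pH thresholds and averaging the class over the tumor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .calibration import CalibrationCurve
from .cestproc import DeltaSTMap

__all__ = [
    "DEFAULT_ACIDITY_BINS",
    "PHeMap",
    "AcidityMap",
    "compute_phe_map",
    "compute_acidity",
    "save_montage",
]

#: default class thresholds (t_low, t_high): voxels at or above t_high are
#: class 1, below t_low class 3.  Solid-tumor pHe typically sits around
#: 6.5-6.8, so these bins straddle the clinically interesting band.  The
#: thresholds are a package reconstruction, overridable in config.
DEFAULT_ACIDITY_BINS = (6.7, 6.9)


@dataclass
class PHeMap:
    """Pixel-wise extracellular pH over a tumor ROI.

    ``values`` is NaN outside the mask, on unreliable voxels and where the
    measured ratio fell outside the calibration range; ``coverage`` is the
    fraction of mask voxels with a defined pH; ``mean_pHe`` averages the
    defined voxels only (NaN when none are defined).
    """

    values: np.ndarray
    mean_pHe: float
    coverage: float
    mask: np.ndarray


@dataclass
class AcidityMap:
    classes: np.ndarray  # 1 | 2 | 3 on defined voxels, 0 elsewhere
    acidity_score: float  # mean class over defined voxels, in [1, 3]


def compute_phe_map(
    d42: DeltaSTMap, d55: DeltaSTMap, curve: CalibrationCurve, mask: np.ndarray
) -> PHeMap:
    """Invert the delta-ST ratio to pH on reliable tumor voxels.

    A voxel contributes when it is inside the mask, reliable in both
    contrast maps, has a non-zero 5.5 ppm denominator, and its ratio maps
    inside the calibration's valid range; everything else is excluded and
    reflected in ``coverage``.
    """
    if d42.values.shape != d55.values.shape or d42.values.shape != mask.shape:
        raise ValueError("delta-ST maps and mask must share one geometry")
    n_mask = int(mask.sum())
    if n_mask == 0:
        raise ValueError("empty tumor mask")
    ok = mask & d42.reliability & d55.reliability
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(ok & (d55.values != 0), d42.values / d55.values, np.nan)
    values = np.full(mask.shape, np.nan)
    values[ok] = curve.invert(ratio[ok])
    defined = np.isfinite(values)
    coverage = float(defined.sum() / n_mask)
    mean = float(values[defined].mean()) if defined.any() else float("nan")
    return PHeMap(values=values, mean_pHe=mean, coverage=coverage, mask=mask)


def compute_acidity(
    phe: PHeMap, bins: tuple[float, float] = DEFAULT_ACIDITY_BINS
) -> AcidityMap:
    """Class voxels into 3 acidity levels and average.

    class 1 : pH >= t_high      (least acidic)
    class 2 : t_low <= pH < t_high
    class 3 : pH < t_low        (most acidic)
    """
    t_low, t_high = bins
    if not t_high > t_low:
        raise ValueError("acidity bins must satisfy t_high > t_low")
    defined = np.isfinite(phe.values)
    classes = np.zeros(phe.values.shape, dtype=np.int8)
    classes[defined & (phe.values >= t_high)] = 1
    classes[defined & (phe.values >= t_low) & (phe.values < t_high)] = 2
    classes[defined & (phe.values < t_low)] = 3
    score = float(classes[defined].mean()) if defined.any() else float("nan")
    return AcidityMap(classes=classes, acidity_score=score)


def save_montage(phe: PHeMap, path, title: str = "", vmin: float = 6.4,
                 vmax: float = 7.2) -> None:
    """Slice montage of a pH map (one panel per slice) as a PNG."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ns = phe.values.shape[2]
    fig, axes = plt.subplots(1, ns, figsize=(3 * ns, 3.2), squeeze=False)
    im = None
    for k in range(ns):
        ax = axes[0, k]
        im = ax.imshow(phe.values[:, :, k].T, origin="lower", cmap="jet",
                       vmin=vmin, vmax=vmax)
        ax.set_title(f"slice {k}")
        ax.axis("off")
    fig.colorbar(im, ax=axes.ravel().tolist(), label="pHe", shrink=0.8)
    if title:
        fig.suptitle(title)
    fig.savefig(path, dpi=110)
    plt.close(fig)
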