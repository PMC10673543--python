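"""Ratiometric pH calibration for iopamidol CEST.

Iopamidol carries two chemically distinct amide sites resonating at 4.2 and
5.5 ppm from water.  Both exchange rates are base-catalysed and grow with
pH, but the 5.5 ppm site exchanges several-fold faster, so its labelling
efficiency under a fixed saturation amplitude falls off at lower pH than the
4.2 ppm site.  The ratio of the two saturation-transfer contrast effects is
therefore a monotone function of pH that is, to first order, independent of
the local agent concentration -- the defining property of ratiometric CEST
pH mapping.

The calibration curve is generated from the same Bloch-McConnell forward
model used by the digital phantoms, which makes pixel-wise pH recovery an
internally consistent, testable loop.  The exchange-rate law and its
constants are package defaults with the correct monotone structure, not
literature-fitted values; override them in config for a specific agent lot,
temperature or field.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .bmsim import (
    AcquisitionProtocol,
    PoolParams,
    ValidationError,
    simulate_zspectrum,
    water_pool,
)

__all__ = [
    "ExchangeLaw",
    "IopamidolModel",
    "CalibrationCurve",
    "build_calibration",
    "invert_ratio",
    "WATER_PROTON_MM",
]

#: proton concentration of bulk water, in mM (2 x 55.4 M)
WATER_PROTON_MM = 110.8e3


@dataclass(frozen=True)
class ExchangeLaw:
    """Base-catalysed exchange: rate = k_ref * 10**(eta * (pH - ph_ref)).

    Strictly increasing in pH for eta > 0.
    """

    k_ref: float  # 1/s at ph_ref
    ph_ref: float = 7.0
    eta: float = 1.0

    def __post_init__(self) -> None:
        if self.k_ref <= 0:
            raise ValidationError("k_ref must be > 0")
        if self.eta <= 0:
            raise ValidationError("eta must be > 0 (rate law must increase with pH)")

    def rate(self, ph: float) -> float:
        return self.k_ref * 10.0 ** (self.eta * (ph - self.ph_ref))


@dataclass(frozen=True)
class IopamidolModel:
    """Two-site exchange model of iopamidol in tissue.

    Default constants are documented package defaults (correct monotone
    structure and realistic orders of magnitude), not measured values.
    """

    pool_42: PoolParams = field(
        default_factory=lambda: PoolParams("iop_4.2", 4.2, 1.2, 0.015, 0.0, 0.0)
    )
    pool_55: PoolParams = field(
        default_factory=lambda: PoolParams("iop_5.5", 5.5, 1.2, 0.010, 0.0, 0.0)
    )
    law_42: ExchangeLaw = field(default_factory=lambda: ExchangeLaw(k_ref=300.0, eta=0.9))
    law_55: ExchangeLaw = field(default_factory=lambda: ExchangeLaw(k_ref=2500.0, eta=1.0))
    concentration: float = 30.0  # mM in tissue
    protons_42: int = 2
    protons_55: int = 1

    def __post_init__(self) -> None:
        if self.pool_42.chemical_shift == self.pool_55.chemical_shift:
            raise ValidationError("the two amide sites must have distinct shifts")
        if self.concentration <= 0:
            raise ValidationError("concentration must be > 0")

    def pools_at(self, ph: float, concentration: float | None = None) -> list[PoolParams]:
        """Agent pools with pH-dependent exchange rates at a concentration."""
        conc = self.concentration if concentration is None else concentration
        f42 = self.protons_42 * conc / WATER_PROTON_MM
        f55 = self.protons_55 * conc / WATER_PROTON_MM
        return [
            replace(self.pool_42, fraction=f42, exchange_rate=self.law_42.rate(ph)),
            replace(self.pool_55, fraction=f55, exchange_rate=self.law_55.rate(ph)),
        ]

    def fingerprint_dict(self) -> dict:
        return {
            "pool_42": [self.pool_42.chemical_shift, self.pool_42.T1, self.pool_42.T2],
            "pool_55": [self.pool_55.chemical_shift, self.pool_55.T1, self.pool_55.T2],
            "law_42": [self.law_42.k_ref, self.law_42.ph_ref, self.law_42.eta],
            "law_55": [self.law_55.k_ref, self.law_55.ph_ref, self.law_55.eta],
            "concentration": self.concentration,
            "protons": [self.protons_42, self.protons_55],
        }


@dataclass
class CalibrationCurve:
    """Monotone map between the delta-ST(4.2)/delta-ST(5.5) ratio and pH."""

    ph_grid: np.ndarray
    ratio_grid: np.ndarray
    valid_range: tuple[float, float]
    protocol_fingerprint: str
    increasing: bool = True

    def __post_init__(self) -> None:
        self.ph_grid = np.asarray(self.ph_grid, dtype=float)
        self.ratio_grid = np.asarray(self.ratio_grid, dtype=float)

    @property
    def ratio_range(self) -> tuple[float, float]:
        return float(self.ratio_grid.min()), float(self.ratio_grid.max())

    def invert(self, ratio) -> np.ndarray:
        """Vectorized monotone inversion; out-of-range ratios map to NaN."""
        r = np.asarray(ratio, dtype=float)
        xp = self.ratio_grid if self.increasing else self.ratio_grid[::-1]
        fp = self.ph_grid if self.increasing else self.ph_grid[::-1]
        ph = np.interp(r, xp, fp)
        lo, hi = self.ratio_range
        out = np.where((r < lo) | (r > hi) | ~np.isfinite(r), np.nan, ph)
        return out if out.ndim else float(out)

    def to_files(self, tsv_path, json_path) -> None:
        np.savetxt(
            tsv_path,
            np.column_stack([self.ph_grid, self.ratio_grid]),
            delimiter="\t",
            header="pH\tratio",
            comments="",
        )
        meta = {
            "valid_range": list(self.valid_range),
            "protocol_fingerprint": self.protocol_fingerprint,
            "increasing": self.increasing,
        }
        with open(json_path, "w") as fh:
            json.dump(meta, fh, indent=2)

    @classmethod
    def from_files(cls, tsv_path, json_path) -> "CalibrationCurve":
        arr = np.loadtxt(tsv_path, delimiter="\t", skiprows=1)
        with open(json_path) as fh:
            meta = json.load(fh)
        return cls(
            arr[:, 0],
            arr[:, 1],
            tuple(meta["valid_range"]),
            meta["protocol_fingerprint"],
            meta["increasing"],
        )


class CalibrationError(RuntimeError):
    """Raised when no monotone calibration can be built on the grid."""


def _fingerprint(model: IopamidolModel, protocol: AcquisitionProtocol,
                 background: Sequence[PoolParams], water: PoolParams) -> str:
    payload = {
        "model": model.fingerprint_dict(),
        "protocol": protocol.fingerprint_dict(),
        "background": [
            [p.name, p.chemical_shift, p.T1, p.T2, p.fraction, p.exchange_rate]
            for p in background
        ],
        "water": [water.T1, water.T2],
    }
    return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()


def contrast_st(
    model: IopamidolModel,
    protocol: AcquisitionProtocol,
    ph: float,
    concentration: float | None = None,
    background: Sequence[PoolParams] = (),
    water: PoolParams | None = None,
) -> tuple[float, float]:
    """Contrast-difference ST at the two amide offsets for one pH.

    Mirrors the in-vivo measurement: the saturation transfer of the tissue
    with agent minus that of the same tissue without agent (the endogenous
    background cancels in the difference, as in post-minus-pre maps).
    """
    water = water or water_pool()
    offs = (model.pool_42.chemical_shift, model.pool_55.chemical_shift)
    proto2 = protocol.with_offsets(offs)
    pre = simulate_zspectrum([water, *background], proto2)
    post = simulate_zspectrum(
        [water, *background, *model.pools_at(ph, concentration)], proto2
    )
    d = pre.z_values - post.z_values  # = ST_post - ST_pre
    return float(d[0]), float(d[1])


def build_calibration(
    model: IopamidolModel,
    protocol: AcquisitionProtocol,
    ph_grid: Sequence[float],
    background: Sequence[PoolParams] = (),
    water: PoolParams | None = None,
    anchor_ph: float = 6.9,
) -> CalibrationCurve:
    """Build the ratiometric calibration curve on a pH grid.

    For each grid pH the forward model yields the contrast-difference ST at
    4.2 and 5.5 ppm; the stored quantity is their ratio (4.2 over 5.5).
    Strict monotonicity is enforced: if the full grid is not monotone the
    curve is truncated to the largest strictly monotone window containing
    ``anchor_ph``; if no such window of length >= 2 exists, the build fails.
    """
    ph = np.asarray(sorted(ph_grid), dtype=float)
    if ph.size < 2:
        raise CalibrationError("pH grid must contain at least two values")
    water = water or water_pool()

    ratios = np.empty(ph.size)
    for i, p in enumerate(ph):
        d42, d55 = contrast_st(model, protocol, p, background=background, water=water)
        if d55 <= 0:
            raise CalibrationError(
                f"non-positive 5.5 ppm contrast at pH {p:.2f}; model unusable"
            )
        ratios[i] = d42 / d55

    diffs = np.diff(ratios)
    if np.all(diffs > 0) or np.all(diffs < 0):
        lo, hi = 0, ph.size - 1
    else:
        lo, hi = _largest_monotone_window(ratios, ph, anchor_ph)
        if hi - lo < 1:
            raise CalibrationError("ratio is non-monotone over the entire pH grid")
    ph, ratios = ph[lo : hi + 1], ratios[lo : hi + 1]
    return CalibrationCurve(
        ph_grid=ph,
        ratio_grid=ratios,
        valid_range=(float(ph[0]), float(ph[-1])),
        protocol_fingerprint=_fingerprint(model, protocol, background, water),
        increasing=bool(ratios[-1] > ratios[0]),
    )


def _largest_monotone_window(
    ratios: np.ndarray, ph: np.ndarray, anchor_ph: float
) -> tuple[int, int]:
    """Indices of the largest strictly monotone run containing anchor_ph."""
    sign = np.sign(np.diff(ratios))
    best = (0, 0)
    start = 0
    for i in range(1, len(sign) + 1):
        if i == len(sign) or sign[i] != sign[start] or sign[i] == 0:
            lo, hi = start, i
            if (
                hi - lo > best[1] - best[0]
                and sign[start] != 0
                and ph[lo] - 1e-9 <= anchor_ph <= ph[hi] + 1e-9
            ):
                best = (lo, hi)
            start = i
    return best


def build_pipeline_calibration(
    model: IopamidolModel,
    protocol: AcquisitionProtocol,
    ph_grid: Sequence[float],
    background: Sequence[PoolParams] = (),
    water: PoolParams | None = None,
    smoothing: float | None = None,
    anchor_ph: float = 6.9,
) -> CalibrationCurve:
    """Calibration built through the pipeline's own measurement operator.

    Instead of reading the model ST at the exact label offsets, this
    variant simulates full Z-spectra on the protocol's offset grid and
    extracts ST via the same cubic smoothing spline used for image data,
    so any smoothing-induced amplitude bias cancels between calibration
    and measurement.  Preferred for processing simulated or acquired
    stacks; `build_calibration` remains the exact-physics reference.
    """
    from .cestproc import DEFAULT_SMOOTHING, smooth_zspectrum, st_at

    lam = DEFAULT_SMOOTHING if smoothing is None else smoothing
    ph = np.asarray(sorted(ph_grid), dtype=float)
    if ph.size < 2:
        raise CalibrationError("pH grid must contain at least two values")
    water = water or water_pool()
    o42 = model.pool_42.chemical_shift
    o55 = model.pool_55.chemical_shift

    pre = simulate_zspectrum([water, *background], protocol)
    s_pre = smooth_zspectrum(pre, lam)
    st_pre = (st_at(s_pre, o42), st_at(s_pre, o55))
    ratios = np.empty(ph.size)
    for i, p in enumerate(ph):
        post = simulate_zspectrum([water, *background, *model.pools_at(p)], protocol)
        s_post = smooth_zspectrum(post, lam)
        d42 = st_at(s_post, o42) - st_pre[0]
        d55 = st_at(s_post, o55) - st_pre[1]
        if d55 <= 0:
            raise CalibrationError(
                f"non-positive 5.5 ppm contrast at pH {p:.2f}; model unusable"
            )
        ratios[i] = d42 / d55

    diffs = np.diff(ratios)
    if np.all(diffs > 0) or np.all(diffs < 0):
        lo, hi = 0, ph.size - 1
    else:
        lo, hi = _largest_monotone_window(ratios, ph, anchor_ph)
        if hi - lo < 1:
            raise CalibrationError("ratio is non-monotone over the entire pH grid")
    ph, ratios = ph[lo : hi + 1], ratios[lo : hi + 1]
    return CalibrationCurve(
        ph_grid=ph,
        ratio_grid=ratios,
        valid_range=(float(ph[0]), float(ph[-1])),
        protocol_fingerprint=_fingerprint(model, protocol, background, water)
        + f":lam={lam}",
        increasing=bool(ratios[-1] > ratios[0]),
    )


def invert_ratio(curve: CalibrationCurve, ratio: float) -> float:
    """pH for a measured contrast ratio; NaN marks out-of-range ratios.

    Exact on grid nodes, monotone piecewise-linear between them.
    """
    return curve.invert(ratio)
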