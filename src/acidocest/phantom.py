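"""Digital mouse-tumor phantoms with known ground-truth pH.

Raw preclinical CEST scans for this kind of study are rarely deposited, so
validation rests on synthetic animals: an ellipsoidal tumor with a
spatially heterogeneous extracellular-pH field is rendered into pre- and
post-contrast CEST stacks through the same Bloch-McConnell physics used to
build the pH calibration, with a smooth B0 inhomogeneity field and Rician
magnitude noise.  Every quantity the in-vivo pipeline estimates (pixel pH,
mean pHe, acidity score, caliper diameters, survival times) has a truth
channel, which is what makes parameter-recovery tests possible.

Emulated acquisition: 7 T, CW saturation 3 uT for 5 s, 8 slices of a
128 x 128 matrix over a 30 mm field of view (reduced matrices are used
throughout the tests to keep runtimes short), offsets covering water and
both iopamidol amide resonances.  Defaults below are the package's study
conditions; they are documented in the methods note and overridable.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .bmsim import (
    AcquisitionProtocol,
    PoolParams,
    simulate_zspectrum,
    water_pool,
    default_background_pools,
    pools_fingerprint,
)
from .calibration import IopamidolModel

__all__ = [
    "default_offsets",
    "default_protocol",
    "PhantomSpec",
    "GroupEffect",
    "CESTStack",
    "GroundTruth",
    "AnimalScan",
    "generate_animal",
    "generate_cohort",
    "Cohort",
]

#: pH clip range for generated fields; matches the default calibration grid
PH_CLIP = (6.0, 7.4)

#: default acidity-class thresholds (shared with phmap)
DEFAULT_ACIDITY_BINS = (6.7, 6.9)


def default_offsets() -> np.ndarray:
    """Saturation offset grid: -10..10 ppm at 0.25 ppm, refined to 0.1 ppm
    over 3.9-5.8 ppm (the two amide labels) and +-1 ppm around water."""
    coarse = np.linspace(-10.0, 10.0, 81)
    fine_label = np.linspace(3.9, 5.8, 20)
    fine_water = np.linspace(-1.0, 1.0, 21)
    return np.unique(np.round(np.concatenate([coarse, fine_label, fine_water]), 4))


def default_protocol() -> AcquisitionProtocol:
    """7 T CW-saturation protocol: 3 uT for 5 s."""
    return AcquisitionProtocol(
        b1_amplitude=3.0,
        saturation_duration=5.0,
        field_strength=7.0,
        offsets=tuple(default_offsets()),
    )


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, pH field, agent, B0 and noise settings for one animal.

    ``tumor_semiaxes_mm`` are the in-plane/through-plane ellipsoid
    semi-axes; caliper diameters derive from them.  ``ph_gradient`` is the
    core-to-rim pH difference (positive: rim less acidic, as perfusion
    geometry suggests); ``heterogeneity_sd`` the voxel-wise pH scatter.
    """

    matrix: tuple[int, int] = (128, 128)
    n_slices: int = 8
    fov_mm: float = 30.0
    slice_thickness_mm: float = 1.5
    tumor_center: tuple[float, float, float] | None = None  # voxel coords
    tumor_semiaxes_mm: tuple[float, float, float] = (4.5, 4.0, 4.5)
    ph_mean: float = 6.75
    ph_gradient: float = 0.2
    heterogeneity_sd: float = 0.05
    agent_concentration: float = 30.0  # mM, post-contrast, tumor tissue
    b0_amplitude_ppm: float = 0.05
    snr: float = 40.0  # Rician SNR at S0; np.inf disables noise
    seed: int = 0

    def __post_init__(self) -> None:
        if self.snr <= 0:
            raise ValueError("snr must be > 0 (use np.inf for noiseless)")
        nx, ny = self.matrix
        cx, cy, cz = self.center_voxels
        rx, ry = self.tumor_semiaxes_mm[0] / self.voxel_mm, self.tumor_semiaxes_mm[1] / self.voxel_mm
        if cx - rx < 0 or cx + rx >= nx or cy - ry < 0 or cy + ry >= ny:
            raise ValueError("tumor geometry exceeds the image matrix")

    @property
    def voxel_mm(self) -> float:
        return self.fov_mm / self.matrix[0]

    @property
    def center_voxels(self) -> tuple[float, float, float]:
        if self.tumor_center is not None:
            return self.tumor_center
        return (self.matrix[0] / 2, self.matrix[1] / 2, (self.n_slices - 1) / 2)

    @property
    def caliper_diameters_mm(self) -> tuple[float, float]:
        """(longest, shortest) in-plane diameters as a caliper would read."""
        a, b, _ = self.tumor_semiaxes_mm
        return (2 * max(a, b), 2 * min(a, b))


@dataclass
class CESTStack:
    """4-D saturated image stack plus unsaturated reference."""

    voxels: np.ndarray  # (nx, ny, n_slices, n_offsets)
    s0: np.ndarray  # (nx, ny, n_slices)
    protocol: AcquisitionProtocol
    phase: str  # 'pre' | 'post'

    def __post_init__(self) -> None:
        if self.voxels.shape[-1] != len(self.protocol.offsets):
            raise ValueError("stack offset axis inconsistent with protocol")
        if self.voxels.shape[:3] != self.s0.shape:
            raise ValueError("S0 geometry inconsistent with stack")
        if np.any(self.voxels < 0) or np.any(self.s0 < 0):
            raise ValueError("signals must be non-negative")


@dataclass
class GroundTruth:
    ph_map: np.ndarray  # NaN outside tumor
    tumor_mask: np.ndarray
    b0_map: np.ndarray
    mean_ph: float
    acidity_truth: float


@dataclass
class AnimalScan:
    pre: CESTStack
    post: CESTStack
    truth: GroundTruth
    spec: PhantomSpec


# cache of simulated Z-spectrum tables keyed by physics fingerprints;
# every animal sharing protocol/model/background reuses one table
_ZTABLE_CACHE: dict = {}


def _ztable(
    protocol: AcquisitionProtocol,
    model: IopamidolModel,
    background: Sequence[PoolParams],
    water: PoolParams,
    ph_step: float = 0.02,
):
    key = (
        tuple(protocol.offsets), protocol.b1_amplitude, protocol.saturation_duration,
        protocol.field_strength, pools_fingerprint([water, *background]),
        str(sorted(model.fingerprint_dict().items())), ph_step,
    )
    if key not in _ZTABLE_CACHE:
        ph_grid = np.round(np.arange(PH_CLIP[0], PH_CLIP[1] + ph_step / 2, ph_step), 6)
        z_pre = simulate_zspectrum([water, *background], protocol).z_values
        z_post = np.empty((ph_grid.size, len(protocol.offsets)))
        for i, ph in enumerate(ph_grid):
            pools = [water, *background, *model.pools_at(ph)]
            z_post[i] = simulate_zspectrum(pools, protocol).z_values
        _ZTABLE_CACHE[key] = (ph_grid, z_pre, z_post)
    return _ZTABLE_CACHE[key]


def _smooth_field(rng: np.random.Generator, nx: int, ny: int, amplitude: float) -> np.ndarray:
    """Smooth 2-D field in [-amplitude, amplitude]: random low-order polynomial."""
    if amplitude == 0:
        return np.zeros((nx, ny))
    X, Y = np.meshgrid(np.linspace(-1, 1, nx), np.linspace(-1, 1, ny), indexing="ij")
    c = rng.normal(size=5)
    f = c[0] * X + c[1] * Y + c[2] * X * Y + c[3] * (X**2 - 1 / 3) + c[4] * (Y**2 - 1 / 3)
    peak = np.abs(f).max()
    return amplitude * f / peak if peak > 0 else f


def _shift_spectra(z: np.ndarray, offsets: np.ndarray, shifts: np.ndarray) -> np.ndarray:
    """Sample shifted spectra S(x) = Z(x - b0) at the nominal offsets.

    z: (n_voxels, n_offsets); shifts: (n_voxels,).  Linear interpolation on
    the offset grid, clamped at the edges.
    """
    x = offsets[None, :] - shifts[:, None]
    idx = np.clip(np.searchsorted(offsets, x) - 1, 0, len(offsets) - 2)
    x0 = offsets[idx]
    w = np.clip((x - x0) / (offsets[idx + 1] - x0), 0.0, 1.0)
    rows = np.arange(z.shape[0])[:, None]
    return (1 - w) * z[rows, idx] + w * z[rows, idx + 1]


def _rician(rng: np.random.Generator, signal: np.ndarray, sigma: float) -> np.ndarray:
    if sigma == 0:
        return signal.copy()
    n1 = rng.normal(0.0, sigma, signal.shape)
    n2 = rng.normal(0.0, sigma, signal.shape)
    return np.sqrt((signal + n1) ** 2 + n2**2)


def generate_animal(
    spec: PhantomSpec,
    protocol: AcquisitionProtocol | None = None,
    model: IopamidolModel | None = None,
    background: Sequence[PoolParams] | None = None,
    water: PoolParams | None = None,
    acidity_bins: tuple[float, float] = DEFAULT_ACIDITY_BINS,
) -> AnimalScan:
    """Render one animal: pre/post CEST stacks plus ground truth.

    Per voxel the composed pool system is water + endogenous background,
    with the two iopamidol pools (exchange rates set by the local truth pH)
    added in the post phase inside the tumor.  The voxel spectrum is taken
    from a cached Bloch-McConnell table (linear interpolation over a 0.02
    pH grid), shifted by the local B0 offset, scaled by S0 and degraded
    with Rician noise.  Fully reproducible from ``spec.seed``.
    """
    protocol = protocol or default_protocol()
    model = model or IopamidolModel()
    background = default_background_pools() if background is None else list(background)
    water = water or water_pool()
    rng = np.random.default_rng(spec.seed)

    nx, ny = spec.matrix
    ns = spec.n_slices
    offsets = np.asarray(protocol.offsets)
    mask, r_ell = _tumor_geometry(spec)

    # truth pH field: mean + core->rim gradient + zero-mean heterogeneity
    ph_map = np.full((nx, ny, ns), np.nan)
    mvox = np.where(mask.reshape(-1))[0]
    r = r_ell.reshape(-1)[mvox]
    base = spec.ph_mean + spec.ph_gradient * (r - r.mean())
    het = rng.normal(0.0, spec.heterogeneity_sd, mvox.size)
    if mvox.size > 1 and spec.heterogeneity_sd > 0:
        het -= het.mean()  # exact zero-mean: truth mean == ph_mean pre-clip
    ph_vox = np.clip(base + het, *PH_CLIP)
    ph_map.reshape(-1)[mvox] = ph_vox

    b0_slice = _smooth_field(rng, nx, ny, spec.b0_amplitude_ppm)
    b0_map = np.repeat(b0_slice[:, :, None], ns, axis=2)

    nvox = nx * ny * ns
    b0_flat = b0_map.reshape(-1)
    if spec.agent_concentration > 0:
        if spec.agent_concentration != model.concentration:
            model = replace(model, concentration=spec.agent_concentration)
        ph_grid, z_pre_row, z_post_tab = _ztable(protocol, model, background, water)
    else:  # no agent: the post phase is physically identical to pre
        z_pre_row = simulate_zspectrum([water, *background], protocol).z_values
    z_pre = np.broadcast_to(z_pre_row, (nvox, offsets.size)).copy()
    z_post = z_pre.copy()
    if spec.agent_concentration > 0:
        # tumor voxels in the post phase carry the agent at the local truth pH
        ti = np.searchsorted(ph_grid, ph_vox, side="right") - 1
        ti = np.clip(ti, 0, ph_grid.size - 2)
        w = ((ph_vox - ph_grid[ti]) / (ph_grid[ti + 1] - ph_grid[ti]))[:, None]
        z_post[mvox] = (1 - w) * z_post_tab[ti] + w * z_post_tab[ti + 1]

    z_pre = _shift_spectra(z_pre, offsets, b0_flat)
    z_post = _shift_spectra(z_post, offsets, b0_flat)

    s0_true = np.ones(nvox)
    sigma = 0.0 if np.isinf(spec.snr) else 1.0 / spec.snr
    pre = CESTStack(
        voxels=_rician(rng, z_pre, sigma).reshape(nx, ny, ns, -1).astype(np.float32),
        s0=_rician(rng, s0_true, sigma).reshape(nx, ny, ns).astype(np.float32),
        protocol=protocol, phase="pre",
    )
    post = CESTStack(
        voxels=_rician(rng, z_post, sigma).reshape(nx, ny, ns, -1).astype(np.float32),
        s0=_rician(rng, s0_true, sigma).reshape(nx, ny, ns).astype(np.float32),
        protocol=protocol, phase="post",
    )

    t_low, t_high = acidity_bins
    classes = np.where(ph_vox >= t_high, 1, np.where(ph_vox >= t_low, 2, 3))
    truth = GroundTruth(
        ph_map=ph_map, tumor_mask=mask, b0_map=b0_map,
        mean_ph=float(ph_vox.mean()), acidity_truth=float(classes.mean()),
    )
    return AnimalScan(pre=pre, post=post, truth=truth, spec=spec)


def _tumor_geometry(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    nx, ny = spec.matrix
    ns = spec.n_slices
    cx, cy, cz = spec.center_voxels
    ax = spec.tumor_semiaxes_mm[0] / spec.voxel_mm
    ay = spec.tumor_semiaxes_mm[1] / spec.voxel_mm
    az = spec.tumor_semiaxes_mm[2] / spec.slice_thickness_mm
    X, Y, Z = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(ns), indexing="ij")
    r = np.sqrt(((X - cx) / ax) ** 2 + ((Y - cy) / ay) ** 2 + ((Z - cz) / max(az, 1e-9)) ** 2)
    return r <= 1.0, r


# ---------------------------------------------------------------------------
# cohorts


@dataclass(frozen=True)
class GroupEffect:
    """Per-group shifts applied to the phantom template.

    ``ph_offset`` moves the group's tumor pH mean; ``growth_rate`` is the
    exponential volume growth rate in 1/day (untreated 4T1-like tumors
    roughly double their volume every ~3 days).
    """

    ph_offset: float = 0.0
    growth_rate: float = 0.22


@dataclass
class CohortAnimal:
    animal_id: str
    group: str
    spec: PhantomSpec
    event_time: float
    event_flag: bool


@dataclass
class Cohort:
    animals: list
    table: pd.DataFrame

    def render(self, animal: "CohortAnimal", **kw) -> AnimalScan:
        return generate_animal(animal.spec, **kw)


def generate_cohort(
    template: PhantomSpec,
    n_per_group: int,
    group_effects: dict[str, GroupEffect],
    seed: int = 0,
    measurement_days: Sequence[float] | None = None,
    volume_threshold_mm3: float = 800.0,
    between_animal_ph_sd: float = 0.0,
    growth_rate_sd: float = 0.03,
    initial_volume_mm3: float = 5.0,
    diameter_ratio: float = 0.8,
) -> Cohort:
    """Two-arm (or k-arm) digital cohort with caliper follow-up and survival.

    Every 2-3 days two perpendicular tumor diameters are 'measured'
    (derived from the growing ellipsoid, with 0.2 mm caliper noise) and
    body weight recorded.  Tumor volume follows V = A * B^2 / 2.  The
    humane endpoint is the first measurement day on which the volume
    exceeds ``volume_threshold_mm3`` (the protocol states this size limit
    with volume units although it calls it a diameter; it is treated as a
    volume here); animals never reaching it are censored at study end.

    Imaging specs per animal are returned un-rendered; call
    ``Cohort.render`` (or ``generate_animal``) to produce the stacks.
    """
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    if measurement_days is None:
        measurement_days = [0, 2, 5, 7, 9, 12, 14, 16, 19, 21, 23, 26, 28]
    ss = np.random.SeedSequence(seed)
    rows = []
    animals = []
    for g_i, (group, eff) in enumerate(sorted(group_effects.items())):
        for a_i in range(n_per_group):
            child = ss.spawn(1)[0]
            arng = np.random.default_rng(child)
            aid = f"{group}_{a_i:02d}"
            g = max(eff.growth_rate + arng.normal(0.0, growth_rate_sd), 0.01)
            ph_mean = template.ph_mean + eff.ph_offset + arng.normal(0.0, between_animal_ph_sd)
            spec = replace(
                template,
                ph_mean=float(np.clip(ph_mean, PH_CLIP[0] + 0.1, PH_CLIP[1] - 0.1)),
                seed=int(child.generate_state(1)[0] % (2**31)),
            )
            event_time, event_flag = None, False
            weight = 20.0 + arng.normal(0.0, 1.0)
            for day in measurement_days:
                v_true = initial_volume_mm3 * np.exp(g * day)
                a_true = (2.0 * v_true / diameter_ratio**2) ** (1.0 / 3.0)
                A = max(a_true + arng.normal(0.0, 0.2), 0.1)
                B = max(min(diameter_ratio * a_true + arng.normal(0.0, 0.2), A), 0.1)
                weight += arng.normal(0.0, 0.15)
                rows.append(
                    dict(animal_id=aid, group=group, day=day, diameter_A=A,
                         diameter_B=B, body_weight=weight)
                )
                if event_time is None and A * B**2 / 2.0 > volume_threshold_mm3:
                    event_time, event_flag = float(day), True
            if event_time is None:
                event_time, event_flag = float(measurement_days[-1]), False
            for r in rows:
                if r["animal_id"] == aid:
                    r["event_time"], r["event_flag"] = event_time, event_flag
            animals.append(CohortAnimal(aid, group, spec, event_time, event_flag))
    table = pd.DataFrame(rows)
    return Cohort(animals=animals, table=table)
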