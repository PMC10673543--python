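"""Physics-core tests: propagator correctness, invariants, water-dip finder."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from acidocest.bmsim import (
    AcquisitionProtocol,
    PoolParams,
    ValidationError,
    ZSpectrum,
    simulate_zspectrum,
    water_pool,
    water_shift_of,
    default_background_pools,
)
from bm_reference import z_reference


def proto(offsets, b1=3.0, t=5.0, field=7.0):
    return AcquisitionProtocol(b1, t, field, tuple(offsets))


class TestPropagator:
    def test_no_rf_leaves_equilibrium(self):
        pools = [water_pool(), PoolParams("amide", 3.5, 1.0, 0.01, 0.001, 50.0)]
        z = simulate_zspectrum(pools, proto([-3, 0, 3.5], b1=0.0)).z_values
        assert np.allclose(z, 1.0, atol=1e-12)

    def test_zero_duration_returns_unity(self):
        pools = [water_pool()]
        z = simulate_zspectrum(pools, proto([0.0, 4.2], t=0.0)).z_values
        assert np.allclose(z, 1.0)

    def test_no_exchange_no_transfer(self):
        # without exchange there is no transfer pathway: saturating at a
        # labile-proton offset far from a narrow water line leaves Z at 1
        # to within the 1% direct-saturation residual
        pools = [
            water_pool(T1=2.4, T2=2.0),
            PoolParams("amide", 8.0, 1.0, 0.01, 0.001, 0.0),
        ]
        z = simulate_zspectrum(pools, proto([8.0])).z_values[0]
        assert z > 0.99

    @pytest.mark.parametrize(
        "extra",
        [
            [("amide", 4.2, 1.2, 0.015, 3e-4, 600.0)],
            [
                ("amide", 4.2, 1.2, 0.015, 3e-4, 600.0),
                ("amine", 2.0, 1.0, 0.008, 5e-4, 1500.0),
            ],
        ],
        ids=["two-pool", "three-pool"],
    )
    def test_matches_explicit_ode_integration(self, extra):
        # matrix-exponential propagation vs an independently coded adaptive
        # explicit Runge-Kutta integration of the same physics
        pools = [water_pool()] + [
            PoolParams(n, s, t1, t2, f, k) for (n, s, t1, t2, f, k) in extra
        ]
        p = proto([4.2], t=2.0)
        z_fast = simulate_zspectrum(pools, p).z_values[0]
        ref_pools = [(0.0, 2.4, 0.05, 1.0, 0.0)] + [
            (s, t1, t2, f, k) for (n, s, t1, t2, f, k) in extra
        ]
        z_ref = z_reference(ref_pools, 3.0, 2.0, 7.0, 4.2)
        assert abs(z_fast - z_ref) < 1e-6

    def test_st_monotone_in_exchange_rate(self):
        # in the slow-to-intermediate regime more exchange means more
        # transfer: 1 - Z at the labile offset never decreases with k
        st = []
        for k in [5.0, 20.0, 50.0, 120.0, 300.0]:
            pools = [water_pool(), PoolParams("amide", 4.2, 1.0, 0.01, 5e-4, k)]
            z = simulate_zspectrum(pools, proto([4.2])).z_values[0]
            st.append(1.0 - z)
        assert np.all(np.diff(st) >= -1e-12)

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(
        t2w=st.floats(0.02, 1.0),
        shift=st.floats(-5.0, 5.0),
        frac=st.floats(1e-5, 0.01),
        k=st.floats(0.0, 2000.0),
        b1=st.floats(0.0, 5.0),
        tsat=st.floats(0.1, 5.0),
    )
    def test_z_in_unit_interval(self, t2w, shift, frac, k, b1, tsat):
        pools = [
            water_pool(T1=2.0, T2=t2w),
            PoolParams("solute", shift, 1.0, 0.02, frac, k),
        ]
        p = AcquisitionProtocol(b1, tsat, 7.0, (-4.0, 0.0, shift if shift != 0 else 1.0))
        z = simulate_zspectrum(pools, p).z_values
        assert np.all(z >= -1e-9) and np.all(z <= 1.0 + 1e-9)


class TestValidation:
    def test_negative_relaxation_rejected(self):
        with pytest.raises(ValidationError):
            PoolParams("bad", 0.0, -1.0, 0.1, 1.0, 0.0)

    def test_fraction_above_one_rejected(self):
        with pytest.raises(ValidationError):
            PoolParams("bad", 1.0, 1.0, 0.1, 1.5, 10.0)

    def test_requires_exactly_one_water_pool(self):
        pools = [PoolParams("a", 1.0, 1.0, 0.1, 0.001, 10.0)]
        with pytest.raises(ValidationError):
            simulate_zspectrum(pools, proto([0.0, 1.0]))

    def test_duplicate_offsets_rejected(self):
        with pytest.raises(ValidationError):
            proto([0.0, 1.0, 1.0])


class TestWaterShift:
    def _spectrum(self, shift=0.0, snr=None, seed=0):
        offs = np.linspace(-2, 2, 41)
        z = 1.0 - 0.8 * 0.1**2 / (0.1**2 + (offs - shift) ** 2)  # Lorentzian dip
        if snr:
            z = z + np.random.default_rng(seed).normal(0, 1 / snr, z.size)
        return ZSpectrum(offs, z)

    def test_symmetric_spectrum_centered_at_zero(self):
        assert water_shift_of(self._spectrum()) == pytest.approx(0.0, abs=1e-6)

    def test_translation_recovered(self):
        assert water_shift_of(self._spectrum(shift=0.3)) == pytest.approx(0.3, abs=0.01)

    def test_noisy_simulated_shift_recovered(self, background, water):
        # full-physics spectrum at B0-mapping power (1 uT: at the 3 uT
        # imaging power the dip is direct-saturation-broadened and the
        # information bound itself exceeds this accuracy) with an injected
        # 0.1 ppm offset at SNR 50; accuracy averaged over noise seeds
        p = proto(np.round(np.arange(-2, 2.001, 0.1), 3), b1=1.0)
        z = simulate_zspectrum([water, *background], p)
        offs = z.offsets
        shifted = np.interp(offs - 0.1, offs, z.z_values)
        errs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            noisy = ZSpectrum(offs, shifted + rng.normal(0, 1 / 50, offs.size))
            errs.append(water_shift_of(noisy) - 0.1)
        assert np.mean(np.abs(errs)) < 0.02

    def test_unbracketed_dip_raises(self):
        offs = np.linspace(1.0, 3.0, 21)
        z = ZSpectrum(offs, np.linspace(0.2, 0.9, 21))
        with pytest.raises(ValueError):
            water_shift_of(z)
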