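"""Z-spectrum processing: splines, ST extraction, contrast-difference maps."""

import numpy as np
import pytest

from acidocest.bmsim import PoolParams, ZSpectrum, simulate_zspectrum
from acidocest.cestproc import (
    STMap,
    delta_st,
    process_stack_pair,
    smooth_zspectrum,
    st_at,
)
from acidocest.phantom import PhantomSpec, generate_animal


class TestSmoothing:
    def test_zero_smoothing_interpolates_exactly(self):
        x = np.linspace(-5, 5, 21)
        y = 1 - 0.5 * np.exp(-((x - 1) ** 2))
        spl = smooth_zspectrum(ZSpectrum(x, y), smoothing=0.0)
        np.testing.assert_allclose(spl(x), y, atol=1e-10)

    def test_constant_spectrum_stays_constant(self):
        x = np.linspace(-5, 5, 15)
        spl = smooth_zspectrum(ZSpectrum(x, np.full(15, 0.7)), smoothing=0.1)
        np.testing.assert_allclose(spl(np.linspace(-4, 4, 50)), 0.7, atol=1e-9)

    def test_smoothing_beats_raw_noise(self, protocol, background, water):
        # spline of an SNR-40 spectrum lies closer to the noiseless truth
        # than the raw samples do
        truth = simulate_zspectrum([water, *background], protocol)
        rng = np.random.default_rng(12)
        noisy = truth.z_values + rng.normal(0, 1 / 40, truth.z_values.size)
        spl = smooth_zspectrum(ZSpectrum(truth.offsets, noisy))
        rms_raw = np.sqrt(np.mean((noisy - truth.z_values) ** 2))
        rms_spl = np.sqrt(np.mean((spl(truth.offsets) - truth.z_values) ** 2))
        assert rms_spl < rms_raw

    def test_too_few_or_unsorted_offsets_rejected(self):
        with pytest.raises(ValueError):
            smooth_zspectrum(ZSpectrum(np.arange(5), np.ones(5)))
        x = np.array([0.0, 1.0, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        with pytest.raises(ValueError):
            smooth_zspectrum(ZSpectrum(x, np.ones(8)))


class TestStAt:
    def test_unit_spectrum_gives_zero_st(self):
        x = np.linspace(-8, 8, 30)
        spl = smooth_zspectrum(ZSpectrum(x, np.ones(30)), smoothing=0.0)
        assert st_at(spl, 4.2) == pytest.approx(0.0, abs=1e-9)

    def test_agent_raises_st_at_label_offset(self, protocol, background, water, model):
        no_agent = simulate_zspectrum([water, *background], protocol)
        with_agent = simulate_zspectrum(
            [water, *background, *model.pools_at(6.8)], protocol
        )
        s0 = smooth_zspectrum(no_agent)
        s1 = smooth_zspectrum(with_agent)
        assert st_at(s1, 4.2) > st_at(s0, 4.2)

    def test_b0_correction_recovers_shifted_st(self, protocol, background, water, model):
        # inject a +0.3 ppm shift, correct it, compare to the unshifted ST
        z = simulate_zspectrum([water, *background, *model.pools_at(6.8)], protocol)
        shifted = np.interp(z.offsets - 0.3, z.offsets, z.z_values)
        s_ref = smooth_zspectrum(z)
        s_shift = smooth_zspectrum(ZSpectrum(z.offsets, shifted))
        st_ref = st_at(s_ref, 4.2)
        st_corr = st_at(s_shift, 4.2, water_shift=0.3)
        assert st_corr == pytest.approx(st_ref, rel=0.02)

    def test_outside_support_is_missing(self):
        x = np.linspace(-8, 8, 30)
        spl = smooth_zspectrum(ZSpectrum(x, np.ones(30)), smoothing=0.0)
        assert np.isnan(st_at(spl, 7.9, water_shift=0.5, support=(-8, 8)))

    def test_st_monotone_in_agent_concentration(self, protocol, background, water, model):
        # 1..30 mM series: more agent, more saturation transfer
        sts = []
        for conc in (1.0, 3.0, 10.0, 20.0, 30.0):
            z = simulate_zspectrum(
                [water, *background, *model.pools_at(6.8, concentration=conc)],
                protocol,
            )
            sts.append(st_at(smooth_zspectrum(z), 4.2))
        assert np.all(np.diff(sts) > 0)


class TestDeltaST:
    def _st(self, vals, offset=4.2, phase="pre"):
        return STMap(np.asarray(vals, dtype=float), offset, phase)

    def test_identical_stacks_give_zero_unreliable(self):
        v = np.random.default_rng(0).uniform(0, 0.3, (4, 4, 2))
        d = delta_st(self._st(v), self._st(v, phase="post"))
        np.testing.assert_array_equal(d.values, np.zeros_like(v))
        assert not d.reliability.any()

    def test_contrast_above_floor_is_reliable(self):
        pre = self._st(np.zeros((2, 2, 1)))
        post = self._st(np.full((2, 2, 1), 0.05), phase="post")
        d = delta_st(pre, post, noise_floor=0.02)
        assert d.reliability.all()

    def test_missing_input_voxel_unreliable(self):
        pre = np.zeros((2, 2, 1))
        pre[0, 0, 0] = np.nan
        d = delta_st(self._st(pre), self._st(np.full((2, 2, 1), 0.1), phase="post"))
        assert not d.reliability[0, 0, 0]
        assert d.reliability[1, 1, 0]

    def test_geometry_and_offset_mismatch_rejected(self):
        with pytest.raises(ValueError):
            delta_st(self._st(np.zeros((2, 2, 1))), self._st(np.zeros((3, 2, 1))))
        with pytest.raises(ValueError):
            delta_st(self._st(np.zeros((2, 2, 1)), offset=4.2),
                     self._st(np.zeros((2, 2, 1)), offset=5.5))


@pytest.fixture(scope="module")
def scan(protocol, model, background):
    spec = PhantomSpec(matrix=(24, 24), n_slices=1,
                       tumor_semiaxes_mm=(4.0, 3.5, 2.0),
                       ph_mean=6.8, snr=np.inf, seed=21)
    return generate_animal(spec, protocol, model, background)


class TestStackProcessing:
    def test_agent_phantom_has_positive_contrast(self, scan, protocol):
        mask = scan.truth.tumor_mask
        res = process_stack_pair(
            scan.pre.voxels, scan.pre.s0, scan.post.voxels, scan.post.s0,
            np.asarray(protocol.offsets), mask,
        )
        for off in (4.2, 5.5):
            assert np.all(res[off]["delta"].values[mask] > 0)

    def test_mask_locality(self, scan, protocol):
        # corrupting voxels outside the mask must not change in-mask output
        mask = scan.truth.tumor_mask
        pre2 = scan.pre.voxels.copy()
        pre2[~mask] = 123.0
        a = process_stack_pair(scan.pre.voxels, scan.pre.s0, scan.post.voxels,
                               scan.post.s0, np.asarray(protocol.offsets), mask)
        b = process_stack_pair(pre2, scan.pre.s0, scan.post.voxels,
                               scan.post.s0, np.asarray(protocol.offsets), mask)
        np.testing.assert_array_equal(
            a[4.2]["delta"].values[mask], b[4.2]["delta"].values[mask]
        )

    def test_batch_matches_single_voxel_reference(self, scan, protocol):
        # the vectorized stack path must agree with the per-spectrum
        # reference operations (smooth_zspectrum + st_at) voxel by voxel
        offs = np.asarray(protocol.offsets)
        mask = scan.truth.tumor_mask
        res = process_stack_pair(scan.pre.voxels, scan.pre.s0, scan.post.voxels,
                                 scan.post.s0, offs, mask)
        idx = np.argwhere(mask)[::40]
        for (i, j, k) in idx:
            z = ZSpectrum(offs, scan.pre.voxels[i, j, k] / scan.pre.s0[i, j, k])
            spl = smooth_zspectrum(z)
            shift = res["water_shift"][i, j, k]
            expected = st_at(spl, 4.2, water_shift=shift,
                             support=(offs[0], offs[-1]))
            assert res[4.2]["st_pre"].values[i, j, k] == pytest.approx(
                expected, abs=1e-8
            )

    def test_empty_mask_rejected(self, scan, protocol):
        with pytest.raises(ValueError):
            process_stack_pair(
                scan.pre.voxels, scan.pre.s0, scan.post.voxels, scan.post.s0,
                np.asarray(protocol.offsets), np.zeros_like(scan.truth.tumor_mask),
            )
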