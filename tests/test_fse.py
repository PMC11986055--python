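"""Fast spin echo engine: EPG, line ordering, k-space, reconstruction."""

import numpy as np
import pytest

from fetalmrsim import (
    ParameterError,
    ValidationError,
    downsample_annotations,
    effective_te_line_order,
    epg_echo_amplitudes,
    reconstruct_slice,
    resample_to_slices,
    sequence_preset,
    simulate_kspace_slice,
    simulate_lr_series,
)
from fetalmrsim.fse import fft2c, ifft2c


def isochromat_fse(t1, t2, esp, etl, exc_deg=90.0, refoc_deg=120.0,
                   n_iso=500):
    """Brute-force Bloch simulation: n_iso spins, uniform dephasing of one
    full cycle per half echo-spacing (crusher convention)."""
    theta = 2 * np.pi * (np.arange(n_iso) + 0.5) / n_iso - np.pi

    def rot(angle_deg, phi_axis):
        a = np.radians(angle_deg)
        Rz = lambda t: np.array([[np.cos(t), -np.sin(t), 0],
                                 [np.sin(t), np.cos(t), 0], [0, 0, 1]])
        Rx = np.array([[1, 0, 0],
                       [0, np.cos(a), -np.sin(a)],
                       [0, np.sin(a), np.cos(a)]])
        return Rz(phi_axis) @ Rx @ Rz(-phi_axis)

    M = np.zeros((n_iso, 3))
    M[:, 2] = 1.0
    M = M @ rot(exc_deg, np.pi / 2).T
    Rref = rot(refoc_deg, 0.0)
    ct, st = np.cos(theta), np.sin(theta)

    def relax(t):
        e2, e1 = np.exp(-t / t2), np.exp(-t / t1)
        M[:, :2] *= e2
        M[:, 2] = 1 + (M[:, 2] - 1) * e1

    def dephase():
        x, y = M[:, 0].copy(), M[:, 1].copy()
        M[:, 0] = x * ct - y * st
        M[:, 1] = x * st + y * ct

    echoes = []
    for _ in range(etl):
        relax(esp / 2)
        dephase()
        M[:] = M @ Rref.T
        relax(esp / 2)
        dephase()
        echoes.append(np.hypot(M[:, 0].mean(), M[:, 1].mean()))
    return np.array(echoes)


class TestEPG:
    @pytest.mark.parametrize("t1,t2,esp,etl", [
        (2700.0, 285.0, 10.0, 32),
        (2200.0, 182.0, 4.08, 64),
        (4000.0, 2000.0, 10.0, 16),
    ])
    def test_cpmg_closed_form_at_180(self, t1, t2, esp, etl):
        e = epg_echo_amplitudes(t1, t2, esp, etl, 90.0, 180.0)
        n = np.arange(1, etl + 1)
        assert np.abs(e - np.exp(-n * esp / t2)).max() < 1e-10

    def test_no_decay_limit(self):
        e = epg_echo_amplitudes(2e9, 1e9, 10.0, 8, 90.0, 180.0)
        assert np.allclose(e, 1.0, atol=1e-6)

    @pytest.mark.parametrize("refoc", [120.0, 150.0, 90.0])
    def test_matches_isochromat_summation(self, refoc):
        epg = epg_echo_amplitudes(2700.0, 285.0, 10.0, 32, 90.0, refoc)
        iso = isochromat_fse(2700.0, 285.0, 10.0, 32, refoc_deg=refoc)
        assert np.max(np.abs(epg - iso) / np.abs(iso)) < 1e-3

    def test_state_overflow_guard(self):
        with pytest.raises(ParameterError):
            epg_echo_amplitudes(2700, 285, 10, 64, max_states=16)

    def test_rejects_bad_relaxation(self):
        with pytest.raises(ValidationError):
            epg_echo_amplitudes(100.0, 200.0, 10, 8)


class TestLineOrder:
    def test_haste_15t_center_echo(self):
        order = effective_te_line_order(sequence_preset("HASTE", 1.5))
        assert order.realized_te_ms == pytest.approx(21 * 4.08)
        c_pos = np.where(order.acquired_rows == order.center_row)[0][0]
        assert order.echo_of_acquired[c_pos] == 21

    def test_full_sampling_is_bijection(self, small_params):
        # te placed so the linear order spans every line exactly once
        from dataclasses import replace
        n = small_params.n_phase_full
        params = replace(small_params,
                         te_eff_ms=(n // 2 + 1) * small_params.echo_spacing_ms,
                         etl=n)
        order = effective_te_line_order(params)
        assert np.array_equal(order.acquired_rows, np.arange(n))
        assert order.filled_rows.size == 0

    def test_acquisition_times_strictly_increasing(self):
        for name, field in [("HASTE", 1.5), ("HASTE", 3), ("SSFSE", 1.5)]:
            order = effective_te_line_order(sequence_preset(name, field))
            assert np.all(np.diff(order.echo_of_acquired) > 0)
            assert np.all(np.diff(order.acquired_rows) > 0)

    def test_etl_respected_by_presets(self):
        for name, field in [("HASTE", 1.5), ("HASTE", 3),
                            ("SSFSE", 1.5), ("SSFSE", 3)]:
            p = sequence_preset(name, field)
            order = effective_te_line_order(p)
            assert order.acquired_rows.size <= p.etl

    def test_unreachable_te(self, small_params):
        from dataclasses import replace
        with pytest.raises(ParameterError, match="feasible"):
            effective_te_line_order(replace(small_params, te_eff_ms=5000.0))


class TestPresets:
    def test_table_values(self):
        h15 = sequence_preset("HASTE", 1.5)
        assert h15.echo_spacing_ms == 4.08 and h15.etl == 134
        assert h15.slice_gap_mm == 0.3 and h15.accel_factor == 2
        assert h15.reference_lines == 42 and h15.noise_sd == 0.05
        s3 = sequence_preset("SSFSE", 3)
        assert s3.slice_gap_mm == 0 and s3.accel_factor == 1
        assert s3.reference_lines == 0 and s3.sampling_pct == 55.0
        s15 = sequence_preset("SSFSE", 1.5)
        assert s15.fov_shift_mm == 1.6 and s15.recon_matrix == 512
        with pytest.raises(ValidationError):
            sequence_preset("HASTE", 7.0)

    def test_range_sampling_stays_in_range(self):
        p = sequence_preset("SSFSE", 1.5)
        rng = np.random.default_rng(0)
        for _ in range(20):
            q = p.sample(rng)
            assert 116 <= q.te_eff_ms <= 124
            assert 0.03 <= q.noise_sd <= 0.07
            assert 2000 <= q.tr_ms <= 3500


class TestResample:
    def test_constant_volume_averaging_identity(self, qmaps48, small_params):
        from fetalmrsim.relaxometry import QuantitativeMaps
        const = QuantitativeMaps(
            t1_map=np.full(qmaps48.shape, 2000.0),
            t2_map=np.full(qmaps48.shape, 123.0),
            pd_map=np.ones(qmaps48.shape), affine=qmaps48.affine)
        slabs = resample_to_slices(const, "axial", small_params, 1)
        inside = slabs.pd > 0
        assert np.allclose(slabs.t2[inside], 123.0)

    def test_run_offset_half_pitch(self, qmaps48):
        p = sequence_preset("HASTE", 1.5)
        s1 = resample_to_slices(qmaps48, "coronal", p, 1)
        s2 = resample_to_slices(qmaps48, "coronal", p, 2)
        d = (s2.geometry["slice_centers_mm"][0]
             - s1.geometry["slice_centers_mm"][0])
        assert d == pytest.approx((3.0 + 0.3) / 2)

    def test_slice_count_matches_extent(self, qmaps48, small_params):
        slabs = resample_to_slices(qmaps48, "axial", small_params, 1)
        brain = qmaps48.pd_map > 0
        idx = np.argwhere(brain)[:, 2]
        extent = (idx.max() - idx.min() + 1) * qmaps48.spacing[2]
        expected = int(np.ceil(extent / small_params.slice_pitch_mm)) \
            + small_params.slice_padding
        assert slabs.pd.shape[0] == expected


class TestKSpace:
    def test_parseval(self):
        rng = np.random.default_rng(0)
        ksp = rng.standard_normal((32, 32)) + 1j * rng.standard_normal((32, 32))
        img = ifft2c(ksp)
        assert np.abs(np.vdot(img, img).real - np.vdot(ksp, ksp).real) \
            < 1e-9 * np.vdot(ksp, ksp).real
        assert np.allclose(fft2c(img), ksp, atol=1e-12)

    def test_noiseless_fullsampling_roundtrip(self, small_params, qmaps48):
        from dataclasses import replace
        n = small_params.n_phase_full
        params = replace(small_params, noise_sd=0.0, etl=n,
                         te_eff_ms=(n // 2 + 1) * small_params.echo_spacing_ms)
        order = effective_te_line_order(params)
        slabs = resample_to_slices(qmaps48, "axial", params, 1)
        s = slabs.pd.shape[0] // 2
        # effectively no decay: every echo shares one amplitude
        t1 = np.full_like(slabs.t1[s], 2e9)
        t2 = np.full_like(slabs.t2[s], 1e9)
        pd = slabs.pd[s]
        ksp, _ = simulate_kspace_slice(t1, t2, pd, params, order,
                                       np.random.default_rng(0))
        img = reconstruct_slice(ksp, params)
        assert np.abs(img - pd).max() < 1e-6 * max(pd.max(), 1.0)

    def test_mask_row_count(self, small_params, qmaps48):
        order = effective_te_line_order(small_params)
        slabs = resample_to_slices(qmaps48, "axial", small_params, 1)
        s = slabs.pd.shape[0] // 2
        ksp, mask = simulate_kspace_slice(
            slabs.t1[s], slabs.t2[s], slabs.pd[s], small_params, order,
            np.random.default_rng(0))
        assert mask.sum() == order.acquired_rows.size

    def test_zero_kspace_reconstructs_to_zero(self, small_params):
        img = reconstruct_slice(
            np.zeros((small_params.n_phase_full,
                      small_params.base_resolution), complex), small_params)
        assert np.all(img == 0)

    def test_haste_3t_recon_grid(self):
        p = sequence_preset("HASTE", 3)
        ksp = np.zeros((p.n_phase_full, p.base_resolution), complex)
        assert reconstruct_slice(ksp, p).shape == (640, 640)


class TestSeries:
    def test_seed_determinism_and_affine(self, qmaps48, small_params):
        a = simulate_lr_series(qmaps48, small_params, "axial", 1, seed=9)
        b = simulate_lr_series(qmaps48, small_params, "axial", 1, seed=9)
        assert np.array_equal(a.data, b.data)
        assert np.all(a.data >= 0)
        # inter-slice spacing equals thickness + gap along the slice axis
        step = np.linalg.norm(a.affine[:3, 2])
        assert step == pytest.approx(small_params.slice_pitch_mm)

    def test_modulated_vs_uniform_wm_differ(self, qmaps48, class_map48,
                                            small_params):
        from fetalmrsim import extract_mask
        from fetalmrsim.relaxometry import QuantitativeMaps
        wm = extract_mask(class_map48, "WM")
        flat = QuantitativeMaps(
            t1_map=qmaps48.t1_map.copy(), t2_map=qmaps48.t2_map.copy(),
            pd_map=qmaps48.pd_map, affine=qmaps48.affine)
        t2_ref = qmaps48.provenance["properties"]["WM"]["t2_ms"]
        t1_ref = qmaps48.provenance["properties"]["WM"]["t1_ms"]
        flat.t2_map[wm] = t2_ref
        flat.t1_map[wm] = t1_ref
        mod = simulate_lr_series(qmaps48, small_params, "axial", 1, seed=3)
        uni = simulate_lr_series(flat, small_params, "axial", 1, seed=3)
        lab, _ = downsample_annotations(class_map48.classes, mod)
        wm_lr = lab == 2
        assert wm_lr.sum() > 50
        assert not np.allclose(mod.data[wm_lr], uni.data[wm_lr])


class TestAnnotations:
    def test_single_class_volume(self, qmaps48, small_params):
        series = simulate_lr_series(qmaps48, small_params, "axial", 1, seed=1)
        ones = np.ones(qmaps48.shape, dtype=np.int16)
        lab, mask = downsample_annotations(ones, series)
        assert set(np.unique(lab)) == {1}
        assert mask.all()

    def test_no_label_invention_and_volume(self, phantom48, qmaps48,
                                           small_params):
        series = simulate_lr_series(qmaps48, small_params, "axial", 1, seed=1)
        lab, mask = downsample_annotations(phantom48.labels, series)
        assert set(np.unique(lab)) <= set(np.unique(phantom48.labels))
        # LR brain volume tracks HR brain volume
        hr_vol = (phantom48.labels != 0).sum() * np.prod(phantom48.spacing)
        pix = small_params.fov_read_mm / small_params.recon_matrix
        lr_vol = mask.sum() * pix * pix * small_params.slice_pitch_mm
        assert lr_vol == pytest.approx(hr_vol, rel=0.15)
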