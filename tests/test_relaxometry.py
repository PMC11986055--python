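"""Reference tissue properties, reward maps, alpha schedule, sigmoid."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fetalmrsim import (
    ValidationError,
    build_alpha_schedule,
    compute_reward_maps,
    modulate_relaxation,
    reference_properties,
    sample_subject_properties,
    sigmoid_modulation,
)
from fetalmrsim.ghmrf import PVMaps
from fetalmrsim.relaxometry import RewardMaps, read_sigma_table


def make_pv(h, i, f, shape=(2, 2, 2), mask=None):
    mask = np.ones(shape, bool) if mask is None else mask
    zeros = np.zeros(shape)
    pv = [np.where(mask, v, 0.0) for v in
          (np.full(shape, h), np.full(shape, i), np.full(shape, f))]
    return PVMaps(pv_hydrated=pv[0], pv_intermediate=pv[1], pv_fibers=pv[2],
                  class_means=np.array([140.0, 100.0, 60.0]),
                  class_sds=np.ones(3), mask=mask)


class TestReferenceProperties:
    def test_table_values_15t(self):
        p = reference_properties(1.5)
        assert p.wm.t1_ms == 2700 and p.wm.t2_ms == 285
        assert p.gm.t1_ms == 2200 and p.gm.t2_ms == 182
        assert p.csf.t1_ms == 4000 and p.csf.t2_ms == 2000

    def test_3t_scaling(self):
        p3, p15 = reference_properties(3), reference_properties(1.5)
        assert p3.gm.t1_ms == pytest.approx(2750)      # 2200 * 1.25
        assert p3.wm.t1_ms == pytest.approx(2970)      # 2700 * 1.10
        assert p3.csf.t1_ms == pytest.approx(4400)
        # T2 is field-independent
        for a, b in ((p3.gm, p15.gm), (p3.wm, p15.wm), (p3.csf, p15.csf)):
            assert a.t2_ms == b.t2_ms

    def test_unsupported_field(self):
        with pytest.raises(ValidationError):
            reference_properties(7.0)


class TestSampling:
    def test_bounds_and_determinism(self):
        for seed in range(200):
            p = sample_subject_properties(1.5, seed)
            assert 172 <= p.gm.t2_ms <= 192 and p.gm.t2_ms.is_integer()
            assert 270 <= p.wm.t2_ms <= 300 and p.wm.t2_ms.is_integer()
            assert p.csf.t2_ms == 2000 and p.csf.t1_ms == 4000
        a = sample_subject_properties(1.5, 123)
        b = sample_subject_properties(1.5, 123)
        assert a == b

    def test_t1_coupling_direction(self):
        ref = reference_properties(1.5)
        for seed in range(300):
            p = sample_subject_properties(1.5, seed)
            base = p.wm.t2_ms / ref.wm.t2_ms * ref.wm.t1_ms
            if p.wm.t2_ms > ref.wm.t2_ms:
                assert base <= p.wm.t1_ms <= base + 300
            elif p.wm.t2_ms < ref.wm.t2_ms:
                assert base - 300 <= p.wm.t1_ms <= base
            else:
                assert p.wm.t1_ms == pytest.approx(base)

    def test_mean_t2_law_of_large_numbers(self):
        vals = np.array([sample_subject_properties(1.5, s).gm.t2_ms
                         for s in range(100_000)])
        # integer uniform on {172..192}: mean 182, sd sqrt((21^2-1)/12)
        se = np.sqrt((21 ** 2 - 1) / 12) / np.sqrt(vals.size)
        assert abs(vals.mean() - 182) < 3 * se


class TestRewardMaps:
    def test_hand_evaluated_example(self):
        r = compute_reward_maps(make_pv(0.6, 0.3, 0.1))
        assert np.allclose(r.w_plus, 1.3) and np.allclose(r.w_minus, 0.8)
        assert np.allclose(r.deviation, 0.3 - 0.2)

    def test_neutral_cases(self):
        for h, i, f in [(1 / 3, 1 / 3, 1 / 3), (0.0, 0.0, 1.0)]:
            r = compute_reward_maps(make_pv(h, i, f))
            assert np.allclose(r.w_plus, 1.0) and np.allclose(r.w_minus, 1.0)

    def test_bounds_on_random_triples(self):
        rng = np.random.default_rng(0)
        pv = rng.dirichlet(np.ones(3), size=(20, 20, 20)).transpose(3, 0, 1, 2)
        maps = PVMaps(*pv, class_means=np.array([3.0, 2.0, 1.0]),
                      class_sds=np.ones(3), mask=np.ones((20, 20, 20), bool))
        r = compute_reward_maps(maps)
        assert np.all((r.w_plus >= 1) & (r.w_plus <= 2))
        assert np.all((r.w_minus >= 0) & (r.w_minus <= 1))


class TestSigmoid:
    @given(st.sampled_from([0.05, 0.2, 1.0]),
           st.floats(-2, 2, allow_nan=False))
    @settings(max_examples=200, deadline=None)
    def test_printed_form_equals_tanh(self, alpha, w):
        printed = alpha * (2.0 / (1.0 + np.exp(-2.0 * w / alpha)) - 1.0) + 1.0
        assert abs(sigmoid_modulation(w, alpha) - printed) < 1e-12

    def test_identity_at_zero_and_oddness(self):
        assert sigmoid_modulation(0.0, 0.2) == 1.0
        d = np.linspace(-1, 1, 41)
        f = sigmoid_modulation(d, 0.2)
        assert np.allclose(f - 1, -(f[::-1] - 1), atol=1e-14)

    def test_worked_example(self):
        rewards = RewardMaps(w_plus=np.array([1.3]), w_minus=np.array([1.0]),
                             mask=np.array([True]))
        out = modulate_relaxation(285.0, rewards, 0.2)
        assert out[0] == pytest.approx(285 * (1 + 0.2 * np.tanh(1.5)),
                                       abs=0.01)

    def test_supremum_bound(self):
        f = sigmoid_modulation(np.array([10.0, 1e6]), 0.2)
        assert np.all(f <= 1.2) and f[1] == pytest.approx(1.2, abs=1e-9)

    @given(st.floats(0.3, 1.0), st.floats(-1.0, 1.0), st.floats(1e-3, 0.1))
    @settings(max_examples=200, deadline=None)
    def test_strictly_increasing(self, alpha, d, eps):
        assert sigmoid_modulation(d + eps, alpha) > sigmoid_modulation(d, alpha)


class TestAlphaSchedule:
    def test_constant_sigma_keeps_alpha(self):
        s = build_alpha_schedule({g: 5.0 for g in range(21, 39)})
        for ga in (21, 25.5, 30, 38):
            assert s(ga) == pytest.approx(0.2)

    def test_single_step_example(self):
        sigma = {g: 1.0 for g in range(21, 39)}
        sigma.update({g: 1.5 for g in range(22, 39)})
        s = build_alpha_schedule(sigma)
        assert s.base_table[21] == 0.2
        assert s.base_table[22] == pytest.approx(0.2 * (2 - 1.5))

    @given(st.lists(st.floats(1.0, 1.9), min_size=17, max_size=17),
           st.integers(0, 10_000))
    @settings(max_examples=50, deadline=None)
    def test_recursion_matches_loop_oracle(self, ratios, seed):
        rng = np.random.default_rng(seed)
        sigma = {21: float(rng.uniform(1, 10))}
        for ga, r in zip(range(22, 39), ratios):
            sigma[ga] = sigma[ga - 1] * r   # ratios < 2 keep alpha positive
        s = build_alpha_schedule(sigma)
        expect = 0.2
        for ga in range(22, 39):
            expect = expect * (2 - sigma[ga] / sigma[ga - 1])
            assert s.base_table[ga] == pytest.approx(expect, rel=1e-12)

    def test_clamping_and_domain(self):
        sigma = {g: 1.0 for g in range(21, 39)}
        sigma[25] = 2.5    # ratio >= 2 drives alpha negative
        with pytest.warns(UserWarning, match="clamped"):
            s = build_alpha_schedule(sigma)
        assert s.base_table[25] == pytest.approx(1e-3)
        with pytest.warns(UserWarning, match="clamping"):
            assert s(40.0) == s(38.0)

    def test_missing_ga_rejected(self):
        with pytest.raises(ValidationError):
            build_alpha_schedule({g: 1.0 for g in range(22, 39)})

    def test_sigma_csv_roundtrip(self, tmp_path):
        p = tmp_path / "sigma.csv"
        p.write_text("ga,sigma\n" + "\n".join(
            f"{g},{5.0 - 0.1 * (g - 21)}" for g in range(21, 39)))
        table = read_sigma_table(p)
        assert table[21] == 5.0 and len(table) == 18
        build_alpha_schedule(table)


class TestQuantitativeMaps:
    def test_uniform_pv_leaves_wm_unmodulated(self, class_map48):
        from fetalmrsim import build_quantitative_maps, extract_mask
        wm = extract_mask(class_map48, "WM")
        pv = make_pv(1 / 3, 1 / 3, 1 / 3, shape=class_map48.shape, mask=wm)
        props = sample_subject_properties(1.5, 5)
        sched = build_alpha_schedule({g: 2.0 for g in range(21, 39)})
        q = build_quantitative_maps(class_map48, pv, props, sched, 28.0)
        assert np.allclose(q.t2_map[wm], props.wm.t2_ms)
        csf = class_map48.classes == 3
        assert np.all(q.t1_map[csf] == 4000) and np.all(q.t2_map[csf] == 2000)

    def test_wm_t2_within_alpha_bound(self, qmaps48, class_map48):
        from fetalmrsim import extract_mask
        wm = extract_mask(class_map48, "WM")
        alpha = qmaps48.provenance["alpha"]
        t2_ref = qmaps48.provenance["properties"]["WM"]["t2_ms"]
        vals = qmaps48.t2_map[wm]
        assert np.all(vals >= t2_ref * (1 - alpha) - 1e-9)
        assert np.all(vals <= t2_ref * (1 + alpha) + 1e-9)
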