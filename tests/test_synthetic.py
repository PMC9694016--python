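import numpy as np
import pytest

from musyn import (
    EXTRA_MUSCLES,
    STANDARD_MUSCLES,
    GenerationError,
    GroundTruth,
    NestedScenarioConfig,
    PHASE_LABELS,
    cosine_tuning,
    gen_coefficients,
    gen_group_synergies,
    gen_synergies,
    nested_scenario,
    perturb_synergy,
    synthesize_repetitions,
)


def _make_gt(W, C, centers, tuning, width=0.1, sigma=0.0, tonic=None, n_reps=1, seed=0):
    M, K = W.shape[0], len(PHASE_LABELS)
    return GroundTruth(
        W_true=W, C_true=C, tuning=tuning, burst_centers=centers,
        burst_width=width, tonic_levels=np.zeros((M, K, 2)) if tonic is None else tonic,
        noise_sigma=sigma, n_reps=n_reps, seed=seed,
        muscle_names=[f"m{i}" for i in range(M)],
    )


class TestGenSynergies:
    def test_single_muscle_single_synergy_is_one(self):
        np.testing.assert_array_equal(gen_synergies(1, 1, 0.0, seed=9), [[1.0]])

    def test_columns_unit_norm_and_separated(self):
        W = gen_synergies(4, 2, sparsity=0.5, seed=7)
        np.testing.assert_allclose(np.linalg.norm(W, axis=0), 1.0, atol=1e-12)
        assert W.min() >= 0
        assert float(W[:, 0] @ W[:, 1]) <= 0.8

    def test_seeded_determinism(self):
        a = gen_synergies(12, 3, sparsity=0.0, seed=1)
        b = gen_synergies(12, 3, sparsity=0.0, seed=1)
        np.testing.assert_array_equal(a, b)

    def test_order_larger_than_muscles_rejected(self):
        with pytest.raises(ValueError, match="order"):
            gen_synergies(3, 4, 0.0, seed=0)

    def test_unsatisfiable_separation_raises_generation_error(self):
        # two synergies over two muscles with no sparsity can never reach
        # similarity <= 0.01 for nonnegative vectors drawn from (0,1)
        with pytest.raises(GenerationError):
            gen_synergies(2, 2, 0.0, seed=0, max_sim=0.01, max_tries=10)

    def test_grouped_synergies_have_disjoint_supports(self):
        W = gen_group_synergies(12, 3, seed=2)
        np.testing.assert_allclose(np.linalg.norm(W, axis=0), 1.0, atol=1e-12)
        supports = [set(np.flatnonzero(W[:, j])) for j in range(3)]
        assert supports[0] | supports[1] | supports[2] == set(range(12))
        for a in range(3):
            for b in range(a + 1, 3):
                assert not supports[a] & supports[b]


class TestGenCoefficients:
    def test_zero_tuning_gives_zero_coefficients(self):
        C, _ = gen_coefficients(2, 4, T=50, tuning=np.zeros((2, 4)), seed=0)
        assert not C.any()

    def test_single_burst_peaks_mid_phase(self):
        C, _ = gen_coefficients(1, 1, T=100, tuning=np.ones((1, 1)), seed=0,
                                center_jitter=0.0)
        row = C[0]
        assert abs(int(np.argmax(row)) - 50) <= 1
        assert row[50] >= row[0] and row[50] >= row[99]

    def test_negative_amplitude_rejected(self):
        with pytest.raises(ValueError, match="nonnegative"):
            gen_coefficients(1, 2, tuning=np.array([[1.0, -0.1]]))

    def test_seeded_determinism(self):
        a, ca = gen_coefficients(3, 16, seed=4)
        b, cb = gen_coefficients(3, 16, seed=4)
        np.testing.assert_array_equal(a, b)
        np.testing.assert_array_equal(ca, cb)


class TestCosineTuning:
    def test_peak_at_preferred_direction_and_zero_opposite(self):
        tun = cosine_tuning(np.array([np.pi / 2]))  # preferred: N
        k_out_n = PHASE_LABELS.index("O->N")
        k_back_n = PHASE_LABELS.index("N->O")  # movement direction S
        assert tun[0, k_out_n] == pytest.approx(1.0)
        assert tun[0, k_back_n] == pytest.approx(0.0, abs=1e-12)

    def test_return_movement_uses_opposite_direction(self):
        tun = cosine_tuning(np.array([np.pi / 2]))
        assert tun[0, PHASE_LABELS.index("S->O")] == pytest.approx(1.0)


class TestSynthesizeRepetitions:
    def _simple_gt(self, **kw):
        W = gen_synergies(3, 2, 0.0, seed=1)
        tuning = np.ones((2, len(PHASE_LABELS)))
        C, centers = gen_coefficients(2, len(PHASE_LABELS), T=100,
                                      tuning=tuning, seed=1)
        return _make_gt(W, C, centers, tuning, width=0.15, **kw)

    def test_noiseless_equals_composition(self):
        gt = self._simple_gt(n_reps=3)
        env = synthesize_repetitions(gt)
        for rep in env.reps:
            np.testing.assert_array_equal(rep, gt.ideal())

    def test_constant_tonic_shifts_one_muscle_exactly(self):
        gt = self._simple_gt()
        gt.tonic_levels[1, :, :] = 0.2
        env = synthesize_repetitions(gt)
        diff = env.reps[0] - gt.ideal()
        np.testing.assert_allclose(diff[1], 0.2, atol=1e-12)
        np.testing.assert_allclose(diff[[0, 2]], 0.0, atol=1e-12)

    def test_averaging_repetitions_reduces_noise(self):
        # the mean over 8 noisy repetitions should be closer to the ideal
        # composition than single repetitions are, on average over seeds
        wins = 0
        for seed in range(20):
            gt = self._simple_gt(sigma=0.05, n_reps=8, seed=seed)
            env = synthesize_repetitions(gt)
            target = gt.ideal()
            mean_err = np.linalg.norm(np.mean(env.reps, axis=0) - target)
            single_err = np.mean([np.linalg.norm(r - target) for r in env.reps])
            wins += mean_err < single_err
        assert wins >= 18

    def test_repetitions_distinct_under_noise(self):
        gt = self._simple_gt(sigma=0.05, n_reps=8)
        env = synthesize_repetitions(gt)
        assert len({rep.tobytes() for rep in env.reps}) == 8

    def test_envelopes_nonnegative(self):
        gt = self._simple_gt(sigma=0.2, n_reps=4)
        env = synthesize_repetitions(gt)
        assert all(rep.min() >= 0 for rep in env.reps)
        assert all(seg.min() >= 0 for rep in env.raw_segments for seg in rep)


class TestNestedScenario:
    def test_config_validation(self):
        with pytest.raises(ValueError, match="disjoint"):
            NestedScenarioConfig(extra_muscles=EXTRA_MUSCLES[:-1] + ["DA"])
        with pytest.raises(ValueError, match="<= 12"):
            NestedScenarioConfig(S_shared=12, S_extra=1)

    def test_loading_concentrations(self, noisy_nested):
        _, _, gt = noisy_nested
        W = gt.W_true
        std = slice(0, 12)
        for j in range(3):  # shared synergies live on the standard muscles
            assert np.sum(W[std, j] ** 2) >= 0.90
        assert np.sum(W[12:, 3] ** 2) >= 0.90  # extra synergy on added muscles

    def test_view_is_row_subset(self, noisy_nested):
        full, view, _ = noisy_nested
        assert view.muscle_names == STANDARD_MUSCLES
        idx = [full.muscle_names.index(m) for m in STANDARD_MUSCLES]
        for rf, rv in zip(full.reps, view.reps):
            np.testing.assert_array_equal(rv, rf[idx])
        for rf, rv in zip(full.raw_segments, view.raw_segments):
            for sf, sv in zip(rf, rv):
                np.testing.assert_array_equal(sv, sf[idx])

    def test_noiseless_ranks_differ_by_extra_synergies(self):
        # with no cross-group leak the extra synergy is invisible in the
        # 12-row view (numerical rank 3) but present in the 32-row data
        cfg = NestedScenarioConfig(noise_sigma=0.0, tonic_max=0.0, leak=0.0, seed=3)
        full, view, _ = nested_scenario(cfg)
        sv_12 = np.linalg.svd(view.reps[0], compute_uv=False)
        sv_32 = np.linalg.svd(full.reps[0], compute_uv=False)
        assert sv_12[3] / sv_12[0] < 1e-8
        assert sv_32[3] / sv_32[0] > 0.1
        assert sv_32[4] / sv_32[0] < 1e-10

    def test_no_extra_synergy_means_equal_rank(self):
        cfg = NestedScenarioConfig(S_extra=0, noise_sigma=0.0, tonic_max=0.0, seed=2)
        full, view, gt = nested_scenario(cfg)
        assert gt.S_true == 3
        sv_32 = np.linalg.svd(full.reps[0], compute_uv=False)
        assert sv_32[3] / sv_32[0] < 1e-10

    def test_bit_identical_on_same_seed(self):
        a = nested_scenario(NestedScenarioConfig(seed=11))
        b = nested_scenario(NestedScenarioConfig(seed=11))
        for rep_a, rep_b in zip(a[0].reps, b[0].reps):
            np.testing.assert_array_equal(rep_a, rep_b)
        np.testing.assert_array_equal(a[2].W_true, b[2].W_true)


class TestPerturbSynergy:
    def test_zero_fraction_is_identity(self):
        W = gen_synergies(6, 2, 0.0, seed=0)
        np.testing.assert_array_equal(perturb_synergy(W, 0, 0.0, seed=1), W)

    def test_perturbed_column_stays_unit_norm(self):
        W = gen_synergies(6, 2, 0.0, seed=0)
        W2 = perturb_synergy(W, 1, 0.5, seed=1)
        assert np.linalg.norm(W2[:, 1]) == pytest.approx(1.0)
        np.testing.assert_array_equal(W2[:, 0], W[:, 0])
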