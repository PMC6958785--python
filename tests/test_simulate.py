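"""Simulation stages: Dirichlet proportions, confounder application, mixing, noise."""

import numpy as np
import pytest

from methdeconv import (
    SimulationConfig,
    make_cohort,
    make_confounder_effects,
    make_reference_profiles,
    simulate_dataset,
    simulate_proportions,
)
from methdeconv.fixtures import CohortMetadata, ConfounderEffects
from methdeconv.simulate import (
    BetaMatrix,
    IndividualProfiles,
    ProportionMatrix,
    SimulationTruth,
    add_noise,
    apply_age_effect,
    apply_plate_effect,
    apply_sex_effect,
    mix,
    tile_profiles,
)


class TestProportions:
    def test_columns_on_simplex(self):
        a = simulate_proportions(SimulationConfig(n_samples=200, n_types=5, seed=1))
        np.testing.assert_allclose(a.values.sum(axis=0), 1.0, atol=1e-12)
        assert a.values.min() >= 0

    def test_large_alpha0_concentrates_at_base_props(self):
        cfg = SimulationConfig(n_samples=100, n_types=5, alpha0=10000.0, seed=2)
        a = simulate_proportions(cfg)
        dev = np.abs(a.values - np.asarray(cfg.base_props)[:, None]).max()
        assert dev < 0.05  # sd per entry <= sqrt(p(1-p)/(alpha0+1)) ~ 0.005

    def test_mean_cancer_epithelial_proportion_near_sixty_percent(self):
        cfg = SimulationConfig(n_samples=10000, n_types=5, alpha0=1.0, seed=3)
        a = simulate_proportions(cfg)
        row = a.type_names.index("cancer_epithelial")
        mean = a.values[row].mean()
        se = a.values[row].std(ddof=1) / np.sqrt(a.n_samples)
        assert abs(mean - 0.60) <= 3 * se

    def test_variance_decreases_with_alpha0(self):
        variances = []
        for alpha0 in (1, 10, 100, 10000):
            cfg = SimulationConfig(n_samples=2000, n_types=5, alpha0=alpha0, seed=4)
            variances.append(simulate_proportions(cfg).values.var(axis=1).mean())
        assert all(a > b for a, b in zip(variances, variances[1:]))

    def test_invalid_config_raises(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_samples=10, n_types=3, alpha0=0.0)
        with pytest.raises(ValueError):
            SimulationConfig(n_samples=10, n_types=3, base_props=(0.5, 0.4, 0.2))


class TestSexEffect:
    @pytest.fixture
    def setup(self):
        profiles = make_reference_profiles(100, 3, seed=1)
        import pandas as pd

        meta = CohortMetadata(
            pd.DataFrame(
                {"sex": [0, 1], "age": [50.0, 60.0], "plate": ["plate00", "plate00"]},
                index=pd.Index(["s0", "s1"], name="sample_id"),
            )
        )
        eff = make_confounder_effects(
            profiles, n_sex_probes=10, n_age_probes=5, n_plates=1, seed=2
        )
        return profiles, meta, eff

    def test_all_male_cohort_unchanged(self, setup):
        profiles, meta, eff = setup
        meta.table["sex"] = 0
        stack = tile_profiles(profiles, meta.sample_ids)
        out = apply_sex_effect(stack, meta, eff)
        np.testing.assert_array_equal(out.values, stack.values)

    def test_shift_is_exact_in_every_type_column(self, setup):
        profiles, meta, eff = setup
        stack = tile_profiles(profiles, meta.sample_ids)
        out = apply_sex_effect(stack, meta, eff)
        pos = stack.probe_positions(eff.sex_probe_ids)
        delta = out.values[1, pos, :] - stack.values[1, pos, :]
        base = stack.values[1, pos, :]
        interior = (base + eff.sex_coefs[:, None] >= 0) & (base + eff.sex_coefs[:, None] <= 1)
        np.testing.assert_allclose(
            delta[interior],
            np.broadcast_to(eff.sex_coefs[:, None], delta.shape)[interior],
        )
        # male sample untouched
        np.testing.assert_array_equal(out.values[0], stack.values[0])

    def test_shift_clamps_at_one(self, setup):
        profiles, meta, eff = setup
        stack = tile_profiles(profiles, meta.sample_ids)
        stack.values[:, :, :] = 0.95
        eff.sex_coefs[:] = 0.2
        out = apply_sex_effect(stack, meta, eff)
        pos = stack.probe_positions(eff.sex_probe_ids)
        assert np.all(out.values[1, pos, :] == 1.0)

    def test_unknown_probe_id_raises(self, setup):
        profiles, meta, eff = setup
        eff.sex_probe_ids[0] = "missing_probe"
        stack = tile_profiles(profiles, meta.sample_ids)
        with pytest.raises(ValueError, match="unknown probe"):
            apply_sex_effect(stack, meta, eff)


class TestAgeEffect:
    def test_zero_effect_scale_is_identity(self):
        profiles = make_reference_profiles(200, 5, seed=3)
        cohort = make_cohort(10, n_plates=2, seed=4)
        eff = make_confounder_effects(
            profiles, n_sex_probes=20, n_age_probes=10, n_plates=2,
            effect_scale=0.0, seed=5,
        )
        stack = tile_profiles(profiles, cohort.sample_ids)
        out = apply_age_effect(apply_sex_effect(stack, cohort, eff), cohort, eff)
        np.testing.assert_allclose(out.values, stack.values, atol=1e-12)

    def test_epithelial_column_equals_linear_prediction(self):
        profiles = make_reference_profiles(200, 5, seed=3)
        cohort = make_cohort(10, n_plates=2, seed=4)
        eff = make_confounder_effects(
            profiles, n_sex_probes=20, n_age_probes=10, n_plates=2, seed=5
        )
        stack = tile_profiles(profiles, cohort.sample_ids)
        out = apply_age_effect(stack, cohort, eff)
        pos = stack.probe_positions(eff.age_probe_ids)
        epi = eff.type_names.index(eff.epithelial_type)
        ages = np.asarray(cohort["age"])
        pred = np.clip(eff.age_intercepts[None, :] + eff.age_slopes[None, :] * ages[:, None], 0, 1)
        np.testing.assert_allclose(out.values[:, pos, epi], pred)

    def test_monotone_in_age_for_positive_slopes(self):
        profiles = make_reference_profiles(200, 5, seed=3)
        import pandas as pd

        meta = CohortMetadata(
            pd.DataFrame(
                {"sex": [0, 0], "age": [40.0, 80.0], "plate": ["plate00"] * 2},
                index=pd.Index(["young", "old"], name="sample_id"),
            )
        )
        eff = make_confounder_effects(
            profiles, n_sex_probes=0, n_age_probes=15, n_plates=1, seed=6
        )
        eff.age_slopes[:] = np.abs(eff.age_slopes)
        stack = tile_profiles(profiles, meta.sample_ids)
        out = apply_age_effect(stack, meta, eff)
        pos = stack.probe_positions(eff.age_probe_ids)
        assert np.all(out.values[1, pos, :] >= out.values[0, pos, :] - 1e-12)


class TestMix:
    def test_two_probe_identity_profiles(self):
        probes, types = ["p1", "p2"], ["a", "b"]
        stack = IndividualProfiles(probes, types, ["s1"], np.eye(2)[None, :, :])
        a = ProportionMatrix(types, ["s1"], np.array([[0.3], [0.7]]))
        truth = SimulationTruth(a, None, stack, None, None)
        d = mix(truth)
        np.testing.assert_allclose(d.values[:, 0], [0.3, 0.7])

    def test_unit_vector_returns_type_profile(self):
        profiles = make_reference_profiles(50, 3, seed=1)
        stack = tile_profiles(profiles, ["s1"])
        a = ProportionMatrix(profiles.type_names, ["s1"], np.array([[0.0], [1.0], [0.0]]))
        d = mix(SimulationTruth(a, profiles, stack, None, None))
        np.testing.assert_allclose(d.values[:, 0], profiles.values[:, 1])

    def test_shape_mismatch_raises(self):
        profiles = make_reference_profiles(50, 3, seed=1)
        stack = tile_profiles(profiles, ["s1", "s2"])
        a = ProportionMatrix(profiles.type_names, ["s1"], np.array([[0.2], [0.5], [0.3]]))
        with pytest.raises(ValueError):
            mix(SimulationTruth(a, profiles, stack, None, None))


class TestPlateEffect:
    @pytest.fixture
    def d_meta(self):
        import pandas as pd

        d = BetaMatrix(["p1", "p2"], ["s1", "s2"], np.array([[0.8, 0.4], [0.2, 0.6]]))
        meta = CohortMetadata(
            pd.DataFrame(
                {"sex": [0, 1], "age": [50.0, 55.0], "plate": ["plate00", "plate01"]},
                index=pd.Index(["s1", "s2"], name="sample_id"),
            )
        )
        return d, meta

    def _effects(self, coefs):
        return ConfounderEffects(
            sex_probe_ids=[], sex_coefs=np.array([]),
            age_probe_ids=[], age_slopes=np.array([]), age_intercepts=np.array([]),
            type_ratios=np.zeros((0, 2)), type_names=["a", "b"], epithelial_type="a",
            plate_labels=["plate00", "plate01"], plate_coefs=np.asarray(coefs),
        )

    def test_unit_coefficients_are_identity(self, d_meta):
        d, meta = d_meta
        out = apply_plate_effect(d, meta, self._effects([1.0, 1.0]))
        np.testing.assert_array_equal(out.values, d.values)

    def test_multiplies_and_clamps(self, d_meta):
        d, meta = d_meta
        out = apply_plate_effect(d, meta, self._effects([1.0, 1.8]))
        np.testing.assert_allclose(out.values[:, 0], d.values[:, 0])
        np.testing.assert_allclose(out.values[:, 1], [0.72, 1.0])  # 0.6*1.8 clamps

    def test_unknown_plate_raises(self, d_meta):
        d, meta = d_meta
        meta.table.loc["s2", "plate"] = "plate99"
        with pytest.raises(ValueError, match="plate"):
            apply_plate_effect(d, meta, self._effects([1.0, 1.0]))


class TestNoise:
    def test_zero_epsilon_is_identity(self):
        d = BetaMatrix(["p1"], ["s1"], np.array([[0.4]]))
        out = add_noise(d, 0.0, seed=1)
        np.testing.assert_array_equal(out.values, d.values)

    def test_skip_at_boundary_keeps_original_value(self, rng):
        # near-boundary entries: any draw leaving [0,1] must leave the entry
        # exactly unchanged (not clamped to the bound)
        values = np.full((200, 50), 0.999)
        d = BetaMatrix([f"p{i}" for i in range(200)], [f"s{j}" for j in range(50)], values)
        out = add_noise(d, 0.5, seed=3)
        assert out.values.max() <= 1.0 and out.values.min() >= 0.0
        changed = out.values != 0.999
        assert changed.any()
        untouched = out.values[~changed]
        assert np.all(untouched == 0.999)
        assert not np.any(out.values == 1.0)  # clamping would produce exact 1.0

    def test_skip_rule_matches_rejection_construction(self):
        rng = np.random.default_rng(42)
        values = rng.uniform(0, 1, (30, 20))
        d = BetaMatrix([f"p{i}" for i in range(30)], [f"s{j}" for j in range(20)], values)
        out = add_noise(d, 0.2, seed=9)
        draws = np.random.default_rng(9).normal(0.0, 0.2, values.shape)
        cand = values + draws
        expected = np.where((cand >= 0) & (cand <= 1), cand, values)
        np.testing.assert_array_equal(out.values, expected)

    def test_mean_absolute_change_bounded_by_half_normal_mean(self, rng):
        values = rng.uniform(0, 1, (500, 100))
        d = BetaMatrix([f"p{i}" for i in range(500)], [f"s{j}" for j in range(100)], values)
        out = add_noise(d, 0.2, seed=5)
        half_normal_mean = 0.2 * np.sqrt(2 / np.pi)  # ~0.1596
        assert np.abs(out.values - values).mean() <= half_normal_mean


class TestFullSimulation:
    def test_noiseless_unconfounded_is_exact_factorization(self, clean_dataset):
        d, truth = clean_dataset
        recon = np.einsum(
            "nmk,kn->mn", truth.individual_profiles.values, truth.A_true.values
        )
        np.testing.assert_allclose(d.values, recon, atol=1e-12)
        np.testing.assert_allclose(
            d.values, truth.T_base.values @ truth.A_true.values, atol=1e-12
        )

    def test_centered_noiseless_matrix_has_rank_k_minus_one(self, clean_dataset):
        d, truth = clean_dataset
        xc = d.values - d.values.mean(axis=1, keepdims=True)
        s = np.linalg.svd(xc, compute_uv=False)
        assert int((s > 1e-10).sum()) == truth.config.n_types - 1

    def test_deterministic_given_seed(self, small_profiles, small_cohort, small_effects):
        cfg = SimulationConfig(n_samples=60, n_types=5, seed=99)
        d1, _ = simulate_dataset(cfg, small_profiles, small_cohort, small_effects)
        d2, _ = simulate_dataset(cfg, small_profiles, small_cohort, small_effects)
        np.testing.assert_array_equal(d1.values, d2.values)

    def test_all_entries_in_unit_interval(self, small_dataset):
        d, _ = small_dataset
        assert d.values.min() >= 0 and d.values.max() <= 1

    def test_noise_replicates_share_signal(self, small_profiles, small_cohort, small_effects):
        cfg = SimulationConfig(n_samples=60, n_types=5, seed=31)
        _, truth = simulate_dataset(cfg, small_profiles, small_cohort, small_effects)
        base = mix(truth)
        base = apply_plate_effect(base, small_cohort, small_effects)
        reps = [add_noise(base, 0.2, seed=s).values for s in (1, 2)]
        assert not np.array_equal(reps[0], reps[1])
        # both stay centered on the same clean matrix
        for rep in reps:
            assert np.abs((rep - base.values).mean()) < 0.01
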