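"""Synthetic cohort generators: copula calibration, behavioral, cytology,
hormone streams, seeding."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from fosnet import (
    BehavioralEffectSpec,
    BehavioralGroupParams,
    ConditionCovSpec,
    EstrousPhaseClassifier,
    MarginalSpec,
    SmearSpec,
    SyntheticCohortConfig,
    generate_behavior_cohort,
    generate_estradiol,
    generate_fos_cohort,
    generate_hormone_cytology_cohort,
    generate_smears,
    hormone_cytology_correlation,
    nearest_psd_correlation,
    olm_score,
    spearman,
    spearman_to_latent_pearson,
    ymaze_score,
)
from fosnet.simulate import ALL_CONDITIONS, sample_condition_counts


def planted_matrix(k, i, j, rho):
    m = np.eye(k)
    m[i, j] = m[j, i] = rho
    return m


class TestCopulaCalibration:
    @pytest.mark.parametrize(
        "rho_s, expected",
        [(0.0, 0.0), (1.0, 1.0), (-1.0, -1.0),
         (0.5, 0.5176380902050415)],  # 2*sin(pi/12), high-precision evaluation
    )
    def test_known_values(self, rho_s, expected):
        assert spearman_to_latent_pearson(rho_s) == pytest.approx(expected, abs=1e-12)

    @given(st.floats(-1, 1), st.floats(-1, 1))
    def test_monotone_odd_and_expanding(self, a, b):
        fa, fb = spearman_to_latent_pearson(a), spearman_to_latent_pearson(b)
        assert spearman_to_latent_pearson(-a) == pytest.approx(-fa, abs=1e-12)
        assert abs(fa) >= abs(a) - 1e-12
        if a + 1e-9 < b:
            assert fa < fb

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            spearman_to_latent_pearson(1.01)

    def test_psd_repair_restores_unit_diagonal_psd(self):
        # elementwise valid but jointly infeasible
        m = np.array([[1.0, 0.9, -0.9], [0.9, 1.0, 0.9], [-0.9, 0.9, 1.0]])
        fixed = nearest_psd_correlation(m)
        assert np.allclose(np.diag(fixed), 1.0)
        assert np.linalg.eigvalsh(fixed).min() >= 0
        psd = np.eye(3)
        assert nearest_psd_correlation(psd) is not None
        np.testing.assert_allclose(nearest_psd_correlation(psd), psd)


class TestFosCohort:
    def test_identity_target_gives_near_zero_spearman(self):
        cfg = SyntheticCohortConfig(
            regions=("R1", "R2", "R3"), n_per_condition=1000,
            marginals=tuple(MarginalSpec(r, mean=10.0) for r in ("R1", "R2", "R3")),
            seed=1)
        table = generate_fos_cohort(cfg)
        sub = table[(table.cycle == "highE2") & (table.stress == "control")]
        for a, b in (("R1", "R2"), ("R1", "R3"), ("R2", "R3")):
            assert abs(spearman(sub[a], sub[b]).rho) < 0.1

    def test_seeded_bit_reproducibility(self):
        cfg = SyntheticCohortConfig(seed=9, missing_rate=0.1)
        pd.testing.assert_frame_equal(generate_fos_cohort(cfg), generate_fos_cohort(cfg))

    def test_planted_spearman_recovered_at_large_n(self):
        rng = np.random.default_rng(4)
        marginals = [MarginalSpec("R1", mean=80.0), MarginalSpec("R2", mean=120.0)]
        counts = sample_condition_counts(5000, marginals,
                                         planted_matrix(2, 0, 1, 0.8), rng)
        assert spearman(counts[:, 0], counts[:, 1]).rho == pytest.approx(0.8, abs=0.05)

    def test_counts_are_nonnegative_integers_or_missing(self):
        cfg = SyntheticCohortConfig(seed=3, missing_rate=0.2)
        table = generate_fos_cohort(cfg)
        values = table[list(cfg.regions)].to_numpy(dtype=float)
        present = values[~np.isnan(values)]
        assert (present >= 0).all()
        assert np.allclose(present, np.round(present))
        assert not np.all(np.isnan(values), axis=1).any()  # >= 1 region per animal

    def test_negative_binomial_marginal(self):
        rng = np.random.default_rng(0)
        m = MarginalSpec("R1", "negative-binomial", mean=50.0, dispersion=2.0)
        counts = sample_condition_counts(4000, [m], np.eye(1), rng)
        assert counts.mean() == pytest.approx(50.0, rel=0.1)
        assert counts.var() > 2 * counts.mean()  # overdispersed

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_per_condition": 3},
            {"missing_rate": 1.0},
            {"marginals": (MarginalSpec("R1"),)},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SyntheticCohortConfig(**kwargs)

    def test_marginal_validation(self):
        with pytest.raises(ValueError):
            MarginalSpec("R1", mean=-1.0)
        with pytest.raises(ValueError):
            MarginalSpec("R1", "negative-binomial", mean=10.0)

    def test_covariance_validation(self):
        with pytest.raises(ValueError):
            ConditionCovSpec(("highE2", "control"),
                             np.array([[1.0, 0.5], [0.4, 1.0]]))

    def test_yaml_round_trip(self, tmp_path):
        cfg = SyntheticCohortConfig(
            regions=("R1", "R2"), n_per_condition=5,
            marginals=(MarginalSpec("R1", mean=30.0),
                       MarginalSpec("R2", "negative-binomial", 40.0, 3.0)),
            covariances=tuple(
                ConditionCovSpec(c, planted_matrix(2, 0, 1, 0.4))
                for c in ALL_CONDITIONS),
            missing_rate=0.05, seed=13)
        path = tmp_path / "cfg.yaml"
        cfg.to_yaml(path)
        again = SyntheticCohortConfig.from_yaml(path)
        assert again.to_dict() == cfg.to_dict()
        pd.testing.assert_frame_equal(generate_fos_cohort(cfg),
                                      generate_fos_cohort(again))


class TestBehaviorCohort:
    def test_null_preference_ratio_unbiased(self):
        spec = BehavioralEffectSpec(groups={
            c: BehavioralGroupParams(preference_ratio=1.0) for c in ALL_CONDITIONS})
        olm, _ = generate_behavior_cohort(spec, n_per_group=400, seed=2)
        ratios = [olm_score(s).preference_ratio for s in olm]
        assert np.mean(ratios) == pytest.approx(1.0, abs=0.05)

    def test_certain_first_entry_novel(self):
        spec = BehavioralEffectSpec(groups={
            c: BehavioralGroupParams(p_first_entry_novel=1.0) for c in ALL_CONDITIONS})
        _, ymaze = generate_behavior_cohort(spec, n_per_group=20, seed=2)
        assert all(ymaze_score(s).first_entry_novel for s in ymaze)

    def test_seeded_reproducibility(self):
        a = generate_behavior_cohort(n_per_group=5, seed=7)
        b = generate_behavior_cohort(n_per_group=5, seed=7)
        assert a == b

    def test_nonpositive_n_rejected(self):
        with pytest.raises(ValueError):
            generate_behavior_cohort(n_per_group=0)

    def test_group_structure_covers_all_conditions(self):
        olm, ymaze = generate_behavior_cohort(n_per_group=3, seed=1)
        assert {(s.cycle, s.stress) for s in olm} == set(ALL_CONDITIONS)
        assert len(ymaze) == 12


class TestSmearsAndHormones:
    def test_heavy_cornified_spec_classifies_estrus(self):
        spec = SmearSpec("estrus", (0.5, 60.0, 1.5))
        smears = generate_smears(1000, spec, seed=5)
        clf = EstrousPhaseClassifier().fit()
        calls = [clf.predict_call(s).phase for s in smears]
        assert np.mean([c == "estrus" for c in calls]) >= 0.95

    def test_uniform_concentrations_have_uniform_mean(self):
        smears = generate_smears(10000, SmearSpec("estrus", (1.0, 1.0, 1.0)), seed=6)
        comp = np.array([s.composition for s in smears])
        assert np.allclose(comp.mean(axis=0), [100 / 3] * 3, atol=2.0)

    def test_simplex_closure(self):
        for s in generate_smears(50, SmearSpec.default("early_proestrus"), seed=1):
            assert sum(s.composition) == pytest.approx(100.0, abs=1e-9)

    def test_estrus_estradiol_mostly_below_limit(self):
        samples = generate_estradiol("estrus", 500, seed=3)
        assert np.mean([h.below_limit for h in samples]) > 0.5
        high = generate_estradiol("early_proestrus", 500, seed=3)
        assert np.mean([h.below_limit for h in high]) < 0.5

    def test_zero_detection_limit_flags_nothing(self):
        samples = generate_estradiol("estrus", 100, detection_limit=0.0, seed=3)
        assert not any(h.below_limit for h in samples)

    def test_seeded_reproducibility(self):
        assert generate_estradiol("estrus", 20, seed=8) == \
            generate_estradiol("estrus", 20, seed=8)
        assert generate_smears(10, SmearSpec.default("estrus"), seed=8) == \
            generate_smears(10, SmearSpec.default("estrus"), seed=8)

    def test_hormone_cytology_signs_match_biology(self):
        samples, smears = generate_hormone_cytology_cohort(n_per_phase=20, seed=4)
        nuc = hormone_cytology_correlation(samples, smears, "nucleated")
        corn = hormone_cytology_correlation(samples, smears, "cornified")
        assert nuc.spearman_rho > 0
        assert corn.spearman_rho < 0
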