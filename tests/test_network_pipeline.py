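"""Per-condition matrices, differential networks, hub scores, pipeline."""

import numpy as np
import pandas as pd
import pytest

from fosnet import (
    CorrelationMatrix,
    DifferentialNetworkAnalysis,
    SyntheticCohortConfig,
    correlation_matrix,
    differential_network,
    generate_fos_cohort,
    node_strength,
    run_pipeline,
    scale_counts,
)
from fosnet.network import DEFAULT_REGIONS


def toy_matrix(r_ab, regions=("A", "B", "C"), n=20, condition=("highE2", "control")):
    r = np.eye(len(regions))
    r[0, 1] = r[1, 0] = r_ab
    n_eff = np.full((len(regions),) * 2, n)
    return CorrelationMatrix(
        condition,
        pd.DataFrame(r, index=regions, columns=regions),
        pd.DataFrame(n_eff, index=regions, columns=regions),
    )


@pytest.fixture(scope="module")
def cohort():
    return generate_fos_cohort(SyntheticCohortConfig(seed=11))


class TestCorrelationMatrix:
    def test_duplicated_regions_correlate_perfectly(self):
        base = [3.0, 9.0, 1.0, 7.0, 5.0]
        t = pd.DataFrame({
            "animal_id": [f"a{i}" for i in range(5)],
            "cycle": "highE2", "stress": "control",
            "R1": base, "R2": base,
        })
        m = correlation_matrix(t, ("highE2", "control"))
        assert m.r.loc["R1", "R2"] == pytest.approx(1.0)

    def test_identity_cohort_has_small_offdiagonals(self):
        cfg = SyntheticCohortConfig(regions=("R1", "R2", "R3", "R4"),
                                    n_per_condition=500, seed=5)
        table = generate_fos_cohort(cfg)
        m = correlation_matrix(table, ("lowE2", "MAS"))
        off = m.r.to_numpy()[~np.eye(4, dtype=bool)]
        assert np.abs(off).max() < 0.15

    def test_symmetry_and_unit_diagonal(self, cohort):
        m = correlation_matrix(cohort, ("highE2", "MAS"))
        assert np.allclose(m.r, m.r.T)
        assert np.allclose(np.diag(m.r), 1.0)
        assert (m.n_eff.to_numpy() <= 7).all()

    def test_absent_condition_rejected(self, cohort):
        with pytest.raises(ValueError):
            correlation_matrix(cohort[cohort.cycle == "highE2"], ("lowE2", "MAS"))


class TestDifferentialNetwork:
    def test_identical_matrices_give_empty_retained_set(self):
        m = toy_matrix(0.6)
        net = differential_network(m, toy_matrix(0.6, condition=("lowE2", "control")),
                                   display_threshold=0.5)
        assert all(e.z_obs == pytest.approx(0.0, abs=1e-12) for e in net.edges)
        assert net.retained == []

    def test_three_region_toy_hand_value(self):
        # (atanh(0.9) - 0) / sqrt(2/17), frozen from high-precision evaluation
        net = differential_network(
            toy_matrix(0.9), toy_matrix(0.0, condition=("lowE2", "control")))
        by_pair = {(e.region_a, e.region_b): e for e in net.edges}
        assert by_pair[("A", "B")].z_obs == pytest.approx(4.292221, abs=1e-6)
        assert by_pair[("A", "C")].z_obs == pytest.approx(0.0, abs=1e-12)
        assert by_pair[("B", "C")].z_obs == pytest.approx(0.0, abs=1e-12)
        assert by_pair[("A", "B")].direction == "increased"

    def test_eleven_regions_yield_55_pairs(self, cohort):
        scaled, _ = scale_counts(cohort)
        m1 = correlation_matrix(scaled, ("highE2", "MAS"))
        m2 = correlation_matrix(scaled, ("highE2", "control"))
        net = differential_network(m1, m2)
        assert len(net.edges) == 55 == len(DEFAULT_REGIONS) * 10 // 2

    def test_antisymmetric_under_group_swap(self, cohort):
        scaled, _ = scale_counts(cohort)
        m1 = correlation_matrix(scaled, ("highE2", "MAS"))
        m2 = correlation_matrix(scaled, ("lowE2", "MAS"))
        fwd = differential_network(m1, m2).to_frame().set_index(["region_a", "region_b"])
        rev = differential_network(m2, m1).to_frame().set_index(["region_a", "region_b"])
        assert np.allclose(fwd["z_obs"], -rev["z_obs"], atol=1e-12)

    def test_region_set_mismatch_rejected(self):
        with pytest.raises(ValueError):
            differential_network(toy_matrix(0.5),
                                 toy_matrix(0.5, regions=("A", "B", "D")))


class TestNodeStrength:
    def test_empty_retained_set_gives_zero_strengths(self):
        net = differential_network(
            toy_matrix(0.1), toy_matrix(0.1, condition=("lowE2", "control")))
        assert (node_strength(net)["strength"] == 0).all()

    def test_single_edge_credits_both_endpoints(self):
        net = differential_network(
            toy_matrix(0.9), toy_matrix(0.0, condition=("lowE2", "control")))
        s = node_strength(net)
        mag = abs(net.retained[0].z_obs)
        assert s.loc["A", "strength"] == pytest.approx(mag)
        assert s.loc["B", "strength"] == pytest.approx(mag)
        assert s.loc["C", "strength"] == 0.0

    def test_handshake_identity(self, cohort):
        res = run_pipeline(cohort, display_threshold=0.5)
        for net in res.networks.values():
            s = node_strength(net)["strength"].sum()
            assert s == pytest.approx(2 * sum(e.magnitude for e in net.retained))


class TestPipeline:
    def test_deterministic_on_fixed_input(self, cohort):
        a = run_pipeline(cohort).zobs_table
        b = run_pipeline(cohort).zobs_table
        pd.testing.assert_frame_equal(a, b)

    def test_four_default_comparisons(self, cohort):
        res = run_pipeline(cohort)
        assert len(res.networks) == 4
        assert len(res.zobs_table) == 4 * 55

    def test_monotone_transform_leaves_zobs_unchanged(self, cohort):
        base = run_pipeline(cohort).zobs_table["z_obs"].to_numpy()
        warped = cohort.copy()
        for region in DEFAULT_REGIONS:
            warped[region] = warped[region] ** 3 + 2.0
        again = run_pipeline(warped).zobs_table["z_obs"].to_numpy()
        assert np.allclose(base, again, atol=1e-12)

    def test_estimator_interface(self, cohort):
        est = DifferentialNetworkAnalysis(display_threshold=1.0, fdr=True)
        assert est.get_params()["display_threshold"] == 1.0
        est.fit(cohort)
        assert set(est.matrices_) == {
            ("highE2", "control"), ("highE2", "MAS"),
            ("lowE2", "control"), ("lowE2", "MAS")}
        assert "q_value" in est.zobs_table_.columns
        assert (est.zobs_table_["q_value"] >= 0).all()
        strengths = est.node_strengths()
        assert set(strengths["comparison"]) == set(est.networks_)

    def test_missing_pairs_excluded_not_imputed(self):
        cfg = SyntheticCohortConfig(regions=("R1", "R2", "R3", "R4", "R5"),
                                    n_per_condition=6, missing_rate=0.35, seed=2)
        table = generate_fos_cohort(cfg)
        res = run_pipeline(table)
        nets = list(res.networks.values())
        assert any(net.excluded_pairs for net in nets)
        for net in nets:
            assert len(net.edges) + len(net.excluded_pairs) == 10
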