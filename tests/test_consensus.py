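import numpy as np
import pytest

from netforge import (
    Network,
    RewiringConfig,
    agreement,
    consensus_partitions,
    empirical_pvalue,
    generate_er,
    initial_agreement,
    intramodule_density,
    matrix_similarity,
    modularity_louvain,
    null_agreement,
    partition_overlap,
    proto_module_analysis,
    run_topological_reinforcement,
)
from netforge.experiments import PlantedPartitionSpec, generate_planted_partition

from .oracles import expected_null_coclassification


class TestAgreement:
    def test_identical_partitions_give_binary_matrix(self):
        p = np.array([0, 0, 1, 1])
        a = agreement([p, p])
        expected = (p[:, None] == p[None, :]).astype(float)
        assert np.array_equal(a, expected)

    def test_direct_count_example(self):
        a = agreement([np.array([0, 0, 1]), np.array([0, 1, 1])])
        assert a[0, 1] == 0.5 and a[0, 2] == 0.0 and a[1, 2] == 0.5

    def test_unit_diagonal_and_symmetry(self, rng):
        parts = [rng.integers(0, 4, size=30) for _ in range(20)]
        a = agreement(parts)
        assert np.allclose(np.diag(a), 1.0)
        assert np.allclose(a, a.T)
        assert a.min() >= 0 and a.max() <= 1

    def test_mismatched_lengths_raise(self):
        with pytest.raises(ValueError):
            agreement([np.zeros(3), np.zeros(4)])


class TestNullAgreement:
    def test_module_sizes_preserved(self, rng):
        parts = [rng.integers(0, 3, size=25) for _ in range(10)]
        shuffled_p = null_agreement(parts, seed=0)
        assert shuffled_p.shape == (25, 25)
        assert np.allclose(np.diag(shuffled_p), 1.0)

    def test_single_module_partitions_give_all_ones(self):
        parts = [np.zeros(8, dtype=int)] * 4
        assert np.all(null_agreement(parts, seed=1) == 1.0)

    def test_expectation_matches_closed_form(self, rng):
        # a fixed node pair's co-classification frequency over many shuffles
        # is sum_m s_m(s_m-1) / (N(N-1)); check within 3 SE
        labels = np.repeat([0, 1, 2], [10, 6, 4])
        n_shuffles = 1000
        vals = [null_agreement([labels], seed=s)[0, 1] for s in range(n_shuffles)]
        expected = expected_null_coclassification(labels)
        se = np.std(vals, ddof=1) / np.sqrt(n_shuffles)
        assert abs(np.mean(vals) - expected) < 3 * se


class TestConsensusPartitions:
    def test_block_constant_agreement_recovers_blocks(self):
        labels = np.repeat([0, 1], [6, 6])
        p = (labels[:, None] == labels[None, :]).astype(float)
        parts = consensus_partitions(p, n=10, seed=0)
        for part in parts:
            assert partition_overlap(part, labels) == pytest.approx(1.0)

    def test_single_run(self):
        p = np.eye(5) + 0.3
        parts = consensus_partitions(p, n=1, seed=0)
        assert len(parts) == 1 and parts[0].shape == (5,)

    def test_zero_offdiagonal_raises(self):
        with pytest.raises(ValueError):
            consensus_partitions(np.eye(4), n=2)


class TestInitialAgreement:
    def test_disjoint_cliques_block_structure(self, two_cliques):
        p_init, parts = initial_agreement(two_cliques, n_detect=20, n_consensus=5, seed=0)
        labels = np.repeat([0, 1], 5)
        expected = (labels[:, None] == labels[None, :]).astype(float)
        assert np.array_equal(p_init, expected)
        assert all(partition_overlap(p, labels) == 1.0 for p in parts)

    def test_er_graph_has_intermediate_agreement(self, er_100_10):
        p_init, _ = initial_agreement(er_100_10, n_detect=50, n_consensus=5, seed=1)
        iu = np.triu_indices(100, 1)
        frac_intermediate = np.mean((p_init[iu] > 0) & (p_init[iu] < 1))
        assert frac_intermediate > 0.1  # Louvain degeneracy on weak signal

    def test_seeded_reproducibility(self, er_100_10):
        a, _ = initial_agreement(er_100_10, n_detect=20, n_consensus=3, seed=5)
        b, _ = initial_agreement(er_100_10, n_detect=20, n_consensus=3, seed=5)
        assert np.array_equal(a, b)


class TestPartitionOverlap:
    def test_identical_nontrivial(self):
        p = np.array([0, 0, 1, 1, 2])
        assert partition_overlap(p, p) == pytest.approx(1.0)

    def test_independent_labels(self):
        assert partition_overlap(np.array([0, 0, 1, 1]),
                                 np.array([0, 1, 0, 1])) == pytest.approx(0.0)

    def test_degenerate_conventions(self):
        with pytest.warns(UserWarning):
            assert partition_overlap(np.zeros(4), np.zeros(4)) == 1.0
        assert partition_overlap(np.zeros(4), np.array([0, 0, 1, 1])) == 0.0

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            partition_overlap(np.zeros(3), np.zeros(4))


class TestMatrixSimilarity:
    def test_self_and_anti_correlation(self, rng):
        m = rng.random((6, 6))
        m = (m + m.T) / 2
        assert matrix_similarity(m, m) == pytest.approx(1.0)
        assert matrix_similarity(m, -m) == pytest.approx(-1.0)

    def test_hand_example_perfect_linear_relation(self):
        m1 = np.array([[0, 1, 2], [1, 0, 3], [2, 3, 0]], float)
        assert matrix_similarity(m1, 2 * m1) == pytest.approx(1.0)

    def test_zero_variance_flagged(self):
        with pytest.warns(UserWarning):
            assert np.isnan(matrix_similarity(np.ones((3, 3)), np.eye(3)))


class TestIntramoduleDensity:
    def test_complete_graph(self):
        net = generate_er(8, 7, seed=0)
        assert intramodule_density(net, np.repeat([0, 1], 4)) == 1.0

    def test_planted_partition_recovers_within_density(self):
        spec = PlantedPartitionSpec(n_nodes=120, n_modules=3, p_within=0.3,
                                    p_between=0.05, seed=1)
        net, truth = generate_planted_partition(spec)
        # binomial sampling noise: 3 SE on pooled within-block pairs
        n_pairs = 3 * (40 * 39 // 2)
        se = np.sqrt(0.3 * 0.7 / n_pairs)
        assert abs(intramodule_density(net, truth) - 0.3) < 3 * se

    def test_all_singletons_raise(self, path4):
        with pytest.raises(ValueError):
            intramodule_density(path4, np.arange(4))

    def test_shuffled_partitions_probe_graph_density(self, er_100_10, rng):
        # random node groups of an ER graph have within-density ≈ overall density
        vals = []
        for _ in range(200):
            labels = modularity_louvain(er_100_10, seed=int(rng.integers(2**31))).labels
            vals.append(intramodule_density(er_100_10, rng.permutation(labels)))
        assert np.mean(vals) == pytest.approx(0.1, abs=0.01)


class TestEmpiricalPvalue:
    def test_conventions(self):
        null = np.arange(99)
        assert empirical_pvalue(1000, null) == pytest.approx(1 / 100)
        assert empirical_pvalue(-5, null, alternative="less") == pytest.approx(1 / 100)
        assert empirical_pvalue(50, null) == pytest.approx((48 + 1 + 1) / 100)


@pytest.fixture(scope="module")
def small_report():
    net = generate_er(100, 10, seed=11)

    def tr_runner(g, seed):
        return run_topological_reinforcement(
            g, RewiringConfig(seed=seed), n_detect=0).final

    return proto_module_analysis(
        net, tr_runner, n_runs=25, n_detect_init=60, n_consensus=15,
        n_null=30, n_density_reps=60, seed=2)


class TestProtoModuleAnalysis:
    def test_agreement_matrices_well_formed(self, small_report):
        for m in (small_report.p, small_report.p_init, small_report.p_null):
            assert np.allclose(np.diag(m), 1.0)
            assert np.allclose(m, m.T)
            assert m.min() >= 0 and m.max() <= 1

    def test_pvalues_present_and_valid(self, small_report):
        for key in ("sim_init_final", "nmi_init_final", "sim_pinit_p", "nmi_pinit_p"):
            assert 0 < small_report.pvalues[key] <= 1

    def test_density_distributions_ordered(self, small_report):
        # consensus and direct-graph partitions find denser-than-chance groups
        assert small_report.dens_consensus.mean() > small_report.dens_null.mean()
        assert small_report.dens_graph.mean() > small_report.dens_null.mean()

    def test_planted_modules_survive_the_pipeline(self):
        spec = PlantedPartitionSpec(n_nodes=80, n_modules=4, p_within=0.35,
                                    p_between=0.03, seed=3)
        net, truth = generate_planted_partition(spec)

        def tr_runner(g, seed):
            return run_topological_reinforcement(
                g, RewiringConfig(seed=seed), n_detect=0).final

        report = proto_module_analysis(net, tr_runner, n_runs=10, n_detect_init=30,
                                       n_consensus=10, n_null=10,
                                       n_density_reps=20, seed=4)
        overlaps = [partition_overlap(p, truth) for p in report.init_consensus_parts]
        assert np.mean(overlaps) > 0.9  # strong planted modules are fixed points
        # and the final-run consensus matches the initial consensus closely
        cross = [partition_overlap(a, b)
                 for a in report.init_consensus_parts for b in report.consensus_parts]
        assert np.mean(cross) > 0.5

    def test_single_run_flagged_degenerate(self, er_100_10):
        def tr_runner(g, seed):
            return run_topological_reinforcement(
                g, RewiringConfig(K=0.1, seed=seed), n_detect=0).final

        report = proto_module_analysis(er_100_10, tr_runner, n_runs=1,
                                       n_detect_init=10, n_consensus=3,
                                       n_null=5, n_density_reps=5, seed=0)
        assert report.flags
        assert set(np.unique(report.p)) <= {0.0, 1.0}
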