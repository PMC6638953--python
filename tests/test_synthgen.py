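"""Planted-network assembly and Gaussian-copula cohort generation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from psychonectome import synthgen as sg
from psychonectome.ggm import unregularized_pcor


def chain3(w1=0.3, w2=0.3):
    return sg.make_planted_network(
        3, chain_specs=[(["A", "B", "C"], [w1, w2])], node_labels=list("ABC"))


class TestMakePlantedNetwork:
    def test_two_node_chain_is_exact(self):
        net = sg.make_planted_network(
            2, chain_specs=[(["A", "B"], [0.5])], node_labels=["A", "B"])
        assert net.pcor[0, 1] == pytest.approx(0.5)  # PD without inflation
        assert np.linalg.eigvalsh(net.precision())[0] > 0

    def test_three_node_chain_marginals_by_hand(self):
        # invert the 3x3 precision [[1,-.3,0],[-.3,1,-.3],[0,-.3,1]] by hand:
        # det = 1 - 2*0.09; Sigma_AC/sqrt(Sigma_AA*Sigma_CC) = 0.09/(1-0.09)
        net = chain3()
        assert net.pcor[0, 1] == pytest.approx(0.3)
        assert net.pcor[1, 2] == pytest.approx(0.3)
        assert net.pcor[0, 2] == 0.0
        R = net.implied_correlation()
        assert R[0, 2] == pytest.approx(0.09 / 0.91, abs=1e-12)
        assert R[0, 2] > 0  # chain induces marginal dependence

    def test_planted_path_edges_realized_within_tolerance(self):
        # the six mindfulness-chain weights 0.33..0.22 on 25 nodes
        weights = [0.33, 0.29, 0.22, 0.23, 0.25, 0.22]
        nodes = ["FFMQ-O", "MAIA", "EQ", "NAS", "SCS-M", "SCS-A", "SCS-H"]
        net = sg.make_planted_network(chain_specs=[(nodes, weights)])
        for (a, b), w in zip(zip(nodes[:-1], nodes[1:]), weights):
            i, j = net.node_labels.index(a), net.node_labels.index(b)
            assert abs(net.pcor[i, j] - w) <= 0.02

    def test_realized_equals_requested_when_diagonally_dominant(self, rng):
        for _ in range(10):
            k = int(rng.integers(3, 8))
            W = np.zeros((k, k))
            for i in range(k):
                for j in range(i + 1, k):
                    W[i, j] = W[j, i] = rng.uniform(-0.9, 0.9)
            # scale rows until diagonally dominant
            s = np.abs(W).sum(axis=1).max()
            W *= 0.95 / max(s, 1e-9)
            edges = [(i, j, W[i, j]) for i in range(k) for j in range(i + 1, k)
                     if abs(W[i, j]) > 0]
            net = sg.make_planted_network(
                k, negative_edges=edges, node_labels=[f"V{i}" for i in range(k)])
            assert np.allclose(net.pcor, W, atol=1e-12)

    def test_pcor_roundtrip_through_implied_correlation(self, rng):
        net = sg.random_sparse_network(k=12, density=0.2, seed=7)
        back = unregularized_pcor(net.implied_correlation()).weights
        assert np.abs(back - net.pcor).max() < 1e-10

    def test_pd_repair_shrinks_uniformly_and_keeps_zeros(self):
        # a 6-clique at 0.4 partial correlation is indefinite and gets repaired
        net = sg.make_planted_network(
            7, block_specs=[([0, 1, 2, 3, 4, 5], 0.4)],
            node_labels=[f"V{i}" for i in range(7)])
        # the ridge floor applies before the unit-diagonal rescale; after it
        # the matrix stays strictly PD
        assert np.linalg.eigvalsh(net.precision())[0] > 0
        assert abs(net.pcor[0, 1]) < 0.4  # shrunk
        assert net.pcor[0, 6] == 0.0      # planted zero stays zero
        ratio = net.pcor[:6, :6][np.triu_indices(6, 1)] / 0.4
        assert np.ptp(ratio) < 1e-10      # uniform shrink

    def test_community_labels(self):
        net = sg.make_planted_network(
            5, block_specs=[([0, 1], 0.3), ([2, 3], 0.3)],
            node_labels=list("ABCDE"))
        assert net.communities == {"A": 0, "B": 0, "C": 1, "D": 1, "E": 2}

    def test_weight_range_and_conflicts_raise(self):
        with pytest.raises(sg.InvalidParameterError):
            sg.make_planted_network(2, chain_specs=[(["A", "B"], [1.2])],
                                    node_labels=["A", "B"])
        with pytest.raises(sg.EdgeConflictError):
            sg.make_planted_network(
                3, chain_specs=[(["A", "B"], [0.3]), (["B", "A"], [0.4])],
                node_labels=list("ABC"))


class TestRandomSparseNetwork:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_density_weights_and_conditioning(self, seed):
        net = sg.random_sparse_network(k=25, density=0.15,
                                       weight_range=(0.2, 0.45), seed=seed)
        nz = np.abs(net.pcor[np.triu_indices(25, 1)])
        nz = nz[nz > 0]
        assert len(nz) == 45
        assert nz.min() >= 0.2 - 1e-12 and nz.max() <= 0.45 + 1e-12
        assert np.linalg.eigvalsh(net.precision())[0] > 0.04

    def test_infeasible_request_raises(self):
        with pytest.raises(sg.InvalidParameterError):
            sg.random_sparse_network(k=10, density=0.8, weight_range=(0.4, 0.45))


class TestSampleCohort:
    def test_independent_nodes_uncorrelated(self):
        net = sg.make_planted_network(4, node_labels=list("ABCD"))
        co = sg.sample_cohort(net, n=5000, levels=5, seed=0)
        r = stats.spearmanr(co.scores).statistic
        off = r[np.triu_indices(4, 1)]
        assert np.abs(off).max() < 0.05

    def test_two_node_continuous_recovers_pcor(self):
        net = sg.make_planted_network(
            2, chain_specs=[(["A", "B"], [0.5])], node_labels=["A", "B"])
        co = sg.sample_cohort(net, n=10000, levels=0, seed=1)
        r = np.corrcoef(co.scores.T)[0, 1]
        assert r == pytest.approx(0.5, abs=0.02)

    def test_ordinal_spearman_matches_monte_carlo_attenuation(self):
        # oracle: 10^6 latent draws at the same rho, discretized identically
        rho = 0.5
        orng = np.random.default_rng(99)
        z1 = orng.standard_normal(10 ** 6)
        z2 = rho * z1 + np.sqrt(1 - rho ** 2) * orng.standard_normal(10 ** 6)
        thr = stats.norm.ppf(np.arange(1, 5) / 5)
        expected = stats.spearmanr(np.searchsorted(thr, z1),
                                   np.searchsorted(thr, z2)).statistic
        net = sg.make_planted_network(
            2, chain_specs=[(["A", "B"], [0.5])], node_labels=["A", "B"])
        co = sg.sample_cohort(net, n=10000, levels=5, seed=2)
        got = stats.spearmanr(co.scores[:, 0], co.scores[:, 1]).statistic
        assert got == pytest.approx(expected, abs=0.04)

    def test_continuous_empirical_matrix_converges(self):
        net = sg.random_sparse_network(k=10, density=0.2, seed=3)
        n = 40000
        co = sg.sample_cohort(net, n=n, levels=0, seed=3)
        R_hat = np.corrcoef(co.scores.T)
        assert np.abs(R_hat - net.implied_correlation()).max() < 6.0 / np.sqrt(n)

    def test_scores_on_ordinal_grid_and_determinism(self):
        net = chain3()
        a = sg.sample_cohort(net, n=50, levels=5, seed=7)
        b = sg.sample_cohort(net, n=50, levels=5, seed=7)
        assert np.array_equal(a.scores, b.scores)
        assert set(np.unique(a.scores)) <= set(range(1, 6))

    def test_tiny_n_rejected(self):
        with pytest.raises(sg.InvalidParameterError):
            sg.sample_cohort(chain3(), n=1)


class TestMakePrePost:
    def test_zero_subject_rho_decouples_occasions(self):
        net = chain3()
        pre, post = sg.make_pre_post(net, net, n=5000, subject_rho=0.0,
                                     levels=0, seed=0)
        for j in range(3):
            r = np.corrcoef(pre.latent[:, j], post.latent[:, j])[0, 1]
            assert abs(r) < 0.05

    def test_subject_rho_half_recovered(self):
        net = chain3()
        pre, post = sg.make_pre_post(net, net, n=5000, subject_rho=0.5,
                                     levels=0, seed=1)
        for j in range(3):
            r = np.corrcoef(pre.latent[:, j], post.latent[:, j])[0, 1]
            assert r == pytest.approx(0.5, abs=0.03)

    def test_each_occasion_keeps_own_structure(self):
        pre_net = chain3(0.4, 0.4)
        post_net = sg.make_planted_network(
            3, block_specs=[(["A", "B", "C"], 0.25)], node_labels=list("ABC"))
        pre, post = sg.make_pre_post(pre_net, post_net, n=20000,
                                     subject_rho=0.4, levels=0, seed=2)
        for cohort, net in ((pre, pre_net), (post, post_net)):
            R_hat = np.corrcoef(cohort.latent.T)
            assert np.abs(R_hat - net.implied_correlation()).max() < 0.03

    def test_label_mismatch_raises(self):
        a = chain3()
        b = sg.make_planted_network(3, node_labels=list("XYZ"))
        with pytest.raises(sg.SchemaError):
            sg.make_pre_post(a, b, n=10)


class TestApplyMcar:
    def test_rate_zero_masks_nothing(self):
        co = sg.sample_cohort(chain3(), n=100, levels=5, seed=0)
        assert not sg.apply_mcar(co, 0.0).missing_mask.any()

    def test_realized_rate_near_nominal(self):
        net = sg.make_planted_network(25)
        co = sg.sample_cohort(net, n=1000, levels=5, seed=1)
        masked = sg.apply_mcar(co, 0.108, seed=2)
        assert masked.missing_mask.mean() == pytest.approx(0.108, abs=0.006)

    def test_rate_out_of_range(self):
        co = sg.sample_cohort(chain3(), n=20, levels=5, seed=0)
        with pytest.raises(sg.InvalidParameterError):
            sg.apply_mcar(co, 0.7)

    def test_missingness_independent_of_values(self):
        # masked-vs-observed mean difference non-significant (alpha=0.01) in
        # at least 99% of column checks across 100 seeds
        net = sg.make_planted_network(5, node_labels=list("ABCDE"))
        checks, fails = 0, 0
        for seed in range(100):
            co = sg.sample_cohort(net, n=400, levels=5, seed=seed)
            masked = sg.apply_mcar(co, 0.108, seed=10_000 + seed)
            for j in range(5):
                m = masked.missing_mask[:, j]
                if m.sum() < 5:
                    continue
                p = stats.ttest_ind(co.scores[m, j], co.scores[~m, j],
                                    equal_var=False).pvalue
                checks += 1
                fails += p < 0.01
        assert fails / checks <= 0.02


class TestIO:
    def test_cohort_roundtrip(self, tmp_path):
        co = sg.apply_mcar(
            sg.sample_cohort(chain3(), n=40, levels=5, seed=5), 0.2, seed=6)
        sg.write_cohort(co, tmp_path / "c.csv", seed=5)
        back = sg.read_cohort(tmp_path / "c.csv")
        assert back.node_labels == co.node_labels
        assert back.levels == 5 and back.occasion == co.occasion
        assert np.array_equal(back.missing_mask, co.missing_mask)
        obs = co.observed()
        assert np.allclose(back.observed()[~co.missing_mask],
                           obs[~co.missing_mask])

    def test_network_roundtrip(self, tmp_path):
        net = sg.random_sparse_network(k=8, density=0.3, seed=9)
        sg.write_planted_network(net, tmp_path / "n.tsv", tmp_path / "n.json")
        back = sg.read_planted_network(tmp_path / "n.json")
        assert back.node_labels == net.node_labels
        assert np.allclose(back.pcor, net.pcor, atol=1e-12)
        assert back.communities == net.communities


@settings(max_examples=25, deadline=None, derandomize=True)
@given(w1=st.floats(-0.6, 0.6), w2=st.floats(-0.6, 0.6))
def test_chain_network_invariants(w1, w2):
    """Any admissible 3-chain yields a symmetric zero-diagonal PD structure."""
    net = sg.make_planted_network(
        3, chain_specs=[(["A", "B", "C"], [w1, w2])], node_labels=list("ABC"))
    assert np.allclose(net.pcor, net.pcor.T)
    assert np.all(np.diag(net.pcor) == 0)
    assert np.linalg.eigvalsh(net.precision())[0] >= 1e-6 - 1e-9
    assert sorted(net.communities) == ["A", "B", "C"]
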