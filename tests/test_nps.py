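import numpy as np
import pandas as pd
import pytest

from colocnet.core import GeneNetwork, SeedGeneSet, ValidationError
from colocnet.nps import (
    ConsensusConfig,
    NPSTable,
    combine_nps,
    compute_nps,
    consensus_nps,
    degree_bins,
    sample_null_seed_sets,
    weighted_subsamples,
)
from colocnet.synth import SyntheticSpec, make_network
from conftest import random_network


def seeds(*genes, source="other", pvalues=None):
    return SeedGeneSet(name="s", source=source, genes=frozenset(genes), pvalues=pvalues)


def line_network(n):
    return GeneNetwork.from_edges([(f"g{i:03d}", f"g{i+1:03d}") for i in range(n - 1)])


class TestDegreeBins:
    def test_25_nodes_two_bins(self):
        net = line_network(25)
        b = degree_bins(net, min_bin_size=10)
        assert sorted(len(x) for x in b.bins) == [10, 15]

    def test_small_network_single_bin(self):
        net = line_network(9)
        b = degree_bins(net, min_bin_size=10)
        assert len(b.bins) == 1
        assert len(b.bins[0]) == 9

    def test_bins_partition_nodes(self, rng):
        net = random_network(rng, 57)
        b = degree_bins(net)
        allg = set().union(*b.bins)
        assert allg == set(net.nodes)
        assert sum(len(x) for x in b.bins) == net.n_nodes

    def test_bins_contiguous_in_degree(self, rng):
        net = random_network(rng, 80)
        b = degree_bins(net)
        deg = net.degree
        maxes = [max(deg[g] for g in x) for x in b.bins]
        mins = [min(deg[g] for g in x) for x in b.bins]
        for i in range(len(b.bins) - 1):
            assert maxes[i] <= mins[i + 1]

    def test_regular_graph_uniform_bins(self):
        # all nodes degree 2 (cycle): bins are arbitrary splits of one class
        edges = [(f"c{i}", f"c{(i+1) % 30}") for i in range(30)]
        net = GeneNetwork.from_edges(edges)
        b = degree_bins(net)
        assert all(len(x) >= 10 for x in b.bins)


class TestNullSampling:
    def test_size_preserved(self, rng):
        net = random_network(rng, 60)
        pos = [g for g in sorted(net.nodes) if net.degree[g] > 0]
        s = seeds(*pos[:5])
        ens = sample_null_seed_sets(net, s, degree_bins(net), R=3, rng_seed=1)
        assert ens.n_sets == 3
        for null_set in ens.sets:
            assert len(set(null_set)) == 5

    def test_bin_index_match(self, rng):
        net = random_network(rng, 60)
        binning = degree_bins(net)
        pos = [g for g in sorted(net.nodes) if net.degree[g] > 0]
        s = seeds(*pos[:6])
        ens = sample_null_seed_sets(net, s, binning, R=5, rng_seed=2)
        for null_set in ens.sets:
            for orig, repl in zip(ens.seed_order, null_set):
                assert binning.bin_of(orig) == binning.bin_of(repl)

    def test_deterministic(self, rng):
        net = random_network(rng, 60)
        binning = degree_bins(net)
        pos = [g for g in sorted(net.nodes) if net.degree[g] > 0]
        s = seeds(*pos[:4])
        e1 = sample_null_seed_sets(net, s, binning, R=4, rng_seed=9)
        e2 = sample_null_seed_sets(net, s, binning, R=4, rng_seed=9)
        assert e1.sets == e2.sets

    def test_bin_too_small_errors(self):
        net = line_network(8)  # single bin of 8
        s = seeds(*[f"g{i:03d}" for i in range(8)])
        binning = degree_bins(net)
        ens = sample_null_seed_sets(net, s, binning, R=2, rng_seed=0)  # exactly fits
        assert ens.n_sets == 2
        with pytest.raises(ValidationError, match="larger bins"):
            sample_null_seed_sets(net, s, binning, R=2, rng_seed=0, exclude_seeds=True)


class TestComputeNps:
    def test_requires_r_at_least_two(self, triangle, seed_a):
        with pytest.raises(ValidationError):
            compute_nps(triangle, seed_a, R=1, rng_seed=0)

    def test_zero_variance_warns_and_zeroes(self):
        net = GeneNetwork.from_edges([("A", "B")])
        s = seeds("A", "B")
        with pytest.warns(RuntimeWarning, match="zero null variance"):
            nps = compute_nps(net, s, R=5, rng_seed=0)
        assert (nps == 0).all()

    def test_deterministic(self, rng):
        net = random_network(rng, 80)
        pos = [g for g in sorted(net.nodes) if net.degree[g] > 0]
        s = seeds(*pos[:6])
        a = compute_nps(net, s, R=20, rng_seed=5)
        b = compute_nps(net, s, R=20, rng_seed=5)
        pd.testing.assert_series_equal(a, b)

    def test_null_calibration_small(self):
        # a random seed set on a synthetic graph: NPS centered near 0
        spec = SyntheticSpec(n_genes=300, module_size=20, density_multiplier=1.0,
                             attachment=4, rng_seed=3)
        net, _ = make_network(spec)
        gen = np.random.default_rng(0)
        pos = np.array([g for g in sorted(net.nodes) if net.degree[g] > 0], dtype=object)
        s = seeds(*gen.choice(pos, size=10, replace=False))
        nps = compute_nps(net, s, R=100, rng_seed=1)
        assert abs(nps.mean()) < 0.2

    def test_signal_detection_planted_module(self):
        spec = SyntheticSpec(n_genes=500, module_size=25, density_multiplier=10.0,
                             seeds_per_source=10, attachment=6, rng_seed=4)
        net, truth = make_network(spec)
        module = truth["module"]
        gen = np.random.default_rng(1)
        s = seeds(*gen.choice(np.array(module, dtype=object), size=10, replace=False))
        nps = compute_nps(net, s, R=100, rng_seed=2, exclude_seeds_from_null=True)
        frac_high = (nps[module] > 2).mean()
        assert frac_high > 0.5


class TestCombineNps:
    def make(self, vals):
        return pd.Series(vals, index=pd.Index([f"g{i}" for i in range(len(vals))], name="gene"))

    def test_product(self):
        t = combine_nps(self.make([2.0, -1.0, 0.0]), self.make([1.5, 3.0, 7.0]))
        assert list(t.frame["nps_combined"]) == [3.0, -3.0, 0.0]

    def test_symmetry(self):
        a, b = self.make([1.0, 2.0]), self.make([3.0, -4.0])
        t1 = combine_nps(a, b)
        t2 = combine_nps(b, a)
        assert np.allclose(t1.frame["nps_combined"], t2.frame["nps_combined"])

    def test_universe_mismatch(self):
        a = self.make([1.0, 2.0])
        b = pd.Series([1.0], index=pd.Index(["g0"], name="gene"))
        with pytest.raises(ValidationError, match="universes"):
            combine_nps(a, b)

    def test_table_validates_product(self):
        frame = pd.DataFrame(
            {"nps_common": [1.0], "nps_rare": [2.0], "nps_combined": [99.0]},
            index=pd.Index(["g0"], name="gene"),
        )
        with pytest.raises(ValidationError):
            NPSTable(frame=frame)


class TestConsensus:
    def test_bypass_branch_identical(self, rng):
        net = random_network(rng, 80)
        pos = [g for g in sorted(net.nodes) if net.degree[g] > 0]
        pv = {g: 1e-8 for g in pos[:6]}
        s = seeds(*pos[:6], pvalues=pv)
        direct = compute_nps(net, s, R=20, rng_seed=7)
        cons = consensus_nps(net, s, ConsensusConfig(), rng_seed=7, R=20)
        assert np.allclose(direct.to_numpy(), cons.to_numpy())

    def test_weight_dominance(self):
        genes = [f"g{i}" for i in range(60)]
        pv = {g: 0.9 for g in genes}
        pv["g0"] = 1e-300
        gen = np.random.default_rng(0)
        subs = weighted_subsamples(genes, pv, size=10, n_subsamples=50, rng=gen)
        assert all("g0" in s for s in subs)

    def test_all_weights_zero_errors(self):
        genes = ["a", "b", "c"]
        with pytest.raises(ValidationError, match="weights"):
            weighted_subsamples(genes, {g: 1.0 for g in genes}, 2, 3, np.random.default_rng(0))

    def test_percentile_of_constant_is_constant(self, rng, monkeypatch):
        net = random_network(rng, 60)
        nodes = sorted(net.nodes)
        const = pd.Series(2.5, index=pd.Index(nodes, name="gene"))
        import colocnet.nps as nps_mod

        monkeypatch.setattr(nps_mod, "compute_nps", lambda *a, **k: const.copy())
        pos = [g for g in nodes if net.degree[g] > 0]
        pv = {g: 1e-4 for g in pos}
        s = seeds(*pos, pvalues=pv)
        cfg = ConsensusConfig(max_seeds=5, n_subsamples=4)
        out = consensus_nps(net, s, cfg, rng_seed=1, R=5)
        assert np.allclose(out.to_numpy(), 2.5)

    def test_config_validation(self):
        with pytest.raises(ValidationError):
            ConsensusConfig(percentile=0)
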