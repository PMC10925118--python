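import itertools
import json

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from colocnet.coloc import (
    ColocConfig,
    PipelineStageError,
    extract_network,
    permutation_test,
    run_colocalization_pipeline,
)
from colocnet.core import GeneNetwork, ValidationError
from colocnet.nps import NPSTable
from colocnet.synth import SyntheticSpec, write_fixture_dir


def npst(common, rare, genes=None):
    genes = genes or [f"g{i}" for i in range(len(common))]
    frame = pd.DataFrame(
        {
            "nps_common": common,
            "nps_rare": rare,
            "nps_combined": np.asarray(common) * np.asarray(rare),
        },
        index=pd.Index(genes, name="gene"),
    )
    return NPSTable(frame=frame)


def full_network(genes):
    edges = list(itertools.combinations(genes, 2))
    return GeneNetwork.from_edges(edges)


class TestExtract:
    def test_passing_gene(self):
        t = npst([2.0, 4.0, 1.6], [2.0, 1.0, 1.6])
        net = full_network([f"g{i}" for i in range(3)])
        genes, sub = extract_network(t, net)
        # g0: product 4 > 3 and both > 1.5 -> in
        # g1: rare 1.0 fails; g2: product 2.56 fails
        assert genes == frozenset({"g0"})

    def test_empty_selection_is_valid(self):
        t = npst([0.0, 1.0], [0.0, 1.0])
        net = full_network(["g0", "g1"])
        genes, sub = extract_network(t, net)
        assert genes == frozenset()
        assert sub.n_nodes == 0

    def test_subgraph_edges_subset(self):
        t = npst([2.0, 2.0, 2.0], [2.0, 2.0, 2.0])
        net = GeneNetwork.from_edges([("g0", "g1")], extra_nodes=["g2"])
        genes, sub = extract_network(t, net)
        assert genes == frozenset({"g0", "g1", "g2"})
        assert sub.edges == frozenset({("g0", "g1")})


def exhaustive_null(c, r, cfg):
    """Brute-force oracle: all pairings of permuted c-labels and r-labels."""
    n = len(c)
    sizes, means = [], []
    for pc in itertools.permutations(range(n)):
        cc = np.asarray(c)[list(pc)]
        for pr in itertools.permutations(range(n)):
            rr = np.asarray(r)[list(pr)]
            prod = cc * rr
            sizes.append(
                int(((prod > cfg.combined_min) & (cc > cfg.common_min) & (rr > cfg.rare_min)).sum())
            )
            means.append(prod.mean())
    return np.array(sizes), np.array(means)


class TestPermutationTest:
    def test_zscore_pvalue_relation(self, rng):
        # centered near the thresholds so permuted sizes actually vary
        c = list(rng.normal(1.8, 0.8, size=12))
        r = list(rng.normal(1.8, 0.8, size=12))
        res = permutation_test(npst(c, r), set(), ColocConfig(n_permutations=200, rng_seed=1))
        assert res.size_p == pytest.approx(float(stats.norm.sf(res.size_z)))
        assert res.mean_p == pytest.approx(float(stats.norm.sf(res.mean_z)))

    def test_exhaustive_oracle_three_genes(self):
        c, r = [2.0, 0.5, -1.0], [1.8, 2.2, 0.1]
        cfg = ColocConfig(n_permutations=4000, rng_seed=3)
        res = permutation_test(npst(c, r), set(), cfg)
        sizes, means = exhaustive_null(c, r, cfg)
        # sampled null moments match enumeration within Monte-Carlo error
        se_size = sizes.std(ddof=1) / np.sqrt(cfg.n_permutations)
        assert res.size_null_mean == pytest.approx(sizes.mean(), abs=5 * se_size)
        se_mean = means.std(ddof=1) / np.sqrt(cfg.n_permutations)
        assert res.mean_null_mean == pytest.approx(means.mean(), abs=5 * se_mean)
        assert res.size_null_sd == pytest.approx(sizes.std(ddof=1), rel=0.15)

    def test_constant_vectors_na_path(self):
        with pytest.warns(RuntimeWarning, match="zero variance"):
            res = permutation_test(
                npst([1.0, 1.0, 1.0], [2.0, 2.0, 2.0]),
                set(),
                ColocConfig(n_permutations=100, rng_seed=0),
            )
        assert np.isnan(res.size_p)
        assert np.isnan(res.mean_p)

    def test_shared_stratum_fixed_when_singleton(self):
        # one shared gene with extreme values; permuting it with the others
        # would change null sizes, within-stratum permutation keeps it fixed
        t = npst([0.0, 0.0, 10.0], [0.0, 0.0, 10.0])
        with pytest.warns(RuntimeWarning):
            res = permutation_test(
                t, {"g2"}, ColocConfig(n_permutations=100, rng_seed=0)
            )
        assert res.size_null_mean == 1.0
        assert res.size_null_sd == 0.0

    def test_shared_gene_missing_from_table(self):
        with pytest.raises(ValidationError):
            permutation_test(npst([1.0], [1.0]), {"nope"}, ColocConfig(rng_seed=0))

    def test_ratio_definition(self, rng):
        c = list(rng.normal(2, 1, size=30))
        r = list(rng.normal(2, 1, size=30))
        res = permutation_test(npst(c, r), set(), ColocConfig(n_permutations=300, rng_seed=2))
        if res.size_null_mean > 0:
            assert res.ratio == pytest.approx(res.size / res.size_null_mean)
            lo, hi = res.ratio_ci
            assert lo <= hi

    def test_reproducible(self, rng):
        c = list(rng.normal(1.8, 0.8, size=15))
        r = list(rng.normal(1.8, 0.8, size=15))
        cfg = ColocConfig(n_permutations=150, rng_seed=42)
        r1 = permutation_test(npst(c, r), {"g0"}, cfg)
        r2 = permutation_test(npst(c, r), {"g0"}, cfg)
        assert r1.stats_dict() == r2.stats_dict()

    def test_config_validation(self):
        with pytest.raises(ValidationError):
            ColocConfig(n_permutations=10)
        with pytest.raises(ValidationError):
            ColocConfig(combined_min=float("inf"))


@pytest.fixture(scope="module")
def fixture_dir(tmp_path_factory):
    out = tmp_path_factory.mktemp("fixture")
    spec = SyntheticSpec(
        n_genes=300, module_size=20, attachment=4, seeds_per_source=8,
        overlap_fraction=1.0, rng_seed=12,
    )
    write_fixture_dir(spec, out)
    return out


def pipeline_config(fixture_dir):
    return {
        "network": str(fixture_dir / "network.tsv"),
        "common_scores": str(fixture_dir / "scores_common.tsv"),
        "rare_scores": str(fixture_dir / "scores_rare.tsv"),
        "catalog": str(fixture_dir / "catalog.gmt"),
        "rng_seed": 7,
        "null_reps": 30,
        "n_permutations": 200,
        "min_seeds": 6,
    }


class TestPipeline:
    def test_manifest_lists_five_stages(self, fixture_dir, tmp_path):
        manifest = run_colocalization_pipeline(pipeline_config(fixture_dir), tmp_path / "run")
        assert manifest["stages_completed"] == ["seeds", "propagate", "nps", "coloc", "enrich"]
        for name in ("nps_table.tsv", "coloc_stats.json", "manifest.json", "selection_report.tsv"):
            assert (tmp_path / "run" / name).exists()

    def test_missing_network_aborts_at_propagate(self, fixture_dir, tmp_path):
        cfg = pipeline_config(fixture_dir)
        cfg["network"] = str(tmp_path / "does_not_exist.tsv")
        with pytest.raises(PipelineStageError) as exc:
            run_colocalization_pipeline(cfg, tmp_path / "run2")
        assert exc.value.stage == "propagate"

    def test_byte_identical_reruns(self, fixture_dir, tmp_path):
        cfg = pipeline_config(fixture_dir)
        run_colocalization_pipeline(cfg, tmp_path / "r1")
        run_colocalization_pipeline(cfg, tmp_path / "r2")
        files = sorted(p.name for p in (tmp_path / "r1").iterdir())
        assert files
        for name in files:
            assert (tmp_path / "r1" / name).read_bytes() == (tmp_path / "r2" / name).read_bytes()

    def test_stats_json_keys(self, fixture_dir, tmp_path):
        run_colocalization_pipeline(pipeline_config(fixture_dir), tmp_path / "r3")
        stats_d = json.loads((tmp_path / "r3" / "coloc_stats.json").read_text())
        for key in ("size", "size_z", "size_p", "mean_z", "mean_p", "ratio", "ratio_ci"):
            assert key in stats_d
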