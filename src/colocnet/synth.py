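"""Synthetic fixtures with known ground truth for every pipeline stage.

Generates degree-heterogeneous graphs with a planted dense module, seed
score tables whose planted genes deterministically pass the selection
thresholds, annotation catalogs, and expression matrices with planted
per-tissue differential expression. Every generator is a pure function of
(spec, rng_seed).

Background p-values are drawn from Uniform(0.3, 1) rather than Uniform(0, 1)
so that no background gene can pass the lenient FDR rule or the fixed
common-variant gate, making threshold recovery of the planted seeds exact by
construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd

from colocnet.core import (
    AnnotationCatalog,
    ExpressionMatrix,
    GeneNetwork,
    GeneScoreTable,
    ValidationError,
)

GRAPH_MODELS = ("preferential-attachment", "configuration-from-power-law")

BACKGROUND_P_MIN = 0.3


@dataclass(frozen=True)
class SyntheticSpec:
    n_genes: int = 2000
    graph_model: str = "preferential-attachment"
    attachment: int = 12  # edges per new node (preferential attachment)
    degree_exponent: float = 2.5  # configuration model power-law exponent
    module_size: int = 50
    density_multiplier: float = 10.0
    module_degree_pick: str = "low"  # draw module genes from the lower degree half
    rewire: bool = True  # trade a background edge for each added within-module edge
    seeds_per_source: int = 20
    overlap_fraction: float = 1.0
    noise_seeds: int = 0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.module_size >= self.n_genes:
            raise ValidationError("module_size must be smaller than n_genes")
        if not (0 <= self.overlap_fraction <= 1):
            raise ValidationError("overlap_fraction must lie in [0, 1]")
        if self.density_multiplier < 1:
            raise ValidationError("density_multiplier must be >= 1")
        if self.graph_model not in GRAPH_MODELS:
            raise ValidationError(f"graph_model must be one of {GRAPH_MODELS}")
        if self.module_degree_pick not in ("low", "uniform"):
            raise ValidationError("module_degree_pick must be 'low' or 'uniform'")


def _symbol(i: int) -> str:
    return f"G{i + 1:06d}"


def make_network(spec: SyntheticSpec) -> tuple[GeneNetwork, dict]:
    """Heavy-tailed random graph with a planted dense module.

    The module's within-group edge density is raised to
    ``density_multiplier`` times the background density of the base graph by
    adding random missing within-module edges; with ``rewire`` each added
    edge retires one module-to-background edge at one endpoint, so module
    genes keep roughly their base degree while their neighborhoods shift
    into the module. Module genes are drawn from the lower half of the
    degree distribution by default (planted disease modules are rarely
    hubs); set ``module_degree_pick='uniform'`` for unconstrained placement.
    Returns the network and a ground-truth dict with the module membership.
    """
    rng = np.random.default_rng(spec.rng_seed)
    n = spec.n_genes
    if spec.graph_model == "preferential-attachment":
        g = nx.barabasi_albert_graph(n, spec.attachment, seed=int(spec.rng_seed))
    else:
        # power-law degree sequence, clipped and parity-fixed
        raw = rng.zipf(spec.degree_exponent, size=n)
        degs = np.clip(raw, 1, max(2, n // 10))
        if degs.sum() % 2:
            degs[0] += 1
        gm = nx.configuration_model(degs.tolist(), seed=int(spec.rng_seed))
        g = nx.Graph(gm)
        g.remove_edges_from(nx.selfloop_edges(g))
    mapping = {i: _symbol(i) for i in g.nodes}
    g = nx.relabel_nodes(g, mapping)
    all_genes = sorted(g.nodes)

    m = spec.module_size
    if spec.module_degree_pick == "low":
        deg = dict(g.degree)
        cutoff = np.median(list(deg.values()))
        candidates = [x for x in all_genes if deg[x] <= cutoff]
        if len(candidates) < m:
            candidates = all_genes
    else:
        candidates = all_genes
    module = sorted(
        rng.choice(np.array(candidates, dtype=object), size=m, replace=False).tolist()
    )
    bg_density = 2 * g.number_of_edges() / (n * (n - 1))
    max_within = m * (m - 1) // 2
    target_within = int(round(spec.density_multiplier * bg_density * max_within))
    if target_within > max_within:
        max_mult = 1.0 / bg_density
        raise ValidationError(
            f"requested within-module density infeasible; maximum multiplier is {max_mult:.1f}"
        )
    module_set = set(module)
    current = [(u, v) for u, v in g.edges if u in module_set and v in module_set]
    need = target_within - len(current)
    if need > 0:
        missing = [
            (module[i], module[j])
            for i in range(m)
            for j in range(i + 1, m)
            if not g.has_edge(module[i], module[j])
        ]
        for k in rng.choice(len(missing), size=need, replace=False):
            u, v = missing[k]
            g.add_edge(u, v)
            if spec.rewire:
                # retire one background edge at an endpoint, keeping the
                # endpoint's degree >= 2 and never stranding the neighbor
                for node in rng.permutation(np.array([u, v], dtype=object)):
                    node = str(node)
                    bg_nb = [
                        w
                        for w in g.neighbors(node)
                        if w not in module_set and g.degree(w) > 1 and g.degree(node) > 2
                    ]
                    if bg_nb:
                        g.remove_edge(node, bg_nb[int(rng.integers(len(bg_nb)))])
                        break

    network = GeneNetwork.from_edges(g.edges, extra_nodes=all_genes)
    truth = {
        "module": module,
        "background_density": bg_density,
        "within_module_edges": target_within if need > 0 else len(current),
        "rng_seed": spec.rng_seed,
    }
    return network, truth


def _plant_seeds(spec: SyntheticSpec, module: list[str], all_genes: list[str], rng) -> list[str]:
    n_mod = int(round(spec.overlap_fraction * spec.seeds_per_source))
    if n_mod > len(module):
        raise ValidationError(
            f"cannot draw {n_mod} module seeds from a module of {len(module)} genes"
        )
    n_bg = spec.seeds_per_source - n_mod + spec.noise_seeds
    background = sorted(set(all_genes) - set(module))
    mod_seeds = rng.choice(np.array(module, dtype=object), size=n_mod, replace=False).tolist()
    bg_seeds = rng.choice(np.array(background, dtype=object), size=n_bg, replace=False).tolist()
    return sorted(str(s) for s in mod_seeds + bg_seeds)


def make_seed_tables(
    spec: SyntheticSpec, truth: Mapping
) -> tuple[GeneScoreTable, GeneScoreTable, dict]:
    """Common-style and rare-style score tables with planted significant genes.

    Planted common genes get p = 10^-Uniform(8, 30); planted rare genes get
    three correlated test p-values 10^-(Uniform(5, 12) +/- 0.4). Background
    p-values are Uniform(0.3, 1) in every column, so the selection
    thresholds recover exactly the planted sets (lenient mode for rare).
    """
    rng = np.random.default_rng(spec.rng_seed + 1)
    module = list(truth["module"])
    all_genes = [_symbol(i) for i in range(spec.n_genes)]
    planted_common = _plant_seeds(spec, module, all_genes, rng)
    planted_rare = _plant_seeds(spec, module, all_genes, rng)

    p_common = rng.uniform(BACKGROUND_P_MIN, 1.0, size=spec.n_genes)
    idx = {g: i for i, g in enumerate(all_genes)}
    for g in planted_common:
        p_common[idx[g]] = 10.0 ** (-rng.uniform(8, 30))
    common = GeneScoreTable(frame=pd.DataFrame({"gene": all_genes, "p_common": p_common}))

    rare_cols = {}
    for col in ("p_burden", "p_skato", "p_skat"):
        rare_cols[col] = rng.uniform(BACKGROUND_P_MIN, 1.0, size=spec.n_genes)
    classes = rng.choice(
        np.array(["pLoF", "missense", "synonymous"], dtype=object), size=spec.n_genes
    )
    for g in planted_rare:
        base = rng.uniform(5, 12)
        for col in ("p_burden", "p_skato", "p_skat"):
            expo = max(4.6, base + rng.uniform(-0.4, 0.4))
            rare_cols[col][idx[g]] = 10.0 ** (-expo)
    rare = GeneScoreTable(
        frame=pd.DataFrame(
            {"gene": all_genes, **rare_cols, "annotation_class": classes.astype(str)}
        )
    )
    seed_truth = {"planted_common": planted_common, "planted_rare": planted_rare}
    return common, rare, seed_truth


def make_expression(
    spec: SyntheticSpec,
    deg_truth: Mapping[str, set[str]],
    lfc: float = 2.0,
    n_per_label: int = 10,
) -> ExpressionMatrix:
    """Log-scale expression matrix with planted per-label shifts.

    Baseline values ~ Normal(5, 1); genes in ``deg_truth[label]`` are
    shifted by +lfc in that label's samples. Labels are balanced at
    ``n_per_label`` samples each.
    """
    if lfc < 0:
        raise ValidationError("lfc must be >= 0")
    if n_per_label < 2:
        raise ValidationError("n_per_label must be >= 2")
    rng = np.random.default_rng(spec.rng_seed + 2)
    genes = [_symbol(i) for i in range(spec.n_genes)]
    gene_set = set(genes)
    for label, gs in deg_truth.items():
        extra = set(gs) - gene_set
        if extra:
            raise ValidationError(f"deg_truth[{label!r}] has genes outside the spec: {sorted(extra)[:3]}")
    labels = sorted(deg_truth)
    samples = [f"{lab}_s{i}" for lab in labels for i in range(n_per_label)]
    mat = rng.normal(5.0, 1.0, size=(len(genes), len(samples)))
    gidx = {g: i for i, g in enumerate(genes)}
    for j, s in enumerate(samples):
        lab = s.rsplit("_s", 1)[0]
        for g in deg_truth[lab]:
            mat[gidx[g], j] += lfc
    values = pd.DataFrame(mat, index=pd.Index(genes, name="gene"), columns=samples)
    label_map = {s: s.rsplit("_s", 1)[0] for s in samples}
    return ExpressionMatrix(values=values, labels=label_map)


def make_catalog(spec: SyntheticSpec, truth: Mapping, n_random: int = 3) -> AnnotationCatalog:
    """Catalog with one category per planted structure plus random decoys."""
    rng = np.random.default_rng(spec.rng_seed + 3)
    all_genes = [_symbol(i) for i in range(spec.n_genes)]
    cats = {"planted_module": frozenset(truth["module"])}
    for k in range(n_random):
        size = int(rng.integers(20, 80))
        cats[f"random_{k}"] = frozenset(
            str(g) for g in rng.choice(np.array(all_genes, dtype=object), size=size, replace=False)
        )
    return AnnotationCatalog(categories=cats, universe=frozenset(all_genes))


def write_fixture_dir(spec: SyntheticSpec, out_dir: str | Path) -> dict:
    """Generate and write a full fixture bundle; returns the truth manifest."""
    from colocnet.core import write_edge_list, write_expression, write_gene_scores, write_gmt

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    network, truth = make_network(spec)
    common, rare, seed_truth = make_seed_tables(spec, truth)
    catalog = make_catalog(spec, truth)
    module = list(truth["module"])
    deg_truth = {
        "tissue_A": set(module[: min(10, len(module))]),
        "tissue_B": set(_symbol(i) for i in range(spec.n_genes - 10, spec.n_genes)),
    }
    expr = make_expression(spec, deg_truth)
    write_edge_list(network, out / "network.tsv")
    write_gene_scores(common, out / "scores_common.tsv")
    write_gene_scores(rare, out / "scores_rare.tsv")
    write_gmt(catalog, out / "catalog.gmt")
    write_expression(expr, out / "expr.tsv", out / "labels.tsv")
    manifest = {
        "spec": asdict(spec),
        "module": module,
        **seed_truth,
        "deg_truth": {k: sorted(v) for k, v in deg_truth.items()},
    }
    (out / "truth.json").write_text(json.dumps(manifest, sort_keys=True, indent=2) + "\n")
    return manifest
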