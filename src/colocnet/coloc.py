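"""Colocalized-network extraction and permutation significance.

Genes pass if nps_combined > combined_min AND nps_common > common_min AND
nps_rare > rare_min (all strict). Significance of the extracted network's
size and mean combined score comes from a label-permutation null: each
permutation shuffles the assignment of nps_common values among genes and,
independently, of nps_rare values, stratified so genes seeded in BOTH
inputs are permuted only among themselves. P-values are one-sided
upper-tail from a Z-test against the permutation null.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd
from scipy import stats

from colocnet.core import (
    GeneNetwork,
    ValidationError,
    read_edge_list,
    read_gene_scores,
    read_gmt,
    write_seed_list,
)
from colocnet.nps import NPSTable, combine_nps, consensus_nps, ConsensusConfig
from colocnet.propagation import PropagationConfig, TransitionSystem

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ColocConfig:
    combined_min: float = 3.0
    common_min: float = 1.5
    rare_min: float = 1.5
    n_permutations: int = 10_000
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for f in (self.combined_min, self.common_min, self.rare_min):
            if not np.isfinite(f):
                raise ValidationError("thresholds must be finite")
        if self.n_permutations < 100:
            raise ValidationError("n_permutations must be >= 100")


@dataclass(frozen=True)
class ColocalizationResult:
    genes: frozenset[str]
    subgraph: Optional[GeneNetwork]
    size: int
    mean_combined: float
    size_null_mean: float
    size_null_sd: float
    size_z: float
    size_p: float
    mean_null_mean: float
    mean_null_sd: float
    mean_z: float
    mean_p: float
    size_p_empirical: float
    mean_p_empirical: float
    ratio: float
    ratio_ci: tuple[float, float]
    n_permutations: int
    rng_seed: int

    def stats_dict(self) -> dict:
        return {
            "size": self.size,
            "mean_combined": self.mean_combined,
            "size_null_mean": self.size_null_mean,
            "size_null_sd": self.size_null_sd,
            "size_z": self.size_z,
            "size_p": self.size_p,
            "mean_null_mean": self.mean_null_mean,
            "mean_null_sd": self.mean_null_sd,
            "mean_z": self.mean_z,
            "mean_p": self.mean_p,
            "size_p_empirical": self.size_p_empirical,
            "mean_p_empirical": self.mean_p_empirical,
            "ratio": self.ratio,
            "ratio_ci": list(self.ratio_ci),
            "n_permutations": self.n_permutations,
            "rng_seed": self.rng_seed,
        }


def _passing_mask(c: np.ndarray, r: np.ndarray, cfg: ColocConfig) -> np.ndarray:
    prod = c * r
    return (prod > cfg.combined_min) & (c > cfg.common_min) & (r > cfg.rare_min)


def extract_network(
    npst: NPSTable, network: GeneNetwork, cfg: ColocConfig | None = None
) -> tuple[frozenset[str], GeneNetwork]:
    """Genes passing all three thresholds plus the induced subgraph.

    Seed genes receive no exemption; an empty selection is a valid result.
    """
    cfg = cfg or ColocConfig()
    c = npst.frame["nps_common"].to_numpy()
    r = npst.frame["nps_rare"].to_numpy()
    mask = _passing_mask(c, r, cfg)
    genes = frozenset(np.array(npst.genes, dtype=object)[mask].tolist())
    return genes, network.subgraph(genes)


def _one_sided_p(z: float) -> float:
    return float(stats.norm.sf(z))


def permutation_test(
    npst: NPSTable,
    shared_genes: Iterable[str],
    cfg: ColocConfig | None = None,
    network: Optional[GeneNetwork] = None,
) -> ColocalizationResult:
    """Label-permutation null for colocalized-network size and mean score.

    ``shared_genes`` are genes that were seeds in BOTH inputs; their labels
    are permuted strictly within the shared stratum (even if it has size 1,
    in which case they stay fixed) to preserve their elevated expectation.
    """
    cfg = cfg or ColocConfig()
    genes = np.array(npst.genes, dtype=object)
    c = npst.frame["nps_common"].to_numpy().copy()
    r = npst.frame["nps_rare"].to_numpy().copy()
    shared = set(shared_genes)
    unknown = shared - set(npst.genes)
    if unknown:
        raise ValidationError(f"shared genes absent from the NPS table: {sorted(unknown)[:5]}")
    is_shared = np.array([g in shared for g in genes])
    idx_shared = np.flatnonzero(is_shared)
    idx_other = np.flatnonzero(~is_shared)

    obs_mask = _passing_mask(c, r, cfg)
    obs_size = int(obs_mask.sum())
    obs_mean = float((c * r).mean())

    rng = np.random.default_rng(cfg.rng_seed)
    sizes = np.empty(cfg.n_permutations)
    means = np.empty(cfg.n_permutations)
    cp = c.copy()
    rp = r.copy()
    for i in range(cfg.n_permutations):
        for vec, base in ((cp, c), (rp, r)):
            for idx in (idx_other, idx_shared):
                if idx.size > 1:
                    vec[idx] = base[idx][rng.permutation(idx.size)]
        sizes[i] = _passing_mask(cp, rp, cfg).sum()
        means[i] = (cp * rp).mean()

    def _z_and_p(obs: float, null: np.ndarray) -> tuple[float, float, float, float]:
        mu = float(null.mean())
        sd = float(null.std(ddof=1))
        if sd == 0:
            warnings.warn("permutation null has zero variance; p reported as NA", RuntimeWarning)
            return mu, sd, float("nan"), float("nan")
        z = (obs - mu) / sd
        return mu, sd, float(z), _one_sided_p(z)

    size_mu, size_sd, size_z, size_p = _z_and_p(obs_size, sizes)
    mean_mu, mean_sd, mean_z, mean_p = _z_and_p(obs_mean, means)
    # exact rank-based permutation p-values (add-one, upper tail); unlike the
    # normal approximation these are valid regardless of null skewness
    size_p_emp = (1 + int((sizes >= obs_size).sum())) / (cfg.n_permutations + 1)
    mean_p_emp = (1 + int((means >= obs_mean).sum())) / (cfg.n_permutations + 1)

    if size_mu > 0:
        ratio = obs_size / size_mu
        lo, hi = np.percentile(sizes, [2.5, 97.5]) / size_mu
    else:
        ratio, lo, hi = float("nan"), float("nan"), float("nan")

    sel_genes, subgraph = (frozenset(), None)
    if network is not None:
        sel_genes, subgraph = extract_network(npst, network, cfg)
    else:
        sel_genes = frozenset(genes[obs_mask].tolist())

    return ColocalizationResult(
        genes=sel_genes,
        subgraph=subgraph,
        size=obs_size,
        mean_combined=obs_mean,
        size_null_mean=size_mu,
        size_null_sd=size_sd,
        size_z=size_z,
        size_p=size_p,
        mean_null_mean=mean_mu,
        mean_null_sd=mean_sd,
        mean_z=mean_z,
        mean_p=mean_p,
        size_p_empirical=float(size_p_emp),
        mean_p_empirical=float(mean_p_emp),
        ratio=float(ratio),
        ratio_ci=(float(lo), float(hi)),
        n_permutations=cfg.n_permutations,
        rng_seed=cfg.rng_seed,
    )


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"pipeline aborted at stage {stage!r}: {message}")
        self.stage = stage


def run_colocalization_pipeline(config: Mapping, out_dir: str | Path) -> dict:
    """Run seeds -> propagate -> nps -> coloc -> enrich end to end.

    ``config`` keys: network (edge-list path), common_scores, rare_scores,
    rare_mode (lenient|stringent), rng_seed, null_reps, n_permutations,
    thresholds {combined_min, common_min, rare_min}, alpha, and optionally
    catalog (GMT path) with catalog_universe (network|catalog). Writes all
    artifacts plus manifest.json to ``out_dir``; returns the manifest dict.
    """
    from colocnet import __version__
    from colocnet.enrichment import annotate_catalog
    from colocnet.seeds import (
        SeedSelectionConfig,
        map_seeds_to_network,
        select_common_seeds,
        select_rare_seeds,
        selection_report,
    )

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng_seed = int(config.get("rng_seed", 0))
    completed: list[str] = []

    # --- stage: seeds -------------------------------------------------
    try:
        sel_cfg = SeedSelectionConfig(
            common_p_threshold=float(config.get("common_p_threshold", 2.6e-6)),
            rare_lenient_q=float(config.get("rare_lenient_q", 0.25)),
            rare_stringent_alpha=float(config.get("rare_stringent_alpha", 0.05)),
            min_seeds=int(config.get("min_seeds", 6)),
        )
        common_table = read_gene_scores(config["common_scores"])
        rare_table = read_gene_scores(config["rare_scores"])
        common_seeds = select_common_seeds(common_table, sel_cfg)
        rare_seeds = select_rare_seeds(rare_table, config.get("rare_mode", "lenient"), sel_cfg)
        report = pd.concat(
            [selection_report(common_table, sel_cfg), selection_report(rare_table, sel_cfg)]
        )
        report.to_csv(out / "selection_report.tsv", sep="\t", index=False)
    except Exception as exc:  # noqa: BLE001
        raise PipelineStageError("seeds", str(exc)) from exc
    completed.append("seeds")

    # --- stage: propagate (network precheck + seed mapping) -----------
    try:
        net_path = Path(config["network"])
        if not net_path.exists():
            raise FileNotFoundError(f"network file not found: {net_path}")
        network = read_edge_list(net_path)
        common_seeds = map_seeds_to_network(common_seeds, network, sel_cfg)
        rare_seeds = map_seeds_to_network(rare_seeds, network, sel_cfg)
        write_seed_list(common_seeds, out / "seeds_common.txt")
        write_seed_list(rare_seeds, out / "seeds_rare.txt")
        ts = TransitionSystem(network)
    except Exception as exc:  # noqa: BLE001
        raise PipelineStageError("propagate", str(exc)) from exc
    completed.append("propagate")

    # --- stage: nps ----------------------------------------------------
    try:
        prop_cfg = PropagationConfig(alpha=float(config.get("alpha", 0.5)))
        R = int(config.get("null_reps", 1000))
        cons = ConsensusConfig(max_seeds=int(config.get("max_seeds", 500)))
        excl = bool(config.get("null_excludes_seeds", False))
        nps_common = consensus_nps(
            network, common_seeds, cons, rng_seed=rng_seed, R=R, propagation=prop_cfg,
            exclude_seeds_from_null=excl,
        )
        nps_rare = consensus_nps(
            network, rare_seeds, cons, rng_seed=rng_seed + 1, R=R, propagation=prop_cfg,
            exclude_seeds_from_null=excl,
        )
        npst = combine_nps(nps_common, nps_rare)
        npst.frame.to_csv(out / "nps_table.tsv", sep="\t", float_format="%.10g")
        meta = {
            "R": R,
            "rng_seed": rng_seed,
            "alpha": prop_cfg.alpha,
            "heat_floor": 1e-12,
            "log": "natural",
            "null_excludes_seeds": excl,
        }
        (out / "nps_meta.json").write_text(json.dumps(meta, sort_keys=True, indent=2) + "\n")
    except PipelineStageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineStageError("nps", str(exc)) from exc
    completed.append("nps")

    # --- stage: coloc ---------------------------------------------------
    try:
        thresholds = config.get("thresholds", {})
        coloc_cfg = ColocConfig(
            combined_min=float(thresholds.get("combined_min", 3.0)),
            common_min=float(thresholds.get("common_min", 1.5)),
            rare_min=float(thresholds.get("rare_min", 1.5)),
            n_permutations=int(config.get("n_permutations", 10_000)),
            rng_seed=rng_seed + 2,
        )
        shared = common_seeds.genes & rare_seeds.genes
        result = permutation_test(npst, shared, coloc_cfg, network=network)
        with open(out / "selected_genes.txt", "w") as fh:
            for g in sorted(result.genes):
                fh.write(g + "\n")
        with open(out / "subnetwork_edges.tsv", "w") as fh:
            if result.subgraph is not None:
                for u, v in sorted(result.subgraph.edges):
                    fh.write(f"{u}\t{v}\n")
        (out / "coloc_stats.json").write_text(
            json.dumps(result.stats_dict(), sort_keys=True, indent=2) + "\n"
        )
    except PipelineStageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineStageError("coloc", str(exc)) from exc
    completed.append("coloc")

    # --- stage: enrich ---------------------------------------------------
    try:
        if config.get("catalog"):
            catalog = read_gmt(config["catalog"])
            if config.get("catalog_universe", "network") == "network":
                catalog = catalog.with_universe(network.nodes)
            if result.genes:
                enr = annotate_catalog(result.genes, catalog)
                enr.frame.to_csv(out / "enrichment.tsv", sep="\t", index=False)
            else:
                pd.DataFrame(
                    columns=["category", "overlap", "category_size", "query_size",
                             "universe_size", "p", "p_adjusted"]
                ).to_csv(out / "enrichment.tsv", sep="\t", index=False)
        else:
            logger.info("no annotation catalog provided; enrichment stage is a no-op")
    except PipelineStageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineStageError("enrich", str(exc)) from exc
    completed.append("enrich")

    manifest = {
        "version": __version__,
        "stages_completed": completed,
        "rng_seed": rng_seed,
        "parameters": {
            "alpha": float(config.get("alpha", 0.5)),
            "null_reps": int(config.get("null_reps", 1000)),
            "n_permutations": int(config.get("n_permutations", 10_000)),
            "thresholds": {
                "combined_min": coloc_cfg.combined_min,
                "common_min": coloc_cfg.common_min,
                "rare_min": coloc_cfg.rare_min,
            },
            "rare_mode": config.get("rare_mode", "lenient"),
            "common_p_threshold": sel_cfg.common_p_threshold,
            "rare_lenient_q": sel_cfg.rare_lenient_q,
            "p_value_sidedness": "one-sided-upper",
        },
        "inputs": {
            "network": str(config["network"]),
            "common_scores": str(config["common_scores"]),
            "rare_scores": str(config["rare_scores"]),
        },
        "results": {"network_size": result.size, "size_p": result.size_p},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, sort_keys=True, indent=2) + "\n")
    return manifest
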