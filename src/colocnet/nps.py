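"""Network proximity scores (NPS) from propagation heats.

A gene's NPS is the z-score of its log observed heat against the log heats
obtained from an ensemble of degree-matched random seed sets:

    NPS_g = (log h_g - mean_r log h_g^(r)) / sd_r(log h_g^(r))

Heats are clamped at a positive floor before the (natural) log so exact
zeros at disconnected genes stay finite. The common and rare scores combine
as an elementwise product.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from colocnet.core import GeneNetwork, SeedGeneSet, ValidationError
from colocnet.propagation import PropagationConfig, TransitionSystem

logger = logging.getLogger(__name__)

HEAT_FLOOR = 1e-12


@dataclass(frozen=True)
class DegreeBinning:
    """Degree-ordered partition of network nodes into bins of >= min size."""

    bins: tuple[frozenset[str], ...]
    bin_index: dict[str, int]
    min_bin_size: int

    def bin_of(self, gene: str) -> int:
        return self.bin_index[gene]


@dataclass(frozen=True)
class NullEnsemble:
    """Degree-matched random seed sets, aligned per-seed with the original set."""

    seed_order: tuple[str, ...]
    sets: tuple[tuple[str, ...], ...]
    rng_seed: int
    log_mean: Optional[pd.Series] = None
    log_sd: Optional[pd.Series] = None

    @property
    def n_sets(self) -> int:
        return len(self.sets)


@dataclass(frozen=True)
class ConsensusConfig:
    max_seeds: int = 500
    n_subsamples: int = 100
    percentile: float = 75.0

    def __post_init__(self) -> None:
        if not (0 < self.percentile < 100):
            raise ValidationError("percentile must be in (0, 100)")
        if self.max_seeds < 1 or self.n_subsamples < 1:
            raise ValidationError("max_seeds and n_subsamples must be positive")


@dataclass(frozen=True)
class NPSTable:
    """Per-gene nps_common, nps_rare and their product nps_combined."""

    frame: pd.DataFrame  # index: gene; columns nps_common, nps_rare, nps_combined

    def __post_init__(self) -> None:
        expected = self.frame["nps_common"] * self.frame["nps_rare"]
        if not np.allclose(expected, self.frame["nps_combined"], rtol=0, atol=0):
            raise ValidationError("nps_combined is not the exact product of its factors")

    @property
    def genes(self) -> list[str]:
        return list(self.frame.index)

    def __len__(self) -> int:
        return len(self.frame)


def degree_bins(network: GeneNetwork, min_bin_size: int = 10) -> DegreeBinning:
    """Greedy degree-ordered binning with a minimum bin occupancy.

    Nodes are sorted by (degree, symbol) and chunked into consecutive bins of
    ``min_bin_size``; a final undersized chunk is merged into its
    predecessor. A network smaller than one bin yields a single bin.
    """
    deg = network.degree
    ordered = sorted(network.nodes, key=lambda g: (deg[g], g))
    n = len(ordered)
    if n == 0:
        raise ValidationError("cannot bin an empty network")
    bins: list[list[str]] = []
    for start in range(0, n, min_bin_size):
        chunk = ordered[start : start + min_bin_size]
        if len(chunk) < min_bin_size and bins:
            bins[-1].extend(chunk)
        else:
            bins.append(list(chunk))
    index = {g: i for i, b in enumerate(bins) for g in b}
    return DegreeBinning(
        bins=tuple(frozenset(b) for b in bins), bin_index=index, min_bin_size=min_bin_size
    )


def sample_null_seed_sets(
    network: GeneNetwork,
    seeds: SeedGeneSet,
    binning: DegreeBinning,
    R: int,
    rng_seed: int,
    exclude_seeds: bool = False,
) -> NullEnsemble:
    """Draw R degree-matched random seed sets.

    Each original seed is replaced by a uniform draw from its degree bin;
    draws are without replacement within one null set. By default null sets
    may overlap the original seeds; ``exclude_seeds`` removes the original
    seeds from the candidate pools.
    """
    missing = set(seeds.genes) - set(network.nodes)
    if missing:
        raise ValidationError(f"seeds not in network: {sorted(missing)[:5]}")
    rng = np.random.default_rng(rng_seed)
    seed_order = tuple(sorted(seeds.genes))
    # positions of each seed grouped by bin, preserving seed_order slots
    by_bin: dict[int, list[int]] = {}
    for pos, g in enumerate(seed_order):
        by_bin.setdefault(binning.bin_of(g), []).append(pos)
    degree = network.degree
    pools: dict[int, np.ndarray] = {}
    for b, positions in by_bin.items():
        # degree-0 genes cannot seed a walk and are never drawn
        members = sorted(m for m in binning.bins[b] if degree[m] > 0)
        if exclude_seeds:
            members = [m for m in members if m not in seeds.genes]
        if len(members) < len(positions):
            raise ValidationError(
                f"degree bin {b} has {len(members)} candidates but must supply "
                f"{len(positions)} null seeds; use larger bins (min_bin_size)"
            )
        pools[b] = np.array(members, dtype=object)
    sets: list[tuple[str, ...]] = []
    for _ in range(R):
        out: list[Optional[str]] = [None] * len(seed_order)
        for b, positions in by_bin.items():
            draw = rng.choice(pools[b], size=len(positions), replace=False)
            for pos, g in zip(positions, draw):
                out[pos] = str(g)
        sets.append(tuple(out))  # type: ignore[arg-type]
    return NullEnsemble(seed_order=seed_order, sets=tuple(sets), rng_seed=rng_seed)


def _log_heats(F: np.ndarray, floor: float) -> np.ndarray:
    return np.log(np.maximum(F, floor))


def compute_nps(
    network: GeneNetwork,
    seeds: SeedGeneSet,
    R: int = 1000,
    rng_seed: int = 0,
    propagation: PropagationConfig | None = None,
    min_bin_size: int = 10,
    heat_floor: float = HEAT_FLOOR,
    exclude_seeds_from_null: bool = False,
    ts: TransitionSystem | None = None,
    binning: DegreeBinning | None = None,
    return_ensemble: bool = False,
):
    """Per-gene NPS vector for one seed set.

    Propagates the observed seed set and R degree-matched null sets in a
    single batched fixed-point iteration, then z-scores the observed
    log-heat against the null log-heats (sample sd, R-1 denominator).
    Genes with zero null variance get NPS 0 with a warning.

    Returns a pandas Series indexed by gene symbol (sorted); with
    ``return_ensemble`` also returns the :class:`NullEnsemble` carrying the
    per-gene null log-heat mean and sd.
    """
    if R < 2:
        raise ValidationError("R must be >= 2 to estimate a null variance")
    propagation = propagation or PropagationConfig()
    ts = ts or TransitionSystem(network)
    binning = binning or degree_bins(network, min_bin_size)
    ensemble = sample_null_seed_sets(
        network, seeds, binning, R, rng_seed, exclude_seeds=exclude_seeds_from_null
    )
    n = ts.n
    F0 = np.zeros((n, R + 1))
    F0[:, 0] = ts.seed_indicator(sorted(seeds.genes))
    for r, null_set in enumerate(ensemble.sets, start=1):
        F0[:, r] = ts.seed_indicator(null_set)
    F = ts.propagate_batch(F0, propagation)
    logF = _log_heats(F, heat_floor)
    obs = logF[:, 0]
    null = logF[:, 1:]
    mean = null.mean(axis=1)
    sd = null.std(axis=1, ddof=1)
    nps = np.zeros(n)
    ok = sd > 0
    nps[ok] = (obs[ok] - mean[ok]) / sd[ok]
    n_degenerate = int((~ok).sum())
    if n_degenerate:
        warnings.warn(
            f"{n_degenerate} genes have zero null variance; their NPS is set to 0",
            RuntimeWarning,
            stacklevel=2,
        )
    series = pd.Series(nps, index=pd.Index(ts.nodes, name="gene"), name=f"nps_{seeds.source}")
    if return_ensemble:
        idx = pd.Index(ts.nodes, name="gene")
        ens = NullEnsemble(
            seed_order=ensemble.seed_order,
            sets=ensemble.sets,
            rng_seed=rng_seed,
            log_mean=pd.Series(mean, index=idx),
            log_sd=pd.Series(sd, index=idx),
        )
        return series, ens
    return series


def combine_nps(nps_common: pd.Series, nps_rare: pd.Series) -> NPSTable:
    """Elementwise product of the two NPS vectors, factors retained."""
    common_genes = set(nps_common.index)
    rare_genes = set(nps_rare.index)
    if common_genes != rare_genes:
        raise ValidationError(
            "NPS vectors cover different universes: "
            f"{len(common_genes - rare_genes)} only in first, "
            f"{len(rare_genes - common_genes)} only in second"
        )
    genes = sorted(common_genes)
    a = nps_common.reindex(genes)
    b = nps_rare.reindex(genes)
    frame = pd.DataFrame(
        {
            "nps_common": a.to_numpy(),
            "nps_rare": b.to_numpy(),
            "nps_combined": a.to_numpy() * b.to_numpy(),
        },
        index=pd.Index(genes, name="gene"),
    )
    return NPSTable(frame=frame)


def weighted_subsamples(
    genes: Sequence[str],
    pvalues: dict[str, float],
    size: int,
    n_subsamples: int,
    rng: np.random.Generator,
) -> list[frozenset[str]]:
    """Draw gene subsets without replacement, weighted by -log10(p)."""
    arr = np.array(sorted(genes), dtype=object)
    weights = np.array([-np.log10(pvalues[g]) for g in arr])
    if np.all(weights == 0):
        raise ValidationError("all subsampling weights are zero (every p-value is 1)")
    probs = weights / weights.sum()
    return [
        frozenset(str(g) for g in rng.choice(arr, size=size, replace=False, p=probs))
        for _ in range(n_subsamples)
    ]


def consensus_nps(
    network: GeneNetwork,
    seeds: SeedGeneSet,
    cfg: ConsensusConfig | None = None,
    rng_seed: int = 0,
    R: int = 1000,
    **nps_kwargs,
) -> pd.Series:
    """Weighted-subsampling consensus NPS for oversized seed sets.

    If the seed set has at most ``max_seeds`` genes this is exactly
    :func:`compute_nps` on the full set. Otherwise ``n_subsamples``
    subsamples of ``max_seeds`` genes are drawn without replacement with
    probability proportional to -log10(p), each is propagated and scored,
    and the per-gene ``percentile`` across subsamples is returned.
    """
    cfg = cfg or ConsensusConfig()
    rng = np.random.default_rng(rng_seed)
    if len(seeds.genes) <= cfg.max_seeds:
        return compute_nps(network, seeds, R=R, rng_seed=rng_seed, **nps_kwargs)
    if seeds.pvalues is None:
        raise ValidationError("consensus subsampling requires per-gene p-values as weights")
    subsets = weighted_subsamples(
        sorted(seeds.genes), dict(seeds.pvalues), cfg.max_seeds, cfg.n_subsamples, rng
    )
    ts = TransitionSystem(network)
    binning = degree_bins(network, nps_kwargs.get("min_bin_size", 10))
    stack = []
    for rep, chosen in enumerate(subsets):
        sub = SeedGeneSet(name=f"{seeds.name}_sub{rep}", source=seeds.source, genes=chosen)
        nps = compute_nps(
            network,
            sub,
            R=R,
            rng_seed=int(rng.integers(2**31 - 1)),
            ts=ts,
            binning=binning,
            **nps_kwargs,
        )
        stack.append(nps.to_numpy())
    arr = np.vstack(stack)
    consensus = np.percentile(arr, cfg.percentile, axis=0)  # linear interpolation
    return pd.Series(consensus, index=pd.Index(ts.nodes, name="gene"), name=f"nps_{seeds.source}")
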