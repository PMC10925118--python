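"""Random walk with restart over a gene network.

Transition convention: column-stochastic W = A D^-1 (a node splits its heat
equally among its neighbors). The fixed point solved for is

    F = (1 - alpha) * F0 + alpha * W @ F

with F0 the uniform indicator over the seed set (mass 1/|S| per seed), so
total heat is conserved at 1 whenever every node reachable from the seeds
has degree >= 1. Degree-0 nodes are excluded from the transition system:
they carry heat 0 and are rejected as seeds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import scipy.sparse as sp

from colocnet.core import GeneNetwork, SeedGeneSet, ValidationError


class ConvergenceError(RuntimeError):
    pass


@dataclass(frozen=True)
class PropagationConfig:
    alpha: float = 0.5
    tol: float = 1e-10
    max_iter: int = 10_000

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValidationError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.tol <= 0:
            raise ValidationError("tol must be positive")


@dataclass(frozen=True)
class HeatVector:
    """Per-gene stationary heat for one seed set."""

    heats: Mapping[str, float]
    seed_name: str
    config: PropagationConfig

    def __post_init__(self) -> None:
        if any(h < 0 for h in self.heats.values()):
            raise ValidationError("negative heat value")

    def __getitem__(self, gene: str) -> float:
        return self.heats[gene]

    def total(self) -> float:
        return float(sum(self.heats.values()))


class TransitionSystem:
    """Indexed, column-stochastic transition matrix for one network.

    Building the sparse matrix once and reusing it across many seed sets
    (observed + null ensemble) is what keeps permutation-scale workloads
    cheap; all propagation entry points funnel through this class.
    """

    def __init__(self, network: GeneNetwork):
        self.nodes = network.sorted_nodes()
        self.index = {g: i for i, g in enumerate(self.nodes)}
        n = len(self.nodes)
        deg = np.zeros(n)
        rows, cols = [], []
        for u, v in network.edges:
            iu, iv = self.index[u], self.index[v]
            rows.append(iu)
            cols.append(iv)
            rows.append(iv)
            cols.append(iu)
            deg[iu] += 1
            deg[iv] += 1
        data = np.ones(len(rows))
        adj = sp.csr_matrix((data, (rows, cols)), shape=(n, n))
        inv_deg = np.zeros(n)
        pos = deg > 0
        inv_deg[pos] = 1.0 / deg[pos]
        # column-stochastic: W[:, j] = A[:, j] / deg(j)
        self.W = (adj @ sp.diags(inv_deg)).tocsr()
        self.degree = deg

    @property
    def n(self) -> int:
        return len(self.nodes)

    def seed_indicator(self, seeds: Sequence[str]) -> np.ndarray:
        f0 = np.zeros(self.n)
        for g in seeds:
            if g not in self.index:
                raise ValidationError(f"seed gene {g!r} not in network")
            i = self.index[g]
            if self.degree[i] == 0:
                raise ValidationError(f"seed gene {g!r} has degree 0 (no outgoing transitions)")
            f0[i] = 1.0
        f0 /= f0.sum()
        return f0

    def propagate_batch(self, F0: np.ndarray, cfg: PropagationConfig) -> np.ndarray:
        """Jacobi fixed-point iteration, vectorized over columns of F0."""
        F = F0.copy()
        restart = (1.0 - cfg.alpha) * F0
        for _ in range(cfg.max_iter):
            F_new = restart + cfg.alpha * (self.W @ F)
            delta = np.abs(F_new - F).max()
            F = F_new
            if delta < cfg.tol:
                return F
        raise ConvergenceError(
            f"propagation did not converge in {cfg.max_iter} iterations (last delta {delta:g})"
        )

    def propagate_exact_batch(self, F0: np.ndarray, cfg: PropagationConfig) -> np.ndarray:
        """Direct dense solve of (I - alpha W) F = (1 - alpha) F0."""
        n = self.n
        A = np.eye(n) - cfg.alpha * self.W.toarray()
        return np.linalg.solve(A, (1.0 - cfg.alpha) * F0)


def _as_heat(ts: TransitionSystem, f: np.ndarray, seed_name: str, cfg: PropagationConfig) -> HeatVector:
    f = np.where(np.abs(f) < 1e-300, 0.0, f)
    f = np.maximum(f, 0.0)  # clip negative round-off
    return HeatVector(heats=dict(zip(ts.nodes, f.tolist())), seed_name=seed_name, config=cfg)


def propagate(
    network: GeneNetwork, seeds: SeedGeneSet, cfg: PropagationConfig | None = None
) -> HeatVector:
    """Iterative random-walk-with-restart propagation from a seed set."""
    cfg = cfg or PropagationConfig()
    ts = TransitionSystem(network)
    f0 = ts.seed_indicator(sorted(seeds.genes))
    f = ts.propagate_batch(f0[:, None], cfg)[:, 0]
    return _as_heat(ts, f, seeds.name, cfg)


def propagate_exact(
    network: GeneNetwork, seeds: SeedGeneSet, cfg: PropagationConfig | None = None
) -> HeatVector:
    """Dense linear-solve oracle; same contract as :func:`propagate`.

    Intended for networks up to a couple of thousand nodes.
    """
    cfg = cfg or PropagationConfig()
    if network.n_nodes > 2000:
        raise ValidationError("propagate_exact limited to networks of <= 2000 nodes")
    ts = TransitionSystem(network)
    f0 = ts.seed_indicator(sorted(seeds.genes))
    f = ts.propagate_exact_batch(f0[:, None], cfg)[:, 0]
    return _as_heat(ts, f, seeds.name, cfg)
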