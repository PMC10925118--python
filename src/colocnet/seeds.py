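"""Seed selection: turn gene-level association tables into seed gene sets.

All threshold comparisons are strict (<); boundary ties are excluded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from colocnet.core import (
    GeneNetwork,
    GeneScoreTable,
    SeedGeneSet,
    ValidationError,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SeedSelectionConfig:
    common_p_threshold: float = 2.6e-6
    rare_lenient_q: float = 0.25
    rare_stringent_alpha: float = 0.05
    min_seeds: int = 6  # "n > 5"
    variant_mac_min: int = 2

    def __post_init__(self) -> None:
        for name in ("common_p_threshold", "rare_lenient_q", "rare_stringent_alpha"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValidationError(f"{name} must be in (0, 1), got {v}")
        if self.min_seeds < 1 or self.variant_mac_min < 0:
            raise ValidationError("count thresholds must be non-negative integers")


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, returned in the input order.

    q_(i) = min_{j >= i} p_(j) * n / j over the sorted p-values, capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValidationError("bh_fdr requires a non-empty p-value list")
    if np.any((p <= 0) | (p > 1)):
        raise ValidationError("p-values must lie in (0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(n)
    q[order] = q_sorted
    return q


def select_common_seeds(table: GeneScoreTable, cfg: SeedSelectionConfig | None = None) -> SeedGeneSet:
    """Genes with p_common strictly below the genome-wide gene threshold."""
    cfg = cfg or SeedSelectionConfig()
    if len(table) == 0:
        raise ValidationError("empty score table")
    if "p_common" not in table.frame.columns:
        raise ValidationError("table lacks a p_common column")
    df = table.frame.dropna(subset=["p_common"])
    sel = df[df["p_common"] < cfg.common_p_threshold]
    genes = frozenset(sel["gene"])
    if not genes:
        # SeedGeneSet forbids empty sets; surface the outcome explicitly.
        raise ValidationError(
            f"no genes pass p_common < {cfg.common_p_threshold} (0 of {len(df)})"
        )
    pvals = dict(zip(sel["gene"], sel["p_common"]))
    return SeedGeneSet(name="common_seeds", source="common", genes=genes, pvalues=pvals)


def select_rare_seeds(
    table: GeneScoreTable, mode: str = "lenient", cfg: SeedSelectionConfig | None = None
) -> SeedGeneSet:
    """Union-over-tests selection of rare-variant seed genes.

    lenient: BH within each test column (over its non-missing genes); a gene
    is selected if any test gives q < rare_lenient_q.
    stringent: Bonferroni within each test column (p < alpha / m_column);
    selected if any test passes.
    """
    cfg = cfg or SeedSelectionConfig()
    if mode not in ("lenient", "stringent"):
        raise ValueError(f"mode must be 'lenient' or 'stringent', got {mode!r}")
    cols = table.rare_test_columns()
    if not cols:
        raise ValidationError("table has none of the rare-test columns (p_burden/p_skato/p_skat)")
    df = table.frame
    selected: set[str] = set()
    best_p: dict[str, float] = {}
    for col in cols:
        sub = df.dropna(subset=[col])
        if len(sub) == 0:
            continue
        p = sub[col].to_numpy(float)
        if mode == "lenient":
            q = bh_fdr(p)
            mask = q < cfg.rare_lenient_q
        else:
            m = len(sub)
            mask = p < cfg.rare_stringent_alpha / m
        for g, pv in zip(sub["gene"][mask], p[mask]):
            selected.add(g)
            best_p[g] = min(best_p.get(g, 1.0), float(pv))
    if not selected:
        raise ValidationError(f"no genes pass rare {mode} selection")
    return SeedGeneSet(
        name=f"rare_seeds_{mode}", source="rare", genes=frozenset(selected), pvalues=best_p
    )


def selection_report(table: GeneScoreTable, cfg: SeedSelectionConfig | None = None) -> pd.DataFrame:
    """Long-format per-gene, per-test report: gene, test, p, q, selected."""
    cfg = cfg or SeedSelectionConfig()
    rows = []
    df = table.frame
    for col in table.pvalue_columns():
        sub = df.dropna(subset=[col])
        if len(sub) == 0:
            continue
        p = sub[col].to_numpy(float)
        if col == "p_common":
            q = np.full(len(sub), np.nan)
            sel = p < cfg.common_p_threshold
        else:
            q = bh_fdr(p)
            sel = q < cfg.rare_lenient_q
        for g, pv, qv, s in zip(sub["gene"], p, q, sel):
            rows.append({"gene": g, "test": col, "p": pv, "q": qv, "selected": bool(s)})
    return pd.DataFrame(rows, columns=["gene", "test", "p", "q", "selected"])


def filter_variants(variant_table: pd.DataFrame, cfg: SeedSelectionConfig | None = None) -> pd.DataFrame:
    """Keep variants with MAC strictly above the configured minimum (MAC > 2)."""
    cfg = cfg or SeedSelectionConfig()
    if "mac" not in variant_table.columns:
        raise ValidationError("variant table requires a 'mac' column")
    if len(variant_table) == 0:
        return variant_table.copy()
    mac = variant_table["mac"]
    if (mac < 0).any():
        raise ValidationError("negative MAC values present")
    if not np.allclose(mac, np.round(mac)):
        raise ValidationError("MAC values must be integers")
    return variant_table[mac > cfg.variant_mac_min].copy()


def map_seeds_to_network(
    seeds: SeedGeneSet, network: GeneNetwork, cfg: SeedSelectionConfig | None = None
) -> SeedGeneSet:
    """Intersect seeds with network nodes; error if fewer than min_seeds remain."""
    cfg = cfg or SeedSelectionConfig()
    kept = set(seeds.genes) & set(network.nodes)
    dropped = set(seeds.genes) - kept
    if dropped:
        logger.info("dropped %d seed genes absent from the network: %s",
                    len(dropped), sorted(dropped)[:10])
    if len(kept) < cfg.min_seeds:
        raise ValidationError(
            f"only {len(kept)} seed genes present in the network; "
            f"at least {cfg.min_seeds} required (n > {cfg.min_seeds - 1})"
        )
    pv = None
    if seeds.pvalues is not None:
        pv = {g: seeds.pvalues[g] for g in kept}
    return SeedGeneSet(name=seeds.name, source=seeds.source, genes=frozenset(kept), pvalues=pv)
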