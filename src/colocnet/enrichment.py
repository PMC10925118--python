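"""Hypergeometric gene-set enrichment and tissue differential-expression calling.

Enrichment p-values are upper-tail hypergeometric probabilities
P[X >= overlap] for X ~ Hypergeom(universe, |category|, |query|). DEG
calling follows a per-label Welch two-sided t-test versus all remaining
labels, Bonferroni-corrected across genes within the label, gated on
|log fold change| >= lfc_min.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from colocnet.core import AnnotationCatalog, ExpressionMatrix, ValidationError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EnrichmentResult:
    """Per-category enrichment rows sorted by p-value."""

    frame: pd.DataFrame  # category, overlap, category_size, query_size, universe_size, p, p_adjusted

    def __post_init__(self) -> None:
        bad = self.frame[
            self.frame["overlap"]
            > np.minimum(self.frame["category_size"], self.frame["query_size"])
        ]
        if len(bad):
            raise ValidationError("overlap exceeds min(category size, query size)")

    def p_for(self, category: str) -> float:
        row = self.frame[self.frame["category"] == category]
        return float(row["p"].iloc[0])


@dataclass(frozen=True)
class DEGConfig:
    bonferroni_alpha: float = 0.05
    lfc_min: float = 0.58

    def __post_init__(self) -> None:
        if not (0 < self.bonferroni_alpha < 1):
            raise ValidationError("bonferroni_alpha must be in (0, 1)")
        if self.lfc_min < 0:
            raise ValidationError("lfc_min must be >= 0")


def hypergeom_overlap(
    query_size: int, category_size: int, universe_size: int, overlap: int
) -> float:
    """Upper-tail P[X >= overlap] of the hypergeometric overlap distribution."""
    if not (0 <= overlap <= min(query_size, category_size)):
        raise ValidationError(
            f"overlap {overlap} inconsistent with query {query_size} / category {category_size}"
        )
    if universe_size < max(query_size, category_size):
        raise ValidationError("universe smaller than query or category")
    if overlap == 0:
        return 1.0
    # sf(k-1) = P[X >= k]
    return float(stats.hypergeom.sf(overlap - 1, universe_size, category_size, query_size))


def annotate_catalog(query: Iterable[str], catalog: AnnotationCatalog) -> EnrichmentResult:
    """Hypergeometric enrichment of a query gene set against every category.

    Query genes outside the catalog universe are dropped (with a logged
    count) before testing. Adjusted p-values are Bonferroni across
    categories.
    """
    query_set = set(query)
    if not catalog.universe:
        raise ValidationError("catalog universe is empty")
    if not query_set:
        raise ValidationError("empty query gene set")
    inside = query_set & set(catalog.universe)
    dropped = len(query_set) - len(inside)
    if dropped:
        logger.info("dropped %d query genes outside the universe", dropped)
    rows = []
    m = len(catalog.categories)
    for name in sorted(catalog.categories):
        cat = catalog.categories[name]
        overlap_genes = sorted(inside & set(cat))
        p = hypergeom_overlap(len(inside), len(cat), len(catalog.universe), len(overlap_genes))
        rows.append(
            {
                "category": name,
                "overlap": len(overlap_genes),
                "category_size": len(cat),
                "query_size": len(inside),
                "universe_size": len(catalog.universe),
                "p": p,
                "p_adjusted": min(1.0, p * m),
                "overlap_genes": ",".join(overlap_genes),
            }
        )
    frame = pd.DataFrame(rows).sort_values(["p", "category"], kind="stable").reset_index(drop=True)
    return EnrichmentResult(frame=frame)


def call_deg(
    expr: ExpressionMatrix, cfg: DEGConfig | None = None
) -> dict[str, dict[str, frozenset[str]]]:
    """Per-label differentially expressed gene sets.

    For each label: Welch two-sided t-test of that label's samples against
    all other samples, per gene; Bonferroni across genes within the label;
    DEG iff adjusted p < bonferroni_alpha and |logFC| >= lfc_min, where
    logFC is the difference of group means of the (already log-scale)
    expression values. Returns {label: {"up": set, "down": set, "both": set}}.
    """
    cfg = cfg or DEGConfig()
    values = expr.values
    n_genes = len(values.index)
    out: dict[str, dict[str, frozenset[str]]] = {}
    sample_labels = np.array([expr.labels[s] for s in values.columns])
    mat = values.to_numpy(float)
    for label in expr.label_names:
        in_group = sample_labels == label
        if in_group.sum() < 2 or (~in_group).sum() < 2:
            raise ValidationError(f"label {label!r} needs >=2 samples on both sides of the split")
        a = mat[:, in_group]
        b = mat[:, ~in_group]
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
        p_adj = np.minimum(1.0, p * n_genes)
        lfc = a.mean(axis=1) - b.mean(axis=1)
        sig = (p_adj < cfg.bonferroni_alpha) & (np.abs(lfc) >= cfg.lfc_min)
        up = frozenset(values.index[sig & (lfc > 0)])
        down = frozenset(values.index[sig & (lfc < 0)])
        out[label] = {"up": up, "down": down, "both": up | down}
    return out


def deg_enrichment(
    query: Iterable[str],
    deg_sets: Mapping[str, frozenset[str]],
    universe: Iterable[str],
    direction: str = "both",
) -> EnrichmentResult:
    """Hypergeometric enrichment of a query against per-label DEG sets.

    ``deg_sets`` maps label -> per-direction sets as returned by
    :func:`call_deg` (or directly label -> gene set).
    """
    uni = frozenset(universe)
    cats = {}
    for label, sets in deg_sets.items():
        genes = sets[direction] if isinstance(sets, Mapping) else sets
        cats[label] = frozenset(genes) & uni
    catalog = AnnotationCatalog(categories=cats, universe=uni)
    return annotate_catalog(query, catalog)
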