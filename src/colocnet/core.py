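"""Domain types shared across the pipeline, and readers/writers for its file formats.

Gene identity is the symbol string, matched case-sensitively after stripping
surrounding whitespace. No alias resolution is attempted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional

import pandas as pd

logger = logging.getLogger(__name__)

VALID_SOURCES = ("common", "rare", "other")

RARE_TEST_COLUMNS = ("p_burden", "p_skato", "p_skat")
P_COLUMNS = ("p_common",) + RARE_TEST_COLUMNS


class ParseError(ValueError):
    """A file could not be parsed; message names the offending line."""


class ValidationError(ValueError):
    """Input values violate a documented contract."""


@dataclass(frozen=True)
class GeneNetwork:
    """Undirected simple graph over gene symbols.

    Edges are stored as frozensets of canonical (sorted) 2-tuples. Degree-0
    nodes are permitted at load time; they are valid non-seed genes but
    invalid as propagation seeds.
    """

    nodes: frozenset[str]
    edges: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        for u, v in self.edges:
            if u == v:
                raise ValidationError(f"self-loop on node {u!r}")
            if u not in self.nodes or v not in self.nodes:
                raise ValidationError(f"edge endpoint not in nodes: ({u!r}, {v!r})")
            if (v, u) in self.edges and (u, v) != tuple(sorted((u, v))):
                raise ValidationError(f"duplicate edge stored in both orders: ({u!r}, {v!r})")

    @classmethod
    def from_edges(
        cls, edges: Iterable[tuple[str, str]], extra_nodes: Iterable[str] = ()
    ) -> "GeneNetwork":
        """Build a network, silently dropping duplicate edges and self-loops.

        Drop counts are emitted to the module logger. Endpoints of dropped
        self-loops are retained as degree-0 nodes.
        """
        nodes: set[str] = set(extra_nodes)
        canon: set[tuple[str, str]] = set()
        n_self = 0
        n_dup = 0
        for u, v in edges:
            u, v = u.strip(), v.strip()
            nodes.add(u)
            nodes.add(v)
            if u == v:
                n_self += 1
                continue
            e = (u, v) if u < v else (v, u)
            if e in canon:
                n_dup += 1
            else:
                canon.add(e)
        if n_self or n_dup:
            logger.info("dropped %d self-loops and %d duplicate edges", n_self, n_dup)
        return cls(nodes=frozenset(nodes), edges=frozenset(canon))

    @property
    def degree(self) -> dict[str, int]:
        deg = {n: 0 for n in self.nodes}
        for u, v in self.edges:
            deg[u] += 1
            deg[v] += 1
        return deg

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def sorted_nodes(self) -> list[str]:
        return sorted(self.nodes)

    def subgraph(self, genes: Iterable[str]) -> "GeneNetwork":
        """Induced subgraph on ``genes`` (intersected with current nodes)."""
        keep = set(genes) & set(self.nodes)
        sub_edges = {e for e in self.edges if e[0] in keep and e[1] in keep}
        return GeneNetwork(nodes=frozenset(keep), edges=frozenset(sub_edges))

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneNetwork):
            return NotImplemented
        return self.nodes == other.nodes and self.edges == other.edges

    def __hash__(self) -> int:
        return hash((self.nodes, self.edges))


@dataclass(frozen=True)
class SeedGeneSet:
    """A named set of seed genes with optional per-gene p-values."""

    name: str
    source: str
    genes: frozenset[str]
    pvalues: Optional[Mapping[str, float]] = None

    def __post_init__(self) -> None:
        if self.source not in VALID_SOURCES:
            raise ValidationError(f"source must be one of {VALID_SOURCES}, got {self.source!r}")
        if not self.genes:
            raise ValidationError("seed gene set must be non-empty")
        if self.pvalues is not None:
            missing = set(self.genes) - set(self.pvalues)
            if missing:
                raise ValidationError(f"pvalues missing for {len(missing)} seed genes")
            for g, p in self.pvalues.items():
                if not (0 < p <= 1):
                    raise ValidationError(f"p-value for {g!r} outside (0, 1]: {p}")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class GeneScoreTable:
    """Gene-level association p-values, one row per gene.

    Columns: gene plus any of p_common, p_burden, p_skato, p_skat, and an
    optional annotation_class. All present p-values lie in (0, 1].
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame
        if "gene" not in df.columns:
            raise ValidationError("score table requires a 'gene' column")
        dupes = df["gene"][df["gene"].duplicated()].unique()
        if len(dupes):
            raise ValidationError(f"duplicate gene symbols: {sorted(dupes)[:5]}")
        present = [c for c in P_COLUMNS if c in df.columns]
        if not present:
            raise ValidationError(f"score table needs at least one of {P_COLUMNS}")
        for col in present:
            vals = df[col].dropna()
            bad = vals[(vals <= 0) | (vals > 1)]
            if len(bad):
                raise ValidationError(
                    f"column {col} has {len(bad)} p-values outside (0, 1]; first bad value {bad.iloc[0]}"
                )

    @property
    def genes(self) -> list[str]:
        return list(self.frame["gene"])

    def pvalue_columns(self) -> list[str]:
        return [c for c in P_COLUMNS if c in self.frame.columns]

    def rare_test_columns(self) -> list[str]:
        return [c for c in RARE_TEST_COLUMNS if c in self.frame.columns]

    def column(self, name: str) -> pd.Series:
        return self.frame.set_index("gene")[name]

    def __len__(self) -> int:
        return len(self.frame)


@dataclass(frozen=True)
class AnnotationCatalog:
    """Map category name -> gene set, plus the enrichment universe.

    Each category set must be contained in the universe.
    """

    categories: Mapping[str, frozenset[str]]
    universe: frozenset[str]

    def __post_init__(self) -> None:
        for name, genes in self.categories.items():
            extra = set(genes) - set(self.universe)
            if extra:
                raise ValidationError(
                    f"category {name!r} has {len(extra)} genes outside the universe"
                )

    def with_universe(self, universe: Iterable[str]) -> "AnnotationCatalog":
        uni = frozenset(universe)
        cats = {k: frozenset(v & uni) for k, v in self.categories.items()}
        return AnnotationCatalog(categories=cats, universe=uni)


@dataclass(frozen=True)
class ExpressionMatrix:
    """Genes x samples expression matrix with a tissue label per sample."""

    values: pd.DataFrame  # index: genes, columns: samples
    labels: Mapping[str, str]  # sample -> tissue label

    def __post_init__(self) -> None:
        missing = set(self.values.columns) - set(self.labels)
        if missing:
            raise ValidationError(f"{len(missing)} samples lack a tissue label")
        counts: dict[str, int] = {}
        for s in self.values.columns:
            counts[self.labels[s]] = counts.get(self.labels[s], 0) + 1
        thin = [lab for lab, c in counts.items() if c < 2]
        if thin:
            raise ValidationError(f"labels with fewer than 2 samples: {sorted(thin)}")

    @property
    def label_names(self) -> list[str]:
        return sorted(set(self.labels.values()))

    def samples_for(self, label: str) -> list[str]:
        return [s for s in self.values.columns if self.labels[s] == label]


# ---------------------------------------------------------------------------
# Readers / writers


def read_edge_list(path: str | Path, format: str = "tsv-2col") -> GeneNetwork:
    """Read an undirected edge list from a 2-column TSV or a SIF file.

    Duplicate edges and self-loops are dropped (counted in the log); the
    resulting network is a simple graph. Raises :class:`ParseError` on
    malformed lines and on an empty graph.
    """
    path = Path(path)
    if format not in ("tsv-2col", "sif"):
        raise ValueError(f"unknown edge-list format {format!r}")
    edges: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if format == "tsv-2col":
                if len(fields) < 2:
                    raise ParseError(f"{path}:{lineno}: expected >=2 columns, got {len(fields)}")
                edges.append((fields[0], fields[1]))
            else:  # SIF: source, interaction type, targets...
                if len(fields) == 1:
                    raise ParseError(f"{path}:{lineno}: SIF line with a single field")
                if len(fields) < 3:
                    raise ParseError(f"{path}:{lineno}: SIF line needs source, type, target")
                src = fields[0]
                for tgt in fields[2:]:
                    edges.append((src, tgt))
    if not edges:
        raise ParseError(f"{path}: no edges found (empty graph)")
    return GeneNetwork.from_edges(edges)


def write_edge_list(network: GeneNetwork, path: str | Path) -> None:
    """Write the network as a sorted 2-column TSV (round-trips with read_edge_list).

    Degree-0 nodes cannot be represented in an edge list and are omitted.
    """
    with open(path, "w") as fh:
        for u, v in sorted(network.edges):
            fh.write(f"{u}\t{v}\n")


def read_gene_scores(path: str | Path) -> GeneScoreTable:
    """Read a gene-level p-value table (TSV with header).

    The header must contain ``gene`` and at least one p-value column among
    p_common, p_burden, p_skato, p_skat. Validation of p-value ranges and
    gene uniqueness happens in :class:`GeneScoreTable`.
    """
    df = pd.read_csv(path, sep="\t")
    if "gene" not in df.columns:
        raise ParseError(f"{path}: missing required 'gene' column")
    df["gene"] = df["gene"].astype(str).str.strip()
    return GeneScoreTable(frame=df)


def write_gene_scores(table: GeneScoreTable, path: str | Path) -> None:
    table.frame.to_csv(path, sep="\t", index=False)


def read_gmt(path: str | Path, universe: Optional[Iterable[str]] = None) -> AnnotationCatalog:
    """Read a GMT gene-set file: name TAB description TAB gene1 TAB gene2 ...

    The universe defaults to the union of all sets unless given explicitly.
    """
    path = Path(path)
    categories: dict[str, frozenset[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: GMT line needs >=3 tab-separated fields")
            name = fields[0].strip()
            genes = frozenset(g.strip() for g in fields[2:] if g.strip())
            categories[name] = genes
    if not categories:
        raise ParseError(f"{path}: empty GMT file")
    if universe is None:
        uni = frozenset().union(*categories.values())
    else:
        uni = frozenset(universe)
    return AnnotationCatalog(categories=categories, universe=uni)


def write_gmt(catalog: AnnotationCatalog, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in sorted(catalog.categories):
            genes = "\t".join(sorted(catalog.categories[name]))
            fh.write(f"{name}\tna\t{genes}\n")


def read_expression(
    expr_path: str | Path, labels_path: str | Path
) -> ExpressionMatrix:
    """Read a genes x samples TSV (first column = gene) and a sample->label TSV."""
    values = pd.read_csv(expr_path, sep="\t", index_col=0)
    lab = pd.read_csv(labels_path, sep="\t")
    if not {"sample", "label"} <= set(lab.columns):
        raise ParseError(f"{labels_path}: needs 'sample' and 'label' columns")
    labels = dict(zip(lab["sample"].astype(str), lab["label"].astype(str)))
    return ExpressionMatrix(values=values, labels=labels)


def write_expression(expr: ExpressionMatrix, expr_path: str | Path, labels_path: str | Path) -> None:
    expr.values.to_csv(expr_path, sep="\t")
    pd.DataFrame(
        {"sample": list(expr.values.columns), "label": [expr.labels[s] for s in expr.values.columns]}
    ).to_csv(labels_path, sep="\t", index=False)


def read_seed_list(path: str | Path, name: str, source: str) -> SeedGeneSet:
    """Read a one-symbol-per-line seed gene file."""
    genes = set()
    with open(path) as fh:
        for line in fh:
            s = line.strip()
            if s:
                genes.add(s)
    return SeedGeneSet(name=name, source=source, genes=frozenset(genes))


def write_seed_list(seeds: SeedGeneSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in sorted(seeds.genes):
            fh.write(g + "\n")
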