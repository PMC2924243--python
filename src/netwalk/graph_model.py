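"""Typed interaction networks, per-gene data vectors, annotation tables, and file I/O.

The network model is deliberately small: genes are plain string identifiers,
an edge is a (source, target, directed, itype) record, and undirected edges
are stored once and expanded to two arcs only when the transition matrix is
built.  Interaction types distinguish direct physical interactions (PPI),
directed signaling events, transcription factor -> target regulation, and
indirect functional-similarity (FS) links derived from annotation overlap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Recognised interaction types.
ITYPES = ("PPI", "SIGNALING", "TF_TARGET", "FS")

DEFAULT_ITYPE = "PPI"


@dataclass(frozen=True)
class Edge:
    """A single interaction record.

    Undirected edges are canonicalized so that ``source <= target``;
    a directed edge keeps its orientation.
    """

    source: str
    target: str
    directed: bool = False
    itype: str = DEFAULT_ITYPE

    def __post_init__(self) -> None:
        if self.itype not in ITYPES:
            raise ValueError(f"unknown interaction type {self.itype!r}; expected one of {ITYPES}")

    def canonical(self) -> "Edge":
        if not self.directed and self.source > self.target:
            return Edge(self.target, self.source, False, self.itype)
        return self

    @property
    def key(self) -> tuple:
        e = self.canonical()
        return (e.source, e.target, e.directed, e.itype)


class InteractionNetwork:
    """A mixed directed/undirected gene interaction graph.

    Nodes are kept in lexicographic order so that matrix indexing is
    reproducible across runs and platforms.  Self-loops are dropped and
    duplicate (source, target, itype) records merged at construction.
    """

    def __init__(self, edges: Iterable[Edge], extra_nodes: Iterable[str] = ()) -> None:
        cleaned: dict[tuple, Edge] = {}
        n_self = 0
        n_dup = 0
        for e in edges:
            if e.source == e.target:
                n_self += 1
                continue
            e = e.canonical()
            if e.key in cleaned:
                n_dup += 1
                continue
            cleaned[e.key] = e
        if n_self:
            logger.warning("dropped %d self-loop edge(s)", n_self)
        if n_dup:
            logger.info("merged %d duplicate edge record(s)", n_dup)
        self._edges: tuple[Edge, ...] = tuple(sorted(cleaned.values(), key=lambda e: e.key))
        nodes = set(extra_nodes)
        for e in self._edges:
            nodes.add(e.source)
            nodes.add(e.target)
        self._nodes: tuple[str, ...] = tuple(sorted(nodes))
        self._index: dict[str, int] = {g: i for i, g in enumerate(self._nodes)}

    # -- basic accessors ---------------------------------------------------

    @property
    def nodes(self) -> tuple[str, ...]:
        return self._nodes

    @property
    def edges(self) -> tuple[Edge, ...]:
        return self._edges

    @property
    def n(self) -> int:
        return len(self._nodes)

    def index_of(self, gene: str) -> int:
        return self._index[gene]

    @property
    def node_index(self) -> Mapping[str, int]:
        return self._index

    def __contains__(self, gene: str) -> bool:
        return gene in self._index

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, InteractionNetwork):
            return NotImplemented
        return self._nodes == other._nodes and self._edges == other._edges

    def __repr__(self) -> str:
        return f"InteractionNetwork(n_nodes={self.n}, n_edges={len(self._edges)})"

    def arcs(self) -> Iterable[tuple[int, int, Edge]]:
        """Yield every directed arc (i, j, parent edge), expanding undirected edges."""
        for e in self._edges:
            i, j = self._index[e.source], self._index[e.target]
            yield i, j, e
            if not e.directed:
                yield j, i, e

    def degrees(self) -> np.ndarray:
        """Total degree per node (undirected edges count once per endpoint)."""
        deg = np.zeros(self.n, dtype=int)
        for e in self._edges:
            deg[self._index[e.source]] += 1
            deg[self._index[e.target]] += 1
        return deg

    # -- derived networks --------------------------------------------------

    def remove_nodes(self, drop: Iterable[str]) -> "InteractionNetwork":
        dropset = set(drop)
        kept = [e for e in self._edges if e.source not in dropset and e.target not in dropset]
        extra = [g for g in self._nodes if g not in dropset]
        return InteractionNetwork(kept, extra_nodes=extra)

    def remove_edges(self, drop_keys: Iterable[tuple]) -> "InteractionNetwork":
        dropset = set(drop_keys)
        kept = [e for e in self._edges if e.key not in dropset]
        return InteractionNetwork(kept, extra_nodes=self._nodes)

    def add_edges(self, new: Iterable[Edge]) -> "InteractionNetwork":
        return InteractionNetwork(list(self._edges) + list(new), extra_nodes=self._nodes)


@dataclass(frozen=True)
class DataVector:
    """Strictly positive per-gene ratio values for one experimental condition.

    Values are ratios of a test versus control sample (for example treated /
    untreated mRNA expression), so 1 means "no change".  Genes missing from
    the vector are imputed to 1 when aligned to a network.
    """

    condition: str
    values: Mapping[str, float]

    def __post_init__(self) -> None:
        for g, v in self.values.items():
            if not np.isfinite(v) or v <= 0:
                raise ValueError(
                    f"data value for gene {g!r} in condition {self.condition!r} "
                    f"must be a positive finite number, got {v!r}"
                )

    def __len__(self) -> int:
        return len(self.values)

    def to_array(self, net: InteractionNetwork, fill: float = 1.0) -> np.ndarray:
        """Dense vector in the network's node order; absent genes get ``fill``."""
        w = np.full(net.n, fill, dtype=float)
        for g, v in self.values.items():
            i = net.node_index.get(g)
            if i is not None:
                w[i] = v
        return w

    def with_values(self, values: Mapping[str, float]) -> "DataVector":
        return DataVector(self.condition, dict(values))


@dataclass(frozen=True)
class AnnotationTable:
    """Flat gene -> annotation-term sets plus the size of the gene universe."""

    gene_terms: Mapping[str, frozenset]
    universe_n: int = 0

    def __post_init__(self) -> None:
        n_ann = len(self.gene_terms)
        if self.universe_n == 0:
            object.__setattr__(self, "universe_n", n_ann)
        if self.universe_n < n_ann:
            raise ValueError(
                f"universe size {self.universe_n} smaller than {n_ann} annotated genes"
            )

    def term_genes(self) -> dict[str, set]:
        """Inverted index: term -> set of carrier genes."""
        inv: dict[str, set] = {}
        for g, terms in self.gene_terms.items():
            for t in terms:
                inv.setdefault(t, set()).add(g)
        return inv


# ---------------------------------------------------------------------------
# Network I/O

_TSV_HEADER = ("source", "target", "directed", "itype")


def _parse_directed(token: str, lineno: int) -> bool:
    t = token.strip().lower()
    if t in ("0", "false", "undirected", "u", ""):
        return False
    if t in ("1", "true", "directed", "d"):
        return True
    raise ValueError(f"line {lineno}: cannot parse directedness flag {token!r}")


def read_network(path: str | Path, dialect: str = "tsv") -> InteractionNetwork:
    """Read an interaction network from a 4-column TSV edge list or a SIF file.

    TSV columns: source, target, directed (0/1, optional, default undirected),
    itype (optional, default PPI).  A leading header row matching the column
    names is skipped.  SIF rows are ``source relation target [target ...]``;
    the relation is used as the interaction type when it matches a known one.
    """
    path = Path(path)
    if dialect not in ("tsv", "sif"):
        raise ValueError(f"unknown dialect {dialect!r}")
    lines = path.read_text().splitlines()
    edges: list[Edge] = []
    isolated: list[str] = []
    n_rows = 0
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t") if dialect == "tsv" else line.split()
        if dialect == "tsv":
            if lineno == 1 and tuple(f.strip().lower() for f in fields[:2]) == _TSV_HEADER[:2]:
                continue
            if len(fields) < 2:
                raise ValueError(f"{path}, line {lineno}: expected >= 2 columns, got {len(fields)}")
            source, target = fields[0].strip(), fields[1].strip()
            if not source or not target:
                raise ValueError(f"{path}, line {lineno}: empty gene identifier")
            directed = _parse_directed(fields[2], lineno) if len(fields) >= 3 else False
            itype = fields[3].strip() if len(fields) >= 4 and fields[3].strip() else DEFAULT_ITYPE
            if itype not in ITYPES:
                raise ValueError(f"{path}, line {lineno}: unknown interaction type {itype!r}")
            edges.append(Edge(source, target, directed, itype))
            n_rows += 1
        else:  # SIF
            if len(fields) == 1:
                isolated.append(fields[0])
                continue
            if len(fields) == 2:
                raise ValueError(
                    f"{path}, line {lineno}: SIF row needs source, relation and >= 1 target"
                )
            source, rel = fields[0], fields[1]
            itype = rel if rel in ITYPES else DEFAULT_ITYPE
            directed = rel in ("SIGNALING", "TF_TARGET")
            for target in fields[2:]:
                edges.append(Edge(source, target, directed, itype))
                n_rows += 1
    if n_rows == 0 and not isolated:
        raise ValueError(f"{path}: no edges found")
    return InteractionNetwork(edges, extra_nodes=isolated)


def write_network(net: InteractionNetwork, path: str | Path, dialect: str = "tsv") -> None:
    """Write a network as TSV (round-trippable), SIF, or GraphML (for viewers)."""
    path = Path(path)
    if dialect == "tsv":
        with open(path, "w") as fh:
            fh.write("\t".join(_TSV_HEADER) + "\n")
            for e in net.edges:
                fh.write(f"{e.source}\t{e.target}\t{int(e.directed)}\t{e.itype}\n")
    elif dialect == "sif":
        with open(path, "w") as fh:
            for e in net.edges:
                fh.write(f"{e.source}\t{e.itype}\t{e.target}\n")
    elif dialect == "graphml":
        import networkx as nx

        g = nx.DiGraph()
        g.add_nodes_from(net.nodes)
        for e in net.edges:
            g.add_edge(e.source, e.target, itype=e.itype, directed=int(e.directed))
            if not e.directed:
                g.add_edge(e.target, e.source, itype=e.itype, directed=0)
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# Data-table I/O


def read_data_table(path: str | Path, strict: bool = True) -> list[DataVector]:
    """Read a genes x conditions table of positive ratio values.

    The first column holds gene identifiers; each remaining column is one
    condition.  Blank / non-numeric cells are missing.  Non-positive values
    are an error in strict mode (ratio data must be positive); with
    ``strict=False`` they are treated as missing and a count is logged.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.shape[1] == 0:
        raise ValueError(f"{path}: table has no condition columns")
    vectors = []
    for cond in df.columns:
        col = pd.to_numeric(df[cond], errors="coerce")
        bad = col.index[(col <= 0) | np.isinf(col)]
        if len(bad) > 0:
            if strict:
                raise ValueError(
                    f"{path}: non-positive value for gene {bad[0]!r} in condition {cond!r}; "
                    "ratio data must be strictly positive"
                )
            logger.warning(
                "condition %r: treating %d non-positive value(s) as missing", cond, len(bad)
            )
            col = col.drop(bad)
        col = col.dropna()
        vectors.append(DataVector(str(cond), {str(g): float(v) for g, v in col.items()}))
    return vectors


def write_data_table(vectors: Sequence[DataVector], path: str | Path) -> None:
    """Write data vectors as a genes x conditions TSV (missing cells left blank)."""
    df = pd.DataFrame({v.condition: pd.Series(v.values) for v in vectors})
    df.index.name = "gene"
    df.to_csv(path, sep="\t")


def read_annotation_table(path: str | Path, universe_n: int = 0) -> AnnotationTable:
    """Read a two-column (gene, term) TSV into an AnnotationTable."""
    gene_terms: dict[str, set] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 2:
            raise ValueError(f"{path}, line {lineno}: expected gene<TAB>term")
        if fields[0] == "gene" and lineno == 1:
            continue
        gene_terms.setdefault(fields[0].strip(), set()).add(fields[1].strip())
    return AnnotationTable({g: frozenset(t) for g, t in gene_terms.items()}, universe_n=universe_n)


def read_pathway_table(path: str | Path) -> dict[str, set]:
    """Read a two-column (pathway, gene) TSV into a pathway -> gene-set mapping."""
    pathways: dict[str, set] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 2:
            raise ValueError(f"{path}, line {lineno}: expected pathway<TAB>gene")
        if fields[0] == "pathway" and lineno == 1:
            continue
        pathways.setdefault(fields[0].strip(), set()).add(fields[1].strip())
    return pathways


# ---------------------------------------------------------------------------


def reverse_tf_edges(net: InteractionNetwork) -> InteractionNetwork:
    """Flip every directed transcription-factor -> target edge to target -> TF.

    Expression changes of target genes are informative about the activity of
    the transcription factor that regulates them, not the other way around,
    so the walk should flow from targets into their regulators.  Apply once
    per analysis: a second application undoes the first.
    """
    flipped = [
        Edge(e.target, e.source, True, e.itype)
        if e.directed and e.itype == "TF_TARGET"
        else e
        for e in net.edges
    ]
    return InteractionNetwork(flipped, extra_nodes=net.nodes)
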