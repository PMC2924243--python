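"""Functional-similarity (FS) edge construction from annotation overlap.

Metabolic enzymes in the same pathway rarely bind each other physically, so
a purely physical interaction network misses coherent metabolic programs.
FS edges add indirect links: two genes are connected when the overlap of
their annotation-term sets is improbable by chance, or when they share a
metabolic-pathway annotation.

The overlap score for genes i and j sharing the term set N is

    s_ij = prod_{k in N}  |G_k| (|G_k| - 1)  /  ( n (n - 1) )

where G_k is the set of genes carrying term k and n the gene universe size:
under independence across terms, the probability that a uniformly random
ordered gene pair carries every shared term.  A term carried by all n genes
contributes a factor of 1 (uninformative); rare shared terms drive s_ij
down.  Pairs with s_ij below a threshold (default 0.001) become FS edges.
"""

from __future__ import annotations

import itertools
import logging
from typing import Iterable, Mapping

from .graph_model import AnnotationTable, Edge, InteractionNetwork

logger = logging.getLogger(__name__)

DEFAULT_FS_THRESHOLD = 0.001


def fs_significance(gene_i: str, gene_j: str, annotations: AnnotationTable) -> float:
    """Significance of annotation overlap between two genes; smaller = stronger.

    Returns 1.0 when the genes share no terms (nothing to score).  Raises if
    either gene is unannotated.
    """
    try:
        terms_i = annotations.gene_terms[gene_i]
        terms_j = annotations.gene_terms[gene_j]
    except KeyError as exc:
        raise KeyError(f"gene {exc.args[0]!r} is not annotated") from None
    shared = terms_i & terms_j
    if not shared:
        return 1.0
    n = annotations.universe_n
    if n < 2:
        return 1.0
    carriers = annotations.term_genes()
    s = 1.0
    denom = n * (n - 1)
    for k in shared:
        m = len(carriers[k])
        s *= m * (m - 1) / denom
    return min(s, 1.0)


def build_fs_network(
    annotations: AnnotationTable,
    kegg_pathways: Mapping[str, Iterable[str]] | None = None,
    threshold: float = DEFAULT_FS_THRESHOLD,
) -> InteractionNetwork:
    """FS edges for all gene pairs with significant annotation overlap,
    plus an edge for every pair co-annotated to the same metabolic pathway.

    Only pairs sharing at least one term are candidates, found through the
    inverted term -> genes index so disjoint annotation sets cost nothing.
    Signaling pathways must not be passed here: they are already represented
    as directed interactions in the physical network.
    """
    if not annotations.gene_terms and not kegg_pathways:
        return InteractionNetwork([])
    n = annotations.universe_n
    denom = n * (n - 1) if n >= 2 else 1
    carriers = annotations.term_genes()
    factor = {k: len(g) * (len(g) - 1) / denom for k, g in carriers.items()}

    # accumulate per-pair products over shared terms via the inverted index
    pair_s: dict[tuple[str, str], float] = {}
    for k, genes in carriers.items():
        f = factor[k]
        if f >= 1.0:
            continue  # a term carried by (nearly) everyone can never help
        members = sorted(genes)
        for a, b in itertools.combinations(members, 2):
            pair_s[(a, b)] = pair_s.get((a, b), 1.0) * f

    edges = [
        Edge(a, b, directed=False, itype="FS")
        for (a, b), s in sorted(pair_s.items())
        if s < threshold
    ]
    n_overlap = len(edges)

    if kegg_pathways:
        for pw in sorted(kegg_pathways):
            members = sorted(set(kegg_pathways[pw]))
            for a, b in itertools.combinations(members, 2):
                edges.append(Edge(a, b, directed=False, itype="FS"))
    net = InteractionNetwork(edges)
    logger.info(
        "FS network: %d edges from annotation overlap, %d total after pathway rule",
        n_overlap,
        len(net.edges),
    )
    return net


def merge_networks(nets: Iterable[InteractionNetwork]) -> InteractionNetwork:
    """Union of node sets and typed edge sets, deduplicated per network rules.

    The same gene pair may appear once per interaction type (a physical PPI
    record and an FS record are distinct interactions); exact duplicates
    merge.
    """
    all_edges: list[Edge] = []
    all_nodes: set[str] = set()
    for net in nets:
        all_edges.extend(net.edges)
        all_nodes.update(net.nodes)
    return InteractionNetwork(all_edges, extra_nodes=all_nodes)
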