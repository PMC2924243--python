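"""Deterministic generators for toy and benchmark inputs.

Every generator is a pure function of its parameters and seed, so fixtures
regenerate bit-identically and ground truth (planted module membership and
edges) is exported alongside the data rather than re-derived by tests.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .graph_model import AnnotationTable, DataVector, Edge, InteractionNetwork

# ---------------------------------------------------------------------------
# Twelve-node didactic toy: a high-value node A attached to a value-1
# background mesh (B..F) that bridges into a coherent moderate-value cluster
# G..L.  Data values: A = 5; G..L = 2; all others = 1.  The wiring lives in
# one constant so every test refers to the same topology, and tests against
# it assert rankings only, never exact values.

TOY_EDGES: tuple[tuple[str, str], ...] = (
    # high-value node A, pendant on the background mesh
    ("A", "B"),
    # dense value-1 background mesh
    ("B", "C"), ("B", "D"), ("B", "E"), ("B", "F"),
    ("C", "D"), ("C", "E"), ("C", "F"),
    ("D", "E"), ("D", "F"),
    ("E", "F"),
    # bridges from the mesh into the cluster
    ("C", "G"), ("C", "H"),
    ("D", "I"), ("D", "J"), ("D", "L"),
    ("E", "H"), ("E", "K"), ("E", "L"),
    ("F", "G"), ("F", "I"), ("F", "K"),
    # the coherent moderate-value cluster, a 6-cycle
    ("G", "H"), ("H", "I"), ("I", "J"), ("J", "K"), ("K", "L"), ("L", "G"),
)

TOY_VALUES: dict[str, float] = {
    "A": 5.0,
    "G": 2.0, "H": 2.0, "I": 2.0, "J": 2.0, "K": 2.0, "L": 2.0,
}

#: undirected intra-cluster edges of the toy (canonical sorted pairs)
TOY_CLUSTER_EDGES: frozenset = frozenset(
    {("G", "H"), ("H", "I"), ("I", "J"), ("J", "K"), ("K", "L"), ("G", "L")}
)


def make_toy_network() -> tuple[InteractionNetwork, DataVector]:
    """The 12-node didactic toy network and its data values (A=5, G..L=2, rest 1)."""
    edges = [Edge(a, b, directed=False, itype="PPI") for a, b in TOY_EDGES]
    net = InteractionNetwork(edges)
    values = {g: TOY_VALUES.get(g, 1.0) for g in net.nodes}
    return net, DataVector("toy", values)


# ---------------------------------------------------------------------------
# Planted-module benchmark


@dataclass(frozen=True)
class PlantedFixture:
    """A scale-free background graph with two planted coherent modules.

    The high module's genes carry ratio values well above 1 and the low
    module's well below, each wired as a clique, mimicking the structure of
    coherently up- and down-regulated processes that the method is meant to
    pull out of expression data.  ``data`` holds one vector per condition;
    module membership and intra-module edges are exported as ground truth.
    """

    network: InteractionNetwork
    data: tuple[DataVector, ...]
    high_nodes: frozenset
    low_nodes: frozenset
    high_edges: frozenset  # canonical (a, b) sorted pairs
    low_edges: frozenset
    params: dict = field(hash=False)

    @property
    def single(self) -> DataVector:
        return self.data[0]


def _gene_name(i: int) -> str:
    return f"G{i:04d}"


def make_planted_fixture(
    n: int = 1000,
    module_size: int = 25,
    high_mean: float = 4.0,
    low_mean: float = 0.25,
    noise_sd: float = 0.25,
    n_conditions: int = 1,
    attachment_m: int = 2,
    seed: int = 42,
    activation: tuple[tuple[bool, bool], ...] | None = None,
) -> PlantedFixture:
    """Generate the planted-module benchmark.

    The background is a preferential-attachment (Barabasi-Albert) graph —
    hub-rich like real interactomes, which is what the topology-bias
    normalization has to cope with.  Two disjoint sets of ``module_size``
    nodes get a full clique of extra PPI edges.  Per condition, log2 ratios
    are drawn Normal(log2 high_mean, noise_sd) in the active high module,
    Normal(log2 low_mean, noise_sd) in the active low module and
    Normal(0, noise_sd) elsewhere, then exponentiated to positive ratios.

    ``activation[c] = (high_active, low_active)`` lets modules switch off in
    individual conditions (values then follow the background distribution);
    by default both modules are active everywhere.
    """
    if 2 * module_size >= n:
        raise ValueError("modules do not fit in the network")
    if not (high_mean > 1.0 > low_mean > 0.0):
        raise ValueError("need high_mean > 1 > low_mean > 0")
    if activation is None:
        activation = tuple((True, True) for _ in range(n_conditions))
    if len(activation) != n_conditions:
        raise ValueError("activation pattern length must equal n_conditions")

    rng = np.random.default_rng(seed)
    base = nx.barabasi_albert_graph(n, attachment_m, seed=int(rng.integers(2**31 - 1)))

    picks = rng.choice(n, size=2 * module_size, replace=False)
    high_idx = set(int(i) for i in picks[:module_size])
    low_idx = set(int(i) for i in picks[module_size:])

    edges = [
        Edge(_gene_name(a), _gene_name(b), directed=False, itype="PPI")
        for a, b in base.edges()
    ]
    for members in (high_idx, low_idx):
        for a, b in itertools.combinations(sorted(members), 2):
            edges.append(Edge(_gene_name(a), _gene_name(b), directed=False, itype="PPI"))
    net = InteractionNetwork(edges, extra_nodes=[_gene_name(i) for i in range(n)])

    high_nodes = frozenset(_gene_name(i) for i in high_idx)
    low_nodes = frozenset(_gene_name(i) for i in low_idx)

    def module_pairs(nodes: frozenset) -> frozenset:
        return frozenset(tuple(sorted(p)) for p in itertools.combinations(sorted(nodes), 2))

    data = []
    for c in range(n_conditions):
        high_on, low_on = activation[c]
        logv = rng.normal(0.0, noise_sd, size=n)
        for i in high_idx:
            if high_on:
                logv[i] = rng.normal(np.log2(high_mean), noise_sd)
        for i in low_idx:
            if low_on:
                logv[i] = rng.normal(np.log2(low_mean), noise_sd)
        values = {_gene_name(i): float(2.0 ** logv[i]) for i in range(n)}
        data.append(DataVector(f"cond{c}", values))

    return PlantedFixture(
        network=net,
        data=tuple(data),
        high_nodes=high_nodes,
        low_nodes=low_nodes,
        high_edges=module_pairs(high_nodes),
        low_edges=module_pairs(low_nodes),
        params=dict(
            n=n,
            module_size=module_size,
            high_mean=high_mean,
            low_mean=low_mean,
            noise_sd=noise_sd,
            n_conditions=n_conditions,
            attachment_m=attachment_m,
            seed=seed,
        ),
    )


def make_scalefree_network(
    n: int = 1000, attachment_m: int = 2, seed: int = 0
) -> InteractionNetwork:
    """Plain preferential-attachment network (no planted structure)."""
    base = nx.barabasi_albert_graph(n, attachment_m, seed=seed)
    edges = [
        Edge(_gene_name(a), _gene_name(b), directed=False, itype="PPI")
        for a, b in base.edges()
    ]
    return InteractionNetwork(edges, extra_nodes=[_gene_name(i) for i in range(n)])


def make_random_data(
    net: InteractionNetwork, noise_sd: float = 1.0, seed: int = 0, condition: str = "random"
) -> DataVector:
    """Lognormal-ratio data with no relation to the network structure."""
    rng = np.random.default_rng(seed)
    logv = rng.normal(0.0, noise_sd, size=net.n)
    return DataVector(condition, {g: float(2.0**v) for g, v in zip(net.nodes, logv)})


# ---------------------------------------------------------------------------
# Annotation fixture for the FS builder


def make_annotation_fixture(
    n_genes: int = 100,
    n_common_terms: int = 3,
    module_assignments: tuple[tuple[str, ...], ...] = (),
    terms_per_module: int = 3,
    seed: int = 0,
) -> AnnotationTable:
    """Annotation table with planted functional modules.

    Genes named ``G0000..`` each carry a couple of widely shared background
    terms; genes of the same planted module additionally share
    ``terms_per_module`` terms exclusive to that module, so their pairwise
    overlap is significant while cross-module overlap is not.
    """
    rng = np.random.default_rng(seed)
    genes = [_gene_name(i) for i in range(n_genes)]
    gene_terms: dict[str, set] = {g: set() for g in genes}
    for t in range(n_common_terms):
        term = f"COMMON{t:03d}"
        # each background term is carried by roughly half the universe
        carriers = rng.choice(n_genes, size=max(2, n_genes // 2), replace=False)
        for i in carriers:
            gene_terms[genes[int(i)]].add(term)
    for m, members in enumerate(module_assignments):
        for t in range(terms_per_module):
            term = f"MODULE{m:02d}_T{t}"
            for g in members:
                gene_terms.setdefault(g, set()).add(term)
    return AnnotationTable(
        {g: frozenset(ts) for g, ts in gene_terms.items() if ts}, universe_n=n_genes
    )
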