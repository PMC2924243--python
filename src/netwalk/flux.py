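"""Data preprocessing and Edge Flux scoring.

The flux through arc i->j at stationarity is ``e_ij = g_i * p_ij``: the
probability mass flowing along the interaction per step of the walk.  Raw
fluxes inherit the network's topological bias, so each is normalized against
the flux ``e_r`` of a background walk over uniform data; the reported score

    s_ij = log2(e_ij / e_r,ij)

is centered at 0, positive where an interaction carries more walker mass
than its topology alone would predict (coherent high-value neighborhoods)
and negative where it carries less (coherent low-value neighborhoods).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .graph_model import DataVector, InteractionNetwork, reverse_tf_edges
from .walk import (
    TransitionMatrix,
    VisitationResult,
    WalkConfig,
    align_data,
    build_transition_matrix,
    restart_vector,
    stationary_distribution,
)

logger = logging.getLogger(__name__)

#: label used for the implicit dangling-node mass in conservation accounting
DANGLING_LABEL = "__dangling__"


def winsorize(w: DataVector, lower: float = 0.001, upper: float = 0.999) -> DataVector:
    """Clip data values to the [0.1th, 99.9th] percentile band.

    Extreme outliers would otherwise dominate every transition probability in
    their neighborhood.  Percentiles are computed over the supplied values
    only (imputation happens later, so imputed 1s never distort the tails)
    with linear interpolation between order statistics.
    """
    if len(w.values) < 2:
        warnings.warn("winsorize: fewer than 2 values, returning input unchanged", stacklevel=2)
        return w
    vals = np.fromiter(w.values.values(), dtype=float)
    lo, hi = np.percentile(vals, [100 * lower, 100 * upper], method="linear")
    clipped = {g: float(min(max(v, lo), hi)) for g, v in w.values.items()}
    return w.with_values(clipped)


def impute_missing(net: InteractionNetwork, w: DataVector) -> DataVector:
    """Align a data vector to a network: absent genes get 1 ("no change").

    Genes in the vector that are not in the network are dropped (logged).
    """
    values = {g: 1.0 for g in net.nodes}
    n_dropped = 0
    for g, v in w.values.items():
        if g in net.node_index:
            values[g] = v
        else:
            n_dropped += 1
    if n_dropped:
        logger.info(
            "condition %r: dropped %d gene(s) absent from the network", w.condition, n_dropped
        )
    return w.with_values(values)


@dataclass(frozen=True)
class EdgeFluxTable:
    """Per-interaction flux scores.

    ``table`` has one row per edge record with combined (both-arc) fluxes
    ``e`` and ``e_r``, the normalized score ``s``, and per-arc columns
    (``e_fwd`` is source->target, ``e_rev`` target->source; the reverse arc
    of a directed edge carries 0).  The uniform mass leaving dangling nodes
    corresponds to no real interaction and is tracked separately so that
    total flux conservation (sum e + dangling mass = 1) stays checkable.
    """

    table: pd.DataFrame
    dangling_mass: float = 0.0
    dangling_mass_r: float = 0.0

    def total_flux(self) -> float:
        return float(self.table["e"].sum() + self.dangling_mass)

    def total_background_flux(self) -> float:
        return float(self.table["e_r"].sum() + self.dangling_mass_r)

    def __len__(self) -> int:
        return len(self.table)

    def sorted_by_score(self, ascending: bool = False) -> pd.DataFrame:
        """Deterministic score ordering; ties broken lexicographically."""
        return self.table.sort_values(
            ["s", "source", "target", "itype"],
            ascending=[ascending, True, True, True],
            kind="mergesort",
        ).reset_index(drop=True)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def _arc_flux_matrix(g: np.ndarray, P: TransitionMatrix) -> tuple[sp.csr_matrix, float]:
    """Sparse matrix of e_ij = g_i p_ij over real arcs, plus dangling mass."""
    F = sp.diags(g) @ P.matrix
    dangling_mass = float(g[P.dangling].sum())
    return F.tocsr(), dangling_mass


def edge_flux(
    g: np.ndarray, P: TransitionMatrix, net: InteractionNetwork
) -> tuple[pd.DataFrame, float]:
    """Raw flux per edge record.

    Returns a frame with columns (source, target, directed, itype, e_fwd,
    e_rev, e) and the dangling mass.  Undirected edges contribute two arcs,
    retained separately and combined by summation for reporting; parallel
    records of different interaction types between the same pair share the
    same arc fluxes (the walker sees one transition).
    """
    if len(g) != P.n or P.nodes != net.nodes:
        raise ValueError("visitation vector, transition matrix and network are misaligned")
    F, dangling_mass = _arc_flux_matrix(g, P)
    coo = F.tocoo()
    lookup = {(int(i), int(j)): float(v) for i, j, v in zip(coo.row, coo.col, coo.data)}
    rows = []
    for e in net.edges:
        i, j = net.index_of(e.source), net.index_of(e.target)
        fwd = lookup.get((i, j), 0.0)
        rev = lookup.get((j, i), 0.0) if not e.directed else 0.0
        rows.append((e.source, e.target, e.directed, e.itype, fwd, rev, fwd + rev))
    df = pd.DataFrame(rows, columns=["source", "target", "directed", "itype", "e_fwd", "e_rev", "e"])
    return df, dangling_mass


def normalized_edge_flux(e: pd.Series, e_r: pd.Series, base: float = 2.0) -> pd.Series:
    """s = log_base(e / e_r); 0 where flux matches the topological expectation.

    Arcs with zero background flux (impossible when the background walk uses
    q > 0) are flagged with NaN and a warning rather than +/-inf.
    """
    e = np.asarray(e, dtype=float)
    e_r = np.asarray(e_r, dtype=float)
    s = np.full(len(e), np.nan)
    ok = e_r > 0
    if not ok.all():
        warnings.warn(
            f"{(~ok).sum()} edge(s) have zero background flux and were excluded "
            "from normalization",
            stacklevel=2,
        )
    with np.errstate(divide="ignore"):
        s[ok] = np.log2(e[ok] / e_r[ok]) / np.log2(base)
    # exact zero where e == e_r, so uniform data gives s identically 0
    s[ok & (e == e_r)] = 0.0
    return pd.Series(s, name="s")


def run_netwalk(
    net: InteractionNetwork,
    w: DataVector,
    config: WalkConfig | None = None,
    winsorize_data: bool = True,
    reverse_tf: bool = True,
    log_base: float = 2.0,
) -> tuple[VisitationResult, EdgeFluxTable]:
    """Full pipeline: preprocessing, both walks, edge flux, normalization.

    Steps: reverse TF->target edges, winsorize the observed values, impute
    missing genes to 1, run foreground and background walks, compute raw and
    background fluxes per edge, normalize.  Deterministic given its inputs.
    """
    if config is None:
        config = WalkConfig()
    if reverse_tf:
        net = reverse_tf_edges(net)
    if winsorize_data:
        w = winsorize(w)
    w = impute_missing(net, w)
    warr = align_data(net, w)

    P = build_transition_matrix(net, warr)
    r = restart_vector(warr, config, net)
    g, it, conv = stationary_distribution(P, r, config)

    ones = np.ones(net.n)
    P_r = build_transition_matrix(net, ones)
    r_r = restart_vector(ones, config, net)
    g_r, it_r, conv_r = stationary_distribution(P_r, r_r, config)

    with np.errstate(divide="ignore", invalid="ignore"):
        g_rel = np.where(g_r > 0, g / g_r, np.nan)
    visit = VisitationResult(
        nodes=net.nodes,
        g=g,
        g_r=g_r,
        g_rel=g_rel,
        iterations=max(it, it_r),
        converged=conv and conv_r,
    )

    df, dmass = edge_flux(g, P, net)
    df_r, dmass_r = edge_flux(g_r, P_r, net)
    df["e_r"] = df_r["e"]
    df["e_r_fwd"] = df_r["e_fwd"]
    df["e_r_rev"] = df_r["e_rev"]
    df["s"] = normalized_edge_flux(df["e"], df["e_r"], base=log_base)
    ef = EdgeFluxTable(table=df, dangling_mass=dmass, dangling_mass_r=dmass_r)
    return visit, ef


def node_table(visit: VisitationResult, w: DataVector) -> pd.DataFrame:
    """Per-gene summary: data value, g, g_r, and relative visitation."""
    warr = [w.values.get(gene, 1.0) for gene in visit.nodes]
    return pd.DataFrame(
        {
            "gene": visit.nodes,
            "w": warr,
            "g": visit.g,
            "g_r": visit.g_r,
            "g_rel": visit.g_rel,
        }
    )


def write_graphml(
    net: InteractionNetwork, ef: EdgeFluxTable, visit: VisitationResult, path
) -> None:
    """Export the scored network for graph viewers, with s and g_rel attached."""
    import networkx as nx

    grel = visit.as_dict("g_rel")
    g = nx.Graph()
    for gene in net.nodes:
        g.add_node(gene, g_rel=float(grel.get(gene, float("nan"))))
    for row in ef.table.itertuples(index=False):
        g.add_edge(row.source, row.target, itype=row.itype, s=float(row.s), e=float(row.e))
    nx.write_graphml(g, path)
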