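"""Subnetwork extraction, multi-condition clustering, and robustness designs.

The walk produces a full distribution of normalized Edge Flux scores rather
than a single network, so subnetworks are extracted at any cutoff (top-k,
bottom-k, or a score threshold), conditions are compared by clustering the
edges-by-conditions score matrix (Ward's method), and the method's
sensitivity to its two inputs — the data and the network — is quantified by
seeded perturbation experiments.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.stats import spearmanr

from .flux import EdgeFluxTable, run_netwalk
from .graph_model import DataVector, Edge, InteractionNetwork
from .walk import WalkConfig, run_walk

logger = logging.getLogger(__name__)

_RULES = ("top_k", "bottom_k", "s_ge", "s_le")


@dataclass(frozen=True)
class Subnetwork:
    """Edge subset of a flux table with its induced nodes and extraction rule."""

    edges: pd.DataFrame
    rule: str
    value: float

    @property
    def nodes(self) -> frozenset:
        return frozenset(self.edges["source"]) | frozenset(self.edges["target"])

    def __len__(self) -> int:
        return len(self.edges)


def extract_subnetwork(ef: EdgeFluxTable, rule: str, value: float) -> Subnetwork:
    """Select edges by score rank or threshold, deterministically.

    ``top_k``/``bottom_k`` take the k highest/lowest s; ties at the boundary
    are broken by lexicographic (source, target, itype) order and logged.
    ``s_ge``/``s_le`` keep all edges at or beyond the threshold.
    """
    if rule not in _RULES:
        raise ValueError(f"unknown extraction rule {rule!r}; expected one of {_RULES}")
    if len(ef) == 0:
        raise ValueError("cannot extract from an empty edge-flux table")
    if rule in ("top_k", "bottom_k"):
        k = int(value)
        if k > len(ef):
            warnings.warn(
                f"requested k={k} exceeds the {len(ef)} available edges; returning all",
                stacklevel=2,
            )
            k = len(ef)
        ordered = ef.sorted_by_score(ascending=(rule == "bottom_k"))
        if k < len(ordered) and k > 0 and ordered["s"].iloc[k - 1] == ordered["s"].iloc[k]:
            logger.info("tie at the rank-%d boundary broken lexicographically", k)
        chosen = ordered.iloc[:k]
    elif rule == "s_ge":
        chosen = ef.sorted_by_score(ascending=False)
        chosen = chosen[chosen["s"] >= value]
    else:
        chosen = ef.sorted_by_score(ascending=True)
        chosen = chosen[chosen["s"] <= value]
    return Subnetwork(edges=chosen.reset_index(drop=True), rule=rule, value=float(value))


def coherence_report(sub: Subnetwork, w: DataVector) -> dict:
    """Distribution of data values over a subnetwork's nodes.

    The boxplot statistics used to judge whether an extracted network is
    coherently up- (median above 1) or down-regulated; no verdict is applied.
    """
    nodes = sorted(sub.nodes)
    if not nodes:
        return {"n_nodes": 0}
    vals = np.array([w.values.get(g, 1.0) for g in nodes])
    q1, med, q3 = np.percentile(vals, [25, 50, 75])
    return {
        "n_nodes": len(nodes),
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "frac_above_1": float(np.mean(vals > 1.0)),
        "frac_below_1": float(np.mean(vals < 1.0)),
    }


# ---------------------------------------------------------------------------
# Multi-condition comparison


def build_ef_matrix(runs: Sequence[tuple[str, EdgeFluxTable]]) -> pd.DataFrame:
    """Edges x conditions matrix of normalized scores.

    Rows are indexed by (source, target, itype); every run must cover the
    identical edge set (all runs on the same network score all edges).
    """
    if not runs:
        raise ValueError("no runs supplied")
    columns = {}
    ref_index = None
    for cond, ef in runs:
        t = ef.table.set_index(["source", "target", "itype"])
        idx = t.index
        if ref_index is None:
            ref_index = idx
        elif set(idx) != set(ref_index):
            raise ValueError(f"condition {cond!r} scores a different edge set")
        columns[cond] = t["s"].reindex(ref_index)
    return pd.DataFrame(columns)


@dataclass(frozen=True)
class EFClustering:
    """Ward clustering of selected edges across conditions."""

    matrix: pd.DataFrame  # selected edges x conditions
    linkage: np.ndarray
    labels: pd.Series  # cluster id per selected edge

    def cut(self, n_clusters: int) -> pd.Series:
        lab = sch.fcluster(self.linkage, t=n_clusters, criterion="maxclust")
        return pd.Series(lab, index=self.matrix.index, name="cluster")


def select_extreme_edges(efm: pd.DataFrame, k: int, include_bottom: bool = True) -> pd.DataFrame:
    """Union over conditions of each condition's k highest (and lowest) edges."""
    if k >= len(efm):
        warnings.warn("k is not smaller than the edge count; using all edges", stacklevel=2)
        return efm
    chosen: set = set()
    for cond in efm.columns:
        order = efm[cond].sort_values(kind="mergesort")
        chosen.update(order.index[-k:])
        if include_bottom:
            chosen.update(order.index[:k])
    return efm.loc[sorted(chosen)]


def cluster_ef(
    efm: pd.DataFrame, k: int, n_clusters: int = 2, include_bottom: bool = True
) -> EFClustering:
    """Ward-linkage clustering of the per-condition extreme edges.

    Rows are the union over conditions of each condition's k highest- and
    lowest-scoring edges; linkage is Ward on Euclidean distances of the raw
    score profiles (no standardization).  Deterministic given the matrix.
    """
    if efm.shape[1] < 2:
        raise ValueError("clustering needs at least 2 conditions")
    sel = select_extreme_edges(efm, k, include_bottom=include_bottom)
    if len(sel) < 2:
        raise ValueError("need at least 2 selected edges to cluster")
    values = sel.to_numpy()
    if np.allclose(values, values.flat[0]):
        warnings.warn("degenerate all-equal score matrix: single cluster", stacklevel=2)
        labels = pd.Series(1, index=sel.index, name="cluster")
        link = sch.linkage(values, method="ward")
        return EFClustering(matrix=sel, linkage=link, labels=labels)
    link = sch.linkage(values, method="ward")
    clustering = EFClustering(matrix=sel, linkage=link, labels=pd.Series(dtype=int))
    labels = clustering.cut(n_clusters)
    return EFClustering(matrix=sel, linkage=link, labels=labels)


# ---------------------------------------------------------------------------
# Robustness experiments

_KINDS = ("data_deletion", "node_deletion", "edge_deletion", "edge_addition", "expansion_factor")


def expansion_transform(w: DataVector, f: float) -> DataVector:
    """Re-expand log2 ratios with factor f: sigma_i = f ** log2(w_i).

    f = 2 reproduces the input; f < 2 compresses the dynamic range and f > 2
    stretches it, leaving the rank order of values untouched.
    """
    if f <= 1.0:
        raise ValueError("expansion factor must exceed 1")
    return w.with_values({g: float(f ** np.log2(v)) for g, v in w.values.items()})


def _topk_nodes(net: InteractionNetwork, w: DataVector, config: WalkConfig, k: int) -> frozenset:
    _, ef = run_netwalk(net, w, config)
    top = extract_subnetwork(ef, "top_k", k)
    return top.nodes


def robustness_experiment(
    net: InteractionNetwork,
    w: DataVector,
    config: WalkConfig,
    kind: str,
    levels: Iterable[float],
    n_reps: int = 5,
    seed: int = 0,
    top_k: int = 100,
) -> pd.DataFrame:
    """Perturb the data or the network, rerun the walk, measure agreement.

    kinds:
      data_deletion    reset a fraction of data values to 1 (missing)
      node_deletion    delete a fraction of nodes
      edge_deletion    delete a fraction of edges
      edge_addition    add that fraction of random new undirected edges
      expansion_factor re-expand log-ratios with factor f (levels are f)

    The metric is the Spearman correlation of relative visitation with the
    unperturbed run over the nodes present in both; for expansion_factor it
    is the node-overlap fraction of the top-``top_k``-edge networks, the
    quantity the original robustness analysis reports.  Every replicate is
    seeded from (seed, kind, level index, rep) so the table is reproducible.
    """
    if kind not in _KINDS:
        raise ValueError(f"unknown perturbation kind {kind!r}; expected one of {_KINDS}")
    levels = list(levels)
    for lv in levels:
        if kind == "expansion_factor":
            if lv <= 1.0:
                raise ValueError(f"expansion factor must be > 1, got {lv}")
        elif not 0.0 <= lv <= 1.0:
            raise ValueError(f"perturbation fraction must be in [0, 1], got {lv}")

    base_visit = run_walk(net, w, config)
    base_rel = pd.Series(base_visit.g_rel, index=base_visit.nodes)
    if kind == "expansion_factor":
        base_top = _topk_nodes(net, w, config, top_k)

    kind_id = _KINDS.index(kind)
    records = []
    for li, level in enumerate(levels):
        for rep in range(n_reps):
            rng = np.random.default_rng(np.random.SeedSequence([seed, kind_id, li, rep]))
            if kind == "expansion_factor":
                if level == 2.0:
                    metric = 1.0
                else:
                    top = _topk_nodes(net, expansion_transform(w, level), config, top_k)
                    metric = len(top & base_top) / max(len(base_top), 1)
                records.append((level, rep, metric))
                continue
            if level == 0.0:
                records.append((level, rep, 1.0))
                continue
            if kind == "data_deletion":
                genes = sorted(w.values)
                n_del = int(round(level * len(genes)))
                drop = rng.choice(len(genes), size=n_del, replace=False)
                kept = {
                    g: v for i, (g, v) in enumerate(sorted(w.values.items())) if i not in set(drop)
                }
                visit = run_walk(net, w.with_values(kept), config)
                pert = pd.Series(visit.g_rel, index=visit.nodes)
            elif kind == "node_deletion":
                n_del = int(round(level * net.n))
                drop = rng.choice(net.n, size=n_del, replace=False)
                sub = net.remove_nodes(net.nodes[i] for i in drop)
                if sub.n < 3:
                    raise ValueError("perturbation removed essentially the whole network")
                visit = run_walk(sub, w, config)
                pert = pd.Series(visit.g_rel, index=visit.nodes)
            elif kind == "edge_deletion":
                keys = [e.key for e in net.edges]
                n_del = int(round(level * len(keys)))
                drop_i = rng.choice(len(keys), size=n_del, replace=False)
                sub = net.remove_edges(keys[i] for i in drop_i)
                visit = run_walk(sub, w, config)
                pert = pd.Series(visit.g_rel, index=visit.nodes)
            else:  # edge_addition
                n_add = int(round(level * len(net.edges)))
                existing = {(e.canonical().source, e.canonical().target) for e in net.edges}
                new: list[Edge] = []
                while len(new) < n_add:
                    a, b = rng.choice(net.n, size=2, replace=False)
                    pair = tuple(sorted((net.nodes[int(a)], net.nodes[int(b)])))
                    if pair not in existing:
                        existing.add(pair)
                        new.append(Edge(pair[0], pair[1], directed=False, itype="PPI"))
                visit = run_walk(net.add_edges(new), w, config)
                pert = pd.Series(visit.g_rel, index=visit.nodes)
            common = base_rel.index.intersection(pert.index)
            rho = spearmanr(base_rel.loc[common], pert.loc[common]).statistic
            records.append((level, rep, float(rho)))
    return pd.DataFrame(records, columns=["level", "rep", "metric"])
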