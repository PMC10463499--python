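"""Co-occurrence network, module structure, and Zi/Pi keystone taxa.

Core genera are those detected in 100% of samples.  The network is built
from all-pairs Spearman correlations of CLR-transformed genus abundances
(after removing very rare and low-summed-abundance genera), keeping edges
with |r| > 0.6 and Benjamini-Hochberg adjusted p < 0.05.  Modules come from
deterministic greedy modularity maximisation (Clauset-Newman-Moore; seeded
Louvain behind a flag).  Nodes are then classified by within-module
connectivity (Zi) and among-module connectivity (Pi) into peripheral nodes,
connectors, module hubs and network hubs; every non-peripheral class is
flagged keystone.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import AbundanceTable
from .features import clr_transform

logger = logging.getLogger("rumenlink")

ZI_THRESHOLD = 2.5
PI_THRESHOLD = 0.62


def core_taxa(table: AbundanceTable) -> list:
    """Taxa with prevalence exactly 1.0 (detected in every sample)."""
    prev = table.prevalence()
    return [t for t, p in zip(table.taxon_ids, prev) if p == 1.0]


@dataclass
class CooccurrenceNetwork:
    graph: nx.Graph
    edges: pd.DataFrame                     # taxon_i, taxon_j, r, p, p_adj
    modules: dict = field(default_factory=dict)   # node -> module id
    modularity: float | None = None

    @property
    def nodes(self):
        return list(self.graph.nodes)


def _spearman_exact_p(x: np.ndarray, y: np.ndarray, r_obs: float) -> float:
    """Two-sided exact permutation p for Spearman's r at tiny n."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    n = len(x)
    total = math.factorial(n)
    count = 0
    abs_obs = abs(r_obs) - 1e-12
    for perm in itertools.permutations(range(n)):
        r = np.corrcoef(rx, ry[list(perm)])[0, 1]
        if abs(r) >= abs_obs:
            count += 1
    return count / total


def build_network(table: AbundanceTable, min_summed_abund: float = 1e-4,
                  min_prev: float = 0.015, r_threshold: float = 0.6,
                  alpha: float = 0.05, clr_pseudocount: float = 1e-6,
                  exact_below: int = 10) -> CooccurrenceNetwork:
    """All-pairs Spearman co-occurrence network on CLR values.

    Prefilter: genera with summed relative abundance < min_summed_abund or
    prevalence < min_prev are excluded.  BH adjustment runs over every tested
    pair; an edge is kept iff |r| > r_threshold AND p_adj < alpha.  Spearman
    p-values use the tie-corrected t approximation, or exact permutation
    enumeration when n_samples < exact_below.
    """
    if table.n_samples < 3:
        raise ValueError("need at least 3 samples to build a network")
    keep = (table.values.sum(axis=0) >= min_summed_abund) & (
        table.prevalence() >= min_prev
    )
    sub = table.take_taxa(np.flatnonzero(keep))
    if sub.n_taxa < 3:
        raise ValueError("fewer than 3 taxa survive the network prefilter")
    clr = clr_transform(sub, pseudocount=clr_pseudocount)
    t = sub.n_taxa
    rmat, pmat = stats.spearmanr(clr)
    rmat = np.atleast_2d(rmat)
    pairs = list(itertools.combinations(range(t), 2))
    rs = np.array([rmat[i, j] for i, j in pairs])
    if table.n_samples < exact_below:
        ps = np.array(
            [_spearman_exact_p(clr[:, i], clr[:, j], rmat[i, j]) for i, j in pairs]
        )
    else:
        ps = np.array([pmat[i, j] for i, j in pairs])
    _, p_adj, *_ = multipletests(ps, method="fdr_bh")
    edge_mask = (np.abs(rs) > r_threshold) & (p_adj < alpha) & np.isfinite(rs)
    edges = pd.DataFrame(
        {
            "taxon_i": [sub.taxon_ids[i] for (i, j), m in zip(pairs, edge_mask) if m],
            "taxon_j": [sub.taxon_ids[j] for (i, j), m in zip(pairs, edge_mask) if m],
            "r": rs[edge_mask],
            "p": ps[edge_mask],
            "p_adj": p_adj[edge_mask],
        }
    )
    g = nx.Graph()
    g.add_nodes_from(sub.taxon_ids)
    for _, e in edges.iterrows():
        g.add_edge(e["taxon_i"], e["taxon_j"], r=e["r"], p=e["p"], p_adj=e["p_adj"])
    return CooccurrenceNetwork(graph=g, edges=edges)


def detect_modules(net: CooccurrenceNetwork, method: str = "greedy",
                   seed: int = 0) -> CooccurrenceNetwork:
    """Assign modules by greedy (CNM) modularity maximisation (deterministic)
    or seeded Louvain; isolated nodes become their own modules."""
    g = net.graph
    if g.number_of_edges() == 0:
        raise ValueError("cannot detect modules in a network without edges")
    if method == "greedy":
        comms = nx.community.greedy_modularity_communities(g)
    elif method == "louvain":
        comms = nx.community.louvain_communities(g, seed=seed)
    else:
        raise ValueError(f"unknown module-detection method {method!r}")
    comms = [set(c) for c in comms]
    net.modules = {}
    for mid, comm in enumerate(sorted(comms, key=lambda c: sorted(c)[0])):
        for node in comm:
            net.modules[node] = mid
    net.modularity = nx.community.modularity(g, comms)
    return net


def classify_node(zi: float, pi: float) -> str:
    """Four-way Zi/Pi classification; boundary values fall to the lower
    class (strict inequalities)."""
    if zi > ZI_THRESHOLD and pi > PI_THRESHOLD:
        return "network_hub"
    if zi > ZI_THRESHOLD:
        return "module_hub"
    if pi > PI_THRESHOLD:
        return "connector"
    return "peripheral"


def zi_pi(net: CooccurrenceNetwork) -> pd.DataFrame:
    """Within-module (Zi) and among-module (Pi) connectivity per node.

    Zi = (k_within - mean_module) / sd_module (0 when sd is 0);
    Pi = 1 - sum_m (k_m / k)^2.  Classification boxes (strict inequalities):
    peripheral (Zi < 2.5, Pi < 0.62), connector (Zi < 2.5, Pi > 0.62),
    module hub (Zi > 2.5, Pi < 0.62), network hub (Zi > 2.5, Pi > 0.62);
    boundary values fall to the lower class.  Isolated nodes are peripheral
    with Zi = Pi = 0.
    """
    if not net.modules:
        raise ValueError("run detect_modules before zi_pi")
    g = net.graph
    modules = net.modules
    k_within = {}
    for node in g.nodes:
        k_within[node] = sum(
            1 for nb in g.neighbors(node) if modules[nb] == modules[node]
        )
    by_module: dict = {}
    for node, mid in modules.items():
        by_module.setdefault(mid, []).append(node)
    rows = []
    for node in g.nodes:
        mid = modules[node]
        deg = g.degree(node)
        members = by_module[mid]
        kw = np.array([k_within[m] for m in members], dtype=float)
        sd = kw.std()  # population SD over module members
        zi = (k_within[node] - kw.mean()) / sd if sd > 0 else 0.0
        if deg == 0:
            pi = 0.0
        else:
            k_by_mod: dict = {}
            for nb in g.neighbors(node):
                k_by_mod[modules[nb]] = k_by_mod.get(modules[nb], 0) + 1
            pi = 1.0 - sum((k / deg) ** 2 for k in k_by_mod.values())
        node_class = classify_node(zi, pi)
        rows.append(
            {
                "taxon": node,
                "module": mid,
                "degree": deg,
                "Zi": zi,
                "Pi": pi,
                "node_class": node_class,
                "keystone": node_class != "peripheral",
            }
        )
    return pd.DataFrame(rows)
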