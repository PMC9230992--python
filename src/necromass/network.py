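"""OTU-soil-variable association networks and keystone-taxon detection.

Edges are Pearson correlations between node series (OTU relative
abundances after rarefaction, and soil variables such as SOC, TN and the
residue pools), retained when p < 0.05 and |rho| > 0.5 (both configurable).
Node importance is summarised by degree, degree centrality, closeness
centrality (Wasserman-Faust component-scaled, so disconnected thresholded
networks are handled sensibly) and betweenness centrality; the keystone
taxon is the OTU node simultaneously maximal in closeness, betweenness and
degree centrality, with a rank-score fallback when the three maxima
disagree.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .ecology import CountTable, _as_frame

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class NetworkSpec:
    """Edge and node selection rules for the association network."""

    top_k: int = 500
    rho_threshold: float = 0.5
    p_threshold: float = 0.05
    multiple_testing: str = "none"  # "none" (raw p, default) or "bh"
    include_otu_otu: bool = True
    log_transform: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.rho_threshold < 1:
            raise ValueError("rho_threshold must be in (0, 1)")
        if not 0 < self.p_threshold < 1:
            raise ValueError("p_threshold must be in (0, 1)")
        if self.multiple_testing not in ("none", "bh"):
            raise ValueError("multiple_testing must be 'none' or 'bh'")


@dataclass
class AssociationNetwork:
    """Undirected correlation network over OTU and soil-variable nodes."""

    graph: nx.Graph
    spec: NetworkSpec
    excluded: list[str] = field(default_factory=list)  # zero-variance series

    @property
    def otu_nodes(self) -> list[str]:
        return [n for n, k in self.graph.nodes(data="kind") if k == "OTU"]

    @property
    def variable_nodes(self) -> list[str]:
        return [n for n, k in self.graph.nodes(data="kind") if k == "variable"]


def select_top_otus(table: CountTable | pd.DataFrame, k: int) -> pd.DataFrame:
    """Keep the k most abundant OTUs (total reads across samples).

    Ties at the cutoff are broken lexicographically by OTU id (smaller id
    kept), so selection is deterministic.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    counts = _as_frame(table)
    if counts.empty:
        raise ValueError("empty count table")
    totals = counts.sum(axis=1)
    order = sorted(counts.index, key=lambda o: (-totals[o], str(o)))
    return counts.loc[order[: min(k, len(order))]]


def _pearson_matrix(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pearson rho and two-sided p (t distribution, n-2 df) for all column pairs."""
    n = x.shape[0]
    if n < 4:
        raise ValueError("need at least 4 samples for correlation p-values")
    rho = np.corrcoef(x, rowvar=False)
    rho = np.clip(rho, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * stats.t.sf(np.abs(t), n - 2)
    p = np.where(np.isclose(np.abs(rho), 1.0), 0.0, p)
    return rho, p


def build_network(
    otus: pd.DataFrame,
    variables: pd.DataFrame,
    spec: NetworkSpec | None = None,
    taxonomy: pd.DataFrame | None = None,
) -> AssociationNetwork:
    """Correlation network over OTU relative abundances and soil variables.

    ``otus``: samples x OTUs relative abundances; ``variables``: samples x
    numeric soil variables, sharing the same sample index.  All OTU-variable
    and variable-variable pairs are tested; OTU-OTU pairs too unless
    ``spec.include_otu_otu`` is off.  Zero-variance series are excluded from
    pairing with a logged note.
    """
    spec = spec or NetworkSpec()
    if not otus.index.equals(variables.index):
        raise ValueError("otus and variables must share the same sample index")
    data = pd.concat([otus, variables], axis=1)
    if data.columns.has_duplicates:
        dup = data.columns[data.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicate node names: {dup}")
    if spec.log_transform:
        otu_part = data[otus.columns]
        data[otus.columns] = np.log(otu_part + otu_part[otu_part > 0].min().min() / 2)
    kinds = {c: "OTU" for c in otus.columns} | {c: "variable" for c in variables.columns}

    sd = data.std(axis=0, ddof=1)
    excluded = sd.index[~(sd > 0)].tolist()
    if excluded:
        logger.info("build_network: excluding zero-variance series: %s", excluded)
        data = data.drop(columns=excluded)

    cols = list(data.columns)
    rho, p = _pearson_matrix(data.to_numpy(float))
    iu = np.triu_indices(len(cols), k=1)
    if spec.multiple_testing == "bh":
        flat = p[iu].copy()
        adj = stats.false_discovery_control(flat, method="bh")
        p = p.copy()
        p[iu] = adj
        p.T[iu] = adj

    g = nx.Graph()
    totals = otus.sum(axis=0)
    for c in cols + excluded:
        attrs = {"kind": kinds[c]}
        if kinds[c] == "OTU":
            attrs["total_abundance"] = float(totals.get(c, 0.0))
            if taxonomy is not None and c in taxonomy.index:
                attrs["taxonomy"] = ";".join(str(v) for v in taxonomy.loc[c])
        g.add_node(c, **attrs)
    for i, j in zip(*iu):
        ci, cj = cols[i], cols[j]
        if kinds[ci] == "OTU" and kinds[cj] == "OTU" and not spec.include_otu_otu:
            continue
        r, pv = float(rho[i, j]), float(p[i, j])
        if pv < spec.p_threshold and abs(r) > spec.rho_threshold:
            g.add_edge(ci, cj, rho=r, p=pv, sign=1 if r > 0 else -1)
    return AssociationNetwork(graph=g, spec=spec, excluded=excluded)


def centralities(net: AssociationNetwork | nx.Graph) -> pd.DataFrame:
    """Degree, degree centrality, closeness and betweenness per node.

    Closeness uses Wasserman-Faust component-size scaling; betweenness is
    normalized shortest-path betweenness on the unweighted graph.  Isolated
    nodes get closeness 0 by convention.
    """
    g = net.graph if isinstance(net, AssociationNetwork) else net
    if g.number_of_nodes() < 2:
        raise ValueError("network must have at least 2 nodes")
    deg = dict(g.degree())
    out = pd.DataFrame(
        {
            "degree": pd.Series(deg, dtype=float),
            "degree_centrality": pd.Series(nx.degree_centrality(g)),
            "closeness": pd.Series(nx.closeness_centrality(g, wf_improved=True)),
            "betweenness": pd.Series(nx.betweenness_centrality(g, normalized=True)),
        }
    )
    out["kind"] = pd.Series(dict(g.nodes(data="kind"))).fillna("OTU")
    return out.sort_index()


@dataclass
class KeystoneReport:
    """Keystone identification outcome and the rule that produced it."""

    keystones: list[str]
    rule: str  # "strict" (triple maximum) or "fallback" (mean normalized score)
    scores: pd.DataFrame  # per OTU candidate: the three centralities (+ score)


def identify_keystones(cent: pd.DataFrame) -> KeystoneReport:
    """Identify keystone OTU(s) from a centrality table.

    Strict rule: OTU node(s) simultaneously maximal in closeness,
    betweenness and degree centrality.  When the three maxima fall on
    different nodes, a logged fallback picks the OTU with the best mean
    min-max-normalized score across the three measures (lexicographic tie
    break).  Variable nodes are anchors, never keystone candidates.
    """
    if cent.empty:
        raise ValueError("empty centrality table")
    otus = cent[cent["kind"] == "OTU"]
    if otus.empty:
        raise ValueError("network has no OTU nodes")
    measures = ["closeness", "betweenness", "degree_centrality"]
    maximal = None
    for m in measures:
        top = set(otus.index[np.isclose(otus[m], otus[m].max())])
        maximal = top if maximal is None else (maximal & top)
    if maximal:
        keys = sorted(maximal)
        return KeystoneReport(keystones=keys, rule="strict", scores=otus[measures].copy())
    logger.info("identify_keystones: no triple-maximal node; using rank-score fallback")
    norm = otus[measures].copy()
    for m in measures:
        rng_ = otus[m].max() - otus[m].min()
        norm[m] = 0.0 if rng_ == 0 else (otus[m] - otus[m].min()) / rng_
    score = norm.mean(axis=1)
    best = score.max()
    keys = sorted(score.index[np.isclose(score, best)])[:1]
    scores = otus[measures].copy()
    scores["score"] = score
    return KeystoneReport(keystones=keys, rule="fallback", scores=scores)


def export_network(
    net: AssociationNetwork,
    cent: pd.DataFrame | None,
    graphml_path: str,
    edges_csv_path: str,
) -> None:
    """Write the network as GraphML (with centrality node attributes) and a
    flat edge-list CSV (node pair, rho, p, sign)."""
    g = net.graph.copy()
    if cent is not None:
        for node in g.nodes:
            if node in cent.index:
                for m in ("degree", "degree_centrality", "closeness", "betweenness"):
                    g.nodes[node][m] = float(cent.loc[node, m])
    nx.write_graphml(g, graphml_path)
    rows = [
        {"node1": u, "node2": v, "rho": d["rho"], "p": d["p"], "sign": d["sign"]}
        for u, v, d in g.edges(data=True)
    ]
    pd.DataFrame(rows, columns=["node1", "node2", "rho", "p", "sign"]).to_csv(
        edges_csv_path, index=False
    )
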