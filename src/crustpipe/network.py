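"""Co-occurrence network inference from ASV tables.

Pipeline: combine rare features (< 0.1% mean relative abundance by
default) into an OTHER bin, compute tie-corrected pairwise Spearman
correlations across samples, BH-FDR-adjust the two-sided p values over
all candidate pairs, keep pairs with |rho| at or above the correlation
threshold and adjusted p below the FDR level (optionally also a
presence/absence co-occurrence criterion), and report the resulting
signed undirected graph with the six standard summary properties: edge
count, node count, percentage of positive links, average clustering
coefficient, density and average degree.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps

OTHER_LABEL = "OTHER"


class NetworkError(ValueError):
    pass


@dataclass(frozen=True)
class NetworkConfig:
    """Thresholds of the co-occurrence filter chain.

    min_rel_abundance : features below this overall mean relative
        abundance are combined into the OTHER bin (default 0.1%).
    r_threshold : minimum |Spearman rho| for an edge (default 0.6).
    alpha_fdr : BH-adjusted p cutoff (default 0.05).
    min_copresence : minimum number of samples where both features are
        present (0 disables the filter).
    jaccard_max_distance : optional maximum Jaccard distance between the
        presence/absence profiles of a pair (None disables).
    """

    min_rel_abundance: float = 0.001
    r_threshold: float = 0.6
    alpha_fdr: float = 0.05
    min_copresence: int = 0
    jaccard_max_distance: float | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.min_rel_abundance < 1:
            raise NetworkError("min_rel_abundance must be in [0, 1)")
        if not 0 < self.alpha_fdr < 1:
            raise NetworkError("alpha_fdr must be in (0, 1)")
        if self.min_copresence < 0:
            raise NetworkError("min_copresence must be >= 0")
        if self.jaccard_max_distance is not None and not (
            0 <= self.jaccard_max_distance <= 1
        ):
            raise NetworkError("jaccard_max_distance must be in [0, 1]")


@dataclass
class CoocNetwork:
    """Signed weighted undirected co-occurrence graph.

    Nodes carry ``abundance`` (mean relative abundance), edges carry
    ``rho``, ``p``, ``p_adj``, ``sign`` ("positive"/"negative") and
    ``weight`` = rho.  Isolated features never enter the graph.
    """

    graph: nx.Graph
    group: str = ""

    def edges_frame(self) -> pd.DataFrame:
        rows = [
            {
                "source": u,
                "target": v,
                "rho": d["rho"],
                "p": d["p"],
                "p_adj": d["p_adj"],
                "sign": d["sign"],
            }
            for u, v, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(
            rows, columns=["source", "target", "rho", "p", "p_adj", "sign"]
        )


@dataclass
class NetworkProperties:
    n_edges: int
    n_nodes: int
    pct_positive: float
    avg_clustering: float
    density: float
    avg_degree: float

    def as_series(self) -> pd.Series:
        return pd.Series(
            {
                "Edge": self.n_edges,
                "Node": self.n_nodes,
                "Percentage of positive links": self.pct_positive,
                "Average clustering coefficient": self.avg_clustering,
                "Density": self.density,
                "Average degree": self.avg_degree,
            }
        )


def relative_abundance(table: pd.DataFrame) -> pd.DataFrame:
    totals = table.sum(axis=0)
    if (totals <= 0).any():
        raise NetworkError("all samples must have positive totals")
    return table / totals


def combine_rare_features(
    table: pd.DataFrame, min_rel_abundance: float = 0.001
) -> pd.DataFrame:
    """Sum features under the mean-relative-abundance cutoff into OTHER.

    The OTHER row keeps column sums intact (features are combined, not
    discarded) but is excluded from network node candidacy downstream.
    """
    if not 0 <= min_rel_abundance < 1:
        raise NetworkError("min_rel_abundance must be in [0, 1)")
    if min_rel_abundance == 0:
        return table
    mean_rel = relative_abundance(table).mean(axis=1)
    rare = mean_rel < min_rel_abundance
    if not rare.any():
        return table
    kept = table.loc[~rare]
    other = table.loc[rare].sum(axis=0).rename(OTHER_LABEL)
    return pd.concat([kept, other.to_frame().T])


def spearman_matrix(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise tie-corrected Spearman rho and two-sided p per feature pair.

    p values use the standard t approximation with n - 2 degrees of
    freedom.  Constant features are dropped with a warning; fewer than 4
    samples is an error.
    """
    n = table.shape[1]
    if n < 4:
        raise NetworkError("Spearman network needs at least 4 samples")
    x = table.to_numpy(dtype=float)
    constant = np.ptp(x, axis=1) == 0
    if constant.any():
        warnings.warn(
            f"dropping {int(constant.sum())} constant feature(s) from correlation"
        )
        table = table.loc[~constant]
        x = x[~constant]
    ranks = sps.rankdata(x, axis=1)
    rho = np.corrcoef(ranks)
    np.fill_diagonal(rho, 1.0)
    rho = np.clip(rho, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * sps.t.sf(np.abs(t), df=n - 2)
    p[np.isnan(t) | np.isinf(t)] = 0.0  # |rho| == 1
    np.fill_diagonal(p, 0.0)
    ids = table.index
    return (
        pd.DataFrame(rho, index=ids, columns=ids),
        pd.DataFrame(p, index=ids, columns=ids),
    )


def build_network(
    table: pd.DataFrame, config: NetworkConfig | None = None, group: str = ""
) -> CoocNetwork:
    """Abundance filter -> Spearman -> BH-FDR -> thresholds -> graph.

    FDR adjustment runs over all candidate pairs before any rho
    thresholding.  Features that end up with no edge are not nodes.  An
    empty result is returned (with a warning), not raised.
    """
    if config is None:
        config = NetworkConfig()
    combined = combine_rare_features(table, config.min_rel_abundance)
    candidates = combined.drop(index=OTHER_LABEL, errors="ignore")
    mean_rel = relative_abundance(table).mean(axis=1)

    # correlate relative abundances: raw counts track sequencing depth,
    # which would correlate every feature with every other
    rho, p = spearman_matrix(relative_abundance(combined).loc[candidates.index])
    ids = rho.index.to_list()
    iu, ju = np.triu_indices(len(ids), k=1)
    rho_v = rho.to_numpy()[iu, ju]
    p_v = p.to_numpy()[iu, ju]
    from crustpipe.stats import bh_fdr

    p_adj = bh_fdr(p_v)
    keep = (np.abs(rho_v) >= config.r_threshold) & (p_adj < config.alpha_fdr)

    if config.min_copresence > 0 or config.jaccard_max_distance is not None:
        present = candidates.to_numpy() > 0
        both = present @ present.T
        either = present.sum(axis=1)[:, None] + present.sum(axis=1)[None, :] - both
        if config.min_copresence > 0:
            keep &= both[iu, ju] >= config.min_copresence
        if config.jaccard_max_distance is not None:
            with np.errstate(invalid="ignore"):
                jac_d = 1.0 - both / np.where(either == 0, 1, either)
            keep &= jac_d[iu, ju] <= config.jaccard_max_distance

    g = nx.Graph()
    for k in np.where(keep)[0]:
        a, b = ids[iu[k]], ids[ju[k]]
        r = float(rho_v[k])
        g.add_edge(
            a,
            b,
            rho=r,
            p=float(p_v[k]),
            p_adj=float(p_adj[k]),
            sign="positive" if r > 0 else "negative",
            weight=r,
        )
    for node in g.nodes:
        g.nodes[node]["abundance"] = float(mean_rel.get(node, 0.0))
    if g.number_of_edges() == 0:
        warnings.warn("no feature pair passed the network thresholds")
    return CoocNetwork(graph=g, group=group)


def network_properties(net: CoocNetwork | nx.Graph) -> NetworkProperties:
    """The six summary properties of a co-occurrence network.

    Density = 2E / (N(N-1)), average degree = 2E / N, percentage of
    positive links = 100 * (#rho > 0) / E, clustering = unweighted local
    clustering averaged over nodes (degree-1 nodes count 0).
    """
    g = net.graph if isinstance(net, CoocNetwork) else net
    n, e = g.number_of_nodes(), g.number_of_edges()
    if n < 2:
        raise NetworkError("properties undefined for fewer than 2 nodes")
    signs = [d.get("rho", 1.0) > 0 for _, _, d in g.edges(data=True)]
    pct_pos = 100.0 * sum(signs) / e if e else float("nan")
    return NetworkProperties(
        n_edges=e,
        n_nodes=n,
        pct_positive=pct_pos,
        avg_clustering=nx.average_clustering(g),
        density=nx.density(g),
        avg_degree=2.0 * e / n,
    )
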