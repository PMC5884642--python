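"""Kinome interaction networks, subnetworks and functional annotation.

Builds the union of curated kinase-kinase interaction sources restricted to
the profiled kinase universe, partitions it into subnetworks by normalized-
Laplacian spectral clustering, infers co-binding linkages by Lasso regression
of each kinase's MIB profile on all others, assembles ego "functional
subnetworks" around understudied kinases from regression linkages plus known
interactions, and scores annotation-term overrepresentation with a
hypergeometric test (Benjamini-Hochberg adjusted).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.linear_model import Lasso, LassoCV
from sklearn.model_selection import KFold
from statsmodels.stats.multitest import multipletests

from .exceptions import DegenerateDataError, FormatError, LookupMissingError, ParameterError
from .io_filter import NormalizedMatrix


# ---------------------------------------------------------------------------
# Edge lists
# ---------------------------------------------------------------------------


@dataclass
class EdgeList:
    """Undirected, deduplicated kinase-kinase edges with source tags.

    ``edges``: DataFrame [kinase_a, kinase_b, sources] with kinase_a <
    kinase_b and comma-joined sorted source tags; ``nodes``: the universe the
    edges were compiled against; ``isolated``: universe nodes with no edge.
    """

    edges: pd.DataFrame
    nodes: set[str] = field(default_factory=set)

    @property
    def isolated(self) -> set[str]:
        touched = set(self.edges["kinase_a"]) | set(self.edges["kinase_b"])
        return self.nodes - touched

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(sorted(self.nodes))
        for _, row in self.edges.iterrows():
            g.add_edge(row["kinase_a"], row["kinase_b"], sources=row["sources"])
        return g

    def to_tsv(self, path) -> None:
        self.edges.to_csv(path, sep="\t", index=False)


def read_edge_list(path, source: str | None = None) -> pd.DataFrame:
    """Read a two-column (plus optional sources) TSV edge list."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: need at least two columns")
    df = df.rename(columns={df.columns[0]: "kinase_a", df.columns[1]: "kinase_b"})
    bad = df["kinase_a"].isna() | df["kinase_b"].isna()
    if bad.any():
        raise FormatError(f"{path}: malformed pair at line {int(bad.idxmax()) + 2}")
    if "sources" not in df.columns:
        df["sources"] = source or str(path)
    return df[["kinase_a", "kinase_b", "sources"]]


def compile_union_network(
    sources: list[pd.DataFrame], universe: set[str]
) -> EdgeList:
    """Union of interaction sources restricted to the kinase universe.

    Self-loops and edges with an endpoint outside the universe are dropped;
    duplicate unordered pairs are merged with their source tags unioned.
    Universe nodes left without any edge are reported via ``EdgeList.isolated``
    (the analysis then runs on the connected 246-of-254-style core).
    """
    if not sources:
        raise ParameterError("at least one edge-list source required")
    merged: dict[tuple[str, str], set[str]] = {}
    for df in sources:
        for _, row in df.iterrows():
            a, b = row["kinase_a"], row["kinase_b"]
            if not isinstance(a, str) or not isinstance(b, str) or not a or not b:
                raise FormatError(f"malformed pair ({a!r}, {b!r})")
            if a == b or a not in universe or b not in universe:
                continue
            key = (a, b) if a < b else (b, a)
            tags = {t for t in str(row.get("sources", "")).split(",") if t}
            merged.setdefault(key, set()).update(tags)
    edges = pd.DataFrame(
        [(a, b, ",".join(sorted(t))) for (a, b), t in sorted(merged.items())],
        columns=["kinase_a", "kinase_b", "sources"],
    )
    return EdgeList(edges, nodes=set(universe))


# ---------------------------------------------------------------------------
# Spectral partitioning
# ---------------------------------------------------------------------------


@dataclass
class NetworkPartition:
    community_of: dict[str, int]
    k: int
    eigengaps: np.ndarray | None = None  # diagnostic only, never auto-applied

    def members(self, c: int) -> set[str]:
        return {n for n, cc in self.community_of.items() if cc == c}

    def sizes(self) -> pd.Series:
        return pd.Series(self.community_of).value_counts().sort_index()


def _spectral_embed_cluster(
    g: nx.Graph, k: int, seed: int
) -> dict[str, int]:
    """Cluster one connected component: normalized-Laplacian embedding into
    the k smallest eigenvectors, rows normalized, then k-means."""
    nodes = sorted(g.nodes)
    if k == 1 or len(nodes) == 1:
        return {n: 0 for n in nodes}
    A = nx.to_numpy_array(g, nodelist=nodes)
    deg = A.sum(axis=1)
    d_isqrt = 1.0 / np.sqrt(np.maximum(deg, 1e-12))
    L = np.eye(len(nodes)) - (A * d_isqrt[:, None]) * d_isqrt[None, :]
    vals, vecs = np.linalg.eigh(L)
    emb = vecs[:, :k]
    norms = np.linalg.norm(emb, axis=1, keepdims=True)
    emb = emb / np.maximum(norms, 1e-12)
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    labels = km.fit_predict(emb)
    return {n: int(c) for n, c in zip(nodes, labels)}


def spectral_partition(net: EdgeList, k: int = 16, seed: int = 0) -> NetworkPartition:
    """Partition the interaction network into ``k`` subnetworks.

    Disconnected components are handled first: each component receives a
    share of ``k`` proportional to its size (at least 1, at most its node
    count) and is clustered independently, since normalized-Laplacian
    eigenvectors are degenerate across components.  Isolated universe nodes
    are excluded from the partition (reported by ``EdgeList.isolated``).
    An eigengap diagnostic of the largest component is attached.
    """
    g = net.to_graph()
    g.remove_nodes_from(list(net.isolated))
    n_nodes = g.number_of_nodes()
    if n_nodes == 0:
        raise ParameterError("network is empty")
    if k > n_nodes:
        raise ParameterError(f"k={k} exceeds node count {n_nodes}")
    if k < 1:
        raise ParameterError("k must be >= 1")

    comps = sorted(nx.connected_components(g), key=len, reverse=True)
    # proportional allocation with minimum 1 per component (largest remainder)
    sizes = np.array([len(c) for c in comps])
    alloc = np.maximum(1, np.floor(k * sizes / sizes.sum()).astype(int))
    alloc = np.minimum(alloc, sizes)
    while alloc.sum() > k:
        i = int(np.argmax(alloc))
        alloc[i] -= 1
    while alloc.sum() < k:
        room = (alloc < sizes)
        frac = k * sizes / sizes.sum() - alloc
        frac[~room] = -np.inf
        alloc[int(np.argmax(frac))] += 1

    community_of: dict[str, int] = {}
    offset = 0
    eigengaps = None
    for ci, comp in enumerate(comps):
        sub = g.subgraph(comp)
        local = _spectral_embed_cluster(sub, int(alloc[ci]), seed)
        for n_, c_ in local.items():
            community_of[n_] = offset + c_
        offset += int(alloc[ci])
        if ci == 0 and len(comp) > 2:
            A = nx.to_numpy_array(sub, nodelist=sorted(comp))
            deg = A.sum(axis=1)
            d_isqrt = 1.0 / np.sqrt(np.maximum(deg, 1e-12))
            L = np.eye(len(comp)) - (A * d_isqrt[:, None]) * d_isqrt[None, :]
            vals = np.linalg.eigvalsh(L)
            eigengaps = np.diff(vals[: min(len(vals), 2 * k)])
    return NetworkPartition(community_of, k=k, eigengaps=eigengaps)


# ---------------------------------------------------------------------------
# Lasso linkages
# ---------------------------------------------------------------------------


@dataclass
class LassoLinkage:
    response: str
    coefficients: pd.Series  # nonzero betas, indexed by predictor kinase
    penalty: float
    seed: int

    @property
    def predictors(self) -> list[str]:
        return list(self.coefficients.index)


def lasso_linkages(
    n: NormalizedMatrix,
    response: str,
    seed: int = 0,
    cv_folds: int = 10,
) -> LassoLinkage:
    """L1-penalized regression of one kinase's profile on all others.

    Predictors are standardized; the penalty is chosen by ``cv_folds``-fold
    cross-validation minimizing mean squared error with a fixed fold seed
    (coordinate descent underneath).  Predictors with a nonzero coefficient
    at the selected penalty are the reported linkages.  Missing entries are
    filled with the per-kinase mean before fitting.
    """
    if response not in n.values.index:
        raise LookupMissingError(f"response kinase {response!r} not in matrix")
    if len(n.samples) < 5:
        raise ParameterError("need >= 5 samples for cross-validated Lasso")
    V = n.values.apply(lambda row: row.fillna(row.mean()), axis=1).fillna(0.0)
    y = V.loc[response].to_numpy(dtype=float)
    if np.std(y) == 0:
        raise DegenerateDataError(f"response {response!r} is constant")
    predictors = [k for k in V.index if k != response]
    X = V.loc[predictors].T.to_numpy(dtype=float)
    mu, sd = X.mean(axis=0), X.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    Xs = (X - mu) / sd
    yc = y - y.mean()

    folds = KFold(n_splits=min(cv_folds, len(y)), shuffle=True, random_state=seed)
    cv_model = LassoCV(cv=folds, alphas=100, max_iter=50000, tol=1e-6)
    cv_model.fit(Xs, yc)
    lam = float(cv_model.alpha_)
    beta = pd.Series(cv_model.coef_, index=predictors)
    nz = beta[beta != 0.0]
    return LassoLinkage(response, nz, penalty=lam, seed=seed)


def lasso_at_penalty(
    n: NormalizedMatrix, response: str, alpha: float
) -> LassoLinkage:
    """Lasso linkage at a fixed penalty (no cross-validation)."""
    V = n.values.apply(lambda row: row.fillna(row.mean()), axis=1).fillna(0.0)
    y = V.loc[response].to_numpy(dtype=float)
    predictors = [k for k in V.index if k != response]
    X = V.loc[predictors].T.to_numpy(dtype=float)
    mu, sd = X.mean(axis=0), X.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    model = Lasso(alpha=alpha, max_iter=50000)
    model.fit((X - mu) / sd, y - y.mean())
    beta = pd.Series(model.coef_, index=predictors)
    return LassoLinkage(response, beta[beta != 0.0], penalty=alpha, seed=-1)


# ---------------------------------------------------------------------------
# Functional ego subnetworks
# ---------------------------------------------------------------------------


@dataclass
class FunctionalSubnetwork:
    center: str
    regression_edges: list[tuple[str, str]]
    known_edges: list[tuple[str, str]]
    members: set[str]

    @property
    def n_members(self) -> int:
        return len(self.members)


def build_functional_subnetwork(
    center: str,
    all_linkages: dict[str, LassoLinkage],
    known: EdgeList,
) -> FunctionalSubnetwork:
    """Ego subnetwork around an understudied kinase.

    Regression edges connect the center to the predictors it selected and to
    every kinase that selected it in turn.  Known interactions incident to
    the center or to any regression partner are layered on top; members are
    the endpoints of both edge classes.
    """
    if center not in all_linkages:
        raise LookupMissingError(f"no linkage computed for {center!r}")
    partners = set(all_linkages[center].predictors)
    partners |= {
        resp for resp, link in all_linkages.items()
        if center in link.predictors and resp != center
    }
    regression_edges = sorted((center, p) for p in partners)

    core = {center} | partners
    known_edges = []
    for _, row in known.edges.iterrows():
        a, b = row["kinase_a"], row["kinase_b"]
        if a in core or b in core:
            known_edges.append((a, b) if a < b else (b, a))
    known_edges = sorted(set(known_edges))
    members = core | {x for e in known_edges for x in e}
    return FunctionalSubnetwork(center, regression_edges, known_edges, members)


# ---------------------------------------------------------------------------
# Enrichment
# ---------------------------------------------------------------------------


def hypergeometric_enrichment(
    members: set[str],
    annotations: pd.DataFrame,
    universe: set[str],
) -> pd.DataFrame:
    """Upper-tail hypergeometric overrepresentation of annotation terms.

    ``annotations``: long DataFrame [kinase, term].  For each term with at
    least one member in the universe, p = P(X >= overlap) under sampling
    ``len(members)`` kinases from the universe without replacement;
    Benjamini-Hochberg adjusted across terms, sorted by p (ties by term).
    """
    if not universe:
        raise ParameterError("empty universe")
    if not set(members) <= universe:
        raise ParameterError("members must be a subset of the universe")
    ann = annotations[annotations["kinase"].isin(universe)]
    M, N = len(universe), len(members)
    rows = []
    for term, grp in ann.groupby("term"):
        term_set = set(grp["kinase"])
        n_term = len(term_set)
        overlap = len(term_set & members)
        p = float(stats.hypergeom.sf(overlap - 1, M, n_term, N))
        rows.append((term, overlap, n_term, p))
    out = pd.DataFrame(rows, columns=["term", "overlap", "term_size", "p"])
    out["universe_size"] = M
    out["subnetwork_size"] = N
    out["p_adj"] = multipletests(out["p"], method="fdr_bh")[1] if len(out) else []
    return out.sort_values(["p", "term"], kind="mergesort").reset_index(drop=True)
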