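"""Seasonal co-occupancy social networks and their statistics.

The association index between two mice is a time-based Jaccard coefficient,
the *co-occupancy index* (COI):

    COI(i, j) = T_ij / (T_i + T_j - T_ij)

where T_ij is the pair's total meeting time within the season and T_i, T_j
their total in-box times.  COI is symmetric, lies in [0, 1], equals 1 only
for identical stay sets and 0 for mice that never meet.  Networks are
undirected with COI edge weights; community structure is found by Louvain
modularity maximization, compared against degree-preserving randomized nulls,
and summarised by small-world coefficients, node metrics, and the spatial
decay of box sharing with distance.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.optimize import curve_fit


@dataclass
class CoiMatrix:
    """Pairwise co-occupancy indices for one season window."""

    window: tuple[float, float]
    pairs: pd.DataFrame          # mouse_a, mouse_b, overlap, coi
    box_time: pd.Series          # per-mouse total in-box seconds
    sex: dict[str, str] = field(default_factory=dict)

    def value(self, a: str, b: str) -> float:
        a, b = sorted((a, b))
        hit = self.pairs[(self.pairs["mouse_a"] == a)
                         & (self.pairs["mouse_b"] == b)]
        return float(hit["coi"].iloc[0]) if len(hit) else 0.0


@dataclass
class SmallWorldResult:
    sigma: float
    C: float
    L: float
    C_rand: float
    L_rand: float
    n_random: int


@dataclass
class DecayFit:
    a: float
    b: float
    rss: float

    def predict(self, x):
        return self.a * np.exp(-self.b * np.asarray(x, dtype=float))


def _clip_total(entries, exits, lo, hi):
    return float(np.clip(np.minimum(exits, hi) - np.maximum(entries, lo),
                         0.0, None).sum())


def compute_coi(meetings: pd.DataFrame, stays: pd.DataFrame,
                window: tuple[float, float]) -> CoiMatrix:
    """Co-occupancy index matrix restricted to one season window.

    Stays and meetings are clipped to the half-open window before computing
    totals; pairs whose combined box time is zero are omitted.
    """
    lo, hi = window
    box_time = {}
    sex = {}
    for mouse, sub in stays.groupby("mouse_id", sort=True):
        t = _clip_total(sub["entry"].to_numpy(), sub["exit"].to_numpy(),
                        lo, hi)
        if t > 0:
            box_time[str(mouse)] = t
        sex[str(mouse)] = str(sub["sex"].iloc[0])
    rows = []
    if len(meetings):
        clipped = np.clip(np.minimum(meetings["end"], hi)
                          - np.maximum(meetings["start"], lo), 0.0, None)
        overlap = clipped.groupby(
            [meetings["mouse_a"], meetings["mouse_b"]]).sum()
        for (a, b), t_ab in overlap.items():
            if t_ab <= 0:
                continue
            t_a = box_time.get(str(a), 0.0)
            t_b = box_time.get(str(b), 0.0)
            denom = t_a + t_b - t_ab
            if t_a + t_b == 0:
                continue
            rows.append((str(a), str(b), float(t_ab), float(t_ab / denom)))
    pairs = pd.DataFrame(rows, columns=["mouse_a", "mouse_b", "overlap",
                                        "coi"])
    return CoiMatrix(window=(lo, hi), pairs=pairs,
                     box_time=pd.Series(box_time, dtype=float), sex=sex)


def build_network(coi: CoiMatrix) -> nx.Graph:
    """Weighted undirected social network: one node per active mouse,
    an edge wherever COI > 0 (weight = COI)."""
    g = nx.Graph()
    for mouse in coi.box_time.index:
        g.add_node(mouse, sex=coi.sex.get(mouse, "unknown"))
    for _, row in coi.pairs.iterrows():
        if row["coi"] > 0:
            g.add_edge(row["mouse_a"], row["mouse_b"],
                       weight=float(row["coi"]))
    return g


# ---------------------------------------------------------------------------
# communities and modularity
# ---------------------------------------------------------------------------

def detect_communities(g: nx.Graph, seed: int = 0, n_restarts: int = 20
                       ) -> tuple[dict[str, int], float]:
    """Louvain community detection on COI weights.

    Louvain is a greedy stochastic optimizer whose single-run output varies
    with its starting order, so the detector runs ``n_restarts`` independent
    passes and keeps the partition with the highest weighted modularity.
    Returns ``(partition, Q)``; deterministic given seed.
    """
    if g.number_of_nodes() == 0:
        raise ValueError("cannot partition an empty graph")
    if g.number_of_edges() == 0:
        partition = {n: i for i, n in enumerate(sorted(g.nodes))}
        return partition, 0.0
    rng = np.random.default_rng(seed)
    best_q, best = -np.inf, None
    for _ in range(max(n_restarts, 1)):
        comms = nx.community.louvain_communities(
            g, weight="weight", seed=int(rng.integers(2**31)))
        q = nx.community.modularity(g, comms, weight="weight")
        if q > best_q:
            best_q, best = q, comms
    partition = {n: i for i, c in enumerate(best) for n in c}
    return partition, float(best_q)


def modularity_of(g: nx.Graph, partition: dict[str, int]) -> float:
    groups: dict[int, set] = {}
    for n, c in partition.items():
        groups.setdefault(c, set()).add(n)
    return float(nx.community.modularity(g, list(groups.values()),
                                         weight="weight"))


def best_partition_exhaustive(g: nx.Graph) -> tuple[dict[str, int], float]:
    """Exhaustive maximum-modularity partition (oracle for tiny graphs).

    Enumerates all set partitions of the node set; exponential, intended only
    for graphs of about ten nodes or fewer.
    """
    nodes = sorted(g.nodes)
    if len(nodes) > 12:
        raise ValueError("exhaustive search limited to <= 12 nodes")
    best_q, best = -np.inf, None
    for part in _set_partitions(nodes):
        q = nx.community.modularity(g, part, weight="weight")
        if q > best_q:
            best_q, best = q, part
    partition = {n: i for i, c in enumerate(best) for n in c}
    return partition, float(best_q)


def _set_partitions(items):
    if len(items) == 1:
        yield [set(items)]
        return
    first, rest = items[0], items[1:]
    for smaller in _set_partitions(rest):
        for i in range(len(smaller)):
            yield smaller[:i] + [smaller[i] | {first}] + smaller[i + 1:]
        yield [{first}] + smaller


def randomize_network(g: nx.Graph, n_rand: int, seed: int = 0
                      ) -> list[nx.Graph]:
    """Degree-preserving null networks.

    Each replicate applies at least 10·|E| attempted double-edge swaps (which
    preserve the degree sequence exactly and introduce no self-loops or
    multi-edges) and then randomly permutes the COI edge weights among edges,
    preserving the weight multiset exactly.  When the topology admits no swap
    (e.g. a star), only weights are permuted and the replicate is flagged via
    ``graph.graph['swaps_failed'] = True``.
    """
    m = g.number_of_edges()
    if m < 2:
        raise ValueError("randomize_network requires >= 2 edges")
    weights = np.array([d["weight"] for _, _, d in g.edges(data=True)])
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_rand):
        h = g.copy()
        swap_seed = int(rng.integers(2**31))
        try:
            nx.double_edge_swap(h, nswap=10 * m, max_tries=200 * m,
                                seed=swap_seed)
        except nx.NetworkXError:
            h.graph["swaps_failed"] = True
        except nx.NetworkXAlgorithmError:
            h.graph["swaps_failed"] = True
        perm = rng.permutation(len(weights))
        for (u, v), w in zip(h.edges(), weights[perm]):
            h[u][v]["weight"] = float(w)
        out.append(h)
    return out


@dataclass
class ModularityTest:
    q_actual: float
    null_q: np.ndarray
    z: float


def modularity_test(g: nx.Graph, n_rand: int = 100, seed: int = 0
                    ) -> ModularityTest:
    """Observed Louvain modularity against degree-preserving nulls.

    Each null replicate is re-partitioned by Louvain; the z-score is
    (Q_actual - mean_null) / sd_null.  Undefined (NaN z) when the null
    standard deviation is zero.
    """
    if g.number_of_edges() == 0:
        raise ValueError("modularity_test requires a graph with edges")
    _, q_actual = detect_communities(g, seed=seed)
    nulls = randomize_network(g, n_rand, seed=seed + 1)
    null_q = np.array([detect_communities(h, seed=seed + 2 + i)[1]
                       for i, h in enumerate(nulls)])
    sd = null_q.std(ddof=1) if n_rand > 1 else 0.0
    if sd == 0:
        warnings.warn("null modularity has zero variance; z undefined",
                      stacklevel=2)
        z = float("nan")
    else:
        z = float((q_actual - null_q.mean()) / sd)
    return ModularityTest(q_actual=float(q_actual), null_q=null_q, z=z)


# ---------------------------------------------------------------------------
# small-world coefficient
# ---------------------------------------------------------------------------

def small_world(g: nx.Graph, n_random: int = 20, seed: int = 0
                ) -> SmallWorldResult:
    """Small-world coefficient sigma = (C/C_rand) / (L/L_rand).

    C is the mean unweighted clustering coefficient and L the mean shortest
    path length on the largest connected component of the binarized (COI > 0)
    graph.  Baselines are Erdős–Rényi graphs matched on node and edge count;
    disconnected baselines are measured on their largest component.  A graph
    with zero clustering yields sigma = 0 rather than an error.
    """
    comp = max(nx.connected_components(g), key=len)
    if len(comp) < 4:
        raise ValueError("largest component must have >= 4 nodes")
    sub = g.subgraph(comp)
    n, m = sub.number_of_nodes(), sub.number_of_edges()
    c = nx.average_clustering(sub)
    length = nx.average_shortest_path_length(sub)
    rng = np.random.default_rng(seed)
    cs, ls = [], []
    for _ in range(n_random):
        r = nx.gnm_random_graph(n, m, seed=int(rng.integers(2**31)))
        cs.append(nx.average_clustering(r))
        rcomp = max(nx.connected_components(r), key=len)
        rsub = r.subgraph(rcomp)
        if rsub.number_of_nodes() > 1:
            ls.append(nx.average_shortest_path_length(rsub))
    c_rand, l_rand = float(np.mean(cs)), float(np.mean(ls))
    if c_rand == 0 or l_rand == 0 or length == 0:
        sigma = 0.0 if c == 0 else float("nan")
    else:
        sigma = (c / c_rand) / (length / l_rand)
    return SmallWorldResult(sigma=float(sigma), C=float(c), L=float(length),
                            C_rand=c_rand, L_rand=l_rand, n_random=n_random)


# ---------------------------------------------------------------------------
# node and community metrics
# ---------------------------------------------------------------------------

def node_metrics(g: nx.Graph, partition: dict[str, int]) -> pd.DataFrame:
    """Per-node degree centrality, clustering coefficient and percentage of
    communities contacted.

    A node contacts the communities of its neighbours (its own community
    counts if any neighbour shares it); the percentage is relative to the
    total number of communities in the partition.
    """
    n = g.number_of_nodes()
    if n <= 1:
        raise ValueError("node metrics undefined for graphs with <= 1 node")
    missing = set(g.nodes) - set(partition)
    if missing:
        raise ValueError(f"partition missing nodes: {sorted(missing)[:5]}")
    n_comm = len(set(partition.values()))
    clustering = nx.clustering(g)
    rows = []
    for node in sorted(g.nodes):
        contacted = {partition[nb] for nb in g.neighbors(node)}
        rows.append({
            "mouse_id": node,
            "sex": g.nodes[node].get("sex", "unknown"),
            "degree_centrality": g.degree(node) / (n - 1),
            "clustering": clustering[node],
            "pct_communities_contacted": 100.0 * len(contacted) / n_comm,
            "community": partition[node],
        })
    return pd.DataFrame(rows)


def community_stats(partition: dict[str, int], stays: pd.DataFrame,
                    window: tuple[float, float], population_size: int,
                    n_boxes: int) -> pd.DataFrame:
    """Per-community size (% of population) and boxes visited (% of boxes).

    A community's boxes are the union of boxes its members used during the
    season window.
    """
    lo, hi = window
    in_win = stays[(stays["entry"] < hi) & (stays["exit"] > lo)]
    boxes_by_mouse = in_win.groupby("mouse_id")["box_id"].agg(set)
    rows = []
    comm_members: dict[int, list] = {}
    for node, c in partition.items():
        comm_members.setdefault(c, []).append(node)
    for c, members in sorted(comm_members.items()):
        boxes: set = set()
        for m in members:
            boxes |= boxes_by_mouse.get(m, set())
        rows.append({
            "community": c,
            "size": len(members),
            "size_pct": 100.0 * len(members) / population_size,
            "boxes_visited": len(boxes),
            "boxes_pct": 100.0 * len(boxes) / n_boxes,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# spatial decay of box sharing
# ---------------------------------------------------------------------------

def box_sharing_vs_distance(stays: pd.DataFrame, layout: pd.DataFrame,
                            window: tuple[float, float]) -> pd.DataFrame:
    """Percentage of shared users versus distance for every box pair.

    For boxes p, q with user sets within the window, the shared percentage is
    ``100 · |users(p) ∩ users(q)| / |users(p) ∪ users(q)|``; pairs where
    neither box had inhabitants are omitted.  Layout columns: box_id, x, y.
    """
    lo, hi = window
    in_win = stays[(stays["entry"] < hi) & (stays["exit"] > lo)]
    users = {str(b): set(sub["mouse_id"]) for b, sub in
             in_win.groupby("box_id")}
    pos = {str(r["box_id"]): (float(r["x"]), float(r["y"]))
           for _, r in layout.iterrows()}
    rows = []
    for p, q in itertools.combinations(sorted(pos), 2):
        up, uq = users.get(p, set()), users.get(q, set())
        union = up | uq
        if not union:
            continue
        dx = pos[p][0] - pos[q][0]
        dy = pos[p][1] - pos[q][1]
        rows.append({
            "box_a": p, "box_b": q,
            "distance": float(np.hypot(dx, dy)),
            "pct_shared": 100.0 * len(up & uq) / len(union),
        })
    return pd.DataFrame(rows)


def fit_decay(points: pd.DataFrame | np.ndarray) -> DecayFit:
    """Fit y = a·exp(-b·x) by non-negative nonlinear least squares.

    ``points`` is either a DataFrame with columns (distance, pct_shared) or a
    2-column array of (x, y).  Initialised at a = max(y), b = 1/mean(x).
    """
    if isinstance(points, pd.DataFrame):
        x = points["distance"].to_numpy(dtype=float)
        y = points["pct_shared"].to_numpy(dtype=float)
    else:
        arr = np.asarray(points, dtype=float)
        x, y = arr[:, 0], arr[:, 1]
    if len(x) < 3:
        raise ValueError("fit_decay requires >= 3 points")
    if np.any(x < 0):
        raise ValueError("distances must be non-negative")
    mean_x = x.mean()
    p0 = (max(y.max(), 1e-9), 1.0 / mean_x if mean_x > 0 else 1.0)

    def model(xx, a, b):
        return a * np.exp(-b * xx)

    try:
        popt, _ = curve_fit(model, x, y, p0=p0,
                            bounds=([0.0, 0.0], [np.inf, np.inf]),
                            xtol=1e-14, ftol=1e-14, gtol=1e-14,
                            maxfev=10000)
    except RuntimeError as e:
        raise RuntimeError(
            f"exponential decay fit failed to converge (n={len(x)}, "
            f"y range {y.min():.3g}..{y.max():.3g}): {e}") from e
    resid = y - model(x, *popt)
    return DecayFit(a=float(popt[0]), b=float(popt[1]),
                    rss=float(np.sum(resid**2)))
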