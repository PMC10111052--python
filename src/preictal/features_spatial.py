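"""Phase-locking networks and their graph-theoretic statistics.

For each epoch the instantaneous phase of every channel is taken from the
analytic (Hilbert) signal, and the phase-locking value between channels a
and b is the mean resultant length

    PLV_ab = | mean_t exp(i * (phi_a(t) - phi_b(t))) |  in [0, 1],

an amplitude-independent synchrony measure (1 = rigid phase locking).
The symmetric PLV matrix is treated as a weighted, undirected brain
network. Strength (weighted degree), eigenvector centrality and per-node
mean PLV ("synchronization") are computed on the weighted graph; the
clustering coefficient, characteristic path length, global efficiency and
the small-world index are computed after binarizing the network by keeping
the strongest fraction of edges (proportional threshold, 30% default).

The small-world index is sigma = (C / C_rand) / (L / L_rand), where the
random references are degree-preserving edge rewirings of the binarized
graph (seeded, 20 references by default). Degenerate cases in tiny or very
sparse graphs are resolved by documented conventions (see
:func:`graph_statistics`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.signal import hilbert

#: fraction of each epoch edge flagged as less reliable for phase use
EDGE_FRACTION = 0.05


@dataclass
class PLVNetwork:
    """Symmetric channel-by-channel phase-locking matrix, unit diagonal."""

    plv: np.ndarray
    band: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        p = np.asarray(self.plv, dtype=np.float64)
        if p.ndim != 2 or p.shape[0] != p.shape[1]:
            raise ValueError("PLV matrix must be square")
        if not np.allclose(p, p.T, atol=1e-9):
            raise ValueError("PLV matrix must be symmetric")
        if p.min() < -1e-9 or p.max() > 1 + 1e-9:
            raise ValueError("PLV entries must lie in [0, 1]")
        self.plv = p

    @property
    def n_channels(self) -> int:
        return self.plv.shape[0]


@dataclass
class GraphStats:
    """Topological summary of one PLV network.

    Per-node arrays are ordered like the channels; global scalars describe
    the whole (binarized, for C/L/E/sigma) network.
    """

    strength: np.ndarray
    clustering: np.ndarray
    eigenvector_centrality: np.ndarray
    synchronization: np.ndarray
    global_efficiency: float
    char_path_length: float
    small_world: float
    disconnected: bool = False
    adjacency: np.ndarray = field(default_factory=lambda: np.empty((0, 0)))


def instantaneous_phase(x: np.ndarray) -> np.ndarray:
    """Phase (radians) of the analytic signal of a zero-meaned epoch.

    The first/last :data:`EDGE_FRACTION` of samples carry Hilbert edge
    effects; :func:`interior_slice` selects the interior when a caller
    wants to trim them.
    """
    x = np.asarray(x, dtype=np.float64)
    if not np.any(x):
        raise ValueError("phase undefined for an all-zero epoch")
    return np.angle(hilbert(x - x.mean()))


def interior_slice(n_samples: int, edge_fraction: float = EDGE_FRACTION) -> slice:
    k = int(n_samples * edge_fraction)
    return slice(k, n_samples - k if k else n_samples)


def plv_matrix(epoch_data: np.ndarray,
               band: tuple[float, float] | None = None) -> PLVNetwork:
    """Pairwise phase-locking values of one multichannel epoch.

    Phases are extracted broadband from the (already band-passed) signal;
    per-band PLV is obtained by band-passing first and passing ``band`` as
    metadata.
    """
    data = np.atleast_2d(np.asarray(epoch_data, dtype=np.float64))
    n_ch, n_s = data.shape
    if n_ch < 2:
        raise ValueError("PLV needs at least 2 channels")
    phases = np.stack([instantaneous_phase(data[c]) for c in range(n_ch)])
    z = np.exp(1j * phases)
    g = (z @ z.conj().T) / n_s
    plv = np.abs(g)
    plv = (plv + plv.T) / 2.0
    np.fill_diagonal(plv, 1.0)
    return PLVNetwork(np.clip(plv, 0.0, 1.0), band)


def binarize_proportional(plv: np.ndarray, density: float = 0.3) -> np.ndarray:
    """Keep the strongest ``density`` fraction of off-diagonal edges.

    Ties are broken deterministically by (weight desc, i, j). Returns a
    boolean adjacency matrix; at least one edge is always kept.
    """
    if not 0 < density <= 1:
        raise ValueError("edge density must be in (0, 1]")
    n = plv.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    w = plv[iu, ju]
    order = np.lexsort((ju, iu, -w))
    k = max(1, int(round(density * w.size)))
    adj = np.zeros((n, n), dtype=bool)
    keep = order[:k]
    adj[iu[keep], ju[keep]] = True
    return adj | adj.T


def rewired_references(adj: np.ndarray, n_refs: int, seed: int
                       ) -> list[nx.Graph]:
    """Seeded degree-preserving rewirings of a binarized graph.

    Each reference applies ~4 double-edge swaps per edge; a graph whose
    topology admits no swap (e.g. a complete graph) is returned unchanged.
    """
    g = nx.from_numpy_array(adj.astype(int))
    e = g.number_of_edges()
    refs = []
    rng = np.random.default_rng(seed)
    for _ in range(n_refs):
        h = g.copy()
        if e >= 2:
            try:
                nx.double_edge_swap(
                    h, nswap=4 * e, max_tries=400 * e,
                    seed=int(rng.integers(2**31 - 1)),
                )
            except nx.NetworkXException:
                pass  # swap-saturated topology; keep the copy
        refs.append(h)
    return refs


def _largest_component_path_length(g: nx.Graph) -> tuple[float, bool]:
    """(characteristic path length, disconnected flag).

    Disconnected graphs are summarised by their largest component; a
    largest component below 2 nodes has no path and maps to 0.
    """
    if g.number_of_nodes() == 0:
        return 0.0, True
    if nx.is_connected(g):
        return float(nx.average_shortest_path_length(g)), False
    comp = max(nx.connected_components(g), key=len)
    if len(comp) < 2:
        return 0.0, True
    return float(nx.average_shortest_path_length(g.subgraph(comp))), True


def _sigma(c: float, l: float, c_rand: float, l_rand: float, n: int) -> float:
    """Small-world index with degenerate-case conventions.

    sigma = (C/C_rand) / (L/L_rand). When the rewired ensemble has zero
    clustering: the ratio is 1 if C is also 0 (equally tree-like) and n
    (the strongest plausible excess) if C > 0. Path ratios with a
    degenerate numerator or denominator default to 1.
    """
    if c_rand > 0:
        c_ratio = c / c_rand
    else:
        c_ratio = 1.0 if c == 0 else float(n)
    l_ratio = l / l_rand if (l_rand > 0 and l > 0) else 1.0
    return c_ratio / l_ratio


def graph_statistics(net: PLVNetwork, density: float = 0.3,
                     seed: int = 0, n_refs: int = 20) -> GraphStats:
    """All topological statistics of one PLV network.

    Weighted measures (strength, eigenvector centrality, synchronization)
    use the raw PLV weights; C, L, global efficiency and sigma use the
    proportionally thresholded binary graph. Deterministic at fixed seed.
    """
    plv = net.plv
    n = net.n_channels
    if n < 4:
        raise ValueError("small-world index undefined for fewer than 4 nodes")

    off = plv - np.eye(n)
    strength = off.sum(axis=1)
    synchronization = strength / (n - 1)

    evals, evecs = np.linalg.eigh(off)
    v = np.abs(evecs[:, int(np.argmax(evals))])
    eig_cent = v / v.max() if v.max() > 0 else v

    adj = binarize_proportional(plv, density)
    gb = nx.from_numpy_array(adj.astype(int))
    cdict = nx.clustering(gb)
    clustering = np.array([cdict[i] for i in range(n)], dtype=float)
    geff = float(nx.global_efficiency(gb))
    cpl, disconnected = _largest_component_path_length(gb)

    c_mean = float(clustering.mean())
    refs = rewired_references(adj, n_refs, seed)
    c_rand = float(np.mean([np.mean(list(nx.clustering(h).values()))
                            for h in refs]))
    l_rand = float(np.mean([_largest_component_path_length(h)[0]
                            for h in refs]))
    sigma = _sigma(c_mean, cpl, c_rand, l_rand, n)

    return GraphStats(
        strength=strength,
        clustering=clustering,
        eigenvector_centrality=eig_cent,
        synchronization=synchronization,
        global_efficiency=geff,
        char_path_length=cpl,
        small_world=sigma,
        disconnected=disconnected,
        adjacency=adj,
    )


def spatial_feature_names(n_channels: int) -> list[str]:
    names: list[str] = []
    for c in range(n_channels):
        names.extend(
            f"ch{c}_{feat}"
            for feat in (
                "plv_sync",
                "strength",
                "clustering",
                "eigcent",
                "global_eff",
                "path_len",
                "small_world",
            )
        )
    return names


def spatial_feature_block(
    epoch_data: np.ndarray,
    density: float = 0.3,
    seed: int = 0,
    n_refs: int = 20,
) -> tuple[np.ndarray, list[str]]:
    """7 spatial features per channel.

    Four are node-level (mean PLV, strength, clustering, eigenvector
    centrality); the three network-level values (global efficiency,
    characteristic path length, small-world index) are broadcast to every
    channel so temporal and spatial blocks tile identically per electrode.
    """
    net = plv_matrix(epoch_data)
    gs = graph_statistics(net, density=density, seed=seed, n_refs=n_refs)
    n_ch = net.n_channels
    values = np.empty(n_ch * 7)
    for c in range(n_ch):
        values[c * 7 : (c + 1) * 7] = (
            gs.synchronization[c],
            gs.strength[c],
            gs.clustering[c],
            gs.eigenvector_centrality[c],
            gs.global_efficiency,
            gs.char_path_length,
            gs.small_world,
        )
    return values, spatial_feature_names(n_ch)
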