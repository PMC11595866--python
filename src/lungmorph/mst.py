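"""Minimum-spanning-tree (MST) fractal dimension of a voxel mask.

Procedure: from the mask's largest 26-connected component, sample N_R
voxels uniformly at random; measure pairwise distances as shortest paths
*through the mask* (26-connected neighborhood, step costs 1, sqrt 2,
sqrt 3 in voxel units); build the minimum spanning tree of the sampled
nodes under that geodesic metric; form the mean edge length

    S(m) = (1/m) * sum_i l_i,        m = N_R - 1.

For a set of dimension h, S(m) decays as a power law S(m) = C * m^(-1/h)
(the mean nearest-link scale of m points in a d-dimensional set shrinks
as m^(-1/d)), so h is recovered as -1/slope of the OLS fit of log S(m)
against log m, averaging S(m) over independent replicate samples per m.

Estimation never needs the full pairwise distance matrix: the total MST
length of the sampled nodes equals the total MST length of the candidate
edge network built from the geodesic Voronoi partition of the component
around the nodes (Mehlhorn's distance-network construction), which takes
a single multi-source Dijkstra sweep per replicate. The exact pairwise
route (`geodesic_distance_matrix` + `mst_edge_lengths`) remains available
and the two routes agree exactly; tests assert that equality.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import dijkstra, minimum_spanning_tree

from .scaling import ScalingFit, fit_loglog
from .segmentation import largest_component
from .volume import VoxelMask

DEFAULT_NODE_GRID = (16, 32, 64, 128, 256, 512)
DEFAULT_REPS = 8


@dataclass
class NodeSample:
    """Distinct foreground voxel coordinates sampled from one component."""

    nodes: np.ndarray  # (N_R, 3) int voxel coordinates
    seed: int

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=np.int64)
        if self.nodes.ndim != 2 or self.nodes.shape[1] != 3:
            raise ValueError("nodes must be an (N_R, 3) coordinate array")
        if len(self.nodes) < 2:
            raise ValueError("need at least 2 nodes")
        if len(np.unique(self.nodes, axis=0)) != len(self.nodes):
            raise ValueError("nodes must be distinct")

    @property
    def n_r(self) -> int:
        return len(self.nodes)


@dataclass
class GeodesicMatrix:
    """Symmetric in-mask shortest-path lengths between sampled nodes."""

    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = self.d.shape[0]
        if self.d.shape != (n, n):
            raise ValueError("distance matrix must be square")
        if not np.all(np.isfinite(self.d)):
            raise ValueError("non-finite geodesic distances (disconnected nodes?)")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix must be symmetric")


@dataclass
class MSTScaling:
    """S(m) scaling samples and the fitted MST fractal dimension h."""

    m_values: np.ndarray
    s_values: np.ndarray  # replicate-averaged S(m)
    reps_per_m: int
    h: float
    fit: ScalingFit
    seed: int
    replicates: np.ndarray = field(default=None)  # (n_m, reps) raw S(m)


# ---------------------------------------------------------------------------
# voxel graph

_OFFSETS = np.array(
    [(dx, dy, dz)
     for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
     if (dx, dy, dz) > (0, 0, 0)],
    dtype=np.int64,
)


def _voxel_graph(mask: VoxelMask, physical: bool = False):
    """26-connectivity weighted graph over foreground voxels.

    Returns (csr graph, (rows, cols, weights) one direction per edge,
    coords (n,3), index volume mapping voxel -> node id or -1).
    """
    fg = mask.foreground
    coords = np.argwhere(fg)
    n = len(coords)
    index = -np.ones(fg.shape, dtype=np.int64)
    index[tuple(coords.T)] = np.arange(n)
    shape = fg.shape
    step = np.asarray(mask.spacing) if physical else np.ones(3)

    rows_list, cols_list, wts_list = [], [], []
    for off in _OFFSETS:
        sl_a = tuple(slice(max(0, -o), s - max(0, o)) for o, s in zip(off, shape))
        sl_b = tuple(slice(max(0, o), s - max(0, -o)) for o, s in zip(off, shape))
        a = index[sl_a]
        b = index[sl_b]
        ok = (a >= 0) & (b >= 0)
        if not ok.any():
            continue
        rows_list.append(a[ok])
        cols_list.append(b[ok])
        w = float(np.linalg.norm(off * step))
        wts_list.append(np.full(int(ok.sum()), w))
    if rows_list:
        rows = np.concatenate(rows_list)
        cols = np.concatenate(cols_list)
        wts = np.concatenate(wts_list)
    else:
        rows = cols = np.empty(0, dtype=np.int64)
        wts = np.empty(0)
    g = sparse.csr_matrix((wts, (rows, cols)), shape=(n, n))
    return g, (rows, cols, wts), coords, index


# ---------------------------------------------------------------------------
# operations

def sample_nodes(mask: VoxelMask, n_r: int, seed: int) -> NodeSample:
    """Uniform sample (without replacement) from the largest 26-component."""
    if n_r < 2:
        raise ValueError("n_r must be >= 2")
    comp = largest_component(mask, connectivity=26)
    coords = np.argwhere(comp.foreground)
    if len(coords) < n_r:
        raise ValueError(
            f"largest component has {len(coords)} voxels < n_r={n_r}"
        )
    rng = np.random.default_rng(seed)
    picks = rng.choice(len(coords), size=n_r, replace=False)
    return NodeSample(nodes=coords[picks], seed=seed)


def geodesic_distance_matrix(
    mask: VoxelMask, sample: NodeSample, physical: bool = False
) -> GeodesicMatrix:
    """Exact pairwise in-mask shortest-path lengths between sample nodes."""
    g, _, _, index = _voxel_graph(mask, physical=physical)
    node_ids = index[tuple(sample.nodes.T)]
    if np.any(node_ids < 0):
        raise ValueError("sample contains voxels outside the mask")
    d_all = dijkstra(g, directed=False, indices=node_ids)
    d = d_all[:, node_ids]
    if not np.all(np.isfinite(d)):
        raise ValueError("unreachable node pair: sample spans >1 component")
    d = 0.5 * (d + d.T)  # symmetrize away float round-off
    np.fill_diagonal(d, 0.0)
    return GeodesicMatrix(d=d)


def mst_edge_lengths(d: GeodesicMatrix) -> np.ndarray:
    """Edge lengths (ascending) of an MST of the complete distance graph."""
    mat = d.d
    n = mat.shape[0]
    if n < 2:
        raise ValueError("need at least 2 nodes for a spanning tree")
    tree = minimum_spanning_tree(sparse.csr_matrix(mat))
    lengths = np.sort(tree.data)
    if len(lengths) != n - 1:
        raise ValueError("distance graph is not connected")
    return lengths


def scaling_sum(lengths) -> float:
    """S(m): the mean MST edge length, (1/m) * sum of the m edge lengths."""
    lengths = np.asarray(lengths, dtype=float)
    if lengths.size == 0:
        raise ValueError("no edge lengths given")
    return float(lengths.mean())


def _terminal_mst_total(edges, dist, nearest, node_ids) -> float:
    """Total MST length of the terminals under the graph metric.

    Builds Mehlhorn's candidate network: one multi-source Dijkstra gives,
    for every voxel, the distance to and identity of its nearest terminal
    (a geodesic Voronoi partition); every mask edge (u, v) crossing two
    Voronoi cells proposes a terminal-terminal edge of weight
    d(t_u, u) + w(u, v) + d(v, t_v). The MST of that candidate network
    has exactly the total weight of the MST of the complete geodesic
    distance graph on the terminals.
    """
    rows, cols, wts = edges
    n_r = len(node_ids)
    term_of = {int(nid): i for i, nid in enumerate(node_ids)}
    su = nearest[rows]
    sv = nearest[cols]
    cross = su != sv
    if not np.any(cross):
        raise ValueError("terminals not connected through the mask")
    w = dist[rows[cross]] + wts[cross] + dist[cols[cross]]
    a = np.fromiter((term_of[int(s)] for s in su[cross]), dtype=np.int64,
                    count=int(cross.sum()))
    b = np.fromiter((term_of[int(s)] for s in sv[cross]), dtype=np.int64,
                    count=int(cross.sum()))
    lo = np.minimum(a, b)
    hi = np.maximum(a, b)
    # keep the lightest candidate per terminal pair
    order = np.lexsort((w, hi, lo))
    lo, hi, w = lo[order], hi[order], w[order]
    first = np.ones(len(lo), dtype=bool)
    first[1:] = (lo[1:] != lo[:-1]) | (hi[1:] != hi[:-1])
    cand = sparse.csr_matrix((w[first], (lo[first], hi[first])), shape=(n_r, n_r))
    tree = minimum_spanning_tree(cand)
    if tree.nnz != n_r - 1:
        raise ValueError("terminals not connected through the mask")
    return float(tree.sum())


def estimate_mst_dimension(
    mask: VoxelMask,
    m_grid: list[int] | None = None,
    reps_per_m: int = DEFAULT_REPS,
    seed: int = 0,
    physical: bool = False,
) -> MSTScaling:
    """MST fractal dimension h from the S(m) power-law fit.

    Parameters
    ----------
    mask
        Input voxel mask; sampling is restricted to its largest
        26-connected component.
    m_grid
        Node counts N_R per scale (default 16..512 in octaves); the
        regression abscissa is m = N_R - 1 edges.
    reps_per_m
        Independent node samples per scale; S(m) is averaged over them.
    seed
        Master seed; per-(N_R, replicate) streams are derived from it.
    physical
        If True, step costs are in mm (scaled by voxel spacing) instead
        of voxel-index units.
    """
    if m_grid is None:
        m_grid = list(DEFAULT_NODE_GRID)
    m_grid = sorted(int(v) for v in m_grid)
    if len(m_grid) < 3:
        raise ValueError("need at least 3 scales for the regression")
    if reps_per_m < 1:
        raise ValueError("reps_per_m must be >= 1")

    comp = largest_component(mask, connectivity=26)
    if comp.n_foreground < max(m_grid):
        raise ValueError(
            f"largest component ({comp.n_foreground} voxels) smaller than "
            f"max node count {max(m_grid)}"
        )
    g, edges, coords, index = _voxel_graph(comp, physical=physical)

    reps = np.empty((len(m_grid), reps_per_m))
    for i, n_r in enumerate(m_grid):
        for rep in range(reps_per_m):
            rng = np.random.default_rng(
                np.random.SeedSequence(entropy=seed, spawn_key=(n_r, rep))
            )
            picks = rng.choice(len(coords), size=n_r, replace=False)
            node_ids = np.sort(picks)
            dist, _, nearest = dijkstra(
                g, directed=False, indices=node_ids,
                min_only=True, return_predecessors=True,
            )
            total = _terminal_mst_total(edges, dist, nearest, node_ids)
            reps[i, rep] = total / (n_r - 1)

    m_values = np.asarray(m_grid, dtype=float) - 1.0
    s_values = reps.mean(axis=1)
    fit = fit_loglog(np.log(m_values), np.log(s_values))
    h = float("nan") if fit.slope >= 0 else -1.0 / fit.slope
    return MSTScaling(
        m_values=m_values,
        s_values=s_values,
        reps_per_m=reps_per_m,
        h=h,
        fit=fit,
        seed=seed,
        replicates=reps,
    )
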