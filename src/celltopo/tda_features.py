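"""Vietoris-Rips persistence and its vectorizations for labeled point clouds.

Diagrams are computed per cell-type channel ("blue", "orange", or "both")
from plain Euclidean distances, capped at a maximum filtration scale.
Dimension 0 (connected components) is computed by union-find over the
sorted edge list; dimension 1 (loops) by GF(2) column reduction of the
flag-complex triangle boundary, with columns stored as Python integer
bitsets over the sorted edges. A fully independent brute-force oracle
(persistent-Betti ranks plus inclusion-exclusion) is provided for small
instances and used by the test suite.

Vectorizations: lifespan-weighted Gaussian persistence images (1-D for H0,
2-D for H1 in (start, persistence) coordinates) and persistence curves
(Betti, life, Gaussian variants).

Interval conventions: H0 intervals all start at 0; the one interval per
connected component that never dies is capped at ``max_filtration`` and
retained by default so the H0 interval count equals the point count
(``infinite="drop"`` removes them instead).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform
from scipy.stats import norm

__all__ = [
    "PersistenceDiagram",
    "ImageConfig",
    "PersistenceImage",
    "PersistenceCurve",
    "FeatureVector",
    "select_channel",
    "compute_diagrams",
    "rips_diagrams_bruteforce",
    "persistence_image_dim0",
    "persistence_image_dim1",
    "normalize_image",
    "persistence_curve",
    "build_feature_vector",
]

CHANNELS = ("blue", "orange", "both")


@dataclass
class PersistenceDiagram:
    """Multiset of (start, end) filtration intervals for one dimension."""

    intervals: np.ndarray  # (m, 2)
    homology_dimension: int
    channel: str = "both"

    def __post_init__(self):
        self.intervals = np.asarray(self.intervals, dtype=float).reshape(-1, 2)
        if self.intervals.size and np.any(self.intervals[:, 1] < self.intervals[:, 0]):
            raise ValueError("interval end must be >= start")

    @property
    def n_intervals(self) -> int:
        return self.intervals.shape[0]

    @property
    def lifespans(self) -> np.ndarray:
        return self.intervals[:, 1] - self.intervals[:, 0]


@dataclass
class ImageConfig:
    sigma: float = 0.1
    grid_min: float = 0.0
    grid_max: float = 3.0
    resolution_1d: int = 100
    resolution_2d: int = 20
    max_filtration: float = 3.0

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.grid_max <= self.grid_min:
            raise ValueError("grid_max must exceed grid_min")
        if self.resolution_1d < 2 or self.resolution_2d < 2:
            raise ValueError("resolutions must be >= 2")

    def centers_1d(self) -> np.ndarray:
        step = (self.grid_max - self.grid_min) / self.resolution_1d
        return self.grid_min + (np.arange(self.resolution_1d) + 0.5) * step

    def centers_2d(self) -> np.ndarray:
        step = (self.grid_max - self.grid_min) / self.resolution_2d
        return self.grid_min + (np.arange(self.resolution_2d) + 0.5) * step


@dataclass
class PersistenceImage:
    values: np.ndarray
    axes: tuple
    normalized: bool = False

    def copy(self) -> "PersistenceImage":
        return PersistenceImage(self.values.copy(), self.axes, self.normalized)


@dataclass
class PersistenceCurve:
    t_grid: np.ndarray
    values: np.ndarray
    variant: str
    bandwidth: float | None = None


@dataclass
class FeatureVector:
    values: np.ndarray
    provenance: list = field(default_factory=list)  # (channel, dim, kind, length)


def select_channel(points: np.ndarray, types: np.ndarray | None,
                   channel: str, type_names=("blue", "orange")) -> np.ndarray:
    """Subset a labeled point cloud to one cell-type channel."""
    points = np.asarray(points, dtype=float)
    if channel == "both" or types is None:
        return points
    if channel not in type_names:
        raise ValueError(f"unknown channel {channel!r}; expected one of "
                         f"{tuple(type_names) + ('both',)}")
    code = list(type_names).index(channel)
    types = np.asarray(types)
    if types.dtype.kind in "USO":
        mask = types == channel
    else:
        mask = types == code
    return points[mask]


# ---------------------------------------------------------------------------
# diagram computation

def _h0_from_edges(n, ei, ej, order, w, cap, infinite):
    parent = np.arange(n)

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    merges = []
    positive = np.zeros(order.shape[0], dtype=bool)
    for rank in range(order.shape[0]):
        e = order[rank]
        ra, rb = find(ei[e]), find(ej[e])
        if ra == rb:
            positive[rank] = True
        else:
            parent[ra] = rb
            merges.append(w[e])
    n_comp = n - len(merges)
    ints = [(0.0, m) for m in merges]
    if infinite == "cap":
        ints.extend([(0.0, cap)] * n_comp)
    return np.array(ints, dtype=float).reshape(-1, 2), positive


def _rips_diagrams(points: np.ndarray, max_dim: int, cap: float,
                   infinite: str = "cap"):
    """H0/H1 Rips persistence of a 2-D point cloud, capped at ``cap``."""
    n = points.shape[0]
    if n == 0:
        return {d: np.empty((0, 2)) for d in range(max_dim + 1)}
    if n == 1:
        out = {0: np.array([[0.0, cap]]) if infinite == "cap" else np.empty((0, 2))}
        if max_dim >= 1:
            out[1] = np.empty((0, 2))
        return out

    dmat = squareform(pdist(points))
    iu, ju = np.triu_indices(n, 1)
    wall = dmat[iu, ju]
    keep = wall <= cap
    ei, ej, w = iu[keep], ju[keep], wall[keep]
    # simplexwise edge order: by length, ties by vertex pair
    order = np.lexsort((ej, ei, w))
    h0, positive = _h0_from_edges(n, ei, ej, order, w, cap, infinite)
    out = {0: h0}
    if max_dim < 1:
        return out

    m = order.shape[0]
    rank_of = np.empty(m, dtype=np.int64)
    rank_of[order] = np.arange(m)
    w_sorted = w[order]
    eid = -np.ones((n, n), dtype=np.int64)
    eid[ei, ej] = rank_of
    eid[ej, ei] = rank_of

    adj = dmat <= cap
    np.fill_diagonal(adj, False)

    # enumerate triangles i < j < k with all three edges present
    tri_e = []
    tri_key = []
    for a in range(m):
        i, j = ei[a], ej[a]
        common = np.nonzero(adj[i] & adj[j])[0]
        for k in common:
            if k <= j:
                continue
            r1 = rank_of[a]
            r2 = eid[i, k]
            r3 = eid[j, k]
            tri_e.append((r1, r2, r3))
            tri_key.append(max(r1, r2, r3))
    if tri_e:
        tri_order = np.argsort(np.asarray(tri_key), kind="stable")
    else:
        tri_order = np.empty(0, dtype=int)

    low_to_col: dict[int, int] = {}
    pairs = []  # (birth edge rank, death value)
    for t in tri_order:
        r1, r2, r3 = tri_e[t]
        col = (1 << int(r1)) | (1 << int(r2)) | (1 << int(r3))
        filt = w_sorted[tri_key[t]]
        while col:
            low = col.bit_length() - 1
            other = low_to_col.get(low)
            if other is None:
                low_to_col[low] = col
                if filt > w_sorted[low]:
                    pairs.append((low, filt))
                break
            col ^= other

    h1 = [(w_sorted[b], d) for b, d in pairs]
    # essential loops: creative edges never killed by a triangle
    paired = set(low_to_col.keys())
    for rank in np.nonzero(positive)[0]:
        if rank not in paired and cap > w_sorted[rank]:
            h1.append((w_sorted[rank], cap))
    out[1] = np.array(sorted(h1), dtype=float).reshape(-1, 2)
    return out


def compute_diagrams(points: np.ndarray, types: np.ndarray | None = None,
                     channel: str = "both", max_dim: int = 1,
                     max_filtration: float = 3.0,
                     infinite: str = "cap",
                     type_names=("blue", "orange")) -> dict[int, PersistenceDiagram]:
    """Rips persistence diagrams of one channel of a labeled point cloud.

    Returns a dict mapping homology dimension to
    :class:`PersistenceDiagram`. With the default ``infinite="cap"``
    convention, H0 has exactly one interval per point.
    """
    if infinite not in ("cap", "drop"):
        raise ValueError("infinite must be 'cap' or 'drop'")
    pts = select_channel(points, types, channel, type_names)
    if pts.shape[0] == 0:
        warnings.warn(f"channel {channel!r} is empty; returning empty diagrams")
        return {d: PersistenceDiagram(np.empty((0, 2)), d, channel)
                for d in range(max_dim + 1)}
    raw = _rips_diagrams(pts, max_dim, max_filtration, infinite)
    return {d: PersistenceDiagram(v, d, channel) for d, v in raw.items()}


# ---------------------------------------------------------------------------
# brute-force oracle (small n): persistent Betti ranks + inclusion-exclusion

def _gf2_rank(mat: np.ndarray) -> int:
    m = mat.copy().astype(np.uint8)
    rank = 0
    rows, cols = m.shape
    for c in range(cols):
        piv = None
        for r in range(rank, rows):
            if m[r, c]:
                piv = r
                break
        if piv is None:
            continue
        m[[rank, piv]] = m[[piv, rank]]
        for r in range(rows):
            if r != rank and m[r, c]:
                m[r] ^= m[rank]
        rank += 1
    return rank


def rips_diagrams_bruteforce(points: np.ndarray, max_filtration: float = np.inf,
                             infinite: str = "cap") -> dict[int, np.ndarray]:
    """Exact H0/H1 Rips intervals for tiny clouds (n <= ~8).

    Enumerates the full clique complex up to dimension 2 at every critical
    edge length and recovers interval multiplicities from persistent Betti
    numbers via inclusion-exclusion — an algorithm independent of the
    boundary-reduction production path.
    """
    points = np.asarray(points, dtype=float)
    n = points.shape[0]
    if n == 0:
        return {0: np.empty((0, 2)), 1: np.empty((0, 2))}
    dmat = squareform(pdist(points)) if n > 1 else np.zeros((1, 1))
    edges = [(dmat[i, j], i, j) for i, j in itertools.combinations(range(n), 2)
             if dmat[i, j] <= max_filtration]
    crits = sorted({0.0} | {e[0] for e in edges})
    tris = list(itertools.combinations(range(n), 3))

    def complex_at(eps):
        es = [(i, j) for d, i, j in edges if d <= eps]
        eset = set(es)
        ts = [t for t in tris if all(tuple(sorted(p)) in eset
                                     for p in itertools.combinations(t, 2))]
        return es, ts

    def boundary1(es):
        b = np.zeros((n, len(es)), dtype=np.uint8)
        for c, (i, j) in enumerate(es):
            b[i, c] = 1
            b[j, c] = 1
        return b

    def boundary2(es, ts):
        idx = {e: c for c, e in enumerate(es)}
        b = np.zeros((len(es), len(ts)), dtype=np.uint8)
        for c, t in enumerate(ts):
            for p in itertools.combinations(t, 2):
                b[idx[tuple(sorted(p))], c] = 1
        return b

    def persistent_betti(k, a, b):
        es_a, ts_a = complex_at(a)
        es_b, ts_b = complex_at(b)
        if k == 0:
            z = n - _gf2_rank(boundary1(es_a))
            bd = boundary1(es_b)  # rows = vertices (all present at any eps)
            # dim(B0(b) ∩ C0(a)) = rank(bd) since all vertices live at a
            return z - _gf2_rank(bd)
        # k == 1: dim(B1(K_b) ∩ C1(K_a)) = rank ∂2(b) − rank of ∂2(b)
        # restricted to rows of edges NOT in K_a; boundaries are cycles,
        # so intersecting with C1(K_a) equals intersecting with Z1(K_a).
        z = len(es_a) - _gf2_rank(boundary1(es_a))
        bd = boundary2(es_b, ts_b)
        full = _gf2_rank(bd)
        old = set(es_a)
        new_rows = [r for r, e in enumerate(es_b) if e not in old]
        proj = _gf2_rank(bd[new_rows]) if new_rows else 0
        return z - (full - proj)
    def betti_pairs(k):
        out = []
        cs = crits
        nc = len(cs)
        B = np.zeros((nc, nc))
        for ia in range(nc):
            for ib in range(ia, nc):
                B[ia, ib] = persistent_betti(k, cs[ia], cs[ib])
        for ia in range(nc):
            for ib in range(ia, nc):
                mult = B[ia, ib] - (B[ia, ib + 1] if ib + 1 < nc else 0)
                if ia > 0:
                    mult -= B[ia - 1, ib] - (B[ia - 1, ib + 1] if ib + 1 < nc else 0)
                for _ in range(int(round(mult))):
                    if ib + 1 < nc:
                        out.append((cs[ia], cs[ib + 1]))
                    else:  # never dies within the cap
                        if infinite == "cap" and np.isfinite(max_filtration):
                            out.append((cs[ia], max_filtration))
                        elif infinite == "inf":
                            out.append((cs[ia], np.inf))
        return np.array(sorted(out), dtype=float).reshape(-1, 2)

    h0 = betti_pairs(0)
    h1 = betti_pairs(1)
    h0 = h0[h0[:, 1] > h0[:, 0]] if infinite == "drop" else h0
    h1 = h1[h1[:, 1] > h1[:, 0]]
    return {0: h0, 1: h1}


# ---------------------------------------------------------------------------
# persistence images

def persistence_image_dim0(diagram: PersistenceDiagram,
                           config: ImageConfig | None = None) -> PersistenceImage:
    """1-D persistence image: lifespan-weighted Gaussians along the merge
    scale. H0 starts are identically zero, so Gaussians are centered at the
    interval *end* (the scale at which the component merges); centering at
    the start would stack all mass at the origin.
    """
    config = config or ImageConfig()
    if diagram.homology_dimension != 0:
        raise ValueError("expected a dimension-0 diagram")
    x = config.centers_1d()
    vals = np.zeros_like(x)
    for start, end in diagram.intervals:
        vals += (end - start) * norm.pdf(x, loc=end, scale=config.sigma)
    return PersistenceImage(vals, (x,))


def persistence_image_dim1(diagram: PersistenceDiagram,
                           config: ImageConfig | None = None) -> PersistenceImage:
    """2-D persistence image on (start, end - start) coordinates with an
    isotropic Gaussian of bandwidth sigma, weighted by lifespan."""
    config = config or ImageConfig()
    if diagram.homology_dimension != 1:
        raise ValueError("expected a dimension-1 diagram")
    c = config.centers_2d()
    vals = np.zeros((c.size, c.size))
    for start, end in diagram.intervals:
        pers = end - start
        gx = norm.pdf(c, loc=start, scale=config.sigma)
        gy = norm.pdf(c, loc=pers, scale=config.sigma)
        vals += pers * np.outer(gx, gy)
    return PersistenceImage(vals, (c, c))


def normalize_image(image: PersistenceImage) -> PersistenceImage:
    """Divide by the maximum intensity; all-zero images pass through."""
    peak = float(np.max(image.values)) if image.values.size else 0.0
    out = image.copy()
    if peak > 0:
        out.values = out.values / peak
    out.normalized = True
    return out


# ---------------------------------------------------------------------------
# persistence curves

def persistence_curve(diagram: PersistenceDiagram, variant: str,
                      t_grid: np.ndarray,
                      bandwidth: float | None = None) -> PersistenceCurve:
    """Scalar summary along the diagram diagonal.

    At each t the intervals with start <= t <= end (the [0,t] x [t, inf)
    region) contribute: their count (``betti``), their summed lifespans
    (``life``), or the integral over the region of a diagonal-distance-
    weighted Gaussian of the given bandwidth placed at each interval
    (``gaussian``).
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if np.any(np.diff(t_grid) < 0):
        raise ValueError("t_grid must be sorted ascending")
    if variant not in ("betti", "life", "gaussian"):
        raise ValueError(f"unknown persistence curve variant {variant!r}")
    if variant == "gaussian" and bandwidth is None:
        raise ValueError("gaussian variant requires a bandwidth")
    b = diagram.intervals[:, 0][None, :]
    d = diagram.intervals[:, 1][None, :]
    t = t_grid[:, None]
    inside = (b <= t) & (t <= d)
    if variant == "betti":
        vals = inside.sum(axis=1).astype(float)
    elif variant == "life":
        vals = np.where(inside, d - b, 0.0).sum(axis=1)
    else:
        w = (d - b) / np.sqrt(2.0)  # distance from the diagonal
        h = bandwidth
        # integral of the unit Gaussian at (b, d) over [0, t] x [t, inf)
        ix = norm.cdf((t - b) / h) - norm.cdf((0.0 - b) / h)
        iy = 1.0 - norm.cdf((t - d) / h)
        vals = (w * ix * iy).sum(axis=1)
    return PersistenceCurve(t_grid, vals, variant, bandwidth)


# ---------------------------------------------------------------------------
# feature vectors

def build_feature_vector(points: np.ndarray, types: np.ndarray | None,
                         channels=("both",), dims=(0, 1),
                         featurization: str = "images",
                         image_config: ImageConfig | None = None,
                         normalize: bool = False,
                         curve_grid: np.ndarray | None = None,
                         curve_variant: str = "betti",
                         curve_bandwidth: float | None = None,
                         type_names=("blue", "orange")) -> FeatureVector:
    """Concatenated topological features for the requested (channel, dim)
    blocks, in the order given (channels outer, dimensions ascending inner).
    """
    if not channels:
        raise ValueError("channels must be nonempty")
    image_config = image_config or ImageConfig()
    if curve_grid is None:
        curve_grid = np.linspace(image_config.grid_min, image_config.grid_max,
                                 image_config.resolution_1d)
    blocks = []
    provenance = []
    for channel in channels:
        dgms = compute_diagrams(points, types, channel,
                                max_dim=max(dims),
                                max_filtration=image_config.max_filtration,
                                type_names=type_names)
        for dim in sorted(dims):
            if featurization == "images":
                if dim == 0:
                    img = persistence_image_dim0(dgms[0], image_config)
                else:
                    img = persistence_image_dim1(dgms[1], image_config)
                if normalize:
                    img = normalize_image(img)
                flat = img.values.ravel()
            elif featurization == "curves":
                pc = persistence_curve(dgms[dim], curve_variant, curve_grid,
                                       curve_bandwidth)
                flat = pc.values
            else:
                raise ValueError(f"unknown featurization {featurization!r}")
            blocks.append(flat)
            provenance.append((channel, dim, featurization, flat.size))
    return FeatureVector(np.concatenate(blocks), provenance)
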