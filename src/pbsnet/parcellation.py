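"""Equal-sized random parcellation of a gray-matter mask.

One pseudo-bootstrap (PBS) sample is produced by (i) drawing the first seed
uniformly at random, (ii) placing the remaining N-1 seeds deterministically
by farthest-point sampling under the density-weighted distance D, and
(iii) growing parcels by assigning every voxel to its D-nearest seed.
Because only the first seed is random, each RNG seed indexes one member of
the PBS ensemble reproducibly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, sparse
from scipy.sparse import csgraph

from .voxel_graph import (GrayMatterMask, VoxelGraph, DensityField,
                          build_adjacency, local_density, _STRUCT26)

logger = logging.getLogger(__name__)


@dataclass
class Parcellation:
    """A labeling of mask voxels into N contiguous parcels (network nodes).

    ``labels[k]`` is the parcel id (1..N) of graph node k; ``seeds[l-1]`` is
    the seed node of parcel l.  Labels follow seed placement order; node
    identities are not comparable across different parcellations — that is
    the premise of pseudo-bootstrap resampling.
    """

    labels: np.ndarray          # (n_voxels,) int, values in 1..N
    seeds: np.ndarray           # (N,) graph node ids
    n_parcels: int
    rng_seed: int
    graph: VoxelGraph = None

    @property
    def sizes(self) -> np.ndarray:
        """Voxel count per parcel, ordered by label 1..N."""
        return np.bincount(self.labels, minlength=self.n_parcels + 1)[1:]

    def label_volume(self) -> np.ndarray:
        """Labels as a 3D integer volume (0 outside the mask)."""
        vol = np.zeros(self.graph.shape, dtype=np.int32)
        c = self.graph.coords
        vol[c[:, 0], c[:, 1], c[:, 2]] = self.labels
        return vol

    def membership_matrix(self, average: bool = True) -> sparse.csr_matrix:
        """Sparse (N x n_voxels) membership (or averaging) matrix."""
        n = self.labels.size
        data = np.ones(n)
        if average:
            data = data / self.sizes[self.labels - 1]
        return sparse.csr_matrix((data, (self.labels - 1, np.arange(n))),
                                 shape=(self.n_parcels, n))


@dataclass
class ParcelSizeStats:
    """Homogeneity statistics of the parcel-size distribution."""

    sizes: np.ndarray
    mean: float
    sd: float
    sd_to_mean_pct: float       # 100 * SD / mean
    median: float
    iqr: float                  # Q3 - Q1, linear-interpolation quantiles
    iqr_to_median: float
    nmv_pct: float              # 100 * (max - min) / min


def place_seeds(graph: VoxelGraph, density: DensityField, n: int,
                rng_seed: int) -> np.ndarray:
    """Place N seeds: first uniformly at random, the rest by farthest-point
    sampling under D (each new seed maximizes its minimum D to all seeds).

    Ties in the argmax are broken by the lowest linear voxel index, which is
    the node enumeration order, so plain argmax suffices.
    """
    v = graph.n_voxels
    if n < 1:
        raise ValueError("n must be >= 1")
    if n > v:
        raise ValueError(f"requested {n} seeds but mask has only {v} voxels")
    rng = np.random.default_rng(rng_seed)
    seeds = np.empty(n, dtype=np.intp)
    seeds[0] = rng.integers(v)
    L = density.values
    # min over placed seeds of D(seed, v)
    g = csgraph.dijkstra(graph.adjacency, directed=False, indices=seeds[0])
    min_d = 2.0 * g / (L[seeds[0]] + L)
    for k in range(1, n):
        seeds[k] = int(np.argmax(min_d))
        g = csgraph.dijkstra(graph.adjacency, directed=False, indices=seeds[k])
        np.minimum(min_d, 2.0 * g / (L[seeds[k]] + L), out=min_d)
    return seeds


def grow_parcels(graph: VoxelGraph, density: DensityField, seeds,
                 method: str = "balanced", chunk_size: int = 128) -> Parcellation:
    """Grow parcels around the seeds under the density-weighted distance D.

    method='balanced' (default): iterative region growing in which, at
    every step, the currently smallest parcel claims the unassigned voxel
    with minimal D-cost on its frontier (cost = density-weighted geodesic
    from the seed through the parcel's own territory).  Growth fronts stay
    26-connected by construction and parcel sizes stay within one voxel of
    each other until a front is walled in, so the size distribution is
    tight by design.

    method='voronoi': exact single-pass assignment of every voxel to the
    seed with minimal D(s, v) = 2 G(s, v) / (L(s) + L(v)) (ties -> lower
    label), computed seed-chunk by seed-chunk; stray fragments (possible
    because L varies along a geodesic) are reassigned deterministically to
    the adjacent parcel whose seed is D-closest.

    Ties are broken by lower parcel label and lower linear voxel index;
    both methods are fully deterministic given (graph, density, seeds).
    """
    if method == "balanced":
        return _grow_balanced(graph, density, seeds)
    if method != "voronoi":
        raise ValueError(f"unknown growth method {method!r}")
    seeds = np.asarray(seeds, dtype=np.intp)
    if np.unique(seeds).size != seeds.size:
        raise ValueError("seeds must be distinct")
    n = seeds.size
    v = graph.n_voxels
    L = density.values
    best_d = np.full(v, np.inf)
    best_lab = np.zeros(v, dtype=np.int32)
    for start in range(0, n, chunk_size):
        chunk = seeds[start:start + chunk_size]
        g = csgraph.dijkstra(graph.adjacency, directed=False, indices=chunk)
        d = 2.0 * g / (L[chunk][:, None] + L[None, :])
        arg = np.argmin(d, axis=0)
        dmin = d[arg, np.arange(v)]
        better = dmin < best_d  # strict: ties keep the earlier (lower) label
        best_d[better] = dmin[better]
        best_lab[better] = start + arg[better] + 1
    labels = _repair_connectivity(graph, density, seeds, best_lab)
    p = Parcellation(labels=labels, seeds=seeds, n_parcels=n,
                     rng_seed=-1, graph=graph)
    return p


def _grow_balanced(graph: VoxelGraph, density: DensityField,
                   seeds) -> Parcellation:
    """Smallest-parcel-first iterative region growing (see grow_parcels)."""
    import heapq

    seeds = np.asarray(seeds, dtype=np.intp)
    if np.unique(seeds).size != seeds.size:
        raise ValueError("seeds must be distinct")
    n = seeds.size
    v = graph.n_voxels
    L = density.values
    adj = graph.adjacency
    indptr, indices, weights = adj.indptr, adj.indices, adj.data
    lin = graph.linear_index()

    labels = np.zeros(v, dtype=np.int32)
    gdist = np.full(v, np.inf)           # geodesic from owner seed via territory
    frontiers = []                        # one heap per parcel: (D, lin, voxel, g)
    for lab, s in enumerate(seeds, start=1):
        labels[s] = lab
        gdist[s] = 0.0
        heap = []
        for e in range(indptr[s], indptr[s + 1]):
            u, w = indices[e], weights[e]
            d = 2.0 * w / (L[s] + L[u])
            heapq.heappush(heap, (d, lin[u], u, w))
        frontiers.append(heap)
    sizes = np.ones(n, dtype=np.int64)
    # scheduler: smallest parcel grows next; ties -> lower label
    sched = [(1, lab) for lab in range(1, n + 1)]
    heapq.heapify(sched)
    claimed = n
    while sched and claimed < v:
        size, lab = heapq.heappop(sched)
        if size != sizes[lab - 1]:
            continue                      # stale scheduler entry
        heap = frontiers[lab - 1]
        vi = -1
        while heap:
            d, _, cand, g = heapq.heappop(heap)
            if labels[cand] == 0:
                vi = cand
                break
        if vi < 0:
            continue                      # walled in: parcel stops growing
        labels[vi] = lab
        gdist[vi] = g
        sizes[lab - 1] += 1
        claimed += 1
        s = seeds[lab - 1]
        for e in range(indptr[vi], indptr[vi + 1]):
            u, w = indices[e], weights[e]
            if labels[u] == 0:
                gu = g + w
                heapq.heappush(heap, (2.0 * gu / (L[s] + L[u]), lin[u], u, gu))
        heapq.heappush(sched, (sizes[lab - 1], lab))
    if claimed < v:
        raise RuntimeError("growth stalled with unassigned voxels")
    labels = _balance_sizes(graph, seeds, labels)
    return Parcellation(labels=labels, seeds=seeds, n_parcels=n,
                        rng_seed=-1, graph=graph)


def _balance_sizes(graph: VoxelGraph, seeds: np.ndarray, labels: np.ndarray,
                   max_sweeps: int = 20) -> np.ndarray:
    """Equalize parcel sizes by migrating boundary voxels.

    Walled-in growth fronts leave some parcels smaller than others; this
    pass repeatedly moves a boundary voxel from a larger parcel to an
    adjacent parcel that is at least two voxels smaller, provided the
    donor's remaining voxels in the 26-neighborhood of the moved voxel
    stay locally connected (a simple-point criterion, sufficient for
    global contiguity) and the voxel is not the donor's seed.  Voxels are
    visited in linear-index order, so the pass is deterministic; each
    transfer strictly reduces the sum of squared sizes, so it terminates.
    """
    adj = graph.adjacency
    indptr, indices = adj.indptr, adj.indices
    n = seeds.size
    sizes = np.bincount(labels, minlength=n + 1)
    is_seed = np.zeros(labels.size, dtype=bool)
    is_seed[seeds] = True
    c = graph.coords
    vol = np.zeros(graph.shape, dtype=np.int32)
    vol[c[:, 0], c[:, 1], c[:, 2]] = labels
    sx, sy, sz = graph.shape
    lin = graph.linear_index()
    for _ in range(max_sweeps):
        moved = 0
        # vectorized candidate scan: boundary voxels whose parcel is at
        # least 2 voxels larger than some 26-neighbor's parcel
        start = np.repeat(np.arange(labels.size), np.diff(indptr))
        nbr_lab = labels[indices]
        own_lab = labels[start]
        gain = (sizes[own_lab] - sizes[nbr_lab] >= 2) & (own_lab != nbr_lab)
        candidates = np.unique(start[gain])
        candidates = candidates[~is_seed[candidates]]
        candidates = candidates[np.argsort(lin[candidates], kind="stable")]
        for vi in candidates:
            p = labels[vi]
            nbrs = indices[indptr[vi]:indptr[vi + 1]]
            nbr_labels = labels[nbrs]
            others = np.unique(nbr_labels[nbr_labels != p])
            if others.size == 0:
                continue
            deficits = sizes[p] - sizes[others]
            best = np.argmax(deficits)
            if deficits[best] < 2:
                continue
            q = others[best]
            x, y, z = c[vi]
            neigh = vol[max(0, x - 1):x + 2, max(0, y - 1):y + 2,
                        max(0, z - 1):z + 2]
            own = neigh == p
            own[min(x, 1), min(y, 1), min(z, 1)] = False  # remove v itself
            ncomp = ndimage.label(own, structure=_STRUCT26)[1]
            if ncomp != 1:
                continue  # moving v could split the donor
            labels[vi] = q
            vol[x, y, z] = q
            sizes[p] -= 1
            sizes[q] += 1
            moved += 1
        if moved == 0:
            break
    return labels


def _repair_connectivity(graph: VoxelGraph, density: DensityField,
                         seeds: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Reassign fragments of parcels that are not 26-connected.

    For each parcel, the component containing its seed is kept; voxels of
    stray components are merged into the adjacent parcel whose seed is
    D-closest, iterating until every parcel is connected.
    """
    vol = np.zeros(graph.shape, dtype=np.int32)
    c = graph.coords
    L = density.values
    for _ in range(100):
        vol[c[:, 0], c[:, 1], c[:, 2]] = labels
        stray = np.zeros(labels.size, dtype=bool)
        for lab in range(1, seeds.size + 1):
            comp, ncomp = ndimage.label(vol == lab, structure=_STRUCT26)
            if ncomp <= 1:
                continue
            seed_xyz = c[seeds[lab - 1]]
            keep = comp[seed_xyz[0], seed_xyz[1], seed_xyz[2]]
            bad = (comp[c[:, 0], c[:, 1], c[:, 2]] > 0) & \
                  (comp[c[:, 0], c[:, 1], c[:, 2]] != keep)
            stray |= bad
        if not stray.any():
            return labels
        logger.debug("reassigning %d stray voxels", int(stray.sum()))
        stray_idx = np.nonzero(stray)[0]
        # distances from the strays themselves: cheap when strays are rare
        g = csgraph.dijkstra(graph.adjacency, directed=False,
                             indices=stray_idx)[:, seeds]
        d = 2.0 * g / (L[stray_idx][:, None] + L[seeds][None, :])
        adj = graph.adjacency
        new = labels.copy()
        for pos, vi in enumerate(stray_idx):
            nbrs = adj.indices[adj.indptr[vi]:adj.indptr[vi + 1]]
            cand = np.unique(labels[nbrs[~stray[nbrs]]])
            cand = cand[cand != labels[vi]]
            if cand.size == 0:
                continue  # interior of a fragment; resolved on a later sweep
            new[vi] = cand[np.argmin(d[pos, cand - 1])]
        labels = new
    raise RuntimeError("parcel connectivity repair did not converge")


def random_parcellation(mask: GrayMatterMask, n: int, rng_seed: int,
                        graph: VoxelGraph | None = None,
                        density: DensityField | None = None) -> Parcellation:
    """One PBS sample: adjacency -> density (M = floor(V/N)) -> seeds -> growth.

    `graph` and `density` may be passed to amortize their computation across
    an ensemble (they depend only on the mask and N, not on the RNG seed).
    """
    if graph is None:
        graph = build_adjacency(mask)
    if n == 1:
        labels = np.ones(graph.n_voxels, dtype=np.int32)
        return Parcellation(labels=labels, seeds=np.array([0], dtype=np.intp),
                            n_parcels=1, rng_seed=rng_seed, graph=graph)
    if density is None:
        m = graph.n_voxels // n
        density = local_density(graph, m)
    seeds = place_seeds(graph, density, n, rng_seed)
    p = grow_parcels(graph, density, seeds)
    p.rng_seed = rng_seed
    return p


def pbs_sample(mask: GrayMatterMask, n: int, count: int,
               base_seed: int) -> list[Parcellation]:
    """Generate `count` independent parcellations with RNG seeds
    base_seed, base_seed+1, ... (the PBS ensemble)."""
    if count < 1:
        raise ValueError("count must be >= 1")
    graph = build_adjacency(mask)
    density = None
    if n > 1:
        density = local_density(graph, graph.n_voxels // n)
    return [random_parcellation(mask, n, base_seed + k, graph=graph,
                                density=density)
            for k in range(count)]


def parcel_size_stats(p: Parcellation) -> ParcelSizeStats:
    """Homogeneity statistics of a parcellation's size distribution.

    Quantiles use linear interpolation (type 7); NMV is the normalized
    maximum variation 100*(max-min)/min.
    """
    sizes = p.sizes.astype(float)
    q1, med, q3 = np.quantile(sizes, [0.25, 0.5, 0.75])
    mean = sizes.mean()
    sd = sizes.std(ddof=1) if sizes.size > 1 else 0.0
    return ParcelSizeStats(
        sizes=sizes,
        mean=float(mean),
        sd=float(sd),
        sd_to_mean_pct=float(100.0 * sd / mean),
        median=float(med),
        iqr=float(q3 - q1),
        iqr_to_median=float((q3 - q1) / med),
        nmv_pct=float(100.0 * (sizes.max() - sizes.min()) / sizes.min()),
    )
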