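"""Per-parcellation connectivity matrices.

Structural networks: a streamline connects parcels (i, j) iff its two
terminal points fall in parcels i and j.  The edge weight normalizes the
inverse fiber lengths by the node volumes,

    w_ij = 2 / (n_i + n_j) * sum_m 1 / L_ij^m

with pairs carrying fewer than `threshold` fibers (default 10) set to zero
to suppress spurious tracts.

Functional networks: node time series are the mean of member-voxel series
(after confound regression); edges are Pearson correlations with the
diagonal stored as zero so ensemble averages exclude self-correlation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .parcellation import Parcellation

logger = logging.getLogger(__name__)


@dataclass
class StreamlineSet:
    """Tractography polylines, each an ordered (k, 3) array of points.

    `frame` declares the coordinate frame ('voxel' or 'mm'); alignment
    with the parcellation is the caller's responsibility.
    """

    streamlines: list
    frame: str = "voxel"

    def __post_init__(self) -> None:
        self.streamlines = [np.asarray(s, dtype=float) for s in self.streamlines]
        for s in self.streamlines:
            if s.ndim != 2 or s.shape[0] < 2 or s.shape[1] != 3:
                raise ValueError("each streamline needs >= 2 points in 3D")
            if not np.isfinite(s).all():
                raise ValueError("streamline coordinates must be finite")

    def __len__(self) -> int:
        return len(self.streamlines)


def streamline_length(points: np.ndarray) -> float:
    """Polyline arc length (sum of segment Euclidean lengths)."""
    return float(np.linalg.norm(np.diff(points, axis=0), axis=1).sum())


@dataclass
class ConnectivityMatrix:
    """Symmetric N x N connectivity with node-size metadata.

    kind 'structural': nonnegative fiber-based weights.
    kind 'functional': Pearson correlations in [-1, 1], zero diagonal.
    """

    weights: np.ndarray
    node_sizes: np.ndarray
    kind: str
    parcellation_id: int = -1

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weights must be square")
        if not np.allclose(w, w.T, atol=1e-10):
            raise ValueError("weights must be symmetric")
        self.weights = w

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]


@dataclass
class TimeSeriesMatrix:
    """T x V (voxel) or T x N (parcel) series with optional T x C confounds."""

    series: np.ndarray
    confounds: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.series = np.asarray(self.series, dtype=float)
        if self.confounds is not None:
            self.confounds = np.asarray(self.confounds, dtype=float)
            if self.confounds.shape[0] != self.series.shape[0]:
                raise ValueError("confounds and series must share the time axis")
            if self.series.shape[0] <= self.confounds.shape[1] + 2:
                raise ValueError("need more timepoints than confounds + 2")


def count_fibers(streamlines: StreamlineSet, p: Parcellation):
    """Assign each streamline to the parcel pair of its two endpoints.

    Endpoint parcels are found by nearest-voxel lookup in the label volume;
    streamlines with an endpoint off the mask are ignored and tallied in
    the discard log.  Self-connections (both endpoints in one parcel) are
    excluded.  Returns ``(lengths, n_discarded)`` where `lengths` maps the
    ordered pair (i, j), i < j (1-based labels) to a list of fiber lengths.
    """
    graph = p.graph
    labels = p.labels
    lengths: dict[tuple[int, int], list[float]] = {}
    discarded = 0
    for line in streamlines.streamlines:
        a = graph.node_at(line[0])
        b = graph.node_at(line[-1])
        if a < 0 or b < 0:
            discarded += 1
            continue
        la, lb = int(labels[a]), int(labels[b])
        if la == lb:
            continue
        key = (min(la, lb), max(la, lb))
        lengths.setdefault(key, []).append(streamline_length(line))
    if discarded:
        logger.info("discarded %d streamlines with off-mask endpoints", discarded)
    return lengths, discarded


def structural_network(fibers: dict, node_sizes, threshold: int = 10,
                       parcellation_id: int = -1,
                       normalization: str = "equation") -> ConnectivityMatrix:
    """Structural connectivity from per-pair fiber-length lists.

    normalization='equation' (default): w_ij = 2/(n_i+n_j) * sum_m 1/L_m.
    normalization='mean': w_ij = count / (mean(n_i, n_j) * mean(L_m)), the
    alternative reading in which the raw count is normalized by the mean
    node volume and mean fiber length.
    Pairs with fewer than `threshold` fibers get weight 0.
    """
    node_sizes = np.asarray(node_sizes, dtype=float)
    if (node_sizes <= 0).any():
        raise ValueError("node sizes must be positive")
    n = node_sizes.size
    w = np.zeros((n, n))
    for (i, j), lens in fibers.items():
        if len(lens) < threshold:
            continue
        lens = np.asarray(lens, dtype=float)
        ni, nj = node_sizes[i - 1], node_sizes[j - 1]
        if normalization == "equation":
            val = 2.0 / (ni + nj) * np.sum(1.0 / lens)
        elif normalization == "mean":
            val = len(lens) / (0.5 * (ni + nj) * lens.mean())
        else:
            raise ValueError(f"unknown normalization {normalization!r}")
        w[i - 1, j - 1] = w[j - 1, i - 1] = val
    return ConnectivityMatrix(weights=w, node_sizes=node_sizes,
                              kind="structural", parcellation_id=parcellation_id)


def regress_confounds(ts: TimeSeriesMatrix) -> TimeSeriesMatrix:
    """Residualize every series on [intercept | confounds] by least squares.

    With no confounds this reduces to mean-centering.  Rank-deficient
    confound matrices are rejected with the offending columns named.
    """
    y = ts.series
    t = y.shape[0]
    if ts.confounds is None or ts.confounds.shape[1] == 0:
        x = np.ones((t, 1))
    else:
        x = np.column_stack([np.ones(t), ts.confounds])
        rank = np.linalg.matrix_rank(x)
        if rank < x.shape[1]:
            # name a minimal set of collinear confound columns
            bad = []
            cols = [np.ones(t)]
            for j in range(ts.confounds.shape[1]):
                trial = np.column_stack(cols + [ts.confounds[:, j]])
                if np.linalg.matrix_rank(trial) == trial.shape[1]:
                    cols.append(ts.confounds[:, j])
                else:
                    bad.append(j)
            raise ValueError(f"confound matrix is rank deficient; "
                             f"collinear columns: {bad}")
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    return TimeSeriesMatrix(series=y - x @ beta, confounds=None)


def functional_network(ts: TimeSeriesMatrix, p: Parcellation,
                       parcellation_id: int = -1) -> ConnectivityMatrix:
    """Pearson FC between parcel-mean time series.

    `ts` must be voxelwise (T x n_voxels, confounds already regressed) or
    already parcel-level (T x N).  The diagonal is stored as 0 so that
    downstream ensemble means exclude self-correlation.
    """
    y = ts.series
    if y.shape[1] == p.labels.size:
        node_series = (p.membership_matrix(average=True) @ y.T).T
    elif y.shape[1] == p.n_parcels:
        node_series = y
    else:
        raise ValueError("series width matches neither voxel nor parcel count")
    var = node_series.var(axis=0)
    dead = np.nonzero(var == 0)[0]
    if dead.size:
        raise ValueError("zero-variance node series for nodes "
                         f"{[int(d) for d in dead + 1]}")
    fc = np.corrcoef(node_series.T)
    np.fill_diagonal(fc, 0.0)
    sizes = p.sizes
    return ConnectivityMatrix(weights=fc, node_sizes=sizes, kind="functional",
                              parcellation_id=parcellation_id)
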