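"""Global network metrics, PBS metric distributions, variance
decomposition and test-retest ICC.

Six whole-network summaries are computed per connectivity matrix: average
(binary) degree, mean strength, mean weighted clustering coefficient
(Onnela geometric-mean form, weights normalized by the maximum), global
efficiency (mean inverse shortest path length on 1/w edge costs),
modularity Q (best of multi-restart Louvain) and the mean Rubinov–Sporns
diversity coefficient of strength across the Louvain modules.

For signed (functional) matrices, clustering, efficiency, modularity and
diversity are computed on the positive weights only; strength keeps the
signed row sums.

The ensemble statistics follow the pseudo-bootstrap design: the
parcellation-related variation of a metric is its SD across the PBS
ensemble; the between-scan variation is the root-mean-square scan-1/scan-2
difference of subjectwise PBS means,

    sigma_BS = sqrt( (1/M) * sum_i (Gbar1_i - Gbar2_i)^2 )

and the between-subject variation is the SD of scan-1 PBS means across
subjects.  Test-retest reliability uses the one-way random-effects
ICC(1,1) = (MSB - MSW) / (MSB + (k-1) MSW), which may be negative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import networkx as nx
from scipy import stats
from scipy.sparse import csgraph, csr_matrix
from statsmodels.stats.diagnostic import lilliefors

from .networks import ConnectivityMatrix

METRIC_NAMES = ("degree", "strength", "clustering", "efficiency",
                "modularity", "diversity")


@dataclass
class GlobalMetrics:
    degree: float
    strength: float
    clustering: float
    efficiency: float
    modularity: float
    diversity: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, k) for k in METRIC_NAMES])


@dataclass
class VarianceDecomposition:
    """Per-metric variation from parcellation, scans, and subjects."""

    sigma_parcellation: dict
    sigma_between_scan: dict
    sigma_subject: dict


@dataclass
class ICCReport:
    icc_of_mean: dict     # ICC on subjectwise PBS-mean metrics
    mean_icc: dict        # mean of per-parcellation ICCs
    p_value: dict         # one-tailed test: icc_of_mean > per-parcellation ICCs
    per_parcellation_icc: dict


def _positive_part(w: np.ndarray) -> np.ndarray:
    return np.where(w > 0, w, 0.0)


def weighted_clustering(w: np.ndarray) -> np.ndarray:
    """Onnela per-node weighted clustering on a nonnegative matrix.

    Weights are normalized by the network maximum; the coefficient of a
    node with binary degree < 2 is 0.
    """
    wmax = w.max()
    if wmax == 0:
        return np.zeros(w.shape[0])
    what = np.cbrt(w / wmax)
    cyc3 = np.diagonal(what @ what @ what)
    k = (w > 0).sum(axis=1)
    denom = k * (k - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(denom > 0, cyc3 / denom, 0.0)
    return c


def global_efficiency(w: np.ndarray) -> float:
    """Mean of 1/d_ij over distinct pairs, path lengths on 1/w edge costs.

    Unreachable pairs contribute 0 (1/inf)."""
    n = w.shape[0]
    if n < 2:
        return 0.0
    with np.errstate(divide="ignore"):
        cost = np.where(w > 0, 1.0 / w, 0.0)
    d = csgraph.dijkstra(csr_matrix(cost), directed=False)
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    np.fill_diagonal(inv, 0.0)
    inv[~np.isfinite(inv)] = 0.0
    return float(inv.sum() / (n * (n - 1)))


def louvain_partition(w: np.ndarray, n_restarts: int = 20,
                      seed: int = 0) -> tuple[list, float]:
    """Best-of-`n_restarts` Louvain partition and its modularity Q.

    Restart seeds are seed, seed+1, ...; on a tie, the earliest restart
    wins, so Q is non-decreasing in the number of restarts."""
    g = nx.from_numpy_array(w)
    best_q, best_part = -np.inf, None
    for r in range(n_restarts):
        part = nx.community.louvain_communities(g, weight="weight",
                                                seed=seed + r)
        q = nx.community.modularity(g, part, weight="weight")
        if q > best_q:
            best_q, best_part = q, part
    return [sorted(c) for c in best_part], float(best_q)


def diversity_coefficient(w: np.ndarray, partition: list) -> np.ndarray:
    """Shannon-entropy diversity of each node's strength across modules,
    normalized by log(#modules); 0 when all strength sits in one module."""
    n = w.shape[0]
    nmod = len(partition)
    if nmod < 2:
        return np.zeros(n)
    module_strength = np.zeros((n, nmod))
    for m, nodes in enumerate(partition):
        module_strength[:, m] = w[:, nodes].sum(axis=1)
    s = module_strength.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(s > 0, module_strength / s, 0.0)
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    h = -plogp.sum(axis=1) / np.log(nmod)
    return h


def global_metrics(c: ConnectivityMatrix, n_restarts: int = 20,
                   seed: int = 0) -> GlobalMetrics:
    """The six global metrics of one network."""
    w = c.weights
    if not np.allclose(np.diagonal(w), 0.0):
        raise ValueError("connectivity must have a zero diagonal")
    n = w.shape[0]
    if n == 0 or not (w != 0).any():
        warnings.warn("empty graph: all metrics set to 0", stacklevel=2)
        return GlobalMetrics(0., 0., 0., 0., 0., 0.)
    wpos = _positive_part(w)
    degree = float((w != 0).sum(axis=1).mean())
    strength = float(w.sum(axis=1).mean())
    clustering = float(weighted_clustering(wpos).mean())
    efficiency = global_efficiency(wpos)
    partition, q = louvain_partition(wpos, n_restarts=n_restarts, seed=seed)
    diversity = float(diversity_coefficient(wpos, partition).mean())
    return GlobalMetrics(degree=degree, strength=strength,
                         clustering=clustering, efficiency=efficiency,
                         modularity=q, diversity=diversity)


def pbs_metric_distribution(metric_table: np.ndarray,
                            names=METRIC_NAMES) -> dict:
    """Summarize PBS ensemble metric samples and test normality.

    `metric_table` is (n_parcellations, n_metrics).  Returns per metric the
    sample vector, mean, SD, and Lilliefors p-value (None, with a flag,
    for constant samples where the test is undefined).
    """
    metric_table = np.atleast_2d(np.asarray(metric_table, dtype=float))
    out = {}
    for k, name in enumerate(names):
        x = metric_table[:, k]
        entry = {"samples": x, "mean": float(x.mean()),
                 "sd": float(x.std(ddof=1)) if x.size > 1 else 0.0,
                 "constant": bool(np.ptp(x) == 0)}
        if entry["constant"] or x.size < 20:
            entry["lilliefors_p"] = None
        else:
            _, p = lilliefors(x, dist="norm")
            entry["lilliefors_p"] = float(p)
        out[name] = entry
    return out


def variance_decomposition(cohort: np.ndarray,
                           names=METRIC_NAMES) -> VarianceDecomposition:
    """Decompose metric variation into parcellation / scan / subject parts.

    `cohort` is (n_subjects, n_scans, n_parcellations[, n_metrics]); two
    scans are required.  sigma_parcellation averages each subject's scan-1
    SD across parcellations; sigma_BS is the RMS difference of the two
    scans' subjectwise PBS means; sigma_subject is the SD of scan-1 PBS
    means across subjects.
    """
    cohort = np.asarray(cohort, dtype=float)
    if cohort.ndim == 3:
        cohort = cohort[..., None]
        names = names[:1]
    ns, nscan, npar, nmet = cohort.shape
    if nscan < 2:
        raise ValueError("two scans per subject are required")
    if ns < 2:
        raise ValueError("sigma_subject is undefined for a single subject")
    means = cohort.mean(axis=2)                       # (S, scan, metric)
    sig_par = cohort[:, 0].std(axis=1, ddof=1).mean(axis=0)
    sig_bs = np.sqrt(((means[:, 0] - means[:, 1]) ** 2).mean(axis=0))
    sig_subj = means[:, 0].std(axis=0, ddof=1)
    return VarianceDecomposition(
        sigma_parcellation=dict(zip(names, sig_par)),
        sigma_between_scan=dict(zip(names, sig_bs)),
        sigma_subject=dict(zip(names, sig_subj)),
    )


def icc(values: np.ndarray) -> float:
    """One-way random-effects ICC(1,1) of a subjects x measurements table.

    ICC = (MSB - MSW) / (MSB + (k-1) MSW); may be negative.  Degenerate
    tables (zero total variance) are rejected.
    """
    y = np.asarray(values, dtype=float)
    if y.ndim != 2 or y.shape[0] < 2 or y.shape[1] < 2:
        raise ValueError("need >= 2 subjects and >= 2 measurements")
    n, k = y.shape
    grand = y.mean()
    if np.ptp(y) == 0:
        raise ValueError("ICC undefined: zero total variance")
    row_means = y.mean(axis=1)
    msb = k * ((row_means - grand) ** 2).sum() / (n - 1)
    msw = ((y - row_means[:, None]) ** 2).sum() / (n * (k - 1))
    return float((msb - msw) / (msb + (k - 1) * msw))


def icc_comparison(cohort: np.ndarray, names=METRIC_NAMES,
                   test: str = "one-sample") -> ICCReport:
    """Compare ICC of subjectwise PBS means against per-parcellation ICCs.

    For each metric: `icc_of_mean` is the ICC of the (subject x scan) table
    of PBS-mean metrics; `mean_icc` averages the ICCs obtained by treating
    each parcellation as a fixed template.  The p-value is a one-tailed
    test that icc_of_mean exceeds the per-parcellation ICC population
    (one-sample t-test by default; `test='paired'` is equivalent here).
    """
    cohort = np.asarray(cohort, dtype=float)
    if cohort.ndim == 3:
        cohort = cohort[..., None]
        names = names[:1]
    ns, nscan, npar, nmet = cohort.shape
    icc_mean, mean_icc, pvals, per_par = {}, {}, {}, {}
    for k, name in enumerate(names):
        means = cohort[..., k].mean(axis=2)           # (S, scan)
        iom = icc(means)
        per = np.array([icc(cohort[:, :, p, k]) for p in range(npar)])
        tstat, p = stats.ttest_1samp(per, iom, alternative="less")
        icc_mean[name] = iom
        mean_icc[name] = float(per.mean())
        pvals[name] = float(p)
        per_par[name] = per
    return ICCReport(icc_of_mean=icc_mean, mean_icc=mean_icc,
                     p_value=pvals, per_parcellation_icc=per_par)
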