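"""Functional-connectivity fingerprinting from the mean-FC vector.

Each subject/session yields one mean FC per PBS parcellation; across the
ensemble these form the mean FC vector (mFCV).  A subject in session 1 is
identified as the session-2 subject whose mFCV has the highest Pearson
correlation (and vice versa):

    ID1_i = ID2_k,  k = argmax_k corr(mFCV1_i, mFCV2_k)

The mFCV deliberately discards all edge-level structure — only how the
mean FC co-varies with the parcellation sample carries the identity
signal, which is what makes it a stringent test of PBS resampling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .networks import ConnectivityMatrix


@dataclass
class MeanFCVector:
    """Per-parcellation mean FC values of one subject/session."""

    subject: int
    session: int
    values: np.ndarray  # (ensemble length,)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.isfinite(self.values).all():
            raise ValueError("mFCV entries must be finite")


@dataclass
class IdentificationResult:
    similarity: np.ndarray          # (n_subjects, n_subjects) Pearson r
    predicted_1to2: np.ndarray      # argmax over session-2 subjects per row
    predicted_2to1: np.ndarray      # argmax over session-1 subjects per column
    accuracy_1to2: float
    accuracy_2to1: float


def mean_fc(c: ConnectivityMatrix) -> float:
    """Mean of the strictly-upper-triangle FC entries (diagonal excluded)."""
    w = c.weights
    iu = np.triu_indices(w.shape[0], k=1)
    return float(w[iu].mean())


def build_mfcv(fc_matrices: list, subject: int, session: int,
               expected_length: int | None = None) -> MeanFCVector:
    """mFCV of one subject/session from its ordered ensemble of FC matrices.

    Ordering must be consistent across subjects: the i-th matrix comes
    from the same parcellation for everyone.
    """
    if expected_length is not None and len(fc_matrices) != expected_length:
        raise ValueError(f"expected {expected_length} FC matrices, "
                         f"got {len(fc_matrices)}")
    vals = np.array([mean_fc(c) for c in fc_matrices])
    return MeanFCVector(subject=subject, session=session, values=vals)


def _corr_rows(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson correlation of every row of `a` with every row of `b`."""
    az = a - a.mean(axis=1, keepdims=True)
    bz = b - b.mean(axis=1, keepdims=True)
    na = np.linalg.norm(az, axis=1)
    nb = np.linalg.norm(bz, axis=1)
    tol_a = 1e-10 * np.maximum(np.linalg.norm(a, axis=1), 1e-30)
    tol_b = 1e-10 * np.maximum(np.linalg.norm(b, axis=1), 1e-30)
    if (na <= tol_a).any() or (nb <= tol_b).any():
        bad = list(np.nonzero(na <= tol_a)[0]) + list(np.nonzero(nb <= tol_b)[0])
        raise ValueError(f"zero-variance vectors for subjects {sorted(set(bad))}")
    return (az @ bz.T) / np.outer(na, nb)


def _identify_from_vectors(v1: np.ndarray, v2: np.ndarray) -> IdentificationResult:
    if v1.shape != v2.shape:
        raise ValueError("sessions must have matching subjects and lengths")
    sim = _corr_rows(v1, v2)
    n = sim.shape[0]
    pred12 = sim.argmax(axis=1)
    pred21 = sim.argmax(axis=0)
    for axis, pred in ((1, pred12), (0, pred21)):
        mx = sim.max(axis=axis)
        ties = (sim == (mx[:, None] if axis == 1 else mx[None, :])).sum(axis=axis)
        if (ties > 1).any():
            warnings.warn("similarity argmax ties broken by lowest subject index",
                          stacklevel=3)
    truth = np.arange(n)
    return IdentificationResult(
        similarity=sim,
        predicted_1to2=pred12,
        predicted_2to1=pred21,
        accuracy_1to2=float((pred12 == truth).mean()),
        accuracy_2to1=float((pred21 == truth).mean()),
    )


def identify(mfcvs_session1: list, mfcvs_session2: list) -> IdentificationResult:
    """Cross-session subject identification by maximum mFCV correlation."""
    v1 = np.stack([m.values for m in mfcvs_session1])
    v2 = np.stack([m.values for m in mfcvs_session2])
    return _identify_from_vectors(v1, v2)


def accuracy_vs_samples(mfcvs_session1: list, mfcvs_session2: list,
                        sample_counts, reps: int = 50,
                        rng_seed: int = 0) -> dict:
    """Mean identification accuracy as a function of ensemble size.

    For each count, `reps` random parcellation subsets (drawn without
    replacement, shared between sessions) are evaluated; the full-ensemble
    count needs a single deterministic evaluation.
    Returns {count: (mean accuracy 1->2, mean accuracy 2->1)}.
    """
    v1 = np.stack([m.values for m in mfcvs_session1])
    v2 = np.stack([m.values for m in mfcvs_session2])
    full = v1.shape[1]
    rng = np.random.default_rng(rng_seed)
    out = {}
    for count in sample_counts:
        if count > full:
            raise ValueError(f"sample count {count} exceeds ensemble length {full}")
        if count == full:
            r = _identify_from_vectors(v1, v2)
            out[count] = (r.accuracy_1to2, r.accuracy_2to1)
            continue
        accs = np.empty((reps, 2))
        for rep in range(reps):
            idx = rng.choice(full, size=count, replace=False)
            r = _identify_from_vectors(v1[:, idx], v2[:, idx])
            accs[rep] = (r.accuracy_1to2, r.accuracy_2to1)
        out[count] = tuple(accs.mean(axis=0))
    return out


def cohort_mfcvs(bold_cohort: dict, ensemble: list, regress: bool = True) -> dict:
    """Build mFCVs for every subject/session of a BOLD cohort.

    `bold_cohort` maps (subject, session) to (T x V series, T x C
    confounds); `ensemble` is the shared, ordered PBS parcellation list.
    Returns {session: [MeanFCVector sorted by subject]}.
    """
    from .networks import TimeSeriesMatrix, regress_confounds, functional_network

    sessions = sorted({k[1] for k in bold_cohort})
    out: dict = {sess: [] for sess in sessions}
    for (subj, sess) in sorted(bold_cohort):
        series, conf = bold_cohort[(subj, sess)]
        ts = TimeSeriesMatrix(series, conf if regress else None)
        ts = regress_confounds(ts)
        fcs = [functional_network(ts, p, parcellation_id=i)
               for i, p in enumerate(ensemble)]
        out[sess].append(build_mfcv(fcs, subj, sess))
    return out


def identify_matrix_baseline(fcs_session1: list, fcs_session2: list) -> IdentificationResult:
    """Template-style baseline: similarity is the Pearson correlation of
    vectorized upper-triangle FC matrices from a single parcellation."""
    def vec(c: ConnectivityMatrix) -> np.ndarray:
        iu = np.triu_indices(c.n_nodes, k=1)
        return c.weights[iu]

    v1 = np.stack([vec(c) for c in fcs_session1])
    v2 = np.stack([vec(c) for c in fcs_session2])
    return _identify_from_vectors(v1, v2)
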