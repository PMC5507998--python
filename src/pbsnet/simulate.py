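"""Synthetic cohorts for exercising every stage of the PBS pipeline.

Three generators are provided:

* :func:`synth_mask` — a hollow-ellipsoid "cortical shell" mask with an
  optional sinusoidal folding perturbation, 26-connected, with a voxel
  count within 5% of a target.
* :func:`synth_streamline_cohort` — multi-subject, two-scan streamline
  sets drawn from subject-specific latent connectomes (shared backbone +
  subject effect) with Poisson fiber counts and scan-level noise.
* :func:`synth_bold_cohort` — two-session voxel BOLD cohorts in which each
  subject's spatial factor loadings persist across sessions while temporal
  factors are redrawn, so the spatial-covariance identity signal that
  fingerprinting exploits is stable across days.

A lightweight :func:`synth_metric_cohort` draws global-metric tables
directly from a subject/scan/parcellation variance-components model, for
testing the variance-decomposition and ICC estimators against known truth.

All draws flow from a single ``numpy.random.Generator`` seeded by the
caller, so every cohort is fully reproducible from (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .voxel_graph import GrayMatterMask
from .networks import StreamlineSet
from .parcellation import Parcellation


@dataclass
class SyntheticCohortSpec:
    """Study-design parameters for the synthetic cohorts.

    Structural defaults emulate a two-scan test-retest cohort in which the
    parcellation-related variation of a metric is smaller than the
    between-scan variation, which is in turn smaller than the
    between-subject variation.  Functional defaults emulate a two-session
    resting-state cohort with a stable per-subject spatial identity signal.
    """

    n_subjects: int = 20
    n_sessions: int = 2
    # mask
    mask_target_voxels: int = 3000
    shell_thickness: float = 2.5
    # structural
    edge_density: float = 0.35        # fraction of node pairs in the backbone
    mean_fiber_count: float = 30.0    # mean fibers per backbone edge
    subject_effect_sd: float = 0.5    # log-scale SD of subject edge effects
    scan_noise_sd: float = 0.15       # log-scale SD of per-scan edge noise
    # functional
    n_timepoints: int = 300
    n_factors: int = 5                # latent spatial factors per subject
    identity_signal: float = 1.0      # strength of subject-specific loadings
    noise_sd: float = 1.0             # white-noise SD on voxel series
    confound_amplitude: float = 1.0   # amplitude of injected confound signals
    n_confounds: int = 8              # 6 motion + WM + CSF
    share_session_factors: bool = False  # reuse temporal factors across sessions
    seed: int = 0


def synth_mask(target_voxels: int, shell_thickness: float = 2.5,
               rng_seed: int = 0, fold_amplitude: float = 0.0) -> GrayMatterMask:
    """Hollow-ellipsoid shell mask with roughly `target_voxels` voxels.

    Semi-axes start from a 1 : 0.85 : 0.72 anisotropy, jittered a few
    percent by `rng_seed` so distinct seeds give distinct shells; the
    outer radius is solved so the voxelized count lands within 5% of the
    target.  `fold_amplitude` > 0 adds a sinusoidal radial perturbation
    that mimics cortical folding.  The result is restricted to its
    largest 26-connected component (the shell itself).
    """
    if target_voxels < 20:
        raise ValueError("target_voxels must be >= 20")
    rng = np.random.default_rng(rng_seed)
    ratios = np.array([1.0, 0.85, 0.72]) * rng.uniform(0.96, 1.04, size=3)

    def count(scale: float) -> tuple[int, np.ndarray]:
        a = scale * ratios
        t = shell_thickness
        ext = np.ceil(a + t + 2).astype(int)
        grid = [np.arange(-e, e + 1) for e in ext]
        x, y, z = np.meshgrid(*grid, indexing="ij")
        # normalized radial coordinate: 1 on the ellipsoid surface
        r = np.sqrt((x / a[0]) ** 2 + (y / a[1]) ** 2 + (z / a[2]) ** 2)
        surf = 1.0
        if fold_amplitude > 0:
            theta = np.arctan2(y, x)
            phi = np.arctan2(z, np.hypot(x, y))
            surf = 1.0 + fold_amplitude * np.sin(4 * theta) * np.cos(3 * phi)
        # half-thickness band around the (possibly folded) surface,
        # measured in true distance via the local gradient norm of r
        gnorm = np.sqrt((x / a[0] ** 2) ** 2 + (y / a[1] ** 2) ** 2
                        + (z / a[2] ** 2) ** 2) / np.maximum(r, 1e-9)
        band = np.abs(r - surf) <= (t / 2.0) * gnorm
        return int(band.sum()), band

    # bracket the outer scale, then bisect the (integer-valued) voxel count
    lo, hi = 1.0, 2.0
    while count(lo)[0] >= target_voxels and lo > 0.3:
        lo *= 0.7
    while count(hi)[0] < target_voxels:
        hi *= 1.5
    best_n, best_band = count(hi)
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        n, band = count(mid)
        if abs(n - target_voxels) < abs(best_n - target_voxels):
            best_n, best_band = n, band
        if n < target_voxels:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-3:
            break
    mask = GrayMatterMask(best_band).largest_component()
    return mask


def synth_streamline_cohort(spec: SyntheticCohortSpec,
                            parcellation: Parcellation) -> dict:
    """Per subject/scan streamline sets from latent connectomes.

    A shared symmetric backbone assigns a latent mean fiber count to a
    random `edge_density` fraction of parcel pairs.  Each subject's latent
    connectome multiplies the backbone by a log-normal subject effect per
    edge (SD `subject_effect_sd`); each scan multiplies by a log-normal
    scan noise (SD `scan_noise_sd`).  Fiber counts are Poisson draws around
    the scan-level latent value; each fiber is a 2-point streamline with
    endpoints uniform inside its two parcels, so its arc length is the
    endpoint distance.

    Returns ``{(subject, scan): StreamlineSet}`` with 0-based indices.
    """
    rng = np.random.default_rng(spec.seed)
    n = parcellation.n_parcels
    iu, ju = np.triu_indices(n, k=1)
    n_pairs = iu.size
    backbone = np.zeros(n_pairs)
    on = rng.random(n_pairs) < spec.edge_density
    backbone[on] = rng.gamma(shape=3.0, scale=spec.mean_fiber_count / 3.0,
                             size=int(on.sum()))
    coords_by_parcel = [parcellation.graph.coords[parcellation.labels == lab]
                        for lab in range(1, n + 1)]
    out = {}
    for s in range(spec.n_subjects):
        subj = backbone * np.exp(
            rng.normal(0.0, spec.subject_effect_sd, n_pairs)
            - 0.5 * spec.subject_effect_sd ** 2)
        for scan in range(spec.n_sessions):
            lam = subj * np.exp(rng.normal(0.0, spec.scan_noise_sd, n_pairs)
                                - 0.5 * spec.scan_noise_sd ** 2)
            counts = rng.poisson(lam)
            lines = []
            for pair_idx in np.nonzero(counts)[0]:
                a, b = iu[pair_idx], ju[pair_idx]
                ca, cb = coords_by_parcel[a], coords_by_parcel[b]
                pa = ca[rng.integers(len(ca), size=counts[pair_idx])]
                pb = cb[rng.integers(len(cb), size=counts[pair_idx])]
                for p0, p1 in zip(pa, pb):
                    lines.append(np.array([p0, p1], dtype=float))
            out[(s, scan)] = StreamlineSet(streamlines=lines, frame="voxel")
    return out


def synth_bold_cohort(spec: SyntheticCohortSpec, mask: GrayMatterMask) -> dict:
    """Per subject/session BOLD time series with a spatial identity signal.

    Voxel series are ``loadings @ factors + confound leakage + noise``.
    Loadings mix a population-shared spatial pattern with a
    subject-specific one (weight `identity_signal`); they are drawn once
    per subject and reused in both sessions.  Temporal factors and noise
    are redrawn per session, so only the spatial covariance structure — the
    fingerprint — persists across days.

    Returns ``{(subject, session): (series TxV, confounds TxC)}``.
    """
    rng = np.random.default_rng(spec.seed)
    v = mask.n_voxels
    t, k, c = spec.n_timepoints, spec.n_factors, spec.n_confounds
    shared = rng.normal(size=(v, k))
    loadings = []
    for _ in range(spec.n_subjects):
        own = rng.normal(size=(v, k))
        w = spec.identity_signal
        loadings.append((shared + w * own) / np.sqrt(1.0 + w * w))
    leak = rng.normal(size=(c, v)) * 0.3
    out = {}
    for s in range(spec.n_subjects):
        subject_factors = rng.normal(size=(t, k))
        for sess in range(spec.n_sessions):
            factors = (subject_factors if spec.share_session_factors or sess == 0
                       else rng.normal(size=(t, k)))
            conf = rng.normal(size=(t, c)) * spec.confound_amplitude
            series = factors @ loadings[s].T + conf @ leak \
                + rng.normal(scale=spec.noise_sd, size=(t, v))
            out[(s, sess)] = (series, conf)
    return out


def synth_metric_cohort(n_subjects: int = 20, n_parcellations: int = 50,
                        n_scans: int = 2, mu: float = 0.0,
                        sigma_subject: float = 1.0, sigma_scan: float = 0.3,
                        sigma_parcellation: float = 0.3,
                        rng_seed: int = 0) -> np.ndarray:
    """Draw a (subjects x scans x parcellations) global-metric table from
    the additive variance-components model

        y[i, s, p] = mu + a[i] + b[i, s] + e[i, s, p]

    with independent normal components of SD `sigma_subject`, `sigma_scan`
    and `sigma_parcellation`.  Ground truth for estimator-recovery tests.
    """
    rng = np.random.default_rng(rng_seed)
    a = rng.normal(0.0, sigma_subject, size=(n_subjects, 1, 1))
    b = rng.normal(0.0, sigma_scan, size=(n_subjects, n_scans, 1))
    e = rng.normal(0.0, sigma_parcellation,
                   size=(n_subjects, n_scans, n_parcellations))
    return mu + a + b + e
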