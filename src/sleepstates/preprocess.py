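"""Standardisation, temporal band-pass, concatenation, PCA and back-projection.

The pipeline mirrors the usual group-HMM preparation of parcellated BOLD data:
each participant's ROI timecourses are demeaned and variance-normalised,
optionally band-pass filtered (0.01-0.1 Hz by default, the slow BOLD band),
concatenated along time, and reduced with PCA.  State parameters estimated in
PC space are mapped back to region space through the PCA mixing matrix M:
``mean_roi = M @ mu`` and ``cov_roi = M @ Sigma @ M.T``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal
from sklearn.decomposition import PCA


@dataclass
class CohortMatrix:
    """Concatenated standardised timecourses with participant bookkeeping."""

    X: np.ndarray  # (total samples) x n_regions
    participant_index: np.ndarray  # row -> participant id, contiguous blocks
    sample_rate: float = 1.0 / 2.08  # Hz

    @property
    def n_participants(self) -> int:
        return len(np.unique(self.participant_index))

    def blocks(self):
        """Yield (participant id, row slice) for each contiguous block."""
        ids = np.unique(self.participant_index)
        for pid in ids:
            rows = np.flatnonzero(self.participant_index == pid)
            yield int(pid), slice(rows[0], rows[-1] + 1)


@dataclass
class PCAReduction:
    """PCA-reduced cohort: Y = X @ M with orthonormal mixing matrix M."""

    Y: np.ndarray  # (total samples) x n_components
    M: np.ndarray  # n_regions x n_components, orthonormal columns
    explained_variance_fraction: float
    participant_index: np.ndarray = None
    sample_rate: float = 1.0 / 2.08


def standardize_subject(ts: np.ndarray) -> np.ndarray:
    """Demean and variance-normalise each region's timecourse (population SD)."""
    ts = np.asarray(ts, dtype=float)
    if ts.ndim != 2 or ts.shape[0] < 2:
        raise ValueError("need a samples x regions matrix with at least 2 samples")
    sd = ts.std(axis=0)  # population (1/N) convention
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        raise ValueError(f"constant timecourse in region(s) {dead.tolist()}: cannot standardise")
    return (ts - ts.mean(axis=0)) / sd


def bandpass(ts, low_hz, high_hz, order=6, sample_rate=1.0 / 2.08):
    """Zero-phase Butterworth band-pass, applied column-wise.

    ``order`` is passed as the design order N to :func:`scipy.signal.butter`
    (a band-pass of design order N has 2N poles).  Filtering is
    forward-backward (``sosfiltfilt``) so no phase lag is introduced into
    state timings.
    """
    ts = np.asarray(ts, dtype=float)
    nyq = sample_rate / 2.0
    if not (0.0 < low_hz < high_hz < nyq):
        raise ValueError(
            f"band ({low_hz}, {high_hz}) Hz must satisfy 0 < low < high < Nyquist ({nyq:.4g} Hz)"
        )
    sos = signal.butter(order, [low_hz, high_hz], btype="band", fs=sample_rate, output="sos")
    return signal.sosfiltfilt(sos, ts, axis=0)


def concatenate(cohort, sample_rate=1.0 / 2.08) -> CohortMatrix:
    """Stack per-participant matrices along time, recording block membership."""
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    n_regions = cohort[0].shape[1]
    for p, X in enumerate(cohort):
        if X.shape[1] != n_regions:
            raise ValueError(
                f"participant {p} has {X.shape[1]} regions, expected {n_regions}"
            )
    X = np.vstack(cohort)
    idx = np.concatenate([np.full(len(Xp), p) for p, Xp in enumerate(cohort)])
    return CohortMatrix(X=X, participant_index=idx, sample_rate=sample_rate)


def _fix_signs(M: np.ndarray) -> np.ndarray:
    """Make each component's largest-|loading| entry positive (reproducibility)."""
    M = M.copy()
    for j in range(M.shape[1]):
        i = np.argmax(np.abs(M[:, j]))
        if M[i, j] < 0:
            M[:, j] = -M[:, j]
    return M


def pca_reduce(cohort: CohortMatrix, n_components=None, variance_target=None) -> PCAReduction:
    """Reduce the concatenated cohort with PCA.

    Exactly one of ``n_components`` and ``variance_target`` must be given.
    With ``variance_target`` the smallest component count whose cumulative
    explained-variance fraction reaches the target is used.
    """
    if (n_components is None) == (variance_target is None):
        raise ValueError("give exactly one of n_components and variance_target")
    X = cohort.X
    n_regions = X.shape[1]
    full = PCA(n_components=min(X.shape[0], n_regions), svd_solver="full").fit(X)
    ratios = full.explained_variance_ratio_
    if variance_target is not None:
        cum = np.cumsum(ratios)
        hit = np.flatnonzero(cum >= variance_target - 1e-12)
        if hit.size == 0:
            raise ValueError(
                f"variance_target={variance_target} unreachable with {len(ratios)} components"
            )
        n_components = int(hit[0] + 1)
    if n_components > n_regions:
        raise ValueError("n_components cannot exceed the number of regions")
    M = _fix_signs(full.components_[:n_components].T)
    Y = (X - full.mean_) @ M
    return PCAReduction(
        Y=Y,
        M=M,
        explained_variance_fraction=float(ratios[:n_components].sum()),
        participant_index=cohort.participant_index,
        sample_rate=cohort.sample_rate,
    )


def backproject_state(mean_in_pc_space, cov_in_pc_space, M):
    """Map PC-space state parameters back to region space via the mixing matrix."""
    M = np.asarray(M, dtype=float)
    mu = np.asarray(mean_in_pc_space, dtype=float)
    Sigma = np.asarray(cov_in_pc_space, dtype=float)
    if M.shape[1] != mu.shape[0] or Sigma.shape != (mu.shape[0], mu.shape[0]):
        raise ValueError("dimension mismatch between mixing matrix and state parameters")
    return M @ mu, M @ Sigma @ M.T


def preprocess_cohort(
    data,
    sample_rate=1.0 / 2.08,
    bandpass_enabled=False,
    low_hz=0.01,
    high_hz=0.1,
    order=6,
    n_components=None,
    variance_target=None,
) -> PCAReduction:
    """Standardise (and optionally filter) per participant, concatenate, PCA.

    The band-pass is applied per participant before concatenation, so filter
    transients never leak across participant boundaries.
    """
    prepped = []
    for X in data:
        Xs = standardize_subject(X)
        if bandpass_enabled:
            Xs = bandpass(Xs, low_hz, high_hz, order=order, sample_rate=sample_rate)
        prepped.append(Xs)
    cohort = concatenate(prepped, sample_rate=sample_rate)
    if n_components is None and variance_target is None:
        n_components = min(cohort.X.shape[1], 25)
    return pca_reduce(cohort, n_components=n_components, variance_target=variance_target)
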