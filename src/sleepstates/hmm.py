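"""Variational-Bayes inference for a Gaussian-observation hidden Markov model.

The model: a sequence of ``K`` latent whole-brain network states, each emitting
from its own multivariate Gaussian (mean activation vector mu_k and covariance
Sigma_k, both defined at the group level), with Markovian switching governed by
a row-stochastic transition matrix A.  State timecourses (posterior state
probabilities gamma) are inferred per participant, with each participant's
block treated as an independent chain sharing the group-level parameters.

Inference is conjugate mean-field VB: Normal-Wishart posteriors over
(mu_k, Lambda_k), Dirichlet posteriors over the transition rows and the
initial distribution, and an exact forward-backward pass over the hidden
states given the expected ("tilde") natural parameters.  The free energy
(negative evidence lower bound)

    F = -(sum_p log Z_p) + KL(q(pi)||p(pi)) + KL(q(A)||p(A))
        + sum_k KL(q(mu_k, Lambda_k)||p(mu_k, Lambda_k))

is non-increasing over iterations; it trades off data fit (the forward-pass
log-normalisers log Z_p) against model complexity (the KL-to-prior terms) and
approximates the negative log model evidence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.special import digamma, gammaln
from sklearn.cluster import KMeans

logger = logging.getLogger(__name__)

_LOG_2PI = np.log(2.0 * np.pi)


# ---------------------------------------------------------------------------
# priors
# ---------------------------------------------------------------------------

@dataclass
class NormalWishartPrior:
    """Conjugate Normal-Wishart prior over each state's (mean, precision).

    Defaults are empirical-Bayes style: prior mean = global data mean, prior
    expected precision = inverse global covariance, with weak pseudo-counts
    (``beta0`` observations for the mean, ``nu0 = D + 2`` degrees of freedom),
    so the prior regularises without dominating.
    """

    m0: np.ndarray
    beta0: float
    W0: np.ndarray
    nu0: float

    @classmethod
    def from_data(cls, Y: np.ndarray, beta0: float = 1e-2, nu0: float | None = None):
        Y = np.asarray(Y, dtype=float)
        D = Y.shape[1]
        if nu0 is None:
            nu0 = float(D + 2)
        cov = np.cov(Y, rowvar=False, bias=True)
        cov = np.atleast_2d(cov) + 1e-8 * np.eye(D)
        W0 = np.linalg.inv(cov) / nu0  # E_prior[Lambda] = nu0 W0 = cov^{-1}
        return cls(m0=Y.mean(axis=0), beta0=float(beta0), W0=W0, nu0=float(nu0))


# ---------------------------------------------------------------------------
# results container
# ---------------------------------------------------------------------------

@dataclass
class StateTimecourses:
    """Posterior state probabilities and hard paths, per participant."""

    gamma: np.ndarray  # (total samples) x K
    path: np.ndarray  # (total samples,) argmax of gamma (lowest index on ties)
    participant_index: np.ndarray

    def per_participant(self):
        ids = np.unique(self.participant_index)
        for pid in ids:
            rows = self.participant_index == pid
            yield int(pid), self.gamma[rows], self.path[rows]


class VBHMMResults:
    """Fitted-model container: state statistics, transition matrix, timecourses.

    Attributes
    ----------
    mu : (K, D) posterior mean of the state means (PC space).
    Sigma : (K, D, D) posterior expected state covariances.
    A : (K, K) posterior mean transition matrix (row stochastic).
    pi0 : (K,) posterior mean initial distribution.
    free_energy_trace : per-iteration free energy, non-increasing.
    timecourses : :class:`StateTimecourses` on the training data.
    """

    def __init__(self, model, posterior, trace, timecourses, seed_used, n_iter, converged,
                 empty_states):
        self.model = model
        self._post = posterior
        self.K = model.K
        self.mu = posterior["m"].copy()
        nu = posterior["nu"]
        D = self.mu.shape[1]
        Winv = np.linalg.inv(posterior["W"])
        denom = np.maximum(nu - D - 1.0, 1e-6)
        self.Sigma = Winv / denom[:, None, None]
        self.A = posterior["alpha"] / posterior["alpha"].sum(axis=1, keepdims=True)
        self.pi0 = posterior["pi_alpha"] / posterior["pi_alpha"].sum()
        self.free_energy_trace = np.asarray(trace)
        self.free_energy = float(trace[-1])
        self.timecourses = timecourses
        self.gamma = timecourses.gamma
        self.path = timecourses.path
        self.participant_index = timecourses.participant_index
        self.seed_used = seed_used
        self.n_iter = n_iter
        self.converged = converged
        self.empty_states = empty_states

    def fractional_occupancy(self) -> np.ndarray:
        counts = np.bincount(self.path, minlength=self.K).astype(float)
        return counts / counts.sum()

    def summary(self) -> str:
        fo = self.fractional_occupancy()
        lines = [
            "Variational-Bayes Gaussian HMM",
            "=" * 46,
            f"states (K):           {self.K}",
            f"observations:         {len(self.path)}",
            f"participants:         {len(np.unique(self.participant_index))}",
            f"dimensions:           {self.mu.shape[1]}",
            f"free energy:          {self.free_energy:.4f}",
            f"iterations:           {self.n_iter} (converged: {self.converged})",
            f"restart seed used:    {self.seed_used}",
            "-" * 46,
            "state  frac.occupancy  self-transition",
        ]
        for k in range(self.K):
            lines.append(f"{k:>5}  {fo[k]:>14.4f}  {self.A[k, k]:>15.4f}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------

class GaussianHMM:
    """VB Gaussian HMM over concatenated multi-participant timecourses.

    Parameters
    ----------
    Y : (N, D) array
        Observations (typically the PCA-reduced cohort matrix).
    participant_index : (N,) array, optional
        Contiguous block labels; each block is one chain.  Default: one chain.
    n_states : int
        Number of hidden states K.
    prior : NormalWishartPrior, optional
        Observation-model prior; default built from the data.
    trans_alpha0, trans_stickiness : float
        Symmetric Dirichlet pseudo-count per transition-row entry, plus an
        additive self-transition boost (BOLD states persist for seconds).
    tol : float
        Relative free-energy change declaring convergence.
    """

    def __init__(self, Y, participant_index=None, n_states=19, prior=None,
                 trans_alpha0=1.0, trans_stickiness=5.0, tol=1e-5, max_iter=500):
        self.Y = np.asarray(Y, dtype=float)
        if self.Y.ndim != 2:
            raise ValueError("Y must be 2-D (samples x dimensions)")
        N, D = self.Y.shape
        if participant_index is None:
            participant_index = np.zeros(N, dtype=int)
        self.participant_index = np.asarray(participant_index)
        if len(self.participant_index) != N:
            raise ValueError("participant_index length must match Y")
        if n_states < 1:
            raise ValueError("need at least one state")
        self.K = int(n_states)
        self.D = D
        self.prior = prior if prior is not None else NormalWishartPrior.from_data(self.Y)
        alpha0 = np.full((self.K, self.K), float(trans_alpha0))
        alpha0[np.diag_indices(self.K)] += float(trans_stickiness)
        self.trans_alpha0 = alpha0
        self.pi_alpha0 = np.ones(self.K)
        self.tol = float(tol)
        self.max_iter = int(max_iter)
        # contiguous block slices
        self._blocks = []
        ids, starts = np.unique(self.participant_index, return_index=True)
        order = np.argsort(starts)
        starts = starts[order]
        bounds = list(starts) + [N]
        for b0, b1 in zip(bounds[:-1], bounds[1:]):
            self._blocks.append(slice(int(b0), int(b1)))

    @classmethod
    def from_reduction(cls, reduction, **kwargs):
        """Build from a :class:`~sleepstates.preprocess.PCAReduction`."""
        return cls(reduction.Y, participant_index=reduction.participant_index, **kwargs)

    # -- expected sufficient statistics ------------------------------------

    def _expected_log_det_lambda(self, W, nu):
        D = self.D
        sign, logdet = np.linalg.slogdet(W)
        i = np.arange(1, D + 1)
        return digamma((nu[:, None] + 1 - i) / 2.0).sum(axis=1) + D * np.log(2.0) + logdet

    def expected_log_emission(self, post, Y=None):
        """E_q[ln N(y_t | mu_k, Lambda_k^{-1})] for every sample and state.

        Equals ``0.5 * (E[ln|Lambda_k|] - D/beta_k
        - nu_k (y - m_k)^T W_k (y - m_k) - D ln 2 pi)``.
        """
        Y = self.Y if Y is None else np.asarray(Y, dtype=float)
        K, D = self.K, self.D
        elogdet = self._expected_log_det_lambda(post["W"], post["nu"])
        out = np.empty((len(Y), K))
        for k in range(K):
            diff = Y - post["m"][k]
            quad = np.einsum("ti,ij,tj->t", diff, post["W"][k], diff)
            out[:, k] = 0.5 * (
                elogdet[k] - D / post["beta"][k] - post["nu"][k] * quad - D * _LOG_2PI
            )
        return out

    @staticmethod
    def _tilde_dirichlet(alpha):
        """exp(E[ln theta]) for Dirichlet rows (geometric-mean parameters)."""
        alpha = np.atleast_2d(alpha)
        return np.exp(digamma(alpha) - digamma(alpha.sum(axis=1, keepdims=True)))

    # -- E step -------------------------------------------------------------

    def _forward_backward(self, log_b, A_tilde, pi_tilde):
        """Scaled forward-backward on one chain; returns gamma, xi_sum,
        first-sample responsibilities and the log-normaliser."""
        T, K = log_b.shape
        shift = log_b.max(axis=1)
        b = np.exp(log_b - shift[:, None])
        alpha = np.empty((T, K))
        c = np.empty(T)
        a = pi_tilde * b[0]
        c[0] = a.sum()
        alpha[0] = a / c[0]
        for t in range(1, T):
            a = (alpha[t - 1] @ A_tilde) * b[t]
            c[t] = a.sum()
            alpha[t] = a / c[t]
        beta = np.empty((T, K))
        beta[-1] = 1.0
        for t in range(T - 2, -1, -1):
            beta[t] = (A_tilde @ (b[t + 1] * beta[t + 1])) / c[t + 1]
        gamma = alpha * beta
        gamma /= gamma.sum(axis=1, keepdims=True)
        # xi summed over t, fully vectorised
        xi_sum = A_tilde * (alpha[:-1].T @ ((b[1:] * beta[1:]) / c[1:, None])) if T > 1 else np.zeros((K, K))
        log_z = float(np.log(c).sum() + shift.sum())
        return gamma, xi_sum, gamma[0], log_z

    def _e_step(self, post, Y=None, blocks=None):
        Y = self.Y if Y is None else Y
        blocks = self._blocks if blocks is None else blocks
        log_b = self.expected_log_emission(post, Y)
        A_tilde = self._tilde_dirichlet(post["alpha"])
        pi_tilde = self._tilde_dirichlet(post["pi_alpha"])[0]
        gamma = np.empty((len(Y), self.K))
        xi_sum = np.zeros((self.K, self.K))
        first = np.zeros(self.K)
        log_z = 0.0
        for sl in blocks:
            g, x, f, lz = self._forward_backward(log_b[sl], A_tilde, pi_tilde)
            gamma[sl] = g
            xi_sum += x
            first += f
            log_z += lz
        return gamma, xi_sum, first, log_z

    # -- M step -------------------------------------------------------------

    def _m_step(self, gamma, xi_sum, first, Y=None):
        Y = self.Y if Y is None else Y
        K, D = self.K, self.D
        pr = self.prior
        Nk = gamma.sum(axis=0)
        empty = Nk < 1.0
        for k in np.flatnonzero(empty):
            logger.warning(
                "state %d has responsibility mass %.3g (< 1 sample); "
                "parameters remain prior-dominated", k, Nk[k]
            )
        safe = np.maximum(Nk, 1e-12)
        xbar = (gamma.T @ Y) / safe[:, None]
        beta = pr.beta0 + Nk
        m = (pr.beta0 * pr.m0 + Nk[:, None] * xbar) / beta[:, None]
        nu = pr.nu0 + Nk
        W0inv = np.linalg.inv(pr.W0)
        W = np.empty((K, D, D))
        for k in range(K):
            diff = Y - xbar[k]
            Sk = (gamma[:, k][:, None] * diff).T @ diff  # Nk * scatter
            dm = (xbar[k] - pr.m0)[:, None]
            Winv = W0inv + Sk + (pr.beta0 * Nk[k] / beta[k]) * (dm @ dm.T)
            Winv = 0.5 * (Winv + Winv.T)
            Wk = np.linalg.inv(Winv)
            W[k] = 0.5 * (Wk + Wk.T)
        alpha = self.trans_alpha0 + xi_sum
        pi_alpha = self.pi_alpha0 + first
        return {"beta": beta, "m": m, "W": W, "nu": nu, "alpha": alpha,
                "pi_alpha": pi_alpha, "Nk": Nk}

    # -- KL complexity terms --------------------------------------------------

    @staticmethod
    def _kl_dirichlet(a, a0):
        a, a0 = np.atleast_2d(a), np.atleast_2d(a0)
        sa, sa0 = a.sum(axis=1), a0.sum(axis=1)
        kl = (
            gammaln(sa) - gammaln(a).sum(axis=1)
            - gammaln(sa0) + gammaln(a0).sum(axis=1)
            + ((a - a0) * (digamma(a) - digamma(sa)[:, None])).sum(axis=1)
        )
        return float(kl.sum())

    def _log_wishart_b(self, W, nu):
        D = self.D
        sign, logdet = np.linalg.slogdet(W)
        i = np.arange(1, D + 1)
        return (
            -0.5 * nu * logdet
            - 0.5 * nu * D * np.log(2.0)
            - 0.25 * D * (D - 1) * np.log(np.pi)
            - gammaln((nu + 1 - i[:, None]).T / 2.0).sum(axis=1)
        )

    def _kl_normal_wishart(self, post):
        pr = self.prior
        K, D = self.K, self.D
        elogdet = self._expected_log_det_lambda(post["W"], post["nu"])
        W0inv = np.linalg.inv(pr.W0)
        kl = 0.0
        lnB_q = self._log_wishart_b(post["W"], post["nu"])
        lnB_p = self._log_wishart_b(pr.W0[None, :, :], np.array([pr.nu0]))[0]
        for k in range(K):
            beta_k, m_k, W_k, nu_k = post["beta"][k], post["m"][k], post["W"][k], post["nu"][k]
            dm = m_k - pr.m0
            quad = float(dm @ W_k @ dm)
            kl_normal = 0.5 * (
                D * np.log(beta_k / pr.beta0) - D
                + pr.beta0 * (D / beta_k + nu_k * quad)
            )
            tr = float(np.trace(W0inv @ W_k))
            kl_wishart = (
                lnB_q[k] - lnB_p
                + 0.5 * (nu_k - pr.nu0) * elogdet[k]
                + 0.5 * nu_k * (tr - D)
            )
            kl += kl_normal + kl_wishart
        return kl

    def _free_energy(self, post, log_z):
        kl = (
            self._kl_dirichlet(post["pi_alpha"], self.pi_alpha0)
            + self._kl_dirichlet(post["alpha"], self.trans_alpha0)
            + self._kl_normal_wishart(post)
        )
        return -log_z + kl

    # -- fitting --------------------------------------------------------------

    def _init_posterior(self, seed):
        K = self.K
        if K == 1:
            gamma = np.ones((len(self.Y), 1))
        else:
            n = len(self.Y)
            rng = np.random.default_rng(seed)
            sub = rng.choice(n, size=min(n, 2000), replace=False)
            km = KMeans(n_clusters=K, n_init=3, random_state=int(rng.integers(2**31)))
            km.fit(self.Y[sub])
            labels = km.predict(self.Y)
            eps = 0.25
            gamma = np.full((n, K), eps / K)
            gamma[np.arange(n), labels] += 1.0 - eps
        xi_sum = np.zeros((K, K))
        first = np.zeros(K)
        for sl in self._blocks:
            g = gamma[sl]
            if g.shape[0] > 1:
                xi_sum += g[:-1].T @ g[1:]
            first += g[0]
        return self._m_step(gamma, xi_sum, first)

    def _fit_once(self, seed):
        post = self._init_posterior(seed)
        trace = []
        prev = np.inf
        converged = False
        gamma = None
        for it in range(self.max_iter):
            gamma, xi, first, log_z = self._e_step(post)
            fe = self._free_energy(post, log_z)
            trace.append(fe)
            if np.isfinite(prev) and abs(prev - fe) < self.tol * max(abs(prev), 1.0):
                converged = True
                break
            prev = fe
            # never update past the final E-step, so the returned posterior is
            # exactly the one that produced the returned gamma and free energy
            if it < self.max_iter - 1:
                post = self._m_step(gamma, xi, first)
        return post, trace, gamma, converged

    def fit(self, n_init=5, seed=None) -> VBHMMResults:
        """Fit with ``n_init`` restarts; return the lowest-free-energy solution."""
        root = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
        children = root.spawn(max(1, int(n_init)))
        best = None
        for i, child in enumerate(children):
            post, trace, gamma, converged = self._fit_once(child)
            if best is None or trace[-1] < best[1][-1]:
                best = (post, trace, gamma, converged, i)
        post, trace, gamma, converged, idx = best
        path = np.argmax(gamma, axis=1)  # argmax takes the lowest index on ties
        tcs = StateTimecourses(gamma=gamma, path=path,
                               participant_index=self.participant_index.copy())
        empty = np.flatnonzero(post["Nk"] < 1.0).tolist()
        return VBHMMResults(self, post, trace, tcs, seed_used=idx,
                            n_iter=len(trace), converged=converged, empty_states=empty)

    # -- post-fit utilities ----------------------------------------------------

    def decode(self, results: VBHMMResults, Y_new=None, participant_index=None,
               viterbi=False) -> StateTimecourses:
        """Forward-backward smoothing of (new) data under a fitted model."""
        if Y_new is None:
            Y_new = self.Y
            participant_index = self.participant_index
        Y_new = np.asarray(Y_new, dtype=float)
        if Y_new.shape[1] != self.D:
            raise ValueError("dimension mismatch with the fitted model")
        if participant_index is None:
            participant_index = np.zeros(len(Y_new), dtype=int)
        blocks = _contiguous_blocks(participant_index)
        post = results._post
        log_b = self.expected_log_emission(post, Y_new)
        A_tilde = self._tilde_dirichlet(post["alpha"])
        pi_tilde = self._tilde_dirichlet(post["pi_alpha"])[0]
        gamma = np.empty((len(Y_new), self.K))
        path = np.empty(len(Y_new), dtype=int)
        for sl in blocks:
            g, _, _, _ = self._forward_backward(log_b[sl], A_tilde, pi_tilde)
            gamma[sl] = g
            if viterbi:
                path[sl] = _viterbi(log_b[sl], np.log(A_tilde), np.log(pi_tilde))
            else:
                path[sl] = np.argmax(g, axis=1)
        return StateTimecourses(gamma=gamma, path=path,
                                participant_index=np.asarray(participant_index).copy())

    def free_energy(self, results: VBHMMResults, Y=None, participant_index=None) -> float:
        """Free energy of a fitted posterior on (training or new) data."""
        if Y is None:
            _, _, _, log_z = self._e_step(results._post)
        else:
            blocks = _contiguous_blocks(
                participant_index if participant_index is not None
                else np.zeros(len(Y), dtype=int)
            )
            _, _, _, log_z = self._e_step(results._post, np.asarray(Y, float), blocks)
        return self._free_energy(results._post, log_z)


def _contiguous_blocks(participant_index):
    participant_index = np.asarray(participant_index)
    blocks = []
    n = len(participant_index)
    start = 0
    for t in range(1, n + 1):
        if t == n or participant_index[t] != participant_index[start]:
            blocks.append(slice(start, t))
            start = t
    return blocks


def _viterbi(log_b, log_A, log_pi):
    T, K = log_b.shape
    delta = log_pi + log_b[0]
    back = np.zeros((T, K), dtype=int)
    for t in range(1, T):
        cand = delta[:, None] + log_A
        back[t] = np.argmax(cand, axis=0)
        delta = cand[back[t], np.arange(K)] + log_b[t]
    path = np.empty(T, dtype=int)
    path[-1] = int(np.argmax(delta))
    for t in range(T - 2, -1, -1):
        path[t] = back[t + 1][path[t + 1]]
    return path


# ---------------------------------------------------------------------------
# model-order scan and state matching
# ---------------------------------------------------------------------------

def scan_model_orders(Y, participant_index, K_list, n_init=2, seed=None,
                      tr_seconds=2.08, **model_kwargs) -> pd.DataFrame:
    """Fit one model per K and tabulate the order-selection diagnostics.

    Columns: minimum free energy, median fractional occupancy across states,
    and mean state lifetime (seconds) — the three curves typically inspected
    when choosing the model order.
    """
    if len(K_list) == 0:
        raise ValueError("K_list must be non-empty")
    root = np.random.SeedSequence(seed)
    rows = []
    for K, child in zip(K_list, root.spawn(len(K_list))):
        model = GaussianHMM(Y, participant_index=participant_index, n_states=int(K),
                            **model_kwargs)
        res = model.fit(n_init=n_init, seed=child)
        fo = res.fractional_occupancy()
        lifetimes = _pooled_mean_lifetime(res.path, res.participant_index, tr_seconds)
        rows.append({
            "K": int(K),
            "free_energy": res.free_energy,
            "median_fractional_occupancy": float(np.median(fo)),
            "mean_lifetime_seconds": lifetimes,
        })
    return pd.DataFrame(rows)


def _pooled_mean_lifetime(path, participant_index, tr_seconds):
    runs = []
    for sl in _contiguous_blocks(participant_index):
        seg = path[sl]
        change = np.flatnonzero(np.diff(seg) != 0)
        edges = np.concatenate([[0], change + 1, [len(seg)]])
        runs.extend(np.diff(edges).tolist())
    return float(np.mean(runs) * tr_seconds)


def match_states(path_true, path_est, K_true=None, K_est=None):
    """Optimal one-to-one state matching (Hungarian on the overlap matrix).

    Returns ``(mapping, accuracy)`` where ``mapping[j]`` is the true-state
    label assigned to estimated state ``j`` (or -1 for unmatched extra
    states) and ``accuracy`` is the fraction of samples on which the
    relabelled estimate equals the truth.
    """
    path_true = np.asarray(path_true, dtype=int)
    path_est = np.asarray(path_est, dtype=int)
    K_true = int(path_true.max()) + 1 if K_true is None else int(K_true)
    K_est = int(path_est.max()) + 1 if K_est is None else int(K_est)
    overlap = np.zeros((K_est, K_true))
    for j in range(K_est):
        mask = path_est == j
        if mask.any():
            overlap[j] = np.bincount(path_true[mask], minlength=K_true)
    rows, cols = linear_sum_assignment(-overlap)
    mapping = np.full(K_est, -1, dtype=int)
    mapping[rows] = cols
    matched = mapping[path_est]
    accuracy = float(np.mean(matched == path_true))
    return mapping, accuracy
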