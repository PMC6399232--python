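"""Inferential machinery: period-preserving permutations, MANOVA, paired tests.

The permutation null preserves each participant's hypnogram *structure* —
stage transition points, stage counts and period (run) lengths — and shuffles
only the labelling of the runs within the participant.  Under this null the
temporal layout of the scoring is held fixed while its association with the
state timecourses is broken.

The MANOVA statistic is Wilks' lambda, det(W) / det(W + B), with W and B the
within- and between-stage scatter matrices of the state timecourses; smaller
values indicate stronger grouping of the states by the stages, so the
permutation p-value is the lower-tail exceedance with add-one correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .metrics import Hypnogram, sensitivity, specificity, switching_rate, range_rate

logger = logging.getLogger(__name__)


def _seed_sequence(seed):
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(seed)


@dataclass
class TestResult:
    """A test statistic with its permutation null and add-one p-value."""

    statistic: float
    null: np.ndarray
    p_value: float
    comparison: str = ""
    n_excluded: int = 0

    def __repr__(self):
        return (f"TestResult({self.comparison or 'test'}: statistic={self.statistic:.4g}, "
                f"p={self.p_value:.4g}, n_perm={len(self.null)}, "
                f"excluded={self.n_excluded})")


def _runs(stages):
    """Run-length decomposition: list of (label, length)."""
    stages = np.asarray(stages, dtype=object)
    change = np.flatnonzero(stages[1:] != stages[:-1])
    starts = np.concatenate([[0], change + 1])
    lengths = np.diff(np.concatenate([starts, [len(stages)]]))
    return [(stages[s], int(l)) for s, l in zip(starts, lengths)]


def permute_hypnogram(hypnogram, seed=None):
    """Shuffle the run labels of a hypnogram, keeping boundaries and lengths.

    The returned hypnogram has identical run boundaries and the same multiset
    of run labels; identical labels may land adjacently (runs are not
    re-merged), so the period structure is preserved exactly.
    """
    if isinstance(hypnogram, Hypnogram):
        stages, tr = hypnogram.stages, hypnogram.tr_seconds
    else:
        stages, tr = np.asarray(hypnogram, dtype=object), 2.08
    runs = _runs(stages)
    rng = np.random.default_rng(seed)
    labels = [lab for lab, _ in runs]
    perm = rng.permutation(len(labels))
    out = np.empty(len(stages), dtype=object)
    pos = 0
    for i, (_, length) in enumerate(runs):
        out[pos:pos + length] = labels[perm[i]]
        pos += length
    return Hypnogram(stages=out, tr_seconds=tr)


def wilks_lambda(features, groups):
    """Wilks' lambda of a grouped multivariate sample.

    Returns ``(lambda, group_means, W, B)``.  Rank-deficient features are
    first projected onto their non-null principal subspace so the determinants
    are well defined.
    """
    X = np.asarray(features, dtype=float)
    groups = np.asarray(groups)
    uniq = np.unique(groups)
    if len(uniq) < 2:
        raise ValueError("need at least two groups")
    Xc = X - X.mean(axis=0)
    # project out null directions (e.g. probabilities summing to 1)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    keep = s > max(X.shape) * np.finfo(float).eps * (s[0] if s.size else 1.0)
    V = Vt[keep].T
    Z = Xc @ V
    grand = Z.mean(axis=0)
    W = np.zeros((Z.shape[1], Z.shape[1]))
    B = np.zeros_like(W)
    means = {}
    for g in uniq:
        Zg = Z[groups == g]
        mg = Zg.mean(axis=0)
        means[g] = mg
        d = Zg - mg
        W += d.T @ d
        dm = (mg - grand)[:, None]
        B += len(Zg) * (dm @ dm.T)
    sign_t, logdet_t = np.linalg.slogdet(W + B)
    if sign_t <= 0:
        raise ValueError("singular total scatter matrix; not enough samples per group")
    sign_w, logdet_w = np.linalg.slogdet(W)
    if sign_w <= 0:
        raise ValueError("singular within-group scatter matrix")
    lam = float(np.exp(logdet_w - logdet_t))
    group_means = pd.DataFrame(means).T
    return lam, group_means, W, B


def _pooled_features(features_list):
    return np.vstack(features_list)


def manova_permutation_test(features, hypnograms, n_permutations=1000, seed=None) -> TestResult:
    """Permutation MANOVA of state timecourses against the hypnograms.

    ``features`` is a per-participant list of (samples x K) matrices (soft
    state probabilities by default) aligned with the per-participant
    hypnograms.  The observed Wilks' lambda is compared against its
    distribution under within-participant period-preserving permutations of
    the stage labels; significance means the observed lambda falls in the
    null's lower tail.
    """
    if len(features) != len(hypnograms):
        raise ValueError("features and hypnograms must align per participant")
    stages = [h.stages if isinstance(h, Hypnogram) else np.asarray(h, dtype=object)
              for h in hypnograms]
    X = _pooled_features(features)
    labels = np.concatenate(stages)
    observed, _, _, _ = wilks_lambda(X, labels)
    root = _seed_sequence(seed)
    null = np.empty(n_permutations)
    n_excluded = 0
    for i, child in enumerate(root.spawn(n_permutations)):
        seeds = child.spawn(len(hypnograms))
        perm_labels = np.concatenate([
            permute_hypnogram(s, seeds[p]).stages for p, s in enumerate(stages)
        ])
        try:
            null[i], _, _, _ = wilks_lambda(X, perm_labels)
        except ValueError:
            null[i] = np.nan
            n_excluded += 1
    valid = null[~np.isnan(null)]
    p = (1.0 + np.sum(valid <= observed)) / (1.0 + len(valid))
    if n_excluded:
        logger.info("%d degenerate permutations excluded from the MANOVA null", n_excluded)
    return TestResult(statistic=observed, null=valid, p_value=float(p),
                      comparison="MANOVA Wilks' lambda", n_excluded=n_excluded)


def stage_dendrogram(group_means, pooled_within_scatter, n_within=None):
    """Single-linkage tree over stage means in Mahalanobis distance.

    ``pooled_within_scatter`` is the within-group scatter matrix W; the
    metric uses the pooled within-group covariance W / (n - g) when
    ``n_within`` (residual degrees of freedom) is given, else W itself as the
    scale.  Returns ``(linkage_matrix, stage_labels)``.
    """
    if isinstance(group_means, pd.DataFrame):
        labels = list(group_means.index)
        M = group_means.to_numpy(dtype=float)
    else:
        M = np.asarray(group_means, dtype=float)
        labels = list(range(M.shape[0]))
    S = np.asarray(pooled_within_scatter, dtype=float)
    if n_within:
        S = S / n_within
    Sinv = np.linalg.pinv(S)
    n = M.shape[0]
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = M[i] - M[j]
            D[i, j] = D[j, i] = np.sqrt(max(d @ Sinv @ d, 0.0))
    Z = linkage(squareform(D, checks=False), method="single")
    return Z, labels


def paired_t_stat(x, y):
    """Paired t statistic; 0 when all differences vanish."""
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    if len(d) < 2:
        raise ValueError("need at least two participants")
    sd = d.std(ddof=1)
    if sd == 0:
        return 0.0
    return float(d.mean() / (sd / np.sqrt(len(d))))


def paired_t_permutation(x, y, null_pairs, comparison="") -> TestResult:
    """Two-sided paired t test against a permutation null.

    ``null_pairs`` is an iterable of (x_perm, y_perm) per-participant value
    arrays computed under permuted hypnograms; pairs containing NaNs (a
    permuted scoring lacking a needed stage) are excluded and counted.
    """
    t_obs = paired_t_stat(x, y)
    null = []
    n_excluded = 0
    for xp, yp in null_pairs:
        xp, yp = np.asarray(xp, float), np.asarray(yp, float)
        if np.any(np.isnan(xp)) or np.any(np.isnan(yp)):
            n_excluded += 1
            continue
        null.append(paired_t_stat(xp, yp))
    null = np.asarray(null)
    p = (1.0 + np.sum(np.abs(null) >= abs(t_obs))) / (1.0 + len(null))
    return TestResult(statistic=t_obs, null=null, p_value=float(p),
                      comparison=comparison, n_excluded=n_excluded)


def _metric_by_stage(path, hyp, metric, K):
    """Per-(state, stage) or per-stage metric values for one participant."""
    if metric == "sensitivity":
        return sensitivity(path, hyp, K=K)
    if metric == "specificity":
        return specificity(path, hyp, K=K)
    if metric == "switching":
        return pd.Series({s: switching_rate(path, hyp, s) for s in hyp.present_stages()})
    if metric == "range":
        return pd.Series({s: range_rate(path, hyp, s) for s in hyp.present_stages()})
    raise ValueError(f"unknown metric {metric!r}")


def stage_pair_tests(paths, hypnograms, metric="sensitivity", K=None,
                     n_permutations=1000, seed=None) -> pd.DataFrame:
    """All stage-pair paired-t permutation tests for one metric.

    For ``sensitivity``/``specificity`` every state is tested on all 6 stage
    pairs; for ``switching``/``range`` the stage pairs are tested once.  One
    shared set of permuted hypnograms drives every comparison's null, as in a
    single randomisation scheme for the whole family.  Returns a tidy frame
    with columns (state, stage_a, stage_b, t, p, n_excluded).
    """
    hyps = [h if isinstance(h, Hypnogram) else Hypnogram(stages=h) for h in hypnograms]
    if K is None:
        K = int(max(np.max(p) for p in paths)) + 1
    stages_all = sorted(set.intersection(*(set(h.present_stages()) for h in hyps)),
                        key=lambda s: ["W", "N1", "N2", "N3", "W_pre", "WASO"].index(s))
    pairs = [(a, b) for i, a in enumerate(stages_all) for b in stages_all[i + 1:]]
    per_state = metric in ("sensitivity", "specificity")

    def collect(hyp_list):
        vals = [_metric_by_stage(p, h, metric, K) for p, h in zip(paths, hyp_list)]
        return vals

    observed = collect(hyps)
    root = _seed_sequence(seed)
    null_values = []
    for child in root.spawn(n_permutations):
        seeds = child.spawn(len(hyps))
        permuted = [permute_hypnogram(h, s) for h, s in zip(hyps, seeds)]
        null_values.append(collect(permuted))

    def extract(vals, stage, state=None):
        out = np.empty(len(vals))
        for i, v in enumerate(vals):
            if stage not in (v.columns if per_state else v.index):
                out[i] = np.nan
            elif per_state:
                out[i] = v.loc[state, stage]
            else:
                out[i] = v[stage]
        return out

    rows = []
    states = range(K) if per_state else [None]
    for state in states:
        for a, b in pairs:
            x = extract(observed, a, state)
            y = extract(observed, b, state)
            null_pairs = ((extract(nv, a, state), extract(nv, b, state))
                          for nv in null_values)
            res = paired_t_permutation(
                x, y, null_pairs,
                comparison=f"{metric} {a} vs {b}" + (f" state {state}" if per_state else ""))
            rows.append({
                "state": state if per_state else -1,
                "stage_a": a,
                "stage_b": b,
                "t": res.statistic,
                "p": res.p_value,
                "n_permutations": len(res.null),
                "n_excluded": res.n_excluded,
            })
    return pd.DataFrame(rows)
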