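"""Group transition matrix, sporadic-state exclusion, thresholding, modules.

The state-transition structure is treated as a directed weighted graph whose
edge weights are transition probabilities.  After dropping states that occur
in too few participants and keeping only the strongest between-state
transitions, the graph is partitioned with Newman's spectral community
detection generalised to directed graphs: the modularity matrix

    B = A - k_out k_in^T / m,   m = total edge weight,

is symmetrised for the eigen-decomposition, leading-eigenvector bisection is
refined by Kernighan-Lin style single-node moves, and the recursion continues
with the generalised modularity matrix until no split increases the directed
modularity Q = (1/m) sum_{ij in same module} B_ij.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class TransitionGraph:
    """Thresholded directed transition graph with its module partition."""

    states: np.ndarray  # retained original state ids
    A_kept: np.ndarray  # directed weighted adjacency after exclusion + threshold
    partition: dict  # state id -> module id
    Q: float
    threshold_fraction: float
    occurrence_fraction: np.ndarray  # per retained state


def group_transition_matrix(paths, participant_index=None, mode="counts",
                            K=None, model_A=None) -> np.ndarray:
    """K x K row-stochastic group transition matrix.

    ``mode="counts"``: empirical transition frequencies pooled over the given
    participants' decoded paths, never counting a transition across a
    participant boundary.  ``mode="model"``: returns the supplied VB posterior
    transition matrix (``model_A``) unchanged.  Unvisited departure states get
    a uniform row so the matrix stays row stochastic.
    """
    if mode == "model":
        if model_A is None:
            raise ValueError("mode='model' requires model_A")
        return np.asarray(model_A, dtype=float)
    if mode != "counts":
        raise ValueError(f"unknown mode {mode!r}")
    if isinstance(paths, np.ndarray) and participant_index is not None:
        seq = []
        for pid in np.unique(participant_index):
            seq.append(paths[np.asarray(participant_index) == pid])
        paths = seq
    if len(paths) == 0:
        raise ValueError("empty participant subset")
    if K is None:
        K = int(max(np.max(p) for p in paths)) + 1
    counts = np.zeros((K, K))
    for path in paths:
        path = np.asarray(path, dtype=int)
        np.add.at(counts, (path[:-1], path[1:]), 1.0)
    rows = counts.sum(axis=1)
    A = np.empty_like(counts)
    for k in range(K):
        A[k] = counts[k] / rows[k] if rows[k] > 0 else 1.0 / K
    return A


def occurrence_fractions(paths, K=None) -> np.ndarray:
    """Fraction of participants in which each state is active >= 1 sample."""
    if K is None:
        K = int(max(np.max(p) for p in paths)) + 1
    present = np.zeros(K)
    for path in paths:
        present[np.unique(np.asarray(path, dtype=int))] += 1.0
    return present / len(paths)


def exclude_sporadic(A, paths, min_fraction=0.25, K=None):
    """Drop states not occurring in strictly more than ``min_fraction`` of
    participants; returns ``(A_reduced, retained_ids, occurrence_fraction)``."""
    if not 0.0 <= min_fraction <= 1.0:
        raise ValueError("min_fraction must lie in [0, 1]")
    A = np.asarray(A, dtype=float)
    frac = occurrence_fractions(paths, K=A.shape[0] if K is None else K)
    retained = np.flatnonzero(frac > min_fraction)
    return A[np.ix_(retained, retained)], retained, frac[retained]


def threshold_transitions(A_reduced, keep_fraction=0.21, keep_self=False) -> np.ndarray:
    """Keep only the strongest between-state transitions.

    Self-transitions are removed first (they would dominate any threshold);
    then the top ``round(keep_fraction * #off-diagonal entries)`` entries by
    probability are retained.  Ties at the cut are broken deterministically by
    (departure id, destination id) lexicographic order.
    """
    if not 0.0 < keep_fraction <= 1.0:
        raise ValueError("keep_fraction must lie in (0, 1]")
    A = np.asarray(A_reduced, dtype=float).copy()
    n = A.shape[0]
    if not keep_self:
        np.fill_diagonal(A, 0.0)
        candidates = [(i, j) for i in range(n) for j in range(n) if i != j]
    else:
        candidates = [(i, j) for i in range(n) for j in range(n)]
    n_keep = int(round(keep_fraction * len(candidates)))
    # sort by (-weight, i, j): strongest first, lexicographic tie-break
    order = sorted(candidates, key=lambda ij: (-A[ij], ij[0], ij[1]))
    out = np.zeros_like(A)
    for i, j in order[:n_keep]:
        out[i, j] = A[i, j]
    return out


# ---------------------------------------------------------------------------
# Newman spectral community detection (directed modularity)
# ---------------------------------------------------------------------------

def directed_modularity(A, labels) -> float:
    """Q = (1/m) sum_{ij: c_i = c_j} (A_ij - k_out_i k_in_j / m)."""
    A = np.asarray(A, dtype=float)
    m = A.sum()
    if m <= 0:
        raise ValueError("graph has no weight")
    kout = A.sum(axis=1)
    kin = A.sum(axis=0)
    B = A - np.outer(kout, kin) / m
    labels = np.asarray(labels)
    same = labels[:, None] == labels[None, :]
    return float((B * same).sum() / m)


def _kl_refine(Bg, s):
    """Kernighan-Lin style refinement: greedy single-node moves on s in {-1,1}."""
    n = len(s)
    improved = True
    while improved:
        improved = False
        current = s @ Bg @ s
        for i in range(n):
            s[i] = -s[i]
            trial = s @ Bg @ s
            if trial > current + 1e-12:
                current = trial
                improved = True
            else:
                s[i] = -s[i]
    return s


def _bisect(Bg):
    """Best bisection of a (generalised) modularity matrix.

    Candidate splits: the sign pattern of the leading eigenvector and every
    contiguous split of the eigenvector-ordered vertices (the standard sweep),
    each polished by Kernighan-Lin moves; the candidate with the largest
    s^T Bg s wins.
    """
    n = Bg.shape[0]
    vals, vecs = np.linalg.eigh(Bg)
    lead = vecs[:, -1]
    candidates = []
    s0 = np.where(lead >= 0, 1.0, -1.0)
    if np.all(s0 == s0[0]):
        s0[np.argmin(lead)] = -s0[0]
    candidates.append(s0)
    order = np.argsort(lead)
    for cut in range(1, n):
        s = np.ones(n)
        s[order[:cut]] = -1.0
        candidates.append(s)
    best_s, best_val = None, -np.inf
    for s in candidates:
        s = _kl_refine(Bg, s.copy())
        val = s @ Bg @ s
        if val > best_val:
            best_val, best_s = val, s
    return np.sign(best_s).astype(int)


def newman_modules(adjacency):
    """Partition a directed weighted graph by spectral modularity maximisation.

    Returns ``(labels, Q)``; ``labels[i]`` is the module id of node i and Q is
    the directed modularity of the partition.  A single-node graph yields one
    module with Q = 0.
    """
    A = np.asarray(adjacency, dtype=float)
    n = A.shape[0]
    if n == 0:
        raise ValueError("empty graph")
    if n == 1:
        return np.zeros(1, dtype=int), 0.0
    m = A.sum()
    if m <= 0:
        raise ValueError("graph has no weight")
    kout = A.sum(axis=1)
    kin = A.sum(axis=0)
    B = A - np.outer(kout, kin) / m
    Bs = 0.5 * (B + B.T)

    labels = np.zeros(n, dtype=int)
    next_id = [1]

    def split(indices):
        if len(indices) < 2:
            return
        Bsub = Bs[np.ix_(indices, indices)]
        # generalised modularity matrix for subdivision
        Bg = Bsub - np.diag(Bsub.sum(axis=1))
        s = _bisect(Bg)
        gain = (s @ Bg @ s) / (2.0 * m)
        if gain <= 1e-12 or np.all(s == s[0]):
            return
        left = indices[s > 0]
        right = indices[s < 0]
        new = next_id[0]
        next_id[0] += 1
        labels[right] = new
        split(left)
        split(right)

    # top-level split uses the plain modularity matrix (row sums of Bs are not
    # zero for directed graphs, so the generalised form with the diagonal
    # correction is used uniformly; at the top level the correction equals the
    # exact delta-Q for a bisection of the whole graph)
    split(np.arange(n))
    labels = _global_refine(Bs, labels)
    best_labels, best_val = labels, _objective(Bs, labels)
    # multistart polish: the refinement landscape has occasional local optima,
    # so also refine from singletons and a few seeded random partitions
    rng = np.random.default_rng(0)
    starts = [np.arange(n)]
    starts += [rng.integers(0, max(2, n // 2), size=n) for _ in range(8)]
    for start in starts:
        cand = _global_refine(Bs, np.asarray(start, dtype=int))
        val = _objective(Bs, cand)
        if val > best_val + 1e-12:
            best_val, best_labels = val, cand
    labels = best_labels
    # compact module ids
    _, labels = np.unique(labels, return_inverse=True)
    return labels.astype(int), directed_modularity(A, labels)


def _objective(Bs, labels):
    same = labels[:, None] == labels[None, :]
    return float((Bs * same).sum())


def _move_gain(Bs, labels, i, target):
    """Objective change from moving node i to module ``target``."""
    same_new = labels == target
    same_old = labels == labels[i]
    same_old = same_old.copy()
    same_old[i] = False
    return 2.0 * (Bs[i, same_new].sum() - Bs[i, same_old].sum())


def _global_refine(Bs, labels):
    """Polish a partition by node moves, KL chains and module merges.

    Works on the symmetrised modularity matrix, whose same-module sum is
    proportional to the directed Q.  Three interleaved strategies until none
    improves: (a) greedy single-node moves (including into a fresh module);
    (b) a Kernighan-Lin chain — every node moved exactly once to its best
    alternative even when the step loses, keeping the best configuration seen
    along the chain, which escapes single-move local optima; (c) merging the
    best pair of modules.
    """
    labels = labels.copy()
    n = len(labels)

    def greedy_moves(lab):
        improved = False
        while True:
            moved = False
            for i in range(n):
                options = set(lab.tolist()) | {lab.max() + 1}
                options.discard(lab[i])
                gains = {t: _move_gain(Bs, lab, i, t) for t in options}
                best_t = max(gains, key=gains.get)
                if gains[best_t] > 1e-12:
                    lab[i] = best_t
                    moved = improved = True
            if not moved:
                return improved

    def kl_chain(lab):
        start_val = _objective(Bs, lab)
        work = lab.copy()
        best_val, best_lab = start_val, lab.copy()
        frozen = np.zeros(n, dtype=bool)
        for _ in range(n):
            cand = []
            for i in np.flatnonzero(~frozen):
                options = set(work.tolist()) | {work.max() + 1}
                options.discard(work[i])
                for t in options:
                    cand.append((_move_gain(Bs, work, i, t), i, t))
            if not cand:
                break
            g, i, t = max(cand)
            work[i] = t
            frozen[i] = True
            val = _objective(Bs, work)
            if val > best_val + 1e-12:
                best_val, best_lab = val, work.copy()
        if best_val > start_val + 1e-12:
            lab[:] = best_lab
            return True
        return False

    def merge_pass(lab):
        mods = np.unique(lab)
        best = (1e-12, None)
        for a_i, a in enumerate(mods):
            for b in mods[a_i + 1:]:
                in_a, in_b = lab == a, lab == b
                gain = 2.0 * Bs[np.ix_(in_a, in_b)].sum()
                if gain > best[0]:
                    best = (gain, (a, b))
        if best[1] is not None:
            a, b = best[1]
            lab[lab == b] = a
            return True
        return False

    while True:
        any_gain = greedy_moves(labels)
        any_gain = kl_chain(labels) or any_gain
        any_gain = merge_pass(labels) or any_gain
        if not any_gain:
            return labels


# ---------------------------------------------------------------------------
# assembly + export
# ---------------------------------------------------------------------------

def build_transition_graph(paths, keep_fraction=0.21, min_fraction=0.25,
                           mode="counts", model_A=None, K=None) -> TransitionGraph:
    """Full chain: group matrix -> sporadic exclusion -> threshold -> modules."""
    if K is None:
        K = int(max(np.max(p) for p in paths)) + 1
    A = group_transition_matrix(paths, mode=mode, K=K, model_A=model_A)
    A_red, retained, occ = exclude_sporadic(A, paths, min_fraction=min_fraction, K=K)
    if len(retained) == 0:
        raise ValueError("all states excluded as sporadic")
    A_kept = threshold_transitions(A_red, keep_fraction=keep_fraction)
    labels, Q = newman_modules(A_kept)
    partition = {int(retained[i]): int(labels[i]) for i in range(len(retained))}
    return TransitionGraph(states=retained, A_kept=A_kept, partition=partition,
                           Q=Q, threshold_fraction=keep_fraction,
                           occurrence_fraction=occ)


def export_transition_map(graph: TransitionGraph, specificity_matrix, outdir=None):
    """Serialise the transition map: edge list, node table, partition JSON.

    ``specificity_matrix`` is the state x stage specificity DataFrame; each
    node carries its module id, occurrence fraction and per-stage specificity
    shares (the pie-chart weights of the map rendering).  Returns
    ``(edges, nodes)`` DataFrames; when ``outdir`` is given, also writes
    edges.tsv, nodes.tsv and partition.json.
    """
    states = graph.states
    edges = []
    for i, si in enumerate(states):
        for j, sj in enumerate(states):
            if graph.A_kept[i, j] > 0:
                edges.append({"source": int(si), "target": int(sj),
                              "probability": float(graph.A_kept[i, j]),
                              "retained": True})
    edges = pd.DataFrame(edges, columns=["source", "target", "probability", "retained"])
    nodes = []
    for i, si in enumerate(states):
        row = {"state": int(si), "module": graph.partition[int(si)],
               "occurrence_fraction": float(graph.occurrence_fraction[i])}
        spec_row = specificity_matrix.loc[int(si)]
        total = spec_row.sum()
        for stage in specificity_matrix.columns:
            row[f"specificity_{stage}"] = float(spec_row[stage] / total) if total > 0 else 0.0
        nodes.append(row)
    nodes = pd.DataFrame(nodes)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        edges.to_csv(outdir / "edges.tsv", sep="\t", index=False)
        nodes.to_csv(outdir / "nodes.tsv", sep="\t", index=False)
        with open(outdir / "partition.json", "w") as fh:
            json.dump({"partition": {str(k): v for k, v in graph.partition.items()},
                       "Q": graph.Q,
                       "threshold_fraction": graph.threshold_fraction}, fh, indent=2)
    return edges, nodes
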