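"""Temporal statistics linking decoded brain states to the hypnogram.

All metrics operate on the hard state path (argmax of the posterior state
probabilities), matching definitions that count the time "in which a state was
active"; soft (probability-weighted) variants of sensitivity and specificity
are available behind the ``soft_gamma`` argument.

Definitions, for a recording sampled every ``tr_seconds``:

- fractional occupancy of state k: fraction of (masked) samples with path = k;
- sensitivity of state k for stage s: time(path = k and stage = s) / time(stage = s)
  — columns over states sum to 1 for each stage present;
- specificity of state k for stage s: time(path = k and stage = s) / time(path = k),
  i.e. P(stage s | state k active) — rows over stages sum to 1 for occupied states;
- mean lifetime of state k: average contiguous run length x TR, in seconds;
- switching rate within a stage: transitions between distinct states, both
  endpoints inside the stage, divided by the stage's total time (transitions
  straddling a stage boundary count for neither stage);
- range rate within a stage: number of unique states visited divided by the
  stage's total time;
- WASO relabelling: wake samples after the first N2 sample become "WASO",
  earlier ones "W_pre".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

STAGE_ORDER = ("W", "N1", "N2", "N3", "W_pre", "WASO")


@dataclass
class Hypnogram:
    """Per-sample stage labels on the fMRI sampling grid."""

    stages: np.ndarray
    tr_seconds: float = 2.08

    def __post_init__(self):
        self.stages = np.asarray(self.stages, dtype=object)
        bad = set(np.unique(self.stages)) - set(STAGE_ORDER)
        if bad:
            raise ValueError(f"unknown stage labels: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.stages)

    def present_stages(self):
        present = set(self.stages.tolist())
        return [s for s in STAGE_ORDER if s in present]


def read_hypnogram(path, tr_seconds=2.08) -> Hypnogram:
    """Read a two-column (sample_index, stage) TSV."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValueError("hypnogram file needs sample_index and stage columns")
    df = df.sort_values(df.columns[0])
    return Hypnogram(stages=df.iloc[:, 1].to_numpy(dtype=object), tr_seconds=tr_seconds)


def read_epoch_hypnogram(path, n_samples, tr_seconds=2.08, epoch_seconds=30.0) -> Hypnogram:
    """Expand an epoch-format (epoch_start_seconds, stage) TSV to the TR grid.

    Each fMRI sample takes the stage of the epoch containing its acquisition
    midpoint ``(i + 0.5) * tr_seconds``.
    """
    df = pd.read_csv(path, sep="\t")
    starts = df.iloc[:, 0].to_numpy(dtype=float)
    labels = df.iloc[:, 1].to_numpy(dtype=object)
    order = np.argsort(starts)
    starts, labels = starts[order], labels[order]
    mid = (np.arange(n_samples) + 0.5) * tr_seconds
    idx = np.searchsorted(starts, mid, side="right") - 1
    if np.any(idx < 0) or np.any(mid >= starts[-1] + epoch_seconds):
        raise ValueError("fMRI samples fall outside the scored epochs")
    return Hypnogram(stages=labels[idx], tr_seconds=tr_seconds)


def _as_stage_array(hypnogram):
    if isinstance(hypnogram, Hypnogram):
        return hypnogram.stages, hypnogram.tr_seconds
    return np.asarray(hypnogram, dtype=object), 2.08


def fractional_occupancy(path, K, mask=None) -> np.ndarray:
    """Fraction of (masked) samples each state is active; sums to 1."""
    path = np.asarray(path, dtype=int)
    if mask is not None:
        mask = np.asarray(mask)
        if mask.dtype == bool:
            sel = path[mask]
        else:
            sel = path[np.asarray(mask, dtype=int)]
        if sel.size == 0:
            raise ValueError("mask selects no samples")
    else:
        sel = path
    counts = np.bincount(sel, minlength=K).astype(float)
    return counts / counts.sum()


def sensitivity(path, hypnogram, K=None, soft_gamma=None) -> pd.DataFrame:
    """State x stage sensitivity matrix: P(state active | stage).

    Stages absent from the recording are omitted (and logged), never
    NaN-filled.  With ``soft_gamma`` the per-sample posterior probabilities
    replace the hard indicator.
    """
    stages, _ = _as_stage_array(hypnogram)
    path = np.asarray(path, dtype=int)
    if len(path) != len(stages):
        raise ValueError("path and hypnogram lengths differ")
    K = int(path.max()) + 1 if K is None else int(K)
    present = [s for s in STAGE_ORDER if s in set(stages.tolist())]
    absent = sorted(set(STAGE_ORDER[:4]) - set(present))
    if absent:
        logger.info("stages %s absent from recording; columns omitted", absent)
    out = np.zeros((K, len(present)))
    for j, s in enumerate(present):
        in_stage = stages == s
        denom = in_stage.sum()
        if soft_gamma is not None:
            out[:, j] = np.asarray(soft_gamma)[in_stage].sum(axis=0) / denom
        else:
            out[:, j] = np.bincount(path[in_stage], minlength=K) / denom
    return pd.DataFrame(out, index=pd.RangeIndex(K, name="state"), columns=present)


def specificity(path, hypnogram, K=None, soft_gamma=None) -> pd.DataFrame:
    """State x stage specificity matrix: P(stage | state active).

    Rows of states that are never active are all-zero and logged.
    """
    stages, _ = _as_stage_array(hypnogram)
    path = np.asarray(path, dtype=int)
    if len(path) != len(stages):
        raise ValueError("path and hypnogram lengths differ")
    K = int(path.max()) + 1 if K is None else int(K)
    present = [s for s in STAGE_ORDER if s in set(stages.tolist())]
    out = np.zeros((K, len(present)))
    for k in range(K):
        if soft_gamma is not None:
            weights = np.asarray(soft_gamma)[:, k]
        else:
            weights = (path == k).astype(float)
        total = weights.sum()
        if total == 0:
            logger.info("state %d never active; specificity row left at zero", k)
            continue
        for j, s in enumerate(present):
            out[k, j] = weights[stages == s].sum() / total
    return pd.DataFrame(out, index=pd.RangeIndex(K, name="state"), columns=present)


def mean_lifetime(path, tr_seconds=2.08, K=None) -> pd.Series:
    """Mean contiguous dwell time per state, in seconds; NaN if never visited."""
    path = np.asarray(path)
    if path.size == 0:
        raise ValueError("empty path")
    K = int(path.max()) + 1 if K is None else int(K)
    change = np.flatnonzero(path[1:] != path[:-1])
    starts = np.concatenate([[0], change + 1])
    lengths = np.diff(np.concatenate([starts, [len(path)]]))
    labels = path[starts]
    out = np.full(K, np.nan)
    for k in range(K):
        runs = lengths[labels == k]
        if runs.size:
            out[k] = runs.mean() * tr_seconds
    return pd.Series(out, index=pd.RangeIndex(K, name="state"), name="mean_lifetime_seconds")


def switching_rate(path, hypnogram, stage) -> float:
    """Within-stage state transitions per second.

    Counts sample pairs (t, t+1) with both samples in the stage and different
    states, divided by the stage's total time; boundary-straddling switches
    count for neither stage.
    """
    stages, tr = _as_stage_array(hypnogram)
    path = np.asarray(path, dtype=int)
    in_stage = stages == stage
    n_stage = int(in_stage.sum())
    if n_stage == 0:
        raise ValueError(f"stage {stage!r} not present in hypnogram")
    both = in_stage[:-1] & in_stage[1:]
    n_switch = int(np.sum(both & (path[:-1] != path[1:])))
    return n_switch / (n_stage * tr)


def range_rate(path, hypnogram, stage) -> float:
    """Unique states visited within a stage per second of that stage."""
    stages, tr = _as_stage_array(hypnogram)
    path = np.asarray(path, dtype=int)
    in_stage = stages == stage
    n_stage = int(in_stage.sum())
    if n_stage == 0:
        raise ValueError(f"stage {stage!r} not present in hypnogram")
    n_unique = len(np.unique(path[in_stage]))
    return n_unique / (n_stage * tr)


def relabel_waso(hypnogram) -> Hypnogram:
    """Split wakefulness into pre-sleep wake and wake-after-sleep-onset.

    Every W sample after the participant's first N2 sample becomes WASO;
    earlier W samples become W_pre.  Without any N2 all W become W_pre.
    """
    stages, tr = _as_stage_array(hypnogram)
    out = stages.copy()
    n2 = np.flatnonzero(stages == "N2")
    first_n2 = n2[0] if n2.size else len(stages)
    for i in np.flatnonzero(stages == "W"):
        out[i] = "WASO" if i > first_n2 else "W_pre"
    return Hypnogram(stages=out, tr_seconds=tr)


def metrics_table(paths, hypnograms, K, tr_seconds=2.08) -> pd.DataFrame:
    """Tidy long-format per-participant metrics table.

    One row per (participant, state, stage) carrying sensitivity, specificity
    and within-stage fractional occupancy, plus per-(participant, state) mean
    lifetimes and per-(participant, stage) switching and range rates
    (replicated down their groups so the table stays rectangular).
    """
    rows = []
    for p, (path, hyp) in enumerate(zip(paths, hypnograms)):
        if not isinstance(hyp, Hypnogram):
            hyp = Hypnogram(stages=hyp, tr_seconds=tr_seconds)
        sens = sensitivity(path, hyp, K=K)
        spec = specificity(path, hyp, K=K)
        life = mean_lifetime(path, tr_seconds=hyp.tr_seconds, K=K)
        for stage in sens.columns:
            sw = switching_rate(path, hyp, stage)
            rr = range_rate(path, hyp, stage)
            mask = hyp.stages == stage
            fo = fractional_occupancy(path, K, mask=mask)
            for k in range(K):
                rows.append({
                    "participant": p,
                    "state": k,
                    "stage": stage,
                    "sensitivity": sens.loc[k, stage],
                    "specificity": spec.loc[k, stage],
                    "fractional_occupancy": fo[k],
                    "mean_lifetime_seconds": life[k],
                    "switching_rate": sw,
                    "range_rate": rr,
                })
    return pd.DataFrame(rows)
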