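"""Synthetic cohorts with planted HMM structure coupled to a hypnogram.

Each participant's recording is a Markov chain over ``K_true`` latent states,
each state emitting from its own multivariate Gaussian (mean map + covariance),
with the chain tilted toward stage-consistent states by per-stage reweighting
of the transition rows.  An AR(1) blend mimics the slow (0.01-0.1 Hz
band-passed) temporal structure of BOLD signals.  Because the coupling acts on
the transition kernel rather than the emissions, the cohort remains Markovian
conditional on the hypnogram, so HMM parameter recovery is a fair test.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

STAGES = ("W", "N1", "N2", "N3")


def _check_row_stochastic(trans: np.ndarray, atol: float = 1e-12) -> None:
    trans = np.asarray(trans, dtype=float)
    if trans.ndim != 2 or trans.shape[0] != trans.shape[1]:
        raise ValueError("transition matrix must be square")
    if np.any(trans < -atol):
        raise ValueError("transition matrix has negative entries")
    rows = trans.sum(axis=1)
    if not np.allclose(rows, 1.0, atol=1e-9):
        raise ValueError(f"transition rows must sum to 1 (got {rows})")


def _check_spd(cov: np.ndarray, label: str = "covariance") -> None:
    cov = np.asarray(cov, dtype=float)
    if not np.allclose(cov, cov.T, atol=1e-10):
        raise ValueError(f"{label} is not symmetric")
    try:
        np.linalg.cholesky(cov + 1e-12 * np.eye(cov.shape[0]))
    except np.linalg.LinAlgError as exc:
        raise ValueError(f"{label} is not positive definite") from exc


@dataclass
class GenerativeSpec:
    """Full description of a planted cohort.

    ``stage_program`` is an ordered list of ``(stage, duration_in_samples)``
    runs per participant; durations must sum to ``n_samples``.
    ``stage_state_weights`` maps each stage label to a strictly positive (or
    degenerate one-hot) weight vector over the ``K_true`` states used to tilt
    the transition rows while that stage is scored.
    """

    n_participants: int = 6
    n_samples: int = 600
    n_regions: int = 12
    K_true: int = 4
    means: np.ndarray = None
    covariances: np.ndarray = None
    trans: np.ndarray = None
    stage_program: list = None
    stage_state_weights: dict = None
    ar_coeff: float = 0.4
    tr_seconds: float = 2.08
    seed: int = 0

    def validate(self) -> None:
        if self.means.shape != (self.K_true, self.n_regions):
            raise ValueError("means must be K_true x n_regions")
        if len(self.covariances) != self.K_true:
            raise ValueError("one covariance per state required")
        for k, cov in enumerate(self.covariances):
            _check_spd(np.asarray(cov), f"covariance of state {k}")
        _check_row_stochastic(self.trans)
        if not 0.0 <= self.ar_coeff < 1.0:
            raise ValueError("ar_coeff must lie in [0, 1)")
        for p, program in enumerate(self.stage_program):
            total = sum(d for _, d in program)
            if total != self.n_samples:
                raise ValueError(
                    f"participant {p}: stage durations sum to {total}, expected {self.n_samples}"
                )
            for stage, _ in program:
                if stage not in STAGES:
                    raise ValueError(f"unknown stage label {stage!r}")
        for stage, w in self.stage_state_weights.items():
            w = np.asarray(w, dtype=float)
            if w.shape != (self.K_true,) or np.any(w < 0) or w.sum() <= 0:
                raise ValueError(f"invalid state weights for stage {stage!r}")


def default_spec(
    n_participants: int = 6,
    n_samples: int = 600,
    n_regions: int = 12,
    K_true: int = 4,
    mean_separation: float = 3.0,
    self_transition: float = 0.90,
    stage_tilt: float = 12.0,
    ar_coeff: float = 0.4,
    seed: int = 0,
) -> GenerativeSpec:
    """Build the default toy cohort specification.

    State means are mutually orthogonal region patterns scaled so the
    between-state mean separation is ``mean_separation`` times the unit noise
    SD; covariances are identity; switching is sticky with uniform
    off-diagonal mass.  The stage program walks W -> N1 -> N2 -> N3 -> W
    (the final W block makes WASO selectors exercisable), and each stage's
    weight vector favours state ``min(stage_index, K_true - 1)`` by a factor
    ``stage_tilt``.
    """
    rng = np.random.default_rng(seed)
    raw = rng.standard_normal((K_true, n_regions))
    q, _ = np.linalg.qr(raw.T)  # orthonormal columns -> orthogonal state patterns
    # pairwise distance between two orthogonal vectors of norm r is r*sqrt(2)
    means = q[:, :K_true].T * (mean_separation / np.sqrt(2.0))
    covariances = np.array([np.eye(n_regions) for _ in range(K_true)])
    off = (1.0 - self_transition) / (K_true - 1) if K_true > 1 else 0.0
    trans = np.full((K_true, K_true), off)
    np.fill_diagonal(trans, self_transition if K_true > 1 else 1.0)

    # per-participant stage program; block lengths vary mildly by participant
    base = np.array([0.25, 0.15, 0.30, 0.20, 0.10])  # W, N1, N2, N3, WASO(W)
    stage_seq = ["W", "N1", "N2", "N3", "W"]
    programs = []
    for p in range(n_participants):
        frac = base + rng.uniform(-0.02, 0.02, size=5)
        frac = np.clip(frac, 0.05, None)
        frac /= frac.sum()
        durs = np.maximum(1, np.round(frac * n_samples).astype(int))
        durs[-1] = n_samples - durs[:-1].sum()
        if durs[-1] < 1:
            durs[-1] = 1
            durs[0] = n_samples - durs[1:].sum()
        programs.append(list(zip(stage_seq, durs.tolist())))

    weights = {}
    for i, stage in enumerate(STAGES):
        w = np.ones(K_true)
        w[min(i, K_true - 1)] = stage_tilt
        weights[stage] = w

    return GenerativeSpec(
        n_participants=n_participants,
        n_samples=n_samples,
        n_regions=n_regions,
        K_true=K_true,
        means=means,
        covariances=covariances,
        trans=trans,
        stage_program=programs,
        stage_state_weights=weights,
        ar_coeff=ar_coeff,
        seed=seed,
    )


@dataclass
class SyntheticCohort:
    """Generated cohort plus the planted ground truth."""

    data: list  # per-participant (n_samples x n_regions) arrays
    hypnograms: list  # per-participant per-sample stage-label arrays
    truth_paths: list  # per-participant planted state paths
    spec: GenerativeSpec = field(repr=False, default=None)

    def __post_init__(self):
        for X, hyp, path in zip(self.data, self.hypnograms, self.truth_paths):
            if not (len(X) == len(hyp) == len(path)):
                raise ValueError("data, hypnogram and truth path lengths must match")


def expand_stage_program(program) -> np.ndarray:
    """Per-sample stage labels from an ordered (stage, duration) run list."""
    out = []
    for stage, dur in program:
        out.extend([stage] * int(dur))
    return np.array(out, dtype=object)


def sample_state_path(trans, stage_labels, stage_state_weights, n_samples, seed):
    """Sample a Markov state path whose kernel is tilted per stage.

    At sample ``t`` the one-step kernel is ``trans`` with each row multiplied
    elementwise by the weight vector of ``stage_labels[t]`` and renormalised.
    The initial state is drawn from the stationary structure of the first
    stage's tilted weights (uniform prior times the weights, renormalised).
    """
    trans = np.asarray(trans, dtype=float)
    _check_row_stochastic(trans)
    K = trans.shape[0]
    if len(stage_labels) < n_samples:
        raise ValueError("stage_labels shorter than n_samples")
    weights = {}
    for stage, w in stage_state_weights.items():
        w = np.asarray(w, dtype=float)
        if np.any(w < 0) or w.sum() <= 0:
            raise ValueError(f"weights for stage {stage!r} must be non-negative with positive sum")
        weights[stage] = w
    rng = np.random.default_rng(seed)
    path = np.empty(n_samples, dtype=int)

    w0 = weights[stage_labels[0]]
    p0 = w0 / w0.sum()
    path[0] = rng.choice(K, p=p0)
    for t in range(1, n_samples):
        w = weights[stage_labels[t]]
        row = trans[path[t - 1]] * w
        s = row.sum()
        if s <= 0:
            raise ValueError(
                f"re-weighted transition row from state {path[t - 1]} at sample {t} sums to zero"
            )
        path[t] = rng.choice(K, p=row / s)
    return path


def emit_observations(path, means, covariances, ar_coeff, seed):
    """Emit Gaussian observations along a state path with AR(1) blending.

    Sample ``t`` is drawn from the Gaussian of ``path[t]`` and blended as
    ``y_t = ar_coeff * y_{t-1} + (1 - ar_coeff) * x_t``; the first sample is
    the raw draw.
    """
    path = np.asarray(path, dtype=int)
    means = np.asarray(means, dtype=float)
    K, n_regions = means.shape
    if path.min() < 0 or path.max() >= K:
        raise ValueError("path values must index rows of means")
    chols = []
    for k in range(K):
        cov = np.asarray(covariances[k], dtype=float)
        if not np.allclose(cov, cov.T, atol=1e-10):
            raise ValueError(f"covariance of state {k} is not symmetric")
        if np.allclose(cov, 0.0):
            chols.append(np.zeros_like(cov))
            continue
        try:
            chols.append(np.linalg.cholesky(cov))
        except np.linalg.LinAlgError as exc:
            raise ValueError(f"covariance of state {k} is not positive definite") from exc
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((len(path), n_regions))
    x = means[path].copy()
    for k in range(K):
        mask = path == k
        if mask.any():
            x[mask] += z[mask] @ chols[k].T
    if ar_coeff == 0.0:
        return x
    y = np.empty_like(x)
    y[0] = x[0]
    for t in range(1, len(path)):
        y[t] = ar_coeff * y[t - 1] + (1.0 - ar_coeff) * x[t]
    return y


def generate_cohort(spec: GenerativeSpec) -> SyntheticCohort:
    """Generate a full cohort; bit-reproducible from ``spec.seed``."""
    spec.validate()
    root = np.random.SeedSequence(spec.seed)
    seeds = root.spawn(spec.n_participants)
    data, hyps, paths = [], [], []
    for p in range(spec.n_participants):
        child = seeds[p].spawn(2)
        stages = expand_stage_program(spec.stage_program[p])
        path = sample_state_path(
            spec.trans, stages, spec.stage_state_weights, spec.n_samples, child[0]
        )
        X = emit_observations(path, spec.means, spec.covariances, spec.ar_coeff, child[1])
        data.append(X)
        hyps.append(stages)
        paths.append(path)
    return SyntheticCohort(data=data, hypnograms=hyps, truth_paths=paths, spec=spec)


def write_cohort(cohort: SyntheticCohort, outdir) -> None:
    """Write per-participant TSV matrices, hypnograms and the truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for p, (X, hyp, path) in enumerate(
        zip(cohort.data, cohort.hypnograms, cohort.truth_paths)
    ):
        np.savetxt(outdir / f"participant_{p:02d}_timecourses.tsv", X, delimiter="\t")
        with open(outdir / f"participant_{p:02d}_hypnogram.tsv", "w") as fh:
            fh.write("sample_index\tstage\n")
            for i, s in enumerate(hyp):
                fh.write(f"{i}\t{s}\n")
    truth = {
        "paths": [p.tolist() for p in cohort.truth_paths],
        "K_true": int(cohort.spec.K_true),
        "means": cohort.spec.means.tolist(),
        "trans": cohort.spec.trans.tolist(),
        "tr_seconds": cohort.spec.tr_seconds,
        "seed": int(cohort.spec.seed),
    }
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth, fh)


def read_cohort(indir):
    """Read matrices and hypnograms written by :func:`write_cohort`.

    Returns ``(data, hypnograms)`` lists ordered by participant index;
    ``hypnograms`` is ``None`` when any participant lacks a hypnogram file
    (staging-dependent analyses are then unavailable).
    """
    indir = Path(indir)
    data, hyps = [], []
    tc_files = sorted(indir.glob("participant_*_timecourses.tsv"))
    if not tc_files:
        raise ValueError(f"no participant_*_timecourses.tsv files in {indir}")
    for tc in tc_files:
        data.append(np.loadtxt(tc, delimiter="\t"))
        hyp_file = indir / tc.name.replace("timecourses", "hypnogram")
        if hyps is not None and hyp_file.exists():
            stages = np.loadtxt(hyp_file, delimiter="\t", skiprows=1, dtype=str,
                                usecols=1)
            hyps.append(stages.astype(object))
        else:
            hyps = None
    return data, hyps
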