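"""End-to-end orchestration: ingestion -> preprocess -> HMM -> metrics -> stats
-> transition graph, driven by a single config with mandatory seeding.

Every stage writes plain TSV/JSON so each can be re-run and inspected
independently; a manifest records the config hash, seeds and every output
file.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import synthetic
from .hmm import GaussianHMM, scan_model_orders
from .metrics import Hypnogram, metrics_table, read_hypnogram
from .preprocess import preprocess_cohort
from .stats import manova_permutation_test, stage_pair_tests, wilks_lambda, stage_dendrogram
from .transitions import build_transition_graph, export_transition_map
from .metrics import specificity as specificity_matrix

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Single source of truth for a pipeline run."""

    output_dir: str = "sleepstates_out"
    seed: int = 0
    tr_seconds: float = 2.08
    # data source: either a directory of TSVs or synthetic generation
    data_dir: str | None = None
    synthetic_cohort: bool = True
    n_participants: int = 6
    n_samples: int = 600
    n_regions: int = 12
    K_true: int = 4
    # preprocessing
    bandpass_enabled: bool = False
    bandpass_low: float = 0.01
    bandpass_high: float = 0.1
    bandpass_order: int = 6
    pca_components: int | None = None
    pca_variance_target: float | None = None
    # model
    K: int = 19
    K_list: list | None = None
    n_init: int = 5
    tol: float = 1e-5
    max_iter: int = 500
    trans_stickiness: float = 5.0
    # stats
    n_permutations: int = 1000
    alpha: float = 0.05
    # transition graph
    keep_fraction: float = 0.21
    min_participant_fraction: float = 0.25
    transition_mode: str = "counts"

    @classmethod
    def from_file(cls, path):
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def to_dict(self):
        return asdict(self)


def select_all_stage_participants(hypnograms):
    """Indices of participants whose hypnogram contains all of W, N1, N2, N3."""
    out = []
    for p, hyp in enumerate(hypnograms):
        stages = hyp.stages if isinstance(hyp, Hypnogram) else np.asarray(hyp, dtype=object)
        if {"W", "N1", "N2", "N3"} <= set(stages.tolist()):
            out.append(p)
    return out


def select_waso_participants(hypnograms):
    """Indices of participants with >= 1 wake sample after their first N2."""
    out = []
    for p, hyp in enumerate(hypnograms):
        stages = hyp.stages if isinstance(hyp, Hypnogram) else np.asarray(hyp, dtype=object)
        n2 = np.flatnonzero(stages == "N2")
        if n2.size and np.any(stages[n2[0] + 1:] == "W"):
            out.append(p)
    return out


def _config_hash(config: PipelineConfig) -> str:
    return hashlib.sha256(
        json.dumps(config.to_dict(), sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage; returns a result bundle and writes all outputs.

    Stage order: ingestion (synthetic or from ``data_dir``) -> per-participant
    standardisation (+ optional band-pass) -> PCA -> VB-HMM fit (or model-order
    scan when ``K_list`` is set) -> state metrics on the all-stage subset ->
    permutation MANOVA + stage-pair tests -> transition graph.  Stages needing
    hypnograms are skipped with a notice when none are available.  Any stage
    failure raises with the stage name; earlier outputs remain on disk.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"config": config.to_dict(), "config_hash": _config_hash(config),
                "seed": config.seed, "stages": {}, "outputs": []}
    bundle = {}
    t_all = time.time()

    def _stage(name):
        logger.info("stage %s starting (seed=%s)", name, config.seed)
        manifest["stages"][name] = {"started": time.time() - t_all}
        return time.time()

    def _done(name, t0, *files):
        manifest["stages"][name]["seconds"] = round(time.time() - t0, 3)
        manifest["outputs"].extend(str(f) for f in files)
        logger.info("stage %s done in %.1fs", name, time.time() - t0)

    try:
        # ---- ingestion ----------------------------------------------------
        t0 = _stage("ingest")
        if config.synthetic_cohort and config.data_dir is None:
            spec = synthetic.default_spec(
                n_participants=config.n_participants,
                n_samples=config.n_samples,
                n_regions=config.n_regions,
                K_true=config.K_true,
                seed=config.seed,
            )
            cohort = synthetic.generate_cohort(spec)
            data, hyps = cohort.data, cohort.hypnograms
            synthetic.write_cohort(cohort, out / "cohort")
            bundle["cohort"] = cohort
        else:
            data, hyps = synthetic.read_cohort(config.data_dir)
            if not hyps:
                hyps = None
        _done("ingest", t0, out / "cohort")

        # ---- preprocess ---------------------------------------------------
        t0 = _stage("preprocess")
        reduction = preprocess_cohort(
            data,
            sample_rate=1.0 / config.tr_seconds,
            bandpass_enabled=config.bandpass_enabled,
            low_hz=config.bandpass_low,
            high_hz=config.bandpass_high,
            order=config.bandpass_order,
            n_components=config.pca_components,
            variance_target=config.pca_variance_target,
        )
        np.savetxt(out / "pca_timecourses.tsv", reduction.Y, delimiter="\t")
        np.savetxt(out / "pca_mixing_matrix.tsv", reduction.M, delimiter="\t")
        bundle["reduction"] = reduction
        _done("preprocess", t0, out / "pca_timecourses.tsv", out / "pca_mixing_matrix.tsv")

        # ---- HMM ------------------------------------------------------------
        if config.K_list:
            t0 = _stage("scan")
            table = scan_model_orders(
                reduction.Y, reduction.participant_index, config.K_list,
                n_init=config.n_init, seed=config.seed,
                tr_seconds=config.tr_seconds, tol=config.tol,
                max_iter=config.max_iter, trans_stickiness=config.trans_stickiness,
            )
            table.to_csv(out / "model_order_scan.tsv", sep="\t", index=False)
            bundle["scan"] = table
            _done("scan", t0, out / "model_order_scan.tsv")

        t0 = _stage("fit")
        K = min(config.K, reduction.Y.shape[0] - 1)
        model = GaussianHMM(
            reduction.Y, participant_index=reduction.participant_index,
            n_states=K, tol=config.tol, max_iter=config.max_iter,
            trans_stickiness=config.trans_stickiness,
        )
        results = model.fit(n_init=config.n_init, seed=config.seed)
        paths, gammas = [], []
        for pid, g, pth in results.timecourses.per_participant():
            np.savetxt(out / f"gamma_p{pid:02d}.tsv", g, delimiter="\t")
            np.savetxt(out / f"path_p{pid:02d}.tsv", pth[:, None], fmt="%d", delimiter="\t")
            paths.append(pth)
            gammas.append(g)
        with open(out / "model.json", "w") as fh:
            json.dump({
                "K": results.K,
                "mu": results.mu.tolist(),
                "Sigma": results.Sigma.tolist(),
                "A": results.A.tolist(),
                "pi0": results.pi0.tolist(),
                "free_energy_trace": results.free_energy_trace.tolist(),
                "seed_used": results.seed_used,
                "converged": bool(results.converged),
            }, fh)
        bundle["model"] = model
        bundle["results"] = results
        bundle["paths"] = paths
        bundle["gammas"] = gammas
        _done("fit", t0, out / "model.json")

        if hyps is None:
            logger.info("no hypnograms available: metrics, stats and transition "
                        "stages that depend on staging are skipped")
            for name in ("metrics", "stats", "transitions"):
                manifest["stages"][name] = {"skipped": "no hypnograms"}
        else:
            hyps = [h if isinstance(h, Hypnogram)
                    else Hypnogram(stages=h, tr_seconds=config.tr_seconds) for h in hyps]
            # ---- metrics on the all-stage subset ---------------------------
            t0 = _stage("metrics")
            subset = select_all_stage_participants(hyps)
            bundle["all_stage_subset"] = subset
            bundle["waso_subset"] = select_waso_participants(hyps)
            use = subset if subset else list(range(len(paths)))
            mt = metrics_table([paths[p] for p in use], [hyps[p] for p in use],
                               K=results.K, tr_seconds=config.tr_seconds)
            mt.to_csv(out / "metrics.tsv", sep="\t", index=False)
            bundle["metrics"] = mt
            _done("metrics", t0, out / "metrics.tsv")

            # ---- group stats ----------------------------------------------
            t0 = _stage("stats")
            feats = [gammas[p] for p in use]
            stage_sets = [hyps[p] for p in use]
            manova = manova_permutation_test(
                feats, stage_sets, n_permutations=config.n_permutations,
                seed=config.seed)
            lam, means, W, B = wilks_lambda(
                np.vstack(feats), np.concatenate([h.stages for h in stage_sets]))
            Z, labels = stage_dendrogram(means, W,
                                         n_within=sum(len(f) for f in feats) - len(means))
            tests = stage_pair_tests(
                [paths[p] for p in use], stage_sets, metric="sensitivity",
                K=results.K, n_permutations=min(config.n_permutations, 200),
                seed=config.seed)
            stats_df = pd.DataFrame([{
                "statistic": manova.statistic, "p": manova.p_value,
                "n_permutations": len(manova.null), "n_excluded": manova.n_excluded,
            }])
            stats_df.to_csv(out / "manova.tsv", sep="\t", index=False)
            tests.to_csv(out / "sensitivity_tests.tsv", sep="\t", index=False)
            bundle["manova"] = manova
            bundle["dendrogram"] = (Z, labels)
            bundle["sensitivity_tests"] = tests
            _done("stats", t0, out / "manova.tsv", out / "sensitivity_tests.tsv")

            # ---- transition graph ------------------------------------------
            t0 = _stage("transitions")
            graph = build_transition_graph(
                [paths[p] for p in use], keep_fraction=config.keep_fraction,
                min_fraction=config.min_participant_fraction,
                mode=config.transition_mode,
                model_A=results.A, K=results.K)
            pooled_path = np.concatenate([paths[p] for p in use])
            pooled_stage = np.concatenate([hyps[p].stages for p in use])
            spec_mat = specificity_matrix(pooled_path, pooled_stage, K=results.K)
            edges, nodes = export_transition_map(graph, spec_mat, outdir=out / "transition_map")
            bundle["graph"] = graph
            bundle["edges"] = edges
            bundle["nodes"] = nodes
            _done("transitions", t0, out / "transition_map")
    except Exception as exc:
        failed = [s for s, v in manifest["stages"].items() if "seconds" not in v
                  and "skipped" not in v]
        stage_name = failed[-1] if failed else "unknown"
        manifest["failed_stage"] = stage_name
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
        raise RuntimeError(f"pipeline stage {stage_name!r} failed: {exc}") from exc

    manifest["total_seconds"] = round(time.time() - t_all, 3)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    bundle["manifest"] = manifest
    return bundle
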