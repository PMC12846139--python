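"""End-to-end workflow: sample → simulate → train → evaluate → assess.

The desk-scale defaults (20 sampled models, the 16-muscle reduced set,
a four-task standardized motion suite at 100 Hz) run the full pipeline
on a single CPU in minutes while exercising every stage of the method;
the full 72-muscle set and larger populations are configuration away.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .anthropometry import (
    AnthroProfile,
    DEFAULT_POPULATION,
    PopulationStats,
    profiles_to_frame,
    sample_population,
)
from .envelope import AssessmentReport, best_match, build_envelope, force_ratio_map
from .io import RunConfig, write_markers_csv, write_motion_csv
from .model import NeckModel, build_default_model, markers_for_motion, scale_model
from .motion import MotionSpec, generate_motion, restrict_motion
from .muscles import REDUCED_MUSCLE_SET
from .staticopt import SOConfig, solve_trajectory
from .surrogate import (
    FEATURE_NAMES,
    MuscleForceSurrogate,
    build_dataset,
    evaluate,
    split_dataset,
)

log = logging.getLogger("neckforce")

__all__ = [
    "standard_motion_suite",
    "concatenate_motions",
    "surrogate_fidelity",
    "assess_subject",
    "run_pipeline",
]


def standard_motion_suite(config: RunConfig | None = None):
    """The standardized Stage-1 style task list as MotionSpec objects."""
    config = config or RunConfig()
    return [MotionSpec(**spec) for spec in config.motions]


def concatenate_motions(motions):
    """Stack several trajectories into one (time re-indexed, same rate).

    Derivatives are computed per segment before stacking so that the
    seams between tasks do not inject artificial velocity/acceleration
    spikes.
    """
    from .model import MotionTrajectory, derive_kinematics

    motions = [m if m.qd is not None else derive_kinematics(m) for m in motions]
    q = np.vstack([m.q for m in motions])
    qd = np.vstack([m.qd for m in motions])
    qdd = np.vstack([m.qdd for m in motions])
    fs = motions[0].fs
    times = np.arange(q.shape[0]) / fs
    return MotionTrajectory(times, q, motions[0].dof_names, qd, qdd)


def _base_model(config: RunConfig) -> NeckModel:
    names = REDUCED_MUSCLE_SET if config.muscle_set == "reduced" else None
    return build_default_model(muscle_names=names)


def _population(config: RunConfig) -> PopulationStats:
    if config.population_mean is None and config.population_cov is None:
        return DEFAULT_POPULATION
    return PopulationStats(
        np.asarray(config.population_mean, dtype=float),
        np.asarray(config.population_cov, dtype=float),
    )


def surrogate_fidelity(
    seed: int = 0,
    n_profiles: int = 20,
    config: RunConfig | None = None,
):
    """Scaled-down fidelity study: simulate, train, report per-muscle metrics.

    Samples ``n_profiles`` anthropometric profiles, simulates the
    standardized motion suite on each rescaled model, builds the
    12-feature dataset, splits 64/16/20, trains one 12-64-32-1 net per
    muscle with early stopping, and evaluates R² and NRMSE per muscle on
    the held-out test split.

    Returns a dict with the metrics table, the fitted surrogate, the
    split sizes and the dataset row count.
    """
    config = config or RunConfig(seed=seed)
    base = _base_model(config)
    profiles = sample_population(_population(config), n_profiles, seed)
    motion = concatenate_motions(
        [generate_motion(s) for s in standard_motion_suite(config)]
    )
    features, labels = build_dataset(profiles, motion, base, config.so_config())
    X = features[FEATURE_NAMES].to_numpy()
    Y = labels.to_numpy()
    n = X.shape[0]
    split = split_dataset(n, seed)
    sur = MuscleForceSurrogate(seed=seed, **config.training)
    sur.fit(
        X[split.train], Y[split.train],
        muscle_names=list(labels.columns),
        validation=(X[split.val], Y[split.val]),
    )
    metrics = evaluate(sur, X[split.test], Y[split.test])
    return {
        "metrics": metrics,
        "min_r2": float(metrics["R2"].min()),
        "max_nrmse": float(metrics["NRMSE"].max()),
        "surrogate": sur,
        "n_rows": n,
        "split": split,
        "features": features,
        "labels": labels,
        "profiles": profiles,
        "base_model": base,
        "motion": motion,
    }


def _marker_envelopes(markers, alpha):
    from .model import MARKER_NAMES

    return {
        m: build_envelope(markers.positions[:, k, :], alpha, marker=m)
        for k, m in enumerate(MARKER_NAMES)
    }


def assess_subject(
    subject_markers,
    subject_profile: AnthroProfile,
    database_markers: dict,
    surrogate: MuscleForceSurrogate | None = None,
    alpha: float = float("inf"),
    resolution: int = 48,
) -> AssessmentReport:
    """Best-match a subject against the simulated envelope database.

    ``database_markers`` maps model id → MarkerTrajectory of the ideal
    motion.  With a trained surrogate the report also includes the
    per-muscle peak-force-ratio deficit screen (forces predicted from
    the subject's actual markers vs. the matched model's ideal markers,
    both with the subject's anthropometric parameters).
    """
    subject_envs = _marker_envelopes(subject_markers, alpha)
    database = {mid: _marker_envelopes(mk, alpha)
                for mid, mk in database_markers.items()}
    report = best_match(subject_envs, database, resolution)
    if surrogate is not None:
        anthro = [subject_profile.neck_length, subject_profile.shoulder_width,
                  subject_profile.head_mass]
        X_actual = np.hstack([
            subject_markers.positions.reshape(-1, 9),
            np.tile(anthro, (subject_markers.times.size, 1)),
        ])
        ideal = database_markers[report.best_model]
        X_ideal = np.hstack([
            ideal.positions.reshape(-1, 9),
            np.tile(anthro, (ideal.times.size, 1)),
        ])
        actual_df = pd.DataFrame(surrogate.predict(X_actual),
                                 columns=surrogate.muscle_names_)
        ideal_df = pd.DataFrame(surrogate.predict(X_ideal),
                                columns=surrogate.muscle_names_)
        ratios, impaired, compensating = force_ratio_map(actual_df, ideal_df)
        report.force_ratios = ratios
        report.impaired = impaired
        report.compensating = compensating
    return report


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full workflow and write all artifacts to the output dir.

    Stages: sample population → simulate forces and build the dataset →
    train the per-muscle surrogates → evaluate on the test split →
    assess a restricted-motion "patient" fixture and an unrestricted
    "healthy" fixture against the simulated envelope database.  Every
    stage logs seeds and row counts; artifact checksums land in
    ``run_log.json``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO, format="%(name)s: %(message)s")
    rng_seed = config.seed

    log.info("stage sample: n=%d seed=%d", config.n_models, rng_seed)
    result = surrogate_fidelity(rng_seed, config.n_models, config)
    profiles = result["profiles"]
    base = result["base_model"]
    profiles_to_frame(profiles, rng_seed).to_csv(out / "population.csv", index=False)

    suite = standard_motion_suite(config)
    motion = result["motion"]
    write_motion_csv(out / "motion_suite.csv", motion)

    features, labels = result["features"], result["labels"]
    features.to_csv(out / "features.csv", index=False)
    labels.to_csv(out / "labels.csv", index=False)
    log.info("stage dataset: %d rows x %d muscles", len(features), labels.shape[1])

    sur = result["surrogate"]
    sur.save(out / "ensemble.npz")
    metrics = result["metrics"]
    metrics.to_csv(out / "metrics.csv", index=False)
    log.info("stage evaluate: min R2=%.4f max NRMSE=%.4f",
             result["min_r2"], result["max_nrmse"])

    # envelope database from each model's ideal suite
    database = {}
    for pid, profile in enumerate(profiles):
        m = scale_model(base, profile)
        database[pid] = markers_for_motion(m, motion)

    subject_profile = profiles[0]
    subject_model = scale_model(base, subject_profile)
    healthy_markers = database[0]
    restricted = concatenate_motions([
        generate_motion(restrict_motion(s, config.patient_sectors,
                                        config.patient_factor))
        for s in suite
    ])
    patient_markers = markers_for_motion(subject_model, restricted)
    write_markers_csv(out / "patient_markers.csv", patient_markers)

    reports = {}
    for label, markers in (("healthy", healthy_markers),
                           ("patient", patient_markers)):
        rep = assess_subject(markers, subject_profile, database, sur,
                             config.envelope_alpha, config.iou_resolution)
        (out / f"assessment_{label}.txt").write_text(rep.summary() + "\n")
        if rep.force_ratios is not None:
            rep.force_ratios.to_csv(out / f"force_ratios_{label}.csv")
        reports[label] = rep
        log.info("stage assess(%s): best=%s total=%.4f", label,
                 rep.best_model, rep.total_score)

    run_log = {
        "seed": rng_seed,
        "n_models": config.n_models,
        "n_rows": int(len(features)),
        "min_r2": result["min_r2"],
        "checksums": {p.name: _sha256(p) for p in sorted(out.glob("*.csv"))},
    }
    (out / "run_log.json").write_text(json.dumps(run_log, indent=2))
    return {"config": config, "metrics": metrics, "reports": reports,
            "surrogate": sur, "run_log": run_log}
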