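"""Verification experiments run on synthetic study conditions.

Each function here generates synthetic fleets under the study conditions
(12 devices spanning all coil styles, quadruplicate sessions, 20%
multiplicative noise unless stated otherwise), runs the full pipeline
(screen -> summarize -> score -> calibrate -> predict) and measures one
property of it: closed-loop exactness in the noiseless limit, recovery of
the generating exponential parameters, selection of the generating score
model against the power-containing alternatives, and sensitivity /
false-flag rate of the Grubbs screen against the generator's ground
truth.  The same routines back the acceptance test suite and the
reproduction script, so the numbers reported in both places come from one
computation path.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from coiltox.calibration import fit_exponential, rank_models, train_predict_evaluate
from coiltox.emissions import summarize_fleet
from coiltox.scoring import builtin_models
from coiltox.synthetic import SyntheticConfig, generate_fleet, generate_sessions

__all__ = [
    "noiseless_closed_loop",
    "parameter_recovery",
    "model_selection_rate",
    "outlier_screening_rates",
    "study_workflow",
]

def _study_config(seed: int, **overrides) -> SyntheticConfig:
    base = SyntheticConfig(seed=seed)
    return replace(base, **overrides)


def _run_pipeline(config: SyntheticConfig, n_train: int = 9):
    fleet = generate_fleet(config)
    sessions, truth = generate_sessions(fleet, config)
    summaries = summarize_fleet(sessions)
    fit, evaluation = train_predict_evaluate(
        builtin_models()[0], fleet[:n_train], summaries, fleet, summaries
    )
    return fleet, truth, summaries, fit, evaluation


def noiseless_closed_loop(seed: int = 0) -> dict:
    """Noise-free benchmark: calibration and prediction must be exact."""
    config = _study_config(seed, noise_sigma=0.0, outlier_rate=0.0)
    _, truth, _, fit, evaluation = _run_pipeline(config)
    return {
        "fit_r2": fit.fit_r2,
        "predictive_r2": evaluation.predictive_r2,
        "a_abs_err": abs(fit.a - truth.a_true),
        "b_abs_err": abs(fit.b - truth.b_true),
    }


def parameter_recovery(n_fleets: int = 200, seed: int = 0) -> dict:
    """Median relative errors of (a, b) over replicated noisy studies.

    Conditions: 12 devices x 4 replicates, lognormal sigma 0.2, no gross
    outliers, log-linear calibration on all 12 device means.
    """
    a_errors, b_errors = [], []
    for i in range(n_fleets):
        config = _study_config(seed + i * 3, noise_sigma=0.2, outlier_rate=0.0)
        _, truth, _, fit, _ = _run_pipeline(config, n_train=config.n_devices)
        a_errors.append(abs(fit.a - truth.a_true) / truth.a_true)
        b_errors.append(abs(fit.b - truth.b_true) / truth.b_true)
    return {
        "median_rel_err_a": float(np.median(a_errors)),
        "median_rel_err_b": float(np.median(b_errors)),
        "n_fleets": n_fleets,
    }


def model_selection_rate(n_fleets: int = 200, seed: int = 0) -> dict:
    """How often the generating geometric score wins the candidate ranking.

    Fleets are generated from the geometric score at sigma 0.2; candidates
    are the geometric score plus the two power-containing alternatives;
    calibration on 9 devices, evaluation on all 12 (the study design).
    """
    models = builtin_models()
    wins = 0
    for i in range(n_fleets):
        config = _study_config(seed + i * 3, noise_sigma=0.2, outlier_rate=0.0)
        fleet = generate_fleet(config)
        sessions, _ = generate_sessions(fleet, config)
        summaries = summarize_fleet(sessions)
        ranking = rank_models(models, fleet[:9], summaries, fleet, summaries)
        wins += ranking[0].model.name == "model1"
    return {"win_rate": wins / n_fleets, "n_fleets": n_fleets}


def outlier_screening_rates(
    n_fleets: int = 200, seed: int = 0, outlier_rate: float = 0.10
) -> dict:
    """Sensitivity and false-flag rate of the Grubbs screen vs ground truth.

    x20 high-side outliers are injected independently per session at the
    given rate; screening runs at alpha 0.05 on quadruplicate devices.
    A session counts as flagged when the screen removed it.
    """
    tp = fn = fp = tn = 0
    for i in range(n_fleets):
        config = _study_config(
            seed + i * 3, noise_sigma=0.2, outlier_rate=outlier_rate,
            outlier_multiplier=20.0,
        )
        fleet = generate_fleet(config)
        sessions, truth = generate_sessions(fleet, config)
        summaries = summarize_fleet(sessions, alpha=0.05)
        injected = set(truth.outlier_sessions)
        for session in sessions:
            key = (session.device_id, session.replicate_id)
            flagged = session.replicate_id in summaries[session.device_id].removed_replicates
            if key in injected:
                tp += flagged
                fn += not flagged
            else:
                fp += flagged
                tn += not flagged
    return {
        "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
        "false_flag_rate": fp / (fp + tn) if fp + tn else float("nan"),
        "n_injected": tp + fn,
        "n_clean": fp + tn,
        "n_fleets": n_fleets,
    }


def study_workflow(seed: int = 0, noise_sigma: float = 0.2) -> dict:
    """One full synthetic study mirroring the experimental workflow.

    Generates a 12-device fleet with occasional gross outliers, screens and
    summarizes the sessions, calibrates the exponential on the first nine
    devices and evaluates predictions on all twelve, then ranks the
    candidate models.
    """
    config = _study_config(seed, noise_sigma=noise_sigma)
    fleet = generate_fleet(config)
    sessions, truth = generate_sessions(fleet, config)
    summaries = summarize_fleet(sessions)
    fit, evaluation = train_predict_evaluate(
        builtin_models()[0], fleet[:9], summaries, fleet, summaries
    )
    ranking = rank_models(builtin_models(), fleet[:9], summaries, fleet, summaries)
    return {
        "a": fit.a,
        "b": fit.b,
        "a_true": truth.a_true,
        "b_true": truth.b_true,
        "fit_r2": fit.fit_r2,
        "log_r2": fit.log_r2,
        "predictive_r2": evaluation.predictive_r2,
        "n_outliers_removed": int(
            sum(s.n_outliers_removed for s in summaries.values())
        ),
        "n_outliers_injected": len(truth.outlier_sessions),
        "ranking": [
            (r.model.name, r.predictive_r2) for r in ranking if not r.failed
        ],
    }
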