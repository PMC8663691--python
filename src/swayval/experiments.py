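"""Simulation studies that validate the pipeline against its own generator.

Each function runs the full chain (generate cohort -> metrics -> ICC or
regression) under conditions where the truth is known by construction, so the
estimates can be checked for recovery, coverage, or the qualitative ordering
the instrument comparison is built around.  All randomness flows from a single
root seed via independent spawned streams.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .agreement import agreement_table, aggregate_pairs, fit_univariate
from .reliability import build_rating_matrix, icc_two_way_mixed, reliability_table
from .sway_metrics import metrics_table
from .synthetic_data import (
    CohortConfig,
    HeadsetObservationParams,
    SwayProcessParams,
    calibrate_gain_log_sd,
    generate_cohort,
)


def _child_seeds(seed: int, n: int, label: int) -> list[int]:
    """Deterministic sub-seeds below 2^31 derived from one root seed."""
    ss = np.random.SeedSequence(seed, spawn_key=(label,))
    return [int(s) for s in ss.generate_state(n) % (2**31)]


def icc_parameter_recovery(
    targets: tuple[float, ...] = (0.3, 0.6, 0.9),
    n_subjects: int = 200,
    n_reps: int = 50,
    v_total: float = 0.2,
    seed: int = 0,
) -> dict[float, float]:
    """Mean estimated log-RMS ICC of COP traces for cohorts with a known ICC dial.

    For each target the generator's log-amplitude variances are set to
    tau2 = target * v_total, omega2 = (1 - target) * v_total; the estimate is
    the single-measure consistency ICC of log(COP RMS) over subjects x trials.
    Trace-level RMS estimation noise (~1/(2 T theta) in log variance) slightly
    attenuates the attained ICC below the dial; v_total = 0.2 keeps that
    attenuation within a few hundredths.
    """
    out: dict[float, float] = {}
    for ti, target in enumerate(targets):
        proc = SwayProcessParams(tau2=target * v_total, omega2=(1 - target) * v_total)
        estimates = []
        for rep_seed in _child_seeds(seed, n_reps, 100 + ti):
            config = CohortConfig(
                n_subjects=n_subjects,
                conditions=("EC",),
                directions=("ML",),
                seed=rep_seed,
                process=proc,
            )
            metrics = metrics_table(generate_cohort(config))
            metrics = metrics.assign(rms_cm=np.log(metrics["rms_cm"]))
            mat = build_rating_matrix(metrics, "FP", "rms", "EC", "ML")
            estimates.append(icc_two_way_mixed(mat).icc)
        out[target] = float(np.mean(estimates))
    return out


def simulate_rating_matrix(
    rng: np.random.Generator,
    n: int = 20,
    k: int = 3,
    icc: float = 0.6,
    trial_effects: tuple[float, ...] | None = None,
) -> np.ndarray:
    """n x k ratings from the two-way mixed model with known consistency ICC.

    y_ij = s_i + b_j + e_ij with Var(s) = icc, Var(e) = 1 - icc and fixed
    trial effects b_j (which the consistency ICC ignores).
    """
    if trial_effects is None:
        trial_effects = tuple(0.1 * j for j in range(k))
    s = rng.normal(0, np.sqrt(icc), size=(n, 1))
    e = rng.normal(0, np.sqrt(1 - icc), size=(n, k))
    return s + np.asarray(trial_effects) + e


def ci_coverage(
    true_icc: float = 0.6,
    n: int = 20,
    k: int = 3,
    n_sims: int = 1000,
    seed: int = 0,
) -> float:
    """Fraction of 95% F-pivot ICC CIs that cover the true consistency ICC."""
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed, spawn_key=(200,))))
    covered = 0
    for _ in range(n_sims):
        mat = simulate_rating_matrix(rng, n=n, k=k, icc=true_icc)
        res = icc_two_way_mixed(mat)
        if res.ci_low_untruncated <= true_icc <= res.ci_high:
            covered += 1
    return covered / n_sims


def agreement_correlation_recovery(
    rhos: tuple[float, ...] = (0.5, 0.8, 0.95),
    n_subjects: int = 500,
    pilot_subjects: int = 1000,
    seed: int = 0,
) -> dict[float, float]:
    """Estimated first-trial RMS R^2 for cohorts whose latent linkage is set to rho.

    The headset linkage is reduced to its subject-level gain term (jitter and
    drift off, cutoff near the headset Nyquist), so the two devices share the
    latent path and differ only by a per-subject lognormal gain whose log-SD
    is solved in closed form from a pilot estimate of the COP log-RMS variance.
    """
    proc = SwayProcessParams()
    # pilot: estimate the subject-level log-RMS variance of first-trial COP RMS
    pilot_cfg = CohortConfig(
        n_subjects=pilot_subjects,
        n_trials=2,
        conditions=("EC",),
        directions=("ML",),
        seed=_child_seeds(seed, 1, 300)[0],
        process=proc,
        headset=HeadsetObservationParams(
            smooth_cutoff=4.5, jitter_sd=0.0, drift_sd=0.0, gain_log_sd=0.0
        ),
    )
    pilot_metrics = metrics_table(generate_cohort(pilot_cfg))
    fp1 = pilot_metrics[
        (pilot_metrics.device == "FP") & (pilot_metrics.trial == 1)
    ]["rms_cm"]
    log_rms_var = float(np.var(np.log(fp1), ddof=1))

    out: dict[float, float] = {}
    for ri, rho in enumerate(rhos):
        head = HeadsetObservationParams(
            smooth_cutoff=4.5,
            jitter_sd=0.0,
            drift_sd=0.0,
            gain_log_sd=calibrate_gain_log_sd(rho, log_rms_var),
        )
        config = CohortConfig(
            n_subjects=n_subjects,
            n_trials=2,
            conditions=("EC",),
            directions=("ML",),
            seed=_child_seeds(seed, len(rhos), 301)[ri],
            process=proc,
            headset=head,
        )
        metrics = metrics_table(generate_cohort(config))
        pairs = aggregate_pairs(metrics, "rms", "EC", "ML", "first_trial")
        out[rho] = fit_univariate(pairs).r2
    return out


def headline_replicates(
    n_seeds: int = 50,
    config: CohortConfig | None = None,
    seed: int = 0,
) -> dict:
    """Replicate the default 20-subject study and average its two result tables.

    Returns mean R^2 per agreement cell, mean ICC per reliability cell, and the
    derived headline quantities: per-cell mean NPL vs RMS vs P2P R^2, and the
    mean force-plate vs headset NPL ICC.
    """
    base = config if config is not None else CohortConfig()
    agree_frames, rel_frames = [], []
    for rep_seed in _child_seeds(seed, n_seeds, 400):
        cfg = replace(base, seed=rep_seed)
        metrics = metrics_table(generate_cohort(cfg))
        agree_frames.append(agreement_table(metrics))
        rel_frames.append(reliability_table(metrics))
    agree = pd.concat(agree_frames)
    rel = pd.concat(rel_frames)
    mean_r2 = (
        agree.groupby(["metric", "aggregation", "condition", "direction"])["r2"]
        .mean()
        .reset_index()
    )
    mean_icc = rel.groupby(["device", "metric", "condition", "direction"])["icc"].mean().reset_index()
    npl_icc = mean_icc[mean_icc.metric == "npl"].groupby("device")["icc"].mean()
    return {
        "mean_r2": mean_r2,
        "mean_icc": mean_icc,
        "mean_r2_by_metric": mean_r2.groupby("metric")["r2"].mean().to_dict(),
        "fp_npl_icc": float(npl_icc["FP"]),
        "vr_npl_icc": float(npl_icc["VR"]),
        "n_seeds": n_seeds,
    }


def npl_ordering_holds(mean_r2: pd.DataFrame) -> bool:
    """True when every NPL cell's mean R^2 sits below RMS and P2P in that cell."""
    wide = mean_r2.pivot_table(
        index=["aggregation", "condition", "direction"], columns="metric", values="r2"
    )
    return bool(((wide["npl"] < wide["rms"]) & (wide["npl"] < wide["p2p"])).all())
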