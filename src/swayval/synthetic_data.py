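"""Synthetic postural-sway cohort generator.

Emulates the dual-device study design this package analyzes: each subject
stands quietly for three 20-second trials per visual condition (eyes open /
eyes closed) while a force plate records center-of-pressure (COP) position at
200 Hz and a VR headset records head position at 10 Hz, in the medial-lateral
(ML) and anterior-posterior (AP) directions.

The latent sway in each direction is a stationary Ornstein-Uhlenbeck (OU)
process -- the simplest stabilogram surrogate with COP-like mean reversion --
whose marginal SD is a per-subject, per-trial lognormal amplitude.  Between-
and within-subject log-amplitude variances (tau2, omega2) dial the cohort's
test-retest reliability: the log-amplitude intraclass correlation is
tau2 / (tau2 + omega2).

The headset observes the *same* latent path from above the center of gravity:
its output is a gain-amplified, low-passed, decimated copy of the COP path
plus slow drift and high-frequency jitter.  Amplitude (RMS, peak-to-peak)
therefore couples strongly across devices while path length, which at 10 Hz is
dominated by the jitter floor, decorrelates -- the mechanism behind the
qualitative headline the pipeline reproduces.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

from .io_formats import (
    CONDITIONS,
    DIRECTIONS,
    MANIFEST_COLUMNS,
    CohortManifest,
    TraceMeta,
    TrialTrace,
    write_trace,
)

logger = logging.getLogger(__name__)

# stream codes for counter-based seed splitting (root seed + spawn key);
# adding subjects or trials never perturbs existing streams
_STREAM_SUBJECT = 1
_STREAM_TRIAL = 2
_STREAM_COP = 3
_STREAM_HEADSET = 4
_STREAM_GAIN = 5


@dataclass(frozen=True)
class SwayProcessParams:
    """Latent sway process and study-design constants.

    theta : OU mean-reversion rate (1/s); 1/theta is the sway correlation time.
    sigma_base : baseline (eyes-open ML) stationary sway SD in cm.
    ec_multiplier : eyes-closed amplitude multiplier (sway grows without vision).
    tau2, omega2 : between-subject and within-subject (trial) log-amplitude
        variances; tau2/(tau2+omega2) is the target log-amplitude ICC.
    duration : trial length in s; fp_rate / vr_rate : device sampling rates (Hz).
    """

    theta: float = 5.0
    sigma_base: float = 0.3
    ec_multiplier: float = 1.5
    tau2: float = 0.04
    omega2: float = 0.04
    duration: float = 20.0
    fp_rate: float = 200.0
    vr_rate: float = 10.0

    def __post_init__(self) -> None:
        if not (self.theta > 0):
            raise ValueError("theta must be > 0")
        if not (self.sigma_base > 0):
            raise ValueError("sigma_base must be > 0")
        if self.ec_multiplier < 1:
            raise ValueError("ec_multiplier must be >= 1")
        if self.tau2 < 0 or self.omega2 < 0:
            raise ValueError("variance components must be >= 0")
        if not (self.duration > 0):
            raise ValueError("duration must be > 0")
        if not (self.fp_rate > self.vr_rate > 0):
            raise ValueError("need fp_rate > vr_rate > 0")


@dataclass(frozen=True)
class HeadsetObservationParams:
    """How the headset re-expresses the latent COP path.

    gain : head excursion per unit COP excursion (>= 1: sway moves the head,
        high above the center of gravity, more than the COP).
    smooth_cutoff : low-pass cutoff (Hz) applied to the COP path before gain;
        the head does not follow high-frequency COP adjustments.
    jitter_sd : SD (cm) of additive per-sample tracking noise; the dominant
        contributor to headset path length at 10 Hz.
    drift_sd : scale (cm) of slow Brownian tracking drift over one trial.
    gain_log_sd : SD of a per-subject lognormal gain factor (head height,
        headset fit); decouples headset amplitude from COP amplitude across
        subjects and thereby dials the between-device amplitude correlation.
    """

    gain: float = 1.5
    smooth_cutoff: float = 0.5
    jitter_sd: float = 0.15
    drift_sd: float = 0.05
    gain_log_sd: float = 0.2

    def __post_init__(self) -> None:
        if self.gain < 1:
            raise ValueError("gain must be >= 1")
        if not (self.smooth_cutoff > 0):
            raise ValueError("smooth_cutoff must be > 0")
        if self.jitter_sd < 0 or self.drift_sd < 0 or self.gain_log_sd < 0:
            raise ValueError("noise scales must be >= 0")


@dataclass(frozen=True)
class CohortConfig:
    n_subjects: int = 20
    n_trials: int = 3
    conditions: tuple[str, ...] = CONDITIONS
    directions: tuple[str, ...] = DIRECTIONS
    seed: int = 0
    ap_anisotropy: float = 1.2  # AP sway exceeds ML in quiet standing
    process: SwayProcessParams = field(default_factory=SwayProcessParams)
    headset: HeadsetObservationParams = field(default_factory=HeadsetObservationParams)

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if self.n_trials < 2:
            raise ValueError("n_trials must be >= 2")
        for c in self.conditions:
            if c not in CONDITIONS:
                raise ValueError(f"unknown condition {c!r}")
        for d in self.directions:
            if d not in DIRECTIONS:
                raise ValueError(f"unknown direction {d!r}")
        if self.headset.smooth_cutoff >= self.process.vr_rate / 2:
            raise ValueError("smooth_cutoff must be below the headset Nyquist frequency")


def _rng(root_seed: int, *key: int) -> np.random.Generator:
    return np.random.Generator(np.random.PCG64(np.random.SeedSequence(root_seed, spawn_key=key)))


def simulate_cop_trace(
    params: SwayProcessParams, amplitude_scale: float, seed: int | np.random.Generator
) -> TrialTrace:
    """Simulate one force-plate COP channel as a stationary OU series.

    Exact discretization: x_{t+dt} = x_t e^{-theta dt} + s eps with
    s^2 = amplitude_scale^2 (1 - e^{-2 theta dt}) and x_0 drawn from the
    stationary N(0, amplitude_scale^2).  The series is linear in
    amplitude_scale for a fixed seed.
    """
    if not (amplitude_scale > 0):
        raise ValueError("amplitude_scale must be > 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.Generator(np.random.PCG64(seed))
    n = round(params.duration * params.fp_rate) + 1
    dt = 1.0 / params.fp_rate
    phi = math.exp(-params.theta * dt)
    innov_sd = math.sqrt(max(1.0 - phi * phi, 0.0))
    z = rng.standard_normal(n)
    # unit-SD OU via the AR(1) recursion x_j = phi x_{j-1} + innov_sd z_j, x_0 = z_0
    w = z * innov_sd
    w[0] = z[0]
    x = signal.lfilter([1.0], [1.0, -phi], w)
    return TrialTrace(values=amplitude_scale * x, rate=params.fp_rate, duration=params.duration)


def observe_headset_trace(
    cop: TrialTrace,
    params: HeadsetObservationParams,
    seed: int | np.random.Generator,
    vr_rate: float = 10.0,
    gain_scale: float = 1.0,
) -> TrialTrace:
    """Derive the headset's 10 Hz view of a 200 Hz COP trace.

    gain * lowpass(cop), decimated to ``vr_rate``, plus slow Brownian drift
    (SD ``drift_sd`` at the end of the trial) and iid jitter.  With
    gain = 1 and zero noise the output is exactly the low-passed, decimated COP.
    ``gain_scale`` carries the per-subject lognormal gain factor (which may
    fall below 1) without touching the validated base gain.
    """
    if not (0 < params.smooth_cutoff < vr_rate / 2):
        raise ValueError("smooth_cutoff must lie in (0, vr_rate/2)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.Generator(np.random.PCG64(seed))
    sos = signal.butter(4, params.smooth_cutoff, btype="low", fs=cop.rate, output="sos")
    smooth = signal.sosfiltfilt(sos, cop.values)

    n_vr = round(cop.duration * vr_rate) + 1
    step = cop.rate / vr_rate
    if abs(step - round(step)) < 1e-9:
        decimated = smooth[:: int(round(step))][:n_vr]
    else:
        logger.warning(
            "vr_rate %.3f is not a divisor of fp_rate %.3f; falling back to linear interpolation",
            vr_rate,
            cop.rate,
        )
        t_vr = np.arange(n_vr) / vr_rate
        decimated = np.interp(t_vr, cop.times, smooth)

    out = params.gain * gain_scale * decimated
    if params.drift_sd > 0:
        inc = rng.standard_normal(n_vr) * math.sqrt(1.0 / vr_rate)
        inc[0] = 0.0
        out = out + params.drift_sd * np.cumsum(inc) / math.sqrt(cop.duration)
    if params.jitter_sd > 0:
        out = out + params.jitter_sd * rng.standard_normal(n_vr)
    return TrialTrace(values=out, rate=vr_rate, duration=cop.duration)


def subject_amplitude(
    condition: str, subject_effect: float, trial_effect: float, params: SwayProcessParams
) -> float:
    """Stationary sway SD (cm) for one subject-trial under one condition.

    sigma_base * ec_multiplier^{[EC]} * exp(subject_effect + trial_effect),
    with subject_effect ~ N(0, tau2) per subject and trial_effect ~ N(0,
    omega2) per trial, so the log-amplitude ICC is tau2/(tau2+omega2).
    """
    mult = params.ec_multiplier if condition == "EC" else 1.0
    return params.sigma_base * mult * math.exp(subject_effect + trial_effect)


def calibrate_gain_log_sd(rho: float, log_rms_var: float) -> float:
    """Per-subject log-gain SD that sets the between-device RMS correlation to rho.

    When jitter and drift are off and the cutoff sits near the headset Nyquist,
    headset RMS = gain_i * (attenuated COP RMS), so on the log scale the
    devices differ only by the per-subject gain term.  For bivariate lognormal
    amplitudes with log-variance s2 on the COP side, the raw-scale correlation
    equals rho when gamma2 = ln(1 + (e^{s2}-1)/rho^2) - s2.
    """
    if not (0 < rho <= 1):
        raise ValueError("rho must be in (0, 1]")
    if not (log_rms_var > 0):
        raise ValueError("log_rms_var must be > 0")
    gamma2 = math.log1p(math.expm1(log_rms_var) / rho**2) - log_rms_var
    return math.sqrt(max(gamma2, 0.0))


def generate_cohort(
    config: CohortConfig, out_dir=None, overwrite: bool = False
) -> CohortManifest:
    """Generate a full dual-device cohort; optionally write it to ``out_dir``.

    For every (subject, condition, trial, direction) a COP trace and its paired
    headset trace are derived from the same latent sway path.  Random streams
    are split per record from the root seed, so regeneration is byte-identical
    and adding subjects does not perturb existing subjects' traces.
    """
    if out_dir is not None:
        out_dir = Path(out_dir)
        if out_dir.exists() and any(out_dir.iterdir()) and not overwrite:
            raise FileExistsError(f"{out_dir} exists and is not empty; pass overwrite=True")
        out_dir.mkdir(parents=True, exist_ok=True)

    proc, head = config.process, config.headset
    rows: list[dict] = []
    traces: dict[TraceMeta, TrialTrace] = {}
    cond_idx = {c: i for i, c in enumerate(CONDITIONS)}
    dir_idx = {d: i for i, d in enumerate(DIRECTIONS)}

    for sid in range(1, config.n_subjects + 1):
        u = _rng(config.seed, _STREAM_SUBJECT, sid).standard_normal() * math.sqrt(proc.tau2)
        gain_scale_i = math.exp(
            _rng(config.seed, _STREAM_GAIN, sid).standard_normal() * head.gain_log_sd
        )
        for cond in config.conditions:
            for trial in range(1, config.n_trials + 1):
                w = _rng(config.seed, _STREAM_TRIAL, sid, cond_idx[cond], trial).standard_normal()
                w *= math.sqrt(proc.omega2)
                amp = subject_amplitude(cond, u, w, proc)
                for direction in config.directions:
                    scale = amp * (config.ap_anisotropy if direction == "AP" else 1.0)
                    cop = simulate_cop_trace(
                        proc,
                        scale,
                        _rng(config.seed, _STREAM_COP, sid, cond_idx[cond], trial, dir_idx[direction]),
                    )
                    vr = observe_headset_trace(
                        cop,
                        head,
                        _rng(
                            config.seed,
                            _STREAM_HEADSET,
                            sid,
                            cond_idx[cond],
                            trial,
                            dir_idx[direction],
                        ),
                        vr_rate=proc.vr_rate,
                        gain_scale=gain_scale_i,
                    )
                    for device, trace in (("FP", cop), ("VR", vr)):
                        meta = TraceMeta(sid, cond, trial, direction, device)
                        trace.meta = meta
                        traces[meta] = trace
                        rows.append(
                            {
                                "subject_id": sid,
                                "condition": cond,
                                "trial": trial,
                                "direction": direction,
                                "device": device,
                                "rate_hz": trace.rate,
                                "path": meta.filename,
                            }
                        )
                        if out_dir is not None:
                            write_trace(trace, out_dir / meta.filename)

    records = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    manifest = CohortManifest(records=records, root=out_dir, traces=traces)
    if out_dir is not None:
        manifest.write(out_dir / "manifest.csv")
    return manifest
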