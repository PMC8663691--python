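"""Postural-sway summary variables computed from a single position trace.

Three standard posturography measures, computed per direction at each device's
native sampling rate (no resampling or filtering beforehand):

* normalized path length, NPL = (1/t) * sum_j |p_{j+1} - p_j|  [cm/s]
* root mean square, RMS = sqrt((1/N) * sum_j (p_j - p_avg)^2)  [cm]
* peak-to-peak, P2P = max(p) - min(p)  [cm]

where t is the trial duration, N the number of samples, p_avg the trace mean.
All three are translation-invariant and scale by |c| under p -> c*p.  NPL is
sampling-rate sensitive by construction: finer sampling of a noisy process
accumulates more path, so the 200 Hz force plate and the 10 Hz headset are not
expected to agree on NPL even for a shared underlying path.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io_formats import CohortManifest, TrialTrace

METRIC_NAMES = ("npl", "rms", "p2p")

METRIC_COLUMNS = {"npl": "npl_cm_per_s", "rms": "rms_cm", "p2p": "p2p_cm"}


def normalized_path_length(trace: TrialTrace) -> float:
    """Total excursion divided by trial duration, in cm/s."""
    if trace.values.size < 2:
        raise ValueError("NPL needs at least 2 samples")
    if not (trace.duration > 0):
        raise ValueError("NPL needs a positive duration")
    return float(np.sum(np.abs(np.diff(trace.values))) / trace.duration)


def root_mean_square(trace: TrialTrace) -> float:
    """RMS deviation about the trace mean (population convention, divisor N), in cm."""
    if trace.values.size < 1:
        raise ValueError("RMS needs at least 1 sample")
    p = trace.values
    return float(np.sqrt(np.mean((p - p.mean()) ** 2)))


def peak_to_peak(trace: TrialTrace) -> float:
    """Range of the trace, max - min, in cm."""
    if trace.values.size < 1:
        raise ValueError("P2P needs at least 1 sample")
    return float(np.max(trace.values) - np.min(trace.values))


def compute_metrics(trace: TrialTrace) -> dict[str, float]:
    return {
        "npl": normalized_path_length(trace),
        "rms": root_mean_square(trace),
        "p2p": peak_to_peak(trace),
    }


def metrics_table(manifest: CohortManifest) -> pd.DataFrame:
    """One row of NPL/RMS/P2P per trace in the cohort, at native rates.

    Columns: subject_id, condition, trial, direction, device,
    npl_cm_per_s, rms_cm, p2p_cm.
    """
    rows = []
    for meta, trace in manifest.iter_traces():
        try:
            m = compute_metrics(trace)
        except ValueError as exc:
            raise ValueError(f"metric computation failed for {meta}: {exc}") from exc
        rows.append(
            {
                "subject_id": meta.subject_id,
                "condition": meta.condition,
                "trial": meta.trial,
                "direction": meta.direction,
                "device": meta.device,
                "npl_cm_per_s": m["npl"],
                "rms_cm": m["rms"],
                "p2p_cm": m["p2p"],
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "subject_id",
            "condition",
            "trial",
            "direction",
            "device",
            "npl_cm_per_s",
            "rms_cm",
            "p2p_cm",
        ],
    )
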