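"""Test-retest reliability via the two-way mixed-effects intraclass correlation.

Each (device, metric, condition, direction) cell of the cohort yields an
n_subjects x k_trials rating matrix.  Reliability is the single-measure
consistency ICC from a two-way mixed-effects ANOVA with subjects as random
rows and trials as fixed columns (Shrout & Fleiss ICC(3,1); McGraw & Wong
ICC(C,1)):

    ICC = (MS_rows - MS_error) / (MS_rows + (k - 1) * MS_error)

with the 95% CI from the exact F pivot: F = MS_rows / MS_error on
(n-1, (n-1)(k-1)) df, F_L = F / F_{1-a/2}(n-1, (n-1)(k-1)),
F_U = F * F_{1-a/2}((n-1)(k-1), n-1), bounds (F_x - 1)/(F_x + k - 1).
The average-measures form ICC(3,k) = (MS_rows - MS_error)/MS_rows is available
behind the ``form`` flag.  Consistency ICC ignores additive trial (column)
effects and is invariant under affine transforms of the whole matrix.

Point estimates may be negative and are reported as computed (classified
poor); only CI lower bounds are floored at zero for reporting, mirroring the
common printed style "(0-0.771)"; the untruncated bound is retained.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .sway_metrics import METRIC_COLUMNS, METRIC_NAMES

logger = logging.getLogger(__name__)

CLASSIFICATION_BANDS = (0.5, 0.75, 0.90)  # poor | moderate | good | excellent cut-points


@dataclass
class ICCResult:
    icc: float
    ci_low: float
    ci_high: float
    classification: str
    ms_rows: float
    ms_cols: float
    ms_error: float
    df_rows: int
    df_cols: int
    df_error: int
    n: int
    k: int
    form: str = "single"
    estimable: bool = True
    ci_low_untruncated: float = float("nan")


def classify_icc(icc: float) -> str:
    """Classification bands: poor <0.5, moderate [0.5,0.75), good [0.75,0.90], excellent >0.90."""
    if not (icc <= 1):
        raise ValueError("ICC cannot exceed 1")
    if icc < 0.5:
        return "poor"
    if icc < 0.75:
        return "moderate"
    if icc <= 0.90:
        return "good"
    return "excellent"


def build_rating_matrix(
    metrics: pd.DataFrame, device: str, metric_name: str, condition: str, direction: str
) -> pd.DataFrame:
    """Subjects x trials matrix of one metric for one (device, condition, direction) cell.

    Subjects with incomplete trials are dropped listwise (count logged).
    """
    if metric_name not in METRIC_NAMES:
        raise ValueError(f"unknown metric {metric_name!r}; expected one of {METRIC_NAMES}")
    col = METRIC_COLUMNS[metric_name]
    sub = metrics[
        (metrics.device == device)
        & (metrics.condition == condition)
        & (metrics.direction == direction)
    ]
    if sub.empty:
        raise ValueError(f"no rows for device={device} condition={condition} direction={direction}")
    wide = sub.pivot_table(index="subject_id", columns="trial", values=col, aggfunc="first")
    wide = wide.sort_index()
    complete = wide.dropna()
    n_dropped = len(wide) - len(complete)
    if n_dropped:
        logger.info(
            "dropped %d subject(s) with incomplete trials for (%s, %s, %s, %s)",
            n_dropped,
            device,
            metric_name,
            condition,
            direction,
        )
    if len(complete) < 2 or complete.shape[1] < 2:
        raise ValueError("fewer than 2 complete subjects or trials; cannot form a rating matrix")
    return complete


def _two_way_anova(values: np.ndarray):
    n, k = values.shape
    grand = values.mean()
    row_means = values.mean(axis=1)
    col_means = values.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((values - grand) ** 2)
    ss_error = ss_total - ss_rows - ss_cols
    df_rows, df_cols, df_error = n - 1, k - 1, (n - 1) * (k - 1)
    return ss_rows / df_rows, ss_cols / df_cols, ss_error / df_error, df_rows, df_cols, df_error


def icc_two_way_mixed(
    matrix: pd.DataFrame | np.ndarray, alpha: float = 0.05, form: str = "single"
) -> ICCResult:
    """Two-way mixed-effects consistency ICC with its F-pivot CI.

    ``form`` is "single" for ICC(3,1) (default) or "average" for ICC(3,k).
    Degenerate matrices: MS_error = 0 with subject variance present gives
    ICC = 1 with CI [1, 1]; an all-identical matrix is flagged not estimable.
    """
    values = np.asarray(matrix, dtype=float)
    if values.ndim != 2 or values.shape[0] < 2 or values.shape[1] < 2:
        raise ValueError("rating matrix must be at least 2 x 2")
    if np.isnan(values).any():
        raise ValueError("rating matrix contains missing cells")
    if form not in ("single", "average"):
        raise ValueError("form must be 'single' or 'average'")
    n, k = values.shape
    ms_rows, ms_cols, ms_error, df_rows, df_cols, df_error = _two_way_anova(values)

    common = dict(
        ms_rows=ms_rows,
        ms_cols=ms_cols,
        ms_error=ms_error,
        df_rows=df_rows,
        df_cols=df_cols,
        df_error=df_error,
        n=n,
        k=k,
        form=form,
    )
    scale = max(abs(ms_rows), abs(ms_error), np.mean(values**2), 1e-300)
    if ms_error / scale < 1e-14:
        if ms_rows / scale < 1e-14:
            logger.info("all ratings identical; ICC not estimable")
            return ICCResult(
                icc=float("nan"),
                ci_low=float("nan"),
                ci_high=float("nan"),
                classification="not_estimable",
                estimable=False,
                **common,
            )
        return ICCResult(
            icc=1.0, ci_low=1.0, ci_high=1.0, classification="excellent",
            ci_low_untruncated=1.0, **common,
        )

    f_obs = ms_rows / ms_error
    fq_lo = stats.f.ppf(1 - alpha / 2, df_rows, df_error)
    fq_hi = stats.f.ppf(1 - alpha / 2, df_error, df_rows)
    f_l = f_obs / fq_lo
    f_u = f_obs * fq_hi
    if form == "single":
        icc = (ms_rows - ms_error) / (ms_rows + (k - 1) * ms_error)
        lo = (f_l - 1) / (f_l + k - 1)
        hi = (f_u - 1) / (f_u + k - 1)
    else:
        icc = (ms_rows - ms_error) / ms_rows
        lo = 1 - 1 / f_l
        hi = 1 - 1 / f_u
    lo_reported = max(lo, 0.0)
    if lo < 0:
        logger.info("ICC CI lower bound %.4f truncated to 0 for reporting", lo)
    return ICCResult(
        icc=float(icc),
        ci_low=float(lo_reported),
        ci_high=float(hi),
        classification=classify_icc(float(icc)),
        ci_low_untruncated=float(lo),
        **common,
    )


def reliability_table(
    metrics: pd.DataFrame,
    devices: tuple[str, ...] = ("FP", "VR"),
    conditions: tuple[str, ...] = ("EO", "EC"),
    directions: tuple[str, ...] = ("ML", "AP"),
    metric_names: tuple[str, ...] = METRIC_NAMES,
    alpha: float = 0.05,
    form: str = "single",
) -> pd.DataFrame:
    """ICC per (condition x direction) row and (device x metric) column.

    The default cohort yields 4 rows x 6 ICC cells.  Per-cell failures are
    flagged (estimable = False), never abort the whole table.
    """
    rows = []
    for condition in conditions:
        for direction in directions:
            for metric_name in metric_names:
                for device in devices:
                    base = {
                        "condition": condition,
                        "direction": direction,
                        "device": device,
                        "metric": metric_name,
                    }
                    try:
                        mat = build_rating_matrix(metrics, device, metric_name, condition, direction)
                        res = icc_two_way_mixed(mat, alpha=alpha, form=form)
                        rows.append(
                            base
                            | {
                                "icc": res.icc,
                                "ci_low": res.ci_low,
                                "ci_high": res.ci_high,
                                "classification": res.classification,
                                "n": res.n,
                                "k": res.k,
                                "estimable": res.estimable,
                            }
                        )
                    except ValueError as exc:
                        logger.warning("reliability cell %s failed: %s", base, exc)
                        rows.append(
                            base
                            | {
                                "icc": float("nan"),
                                "ci_low": float("nan"),
                                "ci_high": float("nan"),
                                "classification": "error",
                                "n": 0,
                                "k": 0,
                                "estimable": False,
                            }
                        )
    return pd.DataFrame(rows)
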