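"""Between-device agreement: COP metrics regressed on headset metrics.

For each (metric, condition, direction) cell and each aggregation (first trial
only, or the per-subject mean of the three trials) an ordinary least-squares
regression is fit with the force-plate COP metric as the response and the
headset metric as the univariate predictor.  The coefficient of determination
R^2 -- equal to the squared Pearson correlation for a single predictor -- is
the agreement measure; significance comes from the regression F test
(equivalent to the slope t test) with two printed tiers, p < .001 and p < .05.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .sway_metrics import METRIC_COLUMNS, METRIC_NAMES

logger = logging.getLogger(__name__)

AGGREGATIONS = ("first_trial", "mean_of_3")


@dataclass
class PairedMetricVector:
    """Subject-aligned (headset, force-plate) metric values for one cell."""

    x: np.ndarray  # VR metric per subject (predictor)
    y: np.ndarray  # FP/COP metric per subject (response)
    subject_ids: np.ndarray
    metric: str
    condition: str
    direction: str
    aggregation: str

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.size != self.y.size:
            raise ValueError("x and y must have equal length")
        if self.x.size < 3:
            raise ValueError("need at least 3 paired subjects")
        if np.isnan(self.x).any() or np.isnan(self.y).any():
            raise ValueError("paired vectors contain missing values")


@dataclass
class AgreementResult:
    metric: str
    aggregation: str
    condition: str
    direction: str
    n: int
    slope: float
    intercept: float
    r2: float
    p_value: float
    tier: str
    estimable: bool = True


def significance_tier(p_value: float) -> str:
    if p_value < 0.001:
        return "p<.001"
    if p_value < 0.05:
        return "p<.05"
    return "ns"


def aggregate_pairs(
    metrics: pd.DataFrame,
    metric_name: str,
    condition: str,
    direction: str,
    aggregation: str = "mean_of_3",
) -> PairedMetricVector:
    """Collapse the metrics table to one (VR, FP) value pair per subject.

    ``first_trial`` keeps trial 1 only; ``mean_of_3`` averages the subject's
    trials.  Subjects missing either device (or trial 1, for first_trial) are
    dropped with a logged count.
    """
    if metric_name not in METRIC_NAMES:
        raise ValueError(f"unknown metric {metric_name!r}")
    if aggregation not in AGGREGATIONS:
        raise ValueError(f"unknown aggregation {aggregation!r}; expected one of {AGGREGATIONS}")
    col = METRIC_COLUMNS[metric_name]
    sub = metrics[(metrics.condition == condition) & (metrics.direction == direction)]
    if aggregation == "first_trial":
        sub = sub[sub.trial == 1]
    if sub.empty:
        raise ValueError(
            f"no rows for metric={metric_name} condition={condition} direction={direction} "
            f"aggregation={aggregation}"
        )
    per_subject = sub.pivot_table(index="subject_id", columns="device", values=col, aggfunc="mean")
    if "FP" not in per_subject.columns or "VR" not in per_subject.columns:
        raise ValueError("both FP and VR records are required for agreement")
    complete = per_subject.dropna().sort_index()
    n_dropped = len(per_subject) - len(complete)
    if n_dropped:
        logger.info(
            "dropped %d subject(s) without complete device pairs for (%s, %s, %s, %s)",
            n_dropped, metric_name, condition, direction, aggregation,
        )
    if len(complete) < 3:
        raise ValueError("fewer than 3 complete subject pairs")
    return PairedMetricVector(
        x=complete["VR"].to_numpy(),
        y=complete["FP"].to_numpy(),
        subject_ids=complete.index.to_numpy(),
        metric=metric_name,
        condition=condition,
        direction=direction,
        aggregation=aggregation,
    )


def fit_univariate(pairs: PairedMetricVector, alpha: float = 0.05) -> AgreementResult:
    """OLS fit y = a + b x with R^2 and the regression F-test p-value.

    Zero predictor variance is flagged not estimable; zero response variance
    yields R^2 = 0 with a flag.
    """
    x, y = pairs.x, pairs.y
    n = x.size
    base = dict(
        metric=pairs.metric,
        aggregation=pairs.aggregation,
        condition=pairs.condition,
        direction=pairs.direction,
        n=n,
    )
    if np.var(x) == 0:
        logger.warning("predictor variance is zero for %s; cell not estimable", base)
        return AgreementResult(
            slope=float("nan"), intercept=float("nan"), r2=float("nan"),
            p_value=float("nan"), tier="not_estimable", estimable=False, **base,
        )
    if np.var(y) == 0:
        logger.warning("response variance is zero for %s; R^2 defined as 0", base)
        return AgreementResult(
            slope=0.0, intercept=float(y[0]), r2=0.0, p_value=1.0, tier="ns",
            estimable=False, **base,
        )
    fit = stats.linregress(x, y)
    r2 = float(fit.rvalue**2)
    # F test of the regression, identical to the slope t test for one predictor
    if r2 >= 1.0:
        p = 0.0
    else:
        f_stat = (n - 2) * r2 / (1 - r2)
        p = float(stats.f.sf(f_stat, 1, n - 2))
    return AgreementResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r2=r2,
        p_value=p,
        tier=significance_tier(p),
        **base,
    )


def agreement_table(
    metrics: pd.DataFrame,
    metric_names: tuple[str, ...] = METRIC_NAMES,
    aggregations: tuple[str, ...] = AGGREGATIONS,
    conditions: tuple[str, ...] = ("EO", "EC"),
    directions: tuple[str, ...] = ("ML", "AP"),
    alpha: float = 0.05,
) -> pd.DataFrame:
    """R^2 per metric x aggregation row-group and condition x direction column.

    The default cohort yields 3 x 2 x 4 = 24 cells.  Per-cell failures are
    flagged, never abort the table.
    """
    if metrics.empty:
        raise ValueError("empty metrics table")
    rows = []
    for metric_name in metric_names:
        for aggregation in aggregations:
            for condition in conditions:
                for direction in directions:
                    base = {
                        "metric": metric_name,
                        "aggregation": aggregation,
                        "condition": condition,
                        "direction": direction,
                    }
                    try:
                        pairs = aggregate_pairs(metrics, metric_name, condition, direction, aggregation)
                        res = fit_univariate(pairs, alpha=alpha)
                        rows.append(
                            base
                            | {
                                "n": res.n,
                                "slope": res.slope,
                                "intercept": res.intercept,
                                "r2": res.r2,
                                "p_value": res.p_value,
                                "tier": res.tier,
                                "estimable": res.estimable,
                            }
                        )
                    except ValueError as exc:
                        logger.warning("agreement cell %s failed: %s", base, exc)
                        rows.append(
                            base
                            | {
                                "n": 0,
                                "slope": float("nan"),
                                "intercept": float("nan"),
                                "r2": float("nan"),
                                "p_value": float("nan"),
                                "tier": "error",
                                "estimable": False,
                            }
                        )
    return pd.DataFrame(rows)
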