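"""Device-agreement regression: exactness, oracle equivalence, aggregation rules."""

import numpy as np
import pandas as pd
import pytest

from oracles import ols_r2_closed_form
from swayval import aggregate_pairs, agreement_table, fit_univariate, significance_tier
from swayval.agreement import PairedMetricVector


def pairs_from(x, y, **kw):
    defaults = dict(
        subject_ids=np.arange(len(x)),
        metric="rms",
        condition="EC",
        direction="ML",
        aggregation="first_trial",
    )
    defaults.update(kw)
    return PairedMetricVector(x=np.asarray(x, float), y=np.asarray(y, float), **defaults)


def synthetic_metrics(n_subjects=6, trial_values=None):
    """Hand-built metrics table with controlled per-trial values."""
    rows = []
    for sid in range(1, n_subjects + 1):
        for trial in (1, 2, 3):
            for device in ("FP", "VR"):
                v = trial_values(sid, trial, device)
                rows.append(
                    {
                        "subject_id": sid,
                        "condition": "EC",
                        "trial": trial,
                        "direction": "ML",
                        "device": device,
                        "npl_cm_per_s": v,
                        "rms_cm": v,
                        "p2p_cm": v,
                    }
                )
    return pd.DataFrame(rows)


class TestFit:
    def test_exact_line_recovered(self):
        x = np.arange(1.0, 11.0)
        res = fit_univariate(pairs_from(x, 2 * x + 1))
        assert res.slope == pytest.approx(2.0, abs=1e-12)
        assert res.intercept == pytest.approx(1.0, abs=1e-12)
        assert res.r2 == pytest.approx(1.0, abs=1e-12)
        assert res.tier == "p<.001"

    def test_closed_form_oracle(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        y = [1.2, 1.9, 3.3, 3.8, 5.1]
        res = fit_univariate(pairs_from(x, y))
        assert res.r2 == pytest.approx(ols_r2_closed_form(x, y), abs=1e-12)

    def test_r2_equals_squared_pearson(self, rng):
        for _ in range(20):
            x = rng.normal(0, 2, 30)
            y = 0.5 * x + rng.normal(0, 1, 30)
            res = fit_univariate(pairs_from(x, y))
            assert res.r2 == pytest.approx(np.corrcoef(x, y)[0, 1] ** 2, abs=1e-12)

    def test_null_r2_small_at_large_n(self, rng):
        # independent x, y: r2 ~ Beta(1/2, (n-2)/2), P(r2 < 0.02) > 0.99 at n = 1000
        x = rng.normal(0, 1, 1000)
        y = rng.normal(0, 1, 1000)
        assert fit_univariate(pairs_from(x, y)).r2 < 0.02

    def test_affine_rescaling_leaves_r2(self, rng):
        x = rng.normal(0, 1, 25)
        y = x + rng.normal(0, 0.5, 25)
        base = fit_univariate(pairs_from(x, y)).r2
        res = fit_univariate(pairs_from(100 * x - 3, 0.01 * y + 7))
        assert res.r2 == pytest.approx(base, abs=1e-12)

    def test_degenerate_variances_flagged(self):
        res = fit_univariate(pairs_from([1.0, 1.0, 1.0], [1.0, 2.0, 3.0]))
        assert not res.estimable and res.tier == "not_estimable"
        res = fit_univariate(pairs_from([1.0, 2.0, 3.0], [4.0, 4.0, 4.0]))
        assert res.r2 == 0.0 and not res.estimable

    @pytest.mark.parametrize(
        "p,expected", [(0.0005, "p<.001"), (0.001, "p<.05"), (0.049, "p<.05"), (0.05, "ns"), (0.9, "ns")]
    )
    def test_tier_boundaries(self, p, expected):
        assert significance_tier(p) == expected


class TestAggregation:
    def test_default_cohort_pair_counts(self, default_metrics):
        for agg in ("first_trial", "mean_of_3"):
            pairs = aggregate_pairs(default_metrics, "rms", "EC", "AP", agg)
            assert pairs.x.size == pairs.y.size == 20

    def test_first_trial_requires_trial_one(self, default_metrics):
        no_t1 = default_metrics[default_metrics.trial != 1]
        with pytest.raises(ValueError):
            aggregate_pairs(no_t1, "rms", "EC", "AP", "first_trial")

    def test_mean_of_3_equals_first_trial_for_constant_trials(self):
        # subject-level values identical across trials -> aggregations coincide
        metrics = synthetic_metrics(
            trial_values=lambda sid, trial, device: sid * (1.0 if device == "FP" else 2.0)
        )
        first = aggregate_pairs(metrics, "rms", "EC", "ML", "first_trial")
        mean3 = aggregate_pairs(metrics, "rms", "EC", "ML", "mean_of_3")
        np.testing.assert_allclose(first.x, mean3.x)
        np.testing.assert_allclose(first.y, mean3.y)

    def test_subject_without_device_pair_dropped(self, default_metrics):
        drop = ~((default_metrics.subject_id == 3) & (default_metrics.device == "VR"))
        pairs = aggregate_pairs(default_metrics[drop], "rms", "EC", "AP", "mean_of_3")
        assert pairs.x.size == 19
        assert 3 not in pairs.subject_ids

    def test_unknown_aggregation_rejected(self, default_metrics):
        with pytest.raises(ValueError, match="aggregation"):
            aggregate_pairs(default_metrics, "rms", "EC", "AP", "median")


class TestTable:
    def test_default_cohort_24_cells(self, default_metrics):
        table = agreement_table(default_metrics)
        assert len(table) == 24  # 3 metrics x 2 aggregations x 2 cond x 2 dir
        assert table.estimable.all()
        assert ((table.r2 >= 0) & (table.r2 <= 1)).all()

    def test_empty_metrics_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            agreement_table(pd.DataFrame())

    def test_noise_free_linkage_gives_near_unit_r2(self):
        from swayval import CohortConfig, HeadsetObservationParams, generate_cohort
        from swayval.sway_metrics import metrics_table

        cfg = CohortConfig(
            n_subjects=10,
            conditions=("EC",),
            directions=("ML",),
            seed=17,
            headset=HeadsetObservationParams(
                smooth_cutoff=4.5, jitter_sd=0.0, drift_sd=0.0, gain_log_sd=0.0
            ),
        )
        m = metrics_table(generate_cohort(cfg))
        table = agreement_table(m, conditions=("EC",), directions=("ML",))
        rms_p2p = table[table.metric.isin(["rms", "p2p"])]
        assert (rms_p2p.r2 > 0.95).all()

    def test_averaging_attenuates_trial_level_noise(self):
        """With trial-level headset-only noise, 3-trial averaging raises mean R^2.

        Holds in expectation (asserted over replicate cohorts), in a regime
        where the per-trial headset jitter dominates the linkage noise and the
        per-subject gain is fixed.
        """
        from dataclasses import replace

        from swayval import CohortConfig, HeadsetObservationParams, generate_cohort
        from swayval.sway_metrics import metrics_table

        head = HeadsetObservationParams(jitter_sd=0.3, drift_sd=0.2, gain_log_sd=0.0)
        base = CohortConfig(n_subjects=20, conditions=("EC",), directions=("ML",), headset=head)
        diffs = []
        for seed in range(25):
            m = metrics_table(generate_cohort(replace(base, seed=seed)))
            t = agreement_table(m, conditions=("EC",), directions=("ML",), metric_names=("rms",))
            r2 = t.set_index("aggregation").r2
            diffs.append(r2["mean_of_3"] - r2["first_trial"])
        assert np.mean(diffs) > 0
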