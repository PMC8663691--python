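"""One-command orchestration: cohort -> metrics -> reliability -> agreement -> report.

Outputs, under the run's output directory:

* ``metrics.csv`` -- one NPL/RMS/P2P row per trace;
* ``reliability.csv`` and ``agreement.csv`` -- the two result tables;
* ``report.md`` -- the reliability table laid out as condition x direction rows
  by (device x metric) ICC columns, and the agreement table as metric x
  aggregation row groups by condition x direction R^2 columns;
* ``run_log.json`` -- seed, parameters, and package version;
* optional per-trial FP-vs-VR overlay plots (diagnostic only).

Any stage failure aborts the run with the stage name; partial outputs are
removed so a run directory is either complete or absent.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .agreement import agreement_table
from .io_formats import CohortManifest, TraceMeta, load_cohort
from .reliability import reliability_table
from .sway_metrics import metrics_table
from .synthetic_data import CohortConfig, generate_cohort

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Exactly one cohort source: a CohortConfig to simulate, or an existing directory."""

    out_dir: Path
    simulate: CohortConfig | None = None
    cohort_dir: Path | None = None
    alpha: float = 0.05
    icc_form: str = "single"
    make_plots: bool = False
    overwrite: bool = False
    write_cohort: bool = False

    def __post_init__(self) -> None:
        if (self.simulate is None) == (self.cohort_dir is None):
            raise ValueError("exactly one of simulate / cohort_dir must be given")
        self.out_dir = Path(self.out_dir)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")


def _icc_report_table(rel: pd.DataFrame) -> pd.DataFrame:
    """Condition x direction rows by device x metric columns, 'icc (lo-hi)' cells."""
    rel = rel.copy()
    rel["cell"] = rel.apply(
        lambda r: f"{r.icc:.3f} ({r.ci_low:.3f}-{r.ci_high:.3f})"
        if r.estimable
        else "n.e.",
        axis=1,
    )
    rel["row"] = rel.condition + " (" + rel.direction.map({"ML": "M-L", "AP": "A-P"}) + ")"
    rel["col"] = rel.metric.str.upper() + " of " + rel.device + " outputs"
    col_order = [f"{m.upper()} of {d} outputs" for m in ("npl", "rms", "p2p") for d in ("FP", "VR")]
    row_order = [f"{c} ({d})" for c in ("EO", "EC") for d in ("M-L", "A-P")]
    wide = rel.pivot_table(index="row", columns="col", values="cell", aggfunc="first")
    return wide.reindex(index=row_order, columns=col_order)


def _agreement_report_table(agr: pd.DataFrame) -> pd.DataFrame:
    """Metric x aggregation rows by condition x direction columns, R^2 with tier marks."""
    marks = {"p<.001": "***", "p<.05": "*", "ns": "", "not_estimable": "n.e.", "error": "err"}
    agr = agr.copy()
    agr["cell"] = agr.apply(
        lambda r: f"{r.r2:.3f}{marks.get(r.tier, '')}" if r.estimable else marks.get(r.tier, "n.e."),
        axis=1,
    )
    agg_labels = {"first_trial": "First trial", "mean_of_3": "3-trial average"}
    agr["row"] = agr.metric.str.upper() + " / " + agr.aggregation.map(agg_labels)
    agr["col"] = (
        agr.condition + " " + agr.direction.map({"ML": "M-L", "AP": "A-P"})
    )
    row_order = [
        f"{m.upper()} / {agg_labels[a]}" for m in ("npl", "rms", "p2p") for a in ("first_trial", "mean_of_3")
    ]
    col_order = [f"{c} {d}" for c in ("EO", "EC") for d in ("M-L", "A-P")]
    wide = agr.pivot_table(index="row", columns="col", values="cell", aggfunc="first")
    return wide.reindex(index=row_order, columns=col_order)


def render_report(rel: pd.DataFrame, agr: pd.DataFrame, run_info: dict) -> str:
    lines = [
        "# Sway instrument-validation report",
        "",
        f"Package version {run_info.get('version', '?')}; seed {run_info.get('seed', 'n/a')}.",
        "",
        "## Test-retest reliability (ICC, 95% CI) across the three trials",
        "",
        _icc_report_table(rel).to_markdown(),
        "",
        "## Device agreement: COP metrics regressed on headset metrics (R^2)",
        "",
        _agreement_report_table(agr).to_markdown(),
        "",
        "`***` p < .001, `*` p < .05 (regression F test); n.e. = not estimable.",
        "",
    ]
    return "\n".join(lines)


def _overlay_plots(manifest: CohortManifest, out_dir: Path, subject_id: int = 1, trial: int = 1) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    for condition in ("EO", "EC"):
        fig, axes = plt.subplots(2, 1, figsize=(9, 6), sharex=True)
        found = False
        for ax, direction in zip(axes, ("ML", "AP")):
            try:
                fp = manifest.get_trace(TraceMeta(subject_id, condition, trial, direction, "FP"))
                vr = manifest.get_trace(TraceMeta(subject_id, condition, trial, direction, "VR"))
            except KeyError:
                continue
            found = True
            ax.plot(fp.times, fp.values, color="green", lw=0.7, label="force plate (COP)")
            ax.plot(vr.times, vr.values, color="blue", lw=1.2, label="VR headset")
            ax.set_ylabel(f"{direction} position (cm)")
            ax.legend(loc="upper right", fontsize=8)
        axes[-1].set_xlabel("time (s)")
        fig.suptitle(f"Subject {subject_id}, {condition}, trial {trial}: FP vs VR traces")
        if found:
            fig.savefig(out_dir / f"overlay_S{subject_id:02d}_{condition}_T{trial}.png", dpi=120)
        plt.close(fig)


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis; returns paths and in-memory tables."""
    out_dir = config.out_dir
    if out_dir.exists() and any(out_dir.iterdir()) and not config.overwrite:
        raise FileExistsError(f"{out_dir} exists and is not empty; pass overwrite=True")
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        stage = "cohort"
        if config.simulate is not None:
            cohort_dir = out_dir / "cohort" if config.write_cohort else None
            manifest = generate_cohort(config.simulate, out_dir=cohort_dir, overwrite=config.overwrite)
        else:
            manifest = load_cohort(Path(config.cohort_dir) / "manifest.csv")

        stage = "metrics"
        metrics = metrics_table(manifest)
        p = out_dir / "metrics.csv"
        metrics.to_csv(p, index=False, float_format="%.10g")
        written.append(p)

        stage = "reliability"
        rel = reliability_table(metrics, alpha=config.alpha, form=config.icc_form)
        p = out_dir / "reliability.csv"
        rel.to_csv(p, index=False, float_format="%.10g")
        written.append(p)

        stage = "agreement"
        agr = agreement_table(metrics, alpha=config.alpha)
        p = out_dir / "agreement.csv"
        agr.to_csv(p, index=False, float_format="%.10g")
        written.append(p)

        stage = "report"
        run_info = {
            "version": __version__,
            "seed": None if config.simulate is None else config.simulate.seed,
            "alpha": config.alpha,
            "icc_form": config.icc_form,
            "cohort": "simulated" if config.simulate is not None else str(config.cohort_dir),
            "config": dataclasses.asdict(config.simulate) if config.simulate is not None else None,
        }
        p = out_dir / "report.md"
        p.write_text(render_report(rel, agr, run_info), encoding="utf-8")
        written.append(p)
        p = out_dir / "run_log.json"
        p.write_text(json.dumps(run_info, indent=2, default=str), encoding="utf-8")
        written.append(p)

        if config.make_plots:
            stage = "plots"
            _overlay_plots(manifest, out_dir)
    except Exception as exc:
        for p in written:
            p.unlink(missing_ok=True)
        raise PipelineError(stage, exc) from exc

    return {"out_dir": out_dir, "metrics": metrics, "reliability": rel, "agreement": agr}
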