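"""End-to-end analysis pipeline and report rendering.

``run_pipeline`` ties the stages together: read (or simulate) trial and
anchor tables, aggregate trials into limb/dog metrics, compute change
scores, join the anchor grouping, run the supporting hypothesis tests,
and estimate the six MCIDs per measurement.  It emits three report
tables —

* **cohort summary** — per measurement: n, T0 and D15 mean/SD, and the
  paired signed-rank p-value for the T0 → D15 change;
* **group summary** — the same statistics split by anchor group, with
  rank-test p-values comparing the groups at T0, at D15 and on change;
* **MCID table** — AC, CD, MDC, ROC cutoff (AUC) and the two
  distribution-based estimates, with the AUC discriminative label —

plus ROC point files, a machine-readable run manifest and a plain-text
rendering.  Report rounding follows the clinical convention used
throughout: anchor-based estimates to one decimal, distribution-based
to two, AUC to three.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import __version__
from .cohort_anchor import GROUP_BETTER, GROUP_SAME, build_analysis_table
from .exceptions import DegenerateDataError, ValidationError
from .group_stats import mann_whitney, wilcoxon_signed_rank
from .io import (
    read_anchors_csv,
    read_trials_csv,
    write_anchors_csv,
    write_trials_csv,
)
from .mcid_estimators import (
    MCIDEstimateSet,
    ReliabilityInput,
    group_summaries,
    summarize_mcid,
)
from .roc_analysis import ROCResult, classify_auc
from .stance_metrics import (
    DEFAULT_MIN_TRIALS,
    DEFAULT_SUM_TOL,
    aggregate_cohort,
    build_change_table,
    cohort_summary,
)
from .synthetic_cohort import GeneratorConfig, generate_cohort

logger = logging.getLogger(__name__)

MEASUREMENT_TITLES = {"deviation": "Deviation", "si": "Symmetry Index"}


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration of one pipeline run.

    Exactly one input source must be active: CSV paths
    (``trials_path`` + ``anchors_path``) or a simulation config.
    """

    trials_path: Optional[Path] = None
    anchors_path: Optional[Path] = None
    simulate: Optional[GeneratorConfig] = None
    reliability: Optional[float] = None
    reliability_source: str = ""
    confidence: float = 0.95
    sd_source: str = "t0"
    use_z: bool = False
    min_trials: int = DEFAULT_MIN_TRIALS
    sum_tol: float = DEFAULT_SUM_TOL
    output_dir: Optional[Path] = None

    def validate(self) -> None:
        from_files = self.trials_path is not None or self.anchors_path is not None
        if from_files and self.simulate is not None:
            raise ValidationError("pass input CSV paths or a simulation config, not both")
        if not from_files and self.simulate is None:
            raise ValidationError("no input: supply trials+anchors CSVs or simulate")
        if from_files and (self.trials_path is None or self.anchors_path is None):
            raise ValidationError("both trials_path and anchors_path are required")


@dataclass
class PipelineReport:
    limb_table: pd.DataFrame
    dog_table: pd.DataFrame
    analysis_table: pd.DataFrame
    cohort_table: pd.DataFrame
    group_table: pd.DataFrame
    estimates: list[MCIDEstimateSet]
    rocs: dict[str, ROCResult]
    manifest: dict
    text: str
    output_dir: Optional[Path] = None
    written: list[str] = field(default_factory=list)


def _cohort_table(change_table: pd.DataFrame) -> pd.DataFrame:
    table = cohort_summary(change_table)
    pvals = []
    for measurement in table["measurement"]:
        grp = change_table[change_table["measurement"] == measurement]
        try:
            pvals.append(wilcoxon_signed_rank(grp["value_t0"], grp["value_d15"]).p_value)
        except DegenerateDataError:
            # no change anywhere: nothing to test
            pvals.append(float("nan"))
    table["p_value"] = pvals
    return table


def _group_table(analysis: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for measurement in sorted(analysis["measurement"].unique()):
        sub = analysis[analysis["measurement"] == measurement]
        same = sub[sub["group"] == GROUP_SAME]
        better = sub[sub["group"] == GROUP_BETTER]
        p_t0 = mann_whitney(same["value_t0"], better["value_t0"]).p_value
        p_d15 = mann_whitney(same["value_d15"], better["value_d15"]).p_value
        p_change = mann_whitney(same["change"], better["change"]).p_value
        for summary in group_summaries(analysis, measurement):
            row = {"measurement": measurement, **vars(summary)}
            row.update(p_t0=p_t0, p_d15=p_d15, p_change=p_change)
            rows.append(row)
    return pd.DataFrame(rows)


def _fmt(value: float, decimals: int) -> str:
    return f"{value:.{decimals}f}"


def mcid_table(
    estimates: list[MCIDEstimateSet], rounded: bool = True
) -> pd.DataFrame:
    """MCID estimates as a frame (optionally at report precision)."""
    rows = []
    for est in estimates:
        rows.append(
            {
                "measurement": est.measurement,
                "ac": round(est.ac, 1) if rounded else est.ac,
                "cd": round(est.cd, 1) if rounded else est.cd,
                "mdc": round(est.mdc, 1) if rounded else est.mdc,
                "roc_cutoff": round(est.roc_cutoff, 1) if rounded else est.roc_cutoff,
                "roc_auc": round(est.roc_auc, 3) if rounded else est.roc_auc,
                "auc_label": classify_auc(est.roc_auc),
                "effect_size_mcid": round(est.effect_size_mcid, 2)
                if rounded
                else est.effect_size_mcid,
                "sem_mcid": (
                    None
                    if est.sem_mcid is None
                    else (round(est.sem_mcid, 2) if rounded else est.sem_mcid)
                ),
            }
        )
    return pd.DataFrame(rows)


def render_tables(
    estimates: list[MCIDEstimateSet],
    sd_source: str = "t0",
    footnotes: tuple[str, ...] = (),
) -> str:
    """Aligned plain-text MCID table (column order AC, CD, MDC,
    ROC cutoff (AUC), effect size, SEM)."""
    header = [
        "Measurement",
        "AC",
        "CD",
        "MDC",
        "ROC cutoff (AUC)",
        "Effect size",
        "SEM",
    ]
    body = []
    for est in estimates:
        roc = (
            f"{_fmt(est.roc_cutoff, 1)} ({_fmt(est.roc_auc, 3)})"
            if est.roc_cutoff == est.roc_cutoff  # not NaN
            else f"n/a ({_fmt(est.roc_auc, 3)})"
        )
        body.append(
            [
                MEASUREMENT_TITLES.get(est.measurement, est.measurement),
                _fmt(est.ac, 1),
                _fmt(est.cd, 1),
                _fmt(est.mdc, 1),
                roc,
                f"±{_fmt(est.effect_size_mcid, 2)}",
                "n/a" if est.sem_mcid is None else f"±{_fmt(est.sem_mcid, 2)}",
            ]
        )
    widths = [
        max(len(header[i]), *(len(r[i]) for r in body)) if body else len(header[i])
        for i in range(len(header))
    ]
    lines = [
        "  ".join(h.ljust(w) for h, w in zip(header, widths)),
        "  ".join("-" * w for w in widths),
    ]
    lines += ["  ".join(cell.ljust(w) for cell, w in zip(row, widths)) for row in body]
    lines.append("")
    lines.append(
        f"Distribution-based estimates use the {sd_source.upper()} score SD; "
        "anchor-based estimates are signed (negative = improvement)."
    )
    for note in footnotes:
        lines.append(note)
    return "\n".join(lines) + "\n"


def run_pipeline(config: PipelineConfig) -> PipelineReport:
    """Run the full analysis and (optionally) write the report bundle."""
    config.validate()
    simulated = config.simulate is not None
    if simulated:
        cohort = generate_cohort(config.simulate)
        trials, anchors = cohort.trials, cohort.anchors
        logger.info(
            "simulated cohort: %d dogs, seed %d",
            config.simulate.n_dogs,
            config.simulate.seed,
        )
    else:
        trials = read_trials_csv(config.trials_path)
        anchors = read_anchors_csv(config.anchors_path)
        cohort = None

    limb_table, dog_table = aggregate_cohort(
        trials, min_trials=config.min_trials, sum_tol=config.sum_tol
    )
    change_table = build_change_table(limb_table, dog_table)
    analysis = build_analysis_table(change_table, anchors)

    cohort_tbl = _cohort_table(change_table)
    group_tbl = _group_table(analysis)
    reliability = (
        None
        if config.reliability is None
        else ReliabilityInput(config.reliability, config.reliability_source)
    )
    estimates, rocs = summarize_mcid(
        analysis,
        reliability=reliability,
        confidence=config.confidence,
        sd_source=config.sd_source,
        use_z=config.use_z,
    )

    footnotes = [
        "Units: deviation in percent body-weight points; SI unitless (x100).",
        "Limb-level rows share a dog (two limbs per dog); p-values do not "
        "adjust for within-dog clustering.",
    ]
    if analysis.attrs.get("si_replicated"):
        footnotes.append(
            "SI is computed per dog and replicated onto both limbs for the "
            "limb-level table."
        )
    text = render_tables(estimates, sd_source=config.sd_source, footnotes=tuple(footnotes))

    manifest = {
        "package": "stancemcid",
        "version": __version__,
        "input": "simulated" if simulated else "csv",
        "generator_config": (
            None if not simulated else {**vars(config.simulate)}
        ),
        "seed": None if not simulated else config.simulate.seed,
        "estimator_settings": {
            "confidence": config.confidence,
            "sd_source": config.sd_source,
            "use_z": config.use_z,
            "reliability": config.reliability,
            "reliability_source": config.reliability_source,
            "min_trials": config.min_trials,
            "sum_tol": config.sum_tol,
        },
        "n_units": int(len(change_table)),
        "n_excluded_units": int(analysis.attrs.get("n_excluded_units", 0)),
        "group_sizes": {
            f"{m}/{g}": int(v)
            for (m, g), v in analysis.attrs.get("group_sizes", {}).items()
        },
        "n_truncated_trials": (
            None
            if cohort is None or cohort.truth is None
            else cohort.truth.n_truncated_trials
        ),
    }

    report = PipelineReport(
        limb_table=limb_table,
        dog_table=dog_table,
        analysis_table=analysis,
        cohort_table=cohort_tbl,
        group_table=group_tbl,
        estimates=estimates,
        rocs=rocs,
        manifest=manifest,
        text=text,
        output_dir=config.output_dir,
    )
    if config.output_dir is not None:
        _write_bundle(report, trials, anchors, simulated)
    return report


def _write_bundle(
    report: PipelineReport, trials: pd.DataFrame, anchors: pd.DataFrame, simulated: bool
) -> None:
    out = Path(report.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    def save(df: pd.DataFrame, name: str) -> None:
        df.to_csv(out / name, index=False)
        report.written.append(name)

    if simulated:
        write_trials_csv(trials, out / "trials.csv")
        write_anchors_csv(anchors, out / "anchors.csv")
        report.written += ["trials.csv", "anchors.csv"]
    save(report.limb_table, "limb_table.csv")
    save(report.dog_table, "dog_table.csv")
    save(report.analysis_table, "analysis_table.csv")
    save(report.cohort_table, "cohort_summary.csv")
    save(report.group_table, "group_summary.csv")
    save(mcid_table(report.estimates), "mcid_estimates.csv")
    for measurement, roc in report.rocs.items():
        save(roc.points, f"roc_points_{measurement}.csv")
    (out / "mcid_report.txt").write_text(report.text, encoding="utf-8")
    report.written.append("mcid_report.txt")
    (out / "manifest.json").write_text(
        json.dumps(report.manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    report.written.append("manifest.json")
    logger.info("wrote %d report files to %s", len(report.written), out)
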