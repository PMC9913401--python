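"""Three-analysis comparison: original life table vs simulated
deprivation-specific life tables.

One cohort is analyzed once per life table: the non-parametric arm computes
age-standardized net survival per deprivation quintile and the Q1-Q5 gap at
1 and 5 years; the flexible arm selects among the four EDI-effect model forms
by corrected AIC and evaluates excess-hazard-ratio curves.  Each sensitivity
analysis is then classified against the main analysis as ``consistent``,
``attenuated``, ``inconsistent`` or ``inversed`` using explicit, configurable
rules (CI overlap, sign flips, and changes of the selected form to or from
"no effect").
"""

from __future__ import annotations

import dataclasses
import json
import pathlib
import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from . import excess_model as em
from . import netsurv as ns
from .lifetables import LifeTable

__all__ = [
    "RunConfig",
    "AnalysisResult",
    "ComparisonReport",
    "run_comparison",
    "write_report",
    "read_report",
    "classify_concordance",
]

SCHEMA_VERSION = 1


@dataclasses.dataclass
class RunConfig:
    """Knobs of one comparison run (all defaults are plain conventions)."""

    horizons: tuple[float, float] = (1.0, 5.0)
    age_groups: Sequence[tuple[float, float]] = ns.ICSS_AGE_GROUPS
    weights: Sequence[float] = ns.ICSS_WEIGHTS
    run_flexible: bool = True
    basis_config: em.BasisConfig | None = None
    penalty_grid: Sequence[float] = em.DEFAULT_PENALTY_GRID
    gl_nodes: int = 12
    ehr_time_grid: tuple[float, ...] = tuple(np.linspace(0.05, 5.0, 25))
    ehr_eval_time: float = 1.0
    # concordance thresholds
    sign_eps: float = 0.0       # gaps within +-eps count as zero-signed
    grid_step: float = 1.0 / 52.0


@dataclasses.dataclass
class AnalysisResult:
    label: str
    stratified: bool
    gaps: dict[float, ns.DeprivationGap]
    asns_by_quintile: dict[int, dict[float, float]]
    selected_form: int | None = None
    aicc_table: dict[int, float] | None = None
    ehr_vs_edi: em.EHRCurve | None = None
    ehr_over_time: list[em.EHRCurve] | None = None
    error: str | None = None

    def to_dict(self) -> dict:
        out = {
            "label": self.label,
            "stratified": self.stratified,
            "gaps": {str(h): g.to_dict() for h, g in self.gaps.items()},
            "asns_by_quintile": {
                str(q): {str(h): (None if not np.isfinite(v) else float(v))
                         for h, v in d.items()}
                for q, d in self.asns_by_quintile.items()
            },
            "selected_form": self.selected_form,
            "aicc_table": None if self.aicc_table is None
            else {str(k): (None if np.isnan(v) else float(v))
                  for k, v in self.aicc_table.items()},
            "error": self.error,
        }
        return out


@dataclasses.dataclass
class ComparisonReport:
    analyses: dict[str, AnalysisResult]
    concordance: dict[str, str]
    main_label: str

    def to_dict(self) -> dict:
        return {
            "schema_version": SCHEMA_VERSION,
            "main_label": self.main_label,
            "analyses": {k: v.to_dict() for k, v in self.analyses.items()},
            "concordance": self.concordance,
        }


def _overlap(a: ns.DeprivationGap, b: ns.DeprivationGap) -> bool:
    return a.ci_low <= b.ci_high and b.ci_low <= a.ci_high


def classify_concordance(
    main: AnalysisResult, sens: AnalysisResult, config: RunConfig, horizon: float = 5.0
) -> str:
    """Declared operationalization of the consistent / attenuated /
    inconsistent / inversed reading of a sensitivity analysis."""
    if main.error or sens.error:
        return "failed"
    gm, gs = main.gaps[horizon], sens.gaps[horizon]
    sgn = lambda x: 0.0 if abs(x) <= config.sign_eps else np.sign(x)
    if sgn(gm.gap) * sgn(gs.gap) < 0 and not _overlap(gm, gs):
        return "inversed"
    if main.selected_form is not None and sens.selected_form is not None:
        if (main.selected_form == 1) != (sens.selected_form == 1):
            return "inconsistent"
    if sgn(gm.gap) == sgn(gs.gap) and abs(gs.gap) < abs(gm.gap):
        return "attenuated"
    same_form = (main.selected_form is None or sens.selected_form is None
                 or main.selected_form == sens.selected_form)
    if same_form and _overlap(gm, gs):
        return "consistent"
    return "inconsistent"


def _analyze(
    label: str, cohort: pd.DataFrame, lt: LifeTable, config: RunConfig
) -> AnalysisResult:
    horizons = list(config.horizons)
    gaps = {
        h: ns.deprivation_gap(
            cohort, lt, horizon=h, age_groups=config.age_groups,
            weights=config.weights, grid_step=config.grid_step,
        )
        for h in horizons
    }
    asns: dict[int, dict[float, float]] = {}
    for q in range(1, 6):
        sub = cohort.loc[cohort["quintile"] == q]
        if sub.empty:
            continue
        curve = ns.age_standardized_ns(
            sub, lt, horizons, age_groups=config.age_groups,
            weights=config.weights, grid_step=config.grid_step,
        )
        asns[q] = {h: float(v) for h, v in zip(curve.time, curve.ns)}
    result = AnalysisResult(
        label=label,
        stratified=lt.stratified_by_deprivation,
        gaps=gaps,
        asns_by_quintile=asns,
    )
    if config.run_flexible:
        try:
            fit, table = em.select_model(
                cohort, lt, basis_config=config.basis_config,
                penalty_grid=config.penalty_grid, gl_nodes=config.gl_nodes,
            )
            result.selected_form = fit.form
            result.aicc_table = table
            med_age = float(cohort["age_dx"].median())
            result.ehr_vs_edi = em.ehr_vs_edi(fit, config.ehr_eval_time, med_age)
            result.ehr_over_time = em.ehr_p90_p10_over_time(
                fit, np.asarray(config.ehr_time_grid)
            )
        except (em.FitError, ValueError) as exc:
            warnings.warn(f"flexible arm failed for {label!r}: {exc}", stacklevel=2)
            result.error = str(exc)
    return result


def run_comparison(
    cohort: pd.DataFrame,
    lt_main: LifeTable,
    lt_sims: Sequence[tuple[str, LifeTable]],
    config: RunConfig | None = None,
    main_label: str = "main",
) -> ComparisonReport:
    """Analyze one cohort under the main table and each simulated table."""
    config = config or RunConfig()
    if lt_main.stratified_by_deprivation:
        raise ValueError("the main life table must be unstratified")
    labels = [main_label] + [lab for lab, _ in lt_sims]
    if len(set(labels)) != len(labels):
        raise ValueError("analysis labels must be unique")
    for lab, lt in lt_sims:
        if not lt.stratified_by_deprivation:
            raise ValueError(f"sensitivity table {lab!r} must be deprivation-stratified")
    ns.validate_cohort(cohort)

    analyses = {main_label: _analyze(main_label, cohort, lt_main, config)}
    for lab, lt in lt_sims:
        analyses[lab] = _analyze(lab, cohort, lt, config)
    concordance = {
        lab: classify_concordance(analyses[main_label], analyses[lab], config)
        for lab, _ in lt_sims
    }
    return ComparisonReport(
        analyses=analyses, concordance=concordance, main_label=main_label
    )


def write_report(report: ComparisonReport, path, strict: bool = False) -> list[str]:
    """Write report.json plus delimited curve files; returns written names.

    With ``strict`` a failed analysis arm raises after writing."""
    path = pathlib.Path(path)
    path.mkdir(parents=True, exist_ok=True)
    written = []
    with open(path / "report.json", "w") as fh:
        json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    written.append("report.json")
    for lab in sorted(report.analyses):
        res = report.analyses[lab]
        if res.ehr_vs_edi is not None:
            name = f"ehr_vs_edi_{lab}.csv"
            res.ehr_vs_edi.to_frame().to_csv(path / name, index=False)
            written.append(name)
        if res.ehr_over_time is not None:
            name = f"ehr_over_time_{lab}.csv"
            pd.concat([c.to_frame() for c in res.ehr_over_time]).to_csv(
                path / name, index=False
            )
            written.append(name)
    failed = [lab for lab, res in report.analyses.items() if res.error]
    if strict and failed:
        raise RuntimeError(f"analysis arm(s) failed: {failed}")
    return written


def read_report(path) -> dict:
    with open(pathlib.Path(path) / "report.json") as fh:
        return json.load(fh)
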