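"""Full-cohort analysis: the model object, its results, and report rendering.

:class:`CohortAnalysis` is built from a cohort (or a DataFrame / CSV path) and
``fit()`` runs the whole analysis plan: per-variable marginals, age
descriptives, the cross-tabulation battery mirroring the study's published
tables (each pairing tested with Pearson chi-square, with a Monte Carlo
simulated p attached automatically whenever any expected cell count falls
below 5), the composite-score distribution and its association battery, ROC
evaluation of the score against both advanced-disease endpoints, the
Kruskal-Wallis comparison of Ki-67 across age classes, and the sample-size
note.  The returned :class:`AnalysisResults` carries every statistic plus the
seeds and replicate counts needed to recompute it, and renders to JSON,
Markdown or TSV.

When only published two-way tables are available (no patient-level data),
:func:`score_table_battery` runs the score association battery directly on
the shipped fixtures.
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd

from . import __version__
from .cohort import (
    Cohort,
    ContingencyTable,
    read_cohort_csv,
    crosstab,
    VOCABULARIES,
)
from .fixtures import fixture
from .power import PowerSpec
from .roc import ENDPOINTS, RocResult, endpoint_labels, evaluate_score
from .score import score_cohort
from .stats import (
    ChiSquareResult,
    KruskalWallisResult,
    MeanSummary,
    ProportionCI,
    clopper_pearson,
    kruskal_wallis,
    pearson_chi_square,
    summarize_numeric,
)

__all__ = [
    "RunSettings",
    "BatteryEntry",
    "AnalysisResults",
    "CohortAnalysis",
    "score_table_battery",
    "diagnostic_yield",
    "render_report",
]

logger = logging.getLogger(__name__)

#: The cross-tabulation plan, mirroring the study's table structure:
#: (section, row_var, col_var).
CROSSTAB_PLAN: tuple[tuple[str, str, str], ...] = (
    ("by_sex", "residence", "sex"),
    ("by_sex", "smoker", "sex"),
    ("by_sex", "comorbidity", "sex"),
    ("by_sex", "occupational_exposure", "sex"),
    ("by_residence", "smoker", "residence"),
    ("by_residence", "comorbidity", "residence"),
    ("by_residence", "occupational_exposure", "residence"),
    ("by_exposure", "smoker", "occupational_exposure"),
    ("by_exposure", "comorbidity", "occupational_exposure"),
    ("by_smoking", "smoker", "comorbidity"),
    ("by_group", "sex", "diagnostic_group"),
    ("by_group", "comorbidity", "diagnostic_group"),
    ("by_group", "tnm_stage", "diagnostic_group"),
    ("by_group", "p63", "diagnostic_group"),
    ("by_group", "pdl1", "diagnostic_group"),
    ("by_group", "egfr", "diagnostic_group"),
    ("by_group", "occupational_exposure", "diagnostic_group"),
    ("by_age_class", "sex", "age_class"),
    ("by_age_class", "smoker", "age_class"),
    ("by_age_class", "residence", "age_class"),
    ("by_age_class", "comorbidity_any", "age_class"),
    ("by_age_class", "diagnostic_group", "age_class"),
    ("by_age_class", "tnm_stage", "age_class"),
    ("by_age_class", "p63", "age_class"),
    ("by_age_class", "pdl1", "age_class"),
    ("by_age_class", "egfr_binary", "age_class"),
    ("by_age_class", "occupational_exposure", "age_class"),
    ("by_score", "diagnostic_group", "exposure_class"),
    ("by_score", "comorbidity_any", "exposure_class"),
    ("by_score", "histology", "exposure_class"),
    ("by_score", "tnm_stage", "exposure_class"),
    ("by_score", "p63", "exposure_class"),
    ("by_score", "pdl1", "exposure_class"),
    ("by_score", "egfr_binary", "exposure_class"),
    ("by_score", "occupational_exposure", "exposure_class"),
)

#: Fixture ids of the published score-association battery.
SCORE_BATTERY_IDS: tuple[str, ...] = (
    "table7_group_score",
    "table7_comorbidity_score",
    "table7_histology_score",
    "table7_tnm_score",
    "table7_p63_score",
    "table7_pdl1_score",
    "table7_egfr_score",
    "table7_exposure_score",
)


@dataclass(frozen=True)
class RunSettings:
    """Run configuration: seeds, replicate counts and the Monte Carlo trigger."""

    seed: int = 0
    mc_reps: int = 10_000
    boot_reps: int = 1000
    mc_threshold: float = 5.0
    level: float = 0.95
    power_w: float = 0.25
    power_alpha: float = 0.05
    power_target: float = 0.80
    power_df: int = 1
    #: optional (conclusive, rebiopsy) counts for the diagnostic-yield note.
    diagnostic_counts: tuple[int, int] | None = None


@dataclass(frozen=True)
class BatteryEntry:
    """One cross-tabulation with its chi-square result."""

    section: str
    row_var: str
    col_var: str
    table: ContingencyTable
    chi_square: ChiSquareResult


@dataclass(frozen=True)
class AnalysisResults:
    """Everything the analysis computed, with the seeds needed to recompute it."""

    n: int
    marginals: dict[str, dict[str, int]]
    age_summary: MeanSummary | None
    batteries: tuple[BatteryEntry, ...]
    score_summary: dict[str, int]
    roc: dict[str, RocResult]
    ki67_by_age_class: KruskalWallisResult | None
    power: PowerSpec
    diagnostic: dict[str, ProportionCI] | None
    settings: RunSettings
    version: str = __version__

    def battery(self, row_var: str, col_var: str) -> BatteryEntry:
        for entry in self.batteries:
            if (entry.row_var, entry.col_var) == (row_var, col_var):
                return entry
        raise KeyError(f"no battery entry for {row_var} x {col_var}")

    def to_dict(self) -> dict:
        """Lossless, JSON-serializable representation."""
        return json.loads(json.dumps(asdict(self), default=_jsonable))

    def to_json(self, indent: int = 1) -> str:
        return json.dumps(asdict(self), default=_jsonable, indent=indent)

    def summary(self) -> str:
        """Human-readable overview of the fitted analysis."""
        lines = [
            "EXPoSURE cohort analysis".center(64),
            "=" * 64,
            f"n patients: {self.n:>5}    package version: {self.version}",
            f"seed: {self.settings.seed}   MC replicates: {self.settings.mc_reps}"
            f"   bootstrap replicates: {self.settings.boot_reps}",
        ]
        if self.age_summary is not None:
            a = self.age_summary
            lines += [
                "-" * 64,
                f"Age (years): mean {a.mean:.2f} (sd {a.sd:.2f}), "
                f"95% CI [{a.ci_t[0]:.2f}, {a.ci_t[1]:.2f}], "
                f"median {a.median:.1f}, skewness {a.skewness:.3f}",
            ]
        lines += ["-" * 64, "Composite score classes: "
                  + ", ".join(f"{k}={v}" for k, v in self.score_summary.items())]
        lines += ["-" * 64,
                  f"{'pairing':<38}{'chi2':>8}{'df':>4}{'p':>8}{'V':>7}  MC"]
        for e in self.batteries:
            c = e.chi_square
            mc = f" p_mc={c.monte_carlo.p_hat:.3f}" if c.monte_carlo else ""
            lines.append(
                f"{e.row_var + ' x ' + e.col_var:<38}"
                f"{c.statistic:>8.3f}{c.df:>4}{c.p_asymptotic:>8.3f}"
                f"{c.cramers_v:>7.3f}{mc}"
            )
        lines.append("-" * 64)
        for name, r in self.roc.items():
            lines.append(
                f"ROC {name}: AUC {r.auc:.3f} "
                f"(95% CI {r.ci_low:.3f}-{r.ci_high:.3f}), "
                f"corrected {r.corrected_auc:.3f}"
            )
        if self.ki67_by_age_class is not None:
            k = self.ki67_by_age_class
            lines.append(
                f"Ki-67 by age class: H={k.H:.3f}, df={k.df}, p={k.p:.3f}"
            )
        p = self.power
        lines.append(
            f"Design: w={p.w}, alpha={p.alpha}, power={p.power}, df={p.df}"
            f" => required n = {p.n_required}"
        )
        if self.diagnostic:
            for key, ci in self.diagnostic.items():
                lines.append(
                    f"{key}: {100 * ci.p_hat:.1f}% "
                    f"(95% CI {100 * ci.ci_low:.1f}-{100 * ci.ci_high:.1f}%)"
                )
        lines.append("=" * 64)
        return "\n".join(lines)


def _jsonable(obj):
    if isinstance(obj, ContingencyTable):
        return {
            "row_var": obj.row_var,
            "col_var": obj.col_var,
            "row_labels": list(obj.row_labels),
            "col_labels": list(obj.col_labels),
            "counts": [list(r) for r in obj.counts],
        }
    if hasattr(obj, "__dataclass_fields__"):
        return asdict(obj)
    if isinstance(obj, tuple):
        return list(obj)
    raise TypeError(f"not JSON-serializable: {type(obj)}")


class CohortAnalysis:
    """The analysis model: a cohort plus run settings; ``fit()`` yields results."""

    def __init__(self, cohort: Cohort, settings: RunSettings | None = None):
        if cohort.n == 0:
            raise ValueError("cannot analyse an empty cohort")
        self.cohort = cohort
        self.settings = settings or RunSettings()

    @classmethod
    def from_csv(cls, path: str | Path, settings: RunSettings | None = None):
        return cls(read_cohort_csv(path), settings)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, settings: RunSettings | None = None):
        return cls(Cohort.from_dataframe(df), settings)

    def _test_table(self, table: ContingencyTable, seed: int) -> ChiSquareResult:
        """Chi-square with the automatic Monte Carlo trigger."""
        s = self.settings
        result = pearson_chi_square(table)
        if result.min_expected < s.mc_threshold:
            logger.info(
                "min expected %.2f < %.1f for %s x %s: attaching Monte Carlo p",
                result.min_expected, s.mc_threshold, table.row_var, table.col_var,
            )
            result = pearson_chi_square(table, mc_replicates=s.mc_reps, seed=seed)
        return result

    def fit(self) -> AnalysisResults:
        s = self.settings
        cohort = self.cohort
        _, score_summary = score_cohort(cohort)

        marginals: dict[str, dict[str, int]] = {}
        for var in VOCABULARIES:
            counts = Counter(getattr(r, var) for r in cohort)
            marginals[var] = {lab: counts.get(lab, 0) for lab in VOCABULARIES[var]}

        ages = [r.age_years for r in cohort if r.age_years is not None]
        age_summary = summarize_numeric(ages, s.level) if len(ages) >= 3 else None

        batteries = []
        for i, (section, row_var, col_var) in enumerate(CROSSTAB_PLAN):
            table = crosstab(cohort, row_var, col_var)
            result = self._test_table(table, seed=s.seed * 1000 + i)
            batteries.append(
                BatteryEntry(section, row_var, col_var, table, result)
            )

        from .score import score_record  # local import keeps module load light

        points = [score_record(r).points for r in cohort]
        roc: dict[str, RocResult] = {}
        for j, name in enumerate(ENDPOINTS):
            labels = endpoint_labels(cohort, name)
            if labels.min() == labels.max():
                logger.warning("endpoint %s has a single class; skipping ROC", name)
                continue
            roc[name] = evaluate_score(
                points, labels, endpoint=name,
                B=s.boot_reps, seed=s.seed * 100 + j, level=s.level,
            )

        ki67 = [r.ki67_percent for r in cohort]
        age_classes = [r.age_class for r in cohort]
        kw = None
        if all(v is not None for v in ki67) and all(a is not None for a in age_classes):
            if len(set(age_classes)) >= 2:
                kw = kruskal_wallis(ki67, age_classes)

        power = PowerSpec.solve(s.power_w, s.power_alpha, s.power_target, s.power_df)

        diagnostic = None
        if s.diagnostic_counts is not None:
            conclusive, rebiopsy = s.diagnostic_counts
            diagnostic = diagnostic_yield(conclusive, rebiopsy, cohort.n, s.level)

        return AnalysisResults(
            n=cohort.n,
            marginals=marginals,
            age_summary=age_summary,
            batteries=tuple(batteries),
            score_summary=score_summary,
            roc=roc,
            ki67_by_age_class=kw,
            power=power,
            diagnostic=diagnostic,
            settings=s,
        )


def score_table_battery(
    mc_reps: int = 10_000, seed: int = 0, mc_threshold: float = 5.0
) -> dict[str, ChiSquareResult]:
    """The published score-association battery, computed from the shipped tables.

    Used when only aggregated (two-way) data exist; each fixture is tested
    with Pearson chi-square, Monte Carlo p attached when the expected-cell
    trigger fires.
    """
    results: dict[str, ChiSquareResult] = {}
    for i, table_id in enumerate(SCORE_BATTERY_IDS):
        table = fixture(table_id).table
        result = pearson_chi_square(table)
        if result.min_expected < mc_threshold:
            result = pearson_chi_square(
                table, mc_replicates=mc_reps, seed=seed * 1000 + i
            )
        results[table_id] = result
    return results


def diagnostic_yield(
    conclusive: int, rebiopsy: int, n: int, level: float = 0.95
) -> dict[str, ProportionCI]:
    """Exact CIs for the diagnostic yield and the rebiopsy rate."""
    if conclusive + rebiopsy != n:
        raise ValueError(
            f"conclusive ({conclusive}) + rebiopsy ({rebiopsy}) must equal n ({n})"
        )
    return {
        "diagnostic_yield": clopper_pearson(conclusive, n, level),
        "rebiopsy_rate": clopper_pearson(rebiopsy, n, level),
    }


def _format_table_md(table: ContingencyTable, n_total: int) -> list[str]:
    lines = ["| " + table.row_var + " | " + " | ".join(table.col_labels) + " |"]
    lines.append("|" + "---|" * (len(table.col_labels) + 1))
    arr = table.to_array()
    for i, rl in enumerate(table.row_labels):
        cells = [
            f"{arr[i, j]} ({100 * arr[i, j] / n_total:.1f}%)"
            for j in range(arr.shape[1])
        ]
        lines.append("| " + rl + " | " + " | ".join(cells) + " |")
    return lines


def render_report(results: AnalysisResults, fmt: str) -> dict[str, str]:
    """Render an analysis report as ``{filename: content}`` text files.

    ``json`` is lossless (parses back to ``to_dict()``); ``markdown`` mirrors
    the published table layout (one section per battery, percentages of the
    full cohort, chi-square to 3 decimals); ``tsv`` emits machine-readable
    tables whose counts round-trip.
    """
    if fmt == "json":
        return {"report.json": results.to_json()}
    if fmt == "markdown":
        lines = ["# Cohort analysis report", "", "```", results.summary(), "```", ""]
        sections: dict[str, list[BatteryEntry]] = {}
        for e in results.batteries:
            sections.setdefault(e.section, []).append(e)
        for section, entries in sections.items():
            lines.append(f"## {section}")
            for e in entries:
                c = e.chi_square
                lines.append("")
                lines.append(
                    f"### {e.row_var} x {e.col_var} "
                    f"(chi2 = {c.statistic:.3f}, df = {c.df}, "
                    f"p = {c.p_asymptotic:.3f}, V = {c.cramers_v:.3f})"
                )
                if c.monte_carlo:
                    mc = c.monte_carlo
                    lines.append(
                        f"Monte Carlo p = {mc.p_hat:.3f} "
                        f"({100 * mc.level:.0f}% CI {mc.ci_low:.3f}-{mc.ci_high:.3f}, "
                        f"B = {mc.replicates})"
                    )
                lines += _format_table_md(e.table, results.n)
            lines.append("")
        return {"report.md": "\n".join(lines)}
    if fmt == "tsv":
        blocks = []
        for e in results.batteries:
            arr = e.table.to_array()
            header = "\t".join([f"{e.row_var}|{e.col_var}", *e.table.col_labels])
            rows = [
                "\t".join([rl, *(str(v) for v in arr[i])])
                for i, rl in enumerate(e.table.row_labels)
            ]
            c = e.chi_square
            meta = (
                f"# section={e.section}\tchi2={c.statistic:.6f}\tdf={c.df}"
                f"\tp={c.p_asymptotic:.6f}"
            )
            blocks.append("\n".join([meta, header, *rows]))
        return {"report.tsv": "\n\n".join(blocks) + "\n"}
    raise ValueError(f"unknown format {fmt!r}; choose json, markdown or tsv")
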