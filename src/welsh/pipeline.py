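"""End-to-end validation analysis: QC -> scoring -> stratified statistics.

:func:`run_analysis` reproduces the report surfaces of a questionnaire
validation study from a list of participant records (real or synthetic):

* a by-sex cohort characteristics table (Welch t tests for continuous
  variables, chi-square tests for categorical ones);
* the per-education completion-error table with Wilson 95% CIs and an
  overall chi-square test of error count vs literacy;
* the two-round completion-flow counts;
* per-stratum (sex x education) Spearman correlations between WELSH score
  and maximal walking distance, with OLS calibration lines
  (``MWD = slope * score + intercept``), Benjamini-Hochberg adjusted;
* the pooled correlation and calibration line;
* Fisher r-to-z contrasts between the largest university stratum and its
  comparators, BH-adjusted as a separate family.

Score is always the predictor and MWD the response.  Strata below a
configurable minimum size are marked insufficient rather than estimated.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import stats
from .qc import (
    CompletionOutcome,
    ErrorRateRow,
    FlowCounts,
    Status,
    completion_flow_summary,
    error_rates_by_stratum,
    percent_half_up,
    round_half_up,
)
from .records import (
    COMORBIDITY_FIELDS,
    Education,
    ParticipantRecord,
    RejectedRow,
    Sex,
    read_records,
    write_records,
)
from .scoring import DEFAULT_TABLE, ScoreTable, welsh_score
from .stats import CorrelationResult, FitLine, ZComparison


@dataclass(frozen=True)
class AnalysisConfig:
    """Switches of the validation analysis."""

    min_stratum_n: int = 10
    #: keep participants who never self-completed (scored with help)
    include_unable: bool = True
    #: pooled/Welch choice for the by-sex t tests
    equal_var: bool = False
    #: also report Pearson correlations next to Spearman
    report_pearson: bool = True
    score_table: ScoreTable = DEFAULT_TABLE


@dataclass(frozen=True)
class ContinuousRow:
    variable: str
    mean_total: float
    sd_total: float
    mean_m: float
    sd_m: float
    mean_f: float
    sd_f: float
    p: float


@dataclass(frozen=True)
class CategoricalRow:
    variable: str
    k_total: int
    k_m: int
    k_f: int
    p: float


@dataclass(frozen=True)
class StratumResult:
    sex: Sex
    education: Education
    n: int
    mwd_mean: float
    mwd_sd: float
    score_mean: float
    score_sd: float
    corr: Optional[CorrelationResult]
    pearson_r: Optional[float]
    fit: Optional[FitLine]
    insufficient: bool = False


@dataclass(frozen=True)
class LabelledContrast:
    label: str
    comparison: ZComparison


@dataclass(frozen=True)
class ValidationReport:
    n_analyzed: int
    n_males: int
    n_females: int
    continuous: tuple[ContinuousRow, ...]
    categorical: tuple[CategoricalRow, ...]
    error_rows: tuple[ErrorRateRow, ...]
    error_chi2: Optional[tuple[float, int, float]]
    flow: Optional[FlowCounts]
    strata: tuple[StratumResult, ...]
    pooled: CorrelationResult
    pooled_pearson: Optional[float]
    pooled_fit: FitLine
    contrasts: tuple[LabelledContrast, ...]


def score_records(
    records: Sequence[ParticipantRecord], table: ScoreTable = DEFAULT_TABLE
) -> list[ParticipantRecord]:
    """Fill in missing scores from clean final responses."""
    out = []
    for rec in records:
        if rec.score is None and not rec.response.has_sentinel:
            from dataclasses import replace

            rec = replace(rec, score=welsh_score(rec.response, table).score)
        out.append(rec)
    return out


def _sex_split(records, attr):
    m = [getattr(r, attr) for r in records if r.sex is Sex.MALE]
    f = [getattr(r, attr) for r in records if r.sex is Sex.FEMALE]
    return np.asarray(m, dtype=float), np.asarray(f, dtype=float)


def run_analysis(
    records: Sequence[ParticipantRecord], config: AnalysisConfig = AnalysisConfig()
) -> ValidationReport:
    """Run the full stratified validation analysis on scored records."""
    records = score_records(records, config.score_table)
    analyzed = [
        r
        for r in records
        if r.score is not None
        and r.mwd is not None
        and (config.include_unable or r.outcome is None or r.outcome.status is not Status.UNABLE)
    ]
    if not analyzed:
        raise ValueError("no analyzable records (need score and walking distance)")

    n_m = sum(1 for r in analyzed if r.sex is Sex.MALE)
    n_f = len(analyzed) - n_m

    # --- by-sex characteristics table ---
    continuous = []
    for var, attr in (
        ("age_years", "age"),
        ("weight_kg", "weight_kg"),
        ("height_cm", "height_cm"),
        ("bmi", "bmi"),
        ("welsh_score", "score"),
        ("mwd_m", "mwd"),
    ):
        xm, xf = _sex_split(analyzed, attr)
        total = np.concatenate([xm, xf])
        if xm.size >= 2 and xf.size >= 2 and (np.var(xm) > 0 or np.var(xf) > 0):
            _, _, p = stats.two_sample_t(xm, xf, equal_var=config.equal_var)
        else:
            p = float("nan")
        continuous.append(
            ContinuousRow(
                var,
                float(total.mean()), float(total.std(ddof=1)),
                float(xm.mean()) if xm.size else float("nan"),
                float(xm.std(ddof=1)) if xm.size > 1 else float("nan"),
                float(xf.mean()) if xf.size else float("nan"),
                float(xf.std(ddof=1)) if xf.size > 1 else float("nan"),
                p,
            )
        )

    categorical = []
    flags = [("smoker", lambda r: r.smoker)] + [
        (name, (lambda r, _n=name: getattr(r, _n))) for name in COMORBIDITY_FIELDS
    ] + [
        (f"education_{lvl.value}", (lambda r, _l=lvl: r.education is _l))
        for lvl in Education
    ]
    for var, pred in flags:
        km = sum(1 for r in analyzed if r.sex is Sex.MALE and pred(r))
        kf = sum(1 for r in analyzed if r.sex is Sex.FEMALE and pred(r))
        table = [[km, n_m - km], [kf, n_f - kf]]
        try:
            _, _, p = stats.chi_square_independence(table)
        except stats.StatError:
            p = float("nan")
        categorical.append(CategoricalRow(var, km + kf, km, kf, p))

    # --- completion-error table and flow ---
    with_outcome = [r for r in records if r.outcome is not None]
    error_rows: tuple[ErrorRateRow, ...] = ()
    error_chi2 = None
    flow = None
    if with_outcome:
        groups = [
            (lvl.value, [r.outcome for r in with_outcome if r.education is lvl])
            for lvl in Education
        ]
        error_rows = tuple(error_rates_by_stratum(groups))
        table = [[row.k, row.n - row.k] for row in error_rows if row.n > 0]
        if len(table) >= 2:
            try:
                error_chi2 = stats.chi_square_independence(table)
            except stats.StatError:
                error_chi2 = None
        flow = completion_flow_summary([r.outcome for r in with_outcome])

    # --- stratified and pooled correlations ---
    strata_results: list[StratumResult] = []
    for sex in Sex:
        for lvl in Education:
            sub = [r for r in analyzed if r.sex is sex and r.education is lvl]
            if not sub:
                continue
            s = np.array([r.score for r in sub], dtype=float)
            d = np.array([r.mwd for r in sub], dtype=float)
            base = dict(
                sex=sex, education=lvl, n=len(sub),
                mwd_mean=float(d.mean()), mwd_sd=float(d.std(ddof=1)) if len(sub) > 1 else 0.0,
                score_mean=float(s.mean()), score_sd=float(s.std(ddof=1)) if len(sub) > 1 else 0.0,
            )
            if len(sub) < config.min_stratum_n or np.ptp(s) == 0 or np.ptp(d) == 0:
                strata_results.append(
                    StratumResult(**base, corr=None, pearson_r=None, fit=None, insufficient=True)
                )
                continue
            corr = stats.spearman_rho(s, d)
            pearson = float(np.corrcoef(s, d)[0, 1]) if config.report_pearson else None
            strata_results.append(
                StratumResult(**base, corr=corr, pearson_r=pearson, fit=stats.fit_line(s, d))
            )

    # BH family 1: the per-stratum correlation p values
    estimated = [i for i, sr in enumerate(strata_results) if sr.corr is not None]
    if estimated:
        adj = stats.bh_adjust([strata_results[i].corr.p_raw for i in estimated])
        from dataclasses import replace as _replace

        for i, q in zip(estimated, adj):
            sr = strata_results[i]
            strata_results[i] = _replace(sr, corr=sr.corr.with_adjusted(q))

    s_all = np.array([r.score for r in analyzed], dtype=float)
    d_all = np.array([r.mwd for r in analyzed], dtype=float)
    pooled = stats.spearman_rho(s_all, d_all)
    pooled_pearson = float(np.corrcoef(s_all, d_all)[0, 1]) if config.report_pearson else None
    pooled_fit = stats.fit_line(s_all, d_all)

    contrasts = _education_contrasts(strata_results)

    return ValidationReport(
        n_analyzed=len(analyzed),
        n_males=n_m,
        n_females=n_f,
        continuous=tuple(continuous),
        categorical=tuple(categorical),
        error_rows=error_rows,
        error_chi2=error_chi2,
        flow=flow,
        strata=tuple(strata_results),
        pooled=pooled,
        pooled_pearson=pooled_pearson,
        pooled_fit=pooled_fit,
        contrasts=contrasts,
    )


def _education_contrasts(strata: Sequence[StratumResult]) -> tuple[LabelledContrast, ...]:
    """Fisher-z contrasts anchored on the largest university stratum.

    The reference stratum is the university group with the larger n; it is
    compared against the opposite-sex university group and against the
    same-sex groups of the three lower education levels.  The four p values
    are BH-adjusted as one family.
    """
    by_key = {(sr.sex, sr.education): sr for sr in strata if sr.corr is not None}
    uni = [sr for sr in strata
           if sr.education is Education.UNIVERSITY and sr.corr is not None]
    if not uni:
        return ()
    ref = max(uni, key=lambda sr: sr.n)
    other_sex = Sex.FEMALE if ref.sex is Sex.MALE else Sex.MALE
    comparators = [(other_sex, Education.UNIVERSITY)] + [
        (ref.sex, lvl) for lvl in (Education.NONE, Education.PRIMARY, Education.SECONDARY)
    ]
    out: list[LabelledContrast] = []
    for key in comparators:
        if key not in by_key:
            continue
        comp = by_key[key]
        z = stats.fisher_z_compare(ref.corr.rho, ref.n, comp.corr.rho, comp.n)
        label = (f"{ref.education.value}/{ref.sex.value}"
                 f" vs {key[1].value}/{key[0].value}")
        out.append(LabelledContrast(label, z))
    if out:
        adj = stats.bh_adjust([lc.comparison.p for lc in out])
        out = [LabelledContrast(lc.label, lc.comparison.with_adjusted(q))
               for lc, q in zip(out, adj)]
    return tuple(out)


# ---------------------------------------------------------------------------
# rendering


def _enum_safe(obj):
    import enum

    if isinstance(obj, enum.Enum):
        return obj.value
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serializable: {obj!r}")


def report_to_dict(report: ValidationReport) -> dict:
    """Full-precision nested-dict form of the report (JSON-serializable)."""
    d = asdict(report)
    if report.flow is not None:
        d["flow"] = report.flow.as_dict()
    return json.loads(json.dumps(d, default=_enum_safe))


def _md_table(headers: list[str], rows: list[list]) -> str:
    out = ["| " + " | ".join(headers) + " |",
           "| " + " | ".join("---" for _ in headers) + " |"]
    for row in rows:
        out.append("| " + " | ".join(str(c) for c in row) + " |")
    return "\n".join(out)


def _fmt_p(p: Optional[float]) -> str:
    if p is None or np.isnan(p):
        return "-"
    return "<0.001" if p < 0.001 else f"{p:.3f}"


def render_report(report: ValidationReport, format: str = "json") -> str:
    """Render the report as full-precision JSON or display-rounded markdown.

    Markdown display rounding follows the study's reporting style:
    percentages to one decimal (half-up), correlations to three decimals,
    means as integers.
    """
    if format == "json":
        return json.dumps(report_to_dict(report), indent=2)
    if format != "markdown":
        raise ValueError(f"unknown format {format!r}")

    parts = [f"# Validation report (n = {report.n_analyzed})", ""]
    parts.append("## Cohort characteristics by sex")
    rows = [
        [c.variable, f"{c.mean_total:.1f} ± {c.sd_total:.1f}",
         f"{c.mean_m:.1f} ± {c.sd_m:.1f}", f"{c.mean_f:.1f} ± {c.sd_f:.1f}",
         _fmt_p(c.p)]
        for c in report.continuous
    ]
    parts.append(_md_table(
        ["variable", f"total (n={report.n_analyzed})",
         f"males (n={report.n_males})", f"females (n={report.n_females})", "p"], rows))
    rows = [[c.variable, c.k_total, c.k_m, c.k_f, _fmt_p(c.p)] for c in report.categorical]
    parts.append("")
    parts.append(_md_table(["variable", "total", "males", "females", "p"], rows))

    if report.error_rows:
        parts += ["", "## Completion errors by education level"]
        rows = []
        for r in report.error_rows:
            if r.n == 0:
                rows.append([r.stratum, 0, 0, "-", "-"])
            else:
                rows.append([
                    r.stratum, r.k, r.n, f"{percent_half_up(r.k, r.n)}%",
                    f"({round_half_up(100 * r.ci_low)}%, {round_half_up(100 * r.ci_high)}%)",
                ])
        parts.append(_md_table(["education", "errored", "n", "rate", "Wilson 95% CI"], rows))
        if report.error_chi2 is not None:
            c2, df, p = report.error_chi2
            parts.append(f"\nChi-square vs literacy: {c2:.1f} (df={df}), p {_fmt_p(p)}")

    if report.flow is not None:
        parts += ["", "## Completion flow", "```json",
                  json.dumps(report.flow.as_dict(), indent=2), "```"]

    parts += ["", "## Score-distance correlation by stratum"]
    rows = []
    for sr in report.strata:
        if sr.insufficient or sr.corr is None:
            rows.append([sr.sex.value, sr.education.value, sr.n, "-", "-", "-", "-", "-",
                         "insufficient"])
            continue
        rows.append([
            sr.sex.value, sr.education.value, sr.n,
            f"{round(sr.mwd_mean)} ± {round(sr.mwd_sd)}",
            f"{round(sr.score_mean)} ± {round(sr.score_sd)}",
            f"{sr.corr.rho:.3f}", f"{sr.fit.slope:.2f}", f"{sr.fit.intercept:.0f}",
            _fmt_p(sr.corr.p_adj),
        ])
    parts.append(_md_table(
        ["sex", "education", "n", "MWD (m)", "score", "r", "slope", "intercept", "adj p"], rows))
    parts.append(
        f"\nPooled: r = {report.pooled.rho:.3f} (p {_fmt_p(report.pooled.p_raw)}), "
        f"MWD = {report.pooled_fit.slope:.1f} x score + {report.pooled_fit.intercept:.0f}"
    )
    if report.pooled_pearson is not None:
        parts.append(f"Pooled Pearson r = {report.pooled_pearson:.3f}")

    if report.contrasts:
        parts += ["", "## Correlation contrasts (Fisher r-to-z)"]
        rows = [[lc.label, f"{lc.comparison.z_stat:.2f}", _fmt_p(lc.comparison.p),
                 _fmt_p(lc.comparison.p_adj)] for lc in report.contrasts]
        parts.append(_md_table(["contrast", "z", "p", "BH p"], rows))

    return "\n".join(parts) + "\n"


def load_s1_spreadsheet(path) -> "pd.DataFrame":  # pragma: no cover - optional
    """Optional loader for a deposited supplementary spreadsheet (XLS/XLSX).

    Returns the raw sheet as a DataFrame for the user to rename onto the
    :data:`welsh.records.COLUMNS` dictionary and feed through
    :func:`welsh.records.read_records`; the deposited file is not shipped
    with this package and its column names vary.  Requires ``openpyxl``
    (``pip install welsh[xls]``).
    """
    import pandas as pd

    return pd.read_excel(path)
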