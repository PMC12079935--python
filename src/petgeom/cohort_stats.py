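"""Cohort-level statistics: Spearman correlations, ROC with Youden cut-off,
logistic and Cox regressions, Kaplan-Meier curves with the log-rank test,
and table-shaped reports.

Conventions:

* AUC is pairwise concordance (ties count 1/2). Orientation is auto-chosen
  so the reported AUC is >= 0.5 and the chosen direction is recorded.
* AUC confidence intervals are stratified percentile bootstrap.
* Regression CIs and p-values are Wald; Cox ties are handled with the Efron
  correction.
* The Youden cut-off is the smallest empirical threshold maximizing
  sensitivity + specificity - 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidArgumentError, InvalidInputError

__all__ = [
    "ROCResult",
    "FitResult",
    "KMResult",
    "SpearmanResult",
    "spearman_matrix",
    "auc_concordance",
    "roc_youden",
    "logistic_fit",
    "cox_fit",
    "km_logrank",
    "dichotomize",
    "build_report",
    "Report",
    "ROC_REPORT_COLUMNS",
    "REGRESSION_REPORT_COLUMNS",
]

ROC_REPORT_COLUMNS = (
    "parameter",
    "auc",
    "ci_low",
    "ci_high",
    "sensitivity",
    "specificity",
    "cutoff",
)
REGRESSION_REPORT_COLUMNS = (
    "parameter",
    "uni_p_value",
    "uni_ratio",
    "uni_ci_low",
    "uni_ci_high",
    "multi_p_value",
    "multi_ratio",
    "multi_ci_low",
    "multi_ci_high",
)


# ---------------------------------------------------------------------------
# Spearman correlations
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SpearmanResult:
    r: pd.DataFrame
    p: pd.DataFrame
    warnings: tuple[str, ...] = ()


def spearman_matrix(table: pd.DataFrame, columns: Sequence[str]) -> SpearmanResult:
    """Pairwise Spearman rank correlations with t-approximation p-values.

    Ranks use midranks for ties. A constant column yields an undefined
    correlation, reported as NaN with a warning.
    """
    columns = list(columns)
    data = table[columns].dropna()
    if len(data) < 3:
        raise InvalidInputError("need at least 3 complete rows")
    k = len(columns)
    r = np.eye(k)
    p = np.zeros((k, k))
    notes: list[str] = []
    constant = {c for c in columns if data[c].nunique() <= 1}
    for note_col in sorted(constant):
        notes.append(f"column {note_col!r} is constant; correlations undefined")
    for a in range(k):
        for b in range(a + 1, k):
            if columns[a] in constant or columns[b] in constant:
                r[a, b] = r[b, a] = np.nan
                p[a, b] = p[b, a] = np.nan
                continue
            res = stats.spearmanr(data[columns[a]], data[columns[b]])
            r[a, b] = r[b, a] = res.statistic
            p[a, b] = p[b, a] = res.pvalue
    for a in range(k):
        if columns[a] in constant:
            r[a, a] = np.nan
            p[a, a] = np.nan
    return SpearmanResult(
        r=pd.DataFrame(r, index=columns, columns=columns),
        p=pd.DataFrame(p, index=columns, columns=columns),
        warnings=tuple(notes),
    )


# ---------------------------------------------------------------------------
# ROC / Youden
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ROCResult:
    auc: float
    ci_low: float
    ci_high: float
    cutoff: float
    sensitivity: float
    specificity: float
    orientation: str  # "higher_predicts_event" | "lower_predicts_event"
    n_boot: int = 0


def _check_labels(labels: np.ndarray) -> None:
    classes = np.unique(labels)
    if not np.isin(classes, (0, 1)).all():
        raise InvalidArgumentError("labels must be binary 0/1")
    if len(classes) < 2:
        raise InvalidInputError("both classes must be present")


def auc_concordance(scores: Sequence[float], labels: Sequence[int]) -> float:
    """AUC as normalized pairwise concordance, via midranks (ties count 1/2)."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    _check_labels(labels)
    ranks = stats.rankdata(scores)
    n1 = int((labels == 1).sum())
    n0 = len(labels) - n1
    return float((ranks[labels == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def _youden_cutoff(
    scores: np.ndarray, labels: np.ndarray, higher_predicts_event: bool
) -> tuple[float, float, float]:
    """Exhaustive search over empirical thresholds; smallest cutoff on ties."""
    best = (-np.inf, np.inf, 0.0, 0.0)
    pos = labels == 1
    n1 = pos.sum()
    n0 = len(labels) - n1
    for c in np.unique(scores):
        called = scores >= c if higher_predicts_event else scores <= c
        sens = (called & pos).sum() / n1
        spec = (~called & ~pos).sum() / n0
        j = sens + spec - 1.0
        if j > best[0] + 1e-15 or (abs(j - best[0]) <= 1e-15 and c < best[1]):
            best = (j, float(c), float(sens), float(spec))
    return best[1], best[2], best[3]


def roc_youden(
    scores: Sequence[float],
    labels: Sequence[int],
    n_boot: int = 2000,
    seed: int = 0,
) -> ROCResult:
    """ROC analysis: AUC, stratified-bootstrap 95% CI, Youden cut-off.

    Orientation is chosen so AUC >= 0.5 and recorded; the cut-off is on the
    original score scale, with events called on the event side of it
    (``score >= cutoff`` or ``score <= cutoff`` per orientation).
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise InvalidArgumentError("scores and labels must have the same length")
    _check_labels(labels)
    if n_boot < 1:
        raise InvalidArgumentError("n_boot must be >= 1")

    auc = auc_concordance(scores, labels)
    higher = auc >= 0.5
    if not higher:
        auc = 1.0 - auc
    orientation = "higher_predicts_event" if higher else "lower_predicts_event"

    cutoff, sens, spec = _youden_cutoff(scores, labels, higher)

    rng = np.random.default_rng(seed)
    idx1 = np.nonzero(labels == 1)[0]
    idx0 = np.nonzero(labels == 0)[0]
    boots = np.empty(n_boot)
    oriented = scores if higher else -scores
    for b in range(n_boot):
        take = np.concatenate(
            [rng.choice(idx1, size=len(idx1)), rng.choice(idx0, size=len(idx0))]
        )
        boots[b] = auc_concordance(oriented[take], labels[take])
    ci_low, ci_high = np.percentile(boots, [2.5, 97.5])
    # Percentile bounds can exclude the point estimate in tiny samples; the
    # reported interval is widened to bracket it.
    ci_low = min(float(ci_low), auc)
    ci_high = max(float(ci_high), auc)
    return ROCResult(
        auc=auc,
        ci_low=ci_low,
        ci_high=ci_high,
        cutoff=cutoff,
        sensitivity=sens,
        specificity=spec,
        orientation=orientation,
        n_boot=n_boot,
    )


# ---------------------------------------------------------------------------
# Regressions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FitResult:
    """Per-predictor estimates from a logistic or Cox model.

    ``table`` has one row per predictor with columns: parameter, estimate,
    ratio, ci_low, ci_high, p_value. In univariate mode each row comes from
    its own single-predictor model.
    """

    table: pd.DataFrame
    model_kind: str  # "logistic" | "cox"
    mode: str  # "univariate" | "multivariate"
    converged: bool
    warnings: tuple[str, ...] = ()

    def row(self, parameter: str) -> pd.Series:
        match = self.table[self.table["parameter"] == parameter]
        if match.empty:
            raise KeyError(parameter)
        return match.iloc[0]


_FIT_COLUMNS = ["parameter", "estimate", "ratio", "ci_low", "ci_high", "p_value"]


def _logistic_single(
    y: np.ndarray, X: pd.DataFrame
) -> tuple[pd.DataFrame, bool, list[str]]:
    import statsmodels.api as sm

    notes: list[str] = []
    design = sm.add_constant(X, has_constant="add")
    converged = True
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            fit = sm.GLM(y, design, family=sm.families.Binomial()).fit()
        except Exception as exc:  # noqa: BLE001 - separation raises internally
            raise InvalidInputError(f"logistic fit failed: {exc}") from exc
    for w in caught:
        notes.append(str(w.message))
    mu = np.asarray(fit.fittedvalues)
    if np.any(mu < 1e-10) or np.any(mu > 1 - 1e-10) or np.any(
        np.abs(fit.params.iloc[1:]) > 15
    ):
        converged = False
        notes.append("possible complete separation: estimates unreliable")
    ci = fit.conf_int()
    rows = []
    for name in X.columns:
        est = float(fit.params[name])
        rows.append(
            {
                "parameter": name,
                "estimate": est,
                "ratio": float(np.exp(est)),
                "ci_low": float(np.exp(ci.loc[name, 0])),
                "ci_high": float(np.exp(ci.loc[name, 1])),
                "p_value": float(fit.pvalues[name]),
            }
        )
    return pd.DataFrame(rows, columns=_FIT_COLUMNS), converged, notes


def logistic_fit(
    table: pd.DataFrame,
    outcome: str,
    predictors: Sequence[str],
    mode: str = "univariate",
) -> FitResult:
    """Logistic regression (IRLS maximum likelihood) with Wald 95% CIs.

    ``univariate`` fits each predictor in its own model; ``multivariate``
    fits all predictors jointly. Odds ratios are ``exp(coefficient)``.
    """
    if mode not in ("univariate", "multivariate"):
        raise InvalidArgumentError(f"unknown mode {mode!r}")
    predictors = list(predictors)
    if not predictors:
        raise InvalidArgumentError("at least one predictor required")
    y = np.asarray(table[outcome], dtype=float)
    _check_labels(y.astype(int))
    if len(table) <= 5 * len(predictors):
        raise InvalidInputError(
            f"need n > 5 x predictors ({len(table)} rows, {len(predictors)} predictors)"
        )
    for name in predictors:
        if table[name].nunique() <= 1:
            raise InvalidArgumentError(f"predictor {name!r} is constant")

    notes: list[str] = []
    converged = True
    if mode == "multivariate":
        frame, converged, notes = _logistic_single(y, table[predictors].astype(float))
    else:
        parts = []
        for name in predictors:
            part, ok, msgs = _logistic_single(y, table[[name]].astype(float))
            parts.append(part)
            converged = converged and ok
            notes.extend(msgs)
        frame = pd.concat(parts, ignore_index=True)
    return FitResult(
        table=frame,
        model_kind="logistic",
        mode=mode,
        converged=converged,
        warnings=tuple(notes),
    )


def _cox_single(
    data: pd.DataFrame, time: str, event: str, predictors: list[str]
) -> tuple[pd.DataFrame, bool, list[str]]:
    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceWarning

    notes: list[str] = []
    converged = True
    fitter = CoxPHFitter()
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        fitter.fit(
            data[[time, event, *predictors]],
            duration_col=time,
            event_col=event,
            show_progress=False,
            fit_options={"precision": 1e-9},  # default stops short of the MLE
        )
    for w in caught:
        if issubclass(w.category, ConvergenceWarning):
            converged = False
        notes.append(str(w.message))
    summary = fitter.summary
    rows = []
    for name in predictors:
        est = float(summary.loc[name, "coef"])
        rows.append(
            {
                "parameter": name,
                "estimate": est,
                "ratio": float(np.exp(est)),
                "ci_low": float(np.exp(summary.loc[name, "coef lower 95%"])),
                "ci_high": float(np.exp(summary.loc[name, "coef upper 95%"])),
                "p_value": float(summary.loc[name, "p"]),
            }
        )
    return pd.DataFrame(rows, columns=_FIT_COLUMNS), converged, notes


def cox_fit(
    table: pd.DataFrame,
    time: str,
    event: str,
    predictors: Sequence[str],
    mode: str = "univariate",
) -> FitResult:
    """Cox proportional hazards (Efron ties) with Wald 95% CIs."""
    if mode not in ("univariate", "multivariate"):
        raise InvalidArgumentError(f"unknown mode {mode!r}")
    predictors = list(predictors)
    if not predictors:
        raise InvalidArgumentError("at least one predictor required")
    times = np.asarray(table[time], dtype=float)
    events = np.asarray(table[event], dtype=float)
    if np.any(times <= 0):
        raise InvalidInputError("all survival times must be positive")
    if events.sum() < 1:
        raise InvalidInputError("at least one event is required")

    notes: list[str] = []
    converged = True
    if mode == "multivariate":
        frame, converged, notes = _cox_single(table, time, event, predictors)
    else:
        parts = []
        for name in predictors:
            part, ok, msgs = _cox_single(table, time, event, [name])
            parts.append(part)
            converged = converged and ok
            notes.extend(msgs)
        frame = pd.concat(parts, ignore_index=True)
    return FitResult(
        table=frame,
        model_kind="cox",
        mode=mode,
        converged=converged,
        warnings=tuple(notes),
    )


# ---------------------------------------------------------------------------
# Kaplan-Meier / log-rank
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class KMResult:
    """Per-group product-limit curves plus the log-rank test."""

    curves: Mapping[str, pd.DataFrame]  # columns: time, survival
    logrank_chi2: float
    logrank_p: float
    group_sizes: Mapping[str, int] = field(default_factory=dict)


def km_logrank(
    table: pd.DataFrame, time: str, event: str, group: str
) -> KMResult:
    """Kaplan-Meier estimates per group and the (groups-1)-df log-rank test."""
    from lifelines import KaplanMeierFitter
    from lifelines.statistics import multivariate_logrank_test

    groups = table[group]
    labels = [g for g in pd.unique(groups)]
    if len(labels) < 2:
        raise InvalidInputError("need at least two nonempty groups")

    curves: dict[str, pd.DataFrame] = {}
    sizes: dict[str, int] = {}
    for label in labels:
        sub = table[groups == label]
        fitter = KaplanMeierFitter()
        fitter.fit(sub[time], event_observed=sub[event])
        sf = fitter.survival_function_
        curves[str(label)] = pd.DataFrame(
            {"time": sf.index.to_numpy(dtype=float), "survival": sf.iloc[:, 0].to_numpy()}
        )
        sizes[str(label)] = len(sub)

    test = multivariate_logrank_test(table[time], groups, table[event])
    chi2 = float(test.test_statistic)
    p = float(stats.chi2.sf(chi2, df=len(labels) - 1))
    return KMResult(curves=curves, logrank_chi2=chi2, logrank_p=p, group_sizes=sizes)


def dichotomize(
    table: pd.DataFrame, column: str, cutoff: float, group_col: Optional[str] = None
) -> pd.DataFrame:
    """Add a binary group label: ``high`` if value > cutoff, else ``low``.

    Values equal to the cutoff go to the lower group.
    """
    if not np.isfinite(cutoff):
        raise InvalidArgumentError("cutoff must be finite")
    group_col = group_col or f"{column}_group"
    out = table.copy()
    out[group_col] = np.where(out[column] > cutoff, "high", "low")
    counts = out[group_col].value_counts()
    if len(counts) < 2:
        warnings.warn(
            f"cutoff {cutoff} puts all rows in one group ({counts.index[0]})",
            stacklevel=2,
        )
    return out


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Report:
    tables: Mapping[str, pd.DataFrame]

    def to_text(self) -> str:
        chunks = []
        for name, frame in self.tables.items():
            chunks.append(f"== {name} ==")
            chunks.append(frame.to_string(index=False, na_rep=""))
            chunks.append("")
        return "\n".join(chunks)

    def write(self, directory) -> list[str]:
        from pathlib import Path

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        written = []
        for name, frame in self.tables.items():
            path = directory / f"{name}.csv"
            frame.to_csv(path, index=False, na_rep="")
            written.append(str(path))
        (directory / "report.txt").write_text(self.to_text())
        written.append(str(directory / "report.txt"))
        return written


def _regression_table(
    uni: Optional[FitResult], multi: Optional[FitResult]
) -> pd.DataFrame:
    params: list[str] = []
    for res in (uni, multi):
        if res is not None:
            for p in res.table["parameter"]:
                if p not in params:
                    params.append(p)
    rows = []
    for p in params:
        row: dict[str, object] = {"parameter": p}
        for prefix, res in (("uni", uni), ("multi", multi)):
            if res is not None and (res.table["parameter"] == p).any():
                r = res.row(p)
                row[f"{prefix}_p_value"] = r["p_value"]
                row[f"{prefix}_ratio"] = r["ratio"]
                row[f"{prefix}_ci_low"] = r["ci_low"]
                row[f"{prefix}_ci_high"] = r["ci_high"]
            else:
                for suffix in ("p_value", "ratio", "ci_low", "ci_high"):
                    row[f"{prefix}_{suffix}"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows, columns=list(REGRESSION_REPORT_COLUMNS))


def build_report(
    roc: Optional[Mapping[str, ROCResult]] = None,
    logistic: Optional[tuple[Optional[FitResult], Optional[FitResult]]] = None,
    cox: Optional[tuple[Optional[FitResult], Optional[FitResult]]] = None,
    km: Optional[KMResult] = None,
) -> Report:
    """Assemble deterministic table-shaped reports from analysis results.

    ``logistic`` and ``cox`` are (univariate, multivariate) pairs; either
    element may be None. Missing values render blank, not zero.
    """
    tables: dict[str, pd.DataFrame] = {}
    if roc is not None:
        rows = [
            {
                "parameter": name,
                "auc": r.auc,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "sensitivity": r.sensitivity,
                "specificity": r.specificity,
                "cutoff": r.cutoff,
            }
            for name, r in roc.items()
        ]
        tables["roc"] = pd.DataFrame(rows, columns=list(ROC_REPORT_COLUMNS))
    if logistic is not None:
        tables["logistic"] = _regression_table(*logistic)
    if cox is not None:
        tables["cox"] = _regression_table(*cox)
    if km is not None:
        rows = []
        for label, curve in km.curves.items():
            for t, s in zip(curve["time"], curve["survival"]):
                rows.append({"group": label, "time": t, "survival": s})
        tables["km_curves"] = pd.DataFrame(rows, columns=["group", "time", "survival"])
        tables["km_test"] = pd.DataFrame(
            [{"logrank_chi2": km.logrank_chi2, "logrank_p": km.logrank_p}]
        )
    if not tables:
        raise InvalidArgumentError("at least one result object is required")
    return Report(tables=tables)
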