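"""Survival layer: Cox regression, PH diagnostics, Kaplan-Meier, log-rank,
fixed-horizon ROC and Mann-Whitney comparisons.

Overall survival is measured in months from the baseline PET/CT to death
from any cause; censored follow-up is handled throughout.  Cox models use
Efron tie handling and Wald confidence intervals.  The proportional-
hazards assumption is checked with a score test on scaled Schoenfeld
residuals against time (identity transform).  The fixed-horizon ROC
dichotomizes the outcome at a horizon (default 60 months = 5-year OS):
death at or before the horizon is a case, survival beyond it a control,
and patients censored before the horizon are excluded; the operating
cutoff maximizes Youden's J.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats

__all__ = [
    "PatientRecord",
    "CoxFit",
    "KMCurve",
    "RocResult",
    "records_to_frame",
    "fit_cox",
    "schoenfeld_ph_test",
    "km_estimate",
    "survival_at",
    "logrank",
    "roc_fixed_horizon",
    "mannwhitney",
]

ALPHA = 0.05  # two-sided, used for every CI and test in this module


@dataclass(frozen=True)
class PatientRecord:
    """One cohort row: clinical covariates, tumor-burden markers, outcome."""

    id: str
    age: float  # years
    gender: Literal["male", "female"]
    grading: Literal["G1", "G2", "G3"]
    primary_site: Literal["GEP", "bronchopulmonary", "CUP"]
    cga: float  # chromogranin A, ug/l
    ldh: float  # U/l
    ggt: float  # gamma-GT, U/l
    mtv_ml: float
    os_months: float
    event: bool  # True = death observed, False = censored

    def __post_init__(self) -> None:
        if self.os_months <= 0:
            raise ValueError(f"os_months must be > 0 (patient {self.id})")
        for name in ("cga", "ldh", "ggt", "mtv_ml"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0 (patient {self.id})")


_GRADE_CODE = {"G1": 1, "G2": 2, "G3": 3}


def records_to_frame(records: Sequence[PatientRecord]) -> pd.DataFrame:
    """Cohort table with numeric covariate encodings.

    gender: male=1, female=0; grading: ordinal 1/2/3; primary site kept
    as a categorical string column; ``ggt_log`` = ln(gamma-GT) added
    since gamma-GT enters the models on the log scale.
    """
    rows = [
        {
            "id": r.id,
            "age": r.age,
            "gender": 1 if r.gender == "male" else 0,
            "grading": _GRADE_CODE[r.grading],
            "primary_site": r.primary_site,
            "cga": r.cga,
            "ldh": r.ldh,
            "ggt": r.ggt,
            "ggt_log": float(np.log(r.ggt)),
            "mtv_ml": r.mtv_ml,
            "os_months": r.os_months,
            "event": int(r.event),
        }
        for r in records
    ]
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class CoxFit:
    """Cox proportional-hazards fit summary.

    ``summary`` is indexed by covariate with columns ``coef``,
    ``hazard_ratio``, ``ci95_low``, ``ci95_high``, ``p_value``.
    """

    summary: pd.DataFrame
    covariates: tuple[str, ...]
    n: int
    n_events: int
    variance_matrix: np.ndarray = field(repr=False)
    log_likelihood: float = float("nan")
    _data: pd.DataFrame = field(default=None, repr=False, compare=False)  # type: ignore[assignment]

    def coef(self, covariate: str) -> float:
        return float(self.summary.loc[covariate, "coef"])

    def hazard_ratio(self, covariate: str) -> float:
        return float(self.summary.loc[covariate, "hazard_ratio"])


class DegenerateModelError(ValueError):
    """Cox model cannot be fit (no events, constant covariate...)."""


def fit_cox(
    records: Sequence[PatientRecord] | pd.DataFrame,
    covariates: Sequence[str],
    duration_col: str = "os_months",
    event_col: str = "event",
) -> CoxFit:
    """Cox partial-likelihood fit (Efron ties, Wald CIs).

    ``records`` may be a list of :class:`PatientRecord` or a prepared
    DataFrame containing ``duration_col``, ``event_col`` and the
    requested covariate columns.
    """
    df = records_to_frame(records) if not isinstance(records, pd.DataFrame) else records
    missing = [c for c in covariates if c not in df.columns]
    if missing:
        raise KeyError(f"covariates not in cohort table: {missing}")
    sub = df[list(covariates) + [duration_col, event_col]].astype(float)
    if not np.all(np.isfinite(sub.to_numpy())):
        raise ValueError("non-finite values in model columns")
    n_events = int(sub[event_col].sum())
    if n_events < 2:
        raise DegenerateModelError(f"need >= 2 events, got {n_events}")
    for c in covariates:
        if sub[c].nunique() < 2:
            raise DegenerateModelError(f"covariate {c!r} is constant")

    cph = CoxPHFitter()
    try:
        cph.fit(sub, duration_col=duration_col, event_col=event_col)
    except Exception as exc:  # lifelines ConvergenceError and friends
        raise DegenerateModelError(f"Cox fit failed: {exc}") from exc

    s = cph.summary
    summary = pd.DataFrame(
        {
            "coef": s["coef"],
            "hazard_ratio": s["exp(coef)"],
            "ci95_low": np.exp(s["coef lower 95%"]),
            "ci95_high": np.exp(s["coef upper 95%"]),
            "p_value": s["p"],
        }
    )
    summary.index.name = "covariate"
    return CoxFit(
        summary=summary,
        covariates=tuple(covariates),
        n=len(sub),
        n_events=n_events,
        variance_matrix=np.asarray(cph.variance_matrix_),
        log_likelihood=float(cph.log_likelihood_),
        _data=sub.rename(columns={duration_col: "_T", event_col: "_E"}),
    )


# ---------------------------------------------------------------------------
# Schoenfeld proportional-hazards diagnostics


def _schoenfeld_residuals(
    times: np.ndarray, events: np.ndarray, X: np.ndarray, beta: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Unscaled Schoenfeld residuals at each event time (Breslow risk sets).

    For event i, residual = x_i - xbar(t_i), where xbar is the
    risk-weighted covariate mean over the risk set at t_i with weights
    exp(x beta).  Returns (event_times_sorted, residuals (d, p)).
    """
    order = np.argsort(times, kind="stable")
    t, e, x = times[order], events[order], X[order]
    risk = np.exp(x @ beta)
    ev_idx = np.flatnonzero(e.astype(bool))
    resid = np.empty((ev_idx.size, x.shape[1]))
    for k, i in enumerate(ev_idx):
        at_risk = t >= t[i]
        w = risk[at_risk]
        xbar = (w[:, None] * x[at_risk]).sum(0) / w.sum()
        resid[k] = x[i] - xbar
    return t[ev_idx], resid


def schoenfeld_ph_test(fit: CoxFit, records: Sequence[PatientRecord] | pd.DataFrame | None = None) -> pd.Series:
    """Per-covariate p-values for the proportional-hazards assumption.

    Score test of a linear time trend in the scaled Schoenfeld
    residuals (identity time transform): with d events, residual matrix
    S (d x p), scaled residuals S* = d * S V (V the coefficient
    covariance), and centered event times g, the statistic for
    covariate j is

        T_j = (sum_k g_k S*_kj)^2 / (d * V_jj * sum_k g_k^2)

    which is chi-squared with 1 df under proportional hazards.
    """
    if records is None:
        df = fit._data
        if df is None:
            raise ValueError("fit carries no data; pass records explicitly")
    else:
        df = records_to_frame(records) if not isinstance(records, pd.DataFrame) else records
        df = df[list(fit.covariates) + ["os_months", "event"]].rename(
            columns={"os_months": "_T", "event": "_E"}
        )
    if fit.n_events < 2:
        raise DegenerateModelError("too few events for a PH test")

    X = df[list(fit.covariates)].to_numpy(dtype=float)
    times = df["_T"].to_numpy(dtype=float)
    events = df["_E"].to_numpy(dtype=float)
    beta = fit.summary["coef"].to_numpy()

    ev_times, resid = _schoenfeld_residuals(times, events, X, beta)
    d = ev_times.size
    scaled = d * resid @ fit.variance_matrix  # + beta, dropped: g is centered
    g = ev_times - ev_times.mean()
    num = (g[:, None] * scaled).sum(0) ** 2
    den = d * np.diag(fit.variance_matrix) * (g**2).sum()
    stat = num / den
    p = stats.chi2.sf(stat, df=1)
    return pd.Series(p, index=list(fit.covariates), name="p_ph")


# ---------------------------------------------------------------------------
# Kaplan-Meier and log-rank


@dataclass(frozen=True)
class KMCurve:
    """Product-limit survival curve (right-continuous step function)."""

    event_times: np.ndarray  # distinct observed times (months), sorted
    survival_prob: np.ndarray
    n_at_risk: np.ndarray


def km_estimate(times: Sequence[float], events: Sequence[bool]) -> KMCurve:
    """Kaplan-Meier product-limit estimator."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if t.size == 0:
        raise ValueError("empty input")
    if np.any(t <= 0):
        raise ValueError("times must be > 0")
    kmf = KaplanMeierFitter()
    kmf.fit(t, e)
    tbl = kmf.event_table.iloc[1:] if kmf.event_table.index[0] == 0 else kmf.event_table
    grid = tbl.index.to_numpy(dtype=float)
    surv = kmf.survival_function_at_times(grid).to_numpy()
    return KMCurve(
        event_times=grid,
        survival_prob=surv,
        n_at_risk=tbl["at_risk"].to_numpy(dtype=int),
    )


def survival_at(curve: KMCurve, t_months: float) -> float:
    """S(t) with the right-continuous step convention; S = 1 before the first time."""
    idx = np.searchsorted(curve.event_times, t_months, side="right") - 1
    return 1.0 if idx < 0 else float(curve.survival_prob[idx])


def logrank(
    times_a: Sequence[float],
    events_a: Sequence[bool],
    times_b: Sequence[float],
    events_b: Sequence[bool],
) -> tuple[float, float]:
    """Two-sample log-rank test; returns (chi2 statistic, p-value)."""
    ta, tb = np.asarray(times_a, float), np.asarray(times_b, float)
    if ta.size == 0 or tb.size == 0:
        raise ValueError("both groups must be non-empty")
    ea, eb = np.asarray(events_a, int), np.asarray(events_b, int)
    if ea.sum() + eb.sum() == 0:
        raise ValueError("need at least one event overall")
    res = _ll_logrank(ta, tb, ea, eb)
    return float(res.test_statistic), float(res.p_value)


# ---------------------------------------------------------------------------
# Fixed-horizon ROC


@dataclass(frozen=True)
class RocResult:
    auc: float
    auc_ci95: tuple[float, float]
    cutoff: float
    sensitivity: float
    specificity: float
    n_cases: int
    n_controls: int
    ci_method: str = "delong"


class DegenerateOutcomeError(ValueError):
    """No cases or no controls after fixed-horizon dichotomization."""


def _delong_auc_variance(cases: np.ndarray, controls: np.ndarray) -> tuple[float, float]:
    """Empirical AUC and its DeLong variance (placement-value form)."""
    m, n = cases.size, controls.size
    # placement of each case among controls and vice versa (ties count 1/2)
    v10 = np.empty(m)
    for i, c in enumerate(cases):
        v10[i] = (np.count_nonzero(controls < c) + 0.5 * np.count_nonzero(controls == c)) / n
    v01 = np.empty(n)
    for j, c in enumerate(controls):
        v01[j] = (np.count_nonzero(cases > c) + 0.5 * np.count_nonzero(cases == c)) / m
    auc = v10.mean()
    var = (np.var(v10, ddof=1) / m if m > 1 else 0.0) + (np.var(v01, ddof=1) / n if n > 1 else 0.0)
    return float(auc), float(var)


def roc_fixed_horizon(
    marker: Sequence[float],
    times: Sequence[float],
    events: Sequence[bool],
    horizon_months: float = 60.0,
    *,
    bootstrap_threshold: int = 10,
    n_bootstrap: int = 2000,
    seed: int = 0,
) -> RocResult:
    """ROC analysis of a risk marker against survival status at a horizon.

    Cases: death at or before the horizon.  Controls: follow-up beyond
    the horizon (with or without later event).  Censored before the
    horizon without an event: excluded.  Higher marker = higher risk.
    The reported cutoff maximizes Youden's J for the rule
    ``marker > cutoff`` -> predicted case; J-ties break toward the
    higher cutoff, i.e. toward higher specificity.  The AUC CI is
    DeLong unless either arm is smaller than ``bootstrap_threshold``,
    in which case a seeded percentile bootstrap is used.
    """
    x = np.asarray(marker, dtype=float)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if horizon_months <= 0:
        raise ValueError("horizon must be > 0")
    case = (t <= horizon_months) & (e == 1)
    control = t > horizon_months
    keep = case | control
    cases, controls = x[case], x[control]
    if cases.size == 0 or controls.size == 0:
        raise DegenerateOutcomeError(
            f"dichotomization at {horizon_months} months left "
            f"{cases.size} cases / {controls.size} controls"
        )

    auc, var = _delong_auc_variance(cases, controls)

    if min(cases.size, controls.size) < bootstrap_threshold:
        rng = np.random.default_rng(seed)
        boots = np.empty(n_bootstrap)
        for b in range(n_bootstrap):
            bc = rng.choice(cases, cases.size, replace=True)
            bn = rng.choice(controls, controls.size, replace=True)
            boots[b], _ = _delong_auc_variance(bc, bn)
        lo, hi = np.quantile(boots, [ALPHA / 2, 1 - ALPHA / 2])
        ci, method = (float(lo), float(hi)), "bootstrap"
    else:
        z = stats.norm.ppf(1 - ALPHA / 2)
        se = np.sqrt(var)
        ci, method = (max(0.0, auc - z * se), min(1.0, auc + z * se)), "delong"

    # Youden scan over candidate cutoffs (each observed marker value);
    # rule: predicted case iff marker > cutoff.
    cand = np.unique(x[keep])
    best = None
    for c in cand:
        sens = np.count_nonzero(cases > c) / cases.size
        spec = np.count_nonzero(controls <= c) / controls.size
        j = sens + spec - 1.0
        # strict > on J keeps the first (lowest) cutoff; prefer ties at
        # higher cutoff = higher specificity, hence >=
        if best is None or j >= best[0] - 1e-12:
            if best is None or j > best[0] + 1e-12 or spec >= best[3]:
                best = (j, c, sens, spec)
    assert best is not None
    _, cutoff, sens, spec = best
    return RocResult(
        auc=auc,
        auc_ci95=ci,
        cutoff=float(cutoff),
        sensitivity=float(sens),
        specificity=float(spec),
        n_cases=int(cases.size),
        n_controls=int(controls.size),
        ci_method=method,
    )


def mannwhitney(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns (U statistic, p-value)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)
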