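"""Censored survival analysis: Kaplan-Meier, log-rank, Cox proportional hazards.

The Cox fitter maximizes the partial likelihood by damped Newton iterations
with the Efron tie correction by default (months-resolution follow-up ties
heavily); Breslow is available behind a flag. Convergence is declared when
the score vector's max-norm drops below 1e-8; monotone likelihoods (complete
separation) surface as ``converged=False``, never silently.

The covariate-selection helper mirrors a common clinical workflow: every
candidate is fit alone against the endpoint, any candidate with at least one
level reaching Wald p < alpha enters the joint model (a multi-level factor is
kept whole even when some levels miss the cut), and the selected set is
refit together.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .datatypes import CohortTable, ScoreFrame
from .errors import DegenerateInputError, SingularityError
from .stats import TestResult

log = logging.getLogger(__name__)

NOT_REACHED = "NR"  # sentinel for medians/CI bounds the curve never crosses

Z95 = 1.959963984540054


# ---------------------------------------------------------------------------
# Kaplan-Meier


@dataclass(frozen=True)
class SurvivalFit:
    """Product-limit estimate over the distinct event times of one group."""

    event_times: np.ndarray        # distinct times with >= 1 event, ascending
    survival: np.ndarray           # S(t) just after each event time
    greenwood_se: np.ndarray
    n_at_risk: np.ndarray          # subjects at risk just before each event time
    n_events: np.ndarray           # deaths at each event time
    n: int
    median_survival: float | str   # months, or NOT_REACHED
    median_ci95: tuple[float | str, float | str]

    def survival_at(self, t: float) -> float:
        """Step-function value of S at time t (1 before the first event)."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def restricted_mean(self, tau: float) -> float:
        """Area under S(t) from 0 to tau (restricted mean survival time)."""
        knots = np.concatenate([[0.0], self.event_times, [np.inf]])
        values = np.concatenate([[1.0], self.survival])
        area = 0.0
        for i in range(len(values)):
            left = min(knots[i], tau)
            right = min(knots[i + 1], tau)
            if right > left:
                area += values[i] * (right - left)
        return area


def km_fit(times, events) -> SurvivalFit:
    """Kaplan-Meier product-limit estimator with Greenwood standard errors.

    Median survival is the first event time where S drops to 0.5 or below;
    its 95% CI comes from the log(-log S) transformed confidence band. Bounds
    the curve never crosses are reported as the NOT_REACHED sentinel.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise DegenerateInputError("Kaplan-Meier needs at least one subject")
    if (times < 0).any():
        raise DegenerateInputError("negative survival time")
    order = np.argsort(times, kind="stable")
    times, events = times[order], events[order]
    n = len(times)

    uniq = np.unique(times[events == 1])
    survival, se, at_risk, deaths = [], [], [], []
    s = 1.0
    gw_sum = 0.0  # running sum of d / (n_i (n_i - d_i))
    for t in uniq:
        n_i = int((times >= t).sum())
        d_i = int(((times == t) & (events == 1)).sum())
        s *= 1.0 - d_i / n_i
        if n_i > d_i:
            gw_sum += d_i / (n_i * (n_i - d_i))
            se_i = s * np.sqrt(gw_sum)
        else:
            se_i = 0.0  # S hit zero; Greenwood variance degenerates
        survival.append(s)
        se.append(se_i)
        at_risk.append(n_i)
        deaths.append(d_i)

    survival = np.array(survival)
    se = np.array(se)

    # log-log transformed 95% band, used for the median CI
    lo = np.zeros_like(survival)
    hi = np.ones_like(survival)
    gw = np.where(survival > 0, se / np.maximum(survival, 1e-300), 0.0)
    for i, s_i in enumerate(survival):
        if s_i <= 0.0:
            lo[i] = hi[i] = 0.0
        elif s_i >= 1.0:
            lo[i] = hi[i] = 1.0
        else:
            v = gw[i] / abs(np.log(s_i))
            lo[i] = s_i ** np.exp(Z95 * v)
            hi[i] = s_i ** np.exp(-Z95 * v)

    def _first_crossing(curve: np.ndarray) -> float | str:
        below = np.flatnonzero(curve <= 0.5)
        return float(uniq[below[0]]) if below.size else NOT_REACHED

    median = _first_crossing(survival)
    median_ci = (_first_crossing(lo), _first_crossing(hi))

    return SurvivalFit(
        event_times=uniq,
        survival=survival,
        greenwood_se=se,
        n_at_risk=np.array(at_risk),
        n_events=np.array(deaths),
        n=n,
        median_survival=median,
        median_ci95=median_ci,
    )


def km_table(fit: SurvivalFit) -> pd.DataFrame:
    """TSV-ready export of a Kaplan-Meier fit."""
    return pd.DataFrame(
        {
            "time": fit.event_times,
            "survival": fit.survival,
            "se": fit.greenwood_se,
            "n_at_risk": fit.n_at_risk,
            "n_events": fit.n_events,
        }
    )


# ---------------------------------------------------------------------------
# Log-rank


def log_rank(times, events, group) -> TestResult:
    """k-group log-rank test (hypergeometric variance, chi-square df = k-1)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    group = np.asarray(group)
    levels = [g for g in pd.unique(group) if (group == g).any()]
    k = len(levels)
    if k < 2:
        raise DegenerateInputError("log-rank needs at least two non-empty groups")
    membership = np.stack([(group == g).astype(float) for g in levels], axis=1)

    observed = np.zeros(k)
    expected = np.zeros(k)
    var = np.zeros((k, k))
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        n = at_risk.sum()
        n_j = membership[at_risk].sum(axis=0)
        dead = at_risk & (times == t) & (events == 1)
        d = dead.sum()
        d_j = membership[dead].sum(axis=0)
        observed += d_j
        expected += d * n_j / n
        if n > 1:
            frac = n_j / n
            v = d * (n - d) / (n - 1) * (np.diag(frac) - np.outer(frac, frac))
            var += v

    diff = (observed - expected)[: k - 1]
    vsub = var[: k - 1, : k - 1]
    try:
        stat = float(diff @ np.linalg.solve(vsub, diff))
    except np.linalg.LinAlgError:
        stat = float(diff @ np.linalg.pinv(vsub) @ diff)
    df = k - 1
    p = float(sps.chi2.sf(stat, df))
    return TestResult(
        statistic=stat,
        p_value=p,
        method="log_rank",
        n_per_group=tuple(int(membership[:, j].sum()) for j in range(k)),
        extras={"df": df, "groups": [str(g) for g in levels]},
    )


# ---------------------------------------------------------------------------
# Cox proportional hazards


@dataclass(frozen=True)
class CoxResult:
    summary: pd.DataFrame          # coef, hr, se, ci_low, ci_high, p per covariate
    log_likelihood: float
    n: int
    n_events: int
    converged: bool
    iterations: int
    ties: str
    score_norm: float = field(default=np.nan)

    def hazard_ratio(self, covariate: str) -> float:
        return float(self.summary.at[covariate, "hr"])


def _cox_derivatives(beta, times, events, X, ties):
    """Partial log-likelihood, score and information at beta.

    Risk-set aggregates come from reverse cumulative sums over time-sorted
    samples; death-set aggregates per tie group come from ``reduceat``. The
    Efron correction subtracts the within-tie death mass in d equal
    fractions; Breslow keeps the full risk set for every tied death. The
    per-death contributions are flattened into one vectorized pass.
    """
    n, p = X.shape
    eta = np.clip(X @ beta, -500, 500)
    w = np.exp(eta)
    wx = w[:, None] * X
    wxx = wx[:, :, None] * X[:, None, :]

    # reverse cumulative sums: index i holds the sum over {j : time_j >= time_i}
    rc_w = np.cumsum(w[::-1])[::-1]
    rc_wx = np.cumsum(wx[::-1], axis=0)[::-1]
    rc_wxx = np.cumsum(wxx[::-1], axis=0)[::-1]

    _, first = np.unique(times, return_index=True)
    is_event = events == 1
    we = w * is_event
    d_k = np.add.reduceat(is_event.astype(np.int64), first)
    s_d = np.add.reduceat(we, first)
    u_d = np.add.reduceat(we[:, None] * X, first, axis=0)
    m_d = np.add.reduceat(we[:, None, None] * X[:, :, None] * X[:, None, :], first, axis=0)

    keep = d_k > 0
    d_keep = d_k[keep]
    rep = np.repeat(np.flatnonzero(keep), d_keep)
    offsets = np.concatenate([[0], np.cumsum(d_keep)[:-1]])
    l = np.arange(len(rep)) - np.repeat(offsets, d_keep)
    frac = l / d_k[rep] if ties == "efron" else np.zeros(len(rep))

    phi = rc_w[first][rep] - frac * s_d[rep]
    z = rc_wx[first][rep] - frac[:, None] * u_d[rep]
    m = rc_wxx[first][rep] - frac[:, None, None] * m_d[rep]

    loglik = float((eta * is_event).sum() - np.log(phi).sum())
    score = (X * is_event[:, None]).sum(axis=0) - (z / phi[:, None]).sum(axis=0)
    info = (m / phi[:, None, None]).sum(axis=0) - np.einsum(
        "li,lj,l->ij", z, z, 1.0 / phi**2
    )
    return loglik, score, info


def cox_fit(times, events, covariates: pd.DataFrame, ties: str = "efron") -> CoxResult:
    """Fit a Cox proportional-hazards model by damped Newton iterations.

    ``covariates`` is a named design matrix (one column per covariate or
    factor-level indicator). Raises SingularityError for constant or linearly
    dependent columns; flags (not hides) non-convergence, which is the
    signature of a monotone partial likelihood under complete separation.
    """
    if ties not in ("efron", "breslow"):
        raise ValueError(f"unknown tie method {ties!r}")
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    X = covariates.to_numpy(dtype=float)
    names = list(covariates.columns)
    n, p = X.shape
    if events.sum() < 1:
        raise DegenerateInputError("Cox model needs at least one event")
    stds = X.std(axis=0)
    if (stds == 0).any():
        bad = names[int(np.flatnonzero(stds == 0)[0])]
        raise SingularityError(f"covariate {bad!r} is constant across subjects")
    centered = X - X.mean(axis=0)
    if np.linalg.matrix_rank(centered) < p:
        raise SingularityError("design matrix is rank-deficient (collinear covariates)")

    order = np.argsort(times, kind="stable")
    times_s, events_s, X_s = times[order], events[order], centered[order]

    beta = np.zeros(p)
    loglik, score, info = _cox_derivatives(beta, times_s, events_s, X_s, ties)
    converged = False
    iterations = 0
    max_iter = 100
    for iterations in range(1, max_iter + 1):
        if np.max(np.abs(score)) < 1e-8:
            converged = True
            break
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            log.warning("Cox information matrix singular at iteration %d", iterations)
            break
        # damped update: halve the step until the likelihood does not decrease
        # (tolerance scaled to |loglik| so float noise near the optimum never
        # rejects the full quadratic-regime Newton step)
        tol = 1e-10 * (1.0 + abs(loglik))
        improved = False
        for _ in range(30):
            cand = beta + step
            ll_new, sc_new, info_new = _cox_derivatives(cand, times_s, events_s, X_s, ties)
            if ll_new >= loglik - tol:
                beta, loglik, score, info = cand, ll_new, sc_new, info_new
                improved = True
                break
            step /= 2.0
        if not improved:
            break
    else:
        iterations = max_iter
    if not converged and np.max(np.abs(score)) < 1e-8:
        converged = True
    if not converged:
        log.warning(
            "Cox fit did not converge (max|score| = %.3g after %d iterations); "
            "possible monotone likelihood / complete separation",
            float(np.max(np.abs(score))), iterations,
        )

    try:
        cov = np.linalg.inv(info)
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        z = beta / se
        pvals = 2.0 * sps.norm.sf(np.abs(z))
        summary = pd.DataFrame(
            {
                "coef": beta,
                "hr": np.exp(beta),
                "se": se,
                "ci_low": np.exp(beta - Z95 * se),
                "ci_high": np.exp(beta + Z95 * se),
                "p": pvals,
            },
            index=pd.Index(names, name="covariate"),
        )
    return CoxResult(
        summary=summary,
        log_likelihood=float(loglik),
        n=n,
        n_events=int(events.sum()),
        converged=converged,
        iterations=iterations,
        ties=ties,
        score_norm=float(np.max(np.abs(score))),
    )


# ---------------------------------------------------------------------------
# Covariate encoding and univariate -> multivariate selection

#: factor encodings: candidate -> list of (column name, level); reference first
FACTOR_ENCODINGS = {
    "sex": [("sex_male", "male")],
    "stage": [("stage_II", "II"), ("stage_III", "III"), ("stage_IV", "IV")],
    "etiology": [
        ("etiology_alcohol", "alcohol"),
        ("etiology_hepB", "hepB"),
        ("etiology_hepC", "hepC"),
        ("etiology_other", "other"),
    ],
    "inflammation": [("inflammation_mild", "mild"), ("inflammation_severe", "severe")],
    "til_status": [("til_positive", "positive")],
    "cyt_group": [("cyt_high", "high")],
}

DEFAULT_CANDIDATES = ("age", "sex", "stage", "etiology", "inflammation", "til_status", "cyt_group")


def _candidate_design(merged: pd.DataFrame, candidate: str) -> pd.DataFrame | None:
    """Indicator columns for one candidate; None when no usable variation."""
    if candidate == "age":
        if "age" not in merged.columns:
            return None
        return merged[["age"]].astype(float)
    if candidate not in FACTOR_ENCODINGS or candidate not in merged.columns:
        return None
    cols = {}
    raw = merged[candidate]
    for col, level in FACTOR_ENCODINGS[candidate]:
        indicator = (raw == level).astype(float)
        indicator[raw.isna()] = np.nan
        cols[col] = indicator
    design = pd.DataFrame(cols, index=merged.index)
    # levels absent from the analysis subset would be constant-zero columns
    keep = [c for c in design.columns if design[c].dropna().nunique() > 1]
    dropped = set(design.columns) - set(keep)
    if dropped:
        log.warning("candidate %s: dropping empty level column(s) %s", candidate, sorted(dropped))
    return design[keep] if keep else None


def _merged_cohort(cohort: CohortTable, frame: ScoreFrame) -> pd.DataFrame:
    merged = cohort.data.merge(
        frame.data.reset_index(), on="sample_id", how="inner", validate="one_to_one"
    )
    if merged.empty:
        raise DegenerateInputError("cohort and score frame share no samples")
    return merged


def univariate_screen_then_multivariate(
    cohort: CohortTable,
    frame: ScoreFrame,
    endpoint: str = "OS",
    candidates: tuple[str, ...] = DEFAULT_CANDIDATES,
    alpha: float = 0.05,
    ties: str = "efron",
) -> tuple[pd.DataFrame, CoxResult | None]:
    """Screen candidates one at a time, then jointly refit the significant set.

    A multi-level factor enters the joint model when ANY of its level
    indicators reaches Wald p < alpha in its univariate fit. Rows are dropped
    per-analysis: each univariate fit uses every sample with the endpoint and
    that candidate observed. Returns the univariate table and the joint fit
    (None, with a warning, when nothing is selected).
    """
    merged = _merged_cohort(cohort, frame)
    ep = merged[[f"{endpoint}_time", f"{endpoint}_event"]].rename(
        columns={f"{endpoint}_time": "time", f"{endpoint}_event": "event"}
    )
    rows = []
    selected: list[str] = []
    for cand in candidates:
        design = _candidate_design(merged, cand)
        if design is None:
            log.warning("candidate %s unavailable; skipped", cand)
            continue
        keep = ep["time"].notna() & ep["event"].notna() & design.notna().all(axis=1)
        if keep.sum() < 2 or ep.loc[keep, "event"].sum() < 1:
            log.warning("candidate %s: too few usable rows; skipped", cand)
            continue
        fit = cox_fit(ep.loc[keep, "time"], ep.loc[keep, "event"], design[keep], ties=ties)
        any_sig = False
        for cov, r in fit.summary.iterrows():
            rows.append(
                {
                    "candidate": cand,
                    "covariate": cov,
                    "n": fit.n,
                    "n_events": fit.n_events,
                    "hr": r["hr"],
                    "ci_low": r["ci_low"],
                    "ci_high": r["ci_high"],
                    "p": r["p"],
                    "selected": False,
                }
            )
            if r["p"] < alpha:
                any_sig = True
        if any_sig:
            selected.append(cand)
    table = pd.DataFrame(rows)
    if not table.empty:
        table.loc[table["candidate"].isin(selected), "selected"] = True

    if not selected:
        log.warning("no candidate reached p < %.3g; multivariate model is empty", alpha)
        return table, None

    blocks = [_candidate_design(merged, c) for c in selected]
    design = pd.concat([b for b in blocks if b is not None], axis=1)
    keep = ep["time"].notna() & ep["event"].notna() & design.notna().all(axis=1)
    multi = cox_fit(ep.loc[keep, "time"], ep.loc[keep, "event"], design[keep], ties=ties)
    return table, multi


def cox_table(result: CoxResult) -> pd.DataFrame:
    """TSV-ready Cox summary (HR, CI bounds, p) per covariate."""
    out = result.summary[["hr", "ci_low", "ci_high", "p"]].copy()
    out["p"] = out["p"].map(lambda v: float(f"{v:.3g}"))
    return out.reset_index()


# ---------------------------------------------------------------------------
# Two-factor stratification


@dataclass(frozen=True)
class StratificationResult:
    labels: pd.Series                  # 'high/high', 'high/low', ...
    logrank: TestResult
    fits: dict                         # label -> SurvivalFit
    group_sizes: dict


def two_factor_stratification(
    cohort: CohortTable,
    frame: ScoreFrame,
    factor_a: str = "cyt",
    factor_b: str = "checkpoint_index",
    endpoint: str = "OS",
) -> StratificationResult:
    """Cross two dichotomized scores into four survival strata.

    Labels are '<a>/<b>' with each side 'high' or 'low'. Empty cells are
    omitted with a warning (the log-rank df shrinks accordingly). Returns the
    k-group log-rank result and a Kaplan-Meier fit per non-empty stratum.
    """
    merged = _merged_cohort(cohort, frame)
    a = merged[f"{factor_a}_group"]
    b = merged[f"{factor_b}_group"]
    labels = a.str.cat(b, sep="/")
    keep = (
        labels.notna()
        & merged[f"{endpoint}_time"].notna()
        & merged[f"{endpoint}_event"].notna()
    )
    labels = labels[keep]
    times = merged.loc[keep, f"{endpoint}_time"].to_numpy(dtype=float)
    events = merged.loc[keep, f"{endpoint}_event"].to_numpy(dtype=int)

    all_cells = [f"{x}/{y}" for x in ("high", "low") for y in ("high", "low")]
    present = [c for c in all_cells if (labels == c).any()]
    missing = set(all_cells) - set(present)
    if missing:
        log.warning("empty stratification cell(s) %s omitted", sorted(missing))
    result = log_rank(times, events, labels.to_numpy())
    fits = {
        cell: km_fit(times[labels.to_numpy() == cell], events[labels.to_numpy() == cell])
        for cell in present
    }
    sizes = {cell: int((labels == cell).sum()) for cell in present}
    labels.index = merged.loc[keep, "sample_id"]
    return StratificationResult(labels=labels, logrank=result, fits=fits, group_sizes=sizes)
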