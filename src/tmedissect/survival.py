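"""Survival analysis of TME phenotypes and noncoding markers.

Kaplan-Meier curves with log-rank tests, Cox proportional-hazards fits
(Efron tie handling, via lifelines), maximally selected log-rank cutpoints
for continuous markers, and fixed-effect inverse-variance pooling of
per-tumor-type hazard ratios.  An inflamed-TME hazard ratio below 1 means
immune infiltration is protective.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError, ConvergenceWarning
from lifelines.statistics import multivariate_logrank_test

logger = logging.getLogger("tmedissect")

Z95 = 1.96


@dataclass
class KMLogrankResult:
    curves: dict[str, pd.DataFrame]  # group -> columns (time, survival)
    chi2: float
    p_value: float
    df: int
    no_events: bool = False


@dataclass
class CoxFit:
    summary: pd.DataFrame  # per covariate: beta, hazard_ratio, se, ci_lower, ci_upper, p
    converged: bool = True


def km_logrank(table: pd.DataFrame, group: pd.Series) -> KMLogrankResult:
    """Product-limit curves per group plus the (groups-1)-df log-rank test.

    ``table`` needs columns ``time`` and ``event``.  A group with zero
    subjects is an error; with no events anywhere the log-rank statistic is
    undefined and flagged via ``no_events``.
    """
    group = group.reindex(table.index)
    levels = (
        list(group.cat.categories) if isinstance(group.dtype, pd.CategoricalDtype)
        else sorted(group.dropna().unique())
    )
    if len(levels) < 2:
        raise ValueError("need >= 2 groups")
    curves: dict[str, pd.DataFrame] = {}
    for g in levels:
        mask = group == g
        if not mask.any():
            raise ValueError(f"group {g!r} has zero subjects")
        km = KaplanMeierFitter()
        km.fit(table.loc[mask, "time"], table.loc[mask, "event"])
        sf = km.survival_function_
        curves[str(g)] = pd.DataFrame(
            {"time": sf.index.to_numpy(), "survival": sf.iloc[:, 0].to_numpy()}
        )
    if table["event"].sum() == 0:
        return KMLogrankResult(curves, np.nan, np.nan, len(levels) - 1, no_events=True)
    res = multivariate_logrank_test(table["time"], group, table["event"])
    return KMLogrankResult(
        curves, float(res.test_statistic), float(res.p_value), len(levels) - 1
    )


def cox_fit(
    table: pd.DataFrame,
    covariates: list[str],
    duration_col: str = "time",
    event_col: str = "event",
) -> CoxFit:
    """Cox proportional-hazards fit with Efron tie correction.

    Returns per-covariate beta, HR = exp(beta), robust-free SE from the
    inverse observed information, the 95% CI exp(beta +/- 1.96 se), and the
    Wald p.  Monotone likelihood (perfect separation) is flagged
    ``converged=False`` with a warning, never silent.
    """
    df = table[[duration_col, event_col, *covariates]].dropna()
    if df[event_col].sum() < 1:
        raise ValueError("need at least one event")
    cph = CoxPHFitter(penalizer=0.0)
    converged = True
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            cph.fit(df, duration_col=duration_col, event_col=event_col)
        except ConvergenceError as exc:
            warnings.warn(
                f"Cox fit did not converge (monotone likelihood / separation?): {exc}",
                stacklevel=2,
            )
            nan = np.full(len(covariates), np.nan)
            summary = pd.DataFrame(
                {"beta": nan, "hazard_ratio": nan, "se": nan,
                 "ci_lower": nan, "ci_upper": nan, "p_value": nan},
                index=pd.Index(covariates, name="covariate"),
            )
            return CoxFit(summary=summary, converged=False)
    if any(issubclass(w.category, ConvergenceWarning) for w in caught):
        converged = False
    beta = cph.params_.reindex(covariates)
    se = cph.standard_errors_.reindex(covariates)
    if (beta.abs() > 10).any():
        converged = False
    if not converged:
        warnings.warn(
            "Cox fit flagged non-converged (diverging |beta| or convergence warning)",
            stacklevel=2,
        )
    summary = pd.DataFrame(
        {
            "beta": beta,
            "hazard_ratio": np.exp(beta),
            "se": se,
            "ci_lower": np.exp(beta - Z95 * se),
            "ci_upper": np.exp(beta + Z95 * se),
            "p_value": cph.summary["p"].reindex(covariates),
        }
    )
    summary.index.name = "covariate"
    return CoxFit(summary=summary, converged=converged)


def logrank_scores(time: np.ndarray, event: np.ndarray) -> np.ndarray:
    """Per-subject log-rank (Savage/Peto) scores: a_i = delta_i - Lambda(t_i)
    with Lambda the Nelson-Aalen cumulative hazard at the subject's time."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=float)
    cumhaz = np.zeros_like(time)
    haz = 0.0
    for t in np.unique(time):
        at_t = time == t
        n_risk = (time >= t).sum()
        haz += event[at_t].sum() / n_risk
        cumhaz[at_t] = haz
    return event - cumhaz


def optimal_cutpoint(
    marker: pd.Series, table: pd.DataFrame, minprop: float = 0.1
) -> tuple[float, pd.Series]:
    """Maximally selected log-rank cutpoint of a continuous marker.

    Candidates are the midpoints of consecutive sorted unique values that
    leave at least ``minprop`` of samples on each side.  Each candidate is
    scored by the standardized linear rank statistic of the log-rank scores
    (the maximally-selected-rank-statistics construction): with scores a_i,
    S = sum of a_i in the low group, E and V its permutation mean and
    variance; the cutoff maximizing |S - E| / sqrt(V) wins (ties: the
    smallest cutoff).  Groups are labeled "low" (<= cutoff) and "high".
    """
    marker = marker.reindex(table.index).dropna()
    values = np.sort(marker.unique())
    if values.size < 2:
        raise ValueError("marker must have >= 2 distinct values")
    tab = table.loc[marker.index]
    n = len(marker)
    min_n = minprop * n
    a = logrank_scores(tab["time"].to_numpy(), tab["event"].to_numpy())
    a_mean = a.mean()
    ss = np.sum((a - a_mean) ** 2)
    best_z, best_cut = -np.inf, None
    for cut in (values[:-1] + values[1:]) / 2.0:
        low = (marker <= cut).to_numpy()
        k = int(low.sum())
        if k < min_n or n - k < min_n:
            continue
        s = a[low].sum()
        var = k * (n - k) / (n * (n - 1)) * ss
        if var <= 0:
            continue
        z = abs(s - k * a_mean) / np.sqrt(var)
        if z > best_z + 1e-12:
            best_z, best_cut = z, float(cut)
    if best_cut is None:
        raise ValueError(f"no candidate cutoff leaves >= {minprop:.0%} of samples on each side")
    groups = pd.Series(np.where(marker <= best_cut, "low", "high"), index=marker.index)
    return best_cut, groups


def pool_hr(fits: pd.DataFrame | list[tuple[float, float]]) -> dict[str, float]:
    """Fixed-effect inverse-variance pooling of log hazard ratios.

    ``fits`` is either a DataFrame with columns ``beta`` and ``se`` (one row
    per tumor type) or a list of (beta, se) pairs.  Studies with non-finite
    SE are ignored; all-infinite SE is an error.  Returns the pooled HR with
    its 95% CI.
    """
    if isinstance(fits, pd.DataFrame):
        beta = fits["beta"].to_numpy(dtype=float)
        se = fits["se"].to_numpy(dtype=float)
    else:
        arr = np.asarray(fits, dtype=float)
        beta, se = arr[:, 0], arr[:, 1]
    ok = np.isfinite(se) & (se > 0) & np.isfinite(beta)
    if not ok.any():
        raise ValueError("no fit with finite standard error")
    w = 1.0 / se[ok] ** 2
    pooled = float(np.sum(w * beta[ok]) / np.sum(w))
    pooled_se = float(1.0 / np.sqrt(np.sum(w)))
    from scipy.stats import norm

    z = pooled / pooled_se
    return {
        "hr": float(np.exp(pooled)),
        "ci_lower": float(np.exp(pooled - Z95 * pooled_se)),
        "ci_upper": float(np.exp(pooled + Z95 * pooled_se)),
        "log_hr": pooled,
        "se": pooled_se,
        "p_value": float(2 * norm.sf(abs(z))),
        "n_studies": int(ok.sum()),
    }


def pooled_tme_hazard(
    table: pd.DataFrame,
    labels: pd.Series,
    retained: pd.Series,
    tumor_type: pd.Series | None = None,
    extra_covariates: list[str] | None = None,
) -> tuple[dict[str, float], pd.DataFrame]:
    """End-of-pipeline pooled hazard ratio of the inflamed TME.

    Fits, per tumor type, a Cox model on the retained (non-median) samples
    with the binary covariate inflamed = 1 / noninflamed = 0 (plus any
    ``extra_covariates``), then pools the inflamed log HRs by inverse
    variance.  Returns the pooled result and the per-type forest table.
    """
    if tumor_type is None:
        tumor_type = table["tumor_type"]
    keep = retained.reindex(table.index).fillna(False).astype(bool)
    rows = []
    for tt in sorted(tumor_type.dropna().unique()):
        mask = keep & (tumor_type == tt)
        sub = table.loc[mask].copy()
        lab = labels.reindex(sub.index)
        sub["inflamed"] = (lab == "inflamed").astype(float)
        if sub["inflamed"].nunique() < 2 or sub["event"].sum() < 2:
            logger.warning("tumor type %s skipped in pooling (degenerate groups)", tt)
            continue
        fit = cox_fit(sub, ["inflamed", *(extra_covariates or [])])
        row = fit.summary.loc["inflamed"]
        rows.append(
            (tt, row["beta"], row["se"], row["hazard_ratio"],
             row["ci_lower"], row["ci_upper"], row["p_value"])
        )
    forest = pd.DataFrame(
        rows, columns=["tumor_type", "beta", "se", "hr", "ci_lower", "ci_upper", "p_value"]
    ).set_index("tumor_type")
    return pool_hr(forest), forest
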