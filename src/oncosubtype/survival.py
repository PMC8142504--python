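"""Cox proportional-hazards fitting, Kaplan-Meier/log-rank tests, and the
prognostic immune-gene screen with MAD filtering.

Single multi-covariate fits go through lifelines (Efron tie handling). The
per-gene univariate screen uses an in-package vectorised Newton solver that
fits one scalar log-hazard-ratio per gene simultaneously across all genes;
it maximises the same Efron partial likelihood and is cross-checked against
lifelines in the test suite.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

from .io import ClinicalTable, ExpressionMatrix, log2cpm

logger = logging.getLogger(__name__)

BETA_CAP = 20.0


class DegenerateCovariateError(ValueError):
    """A covariate is constant (or collinear) — the hazard ratio is undefined."""


@dataclass
class CoxFit:
    """Per-covariate Wald summary of a Cox proportional-hazards fit."""

    summary: pd.DataFrame  # beta, hr, se, z, p, ci_lower, ci_upper per covariate
    log_likelihood: float
    n: int
    n_events: int
    converged: bool = True

    def __post_init__(self) -> None:
        s = self.summary
        if (s["hr"] <= 0).any():
            raise ValueError("hazard ratios must be positive")
        ok = (s["ci_lower"] <= s["hr"]) & (s["hr"] <= s["ci_upper"])
        if not ok[self.summary["se"].notna()].all():
            raise ValueError("confidence interval does not bracket HR")


@dataclass
class ScreenResult:
    """Outcome of the per-gene prognostic screen."""

    table: pd.DataFrame  # per gene: beta, hr, se, z, p, ci_lower, ci_upper, mad
    retained_genes: list[str] = field(default_factory=list)
    mad_retained_genes: list[str] = field(default_factory=list)


def fit_cox(covariates: pd.DataFrame, time, event) -> CoxFit:
    """Fit a Cox PH model (Efron ties) and return Wald statistics.

    Monotone likelihood (perfect separation) is flagged ``converged=False``
    with coefficients capped at |beta| <= 20.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if event.sum() < 2:
        raise ValueError("need at least 2 events to fit a Cox model")
    const = covariates.std(axis=0) == 0
    if const.any():
        raise DegenerateCovariateError(
            f"constant covariates: {list(covariates.columns[const])}"
        )
    df = covariates.copy()
    df["__time"] = time
    df["__event"] = event
    cph = CoxPHFitter()
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            cph.fit(df, duration_col="__time", event_col="__event",
                    fit_options={"precision": 1e-9})
        except ConvergenceError:
            converged = False
            cph = CoxPHFitter(penalizer=0.1)
            cph.fit(df, duration_col="__time", event_col="__event")
    s = cph.summary
    beta = np.clip(s["coef"].to_numpy(), -BETA_CAP, BETA_CAP)
    if not np.allclose(beta, s["coef"].to_numpy()):
        converged = False
    summary = pd.DataFrame(
        {
            "beta": beta,
            "hr": np.exp(beta),
            "se": s["se(coef)"].to_numpy(),
            "z": s["z"].to_numpy(),
            "p": s["p"].to_numpy(),
            "ci_lower": np.exp(s["coef lower 95%"].to_numpy()),
            "ci_upper": np.exp(s["coef upper 95%"].to_numpy()),
        },
        index=s.index,
    )
    return CoxFit(
        summary=summary,
        log_likelihood=float(cph.log_likelihood_),
        n=len(df),
        n_events=int(event.sum()),
        converged=converged,
    )


def efron_partial_loglik(beta: float, x: np.ndarray, time, event) -> float:
    """Efron log partial likelihood for a single covariate (reference form)."""
    x = np.asarray(x, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    eta = beta * x
    r = np.exp(eta)
    ll = 0.0
    for t in np.unique(time[event == 1]):
        dead = (time == t) & (event == 1)
        risk = time >= t
        d = int(dead.sum())
        sum_risk = r[risk].sum()
        sum_dead = r[dead].sum()
        ll += eta[dead].sum()
        for j in range(d):
            ll -= np.log(sum_risk - (j / d) * sum_dead)
    return ll


def cox_score_test(x, time, event) -> dict:
    """Score test of beta=0 for a single covariate in the Cox model.

    For a binary covariate without tied event times this statistic equals
    the two-sample log-rank chi-square exactly.
    """
    x = np.asarray(x, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    u = 0.0
    v = 0.0
    for t in np.unique(time[event == 1]):
        dead = (time == t) & (event == 1)
        risk = time >= t
        d = int(dead.sum())
        n = int(risk.sum())
        xr = x[risk]
        u += x[dead].sum() - d * xr.mean()
        if n > 1:
            v += d * ((n - d) / (n - 1)) * np.mean((xr - xr.mean()) ** 2)
    chi2 = u**2 / v if v > 0 else 0.0
    return {"u": u, "var": v, "chi2": chi2, "p": float(stats.chi2.sf(chi2, df=1))}


def km_logrank(labels, time, event) -> dict:
    """K-group log-rank test plus per-group Kaplan-Meier curves."""
    labels = pd.Series(labels).astype(str).reset_index(drop=True)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    groups = sorted(labels.unique())
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for g in groups:
        if (labels == g).sum() == 0:
            raise ValueError(f"group {g} empty")
    res = multivariate_logrank_test(time, labels, event)
    curves = {}
    for g in groups:
        m = (labels == g).to_numpy()
        kmf = KaplanMeierFitter()
        kmf.fit(time[m], event[m], label=g)
        sf = kmf.survival_function_[g]
        ci = kmf.confidence_interval_
        curves[g] = pd.DataFrame(
            {
                "survival": sf,
                "ci_lower": ci.iloc[:, 0].to_numpy(),
                "ci_upper": ci.iloc[:, 1].to_numpy(),
            },
            index=sf.index,
        )
    return {"chi2": float(res.test_statistic), "p": float(res.p_value), "curves": curves}


def _univariate_cox_batch(
    X: np.ndarray, time: np.ndarray, event: np.ndarray,
    max_iter: int = 60, tol: float = 1e-9,
) -> tuple[np.ndarray, np.ndarray]:
    """Newton fit of one scalar beta per row of X (genes x samples).

    Maximises the Efron partial likelihood per gene with step-halving;
    returns (beta, se). Vectorised over genes.
    """
    order = np.lexsort((1 - event, time))
    X = X[:, order]
    time = time[order]
    event = event[order].astype(bool)
    G, M = X.shape
    # tie groups over event times
    ev_times = time[event]
    uniq = np.unique(ev_times)
    beta = np.zeros(G)

    # risk set for time t: all samples with time >= t; with ascending sort,
    # suffix sums give risk-set aggregates.
    def loglik_grad_hess(b):
        eta = b[:, None] * X
        eta = np.clip(eta, -500, 500)
        r = np.exp(eta)
        rx = r * X
        rxx = rx * X
        # suffix cumulative sums (risk sets)
        S0 = np.cumsum(r[:, ::-1], axis=1)[:, ::-1]
        S1 = np.cumsum(rx[:, ::-1], axis=1)[:, ::-1]
        S2 = np.cumsum(rxx[:, ::-1], axis=1)[:, ::-1]
        ll = np.zeros(G)
        grad = np.zeros(G)
        hess = np.zeros(G)
        for t in uniq:
            dead = (time == t) & event
            first = int(np.searchsorted(time, t, side="left"))
            d = int(dead.sum())
            s0, s1, s2 = S0[:, first], S1[:, first], S2[:, first]
            d0 = r[:, dead].sum(axis=1)
            d1 = rx[:, dead].sum(axis=1)
            d2 = rxx[:, dead].sum(axis=1)
            ll += eta[:, dead].sum(axis=1)
            grad += X[:, dead].sum(axis=1)
            for j in range(d):
                f = j / d
                a0 = s0 - f * d0
                a1 = s1 - f * d1
                a2 = s2 - f * d2
                ll -= np.log(a0)
                grad -= a1 / a0
                hess -= a2 / a0 - (a1 / a0) ** 2
        return ll, grad, hess

    ll, grad, hess = loglik_grad_hess(beta)
    for _ in range(max_iter):
        step = np.where(hess < 0, -grad / hess, 0.0)
        step = np.clip(step, -2.0, 2.0)
        new_beta = np.clip(beta + step, -BETA_CAP, BETA_CAP)
        new_ll, new_grad, new_hess = loglik_grad_hess(new_beta)
        # step-halving where the likelihood decreased
        for _h in range(30):
            worse = new_ll < ll - 1e-12
            if not worse.any():
                break
            new_beta[worse] = (beta[worse] + new_beta[worse]) / 2
            new_ll, new_grad, new_hess = loglik_grad_hess(new_beta)
        moved = np.abs(new_beta - beta).max()
        beta, ll, grad, hess = new_beta, new_ll, new_grad, new_hess
        if np.abs(grad).max() < tol or moved < 1e-12:
            break
    se = np.sqrt(np.where(hess < 0, -1.0 / hess, np.nan))
    return beta, se


def univariate_cox_screen(
    values: pd.DataFrame, time, event
) -> pd.DataFrame:
    """Per-gene univariate Cox fits (rows of ``values`` are genes)."""
    X = values.to_numpy(dtype=float)
    keep = X.std(axis=1) > 0
    beta = np.full(len(values), np.nan)
    se = np.full(len(values), np.nan)
    if keep.any():
        b, s = _univariate_cox_batch(
            X[keep], np.asarray(time, float), np.asarray(event, int)
        )
        beta[keep], se[keep] = b, s
    z = beta / se
    p = 2 * stats.norm.sf(np.abs(z))
    return pd.DataFrame(
        {
            "beta": beta,
            "hr": np.exp(beta),
            "se": se,
            "z": z,
            "p": p,
            "ci_lower": np.exp(beta - 1.959963984540054 * se),
            "ci_upper": np.exp(beta + 1.959963984540054 * se),
        },
        index=values.index,
    )


def mad(values: np.ndarray, axis=None):
    """Unscaled median absolute deviation: median(|x - median(x)|)."""
    med = np.median(values, axis=axis, keepdims=True)
    return np.median(np.abs(values - med), axis=axis)


def screen_irgs(
    expr: ExpressionMatrix,
    clinical: ClinicalTable,
    irg_list,
    p_threshold: float = 0.05,
    mad_threshold: float = 0.5,
    endpoint: str = "os",
) -> ScreenResult:
    """Prognostic immune-gene screen.

    Univariate Cox per gene on log2(CPM+1) (counts) or as-is (intensities);
    genes with Wald p < ``p_threshold`` are retained, and of those, genes
    with unscaled MAD <= ``mad_threshold`` are removed from the NMF
    candidate list.
    """
    present = [g for g in irg_list if g in expr.values.index]
    if not present:
        raise ValueError("no screen genes present in the expression matrix")
    surv = clinical.survival(endpoint)
    common = [s for s in expr.sample_ids if s in surv.index]
    dropped = set(expr.sample_ids) ^ set(common) | (set(surv.index) - set(common))
    if dropped:
        logger.info("screen: dropped %d samples without both expression and survival",
                    len(dropped))
    surv = surv.loc[common]
    if int(surv["event"].sum()) < 10:
        raise ValueError("fewer than 10 samples with events — screen unreliable")
    vals = log2cpm(expr.restrict_samples(common), genes=present)
    table = univariate_cox_screen(vals, surv["time"], surv["event"])
    table["mad"] = mad(vals.to_numpy(), axis=1)
    retained = table.index[table["p"] < p_threshold].tolist()
    mad_retained = table.loc[retained].index[
        table.loc[retained, "mad"] > mad_threshold
    ].tolist()
    return ScreenResult(table=table, retained_genes=retained,
                        mad_retained_genes=mad_retained)
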