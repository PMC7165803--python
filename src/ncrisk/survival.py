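"""Survival statistics core: Kaplan-Meier, Cox PH, log-rank, Fisher exact.

Everything here is implemented directly on numpy arrays because these
estimators sit in the hot loop of the tree search and the power
simulations; the implementations are cross-checked against independent
references in the test suite.

Conventions
-----------
* times are months as decimals; exact ties are treated as ties (no jitter);
* event indicator: 1 = event (death), 0 = censored;
* confidence intervals are 95% two-sided throughout;
* an unreached median / CI bound is encoded as ``math.inf`` (printed "NR").
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

NOT_REACHED = math.inf

_Z95 = float(stats.norm.ppf(0.975))


def _validate_surv_input(times, events):
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=float)
    if t.ndim != 1 or t.shape != e.shape:
        raise ValueError("times and events must be 1-d arrays of equal length")
    if t.size == 0:
        raise ValueError("empty input")
    if np.any(t < 0) or np.any(np.isnan(t)):
        raise ValueError("times must be non-negative and finite")
    if not np.all(np.isin(e, (0.0, 1.0))):
        raise ValueError("events must be 0/1")
    return t, e.astype(int)


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------

@dataclass
class KaplanMeierEstimate:
    """Product-limit survival estimate with Greenwood variance.

    ``event_times`` lists the distinct times with at least one event;
    ``surv`` is S(t) just after each such time. ``greenwood_var`` is the
    Greenwood variance of S(t) itself (S(t)^2 times the cumulative sum of
    d/(n(n-d))). Pointwise confidence intervals use the log(-log S)
    transform; the median CI is the threshold crossing of the CI bands
    (Brookmeyer-Crowley style).
    """

    event_times: np.ndarray
    n_at_risk: np.ndarray
    n_events: np.ndarray
    surv: np.ndarray
    greenwood_var: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n: int
    n_events_total: int
    median: float
    median_ci_low: float
    median_ci_high: float

    @property
    def median_reached(self) -> bool:
        return math.isfinite(self.median)

    def survival_at(self, t: float) -> float:
        """S(t) of the step function (1 before the first event)."""
        i = int(np.searchsorted(self.event_times, t, side="right")) - 1
        return 1.0 if i < 0 else float(self.surv[i])

    def survival_ci_at(self, t: float) -> tuple[float, float, float]:
        """(S(t), 95% CI low, high)."""
        i = int(np.searchsorted(self.event_times, t, side="right")) - 1
        if i < 0:
            return 1.0, 1.0, 1.0
        return (float(self.surv[i]), float(self.ci_low[i]),
                float(self.ci_high[i]))

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({
            "time": self.event_times,
            "n_at_risk": self.n_at_risk,
            "n_events": self.n_events,
            "surv": self.surv,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
        })


def _first_crossing(times: np.ndarray, values: np.ndarray,
                    level: float) -> float:
    """Smallest listed time with value <= level, inf if none."""
    below = values <= level + 1e-12
    if not below.any():
        return NOT_REACHED
    return float(times[np.argmax(below)])


def km_fit(times, events) -> KaplanMeierEstimate:
    """Kaplan-Meier product-limit fit.

    With no censoring the estimate equals one minus the empirical CDF. A
    cohort with no events yields S = 1 everywhere and an unreached median
    (not an error).
    """
    t, e = _validate_surv_input(times, events)
    n = t.size
    order = np.argsort(t, kind="stable")
    ts, es = t[order], e[order]
    ut, first, counts = np.unique(ts, return_index=True, return_counts=True)
    d = np.add.reduceat(es, first)  # events per distinct time
    at_risk = n - first
    has_event = d > 0
    ut, d_, risk = ut[has_event], d[has_event], at_risk[has_event]

    if ut.size == 0:
        return KaplanMeierEstimate(
            event_times=np.empty(0), n_at_risk=np.empty(0, int),
            n_events=np.empty(0, int), surv=np.empty(0),
            greenwood_var=np.empty(0), ci_low=np.empty(0),
            ci_high=np.empty(0), n=n, n_events_total=0,
            median=NOT_REACHED, median_ci_low=NOT_REACHED,
            median_ci_high=NOT_REACHED)

    frac = d_ / risk
    surv = np.cumprod(1.0 - frac)
    with np.errstate(divide="ignore", invalid="ignore"):
        gw_terms = np.where(risk > d_, d_ / (risk * (risk - d_)), np.inf)
        gw_cum = np.cumsum(gw_terms)
        var = surv**2 * gw_cum
        # log(-log) transformed CI where 0 < S < 1
        logs = np.log(surv)
        se_ll = np.sqrt(gw_cum) / np.abs(logs)
        lo = surv ** np.exp(_Z95 * se_ll)
        hi = surv ** np.exp(-_Z95 * se_ll)
    zero = surv <= 0
    lo[zero] = 0.0
    hi[zero] = 0.0
    var[zero] = 0.0

    return KaplanMeierEstimate(
        event_times=ut, n_at_risk=risk.astype(int),
        n_events=d_.astype(int), surv=surv, greenwood_var=var,
        ci_low=lo, ci_high=hi, n=n, n_events_total=int(d_.sum()),
        median=_first_crossing(ut, surv, 0.5),
        median_ci_low=_first_crossing(ut, lo, 0.5),
        median_ci_high=_first_crossing(ut, hi, 0.5),
    )


def loglog_transform(km: KaplanMeierEstimate) -> np.ndarray:
    """(ln t, ln(-ln S(t))) pairs, emitted only where 0 < S < 1 and t > 0.

    Under proportional hazards two groups' transformed curves are parallel
    (a constant vertical offset), the classic visual check of the PH
    assumption.
    """
    mask = (km.surv > 0) & (km.surv < 1) & (km.event_times > 0)
    t = km.event_times[mask]
    s = km.surv[mask]
    return np.column_stack([np.log(t), np.log(-np.log(s))])


# ---------------------------------------------------------------------------
# Cox proportional hazards
# ---------------------------------------------------------------------------

@dataclass
class CoxModelFit:
    """Maximum partial-likelihood Cox fit.

    ``ln_hr`` are the coefficients; confidence intervals and Wald p-values
    come from the observed information. ``converged`` is False for monotone
    likelihoods (perfect risk-set separation) — reported, never silent.
    """

    names: list[str]
    ln_hr: np.ndarray
    se: np.ndarray
    n_used: int
    n_events: int
    ties_method: str
    converged: bool
    log_likelihood: float
    log_likelihood_null: float
    diagnostics: str = ""

    @property
    def hr(self) -> np.ndarray:
        return np.exp(self.ln_hr)

    @property
    def ci_low(self) -> np.ndarray:
        with np.errstate(over="ignore"):
            return np.exp(self.ln_hr - _Z95 * self.se)

    @property
    def ci_high(self) -> np.ndarray:
        with np.errstate(over="ignore"):
            return np.exp(self.ln_hr + _Z95 * self.se)

    @property
    def wald_p(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.abs(self.ln_hr) / self.se
        return 2.0 * stats.norm.sf(z)

    def to_dict(self) -> dict:
        return {
            "covariates": [
                {"name": nm, "ln_hr": float(b), "se": float(s),
                 "hr": float(h), "ci_low": float(lo), "ci_high": float(hi),
                 "wald_p": float(p)}
                for nm, b, s, h, lo, hi, p in zip(
                    self.names, self.ln_hr, self.se, self.hr,
                    self.ci_low, self.ci_high, self.wald_p)
            ],
            "n_used": self.n_used,
            "n_events": self.n_events,
            "ties_method": self.ties_method,
            "converged": self.converged,
            "log_likelihood": self.log_likelihood,
        }


class _CoxData:
    """Pre-sorted design with tie-group bookkeeping for the partial likelihood."""

    def __init__(self, X: np.ndarray, times: np.ndarray, events: np.ndarray,
                 ties: str):
        order = np.argsort(times, kind="stable")
        self.X = X[order]
        self.t = times[order]
        self.e = events[order]
        self.n, self.p = X.shape
        self.ties = ties
        ut, first = np.unique(self.t, return_index=True)
        d = np.add.reduceat(self.e, first)
        keep = d > 0
        self.first = first          # start index of every distinct time
        self.d = d                  # events per distinct time
        self.event_groups = np.flatnonzero(keep)
        self.d_max = int(d.max()) if keep.any() else 0

    def quantities(self, beta: np.ndarray):
        """Log partial likelihood, score and observed information at beta."""
        X, e, first, d = self.X, self.e, self.first, self.d
        xb = X @ beta
        xb = xb - xb.max()  # invariant shift; guards overflow
        r = np.exp(xb)
        rX = r[:, None] * X
        rXX = rX[:, :, None] * X[:, None, :]

        # suffix sums -> risk-set aggregates at each distinct time
        S0 = np.cumsum(r[::-1])[::-1]
        S1 = np.cumsum(rX[::-1], axis=0)[::-1]
        S2 = np.cumsum(rXX[::-1], axis=0)[::-1]
        g = self.event_groups
        S0g, S1g, S2g = S0[first[g]], S1[first[g]], S2[first[g]]

        # per-tie-group sums over the deaths themselves (Efron correction)
        ew = e.astype(float)
        s0d = np.add.reduceat(r * ew, first)[g]
        s1d = np.add.reduceat(rX * ew[:, None], first, axis=0)[g]
        s2d = np.add.reduceat(rXX * ew[:, None, None], first, axis=0)[g]
        dg = d[g].astype(float)

        loglik = float(xb @ e)
        grad = (X * e[:, None]).sum(axis=0)
        info = np.zeros((self.p, self.p))
        for level in range(self.d_max):
            act = dg > level
            if not act.any():
                break
            if self.ties == "efron":
                f = level / dg[act]
            else:  # breslow: the l-th death repeats the full-risk-set term
                f = np.zeros(int(act.sum()))
            den = S0g[act] - f * s0d[act]
            num1 = S1g[act] - f[:, None] * s1d[act]
            num2 = S2g[act] - f[:, None, None] * s2d[act]
            loglik -= float(np.sum(np.log(den)))
            b = num1 / den[:, None]
            grad -= b.sum(axis=0)
            info += (num2 / den[:, None, None]
                     - b[:, :, None] * b[:, None, :]).sum(axis=0)
        return loglik, grad, info


def cox_fit(covariates, times, events, ties_method: str = "efron",
            names: list[str] | None = None, max_iter: int = 100,
            tol: float = 1e-9) -> CoxModelFit:
    """Cox proportional-hazards fit by Newton-Raphson on the partial likelihood.

    Parameters
    ----------
    covariates : array-like, shape (n,) or (n, p)
        Numeric covariates; complete cases only (no NaN).
    ties_method : {"efron", "breslow"}
        Efron's correction is the default; with no tied event times the two
        coincide exactly.

    Raises ``ValueError`` for empty input, no events, or a constant
    (degenerate) covariate. A monotone likelihood is flagged via
    ``converged=False`` with a diagnostic string.
    """
    t, e = _validate_surv_input(times, events)
    X = np.asarray(covariates, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] != t.size:
        raise ValueError("covariates and times must have equal length")
    if np.isnan(X).any():
        raise ValueError("covariates contain NaN; drop incomplete cases first")
    if e.sum() == 0:
        raise ValueError("no events: Cox model undefined")
    if ties_method not in ("efron", "breslow"):
        raise ValueError("ties_method must be 'efron' or 'breslow'")
    sd = X.std(axis=0)
    if np.any(sd == 0):
        raise ValueError("degenerate covariate (constant within sample)")
    if names is None:
        names = [f"x{j}" for j in range(X.shape[1])]

    # center for numerical stability (coefficients unchanged)
    Xc = X - X.mean(axis=0)
    data = _CoxData(Xc, t, e, ties_method)
    beta = np.zeros(X.shape[1])
    ll, grad, info = data.quantities(beta)
    ll_null = ll
    converged = False
    diag = ""
    for _ in range(max_iter):
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            diag = "singular information matrix"
            break
        if np.max(np.abs(step)) < tol:
            converged = True
            break
        # step-halving line search
        for half in range(30):
            cand = beta + step / (2**half)
            ll_new, grad_new, info_new = data.quantities(cand)
            if ll_new >= ll - 1e-10:
                break
        improvement = ll_new - ll
        beta, ll, grad, info = cand, ll_new, grad_new, info_new
        if np.max(np.abs(step)) < 1e-7 or abs(improvement) < 1e-11:
            converged = True
            break
    if np.max(np.abs(beta)) > 18:
        converged = False
        diag = diag or ("monotone partial likelihood (perfect separation "
                        "of risk sets); estimates diverge")
    try:
        cov = np.linalg.inv(info)
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        se = np.full(X.shape[1], np.nan)
        converged = False
        diag = diag or "singular information matrix at optimum"
    if not converged and not diag:
        diag = "Newton-Raphson failed to converge"
    return CoxModelFit(
        names=list(names), ln_hr=beta, se=se, n_used=int(t.size),
        n_events=int(e.sum()), ties_method=ties_method, converged=converged,
        log_likelihood=float(ll), log_likelihood_null=float(ll_null),
        diagnostics=diag)


def cox_score_test_at_zero(covariates, times, events) -> tuple[float, float]:
    """Score (log-rank type) chi-square test of beta = 0 and its p-value."""
    t, e = _validate_surv_input(times, events)
    X = np.asarray(covariates, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    data = _CoxData(X - X.mean(axis=0), t, e, "breslow")
    _, grad, info = data.quantities(np.zeros(X.shape[1]))
    stat = float(grad @ np.linalg.solve(info, grad))
    p = float(stats.chi2.sf(stat, X.shape[1]))
    return stat, p


# ---------------------------------------------------------------------------
# Log-rank test
# ---------------------------------------------------------------------------

@dataclass
class LogRankResult:
    """k-group log-rank test via hypergeometric observed-minus-expected."""

    chi_square: float
    df: int
    p_value: float
    group_labels: list
    observed: np.ndarray
    expected: np.ndarray


def logrank_test(times, events, group_labels) -> LogRankResult:
    """k-sample log-rank test (chi-square with k-1 degrees of freedom)."""
    t, e = _validate_surv_input(times, events)
    g = np.asarray(group_labels)
    if g.shape != t.shape:
        raise ValueError("group_labels must match times in length")
    labels, gi = np.unique(g, return_inverse=True)
    k = labels.size
    if k < 2:
        raise ValueError("log-rank test requires at least two groups")

    order = np.argsort(t, kind="stable")
    ts, es, gs = t[order], e[order], gi[order]
    onehot = np.zeros((t.size, k))
    onehot[np.arange(t.size), gs] = 1.0

    ut, first = np.unique(ts, return_index=True)
    nrisk_g = np.cumsum(onehot[::-1], axis=0)[::-1]
    nrisk_g = nrisk_g[first]                       # (m, k)
    d_g = np.add.reduceat(onehot * es[:, None], first, axis=0)
    d_tot = d_g.sum(axis=1)
    keep = d_tot > 0
    nrisk_g, d_g, d_tot = nrisk_g[keep], d_g[keep], d_tot[keep]
    n_tot = nrisk_g.sum(axis=1)

    observed = d_g.sum(axis=0)
    p_g = nrisk_g / n_tot[:, None]
    expected = (d_tot[:, None] * p_g).sum(axis=0)

    with np.errstate(divide="ignore", invalid="ignore"):
        w = np.where(n_tot > 1, d_tot * (n_tot - d_tot) / (n_tot - 1), 0.0)
    V = np.einsum("t,tg,th->gh", w, p_g, -p_g)
    V[np.diag_indices(k)] += w @ p_g

    oe = (observed - expected)[: k - 1]
    Vr = V[: k - 1, : k - 1]
    try:
        stat = float(oe @ np.linalg.solve(Vr, oe))
    except np.linalg.LinAlgError:
        stat = float(oe @ np.linalg.pinv(Vr) @ oe)
    stat = max(stat, 0.0)
    df = k - 1
    return LogRankResult(
        chi_square=stat, df=df, p_value=float(stats.chi2.sf(stat, df)),
        group_labels=list(labels), observed=observed, expected=expected)


# ---------------------------------------------------------------------------
# Fisher exact test
# ---------------------------------------------------------------------------

def fisher_exact(table) -> float:
    """Two-sided Fisher exact p for a 2x2 table of non-negative integer counts.

    The two-sided p sums hypergeometric probabilities of all tables with the
    observed margins that are no more probable than the observed table.
    Raises ``ValueError`` on a zero margin.
    """
    a = np.asarray(table)
    if a.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(a < 0) or not np.all(np.equal(np.mod(a, 1), 0)):
        raise ValueError("table entries must be non-negative integers")
    if np.any(a.sum(axis=0) == 0) or np.any(a.sum(axis=1) == 0):
        raise ValueError("zero margin: Fisher exact test undefined")
    return float(stats.fisher_exact(a.astype(int), alternative="two-sided")[1])
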