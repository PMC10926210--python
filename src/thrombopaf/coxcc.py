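"""Cox proportional-hazards estimation for case-cohort data.

The model uses attained age as the time scale with delayed entry at the age
of study inclusion (left truncation). For a case-cohort sample the default
risk-set construction is Prentice's: subcohort members are at risk over
``(entry_age, exit_age]``, while cases outside the subcohort enter the risk
set only immediately before their own event age (implemented by moving their
entry to the largest float below their exit age). An ``unweighted`` option
treats the sample as if it were a plain cohort, for sensitivity analyses.

The partial likelihood is maximized by Newton's method with step-halving;
ties are handled by Breslow's (default) or Efron's method. Variance is
reported both model-based (inverse information) and robust, via dfbeta
(infinitesimal-jackknife) residuals aggregated per individual -- the
sandwich estimator appropriate under Prentice weighting. Score residuals
use the Breslow form, exact when event times are distinct.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .cohort import CaseCohortSample

__all__ = ["CoxFit", "fit_cox_casecohort", "check_proportional_hazards",
           "ConvergenceError"]

_ETA_CLIP = 500.0  # keeps exp() finite; far beyond any plausible log-HR


class ConvergenceError(RuntimeError):
    """Raised when the partial likelihood cannot be maximized."""


@dataclass
class CoxFit:
    """Result of a Cox partial-likelihood fit."""

    names: list[str]
    coef: np.ndarray
    se_robust: np.ndarray
    se_model: np.ndarray
    n_events: int
    n_used: int
    n_dropped: int
    converged: bool
    n_iterations: int
    log_partial_likelihood: float
    ties: str
    weighting: str
    alpha: float = 0.05
    diagnostic: str = ""
    # internals retained for the proportional-hazards test
    _schoenfeld: np.ndarray | None = field(default=None, repr=False)
    _event_ages: np.ndarray | None = field(default=None, repr=False)
    _information: np.ndarray | None = field(default=None, repr=False)

    @property
    def hr(self) -> np.ndarray:
        return np.exp(self.coef)

    def ci(self, robust: bool = True) -> tuple[np.ndarray, np.ndarray]:
        """(lower, upper) HR confidence bounds at level 1 - alpha."""
        se = self.se_robust if robust else self.se_model
        z = stats.norm.ppf(1 - self.alpha / 2)
        return np.exp(self.coef - z * se), np.exp(self.coef + z * se)

    def to_dict(self) -> dict:
        lo, hi = self.ci()
        return {
            "names": self.names,
            "coef": self.coef.tolist(),
            "hr": self.hr.tolist(),
            "hr_ci_low": lo.tolist(),
            "hr_ci_high": hi.tolist(),
            "se_robust": self.se_robust.tolist(),
            "se_model": self.se_model.tolist(),
            "n_events": self.n_events,
            "n_used": self.n_used,
            "n_dropped": self.n_dropped,
            "converged": self.converged,
            "n_iterations": self.n_iterations,
            "log_partial_likelihood": self.log_partial_likelihood,
            "ties": self.ties,
            "weighting": self.weighting,
        }


def _prepare(entry, exit_, event, X):
    """Static structures reused across Newton iterations: sort orders,
    event groups, and risk-set searchsorted positions (beta-independent)."""
    n, p = X.shape
    order_exit = np.argsort(exit_, kind="stable")
    order_entry = np.argsort(entry, kind="stable")
    ev_rows = np.flatnonzero(event == 1)
    tu, group = np.unique(exit_[ev_rows], return_inverse=True)
    d = np.bincount(group, minlength=tu.size).astype(float)
    pos_exit = np.searchsorted(exit_[order_exit], tu, side="left")
    pos_entry = np.searchsorted(entry[order_entry], tu, side="left")
    iu, ju = np.triu_indices(p)
    X2 = X[:, iu] * X[:, ju]  # packed upper triangle of x x^T
    sum_x_events = np.zeros((tu.size, p))
    np.add.at(sum_x_events, group, X[ev_rows])
    return {
        "order_exit": order_exit, "order_entry": order_entry,
        "ev_rows": ev_rows, "tu": tu, "group": group, "d": d,
        "pos_exit": pos_exit, "pos_entry": pos_entry,
        "iu": iu, "ju": ju, "X2": X2, "sum_x_events": sum_x_events,
        "p": p, "n": n,
    }


def _unpack_sym(v, p, iu, ju):
    """Packed upper triangle (m, p(p+1)/2) -> symmetric (m, p, p)."""
    M = np.zeros((v.shape[0], p, p))
    M[:, iu, ju] = v
    M[:, ju, iu] = v
    return M


def _loglik_grad_hess(beta, X, entry, exit_, event, prep, ties):
    p = prep["p"]
    iu, ju = prep["iu"], prep["ju"]
    d = prep["d"]
    ev_rows, group = prep["ev_rows"], prep["group"]
    m = prep["tu"].size
    npairs = iu.size

    eta = np.clip(X @ beta, -_ETA_CLIP, _ETA_CLIP)
    r = np.exp(eta)
    # all risk-set summands in one (n, 1+p+npairs) block: r, r*x, r*x_i*x_j
    M = np.empty((prep["n"], 1 + p + npairs))
    M[:, 0] = r
    M[:, 1 : 1 + p] = r[:, None] * X
    M[:, 1 + p :] = r[:, None] * prep["X2"]

    suff_exit = np.zeros((prep["n"] + 1, M.shape[1]))
    suff_exit[:-1] = np.cumsum(M[prep["order_exit"]][::-1], axis=0)[::-1]
    suff_entry = np.zeros((prep["n"] + 1, M.shape[1]))
    suff_entry[:-1] = np.cumsum(M[prep["order_entry"]][::-1], axis=0)[::-1]
    S = suff_exit[prep["pos_exit"]] - suff_entry[prep["pos_entry"]]
    S0 = S[:, 0]
    S1 = S[:, 1 : 1 + p]
    S2 = S[:, 1 + p :]

    sum_eta_events = eta[ev_rows].sum()

    if ties == "breslow":
        ll = sum_eta_events - float(d @ np.log(S0))
        xbar = S1 / S0[:, None]
        grad = prep["sum_x_events"].sum(axis=0) - d @ xbar
        # packed Hessian: sum_t d_t (S2/S0 - xbar_i xbar_j)
        hp = d @ (S2 / S0[:, None] - xbar[:, iu] * xbar[:, ju])
        hess = np.zeros((p, p))
        hess[iu, ju] = -hp
        hess[ju, iu] = -hp
    elif ties == "efron":
        e0 = np.zeros(m)
        np.add.at(e0, group, r[ev_rows])
        e1 = np.zeros((m, p))
        np.add.at(e1, group, M[ev_rows, 1 : 1 + p])
        e2p = np.zeros((m, npairs))
        np.add.at(e2p, group, M[ev_rows, 1 + p :])
        ll = sum_eta_events
        grad = prep["sum_x_events"].sum(axis=0).astype(float)
        hess = np.zeros((p, p))
        max_d = int(d.max())
        for l in range(max_d):
            msk = d > l
            frac = (l / d[msk])[:, None]
            s0l = S0[msk] - frac[:, 0] * e0[msk]
            s1l = S1[msk] - frac * e1[msk]
            s2l = _unpack_sym(S2[msk] - frac * e2p[msk], p, iu, ju)
            ll -= float(np.log(s0l).sum())
            xbar = s1l / s0l[:, None]
            grad -= xbar.sum(axis=0)
            V = s2l / s0l[:, None, None] - xbar[:, :, None] * xbar[:, None, :]
            hess -= V.sum(axis=0)
    else:
        raise ValueError(f"unknown ties method {ties!r}")
    return ll, grad, hess, (r, S0, S1)


def _newton(X, entry, exit_, event, ties, beta0, tol, max_iter):
    p = X.shape[1]
    prep = _prepare(entry, exit_, event, X)
    beta = np.zeros(p) if beta0 is None else np.asarray(beta0, dtype=float).copy()
    ll, grad, hess, extras = _loglik_grad_hess(beta, X, entry, exit_, event, prep, ties)
    converged = False
    it = 0
    diagnostic = ""
    # decreases below roundoff scale are accepted, not fought with halvings
    ll_rtol = 1e-10 * (abs(ll) + 1.0)
    for it in range(1, max_iter + 1):
        if np.max(np.abs(grad)) <= tol:
            converged = True
            it -= 1
            break
        try:
            delta = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError:
            delta = np.linalg.lstsq(-hess, grad, rcond=None)[0]
        step = 1.0
        for _ in range(30):  # step-halving keeps the objective non-decreasing
            cand = beta + step * delta
            ll_new, g_new, h_new, ex_new = _loglik_grad_hess(
                cand, X, entry, exit_, event, prep, ties
            )
            if np.isfinite(ll_new) and (
                ll_new >= ll - ll_rtol or np.max(np.abs(g_new)) <= tol
            ):
                break
            step /= 2
        beta, ll, grad, hess, extras = cand, ll_new, g_new, h_new, ex_new
        if np.max(np.abs(beta)) > 50:
            diagnostic = (
                "monotone partial likelihood (complete separation): "
                "coefficient diverging, no finite maximizer"
            )
            break
    else:
        diagnostic = f"no convergence in {max_iter} Newton iterations"
    if not converged and not diagnostic.startswith("monotone") \
            and np.max(np.abs(grad)) <= tol:
        converged = True
    # a vanishing gradient at an absurd coefficient is a separation plateau,
    # not a maximum: no plausible log-HR approaches 15
    if converged and np.max(np.abs(beta)) > 15:
        converged = False
        diagnostic = (
            "monotone partial likelihood (complete separation): "
            "gradient flat at diverging coefficient"
        )
    return beta, ll, grad, hess, extras, prep, converged, it, diagnostic


def _score_residuals(beta, X, entry, exit_, event, prep, extras):
    """Per-individual score residuals, Breslow form, with delayed entry."""
    ev_rows, tu, group, d = prep["ev_rows"], prep["tu"], prep["group"], prep["d"]
    r, S0, S1 = extras
    xbar = S1 / S0[:, None]
    a0 = d / S0                                   # d_t / S0_t
    a1 = (d / S0)[:, None] * xbar                 # d_t S1_t / S0_t^2
    P0 = np.concatenate([[0.0], np.cumsum(a0)])
    P1 = np.vstack([np.zeros(X.shape[1]), np.cumsum(a1, axis=0)])
    k_lo = np.searchsorted(tu, entry, side="right")   # event times > entry
    k_hi = np.searchsorted(tu, exit_, side="right")   # event times <= exit
    C0 = P0[k_hi] - P0[k_lo]
    C1 = P1[k_hi] - P1[k_lo]
    U = -r[:, None] * (X * C0[:, None] - C1)
    U[ev_rows] += X[ev_rows] - xbar[group]
    return U, xbar


def fit_cox_casecohort(
    sample: CaseCohortSample,
    exposure,
    covariates=None,
    weighting: str = "prentice",
    ties: str = "breslow",
    alpha: float = 0.05,
    beta0=None,
    tol: float = 1e-8,
    max_iter: int = 50,
    exposure_name: str = "exposure",
    covariate_names=None,
) -> CoxFit:
    """Fit the case-cohort Cox model on the age scale.

    Parameters
    ----------
    sample
        Case-cohort data; rows neither cases nor subcohort members are
        rejected at construction.
    exposure
        Per-row 0/1 indicator (e.g. carrier status), NaN allowed (row
        dropped, complete case).
    covariates
        Optional (n,) or (n, k) array of additional covariates, e.g.
        standardized BMI; NaN rows dropped.
    weighting
        ``"prentice"`` (default) or ``"unweighted"``.
    ties
        ``"breslow"`` (default) or ``"efron"``.

    Returns a :class:`CoxFit`. A monotone likelihood (complete separation)
    is flagged via ``converged=False`` and ``diagnostic``; no finite
    estimate is fabricated.
    """
    if weighting not in ("prentice", "unweighted"):
        raise ValueError(f"unknown weighting {weighting!r}")
    df = sample.data
    n = len(df)
    expo = np.asarray(exposure, dtype=float)
    if expo.shape != (n,):
        raise ValueError("exposure must be one value per sample row")
    cols = [expo]
    names = [exposure_name]
    if covariates is not None:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        if cov.shape[0] != n:
            raise ValueError("covariates must have one row per sample row")
        cols.extend(cov.T)
        if covariate_names is None:
            covariate_names = [f"covariate_{j}" for j in range(cov.shape[1])]
        names.extend(covariate_names)
    X = np.column_stack(cols)

    keep = np.isfinite(X).all(axis=1)
    n_dropped = int((~keep).sum())
    X = X[keep]
    entry = df["entry_age"].to_numpy(dtype=float)[keep]
    exit_ = df["exit_age"].to_numpy(dtype=float)[keep]
    event = df["event"].to_numpy(dtype=int)[keep]
    in_sub = df["in_subcohort"].to_numpy(dtype=bool)[keep]

    n_events = int(event.sum())
    if n_events == 0:
        raise ValueError("no events in sample: Cox model undefined")
    if np.ptp(X, axis=0).min() == 0:
        flat = np.asarray(names)[np.ptp(X, axis=0) == 0]
        raise ValueError(
            f"covariate(s) {flat.tolist()} constant across individuals: "
            "partial likelihood is flat"
        )

    if weighting == "prentice":
        entry = entry.copy()
        outside = (event == 1) & ~in_sub
        entry[outside] = np.nextafter(exit_[outside], -np.inf)

    beta, ll, grad, hess, extras, prep, converged, it, diag = _newton(
        X, entry, exit_, event, ties, beta0, tol, max_iter
    )
    info = -hess
    try:
        cov_model = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov_model = np.full_like(info, np.nan)
    if converged:
        U, xbar = _score_residuals(beta, X, entry, exit_, event, prep, extras)
        D = U @ cov_model
        cov_robust = D.T @ D
        se_robust = np.sqrt(np.diag(cov_robust))
        ev_rows, group = prep["ev_rows"], prep["group"]
        schoenfeld = X[ev_rows] - xbar[group]
        event_ages = exit_[ev_rows]
    else:
        se_robust = np.full(X.shape[1], np.nan)
        schoenfeld = None
        event_ages = None

    return CoxFit(
        names=names,
        coef=beta,
        se_robust=se_robust,
        se_model=np.sqrt(np.diag(cov_model)),
        n_events=n_events,
        n_used=int(keep.sum()),
        n_dropped=n_dropped,
        converged=converged,
        n_iterations=it,
        log_partial_likelihood=float(ll),
        ties=ties,
        weighting=weighting,
        alpha=alpha,
        diagnostic=diag,
        _schoenfeld=schoenfeld,
        _event_ages=event_ages,
        _information=info,
    )


def check_proportional_hazards(fit: CoxFit, sample: CaseCohortSample | None = None):
    """Grambsch-Therneau test on scaled Schoenfeld residuals vs event age.

    For each covariate, regresses the Schoenfeld residuals on the event age
    (identity transform) and returns the score-type chi-square statistic
    with one degree of freedom and its p-value. A statistic near zero means
    no evidence of a time-varying coefficient.

    Returns a dict ``{covariate: (statistic, p_value)}``.
    """
    if not fit.converged:
        raise ValueError("proportional-hazards test requires a converged fit")
    s = fit._schoenfeld
    g = fit._event_ages
    if s is None or g is None:
        raise ValueError("fit does not carry Schoenfeld residuals")
    m = s.shape[0]
    if m < 2:
        raise ValueError("proportional-hazards test requires >= 2 events")
    gc = g - g.mean()
    ssg = float(gc @ gc)
    info = fit._information
    out = {}
    for j, name in enumerate(fit.names):
        num = float(gc @ s[:, j])
        denom = ssg * info[j, j] / m
        if denom <= 0 or ssg == 0:
            stat = 0.0
        else:
            stat = m * num**2 / (info[j, j] * ssg)
        out[name] = (stat, float(stats.chi2.sf(stat, df=1)))
    return out
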