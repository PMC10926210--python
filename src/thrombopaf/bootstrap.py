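"""Bias-corrected (BC) percentile bootstrap confidence intervals.

The default resampling respects the case-cohort design: each replicate
resamples (a) subcohort members and (b) cases outside the subcohort
independently, with replacement, preserving both stratum sizes, and re-runs
the full estimator (prevalence + Cox fit + PAF). An ``iid_rows`` option
resamples rows ignoring the design, for sensitivity analyses.

The BC interval shifts the percentile levels by the bias constant

    z0 = Phi^-1( (#{theta* < theta_hat} + 0.5 #{theta* = theta_hat}) / B )

and reads the empirical quantiles at Phi(2 z0 + z_{alpha/2}) and
Phi(2 z0 + z_{1-alpha/2}). No acceleration term is used (BC, not BCa).
Quantiles follow numpy's default linear interpolation, so intervals are
reproducible bit-for-bit given the seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .cohort import CaseCohortSample

__all__ = ["BootstrapSpec", "BootstrapResult", "bias_corrected_interval",
           "bootstrap_paf", "BootstrapFailure"]


class BootstrapFailure(RuntimeError):
    """Raised when too many bootstrap replicates fail."""


@dataclass
class BootstrapSpec:
    """Bootstrap settings: B replicates at level 1 - alpha."""

    n_replicates: int = 10_000
    alpha: float = 0.05
    seed: int = 0
    resampling: str = "stratified_design"  # or "iid_rows"
    max_failure_fraction: float = 0.10

    def __post_init__(self) -> None:
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.resampling not in ("stratified_design", "iid_rows"):
            raise ValueError(f"unknown resampling {self.resampling!r}")


@dataclass
class BootstrapResult:
    point: float
    ci_low: float
    ci_high: float
    replicates: np.ndarray
    n_failed: int
    degenerate: bool = False


def bias_corrected_interval(
    replicates, point: float, alpha: float = 0.05
) -> tuple[float, float]:
    """BC percentile interval endpoints from bootstrap replicates.

    Ties with the point estimate count half toward the bias constant, which
    keeps z0 finite at small B. If every replicate falls on one side of the
    point estimate, z0 is infinite and the interval degenerates; the
    endpoints are then clamped to the replicate extremes with a warning.
    """
    theta = np.asarray(replicates, dtype=float)
    theta = theta[np.isfinite(theta)]
    if theta.size < 2:
        raise ValueError("need >= 2 finite replicates")
    b = theta.size
    prop = ((theta < point).sum() + 0.5 * (theta == point).sum()) / b
    if prop in (0.0, 1.0):
        warnings.warn(
            "all bootstrap replicates on one side of the point estimate; "
            "bias constant infinite, interval clamped to replicate extremes",
            stacklevel=2,
        )
        return float(theta.min()), float(theta.max())
    z0 = stats.norm.ppf(prop)
    zlo = stats.norm.ppf(alpha / 2)
    zhi = stats.norm.ppf(1 - alpha / 2)
    q_lo = stats.norm.cdf(2 * z0 + zlo)
    q_hi = stats.norm.cdf(2 * z0 + zhi)
    lo, hi = np.quantile(theta, [q_lo, q_hi])
    return float(lo), float(hi)


def _resample_rows(
    rng: np.random.Generator,
    spec: BootstrapSpec,
    strata: tuple[np.ndarray, np.ndarray],
    n_rows: int,
) -> np.ndarray:
    if spec.resampling == "stratified_design":
        sub_rows, case_rows = strata
        parts = [sub_rows[rng.integers(0, sub_rows.size, sub_rows.size)]]
        if case_rows.size:
            parts.append(case_rows[rng.integers(0, case_rows.size, case_rows.size)])
        return np.concatenate(parts)
    return rng.integers(0, n_rows, n_rows)


def bootstrap_paf(
    sample: CaseCohortSample,
    estimator,
    spec: BootstrapSpec,
) -> BootstrapResult:
    """BC bootstrap interval for any PAF-producing estimator.

    ``estimator`` is a callable on a :class:`CaseCohortSample` returning a
    float. Estimators implementing the fast-path protocol
    (``prepare(sample)`` / ``strata(state)`` / ``estimate_rows(state, rows)``,
    see :class:`~thrombopaf.paf.SingleSnpPafEstimator`) are re-run on plain
    row indices, which makes B = 10,000 practical; otherwise rows are
    resampled at the DataFrame level. Either way each replicate re-runs the
    FULL estimation chain.

    Replicates on which the estimator fails are dropped and counted; more
    than ``spec.max_failure_fraction`` failures raises
    :class:`BootstrapFailure`. Per-replicate seeds derive from
    ``(spec.seed, replicate index)``, so results do not depend on execution
    order. Deterministic given the seed.
    """
    if spec.n_replicates < 100:
        warnings.warn(
            f"n_replicates={spec.n_replicates} < 100: interval will be unstable",
            stacklevel=2,
        )
    fast = hasattr(estimator, "prepare") and hasattr(estimator, "estimate_rows")
    if fast:
        state = estimator.prepare(sample)
        strata = estimator.strata(state)
        n_rows = state["entry"].size
        point = estimator.estimate_rows(state, np.arange(n_rows))
    else:
        df = sample.data
        in_sub = df["in_subcohort"].to_numpy(dtype=bool)
        is_case = df["is_case"].to_numpy(dtype=bool)
        strata = (np.flatnonzero(in_sub), np.flatnonzero(is_case & ~in_sub))
        n_rows = len(df)
        point = float(estimator(sample))

    reps = np.full(spec.n_replicates, np.nan)
    n_failed = 0
    last_error: Exception | None = None
    for b in range(spec.n_replicates):
        # per-replicate generator keyed by (seed, index): order-independent
        rng = np.random.Generator(
            np.random.PCG64(np.random.SeedSequence([int(spec.seed), b]))
        )
        rows = _resample_rows(rng, spec, strata, n_rows)
        try:
            if fast:
                reps[b] = estimator.estimate_rows(state, rows)
            else:
                sub = sample.data.iloc[rows].reset_index(drop=True)
                resampled = CaseCohortSample(
                    sub,
                    subcohort_size=int(sub["in_subcohort"].sum()),
                    source_size=sample.source_size,
                    sampling_fraction=sample.sampling_fraction,
                )
                reps[b] = float(estimator(resampled))
        except (ValueError, np.linalg.LinAlgError) as exc:
            n_failed += 1
            last_error = exc
    if n_failed > spec.max_failure_fraction * spec.n_replicates:
        raise BootstrapFailure(
            f"{n_failed}/{spec.n_replicates} bootstrap replicates failed; "
            f"last failure: {last_error}"
        )
    good = reps[np.isfinite(reps)]
    if np.all(good == good[0]) and good[0] == point:
        return BootstrapResult(point, point, point, good, n_failed)
    prop = ((good < point).sum() + 0.5 * (good == point).sum()) / good.size
    degenerate = prop in (0.0, 1.0)
    lo, hi = bias_corrected_interval(good, point, spec.alpha)
    return BootstrapResult(point, lo, hi, good, n_failed, degenerate)
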