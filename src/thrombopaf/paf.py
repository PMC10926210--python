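"""Population attributable fraction (PAF) estimation.

Levin's formula attributes a fraction of disease to an exposure with
population carrier prevalence ``p`` and relative risk ``HR``::

    PAF = p (HR - 1) / (p (HR - 1) + 1)

For a single SNP the exposure is carriership (>=1 risk allele); for the
cumulative multi-SNP model it is the *union* indicator -- carrier at any SNP
of the set, with noncarrier-at-all-SNPs as reference -- and SNPs are added
stepwise in a fixed order. Prevalence is always estimated from subcohort
members only (the population-representative part of the case-cohort
design); hazard ratios come from the Prentice-weighted, BMI-adjusted Cox
model on the age scale.

Age-stratified curves clip each individual's risk interval to the age band:
entry is raised to the band start, exit lowered to the band end, and the
event counts only if the event age falls inside the band.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cohort import CaseCohortSample
from .coxcc import CoxFit, fit_cox_casecohort
from .genotypes import carrier_indicator, carrier_prevalence

__all__ = [
    "levin_paf",
    "PafResult",
    "CumulativeCurve",
    "single_snp_paf",
    "combined_carrier",
    "cumulative_paf_curve",
    "age_band_cumulative_paf",
    "clip_to_age_band",
    "SingleSnpPafEstimator",
    "CumulativePafEstimator",
    "DEFAULT_AGE_BANDS",
]

#: Half-open (low, high] age bands in years: young, middle-aged, elderly.
DEFAULT_AGE_BANDS = ((0.0, 50.0), (50.0, 75.0), (75.0, float("inf")))


def levin_paf(p: float, hr: float) -> float:
    """Levin's attributable fraction ``p(hr-1) / (p(hr-1) + 1)``.

    ``p`` is the exposure prevalence in the population, ``hr`` the relative
    risk of exposed vs unexposed. Negative when ``hr < 1`` (protective);
    always < 1.
    """
    p = float(p)
    hr = float(hr)
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"prevalence must be in [0, 1], got {p}")
    if not hr > 0.0:
        raise ValueError(f"hazard ratio must be > 0, got {hr}")
    x = p * (hr - 1.0)
    return x / (x + 1.0)


@dataclass
class PafResult:
    """PAF for one exposure definition (a SNP or a SNP set)."""

    exposure_label: str
    sex: str
    p: float
    hr: float
    paf: float
    ci_low: float = float("nan")
    ci_high: float = float("nan")
    n_used: int = 0
    n_events: int = 0
    fit: CoxFit | None = field(default=None, repr=False)

    def with_ci(self, lo: float, hi: float) -> "PafResult":
        return replace(self, ci_low=lo, ci_high=hi)


@dataclass
class CumulativeCurve:
    """Cumulative PAF after each SNP addition, for one sex (and age band)."""

    sex: str
    snp_ids: list[str]
    results: list[PafResult]
    age_band: tuple[float, float] | None = None
    truncated: bool = False

    @property
    def cumulative_paf(self) -> list[float]:
        return [r.paf for r in self.results]

    def to_dict(self) -> dict:
        return {
            "sex": self.sex,
            "age_band": list(self.age_band) if self.age_band else None,
            "snp_ids": self.snp_ids,
            "prevalence": [r.p for r in self.results],
            "hr": [r.hr for r in self.results],
            "cumulative_paf": [r.paf for r in self.results],
            "ci_low": [r.ci_low for r in self.results],
            "ci_high": [r.ci_high for r in self.results],
            "n_used": [r.n_used for r in self.results],
            "truncated": self.truncated,
        }


def _standardized_bmi(df: pd.DataFrame) -> np.ndarray:
    bmi = df["bmi"].to_numpy(dtype=float)
    ok = np.isfinite(bmi)
    if ok.sum() < 2:
        raise ValueError("need >= 2 nonmissing BMI values")
    mu = bmi[ok].mean()
    sd = bmi[ok].std(ddof=0)
    if sd == 0:
        raise ValueError("BMI constant: cannot standardize")
    return (bmi - mu) / sd


def single_snp_paf(
    sample: CaseCohortSample,
    snp_id: str,
    sex: str,
    weighting: str = "prentice",
    ties: str = "breslow",
    adjust_bmi: bool = True,
) -> PafResult:
    """Levin PAF of one SNP in one sex.

    Prevalence is the carrier proportion among subcohort members of that
    sex; the HR is the BMI-adjusted case-cohort Cox estimate. Individuals
    missing the genotype or BMI are dropped (complete case on this model).
    """
    sub = sample.restrict_sex(sex)
    if snp_id not in sub.data.columns:
        raise KeyError(f"snp_id {snp_id!r} not present in sample")
    carrier = carrier_indicator(sub.data[snp_id], snp_id)
    covariates = _standardized_bmi(sub.data) if adjust_bmi else None
    fit = fit_cox_casecohort(
        sub, carrier, covariates,
        weighting=weighting, ties=ties,
        exposure_name=f"carrier_{snp_id}",
        covariate_names=["bmi_z"] if adjust_bmi else None,
    )
    if not fit.converged:
        raise ValueError(
            f"Cox fit for {snp_id}/{sex} did not converge: {fit.diagnostic}"
        )
    in_sub = sub.data["in_subcohort"].to_numpy(dtype=bool)
    prev = carrier_prevalence(carrier, in_sub, snp_id)
    hr = float(fit.hr[0])
    return PafResult(
        exposure_label=snp_id,
        sex=sex,
        p=prev.proportion,
        hr=hr,
        paf=levin_paf(prev.proportion, hr),
        n_used=fit.n_used,
        n_events=fit.n_events,
        fit=fit,
    )


def combined_carrier(sample: CaseCohortSample, snp_set) -> np.ndarray:
    """Union carrier indicator over a SNP set.

    1 if carrier (>=1 risk allele) at ANY SNP of the set, 0 if noncarrier at
    ALL of them, NaN (excluded, complete case) if missing at any SNP.
    """
    snp_set = list(snp_set)
    if not snp_set:
        raise ValueError("snp_set must be nonempty")
    for s in snp_set:
        if s not in sample.data.columns:
            raise KeyError(f"snp_id {s!r} not present in sample")
    mat = np.column_stack(
        [carrier_indicator(sample.data[s], s) for s in snp_set]
    )
    out = (np.nansum(mat, axis=1) >= 1).astype(float)
    out[np.isnan(mat).any(axis=1)] = np.nan
    return out


def cumulative_paf_curve(
    sample: CaseCohortSample,
    panel_order,
    sex: str,
    weighting: str = "prentice",
    ties: str = "breslow",
    adjust_bmi: bool = True,
) -> CumulativeCurve:
    """Cumulative PAF as SNPs are added one by one in ``panel_order``.

    Every prefix is evaluated on ONE complete-case set -- individuals
    nonmissing at *all* SNPs of the full model (and BMI) -- so the points of
    the curve are mutually comparable. Combined prevalence is non-decreasing
    along the curve by construction (union over growing sets).

    If a prefix has zero combined carriers or its fit has zero events the
    curve is truncated at the previous point and flagged.
    """
    panel_order = list(panel_order)
    if not panel_order:
        raise ValueError("panel_order must be nonempty")
    sub = sample.restrict_sex(sex)
    full_union = combined_carrier(sub, panel_order)
    keep = ~np.isnan(full_union)
    if adjust_bmi:
        keep &= np.isfinite(sub.data["bmi"].to_numpy(dtype=float))
    cc = CaseCohortSample(
        sub.data.loc[keep].reset_index(drop=True),
        subcohort_size=int(sub.data.loc[keep, "in_subcohort"].sum()),
        source_size=sub.source_size,
        sampling_fraction=sub.sampling_fraction,
    )
    covariates = _standardized_bmi(cc.data) if adjust_bmi else None
    in_sub = cc.data["in_subcohort"].to_numpy(dtype=bool)

    results: list[PafResult] = []
    truncated = False
    for k in range(1, len(panel_order) + 1):
        prefix = panel_order[:k]
        expo = combined_carrier(cc, prefix)
        label = "+".join(prefix)
        if np.nansum(expo) == 0:
            truncated = True
            break
        try:
            fit = fit_cox_casecohort(
                cc, expo, covariates,
                weighting=weighting, ties=ties,
                exposure_name=f"carrier_any({label})",
                covariate_names=["bmi_z"] if adjust_bmi else None,
            )
        except ValueError:
            truncated = True
            break
        if not fit.converged:
            # e.g. separation once the reference group is nearly empty
            truncated = True
            break
        prev = carrier_prevalence(expo, in_sub, label)
        hr = float(fit.hr[0])
        results.append(
            PafResult(
                exposure_label=label,
                sex=sex,
                p=prev.proportion,
                hr=hr,
                paf=levin_paf(prev.proportion, hr),
                n_used=fit.n_used,
                n_events=fit.n_events,
                fit=fit,
            )
        )
    return CumulativeCurve(
        sex=sex,
        snp_ids=panel_order[: len(results)],
        results=results,
        truncated=truncated,
    )


def clip_to_age_band(
    sample: CaseCohortSample, band: tuple[float, float]
) -> CaseCohortSample:
    """Intersect every risk interval with the half-open age band (low, high].

    Entry is clipped up to the band start, exit down to the band end;
    individuals whose interval misses the band are dropped; the event flag
    survives only if the event age lies inside the band. An individual whose
    follow-up spans a boundary contributes censored risk time to the earlier
    band and (if they had an event later) the event to the band containing
    the event age.
    """
    lo, hi = band
    if not lo < hi:
        raise ValueError(f"invalid age band {band}")
    df = sample.data
    entry = np.maximum(df["entry_age"].to_numpy(dtype=float), lo)
    exit_ = np.minimum(df["exit_age"].to_numpy(dtype=float), hi)
    keep = exit_ > entry
    event = (
        (df["event"].to_numpy(dtype=int) == 1)
        & (df["exit_age"].to_numpy(dtype=float) > lo)
        & (df["exit_age"].to_numpy(dtype=float) <= hi)
    )
    out = df.loc[keep].copy()
    out["entry_age"] = entry[keep]
    out["exit_age"] = exit_[keep]
    out["event"] = event[keep].astype(int)
    out["is_case"] = event[keep]
    # rows kept only through case status but censored within this band drop out
    still = out["in_subcohort"] | out["is_case"]
    out = out.loc[still]
    return CaseCohortSample(
        out.reset_index(drop=True),
        subcohort_size=int(out["in_subcohort"].sum()),
        source_size=sample.source_size,
        sampling_fraction=sample.sampling_fraction,
    )


def age_band_cumulative_paf(
    sample: CaseCohortSample,
    panel_order,
    sex: str,
    bands=DEFAULT_AGE_BANDS,
    weighting: str = "prentice",
    ties: str = "breslow",
    adjust_bmi: bool = True,
) -> list[CumulativeCurve]:
    """Cumulative PAF curves stratified by attained-age band.

    Bands must be non-overlapping, ordered, and cover (0, inf). A band with
    zero events yields an empty, truncated curve rather than fabricated
    numbers.
    """
    bands = [tuple(b) for b in bands]
    for (a_lo, a_hi), (b_lo, _) in zip(bands, bands[1:]):
        if a_hi != b_lo:
            raise ValueError("age bands must be contiguous and ordered")
    if bands[0][0] != 0.0 or not np.isinf(bands[-1][1]):
        raise ValueError("age bands must cover (0, inf)")
    curves = []
    for band in bands:
        clipped = clip_to_age_band(sample, band)
        if int(clipped.data["event"].sum()) == 0:
            curves.append(
                CumulativeCurve(sex=sex, snp_ids=[], results=[],
                                age_band=band, truncated=True)
            )
            continue
        curve = cumulative_paf_curve(
            clipped, panel_order, sex,
            weighting=weighting, ties=ties, adjust_bmi=adjust_bmi,
        )
        curve.age_band = band
        curves.append(curve)
    return curves


class _ArrayPafEstimator:
    """Shared machinery for bootstrap-friendly PAF estimators.

    Subclasses define the exposure; ``prepare`` extracts plain arrays once,
    after which ``estimate_rows`` re-runs the full estimator (prevalence +
    Cox + Levin PAF) on any multiset of row indices in a few hundred
    microseconds. ``__call__`` on a sample gives the plain estimate.
    """

    def __init__(self, sex: str, weighting: str = "prentice",
                 ties: str = "breslow", adjust_bmi: bool = True):
        self.sex = sex
        self.weighting = weighting
        self.ties = ties
        self.adjust_bmi = adjust_bmi

    # -- exposure hook -----------------------------------------------------
    def _exposure(self, sample: CaseCohortSample) -> np.ndarray:
        raise NotImplementedError

    def _label(self) -> str:
        raise NotImplementedError

    # -- slow path ---------------------------------------------------------
    def __call__(self, sample: CaseCohortSample) -> float:
        state = self.prepare(sample)
        return self.estimate_rows(state, np.arange(len(state["entry"])))

    # -- fast path (protocol used by bootstrap_paf) ------------------------
    def prepare(self, sample: CaseCohortSample) -> dict:
        sub = sample.restrict_sex(self.sex) if self.sex != "both" else sample
        df = sub.data
        expo = self._exposure(sub)
        entry = df["entry_age"].to_numpy(dtype=float)
        exit_ = df["exit_age"].to_numpy(dtype=float)
        event = df["event"].to_numpy(dtype=int)
        in_sub = df["in_subcohort"].to_numpy(dtype=bool)
        if self.weighting == "prentice":
            entry = entry.copy()
            outside = (event == 1) & ~in_sub
            entry[outside] = np.nextafter(exit_[outside], -np.inf)
        bmi = df["bmi"].to_numpy(dtype=float) if self.adjust_bmi else None
        return {
            "entry": entry, "exit": exit_, "event": event,
            "in_subcohort": in_sub, "exposure": expo, "bmi": bmi,
            "beta0": None,
        }

    def strata(self, state: dict) -> tuple[np.ndarray, np.ndarray]:
        """(subcohort row indices, outside-subcohort case rows)."""
        in_sub = state["in_subcohort"]
        case = state["event"] == 1
        return np.flatnonzero(in_sub), np.flatnonzero(case & ~in_sub)

    def estimate_rows(self, state: dict, rows: np.ndarray) -> float:
        from .coxcc import _newton  # local import avoids cycle at module load

        expo = state["exposure"][rows]
        entry = state["entry"][rows]
        exit_ = state["exit"][rows]
        event = state["event"][rows]
        in_sub = state["in_subcohort"][rows]
        ok = np.isfinite(expo)
        if state["bmi"] is not None:
            bmi = state["bmi"][rows]
            ok &= np.isfinite(bmi)
        expo, entry, exit_, event, in_sub = (
            expo[ok], entry[ok], exit_[ok], event[ok], in_sub[ok]
        )
        if event.sum() == 0:
            raise ValueError("no events in resample")
        if not in_sub.any():
            raise ValueError("no subcohort members in resample")
        p = float(expo[in_sub].mean())
        if expo.min() == expo.max():
            raise ValueError("exposure constant in resample")
        if state["bmi"] is not None:
            b = bmi[ok]
            X = np.column_stack([expo, (b - b.mean()) / b.std(ddof=0)])
        else:
            X = expo[:, None]
        # gradient tolerance 1e-6 here: coefficient error is O(1e-9), far
        # below bootstrap noise, and saves one Newton evaluation per replicate
        beta, ll, grad, hess, extras, prep, conv, it, diag = _newton(
            X, entry, exit_, event, self.ties, state["beta0"],
            tol=1e-6, max_iter=50,
        )
        if not conv:
            raise ValueError(f"Cox fit failed: {diag or 'no convergence'}")
        if state["beta0"] is None:
            state["beta0"] = beta  # warm-start subsequent replicates
        return levin_paf(p, float(np.exp(beta[0])))


class SingleSnpPafEstimator(_ArrayPafEstimator):
    """PAF estimator for one SNP; usable directly or under the bootstrap."""

    def __init__(self, snp_id: str, sex: str, **kw):
        super().__init__(sex, **kw)
        self.snp_id = snp_id

    def _exposure(self, sample: CaseCohortSample) -> np.ndarray:
        return carrier_indicator(sample.data[self.snp_id], self.snp_id)

    def _label(self) -> str:
        return self.snp_id


class CumulativePafEstimator(_ArrayPafEstimator):
    """PAF estimator for the union exposure over a SNP set."""

    def __init__(self, snp_set, sex: str, **kw):
        super().__init__(sex, **kw)
        self.snp_set = list(snp_set)

    def _exposure(self, sample: CaseCohortSample) -> np.ndarray:
        return combined_carrier(sample, self.snp_set)

    def _label(self) -> str:
        return "+".join(self.snp_set)
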