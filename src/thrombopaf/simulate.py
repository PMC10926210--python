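"""Synthetic source cohorts with proportional-hazards event times on the age
scale, and case-cohort sampling.

The generator emulates a two-sex population-based cohort: entry ages from a
truncated normal (inclusion at age >=25), BMI from a normal, genotypes drawn
independently per locus under Hardy-Weinberg equilibrium, and incident-event
ages from a Gompertz baseline hazard

    h0(a) = lambda * exp(gamma * a)

multiplied by exp(beta_snp * carrier + ... + beta_bmi * z_bmi), with
sex-specific carrier log hazard ratios. Event ages are drawn by inverse
transform from the conditional cumulative hazard given survival to entry.
Follow-up ends at the event, at entry + max_followup, or at the
administrative censoring age, whichever comes first.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from ._rng import substream
from .cohort import CaseCohortSample, validate_cohort
from .genotypes import carrier_indicator
from .panel import Panel, SnpDef, default_panel

__all__ = ["CohortConfig", "simulate_cohort", "sample_case_cohort"]


@dataclass
class CohortConfig:
    """Parameters of the synthetic source cohort.

    Defaults describe a Norwegian-style adult cohort: inclusion from age 25
    (mean 47, SD 15), up to 18 years of follow-up, administrative censoring
    at age 90, and a Gompertz baseline calibrated so that with the default
    17-SNP panel the population-average cumulative incidence by age 90 is
    roughly 8-10%, giving follow-up case fractions of order 1.5%.
    """

    n_individuals: int = 20_000
    prop_female: float = 0.529
    entry_age_mean: float = 47.0
    entry_age_sd: float = 15.0
    entry_age_min: float = 25.0
    entry_age_max: float = 80.0
    max_followup: float = 18.0
    admin_censor_age: float = 90.0
    baseline_lambda: float = 3e-6
    baseline_gamma: float = 0.07
    bmi_mean: float = 26.2
    bmi_sd: float = 4.0
    bmi_log_hr: float = 0.2
    panel: Panel = field(default_factory=default_panel)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < 2:
            raise ValueError("n_individuals must be >= 2")
        if not 0.0 <= self.prop_female <= 1.0:
            raise ValueError("prop_female must be in [0, 1]")
        if self.baseline_lambda <= 0:
            raise ValueError("baseline_lambda must be > 0")
        if min(self.entry_age_min, self.entry_age_mean, self.admin_censor_age) < 0:
            raise ValueError("ages must be nonnegative")
        if not isinstance(self.panel, Panel):
            self.panel = Panel(
                s if isinstance(s, SnpDef) else SnpDef(**s) for s in self.panel
            )

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        if "panel" in doc:
            doc["panel"] = Panel(SnpDef(**e) for e in doc["panel"])
        return cls(**doc)

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "panel"}
        d["panel"] = []
        for s in self.panel:
            entry = asdict(s)
            entry["coding_rule"] = entry["coding_rule"].value
            d["panel"].append(entry)
        return d


def _gompertz_event_age(
    rng: np.random.Generator,
    entry: np.ndarray,
    multiplier: np.ndarray,
    lam: float,
    gamma: float,
) -> np.ndarray:
    """Inverse-transform event ages conditional on survival to entry.

    Solves H(a) - H(entry) = E / multiplier with E ~ Exp(1), where
    H(a) = lam/gamma * (exp(gamma*a) - 1); gamma -> 0 reduces to the
    exponential limit H(a) = lam*a.
    """
    e = rng.exponential(size=entry.shape) / multiplier
    if gamma == 0.0:
        return entry + e / lam
    # exp(gamma*a) = exp(gamma*entry) + gamma*e/lam, always > 0
    return np.log(np.exp(gamma * entry) + gamma * e / lam) / gamma


def simulate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Generate a full source cohort table. Deterministic given config.seed."""
    n = config.n_individuals
    seed = config.seed

    sex_rng = substream(seed, "sex")
    sex = np.where(sex_rng.random(n) < config.prop_female, "female", "male")

    age_rng = substream(seed, "ages")
    lo, hi = config.entry_age_min, config.entry_age_max
    entry = np.empty(n)
    todo = np.arange(n)
    while todo.size:  # rejection sampling of the truncated normal
        draw = age_rng.normal(config.entry_age_mean, config.entry_age_sd, todo.size)
        ok = (draw >= lo) & (draw <= hi)
        entry[todo[ok]] = draw[ok]
        todo = todo[~ok]

    bmi_rng = substream(seed, "bmi")
    bmi = bmi_rng.normal(config.bmi_mean, config.bmi_sd, n)

    log_mult = config.bmi_log_hr * (bmi - config.bmi_mean) / config.bmi_sd
    genotypes = {}
    is_female = sex == "female"
    for snp in config.panel:
        g_rng = substream(seed, f"genotypes:{snp.snp_id}")
        q = snp.risk_allele_freq
        g = g_rng.binomial(2, q, n).astype(float)
        genotypes[snp.snp_id] = g
        carrier = carrier_indicator(g, snp.snp_id)
        beta = np.where(is_female, snp.log_hr_female, snp.log_hr_male)
        log_mult = log_mult + beta * carrier

    ev_rng = substream(seed, "event_times")
    event_age = _gompertz_event_age(
        ev_rng, entry, np.exp(log_mult), config.baseline_lambda, config.baseline_gamma
    )
    censor_age = np.minimum(entry + config.max_followup, config.admin_censor_age)
    event = event_age <= censor_age
    exit_age = np.where(event, event_age, censor_age)

    df = pd.DataFrame(
        {
            "id": np.arange(n),
            "sex": sex,
            "entry_age": entry,
            "exit_age": exit_age,
            "event": event.astype(int),
            "bmi": bmi,
            **genotypes,
        }
    )
    return validate_cohort(df, config.panel)


def sample_case_cohort(
    cohort: pd.DataFrame, subcohort_size: int, seed: int = 0
) -> CaseCohortSample:
    """Draw the case-cohort analysis sample: all cases plus a simple random
    subcohort of ``subcohort_size`` individuals.

    Every person in the source cohort -- including cases -- has the same
    probability of entering the subcohort, so cases can be subcohort members.
    """
    n = len(cohort)
    if not 0 < subcohort_size <= n:
        raise ValueError(f"subcohort_size must be in (0, {n}], got {subcohort_size}")
    rng = substream(seed, "subcohort_sampling")
    chosen = rng.choice(n, size=subcohort_size, replace=False)
    in_sub = np.zeros(n, dtype=bool)
    in_sub[chosen] = True
    is_case = cohort["event"].to_numpy().astype(bool)
    keep = in_sub | is_case
    data = cohort.loc[keep].copy()
    data["in_subcohort"] = in_sub[keep]
    data["is_case"] = is_case[keep]
    return CaseCohortSample(
        data.reset_index(drop=True),
        subcohort_size=subcohort_size,
        source_size=n,
    )
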