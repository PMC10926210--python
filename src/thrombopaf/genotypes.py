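"""Carrier classification and genotype frequency estimation.

Genotypes are risk-allele counts per individual and SNP: 0, 1, 2, or missing
(``NaN``). Individuals with >=1 risk allele are *carriers*; no distinction is
made between heterozygous and homozygous carriers anywhere downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeCodingError",
    "classify_carrier",
    "carrier_indicator",
    "carrier_prevalence",
    "allele_frequency",
    "PrevalenceEstimate",
]

_VALID_COUNTS = (0.0, 1.0, 2.0)


class GenotypeCodingError(ValueError):
    """A genotype value outside {0, 1, 2, missing}."""


def _as_float_counts(g, snp_id: str = "?") -> np.ndarray:
    """Validate and return risk-allele counts as a float array with NaN missing."""
    if isinstance(g, pd.Series):
        arr = g.to_numpy(dtype=float, na_value=np.nan)
        index = g.index
    else:
        arr = np.asarray(g, dtype=float)
        index = None
    bad = ~(np.isnan(arr) | np.isin(arr, _VALID_COUNTS))
    if bad.any():
        where = np.flatnonzero(bad)[0]
        ident = index[where] if index is not None else where
        raise GenotypeCodingError(
            f"invalid risk-allele count {arr[bad][0]!r} for individual "
            f"{ident!r} at SNP {snp_id}: values must be 0, 1, 2 or missing"
        )
    return arr


def classify_carrier(g, snp_id: str = "?") -> pd.Series:
    """Classify individuals as carrier (>=1 risk allele) or noncarrier.

    Returns a pandas Categorical series with categories
    ``["noncarrier", "carrier"]``; missing genotypes stay missing.
    """
    arr = _as_float_counts(g, snp_id)
    labels = np.where(arr >= 1, "carrier", "noncarrier").astype(object)
    labels[np.isnan(arr)] = None
    index = g.index if isinstance(g, pd.Series) else None
    return pd.Series(
        pd.Categorical(labels, categories=["noncarrier", "carrier"]), index=index
    )


def carrier_indicator(g, snp_id: str = "?") -> np.ndarray:
    """Carrier status as float 0/1 with NaN for missing genotypes."""
    arr = _as_float_counts(g, snp_id)
    out = (arr >= 1).astype(float)
    out[np.isnan(arr)] = np.nan
    return out


@dataclass(frozen=True)
class PrevalenceEstimate:
    """A proportion with its numerator and nonmissing denominator."""

    proportion: float
    numerator: int
    denominator: int


def carrier_prevalence(g, mask=None, snp_id: str = "?") -> PrevalenceEstimate:
    """Carrier prevalence among nonmissing genotypes in ``mask``.

    ``mask`` is a boolean selector over individuals (default: all). Missing
    genotypes are excluded from the denominator (per-SNP complete case).
    """
    arr = _as_float_counts(g, snp_id)
    if mask is not None:
        marr = np.asarray(mask, dtype=bool)
        if marr.shape != arr.shape:
            raise ValueError("mask length does not match genotype vector")
        if not marr.any():
            raise ValueError("mask selects no individuals")
        arr = arr[marr]
    ok = ~np.isnan(arr)
    denom = int(ok.sum())
    if denom == 0:
        raise ValueError(f"all genotypes missing for SNP {snp_id}: prevalence undefined")
    num = int((arr[ok] >= 1).sum())
    return PrevalenceEstimate(num / denom, num, denom)


def allele_frequency(g, mask=None, snp_id: str = "?") -> PrevalenceEstimate:
    """Risk-allele frequency among nonmissing genotypes in ``mask``.

    Frequency = (heterozygotes + 2 x homozygotes) / (2 x nonmissing), and is
    invariant to individual ordering.
    """
    arr = _as_float_counts(g, snp_id)
    if mask is not None:
        marr = np.asarray(mask, dtype=bool)
        if marr.shape != arr.shape:
            raise ValueError("mask length does not match genotype vector")
        if not marr.any():
            raise ValueError("mask selects no individuals")
        arr = arr[marr]
    ok = ~np.isnan(arr)
    denom = int(ok.sum())
    if denom == 0:
        raise ValueError(f"all genotypes missing for SNP {snp_id}: frequency undefined")
    num = int(arr[ok].sum())
    return PrevalenceEstimate(num / (2 * denom), num, 2 * denom)
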