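"""Levin PAF arithmetic, cumulative models, and age-band stratification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thrombopaf import (
    CohortConfig,
    Panel,
    SnpDef,
    age_band_cumulative_paf,
    combined_carrier,
    cumulative_paf_curve,
    levin_paf,
    sample_case_cohort,
    simulate_cohort,
    single_snp_paf,
)
from thrombopaf.paf import clip_to_age_band

from conftest import Q_PREV20, make_sample


class TestLevinFormula:
    @pytest.mark.parametrize(
        "p, hr, percent_1dp",
        [
            (444 / 6909, 2.48, 8.7),    # factor V Leiden, women
            (425 / 6160, 2.17, 7.5),    # factor V Leiden, men
            (88 / 6160, 1.79, 1.1),     # prothrombin G20210A, men
            (85 / 6909, 1.17, 0.2),     # prothrombin G20210A, women
        ],
    )
    def test_printed_carrier_counts_reproduce_published_pafs(
        self, p, hr, percent_1dp
    ):
        assert round(100 * levin_paf(p, hr), 1) == percent_1dp

    def test_null_and_closed_form_values(self):
        assert levin_paf(0.37, 1.0) == 0.0
        assert levin_paf(0.5, 2.0) == pytest.approx(1 / 3)
        assert levin_paf(0.0, 5.0) == 0.0

    def test_saturated_prevalence_limit(self):
        hr = 3.7
        assert levin_paf(1.0, hr) == pytest.approx((hr - 1) / hr)

    def test_protective_exposure_gives_negative_paf(self):
        assert levin_paf(0.4, 0.8) < 0

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            levin_paf(1.2, 2.0)
        with pytest.raises(ValueError):
            levin_paf(0.5, 0.0)
        with pytest.raises(ValueError):
            levin_paf(0.5, -1.0)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        p=st.floats(0.01, 1.0),
        hr1=st.floats(1.001, 50.0),
        hr2=st.floats(1.001, 50.0),
    )
    def test_monotone_in_hr(self, p, hr1, hr2):
        lo, hi = sorted([hr1, hr2])
        if lo < hi:
            assert levin_paf(p, lo) <= levin_paf(p, hi)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        p1=st.floats(0.0, 1.0),
        p2=st.floats(0.0, 1.0),
        hr=st.floats(1.001, 50.0),
    )
    def test_monotone_in_prevalence(self, p1, p2, hr):
        lo, hi = sorted([p1, p2])
        assert levin_paf(lo, hr) <= levin_paf(hi, hr)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(p=st.floats(0.0, 1.0), hr=st.floats(0.1, 50.0))
    def test_always_below_one(self, p, hr):
        assert levin_paf(p, hr) < 1.0


def _combined_fixture():
    df = pd.DataFrame({
        "id": range(5),
        "sex": ["female"] * 5,
        "entry_age": 40.0,
        "exit_age": [50.0, 51.0, 52.0, 53.0, 54.0],
        "event": [1, 0, 1, 0, 0],
        "bmi": 25.0,
        "rsA": [1.0, 0.0, 0.0, np.nan, 2.0],
        "rsB": [0.0, 0.0, 1.0, 1.0, 0.0],
    })
    return make_sample(df)


def test_combined_carrier_union_semantics():
    sample = _combined_fixture()
    out = combined_carrier(sample, ["rsA", "rsB"])
    # carrier at exactly one SNP -> combined carrier; missing at any -> NaN
    assert out[0] == 1.0 and out[2] == 1.0 and out[4] == 1.0
    assert out[1] == 0.0
    assert np.isnan(out[3])
    with pytest.raises(KeyError):
        combined_carrier(sample, ["rsZZZ"])
    with pytest.raises(ValueError):
        combined_carrier(sample, [])


@pytest.fixture(scope="module")
def six_snp_sample():
    rng_seed = 31
    panel = Panel([
        SnpDef(f"rs{i}", f"G{i}", risk_allele_freq=q,
               log_hr_female=b, log_hr_male=b)
        for i, (q, b) in enumerate([
            (0.25, 0.30), (0.35, 0.25), (0.25, 0.25),
            (0.034, 0.90), (0.15, 0.15), (0.0065, 0.50),
        ])
    ])
    cohort = simulate_cohort(CohortConfig(
        n_individuals=12_000, panel=panel, seed=rng_seed,
        baseline_lambda=2e-5,
    ))
    return sample_case_cohort(cohort, 1_500, seed=2)


def test_cumulative_prevalence_non_decreasing(six_snp_sample):
    order = [f"rs{i}" for i in range(6)]
    curve = cumulative_paf_curve(six_snp_sample, order, "female")
    prevs = [r.p for r in curve.results]
    assert len(prevs) == 6
    assert all(b >= a for a, b in zip(prevs, prevs[1:]))
    assert not curve.truncated


def test_single_prefix_consistent_with_single_snp(six_snp_sample):
    """With no missing genotypes the one-SNP prefix of the curve equals the
    single-SNP estimate (same complete-case set)."""
    assert not six_snp_sample.data[[f"rs{i}" for i in range(6)]].isna().any().any()
    curve = cumulative_paf_curve(six_snp_sample, ["rs0"], "male")
    single = single_snp_paf(six_snp_sample, "rs0", "male")
    assert curve.results[0].p == pytest.approx(single.p, abs=1e-12)
    assert curve.results[0].hr == pytest.approx(single.hr, rel=1e-8)
    assert curve.results[0].paf == pytest.approx(single.paf, rel=1e-8)


def test_single_snp_paf_recovers_generating_truth(sim_casecohort):
    """Prevalence 0.2, HR 2 -> true PAF = 1/6; one seeded replicate lands
    within sampling error of it."""
    res = single_snp_paf(sim_casecohort, "rs0", "female")
    assert abs(res.paf - 1 / 6) < 0.08
    truth = levin_paf(0.2, 2.0)
    assert truth == pytest.approx(1 / 6, abs=1e-12)


def test_adding_null_snp_preserves_true_paf():
    """A SNP with HR 1 dilutes the combined HR but raises the combined
    prevalence such that the true PAF is unchanged; estimates over
    replicates should show no systematic shift."""
    panel = Panel([
        SnpDef("rsC", "C", risk_allele_freq=Q_PREV20,
               log_hr_female=np.log(2), log_hr_male=np.log(2)),
        SnpDef("rsN", "N", risk_allele_freq=0.25),
    ])
    diffs = []
    for rep in range(30):
        cohort = simulate_cohort(CohortConfig(
            n_individuals=6_000, panel=panel, seed=700 + rep,
            baseline_lambda=2.5e-5, bmi_log_hr=0.0,
        ))
        sample = sample_case_cohort(cohort, 1_000, seed=rep)
        curve = cumulative_paf_curve(
            sample, ["rsC", "rsN"], "female", adjust_bmi=False)
        if len(curve.results) == 2:
            diffs.append(curve.results[1].paf - curve.results[0].paf)
    assert len(diffs) >= 25
    assert abs(np.mean(diffs)) < 0.03


class TestAgeBandClipping:
    def test_event_assigned_to_band_containing_event_age(self):
        df = pd.DataFrame({
            "id": [0], "sex": ["female"], "entry_age": [40.0],
            "exit_age": [60.0], "event": [1], "bmi": [25.0],
        })
        sample = make_sample(df)
        young = clip_to_age_band(sample, (0.0, 50.0))
        mid = clip_to_age_band(sample, (50.0, 75.0))
        old = clip_to_age_band(sample, (75.0, np.inf))
        # censored risk time 40-50 in the first band
        assert young.n == 1
        assert young.data.loc[0, "entry_age"] == 40.0
        assert young.data.loc[0, "exit_age"] == 50.0
        assert young.data.loc[0, "event"] == 0
        # the event falls in the second band, risk time 50-60
        assert mid.n == 1
        assert mid.data.loc[0, "entry_age"] == 50.0
        assert mid.data.loc[0, "exit_age"] == 60.0
        assert mid.data.loc[0, "event"] == 1
        # no follow-up beyond 60
        assert old.n == 0

    def test_boundary_event_belongs_to_lower_band(self):
        """Half-open (low, high] bands: an event exactly at 50 is in the
        first band."""
        df = pd.DataFrame({
            "id": [0], "sex": ["male"], "entry_age": [40.0],
            "exit_age": [50.0], "event": [1], "bmi": [25.0],
        })
        sample = make_sample(df)
        young = clip_to_age_band(sample, (0.0, 50.0))
        assert young.data.loc[0, "event"] == 1
        assert clip_to_age_band(sample, (50.0, 75.0)).n == 0

    def test_single_band_matches_unstratified_curve(self, six_snp_sample):
        order = ["rs0", "rs3"]
        whole = cumulative_paf_curve(six_snp_sample, order, "female")
        [banded] = age_band_cumulative_paf(
            six_snp_sample, order, "female", bands=[(0.0, np.inf)])
        for a, b in zip(whole.results, banded.results):
            assert b.paf == pytest.approx(a.paf, rel=1e-9)
            assert b.p == pytest.approx(a.p, abs=1e-12)

    def test_bands_must_tile_the_age_axis(self, six_snp_sample):
        with pytest.raises(ValueError, match="contiguous"):
            age_band_cumulative_paf(
                six_snp_sample, ["rs0"], "female",
                bands=[(0.0, 50.0), (60.0, np.inf)])
        with pytest.raises(ValueError, match="cover"):
            age_band_cumulative_paf(
                six_snp_sample, ["rs0"], "female",
                bands=[(0.0, 50.0), (50.0, 80.0)])

    def test_empty_band_flagged_not_fabricated(self, six_snp_sample):
        curves = age_band_cumulative_paf(
            six_snp_sample, ["rs0"], "female",
            bands=[(0.0, 1.0), (1.0, np.inf)])
        assert curves[0].truncated
        assert curves[0].results == []
        assert curves[1].results


def test_sexes_never_mix(six_snp_sample):
    """Sex-stratified results are computed on disjoint subsets."""
    f = six_snp_sample.restrict_sex("female")
    m = six_snp_sample.restrict_sex("male")
    assert f.n + m.n == six_snp_sample.n
    assert set(f.data["id"]).isdisjoint(set(m.data["id"]))
    with pytest.raises(ValueError):
        six_snp_sample.restrict_sex("other")
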