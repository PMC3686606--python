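"""Synthetic cohort generator: calibration, marginals, outcomes, determinism."""

import math

import numpy as np
import pandas as pd
import pytest

from bicarotid import (
    CohortConfig,
    calibrate_within_correlation,
    draw_arterial_measures,
    draw_outcomes,
    generate_cohort,
    orthant_both_large,
    read_cohort_csv,
    write_cohort_csv,
)
from bicarotid.cohort import COHORT_COLUMNS, ConfigurationError


class TestCalibration:
    def test_independence_target(self):
        assert calibrate_within_correlation(0.25) == pytest.approx(0.0, abs=1e-12)

    def test_closed_form_inversion(self):
        rho = calibrate_within_correlation(0.32)
        assert rho == pytest.approx(math.sin(2 * math.pi * 0.07), abs=1e-12)
        assert orthant_both_large(rho) == pytest.approx(0.32, abs=1e-12)

    def test_monte_carlo_cross_check(self):
        # independent bivariate-normal simulation of the orthant probability
        rho = calibrate_within_correlation(0.32)
        rng = np.random.default_rng(42)
        n = 400_000
        z1 = rng.standard_normal(n)
        z2 = rho * z1 + math.sqrt(1 - rho**2) * rng.standard_normal(n)
        p = np.mean((z1 >= 0) & (z2 >= 0))
        assert p == pytest.approx(0.32, abs=3 * math.sqrt(0.32 * 0.68 / n))

    def test_comonotone_limit(self):
        assert calibrate_within_correlation(0.5 - 1e-9) == pytest.approx(1.0, abs=1e-4)

    @pytest.mark.parametrize("bad", [0.2, 0.5, 0.7])
    def test_domain_errors(self, bad):
        with pytest.raises(ValueError):
            calibrate_within_correlation(bad)


class TestArterialMeasures:
    def test_marginal_medians_sign_test(self):
        """Each measure is >= its log-location median with probability 1/2."""
        cfg = CohortConfig(n_subjects=20_000, seed=5)
        m = draw_arterial_measures(cfg, 20_000)
        women = m[m["sex"] == "F"]
        n = len(women)
        k = (women["r_imt_mm"] >= 0.609).sum()
        # binomial bound on the sign test at p = 1/2
        assert abs(k - n / 2) < 4 * math.sqrt(n / 4)

    def test_independence_gives_uniform_quadrants(self):
        cfg = CohortConfig(n_subjects=40_000, rho_within=0.0, rho_between=0.0, seed=6)
        m = draw_arterial_measures(cfg, 40_000)
        men = m[m["sex"] == "M"]
        big_i = men["r_imt_mm"] >= 0.663
        big_d = men["r_dia_mm"] >= 8.092
        n = len(men)
        se3 = 3 * math.sqrt(0.25 * 0.75 / n)
        for q in (big_i & big_d, big_i & ~big_d, ~big_i & big_d, ~big_i & ~big_d):
            assert q.mean() == pytest.approx(0.25, abs=se3)

    def test_calibrated_prevalence_matches_orthant_formula(self):
        cfg = CohortConfig(n_subjects=60_000, seed=7)
        m = draw_arterial_measures(cfg, 60_000)
        men = m[m["sex"] == "M"]
        p = ((men["r_imt_mm"] >= 0.663) & (men["r_dia_mm"] >= 8.092)).mean()
        target = orthant_both_large(cfg.rho_within)
        assert p == pytest.approx(target, abs=3 * math.sqrt(target * (1 - target) / len(men)))

    def test_nonpositive_definite_rejected(self):
        with pytest.raises(ConfigurationError, match="rho"):
            CohortConfig(rho_within=1.0)


class TestOutcomes:
    def test_zero_hazard_means_zero_events(self):
        cfg = CohortConfig(n_subjects=3000, baseline_hazard=0.0, seed=8)
        cohort = generate_cohort(cfg)
        assert cohort["event"].sum() == 0
        assert (cohort["time_years"] >= cfg.censor_min_years).all()

    def test_flat_hazard_incidence(self):
        """All log-HRs zero: incidence ~ 1 - exp(-h0 * 11yr) at 11-yr mean follow-up."""
        cfg = CohortConfig(
            n_subjects=60_000, baseline_hazard=0.0016,
            log_hazard_by_phenotype={i: 0.0 for i in range(1, 11)}, seed=9,
        )
        cohort = generate_cohort(cfg)
        expected = 1 - math.exp(-0.0016 * 11.0)
        se3 = 3 * math.sqrt(expected * (1 - expected) / len(cohort))
        assert cohort["event"].mean() == pytest.approx(expected, abs=se3 + 2e-4)

    def test_event_times_bounded_by_censoring(self):
        cohort = generate_cohort(CohortConfig(n_subjects=2000, seed=10))
        assert (cohort["time_years"] > 0).all()
        assert (cohort["time_years"] <= 12.0 + 1e-12).all()
        ev = cohort[cohort["event"] == 1]
        assert (ev["time_years"] <= 12.0).all()

    def test_unknown_phenotype_hazard_rejected(self):
        with pytest.raises(ConfigurationError, match="phenotype"):
            CohortConfig(log_hazard_by_phenotype={1: 0.0})


class TestDeterminismAndSchema:
    def test_bit_reproducible(self):
        cfg = CohortConfig(n_subjects=500, seed=11)
        a, b = generate_cohort(cfg), generate_cohort(cfg)
        pd.testing.assert_frame_equal(a, b)

    def test_seed_changes_output(self):
        a = generate_cohort(CohortConfig(n_subjects=500, seed=1))
        b = generate_cohort(CohortConfig(n_subjects=500, seed=2))
        assert not a["r_imt_mm"].equals(b["r_imt_mm"])

    def test_csv_round_trip_and_header(self, tmp_path):
        cohort = generate_cohort(CohortConfig(n_subjects=50, seed=12))
        path = tmp_path / "cohort.csv"
        write_cohort_csv(cohort, path)
        header = path.read_text().splitlines()[0]
        assert header == ",".join(COHORT_COLUMNS)
        back = read_cohort_csv(path)
        assert list(back.columns[: len(COHORT_COLUMNS)]) == COHORT_COLUMNS
        assert len(back) == 50

    def test_missing_values_forbidden_in_csv(self, tmp_path):
        cohort = generate_cohort(CohortConfig(n_subjects=10, seed=13))
        cohort.loc[0, "r_imt_mm"] = np.nan
        with pytest.raises(ValueError, match="missing"):
            write_cohort_csv(cohort, tmp_path / "bad.csv")


def test_phenotype1_prevalence_monotone_in_between_side_correlation():
    """Stronger right-left coupling concentrates subjects in phenotype 1."""
    from bicarotid import MedianTable, classify_cohort

    prevs = []
    for rho_b in (0.0, 0.35, 0.7):
        cfg = CohortConfig(n_subjects=20_000, rho_between=rho_b, seed=14)
        m = draw_arterial_measures(cfg, 20_000)
        cl = classify_cohort(m, cfg.population_medians())
        prevs.append((cl["phenotype_id"] == 1).mean())
    assert prevs[0] < prevs[1] < prevs[2]
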