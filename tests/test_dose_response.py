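"""BED/EQD2/TCP layer: printed-value checks and defining-property invariants."""

import math

import numpy as np
import pytest
from scipy.optimize import brentq

from umasurv import (
    DomainError,
    FractionationScheme,
    TCPContext,
    UMAParameters,
    bed,
    bed50,
    convert_fraction_number,
    d50,
    eqd2,
    gamma50,
    log_survival,
    poisson_tcp,
    summary_table,
    survival,
    survival_course,
    tcp,
    td50,
    td_for_probability,
)

SCHEME = FractionationScheme(5, 10.0)


def bed_bisection_oracle(params, m, D):
    """Independent root-find of survival(B) = survival(D)**m."""
    target = m * log_survival(params, D)
    return brentq(lambda b: log_survival(params, b) - target, 0.0, m * D + 100.0,
                  xtol=1e-12, rtol=1e-14)


class TestBED:
    def test_sw1573_course(self, sw1573):
        assert bed(sw1573, SCHEME) == pytest.approx(38.97, abs=0.02)

    def test_single_fraction_is_its_own_bed(self, sw1573):
        assert bed(sw1573, FractionationScheme(1, 7.3)) == pytest.approx(7.3, abs=1e-12)

    def test_hc12_against_bisection_oracle(self):
        p = UMAParameters(0.59, 4.5)
        value = bed(p, SCHEME)
        assert value == pytest.approx(39.88, abs=0.01)
        assert value == pytest.approx(bed_bisection_oracle(p, 5, 10.0), abs=1e-8)

    def test_defining_property_over_parameter_space(self, random_clinical_params):
        rng = np.random.default_rng(11)
        for p in random_clinical_params:
            m = int(rng.integers(1, 11))
            D = float(rng.uniform(0.5, 20.0))
            b = bed(p, FractionationScheme(m, D))
            lhs = log_survival(p, b)
            rhs = m * log_survival(p, D)
            assert lhs == pytest.approx(rhs, rel=1e-10, abs=1e-10)

    def test_rejects_nonclinical_branch(self):
        with pytest.raises(DomainError):
            bed(UMAParameters(-0.3, 1.0), SCHEME)


class TestEQD2:
    def test_sw1573_value(self, sw1573):
        assert eqd2(sw1573, SCHEME) == pytest.approx(185.5, abs=0.2)

    def test_hx149m_value(self):
        assert eqd2(UMAParameters(0.44, 4.0), SCHEME) == pytest.approx(100.94, abs=0.05)

    def test_two_gray_course_is_its_own_eqd2(self, random_clinical_params):
        for p in random_clinical_params[:20]:
            for m in (1, 7, 30):
                assert eqd2(p, FractionationScheme(m, 2.0)) == pytest.approx(2.0 * m, rel=1e-14)

    def test_invariant_under_iso_survival_refractionation(self, random_clinical_params):
        for p in random_clinical_params[:20]:
            d_new = convert_fraction_number(p, SCHEME, 3)
            assert eqd2(p, FractionationScheme(3, d_new)) == pytest.approx(
                eqd2(p, SCHEME), rel=1e-8
            )


class TestPoissonTCP:
    def test_printed_survival_rows(self):
        assert poisson_tcp(1e4, 0.1058**5) == pytest.approx(0.876, abs=5e-4)
        assert poisson_tcp(1e6, 0.0471**5) == pytest.approx(0.793, abs=5e-4)

    def test_half_probability_at_ln2_over_n0(self):
        for N0 in (1e2, 1e4, 1e6):
            assert poisson_tcp(N0, math.log(2.0) / N0) == pytest.approx(0.5, rel=1e-14)

    def test_course_tcp_sw1573(self, sw1573):
        assert tcp(sw1573, TCPContext(1e6), SCHEME) >= 0.9999

    def test_stem_cell_complication_probability(self):
        """Single 3 Gy exposure of ~30 follicle stem-cell clusters: ~10% risk."""
        adsc = UMAParameters(0.90, 1.20)
        ntcp = tcp(adsc, TCPContext(30, "normal_tissue_complication"),
                   FractionationScheme(1, 3.0))
        assert ntcp == pytest.approx(0.092, abs=0.002)

    def test_zero_dose_course_fails_to_control(self, sw1573):
        assert tcp(sw1573, TCPContext(1e4), FractionationScheme(5, 0.0)) < 1e-100


class TestD50:
    @pytest.mark.parametrize("N0,expected", [(1e5, 5.30), (1e6, 5.85)])
    def test_printed_values(self, sw1573, N0, expected):
        assert round(d50(sw1573, 5, TCPContext(N0)), 2) == expected

    def test_defining_property_tcp_is_half(self, random_clinical_params):
        rng = np.random.default_rng(5)
        for p in random_clinical_params[:25]:
            m = int(rng.integers(1, 11))
            N0 = float(10 ** rng.uniform(1, 8))
            dose = d50(p, m, TCPContext(N0))
            assert tcp(p, TCPContext(N0), FractionationScheme(m, dose)) == pytest.approx(
                0.5, abs=1e-10
            )

    def test_small_population_rejected(self, sw1573):
        with pytest.raises(DomainError):
            d50(sw1573, 5, TCPContext(0.5))


class TestBED50:
    def test_sw1573_recomputed_value(self, sw1573):
        # bisection oracle: survival(B) = ln2/N0
        N0 = 1e4
        oracle = brentq(
            lambda b: log_survival(sw1573, b) - math.log(math.log(2.0) / N0),
            0.0, 200.0, xtol=1e-12,
        )
        value = bed50(sw1573, 5, TCPContext(N0))
        assert value == pytest.approx(13.40, abs=0.01)
        assert value == pytest.approx(oracle, abs=1e-8)

    def test_single_fraction_equals_d50(self, sw1573):
        ctx = TCPContext(1e5)
        assert bed50(sw1573, 1, ctx) == pytest.approx(d50(sw1573, 1, ctx), abs=1e-10)

    def test_monotone_in_clonogen_count(self, table1_params):
        for p in table1_params:
            values = [bed50(p, 5, TCPContext(N0)) for N0 in (1e4, 1e5, 1e6)]
            assert values[0] < values[1] < values[2]


class TestGamma50:
    @pytest.mark.parametrize(
        "gamma,n,expected", [(0.90, 12.0, 0.27), (0.59, 4.5, 0.18)]
    )
    def test_printed_values(self, gamma, n, expected):
        assert round(gamma50(UMAParameters(gamma, n), 5, TCPContext(1e4)), 2) == expected

    def test_matches_numerical_tcp_slope(self, random_clinical_params):
        for p in random_clinical_params[:15]:
            m, N0 = 5, 3e4
            td = td50(p, m, TCPContext(N0))
            h = td * 1e-5

            def tcp_of_total(t):
                return tcp(p, TCPContext(N0), FractionationScheme(m, t / m))

            slope = (tcp_of_total(td + h) - tcp_of_total(td - h)) / (2 * h)
            assert gamma50(p, m, TCPContext(N0)) == pytest.approx(slope, rel=1e-6)

    def test_exact_coefficient_identity(self, sw1573):
        from umasurv.model import rs

        ctx = TCPContext(1e4)
        dose = d50(sw1573, 5, ctx)
        assert gamma50(sw1573, 5, ctx) == 0.5 * math.log(2.0) * rs(sw1573, dose)


class TestTDForProbability:
    def test_tumour_dose_estimate(self, sw1573):
        ctx = TCPContext(1e4)
        assert td_for_probability(sw1573, 5, ctx, 0.8) == pytest.approx(24.76, abs=0.05)

    def test_normal_tissue_sign_flip(self, sw1573):
        ctx = TCPContext(1e4, "normal_tissue_complication")
        offset = 0.3 / gamma50(sw1573, 5, ctx)
        assert td_for_probability(sw1573, 5, ctx) == pytest.approx(
            td50(sw1573, 5, ctx) - offset, abs=1e-10
        )

    def test_linearised_tumour_dose_lands_above_midpoint(self, table1_params):
        for p in table1_params:
            ctx = TCPContext(1e4)
            td = td_for_probability(p, 5, ctx, 0.8)
            prob = tcp(p, TCPContext(1e4), FractionationScheme(5, td / 5.0))
            assert 0.5 < prob < 0.95


class TestFractionConversion:
    @pytest.mark.parametrize(
        "gamma,n,expected", [(0.90, 12.0, 14.83), (0.44, 4.0, 14.69)]
    )
    def test_printed_three_fraction_doses(self, gamma, n, expected):
        value = convert_fraction_number(UMAParameters(gamma, n), SCHEME, 3)
        assert round(value, 2) == expected

    def test_identity_conversion(self, sw1573):
        assert convert_fraction_number(sw1573, SCHEME, 5) == pytest.approx(10.0, rel=1e-12)

    def test_course_survival_preserved(self, random_clinical_params):
        rng = np.random.default_rng(17)
        for p in random_clinical_params[:25]:
            m, i = int(rng.integers(1, 11)), int(rng.integers(1, 11))
            D = float(rng.uniform(1.0, 15.0))
            d_new = convert_fraction_number(p, FractionationScheme(m, D), i)
            assert i * log_survival(p, d_new) == pytest.approx(
                m * log_survival(p, D), rel=1e-10
            )

    def test_exponential_tail_plateau_across_cell_lines(self, table1_params):
        """On the straight portion, 5->3 conversion is nearly line-independent."""
        values = [convert_fraction_number(p, SCHEME, 3) for p in table1_params]
        assert max(values) - min(values) <= 0.35


class TestSummaryTable:
    def test_sw1573_row_reproduces_printed_panel(self, table1_params):
        rows = summary_table(table1_params, SCHEME, [1e4, 1e5, 1e6], 3)
        row = rows[0].as_dict()
        assert row["label"] == "SW1573 24 h DP"
        assert float(f"{row['S(D)']:.2g}") == 0.0015
        assert round(row["RS(0)_per_Gy"], 3) == 0.075
        assert round(row["GRS_per_Gy"], 2) == 0.33
        assert round(row["D50_Gy(N0=100000)"], 2) == 5.30
        assert round(row["D50_Gy(N0=1e+06)"], 2) == 5.85
        assert round(row["Gamma50_per_Gy(N0=10000)"], 2) == 0.27
        assert round(row["D_3fx_Gy"], 2) == 14.83
        assert row["TCP(N0=1e+06)_pct"] == pytest.approx(100.0, abs=0.05)

    def test_empty_input_gives_empty_table(self):
        assert summary_table([], SCHEME, [1e4]) == []

    def test_three_population_variants_per_row(self, table1_params):
        rows = summary_table(table1_params, SCHEME, [1e4, 1e5, 1e6])
        assert len(rows) == 5
        for r in rows:
            assert set(r.tcp) == {1e4, 1e5, 1e6}
            assert set(r.d50) == set(r.bed50) == set(r.gamma50) == {1e4, 1e5, 1e6}

    def test_failing_cell_line_marked_not_fatal(self, sw1573):
        bad = UMAParameters(-0.3, 1.0, "growth-line")
        rows = summary_table([sw1573, bad], SCHEME, [1e4])
        assert rows[0].error is None
        assert rows[1].error is not None
        assert rows[1].as_dict()["error"]
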