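"""Disproportionality statistics against hand values and independent oracles."""

import math

import numpy as np
import pytest
from scipy import integrate, special, stats as sps

from faersig.smq import SmqDefinition, aggregate_smq, count_pt_pairs
from faersig.stats import (
    ContingencyTable,
    MgpsPrior,
    SignalEstimate,
    bonferroni,
    build_contingency,
    contingency_from_totals,
    ebgm_estimate,
    evaluate_signal,
    fit_mgps_prior,
    ic_estimate,
    mixture_log_marginal,
    pearson_chi2,
    prr_estimate,
    pvalue_2x2,
    ror_estimate,
)
from faersig.synth import simulate_pair_table

from conftest import make_report


def random_tables(n, seed, low=1, high=500):
    rng = np.random.default_rng(seed)
    return [
        ContingencyTable(*rng.integers(low, high, size=4).tolist()) for _ in range(n)
    ]


class TestBuildContingency:
    def test_degenerate_single_pair_dataset(self):
        t = contingency_from_totals(5, 5, 5, 5)
        assert t.cells() == (5, 0, 0, 0)

    def test_hand_arithmetic(self):
        t = contingency_from_totals(10, 100, 110, 10_100)
        assert t.cells() == (10, 90, 100, 9_900)

    def test_inconsistent_totals_fatal(self):
        with pytest.raises(ValueError, match="inconsistent"):
            contingency_from_totals(10, 5, 110, 10_100)

    def test_cells_agree_with_brute_force_over_reports(self):
        """Pair counting equals a double loop over reports x events."""
        smq = SmqDefinition(name="mini", member_pts=("osteoporosis", "bone loss"))
        rng = np.random.default_rng(77)
        drugs = ["ADEFOVIR", "OTHER A", "OTHER B"]
        events = ["osteoporosis", "bone loss", "headache"]
        reports = []
        for i in range(400):
            drug = drugs[rng.integers(len(drugs))]
            reactions = {e for e in events if rng.random() < 0.3} or {"headache"}
            reports.append(
                make_report(pid=str(i), drugs=((drug, "PS", None),), reactions=reactions)
            )
        counts = count_pt_pairs(reports, "ADEFOVIR", smq)
        for pt in smq.member_pts:
            table = build_contingency(counts, "ADEFOVIR", pt)
            a = sum(
                1 for r in reports
                if r.has_primary_suspect("ADEFOVIR") and pt in r.reactions
            )
            b = sum(
                1 for r in reports
                if r.has_primary_suspect("ADEFOVIR") and pt not in r.reactions
            )
            c = sum(
                1 for r in reports
                if not r.has_primary_suspect("ADEFOVIR") and pt in r.reactions
            )
            d = len(reports) - a - b - c
            assert table.cells() == (a, b, c, d)


class TestRor:
    def test_uniform_table_is_null(self):
        est = ror_estimate(ContingencyTable(10, 10, 10, 10))
        assert est.point == pytest.approx(1.0)
        assert est.interval_low < 1.0 < est.interval_high
        assert not est.is_signal

    def test_hand_values(self):
        est = ror_estimate(ContingencyTable(10, 90, 100, 9_900))
        assert est.point == pytest.approx(11.0)
        assert est.interval_low == pytest.approx(5.56, abs=0.01)
        assert est.interval_high == pytest.approx(21.77, abs=0.01)
        assert est.is_signal

    def test_zero_cell_undefined_without_continuity(self):
        est = ror_estimate(ContingencyTable(0, 10, 10, 10))
        assert not est.defined
        assert math.isnan(est.point)
        assert not est.is_signal
        cont = ror_estimate(ContingencyTable(0, 10, 10, 10), continuity=True)
        assert cont.defined
        assert cont.point == pytest.approx((0.5 * 10.5) / (10.5 * 10.5))

    def test_point_matches_published_ci_geometry(self):
        """Printed ROR 38.42 with CI (33.46, 44.13): the point is the
        geometric mean of the bounds under the Wald construction."""
        reconstructed = math.sqrt(33.46 * 44.13)
        assert reconstructed == pytest.approx(38.42, rel=0.01)


class TestPrr:
    def test_uniform_table(self):
        est = prr_estimate(ContingencyTable(10, 10, 10, 10))
        assert est.point == pytest.approx(1.0)
        assert est.chi2 == pytest.approx(0.0)

    def test_hand_values(self):
        est = prr_estimate(ContingencyTable(10, 90, 100, 9_900))
        assert est.point == pytest.approx(10.0)
        assert est.chi2 == pytest.approx(74.45, abs=0.01)

    def test_a_zero_undefined(self):
        assert not prr_estimate(ContingencyTable(0, 10, 10, 10)).defined


class TestLogSymmetryAndOracle:
    def test_formula_oracle_on_random_tables(self):
        """ROR/PRR/chi2/IC match direct formula evaluation to 1e-10."""
        for table in random_tables(1000, seed=5):
            a, b, c, d = (float(x) for x in table.cells())
            n = a + b + c + d
            ror = ror_estimate(table)
            assert ror.point == pytest.approx(a * d / (b * c), abs=1e-10, rel=1e-10)
            prr = prr_estimate(table)
            assert prr.point == pytest.approx(
                (a / (a + b)) / (c / (c + d)), abs=1e-10, rel=1e-10
            )
            chi2 = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
            assert prr.chi2 == pytest.approx(chi2, abs=1e-10, rel=1e-10)
            e = (a + b) * (a + c) / n
            ic = ic_estimate(table)
            assert ic.point == pytest.approx(
                math.log2((a + 0.5) / (e + 0.5)), abs=1e-10
            )

    def test_log_symmetry_of_wald_intervals(self):
        for table in random_tables(200, seed=11):
            for est in (ror_estimate(table), prr_estimate(table)):
                geo = math.sqrt(est.interval_low * est.interval_high)
                assert geo == pytest.approx(est.point, rel=1e-9)


class TestIc:
    def test_hand_values(self):
        est = ic_estimate(ContingencyTable(10, 90, 100, 9_900))
        assert est.point == pytest.approx(2.724, abs=0.001)
        assert est.interval_low == pytest.approx(1.647, abs=0.001)

    def test_null_association_near_zero(self):
        # a == E exactly for a balanced table with large counts
        est = ic_estimate(ContingencyTable(1000, 1000, 1000, 1000))
        assert abs(est.point) < 0.01

    def test_shrinks_toward_null(self):
        for table in random_tables(100, seed=3):
            if table.a > table.expected:
                est = ic_estimate(table)
                assert est.point < math.log2(table.a / table.expected)


class TestPvalue:
    def test_uniform_table_p_one(self):
        assert pvalue_2x2(ContingencyTable(10, 10, 10, 10)) == pytest.approx(1.0)

    def test_chi2_branch_matches_scipy(self):
        table = ContingencyTable(30, 70, 40, 160)
        expected = sps.chi2_contingency(
            [[30, 70], [40, 160]], correction=False
        ).pvalue
        assert pvalue_2x2(table) == pytest.approx(expected, rel=1e-12)

    def test_fisher_branch_matches_hypergeometric_enumeration(self):
        """Small-table p equals summing hypergeometric probabilities of all
        tables with fixed margins at most as probable as observed."""
        table = ContingencyTable(3, 7, 1, 9)
        n, row1, col1 = 20, 10, 4
        p_obs = sps.hypergeom.pmf(3, n, row1, col1)
        p_enum = sum(
            sps.hypergeom.pmf(k, n, row1, col1)
            for k in range(0, min(row1, col1) + 1)
            if sps.hypergeom.pmf(k, n, row1, col1) <= p_obs * (1 + 1e-9)
        )
        assert pvalue_2x2(table) == pytest.approx(p_enum, rel=1e-9)


class TestBonferroni:
    def test_basic_rules(self):
        assert bonferroni([0.03], m=1)[0] == pytest.approx(0.03)
        assert bonferroni([0.01], m=10)[0] == pytest.approx(0.1)
        assert bonferroni([0.2], m=10)[0] == pytest.approx(1.0)

    def test_order_preserving_and_monotone(self):
        p = [0.001, 0.01, 0.04, 0.2]
        adj = bonferroni(p)
        assert list(adj) == sorted(adj)
        assert all(x >= y for x, y in zip(adj, p))

    def test_invalid_inputs_fatal(self):
        with pytest.raises(ValueError):
            bonferroni([1.5])
        with pytest.raises(ValueError):
            bonferroni([0.1, 0.2], m=1)


class TestEvaluateSignal:
    @staticmethod
    def _est(method, point, low, high, a, signal):
        return SignalEstimate(
            method=method, point=point, interval_low=low, interval_high=high,
            a_count=a, is_signal=signal,
        )

    def test_strong_published_magnitude_pair_is_consensus_positive(self):
        # a = 207 with ROR CI (33.46, 44.13): lower bound > 1 and a >= 3
        ests = [self._est("ROR", 38.42, 33.46, 44.13, 207, True)]
        assert evaluate_signal(ests).consensus

    def test_single_report_pair_is_negative(self):
        # a = 1 (< 3) with CI straddling 1
        ests = [self._est("ROR", 0.47, 0.07, 3.34, 1, False)]
        assert not evaluate_signal(ests).consensus

    def test_zero_count_never_signals(self):
        ests = [self._est("IC", 5.0, 4.0, 6.0, 0, True)]
        assert not evaluate_signal(ests).consensus

    def test_consensus_is_or_of_flags(self):
        ests = [
            self._est("ROR", 1.2, 0.9, 1.5, 50, False),
            self._est("IC", 0.5, 0.1, 0.9, 50, True),
        ]
        decision = evaluate_signal(ests)
        assert decision.consensus
        assert decision.flags == {"ROR": False, "IC": True}


class TestMgps:
    def test_marginal_likelihood_matches_quadrature(self):
        """Closed-form NB mixture equals numeric integration of the
        Poisson-gamma mixture on five hand-built tables."""
        prior = MgpsPrior(0.7, 0.4, 3.0, 2.0, 0.35)
        tables = [
            ContingencyTable(5, 10, 20, 1000),
            ContingencyTable(0, 3, 7, 300),
            ContingencyTable(12, 2, 30, 500),
            ContingencyTable(1, 1, 1, 1),
            ContingencyTable(40, 100, 60, 4000),
        ]
        for table in tables:
            lm = float(
                mixture_log_marginal(
                    np.array([table.a]), np.array([table.expected]), prior
                )[0]
            )
            def integrand(lam):
                return sps.poisson.pmf(table.a, lam * table.expected) * (
                    prior.w * sps.gamma.pdf(lam, prior.alpha1, scale=1 / prior.beta1)
                    + (1 - prior.w)
                    * sps.gamma.pdf(lam, prior.alpha2, scale=1 / prior.beta2)
                )
            quad, _ = integrate.quad(integrand, 0, np.inf, limit=200)
            assert lm == pytest.approx(math.log(quad), abs=1e-6)

    def test_single_gamma_parameter_recovery(self):
        """5,000 pairs simulated from Gamma(2, 2): recovered within 15%."""
        rng = np.random.default_rng(2024)
        e = rng.uniform(0.5, 50, 5000)
        lam = rng.gamma(2.0, 1 / 2.0, 5000)
        a = rng.poisson(lam * e)
        n_grand = 10_000_000
        tables = [
            contingency_from_totals(int(ai), 1000, int(round(ei * n_grand / 1000)), n_grand)
            for ai, ei in zip(a, e)
        ]
        prior = fit_mgps_prior(tables, single_component=True)
        assert prior.alpha1 == pytest.approx(2.0, rel=0.15)
        assert prior.beta1 == pytest.approx(2.0, rel=0.15)

    def test_null_data_concentrates_prior_at_one(self):
        """a_i = round(E_i) with large counts: prior mass piles up at
        lambda = 1 (mixture mean near 1, dominant component mean near 1)."""
        e = np.linspace(50, 500, 300)
        tables = [
            contingency_from_totals(int(round(ei)), 2000, int(round(ei * 5000)), 10_000_000)
            for ei in e
        ]
        prior = fit_mgps_prior(tables)
        mix_mean = prior.w * prior.alpha1 / prior.beta1 + (1 - prior.w) * prior.alpha2 / prior.beta2
        assert mix_mean == pytest.approx(1.0, abs=0.05)
        dominant = (
            prior.alpha1 / prior.beta1 if prior.w >= 0.5 else prior.alpha2 / prior.beta2
        )
        assert dominant == pytest.approx(1.0, abs=0.1)


class TestEbgm:
    def test_digamma_closed_form_for_single_gamma_prior(self):
        """With both components Gamma(2, 2), the posterior is Gamma(2+a, 2+E)
        and the geometric mean is exp(psi(2+a) - ln(2+E))."""
        prior = MgpsPrior(2.0, 2.0, 2.0, 2.0, 0.5)
        table = ContingencyTable(10, 90, 100, 9_900)
        est = ebgm_estimate(table, prior)
        closed = math.exp(special.digamma(12.0) - math.log(2.0 + table.expected))
        assert est.point == pytest.approx(closed, abs=1e-8)

    def test_degenerate_prior_pins_estimate_near_one(self):
        prior = MgpsPrior(4000.0, 4000.0, 4000.0, 4000.0, 0.5)
        for table in (ContingencyTable(10, 90, 100, 9_900), ContingencyTable(50, 5, 5, 50)):
            est = ebgm_estimate(table, prior)
            assert est.point == pytest.approx(1.0, abs=0.05)

    def test_eb05_below_point_below_eb95(self):
        prior = MgpsPrior(0.7, 0.4, 3.0, 2.0, 0.35)
        for table in random_tables(50, seed=21):
            est = ebgm_estimate(table, prior)
            assert est.interval_low < est.point < est.interval_high

    def test_quantiles_match_mixture_cdf(self):
        from faersig.stats import _posterior_mixture, _mixture_gamma_cdf

        prior = MgpsPrior(0.7, 0.4, 3.0, 2.0, 0.35)
        table = ContingencyTable(12, 40, 30, 800)
        est = ebgm_estimate(table, prior)
        q, shapes, rates = _posterior_mixture(table, prior)
        assert _mixture_gamma_cdf(est.interval_low, q, shapes, rates) == pytest.approx(0.05, abs=1e-8)
        assert _mixture_gamma_cdf(est.interval_high, q, shapes, rates) == pytest.approx(0.95, abs=1e-8)

    def test_shrinkage_ordering_and_consistency(self):
        """For a/E > 1: EBGM <= a/E; scaling all counts up at fixed ratio
        moves EBGM toward a/E."""
        prior = MgpsPrior(0.5, 0.5, 2.0, 2.0, 0.4)
        base = ContingencyTable(20, 80, 100, 9_800)
        ratio = base.a / base.expected
        small = ebgm_estimate(base, prior)
        assert small.point <= ratio
        big = ebgm_estimate(
            ContingencyTable(2000, 8000, 10_000, 980_000), prior
        )
        big_ratio = 2000 / ContingencyTable(2000, 8000, 10_000, 980_000).expected
        assert abs(big.point - big_ratio) < abs(small.point - ratio)
        assert big.point == pytest.approx(big_ratio, rel=0.02)


class TestPlantedRecovery:
    def test_planted_rate_ratio_recovered_within_ci(self):
        """ROR CI covers a planted rate ratio of 15 in >= 90 of 100 runs at
        n = 200,000 reports."""
        rng = np.random.default_rng(314)
        covered = 0
        for _ in range(100):
            # rare event (5e-4) so the odds ratio tracks the planted rate ratio
            table = simulate_pair_table(200_000, 0.02, 0.0005, 15.0, rng)
            est = ror_estimate(table)
            if est.defined and est.interval_low <= 15.0 <= est.interval_high:
                covered += 1
        assert covered >= 90
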