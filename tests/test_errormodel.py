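"""Error-PDF fitting, the R-factor, and error propagation/correction."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from foldscore.errormodel import (
    ALL,
    NONPOLAR,
    POLAR,
    ContactCounts,
    DeviationRecord,
    ErrorPDF,
    MethodErrorTable,
    correct_energy,
    fit_error_pdf,
    propagate_random,
    propagate_systematic,
    r_factor,
    read_deviation_database,
    write_deviation_database,
)
from foldscore.exceptions import (
    InsufficientDataError,
    TableLookupError,
    ValidationError,
)
from foldscore.simulate import generate_deviation_samples


def records_from_deviations(devs, cls=POLAR):
    return [
        DeviationRecord(f"f{i}", cls, e_approx=-5.0 + d, e_ref=-5.0)
        for i, d in enumerate(devs)
    ]


def table_of(nonpolar=None, polar=None, method="toy"):
    pdfs = {}
    if nonpolar is not None:
        pdfs[NONPOLAR] = ErrorPDF(method, NONPOLAR, *nonpolar)
    if polar is not None:
        pdfs[POLAR] = ErrorPDF(method, POLAR, *polar)
    return MethodErrorTable(method=method, pdfs=pdfs)


class TestDeviationRecord:
    def test_deviation_computed_when_absent(self):
        r = DeviationRecord("f", POLAR, e_approx=-4.0, e_ref=-5.0)
        assert r.deviation == pytest.approx(1.0)

    def test_inconsistent_stored_deviation_rejected(self):
        with pytest.raises(ValidationError):
            DeviationRecord("f", POLAR, e_approx=-4.0, e_ref=-5.0, deviation=0.5)

    def test_unknown_class_rejected(self):
        with pytest.raises(ValidationError):
            DeviationRecord("f", "aromatic", e_approx=0.0, e_ref=-1.0)

    def test_database_round_trip(self, tmp_path):
        records = records_from_deviations([0.5, -0.3, 1.2])
        path = tmp_path / "db.csv"
        write_deviation_database(records, path)
        back = read_deviation_database(path)
        assert back == records


class TestFitErrorPdf:
    def test_all_zero_deviations(self):
        pdf = fit_error_pdf(records_from_deviations([0.0, 0.0, 0.0]), POLAR)
        assert pdf.mu == 0.0 and pdf.sigma2 == 0.0 and pdf.n_samples == 3

    def test_hand_computed_mean_and_unbiased_variance(self):
        pdf = fit_error_pdf(records_from_deviations([1.0, 2.0, 3.0]), POLAR)
        assert pdf.mu == pytest.approx(2.0)
        assert pdf.sigma2 == pytest.approx(1.0)  # n-1 denominator

    def test_all_class_pools_every_record(self):
        recs = records_from_deviations([1.0, 3.0], POLAR) + records_from_deviations(
            [2.0], NONPOLAR
        )
        pdf = fit_error_pdf(recs, ALL)
        assert pdf.mu == pytest.approx(2.0) and pdf.n_samples == 3

    def test_insufficient_data(self):
        with pytest.raises(InsufficientDataError):
            fit_error_pdf(records_from_deviations([1.0]), POLAR)
        with pytest.raises(InsufficientDataError):
            fit_error_pdf(records_from_deviations([1.0, 2.0], NONPOLAR), POLAR)

    def test_invalid_class_label(self):
        with pytest.raises(ValidationError):
            fit_error_pdf(records_from_deviations([1.0, 2.0]), "")

    def test_large_sample_recovers_generating_parameters(self):
        recs = generate_deviation_samples(0.5, 0.04, n=100_000, seed=42)
        pdf = fit_error_pdf(recs, POLAR)
        assert pdf.mu == pytest.approx(0.5, abs=0.01)
        assert pdf.sigma2 == pytest.approx(0.04, abs=0.005)


class TestRFactor:
    def test_perfect_method_scores_zero(self):
        recs = [DeviationRecord("f", POLAR, -5.0, -5.0)]
        assert r_factor(recs) == 0.0

    def test_hand_computed_example(self):
        recs = [
            DeviationRecord("a", POLAR, e_approx=-4.0, e_ref=-5.0),
            DeviationRecord("b", POLAR, e_approx=-12.0, e_ref=-10.0),
        ]
        assert r_factor(recs) == pytest.approx((1 + 2) / 15)

    def test_doubling_deviations_doubles_r_factor(self):
        base = [
            DeviationRecord("a", POLAR, e_approx=-4.0, e_ref=-5.0),
            DeviationRecord("b", POLAR, e_approx=-12.0, e_ref=-10.0),
        ]
        doubled = [
            DeviationRecord(r.fragment_id, r.interaction_class,
                            r.e_ref + 2 * r.deviation, r.e_ref)
            for r in base
        ]
        assert r_factor(doubled) == pytest.approx(2 * r_factor(base))

    def test_zero_references_guarded(self):
        with pytest.raises(ValidationError):
            r_factor([DeviationRecord("a", POLAR, 1.0, 0.0)])
        with pytest.raises(ValidationError):
            r_factor([])


class TestPropagation:
    """Systematic errors sum; random errors add in quadrature."""

    UBQ = ContactCounts.of(nonpolar=42, polar=50)

    def test_hundred_contacts_at_sigma_one(self):
        # 100 chemically accurate (1 kcal/mol) contacts -> 10 kcal/mol bar
        t = table_of(polar=(0.0, 1.0))
        assert propagate_random(ContactCounts.of(polar=100), t) == pytest.approx(10.0)

    def test_hundred_sources_at_tenth_kcal(self):
        # the 0.1 kcal/mol-per-amino-acid accuracy target -> 1 kcal/mol bar
        t = table_of(polar=(0.0, 0.01))
        assert propagate_random(ContactCounts.of(polar=100), t) == pytest.approx(1.0)

    def test_zero_counts_give_zero_errors(self):
        t = table_of(nonpolar=(1.0, 1.0), polar=(2.0, 2.0))
        zero = ContactCounts.of()
        assert propagate_systematic(zero, t) == 0.0
        assert propagate_random(zero, t) == 0.0

    def test_missing_class_is_loud(self):
        t = table_of(nonpolar=(0.1, 0.2))
        with pytest.raises(TableLookupError, match="polar"):
            propagate_systematic(ContactCounts.of(polar=5), t)
        with pytest.raises(TableLookupError, match="polar"):
            propagate_random(ContactCounts.of(polar=5), t)

    def test_monte_carlo_oracle(self):
        """Per-contact simulation reproduces both propagation laws."""
        rng = np.random.default_rng(7)
        t = table_of(nonpolar=(-0.3, 0.4), polar=(1.1, 2.5))
        counts = ContactCounts.of(nonpolar=23, polar=31)
        reps = 100_000
        totals = np.zeros(reps)
        for cls, n in counts.items():
            pdf = t.get(cls)
            totals += rng.normal(pdf.mu, pdf.sigma, size=(reps, n)).sum(axis=1)
        sys_err = propagate_systematic(counts, t)
        rand_err = propagate_random(counts, t)
        assert abs(totals.mean() - sys_err) <= 3 * rand_err / math.sqrt(reps)
        assert totals.std(ddof=1) == pytest.approx(rand_err, rel=0.02)

    @given(
        n1=st.integers(0, 200), n2=st.integers(0, 200),
        p1=st.integers(0, 200), p2=st.integers(0, 200),
    )
    @settings(deadline=None, max_examples=50)
    def test_additivity_over_disjoint_union(self, n1, n2, p1, p2):
        t = table_of(nonpolar=(0.37, 0.8), polar=(-1.2, 2.1))
        a = ContactCounts.of(nonpolar=n1, polar=p1)
        b = ContactCounts.of(nonpolar=n2, polar=p2)
        merged = a + b
        assert propagate_systematic(merged, t) == pytest.approx(
            propagate_systematic(a, t) + propagate_systematic(b, t)
        )
        assert propagate_random(merged, t) == pytest.approx(
            math.hypot(propagate_random(a, t), propagate_random(b, t))
        )

    @given(k=st.integers(1, 50))
    @settings(deadline=None, max_examples=30)
    def test_scale_covariance(self, k):
        t = table_of(nonpolar=(0.37, 0.8), polar=(-1.2, 2.1))
        c = ContactCounts.of(nonpolar=7, polar=11)
        assert propagate_systematic(c.scaled(k), t) == pytest.approx(
            k * propagate_systematic(c, t)
        )
        assert propagate_random(c.scaled(k), t) == pytest.approx(
            math.sqrt(k) * propagate_random(c, t)
        )

    def test_fit_then_propagate_unit_counts_reproduces_parameters(self):
        recs = records_from_deviations([0.2, 0.8, 1.4], POLAR)
        pdf = fit_error_pdf(recs, POLAR)
        t = MethodErrorTable(method="fitted", pdfs={POLAR: pdf})
        one = ContactCounts.of(polar=1)
        assert propagate_systematic(one, t) == pytest.approx(pdf.mu)
        assert propagate_random(one, t) == pytest.approx(math.sqrt(pdf.sigma2))

    def test_negative_variance_rejected_at_construction(self):
        with pytest.raises(ValidationError):
            ErrorPDF("m", POLAR, mu=0.0, sigma2=-1.0)


class TestCorrectEnergy:
    def test_zero_counts_identity(self):
        t = table_of(nonpolar=(1.0, 1.0), polar=(1.0, 1.0))
        res = correct_energy(-50.0, ContactCounts.of(), t)
        assert res.e_corrected == -50.0
        assert res.estimate.random == 0.0

    def test_correction_subtracts_systematic(self):
        t = table_of(nonpolar=(0.5, 0.0), polar=(1.0, 0.0))
        res = correct_energy(-100.0, ContactCounts.of(nonpolar=10, polar=10), t)
        assert res.e_corrected == pytest.approx(-115.0)
        assert res.estimate.systematic == pytest.approx(15.0)

    def test_single_application_not_idempotent(self):
        t = table_of(polar=(1.0, 0.0))
        c = ContactCounts.of(polar=10)
        once = correct_energy(-100.0, c, t)
        twice = correct_energy(once.e_corrected, c, t)
        assert twice.e_corrected == pytest.approx(once.e_corrected - 10.0)

    def test_reproducible_from_counts_and_table(self):
        t = table_of(nonpolar=(0.3, 0.7), polar=(0.9, 1.3))
        c = ContactCounts.of(nonpolar=4, polar=6)
        r1 = correct_energy(-80.0, c, t)
        r2 = correct_energy(-80.0, c, t)
        assert r1 == r2
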