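"""Case matching, exposure classification, 2x2 construction, ROR/CI/chi-square."""

import math

import numpy as np
import pytest

from conftest import make_report
from oipnkit import (
    DEFAULT_CASE,
    CaseDefinition,
    ContingencyTable,
    DegenerateTableError,
    ExposureDefinition,
    Role,
    analyze_panel,
    build_table,
    chi_square_test,
    classify_exposure,
    compute_ror,
    compute_wald_ci,
    default_ppi_panel,
    match_case,
)


class TestCaseAndExposure:
    @pytest.mark.parametrize(
        "reactions,expected",
        [
            ({"Peripheral sensory neuropathy"}, True),
            ({"Peripheral neuropathy"}, True),
            ({"PERIPHERAL NEUROPATHY "}, True),
            ({"peripheral sensorimotor neuropathy"}, True),
            ({"Nausea"}, False),
            (set(), False),
            ({"Neuropathy"}, False),  # exact term match, not substring
        ],
    )
    def test_match_case_default_definition(self, reactions, expected):
        rep = make_report("R1", reactions=reactions)
        assert match_case(rep, DEFAULT_CASE) is expected

    def test_case_terms_must_be_unique_after_folding(self):
        with pytest.raises(ValueError):
            CaseDefinition(name="dup", terms=("Nausea", " NAUSEA "))

    def test_classify_exposure_roles(self):
        exp_conc = ExposureDefinition("omeprazole", ("OMEPRAZOLE",), frozenset({Role.CONCOMITANT}))
        rep = make_report("R1", drugs=[("OMEPRAZOLE", Role.SUSPECT)])
        assert not classify_exposure(rep, exp_conc)
        assert classify_exposure(rep, ExposureDefinition("omeprazole", ("OMEPRAZOLE",)))

    def test_anchor_only_report_unexposed(self, omeprazole_exposure):
        assert not classify_exposure(make_report("R1"), omeprazole_exposure)

    def test_two_member_ppis_still_one_exposure(self):
        any_ppi = ExposureDefinition("any PPI", ("OMEPRAZOLE", "PANTOPRAZOLE"))
        rep = make_report("R1", drugs=["OMEPRAZOLE", "PANTOPRAZOLE"])
        assert classify_exposure(rep, any_ppi)


class TestBuildTable:
    def test_exhaustive_four_report_cohort(self, omeprazole_exposure):
        case_term = "Peripheral neuropathy"
        reports = [
            make_report("a", drugs=["OMEPRAZOLE"], reactions=[case_term]),
            make_report("b", drugs=["OMEPRAZOLE"]),
            make_report("c", reactions=[case_term]),
            make_report("d"),
        ]
        table = build_table(reports, DEFAULT_CASE, omeprazole_exposure)
        assert table.cells == (1, 1, 1, 1)

    def test_no_exposed_reports(self, omeprazole_exposure):
        reports = [make_report("a", reactions=["Nausea"]), make_report("b")]
        table = build_table(reports, DEFAULT_CASE, omeprazole_exposure)
        assert (table.n11, table.n12) == (0, 0)
        assert table.total == 2

    def test_empty_cohort_raises(self, omeprazole_exposure):
        with pytest.raises(ValueError):
            build_table([], DEFAULT_CASE, omeprazole_exposure)

    def test_partitions_cohort(self, small_cohort, omeprazole_exposure):
        _, reports = small_cohort
        table = build_table(reports, DEFAULT_CASE, omeprazole_exposure)
        assert table.total == len(reports)

    def test_matches_naive_double_loop(self, small_cohort, omeprazole_exposure):
        """Independent brute-force re-count over every (report, cell)."""
        _, reports = small_cohort
        counts = {"n11": 0, "n12": 0, "n21": 0, "n22": 0}
        folded = {t.casefold() for t in DEFAULT_CASE.terms}
        for rep in reports:
            exposed = False
            for name, role in rep.drugs:
                if name in omeprazole_exposure.members and role in omeprazole_exposure.roles_counted:
                    exposed = True
            case = False
            for pt in rep.reactions:
                if " ".join(pt.split()).casefold() in folded:
                    case = True
            key = f"n{1 if exposed else 2}{1 if case else 2}"
            counts[key] += 1
        table = build_table(reports, DEFAULT_CASE, omeprazole_exposure)
        assert table.cells == (counts["n11"], counts["n12"], counts["n21"], counts["n22"])


class TestRor:
    def test_null_table(self):
        assert compute_ror(ContingencyTable(10, 10, 10, 10)) == 1.0

    def test_reconstructed_marginal_table(self):
        assert compute_ror(ContingencyTable(40, 1267, 3113, 44932)) == pytest.approx(0.4557, abs=5e-5)

    def test_cross_product_full_precision(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            a, b, c, d = (int(x) for x in rng.integers(1, 1000, size=4))
            assert compute_ror(ContingencyTable(a, b, c, d)) == (a * d) / (b * c)

    def test_label_swaps_invert(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            a, b, c, d = (int(x) for x in rng.integers(1, 500, size=4))
            ror = compute_ror(ContingencyTable(a, b, c, d))
            assert compute_ror(ContingencyTable(c, d, a, b)) == pytest.approx(1 / ror, rel=1e-12)
            assert compute_ror(ContingencyTable(b, a, d, c)) == pytest.approx(1 / ror, rel=1e-12)

    def test_zero_cell_requires_haldane(self):
        table = ContingencyTable(0, 10, 5, 20)
        with pytest.raises(DegenerateTableError):
            compute_ror(table)
        assert compute_ror(table, haldane=True) == pytest.approx((0.5 * 20.5) / (10.5 * 5.5))


class TestWaldCi:
    def test_hand_computed_null_table(self):
        lo, hi = compute_wald_ci(ContingencyTable(10, 10, 10, 10))
        # exp(+/- 1.96 * sqrt(0.4)) by hand
        assert (lo, hi) == (pytest.approx(0.2895, abs=5e-5), pytest.approx(3.4543, abs=5e-5))

    def test_log_symmetry_identity(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            a, b, c, d = (int(x) for x in rng.integers(1, 800, size=4))
            t = ContingencyTable(a, b, c, d)
            lo, hi = compute_wald_ci(t)
            assert lo * hi == pytest.approx(compute_ror(t) ** 2, rel=1e-10)

    def test_interval_contains_ror(self):
        rng = np.random.default_rng(12)
        for _ in range(50):
            a, b, c, d = (int(x) for x in rng.integers(1, 300, size=4))
            t = ContingencyTable(a, b, c, d)
            lo, hi = compute_wald_ci(t)
            assert lo <= compute_ror(t) <= hi

    def test_interval_shrinks_under_integer_scaling(self):
        t = ContingencyTable(8, 15, 40, 200)
        lo1, hi1 = compute_wald_ci(t)
        for k in (2, 3, 5):
            tk = ContingencyTable(8 * k, 15 * k, 40 * k, 200 * k)
            lok, hik = compute_wald_ci(tk)
            assert lok > lo1 and hik < hi1
            lo1, hi1 = lok, hik

    def test_z_is_printed_constant_at_95(self):
        t = ContingencyTable(10, 10, 10, 10)
        lo, _ = compute_wald_ci(t, level=0.95)
        assert lo == pytest.approx(math.exp(-1.96 * math.sqrt(0.4)), rel=1e-14)

    def test_other_levels_use_exact_quantile(self):
        t = ContingencyTable(10, 10, 10, 10)
        lo90, hi90 = compute_wald_ci(t, level=0.90)
        lo95, hi95 = compute_wald_ci(t, level=0.95)
        assert lo95 < lo90 < 1 < hi90 < hi95

    def test_zero_cell_requires_haldane(self):
        with pytest.raises(DegenerateTableError):
            compute_wald_ci(ContingencyTable(5, 0, 5, 5))
        lo, hi = compute_wald_ci(ContingencyTable(5, 0, 5, 5), haldane=True)
        assert 0 < lo < hi


class TestChiSquare:
    def test_perfect_independence(self):
        stat, p, applied = chi_square_test(ContingencyTable(10, 10, 10, 10))
        assert stat == 0.0 and p == 1.0 and not applied

    def test_uncorrected_closed_form(self):
        rng = np.random.default_rng(5)
        for _ in range(300):
            a, b, c, d = (int(x) for x in rng.integers(5, 200, size=4))
            t = ContingencyTable(a, b, c, d)
            stat, _, applied = chi_square_test(t)
            assert not applied
            n = t.total
            closed = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
            assert stat == pytest.approx(closed, rel=1e-12)

    def test_yates_closed_form(self):
        t = ContingencyTable(2, 8, 8, 2)
        stat, _, applied = chi_square_test(t)
        assert applied
        n = 20
        closed = n * (abs(2 * 2 - 8 * 8) - n / 2) ** 2 / (10 * 10 * 10 * 10)
        assert stat == pytest.approx(closed, rel=1e-12)

    @pytest.mark.parametrize(
        "cells,rule,expect_applied",
        [
            ((4, 100, 100, 100), "observed", True),
            ((5, 100, 100, 100), "observed", False),
            ((6, 6, 6, 200), "expected", True),  # min expected ~2.5
            ((50, 50, 50, 50), "expected", False),
            ((50, 50, 50, 50), "always", True),
            ((2, 8, 8, 2), "never", False),
        ],
    )
    def test_yates_trigger_rules(self, cells, rule, expect_applied):
        _, _, applied = chi_square_test(ContingencyTable(*cells), yates=rule)
        assert applied is expect_applied

    def test_zero_marginal_raises(self):
        with pytest.raises(DegenerateTableError):
            chi_square_test(ContingencyTable(0, 0, 10, 10))


class TestAnalyzePanel:
    def test_empty_exposure_list(self, small_cohort):
        _, reports = small_cohort
        assert analyze_panel(reports, DEFAULT_CASE, []) == []

    def test_class_row_counts_report_once(self):
        case_term = "Peripheral neuropathy"
        reports = [
            make_report("a", drugs=["OMEPRAZOLE", "PANTOPRAZOLE"], reactions=[case_term]),
            make_report("b"),
            make_report("c", reactions=[case_term]),
            make_report("d", drugs=["OMEPRAZOLE"]),
        ]
        panel = default_ppi_panel()
        results = {r.exposure: r for r in analyze_panel(reports, DEFAULT_CASE, panel)}
        assert results["any PPI"].table.n11 == 1
        assert results["any PPI"].table.n12 == 1

    def test_degenerate_row_marked_not_fatal(self, small_cohort):
        _, reports = small_cohort
        ghost = ExposureDefinition("ghost", ("NEVERUSEDDRUG",))
        omz = ExposureDefinition("omeprazole", ("OMEPRAZOLE",))
        results = analyze_panel(reports, DEFAULT_CASE, [ghost, omz])
        assert results[0].error is not None and results[0].ror is None
        assert results[1].error is None and results[1].ror is not None

    def test_planted_multipliers_recovered(self, small_cohort):
        """Per-drug RORs sit inside their own 95% CIs around the planted values."""
        cfg, reports = small_cohort
        exposures = [
            ExposureDefinition("omeprazole", ("OMEPRAZOLE",)),
            ExposureDefinition("pantoprazole", ("PANTOPRAZOLE",)),
        ]
        results = {r.exposure: r for r in analyze_panel(reports, DEFAULT_CASE, exposures)}
        for name, planted in [("omeprazole", 0.456), ("pantoprazole", 0.54)]:
            r = results[name]
            assert r.ci_low <= r.ror <= r.ci_high
            # 2,000 reports: wide CIs, but the planted value must be covered
            assert r.ci_low <= planted <= r.ci_high
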