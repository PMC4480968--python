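"""Odds ratios, chi-square / Fisher tests, genetic models, HWE, Bonferroni."""

import math
from itertools import product

import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from stonekit import (
    GenotypeCounts,
    TwoByTwo,
    bonferroni,
    chi2_test_2x2,
    fisher_exact_2x2,
    hwe_chi2,
    model_contrasts,
    odds_ratio_woolf,
)
from stonekit.association import association_sweep, expected_counts
from stonekit.genotype_data import STUDY_SNPS, study_count_fixture


# Every crude OR / 95% CI printed for the study cohort that is arithmetically
# consistent with the genotype count tables.  Excluded as inconsistent with
# the counts: rs219777 allelic (printed 1.90, computed 1.71), rs2228570 and
# rs731236 allelic (printed 1.25 / 0.94, computed 1.19 / 1.11), and the
# rs731236 crude genotype ORs (printed 1.66/3.28/1.73, which duplicate
# rs219777's values; computed 1.81/1.15/1.46).
GOLDEN = [
    # snp, model, contrast fragment, OR, CI low, CI high
    ("rs1801725", "allelic", "T vs G", 2.54, 1.69, 3.81),
    ("rs1042636", "allelic", "G vs A", 2.21, 1.58, 3.07),
    ("rs1801726", "allelic", "G vs C", 1.10, 0.46, 2.63),
    ("rs219778", "allelic", "C vs T", 3.01, 1.82, 4.96),
    ("rs219780", "allelic", "A vs G", 2.19, 1.40, 3.43),
    ("rs1801725", "genotypic", "GT vs GG", 3.10, 1.96, 4.88),
    ("rs1801725", "genotypic", "TT vs GG", 2.79, 0.25, 31.17),
    ("rs1042636", "genotypic", "AG vs AA", 2.17, 1.44, 3.27),
    ("rs1042636", "genotypic", "GG vs AA", 22.67, 2.94, 174.82),
    ("rs1801726", "genotypic", "CG vs CC", 1.11, 0.46, 2.67),
    ("rs2228570", "genotypic", "CT vs CC", 1.61, 1.07, 2.41),
    ("rs2228570", "genotypic", "TT vs CC", 0.73, 0.28, 1.95),
    ("rs219777", "genotypic", "CT vs CC", 1.66, 0.96, 2.88),
    ("rs219777", "genotypic", "TT vs CC", 3.28, 0.34, 31.89),
    ("rs219778", "genotypic", "TC vs TT", 3.37, 1.95, 5.82),
    ("rs219778", "genotypic", "CC vs TT", 3.79, 0.39, 36.80),
    ("rs219780", "genotypic", "GA vs GG", 2.35, 1.43, 3.85),
    ("rs219780", "genotypic", "AA vs GG", 3.65, 0.38, 35.46),
    ("rs1801725", "dominant", "GT+TT vs GG", 3.09, 1.97, 4.85),
    ("rs2228570", "dominant", "CT+TT vs CC", 1.50, 1.01, 2.24),
    ("rs219777", "dominant", "CT+TT vs CC", 1.73, 1.01, 2.95),
    ("rs219778", "dominant", "TC+CC vs TT", 3.39, 1.98, 5.79),
    ("rs219780", "dominant", "GA+AA vs GG", 2.39, 1.47, 3.89),
    ("rs1042636", "recessive", "GG vs AA+AG", 16.14, 2.11, 123.37),
]


@pytest.fixture(scope="module")
def sweep():
    return {
        (r.snp_id, r.model, r.contrast): r
        for r in association_sweep(study_count_fixture(), snps=STUDY_SNPS)
    }


class TestGoldenReproduction:
    @pytest.mark.parametrize("snp,model,contrast,orr,lo,hi", GOLDEN)
    def test_printed_or_and_ci_reproduce_to_two_decimals(
        self, sweep, snp, model, contrast, orr, lo, hi
    ):
        r = sweep[(snp, model, contrast)]
        assert round(r.or_estimate, 2) == orr
        assert round(r.ci_low, 2) == lo
        assert round(r.ci_high, 2) == hi

    def test_homalt_contrast_omitted_when_no_carriers(self, sweep):
        # no homozygous-variant subject exists anywhere for rs1801726,
        # matching the blank table cell
        assert ("rs1801726", "genotypic", "GG vs CC") not in sweep
        assert ("rs1801726", "recessive", "GG vs CC+CG") not in sweep

    def test_allelic_significance_calls(self, sweep):
        assert sweep[("rs1801725", "allelic", "T vs G")].p_raw < 0.001
        assert sweep[("rs219780", "allelic", "A vs G")].p_raw <= 0.001
        assert sweep[("rs1801726", "allelic", "G vs C")].p_raw > 0.5

    def test_bonferroni_kills_vdr_dominant_signals(self, sweep):
        # nominally significant dominant contrasts at the two VDR SNPs do
        # not survive correction for the eight SNPs tested
        r = sweep[("rs2228570", "dominant", "CT+TT vs CC")]
        assert r.p_raw < 0.05 < r.p_bonferroni
        r = sweep[("rs731236", "dominant", "CT+TT vs CC")]
        assert r.p_bonferroni > 0.05


class TestWoolfOddsRatio:
    def test_reported_allelic_or_example(self):
        orr, lo, hi = odds_ratio_woolf(TwoByTwo(86, 314, 39, 361))
        assert (round(orr, 2), round(lo, 2), round(hi, 2)) == (2.54, 1.69, 3.81)

    def test_balanced_table_is_null_and_log_symmetric(self):
        orr, lo, hi = odds_ratio_woolf(TwoByTwo(10, 10, 10, 10))
        assert orr == pytest.approx(1.0)
        assert lo * hi == pytest.approx(1.0)  # symmetric about 1 on log scale

    def test_haldane_correction_with_single_zero_cell(self):
        orr, _, _ = odds_ratio_woolf(TwoByTwo(0, 10, 5, 5))
        assert orr == pytest.approx((0.5 * 5.5) / (10.5 * 5.5), rel=1e-12)

    def test_empty_margin_raises(self):
        with pytest.raises(ValueError):
            odds_ratio_woolf(TwoByTwo(0, 0, 5, 5))

    @given(st.tuples(*[st.integers(1, 200)] * 4))
    @settings(max_examples=100, deadline=None)
    def test_or_antisymmetry_and_ci_log_symmetry(self, cells):
        a, b, c, d = cells
        o1, l1, h1 = odds_ratio_woolf(TwoByTwo(a, b, c, d))
        o2, _, _ = odds_ratio_woolf(TwoByTwo(b, a, d, c))
        assert o1 * o2 == pytest.approx(1.0, rel=1e-9)
        # CI symmetric about the estimate on the log scale
        assert math.log(h1) - math.log(o1) == pytest.approx(
            math.log(o1) - math.log(l1), rel=1e-9
        )


class TestChi2:
    def test_allelic_example_value(self):
        chi2, p = chi2_test_2x2(TwoByTwo(86, 314, 39, 361))
        assert chi2 == pytest.approx(20.94, abs=0.01)
        assert p < 0.001

    def test_no_association_gives_zero(self):
        chi2, p = chi2_test_2x2(TwoByTwo(10, 10, 10, 10))
        assert chi2 == 0.0
        assert p == 1.0

    @given(st.tuples(*[st.integers(1, 100)] * 4))
    @settings(max_examples=100, deadline=None)
    def test_matches_closed_form(self, cells):
        a, b, c, d = cells
        chi2, _ = chi2_test_2x2(TwoByTwo(a, b, c, d))
        n = a + b + c + d
        closed = n * (a * d - b * c) ** 2 / (
            (a + b) * (c + d) * (a + c) * (b + d)
        )
        assert chi2 == pytest.approx(closed, abs=1e-9)


def _fisher_enumeration(a, b, c, d):
    """Independent oracle: enumerate all tables with the observed margins."""
    r1, c1 = a + b, a + c
    n = a + b + c + d
    p_obs = stats.hypergeom.pmf(a, n, c1, r1)
    total = 0.0
    for x in range(max(0, r1 + c1 - n), min(r1, c1) + 1):
        px = stats.hypergeom.pmf(x, n, c1, r1)
        if px <= p_obs * (1 + 1e-9):
            total += px
    return min(total, 1.0)


class TestFisherExact:
    def test_most_probable_table_has_p_one(self):
        assert fisher_exact_2x2(TwoByTwo(5, 5, 5, 5)) == pytest.approx(1.0)

    @given(st.tuples(*[st.integers(0, 10)] * 4))
    @settings(max_examples=200, deadline=None)
    def test_agrees_with_full_enumeration(self, cells):
        a, b, c, d = cells
        if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
            return  # degenerate margins: p = 1 trivially either way
        p = fisher_exact_2x2(TwoByTwo(a, b, c, d))
        assert p == pytest.approx(_fisher_enumeration(a, b, c, d), abs=1e-9)


class TestModelContrasts:
    def test_fisher_triggered_when_expected_cell_below_five(self):
        case = GenotypeCounts("rs1042636", "case", 86, 99, 15)
        control = GenotypeCounts("rs1042636", "control", 130, 69, 1)
        results = model_contrasts(case, control, "genotypic")
        by_contrast = {r.contrast: r for r in results}
        hom = by_contrast["homAlt vs homRef"]
        assert min(expected_counts(hom.table)) > 5
        assert hom.test_used == "chi2"
        # the rare rs219777 homozygote contrast routes to Fisher
        case = GenotypeCounts("rs219777", "case", 159, 38, 3)
        control = GenotypeCounts("rs219777", "control", 174, 25, 1)
        results = model_contrasts(case, control, "genotypic")
        hom = {r.contrast: r for r in results}["homAlt vs homRef"]
        assert hom.test_used == "fisher"

    def test_unknown_model_rejected(self):
        case = GenotypeCounts("x", "case", 10, 5, 1)
        with pytest.raises(ValueError):
            model_contrasts(case, case, "additive")


class TestHwe:
    def test_control_rs731236_fails_hwe(self):
        h = hwe_chi2(GenotypeCounts("rs731236", "control", 77, 58, 65))
        assert h.chi2 == pytest.approx(34.93, abs=0.01)
        assert h.p < 0.05
        assert not h.in_hwe

    def test_control_rs1801725_passes_hwe(self):
        h = hwe_chi2(GenotypeCounts("rs1801725", "control", 162, 37, 1))
        assert h.chi2 == pytest.approx(0.52, abs=0.01)
        assert h.in_hwe

    def test_exact_hwe_proportions_give_zero_statistic(self):
        h = hwe_chi2(GenotypeCounts("x", "case", 25, 50, 25))
        assert h.chi2 == pytest.approx(0.0, abs=1e-12)
        assert h.p == pytest.approx(1.0)

    def test_monomorphic_snp_undefined(self):
        with pytest.raises(ValueError, match="monomorphic"):
            hwe_chi2(GenotypeCounts("x", "case", 50, 0, 0))

    @given(st.integers(1, 40), st.integers(0, 40), st.integers(0, 40))
    @settings(max_examples=100, deadline=None)
    def test_zero_iff_counts_equal_expectations(self, h0, h1, h2):
        gc = GenotypeCounts("x", "case", h0, h1, h2)
        n = gc.n_total
        n_ref = 2 * h0 + h1
        if n_ref in (0, 2 * n):
            return
        p = n_ref / (2 * n)
        expected = (n * p * p, 2 * n * p * (1 - p), n * (1 - p) ** 2)
        res = hwe_chi2(gc)
        matches = all(abs(o - e) < 1e-9 for o, e in zip(gc.as_tuple(), expected))
        assert (res.chi2 < 1e-12) == matches


class TestBonferroni:
    def test_scales_and_caps(self):
        assert bonferroni([0.01, 0.3], m=8) == [0.08, 1.0]

    def test_default_m_is_count(self):
        assert bonferroni([0.1, 0.2]) == [0.2, 0.4]

    def test_invalid_m_rejected(self):
        with pytest.raises(ValueError):
            bonferroni([0.5], m=0)

    def test_adjusted_never_below_raw(self):
        ps = [0.001, 0.2, 0.9]
        assert all(pa >= p for pa, p in zip(bonferroni(ps, m=5), ps))
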