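"""Count-based case-control association statistics.

Implements the classical toolkit for a candidate-gene study: 2x2 odds
ratios with Woolf (log-normal) confidence intervals, Pearson chi-square
and Fisher exact tests, the standard genetic-model contrasts (allelic,
genotypic, dominant, recessive), chi-square Hardy-Weinberg testing, and
Bonferroni correction.

Contrasts are oriented so that the variant (alt-allele-bearing) category
is the exposure: OR > 1 means the variant increases disease odds.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

from scipy import stats

from .genotype_data import GenotypeCounts, allele_counts

logger = logging.getLogger(__name__)

MODELS = ("allelic", "genotypic", "dominant", "recessive")


@dataclass(frozen=True)
class TwoByTwo:
    """2x2 exposure-by-disease table.

    a = exposed cases, b = unexposed cases,
    c = exposed controls, d = unexposed controls.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for v in (self.a, self.b, self.c, self.d):
            if v < 0:
                raise ValueError("negative cell in 2x2 table")

    @property
    def cells(self) -> tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)

    @property
    def margins(self) -> tuple[int, int, int, int]:
        return (self.a + self.b, self.c + self.d, self.a + self.c, self.b + self.d)


@dataclass
class AssociationResult:
    snp_id: str
    model: str
    contrast: str
    or_estimate: float
    ci_low: float
    ci_high: float
    p_raw: float
    p_bonferroni: float
    test_used: str  # "chi2" or "fisher"
    table: TwoByTwo | None = None


@dataclass
class HweResult:
    snp_id: str
    group: str
    chi2: float
    df: int
    p: float
    in_hwe: bool  # at alpha = 0.05


def odds_ratio_woolf(
    t: TwoByTwo, alpha: float = 0.05
) -> tuple[float, float, float]:
    """Odds ratio ad/(bc) with the Woolf log-normal confidence interval.

    CI = exp(ln OR +/- z * sqrt(1/a + 1/b + 1/c + 1/d)).  At the default
    95% level the conventional critical value 1.96 is used (the value
    standard epidemiology software prints); other levels use the exact
    normal quantile.

    If exactly one cell is zero the Haldane-Anscombe correction (+0.5 to
    every cell) is applied.  A table with an entirely empty margin has no
    defined OR and raises.
    """
    a, b, c, d = t.cells
    if min(t.margins) == 0:
        raise ValueError(f"OR undefined: empty margin in table {t.cells}")
    n_zero = sum(1 for v in t.cells if v == 0)
    if n_zero > 1:
        raise ValueError(f"OR undefined: {n_zero} zero cells in table {t.cells}")
    if n_zero == 1:
        a, b, c, d = (v + 0.5 for v in t.cells)
    orr = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = 1.96 if alpha == 0.05 else float(stats.norm.ppf(1 - alpha / 2))
    return orr, orr * math.exp(-z * se), orr * math.exp(z * se)


def chi2_test_2x2(t: TwoByTwo) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 table, df = 1, no continuity correction."""
    if min(t.margins) == 0:
        raise ValueError(f"chi-square undefined: empty margin in {t.cells}")
    chi2, p, _, _ = stats.chi2_contingency(
        [[t.a, t.b], [t.c, t.d]], correction=False
    )
    return float(chi2), float(p)


def fisher_exact_2x2(t: TwoByTwo) -> float:
    """Two-sided Fisher exact p: total hypergeometric probability of all
    tables (margins fixed) no more probable than the observed one."""
    _, p = stats.fisher_exact([[t.a, t.b], [t.c, t.d]], alternative="two-sided")
    return float(p)


def expected_counts(t: TwoByTwo) -> list[float]:
    """Expected cell counts under independence (the Fisher-trigger rule)."""
    r1, r2, c1, c2 = t.margins
    n = r1 + r2
    return [r1 * c1 / n, r1 * c2 / n, r2 * c1 / n, r2 * c2 / n]


def _choose_test(t: TwoByTwo) -> str:
    """Fisher when any expected cell < 5 (classic rule), else chi-square."""
    return "fisher" if min(expected_counts(t)) < 5 else "chi2"


def _result(
    snp_id: str, model: str, contrast: str, t: TwoByTwo, alpha: float
) -> AssociationResult:
    orr, lo, hi = odds_ratio_woolf(t, alpha=alpha)
    test = _choose_test(t)
    if test == "chi2":
        _, p = chi2_test_2x2(t)
    else:
        p = fisher_exact_2x2(t)
    return AssociationResult(
        snp_id=snp_id, model=model, contrast=contrast,
        or_estimate=orr, ci_low=lo, ci_high=hi,
        p_raw=p, p_bonferroni=p, test_used=test, table=t,
    )


def _genotype_labels(case: GenotypeCounts) -> tuple[str, str, str]:
    # labels only know the genotype class, not the base letters; the display
    # layer substitutes alleles where a SnpDef is at hand
    return ("homRef", "het", "homAlt")


def model_contrasts(
    case: GenotypeCounts,
    control: GenotypeCounts,
    model: str,
    snp=None,
    alpha: float = 0.05,
) -> list[AssociationResult]:
    """Association contrasts for one SNP under one genetic model.

    allelic   — alt vs ref allele counts (one 2x2);
    genotypic — het vs homRef and homAlt vs homRef;
    dominant  — (het + homAlt) vs homRef;
    recessive — homAlt vs (homRef + het).

    The test is Fisher exact whenever any expected cell is below 5, else
    Pearson chi-square.  A contrast whose variant row is empty in both
    groups (e.g. no homozygous-variant subject anywhere) is omitted with a
    logged note, mirroring a blank table cell.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}")
    sid = case.snp_id
    if snp is not None:
        r, a = snp.ref_allele, snp.alt_allele
        g = {"homRef": r + r, "het": r + a, "homAlt": a + a, "ref": r, "alt": a}
    else:
        g = {"homRef": "homRef", "het": "het", "homAlt": "homAlt",
             "ref": "ref", "alt": "alt"}

    results: list[AssociationResult] = []

    def emit(contrast: str, t: TwoByTwo) -> None:
        if t.a + t.c == 0:
            logger.info("%s %s: contrast %r omitted (no variant carriers)",
                        sid, model, contrast)
            return
        results.append(_result(sid, model, contrast, t, alpha))

    if model == "allelic":
        ref_ca, alt_ca = allele_counts(case)
        ref_co, alt_co = allele_counts(control)
        emit(f"{g['alt']} vs {g['ref']}", TwoByTwo(alt_ca, ref_ca, alt_co, ref_co))
    elif model == "genotypic":
        emit(f"{g['het']} vs {g['homRef']}",
             TwoByTwo(case.n_het, case.n_hom_ref, control.n_het, control.n_hom_ref))
        emit(f"{g['homAlt']} vs {g['homRef']}",
             TwoByTwo(case.n_hom_alt, case.n_hom_ref,
                      control.n_hom_alt, control.n_hom_ref))
    elif model == "dominant":
        emit(f"{g['het']}+{g['homAlt']} vs {g['homRef']}",
             TwoByTwo(case.n_het + case.n_hom_alt, case.n_hom_ref,
                      control.n_het + control.n_hom_alt, control.n_hom_ref))
    else:  # recessive
        emit(f"{g['homAlt']} vs {g['homRef']}+{g['het']}",
             TwoByTwo(case.n_hom_alt, case.n_hom_ref + case.n_het,
                      control.n_hom_alt, control.n_hom_ref + control.n_het))
    return results


def hwe_chi2(gc: GenotypeCounts) -> HweResult:
    """Chi-square goodness-of-fit to Hardy-Weinberg proportions, df = 1.

    Expected counts are n p^2, 2 n p q, n q^2 at the observed allele
    frequency.  Undefined (raises) for a monomorphic SNP.
    """
    n = gc.n_total
    if n == 0:
        raise ValueError(f"{gc.snp_id}/{gc.group}: no subjects")
    n_ref, n_alt = allele_counts(gc)
    if n_ref == 0 or n_alt == 0:
        raise ValueError(f"{gc.snp_id}/{gc.group}: monomorphic, HWE undefined")
    p = n_ref / (2 * n)
    q = 1 - p
    expected = (n * p * p, 2 * n * p * q, n * q * q)
    observed = gc.as_tuple()
    chi2 = sum((o - e) ** 2 / e for o, e in zip(observed, expected))
    pval = float(stats.chi2.sf(chi2, 1))
    return HweResult(gc.snp_id, gc.group, chi2, 1, pval, in_hwe=pval >= 0.05)


def bonferroni(p_values: list[float], m: int | None = None) -> list[float]:
    """Bonferroni adjustment: p_adj = min(1, m p); m defaults to len(p_values)."""
    if m is None:
        m = len(p_values)
    if m < 1:
        raise ValueError("number of tests m must be >= 1")
    for p in p_values:
        if not 0 <= p <= 1:
            raise ValueError(f"p-value {p} outside [0, 1]")
    return [min(1.0, m * p) for p in p_values]


def association_sweep(
    fixture: dict[str, tuple[GenotypeCounts, GenotypeCounts]],
    models: tuple[str, ...] = MODELS,
    snps=None,
    bonferroni_m: int | None = None,
) -> list[AssociationResult]:
    """All contrasts for all SNPs, with Bonferroni-adjusted p-values.

    ``bonferroni_m`` defaults to the number of SNPs in the fixture.
    """
    snps_by_id = {s.snp_id: s for s in (snps or [])}
    m = bonferroni_m if bonferroni_m is not None else len(fixture)
    out: list[AssociationResult] = []
    for snp_id, (case, control) in fixture.items():
        for model in models:
            out.extend(
                model_contrasts(case, control, model, snp=snps_by_id.get(snp_id))
            )
    adj = bonferroni([r.p_raw for r in out], m=m)
    for r, pa in zip(out, adj):
        r.p_bonferroni = pa
    return out
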