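"""Quantitative-trait comparisons.

Two-sample tests used for cohort characteristics and genotype-stratified
trait tables: Student's pooled-variance t-test (default; Welch optional),
in both raw-data and summary-statistic (mean, SD, n) form, and the
Mann-Whitney U test for non-parametric variables.

Sign convention: the t statistic is positive when the second group's
mean exceeds the first's (statistic computed as group2 - group1).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .genotype_data import CASE, CONTROL, MISSING, CohortDataset

#: genotype-grouping presets: genotype code -> stratum index (0 or 1)
GROUPINGS: dict[str, dict[int, int]] = {
    "dominant": {0: 0, 1: 1, 2: 1},      # homRef vs carriers
    "recessive": {0: 0, 1: 0, 2: 1},     # non-homAlt vs homAlt
    "het_vs_homref": {0: 0, 1: 1},
}


@dataclass
class TraitComparison:
    trait: str
    group_labels: tuple[str, str]
    n1: int
    n2: int
    mean1: float
    sd1: float
    mean2: float
    sd2: float
    statistic: float
    p: float
    test: str  # student_t, welch_t, mann_whitney


def t_test_summary(
    mean1: float, sd1: float, n1: int,
    mean2: float, sd2: float, n2: int,
    variant: str = "student",
) -> tuple[float, float, float]:
    """Two-sided two-sample t-test from summary statistics.

    Returns (t, df, p) with t computed on mean2 - mean1.  ``variant`` is
    "student" (pooled variance) or "welch".
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 observations per group")
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("standard deviations must be positive")
    res = stats.ttest_ind_from_stats(
        mean2, sd2, n2, mean1, sd1, n1, equal_var=(variant == "student")
    )
    if variant == "student":
        df = float(n1 + n2 - 2)
    else:  # Welch-Satterthwaite
        v1, v2 = sd1**2 / n1, sd2**2 / n2
        df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    return float(res.statistic), df, float(res.pvalue)


def t_test_raw(
    x: Sequence[float], y: Sequence[float], variant: str = "student"
) -> tuple[float, float, float]:
    """Two-sided t-test on raw samples; (t, df, p), t on mean(y) - mean(x)."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need at least 2 observations per group")
    if np.ptp(np.concatenate([x, y])) == 0:
        # constant data: no evidence of difference; scipy returns NaN here
        df = len(x) + len(y) - 2 if variant == "student" else float("nan")
        return 0.0, df, 1.0
    res = stats.ttest_ind(y, x, equal_var=(variant == "student"))
    return float(res.statistic), float(res.df), float(res.pvalue)


def mann_whitney_u(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Exact null distribution for small samples (both n <= 20, no ties),
    normal approximation with tie correction otherwise.
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = "exact" if (len(x) <= 20 and len(y) <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def trait_by_genotype(
    ds: CohortDataset,
    snp_id: str,
    trait: str,
    grouping: str = "dominant",
    within: str = "all",
    test: str = "student_t",
) -> TraitComparison:
    """Compare a quantitative trait between genotype strata of one SNP.

    ``grouping`` is one of the presets in :data:`GROUPINGS`; ``within``
    restricts to cases, controls, or the full cohort.  Subjects missing
    the trait or the genotype are excluded.
    """
    if grouping not in GROUPINGS:
        raise ValueError(f"unknown grouping {grouping!r}")
    if within == "all":
        subjects = ds.subjects
    elif within in (CASE, CONTROL):
        subjects = ds.group(within)
    else:
        raise ValueError(f"unknown 'within' group {within!r}")
    coding = GROUPINGS[grouping]
    strata: tuple[list[float], list[float]] = ([], [])
    for subj in subjects:
        g = subj.genotypes.get(snp_id, MISSING)
        if g == MISSING or g not in coding or trait not in subj.traits:
            continue
        strata[coding[g]].append(subj.traits[trait])
    labels = {
        "dominant": ("homRef", "carrier"),
        "recessive": ("non-homAlt", "homAlt"),
        "het_vs_homref": ("homRef", "het"),
    }[grouping]
    for lab, vals in zip(labels, strata):
        if len(vals) < 2:
            raise ValueError(
                f"{snp_id}/{trait}: stratum {lab!r} has {len(vals)} subjects (< 2)"
            )
    x, y = strata
    if test in ("student_t", "welch_t"):
        variant = "student" if test == "student_t" else "welch"
        stat, _, p = t_test_raw(x, y, variant=variant)
    elif test == "mann_whitney":
        stat, p = mann_whitney_u(x, y)
    else:
        raise ValueError(f"unknown test {test!r}")
    return TraitComparison(
        trait=trait, group_labels=labels,
        n1=len(x), n2=len(y),
        mean1=float(np.mean(x)), sd1=float(np.std(x, ddof=1)),
        mean2=float(np.mean(y)), sd2=float(np.std(y, ddof=1)),
        statistic=stat, p=p, test=test,
    )
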