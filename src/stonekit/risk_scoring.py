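"""Combined-risk-allele and weighted allele-dosage analyses.

Two multi-locus summaries of risk-allele carriage:

* **Combined-carrier contrasts** — subjects are stratified by how many of
  a set of risk alleles they carry (e.g. carriers of both risk alleles at
  two SNPs vs carriers of exactly one vs none) and any two disjoint
  strata are compared in a 2x2 case-control table.

* **Weighted allele-dosage score** — each subject's risk-allele counts
  R_i in {0,1,2} across k SNPs are combined into the weighted mean of the
  per-locus risk-allele proportion R_i/2 with weights W_i = log OR of the
  risk allele:

      score = sum_i W_i (R_i/2) / sum_i W_i            in [0, 1]
      effective_alleles = 2k * score
                        = k * sum_i W_i R_i / sum_i W_i  in [0, 2k]

  The "effective" number of risk alleles rescales the score back to an
  allele-count axis (a subject homozygous for every risk allele has 2k
  effective alleles; with equal weights it reduces to the plain count).
  Since the weights enter only as ratios, the logarithm base is
  irrelevant.  Subjects are then binned into effective-allele categories
  and each category's odds of disease is compared with the lowest
  (reference) category.

Subjects missing a genotype at any scored SNP are excluded, and the
exclusion count is reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .association import AssociationResult, _choose_test, _result
from .genotype_data import CASE, CONTROL, MISSING, CohortDataset
from .association import TwoByTwo

#: Allelic odds ratios of the four risk SNPs reported for the study cohort
#: (rs1801725, rs1042636, rs219778, rs219780); the default weight source.
STUDY_ALLELIC_ORS: dict[str, float] = {
    "rs1801725": 2.54,
    "rs1042636": 2.21,
    "rs219778": 3.01,
    "rs219780": 2.19,
}


@dataclass(frozen=True)
class DosageWeights:
    """Per-SNP log-OR weights for the dosage score."""

    snp_ids: tuple[str, ...]
    W: tuple[float, ...]
    source: str = ""

    def __post_init__(self) -> None:
        if len(self.snp_ids) != len(self.W) or len(self.snp_ids) < 1:
            raise ValueError("need one positive weight per SNP, at least one SNP")
        if any(w <= 0 for w in self.W):
            raise ValueError("weights must be positive (risk alleles have OR > 1)")

    @property
    def k(self) -> int:
        return len(self.snp_ids)

    @classmethod
    def from_odds_ratios(
        cls, ors: dict[str, float], base: float = math.e, source: str = ""
    ) -> "DosageWeights":
        """Weights as log(OR); any base gives the same score (ratios only)."""
        ids = tuple(ors)
        return cls(ids, tuple(math.log(ors[i], base) for i in ids), source=source)


def default_weights() -> DosageWeights:
    """log-OR weights from the study's four significant risk SNPs."""
    return DosageWeights.from_odds_ratios(
        STUDY_ALLELIC_ORS, source="study allelic ORs"
    )


def dosage_score(
    R: Sequence[int], weights: DosageWeights
) -> tuple[float, float]:
    """(score, effective_alleles) for one subject's risk-allele counts R."""
    if len(R) != weights.k:
        raise ValueError(f"expected {weights.k} genotype counts, got {len(R)}")
    for r in R:
        if r not in (0, 1, 2):
            raise ValueError(f"risk-allele count {r!r} not in {{0, 1, 2}}")
    wsum = sum(weights.W)
    score = sum(w * (r / 2) for w, r in zip(weights.W, R)) / wsum
    return score, 2 * weights.k * score


def _risk_allele_count(subj, snp, snp_id: str) -> int:
    """Risk-allele count: the genotype code if risk=alt, else its complement."""
    g = subj.genotypes.get(snp_id, MISSING)
    if g == MISSING:
        return MISSING
    return g if snp.risk_allele == "alt" else 2 - g


class CarrierStratum:
    """A stratum defined by how many of the listed SNPs carry >=1 risk allele.

    ``n_carried`` is the set of admissible counts of risk-SNPs carried,
    e.g. {2} = carries the risk allele at both of two SNPs; {0} = at none.
    """

    def __init__(self, label: str, n_carried: Iterable[int]):
        self.label = label
        self.n_carried = frozenset(n_carried)


def combined_carrier_or(
    ds: CohortDataset,
    snp_set: Sequence[str],
    stratum_a: CarrierStratum,
    stratum_b: CarrierStratum,
) -> AssociationResult:
    """Case-control OR comparing two disjoint carrier strata.

    Subjects missing a genotype at any SNP of ``snp_set`` are excluded
    (the analysis uses only fully genotyped individuals).  ``stratum_a``
    is the exposed group, ``stratum_b`` the reference.
    """
    if stratum_a.n_carried & stratum_b.n_carried:
        raise ValueError(
            f"strata {stratum_a.label!r} and {stratum_b.label!r} are not disjoint"
        )
    snps = {sid: ds.snp(sid) for sid in snp_set}
    tallies = {  # (stratum, status) -> count
        (s, st): 0 for s in ("a", "b") for st in (CASE, CONTROL)
    }
    for subj in ds.subjects:
        counts = [_risk_allele_count(subj, snps[sid], sid) for sid in snp_set]
        if MISSING in counts:
            continue
        carried = sum(1 for c in counts if c >= 1)
        if carried in stratum_a.n_carried:
            tallies[("a", subj.status)] += 1
        elif carried in stratum_b.n_carried:
            tallies[("b", subj.status)] += 1
    for key, label in ((("a", CASE), stratum_a.label), (("b", CASE), stratum_b.label)):
        stratum = key[0]
        if tallies[(stratum, CASE)] + tallies[(stratum, CONTROL)] == 0:
            raise ValueError(f"stratum {label!r} is empty")
    t = TwoByTwo(
        tallies[("a", CASE)], tallies[("b", CASE)],
        tallies[("a", CONTROL)], tallies[("b", CONTROL)],
    )
    return _result(
        "+".join(snp_set), "combined", f"{stratum_a.label} vs {stratum_b.label}",
        t, alpha=0.05,
    )


@dataclass
class DosageCategory:
    label: str
    low: float   # inclusive for the reference bin, exclusive above (see bins)
    high: float  # inclusive
    n_case: int = 0
    n_control: int = 0
    or_vs_ref: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None
    p: float | None = None

    @property
    def n(self) -> int:
        return self.n_case + self.n_control


@dataclass
class DosageResult:
    weights: DosageWeights
    subject_ids: list[str]
    scores: list[float]
    effective_alleles: list[float]
    categories: list[DosageCategory]
    n_excluded: int
    note: str = ""


def _make_bins(boundaries: Sequence[float], k: int) -> list[tuple[str, float, float]]:
    """Category bins from boundaries [b1, b2, ...]: reference [0, b1],
    then (b1, b2], ..., (b_last, 2k]."""
    bins = []
    lo = 0.0
    b = list(boundaries)
    labels = [f"<={b[0]:g}"] + [f"({x:g},{y:g}]" for x, y in zip(b, b[1:])] + [f">{b[-1]:g}"]
    edges = [0.0] + b + [2.0 * k]
    for i, lab in enumerate(labels):
        bins.append((lab, edges[i], edges[i + 1]))
    return bins


def dosage_category_analysis(
    ds: CohortDataset,
    weights: DosageWeights | None = None,
    boundaries: Sequence[float] = (2.0, 3.0, 4.0),
) -> DosageResult:
    """Per-subject dosage scores, category assignment, and category ORs.

    Categories partition the effective-allele axis at ``boundaries``:
    the reference bin is [0, b1] ("b1 or fewer effective risk alleles"),
    subsequent bins are half-open (b_i, b_{i+1}], the last reaching 2k.
    Each non-reference category's OR (Woolf CI; chi-square or Fisher p by
    the expected-count rule) is computed against the reference bin.
    """
    weights = weights or default_weights()
    snps = {sid: ds.snp(sid) for sid in weights.snp_ids}
    bins = _make_bins(boundaries, weights.k)
    cats = [DosageCategory(lab, lo, hi) for lab, lo, hi in bins]

    ids, scores, effs = [], [], []
    n_excluded = 0
    assignments = []
    for subj in ds.subjects:
        R = [_risk_allele_count(subj, snps[sid], sid) for sid in weights.snp_ids]
        if MISSING in R:
            n_excluded += 1
            continue
        score, eff = dosage_score(R, weights)
        ids.append(subj.subject_id)
        scores.append(score)
        effs.append(eff)
        for ci, cat in enumerate(cats):
            in_bin = (cat.low <= eff <= cat.high) if ci == 0 else (cat.low < eff <= cat.high)
            if in_bin:
                assignments.append(ci)
                if subj.status == CASE:
                    cat.n_case += 1
                else:
                    cat.n_control += 1
                break

    ref = cats[0]
    note = ""
    if ref.n == 0:
        raise ValueError("reference dosage category is empty")
    occupied = [c for c in cats if c.n > 0]
    if len(occupied) == 1:
        note = "all subjects fall in a single category; no ORs computable"
    else:
        for cat in cats[1:]:
            if cat.n == 0:
                continue
            t = TwoByTwo(cat.n_case, ref.n_case, cat.n_control, ref.n_control)
            try:
                res = _result("dosage", "category", f"{cat.label} vs {ref.label}", t, 0.05)
            except ValueError:
                continue  # empty margin (e.g. no cases anywhere in the pair)
            cat.or_vs_ref = res.or_estimate
            cat.ci_low, cat.ci_high = res.ci_low, res.ci_high
            cat.p = res.p_raw
    return DosageResult(
        weights=weights, subject_ids=ids, scores=scores,
        effective_alleles=effs, categories=cats,
        n_excluded=n_excluded, note=note,
    )
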