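"""Synthetic case-control cohorts with controlled statistical structure.

The generator produces individual-level :class:`~stonekit.genotype_data.CohortDataset`
objects in two genotype modes:

* **exact-count mode** — per-SNP genotype counts per group are hit
  EXACTLY, by laying out the genotype vector and permuting it within the
  group with the seeded RNG.  Every count-based statistic (OR, CI,
  chi-square, HWE) is then seed-invariant; the seed only moves which
  subject carries which genotype.
* **frequency mode** — genotypes are sampled under Hardy-Weinberg
  proportions at a given alt-allele frequency; optional pairwise r^2
  targets are honoured by sampling two-locus haplotypes at the
  corresponding D.

Traits are drawn from per-stratum normal models: a trait may be
stratified on one SNP's carrier status within each case/control group,
with a group-level normal as the fallback.  Covariates follow normal
(age, BMI) and Bernoulli (sex) models per group.

:func:`study_cohort` instantiates the published kidney-stone study
conditions: 200 cases and 200 controls whose eight per-SNP genotype
count tables equal the printed ones exactly, with trait and covariate
models taken from the printed group and genotype-stratum summaries.
Joint genotypes across SNPs are independent (the study does not publish
them), so multi-locus results on this cohort exercise the procedures,
not the paper's joint-genotype values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .genotype_data import (
    CASE,
    CONTROL,
    CohortDataset,
    GenotypeCounts,
    SnpDef,
    STUDY_SNPS,
    Subject,
    study_count_fixture,
)


@dataclass(frozen=True)
class Normal:
    mean: float
    sd: float


@dataclass
class TraitSpec:
    """Normal trait model per group, optionally stratified on one SNP.

    ``stratified`` maps ``(status, stratum)`` with stratum in
    {"homref", "carrier"} (carrier = >=1 alt allele at ``stratify_snp``)
    to a :class:`Normal`; strata not listed fall back to the group model.
    """

    name: str
    case: Normal
    control: Normal
    stratify_snp: str | None = None
    stratified: dict[tuple[str, str], Normal] = field(default_factory=dict)


@dataclass
class SnpSim:
    """Genotype model for one SNP: exact per-group counts or an alt frequency.

    ``alt_freq`` may be a single frequency (shared by both groups, a null
    SNP) or a ``(case, control)`` pair, which induces an allelic odds
    ratio of (p1/q1)/(p2/q2) in expectation.
    """

    snp: SnpDef
    exact: tuple[tuple[int, int, int], tuple[int, int, int]] | None = None  # (case, control)
    alt_freq: float | tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if (self.exact is None) == (self.alt_freq is None):
            raise ValueError(f"{self.snp.snp_id}: give exactly one of exact counts or alt_freq")
        if self.alt_freq is not None:
            for f in self.freqs:
                if not 0 < f < 1:
                    raise ValueError(f"{self.snp.snp_id}: alt_freq must be in (0, 1)")

    @property
    def freqs(self) -> tuple[float, float]:
        """(case, control) alt frequencies."""
        if isinstance(self.alt_freq, tuple):
            return self.alt_freq
        return (self.alt_freq, self.alt_freq)


@dataclass
class CohortSpec:
    n_case: int
    n_control: int
    snps: list[SnpSim]
    r2_targets: dict[tuple[str, str], float] = field(default_factory=dict)
    traits: list[TraitSpec] = field(default_factory=list)
    age: tuple[Normal, Normal] | None = None       # (case, control)
    male_prob: tuple[float, float] | None = None   # (case, control)
    bmi: tuple[Normal, Normal] | None = None
    seed: int = 0


def _exact_genotype_vector(counts: tuple[int, int, int], n: int, snp_id: str,
                           rng: np.random.Generator) -> np.ndarray:
    if sum(counts) != n:
        raise ValueError(f"{snp_id}: exact counts {counts} do not sum to group size {n}")
    v = np.repeat([0, 1, 2], counts)
    rng.shuffle(v)
    return v


def _hwe_genotypes(p_alt: float, n: int, rng: np.random.Generator) -> np.ndarray:
    return rng.binomial(2, p_alt, size=n)


def _haplotype_pair_genotypes(
    p1: float, p2: float, r2: float, n: int, rng: np.random.Generator,
    pair: tuple[str, str],
) -> tuple[np.ndarray, np.ndarray]:
    """Sample genotypes at two loci from haplotypes at the D implied by r^2."""
    q1, q2 = 1 - p1, 1 - p2
    d = float(np.sqrt(r2 * p1 * q1 * p2 * q2))  # positive-D convention
    d_max = min(p1 * q2, q1 * p2)
    if d > d_max + 1e-12:
        r2_max = d_max**2 / (p1 * q1 * p2 * q2)
        raise ValueError(
            f"r^2 target {r2} infeasible for {pair} at frequencies "
            f"({p1}, {p2}); feasible maximum is {r2_max:.4f}"
        )
    f = np.array([p1 * p2 + d, p1 * q2 - d, q1 * p2 - d, q1 * q2 + d])
    f = np.clip(f, 0, None)
    f /= f.sum()
    # two haplotypes per subject; haplotype index -> (allele1, allele2)
    alleles = np.array([(1, 1), (1, 0), (0, 1), (0, 0)])
    h = rng.choice(4, size=(n, 2), p=f)
    g1 = alleles[h, 0].sum(axis=1)
    g2 = alleles[h, 1].sum(axis=1)
    return g1, g2


def generate_cohort(spec: CohortSpec) -> CohortDataset:
    """Generate a cohort per ``spec``; fully reproducible from ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    by_id = {s.snp.snp_id: s for s in spec.snps}
    for (s1, s2), r2 in spec.r2_targets.items():
        for sid in (s1, s2):
            if sid not in by_id:
                raise ValueError(f"r2 target names unknown SNP {sid!r}")
            if by_id[sid].exact is not None:
                raise ValueError(
                    f"r2 target on {sid}: LD targets require frequency-mode SNPs"
                )
        if not 0 <= r2 <= 1:
            raise ValueError(f"r2 target {r2} outside [0, 1]")

    group_sizes = {CASE: spec.n_case, CONTROL: spec.n_control}
    geno: dict[str, dict[str, np.ndarray]] = {CASE: {}, CONTROL: {}}
    linked = {sid for pair in spec.r2_targets for sid in pair}
    for grp, n in group_sizes.items():
        gi = 0 if grp == CASE else 1
        for (s1, s2), r2 in spec.r2_targets.items():
            g1, g2 = _haplotype_pair_genotypes(
                by_id[s1].freqs[gi], by_id[s2].freqs[gi], r2, n, rng, (s1, s2)
            )
            geno[grp][s1], geno[grp][s2] = g1, g2
        for sim in spec.snps:
            sid = sim.snp.snp_id
            if sid in linked:
                continue
            if sim.exact is not None:
                counts = sim.exact[0] if grp == CASE else sim.exact[1]
                geno[grp][sid] = _exact_genotype_vector(counts, n, sid, rng)
            else:
                geno[grp][sid] = _hwe_genotypes(sim.freqs[gi], n, rng)

    subjects: list[Subject] = []
    for grp, n in group_sizes.items():
        gi = 0 if grp == CASE else 1
        for i in range(n):
            sid = f"{grp[:2]}{i + 1:04d}"
            genotypes = {snp: int(geno[grp][snp][i]) for snp in geno[grp]}
            age = float(rng.normal(spec.age[gi].mean, spec.age[gi].sd)) if spec.age else None
            sex = None
            if spec.male_prob:
                sex = "male" if rng.random() < spec.male_prob[gi] else "female"
            bmi = float(rng.normal(spec.bmi[gi].mean, spec.bmi[gi].sd)) if spec.bmi else None
            traits = {}
            for ts in spec.traits:
                model = ts.case if grp == CASE else ts.control
                if ts.stratify_snp is not None and ts.stratify_snp in genotypes:
                    stratum = "carrier" if genotypes[ts.stratify_snp] >= 1 else "homref"
                    model = ts.stratified.get((grp, stratum), model)
                traits[ts.name] = float(rng.normal(model.mean, model.sd))
            subjects.append(Subject(
                subject_id=sid, status=grp, age=age, sex=sex, bmi=bmi,
                traits=traits, genotypes=genotypes,
            ))
    return CohortDataset(snps=[s.snp for s in spec.snps], subjects=subjects)


# ---------------------------------------------------------------------------
# The published study conditions
# ---------------------------------------------------------------------------

#: Group-level trait models (mean +/- SD) for cases and controls.
STUDY_TRAITS: dict[str, tuple[Normal, Normal]] = {
    "serum_creatinine": (Normal(1.21, 0.477), Normal(0.714, 0.096)),
    "serum_calcium": (Normal(9.42, 0.32), Normal(9.46, 0.238)),
    "urinary_calcium": (Normal(7.87, 0.59), Normal(4.04, 0.68)),
    "urinary_oxalate": (Normal(28.11, 3.07), Normal(27.51, 3.11)),
    "urinary_citrate": (Normal(2.58, 0.96), Normal(2.77, 1.21)),
    "urinary_potassium": (Normal(64.21, 4.77), Normal(64.59, 4.61)),
    "urinary_phosphate": (Normal(27.45, 4.29), Normal(26.81, 3.33)),
    "urinary_urate": (Normal(2.89, 0.47), Normal(2.78, 0.86)),
    "urine_ph": (Normal(5.72, 0.31), Normal(5.79, 0.55)),
}

#: Genotype-stratified trait models: serum calcium by rs1801725 carrier
#: status, urinary calcium by rs1042636 carrier status, per group.
_STRATIFIED = {
    "serum_calcium": ("rs1801725", {
        (CASE, "homref"): Normal(9.20, 0.20),
        (CASE, "carrier"): Normal(9.72, 0.18),
        (CONTROL, "homref"): Normal(9.45, 0.21),
        (CONTROL, "carrier"): Normal(9.64, 0.25),
    }),
    "urinary_calcium": ("rs1042636", {
        (CASE, "homref"): Normal(7.58, 0.57),
        (CASE, "carrier"): Normal(8.10, 0.51),
        (CONTROL, "homref"): Normal(4.04, 0.71),
        (CONTROL, "carrier"): Normal(4.02, 0.62),
    }),
}

STUDY_AGE = (Normal(39.93, 11.37), Normal(38.13, 10.16))
STUDY_MALE_PROB = (0.665, 0.610)
STUDY_BMI = (Normal(22.11, 1.19), Normal(22.20, 1.34))


def study_spec(seed: int = 0) -> CohortSpec:
    """The study conditions as a :class:`CohortSpec` (200/200, exact counts)."""
    fixture = study_count_fixture()
    snps = [
        SnpSim(snp, exact=(fixture[snp.snp_id][0].as_tuple(),
                           fixture[snp.snp_id][1].as_tuple()))
        for snp in STUDY_SNPS
    ]
    traits = []
    for name, (case_m, control_m) in STUDY_TRAITS.items():
        ts = TraitSpec(name, case_m, control_m)
        if name in _STRATIFIED:
            ts.stratify_snp, ts.stratified = _STRATIFIED[name]
        traits.append(ts)
    return CohortSpec(
        n_case=200, n_control=200, snps=snps, traits=traits,
        age=STUDY_AGE, male_prob=STUDY_MALE_PROB, bmi=STUDY_BMI, seed=seed,
    )


def study_cohort(seed: int = 0) -> CohortDataset:
    """A 200-case / 200-control cohort matching the published study margins.

    Per-SNP genotype counts equal the printed tables exactly (seed moves
    only the within-group assignment); traits and covariates are drawn
    from the printed normal summaries.  Joint genotypes are independent
    across SNPs.
    """
    return generate_cohort(study_spec(seed))
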