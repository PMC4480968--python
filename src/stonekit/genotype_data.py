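"""Cohort data model for candidate-gene case-control studies.

Genotypes are coded as the integer count of alternate alleles (0, 1, 2);
missing calls use the sentinel :data:`MISSING`.  All downstream statistics
consume genotype counts, never raw allele strings, so the coding is fixed
here once and validated at load time.

The module also carries the published per-SNP genotype counts of the
eastern-India calcium kidney-stone cohort (200 cases / 200 controls,
eight SNPs in *CaSR*, *VDR* and *CLDN14*) as an importable fixture:
count-based statistics on that cohort are fully determined by these
tables, so the whole association layer can be exercised without any
individual-level data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

logger = logging.getLogger(__name__)

#: Sentinel for a missing genotype call.
MISSING: int = -1

CASE = "case"
CONTROL = "control"


@dataclass(frozen=True)
class SnpDef:
    """Identity and allele coding of one biallelic SNP.

    ``risk_allele`` designates which of the two alleles is treated as the
    risk (exposure) allele in association contrasts and dosage scores.
    """

    snp_id: str
    gene: str
    ref_allele: str
    alt_allele: str
    risk_allele: str = "alt"
    annotation: str = ""

    def __post_init__(self) -> None:
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"{self.snp_id}: ref and alt allele are identical")
        if self.risk_allele not in ("ref", "alt"):
            raise ValueError(f"{self.snp_id}: risk_allele must be 'ref' or 'alt'")
        for a in (self.ref_allele, self.alt_allele):
            if len(a) != 1:
                raise ValueError(f"{self.snp_id}: allele {a!r} is not a single base")

    @property
    def risk_base(self) -> str:
        return self.alt_allele if self.risk_allele == "alt" else self.ref_allele


@dataclass
class Subject:
    """One study participant: status, covariates, traits and genotype calls."""

    subject_id: str
    status: str  # "case" or "control"
    age: float | None = None
    sex: str | None = None  # "male" / "female"
    bmi: float | None = None
    traits: dict[str, float] = field(default_factory=dict)
    genotypes: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.status not in (CASE, CONTROL):
            raise ValueError(f"subject {self.subject_id}: bad status {self.status!r}")
        for snp, g in self.genotypes.items():
            if g not in (0, 1, 2, MISSING):
                raise ValueError(
                    f"subject {self.subject_id}, SNP {snp}: genotype code {g!r} "
                    "not in {0, 1, 2, missing}"
                )
        for name, v in self.traits.items():
            if v is None or v != v:  # NaN-as-present forbidden
                raise ValueError(
                    f"subject {self.subject_id}: trait {name!r} present but not a number"
                )


@dataclass
class CohortDataset:
    """Subjects x SNPs genotype matrix plus status, covariates and traits."""

    snps: list[SnpDef]
    subjects: list[Subject]

    def __post_init__(self) -> None:
        ids = [s.subject_id for s in self.subjects]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate subject IDs: {dup}")
        known = {s.snp_id for s in self.snps}
        for subj in self.subjects:
            unknown = set(subj.genotypes) - known
            if unknown:
                raise ValueError(
                    f"subject {subj.subject_id} has genotypes for undeclared SNPs: "
                    f"{sorted(unknown)}"
                )

    @property
    def snp_ids(self) -> list[str]:
        return [s.snp_id for s in self.snps]

    def snp(self, snp_id: str) -> SnpDef:
        for s in self.snps:
            if s.snp_id == snp_id:
                return s
        raise KeyError(f"unknown SNP {snp_id!r}")

    def group(self, status: str) -> list[Subject]:
        return [s for s in self.subjects if s.status == status]

    @property
    def n_case(self) -> int:
        return len(self.group(CASE))

    @property
    def n_control(self) -> int:
        return len(self.group(CONTROL))

    def genotype_frame(self) -> pd.DataFrame:
        """Genotype matrix as a DataFrame (subjects x SNPs, MISSING sentinel kept)."""
        data = {
            subj.subject_id: [subj.genotypes.get(s, MISSING) for s in self.snp_ids]
            for subj in self.subjects
        }
        return pd.DataFrame.from_dict(data, orient="index", columns=self.snp_ids)


@dataclass(frozen=True)
class GenotypeCounts:
    """Per-group genotype counts (homRef, het, homAlt) for one SNP.

    This is the unit of every count-based test in the package.
    """

    snp_id: str
    group: str
    n_hom_ref: int
    n_het: int
    n_hom_alt: int

    def __post_init__(self) -> None:
        for n in (self.n_hom_ref, self.n_het, self.n_hom_alt):
            if n < 0 or int(n) != n:
                raise ValueError(f"{self.snp_id}/{self.group}: negative or non-integer count")

    @property
    def n_total(self) -> int:
        return self.n_hom_ref + self.n_het + self.n_hom_alt

    def as_tuple(self) -> tuple[int, int, int]:
        return (self.n_hom_ref, self.n_het, self.n_hom_alt)


def allele_counts(gc: GenotypeCounts) -> tuple[int, int]:
    """Return (n_ref_alleles, n_alt_alleles); the two always sum to 2 * n_total."""
    n_alt = gc.n_het + 2 * gc.n_hom_alt
    n_ref = 2 * gc.n_hom_ref + gc.n_het
    return n_ref, n_alt


def allele_frequency(gc: GenotypeCounts) -> float:
    """Alternate-allele frequency n_alt / (2 n_total)."""
    if gc.n_total == 0:
        raise ValueError(f"{gc.snp_id}/{gc.group}: no genotyped subjects")
    _, n_alt = allele_counts(gc)
    return n_alt / (2 * gc.n_total)


def counts_from_dataset(
    ds: CohortDataset, snp_id: str
) -> tuple[GenotypeCounts, GenotypeCounts]:
    """Tabulate (case, control) genotype counts for one SNP, skipping missing calls."""
    if snp_id not in ds.snp_ids:
        raise KeyError(f"unknown SNP {snp_id!r}")
    out = []
    for grp in (CASE, CONTROL):
        tallies = [0, 0, 0]
        for subj in ds.group(grp):
            g = subj.genotypes.get(snp_id, MISSING)
            if g != MISSING:
                tallies[g] += 1
        out.append(GenotypeCounts(snp_id, grp, *tallies))
    return out[0], out[1]


# ---------------------------------------------------------------------------
# TSV dialect
# ---------------------------------------------------------------------------
# Genotype table: one header row; subjects as rows; column `subject_id`;
# SNP columns hold unordered two-character genotype strings ("GT" == "TG"),
# empty/"NA"/"./." meaning missing.
# Phenotype table: columns subject_id, status, age, sex, bmi, then traits.

_MISSING_STRINGS = {"", "NA", "na", "./.", ".", "--"}


def _code_genotype(snp: SnpDef, value: str, subject_id: str) -> int:
    if value is None or (isinstance(value, float) and value != value):
        return MISSING
    s = str(value).strip()
    if s in _MISSING_STRINGS:
        return MISSING
    if len(s) != 2:
        raise ValueError(
            f"subject {subject_id}, SNP {snp.snp_id}: malformed genotype {s!r}"
        )
    code = 0
    for base in s:
        if base == snp.alt_allele:
            code += 1
        elif base != snp.ref_allele:
            raise ValueError(
                f"subject {subject_id}, SNP {snp.snp_id}: allele {base!r} in "
                f"genotype {s!r} is neither ref ({snp.ref_allele}) nor alt "
                f"({snp.alt_allele})"
            )
    return code


def _genotype_string(snp: SnpDef, code: int) -> str:
    if code == MISSING:
        return "NA"
    return {
        0: snp.ref_allele * 2,
        1: snp.ref_allele + snp.alt_allele,
        2: snp.alt_allele * 2,
    }[code]


def load_cohort(
    genotype_table: str | Path,
    phenotype_table: str | Path,
    snps: Iterable[SnpDef],
) -> CohortDataset:
    """Load and join genotype and phenotype TSVs into a :class:`CohortDataset`.

    Only subjects present in both files are kept; the join outcome (matched /
    dropped counts) is logged.  Genotype strings are validated against each
    SNP's declared alleles and converted to 0/1/2 alt-allele counts.
    """
    snps = list(snps)
    by_id = {s.snp_id: s for s in snps}
    geno = pd.read_csv(genotype_table, sep="\t", dtype=str)
    pheno = pd.read_csv(phenotype_table, sep="\t")
    for frame, path in ((geno, genotype_table), (pheno, phenotype_table)):
        if "subject_id" not in frame.columns:
            raise ValueError(f"{path}: missing subject_id column")
        if frame["subject_id"].duplicated().any():
            dup = frame.loc[frame["subject_id"].duplicated(), "subject_id"].tolist()
            raise ValueError(f"{path}: duplicate subject IDs {dup}")

    geno = geno.set_index("subject_id")
    pheno = pheno.set_index("subject_id")
    shared = geno.index.intersection(pheno.index)
    dropped = len(geno.index.union(pheno.index)) - len(shared)
    if dropped:
        logger.warning(
            "cohort join: %d subjects matched, %d dropped (absent from one file)",
            len(shared), dropped,
        )
    else:
        logger.info("cohort join: %d subjects matched, 0 dropped", len(shared))

    trait_cols = [
        c for c in pheno.columns if c not in ("status", "age", "sex", "bmi")
    ]
    subjects = []
    for sid in shared:
        prow = pheno.loc[sid]
        grow = geno.loc[sid]
        genotypes = {
            snp_id: _code_genotype(by_id[snp_id], grow.get(snp_id), sid)
            for snp_id in by_id
            if snp_id in geno.columns
        }
        traits = {
            c: float(prow[c]) for c in trait_cols if pd.notna(prow[c])
        }
        subjects.append(
            Subject(
                subject_id=str(sid),
                status=str(prow["status"]),
                age=float(prow["age"]) if pd.notna(prow.get("age")) else None,
                sex=str(prow["sex"]) if pd.notna(prow.get("sex")) else None,
                bmi=float(prow["bmi"]) if pd.notna(prow.get("bmi")) else None,
                traits=traits,
                genotypes=genotypes,
            )
        )
    return CohortDataset(snps=snps, subjects=subjects)


def write_cohort(
    ds: CohortDataset, genotype_table: str | Path, phenotype_table: str | Path
) -> None:
    """Write a dataset back to the genotype/phenotype TSV dialect."""
    grows = []
    prows = []
    trait_names = sorted({t for s in ds.subjects for t in s.traits})
    for subj in ds.subjects:
        grow = {"subject_id": subj.subject_id}
        for snp in ds.snps:
            grow[snp.snp_id] = _genotype_string(
                snp, subj.genotypes.get(snp.snp_id, MISSING)
            )
        grows.append(grow)
        prow = {
            "subject_id": subj.subject_id,
            "status": subj.status,
            "age": subj.age,
            "sex": subj.sex,
            "bmi": subj.bmi,
        }
        for t in trait_names:
            prow[t] = subj.traits.get(t)
        prows.append(prow)
    pd.DataFrame(grows).to_csv(genotype_table, sep="\t", index=False)
    pd.DataFrame(prows).to_csv(phenotype_table, sep="\t", index=False)


def load_vcf_genotypes(path: str | Path, snps: Iterable[SnpDef]) -> dict[str, dict[str, int]]:
    """Read genotypes for the given SNPs from a VCF 4.x file.

    Returns ``{snp_id: {sample: code}}`` with GT 0/0, 0/1, 1/1 mapped to
    0, 1, 2 and ./. to missing.  Multi-allelic records are rejected: the
    data model is strictly biallelic.
    """
    from cyvcf2 import VCF

    wanted = {s.snp_id: s for s in snps}
    out: dict[str, dict[str, int]] = {}
    vcf = VCF(str(path))
    samples = vcf.samples
    for rec in vcf:
        rid = rec.ID
        if rid not in wanted:
            continue
        if len(rec.ALT) != 1:
            raise ValueError(f"{rid}: multi-allelic record (ALT={rec.ALT}); only biallelic SNPs supported")
        snp = wanted[rid]
        if rec.REF != snp.ref_allele or rec.ALT[0] != snp.alt_allele:
            raise ValueError(
                f"{rid}: VCF alleles {rec.REF}/{rec.ALT[0]} do not match declared "
                f"{snp.ref_allele}/{snp.alt_allele}"
            )
        calls = {}
        for sample, gt in zip(samples, rec.gt_types):
            # cyvcf2 gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
            calls[sample] = {0: 0, 1: 1, 3: 2, 2: MISSING}[int(gt)]
        out[rid] = calls
    return out


# ---------------------------------------------------------------------------
# Published count tables for the kidney-stone cohort
# ---------------------------------------------------------------------------

#: The eight SNPs of the study, with allele coding and risk-allele designation.
#: The risk allele is the alternate (minor/variant) allele at every locus.
STUDY_SNPS: tuple[SnpDef, ...] = (
    SnpDef("rs1801725", "CaSR", "G", "T", "alt", "Ala986Ser"),
    SnpDef("rs1042636", "CaSR", "A", "G", "alt", "Arg990Gly"),
    SnpDef("rs1801726", "CaSR", "C", "G", "alt", "Glu1011Gln"),
    SnpDef("rs2228570", "VDR", "C", "T", "alt", "Met1Thr(FokI)"),
    SnpDef("rs731236", "VDR", "C", "T", "alt", "TaqI(intron 9)"),
    SnpDef("rs219777", "CLDN14", "C", "T", "alt", "intronic c>t"),
    SnpDef("rs219778", "CLDN14", "T", "C", "alt", "intronic t>c"),
    SnpDef("rs219780", "CLDN14", "G", "A", "alt", "Thr229Thr"),
)

#: SNP sets used in the combined-risk-allele analyses.
CASR_RISK_PAIR = ("rs1801725", "rs1042636")
CLDN14_RISK_PAIR = ("rs219778", "rs219780")
FOUR_RISK_SNPS = CASR_RISK_PAIR + CLDN14_RISK_PAIR

# (case homRef/het/homAlt), (control homRef/het/homAlt) per SNP, as published
# for the 200-case / 200-control cohort.
_STUDY_COUNTS: dict[str, tuple[tuple[int, int, int], tuple[int, int, int]]] = {
    "rs1801725": ((116, 82, 2), (162, 37, 1)),
    "rs1042636": ((86, 99, 15), (130, 69, 1)),
    "rs1801726": ((189, 11, 0), (190, 10, 0)),
    "rs2228570": ((78, 115, 7), (98, 90, 12)),
    "rs731236": ((60, 82, 58), (77, 58, 65)),
    "rs219777": ((159, 38, 3), (174, 25, 1)),
    "rs219778": ((141, 56, 3), (178, 21, 1)),
    "rs219780": ((139, 58, 3), (169, 30, 1)),
}


def study_count_fixture() -> dict[str, tuple[GenotypeCounts, GenotypeCounts]]:
    """Published genotype counts of the kidney-stone cohort, per SNP.

    Returns ``{snp_id: (case_counts, control_counts)}`` for the eight SNPs,
    verbatim as printed for the 200/200 cohort.  All count-based statistics
    of the study are reproducible from these tables alone.
    """
    return {
        snp_id: (
            GenotypeCounts(snp_id, CASE, *case),
            GenotypeCounts(snp_id, CONTROL, *control),
        )
        for snp_id, (case, control) in _STUDY_COUNTS.items()
    }


def fixture_as_json() -> str:
    """The count fixture serialized as JSON (for export / external tools)."""
    import json

    return json.dumps(
        {
            snp: {"case": list(case), "control": list(control)}
            for snp, (case, control) in _STUDY_COUNTS.items()
        },
        indent=2,
    )
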