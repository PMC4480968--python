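"""Pairwise linkage disequilibrium from unphased genotypes.

Two-locus haplotype frequencies are estimated by expectation-maximization
on the unphased genotype likelihood: with biallelic loci, only the
double-heterozygote class has ambiguous phase, and the EM iterates between
probabilistically resolving it and re-estimating the four haplotype
frequencies.  From the fitted frequencies the usual summaries D, D' and
r^2 are computed.

Haplotypes are ordered (alt-alt, alt-ref, ref-alt, ref-ref) relative to
the two loci's alt alleles; D = p(alt,alt) - p_A p_B with p_A, p_B the alt
frequencies.  r^2 is invariant to which allele is labelled alt.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .genotype_data import MISSING, CASE, CONTROL, CohortDataset

logger = logging.getLogger(__name__)

# haplotype index order: 0 = (alt, alt), 1 = (alt, ref), 2 = (ref, alt), 3 = (ref, ref)
_HAPS = ((1, 1), (1, 0), (0, 1), (0, 0))


@dataclass
class JointGenotypeCounts:
    """3x3 grid of subject counts over genotype pairs at two SNPs."""

    n: np.ndarray  # shape (3, 3); n[g1][g2], g = alt-allele count

    def __post_init__(self) -> None:
        self.n = np.asarray(self.n, dtype=float)
        if self.n.shape != (3, 3) or (self.n < 0).any():
            raise ValueError("joint genotype counts must be a non-negative 3x3 grid")

    @property
    def total(self) -> float:
        return float(self.n.sum())

    def marginal_alt_freqs(self) -> tuple[float, float]:
        g = np.arange(3, dtype=float)
        n1 = self.n.sum(axis=1)
        n2 = self.n.sum(axis=0)
        return float(g @ n1 / (2 * self.total)), float(g @ n2 / (2 * self.total))


@dataclass
class LdResult:
    hap_freqs: tuple[float, float, float, float]  # (p_AB, p_Ab, p_aB, p_ab)
    D: float
    D_prime: float
    r2: float
    em_iterations: int
    loglik: float
    converged: bool = True
    degenerate: bool = False  # flat likelihood (e.g. all double heterozygotes)


def _cell_prob(f: np.ndarray, g1: int, g2: int) -> float:
    """P(genotype pair) under random union of haplotypes with freqs f."""
    p = 0.0
    for i, (a1, b1) in enumerate(_HAPS):
        for j, (a2, b2) in enumerate(_HAPS):
            if a1 + a2 == g1 and b1 + b2 == g2:
                p += f[i] * f[j]
    return p


def _loglik(f: np.ndarray, j: JointGenotypeCounts) -> float:
    ll = 0.0
    for g1 in range(3):
        for g2 in range(3):
            n = j.n[g1, g2]
            if n > 0:
                p = _cell_prob(f, g1, g2)
                if p <= 0:
                    return -np.inf
                ll += n * np.log(p)
    return ll


def em_haplotype_freqs(
    j: JointGenotypeCounts, tol: float = 1e-8, max_iter: int = 1000
) -> LdResult:
    """EM estimate of two-locus haplotype frequencies from unphased counts.

    Initialized at linkage equilibrium of the observed allele frequencies;
    iterates until the largest absolute frequency change falls below
    ``tol``.  The log-likelihood is non-decreasing across iterations.  If
    every subject is a double heterozygote the likelihood is flat and the
    equilibrium initializer is returned with ``degenerate=True``.
    """
    n_total = j.total
    if n_total == 0:
        raise ValueError("no subjects with genotypes at both loci")
    p_a, p_b = j.marginal_alt_freqs()
    if p_a in (0.0, 1.0) or p_b in (0.0, 1.0):
        raise ValueError("monomorphic locus: LD undefined")

    # unambiguous haplotype contributions per genotype cell (alt1, ref1 x alt2, ref2)
    f = np.array(
        [p_a * p_b, p_a * (1 - p_b), (1 - p_a) * p_b, (1 - p_a) * (1 - p_b)]
    )
    n_dh = j.n[1, 1]
    if n_dh == n_total:
        logger.warning("all subjects double-heterozygous: flat likelihood, "
                       "returning linkage-equilibrium frequencies")
        return LdResult(tuple(f), *(_ld_from_freqs(f)), em_iterations=0,
                        loglik=_loglik(f, j), converged=True, degenerate=True)

    # fixed (phase-certain) haplotype counts from the eight unambiguous cells
    fixed = np.zeros(4)
    for g1 in range(3):
        for g2 in range(3):
            if (g1, g2) == (1, 1):
                continue
            n = j.n[g1, g2]
            if n == 0:
                continue
            # alleles at each locus split deterministically into two haplotypes
            a_alleles = {0: (0, 0), 1: (1, 0), 2: (1, 1)}[g1]
            b_alleles = {0: (0, 0), 1: (1, 0), 2: (1, 1)}[g2]
            # het at exactly one locus: pairing is still unique up to order
            for a, b in zip(a_alleles, b_alleles):
                fixed[_HAPS.index((a, b))] += n

    converged = False
    it = 0
    prev_ll = -np.inf
    for it in range(1, max_iter + 1):
        # E-step: split double heterozygotes between the two phase configs
        cis = f[0] * f[3]       # (alt,alt)/(ref,ref)
        trans = f[1] * f[2]     # (alt,ref)/(ref,alt)
        denom = cis + trans
        w_cis = 0.5 if denom == 0 else cis / denom
        counts = fixed.copy()
        counts[0] += n_dh * w_cis
        counts[3] += n_dh * w_cis
        counts[1] += n_dh * (1 - w_cis)
        counts[2] += n_dh * (1 - w_cis)
        # M-step
        f_new = counts / (2 * n_total)
        delta = np.abs(f_new - f).max()
        ll = _loglik(f_new, j)
        if ll < prev_ll - 1e-9:
            raise AssertionError("EM log-likelihood decreased")  # pragma: no cover
        prev_ll = ll
        f = f_new
        if delta < tol:
            converged = True
            break
    if not converged:
        warnings.warn(f"haplotype EM did not converge in {max_iter} iterations; "
                      "returning last iterate")
    D, D_prime, r2 = _ld_from_freqs(f)
    return LdResult(tuple(f), D, D_prime, r2, em_iterations=it,
                    loglik=prev_ll, converged=converged)


def _ld_from_freqs(f: np.ndarray) -> tuple[float, float, float]:
    p_a = f[0] + f[1]
    p_b = f[0] + f[2]
    D = f[0] - p_a * p_b
    if D > 0:
        d_max = min(p_a * (1 - p_b), (1 - p_a) * p_b)
    else:
        d_max = min(p_a * p_b, (1 - p_a) * (1 - p_b))
    d_prime = 0.0 if d_max == 0 else abs(D) / d_max
    denom = p_a * (1 - p_a) * p_b * (1 - p_b)
    r2 = 0.0 if denom == 0 else D * D / denom
    return float(D), float(d_prime), float(r2)


def ld_statistics(
    hap_freqs: tuple[float, float, float, float]
) -> tuple[float, float, float]:
    """(D, D', r^2) from haplotype frequencies (p_AB, p_Ab, p_aB, p_ab)."""
    f = np.asarray(hap_freqs, dtype=float)
    if f.min() < -1e-12 or abs(f.sum() - 1) > 1e-9:
        raise ValueError("haplotype frequencies must be non-negative and sum to 1")
    p_a = f[0] + f[1]
    p_b = f[0] + f[2]
    if p_a in (0.0, 1.0) or p_b in (0.0, 1.0):
        raise ValueError("fixed allele: LD undefined")
    return _ld_from_freqs(f)


def joint_counts(ds: CohortDataset, snp1: str, snp2: str, group: str) -> JointGenotypeCounts:
    """Tabulate the 3x3 joint genotype grid for one group ('case'/'control'/'pooled')."""
    if group == "pooled":
        subjects = ds.subjects
    elif group in (CASE, CONTROL):
        subjects = ds.group(group)
    else:
        raise ValueError(f"unknown group {group!r}")
    n = np.zeros((3, 3))
    for s in subjects:
        g1 = s.genotypes.get(snp1, MISSING)
        g2 = s.genotypes.get(snp2, MISSING)
        if g1 != MISSING and g2 != MISSING:
            n[g1, g2] += 1
    return JointGenotypeCounts(n)


def ld_matrix(
    ds: CohortDataset, snp_ids: list[str] | None = None, group: str = "pooled"
) -> "pd.DataFrame":
    """Symmetric pairwise r^2 matrix (diagonal 1 by convention).

    Pairs whose EM fails (e.g. a monomorphic locus in the group) are left
    as NaN and reported in the log.
    """
    import pandas as pd

    ids = snp_ids or ds.snp_ids
    if len(ids) < 2:
        raise ValueError("need at least two SNPs for an LD matrix")
    m = np.full((len(ids), len(ids)), np.nan)
    np.fill_diagonal(m, 1.0)
    for i in range(len(ids)):
        for k in range(i + 1, len(ids)):
            try:
                res = em_haplotype_freqs(joint_counts(ds, ids[i], ids[k], group))
                m[i, k] = m[k, i] = res.r2
            except ValueError as exc:
                logger.warning("LD %s-%s (%s) skipped: %s", ids[i], ids[k], group, exc)
    return pd.DataFrame(m, index=ids, columns=ids)
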