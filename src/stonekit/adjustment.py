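"""Covariate-adjusted odds ratios via logistic regression.

Each genotype contrast is coded as a binary exposure and fitted in its
own logistic model of case status on exposure plus covariates (by
default age, sex, BMI).  The adjusted OR is exp of the exposure
coefficient with a Wald 95% CI.  Sex is coded 0/1 (female/male); age and
BMI enter untransformed — the OR for the exposure is invariant to affine
rescaling of covariates, so centering conventions do not matter.

Separation (an exposure that perfectly predicts outcome) is detected and
reported rather than papered over: ``converged`` is False and no estimate
is fabricated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm

from .genotype_data import CASE, MISSING, CohortDataset

DEFAULT_COVARIATES = ("age", "sex", "bmi")

#: exposure coding per contrast: genotype codes mapped to 1 (exposed),
#: 0 (unexposed); codes absent from the map exclude the subject.
CONTRAST_CODING: dict[str, dict[int, int]] = {
    "dominant": {0: 0, 1: 1, 2: 1},
    "recessive": {0: 0, 1: 0, 2: 1},
    "het_vs_homref": {0: 0, 1: 1},
    "homalt_vs_homref": {0: 0, 2: 1},
    "allelic_additive": {0: 0, 1: 1, 2: 2},  # per-allele trend, not a 2x2 contrast
}


@dataclass
class AdjustedResult:
    snp_id: str
    model: str
    contrast: str
    or_adj: float | None
    ci_low: float | None
    ci_high: float | None
    covariates: list[str] = field(default_factory=list)
    converged: bool = True
    n_used: int = 0
    note: str = ""


def _covariate_value(subj, name: str) -> float | None:
    if name == "age":
        return subj.age
    if name == "bmi":
        return subj.bmi
    if name == "sex":
        if subj.sex is None:
            return None
        return {"female": 0.0, "male": 1.0}[subj.sex]
    return subj.traits.get(name)


def adjusted_or(
    ds: CohortDataset,
    snp_id: str,
    contrast: str = "dominant",
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
) -> AdjustedResult:
    """Covariate-adjusted OR for one genotype contrast at one SNP.

    Subjects with a missing genotype, an excluded genotype class, or any
    missing covariate are dropped; ``n_used`` reports the fitted sample.
    With no covariates the fit is saturated in the exposure and the
    adjusted OR equals the crude 2x2 OR.
    """
    if contrast not in CONTRAST_CODING:
        raise ValueError(f"unknown contrast {contrast!r}; "
                         f"choose from {sorted(CONTRAST_CODING)}")
    coding = CONTRAST_CODING[contrast]
    rows: list[tuple[float, list[float], int]] = []
    for subj in ds.subjects:
        g = subj.genotypes.get(snp_id, MISSING)
        if g == MISSING or g not in coding:
            continue
        covs = [_covariate_value(subj, c) for c in covariates]
        if any(v is None for v in covs):
            continue
        rows.append((float(coding[g]), [float(v) for v in covs],
                     1 if subj.status == CASE else 0))
    if not rows:
        raise ValueError(f"{snp_id}/{contrast}: no usable subjects")
    y = np.array([r[2] for r in rows], dtype=float)
    if y.sum() < 2 or (1 - y).sum() < 2:
        raise ValueError(f"{snp_id}/{contrast}: fewer than 2 subjects per outcome class")
    exposure = np.array([r[0] for r in rows])
    X = np.column_stack([exposure] + [np.array([r[1][i] for r in rows])
                                      for i in range(len(covariates))])
    X = sm.add_constant(X, prepend=True)
    names = ["const", "exposure", *covariates]

    result = AdjustedResult(
        snp_id=snp_id, model=contrast, contrast=contrast,
        or_adj=None, ci_low=None, ci_high=None,
        covariates=list(covariates), n_used=len(rows),
    )
    with warnings.catch_warnings():
        warnings.simplefilter("error")  # separation surfaces as a warning
        try:
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200, tol=1e-10)
        except Exception as exc:  # PerfectSeparation*, convergence warnings
            result.converged = False
            result.note = f"not converged: {exc}"
            return result
    if not fit.mle_retvals.get("converged", False):
        result.converged = False
        result.note = "optimizer reported non-convergence"
        return result
    idx = names.index("exposure")
    beta = fit.params[idx]
    se = fit.bse[idx]
    if not np.isfinite(se) or se > 50:
        result.converged = False
        result.note = "quasi-complete separation: unstable standard error"
        return result
    result.or_adj = float(np.exp(beta))
    result.ci_low = float(np.exp(beta - 1.96 * se))
    result.ci_high = float(np.exp(beta + 1.96 * se))
    return result
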