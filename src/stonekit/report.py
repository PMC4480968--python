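"""End-to-end analysis orchestration and report writers.

``run_full_analysis`` ties the stages together — association sweep
(allelic/genotypic/dominant/recessive), HWE per group, pairwise LD,
dosage categories, and trait comparisons — and writes one TSV per table
plus a JSON summary.  Display formatting follows the conventions of the
published tables (ORs/CIs to 2 decimals, frequencies to 2 decimals,
p-values to 3 decimals with a "<0.001" floor); full precision is kept in
the JSON.
"""

from __future__ import annotations

import json
import logging
import shutil
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .association import association_sweep, hwe_chi2, MODELS
from .genotype_data import (
    CASE, CONTROL, CohortDataset, allele_frequency, counts_from_dataset,
)
from .ld import ld_matrix
from .risk_scoring import DosageWeights, default_weights, dosage_category_analysis
from .traits import trait_by_genotype

logger = logging.getLogger(__name__)


def fmt_or(x: float | None) -> str:
    return "" if x is None else f"{x:.2f}"


def fmt_p(p: float | None) -> str:
    if p is None:
        return ""
    return "<0.001" if p < 0.001 else f"{p:.3f}"


@dataclass
class RunConfig:
    genotypes: Path
    phenotypes: Path
    out_dir: Path
    models: tuple[str, ...] = MODELS
    bonferroni_m: int | None = None
    covariates: tuple[str, ...] = ()
    dosage_weights: DosageWeights | None = None
    traits: tuple[str, ...] = ("serum_calcium", "urinary_calcium")
    trait_snps: tuple[str, ...] = ("rs1801725", "rs1042636")
    ld_groups: tuple[str, ...] = (CASE, CONTROL)
    seed: int = 0


def association_table(ds: CohortDataset, models=MODELS,
                      bonferroni_m: int | None = None) -> pd.DataFrame:
    fixture = {sid: counts_from_dataset(ds, sid) for sid in ds.snp_ids}
    results = association_sweep(fixture, models=models, snps=ds.snps,
                                bonferroni_m=bonferroni_m)
    rows = []
    for r in results:
        rows.append({
            "snp": r.snp_id, "model": r.model, "contrast": r.contrast,
            "or": fmt_or(r.or_estimate), "ci_low": fmt_or(r.ci_low),
            "ci_high": fmt_or(r.ci_high), "p": fmt_p(r.p_raw),
            "p_adj": fmt_p(r.p_bonferroni), "test": r.test_used,
        })
    return pd.DataFrame(rows, columns=["snp", "model", "contrast", "or",
                                       "ci_low", "ci_high", "p", "p_adj", "test"])


def hwe_table(ds: CohortDataset) -> pd.DataFrame:
    rows = []
    for sid in ds.snp_ids:
        case, control = counts_from_dataset(ds, sid)
        for gc in (case, control):
            try:
                h = hwe_chi2(gc)
            except ValueError as exc:
                logger.info("HWE %s/%s skipped: %s", sid, gc.group, exc)
                continue
            rows.append({
                "snp": sid, "group": gc.group,
                "alt_freq": f"{allele_frequency(gc):.2f}",
                "chi2": f"{h.chi2:.3f}", "p": fmt_p(h.p),
                "in_hwe": h.in_hwe,
            })
    return pd.DataFrame(rows, columns=["snp", "group", "alt_freq", "chi2", "p", "in_hwe"])


def dosage_table(ds: CohortDataset, weights: DosageWeights | None = None) -> pd.DataFrame:
    res = dosage_category_analysis(ds, weights=weights)
    n_all = len(res.subject_ids)
    rows = []
    for cat in res.categories:
        rows.append({
            "category": cat.label, "n_case": cat.n_case, "n_control": cat.n_control,
            "fraction": f"{cat.n / n_all:.3f}" if n_all else "",
            "or_vs_ref": fmt_or(cat.or_vs_ref),
            "ci_low": fmt_or(cat.ci_low), "ci_high": fmt_or(cat.ci_high),
            "p": fmt_p(cat.p),
        })
    return pd.DataFrame(rows, columns=["category", "n_case", "n_control",
                                       "fraction", "or_vs_ref", "ci_low",
                                       "ci_high", "p"])


def traits_table(ds: CohortDataset, pairs) -> pd.DataFrame:
    rows = []
    for snp_id, trait in pairs:
        for within in (CASE, CONTROL):
            try:
                c = trait_by_genotype(ds, snp_id, trait, grouping="dominant",
                                      within=within)
            except ValueError as exc:
                logger.info("trait %s by %s in %s skipped: %s",
                            trait, snp_id, within, exc)
                continue
            rows.append({
                "snp": snp_id, "trait": trait, "within": within,
                "n_homref": c.n1, "n_carrier": c.n2,
                "mean_homref": f"{c.mean1:.2f}", "sd_homref": f"{c.sd1:.2f}",
                "mean_carrier": f"{c.mean2:.2f}", "sd_carrier": f"{c.sd2:.2f}",
                "p": fmt_p(c.p), "test": c.test,
            })
    return pd.DataFrame(rows, columns=["snp", "trait", "within", "n_homref",
                                       "n_carrier", "mean_homref", "sd_homref",
                                       "mean_carrier", "sd_carrier", "p", "test"])


def run_full_analysis(ds: CohortDataset, cfg: RunConfig) -> dict[str, Path]:
    """Run every stage on ``ds`` and write the report bundle under cfg.out_dir.

    Emits assoc.tsv, hwe.tsv, ld_<group>.tsv, dosage.tsv, traits.tsv and
    summary.json.  Any stage failure removes partial outputs and
    re-raises with the stage name.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    stage = "setup"
    try:
        stage = "association"
        df = association_table(ds, models=cfg.models, bonferroni_m=cfg.bonferroni_m)
        written["assoc"] = out / "assoc.tsv"
        df.to_csv(written["assoc"], sep="\t", index=False)

        stage = "hwe"
        hwe_table(ds).to_csv(out / "hwe.tsv", sep="\t", index=False)
        written["hwe"] = out / "hwe.tsv"

        stage = "ld"
        for grp in cfg.ld_groups:
            m = ld_matrix(ds, group=grp)
            p = out / f"ld_{grp}.tsv"
            m.round(6).to_csv(p, sep="\t")
            written[f"ld_{grp}"] = p

        stage = "dosage"
        dosage_table(ds, weights=cfg.dosage_weights).to_csv(
            out / "dosage.tsv", sep="\t", index=False)
        written["dosage"] = out / "dosage.tsv"

        stage = "traits"
        pairs = list(zip(cfg.trait_snps, cfg.traits))
        traits_table(ds, pairs).to_csv(out / "traits.tsv", sep="\t", index=False)
        written["traits"] = out / "traits.tsv"

        stage = "summary"
        summary = {
            "stonekit_version": __version__,
            "seed": cfg.seed,
            "n_case": ds.n_case,
            "n_control": ds.n_control,
            "snps": ds.snp_ids,
            "tables": {k: str(v) for k, v in written.items()},
        }
        (out / "summary.json").write_text(json.dumps(summary, indent=2))
        written["summary"] = out / "summary.json"
    except Exception as exc:
        for p in written.values():
            p.unlink(missing_ok=True)
        raise RuntimeError(f"analysis stage {stage!r} failed: {exc}") from exc
    return written


def ld_heatmap(matrix: pd.DataFrame, path: Path, title: str = "") -> None:
    """Grayscale r^2 heatmap: white r2=0, gray intermediate, black r2=1."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    ax.imshow(matrix.to_numpy(), cmap="Greys", vmin=0, vmax=1)
    ax.set_xticks(range(len(matrix.columns)), matrix.columns, rotation=90)
    ax.set_yticks(range(len(matrix.index)), matrix.index)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def dosage_barplot(table: pd.DataFrame, path: Path) -> None:
    """Bar plot of category ORs against the reference dosage category."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    plotted = table[table["or_vs_ref"] != ""]
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.bar(plotted["category"], plotted["or_vs_ref"].astype(float), color="0.4")
    ax.set_xlabel("effective risk alleles")
    ax.set_ylabel("OR vs reference")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
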