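"""Table loading/validation, run orchestration and reporting.

The on-disk interchange format is plain CSV with the column schemas
used throughout the package (fish tables, droplet tables, paired diet
tables). ``run_screen`` ties the per-gene statistics together across a
whole screen: per-gene analyses with fault isolation (one failing gene
does not abort the run), family-wise BH-FDR, hit classification, and a
per-gene results table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import screen as sc
from .simulate import FISH_COLUMNS

__all__ = ["load_fish_table", "load_paired_diet_table", "run_screen",
           "ScreenRun", "decode_groups"]

log = logging.getLogger(__name__)

PAIRED_DIET_COLUMNS = ["fish_id", "genotype", "diet", "timepoint", "stratum",
                       "mean_feret"]

VALID_GENOTYPES = {"control", "mutant"}
VALID_DIETS = {"control", "HFD"}


def load_fish_table(path) -> pd.DataFrame:
    """Load and validate a per-fish CSV (one row per fish).

    Required columns: fish_id, gene, genotype (control|mutant),
    experiment, standard_length, sat_area, total_lipid_area, mean_feret,
    n_droplets. Rejects unknown genotype values and duplicate fish ids
    within a gene+experiment.
    """
    df = pd.read_csv(path)
    missing = [c for c in FISH_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"fish table is missing required columns: {missing}")
    bad = set(df["genotype"].unique()) - VALID_GENOTYPES
    if bad:
        raise ValueError(f"unknown genotype values: {sorted(bad)}")
    dup = df.duplicated(subset=["gene", "experiment", "fish_id"])
    if dup.any():
        raise ValueError(
            f"duplicate fish_id within gene+experiment: "
            f"{df.loc[dup, 'fish_id'].tolist()[:5]}")
    return df


def load_paired_diet_table(path) -> pd.DataFrame:
    """Load and validate a paired diet observation CSV."""
    df = pd.read_csv(path)
    missing = [c for c in PAIRED_DIET_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"paired diet table is missing columns: {missing}")
    bad = set(df["diet"].unique()) - VALID_DIETS
    if bad:
        raise ValueError(f"unknown diet values: {sorted(bad)}")
    return df


def decode_groups(df: pd.DataFrame, code_map: dict, column: str = "genotype"
                  ) -> pd.DataFrame:
    """Replace coded group labels using a code map (blinded analysis
    support: data can be analysed under opaque codes and decoded only
    for reporting)."""
    unknown = set(df[column].unique()) - set(code_map)
    if unknown:
        raise ValueError(f"labels missing from code map: {sorted(unknown)}")
    out = df.copy()
    out[column] = out[column].map(code_map)
    return out


@dataclass
class ScreenRun:
    """Results bundle of a full screen analysis."""

    results: dict  # gene -> GeneScreenResult
    table: pd.DataFrame
    exclusions: list = field(default_factory=list)


def run_screen(
    fish: pd.DataFrame,
    lethal_genes: tuple = (),
    alpha: float = 0.05,
    power_d: float = 0.8,
) -> ScreenRun:
    """Analyse every gene in a fish table and assemble the screen report.

    Per gene: pooled and stratified KS tests, LMM intercept and slope
    models, power at ``power_d``; then BH-FDR within each of the four
    test families (pooled KS, stratified KS, LMM intercept, LMM slope)
    across the multi-experiment genes, and the dual-criterion hit
    classification. Lethal genes and genes whose analysis fails are
    carried through with a status and excluded from FDR families.
    """
    results: dict = {}
    exclusions: list = []
    genes = list(dict.fromkeys(fish["gene"])) if len(fish) else []
    for gene in list(lethal_genes):
        results[gene] = sc.GeneScreenResult(gene=gene, status="lethal")
        exclusions.append((gene, "lethal before phenotyping"))
    for gene in genes:
        if gene in results:
            continue
        data = fish[fish["gene"] == gene]
        try:
            results[gene] = sc.analyze_gene(gene, data, power_d=power_d,
                                            alpha=alpha)
            if results[gene].status == "single-experiment":
                exclusions.append((gene, "single experiment: OLS route, no FDR"))
        except Exception as exc:  # gene-level fault isolation
            log.warning("gene %s failed: %s", gene, exc)
            results[gene] = sc.GeneScreenResult(gene=gene, status="failed",
                                                error=str(exc))
            exclusions.append((gene, f"analysis failed: {exc}"))

    ok = [r for r in results.values() if r.status == "ok"]
    if ok:
        families = {
            "ks_pooled": [r.ks_pooled.p for r in ok],
            "ks_stratified": [r.ks_stratified.p for r in ok],
            "lmm_intercept": [r.lmm.p for r in ok],
            "lmm_slope": [r.lmm_slope.p for r in ok],
        }
        adjusted = {k: sc.adjust_fdr(v) for k, v in families.items()}
        for i, r in enumerate(ok):
            r.adjusted = {k: float(adjusted[k][i]) for k in families}
        frame = pd.DataFrame(
            {
                "ks_pooled_p": [r.ks_pooled.p for r in ok],
                "ks_stratified_adj_p": [r.adjusted["ks_stratified"] for r in ok],
                "lmm_adj_p": [r.adjusted["lmm_intercept"] for r in ok],
            },
            index=[r.gene for r in ok],
        )
        classes = sc.classify_hits(frame, alpha=alpha)
        for r in ok:
            r.classification = classes[r.gene]

    rows = []
    for r in results.values():
        row = {
            "gene": r.gene, "status": r.status,
            "n_experiments": r.n_experiments,
            "n_control": r.n_control, "n_mutant": r.n_mutant,
            "classification": r.classification, "direction": r.direction,
            "power_d08_pct": None if r.power_d08 is None else 100 * r.power_d08,
            "consistency": r.consistency,
        }
        if r.status == "ok":
            row.update(
                ks_effect_um=r.ks_stratified.effect,
                ks_pooled_p=r.ks_pooled.p,
                ks_pooled_adj_p=r.adjusted.get("ks_pooled"),
                ks_stratified_p=r.ks_stratified.p,
                ks_stratified_adj_p=r.adjusted.get("ks_stratified"),
                lmm_pct_change=r.lmm.pct_change,
                lmm_p=r.lmm.p,
                lmm_adj_p=r.adjusted.get("lmm_intercept"),
                lmm_ci_low=r.lmm.ci_low, lmm_ci_high=r.lmm.ci_high,
                slope_beta=r.lmm_slope.beta,
                slope_p=r.lmm_slope.p,
                slope_adj_p=r.adjusted.get("lmm_slope"),
            )
        elif r.status == "single-experiment":
            row.update(ks_pooled_p=r.single.ks_p,
                       lmm_pct_change=r.single.pct_change, lmm_p=r.single.p)
        rows.append(row)
    table = pd.DataFrame(rows)
    return ScreenRun(results=results, table=table, exclusions=exclusions)
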