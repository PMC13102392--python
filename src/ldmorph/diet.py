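"""Paired baseline/post-diet spatial analysis of adipose expansion.

The same fish are imaged before and after a two-week dietary challenge
(high-fat diet by egg-yolk immersion vs control diet), with the depot
divided into 200 µm anterior-posterior strata. The diet effect per
stratum and genotype is a difference-in-differences: the mean
within-fish change (post - baseline) on HFD minus the mean change on
control diet. Per-stratum p-values are BH-adjusted within genotype.
Averaging the per-stratum effects gives each genotype's overall
hypertrophic response; a mutant's *blunting* is reported as the percent
reduction relative to wild-type.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .screen import adjust_fdr

__all__ = [
    "paired_changes",
    "stratum_diet_effect",
    "baseline_genotype_contrast",
    "overall_diet_contrast",
    "diet_response_table",
]

MIN_FISH_PER_DIET_GROUP = 3

PAIRED_COLUMNS = ["fish_id", "genotype", "diet", "timepoint", "stratum", "mean_feret"]


def paired_changes(observations: pd.DataFrame) -> pd.DataFrame:
    """Per-fish, per-stratum change in mean Feret diameter (post - baseline).

    Strata observed at only one timepoint for a fish — typically new
    posterior growth appearing after the diet — are flagged as emergent
    and excluded from paired contrasts. Raises if a fish lacks a
    timepoint entirely.
    """
    obs = observations
    missing = [c for c in PAIRED_COLUMNS if c not in obs.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    for fid, grp in obs.groupby("fish_id"):
        tps = set(grp["timepoint"])
        if not {"baseline", "post"} <= tps:
            raise ValueError(f"fish {fid!r} lacks a timepoint (has {sorted(tps)})")
    wide = obs.pivot_table(
        index=["fish_id", "genotype", "diet", "stratum"],
        columns="timepoint", values="mean_feret", aggfunc="first",
    ).reset_index()
    wide["emergent"] = wide["baseline"].isna() | wide["post"].isna()
    wide["delta"] = wide["post"] - wide["baseline"]
    return wide[["fish_id", "genotype", "diet", "stratum", "baseline", "post",
                 "delta", "emergent"]]


def stratum_diet_effect(
    deltas: pd.DataFrame,
    genotype: str,
    alpha: float = 0.05,
    min_n: int = MIN_FISH_PER_DIET_GROUP,
) -> pd.DataFrame:
    """Per-stratum HFD effect for one genotype, with BH across strata.

    Effect = mean delta(HFD) - mean delta(control diet); p from Welch's
    t-test with the fish as the observational unit (each fish
    contributes one delta per stratum). Strata with fewer than ``min_n``
    fish in either diet group are reported untestable (NaN p, excluded
    from the FDR family).
    """
    d = deltas[(deltas["genotype"] == genotype) & ~deltas["emergent"]]
    rows = []
    for stratum, grp in d.groupby("stratum"):
        hfd = grp.loc[grp["diet"] == "HFD", "delta"].to_numpy(dtype=float)
        ctl = grp.loc[grp["diet"] == "control", "delta"].to_numpy(dtype=float)
        row = {"genotype": genotype, "stratum": stratum,
               "n_hfd": len(hfd), "n_control": len(ctl)}
        if len(hfd) < min_n or len(ctl) < min_n:
            row.update(diet_effect=np.nan, p=np.nan, testable=False)
        else:
            res = stats.ttest_ind(hfd, ctl, equal_var=False)
            row.update(diet_effect=float(hfd.mean() - ctl.mean()),
                       p=float(res.pvalue), testable=True)
        rows.append(row)
    out = pd.DataFrame(rows).sort_values("stratum").reset_index(drop=True)
    out["adj_p"] = np.nan
    testable = out["testable"]
    if testable.any():
        out.loc[testable, "adj_p"] = adjust_fdr(out.loc[testable, "p"])
    out["significant"] = out["adj_p"] < alpha
    return out


def baseline_genotype_contrast(
    observations: pd.DataFrame,
    reference_genotype: str,
    test_genotype: str,
    strata: list | None = None,
    alpha: float = 0.05,
    min_n: int = MIN_FISH_PER_DIET_GROUP,
) -> pd.DataFrame:
    """Per-stratum baseline LD-size difference between genotypes.

    Compares mean Feret diameter at the baseline timepoint,
    ``test_genotype`` minus ``reference_genotype``, stratum by stratum
    (Welch's t, BH across strata). ``strata`` restricts the comparison
    to a subset (e.g. the anterior strata present in both genotypes).
    """
    base = observations[observations["timepoint"] == "baseline"]
    if strata is not None:
        base = base[base["stratum"].isin(strata)]
    rows = []
    for stratum, grp in base.groupby("stratum"):
        ref = grp.loc[grp["genotype"] == reference_genotype, "mean_feret"].to_numpy(float)
        tst = grp.loc[grp["genotype"] == test_genotype, "mean_feret"].to_numpy(float)
        row = {"stratum": stratum, "n_reference": len(ref), "n_test": len(tst)}
        if len(ref) < min_n or len(tst) < min_n:
            row.update(difference=np.nan, p=np.nan, testable=False)
        else:
            res = stats.ttest_ind(tst, ref, equal_var=False)
            row.update(difference=float(tst.mean() - ref.mean()),
                       p=float(res.pvalue), testable=True)
        rows.append(row)
    out = pd.DataFrame(rows).sort_values("stratum").reset_index(drop=True)
    out["adj_p"] = np.nan
    testable = out["testable"]
    if testable.any():
        out.loc[testable, "adj_p"] = adjust_fdr(out.loc[testable, "p"])
    out["significant"] = out["adj_p"] < alpha
    return out


def overall_diet_contrast(
    wildtype_effects, mutant_effects
) -> tuple[float, float, int]:
    """Overall (stratum-averaged) diet effects and the mutant blunting.

    Inputs are per-stratum diet effects (µm) for each genotype — scalars
    are accepted for already-averaged values. Returns the two unweighted
    stratum means and the percent reduction,
    ``100 * (wt - mut) / wt`` rounded to the nearest integer.
    """
    wt = float(np.mean(np.atleast_1d(np.asarray(wildtype_effects, dtype=float))))
    mut = float(np.mean(np.atleast_1d(np.asarray(mutant_effects, dtype=float))))
    if abs(wt) < 1e-12:
        raise ValueError("wild-type diet effect is ~0: percent reduction undefined")
    reduction = int(round(100.0 * (wt - mut) / wt))
    return wt, mut, reduction


def diet_response_table(
    observations: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """Full per-genotype, per-stratum diet-effect table from raw paired
    observations."""
    deltas = paired_changes(observations)
    pieces = [
        stratum_diet_effect(deltas, g, alpha=alpha)
        for g in observations["genotype"].unique()
    ]
    return pd.concat(pieces, ignore_index=True)
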