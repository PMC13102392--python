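"""Per-gene screening statistics for batched F0 CRISPR morphology screens.

Each gene is assayed in 2-3 independent injection experiments, each with
its own Cas9-only control fish. Batch (experiment) effects are the main
false-positive risk, so two complementary views are combined:

* **Distribution tests** — two-sample Kolmogorov-Smirnov tests on
  morphology values, both pooled across experiments and stratified
  within each experiment (experiment-specific control smoothers) with
  per-experiment p-values combined by Fisher's method
  (chi2 = -2 * sum(ln p_i), df = 2k).
* **Mixed models** — ``log(Feret) ~ log(AreaSum) + Genotype +
  (1|Experiment)`` for a uniform log-scale diameter shift, and the
  ``log(AreaSum) x Genotype`` interaction model for allometric slope
  changes. Genotype effects are back-transformed to percentage change,
  ``(exp(beta) - 1) * 100``.

Benjamini-Hochberg FDR is applied separately per test family; a gene is
a *robust* hit only when both the stratified KS test and the LMM
intercept test survive FDR — a dual criterion that guards against batch
artifacts. Effect size (Cohen's d) and noncentral-t power calculations
support design of follow-up experiments.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests

from .morphology import morphology_table

__all__ = [
    "ks_two_sample",
    "fisher_combine",
    "pooled_ks_test",
    "stratified_ks_test",
    "fit_lmm_intercept",
    "fit_lmm_interaction",
    "fit_trait_lmm",
    "single_experiment_analysis",
    "adjust_fdr",
    "classify_hits",
    "cohens_d",
    "power_two_sample",
    "sample_size_for_power",
    "compute_consistency",
    "KsResult",
    "StratifiedKsResult",
    "LmmResult",
    "GeneScreenResult",
]

log = logging.getLogger(__name__)

MIN_N_PER_EXPERIMENT = 5  # per genotype, for the stratified KS test


# ---------------------------------------------------------------------------
# distribution tests


def ks_two_sample(a, b) -> tuple[float, float]:
    """Two-sample KS test: D = sup |ECDF_a - ECDF_b| and two-sided p.

    Uses the exact null distribution for small samples and the
    asymptotic one otherwise (scipy's ``method='auto'`` switch).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("empty sample")
    res = stats.ks_2samp(a, b, method="auto")
    return float(res.statistic), float(res.pvalue)


def fisher_combine(p_list) -> tuple[float, int, float]:
    """Fisher's method: chi2 = -2 sum(ln p_i) on 2k df; returns (chi2, df, p)."""
    p = np.asarray(list(p_list), dtype=float)
    if len(p) == 0:
        raise ValueError("no p-values to combine")
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    chi2 = float(-2.0 * np.log(p).sum())
    df = 2 * len(p)
    return chi2, df, float(stats.chi2.sf(chi2, df))


@dataclass
class KsResult:
    d: float
    p: float
    effect: float  # mutant mean - control mean morphology value, µm
    n_control: int
    n_mutant: int


def _split(gene_data: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    ctrl = gene_data[gene_data["genotype"] == "control"]
    mut = gene_data[gene_data["genotype"] == "mutant"]
    return ctrl, mut


def pooled_ks_test(gene_data: pd.DataFrame, basis_dim: int = 10) -> KsResult:
    """KS test of control residuals vs mutant deviations, pooled fit.

    One smoother is fitted to all the gene's matched controls pooled
    across experiments; mutants are scored against it.
    """
    ctrl, mut = _split(gene_data)
    tab = morphology_table(ctrl, mut, scope="pooled", basis_dim=basis_dim)
    cv = tab.loc[tab["role"] == "control", "morphology_value_um"].to_numpy()
    mv = tab.loc[tab["role"] == "mutant", "morphology_value_um"].to_numpy()
    d, p = ks_two_sample(cv, mv)
    return KsResult(d=d, p=p, effect=float(mv.mean() - cv.mean()),
                    n_control=len(cv), n_mutant=len(mv))


@dataclass
class StratifiedKsResult:
    per_experiment_p: dict
    chi2: float
    df: int
    p: float
    effect: float  # sample-size-weighted mean per-experiment effect, µm
    n_experiments: int


def stratified_ks_test(
    gene_data: pd.DataFrame,
    basis_dim: int = 10,
    min_n: int = MIN_N_PER_EXPERIMENT,
) -> StratifiedKsResult:
    """Within-experiment KS tests combined with Fisher's method.

    Each experiment gets its own control smoother; the per-experiment
    mutant-vs-control KS p-values are Fisher-combined, and the effect is
    the sample-size-weighted mean of per-experiment (mutant mean -
    control mean) morphology values. Experiments with fewer than
    ``min_n`` fish in either genotype are skipped.
    """
    per_p: dict = {}
    effects, weights = [], []
    for exp, grp in gene_data.groupby("experiment", sort=False):
        ctrl, mut = _split(grp)
        if len(ctrl) < min_n or len(mut) < min_n:
            log.warning("stratified KS: experiment %r skipped (n ctrl=%d, mut=%d "
                        "below minimum %d)", exp, len(ctrl), len(mut), min_n)
            continue
        tab = morphology_table(ctrl, mut, scope="pooled", basis_dim=basis_dim,
                               min_controls=min_n)
        cv = tab.loc[tab["role"] == "control", "morphology_value_um"].to_numpy()
        mv = tab.loc[tab["role"] == "mutant", "morphology_value_um"].to_numpy()
        _, p = ks_two_sample(cv, mv)
        per_p[exp] = p
        effects.append(mv.mean() - cv.mean())
        weights.append(len(grp))
    if not per_p:
        raise ValueError("no experiment meets the per-experiment minimum n")
    chi2, df, p = fisher_combine(list(per_p.values()))
    effect = float(np.average(effects, weights=weights))
    return StratifiedKsResult(per_experiment_p=per_p, chi2=chi2, df=df, p=p,
                              effect=effect, n_experiments=len(per_p))


# ---------------------------------------------------------------------------
# mixed models


@dataclass
class LmmResult:
    beta: float
    se: float
    p: float
    pct_change: float
    ci_low: float
    ci_high: float
    converged: bool
    n_experiments: int
    batch_sd: float  # random-intercept SD on the log scale


def _prep_lmm_frame(gene_data: pd.DataFrame) -> pd.DataFrame:
    d = gene_data.copy()
    if (d["mean_feret"] <= 0).any() or (d["sat_area"] <= 0).any():
        raise ValueError("log-scale model requires positive mean_feret and sat_area")
    d["log_feret"] = np.log(d["mean_feret"].astype(float))
    d["log_area"] = np.log(d["sat_area"].astype(float))
    d["is_mutant"] = (d["genotype"] == "mutant").astype(float)
    return d


def pct_change_from_beta(beta: float) -> float:
    """Back-transform a log-scale coefficient to percent change."""
    return (np.exp(beta) - 1.0) * 100.0


def _robust_mixedlm_fit(model):
    """REML fit with optimizer fallbacks (lbfgs can hit singular steps on
    boundary-variance data)."""
    last = None
    for method in ("lbfgs", "powell", "cg"):
        try:
            return model.fit(reml=True, method=[method])
        except (np.linalg.LinAlgError, ValueError) as exc:
            last = exc
    raise RuntimeError(f"mixed model failed to converge: {last}")


def _fit_mixedlm(formula: str, d: pd.DataFrame, term: str) -> tuple:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(formula, d, groups=d["experiment"])
        res = _robust_mixedlm_fit(model)
    beta = float(res.params[term])
    se = float(res.bse[term])
    p = float(2.0 * stats.norm.sf(abs(beta / se)))  # Wald z
    batch_sd = float(np.sqrt(max(res.cov_re.iloc[0, 0], 0.0)))
    return beta, se, p, bool(res.converged), batch_sd


def fit_lmm_intercept(gene_data: pd.DataFrame) -> LmmResult:
    """Random-intercept LMM: log(Feret) ~ log(AreaSum) + Genotype + (1|Experiment).

    Tests for a uniform (depot-size-independent) log-scale shift in LD
    diameter. Fit by REML; genotype p-value is a two-sided Wald z test.
    The genotype effect is back-transformed to percent change with a
    95% CI, ``(exp(beta +/- 1.96*SE) - 1) * 100``.
    """
    d = _prep_lmm_frame(gene_data)
    n_exp = d["experiment"].nunique()
    if n_exp < 2:
        raise ValueError("mixed model needs >= 2 experiments; use "
                         "single_experiment_analysis for one experiment")
    if d["is_mutant"].nunique() < 2:
        raise ValueError("both genotypes must be present")
    beta, se, p, conv, batch_sd = _fit_mixedlm(
        "log_feret ~ log_area + is_mutant", d, "is_mutant")
    return LmmResult(
        beta=beta, se=se, p=p,
        pct_change=pct_change_from_beta(beta),
        ci_low=pct_change_from_beta(beta - 1.96 * se),
        ci_high=pct_change_from_beta(beta + 1.96 * se),
        converged=conv, n_experiments=n_exp, batch_sd=batch_sd,
    )


def fit_lmm_interaction(gene_data: pd.DataFrame) -> LmmResult:
    """Interaction LMM: log(Feret) ~ log(AreaSum) x Genotype + (1|Experiment).

    The returned coefficient is the genotype difference in allometric
    slope (log-log scale); a significant interaction means the phenotype
    magnitude depends on depot size.
    """
    d = _prep_lmm_frame(gene_data)
    n_exp = d["experiment"].nunique()
    if n_exp < 2:
        raise ValueError("mixed model needs >= 2 experiments")
    beta, se, p, conv, batch_sd = _fit_mixedlm(
        "log_feret ~ log_area * is_mutant", d, "log_area:is_mutant")
    return LmmResult(
        beta=beta, se=se, p=p,
        pct_change=pct_change_from_beta(beta),
        ci_low=pct_change_from_beta(beta - 1.96 * se),
        ci_high=pct_change_from_beta(beta + 1.96 * se),
        converged=conv, n_experiments=n_exp, batch_sd=batch_sd,
    )


def fit_trait_lmm(
    gene_data: pd.DataFrame, trait: str, length_exponent: float = 2.0
) -> LmmResult:
    """Genotype effect on a whole-fish trait: log(trait) ~ Genotype + (1|Exp).

    ``trait`` is ``standard_length`` (mm) or ``total_adiposity``; total
    adiposity is the total lipid area normalized by standard length to
    the ``length_exponent`` power (default 2, giving a dimensionless
    relative adiposity).
    """
    d = gene_data.copy()
    if trait == "standard_length":
        y = d["standard_length"].astype(float)
    elif trait == "total_adiposity":
        y = d["total_lipid_area"].astype(float) / d["standard_length"].astype(float) ** length_exponent
    else:
        raise ValueError(f"unknown trait: {trait!r}")
    if (y <= 0).any():
        raise ValueError("trait values must be positive for the log model")
    d["log_trait"] = np.log(y)
    d["is_mutant"] = (d["genotype"] == "mutant").astype(float)
    if d["experiment"].nunique() < 2:
        raise ValueError("mixed model needs >= 2 experiments")
    beta, se, p, conv, batch_sd = _fit_mixedlm("log_trait ~ is_mutant", d, "is_mutant")
    return LmmResult(
        beta=beta, se=se, p=p,
        pct_change=pct_change_from_beta(beta),
        ci_low=pct_change_from_beta(beta - 1.96 * se),
        ci_high=pct_change_from_beta(beta + 1.96 * se),
        converged=conv, n_experiments=d["experiment"].nunique(), batch_sd=batch_sd,
    )


@dataclass
class SingleExperimentResult:
    """OLS + KS analysis for a gene assayed in a single experiment.

    Flagged preliminary: no batch correction is possible and the result
    is excluded from FDR families.
    """

    beta: float
    se: float
    p: float
    pct_change: float
    ks_d: float
    ks_p: float
    preliminary: bool = True


def single_experiment_analysis(gene_data: pd.DataFrame) -> SingleExperimentResult:
    """OLS log(Feret) ~ log(AreaSum) + Genotype plus a pooled KS test."""
    d = _prep_lmm_frame(gene_data)
    if d["experiment"].nunique() != 1:
        raise ValueError("single-experiment analysis requires exactly one experiment")
    if d["is_mutant"].nunique() < 2:
        raise ValueError("both genotypes must be present")
    res = smf.ols("log_feret ~ log_area + is_mutant", d).fit()
    ks = pooled_ks_test(gene_data)
    beta = float(res.params["is_mutant"])
    return SingleExperimentResult(
        beta=beta, se=float(res.bse["is_mutant"]), p=float(res.pvalues["is_mutant"]),
        pct_change=pct_change_from_beta(beta), ks_d=ks.d, ks_p=ks.p,
    )


# ---------------------------------------------------------------------------
# multiple testing, classification, effect size, power

FDR_FAMILIES = ("ks_pooled", "ks_stratified", "lmm_intercept", "lmm_slope")


def adjust_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values for one test family."""
    p = np.asarray(list(p_values), dtype=float)
    if len(p) == 0:
        raise ValueError("empty p-value family")
    return multipletests(p, method="fdr_bh")[1]


def classify_hits(results: pd.DataFrame, alpha: float = 0.05) -> pd.Series:
    """Classify genes from their (adjusted) p-values.

    * ``robust`` — stratified KS *and* LMM intercept both FDR-significant
      (the dual criterion: the distributional effect reproduces within
      experiments and the mean shift survives batch correction);
    * ``distributional-only`` — stratified KS significant, LMM not;
    * ``suggestive`` — only the raw pooled KS p < alpha
      (requires a ``ks_pooled_p`` column; skipped if absent);
    * ``ns`` — otherwise.
    """
    strat = results["ks_stratified_adj_p"] < alpha
    lmm = results["lmm_adj_p"] < alpha
    out = pd.Series("ns", index=results.index, dtype=object)
    if "ks_pooled_p" in results.columns:
        out[results["ks_pooled_p"] < alpha] = "suggestive"
    out[strat & ~lmm] = "distributional-only"
    out[strat & lmm] = "robust"
    return out


def cohens_d(a, b) -> float:
    """Standardized mean difference with (n-1)-weighted pooled SD."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs n >= 2")
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if sp2 == 0:
        raise ValueError("zero pooled SD")
    return float((a.mean() - b.mean()) / np.sqrt(sp2))


def power_two_sample(
    n1: int, n2: int, d: float, alpha: float = 0.05, two_sided: bool = True
) -> float:
    """Power of the two-sample t-test at standardized effect size d.

    Noncentral-t calculation: ncp = d * sqrt(n1*n2/(n1+n2)),
    df = n1 + n2 - 2.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if d < 0:
        raise ValueError("d must be >= 0")
    df = n1 + n2 - 2
    ncp = d * np.sqrt(n1 * n2 / (n1 + n2))
    if two_sided:
        tc = stats.t.ppf(1 - alpha / 2, df)
        upper = stats.nct.sf(tc, df, ncp)
        lower = stats.nct.cdf(-tc, df, ncp)  # negligible wrong-tail mass can
        if not np.isfinite(lower):          # underflow to nan at large ncp
            lower = 0.0
        return float(min(upper + lower, 1.0))
    tc = stats.t.ppf(1 - alpha, df)
    return float(stats.nct.sf(tc, df, ncp))


def sample_size_for_power(
    d: float,
    power: float = 0.8,
    alpha: float = 0.05,
    n_control: int | None = None,
    two_sided: bool = True,
    max_n: int = 100_000,
) -> int:
    """Smallest mutant group size reaching the requested power.

    With ``n_control=None`` both groups grow together (equal
    allocation); otherwise the control group is fixed and only the
    mutant group is sized.
    """
    if not 0 < power < 1:
        raise ValueError("power must lie in (0, 1)")
    for n in range(2, max_n + 1):
        n1 = n if n_control is None else n_control
        if power_two_sample(n1, n, d, alpha=alpha, two_sided=two_sided) >= power:
            return n
    raise ValueError(f"power {power} unreachable within n <= {max_n}")


def compute_consistency(per_experiment_effects) -> float:
    """Replicate consistency score in [0, 1].

    Agreement in direction and magnitude across experiment-level
    effects: (fraction of effect pairs with the same sign) x
    1/(1 + CV), where CV = SD/|mean|. Identical replicate effects score
    1; sign-discordant replicates score towards 0.
    """
    e = np.asarray(list(per_experiment_effects), dtype=float)
    if len(e) < 2:
        raise ValueError("need >= 2 experiment-level effects")
    pairs = [(i, j) for i in range(len(e)) for j in range(i + 1, len(e))]
    agree = np.mean([np.sign(e[i]) == np.sign(e[j]) and e[i] != 0 for i, j in pairs])
    mean = e.mean()
    if mean == 0:
        return float(agree) * 0.0
    cv = e.std(ddof=1) / abs(mean)
    return float(agree / (1.0 + cv))


# ---------------------------------------------------------------------------
# per-gene orchestration


@dataclass
class GeneScreenResult:
    """All per-gene statistics; adjusted p-values are filled in across
    genes by the run-level FDR step."""

    gene: str
    status: str  # "ok" | "single-experiment" | "lethal" | "failed"
    n_experiments: int = 0
    n_control: int = 0
    n_mutant: int = 0
    ks_pooled: KsResult | None = None
    ks_stratified: StratifiedKsResult | None = None
    lmm: LmmResult | None = None
    lmm_slope: LmmResult | None = None
    single: SingleExperimentResult | None = None
    consistency: float | None = None
    power_d08: float | None = None
    direction: str | None = None
    adjusted: dict = field(default_factory=dict)
    classification: str | None = None
    error: str | None = None


def analyze_gene(
    gene: str,
    gene_data: pd.DataFrame,
    lethal: bool = False,
    power_d: float = 0.8,
    alpha: float = 0.05,
) -> GeneScreenResult:
    """Run the full per-gene analysis (KS tests, LMMs, power, consistency).

    Genes lethal before phenotyping are passed through with status
    ``lethal`` and no statistics; they are excluded from FDR families.
    """
    if lethal:
        return GeneScreenResult(gene=gene, status="lethal")
    ctrl, mut = _split(gene_data)
    n_exp = gene_data["experiment"].nunique()
    res = GeneScreenResult(gene=gene, status="ok", n_experiments=n_exp,
                           n_control=len(ctrl), n_mutant=len(mut))
    if len(ctrl) >= 2 and len(mut) >= 2:
        res.power_d08 = power_two_sample(len(ctrl), len(mut), power_d, alpha=alpha)
    if n_exp == 1:
        res.status = "single-experiment"
        res.single = single_experiment_analysis(gene_data)
        res.direction = "hypertrophic" if res.single.beta > 0 else "hyperplastic"
        return res
    res.ks_pooled = pooled_ks_test(gene_data)
    res.ks_stratified = stratified_ks_test(gene_data)
    res.lmm = fit_lmm_intercept(gene_data)
    res.lmm_slope = fit_lmm_interaction(gene_data)
    res.direction = "hypertrophic" if res.ks_stratified.effect > 0 else "hyperplastic"
    # experiment-level mean morphology-value differences for consistency
    effs = []
    for _, grp in gene_data.groupby("experiment", sort=False):
        c, m = _split(grp)
        if len(c) >= MIN_N_PER_EXPERIMENT and len(m) >= MIN_N_PER_EXPERIMENT:
            tab = morphology_table(c, m, scope="pooled")
            cv = tab.loc[tab["role"] == "control", "morphology_value_um"]
            mv = tab.loc[tab["role"] == "mutant", "morphology_value_um"]
            effs.append(mv.mean() - cv.mean())
    if len(effs) >= 2:
        res.consistency = compute_consistency(effs)
    return res
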