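"""Sensitivity analyses for screen hits.

Mean-shift tests can be fooled by variance changes, heavy tails or
model misspecification, so each candidate gene is re-examined with:

* an F-test and higher-order moments for variance heterogeneity
  between genotypes;
* a heteroscedastic mixed model (random experiment intercept, separate
  residual variances per genotype) fit by profiled maximum likelihood;
* a within-experiment permutation test of the genotype effect;
* Welch's t-test on morphology values (no equal-variance assumption).

The three inferential checks are summarized by a consensus label:
``ALL SIG`` (every method p < alpha), ``ALL NS`` (none significant), or
``MIXED``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats, optimize
import statsmodels.formula.api as smf

from .morphology import morphology_table
from .screen import _prep_lmm_frame, _split

__all__ = [
    "variance_f_test",
    "distribution_moments",
    "heteroscedastic_lmm",
    "permutation_test",
    "welch_test",
    "consensus_classify",
    "VarianceStats",
    "HeteroLmmResult",
    "PermutationResult",
]


@dataclass
class VarianceStats:
    variance_ratio: float  # sigma^2(mutant) / sigma^2(control)
    f_p: float  # two-sided
    df_mutant: int
    df_control: int


def variance_f_test(control_values, mutant_values) -> VarianceStats:
    """F-test of equal morphology-value variance between genotypes.

    Ratio is var(mutant)/var(control); the two-sided p doubles the
    smaller tail of F(n_mut-1, n_ctrl-1). BH correction across genes is
    the caller's job.
    """
    c = np.asarray(control_values, dtype=float)
    m = np.asarray(mutant_values, dtype=float)
    if len(c) < 2 or len(m) < 2:
        raise ValueError("each group needs n >= 2")
    vc, vm = c.var(ddof=1), m.var(ddof=1)
    if vc == 0 or vm == 0:
        raise ValueError("zero variance")
    ratio = vm / vc
    dfm, dfc = len(m) - 1, len(c) - 1
    tail = stats.f.sf(ratio, dfm, dfc)
    p = min(1.0, 2.0 * min(tail, 1.0 - tail))
    return VarianceStats(variance_ratio=float(ratio), f_p=float(p),
                         df_mutant=dfm, df_control=dfc)


def distribution_moments(values) -> tuple[float, float, float]:
    """(skewness g1, excess kurtosis g2, tail %) of a sample.

    Moment (biased) definitions: g1 = m3/m2^1.5, g2 = m4/m2^2 - 3.
    Tail % is the percentage of points more than 2 sample SDs from the
    mean.
    """
    x = np.asarray(values, dtype=float)
    if len(x) < 4:
        raise ValueError("need n >= 4")
    if x.var(ddof=0) == 0:
        raise ValueError("zero variance")
    g1 = float(stats.skew(x, bias=True))
    g2 = float(stats.kurtosis(x, fisher=True, bias=True))
    tail = 100.0 * np.mean(np.abs(x - x.mean()) > 2 * x.std(ddof=1))
    return g1, g2, float(tail)


# ---------------------------------------------------------------------------
# heteroscedastic random-intercept model


@dataclass
class HeteroLmmResult:
    beta: float
    se: float
    p: float
    sigma_control: float  # residual SD, control fish (log scale)
    sigma_mutant: float
    sigma_batch: float
    loglik: float
    converged: bool


def _profile_loglik(theta, groups, fix_batch_zero: bool):
    """Profiled ML negative log-likelihood; beta solved by GLS.

    theta = (log sd_batch, log sd_control, log sd_mutant); each group is
    (X, y, is_mutant) for one experiment. V = diag + sd_batch^2 * 11';
    Woodbury keeps everything O(n) per experiment.
    """
    if fix_batch_zero:
        sb2 = 0.0
        sc, sm = np.exp(theta)
    else:
        sb2 = np.exp(theta[0]) ** 2
        sc, sm = np.exp(theta[1]), np.exp(theta[2])
    XtViX = 0.0
    XtViy = 0.0
    logdet = 0.0
    quad_parts = []
    for X, y, mut in groups:
        d = np.where(mut, sm**2, sc**2)
        di = 1.0 / d
        s = di.sum()
        c = sb2 / (1.0 + sb2 * s)
        # V^-1 A = D^-1 A - c * (D^-1 1)(1' D^-1 A)
        ViX = di[:, None] * X - c * np.outer(di, di @ X)
        Viy = di * y - c * di * (di @ y)
        XtViX = XtViX + X.T @ ViX
        XtViy = XtViy + X.T @ Viy
        logdet += np.log(d).sum() + np.log1p(sb2 * s)
        quad_parts.append((X, y, ViX, Viy))
    beta = np.linalg.solve(XtViX, XtViy)
    quad = 0.0
    for X, y, ViX, Viy in quad_parts:
        r_v = Viy - ViX @ beta  # V^-1 (y - X beta)
        quad += (y - X @ beta) @ r_v
    n = sum(len(y) for _, y, _ in groups)
    nll = 0.5 * (logdet + quad + n * np.log(2 * np.pi))
    return nll, beta, XtViX


def heteroscedastic_lmm(gene_data: pd.DataFrame) -> HeteroLmmResult:
    """LMM with per-genotype residual variances, profiled ML.

    Same fixed structure as the intercept model (log Feret on log
    AreaSum + genotype, random experiment intercept) but the residual
    SD is allowed to differ between control and mutant fish. With one
    experiment the batch SD is fixed at zero (unidentifiable), which
    reduces the fit to weighted least squares.
    """
    d = _prep_lmm_frame(gene_data)
    if d["is_mutant"].nunique() < 2:
        raise ValueError("both genotypes must be present")
    groups = []
    for _, grp in d.groupby("experiment", sort=False):
        X = np.column_stack([np.ones(len(grp)), grp["log_area"], grp["is_mutant"]])
        groups.append((X, grp["log_feret"].to_numpy(), grp["is_mutant"].to_numpy(bool)))
    fix_batch = len(groups) == 1
    resid_sd = d.groupby("is_mutant")["log_feret"].std(ddof=1)
    s0 = float(np.nanmean(resid_sd))
    if not np.isfinite(s0) or s0 <= 0:
        s0 = 0.1
    x0 = np.log([s0, s0] if fix_batch else [s0 / 2, s0, s0])

    def objective(theta):
        return _profile_loglik(theta, groups, fix_batch)[0]

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        opt = optimize.minimize(objective, x0, method="Nelder-Mead",
                                options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 4000})
    nll, beta, XtViX = _profile_loglik(opt.x, groups, fix_batch)
    cov = np.linalg.inv(XtViX)
    b, se = float(beta[2]), float(np.sqrt(cov[2, 2]))
    if fix_batch:
        sb, sc, sm = 0.0, *np.exp(opt.x)
    else:
        sb, sc, sm = np.exp(opt.x)
    return HeteroLmmResult(
        beta=b, se=se, p=float(2 * stats.norm.sf(abs(b / se))),
        sigma_control=float(sc), sigma_mutant=float(sm), sigma_batch=float(sb),
        loglik=float(-nll), converged=bool(opt.success),
    )


# ---------------------------------------------------------------------------
# permutation test


@dataclass
class PermutationResult:
    perm_p: float  # add-one estimator, in [1/(B+1), 1]
    raw_proportion: float
    observed: float
    B: int
    seed: int


def permutation_test(
    gene_data: pd.DataFrame,
    B: int = 1000,
    seed: int = 0,
    refit: bool = False,
) -> PermutationResult:
    """Within-experiment permutation test of the genotype effect.

    Genotype labels are shuffled independently within each experiment
    (group counts preserved), and the absolute genotype coefficient of
    the size-adjusted model is recomputed. With ``refit=False``
    (default) variance components are frozen at the observed-data REML
    fit and only the GLS fixed-effect solve is repeated per permutation;
    ``refit=True`` refits the full mixed model each time (slow). For a
    single experiment the statistic is the OLS coefficient either way.

    perm_p = (1 + #{|stat*| >= |stat|}) / (B + 1), which cannot be zero;
    the raw exceedance proportion is also reported.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    d = _prep_lmm_frame(gene_data)
    for exp, grp in d.groupby("experiment"):
        if grp["is_mutant"].nunique() < 2:
            raise ValueError(f"experiment {exp!r} lacks one of the genotypes")
    rng = np.random.default_rng(seed)
    n_exp = d["experiment"].nunique()

    if n_exp >= 2 and refit:
        from .screen import fit_lmm_intercept

        obs = abs(fit_lmm_intercept(d).beta)

        def stat(dd):
            return abs(fit_lmm_intercept(dd).beta)

        exceed = 0
        for _ in range(B):
            dd = d.copy()
            dd["genotype"] = (
                dd.groupby("experiment")["genotype"]
                .transform(lambda s: rng.permutation(s.to_numpy()))
            )
            dd["is_mutant"] = (dd["genotype"] == "mutant").astype(float)
            if stat(dd) >= obs:
                exceed += 1
        return PermutationResult(
            perm_p=(1 + exceed) / (B + 1), raw_proportion=exceed / B,
            observed=obs, B=B, seed=seed)

    # fast path: GLS with frozen variance components (OLS if one experiment)
    if n_exp >= 2:
        from .screen import _robust_mixedlm_fit

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = _robust_mixedlm_fit(
                smf.mixedlm("log_feret ~ log_area + is_mutant", d,
                            groups=d["experiment"]))
        sb2 = max(float(res.cov_re.iloc[0, 0]), 0.0)
        s2 = float(res.scale)
    else:
        sb2, s2 = 0.0, 1.0  # OLS: any common scale gives the same beta

    groups = []
    for _, grp in d.groupby("experiment", sort=False):
        base = np.column_stack([np.ones(len(grp)), grp["log_area"].to_numpy()])
        groups.append((base, grp["log_feret"].to_numpy(),
                       grp["is_mutant"].to_numpy(), len(grp)))

    def gls_beta(mut_cols) -> float:
        XtViX = np.zeros((3, 3))
        XtViy = np.zeros(3)
        for (base, y, _, n), mut in zip(groups, mut_cols):
            X = np.column_stack([base, mut])
            di = np.full(n, 1.0 / s2)
            c = sb2 / (1.0 + sb2 * di.sum())
            ViX = di[:, None] * X - c * np.outer(di, di @ X)
            Viy = di * y - c * di * (di @ y)
            XtViX += X.T @ ViX
            XtViy += X.T @ Viy
        return float(np.linalg.solve(XtViX, XtViy)[2])

    obs = abs(gls_beta([g[2] for g in groups]))
    exceed = 0
    for _ in range(B):
        perm = [rng.permutation(g[2]) for g in groups]
        if abs(gls_beta(perm)) >= obs:
            exceed += 1
    return PermutationResult(
        perm_p=(1 + exceed) / (B + 1), raw_proportion=exceed / B,
        observed=obs, B=B, seed=seed)


def welch_test(control_values, mutant_values) -> tuple[float, float, float]:
    """Welch's t-test (Satterthwaite df): returns (t, df, p)."""
    c = np.asarray(control_values, dtype=float)
    m = np.asarray(mutant_values, dtype=float)
    if len(c) < 2 or len(m) < 2:
        raise ValueError("each group needs n >= 2")
    if c.var(ddof=1) == 0 and m.var(ddof=1) == 0:
        raise ValueError("zero variance in both groups")
    res = stats.ttest_ind(m, c, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def consensus_classify(
    hetero_p: float, perm_p: float, welch_p: float, alpha: float = 0.05
) -> str:
    """ALL SIG / ALL NS / MIXED from the three sensitivity p-values."""
    ps = [hetero_p, perm_p, welch_p]
    if any(not 0 <= p <= 1 for p in ps):
        raise ValueError("p-values must lie in [0, 1]")
    sig = [p < alpha for p in ps]
    if all(sig):
        return "ALL SIG"
    if not any(sig):
        return "ALL NS"
    return "MIXED"


def gene_robustness(
    gene_data: pd.DataFrame,
    B: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> dict:
    """Convenience bundle: all sensitivity checks for one gene's data.

    Morphology values for the F-test/moments/Welch components come from
    the pooled control fit.
    """
    ctrl, mut = _split(gene_data)
    tab = morphology_table(ctrl, mut, scope="pooled")
    cv = tab.loc[tab["role"] == "control", "morphology_value_um"].to_numpy()
    mv = tab.loc[tab["role"] == "mutant", "morphology_value_um"].to_numpy()
    var = variance_f_test(cv, mv)
    g1c, g2c, tailc = distribution_moments(cv)
    g1m, g2m, tailm = distribution_moments(mv)
    het = heteroscedastic_lmm(gene_data)
    perm = permutation_test(gene_data, B=B, seed=seed)
    t, df, wp = welch_test(cv, mv)
    return {
        "variance": var,
        "moments_control": (g1c, g2c, tailc),
        "moments_mutant": (g1m, g2m, tailm),
        "hetero_lmm": het,
        "permutation": perm,
        "welch": (t, df, wp),
        "consensus": consensus_classify(het.p, perm.perm_p, wp, alpha=alpha),
    }
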