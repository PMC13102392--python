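"""Synthetic screen- and diet-experiment-shaped datasets with ground truth.

The generator emulates the statistical structure the analysis assumes
in juvenile zebrafish subcutaneous adipose:

* mean LD diameter follows a saturating-exponential curve of log depot
  area, ``D(A) = D_max * (1 - exp(-kappa * (ln A - a0)))``, plateauing
  near 65 µm;
* droplet count is depot lipid area divided by mean droplet area, so
  larger droplets at fixed depot size means fewer of them (the inverse
  count-size relation);
* experiments carry log-scale random intercepts (batch effects);
* genotype effects act on the log diameter scale: a uniform shift
  ``beta`` (so mutant/control diameter ratio at fixed area is
  exp(beta) in expectation), an allometric slope change ``gamma``, and
  residual variance inflation;
* droplets thin out in size toward the posterior (newest) strata;
* diet experiments impose a per-stratum hypertrophy profile on
  wild-type fish, scaled by a blunting factor in mutants.

All noise is log-normal on diameters, so the log-scale analysis models
are exactly correctly specified. Every dataset is reproducible from its
seed and ships with its ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .geometry import LabelImage

__all__ = [
    "SimulationConfig",
    "GeneEffect",
    "DietConfig",
    "simulate_fish",
    "simulate_screen",
    "simulate_diet_experiment",
    "render_masks",
]

FISH_COLUMNS = [
    "fish_id", "gene", "genotype", "experiment", "standard_length",
    "sat_area", "total_lipid_area", "mean_feret", "n_droplets",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Population and design parameters for screen-shaped data.

    Defaults describe a juvenile zebrafish screen batch: fish of
    7-12 mm standard length whose depots span roughly 2e5-2e6 µm², mean
    LD diameters rising from ~30 µm towards the ~65 µm plateau.
    """

    n_experiments: int = 2
    n_control: int = 30
    n_mutant: int = 30
    sl_range: tuple[float, float] = (7.0, 12.0)  # mm
    # log-normal depot area around an SL-driven mean:
    # ln(AreaSum) = area_intercept + area_sl_slope * ln(SL) + N(0, sigma_area)
    area_intercept: float = 6.9
    area_sl_slope: float = 3.0
    sigma_area: float = 0.25
    # saturating size curve D(lnA) = d_max * (1 - exp(-kappa*(lnA - a0)))
    d_max: float = 65.0
    kappa: float = 0.55
    a0: float = 11.0
    d_floor: float = 5.0  # µm, guards the curve's left tail
    # noise (log scale)
    sigma_fish: float = 0.04
    sigma_ld: float = 0.35
    sigma_batch: float = 0.05
    # depot composition / geometry
    lipid_fraction: float = 0.6  # lipid area / SAT area
    aspect: float = 8.0  # depot length / height
    stratum_width: float = 200.0  # µm
    posterior_deficit: float = 0.03  # fractional diameter loss per stratum
    # reference log-area at which slope effects vanish
    lnarea_ref: float = 13.5


@dataclass(frozen=True)
class GeneEffect:
    """Ground-truth genotype effect for one gene.

    beta: uniform log-scale diameter shift (ln(1.2) = +20% diameter);
    gamma: change in the log-log allometric slope;
    variance_inflation: multiplier on the mutant fish-level residual SD;
    lethal: gene drops out before phenotyping (no fish simulated).
    """

    beta: float = 0.0
    gamma: float = 0.0
    variance_inflation: float = 1.0
    lethal: bool = False


def _size_curve(lnA: np.ndarray, cfg: SimulationConfig) -> np.ndarray:
    d = cfg.d_max * (1.0 - np.exp(-cfg.kappa * (lnA - cfg.a0)))
    return np.maximum(d, cfg.d_floor)


def simulate_fish(
    cfg: SimulationConfig,
    genotype: str,
    rng: np.random.Generator,
    effect: GeneEffect = GeneEffect(),
    batch_intercept: float = 0.0,
    with_droplets: bool = False,
):
    """Simulate one fish; optionally its droplet table.

    Returns a dict of per-fish fields (see ``FISH_COLUMNS``) and, when
    ``with_droplets`` is set, a droplet table with ground-truth stratum
    labels. The fish's mean Feret diameter equals the droplet mean
    exactly (droplet diameters are rescaled to their target mean, so
    fish-level noise is carried by sigma_fish alone).
    """
    mutant = genotype == "mutant"
    sl = rng.uniform(*cfg.sl_range)
    lnA = (cfg.area_intercept + cfg.area_sl_slope * np.log(sl)
           + rng.normal(0.0, cfg.sigma_area))
    area = float(np.exp(lnA))
    ln_d = np.log(_size_curve(lnA, cfg)) + batch_intercept
    sigma_fish = cfg.sigma_fish * (effect.variance_inflation if mutant else 1.0)
    if mutant:
        ln_d += effect.beta + effect.gamma * (lnA - cfg.lnarea_ref)
    ln_d += rng.normal(0.0, sigma_fish) if sigma_fish > 0 else 0.0
    d_fish = float(np.exp(ln_d))

    lipid_area = cfg.lipid_fraction * area
    mean_droplet_area = np.pi / 4.0 * d_fish**2 * np.exp(cfg.sigma_ld**2)
    n_droplets = max(1, int(round(lipid_area / mean_droplet_area)))

    record = {
        "standard_length": float(sl),
        "sat_area": area,
        "total_lipid_area": lipid_area,
        "mean_feret": d_fish,
        "n_droplets": n_droplets,
        "genotype": genotype,
    }
    if not with_droplets:
        return record, None

    length = float(np.sqrt(area * cfg.aspect))
    x = np.sort(rng.uniform(0.0, length, n_droplets))
    y = rng.uniform(0.0, length / cfg.aspect, n_droplets)
    stratum = np.floor((x - x.min()) / cfg.stratum_width).astype(int) + 1
    raw = (1.0 - cfg.posterior_deficit) ** (stratum - 1) * np.exp(
        rng.normal(0.0, cfg.sigma_ld, n_droplets) if cfg.sigma_ld > 0 else 0.0
    )
    feret = raw * (d_fish / raw.mean())  # rescale: droplet mean == fish mean
    droplets = pd.DataFrame(
        {
            "droplet_id": np.arange(1, n_droplets + 1),
            "x_um": x,
            "y_um": y,
            "feret_um": feret,
            "area_um2": np.pi / 4.0 * feret**2,
            "true_stratum": stratum,
        }
    )
    return record, droplets


def simulate_screen(
    cfg: SimulationConfig,
    gene_effects: dict[str, GeneEffect],
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Simulate a full screen: per gene, matched controls and mutants in
    each of k experiments.

    Returns the fish table (``FISH_COLUMNS``) and a ground-truth dict
    (per-gene effects, batch intercepts, seed). Lethal genes contribute
    no fish but are recorded in the ground truth.
    """
    if not gene_effects:
        raise ValueError("need at least one gene")
    rng = np.random.default_rng(seed)
    rows = []
    truth = {"seed": seed, "genes": {}, "batch_intercepts": {}}
    for gene, eff in gene_effects.items():
        truth["genes"][gene] = {
            "beta": eff.beta, "gamma": eff.gamma,
            "variance_inflation": eff.variance_inflation, "lethal": eff.lethal,
            "expected_pct_change": (np.exp(eff.beta) - 1.0) * 100.0,
        }
        if eff.lethal:
            continue
        for k in range(1, cfg.n_experiments + 1):
            exp_id = f"{gene}_exp{k}"
            b = rng.normal(0.0, cfg.sigma_batch) if cfg.sigma_batch > 0 else 0.0
            truth["batch_intercepts"][exp_id] = b
            for genotype, n in (("control", cfg.n_control), ("mutant", cfg.n_mutant)):
                for i in range(n):
                    rec, _ = simulate_fish(cfg, genotype, rng, effect=eff,
                                           batch_intercept=b)
                    rec.update(gene=gene, experiment=exp_id,
                               fish_id=f"{gene}_e{k}_{genotype[0]}{i + 1}")
                    rows.append(rec)
    fish = pd.DataFrame(rows, columns=FISH_COLUMNS)
    return fish, truth


def simulate_gene_dataset(
    cfg: SimulationConfig,
    effect: GeneEffect = GeneEffect(),
    seed: int = 0,
    allocation: list[tuple[int, int]] | None = None,
    gene: str = "g",
) -> pd.DataFrame:
    """Simulate one gene's dataset with explicit per-experiment allocation.

    ``allocation`` is a list of (n_control, n_mutant) pairs, one per
    experiment; by default the config's balanced design. Unbalanced
    allocations (e.g. controls mostly in one batch) reproduce the
    batch-confounding failure mode that the stratified tests guard
    against.
    """
    rng = np.random.default_rng(seed)
    if allocation is None:
        allocation = [(cfg.n_control, cfg.n_mutant)] * cfg.n_experiments
    rows = []
    for k, (nc, nm) in enumerate(allocation, start=1):
        b = rng.normal(0.0, cfg.sigma_batch) if cfg.sigma_batch > 0 else 0.0
        for genotype, n in (("control", nc), ("mutant", nm)):
            for i in range(n):
                rec, _ = simulate_fish(cfg, genotype, rng, effect=effect,
                                       batch_intercept=b)
                rec.update(gene=gene, experiment=f"exp{k}",
                           fish_id=f"e{k}_{genotype[0]}{i + 1}")
                rows.append(rec)
    return pd.DataFrame(rows, columns=FISH_COLUMNS)


# ---------------------------------------------------------------------------
# paired diet experiment


@dataclass(frozen=True)
class DietConfig:
    """Paired baseline/post diet experiment parameters.

    Wild-type HFD effects follow a linear anterior-to-posterior profile
    (default 20.7 to 28.1 µm over 15 strata, stratum average +24.4 µm);
    mutant effects are the wild-type profile scaled by ``blunting``
    (default 0.32, i.e. a 68% reduction). Mutants may also carry a
    baseline hypertrophic shift declining posteriorly.
    """

    n_per_group: int = 8  # fish per genotype per diet arm
    n_strata: int = 15
    baseline_anterior: float = 45.0  # wild-type stratum-1 baseline mean, µm
    baseline_slope: float = -1.5  # µm per stratum
    mutant_baseline_shift: float = 22.2  # µm at stratum 1
    mutant_baseline_shift_slope: float = -1.1  # µm per stratum
    growth: float = 4.0  # control-diet change, µm, all strata
    diet_profile_range: tuple[float, float] = (20.7, 28.1)  # µm, stratum 1 -> last
    blunting: float = 0.32  # mutant diet effect = blunting * wild-type profile
    sigma_baseline: float = 5.0  # per fish per stratum, µm
    sigma_delta: float = 6.0  # noise on the within-fish change, µm

    def wildtype_profile(self) -> np.ndarray:
        return np.linspace(*self.diet_profile_range, self.n_strata)


def simulate_diet_experiment(
    cfg: DietConfig = DietConfig(), seed: int = 0
) -> tuple[pd.DataFrame, dict]:
    """Simulate paired per-stratum observations for a diet challenge.

    Each fish appears at both timepoints; its post value is baseline +
    control-diet growth + (diet profile x blunting, HFD fish only) +
    noise. Returns the long observation table (see
    :data:`ldmorph.diet.PAIRED_COLUMNS`) and the ground truth.
    """
    rng = np.random.default_rng(seed)
    strata = np.arange(1, cfg.n_strata + 1)
    wt_profile = cfg.wildtype_profile()
    mut_profile = cfg.blunting * wt_profile
    truth = {
        "seed": seed,
        "strata": strata.tolist(),
        "true_effect_wildtype": wt_profile.tolist(),
        "true_effect_mutant": mut_profile.tolist(),
        "true_reduction_pct": 100.0 * (1.0 - cfg.blunting),
    }
    rows = []
    fid = 0
    for genotype, profile in (("wildtype", wt_profile), ("mutant", mut_profile)):
        base_mean = cfg.baseline_anterior + cfg.baseline_slope * (strata - 1)
        if genotype == "mutant":
            base_mean = base_mean + np.maximum(
                cfg.mutant_baseline_shift
                + cfg.mutant_baseline_shift_slope * (strata - 1), 0.0)
        for diet in ("control", "HFD"):
            for _ in range(cfg.n_per_group):
                fid += 1
                fish_id = f"{genotype[0]}{diet[0]}{fid}"
                baseline = base_mean + rng.normal(0.0, cfg.sigma_baseline, cfg.n_strata)
                delta = cfg.growth + rng.normal(0.0, cfg.sigma_delta, cfg.n_strata)
                if diet == "HFD":
                    delta = delta + profile
                for s, b, d in zip(strata, baseline, delta):
                    rows.append((fish_id, genotype, diet, "baseline", int(s), b))
                    rows.append((fish_id, genotype, diet, "post", int(s), b + d))
    obs = pd.DataFrame(
        rows, columns=["fish_id", "genotype", "diet", "timepoint", "stratum",
                       "mean_feret"],
    )
    return obs, truth


# ---------------------------------------------------------------------------
# label-mask rendering


def render_masks(
    droplets: pd.DataFrame,
    pixel_size: float,
    seed: int = 0,
    shape: tuple[int, int] | None = None,
    max_retries: int = 200,
) -> tuple[LabelImage, pd.DataFrame]:
    """Render droplets as non-overlapping filled discs on a label canvas.

    Each droplet becomes a disc of radius ``feret_um / 2`` centred near
    its (x, y); colliding placements are re-jittered up to
    ``max_retries`` times (then the canvas is declared too small). The
    returned ground-truth table holds the *placed* centre coordinates
    (µm, pixel-centre convention matching ``measure_droplets``) and
    radii.

    Ground-truth x/y in the table are synthetic placements, not
    measurements.
    """
    from skimage.draw import disk

    rng = np.random.default_rng(seed)
    ps = float(pixel_size)
    r_px = droplets["feret_um"].to_numpy(float) / 2.0 / ps
    cx = droplets["x_um"].to_numpy(float) / ps
    cy = droplets["y_um"].to_numpy(float) / ps
    if shape is None:
        margin = float(r_px.max()) + 4
        shape = (int(np.ceil(cy.max() + margin + 2)) + int(margin),
                 int(np.ceil(cx.max() + margin + 2)) + int(margin))
        cx = cx + margin / 2
        cy = cy + margin / 2
    canvas = np.zeros(shape, dtype=np.int32)
    placed = []
    order = np.argsort(-r_px)  # large discs first
    for idx in order:
        label = int(droplets["droplet_id"].iloc[idx])
        r = max(r_px[idx], 1.0)
        for attempt in range(max_retries):
            jitter = rng.normal(0.0, r, 2) * min(attempt / 10.0, 3.0)
            c0 = float(np.clip(cy[idx] + jitter[0], r + 1, shape[0] - r - 2))
            c1 = float(np.clip(cx[idx] + jitter[1], r + 1, shape[1] - r - 2))
            rr, cc = disk((c0, c1), r + 1.0, shape=shape)  # 1-px clearance halo
            if canvas[rr, cc].any():
                continue
            rr, cc = disk((c0, c1), r, shape=shape)
            canvas[rr, cc] = label
            placed.append({"droplet_id": label, "x_um": (c1 + 0.5) * ps,
                           "y_um": (c0 + 0.5) * ps, "radius_um": r * ps})
            break
        else:
            raise RuntimeError(
                f"could not place droplet {label} after {max_retries} retries; "
                "canvas too small or too crowded")
    truth_cols = ["droplet_id", "x_um", "y_um", "radius_um"]
    if placed:
        truth = pd.DataFrame(placed).sort_values("droplet_id").reset_index(drop=True)
    else:
        truth = pd.DataFrame(columns=truth_cols)
    return LabelImage(pixels=canvas, pixel_size=ps), truth
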