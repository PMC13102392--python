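"""The morphology value: residual deviation from the size-scaling smoother.

Across wild-type fish, mean lipid-droplet (LD) Feret diameter rises
steeply with depot size and then saturates. A penalized regression
spline of mean Feret diameter on log total SAT area (``Feret ~
s(log(AreaSum))``) fitted to control fish captures this allometry; each
fish's *morphology value* is its observed mean Feret diameter minus the
smoother's prediction at its depot size. Positive values mean larger
LDs than expected at that depot size (hypertrophic morphology: few,
large adipocytes); negative values mean hyperplastic morphology (many,
small adipocytes).

Fits use natural logarithms throughout and report values in µm.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gam import PenalizedSpline

__all__ = [
    "MorphologyFit",
    "fit_morphology_gam",
    "morphology_value",
    "morphology_table",
]

log = logging.getLogger(__name__)

#: below this |value| (µm) the direction is reported as neutral
NEUTRAL_TOL_UM = 1e-9

MIN_FISH_POOLED = 8
MIN_FISH_PER_EXPERIMENT = 5


@dataclass
class MorphologyFit:
    """A fitted control smoother of mean Feret diameter vs log depot area."""

    smoother: PenalizedSpline
    basis_dim: int
    smoothing_parameter: float
    r_squared: float
    n_fit: int

    def predict(self, log_area: np.ndarray | float) -> np.ndarray:
        """Predicted mean Feret diameter (µm) at log(AreaSum)."""
        return self.smoother.predict(log_area)


def fit_morphology_gam(
    fish: pd.DataFrame, basis_dim: int = 10, min_fish: int = MIN_FISH_POOLED
) -> MorphologyFit:
    """Fit the control size-scaling smoother.

    ``fish`` needs ``sat_area`` (µm², > 0) and ``mean_feret`` (µm)
    columns; smoothing is selected by GCV.
    """
    ok = fish[(fish["sat_area"] > 0) & (fish["mean_feret"] > 0)]
    if len(ok) < min_fish:
        raise ValueError(
            f"need at least {min_fish} fish with positive depot area and "
            f"mean Feret diameter, got {len(ok)}"
        )
    x = np.log(ok["sat_area"].to_numpy(dtype=float))
    y = ok["mean_feret"].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("degenerate depot areas: all AreaSum values identical")
    sp = PenalizedSpline(n_basis=basis_dim).fit(x, y)
    return MorphologyFit(
        smoother=sp,
        basis_dim=basis_dim,
        smoothing_parameter=sp.lam_,
        r_squared=sp.r_squared_,
        n_fit=sp.n_fit_,
    )


def morphology_value(fit: MorphologyFit, fish: pd.Series | pd.DataFrame) -> pd.DataFrame:
    """Morphology value(s): observed mean Feret minus the control prediction.

    Returns a frame with columns ``predicted_um``, ``morphology_value_um``,
    ``direction`` (hypertrophic/hyperplastic/neutral) and ``extrapolated``
    (depot area outside the fitted range).
    """
    if fit is None:
        raise ValueError("no fitted smoother supplied")
    if isinstance(fish, pd.Series):
        fish = fish.to_frame().T
    area = fish["sat_area"].to_numpy(dtype=float)
    if np.any(area <= 0):
        raise ValueError("non-positive sat_area")
    log_area = np.log(area)
    pred = fit.predict(log_area)
    value = fish["mean_feret"].to_numpy(dtype=float) - pred
    direction = np.where(
        value > NEUTRAL_TOL_UM,
        "hypertrophic",
        np.where(value < -NEUTRAL_TOL_UM, "hyperplastic", "neutral"),
    )
    return pd.DataFrame(
        {
            "predicted_um": pred,
            "morphology_value_um": value,
            "direction": direction,
            "extrapolated": ~fit.smoother.in_range(log_area),
        },
        index=fish.index,
    )


def morphology_table(
    controls: pd.DataFrame,
    mutants: pd.DataFrame | None = None,
    scope: str = "pooled",
    basis_dim: int = 10,
    min_controls: int | None = None,
) -> pd.DataFrame:
    """Morphology values for every fish, from control-only smoother fits.

    scope='pooled' fits one smoother to all controls; scope='per-experiment'
    fits a separate smoother to each experiment's controls and scores that
    experiment's fish against it (the batch-robust variant used by the
    stratified screen tests). Control values are in-sample residuals;
    mutant values are deviations from the control fit. Experiments with
    fewer controls than the per-experiment minimum are excluded with a
    logged warning.
    """
    if mutants is None:
        mutants = controls.iloc[0:0]
    both = pd.concat([controls.assign(_role="control"), mutants.assign(_role="mutant")])
    pieces = []
    if scope == "pooled":
        fit = fit_morphology_gam(controls, basis_dim=basis_dim,
                                 min_fish=min_controls or MIN_FISH_POOLED)
        vals = morphology_value(fit, both)
        pieces.append(both.join(vals).assign(scope="pooled"))
    elif scope == "per-experiment":
        for exp, grp in both.groupby("experiment", sort=False):
            ctrl = grp[grp["_role"] == "control"]
            if len(ctrl) < MIN_FISH_PER_EXPERIMENT:
                log.warning(
                    "experiment %r excluded from per-experiment morphology fit: "
                    "%d controls < minimum %d", exp, len(ctrl), MIN_FISH_PER_EXPERIMENT
                )
                continue
            fit = fit_morphology_gam(ctrl, basis_dim=basis_dim,
                                     min_fish=MIN_FISH_PER_EXPERIMENT)
            vals = morphology_value(fit, grp)
            pieces.append(grp.join(vals).assign(scope="per-experiment"))
        if not pieces:
            raise ValueError("no experiment met the per-experiment control minimum")
    else:
        raise ValueError(f"unknown scope: {scope!r}")
    out = pd.concat(pieces)
    out = out.rename(columns={"_role": "role"})
    return out
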