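"""Anterior-posterior stratification of the subcutaneous adipose depot.

Droplets are binned into successive strata of fixed width (default
200 µm) anchored at the most anterior droplet centroid, so that fish of
different sizes can be compared at anatomically equivalent positions.
Stratum 1 is the anterior-most bin; intervals are half-open
[a + (i-1)*w, a + i*w) along the posterior direction.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["assign_strata", "stratum_summaries"]

DEFAULT_STRATUM_WIDTH_UM = 200.0


def assign_strata(
    droplets: pd.DataFrame,
    width: float = DEFAULT_STRATUM_WIDTH_UM,
    orientation: str = "anterior-at-min-x",
) -> pd.Series:
    """Assign each droplet a 1-based stratum index.

    Parameters
    ----------
    droplets
        Droplet table with an ``x_um`` column (centroid along the
        anterior-posterior raster axis).
    width
        Stratum width in µm (> 0).
    orientation
        ``"anterior-at-min-x"`` (default; anterior end at the lowest x,
        matching right-flank imaging with the head on the left) or
        ``"anterior-at-max-x"``.

    Returns
    -------
    pandas.Series of integer stratum labels, aligned with ``droplets``.
    The anchoring (anterior-most) droplet is always in stratum 1.
    """
    if len(droplets) == 0:
        raise ValueError("empty droplet set")
    if not width > 0:
        raise ValueError(f"stratum width must be > 0, got {width}")
    x = np.asarray(droplets["x_um"], dtype=float)
    if orientation == "anterior-at-min-x":
        offset = x - x.min()
    elif orientation == "anterior-at-max-x":
        offset = x.max() - x
    else:
        raise ValueError(f"unknown orientation: {orientation!r}")
    stratum = np.floor(offset / width).astype(int) + 1
    return pd.Series(stratum, index=droplets.index, name="stratum")


def stratum_summaries(
    droplets: pd.DataFrame,
    width: float = DEFAULT_STRATUM_WIDTH_UM,
    orientation: str = "anterior-at-min-x",
) -> pd.DataFrame:
    """Per-stratum droplet count, mean and SD of Feret diameter.

    Strata containing no droplets are omitted. SD is the sample standard
    deviation (ddof=1); NaN for single-droplet strata.
    """
    if len(droplets) == 0:
        raise ValueError("empty droplet set")
    d = droplets.copy()
    d["stratum"] = assign_strata(d, width=width, orientation=orientation)
    out = (
        d.groupby("stratum")["feret_um"]
        .agg(n_droplets="size", mean_feret="mean", sd_feret=lambda v: v.std(ddof=1))
        .reset_index()
    )
    return out
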