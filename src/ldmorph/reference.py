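"""Published summary statistics of the 21-gene zebrafish F0 screen.

Per-gene printed values from the screen of candidate adipose-morphology
genes (raw per-fish data were not deposited): replicate count, sample
sizes, weighted KS effect (µm), BH-adjusted p-values for the pooled KS,
stratified (Fisher-combined) KS and LMM-intercept families, the LMM
percent change in LD diameter, the phenotype direction, and the printed
power (%) of a two-sided two-sample t-test at d = 0.8, alpha = 0.05.
Genes assayed in a single replicate or lethal before phenotyping are
not part of this table.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["load_reference_screen"]

_ROWS = [
    # gene, reps, n_ctrl, n_mut, ks_effect_um, ks_pooled_adj_p,
    # ks_stratified_adj_p, lmm_pct_change, lmm_adj_p, direction, power_pct
    ("txnipa",  3, 45, 30, +4.6, 0.066, 1.41e-4, +19.9, 1.63e-4, "hypertrophic", 92),
    ("mmp14b",  2, 34, 30, +5.4, 0.002, 0.005,   +15.8, 1.93e-4, "hypertrophic", 88),
    ("foxp1b",  2, 42, 45, +8.8, 0.064, 0.019,   +17.0, 0.049,   "hypertrophic", 96),
    ("ptprdb",  2, 35, 24, +4.0, 0.080, 0.057,   +18.5, 0.087,   "hypertrophic", 84),
    ("cxcl14",  2, 27, 24, -4.4, 0.522, 0.077,   -8.7,  0.348,   "hyperplastic", 80),
    ("prrx1b",  3, 65, 60, -3.5, 0.178, 0.077,   -5.9,  0.358,   "hyperplastic", 99),
    ("ptenb",   2, 27, 25, -4.7, 0.054, 0.077,   -7.9,  0.411,   "hyperplastic", 81),
    ("pid1",    2, 27, 26, -2.7, 0.869, 0.204,   -6.5,  0.565,   "hyperplastic", 81),
    ("nav3",    3, 49, 42, -2.4, 0.194, 0.562,   -6.1,  0.650,   "hyperplastic", 96),
    ("sdk1a",   2, 29, 25, +0.6, 0.869, 0.482,   +7.6,  0.694,   "hypertrophic", 82),
    ("runx1t1", 2, 29, 22, +1.1, 0.706, 0.795,   +7.6,  0.736,   "hypertrophic", 79),
    ("sparc",   2, 24, 23, -2.1, 0.286, 0.553,   -7.1,  0.736,   "hyperplastic", 77),
    ("kazna",   2, 36, 23, -3.1, 0.706, 0.148,   -4.7,  0.759,   "hyperplastic", 84),
    ("tmem115", 2, 27, 29, -3.1, 0.488, 0.019,   -3.8,  0.759,   "hyperplastic", 84),
    ("cd81a",   2, 24, 26, +0.0, 0.862, 0.064,   -5.0,  0.759,   "hypertrophic", 79),
    ("lrmda",   2, 27, 22, -0.4, 0.527, 0.077,   -2.7,  0.778,   "hyperplastic", 78),
    ("tbx15",   3, 37, 26, +3.4, 0.706, 0.019,   +3.7,  0.778,   "hypertrophic", 87),
    ("cacnb4a", 2, 29, 27, +0.9, 0.706, 0.852,   +2.6,  0.804,   "hypertrophic", 84),
    ("pard3ab", 2, 36, 32, -1.5, 0.869, 0.750,   +2.1,  0.804,   "hypertrophic", 90),
    ("ptprga",  2, 35, 35, -1.4, 0.269, 0.077,   -1.6,  0.804,   "hyperplastic", 91),
    ("srpx",    2, 36, 20, -5.7, 0.155, 0.204,   -0.9,  0.836,   "hyperplastic", 80),
]

_COLUMNS = [
    "gene", "n_experiments", "n_control", "n_mutant", "ks_effect_um",
    "ks_pooled_adj_p", "ks_stratified_adj_p", "lmm_pct_change", "lmm_adj_p",
    "direction", "power_pct",
]


def load_reference_screen() -> pd.DataFrame:
    """The published per-gene screen summary table as a DataFrame."""
    return pd.DataFrame(_ROWS, columns=_COLUMNS)
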