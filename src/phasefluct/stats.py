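"""Per-cell summary statistics and two-group comparison.

Two scalar summaries are computed per cell: the mean OPD over the analysis
mask (a morphology/dry-mass proxy) and the mean absolute value of the
spatio-temporal fluctuation map (a stiffness proxy; softer, more metastatic
cells fluctuate more).  Group differences are tested with Welch's t-test by
default (Mann-Whitney U available for a rank-based alternative).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .fluctuation import CellMask, FluctuationMap
from .holography import OPDMap

__all__ = ["CellSummary", "mean_opd", "mean_abs_fluct", "compare_groups"]


@dataclass
class CellSummary:
    cell_id: str
    label: str
    mean_opd_nm: float
    mean_abs_fluct: float

    def __post_init__(self):
        if self.label not in ("primary", "metastatic"):
            raise ValueError("label must be 'primary' or 'metastatic'")
        if not np.isfinite(self.mean_opd_nm):
            raise ValueError("mean_opd_nm must be finite")
        if self.mean_abs_fluct < 0:
            raise ValueError("mean_abs_fluct must be >= 0")


def mean_opd(opd: OPDMap | np.ndarray, mask: CellMask) -> float:
    """Arithmetic mean OPD (nm) over the true pixels of the mask."""
    values = opd.values if isinstance(opd, OPDMap) else np.asarray(opd, dtype=float)
    if values.shape != mask.pixels.shape:
        raise ValueError("mask shape does not match OPD map")
    if not mask.pixels.any():
        raise ValueError("empty mask")
    return float(values[mask.pixels].mean())


def mean_abs_fluct(fmap: FluctuationMap) -> float:
    """Mean of |entries| over all (omega, q) bins of the fluctuation map."""
    if fmap.power.size == 0:
        raise ValueError("empty fluctuation map")
    return float(np.abs(fmap.power).mean())


def compare_groups(a, b, test: str = "welch") -> float:
    """Two-sided two-sample p-value between per-cell summary groups.

    ``test`` is ``"welch"`` (default, unequal-variance t-test) or
    ``"mannwhitney"``.  Two degenerate identical groups (zero variance, equal
    means) give p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("each group needs at least 3 observations")
    if np.var(a) == 0 and np.var(b) == 0:
        return 1.0 if a.mean() == b.mean() else 0.0
    if test == "welch":
        p = sps.ttest_ind(a, b, equal_var=False).pvalue
    elif test == "mannwhitney":
        p = sps.mannwhitneyu(a, b, alternative="two-sided").pvalue
    else:
        raise ValueError(f"unknown test '{test}'")
    return float(p)
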