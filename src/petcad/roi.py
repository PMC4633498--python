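"""Voxelwise two-sample t-test, thresholding, and atlas-based region ranking.

The univariate stage of the pipeline: a mass-univariate pooled-variance
two-sample t-test compares APS against PD at every voxel, oriented so that a
positive t statistic means APS > PD (the PD-hypointensity hypothesis for
D2/3-receptor imaging).  The one-tailed p map is thresholded (default
p < 0.001, uncorrected), the suprathreshold mask is intersected with the
atlas, and regions are ranked by the fraction of their voxels that survive
the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from ._common import ConfigurationError
from .phantom import AtlasVolume
from .preprocess import Volume


@dataclass
class TStatMap:
    """Voxelwise t statistics and one-tailed p values with shared df."""

    t: np.ndarray
    p: np.ndarray
    df: int

    def __post_init__(self) -> None:
        if self.t.shape != self.p.shape:
            raise ValueError("t and p maps must share a grid")
        if self.df < 1:
            raise ValueError("degrees of freedom must be >= 1")


@dataclass
class RegionRanking:
    """Per-region suprathreshold fraction and voxel count."""

    fractions: dict[int, float]
    counts: dict[int, int]

    def __post_init__(self) -> None:
        for r, f in self.fractions.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"region {r}: fraction {f} outside [0, 1]")


def _stack(group: list[Volume] | np.ndarray) -> np.ndarray:
    if isinstance(group, np.ndarray):
        return np.asarray(group, dtype=np.float64)
    return np.stack([v.data for v in group]).astype(np.float64)


def voxel_two_sample_t(
    group_pd, group_aps, two_tailed: bool = False
) -> TStatMap:
    """Pooled-variance two-sample t at every voxel, oriented APS minus PD.

    Accepts lists of :class:`Volume` or pre-stacked arrays with subjects on
    the first axis.  One-tailed p values come from the upper tail of Student's
    t with ``n_pd + n_aps - 2`` degrees of freedom (``two_tailed=True``
    switches to the symmetric two-tailed p).  Zero-variance voxels are kept
    total and deterministic: equal group means give t = 0 (p = 0.5), unequal
    means give t = +/-inf (p = 0 or 1).
    """
    a = _stack(group_aps)
    b = _stack(group_pd)
    n_a, n_b = a.shape[0], b.shape[0]
    if n_a < 2 or n_b < 2:
        raise ValueError("each group needs at least 2 volumes")
    if a.shape[1:] != b.shape[1:]:
        raise ValueError("groups must share the voxel grid")
    df = n_a + n_b - 2
    mean_diff = a.mean(axis=0) - b.mean(axis=0)  # APS - PD
    ss = a.var(axis=0, ddof=1) * (n_a - 1) + b.var(axis=0, ddof=1) * (n_b - 1)
    sp2 = ss / df
    se = np.sqrt(sp2 * (1.0 / n_a + 1.0 / n_b))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean_diff / se
    zero_var = se == 0
    t = np.where(zero_var & (mean_diff == 0), 0.0, t)
    t = np.where(zero_var & (mean_diff > 0), np.inf, t)
    t = np.where(zero_var & (mean_diff < 0), -np.inf, t)
    if two_tailed:
        p = 2.0 * stats.t.sf(np.abs(t), df)
    else:
        p = stats.t.sf(t, df)
    return TStatMap(t=t, p=p, df=df)


def threshold_map(tmap: TStatMap, p_threshold: float = 0.001) -> np.ndarray:
    """Binary mask of voxels with p strictly below the (uncorrected) threshold."""
    if not 0.0 < p_threshold < 1.0:
        raise ValueError(f"p_threshold must lie in (0, 1), got {p_threshold}")
    return tmap.p < p_threshold


def rank_regions(mask: np.ndarray, atlas: AtlasVolume) -> RegionRanking:
    """Fraction of each atlas region's voxels inside the suprathreshold mask."""
    if mask.shape != atlas.shape:
        raise ValueError("mask and atlas must share a grid")
    fractions: dict[int, float] = {}
    counts: dict[int, int] = {}
    for r in atlas.region_ids:
        region = atlas.labels == r
        n = int(region.sum())
        if n == 0:  # pragma: no cover - region_ids only lists present labels
            raise ConfigurationError(f"atlas region {r} is empty")
        fractions[r] = float(np.count_nonzero(mask & region)) / n
        counts[r] = n
    if not fractions:
        raise ConfigurationError("atlas contains no regions")
    return RegionRanking(fractions=fractions, counts=counts)


def select_regions(ranking: RegionRanking, n_regions: int = 4) -> list[int]:
    """The ``n_regions`` ids with the largest suprathreshold fractions.

    Ties are broken in favour of the smaller region id, making the selection
    deterministic.
    """
    ids = sorted(ranking.fractions)
    if n_regions > len(ids):
        raise ValueError(
            f"cannot select {n_regions} regions from {len(ids)} atlas regions"
        )
    order = sorted(ids, key=lambda r: (-ranking.fractions[r], r))
    return order[:n_regions]
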