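"""Informative-patch selection.

The primary selector runs a two-sample t-test per patch comparing pixel
intensities of the lung region (group 1) against the non-lung region
(group 2); patches whose two-sided p-value falls below a significance
threshold (default 0.003) are retained as showing genuine lung/non-lung
contrast. Patches almost entirely outside the lung field are discarded
without testing, and patches almost entirely inside it are retained
without testing — they are exactly the diagnostically relevant region
and offer no second group to test against.

A mask-free adaptive-thresholding selector (Otsu) is provided as the
simpler baseline: it keeps patches with a sufficient fraction of dark
(radiolucent, i.e. aerated-lung-like) pixels.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy import stats
from skimage.filters import threshold_otsu

from .errors import InsufficientDataError, ValidationError
from .patching import Patch

logger = logging.getLogger(__name__)

RETAIN = "retain"
DISCARD = "discard"
FORCED_RETAIN = "forced_retain"
FORCED_DISCARD = "forced_discard"


@dataclass(frozen=True)
class SelectionConfig:
    """Configuration of the t-test selector.

    ``p_threshold`` is the per-patch significance level below which a
    patch is retained (no multiplicity correction — the rule is applied
    raw, per patch). ``min_group_fraction`` bounds the smaller pixel
    group: below it the patch is forced-discarded (mostly non-lung),
    above its complement forced-retained (fully lung). ``test_flavor``
    selects Welch (unequal variances, the default) or the pooled
    equal-variance statistic.
    """

    p_threshold: float = 0.003
    min_group_fraction: float = 0.05
    test_flavor: str = "welch"

    def __post_init__(self) -> None:
        if not (0 < self.p_threshold < 1):
            raise ValidationError("p_threshold must lie in (0, 1)")
        if self.test_flavor not in ("welch", "pooled"):
            raise ValidationError("test_flavor must be 'welch' or 'pooled'")


@dataclass
class PatchStats:
    """Per-patch test result and retention decision."""

    t_statistic: float
    dof: float
    p_value: float
    mean_lung: float
    mean_nonlung: float
    n_lung: int
    n_nonlung: int
    decision: str

    @property
    def retained(self) -> bool:
        return self.decision in (RETAIN, FORCED_RETAIN)


def two_sample_t(
    group1: Sequence[float], group2: Sequence[float], flavor: str = "welch"
) -> tuple[float, float, float]:
    """Two-sided two-sample t-test of equal means.

    Returns ``(t, dof, p)``. The ``welch`` flavor uses the
    unequal-variance statistic with Welch-Satterthwaite degrees of
    freedom; ``pooled`` uses the classic equal-variance statistic with
    ``n1 + n2 - 2`` degrees of freedom. Degenerate zero-variance inputs
    follow a sentinel convention: equal means give ``(0, dof, 1)``,
    unequal means give ``(+/-inf, dof, 0)``.
    """
    x = np.asarray(group1, dtype=np.float64)
    y = np.asarray(group2, dtype=np.float64)
    n1, n2 = x.size, y.size
    if n1 < 2 or n2 < 2:
        raise InsufficientDataError(f"need >= 2 values per group, got {n1} and {n2}")
    m1, m2 = x.mean(), y.mean()
    if np.ptp(x) == 0 and np.ptp(y) == 0:
        # degenerate constant groups: variance is identically zero
        dof = n1 + n2 - 2
        if x[0] == y[0]:
            return 0.0, float(dof), 1.0
        return math.copysign(math.inf, m1 - m2), float(dof), 0.0
    v1, v2 = x.var(ddof=1), y.var(ddof=1)

    if flavor == "pooled":
        dof = n1 + n2 - 2
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / dof
        denom = math.sqrt(sp2 * (1 / n1 + 1 / n2))
    elif flavor == "welch":
        a, b = v1 / n1, v2 / n2
        denom = math.sqrt(a + b)
        if a + b > 0:
            dof = (a + b) ** 2 / (a**2 / (n1 - 1) + b**2 / (n2 - 1))
        else:
            dof = n1 + n2 - 2
    else:
        raise ValidationError(f"unknown test flavor {flavor!r}")

    if denom == 0.0:
        if m1 == m2:
            return 0.0, float(dof), 1.0
        return math.copysign(math.inf, m1 - m2), float(dof), 0.0

    t = (m1 - m2) / denom
    p = 2.0 * stats.t.sf(abs(t), dof)
    return float(t), float(dof), float(min(p, 1.0))


def score_patch(patch: Patch, mask: np.ndarray, config: SelectionConfig) -> PatchStats:
    """Run the lung/non-lung intensity t-test on one patch.

    ``mask`` is the parent image's lung mask at working resolution; the
    patch's box indexes into it. Returns the :class:`PatchStats` with
    the retention decision already applied.
    """
    r0, c0, r1, c1 = patch.box
    if r1 > mask.shape[0] or c1 > mask.shape[1]:
        raise ValidationError(f"patch box {patch.box} not aligned to mask {mask.shape}")
    submask = mask[r0:r1, c0:c1]
    if submask.shape != patch.pixels.shape:
        raise ValidationError(
            f"mask window {submask.shape} != patch pixels {patch.pixels.shape}"
        )
    lung = patch.pixels[submask == 1]
    nonlung = patch.pixels[submask == 0]
    n = patch.pixels.size
    frac = lung.size / n

    mean_lung = float(lung.mean()) if lung.size else math.nan
    mean_nonlung = float(nonlung.mean()) if nonlung.size else math.nan

    if frac < config.min_group_fraction:
        return PatchStats(
            math.nan, math.nan, math.nan, mean_lung, mean_nonlung,
            lung.size, nonlung.size, FORCED_DISCARD,
        )
    if frac > 1 - config.min_group_fraction:
        return PatchStats(
            math.nan, math.nan, math.nan, mean_lung, mean_nonlung,
            lung.size, nonlung.size, FORCED_RETAIN,
        )
    t, dof, p = two_sample_t(lung, nonlung, config.test_flavor)
    decision = RETAIN if p < config.p_threshold else DISCARD
    return PatchStats(t, dof, p, mean_lung, mean_nonlung, lung.size, nonlung.size, decision)


def select_patches(
    patches: Iterable[Patch],
    mask_lookup: Callable[[str], np.ndarray],
    config: SelectionConfig | None = None,
) -> tuple[list[Patch], list[PatchStats]]:
    """Apply :func:`score_patch` to every patch.

    ``mask_lookup`` maps a parent image id to its working-resolution
    lung mask. Returns the retained patches in input order and the full
    list of per-patch statistics (parallel to the input).
    """
    config = config or SelectionConfig()
    retained, all_stats = [], []
    for patch in patches:
        st = score_patch(patch, mask_lookup(patch.parent_id), config)
        all_stats.append(st)
        if st.retained:
            retained.append(patch)
    if all_stats:
        logger.info(
            "t-test selection: retained %d/%d patches (%.1f%%)",
            len(retained), len(all_stats), 100 * len(retained) / len(all_stats),
        )
    return retained, all_stats


def threshold_select(
    patches: Iterable[Patch],
    dark_cutoff: float | None = None,
    min_dark_fraction: float = 0.3,
) -> list[Patch]:
    """Mask-free adaptive-thresholding baseline selector.

    Per patch, pixels below ``dark_cutoff`` (Otsu's threshold of the
    patch when unset) count as dark; patches whose dark fraction reaches
    ``min_dark_fraction`` are retained. Constant patches, for which Otsu
    is undefined, are discarded with a warning.
    """
    retained = []
    for patch in patches:
        cutoff = dark_cutoff
        if cutoff is None:
            if np.ptp(patch.pixels) < 1e-9:
                logger.warning(
                    "%s %s: constant patch, Otsu undefined -> discarded",
                    patch.parent_id, patch.box,
                )
                continue
            cutoff = float(threshold_otsu(patch.pixels))
        if float(np.mean(patch.pixels < cutoff)) >= min_dark_fraction:
            retained.append(patch)
    return retained
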