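"""Block-bootstrap uncertainty and significance tests.

Uncertainty on any statistic of the location data comes from random
halves of 400-s blocks: the window is tiled into blocks longer than twice
a mouse's correlation time, a random half of the blocks is used to
recompute the statistic, and the spread across repetitions, sigma_bs, is
extrapolated to the full data as sigma = sigma_bs / sqrt(2) (half the
data has twice the variance of the full data for an effectively
independent-block statistic).

Group comparisons across 5-day segments use Welch's t-test (means) and
the two-sample F-test (variances), two-sided, with a Bonferroni family of
six pairwise comparisons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .events import LocationMatrix

__all__ = [
    "HalfSplit",
    "BootstrapEstimate",
    "TestResult",
    "split_random_halves",
    "bootstrap_sigma",
    "compare_groups",
]

DEFAULT_BLOCK_S = 400.0
BONFERRONI_FAMILY = 6
STAR_LEVELS = (0.05, 0.01, 0.001)       # mean/variance comparisons
STAR_LEVELS_DTI = (0.025, 0.005, 0.0005)  # global-DTI comparisons


@dataclass
class HalfSplit:
    """Two disjoint halves of the 400-s block tiling of a window."""

    half_a: np.ndarray  # time-bin indices
    half_b: np.ndarray
    n_blocks: int
    block_s: float
    seed: int | None


@dataclass
class BootstrapEstimate:
    """Replicates of a statistic over random halves, with extrapolated SD."""

    replicates: np.ndarray
    sigma_bs: np.ndarray
    sigma: np.ndarray
    n_rep: int
    n_failed: int = 0

    @property
    def mean(self):
        return self.replicates.mean(axis=0)


@dataclass
class TestResult:
    """A two-sided test with Bonferroni-corrected star coding."""

    test: str
    statistic: float
    pvalue: float
    family_size: int
    levels: tuple[float, ...]
    stars: str

    @property
    def significant(self) -> bool:
        return self.pvalue <= self.levels[0] / self.family_size


def split_random_halves(loc: LocationMatrix, block_s: float = DEFAULT_BLOCK_S,
                        seed: int | None = None) -> HalfSplit:
    """Partition the window's bins into two random halves of whole blocks.

    Blocks are tiled from the window start along the bin axis; a trailing
    partial block is dropped.  Deterministic given the seed.
    """
    bins_per_block = int(round(block_s / loc.resolution))
    n_blocks = loc.n_bins // bins_per_block
    if n_blocks < 2:
        raise ValueError(
            f"window too short: {loc.n_bins} bins make {n_blocks} blocks "
            f"of {block_s} s")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_blocks)
    half = n_blocks // 2
    block_of = np.arange(loc.n_bins) // bins_per_block

    def bins_of(blocks):
        return np.flatnonzero(np.isin(block_of, blocks))

    return HalfSplit(half_a=bins_of(order[:half]),
                     half_b=bins_of(order[half:2 * half + n_blocks % 2]),
                     n_blocks=n_blocks, block_s=block_s, seed=seed)


def bootstrap_sigma(statistic, loc: LocationMatrix, n_rep: int = 10,
                    seed: int | None = 0, block_s: float = DEFAULT_BLOCK_S,
                    extrapolate: str = "sqrt2") -> BootstrapEstimate:
    """SD of ``statistic`` over random halves, extrapolated to full data.

    ``statistic`` maps a LocationMatrix to a scalar or array (it may
    involve refitting a model).  Each repetition evaluates it on one
    random half; failures are dropped with a warning above 20%.
    ``extrapolate="half"`` applies the literal division by two instead of
    the sqrt(2) scaling.
    """
    rng = np.random.default_rng(seed)
    reps, failures = [], 0
    for _ in range(n_rep):
        split = split_random_halves(loc, block_s,
                                    seed=int(rng.integers(2 ** 31)))
        try:
            reps.append(np.asarray(statistic(loc.restrict_bins(split.half_a)),
                                   dtype=float))
        except Exception as err:  # noqa: BLE001 - replicate-level guard
            failures += 1
            warnings.warn(f"bootstrap replicate failed: {err!r}")
    if not reps:
        raise RuntimeError("all bootstrap replicates failed")
    if failures > 0.2 * n_rep:
        warnings.warn(f"{failures}/{n_rep} bootstrap replicates failed")
    reps = np.stack(reps)
    sigma_bs = reps.std(axis=0, ddof=1)
    factor = np.sqrt(2.0) if extrapolate == "sqrt2" else 2.0
    return BootstrapEstimate(replicates=reps, sigma_bs=sigma_bs,
                             sigma=sigma_bs / factor, n_rep=len(reps),
                             n_failed=failures)


def _stars(p: float, family_size: int, levels) -> str:
    return "*" * int(sum(p <= lvl / family_size for lvl in levels))


def compare_groups(a, b, test: str = "welch_t",
                   family_size: int = BONFERRONI_FAMILY,
                   levels: tuple[float, ...] = STAR_LEVELS) -> TestResult:
    """Two-sided Welch t-test or two-sample F-test with Bonferroni stars.

    ``levels`` selects the star convention: ``STAR_LEVELS`` for mean and
    variance comparisons, ``STAR_LEVELS_DTI`` for the stricter global-DTI
    convention.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least two values per group")
    if test == "welch_t":
        if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
            raise ValueError("both groups have zero variance")
        stat, p = sps.ttest_ind(a, b, equal_var=False)
    elif test == "f_var":
        va, vb = a.var(ddof=1), b.var(ddof=1)
        if vb == 0:
            raise ValueError("zero variance in the second group")
        stat = va / vb
        dist = sps.f(a.size - 1, b.size - 1)
        p = 2.0 * min(dist.cdf(stat), dist.sf(stat))
    else:
        raise ValueError(f"unknown test {test!r}")
    return TestResult(test=test, statistic=float(stat), pvalue=float(p),
                      family_size=family_size, levels=tuple(levels),
                      stars=_stars(float(p), family_size, levels))
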