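"""Empirical co-localization statistics of a discretized cohort.

These are the observables the maximum-entropy models constrain or predict:
per-mouse compartment occupancies, pairwise and triplet same-compartment
probabilities, in-cohort sociability (excess co-localization beyond
independence), and the distribution of how many mice share a compartment.

Pseudocounted quantities (additive smoothing with strength ``lam``,
default 8) feed model inference, where a mouse camping in one compartment
for a whole window would otherwise produce infinite fields; sociability
and the triplet correlations are computed on raw frequencies, since
smoothing would bias their zero point.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ensemble import triplet_index
from .events import LocationMatrix

__all__ = [
    "OccupancyStats",
    "PairStats",
    "TripletStats",
    "OccupancyHistogram",
    "occupancy_frequencies",
    "pair_cooccupancy",
    "in_cohort_sociability",
    "triplet_correlations",
    "k_occupancy_distribution",
    "pseudocounted_frequencies",
]

DEFAULT_PSEUDOCOUNT = 8.0


def pseudocounted_frequencies(counts: np.ndarray, n_obs, lam: float, q: int,
                              prior: float | None = None) -> np.ndarray:
    """Additively smoothed frequencies ``(lam*prior + counts) / (n_obs + lam)``.

    ``prior`` defaults to ``1/q``, the value appropriate both for a single
    mouse's compartment and for the chance of two mice sharing one.  With
    ``n_obs == 0`` the estimate falls back to the prior itself.
    """
    if prior is None:
        prior = 1.0 / q
    counts = np.asarray(counts, dtype=float)
    denom = np.asarray(n_obs, dtype=float) + lam
    return (lam * prior + counts) / denom


def _masked_onehot(loc: LocationMatrix):
    """(q, N, T) float32 one-hot of valid labels, plus the valid mask."""
    X = np.zeros((loc.q, loc.n_mice, loc.n_bins), dtype=np.float32)
    for r in range(1, loc.q + 1):
        X[r - 1] = (loc.sigma == r) & loc.valid
    return X, loc.valid.astype(np.float32)


@dataclass
class OccupancyStats:
    """Per-mouse compartment occupancy probabilities.

    ``m`` is pseudocounted (used for inference), ``f`` is the raw
    frequency, ``t_used`` the number of valid bins per mouse.
    """

    m: np.ndarray
    f: np.ndarray
    lam: float
    q: int
    t_used: np.ndarray
    mouse_ids: list[str] = field(default_factory=list)


@dataclass
class PairStats:
    """Pairwise same-compartment statistics.

    ``gamma`` is the pseudocounted probability that two mice share a
    compartment; ``c`` is the in-cohort sociability (raw excess
    co-localization over the independent prediction); ``f_pair`` the raw
    joint frequencies ``f_ij(r, r')``; ``t_joint`` jointly valid bins.
    """

    gamma: np.ndarray
    c: np.ndarray
    f_pair: np.ndarray
    t_joint: np.ndarray
    lam: float
    q: int


@dataclass
class TripletStats:
    """Three-mouse statistics on the i<j<k triplets.

    ``c3`` — fully connected third cumulant; ``c3_star`` — same-compartment
    triplet probability minus the product of individual preferences;
    ``gamma3`` — raw triplet coincidence probability.  All are vectors
    aligned with :func:`ecohab_maxent.ensemble.triplet_index`.
    """

    c3: np.ndarray
    c3_star: np.ndarray
    gamma3: np.ndarray
    n_mice: int

    def index(self):
        return triplet_index(self.n_mice)


@dataclass
class OccupancyHistogram:
    """Distribution of the number of mice simultaneously in a compartment."""

    per_compartment: np.ndarray  # (q, N+1)
    aggregated: np.ndarray  # (N+1,), averaged over compartments
    support: np.ndarray


def occupancy_frequencies(loc: LocationMatrix,
                          lam: float = DEFAULT_PSEUDOCOUNT) -> OccupancyStats:
    """Pseudocounted and raw per-mouse compartment occupancies."""
    t_used = loc.valid.sum(axis=1)
    if (t_used == 0).any():
        bad = [m for m, t in zip(loc.mouse_ids, t_used) if t == 0]
        raise ValueError(f"mice with no valid bins (exclude them first): {bad}")
    X, _ = _masked_onehot(loc)
    counts = X.sum(axis=2).T.astype(float)  # (N, q)
    m = pseudocounted_frequencies(counts, t_used[:, None], lam, loc.q)
    f = counts / t_used[:, None]
    return OccupancyStats(m=m, f=f, lam=lam, q=loc.q, t_used=t_used,
                          mouse_ids=list(loc.mouse_ids))


def pair_cooccupancy(loc: LocationMatrix,
                     lam: float = DEFAULT_PSEUDOCOUNT) -> PairStats:
    """Pairwise coincidence probabilities and in-cohort sociability.

    Each pair statistic uses only bins where both mice are valid; the
    marginals entering the sociability are taken over the same bins so
    independent mice give zero in expectation.
    """
    if loc.n_mice < 2:
        raise ValueError("need at least two mice")
    X, V = _masked_onehot(loc)
    n, q = loc.n_mice, loc.q
    t_joint = V @ V.T
    same = np.zeros((n, n), dtype=np.float64)
    c = np.zeros((n, n), dtype=np.float64)
    f_pair = np.zeros((n, n, q, q), dtype=np.float64)
    with np.errstate(invalid="ignore", divide="ignore"):
        for r in range(q):
            for s in range(q):
                f_pair[:, :, r, s] = (X[r] @ X[s].T) / t_joint
        for r in range(q):
            srr = X[r] @ X[r].T
            same += srr
            # marginal of mouse i over bins jointly valid with j
            mr = (X[r] @ V.T) / t_joint
            c += srr / t_joint - mr * mr.T
    gamma = pseudocounted_frequencies(same, t_joint, lam, q)
    np.fill_diagonal(gamma, 1.0)
    np.fill_diagonal(c, np.nan)
    return PairStats(gamma=gamma, c=c, f_pair=f_pair, t_joint=t_joint,
                     lam=lam, q=q)


def in_cohort_sociability(loc: LocationMatrix) -> np.ndarray:
    """Excess probability of two mice sharing a compartment (NaN diagonal)."""
    return pair_cooccupancy(loc).c


def triplet_correlations(loc: LocationMatrix) -> TripletStats:
    """Raw three-mouse correlations over the i<j<k triplets."""
    if loc.n_mice < 3:
        raise ValueError("need at least three mice")
    X, V = _masked_onehot(loc)
    n, q = loc.n_mice, loc.q
    ti, tj, tk = triplet_index(n)
    nt = len(ti)
    t3 = np.einsum("it,jt,kt->ijk", V, V, V, optimize=True)[ti, tj, tk]

    gamma3 = np.zeros(nt)
    c3_star = np.zeros(nt)
    c3 = np.zeros(nt)
    for r in range(q):
        A, B = X[r], V
        e = lambda x, y, z: np.einsum("it,jt,kt->ijk", x, y, z,
                                      optimize=True)[ti, tj, tk]
        fijk = e(A, A, A) / t3
        mi = e(A, B, B) / t3
        mj = e(B, A, B) / t3
        mk = e(B, B, A) / t3
        fjk = e(B, A, A) / t3
        fik = e(A, B, A) / t3
        fij = e(A, A, B) / t3
        gamma3 += fijk
        c3_star += fijk - mi * mj * mk
        c3 += fijk - mi * fjk - mj * fik - mk * fij + 2 * mi * mj * mk
    return TripletStats(c3=c3, c3_star=c3_star, gamma3=gamma3, n_mice=n)


def k_occupancy_distribution(loc: LocationMatrix) -> OccupancyHistogram:
    """How many mice share a compartment, per compartment and pooled.

    Counts valid mice only; the pooled histogram averages the
    per-compartment distributions.
    """
    X, _ = _masked_onehot(loc)
    n = loc.n_mice
    support = np.arange(n + 1)
    per = np.zeros((loc.q, n + 1))
    for r in range(loc.q):
        k = X[r].sum(axis=0).astype(int)
        per[r] = np.bincount(k, minlength=n + 1) / loc.n_bins
    return OccupancyHistogram(per_compartment=per, aggregated=per.mean(axis=0),
                              support=support)
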