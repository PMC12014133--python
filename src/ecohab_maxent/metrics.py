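"""Sociability read-outs derived from data plus a fitted pairwise model.

* nested conditional log-likelihoods — how much individual compartment
  preferences and pairwise interactions each add over a uniform null;
* in-state calibration — is the model's conditional probability of a
  mouse's compartment an unbiased predictor;
* mutual information between one mouse's position and the rest of the
  cohort, in bits (0 = unpredictable, 2 = perfectly predictable over four
  compartments);
* food-compartment preference from the gauged fields;
* the dissatisfaction triplet index (DTI), a frustration statistic on the
  signed coupling network.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ensemble import pair_index, triplet_index
from .events import LocationMatrix
from .stats import DEFAULT_PSEUDOCOUNT, occupancy_frequencies
from .topology import HabitatTopology

__all__ = [
    "LikelihoodReport",
    "CalibrationCurve",
    "MIReport",
    "FoodPreference",
    "DTIReport",
    "conditional_loglikelihoods",
    "in_state_calibration",
    "mutual_information",
    "food_preference",
    "global_dti",
]


def _conditional_probs(h, J, loc: LocationMatrix) -> np.ndarray:
    from .model import conditional_distribution

    return conditional_distribution(h, J, loc)


@dataclass
class LikelihoodReport:
    """Per-mouse mean conditional log-likelihoods of the nested models.

    ``l0`` — uniform null, exactly ``log(1/q)``; ``l1`` — independent
    model using each mouse's own (pseudocounted) occupancy; ``l12`` — the
    pairwise model's conditional given everyone else's position.  Natural
    log, per 2-s observation.
    """

    l0: float
    l1: np.ndarray
    l12: np.ndarray
    mouse_ids: list[str] | None = None


def conditional_loglikelihoods(h, J, loc: LocationMatrix, *, occ=None,
                               lam: float = DEFAULT_PSEUDOCOUNT
                               ) -> LikelihoodReport:
    """Time-averaged log-likelihood of each mouse's observed location."""
    n, q = h.shape
    if occ is None:
        occ = occupancy_frequencies(loc, lam)
    p_cond = _conditional_probs(h, J, loc)
    l1 = np.zeros(n)
    l12 = np.zeros(n)
    for i in range(n):
        ok = loc.valid[i]
        obs = loc.sigma[i, ok].astype(int) - 1
        l1[i] = np.log(occ.m[i, obs]).mean()
        l12[i] = np.log(p_cond[i, obs, np.flatnonzero(ok)]).mean()
    return LikelihoodReport(l0=float(np.log(1.0 / q)), l1=l1, l12=l12,
                            mouse_ids=list(loc.mouse_ids))


@dataclass
class CalibrationCurve:
    """Predicted in-state probability vs observed frequency, by percentile.

    ``pred``/``obs`` are averaged over mice and compartments at fixed
    percentile bin; ``per_mouse_*`` keep the (N, n_bins) resolution.  A
    well-calibrated (unbiased) model lies on the diagonal.
    """

    pred: np.ndarray
    obs: np.ndarray
    per_mouse_pred: np.ndarray
    per_mouse_obs: np.ndarray
    n_bins: int


def in_state_calibration(h, J, loc: LocationMatrix,
                         n_bins: int = 10) -> CalibrationCurve:
    """Percentile-binned calibration of the conditional compartment model.

    For each mouse and compartment the model-predicted conditional
    probabilities are ranked across time into equal-count bins; within a
    bin the mean prediction is compared to the frequency with which the
    mouse was actually there.
    """
    n, q = h.shape
    p_cond = _conditional_probs(h, J, loc)
    pm_pred = np.zeros((n, n_bins))
    pm_obs = np.zeros((n, n_bins))
    for i in range(n):
        ok = np.flatnonzero(loc.valid[i])
        obs_sig = loc.sigma[i, ok].astype(int) - 1
        acc_p = np.zeros((q, n_bins))
        acc_o = np.zeros((q, n_bins))
        for r in range(q):
            p = p_cond[i, r, ok]
            hit = (obs_sig == r).astype(float)
            order = np.argsort(p, kind="stable")
            chunks = np.array_split(order, n_bins)
            for b, ch in enumerate(chunks):
                acc_p[r, b] = p[ch].mean()
                acc_o[r, b] = hit[ch].mean()
        pm_pred[i] = acc_p.mean(axis=0)
        pm_obs[i] = acc_o.mean(axis=0)
    return CalibrationCurve(pred=pm_pred.mean(axis=0), obs=pm_obs.mean(axis=0),
                            per_mouse_pred=pm_pred, per_mouse_obs=pm_obs,
                            n_bins=n_bins)


@dataclass
class MIReport:
    """Mutual information between each mouse and the rest of the cohort."""

    mi_bits: np.ndarray
    marginal_entropy_bits: np.ndarray
    conditional_entropy_bits: np.ndarray
    mouse_ids: list[str] | None = None

    @property
    def mean(self) -> float:
        return float(self.mi_bits.mean())


def mutual_information(h, J, loc: LocationMatrix, *, occ=None,
                       lam: float = DEFAULT_PSEUDOCOUNT,
                       marginal: str = "empirical", space=None) -> MIReport:
    """I(sigma_i; rest) = H(sigma_i) - <H(sigma_i | rest)>, in bits.

    The conditional entropy averages the entropy of the model's
    closed-form conditional over the observed configurations of the other
    mice.  The marginal entropy uses the pseudocounted empirical occupancy
    by default (``marginal="model"`` substitutes the model marginal from
    exact enumeration).
    """
    n, q = h.shape
    if marginal == "model":
        if space is None:
            from .ensemble import StateSpace

            space = StateSpace(n, q)
        marg = space.moments(h, J).m
    else:
        if occ is None:
            occ = occupancy_frequencies(loc, lam)
        marg = occ.m
    h_marg = -(marg * np.log2(marg)).sum(axis=1)
    p_cond = _conditional_probs(h, J, loc)
    h_cond = np.zeros(n)
    with np.errstate(invalid="ignore"):
        ent_t = -(p_cond * np.log2(np.where(p_cond > 0, p_cond, 1.0))).sum(axis=1)
    for i in range(n):
        h_cond[i] = ent_t[i, loc.valid[i]].mean()
    return MIReport(mi_bits=h_marg - h_cond, marginal_entropy_bits=h_marg,
                    conditional_entropy_bits=h_cond,
                    mouse_ids=list(loc.mouse_ids))


@dataclass
class FoodPreference:
    """Field imbalance toward the food compartments, per mouse."""

    delta_h: np.ndarray
    food_compartments: tuple[int, ...]
    mouse_ids: list[str] | None = None

    @property
    def mean(self) -> float:
        return float(self.delta_h.mean())

    @property
    def var(self) -> float:
        return float(self.delta_h.var(ddof=1))


def food_preference(h, topology: HabitatTopology) -> FoodPreference:
    """Delta h_i = sum of gauged fields over food compartments minus the
    rest — gauge-invariant because it is a difference of sums."""
    from .model import fix_gauge

    hg = fix_gauge(h)
    food = sorted(topology.food_compartments)
    food_idx = [r - 1 for r in food]
    other_idx = [r - 1 for r in topology.compartments if r not in food]
    dh = hg[:, food_idx].sum(axis=1) - hg[:, other_idx].sum(axis=1)
    return FoodPreference(delta_h=dh, food_compartments=tuple(food))


@dataclass
class DTIReport:
    """Dissatisfaction triplet index: frustration of the coupling network.

    A triangle of couplings with exactly one negative edge cannot satisfy
    all three preferences at once; its local index is ``-J_ij J_jk J_ki``
    (positive in that case) and zero for any other sign pattern.  The
    global index ``F`` averages over all triangles.
    """

    f_triplets: np.ndarray
    f_global: float
    shuffled: np.ndarray | None = None

    @property
    def shuffled_mean(self) -> float | None:
        return None if self.shuffled is None else float(self.shuffled.mean())


def global_dti(J: np.ndarray, *, n_shuffles: int = 0,
               seed: int | None = 0) -> DTIReport:
    """Per-triplet and global DTI, with an optional shuffled-J reference.

    Shuffling permutes the coupling values over the pairs (preserving the
    multiset); a structured network shows a global DTI different from its
    shuffled reference, an unstructured one does not.
    """
    n = J.shape[0]
    if n < 3:
        raise ValueError("DTI needs at least three mice")
    ti, tj, tk = triplet_index(n)

    def dti_of(Jm):
        a, b, c = Jm[ti, tj], Jm[tj, tk], Jm[tk, ti]
        one_neg = ((a < 0).astype(int) + (b < 0).astype(int)
                   + (c < 0).astype(int)) == 1
        return np.where(one_neg, -(a * b * c), 0.0)

    f = dti_of(J)
    shuffled = None
    if n_shuffles:
        rng = np.random.default_rng(seed)
        iu, ju = pair_index(n)
        vals = J[iu, ju]
        shuffled = np.empty(n_shuffles)
        for s in range(n_shuffles):
            perm = rng.permutation(vals)
            Jp = np.zeros_like(J)
            Jp[iu, ju] = perm
            Jp[ju, iu] = perm
            shuffled[s] = dti_of(Jp).mean()
    return DTIReport(f_triplets=f, f_global=float(f.mean()), shuffled=shuffled)
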