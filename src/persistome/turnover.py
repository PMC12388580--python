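"""Temporal turnover of community composition.

PCoA ordination of a dissimilarity matrix, one-way ANOSIM across
developmental stages, the time-decay relationship (log10 community
similarity regressed on log10 time separation; its slope w is the
turnover rate), and an ANCOVA-style comparison of two turnover slopes
(e.g. taxonomic Bray-Curtis vs phylogenetic weighted-UniFrac decay)
supplemented with a permutation test, because pairwise similarity points
are not independent.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from skbio import DistanceMatrix
from skbio.stats.distance import anosim as _skbio_anosim
from skbio.stats.ordination import pcoa as _skbio_pcoa


@dataclass
class PcoaResult:
    samples: pd.DataFrame            # coordinates on positive-eigenvalue axes
    eigvals: pd.Series               # all eigenvalues, descending (negatives kept)
    proportion_explained: pd.Series  # over positive eigenvalues only
    negative_eigvals: list


@dataclass
class AnosimResult:
    r_statistic: float
    p_value: float
    n_permutations: int


@dataclass
class TimeDecayFit:
    slope_w: float
    intercept: float
    r_squared: float
    p_value: float
    n_pairs: int
    pairs: list = field(default_factory=list)   # (log10 dt, log10 similarity)
    n_dropped_zero_similarity: int = 0


@dataclass
class SlopeComparison:
    f_statistic: float
    p_value: float
    slope_difference: float
    permutation_p: float


def _as_dm(dist) -> DistanceMatrix:
    if isinstance(dist, DistanceMatrix):
        return dist
    arr = np.asarray(dist, dtype=float)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(arr, arr.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    return DistanceMatrix(arr)


def pcoa(dist) -> PcoaResult:
    """Principal coordinate analysis via Gower double-centering.

    Coordinates are returned for positive-eigenvalue axes only; negative
    eigenvalues (non-Euclidean input) are reported, not corrected.
    """
    dm = _as_dm(dist)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = _skbio_pcoa(dm, method="eigh", warn_neg_eigval=False)
    eig = res.eigvals
    pos = eig[eig > 1e-10 * max(eig.abs().max(), 1.0)]
    samples = res.samples[pos.index]
    prop = pos / pos.sum() if len(pos) else pos
    return PcoaResult(samples=samples, eigvals=eig,
                      proportion_explained=prop,
                      negative_eigvals=[float(e) for e in eig[eig < 0]])


def anosim(dist, groups, n_perm: int = 999, seed: int = 0) -> AnosimResult:
    """One-way analysis of similarity.

    R = (mean between-group rank - mean within-group rank) / (M/4),
    M = number of sample pairs; p by label permutation.
    """
    dm = _as_dm(dist)
    labels = np.asarray(groups)
    if len(labels) != dm.shape[0]:
        raise ValueError("groups must align with the distance matrix")
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("need >= 2 groups")
    if (counts < 2).any():
        raise ValueError("every group needs >= 2 samples")
    if n_perm < 99:
        raise ValueError("use >= 99 permutations")
    res = _skbio_anosim(dm, labels, permutations=n_perm, seed=seed)
    return AnosimResult(float(res["test statistic"]), float(res["p-value"]),
                        int(res["number of permutations"]))


def anosim_r(dist, groups) -> float:
    """Observed ANOSIM R alone (no permutations)."""
    dm = _as_dm(dist)
    labels = np.asarray(groups)
    n = dm.shape[0]
    iu = np.triu_indices(n, k=1)
    d = dm.data[iu]
    ranks = stats.rankdata(d)
    within = labels[iu[0]] == labels[iu[1]]
    if within.all() or not within.any():
        raise ValueError("need both within- and between-group pairs")
    r_b = ranks[~within].mean()
    r_w = ranks[within].mean()
    # Clarke's denominator n(n-1)/4, i.e. half the number of unordered pairs
    return float((r_b - r_w) / (n * (n - 1) / 4.0))


def time_decay_fit(dist, times, mode: str = "interval") -> TimeDecayFit:
    """Time-decay of community similarity, log-log linear regression.

    similarity = 1 - dissimilarity; unordered sample pairs with
    time separation > 0 and similarity > 0 are retained (zero-similarity
    pairs are dropped and counted). y = log10(similarity) is regressed
    on x = log10(dt) by OLS; the slope is the turnover rate w.

    mode: ``interval`` regresses on the pairwise time separation dt
    (default); ``age`` regresses on the mean age of the pair.
    """
    dm = _as_dm(dist)
    t = pd.Series(times).reindex(pd.Index(dm.ids)) if isinstance(times, (pd.Series, dict)) \
        else pd.Series(np.asarray(times, dtype=float), index=dm.ids)
    if t.isna().any():
        raise ValueError("times missing for some samples")
    tv = t.to_numpy(dtype=float)
    n = dm.shape[0]
    xs, ys = [], []
    n_zero_sim = 0
    for i, j in itertools.combinations(range(n), 2):
        dt = abs(tv[i] - tv[j])
        if dt <= 0:
            continue
        sim = 1.0 - dm.data[i, j]
        if sim <= 0:
            n_zero_sim += 1
            continue
        x = dt if mode == "interval" else 0.5 * (tv[i] + tv[j])
        xs.append(np.log10(x))
        ys.append(np.log10(sim))
    if len(xs) < 3:
        raise ValueError(f"insufficient data: only {len(xs)} usable pairs")
    xs = np.asarray(xs)
    ys = np.asarray(ys)
    if np.ptp(xs) == 0:
        raise ValueError("degenerate regressor: all time separations equal")
    res = stats.linregress(xs, ys)
    return TimeDecayFit(slope_w=float(res.slope), intercept=float(res.intercept),
                        r_squared=float(res.rvalue ** 2),
                        p_value=float(res.pvalue), n_pairs=len(xs),
                        pairs=list(zip(xs.tolist(), ys.tolist())),
                        n_dropped_zero_similarity=n_zero_sim)


def _interaction_f(x, y, g):
    """F statistic (= t^2) and p for the slope x group interaction."""
    X = np.column_stack([np.ones_like(x), x, g, x * g])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = len(y) - X.shape[1]
    sse = float(resid @ resid)
    coef = float(beta[3])
    if dof <= 0:
        return np.nan, np.nan, coef
    # numerically zero residual: the stacked model fits both lines exactly
    if sse <= 1e-12 * (1.0 + float(y @ y)):
        if abs(coef) < 1e-8:
            return 0.0, 1.0, coef
        return np.inf, 0.0, coef
    sigma2 = sse / dof
    xtx_inv = np.linalg.pinv(X.T @ X)
    se = np.sqrt(sigma2 * xtx_inv[3, 3])
    if se == 0.0:
        return (0.0, 1.0, coef) if coef == 0.0 else (np.inf, 0.0, coef)
    tstat = coef / se
    f = tstat ** 2
    p = 2.0 * stats.t.sf(abs(tstat), dof)
    return float(f), float(p), coef


def compare_slopes(fit_a: TimeDecayFit, fit_b: TimeDecayFit,
                   n_perm: int = 999, seed: int = 0) -> SlopeComparison:
    """ANCOVA-style test of whether two time-decay slopes differ.

    Stacked regression y ~ x + group + x:group; F and parametric p for
    the interaction term, plus a permutation p (group labels of points
    shuffled) as the pairwise points violate independence.
    """
    if not fit_a.pairs or not fit_b.pairs:
        raise ValueError("fits must carry their (x, y) pair lists")
    xa, ya = map(np.asarray, zip(*fit_a.pairs))
    xb, yb = map(np.asarray, zip(*fit_b.pairs))
    x = np.concatenate([xa, xb])
    y = np.concatenate([ya, yb])
    g = np.concatenate([np.zeros(len(xa)), np.ones(len(xb))])
    if np.ptp(x) == 0:
        raise ValueError("degenerate regressor: all x equal")
    f_obs, p_param, coef = _interaction_f(x, y, g)
    slope_diff = float(fit_b.slope_w - fit_a.slope_w)

    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        gp = rng.permutation(g)
        _, _, coef_p = _interaction_f(x, y, gp)
        if abs(coef_p) >= abs(coef) - 1e-15:
            exceed += 1
    perm_p = (exceed + 1) / (n_perm + 1)
    return SlopeComparison(f_statistic=f_obs, p_value=p_param,
                           slope_difference=slope_diff,
                           permutation_p=float(perm_p))
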