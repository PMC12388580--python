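"""Sloan neutral community model: fit, null comparison, ASV partition.

The Sloan model treats a local community of size Nt as continuously
sampled from a source community; a taxon of source mean relative
abundance p is predicted to be detected (frequency above the detection
limit d = 1/Nt) with probability

    occ(p, m) = 1 - I_d(Nt*m*p, Nt*m*(1 - p))

where I is the regularized incomplete beta function and m the migration
(dispersal) parameter. Detection in sequencing data is count-based (a
taxon is seen iff it draws >= 1 of the Nt reads), whose exact
probability under the same model is the beta-binomial form

    occ(p, m) = 1 - B(a, b + Nt) / B(a, b),   a = Nt*m*p, b = Nt*m*(1-p)

i.e. 1 - E[(1 - x)^Nt] over the Sloan frequency distribution. The
count-detection form is the fitting default (the frequency-threshold
form systematically overestimates m on count tables because taxa with
frequency just below d are still frequently detected); the classic form
is available as ``detection="frequency"`` and as `sloan_occupancy`.

m is estimated by least squares between observed and predicted
occupancy across taxa. The null alternative is a binomial sampling
model, occ(p) = 1 - (1 - p)^Nt, with no free parameter; both are
compared by Gaussian-error AIC from the SSE. Taxa above the Wilson 95%
band around the fitted curve are environmentally selected, below it
dispersal-limited, inside it neutral.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special
from statsmodels.stats.proportion import proportion_confint

from .containers import AbsoluteTable, CountTable


class FitFailure(RuntimeError):
    """Optimizer could not produce a usable migration estimate."""


@dataclass
class NeutralFit:
    m: float
    Nt: float
    d: float
    r_squared: float
    aic: float
    sse: float
    n_taxa: int
    n_samples: int
    per_asv: pd.DataFrame = field(repr=False, default=None)
    # per_asv columns: p, observed, predicted, ci_lower, ci_upper, partition


@dataclass
class BinomialFit:
    aic: float
    r_squared: float
    sse: float
    n_taxa: int
    per_asv: pd.DataFrame = field(repr=False, default=None)


def sloan_occupancy(p, m: float, Nt: float) -> np.ndarray:
    """Frequency-threshold Sloan prediction: P(local frequency > 1/Nt)."""
    p = np.asarray(p, dtype=float)
    d = 1.0 / Nt
    a = Nt * m * p
    b = Nt * m * (1.0 - p)
    with np.errstate(invalid="ignore"):
        pred = 1.0 - special.betainc(a, b, d)
    return np.clip(np.where(np.isfinite(pred), pred, 0.0), 0.0, 1.0)


def sloan_occupancy_counts(p, m: float, Nt: float) -> np.ndarray:
    """Count-detection Sloan prediction: P(>= 1 read among Nt).

    Beta-binomial zero-class complement, 1 - B(a, b+Nt)/B(a, b).
    """
    p = np.asarray(p, dtype=float)
    a = Nt * m * p
    b = Nt * m * (1.0 - p)
    with np.errstate(invalid="ignore"):
        pred = 1.0 - np.exp(special.betaln(a, b + Nt) - special.betaln(a, b))
    return np.clip(np.where(np.isfinite(pred), pred, 0.0), 0.0, 1.0)


def binomial_occupancy(p, Nt: float) -> np.ndarray:
    """Detection probability under pure binomial sampling at depth Nt."""
    p = np.asarray(p, dtype=float)
    return 1.0 - np.exp(Nt * np.log1p(-np.clip(p, 0.0, 1.0 - 1e-16)))


def _table_stats(table, allow_noninteger: bool):
    df = table.asv_counts if isinstance(table, CountTable) else (
        table.counts if isinstance(table, AbsoluteTable) else pd.DataFrame(table))
    x = df.to_numpy(dtype=float)
    if (x < 0).any():
        raise ValueError("counts must be non-negative")
    if not allow_noninteger and not np.allclose(x, np.round(x)):
        raise ValueError("expected integer read counts; pass allow_noninteger=True "
                         "for calibrated tables")
    if df.shape[1] < 10 or df.shape[0] < 5:
        raise ValueError("need >= 10 taxa and >= 5 samples")
    totals = x.sum(axis=1)
    if (totals == 0).any():
        raise ValueError("all-zero samples present")
    rel = x / totals[:, None]
    p = rel.mean(axis=0)
    observed = (x > 0).mean(axis=0)
    Nt = float(totals.mean())
    # taxa never observed carry p = occupancy = 0: no information, drop
    keep = p > 0
    return df.loc[:, keep], p[keep], observed[keep], Nt


def _aic_from_sse(sse: float, n: int, k: int) -> float:
    # Gaussian-error AIC for a least-squares fit with k free parameters
    return n * np.log(max(sse, 1e-300) / n) + 2 * k


def fit_sloan(table, allow_noninteger: bool = False,
              ci_level: float = 0.95,
              detection: str = "counts") -> NeutralFit:
    """Least-squares Sloan fit of occupancy vs mean relative abundance.

    Multi-start bounded 1-D optimization of m in (1e-6, 1]; R^2 computed
    against the observed-occupancy mean; Wilson score intervals (at
    ``ci_level``, n = number of samples) around the fitted curve define
    the neutral band for the per-ASV partition.

    ``detection``: ``counts`` (default, beta-binomial >= 1-read
    detection) or ``frequency`` (classic threshold at d = 1/Nt).
    """
    if detection not in ("counts", "frequency"):
        raise ValueError("detection must be 'counts' or 'frequency'")
    occ_fn = sloan_occupancy_counts if detection == "counts" else sloan_occupancy
    df, p, observed, Nt = _table_stats(table, allow_noninteger)
    n_taxa = len(p)
    n_samples = df.shape[0]

    def sse_of(m):
        return float(np.sum((observed - occ_fn(p, m, Nt)) ** 2))

    # multi-start: bracket each start, refine the best bracket by bounded search
    starts = (0.01, 0.1, 0.5, 0.9)
    best_x, best_f = None, np.inf
    for start in starts:
        lo, hi = max(1e-6, start / 10.0), min(1.0, start * 10.0)
        res = optimize.minimize_scalar(sse_of, bounds=(lo, hi),
                                       method="bounded",
                                       options={"xatol": 1e-10})
        if np.isfinite(res.fun) and res.fun < best_f:
            best_x, best_f = float(res.x), float(res.fun)
    if best_x is None:
        raise FitFailure("Sloan SSE minimization did not converge")
    m_hat = float(np.clip(best_x, 1e-6, 1.0))
    sse = sse_of(m_hat)
    sst = float(np.sum((observed - observed.mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else np.nan
    aic = _aic_from_sse(sse, n_taxa, k=1)

    predicted = occ_fn(p, m_hat, Nt)
    ci_lo, ci_hi = proportion_confint(
        predicted * n_samples, n_samples, alpha=1 - ci_level,
        method="wilson")
    ci_lo = np.minimum(ci_lo, predicted)
    ci_hi = np.maximum(ci_hi, predicted)
    partition = np.where(observed > ci_hi, "above",
                         np.where(observed < ci_lo, "below", "neutral"))
    per_asv = pd.DataFrame({
        "p": p, "observed": observed, "predicted": predicted,
        "ci_lower": ci_lo, "ci_upper": ci_hi, "partition": partition,
    }, index=df.columns)
    per_asv.index.name = "asv_id"
    return NeutralFit(m=m_hat, Nt=Nt, d=1.0 / Nt, r_squared=r2, aic=aic,
                      sse=sse, n_taxa=n_taxa, n_samples=n_samples,
                      per_asv=per_asv)


def fit_binomial(table, allow_noninteger: bool = False) -> BinomialFit:
    """Parameter-free binomial sampling null on the same axes."""
    df, p, observed, Nt = _table_stats(table, allow_noninteger)
    predicted = binomial_occupancy(p, Nt)
    sse = float(np.sum((observed - predicted) ** 2))
    sst = float(np.sum((observed - observed.mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else np.nan
    per_asv = pd.DataFrame({"p": p, "observed": observed,
                            "predicted": predicted}, index=df.columns)
    per_asv.index.name = "asv_id"
    return BinomialFit(aic=_aic_from_sse(sse, len(p), k=0), r_squared=r2,
                       sse=sse, n_taxa=len(p), per_asv=per_asv)


def compare_models(neutral: NeutralFit, binom: BinomialFit) -> dict:
    """AIC model comparison; lower AIC wins, ties go to the simpler model."""
    if neutral.n_taxa != binom.n_taxa or \
            not neutral.per_asv.index.equals(binom.per_asv.index):
        raise ValueError("fits cover different taxa sets")
    delta = binom.aic - neutral.aic
    preferred = "neutral" if neutral.aic < binom.aic else "binomial"
    return {"preferred": preferred, "delta_aic": float(delta),
            "aic_neutral": float(neutral.aic), "aic_binomial": float(binom.aic)}
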