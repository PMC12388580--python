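"""Persistent-microbiome detection from abundance-occupancy structure.

Taxa are ranked by an occupancy-based index (stage-mean occupancy plus a
replicate-consistency term, abundance as tie-break), their cumulative
contribution to Bray-Curtis beta-diversity is accumulated along the
ranking, and the core is truncated where the marginal relative gain
falls to <= 2% (first-order-difference "elbow" / last-2%-increase rule).
This replaces presence/absence "core" definitions: membership requires
both wide distribution and real contribution to between-sample
structure.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import AbsoluteTable, CountTable


def _frame_and_meta(table, stage_labels=None):
    if isinstance(table, (CountTable, AbsoluteTable)):
        df = table.asv_counts if isinstance(table, CountTable) else table.counts
        if stage_labels is None and table.metadata is not None \
                and "stage" in table.metadata.columns:
            stage_labels = table.metadata["stage"]
    else:
        df = pd.DataFrame(table)
    if stage_labels is None:
        stages = pd.Series("all", index=df.index)
    else:
        stages = pd.Series(np.asarray(stage_labels), index=df.index)
    return df, stages


@dataclass
class CoreSet:
    ranked_ids: list
    cumulative_contribution: np.ndarray
    elbow_rank: int
    persistent_ids: list
    abundance_share: float
    occupancy: pd.DataFrame = field(default=None, repr=False)


def occupancy_abundance(table, stage_labels=None,
                        detection_threshold: float = 1.0) -> pd.DataFrame:
    """Occupancy, abundance and ranking index for every ASV.

    A taxon is "present" in a sample when its count >= detection
    threshold (default 1). The ranking index is

        rank_index = mean over stages of (fraction of that stage's
                     replicates where present)
                   + fraction of stages where present in ALL replicates

    so it rewards both even distribution across developmental stages and
    replicate-level consistency; ties are broken by mean log10 abundance.
    Returns a DataFrame indexed by asv_id, sorted by (rank_index,
    mean_log10_abundance) descending.
    """
    df, stages = _frame_and_meta(table, stage_labels)
    if df.shape[0] == 0:
        raise ValueError("table has no samples")
    present = (df >= detection_threshold)
    occupancy = present.mean(axis=0)

    stage_occ = present.groupby(stages, sort=False).mean()            # stage x asv
    stage_full = present.groupby(stages, sort=False).all()
    stage_mean_occ = stage_occ.mean(axis=0)
    replicate_consistency = stage_full.mean(axis=0)
    rank_index = stage_mean_occ + replicate_consistency

    with np.errstate(divide="ignore", invalid="ignore"):
        mean_abund = df.where(present).mean(axis=0)
        mean_log10 = np.log10(mean_abund.where(mean_abund > 0))

    out = pd.DataFrame({
        "occupancy": occupancy,
        "mean_log10_abundance": mean_log10,
        "rank_index": rank_index,
    })
    for st in stage_occ.index:
        out[f"occ_{st}"] = stage_occ.loc[st]
    out.index.name = "asv_id"
    return out.sort_values(["rank_index", "mean_log10_abundance"],
                           ascending=False, kind="mergesort")


def _pairwise_taxon_weights(df: pd.DataFrame, chunk: int = 200) -> pd.Series:
    """Per-taxon additive Bray-Curtis contribution weights.

    For each unordered sample pair, the full Bray-Curtis numerator
    sum_i |x_i - y_i| is partitioned across taxa; the weight of taxon i
    is the mean over pairs of |x_i - y_i| / (full numerator). Weights sum
    to 1 (pairs with identical profiles contribute nothing and are
    excluded from the mean).
    """
    x = df.to_numpy(dtype=float)
    n = x.shape[0]
    pairs = list(itertools.combinations(range(n), 2))
    ia = np.array([p[0] for p in pairs])
    ib = np.array([p[1] for p in pairs])
    weights = np.zeros(x.shape[1])
    used = 0
    for lo in range(0, len(pairs), chunk):
        sl = slice(lo, lo + chunk)
        diff = np.abs(x[ia[sl]] - x[ib[sl]])          # (chunk, taxa)
        num = diff.sum(axis=1)
        keep = num > 0
        if keep.any():
            weights += (diff[keep] / num[keep, None]).sum(axis=0)
            used += int(keep.sum())
    if used == 0:
        raise ValueError("all sample pairs identical; contribution undefined")
    return pd.Series(weights / used, index=df.columns)


def core_contribution(table, ranked_ids, k: int) -> float:
    """Mean share of Bray-Curtis dissimilarity carried by the top-k taxa.

    For each sample pair, sum_{i in top-k} |x_i - y_i| over the full
    numerator sum_i |x_i - y_i|; averaged over pairs. Equals 1 at
    k = n_taxa.
    """
    df, _ = _frame_and_meta(table)
    if not (1 <= k <= df.shape[1]):
        raise ValueError(f"k must be in [1, {df.shape[1]}]")
    w = _pairwise_taxon_weights(df)
    return float(w[list(ranked_ids)[:k]].sum())


def find_elbow(cumulative_contribution, last_increase_threshold: float = 0.02,
               relative: bool = True) -> int:
    """Stopping rank of the cumulative-contribution curve (1-based).

    Returns the largest rank r >= 2 whose first-order difference
    c[r] - c[r-1] still exceeds the threshold — by default relative to
    the running value (gain > 2% of c[r-1], the "last 2% increase"
    rule); with ``relative=False`` the absolute difference is compared.
    Returns 1 when no gain ever clears the threshold.
    """
    c = np.asarray(cumulative_contribution, dtype=float)
    if len(c) < 2:
        raise ValueError("need a sequence of length >= 2")
    if np.any(np.diff(c) < -1e-12):
        raise ValueError("cumulative contribution must be nondecreasing")
    gains = np.diff(c)
    ref = c[:-1] if relative else np.ones_like(gains)
    ok = gains > last_increase_threshold * ref
    if not ok.any():
        return 1
    return int(np.max(np.nonzero(ok)[0])) + 2    # diff index 0 <-> rank 2


def classify_persistent(table, stage_labels=None,
                        threshold: float = 0.02,
                        detection_threshold: float = 1.0,
                        relative_elbow: bool = True) -> CoreSet:
    """Full persistent-microbiome detection.

    Ranks taxa by occupancy (abundance tie-break), accumulates their
    Bray-Curtis contribution, cuts at the elbow, and reports the
    persistent membership plus its share of total community abundance.

    The contribution curve is computed on row-normalized (relative)
    profiles so that it measures compositional turnover; on an absolute
    table, differences in total load between samples would otherwise
    spread Bray-Curtis mass across every taxon in proportion to
    abundance and mask which taxa actually restructure. Occupancy,
    ranking and the abundance share still use the table as given.
    """
    df, stages = _frame_and_meta(table, stage_labels)
    occ = occupancy_abundance(df, stages, detection_threshold)
    ranked = list(occ.index)
    rel = df.div(df.sum(axis=1), axis=0)
    w = _pairwise_taxon_weights(rel)
    cumulative = np.cumsum(w[ranked].to_numpy())
    elbow = find_elbow(cumulative, threshold, relative=relative_elbow)
    persistent = ranked[:elbow]
    share = float(df[persistent].to_numpy().sum() / df.to_numpy().sum())
    return CoreSet(ranked_ids=ranked, cumulative_contribution=cumulative,
                   elbow_rank=elbow, persistent_ids=persistent,
                   abundance_share=share, occupancy=occ)
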