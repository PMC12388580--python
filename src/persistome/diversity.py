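"""Alpha and beta diversity plus stage-wise group comparison.

Alpha: observed richness, Shannon-Wiener (natural log, so Pielou's
J = H/ln S reaches 1 at perfect evenness), Pielou's evenness, Faith's
phylogenetic diversity (root-inclusive). Beta: Bray-Curtis and
normalized weighted UniFrac. Group comparison: Kruskal-Wallis omnibus,
pairwise Dunn tests with Benjamini-Hochberg correction, and a compact
letter display.

Metrics are computed on the table as given (reads or absolute copies,
the caller's choice); no rarefaction is applied.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from skbio import DistanceMatrix, TreeNode
from skbio.diversity import beta_diversity
from skbio.diversity.alpha import faith_pd
from statsmodels.stats.multitest import multipletests

from .containers import AbsoluteTable, CountTable


def _as_frame(table) -> pd.DataFrame:
    if isinstance(table, CountTable):
        return table.asv_counts
    if isinstance(table, AbsoluteTable):
        return table.counts
    return pd.DataFrame(table)


@dataclass
class AlphaRecord:
    sample_id: str
    richness: int
    shannon: float          # nats
    pielou: float           # nan when richness <= 1
    faith_pd: float         # nan when no tree given


def alpha_diversity(table, tree: TreeNode | None = None) -> pd.DataFrame:
    """Per-sample alpha diversity.

    Returns a DataFrame indexed by sample id with columns richness,
    shannon, pielou, faith_pd. Empty samples get richness 0 and NaN for
    the remaining metrics; Pielou's evenness is NaN when richness <= 1
    (H/ln S is undefined there).
    """
    df = _as_frame(table)
    taxa = list(df.columns)
    if tree is not None:
        tip_names = {t.name for t in tree.tips()}
        observed = set(df.columns[(df > 0).any(axis=0)])
        uncovered = observed - tip_names
        if uncovered:
            raise ValueError(f"tree lacks tips for observed taxa: {sorted(uncovered)[:5]}")
    records = []
    for sid, row in df.iterrows():
        x = row.to_numpy(dtype=float)
        present = x > 0
        richness = int(present.sum())
        if richness == 0:
            records.append(AlphaRecord(str(sid), 0, np.nan, np.nan, np.nan))
            continue
        p = x[present] / x[present].sum()
        shannon = float(-(p * np.log(p)).sum())
        pielou = shannon / np.log(richness) if richness > 1 else np.nan
        fpd = np.nan
        if tree is not None:
            fpd = float(faith_pd(x, taxa=taxa, tree=tree))
        records.append(AlphaRecord(str(sid), richness, shannon, pielou, fpd))
    out = pd.DataFrame([r.__dict__ for r in records]).set_index("sample_id")
    return out


def beta_matrix(table, metric: str = "bray_curtis",
                tree: TreeNode | None = None) -> DistanceMatrix:
    """Pairwise dissimilarity matrix.

    metric: ``bray_curtis`` (d = sum|x-y| / sum(x+y)) or
    ``weighted_unifrac`` (normalized form, 0 for identical samples;
    requires a rooted tree).
    """
    df = _as_frame(table)
    zero = df.sum(axis=1) == 0
    if zero.any():
        raise ValueError(f"all-zero samples make the metric undefined: "
                         f"{list(df.index[zero])[:5]}")
    ids = [str(s) for s in df.index]
    if metric in ("bray_curtis", "braycurtis"):
        return beta_diversity("braycurtis", df.to_numpy(dtype=float), ids=ids)
    if metric == "weighted_unifrac":
        if tree is None:
            raise ValueError("weighted_unifrac requires a rooted tree")
        return beta_diversity("weighted_unifrac", df.to_numpy(dtype=float),
                              ids=ids, taxa=list(df.columns), tree=tree,
                              normalized=True)
    raise ValueError(f"unknown metric {metric!r}")


def _dunn_zstats(values: np.ndarray, labels: np.ndarray):
    """Pairwise Dunn z statistics on ranks, with tie correction."""
    n = len(values)
    ranks = stats.rankdata(values)
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = (tie_counts ** 3 - tie_counts).sum() / (12.0 * (n - 1))
    groups = list(dict.fromkeys(labels))
    mean_rank = {g: ranks[labels == g].mean() for g in groups}
    sizes = {g: int((labels == g).sum()) for g in groups}
    rows = []
    for a, b in itertools.combinations(groups, 2):
        se = np.sqrt((n * (n + 1) / 12.0 - tie_term)
                     * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = (mean_rank[a] - mean_rank[b]) / se
        p = 2.0 * stats.norm.sf(abs(z))
        rows.append((a, b, z, p))
    return rows


def compact_letter_display(groups, not_different_pairs) -> dict:
    """Assign letters so groups share a letter iff not significantly different.

    Maximal cliques of the "not significantly different" graph each get a
    letter; isolated groups get their own.
    """
    g = nx.Graph()
    g.add_nodes_from(groups)
    g.add_edges_from(not_different_pairs)
    cliques = sorted(nx.find_cliques(g),
                     key=lambda c: min(groups.index(x) for x in c))
    letters = {grp: "" for grp in groups}
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    for i, clique in enumerate(cliques):
        letter = alphabet[i % len(alphabet)] * (1 + i // len(alphabet))
        for grp in clique:
            letters[grp] += letter
    return letters


def compare_groups(values, groups, alpha: float = 0.05) -> pd.DataFrame:
    """Stage-wise comparison of a per-sample metric with a letter display.

    Kruskal-Wallis omnibus; if significant, pairwise Dunn tests with
    Benjamini-Hochberg correction at `alpha`. Returns one row per group:
    n, median, letters. Groups sharing a letter are not significantly
    different.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(groups)
    if values.shape != labels.shape:
        raise ValueError("values and groups must align")
    group_order = list(dict.fromkeys(labels))
    if len(group_order) < 2:
        raise ValueError("need >= 2 groups")
    for g in group_order:
        if (labels == g).sum() < 2:
            raise ValueError(f"group {g!r} has < 2 samples")

    samples = [values[labels == g] for g in group_order]
    kw_stat, kw_p = stats.kruskal(*samples)

    pairs = _dunn_zstats(values, labels)
    raw_p = [p for *_, p in pairs]
    if kw_p < alpha and len(raw_p) > 0:
        _, q, *_ = multipletests(raw_p, alpha=alpha, method="fdr_bh")
        nd_pairs = [(a, b) for (a, b, _, _), qv in zip(pairs, q) if qv >= alpha]
    else:
        # omnibus not significant: no pair is declared different
        q = [np.nan] * len(raw_p)
        nd_pairs = [(a, b) for a, b, _, _ in pairs]
    letters = compact_letter_display(group_order, nd_pairs)

    out = pd.DataFrame({
        "group": group_order,
        "n": [int((labels == g).sum()) for g in group_order],
        "median": [float(np.median(values[labels == g])) for g in group_order],
        "letters": [letters[g] for g in group_order],
    }).set_index("group")
    out.attrs["kruskal_h"] = float(kw_stat)
    out.attrs["kruskal_p"] = float(kw_p)
    out.attrs["dunn"] = pd.DataFrame(
        [(a, b, z, p, qv) for (a, b, z, p), qv in zip(pairs, q)],
        columns=["group_a", "group_b", "z", "p_raw", "q_bh"])
    return out
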