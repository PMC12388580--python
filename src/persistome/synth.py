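"""Synthetic longitudinal 16S datasets with known ground truth.

Emulates the processed design of a high-frequency prawn-larval sampling
study: 126 samples (21 days posthatch x 6 tank replicates, the days
mapped onto 11 zoeal stages plus postlarva), ~1e5-1e6 16S copies per
sample, a small planted persistent set carrying most of the abundance,
stage-specific transient taxa, and spike-in reads generated under a
per-sample linear read/copy relationship.

Every operation takes one integer seed and derives all randomness from a
local ``numpy.random.Generator``; no global RNG state is touched.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import TreeNode

from .containers import CountTable, SpikeInManifest, SimulationTruth

#: 21 sampling days mapped to the 11 zoeal stages + postlarva.
STAGE_BY_DPH = {
    1: "ZoeaI", 2: "ZoeaII", 3: "ZoeaIII", 4: "ZoeaIV", 5: "ZoeaV",
    6: "ZoeaV", 7: "ZoeaVI", 8: "ZoeaVI", 9: "ZoeaVII", 10: "ZoeaVII",
    11: "ZoeaVIII", 12: "ZoeaVIII", 13: "ZoeaIX", 14: "ZoeaIX",
    15: "ZoeaX", 16: "ZoeaX", 17: "ZoeaXI", 18: "ZoeaXI", 19: "ZoeaXI",
    20: "Postlarva", 21: "Postlarva",
}


def study_design() -> list:
    """The (stage label, day posthatch) schedule of the emulated study.

    21 sampling days; with 6 tanks each this yields the study's 126
    samples across 12 distinct developmental stages.
    """
    return [(STAGE_BY_DPH[d], d) for d in sorted(STAGE_BY_DPH)]


@dataclass
class SourceProfile:
    """A source (meta)community: ASV ids and their mean relative abundances."""

    asv_ids: list
    rel_abundance: np.ndarray

    def __post_init__(self):
        self.asv_ids = list(self.asv_ids)
        self.rel_abundance = np.asarray(self.rel_abundance, dtype=float)
        if len(self.asv_ids) < 2:
            raise ValueError("a source profile needs at least 2 taxa")
        if len(self.asv_ids) != len(self.rel_abundance):
            raise ValueError("ids and abundances differ in length")
        if (self.rel_abundance < 0).any():
            raise ValueError("relative abundances must be non-negative")
        if abs(self.rel_abundance.sum() - 1.0) > 1e-12:
            raise ValueError("relative abundances must sum to 1")


def make_source_profile(n_taxa: int, lognormal_sigma: float, seed: int,
                        prefix: str = "ASV") -> SourceProfile:
    """Heavy-tailed source community: lognormal abundances, sorted descending.

    ``lognormal_sigma`` is the log-scale standard deviation; 0 gives a
    uniform profile, ~2 gives the few-dominant/many-rare shape typical of
    amplicon surveys.
    """
    if n_taxa < 2:
        raise ValueError("n_taxa must be >= 2")
    if lognormal_sigma < 0:
        raise ValueError("lognormal_sigma must be >= 0")
    rng = np.random.default_rng(seed)
    w = rng.lognormal(mean=0.0, sigma=lognormal_sigma, size=n_taxa)
    w = np.sort(w)[::-1]
    ids = [f"{prefix}{i + 1}" for i in range(n_taxa)]
    return SourceProfile(ids, w / w.sum())


def sample_neutral_table(source: SourceProfile, m: float, Nt: int,
                         n_samples: int, seed: int) -> CountTable:
    """Forward-simulate local communities under Sloan neutral sampling.

    Each sample's local relative abundances are independent
    Beta(Nt*m*p_i, Nt*m*(1-p_i)) draws renormalized across taxa, then
    reads are drawn multinomially at depth Nt. Small m concentrates each
    sample on few taxa (strong drift); m -> 1 pins every sample at the
    source profile.
    """
    if not (0.0 < m <= 1.0):
        raise ValueError("m must be in (0, 1]")
    if Nt < 1 or n_samples < 1:
        raise ValueError("Nt and n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    p = source.rel_abundance
    a = Nt * m * p
    b = Nt * m * (1.0 - p)
    x = rng.beta(a, b, size=(n_samples, len(p)))
    rowsum = x.sum(axis=1, keepdims=True)
    # underflow guard: an all-zero row collapses onto the dominant taxon
    dead = rowsum[:, 0] == 0.0
    if dead.any():
        x[dead, np.argmax(p)] = 1.0
        rowsum = x.sum(axis=1, keepdims=True)
    x /= rowsum
    counts = rng.multinomial(Nt, x)
    sample_ids = [f"S{i + 1}" for i in range(n_samples)]
    df = pd.DataFrame(counts, index=sample_ids, columns=source.asv_ids)
    return CountTable(df)


def plant_succession_table(stages, tanks_per_stage: int,
                           persistent_profile: SourceProfile,
                           transient_pool: SourceProfile,
                           persistent_fraction: float, Nt: int, seed: int,
                           transient_width: int | None = None,
                           volatility_max: float = 1.5,
                           volatility_shape: float = 3.0,
                           stage_autocorr: float = 0.5,
                           mass_g: float = 0.03,
                           mass_jitter_sigma: float = 0.1) -> CountTable:
    """Longitudinal table with a planted persistent set and stage transients.

    Parameters
    ----------
    stages : sequence of (stage_label, dph)
        Sampling schedule; ``study_design()`` gives the emulated study's.
    persistent_profile, transient_pool : SourceProfile
        Disjoint id sets. Persistent taxa are present in every sample and
        jointly carry ``persistent_fraction`` of the expected reads.
    transient_width : int, optional
        Number of pool taxa active per stage. Each stage's transients are
        a sliding window over the (abundance-ordered) pool, so temporally
        close stages share transients and distant stages do not — the
        community similarity therefore decays with time separation.
    volatility_max, volatility_shape, stage_autocorr :
        Persistent taxa carry stage-level dynamics: taxon i's expected
        abundance is modulated by exp(sigma_i * W_{i,stage}) with W a
        stationary AR(1) over stages (autocorrelation ``stage_autocorr``)
        and sigma_i = volatility_max * (rank_i / n)^volatility_shape,
        rank_i counting down the abundance ordering. Dominant persistent
        members are thus temporally stable while minor ones wax and wane
        across stages — so every planted taxon, not just the dominant
        few, contributes visibly to between-sample turnover; larger
        ``volatility_shape`` concentrates the dynamics in the minor
        members.

    Every persistent taxon is guaranteed >= 1 read per sample (one read
    reserved per persistent taxon before the multinomial draw), making
    persistent occupancy exactly 1 by construction; row sums equal Nt.
    """
    stages = list(stages)
    if not stages:
        raise ValueError("stage list must be non-empty")
    if not (0.0 < persistent_fraction < 1.0):
        raise ValueError("persistent_fraction must be in (0, 1)")
    if tanks_per_stage < 1:
        raise ValueError("tanks_per_stage must be >= 1")
    if not (0.0 <= stage_autocorr < 1.0):
        raise ValueError("stage_autocorr must be in [0, 1)")
    overlap = set(persistent_profile.asv_ids) & set(transient_pool.asv_ids)
    if overlap:
        raise ValueError(f"persistent and transient ids overlap: {sorted(overlap)[:5]}")
    n_pers = len(persistent_profile.asv_ids)
    if Nt <= n_pers:
        raise ValueError("Nt must exceed the number of persistent taxa")

    rng = np.random.default_rng(seed)
    pool_p = transient_pool.rel_abundance
    n_pool = len(pool_p)
    width = transient_width if transient_width is not None else min(n_pool, max(2, n_pool // 5))
    width = min(width, n_pool)

    # volatility gradient along the (descending-abundance) persistent block
    order = np.argsort(persistent_profile.rel_abundance)[::-1]
    sigma = np.empty(n_pers)
    sigma[order] = volatility_max * (np.arange(1, n_pers + 1) / n_pers) ** volatility_shape
    rho = stage_autocorr
    walk = rng.normal(size=n_pers)     # stationary N(0,1) start

    all_ids = list(persistent_profile.asv_ids) + list(transient_pool.asv_ids)
    n_stages = len(stages)
    rows, sample_ids, meta_rows = [], [], []
    for si, (stage_label, dph) in enumerate(stages):
        if si > 0:
            walk = rho * walk + np.sqrt(1.0 - rho ** 2) * rng.normal(size=n_pers)
        pers = persistent_profile.rel_abundance * np.exp(sigma * walk - 0.5 * sigma ** 2)
        pers *= persistent_fraction / pers.sum()
        start = 0 if n_stages == 1 else round(si * (n_pool - width) / (n_stages - 1))
        window = np.zeros(n_pool)
        window[start:start + width] = pool_p[start:start + width]
        window *= (1.0 - persistent_fraction) / window.sum()
        expected = np.concatenate([pers, window])
        for tank in range(1, tanks_per_stage + 1):
            draw = rng.multinomial(Nt - n_pers, expected)
            draw[:n_pers] += 1          # persistence guarantee
            rows.append(draw)
            sample_ids.append(f"D{dph:02d}T{tank}")
            meta_rows.append({"dph": dph, "stage": stage_label, "tank": tank,
                              "mass_g": float(mass_g * rng.lognormal(0.0, mass_jitter_sigma))})
    counts = pd.DataFrame(np.asarray(rows), index=sample_ids, columns=all_ids)
    metadata = pd.DataFrame(meta_rows, index=sample_ids)
    return CountTable(counts, metadata)


def add_spikein_reads(table: CountTable, spike_copies: SpikeInManifest,
                      read_per_copy_k, seed: int = 0,
                      poisson_noise: bool = False) -> CountTable:
    """Append spike-in read columns under a per-sample linear read/copy law.

    Noiseless (default): reads = round(k_sample * copies). With
    ``poisson_noise`` reads ~ Poisson(k_sample * copies).

    ``read_per_copy_k`` is a mapping/Series sample_id -> reads per copy,
    or a scalar applied to every sample.
    """
    collision = set(spike_copies.spike_ids) & set(table.counts.columns)
    if collision:
        raise ValueError(f"spike ids collide with ASV ids: {sorted(collision)}")
    if np.isscalar(read_per_copy_k):
        k = pd.Series(float(read_per_copy_k), index=table.counts.index)
    else:
        k = pd.Series(read_per_copy_k, dtype=float).reindex(table.counts.index)
        if k.isna().any():
            raise ValueError("read_per_copy_k missing for some samples")
    if (k <= 0).any():
        raise ValueError("read_per_copy_k must be positive")
    copies = spike_copies.copies.reindex(table.counts.index)
    if copies.isna().any().any():
        raise ValueError("manifest missing samples present in the table")
    if (copies.nunique(axis=1) < 3).any():
        raise ValueError("need >= 3 distinct spike-in copy levels per sample")

    lam = copies.mul(k, axis=0)
    if poisson_noise:
        rng = np.random.default_rng(seed)
        reads = pd.DataFrame(rng.poisson(lam.values), index=lam.index,
                             columns=lam.columns)
    else:
        reads = lam.round().astype(np.int64)
    counts = pd.concat([table.counts, reads], axis=1)
    return CountTable(counts, table.metadata.copy(),
                      tuple(spike_copies.spike_ids))


def random_rooted_tree(asv_ids, seed: int) -> TreeNode:
    """Random binary rooted tree over the given tips.

    Coalescent-style: repeatedly join two uniformly chosen lineages under
    a fresh parent; every branch gets an independent Exponential(1)
    length. Only positivity and rootedness matter downstream (Faith's PD,
    weighted UniFrac).
    """
    asv_ids = list(asv_ids)
    if len(asv_ids) < 2:
        raise ValueError("need >= 2 tips")
    if len(set(asv_ids)) != len(asv_ids):
        raise ValueError("duplicate tip ids")
    rng = np.random.default_rng(seed)
    nodes = [TreeNode(name=str(t)) for t in asv_ids]
    while len(nodes) > 1:
        i, j = rng.choice(len(nodes), size=2, replace=False)
        i, j = (int(i), int(j)) if i < j else (int(j), int(i))
        right = nodes.pop(j)
        left = nodes.pop(i)
        left.length = float(rng.exponential(1.0))
        right.length = float(rng.exponential(1.0))
        parent = TreeNode(children=[left, right])
        nodes.append(parent)
    root = nodes[0]
    root.length = None
    return root


def simulate_dataset(n_taxa: int = 2000, n_persistent: int = 80,
                     persistent_fraction: float = 0.95, Nt: int = 50_000,
                     stages=None, tanks_per_stage: int = 6,
                     spike_levels=(1e3, 1e4, 1e5), seed: int = 0,
                     lognormal_sigma: float = 2.0):
    """Full synthetic study: succession table + spike-ins + tree + truth.

    Defaults emulate the study conditions: 126 samples (21 days x 6
    tanks), 2000 ASVs of which 80 planted persistent taxa (<1% of ASVs)
    carry 95% of the reads, and 3 spike-in gradient levels per sample.
    With 5e4 reads/sample and read-per-copy factors around 0.05-0.25 the
    implied totals land in the study's 1e5-1e6 copies/sample range
    (log10 copies/g around 7 at 0.03 g wet mass).

    Per-sample read-per-copy factors are snapped to a 1e-3 grid so that
    noiseless spike reads are exact integers.

    Returns ``(CountTable, SpikeInManifest, TreeNode, SimulationTruth)``.
    """
    if n_persistent < 2 or n_taxa - n_persistent < 2:
        raise ValueError("need >= 2 persistent and >= 2 transient taxa")
    rng = np.random.default_rng(seed)
    sub = [int(s) for s in rng.integers(0, 2**31 - 1, size=5)]
    # persistent block: shallow Zipf-like ranking (every member is a real
    # community player); the transient pool keeps the heavy lognormal tail
    w = np.arange(1, n_persistent + 1, dtype=float) ** -0.3
    persistent = SourceProfile([f"ASV{i + 1}" for i in range(n_persistent)],
                               w / w.sum())
    pool_ids = [f"ASV{i + 1}" for i in range(n_persistent, n_taxa)]
    pool = make_source_profile(n_taxa - n_persistent, lognormal_sigma, sub[1], prefix="T")
    pool = SourceProfile(pool_ids, pool.rel_abundance)
    stages = list(stages) if stages is not None else study_design()
    table = plant_succession_table(stages, tanks_per_stage, persistent, pool,
                                   persistent_fraction, Nt, sub[2])

    k = 0.001 * rng.integers(50, 251, size=len(table.sample_ids))  # 0.05-0.25 reads/copy
    k = pd.Series(k, index=table.counts.index)
    spike_ids = [f"SPIKE{i + 1}" for i in range(len(spike_levels))]
    copies = pd.DataFrame({sid: float(lvl) for sid, lvl in zip(spike_ids, spike_levels)},
                          index=table.counts.index)
    manifest = SpikeInManifest(copies)
    table = add_spikein_reads(table, manifest, k, seed=sub[3])

    tree = random_rooted_tree(table.asv_ids, sub[4])

    source_ids = list(persistent.asv_ids) + list(pool.asv_ids)
    source_rel = np.concatenate([
        persistent_fraction * persistent.rel_abundance,
        (1 - persistent_fraction) * pool.rel_abundance,
    ])
    truth = SimulationTruth(
        source_asv_ids=source_ids,
        source_rel_abundance=source_rel.tolist(),
        migration_m=None,
        reads_per_sample_Nt=Nt,
        persistent_ids=list(persistent.asv_ids),
        read_per_copy_k=k.to_dict(),
        seed=seed,
    )
    return table, manifest, tree, truth
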