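"""Core in-memory containers shared by all pipeline stages.

The lingua franca is a pandas DataFrame of read counts (samples as rows,
ASVs as columns) bundled with per-sample metadata. Spike-in columns live
inside the same table but are flagged so calibration can find them and
every downstream stage can strip them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

METADATA_COLUMNS = ("dph", "stage", "tank", "mass_g")


class CalibrationError(RuntimeError):
    """Raised when a spike-in standard curve cannot be used (e.g. zero reads)."""


class MissingMetadataError(KeyError):
    """Raised when a sample lacks a required curve or metadata field."""


@dataclass
class CountTable:
    """Sample x ASV read counts plus sample metadata.

    Parameters
    ----------
    counts : DataFrame
        Non-negative counts, index = sample ids, columns = ASV ids
        (possibly including spike-in ids).
    metadata : DataFrame
        Indexed by sample id; typical columns: dph, stage, tank, mass_g.
    spike_ids : tuple of str
        Columns of `counts` that are spike-in controls, not community members.
    """

    counts: pd.DataFrame
    metadata: pd.DataFrame = None
    spike_ids: tuple = ()

    def __post_init__(self):
        if self.metadata is None:
            self.metadata = pd.DataFrame(index=self.counts.index)
        self.spike_ids = tuple(self.spike_ids)
        if (np.asarray(self.counts.values) < 0).any():
            raise ValueError("counts must be non-negative")
        missing = set(self.spike_ids) - set(self.counts.columns)
        if missing:
            raise ValueError(f"spike ids absent from table: {sorted(missing)}")
        if not self.counts.index.equals(self.metadata.index):
            self.metadata = self.metadata.reindex(self.counts.index)

    @property
    def sample_ids(self) -> list:
        return list(self.counts.index)

    @property
    def asv_ids(self) -> list:
        """Community ASV ids (spike-ins excluded)."""
        return [c for c in self.counts.columns if c not in set(self.spike_ids)]

    @property
    def asv_counts(self) -> pd.DataFrame:
        """Counts restricted to community ASVs."""
        return self.counts[self.asv_ids]

    @property
    def spike_counts(self) -> pd.DataFrame:
        return self.counts[list(self.spike_ids)]

    def drop_spikes(self) -> "CountTable":
        return CountTable(self.asv_counts.copy(), self.metadata.copy(), ())


@dataclass
class SpikeInManifest:
    """Known copy numbers of each spike-in added to each sample.

    `copies` is a DataFrame indexed by sample id with one column per
    spike-in id, values = copies added (must be > 0, >= 3 distinct levels
    per sample for a usable standard curve).
    """

    copies: pd.DataFrame

    def __post_init__(self):
        if (self.copies.values <= 0).any():
            raise ValueError("spike-in copy numbers must be positive")

    @property
    def spike_ids(self) -> list:
        return list(self.copies.columns)

    def levels_for(self, sample_id) -> pd.Series:
        if sample_id not in self.copies.index:
            raise MissingMetadataError(f"no spike-in copies recorded for {sample_id!r}")
        return self.copies.loc[sample_id]


@dataclass
class AbsoluteTable:
    """Calibrated community table: 16S copies per sample and per gram."""

    counts: pd.DataFrame          # copies per sample
    per_gram: pd.DataFrame        # copies per gram wet mass
    metadata: pd.DataFrame = None

    def __post_init__(self):
        if self.metadata is None:
            self.metadata = pd.DataFrame(index=self.counts.index)

    @property
    def log10_total(self) -> pd.Series:
        """Per-sample log10 total copies/g — the absolute-abundance trajectory."""
        totals = self.per_gram.sum(axis=1)
        with np.errstate(divide="ignore"):
            return np.log10(totals).rename("log10_total")

    @property
    def sample_ids(self) -> list:
        return list(self.counts.index)

    @property
    def asv_ids(self) -> list:
        return list(self.counts.columns)


@dataclass
class SimulationTruth:
    """Ground truth attached to a synthetic dataset for recovery testing."""

    source_asv_ids: list
    source_rel_abundance: list
    migration_m: float = None
    reads_per_sample_Nt: int = None
    persistent_ids: list = field(default_factory=list)
    read_per_copy_k: dict = field(default_factory=dict)   # sample_id -> reads/copy
    seed: int = None

    def to_dict(self) -> dict:
        return {
            "source_asv_ids": list(self.source_asv_ids),
            "source_rel_abundance": [float(x) for x in self.source_rel_abundance],
            "migration_m": self.migration_m,
            "reads_per_sample_Nt": self.reads_per_sample_Nt,
            "persistent_ids": list(self.persistent_ids),
            "read_per_copy_k": {str(k): float(v) for k, v in self.read_per_copy_k.items()},
            "seed": self.seed,
        }
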