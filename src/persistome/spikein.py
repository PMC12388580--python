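"""Spike-in standard curves and absolute quantification.

Each sample receives synthetic spike-ins at >= 3 known gradient copy
numbers. The per-sample standard curve is a through-origin least-squares
fit of spike reads on spike copies (zero copies must map to zero reads),
giving a reads-per-copy slope k. Community reads are then converted to
copies by reads/k and to copies per gram by the sample's wet mass.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import (AbsoluteTable, CalibrationError, CountTable,
                         MissingMetadataError, SpikeInManifest)

logger = logging.getLogger(__name__)

#: wet mass assumed when metadata lacks mass_g (grams per pooled larval sample)
DEFAULT_MASS_G = 0.03

#: through-origin r^2 below this records a linearity warning on the curve
R2_WARN_THRESHOLD = 0.98


@dataclass
class StandardCurve:
    """Per-sample read/copy calibration: reads = k * copies."""

    sample_id: str
    k: float                 # reads per copy (through-origin slope)
    r_squared: float         # uncentered r^2 of the through-origin fit
    n_points: int
    warning: str | None = None


def fit_standard_curve(spike_reads, manifest: SpikeInManifest,
                       sample_id) -> StandardCurve:
    """Fit one sample's standard curve from its spike-in reads.

    ``spike_reads``: mapping/Series spike_id -> observed reads.
    Slope is the closed-form through-origin estimator
    k = sum(reads*copies) / sum(copies^2); r^2 is computed against the
    through-origin fit with the uncentered total sum of squares, so it
    lies in [0, 1].
    """
    copies = manifest.levels_for(sample_id)
    reads = pd.Series(spike_reads, dtype=float).reindex(copies.index)
    if reads.isna().any():
        missing = list(reads.index[reads.isna()])
        raise ValueError(f"reads missing for spike-ins {missing} in {sample_id!r}")
    c = copies.to_numpy(dtype=float)
    r = reads.to_numpy(dtype=float)
    if len(np.unique(c)) < 3:
        raise ValueError("need >= 3 distinct spike-in copy levels")
    if (c <= 0).any():
        raise ValueError("spike-in copy numbers must be positive")
    if not (r > 0).any():
        raise CalibrationError(f"all spike-in reads are zero for {sample_id!r}")

    k = float(np.dot(r, c) / np.dot(c, c))
    sse = float(np.sum((r - k * c) ** 2))
    sst = float(np.sum(r ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else 0.0
    warning = None
    if k <= 0:
        raise CalibrationError(f"non-positive slope for {sample_id!r} (k={k:g})")
    if r2 < R2_WARN_THRESHOLD:
        warning = f"standard curve r^2={r2:.4f} < {R2_WARN_THRESHOLD}"
        logger.warning("%s: %s", sample_id, warning)
    return StandardCurve(str(sample_id), k, r2, len(c), warning)


def fit_all_curves(table: CountTable, manifest: SpikeInManifest) -> dict:
    """Standard curve for every sample, from the table's spike-in columns."""
    if not table.spike_ids:
        raise ValueError("table has no spike-in columns flagged")
    return {s: fit_standard_curve(table.spike_counts.loc[s], manifest, s)
            for s in table.sample_ids}


def reads_to_copies(table: CountTable, curves: dict,
                    metadata: pd.DataFrame | None = None) -> AbsoluteTable:
    """Convert community reads to absolute copies and copies per gram.

    copies[s, i] = reads[s, i] / k_s; spike-in columns are stripped.
    Wet mass comes from metadata column ``mass_g``; samples without one
    fall back to 0.03 g (flagged in the log).
    """
    md = metadata if metadata is not None else table.metadata
    asv = table.asv_counts
    ks = []
    for s in asv.index:
        if s not in curves:
            raise MissingMetadataError(f"no standard curve for sample {s!r}")
        curve = curves[s]
        if curve.k <= 0:
            raise CalibrationError(f"unusable curve for {s!r} (k={curve.k:g})")
        ks.append(curve.k)
    copies = asv.div(pd.Series(ks, index=asv.index), axis=0)

    if md is not None and "mass_g" in md.columns:
        mass = md["mass_g"].reindex(asv.index).astype(float)
    else:
        mass = pd.Series(np.nan, index=asv.index)
    n_default = int(mass.isna().sum())
    if n_default:
        logger.warning("%d sample(s) missing mass_g; using default %.3f g",
                       n_default, DEFAULT_MASS_G)
        mass = mass.fillna(DEFAULT_MASS_G)
    if (mass <= 0).any():
        raise MissingMetadataError("non-positive mass_g in metadata")
    per_gram = copies.div(mass, axis=0)
    return AbsoluteTable(copies, per_gram, md.copy() if md is not None else None)


def quantify(table: CountTable, manifest: SpikeInManifest,
             metadata: pd.DataFrame | None = None):
    """Convenience wrapper: fit all curves, convert, return both.

    Returns ``(AbsoluteTable, curves dict)``.
    """
    curves = fit_all_curves(table, manifest)
    return reads_to_copies(table, curves, metadata), curves


def calibration_report(curves: dict) -> pd.DataFrame:
    """Tabular QC report of the per-sample standard curves."""
    rows = [{"sample_id": c.sample_id, "k": c.k, "r_squared": c.r_squared,
             "n_points": c.n_points, "warnings": c.warning or ""}
            for c in curves.values()]
    return pd.DataFrame(rows).set_index("sample_id")
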