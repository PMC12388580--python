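"""Packaged reference data.

The persistent-microbiome membership reported for the giant freshwater
prawn (GFP) larval study: ASV identifiers grouped by phylum (classes for
Proteobacteria). Useful for cross-referencing one's own persistent-set
calls against the published one.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

_DATA = "data/persistent_asvs_gfp.tsv"


def load_persistent_reference() -> pd.DataFrame:
    """The published persistent-set membership, one row per member.

    Columns: lineage (phylum, or class for Proteobacteria) and asv_id.
    One Deinococcota member was reported without an identifier; its
    asv_id is NaN.
    """
    with resources.files(__package__).joinpath(_DATA).open() as fh:
        return pd.read_csv(fh, sep="\t", comment="#")


def persistent_reference_count() -> int:
    """Number of reported persistent members (named ids must be unique)."""
    df = load_persistent_reference()
    named = df["asv_id"].dropna()
    if named.duplicated().any():
        raise ValueError("duplicate ASV ids in the reference membership")
    return int(len(df))
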