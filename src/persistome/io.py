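"""Reading and writing the pipeline's on-disk formats.

One TSV dialect for count tables (samples as rows, first column
``sample_id``, remaining columns ASV ids), with the classic QIIME-style
orientation ("#OTU ID" header, taxa as rows) auto-detected on read.
Trees are newick, read through scikit-bio.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from skbio import TreeNode

from .containers import CountTable, SpikeInManifest, AbsoluteTable


def _write_with_header(df: pd.DataFrame, path, index_label, provenance: str | None):
    path = Path(path)
    with path.open("w") as fh:
        if provenance:
            fh.write(f"# {provenance}\n")
        df.to_csv(fh, sep="\t", index_label=index_label)


def write_counts(table: CountTable, path, provenance: str | None = None) -> None:
    _write_with_header(table.counts, path, "sample_id", provenance)


def write_metadata(table: CountTable, path, provenance: str | None = None) -> None:
    _write_with_header(table.metadata, path, "sample_id", provenance)


def read_counts(counts_path, metadata_path=None, spike_ids=()) -> CountTable:
    """Read a count table TSV; accepts both dialects.

    Native dialect: samples as rows, header ``sample_id<TAB>ASV...``.
    QIIME-style: first header cell ``#OTU ID`` (taxa as rows) — transposed
    on read.
    """
    counts_path = Path(counts_path)
    n_comment = 0
    with counts_path.open() as fh:
        first = fh.readline()
        while first.startswith("# "):   # provenance lines; "#OTU ID" has no space
            n_comment += 1
            first = fh.readline()
    qiime_style = first.split("\t")[0].strip().lstrip("#").strip().lower() in (
        "otu id", "asv id", "otu_id", "asv_id")
    df = pd.read_csv(counts_path, sep="\t", index_col=0, skiprows=n_comment)
    if qiime_style:
        df = df.T
    df = df.apply(pd.to_numeric)
    metadata = None
    if metadata_path is not None:
        metadata = read_metadata(metadata_path)
    return CountTable(df, metadata, tuple(spike_ids))


def read_metadata(path) -> pd.DataFrame:
    md = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    return md


def write_manifest(manifest: SpikeInManifest, path, provenance: str | None = None) -> None:
    """Long format: spike_id, sample_id, copies."""
    long = (manifest.copies.stack().rename("copies").reset_index())
    long.columns = ["sample_id", "spike_id", "copies"]
    long = long[["spike_id", "sample_id", "copies"]]
    path = Path(path)
    with path.open("w") as fh:
        if provenance:
            fh.write(f"# {provenance}\n")
        long.to_csv(fh, sep="\t", index=False)


def read_manifest(path) -> SpikeInManifest:
    long = pd.read_csv(path, sep="\t", comment="#")
    copies = long.pivot(index="sample_id", columns="spike_id", values="copies")
    copies.columns.name = None
    return SpikeInManifest(copies)


def write_absolute(table: AbsoluteTable, prefix, provenance: str | None = None) -> None:
    prefix = Path(prefix)
    _write_with_header(table.counts, prefix.with_suffix(".copies.tsv"),
                       "sample_id", provenance)
    _write_with_header(table.per_gram, prefix.with_suffix(".per_gram.tsv"),
                       "sample_id", provenance)


def write_tree(tree: TreeNode, path) -> None:
    tree.write(str(path), format="newick")


def read_tree(path) -> TreeNode:
    return TreeNode.read(str(path), format="newick")


def write_json(obj: dict, path, provenance: str | None = None) -> None:
    if provenance:
        obj = {"provenance": provenance, **obj}
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path) -> dict:
    return json.loads(Path(path).read_text())
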