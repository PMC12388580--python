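"""End-to-end orchestration of the analysis stages.

Order: quantify -> diversity -> turnover -> persistence -> neutral.
Every output carries a provenance header (package version, seed, config
hash); a stage failure aborts the run with the stage name, leaving a
FAILED marker next to whatever partial outputs exist. Re-running with
the same config and seed reproduces byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, io
from .containers import CountTable
from .diversity import alpha_diversity, beta_matrix, compare_groups
from .neutral import compare_models, fit_binomial, fit_sloan
from .persistence import classify_persistent
from .spikein import calibration_report, quantify
from .synth import simulate_dataset
from .turnover import anosim, compare_slopes, pcoa, time_decay_fit

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Inputs, thresholds and bookkeeping for one pipeline run."""

    counts: str = None
    manifest: str = None
    metadata: str = None
    tree: str = None
    spike_ids: tuple = ()
    outdir: str = "results"
    seed: int = 0
    n_permutations: int = 999
    detection_threshold: float = 1.0
    elbow_threshold: float = 0.02
    ci_level: float = 0.95
    beta_metric: str = "bray_curtis"
    # which table feeds each analysis: "absolute" or "reads"
    table_choice: dict = field(default_factory=lambda: {
        "diversity": "absolute", "turnover": "absolute",
        "persistence": "absolute", "neutral": "reads"})
    # simulation parameters (simulate command)
    sim: dict = field(default_factory=dict)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        import yaml
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        return cfg

    def digest(self) -> str:
        # analytic configuration only: where outputs land is not provenance
        blob = json.dumps(
            {k: (list(v) if isinstance(v, tuple) else v)
             for k, v in self.__dict__.items() if k != "outdir"},
            sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    def provenance(self) -> str:
        return f"persistome {__version__} seed={self.seed} config={self.digest()}"


def simulate_command(config: RunConfig) -> dict:
    """Write a synthetic dataset (counts, manifest, metadata, tree, truth)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim = dict(config.sim)
    sim.setdefault("seed", config.seed)
    table, manifest, tree, truth = simulate_dataset(**sim)
    prov = config.provenance()
    io.write_counts(table, outdir / "counts.tsv", prov)
    io.write_metadata(table, outdir / "metadata.tsv", prov)
    io.write_manifest(manifest, outdir / "manifest.tsv", prov)
    io.write_tree(tree, outdir / "tree.nwk")
    io.write_json(truth.to_dict(), outdir / "truth.json", prov)
    return {"n_samples": len(table.sample_ids),
            "n_taxa": len(table.asv_ids),
            "spike_ids": list(table.spike_ids),
            "outdir": str(outdir)}


def run_pipeline(config: RunConfig) -> dict:
    """Execute all analysis stages; returns a run report dict."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    prov = config.provenance()
    report = {"stages": [], "provenance": prov}
    failed_marker = outdir / "FAILED"
    if failed_marker.exists():
        failed_marker.unlink()

    def _fail(stage, exc):
        failed_marker.write_text(f"stage {stage} failed: {exc}\n")
        raise StageError(stage, exc)

    # ---- load inputs
    try:
        manifest = io.read_manifest(config.manifest)
        table = io.read_counts(config.counts, config.metadata,
                               spike_ids=manifest.spike_ids)
        tree = io.read_tree(config.tree) if config.tree else None
    except Exception as exc:                      # noqa: BLE001
        _fail("load", exc)

    # ---- quantify
    try:
        abs_tab, curves = quantify(table, manifest)
        io.write_absolute(abs_tab, outdir / "absolute", prov)
        rep = calibration_report(curves)
        with (outdir / "calibration.tsv").open("w") as fh:
            fh.write(f"# {prov}\n")
            rep.to_csv(fh, sep="\t")
        report["stages"].append("quantify")
    except Exception as exc:                      # noqa: BLE001
        _fail("quantify", exc)

    reads_tab = table.drop_spikes()
    choice = {"absolute": abs_tab, "reads": reads_tab}
    md = table.metadata

    # ---- diversity
    try:
        if config.beta_metric == "weighted_unifrac" and tree is None:
            raise ValueError("weighted_unifrac requested but no tree given")
        alpha = alpha_diversity(choice[config.table_choice["diversity"]], tree)
        with (outdir / "alpha.tsv").open("w") as fh:
            fh.write(f"# {prov}\n")
            alpha.to_csv(fh, sep="\t")
        letters = compare_groups(alpha["shannon"].to_numpy(),
                                 md["stage"].to_numpy())
        with (outdir / "alpha_letters.tsv").open("w") as fh:
            fh.write(f"# {prov}\n")
            letters.to_csv(fh, sep="\t")
        dm = beta_matrix(choice[config.table_choice["turnover"]],
                         config.beta_metric, tree)
        dm_df = pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids)
        with (outdir / "beta.tsv").open("w") as fh:
            fh.write(f"# {prov}\n")
            dm_df.to_csv(fh, sep="\t", index_label="sample_id")
        report["stages"].append("diversity")
    except Exception as exc:                      # noqa: BLE001
        _fail("diversity", exc)

    # ---- turnover
    try:
        ord_res = pcoa(dm)
        coords = ord_res.samples.copy()
        with (outdir / "pcoa.tsv").open("w") as fh:
            fh.write(f"# {prov}\n")
            coords.to_csv(fh, sep="\t", index_label="sample_id")
        an = anosim(dm, md["stage"].to_numpy(), config.n_permutations,
                    config.seed)
        td = time_decay_fit(dm, md["dph"].astype(float))
        io.write_json({
            "anosim": {"r": an.r_statistic, "p": an.p_value,
                       "n_permutations": an.n_permutations},
            "time_decay": {"slope_w": td.slope_w, "intercept": td.intercept,
                           "r_squared": td.r_squared, "p": td.p_value,
                           "n_pairs": td.n_pairs,
                           "n_dropped": td.n_dropped_zero_similarity},
            "pcoa_proportion_explained":
                ord_res.proportion_explained[:5].round(6).to_dict(),
        }, outdir / "turnover.json", prov)
        if tree is not None:
            dm_phylo = beta_matrix(choice[config.table_choice["turnover"]],
                                   "weighted_unifrac", tree)
            td_phylo = time_decay_fit(dm_phylo, md["dph"].astype(float))
            cmp_res = compare_slopes(td, td_phylo, config.n_permutations,
                                     config.seed)
            io.write_json({
                "taxonomic_slope_w": td.slope_w,
                "phylogenetic_slope_w": td_phylo.slope_w,
                "f_statistic": cmp_res.f_statistic,
                "p_value": cmp_res.p_value,
                "permutation_p": cmp_res.permutation_p,
                "slope_difference": cmp_res.slope_difference,
            }, outdir / "slope_comparison.json", prov)
        report["stages"].append("turnover")
    except Exception as exc:                      # noqa: BLE001
        _fail("turnover", exc)

    # ---- persistence
    try:
        core = classify_persistent(choice[config.table_choice["persistence"]],
                                   md["stage"],
                                   threshold=config.elbow_threshold,
                                   detection_threshold=config.detection_threshold)
        with (outdir / "occupancy.tsv").open("w") as fh:
            fh.write(f"# {prov}\n")
            core.occupancy.to_csv(fh, sep="\t")
        io.write_json({
            "elbow_rank": core.elbow_rank,
            "persistent_ids": list(core.persistent_ids),
            "abundance_share": core.abundance_share,
            "cumulative_contribution":
                [round(float(c), 8) for c in core.cumulative_contribution[:200]],
        }, outdir / "core.json", prov)
        report["stages"].append("persistence")
    except Exception as exc:                      # noqa: BLE001
        _fail("persistence", exc)

    # ---- neutral model
    try:
        ntab = choice[config.table_choice["neutral"]]
        allow = config.table_choice["neutral"] == "absolute"
        nfit = fit_sloan(ntab, allow_noninteger=allow, ci_level=config.ci_level)
        bfit = fit_binomial(ntab, allow_noninteger=allow)
        cmp_aic = compare_models(nfit, bfit)
        with (outdir / "neutral_per_asv.tsv").open("w") as fh:
            fh.write(f"# {prov}\n")
            nfit.per_asv.to_csv(fh, sep="\t")
        io.write_json({
            "m": nfit.m, "Nt": nfit.Nt, "d": nfit.d,
            "r_squared": nfit.r_squared, "aic_neutral": nfit.aic,
            "aic_binomial": bfit.aic, "preferred": cmp_aic["preferred"],
            "delta_aic": cmp_aic["delta_aic"],
            "partition_counts":
                nfit.per_asv["partition"].value_counts().to_dict(),
        }, outdir / "neutral.json", prov)
        report["stages"].append("neutral")
    except Exception as exc:                      # noqa: BLE001
        _fail("neutral", exc)

    report["completed"] = len(report["stages"]) == 5
    io.write_json(report, outdir / "report.json", prov)
    return report
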