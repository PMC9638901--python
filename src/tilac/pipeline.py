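"""Pipeline orchestration: staged runs, manifests, logging and reporting."""

from __future__ import annotations

import hashlib
import json
import logging
import platform
import sys
import time
from dataclasses import replace
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from . import __version__
from .core import (
    aggregate_reads,
    filter_low_coverage,
    read_count_table,
    read_sample_sheet,
    reads_per_gene_sample,
    write_count_table,
    write_sample_sheet,
    write_tallies,
)
from .model import SamplerConfig, fit_posterior, write_posterior
from .significance import TestConfig, call_significance, write_results
from .simulate import SimConfig, emit_synthetic_sam, simulate_reads, synthetic_template

__all__ = ["run_pipeline", "write_manifest", "report", "get_logger"]


def get_logger(out_dir: str | Path | None = None) -> logging.Logger:
    """Stage logger: human-readable to stderr, JSON-lines alongside outputs."""
    logger = logging.getLogger("tilac")
    logger.setLevel(logging.INFO)
    logger.handlers.clear()
    sh = logging.StreamHandler(sys.stderr)
    sh.setFormatter(logging.Formatter("[%(asctime)s] %(levelname)s %(message)s", "%H:%M:%S"))
    logger.addHandler(sh)
    if out_dir is not None:

        class _JsonLines(logging.Handler):
            def __init__(self, path: Path):
                super().__init__()
                self.path = path

            def emit(self, record: logging.LogRecord) -> None:
                entry = {
                    "time": record.created,
                    "level": record.levelname,
                    "message": record.getMessage(),
                }
                with open(self.path, "a") as fh:
                    fh.write(json.dumps(entry) + "\n")

        logger.addHandler(_JsonLines(Path(out_dir) / "log.jsonl"))
    return logger


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    out_dir: str | Path,
    subcommand: str,
    config: Mapping[str, Any],
    seed: int | None,
    inputs: Mapping[str, str | Path] | None = None,
    outputs: Mapping[str, str | Path] | None = None,
) -> Path:
    """Record what was run: version, config, seed, file paths and checksums."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    def file_entry(p: str | Path) -> dict:
        p = Path(p)
        entry = {"path": str(p)}
        if p.is_file():
            entry["sha256"] = _sha256(p)
        return entry

    manifest = {
        "tool": "tilac",
        "version": __version__,
        "subcommand": subcommand,
        "config": {k: v for k, v in config.items()},
        "seed": seed,
        "inputs": {k: file_entry(v) for k, v in (inputs or {}).items()},
        "outputs": {k: file_entry(v) for k, v in (outputs or {}).items()},
        "python": platform.python_version(),
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S%z"),
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return path


def _sim_config_from_dict(section: Mapping[str, Any]) -> SimConfig:
    kwargs = dict(section)
    n_template = kwargs.pop("synthetic_template", None)
    if n_template:
        kwargs.setdefault("ratio_mode", "template")
        kwargs.setdefault("read_count_mode", "template")
        kwargs["template"] = synthetic_template(int(n_template), int(kwargs.get("seed", 0)))
    if "ratio_grid" in kwargs:
        kwargs["ratio_grid"] = tuple(float(x) for x in kwargs["ratio_grid"])
    return SimConfig(**kwargs)


def run_pipeline(config: Mapping[str, Any], out_dir: str | Path, seed: int | None = None) -> dict:
    """Execute the staged pipeline described by ``config``.

    Two entry modes: ``simulate`` (generate counts from the simulator) or
    ``sam`` (tally aligned reads).  Either feeds aggregate -> coverage filter
    -> model fit -> composite-null test; a manifest and stage logs are
    written next to the outputs.  Any stage failure aborts with the failing
    stage named.

    Returns a dict of output paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    logger = get_logger(out_dir)
    seed = int(config.get("seed", 0)) if seed is None else int(seed)
    mode = config.get("mode", "simulate")
    outputs: dict[str, Path] = {}
    inputs: dict[str, Path] = {}
    stage = "setup"
    try:
        if mode == "simulate":
            stage = "simulate"
            sim_cfg = _sim_config_from_dict(config.get("simulate", {}))
            sim = simulate_reads(sim_cfg, seed=seed)
            counts = sim.counts
            design = sim.design
            outputs["counts"] = out_dir / "counts.tsv"
            write_count_table(counts, outputs["counts"])
            outputs["truth"] = out_dir / "truth.tsv"
            sim.truth.to_csv(outputs["truth"], sep="\t", index=False)
            outputs["samples"] = out_dir / "samples.tsv"
            write_sample_sheet(design, outputs["samples"])
            if config.get("emit_sam"):
                stage = "emit_sam"
                paths = emit_synthetic_sam(sim.tallies, out_dir / "sam",
                                           read_length=sim_cfg.read_length)
                outputs.update({f"sam_{k}": v for k, v in paths.items()})
            logger.info("simulate: %d transcripts, %d count groups",
                        sim.truth.shape[0], len(counts))
        elif mode == "sam":
            stage = "tally"
            from .tally import GeneIndex, load_gene_models, tally_sam

            tcfg = config["tally"]
            index = GeneIndex(load_gene_models(tcfg["annotation"]))
            inputs["annotation"] = Path(tcfg["annotation"])
            frames = []
            for entry in tcfg["samples"]:
                frames.append(
                    tally_sam(
                        entry["sam"],
                        entry["sample_id"],
                        index,
                        fasta_path=tcfg.get("fasta"),
                        vcf_path=tcfg.get("vcf_mask"),
                        min_baseq=int(tcfg.get("min_baseq", 20)),
                        strandedness=tcfg.get("strandedness", "unstranded"),
                    )
                )
                inputs[f"sam_{entry['sample_id']}"] = Path(entry["sam"])
            tallies = pd.concat(frames, ignore_index=True)
            outputs["tallies"] = out_dir / "tallies.tsv"
            write_tallies(tallies, outputs["tallies"])
            logger.info("tally: %d reads tallied from %d samples",
                        len(tallies), len(tcfg["samples"]))
            stage = "aggregate"
            counts = aggregate_reads(tallies)
            design = read_sample_sheet(config["samples"])
            outputs["counts"] = out_dir / "counts.tsv"
            write_count_table(counts, outputs["counts"])
        elif mode == "counts":
            stage = "load"
            counts = read_count_table(config["counts"])
            design = read_sample_sheet(config["samples"])
            inputs["counts"] = Path(config["counts"])
            inputs["samples"] = Path(config["samples"])
        else:
            raise ValueError(f"unknown pipeline mode {mode!r}")

        if config.get("fit", True) is not False:
            stage = "filter"
            fcfg = config.get("filter", {})
            min_reads = int(fcfg.get("min_reads", 200))
            min_samples = int(fcfg.get("min_samples", 2))
            n_before = counts["gene_id"].nunique()
            counts = filter_low_coverage(counts, min_reads, min_samples)
            n_after = counts["gene_id"].nunique()
            logger.info(
                "filter: %d of %d genes removed by the %d-read / %d-sample rule",
                n_before - n_after, n_before, min_reads, min_samples,
            )
            if counts.empty:
                raise ValueError("no genes left after coverage filtering")

            stage = "fit"
            fit_cfg = config.get("fit") or {}
            sampler = SamplerConfig(**fit_cfg.get("sampler", {})) if fit_cfg.get("sampler") else None
            post = fit_posterior(counts, design, seed=seed, sampler=sampler)
            outputs["posterior"] = out_dir / "posterior.tsv"
            outputs["fit_metadata"] = out_dir / "fit_metadata.json"
            write_posterior(post, outputs["posterior"], outputs["fit_metadata"])
            logger.info("fit: %d genes, %d converged", len(post.genes),
                        int(post.genes["converged"].sum()))

            stage = "test"
            tcfg2 = config.get("test", {})
            test_cfg = TestConfig(
                mu_cutoff=float(tcfg2.get("mu_cutoff", 0.5)),
                alpha=float(tcfg2.get("alpha", 0.05)),
            )
            results = call_significance(post.genes, test_cfg)
            outputs["results"] = out_dir / "results.tsv"
            write_results(results, outputs["results"])
            logger.info("test: %d significant of %d tested",
                        int(results["significant"].sum()), len(results))

            if config.get("report", False):
                stage = "report"
                outputs.update(report(results, counts, out_dir))
    except Exception as err:
        logger.error("pipeline failed at stage %r: %s", stage, err)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    write_manifest(out_dir, "pipeline", dict(config), seed, inputs, outputs)
    return {k: str(v) for k, v in outputs.items()}


def report(
    results: pd.DataFrame,
    counts: pd.DataFrame | None,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Summary tables and an MA-style figure for a set of test results.

    Writes a significance summary (counts by direction), a ranked gene table
    ordered by log2 ratio, and — when a count table is supplied — a scatter
    of log2 ratio against total read count with significant genes
    highlighted.
    """
    if results.empty:
        raise ValueError("no test results to report")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}

    summary = (
        results.groupby("direction").size().reindex(["up", "down", "none"], fill_value=0)
    ).rename("n_genes").reset_index()
    outputs["summary"] = out_dir / "summary.tsv"
    summary.to_csv(outputs["summary"], sep="\t", index=False)

    ranked = results.sort_values("log2_ratio_mean", ascending=False).reset_index(drop=True)
    ranked.insert(0, "rank", np.arange(1, len(ranked) + 1))
    outputs["ranked"] = out_dir / "ranked_genes.tsv"
    ranked.to_csv(outputs["ranked"], sep="\t", index=False)

    if counts is not None and not counts.empty:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        totals = reads_per_gene_sample(counts).groupby("gene_id")["n_reads"].sum()
        merged = results.merge(totals.rename("total_reads"), on="gene_id", how="left")
        fig, ax = plt.subplots(figsize=(5, 4))
        sig = merged["significant"].astype(bool)
        ax.scatter(merged.loc[~sig, "total_reads"], merged.loc[~sig, "log2_ratio_mean"],
                   s=8, c="0.6", label="not significant")
        ax.scatter(merged.loc[sig, "total_reads"], merged.loc[sig, "log2_ratio_mean"],
                   s=10, c="crimson", label="significant")
        ax.set_xscale("log")
        ax.axhline(0, lw=0.6, c="k")
        ax.set_xlabel("total reads per gene")
        ax.set_ylabel("posterior mean log2 ratio")
        ax.legend(frameon=False, fontsize=8)
        fig.tight_layout()
        outputs["ma_plot"] = out_dir / "ma_plot.png"
        fig.savefig(outputs["ma_plot"], dpi=150)
        plt.close(fig)
    return outputs
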