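"""Configured end-to-end pipeline over the library stages.

Sequence: tile every sample's cytosine report, summarise the reference
line's methylation states, call context-specific DMRs of every line
against the reference, merge them across comparisons, genotype the
merged regions in all lines, then run the downstream association
analyses that the configuration enables (state clustering, NJ tree from
SNPs, DMR/SNP density correlation, TE-indel proximity).

The pipeline is a pure function of (inputs, configuration, seeds).
Completed stages are skipped on re-runs via content hashing: each
stage's SHA-256 over its input files and parameters is recorded in a
manifest, and a stage re-executes only when that digest changes.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Mapping, Optional

import pandas as pd
import yaml

from . import analysis, dmr as dmr_mod, io as io_mod, tiling

logger = logging.getLogger("tilemeth.pipeline")

DEFAULT_BIN_SIZE = {"CG": 1_000_000, "CHG": 1_000_000, "CHH": 5_000_000}


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


class PipelineConfig:
    """Validated pipeline configuration (YAML-friendly dict)."""

    def __init__(self, cfg: Mapping):
        self.samples: dict = dict(cfg["samples"])
        self.reference: str = cfg["reference"]
        if self.reference not in self.samples:
            raise ValueError("reference line missing from sample table")
        self.contexts: list = list(cfg.get("contexts", io_mod.CONTEXTS))
        self.preset: str = cfg.get("preset", "results")
        self.outdir = Path(cfg["outdir"])
        self.genes: Optional[str] = cfg.get("genes")
        self.tes: Optional[str] = cfg.get("tes")
        self.snps: Optional[str] = cfg.get("snps")
        self.te_indels: Optional[str] = cfg.get("te_indels")
        self.bin_size: dict = {**DEFAULT_BIN_SIZE, **cfg.get("bin_size", {})}
        self.proximity_window: int = int(cfg.get("proximity_window", 500))
        self.n_perm: int = int(cfg.get("n_perm", 200))
        self.seed: int = int(cfg.get("seed", 0))
        self.tile_size: int = int(cfg.get("tile_size", 100))
        for name, path in self.samples.items():
            if not Path(path).exists():
                raise FileNotFoundError(f"sample {name!r}: no such file {path}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with Path(path).open() as fh:
            return cls(yaml.safe_load(fh))


def _file_digest(path) -> str:
    h = hashlib.sha256()
    with Path(path).open("rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class _Stages:
    """Stage runner with a content-hash manifest for cached re-runs."""

    def __init__(self, outdir: Path):
        self.outdir = outdir
        self.manifest_path = outdir / "manifest.json"
        self.manifest = (
            json.loads(self.manifest_path.read_text())
            if self.manifest_path.exists()
            else {}
        )
        self.cached: list = []

    def run(self, name: str, inputs: list, params, outputs: list, fn):
        key_parts = [json.dumps(params, sort_keys=True, default=str)]
        key_parts += [_file_digest(p) for p in inputs]
        digest = hashlib.sha256("\n".join(key_parts).encode()).hexdigest()
        outputs = [Path(o) for o in outputs]
        if self.manifest.get(name) == digest and all(o.exists() for o in outputs):
            logger.info("stage %s: cached", name)
            self.cached.append(name)
            return
        logger.info("stage %s: running (params=%s)", name, params)
        try:
            fn()
        except Exception as exc:  # surface the failing stage by name
            raise PipelineError(name, exc) from exc
        self.manifest[name] = digest
        self.manifest_path.write_text(json.dumps(self.manifest, indent=1))


def run_pipeline(config) -> dict:
    """Run all configured stages; returns a summary dict (also written to
    ``summary.json`` in the output directory)."""
    if not isinstance(config, PipelineConfig):
        config = (
            PipelineConfig.from_yaml(config)
            if isinstance(config, (str, Path))
            else PipelineConfig(config)
        )
    outdir = config.outdir
    outdir.mkdir(parents=True, exist_ok=True)
    log_fh = logging.FileHandler(outdir / "pipeline.log")
    log_fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logging.getLogger("tilemeth").addHandler(log_fh)
    logging.getLogger("tilemeth").setLevel(logging.INFO)
    stages = _Stages(outdir)
    summary: dict = {"stages_cached": stages.cached}

    try:
        # -- tiling ---------------------------------------------------------
        tile_dir = outdir / "tiles"
        tile_dir.mkdir(exist_ok=True)
        tile_paths = {ln: tile_dir / f"{ln}.tiles.tsv" for ln in config.samples}
        for line, cx_path in sorted(config.samples.items()):
            stages.run(
                f"tile:{line}",
                [cx_path],
                {"tile_size": config.tile_size},
                [tile_paths[line]],
                lambda cx=cx_path, out=tile_paths[line]: tiling.write_tile_table(
                    tiling.aggregate_tiles(
                        io_mod.records_to_frame(io_mod.read_cx_report(cx)),
                        config.tile_size,
                    ),
                    out,
                ),
            )
        tiles = {ln: tiling.read_tile_table(p) for ln, p in tile_paths.items()}

        # -- reference state summary ---------------------------------------
        state_path = outdir / "reference_states.tsv"

        def state_stage():
            ref_tiles = tiles[config.reference]
            genes = (
                io_mod.read_annotations(config.genes, "gene") if config.genes else []
            )
            tes = io_mod.read_annotations(config.tes, "TE") if config.tes else []
            states = tiling.annotate_tiles(ref_tiles, genes, tes)
            df = pd.DataFrame(
                {
                    "composite": [s.composite or "undefined" for s in states],
                    "annotation": [s.annotation for s in states],
                }
            )
            counts = (
                df.value_counts().rename("n_tiles").reset_index()
                .sort_values(["composite", "annotation"])
            )
            counts.to_csv(state_path, sep="\t", index=False)

        stages.run(
            "state",
            [tile_paths[config.reference]]
            + [p for p in (config.genes, config.tes) if p],
            {},
            [state_path],
            state_stage,
        )

        # -- DMR calling per context and line -------------------------------
        alt_lines = sorted(ln for ln in config.samples if ln != config.reference)
        dmr_dir = outdir / "dmrs"
        dmr_dir.mkdir(exist_ok=True)
        merged_dmrs: dict = {}
        for context in config.contexts:
            params = dmr_mod.DMParams.for_context(context, config.preset)
            pair_sets = {}
            for line in alt_lines:
                pair = (config.reference, line)
                bed = dmr_dir / f"{context}.{line}.bed"
                stages.run(
                    f"dmr:{context}:{line}",
                    [tile_paths[config.reference], tile_paths[line]],
                    {"preset": config.preset, "context": context},
                    [bed],
                    lambda a=config.reference, b=line, p=params, out=bed: (
                        dmr_mod.write_dmr_bed(
                            dmr_mod.call_dmrs(tiles[a], tiles[b], p, pair=(a, b)),
                            out,
                        )
                    ),
                )
                pair_sets[pair] = dmr_mod.call_dmrs(
                    tiles[config.reference], tiles[line], params,
                    pair=(config.reference, line),
                )
            merged = dmr_mod.merge_pairwise(pair_sets) if pair_sets else []
            for d in merged:
                d.levels = dmr_mod.genotype_dmr_states(d, tiles)
            merged_dmrs[context] = merged
            merged_bed = dmr_dir / f"{context}.merged.bed"
            dmr_mod.write_dmr_bed(merged, merged_bed)
            summary[f"n_dmrs_{context}"] = len(merged)
            summary[f"n_dmrs_per_line_{context}"] = {
                line: len(pair_sets[(config.reference, line)]) for line in alt_lines
            }

        # -- clustering ------------------------------------------------------
        for context in config.contexts:
            merged = merged_dmrs[context]
            if len(merged) >= 2 and len(config.samples) >= 2:
                matrix = pd.DataFrame(
                    [d.levels for d in merged],
                    index=[f"{d.chrom}:{d.start}-{d.end}" for d in merged],
                    dtype=float,
                )
                matrix.to_csv(outdir / f"state_matrix.{context}.tsv", sep="\t")
                try:
                    dend = analysis.cluster_dmr_states(matrix)
                    summary[f"cluster_{context}"] = repr(dend.nested)
                except ValueError as exc:
                    logger.warning("clustering skipped for %s: %s", context, exc)

        # -- NJ tree from SNPs ----------------------------------------------
        if config.snps:
            snps = io_mod.read_snp_table(config.snps)
            dist = analysis.snp_distance_matrix(snps, sorted(config.samples))
            dist.to_csv(outdir / "snp_distances.tsv", sep="\t")
            if len(config.samples) >= 3:
                tree = analysis.neighbor_joining(dist)
                tree.write(str(outdir / "nj_tree.nwk"))
            # density correlation per context
            for context in config.contexts:
                merged = merged_dmrs[context]
                if not merged:
                    continue
                try:
                    bins, r2 = analysis.density_correlation(
                        merged, snps, config.bin_size[context]
                    )
                except ValueError as exc:
                    logger.warning("density correlation skipped (%s): %s",
                                   context, exc)
                    continue
                bins.to_csv(outdir / f"density.{context}.tsv", sep="\t", index=False)
                summary[f"density_r2_{context}"] = r2

        # -- TE-indel proximity ----------------------------------------------
        if config.te_indels:
            tes_poly = io_mod.read_te_polymorphisms(config.te_indels)
            rows = []
            for context in config.contexts:
                merged = merged_dmrs[context]
                res = analysis.te_dmr_proximity(
                    merged, tes_poly, window=config.proximity_window,
                    n_perm=config.n_perm, seed=config.seed,
                )
                rows.append(
                    (context, res.n_dmrs, res.near_insertion, res.near_deletion,
                     res.near_any, res.p_any)
                )
                summary[f"te_near_any_{context}"] = res.near_any
            pd.DataFrame(
                rows,
                columns=["context", "n_dmrs", "near_insertion", "near_deletion",
                         "near_any", "p_any"],
            ).to_csv(outdir / "te_proximity.tsv", sep="\t", index=False)

        (outdir / "summary.json").write_text(json.dumps(summary, indent=1))
        return summary
    finally:
        logging.getLogger("tilemeth").removeHandler(log_fh)
        log_fh.close()
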