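"""Config-driven orchestration: simulate -> blocks -> enrich -> cna -> expr.

One YAML/JSON config drives the whole run; all randomness flows from a
single top-level seed expanded per stage, and every stage communicates with
the next through plain files in the output directory, so any stage can be
re-run or replaced.  The final JSON report echoes the config and collects
each stage's headline numbers; given the same config and seed it is
byte-identical across runs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .genome_intervals import IntervalSet, read_bed, write_bed
from . import io_formats as io
from .block_calling import BlockConfig, call_blocks
from .cna_analysis import cna_block_overlap, cna_index, compare_groups
from .expression_stats import (
    cin25_score,
    deg_summary,
    mad_in_blocks,
    proliferation_normalize,
    regularized_t,
)
from .feature_enrichment import PermutationConfig, enrich_table
from .synthetic_data import (
    CASE_GROUP,
    REF_GROUP,
    CNASpec,
    ExpressionSpec,
    SimConfig,
    TrackSpec,
    simulate_cna,
    simulate_expression,
    simulate_methylome,
    simulate_tracks,
)

log = logging.getLogger("hypoblocks")

KNOWN_SECTIONS = {"seed", "simulate", "blocks", "enrichment", "cna", "expression"}


class ConfigError(ValueError):
    pass


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    validate_config(cfg)
    return cfg


def validate_config(cfg: dict) -> None:
    """Collect every schema problem before failing."""
    problems = []
    if not isinstance(cfg, dict):
        raise ConfigError("config must be a mapping")
    if "seed" not in cfg:
        problems.append("missing top-level 'seed'")
    unknown = set(cfg) - KNOWN_SECTIONS
    if unknown:
        problems.append(f"unknown section(s): {', '.join(sorted(unknown))}")
    sim = cfg.get("simulate")
    if sim is None:
        problems.append(
            "no 'simulate' section and no external inputs configured: "
            "the pipeline has no methylome to analyze"
        )
    if problems:
        raise ConfigError("; ".join(problems))


def _filter_kwargs(cls, d: dict) -> dict:
    names = {f.name for f in dataclasses.fields(cls)}
    return {k: v for k, v in d.items() if k in names}


def _stage_seeds(seed: int) -> dict[str, int]:
    return {
        name: int(s.generate_state(1)[0] % (2**31))
        for name, s in zip(
            ["simulate", "enrichment", "cna", "expression"],
            np.random.SeedSequence(int(seed)).spawn(4),
        )
    }


def simulate_inputs(config: dict, outdir, stage_seed: int | None = None) -> dict:
    """Generate and write every synthetic input; returns the in-memory objects."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "truth").mkdir(exist_ok=True)
    if stage_seed is None:
        stage_seed = _stage_seeds(config["seed"])["simulate"]

    sim_cfg_raw = dict(config.get("simulate") or {})
    track_specs_raw = sim_cfg_raw.pop("tracks", {})
    cna_raw = sim_cfg_raw.pop("cna", {})
    expr_raw = sim_cfg_raw.pop("expression", {})
    sim = SimConfig(seed=stage_seed, **_filter_kwargs(SimConfig, sim_cfg_raw))
    genome = sim.genome()

    methylome, truth = simulate_methylome(sim)
    span_tracks = {n for n, s in track_specs_raw.items() if s.get("span")}
    tracks = simulate_tracks(
        sim,
        truth.blocks,
        {n: TrackSpec(**_filter_kwargs(TrackSpec, s)) for n, s in track_specs_raw.items()},
    )
    cna_spec = CNASpec(**_filter_kwargs(CNASpec, cna_raw))
    segments = simulate_cna(sim, truth.blocks, cna_spec)
    expr_spec = ExpressionSpec(**_filter_kwargs(ExpressionSpec, expr_raw))
    expr, gene_coords = simulate_expression(sim, truth.blocks, expr_spec)

    genome.to_tsv(outdir / "genome.tsv")
    io.write_methylome(methylome, outdir / "methylome.tsv")
    io.write_groups(methylome.groups, outdir / "groups.tsv")
    for name, track in tracks.items():
        write_bed(track.normalize(), outdir / f"track_{name}.bed")
    io.write_segments(segments, outdir / "cna_segments.tsv")
    io.write_expression(expr, outdir / "expression.tsv")
    io.write_gene_coords(gene_coords, outdir / "genes.bed")
    write_bed(truth.blocks, outdir / "truth" / "blocks.bed")
    return {
        "sim": sim,
        "genome": genome,
        "methylome": methylome,
        "truth": truth,
        "tracks": tracks,
        "span_tracks": span_tracks,
        "segments": segments,
        "cna_spec": cna_spec,
        "expr_spec": expr_spec,
        "expr": expr,
        "gene_coords": gene_coords,
        "report": {
            "outputs": ["methylome.tsv", "groups.tsv", "cna_segments.tsv",
                        "expression.tsv", "genes.bed", "truth/blocks.bed"],
            "n_cpgs": methylome.n_sites,
            "n_samples": len(methylome.samples),
            "truth_block_bases": truth.blocks.bases(),
            "truth_block_fraction": truth.blocks.bases() / genome.total_size,
        },
    }


def run_pipeline(config, outdir) -> dict:
    """Run every stage in dependency order; returns the report dict.

    ``config`` is a path or an already-validated mapping.  A failing stage
    leaves the outputs of completed stages on disk and raises with the stage
    name.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    else:
        validate_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    seed = int(config["seed"])
    stage_seeds = _stage_seeds(seed)
    report: dict = {
        "tool": "hypoblocks",
        "version": __version__,
        "seed": seed,
        "config": config,
        "stages": {},
    }

    stage = "simulate"
    try:
        sim_objs = simulate_inputs(config, outdir, stage_seeds["simulate"])
        genome = sim_objs["genome"]
        methylome = sim_objs["methylome"]
        truth = sim_objs["truth"]
        tracks = sim_objs["tracks"]
        span_tracks = sim_objs["span_tracks"]
        segments = sim_objs["segments"]
        cna_spec = sim_objs["cna_spec"]
        expr_spec = sim_objs["expr_spec"]
        expr = sim_objs["expr"]
        gene_coords = sim_objs["gene_coords"]
        report["stages"]["simulate"] = sim_objs["report"]
        log.info("simulate: %d CpGs, %d truth blocks", methylome.n_sites, len(truth.blocks))

        stage = "blocks"
        block_cfg = BlockConfig(**_filter_kwargs(BlockConfig, config.get("blocks") or {}))
        blocks, tilestats = call_blocks(
            methylome, (REF_GROUP, CASE_GROUP), genome, block_cfg
        )
        write_bed(
            blocks.blocks,
            outdir / "blocks.bed",
            scores=[-100 * d for d in blocks.stats["mean_delta"]] if len(blocks.stats) else None,
        )
        tilestats.round(6).to_csv(outdir / "tiles.tsv", sep="\t", index=False)
        pct_genome = 100 * blocks.total_bases() / genome.total_size
        report["stages"]["blocks"] = {
            "outputs": ["blocks.bed", "tiles.tsv"],
            "n_blocks": len(blocks),
            "block_bases": blocks.total_bases(),
            "pct_genome": round(pct_genome, 3),
        }
        log.info("blocks: %d blocks, %.1f%% of genome", len(blocks), pct_genome)

        stage = "enrichment"
        enr_cfg = config.get("enrichment") or {}
        perm = PermutationConfig(
            n_permutations=int(enr_cfg.get("n_permutations", 1000)),
            seed=stage_seeds["enrichment"],
        )
        results = enrich_table(blocks, tracks, genome, perm, span_tracks=span_tracks)
        enrich_json = [r.as_dict() for r in results]
        _write_json(enrich_json, outdir / "enrich.json")
        report["stages"]["enrichment"] = {
            "outputs": ["enrich.json"],
            "tracks": {r.feature_name: {"fold": round(r.fold_enrichment, 2), "p": r.p}
                       for r in results},
        }

        stage = "cna"
        indices = cna_index(segments, genome)
        labels = {ix.sample: cna_spec.group for ix in indices}
        overlap = cna_block_overlap(segments, blocks, genome)
        cna_json = {
            "indices": {ix.sample: ix.fraction_altered for ix in indices},
            "median_index": float(np.median([ix.fraction_altered for ix in indices])),
            "density_in": overlap.density_in,
            "density_out": overlap.density_out,
            "density_ratio": (
                overlap.density_in / overlap.density_out if overlap.density_out else None
            ),
            "p": overlap.p,
        }
        _write_json(cna_json, outdir / "cna.json")
        report["stages"]["cna"] = {"outputs": ["cna.json"], **{k: v for k, v in cna_json.items() if k != "indices"}}

        stage = "expression"
        expr_section = config.get("expression") or {}
        marker = expr_section.get("marker", "MKI67")
        maintenance = expr_section.get(
            "maintenance_genes", list(expr_spec.maintenance_genes)
        )
        signature = expr_section.get("signature", list(expr_spec.signature_genes))
        reg = regularized_t(expr, (REF_GROUP, CASE_GROUP))
        degs = deg_summary(reg, p_cutoff=float(expr_section.get("deg_p", 0.01)))
        prolif = {
            g: {
                "median_ref": r["median_ref"],
                "median_case": r["median_case"],
                "p": r["p"],
            }
            for g in maintenance
            if g in expr.values.index
            for r in [proliferation_normalize(expr, g, marker, (REF_GROUP, CASE_GROUP))]
        }
        case_samples = expr.samples_in_group(CASE_GROUP)
        mad = mad_in_blocks(expr, gene_coords, blocks, case_samples)
        cin = cin25_score(expr, signature, (REF_GROUP, CASE_GROUP))
        expr_json = {
            "deg": degs,
            "proliferation_normalized": prolif,
            "mad": {k: mad[k] for k in
                    ("median_mad_in", "median_mad_out", "n_in", "n_out", "p")},
            "cin25": {"score": cin["score"], "n_significant": cin["n_significant"],
                      "n_present": cin["n_present"]},
        }
        _write_json(expr_json, outdir / "expr.json")
        report["stages"]["expression"] = {"outputs": ["expr.json"], **expr_json}
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    _write_json(report, outdir / "report.json")
    return report


def _write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_jsonable)
        fh.write("\n")


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON-serializable: {type(x)}")
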