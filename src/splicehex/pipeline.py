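"""End-to-end driver: simulate -> quantify -> map -> profile -> rank.

The pipeline runs the stages in dependency order on a simulated cohort (or
on files already on disk), writes each stage's tables under the output
directory and records a machine-readable manifest of parameters, seeds and
input digests.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, assoc, hexrank, io, seqfx, sse, synthio
from .genome import ACCEPTOR, DONOR

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything one run needs: stage parameters and the master seed."""

    outdir: str = "splicehex_out"
    seed: int = 0
    synth: synthio.SynthConfig | None = None
    min_reads: int = 10
    min_replicates: int = 3
    min_genotypes: int = 100
    min_passing: int = 2
    maf_min: float = 0.05
    min_peak_snps: int = 1
    merge_window: int = 100_000
    noise_factor: float = 1.33
    spread_window: int = 750_000
    k: int = 6
    window: int = 100
    mappable_min_obs: int = 100

    def __post_init__(self):
        if self.synth is None:
            self.synth = synthio.SynthConfig(seed=self.seed)


def _digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig, stages: tuple[str, ...] = (
        "simulate", "sse", "gwas", "seqfx", "hexrank")) -> dict:
    """Run the configured stages and return the in-memory result bundle.

    Any stage failure raises with a stage-tagged message; outputs and a run
    manifest land under ``config.outdir``.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    state: dict = {}
    manifest = {"version": __version__, "python": sys.version.split()[0],
                "seed": config.seed, "engine": "per-variant OLS",
                "parameters": {k: v for k, v in asdict(config).items()
                               if k not in ("synth",)},
                "synth": asdict(config.synth), "stages": [], "inputs": {}}
    for stage in stages:
        try:
            _STAGES[stage](config, state, outdir)
        except Exception as exc:  # noqa: BLE001 - tag and re-raise
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        manifest["stages"].append(stage)
    for name in ("genome", "annotation", "vcf"):
        path = state.get("paths", {}).get(name)
        if path and Path(path).exists():
            manifest["inputs"][name] = _digest(path)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    state["manifest"] = manifest
    return state


def _stage_simulate(config, state, outdir):
    model = synthio.TrueStrengthModel.distance_decay(seed=config.seed)
    genome, sites = synthio.generate_genome(config.synth, model)
    variants, dosages = synthio.simulate_genotypes(config.synth, sites, genome)
    truth = synthio.true_sse(sites, model, genome, variants, dosages)
    matrix = synthio.simulate_junction_counts(truth, config.synth, sites)
    state.update(model=model, genome=genome, sites=sites, variants=variants,
                 dosages=dosages, truth=truth, matrix=matrix)
    state["paths"] = io.write_cohort(outdir / "cohort", genome, sites,
                                     variants, dosages, matrix,
                                     ploidy=config.synth.ploidy)


def _stage_sse(config, state, outdir):
    if "matrix" not in state:
        raise RuntimeError("missing upstream output: run 'simulate' first")
    matrix = state["matrix"]
    retained = sse.filter_sites(matrix, config.min_reads, config.min_replicates,
                                config.min_genotypes)
    sub = sse.SSEMatrix(sites=matrix.sites.loc[retained],
                        samples=matrix.samples,
                        alpha=matrix.alpha[matrix.sites.index.get_indexer(retained)],
                        beta=matrix.beta[matrix.sites.index.get_indexer(retained)])
    table = sse.genotype_average(sub, config.min_reads, config.min_passing)
    replicated = config.synth.replicates_per_genotype > 1
    summaries = sse.site_summaries(sub, config.min_reads, config.min_passing,
                                   replicated=replicated)
    mappable = sse.select_mappable_sites(
        summaries, mode="replicated" if replicated else "variance_only",
        min_obs=config.mappable_min_obs)
    state.update(filtered=sub, genotype_table=table, summaries=summaries,
                 mappable=mappable)
    io.write_table(table, outdir / "sse_matrix.tsv")
    io.write_table(summaries, outdir / "site_summaries.tsv")


def _stage_gwas(config, state, outdir):
    if "genotype_table" not in state:
        raise RuntimeError("missing upstream output: run 'sse' first")
    gmat = assoc.GenotypeMatrix(variants=state["variants"],
                                dosages=state["dosages"])
    rows = []
    for site_id in state["mappable"]:
        rec = assoc.map_site(state["genotype_table"].loc[site_id], gmat,
                             state["sites"].loc[site_id], site_id=site_id,
                             maf_min=config.maf_min,
                             min_peak_snps=config.min_peak_snps,
                             merge_window=config.merge_window,
                             noise_factor=config.noise_factor,
                             spread_window=config.spread_window)
        if rec is not None:
            rows.append(rec)
    top = pd.DataFrame(rows)
    if len(top):
        top = top.set_index("site_id")
    state["top_associations"] = top
    io.write_table(top, outdir / "top_associations.tsv")


def _stage_seqfx(config, state, outdir):
    if "genotype_table" not in state:
        raise RuntimeError("missing upstream output: run 'sse' first")
    site_strength = state["genotype_table"].mean(axis=1)
    profile = seqfx.position_nucleotide_means(state["sites"].loc[site_strength.index],
                                              state["genome"], site_strength)
    state["position_profile"] = profile
    io.write_table(profile, outdir / "position_profile.tsv", index=False)
    top = state.get("top_associations")
    if top is not None and len(top):
        enriched = top.reset_index().merge(
            state["variants"][["ref", "alt"]], left_on="top_snp",
            right_index=True, how="left")
        promoting = seqfx.infer_promoting_nucleotides(enriched, state["sites"])
        state["promoting_profile"] = promoting
        io.write_table(promoting, outdir / "promoting_profile.tsv", index=False)


def _stage_hexrank(config, state, outdir):
    if "genotype_table" not in state:
        raise RuntimeError("missing upstream output: run 'sse' first")
    site_strength = state["genotype_table"].mean(axis=1)
    sites = state["sites"].loc[site_strength.dropna().index]
    tables, choices = {}, []
    for stype in (DONOR, ACCEPTOR):
        sub = sites[sites["site_type"] == stype]
        if sub.empty:
            continue
        table = hexrank.strength_table(sub, site_strength, state["genome"],
                                       k=config.k)
        tables[stype] = table
        io.write_table(table, outdir / f"strength_table_{stype}.tsv", index=False)
        res = hexrank.choice_explained(state["genome"], sub, table,
                                       k=config.k, window=config.window)
        choices.append({"site_type": stype, "k": res.k, "window": res.window,
                        "n_tested": res.n_sites_tested, "n_success": res.n_success,
                        "raw_rate": res.raw_rate,
                        "possible_fraction": res.possible_fraction,
                        "adjusted_percent": res.adjusted_percent})
    state["strength_tables"] = tables
    state["choice_results"] = pd.DataFrame(choices)
    io.write_table(state["choice_results"], outdir / "choice_explained.tsv",
                   index=False)


_STAGES = {"simulate": _stage_simulate, "sse": _stage_sse, "gwas": _stage_gwas,
           "seqfx": _stage_seqfx, "hexrank": _stage_hexrank}
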