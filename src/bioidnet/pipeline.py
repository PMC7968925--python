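"""End-to-end pipeline: config, stage chaining, run manifest.

``run_pipeline`` executes impute -> normalize -> filter -> dispersion ->
LRT -> BH -> candidates -> network build -> prune -> MCL -> specificity ->
cluster filter -> diffusion -> rank -> enrichment, writing one TSV per
stage plus a JSON manifest (versions, config, seeds, row counts).  All
stage parameters default to the study's published thresholds.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from . import diffexp, diffusion, network as netmod
from .io import (
    ParseError,
    read_design,
    read_edge_list,
    read_gmt,
    read_psm_table,
    read_seeds,
    read_specificity,
    write_table,
)

logger = logging.getLogger("bioidnet.pipeline")


def setup_logging(level: int = logging.INFO) -> None:
    """Timestamped, stage-tagged logging to stderr."""
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(
        logging.Formatter("%(asctime)s [%(name)s] %(levelname)s %(message)s")
    )
    root = logging.getLogger("bioidnet")
    root.handlers[:] = [handler]
    root.setLevel(level)


@dataclass
class RunConfig:
    """All pipeline parameters; defaults are the published thresholds
    (adjp < 0.05, fold-change > 3, PSM > 2 in >= 2 replicates, STRING
    combined score > 0.4, diffusion time 0.25, top 30 ranked candidates)."""

    psm: str = ""
    design: str = ""
    edges: str = ""
    seeds: str = ""
    specificity: str = ""
    categories: str = ""
    outdir: str = "results"
    alpha: float = 0.05
    fc_min: float = 3.0
    min_psm: int = 2
    min_reps: int = 2
    score_cutoff: float = 0.4
    inflation: float = 2.0
    t: float = 0.25
    top_k: int = 30
    max_nonspecific_frac: float = 0.5
    n_resamples: int = 10000
    sampler_seed: int = 0
    upper_case: bool = False
    restrict_to_candidates: bool = True

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        """Load a flat key = value config file; keyword overrides win."""
        values: dict = {}
        fields = {f.name: f for f in dataclasses.fields(cls)}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ParseError(f"{path}: line {lineno}: expected key = value")
            key, raw = (s.strip() for s in line.split("=", 1))
            if key not in fields:
                raise ParseError(f"{path}: line {lineno}: unknown key '{key}'")
            ftype = fields[key].type
            if ftype == "bool":
                values[key] = raw.lower() in ("1", "true", "yes")
            elif ftype == "int":
                values[key] = int(raw)
            elif ftype == "float":
                values[key] = float(raw)
            else:
                values[key] = raw
        values.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**values)

    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for f in dataclasses.fields(self):
                fh.write(f"{f.name} = {getattr(self, f.name)}\n")

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and return the manifest (also written to outdir).

    The candidate network is the edge-list subgraph induced on called
    candidates (plus any seed genes among them); pass
    ``restrict_to_candidates=False`` to diffuse over the full edge list.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}
    stage_box = {"stage": "setup"}
    try:
        return _run_stages(config, outdir, counts, stage_box)
    except Exception as exc:
        logger.error("stage %s failed: %s", stage_box["stage"], exc)
        raise


def _run_stages(
    config: RunConfig, outdir: Path, counts: dict[str, int], stage_box: dict
) -> dict:
    def stage_mark(name: str) -> str:
        stage_box["stage"] = name
        return name

    stage = stage_mark("differential")
    logger.info("stage %s: reading %s", stage, config.psm)
    design = read_design(config.design)
    psm = read_psm_table(config.psm, design, upper_case=config.upper_case, impute=False)
    psm = diffexp.impute_missing(psm)
    norm = diffexp.sum_normalize(psm)
    retained = diffexp.filter_detected(psm, config.min_psm, config.min_reps)
    disp = diffexp.estimate_dispersion(norm.loc[retained], psm.condition)
    tested = diffexp.lrt_differential(norm.loc[retained], psm.condition, disp)
    results = diffexp.call_candidates(tested, config.alpha, config.fc_min)
    candidates = diffexp.candidate_list(results)
    out = results.reset_index()[
        ["protein_id", "mean_bait", "mean_control", "log2fc", "lrt_stat",
         "pvalue", "adjp", "candidate"]
    ]
    write_table(out, outdir / "differential.tsv")
    counts["differential.tsv"] = len(out)

    stage = stage_mark("network")
    logger.info("stage %s: building network from %s", stage, config.edges)
    net = read_edge_list(config.edges, config.score_cutoff, upper_case=config.upper_case)
    seeds = read_seeds(config.seeds, upper_case=config.upper_case)
    if config.restrict_to_candidates:
        keep = set(candidates) | set(seeds.genes)
        net = type(net)(graph=net.graph.subgraph(keep & set(net.graph.nodes)).copy())
    net = netmod.prune_unconnected(net)
    if net.graph.number_of_nodes() == 0:
        raise ParseError("no network nodes remain after candidate restriction")
    clusters = netmod.mcl_cluster(net, inflation=config.inflation)
    write_table(clusters.to_table(), outdir / "clusters.tsv")
    counts["clusters.tsv"] = len(clusters.membership)
    metrics = netmod.topology_metrics(net)
    write_table(metrics, outdir / "metrics.tsv")
    counts["metrics.tsv"] = len(metrics)

    stage = stage_mark("specificity")
    if config.specificity:
        reference = read_specificity(config.specificity, upper_case=config.upper_case)
        annotations = diffusion.annotate_specificity(net.nodes, reference)
        clusters_kept = diffusion.exclude_nonspecific_clusters(
            clusters, annotations, config.max_nonspecific_frac
        )
    else:
        reference = None
        clusters_kept = clusters

    stage = stage_mark("diffusion")
    logger.info("stage %s: diffusing %d seeds at t=%g", stage, len(seeds.genes), config.t)
    diff = diffusion.heat_diffuse(net, seeds, t=config.t)
    dtab = diff.table.copy()
    dtab["cluster_id"] = dtab["node"].map(lambda n: clusters_kept.membership.get(n, -1))
    if reference is not None:
        dtab["specificity"] = dtab["node"].map(reference.classify)
    write_table(dtab, outdir / "diffusion.tsv")
    counts["diffusion.tsv"] = len(dtab)
    ranked = diffusion.rank_candidates(
        diff, candidates, top_k=config.top_k, clusters=clusters_kept,
        specificity=reference,
    )
    write_table(ranked, outdir / "ranked.tsv")
    counts["ranked.tsv"] = len(ranked)

    stage = stage_mark("enrichment")
    if config.categories:
        cats = read_gmt(config.categories, upper_case=config.upper_case)
        universe = set(net.nodes)
        target = set(ranked["node"])
        enr = diffusion.resampling_enrichment(
            target, cats, universe,
            n_resamples=config.n_resamples, sampler_seed=config.sampler_seed,
        )
        write_table(enr, outdir / "enrichment.tsv")
        counts["enrichment.tsv"] = len(enr)

    manifest = {
        "version": __version__,
        "config": config.as_dict(),
        "dispersion": disp.phi,
        "n_candidates": len(candidates),
        "mcl_converged": clusters.converged,
        "row_counts": counts,
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    logger.info("pipeline complete: %d candidates, %d clusters",
                len(candidates), clusters_kept.n_clusters)
    return manifest
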