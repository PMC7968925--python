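"""Synthetic data with planted ground truth for every pipeline stage.

Two generators emulate the study design end-to-end:

* :func:`simulate_psm` — a bait-vs-control spectral-count experiment:
  negative-binomial PSM counts with per-sample library-size variation, a
  planted subset of truly bait-enriched proteins at a fixed fold, and
  independent per-cell dropout (zero-inflation) standing in for peptides
  below the detection limit.

* :func:`simulate_network` — a weighted planted-partition graph whose
  blocks play the role of functional modules: one block hosts the
  phenotype seed genes, another is labeled non-specific (the sticky
  background interactors every bait pulls down).

All outputs are deterministic functions of their seed, and
:func:`write_fixture_bundle` serializes a complete, self-consistent input
set (PSM table, design, edge list, seeds, specificity reference, category
sets, truth manifest) in the package's own file dialects.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .io import (
    CategorySets,
    FunctionalNetwork,
    PsmMatrix,
    SeedSet,
    SpecificityReference,
    write_design,
    write_edge_list,
    write_gmt,
    write_psm_table,
    write_seeds,
    write_specificity,
)
from .network import ClusterAssignment, renumber_clusters

logger = logging.getLogger("bioidnet.simulate")

# library-size variation: lognormal with sigma 0.2 (~20% spread), the scale
# of loading differences the sum normalization is meant to remove
_LIBSIZE_SIGMA = 0.2
_N_SEED_GENES = 3
_WEIGHT_LOW, _WEIGHT_HIGH = 0.41, 1.0  # above the 0.4 construction cutoff


@dataclass
class PsmTruth:
    """Ground truth of a simulated PSM experiment."""

    planted: list[str]
    fold: float
    phi: float
    baseline_mean: float
    libsize_factors: dict[str, float]
    zero_rate: float
    seed: int


@dataclass
class NetworkTruth:
    """Parameters and ground truth of a planted-partition network."""

    block_sizes: tuple[int, ...] = (15, 15, 15, 15)
    p_in: float = 0.6
    p_out: float = 0.02
    seed_block: int = 0
    nonspecific_block: int = 3
    seed: int = 0
    node_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.p_in > self.p_out:
            raise ValueError("p_in must exceed p_out")
        if not (0 <= self.seed_block < len(self.block_sizes)):
            raise ValueError("seed_block out of range")
        if not (0 <= self.nonspecific_block < len(self.block_sizes)):
            raise ValueError("nonspecific_block out of range")

    def blocks(self) -> list[list[str]]:
        names = self.node_names
        out, i = [], 0
        for size in self.block_sizes:
            out.append(names[i : i + size])
            i += size
        return out


def _protein_names(n: int) -> list[str]:
    return [f"G{i:04d}" for i in range(1, n + 1)]


def simulate_psm(
    n_proteins: int = 500,
    n_true: int = 60,
    fold: float = 8.0,
    phi: float = 0.3,
    baseline_mean: float = 20.0,
    n_bait_reps: int = 3,
    n_control_reps: int = 3,
    zero_rate: float = 0.02,
    seed: int = 0,
) -> tuple[PsmMatrix, PsmTruth]:
    """Simulate a bait/control PSM matrix with planted interactors.

    Counts are NB with mean = baseline * libsize * fold^[planted & bait]
    and dispersion ``phi`` (Poisson when phi = 0); each cell is then
    independently zeroed with probability ``zero_rate``.  The planted
    proteins are the first ``n_true`` symbols so block structure downstream
    can reuse them directly.
    """
    if n_true > n_proteins:
        raise ValueError("n_true exceeds n_proteins")
    if not (0 <= zero_rate < 1):
        raise ValueError("zero_rate must be in [0, 1)")
    if fold < 1 or phi < 0 or baseline_mean <= 0:
        raise ValueError("fold >= 1, phi >= 0 and baseline_mean > 0 required")
    rng = np.random.default_rng(seed)
    proteins = _protein_names(n_proteins)
    planted = proteins[:n_true]
    samples = [f"bait_{r}" for r in range(1, n_bait_reps + 1)] + [
        f"ctrl_{r}" for r in range(1, n_control_reps + 1)
    ]
    n_samples = len(samples)
    libsize = np.exp(rng.normal(0.0, _LIBSIZE_SIGMA, size=n_samples))

    mu = np.full((n_proteins, n_samples), baseline_mean)
    mu[:n_true, :n_bait_reps] *= fold
    mu = mu * libsize[None, :]
    if phi == 0:
        counts = rng.poisson(mu)
    else:
        r = 1.0 / phi
        counts = rng.negative_binomial(r, r / (r + mu))
    if zero_rate > 0:
        counts = np.where(rng.random(mu.shape) < zero_rate, 0, counts)

    condition = pd.Series(
        ["bait"] * n_bait_reps + ["control"] * n_control_reps, index=samples
    )
    replicate = pd.Series(
        list(range(1, n_bait_reps + 1)) + list(range(1, n_control_reps + 1)),
        index=samples,
    )
    psm = PsmMatrix(
        counts=pd.DataFrame(counts.astype(float), index=proteins, columns=samples),
        condition=condition,
        replicate=replicate,
    )
    truth = PsmTruth(
        planted=planted,
        fold=fold,
        phi=phi,
        baseline_mean=baseline_mean,
        libsize_factors=dict(zip(samples, libsize.round(6))),
        zero_rate=zero_rate,
        seed=seed,
    )
    return psm, truth


def simulate_network(
    truth: NetworkTruth,
) -> tuple[FunctionalNetwork, SeedSet, SpecificityReference, ClusterAssignment]:
    """Weighted planted-partition graph with seeds and specificity labels.

    Within-block edges appear with probability p_in, between-block with
    p_out; present edges get a combined score uniform on [0.41, 1], i.e.
    always above the construction cutoff so the planted blocks survive
    network building exactly.  Three seed genes are placed in the seed
    block; every member of the designated non-specific block is labeled
    'nonspecific' and all other nodes 'specific'.
    """
    rng = np.random.default_rng(truth.seed)
    n = sum(truth.block_sizes)
    if not truth.node_names:
        truth.node_names = _protein_names(n)
    if len(truth.node_names) != n:
        raise ValueError("node_names length must equal total block size")
    blocks = truth.blocks()
    g = nx.Graph()
    g.add_nodes_from(truth.node_names)
    block_of = {node: b for b, members in enumerate(blocks) for node in members}
    names = truth.node_names
    for i in range(n):
        for j in range(i + 1, n):
            p = truth.p_in if block_of[names[i]] == block_of[names[j]] else truth.p_out
            if rng.random() < p:
                w = round(rng.uniform(_WEIGHT_LOW, _WEIGHT_HIGH), 3)
                g.add_edge(names[i], names[j], weight=w)

    seed_members = blocks[truth.seed_block]
    seed_genes = sorted(rng.choice(seed_members, size=_N_SEED_GENES, replace=False))
    seeds = SeedSet(heat={s: 1.0 for s in seed_genes})
    nonspecific = set(blocks[truth.nonspecific_block])
    reference = SpecificityReference(
        classes={
            node: ("nonspecific" if node in nonspecific else "specific")
            for node in names
        },
        provenance="synthetic bait/control interaction survey",
    )
    planted_partition = ClusterAssignment(membership=renumber_clusters(blocks))
    return FunctionalNetwork(graph=g), seeds, reference, planted_partition


PRESETS: dict[str, dict] = {
    "tiny": dict(
        n_proteins=20, n_true=8, fold=8.0, phi=0.2, baseline_mean=20.0,
        n_bait_reps=3, n_control_reps=3, zero_rate=0.02,
        block_sizes=(4, 4), p_in=0.9, p_out=0.05,
        seed_block=0, nonspecific_block=1,
    ),
    "default": dict(
        n_proteins=500, n_true=60, fold=8.0, phi=0.3, baseline_mean=20.0,
        n_bait_reps=3, n_control_reps=3, zero_rate=0.02,
        block_sizes=(15, 15, 15, 15), p_in=0.6, p_out=0.02,
        seed_block=0, nonspecific_block=3,
    ),
    "stress": dict(
        n_proteins=2000, n_true=120, fold=8.0, phi=0.3, baseline_mean=20.0,
        n_bait_reps=3, n_control_reps=3, zero_rate=0.1,
        block_sizes=(20, 20, 20, 20, 20, 20), p_in=0.5, p_out=0.02,
        seed_block=0, nonspecific_block=5,
    ),
}


def build_bundle(preset: str, seed: int):
    """In-memory fixture bundle for a preset: all stage inputs plus truths."""
    if preset not in PRESETS:
        raise ValueError(f"unknown preset '{preset}'; choose from {sorted(PRESETS)}")
    p = PRESETS[preset]
    psm, psm_truth = simulate_psm(
        n_proteins=p["n_proteins"], n_true=p["n_true"], fold=p["fold"],
        phi=p["phi"], baseline_mean=p["baseline_mean"],
        n_bait_reps=p["n_bait_reps"], n_control_reps=p["n_control_reps"],
        zero_rate=p["zero_rate"], seed=seed,
    )
    net_truth = NetworkTruth(
        block_sizes=tuple(p["block_sizes"]), p_in=p["p_in"], p_out=p["p_out"],
        seed_block=p["seed_block"], nonspecific_block=p["nonspecific_block"],
        seed=seed + 1, node_names=psm_truth.planted[: sum(p["block_sizes"])],
    )
    if sum(p["block_sizes"]) > p["n_true"]:
        raise ValueError("preset blocks exceed planted proteins")
    network, seeds, reference, partition = simulate_network(net_truth)
    # category sets over the network universe: the seed block (phenotype-like
    # category), the non-specific block, and a random draw of a third
    rng = np.random.default_rng(seed + 2)
    blocks = net_truth.blocks()
    random_set = sorted(
        rng.choice(net_truth.node_names, size=max(3, len(blocks[0]) // 2), replace=False)
    )
    cats = CategorySets(
        sets={
            "seed_block": blocks[net_truth.seed_block],
            "nonspecific_block": blocks[net_truth.nonspecific_block],
            "random_set": random_set,
        },
        descriptions={
            "seed_block": "module hosting the phenotype seeds",
            "nonspecific_block": "module of sticky background interactors",
            "random_set": "uniform random draw from network nodes",
        },
    )
    return psm, psm_truth, network, seeds, reference, partition, cats, net_truth


def write_fixture_bundle(outdir: str | Path, preset: str = "default", seed: int = 0) -> dict[str, Path]:
    """Write a complete offline input bundle plus a truth manifest.

    Returns a name -> path map.  Re-running with the same preset and seed
    reproduces every file byte for byte.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    psm, psm_truth, network, seeds, reference, partition, cats, net_truth = build_bundle(
        preset, seed
    )
    paths = {
        "psm": outdir / "psm.tsv",
        "design": outdir / "design.tsv",
        "edges": outdir / "edges.tsv",
        "seeds": outdir / "seeds.txt",
        "specificity": outdir / "specificity.tsv",
        "categories": outdir / "categories.gmt",
        "truth": outdir / "truth.json",
    }
    write_psm_table(psm, paths["psm"])
    write_design(psm, paths["design"])
    write_edge_list(network, paths["edges"])
    write_seeds(seeds, paths["seeds"])
    write_specificity(reference, paths["specificity"])
    write_gmt(cats, paths["categories"])
    manifest = {
        "preset": preset,
        "seed": seed,
        "psm_truth": asdict(psm_truth),
        "network_truth": {
            "block_sizes": list(net_truth.block_sizes),
            "p_in": net_truth.p_in,
            "p_out": net_truth.p_out,
            "seed_block": net_truth.seed_block,
            "nonspecific_block": net_truth.nonspecific_block,
            "seed": net_truth.seed,
            "blocks": net_truth.blocks(),
        },
        "seed_genes": seeds.genes,
        "planted_partition": partition.membership,
    }
    paths["truth"].write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    logger.info("wrote %s bundle (seed %d) to %s", preset, seed, outdir)
    return paths
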