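"""Seed-heat diffusion, candidate ranking, specificity filtering, enrichment.

Phenotype-associated seed genes receive unit heat which diffuses over the
weighted network under the combinatorial graph Laplacian L = D - W:

    h(t) = exp(-L t) h(0)

The kernel conserves total heat and concentrates it near the seeds at small
t, so ranking nodes by h(t) prioritizes candidates topologically close to
the phenotype hot-spots.  A normalized-Laplacian variant is available
behind a flag but is off by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, sparse, stats

from .io import CategorySets, FunctionalNetwork, SeedSet, SpecificityReference
from .network import ClusterAssignment, renumber_clusters

logger = logging.getLogger("bioidnet.diffusion")

_DENSE_LIMIT = 5000  # above this, use a sparse matrix-exponential action


@dataclass
class DiffusionResult:
    """Per-node heat at time t with deterministic ranking (1 = hottest)."""

    table: pd.DataFrame  # node, heat, rank, is_seed
    t: float

    def heat(self) -> pd.Series:
        return self.table.set_index("node")["heat"]


def heat_diffuse(
    net: FunctionalNetwork,
    seeds: SeedSet,
    t: float = 0.25,
    normalized: bool = False,
) -> DiffusionResult:
    """Diffuse seed heat for time t and rank all network nodes.

    Seeds absent from the network are dropped with a warning; if none
    remain an error lists them.  Ties in heat are broken lexicographically
    by symbol so ranks are stable across runs.
    """
    if t < 0:
        raise ValueError("diffusion time must be >= 0")
    order = net.nodes
    present = [g for g in seeds.genes if g in net.graph]
    missing = [g for g in seeds.genes if g not in net.graph]
    if missing:
        logger.warning("seeds not in network, dropped: %s", ", ".join(missing))
    if not present:
        raise ValueError(f"no seed overlaps the network; missing: {missing}")

    w, _ = net.adjacency(order)
    deg = w.sum(axis=1)
    lap = np.diag(deg) - w
    if normalized:
        inv_sqrt = np.where(deg > 0, 1.0 / np.sqrt(np.maximum(deg, 1e-300)), 0.0)
        lap = inv_sqrt[:, None] * lap * inv_sqrt[None, :]

    h0 = np.zeros(len(order))
    idx = {n: i for i, n in enumerate(order)}
    for g in present:
        h0[idx[g]] = seeds.heat[g]

    if t == 0:  # identity kernel, exactly
        h = h0.copy()
    elif len(order) <= _DENSE_LIMIT:
        evals, evecs = linalg.eigh(lap)
        h = evecs @ (np.exp(-evals * t) * (evecs.T @ h0))
    else:
        h = sparse.linalg.expm_multiply(-t * sparse.csr_matrix(lap), h0)
    h = np.maximum(h, 0.0)  # clip eigensolver noise at the boundary

    table = pd.DataFrame({"node": order, "heat": h})
    table["is_seed"] = table["node"].isin(present).astype(int)
    table = table.sort_values(["heat", "node"], ascending=[False, True], kind="mergesort")
    table["rank"] = np.arange(1, len(table) + 1)
    table = table[["node", "heat", "rank", "is_seed"]].reset_index(drop=True)
    return DiffusionResult(table=table, t=t)


def rank_candidates(
    diffusion: DiffusionResult,
    candidates: list[str],
    top_k: int = 30,
    clusters: ClusterAssignment | None = None,
    specificity: SpecificityReference | None = None,
) -> pd.DataFrame:
    """Top-k candidates by diffusion rank, annotated with cluster and class.

    Candidates absent from the diffusion network are excluded and reported
    in the table's ``attrs['missing']`` (and the log).
    """
    in_net = set(diffusion.table["node"])
    missing = sorted(set(candidates) - in_net)
    if missing:
        logger.warning("candidates not in network, excluded: %s", ", ".join(missing))
    tab = diffusion.table[diffusion.table["node"].isin(set(candidates))].copy()
    tab = tab.head(top_k)
    if clusters is not None:
        tab["cluster_id"] = tab["node"].map(
            lambda n: clusters.membership.get(n, -1)
        )
    if specificity is not None:
        tab["specificity"] = tab["node"].map(specificity.classify)
    tab = tab.reset_index(drop=True)
    tab.attrs["missing"] = missing
    return tab


def annotate_specificity(
    candidates: list[str], reference: SpecificityReference
) -> dict[str, str]:
    """Label each candidate specific / nonspecific / unobserved.

    'unobserved' marks proteins outside the bait/control interaction
    survey — the potential new interactors.
    """
    return {c: reference.classify(c) for c in candidates}


def exclude_nonspecific_clusters(
    clusters: ClusterAssignment,
    annotations: dict[str, str],
    max_nonspecific_frac: float = 0.5,
) -> ClusterAssignment:
    """Drop clusters dominated by non-specific interactors.

    A cluster is dropped when its fraction of 'nonspecific' members exceeds
    ``max_nonspecific_frac`` (strict).  Surviving clusters are renumbered
    deterministically (size, then smallest symbol).
    """
    unannotated = [n for n in clusters.membership if n not in annotations]
    if unannotated:
        raise ValueError(f"unannotated nodes: {sorted(unannotated)[:5]}...")
    kept: list[list[str]] = []
    for cid in range(clusters.n_clusters):
        members = clusters.members(cid)
        frac = sum(annotations[n] == "nonspecific" for n in members) / len(members)
        if frac > max_nonspecific_frac:
            logger.info(
                "dropping cluster %d (%d members, %.0f%% nonspecific)",
                cid, len(members), 100 * frac,
            )
        else:
            kept.append(members)
    return ClusterAssignment(
        membership=renumber_clusters(kept), converged=clusters.converged
    )


def resampling_enrichment(
    target_set: set[str],
    categories: CategorySets,
    universe: set[str],
    n_resamples: int = 10000,
    sampler_seed: int = 0,
) -> pd.DataFrame:
    """Over-representation of the target in each category by resampling.

    The null overlap distribution comes from size-matched uniform draws
    (without replacement) from the universe; the add-one estimator
    p = (1 + #{null >= observed}) / (n_resamples + 1) never returns 0.
    """
    target = set(target_set) & set(universe) if target_set else set()
    if len(set(target_set) - set(universe)):
        raise ValueError("target set is not a subset of the universe")
    uni = sorted(universe)
    k = len(target)
    if k > len(uni):
        raise ValueError("target larger than universe")
    rng = np.random.default_rng(sampler_seed)
    member_masks = {
        name: np.isin(uni, sorted(set(members) & set(universe)))
        for name, members in categories.sets.items()
    }
    # one draw matrix shared across categories: rows are resampled targets
    draws = np.empty((n_resamples, k), dtype=np.int64)
    for r in range(n_resamples):
        draws[r] = rng.choice(len(uni), size=k, replace=False)
    rows = []
    for name in categories.sets:
        mask = member_masks[name]
        observed = int(sum(1 for g in target if mask[uni.index(g)]))
        null = mask[draws].sum(axis=1)
        p = (1.0 + int((null >= observed).sum())) / (n_resamples + 1.0)
        rows.append(
            {
                "category": name,
                "overlap": observed,
                "pvalue": p,
                "n_resamples": n_resamples,
                "sampler_seed": sampler_seed,
            }
        )
    return pd.DataFrame(
        rows, columns=["category", "overlap", "pvalue", "n_resamples", "sampler_seed"]
    )


def hypergeometric_tail(
    universe_size: int, category_size: int, target_size: int, observed: int
) -> float:
    """Exact P(overlap >= observed) under uniform sampling — the closed-form
    counterpart of :func:`resampling_enrichment`, useful as a cross-check."""
    return float(
        stats.hypergeom.sf(observed - 1, universe_size, category_size, target_size)
    )
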