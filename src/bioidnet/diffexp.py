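"""Differential binding: candidate interactor calling from spectral counts.

The bait (e.g. a BirA*-fused transcription factor) and the control fusion
produce PSM counts per protein and replicate.  Candidates are called by:

1. impute missing PSM values to 0,
2. sum-normalize each sample to the grand mean library size,
3. keep proteins detected (raw PSM > ``min_psm``) in at least ``min_reps``
   bait replicates,
4. fit a negative-binomial GLM with a common dispersion shared by all
   proteins, test the condition effect by likelihood-ratio against the
   intercept-only model (chi-squared, 1 df),
5. adjust p-values by Benjamini-Hochberg and call candidates at
   adjp < alpha and fold-change > fc_min (both strict).

The NB log-likelihood is evaluated in its continuous (gamma-function)
form so that sum-normalized, real-valued counts are handled exactly; the
per-group mean is then the maximum-likelihood mean for any fixed
dispersion, which makes the common-dispersion profile likelihood cheap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from statsmodels.stats.multitest import multipletests

from .io import NumericError, PsmMatrix

logger = logging.getLogger("bioidnet.diffexp")

_PSEUDOCOUNT = 0.5  # added to each condition mean for bounded log fold-changes
_PHI_UPPER = 50.0


@dataclass
class DispersionEstimate:
    """Common NB dispersion phi (var = mu + phi mu^2), shared by all proteins."""

    phi: float
    method: str = "profile_likelihood"

    def __post_init__(self) -> None:
        if not np.isfinite(self.phi) or self.phi < 0:
            raise NumericError(f"invalid dispersion {self.phi}")


def impute_missing(psm: PsmMatrix) -> PsmMatrix:
    """Set every absent/NaN PSM cell to exactly 0; observed cells unchanged."""
    return PsmMatrix(
        counts=psm.counts.fillna(0.0),
        condition=psm.condition,
        replicate=psm.replicate,
    )


def sum_normalize(psm: PsmMatrix) -> pd.DataFrame:
    """Scale each sample by (grand mean of sample totals) / (its own total).

    Equalizes library size across samples while preserving the count scale,
    so NB modelling downstream stays on a count-like quantity.
    """
    totals = psm.counts.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise NumericError(f"sample(s) with zero total PSM: {list(zero.index)}")
    factors = totals.mean() / totals
    return psm.counts * factors


def filter_detected(psm: PsmMatrix, min_psm: int = 2, min_reps: int = 2) -> pd.Index:
    """Proteins with raw PSM > min_psm in >= min_reps bait replicates.

    Operates on raw (pre-normalization) counts and bait samples only: the
    rule describes repeated detection of the labeled protein.
    """
    bait = psm.samples("bait")
    if min_reps > len(bait):
        raise ValueError(f"min_reps={min_reps} exceeds {len(bait)} bait replicates")
    raw = psm.counts[bait].fillna(0.0)
    hits = (raw > min_psm).sum(axis=1)
    return psm.counts.index[hits >= min_reps]


def nb_loglik(y: np.ndarray, mu: np.ndarray, phi: float) -> np.ndarray:
    """Elementwise NB2 log-likelihood, continuous in y (gamma-function form).

    Reduces to the (continuous) Poisson log-likelihood as phi -> 0.
    """
    y = np.asarray(y, dtype=float)
    mu = np.maximum(np.asarray(mu, dtype=float), 1e-300)
    if phi < 1e-10:
        return y * np.log(mu) - mu - special.gammaln(y + 1.0)
    r = 1.0 / phi
    return (
        special.gammaln(y + r)
        - special.gammaln(r)
        - special.gammaln(y + 1.0)
        + r * np.log(r / (r + mu))
        + y * np.log(mu / (r + mu))
    )


def _condition_means(norm: pd.DataFrame, condition: pd.Series) -> pd.DataFrame:
    return norm.T.groupby(condition).mean().T


def _profile_loglik(norm: np.ndarray, groups: list[np.ndarray], phi: float) -> float:
    """Pooled Cox-Reid adjusted NB log-likelihood at phi.

    Per-protein, per-condition means are profiled out (the group sample
    mean is the NB mean MLE for fixed phi); the Cox-Reid term
    -0.5 log I(mu-hat), with I the Fisher information of the group's
    log-mean, removes the downward bias that plain profiling incurs from
    spending one degree of freedom per group on the mean.
    """
    total = 0.0
    for cols in groups:
        y = norm[:, cols]
        mu = y.mean(axis=1, keepdims=True)
        ok = mu[:, 0] > 0
        mu_ok = mu[ok]
        total += nb_loglik(y[ok], np.broadcast_to(mu_ok, y[ok].shape), phi).sum()
        info = y.shape[1] * mu_ok / (1.0 + phi * mu_ok)
        total -= 0.5 * np.log(info).sum()
        # all-zero groups contribute 0 to the likelihood at mu=0
    return total


def estimate_dispersion(norm: pd.DataFrame, condition: pd.Series) -> DispersionEstimate:
    """Common dispersion maximizing the pooled adjusted profile likelihood.

    One dispersion is shared by every protein ("sample dispersion"), which
    suits designs with very few replicates per condition; the Cox-Reid
    adjustment keeps the estimate approximately unbiased at 2-3 replicates.
    """
    conds = pd.unique(condition)
    if max((condition == c).sum() for c in conds) < 2:
        raise ValueError("need >=2 samples in at least one condition")
    mat = norm.to_numpy(dtype=float)
    cols = np.arange(norm.shape[1])
    groups = [cols[(condition == c).to_numpy()] for c in conds]

    def neg_ll(phi: float) -> float:
        return -_profile_loglik(mat, groups, phi)

    res = optimize.minimize_scalar(
        neg_ll, bounds=(0.0, _PHI_UPPER), method="bounded",
        options={"xatol": 1e-8},
    )
    if not res.success:
        grad = (neg_ll(res.x + 1e-6) - neg_ll(res.x - 1e-6)) / 2e-6
        raise NumericError(f"dispersion optimizer did not converge (|grad|={abs(grad):.3g})")
    phi = float(res.x)
    # snap to the Poisson boundary when the optimum sits at it
    if phi < 1e-6 and neg_ll(0.0) <= res.fun + 1e-9:
        phi = 0.0
    logger.info("common dispersion phi=%.4g", phi)
    return DispersionEstimate(phi=phi)


def lrt_differential(
    norm: pd.DataFrame,
    condition: pd.Series,
    dispersion: DispersionEstimate,
) -> pd.DataFrame:
    """Per-protein NB likelihood-ratio test of the condition effect.

    Full model: NB(log link) with a condition effect, i.e. separate bait and
    control means; null model: a single intercept.  With the dispersion held
    at the common estimate both MLEs are group sample means, and the
    statistic 2*(ll_full - ll_null) is referred to chi-squared with 1 df.
    Degenerate all-zero proteins get statistic 0, p = 1, fold-change 0.
    """
    phi = dispersion.phi
    mat = norm.to_numpy(dtype=float)
    is_bait = (condition == "bait").to_numpy()
    bait, ctrl = mat[:, is_bait], mat[:, ~is_bait]
    mean_bait = bait.mean(axis=1)
    mean_ctrl = ctrl.mean(axis=1)
    mean_all = mat.mean(axis=1)

    def ll_at(y: np.ndarray, mu: np.ndarray) -> np.ndarray:
        out = np.zeros(y.shape[0])
        ok = mu > 0
        if ok.any():
            sub = y[ok]
            out[ok] = nb_loglik(
                sub, np.broadcast_to(mu[ok, None], sub.shape), phi
            ).sum(axis=1)
        return out

    ll_full = ll_at(bait, mean_bait) + ll_at(ctrl, mean_ctrl)
    ll_null = ll_at(mat, mean_all)
    stat = np.maximum(2.0 * (ll_full - ll_null), 0.0)
    pval = stats.chi2.sf(stat, df=1)

    log2fc = np.log2((mean_bait + _PSEUDOCOUNT) / (mean_ctrl + _PSEUDOCOUNT))
    degenerate = mean_all == 0
    stat[degenerate] = 0.0
    pval[degenerate] = 1.0
    log2fc[degenerate] = 0.0

    return pd.DataFrame(
        {
            "protein_id": norm.index,
            "mean_bait": mean_bait,
            "mean_control": mean_ctrl,
            "log2fc": log2fc,
            "lrt_stat": stat,
            "pvalue": pval,
        }
    ).set_index("protein_id")


def call_candidates(
    results: pd.DataFrame, alpha: float = 0.05, fc_min: float = 3.0
) -> pd.DataFrame:
    """Benjamini-Hochberg adjust and flag candidates.

    A candidate has adjp < alpha and fold-change > fc_min, both strict
    (fold-change on the pseudo-counted condition means).  The returned
    table is sorted by adjp then symbol; the ``candidate`` column is 0/1.
    """
    out = results.copy()
    if len(out):
        out["adjp"] = multipletests(out["pvalue"].to_numpy(), method="fdr_bh")[1]
    else:
        out["adjp"] = pd.Series(dtype=float)
    fold = 2.0 ** out["log2fc"]
    out["candidate"] = ((out["adjp"] < alpha) & (fold > fc_min)).astype(int)
    out = out.sort_values(["adjp", "protein_id"], kind="mergesort")
    n_cand = int(out["candidate"].sum())
    logger.info("called %d candidates of %d tested proteins", n_cand, len(out))
    return out


def candidate_list(results: pd.DataFrame) -> list[str]:
    """Candidate symbols in the table's (adjp, symbol) order."""
    return list(results.index[results["candidate"] == 1])


def overlap_stats(
    set_a: set[str], set_b: set[str], universe_size: int
) -> dict[str, float | bool]:
    """Odds ratio and chi-squared p for the overlap of two sets in a universe.

    Builds the 2x2 in/out contingency table.  Haldane's 0.5 correction is
    applied to the odds ratio only when a zero cell occurs (flagged in the
    output); the chi-squared test uses no continuity correction.
    """
    set_a, set_b = set(set_a), set(set_b)
    union = len(set_a | set_b)
    if universe_size < union:
        raise ValueError(f"universe size {universe_size} < union size {union}")
    both = len(set_a & set_b)
    only_a = len(set_a) - both
    only_b = len(set_b) - both
    neither = universe_size - union
    table = np.array([[both, only_a], [only_b, neither]], dtype=float)
    corrected = bool((table == 0).any())
    t = table + 0.5 if corrected else table
    odds_ratio = (t[0, 0] * t[1, 1]) / (t[0, 1] * t[1, 0])
    chi2_stat, p, _, _ = stats.chi2_contingency(table, correction=False)
    return {
        "odds_ratio": float(odds_ratio),
        "chi2_stat": float(chi2_stat),
        "pvalue": float(p),
        "haldane_corrected": corrected,
        "overlap": both,
    }
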