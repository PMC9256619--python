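"""Artifact checks for the co-occurrence analysis.

Two nulls: (1) a temporal-autocorrelation check asking how often
independent random-walk time series masquerade as significant
co-occurrences when replicate series are pooled the way the real plots
and weeks are pooled; (2) a spatial (dispersal-limitation) attribution
that flags network edges whose correlation does not survive partialling
out the plot coordinates.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from scipy.stats import t as tdist

from . import synth
from .correlations import bh_fdr, spearman_records

logger = logging.getLogger(__name__)

__all__ = [
    "autocorrelation_null",
    "partial_spearman",
    "spatial_link_attribution",
]


def autocorrelation_null(
    n_taxa: int = 6,
    n_timepoints: int = 6,
    n_replicates: int = 6,
    n_iters: int = 20,
    rho_min: float = 0.6,
    q_max: float = 0.05,
    seed: int = 0,
) -> dict:
    """Count spurious significant pairs among independent random walks.

    Per iteration: simulate ``n_replicates`` Gaussian random walks of
    ``n_timepoints`` steps for each taxon, pool the replicate x timepoint
    observations per taxon (as replicate plots and weeks are pooled in the
    real analysis), compute all pairwise Spearman correlations, and count
    pairs passing the network edge criteria (rho > rho_min, BH q < q_max).
    The drought configuration is 6 walks of 6 points (36 observations,
    15 pairs); the rewetting configuration uses 8 points.
    """
    if n_timepoints < 2:
        raise ValueError("random-walk series need at least 2 timepoints")
    if n_iters < 1:
        raise ValueError("need at least 1 iteration")
    if not (0 <= q_max <= 1) or rho_min < 0:
        raise ValueError("invalid significance criteria")
    seeds = np.random.SeedSequence(seed).generate_state(n_iters) % (2**31)
    counts = []
    for it in range(n_iters):
        walks = synth.generate_random_walks(
            n_taxa, n_timepoints, n_replicates, seed=int(seeds[it])
        )
        pooled = walks.pivot_table(
            index=["replicate", "t"], columns="taxon", values="value"
        )
        records = spearman_records(pooled)
        sig = (records["rho"] > rho_min) & (records["q"] < q_max)
        counts.append(int(sig.sum()))
    n_pairs = n_taxa * (n_taxa - 1) // 2
    return {
        "config": {
            "n_taxa": n_taxa,
            "n_timepoints": n_timepoints,
            "n_replicates": n_replicates,
            "n_iters": n_iters,
            "rho_min": rho_min,
            "q_max": q_max,
            "n_pairs": n_pairs,
        },
        "counts": counts,
        "median": float(np.median(counts)),
        "max": int(max(counts)),
    }


def partial_spearman(
    x: np.ndarray, y: np.ndarray, covariates: np.ndarray
) -> tuple[float, float]:
    """Partial rank correlation of x and y controlling for covariates.

    Ranks all variables, residualizes the ranks of x and y on the ranked
    covariates (with intercept) by least squares, and correlates the
    residuals.  p-value from the t approximation on n - 2 - k degrees of
    freedom, k the number of covariates.
    """
    x = rankdata(np.asarray(x, float))
    y = rankdata(np.asarray(y, float))
    cov = np.column_stack(
        [np.ones(len(x))] + [rankdata(c) for c in np.asarray(covariates, float).T]
    )
    k = cov.shape[1] - 1
    rx = x - cov @ np.linalg.lstsq(cov, x, rcond=None)[0]
    ry = y - cov @ np.linalg.lstsq(cov, y, rcond=None)[0]
    denom = np.sqrt((rx**2).sum() * (ry**2).sum())
    if denom == 0:
        return 0.0, 1.0
    r = float((rx * ry).sum() / denom)
    df = len(x) - 2 - k
    if df <= 0:
        return r, 1.0
    r_ = min(max(r, -0.999999), 0.999999)
    t = r_ * np.sqrt(df / (1 - r_**2))
    return r, float(2 * tdist.sf(abs(t), df))


def spatial_link_attribution(
    table: pd.DataFrame,
    metadata: pd.DataFrame,
    net,
    rho_min: float = 0.6,
    q_max: float = 0.05,
) -> dict | None:
    """Fraction of network edges attributable to spatial structure.

    For each edge, the partial Spearman correlation of the two taxa is
    computed controlling for the plot coordinates (x, y).  An edge is
    spatially driven when its marginal correlation met the network
    criteria but the partial correlation does not (partial rho <= rho_min
    or partial BH-q >= q_max over the tested edges).  Returns None on an
    empty network.
    """
    if net.number_of_edges() == 0:
        logger.warning("spatial_link_attribution: empty network")
        return None
    coords = metadata.loc[table.index, ["x", "y"]].to_numpy(float)
    if np.allclose(coords.std(axis=0), 0):
        raise ValueError("constant plot coordinates: no spatial signal possible")
    rows = []
    for u, v in sorted(net.edges):
        r, p = partial_spearman(
            table[u].to_numpy(float), table[v].to_numpy(float), coords
        )
        rows.append({"taxon_a": u, "taxon_b": v, "partial_rho": r, "partial_p": p})
    edges = pd.DataFrame(rows)
    edges["partial_q"] = bh_fdr(edges["partial_p"].to_numpy())
    edges["spatially_driven"] = ~(
        (edges["partial_rho"] > rho_min) & (edges["partial_q"] < q_max)
    )
    frac = float(edges["spatially_driven"].mean())
    return {
        "n_edges": len(edges),
        "n_spatial": int(edges["spatially_driven"].sum()),
        "fraction_spatial": frac,
        "edges": edges,
    }
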