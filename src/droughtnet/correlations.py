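"""All-correlation analysis: Spearman matrices over taxa, BH-FDR, link-class
partition (bacterium-bacterium, fungus-fungus, bacterium-fungus), summary
statistics, and a stratified permutation contrast for the stress-gradient
prediction that positive associations become relatively more frequent under
stress.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import spearmanr
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "spearman_records",
    "bh_fdr",
    "partition_link_classes",
    "summarize",
    "sgh_contrast",
]


def spearman_records(table: pd.DataFrame, method: str = "spearman") -> pd.DataFrame:
    """All pairwise taxon correlations as a tidy record set.

    One record per unordered taxon pair: rho (Pearson correlation of
    mid-ranks), the t-approximation p-value on n-2 degrees of freedom, and
    the BH-FDR q-value over all pairs.  Taxa with fewer than two distinct
    values have undefined rank correlations; their records are dropped and
    logged.  ``method="pearson"`` is available as an option.
    """
    n, m = table.shape
    if n < 4:
        raise ValueError("need at least 4 samples for correlation analysis")
    if m < 2:
        raise ValueError("need at least 2 taxa")
    values = table.to_numpy(float)
    constant = np.array([len(np.unique(col)) < 2 for col in values.T])
    if constant.any():
        logger.warning(
            "dropping %d constant taxa from correlation analysis: %s",
            constant.sum(), table.columns[constant].tolist()[:10],
        )
    keep = table.columns[~constant]
    values = values[:, ~constant]
    if values.shape[1] < 2:
        raise ValueError("fewer than 2 non-constant taxa")
    if method == "spearman":
        rho, p = spearmanr(values)
    elif method == "pearson":
        from scipy.stats import t as tdist

        rho = np.corrcoef(values, rowvar=False)
        with np.errstate(divide="ignore", invalid="ignore"):
            tstat = rho * np.sqrt((n - 2) / (1 - rho**2))
        p = 2 * tdist.sf(np.abs(tstat), n - 2)
    else:
        raise ValueError(f"unknown method {method!r}")
    if values.shape[1] == 2:  # spearmanr returns scalars for two columns
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
        p = np.array([[0.0, float(p)], [float(p), 0.0]])
    iu = np.triu_indices(values.shape[1], k=1)
    records = pd.DataFrame(
        {
            "taxon_a": keep.to_numpy()[iu[0]],
            "taxon_b": keep.to_numpy()[iu[1]],
            "rho": rho[iu],
            "p": p[iu],
        }
    )
    bad = records["rho"].isna()
    if bad.any():
        logger.warning("dropping %d undefined correlation records", bad.sum())
        records = records.loc[~bad].reset_index(drop=True)
    records["q"] = bh_fdr(records["p"].to_numpy())
    return records


def bh_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values with monotonicity, capped at 1."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def partition_link_classes(
    records: pd.DataFrame, kingdoms: pd.Series
) -> pd.DataFrame:
    """Tag each record BB, FF or BF from its endpoints' kingdoms."""
    taxa = pd.unique(
        np.concatenate([records["taxon_a"].to_numpy(), records["taxon_b"].to_numpy()])
    )
    unknown = [t for t in taxa if t not in kingdoms.index]
    if unknown:
        raise ValueError(f"taxa with unknown kingdom: {unknown[:10]}")
    ka = kingdoms.loc[records["taxon_a"]].to_numpy()
    kb = kingdoms.loc[records["taxon_b"]].to_numpy()
    out = records.copy()
    out["link_class"] = np.where(
        ka == kb, np.where(ka == "bacteria", "BB", "FF"), "BF"
    )
    return out


def summarize(records: pd.DataFrame) -> dict:
    """Combined / positive / negative correlation summary.

    Negative mean is reported multiplied by -1 so its magnitude is
    directly comparable to the positive mean.  rho == 0 counts as
    non-positive.  Empty positive or negative subsets yield None.
    """
    if records.empty:
        raise ValueError("empty record set")
    rho = records["rho"].to_numpy()
    pos, neg = rho[rho > 0], rho[rho < 0]
    return {
        "n_pairs": int(rho.size),
        "mean_combined": float(rho.mean()),
        "mean_positive": float(pos.mean()) if pos.size else None,
        "mean_negative_x_minus1": float(-neg.mean()) if neg.size else None,
        "fraction_positive": float(pos.size / rho.size),
        "n_positive": int(pos.size),
        "n_negative": int(neg.size),
    }


def _class_stats(values: np.ndarray, ka: np.ndarray, kb: np.ndarray) -> dict:
    """Mean rho and fraction positive per link class for one sample subset."""
    rho = spearmanr(values)[0]
    rho = np.atleast_2d(rho)
    iu = np.triu_indices(values.shape[1], k=1)
    r = rho[iu]
    cls = np.where(ka[iu[0]] == kb[iu[1]], np.where(ka[iu[0]] == "bacteria", "BB", "FF"), "BF")
    # note ka == kb arrays are the same kingdom vector indexed differently
    out = {}
    for c in ("BB", "FF", "BF", "ALL"):
        rc = r if c == "ALL" else r[cls == c]
        rc = rc[~np.isnan(rc)]
        if rc.size == 0:
            out[c] = None
        else:
            pos = rc[rc > 0]
            out[c] = (
                float(rc.mean()),
                float((rc > 0).mean()),
                float(pos.mean()) if pos.size else 0.0,
            )
    return out


def sgh_contrast(
    tables: dict[str, tuple[pd.DataFrame, pd.DataFrame]],
    kingdoms: pd.Series,
    n_perm: int = 999,
    seed: int = 0,
) -> pd.DataFrame:
    """Stratified permutation contrast of correlation structure between
    treatments.

    ``tables`` maps each stratum (compartment) to its
    ``(control_table, treatment_table)`` pair of samples x taxa counts on a
    shared taxon set.  For every stratum and link class the observed
    effect is the treatment-minus-control difference in mean Spearman rho
    (combined), in the fraction of positive correlations, and in the mean
    of the positive correlations; the null distribution is
    built by shuffling treatment labels across that stratum's communities
    and recomputing, preserving group sizes.  Two-sided
    p = (1 + #{|null| >= |obs|}) / (n_perm + 1).  A pooled row averages the
    effect over strata, with labels permuted within each stratum.
    """
    if n_perm < 1:
        raise ValueError("need at least 1 permutation")
    rng = np.random.default_rng(seed)
    strata = {}
    for comp, (ctrl, trt) in tables.items():
        if ctrl.shape[0] < 2 or trt.shape[0] < 2:
            logger.warning("sgh_contrast: stratum %s has <2 samples per group; skipped", comp)
            continue
        taxa = ctrl.columns.intersection(trt.columns)
        kk = kingdoms.loc[taxa].to_numpy()
        combined = np.vstack([ctrl[taxa].to_numpy(float), trt[taxa].to_numpy(float)])
        strata[comp] = (combined, ctrl.shape[0], kk)
    if not strata:
        raise ValueError("no usable strata")

    def effects(assignment: dict[str, np.ndarray]) -> dict[tuple[str, str, str], float]:
        eff: dict[tuple[str, str, str], float] = {}
        pooled: dict[tuple[str, str], list[float]] = {}
        for comp, (combined, n_ctrl, kk) in strata.items():
            idx = assignment[comp]
            ctrl_stats = _class_stats(combined[idx[:n_ctrl]], kk, kk)
            trt_stats = _class_stats(combined[idx[n_ctrl:]], kk, kk)
            for c in ("BB", "FF", "BF", "ALL"):
                if ctrl_stats[c] is None or trt_stats[c] is None:
                    continue
                for i, stat in enumerate(
                    ("mean_rho", "fraction_positive", "mean_positive")
                ):
                    d = trt_stats[c][i] - ctrl_stats[c][i]
                    eff[(comp, c, stat)] = d
                    pooled.setdefault((c, stat), []).append(d)
        for (c, stat), vals in pooled.items():
            eff[("pooled", c, stat)] = float(np.mean(vals))
        return eff

    identity = {
        comp: np.arange(combined.shape[0])
        for comp, (combined, _, _) in strata.items()
    }
    observed = effects(identity)
    exceed = {k: 0 for k in observed}
    for _ in range(n_perm):
        perm = {
            comp: rng.permutation(combined.shape[0])
            for comp, (combined, _, _) in strata.items()
        }
        null = effects(perm)
        for k, obs in observed.items():
            if k in null and abs(null[k]) >= abs(obs):
                exceed[k] += 1
    rows = []
    for (comp, cls, stat), obs in observed.items():
        rows.append(
            {
                "stratum": comp,
                "link_class": cls,
                "statistic": stat,
                "effect": obs,
                "direction": "increase" if obs > 0 else ("decrease" if obs < 0 else "none"),
                "p": (1 + exceed[(comp, cls, stat)]) / (n_perm + 1),
                "n_perm": n_perm,
            }
        )
    return pd.DataFrame(rows)
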