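"""Community-composition resistance and resilience statistics.

Resistance to drought is detected per week by comparing Bray-Curtis
dissimilarities of between-group sample pairs (control vs drought) against
within-group pairs (control-control and drought-drought) with a two-sided
unpaired Welch t-test, Bonferroni-adjusted over the weeks tested within one
compartment x kingdom x resolution family.  Resilience after rewetting is
the per-plot-pair drop, relative to the last drought week, of the excess of
between-group over within-group dissimilarity.  Kingdom contrasts compare
the per-pair statistics between bacteria and fungi on the shared plot
pairs.

Pair dissimilarities within a week share samples and are therefore not
independent; as in the procedure this implements, the t-tests ignore that
dependence, and every result row carries a ``dependent_pairs`` caveat flag.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import ttest_ind

__all__ = [
    "bray_curtis",
    "pair_values",
    "between_pair_excess",
    "resistance_test",
    "resistance_table",
    "resilience_pairs",
    "resilience_series",
    "kingdom_contrast",
    "window_kingdom_contrast",
    "dual_resolution_consistency",
]


def bray_curtis(table: pd.DataFrame) -> pd.DataFrame:
    """Bray-Curtis dissimilarity matrix between sample rows.

    BC(u, v) = sum_k |u_k - v_k| / sum_k (u_k + v_k), in [0, 1], zero
    diagonal.  A pair of all-zero samples is undefined and rejected.
    """
    if table.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    zero = table.index[table.sum(axis=1) == 0].tolist()
    if len(zero) >= 2:
        raise ValueError(f"Bray-Curtis undefined for all-zero samples: {zero}")
    d = squareform(pdist(table.to_numpy(float), metric="braycurtis"))
    return pd.DataFrame(d, index=table.index, columns=table.index)


def pair_values(
    D: pd.DataFrame, metadata: pd.DataFrame, week: int
) -> tuple[pd.Series, pd.Series]:
    """Within- and between-group dissimilarities for one week.

    Returns ``(within, between)``: within pairs join two samples of the
    same treatment (control-control or drought-drought), between pairs
    join control and drought.  Series are indexed by frozenset-free
    ``"plotA|plotB"`` keys; between pairs use ``"controlplot|droughtplot"``
    order so they match across kingdoms.
    """
    meta = metadata.loc[metadata["week"] == week]
    samples = [s for s in meta.index if s in D.index]
    within, between = {}, {}
    for a, b in itertools.combinations(samples, 2):
        ta, tb = metadata.loc[a, "treatment"], metadata.loc[b, "treatment"]
        pa, pb = metadata.loc[a, "plot"], metadata.loc[b, "plot"]
        val = D.loc[a, b]
        if ta == tb:
            key = "|".join(sorted((str(pa), str(pb))))
            within[key] = val
        else:
            if ta != "control":
                pa, pb = pb, pa
            between[f"{pa}|{pb}"] = val
    return pd.Series(within, dtype=float), pd.Series(between, dtype=float)


def between_pair_excess(
    D: pd.DataFrame, metadata: pd.DataFrame, week: int
) -> pd.Series:
    """Per between-pair excess dissimilarity d_p = BC_between,p - mean(BC_within)."""
    within, between = pair_values(D, metadata, week)
    if within.empty or between.empty:
        raise ValueError(f"week {week}: missing within or between pairs")
    return between - within.mean()


def resistance_test(D: pd.DataFrame, metadata: pd.DataFrame, week: int) -> dict:
    """Two-sided Welch t-test of between- vs within-group dissimilarity."""
    within, between = pair_values(D, metadata, week)
    if len(within) < 2 or len(between) < 2:
        raise ValueError(f"week {week}: need >= 2 pairs in each class")
    degenerate = within.std() == 0 and between.std() == 0
    if degenerate:
        p = 1.0
    else:
        p = float(ttest_ind(between, within, equal_var=False).pvalue)
    return {
        "week": week,
        "n_within": len(within),
        "n_between": len(between),
        "mean_within": float(within.mean()),
        "mean_between": float(between.mean()),
        "statistic": float(between.mean() - within.mean()),
        "p_raw": p,
        "degenerate": degenerate,
        "dependent_pairs": True,
    }


def resistance_table(
    D: pd.DataFrame,
    metadata: pd.DataFrame,
    weeks: tuple[int, ...],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Resistance tests over a window, Bonferroni-adjusted across its weeks.

    A week is significant (community affected by drought) when the
    adjusted p is below ``alpha`` and mean(between) > mean(within).
    """
    rows = [resistance_test(D, metadata, w) for w in weeks]
    out = pd.DataFrame(rows)
    out["p_bonferroni"] = np.minimum(1.0, out["p_raw"] * len(weeks))
    out["significant"] = (out["p_bonferroni"] < alpha) & (out["statistic"] > 0)
    return out


def resilience_pairs(
    D: pd.DataFrame, metadata: pd.DataFrame, baseline_week: int, week: int
) -> pd.Series:
    """Per matched plot-pair resilience R_p(t) = d_p(baseline) - d_p(t).

    d_p is the between-pair excess over the week's mean within-group
    dissimilarity.  Positive R means the drought community moved back
    toward the control.  Pairs are matched by (control plot, drought plot)
    identity; pairs absent at either week are dropped.
    """
    if baseline_week >= week:
        raise ValueError("baseline week must precede the recovery week")
    base = between_pair_excess(D, metadata, baseline_week)
    now = between_pair_excess(D, metadata, week)
    shared = base.index.intersection(now.index)
    if shared.empty:
        raise ValueError("no matched plot pairs between baseline and recovery week")
    return (base.loc[shared] - now.loc[shared]).rename(f"R_w{week}")


def resilience_series(
    D: pd.DataFrame,
    metadata: pd.DataFrame,
    baseline_week: int = 8,
    recovery_weeks: tuple[int, ...] = tuple(range(9, 18)),
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Resilience per recovery week, with the per-week between-vs-within test.

    Each row carries the mean matched-pair resilience R(t) and the
    between-vs-within t-test at week t (Bonferroni over the recovery
    weeks): a week at which the difference is no longer significant
    indicates recovery of composition.
    """
    rows = []
    for w in recovery_weeks:
        if w <= baseline_week:
            raise ValueError("recovery weeks must follow the baseline week")
        r = resilience_pairs(D, metadata, baseline_week, w)
        row = resistance_test(D, metadata, w)
        row.update(
            {
                "baseline_week": baseline_week,
                "resilience": float(r.mean()),
                "n_matched_pairs": len(r),
            }
        )
        rows.append(row)
    out = pd.DataFrame(rows)
    out["p_bonferroni"] = np.minimum(1.0, out["p_raw"] * len(recovery_weeks))
    out["significant"] = (out["p_bonferroni"] < alpha) & (out["statistic"] > 0)
    return out


def kingdom_contrast(
    bacterial: pd.Series, fungal: pd.Series, mode: str = "resistance"
) -> dict:
    """Two-sided t-test of per-pair statistics between kingdoms.

    For resistance the inputs are per-pair excess dissimilarities d_p (a
    smaller excess = more resistant); for resilience the per-pair R values
    (a larger R = more resilient).  Both kingdoms are compared on the
    intersection of plot-pair identities.
    """
    if mode not in ("resistance", "resilience"):
        raise ValueError(f"unknown mode {mode!r}")
    shared = bacterial.index.intersection(fungal.index)
    if shared.empty:
        raise ValueError("no shared plot pairs between kingdoms")
    b, f = bacterial.loc[shared], fungal.loc[shared]
    if np.allclose(b, f):
        return {"p": 1.0, "direction": None, "n_pairs": len(shared), "mode": mode}
    p = float(ttest_ind(b, f, equal_var=False).pvalue)
    if mode == "resistance":
        direction = "fungi_more_resistant" if f.mean() < b.mean() else "bacteria_more_resistant"
    else:
        direction = "bacteria_more_resilient" if b.mean() > f.mean() else "fungi_more_resilient"
    return {"p": p, "direction": direction, "n_pairs": len(shared), "mode": mode}


def window_kingdom_contrast(
    D_bact: pd.DataFrame,
    meta_bact: pd.DataFrame,
    D_fung: pd.DataFrame,
    meta_fung: pd.DataFrame,
    weeks: tuple[int, ...],
    mode: str = "resistance",
    baseline_week: int = 8,
) -> dict:
    """Kingdom contrast pooled over a window's weeks.

    Concatenates the per-pair statistics (excess dissimilarity for
    resistance, matched-pair R for resilience) across the given weeks,
    keyed by week x plot pair, and contrasts kingdoms on the shared keys.
    Pooling a window is the power-appropriate version of the per-week
    contrast when the question is the overall kingdom asymmetry.
    """
    def collect(D, meta):
        parts = {}
        for w in weeks:
            if mode == "resistance":
                s = between_pair_excess(D, meta, w)
            else:
                s = resilience_pairs(D, meta, baseline_week, w)
            parts.update({f"w{w}|{k}": v for k, v in s.items()})
        return pd.Series(parts, dtype=float)

    return kingdom_contrast(collect(D_bact, meta_bact), collect(D_fung, meta_fung), mode=mode)


def dual_resolution_consistency(
    otu_rows: pd.DataFrame, family_rows: pd.DataFrame
) -> pd.DataFrame:
    """Keep only results robust across OTU- and family-level analyses.

    A week's result is robust iff the significance flag agrees at both
    resolutions and, when significant, the direction (sign of the
    between-minus-within statistic) agrees too.  Non-robust weeks are
    retained with ``robust = False`` and excluded from headline output by
    callers.
    """
    merged = otu_rows.merge(
        family_rows[["week", "significant", "statistic"]],
        on="week",
        suffixes=("", "_family"),
    )
    same_sig = merged["significant"] == merged["significant_family"]
    same_dir = np.sign(merged["statistic"]) == np.sign(merged["statistic_family"])
    merged["robust"] = same_sig & (~merged["significant"] | same_dir)
    return merged
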