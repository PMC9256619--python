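"""Count-table I/O and preparation: rarefaction, family aggregation,
occurrence filtering, and splitting samples into analysis windows.

Count tables are pandas DataFrames with samples as rows and taxa as
columns, integer counts >= 0, and unique identifiers on both axes.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "read_count_table",
    "write_count_table",
    "read_metadata",
    "read_taxonomy",
    "validate_count_table",
    "rarefy",
    "aggregate_family",
    "filter_occurrence",
    "split_windows",
    "DROUGHT_WEEKS",
    "REWET_WEEKS",
]

# Analysis windows: the drought contrast uses the six unwatered weeks; the
# rewetting contrast uses the eight weeks after watering resumes, giving
# 36 and 48 communities per treatment x compartment at 6 plots.
DROUGHT_WEEKS = tuple(range(3, 9))
REWET_WEEKS = tuple(range(10, 18))


def validate_count_table(table: pd.DataFrame) -> None:
    """Raise ValueError if the table violates the count-table contract."""
    if table.index.duplicated().any():
        dups = table.index[table.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicated sample identifiers: {dups}")
    if table.columns.duplicated().any():
        dups = table.columns[table.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicated taxon identifiers: {dups}")
    values = table.to_numpy()
    if values.size:
        if not np.issubdtype(values.dtype, np.number):
            raise ValueError("non-numeric cells in count table")
        if (values < 0).any():
            r, c = np.argwhere(values < 0)[0]
            raise ValueError(
                f"negative count at sample {table.index[r]!r}, taxon {table.columns[c]!r}"
            )
        if not np.allclose(values, np.rint(values)):
            r, c = np.argwhere(~np.isclose(values, np.rint(values)))[0]
            raise ValueError(
                f"non-integer count at sample {table.index[r]!r}, taxon {table.columns[c]!r}"
            )


def read_count_table(path: str | Path, format: str = "tsv") -> pd.DataFrame:
    """Read a samples x taxa count table.

    TSV dialect: tab-separated, header row of taxon ids, first column the
    sample id.  Sample order is preserved from the file.
    """
    if format == "biom":
        raise NotImplementedError(
            "BIOM input is not supported; convert to TSV (samples x taxa)"
        )
    if format != "tsv":
        raise ValueError(f"unknown format {format!r}")
    with open(path) as fh:  # pandas mangles duplicate headers; check raw
        header = fh.readline().rstrip("\n").split("\t")[1:]
    dup = sorted({h for h in header if header.count(h) > 1})
    if dup:
        raise ValueError(f"duplicated taxon identifiers: {dup}")
    table = pd.read_csv(path, sep="\t", index_col=0)
    validate_count_table(table)
    return table.astype(np.int64)


def write_count_table(table: pd.DataFrame, path: str | Path) -> None:
    validate_count_table(table)
    table.to_csv(path, sep="\t")


def read_metadata(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", index_col=0)
    required = {"treatment", "plot", "compartment", "week"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"metadata missing columns: {sorted(missing)}")
    return meta


def read_taxonomy(path: str | Path) -> pd.DataFrame:
    tax = pd.read_csv(path, sep="\t", index_col=0, keep_default_na=False)
    if "kingdom" not in tax.columns:
        raise ValueError("taxonomy table needs a 'kingdom' column")
    if "amf" in tax.columns:
        tax["amf"] = tax["amf"].astype(str).str.lower().isin(("true", "1", "yes"))
    return tax


def rarefy(table: pd.DataFrame, depth: int = 10_000, seed: int = 0) -> pd.DataFrame:
    """Subsample each sample's reads to a common depth, without replacement.

    Samples whose total is below ``depth`` are dropped (and logged; the
    dropped ids are also available as ``result.attrs['dropped_samples']``).
    Each retained row sums exactly to ``depth``.  Deterministic given
    ``seed``.
    """
    if depth <= 0:
        raise ValueError("rarefaction depth must be positive")
    validate_count_table(table)
    totals = table.sum(axis=1)
    keep = totals >= depth
    dropped = table.index[~keep].tolist()
    if dropped:
        logger.warning(
            "rarefy: dropping %d sample(s) below depth %d: %s",
            len(dropped), depth, dropped,
        )
    rng = np.random.default_rng(seed)
    out = np.empty((int(keep.sum()), table.shape[1]), dtype=np.int64)
    counts = table.loc[keep].to_numpy(np.int64)
    for i, row in enumerate(counts):
        if row.sum() == depth:
            out[i] = row
        else:
            # exact multivariate hypergeometric = without-replacement draw
            out[i] = rng.multivariate_hypergeometric(row, depth)
    result = pd.DataFrame(out, index=table.index[keep], columns=table.columns)
    result.attrs["dropped_samples"] = dropped
    return result


def aggregate_family(table: pd.DataFrame, taxonomy: pd.DataFrame) -> pd.DataFrame:
    """Sum OTU columns within each family; per-sample totals are conserved.

    Every taxon must appear in the taxonomy; an empty family label is
    treated as "unassigned".
    """
    validate_count_table(table)
    missing = table.columns.difference(taxonomy.index)
    if len(missing):
        raise ValueError(f"taxa missing from taxonomy: {missing.tolist()}")
    fam = taxonomy.loc[table.columns, "family"].astype(str)
    fam = fam.where(fam.str.len() > 0, "unassigned")
    agg = table.T.groupby(fam.values).sum().T
    agg.index.name = table.index.name
    agg.columns.name = "family"
    return agg


def filter_occurrence(table: pd.DataFrame, min_communities: int = 8) -> pd.DataFrame:
    """Drop taxa with nonzero counts in fewer than ``min_communities`` samples."""
    if min_communities < 1:
        raise ValueError("min_communities must be >= 1")
    occ = (table > 0).sum(axis=0)
    kept = table.loc[:, occ >= min_communities]
    if kept.shape[1] == 0:
        logger.warning("filter_occurrence: no taxa pass the threshold")
    return kept


def split_windows(
    table: pd.DataFrame,
    metadata: pd.DataFrame,
    drought_weeks: tuple[int, ...] = DROUGHT_WEEKS,
    rewet_weeks: tuple[int, ...] = REWET_WEEKS,
    kingdom: str = "bacteria",
) -> dict[str, tuple[pd.DataFrame, pd.DataFrame]]:
    """Split samples into the drought and rewetting analysis windows.

    Each window holds control plus (re)droughted samples of its weeks.
    Fungal leaf samples of weeks 1-8 are excluded (non-fungal reads
    dominate early leaves); exclusions are logged and recorded in
    ``attrs['excluded_samples']`` of the drought-window table.
    """
    missing = table.index.difference(metadata.index)
    if len(missing):
        raise ValueError(f"samples without metadata: {missing.tolist()}")
    meta = metadata.loc[table.index]
    out: dict[str, tuple[pd.DataFrame, pd.DataFrame]] = {}
    for label, weeks in (("drought", drought_weeks), ("rewetting", rewet_weeks)):
        mask = meta["week"].isin(weeks)
        excluded: list[str] = []
        if kingdom == "fungi":
            leaf_early = (meta["compartment"] == "leaf") & (meta["week"] <= 8)
            excluded = table.index[mask & leaf_early].tolist()
            if excluded:
                logger.warning(
                    "split_windows: excluding %d early fungal leaf sample(s)",
                    len(excluded),
                )
            mask &= ~leaf_early
        sub = table.loc[mask]
        sub.attrs["excluded_samples"] = excluded
        out[label] = (sub, meta.loc[mask])
    return out
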