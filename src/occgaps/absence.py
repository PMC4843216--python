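"""Per-cell survey-history classification and covariate attachment.

A *data-absent* cell holds at least one record of any species before the
cutoff year but none after it — an ambiguity between local extinction and
survey effort having lapsed.  Cells are cross-classified against per-cell
covariates (biogeographic realm, land cover, protected-area overlap, mean
human influence index, country) supplied as a precomputed table; polygon
overlay happens upstream of this package.
"""

from __future__ import annotations

import logging
from typing import Optional

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "DATA_ABSENT",
    "SURVEYED_BOTH",
    "POST_ONLY",
    "NEVER",
    "classify_cells",
    "attach_covariates",
    "summarize_by_country",
]

DATA_ABSENT = "data_absent"
SURVEYED_BOTH = "surveyed_both"
POST_ONLY = "post_only"
NEVER = "never"  # representable, never produced from a record table

LANDCOVER_LEVELS = ("forest", "grassland_shrubland", "anthrome")


def classify_cells(gridded: pd.DataFrame) -> pd.DataFrame:
    """Classify every recorded cell by its survey history.

    Parameters
    ----------
    gridded : DataFrame
        Per-record rows with at least ``ix, iy, period`` (period in
        {'pre', 'post'}), as produced by :func:`occgaps.records.grid_records`.

    Returns
    -------
    DataFrame with columns ``ix, iy, status`` — one row per cell with at
    least one record.  Statuses are mutually exclusive and exhaustive:
    *data_absent* (pre records only), *surveyed_both*, *post_only*.
    """
    if gridded.empty:
        return pd.DataFrame(columns=["ix", "iy", "status"])
    flags = (
        gridded.assign(
            has_pre=gridded["period"].eq("pre"),
            has_post=gridded["period"].eq("post"),
        )
        .groupby(["ix", "iy"], as_index=False)[["has_pre", "has_post"]]
        .any()
    )
    status = pd.Series(POST_ONLY, index=flags.index)
    status[flags["has_pre"] & ~flags["has_post"]] = DATA_ABSENT
    status[flags["has_pre"] & flags["has_post"]] = SURVEYED_BOTH
    out = flags[["ix", "iy"]].copy()
    out["status"] = status
    return out.sort_values(["ix", "iy"], ignore_index=True)


def attach_covariates(
    statuses: pd.DataFrame, covariates: pd.DataFrame
) -> tuple[pd.DataFrame, int]:
    """Join per-cell covariates onto classified cells.

    Cells without a covariate row (e.g. coastal cells whose centroid falls
    over the sea) are dropped and counted; a covariate table with duplicate
    cells is rejected.

    Returns ``(joined, n_dropped)``.
    """
    dup = covariates.duplicated(subset=["ix", "iy"])
    if dup.any():
        bad = covariates.loc[dup, ["ix", "iy"]].drop_duplicates().values.tolist()
        raise ValueError(f"duplicate covariate rows for cells: {bad}")
    unknown = set(covariates["landcover"].dropna()) - set(LANDCOVER_LEVELS)
    if unknown:
        raise ValueError(f"unknown land-cover classes: {sorted(unknown)}")
    joined = statuses.merge(covariates, on=["ix", "iy"], how="inner")
    n_dropped = len(statuses) - len(joined)
    if n_dropped:
        logger.info("%d recorded cells lacked covariates and were dropped", n_dropped)
    return joined, n_dropped


def summarize_by_country(
    joined: pd.DataFrame, country_covariates: Optional[pd.DataFrame] = None
) -> pd.DataFrame:
    """Per-country counts of surveyed and data-absent cells.

    ``n_surveyed`` counts every cell with at least one record of any period;
    ``n_data_absent`` the subset with pre-cutoff records only.  Countries
    with no recorded cells are simply absent.  If ``country_covariates``
    (columns ``country, log_gdp_pc, gpi_rank, english_official``) is given,
    it is joined on.
    """
    tab = (
        joined.assign(is_absent=joined["status"].eq(DATA_ABSENT))
        .groupby("country", as_index=False)
        .agg(n_data_absent=("is_absent", "sum"), n_surveyed=("status", "size"))
    )
    tab["n_data_absent"] = tab["n_data_absent"].astype(int)
    if country_covariates is not None:
        tab = tab.merge(country_covariates, on="country", how="left")
    return tab.sort_values("country", ignore_index=True)
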