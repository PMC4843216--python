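"""Species richness and extent of occurrence under four data-absence readings.

For every (species, cell) pair with at least one record, the post-cutoff
status is resolved under four alternative assumptions about cells that hold
old records but no recent ones:

I    optimistic — every species recorded historically is still extant;
II   model-based — recorded post-cutoff, or (recorded only pre-cutoff and
     the effort-aware persistence model calls it extant);
III  effort-informed pessimistic — recorded post-cutoff, or recorded
     pre-cutoff in a cell where *no* species has any post-cutoff record
     (someone looked and saw other species: count it locally extinct);
IV   pessimistic — extant only if recorded post-cutoff.

The extant sets are nested: I ⊇ II and I ⊇ III ⊇ IV (II and III are not
ordered in general).  Richness is the per-cell count of extant species; the
extent of occurrence (EOO) is the area of the convex hull of the centroids
of a species' extant cells, computed in the equal-area projection plane so
planar area is ground area.
"""

from __future__ import annotations

import pandas as pd
from shapely.geometry import MultiPoint

from .grid import GridSpec, centroids_of

__all__ = [
    "ASSUMPTIONS",
    "extant_under",
    "extant_matrix",
    "richness_per_cell",
    "eoo_area",
    "eoo_table",
]

ASSUMPTIONS = ("I", "II", "III", "IV")


def _pair_flags(gridded: pd.DataFrame) -> pd.DataFrame:
    """Per (species, cell): any-pre / any-post record flags, plus the
    cell-level any-species-post flag."""
    pairs = (
        gridded.assign(
            pre=gridded["period"].eq("pre"), post=gridded["period"].eq("post")
        )
        .groupby(["species_id", "ix", "iy"], as_index=False)[["pre", "post"]]
        .any()
    )
    cell_post = (
        pairs.groupby(["ix", "iy"], as_index=False)["post"]
        .any()
        .rename(columns={"post": "cell_has_post"})
    )
    return pairs.merge(cell_post, on=["ix", "iy"])


def extant_under(
    gridded: pd.DataFrame,
    persistence: pd.DataFrame,
    assumption: str,
) -> pd.DataFrame:
    """Extant/extinct call for every recorded (species, cell) pair.

    ``persistence`` is the table from
    :func:`occgaps.persistence.persistence_table`; it is only consulted for
    assumption II, and must not mention pairs absent from the records.

    Returns columns ``species_id, ix, iy, extant``.
    """
    if assumption not in ASSUMPTIONS:
        raise ValueError(f"unknown assumption {assumption!r}")
    pairs = _pair_flags(gridded)
    key = ["species_id", "ix", "iy"]
    if not persistence.empty:
        merged = persistence[key].merge(pairs[key], on=key, how="left", indicator=True)
        orphans = merged[merged["_merge"] == "left_only"]
        if len(orphans):
            raise ValueError(
                "persistence table mentions (species, cell) pairs with no "
                f"records: {orphans[key].values.tolist()[:5]}"
            )
    if assumption == "I":
        extant = pd.Series(True, index=pairs.index)
    elif assumption == "IV":
        extant = pairs["post"]
    elif assumption == "III":
        extant = pairs["post"] | (pairs["pre"] & ~pairs["cell_has_post"])
    else:  # II
        calls = persistence[key + ["extant_call"]] if not persistence.empty else None
        if calls is not None:
            pairs = pairs.merge(calls, on=key, how="left")
            # pre-only pairs missing from the persistence table carry no
            # usable series; the posterior equals the prior, i.e. extant
            model_call = (
                pairs["extant_call"].astype("boolean").fillna(True).astype(bool)
            )
        else:
            model_call = pd.Series(True, index=pairs.index)
        extant = pairs["post"] | (~pairs["post"] & model_call)
    out = pairs[key].copy()
    out["extant"] = extant.to_numpy()
    return out


def extant_matrix(gridded: pd.DataFrame, persistence: pd.DataFrame) -> pd.DataFrame:
    """All four assumption columns side by side: ``extant_I .. extant_IV``."""
    key = ["species_id", "ix", "iy"]
    out = None
    for a in ASSUMPTIONS:
        col = extant_under(gridded, persistence, a).rename(
            columns={"extant": f"extant_{a}"}
        )
        out = col if out is None else out.merge(col, on=key)
    return out


def richness_per_cell(matrix: pd.DataFrame) -> pd.DataFrame:
    """Extant-species count per cell under each assumption.

    Every cell appearing in the matrix is reported, including cells whose
    richness drops to zero under the pessimistic assumptions.
    """
    cols = [f"extant_{a}" for a in ASSUMPTIONS if f"extant_{a}" in matrix.columns]
    rich = matrix.groupby(["ix", "iy"], as_index=False)[cols].sum()
    rich = rich.rename(columns={c: c.replace("extant", "richness") for c in cols})
    for c in rich.columns[2:]:
        rich[c] = rich[c].astype(int)
    return rich.sort_values(["ix", "iy"], ignore_index=True)


def eoo_area(cells: pd.DataFrame, spec: GridSpec = GridSpec()) -> float:
    """Convex-hull area (km²) of the centroids of a set of cells.

    Fewer than three non-collinear centroids span no area and return 0.
    """
    if len(cells) < 3:
        return 0.0
    x, y = centroids_of(cells["ix"].to_numpy(), cells["iy"].to_numpy(), spec)
    return float(MultiPoint(list(zip(x, y))).convex_hull.area)


def eoo_table(matrix: pd.DataFrame, spec: GridSpec = GridSpec()) -> pd.DataFrame:
    """Per species × assumption EOO area, and as a percentage of assumption I.

    Because every assumption's extant set is contained in assumption I's,
    the percentage lies in [0, 100]; when both areas are zero (a range too
    small to span a hull either way) the percentage is reported as 100.
    """
    rows = []
    for sp, sp_rows in matrix.groupby("species_id"):
        area_i = eoo_area(sp_rows[sp_rows["extant_I"]], spec)
        for a in ASSUMPTIONS:
            area = eoo_area(sp_rows[sp_rows[f"extant_{a}"]], spec)
            if area_i > 0:
                pct = 100.0 * area / area_i
            else:
                pct = 100.0 if area == 0 else float("nan")
            rows.append((sp, a, area, pct))
    return pd.DataFrame(
        rows, columns=["species_id", "assumption", "area_km2", "pct_of_optimistic"]
    )
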