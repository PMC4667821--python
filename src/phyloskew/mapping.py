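"""Rasterize occurrences to 1x1-degree cells, rank, prioritize and summarize.

Cell (i, j) covers latitudes [i, i+1) and longitudes [j, j+1): coordinates
are floored to integer indices, duplicate presences collapse to one, and
there is no wraparound merging at the antimeridian.  Cells with fewer than 11
species (the "more than 10" filter) are excluded from skew mapping because of
the small-sample bias of the effective-sampling estimate.

Percentile ranks use the mid-rank convention (average of fraction-below and
fraction-at-or-below, times 100).  "Top 5%" priority selection flags a cell
for an index when its value reaches the empirical 95th-percentile threshold
(computed with the 'higher' quantile rule so that exactly 5% of distinct
values qualify); ties at the threshold are included.  The phylogenetic
priority set is the union of the PD, AvTD and PE flags; the full priority
set adds species richness.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import json

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .bd import BirthDeathParams
from .diversity import MIN_SR_FOR_SKEW, community_indices
from .tree import TimeTree

__all__ = [
    "GridError",
    "OccurrenceGrid",
    "PriorityMap",
    "LatitudeProfile",
    "build_grid",
    "filter_cells",
    "percentile_rank",
    "compute_cell_indices",
    "add_percentile_ranks",
    "select_priority",
    "correlate_indices",
    "latitude_profile",
    "INDEX_COLUMNS",
]

#: stable output column order of the cell index table
INDEX_COLUMNS = [
    "cell_lat",
    "cell_lon",
    "sr",
    "pd",
    "avtd",
    "rho0",
    "rhoE",
    "ps",
    "pe",
    "flags",
]


class GridError(ValueError):
    """Malformed occurrence records."""


@dataclass(frozen=True)
class OccurrenceGrid:
    """Presence sets of species per integer (lat, lon) cell."""

    cells: dict[tuple[int, int], frozenset[str]]
    n_dropped_unknown: int = 0
    dropped_species: frozenset[str] = frozenset()

    def __len__(self) -> int:
        return len(self.cells)

    @property
    def species(self) -> frozenset[str]:
        out: set[str] = set()
        for members in self.cells.values():
            out |= members
        return frozenset(out)


def build_grid(
    records: pd.DataFrame | str | Path,
    known_species: Iterable[str] | None = None,
) -> OccurrenceGrid:
    """Rasterize species/latitude/longitude rows to 1x1-degree presence cells.

    ``records`` is a DataFrame or a CSV path with a header row naming
    ``species``, ``latitude`` and ``longitude`` ('#' comment lines allowed).
    Coordinates must lie in [-90, 90) x [-180, 180); offending rows are
    reported by row number.  When ``known_species`` is given (normally the
    reference tree's tip set), records for other species are dropped with a
    count and a warning.
    """
    if not isinstance(records, pd.DataFrame):
        records = pd.read_csv(records, comment="#")
    required = {"species", "latitude", "longitude"}
    missing = required - set(records.columns)
    if missing:
        raise GridError(f"records are missing columns: {sorted(missing)}")

    lat = records["latitude"].to_numpy(dtype=float)
    lon = records["longitude"].to_numpy(dtype=float)
    bad = ~((lat >= -90) & (lat < 90) & (lon >= -180) & (lon < 180))
    if bad.any():
        rows = np.flatnonzero(bad)[:10].tolist()
        raise GridError(
            f"{int(bad.sum())} records have out-of-range coordinates "
            f"(row numbers {rows}{'...' if bad.sum() > 10 else ''})"
        )

    species = records["species"].astype(str)
    n_dropped = 0
    dropped: set[str] = set()
    if known_species is not None:
        known = frozenset(known_species)
        unknown_mask = ~species.isin(known).to_numpy()
        n_dropped = int(unknown_mask.sum())
        if n_dropped:
            dropped = set(species[unknown_mask])
            warnings.warn(
                f"dropped {n_dropped} records of {len(dropped)} species absent "
                "from the reference tree",
                stacklevel=2,
            )
            keep = ~unknown_mask
            species = species[keep]
            lat = lat[keep]
            lon = lon[keep]

    cells: dict[tuple[int, int], set[str]] = {}
    for sp, la, lo in zip(species, np.floor(lat).astype(int), np.floor(lon).astype(int)):
        cells.setdefault((la, lo), set()).add(sp)
    return OccurrenceGrid(
        cells={k: frozenset(v) for k, v in cells.items()},
        n_dropped_unknown=n_dropped,
        dropped_species=frozenset(dropped),
    )


def filter_cells(grid: OccurrenceGrid, min_sr: int = MIN_SR_FOR_SKEW) -> OccurrenceGrid:
    """Retain exactly the cells with at least ``min_sr`` species."""
    return OccurrenceGrid(
        cells={k: v for k, v in grid.cells.items() if len(v) >= min_sr},
        n_dropped_unknown=grid.n_dropped_unknown,
        dropped_species=grid.dropped_species,
    )


def percentile_rank(values: Sequence[float]) -> np.ndarray:
    """Mid-rank percentiles in [0, 100].

    Each value's rank is the average of the fraction of values strictly below
    and the fraction at-or-below, times 100 — i.e. ties get the mid-rank, and
    the result is invariant under any strictly increasing transform.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 1:
        raise ValueError("need at least one value")
    return 100.0 * (rankdata(values, method="average") - 0.5) / values.size


def compute_cell_indices(
    grid: OccurrenceGrid,
    tree: TimeTree,
    meta_params: BirthDeathParams,
    s_meta: int | None = None,
    min_sr_skew: int = MIN_SR_FOR_SKEW,
    fit_seed: int = 0,
) -> pd.DataFrame:
    """Per-cell index table: SR, PD, AvTD, ρ_0, ρ̂_E, PS, PE and fit flags.

    ``meta_params`` carries the step-one (λ̂, μ̂) estimates; every cell's
    ρ̂_E is fitted from the divergence times of its induced subtree.  Rows
    are ordered by cell index for determinism; columns follow
    :data:`INDEX_COLUMNS`.
    """
    rows = []
    for (la, lo) in sorted(grid.cells):
        members = grid.cells[(la, lo)]
        ci = community_indices(
            tree,
            members,
            meta_params,
            s_meta=s_meta,
            min_sr_skew=min_sr_skew,
            fit_seed=fit_seed,
        )
        rows.append(
            {
                "cell_lat": la,
                "cell_lon": lo,
                "sr": ci.sr,
                "pd": ci.pd,
                "avtd": ci.avtd,
                "rho0": ci.rho0,
                "rhoE": ci.rhoE,
                "ps": ci.ps,
                "pe": ci.pe,
                "flags": ci.flags,
            }
        )
    return pd.DataFrame(rows, columns=INDEX_COLUMNS)


def add_percentile_ranks(
    table: pd.DataFrame, columns: Sequence[str] = ("sr", "pd", "avtd", "pe")
) -> pd.DataFrame:
    """Append ``<col>_pct`` mid-rank percentile columns (NaN rows excluded)."""
    out = table.copy()
    for col in columns:
        vals = out[col]
        mask = vals.notna()
        pct = np.full(len(out), np.nan)
        if mask.any():
            pct[mask.to_numpy()] = percentile_rank(vals[mask].to_numpy())
        out[f"{col}_pct"] = pct
    return out


@dataclass(frozen=True)
class PriorityMap:
    """Per-cell priority flags and the derived union sets.

    ``flags`` has one row per cell with boolean columns ``pd_top``,
    ``avtd_top``, ``pe_top`` and ``sr_top``.  The phylogenetic priority set
    is the union of the first three; the full priority set adds ``sr_top``.
    """

    flags: pd.DataFrame
    thresholds: dict[str, float]
    quantile: float

    def _cells(self, columns: Sequence[str]) -> frozenset[tuple[int, int]]:
        mask = self.flags[list(columns)].any(axis=1)
        return frozenset(
            (int(r.cell_lat), int(r.cell_lon))
            for r in self.flags[mask].itertuples()
        )

    @property
    def phylogenetic_priority(self) -> frozenset[tuple[int, int]]:
        return self._cells(("pd_top", "avtd_top", "pe_top"))

    @property
    def full_priority(self) -> frozenset[tuple[int, int]]:
        return self._cells(("pd_top", "avtd_top", "pe_top", "sr_top"))

    def to_csv(self, path: str | Path) -> None:
        self.flags.to_csv(path, index=False)

    def to_geojson(self, path: str | Path) -> None:
        """Write the flagged 1x1-degree squares as GeoJSON polygons."""
        features = []
        flagged = self.flags[
            self.flags[["pd_top", "avtd_top", "pe_top", "sr_top"]].any(axis=1)
        ]
        for r in flagged.itertuples():
            la, lo = int(r.cell_lat), int(r.cell_lon)
            ring = [[lo, la], [lo + 1, la], [lo + 1, la + 1], [lo, la + 1], [lo, la]]
            features.append(
                {
                    "type": "Feature",
                    "geometry": {"type": "Polygon", "coordinates": [ring]},
                    "properties": {
                        "cell_lat": la,
                        "cell_lon": lo,
                        "pd_top": bool(r.pd_top),
                        "avtd_top": bool(r.avtd_top),
                        "pe_top": bool(r.pe_top),
                        "sr_top": bool(r.sr_top),
                    },
                }
            )
        Path(path).write_text(
            json.dumps({"type": "FeatureCollection", "features": features})
        )


def select_priority(
    table: pd.DataFrame,
    quantile: float = 0.95,
    min_sr: int = MIN_SR_FOR_SKEW,
) -> PriorityMap:
    """Flag cells in the top (1 - quantile) tail of PD, AvTD, PE and SR.

    A cell is flagged for an index when its value is >= the empirical
    ``quantile`` threshold of that index across cells ('higher' quantile
    rule; ties at the threshold included).  Only cells passing the species
    filter participate.  A constant index column degenerates to flagging
    every cell; a warning is emitted.
    """
    if len(table) == 0:
        raise ValueError("empty index table")
    eligible = table[table["sr"] >= min_sr]
    if len(eligible) == 0:
        raise ValueError(f"no cells with at least {min_sr} species")
    flags = eligible[["cell_lat", "cell_lon"]].copy()
    thresholds: dict[str, float] = {}
    for col in ("pd", "avtd", "pe", "sr"):
        vals = eligible[col].to_numpy(dtype=float)
        if np.isnan(vals).any():
            raise ValueError(f"column {col!r} has NaN entries among eligible cells")
        thr = float(np.quantile(vals, quantile, method="higher"))
        if np.min(vals) == np.max(vals):
            warnings.warn(
                f"index {col!r} is constant across cells; all cells flagged",
                stacklevel=2,
            )
        thresholds[col] = thr
        flags[f"{col}_top"] = vals >= thr
    return PriorityMap(
        flags=flags.reset_index(drop=True), thresholds=thresholds, quantile=quantile
    )


def correlate_indices(
    table: pd.DataFrame, columns: Sequence[str] = ("sr", "pd", "avtd", "pe")
) -> pd.DataFrame:
    """Pairwise Pearson correlations of the index columns (unit diagonal).

    A zero-variance column yields NaN off-diagonal entries and a warning; the
    diagonal is forced to 1.
    """
    if len(table) < 3:
        raise ValueError("need at least 3 cells to correlate")
    sub = table[list(columns)].astype(float)
    degenerate = [c for c in columns if sub[c].nunique(dropna=True) <= 1]
    if degenerate:
        warnings.warn(
            f"zero-variance columns {degenerate}: correlations undefined",
            stacklevel=2,
        )
    corr = sub.corr(method="pearson")
    np.fill_diagonal(corr.values, 1.0)
    return corr


@dataclass(frozen=True)
class LatitudeProfile:
    """Binned means plus LOWESS trends of one index against latitude."""

    column: str
    binned: pd.DataFrame  # bin_center, mean, count (signed latitude)
    lowess_signed: np.ndarray  # (k, 2) array of (latitude, smoothed value)
    lowess_abs: np.ndarray  # (k, 2) array of (|latitude|, smoothed value)


def latitude_profile(
    table: pd.DataFrame,
    column: str,
    bin_width: float = 10.0,
    lat_column: str = "cell_lat",
) -> LatitudeProfile:
    """Mean of ``column`` per latitude band, with LOWESS smooths.

    Bands are ``bin_width``-degree intervals of signed latitude (cell
    centers); empty bands simply do not appear.  LOWESS (span 2/3, tricube
    weights) is fitted against signed latitude and against |latitude|
    separately.
    """
    from statsmodels.nonparametric.smoothers_lowess import lowess

    sub = table[[lat_column, column]].dropna()
    if len(sub) == 0:
        raise ValueError("no finite values to profile")
    lat = sub[lat_column].to_numpy(dtype=float) + 0.5  # cell centers
    y = sub[column].to_numpy(dtype=float)
    bin_idx = np.floor(lat / bin_width) * bin_width + bin_width / 2.0
    binned = (
        pd.DataFrame({"bin_center": bin_idx, column: y})
        .groupby("bin_center", as_index=False)
        .agg(mean=(column, "mean"), count=(column, "size"))
    )
    smooth_signed = lowess(y, lat, frac=2.0 / 3.0, return_sorted=True)
    smooth_abs = lowess(y, np.abs(lat), frac=2.0 / 3.0, return_sorted=True)
    return LatitudeProfile(
        column=column,
        binned=binned,
        lowess_signed=np.asarray(smooth_signed),
        lowess_abs=np.asarray(smooth_abs),
    )
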