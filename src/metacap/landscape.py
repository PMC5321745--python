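"""Patch tables, distance geometry, habitat quality and occupancy histories.

The landscape is the immutable substrate of every later stage: a table of
habitat patches (planar km coordinates, area in ha, four habitat-quality
variables) plus the full pairwise Euclidean distance matrix.  Occupancy
surveys are stored as patch x year arrays with an explicit missing-data
mask, because partial survey coverage is a first-class feature of the data
this package is built for.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

PATCH_COLUMNS = [
    "id",
    "x_km",
    "y_km",
    "area_ha",
    "host_plantago",
    "host_veronica",
    "pct_dry",
    "pct_low",
    "pct_grazed",
]

_QUALITY_PCT = ["pct_dry", "pct_low", "pct_grazed"]


@dataclass(frozen=True)
class Landscape:
    """An ordered set of habitat patches with pairwise distances.

    Parameters
    ----------
    patches
        One row per patch with the columns in :data:`PATCH_COLUMNS`;
        percentages stored as fractions in [0, 1].
    distance_matrix
        Symmetric Euclidean distance matrix in km, zero diagonal.
    """

    patches: pd.DataFrame
    distance_matrix: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        _validate_patches(self.patches)
        d = np.asarray(self.distance_matrix, dtype=float)
        n = len(self.patches)
        if d.shape != (n, n):
            raise ValueError(f"distance matrix shape {d.shape} != ({n}, {n})")
        if not np.allclose(d, d.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.diag(d) != 0):
            raise ValueError("distance matrix has nonzero diagonal")

    @property
    def n_patches(self) -> int:
        return len(self.patches)

    @property
    def ids(self) -> np.ndarray:
        return self.patches["id"].to_numpy()

    @property
    def areas(self) -> np.ndarray:
        return self.patches["area_ha"].to_numpy(dtype=float)

    @property
    def coords(self) -> np.ndarray:
        return self.patches[["x_km", "y_km"]].to_numpy(dtype=float)

    @classmethod
    def from_patches(cls, patches: pd.DataFrame) -> "Landscape":
        """Build a landscape, computing distances from the coordinates."""
        patches = patches.reset_index(drop=True)
        xy = patches[["x_km", "y_km"]].to_numpy(dtype=float)
        d = squareform(pdist(xy)) if len(patches) > 1 else np.zeros((len(patches),) * 2)
        return cls(patches=patches, distance_matrix=d)

    def index_of(self, ids) -> np.ndarray:
        """Positional indices of the given patch ids (error on unknown ids)."""
        lookup = pd.Index(self.patches["id"])
        idx = lookup.get_indexer(np.asarray(ids))
        if np.any(idx < 0):
            missing = np.asarray(ids)[idx < 0]
            raise KeyError(f"unknown patch ids: {list(pd.unique(missing))[:10]}")
        return idx


@dataclass(frozen=True)
class QualityIndex:
    """Composite habitat quality score per patch.

    ``q_tilde`` is the mean of four min-max rescaled components
    (host plants, percentage dry, percentage low, minus percentage grazed),
    each in [-1, 1], so the composite is bounded in [-1, 1].  ``components``
    holds the rescaled columns for diagnostics.
    """

    q_tilde: np.ndarray
    components: pd.DataFrame = field(repr=False)


@dataclass(frozen=True)
class OccupancyHistory:
    """Patch x year presence/absence with missing mask and larval-group counts.

    ``occupied`` and ``n_groups`` are float arrays with NaN marking
    unsurveyed patch-years; the two masks are identical by construction.
    """

    years: np.ndarray
    occupied: np.ndarray
    n_groups: np.ndarray | None = None

    def __post_init__(self) -> None:
        occ = np.asarray(self.occupied, dtype=float)
        if occ.ndim != 2 or occ.shape[1] != len(self.years):
            raise ValueError("occupied must be patch x year")
        vals = occ[~np.isnan(occ)]
        if vals.size and not np.all(np.isin(vals, (0.0, 1.0))):
            raise ValueError("occupied entries must be 0, 1 or NaN")
        if self.n_groups is not None:
            ng = np.asarray(self.n_groups, dtype=float)
            if ng.shape != occ.shape:
                raise ValueError("n_groups shape mismatch")
            if not np.array_equal(np.isnan(ng), np.isnan(occ)):
                raise ValueError("missing masks of occupied and n_groups differ")
            both = ~np.isnan(ng)
            if np.any((ng[both] >= 1) & (occ[both] == 0)):
                raise ValueError("n_groups >= 1 in a patch-year marked unoccupied")

    @property
    def observed(self) -> np.ndarray:
        """Boolean mask of surveyed patch-years."""
        return ~np.isnan(np.asarray(self.occupied, dtype=float))

    @property
    def n_years(self) -> int:
        return len(self.years)


@dataclass(frozen=True)
class OccupancyIncidence:
    """Per-patch fraction of observed years occupied (p-bar).

    ``defined`` is False for patches never surveyed; their ``p_bar`` is NaN
    and they must be excluded from downstream fits.
    """

    p_bar: np.ndarray
    n_observed_years: np.ndarray

    @property
    def defined(self) -> np.ndarray:
        return self.n_observed_years > 0


def _validate_patches(patches: pd.DataFrame) -> None:
    missing = [c for c in PATCH_COLUMNS if c not in patches.columns]
    if missing:
        raise ValueError(f"patch table missing columns: {missing}")
    ids = patches["id"]
    dup = ids[ids.duplicated()]
    if len(dup):
        raise ValueError(f"duplicate patch id {dup.iloc[0]!r}")
    if np.any(patches["area_ha"].to_numpy(dtype=float) <= 0):
        bad = patches.loc[patches["area_ha"] <= 0, "id"].iloc[0]
        raise ValueError(f"non-positive area for patch {bad!r}")
    for col in ("host_plantago", "host_veronica"):
        v = patches[col].to_numpy(dtype=float)
        if not np.all(np.isin(v, (0, 1, 2, 3))):
            raise ValueError(f"{col} must be an ordinal score in {{0,1,2,3}}")
    for col in _QUALITY_PCT:
        v = patches[col].to_numpy(dtype=float)
        if np.any((v < 0) | (v > 1)):
            raise ValueError(f"{col} outside [0, 1] after unit conversion")


def load_patch_table(path, percent_unit: str = "fraction") -> Landscape:
    """Read ``patches.csv`` and return a validated :class:`Landscape`.

    Parameters
    ----------
    path
        CSV with header; columns as in :data:`PATCH_COLUMNS`.
    percent_unit
        ``"fraction"`` if the pct_* columns are already in [0, 1],
        ``"percent"`` if they are 0-100 and should be divided by 100.
    """
    if percent_unit not in ("fraction", "percent"):
        raise ValueError("percent_unit must be 'fraction' or 'percent'")
    df = pd.read_csv(path)
    missing = [c for c in PATCH_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"patch table missing columns: {missing}")
    df = df[PATCH_COLUMNS].copy()
    if percent_unit == "percent":
        for col in _QUALITY_PCT:
            v = df[col].to_numpy(dtype=float)
            if np.any((v < 0) | (v > 100)):
                raise ValueError(f"{col} outside [0, 100] in file")
            df[col] = v / 100.0
    return Landscape.from_patches(df)


def _rescale_pm1(v: np.ndarray) -> np.ndarray:
    """Min-max rescale to [-1, 1]; constant columns map to 0."""
    lo, hi = np.min(v), np.max(v)
    if hi == lo:
        return np.zeros_like(v, dtype=float)
    return 2.0 * (v - lo) / (hi - lo) - 1.0


def quality_index(landscape: Landscape, host_combine: str = "max") -> QualityIndex:
    """Composite habitat quality Q-tilde per patch.

    Four components — host-plant abundance, percentage dry, percentage low
    and percentage grazed — are each min-max rescaled across the patch set
    to [-1, 1]; the grazing component's sign is reversed because heavy
    grazing means low quality.  The composite is the mean of the four, so
    it stays within [-1, 1] and is monotone in each raw variable.

    ``host_combine`` selects how the two host-species ordinal scores merge
    into the single host component: ``"max"`` (the butterfly needs at least
    one host; default) or ``"sum"``.
    """
    p = landscape.patches
    if len(p) < 2:
        warnings.warn("single-patch landscape: quality components undefined, set to 0")
    if host_combine == "max":
        host = np.maximum(p["host_plantago"].to_numpy(dtype=float),
                          p["host_veronica"].to_numpy(dtype=float))
    elif host_combine == "sum":
        host = (p["host_plantago"].to_numpy(dtype=float)
                + p["host_veronica"].to_numpy(dtype=float))
    else:
        raise ValueError("host_combine must be 'max' or 'sum'")
    comps = pd.DataFrame(
        {
            "host": _rescale_pm1(host),
            "dry": _rescale_pm1(p["pct_dry"].to_numpy(dtype=float)),
            "low": _rescale_pm1(p["pct_low"].to_numpy(dtype=float)),
            "grazed": -_rescale_pm1(p["pct_grazed"].to_numpy(dtype=float)),
        }
    )
    return QualityIndex(q_tilde=comps.mean(axis=1).to_numpy(), components=comps)


def load_occupancy(path, landscape: Landscape) -> OccupancyHistory:
    """Read long-format ``occupancy.csv`` (patch_id, year, occupied, n_groups).

    Empty ``occupied``/``n_groups`` fields mean the patch was not surveyed
    that year.  Patches absent from the file in a given year are missing
    for that year as well.
    """
    df = pd.read_csv(path)
    for col in ("patch_id", "year"):
        if col not in df.columns:
            raise ValueError(f"occupancy table missing column {col!r}")
    years = np.sort(df["year"].unique())
    n, t = landscape.n_patches, len(years)
    occ = np.full((n, t), np.nan)
    ngr = np.full((n, t), np.nan)
    pidx = landscape.index_of(df["patch_id"].to_numpy())
    yidx = np.searchsorted(years, df["year"].to_numpy())
    occ_vals = pd.to_numeric(df["occupied"], errors="coerce").to_numpy(dtype=float)
    grp_vals = (pd.to_numeric(df["n_groups"], errors="coerce").to_numpy(dtype=float)
                if "n_groups" in df.columns else np.where(np.isnan(occ_vals), np.nan, 0.0))
    # a row with an empty occupied field is an unsurveyed patch-year
    seen = ~np.isnan(occ_vals)
    occ[pidx[seen], yidx[seen]] = occ_vals[seen]
    ngr[pidx[seen], yidx[seen]] = np.where(np.isnan(grp_vals[seen]), 0.0, grp_vals[seen])
    return OccupancyHistory(years=years, occupied=occ, n_groups=ngr)


def save_occupancy(history: OccupancyHistory, landscape: Landscape, path) -> None:
    """Write a history back to long format (missing entries as empty fields)."""
    n, t = history.occupied.shape
    rows = pd.DataFrame(
        {
            "patch_id": np.repeat(landscape.ids, t),
            "year": np.tile(history.years, n),
            "occupied": history.occupied.ravel(),
            "n_groups": (history.n_groups.ravel() if history.n_groups is not None
                         else np.full(n * t, np.nan)),
        }
    )
    rows.to_csv(path, index=False)


def incidence_from_history(history: OccupancyHistory) -> OccupancyIncidence:
    """Fraction of observed years each patch was occupied.

    Missing years are excluded from numerator and denominator alike; a
    patch with no observed years gets NaN and ``defined=False``.
    """
    occ = np.asarray(history.occupied, dtype=float)
    n_obs = np.sum(~np.isnan(occ), axis=1)
    with np.errstate(invalid="ignore"):
        p_bar = np.where(n_obs > 0, np.nansum(occ, axis=1) / np.maximum(n_obs, 1), np.nan)
    return OccupancyIncidence(p_bar=p_bar, n_observed_years=n_obs)
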