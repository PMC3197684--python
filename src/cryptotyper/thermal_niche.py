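"""Water-column thermal niche from core-top assemblages and gridded
temperatures.

The bipolarity question — does the cold-water genotype also live in the
northern subpolar ocean? — is addressed indirectly: abundances of the
morpho-species in core-top (surface sediment) samples are compared with the
thermal structure of the overlying water column. The analysis comprises

* one-pass inverse-angular-distance interpolation of missing values in a
  1-degree gridded temperature climatology (13 standard depths, 0-500 m),
* a correlation-matrix PCA of the 13 depth temperatures (PC1 is a mean
  thermal state of the upper water column; PC2 a surface/subsurface
  contrast),
* a least-squares regression of bin-mean PC1 on 1 degC SST bins,
* occurrence statistics of a focal species across localities, and
* the genotype boundary temperature estimated from plankton-tow stations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: The 13 standard depths (m) of the temperature climatology.
DEPTHS = (0, 10, 20, 30, 50, 75, 100, 125, 150, 250, 300, 400, 500)

TEMP_COLUMNS = [f"t{d}m" for d in DEPTHS]


class ThermalNicheError(ValueError):
    pass


@dataclass
class CoreTopSample:
    """One core-top locality: morpho-species counts plus the 13
    depth-temperatures of the overlying water column (NaN = missing)."""

    locality_id: str
    lat: float
    lon: float
    species_counts: dict[str, int]
    temps: np.ndarray  # 13 values, aligned with DEPTHS

    def __post_init__(self) -> None:
        self.temps = np.asarray(self.temps, dtype=float)
        if self.temps.shape != (13,):
            raise ThermalNicheError("temps must hold the 13 standard depths")
        if any(v < 0 for v in self.species_counts.values()):
            raise ThermalNicheError("negative species count")


# ---------------------------------------------------------------------------
# Gridded field and interpolation
# ---------------------------------------------------------------------------
# Grid convention: 1-degree cells identified by the integer (lat, lon) of
# their south-west corner; values refer to the cell center (lat+0.5,
# lon+0.5). Longitude wraps at +/-180.


def _cell_center(lat: int, lon: int) -> tuple[float, float]:
    return lat + 0.5, lon + 0.5


def angular_distance_deg(lat1, lon1, lat2, lon2) -> float:
    """Great-circle central angle (degrees) between two points."""
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dl = np.radians(lon2 - lon1)
    cosang = np.sin(p1) * np.sin(p2) + np.cos(p1) * np.cos(p2) * np.cos(dl)
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def _neighbors(lat: int, lon: int):
    for dlat in (-1, 0, 1):
        for dlon in (-1, 0, 1):
            if dlat == dlon == 0:
                continue
            nlon = lon + dlon
            if nlon < -180:
                nlon += 360
            elif nlon >= 180:
                nlon -= 360
            yield lat + dlat, nlon


def grid_to_lookup(grid: pd.DataFrame) -> dict:
    """Index a long-format grid (lat, lon, depth, temp) for cell lookup."""
    return {
        (int(r.lat), int(r.lon), int(r.depth)): r.temp
        for r in grid.itertuples(index=False)
    }


def interpolate_missing(lookup: dict, target_cell: tuple[int, int], depth: int,
                        flat_weights: bool = False) -> float | None:
    """Fill one missing locality x depth value from its <= 8 surrounding
    1-degree cells (a 3 x 3 degree neighbourhood).

    The fill is a weighted average of the non-missing neighbour values with
    weight 1 / angular distance between cell centers (great-circle central
    angle), so at high latitude the meridional neighbours weigh more than
    the zonal ones. ``flat_weights`` switches to planar 1 / (1 or sqrt(2))
    degree weights. Returns None when all 8 neighbours are missing.
    """
    lat, lon = target_cell
    clat, clon = _cell_center(lat, lon)
    num = den = 0.0
    found = False
    for nlat, nlon in _neighbors(lat, lon):
        v = lookup.get((nlat, nlon, depth))
        if v is None or (isinstance(v, float) and np.isnan(v)):
            continue
        if flat_weights:
            d = np.hypot(nlat - lat, min(abs(nlon - lon), 360 - abs(nlon - lon)))
        else:
            d = angular_distance_deg(clat, clon, *(_cell_center(nlat, nlon)))
        w = 1.0 / d
        num += w * v
        den += w
        found = True
    if not found:
        return None
    return num / den


def fill_missing_temps(samples: list[CoreTopSample], grid: pd.DataFrame,
                       flat_weights: bool = False):
    """One-pass fill of missing locality x depth temperatures.

    Only originally observed grid values feed the interpolation (no
    cascading from previously filled cells). Returns the list of
    (locality_id, depth) couples left unfilled.
    """
    lookup = grid_to_lookup(grid)
    unfilled = []
    for s in samples:
        cell = (int(np.floor(s.lat)), int(np.floor(s.lon)))
        for k, d in enumerate(DEPTHS):
            if np.isnan(s.temps[k]):
                v = interpolate_missing(lookup, cell, d, flat_weights=flat_weights)
                if v is None:
                    unfilled.append((s.locality_id, d))
                else:
                    s.temps[k] = v
    return unfilled


# ---------------------------------------------------------------------------
# Correlation-matrix PCA
# ---------------------------------------------------------------------------


@dataclass
class ThermalPCAResult:
    scores: pd.DataFrame        # localities x components
    loadings: pd.DataFrame      # depths x components (correlation loadings)
    eigenvalues: np.ndarray
    variance_explained: np.ndarray  # percent, sums to 100

    @property
    def pc1(self) -> np.ndarray:
        return self.scores["PC1"].to_numpy()


def samples_to_temp_frame(samples: list[CoreTopSample]) -> pd.DataFrame:
    return pd.DataFrame(
        [s.temps for s in samples],
        index=[s.locality_id for s in samples],
        columns=TEMP_COLUMNS,
    )


def thermal_pca(temps: pd.DataFrame) -> ThermalPCAResult:
    """PCA of the correlation matrix of the 13 depth-temperature variables.

    Variables are z-scored; eigenvalues therefore sum to 13 and
    ``variance_explained`` to 100. PC1 is oriented to correlate positively
    with the depth-mean temperature (so high PC1 = warm water column);
    higher components are oriented so the deepest-depth loading is
    non-negative, which for typical fields makes PC2 the conventional
    "cold-surface / warm-subsurface positive" contrast.
    """
    X = temps.to_numpy(dtype=float)
    if X.shape[0] < X.shape[1] + 1:
        raise ThermalNicheError("need more localities than variables")
    if np.isnan(X).any():
        raise ThermalNicheError("missing temperatures: run fill_missing_temps first")
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = temps.columns[np.flatnonzero(sd == 0)[0]]
        raise ThermalNicheError(f"constant temperature variable {bad!r}")
    Z = (X - X.mean(axis=0)) / sd
    R = np.corrcoef(Z, rowvar=False)
    eigval, eigvec = np.linalg.eigh(R)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    scores = Z @ eigvec
    # orientation
    mean_t = X.mean(axis=1)
    if np.corrcoef(scores[:, 0], mean_t)[0, 1] < 0:
        eigvec[:, 0] *= -1
        scores[:, 0] *= -1
    for k in range(1, eigvec.shape[1]):
        ref = eigvec[-1, k] if eigvec[-1, k] != 0 else eigvec[np.argmax(np.abs(eigvec[:, k])), k]
        if ref < 0:
            eigvec[:, k] *= -1
            scores[:, k] *= -1
    comp = [f"PC{i + 1}" for i in range(eigvec.shape[1])]
    # correlation loadings: eigvec scaled by sqrt(eigenvalue)
    loadings = eigvec * np.sqrt(np.clip(eigval, 0, None))
    return ThermalPCAResult(
        scores=pd.DataFrame(scores, index=temps.index, columns=comp),
        loadings=pd.DataFrame(loadings, index=temps.columns, columns=comp),
        eigenvalues=eigval,
        variance_explained=100.0 * eigval / eigval.sum(),
    )


# ---------------------------------------------------------------------------
# PC1 vs SST regression, occurrence statistics, boundary temperature
# ---------------------------------------------------------------------------


@dataclass
class BinnedRegression:
    slope: float
    intercept: float
    bins: pd.DataFrame  # bin_center, mean_pc1, sd_pc1, n


def pc1_sst_regression(pc1, sst, sst_range=(0.0, 25.0)) -> BinnedRegression:
    """Least-squares regression of bin-mean PC1 on 1 degC SST bins.

    Localities are binned by floor(SST); the regression uses bin centers as
    the predictor, over bins whose center lies inside ``sst_range``. Empty
    bins are skipped.
    """
    pc1 = np.asarray(pc1, dtype=float)
    sst = np.asarray(sst, dtype=float)
    lo = np.floor(sst).astype(int)
    rows = []
    for b in np.unique(lo):
        center = b + 0.5
        if not sst_range[0] <= center <= sst_range[1]:
            continue
        sel = lo == b
        vals = pc1[sel]
        rows.append(
            {
                "bin_center": center,
                "mean_pc1": float(vals.mean()),
                "sd_pc1": float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
                "n": int(vals.size),
            }
        )
    if len(rows) < 3:
        raise ThermalNicheError("need at least 3 non-empty SST bins")
    bins = pd.DataFrame(rows).sort_values("bin_center").reset_index(drop=True)
    slope, intercept = np.polyfit(bins["bin_center"], bins["mean_pc1"], 1)
    return BinnedRegression(float(slope), float(intercept), bins)


@dataclass
class OccurrenceStats:
    n_localities: int
    n_present: int
    pct_present: float
    mean_rel_abundance_pct: float  # among presence localities
    ci_low_pct: float
    ci_high_pct: float


def occurrence_stats(samples: list[CoreTopSample], focal_species: str) -> OccurrenceStats:
    """Presence and relative-abundance statistics of a focal morpho-species.

    Relative abundance = focal count / total assemblage count per locality;
    the interval is the 2.5/97.5 percentile range over presence localities.
    Localities with a zero total count are excluded.
    """
    rels = []
    n_used = 0
    for s in samples:
        if focal_species not in s.species_counts:
            raise ThermalNicheError(f"{focal_species!r} absent from the count table")
        total = sum(s.species_counts.values())
        if total == 0:
            continue
        n_used += 1
        rels.append(s.species_counts[focal_species] / total)
    rels = np.asarray(rels)
    present = rels[rels > 0]
    if present.size == 0:
        return OccurrenceStats(n_used, 0, 0.0, float("nan"), float("nan"), float("nan"))
    lo, hi = np.percentile(present, [2.5, 97.5])
    return OccurrenceStats(
        n_localities=n_used,
        n_present=int(present.size),
        pct_present=100.0 * present.size / n_used,
        mean_rel_abundance_pct=100.0 * float(present.mean()),
        ci_low_pct=100.0 * float(lo),
        ci_high_pct=100.0 * float(hi),
    )


@dataclass
class BoundaryEstimate:
    warm_edge_type2: float  # max SST over Type II stations
    cold_edge_type1: float  # min SST over Type I stations
    overlap: bool           # sympatry detected


def boundary_temperature(stations) -> BoundaryEstimate:
    """Thermal boundary between the genotypes from station occupancy.

    The warm edge of the cold genotype (Type II) is the maximum SST over
    Type II-bearing stations; the cold edge of Type I the minimum SST over
    Type I stations. Under strict allopatry the interval
    [warm_edge, cold_edge] brackets the front; overlap (warm edge above
    cold edge) flags sympatry.
    """
    sst1 = [s.sst for s in stations if s.count("I") > 0]
    sst2 = [s.sst for s in stations if s.count("II") > 0]
    if not sst1 or not sst2:
        missing = "I" if not sst1 else "II"
        raise ThermalNicheError(f"genotype {missing} absent from all stations")
    warm2, cold1 = max(sst2), min(sst1)
    return BoundaryEstimate(warm2, cold1, warm2 > cold1)


# ---------------------------------------------------------------------------
# Core-top table I/O
# ---------------------------------------------------------------------------


def coretops_to_frame(samples: list[CoreTopSample]) -> pd.DataFrame:
    species = sorted({sp for s in samples for sp in s.species_counts})
    rows = []
    for s in samples:
        row = {"locality_id": s.locality_id, "lat": s.lat, "lon": s.lon}
        for sp in species:
            row[sp] = s.species_counts.get(sp, 0)
        for col, v in zip(TEMP_COLUMNS, s.temps):
            row[col] = v
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_coretops(df: pd.DataFrame) -> list[CoreTopSample]:
    species = [c for c in df.columns
               if c not in {"locality_id", "lat", "lon"} and c not in TEMP_COLUMNS]
    out = []
    for _, row in df.iterrows():
        out.append(
            CoreTopSample(
                locality_id=str(row["locality_id"]),
                lat=float(row["lat"]),
                lon=float(row["lon"]),
                species_counts={sp: int(row[sp]) for sp in species},
                temps=np.array([row[c] for c in TEMP_COLUMNS], dtype=float),
            )
        )
    return out
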