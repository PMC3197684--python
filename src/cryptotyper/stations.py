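"""Plankton-tow sampling stations: coordinates, CTD profiles, genotype counts.

A station is one oceanographic sampling point with a sea-surface temperature
(defined as the 10 m temperature when a CTD profile exists), an optional
0-250 m temperature/fluorescence profile, and the number of individuals
assigned to each genotype at that station. Stations are shared between the
sampling-sufficiency and thermal-niche analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd


@dataclass
class StationRecord:
    station_id: str
    lat: float
    lon: float
    sst: float
    cruise: str = ""
    side: str = ""  # "north" / "south" of the front (warm / cold side)
    genotype_counts: dict[str, int] = field(default_factory=dict)
    #: CTD profile: DataFrame with depth, temperature, fluorescence columns
    profile: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.profile is not None and len(self.profile) > 0:
            depths = self.profile["depth"].to_numpy()
            if not (depths[1:] > depths[:-1]).all():
                raise ValueError(f"station {self.station_id}: depths not increasing")

    @property
    def n_genotyped(self) -> int:
        return sum(self.genotype_counts.values())

    def count(self, genotype: str) -> int:
        return int(self.genotype_counts.get(genotype, 0))


STATION_COLUMNS = ["station_id", "cruise", "lat", "lon", "sst", "side",
                   "n_type1", "n_type2"]


def stations_to_frame(stations) -> pd.DataFrame:
    rows = [
        {
            "station_id": s.station_id,
            "cruise": s.cruise,
            "lat": s.lat,
            "lon": s.lon,
            "sst": s.sst,
            "side": s.side,
            "n_type1": s.count("I"),
            "n_type2": s.count("II"),
        }
        for s in stations
    ]
    return pd.DataFrame(rows, columns=STATION_COLUMNS)


def frame_to_stations(df: pd.DataFrame, profiles: pd.DataFrame | None = None):
    """Inverse of :func:`stations_to_frame`.

    ``profiles`` is an optional long-format table with columns
    station_id, depth, temperature, fluorescence.
    """
    stations = []
    for _, row in df.iterrows():
        prof = None
        if profiles is not None:
            sub = profiles[profiles["station_id"] == row["station_id"]]
            if len(sub):
                prof = sub[["depth", "temperature", "fluorescence"]].reset_index(drop=True)
        stations.append(
            StationRecord(
                station_id=str(row["station_id"]),
                cruise=str(row.get("cruise", "")),
                lat=float(row["lat"]),
                lon=float(row["lon"]),
                sst=float(row["sst"]),
                side=str(row.get("side", "")),
                genotype_counts={"I": int(row["n_type1"]), "II": int(row["n_type2"])},
                profile=prof,
            )
        )
    return stations


def profiles_to_frame(stations) -> pd.DataFrame:
    frames = []
    for s in stations:
        if s.profile is not None:
            f = s.profile.copy()
            f.insert(0, "station_id", s.station_id)
            frames.append(f)
    if not frames:
        return pd.DataFrame(columns=["station_id", "depth", "temperature", "fluorescence"])
    return pd.concat(frames, ignore_index=True)
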