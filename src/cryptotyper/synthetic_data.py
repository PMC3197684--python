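"""Synthetic inputs with the statistical structure the pipeline assumes.

Every stage of the analysis can be exercised offline through four
generators that emulate, at the published study's scale:

* a two-genotype rDNA clone library (ITS ~1000 bp, SSU ~620 bp) whose
  between-genotype divergence exceeds the within-genotype and
  intra-individual clone divergences, and whose Type I ITS amplicons carry
  an engineered CCWGG restriction site (absent from Type II) at ~40% of the
  amplicon length — reproducing the diagnostic two-band digest;
* plankton-tow stations whose genotype occupancy is strictly allopatric
  across an SST front (8-12 degC by default), with CTD-like temperature and
  fluorescence profiles;
* a 1-degree gridded 13-depth temperature climatology with a configurable
  fraction of missing locality x depth values, plus core-top assemblages of
  37 morpho-species whose focal-species abundance declines with the mean
  water-column temperature beyond a transitional optimum;
* two morphometric populations (154 north / 152 south by default) whose
  discrimination is significant but weak, calibrated so a two-group
  discriminant analysis classifies roughly two thirds of specimens
  correctly.

Sequence evolution is a uniform (Jukes-Cantor-like) substitution process
from a random ancestor: only the ordering and magnitude of distances
matter downstream, not the substitution model. All outputs are
bit-reproducible for a given seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .seqalign import SequenceRecord
from .stations import StationRecord
from .thermal_niche import DEPTHS, TEMP_COLUMNS, CoreTopSample

_BASES = np.array(list("ACGT"))


class SimConfigError(ValueError):
    pass


@dataclass
class SimConfig:
    """Study-scale simulation parameters.

    Divergences are expected p-distances (substitutions/site) at the level
    they name: ``inter_type_divergence`` between clones of different
    genotypes, ``intra_type_divergence`` between an individual and its
    genotype ancestor, ``intra_individual_divergence`` between a clone and
    its individual. SSU sequences evolve at ``ssu_rate_scale`` times the
    ITS rates.
    """

    seed: int = 0
    n_individuals_per_type: int = 20
    clones_per_individual: int = 2
    amplicon_length_its: int = 1000
    amplicon_length_ssu: int = 620
    inter_type_divergence: float = 0.14
    intra_type_divergence: float = 0.02
    intra_individual_divergence: float = 0.005
    ssu_rate_scale: float = 0.12
    n_stations: int = 49
    front_sst_low: float = 8.0
    front_sst_high: float = 12.0
    sst_range: tuple[float, float] = (1.0, 24.0)
    grid_extent: int = 10       # longitudinal extent (deg) of the 1-deg grid
    n_localities: int = 1265
    missing_cell_fraction: float = 0.0327
    n_specimens_north: int = 154
    n_specimens_south: int = 152
    morpho_effect_size: float = 0.82  # standardized mean difference
    motif_position_fraction: float = 0.4

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        d_inter, d_intra, d_ind = (
            self.inter_type_divergence,
            self.intra_type_divergence,
            self.intra_individual_divergence,
        )
        if not d_inter > d_intra >= d_ind >= 0:
            raise SimConfigError(
                "divergences must satisfy inter > intra_type >= intra_individual >= 0"
            )
        for name in ("n_individuals_per_type", "clones_per_individual",
                     "amplicon_length_its", "amplicon_length_ssu"):
            if getattr(self, name) < 1:
                raise SimConfigError(f"{name} must be >= 1")
        for name in ("n_stations", "grid_extent", "n_localities",
                     "n_specimens_north", "n_specimens_south"):
            if getattr(self, name) < 0:
                raise SimConfigError(f"{name} must be >= 0")
        if not 0 <= self.missing_cell_fraction <= 1:
            raise SimConfigError("missing_cell_fraction must lie in [0, 1]")
        if not self.front_sst_low < self.front_sst_high:
            raise SimConfigError("front_sst_low must be below front_sst_high")

    def _rngs(self) -> dict[str, np.random.Generator]:
        children = np.random.SeedSequence(self.seed).spawn(4)
        names = ("sequences", "stations", "coretops", "morphometry")
        return {n: np.random.default_rng(ss) for n, ss in zip(names, children)}

    def rng_for(self, stage: str) -> np.random.Generator:
        return self._rngs()[stage]


# ---------------------------------------------------------------------------
# Sequences
# ---------------------------------------------------------------------------


def _mutate(codes: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute each site with probability ``rate`` to one of the three
    other bases (uniform), so the expected parent-child p-distance is
    exactly ``rate``."""
    out = codes.copy()
    if rate <= 0:
        return out
    hit = np.flatnonzero(rng.random(codes.size) < rate)
    if hit.size:
        out[hit] = (out[hit] + rng.integers(1, 4, size=hit.size)) % 4
    return out


def _decode(codes: np.ndarray) -> str:
    return "".join(_BASES[codes])


_MOTIFS = ("CCAGG", "CCTGG")  # the two disambiguations of CCWGG


def _ablate_motif(seq: list[str], start: int, stop: int) -> None:
    """Destroy every CCWGG occurrence starting in [start, stop)."""
    changed = True
    while changed:
        changed = False
        for p in range(start, min(stop, len(seq) - 4)):
            if "".join(seq[p : p + 5]) in _MOTIFS:
                seq[p + 2] = "G"  # CCWGG -> CCGGG, no longer a site
                changed = True


def _engineer_its_motif(bases: str, genotype: str, pos: int) -> str:
    seq = list(bases)
    if genotype == "I":
        _ablate_motif(seq, 0, pos)
        seq[pos : pos + 5] = "CCAGG"
    else:
        _ablate_motif(seq, 0, len(seq))
    return "".join(seq)


def generate_sequences(config: SimConfig) -> list[SequenceRecord]:
    """Two-genotype clone library for both markers (ITS and SSU).

    Each genotype descends from its own ancestor; the two ancestors are
    separated so that the expected clone-to-clone between-type p-distance
    matches ``inter_type_divergence`` (the two within-type branches are
    subtracted from the ancestral branch). Every Type I ITS amplicon
    carries a CCWGG site whose first occurrence sits at
    ``motif_position_fraction`` of the amplicon; Type II ITS amplicons
    carry none.
    """
    rng = config.rng_for("sequences")
    records: list[SequenceRecord] = []
    d_ind = config.intra_individual_divergence
    d_intra = config.intra_type_divergence
    d_anc = config.inter_type_divergence - 2 * (d_intra + d_ind)
    if d_anc <= 0:
        raise SimConfigError(
            "inter_type_divergence must exceed twice the within-type budget "
            "(intra_type + intra_individual)"
        )
    for marker, L, scale in (
        ("ITS", config.amplicon_length_its, 1.0),
        ("SSU", config.amplicon_length_ssu, config.ssu_rate_scale),
    ):
        root = rng.integers(0, 4, size=L, dtype=np.int8)
        anc = {"I": root, "II": _mutate(root, d_anc * scale, rng)}
        motif_pos = int(round(config.motif_position_fraction * L))
        for genotype in ("I", "II"):
            for i in range(config.n_individuals_per_type):
                specimen = f"{genotype}{i + 1:03d}"
                station = f"{'W' if genotype == 'I' else 'C'}{i % 5 + 1}"
                indiv = _mutate(anc[genotype], d_intra * scale, rng)
                for c in range(config.clones_per_individual):
                    clone = _mutate(indiv, d_ind * scale, rng)
                    bases = _decode(clone)
                    if marker == "ITS":
                        bases = _engineer_its_motif(bases, genotype, motif_pos)
                    records.append(
                        SequenceRecord(
                            id=f"{marker}_{specimen}_c{c + 1}",
                            bases=bases,
                            specimen_id=specimen,
                            station_id=station,
                            marker=marker,
                            genotype=genotype,
                        )
                    )
    return records


# ---------------------------------------------------------------------------
# Stations
# ---------------------------------------------------------------------------

_PROFILE_DEPTHS = np.arange(0, 251, 10)


def _station_profile(sst: float, rng: np.random.Generator) -> pd.DataFrame:
    # exponential thermocline anchored so that T(10 m) == SST
    t_deep = 2.0
    t0 = t_deep + (sst - t_deep) / math.exp(-10 / 120)
    temp = t_deep + (t0 - t_deep) * np.exp(-_PROFILE_DEPTHS / 120)
    # deep chlorophyll maximum, stronger in cold nutrient-rich water
    peak_depth = rng.uniform(30, 80)
    amp = rng.uniform(0.5, 1.0) * (1.5 if sst < 10 else 1.0)
    fluo = amp * np.exp(-((_PROFILE_DEPTHS - peak_depth) ** 2) / (2 * 25**2))
    return pd.DataFrame(
        {"depth": _PROFILE_DEPTHS, "temperature": temp, "fluorescence": fluo}
    )


def generate_stations(config: SimConfig) -> list[StationRecord]:
    """Strictly allopatric stations along an SST transect.

    SSTs cover ``sst_range`` as a jittered stratified transect (like a
    cruise track crossing the front). Stations warmer than the front band
    carry only Type I, colder only Type II; inside the band the assignment
    follows a hidden front temperature drawn uniformly within the band per
    seed (the data being emulated do not resolve where in the band the
    front sits, only that occupancy is strictly allopatric).
    """
    rng = config.rng_for("stations")
    n = config.n_stations
    if n == 0:
        return []
    lo, hi = config.sst_range
    ssts = lo + (np.arange(n) + rng.random(n)) * (hi - lo) / n
    rng.shuffle(ssts)
    hidden_front = rng.uniform(config.front_sst_low, config.front_sst_high)
    stations = []
    for k, sst in enumerate(ssts):
        genotype = "I" if sst > hidden_front else "II"
        counts = {"I": 0, "II": 0}
        counts[genotype] = int(rng.integers(1, 40))
        lat = -(58.0 - 1.6 * sst) + rng.normal(0, 1.5)
        lon = float(rng.uniform(-180, 180))
        prof = _station_profile(float(sst), rng)
        stations.append(
            StationRecord(
                station_id=f"S{k + 1:02d}",
                cruise="SYNTH",
                lat=float(lat),
                lon=lon,
                sst=float(prof.loc[prof["depth"] == 10, "temperature"].iloc[0]),
                side="north" if genotype == "I" else "south",
                genotype_counts=counts,
                profile=prof,
            )
        )
    return stations


# ---------------------------------------------------------------------------
# Core-top grid
# ---------------------------------------------------------------------------


def generate_coretop_grid(config: SimConfig) -> tuple[list[CoreTopSample], pd.DataFrame]:
    """Core-top assemblages plus the 1-degree gridded temperature field.

    The grid spans latitudes -65..64 and ``grid_extent`` degrees of
    longitude; each locality occupies one distinct cell. Temperatures
    decrease smoothly poleward and downward (an exponential thermocline
    whose depth scale varies between cells, which injects the
    surface/subsurface contrast that loads on PC2). Exactly
    floor(missing_cell_fraction * n_localities * 13) locality x depth
    couples are masked missing, both in the samples and in the grid. The
    focal species (species_01) has a transitional thermal optimum: its
    relative abundance falls off as the mean water-column temperature moves
    away from ~13.5 degC and it is absent at the extremes.
    """
    rng = config.rng_for("coretops")
    lats = np.arange(-65, 65)
    lons = np.arange(0, config.grid_extent)
    cells = [(int(la), int(lo)) for la in lats for lo in lons]
    if config.n_localities > len(cells):
        raise SimConfigError(
            f"n_localities={config.n_localities} exceeds the {len(cells)}-cell grid; "
            "increase grid_extent"
        )
    pick = rng.choice(len(cells), size=config.n_localities, replace=False)
    depths = np.asarray(DEPTHS, dtype=float)

    def cell_temps(lat: int) -> np.ndarray:
        # warm mixed layer over an exponential thermocline; the mixed-layer
        # depth varies between cells independently of surface temperature,
        # which is the surface/subsurface contrast that loads on PC2
        t_deep = 1.5
        t_surf = max(2.0 + 26.0 * math.cos(math.radians(lat + 0.5)) ** 1.7
                     + rng.normal(0, 0.6), t_deep + 0.5)
        mld = rng.uniform(10, 110)
        scale = rng.uniform(160, 400)
        return t_deep + (t_surf - t_deep) * np.exp(
            -np.maximum(depths - mld, 0.0) / scale
        )

    grid_rows = []
    temps_by_cell: dict[tuple[int, int], np.ndarray] = {}
    for la, lo in cells:
        temps_by_cell[(la, lo)] = cell_temps(la)

    samples: list[CoreTopSample] = []
    n_species = 37
    species = [f"species_{i + 1:02d}" for i in range(n_species)]
    for j, ci in enumerate(pick):
        la, lo = cells[ci]
        temps = temps_by_cell[(la, lo)].copy()
        mean_t = temps.mean()
        rel = max(0.35 * math.exp(-(((mean_t - 15.0) / 3.5) ** 2)) - 0.04, 0.0)
        total = int(rng.lognormal(math.log(379), 0.5)) + 20
        n_focal = rng.binomial(total, rel)
        others = rng.multinomial(total - n_focal, rng.dirichlet(np.full(n_species - 1, 0.5)))
        counts = {species[0]: int(n_focal)}
        counts.update({sp: int(c) for sp, c in zip(species[1:], others)})
        samples.append(
            CoreTopSample(
                locality_id=f"L{j + 1:04d}",
                lat=la + 0.5,
                lon=lo + 0.5,
                species_counts=counts,
                temps=temps,
            )
        )

    # mask missing locality x depth couples
    n_couples = config.n_localities * len(DEPTHS)
    n_missing = int(math.floor(config.missing_cell_fraction * n_couples))
    if n_missing:
        masked = rng.choice(n_couples, size=n_missing, replace=False)
        for m in masked:
            li, di = divmod(int(m), len(DEPTHS))
            samples[li].temps[di] = np.nan
            cell = cells[pick[li]]
            temps_by_cell[cell][di] = np.nan

    for (la, lo), temps in temps_by_cell.items():
        for d, t in zip(DEPTHS, temps):
            grid_rows.append({"lat": la, "lon": lo, "depth": d,
                              "temp": float(t) if np.isfinite(t) else np.nan})
    grid = pd.DataFrame(grid_rows)
    return samples, grid


# ---------------------------------------------------------------------------
# Morphometry
# ---------------------------------------------------------------------------

#: Calibrated dispersion of the log aperture/chamber ratio.
_LOG_RATIO_SD = 0.16


def generate_morphometry(config: SimConfig) -> pd.DataFrame:
    """Two weakly differentiated morphometric populations.

    Shell size (major axis, micrometers) is log-normal and shared between
    groups; the log aperture/terminal-chamber ratio differs between groups
    by ``morpho_effect_size`` standard deviations, with the north group
    (warm side, Type I) carrying the larger size-normalized aperture. At
    the default effect size (0.82 SD) a two-group discriminant analysis on
    (log size, log ratio) classifies about 66% of specimens correctly at
    the default sample sizes.
    """
    rng = config.rng_for("morphometry")
    rows = []
    delta = config.morpho_effect_size * _LOG_RATIO_SD
    for group, n, sign in (("north", config.n_specimens_north, +1),
                           ("south", config.n_specimens_south, -1)):
        major = np.exp(rng.normal(math.log(450.0), 0.18, size=n))
        chamber = major * np.exp(rng.normal(-0.85, 0.10, size=n))
        log_ratio = rng.normal(-0.72 + sign * delta / 2, _LOG_RATIO_SD, size=n)
        aperture = chamber * np.exp(log_ratio)
        for i in range(n):
            rows.append(
                {
                    "specimen_id": f"{group[0].upper()}{i + 1:03d}",
                    "major_axis": major[i],
                    "chamber_axis": chamber[i],
                    "aperture_axis": aperture[i],
                    "group": group,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# File emission (used by the `simulate` CLI subcommand)
# ---------------------------------------------------------------------------


def write_all(config: SimConfig, outdir) -> dict[str, str]:
    """Generate every input and write it under ``outdir``.

    Emits: sequences.fasta, stations.csv, profiles.csv, coretops.csv,
    grid.csv, morphometry.csv. Returns the path map.
    """
    from pathlib import Path

    from .seqalign import write_fasta
    from .stations import profiles_to_frame, stations_to_frame
    from .thermal_niche import coretops_to_frame

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    records = generate_sequences(config)
    paths["sequences"] = str(outdir / "sequences.fasta")
    write_fasta(records, paths["sequences"])

    stations = generate_stations(config)
    paths["stations"] = str(outdir / "stations.csv")
    stations_to_frame(stations).to_csv(paths["stations"], index=False)
    paths["profiles"] = str(outdir / "profiles.csv")
    profiles_to_frame(stations).to_csv(paths["profiles"], index=False)

    samples, grid = generate_coretop_grid(config)
    paths["coretops"] = str(outdir / "coretops.csv")
    coretops_to_frame(samples).to_csv(paths["coretops"], index=False)
    paths["grid"] = str(outdir / "grid.csv")
    grid.to_csv(paths["grid"], index=False)

    paths["morphometry"] = str(outdir / "morphometry.csv")
    generate_morphometry(config).to_csv(paths["morphometry"], index=False)
    return paths
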