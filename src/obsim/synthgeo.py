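"""Synthetic geography generator and geography file I/O.

Real inputs behind this kind of analysis -- a national facility survey, a
census population raster and a proprietary road network -- are not publicly
packaged, so every downstream stage is exercised on synthetic geographies
that reproduce the statistical structure the analysis relies on:

* a rectangular region tiled by 1-km^2 grid cells holding the female
  population aged 15-49, concentrated in a small number of urban clusters;
* contiguous rectangular municipalities grouped into medical service areas
  (MSAs), the administrative zones used by the MSA-constrained scenario;
* hospitals placed preferentially in populous cells, with right-skewed
  monthly delivery volumes and correlated obstetrician/midwife staffing
  (gamma marginals moment-matched to a configurable mean/SD, coupled
  through a shared latent facility-size factor via a Gaussian copula);
* an undirected road network (unit lattice plus faster diagonal shortcuts)
  whose edge speeds fall in the 10-80 km/h road-class range.

Generation is fully deterministic for a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import ndtr

from .access import RoadNetwork
from .errors import ConfigurationError, GeographyIOError

__all__ = [
    "SyntheticConfig",
    "Geography",
    "generate_geography",
    "write_geography",
    "read_geography",
    "export_geojson",
    "DESIGNATIONS",
]

DESIGNATIONS = ("general_pmc", "regional_pmc", "academic", "other")

# National 2011 composition used for default designation counts: of 1075
# obstetrics hospitals, 95 general PMCs, 279 regional PMCs and a 405-strong
# fixed set (academic hospitals + PMCs), leaving 31 academic by subtraction.
_NATIONAL_BASELINE = 1075
_NATIONAL_GENERAL = 95
_NATIONAL_REGIONAL = 279
_NATIONAL_ACADEMIC = 31

HOSPITAL_COLUMNS = [
    "id", "x_km", "y_km", "municipality_id", "msa_id",
    "deliveries_per_month", "obstetricians_fte", "midwives_fte", "designation",
]
CELL_COLUMNS = ["id", "x_km", "y_km", "municipality_id", "female_pop_15_49"]


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic geography.

    Staffing and volume defaults are the observed national hospital-level
    moments: deliveries/month 44.1 (SD 39.3), obstetricians 5.5 (4.6) FTE,
    midwives 15.3 (11.8) FTE.  Road-class speeds must lie in [10, 80] km/h.
    """

    seed: int = 0
    region_width_km: float = 100.0
    region_height_km: float = 80.0
    n_msas: int = 12
    municipalities_per_msa: int = 5
    n_urban_clusters: int = 6
    total_female_pop: float = 400_000
    n_hospitals: int = 120
    delivery_mean: float = 44.1
    delivery_sd: float = 39.3
    obstetrician_mean: float = 5.5
    obstetrician_sd: float = 4.6
    midwife_mean: float = 15.3
    midwife_sd: float = 11.8
    staff_volume_correlation: float = 0.6
    road_class_speeds_kmh: tuple[float, ...] = (30.0, 40.0, 50.0, 80.0)
    network_density: float = 4.2
    # Designation counts; None means scale the national 95/279/31-of-1075
    # composition down to n_hospitals.
    n_general_pmc: int | None = None
    n_regional_pmc: int | None = None
    n_academic: int | None = None

    def validate(self) -> None:
        if self.region_width_km <= 0 or self.region_height_km <= 0:
            raise ConfigurationError("region dimensions must be positive")
        if self.n_msas < 1 or self.municipalities_per_msa < 1:
            raise ConfigurationError("MSA/municipality counts must be >= 1")
        if self.n_urban_clusters < 1:
            raise ConfigurationError("n_urban_clusters must be >= 1")
        if self.total_female_pop <= 0:
            raise ConfigurationError("total_female_pop must be positive")
        if self.n_hospitals < 0:
            raise ConfigurationError("n_hospitals must be >= 0")
        for name in ("delivery", "obstetrician", "midwife"):
            mean = getattr(self, f"{name}_mean")
            sd = getattr(self, f"{name}_sd")
            if mean < 0 or sd < 0:
                raise ConfigurationError(f"{name} mean/sd must be >= 0")
        if not 0.0 <= self.staff_volume_correlation <= 1.0:
            raise ConfigurationError("staff_volume_correlation must lie in [0, 1]")
        if not self.road_class_speeds_kmh:
            raise ConfigurationError("at least one road-class speed is required")
        for s in self.road_class_speeds_kmh:
            if not 10.0 <= s <= 80.0:
                raise ConfigurationError(f"road speed {s} outside [10, 80] km/h")
        if self.network_density <= 0:
            raise ConfigurationError("network_density must be positive")
        nrows, ncols = self.grid_shape()
        if self.n_msas * self.municipalities_per_msa > nrows * ncols:
            raise ConfigurationError(
                "infeasible tiling: more municipalities than 1-km grid cells"
            )

    def grid_shape(self) -> tuple[int, int]:
        """(rows, cols) of the 1-km cell grid covering the region."""
        return (max(1, round(self.region_height_km)),
                max(1, round(self.region_width_km)))

    def designation_counts(self) -> tuple[int, int, int]:
        """(general, regional, academic) counts, scaled from the national mix
        when not set explicitly."""
        s = self.n_hospitals / _NATIONAL_BASELINE
        n_gen = (self.n_general_pmc if self.n_general_pmc is not None
                 else round(_NATIONAL_GENERAL * s))
        n_reg = (self.n_regional_pmc if self.n_regional_pmc is not None
                 else round(_NATIONAL_REGIONAL * s))
        n_aca = (self.n_academic if self.n_academic is not None
                 else round(_NATIONAL_ACADEMIC * s))
        if min(n_gen, n_reg, n_aca) < 0 or n_gen + n_reg + n_aca > self.n_hospitals:
            raise ConfigurationError("designation counts exceed n_hospitals")
        return n_gen, n_reg, n_aca


@dataclass
class Geography:
    """A complete synthetic study region.

    ``cells`` and ``hospitals`` are plain DataFrames (see ``CELL_COLUMNS`` /
    ``HOSPITAL_COLUMNS``), ``network`` the road graph, ``msa_index`` the
    municipality -> MSA mapping with columns ``municipality_id, msa_id``.
    """

    cells: pd.DataFrame
    hospitals: pd.DataFrame
    network: RoadNetwork
    msa_index: pd.DataFrame

    def equals(self, other: "Geography") -> bool:
        return (
            self.cells.reset_index(drop=True).equals(other.cells.reset_index(drop=True))
            and self.hospitals.reset_index(drop=True).equals(
                other.hospitals.reset_index(drop=True))
            and self.network.nodes.reset_index(drop=True).equals(
                other.network.nodes.reset_index(drop=True))
            and self.network.edges.reset_index(drop=True).equals(
                other.network.edges.reset_index(drop=True))
            and self.msa_index.reset_index(drop=True).equals(
                other.msa_index.reset_index(drop=True))
        )

    @property
    def municipality_to_msa(self) -> dict:
        return dict(zip(self.msa_index["municipality_id"], self.msa_index["msa_id"]))


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _municipality_strips(n_muni: int, nrows: int, ncols: int) -> tuple[int, int]:
    """Pick a (cols_strips, rows_strips) divisor pair of n_muni whose aspect
    best matches the grid; municipalities become contiguous rectangles."""
    best = None
    target = ncols / nrows
    for a in range(1, n_muni + 1):
        if n_muni % a:
            continue
        b = n_muni // a
        if a > ncols or b > nrows:
            continue
        score = abs(math.log((a / b) / target))
        if best is None or score < best[0]:
            best = (score, a, b)
    if best is None:
        raise ConfigurationError(
            f"cannot tile a {nrows}x{ncols} grid into {n_muni} rectangular "
            "municipalities"
        )
    return best[1], best[2]


def _largest_remainder(target: np.ndarray, total: float) -> np.ndarray:
    """Integerize non-negative targets so the sum is exactly round(total)."""
    base = np.floor(target)
    short = int(round(total)) - int(base.sum())
    frac = target - base
    # deterministic: largest fractional parts first, ties by cell index
    order = np.lexsort((np.arange(len(target)), -frac))
    out = base.copy()
    out[order[:short]] += 1.0
    return out


def _correlated_gamma(rng: np.random.Generator, z_shared: np.ndarray,
                      mean: float, sd: float, rho_gauss: float) -> np.ndarray:
    """Gamma sample moment-matched to (mean, sd), coupled to the shared
    latent factor through a Gaussian copula with latent correlation
    ``rho_gauss``."""
    n = len(z_shared)
    eps = rng.standard_normal(n)
    g = math.sqrt(rho_gauss) * z_shared + math.sqrt(1.0 - rho_gauss) * eps
    if sd == 0 or mean == 0:
        return np.full(n, float(mean))
    shape = (mean / sd) ** 2
    scale = sd ** 2 / mean
    u = ndtr(g)
    return stats.gamma.ppf(u, shape, scale=scale)


def generate_geography(config: SyntheticConfig) -> Geography:
    """Build a synthetic geography; deterministic for a fixed seed.

    Populations are integerized by largest remainder so their sum equals
    ``total_female_pop`` exactly.  The Gaussian-copula latent correlation is
    set to ``2 sin(pi * rho / 6)`` so the rank (Spearman) correlation between
    deliveries and each staffing variable comes out at approximately
    ``staff_volume_correlation``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    nrows, ncols = config.grid_shape()
    n_cells = nrows * ncols
    W, H = float(ncols), float(nrows)

    rows, cols = np.divmod(np.arange(n_cells), ncols)
    cx = cols + 0.5
    cy = rows + 0.5

    # municipalities: rectangular strips; MSAs: blocks of consecutive ids
    n_muni = config.n_msas * config.municipalities_per_msa
    a, b = _municipality_strips(n_muni, nrows, ncols)
    strip_col = (cols * a) // ncols
    strip_row = (rows * b) // nrows
    municipality = (strip_row * a + strip_col).astype(np.int64)
    msa_of_muni = np.arange(n_muni) // config.municipalities_per_msa

    # population: Gaussian urban clusters over a thin uniform floor
    centers = rng.uniform([0.0, 0.0], [W, H], size=(config.n_urban_clusters, 2))
    sigmas = rng.uniform(0.03, 0.10, size=config.n_urban_clusters) * max(W, H)
    weights = rng.dirichlet(np.full(config.n_urban_clusters, 2.0))
    dens = np.zeros(n_cells)
    for (px, py), sg, w in zip(centers, sigmas, weights):
        d2 = (cx - px) ** 2 + (cy - py) ** 2
        dens += w * np.exp(-0.5 * d2 / sg ** 2)
    if dens.sum() > 0:
        dens /= dens.sum()
    dens = 0.95 * dens + 0.05 / n_cells
    pop = _largest_remainder(dens * config.total_female_pop,
                             config.total_female_pop)

    cells = pd.DataFrame({
        "id": np.arange(n_cells, dtype=np.int64),
        "x_km": cx,
        "y_km": cy,
        "municipality_id": municipality,
        "female_pop_15_49": pop,
    })

    hospitals = _place_hospitals(config, rng, cells, msa_of_muni)
    network = _build_network(config, rng, nrows, ncols, cx, cy)
    msa_index = pd.DataFrame({
        "municipality_id": np.arange(n_muni, dtype=np.int64),
        "msa_id": msa_of_muni.astype(np.int64),
    })
    return Geography(cells=cells, hospitals=hospitals, network=network,
                     msa_index=msa_index)


def _place_hospitals(config: SyntheticConfig, rng: np.random.Generator,
                     cells: pd.DataFrame, msa_of_muni: np.ndarray) -> pd.DataFrame:
    n = config.n_hospitals
    if n == 0:
        return pd.DataFrame(columns=HOSPITAL_COLUMNS).astype({
            "x_km": float, "y_km": float, "deliveries_per_month": float,
            "obstetricians_fte": float, "midwives_fte": float,
            "municipality_id": np.int64, "msa_id": np.int64,
        })
    pop = cells["female_pop_15_49"].to_numpy()
    p = pop + 1.0
    p = p / p.sum()
    replace_cells = n > len(cells)
    cell_idx = rng.choice(len(cells), size=n, replace=replace_cells, p=p)

    z_shared = rng.standard_normal(n)
    rho = config.staff_volume_correlation
    rho_g = 2.0 * math.sin(math.pi * rho / 6.0)  # target Spearman -> Gaussian
    deliveries = _correlated_gamma(rng, z_shared, config.delivery_mean,
                                   config.delivery_sd, rho_g)
    obstetricians = _correlated_gamma(rng, z_shared, config.obstetrician_mean,
                                      config.obstetrician_sd, rho_g)
    midwives = _correlated_gamma(rng, z_shared, config.midwife_mean,
                                 config.midwife_sd, rho_g)

    # designation tiers follow the latent facility size, largest first
    n_gen, n_reg, n_aca = config.designation_counts()
    order = np.argsort(-z_shared, kind="stable")
    designation = np.full(n, "other", dtype=object)
    designation[order[:n_gen]] = "general_pmc"
    designation[order[n_gen:n_gen + n_reg]] = "regional_pmc"
    designation[order[n_gen + n_reg:n_gen + n_reg + n_aca]] = "academic"

    muni = cells["municipality_id"].to_numpy()[cell_idx]
    width = len(str(max(n - 1, 1)))
    return pd.DataFrame({
        "id": [f"h{i:0{width}d}" for i in range(n)],
        "x_km": cells["x_km"].to_numpy()[cell_idx],
        "y_km": cells["y_km"].to_numpy()[cell_idx],
        "municipality_id": muni,
        "msa_id": msa_of_muni[muni].astype(np.int64),
        "deliveries_per_month": deliveries,
        "obstetricians_fte": obstetricians,
        "midwives_fte": midwives,
        "designation": designation,
    })


def _build_network(config: SyntheticConfig, rng: np.random.Generator,
                   nrows: int, ncols: int,
                   cx: np.ndarray, cy: np.ndarray) -> RoadNetwork:
    """Unit lattice over cell centroids plus random diagonal shortcuts at the
    fastest road class until the mean degree approaches ``network_density``."""
    n_cells = nrows * ncols
    idx = np.arange(n_cells).reshape(nrows, ncols)
    right_u = idx[:, :-1].ravel()
    right_v = idx[:, 1:].ravel()
    down_u = idx[:-1, :].ravel()
    down_v = idx[1:, :].ravel()
    u = np.concatenate([right_u, down_u])
    v = np.concatenate([right_v, down_v])
    length = np.ones(len(u))
    speeds = np.asarray(config.road_class_speeds_kmh, dtype=float)
    local = speeds[:-1] if len(speeds) > 1 else speeds
    speed = rng.choice(local, size=len(u))

    n_extra = max(0, round(config.network_density * n_cells / 2.0) - len(u))
    if n_extra and nrows > 1 and ncols > 1:
        dr_u = idx[:-1, :-1].ravel()
        dr_v = idx[1:, 1:].ravel()
        dl_u = idx[:-1, 1:].ravel()
        dl_v = idx[1:, :-1].ravel()
        cand_u = np.concatenate([dr_u, dl_u])
        cand_v = np.concatenate([dr_v, dl_v])
        take = rng.choice(len(cand_u), size=min(n_extra, len(cand_u)),
                          replace=False)
        take.sort()
        u = np.concatenate([u, cand_u[take]])
        v = np.concatenate([v, cand_v[take]])
        length = np.concatenate([length, np.full(len(take), math.sqrt(2.0))])
        speed = np.concatenate([speed, np.full(len(take), speeds.max())])

    nodes = pd.DataFrame({"id": np.arange(n_cells, dtype=np.int64),
                          "x_km": cx, "y_km": cy})
    edges = pd.DataFrame({"node_u": u.astype(np.int64),
                          "node_v": v.astype(np.int64),
                          "length_km": length, "speed_kmh": speed})
    return RoadNetwork(nodes, edges)


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

_FILES = {
    "hospitals.csv": HOSPITAL_COLUMNS,
    "cells.csv": CELL_COLUMNS,
    "nodes.csv": ["id", "x_km", "y_km"],
    "edges.csv": ["node_u", "node_v", "length_km", "speed_kmh"],
    "msa.csv": ["municipality_id", "msa_id"],
}


def write_geography(geo: Geography, directory: str | Path) -> dict[str, Path]:
    """Write the five-table CSV representation; returns written paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    frames = {
        "hospitals.csv": geo.hospitals,
        "cells.csv": geo.cells,
        "nodes.csv": geo.network.nodes,
        "edges.csv": geo.network.edges,
        "msa.csv": geo.msa_index,
    }
    paths = {}
    for name, frame in frames.items():
        path = directory / name
        frame.to_csv(path, index=False)
        paths[name] = path
    return paths


def _load_table(directory: Path, name: str) -> pd.DataFrame:
    path = directory / name
    if not path.exists():
        raise GeographyIOError(name, "-", "file missing")
    try:
        # round_trip parsing so write -> read is float-exact
        frame = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:  # malformed CSV
        raise GeographyIOError(name, "-", f"unreadable: {exc}") from exc
    missing = [c for c in _FILES[name] if c not in frame.columns]
    if missing:
        raise GeographyIOError(name, "header", f"missing columns {missing}")
    return frame[_FILES[name]]


def read_geography(directory: str | Path) -> Geography:
    """Read and validate a geography written by :func:`write_geography`.

    Row-level violations (negative populations, dangling foreign keys) raise
    :class:`GeographyIOError` naming the file and offending row.
    """
    directory = Path(directory)
    hospitals = _load_table(directory, "hospitals.csv")
    cells = _load_table(directory, "cells.csv")
    nodes = _load_table(directory, "nodes.csv")
    edges = _load_table(directory, "edges.csv")
    msa = _load_table(directory, "msa.csv")

    neg = cells.index[cells["female_pop_15_49"] < 0]
    if len(neg):
        raise GeographyIOError("cells.csv", int(neg[0]),
                               "negative female_pop_15_49")
    known_muni = set(msa["municipality_id"])
    bad = cells.index[~cells["municipality_id"].isin(known_muni)]
    if len(bad):
        raise GeographyIOError("cells.csv", int(bad[0]),
                               "unknown municipality_id")
    muni_to_msa = dict(zip(msa["municipality_id"], msa["msa_id"]))
    for row, h in hospitals.iterrows():
        if h["municipality_id"] not in muni_to_msa:
            raise GeographyIOError("hospitals.csv", int(row),
                                   f"unknown municipality_id {h['municipality_id']}")
        if muni_to_msa[h["municipality_id"]] != h["msa_id"]:
            raise GeographyIOError("hospitals.csv", int(row),
                                   "msa_id does not match municipality's MSA")
        if h["deliveries_per_month"] < 0:
            raise GeographyIOError("hospitals.csv", int(row),
                                   "negative deliveries_per_month")
    known_nodes = set(nodes["id"])
    dangling = edges.index[~(edges["node_u"].isin(known_nodes)
                             & edges["node_v"].isin(known_nodes))]
    if len(dangling):
        raise GeographyIOError("edges.csv", int(dangling[0]),
                               "edge endpoint not in nodes.csv")
    network = RoadNetwork(nodes, edges)
    return Geography(cells=cells, hospitals=hospitals, network=network,
                     msa_index=msa)


def export_geojson(geo: Geography, path: str | Path) -> Path:
    """Optional GeoJSON export: cells and hospitals as Point features with
    properties mirroring the CSV columns (planar km coordinates)."""
    import json

    features = []
    for _, c in geo.cells.iterrows():
        features.append({
            "type": "Feature",
            "geometry": {"type": "Point", "coordinates": [c["x_km"], c["y_km"]]},
            "properties": {"kind": "cell", "id": int(c["id"]),
                           "municipality_id": int(c["municipality_id"]),
                           "female_pop_15_49": float(c["female_pop_15_49"])},
        })
    for _, h in geo.hospitals.iterrows():
        features.append({
            "type": "Feature",
            "geometry": {"type": "Point", "coordinates": [h["x_km"], h["y_km"]]},
            "properties": {"kind": "hospital", "id": h["id"],
                           "municipality_id": int(h["municipality_id"]),
                           "msa_id": int(h["msa_id"]),
                           "deliveries_per_month": float(h["deliveries_per_month"]),
                           "designation": h["designation"]},
        })
    path = Path(path)
    path.write_text(json.dumps({"type": "FeatureCollection",
                                "features": features}))
    return path
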