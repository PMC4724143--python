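"""Shared fixtures.

`lattice_geography` builds fully explicit geographies on a uniform-speed
unit lattice, where the shortest-path drive time between two cells is just
their Manhattan distance times the per-edge minutes -- so every expected
value can be worked out by hand (or by the independent Manhattan oracle in
the tests)."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from obsim import (Geography, RoadNetwork, SyntheticConfig,
                   generate_geography, travel_time_matrix)


def lattice_geography(nrows, ncols, pops, hospitals, muni_of_cell,
                      msa_of_muni, speed_kmh=10.0):
    """Explicit test geography on a 1-km lattice with one uniform speed.

    ``pops``: per-cell population, length nrows*ncols (row-major).
    ``hospitals``: list of dicts with keys id, cell, deliveries,
    obstetricians, midwives, designation.
    """
    n = nrows * ncols
    rows, cols = np.divmod(np.arange(n), ncols)
    muni = np.asarray(muni_of_cell, dtype=np.int64)
    cells = pd.DataFrame({
        "id": np.arange(n, dtype=np.int64),
        "x_km": cols + 0.5, "y_km": rows + 0.5,
        "municipality_id": muni,
        "female_pop_15_49": np.asarray(pops, dtype=float),
    })
    idx = np.arange(n).reshape(nrows, ncols)
    u = np.concatenate([idx[:, :-1].ravel(), idx[:-1, :].ravel()])
    v = np.concatenate([idx[:, 1:].ravel(), idx[1:, :].ravel()])
    nodes = pd.DataFrame({"id": np.arange(n, dtype=np.int64),
                          "x_km": cols + 0.5, "y_km": rows + 0.5})
    edges = pd.DataFrame({"node_u": u.astype(np.int64),
                          "node_v": v.astype(np.int64),
                          "length_km": 1.0, "speed_kmh": float(speed_kmh)})
    hosp = pd.DataFrame({
        "id": [h["id"] for h in hospitals],
        "x_km": [cols[h["cell"]] + 0.5 for h in hospitals],
        "y_km": [rows[h["cell"]] + 0.5 for h in hospitals],
        "municipality_id": [muni[h["cell"]] for h in hospitals],
        "msa_id": [msa_of_muni[muni[h["cell"]]] for h in hospitals],
        "deliveries_per_month": [float(h["deliveries"]) for h in hospitals],
        "obstetricians_fte": [float(h.get("obstetricians", 1.0))
                              for h in hospitals],
        "midwives_fte": [float(h.get("midwives", 2.0)) for h in hospitals],
        "designation": [h.get("designation", "other") for h in hospitals],
    })
    msa_index = pd.DataFrame({
        "municipality_id": np.arange(len(msa_of_muni), dtype=np.int64),
        "msa_id": np.asarray(msa_of_muni, dtype=np.int64),
    })
    return Geography(cells=cells, hospitals=hosp,
                     network=RoadNetwork(nodes, edges), msa_index=msa_index)


def manhattan_minutes(geo, minutes_per_km=6.0):
    """Independent drive-time oracle for uniform-speed lattice geographies:
    Manhattan distance between cell centroids times minutes per km."""
    cx = geo.cells["x_km"].to_numpy()[:, None]
    cy = geo.cells["y_km"].to_numpy()[:, None]
    hx = geo.hospitals["x_km"].to_numpy()[None, :]
    hy = geo.hospitals["y_km"].to_numpy()[None, :]
    return (np.abs(cx - hx) + np.abs(cy - hy)) * minutes_per_km


# --- the 6-hospital, 2-MSA, 50-cell hand fixture ---------------------------

HAND_HOSPITALS = [
    # (col, row): h0 (2,1) h1 (7,1) h2 (1,4) h3 (8,4) h4 (4,0) h5 (5,3)
    # volume concentrates in the left MSA so the volume-only scenario
    # strips the right MSA while the MSA-constrained one keeps h3
    dict(id="h0", cell=12, deliveries=80.0, obstetricians=10.0,
         midwives=20.0, designation="general_pmc"),
    dict(id="h1", cell=17, deliveries=15.0, obstetricians=7.0,
         midwives=14.0, designation="regional_pmc"),
    dict(id="h2", cell=41, deliveries=40.0, obstetricians=4.0,
         midwives=8.0, designation="other"),
    dict(id="h3", cell=48, deliveries=30.0, obstetricians=3.0,
         midwives=6.0, designation="academic"),
    dict(id="h4", cell=4, deliveries=20.0, obstetricians=2.0,
         midwives=4.0, designation="other"),
    dict(id="h5", cell=35, deliveries=10.0, obstetricians=1.0,
         midwives=2.0, designation="other"),
]


def _hand_geo():
    nrows, ncols = 5, 10
    ids = np.arange(nrows * ncols)
    rows, cols = np.divmod(ids, ncols)
    # quadrant municipalities, grouped into a left and a right MSA
    muni = (2 * (rows >= 3) + (cols >= 5)).astype(int)
    pops = 10.0 + (ids % 3)
    return lattice_geography(nrows, ncols, pops, HAND_HOSPITALS, muni,
                             msa_of_muni=[0, 1, 0, 1], speed_kmh=10.0)


@pytest.fixture(scope="session")
def hand_geo():
    """6 hospitals, 2 MSAs (4 municipalities), 50 cells; 10 km/h lattice so
    one cell step costs 6 minutes and the 30-min band is Manhattan radius 5."""
    return _hand_geo()


@pytest.fixture(scope="session")
def hand_matrix(hand_geo):
    return travel_time_matrix(hand_geo)


@pytest.fixture(scope="session")
def demo_geo():
    """Mid-sized generated geography shared by property tests."""
    cfg = SyntheticConfig(seed=11, region_width_km=50, region_height_km=40,
                          n_msas=5, municipalities_per_msa=4,
                          n_urban_clusters=4, total_female_pop=150_000,
                          n_hospitals=30,
                          road_class_speeds_kmh=(10.0, 20.0, 30.0, 80.0))
    return generate_geography(cfg)


@pytest.fixture(scope="session")
def demo_matrix(demo_geo):
    return travel_time_matrix(demo_geo)
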