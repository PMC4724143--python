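"""Retained-set selection: volume ranking, MSA constraint, and the
maximal-covering solvers against exhaustive oracles."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from obsim import (CapacityError, CoverageSets, SyntheticConfig,
                   build_coverage_sets, covered_population,
                   generate_geography, scenario_fixed,
                   scenario_maxcover_exact, scenario_maxcover_greedy,
                   scenario_msa_volume, scenario_volume)


def _hospitals(rows):
    return pd.DataFrame(rows, columns=["id", "msa_id", "deliveries_per_month",
                                       "obstetricians_fte", "midwives_fte",
                                       "designation"])


def _h(hid, msa, vol, desig="other"):
    return (hid, msa, float(vol), 1.0, 2.0, desig)


# --- S1: volume ------------------------------------------------------------

def test_volume_keeps_top_k():
    hosp = _hospitals([_h("a", 0, 50), _h("b", 0, 40), _h("c", 0, 30)])
    assert scenario_volume(hosp, 2).hospital_ids == ("a", "b")


def test_volume_k_equals_n_keeps_all():
    hosp = _hospitals([_h("a", 0, 50), _h("b", 0, 40), _h("c", 0, 30)])
    assert set(scenario_volume(hosp, 3).hospital_ids) == {"a", "b", "c"}


def test_volume_tie_breaks_by_ascending_id():
    hosp = _hospitals([_h("h9", 0, 40), _h("h2", 0, 40), _h("h1", 0, 50)])
    assert scenario_volume(hosp, 2).hospital_ids == ("h1", "h2")


def test_volume_k_above_n_warns_and_retains_all():
    hosp = _hospitals([_h("a", 0, 50), _h("b", 0, 40)])
    with pytest.warns(UserWarning, match="retaining all"):
        rs = scenario_volume(hosp, 5)
    assert len(rs) == 2


def test_volume_nested_across_k():
    rng = np.random.default_rng(1)
    hosp = _hospitals([_h(f"h{i:02d}", 0, v)
                       for i, v in enumerate(rng.uniform(0, 100, 20))])
    prev: set = set()
    for k in range(1, 21):
        cur = set(scenario_volume(hosp, k).hospital_ids)
        assert prev <= cur
        prev = cur


# --- S2: MSA + volume ------------------------------------------------------

def test_msa_constraint_protects_small_msa():
    hosp = _hospitals([_h("a", 0, 60), _h("b", 0, 10), _h("c", 1, 5)])
    assert set(scenario_msa_volume(hosp, 2).hospital_ids) == {"a", "c"}
    assert set(scenario_volume(hosp, 2).hospital_ids) == {"a", "b"}


def test_msa_constraint_k3_keeps_everything():
    hosp = _hospitals([_h("a", 0, 60), _h("b", 0, 10), _h("c", 1, 5)])
    assert set(scenario_msa_volume(hosp, 3).hospital_ids) == {"a", "b", "c"}


def test_single_msa_reduces_to_volume_scenario():
    hosp = _hospitals([_h(f"h{i}", 0, v)
                       for i, v in enumerate([9, 3, 7, 5, 1])])
    for k in range(1, 6):
        assert (set(scenario_msa_volume(hosp, k).hospital_ids)
                == set(scenario_volume(hosp, k).hospital_ids))


def test_k_below_msa_count_keeps_top_representatives_with_warning():
    hosp = _hospitals([_h("a", 0, 60), _h("b", 1, 40), _h("c", 2, 50)])
    with pytest.warns(UserWarning, match="MSA"):
        rs = scenario_msa_volume(hosp, 2)
    assert set(rs.hospital_ids) == {"a", "c"}


def test_msa_stage1_tie_breaks_by_lowest_id():
    hosp = _hospitals([_h("z", 0, 40), _h("m", 0, 40), _h("q", 1, 1)])
    rs = scenario_msa_volume(hosp, 2)
    assert set(rs.hospital_ids) == {"m", "q"}


def test_every_hospital_bearing_msa_represented(demo_geo):
    hosp = demo_geo.hospitals
    n_msas = hosp["msa_id"].nunique()
    for k in (n_msas, n_msas + 3, len(hosp)):
        rs = scenario_msa_volume(hosp, k)
        kept = hosp[hosp["id"].isin(rs.hospital_ids)]
        assert kept["msa_id"].nunique() == n_msas


# --- coverage sets ---------------------------------------------------------

def test_coverage_sets_threshold_inclusive_and_match_scan(demo_matrix,
                                                          demo_geo):
    cov = build_coverage_sets(demo_matrix, demo_geo.cells, threshold_min=30)
    order = np.argsort(demo_matrix.hospital_ids, kind="stable")
    scan = demo_matrix.minutes[:, order] <= 30.0
    assert (cov.cover == scan).all()
    assert list(cov.hospital_ids) == sorted(demo_matrix.hospital_ids)


def test_coverage_sets_boundary_and_unreachable():
    from test_access import _matrix_from_minutes

    matrix = _matrix_from_minutes([[30.0], [30.01], [np.inf]], ["hA"])
    cells = pd.DataFrame({"id": [0, 1, 2], "municipality_id": 0,
                          "female_pop_15_49": [1.0, 1.0, 1.0]})
    cov = build_coverage_sets(matrix, cells)
    assert cov.cover[:, 0].tolist() == [True, False, False]


# --- max cover -------------------------------------------------------------

def _cov(cover, weights, ids=None):
    cover = np.asarray(cover, dtype=bool)
    ids = ids or [f"H{j}" for j in range(cover.shape[1])]
    return CoverageSets(cover=cover, weights=np.asarray(weights, float),
                        cell_ids=np.arange(cover.shape[0]),
                        hospital_ids=np.asarray(ids, dtype=object),
                        threshold_min=30.0)


def _greedy_trap():
    """Weights 10,10,9,9; A={c1,c2}, B={c1,c3}, C={c2,c4}: greedy takes A
    (gain 20) then covers 29; the optimum {B,C} covers 38."""
    cover = np.array([[1, 1, 0],
                      [1, 0, 1],
                      [0, 1, 0],
                      [0, 0, 1]])
    return _cov(cover, [10, 10, 9, 9], ids=["A", "B", "C"])


def test_greedy_trap_instance():
    cov = _greedy_trap()
    greedy = scenario_maxcover_greedy(cov, 2)
    assert greedy.hospital_ids[0] == "A"
    assert covered_population(cov, greedy) == 29.0


def test_exact_beats_greedy_on_trap_instance():
    cov = _greedy_trap()
    exact = scenario_maxcover_exact(cov, 2, mode="exhaustive")
    assert exact.hospital_ids == ("B", "C")
    assert covered_population(cov, exact) == 38.0


def test_exact_k1_is_argmax():
    cov = _cov(np.array([[1, 0], [1, 0], [0, 1]]), [5, 5, 100])
    assert scenario_maxcover_exact(cov, 1).hospital_ids == ("H1",)


def test_greedy_saturates_at_union_coverage():
    cov = _greedy_trap()
    rs = scenario_maxcover_greedy(cov, 3)
    assert covered_population(cov, rs) == 38.0


def test_disjoint_sets_make_greedy_optimal():
    cover = np.eye(4, dtype=bool)
    cov = _cov(cover, [4, 3, 2, 1])
    g = scenario_maxcover_greedy(cov, 2)
    e = scenario_maxcover_exact(cov, 2)
    assert covered_population(cov, g) == covered_population(cov, e) == 7.0


def _random_instance(rng):
    n = int(rng.integers(3, 13))
    m = int(rng.integers(4, 20))
    cover = rng.random((m, n)) < 0.35
    weights = rng.integers(1, 20, size=m).astype(float)
    return _cov(cover, weights)


def _brute_force_optimum(cov, k):
    best = -1.0
    best_combo = None
    for combo in itertools.combinations(range(cov.n_hospitals),
                                        min(k, cov.n_hospitals)):
        covered = 0.0
        for c in range(len(cov.weights)):
            if any(cov.cover[c, j] for j in combo):
                covered += cov.weights[c]
        if covered > best:
            best, best_combo = covered, combo
    return best, best_combo


@pytest.mark.parametrize("seed", range(8))
def test_exact_matches_bruteforce_and_greedy_bound(seed):
    rng = np.random.default_rng(seed)
    for _ in range(5):
        cov = _random_instance(rng)
        k = int(rng.integers(1, 5))
        opt, _combo = _brute_force_optimum(cov, k)
        exact = scenario_maxcover_exact(cov, k, mode="exhaustive")
        greedy = scenario_maxcover_greedy(cov, k)
        v_exact = covered_population(cov, exact)
        v_greedy = covered_population(cov, greedy)
        assert v_exact == pytest.approx(opt)
        assert v_greedy <= v_exact + 1e-9
        assert v_greedy >= (1 - 1 / math.e) * opt - 1e-9


@pytest.mark.parametrize("seed", range(4))
def test_ilp_matches_exhaustive(seed):
    rng = np.random.default_rng(100 + seed)
    cov = _random_instance(rng)
    k = int(rng.integers(1, 4))
    v_ex = covered_population(
        cov, scenario_maxcover_exact(cov, k, mode="exhaustive"))
    v_ilp = covered_population(
        cov, scenario_maxcover_exact(cov, k, mode="ilp"))
    assert v_ilp == pytest.approx(v_ex)


def test_greedy_nested_across_k():
    rng = np.random.default_rng(7)
    cov = _random_instance(rng)
    prev: set = set()
    for k in range(1, cov.n_hospitals + 1):
        cur = set(scenario_maxcover_greedy(cov, k).hospital_ids)
        assert prev <= cur
        prev = cur


def test_exhaustive_capacity_guard():
    rng = np.random.default_rng(0)
    cover = rng.random((5, 30)) < 0.3
    cov = _cov(cover, np.ones(5))
    with pytest.raises(CapacityError):
        scenario_maxcover_exact(cov, 3, mode="exhaustive")


# --- fixed designation set -------------------------------------------------

def test_fixed_set_matches_national_designation_counts():
    """A generator parameterized to the national composition (95 general +
    279 regional PMCs + 31 academic of 1075) yields a 405-facility set."""
    cfg = SyntheticConfig(seed=2, region_width_km=110, region_height_km=90,
                          n_msas=10, municipalities_per_msa=5,
                          total_female_pop=2_000_000, n_hospitals=1075,
                          n_general_pmc=95, n_regional_pmc=279, n_academic=31)
    geo = generate_geography(cfg)
    rs = scenario_fixed(geo.hospitals)
    assert len(rs) == 405


def test_fixed_empty_and_full_designation_sets():
    hosp = _hospitals([_h("a", 0, 60, "general_pmc"),
                       _h("b", 0, 10, "other"),
                       _h("c", 1, 5, "academic")])
    assert scenario_fixed(hosp, ()).hospital_ids == ()
    assert len(scenario_fixed(
        hosp, ("general_pmc", "regional_pmc", "academic", "other"))) == 3
    assert scenario_fixed(hosp).hospital_ids == ("a", "c")
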