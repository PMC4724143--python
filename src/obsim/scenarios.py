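"""Retained-facility selection under the intensification scenarios.

Three closure policies are modelled, each producing the set of hospitals
kept open at a target size k:

* **S1 (volume)** — keep the k hospitals with the most deliveries per month,
  ignoring administrative boundaries.
* **S2 (MSA + volume)** — first guarantee the highest-volume hospital of
  every medical service area a slot, then fill the remainder by volume.
* **S3 (max-cover)** — the maximal covering location problem (MCLP): choose
  k hospitals maximizing the female population 15-49 within the drive-time
  threshold of at least one of them.  Greedy (1 - 1/e guarantee) and exact
  (exhaustive enumeration, or MILP via HiGHS) modes are provided.

A fixed-designation policy keeps every hospital of the given designations
(the academic + perinatal-medical-center set), whatever its volume.

All ties break by ascending hospital id so every selection is reproducible.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .access import AccessMatrix, THRESHOLD_NEAR_MIN
from .errors import CapacityError, DataError

__all__ = [
    "RetainedSet",
    "CoverageSets",
    "scenario_volume",
    "scenario_msa_volume",
    "build_coverage_sets",
    "scenario_maxcover_greedy",
    "scenario_maxcover_exact",
    "scenario_fixed",
    "covered_population",
    "SCENARIO_LABELS",
]

SCENARIO_LABELS = ("S1_volume", "S2_msa_volume", "S3_maxcover_greedy",
                   "S3_maxcover_exact", "FIXED_designation")

EXHAUSTIVE_MAX_CANDIDATES = 25
EXHAUSTIVE_MAX_SUBSETS = 2_000_000


@dataclass(frozen=True)
class RetainedSet:
    """A scenario's chosen facilities at target size k (selection order
    preserved; ids unique, subset of the baseline)."""

    scenario_label: str
    target_k: int
    hospital_ids: tuple

    def __len__(self) -> int:
        return len(self.hospital_ids)


def _volume_order(hospitals: pd.DataFrame) -> pd.DataFrame:
    """Hospitals sorted by descending deliveries, ties by ascending id."""
    return hospitals.sort_values(
        ["deliveries_per_month", "id"], ascending=[False, True],
        kind="stable")


def _check_k(k: int, n: int, label: str) -> int:
    if k < 1:
        raise DataError(f"{label}: target k must be >= 1")
    if k > n:
        warnings.warn(
            f"{label}: target k={k} exceeds {n} baseline hospitals; "
            "retaining all", stacklevel=3)
        return n
    return k


def scenario_volume(hospitals: pd.DataFrame, k: int) -> RetainedSet:
    """S1: the k highest-volume hospitals; nested across k."""
    kk = _check_k(k, len(hospitals), "S1_volume")
    ids = tuple(_volume_order(hospitals)["id"].head(kk))
    return RetainedSet("S1_volume", k, ids)


def scenario_msa_volume(hospitals: pd.DataFrame, k: int) -> RetainedSet:
    """S2: one slot per hospital-bearing MSA first, then fill by volume.

    Stage 1 marks each MSA's highest-volume hospital (ties -> lowest id);
    stage 2 adds the globally highest-volume unmarked hospitals.  If k is
    smaller than the number of hospital-bearing MSAs, the k highest-volume
    MSA representatives are kept with a warning.
    """
    kk = _check_k(k, len(hospitals), "S2_msa_volume")
    ordered = _volume_order(hospitals)
    reps = ordered.drop_duplicates("msa_id")  # first per MSA = its top
    if kk < len(reps):
        warnings.warn(
            f"S2_msa_volume: k={kk} below the {len(reps)} hospital-bearing "
            "MSAs; keeping the highest-volume MSA representatives",
            stacklevel=2)
        ids = tuple(reps["id"].head(kk))
        return RetainedSet("S2_msa_volume", k, ids)
    marked = set(reps["id"])
    fill = ordered[~ordered["id"].isin(marked)]["id"].head(kk - len(reps))
    chosen = set(reps["id"]) | set(fill)
    # report in global volume order for a stable, meaningful ranking
    ids = tuple(ordered[ordered["id"].isin(chosen)]["id"])
    return RetainedSet("S2_msa_volume", k, ids)


def scenario_fixed(hospitals: pd.DataFrame,
                   designations: Iterable[str] = ("general_pmc",
                                                  "regional_pmc",
                                                  "academic")) -> RetainedSet:
    """Keep every hospital with one of the given designations, in id order."""
    wanted = set(designations)
    kept = hospitals[hospitals["designation"].isin(wanted)].sort_values("id")
    ids = tuple(kept["id"])
    return RetainedSet("FIXED_designation", len(ids), ids)


# ---------------------------------------------------------------------------
# maximal covering location problem
# ---------------------------------------------------------------------------

@dataclass
class CoverageSets:
    """Per-hospital 30-min coverage sets in matrix form.

    ``cover[c, h]`` is True iff cell c lies within ``threshold_min`` of
    hospital h; ``weights[c]`` is the cell's female population.  Hospital
    columns are ordered by ascending id (tie-break order of the solvers).
    """

    cover: np.ndarray          # bool, (n_cells, n_hospitals)
    weights: np.ndarray        # float, (n_cells,)
    cell_ids: np.ndarray
    hospital_ids: np.ndarray
    threshold_min: float

    @property
    def n_hospitals(self) -> int:
        return self.cover.shape[1]

    def covered_weight(self, columns: Sequence[int]) -> float:
        if len(columns) == 0:
            return 0.0
        mask = self.cover[:, list(columns)].any(axis=1)
        return float(self.weights[mask].sum())


def build_coverage_sets(matrix: AccessMatrix, cells: pd.DataFrame,
                        threshold_min: float = THRESHOLD_NEAR_MIN
                        ) -> CoverageSets:
    """Threshold the drive-time matrix: cell c is in hospital h's set iff
    minutes[c, h] <= threshold (inclusive; unreachable cells in no set)."""
    order = np.argsort(matrix.hospital_ids, kind="stable")
    cover = matrix.minutes[:, order] <= threshold_min
    pop = cells.set_index("id")["female_pop_15_49"]
    weights = pop.loc[matrix.cell_ids].to_numpy(dtype=float)
    return CoverageSets(cover=cover, weights=weights,
                        cell_ids=matrix.cell_ids,
                        hospital_ids=matrix.hospital_ids[order],
                        threshold_min=threshold_min)


def covered_population(cov: CoverageSets, retained: RetainedSet | Iterable
                       ) -> float:
    """Population within threshold of at least one retained hospital."""
    ids = getattr(retained, "hospital_ids", retained)
    lookup = {h: j for j, h in enumerate(cov.hospital_ids)}
    try:
        cols = [lookup[h] for h in ids]
    except KeyError as exc:
        raise DataError(f"unknown hospital id {exc.args[0]!r}") from exc
    return cov.covered_weight(cols)


def scenario_maxcover_greedy(cov: CoverageSets, k: int) -> RetainedSet:
    """S3, greedy: repeatedly add the hospital with the largest marginal
    newly-covered population (ties -> smallest id).  Nested across k and
    within a factor 1 - 1/e of the optimum (submodular maximization)."""
    kk = _check_k(k, cov.n_hospitals, "S3_maxcover_greedy")
    uncovered = cov.weights.astype(float).copy()
    selected: list[int] = []
    available = np.ones(cov.n_hospitals, dtype=bool)
    for _ in range(kk):
        gains = uncovered @ cov.cover
        gains[~available] = -1.0
        j = int(np.argmax(gains))  # argmax returns first = smallest id
        selected.append(j)
        available[j] = False
        uncovered[cov.cover[:, j]] = 0.0
    ids = tuple(cov.hospital_ids[j] for j in selected)
    return RetainedSet("S3_maxcover_greedy", k, ids)


def scenario_maxcover_exact(cov: CoverageSets, k: int,
                            mode: str = "auto") -> RetainedSet:
    """S3, exact: a k-subset attaining the maximum covered population.

    ``mode``: ``"exhaustive"`` enumerates all k-subsets (guarded to <= 25
    candidates and a bounded subset count; returns the lexicographically
    smallest optimum), ``"ilp"`` solves the standard MCLP integer program
    with HiGHS, ``"auto"`` picks exhaustive when feasible, else ILP.
    """
    kk = _check_k(k, cov.n_hospitals, "S3_maxcover_exact")
    n = cov.n_hospitals
    n_subsets = math.comb(n, kk)
    if mode == "auto":
        mode = ("exhaustive"
                if n <= EXHAUSTIVE_MAX_CANDIDATES
                and n_subsets <= EXHAUSTIVE_MAX_SUBSETS else "ilp")
    if mode == "exhaustive":
        if n > EXHAUSTIVE_MAX_CANDIDATES or n_subsets > EXHAUSTIVE_MAX_SUBSETS:
            raise CapacityError(
                f"exhaustive MCLP infeasible for n={n}, k={kk} "
                f"({n_subsets} subsets); use ilp mode")
        cols = _exact_exhaustive(cov, kk)
    elif mode == "ilp":
        cols = _exact_ilp(cov, kk)
    else:
        raise DataError(f"unknown exact mode {mode!r}")
    ids = tuple(cov.hospital_ids[j] for j in cols)
    return RetainedSet("S3_maxcover_exact", k, ids)


def _exact_exhaustive(cov: CoverageSets, k: int) -> tuple[int, ...]:
    # combinations iterate in lexicographic id order; only strictly better
    # values replace the incumbent, so the first optimum found is the
    # lexicographically smallest
    best_val = -1.0
    best: tuple[int, ...] = ()
    for combo in itertools.combinations(range(cov.n_hospitals), k):
        val = cov.covered_weight(combo)
        if val > best_val:
            best_val = val
            best = combo
    return best


def _exact_ilp(cov: CoverageSets, k: int) -> tuple[int, ...]:
    """MCLP integer program: binary select x_h and cover y_c variables,
    y_c <= sum of x_h over hospitals covering c, sum x_h = k, maximize
    sum pop_c * y_c."""
    from scipy import sparse
    from scipy.optimize import LinearConstraint, milp

    n = cov.n_hospitals
    # only cells with weight and at least one covering hospital matter
    coverable = cov.cover.any(axis=1) & (cov.weights > 0)
    cover = cov.cover[coverable]
    w = cov.weights[coverable]
    m = cover.shape[0]
    # variables: x (n) then y (m)
    c_obj = np.concatenate([np.zeros(n), -w])
    rows_a = sparse.hstack(
        [sparse.csr_matrix(-cover.astype(float)), sparse.eye(m, format="csr")])
    cons = [
        LinearConstraint(rows_a, -np.inf, 0.0),
        LinearConstraint(
            sparse.csr_matrix(np.concatenate([np.ones(n), np.zeros(m)])),
            k, k),
    ]
    from scipy.optimize import Bounds
    res = milp(c_obj, constraints=cons, integrality=np.ones(n + m),
               bounds=Bounds(0, 1))
    if not res.success:
        raise CapacityError(f"MILP solver failed: {res.message}")
    x = np.round(res.x[:n]).astype(bool)
    cols = list(np.flatnonzero(x))
    # numerical safety: pad/trim to exactly k
    if len(cols) > k:
        cols = cols[:k]
    j = 0
    while len(cols) < k and j < n:
        if j not in cols:
            cols.append(j)
        j += 1
    return tuple(sorted(cols))
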