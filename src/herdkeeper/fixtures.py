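"""Synthetic pedigree generators with ground-truth side records.

The generator builds a multi-generation pedigree forward in time with known
demography (litters per year, litter-size distribution, sire skew, optional
subpopulations) and records the truth — births, litters, top-sire fractions,
generation intervals, mean inbreeding per year — while generating, so tests
of the monitoring tables never depend on the code under test.  The truth
inbreeding values are computed with the O(n^2) tabular relationship-matrix
recursion, an implementation independent of the production ancestor-tracing
algorithm.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .pedigree_io import PedigreeRecord, Sex, write_pedigree

__all__ = [
    "FixtureSpec",
    "tabular_relationship_matrix",
    "generate_pedigree",
    "random_pedigree",
    "classic_pedigrees",
]


@dataclass
class FixtureSpec:
    years: int = 5
    dams_per_year: int = 4
    litter_size_dist: dict[int, float] = field(default_factory=lambda: {2: 1.0})
    sires_per_year: int = 2
    sire_skew: float = 0.0  # probability a litter goes to the designated top sire
    founder_males: int = 4
    founder_females: int = 8
    n_subpops: int = 1
    seed: int = 0


def tabular_relationship_matrix(
    sire_idx: np.ndarray, dam_idx: np.ndarray
) -> np.ndarray:
    """Numerator relationship matrix by the recursive tabular method.

    ``sire_idx``/``dam_idx`` are 0-based positions into a sorted pedigree
    (-1 = unknown).  a_ij = (a_{i,sire(j)} + a_{i,dam(j)}) / 2 for i < j and
    a_jj = 1 + a_{sire(j),dam(j)} / 2.  O(n^2); the brute-force oracle.
    """
    n = len(sire_idx)
    A = np.zeros((n, n))
    for j in range(n):
        s, d = sire_idx[j], dam_idx[j]
        if s >= 0 and d >= 0:
            A[j, j] = 1.0 + 0.5 * A[s, d]
        else:
            A[j, j] = 1.0
        for i in range(j):
            val = 0.0
            if s >= 0:
                val += 0.5 * A[i, s]
            if d >= 0:
                val += 0.5 * A[i, d]
            A[i, j] = A[j, i] = val
    return A


def _records_to_indices(records: list[PedigreeRecord]) -> tuple[np.ndarray, np.ndarray]:
    pos = {r.animal_id: i for i, r in enumerate(records)}
    sire = np.array(
        [pos[r.sire_id] if r.sire_id is not None else -1 for r in records]
    )
    dam = np.array(
        [pos[r.dam_id] if r.dam_id is not None else -1 for r in records]
    )
    return sire, dam


def generate_pedigree(
    spec: FixtureSpec,
    path: str | Path | None = None,
    truth_path: str | Path | None = None,
    compute_f_truth: bool | None = None,
) -> tuple[list[PedigreeRecord], dict]:
    """Generate a pedigree and its truth record; optionally write both.

    ``compute_f_truth`` defaults to True for pedigrees up to 2000 animals
    (the tabular oracle is quadratic).  Runs are reproducible from the seed
    and the written files are byte-identical across repeats.
    """
    rng = np.random.default_rng(spec.seed)
    records: list[PedigreeRecord] = []
    males: list[tuple[str, int]] = []  # (id, birth_year)
    females: list[tuple[str, int]] = []
    counter = 0

    def new_id() -> str:
        nonlocal counter
        counter += 1
        return f"X{counter:05d}"

    for k in range(spec.founder_males):
        aid = new_id()
        records.append(PedigreeRecord(aid, None, None, Sex.MALE, 2000,
                                      subpop=_sub(spec, k)))
        males.append((aid, 2000))
    for k in range(spec.founder_females):
        aid = new_id()
        records.append(PedigreeRecord(aid, None, None, Sex.FEMALE, 2000,
                                      subpop=_sub(spec, k)))
        females.append((aid, 2000))

    sizes = np.array(sorted(spec.litter_size_dist))
    size_cum = np.cumsum([spec.litter_size_dist[int(s)] for s in sizes])

    truth = {
        "births_by_year": {},
        "litters_by_year": {},
        "top_sire_fractions": {},
        "generation_interval": {},
    }
    for year in range(2001, 2001 + spec.years):
        sire_pool = [m for m in males if m[1] < year]
        dam_pool = [f for f in females if f[1] < year]
        designated = sire_pool[0] if sire_pool else None
        rng.shuffle(dam_pool)
        active_sires = sire_pool[-spec.sires_per_year:]
        n_litters = min(spec.dams_per_year, len(dam_pool))
        births = {"male": 0, "female": 0}
        sire_counts: dict[str, int] = {}
        age_sum, age_n = 0.0, 0
        for li in range(n_litters):
            dam = dam_pool[li]
            if designated is not None and rng.random() < spec.sire_skew:
                sire = designated
            else:
                sire = active_sires[int(rng.integers(len(active_sires)))]
            size = int(sizes[np.searchsorted(size_cum, rng.random(), "right")])
            for _ in range(size):
                sex = Sex.MALE if rng.integers(2) == 0 else Sex.FEMALE
                aid = new_id()
                records.append(
                    PedigreeRecord(
                        aid, sire[0], dam[0], sex, year,
                        subpop=_sub(spec, counter),
                    )
                )
                births["male" if sex == Sex.MALE else "female"] += 1
                (males if sex == Sex.MALE else females).append((aid, year))
            sire_counts[sire[0]] = sire_counts.get(sire[0], 0) + size
            age_sum += (year - sire[1]) * size + (year - dam[1]) * size
            age_n += 2 * size
        total = births["male"] + births["female"]
        truth["births_by_year"][year] = {**births, "total": total}
        truth["litters_by_year"][year] = n_litters
        if total:
            fracs = sorted(
                ((c / total, s) for s, c in sire_counts.items()),
                key=lambda t: (-t[0], t[1]),
            )
            truth["top_sire_fractions"][year] = [f for f, _ in fracs]
        if age_n:
            truth["generation_interval"][year] = age_sum / age_n

    if compute_f_truth is None:
        compute_f_truth = len(records) <= 2000
    if compute_f_truth:
        sire_idx, dam_idx = _records_to_indices(records)
        A = tabular_relationship_matrix(sire_idx, dam_idx)
        F = np.diag(A) - 1.0
        mean_f = {}
        for year in range(2000, 2001 + spec.years):
            sel = [i for i, r in enumerate(records) if r.birth_year == year]
            if sel:
                mean_f[year] = float(F[sel].mean())
        truth["mean_F_by_year"] = mean_f

    if path is not None:
        write_pedigree(records, path)
    if truth_path is not None:
        Path(truth_path).write_text(
            json.dumps({"spec": asdict(spec), "truth": truth}, indent=2, sort_keys=True)
        )
    return records, truth


def _sub(spec: FixtureSpec, k: int) -> str | None:
    if spec.n_subpops <= 1:
        return None
    return f"S{k % spec.n_subpops + 1}"


def random_pedigree(
    n: int, seed: int, p_founder: float = 0.25, with_years: bool = True
) -> list[PedigreeRecord]:
    """A random acyclic pedigree of n animals (founder or random earlier parents)."""
    rng = np.random.default_rng(seed)
    records: list[PedigreeRecord] = []
    males: list[int] = []
    females: list[int] = []
    for i in range(n):
        sex = Sex.MALE if rng.integers(2) == 0 else Sex.FEMALE
        year = 2000 + i // max(n // 10, 1) if with_years else None
        if not males or not females or rng.random() < p_founder:
            rec = PedigreeRecord(f"R{i:04d}", None, None, sex, year)
        else:
            sire = males[int(rng.integers(len(males)))]
            dam = females[int(rng.integers(len(females)))]
            rec = PedigreeRecord(
                f"R{i:04d}", f"R{sire:04d}", f"R{dam:04d}", sex, year
            )
        records.append(rec)
        (males if sex == Sex.MALE else females).append(i)
    return records


def classic_pedigrees() -> dict[str, list[PedigreeRecord]]:
    """Small named pedigrees with analytically known inbreeding/kinship.

    - ``fullsib``: mating of two full sibs; child F = 1/4.
    - ``halfsib``: mating of two paternal half sibs; child F = 1/8.
    - ``parent_offspring``: sire mated to his own daughter; child F = 1/4.
    - ``three_gen``: three loopless generations, all F = 0.
    - ``loop``: two animals that are each other's sire (topological error).
    """
    M, F_, U = Sex.MALE, Sex.FEMALE, None

    def rec(aid, s, d, sex, y):
        return PedigreeRecord(aid, s, d, sex, y)

    return {
        "fullsib": [
            rec("A", U, U, M, 2000), rec("B", U, U, F_, 2000),
            rec("S1", "A", "B", M, 2001), rec("S2", "A", "B", F_, 2001),
            rec("X", "S1", "S2", M, 2002),
        ],
        "halfsib": [
            rec("A", U, U, M, 2000), rec("B", U, U, F_, 2000),
            rec("C", U, U, F_, 2000),
            rec("H1", "A", "B", M, 2001), rec("H2", "A", "C", F_, 2001),
            rec("X", "H1", "H2", F_, 2002),
        ],
        "parent_offspring": [
            rec("A", U, U, M, 2000), rec("B", U, U, F_, 2000),
            rec("D", "A", "B", F_, 2001),
            rec("X", "A", "D", M, 2002),
        ],
        "three_gen": [
            rec("A", U, U, M, 2000), rec("B", U, U, F_, 2000),
            rec("C", U, U, M, 2000), rec("D", U, U, F_, 2000),
            rec("E", "A", "B", M, 2001), rec("F", "C", "D", F_, 2001),
            rec("G", "E", "F", F_, 2002),
        ],
        "loop": [
            rec("A", "B", U, M, 2000),
            rec("B", "A", U, M, 2000),
            rec("C", "A", U, M, 2001),
        ],
    }
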