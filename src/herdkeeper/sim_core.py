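"""Individual-based stochastic simulator of a constant-size captive population.

The simulated unit of time is one breeding cycle, called a year.  The
population consists of one or more subpopulations, each with fixed numbers of
breeding males and females distributed over age classes.  Every year the
cycle is: mating and birth, evaluation (recording), migration between
subpopulations, then culling and replacement of culled animals by this year's
newborns so that the configured age structure is restored.  Pairwise kinship
is carried as a live symmetric matrix over the current animals (rows and
columns are deleted when an animal dies), so memory scales with the census
size, not with the number of simulated years: a newborn's inbreeding equals
the kinship of its parents and its kinship with any animal x is the mean of
its parents' kinships with x.

Reproduction is litter-based: for each litter a dam is drawn uniformly
without replacement from the eligible breeding females (one litter per female
per year), the sire's subpopulation comes from the fertilization matrix, and
the sire is drawn uniformly among eligible males — except that designated top
sires are used first until they reach their configured contribution.  Litter
sizes follow the configured distribution and newborn sexes are independent
fair coin flips.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from typing import Sequence

import numpy as np
import pandas as pd

from . import rates as rates_mod
from .genome import FrequencyTrack, GenomeSpec, init_genomes, meiosis, survival_probability
from .management import (
    ManagementPolicy,
    cap_selected_sons,
    eligible_parents,
    optimal_contributions_allocate,
    pick_sire,
)
from .pedigree_io import Pedigree, PedigreeRecord, Sex, topological_sort

__all__ = [
    "SubpopSpec",
    "MatrixSchedule",
    "SimConfig",
    "PopulationState",
    "YearRecord",
    "RunOutput",
    "largest_remainder",
    "init_founders",
    "seed_founders_from_real",
    "make_litters",
    "migrate",
    "age_cull_replace",
    "run_simulation",
    "newborn_f_trajectories",
]

MALE, FEMALE = 0, 1


def largest_remainder(total: int, weights: Sequence[float]) -> np.ndarray:
    """Integer apportionment of ``total`` by the largest-remainder rule."""
    w = np.asarray(weights, dtype=float)
    if w.sum() <= 0:
        out = np.zeros(len(w), dtype=np.int64)
        return out
    quota = total * w / w.sum()
    base = np.floor(quota).astype(np.int64)
    rem = total - base.sum()
    if rem > 0:
        # stable: larger remainder first, earlier class on ties
        order = np.lexsort((np.arange(len(w)), -(quota - base)))
        base[order[:rem]] += 1
    return base


@dataclass
class SubpopSpec:
    males: int
    females: int


@dataclass
class MatrixSchedule:
    """A yearly-cycled schedule of square subpopulation matrices.

    ``kind`` is "probability" (each cell: per-animal/litter probability) or
    "count" (each cell: exact number).  For migration the diagonal means
    "stay" (written ``*`` in config files) and ``ages``/``sexes`` optionally
    restrict which animals are exposed.  When several matrices are given they
    are used consecutively over the years, wrapping around.
    """

    matrices: list[np.ndarray]
    kind: str = "probability"
    ages: list[int] | None = None
    sexes: list[str] | None = None

    def at_year(self, year: int) -> np.ndarray:
        # years are 1-based; year 1 uses the first matrix
        return self.matrices[(year - 1) % len(self.matrices)]

    def validate(self, n_subpops: int, is_migration: bool) -> list[str]:
        issues = []
        if self.kind not in ("probability", "count"):
            issues.append(f"matrix kind must be probability or count: {self.kind}")
        for k, m in enumerate(self.matrices):
            m = np.asarray(m, dtype=float)
            if m.shape != (n_subpops, n_subpops):
                issues.append(
                    f"matrix {k} has shape {m.shape}, expected "
                    f"({n_subpops}, {n_subpops})"
                )
                continue
            off = m.copy()
            if is_migration:
                np.fill_diagonal(off, 0.0)
            if (off < 0).any():
                issues.append(f"matrix {k} has negative cells")
            if self.kind == "probability":
                if is_migration:
                    if (off.sum(axis=1) > 1 + 1e-9).any():
                        issues.append(
                            f"migration matrix {k}: off-diagonal row sums exceed 1"
                        )
                elif (m.sum(axis=1) > 1 + 1e-9).any():
                    issues.append(f"matrix {k}: probability row sums exceed 1")
        return issues


@dataclass
class SimConfig:
    """All simulator inputs.

    ``litters_per_year`` is the total over subpopulations; litters are
    allocated to subpopulations proportionally to their breeding females
    (every subpopulation shares the same female-to-litter ratio), by the
    largest-remainder rule.  ``top_sires = (count, fraction)`` designates
    males that are used first each year until together they have sired
    ``ceil(fraction * litters)`` litters.
    """

    years: int
    subpops: list[SubpopSpec]
    litters_per_year: int
    litter_size_dist: dict[int, float]
    male_age_dist: Sequence[float] = (1.0,)
    female_age_dist: Sequence[float] = (1.0,)
    runs: int = 1
    random_seed: int | None = None
    top_sires: tuple[int, float] | None = None
    fertilization: MatrixSchedule | None = None
    migration: MatrixSchedule | None = None
    genome: GenomeSpec | None = None
    policy: ManagementPolicy = dc_field(default_factory=ManagementPolicy)
    record_pedigree: bool = False
    track_all_loci: bool = False

    def validate(self) -> list[str]:
        issues = []
        if self.years < 1:
            issues.append("years must be at least 1")
        if self.runs < 1:
            issues.append("runs must be at least 1")
        if not self.subpops:
            issues.append("at least one subpopulation is required")
        for i, sp in enumerate(self.subpops):
            if sp.males < 0 or sp.females < 0:
                issues.append(f"subpop {i}: negative breeding numbers")
            if sp.females == 0 and self.litters_per_year > 0:
                issues.append(
                    f"subpop {i}: no breeding females but litters expected"
                )
        if self.litters_per_year < 0:
            issues.append("litters_per_year must be non-negative")
        if abs(sum(self.litter_size_dist.values()) - 1.0) > 1e-9:
            issues.append("litter_size_dist probabilities must sum to 1")
        if any(s < 1 for s in self.litter_size_dist):
            issues.append("litter sizes must be at least 1")
        for name, dist in (
            ("male_age_dist", self.male_age_dist),
            ("female_age_dist", self.female_age_dist),
        ):
            if abs(sum(dist) - 1.0) > 1e-9:
                issues.append(f"{name} must sum to 1")
            if any(p < 0 for p in dist):
                issues.append(f"{name} has negative entries")
        if self.top_sires is not None:
            count, contrib = self.top_sires
            if count < 0:
                issues.append("top_sires count must be non-negative")
            if not 0.0 <= contrib <= 1.0:
                issues.append("top_sires contribution must be in [0, 1]")
        n = len(self.subpops)
        if self.fertilization is not None:
            issues += self.fertilization.validate(n, is_migration=False)
        if self.migration is not None:
            issues += self.migration.validate(n, is_migration=True)
        if self.genome is not None:
            issues += self.genome.validate()
        issues += self.policy.validate()
        return issues


@dataclass
class YearRecord:
    year: int
    size: int
    litters_born: int
    births: int
    mean_age: float
    mean_F_newborn: float
    mean_F_selected: float
    mean_kinship_incl_self: float
    mean_kinship_excl_self: float
    mean_f_newborn_incl_self: float
    extinct: bool
    size_by_subpop: list[int]
    births_by_subpop: list[int]
    mean_F_newborn_by_subpop: list[float]


class PopulationState:
    """Live animals with their pairwise-kinship store and optional genomes."""

    def __init__(self, config: SimConfig, rng: np.random.Generator):
        self.config = config
        self.rng = rng
        self.year = 0
        self.next_uid = 1
        n0 = 0
        self.uid = np.empty(n0, dtype=np.int64)
        self.sex = np.empty(n0, dtype=np.int8)
        self.age = np.empty(n0, dtype=np.int64)
        self.subpop = np.empty(n0, dtype=np.int64)
        self.breeding = np.empty(n0, dtype=bool)
        self.litters_year = np.empty(n0, dtype=np.int64)
        self.litters_life = np.empty(n0, dtype=np.int64)
        self.K = np.empty((n0, n0))
        self.genomes: np.ndarray | None = (
            np.empty((n0, 2, config.genome.n_loci), dtype=np.uint8)
            if config.genome
            else None
        )
        self.sons_selected: dict[int, int] = {}
        self.top_sire_uids: set[int] = set()
        self.pedigree_log: list[tuple[int, int, int, int, int]] = []
        # (uid, sire_uid, dam_uid, sex, birth_year); 0 = unknown parent
        self.F_log: dict[int, float] = {}  # uid -> F at creation (bookkeeping)

    # -- derived quantities -------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.uid)

    @property
    def F(self) -> np.ndarray:
        return 2.0 * np.diag(self.K) - 1.0

    def mean_kinship(self) -> np.ndarray:
        """Per-animal mean kinship with all living animals (incl. itself)."""
        return self.K.mean(axis=1)

    def population_mean_kinship(self, include_self: bool = True) -> float:
        n = self.n
        if n == 0:
            return math.nan
        total = float(self.K.sum())
        if include_self:
            return total / (n * n)
        if n < 2:
            return math.nan
        return (total - float(np.trace(self.K))) / (n * (n - 1))

    # -- mutation -----------------------------------------------------------
    def add_animals(
        self,
        sexes: np.ndarray,
        ages: np.ndarray,
        subpops: np.ndarray,
        K_rows: np.ndarray,
        K_diag: np.ndarray,
        breeding: bool | np.ndarray,
        genomes: np.ndarray | None,
        sires: np.ndarray | None = None,
        dams: np.ndarray | None = None,
    ) -> np.ndarray:
        """Append animals; K_rows has shape (n_new, n_old) and K_diag (n_new,).

        The kinship block among the new animals themselves is derived from
        parent rows when ``sires``/``dams`` (old-animal indices, -1 unknown)
        are given, else new animals are mutually unrelated.
        """
        m = len(sexes)
        old = self.n
        uids = np.arange(self.next_uid, self.next_uid + m, dtype=np.int64)
        self.next_uid += m
        K_new = np.empty((old + m, old + m))
        K_new[:old, :old] = self.K
        K_new[old:, :old] = K_rows
        K_new[:old, old:] = K_rows.T
        if m:
            if sires is not None:
                # kinship among the newborns: f(a, b) = (f(a, sire_b) + f(a, dam_b)) / 2
                # with the parents old animals, so the whole block comes from K_rows
                block = 0.5 * (K_rows[:, sires] + K_rows[:, dams])
                block = 0.5 * (block + block.T)  # enforce exact float symmetry
            else:
                block = np.zeros((m, m))
            np.fill_diagonal(block, K_diag)
            K_new[old:, old:] = block
        self.K = K_new
        self.uid = np.concatenate([self.uid, uids])
        self.sex = np.concatenate([self.sex, sexes.astype(np.int8)])
        self.age = np.concatenate([self.age, ages.astype(np.int64)])
        self.subpop = np.concatenate([self.subpop, subpops.astype(np.int64)])
        if isinstance(breeding, bool):
            breeding = np.full(m, breeding)
        self.breeding = np.concatenate([self.breeding, breeding])
        self.litters_year = np.concatenate(
            [self.litters_year, np.zeros(m, dtype=np.int64)]
        )
        self.litters_life = np.concatenate(
            [self.litters_life, np.zeros(m, dtype=np.int64)]
        )
        if self.genomes is not None:
            if genomes is None:
                raise ValueError("genome simulation active but no genomes supplied")
            self.genomes = np.concatenate([self.genomes, genomes], axis=0)
        return np.arange(old, old + m)

    def keep(self, mask: np.ndarray) -> None:
        idx = np.nonzero(mask)[0]
        self.uid = self.uid[idx]
        self.sex = self.sex[idx]
        self.age = self.age[idx]
        self.subpop = self.subpop[idx]
        self.breeding = self.breeding[idx]
        self.litters_year = self.litters_year[idx]
        self.litters_life = self.litters_life[idx]
        self.K = self.K[np.ix_(idx, idx)]
        if self.genomes is not None:
            self.genomes = self.genomes[idx]
        self.top_sire_uids &= set(self.uid.tolist())


def _sex_targets(config: SimConfig) -> list[dict[int, np.ndarray]]:
    """Per-subpop, per-sex breeding targets per age class (largest remainder)."""
    out = []
    for sp in config.subpops:
        out.append(
            {
                MALE: largest_remainder(sp.males, config.male_age_dist),
                FEMALE: largest_remainder(sp.females, config.female_age_dist),
            }
        )
    return out


def _carried_targets(targets: np.ndarray) -> np.ndarray:
    """Total animals to carry per age class: max of later breeding targets.

    When an older age class is larger than a younger one, non-breeding
    juveniles must be carried through the younger classes so that enough
    animals are available on aging.
    """
    return np.maximum.accumulate(targets[::-1])[::-1]


def init_founders(config: SimConfig, rng: np.random.Generator) -> PopulationState:
    """Unrelated, non-inbred founders matching the configured age structure."""
    state = PopulationState(config, rng)
    targets = _sex_targets(config)
    sexes, ages, subpops = [], [], []
    for p, per_sex in enumerate(targets):
        for sex, tgt in per_sex.items():
            carried = _carried_targets(tgt)
            for age_class, count in enumerate(carried, start=1):
                sexes += [sex] * int(count)
                ages += [age_class] * int(count)
                subpops += [p] * int(count)
    m = len(sexes)
    genomes = (
        init_genomes(config.genome, m, rng) if config.genome is not None else None
    )
    state.add_animals(
        sexes=np.array(sexes),
        ages=np.array(ages),
        subpops=np.array(subpops),
        K_rows=np.empty((m, 0)),
        K_diag=np.full(m, 0.5),
        breeding=True,
        genomes=genomes,
    )
    # founders with an age structure were born in past years
    for i in range(state.n):
        state.pedigree_log.append(
            (int(state.uid[i]), 0, 0, int(state.sex[i]), -int(state.age[i]))
        )
        state.F_log[int(state.uid[i])] = 0.0
    # mark carried juveniles non-breeding where targets demand it
    for p, per_sex in enumerate(targets):
        for sex, tgt in per_sex.items():
            carried = _carried_targets(tgt)
            for age_class in range(1, len(tgt) + 1):
                extra = int(carried[age_class - 1] - tgt[age_class - 1])
                if extra > 0:
                    pool = np.nonzero(
                        (state.subpop == p)
                        & (state.sex == sex)
                        & (state.age == age_class)
                    )[0]
                    state.breeding[pool[:extra]] = False
    return state


def seed_founders_from_real(
    state: PopulationState,
    real: Sequence[tuple[str, int, float]] | pd.DataFrame,
    real_kinship: np.ndarray | None = None,
) -> PopulationState:
    """Copy inbreeding/kinship of an existing population onto the founders.

    ``real`` lists (sex, age, F) per real animal (sex as "male"/"female");
    ``real_kinship`` optionally gives their pairwise kinship matrix in the
    same order.  Each simulated founder is matched to an unused real animal
    of the same sex and age, then of the same sex and nearest age; matching
    is injective.  Unmatched simulated animals keep F = 0 and kinship 0.
    """
    if isinstance(real, pd.DataFrame):
        rows = list(real[["sex", "age", "F"]].itertuples(index=False, name=None))
    else:
        rows = list(real)
    if not rows:
        return state
    available = list(range(len(rows)))
    match: dict[int, int] = {}
    for i in range(state.n):
        want_sex = "male" if state.sex[i] == MALE else "female"
        best, best_gap = None, None
        for j in available:
            sex, age, _ = rows[j]
            if sex != want_sex:
                continue
            gap = abs(int(age) - int(state.age[i]))
            if best is None or gap < best_gap:
                best, best_gap = j, gap
        if best is not None:
            match[i] = best
            available.remove(best)
    for i, j in match.items():
        state.K[i, i] = 0.5 * (1.0 + float(rows[j][2]))
    if real_kinship is not None:
        for i, j in match.items():
            for i2, j2 in match.items():
                if i != i2:
                    state.K[i, i2] = real_kinship[j, j2]
    return state


def _refresh_top_sires(state: PopulationState, config: SimConfig) -> None:
    if config.top_sires is None:
        return
    count, _ = config.top_sires
    alive = set(state.uid.tolist())
    state.top_sire_uids &= alive
    need = count - len(state.top_sire_uids)
    if need > 0:
        pool = np.nonzero(
            (state.sex == MALE)
            & state.breeding
            & (state.age >= 1)
            & ~np.isin(state.uid, list(state.top_sire_uids))
        )[0]
        if pool.size:
            picked = state.rng.choice(pool, size=min(need, pool.size), replace=False)
            state.top_sire_uids |= {int(state.uid[i]) for i in picked}


@dataclass
class _BirthBatch:
    sires: list[int] = dc_field(default_factory=list)  # old-animal indices
    dams: list[int] = dc_field(default_factory=list)
    sexes: list[int] = dc_field(default_factory=list)
    subpops: list[int] = dc_field(default_factory=list)
    genomes: list[np.ndarray] = dc_field(default_factory=list)
    litters: int = 0
    parent_age_sum: float = 0.0
    parent_age_n: int = 0


def _fertility_ok(
    state: PopulationState, parent: int, config: SimConfig
) -> bool:
    spec = config.genome
    if spec is None or spec._selected.size == 0:
        return True
    counts = state.genomes[parent].sum(axis=0)
    p = survival_probability(counts, spec, state.year, fertility=True)
    return p >= 1.0 or state.rng.random() < p


def make_litters(
    state: PopulationState, config: SimConfig, year: int
) -> np.ndarray:
    """One year of mating and birth; returns the indices of the newborns.

    Fewer litters than configured are produced when eligible dams or sires
    run out (breeding restrictions or sex-ratio accidents); failed fertility
    draws also consume their litter slot.
    """
    rng = state.rng
    policy = config.policy
    state.litters_year[:] = 0
    _refresh_top_sires(state, config)

    n_sub = len(config.subpops)
    females_per_sub = np.array([sp.females for sp in config.subpops], dtype=float)
    litters_per_sub = largest_remainder(config.litters_per_year, females_per_sub)

    sizes = np.array(sorted(config.litter_size_dist), dtype=np.int64)
    size_p = np.array([config.litter_size_dist[int(s)] for s in sizes])
    size_cum = np.cumsum(size_p)

    quota_left = 0
    if config.top_sires is not None:
        count, contrib = config.top_sires
        if count > 0 and contrib > 0:
            quota_left = math.ceil(contrib * int(litters_per_sub.sum()))

    fert = config.fertilization
    fert_matrix = fert.at_year(year) if fert is not None else None
    fert_counts = (
        np.asarray(fert_matrix, dtype=float).copy()
        if fert is not None and fert.kind == "count"
        else None
    )

    batch = _BirthBatch()
    oc_quota: dict[int, np.ndarray] | None = None
    oc_sires: dict[int, np.ndarray] = {}

    eligible_m = {
        p: eligible_parents(state, policy, "male", p) for p in range(n_sub)
    }
    for p in range(n_sub):
        n_litters = int(litters_per_sub[p])
        if n_litters == 0:
            continue
        dams_pool = eligible_parents(state, policy, "female", p)
        dams_order = rng.permutation(dams_pool)
        litter_sizes = sizes[
            np.searchsorted(size_cum, rng.random(n_litters), side="right")
        ]
        if policy.optimal_contributions and eligible_m[p].size:
            planned = dams_order[:n_litters]
            alloc = optimal_contributions_allocate(
                state, eligible_m[p], planned, n_litters
            )
            oc_quota = oc_quota or {}
            oc_quota[p] = alloc.copy()
            oc_sires[p] = eligible_m[p]
        for li in range(n_litters):
            if li >= len(dams_order):
                break  # not enough eligible dams; fewer litters this year
            dam = int(dams_order[li])
            # sire subpopulation
            sire_sub = p
            if fert_matrix is not None:
                if fert_counts is not None:
                    row = fert_counts[p]
                    choices = np.nonzero(row > 0)[0]
                    if choices.size:
                        sire_sub = int(choices[0])
                        fert_counts[p, sire_sub] -= 1
                else:
                    r = rng.random()
                    acc = 0.0
                    for q in range(n_sub):
                        acc += fert_matrix[p, q]
                        if r < acc:
                            sire_sub = q
                            break
            candidates = eligible_m[sire_sub]
            if policy.max_litters_per_sire_year is not None:
                candidates = candidates[
                    state.litters_year[candidates] < policy.max_litters_per_sire_year
                ]
            sire = None
            if oc_quota is not None and sire_sub in oc_sires:
                pool = oc_sires[sire_sub]
                left = oc_quota[sire_sub]
                open_m = np.nonzero(left > 0)[0]
                open_m = [m for m in open_m if pool[m] in candidates]
                if open_m:
                    pick = pick_sire(
                        state, dam, np.array([pool[m] for m in open_m]), policy, rng
                    )
                    if pick is not None:
                        sire = pick
                        left[int(np.nonzero(pool == sire)[0][0])] -= 1
            if sire is None and quota_left > 0 and state.top_sire_uids:
                tops = np.nonzero(np.isin(state.uid, list(state.top_sire_uids)))[0]
                tops = tops[np.isin(tops, candidates)]
                if tops.size:
                    sire = pick_sire(state, dam, tops, policy, rng)
                    if sire is not None:
                        quota_left -= 1
            if sire is None:
                pool = candidates
                if config.top_sires is not None and state.top_sire_uids:
                    # the designated contribution is a hard cap: once it is
                    # reached, remaining litters go to the other males
                    rest = pool[
                        ~np.isin(state.uid[pool], list(state.top_sire_uids))
                    ]
                    if rest.size:
                        pool = rest
                sire = pick_sire(state, dam, pool, policy, rng)
            if sire is None:
                continue  # no eligible sire: litter skipped
            if not (
                _fertility_ok(state, sire, config)
                and _fertility_ok(state, dam, config)
            ):
                continue  # failed conception consumes the litter slot
            state.litters_year[dam] += 1
            state.litters_life[dam] += 1
            state.litters_year[sire] += 1
            state.litters_life[sire] += 1
            batch.litters += 1
            batch.parent_age_sum += float(state.age[sire] + state.age[dam])
            batch.parent_age_n += 2
            litter_size = int(litter_sizes[li])
            born_sexes = rng.integers(0, 2, litter_size)
            for sx in born_sexes:
                genome = None
                if config.genome is not None:
                    genome = np.stack(
                        [
                            meiosis(state.genomes[sire], config.genome, rng),
                            meiosis(state.genomes[dam], config.genome, rng),
                        ]
                    )
                    counts = genome.sum(axis=0)
                    p_surv = survival_probability(
                        counts, config.genome, year, fertility=False
                    )
                    if p_surv < 1.0 and rng.random() >= p_surv:
                        continue  # newborn does not survive
                batch.sires.append(sire)
                batch.dams.append(dam)
                batch.sexes.append(int(sx))
                batch.subpops.append(p)
                if genome is not None:
                    batch.genomes.append(genome)

    m = len(batch.sires)
    state._year_litters = batch.litters
    state._year_parent_age = (
        batch.parent_age_sum / batch.parent_age_n if batch.parent_age_n else math.nan
    )
    if m == 0:
        state._newborn_idx = np.empty(0, dtype=np.int64)
        state._newborn_sire_uid = np.empty(0, dtype=np.int64)
        return state._newborn_idx
    sires = np.array(batch.sires)
    dams = np.array(batch.dams)
    K_rows = 0.5 * (state.K[sires, :] + state.K[dams, :])
    F_new = state.K[sires, dams]
    K_diag = 0.5 * (1.0 + F_new)
    sire_uids = state.uid[sires]
    dam_uids = state.uid[dams]
    idx = state.add_animals(
        sexes=np.array(batch.sexes),
        ages=np.zeros(m, dtype=np.int64),
        subpops=np.array(batch.subpops),
        K_rows=K_rows,
        K_diag=K_diag,
        breeding=False,
        genomes=np.stack(batch.genomes) if batch.genomes else None,
        sires=sires,
        dams=dams,
    )
    if config.record_pedigree:
        for k in range(m):
            state.pedigree_log.append(
                (
                    int(state.uid[idx[k]]),
                    int(sire_uids[k]),
                    int(dam_uids[k]),
                    int(batch.sexes[k]),
                    year,
                )
            )
            state.F_log[int(state.uid[idx[k]])] = float(F_new[k])
    state._newborn_idx = idx
    state._newborn_sire_uid = sire_uids
    return idx


def migrate(state: PopulationState, config: SimConfig, year: int) -> None:
    """Move animals between subpopulations following the yearly matrix."""
    sched = config.migration
    if sched is None:
        return
    matrix = np.asarray(sched.at_year(year), dtype=float)
    n_sub = len(config.subpops)
    eligible = np.ones(state.n, dtype=bool)
    if sched.ages is not None:
        eligible &= np.isin(state.age, sched.ages)
    if sched.sexes is not None:
        codes = [MALE if s == "male" else FEMALE for s in sched.sexes]
        eligible &= np.isin(state.sex, codes)
    origin = state.subpop.copy()
    moved = np.zeros(state.n, dtype=bool)
    rng = state.rng
    for a in range(n_sub):
        pool = np.nonzero(eligible & (origin == a) & ~moved)[0]
        if pool.size == 0:
            continue
        if sched.kind == "count":
            rng.shuffle(pool)
            cursor = 0
            for b in range(n_sub):
                if b == a or matrix[a, b] <= 0:
                    continue
                want = int(matrix[a, b])
                take = pool[cursor : cursor + want]  # shortfall: move available
                state.subpop[take] = b
                moved[take] = True
                cursor += len(take)
        else:
            # the diagonal "stay" probability is the remainder by construction
            probs = matrix[a].copy()
            probs[a] = 0.0
            draws = rng.random(pool.size)
            acc = 0.0
            dest = np.full(pool.size, a)
            for b in range(n_sub):
                if b == a or probs[b] <= 0:
                    continue
                dest[(draws >= acc) & (draws < acc + probs[b])] = b
                acc += probs[b]
            state.subpop[pool] = dest
            moved[pool[dest != a]] = True


def age_cull_replace(
    state: PopulationState, config: SimConfig, year: int
) -> dict:
    """Age the population, cull surpluses and recruit this year's newborns.

    Ages are incremented; per-age-class breeding targets are restored by
    uniform-random culling of surpluses and uniform-random recruitment of
    newborns; carried juveniles fill age classes that grow with age.  Animals
    over a lifetime litter quota are removed and replaced like any culled
    animal.  When too few newborns are available the population shrinks.
    Returns selection bookkeeping (mean F of the recruited newborns).
    """
    rng = state.rng
    policy = config.policy
    targets = _sex_targets(config)
    newborn = state.age == 0
    state.age[~newborn] += 1

    keep = np.ones(state.n, dtype=bool)
    # lifetime-limit removals
    if policy.max_litters_per_sire_life is not None:
        keep &= ~(
            (state.sex == MALE)
            & (state.litters_life >= policy.max_litters_per_sire_life)
        )
    if policy.max_litters_per_dam_life is not None:
        keep &= ~(
            (state.sex == FEMALE)
            & (state.litters_life >= policy.max_litters_per_dam_life)
        )

    selected_F: list[float] = []
    n_sub = len(config.subpops)
    for p in range(n_sub):
        for sex in (MALE, FEMALE):
            tgt = targets[p][sex]
            carried = _carried_targets(tgt)
            max_age = len(tgt)
            in_class = (state.subpop == p) & (state.sex == sex)
            keep &= ~(in_class & (state.age > max_age) & (state.age > 0))
            for age_class in range(max_age, 0, -1):
                members = np.nonzero(
                    in_class & (state.age == age_class) & keep
                )[0]
                breeders = members[state.breeding[members]]
                juveniles = members[~state.breeding[members]]
                want_b = int(tgt[age_class - 1])
                want_total = int(carried[age_class - 1])
                if breeders.size < want_b and juveniles.size:
                    promote = rng.choice(
                        juveniles,
                        size=min(want_b - breeders.size, juveniles.size),
                        replace=False,
                    )
                    state.breeding[promote] = True
                    breeders = np.concatenate([breeders, promote])
                    juveniles = juveniles[~np.isin(juveniles, promote)]
                if breeders.size > want_b:
                    cull = rng.choice(
                        breeders, size=breeders.size - want_b, replace=False
                    )
                    keep[cull] = False
                    breeders = breeders[~np.isin(breeders, cull)]
                want_j = max(want_total - want_b, 0)
                if juveniles.size > want_j:
                    cull = rng.choice(
                        juveniles, size=juveniles.size - want_j, replace=False
                    )
                    keep[cull] = False
            # recruitment of newborns into age class 1
            have = np.nonzero(in_class & (state.age == 1) & keep)[0]
            have_b = int(state.breeding[have].sum())
            deficit_total = int(carried[0]) - have.size
            pool = np.nonzero(
                newborn & (state.subpop == p) & (state.sex == sex) & keep
            )[0]
            if deficit_total > 0 and pool.size:
                if sex == MALE and policy.max_sons_per_sire is not None:
                    uid_to_sire = {
                        int(state.uid[i]): int(s)
                        for i, s in zip(
                            state._newborn_idx, state._newborn_sire_uid
                        )
                    }
                    recruits = cap_selected_sons(
                        pool,
                        [uid_to_sire.get(int(state.uid[i])) for i in pool],
                        deficit_total,
                        policy,
                        rng,
                        sons_already=state.sons_selected,
                    )
                    recruits = np.asarray(recruits, dtype=np.int64)
                else:
                    recruits = rng.choice(
                        pool, size=min(deficit_total, pool.size), replace=False
                    )
                state.age[recruits] = 1
                need_b = max(int(tgt[0]) - have_b, 0)
                make_b = recruits[:need_b]
                state.breeding[make_b] = True
                selected_F.extend((2.0 * state.K[i, i] - 1.0) for i in recruits)

    keep &= state.age >= 1  # unrecruited newborns leave the simulation
    state.keep(keep)
    state.litters_year[:] = 0
    return {
        "mean_F_selected": float(np.mean(selected_F)) if selected_F else math.nan,
        "n_selected": len(selected_F),
    }


@dataclass
class RunOutput:
    """Per-year records and summary rates for one simulation run."""

    run: int
    seed: int
    years: pd.DataFrame
    delta_F: float
    delta_f: float
    Ne_F: float | None
    Ne_f: float | None
    L_realized: float
    extinct_year: int | None
    pedigree_records: list[PedigreeRecord] | None = None
    frequency_track: FrequencyTrack | None = None
    F_bookkeeping: dict[int, float] | None = None  # uid -> F carried by the sim

    def pedigree(self) -> Pedigree:
        if self.pedigree_records is None:
            raise ValueError("run was not configured with record_pedigree")
        return topological_sort(self.pedigree_records)


def _pedigree_records(state: PopulationState) -> list[PedigreeRecord]:
    records = []
    for uid, sire, dam, sex, year in state.pedigree_log:
        records.append(
            PedigreeRecord(
                animal_id=f"A{uid}",
                sire_id=f"A{sire}" if sire else None,
                dam_id=f"A{dam}" if dam else None,
                sex=Sex.MALE if sex == MALE else Sex.FEMALE,
                birth_year=year,
            )
        )
    return records


def _run_once(config: SimConfig, seed_seq: np.random.SeedSequence, run: int) -> RunOutput:
    rng = np.random.default_rng(seed_seq)
    state = init_founders(config, rng)
    track = None
    if config.genome is not None:
        track = FrequencyTrack(
            config.genome,
            loci=None if not config.track_all_loci else range(config.genome.n_loci),
        )
        track.update(state.genomes, state.subpop, 0)
    records: list[YearRecord] = []
    age_sum, age_n = 0.0, 0
    extinct_year = None
    n_sub = len(config.subpops)
    for year in range(1, config.years + 1):
        state.year = year
        newborn_idx = make_litters(state, config, year)
        births = len(newborn_idx)
        F_new = (
            2.0 * np.diag(state.K)[newborn_idx] - 1.0
            if births
            else np.empty(0)
        )
        f_new = (
            float(state.K[np.ix_(newborn_idx, newborn_idx)].mean())
            if births
            else math.nan
        )
        by_sub_births = [
            int((state.subpop[newborn_idx] == p).sum()) for p in range(n_sub)
        ]
        by_sub_F = []
        for p in range(n_sub):
            sel = newborn_idx[state.subpop[newborn_idx] == p]
            by_sub_F.append(
                float((2.0 * np.diag(state.K)[sel] - 1.0).mean())
                if sel.size
                else math.nan
            )
        if not math.isnan(state._year_parent_age):
            age_sum += state._year_parent_age * state._year_litters
            age_n += state._year_litters
        migrate(state, config, year)
        sel_info = age_cull_replace(state, config, year)
        if track is not None:
            track.update(state.genomes, state.subpop, year)
        extinct = state.n == 0 or not (
            (state.sex == MALE).any() and (state.sex == FEMALE).any()
        )
        if extinct and extinct_year is None:
            extinct_year = year
        records.append(
            YearRecord(
                year=year,
                size=state.n,
                litters_born=state._year_litters,
                births=births,
                mean_age=float(state.age.mean()) if state.n else math.nan,
                mean_F_newborn=float(F_new.mean()) if births else math.nan,
                mean_F_selected=sel_info["mean_F_selected"],
                mean_kinship_incl_self=state.population_mean_kinship(True),
                mean_kinship_excl_self=state.population_mean_kinship(False),
                mean_f_newborn_incl_self=f_new,
                extinct=extinct,
                size_by_subpop=[
                    int((state.subpop == p).sum()) for p in range(n_sub)
                ],
                births_by_subpop=by_sub_births,
                mean_F_newborn_by_subpop=by_sub_F,
            )
        )
        if state.n == 0:
            break
    frame = pd.DataFrame([r.__dict__ for r in records])
    L = age_sum / age_n if age_n else math.nan
    final = frame.mean_F_newborn.dropna()
    f_final = frame.mean_f_newborn_incl_self.dropna()
    n_years = int(frame.year.iloc[-1]) if len(frame) else config.years
    dF = (
        rates_mod.sim_delta_f(float(final.iloc[-1]), L, n_years)
        if len(final) and np.isfinite(L)
        else math.nan
    )
    df_kin = (
        rates_mod.sim_delta_f(float(f_final.iloc[-1]), L, n_years)
        if len(f_final) and np.isfinite(L)
        else math.nan
    )
    return RunOutput(
        run=run,
        seed=int(seed_seq.generate_state(1)[0] % (2**31)),
        years=frame,
        delta_F=dF,
        delta_f=df_kin,
        Ne_F=rates_mod.effective_size(dF) if np.isfinite(dF) else None,
        Ne_f=rates_mod.effective_size(df_kin) if np.isfinite(df_kin) else None,
        L_realized=L,
        extinct_year=extinct_year,
        pedigree_records=_pedigree_records(state) if config.record_pedigree else None,
        frequency_track=track,
        F_bookkeeping=dict(state.F_log) if config.record_pedigree else None,
    )


def run_simulation(config: SimConfig, seed: int | None = None) -> list[RunOutput]:
    """Run the configured number of replicates; one master seed, child streams.

    The same configuration and seed always produce bit-identical outputs.
    """
    issues = config.validate()
    if issues:
        raise ValueError("invalid simulation config:\n- " + "\n- ".join(issues))
    if seed is None:
        seed = config.random_seed
    master = np.random.SeedSequence(seed)
    children = master.spawn(config.runs)
    return [_run_once(config, child, run) for run, child in enumerate(children)]


def newborn_f_trajectories(outputs: Sequence[RunOutput], years: int) -> np.ndarray:
    """(runs, years) array of mean newborn inbreeding, NaN-padded."""
    out = np.full((len(outputs), years), np.nan)
    for i, run in enumerate(outputs):
        y = run.years.year.to_numpy() - 1
        out[i, y[y < years]] = run.years.mean_F_newborn.to_numpy()[y < years]
    return out
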