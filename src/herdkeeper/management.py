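"""Genetic-management rules: breeding eligibility and mate allocation.

The policy bundles the management options a captive-population manager can
switch on: litter quotas per sire (per year or per life) and per dam, a cap on
the number of sons recruited per sire, exclusion of animals above an
own-inbreeding threshold, mean-kinship-based exclusion, a pairwise-kinship
ceiling for matings, minimum-kinship mate choice, and an optimal-contribution
litter allocation.  All rules act inside the yearly mating and replacement
steps of the simulator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations_with_replacement
from typing import Sequence

import numpy as np

__all__ = [
    "ManagementPolicy",
    "eligible_parents",
    "pick_sire",
    "optimal_contributions_allocate",
    "cap_selected_sons",
]


@dataclass
class ManagementPolicy:
    max_litters_per_sire_year: int | None = None
    max_litters_per_sire_life: int | None = None
    max_litters_per_dam_life: int | None = None
    max_sons_per_sire: int | None = None
    max_inbreeding_offspring: float | None = None  # threshold on own F
    max_parent_kinship: float | None = None
    minimize_kinship_mating: bool = False
    mean_kinship_exclusion: bool = False
    mean_kinship_literal_direction: bool = False
    optimal_contributions: bool = False

    def is_null(self) -> bool:
        return self == ManagementPolicy()

    def validate(self) -> list[str]:
        issues = []
        if self.minimize_kinship_mating and self.optimal_contributions:
            issues.append(
                "at most one of minimize_kinship_mating and optimal_contributions "
                "may be active"
            )
        for name in (
            "max_litters_per_sire_year",
            "max_litters_per_sire_life",
            "max_litters_per_dam_life",
            "max_sons_per_sire",
        ):
            v = getattr(self, name)
            if v is not None and v < 1:
                issues.append(f"{name} must be at least 1")
        for name in ("max_inbreeding_offspring", "max_parent_kinship"):
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 1.0:
                issues.append(f"{name} must be in [0, 1]")
        return issues


def eligible_parents(state, policy: ManagementPolicy, sex: str,
                     subpop: int | None = None) -> np.ndarray:
    """Indices of living breeding animals of one sex eligible under the policy.

    Removes animals over their yearly or lifetime litter quota, over the
    own-inbreeding threshold, and — with mean-kinship exclusion on — animals
    whose mean kinship with all living animals strictly exceeds the population
    average (conserving rare lineages means removing over-represented, i.e.
    high mean-kinship, animals; the literal opposite direction is available
    behind ``mean_kinship_literal_direction``).  Ties at the average are kept.
    """
    sex_code = 0 if sex == "male" else 1
    mask = (state.sex == sex_code) & state.breeding & (state.age >= 1)
    if subpop is not None:
        mask &= state.subpop == subpop
    if policy.max_litters_per_sire_year is not None and sex == "male":
        mask &= state.litters_year < policy.max_litters_per_sire_year
    if policy.max_litters_per_sire_life is not None and sex == "male":
        mask &= state.litters_life < policy.max_litters_per_sire_life
    if policy.max_litters_per_dam_life is not None and sex == "female":
        mask &= state.litters_life < policy.max_litters_per_dam_life
    if policy.max_inbreeding_offspring is not None:
        mask &= state.F <= policy.max_inbreeding_offspring
    if policy.mean_kinship_exclusion and mask.any():
        mk = state.mean_kinship()
        avg = mk.mean()
        if policy.mean_kinship_literal_direction:
            mask &= ~(mk < avg)
        else:
            mask &= ~(mk > avg)
    return np.nonzero(mask)[0]


def pick_sire(
    state,
    dam: int,
    candidates: np.ndarray,
    policy: ManagementPolicy,
    rng: np.random.Generator,
) -> int | None:
    """Choose a sire for one dam, or None when no candidate qualifies.

    Applies the pairwise-kinship ceiling first; under minimum-kinship mating
    the lowest-kinship male wins with uniform random tie-breaking, otherwise
    the choice is uniform among the remaining candidates.
    """
    if len(candidates) == 0:
        return None
    kin = state.K[dam, candidates]
    if policy.max_parent_kinship is not None:
        keep = kin <= policy.max_parent_kinship
        candidates, kin = candidates[keep], kin[keep]
        if len(candidates) == 0:
            return None
    if policy.minimize_kinship_mating:
        best = kin.min()
        ties = candidates[kin <= best + 1e-12]
        return int(ties[rng.integers(len(ties))])
    return int(candidates[rng.integers(len(candidates))])


def _allocation_score(
    K: np.ndarray, sires: np.ndarray, dams: np.ndarray, x: np.ndarray
) -> float:
    """c'Kc for the contribution vector implied by litters-per-sire x."""
    n = len(K)
    c = np.zeros(n)
    total = x.sum()
    if total == 0:
        return np.inf
    c[sires] += x / (2.0 * total)
    c[dams] += 1.0 / (2.0 * len(dams))
    return float(c @ K @ c)


def optimal_contributions_allocate(
    state,
    sires: np.ndarray,
    dams: np.ndarray,
    litters_needed: int,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Integer litters per candidate sire minimizing next-cohort mean kinship.

    Greedy heuristic: litters are assigned one at a time to the sire whose
    addition minimizes c'Kc, where c gives each planned dam an equal
    contribution and each sire a contribution proportional to its allocated
    litters.  Ties break toward the lower candidate index for determinism.
    This is a documented heuristic (checked against exhaustive search on
    small instances in the test suite), not a Lagrangian optimal-contribution
    solver.
    """
    sires = np.asarray(sires, dtype=np.int64)
    dams = np.asarray(dams, dtype=np.int64)
    if sires.size == 0:
        raise ValueError("no eligible sires to allocate litters to")
    K = state.K
    x = np.zeros(sires.size, dtype=np.int64)
    for _ in range(litters_needed):
        scores = np.empty(sires.size)
        for m in range(sires.size):
            x[m] += 1
            scores[m] = _allocation_score(K, sires, dams, x)
            x[m] -= 1
        x[int(np.argmin(scores))] += 1
    return x


def optimal_contributions_bruteforce(
    state, sires: np.ndarray, dams: np.ndarray, litters_needed: int
) -> np.ndarray:
    """Exhaustive-search reference for tiny allocation instances."""
    sires = np.asarray(sires, dtype=np.int64)
    dams = np.asarray(dams, dtype=np.int64)
    best, best_score = None, np.inf
    for combo in combinations_with_replacement(range(sires.size), litters_needed):
        x = np.bincount(combo, minlength=sires.size).astype(np.int64)
        score = _allocation_score(state.K, sires, dams, x)
        if score < best_score - 1e-15:
            best, best_score = x, score
    return best


def cap_selected_sons(
    newborn_males: Sequence[int],
    sire_uids: Sequence[int],
    demand: int,
    policy: ManagementPolicy,
    rng: np.random.Generator,
    sons_already: dict[int, int] | None = None,
) -> list[int]:
    """Recruit up to ``demand`` newborn males, at most cap sons per sire.

    ``sons_already`` carries lifetime counts of sons previously recruited per
    sire uid, so the cap holds across years.  The draw is uniform among the
    males whose sire is still under the cap; a shortfall simply returns fewer
    recruits.
    """
    newborn_males = list(newborn_males)
    sire_uids = list(sire_uids)
    cap = policy.max_sons_per_sire
    order = rng.permutation(len(newborn_males))
    counts: dict[int, int] = dict(sons_already or {})
    chosen: list[int] = []
    for k in order:
        if len(chosen) >= demand:
            break
        sire = sire_uids[k]
        if cap is not None and sire is not None and counts.get(sire, 0) >= cap:
            continue
        chosen.append(newborn_males[k])
        if sire is not None:
            counts[sire] = counts.get(sire, 0) + 1
    if sons_already is not None:
        sons_already.clear()
        sons_already.update(counts)
    return chosen
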