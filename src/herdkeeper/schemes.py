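"""Rotational-mating presets: breeding circle, Falconer's scheme and MAI.

Rotational mating splits a population into groups that systematically
exchange young, unbred animals; it needs no pedigree knowledge, which makes
it attractive for group-living species where parentage cannot be recorded.
The presets implement the exchange of *all newborn males* (females stay in
their natal group) under three classic donor-recipient patterns for G groups:

- breeding circle: group i always donates to group i+1 (offset 1 each year);
- Falconer's scheme: the donor offset cycles 1, 2, ..., G-1 over the years,
  so every donor-recipient combination is used before the cycle restarts;
- maximum avoidance of inbreeding (MAI): the offset doubles each year
  (1, 2, 4, 8, ...), postponing exchange between groups already related
  through earlier transfers; the cycle length is ceil(log2 G).

Each preset returns the migration schedule as plain data (a list of matrices
applied consecutively over the years), so any other pattern can be supplied
by hand.  The companion zoo-example configurations describe a deer-like
population: G groups of 2 breeding males and 12 breeding females, litter
sizes 1-4, overlapping generations (females breed from age 1 to 6, males at
ages 1-2), 5 litters per group per year.
"""

from __future__ import annotations

import math

import numpy as np

from .management import ManagementPolicy
from .sim_core import MatrixSchedule, SimConfig, SubpopSpec

__all__ = [
    "SCHEMES",
    "rotation_offsets",
    "offset_matrix",
    "rotation_migration",
    "zoo_rotation_config",
    "first_sustained_crossing",
]

SCHEMES = ("panmictic", "isolated", "circle", "falconer", "mai")

ZOO_MALES_PER_GROUP = 2
ZOO_FEMALES_PER_GROUP = 12
ZOO_LITTERS_PER_GROUP = 5
ZOO_LITTER_SIZE_DIST = {1: 0.25, 2: 0.25, 3: 0.25, 4: 0.25}
ZOO_MALE_AGE_DIST = (0.5, 0.5)
ZOO_FEMALE_AGE_DIST = (0.25, 0.20, 0.20, 0.15, 0.12, 0.08)


def rotation_offsets(scheme: str, groups: int) -> list[int]:
    """Donor-recipient offsets used consecutively over the years."""
    if scheme == "circle":
        return [1]
    if scheme == "falconer":
        return list(range(1, groups))
    if scheme == "mai":
        return [(2**k) % groups for k in range(max(math.ceil(math.log2(groups)), 1))]
    raise ValueError(f"unknown rotational scheme {scheme!r}")


def offset_matrix(groups: int, offset: int) -> np.ndarray:
    """Migration-probability matrix sending group i to group (i+offset) mod G."""
    m = np.zeros((groups, groups))
    for i in range(groups):
        m[i, (i + offset) % groups] = 1.0
    return m


def rotation_migration(scheme: str, groups: int) -> MatrixSchedule | None:
    """Migration schedule moving every newborn male one scheme-step onward."""
    if scheme in ("panmictic", "isolated"):
        return None
    return MatrixSchedule(
        matrices=[offset_matrix(groups, o) for o in rotation_offsets(scheme, groups)],
        kind="probability",
        ages=[0],
        sexes=["male"],
    )


def zoo_rotation_config(
    scheme: str = "circle",
    groups: int = 12,
    years: int = 300,
    runs: int = 1,
    seed: int | None = None,
    males_per_group: int = ZOO_MALES_PER_GROUP,
    females_per_group: int = ZOO_FEMALES_PER_GROUP,
    litters_per_group: int = ZOO_LITTERS_PER_GROUP,
) -> SimConfig:
    """The 12-group zoo comparison: one config per breeding scheme.

    ``panmictic`` merges all groups into one population of the same total
    size (groups * males, groups * females breeding animals and the same
    total litter number), ``isolated`` keeps the groups closed, and the
    rotational schemes add the corresponding migration schedule.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"scheme must be one of {SCHEMES}")
    if scheme == "panmictic":
        subpops = [
            SubpopSpec(males_per_group * groups, females_per_group * groups)
        ]
    else:
        subpops = [
            SubpopSpec(males_per_group, females_per_group) for _ in range(groups)
        ]
    return SimConfig(
        years=years,
        runs=runs,
        random_seed=seed,
        subpops=subpops,
        litters_per_year=litters_per_group * groups,
        litter_size_dist=dict(ZOO_LITTER_SIZE_DIST),
        male_age_dist=ZOO_MALE_AGE_DIST,
        female_age_dist=ZOO_FEMALE_AGE_DIST,
        migration=rotation_migration(scheme, groups),
        policy=ManagementPolicy(),
    )


def rotation_experiment(
    scheme_names: list[str],
    years: int = 350,
    runs: int = 50,
    seed: int = 1,
    groups: int = 12,
) -> dict[str, np.ndarray]:
    """Replicate-mean newborn-inbreeding trajectories for several schemes.

    Each scheme gets its own child seed derived deterministically from the
    master seed (in the order the schemes are listed), so a scheme's
    trajectory does not change when other schemes are added or removed.
    """
    from .sim_core import newborn_f_trajectories, run_simulation

    children = np.random.SeedSequence(seed).spawn(len(scheme_names))
    out: dict[str, np.ndarray] = {}
    for scheme, child in zip(scheme_names, children):
        cfg = zoo_rotation_config(scheme=scheme, groups=groups, years=years,
                                  runs=runs)
        runs_out = run_simulation(cfg, seed=int(child.generate_state(1)[0] % 2**31))
        out[scheme] = np.nanmean(newborn_f_trajectories(runs_out, years), axis=0)
    return out


def first_sustained_crossing(
    a: np.ndarray, b: np.ndarray, window: int = 10
) -> int | None:
    """First year (1-based) where curve ``a`` falls below ``b`` and stays below.

    "Stays below" means for at least ``window`` consecutive recorded years
    (or to the end of the shorter series), which suppresses single-year noise
    crossings of stochastic replicate-mean trajectories.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n = min(len(a), len(b))
    below = a[:n] < b[:n]
    for t in range(n):
        if below[t] and below[t : min(t + window, n)].all():
            return t + 1
    return None
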