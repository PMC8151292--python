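"""Simulation configuration files: YAML schema, parsing and validation.

The schema mirrors the simulator inputs one to one::

    years: 100
    runs: 25
    random_seed: 1
    subpops:                # one entry per subpopulation
      - {males: 10, females: 50}
    litters_per_year: 25
    litter_size_dist: {1: 0.20, 2: 0.70, 3: 0.10}
    male_age_dist: [0.75, 0.20, 0.05]
    female_age_dist: [0.75, 0.20, 0.05]
    top_sires: {count: 4, contribution: 0.50}      # optional
    fertilization:                                  # optional
      kind: probability            # or count
      matrices:
        - [[1.0, 0.0], [0.1, 0.9]]
    migration:                                      # optional
      kind: count                  # or probability
      ages: [0]                    # optional restriction
      sexes: [male]                # optional restriction
      matrices:
        - [["*", 5], [0, "*"]]     # "*" on the diagonal: remainder stays
    genome:                                         # optional
      n_loci: 10
      n_chromosomes: 2
      map_length: 1.0
      mutation_rate: 1.0e-6
      start_freq: 0.5
      special_loci:
        - {index: 0, start_freq: 0.5, s: 1.0, h: 0.0, affects: survival,
           first_year: 0}
    policy:                                         # optional
      max_litters_per_sire_year: 5
      minimize_kinship_mating: false

Validation reports every violated invariant at once, naming the field.
"""

from __future__ import annotations

from pathlib import Path
from typing import Any

import numpy as np
import yaml

from .genome import GenomeSpec, LocusSpec
from .management import ManagementPolicy
from .sim_core import MatrixSchedule, SimConfig, SubpopSpec

__all__ = ["load_sim_config", "sim_config_from_dict", "validate_config",
           "sim_config_to_dict"]


def _matrix(rows: list[list[Any]]) -> np.ndarray:
    """Parse a matrix whose diagonal may carry the '*' stay marker."""
    out = np.zeros((len(rows), len(rows[0])))
    for i, row in enumerate(rows):
        for j, cell in enumerate(row):
            out[i, j] = 0.0 if cell == "*" else float(cell)
    return out


def _schedule(block: dict) -> MatrixSchedule:
    return MatrixSchedule(
        matrices=[_matrix(m) for m in block["matrices"]],
        kind=block.get("kind", "probability"),
        ages=block.get("ages"),
        sexes=block.get("sexes"),
    )


def sim_config_from_dict(data: dict) -> SimConfig:
    genome = None
    if "genome" in data and data["genome"] is not None:
        g = dict(data["genome"])
        specials = [LocusSpec(**sp) for sp in g.pop("special_loci", [])]
        genome = GenomeSpec(**g, special_loci=specials)
    policy = ManagementPolicy(**(data.get("policy") or {}))
    top = data.get("top_sires")
    if isinstance(top, dict):
        top = (int(top["count"]), float(top["contribution"]))
    elif top is not None:
        top = (int(top[0]), float(top[1]))
    return SimConfig(
        years=int(data["years"]),
        runs=int(data.get("runs", 1)),
        random_seed=data.get("random_seed"),
        subpops=[
            SubpopSpec(int(sp["males"]), int(sp["females"]))
            for sp in data["subpops"]
        ],
        litters_per_year=int(data["litters_per_year"]),
        litter_size_dist={
            int(k): float(v) for k, v in data["litter_size_dist"].items()
        },
        male_age_dist=tuple(data.get("male_age_dist", (1.0,))),
        female_age_dist=tuple(data.get("female_age_dist", (1.0,))),
        top_sires=top,
        fertilization=(
            _schedule(data["fertilization"]) if data.get("fertilization") else None
        ),
        migration=_schedule(data["migration"]) if data.get("migration") else None,
        genome=genome,
        policy=policy,
        record_pedigree=bool(data.get("record_pedigree", False)),
        track_all_loci=bool(data.get("track_all_loci", False)),
    )


def load_sim_config(path: str | Path) -> SimConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} does not contain a mapping")
    return sim_config_from_dict(data)


def validate_config(config: SimConfig | dict) -> list[str]:
    """All violated invariants (empty list = valid)."""
    if isinstance(config, dict):
        try:
            config = sim_config_from_dict(config)
        except (KeyError, TypeError, ValueError) as exc:
            return [f"config cannot be constructed: {exc}"]
    return config.validate()


def sim_config_to_dict(config: SimConfig) -> dict:
    """Round-trippable plain-data form of a config (for manifests)."""
    out: dict[str, Any] = {
        "years": config.years,
        "runs": config.runs,
        "random_seed": config.random_seed,
        "subpops": [
            {"males": sp.males, "females": sp.females} for sp in config.subpops
        ],
        "litters_per_year": config.litters_per_year,
        "litter_size_dist": {
            int(k): float(v) for k, v in config.litter_size_dist.items()
        },
        "male_age_dist": list(config.male_age_dist),
        "female_age_dist": list(config.female_age_dist),
    }
    if config.top_sires is not None:
        out["top_sires"] = {
            "count": config.top_sires[0],
            "contribution": config.top_sires[1],
        }
    for name in ("fertilization", "migration"):
        sched = getattr(config, name)
        if sched is not None:
            out[name] = {
                "kind": sched.kind,
                "ages": sched.ages,
                "sexes": sched.sexes,
                "matrices": [np.asarray(m).tolist() for m in sched.matrices],
            }
    if config.genome is not None:
        g = config.genome
        out["genome"] = {
            "n_loci": g.n_loci,
            "n_chromosomes": g.n_chromosomes,
            "map_length": g.map_length,
            "mutation_rate": g.mutation_rate,
            "start_freq": g.start_freq,
            "special_loci": [
                {
                    "index": sp.index,
                    "start_freq": sp.start_freq,
                    "s": sp.s,
                    "h": sp.h,
                    "affects": sp.affects,
                    "first_year": sp.first_year,
                }
                for sp in g.special_loci
            ],
        }
    policy = {
        k: v
        for k, v in config.policy.__dict__.items()
        if v not in (None, False)
    }
    if policy:
        out["policy"] = policy
    return out
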