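"""Per-year monitoring tables extracted from a sorted pedigree.

The report covers the population-structure quantities that drive inbreeding
rates in small captive populations: births and later breeding use, litter
counts and sizes, parental ages and generation intervals, pedigree
completeness, skew of sire contributions, per-variety and per-subpopulation
births, descent between subpopulations, inbreeding/kinship levels and rates,
and a compact summary of the recent population usable as simulator input.
Every table has one row per calendar year from the first to the last known
birth year, including years without births.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import rates as rates_mod
from . import relatedness
from .pedigree_io import Pedigree, Sex

__all__ = [
    "Litter",
    "MonitorReport",
    "infer_litters",
    "births_by_year",
    "parents_per_year",
    "lifetime_offspring_stats",
    "litter_size_histogram",
    "parent_age_tables",
    "generation_interval",
    "generation_interval_by_year",
    "pedigree_completeness",
    "pedigree_depth_by_year",
    "top_sire_contributions",
    "top_sire_table",
    "varieties_by_year",
    "inbreeding_kinship_by_year",
    "rate_table",
    "subpop_births",
    "subpop_descent",
    "subpop_relatedness",
    "pointer_summary",
    "build_report",
]


@dataclass
class Litter:
    dam_id: str
    sire_id: str | None
    birth_year: int
    size: int
    offspring: list[str]


def _frame(pedigree: Pedigree) -> pd.DataFrame:
    df = pedigree.to_dataframe()
    df["pos"] = np.arange(len(df))
    return df


def _year_index(pedigree: Pedigree) -> pd.RangeIndex:
    span = pedigree.known_year_span()
    if span is None:
        return pd.RangeIndex(0, 0, name="year")
    return pd.RangeIndex(span[0], span[1] + 1, name="year")


def _known(df: pd.DataFrame) -> pd.DataFrame:
    return df[df.birth_year.notna()]


def _parent_set(df: pd.DataFrame) -> set[str]:
    return set(df.sire_id.dropna()) | set(df.dam_id.dropna())


def infer_litters(pedigree: Pedigree, by_sire: bool = False) -> list[Litter]:
    """Group offspring into litters.

    By default a litter is one dam's offspring of one birth year (a female
    produces at most one litter per breeding cycle); ``by_sire`` additionally
    splits on the sire, for species where a dam may have mixed-sire years.
    Offspring with unknown dam cannot be assigned and are excluded.
    """
    df = _known(_frame(pedigree))
    df = df[df.dam_id.notna()]
    keys = ["dam_id", "birth_year"] + (["sire_id"] if by_sire else [])
    litters = []
    for key, grp in df.groupby(keys, dropna=False, sort=True):
        dam = key[0]
        year = int(key[1])
        sires = grp.sire_id.dropna().unique()
        sire = sires[0] if len(sires) == 1 else None
        litters.append(
            Litter(
                dam_id=dam, sire_id=sire, birth_year=year,
                size=len(grp), offspring=list(grp.animal_id),
            )
        )
    return litters


def births_by_year(pedigree: Pedigree) -> pd.DataFrame:
    """Young born per year: males, females, total, and later breeding use."""
    df = _known(_frame(pedigree))
    parents = _parent_set(_frame(pedigree))
    idx = _year_index(pedigree)
    used = df[df.animal_id.isin(parents)]
    out = pd.DataFrame(
        {
            "males": df[df.sex == "male"].groupby("birth_year").size(),
            "females": df[df.sex == "female"].groupby("birth_year").size(),
            "total": df.groupby("birth_year").size(),
            "later_used_in_breeding": used.groupby("birth_year").size(),
        }
    )
    out = out.reindex(idx).fillna(0).astype(int)
    out["not_used"] = out.total - out.later_used_in_breeding
    return out


def parents_per_year(pedigree: Pedigree) -> pd.DataFrame:
    """Distinct parents and per-father litter/offspring counts per year."""
    df = _known(_frame(pedigree))
    litters = infer_litters(pedigree)
    idx = _year_index(pedigree)
    lit = pd.DataFrame(
        [(l.birth_year, l.dam_id, l.sire_id, l.size) for l in litters],
        columns=["year", "dam_id", "sire_id", "size"],
    )
    rows = []
    for year in idx:
        born = df[df.birth_year == year]
        ly = lit[lit.year == year]
        n_sires = born.sire_id.nunique()
        rows.append(
            {
                "n_mothers": born.dam_id.nunique(),
                "n_fathers": n_sires,
                "avg_litter_size": ly["size"].mean() if len(ly) else math.nan,
                "litters_per_father": (
                    ly.sire_id.notna().sum() / n_sires if n_sires else math.nan
                ),
                "offspring_per_father": (
                    born.sire_id.notna().sum() / n_sires if n_sires else math.nan
                ),
            }
        )
    return pd.DataFrame(rows, index=idx)


def lifetime_offspring_stats(
    pedigree: Pedigree, year: int, include_nonbreeders: bool = False
) -> dict[str, tuple[float, float, float]]:
    """Per-sex (mean, sd, max) of lifetime offspring counts of a birth cohort.

    By default computed over the cohort members that ever breed; with
    ``include_nonbreeders`` animals with zero lifetime offspring count too
    (both variants are reported because either reading of "offspring per
    parent over its life" is defensible).
    """
    df = _frame(pedigree)
    counts = pd.concat([df.sire_id.dropna(), df.dam_id.dropna()]).value_counts()
    cohort = _known(df)
    cohort = cohort[cohort.birth_year == year]
    out = {}
    for sex in ("male", "female"):
        members = cohort[cohort.sex == sex].animal_id
        k = counts.reindex(members).fillna(0).to_numpy()
        if not include_nonbreeders:
            k = k[k > 0]
        if k.size == 0:
            out[sex] = (math.nan, math.nan, math.nan)
        else:
            out[sex] = (float(k.mean()), float(k.std(ddof=0)), float(k.max()))
    return out


def _lifetime_table(pedigree: Pedigree) -> pd.DataFrame:
    idx = _year_index(pedigree)
    rows = []
    for year in idx:
        breeders = lifetime_offspring_stats(pedigree, year)
        everyone = lifetime_offspring_stats(pedigree, year, include_nonbreeders=True)
        row = {}
        for sex in ("male", "female"):
            for i, stat in enumerate(("mean", "sd", "max")):
                row[f"{sex}_{stat}"] = breeders[sex][i]
                row[f"{sex}_{stat}_incl_nonbreeders"] = everyone[sex][i]
        rows.append(row)
    return pd.DataFrame(rows, index=idx)


def litter_size_histogram(pedigree: Pedigree) -> pd.DataFrame:
    """Number of litters of each size per year."""
    litters = infer_litters(pedigree)
    idx = _year_index(pedigree)
    max_size = max((l.size for l in litters), default=1)
    out = pd.DataFrame(
        0, index=idx, columns=[f"size_{s}" for s in range(1, max_size + 1)]
    )
    for l in litters:
        out.loc[l.birth_year, f"size_{l.size}"] += 1
    return out


def _parent_ages(pedigree: Pedigree) -> pd.DataFrame:
    """One row per offspring with known birth year: sire/dam ages at birth."""
    df = _frame(pedigree)
    yr = df.set_index("animal_id").birth_year
    born = _known(df)
    out = pd.DataFrame(
        {
            "year": born.birth_year.astype(int),
            "sire_age": born.birth_year.to_numpy()
            - yr.reindex(born.sire_id).to_numpy(),
            "dam_age": born.birth_year.to_numpy()
            - yr.reindex(born.dam_id).to_numpy(),
        }
    )
    return out


def parent_age_tables(pedigree: Pedigree) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Counts of young born to fathers/mothers of each age, per year."""
    ages = _parent_ages(pedigree)
    idx = _year_index(pedigree)
    tables = []
    for col in ("sire_age", "dam_age"):
        known = ages[ages[col].notna() & (ages[col] >= 0)]
        if len(known):
            pivot = (
                known.assign(age=known[col].astype(int))
                .groupby(["year", "age"]).size().unstack(fill_value=0)
            )
            pivot.columns = [f"age_{a}" for a in pivot.columns]
        else:
            pivot = pd.DataFrame()
        tables.append(pivot.reindex(idx).fillna(0).astype(int))
    return tables[0], tables[1]


def generation_interval(
    pedigree: Pedigree, year: int
) -> tuple[float, float, float]:
    """(L_sires, L_dams, L_parents): mean parent age at birth for one cohort.

    Parents with unknown birth year are skipped.
    """
    ages = _parent_ages(pedigree)
    ages = ages[ages.year == year]
    sire = ages.sire_age.dropna().to_numpy()
    dam = ages.dam_age.dropna().to_numpy()
    both = np.concatenate([sire, dam])
    return (
        float(sire.mean()) if sire.size else math.nan,
        float(dam.mean()) if dam.size else math.nan,
        float(both.mean()) if both.size else math.nan,
    )


def generation_interval_by_year(pedigree: Pedigree) -> pd.DataFrame:
    idx = _year_index(pedigree)
    rows = [generation_interval(pedigree, y) for y in idx]
    return pd.DataFrame(rows, index=idx, columns=["L_sires", "L_dams", "L_parents"])


def pedigree_completeness(
    pedigree: Pedigree, animal_id: str, max_gen: int = 10
) -> tuple[float, int]:
    """(generation equivalent, complete generations) for one animal.

    The generation equivalent sums (1/2)^g over every known ancestor slot at
    generation g (parents g=1); complete generations is the largest k at
    which all 2^k ancestor slots are filled.  Both capped at ``max_gen``.
    """
    ge, cg = _completeness_arrays(pedigree, max_gen)
    pos = pedigree.index[animal_id]
    return float(ge[pos]), int(cg[pos])


def _completeness_arrays(
    pedigree: Pedigree, max_gen: int = 10
) -> tuple[np.ndarray, np.ndarray]:
    n = len(pedigree)
    sire1, dam1 = pedigree.sire1, pedigree.dam1
    ge = np.zeros(n + 1)
    cg = np.zeros(n + 1, dtype=np.int64)
    cg[0] = -1  # unknown parent: depth of complete ancestry below the slot
    for i in range(1, n + 1):
        s, d = sire1[i], dam1[i]
        contrib = 0.0
        if s:
            contrib += 0.5 * (1.0 + ge[s])
        if d:
            contrib += 0.5 * (1.0 + ge[d])
        ge[i] = min(contrib, float(2 * max_gen))  # cap is cosmetic; ge <= max_gen
        if s and d:
            cg[i] = min(1 + min(cg[s], cg[d]), max_gen)
        else:
            cg[i] = 0
    return ge[1:], cg[1:]


def pedigree_depth_by_year(pedigree: Pedigree, max_gen: int = 10) -> pd.DataFrame:
    """Mean generation equivalent and % complete-generation classes per year."""
    ge, cg = _completeness_arrays(pedigree, max_gen)
    df = _known(_frame(pedigree))
    idx = _year_index(pedigree)
    rows = []
    for year in idx:
        pos = df[df.birth_year == year].pos.to_numpy()
        if pos.size == 0:
            rows.append({"generation_equivalent": math.nan})
            continue
        row = {"generation_equivalent": float(ge[pos].mean())}
        for k in range(5):
            row[f"pct_complete_{k}"] = 100.0 * float((cg[pos] == k).mean())
        row["pct_complete_gt4"] = 100.0 * float((cg[pos] > 4).mean())
        rows.append(row)
    return pd.DataFrame(rows, index=idx)


def top_sire_contributions(
    pedigree: Pedigree, year: int, k: int = 10
) -> list[float]:
    """Fractions of a year's offspring sired by the k most-used sires.

    Sorted descending; ties broken by sire id so the output is deterministic.
    """
    df = _known(_frame(pedigree))
    born = df[df.birth_year == year]
    total = len(born)
    if total == 0:
        return []
    counts = born.sire_id.dropna().value_counts()
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[:k]
    return [cnt / total for _, cnt in ranked]


def top_sire_table(pedigree: Pedigree, k: int = 10) -> pd.DataFrame:
    idx = _year_index(pedigree)
    df = _known(_frame(pedigree))
    rows = []
    for year in idx:
        contribs = top_sire_contributions(pedigree, year, k)
        contribs += [math.nan] * (k - len(contribs))
        n_fathers = df[df.birth_year == year].sire_id.nunique()
        rows.append([n_fathers, *contribs])
    cols = ["n_fathers"] + [f"top_{i}" for i in range(1, k + 1)]
    return pd.DataFrame(rows, index=idx, columns=cols)


def varieties_by_year(pedigree: Pedigree) -> pd.DataFrame:
    """Number of animals born each year in each variety."""
    df = _known(_frame(pedigree))
    idx = _year_index(pedigree)
    if df.variety.notna().sum() == 0:
        return pd.DataFrame(index=idx)
    pivot = (
        df[df.variety.notna()]
        .groupby(["birth_year", "variety"]).size().unstack(fill_value=0)
    )
    return pivot.reindex(idx).fillna(0).astype(int)


def inbreeding_kinship_by_year(pedigree: Pedigree) -> pd.DataFrame:
    """Mean F and kinship of each birth cohort, plus parent-group kinships."""
    summaries = relatedness.mean_kinship_by_year(pedigree)
    df = _known(_frame(pedigree))
    idx = _year_index(pedigree)
    base = pd.DataFrame(
        {
            "n": [s.n for s in summaries],
            "mean_F": [s.mean_F for s in summaries],
            "mean_f_incl_self": [s.mean_f_incl_self for s in summaries],
            "mean_f_excl_self": [s.mean_f_excl_self for s in summaries],
            "mean_f_future_parents": [s.mean_f_future_parents for s in summaries],
        },
        index=pd.Index([s.year for s in summaries], name="year"),
    ).reindex(idx)
    fathers, mothers = [], []
    for year in idx:
        born = df[df.birth_year == year]
        sires = [pedigree.index[a] for a in born.sire_id.dropna().unique()]
        dams = [pedigree.index[a] for a in born.dam_id.dropna().unique()]
        fathers.append(relatedness.group_mean_kinship(pedigree, sires))
        mothers.append(relatedness.group_mean_kinship(pedigree, dams))
    base["mean_f_fathers"] = fathers
    base["mean_f_mothers"] = mothers
    return base


def rate_table(pedigree: Pedigree) -> pd.DataFrame:
    """Whole-period and per-period rates for F and kinship, with Ne columns."""
    span = pedigree.known_year_span()
    if span is None:
        return pd.DataFrame()
    first, last = span
    ik = inbreeding_kinship_by_year(pedigree)
    gi = generation_interval_by_year(pedigree)
    F_by_year = {int(y): float(v) for y, v in ik.mean_F.items() if np.isfinite(v)}
    f_by_year = {
        int(y): float(v) for y, v in ik.mean_f_incl_self.items() if np.isfinite(v)
    }
    ages = _parent_ages(pedigree)
    periods = [(first, last)] + rates_mod.partition_periods(first, last)
    rows = []
    for period in periods:
        sel = ages[(ages.year >= period[0]) & (ages.year <= period[1])]
        both = pd.concat([sel.sire_age, sel.dam_age]).dropna()
        L = float(both.mean()) if len(both) else math.nan
        if not np.isfinite(L) or L <= 0:
            L = 1.0
        est_F = rates_mod.RateEstimate.from_series(period, L, F_by_year)
        est_f = rates_mod.RateEstimate.from_series(period, L, f_by_year)
        rows.append(
            {
                "first_year": period[0],
                "last_year": period[1],
                "n_years": est_F.n,
                "L": L,
                "dF_year": est_F.dF_year,
                "dF_generation": est_F.dF_generation,
                "dF_regression": est_F.dF_regression,
                "Ne_F": est_F.Ne,
                "df_year": est_f.dF_year,
                "df_generation": est_f.dF_generation,
                "df_regression": est_f.dF_regression,
                "Ne_f": est_f.Ne,
            }
        )
    return pd.DataFrame(rows)


def subpop_births(pedigree: Pedigree) -> pd.DataFrame:
    """Number of young born per year in each subpopulation."""
    df = _known(_frame(pedigree))
    idx = _year_index(pedigree)
    if df.subpop.notna().sum() == 0:
        return pd.DataFrame(index=idx)
    pivot = (
        df[df.subpop.notna()]
        .groupby(["birth_year", "subpop"]).size().unstack(fill_value=0)
    )
    return pivot.reindex(idx).fillna(0).astype(int)


def subpop_descent(pedigree: Pedigree) -> pd.DataFrame:
    """Counts of parents from subpop a used for young born in subpop b.

    Rows: subpopulation of birth of the young; columns: subpopulation of the
    parent; whole period.  Each parent is counted once per offspring.
    """
    df = _frame(pedigree)
    sub = df.set_index("animal_id").subpop
    born = df[df.subpop.notna()]
    pairs = []
    for _, rec in born.iterrows():
        for pid in (rec.sire_id, rec.dam_id):
            if pid is None:
                continue
            origin = sub.get(pid)
            if origin is not None:
                pairs.append((rec.subpop, origin))
    if not pairs:
        return pd.DataFrame()
    tall = pd.DataFrame(pairs, columns=["born_in", "parent_from"])
    return tall.groupby(["born_in", "parent_from"]).size().unstack(fill_value=0)


def subpop_relatedness(pedigree: Pedigree) -> pd.DataFrame:
    """Average kinship between each year's young of every subpop combination."""
    return relatedness.kinship_between_groups(pedigree, per_year=True)


def pointer_summary(pedigree: Pedigree, window: int = 6) -> dict:
    """Summary of the recent population in the simulator's config schema.

    Based on the last ``window`` birth years: mean litters per year, distinct
    breeding males/females per year, the combined contribution of the 4 most
    popular sires (computed per year then averaged), the litter-size
    distribution and the parental age distribution per sex.
    """
    span = pedigree.known_year_span()
    if span is None:
        raise ValueError(
            "pedigree has no animals with known birth year; configure manually"
        )
    first, last = span
    lo = max(first, last - window + 1)
    years = list(range(lo, last + 1))
    df = _known(_frame(pedigree))
    win = df[df.birth_year.isin(years)]
    if len(win) == 0:
        raise ValueError(
            "no births in the summary window; configure the simulator manually"
        )
    litters = [l for l in infer_litters(pedigree) if l.birth_year in years]
    litters_per_year = len(litters) / len(years)
    males = win.groupby("birth_year").sire_id.nunique().mean()
    females = win.groupby("birth_year").dam_id.nunique().mean()
    top4 = [sum(top_sire_contributions(pedigree, y, 4)) for y in years]
    top4 = [t for t in top4 if t > 0]
    sizes = pd.Series([l.size for l in litters]).value_counts(normalize=True)
    ages = _parent_ages(pedigree)
    ages = ages[ages.year.isin(years)]

    def age_dist(col: str) -> list[float]:
        a = ages[col].dropna()
        a = a[a >= 1].astype(int)
        if len(a) == 0:
            return []
        counts = a.value_counts(normalize=True).sort_index()
        full = counts.reindex(range(1, counts.index.max() + 1), fill_value=0.0)
        return [float(v) for v in full]

    summary = {
        "years": 100,
        "runs": 25,
        "subpops": [
            {
                "males": int(round(males)) if np.isfinite(males) else None,
                "females": int(round(females)) if np.isfinite(females) else None,
            }
        ],
        "litters_per_year": int(round(litters_per_year)),
        "litter_size_dist": {int(s): float(p) for s, p in sizes.sort_index().items()},
        "male_age_dist": age_dist("sire_age"),
        "female_age_dist": age_dist("dam_age"),
        "top_sires": {
            "count": 4,
            "contribution": float(np.mean(top4)) if top4 else None,
        },
        "window_years": [int(lo), int(last)],
    }
    if win.sire_id.notna().sum() == 0:
        summary["missing"] = ["sire information absent in the summary window"]
    return summary


@dataclass
class MonitorReport:
    """The full set of monitoring tables (one DataFrame per item)."""

    births_by_year: pd.DataFrame
    parents_per_year: pd.DataFrame
    lifetime_offspring_stats: pd.DataFrame
    litter_size_histogram_by_year: pd.DataFrame
    sire_age_table: pd.DataFrame
    dam_age_table: pd.DataFrame
    generation_interval_by_year: pd.DataFrame
    pedigree_depth_by_year: pd.DataFrame
    top_sires_by_year: pd.DataFrame
    varieties_by_year: pd.DataFrame
    inbreeding_kinship_by_year: pd.DataFrame
    rate_table: pd.DataFrame
    subpop_births: pd.DataFrame
    subpop_descent: pd.DataFrame
    subpop_relatedness: pd.DataFrame
    pointer_summary: dict
    subpop_reports: dict

    def tables(self) -> dict[str, pd.DataFrame]:
        out = {}
        for f in fields(self):
            value = getattr(self, f.name)
            if isinstance(value, pd.DataFrame):
                out[f.name] = value
        return out

    def write(self, out_dir: str | Path) -> list[Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        written = []
        for name, table in self.tables().items():
            path = out_dir / f"{name}.tsv"
            table.to_csv(path, sep="\t", float_format="%.6g", na_rep="undefined")
            written.append(path)
        report = out_dir / "report.txt"
        with open(report, "w") as fh:
            fh.write(self.to_text())
        written.append(report)
        return written

    def to_text(self) -> str:
        chunks = ["Pedigree monitoring report", "=" * 26, ""]
        for name, table in self.tables().items():
            chunks.append(name.replace("_", " "))
            chunks.append("-" * len(name))
            chunks.append(
                table.to_string(float_format=lambda v: f"{v:.6g}", na_rep="undefined")
            )
            chunks.append("")
        chunks.append("summary for simulation input")
        chunks.append("----------------------------")
        chunks.append(repr(self.pointer_summary))
        return "\n".join(chunks) + "\n"


def _restrict(pedigree: Pedigree, subpop: str) -> Pedigree:
    """A pedigree view for one subpopulation, keeping all ancestors.

    Animals of other subpopulations stay in the pedigree (they carry the
    ancestry) but lose their birth year so they never appear in yearly rows.
    """
    from dataclasses import replace

    records = [
        rec if rec.subpop == subpop else replace(rec, birth_year=None)
        for rec in pedigree.records
    ]
    return Pedigree(records)


def build_report(
    pedigree: Pedigree, per_subpop: bool = True, top_k: int = 10
) -> MonitorReport:
    """Build all monitoring tables; analyses repeat per subpopulation."""
    subpops = sorted(
        {r.subpop for r in pedigree.records if r.subpop is not None}
    )
    sire_ages, dam_ages = parent_age_tables(pedigree)
    try:
        summary = pointer_summary(pedigree)
    except ValueError as exc:
        summary = {"error": str(exc)}
    report = MonitorReport(
        births_by_year=births_by_year(pedigree),
        parents_per_year=parents_per_year(pedigree),
        lifetime_offspring_stats=_lifetime_table(pedigree),
        litter_size_histogram_by_year=litter_size_histogram(pedigree),
        sire_age_table=sire_ages,
        dam_age_table=dam_ages,
        generation_interval_by_year=generation_interval_by_year(pedigree),
        pedigree_depth_by_year=pedigree_depth_by_year(pedigree),
        top_sires_by_year=top_sire_table(pedigree, top_k),
        varieties_by_year=varieties_by_year(pedigree),
        inbreeding_kinship_by_year=inbreeding_kinship_by_year(pedigree),
        rate_table=rate_table(pedigree),
        subpop_births=subpop_births(pedigree),
        subpop_descent=subpop_descent(pedigree),
        subpop_relatedness=(
            subpop_relatedness(pedigree) if subpops else pd.DataFrame()
        ),
        pointer_summary=summary,
        subpop_reports={},
    )
    if per_subpop and len(subpops) > 1:
        for sp in subpops:
            report.subpop_reports[sp] = build_report(
                _restrict(pedigree, sp), per_subpop=False, top_k=top_k
            )
    return report
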