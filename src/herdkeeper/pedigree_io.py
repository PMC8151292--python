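"""Reading, validation, repair and topological sorting of pedigree files.

A pedigree file is a delimited text file with one row per animal carrying at
least an animal ID, sire ID, dam ID, sex and date (or year) of birth, in any
column order, with or without a header.  Unknown parents and unknown dates are
encoded by configurable tokens.  Parsing never aborts on repairable data
problems: offspring recorded before their parents get that parent link blanked,
parents referenced but absent get a phantom record, and animals used both as a
sire and as a dam are reported.  The only fatal data condition is a pedigree
loop (an animal that is its own ancestor), which makes a topological sort
impossible.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field, replace
from enum import Enum
from heapq import heappush, heappop
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "Sex",
    "PedigreeRecord",
    "IssueReport",
    "Pedigree",
    "PedigreeError",
    "DuplicateIdError",
    "PedigreeLoopError",
    "parse_pedigree",
    "validate_and_repair",
    "topological_sort",
    "write_pedigree",
    "load",
    "DEFAULT_UNKNOWN_TOKENS",
    "DEFAULT_SEX_CODES",
    "MANDATORY_ROLES",
]

DEFAULT_UNKNOWN_TOKENS = ("0", "", "?")

DEFAULT_SEX_CODES = {
    "m": "male", "male": "male", "1": "male",
    "f": "female", "female": "female", "v": "female", "2": "female",
    "u": "unknown", "unknown": "unknown",
}

MANDATORY_ROLES = ("id", "sire", "dam", "sex", "year")
OPTIONAL_ROLES = ("name", "subpop", "variety")

_YEAR_RE = re.compile(r"(\d{4})")


class Sex(str, Enum):
    MALE = "male"
    FEMALE = "female"
    UNKNOWN = "unknown"


class PedigreeError(ValueError):
    """Base class for pedigree data and configuration errors."""


class DuplicateIdError(PedigreeError):
    def __init__(self, ids: Sequence[str]):
        self.ids = list(ids)
        super().__init__(f"duplicate animal ids in pedigree: {', '.join(self.ids)}")


class PedigreeLoopError(PedigreeError):
    """Raised when sorting is impossible because animals are their own ancestors."""

    def __init__(self, loop_members: Sequence[str]):
        self.loop_members = list(loop_members)
        super().__init__(
            "pedigree loop detected; animals on the loop: "
            + ", ".join(self.loop_members)
        )


@dataclass
class PedigreeRecord:
    animal_id: str
    sire_id: str | None
    dam_id: str | None
    sex: Sex = Sex.UNKNOWN
    birth_year: int | None = None
    name: str | None = None
    subpop: str | None = None
    variety: str | None = None
    is_phantom: bool = False


@dataclass
class IssueReport:
    """Data problems found (and repaired) while preparing a pedigree."""

    born_before_parent: list[tuple[str, str]] = field(default_factory=list)
    dual_sex_parents: list[str] = field(default_factory=list)
    phantom_parents_created: list[str] = field(default_factory=list)
    unparseable_dates: list[str] = field(default_factory=list)
    loop_members: list[str] = field(default_factory=list)

    def to_text(self) -> str:
        lines = ["Pedigree issue report", "====================="]
        if not any(
            (self.born_before_parent, self.dual_sex_parents,
             self.phantom_parents_created, self.unparseable_dates,
             self.loop_members)
        ):
            lines.append("No issues found.")
        for child, parent in self.born_before_parent:
            lines.append(
                f"offspring {child} born before parent {parent}; parent set to unknown"
            )
        for aid in self.dual_sex_parents:
            lines.append(f"animal {aid} used both as a sire and as a dam")
        for aid in self.phantom_parents_created:
            lines.append(f"parent {aid} absent from file; phantom record created")
        for aid in self.unparseable_dates:
            lines.append(f"animal {aid}: unparseable birth date, set to unknown")
        if self.loop_members:
            lines.append(
                "pedigree loop; members: " + ", ".join(self.loop_members)
            )
        return "\n".join(lines) + "\n"

    def to_frame(self):
        import pandas as pd

        rows = []
        for child, parent in self.born_before_parent:
            rows.append(("born_before_parent", child, parent))
        for aid in self.dual_sex_parents:
            rows.append(("dual_sex_parent", aid, ""))
        for aid in self.phantom_parents_created:
            rows.append(("phantom_parent_created", aid, ""))
        for aid in self.unparseable_dates:
            rows.append(("unparseable_date", aid, ""))
        for aid in self.loop_members:
            rows.append(("loop_member", aid, ""))
        return pd.DataFrame(rows, columns=["issue", "animal", "other"])


def _parse_year(token: str) -> int | None:
    token = token.strip()
    try:
        value = int(token)
    except ValueError:
        m = _YEAR_RE.search(token)
        return int(m.group(1)) if m else None
    if 0 < value < 10000:
        return value
    return None


def _detect_delimiter(sample: str) -> str:
    counts = {d: sample.count(d) for d in (",", "\t", ";")}
    best = max(counts, key=counts.get)
    return best if counts[best] > 0 else " "


def parse_pedigree(
    path: str | Path | Iterable[str],
    column_spec: Mapping[str, int | str] | None = None,
    sex_codes: Mapping[str, str] | None = None,
    has_header: bool = False,
    delimiter: str | None = None,
    unknown_tokens: Sequence[str] = DEFAULT_UNKNOWN_TOKENS,
) -> tuple[list[PedigreeRecord], IssueReport]:
    """Read a pedigree file into records.

    ``column_spec`` maps the roles ``id, sire, dam, sex, year`` (plus optional
    ``name, subpop, variety``) to 0-based column indices, or to header names
    when ``has_header`` is true.  Dates are reduced to the birth year; rows
    whose date cannot be parsed get an unknown year and are logged on the
    returned :class:`IssueReport`.
    """
    if column_spec is None:
        column_spec = {role: i for i, role in enumerate(MANDATORY_ROLES)}
    missing = [r for r in MANDATORY_ROLES if r not in column_spec]
    if missing:
        raise PedigreeError(
            f"column_spec lacks mandatory roles: {', '.join(missing)}"
        )
    codes = {k.lower(): v for k, v in (sex_codes or DEFAULT_SEX_CODES).items()}
    unknown = {t.lower() for t in unknown_tokens}

    if isinstance(path, (str, Path)):
        text = Path(path).read_text()
        lines = text.splitlines()
    else:
        lines = [str(line).rstrip("\n") for line in path]
    lines = [ln for ln in lines if ln.strip()]
    if not lines:
        return [], IssueReport()
    if delimiter is None:
        delimiter = _detect_delimiter(lines[0])

    if delimiter == " ":
        rows = [ln.split() for ln in lines]
    else:
        rows = list(csv.reader(lines, delimiter=delimiter))

    header: list[str] | None = None
    if has_header:
        header, rows = [c.strip() for c in rows[0]], rows[1:]

    def col_index(role: str) -> int | None:
        if role not in column_spec:
            return None
        ref = column_spec[role]
        if isinstance(ref, int):
            return ref
        if header is None:
            raise PedigreeError(
                f"column for role {role!r} given by name {ref!r} but file has no header"
            )
        try:
            return header.index(ref)
        except ValueError:
            raise PedigreeError(f"header has no column named {ref!r}") from None

    idx = {role: col_index(role) for role in (*MANDATORY_ROLES, *OPTIONAL_ROLES)}

    report = IssueReport()
    records: list[PedigreeRecord] = []
    seen: dict[str, int] = {}
    dups: list[str] = []

    def cell(row: list[str], role: str) -> str | None:
        i = idx[role]
        if i is None or i >= len(row):
            return None
        return row[i].strip()

    for row in rows:
        aid = cell(row, "id")
        if aid is None or aid.lower() in unknown:
            continue
        sire = cell(row, "sire")
        dam = cell(row, "dam")
        sire = None if sire is None or sire.lower() in unknown else sire
        dam = None if dam is None or dam.lower() in unknown else dam
        sex_tok = (cell(row, "sex") or "").lower()
        sex = Sex(codes.get(sex_tok, "unknown"))
        year_tok = cell(row, "year")
        if year_tok is None or year_tok.lower() in unknown:
            year = None
        else:
            year = _parse_year(year_tok)
            if year is None:
                report.unparseable_dates.append(aid)
        rec = PedigreeRecord(
            animal_id=aid, sire_id=sire, dam_id=dam, sex=sex, birth_year=year,
            name=cell(row, "name"), subpop=cell(row, "subpop"),
            variety=cell(row, "variety"),
        )
        if aid in seen:
            dups.append(aid)
        seen[aid] = len(records)
        records.append(rec)
    if dups:
        raise DuplicateIdError(sorted(set(dups)))
    return records, report


def validate_and_repair(
    records: Sequence[PedigreeRecord],
    report: IssueReport | None = None,
) -> tuple[list[PedigreeRecord], IssueReport]:
    """Repair birth-order violations, create phantom parents, flag dual-sex use.

    A parent born strictly *after* its offspring has that parent link set to
    unknown (equal birth years are allowed: within-year generations occur in
    fast-breeding species).  Every referenced but absent parent gets a phantom
    record with unknown birth year and a sex inferred from the role it appears
    in.  An id used both as a sire and as a dam is reported but the links are
    kept.  Repairs never abort the analysis.
    """
    report = report or IssueReport()
    out = [replace(r) for r in records]
    index = {r.animal_id: r for r in out}

    used_as_sire = {r.sire_id for r in out if r.sire_id is not None}
    used_as_dam = {r.dam_id for r in out if r.dam_id is not None}
    report.dual_sex_parents.extend(sorted(used_as_sire & used_as_dam))

    phantoms: dict[str, PedigreeRecord] = {}
    for rec in out:
        for role, pid in (("sire", rec.sire_id), ("dam", rec.dam_id)):
            if pid is None or pid in index or pid in phantoms:
                continue
            phantoms[pid] = PedigreeRecord(
                animal_id=pid, sire_id=None, dam_id=None,
                sex=Sex.MALE if role == "sire" else Sex.FEMALE,
                birth_year=None, is_phantom=True,
            )
            report.phantom_parents_created.append(pid)
    out.extend(phantoms.values())
    index.update(phantoms)

    for rec in out:
        for role in ("sire_id", "dam_id"):
            pid = getattr(rec, role)
            if pid is None:
                continue
            parent = index[pid]
            if (
                rec.birth_year is not None
                and parent.birth_year is not None
                and parent.birth_year > rec.birth_year
            ):
                setattr(rec, role, None)
                report.born_before_parent.append((rec.animal_id, pid))
    return out, report


def topological_sort(
    records: Sequence[PedigreeRecord],
    report: IssueReport | None = None,
) -> "Pedigree":
    """Sort records so that every parent precedes its offspring.

    Ordering is stable: among records whose relative order is unconstrained,
    the original file order is preserved.  A pedigree loop aborts the sort
    with a :class:`PedigreeLoopError` listing one detected ancestor cycle.
    """
    pos = {r.animal_id: i for i, r in enumerate(records)}
    n = len(records)
    children: list[list[int]] = [[] for _ in range(n)]
    indeg = [0] * n
    for i, rec in enumerate(records):
        for pid in (rec.sire_id, rec.dam_id):
            if pid is None:
                continue
            if pid not in pos:
                raise PedigreeError(
                    f"unresolved parent id {pid!r}; run validate_and_repair first"
                )
            children[pos[pid]].append(i)
            indeg[i] += 1

    heap: list[int] = []
    for i, d in enumerate(indeg):
        if d == 0:
            heappush(heap, i)
    order: list[int] = []
    while heap:
        i = heappop(heap)
        order.append(i)
        for j in children[i]:
            indeg[j] -= 1
            if indeg[j] == 0:
                heappush(heap, j)

    if len(order) < n:
        remaining = {i for i in range(n) if indeg[i] > 0}
        # walk parent links inside the remaining set until a node repeats
        start = min(remaining)
        trail, seen_at = [], {}
        node = start
        while node not in seen_at:
            seen_at[node] = len(trail)
            trail.append(node)
            rec = records[node]
            nxt = None
            for pid in (rec.sire_id, rec.dam_id):
                if pid is not None and pos[pid] in remaining:
                    nxt = pos[pid]
                    break
            node = nxt
        cycle = trail[seen_at[node]:]
        members = sorted(records[i].animal_id for i in cycle)
        if report is not None:
            report.loop_members = list(members)
        raise PedigreeLoopError(members)

    return Pedigree([records[i] for i in order])


class Pedigree:
    """An ordered pedigree in which parents occur before offspring."""

    def __init__(self, records: Sequence[PedigreeRecord]):
        self.records: list[PedigreeRecord] = list(records)
        self.index: dict[str, int] = {
            r.animal_id: i for i, r in enumerate(self.records)
        }
        if len(self.index) != len(self.records):
            raise DuplicateIdError(
                sorted(
                    {r.animal_id for i, r in enumerate(self.records)
                     if self.index[r.animal_id] != i}
                )
            )
        n = len(self.records)
        # 1-based parent arrays with 0 = unknown, used by the relatedness code
        self.sire1 = np.zeros(n + 1, dtype=np.int64)
        self.dam1 = np.zeros(n + 1, dtype=np.int64)
        for i, rec in enumerate(self.records):
            for pid, arr in ((rec.sire_id, self.sire1), (rec.dam_id, self.dam1)):
                if pid is not None:
                    p = self.index[pid]
                    if p >= i:
                        raise PedigreeError(
                            f"pedigree not sorted: parent {pid} does not precede "
                            f"offspring {rec.animal_id}"
                        )
                    arr[i + 1] = p + 1
        self._F: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, animal_id: str) -> PedigreeRecord:
        return self.records[self.index[animal_id]]

    @property
    def ids(self) -> list[str]:
        return [r.animal_id for r in self.records]

    @property
    def birth_years(self) -> np.ndarray:
        return np.array(
            [np.nan if r.birth_year is None else r.birth_year for r in self.records]
        )

    def known_year_span(self) -> tuple[int, int] | None:
        years = [r.birth_year for r in self.records if r.birth_year is not None]
        if not years:
            return None
        return min(years), max(years)

    def parents_of(self, animal_id: str) -> tuple[str | None, str | None]:
        rec = self[animal_id]
        return rec.sire_id, rec.dam_id

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "animal_id": [r.animal_id for r in self.records],
                "sire_id": [r.sire_id for r in self.records],
                "dam_id": [r.dam_id for r in self.records],
                "sex": [r.sex.value for r in self.records],
                "birth_year": [r.birth_year for r in self.records],
                "subpop": [r.subpop for r in self.records],
                "variety": [r.variety for r in self.records],
                "is_phantom": [r.is_phantom for r in self.records],
            }
        )


def write_pedigree(
    pedigree: Pedigree | Sequence[PedigreeRecord],
    path: str | Path,
    delimiter: str = ",",
    unknown_token: str = "?",
    sex_tokens: Mapping[Sex, str] | None = None,
    include_phantoms: bool = True,
) -> None:
    """Write records as ``id, sire, dam, sex, year[, subpop, variety]``."""
    sex_tokens = sex_tokens or {Sex.MALE: "M", Sex.FEMALE: "F", Sex.UNKNOWN: "U"}
    records = pedigree.records if isinstance(pedigree, Pedigree) else list(pedigree)
    has_subpop = any(r.subpop is not None for r in records)
    has_variety = any(r.variety is not None for r in records)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        for rec in records:
            if rec.is_phantom and not include_phantoms:
                continue
            row = [
                rec.animal_id,
                rec.sire_id if rec.sire_id is not None else unknown_token,
                rec.dam_id if rec.dam_id is not None else unknown_token,
                sex_tokens[rec.sex],
                rec.birth_year if rec.birth_year is not None else unknown_token,
            ]
            if has_subpop:
                row.append(rec.subpop if rec.subpop is not None else unknown_token)
            if has_variety:
                row.append(rec.variety if rec.variety is not None else unknown_token)
            writer.writerow(row)


def load(
    path: str | Path | Iterable[str],
    **parse_kwargs,
) -> tuple[Pedigree, IssueReport]:
    """Parse, repair and sort a pedigree file in one call."""
    records, report = parse_pedigree(path, **parse_kwargs)
    records, report = validate_and_repair(records, report)
    pedigree = topological_sort(records, report)
    return pedigree, report
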