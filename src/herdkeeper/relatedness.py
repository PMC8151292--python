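"""Inbreeding coefficients and group-average kinships from a sorted pedigree.

Inbreeding coefficients are computed with the ancestor-tracing algorithm of
Meuwissen & Luo, which obtains the diagonal of the numerator relationship
matrix A without ever materialising it.  Group averages of kinship
(f_ij = a_ij / 2) use the indirect matrix-vector product A @ x derived from
the decomposition A = T D T', so the mean kinship of arbitrarily large groups
costs one linear pass over the pedigree per group.  Phantom and unknown
parents are treated as unrelated, non-inbred founders throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .pedigree_io import Pedigree

__all__ = [
    "inbreeding_coefficients",
    "inbreeding_series",
    "relationship_times_vector",
    "kinship_of_pair",
    "group_mean_kinship",
    "KinshipSummary",
    "mean_kinship_by_year",
    "kinship_between_groups",
]


def _ml_inbreeding(sire1: np.ndarray, dam1: np.ndarray) -> np.ndarray:
    """Meuwissen & Luo inbreeding coefficients.

    ``sire1``/``dam1`` are 1-based parent index arrays of length n+1 with
    entry 0 unused and 0 meaning "unknown parent"; parents must have lower
    index than offspring.  Returns F for animals 1..n (0-based array of
    length n).

    The algorithm traces, for each animal i, the set of its ancestors with a
    descending linked list (``point``), accumulating for each ancestor j the
    coefficient L_j (the fraction of genes of i expected to derive from j) and
    the within-family variance D_j; then F_i = sum_j L_j^2 D_j - 1 is obtained
    without the relationship matrix.
    """
    n = len(sire1) - 1
    F = np.zeros(n + 1)
    Fpad = np.empty(n + 1)
    Fpad[0] = -1.0  # unknown-parent convention: F = -1 so D = 1 for founders
    L = np.zeros(n + 1)
    D = np.zeros(n + 1)
    point = np.zeros(n + 1, dtype=np.int64)
    for i in range(1, n + 1):
        s, d = sire1[i], dam1[i]
        D[i] = 0.5 - 0.25 * (Fpad[s] + Fpad[d])
        if s == 0 or d == 0:
            F[i] = 0.0
            Fpad[i] = 0.0
            continue
        fi = -1.0
        L[i] = 1.0
        j = i
        while j != 0:
            k = j
            r = 0.5 * L[k]
            ks, kd = sire1[k], dam1[k]
            if ks < kd:  # insert larger index first: list is kept descending
                ks, kd = kd, ks
            if ks > 0:
                while point[k] > ks:
                    k = point[k]
                L[ks] += r
                if ks != point[k]:
                    point[ks] = point[k]
                    point[k] = ks
                if kd > 0:
                    while point[k] > kd:
                        k = point[k]
                    L[kd] += r
                    if kd != point[k]:
                        point[kd] = point[k]
                        point[k] = kd
            fi += L[j] * L[j] * D[j]
            L[j] = 0.0
            nxt = point[j]
            point[j] = 0
            j = nxt
        if fi < 0.0:  # F is non-negative; deep pedigrees can round to -1e-16
            fi = 0.0
        F[i] = fi
        Fpad[i] = fi
    return F[1:]


def inbreeding_coefficients(pedigree: Pedigree) -> np.ndarray:
    """F for every animal, in pedigree order.  Cached on the pedigree."""
    if pedigree._F is None:
        pedigree._F = _ml_inbreeding(pedigree.sire1, pedigree.dam1)
    return pedigree._F


def inbreeding_series(pedigree: Pedigree) -> pd.Series:
    """F keyed by animal id."""
    return pd.Series(inbreeding_coefficients(pedigree), index=pedigree.ids, name="F")


def relationship_times_vector(pedigree: Pedigree, x: np.ndarray) -> np.ndarray:
    """Indirect product ``A @ x`` of the numerator relationship matrix.

    Uses A = T D T' where T is the lower-triangular gene-flow matrix and D the
    diagonal of Mendelian-sampling variances: a backward pass computes
    w = T' x, then y = T (D w) by a forward pass.  O(n) per call.
    """
    n = len(pedigree)
    if len(x) != n:
        raise ValueError("vector length must equal pedigree size")
    F = inbreeding_coefficients(pedigree)
    sire1, dam1 = pedigree.sire1, pedigree.dam1
    # D_i = 0.5 - 0.25 (F_sire + F_dam), with F = -1 for unknown parents
    Fpad = np.concatenate(([-1.0], F))
    D = 0.5 - 0.25 * (Fpad[sire1[1:]] + Fpad[dam1[1:]])

    w = np.concatenate(([0.0], np.asarray(x, dtype=float)))
    for i in range(n, 0, -1):
        wi = w[i]
        if wi != 0.0:
            s, d = sire1[i], dam1[i]
            if s:
                w[s] += 0.5 * wi
            if d:
                w[d] += 0.5 * wi
    y = np.zeros(n + 1)
    u = D * w[1:]
    for i in range(1, n + 1):
        s, d = sire1[i], dam1[i]
        yi = u[i - 1]
        if s:
            yi += 0.5 * y[s]
        if d:
            yi += 0.5 * y[d]
        y[i] = yi
    return y[1:]


def kinship_of_pair(pedigree: Pedigree, i: str, j: str) -> float:
    """Kinship f_ij = a_ij / 2; ``kinship_of_pair(p, i, i) = (1 + F_i) / 2``."""
    for aid in (i, j):
        if aid not in pedigree.index:
            raise KeyError(f"unknown animal id {aid!r}")
    pi, pj = pedigree.index[i], pedigree.index[j]
    x = np.zeros(len(pedigree))
    x[pi] = 1.0
    return 0.5 * relationship_times_vector(pedigree, x)[pj]


def group_mean_kinship(
    pedigree: Pedigree,
    group_a: Sequence[int],
    group_b: Sequence[int] | None = None,
    include_self: bool = True,
) -> float:
    """Mean kinship over pairs drawn from two index groups (or within one).

    Within-group averages with ``include_self`` use all n^2 ordered pairs
    (equivalently all unordered pairs plus the n self-kinships); without it,
    the n diagonal terms (1 + F_i)/2 are removed and the mean runs over the
    n(n-1) off-diagonal pairs.  Cross-group averages ignore ``include_self``.
    """
    a = np.asarray(group_a, dtype=np.int64)
    if a.size == 0:
        return float("nan")
    x = np.zeros(len(pedigree))
    np.add.at(x, a, 1.0)
    y = relationship_times_vector(pedigree, x)
    if group_b is not None:
        b = np.asarray(group_b, dtype=np.int64)
        if b.size == 0:
            return float("nan")
        return 0.5 * float(y[b].sum()) / (a.size * b.size)
    total = float(y[a].sum())
    if include_self:
        return 0.5 * total / (a.size * a.size)
    if a.size < 2:
        return float("nan")
    F = inbreeding_coefficients(pedigree)
    diag = float((1.0 + F[a]).sum())
    return 0.5 * (total - diag) / (a.size * (a.size - 1))


@dataclass
class KinshipSummary:
    year: int
    n: int
    mean_f_incl_self: float
    mean_f_excl_self: float
    mean_f_future_parents: float
    mean_F: float
    group_pair_f: dict[tuple[str, str], float] = field(default_factory=dict)


def _parent_ids(pedigree: Pedigree) -> set[str]:
    used: set[str] = set()
    for rec in pedigree.records:
        if rec.sire_id is not None:
            used.add(rec.sire_id)
        if rec.dam_id is not None:
            used.add(rec.dam_id)
    return used


def mean_kinship_by_year(
    pedigree: Pedigree, include_self: bool = True
) -> list[KinshipSummary]:
    """Average kinship of the animals born in each calendar year.

    Every year from the first to the last known birth year is reported, even
    when no animal was born (undefined means).  Animals with unknown birth
    year contribute ancestry but never appear in a yearly group.  The
    ``include_self`` flag only selects which average downstream consumers
    treat as primary; both are always computed, together with the mean
    kinship of the year's animals that are later used as parents.
    """
    span = pedigree.known_year_span()
    if span is None:
        return []
    first, last = span
    years = np.array(
        [r.birth_year if r.birth_year is not None else -1 for r in pedigree.records]
    )
    parents = _parent_ids(pedigree)
    is_parent = np.array([r.animal_id in parents for r in pedigree.records])
    F = inbreeding_coefficients(pedigree)
    out = []
    for year in range(first, last + 1):
        idx = np.nonzero(years == year)[0]
        fut = idx[is_parent[idx]]
        out.append(
            KinshipSummary(
                year=year,
                n=idx.size,
                mean_f_incl_self=group_mean_kinship(pedigree, idx, include_self=True),
                mean_f_excl_self=group_mean_kinship(pedigree, idx, include_self=False),
                mean_f_future_parents=group_mean_kinship(
                    pedigree, fut, include_self=True
                ),
                mean_F=float(F[idx].mean()) if idx.size else float("nan"),
            )
        )
    return out


def kinship_between_groups(
    pedigree: Pedigree,
    group_map: Mapping[str, str] | None = None,
    per_year: bool = False,
) -> dict[tuple[str, str], float] | pd.DataFrame:
    """Mean kinship over cross-group animal pairs.

    ``group_map`` maps animal id to a group label; by default the subpop
    labels on the pedigree records are used.  With ``per_year`` the average is
    restricted, per calendar year, to animals born that year in each group
    (one row per year, one column per ordered group combination including the
    within-group diagonal); otherwise a single whole-period value per group
    pair is returned.
    """
    if group_map is None:
        group_map = {
            r.animal_id: r.subpop for r in pedigree.records if r.subpop is not None
        }
    labels = sorted(set(group_map.values()))
    members: dict[str, np.ndarray] = {
        g: np.array(
            [pedigree.index[a] for a, lbl in group_map.items() if lbl == g],
            dtype=np.int64,
        )
        for g in labels
    }
    if not per_year:
        out: dict[tuple[str, str], float] = {}
        for ga in labels:
            for gb in labels:
                if ga == gb:
                    out[(ga, gb)] = group_mean_kinship(
                        pedigree, members[ga], include_self=True
                    )
                else:
                    out[(ga, gb)] = group_mean_kinship(
                        pedigree, members[ga], members[gb]
                    )
        return out

    span = pedigree.known_year_span()
    if span is None:
        return pd.DataFrame()
    first, last = span
    years = np.array(
        [r.birth_year if r.birth_year is not None else -1 for r in pedigree.records]
    )
    rows = []
    for year in range(first, last + 1):
        row: dict[str, float] = {"year": year}
        for ga in labels:
            ia = members[ga][years[members[ga]] == year]
            for gb in labels:
                ib = members[gb][years[members[gb]] == year]
                key = f"{ga}|{gb}"
                if ga == gb:
                    row[key] = group_mean_kinship(pedigree, ia, include_self=True)
                else:
                    row[key] = group_mean_kinship(pedigree, ia, ib)
        rows.append(row)
    return pd.DataFrame(rows).set_index("year")
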