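"""Biallelic multi-locus genomes: meiosis, mutation, fitness and tracking.

Loci live on one or more chromosomes of a given map length (Morgan).  Meiosis
follows the Haldane model: the crossover count per chromosome is Poisson in
the map length with uniform crossover positions (no interference), and
chromosomes assort independently.  Each transmitted allele may flip with a
per-locus mutation probability.  A locus can carry a deleterious (focal)
allele with selection differential s and recessiveness h: a homozygote
survives with probability 1 - s and a heterozygote with 1 - h*s; the penalty
can act on newborn survival or on the fertility of a planned litter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "MAX_LOCI",
    "LocusSpec",
    "GenomeSpec",
    "init_genomes",
    "meiosis",
    "survival_probability",
    "apply_fitness",
    "FrequencyTrack",
]

MAX_LOCI = 32768


@dataclass
class LocusSpec:
    """Properties of one special locus (index into the genome's loci)."""

    index: int
    start_freq: float | None = None
    s: float = 0.0
    h: float = 0.0
    affects: str = "survival"  # or "fertility"
    first_year: int = 0
    position: tuple[int, float] | None = None  # (chromosome, Morgan offset)

    def validate(self) -> list[str]:
        issues = []
        if not 0.0 <= self.s <= 1.0:
            issues.append(f"locus {self.index}: s must be in [0, 1], got {self.s}")
        if not 0.0 <= self.h <= 1.0:
            issues.append(f"locus {self.index}: h must be in [0, 1], got {self.h}")
        if self.affects not in ("survival", "fertility"):
            issues.append(
                f"locus {self.index}: affects must be survival or fertility"
            )
        if self.start_freq is not None and not 0.0 <= self.start_freq <= 1.0:
            issues.append(f"locus {self.index}: start_freq must be in [0, 1]")
        return issues


@dataclass
class GenomeSpec:
    """Layout and properties of the simulated genome.

    By default all loci are neutral, evenly spaced over the chromosomes, and
    start at the same allele frequency; ``special_loci`` override individual
    loci (frequency, selection, position).
    """

    n_loci: int = 1
    n_chromosomes: int = 1
    map_length: float = 1.0  # Morgan per chromosome
    mutation_rate: float = 0.0
    start_freq: float = 0.5
    special_loci: list[LocusSpec] = field(default_factory=list)

    def __post_init__(self):
        if self.n_loci > MAX_LOCI:
            raise ValueError(f"n_loci may not exceed {MAX_LOCI}")
        if self.n_loci < 1 or self.n_chromosomes < 1:
            raise ValueError("need at least one locus on at least one chromosome")
        self._build_layout()

    def _build_layout(self) -> None:
        per = np.full(self.n_chromosomes, self.n_loci // self.n_chromosomes)
        per[: self.n_loci % self.n_chromosomes] += 1
        per = per[per > 0]
        chrom = np.repeat(np.arange(len(per)), per)
        pos = np.empty(self.n_loci)
        start = 0
        blocks = []
        for c, m in enumerate(per):
            if m == 1:
                pos[start] = self.map_length / 2.0
            else:
                pos[start : start + m] = np.linspace(0.0, self.map_length, m)
            blocks.append((start, start + int(m)))
            start += int(m)
        for sp in self.special_loci:
            if sp.position is not None:
                c, offset = sp.position
                chrom[sp.index] = c
                pos[sp.index] = offset
        self.chromosome = chrom
        self.position = pos
        self._blocks = blocks
        self._single_locus_chroms = all(e - s == 1 for s, e in blocks)
        freqs = np.full(self.n_loci, self.start_freq)
        s_arr = np.zeros(self.n_loci)
        h_arr = np.zeros(self.n_loci)
        first = np.zeros(self.n_loci, dtype=np.int64)
        fert = np.zeros(self.n_loci, dtype=bool)
        for sp in self.special_loci:
            if sp.start_freq is not None:
                freqs[sp.index] = sp.start_freq
            s_arr[sp.index] = sp.s
            h_arr[sp.index] = sp.h
            first[sp.index] = sp.first_year
            fert[sp.index] = sp.affects == "fertility"
        self.start_freqs = freqs
        self._s = s_arr
        self._h = h_arr
        self._first_year = first
        self._fertility = fert
        self._selected = np.nonzero(s_arr > 0)[0]

    def validate(self) -> list[str]:
        issues = []
        if not 0.0 <= self.start_freq <= 1.0:
            issues.append("start_freq must be in [0, 1]")
        if self.mutation_rate < 0 or self.mutation_rate > 1:
            issues.append("mutation_rate must be in [0, 1]")
        if self.map_length < 0:
            issues.append("map_length must be non-negative")
        for sp in self.special_loci:
            if not 0 <= sp.index < self.n_loci:
                issues.append(f"special locus index {sp.index} out of range")
            issues.extend(sp.validate())
        return issues


def init_genomes(
    spec: GenomeSpec, n_animals: int, rng: np.random.Generator
) -> np.ndarray:
    """Founder genomes: haplotype alleles i.i.d. Bernoulli(start frequency).

    Shape (n_animals, 2, n_loci), dtype uint8, allele 1 = the focal allele.
    """
    return (
        rng.random((n_animals, 2, spec.n_loci)) < spec.start_freqs
    ).astype(np.uint8)


def meiosis(
    genome: np.ndarray, spec: GenomeSpec, rng: np.random.Generator
) -> np.ndarray:
    """One gamete from a diploid genome of shape (2, n_loci)."""
    L = spec.n_loci
    if spec._single_locus_chroms:
        # unlinked loci: free recombination, one independent draw per locus
        src = rng.integers(0, 2, L)
        gamete = genome[src, np.arange(L)].copy()
    else:
        gamete = np.empty(L, dtype=np.uint8)
        for s, e in spec._blocks:
            start = int(rng.integers(0, 2))
            k = int(rng.poisson(spec.map_length))
            if k == 0:
                gamete[s:e] = genome[start, s:e]
            else:
                cuts = np.sort(rng.uniform(0.0, spec.map_length, k))
                par = (start + np.searchsorted(cuts, spec.position[s:e])) % 2
                gamete[s:e] = genome[par, np.arange(s, e)]
    if spec.mutation_rate > 0.0:
        flips = rng.random(L) < spec.mutation_rate
        gamete[flips] ^= 1
    return gamete


def survival_probability(
    genotype_counts: np.ndarray, spec: GenomeSpec, year: int, fertility: bool = False
) -> float:
    """Product over active deleterious loci of the genotype survival.

    ``genotype_counts`` holds the number of focal-allele copies (0/1/2) per
    locus.  Only loci whose effect class matches ``fertility`` and whose
    first effective year is <= ``year`` act.
    """
    sel = spec._selected
    if sel.size == 0:
        return 1.0
    active = sel[
        (spec._first_year[sel] <= year) & (spec._fertility[sel] == fertility)
    ]
    if active.size == 0:
        return 1.0
    g = genotype_counts[active]
    s, h = spec._s[active], spec._h[active]
    probs = np.where(g == 2, 1.0 - s, np.where(g == 1, 1.0 - h * s, 1.0))
    return float(np.prod(probs))


def apply_fitness(
    genotype_counts: np.ndarray,
    spec: GenomeSpec,
    year: int,
    rng: np.random.Generator,
    fertility: bool = False,
) -> bool:
    """Bernoulli survival/conception draw for one genotype."""
    p = survival_probability(genotype_counts, spec, year, fertility)
    if p >= 1.0:
        return True
    return bool(rng.random() < p)


class FrequencyTrack:
    """Allele and genotype frequencies per year, with absorption bookkeeping.

    Tracks the focal-allele frequency and genotype frequencies over the living
    animals each year, overall and per subpopulation, for the tracked loci
    (the special loci by default, every locus on request).  Records the first
    year each locus hits frequency 1 (fixation) or 0 (elimination); without
    mutation those states are absorbing.
    """

    def __init__(self, spec: GenomeSpec, loci: Sequence[int] | None = None):
        self.spec = spec
        if loci is None:
            loci = [sp.index for sp in spec.special_loci] or list(range(spec.n_loci))
        self.loci = np.asarray(sorted(set(loci)), dtype=np.int64)
        self.years: list[int] = []
        self.freq: list[np.ndarray] = []
        self.geno: list[np.ndarray] = []  # (n_loci_tracked, 3)
        self.freq_by_subpop: dict[int, list[np.ndarray]] = {}
        self.heterozygosity: list[float] = []
        self.fixation_year: dict[int, int | None] = {int(l): None for l in self.loci}
        self.elimination_year: dict[int, int | None] = {
            int(l): None for l in self.loci
        }

    def update(
        self, genomes: np.ndarray, subpops: np.ndarray, year: int
    ) -> None:
        if genomes.shape[0] == 0:
            return
        g = genomes[:, :, self.loci]
        counts = g.sum(axis=1)  # (n_animals, n_tracked)
        freq = counts.mean(axis=0) / 2.0
        geno = np.stack(
            [(counts == k).mean(axis=0) for k in (0, 1, 2)], axis=1
        )
        self.years.append(year)
        self.freq.append(freq)
        self.geno.append(geno)
        het = genomes[:, 0, :] != genomes[:, 1, :]
        self.heterozygosity.append(float(het.mean()))
        for sp in np.unique(subpops):
            mask = subpops == sp
            self.freq_by_subpop.setdefault(int(sp), []).append(
                counts[mask].mean(axis=0) / 2.0
            )
        for pos, locus in enumerate(self.loci):
            locus = int(locus)
            if freq[pos] >= 1.0 and self.fixation_year[locus] is None:
                self.fixation_year[locus] = year
            if freq[pos] <= 0.0 and self.elimination_year[locus] is None:
                self.elimination_year[locus] = year

    def final_frequencies(self) -> np.ndarray:
        return self.freq[-1] if self.freq else np.full(self.loci.size, np.nan)

    def to_frame(self):
        import pandas as pd

        rows = []
        for i, year in enumerate(self.years):
            for pos, locus in enumerate(self.loci):
                rows.append(
                    {
                        "year": year,
                        "locus": int(locus),
                        "freq": float(self.freq[i][pos]),
                        "geno_aa": float(self.geno[i][pos, 0]),
                        "geno_ab": float(self.geno[i][pos, 1]),
                        "geno_bb": float(self.geno[i][pos, 2]),
                    }
                )
        return pd.DataFrame(rows)
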