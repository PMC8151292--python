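# Methods

This note documents the models behind `herdkeeper`, the conventions and
defaults that matter for interpreting its output, and the limits of what the
synthetic-data tests demonstrate.

## Pedigree preparation

A pedigree file needs five roles per row — animal id, sire id, dam id, sex,
birth date — in any column order, with or without a header.  Dates are
reduced to the birth **year**: every monitoring table is per calendar year,
so sub-year resolution would not change any output.  Unknown parents and
dates are encoded by configurable tokens (default `0`, empty, `?`).

Repairs never abort an analysis:

- a parent born *strictly after* its offspring has that link set to unknown
  and is reported; equal birth years are allowed (within-year generations
  occur in fast breeders);
- parents referenced but absent get a phantom record (unknown year, sex
  inferred from the role they appear in); phantoms are treated as unrelated,
  non-inbred founders everywhere;
- ids used both as sire and dam are reported but the links are kept — the
  data cannot tell which role is wrong.

The only fatal condition is a pedigree loop (an animal its own ancestor):
sorting stops and one detected cycle is reported, which is what a studbook
keeper needs to locate the bad record.  Sorting is otherwise stable:
unconstrained records keep their file order, making the pipeline
deterministic and round-trippable.

## Inbreeding and kinship

F is computed with the Meuwissen–Luo ancestor-tracing algorithm (linked-list
variant), O(n · mean ancestor count), which handles a 25 000-animal pedigree
in minutes on one CPU without ever forming the relationship matrix A.  Group
averages (per birth-year cohort, parent groups, subpopulation pairs) use the
indirect product A·x via the decomposition A = T D T′ — one backward and one
forward pass over the pedigree per group, so the 17 monitoring tables cost
O(years × n).

Conventions that are easy to get wrong and are therefore fixed here:

- kinship f = a/2; self-kinship f(i,i) = (1 + F_i)/2;
- "including self" averages run over all n² ordered pairs of the group;
  "excluding self" removes the n diagonal terms and divides by n(n−1);
- animals with unknown birth year contribute ancestry but never appear in
  per-year rows;
- kinship *rates* use the including-self cohort average (group coancestry),
  the quantity whose complement is the group's expected future diversity.

An independent O(n²) tabular implementation of A (the textbook recursion)
ships in `fixtures` and is used both to validate generated truth records and
as the oracle the test suite compares the production algorithm against.

## Rates, periods, effective size

Over a period of n years (n = last − first; the convention is stated because
"a 5-year period" is ambiguous) with cohort means F₁ and Fₙ:

- generation-based: ΔF = 1 − ((1−Fₙ)/(1−F₁))^(L/n), with L the mean age of
  parents at offspring birth over the period's litters; year-based: L = 1;
- regression: minus the OLS slope of ln(1−F_y) on year.  On the geometric
  series F_y = 1−(1−r)^y this returns −ln(1−r), which differs from r at
  O(r²); the two estimators agree in the small-rate limit only;
- simulation runs start from unrelated founders (F = 0), so their rate
  reduces to ΔF = 1 − (1−Fₙ)^(L/n);
- Ne = 1/(2ΔF) for ΔF > 0; zero or negative rates (incomplete pedigrees,
  imports) leave Ne undefined rather than negative.

Whole-period rates are always computed; when the span reaches 10 years it is
additionally split into 5–6-year periods: floor(span/5) periods with the
excess years spread as equally as possible over the leading periods (spans
of 11–14 years make periods of up to 7 years — the only consistent reading
of the 5–6-year rule there).

## The simulator

One time step is a breeding cycle ("year"): a female can produce at most one
litter per cycle.  The yearly cycle is mating & birth → recording →
migration → culling & replacement.  Populations are kept at a constant census
with a fixed age structure — the situation of managed captive populations —
rather than being driven by birth and death rates.  Per-age-class breeding
targets come from the configured age distributions by largest-remainder
rounding; when an older class is larger than a younger one, non-breeding
juveniles are carried so that enough animals are available on aging.

Mating: for each litter the dam is drawn uniformly without replacement from
the eligible females of the target subpopulation; the sire's subpopulation
comes from the fertilization matrix row; the sire is uniform among eligible
males, so unrestricted litters per sire are asymptotically Poisson.
Designated top sires are used first until they reach their quota —
implemented as a hard per-year cap of ceil(fraction × litters), after which
they are excluded from the random pool, so the configured contribution is an
exact ceiling, not an expectation.  Litter sizes follow the configured
distribution; newborn sexes are independent fair coin flips.

Kinship is carried as a live symmetric matrix over the current animals
(rows/columns deleted at death, so memory is bounded by census size, not
simulation length): F(newborn) = K(sire, dam), K(newborn, x) =
(K(sire,x) + K(dam,x))/2.  This *is* the pedigree recursion, so the stored
coefficients equal a from-scratch pedigree recomputation to rounding error —
the strongest internal consistency check the suite runs.

Migration matrices are applied to newborns before recruitment (so rotational
schemes exchange only unbred animals), support counts or probabilities,
age/sex restrictions, and consecutive yearly schedules (year 1 uses the
first matrix).  Shortfalls (not enough eligible dams, failed fertility
draws, too few newborns to recruit) simply reduce litters or census;
populations can shrink and go extinct, which is recorded, never repaired.

Reproducibility: one master seed; each run gets a spawned child stream, so a
run's trajectory is independent of how many runs are requested, and the same
config + seed is bit-identical.

### Genetic management

Eligibility filters: per-year/lifetime litter quotas for sires, lifetime
quotas for dams (animals over a lifetime quota are removed and replaced),
own-F thresholds, and mean-kinship exclusion.  The exclusion removes animals
whose mean kinship with the living population *exceeds* the average —
conserving rare lineages requires removing over-represented animals; the
literal opposite direction is available behind an explicit flag
(`mean_kinship_literal_direction`) for comparison, since both readings
circulate.  Mate allocation: a pairwise-kinship ceiling, minimum-kinship
mating (argmin with uniform tie-breaks), and an optimal-contribution mode
that assigns litters to sires greedily to minimize c′Kc of the planned
parents — a documented heuristic validated against exhaustive search on
small instances, not a Lagrangian OC solver.  A cap on recruited sons per
sire holds across years.

### Genome

Up to 32 768 biallelic loci on one or more chromosomes, evenly spaced by
default, stored as unpacked byte haplotypes (64 KB per animal at the cap —
a deliberate trade of memory for vectorizable meiosis).  Meiosis follows the
Haldane model: Poisson(map length) crossovers, uniform positions, no
interference, free assortment across chromosomes; single-locus chromosomes
take a vectorized free-recombination path.  Mutation is a symmetric
per-locus flip.  A deleterious locus with selection differential s and
recessiveness h gives genotype survival 1, 1−hs, 1−s; survival loci are
drawn per newborn at birth, fertility loci are drawn per parent at
conception and a failed draw consumes the litter slot (no redraw), so
frequent defects depress the realized birth rate.  Frequencies, genotype
frequencies, heterozygosity and fixation/elimination years are tracked per
year, subpopulation and run.

### Rotational presets

For G groups, every newborn male migrates one scheme-step onward: breeding
circle offset 1 every year; Falconer offsets 1…G−1 cycling; MAI doubling
offsets (1, 2, 4, …, period ⌈log₂G⌉).  The zoo comparison uses a deer-like
demography fixed once: G groups of 2 males and 12 females, litter sizes 1–4
uniform, 5 litters per group per year, females breeding at ages 1–6
(0.25/0.20/0.20/0.15/0.12/0.08), males at ages 1–2 (0.5/0.5).  Crossovers
between replicate-mean inbreeding curves are read as the first year one
curve falls below another and stays below for 10 recorded years, which
suppresses single-year noise crossings of near-parallel curves.

Under these conditions the qualitative ordering is robust (isolated groups
worst by far; circle above panmixia early and below it from about year
65–70; circle above Falconer/MAI early, below them in the long run), but the
year at which the circle overtakes Falconer/MAI is late (~300) and
sensitive: the circle's asymptotic rate advantage over the alternating
schemes is only ~10% here, so the early deficit takes centuries to repay.
Published comparisons with other (unprinted) age structures place this
second crossover much earlier; the first crossover and the ordering, not
the exact second crossover year, are the transferable result.

## Synthetic data: what it shows and what it does not

The fixture generator builds forward-in-time pedigrees with known demography
and writes truth records (births, litters, top-sire fractions, generation
intervals, mean F validated by the tabular oracle) *during* generation, so
monitor tests are independent of the code under test.  Synthetic pedigrees
have clean ids, single-breed structure and no recording errors beyond the
ones deliberately injected; passing tests therefore demonstrate correct
arithmetic and bookkeeping, not robustness to the full zoo of real studbook
pathologies (typo years, duplicated animals under different ids, silent
breed crosses).  The error-repair paths are tested on constructed cases.

Test scale was chosen for minutes-scale wall time: 50–60-animal oracle
pedigrees (the tabular oracle is quadratic), a 25 000-animal performance
pedigree, 25–50 replicates for stochastic checks, 350-year rotation runs.

## Known limitations

- No confidence intervals on Ne; no individual-increase-in-inbreeding
  estimators for incomplete pedigrees.
- Demography is fixed per run (constant litters/year and age structure);
  scenario changes over time are limited to the migration/fertilization
  schedules.
- The OC mode optimizes the next cohort only, greedily.
- Only biallelic loci; no polygenic trait or breeding-value simulation.
- Self-fertilization is impossible by construction (separate sexes), so
  hermaphroditic species are out of scope.
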