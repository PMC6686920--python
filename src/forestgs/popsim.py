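"""Forward simulation of a structured forest breeding population.

The population history mirrors a standard conifer breeding program:

1. a base population of unrelated individuals whose haplotypes are sampled
   from a neutral equilibrium population (coalescent with mutation, or a
   forward Wright-Fisher mixing phase behind the same interface);
2. one cycle of phenotypic truncation selection followed by random mating;
3. a full-sib mating design in which a small set of selected founders is
   crossed into many families (by default 42 parents, 71 families averaging
   13 offspring, SD 5 — about 923 genotyped offspring).

The genome is 12 chromosomes of 100 cM each.  Meiosis assumes no crossover
interference: crossover counts are Poisson with one expected crossover per
Morgan, which reproduces Haldane's map function for recombinant fractions.

Individuals are identified by 1-based integer ids; parent id 0 means
unknown (founder).  Haplotypes are stored for every individual ever
created, row-aligned with the pedigree, as 0/1 allele codes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GenomeSpec:
    """Genome and base-population parameters.

    ``chrom_length_bp`` is the physical length simulated per chromosome; it
    only controls how many segregating sites the neutral model produces and
    is chosen so the expected site count comfortably exceeds
    ``n_marker_loci + n_qtl`` at the default mutation rate and effective
    size.  All downstream genetics happens on the genetic (cM) map.
    """

    n_chromosomes: int = 12
    chrom_length_cm: float = 100.0
    n_marker_loci: int = 10_000
    n_qtl: int = 30
    mutation_rate: float = 2.5e-8
    effective_size: int = 10_000
    chrom_length_bp: int = 500_000
    coalescent_segments: int = 20

    def __post_init__(self) -> None:
        for name in ("n_chromosomes", "n_marker_loci", "n_qtl",
                     "effective_size", "chrom_length_bp"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.chrom_length_cm < 0:
            raise ValueError("chrom_length_cm must be non-negative")
        if not 0 <= self.mutation_rate < 1:
            raise ValueError("mutation_rate must be in [0, 1)")

    @property
    def n_loci(self) -> int:
        return self.n_marker_loci + self.n_qtl


@dataclass
class Population:
    """Haplotypes plus pedigree for every individual created so far.

    ``haplotypes`` has shape (n_individuals, 2, n_loci) with 0/1 allele
    codes; row ``i`` belongs to pedigree id ``i + 1``.  ``chrom`` and
    ``pos_cm`` give the locus map.  ``marker_loci`` and ``qtl_loci`` are
    disjoint index sets into the locus axis.
    """

    haplotypes: np.ndarray
    sire: np.ndarray
    dam: np.ndarray
    generation: np.ndarray
    chrom: np.ndarray
    pos_cm: np.ndarray
    marker_loci: np.ndarray
    qtl_loci: np.ndarray
    phenotype_for_selection: np.ndarray | None = None
    family: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.family is None:
            self.family = np.zeros(self.n_individuals, dtype=np.int64)
        validate_pedigree(self.sire, self.dam, self.generation)

    @property
    def n_individuals(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_loci(self) -> int:
        return self.haplotypes.shape[2]

    @property
    def ids(self) -> np.ndarray:
        return np.arange(1, self.n_individuals + 1)

    @property
    def current_generation(self) -> int:
        return int(self.generation.max())

    def generation_index(self, gen: int | None = None) -> np.ndarray:
        """Row indices of one generation (default: the newest)."""
        if gen is None:
            gen = self.current_generation
        return np.flatnonzero(self.generation == gen)

    def genotypes(self, rows: np.ndarray | None = None) -> np.ndarray:
        """Allele dosages 0/1/2 for the given rows (default: newest generation)."""
        if rows is None:
            rows = self.generation_index()
        return self.haplotypes[rows].sum(axis=1)

    def pedigree_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "id": self.ids,
            "sire": self.sire,
            "dam": self.dam,
            "generation": self.generation,
        })


@dataclass
class MarkerCodings:
    """Additive/dominance marker design matrices on the genotyped individuals.

    ``X`` codes genotypes AA/Aa/aa as 1/0/-1 and ``W`` as 0/1/0, where "A"
    is the allele whose frequency is ``p``.  Monomorphic loci have been
    removed; ``kept_loci`` maps columns back to the original locus indices.
    """

    X: np.ndarray
    W: np.ndarray
    p: np.ndarray
    q: np.ndarray
    kept_loci: np.ndarray

    def __post_init__(self) -> None:
        if self.X.shape != self.W.shape:
            raise ValueError("X and W must share dimensions")
        if np.any((self.p <= 0) | (self.p >= 1)):
            raise ValueError("allele frequencies must be in (0, 1) "
                             "after monomorphic-locus removal")
        if not np.array_equal(self.W == 1, self.X == 0):
            raise ValueError("W must be 1 exactly where X is 0")

    @property
    def n_individuals(self) -> int:
        return self.X.shape[0]

    @property
    def n_loci(self) -> int:
        return self.X.shape[1]


class InsufficientSegregatingLoci(ValueError):
    """Raised when the neutral model yields fewer segregating sites than needed."""


def validate_pedigree(sire: np.ndarray, dam: np.ndarray,
                      generation: np.ndarray) -> None:
    """Check pedigree invariants: parents precede offspring, sire != dam.

    Ids are implicit 1..n in record order, so "parent id < own id" is both
    acyclicity and generation sorting.
    """
    ids = np.arange(1, len(sire) + 1)
    known = sire > 0
    if np.any(sire[known] >= ids[known]) or np.any(dam[dam > 0] >= ids[dam > 0]):
        raise ValueError("every parent must precede its offspring")
    if np.any((sire > 0) != (dam > 0)):
        raise ValueError("individuals must have both parents known or neither")
    if np.any((sire == dam) & known):
        raise ValueError("sire and dam must differ (no selfing)")
    both = known & (dam > 0)
    if np.any(generation[both] <= np.maximum(
            generation[sire[both] - 1], generation[dam[both] - 1])):
        raise ValueError("offspring generation must exceed parents'")


# ---------------------------------------------------------------------------
# Base population
# ---------------------------------------------------------------------------

def _coalescent_haplotypes(spec: GenomeSpec, n_haplotypes: int,
                           seed: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sample haplotypes per chromosome from the standard neutral coalescent.

    Each chromosome is simulated as ``spec.coalescent_segments`` independent
    sub-segments concatenated at their true map positions.  At the default
    effective size, linkage disequilibrium between loci more than one
    segment apart (10 cM) is negligible (r^2 on the order of 1/(4 Ne d)),
    while the scaled recombination rate per coalescent run drops enough to
    make the ancestral-recombination-graph simulation tractable.  Diversity
    summaries (site counts, frequency spectra) are unaffected.
    """
    import msprime

    hap_chunks, chrom_ids, pos_chunks = [], [], []
    n_seg = max(1, spec.coalescent_segments)
    seg_bp = spec.chrom_length_bp / n_seg
    seg_cm = spec.chrom_length_cm / n_seg
    recomb_rate = (spec.chrom_length_cm / 100.0) / spec.chrom_length_bp
    seeds = np.random.default_rng(seed).integers(
        1, 2**31, size=(spec.n_chromosomes, n_seg, 2))
    for c in range(spec.n_chromosomes):
        for s in range(n_seg):
            ts = msprime.sim_ancestry(
                samples=n_haplotypes // 2,
                ploidy=2,
                population_size=spec.effective_size,
                sequence_length=seg_bp,
                recombination_rate=recomb_rate,
                random_seed=int(seeds[c, s, 0]),
            )
            ts = msprime.sim_mutations(
                ts,
                rate=spec.mutation_rate,
                model=msprime.BinaryMutationModel(),
                random_seed=int(seeds[c, s, 1]),
            )
            if ts.num_sites == 0:
                continue
            geno = ts.genotype_matrix()  # (sites, haplotypes)
            counts = geno.sum(axis=1)
            seg = (counts > 0) & (counts < n_haplotypes)
            if not np.any(seg):
                continue
            hap_chunks.append(geno[seg].T.astype(np.uint8))
            pos = np.array([site.position for site in ts.sites()])[seg]
            pos_chunks.append(s * seg_cm + pos / seg_bp * seg_cm)
            chrom_ids.append(np.full(int(seg.sum()), c, dtype=np.int16))
    if not hap_chunks:
        raise InsufficientSegregatingLoci(
            f"0 segregating loci produced; {spec.n_loci} required")
    haps = np.concatenate(hap_chunks, axis=1)
    return haps, np.concatenate(chrom_ids), np.concatenate(pos_chunks)


def _wright_fisher_haplotypes(spec: GenomeSpec, n_haplotypes: int, seed: int,
                              n_generations: int = 10) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Forward-time fallback: seed allele frequencies from the neutral SFS,
    then mix linkage by random-mating Wright-Fisher generations.

    Sites are seeded at twice the equilibrium expectation because the
    short mixing phase, run at the sample size rather than the effective
    size, loses a share of the rare variants to drift.
    """
    rng = np.random.default_rng(seed)
    theta_site = 4 * spec.effective_size * spec.mutation_rate
    mean_sites = (theta_site * spec.chrom_length_bp * spec.n_chromosomes
                  * np.sum(1.0 / np.arange(1, n_haplotypes)))
    n_sites = rng.poisson(2.0 * mean_sites)
    if n_sites == 0:
        raise InsufficientSegregatingLoci(
            f"0 segregating loci produced; {spec.n_loci} required")
    # neutral SFS: P(derived count = x) propto 1/x, x in 1..n-1
    x = np.arange(1, n_haplotypes)
    counts = rng.choice(x, size=n_sites, p=(1.0 / x) / np.sum(1.0 / x))
    haps = np.zeros((n_haplotypes, n_sites), dtype=np.uint8)
    for j, cnt in enumerate(counts):
        haps[rng.choice(n_haplotypes, size=cnt, replace=False), j] = 1
    chrom = rng.integers(0, spec.n_chromosomes, size=n_sites).astype(np.int16)
    pos = rng.uniform(0, spec.chrom_length_cm, size=n_sites)
    order = np.lexsort((pos, chrom))
    haps, chrom, pos = haps[:, order], chrom[order], pos[order]
    n_ind = n_haplotypes // 2
    for _ in range(n_generations):
        new = np.empty_like(haps[:2 * n_ind])
        for i in range(n_ind):
            s, d = rng.choice(n_ind, size=2, replace=False)
            new[2 * i] = make_gamete(haps[2 * s:2 * s + 2], chrom, pos, rng)
            new[2 * i + 1] = make_gamete(haps[2 * d:2 * d + 2], chrom, pos, rng)
        haps = new
        seg = (haps.sum(axis=0) > 0) & (haps.sum(axis=0) < len(haps))
        haps, chrom, pos = haps[:, seg], chrom[seg], pos[seg]
    return haps, chrom, pos


def simulate_base_population(spec: GenomeSpec, n_individuals: int, seed: int,
                             method: str = "coalescent") -> Population:
    """Create the unrelated base population and place marker/QTL loci.

    Haplotypes are drawn from a neutral equilibrium population at the
    spec's effective size and mutation rate (``method='coalescent'``, the
    default) or from a forward Wright-Fisher mixing phase
    (``method='wright_fisher'``).  Marker and QTL loci are disjoint random
    subsets of the segregating sites.
    """
    if n_individuals < 2:
        raise ValueError("need at least 2 individuals")
    if method == "coalescent":
        haps, chrom, pos = _coalescent_haplotypes(spec, 2 * n_individuals, seed)
    elif method == "wright_fisher":
        haps, chrom, pos = _wright_fisher_haplotypes(spec, 2 * n_individuals, seed)
    else:
        raise ValueError(f"unknown base-population method: {method!r}")

    n_seg = haps.shape[1]
    if n_seg < spec.n_loci:
        raise InsufficientSegregatingLoci(
            f"only {n_seg} segregating loci but {spec.n_loci} required "
            f"({spec.n_marker_loci} markers + {spec.n_qtl} QTL); "
            f"shortfall {spec.n_loci - n_seg}")

    rng = np.random.default_rng(seed)
    chosen = np.sort(rng.choice(n_seg, size=spec.n_loci, replace=False))
    haps = haps[:, chosen]
    chrom, pos = chrom[chosen], pos[chosen]
    which_qtl = rng.choice(spec.n_loci, size=spec.n_qtl, replace=False)
    is_qtl = np.zeros(spec.n_loci, dtype=bool)
    is_qtl[which_qtl] = True

    haplotypes = haps.reshape(n_individuals, 2, spec.n_loci)
    zeros = np.zeros(n_individuals, dtype=np.int64)
    logger.info("base population: %d individuals, %d segregating loci "
                "(%d markers, %d QTL)", n_individuals, n_seg,
                spec.n_marker_loci, spec.n_qtl)
    return Population(
        haplotypes=haplotypes,
        sire=zeros.copy(), dam=zeros.copy(), generation=zeros.copy(),
        chrom=chrom, pos_cm=pos,
        marker_loci=np.flatnonzero(~is_qtl),
        qtl_loci=np.flatnonzero(is_qtl),
    )


# ---------------------------------------------------------------------------
# Meiosis and mating
# ---------------------------------------------------------------------------

def make_gamete(parent_haplotypes: np.ndarray, chrom: np.ndarray,
                pos_cm: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Produce one recombinant haplotype from a (2, n_loci) parent.

    Crossovers per chromosome are Poisson with mean length-in-Morgans (no
    interference), placed uniformly; the starting strand is random, and
    chromosomes assort independently.  Recombinant fractions follow
    Haldane's map function r = (1 - exp(-2d)) / 2.
    """
    if parent_haplotypes.shape[0] != 2 or parent_haplotypes.shape[1] != len(pos_cm):
        raise ValueError("parent must have two haplotypes over the locus map")
    gamete = np.empty(parent_haplotypes.shape[1], dtype=parent_haplotypes.dtype)
    for c in np.unique(chrom):
        idx = np.flatnonzero(chrom == c)
        length_cm = pos_cm[idx].max() if len(idx) else 0.0
        n_cross = rng.poisson(length_cm / 100.0)
        start = rng.integers(2)
        if n_cross == 0:
            phase = np.full(len(idx), start)
        else:
            cross_pos = np.sort(rng.uniform(0.0, length_cm, size=n_cross))
            phase = (start + np.searchsorted(cross_pos, pos_cm[idx])) % 2
        gamete[idx] = parent_haplotypes[phase, idx]
    return gamete


def _mate(pop: Population, sires: np.ndarray, dams: np.ndarray,
          generation: int, family: np.ndarray,
          rng: np.random.Generator) -> Population:
    """Append offspring of the given (sire, dam) id pairs to the population."""
    n_off = len(sires)
    off = np.empty((n_off, 2, pop.n_loci), dtype=pop.haplotypes.dtype)
    for i in range(n_off):
        off[i, 0] = make_gamete(pop.haplotypes[sires[i] - 1], pop.chrom,
                                pop.pos_cm, rng)
        off[i, 1] = make_gamete(pop.haplotypes[dams[i] - 1], pop.chrom,
                                pop.pos_cm, rng)
    gen = np.full(n_off, generation, dtype=np.int64)
    return Population(
        haplotypes=np.concatenate([pop.haplotypes, off]),
        sire=np.concatenate([pop.sire, sires]),
        dam=np.concatenate([pop.dam, dams]),
        generation=np.concatenate([pop.generation, gen]),
        chrom=pop.chrom, pos_cm=pop.pos_cm,
        marker_loci=pop.marker_loci, qtl_loci=pop.qtl_loci,
        family=np.concatenate([pop.family, family]),
    )


def breed_generation(pop: Population, phenotypes: np.ndarray, n_select: int,
                     n_offspring: int, rng: np.random.Generator) -> Population:
    """Truncation-select parents on phenotype, then mate random distinct pairs.

    ``phenotypes`` aligns with the population's newest generation.  The top
    ``n_select`` individuals become the parent pool; each offspring draws
    two distinct parents uniformly at random.
    """
    if n_select < 2:
        raise ValueError("need at least 2 selected parents")
    gen_rows = pop.generation_index()
    if len(phenotypes) != len(gen_rows):
        raise ValueError("phenotypes must align with the current generation")
    top = gen_rows[np.argsort(phenotypes)[::-1][:n_select]]
    parent_ids = top + 1
    pairs = np.empty((n_offspring, 2), dtype=np.int64)
    for i in range(n_offspring):
        pairs[i] = rng.choice(parent_ids, size=2, replace=False)
    return _mate(pop, pairs[:, 0], pairs[:, 1], pop.current_generation + 1,
                 np.zeros(n_offspring, dtype=np.int64), rng)


def cclones_design(pop: Population, phenotypes: np.ndarray,
                   rng: np.random.Generator, n_founders: int = 42,
                   n_families: int = 71, family_mean: float = 13.0,
                   family_sd: float = 5.0,
                   total_range: tuple[int, int] | None = (900, 950),
                   ) -> Population:
    """Cross phenotypically selected founders into a full-sib family design.

    The defaults emulate the CCLONES loblolly pine population: 42 selected
    parents crossed into 71 distinct full-sib families whose sizes are
    rounded normal(13, 5) draws truncated at 1, resampled until the total
    offspring count falls in ``total_range`` (about 923 genotyped
    individuals).  Each parent may appear in several crosses; selfing is
    excluded.
    """
    gen_rows = pop.generation_index()
    if len(phenotypes) != len(gen_rows):
        raise ValueError("phenotypes must align with the current generation")
    if len(gen_rows) < n_founders:
        raise ValueError("not enough candidates to select founders from")
    n_pairs = n_founders * (n_founders - 1) // 2
    if n_families > n_pairs:
        raise ValueError(
            f"{n_families} families requested but only {n_pairs} distinct "
            f"pairs exist among {n_founders} founders")

    top = gen_rows[np.argsort(phenotypes)[::-1][:n_founders]]
    founder_ids = top + 1
    pair_idx = rng.choice(n_pairs, size=n_families, replace=False)
    iu, ju = np.triu_indices(n_founders, k=1)
    sires = founder_ids[iu[pair_idx]]
    dams = founder_ids[ju[pair_idx]]

    for _ in range(10_000):
        sizes = np.maximum(1, np.rint(
            rng.normal(family_mean, family_sd, size=n_families))).astype(np.int64)
        if total_range is None or total_range[0] <= sizes.sum() <= total_range[1]:
            break
    else:
        raise RuntimeError("could not draw family sizes inside total_range")

    off_sire = np.repeat(sires, sizes)
    off_dam = np.repeat(dams, sizes)
    family = np.repeat(np.arange(1, n_families + 1), sizes)
    logger.info("mating design: %d founders, %d families, %d offspring",
                n_founders, n_families, sizes.sum())
    return _mate(pop, off_sire, off_dam, pop.current_generation + 1,
                 family, rng)


# ---------------------------------------------------------------------------
# Marker coding
# ---------------------------------------------------------------------------

def encode_markers(pop: Population, loci: np.ndarray | None = None,
                   rows: np.ndarray | None = None) -> MarkerCodings:
    """Build additive (-1/0/1) and dominance (0/1/0) codings with frequencies.

    Computed on the genotyped (newest) generation by default.  Loci that
    are monomorphic among those individuals are dropped and the count
    logged.
    """
    if loci is None:
        loci = pop.marker_loci
    if rows is None:
        rows = pop.generation_index()
    dosage = pop.haplotypes[rows][:, :, loci].sum(axis=1).astype(np.int8)
    p = dosage.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    n_dropped = int((~poly).sum())
    if n_dropped:
        logger.info("dropped %d monomorphic loci (%d retained)",
                    n_dropped, int(poly.sum()))
    dosage = dosage[:, poly]
    X = (dosage - 1).astype(np.int8)
    W = (dosage == 1).astype(np.int8)
    return MarkerCodings(X=X, W=W, p=p[poly], q=1.0 - p[poly],
                         kept_loci=np.asarray(loci)[poly])
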