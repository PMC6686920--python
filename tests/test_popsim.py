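"""Population simulator: coalescent diversity, meiosis, mating designs."""

import numpy as np
import pytest

from forestgs import popsim
from forestgs.popsim import (
    GenomeSpec, Population, simulate_base_population, make_gamete,
    breed_generation, cclones_design, encode_markers,
    InsufficientSegregatingLoci, validate_pedigree,
)


def _toy_population(haps, chrom=None, pos=None, **kw):
    n, _, L = haps.shape
    zeros = np.zeros(n, dtype=np.int64)
    return Population(
        haplotypes=haps.astype(np.uint8),
        sire=kw.get("sire", zeros.copy()), dam=kw.get("dam", zeros.copy()),
        generation=kw.get("generation", zeros.copy()),
        chrom=chrom if chrom is not None else np.zeros(L, dtype=np.int16),
        pos_cm=pos if pos is not None else np.linspace(0, 100, L),
        marker_loci=np.arange(L), qtl_loci=np.array([], dtype=int))


class TestBasePopulation:

    def test_watterson_segregating_sites(self):
        """Mean segregating-site count matches theta * sum 1/i (coalescent)."""
        spec = GenomeSpec(n_chromosomes=1, n_marker_loci=5, n_qtl=1,
                          chrom_length_bp=100_000, effective_size=1000,
                          coalescent_segments=4)
        n_hap = 50
        theta = 4 * spec.effective_size * spec.mutation_rate \
            * spec.chrom_length_bp
        expected = theta * np.sum(1.0 / np.arange(1, n_hap))
        counts = [popsim._coalescent_haplotypes(spec, n_hap, seed)[0].shape[1]
                  for seed in range(1, 21)]
        # MC error of the mean over 20 reps: site counts are roughly
        # Poisson-overdispersed around the expectation
        assert np.mean(counts) == pytest.approx(expected, rel=0.15)

    def test_insufficient_loci_error_names_shortfall(self):
        spec = GenomeSpec(n_chromosomes=1, n_marker_loci=100_000, n_qtl=10,
                          chrom_length_bp=10_000, effective_size=500)
        with pytest.raises(InsufficientSegregatingLoci, match="shortfall"):
            simulate_base_population(spec, 10, seed=1)

    def test_zero_mutation_rate_raises(self):
        spec = GenomeSpec(n_chromosomes=1, n_marker_loci=10, n_qtl=2,
                          chrom_length_bp=50_000, effective_size=500,
                          mutation_rate=0.0)
        with pytest.raises(InsufficientSegregatingLoci):
            simulate_base_population(spec, 10, seed=1)

    def test_marker_and_qtl_loci_disjoint(self, small_rep):
        pop = small_rep.pop
        assert not set(pop.marker_loci) & set(pop.qtl_loci)
        assert len(pop.marker_loci) + len(pop.qtl_loci) == pop.n_loci

    def test_wright_fisher_fallback_matches_interface(self):
        spec = GenomeSpec(n_chromosomes=2, n_marker_loci=50, n_qtl=5,
                          chrom_length_bp=250_000, effective_size=500)
        pop = simulate_base_population(spec, 30, seed=4,
                                       method="wright_fisher")
        assert pop.n_individuals == 30
        assert pop.n_loci == 55
        freqs = pop.genotypes().mean(axis=0) / 2
        assert np.all((freqs > 0) & (freqs < 1))


class TestMeiosis:

    def test_zero_length_chromosome_no_recombination(self, rng):
        haps = np.array([[0, 0, 0], [1, 1, 1]], dtype=np.uint8)
        chrom = np.zeros(3, dtype=np.int16)
        pos = np.zeros(3)
        for _ in range(20):
            g = make_gamete(haps, chrom, pos, rng)
            assert np.array_equal(g, haps[0]) or np.array_equal(g, haps[1])

    def test_homozygous_parent_gamete_identical(self, rng):
        hap = np.tile(np.array([0, 1, 1, 0, 1], dtype=np.uint8), (2, 1))
        chrom = np.zeros(5, dtype=np.int16)
        g = make_gamete(hap, chrom, np.linspace(0, 100, 5), rng)
        assert np.array_equal(g, hap[0])

    def test_haldane_recombinant_fraction_50cm(self):
        """Observed recombinant fraction at 50 cM matches (1-e^-1)/2."""
        rng = np.random.default_rng(42)
        haps = np.array([[0, 0], [1, 1]], dtype=np.uint8)
        chrom = np.zeros(2, dtype=np.int16)
        pos = np.array([0.0, 50.0])
        n = 20_000
        rec = 0
        for _ in range(n):
            g = make_gamete(haps, chrom, pos, rng)
            rec += g[0] != g[1]
        expected = (1 - np.exp(-1.0)) / 2
        assert rec / n == pytest.approx(expected, abs=0.01)

    def test_recombinant_fraction_monotone_and_bounded(self):
        rng = np.random.default_rng(7)
        dists = [5.0, 20.0, 50.0, 90.0]
        pos = np.array([0.0] + dists)
        haps = np.tile(np.array([[0], [1]], dtype=np.uint8), (1, len(pos)))
        chrom = np.zeros(len(pos), dtype=np.int16)
        n = 8_000
        recs = np.zeros(len(dists))
        for _ in range(n):
            g = make_gamete(haps, chrom, pos, rng)
            recs += g[1:] != g[0]
        fracs = recs / n
        assert np.all(np.diff(fracs) > 0)
        assert np.all(fracs < 0.5 + 3 * np.sqrt(0.25 / n))


class TestMating:

    @pytest.fixture(scope="class")
    def base(self):
        spec = GenomeSpec(n_chromosomes=2, n_marker_loci=80, n_qtl=10,
                          chrom_length_bp=100_000, effective_size=1000)
        return simulate_base_population(spec, 120, seed=5)

    def test_truncation_selection_differential(self, base, rng):
        """Top-10% parental mean exceeds population mean by ~ i * sigma_p.

        The selection intensity i comes from an order-statistics
        simulation oracle run in-test.
        """
        n, frac = 120, 0.1
        k = int(n * frac)
        pheno = rng.normal(0, 2.0, size=n)
        pop2 = breed_generation(base, pheno, n_select=k, n_offspring=50,
                                rng=rng)
        parents = np.unique(np.concatenate([
            pop2.sire[pop2.generation == 1], pop2.dam[pop2.generation == 1]]))
        sel_mean = pheno[parents - 1].mean()
        # order-statistics oracle for the intensity of top-k/n selection
        sims = np.sort(rng.normal(size=(4000, n)))[:, -k:].mean(axis=1)
        intensity = sims.mean()
        assert sel_mean - pheno.mean() == pytest.approx(
            intensity * pheno.std(), abs=3 * sims.std() * 2.0)

    def test_no_truncation_zero_differential(self, base, rng):
        pheno = rng.normal(size=120)
        pop2 = breed_generation(base, pheno, n_select=120, n_offspring=300,
                                rng=rng)
        parents = np.unique(np.concatenate([
            pop2.sire[pop2.generation == 1], pop2.dam[pop2.generation == 1]]))
        assert len(parents) > 100  # nearly everyone drawn as a parent
        assert pheno[parents - 1].mean() == pytest.approx(
            pheno.mean(), abs=3 * pheno.std() / np.sqrt(len(parents)))

    def test_breed_requires_two_parents(self, base, rng):
        with pytest.raises(ValueError):
            breed_generation(base, np.zeros(120), n_select=1,
                             n_offspring=10, rng=rng)

    def test_no_selection_preserves_mean_genetic_value(self, base, rng):
        """Without truncation, offspring mean additive value is unchanged."""
        qtl = base.qtl_loci
        a = rng.normal(size=len(qtl))
        gv_parent = (base.genotypes()[:, qtl] - 1.0) @ a
        pop2 = breed_generation(base, np.zeros(120), n_select=120,
                                n_offspring=400, rng=rng)
        gv_off = (pop2.genotypes()[:, qtl] - 1.0) @ a
        se = gv_parent.std() / np.sqrt(400)
        assert gv_off.mean() == pytest.approx(gv_parent.mean(), abs=4 * se)

    def test_drift_is_unbiased_across_replicates(self, base):
        """Mean allele-frequency change over one random-mating generation
        is zero over replicates."""
        deltas = []
        for seed in range(12):
            rng = np.random.default_rng(100 + seed)
            pop2 = breed_generation(base, np.zeros(120), n_select=120,
                                    n_offspring=120, rng=rng)
            f0 = base.genotypes(base.generation_index(0)).mean(0) / 2
            f1 = pop2.genotypes().mean(0) / 2
            deltas.append(np.mean(f1 - f0))
        assert np.mean(deltas) == pytest.approx(0.0, abs=0.005)

    def test_cclones_design_constraints(self, base, rng):
        pheno = rng.normal(size=120)
        pop2 = breed_generation(base, pheno, n_select=40, n_offspring=100,
                                rng=rng)
        pheno2 = rng.normal(size=100)
        pop3 = cclones_design(pop2, pheno2, rng, n_founders=20,
                              n_families=30, family_mean=6, family_sd=2,
                              total_range=None)
        rows = pop3.generation_index()
        sires, dams = pop3.sire[rows], pop3.dam[rows]
        assert np.all(sires != dams)
        founders = np.unique(np.concatenate([sires, dams]))
        assert len(founders) <= 20
        fams = set(zip(sires, dams))
        assert len(fams) == 30
        assert len(np.unique(pop3.family[rows])) == 30
        validate_pedigree(pop3.sire, pop3.dam, pop3.generation)

    def test_cclones_family_size_and_single_family(self, base, rng):
        pheno = rng.normal(size=120)
        pop2 = breed_generation(base, pheno, n_select=40, n_offspring=100,
                                rng=rng)
        pop3 = cclones_design(pop2, np.zeros(100), rng, n_founders=10,
                              n_families=1, family_mean=12, family_sd=3,
                              total_range=None)
        rows = pop3.generation_index()
        assert len(set(zip(pop3.sire[rows], pop3.dam[rows]))) == 1

    def test_cclones_too_many_families_raises(self, base, rng):
        pheno = rng.normal(size=120)
        pop2 = breed_generation(base, pheno, n_select=40, n_offspring=100,
                                rng=rng)
        with pytest.raises(ValueError, match="distinct"):
            cclones_design(pop2, np.zeros(100), rng, n_founders=5,
                           n_families=11, total_range=None)


class TestEncodeMarkers:

    def test_toy_codings_and_frequencies(self):
        # three individuals: AA, Aa, aa at locus 0; monomorphic locus 1
        haps = np.array([[[1, 1], [1, 1]],
                         [[1, 1], [0, 1]],
                         [[0, 1], [0, 1]]])
        pop = _toy_population(haps)
        mc = encode_markers(pop, loci=np.array([0, 1]))
        assert mc.n_loci == 1  # monomorphic locus dropped
        assert np.array_equal(mc.X[:, 0], [1, 0, -1])
        assert np.array_equal(mc.W[:, 0], [0, 1, 0])
        assert mc.p[0] == pytest.approx(0.5)

    def test_heterozygote_coding(self, small_rep):
        mc = small_rep.markers
        assert np.array_equal(mc.W == 1, mc.X == 0)
        assert np.all((mc.p > 0) & (mc.p < 1))


class TestPedigreeInvariants:

    def test_parent_after_offspring_rejected(self):
        with pytest.raises(ValueError, match="precede"):
            validate_pedigree(np.array([0, 3, 1]), np.array([0, 1, 2]),
                              np.array([0, 1, 2]))

    def test_selfing_rejected(self):
        with pytest.raises(ValueError, match="differ"):
            validate_pedigree(np.array([0, 0, 1]), np.array([0, 0, 1]),
                              np.array([0, 0, 1]))

    def test_generation_sorted(self, small_rep):
        pop = small_rep.pop
        validate_pedigree(pop.sire, pop.dam, pop.generation)
        assert pop.current_generation == 2
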