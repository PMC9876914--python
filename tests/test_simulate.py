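"""The synthetic screen generator: mutation spectrum, meiosis, selection,
pooled sequencing, and file round trips."""
import numpy as np
import pytest
from scipy import stats

from ssmap import simulate, snpindex
from ssmap.errors import InputError, SelectionError


class TestMutagenize:
    def test_zero_lambda_gives_empty_set(self, small_genome):
        assert len(simulate.mutagenize(small_genome, 0.0, seed=1)) == 0

    def test_spectrum_and_poisson_count_over_seeds(self, small_genome):
        """All EMS hits are G->A or C->T at G/C sites; counts are Poisson."""
        lam = 50.0
        lo = stats.poisson.ppf(0.0005, lam)
        hi = stats.poisson.ppf(0.9995, lam)
        for seed in range(100):
            ms = simulate.mutagenize(small_genome, lam, seed=seed)
            assert lo <= len(ms) <= hi
            for m in ms:
                assert (m.ref, m.alt) in {("G", "A"), ("C", "T")}
                assert small_genome.base(m.chrom, m.pos) == m.ref

    def test_deterministic_given_seed(self, small_genome):
        a = simulate.mutagenize(small_genome, 100.0, seed=5)
        b = simulate.mutagenize(small_genome, 100.0, seed=5)
        assert a == b

    def test_no_gc_sites_is_an_error(self):
        at_only = simulate.GenomeSpec(
            chromosomes=(("chr1", 10_000),), gc_fraction=0.0, seed=0
        )
        with pytest.raises(InputError, match="G/C"):
            simulate.mutagenize(at_only, 50.0, seed=3)

    def test_negative_lambda_rejected(self, small_genome):
        with pytest.raises(InputError):
            simulate.mutagenize(small_genome, -1.0, seed=0)


class TestMeiosis:
    def test_zero_map_length_gives_single_founder_blocks(self, small_genome):
        plants = simulate.make_bc1f2(small_genome, 20, map_length_cm=0.0, seed=2)
        for p in plants:
            for h1, h2 in p.haplotypes.values():
                assert h1.crossovers == () and h2.crossovers == ()

    def test_negative_map_length_rejected(self, small_genome):
        with pytest.raises(InputError):
            simulate.make_bc1f2(small_genome, 5, map_length_cm=-1.0, seed=0)

    def test_single_locus_dosage_segregates_1_2_1(self, small_genome):
        """Mendelian check: BC1F2 dosage frequencies are 1:2:1 within 3 s.e."""
        n = 10_000
        plants = simulate.make_bc1f2(small_genome, n, map_length_cm=90.0, seed=7)
        pos = np.array([75_000])
        dosages = np.array([p.dosage("chrA", pos)[0] for p in plants])
        counts = np.bincount(dosages, minlength=3)
        for k, p_exp in zip(range(3), (0.25, 0.5, 0.25)):
            se = np.sqrt(n * p_exp * (1 - p_exp))
            assert abs(counts[k] - n * p_exp) <= 3 * se

    @pytest.mark.parametrize("d_cm", [1.0, 10.0, 50.0])
    def test_haldane_recombinant_fraction(self, small_genome, d_cm):
        """Gamete-level recombinant fraction matches r = (1 - e^(-2d/100)) / 2."""
        map_cm, length = 90.0, 150_000
        pos_a = 30_000
        pos_b = pos_a + int(d_cm / map_cm * length)
        plants = simulate.make_bc1f2(small_genome, 4_000, map_cm, seed=int(d_cm))
        positions = np.array([pos_a, pos_b])
        n_rec = n_tot = 0
        for p in plants:
            for hap in p.haplotypes["chrA"]:
                fa, fb = hap.founders_at(positions)
                n_rec += int(fa != fb)
                n_tot += 1
        r_exp = 0.5 * (1 - np.exp(-2 * d_cm / 100))
        se = np.sqrt(r_exp * (1 - r_exp) / n_tot)
        assert abs(n_rec / n_tot - r_exp) <= 3 * se


class TestPhenotypeAndSelection:
    def test_genotype_means(self):
        m = simulate.PhenotypeModel(mu_bg=20, effect=3, h=1.0, sigma=0.0)
        assert m.genotype_mean(np.array([2]))[0] == 26.0
        assert m.genotype_mean(np.array([1]))[0] == m.genotype_mean(np.array([2]))[0]
        rec = simulate.PhenotypeModel(mu_bg=20, effect=3, h=0.0, sigma=0.0)
        assert rec.genotype_mean(np.array([1]))[0] == 20.0

    def test_phenotypes_deterministic_and_causal_required(self, small_genome):
        plants = simulate.make_bc1f2(small_genome, 10, seed=3)
        no_causal = simulate.mutagenize(small_genome, 20.0, seed=3)
        model = simulate.PhenotypeModel()
        with pytest.raises(InputError, match="causal"):
            simulate.assign_phenotypes(plants, model, no_causal, seed=0)
        first = no_causal.entries[0]
        ms = no_causal.with_causal(first.chrom, first.pos)
        a = simulate.assign_phenotypes(plants, model, ms, seed=4)
        b = simulate.assign_phenotypes(plants, model, ms, seed=4)
        np.testing.assert_array_equal(a, b)

    def test_threshold_rule_selects_late_flowering_plants(self):
        spec = simulate.PoolSpec(n_population=4, pool_size=4)
        sel = simulate.select_pool(np.array([19.0, 24.0, 25.0, 26.0]), spec, 20.0)
        assert list(sel) == [2, 3]

    def test_no_qualifying_plant_raises(self):
        spec = simulate.PoolSpec(n_population=3, pool_size=3)
        with pytest.raises(SelectionError, match="suppressor"):
            simulate.select_pool(np.array([18.0, 19.0, 20.0]), spec, 20.0)

    def test_pool_capped_at_m_largest(self):
        spec = simulate.PoolSpec(n_population=6, pool_size=2)
        phen = np.array([26.0, 27.0, 28.0, 25.0, 24.0, 29.0])
        sel = simulate.select_pool(phen, spec, 20.0)
        assert list(sel) == [2, 5]

    def test_recessive_noiseless_selection_is_homozygous_only(self, small_genome):
        """With sigma = 0 and h = 0 only dosage-2 plants can be selected."""
        plants = simulate.make_bc1f2(small_genome, 200, seed=9)
        ms = simulate.mutagenize(small_genome, 30.0, seed=9)
        first = ms.entries[0]
        ms = ms.with_causal(first.chrom, first.pos)
        model = simulate.PhenotypeModel(h=0.0, sigma=0.0)
        phen = simulate.assign_phenotypes(plants, model, ms, seed=1)
        spec = simulate.PoolSpec(n_population=200, pool_size=200)
        sel = simulate.select_pool(phen, spec, model.mu_bg)
        pos = np.array([first.pos])
        for i in sel:
            assert plants[i].dosage(first.chrom, pos)[0] == 2


class TestPooledSequencing:
    def _causal_set(self, genome, seed):
        ms = simulate.mutagenize(genome, 30.0, seed=seed)
        first = ms.entries[0]
        return ms.with_causal(first.chrom, first.pos)

    def test_fixed_allele_reads_all_alternate(self, small_genome):
        """epsilon = 0, all plants homozygous mutant => alt depth = total depth."""
        ms = self._causal_set(small_genome, 21)
        plants = simulate.make_bc1f2(small_genome, 50, map_length_cm=0.0, seed=100)
        homs = [
            p for p in plants
            if all(h1.first == h2.first == simulate.MUTANT
                   for h1, h2 in p.haplotypes.values())
        ]
        assert homs, "seed must yield at least one double-mutant plant"
        spec = simulate.PoolSpec(error_rate=0.0)
        recs = simulate.pool_read_counts(homs, ms, spec, seed=1)
        for r in recs:
            assert r.ref_depth == 0 and r.alt_depth == r.depth

    def test_background_plants_carry_no_induced_alleles(self, small_genome):
        ms = self._causal_set(small_genome, 22)
        bg = simulate.pure_background_plants(small_genome, 10)
        spec = simulate.PoolSpec(error_rate=0.0)
        recs = simulate.pool_read_counts(bg, ms, spec, seed=2)
        for r in recs:
            assert r.alt_depth == 0

    def test_background_origin_sites_are_fixed_in_any_pool(self, small_genome):
        shared = simulate.background_variants(small_genome, 40, seed=5)
        bg = simulate.pure_background_plants(small_genome, 10)
        freqs = simulate.pool_allele_freqs(bg, shared)
        np.testing.assert_array_equal(freqs, np.ones(len(shared)))

    def test_empty_pool_is_an_error(self, small_genome):
        ms = self._causal_set(small_genome, 23)
        with pytest.raises(InputError, match="empty"):
            simulate.pool_read_counts([], ms, simulate.PoolSpec(), seed=0)

    def test_dominant_selection_pool_frequency_two_thirds(self, small_genome):
        """Conditioned on carrying >= 1 allele, a BC1F2 plant is homozygous
        with probability 1/3 and heterozygous with 2/3 (exhaustive enumeration
        of the 1:2:1 classes), so the selected-pool frequency tends to 2/3."""
        cond = {2: 1 / 4, 1: 2 / 4}  # unnormalized, dosage 0 excluded
        expected = sum(d / 2 * w for d, w in cond.items()) / sum(cond.values())
        assert expected == pytest.approx(2 / 3)

        ms = self._causal_set(small_genome, 24)
        causal = ms.causal
        model = simulate.PhenotypeModel(h=1.0, sigma=0.5)
        spec = simulate.PoolSpec(n_population=115, pool_size=35)
        rng = np.random.default_rng(42)
        freqs = []
        for _ in range(50):
            plants = simulate.make_bc1f2(small_genome, 115, seed=rng)
            phen = simulate.assign_phenotypes(plants, model, ms, seed=rng)
            sel = simulate.select_pool(phen, spec, model.mu_bg)
            sub = [plants[i] for i in sel]
            idx = [i for i, m in enumerate(ms) if m == causal][0]
            freqs.append(simulate.pool_allele_freqs(sub, ms)[idx])
        se = np.std(freqs, ddof=1) / np.sqrt(len(freqs))
        assert abs(np.mean(freqs) - 2 / 3) <= 3 * se


class TestOutputs:
    def test_vcf_and_truth_round_trip(self, small_genome, tmp_path):
        ms = simulate.mutagenize(small_genome, 40.0, seed=31)
        first = ms.entries[0]
        ms = ms.with_causal(first.chrom, first.pos)
        plants = simulate.make_bc1f2(small_genome, 20, seed=31)
        spec = simulate.PoolSpec(n_population=20, pool_size=10)
        recs = simulate.pool_read_counts(plants[:10], ms, spec, seed=1)
        bg = simulate.pool_read_counts(
            simulate.pure_background_plants(small_genome, 5), ms, spec, seed=2
        )
        f_mut = simulate.pool_allele_freqs(plants[:10], ms)
        f_bg = simulate.pool_allele_freqs(
            simulate.pure_background_plants(small_genome, 5), ms
        )
        paths = simulate.write_truth_and_vcf(
            recs, bg, ms, f_mut, f_bg, small_genome, tmp_path
        )
        back = snpindex.read_variants(paths["mut_vcf"], "mutant")
        assert [(r.chrom, r.pos, r.ref, r.alt, r.ref_depth, r.alt_depth)
                for r in back] == [
            (r.chrom, r.pos, r.ref, r.alt, r.ref_depth, r.alt_depth)
            for r in sorted(recs, key=lambda r: (r.chrom, r.pos))
        ]
        truth_lines = open(paths["truth"]).read().strip().splitlines()
        assert len(truth_lines) - 1 == len(ms)

    def test_identical_seeds_give_byte_identical_vcfs(self, small_genome, tmp_path):
        ms = simulate.mutagenize(small_genome, 30.0, seed=8)
        plants = simulate.make_bc1f2(small_genome, 10, seed=8)
        spec = simulate.PoolSpec(n_population=10, pool_size=5)
        outputs = []
        for tag in ("a", "b"):
            recs = simulate.pool_read_counts(plants[:5], ms, spec, seed=99)
            path = tmp_path / f"{tag}.vcf"
            simulate.write_vcf(recs, small_genome, path)
            outputs.append(path.read_bytes())
        assert outputs[0] == outputs[1]
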