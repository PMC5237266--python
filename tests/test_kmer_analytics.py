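"""k-mer spectra, site filtering, enrichment ratios and rate conversions."""

import numpy as np
import pandas as pd
import pytest

import trekkit as tk
from trekkit.analytics import (KmerSpectrum, central_cpg_mask, contains_cg_mask,
                               convert_rate, count_kmers, enrichment,
                               enrichment_slope, expected_fractions,
                               filter_mutation_sites, genome_rate_estimate,
                               spectrum_correlation)
from trekkit.analytics import EnrichmentRecord


class TestCountKmers:
    def test_single_bases(self):
        assert count_kmers("ACGT", 1).counts.tolist() == [1, 1, 1, 1]

    def test_overlapping_windows(self):
        spec = count_kmers("AAAA", 2)
        assert spec.counts[tk.kmer_index("AA")] == 3
        assert spec.counts.sum() == 3

    def test_windows_with_n_are_skipped(self):
        spec = count_kmers("AANAA", 2)
        assert spec.counts.sum() == 2

    def test_k_longer_than_sequence_gives_empty_spectrum(self):
        assert count_kmers("ACG", 5).counts.sum() == 0

    @pytest.mark.parametrize("k", [1, 2, 3, 5, 7])
    def test_matches_naive_substring_oracle(self, k):
        rng = np.random.default_rng(k)
        seq = "".join(rng.choice(list("ACGTN"), size=10_000,
                                 p=[0.24, 0.24, 0.24, 0.24, 0.04]))
        got = count_kmers(seq, k).counts
        naive = np.zeros(4 ** k, dtype=int)
        for i in range(len(seq) - k + 1):
            w = seq[i: i + k]
            if "N" not in w:
                naive[tk.kmer_index(w)] += 1
        assert (got == naive).all()

    def test_lexicological_index_round_trips(self):
        for k in (1, 2, 3):
            for idx in range(4 ** k):
                assert tk.kmer_index(tk.index_to_kmer(idx, k)) == idx
        rng = np.random.default_rng(1)
        for idx in rng.integers(0, 4 ** 7, size=200):
            assert tk.kmer_index(tk.index_to_kmer(int(idx), 7)) == idx


class TestExpectedFractions:
    def test_triad_probability_is_base_product(self):
        p = np.array([0.1, 0.2, 0.3, 0.4])
        spec = expected_fractions(p, 3)
        assert spec.fractions[tk.kmer_index("AGT")] == pytest.approx(0.1 * 0.3 * 0.4)

    def test_uniform_composition_gives_equal_fractions(self):
        spec = expected_fractions([0.25] * 4, 5)
        assert np.allclose(spec.fractions, 4.0 ** -5)

    def test_fractions_sum_to_one_for_random_compositions(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            p = rng.dirichlet(np.ones(4))
            for k in (1, 3, 7):
                assert expected_fractions(p, k).fractions.sum() == pytest.approx(1.0)

    def test_k1_reproduces_the_composition(self):
        p = np.array([0.3, 0.15, 0.25, 0.3])
        assert np.allclose(expected_fractions(p, 1).fractions, p)


class TestSpectrumCorrelation:
    def test_identical_spectra_correlate_perfectly(self):
        spec = count_kmers(tk.make_reference(3000, 0.45, seed=3).sequence, 2)
        assert spectrum_correlation(spec, spec) == pytest.approx(1.0)

    def test_contains_cg_drops_exactly_one_dyad(self):
        assert contains_cg_mask(2).sum() == 1  # only CG itself

    def test_central_cpg_mask_examples(self):
        m = central_cpg_mask(3)
        assert m[tk.kmer_index("ACG")]       # central C before G
        assert m[tk.kmer_index("CGT")]       # central G after C
        assert not m[tk.kmer_index("AGC")]

    def test_matches_direct_formula_oracle(self):
        rng = np.random.default_rng(4)
        a = KmerSpectrum.from_counts(3, rng.integers(1, 100, size=64))
        b = KmerSpectrum.from_counts(3, rng.integers(1, 100, size=64))
        x, y = a.fractions, b.fractions
        r = ((x - x.mean()) @ (y - y.mean())) / np.sqrt(
            ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
        assert spectrum_correlation(a, b) == pytest.approx(r, abs=1e-12)


def toy_sites(rows):
    df = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt",
                                     "is_snp", "non_coding"])
    df["cancer_type"] = ""
    return tk.MutationSiteTable(df)


class TestFilterSites:
    def test_snp_and_duplicate_rules(self):
        table = toy_sites([
            ("s", 10, "A", "G", False, True),
            ("s", 11, "C", "T", True, True),    # SNP: dropped
            ("s", 10, "A", "G", False, True),   # duplicate of row 1: dropped
            ("s", 12, "G", "A", False, True),
            ("s", 10, "A", "T", False, True),   # same pos, different alt: kept
        ])
        kept, report = filter_mutation_sites(table)
        assert len(kept) == 3
        assert (report.n_snp, report.n_duplicate) == (1, 1)

    def test_coding_rows_dropped(self):
        table = toy_sites([("s", 1, "A", "G", False, False),
                           ("s", 2, "C", "T", False, True)])
        kept, report = filter_mutation_sites(table)
        assert len(kept) == 1 and report.n_coding == 1

    def test_no_duplicates_is_identity(self):
        table = toy_sites([("s", i, "A", "G", False, True) for i in range(1, 6)])
        kept, _ = filter_mutation_sites(table)
        assert kept.df[["pos"]].values.tolist() == [[i] for i in range(1, 6)]

    def test_matches_set_dedup_oracle(self):
        rng = np.random.default_rng(5)
        rows = [("s", int(rng.integers(1, 20)), "A", "CGT"[rng.integers(3)],
                 bool(rng.random() < 0.2), bool(rng.random() < 0.9))
                for _ in range(300)]
        kept, _ = filter_mutation_sites(toy_sites(rows))
        seen, survivors = set(), []
        for chrom, pos, ref, alt, snp, nc in rows:
            if not nc or snp:
                continue
            key = (chrom, pos, ref, alt)
            if key not in seen:
                seen.add(key)
                survivors.append(key)
        got = list(map(tuple, kept.df[["chrom", "pos", "ref", "alt"]].values))
        assert got == survivors


class TestEnrichment:
    def test_genome_against_itself_gives_unit_ratios(self, truth3_db):
        genome = tk.make_reference(4000, 0.5, seed=6).sequence
        rows = [("synth1", i, genome[i - 1], "A" if genome[i - 1] != "A" else "C",
                 False, True) for i in range(4, len(genome) - 2)]
        records = enrichment(toy_sites(rows), genome, truth3_db)
        for r in records:
            assert r.ratio == pytest.approx(1.0)

    def test_shared_heptamer_ratio_is_reciprocal_genome_fraction(self, truth3_db):
        genome = "AAAAAAA" + tk.make_reference(993, 0.5, seed=7).sequence
        rows = [("synth1", 4, "A", "G", False, True)] * 1  # one site, AAAAAAA context
        records = enrichment(toy_sites(rows), genome, truth3_db)
        assert len(records) == 1
        rec = records[0]
        assert rec.site_fraction == 1.0
        assert rec.ratio == pytest.approx(1.0 / rec.genome_fraction)

    def test_ref_mismatch_rejected(self, truth3_db):
        genome = tk.make_reference(100, 0.5, seed=8).sequence
        wrong = "A" if genome[49] != "A" else "C"
        good = ("synth1", 60, genome[59], "A" if genome[59] != "A" else "C",
                False, True)
        records = enrichment(toy_sites([("synth1", 50, wrong, "G", False, True),
                                        good]), genome, truth3_db)
        assert sum(r.n_sites for r in records) == 1

    def test_uniform_sites_give_unit_mean_ratio(self, truth3_db):
        # two-letter genome so each heptamer recurs often enough for its
        # ratio to concentrate around the null value 1
        genome = tk.make_reference(30_000, 0.0, seed=9)
        table = tk.make_mutation_sites(genome, truth3_db, n=8000,
                                       weighting="uniform", seed=10)
        records = enrichment(table, genome.sequence, truth3_db)
        mean_ratio = np.mean([r.ratio for r in records])
        assert mean_ratio == pytest.approx(1.0, abs=0.1)

    def test_bsp_weighted_sites_give_positive_slope(self, truth3_db):
        genome = tk.make_reference(30_000, 0.0, seed=11)
        table = tk.make_mutation_sites(genome, truth3_db, n=8000,
                                       weighting="bsp", seed=12)
        records = enrichment(table, genome.sequence, truth3_db)
        assert enrichment_slope(records, bsp_max=np.inf) > 0


class TestEnrichmentSlope:
    def make_records(self, bsps, ratios):
        return [EnrichmentRecord(kmer="AAAAAAA", site_fraction=0.0,
                                 genome_fraction=1.0, ratio=r, central_bsp=b,
                                 cpg_central=False, contains_cg=False, n_sites=1)
                for b, r in zip(bsps, ratios)]

    def test_constant_ratio_gives_zero_slope(self):
        recs = self.make_records([0.2, 0.5, 0.9, 1.1], [1.0] * 4)
        assert enrichment_slope(recs) == pytest.approx(0.0)

    def test_exact_line_gives_its_slope(self):
        bsps = [0.2, 0.5, 0.9, 1.1]
        recs = self.make_records(bsps, [2 * b for b in bsps])
        assert enrichment_slope(recs) == pytest.approx(2.0)

    def test_bsp_cutoff_and_cpg_exclusion_apply(self):
        recs = self.make_records([0.2, 0.5, 0.9, 2.5], [0.4, 1.0, 1.8, 99.0])
        recs[0].cpg_central = True
        # retained: 0.5 and 0.9 only -> too few points
        with pytest.raises(ValueError, match="need >= 3"):
            enrichment_slope(recs)

    def test_matches_closed_form_ols_oracle(self):
        rng = np.random.default_rng(13)
        bsps = rng.uniform(0, 1.2, size=40)
        ratios = rng.uniform(0.2, 1.5, size=40)
        slope = enrichment_slope(self.make_records(bsps, ratios))
        xc = bsps - bsps.mean()
        assert slope == pytest.approx(float(xc @ (ratios - ratios.mean()) / (xc @ xc)))


class TestGenomeRateEstimate:
    def singleton_db(self, matrix):
        return tk.TruthModel.singleton(np.asarray(matrix, float)).to_database()

    def test_uniform_composition_equal_bsp_returns_it(self):
        db = self.singleton_db(np.full((4, 4), 0.5))  # BSP = 1.5 everywhere
        est = genome_rate_estimate([0.25] * 4, db)
        assert est.rate_byr == pytest.approx(1.5)

    def test_matches_dot_product_oracle(self):
        rng = np.random.default_rng(14)
        m = rng.uniform(0.1, 1.0, size=(4, 4))
        comp = rng.dirichlet(np.ones(4))
        est = genome_rate_estimate(comp, self.singleton_db(m))
        np.fill_diagonal(m, 0.0)
        assert est.rate_byr == pytest.approx(float(comp @ m.sum(axis=1)))

    def test_per_generation_conversion_is_exact(self):
        db = self.singleton_db(np.full((4, 4), 0.392))  # BSP = 1.176
        est = genome_rate_estimate([0.25] * 4, db, generation_years=20.0)
        assert est.rate_byr == pytest.approx(1.176)
        assert est.rate_per_generation == pytest.approx(2.352e-8)
        assert est.rate_per_generation == est.rate_byr * 20.0 / 1e9

    def test_missing_singleton_errors(self):
        db = tk.TrekDatabase()
        db.add(tk.RateConstant(kmer="A", target_base="C", rate=1.0, context_level=1))
        with pytest.raises(KeyError, match="missing level-1"):
            genome_rate_estimate([0.25] * 4, db)

    def test_linearity_in_each_bsp(self):
        base = np.full((4, 4), 0.3)
        bumped = base.copy()
        bumped[0, 1] += 0.6  # raise A's BSP by 0.6
        comp = [0.3, 0.2, 0.2, 0.3]
        d = genome_rate_estimate(comp, self.singleton_db(bumped)).rate_byr - \
            genome_rate_estimate(comp, self.singleton_db(base)).rate_byr
        assert d == pytest.approx(0.3 * 0.6)


class TestConvertRate:
    def test_crude_human_rate_is_0_64_byr(self):
        assert convert_rate(12.85e-9, 20) == pytest.approx(0.6425)

    def test_zero_passes_through(self):
        assert convert_rate(0.0, 20) == 0.0

    def test_round_trip_with_genome_estimate(self):
        db = tk.TruthModel.singleton(np.full((4, 4), 0.25)).to_database()
        est = genome_rate_estimate([0.25] * 4, db, generation_years=25.0)
        assert convert_rate(est.rate_per_generation, 25.0) == \
            pytest.approx(est.rate_byr)
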