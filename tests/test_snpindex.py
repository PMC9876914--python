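"""SNP index, ΔSNP index, filtering and candidate calling."""
import random

import numpy as np
import pytest
from hypothesis import given, strategies as st

from ssmap import simulate, snpindex
from ssmap.errors import FormatError, UndefinedIndexError
from ssmap.snpindex import VariantRecord

VCF_TEMPLATE = """\
##fileformat=VCFv4.2
##contig=<ID=chr1,length=100000>
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Total depth">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tpool
{rows}
"""


def write_vcf(tmp_path, rows, name="test.vcf"):
    path = tmp_path / name
    path.write_text(VCF_TEMPLATE.format(rows="\n".join(rows)))
    return path


class TestReadVariants:
    def test_parses_biallelic_rows_and_depths(self, tmp_path):
        path = write_vcf(
            tmp_path,
            [
                "chr1\t100\t.\tG\tA\t60\tPASS\t.\tAD:DP\t20,40:60",
                "chr1\t200\t.\tC\tT\t60\tPASS\t.\tAD:DP\t55,5:60",
                "chr1\t300\t.\tG\tA\t60\tPASS\t.\tAD:DP\t0,61:61",
            ],
        )
        recs = snpindex.read_variants(path, "mutant")
        assert len(recs) == 3
        assert (recs[0].ref_depth, recs[0].alt_depth) == (20, 40)
        assert not any(r.multiallelic for r in recs)

    def test_multiallelic_rows_flagged_not_dropped(self, tmp_path):
        path = write_vcf(
            tmp_path,
            ["chr1\t100\t.\tG\tA,T\t60\tPASS\t.\tAD:DP\t20,30,10:60"],
        )
        recs = snpindex.read_variants(path, "mutant")
        assert len(recs) == 1 and recs[0].multiallelic

    def test_missing_ad_field_names_the_field(self, tmp_path):
        path = tmp_path / "noad.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n"
            "##contig=<ID=chr1,length=1000>\n"
            '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="d">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tpool\n"
            "chr1\t100\t.\tG\tA\t60\tPASS\t.\tDP\t60\n"
        )
        with pytest.raises(FormatError, match="AD"):
            snpindex.read_variants(path, "mutant")


class TestIndices:
    @pytest.mark.parametrize(
        "ref_d,alt_d,expected",
        [(60, 0, 0.0), (0, 60, 1.0), (20, 40, 2 / 3)],
    )
    def test_snp_index_values(self, ref_d, alt_d, expected):
        rec = VariantRecord("chr1", 1, "G", "A", ref_d, alt_d)
        assert snpindex.snp_index(rec) == pytest.approx(expected, abs=1e-4)

    def test_zero_depth_is_undefined(self):
        rec = VariantRecord("chr1", 1, "G", "A", 0, 0)
        with pytest.raises(UndefinedIndexError):
            snpindex.snp_index(rec)

    @given(
        ref_d=st.integers(min_value=0, max_value=500),
        alt_d=st.integers(min_value=0, max_value=500),
    )
    def test_index_bounded_in_unit_interval(self, ref_d, alt_d):
        if ref_d + alt_d == 0:
            return
        rec = VariantRecord("chr1", 1, "G", "A", ref_d, alt_d)
        assert 0.0 <= snpindex.snp_index(rec) <= 1.0

    @pytest.mark.parametrize(
        "bg,mut,expected",
        [(0.0, 1.0, -1.0), (0.5, 0.5, 0.0), (None, 2 / 3, -0.6667)],
    )
    def test_delta_examples(self, bg, mut, expected):
        assert snpindex.delta_snp_index(bg, mut) == pytest.approx(expected, abs=1e-4)

    def test_delta_range_validated(self):
        with pytest.raises(ValueError):
            snpindex.delta_snp_index(1.5, 0.5)


def _rec(pos, ref_d, alt_d, qual=60.0, multi=False, chrom="chr1", alt="A"):
    return VariantRecord(chrom, pos, "G", alt, ref_d, alt_d, qual, multi)


class TestFiltering:
    def make_pools(self):
        mut = [
            _rec(100, 10, 50),              # clean mutant-unique site
            _rec(200, 5, 55),               # shared with the background
            _rec(300, 2, 1),                # low depth
            _rec(400, 10, 50, qual=5.0),    # low quality
            _rec(500, 10, 50, multi=True),  # multi-allelic
        ]
        bg = [
            _rec(200, 4, 56),   # alt clearly present
            _rec(100, 59, 1),   # one error read: NOT presence
        ]
        return mut, bg

    def test_each_removal_has_exactly_one_reason(self):
        mut, bg = self.make_pools()
        kept, removed = snpindex.filter_variants(mut, bg)
        assert [r.pos for r in kept] == [100]
        reasons = {r.pos: reason for r, reason in removed}
        assert reasons == {
            200: "shared-with-background",
            300: "low-depth",
            400: "low-quality",
            500: "multi-allelic",
        }

    def test_filtering_is_idempotent_and_order_independent(self):
        mut, bg = self.make_pools()
        kept, _ = snpindex.filter_variants(mut, bg)
        kept2, removed2 = snpindex.filter_variants(kept, bg)
        assert kept2 == kept and removed2 == []
        shuffled = list(mut)
        random.Random(0).shuffle(shuffled)
        kept3, removed3 = snpindex.filter_variants(shuffled, bg)
        assert sorted(r.pos for r in kept3) == sorted(r.pos for r in kept)
        assert {r.pos: why for r, why in removed3} == {
            r.pos: why for r, why in snpindex.filter_variants(mut, bg)[1]
        }

    def test_surviving_sites_use_background_index_zero(self):
        mut, bg = self.make_pools()
        records = snpindex.build_snpindex_records(mut, bg)
        by_pos = {r.pos: r for r in records}
        assert by_pos[100].index_bg is None
        assert by_pos[100].delta == pytest.approx(-50 / 60)
        assert by_pos[200].filter_status == "shared-with-background"
        assert not by_pos[200].candidate


class TestCandidates:
    def test_threshold_and_sorting(self):
        mut = [
            _rec(10, 0, 60),            # delta -1.0
            _rec(20, 17, 43),           # delta -0.7167
            _rec(30, 21, 39),           # delta -0.65
            _rec(40, 60, 0, alt="T"),   # delta 0.0
        ]
        records = snpindex.build_snpindex_records(mut, [])
        cands = snpindex.call_candidates(records, threshold=-0.7)
        assert [c.pos for c in cands] == [10, 20]
        assert cands[0].delta <= cands[1].delta

    def test_threshold_minus_one_keeps_only_fixed_unique_sites(self):
        mut = [_rec(10, 0, 60), _rec(20, 1, 59)]
        records = snpindex.build_snpindex_records(mut, [])
        cands = snpindex.call_candidates(records, threshold=-1.0)
        assert [c.pos for c in cands] == [10]

    def test_ties_broken_by_chrom_then_pos(self):
        mut = [
            _rec(50, 0, 60, chrom="chr2"),
            _rec(10, 0, 60, chrom="chr1"),
            _rec(5, 0, 60, chrom="chr2"),
        ]
        records = snpindex.build_snpindex_records(mut, [])
        cands = snpindex.call_candidates(records)
        assert [(c.chrom, c.pos) for c in cands] == [
            ("chr1", 10), ("chr2", 5), ("chr2", 50)
        ]


class TestRecountOracle:
    def test_indices_match_naive_vcf_recount(self, small_genome, tmp_path):
        """Exact agreement with an independent text-level recount of AD."""
        ms = simulate.mutagenize(small_genome, 60.0, seed=17)
        plants = simulate.make_bc1f2(small_genome, 30, seed=17)
        spec = simulate.PoolSpec(n_population=30, pool_size=15)
        recs = simulate.pool_read_counts(plants[:15], ms, spec, seed=3)
        path = tmp_path / "pool.vcf"
        simulate.write_vcf(recs, small_genome, path)

        parsed = snpindex.read_variants(path, "mutant")
        naive = {}
        for line in path.read_text().splitlines():
            if line.startswith("#"):
                continue
            fields = line.split("\t")
            ad = fields[9].split(":")[0].split(",")
            naive[(fields[0], int(fields[1]))] = (int(ad[0]), int(ad[1]))
        assert len(naive) == len(parsed)
        for rec in parsed:
            ref_d, alt_d = naive[(rec.chrom, rec.pos)]
            assert (rec.ref_depth, rec.alt_depth) == (ref_d, alt_d)
            if ref_d + alt_d > 0:
                assert snpindex.snp_index(rec) == pytest.approx(
                    alt_d / (ref_d + alt_d), abs=0
                )


class TestWindowing:
    def test_windowed_delta_partitions_sites(self):
        mut = [_rec(p, 30, 30) for p in range(100, 1100, 100)]
        records = snpindex.build_snpindex_records(mut, [])
        df = snpindex.windowed_delta(records, window_bp=500, step_bp=500)
        assert df["n_snps"].sum() >= len(mut)
        assert np.allclose(df["mean_delta"], -0.5)
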