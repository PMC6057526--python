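"""VAR/META/PAR/BED/FASTQ dialect round trips and validation."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import svforge.formats as fmt
from svforge.formats import (
    Distribution,
    ForeignRef,
    FormatError,
    LibrarySpec,
    MetaSpec,
    ValidationError,
    VariantSpec,
)

from conftest import EXAMPLE_NEWICK


def write(path, text):
    path.write_text(text)
    return str(path)


class TestVar:
    def test_single_deletion_line(self, tmp_path):
        p = write(tmp_path / "a.var", "v1\t.\t0.5\t2/1\tchr1\t1001\t500\t.\n")
        (v,) = fmt.read_var(p)
        assert v.vid == "v1" and v.pid == ""
        assert v.fraction == 0.5
        assert (v.ploidy, v.haplotypes) == (2, frozenset({1}))
        assert (v.chrom, v.pos, v.del_len, v.ins_seq) == ("chr1", 1001, 500, "")
        assert v.effective_svtype == "DEL"

    def test_header_only_gives_empty_list(self, tmp_path):
        p = write(tmp_path / "a.var", "#vid\tpid\tfraction\n")
        assert fmt.read_var(p) == []

    def test_fraction_out_of_bounds_names_line(self, tmp_path):
        p = write(
            tmp_path / "a.var",
            "#h\nv1\t.\t1.5\t2/1\tchr1\t100\t50\t.\n",
        )
        with pytest.raises(ValidationError, match=r":2:"):
            fmt.read_var(p)

    def test_duplicate_vid_rejected(self, tmp_path):
        line = "v1\t.\t0.5\t2/1\tchr1\t100\t50\t.\n"
        p = write(tmp_path / "a.var", line + line)
        with pytest.raises(ValidationError, match="duplicate"):
            fmt.read_var(p)

    def test_malformed_column_count_names_line(self, tmp_path):
        p = write(tmp_path / "a.var", "v1\t.\t0.5\n")
        with pytest.raises(FormatError, match=r":1:"):
            fmt.read_var(p)

    def test_round_trip_preserves_order_and_foreign_token(self, tmp_path):
        variants = [
            VariantSpec(vid="v1", chrom="chr1", pos=1001, fraction=0.5,
                        haplotypes=frozenset({1}), del_len=500, svtype="DEL"),
            VariantSpec(vid="v2", chrom="chr2", pos=7, fraction=1.0,
                        ins_seq="ACGT", svtype="INS"),
            VariantSpec(vid="v3", chrom="chr1", pos=50, fraction=0.25,
                        foreign=ForeignRef("hpv", "L1", "-")),
        ]
        p = tmp_path / "rt.var"
        fmt.write_var(variants, p)
        assert fmt.read_var(p) == variants
        assert "hpv:L1:-" in p.read_text()

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        pos=st.integers(1, 10**6),
        frac=st.floats(0, 1, allow_nan=False),
        dlen=st.integers(0, 10**4),
        ins=st.text(alphabet="ACGT", max_size=20),
        hom=st.booleans(),
    )
    def test_round_trip_property(self, tmp_path_factory, pos, frac, dlen, ins, hom):
        if dlen + len(ins) == 0:
            dlen = 1
        v = VariantSpec(
            vid="x", chrom="c", pos=pos, fraction=frac, del_len=dlen, ins_seq=ins,
            haplotypes=frozenset({1, 2}) if hom else frozenset({1}),
        )
        p = tmp_path_factory.mktemp("var") / "v.var"
        fmt.write_var([v], p)
        (back,) = fmt.read_var(p)
        assert back == v


class TestPloidyCode:
    @pytest.mark.parametrize(
        "code,expected",
        [
            ("2/1", (2, frozenset({1}))),
            ("2/1,2", (2, frozenset({1, 2}))),
            ("3/2,3", (3, frozenset({2, 3}))),
            ("hom", (2, frozenset({1, 2}))),
            ("het", (2, frozenset({1}))),
        ],
    )
    def test_parse(self, code, expected):
        assert fmt.parse_ploidy_code(code) == expected

    @pytest.mark.parametrize("bad", ["2/3", "0/1", "2/", "2", "x/y"])
    def test_rejects(self, bad):
        with pytest.raises(ValidationError):
            fmt.parse_ploidy_code(bad)


class TestMeta:
    def test_worked_deletion_line(self, tmp_path):
        p = write(
            tmp_path / "m.meta",
            "DEL\t100\tuniform:100,10000\tuniform:0,1\tbernoulli:0.5\n",
        )
        (m,) = fmt.read_meta(p)
        assert m.svtype == "DEL" and m.count == 100
        assert m.size_dist == Distribution("uniform", (100.0, 10000.0))
        assert m.fraction_dist == Distribution("uniform", (0.0, 1.0))
        assert m.ploidy_dist == Distribution("bernoulli", (0.5,))

    def test_fixed_homozygous_insertions(self, tmp_path):
        p = write(tmp_path / "m.meta", "INS\t5\tfixed:300\tfixed:1.0\thom\n")
        (m,) = fmt.read_meta(p)
        assert m.count == 5
        assert m.size_dist.sample_size(None) == 300
        assert m.fraction_dist.sample_fraction(None) == 1.0
        assert m.ploidy_dist.sample_ploidy(None) == (2, frozenset({1, 2}))

    def test_count_zero_allowed_negative_rejected(self, tmp_path):
        ok = write(tmp_path / "z.meta", "DEL\t0\tfixed:100\tfixed:1\thet\n")
        assert fmt.read_meta(ok)[0].count == 0
        bad = write(tmp_path / "n.meta", "DEL\t-1\tfixed:100\tfixed:1\thet\n")
        with pytest.raises(ValidationError):
            fmt.read_meta(bad)

    def test_unknown_family_rejected(self, tmp_path):
        p = write(tmp_path / "m.meta", "DEL\t1\tzipf:2\tfixed:1\thet\n")
        with pytest.raises(ValidationError, match="zipf"):
            fmt.read_meta(p)

    def test_round_trip(self, tmp_path):
        metas = [
            MetaSpec("DEL", 100, Distribution("uniform", (100.0, 10000.0)),
                     Distribution("uniform", (0.0, 1.0)), Distribution("bernoulli", (0.5,))),
            MetaSpec("INS", 2, Distribution("fixed", (300.0,)),
                     Distribution("fixed", (1.0,)), Distribution("hom"), "viral"),
        ]
        p = tmp_path / "rt.meta"
        fmt.write_meta(metas, p)
        assert fmt.read_meta(p) == metas


class TestPar:
    def test_single_library(self, tmp_path):
        p = write(tmp_path / "p.par", "300\t50\t150\t30\t0.0\n")
        (lib,) = fmt.read_par(p)
        assert lib == LibrarySpec(300, 50, 150, 30, 0.0)

    def test_two_libraries_sum_coverage(self, tmp_path):
        p = write(tmp_path / "p.par", "300\t50\t150\t20\t0.0\n3000\t300\t150\t10\t0.0\n")
        libs = fmt.read_par(p)
        assert len(libs) == 2
        assert sum(l.coverage for l in libs) == 30
        assert {l.insert_mean for l in libs} == {300, 3000}

    def test_negative_sd_rejected(self, tmp_path):
        p = write(tmp_path / "p.par", "300\t-1\t150\t30\t0.0\n")
        with pytest.raises(ValidationError):
            fmt.read_par(p)

    def test_short_insert_warns(self):
        with pytest.warns(UserWarning, match="insert_mean"):
            LibrarySpec(100, 10, 150, 30)

    def test_round_trip(self, tmp_path):
        libs = [LibrarySpec(300, 50, 150, 30, 0.01, 0.001, 0.0001)]
        p = tmp_path / "rt.par"
        fmt.write_par(libs, p)
        assert fmt.read_par(p) == libs


class TestBed:
    def test_deletion_interval_is_zero_based_half_open(self):
        v = VariantSpec(vid="v1", chrom="chr1", pos=1001, del_len=500, fraction=0.5,
                        haplotypes=frozenset({1}))
        assert fmt.variant_bed_interval(v) == (1000, 1500)

    def test_pure_insertion_gets_base_before_breakpoint(self):
        v = VariantSpec(vid="v1", chrom="c", pos=10, ins_seq="TT")
        start, end = fmt.variant_bed_interval(v)
        assert (start, end) == (8, 9) and end > start

    def test_ground_truth_round_trip_and_sorting(self, tmp_path):
        vs = [
            VariantSpec(vid="b", chrom="chr2", pos=5, del_len=2),
            VariantSpec(vid="a", chrom="chr1", pos=500, del_len=10),
            VariantSpec(vid="c", chrom="chr1", pos=10, ins_seq="AC"),
        ]
        p = tmp_path / "t.bed"
        fmt.write_ground_truth_bed(vs, p)
        back = fmt.read_ground_truth_bed(p)
        assert sorted(v.vid for v in back) == ["a", "b", "c"]
        assert {v.vid: v for v in back} == {v.vid: v for v in vs}
        rows = [l.split("\t") for l in p.read_text().splitlines() if not l.startswith("#")]
        assert [r[0] for r in rows] == sorted(r[0] for r in rows)

    def test_read_bed3(self, tmp_path):
        p = write(tmp_path / "m.bed", "chr1\t0\t100\nchr1\t200\t300\n")
        assert fmt.read_bed3(p) == [("chr1", 0, 100), ("chr1", 200, 300)]


class TestFastqFasta:
    def test_fastq_pairing_names_match(self, tmp_path):
        class P:
            def __init__(self, name):
                self.name, self.seq1, self.qual1 = name, "ACGT", "IIII"
                self.seq2, self.qual2 = "TTTT", "IIII"

        f1, f2 = tmp_path / "r1.fq", tmp_path / "r2.fq"
        fmt.write_fastq_pair([P("x:0"), P("x:1")], f1, f2)
        names1 = [l[1:-2] for l in f1.read_text().splitlines()[::4]]
        names2 = [l[1:-2] for l in f2.read_text().splitlines()[::4]]
        assert names1 == names2 == ["x:0", "x:1"]

    def test_fasta_round_trip(self, tmp_path):
        p = tmp_path / "x.fa"
        fmt.write_fasta([("a", "ACGT" * 40), ("b", "tt")], p)
        assert fmt.read_fasta(p) == {"a": "ACGT" * 40, "b": "tt"}


class TestNewick:
    def test_example_tree_shape(self):
        tree = fmt.read_newick(EXAMPLE_NEWICK)
        assert len(tree.leaves) == 6
        assert len(tree.internal_nodes) == 5
        assert tree.variant_labels == ["V1", "V5", "V2", "V4", "V3"]

    def test_single_bifurcation(self):
        tree = fmt.read_newick("(C1, C2) V1:1.0")
        assert tree.variant_labels == ["V1"]
        assert tree.internal_nodes[0].fraction == 1.0

    def test_three_way_node_rejected(self):
        with pytest.raises(ValidationError, match="binary"):
            fmt.read_newick("(C1,C2,C3)V1:0.5")

    def test_fraction_out_of_bounds_rejected(self):
        with pytest.raises(ValidationError):
            fmt.read_newick("(C1,C2)V1:1.5")
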