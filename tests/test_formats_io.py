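"""Format readers/writers: coordinate conventions, dialects, round-trips."""

import json

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from regtrail import (
    GenomicRegion, InputError, ParseError,
    extract_sequence, read_bed, read_expression_matrix, read_gene_annotation,
    read_pcm, read_rti_table, write_bed, write_results,
)


class TestBed:
    def test_six_column_line_maps_fields(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t100\t200\tpeak1\t5.0\t+\n")
        (r,) = read_bed(p)
        assert (r.chrom, r.start, r.end, r.name, r.score, r.strand) == (
            "chr1", 100, 200, "peak1", 5.0, "+"
        )

    def test_minimal_record_is_half_open(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t0\t1\n")
        (r,) = read_bed(p)
        assert r.length == 1 and r.start == 0 and r.strand == "."

    def test_track_browser_comment_lines_skipped(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text(
            "track name=x\nbrowser position chr1\n# comment\n\n"
            "chr1\t10\t20\nchr2\t30\t40\n"
        )
        assert len(read_bed(p)) == 2

    @pytest.mark.parametrize("line", ["chr1\tten\t20", "chr1\t20\t20", "chr1\t30\t20"])
    def test_malformed_coordinates_name_line(self, tmp_path, line):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t1\t2\n" + line + "\n")
        with pytest.raises(ParseError, match=":2"):
            read_bed(p)

    @given(
        st.lists(
            st.tuples(
                st.sampled_from(["chr1", "chr2", "chrX"]),
                st.integers(0, 10**6),
                st.integers(1, 5000),
                st.sampled_from(["+", "-", "."]),
            ),
            max_size=20,
        )
    )
    @settings(deadline=None, derandomize=True, max_examples=30)
    def test_round_trip_is_identity_property(self, specs):
        import tempfile
        regions = [
            GenomicRegion(c, s, s + ln, f"r{i}", float(i) / 8, strand)
            for i, (c, s, ln, strand) in enumerate(specs)
        ]
        with tempfile.TemporaryDirectory() as d:
            p = f"{d}/rt.bed"
            write_bed(regions, p)
            assert read_bed(p) == regions

    def test_write_read_round_trip(self, tmp_path, rng):
        regions = [
            GenomicRegion(
                f"chr{rng.integers(1, 4)}", int(s), int(s) + int(rng.integers(1, 500)),
                f"p{i}", float(np.round(rng.normal(), 4)),
                str(rng.choice(["+", "-", "."])),
            )
            for i, s in enumerate(rng.integers(0, 10_000, size=30))
        ]
        p = tmp_path / "rt.bed"
        write_bed(regions, p)
        assert read_bed(p) == regions


class TestGtf:
    def _write(self, tmp_path, rows):
        p = tmp_path / "g.gtf"
        lines = []
        for chrom, start, end, strand, gene, tx in rows:
            attrs = f'gene_id "{gene}"; transcript_id "{tx}";'
            lines.append(
                f"{chrom}\tsrc\ttranscript\t{start}\t{end}\t.\t{strand}\t.\t{attrs}"
            )
        p.write_text("\n".join(lines) + "\n")
        return p

    def test_plus_strand_takes_minimum_start(self, tmp_path):
        p = self._write(tmp_path, [
            ("chr1", 1000, 2000, "+", "gA", "t1"),
            ("chr1", 1200, 2500, "+", "gA", "t2"),
        ])
        (gene,) = read_gene_annotation(p)
        assert gene.tss == 1000 - 1  # GTF 1-based -> internal 0-based

    def test_minus_strand_takes_maximum_end(self, tmp_path):
        p = self._write(tmp_path, [
            ("chr1", 500, 900, "-", "gB", "t1"),
            ("chr1", 600, 1500, "-", "gB", "t2"),
        ])
        (gene,) = read_gene_annotation(p)
        assert gene.tss == 1500 - 1

    def test_single_transcript_identity(self, tmp_path):
        p = self._write(tmp_path, [("chr2", 42, 100, "+", "gC", "t1")])
        (gene,) = read_gene_annotation(p)
        assert gene.tss == 41 and gene.tss_candidates == (41,)

    def test_conflicting_strands_error_names_gene(self, tmp_path):
        p = self._write(tmp_path, [
            ("chr1", 100, 200, "+", "gD", "t1"),
            ("chr1", 300, 400, "-", "gD", "t2"),
        ])
        with pytest.raises(InputError, match="gD"):
            read_gene_annotation(p)

    def test_exon_records_ignored(self, tmp_path):
        p = tmp_path / "g.gtf"
        p.write_text(
            'chr1\ts\ttranscript\t1000\t2000\t.\t+\t.\tgene_id "gE"; transcript_id "t";\n'
            'chr1\ts\texon\t50\t80\t.\t+\t.\tgene_id "gE"; transcript_id "t";\n'
        )
        (gene,) = read_gene_annotation(p)
        assert gene.tss == 999


class TestExpressionMatrix:
    def _write(self, tmp_path, text):
        p = tmp_path / "e.tsv"
        p.write_text(text)
        return p

    def test_groups_from_sample_lists(self, tmp_path):
        p = self._write(
            tmp_path,
            "gene\ts1\ts2\ts3\ts4\ng1\t1\t2\t3\t4\ng2\t5\t6\t7\t8\ng3\t1\t1\t1\t1\n",
        )
        em = read_expression_matrix(p, case_samples=["s1", "s2"],
                                    control_samples=["s3", "s4"])
        assert em.values.shape == (3, 4)
        assert sum(v == "case" for v in em.groups.values()) == 2
        assert sum(v == "control" for v in em.groups.values()) == 2

    def test_duplicate_gene_rows_rejected(self, tmp_path):
        p = self._write(tmp_path, "gene\ts1\ts2\ng1\t1\t2\ng1\t3\t4\n")
        with pytest.raises(InputError, match="duplicate"):
            read_expression_matrix(p)

    def test_unknown_group_sample_rejected(self, tmp_path):
        p = self._write(tmp_path, "gene\ts1\ts2\ng1\t1\t2\n")
        with pytest.raises(InputError):
            read_expression_matrix(p, case_samples=["s1"], control_samples=["nope"])

    def test_non_numeric_cell_rejected(self, tmp_path):
        p = self._write(tmp_path, "gene\ts1\ts2\ng1\t1\tNA?\n")
        with pytest.raises(ParseError):
            read_expression_matrix(p)


class TestPcm:
    JASPAR = (
        ">M0001 TFA\n"
        "A [ 10 0 3 ]\n"
        "C [ 0 12 3 ]\n"
        "G [ 1 0 3 ]\n"
        "T [ 1 0 3 ]\n"
    )
    TRANSFAC = (
        "ID M0001\n"
        "NA TFA\n"
        "P0 A C G T\n"
        "01 10 0 1 1\n"
        "02 0 12 0 0\n"
        "03 3 3 3 3\n"
        "//\n"
    )

    def test_jaspar_block_parses(self, tmp_path):
        p = tmp_path / "m.jaspar"
        p.write_text(self.JASPAR)
        (rec,) = read_pcm(p, "jaspar")
        assert rec.tf_name == "TFA" and rec.length == 3
        assert rec.counts[1, 1] == 12

    def test_cross_dialect_equality(self, tmp_path):
        pj = tmp_path / "m.jaspar"
        pt = tmp_path / "m.transfac"
        pj.write_text(self.JASPAR)
        pt.write_text(self.TRANSFAC)
        (j,) = read_pcm(pj, "jaspar")
        (t,) = read_pcm(pt, "transfac")
        np.testing.assert_array_equal(j.counts, t.counts)

    def test_transfac_shuffled_column_order_normalized(self, tmp_path):
        p = tmp_path / "m.transfac"
        p.write_text(
            "ID M2\nP0 T G C A\n01 1 2 3 4\n02 5 6 7 8\n//\n"
        )
        (rec,) = read_pcm(p, "transfac")
        # rows must come back in A,C,G,T order
        np.testing.assert_array_equal(rec.counts, [[4, 8], [3, 7], [2, 6], [1, 5]])

    def test_empty_file_empty_list(self, tmp_path):
        p = tmp_path / "m.jaspar"
        p.write_text("")
        assert read_pcm(p, "jaspar") == []

    def test_ragged_rows_rejected(self, tmp_path):
        p = tmp_path / "m.jaspar"
        p.write_text(">M T\nA [ 1 2 ]\nC [ 1 ]\nG [ 1 2 ]\nT [ 1 2 ]\n")
        with pytest.raises(ParseError):
            read_pcm(p, "jaspar")

    def test_negative_count_rejected(self, tmp_path):
        p = tmp_path / "m.jaspar"
        p.write_text(">M T\nA [ 1 ]\nC [ -1 ]\nG [ 1 ]\nT [ 1 ]\n")
        with pytest.raises(ParseError):
            read_pcm(p, "jaspar")

    def test_secondary_suffix_flagged(self, tmp_path):
        p = tmp_path / "m.jaspar"
        p.write_text(">M1 TFA\nA [ 9 ]\nC [ 1 ]\nG [ 1 ]\nT [ 1 ]\n"
                     ">M2 TFA_secondary\nA [ 1 ]\nC [ 9 ]\nG [ 1 ]\nT [ 1 ]\n")
        primary, secondary = read_pcm(p, "jaspar")
        assert not primary.is_secondary
        assert secondary.is_secondary and secondary.tf_name == "TFA"


class TestRtiTable:
    def test_dedup_preserves_order(self, tmp_path):
        p = tmp_path / "r.tsv"
        p.write_text("R1\tG1\nR1\tG2\nR1\tG1\n")
        assert read_rti_table(p) == [("R1", "G1"), ("R1", "G2")]

    def test_header_only_file(self, tmp_path):
        p = tmp_path / "r.tsv"
        p.write_text("regulator\ttarget\n")
        assert read_rti_table(p) == []

    def test_blank_field_names_line(self, tmp_path):
        p = tmp_path / "r.tsv"
        p.write_text("R1\tG1\nR2\t\n")
        with pytest.raises(ParseError, match=":2"):
            read_rti_table(p)


class TestSequence:
    def test_slice_and_uppercase(self):
        genome = {"chrX": "acgtACGT"}
        assert extract_sequence(genome, GenomicRegion("chrX", 2, 6)) == "GTAC"

    def test_single_base_at_origin(self):
        assert extract_sequence({"chrX": "acgt"}, GenomicRegion("chrX", 0, 1)) == "A"

    def test_out_of_bounds_and_missing_chrom(self):
        genome = {"chr1": "ACGT"}
        with pytest.raises(InputError, match="exceeds"):
            extract_sequence(genome, GenomicRegion("chr1", 2, 10))
        with pytest.raises(InputError, match="chr9"):
            extract_sequence(genome, GenomicRegion("chr9", 0, 1))

    def test_pyfaidx_store_supported(self, tmp_path):
        import pyfaidx
        from regtrail import write_fasta

        write_fasta({"chr1": "acgtacgtacgt"}, tmp_path / "g.fa")
        fa = pyfaidx.Fasta(str(tmp_path / "g.fa"))
        assert extract_sequence(fa, GenomicRegion("chr1", 1, 5)) == "CGTA"


class TestWriteResults:
    def test_csv_has_header_and_rows(self, tmp_path):
        rows = [{"name": "a", "p": 0.123456789}, {"name": "b", "p": 1e-12}]
        out = tmp_path / "r.csv"
        write_results(rows, out, "csv")
        df = pd.read_csv(out)
        assert list(df.columns) == ["name", "p"]
        assert len(df) == 2
        assert abs(df["p"][0] - 0.123456789) < 1e-7  # >= 6 significant digits

    def test_empty_outputs(self, tmp_path):
        write_results([], tmp_path / "r.csv", "csv")
        write_results([], tmp_path / "r.json", "json")
        assert json.loads((tmp_path / "r.json").read_text()) == []

    def test_json_round_trip_identity(self, tmp_path):
        rows = [{"x": 0.1 + 0.2, "k": 3}, {"x": np.float64(1 / 3), "k": 4}]
        out = tmp_path / "r.json"
        write_results(rows, out, "json")
        back = json.loads(out.read_text())
        assert back[0]["x"] == 0.1 + 0.2
        assert back[1]["x"] == 1 / 3
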