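"""Channel classification, catalog building, TMB and f_deam."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fdeam.catalog96 import (
    CHANNELS_96,
    COMPLEMENT,
    CPG_CT_INDICES,
    ChromosomeEdgeError,
    MutationCatalog96,
    MutationRecord,
    ReferenceMismatchError,
    ValidationError,
    build_catalog,
    build_catalogs,
    catalogs_to_frame,
    classify_channel,
    compute_fdeam,
    compute_tmb,
    extract_context_from_reference,
    normalize_to_pyrimidine,
    read_catalogs,
    read_maf,
    read_vcf,
    write_catalogs,
)

BASES = "ACGT"


class TestNormalization:
    @pytest.mark.parametrize(
        "ref,alt,up,down,expected",
        [
            ("C", "T", "A", "G", ("C>T", "A", "G")),     # pyrimidine passes through
            ("G", "A", "C", "T", ("C>T", "A", "G")),     # rev-comp of CGT -> ACG
            ("A", "C", "T", "T", ("T>G", "A", "A")),     # rev-comp of TAT -> ATA
            ("T", "A", "G", "C", ("T>A", "G", "C")),
            ("G", "C", "A", "A", ("C>G", "T", "T")),
        ],
    )
    def test_examples(self, ref, alt, up, down, expected):
        assert normalize_to_pyrimidine(ref, alt, up, down) == expected

    @pytest.mark.parametrize("bad", [("X", "T", "A", "G"), ("C", "C", "A", "G")])
    def test_invalid_inputs(self, bad):
        with pytest.raises(ValidationError):
            normalize_to_pyrimidine(*bad)

    def test_error_names_offending_field(self):
        with pytest.raises(ValidationError, match="down"):
            normalize_to_pyrimidine("C", "T", "A", "N")

    @given(
        ref=st.sampled_from(BASES),
        alt=st.sampled_from(BASES),
        up=st.sampled_from(BASES),
        down=st.sampled_from(BASES),
    )
    @settings(max_examples=200, derandomize=True)
    def test_strand_involution(self, ref, alt, up, down):
        """A mutation and its full reverse complement share one channel."""
        if ref == alt:
            return
        direct = normalize_to_pyrimidine(ref, alt, up, down)
        revcomp = normalize_to_pyrimidine(
            COMPLEMENT[ref], COMPLEMENT[alt], COMPLEMENT[down], COMPLEMENT[up]
        )
        assert direct == revcomp

    def test_scheme_yields_exactly_96_channels(self):
        seen = {
            classify_channel(MutationRecord("1", 5, ref, alt, up=up, down=down))
            for ref in BASES
            for alt in BASES
            if ref != alt
            for up in BASES
            for down in BASES
        }
        assert seen == set(CHANNELS_96)
        assert len(CHANNELS_96) == 96


class TestClassifyChannel:
    @pytest.mark.parametrize(
        "ref,alt,up,down,label",
        [
            ("C", "T", "A", "G", "A[C>T]G"),
            ("G", "A", "C", "T", "A[C>T]G"),
            ("C", "A", "T", "T", "T[C>A]T"),
        ],
    )
    def test_examples(self, ref, alt, up, down, label):
        rec = MutationRecord("1", 100, ref, alt, up=up, down=down)
        assert classify_channel(rec) == label

    def test_missing_context_instructs_extraction(self):
        with pytest.raises(ValidationError, match="context"):
            classify_channel(MutationRecord("1", 100, "C", "T"))


class TestContextExtraction:
    def test_lookup(self):
        assert extract_context_from_reference({"1": "ACGT"}, "1", 2) == ("A", "C", "G")

    def test_soft_masked_uppercased(self):
        assert extract_context_from_reference({"1": "acgt"}, "1", 3) == ("C", "G", "T")

    @pytest.mark.parametrize("pos", [1, 4])
    def test_chromosome_edges(self, pos):
        with pytest.raises(ChromosomeEdgeError):
            extract_context_from_reference({"1": "ACGT"}, "1", pos)

    def test_reference_mismatch(self):
        with pytest.raises(ReferenceMismatchError):
            extract_context_from_reference({"1": "ACGT"}, "1", 2, expected_ref="T")

    def test_pyfaidx_accessor(self, tmp_path):
        from pyfaidx import Fasta

        fa = tmp_path / "ref.fa"
        fa.write_text(">chr1\nACGTACGT\n")
        genome = Fasta(str(fa))
        assert extract_context_from_reference(genome, "chr1", 2, "C") == ("A", "C", "G")


class TestBuildCatalog:
    def test_empty_gives_all_zero(self):
        cat = build_catalog([], "S1")
        assert cat.tmb == 0 and (cat.counts == 0).all()

    def test_counts_land_in_one_channel(self):
        recs = [MutationRecord("1", i, "C", "T", "S1", "A", "G") for i in range(3)]
        cat = build_catalog(recs, "S1")
        assert cat.as_series()["A[C>T]G"] == 3
        assert cat.tmb == 3

    def test_non_sbs_skipped_and_reported(self):
        recs = [
            MutationRecord("1", 1, "C", "T", "S1", "A", "G"),
            MutationRecord("1", 5, "CA", "C", "S1"),  # 1 bp deletion
        ]
        cat = build_catalog(recs, "S1")
        assert cat.tmb == 1 and cat.n_skipped_non_sbs == 1

    def test_ambiguous_context_skipped_with_count(self):
        recs = [MutationRecord("1", 1, "C", "T", "S1", "N", "G")]
        cat = build_catalog(recs, "S1")
        assert cat.tmb == 0 and cat.n_skipped_ambiguous == 1

    def test_foreign_sample_rejected_with_index(self):
        recs = [MutationRecord("1", 1, "C", "T", "S2", "A", "G")]
        with pytest.raises(ValidationError, match="record 0"):
            build_catalog(recs, "S1")

    @given(st.lists(st.tuples(
        st.sampled_from(BASES), st.sampled_from(BASES),
        st.sampled_from(BASES), st.sampled_from(BASES)), max_size=40))
    @settings(max_examples=50, derandomize=True)
    def test_count_conservation(self, quads):
        """TMB of a built catalog equals the number of valid SBS records."""
        recs = [
            MutationRecord("1", i + 1, ref, alt, "S", up, down)
            for i, (ref, alt, up, down) in enumerate(quads)
            if ref != alt
        ]
        assert compute_tmb(build_catalog(recs, "S")) == len(recs)


class TestFdeam:
    def test_direct_ratio(self):
        counts = np.zeros(96, dtype=int)
        counts[CPG_CT_INDICES[0]] = 4
        counts[10] = 6
        cat = MutationCatalog96("S", counts)
        assert compute_fdeam(cat, min_tmb=10) == pytest.approx(40.0)

    def test_low_tmb_is_na(self):
        assert math.isnan(compute_fdeam(MutationCatalog96("S"), min_tmb=10))

    def test_high_cpg_profile_recovered(self, rng):
        """Multinomial draws from an 89%-CpG profile give f_deam near 89."""
        p = np.full(96, 0.11 / 92)
        p[list(CPG_CT_INDICES)] = 0.89 / 4
        counts = rng.multinomial(2000, p)
        f = compute_fdeam(MutationCatalog96("S", counts))
        assert abs(f - 89.0) < 3.0

    def test_permutation_invariance(self, rng):
        recs = [
            MutationRecord("1", i + 1, "C", "T" if i % 3 else "A", "S", "A", "G")
            for i in range(30)
        ]
        f1 = build_catalog(recs, "S").fdeam()
        shuffled = [recs[i] for i in rng.permutation(30)]
        f2 = build_catalog(shuffled, "S").fdeam()
        assert f1 == f2 and 0 <= f1 <= 100


class TestIO:
    def test_maf_roundtrip(self, tmp_path, rng):
        maf = tmp_path / "m.tsv"
        maf.write_text(
            "sample\tchrom\tpos\tref\talt\tcontext_up\tcontext_down\tvaf\n"
            "S1\tchr1\t100\tC\tT\tA\tG\t0.4\n"
            "S1\tchr1\t200\tG\tA\tC\tT\t0.3\n"
            "S2\tchr2\t50\tT\tG\tA\tA\t0.2\n"
        )
        catalogs = build_catalogs(read_maf(maf))
        assert catalogs["S1"].as_series()["A[C>T]G"] == 2
        assert catalogs["S2"].tmb == 1
        out = tmp_path / "cat.tsv"
        write_catalogs(catalogs, out)
        back = read_catalogs(out)
        assert (back["S1"].counts == catalogs["S1"].counts).all()

    def test_maf_missing_columns(self, tmp_path):
        bad = tmp_path / "bad.tsv"
        bad.write_text("sample\tchrom\tpos\n")
        with pytest.raises(ValidationError, match="ref"):
            read_maf(bad)

    def test_vaf_filter(self, tmp_path):
        maf = tmp_path / "m.tsv"
        maf.write_text(
            "sample\tchrom\tpos\tref\talt\tcontext_up\tcontext_down\tvaf\n"
            "S1\tchr1\t100\tC\tT\tA\tG\t0.4\n"
            "S1\tchr1\t200\tC\tT\tA\tG\t0.01\n"
        )
        assert build_catalogs(read_maf(maf), min_vaf=0.05)["S1"].tmb == 1

    def test_vcf_with_reference(self, tmp_path):
        fa = tmp_path / "ref.fa"
        fa.write_text(">chr1\n" + "ACGTTCGA" * 4 + "\n")
        vcf = tmp_path / "s.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##contig=<ID=chr1,length=32>\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
            "chr1\t2\t.\tC\tT\t.\t.\t.\n"          # A[C>T]G
            "chr1\t6\t.\tC\tA\t.\t.\t.\n"          # T[C>A]G
            "chr1\t4\t.\tTA\tT\t.\t.\t.\n"         # indel, ignored
        )
        from pyfaidx import Fasta

        recs = read_vcf(vcf, "S1", Fasta(str(fa)))
        cat = build_catalog(recs, "S1")
        assert cat.tmb == 2
        assert cat.as_series()["A[C>T]G"] == 1
        assert cat.as_series()["T[C>A]G"] == 1

    def test_frame_has_tmb_and_fdeam_columns(self, default_cohort):
        catalogs = {s.sample_id: s.catalog for s in default_cohort.samples[:4]}
        df = catalogs_to_frame(catalogs)
        assert {"sample", "TMB", "f_deam"} <= set(df.columns)
        assert df.shape[1] == 99
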