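"""Alignment filtering, strand-aware mismatch counting and gene assignment."""

import pandas as pd
import pysam
import pytest

from tilac.simulate import SimConfig, simulate_reads, emit_synthetic_sam
from tilac.tally import (
    GeneIndex,
    GeneModel,
    SnpMask,
    assign_gene,
    count_mismatches,
    filter_alignment,
    load_gene_models,
    load_snp_mask,
    tally_sam,
)


def make_read(seq, contig="chr1", pos=0, flag=99, mapq=60, md=None, quals=None,
              cigar=None, name="r1", header=None):
    header = header or pysam.AlignmentHeader.from_dict(
        {"HD": {"VN": "1.6"}, "SQ": [{"SN": contig, "LN": 10000}]}
    )
    a = pysam.AlignedSegment(header)
    a.query_name = name
    a.query_sequence = seq
    a.flag = flag
    a.reference_id = 0
    a.reference_start = pos
    a.mapping_quality = mapq
    a.cigarstring = cigar or f"{len(seq)}M"
    a.query_qualities = pysam.qualitystring_to_array(quals or "I" * len(seq))
    if md is not None:
        a.set_tag("MD", md)
    return a


class TestFilterAlignment:
    @pytest.mark.parametrize(
        "flag,mapq,keep",
        [
            (99, 60, True),
            (147, 2, True),
            (83, 10, True),
            (163, 5, True),
            (99, 1, False),  # below the MAPQ floor
            (4, 60, False),  # unmapped
            (0, 60, False),  # unpaired
            (355, 60, False),  # secondary
        ],
    )
    def test_flag_and_mapq_predicate(self, flag, mapq, keep):
        assert filter_alignment(make_read("ACGT", flag=flag, mapq=mapq)) is keep


REF10 = "ACGTACGTAC"  # T at 0-based 3 and 7; G at 2 and 6


class TestCountMismatches:
    def test_identical_read_counts_sites_only(self):
        read = make_read(REF10, md="10")
        assert count_mismatches(read, None) == (2, 2, 0, 0)

    def test_single_tc_mismatch_hand_count(self):
        # T->C at the read's 4th position (0-based 3)
        seq = REF10[:3] + "C" + REF10[4:]
        read = make_read(seq, md="3T6")
        assert count_mismatches(read, None) == (2, 2, 1, 0)

    def test_fasta_reference_matches_md_path(self, tmp_path):
        fa = tmp_path / "ref.fa"
        fa.write_text(f">chr1\n{REF10}\n")
        seq = REF10[:3] + "C" + REF10[4:]
        with pysam.FastaFile(str(fa)) as ref:
            assert count_mismatches(make_read(seq), ref) == (2, 2, 1, 0)

    def test_missing_contig_is_hard_error(self, tmp_path):
        fa = tmp_path / "ref.fa"
        fa.write_text(f">chrX\n{REF10}\n")
        with pysam.FastaFile(str(fa)) as ref:
            with pytest.raises(KeyError, match="chr1"):
                count_mismatches(make_read(REF10), ref)

    def test_masked_snp_excluded_from_both_counts(self):
        seq = REF10[:3] + "C" + REF10[4:]
        read = make_read(seq, md="3T6")
        mask = SnpMask(frozenset({("chr1", 3)}))
        assert count_mismatches(read, None, mask=mask) == (1, 2, 0, 0)

    def test_mask_everything_gives_zero_tallies(self):
        read = make_read(REF10, md="10")
        mask = SnpMask(frozenset(("chr1", i) for i in range(10)))
        assert count_mismatches(read, None, mask=mask) == (0, 0, 0, 0)

    def test_minus_strand_reverse_complement_logic(self):
        # minus-strand gene: genomic A->G is a transcript T->C event
        seq = "AGGA"
        read = make_read(seq, md="1A2")  # genomic ref AAGA, read has A->G at pos 1
        n_U, n_G, y_TC, y_GA = count_mismatches(read, None, strand="-")
        assert (n_U, y_TC) == (3, 1)  # three genomic A sites, one A->G
        assert (n_G, y_GA) == (0, 0)

    def test_strand_symmetry(self):
        """Reverse-complementing read+reference and flipping strand preserves counts."""
        ref = "ACGTACGTAC"
        seq = ref[:3] + "C" + ref[4:]
        fwd = count_mismatches(make_read(seq, md="3T6"), None, strand="+")
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        rc = lambda s: "".join(comp[b] for b in reversed(s))
        rc_ref, rc_seq = rc(ref), rc(seq)
        md = []  # rebuild the MD string for the reverse-complemented alignment
        run = 0
        for r, q in zip(rc_ref, rc_seq):
            if r == q:
                run += 1
            else:
                md.extend([str(run), r])
                run = 0
        md.append(str(run))
        rev = count_mismatches(make_read(rc_seq, md="".join(md)), None, strand="-")
        assert fwd == rev

    def test_low_quality_bases_excluded(self):
        seq = REF10[:3] + "C" + REF10[4:]
        quals = "I" * 3 + "#" + "I" * 6  # Q2 at the mismatch
        read = make_read(seq, md="3T6", quals=quals)
        assert count_mismatches(read, None) == (1, 2, 0, 0)

    def test_soft_clips_excluded(self):
        seq = "TT" + REF10  # 2 soft-clipped T's must not count as U sites
        read = make_read(seq, md="10", cigar="2S10M")
        assert count_mismatches(read, None) == (2, 2, 0, 0)


class TestAssignGene:
    @pytest.fixture()
    def index(self):
        return GeneIndex(
            [
                GeneModel("single", "chr1", "+", [(100, 400)]),
                GeneModel("spliced", "chr1", "+", [(1000, 1100), (1500, 1600)], (1000, 1600)),
                GeneModel("left", "chr1", "+", [(5000, 5400)]),
                GeneModel("right", "chr1", "+", [(5300, 5700)]),
            ]
        )

    def test_exonic_intronic_ambiguous_none(self, index):
        assert assign_gene(make_read("A" * 50, pos=150), index) == ("single", "exonic")
        # straddles the intron of the spliced gene
        assert assign_gene(make_read("A" * 50, pos=1080), index) == ("spliced", "intronic")
        assert assign_gene(make_read("A" * 50, pos=5320), index) == (None, "ambiguous")
        assert assign_gene(make_read("A" * 50, pos=9000), index) == (None, "none")

    def test_spliced_read_within_exons_is_exonic(self, index):
        read = make_read("A" * 100, pos=1050, cigar="50M400N50M")
        assert assign_gene(read, index) == ("spliced", "exonic")


class TestAnnotationIO:
    def test_bed12_and_gtf_agree(self, tmp_path):
        gtf = tmp_path / "genes.gtf"
        gtf.write_text(
            'chr1\tsrc\tgene\t101\t400\t.\t+\t.\tgene_id "gA";\n'
            'chr1\tsrc\texon\t101\t200\t.\t+\t.\tgene_id "gA";\n'
            'chr1\tsrc\texon\t301\t400\t.\t+\t.\tgene_id "gA";\n'
        )
        bed = tmp_path / "genes.bed"
        bed.write_text("chr1\t100\t400\tgA\t0\t+\t100\t400\t0\t2\t100,100\t0,200\n")
        from_gtf = load_gene_models(gtf)[0]
        from_bed = load_gene_models(bed)[0]
        assert from_gtf.exons == from_bed.exons == [(100, 200), (300, 400)]
        assert from_gtf.span == from_bed.span == (100, 400)

    def test_vcf_mask_positions_are_zero_based(self, tmp_path):
        vcf = tmp_path / "mask.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##contig=<ID=chr1,length=10000>\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
            "chr1\t4\t.\tT\tC\t.\tPASS\t.\n"
        )
        mask = load_snp_mask(vcf)
        assert ("chr1", 3) in mask and len(mask) == 1


@pytest.fixture(scope="module")
def fixture_dir(tmp_path_factory):
    cfg = SimConfig(ratio_mode="constant", ratio_constant=2.0, n_transcripts=3,
                    read_count=20, seed=11)
    sim = simulate_reads(cfg, seed=11)
    out = tmp_path_factory.mktemp("roundtrip")
    paths = emit_synthetic_sam(sim.tallies, out)
    return sim, paths


class TestRoundTrip:
    def test_tally_recovers_simulated_counts_exactly(self, fixture_dir):
        sim, paths = fixture_dir
        index = GeneIndex(load_gene_models(paths["gtf"]))
        frames = [
            tally_sam(p, key.split(":")[1], index, fasta_path=paths["fasta"])
            for key, p in paths.items()
            if key.startswith("sam:")
        ]
        got = pd.concat(frames, ignore_index=True)
        want = sim.tallies[got.columns]
        key = ["read_id", "sample_id"]
        merged = want.merge(got, on=key, suffixes=("_want", "_got"))
        assert len(merged) == len(want) == len(got)
        for c in ("gene_id", "n_U", "n_G", "y_TC", "y_GA"):
            assert (merged[f"{c}_want"] == merged[f"{c}_got"]).all()
        assert (got["feature_class"] == "exonic").all()

    def test_snp_mask_removes_positions_from_tallies(self, fixture_dir, tmp_path):
        sim, paths = fixture_dir
        index = GeneIndex(load_gene_models(paths["gtf"]))
        sample = sorted(k for k in paths if k.startswith("sam:"))[0].split(":")[1]
        sam = paths[f"sam:{sample}"]
        base = tally_sam(sam, sample, index, fasta_path=paths["fasta"])
        # mask the first reference base of every 200-base window: that base is a
        # T site whenever the corresponding read has n_U >= 1
        vcf = tmp_path / "mask.vcf"
        lines = [
            "##fileformat=VCFv4.2\n",
            *(f"##contig=<ID={g},length=100000>\n" for g in sorted(sim.tallies.gene_id.unique())),
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n",
        ]
        for gene in sorted(sim.tallies.gene_id.unique()):
            n = (sim.tallies.gene_id == gene).sum()
            for j in range(n):
                lines.append(f"{gene}\t{j * 200 + 1}\t.\tT\tC\t.\tPASS\t.\n")
        vcf.write_text("".join(lines))
        masked = tally_sam(sam, sample, index, fasta_path=paths["fasta"], vcf_path=vcf)
        m = base.merge(masked, on="read_id", suffixes=("_b", "_m"))
        had_u = m["n_U_b"] >= 1
        assert (m.loc[had_u, "n_U_m"] == m.loc[had_u, "n_U_b"] - 1).all()
        assert (m.loc[~had_u, "n_U_m"] == m.loc[~had_u, "n_U_b"]).all()
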