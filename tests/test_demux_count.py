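"""Pipeline core: filtering, demux, mapping, SAM import, dedup, counting, GFF."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mascseq._seq import hamming, revcomp
from mascseq.array_model import ProbeSpec, SpotBarcodeSet
from mascseq.demux_count import (
    BarcodeMatchPolicy,
    DedupPolicy,
    MappingHit,
    annotate_reads,
    build_count_matrix,
    build_kmer_index,
    dedup_umis,
    demultiplex,
    gene_map_from_gff,
    import_sam,
    map_reads,
    quality_filter,
    read_fastq_pairs,
)

Q37 = chr(37 + 33)
Q2 = chr(2 + 33)


def _pair(rid, s1, s2, q2=None):
    q2 = q2 if q2 is not None else Q37 * len(s2)
    return ((rid, s1, Q37 * len(s1)), (rid, s2, q2))


class TestQualityFilter:
    def test_clean_pairs_all_kept(self, clean_batch):
        pairs = [
            ((a.read_id, a.sequence, a.quality), (b.read_id, b.sequence, b.quality))
            for a, b in zip(clean_batch["r1"], clean_batch["r2"])
        ]
        kept, report = quality_filter(pairs)
        assert report["kept"] == len(pairs) and len(kept) == len(pairs)

    def test_homopolymer_read_discarded(self):
        pairs = [_pair("r1", "A" * 31, "A" * 121)]
        kept, report = quality_filter(pairs)
        assert not kept and report["discarded_short_after_trim"] == 1

    def test_low_quality_read_discarded(self):
        pairs = [_pair("r1", "A" * 31, "ACGT" * 30 + "A", q2=Q2 * 121)]
        kept, report = quality_filter(pairs)
        assert not kept and report["discarded_low_quality"] == 1

    def test_kept_plus_discarded_equals_input(self):
        pairs = [
            _pair("a", "A" * 31, "ACGT" * 30 + "A"),
            _pair("b", "A" * 31, "G" * 121),
            _pair("c", "A" * 31, "ACGT" * 30 + "C", q2=Q2 * 121),
        ]
        kept, report = quality_filter(pairs)
        discarded = report["discarded_low_quality"] + report["discarded_short_after_trim"]
        assert len(kept) + discarded == report["input"] == 3


class TestDemultiplex:
    def test_exact_prefix_assigned(self, small_barcodes):
        sid, bc = next(iter(small_barcodes.entries.items()))
        r1 = [("r1", bc + "ACGTACGTA" + "TTTT", Q37 * 31)]
        asg, report = demultiplex(r1, small_barcodes)
        assert asg["r1"] == (sid, "ACGTACGTA")
        assert report["exact"] == 1

    def test_single_substitution_corrected_to_true_spot(self, small_barcodes):
        # brute-force nearest-barcode search confirms uniqueness of each correction
        entries = list(small_barcodes.entries.items())
        for sid, bc in entries[:10]:
            mutated = ("G" if bc[0] != "G" else "C") + bc[1:]
            r1 = [("r", mutated + "AAAAAAAAA" + "TTTT", Q37 * 31)]
            asg, report = demultiplex(r1, small_barcodes)
            dists = {s: hamming(mutated, b) for s, b in small_barcodes.entries.items()}
            nearest = min(dists, key=dists.get)
            assert sorted(dists.values())[1] > 1  # unique within 1 mismatch
            assert asg["r"] == (nearest, "AAAAAAAAA") and nearest == sid

    def test_equidistant_read_rejected_as_ambiguous(self):
        permissive = SpotBarcodeSet({"s1": "AA", "s2": "AT"}, min_pairwise_hamming=1)
        spec = ProbeSpec(barcode_length=2, umi_length=2, r1_length=4)
        r1 = [("r", "ACGG", "FFFF")]
        asg, report = demultiplex(r1, permissive, BarcodeMatchPolicy(max_mismatch=1), spec)
        assert not asg and report["ambiguous"] == 1

    def test_short_read_rejected_per_read(self, small_barcodes):
        asg, report = demultiplex([("r", "ACGT", "FFFF")], small_barcodes)
        assert not asg and report["too_short"] == 1

    def test_no_correction_when_disabled(self, small_barcodes):
        sid, bc = next(iter(small_barcodes.entries.items()))
        mutated = ("G" if bc[0] != "G" else "C") + bc[1:]
        r1 = [("r", mutated + "AAAAAAAAA" + "TTTT", Q37 * 31)]
        asg, report = demultiplex(r1, small_barcodes, BarcodeMatchPolicy(max_mismatch=0))
        assert not asg and report["unmatched"] == 1


class TestMapReads:
    def test_exact_substring_maps_with_correct_start(self, small_transcriptome):
        rec = small_transcriptome.records[0]
        read = rec.sequence[40:161]
        hits, report = map_reads([("r", read, Q37 * 121)], small_transcriptome.sequences)
        assert hits == [MappingHit("r", rec.transcript_id, 40, "+")]

    def test_antisense_read_maps_on_minus_strand(self, small_transcriptome):
        rec = small_transcriptome.records[1]
        read = revcomp(rec.sequence[10:131])
        hits, _ = map_reads([("r", read, Q37 * 121)], small_transcriptome.sequences)
        assert hits == [MappingHit("r", rec.transcript_id, 10, "-")]

    def test_shared_sequence_discarded_as_multimapper(self):
        core = "ACGTTGCA" * 40  # 320 nt shared block
        seqs = {"T1": "A" * 30 + core, "T2": "G" * 30 + core}
        read = core[:121]
        hits, report = map_reads([("r", read, Q37 * 121)], seqs)
        assert not hits and report["multimapped"] == 1

    def test_foreign_read_unmapped(self, small_transcriptome):
        rng = np.random.default_rng(0)
        read = "".join("ACGT"[i] for i in rng.integers(0, 4, 121))
        # exhaustive substring scan: the random read is genuinely absent
        assert all(read not in s for s in small_transcriptome.sequences.values())
        hits, report = map_reads([("r", read, Q37 * 121)], small_transcriptome.sequences)
        assert not hits and report["unmapped"] == 1

    def test_read_with_errors_outside_seed_still_maps(self, small_transcriptome):
        rec = small_transcriptome.records[2]
        read = list(rec.sequence[5:126])
        read[60] = "A" if read[60] != "A" else "C"  # one substitution mid-read
        hits, _ = map_reads([("r", "".join(read), Q37 * 121)], small_transcriptome.sequences)
        assert hits and hits[0].transcript_id == rec.transcript_id and hits[0].start == 5

    def test_empty_transcriptome_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            map_reads([("r", "ACGT" * 31, Q37 * 124)], {})


class TestImportSam:
    def _write_sam(self, path, body, refs=(("T1", 500),)):
        header = "@HD\tVN:1.6\n" + "".join(f"@SQ\tSN:{r}\tLN:{l}\n" for r, l in refs)
        path.write_text(header + body)

    def test_primary_mapped_record_imported(self, tmp_path):
        sam = tmp_path / "a.sam"
        self._write_sam(sam, "r1\t0\tT1\t11\t60\t10M\t*\t0\t0\tACGTACGTAC\t*\n")
        hits = import_sam(sam, {"T1": "A" * 500})
        assert hits == [MappingHit("r1", "T1", 10, "+")]

    def test_unmapped_record_skipped(self, tmp_path):
        sam = tmp_path / "a.sam"
        self._write_sam(sam, "r1\t4\t*\t0\t0\t*\t*\t0\t0\tACGT\t*\n")
        assert import_sam(sam, {"T1": "A" * 500}) == []

    def test_unknown_reference_rejected(self, tmp_path):
        sam = tmp_path / "a.sam"
        self._write_sam(sam, "", refs=(("TX", 100),))
        with pytest.raises(ValueError, match="TX"):
            import_sam(sam, {"T1": "A" * 500})

    def test_sam_import_agrees_with_internal_mapper(self, clean_batch, small_transcriptome, tmp_path):
        # Build a SAM from ground-truth provenance and compare against map_reads.
        prov = clean_batch["provenance"]
        seqs = small_transcriptome.sequences
        lines = ["@HD\tVN:1.6\n"] + [
            f"@SQ\tSN:{t}\tLN:{len(s)}\n" for t, s in sorted(seqs.items())
        ]
        by_id = {r.read_id: r.sequence for r in clean_batch["r2"]}
        for row in prov.itertuples():
            flag = 16 if row.strand == "-" else 0
            seq = by_id[row.read_id]
            if row.strand == "-":
                seq = revcomp(seq)
            lines.append(
                f"{row.read_id}\t{flag}\t{row.transcript_id}\t{row.start + 1}\t60\t"
                f"{len(seq)}M\t*\t0\t0\t{seq}\t*\n"
            )
        sam = tmp_path / "truth.sam"
        sam.write_text("".join(lines))
        imported = import_sam(sam, seqs)
        r2 = [(r.read_id, r.sequence, r.quality) for r in clean_batch["r2"]]
        mapped, _ = map_reads(r2, seqs)
        assert sorted(imported) == sorted(mapped)


def dedup_oracle(reads, window_bp, umi_max_mismatch):
    """Independent two-stage oracle: positional components on the all-pairs
    |dstart|<=window graph, then UMI components within each, via networkx."""
    import networkx as nx

    total = 0
    df = pd.DataFrame(reads, columns=["spot", "gene", "strand", "start", "umi"])
    for _key, g in df.groupby(["spot", "gene", "strand"]):
        pos_graph = nx.Graph()
        pos_graph.add_nodes_from(g.index)
        idx = list(g.index)
        for i in range(len(idx)):
            for j in range(i + 1, len(idx)):
                if abs(g.loc[idx[i], "start"] - g.loc[idx[j], "start"]) <= window_bp:
                    pos_graph.add_edge(idx[i], idx[j])
        for comp in nx.connected_components(pos_graph):
            umi_graph = nx.Graph()
            comp = list(comp)
            umi_graph.add_nodes_from(comp)
            for i in range(len(comp)):
                for j in range(i + 1, len(comp)):
                    u1, u2 = g.loc[comp[i], "umi"], g.loc[comp[j], "umi"]
                    if hamming(u1, u2) <= umi_max_mismatch:
                        umi_graph.add_edge(comp[i], comp[j])
            total += nx.number_connected_components(umi_graph)
    return total


def _dedup_count(reads, window_bp=250, umi_max_mismatch=1, umi_length=9):
    df = pd.DataFrame(
        [(f"r{i}", s, u, g, st_, str_) for i, (s, g, str_, st_, u) in enumerate(reads)],
        columns=["read_id", "spot_id", "umi", "transcript_id", "start", "strand"],
    )
    res = dedup_umis(df, {}, DedupPolicy(window_bp, umi_max_mismatch), umi_length)
    return int(res.unique_counts["count"].sum()) if len(res.unique_counts) else 0


class TestDedupUmis:
    def test_chained_duplicates_collapse_to_one(self):
        reads = [("s1", "g1", "+", start, "AAAAAAAAA") for start in (0, 50, 100, 150, 200)]
        assert _dedup_count(reads) == 1 == dedup_oracle(reads, 250, 1)

    def test_far_apart_reads_stay_separate(self):
        reads = [("s1", "g1", "+", 0, "AAAAAAAAA"), ("s1", "g1", "+", 300, "AAAAAAAAA")]
        assert _dedup_count(reads) == 2 == dedup_oracle(reads, 250, 1)

    def test_umi_mismatch_thresholds(self):
        near = [("s1", "g1", "+", 0, "AAAAAAAAA"), ("s1", "g1", "+", 10, "AAAAAAAAT")]
        far = [("s1", "g1", "+", 0, "AAAAAAAAA"), ("s1", "g1", "+", 10, "AAAAAAACT")]
        assert _dedup_count(near) == 1
        assert _dedup_count(far) == 2

    def test_strands_are_separate_keys(self):
        reads = [("s1", "g1", "+", 0, "AAAAAAAAA"), ("s1", "g1", "-", 0, "AAAAAAAAA")]
        assert _dedup_count(reads) == 2

    def test_wrong_length_umi_rejected_per_read(self):
        df = pd.DataFrame(
            [("r1", "s1", "AAAA", "g1", 0, "+"), ("r2", "s1", "AAAAAAAAA", "g1", 0, "+")],
            columns=["read_id", "spot_id", "umi", "transcript_id", "start", "strand"],
        )
        res = dedup_umis(df, {}, DedupPolicy(), umi_length=9)
        assert res.n_rejected_umi == 1
        assert int(res.unique_counts["count"].sum()) == 1

    @settings(derandomize=True, max_examples=150, deadline=None)
    @given(
        st.lists(
            st.tuples(
                st.sampled_from(["s1", "s2"]),
                st.sampled_from(["g1", "g2"]),
                st.sampled_from(["+", "-"]),
                st.integers(0, 600),
                st.text(alphabet="AC", min_size=9, max_size=9),
            ),
            min_size=1,
            max_size=30,
        )
    )
    def test_matches_bruteforce_oracle(self, reads):
        assert _dedup_count(reads) == dedup_oracle(reads, 250, 1)


class TestBuildCountMatrix:
    def test_no_reads_gives_full_zero_matrix(self):
        empty = pd.DataFrame(columns=["read_id", "spot_id", "umi", "transcript_id", "start", "strand"])
        res = dedup_umis(empty, {})
        mat = build_count_matrix(res, ["s1", "s2"], ["g1", "g2"])
        assert mat.unique.shape == (2, 2) and not mat.unique.to_numpy().any()

    def test_single_molecule_single_cell(self):
        df = pd.DataFrame(
            [("r1", "s1", "AAAAAAAAA", "g1", 0, "+")],
            columns=["read_id", "spot_id", "umi", "transcript_id", "start", "strand"],
        )
        mat = build_count_matrix(dedup_umis(df, {}), ["s1", "s2"], ["g1", "g2"])
        assert mat.unique.loc["s1", "g1"] == 1
        assert mat.unique.to_numpy().sum() == 1

    def test_rrna_exclusion_drops_column(self):
        df = pd.DataFrame(
            [("r1", "s1", "AAAAAAAAA", "g1", 0, "+"), ("r2", "s1", "CCCCCCCCC", "g2", 0, "+")],
            columns=["read_id", "spot_id", "umi", "transcript_id", "start", "strand"],
        )
        res = dedup_umis(df, {})
        full = build_count_matrix(res, ["s1"], ["g1", "g2"])
        excl = build_count_matrix(res, ["s1"], ["g1", "g2"], rrna_gene_ids=["g2"])
        assert "g2" not in excl.unique.columns
        assert excl.unique.to_numpy().sum() == full.unique.to_numpy().sum() - 1

    def test_duplicate_ids_rejected(self):
        empty = pd.DataFrame(columns=["read_id", "spot_id", "umi", "transcript_id", "start", "strand"])
        res = dedup_umis(empty, {})
        with pytest.raises(ValueError, match="duplicate"):
            build_count_matrix(res, ["s1", "s1"], ["g1"])

    def test_unique_never_exceeds_raw(self, clean_batch, small_layout, small_transcriptome):
        from mascseq.demux_count import BarcodeMatchPolicy

        r1 = [(r.read_id, r.sequence, r.quality) for r in clean_batch["r1"]]
        r2 = [(r.read_id, r.sequence, r.quality) for r in clean_batch["r2"]]
        asg, _ = demultiplex(r1, small_layout.barcode_set())
        hits, _ = map_reads(r2, small_transcriptome.sequences)
        res = dedup_umis(annotate_reads(hits, asg), small_transcriptome.gene_map)
        mat = build_count_matrix(res, small_layout.barcoded_spot_ids, small_transcriptome.gene_ids)
        assert (mat.unique.to_numpy() <= mat.raw.to_numpy()).all()
        assert mat.raw.to_numpy().sum() <= len(r1)


GFF = """##gff-version 3
chr1\ttest\tgene\t1\t1000\t.\t+\t.\tID=GENE1
chr1\ttest\tmRNA\t1\t1000\t.\t+\t.\tID=T1;Parent=GENE1;gene_id=G1
"""

GFF_NO_TAG = """##gff-version 3
chr1\ttest\tmRNA\t1\t1000\t.\t+\t.\tID=T1
chr1\ttest\tmRNA\t1\t2000\t.\t+\t.\tID=T2
"""


class TestGeneMapFromGff:
    def test_default_tag(self, tmp_path):
        p = tmp_path / "a.gff3"
        p.write_text(GFF)
        gm = gene_map_from_gff(p, "gene_id")
        assert gm.mapping == {"T1": "G1"} and gm.n_missing == 0

    def test_alternate_tag(self, tmp_path):
        p = tmp_path / "a.gff3"
        p.write_text(GFF)
        gm = gene_map_from_gff(p, "ID")
        assert gm.mapping == {"T1": "T1"}

    def test_missing_tag_identity_with_warning_count(self, tmp_path):
        p = tmp_path / "a.gff3"
        p.write_text(GFF_NO_TAG)
        gm = gene_map_from_gff(p, "gene_id")
        assert gm.mapping == {"T1": "T1", "T2": "T2"} and gm.n_missing == 2

    def test_unreadable_gff_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="could not read"):
            gene_map_from_gff(tmp_path / "missing.gff3")


class TestFastqIO:
    def test_pair_count_mismatch_rejected(self, tmp_path):
        (tmp_path / "r1.fastq").write_text("@a\nACGT\n+\nFFFF\n@b\nACGT\n+\nFFFF\n")
        (tmp_path / "r2.fastq").write_text("@a\nACGT\n+\nFFFF\n")
        with pytest.raises(ValueError, match="records"):
            read_fastq_pairs(tmp_path / "r1.fastq", tmp_path / "r2.fastq")
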