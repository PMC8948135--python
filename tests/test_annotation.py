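"""Feature-table parsing, spacer/overlap accounting, partitions, codons."""

import random

import pytest

from mitorearrange import (
    AnnotationError,
    AnnotationTable,
    GeneFeature,
    codon_inventory,
    partition_lengths,
    read_annotation,
    spacer_overlap_report,
    write_annotation,
)
from mitorearrange import datasets

# The published intergenic-length column, one signed value per linear
# consecutive pair in start order (blank printed cells are zero).
PUBLISHED_INTERGENIC = [
    3, 0, 3, 0, -4, 0, 1, 7, 8, 0, 3, 0, 3, 0, 0, 25, 0, 0, -3, 174,
    15, 10, 1, 0, -6, -7, 0, 71, -7, 8, 0, 2, 9, 1, 1, 6, 0,
]


class TestPolydesmusTable:
    def test_inventory(self, annot_table):
        assert len(annot_table) == 38
        assert annot_table.genome_length == 15036
        cats = {c: len(annot_table.by_category(c)) for c in
                ("PCG", "tRNA", "rRNA", "control_region")}
        assert cats == {"PCG": 13, "tRNA": 22, "rRNA": 2, "control_region": 1}

    def test_cox1_length(self, annot_table):
        assert annot_table["cox1"].length == 1533

    def test_intergenic_column_reproduced(self, annot_table):
        rep = spacer_overlap_report(annot_table)
        assert rep.intergenic_column() == PUBLISHED_INTERGENIC
        # the origin-spanning closing pair exists but is flagged
        assert rep.records[-1].closing
        assert (rep.records[-1].upstream, rep.records[-1].downstream) == ("trnW", "cox1")

    def test_spacer_summary(self, annot_table):
        rep = spacer_overlap_report(annot_table)
        assert (rep.n_spacers, rep.total_spacer_bp) == (19, 351)
        assert (rep.min_spacer, rep.max_spacer) == (1, 174)

    def test_overlap_summary(self, annot_table):
        rep = spacer_overlap_report(annot_table)
        assert (rep.n_overlaps, rep.total_overlap_bp, rep.max_overlap_bp) == (5, 27, 7)
        pairs = {(u, d) for u, d, _ in rep.overlapping_pairs()}
        assert pairs == {("atp8", "atp6"), ("rrnS", "trnV"), ("trnP", "nad4L"),
                         ("nad4L", "nad4"), ("trnH", "nad5")}
        deepest = {(u, d) for u, d, bp in rep.overlapping_pairs() if bp == 7}
        assert deepest == {("nad4L", "nad4"), ("trnH", "nad5")}

    def test_partition_lengths(self, annot_table):
        assert partition_lengths(annot_table) == {
            "PCG": 10997, "tRNA": 1415, "rRNA": 1862, "control_region": 437,
        }

    def test_trna_sizes(self, annot_table):
        sizes = [f.length for f in annot_table.by_category("tRNA")]
        assert len(sizes) == 22
        assert (min(sizes), max(sizes)) == (57, 69)

    def test_round_trip(self, annot_table, tmp_path):
        p = tmp_path / "t.tsv"
        write_annotation(annot_table, p)
        assert read_annotation(p) == annot_table


class TestValidation:
    def test_empty_file(self, tmp_path):
        p = tmp_path / "empty.tsv"
        p.write_text("")
        with pytest.raises(AnnotationError):
            read_annotation(p)

    def test_malformed_row_names_line(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text(
            "name\tcategory\tstart\tend\tstrand\tstart_codon\tstop_codon\tanticodon\n"
            "cox1\tPCG\tone\t10\t+\tATG\tTAA\t.\n"
        )
        with pytest.raises(AnnotationError, match="line 2"):
            read_annotation(p)

    def test_duplicate_names_rejected(self):
        f1 = GeneFeature("trnK", "tRNA", 1, 60, "+")
        f2 = GeneFeature("trnK", "tRNA", 100, 160, "+")
        with pytest.raises(AnnotationError, match="trnK"):
            AnnotationTable(200, (f1, f2))

    def test_feature_beyond_genome_rejected(self):
        f = GeneFeature("trnK", "tRNA", 1, 60, "+")
        with pytest.raises(AnnotationError, match="genome length"):
            AnnotationTable(50, (f,))

    def test_codons_required_iff_pcg(self):
        with pytest.raises(AnnotationError):
            GeneFeature("cox1", "PCG", 1, 300, "+")  # no codons
        with pytest.raises(AnnotationError):
            GeneFeature("trnK", "tRNA", 1, 60, "+", start_codon="ATG")


class TestSpacerAlgebra:
    def test_abutting_features_gap_zero(self):
        t = AnnotationTable(300, (
            GeneFeature("trnK", "tRNA", 1, 100, "+"),
            GeneFeature("trnD", "tRNA", 101, 200, "+"),
        ))
        rep = spacer_overlap_report(t)
        assert rep.records[0].gap == 0
        assert rep.n_spacers == 0 and rep.n_overlaps == 0

    def test_gap_conservation_on_random_tables(self):
        """Signed gaps (incl. the closing one) + feature lengths = genome size."""
        rng = random.Random(7)
        names = [f.name for f in datasets.polydesmus_table().by_category("tRNA")]
        for _ in range(50):
            k = rng.randint(2, len(names))
            chosen = rng.sample(names, k)
            pos, feats = 1, []
            for name in chosen:
                gap = rng.randint(0, 30)
                length = rng.randint(55, 70)
                start = pos + gap
                feats.append(GeneFeature(name, "tRNA", start, start + length - 1, "+"))
                pos = start + length
            genome_length = pos + rng.randint(0, 50)
            t = AnnotationTable(genome_length, tuple(feats))
            rep = spacer_overlap_report(t)
            total_gaps = sum(r.gap for r in rep.records)
            total_len = sum(f.length for f in feats)
            assert total_gaps + total_len == genome_length

    def test_partition_lengths_order_invariant(self, annot_table):
        rng = random.Random(1)
        feats = list(annot_table.features)
        rng.shuffle(feats)
        assert partition_lengths(AnnotationTable(annot_table.genome_length, tuple(feats))) \
            == partition_lengths(annot_table)


class TestCodonInventory:
    def test_minimal_pcg(self):
        t = AnnotationTable(9, (
            GeneFeature("atp8", "PCG", 1, 6, "+", start_codon="ATG", stop_codon="TAA"),
        ))
        starts, stops = codon_inventory(t, "ATGTAAGGG")
        assert (starts["atp8"], stops["atp8"]) == ("ATG", "TAA")

    def test_truncated_stop_and_minus_strand(self):
        # atp6 on minus strand, length 7 (= 2 codons + single-base stop "T"):
        # plus-strand genome carries the reverse complement of ATGGGG + T.
        gene = "ATGGGGT"
        from mitorearrange.annotation import revcomp
        t = AnnotationTable(9, (
            GeneFeature("atp6", "PCG", 2, 8, "-", start_codon="ATG", stop_codon="T"),
        ))
        seq = "A" + revcomp(gene) + "C"
        starts, stops = codon_inventory(t, seq)
        assert (starts["atp6"], stops["atp6"]) == ("ATG", "T")

    def test_too_short_pcg_rejected(self):
        t = AnnotationTable(9, (
            GeneFeature("atp8", "PCG", 1, 5, "+", start_codon="ATG", stop_codon="TA"),
        ))
        with pytest.raises(AnnotationError, match="shorter"):
            codon_inventory(t, "ATGTAAGGG")
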