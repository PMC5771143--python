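"""Footprint parsing, length filtering and read-to-codon assignment."""

import numpy as np
import pytest

from mitoribo.footprints import (
    Footprint,
    FootprintLibrary,
    FootprintParseError,
    codon_counts,
    filter_by_length,
    read_footprints,
)
from mitoribo.reference import (
    GenomeReference,
    OrfAnnotation,
    extract_orf_codons,
)

# ---------------------------------------------------------------------------
# independent re-scan oracle
# ---------------------------------------------------------------------------

def _span(fp):
    if fp.strand == "+":
        return fp.five_prime_pos, fp.five_prime_pos + fp.length
    return fp.five_prime_pos - fp.length + 1, fp.five_prime_pos + 1


def _oracle_counts(lib, ref, orfs, mode, offset):
    out = {}
    for orf in orfs:
        n = len(extract_orf_codons(ref, orf))
        vec = np.zeros(n, dtype=int)
        for fp in lib:
            if fp.strand != orf.strand:
                continue
            if mode == "asite_offset":
                if fp.length <= offset:
                    continue
                pos = (
                    fp.five_prime_pos + offset
                    if fp.strand == "+"
                    else fp.five_prime_pos - offset
                )
                if not (orf.cds_start <= pos < orf.cds_end):
                    continue
                rel = (
                    pos - orf.cds_start
                    if orf.strand == "+"
                    else orf.cds_end - 1 - pos
                )
                if rel // 3 < n:
                    vec[rel // 3] += 1
            else:
                s, e = _span(fp)
                for j in range(n):
                    if orf.strand == "+":
                        c0 = orf.cds_start + 3 * j
                    else:
                        c0 = orf.cds_end - 3 * (j + 1)
                    if s <= c0 and c0 + 3 <= e:
                        vec[j] += 1
        out[orf.gene_id] = vec
    return out


class TestReadFootprints:
    def test_bed_strand_arithmetic(self, tmp_path):
        bed = tmp_path / "lib.bed"
        bed.write_text(
            "chrM\t100\t130\t.\t0\t+\n"
            "chrM\t100\t130\t.\t0\t-\n"
        )
        lib = read_footprints(bed, replicate_id="r1", condition="control")
        fps = list(lib)
        assert fps[0] == Footprint(100, 30, "+")
        assert fps[1] == Footprint(129, 30, "-")
        assert lib.total_reads == 2

    def test_bed_errors_carry_line_numbers(self, tmp_path):
        bed = tmp_path / "bad.bed"
        bed.write_text("chrM\t100\t130\t.\t0\t+\nchrM\t100\t400\t.\t0\t+\n")
        with pytest.raises(FootprintParseError, match=":2"):
            read_footprints(bed)
        bed.write_text("chrM\t100\t130\t.\t0\n")
        with pytest.raises(FootprintParseError, match=":1"):
            read_footprints(bed)

    def test_bed_unknown_contig(self, tmp_path):
        bed = tmp_path / "lib.bed"
        bed.write_text("chrX\t100\t130\t.\t0\t+\n")
        with pytest.raises(FootprintParseError, match="chrX"):
            read_footprints(bed, genome_id="chrM")

    def test_sam_parsing_skips_secondary(self, tmp_path):
        sam = tmp_path / "lib.sam"
        sam.write_text(
            "@HD\tVN:1.6\tSO:unsorted\n"
            "@SQ\tSN:chrM\tLN:1000\n"
            "r1\t0\tchrM\t101\t60\t30M\t*\t0\t0\t" + "A" * 30 + "\t*\n"
            "r2\t16\tchrM\t101\t60\t30M\t*\t0\t0\t" + "A" * 30 + "\t*\n"
            "r3\t256\tchrM\t201\t60\t30M\t*\t0\t0\t*\t*\n"
            "r4\t4\t*\t0\t0\t*\t*\t0\t0\t" + "A" * 30 + "\t*\n"
        )
        lib = read_footprints(sam, format="sam", genome_id="chrM")
        fps = list(lib)
        assert len(fps) == 2 and lib.total_reads == 2
        # SAM POS 101 is 0-based 100; reverse read 5' end is its rightmost base
        assert fps[0] == Footprint(100, 30, "+")
        assert fps[1] == Footprint(129, 30, "-")


class TestFilterByLength:
    def test_length_window_boundaries(self):
        lib = FootprintLibrary.from_records(
            [Footprint(100, l, "+") for l in (23, 24, 37, 38)]
        )
        kept = filter_by_length(lib)
        assert sorted(kept.length) == [24, 37]
        assert kept.total_reads == 4  # parsed denominator kept
        assert filter_by_length(lib, denominator="filtered").total_reads == 2

    def test_empty_library(self):
        lib = FootprintLibrary.from_records([])
        assert len(filter_by_length(lib, denominator="filtered")) == 0

    def test_random_lengths_match_recount(self):
        rng = np.random.default_rng(0)
        lens = rng.integers(15, 51, size=10_000)
        lib = FootprintLibrary.from_records(
            [Footprint(100, int(l), "+") for l in lens]
        )
        kept = filter_by_length(lib)
        assert len(kept) == int(np.sum((lens >= 24) & (lens <= 37)))


class TestCodonCounts:
    def test_coverage_mode_full_containment(self, tiny_genome):
        genome, orf = tiny_genome
        lib = FootprintLibrary.from_records([Footprint(10, 30, "+")])
        m = codon_counts(lib, genome, [orf], mode="coverage")
        assert list(m.counts["g1"]) == [1] * 10

    def test_asite_mode_single_assignment(self, tiny_genome):
        genome, orf = tiny_genome
        lib = FootprintLibrary.from_records([Footprint(10, 30, "+")])
        m = codon_counts(lib, genome, [orf], mode="asite_offset", offset=14)
        expected = np.zeros(10, dtype=int)
        expected[4] = 1  # position 14 of the footprint sits in codon 4
        assert list(m.counts["g1"]) == list(expected)

    def test_short_footprint_skipped_with_counter(self, tiny_genome):
        genome, orf = tiny_genome
        lib = FootprintLibrary.from_records([Footprint(10, 15, "+")])
        m = codon_counts(lib, genome, [orf], mode="asite_offset", offset=20)
        assert m.total() == 0 and m.skipped_short == 1

    @pytest.mark.parametrize("mode", ["asite_offset", "coverage"])
    def test_simulated_library_matches_rescan_oracle(self, small_sim, mode):
        _, ref, orfs, libs, _ = small_sim
        lib = libs[0].subset(np.arange(500))  # 500 reads is plenty for the scan
        m = codon_counts(lib, ref, orfs, mode=mode, offset=14)
        oracle = _oracle_counts(lib, ref, orfs, mode, 14)
        for gene_id, vec in oracle.items():
            assert list(m.counts[gene_id]) == list(vec)

    def test_count_mass_invariants(self, small_sim):
        _, ref, orfs, libs, _ = small_sim
        lib = libs[0]
        asite = codon_counts(lib, ref, orfs, mode="asite_offset", offset=14)
        # bicistronic overlap may double-assign, monocistronic genes cannot
        mono = [o for o in orfs if o.transcript_id != "rna_bic"]
        mono_total = sum(asite.counts[o.gene_id].sum() for o in mono)
        assert mono_total <= len(lib)
        cov = codon_counts(lib, ref, orfs, mode="coverage")
        assert cov.total() <= len(lib) * int(np.ceil(lib.length.max() / 3)) * 2

    def test_strand_mirror_invariance(self, small_sim):
        """Reverse-complementing the genome and mirroring records leaves the
        count matrix unchanged."""
        _, ref, orfs, libs, _ = small_sim
        lib = libs[0].subset(np.arange(300))
        L = len(ref)
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        mirror_ref = GenomeReference(
            ref.id, "".join(comp[b] for b in reversed(ref.sequence)), ref.circular
        )
        flip = {"+": "-", "-": "+"}
        mirror_orfs = [
            OrfAnnotation(
                o.gene_id,
                o.transcript_id,
                flip[o.strand],
                L - o.cds_end,
                L - o.cds_start,
                o.leader_length,
                o.incomplete_stop_nt,
            )
            for o in orfs
        ]
        mirror_lib = FootprintLibrary(
            replicate_id=lib.replicate_id,
            condition=lib.condition,
            five_prime=L - 1 - lib.five_prime,
            length=lib.length,
            strand=np.array([flip[s] for s in lib.strand]),
            total_reads=lib.total_reads,
        )
        for mode in ("asite_offset", "coverage"):
            a = codon_counts(lib, ref, orfs, mode=mode, offset=14)
            b = codon_counts(mirror_lib, mirror_ref, mirror_orfs, mode=mode, offset=14)
            for o in orfs:
                assert list(a.counts[o.gene_id]) == list(b.counts[o.gene_id])

    def test_matrix_frame_layout(self, tiny_genome):
        genome, orf = tiny_genome
        lib = FootprintLibrary.from_records([Footprint(10, 30, "+")])
        df = codon_counts(lib, genome, [orf]).to_frame()
        assert list(df.columns) == ["gene_id", "codon_index", "codon", "count"]
        assert df["count"].sum() == 1
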