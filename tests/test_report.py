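"""Locus-level PGT-M calls and summary records."""

import json

import numpy as np
import pytest

from haplarith.cnv import ChromosomeResult, CopyNumberCall, Configuration
from haplarith.haplarithm import (
    Breakpoint,
    HaplarithmProfile,
    HaplotypeBlock,
    InformativeTrack,
)
from haplarith.io import QcMetrics
from haplarith.report import (
    EmbryoAnalysis,
    LocusSpec,
    call_locus,
    read_locus_table,
    summarize_embryo,
    summary_table,
)


def _track(parent, chrom, positions, snp_map):
    pos = np.asarray(positions)
    return InformativeTrack(
        parent,
        np.arange(len(pos)),
        pos,
        np.full(len(pos), chrom, dtype=object),
        np.zeros(len(pos), dtype=np.int8),
        np.full(len(pos), 0.5),
    )


def _profile(snp_map, chrom, blocks, breakpoints, positions):
    tracks = {
        "mat": _track("mat", chrom, positions, snp_map),
        "pat": _track("pat", chrom, positions, snp_map),
    }
    all_blocks = []
    for parent in ("mat", "pat"):
        for b in blocks:
            all_blocks.append(HaplotypeBlock(chrom, b[0], b[1], parent, b[2], b[3]))
    bps = [Breakpoint(chrom, p, parent) for parent in ("mat", "pat") for p in breakpoints]
    return HaplarithmProfile(tracks, {"mat": [], "pat": []}, all_blocks, bps)


def _chrom_result(chrom, m, p, length):
    call = CopyNumberCall(chrom, 1, length, "disomy" if (m, p) == (1, 1) else "x",
                          m, p, Configuration(1, 0, 1, 0) if m else None)
    return ChromosomeResult(chrom, [call], [call], call.state, m, p, False, False)


CHROM = "1"
LEN = 150_000_000


class TestCallLocus:
    def setup_method(self):
        self.positions = np.arange(1, 150) * 1_000_000

    def test_conclusive_inside_clean_block(self, small_map):
        profile = _profile(small_map, CHROM, [(1, LEN, "H2", 100)], [], self.positions)
        results = {CHROM: _chrom_result(CHROM, 1, 1, LEN)}
        locus = LocusSpec("GENE", CHROM, 60_000_000, 61_000_000)
        lc = call_locus(locus, profile, results, small_map)
        assert lc.maternal.haplotype == "H2"
        assert lc.maternal.reason == "none"
        # no recombination sites: flanks run to the chromosome ends
        assert lc.maternal.upstream_bp == 60_000_000 - 1
        assert lc.maternal.downstream_bp == small_map.karyotype.length(CHROM) - 61_000_000
        assert lc.maternal.upstream_informative > 0

    def test_parental_loss_is_inconclusive_no_heterozygosity(self, small_map):
        profile = _profile(small_map, CHROM, [(1, LEN, "none", 50)], [], self.positions)
        results = {CHROM: _chrom_result(CHROM, 0, 1, LEN)}
        lc = call_locus(LocusSpec("G", CHROM, 60_000_000, 61_000_000), profile, results, small_map)
        assert lc.maternal.haplotype == "inconclusive"
        assert lc.maternal.reason == "no_heterozygosity"
        assert lc.paternal.haplotype in ("H1", "H2", "inconclusive")

    def test_recombination_inside_locus_inconclusive(self, small_map):
        profile = _profile(
            small_map, CHROM,
            [(1, 60_500_000, "H1", 60), (60_500_001, LEN, "H2", 60)],
            [60_500_000], self.positions,
        )
        results = {CHROM: _chrom_result(CHROM, 1, 1, LEN)}
        lc = call_locus(LocusSpec("G", CHROM, 60_000_000, 61_000_000), profile, results, small_map)
        assert lc.maternal.reason == "recombination_at_locus"


    def test_unanchored_flank_is_inconclusive(self, small_map):
        """A breakpoint-bounded flank with no informative SNPs between the
        breakpoint and the locus cannot anchor the haplotype: the true
        switch may sit on either side of the locus."""
        positions = np.r_[np.arange(1, 50) * 1_000_000, np.arange(130, 150) * 1_000_000]
        profile = _profile(
            small_map, CHROM,
            [(1, 55_000_000, "H1", 49), (55_000_001, LEN, "H2", 20)],
            [55_000_000], positions,
        )
        results = {CHROM: _chrom_result(CHROM, 1, 1, LEN)}
        lc = call_locus(LocusSpec("G", CHROM, 60_000_000, 61_000_000), profile, results, small_map)
        assert lc.maternal.haplotype == "inconclusive"
        assert lc.maternal.reason == "no_informative_snps"
        assert lc.maternal.upstream_informative == 0

    def test_flanking_metrics_bounded_by_chromosome(self, small_map):
        profile = _profile(
            small_map, CHROM,
            [(1, 40_000_000, "H1", 60), (40_000_001, LEN, "H2", 60)],
            [40_000_000], self.positions,
        )
        results = {CHROM: _chrom_result(CHROM, 1, 1, LEN)}
        locus = LocusSpec("G", CHROM, 60_000_000, 61_000_000)
        lc = call_locus(locus, profile, results, small_map)
        total = lc.maternal.upstream_bp + lc.maternal.downstream_bp + (locus.end_bp - locus.start_bp)
        assert total <= small_map.karyotype.length(CHROM)

    def test_unknown_chromosome_rejected(self, small_map):
        profile = _profile(small_map, CHROM, [(1, LEN, "H1", 10)], [], self.positions)
        with pytest.raises(ValueError):
            call_locus(LocusSpec("G", "99", 1, 2), profile, {}, small_map)

    def test_locus_order_invariance(self, small_map):
        profile = _profile(small_map, CHROM, [(1, LEN, "H1", 80)], [], self.positions)
        results = {CHROM: _chrom_result(CHROM, 1, 1, LEN)}
        loci = [
            LocusSpec("A", CHROM, 10_000_000, 11_000_000),
            LocusSpec("B", CHROM, 90_000_000, 91_000_000),
        ]
        fwd = [call_locus(l, profile, results, small_map) for l in loci]
        rev = [call_locus(l, profile, results, small_map) for l in reversed(loci)]
        assert {c.gene: c.maternal.haplotype for c in fwd} == {
            c.gene: c.maternal.haplotype for c in rev
        }


class TestLocusTable:
    def test_read_with_bed_conversion(self, tmp_path):
        p = tmp_path / "loci.tsv"
        p.write_text("gene\tchrom\tstart\tend\tnote\nG1\t1\t999\t2000\tx\n")
        (one_based,) = read_locus_table(p)
        assert (one_based.start_bp, one_based.end_bp) == (999, 2000)
        (converted,) = read_locus_table(p, strict_bed=True)
        assert (converted.start_bp, converted.end_bp) == (1000, 2000)

    def test_duplicate_gene_rejected(self, tmp_path):
        p = tmp_path / "loci.tsv"
        p.write_text("gene\tchrom\tstart\tend\nG1\t1\t1\t2\nG1\t1\t5\t9\n")
        with pytest.raises(ValueError):
            read_locus_table(p)


class TestSummaries:
    def test_failed_sample_record(self):
        analysis = EmbryoAnalysis(
            "e1", "biopsy", "failed", QcMetrics(0.1, None, 0), failure_reason="call rate"
        )
        rec = summarize_embryo(analysis)
        assert rec["status"] == "failed"
        assert "ploidy" not in rec

    def test_record_json_round_trip(self, family, phased):
        from haplarith.report import analyze_sample
        from haplarith.simulate import NoiseConfig, assemble_embryo, render_array, simulate_meiosis

        snp_map = family.snp_map
        mg = simulate_meiosis(family.mother, snp_map, parent_label="mat", seed=61)
        pg = simulate_meiosis(family.father, snp_map, parent_label="pat", seed=62)
        emb = assemble_embryo(mg, pg, n_cells=1, snp_map=snp_map)
        arr = render_array(emb, snp_map, noise=NoiseConfig.none(), sample_id="emb", seed=0)
        loci = [LocusSpec("G1", "1", 50_000_000, 51_000_000)]
        analysis = analyze_sample(
            arr, family.samples["mother"], family.samples["father"], phased, snp_map, loci=loci
        )
        rec = summarize_embryo(analysis)
        assert json.loads(json.dumps(rec)) == rec
        assert rec["ploidy"] == "biparental_diploid"
        table = summary_table([rec])
        assert table.loc[0, "sample_id"] == "emb"
        assert "G1_mat" in table.columns
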