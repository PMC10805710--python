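"""Signature table, segment classifier, ploidy, sex, event origin."""

import itertools

import numpy as np
import pytest

from haplarith.cnv import (
    ChromosomeResult,
    Configuration,
    CopyNumberCall,
    SIGNATURES,
    _mixture_expected,
    call_genome_ploidy,
    classify_event_origin,
    classify_segment,
    determine_sex,
    segment_logr,
    state_label,
)
from haplarith.config import AnalysisConfig
from haplarith.sample import SampleArray
from haplarith.simulate import LOGR_FLOOR


class TestSignatureTable:
    def test_copy_number_logr_levels(self):
        expected_logr = {1: -1.0, 2: 0.0, 3: np.log2(1.5), 4: 1.0}
        for cfg in SIGNATURES.configs:
            if cfg.n == 0:
                assert cfg.expected()[0] == LOGR_FLOOR
            else:
                assert abs(cfg.expected()[0] - expected_logr[cfg.n]) < 1e-12

    def test_subtrack_level_sets(self):
        # monosomy {0,1}; trisomy {0,1/3,2/3,1}; tetrasomy {0,1/4,1/2,3/4,1}
        for n, levels in ((1, {0, 1}), (3, {0, 1 / 3, 2 / 3, 1}), (4, {0, 0.25, 0.5, 0.75, 1})):
            reachable = set()
            for cfg in SIGNATURES.configs:
                if cfg.n == n:
                    reachable.update(cfg.expected()[1:])
            assert sorted(reachable) == pytest.approx(sorted(levels), abs=1e-12)

    def test_disomy_distance_is_half(self):
        cfg = Configuration(1, 0, 1, 0)
        e = cfg.expected()
        assert e[0] == 0.0
        assert abs(e[1] - e[2]) == pytest.approx(0.5)
        assert abs(e[3] - e[4]) == pytest.approx(0.5)


class TestClassifierExhaustive:
    def test_every_configuration_recovered_from_its_signature(self):
        """Independent oracle loop: generate each configuration's noise-free
        signature and require the classifier to return that configuration."""
        for m1, m2, p1, p2 in itertools.product(range(5), repeat=4):
            n = m1 + m2 + p1 + p2
            if not 1 <= n <= 4:
                continue
            truth = Configuration(m1, m2, p1, p2)
            e = truth.expected()
            cfg, dist, mosaic, frac = classify_segment(e[0], (e[1], e[2]), (e[3], e[4]))
            assert cfg == truth, (truth, cfg)
            assert dist < 1e-9
            assert not mosaic

    def test_unavailable_paternal_track_still_classifies(self):
        # male X: one maternal copy, no paternal informative SNPs
        cfg, dist, _, _ = classify_segment(-1.0, (1.0, 0.0), (np.nan, np.nan))
        assert (cfg.m, cfg.p) == (1, 0)


class TestMosaicMixture:
    def test_half_disomy_half_maternal_monosomy(self):
        """Closed-form mixture observables; fraction recovered within 0.05
        and cross-checked against an independent coarse grid oracle."""
        rho = 0.5  # disomic cell fraction
        disomy = Configuration(1, 0, 1, 0)
        loss = Configuration(0, 0, 1, 0)  # maternal loss
        n_mix = 2 * rho + 1 * (1 - rho)
        observed = np.array(
            [
                np.log2(n_mix / 2),
                (rho * 1) / n_mix, 0.0,
                (rho * 1 + (1 - rho) * 1) / n_mix, 0.0,
            ]
        )
        cfg, dist, mosaic, frac = classify_segment(
            observed[0], (observed[1], observed[2]), (observed[3], observed[4])
        )
        assert mosaic
        assert (cfg.m, cfg.p) == (0, 1)
        assert frac == pytest.approx(0.5, abs=0.05)
        # oracle: coarse independent grid over rho using the closed form
        grid = np.linspace(0, 1, 101)
        dists = [
            np.sqrt(np.mean((_mixture_expected(disomy, loss, r) - observed) ** 2))
            for r in grid
        ]
        assert grid[int(np.argmin(dists))] == pytest.approx(1 - frac, abs=0.02)

    def test_pure_state_not_called_mosaic(self):
        e = Configuration(0, 0, 1, 0).expected()
        cfg, _, mosaic, _ = classify_segment(e[0], (e[1], e[2]), (e[3], e[4]))
        assert not mosaic


class TestSegmentLogr:
    def _embryo(self, snp_map, logr):
        n = len(snp_map)
        return SampleArray("e", "embryo", np.zeros(n, np.int8), np.full(n, 0.5), logr)

    def test_constant_zero_single_segment(self, small_map):
        segs = segment_logr(self._embryo(small_map, np.zeros(len(small_map))), small_map)
        for chrom in small_map.chroms:
            assert len(segs[chrom]) == 1
            assert segs[chrom][0]["mean"] == pytest.approx(0.0)

    def test_monosomic_chromosome_at_minus_one(self, small_map):
        logr = np.zeros(len(small_map))
        logr[small_map.chrom_slice("2")] = -1.0
        segs = segment_logr(self._embryo(small_map, logr), small_map)
        assert len(segs["2"]) == 1
        assert segs["2"][0]["mean"] == pytest.approx(-1.0)

    def test_half_chromosome_loss_breakpoint(self, small_map):
        rng = np.random.default_rng(4)
        logr = rng.normal(0, 0.15, len(small_map))
        sl = small_map.chrom_slice("1")
        n1 = sl.stop - sl.start
        half = sl.start + n1 // 2
        logr[half:sl.stop] -= 1.0
        segs = segment_logr(self._embryo(small_map, logr), small_map)
        assert len(segs["1"]) == 2
        bp_idx = np.searchsorted(small_map.pos_bp[sl], segs["1"][1]["start_bp"])
        assert abs(bp_idx - n1 // 2) <= 5


def _chrom_result(chrom, m, p, mosaic=False, hetero=False, length=10**8):
    state = state_label(m, p) if m is not None else "undetermined"
    call = CopyNumberCall(chrom, 1, length, state, m, p, None, mosaic, 0.5 if mosaic else None)
    return ChromosomeResult(chrom, [call], [call], state, m, p, mosaic, hetero,
                            0.5 if hetero else 0.0)


def _genome(pattern_by_chrom):
    return {c: _chrom_result(c, *mp) for c, mp in pattern_by_chrom.items()}


class TestPloidyAndSex:
    CHROMS = [str(i) for i in range(1, 32)] + ["X"]

    def test_biparental_diploid(self):
        results = _genome({c: (1, 1) for c in self.CHROMS})
        call = call_genome_ploidy(results)
        assert call.label == "biparental_diploid"
        assert call.sex == "female"

    def test_digynic_meiotic_vs_mitotic(self):
        hetero = {c: _chrom_result(c, 2, 1, hetero=True) for c in self.CHROMS}
        assert call_genome_ploidy(hetero).label == "digynic_triploid_meiotic"
        iso = {c: _chrom_result(c, 2, 1, hetero=False) for c in self.CHROMS}
        assert call_genome_ploidy(iso).label == "digynic_triploid_mitotic"

    def test_haploid_upd_and_complex(self):
        assert call_genome_ploidy(_genome({c: (1, 0) for c in self.CHROMS})).label == "gynogenetic_haploid"
        assert call_genome_ploidy(_genome({c: (0, 2) for c in self.CHROMS})).label == "gw_paternal_UPD"
        mixed = {c: (1, 1) for c in self.CHROMS[:12]}
        mixed.update({c: (2, 1) for c in self.CHROMS[12:24]})
        mixed.update({c: (1, 0) for c in self.CHROMS[24:]})
        assert call_genome_ploidy(_genome(mixed)).label == "complex"

    def test_single_aneuploidy_keeps_diploid_label(self):
        pattern = {c: (1, 1) for c in self.CHROMS}
        pattern["31"] = (0, 1)
        assert call_genome_ploidy(_genome(pattern)).label == "biparental_diploid"

    def test_insufficient_coverage_undetermined(self):
        pattern = {c: (None, None) for c in self.CHROMS}
        call = call_genome_ploidy(_genome(pattern))
        assert call.label == "undetermined"
        assert "coverage" in call.reason

    @pytest.mark.parametrize(
        "mp,expected", [((1, 0), "male"), ((1, 1), "female"), ((2, 1), "undetermined")]
    )
    def test_sex_rule(self, mp, expected):
        assert determine_sex(_chrom_result("X", *mp)) == expected

    def test_sex_without_x_call(self):
        assert determine_sex(None) == "undetermined"


class TestEventOrigin:
    def _sample(self, sid, role, aberrations):
        results = {c: _chrom_result(c, 1, 1) for c in ["1", "2", "3"]}
        for chrom, (m, p) in aberrations.items():
            results[chrom] = _chrom_result(chrom, m, p)
        return {"sample_id": sid, "role": role, "results": results}

    def test_shared_biopsy_blastocyst_event_is_meiotic(self):
        events = classify_event_origin(
            [
                self._sample("b", "biopsy", {"2": (0, 1)}),
                self._sample("e", "blastocyst", {"2": (0, 1)}),
            ]
        )
        assert events == [
            {"chrom": "2", "state": "maternal_loss", "samples": ["b", "e"], "origin": "meiotic"}
        ]

    def test_biopsy_only_event_is_low_grade_mosaic(self):
        events = classify_event_origin(
            [
                self._sample("b", "biopsy", {"3": (2, 1)}),
                self._sample("e", "blastocyst", {}),
            ]
        )
        assert events[0]["origin"] == "low_grade_mosaic"

    def test_blastomere_subset_event_is_mitotic(self):
        samples = [self._sample(f"bl{i}", "blastomere", {}) for i in range(4)]
        samples[0] = self._sample("bl0", "blastomere", {"1": (1, 0)})
        events = classify_event_origin(samples)
        assert events[0]["origin"] == "mitotic"

    def test_all_blastomeres_event_is_meiotic(self):
        samples = [self._sample(f"bl{i}", "blastomere", {"1": (0, 1)}) for i in range(3)]
        events = classify_event_origin(samples)
        assert events[0]["origin"] == "meiotic"

    def test_single_sample_undetermined(self):
        events = classify_event_origin([self._sample("b", "biopsy", {"2": (0, 1)})])
        assert events[0]["origin"] == "undetermined"
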