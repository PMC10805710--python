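"""Simulator: map construction, founders, meiosis, embryos, rendering."""

import numpy as np
import pytest

from haplarith.karyotype import Karyotype
from haplarith.sample import GT_AB, GT_NC
from haplarith.simulate import (
    LOGR_FLOOR,
    NoiseConfig,
    RecombConfig,
    assemble_embryo,
    render_array,
    simulate_founder,
    simulate_meiosis,
)
from haplarith.snp_map import build_snp_map

NO_XO = RecombConfig(forced_crossovers={})


class TestBuildSnpMap:
    def test_equal_chromosomes_split_evenly(self):
        kt = Karyotype({"1": 50_000_000, "2": 50_000_000})
        m = build_snp_map(kt, n_snps=100, seed=1)
        n1, n2 = m.n_snps("1"), m.n_snps("2")
        assert n1 + n2 == 100
        assert 30 <= n1 <= 70  # binomial split around 50
        assert np.all(np.diff(m.pos_bp[m.chrom_slice("1")]) >= 0)

    def test_default_karyotype_has_all_chromosomes(self):
        m = build_snp_map(n_snps=70_000, seed=0)
        assert len(m.chroms) == 32
        assert m.chroms[-1] == "X"
        assert all(m.n_snps(c) >= 1 for c in m.chroms)

    def test_deterministic(self):
        a = build_snp_map(n_snps=500, seed=3)
        b = build_snp_map(n_snps=500, seed=3)
        assert a.df.equals(b.df)

    def test_nonpositive_length_rejected(self):
        with pytest.raises(ValueError):
            Karyotype({"1": 0})


class TestFounder:
    def test_heterozygosity_matches_binomial_expectation(self):
        kt = Karyotype({"1": 100_000_000})
        m = build_snp_map(kt, n_snps=10_000, seed=2)
        f = simulate_founder(m, maf_spec=0.5, seed=5)
        het = np.mean(f.h1 != f.h2)
        assert abs(het - 0.5) < 0.02  # 2 f (1-f) with f = 0.5

    def test_zero_frequency_gives_all_A(self, small_map):
        f = simulate_founder(small_map, maf_spec=0.0, seed=1)
        assert not f.h1.any() and not f.h2.any()

    def test_reproducible(self, small_map):
        a = simulate_founder(small_map, seed=9)
        b = simulate_founder(small_map, seed=9)
        assert np.array_equal(a.h1, b.h1) and np.array_equal(a.h2, b.h2)

    def test_male_founder_hemizygous_x(self, small_map):
        f = simulate_founder(small_map, seed=4, sex="male")
        sl = small_map.chrom_slice("X")
        assert np.array_equal(f.h1[sl], f.h2[sl])


class TestMeiosis:
    def test_no_crossover_gamete_is_one_homologue(self, small_map):
        parent = simulate_founder(small_map, seed=1)
        g = simulate_meiosis(parent, small_map, recomb=NO_XO, seed=2)
        for chrom in small_map.chroms:
            sl = small_map.chrom_slice(chrom)
            (strand,) = g.strands[chrom]
            assert np.array_equal(strand.alleles, parent.h1[sl]) or np.array_equal(
                strand.alleles, parent.h2[sl]
            )

    def test_mi_without_crossovers_transmits_both_homologues(self, small_map):
        parent = simulate_founder(small_map, seed=1)
        g = simulate_meiosis(
            parent, small_map, recomb=NO_XO, nondisjunction="MI", nd_chroms=["2"], seed=3
        )
        sl = small_map.chrom_slice("2")
        s1, s2 = g.strands["2"]
        assert np.array_equal(s1.alleles, parent.h1[sl])
        assert np.array_equal(s2.alleles, parent.h2[sl])
        het = parent.h1[sl] != parent.h2[sl]
        # heterodisomy at every parental heterozygous SNP
        assert np.all(s1.alleles[het] != s2.alleles[het])

    def test_mii_strands_identical(self, small_map):
        parent = simulate_founder(small_map, seed=1)
        g = simulate_meiosis(parent, small_map, nondisjunction="MII", nd_chroms=["3"], seed=4)
        s1, s2 = g.strands["3"]
        assert np.array_equal(s1.alleles, s2.alleles)
        assert np.array_equal(s1.origin, s2.origin)

    def test_nullisomic_and_invalid_label(self, small_map):
        parent = simulate_founder(small_map, seed=1)
        g = simulate_meiosis(parent, small_map, nullisomic_chroms=["1"], seed=5)
        assert g.strands["1"] == []
        with pytest.raises(ValueError):
            simulate_meiosis(parent, small_map, nondisjunction="MIII", seed=5)


def _gametes(small_map, seed=0, **kwargs):
    mother = simulate_founder(small_map, seed=seed, individual_id="m")
    father = simulate_founder(small_map, seed=seed + 1, individual_id="f")
    mg = simulate_meiosis(mother, small_map, parent_label="mat", seed=seed + 2, **kwargs)
    pg = simulate_meiosis(father, small_map, parent_label="pat", seed=seed + 3)
    return mg, pg


class TestAssembleEmbryo:
    def test_no_events_gives_identical_diploid_cells(self, small_map):
        mg, pg = _gametes(small_map)
        emb = assemble_embryo(mg, pg, n_cells=4, snp_map=small_map)
        counts = [emb.chrom_modal_counts(i) for i in range(4)]
        assert all(c == counts[0] for c in counts)
        assert all(v == (1, 1) for v in counts[0].values())

    def test_meiotic_trisomy_present_in_every_cell(self, small_map):
        mg, pg = _gametes(small_map, 1, nondisjunction="MI", nd_chroms=["2"])
        emb = assemble_embryo(mg, pg, n_cells=5, snp_map=small_map)
        for i in range(5):
            assert emb.chrom_modal_counts(i)["2"] == (2, 1)

    def test_reciprocal_gain_loss(self, small_map):
        mg, pg = _gametes(small_map)
        plan = [
            {"kind": "loss", "chrom": "2", "parent": "pat", "copy_index": 0, "cells": [0]},
            {"kind": "gain", "chrom": "2", "parent": "pat", "copy_index": 0, "cells": [1]},
        ]
        emb = assemble_embryo(mg, pg, mitotic_event_plan=plan, n_cells=4, snp_map=small_map)
        assert emb.chrom_modal_counts(0)["2"] == (1, 0)
        assert emb.chrom_modal_counts(1)["2"] == (1, 2)
        assert emb.chrom_modal_counts(2)["2"] == (1, 1)

    def test_event_on_absent_copy_rejected(self, small_map):
        mg, pg = _gametes(small_map)
        with pytest.raises(ValueError):
            assemble_embryo(
                mg, pg,
                mitotic_event_plan=[
                    {"kind": "loss", "chrom": "2", "parent": "pat", "copy_index": 3, "cells": [0]}
                ],
                n_cells=2, snp_map=small_map,
            )

    def test_mitotic_events_in_strict_subset(self, small_map):
        mg, pg = _gametes(small_map)
        plan = [{"kind": "gain", "chrom": "1", "parent": "mat", "copy_index": 0, "cells": [0, 1]}]
        emb = assemble_embryo(mg, pg, mitotic_event_plan=plan, n_cells=4, snp_map=small_map)
        affected = [i for i in range(4) if emb.chrom_modal_counts(i)["1"] == (2, 1)]
        assert affected == [0, 1]


class TestRenderArray:
    def test_diploid_heterozygous_snp_noise_free(self, small_map):
        mg, pg = _gametes(small_map)
        emb = assemble_embryo(mg, pg, n_cells=1, snp_map=small_map)
        arr = render_array(emb, small_map, noise=NoiseConfig.none(), seed=0)
        nB = mg.strands["1"][0].alleles.astype(int) + pg.strands["1"][0].alleles
        sl = small_map.chrom_slice("1")
        het = nB == 1
        assert np.allclose(arr.baf[sl][het], 0.5)
        assert np.allclose(arr.logr[sl], 0.0)
        assert np.all(arr.gtype[sl][het] == GT_AB)

    def test_trisomy_baf_thirds_and_logr(self, small_map):
        mg, pg = _gametes(small_map, 2, nondisjunction="MI", nd_chroms=["2"])
        emb = assemble_embryo(mg, pg, n_cells=1, snp_map=small_map)
        arr = render_array(emb, small_map, noise=NoiseConfig.none(), seed=0)
        sl = small_map.chrom_slice("2")
        baf = arr.baf[sl]
        assert set(np.round(baf[np.isfinite(baf)], 6)) <= {0.0, round(1 / 3, 6), round(2 / 3, 6), 1.0}
        assert np.allclose(arr.logr[sl], np.log2(3 / 2))

    def test_monosomy_logr_minus_one_and_nullisomy_floor(self, small_map):
        mother = simulate_founder(small_map, seed=3)
        father = simulate_founder(small_map, seed=4)
        mg = simulate_meiosis(mother, small_map, parent_label="mat", nullisomic_chroms=["3"], seed=5)
        pg = simulate_meiosis(father, small_map, parent_label="pat", nullisomic_chroms=["2"], seed=6)
        emb = assemble_embryo(mg, pg, n_cells=1, snp_map=small_map)
        arr = render_array(emb, small_map, noise=NoiseConfig.none(), seed=0)
        assert np.allclose(arr.logr[small_map.chrom_slice("3")], -1.0)
        # chromosome 2 has one copy; make a nullisomy by dropping both
        mg2 = simulate_meiosis(mother, small_map, parent_label="mat", nullisomic_chroms=["2"], seed=7)
        emb2 = assemble_embryo(mg2, pg, n_cells=1, snp_map=small_map)
        arr2 = render_array(emb2, small_map, noise=NoiseConfig.none(), seed=0)
        sl2 = small_map.chrom_slice("2")
        assert np.allclose(arr2.logr[sl2], LOGR_FLOOR)
        assert np.all(arr2.gtype[sl2] == GT_NC)

    def test_biopsy_baf_is_allele_weighted_mean_of_cells(self, small_map):
        mg, pg = _gametes(small_map)
        plan = [{"kind": "gain", "chrom": "1", "parent": "mat", "copy_index": 0, "cells": [1]}]
        emb = assemble_embryo(mg, pg, mitotic_event_plan=plan, n_cells=2, snp_map=small_map)
        pooled = render_array(emb, small_map, cells=[0, 1], noise=NoiseConfig.none(), seed=0)
        per_cell = [
            render_array(emb, small_map, cells=[i], noise=NoiseConfig.none(), seed=0)
            for i in range(2)
        ]
        counts = [emb.cell_copy_counts(i) for i in range(2)]
        tot = [c[0] + c[1] for c in counts]
        expect = (per_cell[0].baf * tot[0] + per_cell[1].baf * tot[1]) / (tot[0] + tot[1])
        ok = np.isfinite(expect)
        assert np.allclose(pooled.baf[ok], expect[ok])

    def test_deterministic_rendering(self, small_map):
        mg, pg = _gametes(small_map)
        emb = assemble_embryo(mg, pg, n_cells=3, snp_map=small_map)
        a = render_array(emb, small_map, noise=NoiseConfig(), seed=42)
        b = render_array(emb, small_map, noise=NoiseConfig(), seed=42)
        assert np.array_equal(a.gtype, b.gtype)
        assert np.allclose(a.baf, b.baf, equal_nan=True)
        assert np.allclose(a.logr, b.logr)

    def test_noise_config_validation(self):
        with pytest.raises(ValueError):
            NoiseConfig(ado_rate=1.5)
        with pytest.raises(ValueError):
            NoiseConfig(baf_sd=-0.1)
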