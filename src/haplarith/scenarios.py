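"""Ready-made simulation scenarios with exact ground truth.

`simulate_family` builds one mare/stallion pedigree (with paternal
grandparents and a euploid sibling blastocyst for phasing) and
`default_scenarios` defines a 20-embryo panel spanning the error spectrum
seen in preimplantation embryos: euploidy, meiotic whole-chromosome losses
and gains (meiosis-I and meiosis-II type), mitotic mosaic aneuploidy, and
digynic triploidy of meiotic (two distinct maternal genomes) and mitotic
(one duplicated maternal genotype) origin.  Each embryo is rendered as a
10-cell trophectoderm biopsy under the default single-cell WGA noise
model.  Expected chromosome states, genome labels and sexes come from the
simulation truth, never from the analysis under test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cnv import state_label
from .sample import SampleArray
from .simulate import (
    EmbryoTruth,
    Gamete,
    NoiseConfig,
    RecombConfig,
    TruthHaplotypes,
    assemble_embryo,
    render_array,
    simulate_child,
    simulate_founder,
    simulate_meiosis,
)
from .snp_map import SnpMap, build_snp_map


def _sub_seed(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class Family:
    snp_map: SnpMap
    grandsire: TruthHaplotypes
    granddam: TruthHaplotypes
    father: TruthHaplotypes
    mother: TruthHaplotypes
    sibling: EmbryoTruth
    samples: dict[str, SampleArray]  # bulk parents/grandparents + sibling


def simulate_family(
    snp_map: SnpMap,
    seed: int = 0,
    sibling_cells: int = 20,
    bulk_noise: NoiseConfig | None = None,
    sibling_noise: NoiseConfig | None = None,
) -> Family:
    """One pedigree: grandsire + granddam -> father; founder mother; plus a
    euploid male sibling blastocyst usable for phasing."""
    ss = np.random.SeedSequence(seed)
    s = ss.spawn(10)
    grandsire = simulate_founder(snp_map, seed=_sub_seed(s[0]), individual_id="grandsire", sex="male")
    granddam = simulate_founder(snp_map, seed=_sub_seed(s[1]), individual_id="granddam", sex="female")
    father = simulate_child(
        grandsire, granddam, snp_map, seed=_sub_seed(s[2]), individual_id="father", sex="male"
    )
    mother = simulate_founder(snp_map, seed=_sub_seed(s[3]), individual_id="mother", sex="female")

    mat_g = simulate_meiosis(mother, snp_map, parent_label="mat", seed=_sub_seed(s[4]))
    pat_g = simulate_meiosis(
        father, snp_map, parent_label="pat", drop_chroms=("X",), seed=_sub_seed(s[5])
    )
    sibling = assemble_embryo(
        mat_g, pat_g, n_cells=sibling_cells, snp_map=snp_map, embryo_id="sibling"
    )
    bulk = bulk_noise if bulk_noise is not None else NoiseConfig.bulk()
    sib_noise = sibling_noise if sibling_noise is not None else NoiseConfig()
    samples = {
        "mother": render_array(mother, snp_map, noise=bulk, sample_id="mother", role="mother", seed=_sub_seed(s[6])),
        "father": render_array(father, snp_map, noise=bulk, sample_id="father", role="father", seed=_sub_seed(s[7])),
        "grandsire": render_array(grandsire, snp_map, noise=bulk, sample_id="grandsire", role="grandsire", seed=_sub_seed(s[8])),
        "granddam": render_array(granddam, snp_map, noise=bulk, sample_id="granddam", role="granddam", seed=_sub_seed(s[9])),
        "sibling": render_array(
            sibling, snp_map, noise=sib_noise, sample_id="sibling", role="blastocyst", seed=_sub_seed(ss.spawn(1)[0])
        ),
    }
    return Family(snp_map, grandsire, granddam, father, mother, sibling, samples)


# ---------------------------------------------------------------------------
# scenario definitions
# ---------------------------------------------------------------------------
@dataclass
class Scenario:
    """One embryo's condition: meiotic errors enter through the gametes,
    mitotic errors through the event plan applied to cell subsets."""

    name: str
    sex: str = "female"  # intended zygotic sex (X transmission)
    mat_nondisjunction: tuple[str, tuple[str, ...]] | None = None  # (MI|MII, chroms)
    pat_nondisjunction: tuple[str, tuple[str, ...]] | None = None
    mat_nullisomic: tuple[str, ...] = ()
    pat_nullisomic: tuple[str, ...] = ()
    genome_wide_mat_mi: bool = False  # digynic triploidy, meiotic
    maternal_duplication_all_cells: bool = False  # digynic triploidy, mitotic
    mitotic_events: tuple[dict, ...] = ()
    n_cells: int = 20
    biopsy_cells: tuple[int, ...] = tuple(range(10))
    expected_ploidy: str = "biparental_diploid"

    @property
    def expected_sex(self) -> str:
        if self.genome_wide_mat_mi or self.maternal_duplication_all_cells:
            return "undetermined"
        return self.sex


def default_scenarios() -> list[Scenario]:
    """The 20-embryo default panel (chromosome picks echo the error spectrum
    reported for in vitro equine embryos: losses of small chromosomes such
    as 28 and 31, trisomies, reciprocal mitotic events, digynic triploidy)."""
    half = tuple(range(5))  # cells 0-4 of 20; 5 of the 10 biopsied cells
    twofifth = tuple(range(4))
    return [
        Scenario("euploid_f1", sex="female"),
        Scenario("euploid_m1", sex="male"),
        Scenario("euploid_f2", sex="female"),
        Scenario("euploid_m2", sex="male"),
        Scenario("euploid_f3", sex="female"),
        Scenario("euploid_m3", sex="male"),
        Scenario("euploid_f4", sex="female"),
        Scenario("euploid_m4", sex="male"),
        Scenario("mat_monosomy_31", sex="female", mat_nullisomic=("31",)),
        Scenario("mat_monosomy_28", sex="male", mat_nullisomic=("28",)),
        Scenario("pat_monosomy_12", sex="female", pat_nullisomic=("12",)),
        Scenario("mat_trisomy_MI_9", sex="male", mat_nondisjunction=("MI", ("9",))),
        Scenario("mat_trisomy_MII_17", sex="female", mat_nondisjunction=("MII", ("17",))),
        Scenario("pat_trisomy_MI_4", sex="female", pat_nondisjunction=("MI", ("4",))),
        Scenario(
            "mosaic_pat_loss_13", sex="male",
            mitotic_events=(
                {"kind": "loss", "chrom": "13", "parent": "pat", "copy_index": 0, "cells": list(half)},
            ),
        ),
        Scenario(
            "mosaic_mat_gain_7", sex="female",
            mitotic_events=(
                {"kind": "gain", "chrom": "7", "parent": "mat", "copy_index": 0, "cells": list(twofifth)},
            ),
        ),
        Scenario(
            "digynic_meiotic_1", sex="female", genome_wide_mat_mi=True,
            expected_ploidy="digynic_triploid_meiotic",
        ),
        Scenario(
            "digynic_meiotic_2", sex="male", genome_wide_mat_mi=True,
            expected_ploidy="digynic_triploid_meiotic",
        ),
        Scenario(
            "digynic_mitotic_1", sex="female", maternal_duplication_all_cells=True,
            expected_ploidy="digynic_triploid_mitotic",
        ),
        Scenario(
            "digynic_mitotic_2", sex="male", maternal_duplication_all_cells=True,
            expected_ploidy="digynic_triploid_mitotic",
        ),
    ]


@dataclass
class SimulatedEmbryo:
    scenario: Scenario
    truth: EmbryoTruth
    sample: SampleArray  # rendered biopsy
    expected_states: dict[str, dict] = field(default_factory=dict)


def truth_chromosome_states(
    truth: EmbryoTruth, cells: list[int] | tuple[int, ...]
) -> dict[str, dict]:
    """Per-chromosome expected state over the sampled cells.

    Uniform cells give ``{'kind': 'uniform', 'label': ...}``; heterogeneous
    cells give a mosaic record with the minority (aberrant) label and its
    cell fraction among the sampled cells."""
    per_cell = [truth.chrom_modal_counts(c) for c in cells]
    out: dict[str, dict] = {}
    for chrom in truth.snp_map.chroms:
        counts = [pc[chrom] for pc in per_cell]
        uniq = sorted(set(counts))
        if len(uniq) == 1:
            m, p = uniq[0]
            out[chrom] = {"kind": "uniform", "m": m, "p": p, "label": state_label(m, p)}
        else:
            tallies = {u: counts.count(u) for u in uniq}
            # call the non-disomic (or minority) pattern the aberration
            aberrant = min(
                tallies,
                key=lambda u: (u == (1, 1), tallies[u]),
            )
            out[chrom] = {
                "kind": "mosaic",
                "label": state_label(*aberrant),
                "cell_fraction": tallies[aberrant] / len(counts),
            }
    return out


def simulate_scenario_embryo(
    family: Family,
    scenario: Scenario,
    seed: int,
    noise: NoiseConfig | None = None,
    recomb: RecombConfig | None = None,
) -> SimulatedEmbryo:
    """Instantiate one scenario as an embryo plus its rendered biopsy."""
    ss = np.random.SeedSequence(seed)
    s = ss.spawn(4)
    snp_map = family.snp_map

    mat_kwargs: dict = {}
    if scenario.genome_wide_mat_mi:
        mat_kwargs = {"nondisjunction": "MI"}
    elif scenario.mat_nondisjunction is not None:
        nd, chroms = scenario.mat_nondisjunction
        mat_kwargs = {"nondisjunction": nd, "nd_chroms": chroms}
    mat_g = simulate_meiosis(
        family.mother, snp_map, recomb, parent_label="mat",
        nullisomic_chroms=scenario.mat_nullisomic, seed=_sub_seed(s[0]), **mat_kwargs,
    )
    pat_kwargs: dict = {}
    if scenario.pat_nondisjunction is not None:
        nd, chroms = scenario.pat_nondisjunction
        pat_kwargs = {"nondisjunction": nd, "nd_chroms": chroms}
    drop = ("X",) if scenario.sex == "male" else ()
    pat_g = simulate_meiosis(
        family.father, snp_map, recomb, parent_label="pat",
        nullisomic_chroms=scenario.pat_nullisomic, drop_chroms=drop,
        seed=_sub_seed(s[1]), **pat_kwargs,
    )

    events = list(scenario.mitotic_events)
    if scenario.maternal_duplication_all_cells:
        events.append(
            {"kind": "genome_duplication", "parent": "mat", "cells": list(range(scenario.n_cells))}
        )
    truth = assemble_embryo(
        mat_g, pat_g, mitotic_event_plan=events, n_cells=scenario.n_cells,
        seed=_sub_seed(s[2]), embryo_id=scenario.name, snp_map=snp_map,
    )
    sample = render_array(
        truth, snp_map, cells=list(scenario.biopsy_cells),
        noise=noise if noise is not None else NoiseConfig(),
        sample_id=scenario.name, role="biopsy", seed=_sub_seed(s[3]),
    )
    expected = truth_chromosome_states(truth, list(scenario.biopsy_cells))
    return SimulatedEmbryo(scenario, truth, sample, expected)


def simulate_suite(
    seed: int = 0,
    n_snps: int = 70_000,
    scenarios: list[Scenario] | None = None,
    snp_map: SnpMap | None = None,
    noise: NoiseConfig | None = None,
) -> tuple[Family, list[SimulatedEmbryo]]:
    """Build a family and render the scenario panel against it."""
    ss = np.random.SeedSequence(seed)
    s_map, s_fam, s_emb = ss.spawn(3)
    if snp_map is None:
        snp_map = build_snp_map(n_snps=n_snps, seed=_sub_seed(s_map))
    family = simulate_family(snp_map, seed=_sub_seed(s_fam))
    scenarios = scenarios if scenarios is not None else default_scenarios()
    embryos = [
        simulate_scenario_embryo(family, sc, seed=_sub_seed(child), noise=noise)
        for sc, child in zip(scenarios, s_emb.spawn(len(scenarios)))
    ]
    return family, embryos


# ---------------------------------------------------------------------------
# locus-level truth
# ---------------------------------------------------------------------------
def true_locus_haplotype(
    truth: EmbryoTruth,
    sibling: EmbryoTruth,
    parent_key: str,
    chrom: str,
    start_bp: int,
    end_bp: int,
) -> str:
    """Ground-truth inherited homologue at a locus, relative to the
    sibling-anchored phase (H1 = the sibling's transmitted strand).

    Returns 'H1'/'H2' when the embryo transmitted strand agrees/disagrees
    with the sibling's homologue of origin across the locus, 'recombinant'
    when a crossover falls inside it, and 'ambiguous' when the embryo does
    not carry exactly one copy of the parent's chromosome."""
    gam = truth.maternal_gamete if parent_key == "mat" else truth.paternal_gamete
    sib_gam = sibling.maternal_gamete if parent_key == "mat" else sibling.paternal_gamete
    strands = gam.strands.get(chrom, [])
    sib_strands = sib_gam.strands.get(chrom, [])
    if len(strands) != 1 or len(sib_strands) != 1:
        return "ambiguous"
    snp_map = truth.snp_map
    sl = snp_map.chrom_slice(chrom)
    pos = snp_map.pos_bp[sl]
    sel = (pos >= start_bp) & (pos <= end_bp)
    if not sel.any():
        mid = (start_bp + end_bp) // 2
        sel = np.zeros(len(pos), dtype=bool)
        sel[int(np.argmin(np.abs(pos - mid)))] = True
    agree = strands[0].origin[sel] == sib_strands[0].origin[sel]
    if agree.all():
        return "H1"
    if not agree.any():
        return "H2"
    return "recombinant"
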