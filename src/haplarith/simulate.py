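"""Synthetic embryo SNP-array simulator with known ground truth.

The simulator produces everything the analysis consumes — pedigree
genotypes, embryo biopsies, single blastomeres — from first principles:

* founder haplotypes drawn from per-SNP population B-allele frequencies;
* meiosis with Poisson crossovers (no interference) and optional
  nondisjunction, either meiosis-I type (both parental homologues
  transmitted, producing genome- or chromosome-wide heterodisomy) or
  meiosis-II type (one recombined homologue duplicated, isodisomy);
* multi-cell embryos in which meiotic events are shared by every cell and
  mitotic events (whole or segmental gains/losses, genome duplication)
  affect configured cell subsets;
* an array measurement model: pooled allele counts over the sampled cells
  after per-allele whole-genome-amplification dropout give the ideal BAF
  (``#B / #total``), the mean copy number gives the ideal LogR
  (``log2(copies / 2)``), and Gaussian dispersion, genotype miscalls and
  missing calls are layered on top.

Because every transmitted chromosome strand records its homologue of
origin per SNP, phase, haplotype-block and copy-number truth are exact and
available to the tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .karyotype import MBP
from .sample import GT_AA, GT_AB, GT_BB, GT_NC, SampleArray
from .snp_map import SnpMap

#: LogR assigned to regions with zero copies (log2 of 0 is undefined).
LOGR_FLOOR: float = -5.0


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class NoiseConfig:
    """WGA/array noise model for one rendered sample.

    ``ado_rate`` is the per-cell, per-SNP, per-allele dropout probability;
    pooling several biopsied cells dilutes its effect on the pooled BAF,
    which is why multi-cell samples show far lower Mendelian inconsistency
    than single blastomeres.
    """

    ado_rate: float = 0.2
    miscall_rate: float = 0.005
    missing_rate: float = 0.05
    baf_sd: float = 0.05
    logr_sd: float = 0.15
    call_thresholds: tuple[float, float] = (0.15, 0.85)

    def __post_init__(self) -> None:
        for name in ("ado_rate", "miscall_rate", "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.baf_sd < 0 or self.logr_sd < 0:
            raise ValueError("dispersion parameters must be non-negative")

    @classmethod
    def none(cls) -> "NoiseConfig":
        """Noise-free rendering (exact ideal values, all SNPs called)."""
        return cls(0.0, 0.0, 0.0, 0.0, 0.0)

    @classmethod
    def bulk(cls) -> "NoiseConfig":
        """Near-noiseless bulk DNA (parents/grandparents): no ADO, tiny dispersion."""
        return cls(0.0, 0.001, 0.002, 0.01, 0.03)


@dataclass(frozen=True)
class RecombConfig:
    """Crossover model: Poisson count at ``rate_per_mbp`` per Mbp, uniform positions."""

    rate_per_mbp: float = 0.01  # 1 crossover per 100 Mbp
    forced_crossovers: dict[str, list[int]] | None = None  # chrom -> positions

    def expected_count(self, length_bp: int) -> float:
        return self.rate_per_mbp * length_bp / MBP


# ---------------------------------------------------------------------------
# truth containers
# ---------------------------------------------------------------------------
@dataclass
class TruthHaplotypes:
    """Ground-truth phased genotypes of one individual (0 = A, 1 = B)."""

    individual_id: str
    h1: np.ndarray
    h2: np.ndarray
    sex: str = "female"

    def __post_init__(self) -> None:
        self.h1 = np.asarray(self.h1, dtype=np.uint8)
        self.h2 = np.asarray(self.h2, dtype=np.uint8)
        if self.h1.shape != self.h2.shape:
            raise ValueError("h1/h2 shape mismatch")

    def genotype_codes(self) -> np.ndarray:
        return (self.h1 + self.h2).astype(np.int8)


@dataclass
class Strand:
    """One transmitted chromosome copy.

    ``origin`` gives, per SNP of the chromosome, the parental homologue the
    allele came from (0 = homologue 1, 1 = homologue 2); ``crossovers`` are
    the bp positions where the origin switches.
    """

    chrom: str
    parent: str  # 'mat' | 'pat'
    alleles: np.ndarray
    origin: np.ndarray
    crossovers: list[int] = field(default_factory=list)


@dataclass
class CellCopy:
    """A chromosome copy inside one cell; ``present`` masks segmental losses."""

    chrom: str
    parent: str
    alleles: np.ndarray
    origin: np.ndarray
    present: np.ndarray | None = None  # None = fully present

    def presence(self, n: int) -> np.ndarray:
        if self.present is None:
            return np.ones(n, dtype=bool)
        return self.present


@dataclass
class Gamete:
    """Strands transmitted by one meiosis, keyed by chromosome."""

    parent: str  # 'mat' | 'pat'
    strands: dict[str, list[Strand]]
    meta: dict = field(default_factory=dict)


@dataclass
class EmbryoTruth:
    """A multi-cell embryo with per-cell karyotypes and an event log."""

    embryo_id: str
    snp_map: SnpMap
    cells: list[dict[str, list[CellCopy]]]
    maternal_gamete: Gamete
    paternal_gamete: Gamete
    event_log: list[dict] = field(default_factory=list)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def cell_copy_counts(self, cell_idx: int) -> tuple[np.ndarray, np.ndarray]:
        """Per-SNP (maternal, paternal) copy counts for one cell."""
        n = len(self.snp_map)
        mat = np.zeros(n, dtype=np.int16)
        pat = np.zeros(n, dtype=np.int16)
        for chrom, copies in self.cells[cell_idx].items():
            sl = self.snp_map.chrom_slice(chrom)
            m = sl.stop - sl.start
            for cp in copies:
                tgt = mat if cp.parent == "mat" else pat
                tgt[sl] += cp.presence(m)
        return mat, pat

    def chrom_modal_counts(self, cell_idx: int) -> dict[str, tuple[int, int]]:
        """Modal (maternal, paternal) copy number per chromosome for one cell."""
        mat, pat = self.cell_copy_counts(cell_idx)
        out = {}
        for chrom in self.snp_map.chroms:
            sl = self.snp_map.chrom_slice(chrom)
            m = int(np.bincount(mat[sl]).argmax())
            p = int(np.bincount(pat[sl]).argmax())
            out[chrom] = (m, p)
        return out

    def true_sex(self) -> str:
        """Sex implied by the zygotic X constitution (1 mat X = male,
        1 mat + 1 pat X = female, anything else undetermined)."""
        counts = self.chrom_modal_counts(0).get("X", (0, 0))
        if counts == (1, 0):
            return "male"
        if counts == (1, 1):
            return "female"
        return "undetermined"


# ---------------------------------------------------------------------------
# founders and meiosis
# ---------------------------------------------------------------------------
def simulate_founder(
    snp_map: SnpMap,
    maf_spec=None,
    seed: int = 0,
    individual_id: str = "founder",
    sex: str = "female",
) -> TruthHaplotypes:
    """Draw founder haplotypes; each haplotype allele is B with the SNP's
    population B frequency (``maf_spec``: scalar, per-SNP array, or None to
    use the map's ``b_freq`` column).

    Males are hemizygous for X; the array has no Y probes, so a male founder
    is represented with its single X haplotype duplicated (rendering as
    homozygous X genotypes, which is what a clustered array export shows).
    """
    rng = np.random.default_rng(seed)
    if maf_spec is None:
        freq = snp_map.df["b_freq"].to_numpy()
    else:
        freq = np.broadcast_to(np.asarray(maf_spec, dtype=float), (len(snp_map),))
    if np.any((freq < 0) | (freq > 1)):
        raise ValueError("B-allele frequencies must lie in [0, 1]")
    h1 = (rng.random(len(snp_map)) < freq).astype(np.uint8)
    h2 = (rng.random(len(snp_map)) < freq).astype(np.uint8)
    if sex == "male" and "X" in snp_map.chroms:
        sl = snp_map.chrom_slice("X")
        h2[sl] = h1[sl]
    return TruthHaplotypes(individual_id, h1, h2, sex=sex)


def _recombined_origin(
    pos: np.ndarray, crossovers: list[int], start: int
) -> np.ndarray:
    """Homologue-of-origin per SNP for a strand starting on ``start`` and
    switching at each crossover position."""
    if not crossovers:
        return np.full(len(pos), start, dtype=np.uint8)
    switches = np.searchsorted(np.asarray(sorted(crossovers)), pos, side="left")
    return ((start + switches) % 2).astype(np.uint8)


def simulate_meiosis(
    parent: TruthHaplotypes,
    snp_map: SnpMap,
    recomb: RecombConfig | None = None,
    nondisjunction: str = "none",
    nd_chroms=None,
    nullisomic_chroms=(),
    drop_chroms=(),
    parent_label: str = "mat",
    seed: int = 0,
) -> Gamete:
    """Simulate one meiosis, returning the transmitted strand(s) per chromosome.

    ``nondisjunction`` is ``'none'``, ``'MI'`` (both homologues transmitted,
    each independently recombined) or ``'MII'`` (one recombined strand
    duplicated); it applies to ``nd_chroms`` (default: every chromosome).
    ``nullisomic_chroms`` are omitted from the gamete entirely, and
    ``drop_chroms`` removes chromosomes for reasons other than error (e.g.
    a paternal gamete not transmitting X yields a male embryo).
    """
    if nondisjunction not in ("none", "MI", "MII"):
        raise ValueError(f"invalid nondisjunction label {nondisjunction!r}")
    recomb = recomb or RecombConfig()
    rng = np.random.default_rng(seed)
    nd_set = set(snp_map.chroms) if nd_chroms is None else {str(c) for c in nd_chroms}
    null_set = {str(c) for c in nullisomic_chroms}
    drop_set = {str(c) for c in drop_chroms}

    strands: dict[str, list[Strand]] = {}
    meta_events: list[dict] = []
    for chrom in snp_map.chroms:
        if chrom in drop_set:
            continue
        sl = snp_map.chrom_slice(chrom)
        pos = snp_map.pos_bp[sl]
        h = np.stack([parent.h1[sl], parent.h2[sl]])
        length = snp_map.karyotype.length(chrom)

        def draw_xo() -> list[int]:
            if recomb.forced_crossovers is not None:
                return sorted(recomb.forced_crossovers.get(chrom, []))
            k = rng.poisson(recomb.expected_count(length))
            return sorted(int(x) for x in rng.integers(1, length + 1, size=k))

        def make_strand(start: int) -> Strand:
            xo = draw_xo()
            origin = _recombined_origin(pos, xo, start)
            return Strand(chrom, parent_label, h[origin, np.arange(len(pos))], origin, xo)

        if chrom in null_set:
            strands[chrom] = []
            meta_events.append({"kind": "nullisomic_gamete", "chrom": chrom})
            continue
        if nondisjunction != "none" and chrom in nd_set:
            if nondisjunction == "MI":
                strands[chrom] = [make_strand(0), make_strand(1)]
            else:  # MII: duplicate one recombined strand
                s = make_strand(int(rng.integers(2)))
                dup = Strand(chrom, parent_label, s.alleles.copy(), s.origin.copy(), list(s.crossovers))
                strands[chrom] = [s, dup]
            meta_events.append({"kind": f"nondisjunction_{nondisjunction}", "chrom": chrom})
        else:
            strands[chrom] = [make_strand(int(rng.integers(2)))]
    return Gamete(parent_label, strands, {"events": meta_events, "parent_id": parent.individual_id})


def simulate_child(
    sire: TruthHaplotypes,
    dam: TruthHaplotypes,
    snp_map: SnpMap,
    recomb: RecombConfig | None = None,
    seed: int = 0,
    individual_id: str = "child",
    sex: str = "male",
) -> TruthHaplotypes:
    """A (non-embryo) offspring individual: homologue 1 is the sire-derived
    strand, homologue 2 the dam-derived strand — the anchoring convention
    grandparent-based phasing recovers."""
    g_sire = simulate_meiosis(sire, snp_map, recomb, parent_label="pat", seed=seed)
    g_dam = simulate_meiosis(dam, snp_map, recomb, parent_label="mat", seed=seed + 1)
    h1 = np.empty(len(snp_map), dtype=np.uint8)
    h2 = np.empty(len(snp_map), dtype=np.uint8)
    for chrom in snp_map.chroms:
        sl = snp_map.chrom_slice(chrom)
        h1[sl] = g_sire.strands[chrom][0].alleles
        h2[sl] = g_dam.strands[chrom][0].alleles
    if sex == "male" and "X" in snp_map.chroms:
        # a son carries only the dam's X; render hemizygous as duplicated
        sl = snp_map.chrom_slice("X")
        h1[sl] = h2[sl]
    return TruthHaplotypes(individual_id, h1, h2, sex=sex)


# ---------------------------------------------------------------------------
# embryo assembly
# ---------------------------------------------------------------------------
def assemble_embryo(
    maternal_gamete: Gamete,
    paternal_gamete: Gamete,
    mitotic_event_plan=(),
    n_cells: int = 1,
    seed: int = 0,
    embryo_id: str = "embryo",
    snp_map: SnpMap | None = None,
) -> EmbryoTruth:
    """Combine gametes into a zygote and grow ``n_cells`` cells, applying
    mitotic events to their configured cell subsets.

    Events are dicts with keys ``kind`` (``gain``, ``loss`` or
    ``genome_duplication``), ``cells`` (indices), and for gain/loss
    ``chrom``, ``parent``, ``copy_index`` (index among that parent's zygotic
    copies of the chromosome) plus optional ``start_bp``/``end_bp`` for
    segmental events.  ``genome_duplication`` takes ``parent`` in
    ``{'mat', 'pat', 'both'}``.  Meiotic events arrive through the gametes
    and are therefore shared by every cell; mitotic events must name a
    strict subset of cells.
    """
    if snp_map is None:
        raise ValueError("snp_map is required")
    if n_cells < 1:
        raise ValueError("an embryo needs at least one cell")

    zygote: dict[str, list[CellCopy]] = {}
    for chrom in snp_map.chroms:
        copies = []
        for gam in (maternal_gamete, paternal_gamete):
            for s in gam.strands.get(chrom, []):
                copies.append(CellCopy(chrom, s.parent, s.alleles, s.origin, None))
        zygote[chrom] = copies

    cells = [
        {c: [replace(cp) for cp in lst] for c, lst in zygote.items()}
        for _ in range(n_cells)
    ]

    event_log: list[dict] = []
    for gam in (maternal_gamete, paternal_gamete):
        for ev in gam.meta.get("events", []):
            event_log.append({**ev, "origin": "meiotic", "parent": gam.parent})

    for ev in mitotic_event_plan:
        kind = ev["kind"]
        targets = list(ev["cells"])
        if any(t < 0 or t >= n_cells for t in targets):
            raise ValueError(f"event cells {targets} outside 0..{n_cells - 1}")
        if kind == "genome_duplication":
            which = ev.get("parent", "both")
            for t in targets:
                for chrom, lst in cells[t].items():
                    extra = [
                        replace(cp, present=None if cp.present is None else cp.present.copy())
                        for cp in lst
                        if which in ("both", cp.parent)
                    ]
                    lst.extend(extra)
        elif kind in ("gain", "loss"):
            chrom = str(ev["chrom"])
            parent = ev["parent"]
            idx = ev.get("copy_index", 0)
            sl = snp_map.chrom_slice(chrom)
            pos = snp_map.pos_bp[sl]
            m = len(pos)
            start = ev.get("start_bp")
            end = ev.get("end_bp")
            segmental = start is not None or end is not None
            lo = 0 if start is None else start
            hi = snp_map.karyotype.length(chrom) if end is None else end
            in_iv = (pos >= lo) & (pos <= hi)
            for t in targets:
                mine = [cp for cp in cells[t][chrom] if cp.parent == parent]
                if idx >= len(mine):
                    raise ValueError(
                        f"cell {t}: no {parent} copy #{idx} of chromosome {chrom}"
                    )
                cp = mine[idx]
                if kind == "loss":
                    if segmental:
                        pres = cp.presence(m).copy()
                        pres[in_iv] = False
                        cp.present = pres
                    else:
                        cells[t][chrom].remove(cp)
                else:  # gain
                    pres = cp.presence(m).copy()
                    if segmental:
                        pres &= in_iv
                    cells[t][chrom].append(
                        CellCopy(chrom, parent, cp.alleles, cp.origin, pres)
                    )
        else:
            raise ValueError(f"unknown mitotic event kind {kind!r}")
        event_log.append({**ev, "origin": "mitotic"})

    return EmbryoTruth(embryo_id, snp_map, cells, maternal_gamete, paternal_gamete, event_log)


# ---------------------------------------------------------------------------
# array rendering
# ---------------------------------------------------------------------------
def _measure(
    nB: np.ndarray,
    n_total: np.ndarray,
    mean_copies: np.ndarray,
    noise: NoiseConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Shared measurement model: ideal BAF/LogR from pooled counts, then
    dispersion, genotype thresholds, miscalls and missing calls."""
    n = len(nB)
    with np.errstate(divide="ignore", invalid="ignore"):
        baf_ideal = np.where(n_total > 0, nB / np.maximum(n_total, 1), np.nan)
        logr_ideal = np.where(
            mean_copies > 0, np.log2(np.maximum(mean_copies, 1e-12) / 2.0), LOGR_FLOOR
        )

    baf = baf_ideal.copy()
    if noise.baf_sd > 0:
        baf = np.clip(baf + rng.normal(0.0, noise.baf_sd, n), 0.0, 1.0)
    logr = logr_ideal.copy()
    if noise.logr_sd > 0:
        logr = logr + rng.normal(0.0, noise.logr_sd, n)

    lo, hi = noise.call_thresholds
    gtype = np.full(n, GT_AB, dtype=np.int8)
    gtype[baf_ideal <= lo] = GT_AA
    gtype[baf_ideal >= hi] = GT_BB
    gtype[n_total == 0] = GT_NC

    if noise.miscall_rate > 0:
        flip = (rng.random(n) < noise.miscall_rate) & (gtype != GT_NC)
        shift = rng.integers(1, 3, size=n)
        gtype[flip] = ((gtype[flip] + shift[flip]) % 3).astype(np.int8)
    if noise.missing_rate > 0:
        gtype[rng.random(n) < noise.missing_rate] = GT_NC
    return gtype, baf, logr


def render_array(
    truth: EmbryoTruth | TruthHaplotypes,
    snp_map: SnpMap,
    cells=None,
    noise: NoiseConfig | None = None,
    sample_id: str = "sample",
    role: str = "biopsy",
    seed: int = 0,
) -> SampleArray:
    """Render an array measurement of the sampled cells.

    For an :class:`EmbryoTruth`, ``cells`` lists the biopsied cell indices
    (default: all cells).  Each allele of each copy survives WGA with
    probability ``1 - ado_rate`` independently per cell; the pooled
    surviving counts give the ideal BAF and genotype composition, while the
    ideal LogR reflects the true mean copy number of the sampled cells.
    A :class:`TruthHaplotypes` is rendered as bulk DNA (one diploid cell,
    no ADO; pass ``noise=NoiseConfig.bulk()`` or ``.none()``).
    """
    rng = np.random.default_rng(seed)
    n = len(snp_map)

    if isinstance(truth, TruthHaplotypes):
        noise = noise if noise is not None else NoiseConfig.bulk()
        nB = (truth.h1.astype(np.int32) + truth.h2).astype(np.float64)
        n_total = np.full(n, 2.0)
        mean_copies = np.full(n, 2.0)
    else:
        noise = noise if noise is not None else NoiseConfig()
        if cells is None:
            cells = list(range(truth.n_cells))
        if len(cells) == 0:
            raise ValueError("cells must be non-empty")
        nB = np.zeros(n)
        n_total = np.zeros(n)
        copies_sum = np.zeros(n)
        for ci in cells:
            for chrom, copylist in truth.cells[ci].items():
                sl = truth.snp_map.chrom_slice(chrom)
                m = sl.stop - sl.start
                for cp in copylist:
                    pres = cp.presence(m)
                    if noise.ado_rate > 0:
                        keep = pres & (rng.random(m) >= noise.ado_rate)
                    else:
                        keep = pres
                    copies_sum[sl] += pres
                    n_total[sl] += keep
                    nB[sl] += keep & (cp.alleles == 1)
        mean_copies = copies_sum / len(cells)

    gtype, baf, logr = _measure(nB, n_total, mean_copies, noise, rng)
    return SampleArray(sample_id, role, gtype, baf, logr, meta={"n_cells": 0 if cells is None else len(cells or [])})
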