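"""Haplarithm construction: parent-specific BAF subtracks, segments, blocks.

At an *informative* SNP one parent is heterozygous (and phased) while the
other is homozygous, so the embryo's BAF reads out which parental
homologue(s) it inherited.  Folding the BAF towards the homozygous
parent's allele (``f = |BAF - b0|``, ``b0`` 0 for AA / 1 for BB) and
splitting SNPs into subtrack **P1** (the phased homologue-1 allele differs
from the other parent's allele) and **P2** (it matches) yields two
piecewise-constant tracks whose joint levels encode inheritance and copy
number: a disomic region shows (0.5, 0) when homologue 1 was transmitted
and (0, 0.5) for homologue 2, trisomic heterodisomy shows (1/3, 1/3), a
lost parental chromosome (0, 0), and so on.

Subtracks are segmented jointly per chromosome (shared breakpoints), since
inheritance switches and copy-number changes move both levels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import AnalysisConfig, DEFAULT_CONFIG
from .phasing import PhasedParents
from .sample import GT_AA, GT_AB, GT_BB, SampleArray
from .segmentation import auto_penalty, pelt_grouped, segment_means
from .snp_map import SnpMap

P1, P2 = 0, 1


@dataclass
class InformativeTrack:
    """Informative SNPs of one parent, in map order."""

    parent: str  # 'mat' | 'pat'
    idx: np.ndarray  # indices into the SnpMap
    pos_bp: np.ndarray
    chrom: np.ndarray
    subtrack: np.ndarray  # P1 / P2
    f: np.ndarray  # folded BAF in [0, 1]

    def __len__(self) -> int:
        return len(self.idx)

    def chrom_mask(self, chrom: str) -> np.ndarray:
        return self.chrom == chrom


@dataclass
class Segment:
    chrom: str
    start_bp: int
    end_bp: int
    p1_mean: float
    p2_mean: float
    n_p1: int
    n_p2: int
    start_i: int  # first informative-SNP index (within-chromosome track)
    stop_i: int
    low_support: bool = False

    @property
    def n_snps(self) -> int:
        return self.n_p1 + self.n_p2


@dataclass
class HaplotypeBlock:
    chrom: str
    start_bp: int
    end_bp: int
    parent: str
    inherited: str  # 'H1' | 'H2' | 'both' | 'none' | 'undetermined'
    n_support: int


@dataclass
class Breakpoint:
    """A homologue switch (H1 <-> H2), i.e. a detected recombination site."""

    chrom: str
    pos_bp: int
    parent: str


@dataclass
class HaplarithmProfile:
    tracks: dict[str, InformativeTrack]
    segments: dict[str, list[Segment]]
    blocks: list[HaplotypeBlock]
    breakpoints: list[Breakpoint]
    meta: dict = field(default_factory=dict)

    def blocks_for(self, parent: str, chrom: str | None = None) -> list[HaplotypeBlock]:
        out = [b for b in self.blocks if b.parent == parent]
        if chrom is not None:
            out = [b for b in out if b.chrom == chrom]
        return out

    def breakpoints_for(self, parent: str, chrom: str | None = None) -> list[Breakpoint]:
        out = [b for b in self.breakpoints if b.parent == parent]
        if chrom is not None:
            out = [b for b in out if b.chrom == chrom]
        return out


# ---------------------------------------------------------------------------
# informative SNP selection
# ---------------------------------------------------------------------------
def select_informative(
    phased: PhasedParents,
    mother: SampleArray,
    father: SampleArray,
    embryo: SampleArray,
    snp_map: SnpMap,
) -> dict[str, InformativeTrack]:
    """Build the maternal and paternal informative-SNP tracks.

    The embryo's discrete genotype is irrelevant here — a no-call with a
    present BAF still carries signal.  A parent without phase information
    yields an empty track.
    """
    tracks: dict[str, InformativeTrack] = {}
    baf_ok = np.isfinite(embryo.baf)
    for parent_key, target, other in (("mat", mother, father), ("pat", father, mother)):
        phase = phased.get("mother" if parent_key == "mat" else "father")
        if phase is None:
            tracks[parent_key] = InformativeTrack(
                parent_key,
                np.empty(0, dtype=int),
                np.empty(0, dtype=int),
                np.empty(0, dtype=object),
                np.empty(0, dtype=np.int8),
                np.empty(0),
            )
            continue
        other_hom_a = other.gtype == GT_AA
        other_hom_b = other.gtype == GT_BB
        sel = (
            (target.gtype == GT_AB)
            & phase.resolved
            & (other_hom_a | other_hom_b)
            & baf_ok
        )
        idx = np.flatnonzero(sel)
        other_allele = other_hom_b[idx].astype(np.int8)  # 0 if AA, 1 if BB
        b0 = other_allele.astype(float)
        f = np.abs(embryo.baf[idx] - b0)
        sub = np.where(phase.h1_allele[idx] != other_allele, P1, P2).astype(np.int8)
        tracks[parent_key] = InformativeTrack(
            parent_key,
            idx,
            snp_map.pos_bp[idx],
            snp_map.chrom_labels[idx],
            sub,
            f,
        )
    return tracks


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------
def segment_track(
    track: InformativeTrack,
    chrom: str,
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> list[Segment]:
    """Jointly segment the P1/P2 subtracks of one chromosome."""
    mask = track.chrom_mask(chrom)
    f = track.f[mask]
    sub = track.subtrack[mask]
    pos = track.pos_bp[mask]
    n = len(f)
    if n == 0:
        return []
    seg_cfg = config.segmentation
    if n < seg_cfg.min_seg_snps:
        rec = segment_means(f, sub, [], n_groups=2)[0]
        return [
            Segment(
                chrom, int(pos[0]), int(pos[-1]), rec["mean_0"], rec["mean_1"],
                rec["n_0"], rec["n_1"], 0, n, low_support=True,
            )
        ]
    penalty = auto_penalty(f, seg_cfg, groups=sub)
    cps = pelt_grouped(f, sub, penalty, min_size=seg_cfg.min_size)
    out = []
    for rec in segment_means(f, sub, cps, n_groups=2):
        lo, hi = rec["start_idx"], rec["stop_idx"]
        out.append(
            Segment(
                chrom, int(pos[lo]), int(pos[hi - 1]), rec["mean_0"], rec["mean_1"],
                rec["n_0"], rec["n_1"], lo, hi,
            )
        )
    return out


# ---------------------------------------------------------------------------
# haplotype blocks
# ---------------------------------------------------------------------------
def _inheritance_of(p1: float, p2: float, tol: float) -> str:
    """Map joint subtrack levels to the inherited homologue.

    Levels other than the disomic 0.5 occur legitimately (1 for the
    remaining homologue under monosomy of the other parent, 2/3 for an
    isodisomic trisomy, 1/3 under heterodisomy or mosaicism), so a
    homologue is deemed *present* whenever its subtrack clearly exceeds
    zero, and *both* when the two subtracks sit at comparable non-zero
    levels.
    """
    if not (np.isfinite(p1) and np.isfinite(p2)):
        return "undetermined"
    present_floor = max(2 * tol, 0.2)
    if p1 <= tol and p2 <= tol:
        return "none"
    if p2 <= tol and p1 >= present_floor:
        return "H1"
    if p1 <= tol and p2 >= present_floor:
        return "H2"
    if abs(p1 - p2) <= tol and min(p1, p2) >= present_floor:
        return "both"
    return "undetermined"


def call_blocks(
    segments: dict[str, list[Segment]],
    track: InformativeTrack,
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> tuple[list[HaplotypeBlock], list[Breakpoint]]:
    """Classify segments into haplotype blocks and derive recombination
    breakpoints (H1<->H2 transitions, placed midway between the flanking
    informative SNPs)."""
    blocks: list[HaplotypeBlock] = []
    breakpoints: list[Breakpoint] = []
    tol = config.block_tolerance
    for chrom, segs in segments.items():
        if not segs:
            continue
        mask = track.chrom_mask(chrom)
        pos = track.pos_bp[mask]
        calls = [_inheritance_of(s.p1_mean, s.p2_mean, tol) for s in segs]
        # sub-resolution none/undetermined/both slivers are crossover
        # transition windows (runs of informative SNPs whose signal-bearing
        # subtrack switches inside them, reading all-zero or all-equal);
        # absorb them into the neighbouring block
        min_support = config.segmentation.min_seg_snps
        for i, (s, c) in enumerate(zip(segs, calls)):
            if c in ("none", "undetermined", "both") and s.n_snps < min_support:
                if i > 0:
                    calls[i] = calls[i - 1]
                elif len(calls) > 1:
                    calls[i] = calls[i + 1]
        # merge adjacent same-call segments
        merged: list[tuple[str, int, int, int, int]] = []  # call, start_i, stop_i
        for s, c in zip(segs, calls):
            if merged and merged[-1][0] == c:
                prev = merged[-1]
                merged[-1] = (c, prev[1], s.stop_i, prev[3] + s.n_snps)
            else:
                merged.append((c, s.start_i, s.stop_i, s.n_snps))
        prev_call = None
        for c, lo, hi, n_sup in merged:
            start_bp = int(pos[lo])
            end_bp = int(pos[hi - 1])
            if blocks and blocks[-1].chrom == chrom:
                # extend boundaries to the midpoint between flanking SNPs
                mid = (blocks[-1].end_bp + start_bp) // 2
                if {prev_call, c} == {"H1", "H2"}:
                    breakpoints.append(Breakpoint(chrom, mid, track.parent))
                blocks[-1].end_bp = mid
                start_bp = mid + 1
            blocks.append(
                HaplotypeBlock(chrom, start_bp, end_bp, track.parent, c, n_sup)
            )
            prev_call = c
    return blocks, breakpoints


def build_haplarithm(
    phased: PhasedParents,
    mother: SampleArray,
    father: SampleArray,
    embryo: SampleArray,
    snp_map: SnpMap,
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> HaplarithmProfile:
    """Full haplarithm for one embryo sample: tracks, segments, blocks."""
    tracks = select_informative(phased, mother, father, embryo, snp_map)
    segments: dict[str, list[Segment]] = {}
    blocks: list[HaplotypeBlock] = []
    breakpoints: list[Breakpoint] = []
    for parent_key, track in tracks.items():
        segs = {}
        for chrom in snp_map.chroms:
            segs[chrom] = segment_track(track, chrom, config)
        segments[parent_key] = [s for chrom in snp_map.chroms for s in segs[chrom]]
        b, bp = call_blocks(segs, track, config)
        blocks.extend(b)
        breakpoints.extend(bp)
    return HaplarithmProfile(
        tracks,
        segments,
        blocks,
        breakpoints,
        meta={"n_informative": {k: len(t) for k, t in tracks.items()}},
    )
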