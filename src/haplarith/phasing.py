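"""Pedigree-based phasing of parental heterozygous SNPs.

Haplarithmisis needs each parent's heterozygous SNPs assigned to homologue
1 vs homologue 2.  Two deterministic Mendelian routes are supported:

* **grandparents** — at a parent-AB SNP the allele deducibly transmitted by
  the grandsire defines homologue 1 (resolvable when at least one
  grandparent is homozygous and the trio is Mendelian-consistent);
* **sibling embryo** — at SNPs where the parent is AB and the other parent
  homozygous, the allele the sibling inherited from the parent defines
  homologue 1, so homologue labels are relative to the sibling's
  (possibly recombinant) transmitted strand.

The anchoring convention is arbitrary but fixed, and is recorded in the
result so downstream haplotype-block labels are interpretable.  No
population/statistical phasing is attempted: unresolved SNPs are simply
non-informative downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .sample import GT_AA, GT_AB, GT_BB, GT_NC, SampleArray

UNRESOLVED: int = -1


@dataclass
class ParentPhase:
    """Homologue-1 allele (0=A, 1=B, -1 unresolved) at each map SNP; defined
    only where the parent's call is AB."""

    parent_id: str
    h1_allele: np.ndarray
    source: str  # 'grandparent' | 'sibling'
    n_inconsistent: int = 0

    @property
    def n_phased(self) -> int:
        return int(np.sum(self.h1_allele != UNRESOLVED))

    @property
    def resolved(self) -> np.ndarray:
        return self.h1_allele != UNRESOLVED


@dataclass
class PhasedParents:
    """Phase for one or both parents, keyed 'mother'/'father'."""

    mother: ParentPhase | None = None
    father: ParentPhase | None = None
    meta: dict = field(default_factory=dict)

    def get(self, which: str) -> ParentPhase | None:
        return getattr(self, which)


def phase_with_grandparents(
    parent: SampleArray, grandsire: SampleArray, granddam: SampleArray
) -> ParentPhase:
    """Phase one parent from its own parents' genotypes.

    At parent-AB SNPs the grandsire must have transmitted one of A/B and
    the granddam the other; an assignment ``grandsire->A`` is possible iff
    the grandsire can transmit A and the granddam can transmit B.  Exactly
    one possible assignment resolves the SNP (H1 := grandsire-derived
    allele); zero marks a Mendelian-impossible trio (counted, unresolved);
    two is ambiguous (unresolved).
    """
    n = len(parent)
    h1 = np.full(n, UNRESOLVED, dtype=np.int8)
    het = parent.gtype == GT_AB

    def can_transmit(g: np.ndarray, allele: int) -> np.ndarray:
        hom = GT_AA if allele == 0 else GT_BB
        return (g == hom) | (g == GT_AB) | (g == GT_NC)

    gs, gd = grandsire.gtype, granddam.gtype
    # grandsire transmits A (granddam must supply B), or vice versa
    opt_a = can_transmit(gs, 0) & can_transmit(gd, 1)
    opt_b = can_transmit(gs, 1) & can_transmit(gd, 0)

    h1[het & opt_a & ~opt_b] = 0
    h1[het & opt_b & ~opt_a] = 1
    impossible = het & ~opt_a & ~opt_b
    return ParentPhase(
        parent.sample_id, h1, "grandparent", n_inconsistent=int(impossible.sum())
    )


def phase_with_sibling(
    parent: SampleArray,
    other_parent: SampleArray,
    sibling: SampleArray,
    hemizygous_mask: np.ndarray | None = None,
) -> ParentPhase:
    """Phase one parent against a sibling embryo sample.

    Informative where the parent is AB, the other parent homozygous and the
    sibling called: the sibling allele not attributable to the other parent
    is what the parent transmitted, and defines homologue 1.  Sibling calls
    impossible under the parental pair are counted and left unresolved.

    ``hemizygous_mask`` marks SNPs (the X chromosome) where a male sibling
    carries a single maternal copy that the array renders as a homozygous
    call; there a sibling hom call directly names the transmitted maternal
    allele even when it contradicts the diploid expectation.
    """
    n = len(parent)
    h1 = np.full(n, UNRESOLVED, dtype=np.int8)
    het = parent.gtype == GT_AB
    sib = sibling.gtype
    hemi = (
        np.zeros(n, dtype=bool) if hemizygous_mask is None else hemizygous_mask
    )

    inconsistent = 0
    for other_code, other_allele in ((GT_AA, 0), (GT_BB, 1)):
        sel = het & (other_parent.gtype == other_code)
        # sibling = other_allele + transmitted: hom-other -> transmitted same
        # allele as other parent; AB -> transmitted the opposite allele
        same = sel & (sib == (2 * other_allele))
        opposite = sel & (sib == GT_AB)
        bad = sel & (sib == (2 * (1 - other_allele)))
        h1[same] = other_allele
        h1[opposite] = 1 - other_allele
        # hemizygous sibling: its hom call IS the transmitted allele
        h1[bad & hemi] = 1 - other_allele
        inconsistent += int((bad & ~hemi).sum())
    return ParentPhase(parent.sample_id, h1, "sibling", n_inconsistent=inconsistent)


def phase_parents(
    mother: SampleArray,
    father: SampleArray,
    grandsire: SampleArray | None = None,
    granddam: SampleArray | None = None,
    sibling: SampleArray | None = None,
    snp_map=None,
) -> PhasedParents:
    """Phase whichever parents the supplied pedigree allows.

    A sibling phases both parents; grandparents phase the parent they
    belong to (by convention the father, matching the common case where the
    sire's parents are genotyped).  Both routes may be combined; the
    sibling route is preferred for the mother, the grandparent route for
    the father when both are available.  Passing ``snp_map`` lets
    sibling-based maternal phasing treat X-chromosome SNPs as potentially
    hemizygous in the sibling.
    """
    out = PhasedParents()
    if sibling is not None:
        hemi = None
        if snp_map is not None and "X" in snp_map.chroms:
            hemi = np.zeros(len(mother), dtype=bool)
            hemi[snp_map.chrom_slice("X")] = True
        out.mother = phase_with_sibling(mother, father, sibling, hemizygous_mask=hemi)
        out.father = phase_with_sibling(father, mother, sibling)
    if grandsire is not None and granddam is not None:
        out.father = phase_with_grandparents(father, grandsire, granddam)
    if out.mother is None and out.father is None:
        raise ValueError(
            "phasing requires a sibling sample or a grandparent pair"
        )
    out.meta["h1_convention"] = {
        "grandparent": "grandsire-derived allele",
        "sibling": "sibling-transmitted allele",
    }
    return out
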