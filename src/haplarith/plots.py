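"""Haplarithm and circos-style visualisations.

The five-panel haplarithm figure stacks, bottom to top: genome-wide LogR,
the maternal BAF subtracks, maternally inherited haplotype blocks
(pink/red for homologue 1/2), the paternal BAF subtracks and paternally
inherited blocks (light/dark blue).  Loci of interest are marked with
vertical lines.  The circos-style summary draws one concentric ring per
sample over chromosomes 1..X, coloured by aberration type.  Rendering is
deterministic (fixed figure geometry and dpi, no timestamps in metadata).
"""

from __future__ import annotations

import numpy as np
import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
from matplotlib.patches import Rectangle, Wedge

from .cnv import ChromosomeResult
from .haplarithm import HaplarithmProfile, P1
from .report import LocusSpec
from .sample import SampleArray
from .snp_map import SnpMap

BLOCK_COLORS = {
    "mat": {"H1": "#f4a6c0", "H2": "#c0392b", "both": "#8e44ad", "none": "#bdbdbd", "undetermined": "#eeeeee"},
    "pat": {"H1": "#aed6f1", "H2": "#1a5276", "both": "#8e44ad", "none": "#bdbdbd", "undetermined": "#eeeeee"},
}

STATE_COLORS = {
    "disomy": "#f0f0f0",
    "maternal_loss": "#c0392b",
    "paternal_loss": "#1a5276",
    "maternal_gain": "#e67e22",
    "paternal_gain": "#2980b9",
    "maternal_UPD": "#9b59b6",
    "paternal_UPD": "#6c3483",
    "nullisomy": "#000000",
    "undefined_parental_origin": "#27ae60",  # LogR-only, unconfirmed origin
    "undetermined": "#ffffff",
    "segmental": "#f5b041",
}

_SAVEFIG = dict(dpi=100, metadata={"Software": None, "CreationDate": None})


def _genome_offsets(snp_map: SnpMap) -> dict[str, int]:
    offsets = {}
    total = 0
    for chrom in snp_map.chroms:
        offsets[chrom] = total
        total += snp_map.karyotype.length(chrom)
    offsets["_total"] = total
    return offsets


def plot_haplarithm(
    embryo: SampleArray,
    profile: HaplarithmProfile,
    snp_map: SnpMap,
    path,
    loci: list[LocusSpec] = (),
    chrom: str | None = None,
) -> None:
    """Write the five-panel haplarithm figure (genome-wide, or one
    chromosome when ``chrom`` is given)."""
    chroms = [chrom] if chrom else snp_map.chroms
    offsets = _genome_offsets(snp_map) if chrom is None else {chroms[0]: 0}

    fig, axes = plt.subplots(5, 1, figsize=(14, 8), sharex=True)
    ax_logr, ax_mat, ax_matb, ax_pat, ax_patb = axes[::-1]

    for c in chroms:
        sl = snp_map.chrom_slice(c)
        x = snp_map.pos_bp[sl] + offsets[c]
        ax_logr.plot(x, embryo.logr[sl], ".", ms=1, color="#555555", rasterized=True)
    ax_logr.set_ylabel("LogR")
    ax_logr.set_ylim(-2.5, 2.0)
    ax_logr.axhline(0.0, color="k", lw=0.4)

    for parent, ax in (("mat", ax_mat), ("pat", ax_pat)):
        track = profile.tracks[parent]
        for c in chroms:
            m = track.chrom_mask(c)
            x = track.pos_bp[m] + offsets[c]
            sub = track.subtrack[m]
            ax.plot(x[sub == P1], track.f[m][sub == P1], ".", ms=1, color="#d35400", rasterized=True)
            ax.plot(x[sub != P1], track.f[m][sub != P1], ".", ms=1, color="#2471a3", rasterized=True)
        ax.set_ylabel(f"{parent.capitalize()}-BAF")
        ax.set_ylim(-0.05, 1.05)

    for parent, ax in (("mat", ax_matb), ("pat", ax_patb)):
        for block in profile.blocks:
            if block.parent != parent or block.chrom not in offsets:
                continue
            off = offsets[block.chrom]
            ax.add_patch(
                Rectangle(
                    (block.start_bp + off, 0), block.end_bp - block.start_bp, 1,
                    color=BLOCK_COLORS[parent].get(block.inherited, "#eeeeee"),
                )
            )
        ax.set_ylim(0, 1)
        ax.set_yticks([])
        ax.set_ylabel(f"{parent.capitalize()} blocks")

    for ax in axes:
        for c in chroms:
            ax.axvline(offsets[c], color="#cccccc", lw=0.4)
        for locus in loci:
            if locus.chrom in offsets:
                ax.axvline(
                    offsets[locus.chrom] + (locus.start_bp + locus.end_bp) / 2,
                    color="#f1c40f", lw=1.2,
                )
    axes[-1].set_xlabel("genome position (bp)" if chrom is None else f"chromosome {chrom} (bp)")
    fig.suptitle(embryo.sample_id)
    fig.savefig(path, **_SAVEFIG)
    plt.close(fig)


def plot_circos_summary(
    sample_results: dict[str, dict[str, ChromosomeResult]],
    snp_map: SnpMap,
    path,
) -> None:
    """Concentric per-sample rings over chromosomes 1..X, coloured by
    chromosome state (green = copy-number change of undefined parental
    origin)."""
    chroms = snp_map.chroms
    n = len(chroms)
    fig, ax = plt.subplots(figsize=(7, 7), subplot_kw={"aspect": "equal"})
    ax.set_xlim(-1.3, 1.3)
    ax.set_ylim(-1.3, 1.3)
    ax.axis("off")

    r0, width = 0.45, 0.5 / max(len(sample_results), 1)
    for si, (sid, results) in enumerate(sorted(sample_results.items())):
        r_in = r0 + si * width
        for ci, chrom in enumerate(chroms):
            t0 = 90 - ci * 360 / n
            t1 = 90 - (ci + 1) * 360 / n
            state = results[chrom].state if chrom in results else "undetermined"
            ax.add_patch(
                Wedge(
                    (0, 0), r_in + width * 0.9, t1, t0, width=width * 0.9,
                    facecolor=STATE_COLORS.get(state, "#f5b041"),
                    edgecolor="#999999", lw=0.3,
                )
            )
        ax.text(0, -r_in - width * 0.45, sid, ha="center", va="center", fontsize=6)
    for ci, chrom in enumerate(chroms):
        ang = np.deg2rad(90 - (ci + 0.5) * 360 / n)
        ax.text(1.08 * np.cos(ang), 1.08 * np.sin(ang), chrom, ha="center", va="center", fontsize=7)
    handles = [
        plt.Line2D([], [], marker="s", ls="", color=c, label=s)
        for s, c in STATE_COLORS.items()
    ]
    ax.legend(handles=handles, loc="upper left", bbox_to_anchor=(0.98, 1.0), fontsize=6, frameon=False)
    fig.savefig(path, **_SAVEFIG)
    plt.close(fig)
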