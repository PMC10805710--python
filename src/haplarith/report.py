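"""Locus-level PGT-M calls, per-embryo summaries, and the pipeline driver.

For each gene of interest the inherited maternal and paternal haplotype
(homologue 1 or 2) is read off the haplotype block overlapping the locus.
A call is *inconclusive* when the parent's homologues are not both
represented and distinguishable at the locus — a lost or duplicated
homologue (no heterozygosity to read), no informative SNPs supporting the
containing block, or a recombination breakpoint inside the locus interval.
Flanking metrics (distance in bp and informative-SNP count to the nearest
up-/downstream recombination site or chromosome end) quantify how well the
locus call is anchored.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .config import AnalysisConfig, DEFAULT_CONFIG
from .cnv import (
    ChromosomeResult,
    PloidyCall,
    call_chromosomes,
    call_genome_ploidy,
    determine_sex,
)
from .haplarithm import HaplarithmProfile, build_haplarithm
from .io import QcMetrics, call_rate, mendelian_inconsistency_rate, read_sample_table
from .phasing import PhasedParents, phase_parents
from .sample import SampleArray
from .snp_map import SnpMap

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# loci of interest
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class LocusSpec:
    """A gene interval of interest (1-based, closed)."""

    gene: str
    chrom: str
    start_bp: int
    end_bp: int
    note: str = ""

    def __post_init__(self) -> None:
        if self.end_bp < self.start_bp:
            raise ValueError(f"{self.gene}: end before start")


#: Synthetic placeholder intervals for the five classic equine PGT-M genes
#: (congenital hydrocephalus, warmblood fragile foal syndrome, cerebellar
#: abiotrophy, grey coat colour, glycogen branching enzyme deficiency),
#: positioned on the package's synthetic default karyotype.  For real
#: analyses supply assembly coordinates via a locus table.
DEFAULT_LOCI: tuple[LocusSpec, ...] = (
    LocusSpec("B3GALNT2", "1", 40_000_000, 40_200_000, "congenital hydrocephalus (synthetic coords)"),
    LocusSpec("PLOD1", "2", 25_000_000, 25_060_000, "fragile foal syndrome (synthetic coords)"),
    LocusSpec("MUTYH", "2", 120_000_000, 120_050_000, "cerebellar abiotrophy (synthetic coords)"),
    LocusSpec("STX17", "25", 30_000_000, 30_080_000, "grey coat colour (synthetic coords)"),
    LocusSpec("GBE1", "26", 20_000_000, 20_250_000, "glycogen branching enzyme deficiency (synthetic coords)"),
)


def read_locus_table(path, strict_bed: bool = False) -> list[LocusSpec]:
    """Read a BED-like locus table (gene, chrom, start, end[, note]).

    Intervals are 1-based closed by default; ``strict_bed=True`` converts
    from BED's 0-based half-open convention."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    loci = []
    seen = set()
    for rec in df.to_dict("records"):
        start, end = int(rec["start"]), int(rec["end"])
        if strict_bed:
            start, end = start + 1, end
        name = str(rec["gene"])
        if name in seen:
            raise ValueError(f"duplicate locus name {name!r}")
        seen.add(name)
        loci.append(LocusSpec(name, str(rec["chrom"]), start, end, str(rec.get("note", ""))))
    return loci


# ---------------------------------------------------------------------------
# locus calls
# ---------------------------------------------------------------------------
@dataclass
class ParentLocusCall:
    haplotype: str  # 'H1' | 'H2' | 'inconclusive'
    reason: str  # 'none' | 'no_heterozygosity' | 'no_informative_snps' | 'recombination_at_locus'
    upstream_bp: int
    downstream_bp: int
    upstream_informative: int
    downstream_informative: int


@dataclass
class LocusCall:
    gene: str
    chrom: str
    maternal: ParentLocusCall
    paternal: ParentLocusCall


def _parent_locus_call(
    parent_key: str,
    locus: LocusSpec,
    profile: HaplarithmProfile,
    chrom_result: ChromosomeResult,
    chrom_length: int,
) -> ParentLocusCall:
    track = profile.tracks[parent_key]
    mask = track.chrom_mask(locus.chrom)
    pos = track.pos_bp[mask]

    bps = sorted(b.pos_bp for b in profile.breakpoints_for(parent_key, locus.chrom))
    up_edge = max([b for b in bps if b <= locus.start_bp], default=1)
    down_edge = min([b for b in bps if b >= locus.end_bp], default=chrom_length)
    upstream_bp = int(locus.start_bp - up_edge)
    downstream_bp = int(down_edge - locus.end_bp)
    upstream_inf = int(np.sum((pos >= up_edge) & (pos < locus.start_bp)))
    downstream_inf = int(np.sum((pos > locus.end_bp) & (pos <= down_edge)))

    def inconclusive(reason: str) -> ParentLocusCall:
        return ParentLocusCall(
            "inconclusive", reason, upstream_bp, downstream_bp, upstream_inf, downstream_inf
        )

    # parental copy number at the locus
    mid = (locus.start_bp + locus.end_bp) // 2
    copies = None
    for call in chrom_result.calls:
        if call.start_bp <= mid <= call.end_bp:
            copies = call.maternal_copies if parent_key == "mat" else call.paternal_copies
            break
    if copies == 0:
        return inconclusive("no_heterozygosity")

    # recombination site inside the locus
    if any(locus.start_bp <= b <= locus.end_bp for b in bps):
        return inconclusive("recombination_at_locus")

    # a breakpoint-bounded flank without informative SNPs leaves the locus
    # unanchored: the true switch is only localised to an informative-SNP
    # gap that may contain the locus
    if any(b <= locus.start_bp for b in bps) and upstream_inf == 0:
        return inconclusive("no_informative_snps")
    if any(b >= locus.end_bp for b in bps) and downstream_inf == 0:
        return inconclusive("no_informative_snps")

    blocks = profile.blocks_for(parent_key, locus.chrom)
    block = next((b for b in blocks if b.start_bp <= mid <= b.end_bp), None)
    if block is None or block.n_support == 0:
        return inconclusive("no_informative_snps")
    if block.inherited in ("H1", "H2"):
        return ParentLocusCall(
            block.inherited, "none", upstream_bp, downstream_bp, upstream_inf, downstream_inf
        )
    if block.inherited in ("none", "both"):
        # lost or doubly-present homologues: no single haplotype to read
        return inconclusive("no_heterozygosity")
    return inconclusive("no_informative_snps")


def call_locus(
    locus: LocusSpec,
    profile: HaplarithmProfile,
    chrom_results: dict[str, ChromosomeResult],
    snp_map: SnpMap,
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> LocusCall:
    """Inherited parental haplotypes at one gene of interest."""
    if locus.chrom not in snp_map.chroms:
        raise ValueError(f"locus {locus.gene}: chromosome {locus.chrom} not in map")
    length = snp_map.karyotype.length(locus.chrom)
    res = chrom_results[locus.chrom]
    return LocusCall(
        locus.gene,
        locus.chrom,
        maternal=_parent_locus_call("mat", locus, profile, res, length),
        paternal=_parent_locus_call("pat", locus, profile, res, length),
    )


# ---------------------------------------------------------------------------
# per-sample analysis bundle
# ---------------------------------------------------------------------------
@dataclass
class EmbryoAnalysis:
    sample_id: str
    role: str
    status: str  # 'ok' | 'failed'
    qc: QcMetrics
    profile: HaplarithmProfile | None = None
    chrom_results: dict[str, ChromosomeResult] | None = None
    ploidy: PloidyCall | None = None
    sex: str = "undetermined"
    locus_calls: list[LocusCall] = field(default_factory=list)
    failure_reason: str = ""


def analyze_sample(
    embryo: SampleArray,
    mother: SampleArray,
    father: SampleArray,
    phased: PhasedParents,
    snp_map: SnpMap,
    loci=DEFAULT_LOCI,
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> EmbryoAnalysis:
    """Full haplarithmisis analysis of one embryo sample."""
    cr = call_rate(embryo)
    mi = mendelian_inconsistency_rate(embryo, mother, father)
    if cr < config.min_call_rate:
        return EmbryoAnalysis(
            embryo.sample_id, embryo.role, "failed", QcMetrics(cr, mi, 0),
            failure_reason=f"call rate {cr:.2f} below {config.min_call_rate}",
        )
    profile = build_haplarithm(phased, mother, father, embryo, snp_map, config)
    n_inf = sum(profile.meta["n_informative"].values())
    qc = QcMetrics(cr, mi, n_inf)
    if n_inf < config.min_informative_snps:
        return EmbryoAnalysis(
            embryo.sample_id, embryo.role, "failed", qc, profile,
            failure_reason=f"only {n_inf} informative SNPs",
        )
    chrom_results = call_chromosomes(embryo, profile, snp_map, config=config)
    ploidy = call_genome_ploidy(chrom_results, config)
    sex = determine_sex(chrom_results.get("X"))
    locus_calls = [
        call_locus(locus, profile, chrom_results, snp_map, config) for locus in loci
    ]
    return EmbryoAnalysis(
        embryo.sample_id, embryo.role, "ok", qc, profile, chrom_results,
        ploidy, sex, locus_calls,
    )


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------
def summarize_embryo(analysis: EmbryoAnalysis) -> dict:
    """Machine-readable summary record for one analyzed sample."""
    rec: dict = {
        "sample_id": analysis.sample_id,
        "role": analysis.role,
        "status": analysis.status,
        "call_rate": round(analysis.qc.call_rate, 6),
        "mendelian_inconsistency_rate": (
            None
            if analysis.qc.mendelian_inconsistency_rate is None
            or not np.isfinite(analysis.qc.mendelian_inconsistency_rate)
            else round(analysis.qc.mendelian_inconsistency_rate, 6)
        ),
        "n_informative_snps": analysis.qc.n_informative_snps,
        "failure_reason": analysis.failure_reason,
    }
    if analysis.status != "ok":
        return rec
    rec["ploidy"] = analysis.ploidy.label
    rec["sex"] = analysis.sex
    rec["chromosome_states"] = {
        chrom: {
            "state": res.state,
            "maternal_copies": res.m,
            "paternal_copies": res.p,
            "mosaic": res.mosaic,
        }
        for chrom, res in analysis.chrom_results.items()
    }
    rec["aberrations"] = ";".join(
        f"{c}:{r.state}" for c, r in analysis.chrom_results.items() if r.state != "disomy"
    )
    rec["loci"] = {
        lc.gene: {
            "maternal": asdict(lc.maternal),
            "paternal": asdict(lc.paternal),
        }
        for lc in analysis.locus_calls
    }
    return rec


def summary_table(records: list[dict]) -> pd.DataFrame:
    """Flatten summary records into one row per sample."""
    rows = []
    for rec in records:
        row = {
            k: rec.get(k)
            for k in (
                "sample_id", "role", "status", "call_rate",
                "mendelian_inconsistency_rate", "n_informative_snps",
                "ploidy", "sex", "aberrations", "failure_reason",
            )
        }
        for gene, calls in rec.get("loci", {}).items():
            row[f"{gene}_mat"] = calls["maternal"]["haplotype"]
            row[f"{gene}_pat"] = calls["paternal"]["haplotype"]
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# pipeline driver
# ---------------------------------------------------------------------------
def run_pipeline(config: dict | str | Path, out_dir: str | Path | None = None) -> dict:
    """Execute the full analysis from a YAML/dict run configuration.

    Expected keys: ``map`` (map table path), ``samples`` (list of
    ``{id, role, path}``), ``phasing`` (``mode`` plus the pedigree sample
    ids it needs), optional ``loci`` (locus table path), ``output_dir`` and
    ``analysis`` (:class:`AnalysisConfig` overrides).  Samples that fail QC
    are reported as failed analyses; they do not abort the run.
    """
    if not isinstance(config, dict):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    out_dir = Path(out_dir or config.get("output_dir", "haplarith_out"))
    out_dir.mkdir(parents=True, exist_ok=True)

    snp_map = SnpMap.from_table(config["map"])
    analysis_cfg = AnalysisConfig.from_dict(config.get("analysis", {}))

    samples: dict[str, SampleArray] = {}
    roles: dict[str, str] = {}
    for spec in config["samples"]:
        arr = read_sample_table(spec["path"], snp_map, role=spec["role"])
        arr.sample_id = spec["id"]
        samples[spec["id"]] = arr
        roles[spec["id"]] = spec["role"]
        logger.info("loaded %s (%s): call rate %.3f", spec["id"], spec["role"], call_rate(arr))

    def _one_with_role(role: str) -> SampleArray:
        ids = [i for i, r in roles.items() if r == role]
        if len(ids) != 1:
            raise ValueError(f"need exactly one sample with role {role!r}, found {len(ids)}")
        return samples[ids[0]]

    mother = _one_with_role("mother")
    father = _one_with_role("father")

    phasing_cfg = config.get("phasing", {})
    mode = phasing_cfg.get("mode", "sibling")
    if mode == "grandparent":
        try:
            grandsire = samples[phasing_cfg["grandsire"]]
            granddam = samples[phasing_cfg["granddam"]]
        except KeyError as exc:
            raise ValueError(f"grandparent phasing requires sample {exc}") from exc
        phased = phase_parents(mother, father, grandsire=grandsire, granddam=granddam)
    elif mode == "sibling":
        sib_id = phasing_cfg.get("sibling")
        if sib_id is None or sib_id not in samples:
            raise ValueError("sibling phasing requires a 'sibling' sample id")
        phased = phase_parents(mother, father, sibling=samples[sib_id], snp_map=snp_map)
    else:
        raise ValueError(f"unknown phasing mode {mode!r}")

    loci = (
        read_locus_table(config["loci"]) if "loci" in config else list(DEFAULT_LOCI)
    )

    pedigree_ids = {mother.sample_id, father.sample_id}
    pedigree_ids |= {phasing_cfg.get(k) for k in ("grandsire", "granddam", "sibling")}
    records = []
    analyses = {}
    for sid, arr in samples.items():
        if sid in pedigree_ids or roles[sid] in ("mother", "father", "grandsire", "granddam"):
            continue
        analysis = analyze_sample(arr, mother, father, phased, snp_map, loci, analysis_cfg)
        analyses[sid] = analysis
        rec = summarize_embryo(analysis)
        records.append(rec)
        with open(out_dir / f"{sid}.json", "w") as fh:
            json.dump(rec, fh, indent=2)
        logger.info(
            "analyzed %s: status=%s informative=%s", sid, analysis.status,
            analysis.qc.n_informative_snps,
        )

    table = summary_table(records)
    table.to_csv(out_dir / "summary.tsv", sep="\t", index=False)
    return {"records": records, "analyses": analyses, "summary_path": str(out_dir / "summary.tsv")}
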