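"""Joint copy-number, parental-origin, ploidy and sex classification.

Every copy-number configuration is a homologue-count 4-tuple
``(m1, m2, p1, p2)`` (maternal homologue 1/2, paternal homologue 1/2
copies) with total ``n``.  Its noise-free signature is

* LogR = log2(n / 2)  (floored for nullisomy),
* maternal subtrack levels (m1/n, m2/n),
* paternal subtrack levels (p1/n, p2/n),

so biparental disomy sits at LogR 0 with a 0.5 parental-BAF distance,
monosomy at LogR -1 with levels {0, 1}, trisomy at LogR log2(3/2) ~ 0.58
with levels {0, 1/3, 2/3, 1} and tetrasomy at LogR 1 with levels
{0, 1/4, 1/2, 3/4, 1}.  A segment is assigned the configuration nearest in
weighted RMS distance; segments no pure configuration explains are tested
against a two-component mixture of disomic and aberrant cells (mosaicism),
and LogR-only aberrations fall back to an "undefined parental origin"
call, since a copy-number change the haplarithm cannot confirm has no
attributable parent.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .config import AnalysisConfig, DEFAULT_CONFIG
from .haplarithm import HaplarithmProfile
from .sample import SampleArray
from .segmentation import auto_penalty, pelt_grouped, segment_means
from .simulate import LOGR_FLOOR
from .snp_map import SnpMap

MAX_COPIES = 4


# ---------------------------------------------------------------------------
# signature table
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class Configuration:
    m1: int
    m2: int
    p1: int
    p2: int

    @property
    def n(self) -> int:
        return self.m1 + self.m2 + self.p1 + self.p2

    @property
    def m(self) -> int:
        return self.m1 + self.m2

    @property
    def p(self) -> int:
        return self.p1 + self.p2

    def expected(self) -> np.ndarray:
        """(logr, matP1, matP2, patP1, patP2); subtracks NaN for nullisomy."""
        n = self.n
        if n == 0:
            return np.array([LOGR_FLOOR, np.nan, np.nan, np.nan, np.nan])
        return np.array(
            [np.log2(n / 2.0), self.m1 / n, self.m2 / n, self.p1 / n, self.p2 / n]
        )


def state_label(m: int, p: int) -> str:
    """Canonical state name for (maternal, paternal) copy totals."""
    named = {
        (1, 1): "disomy",
        (0, 1): "maternal_loss",
        (1, 0): "paternal_loss",
        (2, 1): "maternal_gain",
        (1, 2): "paternal_gain",
        (0, 0): "nullisomy",
        (2, 0): "maternal_UPD",
        (0, 2): "paternal_UPD",
        (2, 2): "tetrasomy_biparental",
        (3, 1): "maternal_triple_gain",
        (1, 3): "paternal_triple_gain",
    }
    return named.get((m, p), f"mat{m}_pat{p}")


class SignatureTable:
    """All configurations with total copy number <= ``max_copies``."""

    def __init__(self, max_copies: int = MAX_COPIES):
        self.max_copies = max_copies
        configs = [
            Configuration(m1, m2, p1, p2)
            for m1, m2, p1, p2 in itertools.product(range(max_copies + 1), repeat=4)
            if m1 + m2 + p1 + p2 <= max_copies
        ]
        # deterministic tie-break order: least copy-number change from
        # biparental disomy first, then maternal aberrations before paternal
        configs.sort(
            key=lambda c: (
                abs(c.m - 1) + abs(c.p - 1),
                abs(c.p - 1),
                c.n,
                c.m2,
                c.p2,
            )
        )
        self.configs = configs
        self.expected = np.array([c.expected() for c in configs])
        self.counts = np.array([[c.m1, c.m2, c.p1, c.p2] for c in configs], dtype=float)

    def __len__(self) -> int:
        return len(self.configs)

    def disomies(self) -> list[Configuration]:
        return [c for c in self.configs if c.m == 1 and c.p == 1]


SIGNATURES = SignatureTable()


# ---------------------------------------------------------------------------
# per-segment classification
# ---------------------------------------------------------------------------
@dataclass
class CopyNumberCall:
    chrom: str
    start_bp: int
    end_bp: int
    state: str
    maternal_copies: int | None
    paternal_copies: int | None
    config: Configuration | None
    mosaic_flag: bool = False
    mosaic_fraction: float | None = None
    fit_distance: float = float("nan")
    n_snps: int = 0

    @property
    def is_aberrant(self) -> bool:
        return self.state != "disomy"

    @property
    def parent_of_event(self) -> str | None:
        if self.maternal_copies is None:
            return None
        if self.maternal_copies != 1 and self.paternal_copies == 1:
            return "mat"
        if self.paternal_copies != 1 and self.maternal_copies == 1:
            return "pat"
        if self.maternal_copies != 1 and self.paternal_copies != 1:
            return "both"
        return None


def _distance(
    observed: np.ndarray, expected: np.ndarray, weights: np.ndarray
) -> np.ndarray:
    """Weighted RMS distance over jointly available observables.

    ``observed`` is a 5-vector (NaN = unavailable), ``expected`` an
    (n_configs, 5) matrix (NaN = undefined for that configuration).
    """
    avail = np.isfinite(observed)
    use = avail[None, :] & np.isfinite(expected)
    diff = np.where(use, expected - observed[None, :], 0.0)
    wsum = (use * weights[None, :]).sum(axis=1)
    d2 = (weights[None, :] * diff**2).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.sqrt(d2 / np.maximum(wsum, 1e-12))
    out[wsum <= 0] = np.inf
    return out


def _mixture_expected(
    disomy: Configuration, aberrant: Configuration, rho: float
) -> np.ndarray:
    """Signature of a cell mixture: fraction ``rho`` disomic, rest aberrant.

    LogR mixes through the mean copy number; subtracks mix through pooled
    allele counts (copy-number weighted)."""
    n_mix = 2.0 * rho + aberrant.n * (1.0 - rho)
    if n_mix <= 0:
        return np.array([LOGR_FLOOR, np.nan, np.nan, np.nan, np.nan])
    counts_d = np.array([disomy.m1, disomy.m2, disomy.p1, disomy.p2], dtype=float)
    counts_a = np.array([aberrant.m1, aberrant.m2, aberrant.p1, aberrant.p2], dtype=float)
    sub = (rho * counts_d + (1.0 - rho) * counts_a) / n_mix
    return np.concatenate([[np.log2(n_mix / 2.0)], sub])


# the four biparental-disomy homologue patterns a mosaic mixes with
_DISOMY_COUNTS = np.array(
    [[1, 0, 1, 0], [1, 0, 0, 1], [0, 1, 1, 0], [0, 1, 0, 1]], dtype=float
)


def _best_mixture(
    observed: np.ndarray,
    weights: np.ndarray,
    table: SignatureTable,
    rho_grid: np.ndarray,
) -> tuple[float, int, float]:
    """Grid search over (aberrant config, disomy pattern, disomic fraction).

    Returns (distance, aberrant config index, disomic fraction rho);
    vectorised over the whole grid for speed."""
    counts_a = table.counts  # (A, 4)
    n_a = counts_a.sum(axis=1)  # (A,)
    non_disomy = ~np.array([c.m == 1 and c.p == 1 for c in table.configs])

    rho = rho_grid[None, None, :]  # (1, 1, R)
    n_mix = 2.0 * rho + n_a[:, None, None] * (1.0 - rho)  # (A, 1, R)
    # pooled homologue fractions: (A, D, R, 4)
    num = (
        rho[..., None] * _DISOMY_COUNTS[None, :, None, :]
        + (1.0 - rho[..., None]) * counts_a[:, None, None, :]
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        sub = num / np.maximum(n_mix[..., None], 1e-12)
        logr = np.where(n_mix > 0, np.log2(np.maximum(n_mix, 1e-12) / 2.0), LOGR_FLOOR)

    avail = np.isfinite(observed)
    w = weights * avail
    wsum = w.sum()
    obs = np.where(avail, observed, 0.0)
    d2 = w[0] * (logr - obs[0]) ** 2  # (A, 1, R) broadcast over D
    d2 = np.broadcast_to(d2[:, :, :], (len(n_a), 4, len(rho_grid))).copy()
    for k in range(4):
        d2 += w[k + 1] * (sub[..., k] - obs[k + 1]) ** 2
    dist = np.sqrt(d2 / max(wsum, 1e-12))
    dist[~non_disomy, :, :] = np.inf
    flat = int(np.argmin(dist))
    ai, di, ri = np.unravel_index(flat, dist.shape)
    return float(dist[ai, di, ri]), int(ai), float(rho_grid[ri])


def classify_segment(
    logr_mean: float,
    mat_means: tuple[float, float],
    pat_means: tuple[float, float],
    table: SignatureTable = SIGNATURES,
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> tuple[Configuration | None, float, bool, float | None]:
    """Assign the nearest copy-number configuration to one segment.

    Returns ``(configuration, fit_distance, mosaic_flag, mosaic_fraction)``;
    ``configuration`` is None when nothing (pure or mosaic) fits within
    tolerance.  Pass NaN for unavailable observables.
    """
    observed = np.array([logr_mean, *mat_means, *pat_means], dtype=float)
    weights = np.array(
        [config.logr_weight] + [config.subtrack_weight] * 4, dtype=float
    )
    dists = _distance(observed, table.expected, weights)
    best = int(np.argmin(dists))
    d_pure = float(dists[best])
    if d_pure <= config.signature_tolerance:
        return table.configs[best], d_pure, False, None

    # mosaic: two-component disomy/aberration mixture
    rho_grid = np.linspace(0.0, 1.0, 201)
    d_mix, ai, rho = _best_mixture(observed, weights, table, rho_grid)
    frac = 1.0 - rho
    lo, hi = config.mosaic_band
    if (
        d_mix <= config.signature_tolerance
        and d_pure / max(d_mix, 1e-9) >= config.mosaic_improvement
        and lo <= frac <= hi
    ):
        return table.configs[ai], d_mix, True, frac
    return None, d_pure, False, None


# ---------------------------------------------------------------------------
# LogR segmentation
# ---------------------------------------------------------------------------
def segment_logr(
    embryo: SampleArray,
    snp_map: SnpMap,
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> dict[str, list[dict]]:
    """Piecewise-constant segmentation of the LogR track per chromosome."""
    out: dict[str, list[dict]] = {}
    for chrom in snp_map.chroms:
        sl = snp_map.chrom_slice(chrom)
        logr = embryo.logr[sl]
        pos = snp_map.pos_bp[sl]
        ok = np.isfinite(logr)
        v, p = logr[ok], pos[ok]
        if len(v) == 0:
            out[chrom] = []
            continue
        seg_cfg = config.segmentation
        if len(v) < seg_cfg.min_seg_snps:
            out[chrom] = [
                {
                    "chrom": chrom, "start_bp": int(p[0]), "end_bp": int(p[-1]),
                    "mean": float(v.mean()), "n": len(v), "low_support": True,
                }
            ]
            continue
        penalty = auto_penalty(v, seg_cfg)
        cps = pelt_grouped(v, np.zeros(len(v), dtype=int), penalty,
                           min_size=seg_cfg.min_size, n_groups=1)
        segs = []
        for rec in segment_means(v, np.zeros(len(v), dtype=int), cps, n_groups=1):
            lo, hi = rec["start_idx"], rec["stop_idx"]
            segs.append(
                {
                    "chrom": chrom, "start_bp": int(p[lo]), "end_bp": int(p[hi - 1]),
                    "mean": rec["mean_0"], "n": rec["n_0"], "low_support": False,
                }
            )
        out[chrom] = segs
    return out


# ---------------------------------------------------------------------------
# chromosome-level calling
# ---------------------------------------------------------------------------
@dataclass
class ChromosomeResult:
    chrom: str
    intervals: list[CopyNumberCall]  # fine-grained (pre-merge) calls
    calls: list[CopyNumberCall]  # merged by copy-number state
    state: str  # length-majority state label
    m: int | None
    p: int | None
    mosaic: bool
    heterodisomy: bool  # both homologues of one parent over a substantial span
    hetero_span_fraction: float = 0.0


def _interval_edges(boundaries: list[float], length: int, merge_bp: float) -> list[int]:
    """Cluster near-coincident boundaries and return interval edges."""
    if not boundaries:
        return [1, length]
    b = sorted(boundaries)
    clustered: list[list[float]] = [[b[0]]]
    for x in b[1:]:
        if x - clustered[-1][-1] <= merge_bp:
            clustered[-1].append(x)
        else:
            clustered.append([x])
    mids = [int(np.mean(c)) for c in clustered]
    mids = [m for m in mids if 1 < m < length]
    return [1, *mids, length]


def call_chromosome(
    chrom: str,
    embryo: SampleArray,
    profile: HaplarithmProfile,
    logr_segs: list[dict],
    snp_map: SnpMap,
    table: SignatureTable = SIGNATURES,
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> ChromosomeResult:
    """Classify one chromosome over the union of LogR and subtrack
    breakpoints, then merge intervals sharing a copy-number state."""
    sl = snp_map.chrom_slice(chrom)
    pos = snp_map.pos_bp[sl]
    logr = embryo.logr[sl]
    length = snp_map.karyotype.length(chrom)

    boundaries: list[float] = []
    for seg in logr_segs[1:]:
        boundaries.append(seg["start_bp"] - 0.5)
    for parent in ("mat", "pat"):
        segs = [s for s in profile.segments[parent] if s.chrom == chrom]
        for s in segs[1:]:
            boundaries.append(s.start_bp - 0.5)
    edges = _interval_edges(boundaries, length, config.breakpoint_merge_mbp * 1e6)

    tracks = profile.tracks
    intervals: list[CopyNumberCall] = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        in_iv = (pos >= lo) & (pos <= hi)
        lv = logr[in_iv]
        lv = lv[np.isfinite(lv)]
        logr_mean = float(lv.mean()) if len(lv) >= 3 else float("nan")
        sub_means = {}
        n_inf = 0
        for parent in ("mat", "pat"):
            tr = tracks[parent]
            m_iv = (tr.chrom == chrom) & (tr.pos_bp >= lo) & (tr.pos_bp <= hi)
            pair = []
            for s in (0, 1):
                vals = tr.f[m_iv & (tr.subtrack == s)]
                pair.append(float(vals.mean()) if len(vals) >= 3 else float("nan"))
            sub_means[parent] = tuple(pair)
            n_inf += int(m_iv.sum())
        cfg, dist, mosaic, frac = classify_segment(
            logr_mean, sub_means["mat"], sub_means["pat"], table, config
        )
        if cfg is not None:
            call = CopyNumberCall(
                chrom, int(lo), int(hi), state_label(cfg.m, cfg.p), cfg.m, cfg.p,
                cfg, mosaic, frac, dist, n_snps=int(in_iv.sum()),
            )
        else:
            # LogR-only evidence: aberration unconfirmed by the haplarithm
            state = "undetermined"
            if np.isfinite(logr_mean):
                ks = np.arange(0, table.max_copies + 1)
                exp = np.where(ks > 0, np.log2(np.maximum(ks, 1) / 2.0), LOGR_FLOOR)
                k = int(ks[np.argmin(np.abs(exp - logr_mean))])
                if k != 2 and abs(exp[k] - logr_mean) <= 2 * config.signature_tolerance:
                    state = "undefined_parental_origin"
            call = CopyNumberCall(
                chrom, int(lo), int(hi), state, None, None, None,
                fit_distance=dist, n_snps=int(in_iv.sum()),
            )
        intervals.append(call)

    # merge adjacent intervals with the same copy-number state
    merged: list[CopyNumberCall] = []
    for call in intervals:
        if (
            merged
            and merged[-1].state == call.state
            and merged[-1].mosaic_flag == call.mosaic_flag
        ):
            prev = merged[-1]
            total = prev.n_snps + call.n_snps
            if total > 0 and prev.mosaic_fraction is not None and call.mosaic_fraction is not None:
                prev.mosaic_fraction = (
                    prev.mosaic_fraction * prev.n_snps + call.mosaic_fraction * call.n_snps
                ) / total
            prev.end_bp = call.end_bp
            prev.n_snps = total
        else:
            merged.append(
                CopyNumberCall(
                    call.chrom, call.start_bp, call.end_bp, call.state,
                    call.maternal_copies, call.paternal_copies, call.config,
                    call.mosaic_flag, call.mosaic_fraction, call.fit_distance,
                    call.n_snps,
                )
            )

    # absorb sub-resolution slivers into the larger neighbour, then re-merge
    min_len = config.min_segment_mbp * 1e6
    changed = True
    while changed and len(merged) > 1:
        changed = False
        for i, call in enumerate(merged):
            if call.end_bp - call.start_bp < min_len:
                nb = merged[i - 1] if i > 0 else merged[i + 1]
                nb.start_bp = min(nb.start_bp, call.start_bp)
                nb.end_bp = max(nb.end_bp, call.end_bp)
                nb.n_snps += call.n_snps
                merged.pop(i)
                changed = True
                break
        if not changed:
            for i in range(len(merged) - 1):
                a, b = merged[i], merged[i + 1]
                if a.state == b.state and a.mosaic_flag == b.mosaic_flag:
                    a.end_bp = b.end_bp
                    a.n_snps += b.n_snps
                    merged.pop(i + 1)
                    changed = True
                    break

    # chromosome state: the state covering the largest total span
    span = lambda c: c.end_bp - c.start_bp
    by_state: dict[str, int] = {}
    for c in merged:
        by_state[c.state] = by_state.get(c.state, 0) + span(c)
    major_state = max(by_state, key=by_state.get)
    major_calls = [c for c in merged if c.state == major_state]
    major = max(major_calls, key=span)
    frac_major = by_state[major_state] / max(length, 1)
    state = major_state if frac_major >= 0.5 else "segmental"
    # heterodisomy: fraction of the chromosome where both homologues of
    # one parent are called present (distinguishes a meiosis-I extra genome
    # from a duplicated single genotype); judged on span, not single
    # intervals, because boundary intervals misfit heterodisomic configs
    hetero_span = sum(
        span(iv)
        for iv in intervals
        if iv.config is not None
        and span(iv) >= min_len
        and (
            (iv.config.m1 >= 1 and iv.config.m2 >= 1)
            or (iv.config.p1 >= 1 and iv.config.p2 >= 1)
        )
    )
    hetero_frac = hetero_span / max(length, 1)
    return ChromosomeResult(
        chrom,
        intervals,
        merged,
        state,
        major.maternal_copies,
        major.paternal_copies,
        any(c.mosaic_flag for c in major_calls),
        hetero_frac >= 0.2,
        hetero_frac,
    )


def call_chromosomes(
    embryo: SampleArray,
    profile: HaplarithmProfile,
    snp_map: SnpMap,
    table: SignatureTable = SIGNATURES,
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> dict[str, ChromosomeResult]:
    logr_segs = segment_logr(embryo, snp_map, config)
    return {
        chrom: call_chromosome(
            chrom, embryo, profile, logr_segs[chrom], snp_map, table, config
        )
        for chrom in snp_map.chroms
    }


# ---------------------------------------------------------------------------
# genome-wide ploidy, sex, event origin
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class PloidyCall:
    label: str
    sex: str
    reason: str = ""


def determine_sex(x_result: ChromosomeResult | None) -> str:
    """Sex from the X copy-number call: one maternal X = male, biparental
    XX = female, anything else undetermined."""
    if x_result is None or x_result.m is None:
        return "undetermined"
    if (x_result.m, x_result.p) == (1, 0):
        return "male"
    if (x_result.m, x_result.p) == (1, 1):
        return "female"
    return "undetermined"


def call_genome_ploidy(
    results: dict[str, ChromosomeResult],
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> PloidyCall:
    """Genome label from the dominant per-chromosome pattern.

    A genome-wide maternal trisomy pattern is digynic triploidy, *meiotic*
    when heterodisomic regions betray two distinct maternal genomes and
    *mitotic* when a single duplicated maternal genotype is seen; the
    paternal mirror is diandric.  Genome-wide single-parent monosomy or
    disomy yields the haploidy / uniparental-disomy labels.
    """
    autosomes = [c for c in results if c != "X"]
    sex = determine_sex(results.get("X"))
    usable = [c for c in autosomes if results[c].m is not None]
    if len(usable) < config.min_chrom_call_fraction * len(autosomes):
        return PloidyCall("undetermined", sex, "insufficient chromosome coverage")

    patterns = {c: (results[c].m, results[c].p) for c in usable}
    counts: dict[tuple[int, int], int] = {}
    for pat in patterns.values():
        counts[pat] = counts.get(pat, 0) + 1
    modal, modal_n = max(counts.items(), key=lambda kv: kv[1])
    frac = modal_n / len(usable)
    if frac < config.ploidy_pattern_fraction:
        return PloidyCall("complex", sex, "no dominant genome-wide pattern")

    # meiotic extra genomes show heterodisomy on a large share of
    # chromosomes; isolated flags are segmentation artefacts
    trisomic_mat = [c for c in usable if results[c].m == 2]
    trisomic_pat = [c for c in usable if results[c].p == 2]
    hetero_mat = (
        bool(trisomic_mat)
        and np.mean([results[c].heterodisomy for c in trisomic_mat]) >= 0.25
    )
    hetero_pat = (
        bool(trisomic_pat)
        and np.mean([results[c].heterodisomy for c in trisomic_pat]) >= 0.25
    )
    label = "complex"
    if modal == (1, 1):
        label = "biparental_diploid"
    elif modal == (2, 1):
        label = "digynic_triploid_meiotic" if hetero_mat else "digynic_triploid_mitotic"
    elif modal == (1, 2):
        label = "diandric_triploid_meiotic" if hetero_pat else "diandric_triploid_mitotic"
    elif modal == (1, 0):
        label = "gynogenetic_haploid"
    elif modal == (0, 1):
        label = "androgenetic_haploid"
    elif modal == (2, 0):
        label = "gw_maternal_UPD"
    elif modal == (0, 2):
        label = "gw_paternal_UPD"
    return PloidyCall(label, sex)


def classify_event_origin(samples: list[dict]) -> list[dict]:
    """Attribute shared vs private chromosome events across the samples of
    one embryo.

    ``samples`` holds dicts with ``sample_id``, ``role`` and ``results``
    (chromosome -> :class:`ChromosomeResult`).  An identical event (same
    chromosome, state) in every sample is meiotic; one confined to a strict
    subset of blastomeres is mitotic; one seen in a biopsy but absent from
    its whole blastocyst is low-grade mosaicism (present in too small a
    cell fraction to register in the bulk embryo).
    """
    if len(samples) < 2:
        out = []
        for s in samples:
            for chrom, res in s["results"].items():
                if res.state not in ("disomy",):
                    out.append(
                        {
                            "chrom": chrom, "state": res.state,
                            "samples": [s["sample_id"]], "origin": "undetermined",
                        }
                    )
        return out

    roles = {s["sample_id"]: s["role"] for s in samples}
    events: dict[tuple[str, str], list[str]] = {}
    for s in samples:
        for chrom, res in s["results"].items():
            if res.state != "disomy":
                events.setdefault((chrom, res.state), []).append(s["sample_id"])

    blastomeres = [s["sample_id"] for s in samples if s["role"] == "blastomere"]
    biopsy_pairs = [s["sample_id"] for s in samples if s["role"] == "biopsy"]
    blastocysts = [s["sample_id"] for s in samples if s["role"] in ("blastocyst", "embryo")]

    out = []
    all_ids = [s["sample_id"] for s in samples]
    for (chrom, state), carriers in sorted(events.items()):
        if set(carriers) == set(all_ids):
            origin = "meiotic"
        elif blastomeres and set(carriers) < set(blastomeres + []):
            origin = "mitotic"
        elif (
            biopsy_pairs
            and blastocysts
            and any(c in biopsy_pairs for c in carriers)
            and not any(c in blastocysts for c in carriers)
        ):
            origin = "low_grade_mosaic"
        else:
            origin = "undetermined"
        out.append(
            {"chrom": chrom, "state": state, "samples": sorted(carriers), "origin": origin}
        )
    return out
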