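"""Reading/writing sample genotype tables and per-sample QC metrics.

The table dialect mirrors a GenomeStudio final-report export: a header row
followed by tab-separated columns ``Sample ID``, ``SNP Name``, ``Chr``,
``Position``, ``GType``, ``B Allele Freq``, ``Log R Ratio`` and optionally
``GC Score``.  No-calls are written literally as ``NC``; missing numeric
values as ``NaN``.  Numeric fields are printed with 6 decimals, which
bounds round-trip error.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .sample import GT_CODES, GT_LABELS, GT_NC, SampleArray
from .snp_map import SnpMap

logger = logging.getLogger(__name__)

COLUMNS = [
    "Sample ID",
    "SNP Name",
    "Chr",
    "Position",
    "GType",
    "B Allele Freq",
    "Log R Ratio",
]

#: Genotype quality filter applied when a ``GC Score`` column is present;
#: rows scoring below it are demoted to NC (the numeric channels are kept).
DEFAULT_GC_THRESHOLD = 0.75


@dataclass(frozen=True)
class QcMetrics:
    """Per-sample quality summary."""

    call_rate: float
    mendelian_inconsistency_rate: float | None
    n_informative_snps: int | None = None


class SampleTableError(ValueError):
    """Malformed sample table (message names the offending line)."""


def write_sample_table(sample: SampleArray, snp_map: SnpMap, path) -> None:
    """Write one sample as a dialect-exact table, one row per map SNP."""
    df = pd.DataFrame(
        {
            "Sample ID": sample.sample_id,
            "SNP Name": snp_map.snp_ids,
            "Chr": snp_map.chrom_labels,
            "Position": snp_map.pos_bp,
            "GType": [GT_LABELS[g] for g in sample.gtype],
            "B Allele Freq": sample.baf,
            "Log R Ratio": sample.logr,
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.6f", na_rep="NaN")


def read_sample_table(
    path,
    snp_map: SnpMap,
    role: str = "embryo",
    gc_threshold: float = DEFAULT_GC_THRESHOLD,
) -> SampleArray:
    """Read a sample table and align it to ``snp_map`` order.

    SNPs absent from the file are NC with missing numerics; duplicated SNP
    rows resolve last-wins with a warning.  Chromosome labels must match
    the map's for the SNPs it shares; malformed numeric fields raise
    :class:`SampleTableError` naming the first offending line.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing_cols = [c for c in COLUMNS if c not in raw.columns]
    if missing_cols:
        raise SampleTableError(f"{path}: missing columns {missing_cols}")

    def _numeric(col: str) -> np.ndarray:
        vals = pd.to_numeric(raw[col].replace({"": None, "NaN": None, "NA": None}), errors="coerce")
        bad = vals.isna() & ~raw[col].isin(["", "NaN", "NA", "nan"])
        if bad.any():
            line = int(np.flatnonzero(bad)[0]) + 2  # +1 header, +1 one-based
            raise SampleTableError(
                f"{path}: malformed numeric {col!r} value {raw[col][bad.idxmax()]!r} on line {line}"
            )
        return vals.to_numpy(dtype=float)

    baf = _numeric("B Allele Freq")
    logr = _numeric("Log R Ratio")
    bad_gt = ~raw["GType"].isin(GT_CODES)
    if bad_gt.any():
        line = int(np.flatnonzero(bad_gt)[0]) + 2
        raise SampleTableError(f"{path}: unknown GType on line {line}")
    gtype = raw["GType"].map(GT_CODES).to_numpy(dtype=np.int8)

    if "GC Score" in raw.columns:
        score = _numeric("GC Score")
        gtype = np.where(np.nan_to_num(score, nan=1.0) < gc_threshold, GT_NC, gtype).astype(np.int8)

    known_chrom = dict(zip(snp_map.snp_ids, snp_map.chrom_labels.astype(str)))
    in_map = raw["SNP Name"].isin(known_chrom)
    mismatch = in_map & (raw["Chr"] != raw["SNP Name"].map(known_chrom))
    if mismatch.any():
        line = int(np.flatnonzero(mismatch)[0]) + 2
        raise SampleTableError(
            f"{path}: chromosome label disagrees with map on line {line}"
        )

    dup = raw["SNP Name"].duplicated(keep="last")
    if dup.any():
        logger.warning("%s: %d duplicate SNP rows; keeping last", path, int(dup.sum()))
        warnings.warn(f"{path}: duplicate SNP rows resolved last-wins", stacklevel=2)
        raw = raw[~dup]

    idx = pd.Index(snp_map.snp_ids)
    locs = idx.get_indexer(raw["SNP Name"])
    keep = locs >= 0

    out = SampleArray.empty(str(raw["Sample ID"].iloc[0]) if len(raw) else "unknown", role, snp_map)
    out.gtype[locs[keep]] = gtype[np.flatnonzero(keep)]
    out.baf[locs[keep]] = baf[np.flatnonzero(keep)]
    out.logr[locs[keep]] = logr[np.flatnonzero(keep)]
    return out


# ---------------------------------------------------------------------------
# QC metrics
# ---------------------------------------------------------------------------
def call_rate(sample: SampleArray) -> float:
    """Fraction of map SNPs with a genotype call (the 'coverage rate')."""
    return float(np.mean(sample.gtype != GT_NC))


# genotype codes are B-allele counts, so the set of embryo codes compatible
# with a parental pair follows from one allele drawn per parent
_ALLOWED: dict[tuple[int, int], frozenset[int]] = {}
for _m in (0, 1, 2):
    for _f in (0, 1, 2):
        _mat = {0, 1} if _m == 1 else {_m // 2}
        _pat = {0, 1} if _f == 1 else {_f // 2}
        _ALLOWED[(_m, _f)] = frozenset(a + b for a in _mat for b in _pat)


def mendelian_inconsistency_rate(
    embryo: SampleArray, mother: SampleArray, father: SampleArray
) -> float:
    """Fraction of jointly-called SNPs where the embryo genotype is
    impossible under biparental disomic inheritance.

    Deliberately assumes disomy even for aneuploid embryos — it is a generic
    sample-quality metric (WGA artefacts inflate it), not a karyotype
    inference.
    """
    called = (embryo.gtype != GT_NC) & (mother.gtype != GT_NC) & (father.gtype != GT_NC)
    idx = np.flatnonzero(called)
    if len(idx) == 0:
        return float("nan")
    bad = 0
    e, m, f = embryo.gtype[idx], mother.gtype[idx], father.gtype[idx]
    for (mm, ff), allowed in _ALLOWED.items():
        sel = (m == mm) & (f == ff)
        if sel.any():
            bad += int(np.sum(~np.isin(e[sel], list(allowed))))
    return bad / len(idx)


def qc_metrics(
    sample: SampleArray,
    mother: SampleArray | None = None,
    father: SampleArray | None = None,
    n_informative: int | None = None,
) -> QcMetrics:
    mi = (
        mendelian_inconsistency_rate(sample, mother, father)
        if mother is not None and father is not None
        else None
    )
    return QcMetrics(call_rate(sample), mi, n_informative)
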