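"""The array design: an ordered catalogue of biallelic SNPs.

A :class:`SnpMap` fixes the coordinate system every other object in the
package lives on: samples, truth haplotypes and haplarithm tracks are all
vectors indexed by map position.  SNPs are sorted by (chromosome, bp) with
chromosomes in karyotype order, so each chromosome occupies one contiguous
slice of every per-SNP array.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .karyotype import DEFAULT_KARYOTYPE, Karyotype


@dataclass
class SnpMap:
    """Ordered catalogue of biallelic array SNPs.

    Attributes
    ----------
    df:
        One row per SNP with columns ``snp_id``, ``chrom``, ``pos_bp`` and
        ``b_freq`` (population B-allele frequency used by the simulator;
        ignored when analysing real data).  Sorted by (chrom, pos_bp).
    karyotype:
        Chromosome lengths; every chromosome present in ``df`` must be in
        the karyotype.
    """

    df: pd.DataFrame
    karyotype: Karyotype = field(default_factory=lambda: DEFAULT_KARYOTYPE)

    def __post_init__(self) -> None:
        required = {"snp_id", "chrom", "pos_bp"}
        missing = required - set(self.df.columns)
        if missing:
            raise ValueError(f"SnpMap frame missing columns {sorted(missing)}")
        if self.df["snp_id"].duplicated().any():
            raise ValueError("duplicate snp_id in SnpMap")
        order = {c: i for i, c in enumerate(self.karyotype.chroms)}
        unknown = set(self.df["chrom"]) - set(order)
        if unknown:
            raise ValueError(f"chromosomes absent from karyotype: {sorted(unknown)}")
        key = self.df["chrom"].map(order)
        if not (
            key.is_monotonic_increasing
            and self.df.groupby("chrom", sort=False)["pos_bp"].apply(
                lambda s: s.is_monotonic_increasing
            ).all()
        ):
            self.df = (
                self.df.assign(_k=key)
                .sort_values(["_k", "pos_bp"], kind="mergesort")
                .drop(columns="_k")
                .reset_index(drop=True)
            )
        else:
            self.df = self.df.reset_index(drop=True)
        if "b_freq" not in self.df.columns:
            self.df["b_freq"] = 0.5
        self._slices: dict[str, slice] = {}
        chrom_arr = self.df["chrom"].to_numpy()
        start = 0
        for chrom, n in self.df.groupby("chrom", sort=False).size().items():
            self._slices[str(chrom)] = slice(start, start + n)
            start += n
        del chrom_arr

    # -- basic accessors ---------------------------------------------------
    def __len__(self) -> int:
        return len(self.df)

    @property
    def chroms(self) -> list[str]:
        return list(self._slices)

    @property
    def snp_ids(self) -> np.ndarray:
        return self.df["snp_id"].to_numpy()

    @property
    def pos_bp(self) -> np.ndarray:
        return self.df["pos_bp"].to_numpy()

    @property
    def chrom_labels(self) -> np.ndarray:
        return self.df["chrom"].to_numpy()

    def chrom_slice(self, chrom: str) -> slice:
        return self._slices[chrom]

    def n_snps(self, chrom: str) -> int:
        sl = self._slices[chrom]
        return sl.stop - sl.start

    # -- persistence -------------------------------------------------------
    def to_table(self, path) -> None:
        """Write the map as a tab-separated table (snp_id, chrom, pos, b_freq)."""
        self.df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_table(cls, path, karyotype: Karyotype | None = None) -> "SnpMap":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        if karyotype is None:
            # infer lengths generous enough to contain every mapped SNP
            lengths = {
                str(c): int(g["pos_bp"].max()) + 1
                for c, g in df.groupby("chrom", sort=False)
            }
            karyotype = Karyotype(lengths)
        return cls(df, karyotype)


def build_snp_map(
    karyotype: Karyotype | None = None,
    n_snps: int = 70_000,
    seed: int = 0,
    maf_range: tuple[float, float] = (0.05, 0.95),
) -> SnpMap:
    """Draw a synthetic array design over a karyotype.

    SNP counts per chromosome follow a multinomial proportional to physical
    length (with at least one SNP per chromosome); positions are uniform on
    each chromosome and sorted.  Each SNP also receives a population
    B-allele frequency drawn uniformly from ``maf_range``; founder genotypes
    are later sampled from these frequencies so that heterozygosity and the
    informative-SNP fraction resemble a real outbred array cohort.
    """
    karyotype = karyotype or DEFAULT_KARYOTYPE
    chroms = karyotype.chroms
    if n_snps < len(chroms):
        raise ValueError("n_snps must be at least the number of chromosomes")
    rng = np.random.default_rng(seed)
    lengths = np.array([karyotype.length(c) for c in chroms], dtype=float)
    counts = rng.multinomial(n_snps, lengths / lengths.sum())
    # guarantee coverage of every chromosome
    while (counts == 0).any():
        i = int(np.argmin(counts))
        j = int(np.argmax(counts))
        counts[i] += 1
        counts[j] -= 1

    frames = []
    offset = 0
    for chrom, count in zip(chroms, counts):
        pos = np.sort(rng.integers(1, karyotype.length(chrom) + 1, size=count))
        frames.append(
            pd.DataFrame(
                {
                    "snp_id": [f"SNP{offset + k:06d}" for k in range(count)],
                    "chrom": chrom,
                    "pos_bp": pos,
                }
            )
        )
        offset += count
    df = pd.concat(frames, ignore_index=True)
    lo, hi = maf_range
    df["b_freq"] = rng.uniform(lo, hi, size=len(df))
    return SnpMap(df, karyotype)
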