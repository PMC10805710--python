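"""Karyotype configuration: chromosome names and physical lengths.

The default karyotype is an equine-like complement of 31 autosomes plus X,
with autosome lengths decreasing linearly from 190 Mbp (chromosome 1) to
30 Mbp (chromosome 31) and a 130 Mbp X.  Real assembly lengths (e.g. from
EquCab3.0) can be supplied through :class:`Karyotype` when analysing real
array exports; nothing downstream depends on the synthetic defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, field

MBP = 1_000_000

#: Ordered chromosome labels of the default complement.
DEFAULT_CHROMS: tuple[str, ...] = tuple(str(i) for i in range(1, 32)) + ("X",)


def _default_lengths() -> dict[str, int]:
    lengths = {}
    for i in range(31):
        # linear ramp 190 Mbp -> 30 Mbp across the 31 autosomes
        lengths[str(i + 1)] = int(round((190 - i * (160 / 30)) * MBP))
    lengths["X"] = 130 * MBP
    return lengths


@dataclass(frozen=True)
class Karyotype:
    """An ordered set of chromosomes with physical lengths in bp."""

    lengths: dict[str, int] = field(default_factory=_default_lengths)

    def __post_init__(self) -> None:
        for chrom, length in self.lengths.items():
            if length <= 0:
                raise ValueError(
                    f"chromosome {chrom!r} has non-positive length {length}"
                )

    @property
    def chroms(self) -> list[str]:
        return list(self.lengths)

    @property
    def autosomes(self) -> list[str]:
        return [c for c in self.lengths if c != "X"]

    def __len__(self) -> int:
        return len(self.lengths)

    def length(self, chrom: str) -> int:
        return self.lengths[chrom]


DEFAULT_KARYOTYPE = Karyotype()
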