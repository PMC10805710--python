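"""Per-sample array measurements: genotype call, BAF and LogR per map SNP."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .snp_map import SnpMap

# genotype codes: number of B alleles in the called diploid genotype
GT_AA: int = 0
GT_AB: int = 1
GT_BB: int = 2
GT_NC: int = -1  # no call

GT_LABELS = {GT_AA: "AA", GT_AB: "AB", GT_BB: "BB", GT_NC: "NC"}
GT_CODES = {v: k for k, v in GT_LABELS.items()}

ROLES = (
    "mother",
    "father",
    "grandsire",
    "granddam",
    "embryo",
    "biopsy",
    "blastomere",
    "blastocyst",
)


@dataclass
class SampleArray:
    """One sample's measurements on a :class:`SnpMap`.

    ``gtype`` holds genotype codes (``GT_AA``/``GT_AB``/``GT_BB``/``GT_NC``);
    ``baf`` and ``logr`` are float arrays with NaN for missing values.  An
    NC genotype with a present BAF/LogR is legal — the haplarithm reads the
    continuous BAF signal, not the discrete call.
    """

    sample_id: str
    role: str
    gtype: np.ndarray
    baf: np.ndarray
    logr: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}; expected one of {ROLES}")
        n = len(self.gtype)
        if len(self.baf) != n or len(self.logr) != n:
            raise ValueError("gtype/baf/logr length mismatch")
        self.gtype = np.asarray(self.gtype, dtype=np.int8)
        self.baf = np.asarray(self.baf, dtype=float)
        self.logr = np.asarray(self.logr, dtype=float)

    def __len__(self) -> int:
        return len(self.gtype)

    @property
    def called(self) -> np.ndarray:
        return self.gtype != GT_NC

    @classmethod
    def empty(cls, sample_id: str, role: str, snp_map: SnpMap) -> "SampleArray":
        n = len(snp_map)
        return cls(
            sample_id,
            role,
            np.full(n, GT_NC, dtype=np.int8),
            np.full(n, np.nan),
            np.full(n, np.nan),
        )
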