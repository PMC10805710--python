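"""Tunable analysis parameters with documented defaults."""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

from .segmentation import SegmentationConfig


@dataclass(frozen=True)
class AnalysisConfig:
    """Knobs for segmentation, signature matching and reporting.

    ``signature_tolerance`` is the absolute fit distance (root weighted mean
    squared deviation across LogR and the four subtrack means) below which
    a pure copy-number configuration is accepted.  Mosaicism is called when
    no pure configuration fits, a disomy/aberration mixture improves the
    fit by at least ``mosaic_improvement`` and the estimated aberrant-cell
    fraction lies in ``mosaic_band`` — outside that band the evidence is
    treated as a pure state or noise.
    """

    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    logr_weight: float = 1.0
    subtrack_weight: float = 1.0
    signature_tolerance: float = 0.1
    block_tolerance: float = 0.1
    mosaic_band: tuple[float, float] = (0.2, 0.8)
    mosaic_improvement: float = 2.0
    min_segment_mbp: float = 5.0
    breakpoint_merge_mbp: float = 2.0
    ploidy_pattern_fraction: float = 0.8
    min_chrom_call_fraction: float = 0.9
    min_call_rate: float = 0.2
    min_informative_snps: int = 500

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        d = dict(d)
        seg = d.pop("segmentation", None)
        kwargs = dict(d)
        if seg is not None:
            kwargs["segmentation"] = SegmentationConfig(**seg)
        if "mosaic_band" in kwargs:
            kwargs["mosaic_band"] = tuple(kwargs["mosaic_band"])
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)


DEFAULT_CONFIG = AnalysisConfig()
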