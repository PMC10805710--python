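"""Piecewise-constant least-squares changepoint detection.

A small PELT implementation (pruned exact linear time, L2 cost) drives both
the haplarithm subtrack segmentation and the LogR segmentation.  The cost
of a segment is its within-segment sum of squared deviations; the optimal
partition minimises total cost + penalty x (number of segments), which PELT
solves exactly with pruning.  Subtracks P1/P2 of one parent share
breakpoints: the joint cost sums each group's SSE over the merged,
position-ordered sequence, so a changepoint is placed where either (or
both) subtrack level moves.

The default penalty scales with the track's noise level, estimated
robustly from median absolute first differences, with a positive floor so
noise-free data still yields the minimal segmentation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class SegmentationConfig:
    penalty: float | None = None  # explicit penalty; None = auto
    penalty_scale: float = 6.0  # auto: scale * sigma^2 * log(n)
    penalty_floor: float = 0.05  # keeps the penalty positive on noise-free data
    min_seg_snps: int = 10  # below this a chromosome gets one low-support segment
    min_size: int = 1  # hard minimum points per segment in the search


def robust_sigma(values: np.ndarray, groups: np.ndarray | None = None) -> float:
    """Noise SD estimate from median absolute successive differences.

    With ``groups`` the differences are taken within each group separately
    (subtracks interleave along the chromosome, so cross-group differences
    reflect the level offset between subtracks, not noise)."""
    if groups is None:
        groups = np.zeros(len(values), dtype=int)
    diffs = []
    for g in np.unique(groups):
        v = values[(groups == g) & np.isfinite(values)]
        if len(v) >= 3:
            diffs.append(np.abs(np.diff(v)))
    if not diffs:
        return 0.0
    d = np.concatenate(diffs)
    return float(np.median(d) / (np.sqrt(2.0) * 0.6744897501960817))


def auto_penalty(
    values: np.ndarray,
    config: SegmentationConfig,
    groups: np.ndarray | None = None,
) -> float:
    if config.penalty is not None:
        return config.penalty
    n = max(len(values), 2)
    sigma = robust_sigma(values, groups)
    return max(config.penalty_scale * sigma**2 * np.log(n), config.penalty_floor)


def pelt_grouped(
    values: np.ndarray,
    groups: np.ndarray,
    penalty: float,
    min_size: int = 1,
    n_groups: int = 2,
) -> list[int]:
    """Exact penalised L2 segmentation with group-wise means.

    ``values`` are ordered observations, ``groups`` integer labels in
    ``[0, n_groups)``; a segment's cost is the sum over groups of the SSE
    around that group's segment mean.  Returns interior changepoint indices
    (a changepoint at ``t`` starts a new segment at index ``t``).
    """
    n = len(values)
    if n == 0:
        return []
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)

    # prefix sums per group
    cs = np.zeros((n_groups, n + 1))
    cs2 = np.zeros((n_groups, n + 1))
    cn = np.zeros((n_groups, n + 1))
    for g in range(n_groups):
        sel = groups == g
        x = np.where(sel, values, 0.0)
        cs[g, 1:] = np.cumsum(x)
        cs2[g, 1:] = np.cumsum(x * x)
        cn[g, 1:] = np.cumsum(sel)

    def seg_cost(starts: np.ndarray, end: int) -> np.ndarray:
        total = np.zeros(len(starts))
        for g in range(n_groups):
            cnt = cn[g, end] - cn[g, starts]
            s = cs[g, end] - cs[g, starts]
            s2 = cs2[g, end] - cs2[g, starts]
            total += s2 - s * s / np.maximum(cnt, 1)
        return total

    F = np.full(n + 1, np.inf)
    F[0] = -penalty
    prev = np.zeros(n + 1, dtype=int)
    # admissible candidate buffer: tau joins once t - tau >= min_size
    cand_buf = np.zeros(n + 1, dtype=int)
    n_cand = 0
    for t in range(1, n + 1):
        tau = t - min_size
        if tau >= 0:
            cand_buf[n_cand] = tau
            n_cand += 1
        if n_cand == 0:
            # endpoint too early for any admissible split: one segment from 0
            F[t] = F[0] + seg_cost(np.array([0]), t)[0] + penalty
            prev[t] = 0
            continue
        cand = cand_buf[:n_cand]
        costs = F[cand] + seg_cost(cand, t) + penalty
        best = int(np.argmin(costs))
        F[t] = costs[best]
        prev[t] = cand[best]
        keep = costs - penalty <= F[t]
        kept = cand[keep]
        n_cand = len(kept)
        cand_buf[:n_cand] = kept

    # backtrack
    cps = []
    t = n
    while t > 0:
        s = int(prev[t])
        if s > 0:
            cps.append(s)
        t = s
    return sorted(cps)


def segment_means(
    values: np.ndarray, groups: np.ndarray, changepoints: list[int], n_groups: int = 2
) -> list[dict]:
    """Per-segment group means and counts for a given changepoint set."""
    bounds = [0, *changepoints, len(values)]
    out = []
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        rec = {"start_idx": lo, "stop_idx": hi}
        for g in range(n_groups):
            sel = groups[lo:hi] == g
            vals = values[lo:hi][sel]
            rec[f"mean_{g}"] = float(vals.mean()) if len(vals) else float("nan")
            rec[f"n_{g}"] = int(sel.sum())
        out.append(rec)
    return out
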