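"""Differentially methylated region (DMR) calling.

The rule is purely threshold-based, no test statistic: eligible CpGs are
positions present in both samples with coverage >= 4 in both and a
per-CpG methylation difference of at least 10%; a candidate window is
five consecutive eligible CpGs of uniform difference sign with adjacent
genomic gaps of at most 1 kb; the window qualifies when the mean
|difference| reaches 40%. Overlapping qualifying windows of the same
sign merge into one region spanning the first to the last CpG
(half-open: end = last CpG position + 1).

``dmr_oracle`` re-derives the same rule by explicit enumeration of every
window, shares no code with the scanning implementation, and exists to
cross-check it on small inputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_tracks import CompartmethError, Interval
from .methylome import MethylationCallSet


@dataclass(frozen=True)
class DmrParams:
    mean_delta: float = 0.40  # mean |level_a - level_b| over the window
    window_cpgs: int = 5
    min_coverage: int = 4  # required in both samples
    min_cpg_delta: float = 0.10
    max_gap: int = 1_000  # bp between adjacent eligible CpGs

    def __post_init__(self) -> None:
        if not 0 < self.min_cpg_delta <= self.mean_delta <= 1:
            raise CompartmethError("require 0 < min_cpg_delta <= mean_delta <= 1")
        if self.window_cpgs < 2 or self.min_coverage < 1 or self.max_gap <= 0:
            raise CompartmethError("invalid DMR parameters")


@dataclass
class Dmr:
    interval: Interval
    direction: str  # 'hyper' (a > b) or 'hypo' (a < b)
    n_cpgs: int
    mean_delta: float
    positions: np.ndarray
    deltas: np.ndarray  # level_a - level_b per CpG


def _eligible_table(
    a: MethylationCallSet, b: MethylationCallSet, params: DmrParams
) -> pd.DataFrame:
    """Join the two call sets and keep eligible CpGs, per the rule."""
    for name, calls in (("a", a), ("b", b)):
        if not calls.combined:
            raise CompartmethError(f"call set {name} is not strand-combined")
        cpg = calls.cpg()
        if cpg.duplicated(subset=["chrom", "pos"]).any():
            raise CompartmethError(f"call set {name} has duplicate CpG positions")
        by_chrom = cpg.groupby("chrom", sort=False)["pos"]
        if (by_chrom.apply(lambda s: (np.diff(s.to_numpy()) <= 0).any())).any():
            raise CompartmethError(f"call set {name} is not position-sorted")
    left = a.cpg()[["chrom", "pos", "meth", "total"]]
    right = b.cpg()[["chrom", "pos", "meth", "total"]]
    joined = left.merge(right, on=["chrom", "pos"], suffixes=("_a", "_b"))
    joined = joined[
        (joined["total_a"] >= params.min_coverage)
        & (joined["total_b"] >= params.min_coverage)
    ].copy()
    joined["delta"] = (
        joined["meth_a"] / joined["total_a"] - joined["meth_b"] / joined["total_b"]
    )
    joined = joined[joined["delta"].abs() >= params.min_cpg_delta]
    return joined.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)


def _region_from(
    chrom: str, pos: np.ndarray, deltas: np.ndarray, lo: int, hi: int
) -> Dmr:
    """Build a Dmr from eligible-CpG index range [lo, hi] (inclusive)."""
    p = pos[lo : hi + 1]
    d = deltas[lo : hi + 1]
    return Dmr(
        Interval(chrom, int(p[0]), int(p[-1]) + 1),
        "hyper" if d[0] > 0 else "hypo",
        hi - lo + 1,
        float(np.abs(d).mean()),
        p.copy(),
        d.copy(),
    )


def call_dmrs(
    a: MethylationCallSet, b: MethylationCallSet, params: DmrParams | None = None
) -> list[Dmr]:
    """Scan for DMRs between two strand-combined CpG call sets.

    Output is ordered by coordinate. Swapping the inputs yields the same
    intervals with hyper/hypo flipped.
    """
    params = params or DmrParams()
    table = _eligible_table(a, b, params)
    k = params.window_cpgs
    out: list[Dmr] = []
    for chrom, sub in table.groupby("chrom", sort=True):
        pos = sub["pos"].to_numpy()
        deltas = sub["delta"].to_numpy()
        n = pos.size
        if n < k:
            continue
        # segment at sign changes and oversized gaps: inside a segment every
        # k-window automatically satisfies sign uniformity and the gap rule
        sign = np.sign(deltas)
        brk = (sign[1:] != sign[:-1]) | (np.diff(pos) > params.max_gap)
        seg_starts = np.concatenate([[0], np.flatnonzero(brk) + 1, [n]])
        for s, e in zip(seg_starts[:-1], seg_starts[1:]):
            length = e - s
            if length < k:
                continue
            absd = np.abs(deltas[s:e])
            csum = np.concatenate([[0.0], np.cumsum(absd)])
            win_means = (csum[k:] - csum[:-k]) / k  # mean over [i, i+k)
            qual = np.flatnonzero(win_means >= params.mean_delta)
            if qual.size == 0:
                continue
            # chain windows whose CpG index ranges overlap
            run_start = qual[0]
            prev = qual[0]
            for q in qual[1:]:
                if q - prev <= k - 1:
                    prev = q
                else:
                    out.append(
                        _region_from(chrom, pos, deltas, s + run_start, s + prev + k - 1)
                    )
                    run_start = prev = q
            out.append(
                _region_from(chrom, pos, deltas, s + run_start, s + prev + k - 1)
            )
    out.sort(key=lambda d: (d.interval.chrom, d.interval.start))
    return out


def dmr_oracle(
    a: MethylationCallSet, b: MethylationCallSet, params: DmrParams | None = None
) -> list[Dmr]:
    """Brute-force re-derivation of the DMR rule by window enumeration.

    Intended for small inputs (<= ~5,000 CpGs); used to cross-check
    :func:`call_dmrs`.
    """
    params = params or DmrParams()
    table = _eligible_table(a, b, params)
    k = params.window_cpgs
    results: list[Dmr] = []
    for chrom, sub in table.groupby("chrom", sort=True):
        pos = [int(x) for x in sub["pos"]]
        deltas = [float(x) for x in sub["delta"]]
        n = len(pos)
        windows = []  # (start_index, end_index) of qualifying windows
        for i in range(n - k + 1):
            w_pos = pos[i : i + k]
            w_del = deltas[i : i + k]
            if any(
                w_pos[j + 1] - w_pos[j] > params.max_gap for j in range(k - 1)
            ):
                continue
            if not (all(d > 0 for d in w_del) or all(d < 0 for d in w_del)):
                continue
            if sum(abs(d) for d in w_del) / k < params.mean_delta:
                continue
            windows.append((i, i + k - 1))
        merged: list[list[int]] = []
        for w in windows:
            if merged and w[0] <= merged[-1][1] and (
                deltas[w[0]] > 0) == (deltas[merged[-1][0]] > 0):
                merged[-1][1] = max(merged[-1][1], w[1])
            else:
                merged.append([w[0], w[1]])
        for lo, hi in merged:
            p = pos[lo : hi + 1]
            d = deltas[lo : hi + 1]
            results.append(
                Dmr(
                    Interval(chrom, p[0], p[-1] + 1),
                    "hyper" if d[0] > 0 else "hypo",
                    hi - lo + 1,
                    sum(abs(x) for x in d) / len(d),
                    np.array(p),
                    np.array(d),
                )
            )
    results.sort(key=lambda d: (d.interval.chrom, d.interval.start))
    return results


def dmrs_to_intervals(dmrs: list[Dmr]) -> list[Interval]:
    return [
        Interval(d.interval.chrom, d.interval.start, d.interval.end,
                 value=round(100 * d.mean_delta), label=d.direction)
        for d in dmrs
    ]
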