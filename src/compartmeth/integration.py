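"""Compartment-methylation integration statistics.

Brings the Hi-C and methylome sides together: where methylation features
fall relative to A/B compartments, how strongly a signal track (for
example 1-kb CHH methylation) is enriched in A compartments or in fully
methylated regions, how common-compartment methylation averages evolve
along a differentiation series, stage profiles of switching
compartments, and a two-dimensional PCA embedding of samples.

Significance is assessed with seeded circular-shift permutation tests:
features (or the signal track) are rotated around each chromosome by a
random offset and the statistic recomputed; this respects genomic
autocorrelation and needs no distributional assumptions. The empirical
p-value is (1 + #{permutations >= observed}) / (n + 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .compartments import CommonCompartmentTrack, CompartmentTrack
from .core_tracks import (
    BinTrack,
    CompartmethError,
    Interval,
    merge_intervals,
    track_to_intervals,
)
from .methylome import ChhBinTrack, MethylationCallSet, mean_methylation_in

logger = logging.getLogger("compartmeth")

DEFAULT_N_PERMUTATIONS = 1_000


@dataclass
class CompartmentEnrichment:
    feature_class: str
    fraction_in_a: float  # of assigned features (or signal mean ratio basis)
    genomic_fraction_a: float
    fold: float
    p_value: float
    n_features: int = 0
    n_unassigned: int = 0
    note: str = ""


def _a_intervals(track: CompartmentTrack) -> list[Interval]:
    return track_to_intervals(track.track, lambda v: v > 0)


def _genomic_a_fraction(track: CompartmentTrack) -> float:
    lab = track.labels()
    widths = track.bin_table.widths()
    assigned = lab != "."
    if not assigned.any():
        raise CompartmethError("no assigned bins")
    return float(widths[lab == "A"].sum() / widths[assigned].sum())


def feature_compartment_fractions(
    features: list[Interval],
    track: CompartmentTrack,
    n_permutations: int = DEFAULT_N_PERMUTATIONS,
    seed: int = 0,
) -> CompartmentEnrichment:
    """Fraction of features in A compartments, with a permutation p-value.

    Each feature is assigned to A or B by majority base overlap (> 50% of
    its bases inside bins of that label; an exact tie or majority overlap
    with unassigned bins leaves it unassigned). The fold is the A fraction
    over the genomic A fraction; the p-value comes from circularly
    shifting all features per chromosome and recomputing the A fraction.
    """
    if not features:
        raise CompartmethError("empty feature list")
    genome = track.bin_table.genome
    a_frac_genome = _genomic_a_fraction(track)
    a_union = _a_intervals(track)
    b_union = track_to_intervals(track.track, lambda v: v < 0)

    def assign_fraction(shift_by: dict[str, int]) -> tuple[int, int, int]:
        n_a = n_b = n_un = 0
        for iv in features:
            length = genome.length(iv.chrom)
            off = shift_by.get(iv.chrom, 0)
            s = (iv.start + off) % length
            e = s + iv.width
            pieces = (
                [Interval(iv.chrom, s, e)]
                if e <= length
                else [Interval(iv.chrom, s, length), Interval(iv.chrom, 0, e - length)]
            )
            in_a = sum(_covered(p, a_union) for p in pieces) / iv.width
            in_b = sum(_covered(p, b_union) for p in pieces) / iv.width
            if in_a > 0.5:
                n_a += 1
            elif in_b > 0.5:
                n_b += 1
            else:
                n_un += 1
        return n_a, n_b, n_un

    n_a, n_b, n_un = assign_fraction({})
    if n_a + n_b == 0:
        raise CompartmethError("no feature could be assigned to A or B")
    obs = n_a / (n_a + n_b)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        shifts = {
            chrom: int(rng.integers(0, genome.length(chrom)))
            for chrom in genome.names
        }
        pa, pb, _ = assign_fraction(shifts)
        frac = pa / (pa + pb) if pa + pb else 0.0
        if frac >= obs:
            hits += 1
    p = (1 + hits) / (n_permutations + 1)
    return CompartmentEnrichment(
        feature_class="features",
        fraction_in_a=obs,
        genomic_fraction_a=a_frac_genome,
        fold=obs / a_frac_genome if a_frac_genome > 0 else float("inf"),
        p_value=p,
        n_features=n_a + n_b,
        n_unassigned=n_un,
    )


def _covered(piece: Interval, union: list[Interval]) -> int:
    return sum(
        max(0, min(piece.end, t.end) - max(piece.start, t.start))
        for t in union
        if t.chrom == piece.chrom
    )


def signal_compartment_enrichment(
    signal: BinTrack | ChhBinTrack,
    compartments: CompartmentTrack,
    context: list[Interval] | None = None,
    n_permutations: int = DEFAULT_N_PERMUTATIONS,
    seed: int = 0,
    zero_signal_eps: float = 1e-9,
) -> CompartmentEnrichment:
    """Fold enrichment of a signal track in A compartments (or a context).

    The selected bin set is either the bins inside ``context`` intervals
    (when given) or the bins assigned to A. The fold is the mean signal in
    the selected set over the genome-wide mean over unmasked bins. The
    null circularly shifts the signal per chromosome. When the genome-wide
    mean signal is ~0 the result is flagged ``no signal``.
    """
    track = signal.level_track() if isinstance(signal, ChhBinTrack) else signal
    bt = track.bin_table
    genome = bt.genome
    comp_bt = compartments.bin_table
    if comp_bt.genome != genome:
        raise CompartmethError("signal and compartments are on different genomes")
    # selection mask over the signal's bins
    if context is not None:
        merged = merge_intervals(context)
        selected = np.zeros(bt.n_bins, dtype=bool)
        for iv in merged:
            first = bt.bin_index(iv.chrom, iv.start)
            last = bt.bin_index(iv.chrom, min(iv.end - 1, genome.length(iv.chrom) - 1))
            selected[first : last + 1] = True
        label = "context"
    else:
        # a signal bin maps to the compartment bin containing its start
        lab = compartments.labels()
        selected = np.zeros(bt.n_bins, dtype=bool)
        for chrom in genome.names:
            sl = bt.chrom_slice(chrom)
            starts = bt.starts_of(chrom)
            comp_idx = comp_bt.offset_of(chrom) + starts // comp_bt.bin_size
            selected[sl] = lab[comp_idx] == "A"
        label = "A"
    usable = track.valid
    if not (usable & selected).any():
        raise CompartmethError("no unmasked overlap between signal and selection")
    genome_mean = float(track.values[usable].mean())
    a_frac = _genomic_a_fraction(compartments)
    if abs(genome_mean) <= zero_signal_eps:
        return CompartmentEnrichment(
            label, float("nan"), a_frac, float("nan"), 1.0, note="no signal"
        )

    def fold_for(values: np.ndarray, valid: np.ndarray) -> float:
        sel = valid & selected
        return float(values[sel].mean() / values[valid].mean())

    obs = fold_for(track.values, track.valid)
    rng = np.random.default_rng(seed)
    # vectorized circular shifts, one offset per chromosome per permutation
    folds = np.zeros(n_permutations)
    sel_sum = np.zeros(n_permutations)
    sel_cnt = np.zeros(n_permutations)
    all_sum = np.zeros(n_permutations)
    all_cnt = np.zeros(n_permutations)
    for chrom in genome.names:
        sl = bt.chrom_slice(chrom)
        v = track.values[sl]
        ok = track.valid[sl]
        sel = selected[sl]
        n = v.size
        if n == 0:
            continue
        offs = rng.integers(0, n, size=n_permutations)
        idx = (np.arange(n)[None, :] - offs[:, None]) % n  # shifted signal
        vs = v[idx]
        oks = ok[idx]
        sel_sum += (vs * oks * sel[None, :]).sum(axis=1)
        sel_cnt += (oks & sel[None, :]).sum(axis=1)
        all_sum += (vs * oks).sum(axis=1)
        all_cnt += oks.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        folds = (sel_sum / sel_cnt) / (all_sum / all_cnt)
    hits = int(np.sum(folds[np.isfinite(folds)] >= obs))
    p = (1 + hits) / (n_permutations + 1)
    return CompartmentEnrichment(
        label, float("nan"), a_frac, obs, p, n_features=int(selected.sum())
    )


def compartment_mean_methylation_by_stage(
    cohort_calls: dict[str, MethylationCallSet],
    common: CommonCompartmentTrack,
    min_coverage: int = 4,
) -> dict[str, tuple[float, float]]:
    """Mean CpG methylation in common-A and common-B bins, per stage.

    Returns an ordered {stage: (mean_A, mean_B)} table.
    """
    if len(cohort_calls) < 2:
        raise CompartmethError("need >= 2 stages")
    a_ivs = common.intervals_of("common-A")
    b_ivs = common.intervals_of("common-B")
    if not a_ivs or not b_ivs:
        raise CompartmethError("no common compartment bins")
    out: dict[str, tuple[float, float]] = {}
    for stage, calls in cohort_calls.items():
        out[stage] = (
            mean_methylation_in(calls, a_ivs, min_coverage),
            mean_methylation_in(calls, b_ivs, min_coverage),
        )
    return out


@dataclass
class StageProfile:
    stages: list[str]
    lmr_count: list[int]
    pmd_bases: list[int]
    mean_expression: list[float]
    mean_methylation: list[float]


def stage_profiles(
    regions: list[Interval],
    stages: list[str],
    segments_by_stage: dict[str, list],
    expression_by_stage: dict[str, BinTrack],
    calls_by_stage: dict[str, MethylationCallSet],
    min_coverage: int = 4,
) -> StageProfile:
    """Per-stage feature profile inside a fixed set of regions.

    For each stage: the number of LMR segments overlapping the regions,
    the PMD base coverage inside them, the mean expression-track value
    over bins inside them, and the pooled mean CpG methylation.
    """
    if not regions:
        raise CompartmethError("empty region selection")
    merged = merge_intervals(regions)
    lmr_counts, pmd_bases, mean_expr, mean_meth = [], [], [], []
    for stage in stages:
        segs = segments_by_stage[stage]
        lmr = [s.interval for s in segs if s.seg_class == "LMR"]
        pmd = [s.interval for s in segs if s.seg_class == "PMD"]
        lmr_counts.append(
            sum(
                1
                for iv in lmr
                if any(
                    iv.chrom == r.chrom and iv.start < r.end and r.start < iv.end
                    for r in merged
                )
            )
        )
        pmd_bases.append(
            sum(_covered(r, merge_intervals(pmd)) for r in merged) if pmd else 0
        )
        expr = expression_by_stage[stage]
        bt = expr.bin_table
        sel = np.zeros(bt.n_bins, dtype=bool)
        for r in merged:
            first = bt.bin_index(r.chrom, r.start)
            last = bt.bin_index(r.chrom, min(r.end - 1, bt.genome.length(r.chrom) - 1))
            sel[first : last + 1] = True
        sel &= expr.valid
        mean_expr.append(float(expr.values[sel].mean()) if sel.any() else float("nan"))
        mean_meth.append(
            mean_methylation_in(calls_by_stage[stage], merged, min_coverage)
        )
    return StageProfile(list(stages), lmr_counts, pmd_bases, mean_expr, mean_meth)


@dataclass
class SampleEmbedding:
    sample_names: list[str]
    coordinates: np.ndarray  # samples x 2
    variance_explained: tuple[float, float]


def sample_pca(
    samples: dict[str, np.ndarray] | dict[str, BinTrack],
) -> SampleEmbedding:
    """Top-2 PCA embedding of a samples x features matrix.

    Accepts per-sample value vectors (with NaN as missing) or BinTracks;
    only jointly defined columns enter, mean-centered. The embedding is
    deterministic: each axis is oriented so the first sample's coordinate
    is non-negative.
    """
    if len(samples) < 3:
        raise CompartmethError("need >= 3 samples")
    names = list(samples.keys())
    rows = []
    for v in samples.values():
        if isinstance(v, BinTrack):
            row = np.where(v.valid, v.values, np.nan)
        else:
            row = np.asarray(v, dtype=float)
        rows.append(row)
    x = np.vstack(rows)
    joint = np.isfinite(x).all(axis=0)
    if joint.sum() < 3:
        raise CompartmethError("fewer than 3 jointly defined columns")
    x = x[:, joint]
    x = x - x.mean(axis=0, keepdims=True)
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    coords = u[:, :2] * s[:2]
    if coords.shape[1] < 2:
        coords = np.hstack([coords, np.zeros((coords.shape[0], 1))])
    total = float((s**2).sum())
    var = (
        (float(s[0] ** 2 / total), float(s[1] ** 2 / total) if s.size > 1 else 0.0)
        if total > 0
        else (0.0, 0.0)
    )
    for axis in range(2):
        col = coords[:, axis]
        anchor = next((c for c in col if abs(c) > 1e-12), 0.0)
        if anchor < 0:
            coords[:, axis] = -col
    return SampleEmbedding(names, coords, var)
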