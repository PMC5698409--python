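"""A/B compartment inference and compartment algebra.

Per chromosome, the leading principal component (PC1) of the Pearson
correlation matrix of observed/expected Hi-C rows separates the two
megabase-scale chromatin classes; the sign convention is A for PC1 > 0
and B for PC1 < 0, with PC1 = 0 left unassigned. Because the eigenvector
sign is arbitrary, each chromosome's component is oriented so that its
correlation with an activity track (gene density, expression, or any
active-chromatin proxy) is non-negative. Among the first three components
the one most correlated (in absolute value) with the activity track is
chosen, a reproducible surrogate for the manual curation this analysis
otherwise requires.

The differential rule between two samples is: a bin qualifies when the
PC1 signs differ and |PC1_a - PC1_b| >= delta (default 1.0), and a region
requires at least two consecutive qualifying bins of the same direction.
PC1 tracks are variance-standardized per chromosome before differential
calling by default, so the delta threshold is meaningful on any input
scale; this can be switched off.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, stats

from .contact_matrix import ContactMatrix, expected_by_distance, oe_correlation
from .core_tracks import BinTable, BinTrack, CompartmethError, Interval

logger = logging.getLogger("compartmeth")

DEFAULT_DELTA_PC1 = 1.0
DEFAULT_MIN_BINS = 2
N_CANDIDATE_PCS = 3


@dataclass
class CompartmentTrack:
    """Per-bin PC1 values with A/B labels and orientation evidence."""

    track: BinTrack
    orientation_evidence: dict[str, float] = field(default_factory=dict)
    pc_choice: dict[str, int] = field(default_factory=dict)

    @property
    def bin_table(self) -> BinTable:
        return self.track.bin_table

    def labels(self) -> np.ndarray:
        """Per-bin label: 'A' (PC1>0), 'B' (PC1<0), '.' (0 or masked)."""
        out = np.full(self.bin_table.n_bins, ".", dtype="<U1")
        v, ok = self.track.values, self.track.valid
        out[ok & (v > 0)] = "A"
        out[ok & (v < 0)] = "B"
        return out


@dataclass
class DifferentialCompartmentRegion:
    """A maximal run of >= min_bins consecutive bins switching compartment."""

    interval: Interval
    direction: str  # "A->B" or "B->A", sample a relative to sample b
    delta_pc1: np.ndarray
    n_bins: int


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    if x.size < 2 or np.std(x) == 0 or np.std(y) == 0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


def call_compartments(
    m: ContactMatrix,
    activity: BinTrack,
    scale_by_eigenvalue: bool = True,
    standardize: bool = True,
    n_candidates: int = N_CANDIDATE_PCS,
) -> CompartmentTrack:
    """Infer the A/B compartment eigenvector per chromosome.

    Parameters
    ----------
    m
        Balanced contact matrix.
    activity
        Per-bin proxy of active chromatin on the same bin table, used for
        component selection and orientation.
    scale_by_eigenvalue
        Scale the unit eigenvector by sqrt(eigenvalue), the conventional
        principal-component scaling.
    standardize
        Divide each chromosome's PC1 by its standard deviation over
        unmasked bins, giving unit variance per chromosome.
    """
    if not m.balanced:
        raise CompartmethError("compartment calling requires a balanced matrix")
    if activity.bin_table != m.bin_table:
        raise CompartmethError("activity track is on a different bin table")
    bt = m.bin_table
    expected = expected_by_distance(m)
    corr = oe_correlation(m, expected)
    values = np.zeros(bt.n_bins)
    valid = np.zeros(bt.n_bins, dtype=bool)
    evidence: dict[str, float] = {}
    choice: dict[str, int] = {}
    short = bt.short_bin_mask()
    for chrom in m.chroms():
        sl = bt.chrom_slice(chrom)
        usable = m.mask[chrom] & ~short[sl]
        c = corr[chrom]
        idx = np.flatnonzero(usable)  # chromosome-local
        sub = c[np.ix_(idx, idx)]
        if idx.size < 3 or np.isnan(sub).any():
            logger.warning("%s: degenerate correlation matrix; unassigned", chrom)
            continue
        n = sub.shape[0]
        k = min(n_candidates, n)
        evals, evecs = linalg.eigh(sub, subset_by_index=(n - k, n - 1))
        evals, evecs = evals[::-1], evecs[:, ::-1]  # descending
        act_vals, act_ok = activity.chrom_values(chrom)
        act = act_vals[idx]
        act_usable = act_ok[idx]
        best, best_r = 0, 0.0
        for p in range(k):
            r = _pearson(evecs[act_usable, p], act[act_usable])
            if abs(r) > abs(best_r):
                best, best_r = p, r
        vec = evecs[:, best]
        if evals[best] <= 0:
            logger.warning("%s: non-positive leading eigenvalue; unassigned", chrom)
            continue
        if scale_by_eigenvalue:
            vec = vec * np.sqrt(evals[best])
        if best_r < 0:
            vec = -vec
            best_r = -best_r
        if abs(best_r) < 0.1:
            logger.warning(
                "%s: orientation evidence weak (|r|=%.3f); component unreliable",
                chrom,
                abs(best_r),
            )
        if standardize:
            sd = vec.std()
            if sd > 0:
                vec = vec / sd
        values[sl.start + idx] = vec
        valid[sl.start + idx] = True
        evidence[chrom] = best_r
        choice[chrom] = best + 1
        if best != 0:
            logger.info("%s: selected PC%d for the A/B pattern", chrom, best + 1)
    return CompartmentTrack(BinTrack(bt, values, valid), evidence, choice)


def differential_compartments(
    a: CompartmentTrack,
    b: CompartmentTrack,
    delta: float = DEFAULT_DELTA_PC1,
    min_bins: int = DEFAULT_MIN_BINS,
    standardize: bool = True,
) -> list[DifferentialCompartmentRegion]:
    """Regions where two samples disagree in compartment.

    A bin qualifies when both tracks are assigned (nonzero, unmasked), the
    signs differ, and |PC1_a - PC1_b| >= delta. Maximal consecutive runs of
    qualifying bins of uniform direction with >= min_bins bins are
    reported; runs of mixed direction are split at direction changes.
    Swapping the inputs flips every region's direction and leaves the
    intervals unchanged.
    """
    if a.bin_table != b.bin_table:
        raise CompartmethError("tracks are on different bin tables")
    bt = a.bin_table
    regions: list[DifferentialCompartmentRegion] = []
    for chrom in bt.genome.names:
        va, oka = a.track.chrom_values(chrom)
        vb, okb = b.track.chrom_values(chrom)
        if standardize:
            va = _standardized(va, oka)
            vb = _standardized(vb, okb)
        qualifies = (
            oka
            & okb
            & (np.sign(va) != np.sign(vb))
            & (va != 0)
            & (vb != 0)
            & (np.abs(va - vb) >= delta)
        )
        direction = np.where(va > 0, 1, -1)  # 1: A->B, -1: B->A
        starts, ends = bt.starts_of(chrom), bt.ends_of(chrom)
        i = 0
        n = qualifies.size
        while i < n:
            if not qualifies[i]:
                i += 1
                continue
            j = i
            while j + 1 < n and qualifies[j + 1] and direction[j + 1] == direction[i]:
                j += 1
            if j - i + 1 >= min_bins:
                regions.append(
                    DifferentialCompartmentRegion(
                        Interval(chrom, int(starts[i]), int(ends[j])),
                        "A->B" if direction[i] == 1 else "B->A",
                        (va - vb)[i : j + 1].copy(),
                        j - i + 1,
                    )
                )
            i = j + 1
    return regions


def _standardized(v: np.ndarray, ok: np.ndarray) -> np.ndarray:
    if ok.any():
        sd = v[ok].std()
        if sd > 0:
            out = v.copy()
            out[ok] = v[ok] / sd
            return out
    return v


@dataclass
class CommonCompartmentTrack:
    """Per-bin label over a cohort: common-A, common-B, dynamic, unassigned."""

    bin_table: BinTable
    labels: np.ndarray  # '<U10' array of {common-A, common-B, dynamic, unassigned}

    def intervals_of(self, label: str) -> list[Interval]:
        from .core_tracks import merge_intervals

        bt = self.bin_table
        ivs = []
        for chrom in bt.genome.names:
            sl = bt.chrom_slice(chrom)
            starts, ends = bt.starts_of(chrom), bt.ends_of(chrom)
            for k in np.flatnonzero(self.labels[sl] == label):
                ivs.append(Interval(chrom, int(starts[k]), int(ends[k])))
        return merge_intervals(ivs) if ivs else []


def common_compartments(tracks: list[CompartmentTrack]) -> CommonCompartmentTrack:
    """Label bins by cohort-wide compartment consistency.

    common-A iff PC1 > 0 in every track; common-B iff PC1 < 0 in every
    track; any bin unassigned in any track is unassigned; everything else
    is dynamic. Invariant under permutation of the input tracks.
    """
    if len(tracks) < 2:
        raise CompartmethError("common compartments need >= 2 tracks")
    bt = tracks[0].bin_table
    for t in tracks[1:]:
        if t.bin_table != bt:
            raise CompartmethError("tracks are on different bin tables")
    lab = np.stack([t.labels() for t in tracks])
    out = np.full(bt.n_bins, "dynamic", dtype="<U10")
    out[(lab == "A").all(axis=0)] = "common-A"
    out[(lab == "B").all(axis=0)] = "common-B"
    out[(lab == ".").any(axis=0)] = "unassigned"
    return CommonCompartmentTrack(bt, out)


def rebin_track(track: BinTrack, bin_size: int) -> BinTrack:
    """Rebin to a coarser bin size by the mean of constituent unmasked bins.

    A coarse bin with more than 50% of its constituent fine bins masked is
    masked.
    """
    bt = track.bin_table
    if bin_size == bt.bin_size:
        return track.copy()
    if bin_size % bt.bin_size != 0:
        raise CompartmethError("target bin size must be a multiple of the source")
    coarse = BinTable(bt.genome, bin_size)
    values = np.zeros(coarse.n_bins)
    valid = np.zeros(coarse.n_bins, dtype=bool)
    factor = bin_size // bt.bin_size
    for chrom in bt.genome.names:
        v, ok = track.chrom_values(chrom)
        off = coarse.offset_of(chrom)
        for k in range(coarse.n_bins_of(chrom)):
            seg_v = v[k * factor : (k + 1) * factor]
            seg_ok = ok[k * factor : (k + 1) * factor]
            if seg_ok.sum() > seg_ok.size / 2:
                values[off + k] = seg_v[seg_ok].mean()
                valid[off + k] = True
    return BinTrack(coarse, values, valid)


def pc1_correlation(
    a: CompartmentTrack, b: CompartmentTrack, bin_size: int | None = None
) -> tuple[float, float]:
    """Genome-wide Pearson correlation of two PC1 tracks; returns (r, r^2).

    Tracks may be rebinned to a coarser ``bin_size`` first (e.g. 500 kb for
    biological replicates).
    """
    ta, tb = a.track, b.track
    if bin_size is not None:
        ta, tb = rebin_track(ta, bin_size), rebin_track(tb, bin_size)
    if ta.bin_table != tb.bin_table:
        raise CompartmethError("tracks are on different bin tables")
    joint = ta.valid & tb.valid
    if joint.sum() < 3:
        raise CompartmethError("fewer than 3 jointly unmasked bins")
    r, _ = stats.pearsonr(ta.values[joint], tb.values[joint])
    return float(r), float(r * r)


def compartment_fraction(track: CompartmentTrack) -> float:
    """Fraction of the assigned genome (by width) labeled A."""
    lab = track.labels()
    widths = track.bin_table.widths()
    assigned = lab != "."
    if not assigned.any():
        raise CompartmethError("no assigned bins")
    return float(widths[lab == "A"].sum() / widths[assigned].sum())
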