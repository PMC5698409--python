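"""Multi-scale TAD-separation (insulation) score and boundary calling.

For a window depth w (in bins) and bin i, the diamond mean is the mean
balanced contact between the w bins upstream and the w bins downstream
of the boundary between bins i-1 and i. Low diamond means mark
insulation: TAD boundaries. Scores are z-transformed per scale and per
chromosome and averaged over scales (defaults: depths 300 kb to 3 Mb in
300-kb steps, the multi-scale range used for 40-kb matrices). Boundaries
are score minima with a minimum prominence, greedily selected from the
deepest up, enforcing a minimum pairwise distance (default 400 kb).

Depths that are not whole multiples of the bin size are rounded to the
nearest whole number of bins (and deduplicated) with a logged notice.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal, stats

from .contact_matrix import ContactMatrix
from .core_tracks import BinTrack, CompartmethError

logger = logging.getLogger("compartmeth")

DEFAULT_MIN_DEPTH = 300_000
DEFAULT_MAX_DEPTH = 3_000_000
DEFAULT_STEP = 300_000
DEFAULT_MIN_BOUNDARY_DISTANCE = 400_000
DEFAULT_MIN_PROMINENCE = 0.5  # z-units


@dataclass
class InsulationTrack:
    track: BinTrack
    scales: list[int]  # window depths in bp actually used (rounded to bins)


@dataclass
class TadBoundary:
    chrom: str
    bin: int  # chromosome-local bin index; boundary sits at the bin's start
    position: int  # genomic position of the boundary (bin start)
    score: float
    prominence: float


def _depths_in_bins(
    bin_size: int, min_depth: int, max_depth: int, step: int
) -> list[int]:
    if max_depth < min_depth:
        raise CompartmethError("max_depth < min_depth")
    if step <= 0:
        raise CompartmethError("step must be positive")
    depths = np.arange(min_depth, max_depth + 1, step)
    ws = sorted({max(1, int(round(d / bin_size))) for d in depths})
    if any(d % bin_size for d in depths):
        logger.info(
            "depths rounded to whole bins of %d bp: windows %s bins", bin_size, ws
        )
    return ws


def tad_score(
    m: ContactMatrix,
    min_depth: int = DEFAULT_MIN_DEPTH,
    max_depth: int = DEFAULT_MAX_DEPTH,
    step: int = DEFAULT_STEP,
) -> InsulationTrack:
    """Multi-scale insulation score on the balanced matrix.

    Per scale w and chromosome, score[i] = mean of M over
    [i-w, i) x [i, i+w) restricted to unmasked bins, z-transformed over
    the chromosome's defined bins; the final score is the mean over
    scales. Bins within w of a chromosome end are masked at that scale;
    bins masked at every scale stay masked.
    """
    if not m.balanced:
        raise CompartmethError("insulation requires a balanced matrix")
    bt = m.bin_table
    windows = _depths_in_bins(bt.bin_size, min_depth, max_depth, step)
    values = np.zeros(bt.n_bins)
    valid = np.zeros(bt.n_bins, dtype=bool)
    for chrom in m.chroms():
        mat = m.matrices[chrom]
        usable = m.mask[chrom]
        n = mat.shape[0]
        per_scale = np.full((len(windows), n), np.nan)
        for si, w in enumerate(windows):
            raw = np.full(n, np.nan)
            for i in range(w, n - w + 1):
                if i == n:
                    break
                block = mat[i - w : i, i : i + w]
                ok = np.outer(usable[i - w : i], usable[i : i + w])
                if ok.any():
                    raw[i] = block[ok].mean()
            defined = np.isfinite(raw)
            if defined.sum() >= 2 and np.nanstd(raw) > 0:
                z = np.full(n, np.nan)
                z[defined] = stats.zscore(raw[defined])
                per_scale[si] = z
            elif defined.any():
                z = np.full(n, np.nan)
                z[defined] = 0.0
                per_scale[si] = z
        n_def = np.isfinite(per_scale).sum(axis=0)
        with np.errstate(invalid="ignore"):
            mean_score = np.nansum(per_scale, axis=0) / np.maximum(n_def, 1)
        defined = n_def > 0
        sl = bt.chrom_slice(chrom)
        values[sl][defined] = mean_score[defined]
        valid[sl] = defined
    return InsulationTrack(BinTrack(bt, values, valid), [w * bt.bin_size for w in windows])


def find_boundaries(
    track: InsulationTrack,
    min_boundary_distance: int = DEFAULT_MIN_BOUNDARY_DISTANCE,
    min_prominence: float = DEFAULT_MIN_PROMINENCE,
) -> list[TadBoundary]:
    """Call TAD boundaries as prominent local minima of the score.

    Local minima with prominence >= ``min_prominence`` are candidates;
    candidates are accepted greedily in order of ascending score subject
    to every accepted pair being >= ``min_boundary_distance`` apart.
    """
    bt = track.track.bin_table
    out: list[TadBoundary] = []
    for chrom in bt.genome.names:
        vals, ok = track.track.chrom_values(chrom)
        starts = bt.starts_of(chrom)
        candidates: list[TadBoundary] = []
        # split into contiguous valid runs; find minima within each
        idx = np.flatnonzero(ok)
        if idx.size == 0:
            continue
        breaks = np.flatnonzero(np.diff(idx) > 1)
        run_bounds = np.split(idx, breaks + 1)
        for run in run_bounds:
            if run.size < 3:
                continue
            y = -vals[run]
            peaks, props = signal.find_peaks(y, prominence=min_prominence)
            for p, prom in zip(peaks, props["prominences"]):
                b = int(run[p])
                candidates.append(
                    TadBoundary(
                        chrom, b, int(starts[b]), float(vals[b]), float(prom)
                    )
                )
        accepted: list[TadBoundary] = []
        for cand in sorted(candidates, key=lambda c: c.score):
            if all(
                abs(cand.position - a.position) >= min_boundary_distance
                for a in accepted
            ):
                accepted.append(cand)
        out.extend(sorted(accepted, key=lambda c: c.bin))
    return out


def tadscore_correlation(
    a: InsulationTrack, b: InsulationTrack
) -> tuple[float, float]:
    """Pearson correlation of two insulation tracks over joint bins."""
    if a.track.bin_table != b.track.bin_table:
        raise CompartmethError("tracks are on different bin tables")
    joint = a.track.valid & b.track.valid
    if joint.sum() < 3:
        raise CompartmethError("fewer than 3 jointly unmasked bins")
    r, _ = stats.pearsonr(a.track.values[joint], b.track.values[joint])
    return float(r), float(r * r)
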