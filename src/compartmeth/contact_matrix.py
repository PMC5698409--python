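"""Binned Hi-C contact matrices: loading, ICE balancing, O/E, correlation.

Analysis is strictly intra-chromosomal: inter-chromosomal triplets are
dropped at load time with a logged count. Balancing is iterative
proportional fitting (ICE) run per chromosome after masking low-coverage
bins; the observed/expected transform divides by the mean contact at each
bin distance, and compartment analysis downstream runs PCA on the Pearson
correlation matrix of O/E rows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .core_tracks import BinTable, CompartmethError

logger = logging.getLogger("compartmeth")

DEFAULT_ICE_TOL = 1e-5
DEFAULT_ICE_MAX_ITER = 200
DEFAULT_LOW_COVERAGE_QUANTILE = 0.02


@dataclass
class ContactMatrix:
    """Symmetric per-chromosome binned contact matrices.

    ``matrices[chrom]`` is a dense symmetric array over the chromosome's
    bins. ``weights[chrom]`` holds the ICE balancing weight per bin (NaN on
    masked bins) once balanced. ``mask[chrom]`` is True on usable bins.
    """

    bin_table: BinTable
    matrices: dict[str, np.ndarray]
    weights: dict[str, np.ndarray] = field(default_factory=dict)
    mask: dict[str, np.ndarray] = field(default_factory=dict)
    balanced: bool = False

    def __post_init__(self) -> None:
        for chrom, m in self.matrices.items():
            n = self.bin_table.n_bins_of(chrom)
            if m.shape != (n, n):
                raise CompartmethError(f"{chrom}: matrix shape {m.shape} != ({n},{n})")
            if not np.allclose(m, m.T):
                raise CompartmethError(f"{chrom}: matrix is not symmetric")
            if (m < 0).any():
                raise CompartmethError(f"{chrom}: negative counts")
            if chrom not in self.mask:
                self.mask[chrom] = np.ones(n, dtype=bool)

    def chroms(self) -> list[str]:
        return [c for c in self.bin_table.genome.names if c in self.matrices]

    def total_counts(self, chrom: str) -> float:
        m = self.matrices[chrom]
        # each off-diagonal pair stored twice; count unordered pairs once
        return float((m.sum() + np.trace(m)) / 2)


@dataclass
class ExpectedProfile:
    """Mean balanced contact at each bin distance, per chromosome."""

    values: dict[str, np.ndarray]  # e(d), NaN where no unmasked pair exists


def load_matrix(path, bin_table: BinTable) -> ContactMatrix:
    """Load a sparse triplet text file (bin_i, bin_j, count).

    Bin indices are genome-wide (the bin table's concatenation order).
    Only intra-chromosomal entries are kept; the matrix is symmetrized if
    only one triangle is present. Header lines starting with '#' are
    ignored.
    """
    tri = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise CompartmethError(f"{path}:{lineno}: expected 3 columns")
            try:
                i, j, c = int(parts[0]), int(parts[1]), float(parts[2])
            except ValueError:
                raise CompartmethError(f"{path}:{lineno}: malformed triplet") from None
            if not (0 <= i < bin_table.n_bins and 0 <= j < bin_table.n_bins):
                raise CompartmethError(f"{path}:{lineno}: bin index out of range")
            if c < 0:
                raise CompartmethError(f"{path}:{lineno}: negative count")
            tri.append((i, j, c))
    return matrix_from_triplets(tri, bin_table)


def matrix_from_triplets(triplets, bin_table: BinTable) -> ContactMatrix:
    genome = bin_table.genome
    bounds = {
        chrom: (bin_table.offset_of(chrom), bin_table.offset_of(chrom) + bin_table.n_bins_of(chrom))
        for chrom in genome.names
    }

    def chrom_of(idx: int) -> str:
        for chrom, (lo, hi) in bounds.items():
            if lo <= idx < hi:
                return chrom
        raise CompartmethError(f"bin index {idx} out of range")

    mats = {
        chrom: np.zeros((bin_table.n_bins_of(chrom),) * 2) for chrom in genome.names
    }
    n_inter = 0
    for i, j, c in triplets:
        ci, cj = chrom_of(i), chrom_of(j)
        if ci != cj:
            n_inter += 1
            continue
        lo = bounds[ci][0]
        mats[ci][i - lo, j - lo] += c
    if n_inter:
        logger.info("dropped %d inter-chromosomal triplets", n_inter)
    for chrom, m in mats.items():
        lower = np.tril(m, -1)
        upper = np.triu(m, 1)
        if not lower.any():
            m += upper.T
        elif not upper.any():
            m += lower.T
        elif not np.allclose(m, m.T):
            raise CompartmethError(f"{chrom}: inconsistent symmetric entries")
    return ContactMatrix(bin_table, mats)


def write_matrix(m: ContactMatrix, path) -> None:
    """Write the upper triangle (incl. diagonal) as genome-wide triplets."""
    bt = m.bin_table
    with open(path, "w") as fh:
        fh.write(f"# bin_size={bt.bin_size}\n")
        for chrom in m.chroms():
            off = bt.offset_of(chrom)
            mat = m.matrices[chrom]
            ii, jj = np.nonzero(np.triu(mat))
            for i, j in zip(ii, jj):
                v = mat[i, j]
                text = repr(float(v)) if m.balanced else str(int(round(v)))
                fh.write(f"{off + i}\t{off + j}\t{text}\n")


def ice_balance(
    m: ContactMatrix,
    max_iter: int = DEFAULT_ICE_MAX_ITER,
    tol: float = DEFAULT_ICE_TOL,
    low_coverage_quantile: float = DEFAULT_LOW_COVERAGE_QUANTILE,
) -> ContactMatrix:
    """Iterative correction (ICE) per chromosome.

    Bins whose raw coverage falls below ``low_coverage_quantile`` of the
    nonzero row sums — and all zero-sum bins — are masked. Weights are
    updated by proportional fitting until every unmasked row sum is within
    ``tol`` (relative) of the mean row sum, or ``max_iter`` is reached with
    a convergence warning. The zero pattern and symmetry are preserved and
    weights are strictly positive on unmasked bins.
    """
    if m.balanced:
        raise CompartmethError("matrix is already balanced")
    out_m: dict[str, np.ndarray] = {}
    out_w: dict[str, np.ndarray] = {}
    out_mask: dict[str, np.ndarray] = {}
    any_usable = False
    for chrom in m.chroms():
        raw = m.matrices[chrom].astype(float)
        rowsum = raw.sum(axis=1)
        usable = rowsum > 0
        nz = rowsum[usable]
        if nz.size:
            thresh = np.quantile(nz, low_coverage_quantile)
            usable &= rowsum >= thresh
        n_use = int(usable.sum())
        if n_use == 0:
            out_m[chrom] = np.zeros_like(raw)
            out_w[chrom] = np.full(raw.shape[0], np.nan)
            out_mask[chrom] = usable
            continue
        any_usable = True
        w = np.ones(raw.shape[0])
        w[~usable] = 0.0
        work = raw.copy()
        work[~usable, :] = 0.0
        work[:, ~usable] = 0.0
        converged = False
        for _ in range(max_iter):
            s = work.sum(axis=1)
            mean_s = s[usable].mean()
            dev = np.abs(s[usable] / mean_s - 1.0).max() if mean_s > 0 else np.inf
            if dev <= tol:
                converged = True
                break
            b = np.ones_like(s)
            b[usable] = s[usable] / mean_s
            work /= np.outer(b, b)
            w[usable] /= b[usable]
        if not converged:
            logger.warning("%s: ICE did not converge in %d iterations", chrom, max_iter)
        out_m[chrom] = work
        wout = np.where(usable, w, np.nan)
        out_w[chrom] = wout
        out_mask[chrom] = usable
    if not any_usable:
        raise CompartmethError("no usable bins")
    return ContactMatrix(m.bin_table, out_m, out_w, out_mask, balanced=True)


def expected_by_distance(m: ContactMatrix) -> ExpectedProfile:
    """Mean balanced contact per bin distance over unmasked pairs."""
    if not m.balanced:
        raise CompartmethError("expected profile requires a balanced matrix")
    prof: dict[str, np.ndarray] = {}
    for chrom in m.chroms():
        mat = m.matrices[chrom]
        usable = m.mask[chrom]
        n = mat.shape[0]
        e = np.full(n, np.nan)
        for d in range(n):
            i = np.arange(n - d)
            ok = usable[i] & usable[i + d]
            if ok.any():
                e[d] = mat[i[ok], i[ok] + d].mean()
        prof[chrom] = e
    return ExpectedProfile(prof)


def oe_matrix(m: ContactMatrix, expected: ExpectedProfile) -> dict[str, np.ndarray]:
    """Observed/expected transform; NaN where expected is 0 or missing."""
    out: dict[str, np.ndarray] = {}
    for chrom in m.chroms():
        mat = m.matrices[chrom]
        e = expected.values[chrom]
        n = mat.shape[0]
        d = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
        denom = e[d]
        with np.errstate(invalid="ignore", divide="ignore"):
            oe = np.where(denom > 0, mat / denom, np.nan)
        usable = m.mask[chrom]
        oe[~usable, :] = np.nan
        oe[:, ~usable] = np.nan
        out[chrom] = oe
    return out


def _pairwise_pearson_excluding_diagonal(x: np.ndarray) -> np.ndarray:
    """Pearson correlation of the rows of a symmetric matrix where, for
    each row pair (i, j), the columns i and j are excluded.

    Exact complete-case computation per pair (so every entry is a true
    correlation in [-1, 1]), done with matrix products rather than a
    pairwise loop.
    """
    n = x.shape[0]
    k = n - 2  # columns entering each pairwise computation
    if k < 2:
        return np.full((n, n), np.nan)
    d = np.diag(x).copy()
    rs = x.sum(axis=1)
    rq = (x**2).sum(axis=1)
    gram = x @ x.T
    s1_i = rs[:, None] - d[:, None] - x  # sum over shared columns, row i
    s1_j = s1_i.T
    s2_i = rq[:, None] - (d**2)[:, None] - x**2
    s2_j = s2_i.T
    s12 = gram - d[:, None] * x - x * d[None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = s12 - s1_i * s1_j / k
        var_i = s2_i - s1_i**2 / k
        var_j = s2_j - s1_j**2 / k
        r = cov / np.sqrt(var_i * var_j)
    r[~np.isfinite(r)] = np.nan
    np.fill_diagonal(r, 1.0)
    return np.clip(r, -1.0, 1.0)


def oe_correlation(
    m: ContactMatrix, expected: ExpectedProfile
) -> dict[str, np.ndarray]:
    """Pearson correlation matrix of O/E rows, per chromosome.

    The main diagonal of the O/E matrix is excluded from every pairwise
    computation (self-contacts dominate the variance); each entry is an
    exact complete-case Pearson correlation. Chromosomes with fewer than
    3 unmasked bins yield an all-NaN matrix.
    """
    oes = oe_matrix(m, expected)
    out: dict[str, np.ndarray] = {}
    for chrom, oe in oes.items():
        n = oe.shape[0]
        usable = m.mask[chrom]
        corr = np.full((n, n), np.nan)
        if usable.sum() < 3:
            out[chrom] = corr
            continue
        sub = oe[np.ix_(usable, usable)]
        # distances where e(d) = 0 have zero observed contacts everywhere;
        # their O/E carries no signal and enters the correlation as 0
        sub = np.where(np.isfinite(sub), sub, 0.0)
        cval = _pairwise_pearson_excluding_diagonal(sub)
        idx = np.flatnonzero(usable)
        corr[np.ix_(idx, idx)] = cval
        out[chrom] = corr
    return out
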