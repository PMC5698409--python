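"""Synthetic multi-stage cohort with planted ground truth.

Emulates, at desk scale, a differentiation cohort of six samples — ES,
progenitor, fetal, newborn, adult, and an adult DNMT3A/B-knockout — over
a small multi-chromosome genome (default 2 x 20 Mb, 40-kb bins):

* Hi-C contacts per stage from a multiplicative model: distance decay
  ``(1+d)^(-alpha)`` x compartment plaid (same-label pairs boosted by
  ``1+eps``, cross-label damped by ``1-eps*kappa``) x a within-TAD boost
  ``1+tau``; counts are multinomial over intra-chromosomal bin pairs, so
  each chromosome receives exactly N read pairs.
* Per-cytosine bisulfite calls: CpG positions are laid down once and
  shared by every stage and genotype, so per-CpG differences are always
  well-defined. Each CpG's true level depends on its planted region
  class — FMR (high), LMR/UMR (low), PMD (disordered, uniform in
  [0.3, 0.7]) — and counts are binomial at Poisson coverage, split over
  the two strands so strand-combining is exercised downstream.
* Compartment dynamics: a subset of compartment-sized blocks switches
  label at a named stage; methylation features follow the new label one
  stage later (a configurable lag), so chronology analyses have signal.
* The knockout shares the adult compartment truth exactly; its planted
  DMRs (within A compartments) are hypomethylated, and its CHH calls
  carry zero methylated counts. CHH methylation is elevated only in
  designated A-compartment regions of the adult wild type; elsewhere (and
  at earlier stages) CHH sites carry only a low background so that
  genome-wide enrichment statistics are well-defined.

Planted DMRs are generated to realize the caller's eligibility rules
with margin (coverage >= 4 on both sides, per-CpG delta >= 10%, mean
delta >= 40%): counts at DMR CpGs are drawn from band-truncated
binomials. PMDs are always >= 100 kb.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .contact_matrix import ContactMatrix
from .core_tracks import (
    BinTable,
    BinTrack,
    CompartmethError,
    Genome,
    Interval,
    merge_intervals,
    write_bed,
)
from .methylome import CALL_COLUMNS, MethylationCallSet

logger = logging.getLogger("compartmeth")

STAGES = ("ES", "progenitor", "fetal", "newborn", "adult", "adult_KO")
FEATURE_CLASSES = ("UMR", "LMR", "FMR", "PMD", "DMR", "CHH")

DEFAULT_BIN_SIZE = 40_000
DEFAULT_CHROM_LENGTH = 20_000_000


@dataclass(frozen=True)
class HiCParams:
    """Contact generator parameters (all multipliers strictly positive)."""

    decay_alpha: float = 1.0
    plaid_strength: float = 0.4  # eps: same-compartment x(1+eps)
    plaid_kappa: float = 1.0  # cross-compartment x(1-eps*kappa)
    tad_boost: float = 1.0  # within-TAD x(1+tau)
    n_contacts: int = 1_000_000  # read pairs per chromosome

    def __post_init__(self) -> None:
        if self.decay_alpha <= 0:
            raise CompartmethError("decay_alpha must be > 0")
        if not 0 <= self.plaid_strength * self.plaid_kappa < 1:
            raise CompartmethError("cross-compartment multiplier must stay positive")
        if self.tad_boost < 0 or self.plaid_strength < 0:
            raise CompartmethError("multipliers must be >= 0")


@dataclass(frozen=True)
class MethylParams:
    """Methylome generator parameters."""

    mean_coverage: float = 30.0  # Poisson lambda per CpG (deep WGBS)
    cpg_spacing_mean: float = 100.0  # geometric, bp
    fmr_beta: tuple[float, float] = (27.0, 3.0)  # mean 0.90
    lmr_beta: tuple[float, float] = (3.0, 12.0)  # mean 0.20
    umr_beta: tuple[float, float] = (1.0, 24.0)  # mean 0.04
    pmd_band: tuple[float, float] = (0.3, 0.7)  # per-CpG uniform
    ko_dmr_delta: float = 0.6  # hypomethylation of planted DMRs in the KO
    chh_spacing_mean: float = 300.0  # bp, genome-wide CHH sites
    chh_background_rate: float = 0.01
    chh_positive_rate: float = 0.20  # adult WT inside CHH-positive regions

    def __post_init__(self) -> None:
        if self.ko_dmr_delta < 0.5:
            raise CompartmethError("ko_dmr_delta must be >= 0.5")
        if self.mean_coverage < 0:
            raise CompartmethError("coverage must be >= 0")


@dataclass
class TruthModel:
    """Planted ground truth for one synthetic cohort."""

    genome: Genome
    bin_size: int
    stages: tuple[str, ...]
    labels: dict[str, np.ndarray]  # stage -> per-bin 'A'/'B' (genome-wide)
    tad_boundaries: dict[str, list[int]]  # chrom -> local bin indices
    features: dict[str, dict[str, list[Interval]]]  # stage -> class -> intervals
    switch_blocks: dict[str, list[Interval]]  # switch stage -> blocks
    cpg_positions: dict[str, np.ndarray]
    chh_positions: dict[str, np.ndarray]
    methylation_lag: int = 1
    seed: int = 0

    @property
    def bin_table(self) -> BinTable:
        return BinTable(self.genome, self.bin_size)

    def label_intervals(self, stage: str, label: str) -> list[Interval]:
        bt = self.bin_table
        lab = self.labels[stage]
        ivs = []
        for chrom in self.genome.names:
            sl = bt.chrom_slice(chrom)
            starts, ends = bt.starts_of(chrom), bt.ends_of(chrom)
            for k in np.flatnonzero(lab[sl] == label):
                ivs.append(Interval(chrom, int(starts[k]), int(ends[k])))
        return merge_intervals(ivs) if ivs else []

    def effective_stage(self, stage: str) -> str:
        """Stage whose compartments shape this stage's methylation (lagged)."""
        wt = [s for s in self.stages if s != "adult_KO"]
        if stage == "adult_KO":
            stage = "adult"
        i = wt.index(stage)
        return wt[max(0, i - self.methylation_lag)]


def _sub_rng(seed: int, *key) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, *map(_stable_hash, key)]))


def _stable_hash(x) -> int:
    if isinstance(x, (int, np.integer)):
        return int(x)
    digest = hashlib.sha256(str(x).encode()).digest()
    return int.from_bytes(digest[:4], "little")


# ---------------------------------------------------------------------------
# Truth construction
# ---------------------------------------------------------------------------

def make_truth(
    seed: int = 0,
    genome: Genome | None = None,
    bin_size: int = DEFAULT_BIN_SIZE,
    methylation_lag: int = 1,
    pmd_onset_stage: str = "fetal",
) -> TruthModel:
    """Build the default planted truth for a cohort.

    Compartment blocks span 12-24 consecutive bins; a handful switch label
    at the progenitor or fetal stage. TAD boundaries include every
    compartment block edge plus internal splits, always >= 480 kb apart.
    LMRs and (adult-only) DMR and CHH-positive regions live inside A
    blocks, PMDs (>= 100 kb) inside B blocks from ``pmd_onset_stage`` on,
    UMRs in A blocks at every stage; everything else is FMR.
    """
    if genome is None:
        genome = Genome(("chr1", "chr2"), (DEFAULT_CHROM_LENGTH,) * 2)
    bt = BinTable(genome, bin_size)
    rng = _sub_rng(seed, "truth")
    wt_stages = [s for s in STAGES if s != "adult_KO"]

    base = np.empty(bt.n_bins, dtype="<U1")
    blocks: dict[str, list[tuple[int, int]]] = {}  # chrom -> (start_bin, end_bin)
    tadb: dict[str, list[int]] = {}
    for chrom in genome.names:
        n = bt.n_bins_of(chrom)
        off = bt.offset_of(chrom)
        cuts = [0]
        while cuts[-1] < n:
            cuts.append(min(n, cuts[-1] + int(rng.integers(12, 25))))
        if cuts[-1] - cuts[-2] < 12 and len(cuts) > 2:
            cuts.pop(-2)  # fold a short terminal block into its neighbor
        blocks[chrom] = list(zip(cuts[:-1], cuts[1:]))
        lab = "A" if rng.random() < 0.5 else "B"
        for a, b in blocks[chrom]:
            base[off + a : off + b] = lab
            lab = "B" if lab == "A" else "A"
        # TAD boundaries: block edges plus one split in blocks >= 24 bins
        bounds = {a for a, _ in blocks[chrom][1:]}
        for a, b in blocks[chrom]:
            if b - a >= 24:
                bounds.add(a + (b - a) // 2)
        tadb[chrom] = sorted(bounds)

    # stage switches: flip whole blocks at 'progenitor' or 'fetal'
    switch_blocks: dict[str, list[Interval]] = {"progenitor": [], "fetal": []}
    flips: dict[str, list[tuple[str, int, int]]] = {"progenitor": [], "fetal": []}
    for chrom in genome.names:
        interior = blocks[chrom][1:-1]
        if not interior:
            continue
        chosen = rng.choice(len(interior), size=min(4, len(interior)), replace=False)
        for which, stage in zip(chosen, ["progenitor", "progenitor", "fetal", "fetal"]):
            a, b = interior[which]
            flips[stage].append((chrom, a, b))
            switch_blocks[stage].append(
                Interval(chrom, a * bin_size, min(b * bin_size, genome.length(chrom)))
            )

    labels: dict[str, np.ndarray] = {}
    current = base.copy()
    for stage in wt_stages:
        if stage in flips:
            for chrom, a, b in flips[stage]:
                off = bt.offset_of(chrom)
                seg = current[off + a : off + b]
                current[off + a : off + b] = np.where(seg == "A", "B", "A")
        labels[stage] = current.copy()
    labels["adult_KO"] = labels["adult"].copy()

    # CpG / CHH site positions, shared across all stages and genotypes
    cpg_positions: dict[str, np.ndarray] = {}
    chh_positions: dict[str, np.ndarray] = {}
    for chrom in genome.names:
        length = genome.length(chrom)
        for store, mean, name in (
            (cpg_positions, 100.0, "cpg"),
            (chh_positions, 300.0, "chh"),
        ):
            site_rng = _sub_rng(seed, "sites", name, chrom)
            n_exp = int(length / mean * 1.2) + 100
            gaps = 2 + site_rng.geometric(1.0 / (mean - 2), size=n_exp)
            pos = np.cumsum(gaps)
            store[chrom] = pos[pos < length - 2].astype(np.int64)

    features = _plant_features(
        genome, bt, labels, wt_stages, cpg_positions, rng, methylation_lag,
        pmd_onset_stage,
    )
    return TruthModel(
        genome=genome,
        bin_size=bin_size,
        stages=STAGES,
        labels=labels,
        tad_boundaries=tadb,
        features=features,
        switch_blocks=switch_blocks,
        cpg_positions=cpg_positions,
        chh_positions=chh_positions,
        methylation_lag=methylation_lag,
        seed=seed,
    )


def _label_runs(bt: BinTable, lab: np.ndarray, chrom: str, label: str):
    sl = bt.chrom_slice(chrom)
    vals = lab[sl]
    idx = np.flatnonzero(vals == label)
    if idx.size == 0:
        return
    breaks = np.flatnonzero(np.diff(idx) > 1)
    for run in np.split(idx, breaks + 1):
        yield int(run[0]) * bt.bin_size, min(
            (int(run[-1]) + 1) * bt.bin_size, bt.genome.length(chrom)
        )


def _plant_features(
    genome: Genome,
    bt: BinTable,
    labels: dict[str, np.ndarray],
    wt_stages: list[str],
    cpg_positions: dict[str, np.ndarray],
    rng: np.random.Generator,
    lag: int,
    pmd_onset_stage: str,
) -> dict[str, dict[str, list[Interval]]]:
    pmd_onset = wt_stages.index(pmd_onset_stage)
    features: dict[str, dict[str, list[Interval]]] = {}
    # Placement is computed once per (chrom, geometric run, label) from a
    # run-keyed RNG, so stages sharing effective labels share features.
    placement_cache: dict[tuple, dict[str, list[Interval]]] = {}

    def place(chrom: str, start: int, end: int, label: str, with_pmd: bool, seed0: int):
        key = (chrom, start, end, label, with_pmd)
        if key in placement_cache:
            return placement_cache[key]
        r = _sub_rng(seed0, "place", chrom, start, end, label, int(with_pmd))
        out: dict[str, list[Interval]] = {c: [] for c in ("UMR", "LMR", "PMD")}
        width = end - start
        if label == "A":
            # one UMR per run (4 kb), LMRs every ~200 kb (2 kb each)
            margin = 20_000
            if width > 2 * margin + 4_000:
                u = int(r.integers(start + margin, end - margin - 4_000))
                out["UMR"].append(Interval(chrom, u, u + 4_000))
            n_lmr = max(1, width // 200_000)
            lo = start + margin
            for _ in range(n_lmr):
                hi = min(end - margin - 2_000, lo + 160_000)
                if hi <= lo:
                    break
                s = int(r.integers(lo, hi))
                out["LMR"].append(Interval(chrom, s, s + 2_000))
                lo = s + 40_000
        elif with_pmd and width >= 200_000:
            # one central PMD covering ~40% of the block, always >= 120 kb
            plen = max(120_000, min(int(0.4 * width), 400_000))
            s = start + (width - plen) // 2
            out["PMD"].append(Interval(chrom, s, s + plen))
        # drop overlaps between UMR and LMR (UMR wins)
        if out["UMR"]:
            umrs = out["UMR"]
            out["LMR"] = [
                l
                for l in out["LMR"]
                if all(l.end <= u.start or l.start >= u.end for u in umrs)
            ]
        placement_cache[key] = out
        return out

    seed0 = int(rng.integers(2**31))
    # adult-only extras: DMRs and CHH-positive regions inside adult-A runs
    adult_eff = labels[wt_stages[max(0, wt_stages.index("adult") - lag)]]
    dmr_ivs: list[Interval] = []
    chh_ivs: list[Interval] = []
    r_extra = _sub_rng(seed0, "extras")
    for chrom in genome.names:
        runs = list(_label_runs(bt, adult_eff, chrom, "A"))
        for ri, (start, end) in enumerate(runs):
            placed = place(chrom, start, end, "A", False, seed0)
            blocked = placed["UMR"] + placed["LMR"]
            pos = cpg_positions[chrom]
            # two DMRs per A run: 10 consecutive CpGs clear of UMR/LMR
            n_planted = 0
            attempts = 0
            while n_planted < 2 and attempts < 40:
                attempts += 1
                lo = int(r_extra.integers(start + 25_000, max(start + 25_001, end - 25_000)))
                i0 = int(np.searchsorted(pos, lo))
                if i0 + 10 >= pos.size:
                    continue
                p = pos[i0 : i0 + 10]
                if p[-1] + 1 > end - 20_000:
                    continue
                if np.diff(p).max() > 500:
                    continue
                iv = Interval(chrom, int(p[0]), int(p[-1]) + 1)
                # keep clear of UMRs/LMRs, and far enough from other DMRs
                # that the 1-kb gap rule can never chain two planted
                # regions into one call
                clear = all(
                    iv.end + 1_200 <= b.start or iv.start >= b.end + 1_200
                    for b in blocked
                ) and all(
                    iv.end + 2_500 <= b.start or iv.start >= b.end + 2_500
                    for b in dmr_ivs
                    if b.chrom == chrom
                )
                if clear:
                    dmr_ivs.append(iv)
                    n_planted += 1
            # ~every third A run is CHH-positive over its interior
            if ri % 3 == 0 and end - start >= 160_000:
                chh_ivs.append(Interval(chrom, start + 20_000, end - 20_000))

    # isolate every planted DMR by a >1-kb CpG-free flank on both sides, so
    # a planted region's extent is unambiguous under read noise
    for chrom in genome.names:
        pos = cpg_positions[chrom]
        drop = np.zeros(pos.size, dtype=bool)
        for iv in dmr_ivs:
            if iv.chrom != chrom:
                continue
            drop |= (pos >= iv.start - 1_100) & (pos < iv.start)
            drop |= (pos >= iv.end) & (pos < iv.end + 1_100)
        cpg_positions[chrom] = pos[~drop]

    for stage in wt_stages + ["adult_KO"]:
        wt_idx = wt_stages.index("adult" if stage == "adult_KO" else stage)
        eff = labels[wt_stages[max(0, wt_idx - lag)]]
        with_pmd = wt_idx >= pmd_onset
        stage_feats: dict[str, list[Interval]] = {c: [] for c in FEATURE_CLASSES}
        for chrom in genome.names:
            for label in "AB":
                for start, end in _label_runs(bt, eff, chrom, label):
                    placed = place(
                        chrom, start, end, label, with_pmd and label == "B", seed0
                    )
                    for cls in ("UMR", "LMR", "PMD"):
                        stage_feats[cls].extend(placed[cls])
        if stage in ("adult", "adult_KO"):
            stage_feats["DMR"] = list(dmr_ivs)
            stage_feats["CHH"] = list(chh_ivs)
        # FMR truth: complement of the other methylation classes (for the
        # knockout the hypomethylated DMRs are not fully methylated either)
        occupied = stage_feats["UMR"] + stage_feats["LMR"] + stage_feats["PMD"]
        if stage == "adult_KO":
            occupied = occupied + stage_feats["DMR"]
        stage_feats["FMR"] = _complement(genome, occupied)
        features[stage] = stage_feats
    return features


def _complement(genome: Genome, intervals: list[Interval]) -> list[Interval]:
    merged = merge_intervals(intervals) if intervals else []
    out: list[Interval] = []
    for chrom in genome.names:
        length = genome.length(chrom)
        prev = 0
        for iv in [i for i in merged if i.chrom == chrom]:
            if iv.start > prev:
                out.append(Interval(chrom, prev, iv.start))
            prev = max(prev, iv.end)
        if prev < length:
            out.append(Interval(chrom, prev, length))
    return out


# ---------------------------------------------------------------------------
# Hi-C contact generation
# ---------------------------------------------------------------------------

def _tad_ids(n_bins: int, boundaries: list[int]) -> np.ndarray:
    ids = np.zeros(n_bins, dtype=np.int64)
    for b in boundaries:
        ids[b:] += 1
    return ids


def expected_contact_matrix(
    truth: TruthModel, params: HiCParams, stage: str, chrom: str
) -> np.ndarray:
    """Expected (unnormalized) contact intensity for one chromosome."""
    bt = truth.bin_table
    n = bt.n_bins_of(chrom)
    sl = bt.chrom_slice(chrom)
    lab = truth.labels[stage][sl]
    d = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
    intensity = (1.0 + d) ** (-params.decay_alpha)
    same = np.equal.outer(lab, lab)
    eps, kappa = params.plaid_strength, params.plaid_kappa
    intensity *= np.where(same, 1.0 + eps, 1.0 - eps * kappa)
    tid = _tad_ids(n, truth.tad_boundaries[chrom])
    intensity *= np.where(np.equal.outer(tid, tid), 1.0 + params.tad_boost, 1.0)
    return intensity


def generate_contacts(
    truth: TruthModel, params: HiCParams, stage: str, seed: int
) -> ContactMatrix:
    """Sample a symmetric integer contact matrix for every chromosome.

    Exactly ``params.n_contacts`` unordered read pairs are placed per
    chromosome (multinomial over intra-chromosomal bin pairs).
    """
    if stage not in truth.stages:
        raise CompartmethError(f"unknown stage {stage!r}")
    bt = truth.bin_table
    mats: dict[str, np.ndarray] = {}
    for chrom in truth.genome.names:
        rng = _sub_rng(seed, "hic", stage, chrom)
        intensity = expected_contact_matrix(truth, params, stage, chrom)
        n = intensity.shape[0]
        iu = np.triu_indices(n)
        probs = intensity[iu]
        probs = probs / probs.sum()
        counts = rng.multinomial(params.n_contacts, probs)
        m = np.zeros((n, n))
        m[iu] = counts
        m = m + m.T - np.diag(np.diag(m))
        if (m.sum(axis=1) == 0).any():
            logger.warning(
                "%s/%s: empty rows; n_contacts may be too small", stage, chrom
            )
        mats[chrom] = m
    return ContactMatrix(bt, mats)


def generate_activity(
    truth: TruthModel, stage: str, seed: int
) -> BinTrack:
    """Per-bin activity/expression proxy: high in (lagged) A compartments."""
    if stage not in truth.stages:
        raise CompartmethError(f"unknown stage {stage!r}")
    bt = truth.bin_table
    rng = _sub_rng(seed, "activity", stage)
    eff = truth.labels[truth.effective_stage(stage)]
    values = np.where(
        eff == "A",
        rng.normal(2.0, 0.5, bt.n_bins),
        rng.normal(0.3, 0.15, bt.n_bins),
    )
    return BinTrack(bt, np.clip(values, 0.0, None), np.ones(bt.n_bins, dtype=bool))


# ---------------------------------------------------------------------------
# Methylome generation
# ---------------------------------------------------------------------------

def _class_per_cpg(
    truth: TruthModel, stage: str, chrom: str
) -> np.ndarray:
    """Region class per CpG: 0 FMR, 1 LMR, 2 UMR, 3 PMD, 4 DMR."""
    pos = truth.cpg_positions[chrom]
    cls = np.zeros(pos.size, dtype=np.int64)
    feats = truth.features[stage]
    for code, name in ((1, "LMR"), (2, "UMR"), (3, "PMD"), (4, "DMR")):
        for iv in feats.get(name, []):
            if iv.chrom == chrom:
                cls[(pos >= iv.start) & (pos < iv.end)] = code
    return cls


def _truncated_binomial(
    rng: np.random.Generator,
    n: np.ndarray,
    p: np.ndarray,
    lo: float,
    hi: float,
    max_tries: int = 60,
) -> np.ndarray:
    """Binomial draws conditioned on lo <= k/n <= hi (n >= 1 everywhere)."""
    k = rng.binomial(n, p)
    for _ in range(max_tries):
        ratio = k / n
        bad = (ratio < lo) | (ratio > hi)
        if not bad.any():
            break
        k[bad] = rng.binomial(n[bad], p[bad])
    ratio = k / n
    bad = (ratio < lo) | (ratio > hi)
    if bad.any():  # deterministic fallback, still inside the band
        k[bad] = np.clip(
            np.round(p[bad] * n[bad]), np.ceil(lo * n[bad]), np.floor(hi * n[bad])
        ).astype(k.dtype)
    return k


def _true_levels(
    truth: TruthModel, params: MethylParams, stage: str, chrom: str
) -> np.ndarray:
    """Per-CpG true methylation level; shared across stages via class keys."""
    pos = truth.cpg_positions[chrom]
    n = pos.size
    base = truth.seed
    lev_fmr = _sub_rng(base, "lev", chrom, "fmr").beta(*params.fmr_beta, size=n)
    lev_lmr = _sub_rng(base, "lev", chrom, "lmr").beta(*params.lmr_beta, size=n)
    lev_umr = _sub_rng(base, "lev", chrom, "umr").beta(*params.umr_beta, size=n)
    lev_pmd = _sub_rng(base, "lev", chrom, "pmd").uniform(
        params.pmd_band[0], params.pmd_band[1], size=n
    )
    cls = _class_per_cpg(truth, stage, chrom)
    levels = lev_fmr.copy()
    levels[cls == 1] = lev_lmr[cls == 1]
    levels[cls == 2] = lev_umr[cls == 2]
    levels[cls == 3] = lev_pmd[cls == 3]
    # DMR CpGs: high in WT (class 4 + not KO), hypomethylated in the KO
    in_dmr = cls == 4
    if stage == "adult_KO":
        levels[in_dmr] = np.clip(lev_fmr[in_dmr] - params.ko_dmr_delta, 0.02, 1.0)
    else:
        levels[in_dmr] = np.clip(lev_fmr[in_dmr], 0.85, 0.98)
    return levels


def generate_methylome(
    truth: TruthModel, params: MethylParams, stage: str, seed: int
) -> MethylationCallSet:
    """Sample per-cytosine CpG and CHH calls for one stage/genotype.

    CpG counts are emitted per strand (forward C at the CpG position,
    reverse C at position + 1) with the combined total split
    hypergeometrically, so strand combining is exercised and conserves
    counts. At planted DMR CpGs coverage is at least 4 on both strands
    combined and levels are band-truncated (WT >= 0.75, KO <= 0.35), so
    every planted DMR satisfies the caller's eligibility rules with
    margin. CHH methylated counts are exactly zero for the knockout.
    """
    if stage not in truth.stages:
        raise CompartmethError(f"unknown stage {stage!r}")
    frames: list[pd.DataFrame] = []
    for chrom in truth.genome.names:
        rng = _sub_rng(seed, "meth", stage, chrom)
        pos = truth.cpg_positions[chrom]
        n = pos.size
        if params.mean_coverage == 0:
            continue
        cov = rng.poisson(params.mean_coverage, size=n)
        cls = _class_per_cpg(truth, stage, chrom)
        in_dmr = cls == 4
        # guarantee DMR eligibility: coverage >= 4
        cov[in_dmr] = 4 + rng.poisson(max(params.mean_coverage - 4, 0.0), in_dmr.sum())
        levels = _true_levels(truth, params, stage, chrom)
        meth = np.zeros(n, dtype=np.int64)
        has = cov > 0
        meth[has] = rng.binomial(cov[has], levels[has])
        if in_dmr.any():
            lo, hi = (0.0, 0.35) if stage == "adult_KO" else (0.75, 1.0)
            meth[in_dmr] = _truncated_binomial(
                rng, cov[in_dmr], levels[in_dmr], lo, hi
            )
        # split over strands
        fwd_total = rng.binomial(cov, 0.5)
        fwd_meth = np.zeros(n, dtype=np.int64)
        sel = fwd_total > 0
        fwd_meth[sel] = rng.hypergeometric(
            meth[sel], (cov - meth)[sel], fwd_total[sel]
        )
        rev_total = cov - fwd_total
        rev_meth = meth - fwd_meth
        keep_f = fwd_total > 0
        keep_r = rev_total > 0
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": pos[keep_f],
                    "strand": "+",
                    "context": "CpG",
                    "meth": fwd_meth[keep_f],
                    "total": fwd_total[keep_f],
                }
            )
        )
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": pos[keep_r] + 1,
                    "strand": "-",
                    "context": "CpG",
                    "meth": rev_meth[keep_r],
                    "total": rev_total[keep_r],
                }
            )
        )
        # CHH sites
        cpos = truth.chh_positions[chrom]
        ccov = rng.poisson(params.mean_coverage, size=cpos.size)
        rate = np.full(cpos.size, params.chh_background_rate)
        if stage == "adult":
            for iv in truth.features["adult"].get("CHH", []):
                if iv.chrom == chrom:
                    rate[(cpos >= iv.start) & (cpos < iv.end)] = (
                        params.chh_positive_rate
                    )
        if stage == "adult_KO":
            rate[:] = 0.0
        cmeth = np.zeros(cpos.size, dtype=np.int64)
        chas = ccov > 0
        cmeth[chas] = rng.binomial(ccov[chas], rate[chas])
        keep_c = ccov > 0
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": cpos[keep_c],
                    "strand": "+",
                    "context": "CHH",
                    "meth": cmeth[keep_c],
                    "total": ccov[keep_c],
                }
            )
        )
    if not frames:
        df = pd.DataFrame({c: pd.Series(dtype=t) for c, t in zip(
            CALL_COLUMNS, [str, np.int64, str, str, np.int64, np.int64]
        )})
        return MethylationCallSet(df)
    df = pd.concat(frames, ignore_index=True)
    df = df.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
    return MethylationCallSet(df[CALL_COLUMNS])


# ---------------------------------------------------------------------------
# Truth report
# ---------------------------------------------------------------------------

def truth_report(truth: TruthModel, outdir) -> dict[str, str]:
    """Write every planted feature class (per stage) as BED files.

    Also writes the per-stage compartment labels, the switch blocks and
    the TAD boundaries. Returns {name: path}.
    """
    import os

    os.makedirs(outdir, exist_ok=True)
    written: dict[str, str] = {}

    def emit(name: str, intervals: list[Interval]):
        path = os.path.join(outdir, f"{name}.bed")
        write_bed(intervals, path)
        written[name] = path

    for stage in truth.stages:
        for cls in FEATURE_CLASSES:
            emit(f"truth_{stage}_{cls}", truth.features[stage].get(cls, []))
        for label in "AB":
            emit(f"truth_{stage}_compartment_{label}",
                 truth.label_intervals(stage, label))
    for stage, ivs in truth.switch_blocks.items():
        emit(f"truth_switch_at_{stage}", ivs)
    bt = truth.bin_table
    tad_ivs = [
        Interval(chrom, b * truth.bin_size, b * truth.bin_size + 1)
        for chrom in truth.genome.names
        for b in truth.tad_boundaries[chrom]
    ]
    emit("truth_tad_boundaries", tad_ivs)
    return written
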