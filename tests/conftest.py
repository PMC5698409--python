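"""Shared fixtures: one default synthetic cohort, built once per session."""

from __future__ import annotations

import numpy as np
import pytest

import compartmeth as cm

COHORT_SEED = 7


@pytest.fixture(scope="session")
def truth():
    return cm.make_truth(seed=COHORT_SEED)


@pytest.fixture(scope="session")
def hic_params():
    return cm.HiCParams()


@pytest.fixture(scope="session")
def methyl_params():
    return cm.MethylParams()


@pytest.fixture(scope="session")
def balanced_by_stage(truth, hic_params):
    out = {}
    for i, stage in enumerate(cm.STAGES):
        raw = cm.generate_contacts(truth, hic_params, stage, seed=1000 + i)
        out[stage] = cm.ice_balance(raw)
    return out


@pytest.fixture(scope="session")
def compartments_by_stage(truth, balanced_by_stage):
    out = {}
    for i, stage in enumerate(cm.STAGES):
        act = cm.generate_activity(truth, stage, seed=2000 + i)
        out[stage] = cm.call_compartments(balanced_by_stage[stage], act)
    return out


@pytest.fixture(scope="session")
def calls_by_stage(truth, methyl_params):
    return {
        stage: cm.combine_cpg_strands(
            cm.generate_methylome(truth, methyl_params, stage, seed=3000 + i)
        )
        for i, stage in enumerate(cm.STAGES)
    }


@pytest.fixture(scope="session")
def adult_segments(calls_by_stage):
    return cm.segment_methylome(calls_by_stage["adult"])


@pytest.fixture()
def small_genome():
    return cm.Genome(("chr1", "chr2"), (400_000, 200_000))


@pytest.fixture()
def small_bins(small_genome):
    return cm.BinTable(small_genome, 40_000)


def make_callset(records):
    """Build a MethylationCallSet from (chrom, pos, strand, context, m, t)."""
    import pandas as pd

    from compartmeth.methylome import CALL_COLUMNS

    df = pd.DataFrame(records, columns=CALL_COLUMNS)
    return cm.MethylationCallSet(
        df.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
    )


def random_combined_pair(rng, n_max=400):
    """Random strand-combined CpG call-set pair for oracle cross-checks."""
    import pandas as pd

    from compartmeth.methylome import CALL_COLUMNS

    n = int(rng.integers(20, n_max))
    gaps = rng.integers(20, 1500, size=n)
    pos = np.cumsum(gaps)
    frames = []
    for _ in range(2):
        total = rng.integers(0, 30, size=n)
        levels = rng.random(n)
        meth = rng.binomial(total, levels)
        frames.append(
            pd.DataFrame(
                {
                    "chrom": "chr1",
                    "pos": pos,
                    "strand": "+",
                    "context": "CpG",
                    "meth": meth,
                    "total": total,
                }
            )[CALL_COLUMNS]
        )
    return (
        cm.MethylationCallSet(frames[0], combined=True),
        cm.MethylationCallSet(frames[1], combined=True),
    )
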