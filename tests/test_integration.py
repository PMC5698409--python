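"""Compartment-methylation integration statistics."""

import numpy as np
import pytest

import compartmeth as cm
from compartmeth import CompartmethError, Interval
from compartmeth.compartments import CompartmentTrack
from compartmeth.core_tracks import BinTrack
from compartmeth.methylome import segments_of_class

from test_compartments import track_from


def signal_on(bt, values, valid=None):
    return BinTrack(bt, values, np.ones(bt.n_bins, bool) if valid is None else valid)


class TestFeatureFractions:
    def test_all_features_in_a_with_half_genome_a(self):
        track = track_from([1.0] * 5 + [-1.0] * 5)
        feats = [Interval("chr1", 10_000, 30_000), Interval("chr1", 50_000, 70_000)]
        e = cm.feature_compartment_fractions(feats, track, n_permutations=50, seed=1)
        assert e.fraction_in_a == 1.0
        assert e.fold == pytest.approx(2.0)

    def test_tie_features_unassigned(self):
        track = track_from([1.0, -1.0])
        feats = [Interval("chr1", 20_000, 60_000)]  # exactly half in each
        with pytest.raises(CompartmethError):
            cm.feature_compartment_fractions(feats, track, n_permutations=10)

    def test_empty_features_rejected(self):
        track = track_from([1.0, -1.0])
        with pytest.raises(CompartmethError):
            cm.feature_compartment_fractions([], track)

    def test_scattered_features_not_enriched(self):
        rng = np.random.default_rng(61)
        vals = np.repeat(rng.choice([-1.0, 1.0], 25), 4)
        track = track_from(vals)
        feats = [
            Interval("chr1", int(s), int(s) + 2_000)
            for s in rng.integers(0, 100 * 40_000 - 2_000, size=60)
        ]
        e = cm.feature_compartment_fractions(feats, track, n_permutations=200, seed=2)
        assert 0.5 < e.fold < 2.0
        assert e.p_value > 0.05

    def test_planted_dmrs_live_in_a(
        self, truth, calls_by_stage, compartments_by_stage
    ):
        from compartmeth.dmr import dmrs_to_intervals

        dmrs = cm.call_dmrs(calls_by_stage["adult"], calls_by_stage["adult_KO"])
        e = cm.feature_compartment_fractions(
            dmrs_to_intervals(dmrs),
            compartments_by_stage["adult"],
            n_permutations=200,
            seed=3,
        )
        assert e.fraction_in_a >= 0.9
        assert e.p_value <= 0.05


class TestSignalEnrichment:
    def test_constant_signal_fold_one(self):
        comp = track_from([1.0] * 4 + [-1.0] * 6)
        bt1k = cm.BinTable(comp.bin_table.genome, 1_000)
        sig = signal_on(bt1k, np.ones(bt1k.n_bins))
        e = cm.signal_compartment_enrichment(sig, comp, n_permutations=20, seed=4)
        assert e.fold == pytest.approx(1.0)

    def test_fold_invariant_under_positive_rescaling(self):
        rng = np.random.default_rng(62)
        comp = track_from(np.repeat(rng.choice([-1.0, 1.0], 10), 1))
        bt1k = cm.BinTable(comp.bin_table.genome, 1_000)
        sig_values = rng.exponential(1.0, bt1k.n_bins)
        e1 = cm.signal_compartment_enrichment(
            signal_on(bt1k, sig_values), comp, n_permutations=30, seed=5
        )
        e2 = cm.signal_compartment_enrichment(
            signal_on(bt1k, 13.7 * sig_values), comp, n_permutations=30, seed=5
        )
        assert e1.fold == pytest.approx(e2.fold)
        # p may differ by a float-rounding tie in the permutation ranks
        assert e1.p_value == pytest.approx(e2.p_value, abs=2 / 31)

    def test_p_value_reproducible_for_fixed_seed(self):
        rng = np.random.default_rng(63)
        comp = track_from(np.repeat(rng.choice([-1.0, 1.0], 10), 1))
        bt1k = cm.BinTable(comp.bin_table.genome, 1_000)
        sig = signal_on(bt1k, rng.exponential(1.0, bt1k.n_bins))
        p1 = cm.signal_compartment_enrichment(sig, comp, n_permutations=99, seed=6).p_value
        p2 = cm.signal_compartment_enrichment(sig, comp, n_permutations=99, seed=6).p_value
        assert p1 == p2

    def test_adult_chh_enriched_in_a_and_fmr(
        self, truth, calls_by_stage, compartments_by_stage, adult_segments
    ):
        chh = cm.bin_chh(calls_by_stage["adult"], truth.genome)
        comp = compartments_by_stage["adult"]
        in_a = cm.signal_compartment_enrichment(chh, comp, n_permutations=200, seed=7)
        assert in_a.fold > 1 and in_a.p_value <= 0.05
        fmr = segments_of_class(adult_segments, "FMR")
        in_fmr = cm.signal_compartment_enrichment(
            chh, comp, fmr, n_permutations=200, seed=8
        )
        assert in_fmr.fold > 1 and in_fmr.p_value <= 0.05

    def test_knockout_chh_reported_as_no_signal(
        self, truth, calls_by_stage, compartments_by_stage
    ):
        chh = cm.bin_chh(calls_by_stage["adult_KO"], truth.genome)
        e = cm.signal_compartment_enrichment(
            chh, compartments_by_stage["adult"], n_permutations=20, seed=9
        )
        assert e.note == "no signal"
        assert np.isnan(e.fold)


class TestCommonCompartmentMeans:
    def test_sign_of_a_minus_b_flips_along_stages(
        self, calls_by_stage, compartments_by_stage
    ):
        wt = [s for s in cm.STAGES if s != "adult_KO"]
        common = cm.common_compartments([compartments_by_stage[s] for s in wt])
        means = cm.compartment_mean_methylation_by_stage(
            {s: calls_by_stage[s] for s in wt}, common
        )
        diff_es = means["ES"][0] - means["ES"][1]
        diff_adult = means["adult"][0] - means["adult"][1]
        assert diff_es < 0 < diff_adult

    def test_identical_methylomes_give_constant_table(
        self, calls_by_stage, compartments_by_stage
    ):
        wt = ["ES", "progenitor", "fetal"]
        common = cm.common_compartments([compartments_by_stage[s] for s in wt])
        means = cm.compartment_mean_methylation_by_stage(
            {s: calls_by_stage["ES"] for s in wt}, common
        )
        rows = list(means.values())
        assert all(r == rows[0] for r in rows)

    def test_single_stage_rejected(self, calls_by_stage, compartments_by_stage):
        wt = ["ES", "adult"]
        common = cm.common_compartments([compartments_by_stage[s] for s in wt])
        with pytest.raises(CompartmethError):
            cm.compartment_mean_methylation_by_stage(
                {"ES": calls_by_stage["ES"]}, common
            )


@pytest.fixture(scope="module")
def profile(truth, calls_by_stage, compartments_by_stage):
    wt = [s for s in cm.STAGES if s != "adult_KO"]
    segments = {s: cm.segment_methylome(calls_by_stage[s]) for s in wt}
    expression = {
        s: cm.generate_activity(truth, s, seed=900 + i) for i, s in enumerate(wt)
    }
    regions = truth.switch_blocks["progenitor"]
    return cm.stage_profiles(
        regions, wt, segments, expression, {s: calls_by_stage[s] for s in wt}
    )


class TestStageProfiles:
    def test_pmd_coverage_appears_after_lag(self, profile):
        stages = profile.stages
        assert profile.pmd_bases[stages.index("ES")] == 0
        assert profile.pmd_bases[stages.index("progenitor")] == 0
        assert profile.pmd_bases[stages.index("fetal")] > 0
        assert profile.pmd_bases[stages.index("adult")] > 0

    def test_lmr_count_increases_after_b_to_a_switch(self, profile):
        stages = profile.stages
        assert profile.lmr_count[stages.index("adult")] > profile.lmr_count[
            stages.index("ES")
        ] * 0  # at least some LMRs appear in switched blocks
        assert profile.lmr_count[stages.index("adult")] >= profile.lmr_count[
            stages.index("ES")
        ]

    def test_empty_selection_rejected(self, truth, calls_by_stage):
        with pytest.raises(CompartmethError):
            cm.stage_profiles([], ["ES"], {}, {}, {})


class TestSamplePca:
    def test_identical_samples_collapse_to_origin(self):
        v = np.arange(10, dtype=float)
        emb = cm.sample_pca({"a": v, "b": v, "c": v})
        assert np.allclose(emb.coordinates, 0.0)

    def test_duplicated_sample_points_coincide(self):
        rng = np.random.default_rng(71)
        base = {f"s{i}": rng.normal(size=50) for i in range(3)}
        base["dup"] = base["s0"].copy()
        emb = cm.sample_pca(base)
        co = dict(zip(emb.sample_names, emb.coordinates))
        assert np.allclose(co["s0"], co["dup"])

    def test_variance_fractions_ordered(self):
        rng = np.random.default_rng(72)
        emb = cm.sample_pca({f"s{i}": rng.normal(size=30) for i in range(5)})
        v1, v2 = emb.variance_explained
        assert 0 <= v2 <= v1 <= 1

    def test_invariant_under_column_shift(self):
        rng = np.random.default_rng(73)
        data = {f"s{i}": rng.normal(size=40) for i in range(4)}
        shifted = {k: v + 11.5 for k, v in data.items()}
        e1, e2 = cm.sample_pca(data), cm.sample_pca(shifted)
        d1 = np.linalg.norm(e1.coordinates[0] - e1.coordinates[1])
        d2 = np.linalg.norm(e2.coordinates[0] - e2.coordinates[1])
        assert d1 == pytest.approx(d2)

    def test_too_few_samples_rejected(self):
        with pytest.raises(CompartmethError):
            cm.sample_pca({"a": np.zeros(5), "b": np.zeros(5)})

    def test_differentiated_stages_cluster_away_from_es(
        self, compartments_by_stage
    ):
        wt = [s for s in cm.STAGES if s != "adult_KO"]
        emb = cm.sample_pca({s: compartments_by_stage[s].track for s in wt})
        co = dict(zip(emb.sample_names, emb.coordinates))

        def dist(a, b):
            return float(np.linalg.norm(co[a] - co[b]))

        within = max(
            dist(a, b)
            for a, b in (("fetal", "newborn"), ("fetal", "adult"), ("newborn", "adult"))
        )
        assert within < dist("ES", "fetal")
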