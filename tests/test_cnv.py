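"""Normalisation, segmentation, integer ploidy fitting, altered calls, clones."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

import rarepc
from rarepc import cnv
from rarepc.genome import AUTOSOMES, HG19_CHROM_LENGTHS
from rarepc.synthetic import CloneSpec, CNVSimSpec, make_bin_table, simulate_cnv_cells


def _whole(chrom, cn):
    return (chrom, 0, HG19_CHROM_LENGTHS[chrom], cn)


def _flat_bins(n, gc=0.45):
    """Single-chromosome equal-width bin table with constant GC."""
    edges = np.linspace(0, n * 1000, n + 1).astype(int)
    return pd.DataFrame(
        {"chrom": "chr1", "start": edges[:-1], "end": edges[1:], "gc": gc}
    )


class TestNormalize:
    def test_flat_input_gives_exact_ones(self):
        bins = _flat_bins(100)
        ratios = cnv.normalize_bins(np.full(100, 50.0), bins)
        np.testing.assert_allclose(ratios, 1.0, atol=1e-12)

    def test_genome_mean_is_one(self, bins500):
        rng = np.random.default_rng(0)
        counts = rng.poisson(100, len(bins500))
        ratios = cnv.normalize_bins(counts, bins500)
        assert abs(ratios.mean() - 1.0) < 1e-9

    def test_scaling_counts_leaves_ratios_unchanged(self, bins500):
        rng = np.random.default_rng(1)
        counts = rng.poisson(100, len(bins500)).astype(float)
        a = cnv.normalize_bins(counts, bins500)
        b = cnv.normalize_bins(7.0 * counts, bins500)
        np.testing.assert_allclose(a, b, rtol=1e-9)

    def test_gc_bias_is_corrected(self, bins5000):
        spec = CNVSimSpec(
            clone_specs=(CloneSpec("dip", 2),), n_cells=1, n_bins=5000,
            dispersion=0.0, gc_bias_coefficients=(0.2, 2.0, -1.5), seed=8,
        )
        counts, _ = simulate_cnv_cells(spec, bins5000)
        gc = bins5000["gc"].to_numpy()
        width = (bins5000["end"] - bins5000["start"]).to_numpy(float)
        raw_corr = np.corrcoef(counts.iloc[0].to_numpy() / width, gc)[0, 1]
        ratios = cnv.normalize_bins(counts.iloc[0].to_numpy(), bins5000)
        assert abs(raw_corr) > 0.3  # bias was really injected
        assert abs(np.corrcoef(ratios, gc)[0, 1]) < 0.05

    def test_chr13_at_half_coverage_gives_half_ratio(self, bins5000):
        clone = CloneSpec("cl", 2, (_whole("chr13", 1),))
        spec = CNVSimSpec(clone_specs=(clone,), n_cells=1, n_bins=5000,
                          dispersion=0.0, seed=9)
        counts, _ = simulate_cnv_cells(spec, bins5000)
        ratios = cnv.normalize_bins(counts.iloc[0].to_numpy(), bins5000)
        chr13 = (bins5000["chrom"] == "chr13").to_numpy()
        assert abs(ratios[chr13].mean() / ratios.mean() - 0.5) < 0.05

    def test_all_zero_profile_errors(self, bins500):
        with pytest.raises(ValueError, match="zero"):
            cnv.normalize_bins(np.zeros(len(bins500)), bins500)


class TestSegmentation:
    def test_flat_ratios_give_one_segment_per_chromosome(self, bins500):
        segments = cnv.segment_profile(np.ones(len(bins500)), bins500)
        assert len(segments) == bins500["chrom"].nunique()
        assert (segments["n_bins"].to_numpy() == bins500.groupby("chrom", sort=False).size().to_numpy()).all()

    def test_step_breakpoints_recovered_within_two_bins(self):
        rng = np.random.default_rng(5)
        bins = _flat_bins(500)
        ratios = 1.0 + 0.1 * rng.standard_normal(500)
        ratios[200:250] += 0.5
        segments = cnv.segment_profile(ratios, bins)
        cuts = sorted(set(segments["start_bin"]) | set(segments["end_bin"]))
        assert any(abs(c - 200) <= 2 for c in cuts)
        assert any(abs(c - 250) <= 2 for c in cuts)

    def test_min_seg_bins_enforced(self):
        rng = np.random.default_rng(6)
        bins = _flat_bins(200)
        ratios = 1.0 + 0.05 * rng.standard_normal(200)
        ratios[100:103] += 1.0  # shorter than min_seg_bins
        segments = cnv.segment_profile(ratios, bins, min_seg_bins=5)
        assert (segments["n_bins"] >= 5).all()

    def test_segments_partition_chromosomes(self, bins500):
        rng = np.random.default_rng(7)
        ratios = 1.0 + 0.1 * rng.standard_normal(len(bins500))
        segments = cnv.segment_profile(ratios, bins500)
        for chrom, group in segments.groupby("chrom"):
            g = group.sort_values("start_bin")
            assert (g["end_bin"].to_numpy()[:-1] == g["start_bin"].to_numpy()[1:]).all()
        assert segments["n_bins"].sum() == len(bins500)


class TestPloidyFit:
    def test_flat_profile_resolves_to_diploid_by_tie_break(self, bins500):
        segments = cnv.segment_profile(np.ones(len(bins500)), bins500)
        fit = cnv.fit_ploidy(segments, bins500)
        assert fit.ploidy_scale == 2.0
        assert fit.baseline_ploidy == 2
        assert (fit.cn == 2).all()
        assert fit.degenerate

    def test_noise_free_round_trip_recovers_truth_exactly(self, bins5000):
        clone = CloneSpec("cl", 3, (_whole("chr2", 2), _whole("chr13", 1), _whole("chr5", 4)))
        truth_cn = clone.cn_per_bin(bins5000)
        width = (bins5000["end"] - bins5000["start"]).to_numpy(float)
        counts = truth_cn * width  # noise-free expected coverage
        profile = cnv.call_profile("c", counts, bins5000)
        np.testing.assert_array_equal(profile.cn, truth_cn)
        assert profile.baseline_ploidy == 3
        assert profile.altered

    def test_triploid_recovery_from_simulated_reads(self, bins5000):
        clone = CloneSpec("tri", 3, tuple(_whole(c, 2) for c in ("chr2", "chr4", "chr6", "chr8", "chr10")))
        spec = CNVSimSpec(clone_specs=(clone,), n_cells=20, dispersion=0.1, n_bins=5000, seed=14)
        counts, _ = simulate_cnv_cells(spec, bins5000)
        profiles = cnv.call_cells(counts, bins5000)
        recovered = sum(p.baseline_ploidy == 3 for p in profiles)
        assert recovered >= 19

    def test_pentaploid_with_single_chromosome_loss(self, bins5000):
        clone = CloneSpec("pen", 5, (_whole("chr8", 4),))
        spec = CNVSimSpec(clone_specs=(clone,), n_cells=5, dispersion=0.0, n_bins=5000, seed=15)
        counts, _ = simulate_cnv_cells(spec, bins5000)
        chr8 = (bins5000["chrom"] == "chr8").to_numpy()
        for profile in cnv.call_cells(counts, bins5000):
            assert profile.baseline_ploidy == 5
            assert np.median(profile.cn[chr8]) == 4


class TestAlteredCall:
    def _profile(self, cn, bins, baseline):
        return cnv.CopyNumberProfile(
            cell_id="c", ratios=cn / cn.mean(), segments=pd.DataFrame(),
            cn=cn, ploidy_scale=2.0, baseline_ploidy=baseline,
        )

    def test_flat_diploid_is_normal(self, bins500):
        cn = np.full(len(bins500), 2)
        assert not cnv.call_altered(self._profile(cn, bins500, 2), bins500)

    def test_13q_loss_spanning_30_bins_is_altered(self, bins500):
        cn = np.full(len(bins500), 2)
        chr13 = np.flatnonzero((bins500["chrom"] == "chr13").to_numpy())
        cn[chr13[:30]] = 1
        assert cnv.call_altered(self._profile(cn, bins500, 2), bins500)

    def test_short_event_below_min_bins_is_normal(self, bins500):
        cn = np.full(len(bins500), 2)
        chr13 = np.flatnonzero((bins500["chrom"] == "chr13").to_numpy())
        cn[chr13[:5]] = 1
        assert not cnv.call_altered(self._profile(cn, bins500, 2), bins500, min_event_bins=10)

    def test_flat_triploid_is_altered_by_ploidy(self, bins500):
        cn = np.full(len(bins500), 3)
        assert cnv.call_altered(self._profile(cn, bins500, 3), bins500)


class TestCloneGrouping:
    def _profile(self, cid, cn):
        return cnv.CopyNumberProfile(
            cell_id=cid, ratios=cn / cn.mean(), segments=pd.DataFrame(),
            cn=cn, ploidy_scale=2.0, baseline_ploidy=2, altered=True,
        )

    def test_identical_profiles_form_one_clone(self, bins500):
        cn = np.full(len(bins500), 2)
        cn[:40] = 3
        assign = cnv.group_clones([self._profile("a", cn), self._profile("b", cn.copy())], bins500)
        assert assign.assignments["a"] == assign.assignments["b"] == "clone_1"
        assert len(assign.consensus) == 1

    def test_whole_chromosome_difference_splits_at_095_merges_at_090(self, bins500):
        # chr2 is ~8% of autosomal bins: similarity 0.92 between the two cells
        cn1 = np.full(len(bins500), 2)
        cn1[:40] = 3
        cn2 = cn1.copy()
        chr2 = (bins500["chrom"] == "chr2").to_numpy()
        cn2[chr2] = 3
        cells = [self._profile("a", cn1), self._profile("b", cn2)]
        strict = cnv.group_clones(cells, bins500, similarity_threshold=0.95)
        assert strict.assignments["a"] != strict.assignments["b"]
        loose = cnv.group_clones(cells, bins500, similarity_threshold=0.90)
        assert loose.assignments["a"] == loose.assignments["b"]

    def test_five_clone_mixture_recovered_exactly_noise_free(self, bins5000):
        clones = {
            "A": (_whole("chr1", 3),),
            "B": (_whole("chr2", 3),),
            "C": (_whole("chr1", 3), _whole("chr2", 3)),
            "D": (_whole("chr3", 1),),
            "E": (_whole("chr1", 1),),
        }
        cells, labels = [], []
        for i in range(40):
            name = "ABCDE"[i % 5]
            cn = CloneSpec(name, 2, clones[name]).cn_per_bin(bins5000)
            cells.append(self._profile(f"c{i}", cn))
            labels.append(name)
        assign = cnv.group_clones(cells, bins5000)
        predicted = [assign.assignments[f"c{i}"] for i in range(40)]
        assert adjusted_rand_score(labels, predicted) == 1.0
        assert len(assign.consensus) == 5
        # consensus profiles equal the generating clone profiles
        for name in clones:
            members = [c for c, lab in zip(cells, labels) if lab == name]
            clone_label = assign.assignments[members[0].cell_id]
            np.testing.assert_array_equal(assign.consensus[clone_label], members[0].cn)

    def test_no_altered_cells_gives_empty_assignment(self, bins500):
        profile = cnv.CopyNumberProfile(
            cell_id="n", ratios=np.ones(len(bins500)), segments=pd.DataFrame(),
            cn=np.full(len(bins500), 2), ploidy_scale=2.0, baseline_ploidy=2, altered=False,
        )
        assign = cnv.group_clones([profile], bins500)
        assert assign.assignments["n"] == "normal"
        assert assign.consensus == {}

    def test_compartment_counts(self, bins500):
        cn = np.full(len(bins500), 2)
        cn[:40] = 3
        cells = [self._profile("a", cn), self._profile("b", cn.copy())]
        meta = pd.DataFrame({"cell_id": ["a", "b"], "compartment": ["PB", "BMA"]})
        assign = cnv.group_clones(cells, bins500, meta=meta)
        assert assign.counts.loc["clone_1", "PB"] == 1
        assert assign.counts.loc["clone_1", "BMA"] == 1


class TestMonotoneDegradation:
    def test_event_recall_does_not_improve_at_lower_depth(self, bins5000):
        clone = CloneSpec("cl", 2, (_whole("chr13", 1), _whole("chr5", 3)))
        recalls = []
        for reads in (500_000, 50_000):
            spec = CNVSimSpec(clone_specs=(clone,), n_cells=15, reads_per_cell=reads,
                              dispersion=0.1, n_bins=5000, seed=16)
            counts, _ = simulate_cnv_cells(spec, bins5000)
            profiles = cnv.call_cells(counts, bins5000)
            hits = total = 0
            for p in profiles:
                for chrom, true_cn in (("chr13", 1), ("chr5", 3)):
                    mask = (bins5000["chrom"] == chrom).to_numpy()
                    called = np.bincount(p.cn[mask]).argmax()
                    hits += called == true_cn
                    total += 1
            recalls.append(hits / total)
        assert recalls[0] >= recalls[1]
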