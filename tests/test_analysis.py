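"""Downstream analytics: change scores, hubness, permutation tests,
quartile association, dendrograms, gene ranking, perturbation editing."""

import numpy as np
import pytest

from virtualhic.analysis import (
    ChangeScoreTrack,
    PerturbationSpec,
    apply_perturbation,
    enhancer_importance,
    hic_dendrogram,
    interaction_change_score,
    linkage_to_newick,
    promoter_hubness,
    quantile_association,
    rank_genes_by_change,
    region_permutation_test,
)
from virtualhic.coords import GenomicRegion
from virtualhic.io_formats import (
    AnnotationTable,
    ContactMap,
    OneHotSequence,
    TrackSet,
)
from virtualhic.states import DEFAULT_VOCABULARY, MultiLabelStates


def uniform_map(n, value=0.0, chrom="chr1", bin_size=5000):
    region = GenomicRegion(chrom, 0, n * bin_size)
    return ContactMap(region, bin_size, np.full((n, n), float(value)))


class TestChangeScore:
    def test_ceiling_is_28(self):
        a = uniform_map(80, 0.0)
        b = uniform_map(80, 10.0)
        track = interaction_change_score(a, b)
        interior = track.scores[15:-15]
        assert (interior == 28).all()
        assert track.max_possible == 28

    def test_identical_maps_all_zero(self, symmetric_map):
        track = interaction_change_score(symmetric_map, symmetric_map)
        assert (track.scores == 0).all()

    def test_strict_threshold_inequality(self):
        a = uniform_map(80, 0.0)
        b = uniform_map(80, 0.0)
        i, off = 40, 7
        # delta exactly 3.0 -> not counted; 3.5 -> counted once per entry
        b.values[i, i + off] = b.values[i + off, i] = 3.0
        assert interaction_change_score(a, b).scores[i] == 0
        b.values[i, i + off] = b.values[i + off, i] = 3.5
        track = interaction_change_score(a, b)
        assert track.scores[i] == 1
        assert track.scores[i + off] == 1

    def test_excluded_vicinity(self):
        a = uniform_map(80, 0.0)
        b = uniform_map(80, 0.0)
        for off in (-1, 0, 1):
            b.values[40, 40 + off] = 10.0
            b.values[40 + off, 40] = 10.0
        assert interaction_change_score(a, b).scores[40] == 0

    def test_symmetric_in_arguments_and_shift_invariant(self, rng):
        n = 60
        m1 = rng.normal(size=(n, n)); m1 = 0.5 * (m1 + m1.T) * 4
        m2 = rng.normal(size=(n, n)); m2 = 0.5 * (m2 + m2.T) * 4
        region = GenomicRegion("chr1", 0, n * 5000)
        a, b = ContactMap(region, 5000, m1), ContactMap(region, 5000, m2)
        s_ab = interaction_change_score(a, b).scores
        s_ba = interaction_change_score(b, a).scores
        np.testing.assert_array_equal(s_ab, s_ba)
        shift = rng.normal(size=(n, n)); shift = 0.5 * (shift + shift.T)
        a2 = ContactMap(region, 5000, m1 + shift)
        b2 = ContactMap(region, 5000, m2 + shift)
        np.testing.assert_array_equal(
            interaction_change_score(a2, b2).scores, s_ab
        )

    def test_score_bounds_enforced(self):
        with pytest.raises(ValueError):
            ChangeScoreTrack(GenomicRegion("c", 0, 10_000), 5000,
                             np.array([29, 0]))


class TestHubness:
    def _promoters(self, positions, chrom="chr1"):
        return AnnotationTable.from_tuples(
            [(chrom, p, p + 1000, f"gene{i}") for i, p in enumerate(positions)]
        )

    def test_uniform_map_every_promoter_scores_v(self):
        cmap = uniform_map(300, 2.5)
        table = promoter_hubness(cmap, self._promoters([400_000, 700_000]))
        assert np.allclose(table.records.score, 2.5)

    def test_planted_stripe_ranks_first(self, rng):
        n = 300
        m = rng.normal(size=(n, n)); m = 0.5 * (m + m.T)
        p_hot = 100
        m[p_hot, :] += 5.0; m[:, p_hot] += 5.0
        cmap = ContactMap(GenomicRegion("chr1", 0, n * 5000), 5000, m)
        table = promoter_hubness(
            cmap, self._promoters([100 * 5000, 200 * 5000, 250 * 5000])
        )
        assert table.ranked().iloc[0].gene == "gene0"

    def test_threshold_mode_above_max_all_zero(self):
        cmap = uniform_map(300, 1.0)
        table = promoter_hubness(
            cmap, self._promoters([500_000]), mode="count", threshold=100.0
        )
        assert (table.records.score == 0).all()

    def test_edge_window_truncated_with_warning(self):
        cmap = uniform_map(120, 1.0)
        with pytest.warns(UserWarning, match="truncated"):
            table = promoter_hubness(cmap, self._promoters([10_000]))
        assert table.records.score.iloc[0] == pytest.approx(1.0)


class TestPermutationTest:
    def _regions(self, n=50, size=1_000_000):
        return [GenomicRegion("chr1", i * size, (i + 1) * size)
                for i in range(n)]

    def test_constructed_enrichment_significant(self):
        regions = self._regions()
        change = np.zeros(50); enh = np.zeros(50)
        hot = [3, 11, 27, 42]
        for h in hot:
            change[h] = enh[h] = 10.0
        genes = AnnotationTable.from_tuples(
            [("chr1", regions[h].start + 500_000,
              regions[h].start + 510_000, f"g{h}") for h in hot]
        )
        obs, p = region_permutation_test(
            change, enh, regions, genes, top_k=5, n_perm=1000, seed=0,
            gene_flank=0
        )
        assert obs == 1.0
        assert p <= 0.01

    def test_zero_permutations_error(self):
        regions = self._regions(10)
        genes = AnnotationTable.from_tuples([("chr1", 0, 1000, "g")])
        with pytest.raises(ValueError, match="n_perm"):
            region_permutation_test(
                np.ones(10), np.ones(10), regions, genes, n_perm=0
            )

    def test_null_p_values_roughly_uniform(self):
        # DE labels assigned at random -> the permutation p-values follow
        # the uniform distribution (up to the discreteness of the p grid)
        from scipy import stats

        regions = self._regions(200)
        rng = np.random.default_rng(1)
        pvals = []
        for rep in range(200):
            change = rng.normal(size=200)
            enh = change + rng.normal(size=200) * 0.1  # correlated rankings
            gene_idx = rng.choice(200, size=60, replace=True)
            genes = AnnotationTable.from_tuples(
                [("chr1", regions[i].start + 1000,
                  regions[i].start + 2000, f"g{k}")
                 for k, i in enumerate(gene_idx)]
            )
            _, p = region_permutation_test(
                change, enh, regions, genes, top_k=30, n_perm=499,
                seed=int(rng.integers(2**31)), gene_flank=0
            )
            pvals.append(p)
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01


class TestEnhancerImportance:
    def _states(self, enh_bins, n=400):
        region = GenomicRegion("chr1", 0, n * 5000)
        vals = np.zeros((n, 13), dtype=np.int8)
        vals[:, DEFAULT_VOCABULARY.index("Quies")] = 1
        for b in enh_bins:
            vals[b, DEFAULT_VOCABULARY.index("EnhA")] = 1
        return MultiLabelStates(region, 5000, vals)

    def test_window_counting(self):
        states = self._states([100, 101, 120, 300])
        promoters = AnnotationTable.from_tuples(
            [("chr1", 100 * 5000, 100 * 5000 + 1000, "g1")]
        )
        table = enhancer_importance(states, promoters, mode="gene")
        # ±0.25 Mb = ±50 bins around bin 100 -> bins 100,101,120 counted
        assert table.records.score.iloc[0] == 3

    def test_no_enhancers_all_zero(self):
        states = self._states([])
        promoters = AnnotationTable.from_tuples(
            [("chr1", 500_000, 501_000, "g")]
        )
        table = enhancer_importance(states, promoters, mode="gene")
        assert (table.records.score == 0).all()

    def test_region_mode_conserves_total(self):
        states = self._states([5, 100, 250, 399])
        regions = [GenomicRegion("chr1", i * 1_000_000, (i + 1) * 1_000_000)
                   for i in range(2)]
        table = enhancer_importance(states, regions=regions,
                                    mode="region-1Mb")
        assert table.records.score.sum() == 4


class TestQuantileAssociation:
    def test_quartile_sizes_and_coupling(self, small_map,
                                         small_tracks_states):
        _, states = small_tracks_states
        out = quantile_association(small_map, states)
        sizes = out["quartile_sizes"]
        assert max(sizes) - min(sizes) <= 1
        counts = out["enhancer_counts"]
        # activity-coupled enhancer states concentrate in the top quartile
        assert counts[3] > counts[0]
        assert out["p_values"]["q0_vs_q3"] < 0.01


class TestDendrogram:
    def _map(self, rng, n=400, jitter=0.0, base=None):
        if base is None:
            base = rng.normal(size=(n, n))
            base = 0.5 * (base + base.T)
        m = base + jitter * rng.normal(size=(n, n))
        m = 0.5 * (m + m.T)
        return ContactMap(GenomicRegion("chr1", 0, n * 5000), 5000, m), base

    def test_identical_tissues_merge_first(self, rng):
        a, base = self._map(rng)
        b, _ = self._map(rng, jitter=0.0, base=base)  # identical to a
        c, _ = self._map(rng)  # independent
        link, names = hic_dendrogram({"a": a, "b": b, "c": c})
        # first merge joins the identical pair at height ~0
        first = link[0]
        assert {int(first[0]), int(first[1])} == {0, 1}
        assert first[2] == pytest.approx(0.0, abs=1e-9)
        newick = linkage_to_newick(link, names)
        assert newick.endswith(";") and "a" in newick and "c" in newick

    def test_planted_similarity_recovered(self, rng):
        a, base = self._map(rng)
        b, _ = self._map(rng, jitter=0.3, base=base)
        c, _ = self._map(rng)
        link, names = hic_dendrogram({"a": a, "b": b, "c": c})
        assert {int(link[0][0]), int(link[0][1])} == {0, 1}

    def test_grid_mismatch_error(self, rng):
        a, _ = self._map(rng, n=400)
        c, _ = self._map(rng, n=200)
        with pytest.raises(ValueError, match="grid"):
            hic_dendrogram({"a": a, "c": c})


class TestRankGenes:
    def test_zero_track_zero_scores_and_hot_bin_ranking(self):
        region = GenomicRegion("chr1", 0, 500 * 5000)
        scores = np.zeros(500, dtype=int)
        track = ChangeScoreTrack(region, 5000, scores)
        genes = AnnotationTable.from_tuples(
            [("chr1", 300_000, 310_000, "far"),
             ("chr1", 2_000_000, 2_010_000, "near")]
        )
        table = rank_genes_by_change(track, genes)
        assert (table.records.score == 0).all()
        scores[400] = 20  # bin 400 = 2.0 Mb, within near±0.6Mb only
        track = ChangeScoreTrack(region, 5000, scores)
        table = rank_genes_by_change(track, genes)
        ranked = table.ranked()
        assert ranked.iloc[0].gene == "near"
        assert ranked.iloc[0].score == 20

    def test_equal_windows_equal_scores(self, rng):
        region = GenomicRegion("chr1", 0, 600 * 5000)
        track = ChangeScoreTrack(region, 5000,
                                 rng.integers(0, 5, size=600))
        genes = AnnotationTable.from_tuples(
            [("chr1", 1_500_000, 1_510_000, "g1"),
             ("chr1", 1_500_000, 1_510_000, "g2")]
        )
        table = rank_genes_by_change(track, genes)
        assert table.records.score.iloc[0] == table.records.score.iloc[1]


class TestPerturbation:
    def _inputs(self, rng, n_bp=100_000, res=25):
        region = GenomicRegion("chr1", 0, n_bp)
        seq = OneHotSequence.from_string(
            region, "".join(rng.choice(list("ACGT"), size=n_bp))
        )
        tracks = TrackSet(
            region, ["a", "b"], res, rng.normal(size=(2, n_bp // res))
        )
        return seq, tracks

    def test_insertion_length_arithmetic(self, rng):
        seq, tracks = self._inputs(rng)
        spec = PerturbationSpec(
            "insertion", GenomicRegion("chr1", 10_000, 12_000), target=50_000
        )
        new_seq, new_tracks = apply_perturbation(seq, tracks, spec)
        assert len(new_seq.region) == 102_000
        assert new_tracks.values.shape[1] == 102_000 // 25  # +80 positions

    def test_delete_then_reinsert_is_identity(self, rng):
        seq, tracks = self._inputs(rng)
        span = GenomicRegion("chr1", 20_000, 22_000)
        del_seq, del_tracks = apply_perturbation(
            seq, tracks, PerturbationSpec("deletion", span)
        )
        # re-insert the deleted content at the same place
        piece_seq = seq.values[20_000:22_000]
        ins_seq = np.concatenate(
            [del_seq.values[:20_000], piece_seq, del_seq.values[20_000:]]
        )
        np.testing.assert_array_equal(ins_seq, seq.values)
        piece_tr = tracks.values[:, 800:880]
        ins_tr = np.concatenate(
            [del_tracks.values[:, :800], piece_tr,
             del_tracks.values[:, 800:]], axis=1,
        )
        np.testing.assert_array_equal(ins_tr, tracks.values)

    def test_duplication_default_target(self, rng):
        seq, tracks = self._inputs(rng)
        span = GenomicRegion("chr1", 30_000, 31_000)
        new_seq, _ = apply_perturbation(
            seq, tracks, PerturbationSpec("duplication", span)
        )
        np.testing.assert_array_equal(
            new_seq.values[31_000:32_000], seq.values[30_000:31_000]
        )

    def test_out_of_register_edit_rejected(self, rng):
        seq, tracks = self._inputs(rng)
        with pytest.raises(ValueError, match="register|aligned"):
            apply_perturbation(
                seq, tracks,
                PerturbationSpec("deletion", GenomicRegion("chr1", 100, 130)),
            )
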