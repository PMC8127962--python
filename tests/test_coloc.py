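import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from granulekit import synth
from granulekit.coloc import (
    colocalization_fraction,
    fold_enrichment,
    match_granules,
)
from granulekit.detect import segment_granules

from oracles import exhaustive_matching


class TestMatchGranules:
    def test_identical_centroids_all_matched(self, make_granule_set):
        cents = {1: [(10, 10), (20, 20), (30, 15)]}
        a = make_granule_set(cents, channel="A")
        b = make_granule_set(cents, channel="B")
        res = match_granules(a, b, cutoff_um=0.5)
        assert len(res.matches) == 3
        assert all(m.distance_um == 0.0 for m in res.matches)
        per_cell, pooled = colocalization_fraction(res)
        assert per_cell == {1: 100.0}
        assert pooled == 100.0

    def test_empty_b(self, make_granule_set):
        a = make_granule_set({1: [(10, 10), (20, 20)]})
        b = make_granule_set({1: []}, channel="B")
        res = match_granules(a, b)
        assert res.matches == []
        _, pooled = colocalization_fraction(res)
        assert pooled == 0.0

    def test_image_id_mismatch(self, make_granule_set):
        a = make_granule_set({1: [(1, 1)]}, image_id="x")
        b = make_granule_set({1: [(1, 1)]}, image_id="y")
        with pytest.raises(ValueError, match="image id mismatch"):
            match_granules(a, b)

    def test_no_cross_cell_matches(self, make_granule_set):
        # the only B granule sits in another cell, even at the same position
        a = make_granule_set({1: [(10, 10)], 2: []})
        b = make_granule_set({1: [], 2: [(10, 10)]}, channel="B")
        res = match_granules(a, b, cutoff_um=100.0)
        assert res.matches == []

    def test_one_to_one(self, make_granule_set):
        # two A granules near one B granule: only one may claim it
        a = make_granule_set({1: [(10.0, 10.0), (10.0, 12.0)]})
        b = make_granule_set({1: [(10.0, 10.5)]}, channel="B")
        res = match_granules(a, b, cutoff_um=1.0)
        assert len(res.matches) == 1
        assert res.matches[0].granule_a == 0  # the closer one

    def test_planted_offsets_match_exhaustive(self, make_granule_set):
        # 5 A and 5 B, 3 planted within cutoff and 2 beyond
        rng = np.random.default_rng(4)
        a_pts = np.array([[10, 10], [10, 40], [40, 10], [40, 40], [25, 25]], float)
        offsets = np.array(
            [[0.2, 0.1], [-0.3, 0.2], [0.1, -0.4], [30.0, 0.0], [0.0, 30.0]]
        )
        b_pts = a_pts + offsets
        a = make_granule_set({1: [tuple(p) for p in a_pts]})
        b = make_granule_set({1: [tuple(p) for p in b_pts]}, channel="B")
        cutoff = 0.5  # um; 0.1 um/px
        res = match_granules(a, b, cutoff_um=cutoff)
        ours = {(m.granule_a, m.granule_b) for m in res.matches}
        oracle = exhaustive_matching(a_pts * 0.1, b_pts * 0.1, cutoff)
        assert ours == oracle
        assert len(ours) == 3
        del rng

    @pytest.mark.parametrize("seed", range(10))
    def test_greedy_equals_exhaustive_seeded(self, seed, make_granule_set):
        # separated A centroids (> 2x cutoff apart), jittered B
        rng = np.random.default_rng(seed)
        grid = np.array([[y, x] for y in (10, 30, 50) for x in (10, 30, 50)], float)
        a_pts = grid[rng.choice(9, size=5, replace=False)]
        a_pts = a_pts + rng.uniform(-2, 2, size=(5, 2))
        b_pts = a_pts + rng.uniform(-6, 6, size=(5, 2))
        a = make_granule_set({1: [tuple(p) for p in a_pts]})
        b = make_granule_set({1: [tuple(p) for p in b_pts]}, channel="B")
        res = match_granules(a, b, cutoff_um=0.5)
        ours = {(m.granule_a, m.granule_b) for m in res.matches}
        oracle = exhaustive_matching(a_pts * 0.1, b_pts * 0.1, 0.5)
        assert ours == oracle

    def test_symmetric_in_distance(self, make_granule_set):
        rng = np.random.default_rng(6)
        a_pts = [(float(r), float(c)) for r, c in rng.uniform(5, 60, (6, 2))]
        b_pts = [(float(r), float(c)) for r, c in rng.uniform(5, 60, (6, 2))]
        a = make_granule_set({1: a_pts})
        b = make_granule_set({1: b_pts}, channel="B")
        fwd = {
            frozenset((m.granule_a, m.granule_b))
            for m in match_granules(a, b, cutoff_um=2.0).matches
        }
        rev = {
            frozenset((m.granule_b, m.granule_a))
            for m in match_granules(b, a, cutoff_um=2.0).matches
        }
        assert fwd == rev

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 5000))
    def test_fraction_monotone_in_cutoff(self, seed):
        from conftest import make_set

        rng = np.random.default_rng(seed)
        a_pts = [(float(r), float(c)) for r, c in rng.uniform(0, 80, (5, 2))]
        b_pts = [(float(r), float(c)) for r, c in rng.uniform(0, 80, (5, 2))]
        a = make_set({1: a_pts})
        b = make_set({1: b_pts}, channel="B")
        last = -1.0
        for cutoff in [0.1, 0.5, 1.0, 2.0, 5.0, 10.0]:
            _, pooled = colocalization_fraction(match_granules(a, b, cutoff_um=cutoff))
            assert pooled >= last
            last = pooled

    def test_each_granule_in_at_most_one_match(self, make_granule_set):
        rng = np.random.default_rng(7)
        a = make_granule_set({1: [tuple(p) for p in rng.uniform(0, 50, (8, 2))]})
        b = make_granule_set(
            {1: [tuple(p) for p in rng.uniform(0, 50, (8, 2))]}, channel="B"
        )
        res = match_granules(a, b, cutoff_um=5.0)
        a_ids = [m.granule_a for m in res.matches]
        b_ids = [m.granule_b for m in res.matches]
        assert len(a_ids) == len(set(a_ids))
        assert len(b_ids) == len(set(b_ids))
        assert all(m.distance_um <= 5.0 for m in res.matches)


class TestColocalizationFraction:
    def test_three_of_four(self, make_granule_set):
        a = make_granule_set({1: [(10, 10), (20, 20), (30, 30), (45, 45)]})
        b = make_granule_set({1: [(10, 10), (20, 20), (30, 30)]}, channel="B")
        _, pooled = colocalization_fraction(match_granules(a, b, cutoff_um=0.5))
        assert pooled == 75.0

    def test_all_cells_empty_error(self, make_granule_set):
        a = make_granule_set({1: []})
        b = make_granule_set({1: [(5, 5)]}, channel="B")
        res = match_granules(a, b)
        with pytest.raises(ValueError, match="no cells"):
            colocalization_fraction(res, reference="A")

    def test_reference_b(self, make_granule_set):
        a = make_granule_set({1: [(10, 10)]})
        b = make_granule_set({1: [(10, 10), (30, 30)]}, channel="B")
        _, pooled_a = colocalization_fraction(match_granules(a, b), reference="A")
        _, pooled_b = colocalization_fraction(match_granules(a, b), reference="B")
        assert pooled_a == 100.0
        assert pooled_b == 50.0


class TestFoldEnrichment:
    def test_uniform_signal_fold_one(self, reference_field):
        fi, _ = reference_field
        gs = segment_granules(fi, "A")
        uniform = np.full(fi.shape, 42.0)
        enr = fold_enrichment(gs, uniform, fi.cell_mask)
        np.testing.assert_allclose(enr.per_granule["fold"], 1.0)

    def test_direct_ratio(self, make_granule_set):
        # one granule whose pixel reads 300 in a cell with mean 100
        signal = np.full((20, 20), 100.0)
        mask = np.ones((20, 20), dtype=np.uint16)
        gs = make_granule_set({1: [(5, 5)]})
        signal[5, 5] = 300.0
        cell_mean = signal[mask == 1].mean()
        enr = fold_enrichment(gs, signal, mask)
        assert enr.per_granule["fold"][0] == pytest.approx(300.0 / cell_mean)

    def test_scale_invariance(self, reference_field):
        fi, _ = reference_field
        gs = segment_granules(fi, "A")
        e1 = fold_enrichment(gs, fi.channels["B"], fi.cell_mask)
        e2 = fold_enrichment(gs, 13.7 * fi.channels["B"], fi.cell_mask)
        np.testing.assert_allclose(
            e1.per_granule["fold"], e2.per_granule["fold"], rtol=1e-12
        )

    def test_zero_cell_mean_error(self, make_granule_set):
        signal = np.zeros((10, 10))
        mask = np.ones((10, 10), dtype=np.uint16)
        gs = make_granule_set({1: [(4, 4)]})
        with pytest.raises(ValueError, match="zero whole-cell mean"):
            fold_enrichment(gs, signal, mask)

    def test_excess_reports_fold_minus_one(self, reference_field):
        fi, _ = reference_field
        gs = segment_granules(fi, "A")
        base = fold_enrichment(gs, fi.channels["B"], fi.cell_mask)
        exc = fold_enrichment(gs, fi.channels["B"], fi.cell_mask, excess=True)
        np.testing.assert_allclose(
            exc.per_granule["fold"], base.per_granule["fold"] - 1.0
        )

    def test_planted_fold_recovered_zero_noise(self):
        params = synth.FieldParams()  # no noise, flat illumination
        fi, gt = synth.generate_field_image(params, seed=5)
        gs = segment_granules(fi, "A")
        enr = fold_enrichment(gs, fi.channels["B"], fi.cell_mask)
        assert enr.mean_fold == pytest.approx(gt.planted_enrichment, rel=0.05)

    def test_non_recruiting_fold_near_one_zero_noise(self):
        params = synth.FieldParams(recruiting_fraction=0.0)
        fi, gt = synth.generate_field_image(params, seed=6)
        gs = segment_granules(fi, "A")
        enr = fold_enrichment(gs, fi.channels["B"], fi.cell_mask)
        np.testing.assert_allclose(enr.per_granule["fold"], 1.0, atol=1e-9)
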