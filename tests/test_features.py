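import numpy as np
import pytest

from spex import (
    Contact,
    ContactSet,
    DataError,
    GeneRecord,
    SyntheticTrackStore,
    assemble_tensor,
    build_bin_grid,
    decay_basis,
    linear_features,
    read_tensor_archive,
    select_spatial_regions,
    spatial_feature,
    track_predictor,
    window_signal,
    write_tensor_archive,
)
from spex.features import FeatureTensor, LINEAR_SCOPE, MIN_COUNT


def exhaustive_select(contacts, gene, resolution, linear_scope=LINEAR_SCOPE, min_count=MIN_COUNT):
    """Independent oracle: apply the selection rule to every contact."""
    win = (gene.tss, gene.tss + resolution)
    scope = (gene.tss - linear_scope, gene.tss + linear_scope)

    def overlaps(s, e, lo, hi):
        return s < hi and lo < e

    regions = set()
    for c in contacts:
        if c.chrom != gene.chrom or c.count < min_count:
            continue
        for near, other in (((c.start1, c.end1), (c.start2, c.end2)),
                            ((c.start2, c.end2), (c.start1, c.end1))):
            if not overlaps(near[0], near[1], *win):
                continue
            if overlaps(other[0], other[1], *scope):
                continue
            regions.add((gene.chrom, other[0], other[1]))
    return sorted(regions)


def random_contact_set(seed, n=2000, res=5000, n_bins=400):
    rng = np.random.default_rng(seed)
    contacts = [
        Contact("chr1", int(s1) * res, (int(s1) + 1) * res,
                int(s2) * res, (int(s2) + 1) * res, int(c))
        for s1, s2, c in zip(rng.integers(0, n_bins, n),
                             rng.integers(0, n_bins, n),
                             rng.integers(1, 5, n))
    ]
    return ContactSet(res, contacts)


class TestBinGrid:
    def test_plus_strand_tiling(self):
        grid = build_bin_grid(GeneRecord("G", "chr1", 100_000, "+"))
        assert grid.n_bins == 200
        assert grid.starts[0] == 80_000
        assert grid.starts[-1] == 119_800
        assert np.all(np.diff(grid.starts) == 200)
        # bin 100 starts at the TSS
        assert grid.starts[100] == 100_000

    def test_minus_strand_reverses_orientation_not_coordinates(self):
        plus = build_bin_grid(GeneRecord("G", "chr1", 100_000, "+"))
        minus = build_bin_grid(GeneRecord("G", "chr1", 100_000, "-"))
        assert sorted(minus.starts) == sorted(plus.starts)
        # index 0 is the most upstream bin: for '-' that is the highest coordinate
        assert minus.starts[0] == 119_800

    def test_window_truncated_at_chromosome_start(self, caplog):
        with caplog.at_level("INFO"):
            grid = build_bin_grid(GeneRecord("G", "chr1", 4_000, "+"))
        assert grid.truncated
        assert int((~grid.valid).sum()) == (20_000 - 4_000) // 200

    def test_full_scale_raw_value_count(self):
        grid = build_bin_grid(GeneRecord("G", "chr1", 100_000, "+"))
        assert 2002 * grid.n_bins == 400_400


class TestDecayBasis:
    def test_weight_invariants(self):
        basis = decay_basis(10)
        w = basis.weights
        assert w.shape == (20, 200)
        assert np.all((w >= 0) & (w <= 1))
        # upstream rows vanish downstream and vice versa
        assert not w[:10, 100:].any()
        assert not w[10:, :100].any()
        # weights decay with distance on the active side
        assert np.all(np.diff(w[:10, :100], axis=1) > 0)  # approaching the TSS
        assert np.all(np.diff(w[10:, 100:], axis=1) < 0)

    def test_infinite_lambda_limit_is_plain_sum(self, rng):
        sig = rng.normal(size=(3, 200))
        basis = decay_basis(1, lambdas=[1e18])
        out = linear_features(sig, basis)
        np.testing.assert_allclose(out[:, 0], sig[:, :100].sum(axis=1), rtol=1e-10)
        np.testing.assert_allclose(out[:, 1], sig[:, 100:].sum(axis=1), rtol=1e-10)

    def test_linear_features_matches_double_loop_oracle(self, rng):
        sig = rng.normal(size=(3, 200))
        basis = decay_basis(2, lambdas=[400.0, 3200.0])
        out = linear_features(sig, basis)
        expected = np.zeros((3, 4))
        for f in range(3):
            for k in range(4):
                for j in range(200):
                    expected[f, k] += basis.weights[k, j] * sig[f, j]
        np.testing.assert_allclose(out, expected, rtol=1e-12)

    def test_full_scale_feature_count(self):
        basis = decay_basis(10)
        out = linear_features(np.ones((2002, 200)), basis)
        assert out.size == 40_040

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            linear_features(np.ones((3, 100)), decay_basis(10))


class TestSpatialSelection:
    GENE = GeneRecord("G", "chr1", 100_000, "+")

    def make(self, *contacts, res=5000):
        return ContactSet(res, contacts)

    def test_qualifying_contact_yields_other_anchor(self):
        cs = self.make(Contact("chr1", 100_000, 105_000, 400_000, 405_000, 3))
        sel = select_spatial_regions(cs, self.GENE)
        assert sel.regions == [("chr1", 400_000, 405_000)]
        assert not sel.used_fallback

    def test_count_below_threshold_excluded(self):
        cs = self.make(Contact("chr1", 100_000, 105_000, 400_000, 405_000, 1))
        sel = select_spatial_regions(cs, self.GENE)
        assert sel.used_fallback and sel.regions == []

    def test_other_anchor_inside_linear_scope_excluded(self):
        cs = self.make(Contact("chr1", 100_000, 105_000, 110_000, 115_000, 5))
        sel = select_spatial_regions(cs, self.GENE)
        assert sel.used_fallback and sel.regions == []

    def test_anchor_must_overlap_tss_window(self):
        # anchored one bin downstream of the TSS window
        cs = self.make(Contact("chr1", 105_000, 110_000, 400_000, 405_000, 3))
        assert select_spatial_regions(cs, self.GENE).used_fallback

    def test_duplicate_other_anchors_deduplicated(self):
        cs = ContactSet(
            5000,
            [
                Contact("chr1", 95_000, 100_000, 400_000, 405_000, 3),
                Contact("chr1", 100_000, 105_000, 400_000, 405_000, 4),
            ],
        )
        # only the second contact overlaps [tss, tss+res); add a third via
        # an anchor pair that also ends at the same distal bin
        sel = select_spatial_regions(cs, self.GENE)
        assert sel.regions == [("chr1", 400_000, 405_000)]

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exhaustive_filter(self, seed):
        cs = random_contact_set(seed)
        rng = np.random.default_rng(1000 + seed)
        for tss in rng.integers(30_000, 1_900_000, 20):
            gene = GeneRecord("G", "chr1", int(tss), "+")
            sel = select_spatial_regions(cs, gene)
            assert sel.regions == exhaustive_select(list(cs), gene, cs.resolution)

    @pytest.mark.parametrize("seed", range(5))
    def test_threshold_and_scope_monotonicity(self, seed):
        cs = random_contact_set(seed, n=800)
        rng = np.random.default_rng(2000 + seed)
        for tss in rng.integers(30_000, 1_900_000, 10):
            gene = GeneRecord("G", "chr1", int(tss), "+")
            base = set(select_spatial_regions(cs, gene, min_count=2).regions)
            relaxed = set(select_spatial_regions(cs, gene, min_count=1).regions)
            assert base <= relaxed  # lowering min_count never removes regions
            wider = set(select_spatial_regions(cs, gene, linear_scope=40_000).regions)
            assert wider <= base  # raising linear_scope never adds regions


class TestSpatialFeature:
    def test_constant_track_region_sum(self):
        store = SyntheticTrackStore({"chr1": np.full((2, 500_000), 3.0)})
        pred = track_predictor(store)
        gene = GeneRecord("G", "chr1", 100_000, "+")
        grid = build_bin_grid(gene)
        cs = ContactSet(400, [Contact("chr1", 100_000, 100_400, 400_000, 400_400, 2)])
        sel = select_spatial_regions(cs, gene)
        vec = spatial_feature(sel, pred, grid)
        # one region of two 200 bp bins on a constant-3 track sums to 6
        np.testing.assert_allclose(vec, np.full(2, 6.0), rtol=1e-12)

    def test_fallback_equals_unweighted_window_sum(self, tiny_dataset, tiny_predictor):
        gene = tiny_dataset.genes[0]
        grid = build_bin_grid(gene)
        sig = window_signal(grid, tiny_predictor)
        sel = select_spatial_regions(ContactSet(5000), gene)
        assert sel.used_fallback
        np.testing.assert_allclose(
            spatial_feature(sel, tiny_predictor, grid), sig.sum(axis=1), rtol=1e-12
        )

    def test_all_zero_store_gives_all_zero_tensor(self):
        store = SyntheticTrackStore({"chr1": np.zeros((3, 500_000))})
        pred = track_predictor(store)
        gene = GeneRecord("G", "chr1", 100_000, "+")
        cs = ContactSet(5000, [Contact("chr1", 100_000, 105_000, 400_000, 405_000, 4)])
        from spex import build_gene_tensor

        t = build_gene_tensor(gene, cs, pred, decay_basis(10))
        assert not t.matrix.any()


class TestTensorAssemblyAndArchive:
    def test_shape_and_spatial_column_placement(self, rng):
        lin = rng.normal(size=(20, 20))
        sp = rng.normal(size=20)
        t = assemble_tensor(lin, sp, "G1", 10, 5000, False)
        assert t.matrix.shape == (20, 21)
        np.testing.assert_array_equal(t.matrix[:, :-1], lin)
        np.testing.assert_array_equal(t.matrix[:, -1], sp)

    def test_zero_spatial_leaves_decay_columns(self, rng):
        lin = rng.normal(size=(5, 4))
        t = assemble_tensor(lin, np.zeros(5), "G1", 2, 5000, True)
        np.testing.assert_array_equal(t.matrix[:, :-1], lin)

    def test_flatten_round_trip(self, rng):
        t = assemble_tensor(rng.normal(size=(5, 4)), rng.normal(size=5), "G1", 2, 5000, False)
        flat = t.flatten()
        assert flat.shape == (25,)
        np.testing.assert_array_equal(flat.reshape(5, 5), t.matrix)

    def test_row_mismatch_rejected(self):
        with pytest.raises(DataError):
            assemble_tensor(np.ones((5, 4)), np.ones(6), "G1", 2, 5000, False)

    def test_archive_round_trip_bit_exact(self, tmp_path, rng):
        tensors = [
            FeatureTensor(f"G{i}", rng.normal(size=(4, 21)), 10, 5000, bool(i % 2))
            for i in range(10)
        ]
        p = tmp_path / "arch.h5"
        write_tensor_archive(tensors, p)
        back = read_tensor_archive(p)
        assert len(back) == 10
        for t in tensors:
            np.testing.assert_array_equal(back[t.gene_id].matrix, t.matrix)
            assert back[t.gene_id].used_fallback == t.used_fallback

    def test_duplicate_gene_key_rejected(self, tmp_path, rng):
        ts = [FeatureTensor("G", rng.normal(size=(2, 5)), 2, 5000, False)] * 2
        with pytest.raises(DataError, match="duplicate"):
            write_tensor_archive(ts, tmp_path / "a.h5")

    def test_missing_gene_named_in_error(self, tmp_path, rng):
        write_tensor_archive(
            [FeatureTensor("G1", rng.normal(size=(2, 5)), 2, 5000, False)],
            tmp_path / "a.h5",
        )
        with pytest.raises(KeyError, match="G99"):
            read_tensor_archive(tmp_path / "a.h5", gene_ids=["G99"])
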