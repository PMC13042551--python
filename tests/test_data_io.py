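import numpy as np
import pytest

from s3rl.data_io import (SpatialDataset, extract_patches, normalize_expression,
                          read_dataset, select_hvgs, write_dataset)


@pytest.fixture
def tiny_ds():
    return SpatialDataset(
        X=np.array([[0, 1, 2, 0], [3, 0, 0, 1], [5, 5, 0, 0]], dtype=float),
        S=np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0]]),
        gene_names=["g1", "g2", "g3", "g4"],
        spot_ids=["s1", "s2", "s3"],
        labels=np.array([0, 0, 1]),
    )


class TestRoundTrip:
    @pytest.mark.parametrize("fmt", ["h5ad", "mtx_triplet", "csv"])
    def test_read_write_identity(self, tiny_ds, fmt, tmp_path):
        if fmt == "h5ad":
            path = tmp_path / "ds.h5ad"
        elif fmt == "mtx_triplet":
            path = tmp_path / "triplet"
        else:
            path = tmp_path / "expr.csv"
        write_dataset(tiny_ds, path, format=fmt)
        back = read_dataset(path, format=fmt)
        np.testing.assert_array_equal(back.X, tiny_ds.X)
        np.testing.assert_allclose(back.S, tiny_ds.S, atol=1e-6)
        assert back.spot_ids == tiny_ds.spot_ids
        assert back.gene_names == tiny_ds.gene_names
        np.testing.assert_array_equal(np.asarray(back.labels).astype(int),
                                      tiny_ds.labels)

    def test_h5ad_preserves_patches(self, tiny_ds, tmp_path):
        tiny_ds.patches = np.arange(3 * 4 * 4 * 3, dtype=np.uint8).reshape(3, 4, 4, 3)
        write_dataset(tiny_ds, tmp_path / "p.h5ad")
        back = read_dataset(tmp_path / "p.h5ad")
        np.testing.assert_array_equal(back.patches, tiny_ds.patches)

    def test_missing_file_names_the_file(self, tmp_path):
        with pytest.raises(FileNotFoundError, match="matrix.mtx"):
            read_dataset(tmp_path, format="mtx_triplet")

    def test_row_count_mismatch_reports_both_counts(self, tiny_ds, tmp_path):
        write_dataset(tiny_ds, tmp_path / "expr.csv", format="csv")
        coords = tmp_path / "coordinates.csv"
        lines = coords.read_text().splitlines()
        coords.write_text("\n".join(lines[:-1]))  # drop one spot
        with pytest.raises(ValueError, match="2 rows.*3 spots"):
            read_dataset(tmp_path / "expr.csv", format="csv")


class TestNormalize:
    def test_all_zero_row_stays_zero(self):
        out = normalize_expression(np.array([[0.0, 0.0], [1.0, 2.0]]))
        np.testing.assert_array_equal(out[0], [0.0, 0.0])

    def test_log1p_at_target_library_size(self):
        out = normalize_expression(np.array([[1.0, 3.0]]), target_sum=4)
        np.testing.assert_allclose(out[0], np.log1p([1.0, 3.0]), atol=1e-4)

    def test_library_scaling_is_depth_invariant(self, rng):
        x = rng.poisson(3.0, size=(1, 30)).astype(float) + 1
        np.testing.assert_allclose(normalize_expression(x),
                                   normalize_expression(2 * x), atol=1e-12)

    def test_monotone_for_equal_library_size(self):
        x = np.array([[1.0, 3.0]])
        y = np.array([[2.0, 2.0]])  # same library size, reordered mass
        nx, ny = normalize_expression(x), normalize_expression(y)
        assert nx[0, 0] < ny[0, 0] and nx[0, 1] > ny[0, 1]

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            normalize_expression(np.array([[-1.0, 2.0]]))

    def test_optional_bare_log(self):
        x = np.array([[1.0, 3.0]])
        np.testing.assert_allclose(
            normalize_expression(x, library_scale=False), np.log1p(x))


def _hvg_oracle(X, n_top):
    """Independent loop-based reimplementation of the dispersion ranking."""
    import pandas as pd

    lib = X.sum(axis=1, keepdims=True)
    lib[lib == 0] = 1
    Xe = np.expm1(np.log1p(1e4 * X / lib))
    n_genes = X.shape[1]
    mu, disp = np.zeros(n_genes), np.zeros(n_genes)
    for g in range(n_genes):
        col = Xe[:, g]
        mu[g] = col.mean()
        if mu[g] > 0 and len(col) > 1:
            disp[g] = col.var(ddof=1) / mu[g]
    bins = np.asarray(pd.cut(mu, bins=20, labels=False, duplicates="drop"),
                      dtype=float)
    bins[np.isnan(bins)] = -1
    g_sd = disp.std(ddof=1) if n_genes > 1 else 0.0
    dn = np.zeros(n_genes)
    for b in set(bins):
        members = [g for g in range(n_genes) if bins[g] == b]
        vals = disp[members]
        sd = vals.std(ddof=1) if len(members) > 1 else 0.0
        for g in members:
            if sd > 0:
                dn[g] = (disp[g] - vals.mean()) / sd
            elif g_sd > 0:
                dn[g] = (disp[g] - disp.mean()) / g_sd
    dn = np.round(dn, 10)
    order = sorted(range(n_genes), key=lambda g: (-dn[g], g))
    return order[:n_top]


class TestSelectHVGs:
    def test_all_genes_is_identity_as_set(self, rng):
        X = rng.poisson(2.0, size=(20, 8)).astype(float)
        assert set(select_hvgs(X, n_top=8)) == set(range(8))

    def test_dominant_variance_gene_wins(self, rng):
        X = rng.poisson(2.0, size=(200, 3)).astype(float)
        # gene B: same mean, an order of magnitude more variance
        X[:, 1] = 20.0 * (rng.random(200) < 0.1)
        assert select_hvgs(X, n_top=1)[0] == 1

    def test_inflated_dispersion_genes_recovered(self, rng):
        n, m = 300, 20
        X = rng.poisson(5.0, size=(n, m)).astype(float)
        hot = [2, 5, 9, 13, 17]
        for g in hot:  # heavy-tailed counts inflate dispersion at similar mean
            X[:, g] = rng.negative_binomial(0.1, 0.1 / (0.1 + 5.0), size=n)
        picked = select_hvgs(X, n_top=5)
        assert set(picked) == set(_hvg_oracle(X, 5))
        assert set(picked) == set(hot)

    def test_matches_loop_oracle_on_random_counts(self, rng):
        X = rng.poisson(rng.uniform(0.5, 8, size=30), size=(60, 30)).astype(float)
        assert list(select_hvgs(X, n_top=10)) == list(_hvg_oracle(X, 10))

    def test_n_top_too_large_suggests_all_genes(self, rng):
        X = rng.poisson(2.0, size=(10, 5)).astype(float)
        with pytest.raises(ValueError, match="n_top=5"):
            select_hvgs(X, n_top=6)

    def test_broadly_agrees_with_scanpy(self, rng):
        """Cross-check the dispersion ranking against the scanpy routine."""
        import anndata as ad
        import scanpy as sc

        X = rng.poisson(2.0, size=(300, 40)).astype(float)
        hot = list(range(0, 40, 4))
        for g in hot:
            X[:, g] = rng.negative_binomial(0.15, 0.15 / (0.15 + 3.0), size=300)
        adata = ad.AnnData(X=X.copy())
        sc.pp.normalize_total(adata, target_sum=1e4)
        sc.pp.log1p(adata)
        sc.pp.highly_variable_genes(adata, n_top_genes=10, flavor="seurat")
        ours = set(select_hvgs(X, n_top=10))
        theirs = set(np.flatnonzero(adata.var["highly_variable"].to_numpy()))
        assert len(ours & theirs) >= 8


class TestExtractPatches:
    def test_center_block(self, rng):
        img = rng.integers(0, 255, size=(64, 64, 3)).astype(np.uint8)
        p = extract_patches(img, np.array([[32.0, 32.0]]), size=16)
        # center pixel pair (31,32)×(31,32) brackets the coordinate
        np.testing.assert_array_equal(p[0], img[25:41, 25:41])

    def test_corner_uses_reflection(self, rng):
        img = rng.integers(0, 255, size=(32, 32, 3)).astype(np.uint8)
        p = extract_patches(img, np.array([[0.0, 0.0]]), size=16)
        expected = np.pad(img, ((16, 16), (16, 16), (0, 0)), mode="reflect")[9:25, 9:25]
        np.testing.assert_array_equal(p[0], expected)

    def test_constant_image_gives_constant_patches(self):
        img = np.full((40, 40, 3), 77, dtype=np.uint8)
        S = np.array([[5.0, 5.0], [20.0, 33.0]])
        p = extract_patches(img, S, size=16)
        assert p.shape == (2, 16, 16, 3)
        assert (p == 77).all()

    def test_shape_invariant(self, rng):
        img = rng.integers(0, 255, size=(50, 70, 3)).astype(np.uint8)
        S = np.column_stack([rng.uniform(0, 69, 25), rng.uniform(0, 49, 25)])
        for size in (4, 16):
            p = extract_patches(img, S, size=size)
            assert p.shape == (25, size, size, 3)

    def test_out_of_bounds_lists_spot_ids(self):
        img = np.zeros((10, 10, 3), dtype=np.uint8)
        with pytest.raises(ValueError, match="bad_spot"):
            extract_patches(img, np.array([[5.0, 20.0]]), size=4,
                            spot_ids=["bad_spot"])


class TestInvariants:
    def test_spot_id_uniqueness_enforced(self):
        with pytest.raises(ValueError, match="unique"):
            SpatialDataset(X=np.zeros((2, 1)), S=np.zeros((2, 2)),
                           gene_names=["g"], spot_ids=["a", "a"])

    def test_coordinate_row_mismatch_rejected(self):
        with pytest.raises(ValueError, match="coordinate"):
            SpatialDataset(X=np.zeros((3, 1)), S=np.zeros((2, 2)),
                           gene_names=["g"], spot_ids=["a", "b", "c"])
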