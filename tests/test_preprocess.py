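"""Expression-matrix I/O, zero filtering, median-of-ratios size factors
and replicate averaging."""

import numpy as np
import pandas as pd
import pytest

from rhythmpencil import SamplingGrid
from rhythmpencil.preprocess import (
    ExpressionMatrix,
    average_replicates,
    filter_zero_genes,
    normalize,
    read_expression_matrix,
    size_factors,
    write_expression_matrix,
)
from rhythmpencil.synthetic import CohortSpec, generate_cohort


def _matrix(values, grid, n_rep=1, gene_ids=None):
    values = np.asarray(values, dtype=float)
    cols = [f"{ct}_r{k + 1}" for ct in grid.ct_labels() for k in range(n_rep)]
    ids = gene_ids or [f"g{i}" for i in range(values.shape[0])]
    return ExpressionMatrix(pd.DataFrame(values, index=ids, columns=cols), grid)


@pytest.fixture
def grid4():
    return SamplingGrid(0.0, 2.0, 4)


class TestReadWrite:
    def test_well_formed_round_trip(self, grid24, tmp_path):
        spec = CohortSpec(n_genes=20, seed=3, grid=grid24)
        m, _ = generate_cohort(spec)
        path = tmp_path / "m.tsv"
        write_expression_matrix(m, path)
        back = read_expression_matrix(path, grid24)
        pd.testing.assert_frame_equal(back.data, m.data)

    def test_shape_and_labels(self, grid4, tmp_path):
        path = tmp_path / "m.tsv"
        path.write_text(
            "gene_id\tCT00_r1\tCT02_r1\tCT04_r1\tCT06_r1\n"
            "a\t1\t2\t3\t4\nb\t5\t6\t7\t8\n"
        )
        m = read_expression_matrix(path, grid4)
        assert m.data.shape == (2, 4)
        assert m.n_replicates == 1

    def test_off_grid_label_rejected(self, grid4, tmp_path):
        path = tmp_path / "m.tsv"
        path.write_text(
            "gene_id\tCT00_r1\tCT02_r1\tCT04_r1\tCT07_r1\n" "a\t1\t2\t3\t4\n"
        )
        with pytest.raises(ValueError, match="CT7"):
            read_expression_matrix(path, grid4)

    def test_negative_value_rejected(self, grid4, tmp_path):
        path = tmp_path / "m.tsv"
        path.write_text(
            "gene_id\tCT00_r1\tCT02_r1\tCT04_r1\tCT06_r1\n" "a\t1\t-2\t3\t4\n"
        )
        with pytest.raises(ValueError, match="negative"):
            read_expression_matrix(path, grid4)

    def test_duplicate_gene_rejected(self, grid4, tmp_path):
        path = tmp_path / "m.tsv"
        path.write_text(
            "gene_id\tCT00_r1\tCT02_r1\tCT04_r1\tCT06_r1\n"
            "a\t1\t2\t3\t4\na\t1\t2\t3\t4\n"
        )
        with pytest.raises(ValueError, match="duplicate"):
            read_expression_matrix(path, grid4)

    def test_ragged_row_rejected(self, grid4, tmp_path):
        path = tmp_path / "m.tsv"
        path.write_text(
            "gene_id\tCT00_r1\tCT02_r1\tCT04_r1\tCT06_r1\n" "a\t1\t2\t3\n"
        )
        with pytest.raises(ValueError):
            read_expression_matrix(path, grid4)


class TestZeroFilter:
    def test_single_zero_removes_gene(self, grid24):
        vals = np.ones((3, 48))
        vals[1, 11] = 0.0  # one zero at one replicate of one timepoint
        m = _matrix(vals, grid24, n_rep=2)
        out = filter_zero_genes(m)
        assert out.gene_ids == ["g0", "g2"]

    def test_all_positive_unchanged(self, grid4):
        m = _matrix(np.ones((5, 4)) * 3.3, grid4)
        out = filter_zero_genes(m)
        pd.testing.assert_frame_equal(out.data, m.data)

    def test_idempotent(self, grid4, rng):
        vals = rng.uniform(0, 5, (30, 4)) * rng.integers(0, 2, (30, 4))
        m = _matrix(vals, grid4)
        once = filter_zero_genes(m)
        twice = filter_zero_genes(once)
        pd.testing.assert_frame_equal(once.data, twice.data)

    def test_matches_brute_force_scan(self, grid4, rng):
        vals = rng.uniform(0, 5, (50, 4)) * (rng.random((50, 4)) > 0.2)
        m = _matrix(vals, grid4)
        kept = set(filter_zero_genes(m).gene_ids)
        expected = {
            f"g{i}" for i in range(50) if all(vals[i, j] > 0 for j in range(4))
        }
        assert kept == expected


class TestSizeFactors:
    def test_identical_samples_give_unit_factors(self, grid4):
        col = np.array([1.0, 10.0, 100.0, 7.0, 3.0])
        m = _matrix(np.tile(col[:, None], (1, 4)), grid4)
        assert np.allclose(size_factors(m).to_numpy(), 1.0, atol=1e-12)

    def test_doubled_sample_ratio(self):
        grid = SamplingGrid(0, 2, 4)
        base = np.array(
            [[2.0, 4.0, 2.0, 4.0], [6.0, 12.0, 6.0, 12.0], [1.0, 2.0, 1.0, 2.0]]
        )
        m = _matrix(base, grid)
        f = size_factors(m).to_numpy()
        assert f[1] / f[0] == pytest.approx(2.0, rel=1e-12)
        assert f[3] / f[2] == pytest.approx(2.0, rel=1e-12)

    def test_hand_computed_matrix(self, grid4):
        vals = np.array(
            [
                [4.0, 8.0, 2.0, 4.0],
                [10.0, 10.0, 5.0, 20.0],
                [3.0, 6.0, 3.0, 12.0],
                [8.0, 4.0, 4.0, 8.0],
                [5.0, 5.0, 5.0, 5.0],
            ]
        )
        m = _matrix(vals, grid4)
        # oracle: the definition applied by hand with numpy primitives,
        # rescaled to geometric mean 1
        geo = np.exp(np.mean(np.log(vals), axis=1))
        expected = np.median(vals / geo[:, None], axis=0)
        expected /= np.exp(np.mean(np.log(expected)))
        assert np.allclose(size_factors(m).to_numpy(), expected, atol=1e-12)

    def test_deseq2_cross_check(self, grid4):
        """Agrees with pydeseq2's median-of-ratios estimator up to the
        geometric-mean-1 rescaling convention."""
        prep = pytest.importorskip("pydeseq2.preprocessing")
        vals = np.array(
            [
                [40.0, 80.0, 20.0, 40.0],
                [100.0, 100.0, 50.0, 200.0],
                [30.0, 60.0, 30.0, 120.0],
                [80.0, 40.0, 40.0, 80.0],
                [50.0, 50.0, 50.0, 50.0],
                [7.0, 14.0, 21.0, 28.0],
            ]
        )
        m = _matrix(vals, grid4)
        _, ref = prep.deseq2_norm(vals.T)  # samples x genes
        ref = np.asarray(ref, dtype=float)
        ref /= np.exp(np.mean(np.log(ref)))
        assert np.allclose(size_factors(m).to_numpy(), ref, rtol=1e-10)

    def test_requires_all_positive_row(self, grid4):
        vals = np.eye(4) * 5.0
        with pytest.raises(ValueError, match="filter"):
            size_factors(_matrix(vals, grid4))


class TestNormalizeAndAverage:
    def test_unit_factors_identity(self, grid4, rng):
        m = _matrix(rng.uniform(1, 10, (6, 4)), grid4)
        f = pd.Series(1.0, index=m.data.columns)
        pd.testing.assert_frame_equal(normalize(m, f).data, m.data)

    def test_self_normalisation_idempotent(self, grid24, rng):
        m = _matrix(rng.uniform(1, 100, (40, 48)), grid24, n_rep=2)
        normed = normalize(m, size_factors(m))
        assert np.allclose(size_factors(normed).to_numpy(), 1.0, atol=1e-12)

    def test_nonpositive_factor_rejected(self, grid4):
        m = _matrix(np.ones((2, 4)), grid4)
        f = pd.Series([1.0, 0.0, 1.0, 1.0], index=m.data.columns)
        with pytest.raises(ValueError, match="non-positive"):
            normalize(m, f)

    def test_replicate_mean(self, grid4):
        vals = np.array([[10.0, 14.0, 1.0, 3.0, 5.0, 7.0, 2.0, 2.0]])
        m = _matrix(vals, grid4, n_rep=2)
        avg = average_replicates(m)
        assert avg.iloc[0].tolist() == [12.0, 2.0, 6.0, 2.0]

    def test_averaging_matches_direct_recomputation(self, grid24, rng):
        spec = CohortSpec(n_genes=30, seed=9, grid=grid24)
        m, _ = generate_cohort(spec)
        avg = average_replicates(m)
        for g in m.gene_ids:
            row = m.data.loc[g].to_numpy().reshape(24, 2).mean(axis=1)
            assert np.allclose(avg.loc[g].to_numpy(), row)

    def test_commutes_with_gene_subsetting(self, grid24, rng):
        m = _matrix(rng.uniform(1, 10, (10, 48)), grid24, n_rep=2)
        sub_then_avg = average_replicates(
            ExpressionMatrix(m.data.iloc[2:5], grid24)
        )
        avg_then_sub = average_replicates(m).iloc[2:5]
        pd.testing.assert_frame_equal(sub_then_avg, avg_then_sub)
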