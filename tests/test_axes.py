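import numpy as np
import pandas as pd
import pytest

from npcharge.axes import (
    AGGREGATE_HYDROPHOBICITY,
    aggregate_hydrophobicity,
    cluster_rows,
    export_heatmap,
    hydrophobicity_pca,
    property_space,
    signed_squared_correlation,
)
from npcharge.io import ProteinRecord
from npcharge.profiler import NET_CHARGE, PropertyMatrix, build_property_matrix
from npcharge.scales import ResidueScale, ScaleRegistry


def fake_registry(names):
    """Registry whose hydrophobicity scale *names* match synthetic columns."""
    scales = []
    for i, name in enumerate(names):
        vals = {r: float(j + i) for j, r in enumerate("ACDEFGHIKLMNPQRSTVWY")}
        scales.append(ResidueScale(name, "hydrophobicity", vals))
    return ScaleRegistry(scales)


def raw_matrix(data, columns):
    df = pd.DataFrame(data, columns=columns)
    df.index = [f"r{i}" for i in range(len(df))]
    labels = pd.Series("unknown", index=df.index, name="label")
    return PropertyMatrix(values=df, labels=labels, state="raw")


class TestHydrophobicityPCA:
    def test_identical_columns_put_all_variance_on_pc1(self, rng):
        x = rng.normal(size=8)
        matrix = raw_matrix(
            np.column_stack([x, 2 * x + 1, -x, 0.5 * x]), ["s1", "s2", "s3", "s4"]
        ).zscore()
        result = hydrophobicity_pca(matrix, fake_registry(["s1", "s2", "s3", "s4"]),
                                    reference_scale="s1")
        assert result.pc1_variance_fraction == pytest.approx(1.0, abs=1e-9)

    def test_orthogonal_equal_variance_columns_split_evenly(self):
        matrix = raw_matrix(
            np.array([[1.0, 1.0], [1.0, -1.0], [-1.0, 1.0], [-1.0, -1.0]]),
            ["s1", "s2"],
        ).zscore()
        result = hydrophobicity_pca(matrix, fake_registry(["s1", "s2"]),
                                    reference_scale="s1")
        assert result.pc1_variance_fraction == pytest.approx(0.5, abs=1e-9)

    def test_variance_fractions_sum_to_one_and_decrease(self, rng):
        matrix = raw_matrix(rng.normal(size=(20, 5)), [f"s{i}" for i in range(5)]).zscore()
        result = hydrophobicity_pca(matrix, fake_registry([f"s{i}" for i in range(5)]),
                                    reference_scale="s0")
        fr = result.variance_fractions
        assert fr.sum() == pytest.approx(1.0, abs=1e-9)
        assert all(a >= b - 1e-12 for a, b in zip(fr, fr[1:]))

    def test_loadings_are_orthonormal(self, fitted):
        loadings = fitted.pca.loadings
        gram = loadings @ loadings.T
        assert np.allclose(gram, np.eye(len(loadings)), atol=1e-9)

    def test_projection_reconstructs_zscored_matrix(self, rng):
        cols = [f"s{i}" for i in range(6)]
        matrix = raw_matrix(rng.normal(size=(15, 6)), cols).zscore()
        result = hydrophobicity_pca(matrix, fake_registry(cols), reference_scale="s0")
        z = matrix.values.to_numpy()
        reconstructed = (z @ result.loadings.T) @ result.loadings
        assert np.allclose(reconstructed, z, atol=1e-9)

    def test_pc1_fraction_invariant_under_row_and_column_permutation(self, rng):
        cols = [f"s{i}" for i in range(4)]
        data = rng.normal(size=(12, 4)) @ rng.normal(size=(4, 4))
        base = hydrophobicity_pca(raw_matrix(data, cols).zscore(),
                                  fake_registry(cols), reference_scale="s0")
        rows = rng.permutation(12)
        perm_cols = ["s2", "s0", "s3", "s1"]
        permuted = raw_matrix(data[rows][:, [2, 0, 3, 1]], perm_cols).zscore()
        other = hydrophobicity_pca(permuted, fake_registry(cols), reference_scale="s0")
        assert other.pc1_variance_fraction == pytest.approx(
            base.pc1_variance_fraction, abs=1e-9
        )

    def test_requires_zscored_matrix(self, rng):
        cols = ["s0", "s1", "s2"]
        matrix = raw_matrix(rng.normal(size=(5, 3)), cols)
        with pytest.raises(ValueError, match="zscored"):
            hydrophobicity_pca(matrix, fake_registry(cols), reference_scale="s0")

    def test_training_rows_reproduce_their_scores(self, fitted):
        raw = fitted.raw_matrix
        pca = fitted.pca
        z = fitted.zscored_matrix.restrict(list(pca.columns)).values.to_numpy()
        expected = z @ pca.loadings[0]
        for i, sid in enumerate(raw.ids[:10]):
            score = aggregate_hydrophobicity(dict(raw.values.loc[sid]), pca)
            assert score == pytest.approx(expected[i], abs=1e-9)

    def test_training_scores_have_zero_mean(self, fitted):
        scores = fitted.coordinates[AGGREGATE_HYDROPHOBICITY]
        assert scores.mean() == pytest.approx(0.0, abs=1e-9)

    def test_missing_column_named(self, fitted):
        with pytest.raises(ValueError, match="kyte_doolittle"):
            aggregate_hydrophobicity({"not_a_scale": 1.0}, fitted.pca)


class TestSignConvention:
    def test_poly_isoleucine_scores_above_poly_aspartate(self, registry, make_sequence):
        records = [ProteinRecord(f"r{i}", make_sequence(50)) for i in range(6)]
        records += [ProteinRecord("polyI", "I" * 50), ProteinRecord("polyD", "D" * 50)]
        table, _ = property_space(records, registry)
        assert (
            table.loc["polyI", AGGREGATE_HYDROPHOBICITY]
            > table.loc["polyD", AGGREGATE_HYDROPHOBICITY]
        )


class TestSignedSquaredCorrelation:
    def test_perfect_anticorrelation(self):
        x = np.arange(10.0)
        assert signed_squared_correlation(x, -x) == pytest.approx(-1.0)

    def test_perfect_correlation(self):
        x = np.arange(10.0)
        assert signed_squared_correlation(x, 3 * x + 2) == pytest.approx(1.0)

    def test_independent_columns_near_zero(self):
        rng = np.random.default_rng(123)
        x, y = rng.standard_normal(1000), rng.standard_normal(1000)
        assert abs(signed_squared_correlation(x, y)) < 0.05

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            signed_squared_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


def zscored_like(data, columns):
    df = pd.DataFrame(data, columns=columns)
    df.index = [f"r{i}" for i in range(len(df))]
    labels = pd.Series("unknown", index=df.index, name="label")
    return PropertyMatrix(values=df, labels=labels, state="zscored")


class TestClusterRows:
    def test_identical_rows_merge_at_height_zero(self):
        data = np.array([[1.0, 2.0], [1.0, 2.0], [5.0, 5.0]])
        result = cluster_rows(zscored_like(data, ["a", "b"]))
        assert result.linkage_matrix[0, 2] == pytest.approx(0.0)

    def test_top_split_separates_constructed_groups(self, rng):
        lo = rng.normal(-5.0, 0.2, size=(4, 5))
        hi = rng.normal(5.0, 0.2, size=(4, 5))
        matrix = zscored_like(np.vstack([lo, hi]), [f"c{i}" for i in range(5)])
        result = cluster_rows(matrix)
        left, right = result.top_split(matrix.ids)
        groups = {frozenset(left), frozenset(right)}
        assert groups == {
            frozenset({"r0", "r1", "r2", "r3"}),
            frozenset({"r4", "r5", "r6", "r7"}),
        }

    def test_leaf_order_is_permutation_of_ids(self, fitted):
        result = fitted.cluster()
        assert sorted(result.leaf_order) == sorted(fitted.zscored_matrix.ids)

    def test_same_merge_heights_under_row_permutation(self, rng):
        data = rng.normal(size=(10, 4))
        cols = [f"c{i}" for i in range(4)]
        base = cluster_rows(zscored_like(data, cols))
        perm = rng.permutation(10)
        other = cluster_rows(zscored_like(data[perm], cols))
        assert np.allclose(
            np.sort(base.linkage_matrix[:, 2]), np.sort(other.linkage_matrix[:, 2])
        )

    def test_needs_two_rows(self):
        with pytest.raises(ValueError, match="2 rows"):
            cluster_rows(zscored_like(np.ones((1, 3)), ["a", "b", "c"]))


class TestExportHeatmap:
    def test_table_is_input_reordered_and_scale_clipped(self, rng, tmp_path):
        data = rng.normal(size=(6, 4))
        data[0, 0] = 4.2  # beyond the +-3 SD scale
        matrix = zscored_like(data, [f"c{i}" for i in range(4)])
        export = export_heatmap(
            matrix,
            image_path=tmp_path / "h.png",
            table_path=tmp_path / "h.tsv",
        )
        assert export.vmin == -3.0 and export.vmax == 3.0  # default clip
        assert set(export.table.index) == set(matrix.ids)
        for rid in matrix.ids:
            assert np.allclose(export.table.loc[rid], matrix.values.loc[rid])
        assert (tmp_path / "h.png").exists() and (tmp_path / "h.tsv").exists()

    def test_custom_clip_propagates(self, rng):
        matrix = zscored_like(rng.normal(size=(4, 3)), ["a", "b", "c"])
        export = export_heatmap(matrix, clip=2.5)
        assert (export.vmin, export.vmax) == (-2.5, 2.5)


class TestPropertySpaceTable:
    def test_one_row_per_subject_with_two_coordinates(self, fitted):
        coords = fitted.coordinates
        assert len(coords) == len(fitted.model.subjects)
        assert {NET_CHARGE, AGGREGATE_HYDROPHOBICITY} <= set(coords.columns)

    def test_cargo_like_cohort_is_positively_charged(self, fitted):
        cargo = fitted.coordinates.query("label == 'cargo_like'")
        assert cargo[NET_CHARGE].mean() > 0

    def test_receptor_like_cohort_is_negatively_charged(self, fitted):
        rec = fitted.coordinates.query("label == 'receptor_like'")
        assert rec[NET_CHARGE].mean() < 0
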