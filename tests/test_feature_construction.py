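import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from netsmooth import feature_construction as fc
from netsmooth.datatypes import (
    BINARY,
    CONTINUOUS,
    FeatureTable,
    GeneMatrix,
    PriorVector,
)
from netsmooth.errors import ValidationError


def continuous_matrix(values, samples=None, genes=None) -> GeneMatrix:
    values = np.asarray(values, dtype=float)
    samples = samples or [f"S{i}" for i in range(values.shape[0])]
    genes = genes or [f"G{j}" for j in range(values.shape[1])]
    return GeneMatrix(pd.DataFrame(values, index=samples, columns=genes), dtype_flag=CONTINUOUS)


class TestMinCombine:
    def test_large_target_returns_profile(self):
        profile = continuous_matrix([[0.1, 0.2], [0.3, 0.4]])
        target = PriorVector(("G0", "G1"), np.array([9.0, 9.0]))
        assert (fc.min_combine(profile, target).values == profile.values).all()

    def test_zero_target_returns_zero(self):
        profile = continuous_matrix([[0.1, 0.2]])
        target = PriorVector(("G0", "G1"), np.zeros(2))
        assert not fc.min_combine(profile, target).values.any()

    def test_mismatched_gene_order_is_error(self):
        profile = continuous_matrix([[0.1, 0.2]])
        target = PriorVector(("G1", "G0"), np.zeros(2))
        with pytest.raises(ValidationError, match="order"):
            fc.min_combine(profile, target)

    @given(seed=st.integers(0, 500))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_bounded_above_by_both_inputs(self, seed):
        rng = np.random.default_rng(seed)
        profile = continuous_matrix(rng.random((4, 6)))
        target = PriorVector(tuple(profile.gene_symbols), rng.random(6))
        out = fc.min_combine(profile, target).values
        assert (out <= profile.values + 1e-15).all()
        assert (out <= target.values[np.newaxis, :] + 1e-15).all()
        # commutative in the vector sense: min against the two inputs in
        # either role gives the same matrix
        swapped = np.minimum(np.broadcast_to(target.values, profile.values.shape), profile.values)
        assert (out == swapped).all()


class TestRowSummaries:
    def test_constant_row(self):
        table = fc.row_summaries(continuous_matrix([[2.5, 2.5, 2.5]]), prefix="x_")
        assert table.data.loc["S0", "x_mean"] == 2.5
        assert table.data.loc["S0", "x_sd"] == 0.0

    def test_population_sd(self):
        table = fc.row_summaries(continuous_matrix([[0.0, 1.0]]))
        assert table.data.iloc[0].tolist() == [0.5, 0.5]

    def test_invariant_to_column_permutation(self):
        rng = np.random.default_rng(1)
        values = rng.random((3, 8))
        base = fc.row_summaries(continuous_matrix(values))
        permuted = fc.row_summaries(continuous_matrix(values[:, rng.permutation(8)]))
        assert np.allclose(base.data.values, permuted.data.values)


class TestPcaFeatures:
    def test_rank_one_matrix_single_dominant_component(self):
        rng = np.random.default_rng(2)
        u = rng.random((6, 1))
        v = rng.random((1, 8))
        model, _ = fc.pca_features(continuous_matrix(u @ v), k=3)
        assert model.explained_variance_ratio[0] == pytest.approx(1.0, abs=1e-9)
        assert model.explained_variance_ratio[1:].max() < 1e-9

    def test_duplicated_sample_rows_give_duplicated_scores(self):
        rng = np.random.default_rng(3)
        values = rng.random((4, 5))
        doubled = np.vstack([values, values[:1]])
        _, table = fc.pca_features(continuous_matrix(doubled), k=2)
        assert np.allclose(table.data.iloc[0].values, table.data.iloc[4].values)

    def test_orthonormal_components_and_decreasing_variance(self):
        rng = np.random.default_rng(4)
        model, _ = fc.pca_features(continuous_matrix(rng.random((20, 12))), k=6)
        gram = model.components @ model.components.T
        assert np.allclose(gram, np.eye(6), atol=1e-8)
        assert (np.diff(model.explained_variance_ratio) <= 1e-12).all()

    def test_scores_match_svd_oracle_projection(self):
        rng = np.random.default_rng(5)
        values = rng.random((10, 7))
        k = 4
        model, table = fc.pca_features(continuous_matrix(values), k=k)
        centered = values - values.mean(axis=0)
        # independent oracle: truncated SVD reconstruction error
        u, s, vt = np.linalg.svd(centered, full_matrices=False)
        oracle_recon = (u[:, :k] * s[:k]) @ vt[:k]
        recon = table.data.values @ model.components
        assert np.allclose(recon, oracle_recon, atol=1e-8)
        # and the projection identity: scores = centered @ components^T
        assert np.allclose(table.data.values, centered @ model.components.T, atol=1e-8)

    def test_deterministic_given_sign_convention(self):
        rng = np.random.default_rng(6)
        values = rng.random((9, 6))
        _, a = fc.pca_features(continuous_matrix(values), k=3)
        _, b = fc.pca_features(continuous_matrix(values.copy()), k=3)
        assert (a.data.values == b.data.values).all()

    def test_k_too_large_is_error(self):
        with pytest.raises(ValidationError, match="exceeds"):
            fc.pca_features(continuous_matrix(np.zeros((3, 5))), k=4)


class TestLincsFeatures:
    def test_identical_vectors_correlate_perfectly(self):
        row = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("ABCD"))
        corr, dot = fc.lincs_features(row, row)
        assert corr == pytest.approx(1.0)
        assert dot == pytest.approx(float((row**2).sum()))

    def test_negated_signature(self):
        row = pd.Series([1.0, -2.0, 3.0], index=list("ABC"))
        corr, dot = fc.lincs_features(row, -row)
        assert corr == pytest.approx(-1.0)
        assert dot == pytest.approx(-float((row**2).sum()))

    def test_subsetting_matches_manual_intersection(self):
        rng = np.random.default_rng(7)
        genes_a = [f"G{i}" for i in range(20)]
        genes_b = [f"G{i}" for i in range(10, 30)]
        row = pd.Series(rng.normal(size=20), index=genes_a)
        sig = pd.Series(rng.normal(size=20), index=genes_b)
        shuffled = sig.sample(frac=1.0, random_state=1)
        corr, dot = fc.lincs_features(row, shuffled)
        shared = [g for g in genes_a if g in genes_b]
        x = row[shared].values
        y = sig[shared].values
        assert dot == pytest.approx(float(x @ y))
        assert corr == pytest.approx(float(np.corrcoef(x, y)[0, 1]))

    def test_too_few_shared_genes_is_error(self):
        row = pd.Series([1.0, 2.0], index=["A", "B"])
        sig = pd.Series([1.0, 2.0], index=["B", "C"])
        with pytest.raises(ValidationError, match="shared genes"):
            fc.lincs_features(row, sig)

    def test_zero_variance_vector_warns_and_returns_zero_corr(self):
        row = pd.Series([2.0, 2.0, 2.0], index=list("ABC"))
        sig = pd.Series([1.0, 2.0, 3.0], index=list("ABC"))
        with pytest.warns(UserWarning, match="zero-variance"):
            corr, dot = fc.lincs_features(row, sig)
        assert corr == 0.0
        assert dot == pytest.approx(12.0)


class TestAssembleFeatures:
    @staticmethod
    def _inputs(n_samples=12, n_genes=15, n_sets=5, seed=0):
        rng = np.random.default_rng(seed)
        genes = [f"G{j}" for j in range(n_genes)]
        samples = [f"S{i}" for i in range(n_samples)]
        profiles = {
            name: GeneMatrix(
                pd.DataFrame(rng.random((n_samples, n_genes)), index=samples, columns=genes),
                dtype_flag=CONTINUOUS,
            )
            for name in ("mut", "de")
        }
        targets = {
            f"set{k}": PriorVector(tuple(genes), rng.random(n_genes)) for k in range(n_sets)
        }
        expression = pd.DataFrame(rng.normal(size=(n_samples, n_genes)), index=samples, columns=genes)
        lincs = {
            drug: (expression, pd.Series(rng.normal(size=n_genes), index=genes))
            for drug in ("anastrozole", "taxol")
        }
        clinical = FeatureTable(
            pd.DataFrame(rng.integers(0, 2, size=(n_samples, 3)).astype(float),
                         index=samples, columns=["c1", "c2", "c3"])
        )
        return profiles, targets, lincs, clinical

    def test_feature_count_matches_closed_form(self):
        profiles, targets, lincs, clinical = self._inputs()
        table = fc.assemble_features(profiles, targets, lincs_pairs=lincs, clinical=clinical, n_pca=10)
        # 2 profiles x 5 sets x (2 summaries + 10 PCA) + 2 lincs x 2 + 3 clinical
        assert table.shape[1] == 2 * 5 * 12 + 2 * 2 + 3

    def test_feature_names_unique_and_provenance_tagged(self):
        profiles, targets, lincs, clinical = self._inputs()
        table = fc.assemble_features(profiles, targets, lincs_pairs=lincs, clinical=clinical, n_pca=10)
        assert len(set(table.feature_names)) == table.shape[1]
        assert set(table.provenance) == set(table.feature_names)
        assert all(np.isfinite(table.data.values).all() for _ in [0])

    def test_sample_missing_expression_gets_zero_lincs_features(self):
        profiles, targets, lincs, clinical = self._inputs()
        drug, (expression, signature) = next(iter(lincs.items()))
        lincs = {drug: (expression.drop(index="S0"), signature)}
        table = fc.assemble_features(profiles, targets, lincs_pairs=lincs, clinical=clinical, n_pca=10)
        assert table.data.loc["S0", f"lincs_{drug}__corr"] == 0.0
        assert table.data.loc["S0", f"lincs_{drug}__dot"] == 0.0

    def test_empty_source_set_is_error(self):
        with pytest.raises(ValidationError, match="no feature sources"):
            fc.assemble_features({}, {})


class TestNaiveFeatures:
    @staticmethod
    def _binary(n, g, seed):
        rng = np.random.default_rng(seed)
        return GeneMatrix(
            pd.DataFrame(
                (rng.random((n, g)) < 0.3).astype(float),
                index=[f"S{i}" for i in range(n)],
                columns=[f"G{j}" for j in range(g)],
            ),
            dtype_flag=BINARY,
        )

    def test_raw_width_is_sum_of_blocks(self):
        mutations = self._binary(8, 5, 0)
        diff = self._binary(8, 7, 1)
        clinical = FeatureTable(
            pd.DataFrame(np.ones((8, 2)), index=mutations.sample_ids, columns=["a", "b"])
        )
        table = fc.naive_features(mutations, diff, clinical=clinical, pca_k=None)
        assert table.shape == (8, 5 + 7 + 2)

    def test_pca_k_gives_k_columns(self):
        table = fc.naive_features(self._binary(12, 20, 2), self._binary(12, 20, 3), pca_k=8)
        assert table.shape == (12, 8)

    def test_pca_matches_oracle_on_concatenation(self):
        mutations = self._binary(12, 20, 4)
        diff = self._binary(12, 20, 5)
        table = fc.naive_features(mutations, diff, pca_k=8)
        stacked = np.hstack([mutations.values, diff.values])
        centered = stacked - stacked.mean(axis=0)
        u, s, vt = np.linalg.svd(centered, full_matrices=False)
        oracle_scores = u[:, :8] * s[:8]
        # compare up to the per-component sign convention
        for j in range(8):
            col = table.data.values[:, j]
            assert np.allclose(col, oracle_scores[:, j], atol=1e-8) or np.allclose(
                col, -oracle_scores[:, j], atol=1e-8
            )

    def test_invalid_pca_k_is_error(self):
        with pytest.raises(ValidationError, match="pca_k"):
            fc.naive_features(self._binary(5, 4, 6), self._binary(5, 4, 7), pca_k=9)


class TestFeatureTableIo:
    def test_round_trip_with_provenance(self, tmp_path):
        rng = np.random.default_rng(9)
        table = FeatureTable(
            pd.DataFrame(rng.random((4, 3)), index=list("wxyz"), columns=["f1", "f2", "f3"]),
            provenance={"f1": "a", "f2": "b", "f3": "c"},
        )
        path = tmp_path / "features.csv"
        fc.write_feature_table(table, path)
        again = fc.read_feature_table(path)
        assert again.feature_names == table.feature_names
        assert again.provenance == table.provenance
        assert np.allclose(again.data.values, table.data.values)
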