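"""Construction of the predictive feature table.

The core construction takes a network-smoothed per-sample profile matrix
(smoothed mutations M_P or smoothed differential expression D_P) together
with a smoothed target vector T (drug targets, estrogen-receptor proteins,
or estrogen-receptor target genes) and forms the element-wise minimum
matrix  A_{P,T}[i,j] = min(A_P[i,j], T[j]),  which scores gene j's joint
network proximity to both the sample's alterations and the target set.
Each minimum matrix is then collapsed into per-sample features: row mean,
row standard deviation, and the sample scores of its top-k principal
components. Expression-signature similarity features (correlation and dot
product against per-drug perturbation signatures) and one-hot clinical
indicators are stacked alongside.

A deliberately naive baseline (raw binary mutation/expression columns,
optionally PCA-reduced) is provided for comparison.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .datatypes import (
    BINARY,
    CONTINUOUS,
    FeatureTable,
    GeneMatrix,
    PcaModel,
    PriorVector,
)
from .errors import ValidationError

NAIVE_PCA_CHOICES = (None, 8, 32, 128, 512)


def min_combine(profile: GeneMatrix, target: PriorVector) -> GeneMatrix:
    """Element-wise minimum of a smoothed profile matrix and a smoothed
    target vector; requires identical gene order (no silent alignment)."""
    if tuple(profile.gene_symbols) != tuple(target.nodes):
        raise ValidationError("profile columns and target node order differ; align explicitly")
    combined = np.minimum(profile.values, target.values[np.newaxis, :])
    data = pd.DataFrame(combined, index=profile.data.index, columns=profile.data.columns)
    return GeneMatrix(data, dtype_flag=CONTINUOUS)


def row_summaries(matrix: GeneMatrix, prefix: str = "") -> FeatureTable:
    """Per-sample mean and population (ddof=0) standard deviation across genes."""
    values = matrix.values
    names = [f"{prefix}mean", f"{prefix}sd"]
    data = pd.DataFrame(
        {names[0]: values.mean(axis=1), names[1]: values.std(axis=1, ddof=0)},
        index=matrix.data.index,
    )
    return FeatureTable(data, provenance={n: f"row_summary:{prefix.rstrip('_')}" for n in names})


def pca_features(matrix: GeneMatrix, k: int = 10, prefix: str = "") -> tuple[PcaModel, FeatureTable]:
    """Mean-centered PCA of a sample x gene matrix; top-k sample scores
    become features, gene loadings are returned for importance inspection.

    Sign convention: each component is flipped so its largest-|loading| gene
    has a positive loading, making the decomposition deterministic.
    """
    n_samples, n_genes = matrix.shape
    if k > min(n_samples, n_genes):
        raise ValidationError(f"k={k} exceeds min(n_samples, n_genes)={min(n_samples, n_genes)}")
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(matrix.values)
    components = pca.components_.copy()
    for i in range(k):
        lead = np.argmax(np.abs(components[i]))
        if components[i, lead] < 0:
            components[i] *= -1.0
            scores[:, i] *= -1.0
    model = PcaModel(
        components=components,
        explained_variance_ratio=pca.explained_variance_ratio_.copy(),
        mean=pca.mean_.copy(),
        gene_symbols=matrix.gene_symbols,
    )
    names = [f"{prefix}pca{i + 1:02d}" for i in range(k)]
    data = pd.DataFrame(scores, index=matrix.data.index, columns=names)
    table = FeatureTable(data, provenance={n: f"pca:{prefix.rstrip('_')}" for n in names})
    return model, table


def lincs_features(expression_row: pd.Series, signature: pd.Series) -> tuple[float, float]:
    """Pearson correlation and raw dot product between a tumor's log-fold
    expression vector and a drug's perturbation signature, computed over the
    intersection of their gene universes (>= 3 shared genes required).

    Zero-variance input on either side makes the correlation undefined; it
    is reported as 0.0 with a warning. The dot product is always defined.
    """
    shared = expression_row.index.intersection(signature.index)
    if len(shared) < 3:
        raise ValidationError(f"only {len(shared)} shared genes; need at least 3")
    x = expression_row.loc[shared].to_numpy(dtype=float)
    y = signature.loc[shared].to_numpy(dtype=float)
    dot = float(x @ y)
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        warnings.warn("zero-variance vector; correlation undefined, reporting 0", stacklevel=2)
        corr = 0.0
    else:
        corr = float(np.corrcoef(x, y)[0, 1])
    return corr, dot


def _stack(tables: list[FeatureTable], index: pd.Index) -> FeatureTable:
    data = pd.concat([t.data.reindex(index) for t in tables], axis=1)
    provenance: dict[str, str] = {}
    for t in tables:
        provenance.update(t.provenance)
    return FeatureTable(data, provenance=provenance)


def assemble_features(
    profiles: dict[str, GeneMatrix],
    targets: dict[str, PriorVector],
    lincs_pairs: dict[str, tuple[pd.DataFrame, pd.Series]] | None = None,
    clinical: FeatureTable | None = None,
    n_pca: int = 10,
) -> FeatureTable:
    """Stack the full constructed feature set.

    For every (smoothed profile, smoothed target) pair the minimum matrix is
    summarized into row mean, row sd and top ``n_pca`` PCA scores. Each
    expression/signature pair adds a correlation and a dot-product feature
    per sample. Clinical indicator columns are appended unchanged. Feature
    names encode their construction, e.g.
    ``min_sm_mut_x_sm_targets_anastrozole__pca03``.
    """
    if not profiles and lincs_pairs is None and clinical is None:
        raise ValidationError("no feature sources given")
    index = None
    for profile in profiles.values():
        if index is None:
            index = profile.data.index
        elif not index.equals(profile.data.index):
            raise ValidationError("profile matrices have inconsistent sample universes")
    if index is None and clinical is not None:
        index = clinical.data.index
    if index is None and lincs_pairs:
        index = next(iter(lincs_pairs.values()))[0].index
    tables: list[FeatureTable] = []
    for profile_name, profile in profiles.items():
        for target_name, target in targets.items():
            prefix = f"min_sm_{profile_name}_x_sm_{target_name}__"
            combined = min_combine(profile, target)
            tables.append(row_summaries(combined, prefix=prefix))
            _, pca_table = pca_features(combined, k=n_pca, prefix=prefix)
            tables.append(pca_table)
    if lincs_pairs:
        for drug, (expression, signature) in lincs_pairs.items():
            corr = np.zeros(len(index))
            dot = np.zeros(len(index))
            for i, sample in enumerate(index):
                if sample in expression.index:
                    corr[i], dot[i] = lincs_features(expression.loc[sample], signature)
            names = [f"lincs_{drug}__corr", f"lincs_{drug}__dot"]
            data = pd.DataFrame({names[0]: corr, names[1]: dot}, index=index)
            tables.append(FeatureTable(data, provenance={n: f"lincs:{drug}" for n in names}))
    if clinical is not None:
        tables.append(
            FeatureTable(clinical.data.reindex(index, fill_value=0.0), provenance=dict(clinical.provenance))
        )
    if not tables:
        raise ValidationError("assembled feature set is empty")
    return _stack(tables, index)


def naive_features(
    mutations: GeneMatrix,
    diff_expression: GeneMatrix,
    clinical: FeatureTable | None = None,
    pca_k: int | None = None,
) -> FeatureTable:
    """Baseline feature set: raw binary mutation + differential-expression
    columns plus clinical indicators, optionally replaced by the top
    ``pca_k`` principal-component scores of the stacked matrix."""
    if mutations.dtype_flag != BINARY or diff_expression.dtype_flag != BINARY:
        raise ValidationError("naive_features expects binary M and D")
    if pca_k not in NAIVE_PCA_CHOICES:
        raise ValidationError(f"pca_k must be one of {NAIVE_PCA_CHOICES}")
    index = mutations.data.index
    if not index.equals(diff_expression.data.index):
        raise ValidationError("mutation and expression matrices have different samples")
    blocks = [
        mutations.data.add_prefix("mut_"),
        diff_expression.data.add_prefix("de_"),
    ]
    if clinical is not None:
        blocks.append(clinical.data.reindex(index, fill_value=0.0))
    stacked = pd.concat(blocks, axis=1)
    if pca_k is None:
        provenance = {c: "naive:raw" for c in stacked.columns}
        return FeatureTable(stacked, provenance=provenance)
    rank = min(stacked.shape)
    if pca_k > rank:
        raise ValidationError(f"pca_k={pca_k} exceeds matrix rank bound {rank}")
    stacked_matrix = GeneMatrix(stacked, dtype_flag=CONTINUOUS)
    _, table = pca_features(stacked_matrix, k=pca_k, prefix="naive__")
    table.provenance = {n: "naive:pca" for n in table.feature_names}
    return table


def write_feature_table(table: FeatureTable, path) -> None:
    """CSV with a leading comment block recording per-column provenance."""
    with open(path, "w") as fh:
        for name in table.feature_names:
            fh.write(f"# provenance\t{name}\t{table.provenance[name]}\n")
        table.data.to_csv(fh, index_label="sample")


def read_feature_table(path) -> FeatureTable:
    provenance: dict[str, str] = {}
    header_lines = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            header_lines += 1
            _, name, tag = line.rstrip("\n").split("\t")
            provenance[name] = tag
    data = pd.read_csv(path, skiprows=header_lines, index_col=0)
    return FeatureTable(data, provenance=provenance)
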