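"""End-to-end orchestration: smoothing -> features -> labels -> cross-validation.

Convenience layer over the individual modules. It smooths the mutation and
differential-expression matrices and every target gene set over the
network, assembles the constructed feature table, reconstructs non-response
labels from treatment records, and runs leave-one-out cross-validation.
The naive baseline (raw binary features) shares the same labels so the two
feature sets are directly comparable.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import feature_construction as fc
from . import labeling, prediction
from .datatypes import (
    ALL_AI,
    ClinicalTable,
    CvResult,
    FeatureTable,
    GeneMatrix,
    GeneSet,
    LabelVector,
    PriorVector,
    PropagationConfig,
    TreatmentRecord,
    WeightedNetwork,
)
from .errors import ValidationError
from .genomic_io import encode_clinical
from .network_propagation import build_prior, laplacian_normalize, propagate, smooth_matrix
from .synthetic_data import SimBundle, SimConfig, generate_bundle


def smooth_inputs(
    network: WeightedNetwork,
    mutations: GeneMatrix,
    diff_expression: GeneMatrix,
    gene_sets: list[GeneSet],
    cfg: PropagationConfig | None = None,
) -> tuple[dict[str, GeneMatrix], dict[str, PriorVector]]:
    """Smooth the profile matrices and every target gene set over the network.

    Returns ``profiles`` (smoothed mutation and differential-expression
    matrices, columns = network nodes) and ``targets`` (one smoothed vector
    per gene set).
    """
    cfg = cfg or PropagationConfig()
    normalized = laplacian_normalize(network)
    profiles = {
        "mut": smooth_matrix(normalized, mutations, cfg),
        "de": smooth_matrix(normalized, diff_expression, cfg),
    }
    targets = {
        gs.name: propagate(normalized, build_prior(gs, normalized), cfg) for gs in gene_sets
    }
    return profiles, targets


def construct_features(
    network: WeightedNetwork,
    mutations: GeneMatrix,
    diff_expression: GeneMatrix,
    gene_sets: list[GeneSet],
    expression: GeneMatrix | None = None,
    signatures: dict[str, pd.Series] | None = None,
    clinical: ClinicalTable | None = None,
    prop_cfg: PropagationConfig | None = None,
    n_pca: int = 10,
) -> FeatureTable:
    """Build the full constructed feature table for a cohort."""
    profiles, targets = smooth_inputs(network, mutations, diff_expression, gene_sets, prop_cfg)
    lincs_pairs = None
    if signatures is not None and expression is not None:
        lincs_pairs = {drug: (expression.data, sig) for drug, sig in signatures.items()}
    clinical_encoded = encode_clinical(clinical) if clinical is not None else None
    return fc.assemble_features(
        profiles, targets, lincs_pairs=lincs_pairs, clinical=clinical_encoded, n_pca=n_pca
    )


def labels_from_records(
    records: list[TreatmentRecord], drug: str = ALL_AI, augment: bool | None = None
) -> LabelVector:
    """Labels for one task; ER-negative prior-knowledge augmentation is on
    by default for the pooled aromatase-inhibitor task and off per-drug."""
    labels = labeling.build_labels(records, drug=drug)
    if augment is None:
        augment = drug == ALL_AI
    if augment:
        labels = labeling.augment_er_negative(labels, records)
    return labels


def cross_validate_constructed(
    network: WeightedNetwork,
    mutations: GeneMatrix,
    diff_expression: GeneMatrix,
    gene_sets: list[GeneSet],
    labels: LabelVector,
    expression: GeneMatrix | None = None,
    signatures: dict[str, pd.Series] | None = None,
    clinical: ClinicalTable | None = None,
    model_spec: str = "logistic_l2",
    prop_cfg: PropagationConfig | None = None,
    n_pca: int = 10,
    pca_scope: str = "cohort",
    seed: int = 0,
) -> CvResult:
    """Leave-one-out cross-validation on the constructed features.

    ``pca_scope="cohort"`` (default) fits the PCA summaries once on the full
    cohort, mirroring a transductive analysis; ``"train_fold"`` re-fits the
    PCA inside each training fold and projects the held-out sample onto the
    fold's components, avoiding any test-sample leakage into the feature
    construction (slower; smoothing is per-sample and needs no re-fit).
    """
    if pca_scope not in ("cohort", "train_fold"):
        raise ValidationError("pca_scope must be 'cohort' or 'train_fold'")
    if pca_scope == "cohort":
        features = construct_features(
            network, mutations, diff_expression, gene_sets,
            expression=expression, signatures=signatures, clinical=clinical,
            prop_cfg=prop_cfg, n_pca=n_pca,
        )
        features = FeatureTable(
            features.data.reindex(labels.sample_ids), provenance=dict(features.provenance)
        )
        return prediction.loo_cross_validate(features, labels, model_spec=model_spec, seed=seed)
    return _loo_with_fold_pca(
        network, mutations, diff_expression, gene_sets, labels,
        expression=expression, signatures=signatures, clinical=clinical,
        model_spec=model_spec, prop_cfg=prop_cfg, n_pca=n_pca, seed=seed,
    )


def _loo_with_fold_pca(
    network, mutations, diff_expression, gene_sets, labels,
    expression=None, signatures=None, clinical=None,
    model_spec="logistic_l2", prop_cfg=None, n_pca=10, seed=0,
) -> CvResult:
    """Strict leave-one-out: PCA summaries are re-fit on each training fold.

    Smoothing is per-sample (each row diffuses independently), so the
    smoothed matrices can be computed once; only the PCA projection and the
    classifier are re-fit per fold.
    """
    from sklearn.decomposition import PCA

    profiles, targets = smooth_inputs(network, mutations, diff_expression, gene_sets, prop_cfg)
    combined = {
        (p_name, t_name): fc.min_combine(profile, target).data
        for p_name, profile in profiles.items()
        for t_name, target in targets.items()
    }
    static_blocks = []
    lincs_pairs = (
        {drug: (expression.data, sig) for drug, sig in signatures.items()}
        if signatures is not None and expression is not None
        else None
    )
    index = pd.Index(labels.sample_ids)
    # summaries, signature and clinical features involve no cross-sample fit
    for (p_name, t_name), matrix in combined.items():
        values = matrix.reindex(index).to_numpy(dtype=float)
        static_blocks.append(
            pd.DataFrame(
                {
                    f"min_sm_{p_name}_x_sm_{t_name}__mean": values.mean(axis=1),
                    f"min_sm_{p_name}_x_sm_{t_name}__sd": values.std(axis=1, ddof=0),
                },
                index=index,
            )
        )
    if lincs_pairs:
        for drug, (expr, sig) in lincs_pairs.items():
            corr = np.zeros(len(index))
            dot = np.zeros(len(index))
            for i, sample in enumerate(index):
                if sample in expr.index:
                    corr[i], dot[i] = fc.lincs_features(expr.loc[sample], sig)
            static_blocks.append(
                pd.DataFrame({f"lincs_{drug}__corr": corr, f"lincs_{drug}__dot": dot}, index=index)
            )
    if clinical is not None:
        static_blocks.append(encode_clinical(clinical).data.reindex(index, fill_value=0.0))
    static = pd.concat(static_blocks, axis=1)

    y = labels.labels.to_numpy(dtype=int)
    n = len(index)
    scores = np.empty(n)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        if len(np.unique(y[mask])) < 2:
            raise ValidationError(f"training fold for sample {index[i]!r} contains a single class")
        pca_blocks_train = []
        pca_blocks_test = []
        for (p_name, t_name), matrix in combined.items():
            values = matrix.reindex(index).to_numpy(dtype=float)
            pca = PCA(n_components=n_pca, svd_solver="full")
            pca_blocks_train.append(pca.fit_transform(values[mask]))
            pca_blocks_test.append(pca.transform(values[i : i + 1]))
        x_train = np.hstack([static.to_numpy(dtype=float)[mask], *pca_blocks_train])
        x_test = np.hstack([static.to_numpy(dtype=float)[i : i + 1], *pca_blocks_test])
        model = prediction.make_classifier(model_spec, seed=seed)
        model.fit(x_train, y[mask])
        scores[i] = model.predict_proba(x_test)[0, 1]
    score_series = pd.Series(scores, index=index)
    return CvResult(
        scores=score_series,
        fold_assignment=pd.Series(np.arange(n), index=index),
        auc=prediction.roc_auc(scores, y),
        model_spec=model_spec,
    )


def cross_validate_naive(
    mutations: GeneMatrix,
    diff_expression: GeneMatrix,
    labels: LabelVector,
    clinical: ClinicalTable | None = None,
    pca_k: int | None = None,
    model_spec: str = "logistic_l2",
    seed: int = 0,
) -> CvResult:
    """Leave-one-out cross-validation on the naive baseline feature set."""
    clinical_encoded = encode_clinical(clinical) if clinical is not None else None
    features = fc.naive_features(mutations, diff_expression, clinical=clinical_encoded, pca_k=pca_k)
    features = FeatureTable(
        features.data.reindex(labels.sample_ids), provenance=dict(features.provenance)
    )
    return prediction.loo_cross_validate(features, labels, model_spec=model_spec, seed=seed)


def run_synthetic_benchmark(
    cfg: SimConfig,
    model_spec: str = "logistic_l2",
    include_naive: bool = False,
    bundle: SimBundle | None = None,
) -> dict:
    """Generate a synthetic study and cross-validate constructed (and
    optionally naive) features on the pooled aromatase-inhibitor task.

    Returns a dict with the label vector, CV results and AUCs.
    """
    bundle = bundle or generate_bundle(cfg)
    labels = labels_from_records(bundle.records, drug=ALL_AI)
    constructed = cross_validate_constructed(
        bundle.network, bundle.mutations, bundle.diff_expression, bundle.gene_sets, labels,
        expression=bundle.expression, signatures=bundle.signatures, clinical=bundle.clinical,
        model_spec=model_spec, seed=cfg.seed,
    )
    out = {
        "bundle": bundle,
        "labels": labels,
        "constructed": constructed,
        "constructed_auc": constructed.auc,
    }
    if include_naive:
        naive = cross_validate_naive(
            bundle.mutations, bundle.diff_expression, labels,
            clinical=bundle.clinical, model_spec=model_spec, seed=cfg.seed,
        )
        out["naive"] = naive
        out["naive_auc"] = naive.auc
    return out
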