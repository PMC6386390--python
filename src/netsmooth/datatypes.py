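"""Core containers shared by the I/O, propagation, feature and prediction layers.

Sample-by-gene matrices are held as labeled :class:`pandas.DataFrame` objects
inside thin dataclasses that enforce the invariants the downstream algebra
relies on (finite values, unique labels, {0,1} entries for binary matrices).
The interaction network is a :class:`networkx.Graph` with a ``weight``
attribute per edge; its Laplacian-normalized form is a sparse matrix pinned to
an explicit node order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp

from .errors import ValidationError

BINARY = "binary"
CONTINUOUS = "continuous"

#: canonical aromatase-inhibitor drug names
AI_DRUGS = ("anastrozole", "exemestane", "letrozole")
ALL_AI = "ALL_AI"


def _check_unique(labels, what: str) -> None:
    if len(labels) != len(set(labels)):
        dupes = pd.Index(labels)[pd.Index(labels).duplicated()].unique().tolist()
        raise ValidationError(f"duplicate {what}: {dupes[:5]}")


@dataclass
class GeneMatrix:
    """Labeled sample x gene numeric matrix.

    ``dtype_flag`` is ``"binary"`` for mutation / differential-expression
    status matrices (entries restricted to {0,1}) and ``"continuous"`` for
    log-fold expression and network-smoothed matrices.
    """

    data: pd.DataFrame
    dtype_flag: str = CONTINUOUS

    def __post_init__(self):
        if self.dtype_flag not in (BINARY, CONTINUOUS):
            raise ValidationError(f"unknown dtype_flag {self.dtype_flag!r}")
        _check_unique(self.data.index, "sample ids")
        _check_unique(self.data.columns, "gene symbols")
        values = self.data.to_numpy(dtype=float)
        if not np.all(np.isfinite(values)):
            raise ValidationError("gene matrix contains non-finite values")
        if self.dtype_flag == BINARY and not np.isin(values, (0.0, 1.0)).all():
            bad = values[~np.isin(values, (0.0, 1.0))]
            raise ValidationError(f"binary matrix contains non-binary value {bad.flat[0]!r}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def gene_symbols(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


@dataclass
class GeneSet:
    """Named set of gene symbols (e.g. the protein targets of one drug)."""

    name: str
    genes: frozenset[str]

    def __post_init__(self):
        self.genes = frozenset(self.genes)
        if not self.name:
            raise ValidationError("gene set name must be non-empty")
        if not self.genes:
            raise ValidationError(f"gene set {self.name!r} is empty")
        if any(not g for g in self.genes):
            raise ValidationError(f"gene set {self.name!r} contains an empty symbol")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class ClinicalTable:
    """Per-sample categorical clinical variables; missing values allowed (NaN)."""

    data: pd.DataFrame  # samples x variables, object/category dtype

    def __post_init__(self):
        _check_unique(self.data.index, "sample ids")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def variables(self) -> list[str]:
        return list(self.data.columns)


@dataclass
class WeightedNetwork:
    """Undirected protein-interaction graph with positive confidence weights."""

    graph: nx.Graph

    def __post_init__(self):
        for u, v, w in self.graph.edges(data="weight"):
            if w is None or not np.isfinite(w) or w <= 0:
                raise ValidationError(f"edge ({u},{v}) has invalid weight {w!r}")
            if u == v:
                raise ValidationError(f"self-loop on node {u!r}")

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    def number_of_nodes(self) -> int:
        return self.graph.number_of_nodes()

    def number_of_edges(self) -> int:
        return self.graph.number_of_edges()


@dataclass
class NormalizedNetwork:
    """Laplacian-normalized weight matrix W' = D^-1/2 W D^-1/2 on a fixed node order."""

    nodes: tuple[str, ...]
    matrix: sp.csr_matrix  # symmetric, |V| x |V|

    def __post_init__(self):
        if self.matrix.shape != (len(self.nodes), len(self.nodes)):
            raise ValidationError("normalized matrix shape does not match node order")
        self._index = {n: i for i, n in enumerate(self.nodes)}

    def node_index(self, node: str) -> int:
        return self._index[node]

    def __len__(self) -> int:
        return len(self.nodes)


@dataclass
class PropagationConfig:
    """Parameters of the diffusion F(t) = alpha * W' F(t-1) + (1-alpha) * Y.

    ``alpha`` balances network smoothing against the prior (alpha=0 returns
    the prior unchanged); ``epsilon`` is the L2 tolerance on successive
    iterates; ``max_iter`` bounds the iteration count.
    """

    alpha: float = 0.5
    epsilon: float = 1e-6
    max_iter: int = 1000

    def __post_init__(self):
        if not 0.0 <= self.alpha < 1.0:
            raise ValidationError(f"alpha must be in [0,1), got {self.alpha}")
        if self.epsilon <= 0:
            raise ValidationError("epsilon must be positive")
        if self.max_iter < 1:
            raise ValidationError("max_iter must be a positive integer")


@dataclass
class PriorVector:
    """Per-node vector on a network's node order; a binary prior or its smoothed form."""

    nodes: tuple[str, ...]
    values: np.ndarray
    n_excluded: int = 0  # gene-set members absent from the network
    n_iter: int = 0      # iterations used when this is a propagation result

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.nodes),):
            raise ValidationError("prior length does not match node order")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("prior contains non-finite values")

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=list(self.nodes))


@dataclass
class FeatureTable:
    """Sample x feature matrix with a provenance tag per feature column."""

    data: pd.DataFrame
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        _check_unique(self.data.index, "sample ids")
        _check_unique(self.data.columns, "feature names")
        if len(self.data.columns) and not np.all(np.isfinite(self.data.to_numpy(dtype=float))):
            raise ValidationError("feature table contains non-finite values")
        for name in self.data.columns:
            self.provenance.setdefault(name, "unspecified")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def feature_names(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


@dataclass
class PcaModel:
    """Fitted PCA: orthonormal gene loadings, variance shares and centering vector."""

    components: np.ndarray        # k x genes
    explained_variance_ratio: np.ndarray
    mean: np.ndarray              # gene-wise centering vector
    gene_symbols: list[str]


@dataclass
class LabelVector:
    """Binary non-response labels (1 = non-responder) with a per-sample source tag."""

    data: pd.DataFrame  # index: sample_ids; columns: label (int 0/1), source (str)

    SOURCES = ("observed", "er_negative_prior")

    def __post_init__(self):
        _check_unique(self.data.index, "sample ids")
        if not set(self.data.columns) >= {"label", "source"}:
            raise ValidationError("label table requires 'label' and 'source' columns")
        if not self.data["label"].isin([0, 1]).all():
            raise ValidationError("labels must be 0/1")
        if not self.data["source"].isin(self.SOURCES).all():
            raise ValidationError(f"label source must be one of {self.SOURCES}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def labels(self) -> pd.Series:
        return self.data["label"]


@dataclass
class TreatmentRecord:
    """One (patient, drug) treatment episode from the clinical record."""

    patient_id: str
    drug: str  # canonical: anastrozole / exemestane / letrozole / other
    discontinued_for_nonresponse: bool
    died_during_treatment: bool
    er_status: str  # positive / negative / unknown

    def __post_init__(self):
        if not self.patient_id:
            raise ValidationError("patient_id must be non-empty")
        if self.er_status not in ("positive", "negative", "unknown"):
            raise ValidationError(f"invalid er_status {self.er_status!r}")


@dataclass
class CvResult:
    """Out-of-fold scores from cross-validation plus summary AUC."""

    scores: pd.Series            # per-sample predicted probability of non-response
    fold_assignment: pd.Series   # fold index per sample
    auc: float
    importances: pd.Series | None = None
    model_spec: str = ""


@dataclass
class CombinationWeight:
    """Convex weight gamma blending cell-line and patient classifier outputs."""

    gamma: float
    auc_trace: pd.Series  # holdout AUC per candidate gamma

    def __post_init__(self):
        if not 0.0 <= self.gamma <= 1.0:
            raise ValidationError("gamma must lie in [0,1]")


@dataclass
class GrowthExperiment:
    """Replicate cell counts for one cell line under one estradiol condition."""

    cell_line: str
    condition: str  # "E2" or "noE2"
    day0_counts: np.ndarray
    day5_counts: np.ndarray
    er_status: str = "unknown"

    def __post_init__(self):
        self.day0_counts = np.asarray(self.day0_counts, dtype=float)
        self.day5_counts = np.asarray(self.day5_counts, dtype=float)
        if self.condition not in ("E2", "noE2"):
            raise ValidationError(f"condition must be E2/noE2, got {self.condition!r}")
        if self.day0_counts.size == 0 or self.day5_counts.size == 0:
            raise ValidationError("at least one replicate per condition is required")
        if self.day0_counts.size != self.day5_counts.size:
            raise ValidationError("day0/day5 replicate counts must pair up")
        if np.any(self.day0_counts <= 0) or np.any(self.day5_counts <= 0):
            raise ValidationError("cell counts must be positive")
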