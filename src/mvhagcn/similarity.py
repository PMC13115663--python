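"""The similarity views feeding the heterogeneous network.

miRNA views: sequence (Levenshtein), family (co-membership), Gaussian
interaction-profile kernel, lncRNA interaction-profile edit similarity, and
a loaded functional-similarity matrix. Disease views: MeSH-DAG semantic
similarity (structural + specificity-weighted, averaged), GIP kernel, and
lncRNA-profile edit similarity.
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib
import networkx as nx
import numpy as np

from .data_io import (
    AssociationMatrix,
    ContractError,
    DiseaseDAGSet,
    SimilarityMatrix,
)

__all__ = [
    "SemanticConfig",
    "GipConfig",
    "sequence_similarity",
    "family_similarity",
    "semantic_contribution",
    "disease_semantic_similarity",
    "gip_kernel",
    "profile_edit_similarity",
]


@dataclass(frozen=True)
class SemanticConfig:
    """decay_mu: multiplicative decay applied per hierarchy level when a
    term's semantic influence is propagated up the DAG (dimensionless,
    in (0,1)); the specificity weight uses the natural logarithm."""

    decay_mu: float = 0.5

    def __post_init__(self):
        if not 0.0 < self.decay_mu < 1.0:
            raise ContractError("decay_mu must lie in (0, 1)")


@dataclass(frozen=True)
class GipConfig:
    """lambda_prime: dimensionless scale of the GIP bandwidth; the effective
    bandwidth is lambda_prime divided by the mean squared profile norm."""

    lambda_prime: float = 1.0

    def __post_init__(self):
        if self.lambda_prime <= 0:
            raise ContractError("lambda_prime must be positive")


def _finalize(values: np.ndarray, ids, view_name: str) -> SimilarityMatrix:
    values = (values + values.T) / 2.0
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(np.clip(values, 0.0, 1.0), tuple(ids), view_name)


def _edit_distance(a: str, b: str) -> int:
    return edlib.align(a, b, task="distance")["editDistance"]


def sequence_similarity(sequences: dict[str, str]) -> SimilarityMatrix:
    """Levenshtein-based similarity: 1 - dist(i, j) / max(len_i, len_j)."""
    ids = list(sequences)
    for m, s in sequences.items():
        if not s:
            raise ContractError(f"empty sequence for {m!r}")
    n = len(ids)
    values = np.ones((n, n), dtype=np.float64)
    for i in range(n):
        for j in range(i + 1, n):
            a, b = sequences[ids[i]], sequences[ids[j]]
            d = _edit_distance(a, b)
            values[i, j] = values[j, i] = 1.0 - d / max(len(a), len(b))
    return _finalize(values, ids, "sequence")


def family_similarity(families: dict[str, str | None], ids) -> SimilarityMatrix:
    """1 iff both miRNAs carry the same family label; unannotated miRNAs
    match nothing off-diagonal; the diagonal is 1 by convention."""
    ids = [str(i) for i in ids]
    labels = [families.get(i) for i in ids]
    n = len(ids)
    values = np.zeros((n, n), dtype=np.float64)
    for i in range(n):
        for j in range(n):
            if labels[i] is not None and labels[i] == labels[j]:
                values[i, j] = 1.0
    return _finalize(values, ids, "family")


def semantic_contribution(
    dag: nx.DiGraph,
    target_disease: str,
    scheme: int,
    semantic_config: SemanticConfig,
    term_frequency: dict[str, int],
    n_diseases: int | None = None,
) -> dict[str, float]:
    """Per-term semantic contribution to `target_disease` within its DAG.

    Scheme 1 decays geometrically from the disease term: the disease itself
    contributes 1 and each ancestor contributes mu times the best of its
    children (a reverse topological sweep over the child->parent edges).
    Scheme 2 weighs a term by its specificity, -ln(countDAGs(t)/Ndiseases),
    independent of its position in the DAG.
    """
    if scheme not in (1, 2):
        raise ContractError(f"unknown scheme {scheme!r}")
    terms = set(dag.nodes) | {target_disease}
    if scheme == 2:
        if n_diseases is None:
            raise ContractError("scheme 2 requires the total disease count")
        out = {}
        for t in terms:
            freq = term_frequency.get(t, 0)
            if freq < 1:
                raise ContractError(f"term {t!r} has frequency 0")
            out[t] = -np.log(freq / n_diseases)
        return out
    mu = semantic_config.decay_mu
    contrib = {target_disease: 1.0}
    # child -> parent edges: topological order visits children before parents
    for t in nx.topological_sort(dag):
        if t == target_disease:
            continue
        children = list(dag.predecessors(t))
        vals = [mu * contrib[c] for c in children if c in contrib]
        contrib[t] = max(vals) if vals else 0.0
    for t in terms:
        contrib.setdefault(t, 0.0)
    return contrib


def disease_semantic_similarity(
    dag_set: DiseaseDAGSet, semantic_config: SemanticConfig | None = None
) -> SimilarityMatrix:
    """Average of the structural and specificity-weighted DAG similarities.

    For each pair, the shared-ancestor contributions are summed and divided
    by the diseases' total semantic values; diseases with empty DAGs get 0
    to all others and 1 to themselves.
    """
    cfg = semantic_config or SemanticConfig()
    diseases = list(dag_set.graphs)
    n = len(diseases)
    contrib1: dict[str, dict[str, float]] = {}
    contrib2: dict[str, dict[str, float]] = {}
    ancestors: dict[str, set[str]] = {}
    for d in diseases:
        g = dag_set.graphs[d]
        if g.number_of_nodes() == 0:
            ancestors[d] = set()
            continue
        ancestors[d] = dag_set.ancestors(d)
        contrib1[d] = semantic_contribution(g, d, 1, cfg, dag_set.term_frequency)
        contrib2[d] = semantic_contribution(
            g, d, 2, cfg, dag_set.term_frequency, n_diseases=n
        )
    values = np.zeros((n, n), dtype=np.float64)
    for i, di in enumerate(diseases):
        for j in range(i, n):
            dj = diseases[j]
            if i == j:
                values[i, j] = 1.0
                continue
            shared = ancestors[di] & ancestors[dj]
            if not shared:
                continue
            # V sums run over A(D): the disease term plus its ancestors
            v1 = sum(contrib1[di][t] for t in ancestors[di]) + sum(
                contrib1[dj][t] for t in ancestors[dj]
            )
            v2 = sum(contrib2[di][t] for t in ancestors[di]) + sum(
                contrib2[dj][t] for t in ancestors[dj]
            )
            s1 = (
                sum(contrib1[di][t] + contrib1[dj][t] for t in shared) / v1
                if v1 > 0
                else 0.0
            )
            s2 = (
                sum(contrib2[di][t] + contrib2[dj][t] for t in shared) / v2
                if v2 > 0
                else 0.0
            )
            values[i, j] = values[j, i] = (s1 + s2) / 2.0
    return _finalize(values, diseases, "semantic")


def gip_kernel(
    A: AssociationMatrix, axis: str, gip_config: GipConfig | None = None
) -> SimilarityMatrix:
    """Gaussian interaction-profile kernel over rows (miRNAs) or columns
    (diseases) of the association matrix.

    K(i, j) = exp(-lambda * ||P_i - P_j||^2), with the bandwidth lambda set
    to lambda_prime divided by the mean squared profile norm.
    """
    cfg = gip_config or GipConfig()
    if axis == "mirna":
        profiles = A.values
        ids = A.index.mirna_ids
    elif axis == "disease":
        profiles = A.values.T
        ids = A.index.disease_ids
    else:
        raise ContractError(f"axis must be 'mirna' or 'disease', got {axis!r}")
    sq_norms = (profiles**2).sum(axis=1)
    mean_sq = sq_norms.mean()
    if mean_sq <= 0:
        raise ContractError("all profiles are zero; GIP bandwidth is undefined")
    lam = cfg.lambda_prime / mean_sq
    # ||Pi - Pj||^2 via the Gram matrix
    gram = profiles @ profiles.T
    d2 = sq_norms[:, None] + sq_norms[None, :] - 2.0 * gram
    np.maximum(d2, 0.0, out=d2)
    values = np.exp(-lam * d2)
    return _finalize(values, ids, f"gip_{axis}")


def profile_edit_similarity(
    interaction_matrix: np.ndarray, ids, view_name: str = "lncrna"
) -> SimilarityMatrix:
    """Edit-distance similarity between binary interaction profiles.

    Each row of the (entity x lncRNA) matrix is rendered as a 0/1 string and
    compared by Levenshtein distance normalized by the profile length.
    """
    mat = np.asarray(interaction_matrix)
    if mat.ndim != 2 or mat.shape[1] == 0:
        raise ContractError("interaction matrix must have at least one column")
    if not np.isin(mat, (0, 1)).all():
        raise ContractError("interaction matrix must be binary")
    ids = [str(i) for i in ids]
    if len(ids) != mat.shape[0]:
        raise ContractError("row count does not match ids")
    L = mat.shape[1]
    rows = ["".join("1" if x else "0" for x in row) for row in mat.astype(int)]
    n = len(rows)
    values = np.ones((n, n), dtype=np.float64)
    for i in range(n):
        for j in range(i + 1, n):
            d = _edit_distance(rows[i], rows[j])
            values[i, j] = values[j, i] = 1.0 - d / L
    return _finalize(values, ids, view_name)
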