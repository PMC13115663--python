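"""Heterogeneous-network construction.

Fuses the per-view similarity matrices into one integrated miRNA matrix and
one integrated disease matrix, assembles the block adjacency
[[Mm, A], [A^T, Md]], and derives initial node features by random walk with
restart on that network.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._tensor import Tensor
from .data_io import AssociationMatrix, ContractError, EntityIndex, SimilarityMatrix

__all__ = [
    "MIRNA_VIEW_ORDER",
    "DISEASE_VIEW_ORDER",
    "FusionWeights",
    "HeterogeneousAdjacency",
    "RwrConfig",
    "fuse_views",
    "build_adjacency",
    "rwr_features",
]

# canonical ordering of the learnable view weights
MIRNA_VIEW_ORDER = ("functional", "gip", "lncrna", "sequence", "family")
DISEASE_VIEW_ORDER = ("semantic", "gip", "lncrna")


def _softmax(x: np.ndarray) -> np.ndarray:
    z = np.exp(x - x.max())
    return z / z.sum()


@dataclass
class FusionWeights:
    """Learnable view- and layer-mixing weights.

    Raw values are unconstrained; each group (five miRNA views, three
    disease views, two GCN layers) is mapped through its own softmax, so the
    effective weights are nonnegative and sum to one — the "contribution"
    reading of the adaptive fusion. Raw zeros give uniform initial weights.
    """

    alpha_raw: Tensor = field(
        default_factory=lambda: Tensor(np.zeros(5), requires_grad=True)
    )
    beta_raw: Tensor = field(
        default_factory=lambda: Tensor(np.zeros(3), requires_grad=True)
    )
    gamma_raw: Tensor = field(
        default_factory=lambda: Tensor(np.zeros(2), requires_grad=True)
    )

    @property
    def alpha(self) -> np.ndarray:
        return _softmax(self.alpha_raw.data)

    @property
    def beta(self) -> np.ndarray:
        return _softmax(self.beta_raw.data)

    @property
    def gamma(self) -> np.ndarray:
        return _softmax(self.gamma_raw.data)

    def parameters(self) -> list[Tensor]:
        return [self.alpha_raw, self.beta_raw, self.gamma_raw]


def fuse_views(matrices: list[SimilarityMatrix], group_weights) -> SimilarityMatrix:
    """Convex (softmax-weighted) combination of same-id similarity views."""
    if not matrices:
        raise ContractError("no views to fuse")
    weights = np.asarray(group_weights, dtype=np.float64)
    if weights.shape != (len(matrices),):
        raise ContractError(
            f"{len(matrices)} views but {weights.shape} weights supplied"
        )
    ids = matrices[0].ids
    for m in matrices[1:]:
        if m.ids != ids:
            raise ContractError(
                f"view {m.view_name!r} ids do not match {matrices[0].view_name!r}"
            )
    values = np.zeros_like(matrices[0].values)
    for w, m in zip(weights, matrices):
        values += w * m.values
    return SimilarityMatrix(np.clip(values, 0.0, 1.0), ids, "fused")


@dataclass
class HeterogeneousAdjacency:
    """(Nm+Nd)^2 block adjacency of the heterogeneous network, miRNAs first."""

    values: np.ndarray
    index: EntityIndex

    @property
    def n_nodes(self) -> int:
        return self.index.n_mirna + self.index.n_disease

    def blocks(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return (Mm, Md, A) recovered from the block layout."""
        nm = self.index.n_mirna
        return (
            self.values[:nm, :nm],
            self.values[nm:, nm:],
            self.values[:nm, nm:],
        )


def build_adjacency(
    Mm: SimilarityMatrix, Md: SimilarityMatrix, A: AssociationMatrix
) -> HeterogeneousAdjacency:
    """Assemble [[Mm, A], [A^T, Md]] on the shared entity index."""
    nm, nd = A.index.n_mirna, A.index.n_disease
    if Mm.values.shape != (nm, nm) or Md.values.shape != (nd, nd):
        raise ContractError("similarity block dimensions do not match the index")
    if Mm.ids != A.index.mirna_ids or Md.ids != A.index.disease_ids:
        raise ContractError("similarity block ids do not match the index")
    n = nm + nd
    M = np.zeros((n, n), dtype=np.float64)
    M[:nm, :nm] = Mm.values
    M[nm:, nm:] = Md.values
    M[:nm, nm:] = A.values
    M[nm:, :nm] = A.values.T
    return HeterogeneousAdjacency(M, A.index)


@dataclass(frozen=True)
class RwrConfig:
    """restart_r: probability of jumping back to the seed node at each step;
    tol: Frobenius-norm convergence threshold; max_iter: iteration cap."""

    restart_r: float = 0.5
    tol: float = 1e-6
    max_iter: int = 1000

    def __post_init__(self):
        if not 0.0 < self.restart_r <= 1.0:
            raise ContractError("restart_r must lie in (0, 1]")
        if self.tol <= 0:
            raise ContractError("tol must be positive")


def rwr_features(
    M: HeterogeneousAdjacency | np.ndarray, rwr_config: RwrConfig | None = None
) -> np.ndarray:
    """Random-walk-with-restart initial features.

    Runs all seeds simultaneously: D(k) = (1-r) An D(k-1) + r I with An the
    column-normalized adjacency, until the Frobenius difference between
    successive iterates is at most tol. Column t is the converged
    distribution for node t (each column sums to 1). Isolated nodes receive
    a self-loop before normalization.
    """
    cfg = rwr_config or RwrConfig()
    values = M.values if isinstance(M, HeterogeneousAdjacency) else np.asarray(M)
    if (values < 0).any():
        raise ContractError("adjacency must be nonnegative")
    W = np.array(values, dtype=np.float64)
    col_sums = W.sum(axis=0)
    for i in np.where(col_sums == 0)[0]:
        W[i, i] = 1.0
        col_sums[i] = 1.0
    An = W / col_sums[None, :]
    n = W.shape[0]
    r = cfg.restart_r
    D0 = np.eye(n)
    D = D0.copy()
    for _ in range(cfg.max_iter):
        D_next = (1.0 - r) * (An @ D) + r * D0
        resid = np.linalg.norm(D_next - D)
        D = D_next
        if resid <= cfg.tol:
            return D
    raise RuntimeError(
        f"RWR did not converge within {cfg.max_iter} iterations "
        f"(last residual {resid:.3e})"
    )
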